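import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cnvnet.cnv_gene_mapping import (
    CnvRecord,
    Dosage,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from cnvnet.synthetic_data import SimulationConfig, make_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: reduced-scale study: same gene density (one gene per 400 kb) and
#: annotation rate (~24%) as the full-scale defaults, ~5x smaller
SMALL_SCALE = dict(
    n_genes=600,
    n_chromosomes=3,
    genome_length=240_000_000,
    total_genes=5200,
    universe_size=1270,
    focal_term_size=88,
    n_other_terms=30,
    other_term_size_range=(5, 120),
    n_case_large_gains=20,
    n_case_large_losses=8,
    n_case_small_cnvs=20,
    n_control_cnvs=300,
    n_expression_genes=200,
    n_samples=80,
    module_size=15,
    n_modules=2,
)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    params = {**SMALL_SCALE, **overrides}
    return SimulationConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(small_config(seed=11))


def gene(gene_id, chrom, start, end, cds=None, extra_tx=()):
    """Single-exon, single-transcript gene helper for hand-built fixtures."""
    exon = GenomicInterval(chrom, start, end)
    coding = (GenomicInterval(chrom, *cds),) if cds else ()
    txs = (TranscriptModel(f"{gene_id}.t1", (exon,), coding),) + tuple(extra_tx)
    return GeneModel(gene_id, txs)


def cnv(chrom, start, end, dosage=Dosage.GAIN, subject="s1", cohort="c1"):
    return CnvRecord(subject, cohort, GenomicInterval(chrom, start, end), dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
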