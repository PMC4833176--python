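"""End-to-end drivers tying the pipeline stages together.

These are the composition points used by the CLI, the test-bench
experiments, and downstream scripts: CNV table -> filtered gain/loss gene
sets -> enrichment over the behavioural terms, and expression matrix ->
thresholded network -> planted-module cohesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnv_gene_mapping import (
    Dosage,
    assign_genes,
    filter_control_genes,
    filter_large_cnvs,
    gene_sets_by_dosage,
)
from .coexpression_network import correlation_edges, filter_expressed, threshold_network
from .connectivity_tests import GeneSet, cohesion_test
from .enrichment import EnrichmentResult, fold_enrichment, run_enrichment
from .phenotype_annotation import select_test_terms
from .synthetic_data import BEHAVIOURAL_TERM, FOCAL_TERM, SimulationConfig, SyntheticDataset, make_dataset


@dataclass(frozen=True)
class GainEnrichmentOutcome:
    """Summary of one cohort's gain-gene enrichment run."""

    n_gain_genes: int
    n_analyzable: int
    results: list[EnrichmentResult]
    focal_result: EnrichmentResult | None

    @property
    def focal_is_top(self) -> bool:
        return bool(self.results) and self.results[0].term_id == FOCAL_TERM

    @property
    def focal_fold(self) -> float:
        return self.focal_result.fold if self.focal_result else float("nan")


def gain_gene_enrichment(
    ds: SyntheticDataset, fdr_method: str = "storey", alpha_fdr: float = 0.05
) -> GainEnrichmentOutcome:
    """Run the full CNV -> gene -> enrichment pipeline on a synthetic cohort.

    Case CNVs are length-filtered (strictly > the configured cutoff), genes
    are assigned under the gain/loss rules, control-cohort genes changed in
    the same direction are removed, and the surviving gain-genes are tested
    against every behavioural term of the synthetic ontology.
    """
    cfg = ds.config
    case = filter_large_cnvs(ds.case_cnvs, cfg.min_cnv_length)
    sets = gene_sets_by_dosage(assign_genes(case, ds.genes))
    sets = filter_control_genes(sets, ds.control_cnvs, ds.genes)
    gain_genes = sets[Dosage.GAIN]
    terms = select_test_terms(ds.universe, ds.ontology, BEHAVIOURAL_TERM, min_genes=1)
    results = run_enrichment(
        gain_genes, ds.universe, terms, alpha_fdr=alpha_fdr, method=fdr_method
    )
    focal = next((r for r in results if r.term_id == FOCAL_TERM), None)
    return GainEnrichmentOutcome(
        n_gain_genes=len(gain_genes),
        n_analyzable=results[0].counts.n if results else 0,
        results=results,
        focal_result=focal,
    )


def planted_module_cohesion(
    ds: SyntheticDataset,
    n_perm: int = 10_000,
    seed: int | None = None,
    r_threshold: float = 0.7,
):
    """Expression -> network -> cohesion test of the first planted module,
    against a background of every gene surviving the expression filter."""
    expr = filter_expressed(ds.expression)
    net = threshold_network(correlation_edges(expr), "absolute_r", r_threshold)
    module = ds.truth["modules"][0]
    candidates = GeneSet("planted_module", frozenset(module))
    background = GeneSet("expressed_genes", frozenset(expr.index))
    return cohesion_test(
        net, candidates, background,
        n_perm=n_perm, seed=ds.config.seed if seed is None else seed,
    )


def connectivity_null_calibration(
    seed: int,
    n_genes: int = 2000,
    n_modules: int = 40,
    module_size: int = 25,
    set_size: int = 20,
    n_replicates: int = 200,
    n_perm: int = 1000,
) -> np.ndarray:
    """Null p-values of the cohesion test under uniform candidate draws.

    Builds one synthetic co-expression network (many planted modules so the
    statistic is continuous over the background), then repeatedly draws
    candidate sets uniformly from the module genes and records the cohesion
    test's empirical p.  Under this exchangeable null the p-values should be
    uniform on the permutation grid.
    """
    from .synthetic_data import SimulationConfig, make_expression

    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        seed=seed,
        n_samples=120,
        n_expression_genes=n_genes,
        n_modules=n_modules,
        module_size=module_size,
    )
    modules = [
        [f"M{m:02d}_{i:03d}" for i in range(module_size)] for m in range(n_modules)
    ]
    n_bg = n_genes - n_modules * module_size
    background_genes = [f"B{i:04d}" for i in range(n_bg)]
    expr = make_expression(cfg, modules, rng, background_genes=background_genes)
    net = threshold_network(correlation_edges(filter_expressed(expr)), "absolute_r", 0.7)

    pool = sorted(g for mod in modules for g in mod)
    background = GeneSet("module_genes", frozenset(pool))
    ps = np.empty(n_replicates)
    for rep in range(n_replicates):
        cand = frozenset(rng.choice(pool, size=set_size, replace=False))
        res = cohesion_test(
            net, GeneSet("draw", cand), background,
            n_perm=n_perm, seed=int(rng.integers(2**31)),
        )
        ps[rep] = res.p_emp
    return ps


def recovery_experiment(
    base: SimulationConfig, seeds: list[int]
) -> dict[str, list]:
    """Regenerate the cohort under each seed and record enrichment recovery."""
    folds, top_flags, n_values = [], [], []
    for s in seeds:
        cfg = SimulationConfig(**{**base.__dict__, "seed": int(s)})
        outcome = gain_gene_enrichment(make_dataset(cfg))
        folds.append(outcome.focal_fold)
        top_flags.append(outcome.focal_is_top)
        n_values.append(outcome.n_analyzable)
    return {"folds": folds, "focal_is_top": top_flags, "n_analyzable": n_values}
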