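"""Per-term hypergeometric enrichment with FDR control.

For a query gene set of size ``n`` (after intersection with the annotated
universe of size ``N``), a term with ``K`` universe genes, and ``k`` query
genes in the term set, the test statistic is the upper-tail hypergeometric
probability P(X >= k), and fold enrichment is the ratio of proportions
(k/n) / (K/N).  Multiple testing is controlled either with Storey's q-value
(pi0 estimated by the smoother method) or with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import NoAnalyzableGenesError
from .phenotype_annotation import AnnotatedUniverse

logger = logging.getLogger(__name__)

FDR_METHODS = ("storey", "bh")


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts of a 2x2 gene-set overlap: k of n query genes hit a term set of
    size K inside a universe of size N."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"require 0 <= k <= min(n, K), got {self}")
        if not (self.k <= self.n <= self.N and self.K <= self.N):
            raise ValueError(f"inconsistent counts {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    counts: EnrichmentInput
    fold: float
    p_value: float
    q_value: float
    significant: bool


def round_to_sigfigs(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` significant figures (report-layer convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (ndigits - 1))


def fold_enrichment(inp: EnrichmentInput) -> float:
    """Observed proportion over background proportion, (k/n) / (K/N)."""
    if inp.n == 0 or inp.K == 0:
        raise ValueError("fold enrichment undefined for n = 0 or K = 0")
    return (inp.k / inp.n) / (inp.K / inp.N)


def hypergeom_upper_p(inp: EnrichmentInput) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Delegates to the survival function, which sums the exact pmf in log
    space and is stable for large N; k = 0 returns exactly 1.
    """
    if inp.k == 0:
        return 1.0
    return float(hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n))


def _storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with the smoother (cubic fit) pi0 estimate."""
    m = p.size
    lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    # cubic smoother through pi0(lambda), evaluated at the largest lambda
    coeffs = np.polyfit(lambdas, pi0_lambda, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fdr_adjust(p_values: Sequence[float], method: str = "storey") -> list[float]:
    """FDR-adjusted values in input order.

    ``storey`` estimates the null proportion pi0 and is the default;
    ``bh`` is the Benjamini-Hochberg step-up (equivalent to pi0 = 1).
    Storey's smoother is unstable for small families, so a warning is
    emitted below 100 tests.
    """
    if method not in FDR_METHODS:
        raise ValueError(f"unknown FDR method {method!r}; expected one of {FDR_METHODS}")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1].tolist()
    if p.size < 100:
        warnings.warn(
            f"Storey pi0 estimate is unstable for {p.size} < 100 tests; "
            "consider method='bh'",
            stacklevel=2,
        )
    return _storey_qvalues(p).tolist()


def run_enrichment(
    genes: Iterable[str],
    universe: AnnotatedUniverse,
    terms: Sequence[str],
    alpha_fdr: float = 0.05,
    method: str = "storey",
) -> list[EnrichmentResult]:
    """Test each term for over-representation in ``genes``.

    ``genes`` is deduplicated and intersected with the universe first, so
    ``n`` counts distinct analyzable genes.  Results come back sorted by
    (p, term_id); ``significant`` flags q < ``alpha_fdr``.
    """
    analyzable = frozenset(genes) & universe.genes
    n = len(analyzable)
    if n == 0:
        raise NoAnalyzableGenesError(
            "no analyzable genes: query does not intersect the annotated universe"
        )
    N = universe.size
    inputs = []
    for term in terms:
        term_set = universe.term_gene_sets.get(term, frozenset())
        K = len(term_set)
        k = len(analyzable & term_set)
        inputs.append(EnrichmentInput(k=k, n=n, K=K, N=N))
    p_values = [hypergeom_upper_p(inp) for inp in inputs]
    q_values = fdr_adjust(p_values, method=method)
    results = [
        EnrichmentResult(
            term_id=term,
            counts=inp,
            fold=fold_enrichment(inp) if inp.K > 0 else float("nan"),
            p_value=p,
            q_value=q,
            significant=q < alpha_fdr,
        )
        for term, inp, p, q in zip(terms, inputs, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_table(results: Sequence[EnrichmentResult], names: dict[str, str] | None = None):
    """Flatten results for TSV export; fold is rounded to 2 significant
    figures here (full precision lives on the result objects)."""
    import pandas as pd

    names = names or {}
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "name": [names.get(r.term_id, "") for r in results],
            "k": [r.counts.k for r in results],
            "n": [r.counts.n for r in results],
            "K": [r.counts.K for r in results],
            "N": [r.counts.N for r in results],
            "fold": [round_to_sigfigs(r.fold) for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
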