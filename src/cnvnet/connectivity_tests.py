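"""Permutation tests for gene-set connectivity in a co-expression network.

Three tests share one machinery.  The statistic is always a sum of retained
edge weights: within a set (cohesion), or between two disjoint sets.  The
null is built by redrawing the candidate set uniformly without replacement
from a declared background, and the empirical p-value is (k + 1)/(n + 1)
where k counts permutations whose statistic is greater than *or equal to*
the observed one — with 100,000 permutations the smallest attainable p is
1/100,001.

Genes named in a set but absent from the network are deliberately retained:
they contribute zero weight, both to the observed statistic and to every
permutation draw, mirroring an analysis where only part of a candidate set
participates in the expressed network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .coexpression_network import CoexpressionNetwork

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000
_CHUNK = 4_096


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """One gene id per line; blank lines and '#' comments ignored."""
        lines = Path(path).read_text().splitlines()
        members = frozenset(
            ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")
        )
        return cls(name=name or Path(path).stem, members=members)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(sorted(self.members)) + "\n")


@dataclass(frozen=True)
class ConnectivityResult:
    observed: float
    n_perm: int
    k_ge: int
    p_emp: float
    seed: int | None = None
    set_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.k_ge <= self.n_perm:
            raise ValueError("k_ge out of range")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "observed": self.observed,
                    "n_perm": self.n_perm,
                    "k_ge": self.k_ge,
                    "p_emp": self.p_emp,
                    "seed": self.seed,
                    "set_sizes": self.set_sizes,
                },
                indent=2,
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# statistics


def within_set_weight(net: CoexpressionNetwork, s: GeneSet) -> float:
    """Sum of retained edge weights with both endpoints in ``s``."""
    present = s.members & net.nodes
    return float(net.graph.subgraph(present).size(weight="weight"))


def between_set_weight(net: CoexpressionNetwork, a: GeneSet, b: GeneSet) -> float:
    """Sum of retained edge weights with one endpoint in each set.

    The sets must be disjoint; shared genes have to be removed explicitly
    before testing so the exclusion bookkeeping stays visible to the caller.
    """
    shared = a.members & b.members
    if shared:
        raise ValueError(
            f"gene sets {a.name!r} and {b.name!r} share {len(shared)} gene(s); "
            "remove shared genes from both sets before testing"
        )
    a_present = a.members & net.nodes
    b_present = b.members & net.nodes
    total = 0.0
    for gene in a_present:
        for nbr, data in net.graph.adj[gene].items():
            if nbr in b_present:
                total += data["weight"]
    return float(total)


def empirical_p(observed: float, null_stats: Sequence[float]) -> ConnectivityResult:
    """(k + 1)/(n + 1) with k = #{null >= observed}; ties count toward k."""
    null = np.asarray(null_stats, dtype=float)
    if null.size == 0:
        raise ValueError("null_stats must be non-empty")
    k = int((null >= observed).sum())
    n = int(null.size)
    return ConnectivityResult(
        observed=float(observed), n_perm=n, k_ge=k, p_emp=(k + 1) / (n + 1)
    )


# ---------------------------------------------------------------------------
# permutation machinery


def _weight_matrix(net: CoexpressionNetwork, genes: Sequence[str]) -> np.ndarray:
    """Dense symmetric weight matrix over ``genes``; absent genes are zero."""
    index = {g: i for i, g in enumerate(genes)}
    w = np.zeros((len(genes), len(genes)))
    for a, b, weight in net.graph.edges(data="weight"):
        ia, ib = index.get(a), index.get(b)
        if ia is not None and ib is not None:
            w[ia, ib] = weight
            w[ib, ia] = weight
    return w


def _weight_to_target(
    net: CoexpressionNetwork, genes: Sequence[str], target: frozenset[str]
) -> np.ndarray:
    """Per-gene sum of edge weights into ``target``."""
    out = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in net.nodes:
            out[i] = sum(
                data["weight"] for nbr, data in net.graph.adj[g].items() if nbr in target
            )
    return out


def _random_subsets(rng: np.random.Generator, n_draws: int, pool: int, size: int) -> np.ndarray:
    """(n_draws, size) indices: uniform subsets without replacement."""
    keys = rng.random((n_draws, pool))
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def _null_within(
    w: np.ndarray, rng: np.random.Generator, n_perm: int, size: int
) -> np.ndarray:
    stats = np.empty(n_perm)
    pool = w.shape[0]
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        idx = _random_subsets(rng, m, pool, size)
        sub = w[idx[:, :, None], idx[:, None, :]]
        stats[done : done + m] = sub.sum(axis=(1, 2)) / 2.0
        done += m
    return stats


def _null_between(
    wvec: np.ndarray, rng: np.random.Generator, n_perm: int, size: int
) -> np.ndarray:
    stats = np.empty(n_perm)
    pool = wvec.shape[0]
    done = 0
    while done < n_perm:
        m = min(8 * _CHUNK, n_perm - done)
        idx = _random_subsets(rng, m, pool, size)
        stats[done : done + m] = wvec[idx].sum(axis=1)
        done += m
    return stats


# ---------------------------------------------------------------------------
# tests


def cohesion_test(
    net: CoexpressionNetwork,
    candidates: GeneSet,
    background: GeneSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ConnectivityResult:
    """Are the candidates more interconnected than random same-size draws
    from the background?"""
    if not candidates.members <= background.members:
        raise ValueError("candidates must be a subset of the background")
    if len(background) <= len(candidates):
        raise ValueError("background must be strictly larger than the candidate set")
    rng = np.random.default_rng(seed)
    bg = sorted(background.members)
    w = _weight_matrix(net, bg)
    observed = within_set_weight(net, candidates)
    null = _null_within(w, rng, n_perm, len(candidates))
    res = empirical_p(observed, null)
    return ConnectivityResult(
        observed=res.observed,
        n_perm=res.n_perm,
        k_ge=res.k_ge,
        p_emp=res.p_emp,
        seed=seed,
        set_sizes={"candidates": len(candidates), "background": len(background)},
    )


def cross_set_test(
    net: CoexpressionNetwork,
    candidates: GeneSet,
    target: GeneSet,
    background: GeneSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ConnectivityResult:
    """Are the candidates more connected to the target set than random
    same-size draws from the background?

    Genes shared between candidates and target must already have been
    removed from both sets *and* from the background; overlaps raise.
    """
    if candidates.members & target.members:
        raise ValueError("candidates and target overlap; remove shared genes first")
    if background.members & target.members:
        raise ValueError("background and target overlap; remove shared genes first")
    if not candidates.members <= background.members:
        raise ValueError("candidates must be a subset of the background")
    if len(background) <= len(candidates):
        raise ValueError("background must be strictly larger than the candidate set")
    rng = np.random.default_rng(seed)
    bg = sorted(background.members)
    wvec = _weight_to_target(net, bg, target.members)
    observed = between_set_weight(net, candidates, target)
    null = _null_between(wvec, rng, n_perm, len(candidates))
    res = empirical_p(observed, null)
    return ConnectivityResult(
        observed=res.observed,
        n_perm=res.n_perm,
        k_ge=res.k_ge,
        p_emp=res.p_emp,
        seed=seed,
        set_sizes={
            "candidates": len(candidates),
            "target": len(target),
            "background": len(background),
        },
    )


def comparative_background_test(
    net: CoexpressionNetwork,
    candidates: GeneSet,
    competitor: GeneSet,
    target: GeneSet,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ConnectivityResult:
    """Is the target set more connected to the candidates than to a
    competitor set?

    The null redraws candidate-sized subsets from the composite background
    (candidates plus competitor, deduplicated, with any gene annotated with
    the target phenotype removed from all sets).
    """
    cand = candidates.members - target.members
    comp_bg = (candidates.members | competitor.members) - target.members
    overlap = len(candidates.members & competitor.members)
    if not cand:
        raise ValueError("no candidates left after removing target-annotated genes")
    if len(comp_bg) <= len(cand):
        raise ValueError("composite background must be strictly larger than candidates")
    logger.info(
        "comparative background: |candidates'| = %d, |composite| = %d (overlap %d)",
        len(cand),
        len(comp_bg),
        overlap,
    )
    cand_set = GeneSet(candidates.name, cand)
    bg_set = GeneSet("composite_background", frozenset(comp_bg))
    res = cross_set_test(net, cand_set, target, bg_set, n_perm=n_perm, seed=seed)
    return ConnectivityResult(
        observed=res.observed,
        n_perm=res.n_perm,
        k_ge=res.k_ge,
        p_emp=res.p_emp,
        seed=seed,
        set_sizes={
            "candidates_after_exclusion": len(cand),
            "composite_background": len(comp_bg),
            "candidate_competitor_overlap": overlap,
            "target": len(target),
        },
    )
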