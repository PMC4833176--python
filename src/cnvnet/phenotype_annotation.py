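"""Phenotype ontology, orthology, and ancestor-closure gene annotation.

Mouse gene-disruption phenotypes are recorded against terms of a phenotype
ontology (a DAG: each term may have several ``is_a`` parents).  A human gene
enters the annotated universe when its strict 1:1 mouse orthologue carries at
least one phenotype annotation, and it belongs to a term's gene set when the
orthologue is annotated with the term itself or with any descendant
(ancestor closure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import ConfigurationError, OntologyError

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeOntology:
    """Term DAG with child -> parent ``is_a`` edges."""

    parents: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, ps in self.parents.items():
            unknown = ps - self.parents.keys()
            if unknown:
                raise OntologyError(f"{term} references unknown parent(s) {sorted(unknown)}")
        cycle = self._find_cycle()
        if cycle:
            raise OntologyError(f"ontology is not a DAG; cycle: {' -> '.join(cycle)}")
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._children: dict[str, set[str]] | None = None

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def _find_cycle(self) -> list[str] | None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return None
        return [edge[0] for edge in cyc] + [cyc[0][0]]

    def ancestors(self, term: str) -> frozenset[str]:
        """All transitive ``is_a`` ancestors of ``term`` (excluding itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(term)
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """All transitive descendants of ``term`` (excluding itself)."""
        if term not in self.parents:
            raise KeyError(term)
        if self._children is None:
            children: dict[str, set[str]] = {t: set() for t in self.parents}
            for c, ps in self.parents.items():
                for p in ps:
                    children[p].add(c)
            self._children = children
        out: set[str] = set()
        stack = list(self._children[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self._children[t])
        return frozenset(out)


def load_ontology(path: str | Path) -> PhenotypeOntology:
    """Load an OBO 1.2-style file; obsolete terms are dropped.

    Only ``is_a`` relationships define the parent DAG; other relationship
    types present in the file are ignored.
    """
    graph = obonet.read_obo(path)  # edges run child -> parent, keyed by relation
    parents: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ps = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        parents[node] = ps & set(graph.nodes)
        if "name" in data:
            names[node] = data["name"]
    return PhenotypeOntology(parents=parents, names=names)


@dataclass
class OrthologyMap:
    """Strict 1:1 human <-> mouse gene pairing."""

    human_to_mouse: dict[str, str]
    n_dropped: int = 0

    @property
    def mouse_to_human(self) -> dict[str, str]:
        return {m: h for h, m in self.human_to_mouse.items()}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologyMap":
        """Keep only pairs where both genes map uniquely to each other."""
        pairs = list(pairs)
        human_counts: dict[str, int] = {}
        mouse_counts: dict[str, int] = {}
        for h, m in pairs:
            human_counts[h] = human_counts.get(h, 0) + 1
            mouse_counts[m] = mouse_counts.get(m, 0) + 1
        kept = {
            h: m for h, m in pairs if human_counts[h] == 1 and mouse_counts[m] == 1
        }
        dropped = len(pairs) - len(kept)
        if dropped:
            logger.info("dropped %d non-1:1 orthology pair(s)", dropped)
        return cls(human_to_mouse=kept, n_dropped=dropped)


def load_orthology(path: str | Path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"human_id", "mouse_id"}
    if missing := required - set(df.columns):
        raise ConfigurationError(f"{path}: missing required column(s) {sorted(missing)}")
    return OrthologyMap.from_pairs(zip(df["human_id"], df["mouse_id"]))


@dataclass
class AnnotationTable:
    """Direct (pre-closure) mouse gene -> phenotype term assignments."""

    direct: dict[str, frozenset[str]]


def load_annotations(
    path: str | Path, ontology: PhenotypeOntology | None = None
) -> AnnotationTable:
    """Read a (mouse_id, term_id) TSV; terms absent from the ontology are
    dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mouse_id", "term_id"}
    if missing := required - set(df.columns):
        raise ConfigurationError(f"{path}: missing required column(s) {sorted(missing)}")
    dropped = 0
    direct: dict[str, set[str]] = {}
    known = ontology.terms if ontology is not None else None
    for mouse_id, term_id in zip(df["mouse_id"], df["term_id"]):
        if known is not None and term_id not in known:
            dropped += 1
            continue
        direct.setdefault(mouse_id, set()).add(term_id)
    if dropped:
        logger.info("dropped %d annotation row(s) with unknown terms", dropped)
    return AnnotationTable(direct={m: frozenset(ts) for m, ts in direct.items()})


@dataclass
class AnnotatedUniverse:
    """Human genes with any mouse phenotype, and per-term closure gene sets."""

    genes: frozenset[str]
    term_gene_sets: dict[str, frozenset[str]]

    @property
    def size(self) -> int:
        return len(self.genes)

    def term_size(self, term: str) -> int:
        return len(self.term_gene_sets.get(term, frozenset()))

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {"term_id": t, "gene_id": g}
            for t in sorted(self.term_gene_sets)
            for g in sorted(self.term_gene_sets[t])
        ]
        rows += [{"term_id": "", "gene_id": g} for g in sorted(self.genes)]
        pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AnnotatedUniverse":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        genes = frozenset(df.loc[df["term_id"] == "", "gene_id"])
        sets = {
            t: frozenset(sub["gene_id"])
            for t, sub in df[df["term_id"] != ""].groupby("term_id")
        }
        return cls(genes=genes, term_gene_sets=sets)


def annotate_closure(
    onto: PhenotypeOntology, ann: AnnotationTable, orth: OrthologyMap
) -> AnnotatedUniverse:
    """Project mouse annotations to human genes under ancestor closure.

    A human gene is in ``term_gene_sets[t]`` iff its 1:1 mouse orthologue is
    directly annotated with ``t`` or with any descendant of ``t``.  Genes
    without a 1:1 orthologue, or whose orthologue has no annotation, are
    excluded from the universe entirely.
    """
    mouse_to_human = orth.mouse_to_human
    term_sets: dict[str, set[str]] = {}
    genes: set[str] = set()
    for mouse_id, terms in ann.direct.items():
        human_id = mouse_to_human.get(mouse_id)
        if human_id is None or not terms:
            continue
        genes.add(human_id)
        closed: set[str] = set()
        for t in terms:
            closed.add(t)
            closed |= onto.ancestors(t)
        for t in closed:
            term_sets.setdefault(t, set()).add(human_id)
    return AnnotatedUniverse(
        genes=frozenset(genes),
        term_gene_sets={t: frozenset(s) for t, s in term_sets.items()},
    )


def select_test_terms(
    universe: AnnotatedUniverse,
    onto: PhenotypeOntology,
    root_term: str,
    min_genes: int = 1,
    include_root: bool = False,
) -> list[str]:
    """Descendants of ``root_term`` whose closure gene set has >= ``min_genes``
    members, in deterministic lexicographic order."""
    if root_term not in onto.parents:
        raise KeyError(f"unknown root term {root_term!r}")
    terms = set(onto.descendants(root_term))
    if include_root:
        terms.add(root_term)
    return sorted(t for t in terms if universe.term_size(t) >= min_genes)
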