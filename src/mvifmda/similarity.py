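"""Node-similarity matrices for miRNAs and diseases.

Four similarity views feed the predictor:

* ``SD1`` — disease *semantic* similarity from a MeSH-style DAG: each ancestor
  of a disease contributes semantically with a factor that decays by ``delta``
  per generation, and two diseases are similar in proportion to the
  contribution mass of their shared ancestors.
* ``SD2`` — disease *functional* similarity: best-match-average (BMA) between
  the diseases' associated gene sets over a weighted gene functional network
  (HumanNet-style log-likelihood scores, min-max normalized to [0, 1]).
* ``SM1`` — miRNA *sequence* similarity: Needleman-Wunsch global alignment
  scores, min-max normalized over all pairs.
* ``SM2`` — miRNA *functional* similarity: the same BMA formula applied to
  miRNA target-gene sets.

All four are returned as :class:`SimilarityMatrix` objects: square, symmetric,
entries in [0, 1], unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
from Bio import Align

__all__ = [
    "DiseaseDAG",
    "GeneNetwork",
    "SequenceSet",
    "SimilarityMatrix",
    "semantic_contribution",
    "disease_semantic_similarity",
    "gene_to_set_similarity",
    "set_set_functional_similarity",
    "functional_similarity_matrix",
    "needleman_wunsch_score",
    "sequence_similarity_matrix",
    "DEFAULT_DELTA",
    "DEFAULT_SCHEME",
]

DEFAULT_DELTA = 0.5
#: Needleman-Wunsch (match, mismatch, gap) scores; linear gap penalty.
DEFAULT_SCHEME = (1.0, -1.0, -1.0)

RNA_ALPHABET = frozenset("ACGU")


class CycleError(ValueError):
    """The disease hierarchy contains a directed cycle."""


# --------------------------------------------------------------------------- DAG


@dataclass
class DiseaseDAG:
    """A disease hierarchy given as child -> parent edges.

    The ancestor closure ``T(d)`` of a disease is the disease itself plus all
    of its ancestors.  Diseases that appear in no edge are isolated roots with
    ``T(d) = {d}``.
    """

    edges: list[tuple[str, str]]
    extra_nodes: set[str] = field(default_factory=set)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.extra_nodes)
        for child, parent in self.edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"disease hierarchy contains a cycle: {cyc}")
        self._graph = g

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    def closure(self, d: str) -> frozenset:
        """T(d): the disease and all its ancestors."""
        if d not in self._graph:
            raise KeyError(f"unknown disease id: {d!r}")
        # edges point child -> parent, so ancestors are descendants in the digraph
        return frozenset(nx.descendants(self._graph, d)) | {d}

    def parents(self, d: str) -> set[str]:
        return set(self._graph.successors(d))

    def children(self, d: str) -> set[str]:
        return set(self._graph.predecessors(d))


def semantic_contribution(
    dag: DiseaseDAG, d: str, delta: float = DEFAULT_DELTA
) -> dict[str, float]:
    """Semantic contribution D_d(t) of every ancestor t of disease d.

    D_d(d) = 1; for any other ancestor t, D_d(t) = max over children t' of t
    (restricted to the ancestor closure of d) of delta * D_d(t').  With
    delta < 1 the contribution decays strictly along every ancestor chain.
    """
    closure = dag.closure(d)
    contrib: dict[str, float] = {d: 1.0}
    # process nodes in increasing distance from d (BFS over parent links);
    # max-propagation is monotone so a node is final once all in-closure
    # children have been settled — topological order over the closure sub-DAG.
    order = _closure_topo_order(dag, d, closure)
    for t in order:
        if t == d:
            continue
        best = max(
            contrib[c] for c in dag.children(t) if c in closure and c in contrib
        )
        contrib[t] = delta * best
    return contrib


def _closure_topo_order(dag: DiseaseDAG, d: str, closure: frozenset) -> list[str]:
    """Nodes of the closure sub-DAG, children before parents."""
    sub = dag._graph.subgraph(closure)
    return list(nx.topological_sort(sub))


def disease_semantic_similarity(
    dag: DiseaseDAG, disease_ids: list[str], delta: float = DEFAULT_DELTA
) -> "SimilarityMatrix":
    """Semantic similarity matrix SD1 over the given diseases.

    SD1(i, j) is the total contribution of the shared ancestors of i and j
    (counted from both sides) over the total contribution mass of each:

        SD1(i,j) = sum_{t in T(i) ∩ T(j)} (D_i(t) + D_j(t))
                   / (sum_{t in T(i)} D_i(t) + sum_{t in T(j)} D_j(t))
    """
    contribs = {d: semantic_contribution(dag, d, delta) for d in disease_ids}
    totals = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(disease_ids)
    m = np.eye(n)
    for i in range(n):
        ci = contribs[disease_ids[i]]
        for j in range(i + 1, n):
            cj = contribs[disease_ids[j]]
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                m[i, j] = m[j, i] = num / (
                    totals[disease_ids[i]] + totals[disease_ids[j]]
                )
    return SimilarityMatrix(ids=list(disease_ids), values=m, source="semantic")


# ------------------------------------------------------------------ gene network


class GeneNetwork:
    """Weighted gene-gene functional network with log-likelihood scores (LLS).

    Raw scores are min-max normalized over all observed edges into LLSN in
    [0, 1]; gene pairs without an edge contribute 0.
    """

    def __init__(self, edges: list[tuple[str, str, float]]):
        self._llsn: dict[frozenset, float] = {}
        if edges:
            raw = np.array([w for _, _, w in edges], dtype=float)
            lo, hi = raw.min(), raw.max()
            span = hi - lo
            for (a, b, w), r in zip(edges, raw):
                key = frozenset((a, b))
                llsn = 1.0 if span == 0 else (r - lo) / span
                # keep the strongest evidence when an edge is listed twice
                self._llsn[key] = max(self._llsn.get(key, 0.0), llsn)

    def llsn(self, a: str, b: str) -> float:
        """Normalized score of the edge {a, b}; 0 when absent."""
        return self._llsn.get(frozenset((a, b)), 0.0)

    def pair_similarity(self, a: str, b: str) -> float:
        """S(g, g') = 1 for identical genes, else LLSN (0 when unlinked)."""
        return 1.0 if a == b else self.llsn(a, b)

    def dense(self, genes: list[str]) -> np.ndarray:
        """Dense S matrix over an ordered gene list (identity diagonal)."""
        idx = {g: i for i, g in enumerate(genes)}
        m = np.eye(len(genes))
        for key, w in self._llsn.items():
            pair = tuple(key)
            if len(pair) == 2 and pair[0] in idx and pair[1] in idx:
                i, j = idx[pair[0]], idx[pair[1]]
                m[i, j] = m[j, i] = w
        return m


def gene_to_set_similarity(g: str, gene_set: set, net: GeneNetwork) -> float:
    """Best-match similarity of one gene to a gene set: max over the set."""
    if not gene_set:
        raise ValueError("gene set is empty; gene-to-set similarity is undefined")
    return max(net.pair_similarity(g, gi) for gi in gene_set)


def set_set_functional_similarity(
    gs_i: set, gs_j: set, net: GeneNetwork
) -> float:
    """Best-match-average similarity between two gene sets.

    Each gene of each set is matched to its best partner in the other set; the
    matches are averaged over both sets.  An empty set carries no functional
    evidence: the similarity involving one is 0 (warned).
    """
    if not gs_i or not gs_j:
        warnings.warn("empty gene set: functional similarity defined as 0")
        return 0.0
    num = sum(gene_to_set_similarity(g, gs_j, net) for g in gs_i)
    num += sum(gene_to_set_similarity(g, gs_i, net) for g in gs_j)
    return num / (len(gs_i) + len(gs_j))


def functional_similarity_matrix(
    gene_sets: dict[str, set], entity_ids: list[str], net: GeneNetwork
) -> "SimilarityMatrix":
    """BMA functional similarity over all entity pairs (vectorized).

    Works for disease gene sets (SD2) and miRNA target sets (SM2) alike.
    """
    genes = sorted({g for e in entity_ids for g in gene_sets.get(e, ())})
    sim = net.dense(genes)  # gene x gene S matrix
    gidx = {g: i for i, g in enumerate(genes)}
    rows = {e: np.array([gidx[g] for g in sorted(gene_sets.get(e, ()))], dtype=int)
            for e in entity_ids}
    empties = [e for e in entity_ids if rows[e].size == 0]
    if empties:
        warnings.warn(
            f"{len(empties)} entities have empty gene sets; "
            "their functional similarities are 0"
        )
    n = len(entity_ids)
    m = np.eye(n)
    for i in range(n):
        ri = rows[entity_ids[i]]
        if ri.size == 0:
            continue
        for j in range(i + 1, n):
            rj = rows[entity_ids[j]]
            if rj.size == 0:
                continue
            block = sim[np.ix_(ri, rj)]
            num = block.max(axis=1).sum() + block.max(axis=0).sum()
            m[i, j] = m[j, i] = num / (ri.size + rj.size)
    return SimilarityMatrix(ids=list(entity_ids), values=m, source="functional")


# -------------------------------------------------------------------- sequences


@dataclass
class SequenceSet:
    """miRNA id -> RNA sequence over {A, C, G, U}; validated on construction."""

    sequences: dict[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {name!r} has non-RNA characters: {sorted(bad)}"
                )

    def __len__(self):
        return len(self.sequences)


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap  # linear gap penalty
    return al


def needleman_wunsch_score(
    x: str, y: str, scheme: tuple[float, float, float] = DEFAULT_SCHEME
) -> float:
    """Optimal global-alignment score of two RNA strings (linear gap).

    Degenerate cases: aligning against the empty string costs one gap per
    residue of the other string.
    """
    for s in (x, y):
        bad = set(s) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    match, mismatch, gap = scheme
    if not x or not y:
        return gap * (len(x) + len(y))
    return float(_aligner(match, mismatch, gap).score(x, y))


def sequence_similarity_matrix(
    seqs: SequenceSet,
    scheme: tuple[float, float, float] = DEFAULT_SCHEME,
) -> "SimilarityMatrix":
    """Sequence similarity matrix SM1 by min-max normalized alignment scores.

    Raw pairwise scores are computed for all unordered off-diagonal pairs and
    rescaled so the weakest pair maps to 0 and the strongest to 1; the
    diagonal is then set to 1 (self-alignments do not enter the min-max, so a
    single long sequence cannot flatten the scale).
    """
    ids = list(seqs.sequences)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = needleman_wunsch_score(
                seqs.sequences[ids[i]], seqs.sequences[ids[j]], scheme
            )
    off = raw[~np.eye(n, dtype=bool)]
    lo, hi = off.min(), off.max()
    if hi == lo:
        raise ValueError(
            "degenerate normalization: all pairwise alignment scores are equal"
        )
    m = (raw - lo) / (hi - lo)
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(ids=ids, values=m, source="sequence")


# ----------------------------------------------------------------------- matrix


@dataclass
class SimilarityMatrix:
    """Symmetric entity-similarity matrix in [0, 1] with unit diagonal."""

    ids: list[str]
    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError(f"similarity matrix shape {v.shape} does not match "
                             f"{len(self.ids)} ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix is not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values outside [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)
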