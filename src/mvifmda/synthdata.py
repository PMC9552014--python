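"""Synthetic miRNA-disease datasets with planted, recoverable structure.

Real inputs of this problem (curated association catalogues, the MeSH
hierarchy, disease-gene and miRNA-target catalogues, a weighted gene
functional network, miRNA sequences) cannot be bundled, so this module
fabricates all five from one latent mechanism: every miRNA and every disease
belongs to one of ``C`` hidden clusters, and

* associations are Bernoulli(p_in) for same-cluster pairs and
  Bernoulli(p_out) otherwise;
* the disease hierarchy hangs same-cluster diseases under a shared deep
  anchor chain, so semantic similarity is high within clusters;
* gene sets draw mostly from a per-cluster gene module, and the gene network
  wires modules densely with strong log-likelihood scores, so both
  functional similarities carry the cluster signal;
* sequences are per-site substitutions of a per-cluster prototype, so
  alignment similarity does too.

A model that exploits the similarity views can therefore recover held-out
associations, while :func:`null_copy` re-draws the associations uniformly at
the same density to destroy the signal without touching the similarity
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .similarity import DiseaseDAG

__all__ = ["SynthConfig", "Dataset", "simulate", "generate", "null_copy",
           "tiny_fixture", "DEFAULT_PRESET"]

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the planted-cluster generator (defaults = the study preset)."""

    n_mirna: int = 200
    n_disease: int = 80
    n_clusters: int = 5
    p_in: float = 0.25      # same-cluster association probability
    p_out: float = 0.01     # background association probability
    n_genes: int = 600
    genes_per_entity: tuple[int, int] = (6, 14)
    gene_edge_p_in: float = 0.3     # edge probability inside a gene module
    gene_edge_p_out: float = 0.01   # edge probability across modules
    dag_depth: int = 3              # anchor-chain length per cluster
    seq_length: tuple[int, int] = (20, 24)
    mutation_rate: float = 0.15     # per-site substitution from the prototype
    seed: int = 1

    def __post_init__(self):
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        if min(self.n_mirna, self.n_disease, self.n_genes) < 1:
            raise ValueError("entity counts must be positive")
        if self.n_genes < self.n_clusters:
            raise ValueError("need at least one gene per cluster module")
        if self.genes_per_entity[0] < 1:
            raise ValueError("entities need at least one gene")


DEFAULT_PRESET = SynthConfig()


@dataclass
class Dataset:
    """All raw inputs of one study, in memory."""

    mirna_ids: list[str]
    disease_ids: list[str]
    pairs: list[tuple[str, str]]
    dag: DiseaseDAG
    gene_edges: list[tuple[str, str, float]]
    disease_genes: dict[str, set]
    mirna_genes: dict[str, set]
    sequences: dict[str, str]
    truth: dict = field(default_factory=dict)


def _balanced_clusters(n: int, c: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    for k, part in enumerate(np.array_split(rng.permutation(n), c)):
        labels[part] = k
    return labels


def simulate(config: SynthConfig = DEFAULT_PRESET) -> Dataset:
    """Draw one complete dataset; a pure function of the config."""
    rng = np.random.default_rng(config.seed)
    c = config
    mirna_ids = [f"mir-{i:04d}" for i in range(c.n_mirna)]
    disease_ids = [f"DIS:{j:04d}" for j in range(c.n_disease)]
    genes = [f"G{g:05d}" for g in range(c.n_genes)]

    m_clusters = _balanced_clusters(c.n_mirna, c.n_clusters, rng)
    d_clusters = _balanced_clusters(c.n_disease, c.n_clusters, rng)

    # --- associations: planted bipartite clusters
    match = m_clusters[:, None] == d_clusters[None, :]
    probs = np.where(match, c.p_in, c.p_out)
    A = rng.random((c.n_mirna, c.n_disease)) < probs
    pairs = [(mirna_ids[i], disease_ids[j]) for i, j in zip(*np.nonzero(A))]

    # --- disease hierarchy: per-cluster anchor chains under one root
    root = "DIS:root"
    edges: list[tuple[str, str]] = []
    anchors: dict[int, list[str]] = {}
    for k in range(c.n_clusters):
        chain = [f"DIS:anchor-{k}-{lvl}" for lvl in range(c.dag_depth)]
        edges.append((chain[0], root))
        for child, parent in zip(chain[1:], chain[:-1]):
            edges.append((child, parent))
        anchors[k] = chain
    for j, d in enumerate(disease_ids):
        chain = anchors[d_clusters[j]]
        # attach at the deepest or next-to-deepest anchor for some variety
        depth = int(rng.integers(max(0, c.dag_depth - 2), c.dag_depth))
        edges.append((d, chain[depth]))
    dag = DiseaseDAG(edges=edges)

    # --- gene modules and the weighted gene network
    gene_modules = _balanced_clusters(c.n_genes, c.n_clusters, rng)
    module_genes = {k: [genes[g] for g in np.nonzero(gene_modules == k)[0]]
                    for k in range(c.n_clusters)}
    gi, gj = np.triu_indices(c.n_genes, k=1)
    same_module = gene_modules[gi] == gene_modules[gj]
    edge_p = np.where(same_module, c.gene_edge_p_in, c.gene_edge_p_out)
    has_edge = rng.random(edge_p.size) < edge_p
    lls = np.where(same_module, rng.uniform(3.0, 5.0, edge_p.size),
                   rng.uniform(0.5, 1.5, edge_p.size))
    gene_edges = [
        (genes[a], genes[b], float(w))
        for a, b, w in zip(gi[has_edge], gj[has_edge], lls[has_edge])
    ]

    # --- gene sets: mostly the own cluster module, some background
    def draw_gene_set(cluster: int) -> set:
        k = int(rng.integers(c.genes_per_entity[0], c.genes_per_entity[1] + 1))
        n_own = max(1, int(round(0.8 * k)))
        own_pool = module_genes[cluster]
        own = rng.choice(own_pool, size=min(n_own, len(own_pool)),
                         replace=False)
        rest = rng.choice(c.n_genes, size=k - len(own), replace=False)
        return set(own) | {genes[g] for g in rest}

    disease_genes = {d: draw_gene_set(d_clusters[j])
                     for j, d in enumerate(disease_ids)}
    mirna_genes = {m: draw_gene_set(m_clusters[i])
                   for i, m in enumerate(mirna_ids)}

    # --- sequences: substitution-mutated cluster prototypes
    proto = {}
    for k in range(c.n_clusters):
        length = int(rng.integers(c.seq_length[0], c.seq_length[1] + 1))
        proto[k] = rng.choice(_BASES, size=length)
    sequences = {}
    for i, m in enumerate(mirna_ids):
        seq = proto[m_clusters[i]].copy()
        mutate = rng.random(seq.size) < c.mutation_rate
        # substitute with a uniformly random different base
        for pos in np.nonzero(mutate)[0]:
            options = [b for b in _BASES if b != seq[pos]]
            seq[pos] = options[int(rng.integers(3))]
        sequences[m] = "".join(seq)

    truth = {
        "config": _config_dict(c),
        "mirna_clusters": {m: int(k) for m, k in zip(mirna_ids, m_clusters)},
        "disease_clusters": {d: int(k) for d, k in zip(disease_ids, d_clusters)},
        "n_positives": len(pairs),
    }
    return Dataset(
        mirna_ids=mirna_ids, disease_ids=disease_ids, pairs=pairs, dag=dag,
        gene_edges=gene_edges, disease_genes=disease_genes,
        mirna_genes=mirna_genes, sequences=sequences, truth=truth,
    )


def _config_dict(c: SynthConfig) -> dict:
    d = asdict(c)
    d["genes_per_entity"] = list(c.genes_per_entity)
    d["seq_length"] = list(c.seq_length)
    return d


def generate(config: SynthConfig, out_dir: str | Path) -> Dataset:
    """Draw a dataset and write the five input files plus truth.json."""
    from . import io as io_mod

    dataset = simulate(config)
    io_mod.write_dataset(dataset, out_dir)
    return dataset


def null_copy(dataset: Dataset, seed: int | None = None) -> Dataset:
    """Same similarity inputs, associations re-drawn uniformly at random.

    Exactly as many positive pairs as the source dataset, placed uniformly
    over the full miRNA x disease grid, independent of the planted clusters.
    """
    cfg_seed = dataset.truth.get("config", {}).get("seed", 0)
    rng = np.random.default_rng(cfg_seed + 10_007 if seed is None else seed)
    nm, nd = len(dataset.mirna_ids), len(dataset.disease_ids)
    flat = rng.choice(nm * nd, size=len(dataset.pairs), replace=False)
    pairs = [(dataset.mirna_ids[f // nd], dataset.disease_ids[f % nd])
             for f in sorted(flat)]
    truth = dict(dataset.truth)
    truth["null"] = True
    return Dataset(
        mirna_ids=dataset.mirna_ids, disease_ids=dataset.disease_ids,
        pairs=pairs, dag=dataset.dag, gene_edges=dataset.gene_edges,
        disease_genes=dataset.disease_genes, mirna_genes=dataset.mirna_genes,
        sequences=dataset.sequences, truth=truth,
    )


def tiny_fixture() -> Dataset:
    """Deterministic 6 miRNA x 4 disease miniature with hand-checkable values.

    Contains the two canonical toys: diseases DIS:d1/DIS:d2 are each a single
    child of the shared root parent DIS:p (semantic similarity exactly 1/3 at
    the default decay factor), and their singleton gene sets {gA}, {gB} are
    linked with normalized score 0.6 (functional similarity exactly 0.6).
    """
    disease_ids = ["DIS:d1", "DIS:d2", "DIS:d3", "DIS:d4"]
    mirna_ids = [f"mir-t{i}" for i in range(1, 7)]
    dag = DiseaseDAG(
        edges=[("DIS:d1", "DIS:p"), ("DIS:d2", "DIS:p"),
               ("DIS:d3", "DIS:q"), ("DIS:d4", "DIS:q")]
    )
    # raw scores 0.0 and 1.0 pin the min-max scale, so gA-gB normalizes to 0.6
    gene_edges = [("gA", "gB", 0.6), ("gC", "gD", 1.0), ("gE", "gF", 0.0),
                  ("gC", "gE", 0.8)]
    disease_genes = {"DIS:d1": {"gA"}, "DIS:d2": {"gB"},
                     "DIS:d3": {"gC", "gD"}, "DIS:d4": {"gD"}}
    mirna_genes = {"mir-t1": {"gA", "gC"}, "mir-t2": {"gA"},
                   "mir-t3": {"gB", "gD"}, "mir-t4": {"gD"},
                   "mir-t5": {"gE"}, "mir-t6": {"gF", "gB"}}
    sequences = {"mir-t1": "ACGUACGU", "mir-t2": "ACGUACGA",
                 "mir-t3": "UUGGCCAA", "mir-t4": "UUGGCCAU",
                 "mir-t5": "GGGGCCCC", "mir-t6": "AAAAUUUU"}
    pairs = [("mir-t1", "DIS:d1"), ("mir-t2", "DIS:d1"),
             ("mir-t3", "DIS:d2"), ("mir-t4", "DIS:d3"),
             ("mir-t5", "DIS:d4"), ("mir-t6", "DIS:d4")]
    return Dataset(
        mirna_ids=mirna_ids, disease_ids=disease_ids, pairs=pairs, dag=dag,
        gene_edges=gene_edges, disease_genes=disease_genes,
        mirna_genes=mirna_genes, sequences=sequences,
        truth={"config": {"seed": 0}, "fixture": "tiny"},
    )
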