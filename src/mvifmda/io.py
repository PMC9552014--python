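"""File formats, dataset loading, and run configuration.

All tabular inputs are tab-separated UTF-8 with optional ``#`` comment lines:

* associations: ``miRNA<TAB>disease``
* disease hierarchy: ``child<TAB>parent``
* gene network: ``geneA<TAB>geneB<TAB>LLS``
* gene sets (long format): ``entity<TAB>gene``
* sequences: FASTA with record ids matching the association file

Loading applies intersection semantics: the miRNA universe is the FASTA ids,
the disease universe the association-file diseases present in the hierarchy;
association pairs referencing anything else are dropped and counted in a load
manifest, mirroring the multi-source curation step of real studies without
hiding the data loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .model import ModelConfig
from .netbuild import AssociationMatrix, build_association_matrix
from .similarity import (
    DEFAULT_DELTA,
    DEFAULT_SCHEME,
    DiseaseDAG,
    GeneNetwork,
    SequenceSet,
    SimilarityMatrix,
    disease_semantic_similarity,
    functional_similarity_matrix,
    sequence_similarity_matrix,
)
from .synthdata import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "DataError", "ConfigError", "RunConfig",
    "load_dataset", "write_dataset", "prepare_views",
    "read_similarity", "write_similarity",
    "write_predictions", "read_predictions",
    "load_run_config",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid run configuration."""


# ------------------------------------------------------------------- low level


def _read_tsv(path: Path, n_cols: int) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise DataError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(parts)}"
                )
            rows.append(parts)
    return rows


def read_association_pairs(path: Path) -> list[tuple[str, str]]:
    return [(m, d) for m, d in _read_tsv(Path(path), 2)]


def read_dag(path: Path) -> DiseaseDAG:
    return DiseaseDAG(edges=[(c, p) for c, p in _read_tsv(Path(path), 2)])


def read_gene_network(path: Path) -> list[tuple[str, str, float]]:
    out = []
    for lineno, (a, b, w) in enumerate(_read_tsv(Path(path), 3), start=1):
        try:
            out.append((a, b, float(w)))
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric LLS {w!r}") from exc
    return out


def read_gene_sets(path: Path) -> dict[str, set]:
    sets: dict[str, set] = {}
    for entity, gene in _read_tsv(Path(path), 2):
        sets.setdefault(entity, set()).add(gene)
    return sets


def read_sequences(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise DataError(f"duplicate FASTA id: {record.id!r}")
        seqs[record.id] = str(record.seq).upper().replace("T", "U")
    if not seqs:
        raise DataError(f"no FASTA records in {path}")
    return seqs


# --------------------------------------------------------------------- dataset

FILES = {
    "associations": "associations.tsv",
    "dag": "disease_dag.tsv",
    "gene_network": "gene_network.tsv",
    "disease_genes": "disease_genes.tsv",
    "mirna_genes": "mirna_genes.tsv",
    "sequences": "sequences.fasta",
    "truth": "truth.json",
}


def load_dataset(data_dir: str | Path) -> Dataset:
    """Load the five inputs from a directory; see module docstring for rules."""
    d = Path(data_dir)
    for key in ("associations", "dag", "gene_network", "sequences"):
        if not (d / FILES[key]).exists():
            raise DataError(f"missing input file: {d / FILES[key]}")
    raw_pairs = read_association_pairs(d / FILES["associations"])
    dag = read_dag(d / FILES["dag"])
    gene_edges = read_gene_network(d / FILES["gene_network"])
    disease_genes = read_gene_sets(d / FILES["disease_genes"])
    mirna_genes = read_gene_sets(d / FILES["mirna_genes"])
    sequences = read_sequences(d / FILES["sequences"])

    mirna_ids = list(sequences)
    disease_seen: list[str] = []
    dropped = 0
    pairs = []
    for m, dis in raw_pairs:
        if m not in sequences or dis not in dag.nodes:
            dropped += 1
            continue
        if dis not in disease_seen:
            disease_seen.append(dis)
        pairs.append((m, dis))
    disease_ids = sorted(disease_seen)
    if dropped:
        logger.warning("dropped %d association pairs lacking a similarity "
                       "input", dropped)
    if not pairs:
        raise DataError("no association pair has complete similarity inputs")
    truth = {}
    if (d / FILES["truth"]).exists():
        truth = json.loads((d / FILES["truth"]).read_text())
    truth["load_manifest"] = {
        "n_pairs_in_file": len(raw_pairs),
        "n_pairs_kept": len(pairs),
        "n_pairs_dropped": dropped,
        "n_mirna": len(mirna_ids),
        "n_disease": len(disease_ids),
    }
    return Dataset(
        mirna_ids=mirna_ids, disease_ids=disease_ids,
        pairs=sorted(set(pairs)), dag=dag, gene_edges=gene_edges,
        disease_genes=disease_genes, mirna_genes=mirna_genes,
        sequences={m: sequences[m] for m in mirna_ids}, truth=truth,
    )


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    """Write the five input files (plus truth.json) for a dataset."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / FILES["associations"], "w", encoding="utf-8") as fh:
        fh.write("# miRNA\tdisease\n")
        for m, dis in dataset.pairs:
            fh.write(f"{m}\t{dis}\n")
    with open(d / FILES["dag"], "w", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for c, p in dataset.dag.edges:
            fh.write(f"{c}\t{p}\n")
    with open(d / FILES["gene_network"], "w", encoding="utf-8") as fh:
        fh.write("# geneA\tgeneB\tLLS\n")
        for a, b, w in dataset.gene_edges:
            fh.write(f"{a}\t{b}\t{w!r}\n")
    for key, sets in (("disease_genes", dataset.disease_genes),
                      ("mirna_genes", dataset.mirna_genes)):
        with open(d / FILES[key], "w", encoding="utf-8") as fh:
            fh.write("# entity\tgene\n")
            for entity in sets:
                for gene in sorted(sets[entity]):
                    fh.write(f"{entity}\t{gene}\n")
    with open(d / FILES["sequences"], "w", encoding="utf-8") as fh:
        for m, seq in dataset.sequences.items():
            fh.write(f">{m}\n{seq}\n")
    (d / FILES["truth"]).write_text(json.dumps(dataset.truth, indent=1,
                                               sort_keys=True))


def prepare_views(
    dataset: Dataset,
    delta: float = DEFAULT_DELTA,
    scheme: tuple[float, float, float] = DEFAULT_SCHEME,
) -> tuple[AssociationMatrix, list[SimilarityMatrix], list[SimilarityMatrix]]:
    """Compute the association matrix and all four similarity views.

    Returns ``(A, [SM1, SM2], [SD1, SD2])`` ready for network assembly.
    """
    assoc = build_association_matrix(dataset.pairs, dataset.mirna_ids,
                                     dataset.disease_ids)
    net = GeneNetwork(dataset.gene_edges)
    seqs = SequenceSet({m: dataset.sequences[m] for m in dataset.mirna_ids})
    sm1 = sequence_similarity_matrix(seqs, scheme)
    sm2 = functional_similarity_matrix(dataset.mirna_genes, dataset.mirna_ids,
                                       net)
    sd1 = disease_semantic_similarity(dataset.dag, dataset.disease_ids, delta)
    sd2 = functional_similarity_matrix(dataset.disease_genes,
                                       dataset.disease_ids, net)
    return assoc, [sm1, sm2], [sd1, sd2]


# ------------------------------------------------------------------- matrices


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_similarity(path: str | Path, source: str = "") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SimilarityMatrix(ids=[str(c) for c in df.columns],
                            values=df.to_numpy(), source=source)


def write_predictions(scores: np.ndarray, mirna_ids: list[str],
                      disease_ids: list[str], path: str | Path) -> None:
    """Full score matrix as TSV (rows miRNAs, columns diseases)."""
    df = pd.DataFrame(np.asarray(scores, dtype=float), index=mirna_ids,
                      columns=disease_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_predictions(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (df.to_numpy(dtype=float), [str(i) for i in df.index],
            [str(c) for c in df.columns])


# --------------------------------------------------------------- run config


@dataclass
class RunConfig:
    """Everything a run needs: data location, model knobs, evaluation options."""

    data_dir: str | None = None
    out_dir: str = "results"
    seed: int = 0
    repeats: int = 1
    delta: float = DEFAULT_DELTA
    nw_match: float = DEFAULT_SCHEME[0]
    nw_mismatch: float = DEFAULT_SCHEME[1]
    nw_gap: float = DEFAULT_SCHEME[2]
    model: ModelConfig = field(default_factory=ModelConfig)

    @property
    def scheme(self) -> tuple[float, float, float]:
        return (self.nw_match, self.nw_mismatch, self.nw_gap)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    raw.update(overrides)
    return run_config_from_dict(raw, origin=str(path))


def run_config_from_dict(raw: dict, origin: str = "<dict>") -> RunConfig:
    raw = dict(raw)
    model_raw = raw.pop("model", {}) or {}
    top_fields = {f for f in RunConfig.__dataclass_fields__ if f != "model"}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"{origin}: unknown config keys: {sorted(unknown)}")
    model_fields = set(ModelConfig.__dataclass_fields__)
    unknown_model = set(model_raw) - model_fields
    if unknown_model:
        raise ConfigError(
            f"{origin}: unknown model config keys: {sorted(unknown_model)}")
    try:
        model = ModelConfig(**model_raw)
        return RunConfig(model=model, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{origin}: {exc}") from exc
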