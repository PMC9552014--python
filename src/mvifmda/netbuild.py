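"""Association matrix and heterogeneous miRNA-disease network assembly.

Node ordering convention used throughout the package: miRNAs occupy indices
0..Nm-1, diseases Nm..Nm+Nd-1.  Each heterogeneous view is the block matrix

    M = [[SM, A], [A^T, SD]]

pairing one miRNA similarity (SM1 sequence, SM2 functional) with one disease
similarity (SD1 semantic, SD2 functional); the four views in the fixed order
(SM1,SD1), (SM1,SD2), (SM2,SD1), (SM2,SD2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "AssociationMatrix",
    "HeteroNetwork",
    "build_association_matrix",
    "assemble_hetero_networks",
    "mask_associations",
]

#: Degree floor applied in GCN normalization so isolated nodes do not divide by 0.
DEGREE_FLOOR = 1e-12


@dataclass
class AssociationMatrix:
    """Binary Nm x Nd matrix of known miRNA-disease associations."""

    A: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self):
        a = np.asarray(self.A, dtype=float)
        if a.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {a.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(a, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary")
        self.A = a

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    def positives(self) -> list[tuple[str, str]]:
        """Known pairs as (miRNA id, disease id), row-major order."""
        return [
            (self.mirna_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.A))
        ]


@dataclass
class HeteroNetwork:
    """One heterogeneous view: (Nm+Nd) square block matrix over both node types."""

    M: np.ndarray
    n_mirna: int
    n_disease: int
    mirna_source: str
    disease_source: str

    @property
    def name(self) -> str:
        return f"({self.mirna_source},{self.disease_source})"


def build_association_matrix(
    pairs: list[tuple[str, str]],
    mirna_ids: list[str],
    disease_ids: list[str],
) -> AssociationMatrix:
    """Binary matrix with A[i, j] = 1 exactly for the listed pairs.

    Duplicate pairs collapse (set semantics).  Unknown identifiers raise with
    the full list of offenders.
    """
    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    unknown = [
        (m, d) for m, d in pairs if m not in mi or d not in di
    ]
    if unknown:
        raise KeyError(f"pairs with unknown identifiers: {unknown[:10]}"
                       + ("..." if len(unknown) > 10 else ""))
    A = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in pairs:
        A[mi[m], di[d]] = 1.0
    return AssociationMatrix(A=A, mirna_ids=list(mirna_ids),
                             disease_ids=list(disease_ids))


def assemble_hetero_networks(
    assoc: AssociationMatrix,
    mirna_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
) -> list[HeteroNetwork]:
    """All P x Q heterogeneous views [[SM, A], [A^T, SD]] in fixed pair order."""
    nm, nd = assoc.n_mirna, assoc.n_disease
    for sm in mirna_sims:
        if sm.n != nm:
            raise ValueError(f"miRNA similarity side {sm.n} != {nm}")
    for sd in disease_sims:
        if sd.n != nd:
            raise ValueError(f"disease similarity side {sd.n} != {nd}")
    nets = []
    for sm in mirna_sims:
        for sd in disease_sims:
            M = np.block([[sm.values, assoc.A], [assoc.A.T, sd.values]])
            nets.append(
                HeteroNetwork(M=M, n_mirna=nm, n_disease=nd,
                              mirna_source=sm.source, disease_source=sd.source)
            )
    return nets


def mask_associations(
    assoc: AssociationMatrix, test_pairs: set[tuple[str, str]]
) -> AssociationMatrix:
    """Copy of the association matrix with the test pairs zeroed out.

    Every test pair must be a known positive; held-out associations are then
    invisible to network construction and training.
    """
    mi = {m: i for i, m in enumerate(assoc.mirna_ids)}
    di = {d: j for j, d in enumerate(assoc.disease_ids)}
    A = assoc.A.copy()
    for m, d in test_pairs:
        i, j = mi[m], di[d]
        if A[i, j] != 1.0:
            raise ValueError(f"test pair ({m}, {d}) is not a known positive")
        A[i, j] = 0.0
    return AssociationMatrix(A=A, mirna_ids=assoc.mirna_ids,
                             disease_ids=assoc.disease_ids)
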