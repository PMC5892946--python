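"""Eigengene basis construction and projection.

An eigengene is an eigenvector of the gene-gene Pearson correlation matrix of
an expression compendium: a coordinate axis summarizing correlated
transcription.  The compendium is quantile-normalized and log2-transformed,
the G x G correlation matrix is decomposed by SVD, and profiles are expressed
in eigengene coordinates by centering at the compendium per-gene mean and
projecting onto the eigenvectors.  With N < G profiles the correlation matrix
has at most N nonzero eigenvalues, so the basis compresses the G-dimensional
expression space to at most N informative directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression_core import ExpressionMatrix, quantile_normalize

__all__ = ["EigengeneBasis", "compute_basis", "project", "transform_profiles", "project_samples"]


@dataclass
class EigengeneBasis:
    """Ordered eigenvectors/eigenvalues of the gene-gene correlation matrix.

    ``gene_ids`` are the retained (nonzero-variance) genes defining the
    coordinate system; ``vectors`` is (G x G) column-orthonormal with columns
    sorted by decreasing eigenvalue.  ``gene_means`` (per retained gene, on
    the transformed scale) center profiles before projection.  ``reference``
    is the sorted mean linear-scale column of the training compendium, frozen
    so that new samples can be quantile-normalized consistently;
    ``all_gene_ids`` is the full training gene list that ``reference`` spans.
    """

    gene_ids: list[str]
    vectors: np.ndarray
    eigenvalues: np.ndarray
    gene_means: np.ndarray
    all_gene_ids: list[str] = field(default_factory=list)
    reference: np.ndarray | None = None
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"gene_id": self.gene_ids, "mean": self.gene_means}
        ).to_csv(directory / "genes.tsv", sep="\t", index=False)
        pd.DataFrame({"eigenvalue": self.eigenvalues}).to_csv(
            directory / "eigenvalues.tsv", sep="\t", index=False
        )
        np.savetxt(directory / "vectors.tsv", self.vectors, delimiter="\t")
        if self.reference is not None:
            pd.DataFrame(
                {"gene_id": self.all_gene_ids, "reference": self.reference}
            ).to_csv(directory / "reference.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "EigengeneBasis":
        directory = Path(directory)
        genes = pd.read_csv(directory / "genes.tsv", sep="\t")
        eigenvalues = pd.read_csv(directory / "eigenvalues.tsv", sep="\t")[
            "eigenvalue"
        ].to_numpy()
        vectors = np.loadtxt(directory / "vectors.tsv", delimiter="\t")
        all_gene_ids: list[str] = []
        reference = None
        ref_path = directory / "reference.tsv"
        if ref_path.exists():
            ref = pd.read_csv(ref_path, sep="\t")
            all_gene_ids = list(ref["gene_id"])
            reference = ref["reference"].to_numpy()
        return cls(
            gene_ids=list(genes["gene_id"]),
            vectors=np.atleast_2d(vectors),
            eigenvalues=eigenvalues,
            gene_means=genes["mean"].to_numpy(),
            all_gene_ids=all_gene_ids,
            reference=reference,
        )


def compute_basis(compendium: ExpressionMatrix) -> EigengeneBasis:
    """Eigengene basis of a compendium.

    Linear-scale input is quantile-normalized and log2(x+1)-transformed first
    (log2-scale input is used as-is).  Genes with zero variance across
    profiles are dropped before correlating — their Pearson correlation is
    undefined — and recorded on the basis.  The decomposition is the SVD of
    the symmetric correlation matrix; the eigenvalue sum equals the number of
    retained genes (the trace of a correlation matrix) and at most
    ``n_profiles`` eigenvalues are nonzero.
    """
    if compendium.n_samples < 2:
        raise ValueError("need >=2 profiles")
    if compendium.n_genes < 2:
        raise ValueError("need >=2 genes")
    if compendium.scale == "linear":
        normalized = quantile_normalize(compendium)
        reference = np.sort(compendium.values, axis=0).mean(axis=1)
        values = np.log2(normalized.values + 1.0)
    else:
        reference = None
        values = compendium.values
    variances = values.var(axis=1)
    keep = variances > 0
    dropped = [g for g, k in zip(compendium.gene_ids, keep) if not k]
    values_kept = values[keep]
    gene_ids = [g for g, k in zip(compendium.gene_ids, keep) if k]
    if len(gene_ids) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(values_kept)
    # SVD of a symmetric PSD matrix: singular values are the eigenvalues.
    u, s, _ = np.linalg.svd(corr, hermitian=True)
    return EigengeneBasis(
        gene_ids=gene_ids,
        vectors=u,
        eigenvalues=s,
        gene_means=values_kept.mean(axis=1),
        all_gene_ids=list(compendium.gene_ids),
        reference=reference,
        dropped_genes=dropped,
    )


def project(
    profile: np.ndarray,
    basis: EigengeneBasis,
    indices: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Coordinates of an already-transformed profile in eigengene space.

    ``profile`` must be aligned to ``basis.gene_ids`` and on the same
    (log2, quantile-normalized) scale as the training compendium; it is
    centered by the compendium per-gene mean and dotted with the selected
    eigenvectors.  Accepts a vector (returns a coordinate vector) or a
    genes x samples matrix (returns coordinates x samples).
    """
    profile = np.asarray(profile, dtype=float)
    vectors = basis.vectors if indices is None else basis.vectors[:, list(indices)]
    if profile.shape[0] != basis.n_genes:
        raise ValueError(
            f"profile has {profile.shape[0]} genes, basis defines {basis.n_genes}"
        )
    centered = profile - (
        basis.gene_means if profile.ndim == 1 else basis.gene_means[:, None]
    )
    return vectors.T @ centered


def transform_profiles(matrix: ExpressionMatrix, basis: EigengeneBasis) -> np.ndarray:
    """Normalize new profiles onto the basis scale and gene order.

    Linear-scale samples are quantile-normalized against the frozen training
    reference distribution (rank-mapped onto the stored sorted mean column),
    log2(x+1)-transformed, and restricted to the basis gene list.  Log2-scale
    input skips normalization.  Raises on genes missing from the input.
    """
    missing = [g for g in basis.gene_ids if g not in set(matrix.gene_ids)]
    if missing:
        raise ValueError(f"profiles lack basis genes: {missing[:5]}")
    if matrix.scale == "linear":
        if basis.reference is None:
            raise ValueError("basis lacks a frozen normalization reference")
        full_order = {g: i for i, g in enumerate(matrix.gene_ids)}
        rows = [full_order[g] for g in basis.all_gene_ids if g in full_order]
        if len(rows) != len(basis.all_gene_ids):
            absent = set(basis.all_gene_ids) - set(matrix.gene_ids)
            raise ValueError(f"profiles lack reference genes: {sorted(absent)[:5]}")
        values = matrix.values[rows]
        n = values.shape[0]
        positions = np.arange(1, n + 1, dtype=float)
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            ranks = stats.rankdata(values[:, j], method="average")
            out[:, j] = np.interp(ranks, positions, basis.reference)
        values = np.log2(out + 1.0)
        id_order = {g: i for i, g in enumerate(basis.all_gene_ids)}
        keep = [id_order[g] for g in basis.gene_ids]
        return values[keep]
    order = {g: i for i, g in enumerate(matrix.gene_ids)}
    return matrix.values[[order[g] for g in basis.gene_ids]]


def project_samples(
    matrix: ExpressionMatrix,
    basis: EigengeneBasis,
    indices: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Transform raw profiles and project: returns samples x coordinates."""
    return project(transform_profiles(matrix, basis), basis, indices).T
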