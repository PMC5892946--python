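"""Expression-matrix container, quantile normalization, and two-group contrasts.

The container is deliberately thin: an ordered gene list, an ordered sample
list, and a dense ``genes x samples`` array that is either nonnegative
linear-scale expression (count-like) or log2-transformed values.  Downstream
statistics are always computed on ``log2(x + 1)``; the pseudocount of one
keeps zero counts finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize",
    "contrast_stats",
    "significance_flags",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag.

    Parameters
    ----------
    gene_ids : ordered, unique gene identifiers (rows).
    sample_ids : ordered, unique sample identifiers (columns).
    values : dense array of shape ``(len(gene_ids), len(sample_ids))``.
    scale : ``"linear"`` (nonnegative, count-like) or ``"log2"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValueError("linear-scale expression must be nonnegative")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(sample_ids)
        meta = None
        if self.metadata is not None:
            meta = self.metadata[self.metadata["sample_id"].isin(sample_ids)]
            meta = meta.reset_index(drop=True)
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, idx], self.scale, meta
        )

    def log2(self) -> "ExpressionMatrix":
        """Return a log2(x + 1) view; identity if already on the log2 scale."""
        if self.scale == "log2":
            return self
        return replace(self, values=np.log2(self.values + 1.0), scale="log2")

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str = "linear") -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(), scale)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the across-sample mean empirical distribution.

    After normalization the sorted value vector of each column equals the mean
    of the sorted columns of the input; ties within a column receive the mean
    of the reference values at the tied ranks.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile_normalize with a single sample is the identity")
        return matrix
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return replace(matrix, values=out)


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances.

    With few replicates, per-gene variance estimates are unstable; the field's
    differential-expression tools therefore pool dispersion information across
    genes.  This is the standard squeeze: the observed variances are modeled
    as scaled chi-square draws around a common prior variance ``s0^2`` with
    prior degrees of freedom ``d0`` fitted by the method of moments on
    ``log s^2``; the posterior variance is the df-weighted blend
    ``(d0 s0^2 + df s^2) / (d0 + df)``.  Returns ``(posterior_s2, d0)``;
    ``d0 = inf`` (complete pooling) when the observed spread of ``log s^2``
    does not exceed its sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return s2.copy(), 0.0
    e = np.log(positive)
    e_var = float(np.var(e, ddof=1))
    sampling = float(special.polygamma(1, df / 2.0))
    excess = e_var - sampling
    if excess <= 1e-12:
        d0 = np.inf
        log_s0 = float(np.mean(e)) - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
        s0_2 = float(np.exp(log_s0))
        return np.full_like(s2, s0_2), d0
    # invert trigamma(d0/2) = excess by Newton iteration (monotone decreasing)
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / excess) / special.polygamma(2, x)
        x = max(x + step, 1e-8)
        if abs(tri - excess) < 1e-10 * excess:
            break
    d0 = 2.0 * x
    log_s0 = (
        float(np.mean(e))
        - float(special.digamma(df / 2.0))
        + np.log(df / 2.0)
        + float(special.digamma(x))
        - np.log(x)
    )
    s0_2 = float(np.exp(log_s0))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def _welch_p(a: np.ndarray, b: np.ndarray, moderate: bool = True) -> np.ndarray:
    """Per-row two-group unequal-variance p-values.

    With ``moderate`` (default) each group's per-gene variance is squeezed
    toward the genome-wide prior before the Welch statistic is formed,
    stabilizing tests at triplicate sample sizes the way dispersion-pooling
    GLMs do.  Rows where both groups are constant get p = 1 when the means
    agree and p = 0 when they differ (the vanishing-variance limit).
    """
    n1, n2 = a.shape[1], b.shape[1]
    if moderate:
        s2a, d0a = _squeeze_variances(a.var(axis=1, ddof=1), n1 - 1)
        s2b, d0b = _squeeze_variances(b.var(axis=1, ddof=1), n2 - 1)
        va, vb = s2a / n1, s2b / n2
        denom2 = va + vb
        mean_diff = a.mean(axis=1) - b.mean(axis=1)
        dfa = min(d0a, 1e6) + n1 - 1
        dfb = min(d0b, 1e6) + n2 - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_diff / np.sqrt(denom2)
            df = denom2**2 / (va**2 / dfa + vb**2 / dfb)
            p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        mean_diff = a.mean(axis=1) - b.mean(axis=1)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        p[degenerate & (mean_diff == 0)] = 1.0
        p[degenerate & (mean_diff != 0)] = 0.0
    return p


def contrast_stats(
    matrix: ExpressionMatrix,
    initial: Sequence[str],
    final: Sequence[str],
    batch: dict[str, str] | None = None,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-gene two-group contrast: log2 fold change, Welch p, BH-adjusted p.

    ``log2fc`` is mean ``log2(final + 1)`` minus mean ``log2(initial + 1)``.
    The p-value is a two-group unequal-variance comparison on log2 values;
    ``moderate`` (default) shrinks per-gene variances toward the genome-wide
    prior (see :func:`_squeeze_variances`) before forming the statistic.
    If ``batch`` maps sample ids to batch labels, log2 values are mean-centered
    per batch before testing (off by default).

    Returns a DataFrame indexed by gene id with columns ``log2fc, p, p_adj``.
    """
    initial = list(initial)
    final = list(final)
    if set(initial) & set(final):
        raise ValueError("initial and final sample groups overlap")
    if len(initial) < 2 or len(final) < 2:
        raise ValueError("need >=2 replicates per group")
    log = matrix.log2()
    values = log.values
    if batch is not None:
        values = values.copy()
        labels = np.array([batch[s] for s in log.sample_ids])
        for lab in np.unique(labels):
            cols = labels == lab
            values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    a = values[:, matrix.sample_index(final)]
    b = values[:, matrix.sample_index(initial)]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = _welch_p(a, b, moderate=moderate)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "p_adj": p_adj},
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def significance_flags(
    contrast: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
) -> pd.Series:
    """Boolean per-gene flags: |fold change| above a linear-scale threshold and
    adjusted p below threshold (the standard differential-expression call)."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    flag = (np.abs(contrast["log2fc"]) > np.log2(fc_threshold)) & (
        contrast["p_adj"] < p_threshold
    )
    return flag.rename("significant")
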