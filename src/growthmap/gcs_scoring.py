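"""Gene Change Score (GCS) and Venn classification of adaptive responses.

Each gene's transcriptional response to a deletion followed by adaptive
evolution is classified as restorative (R-AE: evolution returns expression to
the WT level) or compensatory (C-AE: evolution moves expression to a state
distinct from WT).  The GCS summarizes six Boolean conditions on the
deletion-vs-WT and sup-vs-deletion fold changes and significances, normalized
to [-1, +1], positive for restorative (opposite-sign fold changes) and
negative for compensatory (same-sign).  Scores are averaged over a grid of
fold-change and significance thresholds spanning the 95th-99th percentiles of
the pooled contrast statistics so that no single threshold choice dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GcsConfig",
    "venn_classify",
    "gcs_single",
    "gcs_scores",
    "grid_thresholds",
    "gcs_grid",
    "select_response_genes",
]


@dataclass(frozen=True)
class GcsConfig:
    """Threshold-grid and cut-off configuration for GCS scoring."""

    percentile_lo: float = 95.0
    percentile_hi: float = 99.0
    grid_side: int = 5
    hi_cut: float = 0.4
    lo_cut: float = -0.2
    use_adjusted_p: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.percentile_lo < self.percentile_hi < 100):
            raise ValueError("need 0 < percentile_lo < percentile_hi < 100")
        if self.grid_side < 1:
            raise ValueError("grid_side must be >= 1")
        if not (self.lo_cut < 0 < self.hi_cut):
            raise ValueError("cuts must straddle zero")


def venn_classify(
    flag_del: Sequence[bool],
    flag_ae: Sequence[bool],
    flag_wt_sup: Sequence[bool],
) -> np.ndarray:
    """Label genes from the three pairwise significance flags.

    Significant in the deletion and the AE contrast only -> R-AE (evolution
    reverted the deletion's effect, leaving WT-vs-sup unchanged).  Significant
    in all three contrasts, or in any pair that includes WT-vs-sup -> C-AE.
    Anything else -> none.
    """
    d = np.asarray(flag_del, dtype=bool)
    a = np.asarray(flag_ae, dtype=bool)
    w = np.asarray(flag_wt_sup, dtype=bool)
    if not (d.shape == a.shape == w.shape):
        raise ValueError("flag vectors must share a gene list")
    labels = np.full(d.shape, "none", dtype=object)
    labels[d & a & ~w] = "R-AE"
    labels[w & (d | a)] = "C-AE"
    return labels


def gcs_scores(
    lfc_del: np.ndarray,
    p_del: np.ndarray,
    lfc_ae: np.ndarray,
    p_ae: np.ndarray,
    p_wt_sup: np.ndarray,
    fc_thr: float,
    p_thr: float,
) -> np.ndarray:
    """Vectorized GCS at a single (fold-change, p-value) threshold pair.

    Six Booleans per gene:
      P  deletion change significant          (p_del < p_thr)
      Q  deletion |log2fc| above threshold    (|lfc_del| > fc_thr)
      R  AE change significant                (p_ae < p_thr)
      S  AE |log2fc| above threshold          (|lfc_ae| > fc_thr)
      T  opposite signs and equal magnitude — threshold-relative:
         sign(lfc_del) != sign(lfc_ae) and |lfc_del + lfc_ae| <= fc_thr
         (the net WT->sup change falls below threshold, i.e. restoration)
      U  same sign and WT-vs-sup significant  (p_wt_sup < p_thr)
    T and U are mutually exclusive by construction.  Genes with neither P nor
    R score 0.  Otherwise score = (P+Q+R+S+T+U)/5, signed positive when the
    fold changes oppose (restorative) and negative when they agree.
    ``fc_thr`` is in log2 units.
    """
    if fc_thr <= 0 or p_thr <= 0:
        raise ValueError("thresholds must be positive")
    arrays = [np.asarray(x, dtype=float) for x in (lfc_del, p_del, lfc_ae, p_ae, p_wt_sup)]
    if any(not np.all(np.isfinite(x)) for x in arrays):
        raise ValueError("non-finite inputs")
    lfc_del, p_del, lfc_ae, p_ae, p_wt_sup = arrays
    opposite = lfc_del * lfc_ae < 0
    same = lfc_del * lfc_ae > 0
    P = p_del < p_thr
    Q = np.abs(lfc_del) > fc_thr
    R = p_ae < p_thr
    S = np.abs(lfc_ae) > fc_thr
    T = opposite & (np.abs(lfc_del + lfc_ae) <= fc_thr)
    U = same & (p_wt_sup < p_thr)
    total = (
        P.astype(float) + Q + R + S + T + U
    ) / 5.0
    sign = np.where(opposite, 1.0, np.where(same, -1.0, 0.0))
    score = sign * total
    score[~(P | R)] = 0.0
    return score


def gcs_single(
    lfc_del: float,
    p_del: float,
    lfc_ae: float,
    p_ae: float,
    p_wt_sup: float,
    fc_thr: float,
    p_thr: float,
) -> float:
    """Scalar convenience wrapper around :func:`gcs_scores`."""
    return float(
        gcs_scores(
            np.array([lfc_del]),
            np.array([p_del]),
            np.array([lfc_ae]),
            np.array([p_ae]),
            np.array([p_wt_sup]),
            fc_thr,
            p_thr,
        )[0]
    )


def grid_thresholds(
    del_contrast: pd.DataFrame,
    ae_contrast: pd.DataFrame,
    cfg: GcsConfig = GcsConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold axes for the scoring grid, recomputed per deletion family.

    Fold-change thresholds are ``grid_side`` evenly spaced percentiles
    (``percentile_lo`` .. ``percentile_hi``) of |log2fc| pooled over the
    deletion and AE contrasts; significance thresholds are the same
    percentiles of pooled -log10(p), converted back to p-values.
    """
    pcol = "p_adj" if cfg.use_adjusted_p else "p"
    lfc = np.abs(
        np.concatenate([del_contrast["log2fc"].to_numpy(), ae_contrast["log2fc"].to_numpy()])
    )
    logp = -np.log10(
        np.maximum(
            np.concatenate([del_contrast[pcol].to_numpy(), ae_contrast[pcol].to_numpy()]),
            1e-300,
        )
    )
    if lfc.size < 20:
        raise ValueError("too few genes to define percentile thresholds")
    qs = np.linspace(cfg.percentile_lo, cfg.percentile_hi, cfg.grid_side)
    fc_thresholds = np.percentile(lfc, qs)
    p_thresholds = 10.0 ** (-np.percentile(logp, qs))
    fc_thresholds = np.maximum(fc_thresholds, 1e-9)
    return fc_thresholds, p_thresholds


def gcs_grid(
    del_contrast: pd.DataFrame,
    ae_contrast: pd.DataFrame,
    wt_sup_contrast: pd.DataFrame,
    cfg: GcsConfig = GcsConfig(),
) -> pd.DataFrame:
    """Average the GCS over the full threshold grid.

    The three contrasts must share a gene index: deletion vs WT, sup vs
    deletion (the AE step), and sup vs WT.  Returns a DataFrame indexed by
    gene with columns ``score`` (mean over the ``grid_side**2`` threshold
    pairs) and ``label`` (R-AE above ``hi_cut``, C-AE below ``lo_cut``,
    strict inequalities, else none).
    """
    if not (
        del_contrast.index.equals(ae_contrast.index)
        and del_contrast.index.equals(wt_sup_contrast.index)
    ):
        raise ValueError("contrasts must share one gene index")
    pcol = "p_adj" if cfg.use_adjusted_p else "p"
    fc_thresholds, p_thresholds = grid_thresholds(del_contrast, ae_contrast, cfg)
    acc = np.zeros(len(del_contrast), dtype=float)
    for fc_thr in fc_thresholds:
        for p_thr in p_thresholds:
            acc += gcs_scores(
                del_contrast["log2fc"].to_numpy(),
                del_contrast[pcol].to_numpy(),
                ae_contrast["log2fc"].to_numpy(),
                ae_contrast[pcol].to_numpy(),
                wt_sup_contrast[pcol].to_numpy(),
                fc_thr,
                p_thr,
            )
    score = acc / (cfg.grid_side**2)
    label = np.full(score.shape, "none", dtype=object)
    label[score > cfg.hi_cut] = "R-AE"
    label[score < cfg.lo_cut] = "C-AE"
    return pd.DataFrame({"score": score, "label": label}, index=del_contrast.index)


def select_response_genes(
    tables: pd.DataFrame | Sequence[pd.DataFrame],
    cfg: GcsConfig = GcsConfig(),
) -> tuple[set[str], set[str]]:
    """Strongest-response gene sets from one or more GCS tables.

    Restorative = score strictly above ``hi_cut``; compensatory = strictly
    below ``lo_cut``.  When several tables are given (one per sup strain of a
    deletion family) the sets are intersected across strains.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    restorative: set[str] | None = None
    compensatory: set[str] | None = None
    for table in tables:
        r = set(table.index[table["score"] > cfg.hi_cut])
        c = set(table.index[table["score"] < cfg.lo_cut])
        restorative = r if restorative is None else restorative & r
        compensatory = c if compensatory is None else compensatory & c
    return restorative or set(), compensatory or set()
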