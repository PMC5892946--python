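"""Growth-rate fitting, fitness comparison, and synthetic-rescue classification.

Specific growth rate k (1/h) is the least-squares slope of ln(OD600) against
time over the log-linear region of a growth curve, i.e. the exponent of
OD600(t) = e^{kt}.  Synthetic rescue is the epistasis pattern in which a
mutation set that is neutral or deleterious alone becomes beneficial in
combination with a deleterious primary mutation; calls are made from
replicate-level fitness of the four backgrounds WT, WT+D (primary deletion),
WT+D+AE (deletion plus adaptively evolved sup mutations), and WT+AE (sup
mutations knocked into the WT background).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ODSeries",
    "RescueCall",
    "BACKGROUNDS",
    "fit_growth_rate",
    "compare_fitness",
    "classify_synthetic_rescue",
    "summarize_mutations",
]

#: Canonical background labels for rescue classification.
BACKGROUNDS = ("WT", "WT+D", "WT+D+AE", "WT+AE")


@dataclass(frozen=True)
class ODSeries:
    """An OD600 time course: strictly increasing times (h), positive ODs."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.size != self.od.size:
            raise ValueError("times and od lengths differ")
        if self.times.size < 3:
            raise ValueError("need >=3 points")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.od))):
            raise ValueError("non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _ln_fit(t: np.ndarray, ln_od: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of ln(OD) vs t."""
    slope, intercept = np.polyfit(t, ln_od, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((ln_od - fitted) ** 2))
    ss_tot = float(np.sum((ln_od - ln_od.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def fit_growth_rate(
    series: ODSeries, window: tuple[int, int] | None = None
) -> float:
    """Specific growth rate (1/h): slope of ln(OD600) vs time.

    ``window`` is an inclusive-exclusive index range restricting the fit; when
    absent the log-linear region is auto-detected as the longest contiguous
    run of >=4 points whose ln-fit R^2 is within 1e-3 of the best achievable
    over all such windows (a pure exponential therefore uses every point).
    Negative slopes are reported as-is (death phases are not clamped).
    """
    if np.any(series.od <= 0):
        raise ValueError("nonpositive OD600 values cannot be log-fitted")
    t, ln_od = series.times, np.log(series.od)
    if window is not None:
        lo, hi = window
        t, ln_od = t[lo:hi], ln_od[lo:hi]
        if t.size < 3:
            raise ValueError("window leaves <3 usable points")
        return _ln_fit(t, ln_od)[0]
    n = t.size
    min_len = min(4, n)
    candidates = []
    for length in range(min_len, n + 1):
        for start in range(0, n - length + 1):
            slope, r2 = _ln_fit(t[start : start + length], ln_od[start : start + length])
            candidates.append((r2, length, -start, slope))
    best_r2 = max(c[0] for c in candidates)
    eligible = [c for c in candidates if c[0] >= best_r2 - 1e-3]
    # prefer the longest (then earliest) near-optimal window
    eligible.sort(key=lambda c: (c[1], c[2]), reverse=True)
    return eligible[0][3]


def compare_fitness(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> str:
    """Two-sided Welch comparison of replicate growth rates.

    Returns ``"greater"`` / ``"less"`` (a relative to b) when significant at
    level ``alpha``, otherwise ``"indistinguishable"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 replicates per group")
    if np.array_equal(a, b) or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
        if a.mean() == b.mean():
            return "indistinguishable"
        return "greater" if a.mean() > b.mean() else "less"
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    if p < alpha:
        return "greater" if a.mean() > b.mean() else "less"
    return "indistinguishable"


@dataclass(frozen=True)
class RescueCall:
    """One classified synthetic-rescue combination."""

    direction: str  # "forward" | "reverse"
    medium: str
    condition_flags: tuple[bool, bool, bool]

    @property
    def is_rescue(self) -> bool:
        return all(self.condition_flags)


def _rates(table: pd.DataFrame, background: str, medium: str) -> np.ndarray:
    sel = table[(table["background"] == background) & (table["medium"] == medium)]
    return sel["rate_per_h"].to_numpy(dtype=float)


def classify_synthetic_rescue(
    table: pd.DataFrame, alpha: float = 0.05
) -> list[RescueCall]:
    """Evaluate forward and reverse synthetic-rescue conditions per medium.

    ``table`` needs columns ``background`` (one of WT, WT+D, WT+D+AE, WT+AE),
    ``medium`` and ``rate_per_h``, with >=2 replicates per background.

    Forward rescue (deletion first, then sup mutations):
      (i)   F(WT+D)    significantly < F(WT)          — deletion deleterious
      (ii)  F(WT+D+AE) significantly > F(WT+D)        — sup mutations rescue
      (iii) F(WT+AE)   NOT significantly > F(WT)      — sup neutral at best

    Reverse rescue (sup strain as starting point; mutations applied in the
    reverse order): reverting the AE mutations is deleterious, restoring the
    deletion afterwards is beneficial, and restoring the deletion in the sup
    strain itself is neutral at best:
      (i)   F(WT+D)    significantly < F(WT+D+AE)
      (ii)  F(WT)      significantly > F(WT+D)
      (iii) F(WT+AE)   NOT significantly > F(WT+D+AE)

    Returns a list of :class:`RescueCall`, one per (direction, medium) whose
    three conditions all hold.
    """
    required = {"background", "medium", "rate_per_h"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    calls: list[RescueCall] = []
    for medium in sorted(table["medium"].unique()):
        groups = {}
        for bg in BACKGROUNDS:
            r = _rates(table, bg, medium)
            if r.size == 0:
                raise ValueError(f"missing background {bg!r} for medium {medium!r}")
            if r.size < 2:
                raise ValueError(f"background {bg!r} has <2 replicates")
            groups[bg] = r
        wt, d, dae, ae = (groups[b] for b in BACKGROUNDS)
        forward = (
            compare_fitness(d, wt, alpha) == "less",
            compare_fitness(dae, d, alpha) == "greater",
            compare_fitness(ae, wt, alpha) != "greater",
        )
        if all(forward):
            calls.append(RescueCall("forward", medium, forward))
        reverse = (
            compare_fitness(d, dae, alpha) == "less",
            compare_fitness(wt, d, alpha) == "greater",
            compare_fitness(ae, dae, alpha) != "greater",
        )
        if all(reverse):
            calls.append(RescueCall("reverse", medium, reverse))
    return calls


def summarize_mutations(
    records: pd.DataFrame,
    loci: Iterable[str],
    strains: Iterable[str] | None = None,
) -> int:
    """Count distinct strains with at least one lesion in any of ``loci``.

    ``records`` needs columns ``strain`` and ``locus``; ``strains`` optionally
    restricts the strains considered (e.g. sup strains only).  Unknown locus
    ids simply match nothing.  Duplicated records do not inflate the count.
    """
    if records.empty:
        return 0
    loci = set(loci)
    sel = records[records["locus"].isin(loci)]
    if strains is not None:
        sel = sel[sel["strain"].isin(set(strains))]
    return int(sel["strain"].nunique())
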