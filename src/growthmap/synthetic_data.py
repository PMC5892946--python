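"""Synthetic inputs for the whole pipeline.

Generators for (a) expression compendia with low-dimensional latent structure
that drives growth rate, (b) WT / deletion / suppressor strain triplets with
planted restored and compensated gene sets and a per-day batch effect,
(c) exponential OD600 curves with multiplicative noise, and (d) packaged
transcriptions of the study's mutation and synthetic-rescue tables.

The count-noise model throughout is the mean-variance law

    sigma^2 = mu * (1 + beta) + alpha * mu^2

with dispersion hyper-parameters ``alpha`` (quadratic) and ``beta`` (linear
overdispersion); the defaults are the DESeq-estimated values for the study's
RNA-seq compendium (alpha = 0.217, beta = 0.539).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .expression_core import ExpressionMatrix

__all__ = [
    "NoiseModel",
    "DEFAULT_NOISE",
    "CompendiumSpec",
    "TripletSpec",
    "generate_compendium",
    "generate_triplets",
    "generate_od_series",
    "simulate_noisy_counts",
    "fit_noise_model",
    "packaged_fixtures",
]


@dataclass(frozen=True)
class NoiseModel:
    """Mean-variance dispersion law ``sigma^2 = mu (1 + beta) + alpha mu^2``.

    ``alpha >= 0``; ``beta >= -1`` so the variance is nonnegative for all
    ``mu >= 0``.  ``NoiseModel(0.0, -1.0)`` is the exact zero-noise element.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta < -1:
            raise ValueError("beta must be >= -1 (nonnegative variance)")

    def variance(self, mu: np.ndarray | float) -> np.ndarray | float:
        mu = np.asarray(mu, dtype=float) if not np.isscalar(mu) else float(mu)
        return mu * (1.0 + self.beta) + self.alpha * mu**2


#: Dispersion hyper-parameters estimated for the study compendium (DESeq fit).
DEFAULT_NOISE = NoiseModel(alpha=0.217, beta=0.539)


def simulate_noisy_counts(
    means: np.ndarray,
    n_replicates: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    clip_negative: bool = True,
) -> np.ndarray:
    """Draw Gaussian replicates of ``means`` under the mean-variance law.

    ``means`` is a 1-D array of per-gene linear-scale means; the result has
    shape ``(len(means), n_replicates)``.  ``clip_negative`` floors draws at
    zero, keeping values physical (counts cannot be negative); disable it to
    sample the unclipped generating law itself.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means < 0):
        raise ValueError("means must be nonnegative")
    sd = np.sqrt(noise.variance(means))
    draws = means[:, None] + rng.normal(size=(means.size, n_replicates)) * sd[:, None]
    if clip_negative:
        np.clip(draws, 0.0, None, out=draws)
    return draws


def fit_noise_model(counts: np.ndarray, n_iter: int = 2, min_mean: float = 2.0):
    """Re-estimate (alpha, beta) from replicated counts by least squares.

    Regresses per-gene sample variance on (sample mean, sample mean squared)
    without intercept, so the coefficients are ``(1 + beta, alpha)``.  Because
    the sampling noise of a sample variance scales with ``sigma^4``, the fit is
    an iterated weighted least squares with weights ``1 / fitted-variance^2``
    (a plain OLS would be dominated by the few largest-mean genes).  Genes
    with sample mean below ``min_mean`` are excluded: at such low expression
    the estimated mean is itself noise-dominated, which biases the linear
    coefficient — the usual low-count filter of dispersion estimators.

    Returns ``(noise_model, stderr_alpha, stderr_beta)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 3:
        raise ValueError("need a genes x replicates array with >=3 replicates")
    mu = counts.mean(axis=1)
    s2 = counts.var(axis=1, ddof=1)
    keep = mu >= max(min_mean, 1e-12)
    if keep.sum() < 10:
        raise ValueError("too few genes above min_mean for the dispersion fit")
    mu, s2 = mu[keep], s2[keep]
    X = np.column_stack([mu, mu**2])
    weights = 1.0 / np.maximum(mu + mu**2, 1e-12) ** 2
    fit = None
    for _ in range(max(1, n_iter)):
        fit = sm.WLS(s2, X, weights=weights).fit()
        predicted = np.maximum(X @ fit.params, 1e-12)
        weights = 1.0 / predicted**2
    beta = float(fit.params[0] - 1.0)
    alpha = float(fit.params[1])
    se_beta = float(fit.bse[0])
    se_alpha = float(fit.bse[1])
    return NoiseModel(alpha=max(alpha, 0.0), beta=max(beta, -1.0)), se_alpha, se_beta


@dataclass(frozen=True)
class CompendiumSpec:
    """Design of a synthetic expression compendium.

    A ``latent_dim``-dimensional latent state drives both expression (through
    gene loadings, in log2 units) and growth rate (through an affine link).
    Exactly ``n_with_growth`` profiles carry growth-rate annotations.
    Per-gene baseline means are log-uniform on ``mean_range`` (the marginal
    distribution of means in real compendia is not standardized; log-uniform
    over 1..1e4 spans the observed dynamic range).
    """

    n_genes: int = 500
    n_profiles: int = 300
    n_with_growth: int = 150
    latent_dim: int = 3
    growth_intercept: float = 0.7
    growth_link: tuple[float, ...] = (0.25, 0.15, 0.10)
    growth_noise_sd: float = 0.02
    loading_sd: float = 0.5
    mean_range: tuple[float, float] = (1.0, 1.0e4)
    noise: NoiseModel = DEFAULT_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_profiles < 2:
            raise ValueError("n_profiles must be >= 2")
        if self.n_with_growth > self.n_profiles:
            raise ValueError("n_with_growth must be <= n_profiles")
        if self.latent_dim >= min(self.n_genes, self.n_profiles):
            raise ValueError("latent_dim must be < min(n_genes, n_profiles)")
        if len(self.growth_link) != self.latent_dim:
            raise ValueError(
                f"growth_link has {len(self.growth_link)} coefficients for "
                f"latent_dim={self.latent_dim}"
            )


def generate_compendium(
    spec: CompendiumSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a compendium and its growth table.

    Expression: per-gene log2 mean plus ``loadings @ latent`` (log2 units),
    exponentiated to the linear scale, then perturbed by heteroscedastic
    noise obeying ``spec.noise``.  The noise draw is a moment-matched
    lognormal (mean equal to the latent-driven mean, variance equal to the
    mean-variance law): values stay positive by construction, so the law is
    satisfied exactly rather than distorted by truncation at zero.  Growth
    rate for the first ``n_with_growth`` profiles is
    ``max(0, c0 + c . z + eps)`` with ``eps ~ Normal(0, growth_noise_sd)`` —
    clamping keeps rates physical.

    Returns ``(matrix, growth)`` where ``growth`` has columns
    ``sample_id, medium, rate_per_h`` plus the latent coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    G, N, m = spec.n_genes, spec.n_profiles, spec.n_with_growth
    lo, hi = spec.mean_range
    base_log2 = rng.uniform(np.log2(lo), np.log2(hi), size=G)
    latent = rng.normal(size=(spec.latent_dim, N))
    loadings = rng.normal(0.0, spec.loading_sd, size=(G, spec.latent_dim))
    log2_mean = base_log2[:, None] + loadings @ latent
    linear_mean = 2.0**log2_mean
    rel_var = spec.noise.variance(linear_mean) / np.maximum(linear_mean, 1e-300) ** 2
    tau2 = np.log1p(rel_var)
    values = np.exp(
        np.log(linear_mean) - tau2 / 2.0 + np.sqrt(tau2) * rng.normal(size=(G, N))
    )

    gene_ids = [f"g{i:04d}" for i in range(G)]
    sample_ids = [f"s{j:04d}" for j in range(N)]
    link = np.asarray(spec.growth_link)
    rates = spec.growth_intercept + link @ latent[:, :m]
    rates = rates + rng.normal(0.0, spec.growth_noise_sd, size=m)
    np.clip(rates, 0.0, None, out=rates)
    growth = pd.DataFrame(
        {
            "sample_id": sample_ids[:m],
            "medium": "M9G",
            "rate_per_h": rates,
        }
    )
    for d in range(spec.latent_dim):
        growth[f"latent_{d}"] = latent[d, :m]
    matrix = ExpressionMatrix(gene_ids, sample_ids, values, scale="linear")
    return matrix, growth


@dataclass(frozen=True)
class TripletSpec:
    """Planted WT / deletion / suppressor triplet design.

    ``restored_genes`` shift by ``effect_size`` (log2) in the deletion strain
    and revert to the WT level in the suppressor.  ``compensated_genes`` shift
    by ``effect_size`` in the deletion strain and by a further ``effect_size``
    in the same direction in the suppressor, ending in a state distinct from
    both WT and deletion — the fully compensatory expression pattern.

    ``replicate_log2_sd`` is within-condition replicate noise (log2 units);
    ``batch_sd`` is an additive per-replicate-day log2 offset shared across
    genes and strains, emulating day-of-collection batch structure.
    """

    restored_genes: frozenset[str] = frozenset()
    compensated_genes: frozenset[str] = frozenset()
    effect_size: float = 2.0
    n_replicates: int = 3
    batch_sd: float = 0.15
    replicate_log2_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "restored_genes", frozenset(self.restored_genes))
        object.__setattr__(self, "compensated_genes", frozenset(self.compensated_genes))
        if self.restored_genes & self.compensated_genes:
            raise ValueError("restored and compensated gene sets overlap")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


ROLES = ("WT", "deletion", "sup")


def generate_triplets(
    spec: TripletSpec, baseline: ExpressionMatrix
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Emit WT, deletion, and sup samples with planted response structure.

    Per-gene log2 baselines are the log2(mean + 1) of the baseline matrix.
    Values are emitted on the linear scale (``2^y - 1``, floored at zero) so
    the downstream ``log2(x + 1)`` transform recovers the planted log2 fold
    changes exactly in the zero-noise limit.

    Returns ``(matrix, metadata)`` with metadata columns
    ``sample_id, strain, role, replicate, batch``.
    """
    unknown = (spec.restored_genes | spec.compensated_genes) - set(baseline.gene_ids)
    if unknown:
        raise ValueError(f"planted genes absent from baseline: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(spec.seed)
    base = np.log2(baseline.values.mean(axis=1) + 1.0)
    restored = np.isin(baseline.gene_ids, list(spec.restored_genes))
    compensated = np.isin(baseline.gene_ids, list(spec.compensated_genes))
    e = spec.effect_size
    targets = {
        "WT": base,
        "deletion": base + e * restored + e * compensated,
        "sup": base + 2.0 * e * compensated,
    }
    batch_offsets = rng.normal(0.0, spec.batch_sd, size=spec.n_replicates)
    columns, ids, meta = [], [], []
    for role in ROLES:
        for r in range(spec.n_replicates):
            y = (
                targets[role]
                + batch_offsets[r]
                + rng.normal(0.0, spec.replicate_log2_sd, size=base.size)
            )
            columns.append(np.clip(2.0**y - 1.0, 0.0, None))
            sid = f"{role}_r{r + 1}"
            ids.append(sid)
            meta.append(
                {
                    "sample_id": sid,
                    "strain": role,
                    "role": role,
                    "replicate": r + 1,
                    "batch": f"day{r + 1}",
                }
            )
    matrix = ExpressionMatrix(
        list(baseline.gene_ids), ids, np.column_stack(columns), scale="linear"
    )
    return matrix, pd.DataFrame(meta)


def generate_od_series(
    rate: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> "ODSeries":
    """OD600(t) = exp(rate * t) * (1 + eps), eps ~ Normal(0, noise_sd)."""
    from .growth_phenotypes import ODSeries  # local import avoids a cycle

    times = np.asarray(times, dtype=float)
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    od = np.exp(rate * times)
    if noise_sd > 0:
        od = od * (1.0 + rng.normal(0.0, noise_sd, size=times.size))
    return ODSeries(times=times, od=np.maximum(od, 1e-9))


def packaged_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSV-backed transcriptions of the study's mutation and rescue tables.

    Returns ``(mutations, rescues)``.  The mutation table lists one row per
    mapped lesion (strain, parent, position, mutation, coding change, locus)
    for the 12 fast strains evolved from WT and the 16 sup strains evolved
    from deletion parents.  The rescue table lists the forward and reverse
    synthetic-rescue mutation combinations with their growth media.
    """
    root = resources.files("growthmap").joinpath("data")
    with resources.as_file(root.joinpath("table1_mutations.tsv")) as p:
        mutations = pd.read_csv(p, sep="\t")
    with resources.as_file(root.joinpath("table3_rescues.tsv")) as p:
        rescues = pd.read_csv(p, sep="\t")
    return mutations, rescues
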