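"""Distance-weighted KNN mapping from eigengene coordinates to growth rate.

The model assumes growth rate is uniquely determined by gene expression:
a query profile, projected onto a small set of eigengenes, is assigned the
inverse-squared-distance weighted average of the growth rates of its k
nearest training profiles.  Training is robustified two ways: noisy
pseudo-profiles simulated per gene under the mean-variance law (four per real
profile, inheriting the parent's growth rate) desensitize the model to count
noise, and zero-growth pseudo-counts placed on a spherical shell around the
training center of mass damp extrapolation toward non-physical expression
states.  Eigengenes are chosen by greedy forward selection under a
cross-validated residual objective regularized by a log-occupation ratio that
penalizes sparsely occupied expression-growth bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression_core import ExpressionMatrix
from .eigengene_space import EigengeneBasis, compute_basis, project_samples
from .synthetic_data import NoiseModel, DEFAULT_NOISE

__all__ = [
    "SelectionConfig",
    "KnnGrowthModel",
    "TrainingCorpus",
    "knn_weights",
    "predict_growth",
    "predict_many",
    "make_noise_profiles",
    "make_pseudocounts",
    "stratified_folds",
    "residual_score",
    "log_occupation_ratio",
    "occupancy_log_ratio",
    "cross_validate",
    "forward_select",
    "train_from_compendium",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of cross-validated forward selection.

    ``lam`` trades residual error against the log-occupation ratio;
    ``n_growth_bins`` (N_f = 13) and decile projection bins (merged when
    adjacent bin means are closer than ``merge_fraction`` of the mean
    absolute projection) define the occupancy grid.  ``pair_divisor`` sets
    the pseudo-count budget m(m-1)/pair_divisor; ``pseudo_multiplier`` the
    number of noisy pseudo-profiles per real profile.
    """

    lam: float = 0.1
    n_growth_bins: int = 13
    n_projection_bins: int = 10
    merge_fraction: float = 0.10
    n_folds: int = 5
    pseudo_multiplier: int = 4
    pair_divisor: int = 16

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_growth_bins < 2:
            raise ValueError("n_growth_bins must be >= 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class TrainingCorpus:
    """Bookkeeping for the composition of an expression-growth training corpus.

    A corpus combines a curated collection (profiles with and without growth
    annotations) with newly measured profiles that all carry growth rates.
    ``n_with_growth`` (m) counts profiles usable for regression;
    ``n_profiles`` (N) counts all profiles usable for estimating gene-gene
    correlations.
    """

    n_curated_with_growth: int = 589
    n_curated_without_growth: int = 1607
    n_measured_with_growth: int = 57

    @property
    def n_with_growth(self) -> int:
        return self.n_curated_with_growth + self.n_measured_with_growth

    @property
    def n_profiles(self) -> int:
        return (
            self.n_curated_with_growth
            + self.n_curated_without_growth
            + self.n_measured_with_growth
        )


@dataclass
class KnnGrowthModel:
    """Fitted KNN regressor over selected eigengene coordinates."""

    coords: np.ndarray
    growth: np.ndarray
    k: int = 8
    selected_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.growth = np.asarray(self.growth, dtype=float)
        if self.coords.shape[0] != self.growth.size:
            raise ValueError("coords rows and growth length differ")
        if self.k > self.coords.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {self.coords.shape[0]}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite training coordinates")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "coords.tsv", self.coords, delimiter="\t")
        pd.DataFrame({"rate_per_h": self.growth}).to_csv(
            directory / "growth.tsv", sep="\t", index=False
        )
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {"k": int(self.k), "selected_indices": [int(i) for i in self.selected_indices]},
                fh,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "KnnGrowthModel":
        directory = Path(directory)
        coords = np.loadtxt(directory / "coords.tsv", delimiter="\t")
        growth = pd.read_csv(directory / "growth.tsv", sep="\t")["rate_per_h"].to_numpy()
        with open(directory / "config.yaml") as fh:
            cfg = yaml.safe_load(fh)
        if coords.ndim == 1:
            coords = coords[:, None]
        return cls(coords, growth, k=cfg["k"], selected_indices=cfg["selected_indices"])


# ---------------------------------------------------------------------------
# core KNN machinery


def knn_weights(query: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """Inverse-squared-distance weights, normalized to sum to one.

    An exact-match neighbor (distance zero) takes all the weight — the limit
    of the weighting rule — with ties broken by neighbor order.
    """
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.shape[0] == 0:
        raise ValueError("empty neighbor set")
    query = np.asarray(query, dtype=float)
    d2 = np.sum((neighbors - query) ** 2, axis=1)
    weights = np.zeros(d2.size)
    zero = np.flatnonzero(d2 == 0)
    if zero.size:
        weights[zero[0]] = 1.0
        return weights
    inv = 1.0 / d2
    return inv / inv.sum()


def _nearest(query: np.ndarray, coords: np.ndarray, k: int) -> np.ndarray:
    d2 = np.sum((coords - query) ** 2, axis=1)
    return np.argsort(d2, kind="stable")[:k]  # stable: ties by training index


def predict_growth(query: np.ndarray, model: KnnGrowthModel) -> float:
    """Distance-weighted average growth of the k nearest training profiles."""
    query = np.asarray(query, dtype=float)
    if query.size != model.coords.shape[1]:
        raise ValueError("query dimension does not match model coordinates")
    idx = _nearest(query, model.coords, model.k)
    w = knn_weights(query, model.coords[idx])
    return float(w @ model.growth[idx])


def predict_many(queries: np.ndarray, model: KnnGrowthModel) -> np.ndarray:
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    return np.array([predict_growth(q, model) for q in queries])


def residual_score(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Sum of squared prediction errors."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("length mismatch")
    return float(np.sum((predicted - actual) ** 2))


# ---------------------------------------------------------------------------
# training-set augmentation


def make_noise_profiles(
    matrix: ExpressionMatrix,
    growth: np.ndarray,
    noise: NoiseModel = DEFAULT_NOISE,
    multiplier: int = 4,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Simulate noisy pseudo-profiles of each growth-annotated profile.

    For every real profile, ``multiplier`` copies are drawn gene-wise from
    Gaussian(mean = observed value, variance = mean-variance law), floored at
    zero.  Each pseudo-profile inherits its parent's growth rate.

    Returns ``(pseudo_matrix, pseudo_growth, parent_index)`` where
    ``parent_index[j]`` is the column of the real matrix that pseudo-profile
    j derives from (used to keep pseudo data inside the parent's CV fold).
    """
    if matrix.scale != "linear":
        raise ValueError("noise profiles are simulated on the linear scale")
    growth = np.asarray(growth, dtype=float)
    if growth.size != matrix.n_samples:
        raise ValueError("growth length must match sample count")
    rng = np.random.default_rng(seed)
    values = matrix.values
    sd = np.sqrt(noise.variance(values))
    cols, parents = [], []
    for j in range(matrix.n_samples):
        draws = values[:, [j]] + rng.normal(size=(matrix.n_genes, multiplier)) * sd[:, [j]]
        np.clip(draws, 0.0, None, out=draws)
        cols.append(draws)
        parents.extend([j] * multiplier)
    pseudo_values = np.concatenate(cols, axis=1)
    ids = [f"pseudo_{p}_{i}" for i, p in enumerate(parents)]
    pseudo = ExpressionMatrix(list(matrix.gene_ids), ids, pseudo_values, scale="linear")
    return pseudo, np.repeat(growth, multiplier), np.array(parents, dtype=int)


def make_pseudocounts(
    coords: np.ndarray,
    seed: int = 0,
    pair_divisor: int = 16,
) -> np.ndarray:
    """Zero-growth points on the spherical shell around the center of mass.

    The shell is centered at the mean coordinate and has radius d equal to
    the maximum pairwise distance among training points.  floor(m(m-1)/
    pair_divisor) distinct point pairs are drawn; for each, both
    intersections of the line through the pair with the shell are emitted.
    All pseudo-counts carry growth rate zero.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    m = coords.shape[0]
    if m < 2:
        raise ValueError("need >=2 training points")
    center = coords.mean(axis=0)
    diffs = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diffs**2, axis=-1))
    d = float(dist.max())
    if d == 0:
        raise ValueError("degenerate training set: all points identical")
    n_pairs = (m * (m - 1)) // pair_divisor
    n_pairs = max(n_pairs, 1)
    iu, ju = np.triu_indices(m, k=1)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(iu.size, size=min(n_pairs, iu.size), replace=False)
    points = []
    for c in chosen:
        gi, gj = coords[iu[c]], coords[ju[c]]
        u = gj - gi
        a = float(u @ u)
        if a == 0:
            continue
        v = gi - center
        b = 2.0 * float(u @ v)
        c0 = float(v @ v) - d * d
        disc = max(b * b - 4.0 * a * c0, 0.0)
        sq = np.sqrt(disc)
        for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            points.append(gi + t * u)
    if not points:
        raise ValueError("no valid pseudo-count pairs")
    return np.array(points)


def stratified_folds(
    growth: Sequence[float], n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Fold assignment preserving the growth-rate distribution in every fold.

    Samples are ranked by growth rate and dealt to folds in consecutive
    rank-blocks of size ``n_folds``, shuffled within each block, so each fold
    holds one sample per block and the folds share the growth distribution.
    """
    growth = np.asarray(growth, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > growth.size:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = np.argsort(growth, kind="stable")
    folds = np.empty(growth.size, dtype=int)
    for start in range(0, growth.size, n_folds):
        block = order[start : start + n_folds]
        labels = rng.permutation(n_folds)[: block.size]
        folds[block] = labels
    return folds


# ---------------------------------------------------------------------------
# occupancy regularizer


def log_occupation_ratio(
    n_occupied: int, n_growth_bins: int, bins_per_eigengene: Sequence[int]
) -> float:
    """L = 2 ln N_o - 2 ln N_f - sum_i ln N_i.

    The occupancy grid has one growth-rate axis (N_f bins) and one projection
    axis per selected eigengene (N_i bins each); N_o of the N_f * prod(N_i)
    cells contain at least one profile.  The (n+1)-th axis of the grid is the
    growth axis itself, so its bin count enters as a second N_f term.
    """
    if n_occupied < 1:
        raise ValueError("need at least one occupied cell")
    return float(
        2.0 * np.log(n_occupied)
        - 2.0 * np.log(n_growth_bins)
        - np.sum(np.log(np.asarray(list(bins_per_eigengene), dtype=float)))
    )


def _equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based bin assignment with near-equal counts (deterministic)."""
    order = np.argsort(values, kind="stable")
    bins = np.empty(values.size, dtype=int)
    edges = np.linspace(0, values.size, n_bins + 1).astype(int)
    for b in range(n_bins):
        bins[order[edges[b] : edges[b + 1]]] = b
    return bins


def _merged_projection_bins(
    projection: np.ndarray, n_bins: int, merge_fraction: float
) -> np.ndarray:
    """Decile bins along one eigengene, merging near-coincident neighbors.

    Adjacent bins whose mean projections differ by less than
    ``merge_fraction`` times the mean absolute projection are merged, so
    directions with little spread contribute fewer effective bins.
    """
    bins = _equal_count_bins(projection, min(n_bins, projection.size))
    scale = float(np.mean(np.abs(projection)))
    threshold = merge_fraction * scale
    while True:
        labels = np.unique(bins)
        if labels.size <= 1:
            break
        means = np.array([projection[bins == lab].mean() for lab in labels])
        gaps = np.abs(np.diff(means))
        merge_at = np.flatnonzero(gaps < threshold)
        if merge_at.size == 0:
            break
        j = merge_at[0]
        bins[bins == labels[j + 1]] = labels[j]
    # relabel 0..K-1 in order
    _, bins = np.unique(bins, return_inverse=True)
    return bins


def occupancy_log_ratio(
    coords: np.ndarray,
    growth: Sequence[float],
    cfg: SelectionConfig = SelectionConfig(),
) -> float:
    """Log-occupation ratio of profiles over the growth x projection grid."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    growth = np.asarray(growth, dtype=float)
    if coords.shape[0] != growth.size or growth.size == 0:
        raise ValueError("empty data or mismatched lengths")
    if coords.shape[1] < 1:
        raise ValueError("need at least one eigengene dimension")
    growth_bins = _equal_count_bins(growth, min(cfg.n_growth_bins, growth.size))
    axes = [growth_bins]
    bins_per_eigengene = []
    for dim in range(coords.shape[1]):
        b = _merged_projection_bins(
            coords[:, dim], cfg.n_projection_bins, cfg.merge_fraction
        )
        axes.append(b)
        bins_per_eigengene.append(int(b.max()) + 1)
    cells = np.stack(axes, axis=1)
    n_occupied = np.unique(cells, axis=0).shape[0]
    return log_occupation_ratio(n_occupied, cfg.n_growth_bins, bins_per_eigengene)


# ---------------------------------------------------------------------------
# cross-validation and forward selection


@dataclass
class CvResult:
    predictions: np.ndarray
    folds: np.ndarray
    r: float
    r2: float


def cross_validate(
    coords: np.ndarray,
    growth: np.ndarray,
    k: int = 8,
    cfg: SelectionConfig = SelectionConfig(),
    seed: int = 0,
    pseudo_coords: np.ndarray | None = None,
    pseudo_parent: np.ndarray | None = None,
    pseudo_growth: np.ndarray | None = None,
    add_pseudocounts: bool = True,
) -> CvResult:
    """Stratified k-fold CV of the KNN regressor.

    Each fold is predicted by a model trained on the remaining folds plus
    their noisy pseudo-profiles (pseudo data never leaks across folds: a
    pseudo-profile trains only when its parent does) and freshly constructed
    zero-growth pseudo-counts.  Returns the pooled out-of-fold predictions,
    the residual score r (sum of squared errors over real samples) and R^2.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    growth = np.asarray(growth, dtype=float)
    folds = stratified_folds(growth, cfg.n_folds, seed=seed)
    predictions = np.empty(growth.size)
    for f in range(cfg.n_folds):
        train = folds != f
        train_coords = [coords[train]]
        train_growth = [growth[train]]
        if pseudo_coords is not None:
            keep = train[pseudo_parent]
            train_coords.append(np.atleast_2d(pseudo_coords)[keep])
            train_growth.append(np.asarray(pseudo_growth, dtype=float)[keep])
        if add_pseudocounts and coords[train].shape[0] >= 2:
            pc = make_pseudocounts(
                coords[train], seed=seed * cfg.n_folds + f + 1,
                pair_divisor=cfg.pair_divisor,
            )
            train_coords.append(pc)
            train_growth.append(np.zeros(pc.shape[0]))
        model = KnnGrowthModel(
            np.concatenate(train_coords, axis=0),
            np.concatenate(train_growth),
            k=min(k, sum(len(g) for g in train_growth)),
        )
        test = np.flatnonzero(~train)
        predictions[test] = predict_many(coords[test], model)
    r = residual_score(predictions, growth)
    ss_tot = float(np.sum((growth - growth.mean()) ** 2))
    r2 = 1.0 - r / ss_tot if ss_tot > 0 else float("nan")
    return CvResult(predictions, folds, r, r2)


def forward_select(
    candidate_coords: np.ndarray,
    growth: np.ndarray,
    k: int = 8,
    cfg: SelectionConfig = SelectionConfig(),
    seed: int = 0,
    pseudo_coords: np.ndarray | None = None,
    pseudo_parent: np.ndarray | None = None,
    pseudo_growth: np.ndarray | None = None,
    max_dims: int | None = None,
) -> tuple[KnnGrowthModel, pd.DataFrame]:
    """Greedy forward selection of eigengene dimensions.

    At each step every remaining candidate is appended in turn, the
    cross-validated residual r is measured, and the candidate minimizing r is
    kept; the search stops when the regularized objective r(n) - lam * L(n)
    stops decreasing.  With ``lam = 0`` the objective reduces to pure
    residual minimization.  Returns the model (trained on all real and
    pseudo data over the winning dimensions) and a per-step history with
    columns ``n, added, r, L, objective, r2``.
    """
    candidate_coords = np.atleast_2d(np.asarray(candidate_coords, dtype=float))
    growth = np.asarray(growth, dtype=float)
    n_candidates = candidate_coords.shape[1]
    limit = min(max_dims or n_candidates, n_candidates)
    selected: list[int] = []
    history: list[dict] = []
    best_objective = np.inf
    best_r2 = np.nan
    while len(selected) < limit:
        best = None
        for cand in range(n_candidates):
            if cand in selected:
                continue
            dims = selected + [cand]
            result = cross_validate(
                candidate_coords[:, dims],
                growth,
                k=k,
                cfg=cfg,
                seed=seed,
                pseudo_coords=None if pseudo_coords is None else pseudo_coords[:, dims],
                pseudo_parent=pseudo_parent,
                pseudo_growth=pseudo_growth,
            )
            if best is None or result.r < best[1].r:
                best = (cand, result)
        cand, result = best
        dims = selected + [cand]
        L = occupancy_log_ratio(candidate_coords[:, dims], growth, cfg)
        objective = result.r - cfg.lam * L
        if objective >= best_objective:
            break
        best_objective = objective
        best_r2 = result.r2
        selected = dims
        history.append(
            {
                "n": len(selected),
                "added": cand,
                "r": result.r,
                "L": L,
                "objective": objective,
                "r2": result.r2,
            }
        )
    if not selected:  # single forced dimension if the objective never improved
        selected = [0]
    train_coords = [candidate_coords[:, selected]]
    train_growth = [growth]
    if pseudo_coords is not None:
        train_coords.append(np.atleast_2d(pseudo_coords)[:, selected])
        train_growth.append(np.asarray(pseudo_growth, dtype=float))
    pc = make_pseudocounts(
        candidate_coords[:, selected], seed=seed, pair_divisor=cfg.pair_divisor
    )
    train_coords.append(pc)
    train_growth.append(np.zeros(pc.shape[0]))
    model = KnnGrowthModel(
        np.concatenate(train_coords, axis=0),
        np.concatenate(train_growth),
        k=k,
        selected_indices=selected,
    )
    return model, pd.DataFrame(history)


def train_from_compendium(
    matrix: ExpressionMatrix,
    growth_table: pd.DataFrame,
    n_candidates: int = 20,
    k: int = 8,
    cfg: SelectionConfig = SelectionConfig(),
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
    basis: EigengeneBasis | None = None,
    use_pseudo_profiles: bool = True,
) -> tuple[EigengeneBasis, KnnGrowthModel, pd.DataFrame]:
    """End-to-end training: basis, augmentation, forward selection.

    ``growth_table`` needs columns ``sample_id`` and ``rate_per_h``; the
    samples it names are the growth-annotated subset of the compendium.  The
    leading ``n_candidates`` eigengenes (by eigenvalue) are the candidate
    pool for forward selection.
    """
    if basis is None:
        basis = compute_basis(matrix)
    n_candidates = min(n_candidates, basis.vectors.shape[1])
    indices = list(range(n_candidates))
    annotated = matrix.subset_samples(list(growth_table["sample_id"]))
    growth = growth_table["rate_per_h"].to_numpy(dtype=float)
    coords = project_samples(annotated, basis, indices)
    pseudo_coords = pseudo_parent = pseudo_growth = None
    if use_pseudo_profiles and cfg.pseudo_multiplier > 0:
        pseudo, pseudo_growth, pseudo_parent = make_noise_profiles(
            annotated, growth, noise=noise, multiplier=cfg.pseudo_multiplier, seed=seed
        )
        pseudo_coords = project_samples(pseudo, basis, indices)
    model, history = forward_select(
        coords,
        growth,
        k=k,
        cfg=cfg,
        seed=seed,
        pseudo_coords=pseudo_coords,
        pseudo_parent=pseudo_parent,
        pseudo_growth=pseudo_growth,
    )
    return basis, model, history
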