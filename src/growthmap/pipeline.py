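"""End-to-end pipeline runs with a single root seed and a manifest.

A run executes: simulate (compendium + planted triplets) -> quantile
normalization -> contrasts -> GCS scoring -> eigengene basis -> KNN training
with forward selection and stratified CV -> cross-background transfer.  Every
artifact is a TSV under the run directory; the manifest records the package
version, the config, derived stage seeds, and a SHA-256 per artifact, so a
rerun with the same config and seed reproduces the run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .expression_core import quantile_normalize, contrast_stats
from .gcs_scoring import GcsConfig, gcs_grid, select_response_genes
from .knn_growth import SelectionConfig, cross_validate, train_from_compendium
from .eigengene_space import project_samples, transform_profiles
from .response_transfer import mean_response, transfer_matrix
from .synthetic_data import (
    CompendiumSpec,
    NoiseModel,
    TripletSpec,
    generate_compendium,
    generate_triplets,
)

__all__ = ["default_config", "run_pipeline"]

#: Seed-splitting offsets per stage (root seed + offset, kept below 2**31).
STAGE_SEEDS = {"compendium": 1, "triplets": 2, "model": 3}


def default_config() -> dict[str, Any]:
    """Demo configuration: small enough for a quick single-CPU run."""
    return {
        "seed": 0,
        "compendium": {
            "n_genes": 600,
            "n_profiles": 120,
            "n_with_growth": 60,
            "latent_dim": 2,
            "growth_link": [0.25, 0.15],
        },
        "triplets": {
            "n_restored": 8,
            "n_compensated": 5,
            "effect_size": 2.0,
            "n_replicates": 3,
        },
        "model": {"k": 8, "lam": 0.1, "n_folds": 5, "n_candidates": 8, "max_dims": 3},
        "gcs": {"hi_cut": 0.4, "lo_cut": -0.2},
        "noise": {"alpha": 0.217, "beta": 0.539},
        "transfer": {"n_backgrounds": 3},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises with the stage name prefixed so the offending
    step is unambiguous.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    noise = NoiseModel(**config.get("noise", {"alpha": 0.217, "beta": 0.539}))
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": config,
        "stages": {},
        "artifacts": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.monotonic()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.monotonic() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _Stage()

    with stage("simulate"):
        comp_cfg = dict(config["compendium"])
        comp_cfg["growth_link"] = tuple(comp_cfg.get("growth_link", (0.25, 0.15)))
        spec = CompendiumSpec(
            **comp_cfg, noise=noise, seed=seed + STAGE_SEEDS["compendium"]
        )
        matrix, growth = generate_compendium(spec)
        matrix.write_tsv(out / "compendium.tsv")
        _write(growth, out / "growth.tsv")

        trip_cfg = config["triplets"]
        rng = np.random.default_rng(seed + STAGE_SEEDS["triplets"])
        chosen = rng.choice(
            matrix.n_genes,
            size=trip_cfg["n_restored"] + trip_cfg["n_compensated"],
            replace=False,
        )
        restored = frozenset(matrix.gene_ids[i] for i in chosen[: trip_cfg["n_restored"]])
        compensated = frozenset(
            matrix.gene_ids[i] for i in chosen[trip_cfg["n_restored"] :]
        )
        tspec = TripletSpec(
            restored_genes=restored,
            compensated_genes=compensated,
            effect_size=trip_cfg["effect_size"],
            n_replicates=trip_cfg["n_replicates"],
            seed=seed + STAGE_SEEDS["triplets"],
        )
        triplet, meta = generate_triplets(tspec, matrix)
        triplet.write_tsv(out / "triplet.tsv")
        _write(meta, out / "triplet_metadata.tsv")

    with stage("normalize"):
        normalized = quantile_normalize(triplet)
        normalized.write_tsv(out / "triplet_normalized.tsv")

    with stage("contrast"):
        by_role = {
            role: list(meta.loc[meta["role"] == role, "sample_id"])
            for role in ("WT", "deletion", "sup")
        }
        contrasts = {
            "del": contrast_stats(normalized, by_role["WT"], by_role["deletion"]),
            "ae": contrast_stats(normalized, by_role["deletion"], by_role["sup"]),
            "wt_sup": contrast_stats(normalized, by_role["WT"], by_role["sup"]),
        }
        for name, frame in contrasts.items():
            _write(frame, out / f"contrast_{name}.tsv", index=True)

    with stage("gcs"):
        gcs_cfg = GcsConfig(**config.get("gcs", {}))
        table = gcs_grid(contrasts["del"], contrasts["ae"], contrasts["wt_sup"], gcs_cfg)
        _write(table, out / "gcs.tsv", index=True)
        restorative, compensatory = select_response_genes(table, gcs_cfg)
        manifest["stages"]["gcs"] = {
            "n_restorative": len(restorative),
            "n_compensatory": len(compensatory),
        }

    with stage("knn"):
        model_cfg = config["model"]
        sel_cfg = SelectionConfig(lam=model_cfg["lam"], n_folds=model_cfg["n_folds"])
        basis, model, history = train_from_compendium(
            matrix,
            growth,
            n_candidates=model_cfg["n_candidates"],
            k=model_cfg["k"],
            cfg=sel_cfg,
            noise=noise,
            seed=seed + STAGE_SEEDS["model"],
        )
        coords = project_samples(
            matrix.subset_samples(list(growth["sample_id"])), basis, model.selected_indices
        )
        cv = cross_validate(
            coords,
            growth["rate_per_h"].to_numpy(),
            k=model_cfg["k"],
            cfg=sel_cfg,
            seed=seed + STAGE_SEEDS["model"],
        )
        _write(history, out / "selection_history.tsv")
        _write(
            pd.DataFrame(
                {
                    "sample_id": growth["sample_id"],
                    "rate_per_h": growth["rate_per_h"],
                    "predicted": cv.predictions,
                    "fold": cv.folds,
                }
            ),
            out / "cv_predictions.tsv",
        )
        model.save(out / "model")
        basis.save(out / "basis")
        manifest["stages"]["knn"] = {
            "selected_indices": [int(i) for i in model.selected_indices],
            "cv_r2": round(cv.r2, 6),
        }

    with stage("transfer"):
        transformed = transform_profiles(triplet, basis)
        cols = {s: i for i, s in enumerate(triplet.sample_ids)}
        sup_cols = [cols[s] for s in by_role["sup"]]
        del_cols = [cols[s] for s in by_role["deletion"]]
        response = mean_response(transformed[:, sup_cols], transformed[:, del_cols])
        n_bg = config.get("transfer", {}).get("n_backgrounds", 3)
        # slow but growing backgrounds: a zero measured rate has no defined
        # percent change
        growing = growth[growth["rate_per_h"] > 0.1]
        slowest = growing.sort_values("rate_per_h").head(n_bg)
        backgrounds = {
            row.sample_id: matrix.subset_samples([row.sample_id])
            for row in slowest.itertuples()
        }
        measured = {row.sample_id: float(row.rate_per_h) for row in slowest.itertuples()}
        grid = transfer_matrix(
            backgrounds, {"sup_response": response}, model, basis, measured
        )
        _write(grid, out / "transfer.tsv")

    manifest["timings_s"] = timings
    for path in sorted(out.rglob("*.tsv")):
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
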