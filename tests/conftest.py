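import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import growthmap as gm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_compendium():
    """Small latent-structured compendium shared across tests."""
    spec = gm.CompendiumSpec(
        n_genes=150, n_profiles=80, n_with_growth=40, latent_dim=2,
        growth_link=(0.25, 0.15), seed=5,
    )
    return gm.generate_compendium(spec)


@pytest.fixture(scope="session")
def planted_triplet():
    """Baseline + planted triplet with moderate noise, plus the truth sets."""
    spec = gm.CompendiumSpec(
        n_genes=600, n_profiles=60, n_with_growth=30, latent_dim=2,
        growth_link=(0.25, 0.15), seed=9,
    )
    baseline, _ = gm.generate_compendium(spec)
    base = baseline.values.mean(axis=1)
    lo, hi = np.percentile(base, [25, 90])
    pool = [g for g, b in zip(baseline.gene_ids, base) if lo <= b <= hi]
    rng = np.random.default_rng(9)
    chosen = rng.choice(len(pool), size=18, replace=False)
    restored = frozenset(pool[i] for i in chosen[:11])
    compensated = frozenset(pool[i] for i in chosen[11:])
    tspec = gm.TripletSpec(
        restored_genes=restored, compensated_genes=compensated, seed=9
    )
    matrix, meta = gm.generate_triplets(tspec, baseline)
    return {
        "baseline": baseline,
        "matrix": matrix,
        "meta": meta,
        "restored": restored,
        "compensated": compensated,
        "spec": tspec,
    }


@pytest.fixture()
def triplet_contrasts(planted_triplet):
    from growthmap.expression_core import contrast_stats, quantile_normalize

    norm = quantile_normalize(planted_triplet["matrix"])
    meta = planted_triplet["meta"]
    roles = {
        r: list(meta.loc[meta["role"] == r, "sample_id"])
        for r in ("WT", "deletion", "sup")
    }
    return {
        "del": contrast_stats(norm, roles["WT"], roles["deletion"]),
        "ae": contrast_stats(norm, roles["deletion"], roles["sup"]),
        "wt_sup": contrast_stats(norm, roles["WT"], roles["sup"]),
    }
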