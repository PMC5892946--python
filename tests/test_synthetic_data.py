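"""Generators: determinism, planted structure, the mean-variance law, fixtures."""

import numpy as np
import pandas as pd
import pytest

import growthmap as gm
from growthmap.eigengene_space import compute_basis, project
from growthmap.expression_core import ExpressionMatrix
from growthmap.growth_phenotypes import fit_growth_rate
from growthmap.synthetic_data import (
    DEFAULT_NOISE,
    NoiseModel,
    fit_noise_model,
    simulate_noisy_counts,
)

ZERO_NOISE = NoiseModel(0.0, -1.0)


class TestNoiseModel:
    def test_variance_law(self):
        assert DEFAULT_NOISE.variance(1.0) == pytest.approx(1.756)
        assert DEFAULT_NOISE.variance(0.0) == 0.0
        assert ZERO_NOISE.variance(123.0) == 0.0

    @pytest.mark.parametrize("alpha,beta", [(-0.1, 0.0), (0.1, -1.5)])
    def test_invalid_parameters_rejected(self, alpha, beta):
        with pytest.raises(ValueError):
            NoiseModel(alpha, beta)

    def test_refit_recovers_generating_parameters(self):
        rng = np.random.default_rng(12)
        means = 10.0 ** rng.uniform(0, 4, size=2500)
        counts = simulate_noisy_counts(means, 50, DEFAULT_NOISE, rng, clip_negative=False)
        fitted, se_a, se_b = fit_noise_model(counts)
        # agreement within 3 combined standard errors of the generating values
        assert abs(fitted.alpha - DEFAULT_NOISE.alpha) < 3 * np.hypot(se_a, 0.004)
        assert abs(fitted.beta - DEFAULT_NOISE.beta) < 3 * np.hypot(se_b, 0.040)

    def test_clipping_keeps_counts_physical(self):
        rng = np.random.default_rng(0)
        draws = simulate_noisy_counts(np.array([0.5] * 100), 20, DEFAULT_NOISE, rng)
        assert draws.min() >= 0.0
        zero = simulate_noisy_counts(np.array([0.0]), 5, DEFAULT_NOISE, rng)
        assert np.all(zero == 0.0)


class TestCompendium:
    def test_seed_reproducibility(self):
        spec = gm.CompendiumSpec(n_genes=60, n_profiles=30, n_with_growth=10, seed=7)
        m1, g1 = gm.generate_compendium(spec)
        m2, g2 = gm.generate_compendium(spec)
        assert np.array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(g1, g2)

    def test_invalid_dimensions_name_the_field(self):
        with pytest.raises(ValueError, match="n_with_growth"):
            gm.CompendiumSpec(n_profiles=10, n_with_growth=20)
        with pytest.raises(ValueError, match="latent_dim"):
            gm.CompendiumSpec(n_genes=5, n_profiles=50, n_with_growth=10,
                              latent_dim=5, growth_link=(1,) * 5)
        with pytest.raises(ValueError, match="growth_link"):
            gm.CompendiumSpec(latent_dim=2, growth_link=(0.1,))

    def test_growth_attached_to_exactly_m_profiles(self, small_compendium):
        matrix, growth = small_compendium
        assert len(growth) == 40
        assert set(growth["sample_id"]) <= set(matrix.sample_ids)
        assert (growth["rate_per_h"] >= 0).all()

    def test_noise_free_growth_affine_in_first_eigengene(self):
        """With one latent factor and no noise, the leading eigengene carries
        growth as an (essentially) affine function of its projection."""
        spec = gm.CompendiumSpec(
            n_genes=80, n_profiles=50, n_with_growth=50, latent_dim=1,
            growth_link=(0.2,), growth_noise_sd=0.0, noise=ZERO_NOISE,
            mean_range=(256.0, 1.0e4), seed=3,
        )
        matrix, growth = gm.generate_compendium(spec)
        log_matrix = ExpressionMatrix(
            matrix.gene_ids, matrix.sample_ids, np.log2(matrix.values + 1.0), "log2"
        )
        basis = compute_basis(log_matrix)
        coords = project(log_matrix.values, basis, [0]).ravel()
        r = np.corrcoef(coords, growth["rate_per_h"])[0, 1]
        assert r**2 > 0.999

    def test_pure_noise_compendium_follows_variance_law(self):
        """Without latent loadings the per-gene mean/variance obey the law."""
        spec = gm.CompendiumSpec(
            n_genes=2500, n_profiles=60, n_with_growth=10, latent_dim=1,
            growth_link=(0.1,), loading_sd=0.0, seed=4,
        )
        matrix, _ = gm.generate_compendium(spec)
        fitted, se_a, se_b = fit_noise_model(matrix.values)
        # clipping at zero slightly deflates low-mean variances; the quadratic
        # coefficient is driven by high-mean genes and must agree closely
        assert fitted.alpha == pytest.approx(DEFAULT_NOISE.alpha, abs=0.02)
        assert fitted.beta == pytest.approx(DEFAULT_NOISE.beta, abs=0.15)


class TestTriplets:
    def test_zero_noise_fold_changes_exact(self, planted_triplet):
        spec = gm.TripletSpec(
            restored_genes=planted_triplet["restored"],
            compensated_genes=planted_triplet["compensated"],
            replicate_log2_sd=0.0, batch_sd=0.0, seed=1,
        )
        matrix, meta = gm.generate_triplets(spec, planted_triplet["baseline"])
        log = np.log2(matrix.values + 1.0)
        cols = {r: meta.index[meta["role"] == r].to_numpy() for r in ("WT", "deletion", "sup")}
        lfc_del = log[:, cols["deletion"]].mean(1) - log[:, cols["WT"]].mean(1)
        lfc_ae = log[:, cols["sup"]].mean(1) - log[:, cols["deletion"]].mean(1)
        restored = np.isin(matrix.gene_ids, list(spec.restored_genes))
        compensated = np.isin(matrix.gene_ids, list(spec.compensated_genes))
        assert np.allclose(lfc_del[restored], 2.0)
        assert np.allclose(lfc_ae[restored], -2.0)
        assert np.allclose(lfc_del[compensated], 2.0)
        assert np.allclose(lfc_ae[compensated], 2.0)
        # round-trip: the planted sets are exactly the genes above threshold
        assert set(np.array(matrix.gene_ids)[np.abs(lfc_del) > 1.0]) == (
            spec.restored_genes | spec.compensated_genes
        )

    def test_empty_sets_give_identical_strains(self, planted_triplet):
        spec = gm.TripletSpec(replicate_log2_sd=0.0, batch_sd=0.0, seed=1)
        matrix, meta = gm.generate_triplets(spec, planted_triplet["baseline"])
        wt = matrix.values[:, meta.index[meta["role"] == "WT"]]
        sup = matrix.values[:, meta.index[meta["role"] == "sup"]]
        assert np.allclose(wt, sup)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gm.TripletSpec(restored_genes={"a"}, compensated_genes={"a"})

    def test_unknown_genes_rejected(self, planted_triplet):
        spec = gm.TripletSpec(restored_genes={"nope"}, seed=0)
        with pytest.raises(ValueError, match="absent"):
            gm.generate_triplets(spec, planted_triplet["baseline"])

    def test_determinism_and_batch_metadata(self, planted_triplet):
        spec = planted_triplet["spec"]
        m1, meta1 = gm.generate_triplets(spec, planted_triplet["baseline"])
        m2, _ = gm.generate_triplets(spec, planted_triplet["baseline"])
        assert np.array_equal(m1.values, m2.values)
        assert set(meta1["batch"]) == {"day1", "day2", "day3"}


class TestOdSeries:
    def test_zero_rate_constant(self):
        series = gm.generate_od_series(0.0, [0, 1, 2, 3], noise_sd=0.0)
        assert np.allclose(series.od, 1.0)

    def test_doubling(self):
        series = gm.generate_od_series(np.log(2), [0.0, 1.0, 2.0], noise_sd=0.0)
        assert series.od[1] == pytest.approx(2.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gm.generate_od_series(0.5, [-1.0, 0.0, 1.0])

    def test_fit_recovers_generating_rate(self):
        series = gm.generate_od_series(
            0.5, np.linspace(0, 5.5, 12), noise_sd=0.01, seed=2
        )
        assert fit_growth_rate(series) == pytest.approx(0.5, abs=0.02)


class TestPackagedFixtures:
    def test_sixteen_sup_strains_from_mutant_parents(self):
        mutations, _ = gm.packaged_fixtures()
        assert mutations.loc[mutations["parent"] != "WT", "strain"].nunique() == 16

    def test_rescue_table_rows(self):
        _, rescues = gm.packaged_fixtures()
        assert (rescues["class"] == "forward").sum() == 3
        assert (rescues["class"] == "reverse").sum() == 4

    def test_dgk_sup3_carries_nusa_lesion(self):
        mutations, _ = gm.packaged_fixtures()
        row = mutations[(mutations["strain"] == "dgk_sup3")]
        assert list(row["locus"]) == ["nusA"]
        assert list(row["coding_change"]) == ["nusA(I49N)"]
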