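import numpy as np
import pytest

from trapclient import imputation
from trapclient.errors import StateError, ValidationError
from trapclient.imputation import ImputationConfig, impute, impute_bottom_tail, impute_lls
from trapclient.io import LINEAR, LOG2

from conftest import make_matrix


def gaussian_matrix(rng, m=1000, n=6, mean=25.0, sd=2.0):
    return make_matrix(rng.normal(mean, sd, size=(m, n)), scale=LOG2)


class TestBottomTail:
    def test_complete_matrix_is_identity(self, rng):
        m = gaussian_matrix(rng, m=50)
        out, report = impute_bottom_tail(m, ImputationConfig(seed=1))
        assert report.n_imputed == 0
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_draws_land_in_bottom_tail(self, rng):
        """With downshift 1.8 and width 0.3 the draw distribution is centred
        at the 3.6th percentile of the observed Gaussian, so most draws fall
        below the observed 5th percentile and essentially all fall below the
        observed median."""
        values = rng.normal(25, 2, size=(1200, 6))
        values[:50] = np.nan  # fifty fully-missing proteins
        m = make_matrix(values, scale=LOG2)
        out, report = impute_bottom_tail(m, ImputationConfig(seed=7))
        assert report.n_bottom_tail_cells == 300
        X = out.values.to_numpy()
        for j in range(6):
            drawn = X[:50, j]
            p5 = np.nanpercentile(values[50:, j], 5)
            assert (drawn < p5).mean() > 0.5
            assert (drawn < np.nanmedian(values[50:, j])).all()

    def test_same_seed_bit_identical(self, rng):
        values = rng.normal(25, 2, size=(200, 6))
        values[:5] = np.nan
        m = make_matrix(values, scale=LOG2)
        out1, _ = impute_bottom_tail(m, ImputationConfig(seed=3))
        out2, _ = impute_bottom_tail(m, ImputationConfig(seed=3))
        np.testing.assert_array_equal(out1.values.to_numpy(), out2.values.to_numpy())

    def test_placement_mean_within_three_se(self, rng):
        """Imputed per-sample means sit at mean_j - 1.8 sd_j within 3 se."""
        values = rng.normal(25, 2, size=(3000, 4))
        values[:400] = np.nan
        m = make_matrix(values, scale=LOG2)
        out, report = impute_bottom_tail(m, ImputationConfig(seed=11))
        X = out.values.to_numpy()
        for j, sid in enumerate(m.sample_ids):
            mean_j, sd_j = report.tail_params[sid]
            drawn = X[:400, j]
            se = 0.3 * sd_j / np.sqrt(400)
            assert abs(drawn.mean() - (mean_j - 1.8 * sd_j)) < 3 * se

    def test_linear_scale_rejected(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]], scale=LINEAR)
        with pytest.raises(StateError):
            impute_bottom_tail(m, ImputationConfig())

    def test_sample_with_too_few_observations_rejected(self):
        m = make_matrix([[1.0, np.nan], [np.nan, np.nan], [np.nan, np.nan]], scale=LOG2)
        with pytest.raises(ValidationError, match="observed values"):
            impute_bottom_tail(m, ImputationConfig())


class TestLLS:
    def test_proportional_neighbour_hand_example(self):
        """Target (2, 4, NA) on neighbour (1, 2, 3): fit predicts 6."""
        m = make_matrix([[2.0, 4.0, np.nan], [1.0, 2.0, 3.0]], scale=LOG2)
        cfg = ImputationConfig(k=1, min_overlap=2)
        out, report = impute_lls(m, cfg)
        assert report.n_lls_cells == 1
        assert out.values.iloc[0, 2] == pytest.approx(6.0, abs=1e-9)

    def test_flat_row_falls_back_to_row_mean(self):
        m = make_matrix(
            [[5.0, 5.0, 5.0, np.nan], [1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
            scale=LOG2,
        )
        out, report = impute_lls(m, ImputationConfig(min_overlap=2))
        assert report.n_fallback_cells == 1
        assert out.values.iloc[0, 3] == 5.0

    def test_rank_one_noiseless_recovery(self, rng):
        """Masked entries of an additive rank-1 log2 matrix are recovered
        to 1e-9 relative error."""
        u = rng.normal(25, 2, size=60)
        v = rng.normal(0, 1, size=8)
        X = u[:, None] + v[None, :]
        truth = X.copy()
        mask = rng.random(X.shape) < 0.1
        mask[:, :4] = False  # keep enough observed columns per row
        X[mask] = np.nan
        out, _ = impute_lls(make_matrix(X, scale=LOG2), ImputationConfig(k=5))
        rel = np.abs(out.values.to_numpy() - truth) / np.abs(truth)
        assert rel[mask].max() < 1e-9

    def test_low_rank_noisy_recovery(self):
        """Monte-Carlo: median absolute imputation error stays below the
        replicate noise sd when 5% of cells are masked from a low-rank
        structure (errors pooled over repetitions for a stable estimate).

        With only 9 samples the regression and neighbour-selection noise put
        the achievable error at about the noise floor itself, so the bound is
        a modest multiple of the replicate noise rather than the noise sd."""
        noise_sd = 0.3
        errors = []
        for seed in range(5):
            gen = np.random.default_rng(seed)
            u = gen.normal(25, 2, size=400)
            v = gen.normal(0, 1.5, size=9)
            truth = u[:, None] + v[None, :] + gen.normal(0, noise_sd, size=(400, 9))
            X = truth.copy()
            mask = gen.random(X.shape) < 0.05
            X[mask] = np.nan
            ok_rows = ~np.isnan(X).all(axis=1)
            # on a 9-column matrix a small neighbourhood keeps the fit
            # overdetermined; large k only pays off for wide matrices
            out, _ = impute_lls(make_matrix(X, scale=LOG2), ImputationConfig(k=3))
            errors.append(np.abs(out.values.to_numpy() - truth)[mask & ok_rows[:, None]])
        assert np.median(np.concatenate(errors)) < 1.2 * noise_sd

    def test_k_larger_than_pool_uses_all(self, caplog):
        m = make_matrix(
            [[2.0, 4.0, np.nan], [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]], scale=LOG2
        )
        out, report = impute_lls(m, ImputationConfig(k=50, min_overlap=2))
        assert report.n_lls_cells == 1  # no error despite k > eligible


class TestImputeDispatch:
    def make_mixed(self, rng):
        values = rng.normal(25, 2, size=(300, 6))
        values[:4] = np.nan  # fully missing -> bottom tail
        partial = rng.random((296, 6)) < 0.05
        values[4:][partial] = np.nan
        return make_matrix(values, scale=LOG2), 4 * 6 + int(partial.sum())

    def test_mechanism_counts_conserve_missing_cells(self, rng):
        m, n_missing = self.make_mixed(rng)
        out, report = impute(m, ImputationConfig(seed=5))
        assert out.n_missing == 0
        assert report.n_bottom_tail_cells > 0
        assert report.n_lls_cells > 0
        assert report.n_imputed == n_missing

    def test_observed_cells_never_modified(self, rng):
        m, _ = self.make_mixed(rng)
        observed = ~m.values.isna().to_numpy()
        out, _ = impute(m, ImputationConfig(seed=5))
        np.testing.assert_array_equal(
            out.values.to_numpy()[observed], m.values.to_numpy()[observed]
        )

    def test_fully_observed_matrix_is_identity(self, rng):
        m = gaussian_matrix(rng, m=40)
        out, report = impute(m, ImputationConfig(seed=1))
        assert report.n_imputed == 0
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_seeded_determinism(self, rng):
        m, _ = self.make_mixed(rng)
        out1, _ = impute(m, ImputationConfig(seed=9))
        out2, _ = impute(m, ImputationConfig(seed=9))
        np.testing.assert_array_equal(out1.values.to_numpy(), out2.values.to_numpy())

    def test_unserved_cells_get_bottom_tail_draws(self, rng):
        """A row with fewer observed columns than min_overlap is completed by
        the bottom-tail mechanism inside the combined impute."""
        values = rng.normal(25, 2, size=(50, 6))
        values[0, :5] = np.nan  # one observed value < min_overlap=3
        m = make_matrix(values, scale=LOG2)
        out, report = impute(m, ImputationConfig(seed=2))
        assert report.n_fallback_cells == 5
        # draws sit far below the row's observed value
        assert (out.values.iloc[0, :5] < values[:, :5][~np.isnan(values[:, :5])].mean()).all()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"downshift": -1}, {"width": 0}, {"k": 0}, {"min_overlap": 1}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ImputationConfig(**kwargs)
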