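import numpy as np
import pandas as pd
import pytest

from trapclient import differential
from trapclient.differential import (
    TestConfig as DiffConfig,
    call_affected,
    moderated_d,
    permutation_fdr,
    unpaired_t,
    volcano_table,
)
from trapclient.errors import StateError, ValidationError

from conftest import make_design, make_matrix


class TestUnpairedT:
    def test_identical_groups(self):
        t, p = unpaired_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_closed_form_worked_example(self):
        """(1,2,3) vs (4,5,6): pooled sd 1, se sqrt(2/3), t = -3/se."""
        t, p = unpaired_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-3)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=2e-4)

    def test_sign_antisymmetry(self, rng):
        a, b = rng.normal(size=4), rng.normal(1, size=5)
        t_ab, p_ab = unpaired_t(a, b)
        t_ba, p_ba = unpaired_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_variance_gap_is_infinite(self):
        t, p = unpaired_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and t < 0 and p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            unpaired_t([1.0], [2.0, 3.0])


class TestModeratedD:
    def test_s0_zero_equals_t(self):
        d = moderated_d([1, 2, 3], [4, 5, 6], s0=0.0)
        t, _ = unpaired_t([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(t)

    def test_zero_variance_gap_with_s0(self):
        assert moderated_d([2.0, 2.0], [1.0, 1.0], s0=0.5) == pytest.approx(2.0)

    def test_magnitude_non_increasing_in_s0(self, rng):
        a, b = rng.normal(size=3), rng.normal(1, size=3)
        mags = [abs(moderated_d(a, b, s0)) for s0 in (0.0, 0.1, 0.5, 2.0)]
        assert all(x >= y for x, y in zip(mags, mags[1:]))


def two_group_design():
    return make_design(
        {"control": ["c1", "c2", "c3"], "siRNA1": ["t1", "t2", "t3"]},
        control="control",
    )


def null_matrix(rng, m=400, design=None, sd=0.25):
    design = design or two_group_design()
    samples = list(design.table.index)
    base = rng.normal(25, 2, size=m)
    X = base[:, None] + rng.normal(0, sd, size=(m, len(samples)))
    return make_matrix(X, sample_ids=samples)


class TestPermutationFdr:
    def test_null_simulation_controls_calls(self, rng):
        """Under a global null the q<0.05 fraction stays within Monte-Carlo
        error of the nominal level."""
        fracs = []
        for _ in range(5):
            m = null_matrix(rng)
            res = permutation_fdr(m, two_group_design(), "siRNA1")
            fracs.append((res.table["q_value"] < 0.05).mean())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs)) if len(fracs) > 1 else 0.0
        assert np.mean(fracs) <= 0.05 + 3 * se + 1e-12

    def test_planted_shift_attains_minimum_q(self, rng):
        design = two_group_design()
        m = null_matrix(rng, m=1000, design=design)
        X = m.values.to_numpy()
        X[0, 3:] -= 8 * 0.25  # 8-sd knockdown in the targeting samples
        res = permutation_fdr(make_matrix(X, sample_ids=list(design.table.index)),
                              design, "siRNA1")
        t = res.table
        assert t.loc["P000", "q_value"] == t["q_value"].min()
        assert t.loc["P000", "mean_diff"] == pytest.approx(-2.0, abs=0.5)

    def test_exhaustive_and_sampled_agree(self, rng):
        design = two_group_design()
        m = null_matrix(rng, m=300, design=design)
        X = m.values.to_numpy()
        X[:20, 3:] -= 1.0
        m = make_matrix(X, sample_ids=list(design.table.index))
        exh = permutation_fdr(m, design, "siRNA1", DiffConfig())
        smp = permutation_fdr(
            m, design, "siRNA1",
            DiffConfig(permutations="sampled", n_sampled=10000, seed=4),
        )
        assert np.abs(
            exh.table["q_value"].to_numpy() - smp.table["q_value"].to_numpy()
        ).max() <= 0.02

    def test_q_monotone_in_statistic_rank(self, rng):
        m = null_matrix(rng, m=500)
        res = permutation_fdr(m, two_group_design(), "siRNA1")
        t = res.table.assign(a=res.table["statistic"].abs()).sort_values(
            "a", ascending=False
        )
        q = t["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_missing_cells_rejected(self, rng):
        m = null_matrix(rng, m=10)
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(StateError, match="impute"):
            permutation_fdr(m, two_group_design(), "siRNA1")

    def test_sampled_without_seed_rejected(self):
        with pytest.raises(ValidationError, match="seed"):
            DiffConfig(permutations="sampled")


def make_result(name, rows):
    """rows: dict protein -> (mean_diff, q)."""
    table = pd.DataFrame(
        {
            "mean_diff": {p: v[0] for p, v in rows.items()},
            "statistic": {p: -v[0] for p, v in rows.items()},
            "p_value": {p: v[1] for p, v in rows.items()},
            "q_value": {p: v[1] for p, v in rows.items()},
        }
    )
    table["direction"] = np.where(
        (table.q_value < 0.05) & (table.mean_diff < 0), "negative",
        np.where((table.q_value < 0.05) & (table.mean_diff > 0), "positive", "none"),
    )
    table.index.name = "protein_id"
    return differential.ContrastResult(name, table, n_permutations=20, pi0=1.0)


class TestCallAffected:
    def test_single_contrast_significance_is_excluded(self):
        r1 = make_result("g1", {"A": (-1.0, 0.01), "B": (-1.0, 0.01)})
        r2 = make_result("g2", {"A": (-1.0, 0.5), "B": (-1.0, 0.01)})
        sets = call_affected([r1, r2])
        assert sets.negatively_affected == {"B"}

    def test_concordant_negative_included(self):
        r1 = make_result("g1", {"A": (-1.0, 0.01)})
        r2 = make_result("g2", {"A": (-0.5, 0.04)})
        assert call_affected([r1, r2]).negatively_affected == {"A"}

    def test_opposite_signs_excluded_from_both(self):
        r1 = make_result("g1", {"A": (-1.0, 0.01)})
        r2 = make_result("g2", {"A": (1.0, 0.01)})
        sets = call_affected([r1, r2])
        assert sets.negatively_affected == set()
        assert sets.positively_affected == set()

    def test_mismatched_universes_rejected(self):
        r1 = make_result("g1", {"A": (-1.0, 0.01)})
        r2 = make_result("g2", {"B": (-1.0, 0.01)})
        with pytest.raises(ValidationError, match="universe"):
            call_affected([r1, r2])


class TestVolcano:
    def test_closed_form_y_values(self):
        res = make_result("g", {"A": (-1.0, 0.05), "B": (0.5, 1.0)})
        v = volcano_table(res).set_index("protein_id")
        assert v.loc["A", "neg_log10_q"] == pytest.approx(1.301, abs=1e-3)
        assert v.loc["B", "neg_log10_q"] == 0.0

    def test_row_count_and_floor(self):
        res = make_result("g", {"A": (-1.0, 0.0), "B": (0.1, 0.5)})
        v = volcano_table(res)
        assert len(v) == 2
        assert np.isfinite(v["neg_log10_q"]).all()
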