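"""Replicate aggregation, reliability (ICC) and measurement-subset selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pesmorph.errors import ValidationError
from pesmorph.ingest import (
    aggregate_repeats, complete_cases, icc_from_matrix, measurement_columns,
    repeat_reliability, select_measurement_subset,
)

from conftest import make_metadata, make_repeat_table


def brute_force_icc(x, variant):
    """Independent variance-components oracle: naive double-loop mean squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / x.size
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msb = ss_rows / (n - 1)
    msw = (ss_tot - ss_rows) / (n * (k - 1))
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return {
        "icc1": (msb - msw) / (msb + (k - 1) * msw),
        "icc2": (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n),
        "icc3": (msb - mse) / (msb + (k - 1) * mse),
        "icc3k": (msb - mse) / msb,
    }[variant]


class TestAggregation:
    @pytest.mark.parametrize(
        "replicates, expected",
        [((1.0, 1.0, 1.0), 1.0), ((2.0, 4.0, 6.0), 4.0), ((10.00, 10.02, 9.98), 10.00)],
    )
    def test_cell_is_arithmetic_mean(self, replicates, expected):
        repeats = make_repeat_table({"S1": replicates})
        table = aggregate_repeats(repeats, make_metadata(["S1"]))
        assert table.loc[0, "M1"] == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant_over_replicate_order(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(5, 20, size=6)
        repeats = make_repeat_table({"S1": vals[:3], "S2": vals[3:]})
        meta = make_metadata(["S1", "S2"])
        shuffled = repeats.sample(frac=1, random_state=0).reset_index(drop=True)
        a = aggregate_repeats(repeats, meta)
        b = aggregate_repeats(shuffled, meta)
        pd.testing.assert_frame_equal(a, b)

    def test_metadata_join_and_orphan_error(self):
        repeats = make_repeat_table({"S1": [1, 2], "S2": [3, 4]})
        with pytest.raises(ValidationError, match="S2"):
            aggregate_repeats(repeats, make_metadata(["S1"]))

    def test_nonpositive_value_rejected_with_identity(self):
        repeats = make_repeat_table({"S1": [1.0, -2.0]})
        with pytest.raises(ValidationError, match="S1/M1"):
            aggregate_repeats(repeats, make_metadata(["S1"]))


class TestICC:
    @pytest.mark.parametrize("variant", ["icc1", "icc2", "icc3", "icc3k"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_mean_squares(self, variant, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 21)
        x = rng.normal(10, 3, size=(n, 3)) + rng.normal(0, 0.5, size=(n, 3))
        assert icc_from_matrix(x, variant) == pytest.approx(
            brute_force_icc(x, variant), abs=1e-10
        )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(12, 3)) + rng.normal(0, 2, size=(12, 1))
        long = pd.DataFrame(
            [(i, j, x[i, j]) for i in range(12) for j in range(3)],
            columns=["targets", "raters", "ratings"],
        )
        res = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")["ICC"]
        assert icc_from_matrix(x, "icc3") == pytest.approx(res["ICC(C,1)"], abs=1e-8)
        assert icc_from_matrix(x, "icc2") == pytest.approx(res["ICC(A,1)"], abs=1e-8)
        assert icc_from_matrix(x, "icc3k") == pytest.approx(res["ICC(C,k)"], abs=1e-8)
        assert icc_from_matrix(x, "icc1") == pytest.approx(res["ICC(1,1)"], abs=1e-8)

    def test_identical_replicates_give_one(self):
        x = np.array([[3.0, 3.0, 3.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
        assert icc_from_matrix(x, "icc3") == pytest.approx(1.0)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(2)
        x = 10.0 + rng.normal(0, 1, size=(400, 3))  # no between-specimen signal
        assert abs(icc_from_matrix(x, "icc3")) < 0.1

    def test_variance_ratio_nine_to_one_gives_point_nine(self):
        # between-specimen variance 9, within-specimen 1 => ICC = 0.9
        rng = np.random.default_rng(3)
        mu = rng.normal(0, 3.0, size=(500, 1))
        x = mu + rng.normal(0, 1.0, size=(500, 3))
        assert icc_from_matrix(x, "icc3") == pytest.approx(0.9, abs=0.03)

    def test_rescaling_leaves_icc_unchanged_and_scales_sd(self):
        repeats = make_repeat_table(
            {f"S{i}": 10 + i + np.array([0.0, 0.1, -0.1]) for i in range(6)}
        )
        scaled = repeats.assign(value_mm=repeats["value_mm"] * 2.54)
        r1 = repeat_reliability(repeats)
        r2 = repeat_reliability(scaled)
        assert r2.table.loc[0, "icc"] == pytest.approx(r1.table.loc[0, "icc"], abs=1e-10)
        assert r2.table.loc[0, "mean_repeat_sd_mm"] == pytest.approx(
            2.54 * r1.table.loc[0, "mean_repeat_sd_mm"])
        assert r2.table.loc[0, "repeat_sd_proportion"] == pytest.approx(
            r1.table.loc[0, "repeat_sd_proportion"])


class TestReliabilityReport:
    def test_flags_fire_on_both_sides_of_threshold(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(20, 3, size=30)
        good = {f"S{i}": mu[i] + rng.normal(0, 0.05, 3) for i in range(30)}
        noisy = {f"S{i}": 20 + rng.normal(0, 3, 3) for i in range(30)}
        repeats = pd.concat([
            make_repeat_table(good, measurement="GOOD"),
            make_repeat_table(noisy, measurement="NOISY"),
        ])
        rep = repeat_reliability(repeats, icc_threshold=0.9)
        assert rep.flagged_measurements == ["NOISY"]

    def test_single_specimen_reports_missing_icc_with_warning(self):
        repeats = pd.concat([
            make_repeat_table({"S1": [5.0, 5.1]}, measurement="LONE"),
            make_repeat_table({f"S{i}": [3 + i, 3.1 + i] for i in range(4)},
                              measurement="OK"),
        ])
        with pytest.warns(UserWarning, match="LONE"):
            rep = repeat_reliability(repeats)
        row = rep.table.set_index("measurement_name").loc["LONE"]
        assert np.isnan(row["icc"])


class TestSubsetSelection:
    def _table(self, n_meas):
        rng = np.random.default_rng(0)
        data = {f"M{i}": rng.uniform(5, 25, size=4) for i in range(1, n_meas + 1)}
        return pd.concat([make_metadata([f"S{i}" for i in range(4)]),
                          pd.DataFrame(data)], axis=1)

    def test_keep_seven_of_twelve(self):
        table = self._table(12)
        keep = [f"M{i}" for i in range(1, 8)]
        out = select_measurement_subset(table, keep)
        assert measurement_columns(out) == keep

    def test_keep_all_is_identity(self):
        table = self._table(5)
        out = select_measurement_subset(table, measurement_columns(table))
        pd.testing.assert_frame_equal(out, table)

    def test_unknown_name_error_names_it(self):
        with pytest.raises(ValidationError, match="M99"):
            select_measurement_subset(self._table(3), ["M1", "M99"])

    def test_complete_cases_drops_and_warns(self):
        table = self._table(3)
        table.loc[1, "M2"] = np.nan
        with pytest.warns(UserWarning, match="S1"):
            out = complete_cases(table)
        assert len(out) == 3 and "S1" not in set(out["specimen_id"])


@given(st.lists(st.floats(min_value=0.5, max_value=500), min_size=2, max_size=6),
       st.floats(min_value=0.01, max_value=100))
def test_aggregation_mean_scales_linearly(reps, c):
    """Rescaling all replicates by c rescales the aggregated mean by c."""
    repeats = make_repeat_table({"S1": reps})
    meta = make_metadata(["S1"])
    base = aggregate_repeats(repeats, meta).loc[0, "M1"]
    scaled = aggregate_repeats(repeats.assign(value_mm=repeats.value_mm * c), meta).loc[0, "M1"]
    assert scaled == pytest.approx(c * base, rel=1e-9)
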