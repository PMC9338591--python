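"""Observer-agreement statistics: ICC, Bland-Altman, paired t, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camangle.agreement import (
    bland_altman,
    classify_reliability,
    icc_absolute,
    paired_t,
    simulate_measurement_table,
    summarize,
)
from camangle.errors import SampleSizeError, TableFormatError
from camangle.volume_io import MeasurementTable


def two_rater_table(col1, col2, raters=("a", "b")):
    rows = []
    for i, (x, y) in enumerate(zip(col1, col2)):
        rows.append({"hip_id": f"h{i}", "plane": "p", "rater": raters[0],
                     "alpha_deg": float(x)})
        rows.append({"hip_id": f"h{i}", "plane": "p", "rater": raters[1],
                     "alpha_deg": float(y)})
    return MeasurementTable(pd.DataFrame(rows))


def anova_icc_oracle(Y):
    """Brute-force ICC(A,1) from explicit sums over the data matrix.

    Coded independently of the library routine: loops, no vectorized mean
    squares, straight from the two-way ANOVA decomposition.
    """
    n, k = Y.shape
    grand = sum(Y[i][j] for i in range(n) for j in range(k)) / (n * k)
    ssr = 0.0
    for i in range(n):
        row = sum(Y[i][j] for j in range(k)) / k
        ssr += k * (row - grand) ** 2
    ssc = 0.0
    for j in range(k):
        col = sum(Y[i][j] for i in range(n)) / n
        ssc += n * (col - grand) ** 2
    sst = sum((Y[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    toy1 = [50.0, 55.0, 61.0, 47.0, 58.0, 66.0]
    toy2 = [52.0, 54.0, 65.0, 45.0, 60.0, 63.0]

    def test_identical_columns_give_exactly_one(self):
        res = icc_absolute(two_rater_table(self.toy1, self.toy1), ("a", "b"))
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_toy_table_matches_anova_oracle(self):
        res = icc_absolute(two_rater_table(self.toy1, self.toy2), ("a", "b"))
        want = anova_icc_oracle(np.column_stack([self.toy1, self.toy2]))
        assert res.icc == pytest.approx(want, abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        t = simulate_measurement_table(rng=np.random.default_rng(3),
                                       noise_sd=4.0)
        res = icc_absolute(t, ("obs1", "obs2"))
        df = t.frame.copy()
        df["unit"] = df.hip_id + "|" + df.plane
        row = pg.intraclass_corr(data=df, targets="unit", raters="rater",
                                 ratings="alpha_deg").set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(float(row["ICC"]), abs=1e-10)
        assert res.p_value == pytest.approx(float(row["pval"]), rel=1e-6)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_constant_offset_penalized_but_pearson_blind(self):
        shifted = [x + 10.0 for x in self.toy1]
        res = icc_absolute(two_rater_table(self.toy1, shifted), ("a", "b"))
        assert res.icc < 1.0
        assert np.corrcoef(self.toy1, shifted)[0, 1] == pytest.approx(1.0)

    def test_invariant_to_common_shift_and_relabeling(self):
        t1 = two_rater_table(self.toy1, self.toy2)
        t2 = two_rater_table([x + 30 for x in self.toy1],
                             [x + 30 for x in self.toy2])
        perm = np.random.default_rng(0).permutation(len(self.toy1))
        t3 = two_rater_table([self.toy1[i] for i in perm],
                             [self.toy2[i] for i in perm])
        a = icc_absolute(t1, ("a", "b")).icc
        assert icc_absolute(t2, ("a", "b")).icc == pytest.approx(a, abs=1e-10)
        assert icc_absolute(t3, ("a", "b")).icc == pytest.approx(a, abs=1e-10)

    def test_missing_cells_and_small_samples_rejected(self):
        t = two_rater_table(self.toy1, self.toy2)
        dropped = MeasurementTable(t.frame.iloc[:-1])
        with pytest.raises(TableFormatError):
            icc_absolute(dropped, ("a", "b"))
        with pytest.raises(SampleSizeError):
            icc_absolute(two_rater_table([1.0, 2, 3], [1.0, 2, 3]), ("a", "b"))

    def test_noise_monotonicity_and_recovery(self):
        means = []
        for noise in (1.0, 3.0, 6.0, 12.0):
            vals = [icc_absolute(
                simulate_measurement_table(rng=np.random.default_rng(100 + s),
                                           subject_sd=6.0, noise_sd=noise),
                ("obs1", "obs2")).icc for s in range(8)]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))
        assert means[0] > 0.9  # noise -> 0 drives ICC -> 1


class TestReliabilityBands:
    @pytest.mark.parametrize("icc,band", [
        (0.77, "good"), (0.93, "excellent"), (0.45, "poor"),
        (0.9, "good"), (0.75, "good"), (0.5, "moderate"),
        (0.9001, "excellent"), (0.4999, "poor"), (-0.2, "poor"),
    ])
    def test_banding_rule(self, icc, band):
        assert classify_reliability(icc) == band

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-1.0, 1.0))
    def test_bands_partition_the_range(self, icc):
        assert classify_reliability(icc) in ("poor", "moderate", "good",
                                             "excellent")


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_unit_sd_differences(self):
        ba = bland_altman(np.array([1.0, 2, 3]), np.array([2.0, 2, 2]))
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_high == pytest.approx(1.96)
        assert ba.loa_low == pytest.approx(-1.96)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(10, 170), min_size=3, max_size=40),
           st.integers(0, 10 ** 6))
    def test_antisymmetry(self, xs, seed):
        x = np.asarray(xs)
        y = x + np.random.default_rng(seed).normal(0, 2, len(x))
        f, b = bland_altman(x, y), bland_altman(y, x)
        assert f.bias == pytest.approx(-b.bias, abs=1e-9)
        assert f.loa_low == pytest.approx(-b.loa_high, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2], [1.0, 2, 3])
        with pytest.raises(SampleSizeError):
            bland_altman([1.0, 2], [1.0, 2])


class TestPairedT:
    def test_degenerate_differences_flagged(self):
        t, p, md = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert np.isnan(t) and np.isnan(p) and md == 0.0

    def test_four_pair_closed_form(self):
        x = np.array([61.0, 55.0, 48.0, 70.0])
        y = np.array([58.0, 56.0, 44.0, 65.0])
        d = x - y
        want_t = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        t, p, md = paired_t(x, y)
        assert t == pytest.approx(want_t, abs=1e-12)
        assert md == pytest.approx(d.mean())
        assert 0 < p < 1

    def test_sign_flip_antisymmetry(self):
        x = np.array([61.0, 55.0, 48.0, 70.0])
        y = np.array([58.0, 56.0, 44.0, 65.0])
        t1, p1, _ = paired_t(x, y)
        t2, p2, _ = paired_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestSummarize:
    def make_table(self, values, rater="a"):
        return MeasurementTable(pd.DataFrame(
            [{"hip_id": f"h{i}", "plane": "p", "rater": rater,
              "alpha_deg": float(v)} for i, v in enumerate(values)]))

    def test_constant_column(self):
        s = summarize(self.make_table([55.0] * 10)).loc["a"]
        assert s["sd"] == 0.0
        assert s["p25"] == s["p50"] == s["p75"] == 55.0

    def test_median_of_1_to_100(self):
        s = summarize(self.make_table(np.arange(1.0, 101.0))).loc["a"]
        assert s["p50"] == pytest.approx(50.5)

    def test_quantiles_match_sorting_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(20, 120, 37)
        s = summarize(self.make_table(vals)).loc["a"]
        srt = np.sort(vals)
        for q, key in ((0.25, "p25"), (0.5, "p50"), (0.75, "p75")):
            pos = q * (len(srt) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            want = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
            assert s[key] == pytest.approx(want, abs=1e-9)
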