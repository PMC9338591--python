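"""Observer-agreement statistics for alpha-angle measurements.

Implements the comparison machinery used when validating automated against
manual alpha readings: the intraclass correlation coefficient for absolute
agreement (two-way random effects, single measures — ICC(A,1) in the
McGraw & Wong taxonomy), its F-based 95% confidence interval and
significance test, the conventional reliability bands, Bland–Altman bias
and 95% limits of agreement, paired t-tests and per-rater descriptive
summaries.

The unit of analysis is the hip x plane combination (each radial plane of
each hip counts once), matching how pooled alpha-angle tables are scored;
per-hip aggregation is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SampleSizeError, TableFormatError
from .volume_io import MeasurementTable

BANDS = ("poor", "moderate", "good", "excellent")


@dataclass
class AgreementResult:
    icc: float
    ci95: tuple[float, float]
    p_value: float
    reliability_band: str
    n_subjects: int
    n_raters: int
    model: str = "two-way random, absolute agreement, single measures (ICC(A,1))"


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def classify_reliability(icc: float) -> str:
    """Conventional ICC reliability bands.

    > 0.9 excellent; [0.75, 0.9) good; [0.5, 0.75) moderate; < 0.5 poor.
    """
    if not -1.0 <= icc <= 1.0:
        raise ValueError(f"ICC must be in [-1, 1], got {icc}")
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def _icc_a1_from_matrix(Y: np.ndarray, alpha_level: float = 0.05):
    """ICC(A,1) with F-based CI from an n x k matrix (subjects x raters)."""
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong (1996) confidence interval for ICC(A,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        fj = msc / mse
        v = ((a * fj + b) ** 2 /
             (a ** 2 * fj ** 2 / (k - 1) + b ** 2 / ((n - 1) * (k - 1))))
        f_lo = stats.f.ppf(1 - alpha_level / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha_level / 2, v, n - 1)
        lower = (n * (msr - f_lo * mse) /
                 (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_hi * msr - mse) /
                 (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
    else:
        lower = upper = 1.0
    # significance of the between-subjects effect
    if mse > 0:
        F = msr / mse
        p = float(stats.f.sf(F, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0
    return float(icc), (float(lower), float(upper)), p


def icc_absolute(table: MeasurementTable, rater_pair: tuple[str, str],
                 per_hip: bool = False) -> AgreementResult:
    """Absolute-agreement ICC between two raters on a complete two-way layout.

    Units are hip x plane combinations (or per-hip means with
    ``per_hip=True``); every unit must be rated by both raters — missing
    cells raise rather than being imputed.
    """
    wide = table.pivot(rater_pair)
    if per_hip:
        wide = wide.groupby(level="hip_id").mean()
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise TableFormatError(f"incomplete layout; units missing a rating: "
                               f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    n = len(wide)
    if n < 5:
        raise SampleSizeError(f"need >= 5 units for an ICC, got {n}")
    Y = wide.to_numpy(dtype=float)
    icc, ci, p = _icc_a1_from_matrix(Y)
    return AgreementResult(icc=icc, ci95=ci, p_value=p,
                           reliability_band=classify_reliability(min(icc, 1.0)),
                           n_subjects=n, n_raters=Y.shape[1])


def bland_altman(x, y) -> BlandAltman:
    """Bias and 95% limits of agreement of paired differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if len(x) < 3:
        raise SampleSizeError("need at least 3 pairs")
    diffs = x - y
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd,
                       means=(x + y) / 2.0, diffs=diffs)


def bland_altman_plot(ba: BlandAltman, path, title: str = "Bland-Altman") -> None:
    """Scatter of difference vs mean with the three dashed agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
    for y, label in ((ba.bias, "bias"), (ba.loa_low, "-1.96 SD"),
                     (ba.loa_high, "+1.96 SD")):
        ax.axhline(y, linestyle="--", color="k", linewidth=1)
        ax.annotate(f"{label}: {y:.1f}", (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean alpha of both methods (deg)")
    ax.set_ylabel("difference (deg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def paired_t(x, y) -> tuple[float, float, float]:
    """Two-sided paired t-test; returns (t, p, mean difference).

    Zero-variance differences leave t/p undefined (returned as nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise SampleSizeError("need equal-length series with >= 3 pairs")
    d = x - y
    mean_diff = float(d.mean())
    if np.isclose(d.std(ddof=1), 0.0):
        return float("nan"), float("nan"), mean_diff
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), mean_diff


def summarize(table: MeasurementTable) -> pd.DataFrame:
    """Per-rater mean, SD, min, max and quartiles (linear interpolation)."""
    if len(table) == 0:
        raise SampleSizeError("empty table")
    g = table.frame.groupby("rater")["alpha_deg"]
    out = pd.DataFrame({
        "mean": g.mean(),
        "sd": g.std(ddof=1),
        "min": g.min(),
        "max": g.max(),
        "p25": g.quantile(0.25, interpolation="linear"),
        "p50": g.quantile(0.50, interpolation="linear"),
        "p75": g.quantile(0.75, interpolation="linear"),
    })
    return out


def simulate_measurement_table(n_subjects: int = 19, n_planes: int = 7,
                               raters: tuple[str, str] = ("obs1", "obs2"),
                               mean_alpha: float = 57.0,
                               subject_sd: float = 6.0,
                               noise_sd: float = 3.0,
                               rng: np.random.Generator | None = None,
                               ) -> MeasurementTable:
    """Two-rater table with a known generating intraclass correlation.

    Each hip x plane unit carries a true alpha ~ Normal(mean, subject_sd);
    each rater adds independent Normal(0, noise_sd) error, so the generating
    ICC is subject_sd^2 / (subject_sd^2 + noise_sd^2).
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_subjects):
        for pl in range(n_planes):
            true = rng.normal(mean_alpha, subject_sd)
            for rater in raters:
                rows.append({"hip_id": f"hip{s:02d}", "plane": f"plane{pl}",
                             "rater": rater,
                             "alpha_deg": float(np.clip(
                                 true + rng.normal(0.0, noise_sd), 1.0, 179.0))})
    return MeasurementTable(pd.DataFrame(rows))
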