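"""Criterion-validity statistics on paired per-subject outcomes.

For every movement x outcome the reference (mocap) and test (wearable)
values of each subject form a paired sample.  Agreement is quantified by:

* Bland-Altman bias and 95% limits of agreement.  Differences are taken
  as reference - test, so a positive bias means the wearable
  under-reports.  LoA = bias +- 1.96 x SD of the differences (sample SD,
  n-1 denominator).
* Intraclass correlation from the two-way mixed single-measures model.
  The default is the consistency form,
  ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E);
  the absolute-agreement form adds the method variance term.
  Bands: poor < 0.5 <= moderate < 0.7 <= good < 0.9 <= excellent.
* RMSE over the paired differences, satisfying
  rmse^2 = bias^2 + (n-1)/n * var(d) and hence rmse >= |bias|.
* A heteroscedasticity check: Kendall rank correlation between |d| and
  the pair means (automating the visual Bland-Altman inspection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "bland_altman",
    "icc_two_way_mixed",
    "rmse",
    "classify_icc",
    "heteroscedasticity_check",
    "build_report",
    "REPORT_COLUMNS",
]

log = logging.getLogger(__name__)

#: 95% limits of agreement factor
LOA_FACTOR = 1.96

#: ICC interpretation band edges (half-open intervals, lower edge inclusive)
ICC_BANDS = ((0.9, "excellent"), (0.7, "good"), (0.5, "moderate"))


@dataclass(eq=False)
class PairedMeasurements:
    """Per-subject (reference, test) value pairs for one movement/outcome."""

    outcome_label: str
    movement_label: str
    subjects: list
    reference: np.ndarray
    test: np.ndarray
    units: str = "deg"

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.shape != self.test.shape or self.reference.ndim != 1:
            raise ValueError("reference and test must be 1-d arrays of equal length")
        if len(self.subjects) != len(self.reference):
            raise ValueError("subject ids must match the number of pairs")
        if np.isnan(self.reference).any() or np.isnan(self.test).any():
            raise ValueError("missing pairs must be removed before construction")
        if self.n < 2:
            raise ValueError("need at least 2 pairs")

    @property
    def n(self) -> int:
        return len(self.reference)

    @property
    def differences(self) -> np.ndarray:
        """reference - test (positive: wearable under-reports)."""
        return self.reference - self.test

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.reference + self.test)


def bland_altman(p: PairedMeasurements) -> tuple:
    """(bias, upper LoA, lower LoA); LoA = bias +- 1.96 x sample SD(d)."""
    d = p.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias + LOA_FACTOR * sd, bias - LOA_FACTOR * sd


def _mean_squares(Y: np.ndarray) -> tuple:
    n, k = Y.shape
    grand = Y.mean()
    row = Y.mean(axis=1)
    col = Y.mean(axis=0)
    ssr = k * np.sum((row - grand) ** 2)
    ssc = n * np.sum((col - grand) ** 2)
    resid = Y - row[:, None] - col[None, :] + grand
    sse = np.sum(resid**2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, ssr + ssc + sse


def icc_two_way_mixed(p: PairedMeasurements, form: str = "consistency") -> float:
    """Single-measures ICC from the two-way mixed ANOVA decomposition.

    ``form='consistency'`` gives ICC(3,1); ``form='absolute'`` the
    absolute-agreement variant, which additionally penalises a systematic
    offset between the methods.
    """
    if p.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    Y = np.column_stack([p.reference, p.test])
    n, k = Y.shape
    msr, msc, mse, sstot = _mean_squares(Y)
    if sstot <= 0:
        raise ValueError("zero total variance; ICC undefined")
    if form == "consistency":
        return float((msr - mse) / (msr + (k - 1) * mse))
    if form == "absolute":
        return float(
            (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        )
    raise ValueError(f"unknown ICC form {form!r}")


def rmse(p: PairedMeasurements) -> float:
    """Root mean square paired difference."""
    d = p.differences
    return math.sqrt(float(np.mean(d**2)))


def classify_icc(icc: float) -> str:
    """Interpretation band: poor / moderate / good / excellent."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    for edge, band in ICC_BANDS:
        if icc >= edge:
            return band
    return "poor"


@dataclass(frozen=True)
class HeteroscedasticityResult:
    statistic: float  # Kendall tau between |difference| and pair mean
    p_value: float
    means: np.ndarray = field(repr=False, default=None)
    differences: np.ndarray = field(repr=False, default=None)

    def __iter__(self):  # unpack like a (statistic, p) tuple
        return iter((self.statistic, self.p_value))


def heteroscedasticity_check(p: PairedMeasurements) -> HeteroscedasticityResult:
    """Kendall tau between |d_i| and pair means, with the plot-ready
    (mean, difference) pairs attached."""
    if p.n < 5:
        raise ValueError("heteroscedasticity check needs at least 5 pairs")
    d = p.differences
    res = stats.kendalltau(np.abs(d), p.means)
    return HeteroscedasticityResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        means=p.means,
        differences=d,
    )


REPORT_COLUMNS = [
    "movement", "outcome", "units", "n",
    "ref_mean", "ref_sd", "test_mean", "test_sd",
    "rmse", "icc", "icc_band", "bias", "loa_upper", "loa_lower",
    "het_tau", "het_p",
]


def _report_row(p: PairedMeasurements, icc_form: str) -> dict:
    bias, upper, lower = bland_altman(p)
    row = {
        "movement": p.movement_label,
        "outcome": p.outcome_label,
        "units": p.units,
        "n": p.n,
        "ref_mean": float(p.reference.mean()),
        "ref_sd": float(p.reference.std(ddof=1)),
        "test_mean": float(p.test.mean()),
        "test_sd": float(p.test.std(ddof=1)),
        "rmse": rmse(p),
        "bias": bias,
        "loa_upper": upper,
        "loa_lower": lower,
    }
    try:
        icc = icc_two_way_mixed(p, form=icc_form)
        row["icc"] = icc
        row["icc_band"] = classify_icc(icc)
    except ValueError:
        row["icc"] = np.nan
        row["icc_band"] = ""
    try:
        het = heteroscedasticity_check(p)
        row["het_tau"], row["het_p"] = het.statistic, het.p_value
    except ValueError:
        row["het_tau"] = row["het_p"] = np.nan
    return row


def build_report(
    summaries: pd.DataFrame,
    icc_form: str = "consistency",
    reference_label: str = "reference",
    test_label: str = "wearable",
) -> pd.DataFrame:
    """Assemble the per-movement, per-outcome agreement table.

    ``summaries`` is long-format with columns subject, movement, system,
    outcome, units, value (one row per trial outcome).  Subjects missing
    either system's value for a given movement x outcome are dropped
    listwise (with a logged count).
    """
    required = {"subject", "movement", "system", "outcome", "value"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns {sorted(missing)}")

    rows = []
    for (movement, outcome), grp in summaries.groupby(
        ["movement", "outcome"], sort=False
    ):
        wide = grp.pivot_table(
            index="subject", columns="system", values="value", aggfunc="first"
        )
        if reference_label not in wide or test_label not in wide:
            log.warning("skipping %s %s: only one system present", movement, outcome)
            continue
        paired = wide[[reference_label, test_label]].dropna()
        dropped = len(wide) - len(paired)
        if dropped:
            log.info(
                "%s %s: dropped %d unpaired subject(s)", movement, outcome, dropped
            )
        if len(paired) < 2:
            log.warning("skipping %s %s: fewer than 2 complete pairs",
                        movement, outcome)
            continue
        units = (
            grp["units"].iloc[0] if "units" in grp else
            ("deg" if outcome in ("ROM", "TROM") else "deg/s")
        )
        p = PairedMeasurements(
            outcome_label=outcome,
            movement_label=movement,
            subjects=list(paired.index),
            reference=paired[reference_label].to_numpy(),
            test=paired[test_label].to_numpy(),
            units=units,
        )
        rows.append(_report_row(p, icc_form))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def format_report_text(report: pd.DataFrame) -> str:
    """Aligned-text rendering of the agreement table (mean +- SD per
    system, RMSE, ICC, bias, upper; lower LoA)."""
    lines = []
    hdr = (
        f"{'movement':<14}{'outcome':<8}{'n':>4}  "
        f"{'ref mean+-SD':>18}  {'test mean+-SD':>18}  "
        f"{'RMSE':>7}  {'ICC':>6} {'band':<10}{'bias':>8}  {'upper; lower LoA':>18}"
    )
    lines.append(hdr)
    lines.append("-" * len(hdr))
    for _, r in report.iterrows():
        ref = f"{r.ref_mean:.1f} +- {r.ref_sd:.1f}"
        test = f"{r.test_mean:.1f} +- {r.test_sd:.1f}"
        loa = f"{r.loa_upper:.1f}; {r.loa_lower:.1f}"
        icc = "   nan" if pd.isna(r.icc) else f"{r.icc:6.3f}"
        lines.append(
            f"{r.movement:<14}{r.outcome:<8}{r.n:>4d}  {ref:>18}  {test:>18}  "
            f"{r.rmse:7.1f}  {icc} {r.icc_band:<10}{r.bias:8.1f}  {loa:>18}"
        )
    return "\n".join(lines) + "\n"
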