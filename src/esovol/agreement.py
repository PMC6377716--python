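"""Observer-agreement statistics for paired volume measurements.

Implements the agreement toolbox used in two-rater CT volumetry studies:

* intraclass correlation coefficients (single measures) in the three
  Shrout–Fleiss forms — one-way random ICC(1,1), two-way random absolute
  agreement ICC(2,1) and two-way mixed consistency ICC(3,1) — with
  F-distribution 95% confidence intervals;
* Fisher r-to-z comparison of two independent correlations;
* Bland–Altman limits of agreement (mean difference ± 1.96 × sample SD);
* the mean absolute percentage difference from the pair mean,
  ``100·|v1−v2|/(v1+v2)`` per item, with a t-based confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import SampleSizeError, UndefinedStatisticError, ValidationError

__all__ = [
    "PairedMeasurements",
    "ICCResult",
    "BlandAltmanResult",
    "AgreementReport",
    "icc",
    "compare_icc_fisher",
    "bland_altman",
    "abs_pct_diff_from_mean",
    "bland_altman_plot",
    "agreement_report",
]

ICCForm = Literal["oneway", "twoway_agreement", "twoway_consistency"]
ICC_FORMS: tuple[str, ...] = ("oneway", "twoway_agreement", "twoway_consistency")


@dataclass
class PairedMeasurements:
    """Two raters' (or two replicates') values per item, in ml."""

    items: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        ids = [str(i) for i, _, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError("item ids must be unique")
        for i, v1, v2 in self.items:
            if v1 < 0 or v2 < 0:
                raise ValidationError(f"item {i!r} has a negative value ({v1}, {v2})")

    @classmethod
    def from_arrays(cls, v1: Sequence[float], v2: Sequence[float], ids: Iterable | None = None) -> "PairedMeasurements":
        v1 = np.asarray(v1, dtype=float)
        v2 = np.asarray(v2, dtype=float)
        if v1.shape != v2.shape or v1.ndim != 1:
            raise ValidationError("v1 and v2 must be 1-D arrays of equal length")
        if ids is None:
            ids = range(len(v1))
        return cls([(str(i), float(a), float(b)) for i, a, b in zip(ids, v1, v2)])

    @property
    def n(self) -> int:
        return len(self.items)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        v1 = np.array([a for _, a, _ in self.items], dtype=float)
        v2 = np.array([b for _, _, b in self.items], dtype=float)
        return v1, v2


@dataclass
class ICCResult:
    value: float
    form: str
    ci: tuple[float, float]
    n: int


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    width: float
    sd: float
    n: int


@dataclass
class AgreementReport:
    """Bundle of all agreement statistics for one paired comparison."""

    icc: ICCResult
    ba: BlandAltmanResult
    apd_mean: float
    apd_ci: tuple[float, float]
    n: int


def _anova_mean_squares(v1: np.ndarray, v2: np.ndarray):
    """Two-way (subjects × raters) ANOVA mean squares for k = 2 raters."""
    x = np.column_stack([v1, v2])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows  # one-way residual (raters nested in subjects)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = ss_within / (n * (k - 1))
    return msr, msc, mse, msw, n, k, ss_total


def icc(p: PairedMeasurements, form: ICCForm = "twoway_agreement", unit: str = "single", alpha: float = 0.05) -> ICCResult:
    """Single-measures intraclass correlation with an F-based CI.

    ``form`` selects the ANOVA model: ``oneway`` = ICC(1,1),
    ``twoway_agreement`` = ICC(2,1) (two-way random, absolute agreement, the
    default for comparing raters who must agree on the actual value),
    ``twoway_consistency`` = ICC(3,1).
    """
    if unit != "single":
        raise ValidationError(f"only single-measures ICC is supported, got unit={unit!r}")
    if form not in ICC_FORMS:
        raise ValidationError(f"unknown ICC form {form!r}; expected one of {ICC_FORMS}")
    if p.n < 2:
        raise SampleSizeError(f"ICC needs at least 2 items, got {p.n}")
    v1, v2 = p.arrays()
    msr, msc, mse, msw, n, k, ss_total = _anova_mean_squares(v1, v2)
    if ss_total == 0.0:
        raise UndefinedStatisticError("ICC undefined: zero total variance (all values identical)")

    if form == "oneway":
        denom = msr + (k - 1) * msw
        if denom == 0.0:
            raise UndefinedStatisticError("ICC undefined: zero denominator in one-way form")
        value = (msr - msw) / denom
        df1, df2 = n - 1, n * (k - 1)
        if msw > 0:
            f = msr / msw
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:  # perfect within-subject agreement: degenerate CI
            lo = hi = value
    elif form == "twoway_consistency":
        denom = msr + (k - 1) * mse
        if denom == 0.0:
            raise UndefinedStatisticError("ICC undefined: zero denominator in consistency form")
        value = (msr - mse) / denom
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if mse > 0:
            f = msr / mse
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        else:
            lo = hi = value
    else:  # twoway_agreement
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0.0:
            raise UndefinedStatisticError("ICC undefined: zero denominator in agreement form")
        value = (msr - mse) / denom
        # Satterthwaite CI (McGraw & Wong 1996)
        r = value
        if mse > 0 and abs(1 - r) > 1e-12:
            a = k * r / (n * (1 - r))
            b = 1 + k * r * (n - 1) / (n * (1 - r))
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else np.inf
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = value
    return ICCResult(value=float(value), form=form, ci=(float(lo), float(min(hi, 1.0))), n=n)


def compare_icc_fisher(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    ``z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3))``;
    two-sided p from the standard normal.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise UndefinedStatisticError("Fisher transform is infinite at |r| = 1")
    if n1 <= 3 or n2 <= 3:
        raise SampleSizeError(f"Fisher comparison needs n > 3 in each group, got {n1}, {n2}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bland_altman(p: PairedMeasurements) -> BlandAltmanResult:
    """Limits of agreement: mean(d) ± 1.96 × SD(d) with d = v1 − v2 and the
    sample (n−1) standard deviation; width = 3.92 × SD(d)."""
    if p.n < 2:
        raise SampleSizeError(f"Bland–Altman needs at least 2 pairs, got {p.n}")
    v1, v2 = p.arrays()
    d = v1 - v2
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=md,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        width=3.92 * sd,
        sd=sd,
        n=p.n,
    )


def abs_pct_diff_from_mean(p: PairedMeasurements, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Mean absolute percentage difference from the pair mean.

    Per item the deviation of either rater from the pair mean, as a
    percentage of that mean — ``|v1 − m̄|/m̄ × 100 = 100·|v1−v2|/(v1+v2)``,
    identical for both raters.  Returns the mean over items and a t-based
    ``1−alpha`` CI.
    """
    v1, v2 = p.arrays()
    s = v1 + v2
    zero = [p.items[i][0] for i in np.nonzero(s == 0)[0]]
    if zero:
        raise UndefinedStatisticError(f"percentage difference undefined for items with both values zero: {zero}")
    pct = 100.0 * np.abs(v1 - v2) / s
    mean = float(pct.mean())
    if p.n > 1:
        se = float(pct.std(ddof=1)) / np.sqrt(p.n)
        t = stats.t.ppf(1 - alpha / 2, p.n - 1)
        ci = (mean - t * se, mean + t * se)
    else:
        ci = (mean, mean)
    return mean, ci


def bland_altman_plot(p: PairedMeasurements, path) -> tuple[np.ndarray, np.ndarray, BlandAltmanResult]:
    """Write a Bland–Altman scatter (difference vs mean) with dotted mean
    line and dashed ±1.96 SD limits; returns the plotted arrays and the
    underlying statistics for verification."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    ba = bland_altman(p)
    v1, v2 = p.arrays()
    means = (v1 + v2) / 2.0
    diffs = v1 - v2
    fig = Figure(figsize=(5, 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.scatter(means, diffs, s=18, color="k")
    ax.axhline(ba.mean_diff, linestyle=":", color="k")
    ax.axhline(ba.loa_lower, linestyle="--", color="k")
    ax.axhline(ba.loa_upper, linestyle="--", color="k")
    ax.set_xlabel("Mean of paired volumes (ml)")
    ax.set_ylabel("Difference (ml)")
    fig.tight_layout()
    fig.savefig(path)
    return means, diffs, ba


def agreement_report(p: PairedMeasurements, form: ICCForm = "twoway_agreement") -> AgreementReport:
    """Convenience bundle: ICC, Bland–Altman and percentage difference."""
    mean, ci = abs_pct_diff_from_mean(p)
    return AgreementReport(icc=icc(p, form=form), ba=bland_altman(p), apd_mean=mean, apd_ci=ci, n=p.n)
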