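"""Inter-grader agreement battery.

For a paired set of measurements (one value per unit from each of two
graders) the battery reports:

* **Bland–Altman**: bias = mean(g1 − g2), limits of agreement (LOA)
  bias ± 1.96·SD of the differences, individual 95% confidence intervals
  on each limit, and the percentage of units inside the LOA band.
* **ICC**: the two-way random-effects, absolute-agreement,
  single-measurement intraclass correlation ICC(A,1), from the two-way
  ANOVA mean squares.
* **CoR** (coefficient of repeatability / smallest real difference):
  primarily 1.96·√2·s_w with s_w² the two-way ANOVA error variance; the
  alternative 1.96·SD(diff) convention is reported alongside, since the
  literature uses both.
* a **repeated-measures Bland–Altman** for clustered data (e.g. 68
  stimulus-level distances per eye): differences are modeled with a
  random cluster intercept, variance components estimated by
  method-of-moments one-way ANOVA (negative moment estimates truncated
  at 0), and LOA widened to ±1.96·√(σ²_cluster + σ²_error).

The LOA multiplier is fixed at 1.96; Student's t enters only the CI
half-widths. ICC is undefined (NaN, flagged) when the data carry no
variance at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError

ICC_FORM = "ICC(A,1): two-way random effects, absolute agreement, single measurement"
LOA_MULTIPLIER = 1.96


@dataclass
class PairedMeasurements:
    """Matched per-unit values from two graders, optionally clustered by eye."""

    unit_ids: np.ndarray
    values_grader1: np.ndarray
    values_grader2: np.ndarray
    cluster_ids: np.ndarray | None = None
    units: str = ""  # unit of measurement for reports ("dB", "points", "um")

    def __post_init__(self) -> None:
        self.values_grader1 = np.asarray(self.values_grader1, dtype=float)
        self.values_grader2 = np.asarray(self.values_grader2, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        n = len(self.unit_ids)
        if len(self.values_grader1) != n or len(self.values_grader2) != n:
            raise InvalidInputError("unit_ids and both value vectors must have equal length")
        if n < 2:
            raise InsufficientDataError("need at least 2 paired units")
        if not (np.all(np.isfinite(self.values_grader1))
                and np.all(np.isfinite(self.values_grader2))):
            raise InvalidInputError("non-finite measurement values")
        if self.cluster_ids is not None:
            self.cluster_ids = np.asarray(self.cluster_ids)
            if len(self.cluster_ids) != n:
                raise InvalidInputError("cluster_ids length mismatch")

    @property
    def differences(self) -> np.ndarray:
        return self.values_grader1 - self.values_grader2

    @property
    def n(self) -> int:
        return len(self.unit_ids)


@dataclass
class RepeatabilityReport:
    """Agreement summary for one paired-grader comparison."""

    n_units: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float] | None
    loa_upper_ci: tuple[float, float] | None
    pct_within_loa: float
    icc: float | None = None
    icc_form: str = ICC_FORM
    cor: float | None = None            # 1.96·√2·s_w (ANOVA error variance)
    cor_sd_diff: float | None = None    # 1.96·SD of differences
    sigma_cluster: float | None = None  # repeated-measures variance components
    sigma_error: float | None = None
    method: str = "bland_altman"
    units: str = ""
    warnings: list[str] = field(default_factory=list)


def _loa_ci(loa: float, sd: float, n: int) -> tuple[float, float]:
    # Individual 95% CI on one limit of agreement (Bland & Altman 1986 variance).
    half = stats.t.ppf(0.975, n - 1) * sd * np.sqrt(1.0 / n + LOA_MULTIPLIER ** 2 / (2 * (n - 1)))
    return (loa - half, loa + half)


def bland_altman(m: PairedMeasurements) -> RepeatabilityReport:
    """Bias, 1.96-SD limits of agreement, and individual CIs on each limit.

    With zero variance and n ≥ 3 the report is valid but degenerate: the
    limits collapse onto the bias.
    """
    d = m.differences
    n = m.n
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd
    cis = (_loa_ci(lo, sd, n), _loa_ci(hi, sd, n)) if n >= 3 else (None, None)
    within = float(np.mean((d >= lo) & (d <= hi)) * 100.0)
    return RepeatabilityReport(
        n_units=n, bias=bias, sd_diff=sd, loa_lower=lo, loa_upper=hi,
        loa_lower_ci=cis[0], loa_upper_ci=cis[1], pct_within_loa=within,
        cor_sd_diff=LOA_MULTIPLIER * sd, units=m.units,
    )


def _two_way_mean_squares(m: PairedMeasurements) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the units × graders two-way ANOVA, k = 2 raters.

    The error sum of squares is accumulated directly from the interaction
    residuals (not by subtraction) so perfect agreement gives MSE == 0.0
    exactly.
    """
    x = np.stack([m.values_grader1, m.values_grader2], axis=1)
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError("ICC/CoR need at least 2 units")
    grand = x.mean()
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    msr = k * np.sum((row - grand) ** 2) / (n - 1)
    msc = n * np.sum((col - grand) ** 2) / (k - 1)
    resid = x - row[:, None] - col[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_agreement(m: PairedMeasurements) -> float:
    """ICC(A,1) — two-way random, absolute agreement, single measurement.

    Returns NaN when the data carry no variance at all (undefined ICC).
    """
    msr, msc, mse = _two_way_mean_squares(m)
    n, k = m.n, 2
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan")
    return (msr - mse) / denom


def coefficient_of_repeatability(m: PairedMeasurements) -> float:
    """CoR = 1.96·√2·s_w with s_w² the two-way ANOVA error variance."""
    _, _, mse = _two_way_mean_squares(m)
    return LOA_MULTIPLIER * float(np.sqrt(2.0 * mse))


def analyze_agreement(m: PairedMeasurements) -> RepeatabilityReport:
    """Full battery on unclustered paired data: Bland–Altman + ICC + CoR."""
    report = bland_altman(m)
    report.icc = icc_agreement(m)
    report.cor = coefficient_of_repeatability(m)
    if np.isnan(report.icc):
        report.warnings.append("ICC undefined: data carry no variance")
    return report


def _variance_components(d: np.ndarray, clusters: np.ndarray) -> tuple[float, float, float]:
    """(mu, sigma2_cluster, sigma2_error) by one-way ANOVA method of moments.

    Handles unbalanced clusters with the standard n0 coefficient; for the
    balanced design this is the textbook moment estimator. Negative
    moment estimates truncate at 0.
    """
    labels, inv = np.unique(clusters, return_inverse=True)
    g = len(labels)
    ni = np.bincount(inv).astype(float)
    N = float(len(d))
    means = np.bincount(inv, weights=d) / ni
    grand = float(np.mean(d))
    ssw = float(np.sum((d - means[inv]) ** 2))
    ssb = float(np.sum(ni * (means - grand) ** 2))
    msw = ssw / (N - g)
    msb = ssb / (g - 1)
    n0 = (N - float(np.sum(ni ** 2)) / N) / (g - 1)
    s2_e = msw
    s2_a = max((msb - msw) / n0, 0.0)
    return grand, s2_a, s2_e


def bland_altman_repeated(m: PairedMeasurements) -> RepeatabilityReport:
    """Bland–Altman limits accounting for repeated measures within eyes.

    The per-stimulus differences d_ij are modeled as μ + a_i + e_ij with a
    random per-cluster (eye) intercept; the LOA are μ ± 1.96·√(σ²_a + σ²_e).
    Falls back to the plain analysis, with a warning, when clustering is
    absent, degenerate (one cluster), or vacuous (one observation per
    cluster — the two coincide exactly there).
    """
    if m.cluster_ids is None:
        raise InvalidInputError("bland_altman_repeated requires cluster_ids")
    labels, counts = np.unique(m.cluster_ids, return_counts=True)
    if len(labels) < 2 or counts.max() == 1:
        report = analyze_agreement(m)
        report.method = "bland_altman (fallback)"
        if len(labels) < 2:
            report.warnings.append("single cluster: repeated-measures model not estimable")
        return report

    d = m.differences
    mu, s2_a, s2_e = _variance_components(d, m.cluster_ids)
    sd_total = float(np.sqrt(s2_a + s2_e))
    lo, hi = mu - LOA_MULTIPLIER * sd_total, mu + LOA_MULTIPLIER * sd_total
    within = float(np.mean((d >= lo) & (d <= hi)) * 100.0)
    report = RepeatabilityReport(
        n_units=m.n, bias=mu, sd_diff=sd_total, loa_lower=lo, loa_upper=hi,
        loa_lower_ci=None, loa_upper_ci=None, pct_within_loa=within,
        icc=icc_agreement(m), cor=coefficient_of_repeatability(m),
        cor_sd_diff=LOA_MULTIPLIER * float(np.std(d, ddof=1)),
        sigma_cluster=float(np.sqrt(s2_a)), sigma_error=float(np.sqrt(s2_e)),
        method="bland_altman_repeated (method-of-moments variance components)",
        units=m.units,
    )
    if np.isnan(report.icc):
        report.warnings.append("ICC undefined: data carry no variance")
    report.warnings.append(
        "ICC pooled over stimuli (eye-level clustering not removed); see variance components"
    )
    return report
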