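"""GC-MS formate quantification, per-cell exchange rates and group statistics.

Formate is derivatized to benzyl formate and quantified against a d2-formate
internal standard (ISTD, 50 uM): the 12C analyte appears at m/z 136, 13C
formate at 137 and the ISTD at 138.  Blank-subtracted area ratios
(analyte/ISTD) are mapped to concentrations through a standards calibration.

Exchange rates follow the exometabolomics convention: the change in medium
amount over the culture window, normalized to the time-averaged cell number
(the log-mean of start and end counts, exact under exponential growth) and
to time, in fmol/cell/h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log

import numpy as np
import scipy.stats

__all__ = [
    "GcmsSample",
    "Calibration",
    "RateResult",
    "QuantificationError",
    "fit_calibration",
    "quantify_formate",
    "log_mean_cells",
    "exchange_rate",
    "retention_fraction",
    "tracer_share_of_efflux",
    "group_compare",
]


class QuantificationError(ValueError):
    """Missing internal standard, singular calibration, or similar."""


@dataclass(frozen=True)
class GcmsSample:
    """Peak areas of one GC-MS injection: m/z 136 / 137 / 138 channels."""

    pa_136: float  # 12C formate (benzyl formate derivative)
    pa_137: float  # 13C formate
    pa_138: float  # d2-formate internal standard
    istd_concentration: float = 50.0  # uM
    is_blank: bool = False
    sample_id: str = ""
    group: str = ""

    def __post_init__(self):
        if min(self.pa_136, self.pa_137, self.pa_138) < 0:
            raise ValueError("peak areas must be nonnegative")
        if self.istd_concentration <= 0:
            raise ValueError("istd_concentration must be positive")


@dataclass(frozen=True)
class Calibration:
    """Linear map from blank-subtracted area ratio to concentration (uM)."""

    slope: float
    intercept: float
    r_squared: float = float("nan")

    def __post_init__(self):
        if self.slope <= 0:
            raise QuantificationError(f"calibration slope {self.slope} <= 0")

    def concentration(self, ratio: float) -> float:
        return self.slope * ratio + self.intercept


@dataclass(frozen=True)
class RateResult:
    """Per-cell exchange rate; ``direction`` carries the sign semantics."""

    metabolite: str
    rate: float  # fmol/cell/h, nonnegative
    direction: str  # "consumption" | "efflux"
    n_avg_cells: float
    window: float  # hours

    def __post_init__(self):
        if self.direction not in ("consumption", "efflux"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")
        if self.window <= 0:
            raise ValueError("window must be positive")


def _mean_blank(blanks) -> tuple:
    if not blanks:
        return 0.0, 0.0
    return (
        float(np.mean([b.pa_136 for b in blanks])),
        float(np.mean([b.pa_137 for b in blanks])),
    )


def fit_calibration(standards, blanks=()) -> Calibration:
    """Least-squares line through (blank-subtracted ratio, known concentration).

    ``standards`` is a list of (known uM, GcmsSample); water blanks measured
    alongside provide the background areas subtracted from the analyte
    channel before ratioing against the internal standard.
    """
    standards = list(standards)
    if len({round(c, 9) for c, _ in standards}) < 2:
        raise QuantificationError(
            "need at least two distinct standard concentrations"
        )
    blank_136, _ = _mean_blank(list(blanks))
    ratios, concs = [], []
    for conc, s in standards:
        if s.pa_138 <= 0:
            raise QuantificationError(
                f"standard {s.sample_id!r} has no internal-standard signal"
            )
        ratios.append((s.pa_136 - blank_136) / s.pa_138)
        concs.append(conc)
    fit = scipy.stats.linregress(ratios, concs)
    if not np.isfinite(fit.slope) or fit.slope <= 0:
        raise QuantificationError("singular or non-positive calibration fit")
    r2 = fit.rvalue**2 if np.isfinite(fit.rvalue) else float("nan")
    return Calibration(float(fit.slope), float(fit.intercept), float(r2))


def quantify_formate(
    sample: GcmsSample, blank: GcmsSample, cal: Calibration
) -> tuple:
    """Concentrations (12C formate, 13C formate) in uM for one sample.

    Per channel: subtract the raw blank area, ratio against the sample's
    internal-standard area (m/z 138), apply the calibration, clamp at zero.
    Blanks are not rescaled by the ISTD ratio — they are prepared identically
    and carry the same ISTD amount.
    """
    if sample.pa_138 <= 0:
        raise QuantificationError(
            f"sample {sample.sample_id!r} has no internal-standard signal"
        )
    c12 = cal.concentration((sample.pa_136 - blank.pa_136) / sample.pa_138)
    c13 = cal.concentration((sample.pa_137 - blank.pa_137) / sample.pa_138)
    return max(c12, 0.0), max(c13, 0.0)


def log_mean_cells(n0: float, nt: float) -> float:
    """Time-averaged cell number under exponential growth.

    (nt - n0) / ln(nt / n0); reduces to n0 when growth is nil.  Exact in the
    sense that n_avg * T equals the integral of N(t) dt for exponential N.
    """
    if n0 <= 0 or nt <= 0:
        raise ValueError("cell counts must be positive")
    if nt == n0:
        return float(n0)
    return (nt - n0) / log(nt / n0)


def exchange_rate(
    c0: float,
    ct: float,
    volume_ml: float,
    n0: float,
    nt: float,
    hours: float,
    direction: str | None = None,
    metabolite: str = "",
) -> RateResult:
    """Per-cell exchange rate from a two-time-point medium measurement.

    Delta amount (fmol) = |ct - c0| mM x volume mL x 1e9; rate = amount /
    (log-mean cell number x hours).  Direction is inferred from the sign of
    the concentration change (rise = efflux, fall = consumption); a requested
    direction that contradicts the data is kept but warned about.
    """
    if hours <= 0:
        raise ValueError("hours must be positive")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    n_avg = log_mean_cells(n0, nt)
    amount_fmol = abs(ct - c0) * volume_ml * 1e9
    rate = amount_fmol / (n_avg * hours)
    inferred = "efflux" if ct > c0 else "consumption" if ct < c0 else None
    if direction is None:
        direction = inferred or "efflux"
    elif inferred is not None and direction != inferred:
        warnings.warn(
            f"{metabolite or 'metabolite'}: concentration change implies "
            f"{inferred} but {direction} was requested",
            stacklevel=2,
        )
    return RateResult(metabolite, rate, direction, n_avg, hours)


def retention_fraction(kyn_efflux: RateResult, formate_efflux: RateResult) -> float:
    """Share of IDO1-generated formate retained intracellularly.

    Kynurenine efflux counts IDO1 turnover (one formate released per
    kynurenine formed); the shortfall of formate efflux below it,
    1 - formate/kynurenine, is the fraction consumed by the cell, clamped to
    [0, 1].
    """
    if kyn_efflux.rate <= 0:
        raise QuantificationError(
            "retention undefined: kynurenine efflux rate is zero"
        )
    return float(np.clip(1.0 - formate_efflux.rate / kyn_efflux.rate, 0.0, 1.0))


def tracer_share_of_efflux(tracer_derived: RateResult, total: RateResult) -> float:
    """Tracer-derived share of a total efflux, in percent."""
    if total.rate <= 0:
        raise QuantificationError("total efflux rate is zero")
    share = 100.0 * tracer_derived.rate / total.rate
    if share > 100.0:
        warnings.warn(
            f"{total.metabolite or 'metabolite'}: tracer-derived rate exceeds "
            "total (isotope effect or noise); share > 100%",
            stacklevel=2,
        )
    return share


def group_compare(values_a, values_b, paired: bool = False) -> tuple:
    """Two-sided Student t test between two groups.

    Pooled-variance unpaired test or difference-based paired test.  When both
    groups are constant and equal the comparison is vacuous and (t, p) =
    (0, 1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if paired and a.size != b.size:
        raise ValueError("paired test requires equal group sizes")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    if paired:
        t, p = scipy.stats.ttest_rel(a, b)
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero-variance, equal-mean comparison is vacuous
        return 0.0, 1.0
    return float(t), float(p)
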