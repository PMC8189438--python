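"""Isotopologue arithmetic for LC-MS tracing data.

The measured mass-isotopomer distribution (MID) of a metabolite is the
convolution of its tracer-derived labeling pattern with the natural-abundance
envelope of the measured ion.  This module provides that envelope (from
standard terrestrial isotope abundances), discrete convolution, peak-area
normalization, and the empirical baseline-subtraction correction in which the
isotopologue fractions observed in unlabeled (12C) control cultures are
subtracted from the labeled samples.

Isotopologues are indexed m+n by nominal mass shift n; an
:class:`IsotopologueVector` holds the fractions m+0 ... m+n_max, which sum
to 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

__all__ = [
    "ElementAbundances",
    "IsotopologueVector",
    "PeakAreaVector",
    "CorrectedFractions",
    "parse_formula",
    "natural_abundance_distribution",
    "convolve",
    "fractions_from_areas",
    "baseline_correct",
    "deconvolve_natural_abundance",
]

_SUM_TOL = 1e-9

#: Standard terrestrial isotope abundances as (mass shift, abundance) pairs.
#: 13C 0.0107, 2H 0.000115, 15N 0.00364, 17O 0.00038, 18O 0.00205.
_DEFAULT_ABUNDANCES = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
    "P": ((0, 1.0),),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ConfigurationError(ValueError):
    """Unknown element, pool, or otherwise inconsistent configuration."""


class EmptySignalError(ValueError):
    """A peak-area vector with no signal cannot be normalized."""


class PairingError(ValueError):
    """Sample and control vectors do not refer to the same measurement."""


@dataclass(frozen=True)
class ElementAbundances:
    """Per-element isotope distributions as (mass shift, abundance) pairs.

    Abundances for each element must sum to 1.  ``scale_carbon13`` returns a
    copy with the 13C abundance multiplied by a factor (renormalizing 12C),
    used to study how correction error shrinks as the background vanishes.
    """

    table: dict = field(default_factory=lambda: dict(_DEFAULT_ABUNDANCES))

    def __post_init__(self):
        for element, pairs in self.table.items():
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"abundances for {element} sum to {total}, not 1"
                )

    def pmf(self, element: str) -> np.ndarray:
        """One-atom mass-shift distribution for *element*."""
        try:
            pairs = self.table[element]
        except KeyError:
            raise ConfigurationError(f"unknown element {element!r}") from None
        out = np.zeros(max(shift for shift, _ in pairs) + 1)
        for shift, ab in pairs:
            out[shift] += ab
        return out

    def scale_carbon13(self, factor: float) -> "ElementAbundances":
        base = dict(self.table)
        p13 = 0.0107 * factor
        base["C"] = ((0, 1.0 - p13), (1, p13))
        return ElementAbundances(base)


@dataclass(frozen=True)
class IsotopologueVector:
    """Fractions over m+0 ... m+n_max for one metabolite.

    ``basis`` records whether the fractions describe tracer-derived labeling
    only (natural abundance stripped / not yet applied) or the envelope as
    measured on the instrument.
    """

    metabolite: str
    fractions: np.ndarray
    basis: str = "tracer_derived"

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fr)
        if self.basis not in ("tracer_derived", "measured"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if fr.ndim != 1 or fr.size == 0:
            raise ValueError("fractions must be a nonempty 1-D vector")
        if np.any(fr < -_SUM_TOL):
            raise ValueError("fractions must be nonnegative")
        if abs(fr.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"fractions sum to {fr.sum()}, not 1")

    @property
    def n_max(self) -> int:
        return self.fractions.size - 1

    def labeled_fraction(self) -> float:
        """Summed fraction of all m+n, n >= 1."""
        return float(self.fractions[1:].sum())


@dataclass(frozen=True)
class PeakAreaVector:
    """Raw instrument peak areas for m+0 ... m+n_max of one metabolite."""

    metabolite: str
    areas: np.ndarray
    sample_id: str = ""
    group: str = ""

    def __post_init__(self):
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if areas.ndim != 1 or areas.size == 0:
            raise ValueError("areas must be a nonempty 1-D vector")
        if np.any(areas < 0):
            raise ValueError("peak areas must be nonnegative")


@dataclass(frozen=True)
class CorrectedFractions:
    """Baseline-corrected 13C fractions m+1 ... m+n_max and their sum."""

    metabolite: str
    corrected: np.ndarray  # index 0 corresponds to m+1
    summed_labeled_fraction: float


def parse_formula(formula) -> dict:
    """Parse ``"C10H14N5O7P"`` (or pass through a dict) to an element->count map."""
    if isinstance(formula, dict):
        counts = {el: int(n) for el, n in formula.items() if int(n) != 0}
    else:
        counts = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos or not match.group(0):
                break
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(
                match.group(2) or 1
            )
            pos = match.end()
        if pos != len(formula) or not counts:
            raise ConfigurationError(f"cannot parse formula {formula!r}")
    if any(n < 0 for n in counts.values()):
        raise ConfigurationError("negative element count")
    return counts


def _n_atom_pmf(one_atom: np.ndarray, n: int) -> np.ndarray:
    """Mass-shift distribution of n i.i.d. atoms (repeated self-convolution)."""
    out = np.ones(1)
    for _ in range(n):
        out = np.convolve(out, one_atom)
    return out


def natural_abundance_distribution(
    formula,
    abundances: ElementAbundances | None = None,
    n_max: int | None = None,
    metabolite: str = "",
) -> IsotopologueVector:
    """Natural-abundance mass-shift envelope of an ion.

    Each atom draws its isotope independently; the per-element distributions
    are binomial/multinomial self-convolutions, combined across elements by
    convolution.  If ``n_max`` is given the distribution is truncated there
    and renormalized.
    """
    counts = parse_formula(formula)
    if not counts:
        raise ConfigurationError("empty formula")
    abundances = abundances or ElementAbundances()
    dist = np.ones(1)
    for element, n in counts.items():
        dist = np.convolve(dist, _n_atom_pmf(abundances.pmf(element), n))
    if n_max is not None and dist.size > n_max + 1:
        dist = dist[: n_max + 1]
    dist = dist / dist.sum()
    return IsotopologueVector(metabolite or str(formula), dist, basis="measured")


def convolve(
    a: IsotopologueVector,
    b: IsotopologueVector,
    n_max: int | None = None,
) -> IsotopologueVector:
    """Discrete convolution of two isotopologue vectors.

    The result is truncated at ``n_max`` (when given) and renormalized; its
    basis is "measured", the usual case being tracer labeling convolved with
    the natural-abundance envelope.
    """
    out = np.convolve(a.fractions, b.fractions)
    if n_max is not None and out.size > n_max + 1:
        out = out[: n_max + 1]
    out = out / out.sum()
    return IsotopologueVector(a.metabolite or b.metabolite, out, basis="measured")


def fractions_from_areas(pa: PeakAreaVector) -> np.ndarray:
    """Normalize peak areas to fractions: fraction_n = PA_n / sum_k PA_k."""
    total = pa.areas.sum()
    if total <= 0:
        raise EmptySignalError(f"no signal for {pa.metabolite} ({pa.sample_id})")
    return pa.areas / total


def baseline_correct(
    sample: PeakAreaVector,
    control: PeakAreaVector,
    clamp: bool = True,
) -> CorrectedFractions:
    """Empirical 13C baseline subtraction against an unlabeled control.

    The control culture (no tracer) provides the baseline fraction for each
    isotopologue; corrected_n = sample_fraction_n - baseline_fraction_n for
    n >= 1, negatives clamped to 0 (fractions are physical proportions), and
    the summed labeled fraction is the total over m+1 ... m+n_max.
    """
    if sample.metabolite != control.metabolite:
        raise PairingError(
            f"metabolite mismatch: {sample.metabolite!r} vs {control.metabolite!r}"
        )
    if sample.areas.size != control.areas.size:
        raise PairingError(
            f"{sample.metabolite}: sample has {sample.areas.size} isotopologues, "
            f"control has {control.areas.size}"
        )
    sample_fr = fractions_from_areas(sample)
    control_fr = fractions_from_areas(control)
    corrected = sample_fr[1:] - control_fr[1:]
    if clamp:
        corrected = np.clip(corrected, 0.0, 1.0)
    summed = float(min(corrected.sum(), 1.0)) if clamp else float(corrected.sum())
    return CorrectedFractions(sample.metabolite, corrected, summed)


def deconvolve_natural_abundance(
    measured: IsotopologueVector,
    formula,
    abundances: ElementAbundances | None = None,
) -> IsotopologueVector:
    """Strip the natural-abundance envelope from a measured MID.

    Solves the lower-triangular convolution system ``measured = A @ tracer``
    by nonnegative least squares, where column j of A is the natural envelope
    shifted by j.  Exact for noiseless inputs; serves as the oracle against
    which the empirical baseline subtraction is compared.  The pipeline's
    reported labeled fractions use the baseline subtraction, not this.
    """
    n = measured.n_max
    natural = natural_abundance_distribution(formula, abundances, n_max=n)
    A = np.zeros((n + 1, n + 1))
    env = natural.fractions
    for j in range(n + 1):
        take = min(env.size, n + 1 - j)
        A[j : j + take, j] = env[:take] / env[:take].sum()
    sol, _ = scipy.optimize.nnls(A, measured.fractions)
    total = sol.sum()
    if total <= 0:
        raise EmptySignalError("deconvolution produced an empty distribution")
    return replace(measured, fractions=sol / total, basis="tracer_derived")
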