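"""Forward atom-bookkeeping model of tracer labeling through the kynurenine
pathway and the folate one-carbon network.

IDO1 opens the indole ring of tryptophan; the resulting N-formyl-kynurenine
loses its formyl carbon as formate, so a fully labeled 13C11-tryptophan yields
m+10 kynurenine plus a one-carbon unit that enters the 10-formyl-THF pool.
That pool — mixed from IDO1-derived formate, serine via SHMT, exogenous
formate, and unlabeled sources — feeds purine carbons C2 and C8, the methyl
group of methionine (via re-methylation of homocysteine), and serine C3 (by
condensation with glycine).  At a 24 h end point the pools are modeled as
fully turned over, so each metabolite's tracer-derived labeling is a
convolution of binomial draws over its atom-provenance slots.

``estimate_pool_fractions`` inverts the forward model to recover the
one-carbon pool labeled fraction p and the glycine per-position labeled
fraction q from observed purine and serine labeling.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .isotopes import (
    ConfigurationError,
    IsotopologueVector,
    parse_formula,
)

__all__ = [
    "TracerSpec",
    "MetaboliteDef",
    "OneCarbonParams",
    "PoolFit",
    "TRP_TRACER",
    "SER_TRACER",
    "FORMATE_TRACER",
    "default_metabolites",
    "one_carbon_pool_fraction",
    "pool_labeled_fractions",
    "labeling_distribution",
    "simulate_labeling",
    "estimate_pool_fractions",
    "estimate_pool_fractions_measured",
]

#: Pools a provenance slot may reference.
KNOWN_POOLS = ("trp_intact", "one_carbon", "methyl", "glycine")

_FRAC_TOL = 1e-9


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value} outside [0, 1]")


@dataclass(frozen=True)
class TracerSpec:
    """Identity and purity of the supplied heavy-isotope tracer."""

    name: str
    target_metabolite: str
    n_labeled_carbons: int
    isotopic_purity: float = 0.99
    medium_concentration: float = 0.0  # mM
    extra_heavy_atoms: int = 0  # e.g. the 15N of the serine tracer

    def __post_init__(self):
        _check_fraction("isotopic_purity", self.isotopic_purity)
        if self.n_labeled_carbons < 0:
            raise ValueError("n_labeled_carbons must be nonnegative")
        if self.medium_concentration < 0:
            raise ValueError("medium_concentration must be nonnegative")


#: The study's three tracers: 0.08 mM 13C11-Trp, 0.4 mM 13C3-15N1-Ser
#: (the 15N rides along on the intact tracer but is never transferred with
#: the donated one-carbon), and 13C1-formate.  Vendor purity 99%.
TRP_TRACER = TracerSpec("13C11-tryptophan", "tryptophan", 11, 0.99, 0.08)
SER_TRACER = TracerSpec("13C3-15N1-serine", "serine", 3, 0.99, 0.4, extra_heavy_atoms=1)
FORMATE_TRACER = TracerSpec("13C1-formate", "formate", 1, 0.99, 1.0)


@dataclass(frozen=True)
class MetaboliteDef:
    """Carbon count, elemental formula and atom-provenance slots.

    Each slot names a pool and how many carbon positions it fills; positions
    not covered by any slot are unlabeled under every tracer.  The
    ``trp_intact`` pool transfers wholesale (all positions labeled together),
    modeling kynurenine inheriting ten contiguous tryptophan carbons.
    """

    name: str
    n_carbons: int
    formula: dict = field(default_factory=dict)
    slots: tuple = ()  # ((pool_name, n_positions), ...)

    def __post_init__(self):
        formula = parse_formula(self.formula) if self.formula else {}
        object.__setattr__(self, "formula", formula)
        slots = tuple((str(p), int(n)) for p, n in self.slots)
        object.__setattr__(self, "slots", slots)
        if formula and formula.get("C", 0) != self.n_carbons:
            raise ConfigurationError(
                f"{self.name}: formula carbon count {formula.get('C', 0)} "
                f"!= n_carbons {self.n_carbons}"
            )
        if any(n < 0 for _, n in slots):
            raise ConfigurationError(f"{self.name}: negative slot size")
        if sum(n for _, n in slots) > self.n_carbons:
            raise ConfigurationError(f"{self.name}: slots exceed carbon count")


@dataclass(frozen=True)
class OneCarbonParams:
    """Source mix of the one-carbon pool and companion pool labeling.

    f_trp, f_ser, f_exo_formate and f_other are the shares of the
    10-formyl-THF pool contributed by IDO1-derived formate, serine/SHMT,
    exogenous formate and unlabeled sources; they must sum to 1.  q_gly is
    the per-position labeled fraction of the glycine pool and
    trp_intracellular_labeled the labeled fraction of intracellular
    tryptophan.  ``ido1_active=False`` forces the f_trp contribution to zero,
    modeling -IFNgamma or epacadostat.
    """

    f_trp: float = 0.0
    f_ser: float = 0.0
    f_exo_formate: float = 0.0
    f_other: float = 1.0
    q_gly: float = 0.0
    trp_intracellular_labeled: float = 0.0
    ido1_active: bool = True

    def __post_init__(self):
        for name in (
            "f_trp",
            "f_ser",
            "f_exo_formate",
            "f_other",
            "q_gly",
            "trp_intracellular_labeled",
        ):
            _check_fraction(name, getattr(self, name))
        total = self.f_trp + self.f_ser + self.f_exo_formate + self.f_other
        if abs(total - 1.0) > _FRAC_TOL:
            raise ValueError(f"source fractions sum to {total}, not 1")


def _load_metabolite_table(text: str) -> dict:
    defs = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, formula, n_carbons, slot_text = line.split("\t")
        slots = []
        if slot_text and slot_text != "-":
            for part in slot_text.split("+"):
                pool, n = part.split(":")
                slots.append((pool, int(n)))
        defs[name] = MetaboliteDef(name, int(n_carbons), formula, tuple(slots))
    return defs


def default_metabolites(path=None) -> dict:
    """Load the shipped metabolite/pathway definition table (or a user file).

    The table is plain TSV (name, formula, carbon count, slot list) so a user
    can override provenance assumptions without touching code.
    """
    if path is not None:
        with open(path) as fh:
            return _load_metabolite_table(fh.read())
    source = importlib.resources.files("c1trace.data").joinpath("metabolites.tsv")
    return _load_metabolite_table(source.read_text())


def _tracer_kind(tracer: TracerSpec) -> str:
    kind = tracer.target_metabolite.strip().lower()
    if kind not in ("tryptophan", "serine", "formate"):
        raise ConfigurationError(f"unsupported tracer target {kind!r}")
    return kind


def one_carbon_pool_fraction(params: OneCarbonParams, tracer: TracerSpec) -> float:
    """Labeled share p of the one-carbon (10-formyl-THF) pool.

    Only the source that carries the tracer's label contributes: the Trp
    tracer labels the pool through the formyl carbon released by IDO1, the
    serine tracer through the SHMT-donated C3, and the formate tracer
    directly.  Each contribution is weighted by the tracer's isotopic purity.
    """
    kind = _tracer_kind(tracer)
    f_trp = params.f_trp if params.ido1_active else 0.0
    source_share = {
        "tryptophan": f_trp,
        "serine": params.f_ser,
        "formate": params.f_exo_formate,
    }[kind]
    return source_share * tracer.isotopic_purity


def pool_labeled_fractions(params: OneCarbonParams, tracer: TracerSpec) -> dict:
    """Effective labeled fraction of every pool under the given tracer.

    The glycine pool carries label only under the serine tracer (glycine
    inherits serine C1-C2; the one-carbon unit donated by the other tracers
    sits on serine C3, which glycine does not retain).  The intracellular
    tryptophan pool is labeled only under the tryptophan tracer.  The methyl
    pool shares the one-carbon pool's fraction (single-pool model).
    """
    kind = _tracer_kind(tracer)
    p = one_carbon_pool_fraction(params, tracer)
    return {
        "one_carbon": p,
        "methyl": p,
        "glycine": params.q_gly if kind == "serine" else 0.0,
        "trp_intact": (
            params.trp_intracellular_labeled if kind == "tryptophan" else 0.0
        ),
    }


def _binom(n: int, p: float) -> np.ndarray:
    # small n (<= 11); direct product avoids scipy overhead in hot loops
    pmf = np.ones(1)
    step = np.array([1.0 - p, p])
    for _ in range(n):
        pmf = np.convolve(pmf, step)
    return pmf


def labeling_distribution(
    mdef: MetaboliteDef, pool_fractions: dict
) -> IsotopologueVector:
    """Tracer-derived MID of one metabolite given per-pool labeled fractions.

    Binomial draw per slot (independent positions), convolved across slots;
    the ``trp_intact`` pool transfers all-or-nothing.  Uncovered carbons add
    a point mass at zero shift and do not extend the support.
    """
    dist = np.ones(1)
    for pool, n in mdef.slots:
        if pool not in KNOWN_POOLS:
            raise ConfigurationError(f"{mdef.name}: unknown pool {pool!r}")
        frac = pool_fractions.get(pool, 0.0)
        if pool == "trp_intact":
            slot = np.zeros(n + 1)
            slot[0] = 1.0 - frac
            slot[n] = frac
        else:
            slot = _binom(n, frac)
        dist = np.convolve(dist, slot)
    return IsotopologueVector(mdef.name, dist, basis="tracer_derived")


def simulate_labeling(
    params: OneCarbonParams,
    tracer: TracerSpec,
    defs,
) -> dict:
    """Forward-simulate tracer-derived MIDs for a panel of metabolites."""
    pools = pool_labeled_fractions(params, tracer)
    if isinstance(defs, dict):
        defs = defs.values()
    return {m.name: labeling_distribution(m, pools) for m in defs}


@dataclass(frozen=True)
class PoolFit:
    """Recovered (p, q_gly) with the residual of the least-squares fit."""

    p: float
    q_gly: float
    residual: float
    uninformative: bool = False


def _model_vectors(p: float, q: float, purine_def, serine_def, n_pur, n_ser):
    pools = {"one_carbon": p, "methyl": p, "glycine": q, "trp_intact": 0.0}
    pur = labeling_distribution(purine_def, pools).fractions
    ser = labeling_distribution(serine_def, pools).fractions
    return _pad(pur, n_pur), _pad(ser, n_ser)


def _pad(v: np.ndarray, n: int) -> np.ndarray:
    if v.size >= n:
        return v[:n]
    return np.pad(v, (0, n - v.size))


def estimate_pool_fractions(
    observed_purine: IsotopologueVector,
    observed_serine: IsotopologueVector,
    purine_def: MetaboliteDef,
    serine_def: MetaboliteDef,
) -> PoolFit:
    """Invert the forward model for (p, q_gly) by bounded least squares.

    Fits the ungated model — pools set directly to (p, q) — so a serine-tracer
    experiment recovers both parameters.  The purine MID alone is symmetric
    under p <-> q (two one-carbon + two glycine positions); the serine MID
    (one one-carbon + two glycine positions) breaks the tie, and a multistart
    over the unit square avoids the mirrored local minimum.  Deterministic
    given its inputs.
    """
    obs_pur = observed_purine.fractions
    obs_ser = observed_serine.fractions
    if obs_pur[0] > 1.0 - _FRAC_TOL and obs_ser[0] > 1.0 - _FRAC_TOL:
        return PoolFit(0.0, 0.0, 0.0, uninformative=True)
    n_pur, n_ser = obs_pur.size, obs_ser.size

    def residuals(theta):
        pur, ser = _model_vectors(
            theta[0], theta[1], purine_def, serine_def, n_pur, n_ser
        )
        return np.concatenate([pur - obs_pur, ser - obs_ser])

    best = None
    for start in ((0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)):
        fit = scipy.optimize.least_squares(
            residuals, start, bounds=([0.0, 0.0], [1.0, 1.0]), xtol=1e-14,
            ftol=1e-14, gtol=1e-14,
        )
        if best is None or fit.cost < best.cost:
            best = fit
    p, q = best.x
    return PoolFit(float(p), float(q), float(2.0 * best.cost))


def estimate_pool_fractions_measured(
    measured_purine: IsotopologueVector,
    measured_serine: IsotopologueVector,
    purine_def: MetaboliteDef,
    serine_def: MetaboliteDef,
    abundances=None,
) -> PoolFit:
    """Fit (p, q_gly) directly in measured space.

    The model MID is convolved with each ion's natural-abundance envelope
    before comparison with the measured fractions, so no correction step (and
    none of the empirical baseline's truncation bias) enters the fit; exact
    for noiseless data.  Requires elemental formulas on both definitions.
    """
    from .isotopes import convolve, natural_abundance_distribution

    obs_pur = measured_purine.fractions
    obs_ser = measured_serine.fractions
    n_pur, n_ser = obs_pur.size, obs_ser.size
    na_pur = natural_abundance_distribution(
        purine_def.formula, abundances, n_max=purine_def.n_carbons
    )
    na_ser = natural_abundance_distribution(
        serine_def.formula, abundances, n_max=serine_def.n_carbons
    )

    def residuals(theta):
        pools = {
            "one_carbon": theta[0],
            "methyl": theta[0],
            "glycine": theta[1],
            "trp_intact": 0.0,
        }
        pur = convolve(
            labeling_distribution(purine_def, pools), na_pur,
            n_max=purine_def.n_carbons,
        ).fractions
        ser = convolve(
            labeling_distribution(serine_def, pools), na_ser,
            n_max=serine_def.n_carbons,
        ).fractions
        return np.concatenate(
            [_pad(pur, n_pur) - obs_pur, _pad(ser, n_ser) - obs_ser]
        )

    best = None
    for start in ((0.25, 0.25), (0.75, 0.25), (0.25, 0.75), (0.75, 0.75)):
        fit = scipy.optimize.least_squares(
            residuals, start, bounds=([0.0, 0.0], [1.0, 1.0]), xtol=1e-14,
            ftol=1e-14, gtol=1e-14,
        )
        if best is None or fit.cost < best.cost:
            best = fit
    p, q = best.x
    return PoolFit(float(p), float(q), float(2.0 * best.cost))
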