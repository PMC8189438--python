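"""Synthetic experiments with known ground truth.

Emulates the study's three measurement processes so every pipeline stage is
testable without the deposited raw data:

* LC-MS isotopologue tables — tracer-derived labeling from the forward
  pathway model, convolved with each ion's natural-abundance envelope,
  scaled to instrument-like peak areas and perturbed by multiplicative
  log-normal noise; an unlabeled control table is generated alongside with
  all tracer labeling off.
* GC-MS formate samples — analyte/ISTD area ratios proportional to
  concentration, plus a standards ladder and water blanks that share the
  same constant instrument background.
* Medium time courses — end-point concentrations from true per-cell rates
  integrated over exponential cell growth, consistent with the log-mean
  normalization used downstream so the zero-noise round trip is exact.

Defaults reproduce the study conditions: n = 3 biological replicates, 99%
tracer purity, a 24 h window, and true rates from the IFNgamma-treated
HPAF-II condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd

from .isotopes import ElementAbundances, convolve, natural_abundance_distribution
from .pathway import (
    TRP_TRACER,
    MetaboliteDef,
    OneCarbonParams,
    TracerSpec,
    default_metabolites,
    pool_labeled_fractions,
    simulate_labeling,
)
from .tables import PEAK_AREA_COLUMNS, write_table

__all__ = [
    "ExperimentConfig",
    "default_config",
    "generate_lcms_tables",
    "generate_gcms_samples",
    "generate_medium_timecourse",
    "generate_experiment",
]

#: True exchange rates (fmol/cell/h) emulating the IFNgamma-treated HPAF-II
#: condition: total formate efflux 29.4 with a tracer-derived share of 13.3;
#: kynurenine efflux set so formate efflux is 32.5% (the 30%-35% midpoint)
#: below it; tryptophan consumption 32.1.
DEFAULT_TRUE_RATES = {
    "formate": (29.4, "efflux"),
    "formate_13C": (13.3, "efflux"),
    "kynurenine": (13.3 / 0.675, "efflux"),
    "tryptophan": (32.1, "consumption"),
}

DEFAULT_C0_MM = {
    "formate": 0.0,
    "formate_13C": 0.0,
    "kynurenine": 0.0,
    "tryptophan": 0.4,
}

GCMS_COLUMNS = [
    "sample_id",
    "group",
    "pa_136",
    "pa_137",
    "pa_138",
    "is_blank",
    "is_standard",
    "standard_um",
]

RATES_COLUMNS = [
    "sample_id",
    "metabolite",
    "c0_mM",
    "ct_mM",
    "volume_mL",
    "n0",
    "nt",
    "hours",
    "direction",
    "depleted",
]


@dataclass
class ExperimentConfig:
    """Complete description of one synthetic tracing experiment."""

    tracer: TracerSpec = TRP_TRACER
    params: OneCarbonParams = field(
        default_factory=lambda: OneCarbonParams(
            f_trp=0.5,
            f_ser=0.4,
            f_exo_formate=0.0,
            f_other=0.1,
            q_gly=0.3,
            trp_intracellular_labeled=0.99,
        )
    )
    metabolites: dict = field(default_factory=default_metabolites)
    n_replicates: int = 3
    noise_cv: float = 0.05
    total_area_scale: float = 1e6
    n0: float = 3e5
    doubling_time_h: float = 24.0
    volume_ml: float = 2.0
    hours: float = 24.0
    true_rates: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RATES))
    c0_mm: dict = field(default_factory=lambda: dict(DEFAULT_C0_MM))
    istd_um: float = 50.0
    gcms_istd_area: float = 1e5
    gcms_background_area: float = 2e3
    standards_um: tuple = (0.0, 10.0, 25.0, 50.0, 100.0)
    n_blanks: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def nt(self) -> float:
        return self.n0 * 2.0 ** (self.hours / self.doubling_time_h)

    def to_jsonable(self) -> dict:
        out = asdict(self)
        out["metabolites"] = sorted(self.metabolites)
        return out


def default_config(**overrides) -> ExperimentConfig:
    return ExperimentConfig(**overrides)


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_lcms_tables(
    cfg: ExperimentConfig, rng: np.random.Generator | None = None
):
    """Labeled and unlabeled-control peak-area tables plus ground truth.

    Per metabolite and replicate, areas are ``total_area_scale x
    (tracer_labeling (*) natural_abundance) x noise``; the control table uses
    the same instrument model with every pool unlabeled.  Identical seeds
    give identical tables.
    """
    rng = rng or cfg.rng()
    abundances = ElementAbundances()
    defs = cfg.metabolites
    labeled_mids = simulate_labeling(cfg.params, cfg.tracer, defs)
    blank_params = OneCarbonParams()  # all pools unlabeled
    control_mids = simulate_labeling(blank_params, cfg.tracer, defs)

    def rows_for(mids, group):
        rows = []
        for name in sorted(defs):
            mdef: MetaboliteDef = defs[name]
            natural = natural_abundance_distribution(
                mdef.formula, abundances, n_max=mdef.n_carbons, metabolite=name
            )
            measured = convolve(mids[name], natural, n_max=mdef.n_carbons)
            for rep in range(1, cfg.n_replicates + 1):
                noise = _lognormal_factors(rng, cfg.noise_cv, measured.fractions.size)
                areas = cfg.total_area_scale * measured.fractions * noise
                for n, area in enumerate(areas):
                    rows.append(
                        {
                            "sample_id": f"{group}_rep{rep}",
                            "group": group,
                            "metabolite": name,
                            "isotopologue": n,
                            "peak_area": area,
                        }
                    )
        return pd.DataFrame(rows, columns=PEAK_AREA_COLUMNS)

    labeled = rows_for(labeled_mids, cfg.tracer.name)
    control = rows_for(control_mids, "12C-control")
    truth = {
        "pool_fractions": pool_labeled_fractions(cfg.params, cfg.tracer),
        "tracer_derived": {
            name: mid.fractions.tolist() for name, mid in labeled_mids.items()
        },
        "summed_labeled_fraction": {
            name: mid.labeled_fraction() for name, mid in labeled_mids.items()
        },
    }
    return labeled, control, truth


def generate_gcms_samples(
    cfg: ExperimentConfig,
    true_c12_um: float,
    true_c13_um: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """GC-MS sample table: replicates, standards ladder and water blanks.

    Channel areas follow ``ISTD_area x concentration / istd_um`` plus a
    constant derivatization background shared by samples, standards and
    blanks (so raw-area blank subtraction removes it exactly at zero noise).
    """
    if min(true_c12_um, true_c13_um) < 0:
        raise ValueError("concentrations must be nonnegative")
    rng = rng or cfg.rng()
    a0, bg = cfg.gcms_istd_area, cfg.gcms_background_area

    def sample_row(sample_id, group, c12, c13, is_blank, is_standard, standard_um):
        noise = _lognormal_factors(rng, cfg.noise_cv, 3)
        return {
            "sample_id": sample_id,
            "group": group,
            "pa_136": (a0 * c12 / cfg.istd_um + bg) * noise[0],
            "pa_137": (a0 * c13 / cfg.istd_um + bg) * noise[1],
            "pa_138": a0 * noise[2],
            "is_blank": is_blank,
            "is_standard": is_standard,
            "standard_um": standard_um,
        }

    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        rows.append(
            sample_row(f"sample_rep{rep}", "sample", true_c12_um, true_c13_um,
                       False, False, np.nan)
        )
    for conc in cfg.standards_um:
        rows.append(
            sample_row(f"std_{conc:g}uM", "standard", conc, 0.0, False, True, conc)
        )
    for i in range(1, cfg.n_blanks + 1):
        rows.append(sample_row(f"blank_{i}", "blank", 0.0, 0.0, True, False, np.nan))
    return pd.DataFrame(rows, columns=GCMS_COLUMNS)


def integrated_cell_hours(n0: float, doubling_time_h: float, hours: float) -> float:
    """Integral of N(t) dt over the window for exponential growth (cell*h)."""
    if doubling_time_h <= 0 or not np.isfinite(doubling_time_h):
        return n0 * hours
    growth = log(2.0) / doubling_time_h
    return n0 * (np.expm1(growth * hours)) / growth


def generate_medium_timecourse(
    cfg: ExperimentConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Two-time-point medium rows consistent with the rate estimator.

    Delta amount = rate x integral of N(t) dt, which equals the log-mean cell
    number times the window, so ``exchange_rate`` recovers the true rate
    exactly at zero noise.  Concentrations that would fall below zero are
    floored and flagged ``depleted``.
    """
    if not cfg.true_rates:
        raise ValueError("true_rates is empty")
    rng = rng or cfg.rng()
    nt = cfg.nt()
    cell_hours = integrated_cell_hours(cfg.n0, cfg.doubling_time_h, cfg.hours)
    rows = []
    for metabolite in sorted(cfg.true_rates):
        rate, direction = cfg.true_rates[metabolite]
        c0 = cfg.c0_mm.get(metabolite, 0.0)
        delta_mm = rate * cell_hours / (cfg.volume_ml * 1e9)
        for rep in range(1, cfg.n_replicates + 1):
            noisy_delta = delta_mm * _lognormal_factors(rng, cfg.noise_cv, 1)[0]
            ct = c0 + noisy_delta if direction == "efflux" else c0 - noisy_delta
            depleted = ct < 0
            rows.append(
                {
                    "sample_id": f"{metabolite}_rep{rep}",
                    "metabolite": metabolite,
                    "c0_mM": c0,
                    "ct_mM": max(ct, 0.0),
                    "volume_mL": cfg.volume_ml,
                    "n0": cfg.n0,
                    "nt": nt,
                    "hours": cfg.hours,
                    "direction": direction,
                    "depleted": depleted,
                }
            )
    return pd.DataFrame(rows, columns=RATES_COLUMNS)


def generate_experiment(cfg: ExperimentConfig, outdir) -> dict:
    """Write the full synthetic experiment (CSV + ground-truth JSON) to disk."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    labeled, control, truth = generate_lcms_tables(cfg, rng)
    gcms_truth = {
        "c12_um": cfg.true_rates.get("formate", (0.0, "efflux"))[0]
        * integrated_cell_hours(cfg.n0, cfg.doubling_time_h, cfg.hours)
        / (cfg.volume_ml * 1e9)
        * 1e3,
        "c13_um": cfg.true_rates.get("formate_13C", (0.0, "efflux"))[0]
        * integrated_cell_hours(cfg.n0, cfg.doubling_time_h, cfg.hours)
        / (cfg.volume_ml * 1e9)
        * 1e3,
    }
    gcms = generate_gcms_samples(cfg, gcms_truth["c12_um"], gcms_truth["c13_um"], rng)
    rates = generate_medium_timecourse(cfg, rng)
    config = cfg.to_jsonable()
    write_table(labeled, outdir / "lcms_labeled.csv", seed=cfg.seed, config=config)
    write_table(control, outdir / "lcms_control.csv", seed=cfg.seed, config=config)
    write_table(gcms, outdir / "gcms_samples.csv", seed=cfg.seed, config=config)
    write_table(rates, outdir / "rates_input.csv", seed=cfg.seed, config=config)
    truth = {
        **truth,
        "gcms": gcms_truth,
        "true_rates": {m: list(v) for m, v in cfg.true_rates.items()},
        "seed": cfg.seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
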