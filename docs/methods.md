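# Methods

## The labeling model

`c1trace` models a 24 h end-point tracing experiment as a steady-state
mixing problem, not a kinetic one: over a day the free metabolite pools turn
over many times, so each pool is described by a single labeled fraction and
each metabolite's tracer-derived mass isotopomer distribution (MID) is a
convolution of independent draws over its atom-provenance slots.

Pools and their labeled fractions:

| pool | meaning | labeled fraction |
|---|---|---|
| `trp_intact` | intracellular tryptophan | `trp_intracellular_labeled` (Trp tracer only) |
| `one_carbon` | 10-formyl-THF | p = Σₛ fₛ·(tracer purity), matching source only |
| `methyl` | 5-CH₃-THF | equal to p (single-pool model) |
| `glycine` | per-position glycine labeling | `q_gly` (serine tracer only) |

The one-carbon pool is mixed from four sources — IDO1-derived formate
(`f_trp`), serine via SHMT (`f_ser`), exogenous formate (`f_exo_formate`)
and unlabeled sources (`f_other`), summing to 1. Only the source that
carries the supplied tracer's label contributes to p, weighted by the
tracer's isotopic purity (0.99 by default, the vendor's 99% specification).
`ido1_active = False` zeroes the `f_trp` contribution without renormalizing
the rest, which models acute IDO1 inhibition (epacadostat) or the absence of
IFNγ induction.

Slot semantics: a slot of *k* positions fed by a pool with labeled fraction
*x* contributes Binomial(*k*, *x*); slots convolve independently;
carbons not covered by a slot are unlabeled. Two exceptions to the binomial
rule: `trp_intact` transfers wholesale (kynurenine inherits ten contiguous
tryptophan carbons: 11 tracer carbons minus the formyl carbon released as
formate, so Trp m+11 → Kyn m+10), and monoisotopic pools behave as point
masses trivially.

Default atom provenance (shipped as a user-overridable TSV in
`c1trace/data/`): purine nucleotides carry two one-carbon positions (C2, C8
from 10-formyl-THF) and two glycine positions; the CO₂-derived C6 and the
ribose are treated as unlabeled under all three tracers, consistent with the
m+1/m+2-dominated purine labeling the model targets. Serine is one
one-carbon position (C3) plus two glycine positions; methionine one methyl
position; acetyl-CoA two one-carbon positions via the adenine ring of the
CoA moiety, with the acetyl positions unlabeled (the acetyl routes
contribute negligibly). NAD(P)⁺ synthesis and TCA entry via α-ketoadipate
are out of scope: the associated labeling is negligible in this system.

### Tracer gating of the glycine pool

The glycine pool's labeled fraction is `q_gly` only under the serine tracer:
glycine inherits serine C1–C2, which carry the serine tracer's carbons,
whereas the one-carbon unit donated under the tryptophan or formate tracers
sits on serine C3, which glycine does not retain. Serine synthesis is
modeled as glycine + one-carbon condensation only; a possible reverse-SHMT
exchange contribution to serine m+1 is not modeled separately because the
end-point data cannot distinguish it from the forward condensation. The ¹⁵N
of the serine tracer travels with the intact tracer molecule (the
`extra_heavy_atoms` field of the tracer spec) but is never transferred with
the donated one-carbon — only carbon transits the THF cycle.

## Natural abundance and the empirical baseline

The measured MID is the tracer-derived MID convolved with the ion's
natural-abundance envelope, computed per element from standard terrestrial
abundances (¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205,
plus sulfur isotopes) by per-element self-convolution and cross-element
convolution, truncated at the ion's carbon count and renormalized.

The pipeline's reported labeled fractions use the empirical baseline
subtraction: isotopologue fractions from unlabeled control cultures are
subtracted per isotopologue (n ≥ 1) from the labeled samples. Properties
worth knowing:

- Negative corrected fractions are clamped to zero before summation —
  fractions are physical proportions, and this matches reporting peaks
  detected above baseline. The summed labeled fraction is capped at 1.
- Control replicates are averaged **as fractions** (per metabolite) before
  subtraction, so controls with different total intensity weigh equally.
- The subtraction is deliberately simple and carries a known multiplicative
  bias: for a true summed labeled fraction L, it recovers approximately
  NA(m+0)·L, where NA(m+0) is the envelope's monoisotopic probability
  (≈0.89 for a C₁₀ ion, ≈0.69 for CoA). The bias shrinks monotonically as
  the ¹³C abundance goes to zero; a test asserts this against an exhaustive
  per-atom enumeration oracle.
- Full matrix deconvolution (nonnegative least squares on the convolution
  matrix) is provided as `deconvolve_natural_abundance` and used as a test
  oracle, but is **not** the default reported correction.

Because of the baseline bias, parameter recovery does not invert corrected
fractions. `estimate_pool_fractions_measured` fits the forward model in
measured space — model MID ⊛ envelope against measured fractions — which is
exact for noiseless data. The fit is bounded least squares over
(p, q) ∈ [0,1]² from four starting points: the purine MID alone is symmetric
under p ↔ q (two one-carbon + two glycine positions), and the serine MID
breaks the tie, so the multistart avoids the mirrored local minimum. The
plain `estimate_pool_fractions` variant fits already-corrected
(tracer-derived) MIDs with the same machinery and is checked against a
0.001-step grid-search oracle. An all-m+0 input returns (0, 0) flagged
`uninformative`.

## GC-MS formate quantification

Formate, ¹³C-formate and the d₂-formate internal standard (50 µM) appear at
m/z 136/137/138 after derivatization. Calibration is ordinary least squares
of known standard concentrations on blank-subtracted area ratios
(analyte − mean blank)/ISTD; quantification applies the same ratioing per
channel and clamps at zero. Blank subtraction is raw per-channel area
subtraction — blanks are prepared identically and carry the same ISTD
amount, so no ISTD rescaling of the blank is applied. Cross-talk of the d₂
channel into 136/137 is not modeled (channels treated as clean).

## Exchange rates

Two-time-point design only (t = 0 medium vs end point): Δamount(fmol) =
|c_t − c₀| mM × volume mL × 10⁹, and rate = Δamount/(n̄·t) with n̄ =
(n_t − n₀)/ln(n_t/n₀). The log-mean is exact for exponential growth —
n̄·t equals ∫N(t)dt — and reduces to n₀ when growth is nil. For 3D cultures
counted by protein, a user-supplied cells-per-mg factor converts BCA protein
to a pseudo-cell count before the same arithmetic. Derived quantities:
retention fraction 1 − formate/kynurenine (kynurenine efflux counts IDO1
turnover, one formate released per kynurenine formed; clamped to [0,1]) and
the tracer-derived share of total efflux in percent (shares above 100% are
reported with a warning: isotope effect or noise). Absolute kynurenine
rates from LC-MS require a user-supplied response factor; none is guessed.

Group comparisons are classical two-sided Student t tests (pooled variance
unpaired, difference-based paired) via scipy; a zero-variance equal-mean
comparison returns (t, p) = (0, 1) by convention.

## The synthetic generator

Defaults are the study conditions: n = 3 biological replicates, tracer
purity 0.99, tracing media at 0.08 mM tryptophan / 0.4 mM serine, a 24 h
window in 2 mL of medium. Noise is multiplicative log-normal with CV 0.05
per isotopologue area (LC-MS area noise is approximately proportional; only
SD bars are available to anchor it, and 5% is a typical well-tuned LC-MS
area CV). Cell numbers default to n₀ = 3×10⁵ with a 24 h doubling time —
6-well-plate scale, chosen so tryptophan is not depleted over the window at
the modeled consumption rate. True rates emulate the IFNγ-treated HPAF-II
condition: total formate efflux 29.4, tracer-derived formate efflux 13.3,
kynurenine efflux 13.3/0.675 = 19.7 (so formate efflux sits at the 30–35%
reduction midpoint below kynurenine), tryptophan consumption 32.1
fmol/cell/h. Medium concentrations integrate rate × exponential growth,
which makes the zero-noise rate round trip exact by construction; depletion
below zero is floored and flagged. The GC-MS model adds a constant
derivatization background shared by samples, standards and blanks, so
raw-area blank subtraction removes it exactly at zero noise. Ground truth
(pool fractions, tracer-derived MIDs, true rates, true concentrations) is
serialized alongside the tables so tests never re-derive it from noisy data.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: chromatographic artifacts, co-elution and
in-source fragmentation; drifting or intensity-dependent (heteroscedastic
beyond proportional) noise; ion-suppression differences between labeled and
unlabeled species; biological between-replicate variation beyond the area
noise; incomplete pool turnover at early time points.

## Numerical choices and limitations

- Isotopologue vectors must sum to 1 within 1e-9 and be nonnegative;
  construction enforces this.
- Truncation at the ion's carbon count always renormalizes; observed
  isotopologue indices above the carbon count are rejected.
- The least-squares fits use tight tolerances (1e-14) and are deterministic
  given their inputs.
- Problem sizes: property suites use 200–1000 random draws and the noisy
  recovery calibration 200 seeds on a two-metabolite panel, which keeps the
  full test suite around a minute while the Monte-Carlo margins stay far
  from their thresholds.
- The model is not a flux model: it recovers pool labeled fractions, not
  absolute fluxes, and assumes complete isotopic steady state at 24 h.
- Raw-spectra processing (mzML, peak picking, RT alignment) is out of
  scope; the pipeline starts at peak-area tables.
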