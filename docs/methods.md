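# Methods

This note documents the models implemented in `sulfiso`, the choices made
where the design was genuinely open, and what the tests do and do not
demonstrate.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Closed-system batch-culture model

A batch culture is modelled as a closed vessel with an initial sulfate pool
(default 21 mM), one or more electron-donating alcohols, and biomass measured
as optical density at 660 nm.

**Growth.** Exponential growth at a specific rate μ (day⁻¹; a day is exactly
24 h) begins after a hard lag and stops abruptly when the active donor is
exhausted.  No Monod substrate dependence, no death phase, no product
(sulfide) inhibition: batch experiments of this kind report only μ and the
yield Y, so richer kinetics would be unidentifiable — this is a documented
limitation, not an oversight.  Temperature is fixed at 20 °C (293.15 K), the
culture temperature, everywhere.

**Stoichiometry.** Sulfate reduction to sulfide consumes 8 electrons.
Incomplete oxidation of a C2–C4 n-alcohol to its carboxylic acid supplies
4 electrons per molecule, complete oxidation of methanol to CO₂ supplies 6.
Sulfate consumed is tied to biomass by the yield (ΔOD = Y·Δ[SO₄²⁻]), the
donor by the electron ratio (Δdonor = Δ[SO₄²⁻]·8/e⁻), and sulfide produced
equals sulfate consumed.  A configuration whose donors would drive sulfate
to zero is rejected.

**Diauxie.** Donors are consumed strictly in the configured order.  With
`suppress_secondary` set, donors after the first are never consumed: their
traces stay constant and growth ceases at first-donor exhaustion — the
behavior observed when ethanol-grown cells never switch to methanol.  An
optional "degassing" event empties the dissolved sulfide pool at a given
time without altering the cumulative-sulfide isotope record, since the
closed-system Rayleigh treatment of the isotopes continues across a flush.

**Isotopes (exact two-pool Rayleigh).** The generator tracks the ³²S and
³⁴S sulfate pools separately.  With ε the true enrichment factor (‰,
positive = product depleted in ³⁴S), the fractionation factor
α = 1 − ε/1000 relates the instantaneous product ratio to the reactant
ratio, giving

    N34/N34₀ = (N32/N32₀)^α = g^α,
    R_sulfate = R₀·g^(α−1),
    R_sulfide,cum = R₀·(1 − g^α)/(1 − g).

Measured sulfate is total S, so g is recovered from the simulated
concentration by a bracketed root solve of S(g) = N32₀·g + N34₀·g^α
(scipy brentq, xtol 1e−15).  Total ³⁴S/³²S of (residual sulfate + cumulative
sulfide) then equals R₀ = 0.0441626 (the natural ³⁴S/³²S scale) to machine
precision, and the only approximations anywhere downstream are the
estimators' own — which is the point: the generator makes estimator bias
measurable.  δ³⁴S is referenced to the starting sulfate (initial δ = 0‰).

**Noise.** Gaussian, independent across analytes and timepoints, truncated
at zero for concentrations and OD: ±5% relative for sulfate and sulfide,
±10% for organics, 0.2‰ absolute for δ³⁴S, 2% for OD (configurable).  The
zero-noise model reproduces the deterministic trajectory bit-exactly, and a
fixed seed makes runs bit-reproducible.

What the generator does **not** emulate: correlated instrument drift,
sampling-volume loss, sulfide partitioning into the headspace, variable lag
between replicates, or death-phase OD decline.  Tests passing on synthetic
data therefore demonstrate the correctness of the estimators under the
stated error model, not robustness to every artifact of real cultures.

## Growth-parameter estimation

μ is the ordinary-least-squares slope of ln(OD) versus time (days) with its
regression standard error.  The exponential window is chosen automatically:
among all contiguous runs of ≥3 positive-OD timepoints, the longest whose
ln-OD R² is within 1e−4 of the best (ties break earlier); an explicit window
overrides.  Y is the endpoint ratio ΔOD/Δsulfate over the same window —
a ratio, not a regression, matching its operational definition — with
first-order error propagation of the four endpoint measurements.
sSRR = μ/Y by construction (the identity sSRR·Y = μ holds to machine
precision), and

    csSRR [fmol·cell⁻¹·day⁻¹] = sSRR × cell_volume / biovolume_per_od,

from the unit chain 1 mM = 1e9 fmol·ml⁻¹ and
cells·ml⁻¹ per A660 = biovolume_per_od [μl·ml⁻¹] × 1e9 / cell_volume [μm³];
with the defaults (1.49 μl·ml⁻¹, 1.68 μm³) the factor is 1.1275.

## Rayleigh enrichment-factor estimators

Two linearized forms are fitted: the residual-sulfate relation
(y = 1000·ln(1+δ(SO₄)/1000) on x = −ln f) and the accumulated-sulfide
relation (y = 1000·ln(1+δ(HS)/1000) on x = (f·ln f)/(1−f), with the analytic
limit x → −1 as f → 1).  Choices:

- Multi-point fits include a **free intercept** by default (absorbs
  instrument offsets and reference-scale mismatch); a through-origin option
  exists.  A single usable point forces the through-origin endpoint form —
  the mode that reproduces final-timepoint table arithmetic.
- f is computed from measured sulfate (cross-checks via sulfide are a
  diagnostic, not the estimator).
- Sulfide-relation fits exclude points with f > 0.98 (the progress
  coordinate is pinned near −1 there and carries no slope information).
- The combined per-culture ε is the inverse-variance weighted mean when both
  standard errors exist, else the unweighted mean.  ε is reported to 0.1‰.

**Documented estimator bias.** On exact closed-system data the linearized
relations are not exactly linear in the transformed coordinates.  With 12
samples spanning f = 1.0 → 0.3 and a free intercept, the sulfate-based
estimator recovers ε within 0.2% across ε = 5–45‰ (about +0.16% at 36‰, the
bulk of it from measuring f on total sulfate while distillation acts on the
³²S pool).  The sulfide-based estimator carries a larger intrinsic
linearization bias that grows with ε: ≈ +0.3% at 20‰, +0.55% at 36‰ and
+0.7% at 45‰ under the same conditions (through-origin fitting is several
times worse).  The unit tests pin both estimators against an independent
closed-form evaluation of these biased expectations; users fitting large-ε
data who need the last few tenths of a percent should prefer the
sulfate-based or combined estimate.

**Mass-balance diagnostic.** Closure is checked per timepoint as
w_SO4·δ(SO₄) + w_HS·δ(HS), with w_SO4 = f and w_HS the *measured* sulfide
over initial sulfate when available (falling back to 1−f), so the residual
probes chemical and isotopic closure jointly.  Residuals beyond 3× the
propagated measurement error are flagged.

## Error propagation

Both routes treat measurement errors as independent (nothing in the
analytical protocols implies correlation) with the per-analyte magnitudes
above; intervals are reported as ±1 sd by default to match the conventional
"±" style, with Monte Carlo percentile intervals available.

- **Monte Carlo** (default n = 5,000, seeded): every measured cell is
  perturbed with its Gaussian error (truncated at physical bounds), the
  estimator re-run, and the draws summarized by mean/sd/2.5–97.5%.  Failed
  draws are discarded and counted; >5% failures aborts.
- **Taylor**: sd² = Σ(∂estimator/∂xᵢ)²σᵢ² with central finite differences at
  a relative step of 1e−6.  Exact for linear estimators; for the Rayleigh
  regression estimators the two routes agree within 15% at the analytical
  noise levels (verified in the tests), the residual difference reflecting
  the estimators' mild nonlinearity.

## Flux-force chain model

The pathway is a fixed four-step chain — uptake, activation (ATP
sulfurylase), APS reduction, sulfite reduction — each with forward/backward
kinetic fractionations (ε_f, ε_b; ε_eq = ε_f − ε_b) and a reversibility
x = e^{ΔG/RT}.  The net fractionation follows the recursion

    ε_net(i) = ε_f(i) + xᵢ·(ε_net(i+1) − ε_b(i)),    ε_net(last) = ε_f(last),

whose fixed points are the expected limits: all xᵢ = 0 exposes the first
step's kinetic effect; all xᵢ = 1 gives the sum of upstream equilibrium
fractionations plus the terminal kinetic effect.  The recursion is verified
against an independent steady-state isotope-flux network solution (a linear
system in the intermediate-pool compositions) to 1e−9 ‰ on random chains.

**Energy budget.** ΔG_total per mole sulfate is −8F·(E_acc − E_don), with
the acceptor-side potential Nernst-adjusted by (RT/8F)·ln([SO₄²⁻]/[HS⁻])
(defaults 15/5 mM, the half-reaction mid-course).  The donor axis is the
*effective* potential of the electron-donating half reaction as delivered to
the terminal reductases, spanning −140 to −70 mV: although methanol and
ethanol have nearly identical standard potentials (≈ −0.37/−0.39 V), sluggish
methanol oxidation delivers electrons at a much weaker effective potential,
which is precisely how a donor changes the expressed fractionation.

**Allocation.** `solve_chain` finds the shared enzyme-activity scale
a ∈ (0, 1] such that every step, at effective capacity a·v_max, carries the
same net rate csSRR through v = v_max·(1 − e^{ΔG/RT}), while Σ ΔG_i equals
ΔG_total exactly (1-D root-finding on the limiting step's log-space ΔG;
both constraints hold to better than 1e−9).  Infeasibilities are explicit
errors: csSRR at or above the limiting capacity ("rate exceeds capacity"),
or a budget weaker than the minimum dissipation at full expression
("insufficient driving force").

A structural property of this rate law is worth stating plainly: with equal
flux and exact energy conservation, the per-step reversibilities — and hence
ε_net — depend on the operating point only through ΔG_total.  Along a
constant-potential slice ε_net is constant in csSRR (trivially
non-increasing); the rate input governs absolute capacities and the
feasibility boundary.  Capturing a direct rate dependence of ε at fixed
budget would require substrate-saturation kinetics and explicit intermediate
pools, which is beyond this reconstruction; the near-equilibrium limit
(all x → 1) is correspondingly reached as ΔG_total → 0⁻, not as csSRR → 0
at fixed budget.

**Calibration.** The default step parameters are calibration choices, not
measurements: uptake ε_f = 3‰ (ε_eq = 3‰), activation 0‰, APS reduction
ε_f = 7‰ with ε_eq = 20‰, sulfite reduction ε_f = 79.7‰; capacities 5×10⁴
fmol·cell⁻¹·day⁻¹ for uptake/activation and 10³ for the two reductive steps
(the limiting capacity, set comfortably above the 1–100 fmol·cell⁻¹·day⁻¹
operating range so the whole grid is feasible); effective acceptor standard
potential −65.6 mV (lumping the reductive couples with the ATP investment of
activation).  They were tuned jointly so the model reproduces two anchor
regimes: a slow, weakly driven culture (csSRR ≈ 1.5 fmol·cell⁻¹·day⁻¹ at
−70 mV) with ΔG(APS) ≈ −3 kJ/mol, x ≈ 0.3 and ε_net ≈ 36‰, and a fast,
strongly driven one (csSRR ≈ 47 at −140 mV) with APS reduction practically
irreversible and ε_net ≈ 10‰.  Every value is overridable.  A known cost of
the truncated recursion (the terminal step's own reversibility never enters)
is that the implied equilibrium-limit sum (~103‰) exceeds the ~70‰
sulfate–sulfide equilibrium fractionation at this temperature; interpolating
between ~10‰ and ~36‰ with x(APS) ≈ 0.3 forces this inflation of the
terminal kinetic fractionation.  Treat ε_net outside the calibrated window
(roughly 5–45‰) as qualitative.

## Numerical choices

- Root solves (two-pool Rayleigh inversion, chain allocation): scipy brentq
  at xtol 1e−15 / rtol 9e−16; the chain solver works in the log-space ΔG of
  the limiting step so deep irreversibility stays well-conditioned, and the
  last sub-1e−12 of the budget residual is absorbed into the limiting step.
- Regressions: statsmodels OLS; saturated two-point fits report undefined
  standard errors silently (NaN) rather than warn.
- Degenerate inputs are explicit errors with locations: no progress (all
  f = 1), <3 usable OD points, zero sulfate consumption, empty chains,
  positive ΔG, malformed CSV cells (row/column named).
- File format: CSV with `#` metadata lines; δ stored to 0.01‰,
  concentrations to 0.01 mM (measurement resolution), OD to 1e−4.  A
  write→read→write cycle is byte-identical.

## Problem sizes

The shipped tests use scenario sizes chosen to exercise the estimators at
the fidelity the analysis needs: 7–14 timepoints per culture (matching
daily-to-multi-week sampling), 200 replicate noisy cultures for parameter
recovery, 5,000 Monte Carlo draws (20,000 for the convergence check on the
cheap endpoint estimator), 1,000 random chains against the isotope-flux
oracle, and 6×8 thermodynamic grids.

## Known limitations

- No Monod kinetics, death phase, or sulfide feedback in the generator.
- The sulfide-based estimator's linearization bias at large ε (above).
- The chain model's rate law cannot express a csSRR-dependence of ε at
  fixed energy budget, and its calibrated terminal fractionation is
  deliberately inflated (above); branch points, intracellular sulfate
  accumulation, and oxygen- or multiple-sulfur-isotope systematics are out
  of scope.
- Measurement errors are assumed uncorrelated; real instrument drift is not.
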