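# Methods

This note records the model, the parameter choices, and the numerical
design behind `nucstab`, at the level of detail a maintainer or reviewer
needs to judge what the package's outputs do and do not mean.

## Scope and assumptions

The package models the aqueous decomposition of a pyrimidine nucleoside
through S_N1-type heterolysis of the N-glycosidic bond, with the ionic
fragments relaxing through fast acid–base steps, plus (for 6-iodouridine)
a bimolecular hydroxide S_N2 channel at C6. Core assumptions:

* **Dilute, unbuffered water.** Initial condition: nucleoside at
  10⁻³ M, every other species (including H₃O⁺/OH⁻) at zero;
  autoionization builds the ions up within microseconds. Real
  experiments are often buffered near pH 7 — the model deliberately is
  not, so its late-time pH (~3.6 for the fast-hydrolysing compounds) is a
  prediction of the closed system, not of a buffered assay.
* **Constant water activity**, 55.5 M folded into the constants of every
  step that consumes or produces water.
* **Ideal solutions**: concentrations, not activities; no ionic-strength
  corrections. At ≤10⁻³ M total solute this is a few-percent effect,
  below the rounding of the input free energies.
* **Transmission coefficient 1** in the Eyring relation; standard state
  1 mol/dm³ for bimolecular constants; temperature 298.15 K by default
  (inputs quoted at "298 K" differ by less than their own rounding).
* Energies are carried in kcal/mol throughout, with
  R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹; there is no unit auto-detection, and
  config keys spell their units out.

## From free energies to constants

Acid/base constants come from proton-exchange thermodynamic cycles
against reference acids of known pKa:

    pK = pK_ref + s·ΔΔG/(RT ln 10)

with s = +1 when the target is a base anion (the reference then enters as
the conjugate base strength pK_b = pKw − pKa) and s = −1 when the target
is a cation acting as an acid. The sign convention corresponds to the
exchange written with the target ion on the left; it is pinned down by
the requirement that all four bundled exchange rows reproduce their
published pK values, which they do within 0.03 pK units (the residual is
consistent with the inputs being rounded to two significant figures; the
unrounded values are not recoverable).

The dissociation constant K_diss is *not* an input: the absolute
dissociation free energies are not published. It is calibrated by
`fit_kdiss` from the residual nucleoside concentration of the published
equilibrium table. Because the residual fixes the dissociated amount
exactly, the calibration is closed-form (solve charge balance for the pH,
then evaluate the defining ratio) and round-trips through the equilibrium
solver to solver precision. The calibrated values — 4.5×10⁻²³ (5IdU),
7.1×10⁻¹⁴ (6IdU), 2.2×10⁻¹⁸ (6IUrd) — agree with the ratios of the
published table cells to within their 2-significant-figure rounding, and
their 6IdU/6IUrd ratio corresponds to a dissociation free-energy gap of
6.2 kcal/mol, matching the published "ca. 6.4 kcal/mol" at the tables'
printed precision.

## Equilibrium speciation

The coupled system (dissociation, cation solvolysis, anion protonation,
water autoionization, two mass balances, electroneutrality) is solved by
two nested strictly monotone scalar root-finds: an outer bracketed search
on ln[Nuc] for the dissociation equilibrium, and for each candidate an
inner bracketed search on log₁₀[H₃O⁺] for charge balance, with every
other species in closed form. Concentrations in these systems span more
than twenty orders of magnitude (sugar cations at 10⁻²¹–10⁻²⁴ M next to
10⁻³ M majors); the nested formulation makes both mass balances, the ion
product, and K_a/K_b hold *by construction*, leaves charge balance and
the K_diss condition at the scalar-solver tolerance (~10⁻¹³ relative),
and cannot diverge because both residuals are monotone with guaranteed
brackets. A damped Newton iteration on the full residual vector was
considered and rejected: it adds failure modes without adding accuracy.

K_diss = 0 is special-cased to the pure-water state, and a dissociation
so weak that the residual is within 10⁻¹³ of the initial concentration is
returned at that boundary.

The hydroxide S_N2 channel of 6-iodouridine is **excluded from the
equilibrium system**. Its reaction free energy (−72.3 kcal/mol,
K ≈ 10⁵³) would predict quantitative conversion to 6-hydroxyuridine at
true thermodynamic equilibrium, which is irrelevant on any chemically
meaningful horizon: once the solution self-acidifies, [OH⁻] drops to
~4×10⁻¹¹ M and the channel throttles itself (see below). Published
long-time speciation tables for this compound list S_N2 products
alongside equilibrium-system species and are then not mass-consistent
with the equilibrium-only system; the report layer flags this rather than
reproducing the inconsistency.

## Kinetics

Each compound's network contains the reversible steps

| step | reaction | forward rate | reverse rate |
|------|----------|--------------|--------------|
| R1 | Nuc ⇌ A⁻ + R⁺ | Eyring on ΔG‡ (18.0/24.1/30.5 kcal/mol) | k₁/K_diss |
| R2 | R⁺ → R + H₃O⁺ | 10¹³ s⁻¹ (placeholder, see below) | k₂/K_a |
| R3 | A⁻ → A + OH⁻ | K_b·10¹⁰ s⁻¹ | 10¹⁰ M⁻¹s⁻¹ (diffusion) |
| R4 | H₃O⁺ + OH⁻ → 2H₂O | 1.4×10¹¹ M⁻¹s⁻¹ (literature) | k₄·K_w |

plus, for 6-iodouridine only, R5: Nuc + OH⁻ → hydrNuc + I⁻ with the
Eyring rate of the 11.8 kcal/mol barrier (1.4×10⁴ M⁻¹s⁻¹) and a
detailed-balance reverse that is numerically negligible (K ≈ 10⁵³).
Every reverse rate is derived from the forward rate and the equilibrium
constant — never set independently — so the ODE system's stationary state
is exactly the speciation module's equilibrium; the network constructor
verifies this and the per-reaction conservation of base units, sugar
units, and charge.

**Fast-step placeholders.** The true rates of R2–R4 are unknown and must
not matter. Two considerations fix the defaults. First, the
detailed-balance reverse of R1 is enormous (k₁/K_diss ≈ 6×10¹²
M⁻¹s⁻¹ for the 6-substituted compounds), so during hydrolysis the
oxocarbenium branches between solvolysis (R2) and recombination at a
ratio (k₁/K_diss)·[A⁻]/k₂ ≈ 10⁹/k₂: with k₂ = 10¹⁰ s⁻¹ the half-life
would be retarded by ~6% *by the placeholder*, defeating its purpose.
R2's forward rate is therefore set at the barrierless scale 10¹³ s⁻¹,
where the observable sits on a plateau (verified flat to 0.6% from 10¹¹
to 10¹⁵ s⁻¹). Second, each placeholder is assigned to its step's
*favorable* direction so that no derived constant exceeds physical
bounds: a fast forward R3 would imply an anion-protonation reverse of
~10²⁰ M⁻¹s⁻¹, ten orders beyond diffusion control and numerically fatal
over century horizons; instead R3's reverse (A + OH⁻ → A⁻ + H₂O) is set
to the diffusion-limited 10¹⁰ M⁻¹s⁻¹ and its uphill forward follows from
detailed balance. `rate_sensitivity` confirms that scaling R2, R3, or R4
(as detailed-balanced pairs) across factors 10⁻²–10² changes half-lives
and terminal concentrations by less than 1%.

**Integration.** The system is integrated with BDF in
*equilibrium-scaled* variables z_i = c_i/c_i(eq) (species with no
equilibrium counterpart, the S_N2 products, are scaled by the initial
concentration). Scaling matters twice over: the raw iteration matrix
mixes magnitudes across ~21 decades and becomes numerically singular at
the large steps needed to reach a 10¹¹ s horizon, and error control in
scaled variables bounds each species *relative to its own equilibrium
magnitude* — the error that matters when the terminal state is compared
with the independent equilibrium solve. Defaults: rtol 10⁻⁸, scaled atol
10⁻¹⁰, log-spaced output grid of 400 points from 10⁻¹³·t_end to t_end.
Scaled values below −10⁻⁴ abort the run; smaller negative excursions are
clamped to zero at output only. The century-scale 5IdU run (t_end =
10¹¹ s) completes in a few seconds and lands within 10⁻⁸ of the
independent equilibrium for every species. A transient scipy
`LinAlgWarning` from a rejected oversized trial step is filtered as
noise.

**Derived times.** The half-life is the first crossing of half the
initial concentration, located by monotone (PCHIP) interpolation in
log-time between output points; if the trajectory never crosses — which
for a long-enough run means the *equilibrium* residual exceeds half the
initial amount, as for 5IdU where 58% survives — the half-life is
reported as undefined rather than extrapolated. Time-to-equilibrium is
the first time the nucleoside concentration enters and stays within a
relative tolerance (default 5%) of the independent equilibrium value.
For 5IdU this gives ~95 years: somewhat *below* the naive 1/k₁ = 116
years because the linearized relaxation rate of the reversible system
exceeds k₁ (the reverse flux grows as equilibrium is approached; the
measured rate is ≈3.3 k₁), and consistent at order of magnitude with the
published "ca. 126 years", whose exact value depends on an unpublished
equilibration criterion and unrounded barrier.

With the bundled barriers the simulations give half-lives of 1.745 s
(6IdU; TST on the printed 18.0 kcal/mol gives ln2/k₁ = 1.75 s, and the
printed 1.4 s corresponds to a barrier ~0.13 kcal/mol lower — within the
0.1 kcal rounding of the input) and 12.9 h (6IUrd; pure dissociation
would give 14.4 h, the S_N2 channel consumes a further ~8% of the
substrate before self-quenching, moving the value toward the published
13.8 h).

## Degradation fits

`fit_first_order` is ordinary least squares on ln C vs t (converted to
seconds); `fit_arrhenius` is unweighted OLS on ln k vs 1/T, reporting
E_a = −slope·R with the slope's standard error propagated, the log
prefactor, and the extrapolated 25 °C rate and half-life. Replicates at
one temperature are pooled into a single regression. Unweighted OLS at
both stages is the field's default when no per-point variance model is
stated. The Arrhenius E_a (an empirical slope, containing the
prefactor's temperature dependence) and an Eyring ΔG‡ are different
conventions; `compare_barriers` reports both — converting the
extrapolated ambient rate into its Eyring-equivalent barrier — and their
differences, rather than conflating them.

## Synthetic data

The decay generator emulates a thermal-degradation study: first-order
decay at 60/65/70/75/80 °C sampled at 8 points spanning two local
half-lives, with the rate law generated from an Arrhenius model
(defaults: E_a = 26.8 kcal/mol, reference rate set so the 80 °C
half-life is one hour — a hot-end window on the order of the ~120 min
conditioning runs such studies use). Measurement noise is multiplicative
lognormal, exp(σZ) with σ = 0.02 by default: HPLC quantitation error is
roughly proportional to signal and concentrations are positive. The
assay's true noise level is not published; 2% is a fixture convention.
One global seed fixes the corpus byte-for-byte, and per-temperature
substreams are derived from (seed, temperature) so adding a temperature
never changes the others' data.

What passing the recovery tests shows — and does not show. Because
lognormal noise is exactly additive-Gaussian in log space, the two-stage
OLS pipeline is unbiased by construction; the 200-seed study checks the
implementation, not the chemistry. The generator produces ideal
first-order, baseline-free, single-analyte data: real chromatograms add
integration error, co-eluting products, and temperature-control drift,
none of which is modelled. Two derived calibration facts worth recording:
with 8 points and 2 fitted parameters, a "±2 SE" interval has t(6)
coverage ≈ 0.91 (not the Gaussian 0.95); and near the 42%-decomposed
equilibrium the K_diss inverse problem amplifies observation error by
d lnK/d ln[Nuc]obs ≈ −3.8, so a 5% observation noise yields only ~⅔ of
fits within a factor 1.2 of the truth (and ~97% within the 2σ factor
1.5). The robustness tests assert these derived coverages.

## Configuration and reporting

Each compound is one YAML document with units in the key names; loading
rejects unknown keys at every level and load→save→load is lossless. The
reporting layer contains no numeric literals: every value in a report is
produced by a module operation from the configuration. The qualitative
verdict uses configurable half-life thresholds (defaults: *unstable*
below 1 min, *moderately stable* below 1 week, *stable* otherwise or
when no half-life exists).

## Known limitations

* No buffered-pH mode; the self-acidification trajectory is a property
  of the closed unbuffered system.
* No activity corrections, no temperature dependence of K_w or of the
  reference pKa values, no solvent isotope effects.
* The S_N2 side-product yield depends on the transient [OH⁻] history and
  hence mildly on the R4 recombination constant; it is reported but is
  not a calibrated observable.
* The one- and two-water neutral hydrolysis channels (barriers ≈ 39–43
  kcal/mol) are omitted: their TST rates are negligible at ambient
  temperature (half-lives of ~10⁹ years or more).
* Input free energies are used as printed (2 s.f. / 0.1 kcal); derived
  rates inherit that rounding exponentially (0.1 kcal ↔ 18% in a rate),
  which is why half-life comparisons carry ±30% bands.
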