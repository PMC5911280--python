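# Methods

## Model and assumptions

The package treats cocrystal dissolution as partly governed by the
equilibrium concentration of API–coformer complexes in aqueous solution.
Three ingredients combine into the complex exponent pAM:

1. **Reaction exponent.** `pK_r = ΔG_r / (RT ln 10)` converts a pairwise
   complexation free energy into a decadic equilibrium exponent. ΔG_r is an
   external input (in practice a COSMO-RS/quantum-chemistry estimate in
   kcal mol⁻¹, hence R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹); the package never
   computes it. The default conversion temperature is 310.15 K (37 °C), the
   temperature of the reference solubility measurements; it is the only
   choice that regenerates the bundled pK_r column within ±0.01.

2. **Speciation.** Only neutral species are assumed to complex. The ionized
   share α of a monoprotic acid is the Henderson–Hasselbalch fraction; for
   diprotic acids two formulas are provided (below). The availability of the
   neutral form is summarized as `p = −log₁₀(c° · (1−α))` per species, and
   `pβ` is the sum of the API and acid p-values. Activity coefficients and
   ionic-strength effects are ignored, and pH is treated as externally
   buffered.

3. **Stoichiometry.** `pAM = b·pK_r + pβ` with `b` the number of pairwise
   heterosynthon-formation events in the repeating motif: 1 for
   monocarboxylic 1:1 pairs, 2 for dicarboxylic acids, whose lattices build
   from [-MAM-]ₙ-type bridged superstructures and whose superstructure free
   energy is close to additive over pairs. The `b = 2` rule is a model
   choice validated numerically: it reproduces all five dicarboxylic
   pMA^est entries of the bundled table within 0.015 when combined with the
   tabulated logβ, while `b = 1` does not.

## Diprotic modes

The default (`printed`) diprotic ionized fraction is

    α = 1 / (1 + 10^(pKa1 + pKa2 − 2pH) + 10^(pKa1 − pH))

kept verbatim so that the bundled reference computations are reproduced
as published. Standard mass-action speciation gives `10^(pKa2 − pH)` in the
last term (then α is exactly the dianion fraction, which the test suite
verifies against a numeric equilibrium solver); that variant is available as
`diprotic_mode="textbook"`. The printed variant never falls below the
textbook one, and at pH well above pKa2 the two coincide. Neither is
asserted as "correct"; the mode is a config switch, defaulting to the
reproducible one.

## Sign and unit conventions

* The bundled table's `log_beta_printed` column stores `−pβ` (log₁₀ of the
  neutral-concentration product). This convention is established by exact
  agreement of `pMA^est = pK_r − logβ` across all monocarboxylic rows; the
  API exposes pβ, and accessors negate the column on read.
* p-values are computed on the mg ml⁻¹ scale by default — the unit of the
  table's c₀ column. A `molar` mode divides the (clamped) mg ml⁻¹
  concentration (≡ g L⁻¹) by the molar mass, giving mol L⁻¹. Neither unit
  convention regenerates the tabulated logβ column exactly, so logβ is
  consumed as data, never validated.
* Saturation: when a solubility limit is supplied, the nominal
  concentration is clamped to it before computing the p-value (the bundled
  table flags one coformer, 1-hydroxy-2-naphthoic acid, loaded at
  0.5 mg ml⁻¹ against a 0.1 mg ml⁻¹ aqueous solubility). The table keeps
  both numbers; the clamp decides.

## API self-dimerization

`dimerization_exponent` bookkeeps API dimer formation as
`pK_r(dimer) + 2·p_M` (two neutral monomers consumed). With the bundled
inputs (ΔG_dimer = 2.45 kcal mol⁻¹, API at 0.1 mg ml⁻¹, pH 6.5) this yields
8.37. The source compilation quotes an estimated pM of 4.8 for the dimer,
which no composition of the speciation and pβ machinery with the tabulated
inputs reproduces; the function therefore documents its own convention and
the discrepancy rather than matching that figure. It plays no role in the
column validations.

## Trend analysis

Fits are simple OLS of y on x per acid class; R² is the squared Pearson
correlation, identical to the coefficient of determination for a
one-predictor linear fit. Degenerate inputs are handled explicitly: a class
with fewer than two retained points or constant x yields an "undefined" fit
(NaN coefficients, warning, no exception); constant y yields slope 0 and
R² 0 with a degenerate flag. Exclusion lists match names
case-insensitively; the default exclusion set for melting-point trends is
{4-Hydroxybenzoic acid, Fumaric Acid}, the two systems whose cocrystals melt
below their coformers.

Melting-point shifts and hydration free energies are accepted only as
user-supplied columns: the underlying values behind the published
melting-point and hydration correlations are not tabulated anywhere, so
those R² figures are not reproduced here. The trend machinery is instead
guaranteed by an oracle-equivalence suite (agreement with a closed-form
normal-equations solve to 10⁻¹⁰) and by parameter recovery on synthetic
studies.

## Synthetic studies

`generate_study(seed, params)` emulates the structure the analysis assumes:
pKa1 ~ U(1.5, 5), pKa2 = pKa1 + U(0.5, 3) for diacids, ΔG_r ~ U(−10, −4)
kcal mol⁻¹ — ranges bracketing the reference coformer set — with pAM
computed through the real speciation/equilibria code at pH 6.5 and 310.15 K,
and SA = slope_class·pAM + intercept_class + N(0, σ²). Defaults: 50
coformers per class, slope_mono = 0.3, slope_di = −0.2, intercepts 0.3 and
−1.0 (placing SA in the realistic −0.3…0.4 band), σ = 0.05. Solubility is
back-filled as S = 0.17·10^SA mg ml⁻¹. All randomness flows through
`numpy.random.default_rng(seed)`; identical (seed, params) regenerate the
study bit-identically.

What passing the synthetic suite shows: the pipeline recovers a linear
SA–pAM structure with class-dependent signs under Gaussian noise, with
2-standard-error slope coverage at the nominal ~95% level. What it does not
show: robustness to non-Gaussian measurement error, errors in ΔG_r itself,
polymorphism, or departures from the linear free-energy relationship — none
of which the generator emulates.

## Numerical choices

* Validation tolerances mirror the printing precision of the reference
  table: pK_r ±0.01, pMA^est ±0.015, SA ±0.02 (S is printed to 2 dp, so SA
  cannot be reproduced more tightly).
* A species fully ionized to machine precision (neutral fraction exactly 0
  in floating point) reports an infinite p-value with a warning; pβ and pAM
  propagate the infinity rather than raising.
* CSV I/O normalizes Unicode minus signs to ASCII on read; the bundled
  resource is sha256-pinned and a corrupted installation raises at load.
* Report JSON serializes all quantities at full precision plus a 2-dp
  "as-printed" view for side-by-side comparison with the reference table.

## Known limitations

* The complexation model stops at pairwise (and doubled-pairwise) events;
  higher-order aggregation, salt formation and polymorph effects enter only
  through whatever is baked into the supplied ΔG_r.
* The printed-mode diprotic formula is kept for reproducibility despite its
  deviation from textbook speciation at pH between the two pKa values.
* Absolute solubility is never predicted — the analysis is a relative,
  class-split linear-trend screen, semi-quantitative by construction.
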