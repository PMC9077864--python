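# Methods

## The measurement problem

A contact-lens-type ocular dosimeter (CLOD) is a curved radiochromic
dosimeter worn on the eye to record the lens dose during radiotherapy. Its
active layer (the lithium salt of pentacosa-10,12-diynoic acid, the same
chromophore as Gafchromic film) darkens with absorbed dose; the readout is a
flatbed scan, analyzed in the red channel, in either transmission or
reflective geometry. Because the dosimeter is curved, a thin wedge of air
separates its surface from the scanner glass, and the two weak reflections at
the glass/gap and gap/lens interfaces interfere: the scan shows Newton's
rings. The methodology implemented here quantifies how an index-matching
*compensating material* in that gap (optical grease, soft silicones, or
nothing) changes sensitivity, accuracy and scan uniformity.

## Analysis chain

1. **ROI statistics.** A square region of interest, side 3.5 mm (41 × 41 px
   at 300 dpi; an option forces an even 40 for strict emulation of readers
   that truncate), yields the mean, sample SD (N−1 denominator) and CV of
   the red-channel counts. The N−1 choice is isolated in one function; the
   original analysis software's convention is unknown.
2. **Net optical density.** For a pixel triple (unexposed `M_unexp`,
   exposed `M_exp`, empty-bed `M_bkg`),

   `netOD = log10((M_unexp − M_bkg)/(M_exp − M_bkg))`.

   This is the conventional (Devic) orientation, positive for a darkening
   dosimeter. The reversed orientation — exposed value in the numerator,
   which yields negative values — circulates in print and is available
   behind `literal_sign=True` / `--eq1-literal` for auditability; it is
   never silently corrected. The netOD uncertainty is first-order
   propagation of the three ROI SDs,
   `σ_netOD = (1/ln10)·√((σ_exp²+σ_bkg²)/(M_exp−M_bkg)² + (σ_unexp²+σ_bkg²)/(M_unexp−M_bkg)²)`,
   verified against Monte-Carlo resampling in the tests.
3. **Dose–response and calibration fits.** `netOD = a·D + b·Dⁿ` and the
   inverse `D = a·netOD + b·netODⁿ` are fitted by unweighted nonlinear
   least squares (optional 1/σ² weighting behind a flag; the original
   protocol states only "least squares"). Both curves pass through the
   origin; the zero-dose point is pinned to netOD = 0 since it defines the
   unexposed state. Initial guesses: slope from the two lowest positive
   abscissae, exponent 1.5; the exponent is bounded to (0.2, 5) and a fit
   touching the bound is flagged. Parameter SDs come from the fit
   covariance; goodness of fit is the adjusted R² with p = 3. Replicates
   are fitted as per-dose means by default (the published curves plot
   per-dose averages); fitting all replicates is equally supported.
   Note the power-law pair (a, b, n) is not globally identifiable from few
   noisy points: (b < 0, n > 1) and (b > 0, n < 1) branches can describe the
   same sublinear data. Parameter-recovery claims therefore refer to
   noiseless or low-noise regimes.
4. **Sensitivity.** `S(D) = dnetOD/dD = a + n·b·Dⁿ⁻¹`, evaluated
   analytically (cross-checked against central finite differences of the
   fitted curve). For n < 1 it diverges at D = 0; that case returns +inf
   with a warning.
5. **Uncertainty budget.** With the calibration parameters named b
   (linear) and c (power) as is conventional in this decomposition:

   - experimental: `σ_D,exp(%) = |b + n·c·netODⁿ⁻¹| · σ_netOD / D_fit × 100`
   - fit: `σ_D,fit(%) = √(netOD²·σ_b² + netOD²ⁿ·σ_c²) / D_fit × 100`
   - total: the single-radical form, algebraically the quadrature of the two.

   The fit term deliberately omits the exponent's uncertainty and the b–c
   covariance — the standard published form is reproduced literally as the
   default; `extended=True` adds both terms for comparison.
6. **Comparison metrics.** Accuracy is
   `|measured − delivered| / delivered × 100`, the relation that reproduces
   the internally consistent cells of the published accuracy benchmark (a
   minority of printed cells differ by ≲0.2 points, consistent with their
   having been computed from unrounded measured doses; these are flagged,
   not reverse-engineered). Per-material averages run over both doses and
   both modes. Uniformity is the ROI CV; the mode comparison is the mean
   reflective/transmission sensitivity ratio over the calibration dose grid.

## The synthetic scan generator

No raw scans are deposited with the original study, so the generator is the
package's data source. It emulates, per rendered footprint:

- **Dose signal**: clean exposed value
  `M = M_bkg + (M_unexp − M_bkg)·10^(−netOD*)` with
  `netOD* = g·(a·D + b·Dⁿ)`; defaults a = 0.3 netOD/Gy, b = 0.1 netOD/Gyⁿ,
  n = 1.8, chosen to give film-like response over 0–1 Gy, and g = 2.5 in
  reflective mode (the reflective/transmission sensitivity factor of
  red-channel film scanning at low dose). Base level 40 000 counts,
  empty-bed level 1000 counts on the 16-bit scale. The generator and the
  netOD module are exact inverses, which anchors the round-trip tests.
- **Gap geometry**: sphere-on-flat thickness `t(r) = r²/(2R)`. R is the
  *effective* curvature of the residual gap, default 4000 mm: a soft lens
  flattens elastically against the glass, so the residual wedge is far
  shallower than the ~8 mm anatomical base curve. This default puts about a
  dozen fringes across a 6 mm-radius footprint at 0.3–0.7 mm spacing — the
  morphology of the artifact as photographed — whereas a literal 8 mm gap
  radius would place every fringe below one 300-dpi pixel and render the
  artifact as unresolvable speckle. Both R and the 6 mm contact radius are
  simulator parameters, not measured properties.
- **Fringe visibility**: normal-incidence Fresnel reflectances
  `Rᵢ = ((nᵢ − n_gap)/(nᵢ + n_gap))²` of the two interfaces, combined as
  `V = 2√(R₁R₂)/(R₁ + R₂ + ε)` with ε = 0.1. The ε regularization makes V
  vanish at perfect index match (the physical point of a compensating
  material) instead of staying near 1 as both reflectances shrink together;
  with glass 1.52 and lens 1.50 it gives V ≈ 0.45 for air and < 0.01 for
  index-matched media. Indices: air 1.00, Dragon Skin 1.40, SORTA-Clear
  1.41, optical grease 1.46 — plausible values, configurable.
- **Ring modulation**: reflected-light law with the half-wave phase shift,
  `factor = 1 − V·cos(4π·n_gap·t/λ)` at λ = 630 nm (effective red-channel
  illumination); dark center at contact, dark rings at `r_m = √(mλR/n_gap)`.
- **Noise**: additive Gaussian per pixel, then integer rounding and
  clipping. Default SDs per material and mode follow the reported ROI
  pixel-value SDs at 25 cGy (transmission 766.3/696.5/695.0/611.9 counts,
  reflective 577.1/495.9/492.9/373.3 for air/DS/SC/OG) — the only anchored
  noise scale available. Poisson shot noise was rejected as over-modeling
  for a scanner CCD at this abstraction level.
- **Placement reproducibility**: each footprint's optical center is
  jittered by a Gaussian of SD 0.05 mm (mask repositioning), and the whole
  gap is offset by |N(0, 0.5 µm)| (the lens seats differently and the
  compensating layer re-forms on every placement). The gap offset matters:
  a quarter-wavelength seating change re-phases every fringe, so the ring
  pattern does *not* cancel between the unexposed and exposed scans of a
  real dosimeter — this is precisely why the artifact degrades accuracy.
  The 0.5 µm scale is a sub-µm seating tolerance; any value above ~0.2 µm
  already randomizes the phase, so behavior is insensitive to the exact
  choice.

Transmission and reflective renderings differ only by the mode gain and the
noise table; no separate transmission optical model is attempted. The red
channel carries signal and rings; green and blue carry the unmodulated base
level. Same seed, same bytes.

### What the generator does not emulate

Scanner lamp warm-up drift and spatial response non-uniformity, polarization
and oblique-incidence effects, the lamp spectrum, dose-rate or energy
dependence, material application defects (bubbles, dust), and any absolute
radiometric calibration of a physical scanner. Consequently the *printed*
uniformity CVs and 50 cGy uncertainty percentages of the original study are
not reproduction targets — the synthetic study reproduces the material and
mode *orderings* (grease best, bare air gap worst; reflective more sensitive
by 2.5×), not their absolute values. Passing tests show the analysis chain
is correct and that the ring/noise physics produces the observed ranking;
they do not validate the generator against real scans.

## The default study

Calibration doses {0, 10, 25, 50, 70, 100} cGy × 3 replicates (the published
range is 0–100 cGy in triplicate; the grid is a reconstruction from the dose
levels that appear in the results), accuracy exposures at 25 and 70 cGy × 3,
four materials × two modes, 3.5 mm ROI. Each (material, mode) group renders
an exposed and an unexposed scan per series; the empty-bed background ROI is
taken from the exposed scan (whether the original background was per-scan or
per-session is unstated). Zero-dose netOD means are pinned to 0 before
fitting. These sizes run the whole study in a few seconds and already
separate the materials cleanly.

## Numerical choices and degenerate inputs

- Fits: `scipy.optimize.curve_fit` (trust-region reflective with bounds),
  tolerances 1e-13, up to 2·10⁴ evaluations; non-convergence raises a fit
  error with diagnostics.
- Slightly negative measured netODs (zero-dose scan noise) are clamped to 0
  for the calibration fit with a warning; below −0.02 is treated as a data
  error.
- Signal at or below background raises immediately; exposed brighter than
  unexposed warns (negative netOD) or raises in strict mode.
- ROI CV is NaN-flagged when the mean is zero; ROI windows clipped by the
  image edge raise rather than truncate.
- Doses are Gy internally and cGy at the CLI and report boundaries.
- Percentages are reported at full precision in JSON; display rounding (1 dp
  for doses and percents, 4 dp for CV) mirrors the field's table formats.

## Known limitations

- The uncertainty budget reproduces the published two-term form; users who
  need the full covariance propagation must opt into the extended mode.
- The power-law family is the only response model offered.
- ROI placement is explicit (from the generator manifest or user
  coordinates); there is no automatic lens detection.
- The accuracy ordering among the three compensating materials is a
  stochastic outcome of the simulated study; with triplicate readouts at two
  doses and two modes, the grease-vs-silicone gap is a factor of ~2 in
  expected error, so an occasional seed can invert adjacent ranks (the
  air-vs-any gap is an order of magnitude and does not invert in practice).
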