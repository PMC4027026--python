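# Methods

This note documents the models behind memspec, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices a user may want to override.

## Powder lineshapes and orientation averaging

Both the ²H and ³¹P generators average over director orientations sampled
uniformly in cos θ (the isotropic powder measure) on a midpoint grid of
2000 points, bin the transition frequencies onto the output axis, and
convolve with a unit-area Lorentzian whose full width at half maximum is the
`broadening` parameter.

For a deuteron with 90°-orientation quadrupolar splitting Δν₉₀ (kHz) the two
transitions sit at ν±(θ) = ±Δν₉₀(3cos²θ − 1)/2: the horns (θ = 90°) are
separated by Δν₉₀ and the 0° shoulders by 2Δν₉₀. Reported splittings are
always the 90° (horn) values, consistent with the 3/4 factor in
Δν_Q = (3/4)(e²qQ/h)·S_CD, with the quadrupolar coupling constant
e²qQ/h = 170 kHz for aliphatic C–D bonds. The geometric form
S = (3cos²β − 1)/2 is implemented with β as printed in the source
experimental protocol (the angle to the direction perpendicular to the
bilayer normal); that phrasing conflicts with the usual bilayer-normal
convention, and we implement the formula as given rather than resolve the
text.

The ³¹P tensor is axially symmetric with σ⊥ = iso + CSA/3 and
σ∥ = iso − 2·CSA/3, so the lowfield (perpendicular, intensity-maximum) and
highfield (parallel) edges are separated by exactly CSA and the isotropic
position is the tensor trace point. Isotropic lines are added as Lorentzians
with linewidths specified in Hz (converted with the spectrometer frequency,
162 MHz for ³¹P by default).

## De-Pake-ing as regularised non-negative inversion

The classical de-Pake-ing product — a weight for every oriented splitting —
is obtained here by solving

  min_w ‖K w − s‖² + λ‖D w‖²,  w ≥ 0,

where column j of K is the broadened powder doublet of grid splitting Δⱼ
(same orientation model as the generator) and D is the second-difference
operator. Defaults: grid 0.5–40 kHz in 0.1 kHz steps; λ chosen at the corner
(maximum Menger curvature) of the L-curve over λ ∈ 10⁻⁶…10⁻¹ (relative to
the operator norm ratio ‖K‖/‖D‖); kernel linewidth taken from the spectrum
metadata when the generator recorded it, otherwise 0.5 kHz — on real data it
should be matched to the apparent width of the sharpest doublet horn, and a
substantially mismatched kernel visibly degrades the inversion. Spectra are
symmetrised about zero first (powder doublets are even); an odd fraction
above 5 % raises a warning, since it usually indicates phasing or baseline
problems rather than noise.

Peak extraction clusters local maxima of w closer than 1 kHz, reports each
cluster at its weight centroid with its summed weight, and caps the list by
descending weight. Weights below ~10 % of the largest component should be
treated as inversion artifacts at moderate signal-to-noise; the pipeline's
"largest splitting" summaries apply exactly that cut. Chain-position
assignment is by magnitude: smallest splitting → terminal CD3, largest →
C2–C8 plateau (treated as one effective component, as it is resolved as
one edge), intermediates → C14…C9 in ascending order.

## ³¹P CSA measurement

After Savitzky–Golay smoothing (9 points, order 2) and baseline removal
(median of the outer 10 % of points), the outermost positions exceeding 5 %
of the maximum bracket the spectrum edges. A bare threshold reading
systematically overestimates the separation on a Lorentzian-broadened
pattern — the tail beyond the singular perpendicular edge crosses 5 % of the
(tall) maximum ~2–3 linewidths out — so by default each bracket is refined
to the half-height point of its local shoulder, which is exact for a step
edge under any symmetric broadening kernel and leaves only a fraction of a
linewidth of bias at the singular edge (measured: +0.3 ppm at CSA 58 ppm,
1 ppm linewidth). `refine_edges=False` restores the literal threshold
reading. Separations below 5 ppm are flagged near-isotropic.

Isotropic components are found by fitting the sharpest feature as a
Lorentzian over a quadratic local baseline (the quadratic follows the powder
density's curvature), subtracting it to measure the powder geometry, and
accepting a component within ±10 % of the CSA of the isotropic position and
narrower than 20 % of the CSA; smaller lines are hunted via a wide median
filter. Classification by fitted full width: ≤ 100 Hz → solubilisation
(solution-like resolved line), ≤ 2 kHz → membrane fragments. These cutoffs
generalise the observed contrast between a few-tens-of-Hz solution line and
the ~600 Hz fragment line; both are arguments, not constants. Area fractions
use the analytic Lorentzian area over the total spectrum area and are
accurate to ~0.05 for fractions 0.1–0.9.

## ESR lineshape and order parameter

The generator is a documented phenomenological construction, not a
slow-motional simulation: Gaussian derivative-shaped features are placed so
that the outermost maximum/minimum sit exactly at center ∓ T∥ and the
flanking inner pair at center ∓ T⊥, with a narrow central m = 0 feature.
Feature widths are capped at 0.25·(T∥ − T⊥) so overlap does not displace the
extrema from their defining positions; only the two separations are
meaningful, the amplitudes merely mimic the look of 5-doxyl-stearate
spectra. Measurement smooths with a moving average (default 7 points), finds
extrema with a prominence floor of max(2 % of the sweep amplitude, 8× the
baseline noise), and refines each by a quadratic fit over ±1.5 G. A pattern
of narrow, deep, adjacent max/min pairs is flagged as an unincorporated
(free-rotating) probe.

The order parameter is computed verbatim from the published expression

  S = 1.723·(2T∥ − 2T⊥ − C)/(T∥ + 2T⊥ + C),  C = 1.4 − 0.053·(T∥ − T⊥),

whose denominator mixes half- and full separations; it can exceed 1 and is
reported as-is (for (60, 20) G it gives 1.357). Because the temperature
analysis only needs a monotone order proxy, this does not affect transition
fitting. The conventional all-half-value Hubbell–McConnell form
S = 1.723·(T∥ − T⊥ − C)/(T∥ + 2T⊥ + C) (0.67 for the same inputs) is
available via `form="standard"`; the printed form stays the default for
fidelity to the protocol the package reproduces.

## Binding analysis

The 1:1 complex concentration is the exact quadratic root, evaluated in the
cancellation-free form [HG] = 2H₀G₀/(s + √(s² − 4H₀G₀)), s = H₀ + G₀ + Kd,
and observed shifts are fast-exchange population averages on the host. The
Job response is |δ_obs − δ_free|·F (host-mole-fraction weighting,
`weighting="host"` switches to H₀), with the maximum refined by quadratic
interpolation and pooled across resonances by the median.

The association constant is fitted as log₁₀ Ka (positivity by
construction) together with one bound shift per resonance, free shifts held
at their pure-host values, by Nelder–Mead from 5 starting values spaced over
log Ka ∈ [1, 8], best residual sum of squares winning, followed by a polish
restart. Titration fixtures carry six host resonances at 2 mM total
concentration with bound-shift changes of 0.05–0.15 ppm, matching the
several-resonance pooling of the original continuous-variations experiment.
At that scale with 0.002 ppm shift noise and 9 fractions, the median
recovery error is ≈ 0.05–0.06 log units for true log Ka 3.5–4.5, degrading
to ≈ 0.12 by log Ka 5.5 as binding saturates (Kd ≪ total concentration) and
collapsing entirely below log Ka ≈ 2.5, where only the product Ka·Δδ is
identifiable. Degenerate (variation-free) series raise a non-identifiability
error rather than fitting silently.

## Transition fitting

Observable-versus-temperature series are fitted with a four-parameter
logistic y(T) = high + (low − high)/(1 + exp((T − midpoint)/width)),
initialised at the temperature of maximum |dy/dT|, bounded trust-region
least squares. Flat series (fitted amplitude below 3× the residual standard
deviation) set a no-transition flag instead of raising. At 1 K sampling over
290–310 K with 2 % noise, midpoints are recovered to better than 0.2 K.

## Synthetic study conditions

The membrane fixtures encode the four systems' published endpoint
splittings at 298 K (CD3/plateau: DMPC 4.0/29.0, +CYSP 4.2/31.0, +POLYA
3.6/26.6, +ASD 4.4/28.0 kHz) with stoichiometric deuteron weights (CD3 = 6,
CD2 = 4 each, plateau = 28). The intermediate C14…C9 values are linear
interpolations between the endpoints — the profile is monotone in reality
but the intermediate numbers are a stand-in, not data. At 308 K all
splittings are scaled by 0.85 to emulate fluid-phase narrowing; that factor
is likewise a package choice. Default desk-scale problem sizes (2048-point
spectra, signal-to-noise 100 for fixtures, 50 for the degraded-membrane
scenario) keep every analysis under a few seconds.

What the generators do **not** emulate: relaxation and finite-pulse
artifacts, spectrometer baseline roll and phase errors, slow-motional ESR
regimes, probe partitioning, polydispersity of the cyclodextrin copolymer
host, and asymmetric Job curves from mixed binding mechanisms. Passing the
round-trip suites therefore demonstrates correctness of the inversion and
measurement algorithms under ideal instrument response, not robustness to
every instrumental pathology of real spectra.

## Limitations

- The de-Pake grid resolution (0.1 kHz) and the 1 kHz merge radius bound how
  close two doublets can be and still be reported separately.
- CSA measurement assumes an axially symmetric pattern; σ₁₁ ≠ σ₂₂ tensors
  and lamellar/hexagonal exchange lineshapes are out of scope.
- The ESR order parameter is apparent: no polarity or partitioning
  correction beyond the printed C term.
- Binding analysis is strictly 1:1 and fast-exchange; m:n models and
  mechanistic discrimination between inclusion and adduct formation are out
  of scope.
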