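# Methods

## Spectral model

A component's Raman spectrum is simulated as a sum of Lorentzian bands,
one per vibrational mode:

    S(ν̃) = Σ_j (I_j / π) · γ / ((ν̃ − ν̃_j)² + γ²),   γ = FWHM / 2.

The mode intensity I_j is the **band area** (integrated intensity), not
the peak height. The integral of a Lorentzian is independent of its
width, so a change of broadening FWHM rescales band heights but leaves
LCF coefficients — which compare areas through the fit — essentially
unchanged; this is the amplitude convention used throughout. The default
FWHM is 10 cm⁻¹, appropriate for solution-phase bands in this window; a
peak table may carry a per-component override (the atmospheric O₂ line is
broadened at 4 cm⁻¹ because it is a sharp gas-phase feature). The default
analysis grid is 1150–1800 cm⁻¹ with a 1 cm⁻¹ step (651 points), the
region where the diagnostic bands of this chemistry live; grid, FWHM and
window are all configurable.

The built-in six-component library (formamide, H₂O, DAMN, AI, purine, O₂)
uses the published band *positions* for this system. Relative
intensities within each component are not published anywhere and are
generator choices, constrained only so each component's assigned
strongest band is strongest, and so that the formamide 1390/1300 band
ratio is 0.54, the value observed at the start of reaction when the
mixture is essentially pure formamide. The AI table is an explicit
synthetic stand-in: no band list for this window is available beyond "a
high-frequency shoulder of the 1390 cm⁻¹ band", so AI gets a 1410 cm⁻¹
band plus deliberately overlapping bands at 1325 (DAMN's position) and
1485 (purine's position), making AI the hardest, most collinear column —
a stress test for the solver, not ground truth about the molecule.

## Normalization

Each spectrum is divided by the maximum intensity inside a ±15 cm⁻¹
window around the formamide reference band at 1390 cm⁻¹. Locating the
reference as a window maximum (rather than the value at exactly
1390 cm⁻¹) tolerates small wavenumber-calibration shifts; the ±15 cm⁻¹
half-width keeps the DAMN 1325 cm⁻¹ band out of the window. Because the
division is a single global scale, normalization is idempotent,
scale-invariant, and preserves every band-intensity ratio. No baseline
correction is applied by default (the monitoring protocol uses none); a
crude linear-offset baseline fitted to the lowest-intensity decile is
available behind a config flag and is only reliable when the low decile
is genuinely signal-free (narrow, sparse bands).

## Constrained fit and the scale gauge

The per-spectrum problem is min_C ‖P·C − D‖₂² with C ≥ 0 and designated
components fixed (formamide = 1). The NNLS core is a first-party
Lawson–Hanson active-set iteration: the entering variable is the most
negative gradient component (first index on exact ties), the termination
and feasibility tolerance is 1e-10 scaled by ‖AᵀB‖∞, the iteration cap is
10·k active-set changes (exceeding it raises a convergence error carrying
the cap and residual), and every returned solution carries a relative KKT
violation diagnostic. The fit is the package's central computation, which
is why it is implemented in-repo and certified against independent
oracles (exhaustive active-set enumeration; projected gradient; SciPy's
solver) in the test suite rather than delegated.

Fixed components are honored in two modes:

* **Literal (residual subtraction).** The fixed contribution is
  subtracted from D and the free columns are fitted to the remainder.
  The constraint holds exactly and the fixed value is interpreted on the
  intensity scale of D as given. This is the right mode when D's scale is
  trusted.

* **Scale gauge** (default for series fitting). Monitoring data carry an
  arbitrary, time-varying global intensity factor (self-absorption decay,
  instrumental fluctuations, the normalization divisor itself). Window-max
  normalization removes that factor only up to band-overlap cross-talk in
  the reference window: tails of neighbouring bands contribute O(10⁻³) of
  the window maximum, and a literal fixed-value fit inherits a bias of
  that order. The gauge mode instead solves the problem with every
  component free, reads the global scale off as the ratio of the fixed
  component's fitted weight to its prescribed value, and divides all
  coefficients by it. For noiseless data this cancels *any* global scale
  exactly (to machine precision, verified at 1e-8 tolerance in the
  acceptance suite), which is the operational property the
  constant-reactant normalization exists to deliver. The gauge requires a
  single fixed component with a positive value; a spectrum in which the
  gauge component is fitted at zero is flagged as a per-point failure.

Normalization is still applied before the gauge fit: it is the protocol's
reporting convention, it is what makes the decay-exempt O₂ artifact
visible, and it conditions the data scale.

## Trajectories and landmarks

Each time point is fitted independently — no temporal smoothing or
regularization — so trend statements are post hoc and time points can be
fitted in any order or subset with identical results. Onset is the
earliest time the coefficient reaches 5 % of the trajectory maximum;
plateau is the earliest time from which all later values stay within
±5 % of their tail mean over at least 3 points. Both thresholds are
config-exposed; the defaults encode "detectable" and "flat" at the
resolution of hourly sampling, since only qualitative timing information
exists to calibrate them against. The onset detector is provably
monotone in its threshold. `band_ratio` reports window-max ratios and
makes no normalization assumption; note that ratios quoted for spectra
normalized *at one of the two bands* pin that band to 1, which can invert
the apparent trend relative to raw data.

## Synthetic data generator

The generator emulates the 12-hour monitoring study: hourly spectra
t = 1…12 h on the default grid,

    D_t = g_t · Σ_i c_i(t) · S_i  (+ decay-exempt terms)  + ε,

with g_t = exp(−λt) a global decay, ε additive white Gaussian noise with
standard deviation σ × (noiseless series maximum), and kinetic profiles
c_i(t) chosen per component:

| component | profile | amplitude | onset/midpoint | rate |
|---|---|---|---|---|
| Form | constant | 1.0 | — | — |
| H₂O | saturating 1−e^(−r·t) | 0.5 | 0 h | 0.35 /h |
| DAMN | sigmoid | 0.5 | 0.5 h | 1.2 /h |
| Purine | sigmoid | 0.6 | 3.5 h | 2.0 /h |
| AI | sigmoid | 0.4 | 6.5 h | 2.0 /h |
| O₂ | constant, decay-exempt | 0.08 | — | — |

Defaults: σ = 0.005 (0.5 % of series max), λ = 0.1 /h (≈70 % of the
signal lost by 12 h). The sigmoid midpoints stagger the products in the
observed order (DAMN first, purine from 3–4 h, AI after 6 h); the rates
are set so that a 5 %-of-maximum detector reads the onsets in that order
with hourly sampling, and the H₂O rate puts the 5 %-flatness plateau at
7 h. The O₂ line is *not* multiplied by g_t — it originates in the
spectrometer's optical path, not in the sample — which makes its
post-normalization weight grow as everything else decays, reproducing the
well-known apparent-growth artifact. Self-absorption is modelled as a
single global exponential scale because normalization cancels any global
scale regardless of its functional form; no wavenumber jitter is applied
by default. All randomness flows from one integer seed
(`numpy.random.default_rng`; replicate seeds are spawned via
`SeedSequence`), and regeneration is bit-identical.

Ground truth is stored twice: the injected kinetic weights, and the
*apparent* weights an ideal gauge fit of normalized data recovers
(identical for components that follow the decay; c/g_t for decay-exempt
ones). Recovery is always scored against the apparent truth, which
coincides with the injected truth when decay is off.

What the generator does **not** emulate — and hence what passing tests do
not certify about real beamline data: resonance-enhanced and therefore
unknown relative Raman cross-sections between species (coefficients are
spectral weights, not concentrations), wavelength-dependent
self-absorption (real absorption distorts band shapes, not just the
global scale), detector/photon noise statistics, cosmic-ray spikes,
baseline drift, and calibration drift. Basis-model error — real product
spectra differing from the simulated pure spectra — is likewise absent:
the generator and the fit share the component library by construction, so
recovery results bound only the estimation error, not the modelling
error.

## Numerical choices

* Degenerate, collinear bases (the AI column) are handled by the
  active-set tie-break (most negative gradient, first index) and the
  iteration cap; termination does not require full column rank.
* Resampling is linear interpolation, exact at coincident points, with
  extrapolation forbidden; linear is monotone and artifact-free for
  smooth Lorentzian sums sampled at 1 cm⁻¹.
* All floats in text artifacts are written with 12 significant digits so
  that identical runs produce byte-identical files.
* Problem sizes throughout (651-point grid, 6 components, 12 time
  points, 50 Monte-Carlo replicates per noise level) keep the full test
  suite and the acceptance script in the seconds range while leaving
  noise-limited quantities well resolved.

## Known limitations

* The gauge mode assumes the fixed component is genuinely present in
  every spectrum; it fails (flagged, not silent) when the reference is
  absent.
* `detect_plateau` on a saturating-but-still-creeping trajectory is
  threshold-sensitive near the boundary; with 0.5 % noise the detected
  H₂O plateau lands at 7 or 8 h depending on the seed, within the hourly
  sampling resolution.
* Coefficients are relative spectral weights; converting them to
  concentrations would require relative Raman cross-sections under the
  actual excitation, which are out of scope.
* The JCAMP-DX format is not read; spectra are exchanged as two-column
  delimited text.
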