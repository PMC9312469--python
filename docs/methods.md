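# Methods

This note documents the models implemented in ffskit, the conventions and
defaults they use, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Observation volume

The confocal detection profile is the standard 3D-Gaussian approximation

    B(x, y, z) = exp(−2(x² + y²)/w0²) · exp(−2 z²/z0²),

with lateral 1/e² radius `w0`, axial radius `z0` and structure parameter
`S = z0/w0`. The default geometry, `w0 = 0.2 µm`, `S = 5`, is typical for a
water-immersion confocal setup at 488 nm. Membrane measurements place the
emitters in the `z = 0` plane, where only the lateral profile matters.

Useful profile integrals (2D / 3D):

    ∫B     = (π/2) w0²             | (π/2)^{3/2} w0² z0
    ∫B²    = (π/4) w0²             | (π^{3/2}/8) w0² z0
    γ      = ∫B²/∫B = 1/2          | 2^{−3/2}

`γ` is the profile contrast factor. The zero-lag FCS amplitude of a single
species is `γ/N_eff`, with `N_eff` the mean molecule number in the
PSF-integral volume `∫B`. The fitted FCS parameter `N` is the amplitude
parameter of the model (`G(0) − G∞ = 1/N`), i.e. `N = N_eff/γ`; no separate
γ is reported.

## Photon-trace simulator

Particles take independent Gaussian steps with per-axis standard deviation
`sqrt(2 D Δt_micro)` in a periodic box, and the detected intensity per
micro-step is `Σ_i ε_i B(r_i)` evaluated at the end-of-step position
(quasi-static emission). Binned counts are Poisson draws around the
integrated intensity plus `background_rate · bin_time`. The brightness
convention is a single one package-wide: `ε` is counts·s⁻¹·molecule⁻¹ at
beam center (CPSM).

- **Particle number.** The number of particles per species is a Poisson draw
  around `mean_number` (open-system statistics); initial positions are
  uniform. A single trace is therefore *conditioned* on its particle draw —
  see the PCH protocol below for why this matters.
- **Micro-steps.** `substeps=None` picks the smallest number keeping the RMS
  micro-step below `w0/5`. Halving the micro-step changes the mean count
  rate by well under 1% (tested).
- **Box size.** The default half-widths are `6·w0` laterally and `6·z0`
  axially; the invariant floor is `4·w0`/`4·z0`. The recovery scenarios use
  the floor to keep particle counts (and runtime) down; the PSF truncated at
  `4·w0` loses only `e⁻³²` of its mass.
- **Determinism.** All randomness flows from one seeded generator
  (numpy SFC64); identical configs give bit-identical traces. Gaussian
  steps are drawn in float32 for speed — the accumulated rounding error in a
  position over 10⁶ steps is ~10⁻⁴ µm, far below any physical scale here.
- **Finite-box artifact (important).** On a torus the occupancy
  autocorrelation decays to zero once the slowest diffusion mode
  (`τ_box ≈ L²/(4π²D)`) has equilibrated, instead of following the slow
  free-space tail. ACF fits must therefore stay within a window of a few
  tens of residence times (see FCS fitting below). This is a limitation of
  the synthetic data, not of the estimators: passing recovery tests shows
  the analysis chain is unbiased on data matching its assumptions within
  the fitted window, not that instrument-scale tails are reproduced.

The simulator does not model triplet/blinking photophysics, detector
dead-time or afterpulsing, vesicle curvature, or polarization-resolved
emission.

## FCS

Two estimators:

- `autocorrelate_direct` — the exact estimator
  `G(τ) = ⟨δF(t) δF(t+τ)⟩/⟨F⟩²` over all valid pairs; lags must be integer
  bin multiples below half the trace duration.
- `autocorrelate_multitau` — the standard log-spaced scheme: `m` lags at
  native binning, then `m/2` lags per level after successive 2× rebinning,
  with symmetric normalization (direct and delayed monitor means). The two
  agree to ~10⁻⁵ at native-bin lags; at rebinned lags each point estimates a
  triangular average of G, whose bias is second order in the kernel width.

Model fits use lmfit least squares (weights `1/sem²` when the curve carries
SEMs, e.g. after `average_curves`). `τ_D` is bounded to
`[2·bin_time, duration/10]`, `N ∈ (0, 10⁶]`, `G∞` free; the structure
parameter is fixed at the beam value. Defaults for the starting point come
from the curve amplitude and half-decay lag. No triplet term is included.
Nested one- vs two-component models are compared by an F-test on residual
sums of squares at α = 0.05, with ties resolved in favour of the
one-component model.

**Fit window.** Recovery scenarios restrict the fitted lags to
`10·τ_D^expected` (3D) or `20·τ_D^expected` (2D), where
`τ_D^expected = w0²/(4 D_truth)`. Fitting the full multi-tau range on
finite-box data biases D upward by 5–11% because the box-mode cutoff
masquerades as a faster decay; inside the window the median recovered D is
within ~1.5% of truth. Choosing the window around the expected residence
time is also standard practice on real data, where long-lag tails carry
drift and depletion artifacts.

## PCH

A single particle uniform in a reference volume `V_ref` emits `k` photons in
a bin of length `T` with probability

    p₁(k) = (1/V_ref) ∫ Poisson(k; εT·B(r)) dr,     k ≥ 1,

and `p₁(0)` carries the remaining mass. For the Gaussian profile the lateral
integral has the closed form `(π w0²/2)·P(k, εT)/k` with `P` the regularized
lower incomplete gamma function; the 3D case adds a 200-node Gauss–Legendre
quadrature along the axis (support truncated at `5·z0`, suppression e⁻⁵⁰).

With the molecule number in `V_ref` Poisson distributed, the per-bin count is
compound Poisson; the package evaluates it exactly with the Panjer recursion
on the photon-emission intensities `ν_k = N̄·p₁(k)`. This is algebraically
identical to the textbook construction (Poisson-weighted N-fold convolutions
of `p₁`) but has no N-truncation error and makes the result manifestly
independent of `V_ref` (verified to < 10⁻⁶ total variation under volume
doubling). The pmf grid is extended until the truncated tail mass is below
10⁻¹², and species plus a Poisson background combine by construction in the
recursion.

Fits minimize a chi-square between expected frequencies `total_bins·P(k)`
and observed ones, with per-bin variance `max(expected, 1)` and tail bins
pooled where the expectation falls below 5. Brightness is reported per bin
and in CPSM (per-bin value divided by the bin time). Two-population fits
constrain `ε₂ ≥ 1.2·ε₁` against label swapping. The *fraction weighed by
brightness* is `F_i = N̄_i ε_i / Σ_j N̄_j ε_j` — each population's share of
the total fluorescence.

**Bin time.** PCH histograms in the recovery scenarios use 50 µs bins
(native 10 µs traces rebinned 5×). This stays ~30× below the membrane
residence time, so the quasi-static assumption (no diffusion within a bin)
still holds, while raising counts per bin enough for the two-population
shape to be identifiable at desk scale. No diffusion-during-bin correction
is applied; this first-order treatment is a documented limitation.

**Two-stage mixture protocol.** A free four-parameter two-population fit is
poorly identified at realistic photon budgets: the chi-square surface has a
long valley trading brightness against occupancy, and single fits can land
anywhere on it. The scenarios therefore mirror the experimental workflow of
anchoring the monomeric population to an independent measurement: a
monomer-only reference acquisition is fitted with one population to
calibrate `ε₁`, and the mixture is then fitted with `ε₁` fixed while the
second-population brightness (through the ratio) and both occupancies stay
free.

**Many short acquisitions.** Because a simulated trace is conditioned on one
particle-number draw, a single long trace's histogram deviates from the
open-volume model by the realized-number fluctuation (conditioning on the
realized numbers reproduces the model to within counting noise, |z| < 1 per
count value). The scenarios pool 32 mixture + 8 reference traces of 2.5 s
per replicate: fresh Poisson number draws per trace marginalize the
occupancy, restoring the open-reservoir statistics the model assumes and
shrinking the dominant noise term (the dimer-number draw) by √32.

## Anisotropy and photobleaching

Steady-state anisotropy follows
`⟨r⟩ = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)`, `G = I_HV/I_HH`; for non-negative
intensities the value is bounded in [−0.5, 1]. Mixtures combine additively
with intensity weights.

The homo-FRET oligomer model assumes the rapid-transfer limit: in an
oligomer with `m` intact fluorophores each photon is emitted by the directly
excited fluorophore `1/m` of the time, giving
`r_m = r_mono/m + (1 − 1/m)·r_et` with `r_et` the limiting anisotropy of
FRET-relayed emission. All intact fluorophores have equal brightness;
bleached subunits are perfectly dark; bleaching is independent per
fluorophore, so the surviving count of an n-mer is Binomial(n, q) with
`q = 1 − b`. The observed anisotropy is the intensity-weighted average over
bleach states of a mixture of monomers (subunit fraction `1 − f_oligo`) and
n-mers (`f_oligo`); a common factor of q is cancelled analytically so the
`b → 1` limit returns `r_mono` exactly.

**Identifiability.** The model reduces, for every n, to

    ⟨r⟩(q) = r_mono − f_oligo (r_mono − r_et) g_n(q),
    g_n(q) = 1 − (1 − (1−q)ⁿ)/(nq),

so the photobleaching curve constrains only the depolarization depth
`f_oligo·(r_mono − r_et)` plus the shape `g_n`. Oligomer size is probed by
comparing residual sums of squares between n = 2 and n = 3 fits (reported
side by side, no automatic selection, matching how such comparisons are
interpreted qualitatively); recovering `r_et` requires fixing `f_oligo` or
vice versa, and the fit API exposes `fix=` for exactly this. On
dimer-generated series with 1% noise the dimer fit wins the RSS comparison
in ≥ 8/10 replicates.

`b` denotes the fluorophore bleached fraction. If an experiment quantifies
bleaching by intensity loss instead, the two coincide under the equal
brightness assumption.

## Recovery scenarios (desk scale)

All scenarios use the default beam and the box floor `4·w0`/`4·z0`;
tolerances quoted are on the median over ten seeded replicates.

| scenario | truth | acquisition per replicate | analysis | tolerance |
|---|---|---|---|---|
| solution-3d | D = 70.09 µm²·s⁻¹, ε = 5·10⁴ CPSM, N_eff = 1 | 1 × 10 s at 100 kHz | multi-tau + 3D-1c fit, window 10 τ_D | 7% |
| membrane-2d | D = 6.12 µm²·s⁻¹, ε = 6500 CPSM, N_eff = 1 | 1 × 20 s at 100 kHz | multi-tau + 2D-1c fit, window 20 τ_D | 10% |
| dimer-mixture | ε₁ = 6500, ε₂ = 17200 CPSM, F₂ = 28.7% | 32 × 2.5 s mixture + 8 × 2.5 s reference | PCH, 50 µs bins, calibrated-ε₁ two-population fit | ±5.3 pp |
| bleach-series | n = 2, r_mono = 0.312, r_et = 0.10, f_oligo = 0.85 | 10 points, b ∈ [0, 0.9], σ = 0.003 | binomial-model fit, f_oligo fixed | ±0.02 |

The reported brightness values (0.065 / 0.172 for monomer / dimer under
EDTA) are interpreted as counts per sampling interval at 100 kHz — i.e.
6500 / 17200 CPSM — which gives realistic YFP count rates; read literally as
counts·s⁻¹ they would produce ~10⁻⁶ counts per bin and no measurable signal.
The recovery targets (diffusion coefficients, F₂, brightness ratio) are
unaffected by this overall scale.

`full_scale=True` switches the FCS scenarios to 60 s at 500 kHz acquisitions
in the default 6× box; the desk-scale settings above are the tested
defaults.

## Numerical notes

- Degenerate inputs are rejected with explicit messages (negative rates,
  undersized boxes, empty traces, zero-mean traces in the correlators,
  all-dark brightness mixtures, zero `I_HH`).
- Fit results flag non-convergence and bound-pinned parameters
  (`results.flagged`) rather than failing silently.
- Text I/O writes floats with 12 significant digits; counts round-trip
  exactly and rewritten files are byte-identical.
- The bleach model handles `q = 0` by the analytic limit (the shared factor
  q is cancelled symbolically), so no 0/0 arises at full bleaching.
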