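# ffskit

Fluorescence fluctuation spectroscopy toolkit for studying membrane-protein
organization — in particular Ca²⁺-modulated oligomerization of a
PI(4,5)P₂-binding PH domain fused to a dimerization-prone YFP. The package
provides the full quantitative chain used in such studies:

- **Brownian-dynamics photon simulation** — point emitters diffusing in 3D
  (solution, D ≈ 70 µm²·s⁻¹) or confined to the membrane plane
  (D ≈ 4–8 µm²·s⁻¹) through a 3D-Gaussian confocal observation volume, with
  Poisson photon statistics and background.
- **FCS** — exact and multi-tau autocorrelators plus one/two-component 2D/3D
  diffusion fits: `G(τ) = G∞ + (1/N)(1+τ/τ_D)⁻¹(1+τ/(S²τ_D))^(−1/2)` in 3D,
  without the axial factor in 2D, and `D = w₀²/(4τ_D)`.
- **PCH** — photon counting histogram analysis: exact single-particle count
  distributions for the Gaussian profile (incomplete-gamma closed form),
  open-volume compound-Poisson mixtures of brightness populations, and one- or
  two-population fits reporting molecular brightness ε (CPSM) and the
  *fraction weighed by brightness* `F_i = N̄_i ε_i / Σ_j N̄_j ε_j`.
- **Homo-FRET anisotropy** — steady-state anisotropy
  `⟨r⟩ = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)` with `G = I_HV/I_HH`, and a
  binomial photobleaching oligomer model: each subunit survives bleaching with
  probability q = 1−b, an n-mer with m intact fluorophores emits at
  `r_m = r_mono/m + (1−1/m)·r_et`, and the ensemble anisotropy is the
  intensity-weighted binomial average, recovering `r_mono` as b → 1.
  Dimer and trimer variants are fitted side by side to probe the
  oligomerization number.

Everything is organised as model objects: construct a model from data
(`FCSDiffusionModel`, `PCHModel`, `BleachRecoveryModel`), call `.fit()`, and
read estimates, uncertainties and `summary()` off the results object.

## Worked example

Simulate a membrane-bound species at the reported GUV diffusion coefficient,
correlate, and fit the 2D one-component model:

```python
from ffskit import (DEFAULT_BEAM, SimConfig, SpeciesParams, simulate_trace,
                    autocorrelate_multitau, fit_acf)
from ffskit.fcs import restrict_lags

beam = DEFAULT_BEAM                      # w0 = 0.2 um, S = 5
cfg = SimConfig(
    species=(SpeciesParams("PH-YFP", D=6.12, epsilon=6500.0, mean_number=40.7),),
    beam=beam, dimensionality=2, box_extent=(0.8, 0.8),
    duration=20.0, bin_time=1e-5, seed=1,
)
trace = simulate_trace(cfg)
curve = autocorrelate_multitau(trace, m=16)
tau_d_expected = beam.w0**2 / (4 * 6.12)
fit = fit_acf(restrict_lags(curve, 20 * tau_d_expected), "2d1c", beam=beam)
print(fit.summary())
```

prints (seed 1):

```
FCS diffusion fit: model 2d1c, 76 lags, reduced chi^2 = 6.453e-05
  converged: True
  N        = 1.89563 +/- 0.01047
  g_inf    = -0.0255048 +/- 0.002807
  tau_d    = 0.00168277 +/- 4.044e-05
  component 1: tau_D = 0.001683 s -> D = 5.943 um^2/s
```

The fitted occupancy N ≈ 1.9 corresponds to the configured mean of ~1
molecule in the PSF-integral area (the zero-lag amplitude is γ/N_eff with
γ = 1/2 in 2D), and the recovered D = 5.94 µm²·s⁻¹ sits within 3% of the
simulated truth 6.12 µm²·s⁻¹ — typical single-trace scatter; the recovery
scenarios report the median over ten seeds.

The same chains are available from the shell:

```bash
ffskit simulate --d 6.12 --epsilon 6500 --mean-number 40.7 --dim 2 \
    --duration 20 --bin-time 1e-5 --box-extent 0.8 --box-extent 0.8 \
    --seed 1 --out trace.tsv
ffskit fcs trace.tsv --model 2d1c --max-lag 0.033
ffskit pch trace.tsv --n-species 1 --dim 2 --rebin 5
ffskit anis --ivv 3 --ivh 1 --ihv 2 --ihh 2
ffskit recover --scenario membrane-2d --replicates 10 --seed 1
```

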