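"""Photon counting histogram (PCH) analysis.

The distribution of per-bin photon counts separates co-diffusing
species by molecular brightness.  A single particle placed uniformly
in a large reference volume ``V_ref`` around a Gaussian profile B(r)
emits k photons in a bin of length T with probability

    p1(k) = (1 / V_ref) * Integral  Poisson(k; eps * T * B(r)) dr ,  k >= 1,

and p1(0) carries the remaining mass.  For the Gaussian profile the
spatial integral reduces to regularized lower incomplete gamma
functions: laterally

    Integral_2D Poisson(k; x B) dA = (pi w0^2 / 2) * P(k, x) / k ,

with x = eps*T and P the regularized lower incomplete gamma function;
the 3D case adds a one-dimensional axial quadrature.  With the
molecule number in ``V_ref`` Poisson distributed, the per-bin count is
a compound-Poisson superposition of single-particle contributions;
species and a Poisson background combine by convolution.  The model
here evaluates that superposition exactly via the Panjer recursion on
the photon-emission intensities nu_k = N * p1(k), which makes the
result manifestly independent of the choice of ``V_ref``.

Brightness is reported both per bin (eps*T) and in CPSM
(counts/s/molecule, the per-bin value divided by the bin time).  The
quasi-static approximation (no diffusion during one bin) is assumed,
appropriate for bins much shorter than the residence time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy import special

from .beam import BeamProfile, DEFAULT_BEAM
from .simulate import PhotonTrace

__all__ = [
    "PCHistogram",
    "PCHSpecies",
    "PCHResults",
    "PCHModel",
    "build_pch",
    "single_particle_pmf",
    "mixture_pmf",
    "fit_pch",
    "brightness_fractions",
]

_MAX_K = 4096


@dataclass
class PCHistogram:
    """Empirical count-frequency table for a fixed bin time."""

    counts_axis: np.ndarray
    frequency: np.ndarray
    bin_time: float

    def __post_init__(self) -> None:
        self.counts_axis = np.asarray(self.counts_axis, dtype=np.int64)
        self.frequency = np.asarray(self.frequency, dtype=np.int64)
        if self.counts_axis.shape != self.frequency.shape:
            raise ValueError("counts_axis and frequency must have equal length")
        if not np.array_equal(self.counts_axis, np.arange(self.counts_axis.size)):
            raise ValueError("counts_axis must be contiguous integers starting at 0")
        if np.any(self.frequency < 0):
            raise ValueError("frequencies must be non-negative")
        if not (self.bin_time > 0):
            raise ValueError(f"bin_time must be positive, got {self.bin_time}")

    @property
    def total_bins(self) -> int:
        return int(self.frequency.sum())

    @property
    def k_max(self) -> int:
        return int(self.counts_axis[-1])

    @property
    def mean(self) -> float:
        return float((self.counts_axis * self.frequency).sum() / self.total_bins)


def build_pch(trace: PhotonTrace) -> PCHistogram:
    """Exact per-bin count-frequency table of a photon trace."""
    if trace.n_bins == 0:
        raise ValueError("cannot histogram an empty trace")
    freq = np.bincount(trace.counts)
    return PCHistogram(
        counts_axis=np.arange(freq.size), frequency=freq, bin_time=trace.bin_time
    )


@dataclass(frozen=True)
class PCHSpecies:
    """One brightness population: eps in CPSM and mean number in the reference volume."""

    epsilon: float
    mean_number: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.mean_number < 0:
            raise ValueError(f"mean_number must be >= 0, got {self.mean_number}")


def _axial_nodes(z0: float, n_nodes: int = 200) -> tuple[np.ndarray, np.ndarray]:
    # profile support is effectively |z| <= 5 z0 (suppression e^-50)
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 5.0 * z0
    return half * (x + 1.0) / 2.0, w * half / 2.0


def _emission_integrals(
    x: float, beam: BeamProfile, dimensionality: int, k_max: int
) -> np.ndarray:
    """I_k = Integral Poisson(k; x B(r)) dr for k = 1..k_max (um^2 or um^3)."""
    k = np.arange(1, k_max + 1)
    lat = math.pi * beam.w0**2 / 2.0
    if x <= 0:
        return np.zeros(k_max)
    if dimensionality == 2:
        return lat * special.gammainc(k, x) / k
    z, w = _axial_nodes(beam.z0)
    lam = x * np.exp(-2.0 * z**2 / beam.z0**2)
    vals = special.gammainc(k[:, None], lam[None, :])  # (k_max, nodes)
    return lat * 2.0 * (vals @ w) / k


def single_particle_pmf(
    epsilon: float,
    bin_time: float,
    beam: BeamProfile = DEFAULT_BEAM,
    dimensionality: int = 2,
    ref_volume: float | None = None,
    k_max: int | None = None,
) -> np.ndarray:
    """Count distribution of one particle uniform in ``ref_volume`` (deterministic quadrature).

    ``ref_volume`` must exceed 50x the PSF-integral volume; the default
    is 100x.  p(0) is assigned the remaining mass so the pmf sums to 1
    exactly.
    """
    if epsilon < 0 or bin_time <= 0:
        raise ValueError("epsilon must be >= 0 and bin_time positive")
    v_psf = beam.psf_integral(dimensionality)
    if ref_volume is None:
        ref_volume = 100.0 * v_psf
    if ref_volume < 50.0 * v_psf:
        raise ValueError(
            f"ref_volume must be >= 50x the PSF-integral volume ({50 * v_psf:g})"
        )
    x = epsilon * bin_time
    if k_max is None:
        k_max = _auto_kmax(x)
    tail = _emission_integrals(x, beam, dimensionality, k_max) / ref_volume
    pmf = np.empty(k_max + 1)
    pmf[1:] = tail
    pmf[0] = 1.0 - tail.sum()
    return pmf


def _auto_kmax(x: float) -> int:
    if x <= 0:
        return 8
    # Poisson at the beam center bounds the tail of the spatial mixture:
    # gammainc(k, x) is the probability a center molecule emits >= k photons
    k = max(8, int(math.ceil(x + 10.0 * math.sqrt(x + 1.0))))
    while k < _MAX_K and special.gammainc(k, x) > 1e-14:
        k *= 2
    return min(k, _MAX_K)


def _panjer(nu: np.ndarray) -> np.ndarray:
    """pmf of a compound Poisson with photon-emission intensities nu_1..nu_K."""
    k_max = nu.size
    pmf = np.zeros(k_max + 1)
    pmf[0] = math.exp(-nu.sum())
    j_nu = np.arange(1, k_max + 1) * nu
    for k in range(1, k_max + 1):
        pmf[k] = np.dot(j_nu[:k], pmf[k - 1 :: -1][:k]) / k
    return pmf


def mixture_pmf(
    species: Sequence[PCHSpecies],
    background_rate: float = 0.0,
    bin_time: float = 1e-5,
    beam: BeamProfile = DEFAULT_BEAM,
    dimensionality: int = 2,
    ref_volume: float | None = None,
    tail_tol: float = 1e-12,
) -> np.ndarray:
    """Open-volume count distribution of a brightness mixture plus Poisson background.

    Each species contributes a Poisson-number superposition of
    single-particle distributions; the exact result is computed by the
    Panjer recursion and extended until the truncated tail mass is
    below ``tail_tol``.
    """
    if len(species) < 1:
        raise ValueError("at least one species is required")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    v_psf = beam.psf_integral(dimensionality)
    if ref_volume is None:
        ref_volume = 100.0 * v_psf
    x_max = max(sp.epsilon * bin_time for sp in species)
    k_max = _auto_kmax(x_max)
    while True:
        nu = np.zeros(k_max)
        for sp in species:
            conc = sp.mean_number / ref_volume
            nu += conc * _emission_integrals(
                sp.epsilon * bin_time, beam, dimensionality, k_max
            )
        nu[0] += background_rate * bin_time
        pmf = _panjer(nu)
        tail = 1.0 - pmf.sum()
        if tail <= tail_tol or k_max >= _MAX_K:
            break
        k_max *= 2
    if tail > tail_tol:
        raise RuntimeError(
            f"pmf truncation failed: tail mass {tail:.3g} above {tail_tol:g} at "
            f"k_max = {k_max}"
        )
    return pmf


def brightness_fractions(fit) -> np.ndarray:
    """Fractions weighed by brightness, F_i = N_i eps_i / sum_j N_j eps_j.

    F_i quantifies each population's contribution to the total
    fluorescence.  Accepts a :class:`PCHResults` or a sequence of
    :class:`PCHSpecies`.
    """
    species = fit.species if hasattr(fit, "species") else list(fit)
    products = np.array([sp.mean_number * sp.epsilon for sp in species])
    total = products.sum()
    if total <= 0:
        raise ValueError("all brightness-number products are zero")
    return products / total


class PCHModel:
    """Chi-square fit of a one- or two-brightness-population PCH model.

    Expected frequencies are ``total_bins * pmf``; per-bin variance is
    approximated as max(expected, 1) and tail bins with expected count
    below 5 are pooled.  Two-population fits constrain
    ``eps2 >= 1.2 * eps1`` to prevent label swapping.
    """

    def __init__(
        self,
        hist: PCHistogram,
        n_species: int = 1,
        beam: BeamProfile = DEFAULT_BEAM,
        dimensionality: int = 2,
        background_rate: float = 0.0,
        ref_volume: float | None = None,
    ) -> None:
        if n_species not in (1, 2):
            raise ValueError(f"n_species must be 1 or 2, got {n_species}")
        if hist.total_bins < 1:
            raise ValueError("histogram is empty")
        self.hist = hist
        self.n_species = n_species
        self.beam = beam
        self.dimensionality = dimensionality
        self.background_rate = background_rate
        self.ref_volume = (
            ref_volume
            if ref_volume is not None
            else 100.0 * beam.psf_integral(dimensionality)
        )

    # -- moment-based starting values ------------------------------------
    def _moment_init(self) -> tuple[float, float]:
        h = self.hist
        k = h.counts_axis.astype(float)
        p = h.frequency / h.total_bins
        mean = float((k * p).sum()) - self.background_rate * h.bin_time
        var = float(((k - (k * p).sum()) ** 2 * p).sum())
        mean = max(mean, 1e-12)
        gamma = self.beam.contrast_gamma(self.dimensionality)
        q = max((var - mean), 1e-3 * mean) / mean
        x = q / gamma  # per-bin brightness of an equivalent single species
        n_psf = mean / x
        return x, n_psf

    def _species_from_params(self, params: lmfit.Parameters) -> list[PCHSpecies]:
        v_psf = self.beam.psf_integral(self.dimensionality)
        scale = self.ref_volume / v_psf
        out = [
            PCHSpecies(
                epsilon=params["x1"].value / self.hist.bin_time,
                mean_number=params["n1"].value * scale,
            )
        ]
        if self.n_species == 2:
            out.append(
                PCHSpecies(
                    epsilon=params["x1"].value * params["ratio"].value / self.hist.bin_time,
                    mean_number=params["n2"].value * scale,
                )
            )
        return out

    def _expected(self, params: lmfit.Parameters, k_size: int) -> np.ndarray:
        pmf = mixture_pmf(
            self._species_from_params(params),
            background_rate=self.background_rate,
            bin_time=self.hist.bin_time,
            beam=self.beam,
            dimensionality=self.dimensionality,
            ref_volume=self.ref_volume,
        )
        if pmf.size < k_size:
            pmf = np.pad(pmf, (0, k_size - pmf.size))
        return pmf[:k_size] * self.hist.total_bins

    def fit(
        self, init: dict | None = None, fix: dict | None = None
    ) -> "PCHResults":
        """Fit the model; ``fix`` holds parameter values to clamp (e.g. a
        calibrated monomer per-bin brightness ``x1``)."""
        h = self.hist
        obs_full = h.frequency.astype(float)
        x0, n0 = self._moment_init()
        params = lmfit.Parameters()
        if self.n_species == 1:
            params.add("x1", value=x0, min=1e-9, max=100.0)
            params.add("n1", value=n0, min=1e-9, max=1e6)
        else:
            params.add("x1", value=x0 / 1.5, min=1e-9, max=100.0)
            params.add("ratio", value=2.5, min=1.2, max=100.0)
            params.add("n1", value=0.8 * n0, min=1e-9, max=1e6)
            params.add("n2", value=0.1 * n0, min=1e-12, max=1e6)
        if init:
            for key, val in init.items():
                if key in params:
                    params[key].set(value=val)
        if fix:
            for key, val in fix.items():
                if key in params:
                    params[key].set(value=val, vary=False)

        # pool the tail where the initial model expects < 5 bins
        exp0 = self._expected(params, obs_full.size)
        pool_at = obs_full.size
        for k in range(obs_full.size):
            if exp0[k:].sum() < 5.0:
                pool_at = max(k, 2)
                break

        def residual(p: lmfit.Parameters) -> np.ndarray:
            exp = self._expected(p, obs_full.size)
            exp_pool = np.concatenate([exp[:pool_at], [exp[pool_at:].sum()]])
            obs_pool = np.concatenate([obs_full[:pool_at], [obs_full[pool_at:].sum()]])
            return (obs_pool - exp_pool) / np.sqrt(np.maximum(exp_pool, 1.0))

        out = lmfit.minimize(residual, params, method="leastsq")
        at_bounds = []
        for name in out.params:
            par = out.params[name]
            if not par.vary:
                continue
            span = par.max - par.min
            if not np.isfinite(span):
                span = 1.0
            if (par.value - par.min) < 1e-8 * span or (par.max - par.value) < 1e-8 * span:
                at_bounds.append(name)
        return PCHResults(model=self, minimizer_result=out, at_bounds=at_bounds,
                          pooled_from=pool_at)


class PCHResults:
    """Fitted brightness populations with uncertainties and goodness of fit."""

    def __init__(self, model, minimizer_result, at_bounds, pooled_from):
        self.model = model
        self.minimizer_result = minimizer_result
        self.at_bounds = at_bounds
        self.pooled_from = pooled_from
        self.success = bool(minimizer_result.success)
        self.message = str(minimizer_result.message)
        self.covar = getattr(minimizer_result, "covar", None)
        self.redchi = float(minimizer_result.redchi)
        species = model._species_from_params(minimizer_result.params)
        order = np.argsort([sp.epsilon for sp in species])
        self.species = [species[i] for i in order]
        p = minimizer_result.params
        self._raw_params = {k: p[k].value for k in p}
        self.stderr = {k: p[k].stderr for k in p}

    @property
    def flagged(self) -> bool:
        return (not self.success) or bool(self.at_bounds)

    @property
    def background_rate(self) -> float:
        return self.model.background_rate

    @property
    def epsilon_cpsm(self) -> np.ndarray:
        """Molecular brightness per species, counts/s/molecule, ascending."""
        return np.array([sp.epsilon for sp in self.species])

    @property
    def epsilon_per_bin(self) -> np.ndarray:
        return self.epsilon_cpsm * self.model.hist.bin_time

    @property
    def mean_numbers(self) -> np.ndarray:
        """Mean molecule number per species in the reference volume."""
        return np.array([sp.mean_number for sp in self.species])

    @property
    def occupancy_psf(self) -> np.ndarray:
        """Mean molecule number per species in the PSF-integral volume."""
        v_psf = self.model.beam.psf_integral(self.model.dimensionality)
        return self.mean_numbers * v_psf / self.model.ref_volume

    @property
    def fractions_by_brightness(self) -> np.ndarray:
        return brightness_fractions(self)

    def predict(self) -> np.ndarray:
        """Expected frequency per count value on the histogram's axis."""
        return self.model._expected(
            self.minimizer_result.params, self.model.hist.frequency.size
        )

    def summary(self) -> str:
        h = self.model.hist
        lines = [
            f"PCH fit: {self.model.n_species} population(s), "
            f"{h.total_bins} bins of {h.bin_time:g} s, "
            f"reduced chi^2 = {self.redchi:.4g}",
            f"  converged: {self.success}"
            + (f"  [at bounds: {', '.join(self.at_bounds)}]" if self.at_bounds else ""),
        ]
        fr = self.fractions_by_brightness
        for i, sp in enumerate(self.species, start=1):
            lines.append(
                f"  population {i}: eps = {sp.epsilon * h.bin_time:.4g} counts/bin "
                f"({sp.epsilon:.4g} CPSM), N_ref = {sp.mean_number:.4g}, "
                f"F_{i} = {100 * fr[i - 1]:.1f}%"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.model.hist
        ax.semilogy(h.counts_axis, h.frequency, "o", ms=4, label="data")
        ax.semilogy(h.counts_axis, self.predict(), "-", label="fit")
        ax.set_xlabel("counts per bin")
        ax.set_ylabel("frequency")
        ax.legend()
        return ax


def fit_pch(
    hist: PCHistogram,
    n_species: int,
    beam: BeamProfile = DEFAULT_BEAM,
    dimensionality: int = 2,
    init: dict | None = None,
    background_rate: float = 0.0,
) -> PCHResults:
    """Fit a one- or two-brightness-population model (functional front end)."""
    return PCHModel(
        hist, n_species, beam, dimensionality, background_rate=background_rate
    ).fit(init=init)
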