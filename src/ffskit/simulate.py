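"""Synthetic photon traces and photobleaching ensembles.

Point emitters perform Brownian motion through a Gaussian observation
volume, either freely in 3D (solution species, D ~ 70 um^2/s) or
confined to the ``z = 0`` plane (membrane-bound species, D ~ 4-8
um^2/s).  Per micro-step the detected intensity is the sum of each
particle's molecular brightness ``epsilon`` (counts/s/molecule at beam
center) weighted by the profile value at its position; binned counts
are Poisson draws around the integrated intensity plus a uniform
background.  Photobleaching ensembles draw the number of surviving
fluorophores per oligomer from a binomial distribution.

Brightness convention: ``epsilon`` is counts per second per molecule at
beam center (CPSM) throughout the package.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np

from .beam import BeamProfile, DEFAULT_BEAM

__all__ = [
    "SpeciesParams",
    "SimConfig",
    "PhotonTrace",
    "BleachEnsemble",
    "simulate_trace",
    "simulate_bleach_ensemble",
    "trace_moments",
    "expected_count_rate",
]


@dataclass(frozen=True)
class SpeciesParams:
    """One diffusing species: label, D (um^2/s), epsilon (CPSM), mean number in the box."""

    label: str
    D: float
    epsilon: float
    mean_number: float

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"diffusion coefficient must be >= 0, got {self.D}")
        if self.epsilon < 0:
            raise ValueError(f"brightness must be >= 0, got {self.epsilon}")
        if self.mean_number < 0:
            raise ValueError(f"mean_number must be >= 0, got {self.mean_number}")


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings for one simulated photon trace.

    ``box_extent`` holds half-widths per axis in um; ``None`` selects
    6*w0 laterally and (in 3D) 6*z0 axially.  ``substeps=None`` picks
    the smallest number of micro-steps keeping the RMS displacement per
    micro-step below w0/5.
    """

    species: tuple[SpeciesParams, ...]
    beam: BeamProfile = DEFAULT_BEAM
    dimensionality: int = 3
    box_extent: tuple[float, ...] | None = None
    duration: float = 1.0
    bin_time: float = 1e-5
    substeps: int | None = None
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.dimensionality not in (2, 3):
            raise ValueError(
                f"dimensionality must be 2 or 3, got {self.dimensionality}"
            )
        if not (self.duration > 0):
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not (self.bin_time > 0):
            raise ValueError(f"bin_time must be positive, got {self.bin_time}")
        if self.substeps is not None and self.substeps < 1:
            raise ValueError(f"substeps must be >= 1, got {self.substeps}")
        if self.background_rate < 0:
            raise ValueError(
                f"background_rate must be >= 0, got {self.background_rate}"
            )
        ext = self.resolved_box_extent()
        lat_min = 4.0 * self.beam.w0
        if ext[0] < lat_min or ext[1] < lat_min:
            raise ValueError(
                f"box_extent lateral half-widths {ext[:2]} are below the "
                f"minimum 4*w0 = {lat_min:g} um"
            )
        if self.dimensionality == 3 and ext[2] < 4.0 * self.beam.z0:
            raise ValueError(
                f"box_extent axial half-width {ext[2]} is below the minimum "
                f"4*z0 = {4.0 * self.beam.z0:g} um"
            )

    def resolved_box_extent(self) -> tuple[float, ...]:
        if self.box_extent is not None:
            ext = tuple(float(v) for v in self.box_extent)
            want = 2 if self.dimensionality == 2 else 3
            if len(ext) != want:
                raise ValueError(
                    f"box_extent must have {want} entries for "
                    f"{self.dimensionality}D, got {len(ext)}"
                )
            return ext
        lat = 6.0 * self.beam.w0
        if self.dimensionality == 2:
            return (lat, lat)
        return (lat, lat, 6.0 * self.beam.z0)

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))

    def resolved_substeps(self) -> int:
        if self.substeps is not None:
            return self.substeps
        d_max = max((s.D for s in self.species), default=0.0)
        if d_max == 0.0:
            return 1
        # RMS micro-step 2*D*dt <= (w0/5)^2
        return max(1, math.ceil(50.0 * d_max * self.bin_time / self.beam.w0**2))

    def box_measure(self) -> float:
        """Box area (2D, um^2) or volume (3D, um^3)."""
        ext = self.resolved_box_extent()
        out = 1.0
        for e in ext:
            out *= 2.0 * e
        return out

    def config_hash(self) -> str:
        payload = {
            "species": [
                (s.label, s.D, s.epsilon, s.mean_number) for s in self.species
            ],
            "beam": (self.beam.w0, self.beam.z0),
            "dimensionality": self.dimensionality,
            "box_extent": self.resolved_box_extent(),
            "duration": self.duration,
            "bin_time": self.bin_time,
            "substeps": self.resolved_substeps(),
            "background_rate": self.background_rate,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class PhotonTrace:
    """Binned detector counts with the sampling bin width and provenance metadata."""

    counts: np.ndarray
    bin_time: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not (self.bin_time > 0):
            raise ValueError(f"bin_time must be positive, got {self.bin_time}")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_time

    @property
    def mean_rate(self) -> float:
        return trace_moments(self)[0]


@dataclass
class BleachEnsemble:
    """Counts of oligomers with m = 0..n surviving fluorophores after photobleaching."""

    n: int
    q: float
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.size != self.n + 1:
            raise ValueError("states must have length n + 1")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"survival probability q must be in [0, 1], got {self.q}")

    @property
    def size(self) -> int:
        return int(self.states.sum())

    @property
    def mean_intact(self) -> float:
        m = np.arange(self.n + 1)
        return float((m * self.states).sum() / self.states.sum())


# ---------------------------------------------------------------------------
# Brownian-dynamics photon kernels.  Gaussian micro-steps are drawn outside
# (numpy SFC64, float32) and scaled per particle inside; the kernels only do
# the walk, periodic wrap and intensity accumulation.  Contributions with
# log-weight below -30 (B < 1e-13) are skipped.


@numba.njit(cache=True, fastmath=True)
def _accumulate_3d(pos, steps, sig, eps_dt, inv_w2, inv_z2, lx, ly, lz, substeps, out):
    nb = out.shape[0]
    m = pos.shape[0]
    k = 0
    for i in range(nb):
        acc = 0.0
        for _ in range(substeps):
            for p in range(m):
                x = pos[p, 0] + sig[p] * steps[k, p, 0]
                y = pos[p, 1] + sig[p] * steps[k, p, 1]
                z = pos[p, 2] + sig[p] * steps[k, p, 2]
                if x > lx:
                    x -= 2.0 * lx
                elif x < -lx:
                    x += 2.0 * lx
                if y > ly:
                    y -= 2.0 * ly
                elif y < -ly:
                    y += 2.0 * ly
                if z > lz:
                    z -= 2.0 * lz
                elif z < -lz:
                    z += 2.0 * lz
                pos[p, 0] = x
                pos[p, 1] = y
                pos[p, 2] = z
                e = -2.0 * (x * x + y * y) * inv_w2 - 2.0 * z * z * inv_z2
                if e > -30.0:
                    acc += eps_dt[p] * math.exp(e)
            k += 1
        out[i] = acc


@numba.njit(cache=True, fastmath=True)
def _accumulate_2d(pos, steps, sig, eps_dt, inv_w2, lx, ly, substeps, out):
    nb = out.shape[0]
    m = pos.shape[0]
    k = 0
    for i in range(nb):
        acc = 0.0
        for _ in range(substeps):
            for p in range(m):
                x = pos[p, 0] + sig[p] * steps[k, p, 0]
                y = pos[p, 1] + sig[p] * steps[k, p, 1]
                if x > lx:
                    x -= 2.0 * lx
                elif x < -lx:
                    x += 2.0 * lx
                if y > ly:
                    y -= 2.0 * ly
                elif y < -ly:
                    y += 2.0 * ly
                pos[p, 0] = x
                pos[p, 1] = y
                e = -2.0 * (x * x + y * y) * inv_w2
                if e > -30.0:
                    acc += eps_dt[p] * math.exp(e)
            k += 1
        out[i] = acc


def simulate_trace(config: SimConfig) -> PhotonTrace:
    """Simulate one binned photon trace for the given acquisition settings.

    The number of particles per species is a Poisson draw around
    ``mean_number`` (open-system statistics); initial positions are
    uniform in the periodic box.  Identical configs (including the
    seed) give bit-identical traces.
    """
    dim = config.dimensionality
    ext = np.asarray(config.resolved_box_extent())
    substeps = config.resolved_substeps()
    dt_micro = config.bin_time / substeps
    n_bins = config.n_bins
    if n_bins < 1:
        raise ValueError("duration must cover at least one bin")

    rng = np.random.Generator(np.random.SFC64(config.seed))

    sig_list: list[np.ndarray] = []
    eps_list: list[np.ndarray] = []
    pos_list: list[np.ndarray] = []
    for sp in config.species:
        m_part = int(rng.poisson(sp.mean_number))
        if m_part == 0:
            continue
        pos_list.append(rng.uniform(-ext, ext, size=(m_part, dim)))
        sig_list.append(np.full(m_part, math.sqrt(2.0 * sp.D * dt_micro)))
        eps_list.append(np.full(m_part, sp.epsilon * dt_micro))

    bg_counts = config.background_rate * config.bin_time
    counts = np.empty(n_bins, dtype=np.int64)

    if not pos_list:
        counts[:] = rng.poisson(bg_counts, size=n_bins)
        return _finish_trace(counts, config)

    pos = np.ascontiguousarray(np.concatenate(pos_list))
    sig = np.concatenate(sig_list)
    eps_dt = np.concatenate(eps_list)
    m_total = pos.shape[0]
    inv_w2 = 1.0 / config.beam.w0**2
    inv_z2 = 1.0 / config.beam.z0**2

    # chunk the trace so the pre-drawn step array stays ~10^7 floats
    chunk_bins = max(1, int(1e7 // max(1, substeps * m_total * dim)))
    done = 0
    while done < n_bins:
        nb = min(chunk_bins, n_bins - done)
        steps = rng.standard_normal((nb * substeps, m_total, dim), dtype=np.float32)
        inten = np.empty(nb)
        if dim == 3:
            _accumulate_3d(
                pos, steps, sig, eps_dt, inv_w2, inv_z2,
                ext[0], ext[1], ext[2], substeps, inten,
            )
        else:
            _accumulate_2d(
                pos, steps, sig, eps_dt, inv_w2, ext[0], ext[1], substeps, inten,
            )
        counts[done : done + nb] = rng.poisson(inten + bg_counts)
        done += nb

    return _finish_trace(counts, config)


def _finish_trace(counts: np.ndarray, config: SimConfig) -> PhotonTrace:
    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "dimensionality": config.dimensionality,
        "duration_s": config.duration,
        "w0_um": config.beam.w0,
        "z0_um": config.beam.z0,
        "background_rate": config.background_rate,
    }
    return PhotonTrace(counts=counts, bin_time=config.bin_time, metadata=meta)


def expected_count_rate(config: SimConfig) -> float:
    """Analytic mean count rate: sum_i N_i * eps_i * (int B / box measure) + background."""
    frac = config.beam.psf_integral(config.dimensionality) / config.box_measure()
    rate = sum(sp.mean_number * sp.epsilon * frac for sp in config.species)
    return rate + config.background_rate


def rebin_trace(trace: PhotonTrace, factor: int) -> PhotonTrace:
    """Merge ``factor`` consecutive bins (counts summed, bin time multiplied)."""
    if factor < 1:
        raise ValueError(f"rebin factor must be >= 1, got {factor}")
    if factor == 1:
        return trace
    n = (trace.n_bins // factor) * factor
    if n == 0:
        raise ValueError("trace too short for the requested rebin factor")
    counts = trace.counts[:n].reshape(-1, factor).sum(axis=1)
    meta = dict(trace.metadata)
    meta["rebinned_by"] = factor * meta.get("rebinned_by", 1)
    return PhotonTrace(counts=counts, bin_time=trace.bin_time * factor, metadata=meta)


def trace_moments(trace: PhotonTrace) -> tuple[float, float]:
    """Mean count rate (counts/s) and per-bin count variance of a trace."""
    if trace.n_bins == 0:
        raise ValueError("cannot compute moments of an empty trace")
    mean_counts = float(trace.counts.mean())
    var = float(trace.counts.var())
    return mean_counts / trace.bin_time, var


def simulate_bleach_ensemble(
    n: int, b: float, size: int, seed: int = 0
) -> BleachEnsemble:
    """Draw an ensemble of n-mers whose surviving-fluorophore counts are Binomial(n, 1-b)."""
    if n < 1:
        raise ValueError(f"oligomer size n must be >= 1, got {n}")
    if not (0.0 <= b <= 1.0):
        raise ValueError(f"bleached fraction b must be in [0, 1], got {b}")
    if size < 1:
        raise ValueError(f"ensemble size must be >= 1, got {size}")
    rng = np.random.default_rng(seed)
    m = rng.binomial(n, 1.0 - b, size=size)
    states = np.bincount(m, minlength=n + 1)
    return BleachEnsemble(n=n, q=1.0 - b, states=states)
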