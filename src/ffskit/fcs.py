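"""Fluorescence correlation spectroscopy: correlators and diffusion fits.

The normalized intensity autocorrelation

    G(tau) = <dF(t) dF(t+tau)> / <F>^2

of a photon trace decays on the residence-time scale of the diffusing
species.  For a Gaussian observation volume the single-component decays
are

    3D:  G(tau) = G_inf + (1/N) (1 + tau/tau_D)^-1 (1 + tau/(S^2 tau_D))^-1/2
    2D:  G(tau) = G_inf + (1/N) (1 + tau/tau_D)^-1

with mean occupancy ``N``, residence time ``tau_D`` and structure
parameter ``S``.  Two-component variants are amplitude-fraction
weighted sums sharing one baseline ``G_inf``.  The residence time maps
to a diffusion coefficient through ``D = w0^2 / (4 tau_D)``.

No triplet-state term is included; the fitted ``N`` is the amplitude
parameter of the model (``G(0) - G_inf = 1/N``).  For oracle checks
against a simulation, the expected zero-lag amplitude of a single
species is ``gamma / N_eff`` with ``N_eff`` the mean molecule number in
the PSF-integral volume and ``gamma`` the profile contrast factor
(2^-3/2 in 3D, 1/2 in 2D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy import stats

from .beam import BeamProfile, DEFAULT_BEAM
from .simulate import PhotonTrace

__all__ = [
    "CorrelationCurve",
    "FCSResults",
    "FCSDiffusionModel",
    "ModelComparison",
    "autocorrelate_direct",
    "autocorrelate_multitau",
    "average_curves",
    "model_acf",
    "fit_acf",
    "taud_to_D",
    "select_model",
]

_MODEL_IDS = ("3d1c", "3d2c", "2d1c", "2d2c")


def _normalize_model_id(model_id: str) -> str:
    mid = model_id.lower().replace("-", "").replace("_", "")
    if mid not in _MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {_MODEL_IDS}")
    return mid


@dataclass
class CorrelationCurve:
    """Lag times (s), normalized autocorrelation amplitudes and optional per-lag SEM."""

    lags: np.ndarray
    G: np.ndarray
    sem: np.ndarray | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.G.shape:
            raise ValueError("lags and G must be 1-d arrays of equal length")
        if self.lags.size and (self.lags[0] <= 0 or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.lags.shape:
                raise ValueError("sem must match lags in length")
            if np.any(self.sem < 0):
                raise ValueError("sem must be non-negative")


def autocorrelate_direct(
    trace: PhotonTrace, lags: Sequence[float]
) -> CorrelationCurve:
    """Exact normalized autocorrelation at the requested lag times.

    Lags must be integer multiples of the bin time and below half the
    trace duration (so every lag retains a meaningful number of pairs).
    Fluctuations are taken around the full-trace mean and normalized by
    its square.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("at least one lag is required")
    kf = lags / trace.bin_time
    k = np.rint(kf).astype(int)
    if np.any(np.abs(kf - k) > 1e-6) or np.any(k < 1):
        raise ValueError("lags must be positive integer multiples of the bin time")
    if lags.max() >= trace.duration / 2.0:
        raise ValueError(
            f"max lag {lags.max():g} s must be below duration/2 = "
            f"{trace.duration / 2.0:g} s"
        )
    c = trace.counts.astype(float)
    mu = c.mean()
    if mu == 0:
        raise ValueError("trace has zero mean count; autocorrelation undefined")
    d = c - mu
    g = np.empty(k.size)
    for i, ki in enumerate(k):
        g[i] = np.mean(d[:-ki] * d[ki:]) / mu**2
    return CorrelationCurve(
        lags=k * trace.bin_time,
        G=g,
        source={"estimator": "direct", "bin_time_s": trace.bin_time,
                "duration_s": trace.duration, **trace.metadata},
    )


def _multitau_lag_bins(m: int, levels: int) -> list[list[int]]:
    out = [list(range(1, m + 1))]
    for _ in range(1, levels):
        out.append(list(range(m // 2 + 1, m + 1)))
    return out


def autocorrelate_multitau(
    trace: PhotonTrace, m: int = 16, levels: int | None = None
) -> CorrelationCurve:
    """Multi-tau autocorrelation with log-spaced lags.

    Level 0 evaluates lags 1..m in native bins; each further level
    rebins the trace by 2 and evaluates lags m/2+1..m in rebinned bins,
    so ``levels`` levels give ``m + (levels-1) * m/2`` points with
    maximum lag ``m * 2^(levels-1)`` native bins.  Each point uses the
    symmetric normalization G = <F_t F_{t+k}> / (<F_t> <F_{t+k}>) - 1
    with means over the direct and delayed monitors.
    """
    if m < 8 or m % 2:
        raise ValueError(f"m must be even and >= 8, got {m}")
    if levels is None:
        levels = 1
        while (
            m * 2**levels * trace.bin_time < trace.duration / 10.0
            and trace.n_bins // 2**levels >= 4 * m
        ):
            levels += 1
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if trace.n_bins < 2 * m:
        raise ValueError(
            f"trace of {trace.n_bins} bins is too short for the first level (m={m})"
        )
    x = trace.counts.astype(float)
    if x.mean() == 0:
        raise ValueError("trace has zero mean count; autocorrelation undefined")
    dt = trace.bin_time
    all_lags: list[float] = []
    all_g: list[float] = []
    for level, lag_bins in enumerate(_multitau_lag_bins(m, levels)):
        n = x.size
        for k in lag_bins:
            if k >= n:
                break
            a = x[: n - k]
            b = x[k:]
            ma = a.mean()
            mb = b.mean()
            if ma == 0 or mb == 0:
                continue
            all_lags.append(k * dt)
            all_g.append(float(np.mean(a * b) / (ma * mb) - 1.0))
        # rebin by 2 for the next level
        if level < levels - 1:
            n2 = (x.size // 2) * 2
            x = x[:n2].reshape(-1, 2).sum(axis=1)
            dt *= 2.0
    return CorrelationCurve(
        lags=np.array(all_lags),
        G=np.array(all_g),
        source={"estimator": "multitau", "m": m, "levels": levels,
                "bin_time_s": trace.bin_time, "duration_s": trace.duration,
                **trace.metadata},
    )


def restrict_lags(
    curve: CorrelationCurve, max_lag: float, min_lag: float = 0.0
) -> CorrelationCurve:
    """Restrict a curve to a fit window around the expected residence time.

    Fitting a finite-box simulation (or a drifting measurement) far into
    the tail is unreliable; the usual practice is to keep a window of a
    few tens of residence times.
    """
    mask = (curve.lags <= max_lag) & (curve.lags >= min_lag)
    if not mask.any():
        raise ValueError("no lags left inside the requested window")
    return CorrelationCurve(
        lags=curve.lags[mask],
        G=curve.G[mask],
        sem=None if curve.sem is None else curve.sem[mask],
        source=dict(curve.source),
    )


def average_curves(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Average replicate curves on a common lag grid; SEM across replicates per lag."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise ValueError("curves must share the same lag grid")
    gmat = np.vstack([c.G for c in curves])
    sem = (
        gmat.std(axis=0, ddof=1) / np.sqrt(len(curves))
        if len(curves) > 1
        else None
    )
    return CorrelationCurve(
        lags=lags, G=gmat.mean(axis=0), sem=sem,
        source={"averaged": len(curves), **curves[0].source},
    )


def _decay(tau: np.ndarray, tau_d: float, S: float | None) -> np.ndarray:
    g = 1.0 / (1.0 + tau / tau_d)
    if S is not None:
        g = g / np.sqrt(1.0 + tau / (S**2 * tau_d))
    return g


def model_acf(model_id: str, params: dict, lags) -> np.ndarray:
    """Evaluate a diffusion ACF model on the given lags.

    ``params`` keys: ``N``, ``g_inf`` and either ``tau_d`` (1-component)
    or ``tau_d1``, ``tau_d2``, ``frac1`` (2-component); 3D models also
    need ``S``.
    """
    mid = _normalize_model_id(model_id)
    tau = np.asarray(lags, dtype=float)
    n = params["N"]
    g_inf = params.get("g_inf", 0.0)
    s = params["S"] if mid.startswith("3d") else None
    if n <= 0:
        raise ValueError(f"N must be positive, got {n}")
    if s is not None and s <= 0:
        raise ValueError(f"S must be positive, got {s}")
    if mid.endswith("1c"):
        tau_d = params["tau_d"]
        if tau_d <= 0:
            raise ValueError(f"tau_d must be positive, got {tau_d}")
        return g_inf + _decay(tau, tau_d, s) / n
    tau_d1, tau_d2 = params["tau_d1"], params["tau_d2"]
    if tau_d1 <= 0 or tau_d2 <= 0:
        raise ValueError("component residence times must be positive")
    f1 = params["frac1"]
    if not (0.0 <= f1 <= 1.0):
        raise ValueError(f"frac1 must be in [0, 1], got {f1}")
    mix = f1 * _decay(tau, tau_d1, s) + (1.0 - f1) * _decay(tau, tau_d2, s)
    return g_inf + mix / n


def taud_to_D(tau_d: float, w0: float) -> float:
    """Convert a residence time to a diffusion coefficient: D = w0^2 / (4 tau_D)."""
    if np.any(np.asarray(tau_d) <= 0):
        raise ValueError(f"tau_d must be positive, got {tau_d}")
    if w0 <= 0:
        raise ValueError(f"w0 must be positive, got {w0}")
    return w0**2 / (4.0 * np.asarray(tau_d))


class FCSDiffusionModel:
    """Weighted least-squares fit of a diffusion ACF model to a correlation curve.

    Follows the model/results split: construct with the data and model
    choice, call :meth:`fit` to obtain an :class:`FCSResults`.  Weights
    are 1/sem^2 where the curve carries SEMs, else unweighted.  The
    structure parameter S is fixed at the beam value.
    """

    def __init__(
        self,
        curve: CorrelationCurve,
        model_id: str = "3d1c",
        beam: BeamProfile = DEFAULT_BEAM,
    ) -> None:
        self.curve = curve
        self.model_id = _normalize_model_id(model_id)
        self.beam = beam
        lags = curve.lags
        if lags.size < 20:
            raise ValueError(
                f"need >= 20 lag points for a stable fit, got {lags.size}"
            )
        if lags[-1] / lags[0] < 100.0:
            raise ValueError("lag range must span at least two decades")

    def _make_params(self, init: dict | None) -> lmfit.Parameters:
        curve = self.curve
        amp = max(curve.G[0], 1e-6)
        n0 = 1.0 / amp
        # half-decay lag as tau_D starting point
        half = amp / 2.0
        idx = int(np.argmin(np.abs(curve.G - half)))
        tau0 = float(curve.lags[idx])
        bin_time = curve.source.get("bin_time_s", curve.lags[0])
        duration = curve.source.get("duration_s")
        tau_lo = 2.0 * bin_time
        tau_hi = duration / 10.0 if duration else float(curve.lags[-1])
        tau0 = min(max(tau0, 1.1 * tau_lo), 0.9 * tau_hi)
        p = lmfit.Parameters()
        p.add("N", value=n0, min=1e-12, max=1e6)
        p.add("g_inf", value=0.0, min=-1.0, max=1.0)
        if self.model_id.endswith("1c"):
            p.add("tau_d", value=tau0, min=tau_lo, max=tau_hi)
        else:
            p.add("tau_d1", value=tau0 / 3.0, min=tau_lo, max=tau_hi)
            p.add("tau_d2", value=min(tau0 * 3.0, 0.9 * tau_hi), min=tau_lo, max=tau_hi)
            p.add("frac1", value=0.5, min=0.0, max=1.0)
        if init:
            for key, val in init.items():
                if key in p:
                    p[key].set(value=val)
        return p

    def _eval(self, params: lmfit.Parameters) -> np.ndarray:
        d = {k: params[k].value for k in params}
        if self.model_id.startswith("3d"):
            d["S"] = self.beam.S
        return model_acf(self.model_id, d, self.curve.lags)

    def fit(self, init: dict | None = None) -> "FCSResults":
        curve = self.curve
        weights = None
        if curve.sem is not None and np.all(curve.sem > 0):
            weights = 1.0 / curve.sem

        def residual(params: lmfit.Parameters) -> np.ndarray:
            r = self._eval(params) - curve.G
            return r * weights if weights is not None else r

        params = self._make_params(init)
        out = lmfit.minimize(residual, params, method="leastsq")
        at_bounds = []
        for name in out.params:
            par = out.params[name]
            if not par.vary:
                continue
            span = (par.max - par.min) if np.isfinite(par.max - par.min) else 1.0
            if (par.value - par.min) < 1e-6 * span or (par.max - par.value) < 1e-6 * span:
                at_bounds.append(name)
        return FCSResults(model=self, minimizer_result=out, at_bounds=at_bounds)


class FCSResults:
    """Fitted parameters, uncertainties and diagnostics of an FCS diffusion fit."""

    def __init__(
        self,
        model: FCSDiffusionModel,
        minimizer_result: lmfit.minimizer.MinimizerResult,
        at_bounds: list[str],
    ) -> None:
        self.model = model
        self.minimizer_result = minimizer_result
        self.at_bounds = at_bounds
        self.success = bool(minimizer_result.success)
        self.message = str(minimizer_result.message)
        self.params = {k: minimizer_result.params[k].value for k in minimizer_result.params}
        self.stderr = {
            k: minimizer_result.params[k].stderr for k in minimizer_result.params
        }
        self.covar = getattr(minimizer_result, "covar", None)
        self.redchi = float(minimizer_result.redchi)
        resid = np.asarray(minimizer_result.residual)
        self.rss = float(np.sum((self.predict() - model.curve.G) ** 2))
        self.n_obs = resid.size
        self.n_free = int(minimizer_result.nvarys)

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def flagged(self) -> bool:
        """True when the fit failed to converge or pinned a parameter at a bound."""
        return (not self.success) or bool(self.at_bounds)

    @property
    def N(self) -> float:
        return self.params["N"]

    @property
    def g_inf(self) -> float:
        return self.params["g_inf"]

    @property
    def tau_d(self) -> np.ndarray:
        if self.model_id.endswith("1c"):
            return np.array([self.params["tau_d"]])
        return np.array([self.params["tau_d1"], self.params["tau_d2"]])

    @property
    def fractions(self) -> np.ndarray:
        if self.model_id.endswith("1c"):
            return np.array([1.0])
        f1 = self.params["frac1"]
        return np.array([f1, 1.0 - f1])

    @property
    def S(self) -> float | None:
        return self.model.beam.S if self.model_id.startswith("3d") else None

    @property
    def D(self) -> np.ndarray:
        """Diffusion coefficient(s) in um^2/s, one per component."""
        return taud_to_D(self.tau_d, self.model.beam.w0)

    def predict(self, lags=None) -> np.ndarray:
        d = dict(self.params)
        if self.model_id.startswith("3d"):
            d["S"] = self.model.beam.S
        return model_acf(self.model_id, d, self.model.curve.lags if lags is None else lags)

    def summary(self) -> str:
        lines = [
            f"FCS diffusion fit: model {self.model_id}, "
            f"{self.n_obs} lags, reduced chi^2 = {self.redchi:.4g}",
            f"  converged: {self.success}"
            + (f"  [at bounds: {', '.join(self.at_bounds)}]" if self.at_bounds else ""),
        ]
        for name, val in self.params.items():
            err = self.stderr.get(name)
            err_s = f" +/- {err:.4g}" if err is not None else ""
            lines.append(f"  {name:8s} = {val:.6g}{err_s}")
        for i, (td, d_um) in enumerate(zip(self.tau_d, self.D), start=1):
            lines.append(
                f"  component {i}: tau_D = {td:.4g} s -> D = {d_um:.4g} um^2/s"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look plot of data, fit and residuals on a log lag axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        if c.sem is not None:
            ax.errorbar(c.lags, c.G, yerr=c.sem, fmt=".", ms=3, label="data")
        else:
            ax.plot(c.lags, c.G, ".", ms=3, label="data")
        ax.plot(c.lags, self.predict(), "-", label=f"fit {self.model_id}")
        ax.set_xscale("log")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("G(tau)")
        ax.legend()
        return ax


def fit_acf(
    curve: CorrelationCurve,
    model_id: str,
    beam: BeamProfile = DEFAULT_BEAM,
    init: dict | None = None,
) -> FCSResults:
    """Fit a diffusion model to a correlation curve (functional front end)."""
    return FCSDiffusionModel(curve, model_id, beam).fit(init=init)


@dataclass
class ModelComparison:
    """Nested-model F-test outcome between one- and two-component fits."""

    choice: str
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


def select_model(fit_1c: FCSResults, fit_2c: FCSResults) -> ModelComparison:
    """Choose between nested 1- and 2-component fits by an F-test at alpha = 0.05.

    The two-component model is selected only when it improves the
    residual sum of squares significantly (p < 0.05 strictly; ties go
    to the parsimonious model).
    """
    c1, c2 = fit_1c.model.curve, fit_2c.model.curve
    if c1.lags.shape != c2.lags.shape or not (
        np.allclose(c1.lags, c2.lags) and np.allclose(c1.G, c2.G)
    ):
        raise ValueError("fits must be made on the same correlation curve")
    df_num = fit_2c.n_free - fit_1c.n_free
    df_den = fit_2c.n_obs - fit_2c.n_free
    if df_num <= 0 or df_den <= 0:
        raise ValueError("fits are not properly nested")
    rss1, rss2 = fit_1c.rss, fit_2c.rss
    if rss2 <= 0 or rss1 <= rss2 * (1 + 1e-12):
        f_stat = max(0.0, (rss1 - rss2) / df_num / max(rss2 / df_den, 1e-300))
    else:
        f_stat = ((rss1 - rss2) / df_num) / (rss2 / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den)) if f_stat > 0 else 1.0
    choice = "2c" if p < 0.05 else "1c"
    return ModelComparison(
        choice=choice, f_statistic=float(f_stat), p_value=p,
        df_num=df_num, df_den=df_den,
    )
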