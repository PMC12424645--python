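"""Simulation and fitting of 1:1 Langmuir binding kinetics.

The closed-form 1:1 (Langmuir) model for a biolayer-interferometry style
experiment with analyte concentration C:

* association (0 <= t <= t1):  R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
  with the steady-state response Req = Rmax * C / (C + KD),
* dissociation (t > t1):       R(t) = R(t1) * exp(-koff * (t - t1)),

where KD = koff / kon.  ``global_fit_1to1`` fits a single (kon, koff, Rmax)
triple across all traces of a concentration series by least squares;
``steady_state_kd`` fits the saturation curve Req(C) = Rmax * C / (KD + C).

No mass-transport limitation, drift or bulk-shift terms are modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.optimize import curve_fit

__all__ = [
    "KineticParams",
    "Sensorgram",
    "simulate_sensorgram",
    "GlobalFitResult",
    "global_fit_1to1",
    "steady_state_kd",
    "SteadyStateResult",
    "end_of_association_read",
    "UnidentifiableError",
]

#: Default phase durations in seconds (association / dissociation).
DEFAULT_T_ASSOC = 1200.0
DEFAULT_T_DISSOC = 1500.0


class UnidentifiableError(ValueError):
    """Raised when a steady-state series cannot constrain KD."""


@dataclass(frozen=True)
class KineticParams:
    """1:1 model parameters: kon (1/M/s), koff (1/s), Rmax (response units)."""

    kon: float
    koff: float
    rmax: float

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0 and self.rmax > 0):
            raise ValueError("kon, koff and Rmax must all be positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant KD = koff / kon (molar)."""
        return self.koff / self.kon

    def req(self, concentration: float) -> float:
        """Steady-state response at the given analyte concentration."""
        return self.rmax * concentration / (concentration + self.kd)


@dataclass
class Sensorgram:
    """Sampled (time, response) trace at one analyte concentration."""

    concentration: float
    time: np.ndarray
    response: np.ndarray
    t_assoc_end: float  # boundary between association and dissociation phases

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def phase(self) -> np.ndarray:
        return np.where(self.time <= self.t_assoc_end, "association", "dissociation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "response": self.response,
                "concentration": self.concentration,
                "phase": self.phase,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Sensorgram":
        assoc = df[df["phase"] == "association"]
        if assoc.empty:
            raise ValueError("sensorgram has no association phase")
        return cls(
            concentration=float(df["concentration"].iloc[0]),
            time=df["time"].to_numpy(float),
            response=df["response"].to_numpy(float),
            t_assoc_end=float(assoc["time"].max()),
        )


def model_response(
    p: KineticParams, concentration: float, time: np.ndarray, t_assoc_end: float
) -> np.ndarray:
    """Closed-form 1:1 response over both phases."""
    t = np.asarray(time, dtype=float)
    kobs = p.kon * concentration + p.koff
    req = p.req(concentration)
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc_end)))
    r1 = req * (1.0 - np.exp(-kobs * t_assoc_end))
    r_dissoc = r1 * np.exp(-p.koff * np.maximum(t - t_assoc_end, 0.0))
    return np.where(t <= t_assoc_end, r_assoc, r_dissoc)


def simulate_sensorgram(
    p: KineticParams,
    concentration: float,
    t_assoc: float = DEFAULT_T_ASSOC,
    t_dissoc: float = DEFAULT_T_DISSOC,
    dt: float = 2.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Sensorgram:
    """Simulate a two-phase sensorgram, optionally with Gaussian noise.

    With ``noise_sd=0`` the trace is the exact closed form; otherwise i.i.d.
    Gaussian noise with the given standard deviation (response units) is
    added, reproducibly from ``seed``.
    """
    if concentration <= 0:
        raise ValueError("analyte concentration must be positive")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValueError("phase durations must be positive")
    time = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    response = model_response(p, concentration, time, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    return Sensorgram(
        concentration=concentration, time=time, response=response, t_assoc_end=t_assoc
    )


@dataclass
class GlobalFitResult:
    """Result of a global 1:1 fit over a concentration series."""

    params: KineticParams
    residuals: dict[float, np.ndarray]  # per-concentration residual traces
    rss: float
    success: bool
    ill_conditioned: bool
    stderr: dict[str, Optional[float]]

    @property
    def kd(self) -> float:
        return self.params.kd

    def to_dict(self) -> dict:
        return {
            "kon": self.params.kon,
            "koff": self.params.koff,
            "rmax": self.params.rmax,
            "kd": self.kd,
            "rss": self.rss,
            "success": self.success,
            "ill_conditioned": self.ill_conditioned,
            "stderr": self.stderr,
            "per_trace_rss": {
                str(c): float(np.sum(r**2)) for c, r in self.residuals.items()
            },
        }


def _initial_guess(grams: Sequence[Sensorgram]) -> tuple[float, float, float]:
    """Deterministic starting point for the global fit.

    koff from a log-linear fit of the dissociation tail of the
    highest-concentration trace; the observed association rate of the same
    trace then gives kon via kobs = kon*C + koff.
    """
    top = max(grams, key=lambda g: g.concentration)
    assoc = top.time <= top.t_assoc_end
    t_a, r_a = top.time[assoc], top.response[assoc]
    t_d, r_d = top.time[~assoc], top.response[~assoc]
    req = float(r_a[-1]) if r_a.size else float(np.max(top.response))
    req = max(req, 1e-12)

    koff0 = 1e-3
    if t_d.size >= 3:
        r1 = r_d[0]
        keep = r_d > 0.05 * max(r1, 1e-12)
        if keep.sum() >= 3:
            slope = np.polyfit(t_d[keep], np.log(np.maximum(r_d[keep], 1e-300)), 1)[0]
            if slope < 0:
                koff0 = -slope
    kobs0 = None
    resid = req - r_a
    keep = resid > 0.05 * req
    if keep.sum() >= 3:
        slope = np.polyfit(t_a[keep], np.log(resid[keep]), 1)[0]
        if slope < 0:
            kobs0 = -slope
    if kobs0 is None or kobs0 <= koff0:
        kobs0 = koff0 * 10.0
    kon0 = max((kobs0 - koff0) / top.concentration, 1e-3)
    rmax0 = 1.5 * max(float(np.max(g.response)) for g in grams)
    return kon0, koff0, max(rmax0, 1e-9)


def global_fit_1to1(grams: Sequence[Sensorgram]) -> GlobalFitResult:
    """Globally fit one (kon, koff, Rmax) triple to a set of sensorgrams.

    All traces share the three parameters; residuals are reported per trace.
    Fewer than three distinct concentrations leave the problem poorly
    conditioned: a warning is emitted and the fit is still returned.
    """
    grams = list(grams)
    if not grams:
        raise ValueError("no sensorgrams to fit")
    concentrations = sorted({g.concentration for g in grams})
    ill = len(concentrations) < 3
    if ill:
        warnings.warn(
            "fewer than 3 distinct analyte concentrations: "
            "the 1:1 global fit is ill-conditioned and intervals will be wide"
        )

    kon0, koff0, rmax0 = _initial_guess(grams)
    params = Parameters()
    params.add("log_kon", value=np.log(kon0))
    params.add("log_koff", value=np.log(koff0))
    params.add("log_rmax", value=np.log(rmax0))

    def residual(pars):
        p = KineticParams(
            kon=float(np.exp(pars["log_kon"])),
            koff=float(np.exp(pars["log_koff"])),
            rmax=float(np.exp(pars["log_rmax"])),
        )
        res = [
            g.response - model_response(p, g.concentration, g.time, g.t_assoc_end)
            for g in grams
        ]
        return np.concatenate(res)

    out = minimize(residual, params, method="leastsq")
    fitted = KineticParams(
        kon=float(np.exp(out.params["log_kon"].value)),
        koff=float(np.exp(out.params["log_koff"].value)),
        rmax=float(np.exp(out.params["log_rmax"].value)),
    )
    residuals = {
        g.concentration: g.response
        - model_response(fitted, g.concentration, g.time, g.t_assoc_end)
        for g in grams
    }
    rss = float(sum(np.sum(r**2) for r in residuals.values()))

    def _scaled_err(name: str, value: float) -> Optional[float]:
        err = out.params[name].stderr
        return None if err is None else float(err) * value  # delta method for exp()

    return GlobalFitResult(
        params=fitted,
        residuals=residuals,
        rss=rss,
        success=bool(out.success),
        ill_conditioned=ill,
        stderr={
            "kon": _scaled_err("log_kon", fitted.kon),
            "koff": _scaled_err("log_koff", fitted.koff),
            "rmax": _scaled_err("log_rmax", fitted.rmax),
        },
    )


@dataclass(frozen=True)
class SteadyStateResult:
    kd: float
    rmax: float
    r_squared: float


def steady_state_kd(
    concentration: Sequence[float], req: Sequence[float]
) -> SteadyStateResult:
    """Fit the saturation curve Req(C) = Rmax * C / (KD + C).

    Needs at least four concentrations with real curvature; a flat series or
    one that never bends (KD far outside the sampled range) raises
    :class:`UnidentifiableError`.
    """
    c = np.asarray(concentration, dtype=float)
    r = np.asarray(req, dtype=float)
    if c.size != r.size:
        raise ValueError("concentration and Req must have equal length")
    if c.size < 4:
        raise ValueError("steady-state fit needs at least 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    scale = max(float(np.max(np.abs(r))), 1e-30)
    if np.ptp(r) <= 1e-9 * scale:
        raise UnidentifiableError("all Req equal: saturation curve is unidentifiable")

    def langmuir(cc, kd, rmax):
        return rmax * cc / (kd + cc)

    p0 = (float(np.median(c)), float(np.max(r)) * 1.2)
    popt, _ = curve_fit(langmuir, c, r, p0=p0, maxfev=20000)
    kd, rmax = float(popt[0]), float(popt[1])
    if not np.isfinite(kd) or kd <= 0:
        raise UnidentifiableError("steady-state fit did not yield a positive KD")
    if kd > 100.0 * c.max() or kd < c.min() / 100.0:
        raise UnidentifiableError(
            "fitted KD lies far outside the sampled concentration range "
            "(saturated-only or linear-only data)"
        )
    resid = r - langmuir(c, kd, rmax)
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return SteadyStateResult(kd=kd, rmax=rmax, r_squared=r2)


def end_of_association_read(gram: Sensorgram, window: float = 10.0) -> float:
    """Steady-state response read: mean response over the last ``window``
    seconds of the association phase."""
    mask = (gram.time <= gram.t_assoc_end) & (gram.time >= gram.t_assoc_end - window)
    if not mask.any():
        raise ValueError("no samples in the end-of-association window")
    return float(gram.response[mask].mean())
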