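"""Dynamic-response analysis: exponential colour-development kinetics.

Colour development in a detection zone follows a single-exponential
approach to a plateau,

    I(t) = I_inf + (I_0 − I_inf) · exp(−t/τ),

where τ (seconds) is the reaction time constant — smaller τ means a faster
reaction, which is how the G/Pt catalyst's acceleration is quantified.  The
same form covers rising and falling traces (hue can fall while saturation
rises); no sign restriction is placed on I_0 − I_inf.

statsmodels-style usage::

    fit = KineticModel(times, intensities).fit()
    fit.tau, fit.r_squared, fit.time_to_fraction(0.95)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FlatTraceError, InputDomainError

# re-exported measured τ table for the physical device
from .reference import TIME_CONSTANTS_S  # noqa: F401

#: relative parameter-change tolerance of the optimiser
FIT_XTOL = 1e-8


def _exp_model(t, i0, i_inf, tau):
    return i_inf + (i0 - i_inf) * np.exp(-t / tau)


@dataclass
class KineticTrace:
    """A time-stamped intensity series for one channel and condition."""

    times: np.ndarray          # seconds, strictly increasing, times[0] ≥ 0
    intensities: np.ndarray    # channel units
    channel: str = "S"
    condition: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise InputDomainError("times and intensities must be equal-length 1-D")
        if self.times.size < 5:
            raise InputDomainError("kinetic trace needs ≥ 5 samples")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise InputDomainError("times must be strictly increasing and start ≥ 0")

    @classmethod
    def from_csv(cls, path, **kw) -> "KineticTrace":
        """Read a `time_s,intensity` CSV (one channel per file)."""
        df = pd.read_csv(path)
        if not {"time_s", "intensity"}.issubset(df.columns):
            raise InputDomainError("trace CSV needs columns time_s,intensity")
        return cls(df["time_s"].to_numpy(), df["intensity"].to_numpy(), **kw)


def _noise_floor(intensities: np.ndarray) -> float:
    """Noise scale estimate from second differences (trend-insensitive).

    For an i.i.d. noise sequence the second difference has variance 6σ²;
    the smooth exponential trend contributes little to it at typical
    sampling rates.
    """
    if intensities.size < 3:
        return 0.0
    d2 = np.diff(intensities, n=2)
    return float(np.sqrt(np.mean(d2**2) / 6.0))


class KineticModel:
    """Single-exponential plateau model for one kinetic trace.

    Initialisation: I_0 from the first sample, I_inf from the mean of the
    last 10 % of samples, τ from the time the trace first crosses 63 % of
    its range (linear interpolation).  τ is bounded in (0, 100·t_max].
    """

    def __init__(self, times, intensities, channel: str = "S",
                 condition: str | None = None):
        self.trace = KineticTrace(times, intensities, channel, condition)

    @classmethod
    def from_trace(cls, trace: KineticTrace) -> "KineticModel":
        m = cls.__new__(cls)
        m.trace = trace
        return m

    # -- initial parameter guesses ------------------------------------
    def _initial_guess(self) -> tuple[float, float, float]:
        t, y = self.trace.times, self.trace.intensities
        i0 = float(y[0])
        tail = max(1, int(np.ceil(0.1 * y.size)))
        i_inf = float(y[-tail:].mean())
        target = i0 + 0.632 * (i_inf - i0)
        tau0 = None
        sign = np.sign(i_inf - i0) or 1.0
        crossed = sign * (y - target) >= 0
        idx = np.flatnonzero(crossed)
        if idx.size and idx[0] > 0:
            j = idx[0]
            frac = (target - y[j - 1]) / (y[j] - y[j - 1]) if y[j] != y[j - 1] else 0.5
            tau0 = t[j - 1] + frac * (t[j] - t[j - 1]) - t[0]
        if tau0 is None or tau0 <= 0:
            tau0 = max((t[-1] - t[0]) / 5.0, 1e-6)
        return i0, i_inf, float(tau0)

    def fit(self) -> "KineticResults":
        t, y = self.trace.times, self.trace.intensities
        rng_y = float(y.max() - y.min())
        sigma = _noise_floor(y)
        if rng_y <= max(3.0 * sigma, 1e-9 * max(1.0, float(np.abs(y).max()))):
            raise FlatTraceError(
                f"trace range {rng_y:.4g} is below 3× the noise estimate {sigma:.4g}; "
                "no resolvable colour development"
            )
        p0 = self._initial_guess()
        tau_max = 100.0 * float(t[-1] if t[-1] > 0 else 1.0)
        bounds = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, tau_max])
        p0 = (p0[0], p0[1], min(max(p0[2], 1e-9), tau_max))
        try:
            popt, pcov = curve_fit(
                _exp_model, t, y, p0=p0, bounds=bounds,
                xtol=FIT_XTOL, ftol=FIT_XTOL, maxfev=20000,
            )
            converged = bool(np.all(np.isfinite(popt)))
            message = "converged"
        except RuntimeError as exc:  # optimiser exhausted without converging
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((3, 3), np.nan)
            converged = False
            message = f"fit failed: {exc}"
        fitted = _exp_model(t, *popt)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
        return KineticResults(
            i0=float(popt[0]), i_inf=float(popt[1]), tau=float(popt[2]),
            i0_se=float(perr[0]), i_inf_se=float(perr[1]), tau_se=float(perr[2]),
            r_squared=float(r2), converged=converged, message=message,
            channel=self.trace.channel, condition=self.trace.condition,
        )


@dataclass
class KineticResults:
    """Fitted exponential colour-development parameters."""

    i0: float
    i_inf: float
    tau: float
    r_squared: float
    converged: bool
    i0_se: float = np.nan
    i_inf_se: float = np.nan
    tau_se: float = np.nan
    message: str = ""
    channel: str = "S"
    condition: str | None = None

    def predict(self, t) -> np.ndarray | float:
        out = _exp_model(np.asarray(t, dtype=float), self.i0, self.i_inf, self.tau)
        return float(out) if out.ndim == 0 else out

    def time_to_fraction(self, fraction: float) -> float:
        """Time (s) to develop a given fraction of the total colour change.

        Solves I(t) − I_0 = fraction·(I_inf − I_0), i.e. t = −τ·ln(1−fraction).
        ``fraction`` = 1 − e⁻¹ ≈ 0.632 returns τ itself.
        """
        if not self.converged:
            raise InputDomainError("time_to_fraction requires a converged fit")
        f = float(fraction)
        if not (0.0 < f < 1.0):
            raise InputDomainError("fraction must lie strictly between 0 and 1")
        return float(-self.tau * np.log1p(-f))

    def summary(self) -> str:
        lines = [
            "Exponential colour-development fit",
            "=" * 46,
            f"condition:   {self.condition or '-'}",
            f"channel:     {self.channel}",
            f"I0:          {self.i0:.4f} (SE {self.i0_se:.4f})",
            f"I_inf:       {self.i_inf:.4f} (SE {self.i_inf_se:.4f})",
            f"tau:         {self.tau:.4f} s (SE {self.tau_se:.4f})",
            f"R²:          {self.r_squared:.4f}",
            f"converged:   {self.converged} ({self.message})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition, "channel": self.channel,
            "i0": self.i0, "i_inf": self.i_inf, "tau_s": self.tau,
            "i0_se": self.i0_se, "i_inf_se": self.i_inf_se, "tau_se": self.tau_se,
            "r_squared": self.r_squared, "converged": self.converged,
            "message": self.message,
        }


def fit_exponential(trace: KineticTrace) -> KineticResults:
    """Convenience wrapper: KineticModel.from_trace(trace).fit()."""
    return KineticModel.from_trace(trace).fit()


def acceleration_ratio(tau_reference: float, tau_catalyzed: float) -> float:
    """Fold-acceleration of the catalysed reaction: τ_reference / τ_catalysed."""
    tr, tc = float(tau_reference), float(tau_catalyzed)
    if tr <= 0 or tc <= 0:
        raise InputDomainError("time constants must be positive")
    return tr / tc


def min_acceleration(analyte: str, reagent: str = "FeCl3+phenanthroline") -> float:
    """Smallest fold-acceleration across the catalysed G/Pt levels.

    Computed from the bundled measured τ table: the uncatalysed (0.0 mM)
    time constant divided by each catalysed one, minimised over levels.
    """
    taus = TIME_CONSTANTS_S[reagent if reagent in TIME_CONSTANTS_S else "DNP/resazurin"][analyte]
    tau0 = taus[0.0]
    return min(acceleration_ratio(tau0, tau) for level, tau in taus.items() if level > 0)
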