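"""Static-response calibration of the colorimetric biosensor.

The readout is linear over the device's working range: a colour-channel
intensity ``y`` responds to analyte concentration ``c`` (mM) as

    y = intercept + b·c

fitted by ordinary least squares.  Performance metrics follow the usual
analytical-chemistry conventions:

* sensitivity = |b| (channel units per mM),
* S = residual standard deviation, sqrt(SSres / (n − 2)),
* LOD = 3.3·S/|b|,  LOQ = 10·S/|b|  (so LOQ/LOD = 10/3.3 always),
* R² = coefficient of determination.

Hue is angular: a calibration series that crosses the 360→0 wrap would
corrupt a naive regression, so hue intensities are unwrapped around their
circular mean before fitting and the same offset is applied when inverting
a reading back to concentration.

Organised statsmodels-style: build a :class:`CalibrationModel` from arrays,
a DataFrame or a CSV, call :meth:`~CalibrationModel.fit`, and work with the
returned :class:`CalibrationResults` (prediction, summary, serialisation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .color import circular_mean_hue
from .errors import (
    ConfigurationError,
    InputDomainError,
    RankDeficiencyError,
    SensitivityZeroError,
)

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0

CHANNELS = ("R", "G", "B", "gray", "H", "S", "V")
CHANNEL_RANGES = {
    "R": (0.0, 255.0), "G": (0.0, 255.0), "B": (0.0, 255.0), "gray": (0.0, 255.0),
    "H": (0.0, 360.0), "S": (0.0, 100.0), "V": (0.0, 100.0),
}

#: analyte → reagent → responsive channel; ``None`` marks a pair the
#: multiplex selectivity test showed does not react (no quantification).
_CHANNEL_ROUTING: dict[str, dict[str, str | None]] = {
    "dopamine": {"FeCl3+phenanthroline": "S", "DNP": "S", "resazurin": None},
    "NADH": {"FeCl3+phenanthroline": "H", "resazurin": "H", "DNP": None},
}


@dataclass(frozen=True)
class ChannelRoute:
    """Which colour channel quantifies an analyte/reagent pair, if any."""

    analyte: str
    reagent: str
    channel: str | None
    selective: bool


def select_channel(analyte: str, reagent: str) -> ChannelRoute:
    """Route an analyte/reagent pair to its responsive colour channel.

    Dopamine is quantified on saturation, NADH on hue.  Pairs the multiplex
    test found unreactive (dopamine+resazurin, NADH+DNP) come back flagged
    non-selective with no channel.
    """
    if analyte not in _CHANNEL_ROUTING:
        raise ConfigurationError(f"unknown analyte {analyte!r}")
    table = _CHANNEL_ROUTING[analyte]
    if reagent not in table:
        raise ConfigurationError(f"unknown reagent {reagent!r} for {analyte}")
    channel = table[reagent]
    return ChannelRoute(analyte, reagent, channel, selective=channel is not None)


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent: (100/n)·Σ|aᵢ−pᵢ|/aᵢ."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.ndim != 1 or a.shape != p.shape or a.size < 1:
        raise InputDomainError("actual and predicted must be equal-length, non-empty")
    if np.any(a == 0):
        raise InputDomainError("MAPE is undefined when an actual value is 0")
    return float(100.0 / a.size * np.sum(np.abs(a - p) / np.abs(a)))


def unwrap_hue(hues, center: float | None = None) -> tuple[np.ndarray, float]:
    """Unwrap hue angles to a continuous line around ``center``.

    ``center`` defaults to the circular mean of the series; each hue is
    mapped to center + signed difference in (−180, 180], removing the
    360→0 discontinuity for regression purposes.
    """
    h = np.asarray(hues, dtype=float)
    if center is None:
        center = circular_mean_hue(np.mod(h, 360.0))
    return center + ((h - center + 180.0) % 360.0) - 180.0, float(center)


@dataclass
class CalibrationPoint:
    """One replicate measurement of one concentration on one channel."""

    concentration: float  # mM
    intensity: float      # channel units
    channel: str = "S"
    replicate_id: int = 0

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise InputDomainError(f"unknown channel {self.channel!r}")
        if self.concentration < 0:
            raise InputDomainError("concentration must be ≥ 0 mM")
        lo, hi = CHANNEL_RANGES[self.channel]
        if not (lo <= self.intensity <= hi):
            raise InputDomainError(
                f"intensity {self.intensity} outside {self.channel} range [{lo}, {hi}]"
            )


class CalibrationModel:
    """Linear calibration model for one analyte/reagent/channel combination.

    Parameters
    ----------
    concentrations, intensities : 1-D arrays of equal length (≥ 3 points,
        ≥ 2 distinct concentrations).
    channel : one of R, G, B, gray, H, S, V.  Hue series are unwrapped
        around their circular mean before fitting.
    analyte, reagent : optional labels carried through to the results.
    linear_range : (mM, mM); defaults to the span of the fitted data.
    """

    def __init__(self, concentrations, intensities, channel: str = "S",
                 analyte: str | None = None, reagent: str | None = None,
                 linear_range: tuple[float, float] | None = None):
        c = np.asarray(concentrations, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if c.ndim != 1 or c.shape != y.shape:
            raise InputDomainError("concentrations and intensities must be equal-length 1-D")
        if channel not in CHANNELS:
            raise InputDomainError(f"unknown channel {channel!r}")
        if c.size < 3:
            raise RankDeficiencyError(
                "need ≥ 3 calibration points (n − 2 residual degrees of freedom)"
            )
        if np.unique(c).size < 2:
            raise RankDeficiencyError("need ≥ 2 distinct concentrations")
        self.channel = channel
        self.analyte = analyte
        self.reagent = reagent
        self.conc = c
        self.hue_center: float | None = None
        if channel == "H":
            y, self.hue_center = unwrap_hue(y)
        self.intensity = y
        self.linear_range = (
            tuple(float(x) for x in linear_range)
            if linear_range is not None
            else (float(c.min()), float(c.max()))
        )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_points(cls, points: Sequence[CalibrationPoint], **kw) -> "CalibrationModel":
        channels = {p.channel for p in points}
        if len(channels) != 1:
            raise InputDomainError("all calibration points must share one channel")
        return cls(
            [p.concentration for p in points],
            [p.intensity for p in points],
            channel=channels.pop(),
            **kw,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, channel: str | None = None, **kw) -> "CalibrationModel":
        """Build from a table with columns concentration_mM, channel, intensity."""
        required = {"concentration_mM", "channel", "intensity"}
        if not required.issubset(df.columns):
            raise InputDomainError(f"calibration table needs columns {sorted(required)}")
        if channel is not None:
            df = df[df["channel"] == channel]
        channels = df["channel"].unique()
        if len(channels) != 1:
            raise InputDomainError("calibration table must contain exactly one channel")
        return cls(df["concentration_mM"].to_numpy(), df["intensity"].to_numpy(),
                   channel=str(channels[0]), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "CalibrationModel":
        return cls.from_dataframe(pd.read_csv(path), **kw)

    # -- estimation ---------------------------------------------------
    def fit(self) -> "CalibrationResults":
        c, y = self.conc, self.intensity
        n = c.size
        res = stats.linregress(c, y)
        slope, intercept = float(res.slope), float(res.intercept)
        fitted = intercept + slope * c
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        residual_sd = float(np.sqrt(ss_res / (n - 2)))
        scale = max(1.0, float(np.max(np.abs(y))))
        if abs(slope) < 1e-12 * scale:
            raise SensitivityZeroError(
                "calibration slope is numerically zero; LOD/LOQ undefined"
            )
        return CalibrationResults(
            model=self,
            slope=slope,
            intercept=intercept,
            slope_se=float(res.stderr),
            intercept_se=float(res.intercept_stderr),
            residual_sd=residual_sd,
            r_squared=float(np.clip(r_squared, 0.0, 1.0)),
            n_points=n,
            conc_mean=float(c.mean()),
            sxx=float(np.sum((c - c.mean()) ** 2)),
        )


@dataclass
class ConcentrationEstimate:
    """Inverse-regression point estimate with first-order standard error."""

    concentration: float  # mM
    se: float             # mM
    flag: str | None = None  # 'below_range' / 'above_range' / None

    def __iter__(self):
        return iter((self.concentration, self.se))


@dataclass
class CalibrationResults:
    """Fitted calibration curve, its quality metrics and inverse prediction."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    r_squared: float
    n_points: int
    conc_mean: float
    sxx: float
    model: CalibrationModel | None = None
    channel: str = field(init=False)
    analyte: str | None = field(init=False)
    reagent: str | None = field(init=False)
    linear_range: tuple[float, float] = field(init=False)
    hue_center: float | None = field(init=False)

    def __post_init__(self):
        m = self.model
        self.channel = m.channel if m else "S"
        self.analyte = m.analyte if m else None
        self.reagent = m.reagent if m else None
        self.linear_range = m.linear_range if m else (0.0, np.inf)
        self.hue_center = m.hue_center if m else None

    # -- derived metrics ----------------------------------------------
    @property
    def sensitivity(self) -> float:
        return abs(self.slope)

    @property
    def lod(self) -> float:
        """Limit of detection, 3.3·S/|b|, in mM."""
        return LOD_FACTOR * self.residual_sd / self.sensitivity

    @property
    def loq(self) -> float:
        """Limit of quantification, 10·S/|b|, in mM."""
        return LOQ_FACTOR * self.residual_sd / self.sensitivity

    # -- prediction ---------------------------------------------------
    def predict_intensity(self, concentration) -> np.ndarray | float:
        c = np.asarray(concentration, dtype=float)
        out = self.intercept + self.slope * c
        return float(out) if out.ndim == 0 else out

    def predict_concentration(self, intensity: float) -> ConcentrationEstimate:
        """Invert a channel reading to concentration with a propagated SE.

        Out-of-range point estimates are returned as-is, flagged
        ``below_range`` / ``above_range`` rather than clipped: the device
        can legitimately report readings above its linear span.
        """
        y = float(intensity)
        if self.channel == "H" and self.hue_center is not None:
            y = self.hue_center + ((y - self.hue_center + 180.0) % 360.0) - 180.0
        c_hat = (y - self.intercept) / self.slope
        se = (self.residual_sd / self.sensitivity) * np.sqrt(
            1.0 + 1.0 / self.n_points + (c_hat - self.conc_mean) ** 2 / self.sxx
        )
        lo, hi = self.linear_range
        flag = "below_range" if c_hat < lo else ("above_range" if c_hat > hi else None)
        return ConcentrationEstimate(float(c_hat), float(se), flag)

    # -- reporting ----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Linear calibration fit",
            "=" * 46,
            f"analyte:        {self.analyte or '-'}",
            f"reagent:        {self.reagent or '-'}",
            f"channel:        {self.channel}",
            f"n points:       {self.n_points}",
            f"slope b:        {self.slope:+.4f} per mM (SE {self.slope_se:.4f})",
            f"intercept:      {self.intercept:.4f} (SE {self.intercept_se:.4f})",
            f"sensitivity:    {self.sensitivity:.4f} per mM",
            f"R²:             {self.r_squared:.4f}",
            f"residual SD S:  {self.residual_sd:.4f}",
            f"LOD (3.3·S/b):  {self.lod:.4f} mM",
            f"LOQ (10·S/b):   {self.loq:.4f} mM",
            f"linear range:   {self.linear_range[0]:g}–{self.linear_range[1]:g} mM",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte, "reagent": self.reagent, "channel": self.channel,
            "slope_b": self.slope, "intercept": self.intercept,
            "slope_se": self.slope_se, "intercept_se": self.intercept_se,
            "residual_sd_S": self.residual_sd, "r_squared": self.r_squared,
            "sensitivity": self.sensitivity, "lod_mM": self.lod, "loq_mM": self.loq,
            "linear_range_mM": list(self.linear_range), "n_points": self.n_points,
            "conc_mean": self.conc_mean, "sxx": self.sxx, "hue_center": self.hue_center,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResults":
        out = cls(
            slope=d["slope_b"], intercept=d["intercept"],
            slope_se=d.get("slope_se", np.nan), intercept_se=d.get("intercept_se", np.nan),
            residual_sd=d["residual_sd_S"], r_squared=d["r_squared"],
            n_points=d["n_points"], conc_mean=d.get("conc_mean", 0.0),
            sxx=d.get("sxx", np.inf), model=None,
        )
        out.channel = d.get("channel", "S")
        out.analyte = d.get("analyte")
        out.reagent = d.get("reagent")
        out.linear_range = tuple(d.get("linear_range_mM", (0.0, np.inf)))
        out.hue_center = d.get("hue_center")
        return out

    @classmethod
    def from_json(cls, path) -> "CalibrationResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_calibration(points: Sequence[CalibrationPoint], **kw) -> CalibrationResults:
    """Convenience wrapper: CalibrationModel.from_points(points).fit()."""
    return CalibrationModel.from_points(points, **kw).fit()
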