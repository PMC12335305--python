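"""End-to-end quantification and accuracy-evaluation workflows.

``quantify_image`` chains segmentation → zone measurement → channel routing →
inverse calibration, reproducing what the handheld app does to a captured
μPAD image.  ``evaluate_accuracy`` compares automatic readings and manual
(fixed-geometry) readings against ground truth via MAPE, the accuracy metric
used to validate the automatic readout against manual measurement.

"Manual" measurement is emulated as measurement over the *known planted
geometry* of a synthetic image — the disk masks the device design defines —
standing in for a human outlining zones in a desktop image tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import zones
from .calibration import CalibrationResults, ChannelRoute, mape, select_channel
from .errors import ConfigurationError, InputDomainError
from .synthetic import SyntheticSpec, zone_truth_masks

#: catalyst levels fabricated for the device (Pt-precursor molarity labels;
#: 0.0 denotes unmodified paper)
GPT_LEVELS = (0.0, 2.5, 5.0, 7.5, 10.0)


@dataclass
class AssayConfig:
    """Configuration of one quantification run."""

    analyte: str
    reagent: str
    gpt_mM: float = 10.0
    channel: str | None = None          # derived via select_channel unless set
    curve: CalibrationResults | None = None
    n_zones: int = 4
    layout: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if float(self.gpt_mM) not in GPT_LEVELS:
            raise ConfigurationError(
                f"gpt_mM must be one of {GPT_LEVELS}, got {self.gpt_mM}"
            )
        self.route: ChannelRoute = select_channel(self.analyte, self.reagent)
        if self.channel is None:
            self.channel = self.route.channel

    @property
    def selective(self) -> bool:
        return self.route.selective


@dataclass
class ZoneReading:
    """One zone's routed channel value and, when selective, its concentration."""

    zone_id: int
    channel: str | None
    channel_value: float
    concentration: float | None
    se: float | None
    flags: tuple[str, ...] = ()


@dataclass
class EvaluationReport:
    """MAPE of automatic and manual readings against ground truth."""

    mape_automatic: float
    mape_manual: float
    truth: tuple[float, ...]
    automatic: tuple[float, ...]
    manual: tuple[float, ...]

    @property
    def difference(self) -> float:
        """|MAPE_automatic − MAPE_manual| in percentage points."""
        return abs(self.mape_automatic - self.mape_manual)

    def summary(self) -> str:
        return "\n".join([
            "Accuracy evaluation (MAPE vs ground truth)",
            "=" * 46,
            f"n readings:       {len(self.truth)}",
            f"MAPE automatic:   {self.mape_automatic:.4f} %",
            f"MAPE manual:      {self.mape_manual:.4f} %",
            f"|difference|:     {self.difference:.4f} percentage points",
        ])


def quantify_image(image: np.ndarray, config: AssayConfig) -> list[ZoneReading]:
    """Quantify every detection zone of a captured μPAD image.

    For a selective analyte/reagent pair each zone's routed channel mean is
    inverted through the calibration curve; out-of-range estimates come back
    flagged, never clipped.  A non-selective pair yields flagged, curve-free
    records carrying the raw channel values (hue by convention).
    """
    measurements = zones.measure_image(image, n_zones=config.n_zones,
                                       layout=config.layout)
    readings: list[ZoneReading] = []
    if not config.selective:
        for m in measurements:
            readings.append(ZoneReading(
                zone_id=m.zone_id, channel=None, channel_value=m.mean_h,
                concentration=None, se=None, flags=("non_selective",),
            ))
        return readings

    if config.curve is None:
        raise ConfigurationError("quantification requires a fitted calibration curve")
    channel = config.channel
    for m in measurements:
        value = m.channel_value(channel)
        est = config.curve.predict_concentration(value)
        flags = (est.flag,) if est.flag else ()
        readings.append(ZoneReading(
            zone_id=m.zone_id, channel=channel, channel_value=value,
            concentration=est.concentration, se=est.se, flags=flags,
        ))
    return readings


def manual_measurements(image: np.ndarray, spec: SyntheticSpec) -> list[zones.ZoneMeasurement]:
    """Measure zones over the known planted geometry (the 'manual' route)."""
    out = []
    for zone_id, mask in enumerate(zone_truth_masks(spec), start=1):
        rows, cols = np.nonzero(mask)
        out.append(zones.measure_zone(image, zones.ZoneMask(zone_id, rows, cols)))
    return out


def quantify_manual(image: np.ndarray, spec: SyntheticSpec,
                    config: AssayConfig) -> list[ZoneReading]:
    """Fixed-geometry counterpart of :func:`quantify_image`."""
    if not config.selective:
        raise ConfigurationError("manual quantification needs a selective pair")
    if config.curve is None:
        raise ConfigurationError("quantification requires a fitted calibration curve")
    readings = []
    for m in manual_measurements(image, spec):
        value = m.channel_value(config.channel)
        est = config.curve.predict_concentration(value)
        readings.append(ZoneReading(
            zone_id=m.zone_id, channel=config.channel, channel_value=value,
            concentration=est.concentration, se=est.se,
            flags=(est.flag,) if est.flag else (),
        ))
    return readings


def evaluate_accuracy(truth: Sequence[float], automatic: Sequence[float],
                      manual: Sequence[float]) -> EvaluationReport:
    """MAPE of automatic and manual readings against true concentrations."""
    t = np.asarray(truth, dtype=float)
    a = np.asarray(automatic, dtype=float)
    m = np.asarray(manual, dtype=float)
    if not (t.shape == a.shape == m.shape):
        raise InputDomainError("truth, automatic and manual must have equal length")
    return EvaluationReport(
        mape_automatic=mape(t, a),
        mape_manual=mape(t, m),
        truth=tuple(map(float, t)),
        automatic=tuple(map(float, a)),
        manual=tuple(map(float, m)),
    )


def readings_to_frame(readings: Sequence[ZoneReading]) -> pd.DataFrame:
    return pd.DataFrame({
        "zone_id": [r.zone_id for r in readings],
        "channel": [r.channel for r in readings],
        "channel_value": [r.channel_value for r in readings],
        "concentration_mM": [r.concentration for r in readings],
        "se_mM": [r.se for r in readings],
        "flags": [";".join(r.flags) for r in readings],
    })
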