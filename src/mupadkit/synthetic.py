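"""Synthetic μPAD image, calibration-series and kinetic-trace generator.

Every analysis routine in this package is exercised against data whose
ground truth is known exactly.  The generator emulates the physical device
under the study conditions: four circular 3 mm detection zones on white
filter paper, a colour channel that responds linearly to concentration over
0.01–10 mM, exponential colour development in time, additive Gaussian pixel
noise, and an optional smooth radial illumination falloff (zero by default,
matching the uniform illumination of the enclosed detection chamber).

The noise model is deliberately simple — i.i.d. additive Gaussian in RGB,
clipped to [0, 255] — so that CLT-based test bounds are exact.  Paper-fibre
texture, chromatography fronts and reagent-spreading dynamics are not
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import color
from .calibration import CHANNEL_RANGES, CalibrationPoint
from .errors import ConfigurationError, InputDomainError
from .kinetics import KineticTrace
from .zones import write_image

#: default image geometry: four zones in a 2×2 layout, ~10 px/mm so a 3 mm
#: zone has a 15 px radius; rendered larger (r=30) for comfortable statistics
DEFAULT_IMAGE_SIZE = (240, 320)
DEFAULT_ZONE_RADIUS = 30
DEFAULT_ZONE_CENTRES = ((70.0, 110.0), (70.0, 210.0), (170.0, 110.0), (170.0, 210.0))


@dataclass(frozen=True)
class ResponseParams:
    """Linear static colour response of one channel to concentration.

    target channel = intercept + slope·min(c, range_max); the remaining HSV
    channels sit at ``base_hsv``.  Defaults describe the dopamine/saturation
    response of the best-performing catalysed device: sensitivity 4.26 %/mM
    over 0.01–10 mM.
    """

    channel: str = "S"
    intercept: float = 10.0
    slope: float = 4.26
    linear_range: tuple[float, float] = (0.01, 10.0)
    base_hsv: tuple[float, float, float] = (20.0, 10.0, 95.0)

    def __post_init__(self):
        if self.channel not in ("H", "S", "V"):
            raise ConfigurationError("response channel must be H, S or V")
        lo, hi = CHANNEL_RANGES[self.channel]
        for c in (0.0, self.linear_range[1]):
            val = self.intercept + self.slope * c
            wrapped = self.channel == "H"  # hue wraps; any real angle is valid
            if not wrapped and not (lo <= val <= hi):
                raise ConfigurationError(
                    f"response puts {self.channel} at {val:.2f}, outside [{lo}, {hi}]"
                )


def response_model(concentration: float, params: ResponseParams) -> tuple[float, float, float]:
    """Planted HSV triple for a concentration (plateaus above the range)."""
    c = float(concentration)
    if c < 0:
        raise InputDomainError("concentration must be ≥ 0 mM")
    c_eff = min(c, params.linear_range[1])
    h, s, v = params.base_hsv
    val = params.intercept + params.slope * c_eff
    if params.channel == "H":
        h = val % 360.0
    elif params.channel == "S":
        s = val
    else:
        v = val
    return (h, s, v)


def response_rgb(concentration: float, params: ResponseParams) -> tuple[float, float, float]:
    """Planted device-RGB triple (real-valued, pre-quantisation)."""
    return color.hsv_to_rgb(*response_model(concentration, params))


@dataclass
class SyntheticSpec:
    """Full ground-truth description of one generated μPAD image."""

    concentrations: tuple[float, ...] = (0.5, 2.0, 5.0, 8.0)
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    zone_centres: tuple[tuple[float, float], ...] = DEFAULT_ZONE_CENTRES
    zone_radius_px: float = DEFAULT_ZONE_RADIUS
    background_rgb: tuple[float, float, float] = (255.0, 255.0, 255.0)
    response: ResponseParams = field(default_factory=ResponseParams)
    noise_sd: float = 0.0
    vignette_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        r = self.zone_radius_px
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be ≥ 0")
        if not (0.0 <= self.vignette_strength <= 1.0):
            raise ConfigurationError("vignette_strength must lie in [0, 1]")
        if len(self.zone_centres) != len(self.concentrations):
            raise ConfigurationError("one concentration per zone centre required")
        centres = np.asarray(self.zone_centres, dtype=float)
        if np.any(centres[:, 0] - r < 0) or np.any(centres[:, 0] + r >= h) \
                or np.any(centres[:, 1] - r < 0) or np.any(centres[:, 1] + r >= w):
            raise ConfigurationError("zones must lie fully inside the image")
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                if np.hypot(*(centres[i] - centres[j])) < 2 * r + 2:
                    raise ConfigurationError(f"zones {i} and {j} overlap")

    # ground truth -----------------------------------------------------
    def planted_hsv(self) -> list[tuple[float, float, float]]:
        return [response_model(c, self.response) for c in self.concentrations]

    def planted_rgb(self) -> list[tuple[float, float, float]]:
        return [color.hsv_to_rgb(*hsv) for hsv in self.planted_hsv()]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["planted_hsv"] = self.planted_hsv()
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        d = json.loads(Path(path).read_text())
        d.pop("planted_hsv", None)
        d["response"] = ResponseParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["response"].items()
        })
        for key in ("concentrations", "image_size", "background_rgb"):
            d[key] = tuple(d[key])
        d["zone_centres"] = tuple(tuple(c) for c in d["zone_centres"])
        return cls(**d)


def zone_truth_masks(spec: SyntheticSpec, erosion_fraction: float = 0.10) -> list[np.ndarray]:
    """Boolean interior masks of the planted zones (anti-aliased rim excluded).

    Uses the same 10 % equivalent-radius margin as the measurement path, so
    ground-truth comparisons never see blended edge pixels.
    """
    h, w = spec.image_size
    rr, cc = np.mgrid[0:h, 0:w]
    margin = erosion_fraction * spec.zone_radius_px
    out = []
    for (r0, c0) in spec.zone_centres:
        dist = np.hypot(rr - r0, cc - c0)
        out.append(dist <= spec.zone_radius_px - max(margin, 1.0))
    return out


def render_image(spec: SyntheticSpec) -> tuple[np.ndarray, list[dict]]:
    """Render a μPAD image from a spec; returns (uint8 image, ground truth).

    The ground truth carries each zone's planted concentration, centre and
    pre-noise, pre-quantisation HSV/RGB values.  Rendering is deterministic
    in (spec, seed): the same spec yields byte-identical images.
    """
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb, dtype=float)

    rr, cc = np.mgrid[0:h, 0:w]
    truth: list[dict] = []
    for (r0, c0), conc, hsv, rgb in zip(
        spec.zone_centres, spec.concentrations, spec.planted_hsv(), spec.planted_rgb()
    ):
        dist = np.hypot(rr - r0, cc - c0)
        alpha = np.clip(spec.zone_radius_px + 0.5 - dist, 0.0, 1.0)  # anti-aliased rim
        img = alpha[..., None] * np.asarray(rgb) + (1.0 - alpha[..., None]) * img
        truth.append({
            "concentration": float(conc), "centre": (float(r0), float(c0)),
            "radius_px": float(spec.zone_radius_px),
            "hsv": tuple(map(float, hsv)), "rgb": tuple(map(float, rgb)),
        })

    if spec.vignette_strength > 0:
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        rad = np.hypot(rr - centre[0], cc - centre[1])
        rad_max = rad.max() or 1.0
        falloff = 1.0 - spec.vignette_strength * 0.5 * (1.0 - np.cos(np.pi * rad / rad_max))
        # multiplying RGB scales V while leaving H and S untouched
        img *= falloff[..., None]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), truth


def save_image(spec: SyntheticSpec, image_path, truth_path=None) -> np.ndarray:
    """Render and write the PNG plus a JSON ground-truth sidecar."""
    img, _ = render_image(spec)
    write_image(image_path, img)
    if truth_path is None:
        truth_path = Path(image_path).with_suffix(".truth.json")
    spec.to_json(truth_path)
    return img


def generate_kinetic_trace(tau: float, i0: float, i_inf: float,
                           times: Sequence[float], noise_sd: float = 0.0,
                           seed: int = 0, channel: str = "S",
                           condition: str | None = None) -> KineticTrace:
    """Exponential development trace with seeded additive Gaussian noise."""
    if tau <= 0:
        raise InputDomainError("tau must be positive")
    t = np.asarray(times, dtype=float)
    y = i_inf + (i0 - i_inf) * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return KineticTrace(t, y, channel=channel, condition=condition)


def generate_calibration_series(params: ResponseParams,
                                concentrations: Sequence[float],
                                noise_sd: float = 0.0, replicates: int = 1,
                                seed: int = 0) -> list[CalibrationPoint]:
    """Noisy linear calibration points: intensity = intercept + slope·c + ε."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise InputDomainError("need at least one concentration")
    if replicates < 1:
        raise InputDomainError("replicates must be ≥ 1")
    rng = np.random.default_rng(seed)
    points: list[CalibrationPoint] = []
    lo, hi = CHANNEL_RANGES[params.channel]
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else 0.0
        y = params.intercept + params.slope * conc + noise
        # hue is angular: wrap rather than clip; linear channels clip to gamut
        y = np.mod(y, 360.0) if params.channel == "H" else np.clip(y, lo, hi)
        for c, yi in zip(conc, y):
            points.append(CalibrationPoint(float(c), float(yi),
                                           channel=params.channel, replicate_id=rep))
    return points


def series_to_frame(points: Sequence[CalibrationPoint]) -> pd.DataFrame:
    return pd.DataFrame({
        "concentration_mM": [p.concentration for p in points],
        "channel": [p.channel for p in points],
        "intensity": [p.intensity for p in points],
        "replicate": [p.replicate_id for p in points],
    })


def trace_to_frame(trace: KineticTrace) -> pd.DataFrame:
    return pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities})
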