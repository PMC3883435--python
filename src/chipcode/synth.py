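"""Synthetic plate scans, replicate difference tables, and UV-Vis spectra.

Generators that emulate the statistical structure the analysis assumes, so
every pipeline stage is testable without a physical plate:

* plate scans whose analyte wells respond linearly in chosen channels to
  concentration, with additive per-pixel Gaussian noise;
* replicate difference tables matching the three-plates-of-three-assays
  replication scheme (nine differences per calibration point);
* absorbance spectra with a single Gaussian band whose height falls and
  whose center red-shifts linearly with concentration.

The shipped ketamine defaults anchor the spectrum model to the reference
endpoints — peak 516 nm / 1.05 AU with no analyte, 520 nm / 0.66 AU at
90 mM — with linear interpolation between them, which is the faithful
emulation of a response reported as linear.  All randomness flows through
explicit seed arguments; there is no global RNG state.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ScenarioError
from .image import PlateImage, roi_mask_indices, roi_pixel_count
from .plate import CHANNELS, PlateLayout
from .spectra import Spectrum

_CH_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass
class PlateScenario:
    """Linear per-slot color response of a synthetic plate.

    ``responses`` maps (sensor, condition, channel) to a slope in color-sum
    units per mM: at concentration c the slot's control-minus-analyte total
    difference is slope * c (before noise).  Unlisted slots do not respond.
    ``baseline`` is the per-pixel (R, G, B) mean of control wells.
    """

    responses: dict = field(default_factory=dict)
    baseline: tuple = (180, 140, 160)
    pixel_noise_sd: float = 2.0
    concentrations: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.pixel_noise_sd < 0:
            raise ScenarioError("pixel noise sd must be >= 0")
        if any(not (0 <= b <= 255) for b in self.baseline):
            raise ScenarioError(f"baseline colors must lie in [0, 255], got {self.baseline}")

    def sigma_delta(self, roi_area: int) -> float:
        """Sd of a control-minus-analyte ROI sum difference implied by pixel noise."""
        return self.pixel_noise_sd * math.sqrt(2.0 * roi_area)

    def to_dict(self) -> dict:
        return {
            "responses": [
                {"sensor": s, "condition": c, "channel": ch, "slope": m}
                for (s, c, ch), m in sorted(self.responses.items())
            ],
            "baseline": list(self.baseline),
            "pixel_noise_sd": self.pixel_noise_sd,
            "concentrations_mM": list(self.concentrations),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateScenario":
        return cls(
            responses={
                (r["sensor"], int(r["condition"]), r["channel"]): float(r["slope"])
                for r in d.get("responses", [])
            },
            baseline=tuple(d.get("baseline", (180, 140, 160))),
            pixel_noise_sd=float(d.get("pixel_noise_sd", 2.0)),
            concentrations=[float(c) for c in d.get("concentrations_mM", [])],
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class PeakModel:
    """Linear-in-concentration Gaussian absorption band for one analyte."""

    lambda0: float       # peak center at c = 0, nm
    lambda_slope: float  # nm per mM (positive = red shift with concentration)
    a0: float            # peak amplitude at c = 0, AU
    a_slope: float       # AU per mM (negative = hypochromic)
    width: float = 30.0  # Gaussian sd, nm

    def __post_init__(self):
        if self.width <= 0:
            raise ScenarioError("peak width must be > 0 nm")

    def center(self, c: float) -> float:
        return self.lambda0 + self.lambda_slope * c

    def amplitude(self, c: float) -> float:
        return self.a0 + self.a_slope * c


@dataclass
class SpectrumScenario:
    """Per-analyte peak models plus grid and noise for spectrum synthesis."""

    peaks: dict = field(default_factory=dict)  # analyte name -> PeakModel
    noise_sd: float = 0.01                     # AU
    grid: tuple = (400.0, 700.0, 1.0)          # (lo, hi, step) nm
    seed: int = 0

    def __post_init__(self):
        if self.grid[2] <= 0:
            raise ScenarioError("grid step must be > 0 nm")
        if self.noise_sd < 0:
            raise ScenarioError("noise sd must be >= 0")

    def wavelengths(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def to_dict(self) -> dict:
        return {
            "peaks": {
                name: {
                    "lambda0_nm": p.lambda0,
                    "lambda_slope_nm_per_mM": p.lambda_slope,
                    "a0_AU": p.a0,
                    "a_slope_AU_per_mM": p.a_slope,
                    "width_nm": p.width,
                }
                for name, p in self.peaks.items()
            },
            "noise_sd_AU": self.noise_sd,
            "grid_nm": list(self.grid),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrumScenario":
        return cls(
            peaks={
                name: PeakModel(
                    lambda0=float(p["lambda0_nm"]),
                    lambda_slope=float(p["lambda_slope_nm_per_mM"]),
                    a0=float(p["a0_AU"]),
                    a_slope=float(p["a_slope_AU_per_mM"]),
                    width=float(p.get("width_nm", 30.0)),
                )
                for name, p in d.get("peaks", {}).items()
            },
            noise_sd=float(d.get("noise_sd_AU", 0.01)),
            grid=tuple(d.get("grid_nm", (400.0, 700.0, 1.0))),
            seed=int(d.get("seed", 0)),
        )


# -- shipped defaults -------------------------------------------------------


def ketamine_scenario_path():
    return resources.files("chipcode.data").joinpath("ketamine_scenario.json")


def load_scenarios(path=None) -> tuple:
    """(PlateScenario, SpectrumScenario) from a scenario JSON (default: shipped)."""
    if path is None:
        raw = json.loads(ketamine_scenario_path().read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return (
        PlateScenario.from_dict(raw["plate"]),
        SpectrumScenario.from_dict(raw["spectrum"]),
    )


def default_plate_scenario() -> PlateScenario:
    return load_scenarios()[0]


def default_spectrum_scenario() -> SpectrumScenario:
    return load_scenarios()[1]


# -- generators -------------------------------------------------------------


def render_plate(
    sc: PlateScenario,
    layout: PlateLayout,
    concentration: float,
    seed: int,
    image_shape: tuple | None = None,
) -> PlateImage:
    """Paint a synthetic 8-bit plate scan at one analyte concentration.

    Control wells take the baseline color; each analyte well's responding
    channels are shifted per-pixel by round(slope * c / roi_area) so the
    resulting ROI-sum difference is slope * c up to rounding.  i.i.d.
    Gaussian pixel noise is added to the whole image and values clip to
    [0, 255].  Bit-identical for a fixed seed.
    """
    area = roi_pixel_count(layout.roi)
    if image_shape is None:
        xs = [layout.well_center(a)[0] for a in layout.well_map]
        ys = [layout.well_center(a)[1] for a in layout.well_map]
        margin = layout.roi.size + 4
        image_shape = (int(max(ys) + margin) + 1, int(max(xs) + margin) + 1)
    h, w = image_shape
    img = np.empty((h, w, 3), dtype=float)
    img[:, :] = (30.0, 30.0, 30.0)  # dark inter-well background
    for addr, a in layout.well_map.items():
        color = np.array(sc.baseline, dtype=float)
        if a.role == "analyte":
            for k, ch in enumerate(CHANNELS):
                m = sc.responses.get((a.sensor, a.condition, ch), 0.0)
                shift = round(m * concentration / area)
                color[k] -= shift  # delta = control - analyte = +slope*c
                if not (0 <= color[k] <= 255):
                    raise ScenarioError(
                        f"well {addr} channel {ch}: shifted mean {color[k]} "
                        f"outside [0, 255] before noise"
                    )
        cx, cy = layout.well_center(addr)
        rows, cols = roi_mask_indices(layout.roi, cx, cy)
        img[rows, cols] = color
    if sc.pixel_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed]))
        img = img + rng.normal(0.0, sc.pixel_noise_sd, size=img.shape)
    return PlateImage(np.clip(np.rint(img), 0, 255).astype(np.uint8), 8)


def generate_difference_table(
    sc: PlateScenario,
    n_plates: int = 3,
    n_assays: int = 3,
    seed: int = 0,
    sigma_delta: float | None = None,
    roi_area: int = 317,
) -> pd.DataFrame:
    """Replicate difference table: delta = slope * c + Normal(0, sigma) per assay.

    n_plates x n_assays rows per (concentration, responding slot); the
    default 3 x 3 yields the reference scheme's nine differences per
    calibration point.  ``sigma_delta`` defaults to the sd implied by the
    scenario's pixel noise over ``roi_area`` pixels.
    """
    if n_plates < 1 or n_assays < 1:
        raise ScenarioError("n_plates and n_assays must be >= 1")
    if sigma_delta is None:
        sigma_delta = sc.sigma_delta(roi_area)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    rows = []
    for conc in sc.concentrations:
        for (sensor, condition, channel), m in sorted(sc.responses.items()):
            for plate in range(1, n_plates + 1):
                for assay in range(1, n_assays + 1):
                    eps = rng.normal(0.0, sigma_delta) if sigma_delta > 0 else 0.0
                    rows.append(
                        {
                            "concentration_mM": conc,
                            "plate": plate,
                            "assay": assay,
                            "sensor": sensor,
                            "condition": condition,
                            "channel": channel,
                            "delta": m * conc + eps,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["concentration_mM", "plate", "assay", "sensor", "condition", "channel", "delta"],
    )


def generate_spectrum(
    sc: SpectrumScenario,
    analyte: str,
    concentration: float,
    replicate: int = 0,
    seed: int = 0,
) -> Spectrum:
    """One synthetic spectrum: Gaussian band plus i.i.d. absorbance noise.

    A(lambda) = amplitude(c) * exp(-(lambda - center(c))^2 / (2 width^2)) + eps.

    Reproducible: the RNG stream is derived from (seed, replicate, analyte,
    concentration), so replicates are independent but any call with the
    same arguments returns the identical spectrum.
    """
    if analyte not in sc.peaks:
        raise ScenarioError(f"no peak model for analyte {analyte!r} in scenario")
    peak = sc.peaks[analyte]
    lam = sc.wavelengths()
    center, amp = peak.center(concentration), peak.amplitude(concentration)
    ab = amp * np.exp(-((lam - center) ** 2) / (2.0 * peak.width**2))
    if sc.noise_sd > 0:
        entropy = [
            int(seed),
            int(replicate),
            zlib.crc32(analyte.encode()),
            int(round(concentration * 1e6)),
        ]
        rng = np.random.default_rng(np.random.SeedSequence(entropy))
        ab = ab + rng.normal(0.0, sc.noise_sd, size=lam.shape)
    return Spectrum(
        wavelengths=lam,
        absorbances=ab,
        sample_id=f"{analyte}-c{concentration}-r{replicate}",
        analyte=analyte,
        concentration=float(concentration),
    )


def generate_spectrum_family(
    sc: SpectrumScenario,
    analyte: str,
    concentrations,
    n_replicates: int = 1,
    seed: int = 0,
) -> list:
    """Replicate spectra for each listed concentration."""
    return [
        generate_spectrum(sc, analyte, c, replicate=r, seed=seed)
        for c in concentrations
        for r in range(n_replicates)
    ]
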