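"""Linear standard curves and inverse prediction of analyte concentration.

The assay's quantitative mode: replicate control-minus-analyte color
differences (or absorbances) measured at known concentrations are averaged
per concentration, fitted by ordinary least squares

    mean response = m * concentration + b,

and the fitted line is inverted, c_hat = (y_obs - b) / m, to estimate the
concentration behind a new observation.  The replication scheme of the
underlying experiment is three plates of three assays each, i.e. nine
difference values per calibration point.

The fit is unweighted and runs on the per-concentration means (matching how
the curves were constructed experimentally); fitting all raw replicates is
available via ``calibrate_from_replicates(..., on_means=False)``.  The
Pearson r is reported signed — a decreasing response gives r near -1, and
|r| is the quantity comparable to a reported "R = 0.99".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, FlatCurveError, InputError

#: Replication scheme of the reference experiment.
N_PLATES_DEFAULT = 3
N_ASSAYS_DEFAULT = 3


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate-averaged response at one known concentration."""

    concentration: float  # mM
    mean_delta: float     # color-sum units (or AU for absorbance curves)
    sd_delta: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise InputError(f"replicate count must be >= 1, got {self.n}")
        if self.sd_delta < 0:
            raise InputError("sd must be non-negative")
        if self.concentration < 0:
            raise InputError("concentrations must be non-negative")


@dataclass
class StandardCurve:
    """OLS line through calibration points, with the fit's diagnostics.

    Attributes
    ----------
    slope, intercept
        Response units per mM, and response units.
    r
        Signed Pearson correlation of (concentration, mean response).
    points
        The averaged calibration points behind the fit.
    channel_slot
        Optional (sensor, condition, channel) tag of the data's origin.
    """

    slope: float
    intercept: float
    r: float
    points: list
    channel_slot: tuple | None = None
    residual_se: float = 0.0  # sqrt(SSE / (n-2)); 0 when n == 2

    @property
    def n(self) -> int:
        return len(self.points)

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def _design(self):
        c = np.array([p.concentration for p in self.points], dtype=float)
        return c.mean(), float(((c - c.mean()) ** 2).sum())

    def summary(self) -> str:
        cbar, sxx = self._design()
        lines = [
            "Standard curve (OLS on per-concentration means)",
            "-" * 48,
            f"slot:        {self.channel_slot}",
            f"slope:       {self.slope:.6g} units/mM",
            f"intercept:   {self.intercept:.6g} units",
            f"Pearson r:   {self.r:.4f}   (|r| = {abs(self.r):.4f})",
            f"points:      {self.n} concentrations, "
            f"{sum(p.n for p in self.points)} replicates total",
            f"residual se: {self.residual_se:.6g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "slot": list(self.channel_slot) if self.channel_slot else None,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "residual_se": self.residual_se,
            "points": [
                {
                    "concentration_mM": p.concentration,
                    "mean_delta": p.mean_delta,
                    "sd_delta": p.sd_delta,
                    "n": p.n,
                }
                for p in self.points
            ],
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "StandardCurve":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r=d["r"],
            residual_se=d.get("residual_se", 0.0),
            channel_slot=tuple(d["slot"]) if d.get("slot") else None,
            points=[
                CalibrationPoint(
                    concentration=p["concentration_mM"],
                    mean_delta=p["mean_delta"],
                    sd_delta=p["sd_delta"],
                    n=p["n"],
                )
                for p in d["points"]
            ],
        )

    @classmethod
    def load(cls, path) -> "StandardCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-prediction estimate with a first-order confidence interval."""

    c_hat: float
    interval: tuple
    confidence: float


# ---------------------------------------------------------------------------


def average_replicates(raw) -> list:
    """Collapse a replicate table to one calibration point per concentration.

    ``raw`` is a DataFrame with at least columns ``concentration_mM`` and
    ``delta`` (plate/assay columns are carried but not used).  The sd uses
    the sample (n-1) denominator; a single replicate gets sd 0.
    """
    if raw is None or len(raw) == 0:
        raise InputError("replicate table is empty")
    if "concentration_mM" not in raw.columns or "delta" not in raw.columns:
        raise InputError(
            f"replicate table needs columns concentration_mM and delta, got {list(raw.columns)}"
        )
    points = []
    for conc, grp in raw.groupby("concentration_mM", sort=True):
        vals = grp["delta"].to_numpy(dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        points.append(
            CalibrationPoint(
                concentration=float(conc),
                mean_delta=float(vals.mean()),
                sd_delta=sd,
                n=len(vals),
            )
        )
    return points


def fit_standard_curve(points, channel_slot=None) -> StandardCurve:
    """Unweighted OLS of mean response on concentration.

    Requires at least two distinct concentrations.  Deterministic; slope,
    intercept, and Pearson r come from the closed-form least-squares
    solution (scipy.stats.linregress).
    """
    if len(points) < 2:
        raise DegenerateDesignError("need at least 2 calibration points")
    c = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.mean_delta for p in points], dtype=float)
    if len(np.unique(c)) < 2:
        raise DegenerateDesignError("all concentrations identical; cannot fit a line")
    res = stats.linregress(c, y)
    resid = y - (res.slope * c + res.intercept)
    dof = len(c) - 2
    se = math.sqrt(float(resid @ resid) / dof) if dof > 0 else 0.0
    # r is undefined when the response is exactly constant; report 0
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        points=sorted(points, key=lambda p: p.concentration),
        channel_slot=channel_slot,
        residual_se=se,
    )


def calibrate_from_replicates(raw, channel_slot=None, on_means: bool = True) -> StandardCurve:
    """Full calibration from a raw replicate table.

    ``on_means=True`` (default) fits the per-concentration means; False
    fits every replicate as its own point.
    """
    points = average_replicates(raw)
    if on_means:
        return fit_standard_curve(points, channel_slot)
    allpts = [
        CalibrationPoint(float(r["concentration_mM"]), float(r["delta"]), 0.0, 1)
        for _, r in raw.iterrows()
    ]
    fit = fit_standard_curve(allpts, channel_slot)
    fit.points = points  # keep the averaged summary for reporting
    return fit


def estimate_concentration(
    curve: StandardCurve, delta_obs: float, confidence: float = 0.95
) -> ConcentrationEstimate:
    """Invert the standard curve for one observed response.

    c_hat = (delta_obs - b) / m.  The interval propagates the OLS residual
    standard error through the inverse-prediction formula to first order:

        se(c_hat) = (s/|m|) * sqrt(1 + 1/n + (c_hat - c_mean)^2 / Sxx)

    with a Student-t quantile on n-2 degrees of freedom.  With only two
    calibration points the residual error is zero and the interval
    degenerates to the point estimate.
    """
    deltas = [p.mean_delta for p in curve.points]
    scale = max(abs(max(deltas) - min(deltas)), 1.0)
    if abs(curve.slope) < 1e-9 * scale:
        raise FlatCurveError(
            f"slope {curve.slope} is numerically zero; concentration not identifiable"
        )
    c_hat = (delta_obs - curve.intercept) / curve.slope
    dof = curve.n - 2
    if dof > 0 and curve.residual_se > 0:
        cbar, sxx = curve._design()
        se = (curve.residual_se / abs(curve.slope)) * math.sqrt(
            1.0 + 1.0 / curve.n + (c_hat - cbar) ** 2 / sxx
        )
        t = stats.t.ppf(0.5 + confidence / 2.0, dof)
        half = t * se
    else:
        half = 0.0
    return ConcentrationEstimate(
        c_hat=c_hat, interval=(c_hat - half, c_hat + half), confidence=confidence
    )
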