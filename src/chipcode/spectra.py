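"""UV-Vis spectrum handling: peak finding, peak shift, and absorbance curves.

On analyte binding the sensor's absorption band both weakens and moves to
longer wavelength (a bathochromic/red shift); both effects grow with
concentration.  This module locates the absorbance maximum on the measured
grid (lambda_max), measures the signed shift between control and treated
spectra (positive = red shift), extracts interpolated absorbance at a fixed
wavelength, and fits absorbance-vs-concentration standard curves by reusing
the calibration machinery.

lambda_max is grid-resolution only — reported shifts are integer multiples
of the grid step, matching how such shifts are conventionally read off a
1 nm instrument grid; sub-grid (parabolic) refinement is deliberately out
of scope.  Ties break to the lowest wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint, StandardCurve, fit_standard_curve
from .errors import (
    DataError,
    DegenerateDesignError,
    ExtrapolationError,
    RegridError,
    WindowError,
)

#: Default analysis window in nm (visible range).
DEFAULT_WINDOW = (400.0, 700.0)


@dataclass
class Spectrum:
    """One absorbance spectrum: strictly increasing nm grid vs AU values."""

    wavelengths: np.ndarray
    absorbances: np.ndarray
    sample_id: str = ""
    analyte: str = ""
    concentration: float | None = None  # mM

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.shape != self.absorbances.shape:
            raise DataError("wavelength and absorbance arrays must have equal length")
        if self.wavelengths.size < 3:
            raise DataError("a spectrum needs at least 3 grid points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DataError("wavelength grid must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class PeakResult:
    """Location and height of the absorbance maximum on the grid."""

    lambda_max: float  # nm
    a_max: float       # AU


@dataclass(frozen=True)
class ShiftResult:
    """Signed peak displacement in nm; positive = red (bathochromic) shift."""

    delta_lambda: float


# ---------------------------------------------------------------------------


def read_spectra(path_or_df) -> list:
    """Parse a long-format spectra table into one Spectrum per sample.

    Columns: sample_id, analyte, concentration_mM, wavelength_nm, absorbance.
    Rows are sorted by wavelength per sample; a duplicated (sample,
    wavelength) pair is a data error.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"sample_id", "analyte", "concentration_mM", "wavelength_nm", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"spectra table missing columns: {sorted(missing)}")
    spectra = []
    for sid, grp in df.groupby("sample_id", sort=True):
        if grp["wavelength_nm"].duplicated().any():
            dupes = grp.loc[grp["wavelength_nm"].duplicated(), "wavelength_nm"].tolist()
            raise DataError(f"sample {sid!r} has duplicated wavelengths: {dupes}")
        grp = grp.sort_values("wavelength_nm")
        spectra.append(
            Spectrum(
                wavelengths=grp["wavelength_nm"].to_numpy(dtype=float),
                absorbances=grp["absorbance"].to_numpy(dtype=float),
                sample_id=str(sid),
                analyte=str(grp["analyte"].iloc[0]),
                concentration=float(grp["concentration_mM"].iloc[0]),
            )
        )
    return spectra


def spectra_to_frame(spectra) -> pd.DataFrame:
    rows = []
    for s in spectra:
        for lam, a in zip(s.wavelengths, s.absorbances):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "analyte": s.analyte,
                    "concentration_mM": s.concentration,
                    "wavelength_nm": lam,
                    "absorbance": a,
                }
            )
    return pd.DataFrame(rows)


def find_lambda_max(s: Spectrum, window: tuple | None = None) -> PeakResult:
    """Grid argmax of absorbance, optionally restricted to a window.

    Exhaustive over grid points; no smoothing.  Equal maxima resolve to the
    lowest wavelength (np.argmax returns the first index of an ascending
    grid).
    """
    lam, ab = s.wavelengths, s.absorbances
    if window is not None:
        lo, hi = window
        mask = (lam >= lo) & (lam <= hi)
        if not mask.any():
            raise WindowError(
                f"window ({lo}, {hi}) nm does not overlap grid "
                f"[{lam[0]}, {lam[-1]}] nm"
            )
        lam, ab = lam[mask], ab[mask]
    i = int(np.argmax(ab))
    return PeakResult(lambda_max=float(lam[i]), a_max=float(ab[i]))


def peak_shift(control: Spectrum, treated: Spectrum, window: tuple | None = None) -> ShiftResult:
    """Signed lambda_max displacement, treated minus control (+ = red shift)."""
    pc = find_lambda_max(control, window)
    pt = find_lambda_max(treated, window)
    return ShiftResult(delta_lambda=pt.lambda_max - pc.lambda_max)


def absorbance_at(s: Spectrum, lam: float) -> float:
    """Absorbance at one wavelength by linear interpolation.

    An exact grid hit returns the stored value; wavelengths outside the
    grid span raise rather than extrapolate.
    """
    if lam < s.wavelengths[0] or lam > s.wavelengths[-1]:
        raise ExtrapolationError(
            f"{lam} nm outside grid span [{s.wavelengths[0]}, {s.wavelengths[-1]}] nm"
        )
    return float(np.interp(lam, s.wavelengths, s.absorbances))


def average_spectra(spectra) -> Spectrum:
    """Point-wise mean of replicate spectra sharing an identical grid."""
    if not spectra:
        raise DataError("no spectra to average")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if len(s) != len(grid) or not np.array_equal(s.wavelengths, grid):
            raise RegridError(
                f"replicate grids differ (sample {s.sample_id!r}); regridding is not performed"
            )
    first = spectra[0]
    return Spectrum(
        wavelengths=grid.copy(),
        absorbances=np.mean([s.absorbances for s in spectra], axis=0),
        sample_id="mean:" + ",".join(s.sample_id for s in spectra),
        analyte=first.analyte,
        concentration=first.concentration,
    )


def fit_absorbance_curve(spectra, lam: float, channel_slot=None) -> StandardCurve:
    """Linear standard curve of absorbance at ``lam`` vs concentration.

    Replicate spectra at the same concentration are averaged (their
    absorbance values at ``lam``) before the unweighted OLS fit; needs at
    least two distinct concentrations.
    """
    by_conc: dict = {}
    for s in spectra:
        if s.concentration is None:
            raise DataError(f"spectrum {s.sample_id!r} has no concentration")
        by_conc.setdefault(float(s.concentration), []).append(absorbance_at(s, lam))
    if len(by_conc) < 2:
        raise DegenerateDesignError("need spectra at >= 2 distinct concentrations")
    points = []
    for conc in sorted(by_conc):
        vals = np.array(by_conc[conc])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        points.append(
            CalibrationPoint(
                concentration=conc, mean_delta=float(vals.mean()), sd_delta=sd, n=len(vals)
            )
        )
    return fit_standard_curve(points, channel_slot=channel_slot or ("UVVis", 0, f"A@{lam}nm"))
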