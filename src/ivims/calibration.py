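"""Range calibration, range prediction and beam-spot verification.

The Z50 depth marker extracted from the fitted vertex depth profile is
linearly related to the primary-ion range.  A weighted linear fit of
(Z50, true range) calibration points yields a per-setup calibration that
is then applied to new (validation) spots; the calibration coefficients
are always re-derived from the package's own runs — they are outputs of a
specific detector/beam configuration, never constants.

Beam-spot verification compares, per shift setting, the SPM beam mean with
the Gaussian-fitted transverse vertex mean: Delta = beam - vertex.  The
Delta-versus-shift relation is fitted linearly; the overall accuracy is
reported as the maximum absolute discrepancy across the shift settings.

The reference beam range itself is defined on the depth-dose curve, at the
distal 70-75% dose fall-off, reported at the center of the containing
voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DepthDoseCurve",
    "RangeCalibration",
    "SpotVerification",
    "reference_range",
    "calibrate_range",
    "predict_range",
    "verify_spot",
]


@dataclass
class DepthDoseCurve:
    """Integrated depth-dose on a regular voxel-center grid (mm, a.u.)."""

    depth: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depth.shape != self.dose.shape or self.depth.ndim != 1:
            raise ValueError("depth and dose must be matching 1D arrays")
        if len(self.depth) < 3 or np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth grid must be increasing with >= 3 points")


def reference_range(curve: DepthDoseCurve, fraction: float = 0.725) -> float:
    """Beam range from the distal dose fall-off of a depth-dose curve.

    The range is the distal depth where the dose first drops through
    ``fraction`` of the Bragg-peak maximum (default 0.725, the midpoint of
    the 70-75% band; configurable within [0.70, 0.75]), reported at the
    middle of the finite-resolution voxel containing the crossing.
    """
    if not 0.70 <= fraction <= 0.75:
        raise ValueError("fraction must lie in the 0.70-0.75 band")
    d = curve.dose
    ipk = int(np.argmax(d))
    level = fraction * d[ipk]
    distal = d[ipk:]
    below = np.flatnonzero(distal < level)
    if below.size == 0:
        raise ValueError("depth-dose curve has no distal crossing of the reference level")
    j = ipk + int(below[0])  # first grid point below the level
    z0, z1 = curve.depth[j - 1], curve.depth[j]
    d0, d1 = d[j - 1], d[j]
    z_cross = z0 if d0 == d1 else z0 + (level - d0) * (z1 - z0) / (d1 - d0)
    # snap to the center of the containing voxel
    spacing = float(np.median(np.diff(curve.depth)))
    idx = int(round((z_cross - curve.depth[0]) / spacing))
    idx = int(np.clip(idx, 0, len(curve.depth) - 1))
    return float(curve.depth[idx])


@dataclass
class RangeCalibration:
    """Linear Z50 -> range model with parameter covariance."""

    slope: float
    intercept: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    chi2_ndf: float
    points: list = field(default_factory=list)  # (z50, true_range, sigma_z50)

    @property
    def z50_span(self) -> tuple[float, float]:
        z = [p[0] for p in self.points]
        return (min(z), max(z))

    def to_yaml(self, path: str | Path, provenance: dict | None = None) -> Path:
        path = Path(path)
        payload = {
            "model": "range = intercept + slope * z50",
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "cov": np.asarray(self.cov).tolist(),
            "chi2_ndf": float(self.chi2_ndf),
            "points": [[float(a), float(b), float(c)] for a, b, c in self.points],
            "provenance": provenance or {},
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RangeCalibration":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            slope=float(payload["slope"]),
            intercept=float(payload["intercept"]),
            cov=np.asarray(payload["cov"], dtype=float),
            chi2_ndf=float(payload["chi2_ndf"]),
            points=[tuple(p) for p in payload.get("points", [])],
        )


def calibrate_range(points: list[tuple[float, float, float]]) -> RangeCalibration:
    """Weighted linear least squares of true range versus Z50.

    ``points`` is a list of (z50, true_range, sigma_z50).  The abscissa
    uncertainty is propagated into an effective ordinate uncertainty via a
    preliminary unweighted slope estimate (sigma_y = |slope| * sigma_z50),
    so for equal sigmas the fit reduces exactly to ordinary least squares.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    z = np.array([p[0] for p in points], dtype=float)
    r = np.array([p[1] for p in points], dtype=float)
    sz = np.array([p[2] for p in points], dtype=float)
    if np.ptp(z) <= 0:
        raise ValueError("degenerate calibration: all z50 values identical")

    A = np.column_stack([np.ones_like(z), z])
    beta0, *_ = np.linalg.lstsq(A, r, rcond=None)
    sigma_y = np.abs(beta0[1]) * sz
    sigma_y = np.clip(sigma_y, max(1e-9, 1e-6 * np.ptp(r)), None)

    w = 1.0 / sigma_y**2
    Aw = A * np.sqrt(w)[:, None]
    rw = r * np.sqrt(w)
    ata = Aw.T @ Aw
    beta = np.linalg.solve(ata, Aw.T @ rw)
    cov = np.linalg.inv(ata)
    resid = r - A @ beta
    ndf = len(z) - 2
    chi2 = float(np.sum((resid / sigma_y) ** 2))
    return RangeCalibration(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        cov=cov,
        chi2_ndf=chi2 / ndf if ndf > 0 else float("nan"),
        points=[tuple(map(float, p)) for p in points],
    )


def predict_range(
    z50_value: float, calib: RangeCalibration, sigma_z50: float = 0.0
) -> tuple[float, float]:
    """Predict the beam range for one Z50 measurement.

    Returns (range, uncertainty): the linear prediction with the calibration
    parameter covariance and the Z50 measurement uncertainty propagated in
    quadrature.  Predictions outside the calibrated Z50 span raise a
    warning but are still returned.
    """
    lo, hi = calib.z50_span
    tol = 0.05 * (hi - lo)
    if not (lo - tol <= z50_value <= hi + tol):
        warnings.warn(
            f"z50 = {z50_value:.2f} mm extrapolates beyond the calibrated span "
            f"[{lo:.2f}, {hi:.2f}] mm",
            stacklevel=2,
        )
    pred = calib.intercept + calib.slope * z50_value
    jac = np.array([1.0, z50_value])
    var = float(jac @ np.asarray(calib.cov) @ jac) + (calib.slope * sigma_z50) ** 2
    return float(pred), float(np.sqrt(max(var, 0.0)))


@dataclass
class SpotVerification:
    """Delta = beam-minus-vertex mean across injected spot shifts."""

    axis: str
    shifts: np.ndarray
    deltas: np.ndarray
    delta_errs: np.ndarray
    slope: float
    intercept: float
    accuracy: float  # max |Delta| over the shift settings
    excluded: int = 0


def verify_spot(
    runs: list[tuple[float, "VertexCloud", "pd.DataFrame"]],
    axis: str = "y",
    min_vertices: int = 100,
) -> SpotVerification:
    """Beam-spot position verification over a set of injected shifts.

    Each run is (injected shift mm, vertex cloud, SPM stream).  Per run the
    beam position is the SPM stream mean on the chosen axis and the vertex
    position the Gaussian-fit mean of the matching vertex projection;
    Delta = beam - vertex.  A line is fitted to Delta versus shift (the
    spot-shift relation), and the overall accuracy is the maximum |Delta|
    across settings.  Runs whose lateral fit fails are excluded and counted.
    """
    from .profiles import fit_lateral

    if len(runs) < 3:
        raise ValueError("need at least 3 shift settings")
    shifts, deltas, errs = [], [], []
    excluded = 0
    for shift, cloud, spm in runs:
        try:
            lat = fit_lateral(cloud, axis=axis, min_vertices=min_vertices)
            if not lat.converged:
                raise ValueError("lateral fit did not converge")
        except ValueError:
            excluded += 1
            continue
        beam_mean = float(np.mean(spm[axis].to_numpy(dtype=float)))
        beam_se = float(np.std(spm[axis].to_numpy(dtype=float)) / np.sqrt(len(spm)))
        shifts.append(float(shift))
        deltas.append(beam_mean - lat.mean)
        errs.append(float(np.hypot(lat.mean_err, beam_se)))
    if len(shifts) < 2:
        raise ValueError("too few usable shift settings after fit exclusions")
    shifts_a = np.asarray(shifts)
    deltas_a = np.asarray(deltas)
    if np.ptp(shifts_a) > 0:
        slope, intercept = np.polyfit(shifts_a, deltas_a, 1)
    else:  # single shift setting repeated: no slope is identifiable
        slope, intercept = float("nan"), float(np.mean(deltas_a))
    return SpotVerification(
        axis=axis,
        shifts=shifts_a,
        deltas=deltas_a,
        delta_errs=np.asarray(errs),
        slope=float(slope),
        intercept=float(intercept),
        accuracy=float(np.max(np.abs(deltas_a))),
        excluded=excluded,
    )
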