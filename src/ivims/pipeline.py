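"""End-to-end convenience workflows: simulate -> tracks -> vertices -> markers.

These functions wire the module chain together the way the CLI and the
verification protocols use it; each step remains individually accessible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beamline import (
    BeamConfig,
    FragmentModelConfig,
    PhantomConfig,
    SpillResult,
    simulate_spill,
)
from .calibration import RangeCalibration, calibrate_range
from .geometry import StackGeometry, make_stack
from .profiles import (
    ErfcFit,
    LateralFit,
    depth_profile,
    detect_boundaries,
    fit_erfc,
    fit_lateral,
    z50,
    z50_uncertainty,
)
from .tracks import CoincidenceStats, build_tracks, correlate_with_beam
from .vertices import VertexCloud, reconstruct_vertices

__all__ = [
    "reconstruct_spill",
    "SpotMarkers",
    "analyze_cloud",
    "run_spot",
    "run_range_calibration",
]


def reconstruct_spill(
    sim: SpillResult,
    gate: float = 10.0,
    parallel_tol: float = 1e-6,
    miss_cut: float | None = None,
    stack_index: int = 0,
) -> tuple[VertexCloud, CoincidenceStats, dict]:
    """Build tracks from one stack of a simulated spill and reconstruct vertices."""
    hits = sim.hits
    front = hits[hits["detector_id"] == 2 * stack_index].reset_index(drop=True)
    back = hits[hits["detector_id"] == 2 * stack_index + 1].reset_index(drop=True)
    tracks, stats = build_tracks(front, back, gate=gate)
    paired, counters = correlate_with_beam(tracks, sim.spm)
    cloud = reconstruct_vertices(
        paired, parallel_tol=parallel_tol, miss_cut=miss_cut, metadata=dict(sim.metadata)
    )
    stats.degenerate = cloud.n_degenerate
    return cloud, stats, counters


@dataclass
class SpotMarkers:
    """Monitoring markers extracted from one scanned spot."""

    erfc: ErfcFit
    z50: float
    z50_err: float
    boundaries: tuple[float, float] | None
    lateral: LateralFit | None
    vertical: LateralFit | None
    n_vertices: int
    extras: dict = field(default_factory=dict)

    def report(self) -> dict:
        rep = {
            "n_vertices": self.n_vertices,
            "erfc": {
                "p0": self.erfc.p0,
                "p1": self.erfc.p1,
                "p2": self.erfc.p2,
                "p3": self.erfc.p3,
                "stderr": self.erfc.stderr,
                "chi2_ndf": self.erfc.redchi,
                "converged": self.erfc.converged,
            },
        }
        if self.erfc.converged:
            rep["z50_mm"] = self.z50
            rep["z50_err_mm"] = self.z50_err
        if self.boundaries is not None:
            rep["entrance_mm"], rep["exit_mm"] = self.boundaries
        for name, lat in (("lateral_y", self.lateral), ("vertical_x", self.vertical)):
            if lat is not None:
                rep[name] = {
                    "mean_mm": lat.mean,
                    "mean_err_mm": lat.mean_err,
                    "sigma_mm": lat.sigma,
                    "sigma_err_mm": lat.sigma_err,
                }
        rep.update(self.extras)
        return rep


def analyze_cloud(
    cloud: VertexCloud,
    phantom: PhantomConfig | None = None,
    bin_width: float = 1.0,
    margin: float = 40.0,
    fit_window: tuple[float, float] | None = None,
    boundary_threshold: float = 0.5,
) -> SpotMarkers:
    """Extract the full marker set from a vertex cloud."""
    phantom = phantom or PhantomConfig()
    prof = depth_profile(
        cloud,
        bin_width=bin_width,
        entrance_z=phantom.entrance_z,
        exit_z=phantom.exit_z,
        margin=margin,
    )
    fit = fit_erfc(prof, window=fit_window)
    if fit.converged:
        z50_val = z50(fit)
        z50_err = z50_uncertainty(fit)
    else:
        z50_val, z50_err = float("nan"), float("nan")
    try:
        bounds = detect_boundaries(prof, threshold=boundary_threshold)
    except ValueError:
        bounds = None
    lat = vert = None
    try:
        lat = fit_lateral(cloud, axis="y")
        vert = fit_lateral(cloud, axis="x")
    except ValueError:
        pass
    return SpotMarkers(
        erfc=fit,
        z50=z50_val,
        z50_err=z50_err,
        boundaries=bounds,
        lateral=lat,
        vertical=vert,
        n_vertices=len(cloud),
    )


def run_spot(
    nominal_range: float,
    seed: int,
    n_primaries: int = 200_000,
    spot_shift_x: float = 0.0,
    spot_shift_y: float = 0.0,
    phantom: PhantomConfig | None = None,
    frag: FragmentModelConfig | None = None,
    stack: StackGeometry | None = None,
    gate: float = 10.0,
    fit_window: tuple[float, float] | None = None,
) -> tuple[SpotMarkers, VertexCloud, SpillResult]:
    """Simulate, reconstruct and analyze a single scanned beam spot."""
    phantom = phantom or PhantomConfig()
    frag = frag or FragmentModelConfig()
    stack = stack or make_stack()
    beam = BeamConfig(
        n_primaries=n_primaries,
        nominal_range=nominal_range,
        spot_shift_x=spot_shift_x,
        spot_shift_y=spot_shift_y,
        seed=seed,
    )
    sim = simulate_spill(beam, phantom, frag, stack, seed=seed)
    cloud, stats, counters = reconstruct_spill(sim, gate=gate)
    markers = analyze_cloud(cloud, phantom=phantom, fit_window=fit_window)
    markers.extras["coincidence"] = stats.as_dict()
    markers.extras["beam_correlation"] = counters
    return markers, cloud, sim


def run_range_calibration(
    calibration_ranges: list[float],
    seeds: list[int],
    n_primaries: int = 200_000,
    phantom: PhantomConfig | None = None,
    frag: FragmentModelConfig | None = None,
    stack: StackGeometry | None = None,
) -> tuple[RangeCalibration, list[dict]]:
    """Build a Z50 -> range calibration from a set of simulated spots."""
    if len(seeds) != len(calibration_ranges):
        raise ValueError("need one seed per calibration range")
    points = []
    details = []
    for rng_mm, seed in zip(calibration_ranges, seeds):
        markers, _, _ = run_spot(rng_mm, seed, n_primaries=n_primaries, phantom=phantom, frag=frag, stack=stack)
        if not markers.erfc.converged or not np.isfinite(markers.z50):
            details.append({"range_mm": rng_mm, "status": "fit_failed"})
            continue
        sz = markers.z50_err if np.isfinite(markers.z50_err) else 1.0
        points.append((markers.z50, rng_mm, sz))
        details.append(
            {
                "range_mm": rng_mm,
                "z50_mm": markers.z50,
                "z50_err_mm": sz,
                "p3_mm": markers.erfc.p3,
                "status": "ok",
            }
        )
    calib = calibrate_range(points)
    return calib, details
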