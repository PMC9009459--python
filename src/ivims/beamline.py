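"""Parametric synthetic beamline: pencil beam, fragmentation, detector hits.

This module replaces a full Monte Carlo particle transport with a minimal
parametric model that reproduces the *statistical shape* features the
vertex-imaging analysis relies on:

* a Gaussian pencil-beam spot (sigma_X 1.3 mm x sigma_Y 1.6 mm at isocenter),
  optionally steered by configurable shifts;
* fragmentation vertices along the beam path with density proportional to
  exp(-depth / lambda) (exponential primary attenuation), sharply truncated
  at the per-event range R ~ Normal(nominal_range, straggling);
* forward-peaked fragment emission (half-normal polar angle, uniform
  azimuth) with Gaussian exit scattering growing with the remaining path;
* background components: secondary-origin vertices (extra position smear,
  biasing the back-projection) and, for helium, out-of-field vertices
  upstream of the phantom emulating beam-nozzle interactions;
* a two-plane pixelated tracker stack and a beam spot monitor (SPM) plane
  100 mm upstream of the isocenter, read out in list mode.

Everything is driven by one root seed; per-stream child generators are
spawned deterministically so runs are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    Line3,
    Point3,
    StackGeometry,
    geometry_hash,
    intersect_plane_batch,
    pixelate,
)

__all__ = [
    "BeamConfig",
    "PhantomConfig",
    "SpeciesConfig",
    "FragmentModelConfig",
    "SpillResult",
    "sample_primary",
    "sample_vertex_depth",
    "emit_fragment",
    "simulate_spill",
    "range_from_energy",
]

SPM_PLANE_Z = -100.0  # mm; virtual diagnostics plane upstream of isocenter


@dataclass(frozen=True)
class BeamConfig:
    """Pencil-beam source parameters.

    ``nominal_range`` is the depth (mm from the phantom entrance) at which
    primary ions stop; fragment production terminates there.
    """

    n_primaries: int = 1_000_000
    spot_sigma_x: float = 1.3
    spot_sigma_y: float = 1.6
    nominal_range: float = 105.2
    range_straggling_sigma: float = 1.0
    spot_shift_x: float = 0.0
    spot_shift_y: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.spot_sigma_x <= 0 or self.spot_sigma_y <= 0:
            raise ValueError("spot sigmas must be positive")
        if self.n_primaries < 0:
            raise ValueError("n_primaries must be non-negative")


@dataclass(frozen=True)
class PhantomConfig:
    """Head-phantom box: grey-matter volume in a cortical-bone shell."""

    extent_x: float = 153.5
    extent_y: float = 106.5
    extent_z: float = 180.5
    shell_thickness: float = 6.75
    voxel_size: float = 1.0

    def __post_init__(self):
        if min(self.extent_x, self.extent_y, self.extent_z) <= 0:
            raise ValueError("phantom extents must be positive")

    @property
    def entrance_z(self) -> float:
        """Lab Z of the upstream phantom face (isocenter at the center)."""
        return -self.extent_z / 2.0

    @property
    def exit_z(self) -> float:
        return self.extent_z / 2.0


@dataclass(frozen=True)
class SpeciesConfig:
    """Emulation parameters for one fragment species.

    relative_yield       mean fragments of this species emitted per primary
    angular_sigma        rad; half-normal polar emission width about +Z
    exit_scatter_sigma   mm per sqrt(mm); lateral Gaussian displacement of the
                         apparent emission point, scaled by sqrt(remaining path)
    primary_vertex_fraction  fraction of in-field vertices from the primary
                         ion (the rest are 'secondary' and get an extra
                         position smear of ``secondary_smear_sigma`` mm)
    out_of_field_fraction    fraction of all vertices placed upstream in the
                         nozzle region instead of inside the phantom
    """

    name: str
    relative_yield: float
    angular_sigma: float
    exit_scatter_sigma: float
    primary_vertex_fraction: float
    out_of_field_fraction: float = 0.0
    secondary_smear_sigma: float = 5.0

    def __post_init__(self):
        if self.relative_yield < 0:
            raise ValueError("relative_yield must be >= 0")
        for f in (self.primary_vertex_fraction, self.out_of_field_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def _default_species() -> tuple[SpeciesConfig, ...]:
    # H-like fragments: abundant, wide emission, ~50% primary-vertex origin.
    # He-like: stiffer (narrower cone), ~90% primary, ~30% out-of-field.
    return (
        SpeciesConfig(
            name="H",
            relative_yield=0.36,
            angular_sigma=0.80,
            exit_scatter_sigma=0.15,
            primary_vertex_fraction=0.5,
            out_of_field_fraction=0.0,
        ),
        SpeciesConfig(
            name="He",
            relative_yield=0.21,
            angular_sigma=0.55,
            exit_scatter_sigma=0.08,
            primary_vertex_fraction=0.9,
            out_of_field_fraction=0.3,
        ),
    )


@dataclass(frozen=True)
class FragmentModelConfig:
    """Fragment field emulation: species mix plus primary attenuation length."""

    species: tuple[SpeciesConfig, ...] = field(default_factory=_default_species)
    mean_free_path: float = 250.0  # mm; order of the carbon nuclear MFP in water
    nozzle_region_z: tuple[float, float] = (-350.0, -150.0)

    def __post_init__(self):
        if self.mean_free_path <= 0:
            raise ValueError("mean_free_path must be positive")


def range_from_energy(energy_mev_u: float, alpha: float = 0.0022, p: float = 1.77) -> float:
    """Convenience power-law range-energy helper, R = alpha * E**p (mm).

    Bragg-Kleeman-style scaling for rough scenario setup; not calibrated to
    any specific beamline table.
    """
    return alpha * energy_mev_u**p


# ---------------------------------------------------------------------------
# Elementary sampling operations (scalar API; simulate_spill vectorizes)


def sample_primary(beam: BeamConfig, rng: np.random.Generator) -> Line3:
    """Draw one primary-beam line: Gaussian transverse anchor, +Z direction."""
    x = beam.spot_shift_x + beam.spot_sigma_x * rng.standard_normal()
    y = beam.spot_shift_y + beam.spot_sigma_y * rng.standard_normal()
    return Line3(Point3(x, y, 0.0), (0.0, 0.0, 1.0))


def _sample_depths(
    beam: BeamConfig, frag: FragmentModelConfig, rng: np.random.Generator, size: int
) -> np.ndarray:
    """In-field vertex depths: truncated-exponential density on [0, R_event]."""
    r_event = beam.nominal_range + beam.range_straggling_sigma * rng.standard_normal(size)
    r_event = np.clip(r_event, 1e-6, None)
    u = rng.random(size)
    lam = frag.mean_free_path
    return -lam * np.log1p(-u * (1.0 - np.exp(-r_event / lam)))


def sample_vertex_depth(
    beam: BeamConfig, frag: FragmentModelConfig, rng: np.random.Generator
) -> float:
    """Draw one in-field fragmentation depth (mm from the phantom entrance)."""
    return float(_sample_depths(beam, frag, rng, 1)[0])


def emit_fragment(
    vertex: Point3,
    species: SpeciesConfig,
    rng: np.random.Generator,
    remaining_path: float = 0.0,
    origin_class: str = "primary",
) -> Line3:
    """Emit one fragment ray from ``vertex``.

    Polar angle ~ |Normal(0, angular_sigma)| about +Z, uniform azimuth.  The
    anchor is displaced laterally by the exit-scattering Gaussian; secondary
    vertices get an extra isotropic smear so their back-projection is biased.
    """
    anchor = vertex.array.copy()
    if origin_class == "secondary":
        anchor += species.secondary_smear_sigma * rng.standard_normal(3)
    s = species.exit_scatter_sigma * math.sqrt(max(remaining_path, 0.0))
    anchor[:2] += s * rng.standard_normal(2)
    theta = abs(rng.normal(0.0, species.angular_sigma)) if species.angular_sigma > 0 else 0.0
    phi = rng.uniform(0.0, 2.0 * math.pi)
    d = np.array(
        [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
    )
    return Line3.through(anchor, d)


# ---------------------------------------------------------------------------
# Full spill simulation


@dataclass
class SpillResult:
    """List-mode output of one spill: tracker hits, SPM stream, ground truth.

    ``hits`` columns:  event_id, t, detector_id, iu, iv, x, y, z
    ``spm`` columns:   event_id, t, x, y, z
    ``truth`` columns: event_id, species, origin_class, x, y, z
    ``detector_id`` is 2*stack_index + (0 front / 1 back).
    """

    hits: pd.DataFrame
    spm: pd.DataFrame
    truth: pd.DataFrame
    metadata: dict


_TRUTH_COLS = ["event_id", "species", "origin_class", "x", "y", "z"]


def simulate_spill(
    beam: BeamConfig,
    phantom: PhantomConfig,
    frag: FragmentModelConfig,
    stack: StackGeometry,
    second_stack: StackGeometry | None = None,
    seed: int | None = None,
    event_period_ns: int = 1000,
    time_jitter_ns: float = 0.0,
    spm_half_aperture: float = 25.0,
) -> SpillResult:
    """Simulate one scanned beam spot and return list-mode streams.

    Per primary: a beam line is sampled and its SPM crossing recorded at the
    virtual plane Z = -100 mm; fragment production is Bernoulli-thinned per
    species; each emitted fragment ray is intersected with the tracker
    plane(s) and pixelated.  Ground truth is written for every emitted
    fragment.  Deterministic for a fixed seed.

    The SPM aperture (default +/-25 mm) is referenced to the steered beam
    axis: the diagnostics block sits in the nozzle downstream of the
    steering dipoles, so the scanned spot stays inside its active area.
    """
    if seed is None:
        seed = beam.seed
    stacks = [stack] + ([second_stack] if second_stack is not None else [])
    for st in stacks:
        if abs(float(st.front.center.z)) < phantom.exit_z:
            raise ValueError("tracker stack must sit outside the phantom")

    root = np.random.SeedSequence(seed)
    beam_rng, frag_rng = (np.random.default_rng(s) for s in root.spawn(2))
    species_seeds = np.random.SeedSequence(seed, spawn_key=(1,)).spawn(len(frag.species))

    n = int(beam.n_primaries)
    bx = beam.spot_shift_x + beam.spot_sigma_x * beam_rng.standard_normal(n)
    by = beam.spot_shift_y + beam.spot_sigma_y * beam_rng.standard_normal(n)
    event_ids = np.arange(n, dtype=np.int64)
    t_event = event_ids * np.int64(event_period_ns)

    in_aperture = (np.abs(bx - beam.spot_shift_x) <= spm_half_aperture) & (
        np.abs(by - beam.spot_shift_y) <= spm_half_aperture
    )
    spm = pd.DataFrame(
        {
            "event_id": event_ids[in_aperture],
            "t": t_event[in_aperture],
            "x": bx[in_aperture],
            "y": by[in_aperture],
            "z": np.full(int(in_aperture.sum()), SPM_PLANE_Z),
        }
    )

    hit_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []

    for sp, sp_seed in zip(frag.species, species_seeds):
        rng = np.random.default_rng(sp_seed)
        produced = rng.random(n) < sp.relative_yield
        idx = np.flatnonzero(produced)
        m = idx.size
        if m == 0:
            continue

        u_origin = rng.random(m)
        oof = u_origin < sp.out_of_field_fraction
        secondary = (~oof) & (
            rng.random(m) >= sp.primary_vertex_fraction
        )
        origin_class = np.where(oof, "out_of_field", np.where(secondary, "secondary", "primary"))

        depths = _sample_depths(beam, frag, rng, m)
        vz = phantom.entrance_z + depths
        z_lo, z_hi = frag.nozzle_region_z
        vz[oof] = rng.uniform(z_lo, z_hi, int(oof.sum()))
        vx = bx[idx].copy()
        vy = by[idx].copy()

        truth_frames.append(
            pd.DataFrame(
                {
                    "event_id": event_ids[idx],
                    "species": sp.name,
                    "origin_class": origin_class,
                    "x": vx,
                    "y": vy,
                    "z": vz,
                }
            )
        )

        # apparent emission point: secondary smear + exit scattering
        ax, ay, az = vx.copy(), vy.copy(), vz.copy()
        nsec = int(secondary.sum())
        if nsec:
            smear = sp.secondary_smear_sigma * rng.standard_normal((nsec, 3))
            ax[secondary] += smear[:, 0]
            ay[secondary] += smear[:, 1]
            az[secondary] += smear[:, 2]
        remaining = np.clip(phantom.exit_z - vz, 0.0, phantom.extent_z)
        s_scatter = sp.exit_scatter_sigma * np.sqrt(remaining)
        ax += s_scatter * rng.standard_normal(m)
        ay += s_scatter * rng.standard_normal(m)

        theta = np.abs(rng.normal(0.0, sp.angular_sigma, m))
        phi = rng.uniform(0.0, 2.0 * math.pi, m)
        dirs = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        anchors = np.column_stack([ax, ay, az])

        for k, st in enumerate(stacks):
            for j, plane in enumerate((st.front, st.back)):
                u, v, hit = intersect_plane_batch(anchors, dirs, plane)
                if not hit.any():
                    continue
                iu, iv, uc, vc = pixelate(u[hit], v[hit], plane)
                lab = plane.to_lab(uc, vc)
                t_hit = t_event[idx[hit]]
                if time_jitter_ns > 0:
                    t_hit = t_hit + np.rint(
                        rng.normal(0.0, time_jitter_ns, int(hit.sum()))
                    ).astype(np.int64)
                hit_frames.append(
                    pd.DataFrame(
                        {
                            "event_id": event_ids[idx[hit]],
                            "t": t_hit,
                            "detector_id": np.int64(2 * k + j),
                            "iu": iu,
                            "iv": iv,
                            "x": lab[:, 0],
                            "y": lab[:, 1],
                            "z": lab[:, 2],
                        }
                    )
                )

    _hit_dtypes = {
        "event_id": "int64",
        "t": "int64",
        "detector_id": "int64",
        "iu": "int64",
        "iv": "int64",
        "x": "float64",
        "y": "float64",
        "z": "float64",
    }
    hits = (
        pd.concat(hit_frames, ignore_index=True)
        if hit_frames
        else pd.DataFrame({c: pd.Series(dtype=dt) for c, dt in _hit_dtypes.items()})
    )
    if not hits.empty:
        hits = hits.sort_values(["event_id", "t", "detector_id"], kind="stable").reset_index(
            drop=True
        )
    truth = (
        pd.concat(truth_frames, ignore_index=True).sort_values("event_id", kind="stable").reset_index(drop=True)
        if truth_frames
        else pd.DataFrame(columns=_TRUTH_COLS)
    )

    metadata = {
        "seed": int(seed),
        "n_primaries": n,
        "geometry_hash": geometry_hash(stack),
        "nominal_range_mm": beam.nominal_range,
        "spot_shift_x_mm": beam.spot_shift_x,
        "spot_shift_y_mm": beam.spot_shift_y,
        "n_stacks": len(stacks),
    }
    return SpillResult(hits=hits, spm=spm, truth=truth, metadata=metadata)
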