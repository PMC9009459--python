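"""Depth-profile markers: erfc fit, Z50, boundaries, lateral Gaussian fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import erfc as sp_erfc

from ivims.profiles import (
    DepthProfile,
    ErfcFit,
    depth_profile,
    detect_boundaries,
    erfc_model,
    fit_erfc,
    fit_lateral,
    z50,
    z50_uncertainty,
)
from ivims.vertices import VertexCloud


def cloud_from_z(z, y=None, x=None):
    n = len(z)
    frame = pd.DataFrame(
        {
            "event_id": np.arange(n),
            "x": x if x is not None else np.zeros(n),
            "y": y if y is not None else np.zeros(n),
            "z": np.asarray(z, dtype=float),
            "miss": np.zeros(n),
        }
    )
    return VertexCloud(frame=frame, n_pairs=n)


def profile_from_model(p0, p1, p2, p3, lo=0.0, hi=160.0, noise_rng=None):
    edges = np.arange(lo, hi + 1.0, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = erfc_model(centers, p0, p1, p2, p3)
    counts = noise_rng.poisson(mu).astype(float) if noise_rng is not None else mu
    return DepthProfile(edges=edges, counts=counts, errors=np.sqrt(np.clip(counts, 1, None)))


def grid_search_erfc(prof, window):
    """Independent oracle: coarse (p2, p3) grid with exact linear (p0, p1)
    profiling, then Nelder-Mead polish of the full weighted SSE."""
    sel = (prof.centers >= window[0]) & (prof.centers < window[1])
    z, c = prof.centers[sel], prof.counts[sel]
    w = 1.0 / np.clip(c, 1.0, None)  # 1/sigma^2 with unit floor

    def sse(params):
        p0, p1, p2, p3 = params
        if p0 < 0 or p2 < 1e-3:
            return 1e30
        return float(np.sum(w * (c - erfc_model(z, p0, p1, p2, p3)) ** 2))

    best = None
    for p2g in np.linspace(1.0, 15.0, 15):
        for p3g in np.linspace(z[0], z[-1], 60):
            basis = sp_erfc((z - p3g) / p2g)
            A = np.column_stack([basis, np.ones_like(z)])
            aw = A * w[:, None]
            try:
                lin = np.linalg.solve(A.T @ aw, aw.T @ c)
            except np.linalg.LinAlgError:
                continue
            cand = (max(lin[0], 0.0), lin[1], p2g, p3g)
            s = sse(cand)
            if best is None or s < best[0]:
                best = (s, cand)
    res = minimize(sse, x0=best[1], method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 20_000})
    return res.x, res.fun


class TestFitErfc:
    def test_exact_model_data_recovered(self):
        prof = profile_from_model(60.0, 3.0, 4.0, 100.0)
        fit = fit_erfc(prof)
        assert fit.converged
        for got, true in zip((fit.p0, fit.p1, fit.p2, fit.p3), (60.0, 3.0, 4.0, 100.0)):
            assert got == pytest.approx(true, rel=1e-6)

    def test_no_distal_edge_rejected(self):
        edges = np.arange(0, 50.0, 1.0)
        counts = np.linspace(1, 100, len(edges) - 1)  # monotone rise
        prof = DepthProfile(edges=edges, counts=counts, errors=np.sqrt(counts))
        with pytest.raises(ValueError, match="distal"):
            fit_erfc(prof)

    def test_poisson_p3_within_three_stderr(self):
        rng = np.random.default_rng(5)
        prof = profile_from_model(60.0, 2.0, 4.0, 100.0, noise_rng=rng)
        fit = fit_erfc(prof)
        assert fit.converged
        assert abs(fit.p3 - 100.0) <= 3 * fit.stderr["p3"]

    def test_matches_grid_search_oracle(self):
        """Weighted fit == coarse-grid + polish oracle on random truth sets."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            p0 = rng.uniform(30, 120)
            p1 = rng.uniform(0, 8)
            p2 = rng.uniform(2, 8)
            p3 = rng.uniform(60, 120)
            prof = profile_from_model(p0, p1, p2, p3, noise_rng=rng)
            window = (p3 - 45.0, p3 + 45.0)
            fit = fit_erfc(prof, window=window)
            (o0, o1, o2, o3), sse_oracle = grid_search_erfc(prof, window)
            # same objective: the fit must not be worse than the oracle, and
            # the located inflection must agree within the polish resolution
            sel = (prof.centers >= window[0]) & (prof.centers < window[1])
            z, c = prof.centers[sel], prof.counts[sel]
            w = 1.0 / np.clip(c, 1.0, None)
            sse_fit = float(np.sum(w * (c - fit(z)) ** 2))
            assert sse_fit <= sse_oracle * (1 + 1e-6) + 1e-9
            assert fit.p3 == pytest.approx(o3, abs=0.05)


class TestZ50:
    def test_equals_p3_without_background(self):
        prof = profile_from_model(50.0, 0.0, 5.0, 90.0)
        fit = fit_erfc(prof)
        assert z50(fit) == pytest.approx(fit.p3, abs=1e-9)

    def test_background_shifts_z50_distally(self):
        """Bisection agrees with a dense-grid inverse; background moves Z50 distal."""
        fit0 = ErfcFit(p0=50.0, p1=0.0, p2=5.0, p3=90.0, window=(0.0, 160.0), converged=True)
        fitb = ErfcFit(p0=50.0, p1=10.0, p2=5.0, p3=90.0, window=(0.0, 160.0), converged=True)
        zb = z50(fitb)
        assert zb > z50(fit0)
        # dense-grid oracle for the crossing
        zz = np.linspace(60, 160, 2_000_001)
        half = 0.5 * (2 * 50.0 + 10.0)
        vals = erfc_model(zz, 50.0, 10.0, 5.0, 90.0)
        idx = np.argmax(vals < half)
        assert zb == pytest.approx(zz[idx], abs=1e-4)

    def test_nonconverged_fit_refused(self):
        fit = ErfcFit(p0=1, p1=0, p2=1, p3=10, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            z50(fit)

    def test_uncertainty_positive_for_wellposed_fit(self):
        rng = np.random.default_rng(8)
        prof = profile_from_model(60.0, 2.0, 4.0, 100.0, noise_rng=rng)
        fit = fit_erfc(prof)
        assert z50_uncertainty(fit) > 0


class TestDepthProfile:
    def test_single_vertex_single_bin(self):
        cloud = cloud_from_z([10.0 - 90.25])
        prof = depth_profile(cloud)
        assert prof.total == 1
        assert prof.counts.max() == 1

    def test_counts_conserved(self, small_sim):
        from ivims.pipeline import reconstruct_spill

        cloud, _, _ = reconstruct_spill(small_sim)
        prof = depth_profile(cloud, margin=2000.0)
        assert prof.total == len(cloud)

    def test_empty_cloud_rejected(self):
        cloud = cloud_from_z([])
        with pytest.raises(ValueError, match="empty"):
            depth_profile(cloud)

    def test_falloff_near_configured_range(self):
        """End-to-end spot at range 105.2 mm: distal half-max within 5 mm."""
        from ivims.pipeline import run_spot

        markers, _, _ = run_spot(105.2, seed=2026, n_primaries=100_000)
        assert abs(z50(markers.erfc) - 105.2) <= 5.0


class TestBoundaries:
    def test_uniform_density_recovers_phantom_extent(self, rng):
        z = rng.uniform(-90.25, 90.25, 40_000)
        prof = depth_profile(cloud_from_z(z))
        entrance, exit_ = detect_boundaries(prof)
        assert abs(entrance - 0.0) <= 1.0
        assert abs(exit_ - 180.5) <= 1.0

    def test_smeared_boxcar_bias_below_bin_width(self, rng):
        """2-mm Gaussian edge smear: interpolated crossings stay within a bin."""
        z = rng.uniform(-90.25, 90.25, 60_000) + rng.normal(0, 2.0, 60_000)
        prof = depth_profile(cloud_from_z(z))
        entrance, exit_ = detect_boundaries(prof)
        assert abs(entrance - 0.0) <= 1.0
        assert abs(exit_ - 180.5) <= 1.0

    def test_monotone_profile_rejected(self):
        edges = np.arange(0.0, 100.0, 1.0)
        counts = np.linspace(5, 500, len(edges) - 1)
        prof = DepthProfile(edges=edges, counts=counts, errors=np.sqrt(counts))
        with pytest.raises(ValueError, match="plateau|crossing"):
            detect_boundaries(prof)


class TestLateral:
    def test_symmetric_cloud_mean_near_zero(self, rng):
        cloud = cloud_from_z(rng.uniform(-80, 20, 5000), y=rng.normal(0, 2.0, 5000))
        fit = fit_lateral(cloud, axis="y")
        assert abs(fit.mean) <= 3 * fit.mean_err

    def test_mean_tracks_injected_shift(self, rng):
        """Linear response: fitted means reproduce the injected offsets."""
        shifts = [-10.0, -5.0, 0.0, 5.0, 10.0]
        means = []
        for i, s in enumerate(shifts):
            r = np.random.default_rng(40 + i)
            cloud = cloud_from_z(r.uniform(-80, 20, 4000), y=r.normal(s, 2.0, 4000))
            means.append(fit_lateral(cloud, axis="y").mean)
        slope = np.polyfit(shifts, means, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    def test_sigma_grows_with_scatter(self, rng):
        c1 = cloud_from_z(rng.uniform(-80, 20, 4000), y=rng.normal(0, 1.5, 4000))
        c2 = cloud_from_z(rng.uniform(-80, 20, 4000), y=rng.normal(0, 4.0, 4000))
        assert fit_lateral(c2, axis="y").sigma > fit_lateral(c1, axis="y").sigma

    def test_too_few_vertices_rejected(self, rng):
        cloud = cloud_from_z(rng.uniform(-80, 20, 30), y=rng.normal(0, 2, 30))
        with pytest.raises(ValueError, match="at least"):
            fit_lateral(cloud, axis="y")

    def test_vertical_fit_uses_trimmed_core(self, rng):
        # heavy-tailed vertical sample: core fit should stay near the core sigma
        core = rng.normal(0, 1.5, 8000)
        tails = rng.normal(0, 8.0, 2000)
        x = np.concatenate([core, tails])
        cloud = cloud_from_z(rng.uniform(-80, 20, 10_000), x=x)
        fit = fit_lateral(cloud, axis="x")
        assert fit.n_used < 10_000
        assert fit.sigma < 4.0
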