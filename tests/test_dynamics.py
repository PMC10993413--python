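"""Residence segments, lateral MSD, diffusivity fits, unwrapped paths."""

import numpy as np
import pytest

from samsurf.dynamics import (
    MsdCurve,
    ResidenceSegment,
    fit_diffusivity,
    ion_paths,
    lateral_msd,
    layer_resident_segments,
    normalized_diffusivity,
    unwrap_lateral,
)
from samsurf.traj_io import BoxSpec

from conftest import make_topology, make_trajectory


def traj_from_xyz(per_frame_xyz, box=BoxSpec(50, 50, 25), dt=1.0):
    n = len(per_frame_xyz[0])
    topo = make_topology(["ion"] * n)
    return make_trajectory([np.asarray(p, float) for p in per_frame_xyz], topo, box, dt=dt)


def single_ion_traj(xyz, **kw):
    return traj_from_xyz([[p] for p in xyz], **kw)


class TestResidenceSegments:
    def test_always_inside(self):
        traj = single_ion_traj([[1, 1, 5]] * 30)
        segs = layer_resident_segments(traj, [0], 0, 10, min_duration=1)
        assert len(segs) == 1 and (segs[0].start, segs[0].end) == (0, 29)

    def test_never_inside(self):
        traj = single_ion_traj([[1, 1, 15]] * 30)
        assert layer_resident_segments(traj, [0], 0, 10, min_duration=1) == []

    def test_constructed_crossings(self):
        """z-path leaving the layer at known frames yields exactly the
        constructed segments, with short visits filtered."""
        z = [5] * 10 + [15] * 3 + [5] * 4 + [15] * 2 + [5] * 12
        traj = single_ion_traj([[1, 1, zz] for zz in z])
        segs = layer_resident_segments(traj, [0], 0, 10, min_duration=5)
        assert [(s.start, s.end) for s in segs] == [(0, 9), (19, 30)]
        segs_all = layer_resident_segments(traj, [0], 0, 10, min_duration=1)
        assert [(s.start, s.end) for s in segs_all] == [(0, 9), (13, 16), (19, 30)]


class TestLateralMsd:
    def test_stationary_ion_zero_msd(self):
        traj = single_ion_traj([[3, 4, 5]] * 40)
        msd = lateral_msd(traj, [ResidenceSegment(0, 0, 39)], max_lag=10)
        np.testing.assert_allclose(msd.msd, 0.0, atol=1e-12)

    def test_ballistic_drift_exact(self):
        """Uniform drift v gives msd(t) = |v|^2 t^2 exactly."""
        v = np.array([0.3, -0.2])
        xyz = [[10 + v[0] * t, 20 + v[1] * t, 5] for t in range(50)]
        traj = single_ion_traj(xyz)
        msd = lateral_msd(traj, [ResidenceSegment(0, 0, 49)], max_lag=12)
        expected = (v @ v) * msd.lag_times**2
        np.testing.assert_allclose(msd.msd, expected, rtol=1e-9, atol=1e-9)

    def test_fft_equals_direct_oracle(self, rng):
        """The FFT time-origin-averaged MSD equals the brute-force double
        loop on a random walk."""
        xy = np.cumsum(rng.normal(size=(200, 2)), axis=0) + 25.0
        xy %= 50.0
        traj = traj_from_xyz([[p] for p in np.column_stack([xy, np.full(200, 5.0)])])
        msd = lateral_msd(traj, [ResidenceSegment(0, 0, 199)], max_lag=50)
        uw = unwrap_lateral(xy, 50.0, 50.0)
        for k in [1, 7, 23, 50]:
            direct = np.mean(np.sum((uw[k:] - uw[:-k]) ** 2, axis=1))
            assert msd.msd[k] == pytest.approx(direct, rel=1e-9)

    def test_segments_never_mix_across_boundaries(self):
        """An ion teleporting between residence segments contributes no
        displacement spanning the gap."""
        a = [[10 + 0.01 * t, 10, 5] for t in range(30)]
        b = [[40 + 0.01 * t, 40, 5] for t in range(30)]  # far away after gap
        traj = traj_from_xyz([[p] for p in a + b], box=BoxSpec(100, 100, 25))
        segs = [ResidenceSegment(0, 0, 29), ResidenceSegment(0, 30, 59)]
        msd = lateral_msd(traj, segs, max_lag=20)
        assert msd.msd.max() < 1.0  # teleport distance ~ 42 A would give ~1800

    def test_n_samples_non_increasing(self, rng):
        xy = np.cumsum(rng.normal(size=(100, 2)), axis=0) + 25
        traj = traj_from_xyz([[p] for p in np.column_stack([xy % 50, np.full(100, 5.0)])])
        msd = lateral_msd(traj, [ResidenceSegment(0, 0, 99)], max_lag=30)
        assert np.all(np.diff(msd.n_samples) <= 0)
        assert msd.msd[0] == 0.0


class TestFitDiffusivity:
    def test_exact_slope(self):
        """msd = 0.4 t in 2D means D = 0.1 A^2/ps = 1.0e-9 m^2/s exactly."""
        t = np.arange(0, 101, dtype=float)
        msd = MsdCurve(lag_times=t, msd=0.4 * t, n_samples=np.full(101, 100), dimensionality=2)
        res = fit_diffusivity(msd)
        assert res.D == pytest.approx(0.1, rel=1e-12)
        assert res.D_1e9_m2_s == pytest.approx(1.0, rel=1e-12)

    def test_unit_identity_everywhere(self, rng):
        t = np.arange(0, 51, dtype=float)
        msd = MsdCurve(lag_times=t, msd=rng.random(51).cumsum(), n_samples=np.full(51, 10),
                       dimensionality=2)
        res = fit_diffusivity(msd)
        assert res.D_1e9_m2_s == pytest.approx(10.0 * res.D, rel=1e-15)

    def test_negative_slope_clamped(self):
        t = np.arange(0, 21, dtype=float)
        msd = MsdCurve(lag_times=t, msd=10.0 - 0.3 * t, n_samples=np.full(21, 5),
                       dimensionality=2)
        res = fit_diffusivity(msd)
        assert res.D == 0.0 and res.clamped

    def test_window_too_small_rejected(self):
        t = np.arange(0, 5, dtype=float)
        msd = MsdCurve(lag_times=t, msd=t, n_samples=np.full(5, 5), dimensionality=2)
        with pytest.raises(ValueError, match="fit window"):
            fit_diffusivity(msd, fit_window=(3.2, 3.4))


def test_free_diffusion_recovery_small():
    """BD free diffusion at D=0.1 A^2/ps is recovered by the MSD fit within
    the sampling error of this problem size (300 ions x 600 frames)."""
    from samsurf import studies

    out = studies.free_diffusion_study(seed=123, n_ions=300, n_frames=600)
    assert out["rel_error_pct"] < 8.0


class TestNormalizedDiffusivity:
    def test_equal_inputs(self):
        assert normalized_diffusivity(0.05, 0.05) == 1.0

    def test_zero_layer(self):
        assert normalized_diffusivity(0.0, 0.1) == 0.0

    def test_nonpositive_bulk_rejected(self):
        with pytest.raises(ValueError):
            normalized_diffusivity(0.1, 0.0)


class TestIonPaths:
    def test_single_frame_single_point(self):
        traj = single_ion_traj([[1, 2, 3]])
        (trace,) = ion_paths(traj, [0])
        assert trace.xy.shape == (1, 2) and trace.path_length == 0.0

    def test_unwrap_continuity_across_boundary(self):
        """A path crossing the periodic x boundary unwraps without jumps
        larger than half a box length."""
        lx = 50.0
        xs = (np.arange(60, dtype=float) * 1.2 + 45.0) % lx
        traj = traj_from_xyz([[[x, 10.0, 5.0]] for x in xs])
        (trace,) = ion_paths(traj, [0])
        steps = np.abs(np.diff(trace.xy[:, 0]))
        assert steps.max() < lx / 2
        np.testing.assert_allclose(np.diff(trace.xy[:, 0]), 1.2, atol=1e-9)

    def test_path_length_additivity(self, rng):
        xy = np.cumsum(rng.normal(size=(80, 2)), axis=0) + 25
        traj = traj_from_xyz([[p] for p in np.column_stack([xy % 50, np.full(80, 5.0)])])
        (trace,) = ion_paths(traj, [0])
        manual = np.linalg.norm(np.diff(trace.xy, axis=0), axis=1).sum()
        assert trace.path_length == pytest.approx(manual, rel=1e-12)

    def test_unknown_ion_rejected(self):
        traj = single_ion_traj([[1, 2, 3]])
        with pytest.raises(ValueError, match="unknown ion"):
            ion_paths(traj, [5])
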