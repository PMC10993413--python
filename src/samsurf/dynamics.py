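"""Bound-layer diffusivity from mean-squared displacement, and ion paths.

Ions enter and leave the bound layer, so "diffusivity in the bound
layer" is estimated over residence segments: maximal runs of consecutive
frames with the ion's z inside the layer, short runs discarded.  The MSD
is time-origin averaged over PBC-unwrapped lateral (x,y) displacements
with origins and lags confined to single segments, and the diffusion
coefficient follows from the Einstein relation MSD(t) = 2*d*D*t fitted
over an interior lag window.

D is reported in A^2/ps and in 1e-9 m^2/s (exact factor 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from samsurf.constants import D_A2_PS_TO_1E9_M2_S
from samsurf.traj_io import Trajectory


@dataclass
class ResidenceSegment:
    """Maximal run of frames an ion spends inside [z_lo, z_hi]."""

    ion_id: int
    start: int  # first frame index (inclusive)
    end: int  # last frame index (inclusive)

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass
class MsdCurve:
    lag_times: np.ndarray  # ps, starting at 0
    msd: np.ndarray  # A^2
    n_samples: np.ndarray  # displacement pairs per lag
    dimensionality: int


@dataclass
class DiffusivityResult:
    D: float  # A^2/ps
    D_1e9_m2_s: float  # exactly 10 * D
    fit_window: tuple[float, float]  # ps
    slope_stderr: float
    dimensionality: int
    clamped: bool = False
    normalized_ratio: float | None = None


@dataclass
class PathTrace:
    ion_id: int
    xy: np.ndarray  # unwrapped, (n, 2) A
    times: np.ndarray  # ps

    @property
    def path_length(self) -> float:
        if len(self.xy) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.xy, axis=0), axis=1).sum())


def layer_resident_segments(
    traj: Trajectory,
    ion_selection: np.ndarray,
    z_lo: float,
    z_hi: float,
    min_duration: int = 10,
) -> list[ResidenceSegment]:
    """Residence segments of each selected ion in the slab [z_lo, z_hi].

    ``min_duration`` is the minimum segment length in frames; shorter
    visits are discarded as transient excursions.
    """
    if not z_lo < z_hi:
        raise ValueError(f"need z_lo < z_hi, got {z_lo}, {z_hi}")
    segments: list[ResidenceSegment] = []
    z = traj.positions_of(np.asarray(ion_selection, dtype=int))[:, :, 2]
    for col, ion in enumerate(np.asarray(ion_selection, dtype=int)):
        inside = (z[:, col] >= z_lo) & (z[:, col] <= z_hi)
        padded = np.concatenate([[False], inside, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
        for s, e in zip(starts, ends):
            if e - s + 1 >= min_duration:
                segments.append(ResidenceSegment(ion_id=int(ion), start=int(s), end=int(e)))
    return segments


def unwrap_lateral(xy: np.ndarray, lx: float, ly: float) -> np.ndarray:
    """Remove periodic x,y jumps from a wrapped coordinate series.

    Assumes physical per-frame displacements below half a box length, the
    standard unwrapping condition.
    """
    xy = np.asarray(xy, dtype=float)
    d = np.diff(xy, axis=0)
    for axis, length in enumerate((lx, ly)):
        d[:, axis] -= length * np.round(d[:, axis] / length)
    out = np.empty_like(xy)
    out[0] = xy[0]
    out[1:] = xy[0] + np.cumsum(d, axis=0)
    return out


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one coordinate series via autocorrelation.

    Standard O(N log N) decomposition msd(k) = S1(k) - 2*S2(k) with S2 the
    FFT autocorrelation.
    """
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conjugate(fx), nfft)[:n].real
    x2 = x * x
    css = np.concatenate([[0.0], np.cumsum(x2)])
    total = css[-1]
    k = np.arange(n)
    # sum over origins i of x_i^2 + x_{i+k}^2
    s1 = css[n - k] + (total - css[k])
    counts = n - k
    return s1 / counts - 2.0 * acf / counts


def lateral_msd(traj: Trajectory, segments: list[ResidenceSegment], max_lag: int) -> MsdCurve:
    """Pooled lateral MSD over residence segments.

    Each segment contributes displacement pairs for lags up to
    min(max_lag, segment length - 1); origins never cross segment
    boundaries, so exits and re-entries cannot contaminate the estimate.
    """
    if not segments:
        raise ValueError("no residence segments supplied")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1 frame")
    longest = max(s.n_frames for s in segments)
    if max_lag >= longest:
        raise ValueError(
            f"max_lag {max_lag} must be shorter than the longest segment ({longest} frames)"
        )
    times = traj.times
    dts = np.diff(times)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("lateral_msd requires uniformly spaced frames")
    dt = float(dts[0]) if len(dts) else 0.0
    box = traj.box
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for seg in segments:
        frames = slice(seg.start, seg.end + 1)
        xy_w = np.array([traj.frames[i].positions[seg.ion_id, :2] for i in range(seg.start, seg.end + 1)])
        xy = unwrap_lateral(xy_w, box.lx, box.ly)
        L = len(xy)
        m = _msd_fft_1d(xy[:, 0]) + _msd_fft_1d(xy[:, 1])
        lags = min(max_lag, L - 1)
        k = np.arange(lags + 1)
        sums[: lags + 1] += m[: lags + 1] * (L - k)
        counts[: lags + 1] += L - k
    if counts[1:].sum() == 0:
        raise ValueError("no valid (origin, lag) pairs")
    msd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    msd[0] = 0.0
    return MsdCurve(
        lag_times=dt * np.arange(max_lag + 1),
        msd=msd,
        n_samples=counts,
        dimensionality=2,
    )


def fit_diffusivity(
    msd: MsdCurve, fit_window: tuple[float, float] | None = None
) -> DiffusivityResult:
    """Einstein-relation fit D = slope / (2 * dim) over a lag window (ps).

    The default window is the interior [10%, 50%] of the maximum lag,
    avoiding the short-time regime and the poorly sampled long-lag tail.
    A negative fitted slope is clamped to D = 0 with a flag.
    """
    t_max = float(msd.lag_times[-1])
    if fit_window is None:
        fit_window = (0.1 * t_max, 0.5 * t_max)
    lo, hi = fit_window
    mask = (msd.lag_times >= lo) & (msd.lag_times <= hi) & np.isfinite(msd.msd)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 lag points in the fit window")
    res = stats.linregress(msd.lag_times[mask], msd.msd[mask])
    D = res.slope / (2.0 * msd.dimensionality)
    clamped = False
    if D < 0:
        D = 0.0
        clamped = True
    return DiffusivityResult(
        D=float(D),
        D_1e9_m2_s=float(D) * D_A2_PS_TO_1E9_M2_S,
        fit_window=(float(lo), float(hi)),
        slope_stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        dimensionality=msd.dimensionality,
        clamped=clamped,
    )


def normalized_diffusivity(D_layer: float, D_bulk: float) -> float:
    """Bound-layer diffusivity over its bulk value (dimensionless).

    ``D_bulk`` typically comes from a potential-free companion run at the
    same Brownian-dynamics parameters.
    """
    if D_bulk <= 0:
        raise ValueError(f"D_bulk must be > 0, got {D_bulk}")
    return D_layer / D_bulk


def ion_paths(
    traj: Trajectory, ion_ids: list[int], stride: int = 1
) -> list[PathTrace]:
    """Unwrapped, stride-decimated lateral paths of individual ions."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = traj.topology.n_atoms
    box = traj.box
    traces = []
    times = traj.times
    for ion in ion_ids:
        if not 0 <= ion < n:
            raise ValueError(f"unknown ion id {ion} (topology has {n} atoms)")
        xy_w = np.array([f.positions[ion, :2] for f in traj.frames])
        xy = unwrap_lateral(xy_w, box.lx, box.ly)
        traces.append(PathTrace(ion_id=int(ion), xy=xy[::stride], times=times[::stride]))
    return traces
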