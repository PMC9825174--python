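"""Kymograph line tracking.

Extracts particle position-versus-time tracks from space-time (kymograph)
images by per-frame 1D Gaussian fitting of fluorescent line profiles, links
detections frame to frame, and re-joins track segments interrupted by
fluorophore blinking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "Kymograph",
    "Trajectory",
    "track_lines",
    "merge_blink_gaps",
]


@dataclass
class Kymograph:
    """Space-time fluorescence image of a stretched DNA molecule.

    ``data`` has shape (space pixels, time frames); column ``j`` is the line
    profile recorded during frame ``j``.
    """

    data: np.ndarray
    pixel_size: float  # um per pixel
    frame_interval: float  # s per frame
    channel: str = "default"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("kymograph must be a non-empty 2D array")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("kymograph intensities must be finite and >= 0")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def extent_um(self) -> float:
        return self.n_pixels * self.pixel_size


@dataclass
class Trajectory:
    """Time-ordered positions of one labeled particle on DNA.

    Frames may be non-contiguous (blink gaps). Times are derived from frame
    indices via ``frame_interval``; positions are in micrometers.
    """

    particle_id: int
    channel: str
    frames: np.ndarray  # int frame indices, strictly increasing
    positions_um: np.ndarray
    frame_interval: float
    amplitudes: np.ndarray | None = None
    sigmas_px: np.ndarray | None = None
    censored_end: bool = False
    merged_gaps: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.size != self.positions_um.size:
            raise ValueError("frames and positions must have equal length")
        if self.frames.size == 0:
            raise ValueError("trajectory must contain at least one sample")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.sigmas_px is not None:
            self.sigmas_px = np.asarray(self.sigmas_px, dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval

    @property
    def start_s(self) -> float:
        return float(self.frames[0] * self.frame_interval)

    @property
    def end_s(self) -> float:
        return float(self.frames[-1] * self.frame_interval)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __len__(self) -> int:
        return int(self.frames.size)

    def is_contiguous(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))


def _gaussian_profile(x: np.ndarray, amp: float, center: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _fit_peak(
    column: np.ndarray, peak_idx: int, background: float, psf_sigma_guess: float
) -> tuple[float, float, float] | None:
    """Fit a 1D Gaussian around one candidate peak; returns (center, amp, sigma)."""
    half = max(3, int(np.ceil(4 * psf_sigma_guess)))
    lo = max(0, peak_idx - half)
    hi = min(column.size, peak_idx + half + 1)
    x = np.arange(lo, hi, dtype=float)
    y = column[lo:hi] - background
    amp0 = max(column[peak_idx] - background, 1e-12)
    try:
        popt, _ = curve_fit(
            _gaussian_profile,
            x,
            y,
            p0=(amp0, float(peak_idx), psf_sigma_guess),
            bounds=((0, lo - 1.0, 0.2), (np.inf, hi + 0.0, 5 * psf_sigma_guess + 2)),
            maxfev=2000,
        )
    except RuntimeError:
        # fall back to an intensity-weighted centroid
        w = np.clip(y, 0, None)
        if w.sum() <= 0:
            return None
        return float(np.sum(x * w) / w.sum()), float(amp0), psf_sigma_guess
    amp, center, sigma = popt
    if not (lo - 1 <= center <= hi):
        return None
    return float(center), float(amp), float(sigma)


def track_lines(
    kymograph: Kymograph,
    detection_threshold: float = 5.0,
    min_track_frames: int = 10,
    psf_sigma_guess: float = 1.2,
    link_gate_px: float = 3.0,
) -> list[Trajectory]:
    """Track fluorescent lines through a kymograph.

    Per frame, pixels rising more than ``detection_threshold`` background-noise
    standard deviations above the frame background (median of the column) are
    treated as candidate peaks and refined by a 1D Gaussian fit. Sub-pixel
    centers are linked frame to frame by nearest neighbor within
    ``link_gate_px`` pixels (ties broken by smaller displacement); a track ends
    on the first frame without a match. Tracks spanning fewer than
    ``min_track_frames`` frames are discarded.

    An all-blank kymograph yields an empty list, not an error.
    """
    if detection_threshold <= 0:
        raise ValueError("detection_threshold must be > 0")
    img = kymograph.data
    n_px, n_frames = img.shape

    # active track state: list of dicts with last position/frame + samples
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0

    for j in range(n_frames):
        col = img[:, j]
        background = float(np.median(col))
        mad = float(np.median(np.abs(col - background)))
        noise_sd = 1.4826 * mad
        if noise_sd <= 0:
            # noiseless rendering: any excursion above background is real
            noise_sd = max(1e-9, 1e-6 * max(col.max() - background, 1.0))
        height = background + detection_threshold * noise_sd
        peaks, _ = find_peaks(col, height=height)
        detections = []
        for p in peaks:
            fit = _fit_peak(col, int(p), background, psf_sigma_guess)
            if fit is not None:
                detections.append(fit)

        # nearest-neighbor linking against tracks present in the previous frame
        still_active: list[dict] = []
        used = [False] * len(detections)
        # greedy over (track, detection) pairs sorted by displacement
        pairs = []
        for ti, tr in enumerate(active):
            for di, det in enumerate(detections):
                d = abs(det[0] - tr["positions_px"][-1])
                if d <= link_gate_px:
                    pairs.append((d, ti, di))
        pairs.sort()
        matched_tracks = set()
        for d, ti, di in pairs:
            if ti in matched_tracks or used[di]:
                continue
            tr = active[ti]
            c, a, s = detections[di]
            tr["frames"].append(j)
            tr["positions_px"].append(c)
            tr["amps"].append(a)
            tr["sigmas"].append(s)
            matched_tracks.add(ti)
            used[di] = True
        for ti, tr in enumerate(active):
            if ti in matched_tracks:
                still_active.append(tr)
            else:
                finished.append(tr)
        for di, det in enumerate(detections):
            if not used[di]:
                c, a, s = det
                still_active.append(
                    {
                        "id": next_id,
                        "frames": [j],
                        "positions_px": [c],
                        "amps": [a],
                        "sigmas": [s],
                    }
                )
                next_id += 1
        active = still_active
    finished.extend(active)

    out: list[Trajectory] = []
    for tr in finished:
        if len(tr["frames"]) < min_track_frames:
            continue
        out.append(
            Trajectory(
                particle_id=tr["id"],
                channel=kymograph.channel,
                frames=np.array(tr["frames"]),
                positions_um=np.array(tr["positions_px"]) * kymograph.pixel_size,
                frame_interval=kymograph.frame_interval,
                amplitudes=np.array(tr["amps"]),
                sigmas_px=np.array(tr["sigmas"]),
                censored_end=tr["frames"][-1] == n_frames - 1,
            )
        )
    out.sort(key=lambda t: (t.frames[0], t.positions_um[0]))
    for new_id, t in enumerate(out):
        t.particle_id = new_id
    return out


def merge_blink_gaps(
    tracks: list[Trajectory],
    max_gap: float = 2.0,
    max_position_jump: float = 0.5,
) -> list[Trajectory]:
    """Re-join track segments separated by short dark (blink) gaps.

    A pair (A ends, B starts) is merged when the dark interval satisfies
    0 < gap < ``max_gap`` seconds (strict upper bound) and the positions at
    the junction differ by at most ``max_position_jump`` micrometers. Merging
    is applied transitively and the operation is idempotent. Segments of the
    same channel overlapping in time at the same position raise a consistency
    error only if they share a particle id.
    """
    if not tracks:
        return []
    dt = tracks[0].frame_interval
    for t in tracks:
        if t.frame_interval != dt:
            raise ValueError("all tracks must share one frame interval")
    segs = sorted(tracks, key=lambda t: (t.frames[0], t.particle_id))
    seen: dict[int, Trajectory] = {}
    for t in segs:
        if t.particle_id in seen:
            other = seen[t.particle_id]
            if t.frames[0] <= other.frames[-1]:
                raise ValueError(
                    f"track id {t.particle_id} has time-overlapping segments"
                )
        seen[t.particle_id] = t

    # repeatedly merge the closest-in-time eligible (end, start) pair; this is
    # transitive (a merged track can merge again) and idempotent (a second
    # pass finds no eligible pair)
    while True:
        best: tuple[float, float, int, int] | None = None
        for i, a in enumerate(segs):
            for j, b in enumerate(segs):
                if i == j:
                    continue
                gap_s = (b.frames[0] - a.frames[-1]) * dt
                jump = abs(b.positions_um[0] - a.positions_um[-1])
                if 0 < gap_s < max_gap and jump <= max_position_jump:
                    key = (gap_s, jump, i, j)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        _, _, i, j = best
        joined = _concatenate(segs[i], segs[j])
        segs = [s for k, s in enumerate(segs) if k not in (i, j)]
        segs.append(joined)
        segs.sort(key=lambda t: (t.frames[0], t.particle_id))
    return segs


def _concatenate(a: Trajectory, b: Trajectory) -> Trajectory:
    def _cat(x, y):
        if x is None or y is None:
            return None
        return np.concatenate([x, y])

    return Trajectory(
        particle_id=a.particle_id,
        channel=a.channel,
        frames=np.concatenate([a.frames, b.frames]),
        positions_um=np.concatenate([a.positions_um, b.positions_um]),
        frame_interval=a.frame_interval,
        amplitudes=_cat(a.amplitudes, b.amplitudes),
        sigmas_px=_cat(a.sigmas_px, b.sigmas_px),
        censored_end=b.censored_end,
        merged_gaps=a.merged_gaps + b.merged_gaps + 1,
    )
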