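"""Motion-phase segmentation, MSD computation, and anomalous-diffusion fitting.

For each motile phase the time-averaged mean squared displacement

    MSD(n dt) = 1/(N - n) * sum_{i=1}^{N-n} (x_{i+n} - x_i)**2

is fit with the one-dimensional anomalous diffusion model

    MSD(n dt) = 2 * D * (n dt)**alpha + y

where D is the diffusion coefficient (um^2/s), alpha the anomalous exponent
(alpha = 1 Brownian, alpha = 2 ballistic) and y a constant intercept absorbing
localization noise. Fits with R^2 < 0.8 or using less than 10% of the MSD
curve are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .tracking import Trajectory

__all__ = [
    "MsdCurve",
    "DiffusionFit",
    "MotionPhase",
    "compute_msd",
    "fit_diffusion",
    "segment_phases",
    "classify_behavior",
]

R2_ACCEPT = 0.8
MIN_CURVE_FRACTION = 0.10


@dataclass
class MsdCurve:
    phase_id: int
    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    n_frames: int  # N, total frames in the phase
    lags: np.ndarray  # n values used

    def __post_init__(self) -> None:
        self.lag_times_s = np.asarray(self.lag_times_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be >= 0")
        if np.any(self.lags < 1) or self.lags.size > self.n_frames - 1:
            raise ValueError("lags must be 1..N-1")

    @property
    def curve_fraction(self) -> float:
        """Fraction of the full MSD curve (lags 1..N-1) covered."""
        return self.lags.max() / (self.n_frames - 1)


@dataclass
class DiffusionFit:
    D_um2_s: float
    alpha: float
    intercept_um2: float
    r_squared: float
    curve_fraction: float
    accepted: bool
    message: str = ""

    @property
    def log10_D(self) -> float:
        return float(np.log10(self.D_um2_s)) if self.D_um2_s > 0 else float("-inf")


@dataclass
class MotionPhase:
    track_id: int
    start_frame: int
    end_frame: int  # inclusive
    label: str  # "motile" | "stationary"
    msd: MsdCurve | None = None
    fit: DiffusionFit | None = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def compute_msd(
    positions: np.ndarray,
    frame_interval: float,
    max_lag_fraction: float = 0.25,
    phase_id: int = 0,
    frames: np.ndarray | None = None,
) -> MsdCurve:
    """Time-averaged MSD of a uniformly sampled 1D position series.

    Positions must come from a contiguous (gap-free) phase; merged blink gaps
    break phases rather than being interpolated across. Passing the frame
    indices enables the uniform-sampling check.
    """
    if frames is not None and np.any(np.diff(np.asarray(frames)) != 1):
        raise ValueError("positions must be uniformly sampled (no gaps)")
    positions = np.asarray(positions, dtype=float)
    N = positions.size
    if N < 2:
        raise ValueError("need at least 2 positions")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    max_lag = max(1, int(np.floor(max_lag_fraction * N)))
    max_lag = min(max_lag, N - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k, n in enumerate(lags):
        d = positions[n:] - positions[:-n]
        msd[k] = np.mean(d * d)
    return MsdCurve(
        phase_id=phase_id,
        lag_times_s=lags * frame_interval,
        msd_um2=msd,
        n_frames=N,
        lags=lags,
    )


def _msd_model(t, D, alpha, y):
    return 2.0 * D * t**alpha + y


def fit_diffusion(msd: MsdCurve) -> DiffusionFit:
    """Weighted least-squares fit of 2*D*(n dt)**alpha + y to an MSD curve.

    The standard deviation of a time-averaged MSD point grows with its
    magnitude and shrinks with the number of averaged displacement pairs
    (N - n), so points are weighted by sqrt(N - n) / MSD(n). This suppresses
    the long-lag tail where the curve is dominated by a few correlated
    displacement pairs and keeps single-trajectory D estimates unbiased.
    alpha is bounded to (0, 2]; D >= 0; y free. The accepted flag applies the
    R^2 >= 0.8 and >= 10% curve-coverage filter. A fit that fails to converge
    is returned rejected with a diagnostic message, not raised.
    """
    if msd.lags.size < 4:
        raise ValueError("need at least 4 MSD points to fit")
    t = msd.lag_times_s
    y_data = msd.msd_um2
    weights = np.sqrt((msd.n_frames - msd.lags).astype(float)) / np.clip(
        y_data, 1e-12, None
    )

    span = t[-1] - t[0]
    d0 = max((y_data[-1] - y_data[0]) / (2 * span), 1e-9) if span > 0 else 1e-9
    model = Model(_msd_model)
    params = model.make_params(
        D=dict(value=d0, min=0.0),
        alpha=dict(value=1.0, min=1e-6, max=2.0),
        y=dict(value=float(y_data[0])),
    )
    try:
        result = model.fit(y_data, params, t=t, weights=weights)
    except Exception as exc:  # lmfit raises on pathological inputs
        return DiffusionFit(
            D_um2_s=float("nan"),
            alpha=float("nan"),
            intercept_um2=float("nan"),
            r_squared=0.0,
            curve_fraction=msd.curve_fraction,
            accepted=False,
            message=f"fit failed: {exc}",
        )
    fitted = result.best_fit
    ss_res = float(np.sum((y_data - fitted) ** 2))
    ss_tot = float(np.sum((y_data - y_data.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-18 else 0.0)
    alpha = float(result.params["alpha"].value)
    message = ""
    if alpha >= 2.0 - 1e-9 or alpha <= 1e-6 + 1e-9:
        message = "alpha at bound"
    accepted = r2 >= R2_ACCEPT and msd.curve_fraction >= MIN_CURVE_FRACTION
    return DiffusionFit(
        D_um2_s=float(result.params["D"].value),
        alpha=alpha,
        intercept_um2=float(result.params["y"].value),
        r_squared=r2,
        curve_fraction=msd.curve_fraction,
        accepted=accepted,
        message=message,
    )


def _window_is_motile(
    positions: np.ndarray, localization_sigma: float, noise_factor: float
) -> bool:
    """Short-lag MSD against the localization-noise floor 4*sigma_loc**2."""
    msds = []
    for n in (1, 2, 3):
        if positions.size > n:
            d = positions[n:] - positions[:-n]
            msds.append(np.mean(d * d))
    if not msds:
        return False
    return float(np.mean(msds)) > noise_factor * 4.0 * localization_sigma**2


def segment_phases(
    track: Trajectory,
    window_frames: int = 10,
    localization_sigma: float = 0.02,
    noise_factor: float = 3.0,
    min_phase_frames: int = 10,
    max_lag_fraction: float = 0.25,
) -> list[MotionPhase]:
    """Segment a track into motile and stationary phases.

    A sliding window is labeled motile when its empirical MSD at lags 1-3
    exceeds the localization-noise floor 4*sigma_loc**2 by ``noise_factor``;
    each frame takes the majority label of the windows covering it, and
    contiguous same-label frames form one phase. Tracks shorter than
    ``min_phase_frames`` return no phases; tracks shorter than the window are
    labeled as a single phase by the whole-track criterion. Blink gaps break
    phases (each contiguous run is segmented separately). Motile phases carry
    their MSD curve and diffusion fit.
    """
    if len(track) < min_phase_frames:
        return []
    phases: list[MotionPhase] = []
    # split at blink gaps: contiguous runs of frames
    breaks = np.nonzero(np.diff(track.frames) > 1)[0]
    run_bounds = np.concatenate([[0], breaks + 1, [len(track)]])
    next_phase_id = 0
    for r0, r1 in zip(run_bounds[:-1], run_bounds[1:]):
        pos = track.positions_um[r0:r1]
        frames = track.frames[r0:r1]
        n = pos.size
        if n < min_phase_frames:
            continue
        if n <= window_frames:
            label = (
                "motile"
                if _window_is_motile(pos, localization_sigma, noise_factor)
                else "stationary"
            )
            labels = np.full(n, label == "motile")
        else:
            votes = np.zeros(n)
            cover = np.zeros(n)
            for s in range(n - window_frames + 1):
                w = pos[s : s + window_frames]
                m = _window_is_motile(w, localization_sigma, noise_factor)
                votes[s : s + window_frames] += m
                cover[s : s + window_frames] += 1
            labels = votes / cover > 0.5
        # contiguous same-label runs -> phases
        change = np.nonzero(np.diff(labels.astype(int)))[0]
        bounds = np.concatenate([[0], change + 1, [n]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            label = "motile" if labels[b0] else "stationary"
            phase = MotionPhase(
                track_id=track.particle_id,
                start_frame=int(frames[b0]),
                end_frame=int(frames[b1 - 1]),
                label=label,
            )
            seg = pos[b0:b1]
            if seg.size >= 2:
                phase.msd = compute_msd(
                    seg,
                    track.frame_interval,
                    max_lag_fraction=max_lag_fraction,
                    phase_id=next_phase_id,
                )
                if label == "motile" and phase.msd.lags.size >= 4:
                    phase.fit = fit_diffusion(phase.msd)
            phases.append(phase)
            next_phase_id += 1
    return phases


def classify_behavior(
    tracks: list[Trajectory],
    phases: dict[int, list[MotionPhase]],
    observation_window: float,
) -> dict[str, int]:
    """2x2 behavior counts: {motile, stationary} x {persistent, dissociated}.

    A particle is motile if any of its phases is motile with an accepted
    diffusion fit; it has dissociated if its track ends before the observation
    window (not end-censored). Counts sum to the number of particles.
    """
    counts = {
        "motile_persistent": 0,
        "motile_dissociated": 0,
        "stationary_persistent": 0,
        "stationary_dissociated": 0,
    }
    for t in tracks:
        t_phases = phases.get(t.particle_id, [])
        motile = any(
            p.label == "motile" and p.fit is not None and p.fit.accepted
            for p in t_phases
        )
        dissociated = not (t.censored_end or t.end_s >= observation_window)
        key = ("motile" if motile else "stationary") + "_" + (
            "dissociated" if dissociated else "persistent"
        )
        counts[key] += 1
    return counts
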