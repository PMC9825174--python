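"""Synthetic single-molecule data with known ground truth.

Generates particle trajectories on stretched DNA, kymograph renderings, dwell
tables, damage-site layouts, and binding isotherms emulating single-molecule
glycosylase experiments: DNA tightropes carrying one abasic site every 2 kb,
lambda-DNA substrates with fiducially marked lesion sites, exponential binding
lifetimes from seconds to ~10^3 s, GFP-like photobleaching (~40 s), blinking
gaps shorter than 2 s, frame rates of 10-30 fps, 1D diffusion with
D ~ 2e-2 um^2/s and anomalous exponent alpha ~ 1-1.3, and ligand-depletion
binding curves with Kd between ~2 and ~32 nM at 8 nM DNA.

Anomalous motion uses exact-covariance fractional Gaussian noise so that the
simulated displacement variance obeys Var[x(t+d)-x(t)] = 2 D d**alpha, the
stationary power-law scaling presumed by the MSD fit 2 D (n dt)**alpha + y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .colocalization import FiducialMap
from .equilibria import BindingPoint, fraction_bound_model
from .tracking import Kymograph, Trajectory

__all__ = [
    "SimulationConfig",
    "ParticleTruth",
    "GroundTruth",
    "simulate_trajectories",
    "render_kymograph",
    "simulate_dwell_times",
    "make_damage_layout",
    "lambda_fiducial_layout",
    "simulate_isotherm",
    "fractional_gaussian_noise",
]

KB_TO_UM_BFORM = 0.34  # B-form DNA helical rise, um per kb


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic generator.

    Defaults emulate a 5-minute movie at 10 frames per second of GFP-tagged
    glycosylase molecules on a lambda-length DNA substrate: mean binding
    lifetime 2.8 s, GFP bleach lifetime 40.4 s, sub-2-s blink gaps, 11% of
    particles motile with D = 2.11e-2 um^2/s. Lifetimes set to ``inf`` disable
    that removal process.
    """

    frame_interval: float = 0.1  # s per frame (10 fps)
    n_frames: int = 3000  # 300 s movie
    diffusion_coefficient: float = 2.11e-2  # um^2/s
    alpha: float = 1.0  # anomalous exponent, (0, 2]
    localization_sigma: float = 0.02  # um
    bind_lifetime: float = 2.8  # s, exponential mean; inf disables
    bleach_lifetime: float = 40.4  # s; inf disables
    blink_on_lifetime: float = 20.0  # s
    blink_off_lifetime: float = 0.5  # s (gaps well below the 2 s merge rule)
    photon_rate: float = 5000.0  # photons/s per emitter
    psf_sigma: float = 1.2  # pixels
    pixel_size: float = 0.1  # um per pixel
    dna_length: float = 48.5  # kb (lambda DNA)
    site_spacing: float = 2.0  # kb between damage sites (tightrope arrays)
    kb_to_um: float = KB_TO_UM_BFORM
    motile_fraction: float = 0.11
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "frame_interval": self.frame_interval,
            "bind_lifetime": self.bind_lifetime,
            "bleach_lifetime": self.bleach_lifetime,
            "blink_on_lifetime": self.blink_on_lifetime,
            "blink_off_lifetime": self.blink_off_lifetime,
            "kb_to_um": self.kb_to_um,
            "pixel_size": self.pixel_size,
            "psf_sigma": self.psf_sigma,
        }
        for name, v in positive.items():
            if not (v > 0) or (math.isnan(v)):
                raise ValueError(f"{name} must be positive (got {v!r})")
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must lie in (0, 2]")
        if self.diffusion_coefficient < 0 or not math.isfinite(self.diffusion_coefficient):
            raise ValueError("diffusion_coefficient must be finite and >= 0")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.photon_rate <= 0 or not math.isfinite(self.photon_rate):
            raise ValueError("photon_rate must be finite and > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.motile_fraction <= 1:
            raise ValueError("motile_fraction must lie in [0, 1]")
        if self.dna_length < self.site_spacing:
            raise ValueError("dna_length must be >= site_spacing")

    @property
    def observation_window(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def dna_length_um(self) -> float:
        return self.dna_length * self.kb_to_um

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParticleTruth:
    """Per-particle ground truth covering every rendered frame."""

    particle_id: int
    motile: bool
    site_index: int | None
    true_dwell_s: float  # last-bound minus first-bound time
    censored: bool
    removal_cause: str  # "dissociated" | "bleached" | "window"
    frames: np.ndarray  # frames where the particle emits (blinks excluded)
    true_positions_um: np.ndarray  # per emitting frame
    states: list[str] = field(default_factory=list)  # per frame of presence


@dataclass
class GroundTruth:
    config: SimulationConfig
    particles: list[ParticleTruth] = field(default_factory=list)

    def __iter__(self):
        return iter(self.particles)


def _fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via Davies-Harte embedding.

    Exact covariance: the sample has autocovariance
    gamma(k) = 0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H). Falls back to a Cholesky
    construction on the rare embeddings with negative eigenvalues.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1); handle H=1 as ballistic motion")
    if n < 1:
        raise ValueError("n must be >= 1")
    if hurst == 0.5:
        return rng.standard_normal(n)
    gamma = _fgn_autocovariance(n, hurst)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    if np.any(lam < -1e-10 * lam.max()):
        cov = np.empty((n, n))
        for i in range(n):
            cov[i] = gamma[np.abs(np.arange(n) - i)]
        return np.linalg.cholesky(cov) @ rng.standard_normal(n)
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    w = np.zeros(m, dtype=complex)
    v = rng.standard_normal(m)  # one draw per circulant slot keeps determinism simple
    w[0] = math.sqrt(lam[0] / m) * v[0]
    w[n] = math.sqrt(lam[n] / m) * v[n]
    j = np.arange(1, n)
    re = v[j]
    im = rng.standard_normal(n - 1)
    w[j] = np.sqrt(lam[j] / (2 * m)) * (re + 1j * im)
    w[m - j] = np.conj(w[j])
    x = np.fft.fft(w)
    return x.real[:n]


def _displacement_steps(
    n_steps: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame displacements with Var[sum over n] = 2 D (n dt)^alpha."""
    D, a, dt = config.diffusion_coefficient, config.alpha, config.frame_interval
    if D == 0 or n_steps == 0:
        return np.zeros(n_steps)
    step_sd = math.sqrt(2 * D * dt**a)
    if a == 2.0:
        return np.full(n_steps, step_sd * rng.standard_normal())
    if a == 1.0:
        return step_sd * rng.standard_normal(n_steps)
    return step_sd * fractional_gaussian_noise(n_steps, a / 2.0, rng)


def _blink_mask(
    n_frames: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Two-state on/off telegraph process, sampled per frame; starts on."""
    mask = np.ones(n_frames, dtype=bool)
    if not math.isfinite(config.blink_off_lifetime) and not math.isfinite(
        config.blink_on_lifetime
    ):
        return mask
    t, on = 0.0, True
    dt = config.frame_interval
    total = n_frames * dt
    while t < total:
        mean = config.blink_on_lifetime if on else config.blink_off_lifetime
        dur = rng.exponential(mean) if math.isfinite(mean) else total - t
        if not on:
            i0 = int(np.ceil(t / dt))
            i1 = min(n_frames, int(np.ceil((t + dur) / dt)))
            mask[i0:i1] = False
        t += dur
        on = not on
    mask[0] = True  # first detected frame defines the dwell start
    return mask


def simulate_trajectories(
    config: SimulationConfig,
    n_particles: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate labeled particles on one DNA substrate.

    Each particle is either stationary at a damage site or undergoes 1D
    diffusion with stationary-increment scaling Var[x(t+d)-x(t)] = 2 D d^alpha
    (drawn with probability ``motile_fraction``). Presence ends at the first of
    exponential dissociation, exponential photobleaching, or the end of the
    observation window (right-censored). Blinking removes frames; independent
    Gaussian localization noise of sd ``localization_sigma`` is added per
    observed frame. Identical seed and config give identical output.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval
    length_um = config.dna_length_um
    sites_um = make_damage_layout(
        "array", spacing=config.site_spacing, length=config.dna_length
    ).to_um(config.kb_to_um).sites

    trajectories: list[Trajectory] = []
    truth = GroundTruth(config=config)
    for pid in range(n_particles):
        motile = bool(rng.random() < config.motile_fraction)
        t_bind = (
            rng.exponential(config.bind_lifetime)
            if math.isfinite(config.bind_lifetime)
            else math.inf
        )
        t_bleach = (
            rng.exponential(config.bleach_lifetime)
            if math.isfinite(config.bleach_lifetime)
            else math.inf
        )
        window = config.observation_window
        t_end = min(t_bind, t_bleach, window)
        if t_end == window:
            cause, censored = "window", True
        elif t_end == t_bleach:
            cause, censored = "bleached", False
        else:
            cause, censored = "dissociated", False
        n_present = max(1, min(config.n_frames, int(np.floor(t_end / dt)) + 1))

        if motile:
            site_index = None
            x0 = rng.uniform(0.1 * length_um, 0.9 * length_um)
            steps = _displacement_steps(n_present - 1, config, rng)
            true_pos = x0 + np.concatenate([[0.0], np.cumsum(steps)])
            true_pos = np.clip(true_pos, 0.0, length_um)
            state = "diffusing"
        else:
            site_index = int(rng.integers(len(sites_um)))
            true_pos = np.full(n_present, sites_um[site_index])
            state = "bound"

        mask = _blink_mask(n_present, config, rng)
        frames = np.nonzero(mask)[0]
        obs_pos = true_pos[frames] + (
            config.localization_sigma * rng.standard_normal(frames.size)
            if config.localization_sigma > 0
            else 0.0
        )
        states = [state if mask[i] else "blinked" for i in range(n_present)]
        truth.particles.append(
            ParticleTruth(
                particle_id=pid,
                motile=motile,
                site_index=site_index,
                true_dwell_s=(n_present - 1) * dt,
                censored=censored,
                removal_cause=cause,
                frames=frames,
                true_positions_um=true_pos[frames],
                states=states,
            )
        )
        trajectories.append(
            Trajectory(
                particle_id=pid,
                channel="sim",
                frames=frames,
                positions_um=obs_pos,
                frame_interval=dt,
                amplitudes=np.full(frames.size, config.photon_rate * dt),
                sigmas_px=np.full(frames.size, config.psf_sigma),
                censored_end=censored,
            )
        )
    return trajectories, truth


def render_kymograph(
    trajectories: list[Trajectory],
    config: SimulationConfig,
    n_pixels: int | None = None,
    n_frames: int | None = None,
    offset: float = 10.0,
    shot_noise: bool = True,
    rng: np.random.Generator | None = None,
    channel: str = "sim",
) -> Kymograph:
    """Render trajectories into a kymograph image.

    Each frame column is the sum of Gaussian line profiles of sd ``psf_sigma``
    pixels centered at the particle positions, each scaled to
    ``photon_rate * frame_interval`` expected photons, with Poisson shot noise
    (optional) and a constant offset. Photon counts are nonnegative integers
    before the offset is added.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    if config.pixel_size <= 0:
        raise ValueError("pixel size must be > 0")
    if n_pixels is None:
        n_pixels = int(np.ceil(config.dna_length_um / config.pixel_size)) + 1
    if n_pixels < 1:
        raise ValueError("spatial window must contain at least one pixel")
    if n_frames is None:
        n_frames = config.n_frames
    grid = np.arange(n_pixels, dtype=float)
    photons_per_frame = config.photon_rate * config.frame_interval
    expected = np.zeros((n_pixels, n_frames))
    for traj in trajectories:
        pos_px = traj.positions_um / config.pixel_size
        if np.any(pos_px < -0.5) or np.any(pos_px > n_pixels - 0.5):
            raise ValueError("trajectory positions fall outside the rendered window")
        for f, p in zip(traj.frames, pos_px):
            if f >= n_frames:
                continue
            prof = np.exp(-0.5 * ((grid - p) / config.psf_sigma) ** 2)
            ssum = prof.sum()
            if ssum > 0:
                expected[:, f] += photons_per_frame * prof / ssum
    counts = rng.poisson(expected).astype(float) if shot_noise else expected
    return Kymograph(
        data=counts + offset,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        channel=channel,
    )


def simulate_dwell_times(
    bind_lifetime: float,
    bleach_lifetime: float,
    observation_window: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list["DwellRecord"]:
    """Draw dwell times from competing dissociation and bleaching exponentials.

    Each dwell is min(Exp(bind), Exp(bleach), window); dwells truncated by the
    window carry a censored flag. ``inf`` disables a process.
    """
    from .kinetics import DwellRecord

    if observation_window <= 0:
        raise ValueError("observation window must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, tau in (("bind", bind_lifetime), ("bleach", bleach_lifetime)):
        if not tau > 0:
            raise ValueError(f"{name} lifetime must be > 0 (or inf to disable)")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    t_bind = (
        rng.exponential(bind_lifetime, n) if math.isfinite(bind_lifetime) else np.full(n, np.inf)
    )
    t_bleach = (
        rng.exponential(bleach_lifetime, n)
        if math.isfinite(bleach_lifetime)
        else np.full(n, np.inf)
    )
    raw = np.minimum(t_bind, t_bleach)
    records = []
    for i, t in enumerate(raw):
        censored = t >= observation_window
        dur = observation_window if censored else float(t)
        records.append(
            DwellRecord(
                particle_id=i,
                channel="sim",
                start_s=0.0,
                end_s=dur,
                censored=bool(censored),
            )
        )
    return records


def make_damage_layout(mode: str, **params) -> FiducialMap:
    """Build a damage-site layout.

    ``array`` mode places sites at spacing, 2*spacing, ... up to ``length``
    (kb), emulating tandem-ligated tightrope substrates with one lesion per
    repeat. ``fiducial`` mode takes explicit site positions, merges pairs
    closer than ``resolution_limit`` into their midpoint, and drops sites
    within ``bead_margin`` of either substrate end.
    """
    if mode == "array":
        spacing = params["spacing"]
        length = params["length"]
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        sites = np.arange(spacing, length + spacing * 1e-9, spacing)
        return FiducialMap(length=length, sites=sites, units=params.get("units", "kb"))
    if mode == "fiducial":
        raw = np.sort(np.asarray(params["sites"], dtype=float))
        length = params["length"]
        res = params["resolution_limit"]
        margin = params["bead_margin"]
        merged: list[float] = []
        i = 0
        while i < raw.size:
            group = [raw[i]]
            while i + 1 < raw.size and raw[i + 1] - group[-1] < res:
                i += 1
                group.append(raw[i])
            merged.append(float(np.mean(group)))
            i += 1
        kept = [s for s in merged if margin <= s <= length - margin]
        return FiducialMap(
            length=length,
            sites=np.array(kept),
            resolution_limit=res,
            bead_margin=margin,
            units=params.get("units", "kb"),
        )
    raise ValueError(f"unknown layout mode {mode!r}")


# Synthetic stand-in for a nickase site map on lambda DNA (48.5 kb): the true
# nick coordinates are not published, so these positions are constructed such
# that one pair falls under the optical resolution limit and one site sits too
# close to a bead, leaving 8 observable sites out of 10.
LAMBDA_SYNTHETIC_NICK_SITES_KB = (
    2.5, 7.0, 12.0, 17.5, 21.0, 21.6, 27.0, 33.0, 39.0, 47.5,
)


def lambda_fiducial_layout(
    resolution_limit: float = 1.0, bead_margin: float = 1.5
) -> FiducialMap:
    """Synthetic lambda-DNA fiducial layout with 10 nick sites, 8 observable."""
    return make_damage_layout(
        "fiducial",
        sites=LAMBDA_SYNTHETIC_NICK_SITES_KB,
        length=48.5,
        resolution_limit=resolution_limit,
        bead_margin=bead_margin,
    )


def simulate_isotherm(
    kd: float,
    dna_conc: float,
    protein_concs,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> list[BindingPoint]:
    """Draw % bound observations from the quadratic binding model.

    Gaussian noise of sd ``noise_sd`` percentage points is added and the
    result clipped to [0, 100].
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    protein_concs = np.asarray(protein_concs, dtype=float)
    pb = np.atleast_1d(fraction_bound_model(dna_conc, protein_concs, kd))
    if noise_sd > 0:
        pb = pb + noise_sd * rng.standard_normal(pb.size)
    pb = np.clip(pb, 0.0, 100.0)
    return [
        BindingPoint(protein_nM=float(p), dna_nM=dna_conc, percent_bound=float(b))
        for p, b in zip(protein_concs, pb)
    ]
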