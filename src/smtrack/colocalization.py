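"""Dual-color colocalization and damage-site (fiducial) classification.

Pairs particle tracks observed in two fluorescence channels when they dwell
within a distance threshold for long enough, and classifies binding events as
on- or off-target against a map of fiducially marked damage sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracking import Trajectory

__all__ = [
    "FiducialMap",
    "ColocalizationResult",
    "call_colocalization",
    "classify_on_target",
    "summarize_dual_color",
]


@dataclass
class FiducialMap:
    """Positions of observable damage sites along a stretched DNA substrate.

    ``length`` and ``sites`` share one unit (kb or um, recorded in ``units``).
    """

    length: float
    sites: np.ndarray
    resolution_limit: float = 0.0
    bead_margin: float = 0.0
    units: str = "kb"

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=float)
        if self.sites.size:
            if np.any(self.sites < 0) or np.any(self.sites > self.length):
                raise ValueError("sites must lie within [0, length]")
            if np.any(np.diff(self.sites) <= 0):
                raise ValueError("sites must be strictly increasing")

    def to_um(self, kb_to_um: float = 0.34) -> "FiducialMap":
        if self.units == "um":
            return self
        return FiducialMap(
            length=self.length * kb_to_um,
            sites=self.sites * kb_to_um,
            resolution_limit=self.resolution_limit * kb_to_um,
            bead_margin=self.bead_margin * kb_to_um,
            units="um",
        )


@dataclass
class ColocalizationResult:
    n_a_only: int
    n_b_only: int
    n_colocalized: int
    pairs: list[dict] = field(default_factory=list)

    @property
    def n_a(self) -> int:
        return self.n_a_only + self.n_colocalized

    @property
    def n_b(self) -> int:
        return self.n_b_only + self.n_colocalized

    @property
    def fractions(self) -> dict:
        """Colocalized fraction under the common denominators.

        ``of_particles`` counts each member of a pair as one colocalized
        particle out of all particles seen in either channel; ``of_pairs_a`` /
        ``of_pairs_b`` are per-channel event fractions.
        """
        n_total = self.n_a + self.n_b
        out = {
            "of_particles": (2 * self.n_colocalized / n_total) if n_total else 0.0,
            "of_pairs_a": (self.n_colocalized / self.n_a) if self.n_a else 0.0,
            "of_pairs_b": (self.n_colocalized / self.n_b) if self.n_b else 0.0,
        }
        return out


def _overlap_stats(
    a: Trajectory, b: Trajectory, distance_threshold: float
) -> tuple[float, float]:
    """Seconds of co-existing time within threshold, and mean separation there."""
    common, ia, ib = np.intersect1d(a.frames, b.frames, return_indices=True)
    if common.size == 0:
        return 0.0, np.inf
    d = np.abs(a.positions_um[ia] - b.positions_um[ib])
    within = d <= distance_threshold
    if not np.any(within):
        return 0.0, np.inf
    overlap_s = float(within.sum() * a.frame_interval)
    return overlap_s, float(d[within].mean())


def call_colocalization(
    tracks_a: list[Trajectory],
    tracks_b: list[Trajectory],
    distance_threshold: float = 0.5,
    min_overlap: float = 1.0,
) -> ColocalizationResult:
    """Call colocalized particle pairs between two channels.

    A pair is colocalized when the two particles co-exist within
    ``distance_threshold`` micrometers for at least ``min_overlap`` seconds.
    Each particle joins at most one pair; candidate pairs are accepted
    greedily by decreasing overlap duration, ties broken by smaller mean
    separation. The result is symmetric under swapping the channels.
    """
    if tracks_a and tracks_b:
        if tracks_a[0].frame_interval != tracks_b[0].frame_interval:
            raise ValueError("channels must share one time base (frame interval)")

    bounds_a = [(t.positions_um.min(), t.positions_um.max()) for t in tracks_a]
    bounds_b = [(t.positions_um.min(), t.positions_um.max()) for t in tracks_b]
    candidates = []
    for i, a in enumerate(tracks_a):
        for j, b in enumerate(tracks_b):
            # cheap rejection: disjoint in space (beyond threshold) or in time
            if (
                bounds_b[j][0] - bounds_a[i][1] > distance_threshold
                or bounds_a[i][0] - bounds_b[j][1] > distance_threshold
                or b.frames[0] > a.frames[-1]
                or a.frames[0] > b.frames[-1]
            ):
                continue
            overlap_s, mean_d = _overlap_stats(a, b, distance_threshold)
            if overlap_s >= min_overlap:
                candidates.append((-overlap_s, mean_d, i, j))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for neg_overlap, mean_d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(
            {
                "id_a": tracks_a[i].particle_id,
                "id_b": tracks_b[j].particle_id,
                "overlap_s": -neg_overlap,
                "mean_distance_um": mean_d,
            }
        )
    n_coloc = len(pairs)
    return ColocalizationResult(
        n_a_only=len(tracks_a) - n_coloc,
        n_b_only=len(tracks_b) - n_coloc,
        n_colocalized=n_coloc,
        pairs=pairs,
    )


def classify_on_target(
    positions, fiducials: FiducialMap, window: float
) -> tuple[np.ndarray, float]:
    """Classify event positions as on-target against the fiducial site map.

    An event is on-target iff its distance to the nearest observable site is
    at most ``window`` (same units as the map). Returns the boolean flags and
    the on-target fraction.
    """
    positions = np.asarray(positions, dtype=float)
    if fiducials.sites.size == 0:
        warnings.warn("empty fiducial map: all events classified off-target")
        return np.zeros(positions.shape, dtype=bool), 0.0
    if positions.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    dist = np.min(np.abs(positions[:, None] - fiducials.sites[None, :]), axis=1)
    on = dist <= window
    return on, float(on.mean())


def summarize_dual_color(
    result: ColocalizationResult,
    behavior_a: dict[int, tuple[str, str]],
    behavior_b: dict[int, tuple[str, str]],
) -> dict:
    """Tabulate motile/stationary x persistent/dissociated per Venn group.

    ``behavior_a``/``behavior_b`` map particle id to a
    (``motile``/``stationary``, ``persistent``/``dissociated``) label pair.
    Fractions within each non-empty group sum to 1.
    """
    paired_a = {p["id_a"] for p in result.pairs}
    paired_b = {p["id_b"] for p in result.pairs}

    def _tab(labels: list[tuple[str, str]]) -> dict:
        cats = [
            ("motile", "persistent"),
            ("motile", "dissociated"),
            ("stationary", "persistent"),
            ("stationary", "dissociated"),
        ]
        counts = {f"{m}_{p}": 0 for m, p in cats}
        for m, p in labels:
            counts[f"{m}_{p}"] += 1
        n = len(labels)
        fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
        return {"n": n, "counts": counts, "fractions": fractions}

    groups = {
        "a_only": [v for k, v in behavior_a.items() if k not in paired_a],
        "b_only": [v for k, v in behavior_b.items() if k not in paired_b],
        "colocalized": [v for k, v in behavior_a.items() if k in paired_a]
        + [v for k, v in behavior_b.items() if k in paired_b],
    }
    return {name: _tab(labels) for name, labels in groups.items()}
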