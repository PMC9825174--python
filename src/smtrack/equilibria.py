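"""Gel quantification arithmetic and equilibrium/excision model fits.

Implements electrophoretic-mobility-shift (EMSA) lane fractions, the
ligand-depletion ("quadratic") binding isotherm used to estimate Kd when the
probe DNA concentration is comparable to Kd, excision time-course fractions,
and fold stimulation between conditions.

The isotherm follows from mass action with total concentrations P (protein)
and D (DNA): the complex concentration is the physically meaningful root of

    x**2 - (D + P + Kd) * x + D * P = 0

and % bound = 100 * x / D = 100 * (D + P + Kd - sqrt((D+P+Kd)**2 - 4 D P)) / (2 D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LaneQuantification",
    "BindingPoint",
    "KdFit",
    "ExcisionTimepoint",
    "lane_fractions",
    "fraction_bound_model",
    "fit_kd",
    "excision_fraction",
    "fold_stimulation",
]


@dataclass
class LaneQuantification:
    """Band intensities (arbitrary units) for one gel lane."""

    lane_id: str
    intensities: dict[str, float]  # species -> raw band intensity
    background: float = 0.0


@dataclass
class BindingPoint:
    protein_nM: float
    dna_nM: float
    percent_bound: float

    def __post_init__(self) -> None:
        if self.protein_nM < 0 or self.dna_nM < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0 <= self.percent_bound <= 100:
            raise ValueError("percent bound must lie in [0, 100]")


@dataclass
class KdFit:
    kd_nM: float
    se_nM: float
    r_squared: float
    n_points: int
    dna_nM: float


@dataclass
class ExcisionTimepoint:
    time_min: float
    fraction_product: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time must be >= 0")
        if not 0 <= self.fraction_product <= 1:
            raise ValueError("fraction product must lie in [0, 1]")


def lane_fractions(lane: LaneQuantification) -> dict[str, float]:
    """Per-species fraction of total lane signal after background subtraction.

    Band intensities falling below the background are clipped to zero with a
    warning; an all-zero lane is undefined and raises.
    """
    sub = {}
    for species, raw in lane.intensities.items():
        v = raw - lane.background
        if v < 0:
            warnings.warn(
                f"lane {lane.lane_id}: species '{species}' below background, clipped to 0"
            )
            v = 0.0
        sub[species] = v
    total = sum(sub.values())
    if total <= 0:
        raise ValueError(f"lane {lane.lane_id}: no signal above background")
    return {s: v / total for s, v in sub.items()}


def fraction_bound_model(dna_nM, protein_nM, kd_nM):
    """% DNA bound under the ligand-depletion (quadratic) binding model.

    Vectorized over ``protein_nM``. Requires D > 0, P >= 0, Kd > 0.
    """
    D = float(dna_nM)
    P = np.asarray(protein_nM, dtype=float)
    Kd = float(kd_nM)
    if D <= 0:
        raise ValueError("DNA concentration must be > 0")
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    if np.any(P < 0):
        raise ValueError("protein concentrations must be >= 0")
    s = D + P + Kd
    disc = s * s - 4.0 * D * P
    pb = 100.0 * (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * D)
    pb = np.clip(pb, 0.0, 100.0)
    return pb if pb.ndim else float(pb)


def complex_concentration(dna_nM: float, protein_nM: float, kd_nM: float) -> float:
    """Concentration of the protein-DNA complex (nM), the physical quadratic root."""
    return fraction_bound_model(dna_nM, protein_nM, kd_nM) / 100.0 * dna_nM


def fit_kd(points: list[BindingPoint]) -> KdFit:
    """Fit Kd to (protein, % bound) points by nonlinear least squares.

    All points must share one total DNA concentration. The initial Kd guess is
    taken from the protein concentration at half-maximal binding. Data with no
    binding transition (all near 0% or all near 100%) are unidentifiable and
    raise.
    """
    if len(points) < 3:
        raise ValueError("at least 3 binding points are required")
    dnas = {p.dna_nM for p in points}
    if len(dnas) != 1:
        raise ValueError("all points must share one DNA concentration")
    D = dnas.pop()
    P = np.array([p.protein_nM for p in points])
    y = np.array([p.percent_bound for p in points])

    if y.max() < 10.0 or y.min() > 90.0:
        raise ValueError("no binding transition in data: Kd unidentifiable")

    # protein concentration at half-maximal observed binding as initial guess
    half = 0.5 * y.max()
    order = np.argsort(P)
    kd0 = float(np.interp(half, y[order], P[order]))
    kd0 = max(kd0, 1e-3)

    popt, pcov = curve_fit(
        lambda protein, kd_nM: fraction_bound_model(D, protein, kd_nM),
        P,
        y,
        p0=(kd0,),
        bounds=((1e-9,), (np.inf,)),
        maxfev=10000,
    )
    kd = float(popt[0])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    resid = y - fraction_bound_model(D, P, kd)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-12 else 0.0)
    return KdFit(
        kd_nM=kd,
        se_nM=se,
        r_squared=r2,
        n_points=len(points),
        dna_nM=D,
    )


def excision_fraction(substrate_intensity: float, product_intensity: float) -> float:
    """Fraction of substrate converted to product: product / (product + substrate)."""
    total = substrate_intensity + product_intensity
    if total <= 0:
        raise ValueError("substrate + product intensity must be > 0")
    if substrate_intensity < 0 or product_intensity < 0:
        raise ValueError("band intensities must be >= 0")
    return product_intensity / total


def fold_stimulation(
    series_plus: list[ExcisionTimepoint],
    series_minus: list[ExcisionTimepoint],
    min_baseline_fraction: float = 0.05,
) -> dict:
    """Fold stimulation of excision between matched time courses.

    Per timepoint, fold = fraction(+stimulator) / fraction(-stimulator); a
    timepoint with zero baseline fraction is reported as missing (NaN), not
    zero. The summary fold is taken at the earliest timepoint where the
    baseline fraction reaches ``min_baseline_fraction`` (0/0-stable).
    """
    t_plus = [p.time_min for p in series_plus]
    t_minus = [p.time_min for p in series_minus]
    if t_plus != t_minus:
        raise ValueError("time grids of the two series must match")
    if len(set(t_plus)) != len(t_plus):
        raise ValueError("timepoints must be unique per condition")

    folds = []
    summary = None
    for p, m in zip(series_plus, series_minus):
        fold = p.fraction_product / m.fraction_product if m.fraction_product > 0 else float("nan")
        folds.append({"time_min": p.time_min, "fold": fold})
        if summary is None and m.fraction_product >= min_baseline_fraction:
            summary = {"time_min": p.time_min, "fold": fold}
    return {"per_timepoint": folds, "summary": summary}
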