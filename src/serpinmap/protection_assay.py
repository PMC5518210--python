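"""Fluorophore-protection kinetics for antibody binding-site mapping.

A thiol-reactive coumarin dye (CPM) conjugates to an engineered single
cysteine, producing a saturating fluorescence increase over ~30 minutes.
Antibody binding over the cysteine shields it, lowering the labelling
intensity and/or slowing its kinetics.  Rather than assume a kinetic
model, each +antibody curve is superimposed onto its −antibody partner by
model-free scaling factors along the intensity and time axes, fitted by
least squares:

    I_plus(t) ≈ a · I_minus(b · t)

The fractional intensity is the fitted intensity scale ``a``; values below
one indicate shielding of the probed position.  Replicates are summarised
per (antibody, position) as mean ± SEM and positions whose mean falls at
or below an advisory threshold are flagged as protected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

WITH_ANTIBODY = "with_antibody"
WITHOUT_ANTIBODY = "without_antibody"

#: Advisory fractional-intensity cutoff for calling a position protected.
DEFAULT_PROTECTION_THRESHOLD = 0.8

_SCALE_BOUNDS = (0.1, 10.0)


@dataclass
class KineticsCurve:
    """One conjugation time course.

    Time in minutes (strictly increasing, ≥ 5 points), intensity in
    arbitrary fluorescence units.  ``position`` is the residue index of the
    single-cysteine mutant probed.
    """

    time: np.ndarray
    intensity: np.ndarray
    condition: str
    position: int
    antibody: str
    replicate: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.condition not in (WITH_ANTIBODY, WITHOUT_ANTIBODY):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.time.size < 5:
            raise ValueError("a kinetics curve needs at least 5 time points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not (
            np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.intensity))
        ):
            raise ValueError("non-finite values in kinetics curve")


@dataclass
class CurvePair:
    """A ±antibody curve pair for one (antibody, position, replicate)."""

    plus: KineticsCurve
    minus: KineticsCurve

    def __post_init__(self) -> None:
        if self.plus.condition != WITH_ANTIBODY:
            raise ValueError("plus curve must have condition 'with_antibody'")
        if self.minus.condition != WITHOUT_ANTIBODY:
            raise ValueError("minus curve must have condition 'without_antibody'")
        key = ("antibody", "position", "replicate")
        for attr in key:
            if getattr(self.plus, attr) != getattr(self.minus, attr):
                raise ValueError(f"curve pair mismatch on {attr}")


@dataclass
class SuperpositionFit:
    """Two-axis scaling superposing a +antibody curve onto its partner.

    ``intensity_scale`` (a) and ``time_scale`` (b) minimise the summed
    squared difference I_plus(t) − a·I_minus(b·t) over the overlapping
    time support; ``converged`` is False when the optimisation failed, in
    which case ``residual`` is infinite.
    """

    intensity_scale: float
    time_scale: float
    residual: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and (
            self.intensity_scale <= 0 or self.time_scale <= 0
        ):
            raise ValueError("scale factors must be positive")


def read_curves(path: str | Path) -> list[CurvePair]:
    """Read kinetics curves from CSV and pair them ±antibody.

    Expected columns: ``time``, ``intensity``, ``condition``, ``position``,
    ``antibody``, ``replicate``.  Curves are grouped by
    (antibody, position, replicate); a group missing either condition
    raises a ``ValueError`` naming it.
    """
    frame = pd.read_csv(path)
    required = {"time", "intensity", "condition", "position", "antibody", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"kinetics CSV missing columns {sorted(missing)}")
    pairs = []
    for (antibody, position, replicate), group in frame.groupby(
        ["antibody", "position", "replicate"], sort=True
    ):
        curves = {}
        for condition, sub in group.groupby("condition"):
            sub = sub.sort_values("time")
            curves[condition] = KineticsCurve(
                time=sub.time.to_numpy(),
                intensity=sub.intensity.to_numpy(),
                condition=str(condition),
                position=int(position),
                antibody=str(antibody),
                replicate=int(replicate),
            )
        if WITH_ANTIBODY not in curves or WITHOUT_ANTIBODY not in curves:
            raise ValueError(
                f"group (antibody={antibody!r}, position={position}, "
                f"replicate={replicate}) lacks a ±antibody partner"
            )
        pairs.append(CurvePair(plus=curves[WITH_ANTIBODY], minus=curves[WITHOUT_ANTIBODY]))
    return pairs


def _baseline(curve: KineticsCurve) -> tuple[np.ndarray, np.ndarray]:
    return curve.time, curve.intensity - curve.intensity[0]


def _residual_for_b(
    b: float,
    t_plus: np.ndarray,
    i_plus: np.ndarray,
    t_minus: np.ndarray,
    i_minus: np.ndarray,
) -> tuple[float, float, int]:
    """Best intensity scale (closed form) and SSR at fixed time scale b.

    Only points whose scaled time b·t lies inside the −antibody support are
    used (no extrapolation)."""
    scaled = b * t_plus
    inside = (scaled >= t_minus[0]) & (scaled <= t_minus[-1])
    n = int(inside.sum())
    if n < 3:
        return math.inf, math.nan, n
    ref = np.interp(scaled[inside], t_minus, i_minus)
    obs = i_plus[inside]
    denom = float(ref @ ref)
    if denom == 0:
        return math.inf, math.nan, n
    a = float(obs @ ref) / denom
    if a <= 0:
        a = 1e-12
    ssr = float(np.sum((obs - a * ref) ** 2))
    return ssr, a, n


def fit_superposition(
    curve_plus: KineticsCurve,
    curve_minus: KineticsCurve,
    baseline_subtract: bool = True,
) -> SuperpositionFit:
    """Fit the model-free two-axis scaling of a +antibody curve.

    The intensity scale ``a`` enters linearly, so for each candidate time
    scale ``b`` the optimal ``a`` has a closed form; ``b`` is scanned over
    a deterministic log-spaced grid in [0.1, 10] and refined by bounded
    scalar minimisation.  Curves are baselined by subtracting their t=0
    intensity unless ``baseline_subtract`` is off.
    """
    if baseline_subtract:
        t_plus, i_plus = _baseline(curve_plus)
        t_minus, i_minus = _baseline(curve_minus)
    else:
        t_plus, i_plus = curve_plus.time, curve_plus.intensity
        t_minus, i_minus = curve_minus.time, curve_minus.intensity

    lo, hi = _SCALE_BOUNDS
    overlap_exists = any(
        _residual_for_b(b, t_plus, i_plus, t_minus, i_minus)[2] >= 3
        for b in (lo, 1.0, hi)
    )
    if not overlap_exists:
        raise ValueError("curves have no overlapping time support")

    def objective(b: float) -> float:
        # mean squared residual: comparable across time scales, which
        # change how many points fall inside the overlap
        ssr, _, n = _residual_for_b(b, t_plus, i_plus, t_minus, i_minus)
        return ssr / n if n else math.inf

    grid = np.geomspace(lo, hi, 201)
    ssrs = [objective(b) for b in grid]
    best = int(np.argmin(ssrs))
    if not math.isfinite(ssrs[best]):
        return SuperpositionFit(
            intensity_scale=math.nan,
            time_scale=math.nan,
            residual=math.inf,
            n_points=0,
            converged=False,
        )
    b_lo = grid[max(best - 1, 0)]
    b_hi = grid[min(best + 1, len(grid) - 1)]
    result = optimize.minimize_scalar(
        objective,
        bounds=(b_lo, b_hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    b = float(result.x)
    ssr, a, n = _residual_for_b(b, t_plus, i_plus, t_minus, i_minus)
    if not math.isfinite(ssr):
        return SuperpositionFit(
            intensity_scale=math.nan,
            time_scale=math.nan,
            residual=math.inf,
            n_points=0,
            converged=False,
        )
    return SuperpositionFit(
        intensity_scale=a, time_scale=b, residual=ssr, n_points=n
    )


def fractional_intensity(fit: SuperpositionFit) -> float:
    """The fitted intensity scale ``a``; < 1 indicates shielding.

    Raises on a non-converged fit, propagating the flag.
    """
    if not fit.converged:
        raise ValueError("superposition fit did not converge")
    return fit.intensity_scale


@dataclass
class ProtectionReport:
    """Per (antibody, position) fractional-intensity summary."""

    frame: pd.DataFrame  # antibody, position, mean, sem, n, protected
    threshold: float = DEFAULT_PROTECTION_THRESHOLD

    def protected_positions(self, antibody: str | None = None) -> set[int]:
        frame = self.frame
        if antibody is not None:
            frame = frame[frame.antibody == antibody]
        return set(frame.loc[frame.protected, "position"].astype(int))


def summarize_protection(
    fractional: dict[tuple[str, int], list[float]],
    threshold: float = DEFAULT_PROTECTION_THRESHOLD,
) -> ProtectionReport:
    """Mean ± SEM per (antibody, position), flagging protected positions.

    ``fractional`` maps (antibody, position) to that position's replicate
    fractional intensities.  SEM is the sample standard deviation over
    √n, and 0 by convention for n = 1.  A position is flagged protected
    when its mean is ≤ ``threshold`` (advisory cutoff).
    """
    rows = []
    for (antibody, position), values in sorted(fractional.items()):
        if len(values) < 1:
            raise ValueError(f"no replicates for ({antibody!r}, {position})")
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        rows.append(
            {
                "antibody": antibody,
                "position": position,
                "mean": mean,
                "sem": sem,
                "n": arr.size,
                "protected": mean <= threshold,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["antibody", "position"], ignore_index=True
    )
    return ProtectionReport(frame=frame, threshold=threshold)


def analyze_curves(
    pairs: list[CurvePair],
    threshold: float = DEFAULT_PROTECTION_THRESHOLD,
    baseline_subtract: bool = True,
) -> ProtectionReport:
    """Fit every curve pair and summarise protection per position."""
    fractional: dict[tuple[str, int], list[float]] = {}
    for pair in pairs:
        fit = fit_superposition(pair.plus, pair.minus, baseline_subtract)
        key = (pair.plus.antibody, pair.plus.position)
        fractional.setdefault(key, []).append(fractional_intensity(fit))
    return summarize_protection(fractional, threshold)
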