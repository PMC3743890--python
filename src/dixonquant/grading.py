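"""Ordinal radiological grading of muscle fatty infiltration (Mercuri scale).

The six-point scale (0, 1, 2a, 2b, 3, 4) grades the T1-weighted appearance
of a muscle by the volume fraction showing fatty change: grade 2a covers
confluent change in less than 30% of the muscle volume, grade 2b 30-60%,
with washed-out (3) and end-stage (4) appearances above.  Since T1-weighted
contrast is not simulated here, grading operates on the *affected volume
fraction* directly — either computed from a fat-fraction map (fraction of
compartment voxels above a visibility threshold) or mapped from a summary
fat fraction — and an observer confusion model perturbs the deterministic
grade to adjacent grades, with heavier confusion at the middle of the
scale where radiological boundaries are least crisp.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "GRADES",
    "GRADE_RANKS",
    "GraderModel",
    "apply_grader",
    "grades_to_ranks",
    "ranks_to_grades",
    "affected_fraction_from_ff_map",
    "affected_fraction_from_ff",
]

#: Grade alphabet in severity order.
GRADES: tuple[str, ...] = ("0", "1", "2a", "2b", "3", "4")

#: Integer ranks used in rank-based tests (0..5 for grades 0..4).
GRADE_RANKS: dict[str, int] = {g: i for i, g in enumerate(GRADES)}


@dataclass
class GraderModel:
    """Threshold grading of the affected volume fraction plus observer noise.

    ``thresholds`` are the five strictly increasing cut points on the
    affected fraction separating the six grades; the 0.30 and 0.60 cuts are
    the published 2a/2b and 2b/3 volume bounds, the others are modelling
    choices (a visible-change onset, an early/late moth-eaten boundary, and
    an end-stage onset).  ``confusion`` gives, per true grade, the
    probability that an observer reports an adjacent grade instead; the
    default is heaviest at 2b, reproducing the observed mid-scale
    unreliability of the scale.
    """

    thresholds: tuple[float, ...] = (0.03, 0.10, 0.30, 0.60, 0.85)
    confusion: tuple[float, ...] = (0.06, 0.18, 0.26, 0.36, 0.26, 0.10)

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        if t.size != len(GRADES) - 1:
            raise ValueError(f"need {len(GRADES) - 1} thresholds")
        if np.any(np.diff(t) <= 0):
            raise ValueError("grade thresholds must be strictly increasing")
        if np.any(t <= 0) or np.any(t >= 1):
            raise ValueError("grade thresholds must lie in (0, 1)")
        c = np.asarray(self.confusion, float)
        if c.size != len(GRADES) or np.any(c < 0) or np.any(c > 1):
            raise ValueError("confusion must be one probability per grade")


def apply_grader(
    affected_fraction,
    model: GraderModel | None = None,
    seed: "int | np.random.Generator | None" = None,
):
    """Grade affected volume fraction(s) in [0, 1] on the 6-point scale.

    With no confusion noise (``seed=None`` and all confusion probabilities
    zero, or simply ``model.confusion`` zeros) the mapping is the pure
    threshold rule: 2a iff the fraction lies in the sub-30% confluent band,
    2b iff in 30-60%, and so on.  With a seed/generator, each observation is
    independently misreported to an adjacent grade with the per-grade
    confusion probability (split equally up/down; edge grades move inward).

    Returns a grade string for scalar input, else an object array.
    """
    if model is None:
        model = GraderModel()
    a = np.asarray(affected_fraction, float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if np.any((a < 0) | (a > 1) | ~np.isfinite(a)):
        raise ValueError("affected fraction must lie in [0, 1]")
    idx = np.searchsorted(np.asarray(model.thresholds), a, side="right")

    conf = np.asarray(model.confusion, float)
    if seed is not None and conf.any():
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        u = rng.random(a.shape)
        direction = np.where(rng.random(a.shape) < 0.5, -1, 1)
        flip = u < conf[idx]
        moved = idx + direction
        # edge grades can only move inward
        moved = np.clip(moved, 0, len(GRADES) - 1)
        moved = np.where(moved == idx, idx - direction, moved)
        idx = np.where(flip, np.clip(moved, 0, len(GRADES) - 1), idx)

    out = np.array([GRADES[i] for i in idx.ravel()], dtype=object).reshape(a.shape)
    return out.item() if scalar else out


def grades_to_ranks(grades) -> np.ndarray:
    """Map grade symbols to integer ranks 0..5; raises on unknown symbols."""
    out = np.empty(len(grades), dtype=int)
    for k, g in enumerate(grades):
        g = str(g)
        if g not in GRADE_RANKS:
            raise ValueError(f"unknown grade symbol {g!r}")
        out[k] = GRADE_RANKS[g]
    return out


def ranks_to_grades(ranks) -> np.ndarray:
    return np.array([GRADES[int(r)] for r in np.asarray(ranks)], dtype=object)


def affected_fraction_from_ff_map(
    ff_map: np.ndarray,
    mask: np.ndarray,
    visibility_threshold: float = 20.0,
) -> float:
    """Fraction of masked voxels whose fat fraction exceeds the threshold.

    Proxy for the radiologically 'affected' volume fraction: voxels above
    the visibility threshold (default 20% FF) read as fatty change on
    T1-weighted images.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(ff_map, float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite fat-fraction values under the mask")
    return float(np.mean(vals > visibility_threshold))


def affected_fraction_from_ff(ff_percent, mean_affected_ff: float = 70.0):
    """Map a summary fat fraction (%) to an affected volume fraction.

    Assumes affected tissue averages ``mean_affected_ff`` percent fat, so a
    muscle at FF f is modelled as a fraction f/mean_affected_ff of affected
    volume (clipped to [0, 1]).  Used when grading simulated cohorts where
    only a per-muscle FF, not an image, exists.
    """
    a = np.asarray(ff_percent, float) / float(mean_affected_ff)
    return np.clip(a, 0.0, 1.0)
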