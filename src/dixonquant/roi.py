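"""Region-of-interest quantification of fat-fraction maps.

ROIs encompass the full cross-section of individual muscles on the
acquisition grid; boundary voxels suffer partial-volume contamination from
neighbouring tissue, so masks are eroded by a configurable margin (default
1 voxel) before summarising.  The per-muscle measurement is the mean (or,
configurably, median) fat fraction over valid masked voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy import ndimage

from .recon import FatFractionMap

__all__ = [
    "EmptyROIError",
    "ROISet",
    "MuscleMeasurement",
    "erode_roi",
    "roi_fat_fraction",
    "measure_all",
    "pair_visits",
    "rasterize_polygon",
    "jitter_mask",
]

logger = logging.getLogger(__name__)

_STRUCT = ndimage.generate_binary_structure(2, 2)  # full 3x3 neighbourhood


class EmptyROIError(ValueError):
    """An ROI became (or was) empty; carries the muscle name."""

    def __init__(self, muscle: str | None, message: str):
        self.muscle = muscle
        super().__init__(message)


def rasterize_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize (y, x) polygon vertices with centre-of-voxel inclusion."""
    verts = np.asarray(vertices, float)
    path = _MplPath(verts[:, ::-1])
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return path.contains_points(pts).reshape(shape)


@dataclass
class ROISet:
    """Named muscle masks for one subject and visit, on the map grid."""

    masks: dict[str, np.ndarray]
    subject_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid")

    @classmethod
    def from_label_image(
        cls, label: np.ndarray, names: dict[int, str] | list[str], **kw
    ) -> "ROISet":
        """Build from an integer label image; 0 is background.

        ``names`` maps label values to muscle names (a list is interpreted
        as labels 1..len(names)).
        """
        label = np.asarray(label)
        if isinstance(names, (list, tuple)):
            names = {i + 1: n for i, n in enumerate(names)}
        masks = {}
        for value, name in names.items():
            if name in masks:
                raise ValueError(f"duplicate muscle name {name!r}")
            masks[name] = label == int(value)
        return cls(masks=masks, **kw)

    @classmethod
    def from_polygons(
        cls, polygons: dict[str, list], shape: tuple[int, int], **kw
    ) -> "ROISet":
        masks = {
            name: rasterize_polygon(verts, shape) for name, verts in polygons.items()
        }
        return cls(masks=masks, **kw)


@dataclass
class MuscleMeasurement:
    """One per-muscle, per-visit fat-fraction summary."""

    subject_id: str
    muscle: str
    visit: str
    ff: float
    n_voxels: int
    fraction_invalid: float
    summary: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff <= 100.0:
            raise ValueError("FF summary must lie in [0, 100]")
        if self.n_voxels <= 0:
            raise ValueError("measurement must use at least one voxel")


def erode_roi(
    mask: np.ndarray, margin_voxels: int, *, muscle: str | None = None
) -> np.ndarray:
    """Erode a mask by ``margin_voxels`` (3x3 structuring element per step).

    Raises :class:`EmptyROIError` when erosion empties the mask — a silent
    empty ROI would vanish from downstream tables without trace.
    """
    if margin_voxels < 0:
        raise ValueError("erosion margin must be >= 0")
    mask = np.asarray(mask, bool)
    if margin_voxels == 0:
        out = mask.copy()
    else:
        out = ndimage.binary_erosion(mask, structure=_STRUCT, iterations=margin_voxels)
    if not out.any():
        raise EmptyROIError(
            muscle,
            f"ROI{f' for {muscle!r}' if muscle else ''} empty after erosion "
            f"by {margin_voxels} voxel(s)",
        )
    return out


def roi_fat_fraction(
    ff_map: FatFractionMap,
    mask: np.ndarray,
    *,
    summary: str = "mean",
    subject_id: str = "",
    muscle: str = "",
    visit: str = "",
) -> MuscleMeasurement:
    """Summarise the fat fraction over valid voxels of one ROI."""
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    mask = np.asarray(mask, bool)
    if mask.shape != ff_map.ff.shape:
        raise ValueError("mask grid does not match the fat-fraction map")
    n_total = int(mask.sum())
    if n_total == 0:
        raise EmptyROIError(muscle or None, f"ROI {muscle!r} is empty")
    use = mask & ff_map.valid
    n_valid = int(use.sum())
    if n_valid == 0:
        raise EmptyROIError(
            muscle or None, f"ROI {muscle!r} contains no valid voxels"
        )
    vals = ff_map.ff[use]
    stat = float(np.mean(vals) if summary == "mean" else np.median(vals))
    return MuscleMeasurement(
        subject_id=subject_id,
        muscle=muscle,
        visit=visit,
        ff=stat,
        n_voxels=n_valid,
        fraction_invalid=1.0 - n_valid / n_total,
        summary=summary,
    )


def measure_all(
    ff_map: FatFractionMap,
    rois: ROISet,
    *,
    erode_margin: int = 1,
    summary: str = "mean",
) -> list[MuscleMeasurement]:
    """Erode and summarise every ROI in the set against one FF map."""
    out = []
    for muscle, mask in rois.masks.items():
        m = erode_roi(mask, erode_margin, muscle=muscle)
        out.append(
            roi_fat_fraction(
                ff_map,
                m,
                summary=summary,
                subject_id=rois.subject_id,
                muscle=muscle,
                visit=rois.visit,
            )
        )
    return out


def pair_visits(
    measurements: "list[MuscleMeasurement] | pd.DataFrame",
    *,
    baseline: str = "baseline",
    followup: str = "12month",
) -> pd.DataFrame:
    """Pair baseline and follow-up measurements per (subject, muscle).

    Returns a wide table with one row per (subject, muscle) having both
    visits; rows without a complete pair are excluded and logged, matching
    a completers-only analysis.  The excluded rows are available as
    ``result.attrs['excluded']``.  Duplicate (subject, muscle, visit)
    entries raise.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "subject_id": m.subject_id,
                    "muscle": m.muscle,
                    "visit": m.visit,
                    "ff": m.ff,
                }
                for m in measurements
            ]
        )
    if df.empty:
        out = pd.DataFrame(
            columns=["subject_id", "muscle", "ff_baseline", "ff_followup"]
        )
        out.attrs["excluded"] = df
        return out
    value_col = "ff" if "ff" in df.columns else "ff_observed"
    dup = df.duplicated(subset=["subject_id", "muscle", "visit"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate measurement for subject {first['subject_id']!r}, "
            f"muscle {first['muscle']!r}, visit {first['visit']!r}"
        )
    wide = df.pivot(index=["subject_id", "muscle"], columns="visit", values=value_col)
    have_both = wide.notna().get(baseline, pd.Series(False, index=wide.index)) & (
        wide.notna().get(followup, pd.Series(False, index=wide.index))
    )
    excluded = wide[~have_both].reset_index()
    if len(excluded):
        subj = sorted(excluded["subject_id"].unique())
        logger.warning(
            "excluding %d unpaired (subject, muscle) rows (subjects: %s)",
            len(excluded),
            ", ".join(map(str, subj)),
        )
    out = (
        wide[have_both]
        .rename(columns={baseline: "ff_baseline", followup: "ff_followup"})[
            ["ff_baseline", "ff_followup"]
        ]
        .reset_index()
    )
    out.columns.name = None
    out.attrs["excluded"] = excluded
    return out


def jitter_mask(
    mask: np.ndarray, rng: np.random.Generator, flip_prob: float = 0.5
) -> np.ndarray:
    """Randomly perturb an ROI boundary, emulating independent observers.

    Inner-boundary voxels are dropped and outer-boundary voxels added each
    with probability ``flip_prob``; the symmetric rule introduces no
    systematic area bias, so two jittered observers of the same truth give
    a Bland-Altman bias near zero.
    """
    mask = np.asarray(mask, bool)
    inner = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT)
    outer = ndimage.binary_dilation(mask, structure=_STRUCT) & ~mask
    out = mask.copy()
    out[inner] = rng.random(int(inner.sum())) >= flip_prob
    out[outer] = rng.random(int(outer.sum())) < flip_prob
    return out
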