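"""Channel-redirected densitometry, percentage-of-sum signals, and the X index.

Each segmented object's pixel set (found on the merged image) is applied
back to the original red and green rasters -- a *redirected measurement* --
yielding one raw integrated density (sum of counts) per channel over the
same area.  Because the two fluorophores label a kinase and its
phospho-substrate within the same somata, the sum of the two signals is
treated as invariable and each channel is expressed as a proportion of that
sum:

    R = red / (red + green),   G = green / (red + green),   R + G = 1

and the two proportions are collapsed onto a single unified scale by

    X = (R - G) / (R + G)  in [-1, +1]

where X = +1 means pure red (kinase) signal and X = -1 pure green
(phospho-tau) signal.  Note that on normalized signals X = 2R - 1, i.e. R, G
and X carry the same information; in particular the rank correlation between
the R and G columns of any group is -1 *by construction* (G = 1 - R), so the
perfect negative per-group Spearman coefficient this pipeline reports is a
structural identity of the normalization, not an empirical finding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import group_stats
from .image_io import TwoChannelImage
from .segmentation import RoiObject, extract_objects, merge_to_gray, threshold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoiMeasurement:
    """Raw integrated densities of one object, measured in both channels."""

    label_id: int
    area_px: int
    raw_int_den_red: int
    raw_int_den_green: int

    def __post_init__(self) -> None:
        if self.raw_int_den_red < 0 or self.raw_int_den_green < 0:
            raise ValueError("raw integrated densities must be nonnegative")


@dataclass(frozen=True)
class RoiSignal:
    """Percentage-of-sum signals (R, G) and the X index for one ROI.

    A zero-sum ROI (no signal in either channel) cannot be normalized; it is
    returned flagged with NaN signals and excluded from statistics, never
    silently dropped.
    """

    label_id: int
    R: float
    G: float
    X: float
    flagged: bool = False


def measure_roi(obj: RoiObject, img: TwoChannelImage) -> RoiMeasurement:
    """Sum each original channel over the object's pixel set (redirected)."""
    rows, cols = obj.coords[:, 0], obj.coords[:, 1]
    h, w = img.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
        raise ValueError(
            f"ROI {obj.label_id} has pixels outside the {h}x{w} image bounds"
        )
    red_sum = int(img.red[rows, cols].sum(dtype=np.int64))
    green_sum = int(img.green[rows, cols].sum(dtype=np.int64))
    return RoiMeasurement(
        label_id=obj.label_id,
        area_px=obj.area_px,
        raw_int_den_red=red_sum,
        raw_int_den_green=green_sum,
    )


def percent_of_sum(m: RoiMeasurement) -> RoiSignal:
    """Express each channel as a proportion of the two-channel sum."""
    total = m.raw_int_den_red + m.raw_int_den_green
    if total == 0:
        logger.warning("ROI %d has zero total signal; flagged", m.label_id)
        return RoiSignal(m.label_id, math.nan, math.nan, math.nan, flagged=True)
    r = m.raw_int_den_red / total
    g = m.raw_int_den_green / total
    return RoiSignal(m.label_id, R=r, G=g, X=x_transform(r, g))


def x_transform(R: float, G: float) -> float:
    """The unified-scale index X = (R - G)/(R + G) in [-1, +1].

    Equals R - G when the signals are already normalized (R + G = 1).
    """
    if R < 0 or G < 0:
        raise ValueError("signal fractions must be nonnegative")
    s = R + G
    if s == 0:
        raise ValueError("X undefined for zero total signal")
    return (R - G) / s


@dataclass(frozen=True)
class CaseSummary:
    case_id: str
    mean_R: float
    mean_G: float
    mean_X: float
    n_rois: int


def aggregate_case(signals: list[RoiSignal], case_id: str) -> CaseSummary:
    """Arithmetic means of the unflagged ROI signals of one case."""
    ok = [s for s in signals if not s.flagged]
    n_flagged = len(signals) - len(ok)
    if n_flagged:
        logger.info("case %s: %d zero-sum ROI(s) excluded", case_id, n_flagged)
    if not ok:
        raise ValueError(f"case {case_id!r} has no measurable (unflagged) ROIs")
    return CaseSummary(
        case_id=case_id,
        mean_R=float(np.mean([s.R for s in ok])),
        mean_G=float(np.mean([s.G for s in ok])),
        mean_X=float(np.mean([s.X for s in ok])),
        n_rois=len(ok),
    )


@dataclass(frozen=True)
class GroupStats:
    """Per-group pooled statistics in the shape of a signal-correlation table."""

    group: str
    spearman_rho: float | None
    spearman_p: float | None
    mean_R: float
    mean_G: float
    mean_X: float
    sd_R: float
    sd_G: float
    sd_X: float
    se_R: float
    n_pairs: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "mean_R": self.mean_R,
            "mean_G": self.mean_G,
            "mean_X": self.mean_X,
            "sd_R": self.sd_R,
            "sd_G": self.sd_G,
            "sd_X": self.sd_X,
            "se_R": self.se_R,
            "n_pairs": self.n_pairs,
            "note": self.note,
        }


def aggregate_group(signals: list[RoiSignal], group: str) -> GroupStats:
    """Pool the unflagged per-ROI signals of a group.

    Spearman's rho (midranks) and its p are computed on the pooled per-ROI
    (R, G) pairs; n_pairs counts the ROIs entering the correlation.  A group
    whose R values are all identical has no rank variation and its rho is
    reported as undefined (None) rather than a number.
    """
    ok = [s for s in signals if not s.flagged]
    if len(ok) < 2:
        raise ValueError(f"group {group!r} needs >= 2 unflagged ROIs")
    r = np.array([s.R for s in ok])
    g = np.array([s.G for s in ok])
    x = np.array([s.X for s in ok])
    ddof = 1
    sd_r = float(np.std(r, ddof=ddof))
    stats_kwargs: dict = {}
    if np.unique(r).size < 2:
        rho: float | None = None
        p: float | None = None
        stats_kwargs["note"] = "rho undefined: all R values identical"
    else:
        res = group_stats.spearman(r, g)
        rho, p = res.statistic, res.p_value
    return GroupStats(
        group=group,
        spearman_rho=rho,
        spearman_p=p,
        mean_R=float(r.mean()),
        mean_G=float(g.mean()),
        mean_X=float(x.mean()),
        sd_R=sd_r,
        sd_G=float(np.std(g, ddof=ddof)),
        sd_X=float(np.std(x, ddof=ddof)),
        se_R=sd_r / math.sqrt(len(ok)),
        n_pairs=len(ok),
        **stats_kwargs,
    )


def quantify_image(
    img: TwoChannelImage,
    *,
    min_area_px: int = 400,
    connectivity: int = 8,
    threshold_method: str = "otsu",
    fixed_value: int | None = None,
    merge_rule: str = "mean2",
) -> pd.DataFrame:
    """Segment one two-channel image and measure every kept object.

    Returns a per-ROI table with columns label_id, area_px, rid_red,
    rid_green, R, G, X, flagged.  Empty if no object passes the area filter.
    """
    gray = merge_to_gray(img, rule=merge_rule)
    try:
        th = threshold(gray, method=threshold_method, fixed_value=fixed_value)
    except ValueError as exc:
        if "constant image" in str(exc):
            logger.warning("blank image skipped: %s", exc)
            return _empty_roi_table()
        raise
    objects = extract_objects(th.mask, min_area_px=min_area_px, connectivity=connectivity)
    rows = []
    for obj in objects:
        m = measure_roi(obj, img)
        s = percent_of_sum(m)
        rows.append(
            {
                "label_id": obj.label_id,
                "area_px": m.area_px,
                "rid_red": m.raw_int_den_red,
                "rid_green": m.raw_int_den_green,
                "R": s.R,
                "G": s.G,
                "X": s.X,
                "flagged": s.flagged,
            }
        )
    return pd.DataFrame(rows) if rows else _empty_roi_table()


def _empty_roi_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["label_id", "area_px", "rid_red", "rid_green", "R", "G", "X", "flagged"]
    )
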