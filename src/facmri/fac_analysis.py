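"""ROI statistics for adipose depots and phantom-validation statistics.

Depot means are computed from manually (or synthetically) segmented
masks after filtering: only voxels above a PDFF threshold (default 75%)
survive, segmentation borders are eroded away to limit partial-volume
contamination, flagged voxels are dropped, and slices contributing
fewer than a minimum pixel count (default 50) are excluded.  Phantom
agreement is assessed with ordinary least-squares regression and
Pearson correlation (Fisher-z confidence interval); scan-rescan
agreement with Bland-Altman statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion, generate_binary_structure

logger = logging.getLogger("facmri")

__all__ = [
    "ROIDefinition",
    "DepotSummary",
    "apply_roi_filters",
    "depot_summary",
    "validation_regression",
    "bland_altman",
    "welch_anova",
]


@dataclass(frozen=True)
class ROIDefinition:
    """A labelled region of interest on one slice."""

    label: str
    mask: np.ndarray
    slice_id: str = "0"


@dataclass(frozen=True)
class DepotSummary:
    """Pooled per-depot statistics across qualifying slices."""

    label: str
    n_pixels: int
    means: dict
    sds: dict


def apply_roi_filters(roi: ROIDefinition, maps: dict,
                      pdff_threshold: float = 0.75,
                      erode_border: int = 1,
                      residual_percentile: float = 95.0) -> np.ndarray:
    """Filtered ROI mask: PDFF gate, border erosion, flag/artifact removal.

    Keeps voxels inside the (eroded) segmentation whose PDFF exceeds the
    threshold, are not flagged invalid by the fit, and whose residual
    lies below the given percentile within the ROI ("artifact-free",
    operationally).
    """
    mask = roi.mask.astype(bool)
    if mask.shape != maps["pdff"].shape:
        raise ValueError("ROI mask and maps have different geometry")
    if erode_border > 0:
        structure = generate_binary_structure(2, 1)     # 4-connected
        mask = binary_erosion(mask, structure=structure,
                              iterations=erode_border)
    mask = mask & (maps["pdff"] > pdff_threshold)
    if "valid" in maps:
        mask = mask & maps["valid"]
    if "residual" in maps and residual_percentile < 100 and mask.sum() > 0:
        cut = np.percentile(maps["residual"][mask], residual_percentile)
        mask = mask & (maps["residual"] <= cut)
    if mask.sum() == 0:
        warnings.warn(f"ROI {roi.label!r} empty after filtering", stacklevel=2)
    return mask


def depot_summary(rois, maps_by_slice: dict, min_pixels: int = 50,
                  metrics=("pdff", "sfa", "mufa", "pufa", "ndb", "nmidb"),
                  **filter_kwargs) -> dict:
    """Pooled per-depot means/SDs over all slices with enough pixels.

    ``maps_by_slice`` maps slice_id -> maps dict.  Slices whose filtered
    ROI has fewer than ``min_pixels`` voxels are excluded (and logged);
    labels with no qualifying slice are omitted with a warning.  Pixels
    are pooled across qualifying slices before averaging.
    """
    pooled = {}
    for roi in rois:
        maps = maps_by_slice[roi.slice_id]
        filt = apply_roi_filters(roi, maps, **filter_kwargs)
        n = int(filt.sum())
        if n < min_pixels:
            logger.info("slice %s of %s excluded (%d px < %d)",
                        roi.slice_id, roi.label, n, min_pixels)
            continue
        vals = pooled.setdefault(roi.label, {m: [] for m in metrics})
        for m in metrics:
            vals[m].append(maps[m][filt])
    out = {}
    for roi in rois:
        if roi.label in out or roi.label not in pooled:
            if roi.label not in pooled and roi.label not in out:
                warnings.warn(f"depot {roi.label!r} has no qualifying slice",
                              stacklevel=2)
            continue
        vals = pooled[roi.label]
        cat = {m: np.concatenate(v) for m, v in vals.items()}
        n = len(next(iter(cat.values())))
        out[roi.label] = DepotSummary(
            label=roi.label,
            n_pixels=n,
            means={m: float(np.mean(v)) for m, v in cat.items()},
            sds={m: float(np.std(v, ddof=1)) if n > 1 else 0.0
                 for m, v in cat.items()},
        )
    return out


def validation_regression(measured, reference) -> dict:
    """OLS regression and Pearson correlation of measured vs reference values.

    Returns slope, intercept, Pearson r with its Fisher-z 95% confidence
    interval, and the two-sided p-value for r != 0.  Callers enforce the
    FAC convention of restricting to pure-fat (100% PDFF) samples.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise ValueError("measured and reference lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 points for regression")
    res = stats.linregress(x, y)
    r = res.rvalue
    n = x.size
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959963985 * se)),
              float(np.tanh(z + 1.959963985 * se)))
    else:
        ci = (np.nan, np.nan)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(r),
        "r_ci95": ci,
        "p": float(res.pvalue),
        "n": int(n),
    }


def bland_altman(reference, repeat) -> dict:
    """Bland-Altman agreement of repeat measurements against a reference.

    ``bias`` is the mean difference (repeat - reference), limits of
    agreement are ``bias +/- 1.96 sd``, and the mean absolute difference
    is reported alongside.
    """
    ref = np.asarray(reference, dtype=float)
    rep = np.asarray(repeat, dtype=float)
    if ref.size != rep.size:
        raise ValueError("paired lists have different lengths")
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = rep - ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "mean_abs_diff": float(np.mean(np.abs(diff))),
        "sd": sd,
        "n": int(ref.size),
    }


def welch_anova(groups: dict) -> dict:
    """Welch's heteroscedastic one-way ANOVA across depot groups.

    Thin utility for comparing depot means without assuming equal
    variances; returns the Welch F statistic and p-value.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([a.size for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    vars_ = np.array([a.var(ddof=1) for a in arrays])
    w = ns / vars_
    mw = np.sum(w * means) / np.sum(w)
    k = len(arrays)
    num = np.sum(w * (means - mw) ** 2) / (k - 1)
    tmp = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1) * tmp
    f = num / den
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3.0 * tmp)
    p = float(stats.f.sf(f, df1, df2))
    return {"F": float(f), "df1": float(df1), "df2": float(df2), "p": p}


def summaries_to_frame(summaries: dict) -> pd.DataFrame:
    """DepotSummary dict -> tidy DataFrame (one row per depot)."""
    rows = []
    for label, s in summaries.items():
        row = {"label": label, "n_pixels": s.n_pixels}
        for m, v in s.means.items():
            row[f"{m}_mean"] = v
        for m, v in s.sds.items():
            row[f"{m}_sd"] = v
        rows.append(row)
    return pd.DataFrame(rows)
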