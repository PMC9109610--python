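"""Comparison metrics: masked Spearman, tertile DSC, ANOVA/Tukey.

A ventilation map is compared to its reference voxel-wise (Spearman rank
correlation over the lung mask) and regionally: both maps are split into
high-, medium- and low-functional lung (HFL/MFL/LFL) at the 33.3rd and
66.7th percentiles of their own in-mask values, and same-named regions are
compared with the Dice similarity coefficient

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|),

averaged over the three regions.  Two independent tertile maps give an
expected DSC of 1/3 — the chance floor against which methods are judged.
Method-level differences in averaged DSC are tested with one-way ANOVA and
Tukey's honestly-significant-difference procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, GeometryError, UndefinedStatisticError
from .imagecore import Mask, Volume
from .ventilation import VentilationImage

__all__ = [
    "FunctionalSegmentation",
    "spearman_masked",
    "tertile_segmentation",
    "dice_coefficient",
    "averaged_dsc",
    "anova_tukey",
    "evaluate_subject",
]

REGIONS = ("LFL", "MFL", "HFL")
_LABELS = {"outside": 0, "LFL": 1, "MFL": 2, "HFL": 3}


@dataclass
class FunctionalSegmentation:
    """Tertile functional-lung labels over the exhale geometry.

    ``labels`` holds 0 outside the mask, 1/2/3 for LFL/MFL/HFL.
    """

    labels: np.ndarray
    mask: Mask
    t_low: float
    t_high: float

    def region(self, name: str) -> np.ndarray:
        if name not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        return self.labels == _LABELS[name]


def _as_values(vol) -> np.ndarray:
    if isinstance(vol, VentilationImage):
        return vol.values
    if isinstance(vol, Volume):
        return vol.values
    return np.asarray(vol)


def spearman_masked(a, b, mask: Mask) -> float:
    """Spearman rank correlation over in-mask voxels (average ranks on ties)."""
    av, bv = _as_values(a), _as_values(b)
    if av.shape != mask.values.shape or bv.shape != mask.values.shape:
        raise GeometryError("inputs and mask must share one grid")
    m = mask.values
    if m.sum() < 3:
        raise DataError("mask must contain at least 3 voxels")
    x, y = av[m], bv[m]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def tertile_segmentation(vi, mask: Mask) -> FunctionalSegmentation:
    """Split in-mask values into equal-count LFL/MFL/HFL regions.

    Thresholds are the 33 1/3 and 66 2/3 linear-interpolation percentiles of
    the in-mask values; LFL = v < t_low, MFL = t_low <= v < t_high,
    HFL = v >= t_high, so threshold ties go deterministically to the higher
    region.
    """
    values = _as_values(vi)
    if values.shape != mask.values.shape:
        raise GeometryError("ventilation and mask must share one grid")
    mask.require_nonempty("tertile mask")
    m = mask.values
    in_mask = values[m]
    if np.ptp(in_mask) == 0:
        raise DataError("constant ventilation in mask: tertiles are degenerate")
    t_low, t_high = np.percentile(in_mask, [100.0 / 3.0, 200.0 / 3.0])
    labels = np.zeros(values.shape, dtype=np.uint8)
    labels[m & (values < t_low)] = _LABELS["LFL"]
    labels[m & (values >= t_low) & (values < t_high)] = _LABELS["MFL"]
    labels[m & (values >= t_high)] = _LABELS["HFL"]
    return FunctionalSegmentation(labels, mask, float(t_low), float(t_high))


def dice_coefficient(
    seg_a: FunctionalSegmentation, seg_b: FunctionalSegmentation, region: str
) -> float:
    """Dice overlap of one named region: 2|A∩B| / (|A| + |B|)."""
    if seg_a.labels.shape != seg_b.labels.shape:
        raise GeometryError("segmentations must share one grid")
    a, b = seg_a.region(region), seg_b.region(region)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn(f"both {region} regions empty; DSC defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def averaged_dsc(seg_a: FunctionalSegmentation, seg_b: FunctionalSegmentation) -> float:
    """Mean of the three regional Dice coefficients."""
    return float(np.mean([dice_coefficient(seg_a, seg_b, r) for r in REGIONS]))


def anova_tukey(dsc_table: pd.DataFrame) -> dict:
    """One-way ANOVA + Tukey HSD across methods on per-subject averaged DSC.

    ``dsc_table`` has one column per method, one row per subject.  Returns
    the overall F statistic and p-value plus Tukey-adjusted p-values for all
    method pairs (studentized-range distribution).
    """
    methods = list(dsc_table.columns)
    if len(methods) < 2:
        raise DataError("need at least 2 methods")
    groups = [np.asarray(dsc_table[mname], dtype=float) for mname in methods]
    sizes = {len(g) for g in groups}
    if len(sizes) != 1 or min(sizes) < 2:
        raise DataError("methods must have equal, >= 2, per-subject counts")
    if any(np.isnan(g).any() for g in groups):
        raise DataError("missing cells in the DSC table")
    f_stat, f_p = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    pairs = {}
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            pairs[(methods[i], methods[j])] = float(tukey.pvalue[i, j])
    return {"F": float(f_stat), "p": float(f_p), "tukey": pairs}


def evaluate_subject(
    estimates: dict[str, VentilationImage],
    reference: VentilationImage,
    mask: Mask,
) -> pd.DataFrame:
    """Per-method Spearman and tertile DSC of estimates against a reference.

    Returns one row per method with columns spearman, dsc_hfl, dsc_mfl,
    dsc_lfl, dsc_avg.
    """
    seg_ref = tertile_segmentation(reference, mask)
    rows = []
    for method, vi in estimates.items():
        seg = tertile_segmentation(vi, mask)
        row = {
            "method": method,
            "spearman": spearman_masked(vi, reference, mask),
            "dsc_hfl": dice_coefficient(seg_ref, seg, "HFL"),
            "dsc_mfl": dice_coefficient(seg_ref, seg, "MFL"),
            "dsc_lfl": dice_coefficient(seg_ref, seg, "LFL"),
        }
        row["dsc_avg"] = float(np.mean([row["dsc_hfl"], row["dsc_mfl"], row["dsc_lfl"]]))
        rows.append(row)
    return pd.DataFrame(rows)
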