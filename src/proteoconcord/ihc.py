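"""Positive-pixel-count quantification of DAB-stained histology images.

Pixels inside a region of interest (ROI, e.g. hippocampal CA1-3 subfields)
are classified from their hue / saturation / intensity: a pixel is a
stain-positive candidate when its circular hue distance to the stain hue is
within a tolerance and its saturation clears a floor, and candidates are
binned by intensity into strong / medium / weak positivity (darker = more
stain). Percent positive area per ROI and the unweighted per-case mean
across ROIs are reported, and case vs control groups are compared by fold
change of means with a Welch t (default) or Mann-Whitney test.

HSI convention: hue on the [0,1) circle from the standard arccos formula,
saturation = 1 - 3*min(R,G,B)/(R+G+B), intensity = (R+G+B)/3 on 0-255.
Achromatic pixels (R=G=B) have saturation 0 and an undefined hue, treated as
hue-matching (the intensity gate still applies); pure black has undefined
saturation and is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PixelClassifierConfig",
    "PositivePixelResult",
    "GroupComparison",
    "rgb_to_hsi",
    "classify_pixel",
    "classify_image",
    "percent_positive",
    "compare_groups",
]


@dataclass(frozen=True)
class PixelClassifierConfig:
    """Hue/saturation gates and intensity class bounds for stain positivity.

    Intensity classes on 0-255: strong [i_sp_lo, i_sp_hi), medium
    [i_sp_hi, i_p_hi), weak [i_p_hi, i_wp_hi). The shipped defaults encode
    saturation_min = 0 and i_wp_hi = 80 (the two vendor-algorithm
    modifications this pipeline standardises on); the remaining thresholds
    are example values for a DAB-brown stain and must be calibrated per
    stain — they carry no canonical status.
    """

    hue_center: float = 0.05
    hue_width: float = 0.15
    saturation_min: float = 0.0
    i_sp_lo: int = 0
    i_sp_hi: int = 60
    i_p_hi: int = 65
    i_wp_hi: int = 80

    def __post_init__(self):
        if not (0 <= self.i_sp_lo < self.i_sp_hi <= self.i_p_hi <= self.i_wp_hi <= 255):
            raise ValueError("intensity bounds must satisfy 0 <= sp_lo < sp_hi <= p_hi <= wp_hi <= 255")
        if not 0 <= self.hue_center < 1 or self.hue_width > 0.5 or self.hue_width < 0:
            raise ValueError("hue_center in [0,1), hue_width in [0, 0.5]")
        if not 0 <= self.saturation_min <= 1:
            raise ValueError("saturation_min in [0,1]")


@dataclass
class PositivePixelResult:
    """Per-ROI class counts/percentages and the per-case ROI average."""

    roi_counts: dict[str, dict[str, int]]
    roi_percent_positive: dict[str, float]
    case_percent_positive: float | None
    skipped_rois: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    mean_cases: float
    mean_controls: float
    fold_change: float | None
    statistic: float
    p: float
    test: str


def rgb_to_hsi(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised RGB -> (hue, saturation, intensity).

    Hue is on [0,1) (NaN where undefined: achromatic pixels), saturation on
    [0,1] (NaN for pure black), intensity on [0,255].
    """
    arr = np.asarray(rgb, dtype=float)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    total = r + g + b
    intensity = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, np.nan)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cos_theta = np.clip(np.where(den > 0, num / den, np.nan), -1.0, 1.0)
        theta = np.arccos(cos_theta) / (2.0 * np.pi)
    hue = np.where(b > g, 1.0 - theta, theta)
    hue = np.where(np.isnan(theta), np.nan, hue)
    return hue, saturation, intensity


def _classify_arrays(hue, sat, intensity, cfg: PixelClassifierConfig) -> np.ndarray:
    """Class codes: 0 negative, 1 weak, 2 medium, 3 strong."""
    hue_dist = np.abs(hue - cfg.hue_center)
    hue_dist = np.minimum(hue_dist, 1.0 - hue_dist)
    hue_ok = np.where(np.isnan(hue), True, hue_dist <= cfg.hue_width)  # achromatic: hue passes
    sat_ok = np.where(np.isnan(sat), False, sat >= cfg.saturation_min)  # black: negative
    candidate = hue_ok & sat_ok
    out = np.zeros(np.shape(intensity), dtype=np.uint8)
    out[candidate & (intensity >= cfg.i_sp_lo) & (intensity < cfg.i_sp_hi)] = 3
    out[candidate & (intensity >= cfg.i_sp_hi) & (intensity < cfg.i_p_hi)] = 2
    out[candidate & (intensity >= cfg.i_p_hi) & (intensity < cfg.i_wp_hi)] = 1
    return out


def classify_pixel(rgb: Sequence[float], cfg: PixelClassifierConfig) -> str:
    """Classify one RGB triple as strong / medium / weak / negative."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,) or arr.min() < 0 or arr.max() > 255:
        raise ValueError("rgb must be three values in [0, 255]")
    code = int(_classify_arrays(*rgb_to_hsi(arr.reshape(1, 3)), cfg)[0])
    return {0: "negative", 1: "weak", 2: "medium", 3: "strong"}[code]


def classify_image(image: np.ndarray, cfg: PixelClassifierConfig) -> np.ndarray:
    """Class-code map (0-3) of an RGB image array (H x W x 3)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an H x W x 3 RGB image array")
    return _classify_arrays(*rgb_to_hsi(img[..., :3]), cfg)


def percent_positive(
    image: np.ndarray,
    roi_masks: Mapping[str, np.ndarray],
    cfg: PixelClassifierConfig | None = None,
) -> PositivePixelResult:
    """Percent positive pixel area per ROI and the per-case ROI mean.

    The per-case value is the unweighted mean of ROI percentages (averaged
    across all regions per case). Empty ROIs are skipped with a record; a
    case with no valid ROI gets a missing value.
    """
    cfg = cfg or PixelClassifierConfig()
    codes = classify_image(image, cfg)
    roi_counts: dict[str, dict[str, int]] = {}
    roi_pct: dict[str, float] = {}
    skipped: list[str] = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask).astype(bool)
        if mask.shape != codes.shape:
            raise ValueError(f"ROI {name!r} mask shape {mask.shape} != image {codes.shape}")
        n_total = int(mask.sum())
        if n_total == 0:
            skipped.append(name)
            continue
        sub = codes[mask]
        counts = {
            "strong": int((sub == 3).sum()),
            "medium": int((sub == 2).sum()),
            "weak": int((sub == 1).sum()),
            "negative": int((sub == 0).sum()),
            "total": n_total,
        }
        roi_counts[name] = counts
        roi_pct[name] = 100.0 * (counts["strong"] + counts["medium"] + counts["weak"]) / n_total
    case_value = float(np.mean(list(roi_pct.values()))) if roi_pct else None
    return PositivePixelResult(roi_counts, roi_pct, case_value, skipped)


def compare_groups(
    case_values: Sequence[float],
    control_values: Sequence[float],
    test: str = "welch_t",
) -> GroupComparison:
    """Fold change of group means plus a two-sided test.

    ``test`` is ``welch_t`` (unequal-variance t) or ``mann_whitney``. A zero
    control mean leaves the fold change undefined (None).
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("need at least 2 values per group")
    mc, mk = float(cases.mean()), float(controls.mean())
    fold = mc / mk if mk != 0 else None
    if test == "welch_t":
        res = stats.ttest_ind(cases, controls, equal_var=False)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(cases, controls, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(mc, mk, fold, float(res.statistic), float(res.pvalue), test)
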