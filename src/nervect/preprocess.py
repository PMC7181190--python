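"""Volume conditioning chain for stained-nerve microCT stacks.

The canonical order is trim → stretch → median → longitudinal smooth →
binarize: cone-beam-affected end slices are removed, the histogram is
stretched to drop irrelevant extreme pixels, a 3×3×3 median filter
suppresses speckle, a 1×1×5 moving average along z exploits the
longitudinal continuity of fascicles, and a two-sided grey range picks
out the fascicle intensity band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volume import Mask, Volume

__all__ = [
    "GreyRange",
    "trim_end_slices",
    "stretch_histogram",
    "median_filter_3d",
    "longitudinal_smooth",
    "binarize",
    "suggest_threshold",
]


@dataclass(frozen=True)
class GreyRange:
    """A closed grey-value interval [low, high] on the normalized scale."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValueError(f"need 0 <= low < high <= 1; got [{self.low}, {self.high}]")


def trim_end_slices(volume: Volume, n_low: int, n_high: int) -> Volume:
    """Drop ``n_low`` slices from the start and ``n_high`` from the end of z."""
    nz = volume.shape[0]
    if n_low < 0 or n_high < 0:
        raise ValueError("trim counts must be non-negative")
    if n_low + n_high >= nz:
        raise ValueError(f"cannot trim {n_low}+{n_high} slices from a {nz}-slice stack")
    return volume.with_data(volume.data[n_low:nz - n_high].copy(),
                            note=f"trim [{n_low}, {n_high}]")


def stretch_histogram(volume: Volume, p_low: float = 0.5, p_high: float = 99.5) -> Volume:
    """Linearly map the [p_low, p_high] percentile band onto [0, 1], clipping outside."""
    if not (0.0 <= p_low < p_high <= 100.0):
        raise ValueError("need 0 <= p_low < p_high <= 100")
    lo, hi = np.percentile(volume.data, [p_low, p_high])
    if hi <= lo:
        raise ValueError(f"degenerate histogram: percentiles {p_low} and {p_high} "
                         f"both map to {lo}")
    out = np.clip((volume.data - lo) / (hi - lo), 0.0, 1.0)
    return volume.with_data(out, note=f"stretch p=({p_low}, {p_high})")


def median_filter_3d(volume: Volume) -> Volume:
    """3×3×3 median filter with reflect padding at the faces."""
    if min(volume.shape) < 3:
        raise ValueError(f"volume {volume.shape} thinner than the 3x3x3 kernel")
    out = ndimage.median_filter(volume.data, size=3, mode="reflect")
    return volume.with_data(out, note="median 3x3x3")


def longitudinal_smooth(volume: Volume) -> Volume:
    """1×1×5 uniform moving average along z with reflect padding; XY untouched."""
    if volume.shape[0] < 5:
        raise ValueError("need at least 5 slices for the 1x1x5 longitudinal kernel")
    out = ndimage.uniform_filter1d(volume.data, size=5, axis=0, mode="reflect")
    np.clip(out, 0.0, 1.0, out=out)  # guard float summation error at the bounds
    return volume.with_data(out, note="longitudinal mean 1x1x5")


def binarize(volume: Volume, range: GreyRange) -> Mask:
    """Threshold to the closed interval: true where low <= grey <= high."""
    data = (volume.data >= range.low) & (volume.data <= range.high)
    return Mask(data, voxel_size_um=volume.voxel_size_um)


def suggest_threshold(volume: Volume, k_classes: int = 4,
                      fascicle_mean_hint: float = 0.55) -> GreyRange:
    """Suggest a fascicle grey range by multi-level Otsu partitioning.

    Partitions the intensity histogram into ``k_classes`` classes, picks
    the class whose mean is nearest the supplied fascicle-mean hint, and
    refines it by further two-level Otsu splits while a sub-class moves
    the mean closer to the hint (the count-weighted global optimum can
    lump a minority tissue such as cling film in with the fascicles). A
    suggestion only — in practice the range is checked against the slices
    and overridden by config where needed.
    """
    if k_classes < 2:
        raise ValueError("need at least 2 intensity classes")
    data = volume.data
    if np.unique(data).size < k_classes:
        raise ValueError("degenerate histogram: fewer distinct grey values than classes")
    try:
        cuts = threshold_multiotsu(data, classes=k_classes)
    except ValueError as e:  # pragma: no cover - skimage degenerate-input path
        raise ValueError(f"degenerate histogram: {e}") from e
    edges = np.concatenate([[0.0], cuts, [1.0]])
    class_means = []
    for i in range(k_classes):
        members = data[(data >= edges[i]) & (data <= edges[i + 1])]
        class_means.append(members.mean() if members.size else np.inf)
    best = int(np.argmin(np.abs(np.asarray(class_means) - fascicle_mean_hint)))
    lo, hi = float(edges[best]), float(edges[best + 1])

    from skimage.filters import threshold_otsu
    for _ in range(4):
        members = data[(data >= lo) & (data <= hi)]
        if members.size == 0 or np.unique(members).size < 2:
            break
        cut = float(threshold_otsu(members))
        lower, upper = members[members <= cut], members[members > cut]
        if lower.size == 0 or upper.size == 0:
            break
        cur_err = abs(members.mean() - fascicle_mean_hint)
        cands = [(abs(lower.mean() - fascicle_mean_hint), lo, cut),
                 (abs(upper.mean() - fascicle_mean_hint), cut, hi)]
        err, new_lo, new_hi = min(cands)
        if err >= cur_err - 1e-12:
            break
        lo, hi = new_lo, new_hi
    return GreyRange(lo, hi)
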