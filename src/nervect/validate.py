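"""Quantitative validation of segmented fascicles against a reference.

Mirrors the histology-based check used for stained-nerve microCT: per
region (fascicle cross-section) the area is measured and converted to an
equivalent-circle diameter ``2 sqrt(A / π)``, and segmented regions are
compared to reference regions as a percentage diameter difference
relative to the reference. Against phantom ground truth, volumetric
overlap is scored with the Dice coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "RegionMeasure",
    "DiameterComparison",
    "measure_regions",
    "compare_diameters",
    "overlap_score",
]


@dataclass(frozen=True)
class RegionMeasure:
    region_id: int
    area_um2: float
    equivalent_diameter_um: float

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("region area must be positive")


@dataclass
class DiameterComparison:
    pairs: list[tuple[int, float, float, float]]  # (id, d_ct, d_ref, pct_diff)
    mean_pct_diff: float
    sd_pct_diff: float


def measure_regions(mask_slice: np.ndarray, voxel_size_um: float) -> list[RegionMeasure]:
    """Measure 8-connected regions of one cross-sectional slice.

    Area is voxel count times the voxel area; the equivalent diameter is
    that of the circle with the same area. Regions are returned in
    descending area order with 1-based ids following that order.
    """
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if mask_slice.ndim != 2:
        raise ValueError("measure_regions expects a single 2D slice")
    if not mask_slice.any():
        raise ValueError("empty slice: no regions to measure")
    labels = measure.label(mask_slice, connectivity=2)
    counts = np.bincount(labels.ravel())[1:]
    order = np.argsort(counts)[::-1]
    out = []
    for rank, idx in enumerate(order, start=1):
        area = float(counts[idx]) * voxel_size_um ** 2
        out.append(RegionMeasure(rank, area, 2.0 * math.sqrt(area / math.pi)))
    return out


def compare_diameters(ct: list[RegionMeasure], ref: list[RegionMeasure],
                      pairing: dict[int, int] | None = None,
                      symmetric: bool = False) -> DiameterComparison:
    """Pairwise percentage diameter difference of segmented vs reference regions.

    ``pairing`` maps ct region ids to ref region ids; by default regions
    are paired by id. The percentage difference is |d_ct − d_ref| / d_ref
    × 100 (relative to the reference); with ``symmetric=True`` the
    denominator is the pair mean instead.
    """
    ref_by_id = {r.region_id: r for r in ref}
    if pairing is None:
        pairing = {c.region_id: c.region_id for c in ct}
    missing = [c.region_id for c in ct if c.region_id not in pairing]
    missing += [cid for cid, rid in pairing.items() if rid not in ref_by_id]
    if missing:
        raise ValueError(f"unpaired region ids: {sorted(set(missing))}")
    seen_refs = list(pairing.values())
    if len(set(seen_refs)) != len(seen_refs):
        raise ValueError("pairing must be one-to-one")
    pairs = []
    for c in ct:
        r = ref_by_id[pairing[c.region_id]]
        d_ct, d_ref = c.equivalent_diameter_um, r.equivalent_diameter_um
        denom = (d_ct + d_ref) / 2.0 if symmetric else d_ref
        pairs.append((c.region_id, d_ct, d_ref, abs(d_ct - d_ref) / denom * 100.0))
    diffs = np.array([p[3] for p in pairs])
    return DiameterComparison(pairs, float(diffs.mean()), float(diffs.std()))


def overlap_score(seg: np.ndarray, truth: np.ndarray, fascicle_id: int | None = None) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of a segmentation vs truth.

    ``truth`` may be boolean or an instance-label volume, in which case
    ``fascicle_id`` selects the instance to compare against.
    """
    a = np.asarray(seg, dtype=bool)
    t = np.asarray(truth)
    b = t == fascicle_id if fascicle_id is not None else t.astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("both masks empty: Dice undefined")
    return 2.0 * int((a & b).sum()) / denom
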