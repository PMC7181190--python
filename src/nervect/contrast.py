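"""Grey-value profiling and protocol-quality metrics.

Two scalar metrics drive protocol selection for stained-nerve microCT:

* the distinguishability score ``d``, the sum of pairwise absolute
  differences between the mean greys of fascicle, interfascicular
  epineurium and adipocyte tissue,

  .. math:: d = |\\bar i_f - \\bar i_e| + |\\bar i_e - \\bar i_a| + |\\bar i_a - \\bar i_f|

  which for three reals equals twice the range ``2 (max - min)``; and

* the fascicle-to-background signal-to-noise ratio,

  .. math:: \\mathrm{SNR} = \\mu_{fascicle} / \\sigma_{background},

  the mean grey of a fascicle pixel block over the standard deviation of
  a background block.

The staining time or scan setting that maximises the metric is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import TissueClass
from .volume import Volume

__all__ = [
    "LineProfile",
    "TissueStats",
    "DistinguishabilityResult",
    "SnrResult",
    "BlockROI",
    "extract_line_profile",
    "tissue_grey_stats",
    "distinguishability",
    "snr",
    "rank_protocols",
]


@dataclass
class LineProfile:
    """Grey values sampled at unit-pixel steps along a straight segment."""

    positions_px: np.ndarray
    greys: np.ndarray
    endpoints: tuple[int, float, float, float, float]  # (z, y0, x0, y1, x1)
    annotations: list[tuple[float, float, TissueClass]] = field(default_factory=list)

    def annotate(self, start_px: float, end_px: float, tissue: TissueClass) -> None:
        """Tag the interval [start_px, end_px] as one tissue type."""
        for s, e, _ in self.annotations:
            if start_px < e and end_px > s:
                raise ValueError("annotated intervals must not overlap")
        self.annotations.append((start_px, end_px, tissue))


@dataclass
class TissueStats:
    """Per-tissue mean, population sd and pixel count of grey values."""

    means: dict[TissueClass, float]
    sds: dict[TissueClass, float]
    counts: dict[TissueClass, int]


@dataclass
class DistinguishabilityResult:
    d: float
    pairwise_terms: tuple[float, float, float]  # |f-e|, |e-a|, |a-f|
    inputs_echo: tuple[float, float, float]  # (fascicle, epineurium, adipocyte)


@dataclass
class SnrResult:
    snr: float
    mu_fascicle: float
    sigma_background: float
    block_shapes: tuple[tuple[int, ...], tuple[int, ...]]


@dataclass(frozen=True)
class BlockROI:
    """An axis-aligned box (z0:z1, y0:y1, x0:x1) in voxel coordinates."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def extract(self, volume: Volume) -> np.ndarray:
        block = volume.data[self.z0:self.z1, self.y0:self.y1, self.x0:self.x1]
        if block.size == 0:
            raise ValueError(f"empty block {self}")
        return block

    def overlaps(self, other: "BlockROI") -> bool:
        return (self.z0 < other.z1 and other.z0 < self.z1
                and self.y0 < other.y1 and other.y0 < self.y1
                and self.x0 < other.x1 and other.x0 < self.x1)


def extract_line_profile(volume: Volume, z: int, start: tuple[float, float],
                         end: tuple[float, float]) -> LineProfile:
    """Sample greys along a straight segment in slice ``z``.

    The segment from ``start`` to ``end`` (both (y, x), pixels) is sampled
    at unit-pixel steps by bilinear interpolation; position 0 is the start
    point and the end point is included when the length is integral, so a
    100-px segment yields 101 samples.
    """
    (y0, x0), (y1, x1) = start, end
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length == 0:
        raise ValueError("zero-length profile segment")
    ny, nx = volume.shape[1:]
    for y, x in (start, end):
        if not (0 <= y <= ny - 1 and 0 <= x <= nx - 1):
            raise ValueError(f"profile endpoint ({y}, {x}) outside slice {ny}x{nx}")
    n = int(np.floor(length + 1e-9)) + 1
    pos = np.arange(n, dtype=np.float64)
    ys = y0 + (y1 - y0) * pos / length
    xs = x0 + (x1 - x0) * pos / length
    greys = ndimage.map_coordinates(volume.data[z], [ys, xs], order=1, mode="nearest")
    return LineProfile(pos, greys, (z, y0, x0, y1, x1))


def tissue_grey_stats(volume_or_profile, regions=None,
                      classes: tuple[TissueClass, ...] | None = None) -> TissueStats:
    """Per-tissue mean and population sd of grey values.

    Accepts either a :class:`Volume` plus a tissue label array of the same
    shape, or an annotated :class:`LineProfile`. Raises when a requested
    class has no member pixels.
    """
    means: dict[TissueClass, float] = {}
    sds: dict[TissueClass, float] = {}
    counts: dict[TissueClass, int] = {}
    if isinstance(volume_or_profile, LineProfile):
        prof = volume_or_profile
        if not prof.annotations:
            raise ValueError("profile has no tissue annotations")
        for s, e, tc in prof.annotations:
            sel = (prof.positions_px >= s) & (prof.positions_px <= e)
            vals = prof.greys[sel]
            if vals.size == 0:
                raise ValueError(f"no profile pixels in interval for {tc.name}")
            means[tc] = float(vals.mean())
            sds[tc] = float(vals.std())
            counts[tc] = int(vals.size)
        return TissueStats(means, sds, counts)
    volume: Volume = volume_or_profile
    labels = np.asarray(regions)
    if labels.shape != volume.shape:
        raise ValueError("label array shape must match the volume")
    if classes is None:
        classes = tuple(TissueClass(c) for c in np.unique(labels) if c != 0)
    for tc in classes:
        vals = volume.data[labels == int(tc)]
        if vals.size == 0:
            raise ValueError(f"tissue class {TissueClass(tc).name} has no member voxels")
        means[tc] = float(vals.mean())
        sds[tc] = float(vals.std())
        counts[tc] = int(vals.size)
    return TissueStats(means, sds, counts)


def distinguishability(stats: TissueStats | dict) -> DistinguishabilityResult:
    """Distinguishability d: sum of pairwise absolute mean differences.

    Requires the fascicle, epineurium and adipocyte means; for any three
    reals d equals twice their range.
    """
    means = stats.means if isinstance(stats, TissueStats) else stats
    try:
        f = means[TissueClass.FASCICLE]
        e = means[TissueClass.EPINEURIUM]
        a = means[TissueClass.ADIPOCYTE]
    except KeyError as missing:
        raise ValueError(f"missing tissue class for distinguishability: {missing}") from None
    terms = (abs(f - e), abs(e - a), abs(a - f))
    return DistinguishabilityResult(d=sum(terms), pairwise_terms=terms,
                                    inputs_echo=(f, e, a))


def snr(volume: Volume, fascicle_block: BlockROI, background_block: BlockROI) -> SnrResult:
    """Fascicle-to-background SNR: block mean over block sd."""
    if fascicle_block.overlaps(background_block):
        raise ValueError("fascicle and background blocks must not overlap")
    fb = fascicle_block.extract(volume)
    bb = background_block.extract(volume)
    sigma = float(bb.std())
    if sigma == 0:
        raise ValueError("background block has zero grey variance; SNR undefined")
    mu = float(fb.mean())
    return SnrResult(snr=mu / sigma, mu_fascicle=mu, sigma_background=sigma,
                     block_shapes=(fb.shape, bb.shape))


def rank_protocols(scores: list[tuple[str, float]]) -> tuple[str, bool]:
    """Return the condition id with the maximal score.

    Ties are broken in favour of the earliest listed condition and
    reported via the returned tie flag.
    """
    if not scores:
        raise ValueError("no conditions to rank")
    for cid, s in scores:
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for condition {cid!r}")
    best_id, best = scores[0]
    tie = False
    for cid, s in scores[1:]:
        if s > best:
            best_id, best, tie = cid, s, False
        elif s == best:
            tie = True
    return best_id, tie
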