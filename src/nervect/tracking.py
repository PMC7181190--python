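"""Seeded region growing, slice-to-slice fascicle tracking and acceptance rules.

Segmentation follows the semi-automatic workflow used for stained-nerve
microCT: a neighbourhood-connected filter grows regions from seed points
within a grey range, an optional morphological closing bridges air pockets,
and per-slice cross-sections are linked along z into fascicle tracks.

Tracking events
---------------
* ``BRANCH`` — one cross-section splits into two or more (anatomical
  branching region); does not disqualify a tracing.
* ``PLEXUS`` — two fascicles merge and re-separate within the plexus
  window (default 3 mm of nerve length); does not disqualify.
* ``BOUNDARY_LOSS`` — the neighbourhood connection discontinues over more
  than half of a fascicle's footprint between consecutive slices.
* ``BOUNDARY_GAIN`` — more than one fascicle (or fascicle plus
  adipocyte/epineurium tissue) segmented as one, with no plexus within the
  window to excuse the merge.

A tracing is acceptable when at least ``min_fascicles`` tracks span the
full retained z-range (following lineage through branches and plexuses)
and no boundary loss or gain is confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

from .preprocess import GreyRange
from .volume import Mask, Volume

__all__ = [
    "EventKind",
    "SeedPoint",
    "SliceRecord",
    "TrackEvent",
    "FascicleTrack",
    "TrackReport",
    "neighborhood_connected",
    "smooth_mask",
    "track_fascicles",
    "detect_boundary_loss",
    "detect_boundary_gain",
    "assess_acceptance",
]


class EventKind(str, Enum):
    BRANCH = "BRANCH"
    PLEXUS = "PLEXUS"
    BOUNDARY_LOSS = "BOUNDARY_LOSS"
    BOUNDARY_GAIN = "BOUNDARY_GAIN"


@dataclass(frozen=True)
class SeedPoint:
    """A (z, y, x) voxel seed, optionally tagged with an intended fascicle id."""

    z: int
    y: int
    x: int
    fascicle_id: int | None = None


@dataclass
class TrackEvent:
    kind: EventKind
    z_um: float
    partners: tuple[int, ...]

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        self.partners = tuple(int(p) for p in self.partners)
        minimum = {EventKind.BRANCH: 2, EventKind.PLEXUS: 2, EventKind.BOUNDARY_GAIN: 2}
        need = minimum.get(self.kind, 0)
        if len(self.partners) < need:
            raise ValueError(f"{self.kind.value} event needs >= {need} partners; got {self.partners}")
        if self.kind is EventKind.PLEXUS and len(self.partners) != 2:
            raise ValueError("PLEXUS event has exactly 2 participants")


@dataclass
class SliceRecord:
    """One slice of a fascicle track: centroid in voxel coords, area in μm²."""

    z: int
    centroid: tuple[float, float]  # (y, x)
    area_um2: float
    footprint: tuple[np.ndarray, np.ndarray] | None = None  # (ys, xs) index arrays

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("slice record area must be positive")


@dataclass
class FascicleTrack:
    id: int
    records: list[SliceRecord] = field(default_factory=list)
    events: list[TrackEvent] = field(default_factory=list)
    # lineage bookkeeping: ids of tracks this one continues from / into
    parents: tuple[int, ...] = ()
    children: tuple[int, ...] = ()
    # founding fascicle identities carried by this track (roots at volume start)
    roots: frozenset[int] = frozenset()

    @property
    def z_start(self) -> int:
        return self.records[0].z

    @property
    def z_end(self) -> int:
        return self.records[-1].z


@dataclass
class TrackReport:
    tracks: list[FascicleTrack]
    acceptable: bool
    reasons: list[str]
    n_tracked: int
    n_loss: int
    n_gain: int


# ---------------------------------------------------------------------------
# region growing and mask smoothing

_STRUCTS = {6: ndimage.generate_binary_structure(3, 1),
            26: ndimage.generate_binary_structure(3, 3)}


def neighborhood_connected(volume: Volume, seeds: list[SeedPoint],
                           range: GreyRange, connectivity: int = 26) -> Mask:
    """Grow the union of connected in-range components containing the seeds.

    Marks every voxel whose grey lies in ``range`` and that is connected
    (6- or 26-neighbourhood) to at least one seed point through in-range
    voxels — the neighbourhood-connected filter of ITK/Seg3D.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    if not seeds:
        raise ValueError("at least one seed point required")
    nz, ny, nx = volume.shape
    in_range = (volume.data >= range.low) & (volume.data <= range.high)
    for s in seeds:
        if not (0 <= s.z < nz and 0 <= s.y < ny and 0 <= s.x < nx):
            raise ValueError(f"seed {s} lies outside the volume {volume.shape}")
        if not in_range[s.z, s.y, s.x]:
            raise ValueError(
                f"seed {s} grey {volume.data[s.z, s.y, s.x]:.4f} outside range "
                f"[{range.low}, {range.high}]")
    labels, _ = ndimage.label(in_range, structure=_STRUCTS[connectivity])
    keep = {labels[s.z, s.y, s.x] for s in seeds}
    out = np.isin(labels, sorted(keep))
    return Mask(out, voxel_size_um=volume.voxel_size_um)


def smooth_mask(mask: Mask, radius_voxels: int) -> Mask:
    """Morphological closing (dilation then erosion) with a ball element."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    if radius_voxels == 0:
        return Mask(mask.data.copy(), voxel_size_um=mask.voxel_size_um)
    zz, yy, xx = np.mgrid[-radius_voxels:radius_voxels + 1,
                          -radius_voxels:radius_voxels + 1,
                          -radius_voxels:radius_voxels + 1]
    ball = zz * zz + yy * yy + xx * xx <= radius_voxels * radius_voxels
    # dilate with background border, erode with foreground border: the
    # standard convention that keeps closing idempotent and does not erode
    # structures touching the volume faces
    dilated = ndimage.binary_dilation(mask.data, structure=ball, border_value=0)
    closed = ndimage.binary_erosion(dilated, structure=ball, border_value=1)
    return Mask(closed, voxel_size_um=mask.voxel_size_um)


# ---------------------------------------------------------------------------
# slice-to-slice tracking

def _slice_components(mask2d: np.ndarray) -> np.ndarray:
    """8-connected component labelling of one cross-sectional slice."""
    labels, _ = ndimage.label(mask2d, structure=np.ones((3, 3), dtype=bool))
    return labels


def track_fascicles(mask: Mask, voxel_size_um: float | None = None,
                    plexus_window_mm: float = 3.0) -> list[FascicleTrack]:
    """Link per-slice cross-sections into fascicle tracks along z.

    Components in consecutive slices are linked when their (y, x)
    footprints share at least one voxel. A 1→n link emits a BRANCH; an
    n→1 merge followed by a re-split within the plexus window emits a
    PLEXUS on the participating tracks; an unresolved merge leaves a
    BOUNDARY_GAIN candidate (confirmed by :func:`detect_boundary_gain`);
    a component that disappears mid-volume leaves a BOUNDARY_LOSS
    candidate (confirmed by :func:`detect_boundary_loss`).
    """
    if voxel_size_um is None:
        voxel_size_um = mask.voxel_size_um
    data = mask.data
    if not data.any():
        raise ValueError("empty mask: nothing to track")
    nz = data.shape[0]
    vox_area = voxel_size_um ** 2
    window_slices = plexus_window_mm * 1000.0 / voxel_size_um

    tracks: dict[int, FascicleTrack] = {}
    next_id = 1
    active: dict[int, int] = {}  # slice component label -> track id
    # pending merges: track id of merged track -> (merge z, participant ids)
    pending_merge: dict[int, tuple[int, tuple[int, ...]]] = {}
    loss_candidates: list[tuple[int, int]] = []  # (track id, z of last slice)

    prev_labels = _slice_components(data[0])
    for lab in range(1, prev_labels.max() + 1):
        ys, xs = np.nonzero(prev_labels == lab)
        t = FascicleTrack(id=next_id, roots=frozenset({next_id}))
        t.records.append(SliceRecord(0, (float(ys.mean()), float(xs.mean())),
                                     len(ys) * vox_area, (ys, xs)))
        tracks[next_id] = t
        active[lab] = next_id
        next_id += 1

    for z in range(1, nz):
        cur_labels = _slice_components(data[z])
        n_cur = cur_labels.max()
        # overlap table: previous component label x current component label
        overlap: dict[int, set[int]] = {}
        rev: dict[int, set[int]] = {}
        both = (prev_labels > 0) & (cur_labels > 0)
        if both.any():
            pairs = np.unique(np.stack([prev_labels[both], cur_labels[both]]), axis=1)
            for p, c in pairs.T:
                overlap.setdefault(int(p), set()).add(int(c))
                rev.setdefault(int(c), set()).add(int(p))

        new_active: dict[int, int] = {}
        handled: set[int] = set()

        # ends without continuation -> boundary-loss candidates (mid-volume only)
        for p, tid in active.items():
            if p not in overlap:
                loss_candidates.append((tid, tracks[tid].z_end))

        for c in range(1, n_cur + 1):
            if c in handled:
                continue
            parents = sorted(rev.get(c, ()))
            if not parents:
                t = FascicleTrack(id=next_id, roots=frozenset({next_id}))
                tracks[next_id] = t
                new_active[c] = next_id
                next_id += 1
                continue
            if len(parents) == 1:
                p = parents[0]
                siblings = sorted(overlap[p])
                if len(siblings) == 1:
                    new_active[c] = active[p]
                    continue
                # 1 -> n: branch
                parent_tid = active[p]
                child_ids = []
                for c2 in siblings:
                    t = FascicleTrack(id=next_id, parents=(parent_tid,),
                                      roots=tracks[parent_tid].roots)
                    tracks[next_id] = t
                    new_active[c2] = next_id
                    child_ids.append(next_id)
                    handled.add(c2)
                    next_id += 1
                tracks[parent_tid].children = tuple(child_ids)
                ev = TrackEvent(EventKind.BRANCH, z * voxel_size_um, tuple(child_ids))
                tracks[parent_tid].events.append(ev)
                # a branch may resolve an earlier merge into a plexus
                if parent_tid in pending_merge:
                    mz, participants = pending_merge.pop(parent_tid)
                    if z - mz <= window_slices:
                        pv = TrackEvent(EventKind.PLEXUS, mz * voxel_size_um, participants[:2])
                        for pid in participants:
                            tracks[pid].events.append(pv)
                        tracks[parent_tid].events = [
                            e for e in tracks[parent_tid].events if e is not ev]
                        tracks[parent_tid].events.append(pv)
                    else:
                        pending_merge[parent_tid] = (mz, participants)
                continue
            # n -> 1: merge
            participant_ids = tuple(active[p] for p in parents)
            roots: frozenset[int] = frozenset()
            for pid in participant_ids:
                roots = roots | tracks[pid].roots
            t = FascicleTrack(id=next_id, parents=participant_ids, roots=roots)
            tracks[next_id] = t
            for pid in participant_ids:
                tracks[pid].children = tracks[pid].children + (next_id,)
            pending_merge[next_id] = (z, participant_ids)
            new_active[c] = next_id
            next_id += 1

        for c, tid in new_active.items():
            ys, xs = np.nonzero(cur_labels == c)
            tracks[tid].records.append(
                SliceRecord(z, (float(ys.mean()), float(xs.mean())),
                            len(ys) * vox_area, (ys, xs)))
        active = new_active
        prev_labels = cur_labels

    # unresolved merges stay as boundary-gain candidates on the merged track
    for tid, (mz, participants) in pending_merge.items():
        tracks[tid].events.append(
            TrackEvent(EventKind.BOUNDARY_GAIN, mz * voxel_size_um, participants))
    for tid, z_last in loss_candidates:
        tracks[tid].events.append(
            TrackEvent(EventKind.BOUNDARY_LOSS, (z_last + 1) * voxel_size_um, (tid,)))
    return [tracks[k] for k in sorted(tracks)]


# ---------------------------------------------------------------------------
# boundary rules

def detect_boundary_loss(track: FascicleTrack, mask: Mask) -> list[TrackEvent]:
    """Confirm boundary-loss events for one track against the full mask.

    At each z-transition the fraction of the previous slice's footprint
    with no in-mask continuation directly below in the next slice is
    computed; a fraction above 0.5 (more than half of the fascicle's
    extent discontinued) is a confirmed BOUNDARY_LOSS.
    """
    if not track.records:
        raise ValueError("track has no slice records")
    vox = mask.voxel_size_um
    events = []
    nz = mask.data.shape[0]
    for rec in track.records:
        z_next = rec.z + 1
        if z_next >= nz:
            continue
        if rec.footprint is None:
            continue
        ys, xs = rec.footprint
        cont = mask.data[z_next, ys, xs]
        frac_lost = 1.0 - cont.mean()
        if frac_lost > 0.5:
            events.append(TrackEvent(EventKind.BOUNDARY_LOSS, z_next * vox, (track.id,)))
    return events


def detect_boundary_gain(tracks: list[FascicleTrack],
                         truth_or_annotation=None,
                         plexus_window_mm: float = 3.0,
                         voxel_size_um: float = 4.0,
                         contamination_threshold: float = 0.1) -> list[TrackEvent]:
    """Confirm boundary-gain events over a set of tracks.

    A merged component covering two or more distinct fascicle identities
    is a BOUNDARY_GAIN unless a plexus — declared in the annotation or
    observed as a PLEXUS event — lies within ``plexus_window_mm`` along z
    of the merge. When reference tissue labels are provided, a track whose
    footprint contains more than ``contamination_threshold`` of adipocyte
    or epineurium voxels is also flagged as a gain.

    ``truth_or_annotation`` may be ``None``, a sequence of declared plexus
    z positions in μm, or an object with ``plexus_z_um`` (sequence) and/or
    ``tissue_labels`` (3D int array with the phantom tissue encoding).
    """
    declared_z: list[float] = []
    tissue_labels = None
    if truth_or_annotation is not None:
        if hasattr(truth_or_annotation, "plexus_z_um"):
            declared_z = list(truth_or_annotation.plexus_z_um)
            tissue_labels = getattr(truth_or_annotation, "tissue_labels", None)
        else:
            declared_z = [float(z) for z in truth_or_annotation]
    observed_z = [e.z_um for t in tracks for e in t.events if e.kind is EventKind.PLEXUS]
    window_um = plexus_window_mm * 1000.0

    confirmed: list[TrackEvent] = []
    for t in tracks:
        for e in t.events:
            if e.kind is not EventKind.BOUNDARY_GAIN:
                continue
            excused = any(abs(e.z_um - pz) <= window_um for pz in declared_z + observed_z)
            if not excused:
                confirmed.append(e)
    if tissue_labels is not None:
        from .phantom import TissueClass  # local import to avoid a cycle
        bad = {int(TissueClass.ADIPOCYTE), int(TissueClass.EPINEURIUM)}
        for t in tracks:
            n_bad = n_tot = 0
            for rec in t.records:
                if rec.footprint is None:
                    continue
                ys, xs = rec.footprint
                lab = tissue_labels[rec.z, ys, xs]
                n_bad += int(np.isin(lab, list(bad)).sum())
                n_tot += lab.size
            if n_tot and n_bad / n_tot > contamination_threshold:
                confirmed.append(TrackEvent(
                    EventKind.BOUNDARY_GAIN, t.records[0].z * voxel_size_um, (t.id, -1)))
    return confirmed


def _lineage_spans(tracks: list[FascicleTrack], z_first: int, z_last: int) -> int:
    """Count founding tracks whose lineage covers [z_first, z_last]."""
    by_id = {t.id: t for t in tracks}
    reaches_end: dict[int, bool] = {}

    def reaches(tid: int) -> bool:
        if tid in reaches_end:
            return reaches_end[tid]
        t = by_id[tid]
        reaches_end[tid] = False  # cycle guard (lineage is a DAG)
        ok = t.z_end >= z_last or any(reaches(c) for c in t.children if c in by_id)
        reaches_end[tid] = ok
        return ok

    n = 0
    for t in tracks:
        if t.parents == () and t.z_start <= z_first and reaches(t.id):
            n += 1
    return n


def assess_acceptance(tracks: list[FascicleTrack], report_spec: dict,
                      confirmed_loss: list[TrackEvent] | None = None,
                      confirmed_gain: list[TrackEvent] | None = None) -> TrackReport:
    """Apply the acceptability rule for a tracing.

    Acceptable iff the number of founding tracks whose lineage spans the
    full retained z-range is at least ``report_spec['min_fascicles']`` and
    no BOUNDARY_LOSS or BOUNDARY_GAIN is confirmed. BRANCH and PLEXUS
    events do not disqualify.
    """
    min_fascicles = int(report_spec["min_fascicles"])
    if min_fascicles < 1:
        raise ValueError("min_fascicles must be >= 1")
    if not tracks:
        raise ValueError("no tracks to assess")
    z_first = min(t.z_start for t in tracks)
    z_last = max(t.z_end for t in tracks)
    n_full = _lineage_spans(tracks, z_first, z_last)
    if confirmed_loss is None:
        confirmed_loss = [e for t in tracks for e in t.events
                          if e.kind is EventKind.BOUNDARY_LOSS]
    if confirmed_gain is None:
        confirmed_gain = [e for t in tracks for e in t.events
                          if e.kind is EventKind.BOUNDARY_GAIN]
    reasons = []
    if n_full < min_fascicles:
        reasons.append(f"only {n_full} full-length fascicle(s); require {min_fascicles}")
    for e in confirmed_loss:
        reasons.append(f"boundary loss at z={e.z_um:.0f} um (track {e.partners[0]})")
    for e in confirmed_gain:
        reasons.append(f"boundary gain at z={e.z_um:.0f} um (tracks {e.partners})")
    return TrackReport(tracks=tracks, acceptable=not reasons, reasons=reasons,
                       n_tracked=n_full, n_loss=len(confirmed_loss),
                       n_gain=len(confirmed_gain))
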