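"""Synthetic stained-nerve microCT phantom generator.

Emulates the cross-sectional appearance of an iodine-stained peripheral
nerve wrapped in cling film and mounted on sponge: a cylindrical nerve of
interfascicular epineurium containing fascicle tubes, a thin cling-film
shell, adipocyte blobs hugging the outside of the film, and sponge/air
everywhere else. Five tissue classes occupy separable normalized grey
levels; defaults put adipocytes at 0.92 and sponge/air at 0.18 with
fascicles (0.55) darker than epineurium (0.75), the ordering seen in
stained-nerve scans.

Fascicle tubes run along z with a sinusoidal wobble and may branch (one
tube splits into two) or form a plexus (two tubes merge into a shared
lumen for a configurable run, then re-separate). The generator returns
the grey volume, per-voxel tissue and instance labels, and ground-truth
per-slice tracks with event positions, so the whole segmentation and
tracking chain can be evaluated against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .tracking import EventKind, FascicleTrack, SliceRecord, TrackEvent
from .volume import Volume

__all__ = [
    "TissueClass",
    "FascicleEvent",
    "FascicleSpec",
    "MovementArtefactSpec",
    "PhantomSpec",
    "PhantomResult",
    "DEFAULT_TISSUE_MEANS",
    "DEFAULT_TISSUE_SDS",
    "RAT_PROFILE",
    "PIG_PROFILE",
    "StainingProfile",
    "build_phantom",
    "staining_contrast_model",
    "add_movement_artefact",
    "save_phantom",
    "spec_from_config",
]


class TissueClass(IntEnum):
    SPONGE_AIR = 1
    CLINGFILM = 2
    EPINEURIUM = 3
    FASCICLE = 4
    ADIPOCYTE = 5


DEFAULT_TISSUE_MEANS: dict[TissueClass, float] = {
    TissueClass.FASCICLE: 0.55,
    TissueClass.EPINEURIUM: 0.75,
    TissueClass.ADIPOCYTE: 0.92,
    TissueClass.CLINGFILM: 0.30,
    TissueClass.SPONGE_AIR: 0.18,
}

DEFAULT_TISSUE_SDS: dict[TissueClass, float] = {
    TissueClass.FASCICLE: 0.02,
    TissueClass.EPINEURIUM: 0.02,
    TissueClass.ADIPOCYTE: 0.03,
    TissueClass.CLINGFILM: 0.02,
    TissueClass.SPONGE_AIR: 0.04,
}


@dataclass(frozen=True)
class FascicleEvent:
    """A declared geometric event on a fascicle tube.

    kind 'branch': this fascicle ends at ``z_um`` and the partner ids
    continue as its children. kind 'plexus': this fascicle and its single
    partner share one lumen for ``run_um`` starting at ``z_um``.
    """

    kind: str  # 'branch' | 'plexus'
    z_um: float
    partners: tuple[int, ...]
    run_um: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in ("branch", "plexus"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "branch" and len(self.partners) < 2:
            raise ValueError("branch event needs >= 2 child ids")
        if self.kind == "plexus" and len(self.partners) != 1:
            raise ValueError("plexus event names exactly one partner")


@dataclass(frozen=True)
class FascicleSpec:
    """One fascicle tube: a wobbling cylinder along z.

    The centreline is ``base + amplitude * (sin, cos)(2π z / period + phase)``
    relative to the nerve axis, all in μm.
    """

    id: int
    radius_um: float
    base_offset_um: tuple[float, float] = (0.0, 0.0)  # (x, y) from nerve axis
    wobble_amplitude_um: float = 0.0
    wobble_period_um: float = 1000.0
    wobble_phase: float = 0.0
    z_start_um: float = 0.0
    z_end_um: float | None = None  # None = to the end of the volume
    events: tuple[FascicleEvent, ...] = ()


@dataclass(frozen=True)
class MovementArtefactSpec:
    max_shift_voxels: int = 2
    affected_fraction: float = 0.1


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of a synthetic nerve volume."""

    shape: tuple[int, int, int] = (256, 256, 600)  # (nx, ny, nz)
    voxel_size_um: float = 4.0
    fascicles: tuple[FascicleSpec, ...] = ()
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    tissue_sds: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_SDS))
    noise_sd: float = 0.01
    artefact: MovementArtefactSpec | None = None
    rng_seed: int = 0
    nerve_radius_um: float | None = None  # None = 0.38 * min(nx, ny) * voxel
    clingfilm_thickness_um: float = 8.0
    n_adipocytes: int = 8
    adipocyte_radius_um: float = 32.0
    transition_um: float = 160.0  # blend length for branch/plexus geometry

    def __post_init__(self) -> None:
        for m in self.tissue_means.values():
            if not 0.0 <= m <= 1.0:
                raise ValueError("tissue means must lie in [0, 1]")
        for s in self.tissue_sds.values():
            if not 0.0 <= s <= 1.0:
                raise ValueError("tissue sds must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nz_um = self.shape[2] * self.voxel_size_um
        for f in self.fascicles:
            if f.radius_um < 2 * self.voxel_size_um:
                raise ValueError(
                    f"fascicle {f.id}: radius {f.radius_um} um not resolvable at "
                    f"{self.voxel_size_um} um voxels (need >= 2 voxels)")
            for e in f.events:
                if not 0.0 < e.z_um < nz_um:
                    raise ValueError(
                        f"fascicle {f.id}: event z={e.z_um} um outside volume (0, {nz_um})")

    @property
    def nerve_radius(self) -> float:
        if self.nerve_radius_um is not None:
            return self.nerve_radius_um
        return 0.38 * min(self.shape[0], self.shape[1]) * self.voxel_size_um


@dataclass
class PhantomResult:
    volume: Volume
    tissue_labels: np.ndarray  # (nz, ny, nx) int8 of TissueClass
    instance_labels: np.ndarray  # (nz, ny, nx) int16 fascicle ids, 0 = none
    truth_tracks: list[FascicleTrack]
    spec_echo: PhantomSpec

    @property
    def plexus_z_um(self) -> list[float]:
        return [e.z_um for t in self.truth_tracks for e in t.events
                if e.kind is EventKind.PLEXUS]


# ---------------------------------------------------------------------------
# staining contrast model

@dataclass(frozen=True)
class StainingProfile:
    """Synthetic staining-response profile for one species preparation."""

    name: str
    optimum_day: float


RAT_PROFILE = StainingProfile("rat_sciatic", optimum_day=1.0)
PIG_PROFILE = StainingProfile("pig_vagus", optimum_day=5.0)


def staining_contrast_model(day: float, species_profile: StainingProfile = RAT_PROFILE,
                            ) -> dict[TissueClass, float]:
    """Synthetic tissue grey means as a function of staining time in days.

    A gamma-like unimodal response ``g(day) = (day/opt) exp(1 - day/opt)``
    drives divergence of the three soft-tissue means from a common
    unstained baseline: contrast rises to a maximum at the profile's
    optimum day and decays toward the baseline plateau as over-staining
    equalises uptake. At day 0 fascicle and epineurium differ by 0.03;
    at the optimum the means equal the phantom defaults (0.55/0.75/0.92).
    This is a stand-in response surface, not a measured relationship.
    """
    if day < 0:
        raise ValueError("staining day must be >= 0")
    opt = species_profile.optimum_day
    g = (day / opt) * math.exp(1.0 - day / opt) if day > 0 else 0.0
    return {
        TissueClass.FASCICLE: 0.62 - 0.07 * g,
        TissueClass.EPINEURIUM: 0.65 + 0.10 * g,
        TissueClass.ADIPOCYTE: 0.66 + 0.26 * g,
        TissueClass.CLINGFILM: 0.30,
        TissueClass.SPONGE_AIR: 0.18,
    }


# ---------------------------------------------------------------------------
# geometry helpers

def _own_path(f: FascicleSpec, z_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unperturbed centreline (x, y) in μm relative to the nerve axis."""
    ang = 2.0 * math.pi * z_um / f.wobble_period_um + f.wobble_phase
    x = f.base_offset_um[0] + f.wobble_amplitude_um * np.sin(ang)
    y = f.base_offset_um[1] + f.wobble_amplitude_um * np.cos(ang)
    return x, y


class _Geometry:
    """Per-slice effective centres/radii after applying declared events."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        nx, ny, nz = spec.shape
        self.nz = nz
        self.z_um = np.arange(nz) * spec.voxel_size_um
        self.by_id = {f.id: f for f in spec.fascicles}
        if len(self.by_id) != len(spec.fascicles):
            raise ValueError("duplicate fascicle ids")
        # active z-index range per fascicle (inclusive start, exclusive end)
        self.active = {}
        # per-fascicle centres/radii arrays over all z (NaN where inactive)
        self.cx = {}
        self.cy = {}
        self.r = {}
        self.merged_pairs: list[tuple[int, int, float, float]] = []  # (a, b, z0_um, z1_um)
        self.branches: list[tuple[int, tuple[int, ...], float]] = []
        self._build()

    def _build(self) -> None:
        spec = self.spec
        vox = spec.voxel_size_um
        z_um = self.z_um
        T = spec.transition_um

        starts = {f.id: f.z_start_um for f in spec.fascicles}
        ends = {f.id: (f.z_end_um if f.z_end_um is not None else self.nz * vox)
                for f in spec.fascicles}
        branch_origin: dict[int, tuple[int, float]] = {}  # child -> (parent, z_e)

        for f in spec.fascicles:
            for e in f.events:
                if e.kind == "branch":
                    ends[f.id] = min(ends[f.id], e.z_um)
                    for c in e.partners:
                        if c not in self.by_id:
                            raise ValueError(f"branch child {c} of fascicle {f.id} not declared")
                        starts[c] = e.z_um
                        branch_origin[c] = (f.id, e.z_um)
                    self.branches.append((f.id, e.partners, e.z_um))
                elif e.kind == "plexus":
                    b = e.partners[0]
                    if b not in self.by_id:
                        raise ValueError(f"plexus partner {b} of fascicle {f.id} not declared")
                    self.merged_pairs.append((f.id, b, e.z_um, e.z_um + e.run_um))

        for f in spec.fascicles:
            x, y = _own_path(f, z_um)
            self.cx[f.id] = x.copy()
            self.cy[f.id] = y.copy()
            self.r[f.id] = np.full(self.nz, f.radius_um)
            i0 = int(np.ceil(starts[f.id] / vox))
            i1 = int(np.ceil(ends[f.id] / vox))
            self.active[f.id] = (max(i0, 0), min(i1, self.nz))

        # branch children glide from the parent's end position onto their own
        # path; the sublinear ramp separates the pair within a few slices of
        # the declared z so the branching region stays short
        for c, (p, z_e) in branch_origin.items():
            px, py = _own_path(self.by_id[p], np.asarray([z_e]))
            t = np.clip((z_um - z_e) / T, 0.0, 1.0) ** 0.4
            self.cx[c] = (1 - t) * px[0] + t * self.cx[c]
            self.cy[c] = (1 - t) * py[0] + t * self.cy[c]

        # plexus participants converge on the midpoint for the merged run
        for a, b, z0, z1 in self.merged_pairs:
            fa, fb = self.by_id[a], self.by_id[b]
            mx = (self.cx[a] + self.cx[b]) / 2.0
            my = (self.cy[a] + self.cy[b]) / 2.0
            w = np.zeros(self.nz)
            w = np.where((z_um >= z0) & (z_um <= z1), 1.0, w)
            pre = (z_um >= z0 - T) & (z_um < z0)
            w = np.where(pre, (z_um - (z0 - T)) / T, w)
            post = (z_um > z1) & (z_um <= z1 + T)
            w = np.where(post, 1.0 - (z_um - z1) / T, w)
            r_sh = math.hypot(fa.radius_um, fb.radius_um)
            for fid, base_r in ((a, fa.radius_um), (b, fb.radius_um)):
                self.cx[fid] = (1 - w) * self.cx[fid] + w * mx
                self.cy[fid] = (1 - w) * self.cy[fid] + w * my
                self.r[fid] = (1 - w) * base_r + w * r_sh

    def active_at(self, iz: int) -> list[int]:
        return [fid for fid, (i0, i1) in self.active.items() if i0 <= iz < i1]

    def merged_at(self, iz: int) -> list[tuple[int, int]]:
        z = self.z_um[iz]
        return [(a, b) for a, b, z0, z1 in self.merged_pairs if z0 <= z <= z1]

    def excused(self, a: int, b: int, iz: int) -> bool:
        """May tubes a and b legally overlap at slice iz?"""
        z = self.z_um[iz]
        T = self.spec.transition_um
        for pa, pb, z0, z1 in self.merged_pairs:
            if {a, b} == {pa, pb} and z0 - T <= z <= z1 + T:
                return True
        for parent, children, z_e in self.branches:
            group = set(children) | {parent}
            if a in group and b in group and z_e <= z <= z_e + 3 * T:
                return True
        return False


# ---------------------------------------------------------------------------
# rasterization

def build_phantom(spec: PhantomSpec) -> PhantomResult:
    """Rasterize a PhantomSpec into a grey volume, labels and truth tracks.

    Geometry is rasterized noise-free at ``voxel_size_um``, then
    per-tissue Gaussian texture and global additive Gaussian noise are
    applied and values clipped to [0, 1]. Identical spec (including seed)
    produces bit-identical output.
    """
    nx, ny, nz = spec.shape
    vox = spec.voxel_size_um
    geom = _Geometry(spec)

    cx0 = (nx - 1) / 2.0 * vox  # nerve axis in μm
    cy0 = (ny - 1) / 2.0 * vox
    xs_um = np.arange(nx) * vox
    ys_um = np.arange(ny) * vox
    xx, yy = np.meshgrid(xs_um, ys_um)  # (ny, nx)

    nerve_r = spec.nerve_radius
    rr2 = (xx - cx0) ** 2 + (yy - cy0) ** 2
    nerve_mask = rr2 <= nerve_r ** 2
    film_mask = (rr2 > nerve_r ** 2) & (rr2 <= (nerve_r + spec.clingfilm_thickness_um) ** 2)

    tissue = np.full((nz, ny, nx), int(TissueClass.SPONGE_AIR), dtype=np.int8)
    tissue[:, film_mask] = int(TissueClass.CLINGFILM)
    tissue[:, nerve_mask] = int(TissueClass.EPINEURIUM)
    instance = np.zeros((nz, ny, nx), dtype=np.int16)

    rng = np.random.default_rng(spec.rng_seed)

    # adipocyte spheres hugging the outside of the cling film
    ad_r = spec.adipocyte_radius_um
    ring_r = nerve_r + spec.clingfilm_thickness_um + ad_r
    z_idx = np.arange(nz)
    for _ in range(spec.n_adipocytes):
        theta = rng.uniform(0, 2 * math.pi)
        r_vox = ad_r / vox
        zc = rng.uniform(r_vox, max(nz - 1 - r_vox, r_vox))
        ax = cx0 + ring_r * math.cos(theta)
        ay = cy0 + ring_r * math.sin(theta)
        dz2 = ((z_idx - zc) * vox) ** 2
        hit_z = np.nonzero(dz2 <= ad_r ** 2)[0]
        for iz in hit_z:
            disc_r2 = ad_r ** 2 - dz2[iz]
            disc = (xx - ax) ** 2 + (yy - ay) ** 2 <= disc_r2
            sel = disc & (tissue[iz] == int(TissueClass.SPONGE_AIR))
            tissue[iz][sel] = int(TissueClass.ADIPOCYTE)

    # fascicle tubes; truth footprints keep each fascicle's full disc,
    # including the lumen shared during a plexus
    truth_fp: dict[int, dict[int, tuple[np.ndarray, np.ndarray]]] = {
        f.id: {} for f in spec.fascicles}
    margin = vox
    for iz in range(nz):
        act = geom.active_at(iz)
        merged = geom.merged_at(iz)
        merged_ids = {fid for pair in merged for fid in pair}
        centres = {}
        for fid in act:
            cxf = cx0 + geom.cx[fid][iz]
            cyf = cy0 + geom.cy[fid][iz]
            rf = geom.r[fid][iz]
            centres[fid] = (cxf, cyf, rf)
            d_axis = math.hypot(cxf - cx0, cyf - cy0)
            if d_axis + rf > nerve_r - margin:
                raise ValueError(
                    f"fascicle {fid} leaves the epineurium at slice {iz} "
                    f"(centre offset {d_axis:.1f} + r {rf:.1f} > {nerve_r - margin:.1f} um)")
        # legality: undeclared overlaps are rejected
        for i, a in enumerate(act):
            for b in act[i + 1:]:
                (ax_, ay_, ar_), (bx_, by_, br_) = centres[a], centres[b]
                if math.hypot(ax_ - bx_, ay_ - by_) < ar_ + br_ and not geom.excused(a, b, iz):
                    raise ValueError(
                        f"fascicles {a} and {b} overlap at slice {iz} without a "
                        f"declared branch/plexus event")
        # rasterize: merged pairs share one lumen split by the bisector of
        # their notional own-path separation so both ids keep voxels
        done: set[int] = set()
        for a, b in merged:
            if a not in act or b not in act:
                continue
            (ax_, ay_, ar_) = centres[a]
            disc = (xx - ax_) ** 2 + (yy - ay_) ** 2 <= ar_ ** 2
            fa, fb = geom.by_id[a], geom.by_id[b]
            oax, oay = _own_path(fa, np.asarray([geom.z_um[iz]]))
            obx, oby = _own_path(fb, np.asarray([geom.z_um[iz]]))
            dxv, dyv = obx[0] - oax[0], oby[0] - oay[0]
            side = (xx - ax_) * dxv + (yy - ay_) * dyv
            shared = np.nonzero(disc)
            truth_fp[a][iz] = shared
            truth_fp[b][iz] = shared
            instance[iz][disc & (side <= 0)] = a
            instance[iz][disc & (side > 0)] = b
            tissue[iz][disc] = int(TissueClass.FASCICLE)
            done.update((a, b))
        for fid in act:
            if fid in done:
                continue
            cxf, cyf, rf = centres[fid]
            disc = (xx - cxf) ** 2 + (yy - cyf) ** 2 <= rf ** 2
            truth_fp[fid][iz] = np.nonzero(disc)
            overlap = disc & (instance[iz] > 0)
            if overlap.any():
                # transitional overlap with an event partner: nearer centre wins
                for other in np.unique(instance[iz][overlap]):
                    oxf, oyf, _ = centres[int(other)]
                    mine = ((xx - cxf) ** 2 + (yy - cyf) ** 2
                            <= (xx - oxf) ** 2 + (yy - oyf) ** 2)
                    take = overlap & (instance[iz] == other) & mine
                    instance[iz][take] = fid
                disc = disc & ((instance[iz] == 0) | (instance[iz] == fid))
            instance[iz][disc] = fid
            tissue[iz][disc] = int(TissueClass.FASCICLE)

    # grey values: per-tissue texture + global noise, clipped
    grey = np.zeros((nz, ny, nx), dtype=np.float64)
    for tc in TissueClass:
        sel = tissue == int(tc)
        n = int(sel.sum())
        if n == 0:
            continue
        mean = spec.tissue_means.get(tc, DEFAULT_TISSUE_MEANS[tc])
        sd = spec.tissue_sds.get(tc, 0.0)
        grey[sel] = mean + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
    if spec.noise_sd > 0:
        grey += rng.normal(0.0, spec.noise_sd, grey.shape)
    np.clip(grey, 0.0, 1.0, out=grey)

    volume = Volume(grey, voxel_size_um=vox, provenance=f"phantom seed={spec.rng_seed}")
    if spec.artefact is not None:
        volume = add_movement_artefact(
            volume, spec.artefact.max_shift_voxels, spec.artefact.affected_fraction,
            seed=spec.rng_seed + 1,
            fill_value=spec.tissue_means.get(TissueClass.SPONGE_AIR, 0.18))

    truth_tracks = _truth_tracks(spec, geom, instance, truth_fp)
    return PhantomResult(volume=volume, tissue_labels=tissue, instance_labels=instance,
                         truth_tracks=truth_tracks, spec_echo=spec)


def _truth_tracks(spec: PhantomSpec, geom: _Geometry, instance: np.ndarray,
                  truth_fp: dict[int, dict[int, tuple[np.ndarray, np.ndarray]]],
                  ) -> list[FascicleTrack]:
    vox = spec.voxel_size_um
    vox_area = vox * vox
    tracks = {}
    for f in spec.fascicles:
        t = FascicleTrack(id=f.id, roots=frozenset({f.id}))
        counts_by_z = {}
        zs = np.nonzero((instance == f.id).any(axis=(1, 2)))[0]
        for iz in zs:
            counts_by_z[int(iz)] = int((instance[iz] == f.id).sum())
        for iz, fp in sorted(truth_fp[f.id].items()):
            n_lab = counts_by_z.get(iz, 0)
            if n_lab == 0:
                continue  # fully engulfed by an event partner at this slice
            ys, xs = fp
            t.records.append(SliceRecord(int(iz), (float(ys.mean()), float(xs.mean())),
                                         n_lab * vox_area, (ys, xs)))
        tracks[f.id] = t

    # event z positions are where the rasterized geometry actually merges
    # or separates — that is what slice-linking can recover
    for parent, children, z_e in geom.branches:
        z_obs = _first_split_z(instance, children, int(round(z_e / vox)))
        ev = TrackEvent(EventKind.BRANCH, z_obs * vox, tuple(children))
        tracks[parent].events.append(ev)
        tracks[parent].children = tuple(children)
        for c in children:
            tracks[c].parents = (parent,)
    for a, b, z0, z1 in geom.merged_pairs:
        z_obs = _first_merge_z(instance, (a, b), int(round(z0 / vox)))
        ev = TrackEvent(EventKind.PLEXUS, z_obs * vox, (a, b))
        tracks[a].events.append(ev)
        tracks[b].events.append(ev)
    return [tracks[k] for k in sorted(tracks)]


def _component_count(slice_inst: np.ndarray, ids: tuple[int, ...]) -> int:
    from scipy import ndimage
    m = np.isin(slice_inst, list(ids))
    if not m.any():
        return 0
    _, n = ndimage.label(m, structure=np.ones((3, 3), dtype=bool))
    return n


def _first_split_z(instance: np.ndarray, ids: tuple[int, ...], iz_hint: int) -> int:
    for iz in range(max(iz_hint, 0), instance.shape[0]):
        if _component_count(instance[iz], ids) >= 2:
            return iz
    return iz_hint


def _first_merge_z(instance: np.ndarray, ids: tuple[int, ...], iz_hint: int) -> int:
    for iz in range(instance.shape[0]):
        if _component_count(instance[iz], ids) == 1:
            return iz
    return iz_hint


# ---------------------------------------------------------------------------
# movement artefact

def add_movement_artefact(volume: Volume, max_shift_voxels: int,
                          affected_fraction: float, seed: int,
                          fill_value: float = 0.18) -> Volume:
    """Laterally shift a contiguous run of slices by random integer offsets.

    Emulates specimen movement during a prolonged scan as rigid in-plane
    translations of ``ceil(affected_fraction * nz)`` consecutive slices,
    each by an offset drawn uniformly from [-max, max]² voxels. Vacated
    voxels are filled with the sponge/air mean grey.
    """
    if max_shift_voxels < 0:
        raise ValueError("max_shift_voxels must be >= 0")
    if not 0.0 <= affected_fraction <= 1.0:
        raise ValueError("affected_fraction must lie in [0, 1]")
    nz, ny, nx = volume.shape
    if max_shift_voxels >= min(ny, nx):
        raise ValueError("shift exceeds the XY extent of the volume")
    n_aff = math.ceil(affected_fraction * nz)
    if max_shift_voxels == 0 or n_aff == 0:
        return volume.with_data(volume.data.copy(), note="movement artefact (no-op)")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, nz - n_aff + 1))
    out = volume.data.copy()
    for iz in range(start, start + n_aff):
        dy = int(rng.integers(-max_shift_voxels, max_shift_voxels + 1))
        dx = int(rng.integers(-max_shift_voxels, max_shift_voxels + 1))
        out[iz] = _translate_slice(out[iz], dy, dx, fill_value)
    return volume.with_data(
        out, note=f"movement artefact slices [{start}, {start + n_aff})")


def _translate_slice(slice2d: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    ny, nx = slice2d.shape
    out = np.full_like(slice2d, fill)
    ys0, ys1 = max(dy, 0), min(ny + dy, ny)
    xs0, xs1 = max(dx, 0), min(nx + dx, nx)
    out[ys0:ys1, xs0:xs1] = slice2d[ys0 - dy:ys1 - dy, xs0 - dx:xs1 - dx]
    return out


def parallel_tubes_spec(n_tubes: int = 4, radius_um: float = 30.0,
                        shape: tuple[int, int, int] = (96, 96, 40),
                        voxel_size_um: float = 4.0, noise_sd: float = 0.0,
                        rng_seed: int = 0, tissue_means: dict | None = None,
                        tissue_sds: dict | None = None,
                        wobble_amplitude_um: float = 0.0) -> PhantomSpec:
    """Straight parallel fascicle tubes evenly spaced on a ring.

    The simplest useful geometry: ``n_tubes`` disjoint tubes at constant
    radius, suitable for calibration and recovery experiments where
    branch/plexus events are not wanted. The radius is reduced when the
    requested tubes would not fit inside the epineurium or would touch
    each other on the ring.
    """
    nerve_r = 0.38 * min(shape[0], shape[1]) * voxel_size_um
    ring = 0.55 * nerve_r if n_tubes > 1 else 0.0
    r_fit = nerve_r - ring - 2 * voxel_size_um
    if n_tubes > 1:
        chord = 2 * ring * math.sin(math.pi / n_tubes)
        r_fit = min(r_fit, chord / 2 - voxel_size_um)
    radius_um = min(radius_um, r_fit)
    fs = []
    for i in range(n_tubes):
        ang = 2 * math.pi * i / n_tubes
        fs.append(FascicleSpec(i + 1, radius_um,
                               (ring * math.cos(ang), ring * math.sin(ang)),
                               wobble_amplitude_um, 1200.0, float(i)))
    kwargs = {}
    if tissue_means is not None:
        kwargs["tissue_means"] = dict(tissue_means)
    if tissue_sds is not None:
        kwargs["tissue_sds"] = dict(tissue_sds)
    return PhantomSpec(shape=shape, voxel_size_um=voxel_size_um,
                       fascicles=tuple(fs), noise_sd=noise_sd, rng_seed=rng_seed,
                       n_adipocytes=4, adipocyte_radius_um=6 * voxel_size_um, **kwargs)


def example_nerve_spec(rng_seed: int = 0, noise_sd: float = 0.01,
                       shape: tuple[int, int, int] = (112, 112, 240),
                       wobble_amplitude_um: float = 5.0,
                       branch_z_um: float | None = None,
                       plexus_z_um: float | None = None) -> PhantomSpec:
    """A desk-scale four-fascicle nerve with one branch and one plexus.

    Four tubes (r = 40 μm) run the length of the volume: tubes 1 and 2
    form a plexus (merge and re-separate), tube 3 branches into two
    children (ids 5 and 6, r = 28 μm), tube 4 is a plain tube. Geometry is
    sized for the default 112×112×240-voxel volume at 4 μm voxels; event
    depths default to mid-volume and can be moved per call.
    """
    nz_um = shape[2] * 4.0
    if branch_z_um is None:
        branch_z_um = 0.5 * nz_um
    if plexus_z_um is None:
        plexus_z_um = 0.35 * nz_um
    w = wobble_amplitude_um
    fs = (
        FascicleSpec(1, 40.0, (-70.0, 0.0), w, 1400.0, 0.0,
                     events=(FascicleEvent("plexus", plexus_z_um, (2,), run_um=160.0),)),
        FascicleSpec(2, 40.0, (70.0, 0.0), w, 1400.0, 2.0),
        FascicleSpec(3, 40.0, (0.0, 110.0), 0.0,
                     events=(FascicleEvent("branch", branch_z_um, (5, 6)),)),
        FascicleSpec(4, 40.0, (0.0, -115.0), w, 1100.0, 4.0),
        FascicleSpec(5, 28.0, (-60.0, 110.0)),
        FascicleSpec(6, 28.0, (60.0, 110.0)),
    )
    return PhantomSpec(shape=shape, fascicles=fs, noise_sd=noise_sd,
                       n_adipocytes=6, adipocyte_radius_um=28.0, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# on-disk representation

def save_phantom(result: PhantomResult, outdir) -> None:
    """Write a phantom to ``outdir``: 16-bit TIFF stacks for the grey
    volume and both label channels, the spec as YAML, truth tracks as JSON
    (centroids in voxel coordinates, areas in μm², event z in μm)."""
    import json
    import os
    from dataclasses import asdict

    import tifffile
    import yaml

    from .volume import write_stack

    os.makedirs(outdir, exist_ok=True)
    write_stack(result.volume, os.path.join(outdir, "volume.tiff"), format="tiff16")
    tifffile.imwrite(os.path.join(outdir, "tissue_labels.tiff"),
                     result.tissue_labels.astype(np.uint16), photometric="minisblack")
    tifffile.imwrite(os.path.join(outdir, "instance_labels.tiff"),
                     result.instance_labels.astype(np.uint16), photometric="minisblack")
    spec = asdict(result.spec_echo)
    spec["tissue_means"] = {TissueClass(k).name: float(v)
                            for k, v in result.spec_echo.tissue_means.items()}
    spec["tissue_sds"] = {TissueClass(k).name: float(v)
                          for k, v in result.spec_echo.tissue_sds.items()}
    with open(os.path.join(outdir, "spec.yaml"), "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
    tracks = []
    for t in result.truth_tracks:
        tracks.append({
            "id": t.id,
            "slices": [{"z": r.z, "centroid_yx": list(r.centroid),
                        "area_um2": r.area_um2} for r in t.records],
            "events": [{"kind": e.kind.value, "z_um": e.z_um,
                        "partners": list(e.partners)} for e in t.events],
        })
    with open(os.path.join(outdir, "truth_tracks.json"), "w") as fh:
        json.dump(tracks, fh, indent=1)


def spec_from_config(cfg: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain (YAML/JSON) config mapping."""
    fascicles = []
    for f in cfg.get("fascicles", []):
        events = tuple(FascicleEvent(e["kind"], float(e["z_um"]),
                                     tuple(e["partners"]),
                                     float(e.get("run_um", 200.0)))
                       for e in f.get("events", []))
        fascicles.append(FascicleSpec(
            id=int(f["id"]), radius_um=float(f["radius_um"]),
            base_offset_um=tuple(f.get("base_offset_um", (0.0, 0.0))),
            wobble_amplitude_um=float(f.get("wobble_amplitude_um", 0.0)),
            wobble_period_um=float(f.get("wobble_period_um", 1000.0)),
            wobble_phase=float(f.get("wobble_phase", 0.0)),
            z_start_um=float(f.get("z_start_um", 0.0)),
            z_end_um=f.get("z_end_um"),
            events=events))
    means = {TissueClass[k]: float(v) for k, v in cfg.get("tissue_means", {}).items()}
    sds = {TissueClass[k]: float(v) for k, v in cfg.get("tissue_sds", {}).items()}
    art = cfg.get("artefact")
    artefact = MovementArtefactSpec(int(art["max_shift_voxels"]),
                                    float(art["affected_fraction"])) if art else None
    return PhantomSpec(
        shape=tuple(cfg.get("shape", (256, 256, 600))),
        voxel_size_um=float(cfg.get("voxel_size_um", 4.0)),
        fascicles=tuple(fascicles),
        tissue_means={**DEFAULT_TISSUE_MEANS, **means},
        tissue_sds={**DEFAULT_TISSUE_SDS, **sds},
        noise_sd=float(cfg.get("noise_sd", 0.01)),
        artefact=artefact,
        rng_seed=int(cfg.get("rng_seed", 0)),
        nerve_radius_um=cfg.get("nerve_radius_um"),
        clingfilm_thickness_um=float(cfg.get("clingfilm_thickness_um", 8.0)),
        n_adipocytes=int(cfg.get("n_adipocytes", 8)),
        adipocyte_radius_um=float(cfg.get("adipocyte_radius_um", 32.0)),
        transition_um=float(cfg.get("transition_um", 160.0)))
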