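"""Synthetic QSM midbrain phantoms with ground-truth labels.

Real QSM cohorts of this kind are generally not redistributable, so this
module generates stand-in subjects: bilateral ellipsoidal nuclei (red
nucleus, substantia nigra, subthalamic nucleus) embedded in a noisy
susceptibility background with a smooth low-order confound field. Two
acquisition domains are emulated:

* ``source`` — 0.63 x 0.63 x 2.00 mm voxels, axial slices, two foreground
  classes (RN and a merged SN–STN, which cannot be separated at 2 mm slice
  thickness);
* ``target`` — 0.83 x 0.83 x 0.80 mm voxels, coronal slices, three foreground
  classes (RN, SN, STN).

Default per-nucleus volumes and mean susceptibilities follow in-vivo
cohort statistics (RN 459.0 +/- 71.2 mm^3 at 0.082 +/- 0.036 ppm, SN 984.5 +/-
210.8 mm^3 at 0.108 +/- 0.042 ppm, STN 230.9 +/- 63.1 mm^3 at 0.070 +/- 0.031
ppm; volumes are bilateral totals). Geometry places the SN infero-lateral to
the RN and the STN supero-lateral to, and nearly abutting, the SN so that
SN/STN separation is the hard case, as it is in vivo.

Partial volume is simulated by computing ellipsoid occupancy fractions on a
2x supersampled grid and block-averaging; ground-truth labels are the
majority vote (fraction >= 0.5) of the supersampled mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dataio import (CatalogEntry, DatasetCatalog, LabelMap, Volume,
                     write_labels, write_volume)

__all__ = [
    "DomainSpec", "NucleusSpec", "PhantomSpec", "PlacementError",
    "source_domain_spec", "target_domain_spec",
    "source_phantom_spec", "target_phantom_spec",
    "generate_subject", "generate_cohort",
]

TWO_CLASS = "two_class"
THREE_CLASS = "three_class"


@dataclass(frozen=True)
class DomainSpec:
    """Grid geometry and label convention of one acquisition protocol."""

    name: str
    matrix_rows: int
    matrix_cols: int
    n_slices: int
    voxel_size: tuple[float, float, float]
    label_scheme: str
    slice_plane: str
    crop_size: int

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")
        if min(self.matrix_rows, self.matrix_cols) < self.crop_size:
            raise ValueError("matrix dimensions must be >= crop size")
        if self.label_scheme not in (TWO_CLASS, THREE_CLASS):
            raise ValueError(f"unknown label_scheme {self.label_scheme!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix_rows, self.matrix_cols, self.n_slices)

    @property
    def n_foreground_classes(self) -> int:
        return 2 if self.label_scheme == TWO_CLASS else 3


@dataclass(frozen=True)
class NucleusSpec:
    """One bilateral nucleus class: intensity/volume statistics and shape.

    ``mean_volume`` is the bilateral total (both hemispheres); each hemisphere
    receives an ellipsoid of half that volume. ``center_offset`` is in mm
    relative to the volume center for the right hemisphere; the left
    hemisphere mirrors the lateral (column) component.
    """

    class_id: int
    name: str
    mean_susceptibility: float  # ppm
    susceptibility_sd: float    # ppm, between-subject
    mean_volume: float          # mm^3, bilateral
    volume_sd: float            # mm^3, between-subject
    center_offset: tuple[float, float, float]  # mm (row, col, slice)
    semiaxis_ratios: tuple[float, float, float]
    edge_softness: float = 0.0  # 0 = uniform fill; >0 = susceptibility tapers
    #                             toward the boundary (diffuse margins, as for
    #                             the SN whose reticular part blends ventrally)

    def __post_init__(self):
        if self.mean_volume <= 0:
            raise ValueError("mean_volume must be > 0")
        if self.class_id < 1:
            raise ValueError("class_id must be >= 1")
        if not 0.0 <= self.edge_softness < 1.0:
            raise ValueError("edge_softness must lie in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Full generative description of a phantom cohort.

    ``distractors`` are rendered into the susceptibility map but never
    labeled: they emulate the adjacent iron-containing tissue (zona incerta
    and neighbouring gray matter) that surrounds the SN/STN complex in vivo
    and has to be excluded by shape and position, not by intensity alone.
    Each distractor abuts the labeled structure named by its ``name`` field
    prefix ``near:<NAME>``; others are placed at their offset directly.
    """

    domain: DomainSpec
    nuclei: tuple[NucleusSpec, ...]
    distractors: tuple[NucleusSpec, ...] = ()
    background_mean: float = 0.0       # ppm
    noise_sd: float = 0.010            # ppm, additive Gaussian
    background_field_amplitude: float = 0.020  # ppm, smooth low-order confound
    jitter_sd: float = 0.8             # mm, per-subject placement jitter
    seed: int = 0

    def __post_init__(self):
        ids = [n.class_id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise ValueError("nucleus class_ids must be unique within a domain")


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without collision."""


# --------------------------------------------------------------- default specs
def target_domain_spec(matrix_rows: int = 288, matrix_cols: int = 240,
                       n_slices: int = 192,
                       voxel_size: tuple[float, float, float] = (0.83, 0.83, 0.80),
                       crop_size: int = 96) -> DomainSpec:
    """High-resolution protocol: coronal delineation, three classes."""
    return DomainSpec("target", matrix_rows, matrix_cols, n_slices, voxel_size,
                      THREE_CLASS, "coronal", crop_size)


def source_domain_spec(matrix_rows: int = 384, matrix_cols: int = 288,
                       n_slices: int = 96,
                       voxel_size: tuple[float, float, float] = (0.63, 0.63, 2.00),
                       crop_size: int = 128) -> DomainSpec:
    """Low-resolution protocol: axial delineation, RN + merged SN–STN."""
    return DomainSpec("source", matrix_rows, matrix_cols, n_slices, voxel_size,
                      TWO_CLASS, "axial", crop_size)


_RN = NucleusSpec(1, "RN", 0.082, 0.036, 459.0, 71.2,
                  (-3.0, 5.5, 0.0), (1.0, 0.9, 0.95), edge_softness=0.0)
_SN = NucleusSpec(2, "SN", 0.108, 0.042, 984.5, 210.8,
                  (6.5, 10.5, 0.0), (1.8, 0.62, 1.05), edge_softness=0.55)
_STN = NucleusSpec(3, "STN", 0.070, 0.031, 230.9, 63.1,
                   (-1.2, 14.8, 0.0), (1.3, 0.65, 0.9), edge_softness=0.5)
# Merged SN–STN class for the thick-slice source protocol: one ellipsoid pair
# with the combined volume and the volume-weighted mean susceptibility.
_SN_STN = NucleusSpec(2, "SN-STN", 0.101, 0.040, 1215.4, 220.0,
                      (5.0, 11.5, 0.0), (1.8, 0.7, 1.05), edge_softness=0.5)

# Unlabeled surroundings: iron-containing tissue abutting the SN/STN complex
# (zona incerta above the STN, peri-nigral gray matter behind the SN). They
# give the network lookalike signal next to the hard classes — the RN has no
# such neighbours, which is part of why it is the easy class in vivo.
_ZI = NucleusSpec(101, "near:STN", 0.055, 0.010, 350.0, 60.0,
                  (-6.5, 16.5, 0.0), (1.5, 0.8, 1.0), edge_softness=0.5)
_PERI_SN = NucleusSpec(102, "near:SN", 0.060, 0.012, 380.0, 60.0,
                       (10.5, 13.0, 2.0), (1.4, 0.8, 1.1), edge_softness=0.5)
_PERI_SRC = NucleusSpec(101, "near:SN-STN", 0.055, 0.012, 450.0, 80.0,
                        (9.0, 14.5, 3.0), (1.5, 0.8, 1.0), edge_softness=0.5)


def target_phantom_spec(domain: DomainSpec | None = None, seed: int = 0,
                        **kwargs) -> PhantomSpec:
    return PhantomSpec(domain or target_domain_spec(), (_RN, _SN, _STN),
                       distractors=(_ZI, _PERI_SN), seed=seed, **kwargs)


def source_phantom_spec(domain: DomainSpec | None = None, seed: int = 0,
                        **kwargs) -> PhantomSpec:
    return PhantomSpec(domain or source_domain_spec(), (_RN, _SN_STN),
                       distractors=(_PERI_SRC,), seed=seed, **kwargs)


# ----------------------------------------------------------------- generation
_UNIT_SPHERE_N = 146


def _unit_sphere_points() -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    i = np.arange(_UNIT_SPHERE_N, dtype=np.float64)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / _UNIT_SPHERE_N
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


_SPHERE = _unit_sphere_points()


@dataclass(frozen=True)
class _Ellipsoid:
    name: str
    class_id: int
    center: np.ndarray   # mm
    semiaxes: np.ndarray  # mm
    chi: float           # subject-level mean susceptibility, ppm
    softness: float = 0.0
    labeled: bool = True

    def contains(self, pts_mm: np.ndarray) -> np.ndarray:
        d = (pts_mm - self.center) / self.semiaxes
        return (d * d).sum(axis=-1) <= 1.0

    def surface_points(self) -> np.ndarray:
        return self.center + _SPHERE * self.semiaxes


def _ellipsoids_overlap(a: _Ellipsoid, b: _Ellipsoid) -> bool:
    # surface/center sampling test; adequate for the modest eccentricities here
    if a.contains(b.center[None])[0] or b.contains(a.center[None])[0]:
        return True
    return bool(a.contains(b.surface_points()).any() or
                b.contains(a.surface_points()).any())


def _abut(fixed: _Ellipsoid, movable: _Ellipsoid, gap_mm: float) -> _Ellipsoid:
    """Slide ``movable`` along the center line until it just clears ``fixed``.

    Emulates structures that touch without a resolvable boundary (SN/STN):
    bisection finds the smallest center separation without overlap, then a
    sub-voxel ``gap_mm`` is added along the separation direction.
    """
    direction = movable.center - fixed.center
    dist = float(np.linalg.norm(direction))
    if dist == 0.0:  # pragma: no cover - jitter never collapses centers
        return movable
    u = direction / dist

    def at(t: float) -> _Ellipsoid:
        return replace(movable, center=fixed.center + u * t)

    lo, hi = 0.2 * dist, 2.5 * dist
    if _ellipsoids_overlap(fixed, at(hi)):  # pragma: no cover - degenerate
        return movable
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _ellipsoids_overlap(fixed, at(mid)):
            lo = mid
        else:
            hi = mid
    return at(hi + gap_mm)


def _place_nuclei(spec: PhantomSpec, rng: np.random.Generator) -> list[_Ellipsoid]:
    """Draw per-subject nucleus geometry; rejection-sample the jitter."""
    dom = spec.domain
    vs = np.asarray(dom.voxel_size)
    center_mm = (np.asarray(dom.shape) - 1) * vs / 2.0
    half_crop_mm = np.array([dom.crop_size * vs[0] / 2.0,
                             dom.crop_size * vs[1] / 2.0,
                             dom.n_slices * vs[2] / 2.0])
    margin = 1.5 * vs  # keep the majority-vote mask strictly inside the window

    # subject-level draws are made once, outside the rejection loop, so the
    # retry only perturbs placement, not the cohort statistics; draws are
    # truncated symmetrically (mean-preserving) — in-vivo cohort ranges do
    # not reach the Gaussian tails, and an iron-rich nucleus never approaches
    # zero susceptibility in vivo (hence the tighter 1.5 SD bound for chi)
    def truncated(mean, sd, width):
        for _ in range(100):
            x = rng.normal(mean, sd)
            if abs(x - mean) <= width * sd:
                return float(x)
        return mean

    structures = list(spec.nuclei) + list(spec.distractors)
    chi = {n.name: truncated(n.mean_susceptibility, n.susceptibility_sd, 1.5)
           for n in structures}
    vol = {n.name: truncated(n.mean_volume, n.volume_sd, 2.0)
           for n in structures}

    last_collision = ("", "")
    for _ in range(100):
        ellipsoids: list[_Ellipsoid] = []
        for n in structures:
            ratios = np.asarray(n.semiaxis_ratios, dtype=np.float64)
            hemi_vol = vol[n.name] / 2.0
            base = (3.0 * hemi_vol / (4.0 * math.pi * np.prod(ratios))) ** (1.0 / 3.0)
            semiaxes = base * ratios
            for side in (+1.0, -1.0):
                offset = np.asarray(n.center_offset) * np.array([1.0, side, 1.0])
                jitter = rng.normal(0.0, spec.jitter_sd, size=3)
                ellipsoids.append(
                    _Ellipsoid(f"{n.name}/{'R' if side > 0 else 'L'}",
                               n.class_id, center_mm + offset + jitter,
                               semiaxes, chi[n.name], n.edge_softness,
                               labeled=n in spec.nuclei))

        # abutment: the STN touches the SN with no resolvable gap (their
        # separation is the hard part of the task), and each "near:<NAME>"
        # distractor is snapped against its named structure per hemisphere
        by_name = {e.name: i for i, e in enumerate(ellipsoids)}
        for side in ("R", "L"):
            if f"SN/{side}" in by_name and f"STN/{side}" in by_name:
                gap = float(rng.uniform(0.1, 0.5))
                i = by_name[f"STN/{side}"]
                ellipsoids[i] = _abut(ellipsoids[by_name[f"SN/{side}"]],
                                      ellipsoids[i], gap)
            for n in spec.distractors:
                key = f"{n.name}/{side}"
                anchor = f"{n.name.split(':', 1)[-1]}/{side}" \
                    if n.name.startswith("near:") else None
                if anchor and anchor in by_name and key in by_name:
                    gap = float(rng.uniform(0.1, 0.5))
                    i = by_name[key]
                    ellipsoids[i] = _abut(ellipsoids[by_name[anchor]],
                                          ellipsoids[i], gap)

        ok = True
        for e in ellipsoids:
            lo = e.center - e.semiaxes - margin
            hi = e.center + e.semiaxes + margin
            if (lo < center_mm - half_crop_mm).any() or (hi > center_mm + half_crop_mm).any():
                ok = False
                last_collision = (e.name, "crop window")
                break
        if ok:
            # same-class (mirrored) pairs additionally need > 1 voxel of
            # clearance, or 26-connectivity would merge the two hemisphere
            # components into one
            pad = 1.2 * float(max(vs))
            for i in range(len(ellipsoids)):
                for j in range(i + 1, len(ellipsoids)):
                    a, b = ellipsoids[i], ellipsoids[j]
                    if a.class_id == b.class_id:
                        a = replace(a, semiaxes=a.semiaxes + pad / 2)
                        b = replace(b, semiaxes=b.semiaxes + pad / 2)
                    if _ellipsoids_overlap(a, b):
                        ok = False
                        last_collision = (ellipsoids[i].name, ellipsoids[j].name)
                        break
                if not ok:
                    break
        if ok:
            return ellipsoids
    raise PlacementError(
        f"could not place nuclei without collision after 100 attempts; "
        f"last conflict: {last_collision[0]} vs {last_collision[1]}")


def _background_field(shape, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth low-frequency confound: random polynomial of degree <= 2."""
    if amplitude == 0.0:
        return np.zeros(shape, dtype=np.float32)
    ax = [np.linspace(-1.0, 1.0, n, dtype=np.float32) for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
    terms = [x, y, z, x * y, y * z, x * z, x * x, y * y, z * z]
    coef = rng.normal(0.0, 1.0, size=len(terms))
    fld = sum(c * t for c, t in zip(coef, terms)).astype(np.float32)
    peak = np.abs(fld).max()
    if peak > 0:
        fld *= amplitude / peak
    return np.broadcast_to(fld, shape).astype(np.float32)


def _rasterize(e: _Ellipsoid, dom: DomainSpec):
    """Per-voxel occupancy fraction on a 2x supersampled grid (bounding box)."""
    vs = np.asarray(dom.voxel_size)
    lo_vox = np.maximum(np.floor((e.center - e.semiaxes) / vs - 1).astype(int), 0)
    hi_vox = np.minimum(np.ceil((e.center + e.semiaxes) / vs + 1).astype(int),
                        np.asarray(dom.shape) - 1)
    idx = [np.arange(lo_vox[d], hi_vox[d] + 1) for d in range(3)]
    # 2x supersampling: subvoxel centers at +/- 0.25 voxel around the center
    frac = np.zeros([len(i) for i in idx], dtype=np.float32)
    for dr in (-0.25, 0.25):
        for dc in (-0.25, 0.25):
            for ds in (-0.25, 0.25):
                r = (idx[0] + dr) * vs[0]
                c = (idx[1] + dc) * vs[1]
                s = (idx[2] + ds) * vs[2]
                rr, cc, ss = np.meshgrid(r, c, s, indexing="ij", sparse=True)
                d0 = (rr - e.center[0]) / e.semiaxes[0]
                d1 = (cc - e.center[1]) / e.semiaxes[1]
                d2 = (ss - e.center[2]) / e.semiaxes[2]
                frac += (d0 * d0 + d1 * d1 + d2 * d2) <= 1.0
    frac /= 8.0
    # intensity profile: uniform for softness 0, otherwise tapering toward
    # the boundary as 1 - softness * r^2 (r = normalized ellipsoid radius at
    # the voxel center, clipped to 1)
    if e.softness > 0:
        r = (idx[0] * vs[0])[:, None, None]
        c = (idx[1] * vs[1])[None, :, None]
        s = (idx[2] * vs[2])[None, None, :]
        r2 = (((r - e.center[0]) / e.semiaxes[0]) ** 2
              + ((c - e.center[1]) / e.semiaxes[1]) ** 2
              + ((s - e.center[2]) / e.semiaxes[2]) ** 2)
        profile = (1.0 - e.softness * np.minimum(r2, 1.0)).astype(np.float32)
    else:
        profile = np.float32(1.0)
    sl = tuple(slice(lo_vox[d], hi_vox[d] + 1) for d in range(3))
    return sl, frac, frac * profile


def generate_subject(spec: PhantomSpec, subject_seed: int) -> tuple[Volume, LabelMap]:
    """Generate one phantom subject deterministically.

    The same ``(spec, subject_seed)`` pair always reproduces bit-identical
    output. Raises :class:`PlacementError` if the jittered nuclei cannot be
    placed without collision.
    """
    if subject_seed < 0:
        raise ValueError("subject_seed must be >= 0")
    dom = spec.domain
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))

    ellipsoids = _place_nuclei(spec, rng)
    data = np.full(dom.shape, spec.background_mean, dtype=np.float32)
    data += _background_field(dom.shape, rng, spec.background_field_amplitude)
    data += rng.normal(0.0, spec.noise_sd, size=dom.shape).astype(np.float32)

    labels = np.zeros(dom.shape, dtype=np.uint8)
    for e in ellipsoids:
        sl, frac, signal = _rasterize(e, dom)
        mask = frac >= 0.5  # majority vote of the supersampled occupancy
        # normalize the signal so the measured class mean matches the
        # subject-level draw despite partial volume and boundary tapering
        # (as it does for in-vivo ROIs drawn on the reconstructed map)
        mean_signal = float(signal[mask].mean()) if mask.any() else 1.0
        amplitude = (e.chi - spec.background_mean) / max(mean_signal, 1e-6)
        data[sl] += (amplitude * signal).astype(np.float32)
        if e.labeled:
            labels[sl][mask] = e.class_id

    vol = Volume(data, dom.voxel_size)
    lab = LabelMap(labels, frozenset(n.class_id for n in spec.nuclei))
    return vol, lab


def generate_cohort(spec: PhantomSpec, n_subjects: int, seed: int,
                    out_dir: str | Path) -> DatasetCatalog:
    """Generate and write a cohort of phantoms plus a JSON manifest.

    Subject seeds are ``seed * 100000 + k`` so cohorts with different seeds
    do not share subjects. Deterministic for a fixed ``(spec, seed)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_spec = replace(spec, seed=spec.seed + seed)
    entries = []
    for k in range(n_subjects):
        vol, lab = generate_subject(cohort_spec, k)
        sid = f"sub-{k:03d}"
        vpath = out_dir / f"{sid}_qsm.nii.gz"
        lpath = out_dir / f"{sid}_labels.nii.gz"
        write_volume(vpath, vol)
        write_labels(lpath, lab, spec.domain.voxel_size)
        entries.append(CatalogEntry(sid, str(vpath), str(lpath)))
    catalog = DatasetCatalog(entries=entries, domain_name=spec.domain.name,
                             label_scheme=spec.domain.label_scheme,
                             voxel_size=spec.domain.voxel_size, seed=seed)
    catalog.save(out_dir / "catalog.json")
    return catalog
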