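"""Parametric voxel geometry for corallite-scale coral tiles.

A tile is a square lattice of corallites (pitch ``CSC``) embedded in a
coenosteum, built from per-morphotype trait means and voxelized into a
:class:`LabelVolume` with three phases: water (0), tissue (1), skeleton (2).

Two contracted-tissue surface conventions are supported.  The default,
``tissue_surface="drape"``, lays a constant-thickness tissue layer (equal to
the maximal coenosteal spine length) over the entire skeletal relief: the
coenosarc tops the coenosteum at spine-tip height and the polyp tissue
lines the calyx walls and floor, so the corallite reads as a cup-shaped
depression in the tissue-water interface whose depth scales with the theca
height.  This is the configuration in which deep, closely spaced corallites
self-shade (their wall tissue receives no direct down-welling beam) and
surface rugosity differences between morphotypes approach twofold.  The
alternative ``tissue_surface="filled"`` fills the calyx cavity flush with
the theca rim.

The z axis increases downward from the top of the water column; voxel
indices are 0-based and all interfaces are half-open ``[lo, hi)`` evaluated
at voxel centers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

WATER, TISSUE, SKELETON = 0, 1, 2

#: traits swapped by :func:`exchange_traits` for each exchange group
EXCHANGE_GROUPS = {"spacing": ("CSC", "CSM"), "height": ("TH",)}

KNOCKOUT_FEATURES = ("corallite", "columella", "spines")


class GeometryError(ValueError):
    """Invalid morphotype parameters or voxelization request."""


@dataclass(frozen=True)
class MorphotypeParams:
    """Corallite/coenosteum trait means (mm) defining one morphotype.

    ``tissue_thickness_rule`` is either the string ``"max_spine_length"``
    (coenosarc thickness equals ``SPL``) or a fixed thickness in mm.
    ``columella_diameter`` defaults to ``CD / 6`` when not given (the trait
    is not part of the measured set).
    """

    CD: float          # calyx diameter
    TH: float          # theca (corallite wall) height = calyx depth
    SL: float          # septal length (radial, inward from theca)
    SW: float          # septal width
    CH: float          # columella height above the calyx floor
    SS: float          # coenosteal spine spacing
    SPL: float         # coenosteal spine length (height)
    SPW: float         # coenosteal spine base width
    CSC: float         # corallite center-to-center spacing
    CSM: float         # minimal corallite margin spacing
    n_septa: int = 6
    tissue_thickness_rule: str | float = "max_spine_length"
    columella_diameter: float | None = None
    allow_ch_above_th: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("CD", "TH", "SL", "SW", "CH", "SS", "SPL", "SPW", "CSC", "CSM"):
            if getattr(self, name) < 0:
                raise GeometryError(f"trait {name} must be >= 0, got {getattr(self, name)}")
        if self.CD > self.CSC:
            raise GeometryError(
                f"CD ({self.CD}) must not exceed CSC ({self.CSC}): corallites overlap"
            )
        if self.CSM > self.CSC - self.CD + 1e-9:
            raise GeometryError(
                f"CSM ({self.CSM}) exceeds CSC - CD ({self.CSC - self.CD:.4g})"
            )
        if self.CH > self.TH and not self.allow_ch_above_th:
            raise GeometryError(
                f"CH ({self.CH}) exceeds TH ({self.TH}); columella would protrude"
            )
        if self.n_septa < 0:
            raise GeometryError("n_septa must be >= 0")

    @property
    def tissue_thickness(self) -> float:
        """Coenosarc thickness over the coenosteum, mm."""
        if self.tissue_thickness_rule == "max_spine_length":
            return self.SPL
        return float(self.tissue_thickness_rule)

    @property
    def columella_d(self) -> float:
        return self.CD / 6.0 if self.columella_diameter is None else self.columella_diameter


@dataclass
class LabelVolume:
    """Voxelized three-phase geometry at fixed isotropic resolution.

    ``labels`` is indexed ``[z, y, x]`` with z increasing downward from the
    top of the water column; ``resolution`` is mm per voxel.
    """

    labels: np.ndarray
    resolution: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GeometryError("resolution must be > 0")
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        bad = set(np.unique(self.labels)) - {WATER, TISSUE, SKELETON}
        if bad:
            raise GeometryError(f"labels contain values outside {{0,1,2}}: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def phase_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=3)
        return {"water": int(counts[0]), "tissue": int(counts[1]), "skeleton": int(counts[2])}

    def tissue_voxels(self) -> int:
        return int((self.labels == TISSUE).sum())

    def surface_height_index(self) -> np.ndarray:
        """z index of the first non-water voxel in each lateral column."""
        solid = self.labels != WATER
        if not solid.any(axis=0).all():
            raise GeometryError("some columns contain no tissue/skeleton voxel")
        return solid.argmax(axis=0)

    def save(self, path: str | Path) -> None:
        """Write an 8-bit multi-page TIFF (one page per z slice) + JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.labels, photometric="minisblack")
        sidecar = {
            "resolution_mm": self.resolution,
            "axis_order": "zyx, z down from top of water column",
            "labels": {"0": "water", "1": "tissue", "2": "skeleton"},
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        labels = tifffile.imread(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(labels=labels, resolution=sidecar["resolution_mm"], meta=sidecar.get("meta", {}))


@dataclass(frozen=True)
class SurfaceMetrics:
    surface_area: float     # mm^2, tissue-water interface
    planar_area: float      # mm^2, projected tile area
    rugosity: float         # surface_area / planar_area, >= 1
    tissue_volume: float    # mm^3
    porosity: float         # pore fraction of the skeleton envelope


def load_default_morphotypes(path: str | Path | None = None) -> dict[str, MorphotypeParams]:
    """Load the shipped shallow/mesophotic trait-mean fixtures."""
    if path is None:
        path = Path(__file__).parent / "data" / "morphotypes.yaml"
    raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for name in ("shallow", "mesophotic"):
        traits = {k: v for k, v in raw[name].items() if k not in ("branch_thickness", "porosity")}
        out[name] = MorphotypeParams(label=name, **traits)
    return out


def _lattice_centers(extent: float, pitch: float) -> np.ndarray:
    n = max(1, round(extent / pitch))
    eff = extent / n
    return (np.arange(n) + 0.5) * eff


def build_tile(
    params: MorphotypeParams,
    resolution: float = 0.02,
    tile_corallites: int = 1,
    water_above: float = 0.3,
    slab_below: float = 0.3,
    knockout: str | None = None,
    tissue_surface: str = "drape",
) -> LabelVolume:
    """Voxelize a ``tile_corallites`` x ``tile_corallites`` corallite lattice.

    The tile is laterally periodic by construction: corallites sit at pitch
    ``CSC`` and the spine lattice pitch is snapped to divide the tile edge,
    so opposite faces carry identical label columns (usable with periodic
    transport boundaries).  ``tissue_surface`` selects the contracted-tissue
    convention (``"drape"`` or ``"filled"``, see module docstring).
    ``knockout`` removes one feature (see :func:`knockout_tile`, which also
    conserves tissue volume for the corallite knock-out).
    """
    if tissue_surface not in ("drape", "filled"):
        raise GeometryError(f"unknown tissue_surface {tissue_surface!r}; expected 'drape' or 'filled'")
    if resolution <= 0:
        raise GeometryError("resolution must be > 0")
    if params.CD > 0 and resolution > params.CD / 10:
        raise GeometryError(
            f"resolution {resolution} too coarse: must be <= CD/10 = {params.CD / 10:.4g} mm"
        )
    if knockout is not None and knockout not in KNOCKOUT_FEATURES:
        raise GeometryError(f"unknown knockout feature {knockout!r}; expected one of {KNOCKOUT_FEATURES}")

    drop_corallite = knockout == "corallite"
    drop_columella = knockout == "columella" or drop_corallite
    drop_spines = knockout == "spines"

    t_tissue = params.tissue_thickness
    cd = 0.0 if drop_corallite else params.CD
    th = 0.0 if drop_corallite else params.TH

    L = tile_corallites * params.CSC
    nx = ny = max(2, round(L / resolution))
    z_tissue_top = water_above
    z_coen = water_above + t_tissue
    z_floor = z_coen + th
    z_bot = z_floor + slab_below
    nz = max(2, math.ceil(z_bot / resolution))

    # voxel-center coordinates, mm
    xc = (np.arange(nx) + 0.5) * resolution
    yc = (np.arange(ny) + 0.5) * resolution
    zc = (np.arange(nz) + 0.5) * resolution
    xx, yy = np.meshgrid(xc, yc)  # [y, x]

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[zc >= z_coen] = SKELETON

    calyx_mask = np.zeros((ny, nx), dtype=bool)
    septa_mask = np.zeros((ny, nx), dtype=bool)
    colu_mask = np.zeros((ny, nx), dtype=bool)
    centers = _lattice_centers(L, params.CSC)
    if cd > 0:
        r_cal = cd / 2.0
        for cy_ in centers:
            for cx_ in centers:
                dx, dy = xx - cx_, yy - cy_
                r2 = dx * dx + dy * dy
                inside = r2 < r_cal**2
                calyx_mask |= inside
                if params.n_septa > 0 and params.SL > 0 and params.SW > 0:
                    for k in range(params.n_septa):
                        ang = 2 * math.pi * k / params.n_septa
                        u = dx * math.cos(ang) + dy * math.sin(ang)
                        v = -dx * math.sin(ang) + dy * math.cos(ang)
                        septa_mask |= (
                            inside & (u >= r_cal - params.SL) & (np.abs(v) <= params.SW / 2)
                        )
                if not drop_columella and params.CH > 0 and params.columella_d > 0:
                    colu_mask |= r2 < (params.columella_d / 2.0) ** 2

        cavity_z = (zc >= z_coen) & (zc < z_floor)
        labels[np.ix_(cavity_z)] = np.where(
            calyx_mask[None, :, :], WATER, labels[np.ix_(cavity_z)]
        )
        # septa span the full calyx depth (thin ridges, wall to SL inward)
        labels[np.ix_(cavity_z)] = np.where(
            septa_mask[None, :, :], SKELETON, labels[np.ix_(cavity_z)]
        )
        colu_z = (zc >= z_floor - params.CH) & (zc < z_floor)
        labels[np.ix_(colu_z)] = np.where(
            (colu_mask & calyx_mask)[None, :, :], SKELETON, labels[np.ix_(colu_z)]
        )

    # coenosteal spines: cones on the coenosteum plane, apex at spine-tip height
    if not drop_spines and params.SPL > 0 and params.SPW > 0 and params.SS > 0:
        sp_centers = _lattice_centers(L, params.SS)
        pts = []
        for sy in sp_centers:
            for sx in sp_centers:
                if cd > 0:
                    d2 = min((sx - cx_) ** 2 + (sy - cy_) ** 2 for cy_ in centers for cx_ in centers)
                    if d2 < (cd / 2.0 + params.SPW / 2.0) ** 2:
                        continue  # no spines inside/overhanging the calyx
                pts.append((sy, sx))
        if pts:
            d2min = np.full((ny, nx), np.inf)
            for sy, sx in pts:
                d2min = np.minimum(d2min, (xx - sx) ** 2 + (yy - sy) ** 2)
            cone_z = np.nonzero((zc >= z_coen - params.SPL) & (zc < z_coen))[0]
            for iz in cone_z:
                h = z_coen - zc[iz]  # height above the coenosteum plane
                r = (params.SPW / 2.0) * (1.0 - h / params.SPL)
                if r > 0:
                    labels[iz][d2min < r * r] = SKELETON

    if tissue_surface == "drape":
        # constant-thickness tissue over the whole relief: coenosarc to the
        # spine-tip plane, polyp tissue lining the calyx walls and floor
        if t_tissue > 0:
            dist_vox = ndimage.distance_transform_edt(labels != SKELETON)
            # +0.5: distances are center-to-center; the skeleton surface sits
            # half a voxel closer, keeping drape thickness resolution-stable
            n_layers = max(1.0, t_tissue / resolution + 0.5)
            drape = (labels == WATER) & (dist_vox <= n_layers) & (zc >= z_tissue_top)[:, None, None]
            labels[drape] = TISSUE
    else:
        # coenosarc layer over the coenosteum (embeds the spines) ...
        coen_layer = (zc >= z_tissue_top) & (zc < z_coen)
        lay = labels[np.ix_(coen_layer)]
        labels[np.ix_(coen_layer)] = np.where(
            (~calyx_mask)[None, :, :] & (lay == WATER), TISSUE, lay
        )
        # ... and polyp tissue filling the calyx cavity flush with the rim
        if cd > 0:
            cavity_z = (zc >= z_coen) & (zc < z_floor)
            cav = labels[np.ix_(cavity_z)]
            labels[np.ix_(cavity_z)] = np.where(
                calyx_mask[None, :, :] & (cav == WATER), TISSUE, cav
            )

    meta = {
        "params": dataclasses.asdict(params),
        "tile_corallites": tile_corallites,
        "water_above_mm": water_above,
        "slab_below_mm": slab_below,
        "z_tissue_top_mm": z_tissue_top,
        "z_coenosteum_mm": z_coen,
        "z_calyx_floor_mm": z_floor,
        "knockout": knockout,
        "tissue_surface": tissue_surface,
        "lateral_extent_mm": L,
    }
    return LabelVolume(labels=labels, resolution=resolution, meta=meta)


def knockout_tile(
    params: MorphotypeParams,
    feature: str,
    resolution: float = 0.02,
    tile_corallites: int = 1,
    **kwargs,
) -> LabelVolume:
    """Build a tile with one skeletal feature removed.

    ``corallite``: the calyx (with its septa and columella) is removed and
    the coenosarc thickened so total tissue volume matches the default tile
    within one voxel layer's dithering precision (<< 1%).  ``columella`` and
    ``spines`` simply omit the feature; the coenosarc thickness keeps the
    default morphotype's value.
    """
    if feature not in KNOCKOUT_FEATURES:
        raise GeometryError(f"unknown knockout feature {feature!r}; expected one of {KNOCKOUT_FEATURES}")
    if feature == "spines":
        # keep the tissue thickness the spines would have set
        params = replace(params, tissue_thickness_rule=params.tissue_thickness, SPL=0.0)
        return build_tile(params, resolution, tile_corallites, **kwargs)
    if feature == "columella":
        if params.CH <= 0:
            raise GeometryError("columella not present (CH = 0)")
        return build_tile(params, resolution, tile_corallites, knockout="columella", **kwargs)

    # corallite knock-out: redistribute the polyp tissue over the coenosteum
    default = build_tile(params, resolution, tile_corallites, **kwargs)
    target = default.tissue_voxels()
    flat = build_tile(params, resolution, tile_corallites, knockout="corallite", **kwargs)
    flat = _conserve_tissue_volume(flat, target)
    flat.meta["knockout"] = "corallite"
    flat.meta["tissue_target_voxels"] = target
    return flat


def _conserve_tissue_volume(vol: LabelVolume, target: int) -> LabelVolume:
    """Thicken/thin the flat coenosarc so tissue voxel count matches ``target``.

    Whole layers are converted water<->tissue above the current surface;
    the final partial layer is dithered with a deterministic spatial hash
    so the match is exact to a single voxel.
    """
    labels = vol.labels.copy()
    nz, ny, nx = labels.shape
    have = int((labels == TISSUE).sum())
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    order = np.argsort((ix * 73856093 + iy * 19349663 + ix * iy * 83492791) % 104729, axis=None)
    for _ in range(10 * nz):
        delta = target - have
        if delta == 0:
            break
        solid_top = (labels != WATER).argmax(axis=0).ravel()  # first solid voxel
        if delta > 0:
            eligible = order[solid_top[order] > 0]
            if len(eligible) == 0:
                raise GeometryError("cannot thicken tissue: no water headroom left")
            pick = eligible[:delta]
            labels[solid_top[pick] - 1, pick // nx, pick % nx] = TISSUE
        else:
            top_lab = labels.reshape(nz, -1)[solid_top, np.arange(ny * nx)]
            eligible = order[top_lab[order] == TISSUE]
            if len(eligible) == 0:
                raise GeometryError("cannot thin tissue: no surface tissue left")
            pick = eligible[: -delta]
            labels[solid_top[pick], pick // nx, pick % nx] = WATER
        have = int((labels == TISSUE).sum())
    if have != target:
        raise GeometryError("tissue-volume conservation did not converge")
    return LabelVolume(labels=labels, resolution=vol.resolution, meta=dict(vol.meta))


def exchange_traits(
    a: MorphotypeParams, b: MorphotypeParams, traits: set[str] | frozenset[str]
) -> MorphotypeParams:
    """Return ``a`` with the named trait groups taken from ``b``.

    ``traits`` is a subset of ``{"spacing", "height"}``: spacing swaps the
    corallite spacing pair (CSC, CSM); height swaps the theca height TH.
    """
    unknown = set(traits) - set(EXCHANGE_GROUPS)
    if unknown:
        raise GeometryError(f"unknown exchange traits {sorted(unknown)}; expected subset of {sorted(EXCHANGE_GROUPS)}")
    updates: dict[str, float] = {}
    for group in traits:
        for name in EXCHANGE_GROUPS[group]:
            updates[name] = getattr(b, name)
    return replace(a, **updates)


def surface_metrics(vol: LabelVolume) -> SurfaceMetrics:
    """Surface area, rugosity, tissue volume and skeletal porosity of a tile.

    The tissue-water interface is a heightfield by construction; its area is
    computed from a periodic triangulation of the per-column surface height
    (exact for a flat slab, convergent for curved surfaces).  Rugosity is
    real area / planar tile area (>= 1).  Porosity is the water fraction of
    the skeleton envelope (per column, from the topmost skeleton voxel down).
    """
    if vol.tissue_voxels() == 0:
        raise GeometryError("volume contains no tissue; surface metrics undefined")
    res = vol.resolution
    hidx = vol.surface_height_index()
    h = hidx.astype(float) * res  # depth of the surface below the grid top
    # periodic triangulated heightfield area (two triangles per cell)
    hx = np.roll(h, -1, axis=1)
    hy = np.roll(h, -1, axis=0)
    hxy = np.roll(hx, -1, axis=0)
    # triangle (0,0)-(1,0)-(0,1) and (1,0)-(1,1)-(0,1) on the unit cell
    a1 = 0.5 * np.sqrt(res**2 * (h - hx) ** 2 + res**2 * (h - hy) ** 2 + res**4)
    a2 = 0.5 * np.sqrt(res**2 * (hxy - hy) ** 2 + res**2 * (hxy - hx) ** 2 + res**4)
    area = float((a1 + a2).sum())
    ny, nx = h.shape
    planar = nx * ny * res * res
    rugosity = area / planar

    tissue_volume = vol.tissue_voxels() * res**3

    skel = vol.labels == SKELETON
    has_skel = skel.any(axis=0)
    porosity = 0.0
    if has_skel.any():
        top = skel.argmax(axis=0)
        nz = vol.labels.shape[0]
        depth_idx = np.arange(nz)[:, None, None]
        envelope = (depth_idx >= top[None, :, :]) & has_skel[None, :, :]
        env_n = int(envelope.sum())
        pores = int((envelope & (vol.labels == WATER)).sum())
        porosity = pores / env_n if env_n else 0.0
    return SurfaceMetrics(
        surface_area=area,
        planar_area=planar,
        rugosity=rugosity,
        tissue_volume=tissue_volume,
        porosity=porosity,
    )


def add_pores(
    vol: LabelVolume, target_porosity: float, pore_radius: float, seed: int
) -> LabelVolume:
    """Carve random spherical pores into the skeleton phase (synthetic).

    A reporting-metric exercise only: transport treats the skeleton as
    homogeneous.  Pores are placed uniformly inside the skeleton until the
    envelope porosity reaches ``target_porosity`` (or placement stalls).
    """
    if not 0 <= target_porosity < 1:
        raise GeometryError("target_porosity must be in [0, 1)")
    labels = vol.labels.copy()
    res = vol.resolution
    rng = np.random.default_rng(seed)
    nz, ny, nx = labels.shape
    r_vox = max(1, round(pore_radius / res))
    zz, yy, xx = np.ogrid[-r_vox : r_vox + 1, -r_vox : r_vox + 1, -r_vox : r_vox + 1]
    ball = zz**2 + yy**2 + xx**2 <= r_vox**2
    out = LabelVolume(labels=labels, resolution=res, meta=dict(vol.meta))
    for _ in range(100000):
        if surface_metrics_porosity(out) >= target_porosity:
            break
        cz = rng.integers(r_vox, nz - r_vox)
        cy = rng.integers(r_vox, ny - r_vox)
        cx = rng.integers(r_vox, nx - r_vox)
        if labels[cz, cy, cx] != SKELETON:
            continue
        sub = labels[cz - r_vox : cz + r_vox + 1, cy - r_vox : cy + r_vox + 1, cx - r_vox : cx + r_vox + 1]
        sub[ball & (sub == SKELETON)] = WATER
    out.labels = labels
    return out


def surface_metrics_porosity(vol: LabelVolume) -> float:
    """Porosity of the skeleton envelope only (cheaper than full metrics)."""
    skel = vol.labels == SKELETON
    has_skel = skel.any(axis=0)
    if not has_skel.any():
        return 0.0
    top = skel.argmax(axis=0)
    nz = vol.labels.shape[0]
    depth_idx = np.arange(nz)[:, None, None]
    envelope = (depth_idx >= top[None, :, :]) & has_skel[None, :, :]
    pores = int((envelope & (vol.labels == WATER)).sum())
    return pores / int(envelope.sum())


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
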