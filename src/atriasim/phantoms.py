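"""Synthetic, ground-truth-bearing inputs for the pipeline.

Two families of objects are generated here:

* **Fiber phantoms** — image volumes whose texture is elongated along an
  analytically known direction field (parallel, circular or helical).  They
  validate the structure-tensor orientation extraction: intensity varies
  least along the local fiber, so the smallest-eigenvalue eigenvector of the
  structure tensor should recover the ground truth.

* **A parametric AVSD atrial geometry** — a flattened, "unrolled" sheet that
  reproduces the topology of the dual atrioventricular nodal inputs in a
  heart with an atrioventricular septal defect: the compact AV node is
  displaced posterior-inferiorly (anterior to the coronary-sinus ostium),
  which shortens the "slow" pathway and elongates the "fast" pathway.  The
  sinus node connects to the compact node via three label-disjoint routes —
  terminal crest + slow pathway (shortest), a septal bundle standing for the
  fast pathway (intermediate), and the common valve annulus (longest) —
  forming a closed conduction circuit.  Path lengths and topology, not
  patient anatomy, drive the electrophysiology, so a parametric sheet is an
  adequate substrate.

The slow-pathway entrance is modelled as a narrow transitional isthmus
(leaving the terminal crest) that opens abruptly into a broad slow-pathway
isthmus region.  This geometric source-sink mismatch is the classical
substrate for unidirectional block of premature wavefronts and provides the
synthetic analogue of the distorted nodal-input anatomy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .volumes import ImageVolume, LabelVolume, OrientationField

__all__ = [
    "FiberPhantomSpec",
    "AVSDGeometrySpec",
    "LabelDictionary",
    "AVSDGeometry",
    "default_label_dictionary",
    "make_fiber_phantom",
    "make_avsd_atria",
    "make_attenuation_volume",
    "DEFAULT_CONTRAST",
]


# ---------------------------------------------------------------------------
# Label dictionary
# ---------------------------------------------------------------------------

_DEFAULT_LABELS = {
    "background": 0,
    "working_myocardium_RA": 1,
    "sinus_node": 2,
    "terminal_crest": 3,
    "bachmann_bundle": 4,
    "slow_pathway": 5,
    "fast_pathway_septal_bundle": 6,
    "valve_annulus": 7,
    "compact_AV_node": 8,
    "AVCA": 9,
    "block_zone": 10,
    "fat": 11,
    "connective_tissue": 12,
    "patch_inert": 13,
}

# electrophysiological class of every label (total mapping)
_EP_CLASS = {
    "background": "inert",
    "working_myocardium_RA": "RA",
    "sinus_node": "CT",
    "terminal_crest": "CT",
    "bachmann_bundle": "CT",
    "slow_pathway": "CT",
    "fast_pathway_septal_bundle": "CT",
    "valve_annulus": "CT",
    "compact_AV_node": "CT",
    "AVCA": "CT",
    "block_zone": "RA_block",
    "fat": "inert",
    "connective_tissue": "inert",
    "patch_inert": "inert",
}


@dataclass(frozen=True)
class LabelDictionary:
    """Bidirectional label-code <-> name map plus the EP-class assignment."""

    name_to_code: Mapping[str, int]

    def __post_init__(self) -> None:
        codes = list(self.name_to_code.values())
        if len(set(codes)) != len(codes):
            raise ValueError("label codes must be unique")
        if self.name_to_code.get("background", None) != 0:
            raise ValueError("background label must exist and have code 0")
        for name in self.name_to_code:
            if name not in _EP_CLASS:
                raise ValueError(f"label {name!r} has no electrophysiological class")

    @property
    def code_to_name(self) -> dict[int, str]:
        return {v: k for k, v in self.name_to_code.items()}

    def code(self, name: str) -> int:
        return self.name_to_code[name]

    def name(self, code: int) -> str:
        return self.code_to_name[code]

    def ep_class(self, name_or_code: str | int) -> str:
        if isinstance(name_or_code, str):
            return _EP_CLASS[name_or_code]
        return _EP_CLASS[self.name(int(name_or_code))]

    def to_json_dict(self) -> dict:
        return {
            "labels": dict(self.name_to_code),
            "ep_class": {k: _EP_CLASS[k] for k in self.name_to_code},
        }


def default_label_dictionary() -> LabelDictionary:
    return LabelDictionary(dict(_DEFAULT_LABELS))


# ---------------------------------------------------------------------------
# Fiber phantoms
# ---------------------------------------------------------------------------

_PATTERNS = ("parallel", "circular", "helical")


@dataclass(frozen=True)
class FiberPhantomSpec:
    pattern: str = "parallel"
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_um: float = 38.5
    fiber_texture_period_um: float = 300.0
    noise_sd: float = 0.0
    seed: int = 0
    helix_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"pattern must be one of {_PATTERNS}, got {self.pattern!r}")
        if len(self.grid_shape) != 3 or any(int(s) < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers, all >= 16")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.fiber_texture_period_um > 0:
            raise ValueError("fiber_texture_period_um must be positive")
        if not 0 <= self.noise_sd < 1:
            raise ValueError("noise_sd must be in [0, 1)")


def _phantom_truth(spec: FiberPhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vec = np.zeros((nx, ny, nz, 3))
    if spec.pattern == "parallel":
        vec[..., 0] = 1.0
        return vec
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    dx, dy = x - cx, y - cy
    r = np.hypot(dx, dy)
    r_safe = np.where(r < 1e-9, 1.0, r)
    tx, ty = -dy / r_safe, dx / r_safe
    if spec.pattern == "circular":
        vec[..., 0], vec[..., 1] = tx, ty
    else:  # helical
        alpha = math.radians(spec.helix_angle_deg)
        vec[..., 0] = math.cos(alpha) * tx
        vec[..., 1] = math.cos(alpha) * ty
        vec[..., 2] = math.sin(alpha)
    # on the axis the tangent is undefined; pick a fixed fallback
    on_axis = r < 1e-9
    vec[on_axis] = (1.0, 0.0, 0.0)
    return vec


def make_fiber_phantom(spec: FiberPhantomSpec) -> tuple[ImageVolume, OrientationField]:
    """Generate a textured volume plus its analytic ground-truth orientation.

    The texture is white noise convolved along the local fiber direction
    (line-integral-convolution style): intensity then varies least along the
    fiber and isotropically across it, which is exactly the contrast a
    structure-tensor analysis exploits.
    """
    period_vox = spec.fiber_texture_period_um / spec.voxel_size_um
    min_size = int(math.ceil(2 * period_vox)) + 8
    if min(spec.grid_shape) < min_size:
        raise ValueError(
            f"grid too small for texture period: need at least {min_size} voxels "
            f"per axis for fiber_texture_period_um={spec.fiber_texture_period_um} "
            f"at voxel_size_um={spec.voxel_size_um}"
        )

    rng = np.random.default_rng(spec.seed)
    truth = _phantom_truth(spec)
    noise = rng.standard_normal(spec.grid_shape)
    # isotropic pre-smoothing sets the cross-fiber grain size, which scales
    # with the texture period the way myocyte width scales with chain
    # spacing; too-fine grain leaves lattice-direction gradient bias on
    # oblique fibers, too-coarse grain starves the tensor window of
    # independent grains
    noise = ndimage.gaussian_filter(noise, max(0.5, period_vox / 10.0))

    nx, ny, nz = spec.grid_shape
    base = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=0,
    ).astype(float)
    # line-integral convolution along streamlines of the direction field
    # (kernel half-length ~ 1.5 texture periods); straight-line sampling
    # would smear across fibers wherever the field curves, and linear
    # interpolation would inject lattice-orientation-dependent artifacts
    n_steps = max(4, int(round(3.0 * period_vox)))
    step = 0.5  # voxels per advection step
    f = np.moveaxis(truth, -1, 0)  # (3, nx, ny, nz)
    src = ndimage.spline_filter(noise, order=3)
    acc = noise.copy()
    count = 1.0
    for sgn in (1.0, -1.0):
        pos = base.copy()
        d_prev = sgn * f
        for _ in range(n_steps):
            d = np.stack([map_coordinates(f[c], pos, order=1, mode="nearest")
                          for c in range(3)])
            # axial field: keep the advection direction consistent
            flip = np.sign(np.sum(d * d_prev, axis=0))
            flip[flip == 0] = 1.0
            d = d * flip
            norm = np.sqrt(np.sum(d * d, axis=0))
            d = d / np.maximum(norm, 1e-9)
            pos = pos + step * d
            d_prev = d
            acc += map_coordinates(src, pos, order=3, prefilter=False,
                                   mode="reflect")
            count += 1.0
    tex = acc / count
    lo, hi = tex.min(), tex.max()
    tex = 0.2 + 0.6 * (tex - lo) / max(hi - lo, 1e-12)
    if spec.noise_sd > 0:
        tex = tex + spec.noise_sd * 0.6 * rng.standard_normal(spec.grid_shape)

    vol = ImageVolume(tex, spacing_mm=spec.voxel_size_um / 1000.0,
                      meta={"phantom": spec.pattern, "seed": spec.seed})
    field = OrientationField(truth, np.ones(spec.grid_shape),
                             spacing_mm=spec.voxel_size_um / 1000.0,
                             meta={"phantom": spec.pattern})
    return vol, field


# ---------------------------------------------------------------------------
# AVSD geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AVSDGeometrySpec:
    """Parameters of the flattened AVSD atrial sheet.

    Route lengths are total sinus-node -> compact-node centerline lengths.
    The displaced node shortens the slow pathway and lengthens the fast one,
    hence ``path_length_fast_mm > path_length_slow_mm``; the common valve
    annulus is the longest route of the circuit.
    """

    path_length_slow_mm: float = 12.0
    path_length_fast_mm: float = 16.5
    annulus_length_mm: float = 26.0
    bundle_width_mm: float = 0.9
    sheet_thickness_mm: float = 0.3
    # None -> auto-layout: SN at a fixed spot, compact node placed at the
    # reach of the distal slow segment below/right of the crest end
    node_positions: Mapping[str, tuple[float, float]] | None = None
    block_zone_extent_mm: float = 2.0
    voxel_size_mm: float = 0.15
    # geometry detail of the distorted nodal-input region: the slow route
    # (terminal crest + slow pathway) takes off from the sinus-node region
    # through a narrow transitional isthmus that opens abruptly into the
    # broad crest — the source-sink mismatch that blocks premature
    # wavefronts while leaving the septal (fast) take-off smooth
    crest_fraction: float = 0.7          # fraction of the slow route on the terminal crest
    slow_width_factor: float = 2.0       # slow-pathway isthmus region width / bundle width
    crest_width_factor: float = 1.5
    slow_isthmus_width_mm: float = 0.45  # transitional isthmus at the crest take-off
    slow_isthmus_length_mm: float = 1.2  # measured beyond the sinus-node blob
    node_radius_mm: float = 1.0
    sn_radius_mm: float = 0.9

    def __post_init__(self) -> None:
        for name in ("path_length_slow_mm", "path_length_fast_mm", "annulus_length_mm",
                     "bundle_width_mm", "sheet_thickness_mm", "block_zone_extent_mm",
                     "voxel_size_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.path_length_fast_mm > self.path_length_slow_mm:
            raise ValueError("path_length_fast_mm must exceed path_length_slow_mm")
        if not self.annulus_length_mm > self.path_length_fast_mm:
            raise ValueError("annulus_length_mm must exceed path_length_fast_mm")
        for name in ("path_length_slow_mm", "path_length_fast_mm", "annulus_length_mm"):
            if getattr(self, name) <= 4 * self.bundle_width_mm:
                raise ValueError(f"{name} must exceed 4 x bundle_width_mm")
        if self.node_positions is not None:
            for key in ("sinus_node", "compact_AV_node"):
                if key not in self.node_positions:
                    raise ValueError(f"node_positions must contain {key!r}")

    def resolved_node_positions(self) -> dict[str, tuple[float, float]]:
        if self.node_positions is not None:
            return {k: tuple(v[:2]) for k, v in self.node_positions.items()}
        sn = (12.0, 16.0)
        crest_len = self.crest_fraction * self.path_length_slow_mm
        slow_len = self.path_length_slow_mm - crest_len
        crest_end = (sn[0], sn[1] - crest_len)
        u = np.array([3.2, -1.2])
        u = u / np.linalg.norm(u)
        node = crest_end + 0.95 * slow_len * u
        return {"sinus_node": sn, "compact_AV_node": (float(node[0]), float(node[1]))}


def _arc_polyline(p0, p1, length, bulge_sign, ds=0.05):
    """Sample a circular arc from p0 to p1 with the given arc length.

    ``bulge_sign`` selects the side of the chord (+1 bulges toward the
    left-hand normal of p1-p0).  Returns (points, unit tangents, arclength).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    chord = float(np.linalg.norm(p1 - p0))
    if length < chord - 1e-9:
        raise ValueError(f"arc length {length} shorter than chord {chord}")
    n = max(8, int(math.ceil(length / ds)))
    if length <= chord * (1 + 1e-9):  # straight segment
        t = np.linspace(0.0, 1.0, n)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        tan = np.tile((p1 - p0) / max(chord, 1e-12), (n, 1))
        return pts, tan, t * chord

    ratio = length / chord
    theta = brentq(lambda th: th / (2.0 * math.sin(th / 2.0)) - ratio,
                   1e-6, 2.0 * math.pi - 1e-6)
    radius = length / theta
    mid = 0.5 * (p0 + p1)
    chat = (p1 - p0) / chord
    nhat = np.array([-chat[1], chat[0]])
    center = mid - bulge_sign * radius * math.cos(theta / 2.0) * nhat
    phi0 = math.atan2(p0[1] - center[1], p0[0] - center[0])
    phi1 = math.atan2(p1[1] - center[1], p1[0] - center[0])
    # choose the sweep (+theta or -theta) that lands on p1
    best = None
    for dphi in (theta, -theta):
        end = center + radius * np.array([math.cos(phi0 + dphi), math.sin(phi0 + dphi)])
        err = np.linalg.norm(end - p1)
        if best is None or err < best[0]:
            best = (err, dphi)
    dphi = best[1]
    t = np.linspace(0.0, 1.0, n)
    phi = phi0 + dphi * t
    pts = center[None, :] + radius * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    tan = np.sign(dphi) * np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    return pts, tan, np.abs(dphi) * radius * t


@dataclass
class AVSDGeometry:
    """Rasterized AVSD sheet: labels, orientation and route metadata.

    Iterable as ``labels, orientation = geometry`` for convenience.
    """

    labels: LabelVolume
    orientation: OrientationField
    dictionary: LabelDictionary
    spec: AVSDGeometrySpec
    routes: dict[str, dict]
    origin_mm: tuple[float, float, float]

    def __iter__(self) -> Iterator:
        return iter((self.labels, self.orientation))


def make_avsd_atria(spec: AVSDGeometrySpec | None = None) -> AVSDGeometry:
    """Rasterize the parametric AVSD sheet onto an isotropic voxel grid.

    The three sinus-node -> compact-node routes are drawn as circular arcs
    whose centerline lengths equal the spec's route lengths; orientation
    vectors run along the local centerline tangent.  A configurable block
    zone sits between the sinus node and the septal bundle, and inert fat /
    connective-tissue pads are included so that attenuation rendering shows
    the full tissue-contrast ordering.
    """
    spec = spec or AVSDGeometrySpec()
    ldict = default_label_dictionary()
    h = spec.voxel_size_mm
    w = spec.bundle_width_mm

    positions = spec.resolved_node_positions()
    sn = np.asarray(positions["sinus_node"][:2], float)
    node = np.asarray(positions["compact_AV_node"][:2], float)

    # --- centerlines ------------------------------------------------------
    crest_len = spec.crest_fraction * spec.path_length_slow_mm
    slow_len = spec.path_length_slow_mm - crest_len
    crest_end = sn + np.array([0.0, -crest_len])
    if np.linalg.norm(node - crest_end) > slow_len + 1e-9:
        raise ValueError(
            "node_positions incompatible with path_length_slow_mm: the distal "
            f"slow segment ({slow_len:.2f} mm) cannot reach the compact node "
            f"({np.linalg.norm(node - crest_end):.2f} mm away from the crest end)"
        )
    crest_pts, crest_tan, crest_s = _arc_polyline(sn, crest_end, crest_len, +1.0)
    slow_pts, slow_tan, slow_s = _arc_polyline(crest_end, node, slow_len, -1.0)
    fast_pts, fast_tan, fast_s = _arc_polyline(sn, node, spec.path_length_fast_mm, +1.0)
    ann_pts, ann_tan, ann_s = _arc_polyline(sn, node, spec.annulus_length_mm, -1.0)
    avca_end = node + np.array([0.3, -2.0])
    avca_pts, avca_tan, avca_s = _arc_polyline(node, avca_end,
                                               float(np.linalg.norm(avca_end - node)), +1.0)

    # --- grid extents -----------------------------------------------------
    margin = 1.0 + w
    all_pts = np.vstack([crest_pts, slow_pts, fast_pts, ann_pts, avca_pts])
    lo = all_pts.min(axis=0) - margin - 5.0  # room for pads/patch on the left
    hi = all_pts.max(axis=0) + margin
    origin = np.array([lo[0], lo[1]])
    nx = int(math.ceil((hi[0] - lo[0]) / h)) + 1
    ny = int(math.ceil((hi[1] - lo[1]) / h)) + 1
    nz = max(1, int(round(spec.sheet_thickness_mm / h)))

    xs = origin[0] + np.arange(nx) * h
    ys = origin[1] + np.arange(ny) * h
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel()], axis=1)

    lab2d = np.zeros((nx, ny), dtype=np.int16)
    tan2d = np.zeros((nx, ny, 2))
    coh2d = np.zeros((nx, ny))

    def paint(pts, tans, widths, code, only_empty=False, coherence=1.0):
        tree = cKDTree(pts)
        dist, idx = tree.query(centers, k=1)
        dist = dist.reshape(nx, ny)
        idx = idx.reshape(nx, ny)
        wmap = np.asarray(widths)[idx] if np.ndim(widths) else float(widths)
        sel = dist <= (wmap / 2.0)
        if only_empty:
            sel &= lab2d == 0
        lab2d[sel] = code
        tan2d[sel] = np.asarray(tans)[idx[sel]]
        coh2d[sel] = coherence

    # the crest take-off narrows to a transitional isthmus just outside the
    # SN blob, then opens abruptly to the full crest width
    isthmus_end = spec.sn_radius_mm + spec.slow_isthmus_length_mm
    crest_widths = np.where(crest_s < isthmus_end,
                            spec.slow_isthmus_width_mm,
                            spec.crest_width_factor * w)
    paint(ann_pts, ann_tan, w, ldict.code("valve_annulus"))
    paint(fast_pts, fast_tan, w, ldict.code("fast_pathway_septal_bundle"))
    paint(crest_pts, crest_tan, crest_widths, ldict.code("terminal_crest"))
    paint(slow_pts, slow_tan, spec.slow_width_factor * w, ldict.code("slow_pathway"))
    paint(avca_pts, avca_tan, 0.8 * w, ldict.code("AVCA"), only_empty=True, coherence=0.8)

    # block zone: a slab between the sinus node and the septal side
    bz_x0, bz_x1 = sn[0] + spec.sn_radius_mm * 0.8, sn[0] + spec.sn_radius_mm * 0.8 + spec.block_zone_extent_mm
    bz_y0, bz_y1 = sn[1] - 0.8, sn[1] + 1.2
    bz = (gx >= bz_x0) & (gx <= bz_x1) & (gy >= bz_y0) & (gy <= bz_y1) & (lab2d == 0)
    lab2d[bz] = ldict.code("block_zone")
    coh2d[bz] = 0.6

    # working-myocardium patch (appendage stand-in) attached left of the SN
    ra_x0, ra_x1 = sn[0] - 4.2, sn[0] - spec.sn_radius_mm * 0.6
    ra_y0, ra_y1 = sn[1] - 1.2, sn[1] + 1.8
    ra = (gx >= ra_x0) & (gx <= ra_x1) & (gy >= ra_y0) & (gy <= ra_y1) & (lab2d == 0)
    lab2d[ra] = ldict.code("working_myocardium_RA")
    tan2d[ra] = (1.0, 0.0)
    coh2d[ra] = 0.6

    # inert pads for attenuation realism (far from active tissue)
    fat = (gx >= origin[0] + 0.5) & (gx <= origin[0] + 3.0) & \
          (gy >= hi[1] - 3.0) & (gy <= hi[1] - 0.5) & (lab2d == 0)
    lab2d[fat] = ldict.code("fat")
    conn = (gx >= origin[0] + 0.5) & (gx <= origin[0] + 3.0) & \
           (gy >= hi[1] - 6.5) & (gy <= hi[1] - 4.0) & (lab2d == 0)
    lab2d[conn] = ldict.code("connective_tissue")

    # nodal blobs overwrite bundle ends
    sn_blob = (gx - sn[0]) ** 2 + (gy - sn[1]) ** 2 <= spec.sn_radius_mm ** 2
    nd_blob = (gx - node[0]) ** 2 + (gy - node[1]) ** 2 <= spec.node_radius_mm ** 2
    lab2d[sn_blob] = ldict.code("sinus_node")
    lab2d[nd_blob] = ldict.code("compact_AV_node")
    coh2d[sn_blob] = 0.6
    coh2d[nd_blob] = 0.6

    # orientation for voxels painted without a tangent: nearest centerline
    all_tan = np.vstack([crest_tan, slow_tan, fast_tan, ann_tan, avca_tan])
    tree_all = cKDTree(all_pts)
    need = (lab2d > 0) & (np.linalg.norm(tan2d, axis=-1) < 1e-9)
    if need.any():
        _, idx = tree_all.query(np.stack([gx[need], gy[need]], axis=1), k=1)
        tan2d[need] = all_tan[idx]

    # --- extrude to 3D ----------------------------------------------------
    labels3 = np.repeat(lab2d[:, :, None], nz, axis=2).astype(np.int16)
    vec3 = np.zeros((nx, ny, nz, 3))
    vec3[..., 0] = tan2d[:, :, None, 0]
    vec3[..., 1] = tan2d[:, :, None, 1]
    norms = np.linalg.norm(vec3, axis=-1, keepdims=True)
    active3 = labels3 > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vec3 = np.where(norms > 1e-12, vec3 / norms, 0.0)
    vec3[~active3] = 0.0
    coh3 = np.repeat(coh2d[:, :, None], nz, axis=2)
    coh3[~active3] = 0.0

    zmid = (nz - 1) // 2

    def to_index(p):
        return (int(round((p[0] - origin[0]) / h)), int(round((p[1] - origin[1]) / h)), zmid)

    routes = {
        "slow": {
            "labels": ["terminal_crest", "slow_pathway"],
            "points": np.vstack([crest_pts, slow_pts]),
            "tangents": np.vstack([crest_tan, slow_tan]),
            "arclength": np.concatenate([crest_s, crest_len + slow_s]),
            "length_mm": spec.path_length_slow_mm,
        },
        "fast": {
            "labels": ["fast_pathway_septal_bundle"],
            "points": fast_pts,
            "tangents": fast_tan,
            "arclength": fast_s,
            "length_mm": spec.path_length_fast_mm,
        },
        "annulus": {
            "labels": ["valve_annulus"],
            "points": ann_pts,
            "tangents": ann_tan,
            "arclength": ann_s,
            "length_mm": spec.annulus_length_mm,
        },
    }

    meta = {
        "origin_mm": (float(origin[0]), float(origin[1]), 0.0),
        "sn_index": to_index(sn),
        "node_index": to_index(node),
        "label_dictionary": ldict.to_json_dict(),
    }
    labels_vol = LabelVolume(labels3, spacing_mm=h, meta=meta)
    orient = OrientationField(vec3, coh3, spacing_mm=h, meta={"source": "avsd_geometry"})
    geom = AVSDGeometry(labels_vol, orient, ldict, spec, routes,
                        (float(origin[0]), float(origin[1]), 0.0))
    _check_route_connectivity(geom)
    return geom


def _check_route_connectivity(geom: AVSDGeometry) -> None:
    """Every route must connect SN to the compact node after rasterization."""
    lab = geom.labels.data
    ldict = geom.dictionary
    sn_idx = geom.labels.meta["sn_index"]
    nd_idx = geom.labels.meta["node_index"]
    struct = np.ones((3, 3, 3), bool)
    for name, route in geom.routes.items():
        codes = {ldict.code(l) for l in route["labels"]}
        codes |= {ldict.code("sinus_node"), ldict.code("compact_AV_node")}
        mask = np.isin(lab, list(codes))
        comp, _ = ndimage.label(mask, structure=struct)
        if comp[sn_idx] == 0 or comp[sn_idx] != comp[nd_idx]:
            raise ValueError(
                f"route {name!r} is not conduction-wise connected between the "
                "sinus node and the compact node after rasterization"
            )


# ---------------------------------------------------------------------------
# Attenuation volume
# ---------------------------------------------------------------------------

# Iodine contrast gives fat > working myocardium > nodal tissue > connective
# tissue in decreasing voxel value.  Values are arbitrary intensity units.
DEFAULT_CONTRAST = {
    "background": 0.05,
    "working_myocardium_RA": 0.70,
    "sinus_node": 0.45,
    "terminal_crest": 0.68,
    "bachmann_bundle": 0.68,
    "slow_pathway": 0.68,
    "fast_pathway_septal_bundle": 0.68,
    "valve_annulus": 0.68,
    "compact_AV_node": 0.45,
    "AVCA": 0.45,
    "block_zone": 0.66,
    "fat": 0.95,
    "connective_tissue": 0.25,
    "patch_inert": 0.30,
}


def make_attenuation_volume(
    labels: LabelVolume,
    contrast_map: Mapping[str, float] | Mapping[int, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dictionary: LabelDictionary | None = None,
) -> ImageVolume:
    """Render a label volume as a virtual contrast-enhanced CT intensity volume.

    ``contrast_map`` maps label names (or codes) to mean intensity; the
    default reproduces the tissue-contrast ordering fat > working myocardium
    > nodal tissue > connective tissue.  Gaussian noise of standard deviation
    ``noise_sd`` (intensity units, range ~1) is added deterministically for a
    fixed seed.
    """
    ldict = dictionary or default_label_dictionary()
    cmap = contrast_map if contrast_map is not None else DEFAULT_CONTRAST
    by_code: dict[int, float] = {}
    for key, val in cmap.items():
        code = ldict.code(key) if isinstance(key, str) else int(key)
        by_code[code] = float(val)

    present = labels.labels_present()
    missing = [int(c) for c in present if int(c) not in by_code]
    if missing:
        names = [ldict.code_to_name.get(c, f"<code {c}>") for c in missing]
        raise ValueError(f"contrast_map is missing labels: {names} (codes {missing})")

    lut_size = int(present.max()) + 1
    lut = np.zeros(lut_size)
    for code, val in by_code.items():
        if code < lut_size:
            lut[code] = val
    out = lut[labels.data]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + noise_sd * rng.standard_normal(out.shape)
    return ImageVolume(out, spacing_mm=labels.spacing_mm,
                       meta={"rendered_from_labels": True, "seed": seed})
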