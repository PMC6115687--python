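"""Simulation-ready tissue models.

Converts a (possibly downsampled) label volume plus an orientation field
into the structures the monodomain solver consumes: an active-node mask,
an electrophysiological class per node (RA working myocardium, CT
conduction-bundle type, RA_block reduced-excitability, or inert), and a
per-node anisotropic diffusion tensor

    D = d_t I + (d_l - d_t) f f^T

whose along-fiber : cross-fiber eigenvalue ratio is d_l/d_t (8:1 by
default).  Inert regions (fat, connective tissue, surgical patch,
background) carry no state and act as no-flux holes; boundaries are
zero-flux throughout, which matches an excised-tissue preparation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from . import cells
from .phantoms import LabelDictionary, default_label_dictionary
from .volumes import LabelVolume, OrientationField

__all__ = [
    "CELL_CLASS_NAMES",
    "CellClass",
    "DiffusionField",
    "TissueModel",
    "assign_cell_classes",
    "virtual_suture",
    "build_diffusion_field",
    "build_tissue_model",
    "strand_model",
    "sheet_model",
]

# class ids used on grids and node arrays; inert nodes are excluded from the
# solver entirely
CELL_CLASS_NAMES = ("RA", "CT", "RA_block", "inert")
_CLASS_ID = {name: i for i, name in enumerate(CELL_CLASS_NAMES)}


@dataclass(frozen=True)
class CellClass:
    """An electrophysiological class and its ionic parameter set."""

    name: str
    params: cells.CellParams | None  # None for inert

    @staticmethod
    def table(model_id: str = "atrial_detailed") -> tuple["CellClass", ...]:
        ra = cells.make_cell_params("RA", model_id)
        ct = cells.make_cell_params("CT", model_id)
        if model_id == "atrial_detailed":
            blk = cells.apply_block_scaling(cells.make_cell_params("RA", model_id))
        else:
            blk = ra  # the fallback model has no Na/Ca conductances to scale
        return (CellClass("RA", ra), CellClass("CT", ct),
                CellClass("RA_block", blk), CellClass("inert", None))


def assign_cell_classes(
    labels: LabelVolume,
    dictionary: LabelDictionary | None = None,
    block_zone_enabled: bool = True,
) -> np.ndarray:
    """Total, deterministic label -> class map as an int8 grid.

    Conduction-system and bundle labels map to CT, working myocardium to
    RA, the block zone to RA_block (or plain RA when disabled), and
    non-tissue labels (background, fat, connective tissue, patch) to inert.
    Unknown labels raise, listing the offending codes.
    """
    ldict = dictionary or default_label_dictionary()
    present = labels.labels_present()
    known = set(ldict.code_to_name)
    unknown = [int(c) for c in present if int(c) not in known]
    if unknown:
        raise ValueError(f"unknown labels in volume: {unknown}")
    lut = np.full(int(present.max()) + 1, _CLASS_ID["inert"], dtype=np.int8)
    for code, name in ldict.code_to_name.items():
        if code > present.max():
            continue
        cls = ldict.ep_class(name)
        if cls == "RA_block" and not block_zone_enabled:
            cls = "RA"
        lut[code] = _CLASS_ID[cls]
    return lut[labels.data]


def virtual_suture(labels: LabelVolume, border_mask: np.ndarray) -> LabelVolume:
    """Assign working-myocardium electrophysiology to dissected borders.

    ``border_mask`` voxels must be background (the mask is disjoint from
    existing tissue; suturing never relabels tissue voxels).  Returns a new
    label volume with those voxels set to ``working_myocardium_RA``.
    """
    border_mask = np.asarray(border_mask, bool)
    if border_mask.shape != labels.shape:
        raise ValueError("border_mask must share the label grid")
    overlap = border_mask & (labels.data != 0)
    if overlap.any():
        raise ValueError(f"border_mask overlaps {int(overlap.sum())} tissue voxels; "
                         "virtual suturing may only fill background")
    out = labels.data.copy()
    out[border_mask] = default_label_dictionary().code("working_myocardium_RA")
    return LabelVolume(out, labels.spacing_mm, dict(labels.meta))


@dataclass
class DiffusionField:
    """Per-voxel symmetric diffusion tensor, 6 components (xx, yy, zz, xy,
    xz, yz) in mm^2/ms; zero on inert voxels."""

    d6: np.ndarray  # (nx, ny, nz, 6)
    d_l: float
    d_t: float
    spacing_mm: float

    @property
    def ratio(self) -> float:
        return self.d_l / self.d_t


def build_diffusion_field(
    class_grid: np.ndarray,
    orientation: OrientationField,
    d_l: float,
    ratio: float = 8.0,
) -> DiffusionField:
    """D = d_t I + (d_l - d_t) f f^T on non-inert voxels, zero elsewhere."""
    if not d_l > 0:
        raise ValueError("d_l must be positive")
    if not ratio >= 1:
        raise ValueError("anisotropy ratio must be >= 1")
    d_t = d_l / ratio
    f = orientation.vectors
    active = class_grid != _CLASS_ID["inert"]
    d6 = np.zeros(class_grid.shape + (6,))
    dl_minus_dt = d_l - d_t
    d6[..., 0] = d_t + dl_minus_dt * f[..., 0] ** 2
    d6[..., 1] = d_t + dl_minus_dt * f[..., 1] ** 2
    d6[..., 2] = d_t + dl_minus_dt * f[..., 2] ** 2
    d6[..., 3] = dl_minus_dt * f[..., 0] * f[..., 1]
    d6[..., 4] = dl_minus_dt * f[..., 0] * f[..., 2]
    d6[..., 5] = dl_minus_dt * f[..., 1] * f[..., 2]
    d6[~active] = 0.0
    return DiffusionField(d6, d_l, d_t, orientation.spacing_mm)


@dataclass
class TissueModel:
    """Flattened active-node view of the tissue, ready for the solver."""

    spacing_mm: float
    mask: np.ndarray             # (nx,ny,nz) bool, active nodes
    idx_of: np.ndarray           # (nx,ny,nz) int64, -1 for inert
    coords: np.ndarray           # (n,3) voxel indices of active nodes
    node_class: np.ndarray       # (n,) int8 into CELL_CLASS_NAMES
    node_label: np.ndarray       # (n,) original label codes
    fibers: np.ndarray           # (n,3) unit fiber per node
    d6: np.ndarray               # (n,6) diffusion tensor per node
    d_l: float
    ratio: float
    model_id: str = "atrial_detailed"
    meta: dict[str, Any] = field(default_factory=dict)
    _lap: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return int(self.coords.shape[0])

    def nodes_with_label(self, code: int) -> np.ndarray:
        return np.flatnonzero(self.node_label == code)

    def scale_rows(self) -> np.ndarray:
        """(3, 7) conductance multipliers for classes RA, CT, RA_block."""
        table = CellClass.table(self.model_id)
        return np.stack([c.params.scale_row() for c in table[:3]])

    def positions_mm(self) -> np.ndarray:
        origin = np.asarray(self.meta.get("origin_mm", (0.0, 0.0, 0.0)))
        return origin[None, :] + self.coords * self.spacing_mm

    def max_trace(self) -> float:
        return float(self.d6[:, :3].sum(axis=1).max()) if self.n_nodes else 0.0

    def laplacian(self) -> sparse.csr_matrix:
        if self._lap is None:
            self._lap = _assemble_laplacian(self.idx_of, self.d6, self.spacing_mm)
        return self._lap

    def with_d_l(self, d_l: float) -> "TissueModel":
        """Rescale the diffusion magnitude (fixed anisotropy ratio)."""
        factor = d_l / self.d_l
        out = TissueModel(self.spacing_mm, self.mask, self.idx_of, self.coords,
                          self.node_class, self.node_label, self.fibers,
                          self.d6 * factor, d_l, self.ratio, self.model_id,
                          dict(self.meta))
        if self._lap is not None:
            out._lap = self._lap * factor
        return out

    def class_counts(self) -> pd.DataFrame:
        names = [CELL_CLASS_NAMES[c] for c in self.node_class]
        return pd.Series(names).value_counts().rename_axis("cell_class") \
            .reset_index(name="n_nodes")

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["spacing_mm"] = self.spacing_mm
            fh.attrs["d_l"] = self.d_l
            fh.attrs["ratio"] = self.ratio
            fh.attrs["model_id"] = self.model_id
            for key in ("mask", "idx_of", "coords", "node_class",
                        "node_label", "fibers", "d6"):
                fh.create_dataset(key, data=getattr(self, key))
            if "origin_mm" in self.meta:
                fh.attrs["origin_mm"] = self.meta["origin_mm"]

    @staticmethod
    def load(path) -> "TissueModel":
        with h5py.File(path, "r") as fh:
            meta = {}
            if "origin_mm" in fh.attrs:
                meta["origin_mm"] = tuple(fh.attrs["origin_mm"])
            return TissueModel(
                float(fh.attrs["spacing_mm"]), fh["mask"][...].astype(bool),
                fh["idx_of"][...], fh["coords"][...],
                fh["node_class"][...], fh["node_label"][...],
                fh["fibers"][...], fh["d6"][...],
                float(fh.attrs["d_l"]), float(fh.attrs["ratio"]),
                str(fh.attrs["model_id"]), meta)


def build_tissue_model(
    labels: LabelVolume,
    orientation: OrientationField,
    d_l: float,
    ratio: float = 8.0,
    dictionary: LabelDictionary | None = None,
    block_zone_enabled: bool = True,
    model_id: str = "atrial_detailed",
) -> TissueModel:
    """Assemble the full simulation-ready model from labels + orientation."""
    if labels.shape != orientation.shape:
        raise ValueError("labels and orientation must share a grid")
    if abs(labels.spacing_mm - orientation.spacing_mm) > 1e-9:
        raise ValueError("labels and orientation must share the voxel spacing")
    class_grid = assign_cell_classes(labels, dictionary, block_zone_enabled)
    active = class_grid != _CLASS_ID["inert"]
    norms = np.linalg.norm(orientation.vectors, axis=-1)
    missing = active & (norms < 1e-9)
    if missing.any():
        raise ValueError(f"{int(missing.sum())} active voxels lack an "
                         "orientation vector; every active node needs a unit f")
    diff = build_diffusion_field(class_grid, orientation, d_l, ratio)

    idx_of = np.full(labels.shape, -1, dtype=np.int64)
    coords = np.argwhere(active)
    idx_of[active] = np.arange(coords.shape[0])
    meta = {}
    if "origin_mm" in labels.meta:
        meta["origin_mm"] = labels.meta["origin_mm"]
    return TissueModel(
        spacing_mm=labels.spacing_mm, mask=active, idx_of=idx_of, coords=coords,
        node_class=class_grid[active].astype(np.int8),
        node_label=np.asarray(labels.data)[active].astype(np.int64),
        fibers=orientation.vectors[active],
        d6=diff.d6[active], d_l=d_l, ratio=ratio, model_id=model_id, meta=meta)


# off-diagonal component column for an axis pair
_CROSS_COL = {(0, 1): 3, (1, 0): 3, (0, 2): 4, (2, 0): 4, (1, 2): 5, (2, 1): 5}


def _neighbor_table(idx_of: np.ndarray) -> np.ndarray:
    """(n, 3, 2) node index of the -/+ neighbor along each axis (-1 if none)."""
    n = int(idx_of.max()) + 1
    nbr = np.full((n, 3, 2), -1, dtype=np.int64)
    for a in range(3):
        sl_c = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_c[a] = slice(0, -1)
        sl_p[a] = slice(1, None)
        here = idx_of[tuple(sl_c)].ravel()
        there = idx_of[tuple(sl_p)].ravel()
        ok = (here >= 0) & (there >= 0)
        nbr[here[ok], a, 1] = there[ok]
        nbr[there[ok], a, 0] = here[ok]
    return nbr


def _assemble_laplacian(idx_of: np.ndarray, d6: np.ndarray, h: float) -> sparse.csr_matrix:
    """Conservative face-flux discretization of div(D grad V) on the active
    voxel graph.

    Normal fluxes use face-averaged tensors; cross-derivative terms use
    averaged (one-sided at boundaries) tangential differences.  Fluxes
    across inert or domain boundaries are zero, so constant fields are
    exact equilibria (zero row sums) and total flux is conserved — the
    natural zero-flux boundary condition of an excised preparation.
    """
    n = int(idx_of.max()) + 1
    nbr = _neighbor_table(idx_of)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(np.asarray(r, np.int64))
        cols.append(np.asarray(c, np.int64))
        vals.append(np.asarray(v, float))

    # per-node tangential-gradient stencils g_b(c) = s*(V[gp] - V[gm])
    gp = np.empty((n, 3), np.int64)
    gm = np.empty((n, 3), np.int64)
    gs = np.empty((n, 3))
    node_ids = np.arange(n, dtype=np.int64)
    for b in range(3):
        m_, p_ = nbr[:, b, 0], nbr[:, b, 1]
        both = (m_ >= 0) & (p_ >= 0)
        one = (m_ >= 0) ^ (p_ >= 0)
        gp[:, b] = np.where(p_ >= 0, p_, node_ids)
        gm[:, b] = np.where(m_ >= 0, m_, node_ids)
        gs[:, b] = np.where(both, 0.5 / h, np.where(one, 1.0 / h, 0.0))

    for a in range(3):
        i = node_ids[nbr[:, a, 1] >= 0]
        if i.size == 0:
            continue
        j = nbr[i, a, 1]
        daa = 0.5 * (d6[i, a] + d6[j, a])
        w = daa / (h * h)
        add(i, j, w); add(i, i, -w); add(j, i, w); add(j, j, -w)
        for b in range(3):
            if b == a:
                continue
            dab = 0.5 * (d6[i, _CROSS_COL[(a, b)]] + d6[j, _CROSS_COL[(a, b)]])
            for c in (i, j):
                coef = dab * 0.5 * gs[c, b] / h
                add(i, gp[c, b], coef); add(i, gm[c, b], -coef)
                add(j, gp[c, b], -coef); add(j, gm[c, b], coef)

    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n))
    return mat.tocsr()


# ---------------------------------------------------------------------------
# Small analytic geometries (strands and sheets) used for calibration and
# convergence checks
# ---------------------------------------------------------------------------


def _direct_model(mask: np.ndarray, fibers_grid: np.ndarray, h: float,
                  d_l: float, ratio: float, cell_class: str,
                  model_id: str) -> TissueModel:
    class_grid = np.where(mask, np.int8(_CLASS_ID[cell_class]),
                          np.int8(_CLASS_ID["inert"]))
    idx_of = np.full(mask.shape, -1, dtype=np.int64)
    coords = np.argwhere(mask)
    idx_of[mask] = np.arange(coords.shape[0])
    orient = OrientationField(np.where(mask[..., None], fibers_grid, 0.0),
                              np.where(mask, 1.0, 0.0), h)
    diff = build_diffusion_field(class_grid, orient, d_l, ratio)
    code = default_label_dictionary().code(
        "working_myocardium_RA" if cell_class == "RA" else "terminal_crest")
    return TissueModel(h, mask, idx_of, coords,
                       class_grid[mask].astype(np.int8),
                       np.full(coords.shape[0], code, np.int64),
                       orient.vectors[mask], diff.d6[mask], d_l, ratio, model_id)


def strand_model(length_mm: float = 20.0, h: float = 0.15, d_l: float = 0.1,
                 ratio: float = 8.0, cell_class: str = "RA",
                 model_id: str = "atrial_detailed") -> TissueModel:
    """A fiber-aligned 1D strand (1x1 voxel cross-section) along x."""
    nx = int(round(length_mm / h)) + 1
    mask = np.ones((nx, 1, 1), bool)
    fib = np.zeros((nx, 1, 1, 3))
    fib[..., 0] = 1.0
    return _direct_model(mask, fib, h, d_l, ratio, cell_class, model_id)


def sheet_model(nx: int, ny: int, h: float = 0.15, d_l: float = 0.1,
                ratio: float = 1.0, fiber=(1.0, 0.0, 0.0),
                cell_class: str = "RA", mask: np.ndarray | None = None,
                model_id: str = "atrial_detailed") -> TissueModel:
    """A single-voxel-thick 2D sheet with a uniform fiber direction."""
    if mask is None:
        mask = np.ones((nx, ny, 1), bool)
    fib = np.zeros(mask.shape + (3,))
    f = np.asarray(fiber, float)
    fib[...] = f / np.linalg.norm(f)
    return _direct_model(mask, fib, h, d_l, ratio, cell_class, model_id)
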