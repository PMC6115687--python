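"""Myocyte-orientation extraction by eigen-analysis of the 3D structure tensor.

The structure tensor ``J = G_w * (∇I ∇Iᵀ)`` (Gaussian-derivative gradients,
Gaussian window smoothing) summarises local intensity variation.  Intensity
varies least *along* a myocyte chain, so the fiber direction is the
eigenvector of the smallest eigenvalue of J.  Orientation is axial data
(f and -f are equivalent); a fixed hemisphere convention makes the output
reproducible, and axial-safe averaging (mean of outer products, then the
dominant eigenvector) is used for downsampling.
"""
from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, LabelVolume, OrientationField

__all__ = [
    "StructureTensorParams",
    "TensorField",
    "compute_structure_tensor",
    "extract_orientation",
    "downsample_scalar",
    "downsample_labels",
    "downsample_orientation",
    "angular_error",
]

log = logging.getLogger(__name__)

# component order of the 6 unique tensor entries
_COMP = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class StructureTensorParams:
    """Scales of the structure-tensor computation, in micrometres.

    ``sigma_gradient_um`` is the derivative (inner) scale and
    ``sigma_window_um`` the tensor-smoothing (outer) scale; the window must
    be at least as large as the derivative scale so that the tensor averages
    over several texture periods.
    """

    sigma_gradient_um: float
    sigma_window_um: float
    downsample_target_mm: float = 0.15

    def __post_init__(self) -> None:
        if not self.sigma_gradient_um > 0 or not self.sigma_window_um > 0:
            raise ValueError("sigma scales must be positive")
        if self.sigma_window_um < self.sigma_gradient_um:
            raise ValueError("sigma_window_um must be >= sigma_gradient_um")
        if not self.downsample_target_mm > 0:
            raise ValueError("downsample_target_mm must be positive")

    @classmethod
    def default_for(cls, vol: ImageVolume) -> "StructureTensorParams":
        """1-voxel derivative scale, 4-voxel window at native resolution."""
        vox_um = vol.spacing_mm * 1000.0
        return cls(sigma_gradient_um=vox_um, sigma_window_um=4.0 * vox_um)


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensor (6 unique components, order
    xx, yy, zz, xy, xz, yz), sharing grid metadata with its source volume."""

    components: np.ndarray  # (nx, ny, nz, 6)
    spacing_mm: float

    def as_matrices(self) -> np.ndarray:
        c = self.components
        m = np.empty(c.shape[:3] + (3, 3))
        for k, (i, j) in enumerate(_COMP):
            m[..., i, j] = c[..., k]
            m[..., j, i] = c[..., k]
        return m

    def min_eigenvalue(self) -> float:
        w = np.linalg.eigvalsh(self.as_matrices())
        return float(w.min())


def compute_structure_tensor(
    vol: ImageVolume, params: StructureTensorParams
) -> TensorField:
    """Smoothed outer product of Gaussian-derivative gradients.

    The tensor scales assume isotropic voxels; volumes carrying an
    ``anisotropic`` metadata flag must be resampled first.
    """
    if vol.meta.get("anisotropic", False):
        raise ValueError(
            "volume has anisotropic voxels; resample to an isotropic grid "
            "before computing the structure tensor"
        )
    if min(vol.shape) < 8:
        raise ValueError("volume must be at least 8 voxels per axis")
    vox_um = vol.spacing_mm * 1000.0
    sg = params.sigma_gradient_um / vox_um
    sw = params.sigma_window_um / vox_um

    data = np.asarray(vol.data, float)
    grads = [ndimage.gaussian_filter1d(data, sg, axis=a, order=1) for a in range(3)]
    comp = np.empty(vol.shape + (6,))
    for k, (i, j) in enumerate(_COMP):
        comp[..., k] = ndimage.gaussian_filter(grads[i] * grads[j], sw)
    return TensorField(comp, vol.spacing_mm)


def _hemisphere_sign(vec: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Axial sign convention: flip into z >= 0; ties broken by y, then x."""
    z, y, x = vec[..., 2], vec[..., 1], vec[..., 0]
    s = np.where(np.abs(z) > tol, np.sign(z),
                 np.where(np.abs(y) > tol, np.sign(y),
                          np.where(np.abs(x) > tol, np.sign(x), 1.0)))
    return s


def extract_orientation(
    tf: TensorField, tissue_mask: np.ndarray | None = None
) -> OrientationField:
    """Fiber direction = eigenvector of the smallest structure-tensor
    eigenvalue; coherence = (λ2 - λ3) / (λ1 + λ2 + λ3 + ε) with eigenvalues
    sorted λ1 >= λ2 >= λ3.

    Near-degenerate smallest eigenvalues give coherence ≈ 0; the returned
    vector is still deterministic (LAPACK eigensolver plus the fixed
    hemisphere convention).  The count of such voxels is logged.
    """
    m = tf.as_matrices()
    w, v = np.linalg.eigh(m)  # ascending eigenvalues
    lam3, lam2, lam1 = w[..., 0], w[..., 1], w[..., 2]
    trace = lam1 + lam2 + lam3
    eps = 1e-12 * max(float(trace.max()), 1.0)
    coherence = (lam2 - lam3) / (trace + eps)
    f = v[..., :, 0]  # eigenvector of the smallest eigenvalue
    f = f * _hemisphere_sign(f)[..., None]

    degen = (lam2 - lam3) <= 1e-9 * (trace + eps)
    if degen.any():
        log.info("extract_orientation: %d voxels with near-degenerate smallest "
                 "eigenvalue (coherence ~ 0)", int(degen.sum()))

    if tissue_mask is not None:
        tissue_mask = np.asarray(tissue_mask, bool)
        f = np.where(tissue_mask[..., None], f, 0.0)
        coherence = np.where(tissue_mask, coherence, 0.0)
    return OrientationField(f, np.clip(coherence, 0.0, 1.0), tf.spacing_mm)


# ---------------------------------------------------------------------------
# Downsampling to modeling resolution
# ---------------------------------------------------------------------------


def _block_factor(spacing_mm: float, target_mm: float) -> tuple[int, bool]:
    if target_mm < spacing_mm - 1e-12:
        raise ValueError("target spacing must be >= source spacing")
    ratio = target_mm / spacing_mm
    f = int(round(ratio))
    integer = abs(ratio - f) < 1e-6 and f >= 1
    return max(f, 1), integer


def _crop_to_multiple(a: np.ndarray, f: int) -> np.ndarray:
    nx, ny, nz = (s - s % f for s in a.shape[:3])
    return a[:nx, :ny, :nz]


def _block_view(a: np.ndarray, f: int) -> np.ndarray:
    """(nx, ny, nz, ...) -> (bx, by, bz, f**3, ...)"""
    a = _crop_to_multiple(a, f)
    nx, ny, nz = a.shape[:3]
    extra = a.shape[3:]
    v = a.reshape(nx // f, f, ny // f, f, nz // f, f, *extra)
    v = np.moveaxis(v, (1, 3, 5), (3, 4, 5))
    return v.reshape(nx // f, ny // f, nz // f, f ** 3, *extra)


def downsample_scalar(vol: ImageVolume, target_mm: float) -> ImageVolume:
    """Block-mean downsampling; non-integer decimation factors fall back to
    spline resampling with an explicit warning."""
    f, integer = _block_factor(vol.spacing_mm, target_mm)
    if integer:
        if f == 1:
            return ImageVolume(vol.data.copy(), vol.spacing_mm, dict(vol.meta))
        out = _block_view(np.asarray(vol.data, float), f).mean(axis=3)
        return ImageVolume(out, vol.spacing_mm * f, dict(vol.meta))
    log.warning("non-integer decimation factor %.3f: resampling with zoom",
                target_mm / vol.spacing_mm)
    zoom = vol.spacing_mm / target_mm
    out = ndimage.zoom(np.asarray(vol.data, float), zoom, order=1)
    return ImageVolume(out, target_mm, dict(vol.meta))


def downsample_labels(labels: LabelVolume, target_mm: float) -> LabelVolume:
    """Block majority vote; background loses ties to tissue."""
    f, integer = _block_factor(labels.spacing_mm, target_mm)
    if not integer:
        log.warning("non-integer decimation factor %.3f: resampling labels with "
                    "nearest-neighbour zoom", target_mm / labels.spacing_mm)
        zoom = labels.spacing_mm / target_mm
        out = ndimage.zoom(labels.data, zoom, order=0)
        return LabelVolume(out, target_mm, dict(labels.meta))
    if f == 1:
        return LabelVolume(labels.data.copy(), labels.spacing_mm, dict(labels.meta))
    blocks = _block_view(labels.data, f)  # (bx,by,bz,f^3) int
    lmax = int(labels.data.max())
    counts = np.empty(blocks.shape[:3] + (lmax + 1,), dtype=np.int32)
    for l in range(lmax + 1):
        counts[..., l] = (blocks == l).sum(axis=3)
    # background loses ties: subtract half a vote from label 0
    score = counts.astype(float)
    score[..., 0] -= 0.5
    out = np.argmax(score, axis=-1).astype(labels.data.dtype)
    return LabelVolume(out, labels.spacing_mm * f, dict(labels.meta))


def downsample_orientation(field: OrientationField, target_mm: float) -> OrientationField:
    """Axial-data-safe downsampling: average the per-voxel outer products
    f fᵀ over each block (zero vectors excluded), then re-extract the
    dominant eigenvector.  Antipodal vectors therefore reinforce rather than
    cancel."""
    f_dec, integer = _block_factor(field.spacing_mm, target_mm)
    if not integer:
        raise ValueError("orientation downsampling requires an integer "
                         "decimation factor; resample the source volume instead")
    if f_dec == 1:
        return OrientationField(field.vectors.copy(), field.coherence.copy(),
                                field.spacing_mm, dict(field.meta))
    vec = np.asarray(field.vectors, float)
    outer = vec[..., :, None] * vec[..., None, :]  # (nx,ny,nz,3,3)
    blocks = _block_view(outer, f_dec)  # (bx,by,bz,f^3,3,3)
    weight = _block_view(np.linalg.norm(vec, axis=-1) > 1e-12, f_dec)  # bool
    nsum = weight.sum(axis=3)
    mean_t = blocks.sum(axis=3) / np.maximum(nsum, 1)[..., None, None]
    w, v = np.linalg.eigh(mean_t)
    dom = v[..., :, 2]  # dominant eigenvector of the mean dyadic
    dom = dom * _hemisphere_sign(dom)[..., None]
    empty = nsum == 0
    dom[empty] = 0.0
    coh = _block_view(field.coherence, f_dec).sum(axis=3) / np.maximum(nsum, 1)
    coh[empty] = 0.0
    return OrientationField(dom, coh, field.spacing_mm * f_dec, dict(field.meta))


def angular_error(
    est: OrientationField | np.ndarray,
    truth: OrientationField | np.ndarray,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Axial angular error arccos(|est . truth|) in degrees.

    Returns median, mean and 95th percentile over ``mask`` (default: voxels
    where both fields carry a vector).
    """
    e = est.vectors if isinstance(est, OrientationField) else np.asarray(est)
    t = truth.vectors if isinstance(truth, OrientationField) else np.asarray(truth)
    if e.shape != t.shape:
        raise ValueError("fields must share a grid")
    ne = np.linalg.norm(e, axis=-1)
    nt = np.linalg.norm(t, axis=-1)
    valid = (ne > 1e-12) & (nt > 1e-12)
    if mask is not None:
        valid &= np.asarray(mask, bool)
    dots = np.abs(np.sum(e * t, axis=-1)) / np.maximum(ne * nt, 1e-300)
    ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))[valid]
    if ang.size == 0:
        raise ValueError("no voxels to compare")
    return {
        "median_deg": float(np.median(ang)),
        "mean_deg": float(np.mean(ang)),
        "p95_deg": float(np.percentile(ang, 95)),
        "n": int(ang.size),
    }
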