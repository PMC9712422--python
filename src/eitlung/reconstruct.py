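"""One-step linearized time-difference image reconstruction.

For each frame the element-space conductivity change is the Tikhonov/NOSER
regularized Gauss-Newton step

    x = (J^T J + lambda^2 R)^{-1} J^T (v - v_ref),

with R the identity or diag(J^T J) (NOSER prior).  The inverse operator is
factorized once and applied to every frame.  Element images are rasterized
onto a fixed 32x32 pixel grid over the bounding square of the domain by
area-weighted centroid binning, which conserves the area-weighted total
signal exactly.

Grid orientation (caudal view): anterior at the top row, the subject's left
on the viewer's right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import ContractError, EITLungValidationError
from .forward import VoltageFrame, VoltageFrameSeries
from .mesh import Mesh

__all__ = [
    "ImageSeries",
    "GRID_N",
    "Rasterizer",
    "ReconstructionOperator",
    "reconstruct_series",
    "select_hyperparameter",
]

log = logging.getLogger(__name__)

GRID_N = 32


@dataclass
class ImageSeries:
    """Reconstructed conductivity-change images on a fixed 32x32 grid.

    ``values`` is (n_frames, 32, 32); pixels outside ``inside_mask`` are
    exactly zero.  Row 0 is anterior, the last column is the subject's left.
    """

    values: np.ndarray
    inside_mask: np.ndarray
    fps: float
    times: np.ndarray
    element_values: np.ndarray | None = None  # (n_frames, E), pre-raster

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.inside_mask = np.asarray(self.inside_mask, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.inside_mask.shape:
            raise ContractError("image values and mask shapes are inconsistent")
        if np.any(self.values[:, ~self.inside_mask] != 0):
            raise ContractError("nonzero pixels outside the inside-body mask")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


class Rasterizer:
    """Exact area-overlap binning from mesh elements to the pixel grid.

    ``P[p, e]`` is the area of the intersection of triangle e with pixel p
    (computed by polygon clipping), so the pixel image of an element field is
    its area-weighted projection and the total signal sum over pixels equals
    the area-weighted sum over elements exactly.
    """

    def __init__(self, mesh: Mesh, grid_n: int = GRID_N):
        from shapely.geometry import Polygon, box

        self.grid_n = grid_n
        px = 2.0 / grid_n  # pixel edge; grid spans the bounding square [-1, 1]^2
        rows, cols, vals = [], [], []
        verts = mesh.nodes[mesh.elements]
        for e in range(mesh.n_elements):
            tri = Polygon(verts[e])
            xmin, ymin, xmax, ymax = tri.bounds
            c0 = max(0, int((xmin + 1.0) / px))
            c1 = min(grid_n - 1, int((xmax + 1.0) / px))
            r0 = max(0, int((1.0 - ymax) / px))
            r1 = min(grid_n - 1, int((1.0 - ymin) / px))
            for r in range(r0, r1 + 1):
                y_hi = 1.0 - r * px
                for c in range(c0, c1 + 1):
                    x_lo = -1.0 + c * px
                    a = tri.intersection(box(x_lo, y_hi - px, x_lo + px, y_hi)).area
                    if a > 0:
                        rows.append(r * grid_n + c)
                        cols.append(e)
                        vals.append(a)
        self.P = sp.csr_matrix(
            (vals, (rows, cols)), shape=(grid_n * grid_n, mesh.n_elements)
        )
        coverage = np.asarray(self.P.sum(axis=1)).ravel()
        self.inside_mask = (coverage > 0).reshape(grid_n, grid_n)

    def __call__(self, element_values: np.ndarray) -> np.ndarray:
        """Rasterize (n_frames, E) element values to (n_frames, 32, 32)."""
        x = np.atleast_2d(element_values)
        img = (self.P @ x.T).T
        return img.reshape(x.shape[0], self.grid_n, self.grid_n)


class ReconstructionOperator:
    """Factorized one-step difference-imaging operator for a fixed J."""

    def __init__(self, J: np.ndarray, lam: float, prior: str = "noser"):
        if lam <= 0:
            raise EITLungValidationError(f"regularization lambda must be > 0, got {lam}")
        if prior not in ("identity", "noser"):
            raise EITLungValidationError(f"unknown prior {prior!r}")
        self.lam = float(lam)
        self.prior = prior
        JtJ = J.T @ J
        if prior == "noser":
            d = np.diag(JtJ).copy()
            d[d <= 0] = d[d > 0].min()
            R = np.diag(d)
        else:
            R = np.eye(J.shape[1])
        self._cho = sla.cho_factor(JtJ + lam**2 * R)
        self._Jt = J.T
        self.n_channels, self.n_elements = J.shape

    def apply(self, dv: np.ndarray) -> np.ndarray:
        """Solve for element-space images; dv is (..., n_channels)."""
        dv = np.atleast_2d(dv)
        if dv.shape[-1] != self.n_channels:
            raise ContractError(
                f"difference data has {dv.shape[-1]} channels, J has {self.n_channels}"
            )
        return sla.cho_solve(self._cho, self._Jt @ dv.T).T


def reconstruct_series(
    J: np.ndarray,
    frames: VoltageFrameSeries,
    reference: VoltageFrame,
    lam: float,
    prior: str = "noser",
    mesh: Mesh | None = None,
    rasterizer: Rasterizer | None = None,
) -> ImageSeries:
    """Reconstruct a time-difference image series from voltage frames.

    Either ``mesh`` or a prebuilt ``rasterizer`` must be supplied to map
    element images onto the pixel grid.
    """
    if rasterizer is None:
        if mesh is None:
            raise ContractError("reconstruct_series needs a mesh or a rasterizer")
        rasterizer = Rasterizer(mesh)
    if J.shape[1] != rasterizer.P.shape[1]:
        raise ContractError("J columns do not match mesh elements")
    op = ReconstructionOperator(J, lam, prior)
    dv = frames.values - reference.values[None, :]
    x = op.apply(dv)
    imgs = rasterizer(x)
    return ImageSeries(imgs, rasterizer.inside_mask, frames.fps, frames.times, element_values=x)


def _noise_figure(s, ut_dv, lam):
    """Noise-to-signal amplification ratio of the regularized inverse.

    In the (prior-whitened) SVD basis J = U S V^T the operator applies the
    filter f_i = s_i / (s_i^2 + lam^2).  White measurement noise of unit RMS
    maps to image energy ||f||^2 / n_ch; the sample signal dv maps to
    ||f * U^T dv||.  The noise figure is their ratio normalized by the input
    noise-to-signal ratio, and decreases monotonically with lam.
    """
    f = s / (s**2 + lam**2)
    noise_gain = np.linalg.norm(f) / np.sqrt(s.size)
    sig_norm = np.linalg.norm(ut_dv)
    sig_gain = np.linalg.norm(f * ut_dv) / sig_norm
    return noise_gain / sig_gain


def select_hyperparameter(
    J: np.ndarray,
    sample_frames: VoltageFrameSeries | np.ndarray,
    target_noise_figure: float = 1.0,
    prior: str = "noser",
    reference: VoltageFrame | None = None,
) -> float:
    """Pick lambda so the image noise-figure matches ``target_noise_figure``.

    Deterministic bisection on log10(lambda) over [1e-6, 10] x s_max.  If the
    target cannot be bracketed, returns the documented default
    ``0.05 * s_max`` (s_max the largest prior-whitened singular value of J)
    with a logged warning.
    """
    vals = sample_frames.values if isinstance(sample_frames, VoltageFrameSeries) else np.atleast_2d(sample_frames)
    if vals.shape[0] < 1:
        raise EITLungValidationError("need at least one sample frame")
    if prior == "noser":
        d = np.sqrt(np.clip(np.einsum("ij,ij->j", J, J), 1e-300, None))
        Jw = J / d[None, :]
    else:
        Jw = J
    s = np.linalg.svd(Jw, compute_uv=False)
    U = np.linalg.svd(Jw, full_matrices=False)[0]
    ref = reference.values if reference is not None else vals.mean(axis=0)
    dv = vals - ref[None, :]
    # use the frame with the largest difference signal as the signal proxy
    proxy = dv[int(np.argmax(np.linalg.norm(dv, axis=1)))]
    if np.linalg.norm(proxy) == 0:
        proxy = vals[0]
    ut_dv = U.T @ proxy
    s_max = s.max()
    default = 0.05 * s_max
    lo, hi = np.log10(1e-6 * s_max), np.log10(10 * s_max)
    nf_lo = _noise_figure(s, ut_dv, 10**lo)
    nf_hi = _noise_figure(s, ut_dv, 10**hi)
    if not (nf_hi <= target_noise_figure <= nf_lo):
        log.warning(
            "noise figure target %.3g outside attainable range [%.3g, %.3g]; "
            "falling back to default lambda %.3g",
            target_noise_figure,
            nf_hi,
            nf_lo,
            default,
        )
        return default
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _noise_figure(s, ut_dv, 10**mid) > target_noise_figure:
            lo = mid
        else:
            hi = mid
    return float(10 ** (0.5 * (lo + hi)))
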