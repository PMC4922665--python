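"""Linear color-distortion correction learned by least squares.

The observed image X is assumed to arise from an unknown, channel-coupled
blur of the true image G. Rather than estimating and inverting a PSF, the
correction is learned directly: arrange X into a design matrix whose row i
is the full L x L x N_c neighborhood of pixel i, arrange G into an
S_i x N_c target matrix, and solve the (optionally ridge-penalized) least
squares problem

    C = argmin ||G - X C||^2 + ridge ||C||^2

so that restoration of any image under the same camera settings is the
single matrix product R = X C. One correction matrix serves an entire
experiment as long as the camera settings are fixed.

`ColorDistortionCorrector` packages the estimate as a scikit-learn style
transformer (fit on one or more distorted/clean pairs, transform any
image); the module-level functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion, remove_small_holes, remove_small_objects
from sklearn.base import BaseEstimator, TransformerMixin

from .io import as_image, as_mask

__all__ = [
    "DesignMatrix",
    "TargetMatrix",
    "CorrectionMatrix",
    "ChartLayout",
    "ColorDistortionCorrector",
    "build_design_matrix",
    "estimate_correction",
    "apply_correction",
    "estimate_ground_truth",
    "calibrate_from_chart",
    "render_chart",
]


@dataclass
class DesignMatrix:
    """Patch matrix: row i holds pixel i's L x L neighborhood, all channels.

    Columns are ordered channel-major: column c*L*L + dr*L + dc holds the
    value of channel c at row offset dr, column offset dc within the
    replicate-padded neighborhood (offsets counted from the top-left of
    the kernel window).
    """

    entries: np.ndarray  # (S_i, M)
    kernel_size: int
    channels: int
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {self.kernel_size}")
        M = self.kernel_size**2 * self.channels
        if self.entries.shape[1] != M:
            raise ValueError(
                f"design matrix has {self.entries.shape[1]} cols, expected M={M}"
            )


@dataclass
class TargetMatrix:
    """S_i x N_c arrangement of the (estimated) undistorted image."""

    entries: np.ndarray
    source_shape: tuple[int, int]

    @property
    def channels(self) -> int:
        return self.entries.shape[1]


@dataclass
class CorrectionMatrix:
    """The M x N_c correction operator C plus its fit metadata.

    ``kernel_size`` is None for solutions of generic (non-image) least
    squares systems; such matrices cannot be applied to images.
    """

    entries: np.ndarray  # (M, N_c)
    kernel_size: int | None
    channels: int
    ridge: float = 0.0
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        if self.kernel_size is None:
            return
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {self.kernel_size}")
        M = self.kernel_size**2 * self.channels
        if self.entries.shape != (M, self.channels):
            raise ValueError(
                f"correction matrix shape {self.entries.shape}, expected ({M}, {self.channels})"
            )

    def save(self, path) -> None:
        """Plain-text format: header `L N_c ridge`, then M rows of N_c values."""
        with open(path, "w") as fh:
            fh.write(f"{self.kernel_size} {self.channels} {self.ridge:.12e}\n")
            for row in self.entries:
                fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "CorrectionMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            L, nc, ridge = int(header[0]), int(header[1]), float(header[2])
            entries = np.loadtxt(fh, ndmin=2)
        return cls(entries=entries, kernel_size=L, channels=nc, ridge=ridge)


def build_design_matrix(img: np.ndarray, kernel_size: int) -> DesignMatrix:
    """Arrange an image into its S_i x M patch matrix (replicate padding).

    With L=1 this degenerates to the plain S_i x N_c pixel matrix.
    """
    a = as_image(img)
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError(f"kernel size must be odd and >= 1, got {kernel_size}")
    H, W, C = a.shape
    L = kernel_size
    h = L // 2
    padded = np.pad(a, ((h, h), (h, h), (0, 0)), mode="edge")
    # (H, W, L, L) windows per channel; column order channel-major, then
    # row offset, then column offset
    cols = np.empty((H * W, L * L * C))
    for c in range(C):
        win = np.lib.stride_tricks.sliding_window_view(padded[:, :, c], (L, L))
        cols[:, c * L * L : (c + 1) * L * L] = win.reshape(H * W, L * L)
    return DesignMatrix(entries=cols, kernel_size=L, channels=C, source_shape=(H, W))


def _as_xy(X, G) -> tuple[np.ndarray, np.ndarray]:
    Xe = X.entries if isinstance(X, DesignMatrix) else np.asarray(X, dtype=np.float64)
    Ge = G.entries if isinstance(G, TargetMatrix) else np.asarray(G, dtype=np.float64)
    if Xe.shape[0] != Ge.shape[0]:
        raise ValueError(
            f"design matrix has {Xe.shape[0]} rows, target has {Ge.shape[0]}"
        )
    return Xe, Ge


def estimate_correction(
    X: DesignMatrix | np.ndarray,
    G: TargetMatrix | np.ndarray,
    ridge: float | str = 0.0,
) -> CorrectionMatrix:
    """Solve min ||G - XC||^2 + ridge ||C||^2 for the correction matrix.

    ``ridge="auto"`` uses 1e-6 * trace(X'X) / M, a scale-aware default that
    stabilizes rank-deficient systems (e.g. images dominated by flat
    background) without noticeably biasing well-conditioned fits. With
    ridge 0 the solution is the minimum-norm pseudoinverse solution and a
    rank-deficient system raises an error advising a positive ridge.
    """
    Xe, Ge = _as_xy(X, G)
    S, M = Xe.shape
    XtX = Xe.T @ Xe
    if ridge == "auto":
        ridge_val = 1e-6 * np.trace(XtX) / M
    else:
        ridge_val = float(ridge)
        if ridge_val < 0:
            raise ValueError("ridge must be >= 0")
    if ridge_val == 0.0:
        C, _, rank, _ = np.linalg.lstsq(Xe, Ge, rcond=None)
        if rank < M:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (rank {rank} < {M}); "
                "pass a positive ridge to regularize the fit"
            )
    else:
        C = linalg.solve(
            XtX + ridge_val * np.eye(M), Xe.T @ Ge, assume_a="pos"
        )
    resid = float(np.sqrt(np.mean((Ge - Xe @ C) ** 2)))
    if isinstance(X, DesignMatrix):
        L, nc = X.kernel_size, X.channels
    else:
        nc = Ge.shape[1]
        L = int(round(np.sqrt(M / nc)))
        if L**2 * nc != M or L % 2 == 0:
            L = None  # generic system, not an image patch matrix
    return CorrectionMatrix(
        entries=C, kernel_size=L, channels=nc, ridge=ridge_val, fit_residual=resid
    )


def apply_correction(
    img: np.ndarray, C: CorrectionMatrix, clip: bool = True
) -> np.ndarray:
    """Restore an image: R = XC, reshaped to image dimensions."""
    a = as_image(img)
    if C.kernel_size is None:
        raise ValueError("correction matrix has no kernel structure")
    if a.shape[2] != C.channels:
        raise ValueError(
            f"image has {a.shape[2]} channels, correction expects {C.channels}"
        )
    X = build_design_matrix(a, C.kernel_size)
    R = (X.entries @ C.entries).reshape(a.shape)
    return np.clip(R, 0.0, 1.0) if clip else R


class ColorDistortionCorrector(TransformerMixin, BaseEstimator):
    """Learned linear correction of cross-channel color distortion.

    Fit on one or more (distorted, clean) image pairs acquired under the
    camera settings to be corrected; transform then restores any image
    taken under the same settings via R = XC.

    Parameters
    ----------
    kernel_size : odd int, default 5
        Spatial support L of the correction; M = L^2 * N_c features per
        pixel. 5 comfortably covers few-pixel chromatic fringes.
    ridge : float or "auto", default "auto"
        Ridge penalty; "auto" scales with trace(X'X)/M.
    subsample : float in (0, 1] or None, default None
        Optional seeded uniform fraction of design-matrix rows used for
        fitting; trades speed for estimator variance on large images.
    random_state : int or None
        Seed for row subsampling.

    Attributes
    ----------
    correction_ : CorrectionMatrix
        The fitted M x N_c operator.
    fit_residual_ : float
        Root-mean-square training residual of G - XC.
    """

    def __init__(
        self,
        kernel_size: int = 5,
        ridge: float | str = "auto",
        subsample: float | None = None,
        random_state: int | None = None,
    ):
        self.kernel_size = kernel_size
        self.ridge = ridge
        self.subsample = subsample
        self.random_state = random_state

    @staticmethod
    def _as_list(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim in (2, 3):
            return [X]
        return list(X)

    def fit(self, X, y):
        """Estimate the correction matrix from distorted/clean pairs.

        Parameters
        ----------
        X : (H, W, C) array or list of arrays
            Distorted image(s).
        y : matching clean/target image(s), or TargetMatrix
        """
        xs = self._as_list(X)
        if isinstance(y, TargetMatrix):
            if len(xs) != 1:
                raise ValueError("a TargetMatrix pairs with exactly one image")
            targets = [y.entries]
        else:
            targets = [as_image(g).reshape(-1, as_image(g).shape[2]) for g in self._as_list(y)]
        if len(xs) != len(targets):
            raise ValueError(f"{len(xs)} distorted images but {len(targets)} targets")
        rows, tgts = [], []
        for xi, gi in zip(xs, targets):
            d = build_design_matrix(xi, self.kernel_size)
            if d.entries.shape[0] != gi.shape[0]:
                raise ValueError("distorted/clean pair differs in pixel count")
            rows.append(d.entries)
            tgts.append(gi)
        Xe = np.vstack(rows)
        Ge = np.vstack(tgts)
        if self.subsample is not None:
            if not 0.0 < self.subsample <= 1.0:
                raise ValueError("subsample must be in (0, 1]")
            rng = np.random.default_rng(self.random_state)
            n = max(Xe.shape[1], int(round(self.subsample * Xe.shape[0])))
            idx = rng.choice(Xe.shape[0], size=min(n, Xe.shape[0]), replace=False)
            Xe, Ge = Xe[idx], Ge[idx]
        fitted = estimate_correction(
            DesignMatrix(
                entries=Xe,
                kernel_size=self.kernel_size,
                channels=xs[0].shape[2] if xs[0].ndim == 3 else 1,
                source_shape=(Xe.shape[0], 1),
            ),
            Ge,
            ridge=self.ridge,
        )
        self.correction_ = fitted
        self.fit_residual_ = fitted.fit_residual
        return self

    def transform(self, X):
        """Restore image(s) with the fitted correction."""
        if not hasattr(self, "correction_"):
            raise AttributeError("corrector is not fitted; call fit first")
        xs = self._as_list(X)
        restored = [apply_correction(x, self.correction_) for x in xs]
        if isinstance(X, np.ndarray) and X.ndim in (2, 3):
            return restored[0]
        return restored


def _blueish(img: np.ndarray) -> np.ndarray:
    hsv = rgb2hsv(img)
    hue = hsv[:, :, 0] * 360.0
    return (hue >= 180.0) & (hue < 280.0) & (hsv[:, :, 1] > 0.25)


def estimate_ground_truth(
    distorted: np.ndarray,
    background_samples: list[tuple[int, int, int, int]] | None = None,
    override_mask: np.ndarray | None = None,
) -> tuple[TargetMatrix, np.ndarray]:
    """Estimate an undistorted calibration target from a young-plant image.

    Relies on the premise that young, unstressed plants are uniformly
    green, so any edge yellowness is distortion. The red channel — the
    sharpest at leaf edges — drives the initial segmentation (Otsu
    threshold); ``override_mask`` replaces it when the automatic attempt
    needs correcting. Each leaf component's target color is the median of
    its eroded interior, the background is set to the median of the
    supplied sample regions (tuples ``(r0, r1, c0, c1)``), and blue
    support-frame components are set to their median color.

    Returns the S_i x N_c target matrix and the plant mask actually used.
    """
    img = as_image(distorted)
    if img.shape[2] != 3:
        raise ValueError("ground-truth estimation expects an RGB image")
    H, W, _ = img.shape
    if override_mask is not None:
        mask = as_mask(override_mask, like=img)
    else:
        red = img[:, :, 0]
        thr = threshold_otsu(red)
        mask = red > thr
        mask = remove_small_objects(mask, max_size=9)
        mask = remove_small_holes(mask, max_size=25)
    if not mask.any():
        raise RuntimeError(
            "initial plant segmentation is empty; supply an override mask"
        )
    frame = _blueish(img) & ~mask
    frame = remove_small_objects(frame, max_size=19)

    target = np.empty_like(img)
    # background color from sampled regions, else from unclaimed pixels
    if background_samples:
        pix = []
        for r0, r1, c0, c1 in background_samples:
            if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
                raise ValueError(f"background region {(r0, r1, c0, c1)} out of bounds")
            pix.append(img[r0:r1, c0:c1].reshape(-1, 3))
        bg = np.median(np.vstack(pix), axis=0)
    elif override_mask is not None:
        rest = ~mask & ~frame
        bg = np.median(img[rest].reshape(-1, 3), axis=0)
    else:
        raise ValueError("background samples are required without an override mask")
    target[:] = bg

    labels, n = ndimage.label(mask)
    selem = disk(2)
    for lab in range(1, n + 1):
        comp = labels == lab
        interior = erosion(comp, selem)
        src = interior if interior.any() else comp
        target[comp] = np.median(img[src].reshape(-1, 3), axis=0)
    if frame.any():
        target[frame] = np.median(img[frame].reshape(-1, 3), axis=0)
    return TargetMatrix(entries=target.reshape(-1, 3), source_shape=(H, W)), mask


@dataclass
class ChartLayout:
    """Grid of color patches with known reference colors.

    ``margin`` is the fraction of each cell excluded on every side, for
    charts whose printed patch borders are unreliable. Keep it small: the
    pixels nearest a patch boundary are the ones whose neighborhoods span
    two colors and therefore carry most of the information about the
    blur.
    """

    origin: tuple[int, int]  # top-left (row, col) of the grid
    cell_size: tuple[int, int]  # (height, width) of one patch
    colors: np.ndarray  # (rows, cols, 3) known patch colors in [0, 1]
    margin: float = 0.05

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.float64)
        if self.colors.ndim != 3 or self.colors.shape[2] != 3:
            raise ValueError("colors must have shape (rows, cols, 3)")
        if not 0.0 <= self.margin <= 0.5:
            raise ValueError("margin must be in [0, 0.5]")


def render_chart(layout: ChartLayout, image_size: tuple[int, int]) -> np.ndarray:
    """Synthesize a clean chart image (patches on mid-gray) for testing."""
    H, W = image_size
    img = np.full((H, W, 3), 0.5)
    ch, cw = layout.cell_size
    r0, c0 = layout.origin
    nrows, ncols = layout.colors.shape[:2]
    if r0 + nrows * ch > H or c0 + ncols * cw > W:
        raise ValueError("chart layout exceeds image bounds")
    for i in range(nrows):
        for j in range(ncols):
            img[r0 + i * ch : r0 + (i + 1) * ch, c0 + j * cw : c0 + (j + 1) * cw] = (
                layout.colors[i, j]
            )
    return img


def calibrate_from_chart(
    chart_image: np.ndarray, layout: ChartLayout, kernel_size: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Pair chart-interior design rows with their known patch colors.

    Returns ``(X_rows, G_rows)`` restricted to cell interiors (borders
    excluded by the layout margin), ready for `estimate_correction`.
    """
    img = as_image(chart_image)
    H, W, _ = img.shape
    ch, cw = layout.cell_size
    r0, c0 = layout.origin
    nrows, ncols = layout.colors.shape[:2]
    if r0 < 0 or c0 < 0 or r0 + nrows * ch > H or c0 + ncols * cw > W:
        raise ValueError("chart layout exceeds image bounds")
    mh = int(round(layout.margin * ch))
    mw = int(round(layout.margin * cw))
    design = build_design_matrix(img, kernel_size)
    flat = design.entries
    rows_idx, targets = [], []
    for i in range(nrows):
        for j in range(ncols):
            rr0, rr1 = r0 + i * ch + mh, r0 + (i + 1) * ch - mh
            cc0, cc1 = c0 + j * cw + mw, c0 + (j + 1) * cw - mw
            if rr0 >= rr1 or cc0 >= cc1:
                raise ValueError(
                    f"margin {layout.margin} leaves no interior pixels in cell ({i}, {j})"
                )
            rr, cc = np.meshgrid(np.arange(rr0, rr1), np.arange(cc0, cc1), indexing="ij")
            idx = (rr * W + cc).ravel()
            rows_idx.append(idx)
            targets.append(np.tile(layout.colors[i, j], (idx.size, 1)))
    idx = np.concatenate(rows_idx)
    return flat[idx], np.vstack(targets)
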