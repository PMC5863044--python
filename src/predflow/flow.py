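"""Sparse Lucas-Kanade optical flow between predicted frames.

Feature points are local maxima of the Shi-Tomasi minimum-eigenvalue
corner response (scikit-image supplies the response map); displacements
are then estimated per point by iterative windowed least squares on the
image gradients, over a small 3-level coarse-to-fine pyramid.  Points
whose gradient system is degenerate, or that drift out of the image, are
flagged untrackable rather than dropped silently.

Defaults mirror the analysis settings used throughout: window size 50
(normalized to the odd 51), corner quality level 0.3, at most 100
features spaced >= 10 px.
"""

from __future__ import annotations

import dataclasses
import pathlib

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import corner_shi_tomasi

from .frames import to_grayscale


@dataclasses.dataclass(frozen=True)
class FlowParams:
    """Feature-detection and Lucas-Kanade solver parameters."""

    window_size: int = 50
    quality_level: float = 0.3
    max_features: int = 100
    min_distance: int = 10
    border_margin: int | None = None  # None -> min_distance
    pyramid_levels: int = 3
    max_iterations: int = 30
    convergence_px: float = 0.01

    def __post_init__(self):
        if not 0 < self.quality_level <= 1:
            raise ValueError("quality_level must be in (0, 1]")
        if self.window_size < 3:
            raise ValueError("window_size too small")

    @property
    def window_odd(self) -> int:
        """Window size normalized to the nearest odd value >= itself."""
        return self.window_size | 1


@dataclasses.dataclass
class FlowVectorSet:
    """Tracked start points and their displacements for one frame pair."""

    points: np.ndarray  # (n, 2) float (x, y) on frame A
    vectors: np.ndarray  # (n, 2) float (dx, dy)
    status: np.ndarray  # (n,) bool, True where tracking succeeded
    pair: str = ""  # e.g. "P1/P2"

    def __len__(self) -> int:
        return len(self.points)

    @property
    def valid(self) -> "FlowVectorSet":
        """Subset with successful tracking status."""
        m = self.status
        return FlowVectorSet(self.points[m], self.vectors[m], self.status[m], self.pair)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "dx": self.vectors[:, 0],
                "dy": self.vectors[:, 1],
                "status": self.status.astype(int),
                "pair": self.pair,
            }
        )

    def to_csv(self, path: str | pathlib.Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | pathlib.Path) -> "FlowVectorSet":
        df = pd.read_csv(path)
        pair = str(df["pair"].iloc[0]) if len(df) else ""
        return cls(
            df[["x", "y"]].to_numpy(float),
            df[["dx", "dy"]].to_numpy(float),
            df["status"].to_numpy(bool),
            pair,
        )


def _as_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = to_grayscale(image)
    return image


def detect_features(image: np.ndarray, params: FlowParams = FlowParams()) -> np.ndarray:
    """Shi-Tomasi corners: local maxima of the minimum-eigenvalue response
    at least ``quality_level`` of the global maximum, spaced
    ``min_distance`` apart, strongest first, at most ``max_features``.

    Returns an (n, 2) array of (x, y) pixel coordinates; may be empty.
    """
    gray = _as_gray(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if float(gray.max() - gray.min()) <= 1e-9:
        return np.empty((0, 2), dtype=np.float64)  # zero gradients everywhere
    response = corner_shi_tomasi(gray, sigma=1.5)
    response[response < 0] = 0.0
    # frame borders carry convolution/padding artifacts in predicted
    # frames and give tracking windows no support: excluded outright
    margin = params.min_distance if params.border_margin is None else params.border_margin
    if margin > 0:
        response[:margin, :] = 0.0
        response[-margin:, :] = 0.0
        response[:, :margin] = 0.0
        response[:, -margin:] = 0.0
    rmax = float(response.max())
    if rmax <= 1e-12:
        return np.empty((0, 2), dtype=np.float64)
    threshold = params.quality_level * rmax
    # greedy non-maximum suppression, strongest response first
    candidates = np.argwhere(response >= threshold)
    strengths = response[candidates[:, 0], candidates[:, 1]]
    order = np.argsort(strengths)[::-1]
    candidates = candidates[order]
    chosen: list[np.ndarray] = []
    min_d2 = params.min_distance ** 2
    for rc in candidates:
        if len(chosen) >= params.max_features:
            break
        if all((rc[0] - c[0]) ** 2 + (rc[1] - c[1]) ** 2 >= min_d2 for c in chosen):
            chosen.append(rc)
    if not chosen:
        return np.empty((0, 2), dtype=np.float64)
    pts = np.asarray(chosen, dtype=np.float64)
    return pts[:, ::-1].copy()  # (row, col) -> (x, y)


def _pyramid(gray: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [gray]
    for _ in range(levels - 1):
        prev = pyr[-1]
        if min(prev.shape) < 16:
            break
        smoothed = ndimage.gaussian_filter(prev, 1.0)
        pyr.append(smoothed[::2, ::2].copy())
    return pyr


def _gradients(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gx = ndimage.sobel(gray, axis=1) / 8.0
    gy = ndimage.sobel(gray, axis=0) / 8.0
    return gx, gy


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")


def compute_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    points: np.ndarray,
    params: FlowParams = FlowParams(),
) -> FlowVectorSet:
    """Iterative pyramidal Lucas-Kanade displacement for each start point.

    For every point the windowed least-squares system ``G d = b`` built
    from spatial gradients of frame A is solved iteratively against the
    warped frame B, coarse-to-fine.  Points with a near-singular gradient
    matrix or that leave the frame are marked untrackable.
    """
    a = _as_gray(frame_a)
    b = _as_gray(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    n = len(points)
    vectors = np.zeros((n, 2), dtype=np.float64)
    status = np.ones(n, dtype=bool)
    if n == 0:
        return FlowVectorSet(points, vectors, status)

    pyr_a = _pyramid(a, params.pyramid_levels)
    pyr_b = _pyramid(b, params.pyramid_levels)
    levels = len(pyr_a)
    half = params.window_odd // 2
    offs = np.arange(-half, half + 1, dtype=np.float64)
    wy, wx = np.meshgrid(offs, offs, indexing="ij")
    grads = [_gradients(pa) for pa in pyr_a]

    h, w = a.shape
    for i, (px, py) in enumerate(points):
        if not (0 <= px < w and 0 <= py < h):
            status[i] = False
            continue
        d = np.zeros(2)
        ok = True
        for lev in reversed(range(levels)):
            scale = 2.0 ** lev
            la, lb = pyr_a[lev], pyr_b[lev]
            gx, gy = grads[lev]
            cx, cy = px / scale, py / scale
            xs = cx + wx
            ys = cy + wy
            ix = _sample(gx, xs, ys)
            iy = _sample(gy, xs, ys)
            g11 = np.sum(ix * ix)
            g12 = np.sum(ix * iy)
            g22 = np.sum(iy * iy)
            det = g11 * g22 - g12 * g12
            trace = g11 + g22
            min_eig = 0.5 * (trace - np.sqrt(max(trace * trace - 4 * det, 0.0)))
            if min_eig < 1e-6 * (params.window_odd ** 2):
                ok = False
                break
            ginv = np.array([[g22, -g12], [-g12, g11]]) / det
            ia = _sample(la, xs, ys)
            dl = d / scale
            for _ in range(params.max_iterations):
                xb = cx + dl[0] + wx
                yb = cy + dl[1] + wy
                if not (-half <= cx + dl[0] < la.shape[1] + half
                        and -half <= cy + dl[1] < la.shape[0] + half):
                    ok = False
                    break
                it = _sample(lb, xb, yb) - ia
                bvec = np.array([np.sum(ix * it), np.sum(iy * it)])
                step = -ginv @ bvec
                dl += step
                if np.hypot(*step) < params.convergence_px:
                    break
            if not ok:
                break
            d = dl * scale
        if not ok or not np.all(np.isfinite(d)):
            status[i] = False
            d = np.zeros(2)
        vectors[i] = d
    return FlowVectorSet(points, vectors, status)


def flow_between(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    params: FlowParams = FlowParams(),
    pair: str = "",
) -> FlowVectorSet:
    """Detect features on frame A and track them into frame B."""
    pts = detect_features(frame_a, params)
    fvs = compute_flow(frame_a, frame_b, pts, params)
    fvs.pair = pair
    return fvs


def render_overlay(
    background: np.ndarray,
    flow: FlowVectorSet,
    path: str | pathlib.Path,
    amplification: float = 30.0,
) -> None:
    """Draw amplified flow vectors over a predicted frame and save as PNG.

    Amplification conventions: 30x for propeller probes, 60x for the
    single-ring and 180x for the four-ring still stimuli.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bg = np.clip(np.asarray(background, dtype=np.float32), 0, 1)
    h, w = bg.shape[:2]
    fig, ax = plt.subplots(figsize=(w / 40, h / 40), dpi=160)
    ax.imshow(bg, interpolation="nearest")
    v = flow.valid
    if len(v):
        ax.quiver(
            v.points[:, 0], v.points[:, 1],
            v.vectors[:, 0] * amplification, v.vectors[:, 1] * amplification,
            angles="xy", scale_units="xy", scale=1.0, color="red", width=0.004,
        )
        ax.plot(v.points[:, 0], v.points[:, 1], ".", color="yellow", markersize=2)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
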