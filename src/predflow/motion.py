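"""Angular-velocity statistics and group comparisons.

Flow vectors measured between predicted frames are converted to angular
velocities about a rotation centre: for a vector with offset r from the
centre and displacement v, omega = (r_x v_y - r_y v_x) / |r|^2, which is
positive for clockwise rotation in y-down image coordinates.  Vectors
closer than a minimum radius are excluded (omega is numerically unstable
near the centre).  Per-pair means are aggregated over training
checkpoints, and stimulus groups are compared with unpaired one-tailed
t-tests (Student's pooled-variance or Welch's).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .flow import FlowVectorSet
from .frames import FrameSequence, to_grayscale


class NoMotionError(ValueError):
    """Raised when a video's moving-pixel mask is empty (static input)."""


class NoUsableVectorsError(ValueError):
    """Raised when every flow vector falls inside the exclusion radius."""


@dataclasses.dataclass(frozen=True)
class RotationCenter:
    """Rotation centre in analysis-frame pixel coordinates."""

    x: float
    y: float
    source: str = "user-supplied"  # estimated-from-motion | geometric-ring-center | user-supplied

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=np.float64)


@dataclasses.dataclass
class AngularVelocitySummary:
    """Per-vector angular velocities for one predicted-frame pair."""

    omegas: np.ndarray  # radians / frame, cw positive
    pair: str = ""
    frames_seen: int = 0

    @property
    def n_vectors(self) -> int:
        return len(self.omegas)

    @property
    def mean(self) -> float:
        return float(np.mean(self.omegas))

    @property
    def se(self) -> float:
        if len(self.omegas) < 2:
            return 0.0
        return float(np.std(self.omegas, ddof=1) / np.sqrt(len(self.omegas)))

    def summary(self) -> str:
        return (f"{self.pair or 'pair'}: mean omega = {self.mean:+.5f} "
                f"± {self.se:.5f} rad/frame (cw+), n = {self.n_vectors}")


@dataclasses.dataclass
class CheckpointAggregate:
    """Mean ± SE of per-checkpoint mean angular velocities in a window."""

    mean: float
    se: float
    n: int
    window: tuple[int, int]


@dataclasses.dataclass
class GroupComparison:
    """Unpaired one-tailed t-test between two groups of values."""

    t: float
    df: float
    p: float
    test: str  # "student" | "welch"
    alternative: str  # "greater" | "less"
    n1: int
    n2: int

    def summary(self) -> str:
        return (f"one-tailed {self.test} t-test ({self.alternative}): "
                f"t = {self.t:.3f}, df = {self.df:.3g}, p = {self.p:.4g} "
                f"(n = {self.n1} vs {self.n2})")


def estimate_center(video: FrameSequence, threshold: float | None = None) -> RotationCenter:
    """Estimate the rotation centre from inter-frame motion.

    Absolute frame differences are thresholded (Otsu by default) to a
    moving-pixel mask, and the intensity-weighted centroid of the mask is
    averaged over frame pairs.  For static videos (empty mask) a
    :class:`NoMotionError` is raised.
    """
    if len(video) < 2:
        raise ValueError("need at least 2 frames to estimate motion")
    gray = np.stack([to_grayscale(f) for f in video.data])
    diffs = np.abs(np.diff(gray, axis=0))
    total = diffs.sum(axis=0)
    if threshold is None:
        if float(total.max()) <= 1e-6:
            raise NoMotionError("no motion: difference mask is empty")
        threshold = threshold_otsu(total)
    mask = total > threshold
    if not mask.any():
        raise NoMotionError("no motion: difference mask is empty")
    weights = total * mask
    ys, xs = np.mgrid[0 : total.shape[0], 0 : total.shape[1]]
    wsum = weights.sum()
    cx = float((xs * weights).sum() / wsum)
    cy = float((ys * weights).sum() / wsum)
    return RotationCenter(cx, cy, source="estimated-from-motion")


def angular_velocity_stats(
    flow: FlowVectorSet,
    center: RotationCenter,
    coord_scale: float = 1.0,
    min_radius: float = 5.0,
    frames_seen: int = 0,
) -> AngularVelocitySummary:
    """Per-vector angular velocity about ``center``, cw positive.

    Coordinates and displacements are rescaled by ``coord_scale`` into the
    original stimulus frame before the calculation (the centre is given in
    that frame).  Vectors within ``min_radius`` of the centre (after
    scaling) are excluded.
    """
    v = flow.valid
    if len(v) == 0:
        raise NoUsableVectorsError("no successfully tracked vectors")
    pts = v.points * coord_scale
    vecs = v.vectors * coord_scale
    rel = pts - center.xy
    r2 = (rel ** 2).sum(axis=1)
    keep = r2 >= min_radius ** 2
    if not keep.any():
        raise NoUsableVectorsError("all vectors inside the exclusion radius")
    rel, vecs, r2 = rel[keep], vecs[keep], r2[keep]
    omegas = (rel[:, 0] * vecs[:, 1] - rel[:, 1] * vecs[:, 0]) / r2
    return AngularVelocitySummary(omegas, pair=flow.pair, frames_seen=frames_seen)


def checkpoint_summary(
    summaries: list[AngularVelocitySummary],
    window: tuple[int, int],
) -> CheckpointAggregate:
    """Mean ± SE of per-checkpoint mean omegas with frames_seen inside
    ``[window[0], window[1]]`` (inclusive)."""
    lo, hi = window
    means = [s.mean for s in summaries if lo <= s.frames_seen <= hi]
    if not means:
        raise ValueError(f"no checkpoints inside window [{lo}, {hi}]")
    means = np.asarray(means, dtype=np.float64)
    n = len(means)
    se = float(np.std(means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CheckpointAggregate(float(means.mean()), se, n, (lo, hi))


def compare_groups(
    a,
    b,
    test: str = "auto",
    absolute: bool = False,
    alternative: str = "greater",
) -> GroupComparison:
    """One-tailed unpaired t-test between two groups.

    ``test`` may be "student" (pooled variance, df = n1 + n2 - 2),
    "welch" (Welch-Satterthwaite df) or "auto", which picks Welch when
    group sizes differ or the variance ratio exceeds 4.  ``absolute``
    compares magnitudes; ``alternative`` states the one-sided direction
    for the mean of ``a`` relative to ``b``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if absolute:
        a, b = np.abs(a), np.abs(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups with equal means: t undefined")
    if test == "auto":
        ratio = max(va, vb) / max(min(va, vb), 1e-300)
        test = "welch" if (len(a) != len(b) or ratio > 4.0) else "student"
    if test == "student":
        res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
        df = len(a) + len(b) - 2
    elif test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        df = float(res.df)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(float(res.statistic), float(df), float(res.pvalue),
                           test, alternative, len(a), len(b))
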