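"""Synthetic stimulus and training-corpus generation.

Three families of input are produced here, all deterministic in their
seeds, so the full pipeline runs without any external downloads:

* rotating-propeller probe videos (15 rpm clockwise/counter-clockwise and
  a 0 rpm static control), rendered with supersampled anti-aliasing;
* static four-colour "rotating snake" ring images (illusion layouts and
  negative controls with the same colours and geometry), repeated into
  20-frame static sequences;
* surrogate ego-motion training corpora: procedural textured scenes viewed
  by a smoothly translating/rotating camera, optionally mixed with
  rotating textured-disc clips.

An analytic rigid-rotation flow-field oracle is included for testing the
flow and angular-velocity stages against exact ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .frames import FrameSequence

# saturated four-colour cycle of the snake illusion, read along the
# direction of perceived motion: blue, black, yellow, white
SNAKE_COLORS = (
    (0.0, 0.0, 1.0),
    (0.0, 0.0, 0.0),
    (1.0, 1.0, 0.0),
    (1.0, 1.0, 1.0),
)


@dataclasses.dataclass(frozen=True)
class PropellerSpec:
    """Rotating-propeller probe video parameters."""

    rpm: float = 15.0
    direction: str = "cw"  # "cw" | "ccw"
    n_blades: int = 3
    blade_asymmetry: float = 0.0  # angular skew of the blade outline per unit radius
    fps: float = 30.0
    n_frames: int = 20
    size: tuple[int, int] = (160, 120)  # (width, height)
    mirror: bool = False
    center: tuple[float, float] | None = None  # pixel (x, y); None -> image centre

    def __post_init__(self):
        if self.rpm < 0:
            raise ValueError("rpm must be >= 0")
        if self.direction not in ("cw", "ccw"):
            raise ValueError("direction must be 'cw' or 'ccw'")

    @property
    def omega(self) -> float:
        """Signed rotation per frame in radians, cw positive on screen."""
        mag = self.rpm * 2.0 * np.pi / (60.0 * self.fps)
        sign = 1.0 if self.direction == "cw" else -1.0
        if self.mirror:
            sign = -sign
        return sign * mag

    @property
    def center_xy(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        w, h = self.size
        return ((w - 1) / 2.0, (h - 1) / 2.0)


@dataclasses.dataclass(frozen=True)
class SnakeRingSpec:
    """Static ring stimulus: illusion layout or negative control."""

    mode: str = "illusion"  # "illusion" | "control"
    n_rings: int = 1  # 1 | 4
    color_cycle: tuple = SNAKE_COLORS
    handedness: str = "ccw"  # perceived direction induced by the first ring
    elements_per_ring: int = 12  # repeating 4-colour units around the ring
    inner_radius_frac: float = 0.25  # of the outer radius
    outer_radius_frac: float = 0.92  # of the available half-extent
    n_bands: int = 2  # concentric bands, phase-staggered
    size: tuple[int, int] = (160, 120)

    def __post_init__(self):
        if self.mode not in ("illusion", "control"):
            raise ValueError("mode must be 'illusion' or 'control'")
        if self.n_rings not in (1, 4):
            raise ValueError("n_rings must be 1 or 4")
        if len(self.color_cycle) != 4:
            raise ValueError("color_cycle must have exactly 4 colors")
        if self.handedness not in ("cw", "ccw"):
            raise ValueError("handedness must be 'cw' or 'ccw'")
        if self.elements_per_ring < 3:
            raise ValueError("too few repeating units to render the 4-color cycle")

    def ring_layout(self) -> list[dict]:
        """Centres, radii and handedness of each ring (pixel coordinates)."""
        w, h = self.size
        rings = []
        if self.n_rings == 1:
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            outer = self.outer_radius_frac * min(w, h) / 2.0
            rings.append({"center": (cx, cy), "outer": outer, "handedness": self.handedness})
        else:
            # 2x2 grid; adjacent rings take opposite handedness
            other = "cw" if self.handedness == "ccw" else "ccw"
            for iy in range(2):
                for ix in range(2):
                    cx = (w / 2.0) * ix + w / 4.0 - 0.5
                    cy = (h / 2.0) * iy + h / 4.0 - 0.5
                    outer = self.outer_radius_frac * min(w / 2.0, h / 2.0) / 2.0
                    hand = self.handedness if (ix + iy) % 2 == 0 else other
                    rings.append({"center": (cx, cy), "outer": outer, "handedness": hand})
        for r in rings:
            r["inner"] = self.inner_radius_frac * r["outer"]
        return rings


@dataclasses.dataclass(frozen=True)
class EgoMotionCorpusSpec:
    """Surrogate first-person training-video parameters.

    The corpus is a concatenation of fixed-length clips; each clip views a
    procedural multi-octave texture under one smooth camera motion drawn
    from the configured ranges.  ``rotation_fraction`` of clips are pure
    in-plane rotations and ``disc_fraction`` show a rotating textured disc
    over a static background, so the corpus contains the rotary image
    motion the probes later test for.
    """

    seed: int = 0
    n_frames: int = 2000
    fps: float = 30.0
    size: tuple[int, int] = (160, 120)
    clip_len: int = 60
    translation_range: tuple[float, float] = (0.5, 3.0)  # px / frame
    rotation_range: tuple[float, float] = (0.02, 0.12)  # rad / frame
    rotation_fraction: float = 0.3
    disc_fraction: float = 0.2
    texture_octaves: int = 4
    mirror_training: bool = False


# ----------------------------------------------------------------- rendering


def _supersample_grid(width: int, height: int, ss: int):
    """Pixel-centre coordinates of an ss-times supersampled raster."""
    xs = (np.arange(width * ss) + 0.5) / ss - 0.5
    ys = (np.arange(height * ss) + 0.5) / ss - 0.5
    return np.meshgrid(xs, ys)


def _downsample(img: np.ndarray, ss: int) -> np.ndarray:
    h, w = img.shape[0] // ss, img.shape[1] // ss
    return img.reshape(h, ss, w, ss, -1).mean(axis=(1, 3))


def make_propeller_video(spec: PropellerSpec, supersample: int = 4) -> FrameSequence:
    """Render a rotating-propeller sequence.

    Blade angle at frame t is ``t * omega`` with omega signed by direction
    (cw positive on screen, y-down coordinates); ``mirror`` flips each
    frame horizontally, which reverses the apparent rotation.
    """
    w, h = spec.size
    if min(w, h) < 8:
        raise ValueError("degenerate geometry: image too small")
    cx, cy = spec.center_xy
    if spec.mirror:
        # render unmirrored about the mirrored centre, flip at the end
        cx = (w - 1) - cx
    xg, yg = _supersample_grid(w, h, supersample)
    dx, dy = xg - cx, yg - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)  # y-down: increases clockwise on screen

    r_tip = 0.45 * min(w, h)
    r_hub = 0.06 * min(w, h)
    if r_tip <= 0:
        raise ValueError("degenerate geometry: zero radius")
    sector = 2.0 * np.pi / spec.n_blades
    base_half_width = 0.30 * sector
    rn = np.clip(r / r_tip, 0.0, 1.2)
    # tapered blade: angular half-width shrinks toward the tip
    half_width = base_half_width * (1.0 - 0.55 * rn)

    background = 0.85
    blade_color = np.array([0.15, 0.12, 0.12], dtype=np.float32)
    hub_color = np.array([0.35, 0.33, 0.33], dtype=np.float32)

    omega = spec.rpm * 2.0 * np.pi / (60.0 * spec.fps)
    if spec.direction == "ccw":
        omega = -omega

    frames = np.empty((spec.n_frames, h, w, 3), dtype=np.float32)
    for t in range(spec.n_frames):
        phase = t * omega
        # angle of each pixel relative to the nearest blade axis
        rel = theta - phase + spec.blade_asymmetry * rn
        rel = np.mod(rel, sector) - sector / 2.0
        blade = (np.abs(rel) < half_width) & (r >= r_hub) & (r <= r_tip)
        hub = r < r_hub
        img = np.full((h * supersample, w * supersample, 3), background, dtype=np.float32)
        img[blade] = blade_color
        img[hub] = hub_color
        frames[t] = _downsample(img, supersample)
    seq = FrameSequence(frames, fps=spec.fps)
    if spec.mirror:
        seq = seq.mirrored()
    return seq


def make_snake_image(spec: SnakeRingSpec, supersample: int = 4) -> np.ndarray:
    """Render the static ring stimulus as one HxWx3 image in [0, 1].

    Illusion mode lays the four-colour cycle in a consistent circular
    order (the handedness sets its direction); control mode keeps the same
    colours and geometry but reverses the cycle between adjacent repeating
    units, so the circular colour order cancels locally and no consistent
    direction exists.
    """
    w, h = spec.size
    xg, yg = _supersample_grid(w, h, supersample)
    img = np.full((h * supersample, w * supersample, 3), 0.5, dtype=np.float32)
    colors = np.asarray(spec.color_cycle, dtype=np.float32)
    n_sectors = spec.elements_per_ring * 4

    for ring in spec.ring_layout():
        cx, cy = ring["center"]
        dx, dy = xg - cx, yg - cy
        r = np.hypot(dx, dy)
        theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
        in_ring = (r >= ring["inner"]) & (r <= ring["outer"])
        band_width = (ring["outer"] - ring["inner"]) / spec.n_bands
        band = np.clip(((r - ring["inner"]) / band_width).astype(np.int64), 0, spec.n_bands - 1)
        # stagger alternate bands by half a repeating unit
        stagger = (band % 2) * (2.0 * np.pi / n_sectors) * 2.0
        sector = np.floor(np.mod(theta + stagger, 2.0 * np.pi) / (2.0 * np.pi / n_sectors))
        sector = sector.astype(np.int64)
        pos_in_unit = sector % 4
        if ring["handedness"] == "cw":
            pos_in_unit = 3 - pos_in_unit
        if spec.mode == "control":
            unit = sector // 4
            flip = unit % 2 == 1
            pos_in_unit = np.where(flip, 3 - pos_in_unit, pos_in_unit)
        color_idx = np.where(in_ring, pos_in_unit, 0)
        ring_pixels = colors[color_idx]
        img = np.where(in_ring[..., None], ring_pixels, img)
    return _downsample(img, supersample).astype(np.float32)


def color_pixel_counts(image: np.ndarray, colors=SNAKE_COLORS,
                       background: tuple = (0.5, 0.5, 0.5)) -> np.ndarray:
    """Count pixels assigned to each palette colour by nearest-colour
    classification (anti-aliased boundary pixels go to the closest
    palette entry; background pixels are excluded)."""
    palette = np.asarray(list(colors) + [background], dtype=np.float32)
    flat = np.asarray(image, dtype=np.float32).reshape(-1, 3)
    d2 = ((flat[:, None, :] - palette[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return np.array([(idx == i).sum() for i in range(len(colors))])


def make_snake_sequence(spec: SnakeRingSpec, n_frames: int = 20) -> FrameSequence:
    """The still ring image repeated into a static probe sequence."""
    return FrameSequence.from_still(make_snake_image(spec), n_frames=n_frames)


# ------------------------------------------------------------ ego-motion corpus


def _make_texture(rng: np.random.Generator, size: int, octaves: int) -> np.ndarray:
    """Multi-octave smooth random RGB texture in [0, 1]."""
    tex = np.zeros((size, size, 3), dtype=np.float32)
    amp, total = 1.0, 0.0
    for o in range(octaves):
        n = max(2, size // (2 ** (octaves - o + 1)))
        coarse = rng.standard_normal((n, n, 3)).astype(np.float32)
        zoomed = ndimage.zoom(coarse, (size / n, size / n, 1), order=3, mode="grid-wrap")
        tex += amp * zoomed[:size, :size]
        total += amp
        amp *= 0.55
    tex /= total
    tex = 0.5 + 0.35 * tex / max(tex.std(), 1e-6) * 0.5
    return np.clip(tex, 0.0, 1.0)


def _sample_window(texture: np.ndarray, center: np.ndarray, angle: float,
                   w: int, h: int) -> np.ndarray:
    """Bilinearly sample a rotated w x h window of the texture (wrapping)."""
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float32)
    xr = xs - (w - 1) / 2.0
    yr = ys - (h - 1) / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    tx = center[0] + ca * xr - sa * yr
    ty = center[1] + sa * xr + ca * yr
    out = np.empty((h, w, 3), dtype=np.float32)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(texture[..., c], [ty, tx], order=1, mode="wrap")
    return out


def make_training_corpus(spec: EgoMotionCorpusSpec) -> FrameSequence:
    """Procedural ego-motion training video, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.size
    tex_size = int(max(w, h) * 3)
    texture = _make_texture(rng, tex_size, spec.texture_octaves)
    frames = np.empty((spec.n_frames, h, w, 3), dtype=np.float32)
    t_out = 0
    while t_out < spec.n_frames:
        clip_len = min(spec.clip_len, spec.n_frames - t_out)
        u = rng.uniform()
        kind = ("rotate" if u < spec.rotation_fraction
                else "disc" if u < spec.rotation_fraction + spec.disc_fraction
                else "translate")
        center = rng.uniform(tex_size * 0.25, tex_size * 0.75, size=2)
        angle = rng.uniform(0, 2 * np.pi)
        drot = 0.0
        vel = np.zeros(2)
        if kind == "translate":
            speed = rng.uniform(*spec.translation_range)
            direction = rng.uniform(0, 2 * np.pi)
            vel = speed * np.array([np.cos(direction), np.sin(direction)])
            drot = rng.uniform(-0.004, 0.004)  # slight camera roll
        else:
            drot = rng.uniform(*spec.rotation_range) * rng.choice([-1.0, 1.0])
        if kind == "disc":
            bg = _sample_window(texture, center, angle, w, h)
            ys, xs = np.mgrid[0:h, 0:w]
            disc_c = np.array([(w - 1) / 2.0, (h - 1) / 2.0]) + rng.uniform(-8, 8, size=2)
            disc_r = rng.uniform(0.25, 0.42) * min(w, h)
            mask = ((xs - disc_c[0]) ** 2 + (ys - disc_c[1]) ** 2) < disc_r ** 2
            disc_tex_center = rng.uniform(tex_size * 0.25, tex_size * 0.75, size=2)
            for t in range(clip_len):
                fg = _sample_window(texture, disc_tex_center, angle + t * drot, w, h)
                frame = bg.copy()
                frame[mask] = fg[mask]
                frames[t_out + t] = frame
        else:
            for t in range(clip_len):
                frames[t_out + t] = _sample_window(
                    texture, center + t * vel, angle + t * drot, w, h)
        t_out += clip_len
    seq = FrameSequence(np.clip(frames, 0, 1), fps=spec.fps)
    if spec.mirror_training:
        seq = seq.mirrored()
    return seq


# ------------------------------------------------------------------- oracles


def rigid_rotation_flow_oracle(
    center: tuple[float, float], omega: float, points: np.ndarray
) -> np.ndarray:
    """Exact displacement of points under rotation by ``omega`` about
    ``center``; omega is cw-positive in y-down image coordinates.

    Returns an (n, 2) array of (dx, dy) displacements.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    rel = points - np.asarray(center, dtype=np.float64)
    ca, sa = np.cos(omega), np.sin(omega)
    new = np.empty_like(rel)
    new[:, 0] = ca * rel[:, 0] - sa * rel[:, 1]
    new[:, 1] = sa * rel[:, 0] + ca * rel[:, 1]
    return new - rel


def warp_rigid_rotation(image: np.ndarray, center: tuple[float, float],
                        omega: float) -> np.ndarray:
    """Rotate an image by ``omega`` (cw-positive, y-down) about ``center``
    with bilinear interpolation — the image-domain counterpart of the
    flow oracle, for closing the loop through the flow estimator."""
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xs - center[0], ys - center[1]
    ca, sa = np.cos(-omega), np.sin(-omega)  # inverse map
    sx = center[0] + ca * dx - sa * dy
    sy = center[1] + sa * dx + ca * dy
    if image.ndim == 2:
        return ndimage.map_coordinates(image, [sy, sx], order=1, mode="nearest").astype(np.float32)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(image[..., c], [sy, sx], order=1, mode="nearest")
    return out
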