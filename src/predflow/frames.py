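"""Frame-sequence container and serial-image I/O.

A :class:`FrameSequence` is the currency passed between every stage of the
pipeline: stimulus generation, network training, closed-loop rollout and
optical-flow analysis.  Frames are float32 RGB in [0, 1], shaped
(n_frames, height, width, 3), with a frame-rate annotation.  On disk the
canonical form is a directory of serial JPEG or PNG stills with
lexicographically ordered names (``frame_000000.png`` ...).
"""

from __future__ import annotations

import dataclasses
import pathlib
import re

import imageio.v3 as iio
import numpy as np

_FRAME_EXTS = (".png", ".jpg", ".jpeg")


@dataclasses.dataclass
class FrameSequence:
    """Ordered raster frames with pixel range and frame-rate metadata."""

    data: np.ndarray  # (T, H, W, 3) float32 in [0, 1]
    fps: float = 30.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 3:  # grayscale -> replicate to RGB
            self.data = np.repeat(self.data[..., None], 3, axis=3)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"expected (T, H, W, 3) frames, got {self.data.shape}")
        if self.data.size and (self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6):
            raise ValueError("pixel values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.data[i]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def mirrored(self) -> "FrameSequence":
        """Horizontally inverted copy of every frame."""
        return FrameSequence(self.data[:, :, ::-1, :].copy(), fps=self.fps)

    def slice(self, start: int, stop: int) -> "FrameSequence":
        return FrameSequence(self.data[start:stop].copy(), fps=self.fps)

    def concat(self, other: "FrameSequence") -> "FrameSequence":
        if other.frame_shape != self.frame_shape:
            raise ValueError("frame shape drift between sequences")
        return FrameSequence(np.concatenate([self.data, other.data]), fps=self.fps)

    # ------------------------------------------------------------------ I/O

    def save(self, directory: str | pathlib.Path, fmt: str = "png") -> list[pathlib.Path]:
        """Write frames as serial stills ``frame_<t>.{png,jpg}``."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for t, frame in enumerate(self.data):
            p = directory / f"frame_{t:06d}.{fmt}"
            iio.imwrite(p, (np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
            paths.append(p)
        return paths

    @classmethod
    def load(cls, directory: str | pathlib.Path, fps: float = 30.0) -> "FrameSequence":
        """Read serial stills in lexicographic filename order."""
        directory = pathlib.Path(directory)
        files = sorted(
            p for p in directory.iterdir()
            if p.suffix.lower() in _FRAME_EXTS and re.match(r".*\d", p.stem)
        )
        if not files:
            raise FileNotFoundError(f"no frame images found in {directory}")
        frames = []
        for p in files:
            img = iio.imread(p)
            if img.ndim == 2:
                img = np.repeat(img[..., None], 3, axis=2)
            frames.append(img[..., :3].astype(np.float32) / 255.0)
        return cls(np.stack(frames), fps=fps)

    @classmethod
    def from_still(cls, image: np.ndarray, n_frames: int = 20, fps: float = 30.0) -> "FrameSequence":
        """Repeat one still image into a static sequence (illusion probes)."""
        image = np.asarray(image, dtype=np.float32)
        return cls(np.broadcast_to(image, (n_frames,) + image.shape).copy(), fps=fps)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Rec. 709 luminance of an RGB frame in [0, 1]."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim == 2:
        return frame
    return frame[..., 0] * 0.2125 + frame[..., 1] * 0.7154 + frame[..., 2] * 0.0721
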