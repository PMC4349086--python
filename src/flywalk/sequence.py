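"""Frame sequences: the two-channel image stack for one fly, plus disk I/O.

A sequence holds the blue backlight channel (dark fly silhouette on a
bright diffuser) and the red transillumination channel (bright body,
wing veins visible where wings overlap the body) for every frame, along
with matching fly-free background frames and the pixel calibration.

On disk a sequence is either a multi-page RGB TIFF (pages = frames, the
R plane carrying the red channel and the B plane the blue channel) with
a companion ``*_bg.tif`` background image, or a ``fly_<id>/`` directory
of per-frame PNGs with a ``background.png``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class FrameSequence:
    fly_id: str
    blue: np.ndarray  # (n_frames, rows, cols) uint8
    red: np.ndarray  # (n_frames, rows, cols) uint8
    background_blue: np.ndarray  # (rows, cols) uint8
    background_red: np.ndarray  # (rows, cols) uint8
    mm_per_px: float = 0.0087
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.blue.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape[1:]

    def __post_init__(self) -> None:
        if self.blue.shape != self.red.shape:
            raise ValueError("blue and red stacks must share one shape")
        if self.background_blue.shape != self.blue.shape[1:]:
            raise ValueError("background shape must match frame shape")

    # -- I/O --------------------------------------------------------------
    def _rgb(self, i: int) -> np.ndarray:
        rgb = np.zeros(self.shape + (3,), dtype=np.uint8)
        rgb[..., 0] = self.red[i]
        rgb[..., 2] = self.blue[i]
        return rgb

    def save_tiff(self, path: str | Path) -> Path:
        path = Path(path)
        stack = np.stack([self._rgb(i) for i in range(self.n_frames)])
        tifffile.imwrite(path, stack, photometric="rgb")
        bg = np.zeros(self.shape + (3,), dtype=np.uint8)
        bg[..., 0] = self.background_red
        bg[..., 2] = self.background_blue
        tifffile.imwrite(path.with_name(path.stem + "_bg.tif"), bg, photometric="rgb")
        return path

    def save_png_dir(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i in range(self.n_frames):
            iio.imwrite(directory / f"frame_{i:03d}.png", self._rgb(i))
        bg = np.zeros(self.shape + (3,), dtype=np.uint8)
        bg[..., 0] = self.background_red
        bg[..., 2] = self.background_blue
        iio.imwrite(directory / "background.png", bg)
        return directory

    @classmethod
    def from_rgb_stack(
        cls, fly_id: str, stack: np.ndarray, background: np.ndarray, mm_per_px: float
    ) -> "FrameSequence":
        return cls(
            fly_id=fly_id,
            blue=np.ascontiguousarray(stack[..., 2]),
            red=np.ascontiguousarray(stack[..., 0]),
            background_blue=np.ascontiguousarray(background[..., 2]),
            background_red=np.ascontiguousarray(background[..., 0]),
            mm_per_px=mm_per_px,
        )

    @classmethod
    def load_tiff(cls, path: str | Path, mm_per_px: float = 0.0087) -> "FrameSequence":
        path = Path(path)
        stack = tifffile.imread(path)
        if stack.ndim == 3:  # single frame
            stack = stack[None]
        bg_path = path.with_name(path.stem + "_bg.tif")
        if not bg_path.exists():
            raise FileNotFoundError(f"missing background image {bg_path}")
        background = tifffile.imread(bg_path)
        return cls.from_rgb_stack(path.stem, stack, background, mm_per_px)

    @classmethod
    def load_png_dir(cls, directory: str | Path, mm_per_px: float = 0.0087):
        directory = Path(directory)
        frames = sorted(directory.glob("frame_*.png"))
        if not frames:
            raise FileNotFoundError(f"no frame_*.png in {directory}")
        stack = np.stack([iio.imread(f) for f in frames])
        bg_path = directory / "background.png"
        if not bg_path.exists():
            raise FileNotFoundError(f"missing {bg_path}")
        background = iio.imread(bg_path)
        fly_id = re.sub(r"^fly_", "", directory.name)
        return cls.from_rgb_stack(f"fly_{fly_id}", stack, background, mm_per_px)


def discover_sequences(directory: str | Path) -> list[Path]:
    """Paths of all sequences under ``directory`` (TIFF files or fly_* dirs)."""
    directory = Path(directory)
    tiffs = [
        p
        for p in sorted(directory.glob("*.tif*"))
        if not p.stem.endswith("_bg")
    ]
    dirs = [p for p in sorted(directory.glob("fly_*")) if p.is_dir()]
    return tiffs + dirs


def load_sequence(path: str | Path, mm_per_px: float = 0.0087) -> FrameSequence:
    path = Path(path)
    if path.is_dir():
        return FrameSequence.load_png_dir(path, mm_per_px)
    return FrameSequence.load_tiff(path, mm_per_px)
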