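"""Rendering spectra files as RT x m/z image sequences for the 3D classifier.

Each mgf file becomes a sequence of square grayscale rasters; one raster
covers a fixed RT window (96.7 s by default), with the window-relative RT on
the horizontal axis and m/z on the vertical axis, intensity encoded as pixel
brightness in [0, 1].  The sequence is padded/truncated to a fixed frame
count (98), optionally augmented at the image level, downsampled by area
averaging to 256 x 256 and stacked into a (256, 256, 98) volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mgf_io import METABOLOMIC, PROTEOMIC, SpectraFile

DEFAULT_MZ_RANGE = {PROTEOMIC: (100.0, 2000.0), METABOLOMIC: (50.0, 1000.0)}


@dataclass
class RasterConfig:
    window_seconds: float = 96.7
    raster_size: int = 512
    volume_size: int = 256
    frames_per_file: int = 98
    mz_range: dict = field(default_factory=lambda: dict(DEFAULT_MZ_RANGE))
    intensity_encoding: str = "log1p_gray"   # or "linear_gray"
    aggregation: str = "max"                 # or "sum"

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.raster_size < self.volume_size:
            raise ValueError("raster_size must be >= volume_size")
        if self.frames_per_file < 1:
            raise ValueError("frames_per_file must be >= 1")
        if self.intensity_encoding not in ("log1p_gray", "linear_gray"):
            raise ValueError(f"unknown encoding {self.intensity_encoding!r}")


@dataclass
class SpectrumImage:
    frame_index: int
    pixels: np.ndarray              # (raster, raster) in [0, 1]; row 0 = lowest m/z
    rt_window: tuple[float, float]


@dataclass
class VolumeTensor:
    voxels: np.ndarray              # (volume, volume, frames) in [0, 1]
    layer: str
    file_id: str


def peak_pixel(rt: float, mz: float, frame_start: float, cfg: RasterConfig,
               mz_lo: float, mz_hi: float) -> tuple[int, int]:
    """(row, col) a single peak maps to inside its window's raster."""
    size = cfg.raster_size
    col = int(np.floor((rt - frame_start) / cfg.window_seconds * size))
    row = int(np.floor((mz - mz_lo) / (mz_hi - mz_lo) * size))
    return min(max(row, 0), size - 1), min(max(col, 0), size - 1)


def render_windows(sf: SpectraFile, cfg: RasterConfig) -> list[SpectrumImage]:
    """Rasterize a file into consecutive RT windows starting at RT = 0.

    The natural frame count is ``ceil(rt_span / window_seconds)``; the
    sequence is then blank-padded or truncated to ``frames_per_file`` so all
    files produce a fixed-shape stack.  Peaks landing on the same pixel are
    aggregated by max (config-switchable to sum).  Rendering is deterministic.
    """
    size = cfg.raster_size
    F = cfg.frames_per_file
    mz_lo, mz_hi = cfg.mz_range[sf.omics_layer]
    frames = np.zeros((F, size, size), dtype=np.float32)
    if len(sf) == 0:
        warnings.warn(f"file {sf.file_id!r} is empty; rendering blank frames")
        return _to_images(frames, cfg)

    rts, mzs, ints = [], [], []
    for s in sf.spectra:
        if len(s) == 0:
            continue
        rts.append(np.full(len(s), s.rt_seconds))
        mzs.append(s.mz)
        ints.append(s.intensity)
    if rts:
        rt = np.concatenate(rts)
        mz = np.concatenate(mzs)
        inten = np.concatenate(ints).astype(np.float32)
        in_range = (mz >= mz_lo) & (mz <= mz_hi)
        rt, mz, inten = rt[in_range], mz[in_range], inten[in_range]
        frame_idx = np.floor(rt / cfg.window_seconds).astype(np.int64)
        visible = frame_idx < F
        rt, mz, inten, frame_idx = (
            rt[visible], mz[visible], inten[visible], frame_idx[visible])
        col = np.floor((rt - frame_idx * cfg.window_seconds)
                       / cfg.window_seconds * size).astype(np.int64)
        row = np.floor((mz - mz_lo) / (mz_hi - mz_lo) * size).astype(np.int64)
        np.clip(col, 0, size - 1, out=col)
        np.clip(row, 0, size - 1, out=row)
        if cfg.aggregation == "max":
            np.maximum.at(frames, (frame_idx, row, col), inten)
        else:
            np.add.at(frames, (frame_idx, row, col), inten)

    if cfg.intensity_encoding == "log1p_gray":
        top = float(np.log1p(frames.max()))
        if top > 0:
            frames = np.log1p(frames) / top
    else:
        top = float(frames.max())
        if top > 1:
            frames = frames / top
    return _to_images(frames, cfg)


def _to_images(frames: np.ndarray, cfg: RasterConfig) -> list[SpectrumImage]:
    w = cfg.window_seconds
    return [
        SpectrumImage(frame_index=i, pixels=frames[i], rt_window=(i * w, (i + 1) * w))
        for i in range(frames.shape[0])
    ]


def natural_frame_count(rt_span: float, cfg: RasterConfig) -> int:
    """Frames needed to cover an RT span before padding/truncation."""
    return int(np.ceil(rt_span / cfg.window_seconds))


# ---------------------------------------------------------------------------
# image-level augmentation

def _shift(img: np.ndarray, rng: np.random.Generator, max_frac: float) -> np.ndarray:
    limit = max(1, int(max_frac * img.shape[0]))
    dr = int(rng.integers(1, limit + 1)) * (1 if rng.random() < 0.5 else -1)
    dc = int(rng.integers(1, limit + 1)) * (1 if rng.random() < 0.5 else -1)
    return np.roll(np.roll(img, dr, axis=0), dc, axis=1)


def _zero_rect(img: np.ndarray, rng: np.random.Generator, max_area: float) -> np.ndarray:
    h, w = img.shape
    rh = int(rng.integers(1, max(2, int(np.sqrt(max_area) * h)) + 1))
    rw = int(rng.integers(1, max(2, int(np.sqrt(max_area) * w)) + 1))
    r0 = int(rng.integers(0, h - rh + 1))
    c0 = int(rng.integers(0, w - rw + 1))
    out = img.copy()
    out[r0:r0 + rh, c0:c0 + rw] = 0.0
    return out


def _crop_rescale(img: np.ndarray, rng: np.random.Generator, keep: float) -> np.ndarray:
    h, w = img.shape
    ch, cw = max(1, int(keep * h)), max(1, int(keep * w))
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    crop = img[r0:r0 + ch, c0:c0 + cw]
    # nearest-neighbour upscale back to the raster size
    ri = np.minimum((np.arange(h) * ch) // h, ch - 1)
    ci = np.minimum((np.arange(w) * cw) // w, cw - 1)
    return crop[np.ix_(ri, ci)]


def augment_images(
    seq: Sequence[SpectrumImage],
    transform_fraction: float = 0.30,
    seed: int = 0,
    max_shift_frac: float = 0.10,
    max_zero_area: float = 0.10,
    crop_keep: float = 0.90,
) -> list[SpectrumImage]:
    """Apply one random transform to a random 30% subset of the frames.

    Each selected frame receives exactly one of {shift, zeroing, crop};
    unselected frames are returned bit-identical.  Deterministic given seed.
    """
    if not (0 <= transform_fraction <= 1):
        raise ValueError("transform_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(seq)
    n_sel = int(round(transform_fraction * n))
    selected = set(rng.choice(n, size=n_sel, replace=False).tolist()) if n_sel else set()
    out = []
    for i, im in enumerate(seq):
        if i in selected:
            which = int(rng.integers(0, 3))
            if which == 0:
                px = _shift(im.pixels, rng, max_shift_frac)
            elif which == 1:
                px = _zero_rect(im.pixels, rng, max_zero_area)
            else:
                px = _crop_rescale(im.pixels, rng, crop_keep)
            out.append(SpectrumImage(im.frame_index, px, im.rt_window))
        else:
            out.append(im)
    return out


def resize_and_stack(seq: Sequence[SpectrumImage], cfg: RasterConfig,
                     layer: str = PROTEOMIC, file_id: str = "") -> VolumeTensor:
    """Area-average each frame down to volume_size and stack along RT.

    Requires exactly ``frames_per_file`` frames (padding is the renderer's
    job) and an integer downsampling factor.
    """
    if len(seq) != cfg.frames_per_file:
        raise ValueError(
            f"expected {cfg.frames_per_file} frames, got {len(seq)}; "
            "pad/truncate in render_windows first"
        )
    if cfg.raster_size % cfg.volume_size:
        raise ValueError("raster_size must be an integer multiple of volume_size")
    f = cfg.raster_size // cfg.volume_size
    v = cfg.volume_size
    vol = np.empty((v, v, cfg.frames_per_file), dtype=np.float32)
    for i, im in enumerate(seq):
        vol[:, :, i] = im.pixels.reshape(v, f, v, f).mean(axis=(1, 3))
    return VolumeTensor(voxels=vol, layer=layer, file_id=file_id)


def file_to_volume(sf: SpectraFile, cfg: RasterConfig,
                   augment: bool = False, seed: int = 0) -> VolumeTensor:
    """Convenience: render, optionally augment, resize and stack one file."""
    seq = render_windows(sf, cfg)
    if augment:
        seq = augment_images(seq, seed=seed)
    return resize_and_stack(seq, cfg, layer=sf.omics_layer, file_id=sf.file_id)


def export_png(image: SpectrumImage, path: str | Path) -> Path:
    """Write one frame as a 16-bit grayscale PNG for inspection."""
    from PIL import Image

    path = Path(path)
    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray((arr * 65535).astype(np.uint16), mode="I;16").save(path)
    return path
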