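"""High-speed video handling and digital kymogram (DKG) extraction.

A digital kymogram is built by sampling one fixed scanline (a pixel row
crossing the glottis in the medial--lateral direction) from every frame of a
high-speed recording and stacking those rows over time.  Row ``r`` of the
kymogram is frame ``r`` of the video; columns are medial--lateral position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FrameStack",
    "PreprocessSettings",
    "Kymogram",
    "read_frames",
    "write_frames",
    "preprocess",
    "extract_kymogram",
    "select_scanline",
    "save_kymogram",
    "load_kymogram",
]


@dataclass
class FrameStack:
    """Monochrome frame sequence with its frame rate.

    ``frames`` is a ``(T, H, W)`` uint8 array; ``fps`` is frames per second.
    """

    frames: np.ndarray
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frames.dtype != np.uint8:
            self.frames = np.clip(np.rint(self.frames), 0, 255).astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def time_s(self, frame: int) -> float:
        """Time of a 0-based frame index in seconds."""
        return frame / self.fps


@dataclass(frozen=True)
class PreprocessSettings:
    """Brightness / contrast / gamma / rotation / resize settings.

    The transfer function is applied in the fixed order
    gamma -> contrast gain -> brightness offset -> rotation -> resize::

        out = clip(((in / 255) ** gamma) * 255 * contrast_gain + brightness_offset, 0, 255)

    ``rotation_deg`` rotates counter-clockwise; multiples of 90 degrees are
    exact (no interpolation).  ``target_size`` is ``(H, W)`` or ``None``;
    resizing uses area averaging so that downsizing (e.g. 960x720 -> 320x240)
    does not alias the fold edges.
    """

    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    gamma: float = 1.0
    rotation_deg: float = 0.0
    target_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.contrast_gain <= 0:
            raise ValueError("contrast_gain must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.brightness_offset == 0.0
            and self.contrast_gain == 1.0
            and self.gamma == 1.0
            and self.rotation_deg % 360 == 0.0
            and self.target_size is None
        )


@dataclass
class Kymogram:
    """Time x position intensity image sampled at one scanline."""

    rows: np.ndarray
    scanline_index: int
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows)
        if self.rows.ndim != 2 or self.rows.shape[0] < 1:
            raise ValueError("rows must be a non-empty (T, W) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.rows.shape[0]

    @property
    def width(self) -> int:
        return self.rows.shape[1]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _to_luma(frames: np.ndarray) -> np.ndarray:
    """Convert (T,H,W[,C]) to monochrome using Rec.601 luma weights."""
    if frames.ndim == 4:
        w = np.array([0.299, 0.587, 0.114])
        frames = frames[..., :3].astype(np.float64) @ w
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return frames


def write_frames(stack: FrameStack, path: str | Path) -> Path:
    """Write a frame stack to NPY (lossless), multipage TIFF (lossless),
    or MP4/AVI (requires the imageio ffmpeg plugin).

    NPY and TIFF writes drop a JSON sidecar (``<name>.<ext>.json``) holding
    the frame rate so the round trip needs no override.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, stack.frames)
        _sidecar_path(path).write_text(
            json.dumps({"fps": stack.fps, "source_id": stack.source_id})
        )
    elif suffix in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, stack.frames)
        _sidecar_path(path).write_text(
            json.dumps({"fps": stack.fps, "source_id": stack.source_id})
        )
    elif suffix in _VIDEO_SUFFIXES:
        try:
            import imageio.v3 as iio

            iio.imwrite(path, stack.frames, fps=stack.fps, plugin="pyav")
        except Exception:
            try:
                import imageio.v2 as iio2

                writer = iio2.get_writer(path, fps=stack.fps)
                for frame in stack.frames:
                    writer.append_data(frame)
                writer.close()
            except Exception as exc:  # pragma: no cover - depends on plugins
                raise RuntimeError(
                    f"cannot encode {suffix} video (no ffmpeg/pyav backend "
                    f"available); use .npy or .tif for lossless storage"
                ) from exc
    else:
        raise ValueError(f"unsupported frame-stack format: {suffix}")
    return path


def read_frames(path: str | Path, fps_override: float | None = None) -> FrameStack:
    """Read a frame stack from NPY, multipage TIFF, or MP4/AVI.

    ``fps`` is taken from the container metadata (video) or JSON sidecar
    (NPY/TIFF) unless ``fps_override`` is given; an input without any frame
    rate and no override is an error.  Color inputs are converted to luma.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    fps = fps_override
    source_id = str(path)
    if suffix == ".npy":
        frames = np.load(path)
    elif suffix in _TIFF_SUFFIXES:
        import tifffile

        frames = tifffile.imread(path)
    elif suffix in _VIDEO_SUFFIXES:
        try:
            import imageio.v3 as iio

            frames = np.asarray(iio.imread(path))
            if fps is None:
                meta = iio.immeta(path)
                fps = meta.get("fps")
        except FileNotFoundError:
            raise
        except Exception as exc:  # pragma: no cover - depends on plugins
            raise RuntimeError(
                f"cannot decode {suffix} video (no ffmpeg/pyav backend available)"
            ) from exc
    else:
        raise ValueError(f"unsupported frame-stack format: {suffix}")

    if suffix in {".npy"} | _TIFF_SUFFIXES and fps is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fps = meta.get("fps")
            source_id = meta.get("source_id", source_id)
    if fps is None:
        raise ValueError(f"{path}: no frame-rate metadata; pass fps_override")

    frames = _to_luma(np.asarray(frames))
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 1:
        raise ValueError(f"{path}: zero frames")
    return FrameStack(frames=frames, fps=float(fps), source_id=source_id)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(stack: FrameStack, settings: PreprocessSettings) -> FrameStack:
    """Apply gamma, gain, offset, rotation and optional resize, in that order."""
    if settings.is_identity:
        return FrameStack(stack.frames.copy(), stack.fps, stack.source_id)

    x = stack.frames.astype(np.float64) / 255.0
    x = x**settings.gamma * 255.0 * settings.contrast_gain + settings.brightness_offset
    x = np.clip(x, 0.0, 255.0)

    deg = settings.rotation_deg % 360.0
    if deg:
        if deg % 90 == 0:
            x = np.rot90(x, k=int(deg // 90), axes=(1, 2))
        else:
            from skimage.transform import rotate

            x = np.stack(
                [rotate(f, deg, resize=False, preserve_range=True) for f in x]
            )

    if settings.target_size is not None:
        from skimage.transform import resize_local_mean

        h, w = settings.target_size
        x = resize_local_mean(x, (x.shape[0], h, w))

    frames = np.clip(np.rint(x), 0, 255).astype(np.uint8)
    return FrameStack(frames, stack.fps, stack.source_id)


# ---------------------------------------------------------------------------
# DKG
# ---------------------------------------------------------------------------


def extract_kymogram(stack: FrameStack, scanline_index: int) -> Kymogram:
    """Sample one scanline from every frame: ``rows[r] = frames[r][scanline]``."""
    height = stack.frames.shape[1]
    if not 0 <= scanline_index < height:
        raise IndexError(
            f"scanline_index {scanline_index} out of range for height {height}"
        )
    rows = stack.frames[:, scanline_index, :].copy()
    return Kymogram(
        rows=rows,
        scanline_index=int(scanline_index),
        fps=stack.fps,
        source_id=stack.source_id,
    )


def select_scanline(
    stack: FrameStack,
    roi: tuple[int, int, int, int] | None = None,
) -> int:
    """Pick the row with maximal temporal intensity variance.

    The mid-membranous scanline is where the folds oscillate, hence where
    pixel intensities vary most over time.  ``roi`` is ``(r0, c0, r1, c1)``
    (half-open) restricting the search; default is the whole frame.
    """
    frames = stack.frames.astype(np.float64)
    t, h, w = frames.shape
    r0, c0, r1, c1 = roi if roi is not None else (0, 0, h, w)
    sub = frames[:, r0:r1, c0:c1]
    row_var = sub.var(axis=0).sum(axis=1)
    return int(r0 + np.argmax(row_var))


def save_kymogram(kym: Kymogram, path: str | Path, png: bool = False) -> Path:
    """Save as NPY + JSON metadata, optionally also a PNG for inspection."""
    path = Path(path)
    if path.suffix.lower() != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, kym.rows)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "fps": kym.fps,
                "scanline_index": kym.scanline_index,
                "source_id": kym.source_id,
            }
        )
    )
    if png:
        import imageio.v3 as iio

        iio.imwrite(path.with_suffix(".png"), np.asarray(kym.rows, dtype=np.uint8))
    return path


def load_kymogram(path: str | Path, fps_override: float | None = None) -> Kymogram:
    path = Path(path)
    rows = np.load(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fps = fps_override if fps_override is not None else meta.get("fps")
    if fps is None:
        raise ValueError(f"{path}: no fps metadata; pass fps_override")
    return Kymogram(
        rows=rows,
        scanline_index=int(meta.get("scanline_index", 0)),
        fps=float(fps),
        source_id=meta.get("source_id", str(path)),
    )
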