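"""Core ultrasound frame representation and preprocessing.

A sonomyographic classifier consumes B-mode ultrasound frames of the
residual forearm, digitized at 8 bits/pixel and downscaled to a fixed
100 (depth) x 140 (lateral) grid before classification.  This module owns
that representation: quantization to 8 bits, area (block-mean) downscaling,
row-major feature vectorization on a [0, 1] scale, and frame I/O as PNG
files or raw binary stacks with a JSON sidecar.

Conventions fixed here and relied on everywhere else:

* rows index depth (axial), columns index lateral position; 0-based;
* flattening is row-major, so feature ``k`` is pixel ``(k // 140, k % 140)``;
* every integer gray level is produced by rounding half away from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical frame geometry after preprocessing: 100 depth rows x 140
#: lateral columns, hence 14,000 features per frame.
FRAME_SHAPE: tuple[int, int] = (100, 140)
N_FEATURES: int = FRAME_SHAPE[0] * FRAME_SHAPE[1]

#: Dynamic range of an 8-bit frame, used as the default SSIM scale L.
DEFAULT_SCALE: int = 255


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero.

    numpy's ``round`` rounds halves to even; image pipelines conventionally
    round 127.5 up to 128, which is the behavior fixed here.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class Frame:
    """One 8-bit grayscale ultrasound frame.

    Parameters
    ----------
    pixels
        ``(100, 140)`` array of integer gray levels in [0, 255], stored
        as ``uint8``.
    scale
        Nominal dynamic range L used by similarity metrics (255 for
        8-bit data).
    """

    pixels: np.ndarray
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != FRAME_SHAPE:
            raise ValueError(
                f"Frame pixels must have shape {FRAME_SHAPE}, got {px.shape}"
            )
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("Frame pixels must be integers in [0, 255]")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("Frame pixels must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Frame):
            return NotImplemented
        return self.scale == other.scale and np.array_equal(self.pixels, other.pixels)


def quantize8(raw_image: np.ndarray, in_max: float) -> Frame:
    """Digitize a nonnegative real-valued image to 8 bits/pixel.

    Intensities are scaled by ``in_max`` (the full-scale input value),
    clipped to [0, 1], mapped to [0, 255] and rounded half away from zero.

    Raises
    ------
    ValueError
        If any input intensity is non-finite (the offending coordinate is
        named), if an intensity is negative, or if ``in_max`` is not
        positive.
    """
    raw = np.asarray(raw_image, dtype=float)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={raw.ndim}")
    if not in_max > 0:
        raise ValueError(f"in_max must be positive, got {in_max}")
    bad = ~np.isfinite(raw)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-finite intensity at pixel ({r}, {c})")
    if raw.min() < 0:
        r, c = np.argwhere(raw < 0)[0]
        raise ValueError(f"negative intensity at pixel ({r}, {c})")
    if raw.shape != FRAME_SHAPE:
        raise ValueError(
            f"quantize8 produces canonical {FRAME_SHAPE} frames; for other "
            "shapes use quantize8_array"
        )
    levels = round_half_away(255.0 * np.clip(raw / in_max, 0.0, 1.0))
    return Frame(levels.astype(np.uint8))


def quantize8_array(raw_image: np.ndarray, in_max: float) -> np.ndarray:
    """Like :func:`quantize8` but returns a bare ``uint8`` array of the
    input's shape (no 100x140 constraint)."""
    raw = np.asarray(raw_image, dtype=float)
    if not in_max > 0:
        raise ValueError(f"in_max must be positive, got {in_max}")
    bad = ~np.isfinite(raw)
    if bad.any():
        idx = tuple(np.argwhere(bad)[0])
        raise ValueError(f"non-finite intensity at pixel {idx}")
    return round_half_away(255.0 * np.clip(raw / in_max, 0.0, 1.0)).astype(np.uint8)


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Sparse-ish (n_out, n_in) matrix of exact interval-overlap weights for
    1-D area resampling; each row sums to 1."""
    if n_in < n_out:
        raise ValueError(f"cannot area-downscale {n_in} -> {n_out} (upscaling)")
    w = np.zeros((n_out, n_in))
    step = n_in / n_out
    for i in range(n_out):
        lo, hi = i * step, (i + 1) * step
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                w[i, j] = overlap / step
    return w


def downscale(raw_frame: np.ndarray, target: tuple[int, int] = FRAME_SHAPE) -> Frame:
    """Downscale a raw image to the canonical 100x140 grid.

    Uses exact area (block-mean) resampling — each output pixel is the
    mean of the input region it covers — followed by 8-bit quantization.
    An input already at the target geometry passes through unchanged.

    Raises
    ------
    ValueError
        If the raw image is smaller than the target in either dimension.
    """
    raw = np.asarray(raw_frame, dtype=float)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={raw.ndim}")
    h, w = raw.shape
    th, tw = target
    if h < th or w < tw:
        raise ValueError(
            f"raw frame {raw.shape} is smaller than target {target}; "
            "upscaling is not supported"
        )
    if (h, w) == (th, tw):
        resampled = raw
    else:
        resampled = _area_weights(h, th) @ raw @ _area_weights(w, tw).T
    levels = round_half_away(np.clip(resampled, 0.0, 255.0))
    return Frame(levels.astype(np.uint8))


def vectorize(frame: Frame) -> np.ndarray:
    """Row-major flattening of a frame, rescaled to [0, 1].

    Feature ``k`` equals ``pixels[k // 140, k % 140] / 255``; keeping the
    classifier's feature scale in [0, 1] makes covariance conditioning
    independent of bit depth.
    """
    if not isinstance(frame, Frame):
        raise TypeError("vectorize expects a Frame")
    return frame.pixels.astype(float).ravel() / 255.0


def devectorize(values: np.ndarray, scale: float = DEFAULT_SCALE) -> Frame:
    """Inverse of :func:`vectorize` (exact on quantized data)."""
    v = np.asarray(values, dtype=float)
    if v.shape != (N_FEATURES,):
        raise ValueError(f"feature vector must have length {N_FEATURES}")
    if v.min() < 0 or v.max() > 1:
        raise ValueError("feature values must lie in [0, 1]")
    levels = round_half_away(v * 255.0).reshape(FRAME_SHAPE)
    return Frame(levels.astype(np.uint8), scale=scale)


# ---------------------------------------------------------------------------
# I/O: PNG per frame, or raw uint8 stack + JSON sidecar
# ---------------------------------------------------------------------------

def write_png(frame: Frame, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), frame.pixels)


def read_png(path: str | Path) -> Frame:
    import imageio.v3 as iio

    px = np.asarray(iio.imread(Path(path)))
    if px.ndim == 3:  # collapse redundant channels from RGB-saved grayscale
        px = px[..., 0]
    return Frame(px.astype(np.uint8))


def write_stack(
    frames: list[Frame],
    path: str | Path,
    frame_rate_hz: float | None = None,
    labels: dict | None = None,
) -> None:
    """Write frames as a raw uint8 stack ``path`` with sidecar ``path + '.json'``.

    The sidecar records shape, frame count, frame rate and arbitrary label
    metadata so a stack is self-describing.
    """
    path = Path(path)
    stack = np.stack([f.pixels for f in frames])
    stack.tofile(path)
    sidecar = {
        "n_frames": len(frames),
        "shape": list(FRAME_SHAPE),
        "dtype": "uint8",
        "frame_rate_hz": frame_rate_hz,
        "labels": labels or {},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> tuple[list[Frame], dict]:
    """Read a raw stack written by :func:`write_stack`; returns (frames, sidecar)."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    n = sidecar["n_frames"]
    shape = tuple(sidecar["shape"])
    data = np.fromfile(path, dtype=np.uint8)
    stack = data.reshape((n, *shape))
    return [Frame(img) for img in stack], sidecar
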