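"""Reading, writing and aligning multi-channel image stacks.

A :class:`ChannelStack` holds one or more named channels, each a sequence of
2-D float frames normalized to [0, 1].  The frame axis is either time (a
movie) or depth (a Z-stack).  Coordinates are (row, col), 0-based, throughout
the package.

Multi-page TIFFs are assumed channel-interleaved: with channels ``(A, B)``
pages are ordered A0, B0, A1, B1, ...  Channel order is always supplied by the
caller (CLI flag or config key), never guessed from embedded metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ConfigError, DataError, DegenerateInputError, StructuralError

__all__ = [
    "ChannelStack",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "register_translation",
]


@dataclass
class ChannelStack:
    """Named multi-channel image sequence with acquisition metadata.

    Parameters
    ----------
    channels
        Mapping channel-name -> float array of shape (n_frames, H, W) with
        values in [0, 1].
    axis_kind
        ``"time"`` for a movie, ``"z"`` for a depth stack.
    frame_interval_s
        Seconds between frames when ``axis_kind == "time"``.  The default of
        75 s matches a typical intravital time-lapse acquisition interval.
    pixel_size_um
        Micrometres per pixel.
    bit_depth_source
        Integer bit depth of the file the stack was read from (used to undo
        the [0, 1] normalization on write).
    """

    channels: dict[str, np.ndarray]
    axis_kind: str = "time"
    frame_interval_s: float = 75.0
    pixel_size_um: float = 1.0
    bit_depth_source: int = 16

    def __post_init__(self) -> None:
        if self.axis_kind not in ("time", "z"):
            raise ConfigError(f"axis_kind must be 'time' or 'z', got {self.axis_kind!r}")
        if self.axis_kind == "time" and not self.frame_interval_s > 0:
            raise ConfigError("frame_interval_s must be > 0 for a time stack")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len({s for s in shapes.values()}) > 1:
            raise StructuralError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise StructuralError(f"channel {name!r} must be (frames, H, W), got {arr.shape}")
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise DataError(f"channel {name!r} has values outside [0, 1]")
            self.channels[name] = arr

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    def frame(self, channel: str, index: int) -> np.ndarray:
        if channel not in self.channels:
            raise ConfigError(f"unknown channel {channel!r}; have {self.channel_names}")
        n = self.n_frames
        if not (0 <= index < n):
            raise StructuralError(f"frame index {index} out of range [0, {n})")
        return self.channels[channel][index]


def _bit_depth_of(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if dtype.kind not in "ui":
        raise DataError(f"expected an integer pixel type, got {dtype}")
    return dtype.itemsize * 8


def read_stack(
    path,
    channel_names: list[str],
    *,
    axis_kind: str = "time",
    frame_interval_s: float = 75.0,
    pixel_size_um: float = 1.0,
) -> ChannelStack:
    """Read a channel-interleaved multi-page TIFF into a :class:`ChannelStack`.

    Intensities are normalized to [0, 1] by dividing by ``2**bit_depth - 1``.

    Raises
    ------
    StructuralError
        If the page count is not divisible by the number of channels.
    """
    if not channel_names:
        raise ConfigError("channel_names must be non-empty")
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise StructuralError(f"expected a stack of 2-D pages, got shape {pages.shape}")
    n_chan = len(channel_names)
    if pages.shape[0] % n_chan:
        raise StructuralError(
            f"page count {pages.shape[0]} not divisible by channel count {n_chan}"
        )
    bit_depth = _bit_depth_of(pages.dtype)
    scale = float(2**bit_depth - 1)
    channels = {
        name: pages[i::n_chan].astype(float) / scale for i, name in enumerate(channel_names)
    }
    return ChannelStack(
        channels=channels,
        axis_kind=axis_kind,
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
        bit_depth_source=bit_depth,
    )


def write_stack(path, stack: ChannelStack) -> None:
    """Write a stack back to a channel-interleaved multi-page TIFF.

    Pixels are re-quantized to the stack's source bit depth, so a read/write
    round trip is lossless up to ``1 / (2**bit_depth - 1)``.
    """
    scale = 2**stack.bit_depth_source - 1
    dtype = np.uint8 if stack.bit_depth_source <= 8 else np.uint16
    if stack.bit_depth_source > 16:
        dtype = np.uint32
    names = stack.channel_names
    pages = np.empty(
        (stack.n_frames * len(names),) + stack.frame_shape, dtype=dtype
    )
    for i, name in enumerate(names):
        pages[i :: len(names)] = np.round(stack.channels[name] * scale).astype(dtype)
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_mask(path) -> np.ndarray:
    """Read a binary mask from PNG or TIFF; any nonzero pixel is foreground."""
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse RGB(A)
        arr = arr[..., :3].max(axis=-1)
    if arr.ndim != 2:
        raise StructuralError(f"mask must be 2-D, got shape {arr.shape}")
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit image (foreground = 255)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise StructuralError(f"mask must be 2-D, got shape {mask.shape}")
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def _shift_frame(frame: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Integer-pixel translation; pixels exposed at the edges are set to 0."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    rs, cs = max(drow, 0), max(dcol, 0)
    re, ce = min(h + drow, h), min(w + dcol, w)
    if re > rs and ce > cs:
        out[rs:re, cs:ce] = frame[rs - drow : re - drow, cs - dcol : ce - dcol]
    return out


def _best_integer_shift(reference: np.ndarray, moving: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Integer (drow, dcol) maximizing the cross-correlation of ``moving``
    shifted onto ``reference``, searched over |shift| <= max_shift.

    Correlation is computed on mean-subtracted images via FFT.  Ties are
    broken by the smallest Euclidean shift, then lexicographically.
    """
    a = reference - reference.mean()
    b = moving - moving.mean()
    # corr(dr, dc) = sum_xy a[r, c] * b[r - dr, c - dc]
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    corr = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    rows = np.fft.fftfreq(a.shape[0], 1 / a.shape[0]).astype(int)
    cols = np.fft.fftfreq(a.shape[1], 1 / a.shape[1]).astype(int)
    rsel = np.abs(rows) <= max_shift
    csel = np.abs(cols) <= max_shift
    sub = corr[np.ix_(rsel, csel)]
    rr, cc = np.meshgrid(rows[rsel], cols[csel], indexing="ij")
    best = sub.max()
    ties = np.isclose(sub, best, rtol=0, atol=1e-9 * max(1.0, abs(best)))
    cand = np.column_stack([rr[ties], cc[ties]])
    order = np.lexsort((cand[:, 1], cand[:, 0], (cand**2).sum(axis=1)))
    dr, dc = cand[order[0]]
    return int(dr), int(dc)


def register_translation(
    stack: ChannelStack, reference_channel: str, *, max_shift: int = 20
) -> tuple[ChannelStack, list[tuple[int, int]]]:
    """Correct small frame-to-frame translational drift.

    Each frame of ``reference_channel`` is aligned to frame 0 by the integer
    pixel shift maximizing cross-correlation; the same shift is applied to
    every channel.  Returns the corrected stack and the applied
    ``(drow, dcol)`` offsets, frame 0 being ``(0, 0)``.

    Raises
    ------
    DegenerateInputError
        If the reference frame is constant (correlation peak undefined).
    """
    if reference_channel not in stack.channels:
        raise ConfigError(f"unknown reference channel {reference_channel!r}")
    ref_frames = stack.channels[reference_channel]
    if stack.n_frames < 2:
        return stack, [(0, 0)] * stack.n_frames
    ref0 = ref_frames[0]
    if np.ptp(ref0) == 0:
        raise DegenerateInputError("reference frame 0 is constant; registration undefined")
    offsets: list[tuple[int, int]] = [(0, 0)]
    for i in range(1, stack.n_frames):
        frame = ref_frames[i]
        if np.ptp(frame) == 0:
            raise DegenerateInputError(f"reference frame {i} is constant; registration undefined")
        offsets.append(_best_integer_shift(ref0, frame, max_shift))
    channels = {}
    for name, arr in stack.channels.items():
        out = arr.copy()
        for i, (dr, dc) in enumerate(offsets):
            if (dr, dc) != (0, 0):
                out[i] = _shift_frame(arr[i], dr, dc)
        channels[name] = out
    corrected = ChannelStack(
        channels=channels,
        axis_kind=stack.axis_kind,
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
        bit_depth_source=stack.bit_depth_source,
    )
    return corrected, offsets
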