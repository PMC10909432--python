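"""Multi-echo magnitude reconstruction utilities.

Square-root-of-sum-of-squares (SqrtSOS) combination, centred k-space
zero-filling and analysis-echo selection. SqrtSOS is implemented as a
generic axis reducer so the same operator serves multi-channel combination
and optional echo combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth.mri import EchoSeries

__all__ = ["ChannelStack", "sqrt_sos", "zero_fill", "crop_kspace", "zero_fill_image", "select_echo"]


@dataclass
class ChannelStack:
    """Per-channel (complex or magnitude) multi-echo data, channel axis first."""

    data: np.ndarray  # (channel, echo, x, y, z)
    echo_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape[0] < 1:
            raise ValueError("at least one channel required")


def sqrt_sos(data: np.ndarray | ChannelStack, axis: int = 0) -> np.ndarray:
    """Square root of the sum of squared magnitudes along ``axis``.

    For a single-element axis this is the magnitude identity; for complex
    input the result is invariant to a global phase on any channel.
    """
    if isinstance(data, ChannelStack):
        data = data.data
    data = np.asarray(data)
    if data.shape[axis] == 0:
        raise ValueError("cannot combine along an empty axis")
    return np.sqrt(np.sum(np.abs(data).astype(float) ** 2, axis=axis))


def _pad_slices(source: tuple[int, ...], target: tuple[int, ...]) -> tuple[slice, ...]:
    """Centred (floor-split) embedding of a source box inside a target box."""
    slices = []
    for s, t in zip(source, target):
        if t < s:
            raise ValueError(f"target size {t} smaller than source {s}")
        before = (t - s) // 2
        slices.append(slice(before, before + s))
    return tuple(slices)


def zero_fill(kspace: np.ndarray, target_matrix: tuple[int, ...]) -> np.ndarray:
    """Embed a centred-DC k-space array in a larger zero matrix.

    Padding is floor-split per axis: ``before = (target - source) // 2``.
    Total k-space energy is conserved exactly (only zeros are added).
    """
    kspace = np.asarray(kspace)
    target_matrix = tuple(int(t) for t in target_matrix)
    if len(target_matrix) != kspace.ndim:
        raise ValueError("target_matrix rank must match k-space rank")
    out = np.zeros(target_matrix, dtype=kspace.dtype)
    out[_pad_slices(kspace.shape, target_matrix)] = kspace
    return out


def crop_kspace(kspace: np.ndarray, source_matrix: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`zero_fill`: extract the centred source box."""
    return np.asarray(kspace)[_pad_slices(tuple(int(s) for s in source_matrix), np.asarray(kspace).shape)]


def zero_fill_image(image: np.ndarray, target_matrix: tuple[int, ...]) -> np.ndarray:
    """Zero-fill interpolate an image to a finer grid via k-space padding.

    Amplitudes are preserved (the added Fourier coefficients are zero and
    the inverse transform is rescaled by the matrix-size ratio), so a
    structure at the grid centre keeps its peak magnitude.
    """
    image = np.asarray(image)
    k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image)))
    kp = zero_fill(k, target_matrix)
    scale = np.prod(target_matrix) / image.size
    out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(kp))) * scale
    return np.abs(out) if np.isrealobj(image) else out


def select_echo(
    series: EchoSeries | np.ndarray, mode: str = "single", index: int = -1
) -> np.ndarray:
    """Pick or combine echoes into one analysis volume.

    ``mode='single'`` returns echo ``index`` (default last: the longest TE
    maximises T2* hypointensity contrast); ``'mean'`` averages across
    echoes; ``'sos'`` combines them with SqrtSOS.
    """
    data = series.data if isinstance(series, EchoSeries) else np.asarray(series)
    n = data.shape[0]
    if mode == "single":
        if not -n <= index < n:
            raise IndexError(f"echo index {index} out of range for {n} echoes")
        return data[index]
    if mode == "mean":
        return data.mean(axis=0)
    if mode == "sos":
        return sqrt_sos(data, axis=0)
    raise ValueError(f"unknown echo mode {mode!r} (use 'single', 'mean' or 'sos')")
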