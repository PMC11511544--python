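"""Per-channel time-series smoothing: width-5 moving average and σ=2 Gaussian.

Two edge policies are exposed.  ``complete_only`` emits a value only where
the full window fits inside the series (output length n − window + 1 for the
moving average); it is the convention under which the packaged filtered
tables align with the raw tables.  ``reflect`` pads by boundary reflection
and preserves length, which is what a streaming pipeline wants.

The published filtered tables were cut from a longer underlying recording,
so their rows correspond to complete windows that extend one sample past
each printed row (filtered row i = mean of raw rows i+1..i+5); that
alignment is established by an offset-search oracle in the test suite, not
assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .session_io import CHANNELS, PhaseSession

__all__ = [
    "FilterKind",
    "EdgePolicy",
    "FilterSpec",
    "moving_average",
    "gaussian_kernel",
    "gaussian_smooth",
    "smooth_session",
]


class FilterKind(str, Enum):
    MOVING_AVERAGE = "moving_average"
    GAUSSIAN = "gaussian"


class EdgePolicy(str, Enum):
    #: emit only outputs whose window lies entirely inside the series
    COMPLETE_ONLY = "complete_only"
    #: reflect-pad the boundaries; output length equals input length
    REFLECT = "reflect"


@dataclass(frozen=True)
class FilterSpec:
    """Configuration of one smoothing filter.

    ``window`` (odd, default 5) applies to the moving average; ``sigma``
    (default 2) and ``truncate`` (kernel half-width in sigmas, default 4)
    apply to the Gaussian.
    """

    kind: FilterKind = FilterKind.MOVING_AVERAGE
    window: int = 5
    sigma: float = 2.0
    truncate: float = 4.0
    edge_policy: EdgePolicy = EdgePolicy.REFLECT

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.truncate > 0:
            raise ValueError(f"truncate must be positive, got {self.truncate}")

    @property
    def label(self) -> str:
        if self.kind is FilterKind.MOVING_AVERAGE:
            return f"ma{self.window}"
        return f"gauss{self.sigma:g}"


def moving_average(
    series: Sequence[float],
    window: int = 5,
    edge_policy: EdgePolicy = EdgePolicy.COMPLETE_ONLY,
) -> np.ndarray:
    """Unweighted sliding mean.

    Under ``complete_only`` output j is the mean of inputs j..j+window−1
    (0-based), so the result has n − window + 1 values and requires
    n ≥ window.  Under ``reflect`` the window is centred and the series is
    reflect-padded, preserving length.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    edge_policy = EdgePolicy(edge_policy)
    if edge_policy is EdgePolicy.COMPLETE_ONLY:
        if len(x) < window:
            raise ValueError(
                f"series of length {len(x)} shorter than window {window}"
            )
        return np.convolve(x, np.full(window, 1.0 / window), mode="valid")
    return ndimage.uniform_filter1d(x, size=window, mode="reflect")


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized discrete Gaussian kernel of half-width ⌈truncate·sigma⌉."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = int(math.ceil(truncate * sigma))
    k = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def gaussian_smooth(
    series: Sequence[float],
    sigma: float = 2.0,
    truncate: float = 4.0,
    edge_policy: EdgePolicy = EdgePolicy.REFLECT,
) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel.

    ``reflect`` delegates to :func:`scipy.ndimage.gaussian_filter1d`;
    ``complete_only`` is a valid-mode convolution and shortens the series by
    twice the kernel half-width.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be one-dimensional and non-empty")
    edge_policy = EdgePolicy(edge_policy)
    kernel = gaussian_kernel(sigma, truncate)
    if edge_policy is EdgePolicy.COMPLETE_ONLY:
        if len(x) < len(kernel):
            raise ValueError(
                f"series of length {len(x)} shorter than kernel {len(kernel)}"
            )
        return np.convolve(x, kernel, mode="valid")
    # ndimage's radius matches ceil(truncate * sigma) used in gaussian_kernel
    return ndimage.gaussian_filter1d(
        x, sigma=sigma, mode="reflect", radius=int(math.ceil(truncate * sigma))
    )


def _apply(spec: FilterSpec, x: np.ndarray) -> np.ndarray:
    if spec.kind is FilterKind.MOVING_AVERAGE:
        return moving_average(x, spec.window, spec.edge_policy)
    return gaussian_smooth(x, spec.sigma, spec.truncate, spec.edge_policy)


def smooth_session(session: PhaseSession, spec: FilterSpec) -> PhaseSession:
    """Smooth every measurement channel of a session independently.

    The alert column is never smoothed — a filtered alert flag is
    meaningless; downstream code recomputes flags from the smoothed vitals.
    Under ``complete_only`` the session shortens to the number of complete
    windows and samples are re-indexed from 1.
    """
    smoothed = {c: _apply(spec, session.channel(c)) for c in CHANNELS}
    # averaging cannot leave the data range, but guard against FP dust
    smoothed["speed_cm_s"] = np.clip(smoothed["speed_cm_s"], 0.0, None)
    return session.with_channels(**smoothed)
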