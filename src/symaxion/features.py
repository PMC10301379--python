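"""Feature extraction: band filtering, differential entropy, and the
symmetric difference / quotient matrices.

The method characterises emotional state through hemispheric asymmetry.  Two
per-epoch descriptions of the 62-channel signal are built on the 9x9 electrode
grid:

* OEF (original EEG feature): the raw sample values, one grid per time point
  (depth T = 200 for a 1-s epoch at 200 Hz);
* DE: per-band differential entropy, one grid per frequency band
  (depth B = 5: delta, theta, alpha, beta, gamma).

For a Gaussian signal the differential entropy of a 1-s window is
``h = 0.5 * ln(2*pi*e*sigma^2)`` (nats), so band-power ratios between mirrored
electrodes appear as additive DE differences.  From either description two
asymmetry maps are derived using the 27 mirror pairs: the subtract symmetric
matrix (SSM, left minus right and right minus left) and the quotient symmetric
matrix (QSM, left over right and right over left).  Midline electrodes are
excluded, so SSM/QSM grids carry at most 54 nonzero cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import ElectrodeLayout, grid_to_vector, vector_to_grid

#: Variance floor applied before taking logs, in squared signal units.
VAR_FLOOR = 1e-12
#: Magnitude below which a quotient denominator is clamped.
QUOTIENT_EPS = 1e-6

KINDS = ("OEF", "DE", "SSM_OEF", "QSM_OEF", "SSM_DE", "QSM_DE")
#: Kinds whose grids carry lateral (non-midline) cells only.
SYMMETRIC_KINDS = ("SSM_OEF", "QSM_OEF", "SSM_DE", "QSM_DE")


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges [{self.low}, {self.high}]")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 50.0),
)


@dataclass
class EpochSet:
    """Segmented EEG: ``data`` is trials x channels x samples (microvolts)."""

    data: np.ndarray
    sampling_rate: float
    labels: np.ndarray
    class_names: tuple[str, ...]
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.labels.size and not (
            0 <= self.labels.min() and self.labels.max() < len(self.class_names)
        ):
            raise ValueError("labels outside class range")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class FeatureStack:
    """A named stack of 2-D feature maps: ``maps`` is epochs x depth x 9 x 9."""

    kind: str
    maps: np.ndarray
    layout: ElectrodeLayout = field(repr=False)
    normalized: bool = False
    band_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("maps must be epochs x depth x H x W")

    @property
    def depth(self) -> int:
        return self.maps.shape[1]

    @property
    def support(self) -> np.ndarray:
        """Mask of grid cells that can be nonzero for this kind."""
        if self.kind in SYMMETRIC_KINDS:
            return self.layout.lateral_mask
        return self.layout.occupancy


def design_bandpass(band: BandSpec, sampling_rate: float, order: int = 4) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if band.high > nyq:
        raise ValueError(f"band {band.name} upper edge {band.high} Hz exceeds Nyquist {nyq} Hz")
    return signal.butter(order, [band.low, band.high], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(epochs: EpochSet, band: BandSpec, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass filter of every trial and channel."""
    sos = design_bandpass(band, epochs.sampling_rate, order)
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=filtered)


def differential_entropy(window: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gaussian differential entropy 0.5*ln(2*pi*e*var) along ``axis`` (nats).

    The variance is the population estimate over the window.  Windows with
    (near-)zero variance are floored at ``VAR_FLOOR`` with a warning, so a
    flat channel produces a large negative value instead of -inf.
    """
    window = np.asarray(window, dtype=float)
    if window.shape[axis] < 2:
        raise ValueError("window must contain at least 2 samples")
    var = window.var(axis=axis)
    if np.any(var < VAR_FLOOR):
        warnings.warn("zero-variance window; variance floored", RuntimeWarning, stacklevel=2)
        var = np.maximum(var, VAR_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def de_stack(
    epochs: EpochSet,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    layout: ElectrodeLayout | None = None,
) -> FeatureStack:
    """Per-epoch stack of per-band differential-entropy grids (depth = #bands)."""
    if layout is None:
        from .montage import build_default_layout

        layout = build_default_layout()
    if epochs.n_channels != layout.n_channels:
        raise ValueError("epoch channel count does not match layout")
    de = np.stack(
        [differential_entropy(bandpass(epochs, b).data) for b in bands], axis=1
    )  # epochs x bands x channels
    return FeatureStack("DE", vector_to_grid(de, layout), layout, band_names=tuple(b.name for b in bands))


def oef_stack(epochs: EpochSet, layout: ElectrodeLayout | None = None) -> FeatureStack:
    """Per-epoch stack of raw-signal grids, one grid per time sample."""
    if layout is None:
        from .montage import build_default_layout

        layout = build_default_layout()
    if epochs.n_channels != layout.n_channels:
        raise ValueError("epoch channel count does not match layout")
    if epochs.n_samples != int(round(epochs.sampling_rate)):
        raise ValueError(
            f"raw-signal grids are defined on 1-s epochs: expected "
            f"{int(round(epochs.sampling_rate))} samples, got {epochs.n_samples}"
        )
    # move the sample axis in front of the channel axis before gridding
    per_sample = np.moveaxis(epochs.data, 2, 1)  # epochs x samples x channels
    return FeatureStack("OEF", vector_to_grid(per_sample, layout), layout)


def symmetric_subtract(values: np.ndarray) -> np.ndarray:
    """Mirror differences d of a lateral-ordered vector (last axis, length 2k).

    ``d[i] = v[i] - v[i+k]`` for the left half and ``d[i+k] = v[i+k] - v[i]``
    for the right half, so the result is antisymmetric under pair swap.
    """
    values = np.asarray(values)
    k2 = values.shape[-1]
    if k2 % 2:
        raise ValueError(f"lateral vector length must be even, got {k2}")
    k = k2 // 2
    left, right = values[..., :k], values[..., k:]
    return np.concatenate([left - right, right - left], axis=-1)


def symmetric_quotient(values: np.ndarray, eps: float = QUOTIENT_EPS) -> np.ndarray:
    """Mirror quotients q: ``q[i] = v[i] / v[i+k]`` and ``q[i+k] = v[i+k] / v[i]``.

    Denominators with magnitude below ``eps`` are clamped to ``sign * eps``
    (exact zeros count as positive), so raw EEG zero crossings never divide
    by zero.
    """
    values = np.asarray(values, dtype=float)
    k2 = values.shape[-1]
    if k2 % 2:
        raise ValueError(f"lateral vector length must be even, got {k2}")
    k = k2 // 2
    guarded = np.where(
        np.abs(values) < eps, np.where(values < 0, -eps, eps), values
    )
    left, right = values[..., :k], values[..., k:]
    gleft, gright = guarded[..., :k], guarded[..., k:]
    return np.concatenate([left / gright, right / gleft], axis=-1)


def _lateral_cells(layout: ElectrodeLayout) -> tuple[list[int], list[int]]:
    cells = [layout.grid_cell[i] for i in layout.lateral_order]
    rows, cols = zip(*cells)
    return list(rows), list(cols)


def _symmetric_stack(stack: FeatureStack, func, kind_prefix: str) -> FeatureStack:
    if stack.kind not in ("OEF", "DE"):
        raise ValueError(f"symmetric maps are derived from OEF or DE stacks, not {stack.kind}")
    layout = stack.layout
    rows, cols = _lateral_cells(layout)
    lateral = stack.maps[..., rows, cols]  # epochs x depth x 54, lateral order
    out_vals = func(lateral)
    out = np.zeros_like(stack.maps)
    out[..., rows, cols] = out_vals
    return FeatureStack(f"{kind_prefix}_{stack.kind}", out, layout, band_names=stack.band_names)


def ssm_stack(stack: FeatureStack) -> FeatureStack:
    """Subtract symmetric matrix stack: per-slice mirror differences on the grid."""
    return _symmetric_stack(stack, symmetric_subtract, "SSM")


def qsm_stack(stack: FeatureStack, eps: float = QUOTIENT_EPS) -> FeatureStack:
    """Quotient symmetric matrix stack: per-slice mirror quotients on the grid."""
    return _symmetric_stack(stack, lambda v: symmetric_quotient(v, eps), "QSM")


def normalize(stack: FeatureStack) -> FeatureStack:
    """Min-max scale each depth slice to [0, 1] over its supported cells.

    Constant slices map to 0.5; cells outside the support stay exactly 0.
    """
    mask = stack.support
    rows, cols = np.nonzero(mask)
    vals = stack.maps[..., rows, cols]  # epochs x depth x n_support
    lo = vals.min(axis=-1, keepdims=True)
    hi = vals.max(axis=-1, keepdims=True)
    span = hi - lo
    flat = span <= 0
    span = np.where(flat, 1.0, span)
    scaled = np.where(flat, 0.5, (vals - lo) / span)
    out = np.zeros_like(stack.maps)
    out[..., rows, cols] = scaled
    return replace(stack, maps=out, normalized=True)
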