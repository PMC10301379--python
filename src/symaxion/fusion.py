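"""Feature fusion: spatial upsampling of the 9x9 maps to 64x64, depth
unification to 50 slices per feature kind, and concatenation into the fused
network input of depth 200.

Both resamplings are linear maps with fixed node geometry, so they are
precomputed once as small operator matrices: spatial interpolation is a
separable bicubic spline (64x9 operator applied to both grid axes, anchors at
0, 63/8, ..., 63 so corners are pinned), and depth unification is 1-D linear
interpolation between uniformly spaced source and target positions.  Because
the two operators act on different axes they commute exactly; the preparation
pipeline exploits this by unifying depth before upsampling, which avoids
materialising the deep raw-signal stack at full spatial size.

Structural zeros of the 9x9 grids are interpolated like ordinary values; the
network input therefore has smooth skirts around the scalp, not a hard mask.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline

from .features import FeatureStack

#: Fixed kind order of the fused tensor.
FUSION_ORDER = ("SSM_OEF", "QSM_OEF", "SSM_DE", "QSM_DE")
TARGET_DEPTH = 50
SPATIAL_SIZE = 64


@lru_cache(maxsize=None)
def spatial_operator(n_nodes: int = 9, size: int = SPATIAL_SIZE) -> np.ndarray:
    """The (size x n_nodes) 1-D cubic-spline interpolation matrix.

    Nodes sit at ``linspace(0, size - 1, n_nodes)``; evaluating the
    not-a-knot cubic spline of each unit impulse at the integer targets gives
    the operator columns.  Node positions are reproduced exactly and linear
    ramps are interpolated without error.
    """
    nodes = np.linspace(0.0, size - 1.0, n_nodes)
    targets = np.arange(size, dtype=float)
    op = np.empty((size, n_nodes))
    eye = np.eye(n_nodes)
    for j in range(n_nodes):
        op[:, j] = CubicSpline(nodes, eye[j], bc_type="not-a-knot")(targets)
    return op


def upsample_spatial(maps: np.ndarray, size: int = SPATIAL_SIZE) -> np.ndarray:
    """Bicubic-spline upsample of trailing (H, W) axes to (size, size)."""
    maps = np.asarray(maps, dtype=float)
    if not np.all(np.isfinite(maps)):
        raise ValueError("non-finite values in input maps")
    a = spatial_operator(maps.shape[-2], size)
    b = spatial_operator(maps.shape[-1], size)
    return np.einsum("ij,...jk,lk->...il", a, maps, b, optimize=True)


@lru_cache(maxsize=None)
def depth_operator(depth: int, target: int = TARGET_DEPTH) -> np.ndarray:
    """The (target x depth) linear-interpolation matrix along the depth axis.

    Source and target slices sit at uniform positions on [0, 1] with the
    endpoints shared, so the first and last slices are preserved and a
    depth-constant stack stays constant.  Identity when depth == target.
    """
    if depth < 2:
        raise ValueError("depth resampling requires at least 2 source slices")
    src = np.linspace(0.0, 1.0, depth)
    dst = np.linspace(0.0, 1.0, target)
    op = np.zeros((target, depth))
    idx = np.clip(np.searchsorted(src, dst, side="right") - 1, 0, depth - 2)
    w = (dst - src[idx]) / (src[idx + 1] - src[idx])
    rows = np.arange(target)
    op[rows, idx] = 1.0 - w
    op[rows, idx + 1] = w
    return op


def unify_depth(stack: np.ndarray, target: int = TARGET_DEPTH) -> np.ndarray:
    """Resample axis -3 (depth) of a ... x depth x H x W array to ``target``.

    The canonical source depths are 200 (raw-signal stacks) and 5 (DE
    stacks); other depths are resampled all the same, with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    depth = stack.shape[-3]
    if depth not in (200, 5, target):
        warnings.warn(f"unusual source depth {depth}", RuntimeWarning, stacklevel=2)
    op = depth_operator(depth, target)
    return np.einsum("td,...dhw->...thw", op, stack, optimize=True)


def fuse(stacks: dict[str, np.ndarray], kinds: tuple[str, ...] = FUSION_ORDER) -> np.ndarray:
    """Concatenate depth-unified, upsampled stacks along depth in fixed order.

    ``kinds`` may be a subset of the canonical four for ablation runs; the
    output depth is ``50 * len(kinds)`` (200 for the full fusion).
    """
    if not kinds:
        raise ValueError("at least one feature kind is required")
    missing = [k for k in kinds if k not in stacks]
    if missing:
        raise KeyError(f"missing feature kinds: {missing}")
    return np.concatenate([np.asarray(stacks[k], dtype=float) for k in kinds], axis=-3)


def prepare(
    feature_stacks: dict[str, FeatureStack],
    kinds: tuple[str, ...] = FUSION_ORDER,
    target_depth: int = TARGET_DEPTH,
    spatial_size: int = SPATIAL_SIZE,
    dtype=np.float32,
) -> np.ndarray:
    """Full fusion pipeline: 9x9 stacks -> (epochs, 50*len(kinds), S, S).

    Depth is unified on the small grids first (the operators commute), then
    each stack is spline-upsampled and the kinds are concatenated in the
    canonical order.
    """
    processed = {}
    for kind in kinds:
        maps = feature_stacks[kind].maps
        processed[kind] = upsample_spatial(unify_depth(maps, target_depth), spatial_size).astype(dtype)
    return fuse(processed, kinds).astype(dtype)
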