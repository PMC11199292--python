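"""Topographic map primitives: zero-mean scalp potential vectors.

A topographic map is the instantaneous electric potential over the sensors,
re-referenced to the average (zero mean across channels). All clustering and
back-fitting operate on these vectors, usually normalized to unit Euclidean
norm so that the Pearson spatial correlation reduces to a dot product.
"""

from __future__ import annotations

import numpy as np

from .montage import SensorMontage

__all__ = [
    "zero_mean",
    "normalize_map",
    "gfp",
    "spatial_correlation",
    "canonical_maps",
    "CANONICAL_LABELS",
]

CANONICAL_LABELS = ("A", "B", "C", "D")


def zero_mean(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the spatial mean (average reference) along `axis`."""
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=axis, keepdims=True)


def normalize_map(values: np.ndarray) -> np.ndarray:
    """Average-reference then scale to unit Euclidean norm."""
    v = zero_mean(values)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize an all-constant map")
    return v / n


def gfp(values: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Global field power: population SD of the potential across channels.

    Accepts a single map (1-D) or stacked maps; `axis` is the channel axis.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < 2:
        raise ValueError("GFP needs at least 2 channels")
    centered = values - values.mean(axis=axis, keepdims=True)
    out = np.sqrt(np.mean(centered**2, axis=axis))
    return float(out) if np.ndim(out) == 0 else out


def spatial_correlation(
    m1: np.ndarray, m2: np.ndarray, polarity_invariant: bool = True
) -> float:
    """Pearson correlation of two maps across channels.

    With ``polarity_invariant=True`` (the microstate convention; scalp fields
    are generated by oscillating dipoles of indeterminate sign) the absolute
    value is returned.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("maps must share channel count")
    a = m1 - m1.mean()
    b = m2 - m2.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spatial correlation undefined for zero-variance map")
    c = float(a @ b / (na * nb))
    return abs(c) if polarity_invariant else c


def _gradient_map(positions: np.ndarray, direction: np.ndarray) -> np.ndarray:
    u = np.asarray(direction, dtype=float)
    v = positions @ (u / np.linalg.norm(u))
    return normalize_map(v)


def _focal_map(positions: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    d = np.arccos(np.clip(positions @ c, -1.0, 1.0))
    return normalize_map(np.exp(-((d / width) ** 2)))


def canonical_maps(montage: SensorMontage) -> np.ndarray:
    """The four prototypical resting-state topographies A-D on `montage`.

    A: right-frontal to left-posterior diagonal gradient; B: the mirrored
    diagonal; C: anterior-posterior gradient; D: fronto-central focal field.
    Returned as a ``(4, n_channels)`` array of zero-mean unit-norm maps.
    Head coordinates: +x right, +y anterior, +z superior.

    Raises
    ------
    ValueError
        If the montage geometry cannot support four distinct maps (any map
        degenerate, or a pair with polarity-invariant correlation > 0.7).
    """
    pos = montage.positions
    try:
        maps = np.stack(
            [
                _gradient_map(pos, np.array([1.0, 0.6, 0.15])),
                _gradient_map(pos, np.array([-1.0, 0.6, 0.15])),
                _gradient_map(pos, np.array([0.0, 1.0, 0.0])),
                _focal_map(pos, np.array([0.0, 0.35, 0.94]), width=0.7),
            ]
        )
    except ValueError as exc:
        raise ValueError(f"degenerate montage for canonical maps: {exc}") from exc
    corr = np.abs(maps @ maps.T)
    np.fill_diagonal(corr, 0.0)
    if corr.max() > 0.7:
        raise ValueError(
            "montage too degenerate: canonical maps not distinct "
            f"(max pairwise |corr| = {corr.max():.3f})"
        )
    return maps
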