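"""Sensor montages: channel labels plus unit-sphere positions.

The packaged 64-channel montage follows the extended 10/10 layout of a
standard 64-electrode actiCAP/actiCHamp cap; positions come from the idealized
spherical head model shipped with MNE and are projected onto the unit sphere.
Other channel counts produce a generic, deterministic spherical arrangement
(useful for small test montages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["SensorMontage", "make_montage", "ACTICAP_64_LABELS"]

#: Channel names of the packaged 64-electrode 10/10 montage (TP9 reference
#: recorded as an ordinary channel; ground not included).
ACTICAP_64_LABELS: tuple[str, ...] = tuple(
    """Fp1 Fz F3 F7 FT9 FC5 FC1 C3 T7 TP9 CP5 CP1 Pz P3 P7 O1 Oz O2 P4 P8
    TP10 CP6 CP2 Cz C4 T8 FT10 FC6 FC2 F4 F8 Fp2 AF7 AF3 AFz F1 F5 FT7 FC3
    C1 C5 TP7 CP3 P1 P5 PO7 PO3 POz PO4 PO8 P6 P2 CPz CP4 TP8 C6 C2 FC4 FT8
    F6 AF8 AF4 F2 FCz""".split()
)


@dataclass(frozen=True)
class SensorMontage:
    """An ordered set of EEG sensors with unit-sphere positions.

    Parameters
    ----------
    labels
        Unique channel names, one per sensor.
    positions
        Array of shape ``(n_channels, 3)``; each row is normalized to the
        unit sphere on construction.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        if len(labels) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if pos.shape != (len(labels), 3):
            raise ValueError(
                f"positions must have shape ({len(labels)}, 3), got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("positions must be nonzero")
        pos = pos / norms[:, None]
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def angular_distances(self) -> np.ndarray:
        """Pairwise great-circle distances (radians) between sensors."""
        cos = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cos)


@lru_cache(maxsize=None)
def _standard_1005_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    return {k: np.asarray(v, dtype=float) for k, v in std.get_positions()["ch_pos"].items()}


def _fibonacci_sphere(n: int) -> np.ndarray:
    # Deterministic quasi-uniform points; golden-angle spiral.
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_montage(n_channels: int) -> SensorMontage:
    """Build a deterministic montage with `n_channels` sensors.

    ``n_channels == 64`` returns the packaged 10/10 cap; ``n_channels == 2``
    returns two antipodal sensors; any other count >= 2 returns a generic
    golden-spiral arrangement with labels ``CH01``, ``CH02``, ...

    Raises
    ------
    ValueError
        If ``n_channels < 2``.
    """
    if n_channels < 2:
        raise ValueError(f"unsupported channel count {n_channels}; need >= 2")
    if n_channels == 64:
        pos = _standard_1005_positions()
        arr = np.array([pos[name] for name in ACTICAP_64_LABELS])
        return SensorMontage(ACTICAP_64_LABELS, arr)
    labels = tuple(f"CH{i + 1:02d}" for i in range(n_channels))
    if n_channels == 2:
        arr = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    else:
        arr = _fibonacci_sphere(n_channels)
    return SensorMontage(labels, arr)
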