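"""Shared containers and conventions.

Axis order is (z, y, x) with 0-based voxel indexing; z increases from
superior (trachea entry) to inferior. Spacing is isotropic and carried in
micrometres internally (NIfTI headers convert to millimetres). HU values
are clipped to the conventional 12-bit CT range [-1024, 3071].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

#: Mouse lung lobes: left lobe and the four right lobes
#: (cranial, middle, caudal, accessory).
LOBES = ("Sx", "Dx Cr", "Dx M", "Dx Ca", "Dx Ac")
LOBE_IDS = {name: i + 1 for i, name in enumerate(LOBES)}


@dataclass
class CTVolume:
    """A reconstructed micro-CT volume in Hounsfield units.

    Parameters
    ----------
    values : ndarray
        3D scalar grid of HU values, axis order (z, y, x).
    spacing_um : float
        Isotropic voxel edge length in micrometres.
    animal_id : str
        Subject identifier.
    day : int
        Acquisition day relative to the first challenge.
    phase : str
        Breathing-cycle phase label; end-expiration by default.
    """

    values: np.ndarray
    spacing_um: float = 50.0
    animal_id: str = ""
    day: int = 0
    phase: str = "expiration"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("CTVolume requires a 3D grid")
        if min(self.values.shape) < 32:
            raise ValueError(
                f"grid {self.values.shape} too small: need at least 32 voxels per axis"
            )
        if self.spacing_um <= 0:
            raise ValueError("voxel spacing must be positive")
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if vmin < HU_MIN - 1e-6 or vmax > HU_MAX + 1e-6:
            raise ValueError(
                f"HU values [{vmin:.1f}, {vmax:.1f}] outside [{HU_MIN}, {HU_MAX}]"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.spacing_um / 1000.0) ** 3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
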