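"""HU density-mask quantification of lung aeration compartments.

Lung voxels are classified into four disjoint HU bands that jointly cover
the real line: hyper-aerated (< -900), normo-aerated [-900, -500),
poorly-aerated [-500, -100] and non-aerated (> -100). The printed normo
and poor bands share the -500 HU boundary; it is assigned to the poor
band once (half-open convention), so every voxel has exactly one class.
The poorly-aerated fraction of total lung volume is the in vivo fibrosis
surrogate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CTVolume, HU_MAX, HU_MIN

COMPARTMENTS = ("hyper", "normo", "poor", "non")


@dataclass(frozen=True)
class AerationBins:
    """HU band edges. normo is [normo_lower, poor_lower); poor is
    [poor_lower, poor_upper]; hyper below, non-aerated above."""

    normo_lower: float = -900.0
    poor_lower: float = -500.0
    poor_upper: float = -100.0

    def __post_init__(self) -> None:
        if not (self.normo_lower < self.poor_lower < self.poor_upper):
            raise ValueError("band edges must increase: normo_lower < poor_lower < poor_upper")

    def classify(self, hu: np.ndarray) -> np.ndarray:
        """Map HU values to compartment codes 0=hyper 1=normo 2=poor 3=non."""
        hu = np.asarray(hu)
        out = np.empty(hu.shape, np.uint8)
        out[hu < self.normo_lower] = 0
        out[(hu >= self.normo_lower) & (hu < self.poor_lower)] = 1
        out[(hu >= self.poor_lower) & (hu <= self.poor_upper)] = 2
        out[hu > self.poor_upper] = 3
        return out


@dataclass
class AerationProfile:
    """Per-volume aeration readout, normalized on total lung volume."""

    total_lung_volume_mm3: float
    frac_hyper: float
    frac_normo: float
    frac_poor: float
    frac_non: float
    n_voxels: int
    animal_id: str = ""
    day: int = 0
    #: integer voxel counts (hyper, normo, poor, non); they partition the
    #: lung exactly, which float fractions can only do to representation
    counts: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        total = self.frac_hyper + self.frac_normo + self.frac_poor + self.frac_non
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions sum to {total}, not 1")
        if self.total_lung_volume_mm3 <= 0:
            raise ValueError("total lung volume must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "hyper": self.frac_hyper,
            "normo": self.frac_normo,
            "poor": self.frac_poor,
            "non": self.frac_non,
        }


def rescale_to_hu(
    raw: np.ndarray,
    air_value: float,
    water_value: float,
    spacing_um: float = 50.0,
    **meta,
) -> CTVolume:
    """Linear raw-unit to HU calibration: air -> -1000, water -> 0.

    Scanner exports are unsigned 16-bit; two reference readings anchor
    the affine map. Output is clipped to [-1024, 3071].
    """
    if air_value == water_value:
        raise ValueError("air and water reference values must differ")
    scale = 1000.0 / (water_value - air_value)
    hu = (np.asarray(raw, np.float64) - water_value) * scale
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    return CTVolume(values=hu.astype(np.float32), spacing_um=spacing_um, **meta)


def classify_aeration(
    ct: CTVolume,
    lung_mask: np.ndarray,
    bins: AerationBins | None = None,
) -> AerationProfile:
    """Density-mask classification of lung voxels into aeration bands.

    Fractions are voxel counts per band divided by the lung voxel count,
    so they sum to one exactly; total lung volume comes from the voxel
    spacing.
    """
    bins = bins or AerationBins()
    lung_mask = np.asarray(lung_mask, bool)
    if lung_mask.shape != ct.values.shape:
        raise ValueError("lung mask must match the CT grid")
    n = int(lung_mask.sum())
    if n == 0:
        raise ValueError("empty lung mask")
    codes = bins.classify(ct.values[lung_mask])
    counts = np.bincount(codes, minlength=4)
    return AerationProfile(
        total_lung_volume_mm3=n * ct.voxel_volume_mm3,
        frac_hyper=counts[0] / n,
        frac_normo=counts[1] / n,
        frac_poor=counts[2] / n,
        frac_non=counts[3] / n,
        n_voxels=n,
        animal_id=ct.animal_id,
        day=ct.day,
        counts=tuple(int(c) for c in counts),
    )


def peel_rind(lung_mask: np.ndarray, voxels: int = 1) -> np.ndarray:
    """Erode a lung mask by a thin rind before density-mask analysis.

    Voxels on the mask surface mix lung and chest-wall attenuation
    through partial-volume blur and land in the poorly-aerated band
    regardless of the underlying tissue; peeling one voxel removes that
    shell. Falls back to the unpeeled mask if peeling would empty it.
    """
    lung_mask = np.asarray(lung_mask, bool)
    if voxels <= 0:
        return lung_mask
    eroded = ndimage.binary_erosion(
        lung_mask, ndimage.generate_binary_structure(3, 1), iterations=voxels
    )
    return eroded if eroded.any() else lung_mask


def quantify_volume(
    ct: CTVolume,
    lung_mask: np.ndarray,
    bins: AerationBins | None = None,
    rind_peel_vox: int = 1,
) -> AerationProfile:
    """Pipeline aeration readout: rind peel then density-mask classify.

    This is the estimator the study-level analyses use on segmented
    masks; pass ``rind_peel_vox=0`` (or call :func:`classify_aeration`
    directly) to classify a mask as given, e.g. ground-truth masks of
    noise-free phantoms.
    """
    return classify_aeration(ct, peel_rind(lung_mask, rind_peel_vox), bins)


def profiles_to_frame(profiles: list[AerationProfile]) -> pd.DataFrame:
    """Long-format table (animal_id, day, compartment, fraction, volume_mm3)."""
    rows = []
    for p in profiles:
        for comp, frac in p.as_dict().items():
            rows.append(
                {
                    "animal_id": p.animal_id,
                    "day": p.day,
                    "compartment": comp,
                    "fraction": frac,
                    "volume_mm3": p.total_lung_volume_mm3,
                }
            )
    return pd.DataFrame(rows)


def aeration_timecourse(
    profiles: list[AerationProfile],
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Groupwise longitudinal summary of aeration fractions.

    ``design`` maps animal_id to group (and optionally route/treatment).
    Returns a long table keyed by (group, day, compartment) with mean,
    sd, s.e.m. and n; s.e.m. is NaN for single-animal cells.
    """
    if "animal_id" not in design.columns or "group" not in design.columns:
        raise ValueError("design table needs animal_id and group columns")
    lookup = design.set_index("animal_id")["group"]
    unknown = {p.animal_id for p in profiles} - set(lookup.index)
    if unknown:
        raise ValueError(f"animals missing from design table: {sorted(unknown)}")
    long = profiles_to_frame(profiles)
    long["group"] = long["animal_id"].map(lookup)
    out = (
        long.groupby(["group", "day", "compartment"])["fraction"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


@dataclass
class Projection2D:
    """Sagittal slab projection and its 2D poorly-aerated fraction."""

    image: np.ndarray
    mask2d: np.ndarray
    frac_poor_2d: float
    plane: str = "sagittal"
    slab_thickness_vox: int = 1

    def __post_init__(self) -> None:
        if self.slab_thickness_vox < 1:
            raise ValueError("slab thickness must be at least 1 voxel")
        if not (0.0 <= self.frac_poor_2d <= 1.0):
            raise ValueError("frac_poor_2d must lie in [0, 1]")


def project_sagittal(
    ct: CTVolume,
    lung_mask: np.ndarray,
    slab_center: int | str = "auto",
    slab_thickness_vox: int = 1,
    bins: AerationBins | None = None,
) -> Projection2D:
    """Mean-intensity sagittal projection and 2D density-mask analysis.

    The slab spans ``slab_thickness_vox`` sagittal (constant-x) planes
    centred on ``slab_center`` ("auto" = lung-mask centroid). Each (z, y)
    pixel is the mean HU over in-lung voxels of the slab; pixels with any
    lung voxel form the 2D mask and are classified with the same bins as
    the 3D analysis.
    """
    bins = bins or AerationBins()
    lung_mask = np.asarray(lung_mask, bool)
    if lung_mask.shape != ct.values.shape:
        raise ValueError("lung mask must match the CT grid")
    if slab_thickness_vox < 1:
        raise ValueError("slab thickness must be at least 1 voxel")
    nx = ct.values.shape[2]
    if isinstance(slab_center, str):
        if slab_center != "auto":
            raise ValueError("slab_center must be an x index or 'auto'")
        if not lung_mask.any():
            raise ValueError("empty lung mask")
        slab_center = int(round(np.nonzero(lung_mask)[2].mean()))
    x0 = max(0, int(slab_center) - slab_thickness_vox // 2)
    x1 = min(nx, x0 + slab_thickness_vox)
    if x0 >= nx or x1 <= 0:
        raise ValueError("slab lies outside the grid")
    slab_hu = ct.values[:, :, x0:x1]
    slab_mask = lung_mask[:, :, x0:x1]
    counts = slab_mask.sum(axis=2)
    mask2d = counts > 0
    if not mask2d.any():
        raise ValueError("slab does not intersect the lung mask")
    with np.errstate(invalid="ignore"):
        image = np.where(
            mask2d,
            (slab_hu * slab_mask).sum(axis=2) / np.maximum(counts, 1),
            np.float32(0.0),
        )
    codes = bins.classify(image[mask2d])
    frac_poor = float((codes == 2).sum() / codes.size)
    return Projection2D(
        image=image.astype(np.float32),
        mask2d=mask2d,
        frac_poor_2d=frac_poor,
        slab_thickness_vox=int(slab_thickness_vox),
    )
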