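"""Lung, airway and vessel segmentation from micro-CT volumes.

Replaces the commercial semi-automatic workflow with a fully automatic
one whose manual steps survive as optional inputs (a trachea seed voxel,
threshold overrides). The pipeline is: threshold-constrained region
growing with leak control for the airway lumen, body-envelope thresholding
plus morphology for the parenchymal lung, an HU criterion inside the
closed lung hull for vessels, and a carina-based sagittal split into left
and right lung.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CTVolume


@dataclass
class SegParams:
    """Tunable segmentation thresholds (HU) and morphology radii (voxels).

    Defaults follow standard small-animal densitometry practice: -200 HU
    separates aerated lung from the body, -850 HU bounds airway-lumen
    region growing, and a step that multiplies the growing wavefront by
    more than ``leak_cap`` aborts growth (leak control at, e.g., a pleural
    breach).
    """

    lung_hu_upper: float = -200.0
    airway_hu_upper: float = -850.0
    closing_radius_vox: int = 2
    min_component_vox: int = 64
    leak_cap: float = 3.0
    min_front_for_leak_check: int = 12
    vessel_hu_lower: float = -100.0
    exclude_vessels_from_lung: bool = False

    def __post_init__(self) -> None:
        if self.airway_hu_upper >= self.lung_hu_upper:
            raise ValueError("airway_hu_upper must be below lung_hu_upper")
        if self.closing_radius_vox < 0 or self.min_component_vox < 0:
            raise ValueError("radii and component sizes must be non-negative")
        if self.leak_cap <= 1.0:
            raise ValueError("leak_cap must exceed 1")


@dataclass
class SegmentationResult:
    """Co-registered masks: parenchymal lung (lumen excluded), airway
    lumen, vessels, and a left(1)/right(2) label grid over the lung."""

    lung_mask: np.ndarray
    airway_mask: np.ndarray
    vessel_mask: np.ndarray
    side_labels: np.ndarray
    seed_points: tuple[tuple[int, int, int], ...] = ()


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return _STRUCT6
    span = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(span, span, span, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= radius**2


def find_trachea_seed(ct: CTVolume, params: SegParams | None = None) -> tuple[int, int, int]:
    """Locate the trachea automatically.

    Takes the largest air-filled connected component that does not touch
    the volume faces (ambient air does; the airway tree does not) and
    returns the centroid of its most superior (lowest z) slice.
    """
    params = params or SegParams()
    air = ct.values < params.airway_hu_upper
    labels, n = ndimage.label(air, structure=_STRUCT6)
    if n == 0:
        raise ValueError("no air-filled region found; supply a trachea seed manually")
    border = np.zeros_like(air)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = set(np.unique(labels[border])) - {0}
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    for lab in touching:
        counts[lab] = 0
    counts[0] = 0
    if counts.max() == 0:
        raise ValueError(
            "no interior air component found; supply a trachea seed manually"
        )
    comp = labels == int(counts.argmax())
    z_top = int(np.flatnonzero(comp.any(axis=(1, 2)))[0])
    ys, xs = np.nonzero(comp[z_top])
    return (z_top, int(round(ys.mean())), int(round(xs.mean())))


def segment_airways(
    ct: CTVolume,
    trachea_seed: tuple[int, int, int] | str = "auto",
    params: SegParams | None = None,
) -> np.ndarray:
    """Segment the airway lumen by seeded region growing under -850 HU.

    Growth proceeds generation by generation (6-connectivity). If one step
    multiplies the wavefront size by more than ``params.leak_cap`` (once
    the front is large enough for the ratio to be meaningful), growth
    stops: the hallmark of a leak into ambient air or a pleural breach.
    """
    params = params or SegParams()
    if isinstance(trachea_seed, str):
        if trachea_seed != "auto":
            raise ValueError("trachea_seed must be a voxel triple or 'auto'")
        trachea_seed = find_trachea_seed(ct, params)
    seed = tuple(int(c) for c in trachea_seed)
    hu = float(ct.values[seed])
    if hu >= params.airway_hu_upper:
        raise ValueError(
            f"seed voxel {seed} has {hu:.0f} HU, not air "
            f"(< {params.airway_hu_upper:.0f} HU required)"
        )
    air = ct.values < params.airway_hu_upper
    mask = np.zeros_like(air)
    mask[seed] = True
    front = mask.copy()
    recent: list[int] = []
    while True:
        grown = ndimage.binary_dilation(front, _STRUCT6) & air & ~mask
        n_new, n_front = int(grown.sum()), int(front.sum())
        if n_new == 0:
            break
        # leak control: inside a tube the wavefront tracks the lumen
        # cross-section; escaping into open air it grows without bound.
        # Compare against the median of recent fronts (a robust tube
        # baseline) so a sustained expansion after a breach trips the
        # cap while startup transients and bifurcations do not.
        if (
            n_front >= params.min_front_for_leak_check
            and len(recent) >= 6
            and n_new > params.leak_cap * float(np.median(recent))
        ):
            break
        if n_front >= params.min_front_for_leak_check:
            # only established (tube-sized) fronts enter the baseline;
            # the ramp-up from a point seed is not a tube cross-section
            recent.append(n_front)
            if len(recent) > 8:
                recent.pop(0)
        mask |= grown
        front = grown
    return mask


def segment_lungs(
    ct: CTVolume,
    airway_mask: np.ndarray,
    params: SegParams | None = None,
) -> np.ndarray:
    """Segment the parenchymal lung (airway lumen excluded).

    Candidate voxels are below ``lung_hu_upper`` inside the body envelope
    (largest non-air component, hole-filled); small components are
    dropped, the largest one or two kept (left and right lung can be
    separate), then morphological closing, hole filling, and subtraction
    of the airway lumen.
    """
    params = params or SegParams()
    if airway_mask.shape != ct.values.shape:
        raise ValueError("airway_mask must match the CT grid")
    non_air = ct.values >= params.lung_hu_upper
    labels, n = ndimage.label(non_air, structure=_STRUCT6)
    if n == 0:
        raise ValueError("no lung found: volume contains no body")
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    body = ndimage.binary_fill_holes(labels == int(counts.argmax()))

    cand = (ct.values < params.lung_hu_upper) & body
    if not cand.any():
        raise ValueError("no lung found: no low-density voxels inside the body")
    # close before component selection so noise-induced cracks cannot
    # fragment the lung and cost a chunk at the keep-largest step
    if params.closing_radius_vox > 0:
        cand = ndimage.binary_closing(cand, structure=_ball(params.closing_radius_vox))
    labels, n = ndimage.label(cand, structure=_STRUCT6)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    keep_ids = [i for i in np.argsort(counts)[::-1][:2] if counts[i] >= max(params.min_component_vox, 1)]
    if not keep_ids:
        raise ValueError("no lung found: all candidate components below minimum size")
    lung = np.isin(labels, keep_ids)
    lung = ndimage.binary_fill_holes(lung)
    lung &= ~airway_mask.astype(bool)
    if not lung.any():
        raise ValueError("no lung found after airway subtraction")
    return lung


def segment_vessels(
    ct: CTVolume,
    lung_mask: np.ndarray,
    airway_mask: np.ndarray | None = None,
    params: SegParams | None = None,
) -> np.ndarray:
    """Segment intrapulmonary vessels: dense voxels inside the lung hull.

    Vessels are landmarks for alignment, not an aeration exclusion by
    default; the mask may be empty.
    """
    params = params or SegParams()
    if not lung_mask.any():
        raise ValueError("lung mask is empty")
    hull = ndimage.binary_fill_holes(
        ndimage.binary_closing(lung_mask, structure=_ball(max(params.closing_radius_vox, 2) + 1))
    )
    # pull the hull clear of the chest wall so dense rim voxels cannot
    # masquerade as vessels, and stay adjacent to actual parenchyma so
    # bridged mediastinal soft tissue is not picked up
    hull = ndimage.binary_erosion(hull, _STRUCT6, iterations=2)
    near_lung = ndimage.binary_dilation(lung_mask, _STRUCT6, iterations=3)
    vessels = hull & near_lung & (ct.values > params.vessel_hu_lower)
    if airway_mask is not None and airway_mask.any():
        wall = ndimage.binary_dilation(airway_mask, _STRUCT6, iterations=2)
        vessels &= ~wall
    return vessels


def find_carina(airway_mask: np.ndarray) -> tuple[int, int, int] | None:
    """Locate the carina: the most superior z slice where the airway
    cross-section splits into two components; returns None if the tree
    never bifurcates (e.g. trachea-only masks)."""
    struct2d = ndimage.generate_binary_structure(2, 1)
    zs = np.flatnonzero(airway_mask.any(axis=(1, 2)))
    for z in zs:
        _, n = ndimage.label(airway_mask[z], structure=struct2d)
        if n >= 2:
            ys, xs = np.nonzero(airway_mask[z])
            return (int(z), int(round(ys.mean())), int(round(xs.mean())))
    return None


def split_left_right(
    lung_mask: np.ndarray, airway_mask: np.ndarray
) -> np.ndarray:
    """Label lung voxels 1 (left) / 2 (right) by the sagittal plane
    through the carina; falls back to the lung centroid plane (with a
    warning) when the airway tree has no bifurcation."""
    carina = find_carina(airway_mask)
    if carina is None:
        warnings.warn(
            "carina not found in airway mask; splitting at the lung centroid plane",
            stacklevel=2,
        )
        xs = np.nonzero(lung_mask)[2]
        plane_x = float(xs.mean())
    else:
        plane_x = float(carina[2])
    side = np.zeros(lung_mask.shape, np.uint8)
    xs = np.arange(lung_mask.shape[2])
    left = xs < plane_x
    side[..., left] = 1
    side[..., ~left] = 2
    side[~lung_mask.astype(bool)] = 0
    return side


def segment(
    ct: CTVolume,
    trachea_seed: tuple[int, int, int] | str = "auto",
    params: SegParams | None = None,
) -> SegmentationResult:
    """Run the full segmentation chain on one volume."""
    params = params or SegParams()
    if isinstance(trachea_seed, str) and trachea_seed == "auto":
        trachea_seed = find_trachea_seed(ct, params)
    airway = segment_airways(ct, trachea_seed, params)
    lung = segment_lungs(ct, airway, params)
    vessels = segment_vessels(ct, lung, airway, params)
    if params.exclude_vessels_from_lung:
        lung = lung & ~vessels
    side = split_left_right(lung, airway)
    return SegmentationResult(
        lung_mask=lung,
        airway_mask=airway,
        vessel_mask=vessels,
        side_labels=side,
        seed_points=(tuple(int(c) for c in trachea_seed),),
    )
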