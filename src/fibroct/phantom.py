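"""Synthetic micro-CT lung phantoms with known ground truth.

The generator emulates a bleomycin (BLM) mouse-fibrosis imaging study:
schematic five-lobe lung geometry around a branching airway tree, fibrotic
lesions grown inside the lung to a prescribed volume fraction, HU synthesis
per tissue compartment with partial-volume blur and additive noise, a
burden time course peaking at day 14 with partial resolution afterwards,
and linked ex vivo readouts (per-lobe Ashcroft grades, hydroxyproline).

Every output is deterministic given the seed; ground-truth masks travel
with each volume so downstream estimates can be scored exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CTVolume, HU_MAX, HU_MIN, LOBES, LOBE_IDS


@dataclass
class PhantomSpec:
    """Geometry and HU parameters of a single phantom volume.

    HU means for normo-aerated parenchyma and fibrotic lesion sit at the
    centres of the two density-mask bands ([-900, -500) and [-500, -100])
    with standard deviations small enough that few noise-free voxels cross
    a band boundary.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_um: float = 50.0
    hu_air: float = -1000.0
    hu_parenchyma_mean: float = -700.0
    hu_parenchyma_sd: float = 60.0
    hu_lesion_mean: float = -300.0
    hu_lesion_sd: float = 70.0
    hu_soft_tissue: float = 40.0
    blur_sigma_vox: float = 0.6
    noise_sd_hu: float = 30.0
    airway_depth: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.grid_shape, int):
            self.grid_shape = (self.grid_shape,) * 3
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 32:
            raise ValueError("grid_shape must be 3 axes of at least 32 voxels")
        if self.voxel_spacing_um <= 0:
            raise ValueError("voxel_spacing_um must be positive")
        if not (-900 <= self.hu_parenchyma_mean < -500):
            raise ValueError("hu_parenchyma_mean must lie in [-900, -500)")
        if not (-500 <= self.hu_lesion_mean <= -100):
            raise ValueError("hu_lesion_mean must lie in [-500, -100]")
        for name in ("hu_parenchyma_sd", "hu_lesion_sd", "noise_sd_hu", "blur_sigma_vox"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.airway_depth < 0:
            raise ValueError("airway_depth must be non-negative")


@dataclass
class BurdenCurveParams:
    """Piecewise fibrotic-burden time course.

    Zero before ``onset_day``, linear rise to ``peak_fraction`` at
    ``peak_day``, then exponential decline at ``resolution_rate`` per day
    (continuous at the peak) — the disease course rises to a day-14
    maximum and partially resolves by day 28.
    """

    peak_day: float = 14.0
    peak_fraction: float = 0.25
    onset_day: float = 3.0
    resolution_rate: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 <= self.peak_fraction <= 0.8):
            raise ValueError("peak_fraction must lie in [0, 0.8]")
        if self.onset_day >= self.peak_day:
            raise ValueError("onset_day must precede peak_day")
        if self.resolution_rate < 0:
            raise ValueError("resolution_rate must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth attached to a synthetic volume.

    ``lung_mask`` is the parenchymal lung (airway lumen excluded);
    ``lobe_labels`` partitions it into the five mouse lobes
    (1=Sx, 2=Dx Cr, 3=Dx M, 4=Dx Ca, 5=Dx Ac). ``body_mask`` is the
    soft-tissue envelope used during HU synthesis.
    """

    lung_mask: np.ndarray
    airway_mask: np.ndarray
    lesion_mask: np.ndarray
    lobe_labels: np.ndarray
    body_mask: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lung = self.lung_mask.astype(bool)
        if (self.lesion_mask & ~lung).any():
            raise ValueError("lesion_mask must be contained in lung_mask")
        if (self.airway_mask & lung).any():
            raise ValueError("airway lumen and lung parenchyma must be disjoint")
        if ((self.lobe_labels > 0) != lung).any():
            raise ValueError("lobe_labels must partition lung_mask")

    @property
    def true_poor_fraction(self) -> float:
        n_lung = int(self.lung_mask.sum())
        if n_lung == 0:
            return 0.0
        return int(self.lesion_mask.sum()) / n_lung

    def lobe_burdens(self) -> dict[str, float]:
        """Lesion fraction of each lobe (lesion voxels / lobe voxels)."""
        out = {}
        for name, lab in LOBE_IDS.items():
            lobe = self.lobe_labels == lab
            n = int(lobe.sum())
            out[name] = int((self.lesion_mask & lobe).sum()) / n if n else 0.0
        return out


@dataclass
class ExVivoLinkage:
    """Linear links from true fibrotic burden to ex vivo readouts.

    The per-lobe Ashcroft latent score is ``intercept + slope * lobe
    burden`` plus Gaussian noise, rounded and clipped to the 0-8 grade
    scale; hydroxyproline (µg, right-lung collagen surrogate) is
    ``baseline + slope * whole-lung burden`` plus noise, floored at 0.
    """

    ashcroft_intercept: float = 0.5
    ashcroft_slope: float = 12.0
    ashcroft_noise_sd: float = 0.6
    hyp_baseline_ug: float = 60.0
    hyp_slope_ug: float = 300.0
    hyp_noise_sd_ug: float = 10.0


@dataclass
class GroupSpec:
    name: str
    route: str = "OA"  # "IT", "OA" or "none" (saline receives no BLM route effect)
    treatment: str = "vehicle"  # "vehicle" or "drug"
    n_animals: int = 7
    bleomycin: bool = True

    def __post_init__(self) -> None:
        if self.route not in ("IT", "OA", "none"):
            raise ValueError("route must be IT, OA or none")
        if self.treatment not in ("vehicle", "drug"):
            raise ValueError("treatment must be vehicle or drug")
        if self.n_animals < 1:
            raise ValueError("each group needs at least one animal")


@dataclass
class CohortSpec:
    """Design of a simulated imaging study.

    Defaults mirror the study layout: groups of seven animals imaged at
    days 7, 14, 21 and 28; intratracheal (IT) delivery concentrates
    lesions in few lobes while oropharyngeal aspiration (OA) spreads them
    uniformly; a drug arm multiplies the fibrotic burden by
    ``drug_burden_factor`` from ``treatment_start_day`` onward.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("saline", route="none", bleomycin=False),
        GroupSpec("BLM", route="OA"),
    )
    days: tuple[int, ...] = (7, 14, 21, 28)
    clustering_it: float = 5.0
    clustering_oa: float = 0.0
    burden: BurdenCurveParams = field(default_factory=BurdenCurveParams)
    linkage: ExVivoLinkage = field(default_factory=ExVivoLinkage)
    burden_cv: float = 0.25
    drug_burden_factor: float = 0.5
    treatment_start_day: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.days = tuple(int(d) for d in self.days)
        if any(b >= a for a, b in zip(self.days[1:], self.days)):
            raise ValueError("days must be strictly increasing")
        if not self.groups:
            raise ValueError("cohort needs at least one group")


# --------------------------------------------------------------------------
# geometry


def _ellipsoid_dist2(shape, center, semi):
    """Squared normalized ellipsoid distance for every voxel."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )


def _paint_cylinder(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float) -> None:
    """Set voxels within ``radius`` of segment p0-p1 (in-place)."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius + 1).astype(int), mask.shape)
    if (hi <= lo).any():
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 < 1e-12:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = ((pts - closest) ** 2).sum(axis=-1)
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= dist2 <= radius**2


def _grow_airway_tree(mask, start, direction, length, radius, depth, rng):
    """Recursive binary branching; each generation shrinks and forks."""
    end = start + direction * length
    _paint_cylinder(mask, start, end, radius)
    if depth <= 0 or radius * 0.7 < 0.9:
        return
    # fork in a plane roughly perpendicular to the parent direction
    ortho = np.cross(direction, [0.0, 1.0, 0.0])
    if np.linalg.norm(ortho) < 1e-6:
        ortho = np.cross(direction, [0.0, 0.0, 1.0])
    ortho = ortho / np.linalg.norm(ortho)
    angle = math.radians(38.0 + rng.uniform(-5, 5))
    for sign in (+1.0, -1.0):
        child = math.cos(angle) * direction + math.sin(angle) * sign * ortho
        child = child / np.linalg.norm(child)
        _grow_airway_tree(
            mask, end, child, length * 0.72, radius * 0.7, depth - 1, rng
        )


# Lobe layout in fractional (z, y, x) grid coordinates: centre and semi-axes.
_LOBE_GEOMETRY = {
    "Sx": ((0.55, 0.50, 0.31), (0.24, 0.21, 0.14)),
    "Dx Cr": ((0.42, 0.47, 0.66), (0.13, 0.17, 0.13)),
    "Dx M": ((0.54, 0.45, 0.69), (0.12, 0.15, 0.12)),
    "Dx Ca": ((0.68, 0.52, 0.65), (0.14, 0.18, 0.13)),
    "Dx Ac": ((0.60, 0.63, 0.55), (0.10, 0.12, 0.10)),
}


def build_lung_geometry(spec: PhantomSpec, lobe_scheme: str = "5-lobe") -> PhantomTruth:
    """Build the lung/airway geometry of one phantom (no lesions yet).

    Five ellipsoid-derived lobes (left lung = Sx; right lung = four
    overlapping lobes) sit inside a soft-tissue body around a trachea
    that bifurcates at the carina into a recursive airway tree with
    ``spec.airway_depth`` branching generations (depth 0 keeps only the
    trachea). Deterministic given ``spec.rng_seed``: the seed jitters
    lobe centres, sizes and branch angles slightly so cohort animals are
    distinct individuals.
    """
    if lobe_scheme != "5-lobe":
        raise ValueError("only the 5-lobe mouse scheme is supported")
    shape = spec.grid_shape
    n = np.array(shape, float)
    if min(shape) < 32:
        raise ValueError(f"grid {shape} too small to contain the lung geometry")
    rng = np.random.default_rng(spec.rng_seed)

    body = _ellipsoid_dist2(shape, n * 0.5, n * (0.46, 0.43, 0.43)) <= 1.0

    dist2 = {}
    for name, (c, s) in _LOBE_GEOMETRY.items():
        center = n * c + rng.uniform(-0.01, 0.01, 3) * n
        semi = n * s * rng.uniform(0.97, 1.03, 3)
        dist2[name] = _ellipsoid_dist2(shape, center, semi)
    stack = np.stack([dist2[name] for name in LOBES])
    inside = (stack <= 1.0).any(axis=0)
    labels = np.where(inside, stack.argmin(axis=0) + 1, 0).astype(np.int8)

    airway = np.zeros(shape, bool)
    # start well below the body apex: the soft-tissue cap above the
    # trachea must survive partial-volume blur or the chest would read
    # as open to ambient air
    trachea_top = np.array([0.15, 0.50, 0.50]) * n
    carina = np.array([0.38, 0.50, 0.50]) * n
    _paint_cylinder(airway, trachea_top, carina, 0.030 * n[0])
    if spec.airway_depth >= 1:
        for target_name in ("Sx", "Dx Ca"):
            target = np.array(_LOBE_GEOMETRY[target_name][0]) * n
            d = target - carina
            d = d / np.linalg.norm(d)
            _grow_airway_tree(
                airway,
                carina,
                d,
                0.16 * n[0],
                0.021 * n[0],
                spec.airway_depth - 1,
                rng,
            )
    airway &= body

    labels[airway] = 0
    lung = labels > 0
    if not lung.any():
        raise ValueError(f"grid {shape} too small to contain the lung geometry")
    return PhantomTruth(
        lung_mask=lung,
        airway_mask=airway,
        lesion_mask=np.zeros(shape, bool),
        lobe_labels=labels,
        body_mask=body,
    )


# --------------------------------------------------------------------------
# burden time course


def burden_at_day(day: float, params: BurdenCurveParams) -> float:
    """Fibrotic burden fraction at a given day (total function of day >= 0)."""
    if day < 0:
        raise ValueError("day must be non-negative")
    if day < params.onset_day:
        return 0.0
    if day <= params.peak_day:
        rise = (day - params.onset_day) / (params.peak_day - params.onset_day)
        return params.peak_fraction * rise
    return params.peak_fraction * math.exp(
        -params.resolution_rate * (day - params.peak_day)
    )


# --------------------------------------------------------------------------
# lesions


def place_lesions(
    truth: PhantomTruth,
    target_fraction: float,
    clustering: float = 0.0,
    rng_seed: int = 0,
    n_seeds: int = 24,
    allowed_lobes: tuple[str, ...] | None = None,
) -> PhantomTruth:
    """Grow fibrotic lesions inside the lung to a target volume fraction.

    Seeds are drawn per lobe and lesions grow by iterative random dilation
    until lesion voxels / lung voxels hits ``target_fraction`` (to the
    voxel). ``clustering`` controls the route contrast: 0 spreads seeds in
    proportion to lobe volume (the uniform OA regime), larger values
    concentrate them in few lobes (the patchy IT regime). Returns a new
    PhantomTruth; deterministic given ``rng_seed``.
    """
    if not (0.0 <= target_fraction <= 0.8):
        raise ValueError("target_fraction must lie in [0, 0.8]")
    if clustering < 0:
        raise ValueError("clustering must be non-negative")
    lung = truth.lung_mask
    n_lung = int(lung.sum())
    target_vox = round(target_fraction * n_lung)
    lesion = np.zeros_like(lung)
    if target_vox == 0:
        return replace(truth, lesion_mask=lesion)

    rng = np.random.default_rng(rng_seed)
    lobe_names = list(allowed_lobes) if allowed_lobes else list(LOBES)
    allowed = np.isin(truth.lobe_labels, [LOBE_IDS[l] for l in lobe_names])
    n_allowed = int(allowed.sum())
    if target_vox > n_allowed:
        raise ValueError(
            "lesion target unreachable: requested "
            f"{target_fraction:.3f} of lung but only "
            f"{n_allowed / n_lung:.3f} is available in the allowed lobes"
        )

    # lobe seed weights: volume-proportional at clustering 0, concentrated
    # in few lobes as clustering rises
    vols = np.array(
        [int((truth.lobe_labels == LOBE_IDS[l]).sum()) for l in lobe_names], float
    )
    tilt = rng.normal(size=len(lobe_names))
    w = vols * np.exp(clustering * tilt)
    w /= w.sum()

    flat_idx = {
        l: np.flatnonzero((truth.lobe_labels == LOBE_IDS[l]).ravel()) for l in lobe_names
    }
    seeds = []
    for _ in range(n_seeds):
        lobe = lobe_names[rng.choice(len(lobe_names), p=w)]
        seeds.append(rng.choice(flat_idx[lobe]))
    lesion.ravel()[np.array(seeds)] = True
    lesion &= allowed

    struct = ndimage.generate_binary_structure(3, 1)
    while int(lesion.sum()) < target_vox:
        needed = target_vox - int(lesion.sum())
        frontier = ndimage.binary_dilation(lesion, struct) & allowed & ~lesion
        idx = np.flatnonzero(frontier.ravel())
        if idx.size == 0:
            # all reachable voxels consumed; reseed in the allowed region
            free = np.flatnonzero((allowed & ~lesion).ravel())
            if free.size == 0:
                raise ValueError(
                    "lesion target unreachable: achieved fraction "
                    f"{int(lesion.sum()) / n_lung:.3f} of {target_fraction:.3f}"
                )
            lesion.ravel()[rng.choice(free)] = True
            continue
        take = min(needed, max(1, int(0.8 * idx.size)))
        chosen = rng.choice(idx, size=take, replace=False)
        lesion.ravel()[chosen] = True
    return replace(truth, lesion_mask=lesion)


# --------------------------------------------------------------------------
# HU synthesis


def synthesize_ct(
    truth: PhantomTruth,
    spec: PhantomSpec,
    animal_id: str = "phantom",
    day: int = 0,
) -> CTVolume:
    """Render a PhantomTruth into an HU volume.

    Each compartment gets its mean HU plus tissue texture (scaled standard
    normal field), the grid is Gaussian-blurred by ``blur_sigma_vox`` to
    emulate partial-volume mixing, and scanner noise of ``noise_sd_hu`` is
    added. The same seed draws the same unit texture/noise fields, so
    varying a standard deviation rescales — rather than redraws — the
    perturbation. Output clipped to [-1024, 3071].
    """
    truth.validate()
    rng = np.random.default_rng(spec.rng_seed)
    shape = truth.lung_mask.shape
    texture = rng.standard_normal(shape)
    noise = rng.standard_normal(shape)

    vol = np.full(shape, spec.hu_air, dtype=np.float64)
    vol[truth.body_mask] = spec.hu_soft_tissue
    parenchyma = truth.lung_mask & ~truth.lesion_mask
    vol[parenchyma] = spec.hu_parenchyma_mean + spec.hu_parenchyma_sd * texture[parenchyma]
    vol[truth.lesion_mask] = spec.hu_lesion_mean + spec.hu_lesion_sd * texture[truth.lesion_mask]
    vol[truth.airway_mask] = spec.hu_air

    if spec.blur_sigma_vox > 0:
        vol = ndimage.gaussian_filter(vol, spec.blur_sigma_vox)
    if spec.noise_sd_hu > 0:
        vol = vol + spec.noise_sd_hu * noise
    np.clip(vol, HU_MIN, HU_MAX, out=vol)
    return CTVolume(
        values=vol.astype(np.float32),
        spacing_um=spec.voxel_spacing_um,
        animal_id=animal_id,
        day=day,
    )


# --------------------------------------------------------------------------
# ex vivo readouts


def simulate_ex_vivo(
    burden: float | dict[str, float],
    linkage: ExVivoLinkage,
    rng_seed: int = 0,
) -> tuple[dict[str, int], float]:
    """Simulate per-lobe Ashcroft grades and hydroxyproline from burden.

    ``burden`` is either one whole-lung fraction (applied to every lobe)
    or a per-lobe mapping of local lesion fractions. Returns
    ``(grades, hydroxyproline_ug)`` where grades maps lobe name to an
    integer 0-8.
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(burden, dict):
        lobe_burden = {l: float(burden[l]) for l in LOBES}
        overall = float(np.mean(list(lobe_burden.values())))
    else:
        overall = float(burden)
        lobe_burden = {l: overall for l in LOBES}
    if not all(0.0 <= b <= 1.0 for b in lobe_burden.values()):
        raise ValueError("burden fractions must lie in [0, 1]")

    grades = {}
    for lobe in LOBES:
        latent = (
            linkage.ashcroft_intercept
            + linkage.ashcroft_slope * lobe_burden[lobe]
            + (rng.normal(0.0, linkage.ashcroft_noise_sd) if linkage.ashcroft_noise_sd else 0.0)
        )
        grades[lobe] = int(np.clip(round(latent), 0, 8))
    hyp = (
        linkage.hyp_baseline_ug
        + linkage.hyp_slope_ug * overall
        + (rng.normal(0.0, linkage.hyp_noise_sd_ug) if linkage.hyp_noise_sd_ug else 0.0)
    )
    return grades, max(0.0, float(hyp))


# --------------------------------------------------------------------------
# cohorts


@dataclass
class AnimalScan:
    animal_id: str
    group: str
    route: str
    treatment: str
    day: int
    ct: CTVolume | None
    truth: PhantomTruth
    true_poor_fraction: float


@dataclass
class CohortData:
    """A simulated study: scans with truth plus tidy design/ex vivo tables."""

    scans: list[AnimalScan]
    design: pd.DataFrame
    exvivo: pd.DataFrame


def _animal_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *key])


def simulate_cohort(
    cohort: CohortSpec,
    spec: PhantomSpec,
    render_ct: bool = True,
) -> CohortData:
    """Simulate every animal of a study design.

    One volume per animal per imaging day: the group burden curve is
    scaled by a per-animal lognormal susceptibility factor
    (CV ``burden_cv``), zeroed for saline animals and multiplied by
    ``drug_burden_factor`` in drug arms from ``treatment_start_day``
    onward. Per-animal rng streams derive from the master seed, so any
    animal regenerates identically in isolation. ``render_ct=False``
    skips HU synthesis (truth-only studies for statistics work).
    """
    scans: list[AnimalScan] = []
    design_rows = []
    exvivo_rows = []
    for gi, group in enumerate(cohort.groups):
        clustering = cohort.clustering_it if group.route == "IT" else cohort.clustering_oa
        for ai in range(group.n_animals):
            animal_id = f"{group.name}-{ai + 1:02d}"
            ss = _animal_seed(cohort.rng_seed, gi, ai)
            geo_seed, susc_seed = [int(s) for s in ss.generate_state(2) >> 1]
            animal_spec = replace(spec, rng_seed=geo_seed)
            geometry = build_lung_geometry(animal_spec)
            susceptibility = float(
                np.random.default_rng(susc_seed).lognormal(
                    mean=-0.5 * math.log(1 + cohort.burden_cv**2),
                    sigma=math.sqrt(math.log(1 + cohort.burden_cv**2)),
                )
            )
            design_rows.append(
                {
                    "animal_id": animal_id,
                    "group": group.name,
                    "route": group.route,
                    "treatment": group.treatment,
                }
            )
            for di, day in enumerate(cohort.days):
                target = burden_at_day(day, cohort.burden) if group.bleomycin else 0.0
                target *= susceptibility
                if group.treatment == "drug" and day >= cohort.treatment_start_day:
                    target *= cohort.drug_burden_factor
                target = min(target, 0.8)
                day_ss = _animal_seed(cohort.rng_seed, gi, ai, di)
                lesion_seed, ct_seed, ev_seed = [
                    int(s) for s in day_ss.generate_state(3) >> 1
                ]
                truth = place_lesions(
                    geometry, target, clustering=clustering, rng_seed=lesion_seed
                )
                ct = None
                if render_ct:
                    ct = synthesize_ct(
                        truth,
                        replace(animal_spec, rng_seed=ct_seed),
                        animal_id=animal_id,
                        day=day,
                    )
                grades, hyp = simulate_ex_vivo(
                    truth.lobe_burdens(), cohort.linkage, rng_seed=ev_seed
                )
                scans.append(
                    AnimalScan(
                        animal_id=animal_id,
                        group=group.name,
                        route=group.route,
                        treatment=group.treatment,
                        day=day,
                        ct=ct,
                        truth=truth,
                        true_poor_fraction=truth.true_poor_fraction,
                    )
                )
                for lobe, grade in grades.items():
                    exvivo_rows.append(
                        {
                            "animal_id": animal_id,
                            "group": group.name,
                            "day": day,
                            "lobe": lobe,
                            "grade": grade,
                            "hydroxyproline_ug": hyp,
                        }
                    )
    return CohortData(
        scans=scans,
        design=pd.DataFrame(design_rows),
        exvivo=pd.DataFrame(exvivo_rows),
    )
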