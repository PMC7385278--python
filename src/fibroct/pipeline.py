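"""End-to-end study orchestration: simulate → segment → quantify →
score → correlate → compare → effect → report.

Each stage writes its outputs under the study directory and records them
(with SHA-256 checksums) in a run manifest; a stage whose outputs already
exist is skipped, so deleting an intermediate and re-running regenerates
only the downstream stages. All randomness derives from the master seed,
so a re-run reproduces every output bit for bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aeration import AerationBins, aeration_timecourse, profiles_to_frame, quantify_volume
from .core import CTVolume, LOBES
from .histo import lobe_heterogeneity, severity_distribution, total_ashcroft
from .io import read_volume, write_volume
from .phantom import (
    BurdenCurveParams,
    CohortSpec,
    ExVivoLinkage,
    GroupSpec,
    PhantomSpec,
    simulate_cohort,
)
from .segmentation import SegParams, segment
from .stats import (
    linear_fit,
    one_way_anova_dunnett,
    treatment_effect,
    two_way_anova_dunnett,
)

STAGES = ("simulate", "segment", "quantify", "score", "correlate", "compare", "effect", "report")


@dataclass
class StudyConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    rng_seed: int = 0
    grid: int = 64
    voxel_spacing_um: float = 50.0
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("saline", route="none", bleomycin=False, n_animals=3),
        GroupSpec("BLM", route="OA", n_animals=3),
        GroupSpec("BLM+drug", route="OA", treatment="drug", n_animals=3),
    )
    days: tuple[int, ...] = (7, 14, 21)
    control_group: str = "saline"
    disease_group: str = "BLM"
    treated_group: str = "BLM+drug"
    effect_mode: str = "inhibition_of_increase"
    phantom: PhantomSpec | None = None
    cohort: CohortSpec | None = None
    seg_params: SegParams = field(default_factory=SegParams)
    bins: AerationBins = field(default_factory=AerationBins)

    def __post_init__(self) -> None:
        if self.phantom is None:
            self.phantom = PhantomSpec(
                grid_shape=(self.grid,) * 3, voxel_spacing_um=self.voxel_spacing_um
            )
        if self.cohort is None:
            self.cohort = CohortSpec(
                groups=tuple(self.groups), days=tuple(self.days), rng_seed=self.rng_seed
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "groups" in raw:
            raw["groups"] = tuple(GroupSpec(**g) for g in raw["groups"])
        if "days" in raw:
            raw["days"] = tuple(raw["days"])
        if "seg_params" in raw:
            raw["seg_params"] = SegParams(**raw["seg_params"])
        if "bins" in raw:
            raw["bins"] = AerationBins(**raw["bins"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # hash the science, not the destination
        payload = json.dumps(fields, sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, per-stage outputs with
    checksums and timings."""

    version: str
    config_hash: str
    rng_seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p.name): _sha256(p) for p in sorted(outputs)},
            "seconds": round(seconds, 3),
        }

    def output_checksums(self) -> dict[str, str]:
        out = {}
        for stage in self.stages.values():
            out.update(stage["outputs"])
        return out

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: StudyConfig, resume: bool = True) -> RunManifest:
    """Run every pipeline stage for the configured study.

    Returns the manifest; intermediate CSV/NIfTI outputs land under
    ``config.out_dir``. With ``resume=True`` a stage whose outputs exist
    is not recomputed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol_dir = out / "volumes"
    mask_dir = out / "masks"
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(), rng_seed=config.rng_seed
    )
    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, out, vol_dir, mask_dir, state, resume)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            manifest.save(out / "manifest.json")
            raise StageError(stage, exc) from exc
        manifest.record(stage, outputs, time.perf_counter() - t0)
    manifest.save(out / "manifest.json")
    return manifest


def _scan_ids(config: StudyConfig) -> list[tuple[str, str, int]]:
    ids = []
    for g in config.cohort.groups:
        for ai in range(g.n_animals):
            for day in config.cohort.days:
                ids.append((f"{g.name}-{ai + 1:02d}", g.name, day))
    return ids


def _stage_simulate(config, out, vol_dir, mask_dir, state, resume):
    vol_dir.mkdir(exist_ok=True)
    design_csv = out / "design.csv"
    exvivo_csv = out / "exvivo.csv"
    truth_csv = out / "truth.csv"
    expected = [design_csv, exvivo_csv, truth_csv]
    vols = {
        (aid, day): vol_dir / f"{aid}_d{day:02d}.nii" for aid, _, day in _scan_ids(config)
    }
    truth_masks = {
        (aid, day): vol_dir / f"{aid}_d{day:02d}_truth.nii"
        for aid, _, day in _scan_ids(config)
    }
    all_files = expected + list(vols.values()) + list(truth_masks.values())
    if resume and all(p.exists() for p in all_files):
        return all_files
    data = simulate_cohort(config.cohort, config.phantom)
    data.design.to_csv(design_csv, index=False)
    data.exvivo.to_csv(exvivo_csv, index=False)
    truth_rows = []
    for scan in data.scans:
        write_volume(scan.ct, vols[(scan.animal_id, scan.day)])
        # truth label volume: lobe labels 1-5, airway 6, lesion flag +10
        labels = scan.truth.lobe_labels.astype(np.int16).copy()
        labels[scan.truth.airway_mask] = 6
        labels[scan.truth.lesion_mask] += 10
        write_volume(labels, truth_masks[(scan.animal_id, scan.day)],
                     spacing_um=config.phantom.voxel_spacing_um)
        truth_rows.append(
            {
                "animal_id": scan.animal_id,
                "group": scan.group,
                "day": scan.day,
                "true_poor_fraction": scan.true_poor_fraction,
            }
        )
    pd.DataFrame(truth_rows).to_csv(truth_csv, index=False)
    return all_files


def _stage_segment(config, out, vol_dir, mask_dir, state, resume):
    mask_dir.mkdir(exist_ok=True)
    outputs = []
    for aid, _, day in _scan_ids(config):
        src = vol_dir / f"{aid}_d{day:02d}.nii"
        dst = mask_dir / f"{aid}_d{day:02d}_seg.nii"
        outputs.append(dst)
        if resume and dst.exists():
            continue
        ct = read_volume(src, animal_id=aid, day=day)
        seg = segment(ct, params=config.seg_params)
        labels = np.zeros(ct.shape, np.int16)
        labels[seg.lung_mask] = seg.side_labels[seg.lung_mask]  # 1 left, 2 right
        labels[seg.airway_mask] = 3
        labels[seg.vessel_mask] = 4
        write_volume(labels, dst, spacing_um=ct.spacing_um)
    return outputs


def _stage_quantify(config, out, vol_dir, mask_dir, state, resume):
    profiles_csv = out / "profiles.csv"
    timecourse_csv = out / "timecourse.csv"
    design = pd.read_csv(out / "design.csv")
    if resume and profiles_csv.exists() and timecourse_csv.exists():
        state["profiles"] = pd.read_csv(profiles_csv)
        return [profiles_csv, timecourse_csv]
    rows = []
    from .aeration import AerationProfile

    profiles = []
    for aid, group, day in _scan_ids(config):
        ct = read_volume(vol_dir / f"{aid}_d{day:02d}.nii", animal_id=aid, day=day)
        labels = read_volume(mask_dir / f"{aid}_d{day:02d}_seg.nii")
        lung = (labels == 1) | (labels == 2)
        prof = quantify_volume(ct, lung, config.bins)
        profiles.append(prof)
        for side, lab in (("left", 1), ("right", 2)):
            side_mask = labels == lab
            if side_mask.any():
                side_prof = quantify_volume(ct, side_mask, config.bins)
                rows.append(
                    {
                        "animal_id": aid,
                        "group": group,
                        "day": day,
                        "side": side,
                        "frac_poor": side_prof.frac_poor,
                    }
                )
    long = profiles_to_frame(profiles)
    long["group"] = long["animal_id"].map(design.set_index("animal_id")["group"])
    long.to_csv(profiles_csv, index=False)
    state["profiles"] = long
    tc = aeration_timecourse(profiles, design)
    tc.to_csv(timecourse_csv, index=False)
    pd.DataFrame(rows).to_csv(out / "profiles_by_side.csv", index=False)
    return [profiles_csv, timecourse_csv, out / "profiles_by_side.csv"]


def _stage_score(config, out, vol_dir, mask_dir, state, resume):
    severity_csv = out / "severity.csv"
    ashcroft_csv = out / "ashcroft.csv"
    hetero_csv = out / "lobe_heterogeneity.csv"
    if resume and severity_csv.exists() and ashcroft_csv.exists() and hetero_csv.exists():
        return [severity_csv, ashcroft_csv, hetero_csv]
    exvivo = pd.read_csv(out / "exvivo.csv")
    sev_rows = []
    for (group, day), sub in exvivo.groupby(["group", "day"]):
        dist = severity_distribution(sub["grade"])
        sev_rows.append(
            {
                "group": group,
                "day": day,
                "freq_mild": dist.freq_mild,
                "freq_moderate": dist.freq_moderate,
                "freq_severe": dist.freq_severe,
                "freq_moderate_severe": dist.freq_moderate_severe,
                "n": dist.n,
            }
        )
    pd.DataFrame(sev_rows).to_csv(severity_csv, index=False)
    ash_rows = []
    for (aid, group, day), sub in exvivo.groupby(["animal_id", "group", "day"]):
        grades = dict(zip(sub["lobe"], sub["grade"]))
        frac_ms = float(np.mean([g >= 4 for g in sub["grade"]]))
        ash_rows.append(
            {
                "animal_id": aid,
                "group": group,
                "day": day,
                "total_ashcroft": total_ashcroft(grades),
                "frac_moderate_severe": frac_ms,
                "hydroxyproline_ug": float(sub["hydroxyproline_ug"].iloc[0]),
            }
        )
    pd.DataFrame(ash_rows).to_csv(ashcroft_csv, index=False)
    het_rows = []
    for (group, day), sub in exvivo.groupby(["group", "day"]):
        if sub["animal_id"].nunique() < 2:
            continue
        het = lobe_heterogeneity(sub)
        het_rows.append(
            {
                "group": group,
                "day": day,
                "heterogeneity_index": het.heterogeneity_index,
                "kw_p": het.comparison.omnibus_p,
            }
        )
    pd.DataFrame(het_rows).to_csv(hetero_csv, index=False)
    return [severity_csv, ashcroft_csv, hetero_csv]


def _stage_correlate(config, out, vol_dir, mask_dir, state, resume):
    corr_csv = out / "correlations.csv"
    if resume and corr_csv.exists():
        return [corr_csv]
    profiles = pd.read_csv(out / "profiles.csv")
    ash = pd.read_csv(out / "ashcroft.csv")
    poor = profiles[profiles["compartment"] == "poor"][
        ["animal_id", "day", "fraction", "group"]
    ].rename(columns={"fraction": "frac_poor"})
    merged = poor.merge(ash, on=["animal_id", "day", "group"])
    disease = merged[merged["group"] != config.control_group]
    rows = []
    for yname in ("frac_moderate_severe", "hydroxyproline_ug", "total_ashcroft"):
        if len(disease) >= 3 and disease["frac_poor"].nunique() > 1:
            fit = linear_fit(disease["frac_poor"], disease[yname])
            rows.append(
                {
                    "x": "frac_poor_3d",
                    "y": yname,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                }
            )
    pd.DataFrame(
        rows, columns=["x", "y", "slope", "intercept", "r_squared", "n"]
    ).to_csv(corr_csv, index=False)
    return [corr_csv]


def _stage_compare(config, out, vol_dir, mask_dir, state, resume):
    cmp_csv = out / "comparisons.csv"
    if resume and cmp_csv.exists():
        return [cmp_csv]
    profiles = pd.read_csv(out / "profiles.csv")
    poor = profiles[profiles["compartment"] == "poor"].rename(
        columns={"fraction": "value"}
    )
    rows = []
    if poor["day"].nunique() > 1:
        res = two_way_anova_dunnett(poor, control=config.control_group)
        rows.append(
            {
                "analysis": "frac_poor two-way ANOVA",
                "effect": "group",
                "p": res.group_p,
            }
        )
        rows.append(
            {"analysis": "frac_poor two-way ANOVA", "effect": "day", "p": res.day_p}
        )
        per_day = res.per_day
    else:
        day = int(poor["day"].iloc[0])
        groups = {g: sub["value"].to_numpy() for g, sub in poor.groupby("group")}
        per_day = {day: one_way_anova_dunnett(groups, control=config.control_group)}
    for day, res in per_day.items():
        for name, p in res.pairwise:
            rows.append(
                {"analysis": f"frac_poor Dunnett day {day}", "effect": name, "p": p}
            )
    pd.DataFrame(rows).to_csv(cmp_csv, index=False)
    return [cmp_csv]


def _stage_effect(config, out, vol_dir, mask_dir, state, resume):
    eff_csv = out / "effect.csv"
    if resume and eff_csv.exists():
        return [eff_csv]
    group_names = {g.name for g in config.cohort.groups}
    rows = []
    if {config.control_group, config.disease_group, config.treated_group} <= group_names:
        profiles = pd.read_csv(out / "profiles.csv")
        poor = profiles[profiles["compartment"] == "poor"]
        last_day = poor["day"].max()
        at_day = poor[poor["day"] == last_day]
        means = at_day.groupby("group")["fraction"].mean()
        eff = treatment_effect(
            means[config.control_group],
            means[config.disease_group],
            means[config.treated_group],
            mode=config.effect_mode,
        )
        rows.append(
            {
                "readout": "frac_poor",
                "day": last_day,
                "mode": eff.mode,
                "percent": eff.percent,
            }
        )
        ash = pd.read_csv(out / "ashcroft.csv")
        at_day = ash[ash["day"] == last_day]
        for col in ("frac_moderate_severe", "hydroxyproline_ug"):
            m = at_day.groupby("group")[col].mean()
            eff = treatment_effect(
                m[config.control_group],
                m[config.disease_group],
                m[config.treated_group],
                mode="reduction_vs_disease",
            )
            rows.append(
                {
                    "readout": col,
                    "day": last_day,
                    "mode": eff.mode,
                    "percent": eff.percent,
                }
            )
    pd.DataFrame(rows, columns=["readout", "day", "mode", "percent"]).to_csv(
        eff_csv, index=False
    )
    return [eff_csv]


def _stage_report(config, out, vol_dir, mask_dir, state, resume):
    from .plots import plot_severity_stacked, plot_timecourse

    report_txt = out / "report.txt"
    figures = []
    tc_all = pd.read_csv(out / "timecourse.csv")
    figures.append(plot_timecourse(tc_all, out / "timecourse_poor.png"))
    sev = pd.read_csv(out / "severity.csv")
    if len(sev):
        figures.append(plot_severity_stacked(sev, out / "severity_stacked.png"))
    lines = [
        f"fibroct {__version__} study report",
        f"config hash: {config.config_hash()}",
        f"master seed: {config.rng_seed}",
        "",
    ]
    tc = pd.read_csv(out / "timecourse.csv")
    poor_tc = tc[tc["compartment"] == "poor"]
    lines.append("poorly-aerated fraction (group mean +/- sem):")
    for _, r in poor_tc.iterrows():
        sem = "n/a" if pd.isna(r["sem"]) else f"{r['sem']:.3f}"
        lines.append(
            f"  {r['group']:>10s} day {int(r['day']):2d}: {r['mean']:.3f} +/- {sem} (n={int(r['n'])})"
        )
    corr = pd.read_csv(out / "correlations.csv")
    if len(corr):
        lines.append("")
        lines.append("correlations with the CT poorly-aerated fraction:")
        for _, r in corr.iterrows():
            lines.append(f"  {r['y']:>22s}: R^2 = {r['r_squared']:.3f} (n={int(r['n'])})")
    eff = pd.read_csv(out / "effect.csv")
    if len(eff):
        lines.append("")
        lines.append("treatment effects:")
        for _, r in eff.iterrows():
            lines.append(f"  {r['readout']:>22s} ({r['mode']}): {r['percent']:.1f}%")
    report_txt.write_text("\n".join(lines) + "\n")
    return [report_txt, *figures]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "quantify": _stage_quantify,
    "score": _stage_score,
    "correlate": _stage_correlate,
    "compare": _stage_compare,
    "effect": _stage_effect,
    "report": _stage_report,
}


def demo_config(out_dir: str | Path, seed: int = 0) -> StudyConfig:
    """The bundled small demonstration study: three arms of three
    animals, days 7/14/21, 64-voxel grid — minutes on one CPU."""
    return StudyConfig(out_dir=str(out_dir), rng_seed=seed, grid=64)
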