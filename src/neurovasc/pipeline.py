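"""End-to-end orchestration: simulate → preprocess → ICA → pair → statistics.

Two layers:

* in-memory analysis (`analyze_study`, `run_replication`) used by tests,
  the acceptance script, and the numbered analysis drivers;
* a run-directory layer (`run_pipeline` and the per-stage functions) that
  persists every intermediate (NIfTI volumes, text regressors, CSV tables,
  JSON manifest) so each stage can be re-run alone from its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decompose import ICADecomposition, load_decomposition, save_decomposition, spatial_ica
from .identify import ComponentPair, find_neural_components, pair_components
from .paradigm import (
    Regressor,
    ValidationError,
    canonical_hrf,
    convolve_to_regressor,
    load_regressor,
    save_regressor,
)
from .physio import baseline_normalize, extract_end_tidal, load_raw_trace, vascular_regressor
from .preprocess import detrend_and_percent, group_average, load_bold, save_bold
from .stats import (
    StatsReport,
    dual_regression_timeseries,
    normalized_r2_table,
    paired_component_tests,
    replication_analysis,
)
from .synthetic import Study, StudyConfig, simulate_study, write_study

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_study",
           "run_replication", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Single-document pipeline configuration (YAML-serializable)."""

    mode: str = "hypercapnia"
    master_seed: int = 0
    n_comp: int = 30
    threshold_level: float = 0.5
    alpha: float = 0.05
    bonferroni_m: int | None = None
    study: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self):
        if isinstance(self.study, dict):
            study_kwargs = dict(self.study)
            study_kwargs.setdefault("mode", self.mode)
            self.study = StudyConfig(**study_kwargs)
        if self.study.mode != self.mode:
            raise ValidationError(
                f"pipeline mode {self.mode!r} != study mode {self.study.mode!r}"
            )
        if not (0 < self.threshold_level <= 1):
            raise ValidationError("threshold_level must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_comp < 2:
            raise ValidationError("n_comp must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValidationError(f"config root must be a mapping, got {type(doc)}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["study"]["pair_specs"] = [asdict(s) for s in self.study.pair_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class AnalysisResult:
    """Everything the hypercapnia-mode analysis produces."""

    study: Study
    preprocessed: dict                 # (subject_id, scan_id) -> BOLDDataset
    group_avg: object
    decomp: ICADecomposition
    neural_labels: dict
    pairs: list
    masks: list
    wm_reg: Regressor
    vis_reg: Regressor
    regressors_by_scan: dict
    scan_ts: dict
    table: pd.DataFrame
    report: StatsReport


def task_regressors(study: Study) -> tuple[Regressor, Regressor]:
    """HRF-convolved working-memory and visual regressors on the TR grid."""
    cfg = study.config
    wm = convolve_to_regressor(
        study.paradigms["working_memory"].timecourse, study.hrf,
        cfg.tr_s, cfg.n_vols, name="working_memory",
    )
    vis = convolve_to_regressor(
        study.paradigms["visual"].timecourse, study.hrf,
        cfg.tr_s, cfg.n_vols, name="visual",
    )
    return wm, vis


def analyze_study(
    study: Study,
    n_comp: int = 30,
    threshold_level: float = 0.5,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Full in-memory hypercapnia-mode analysis chain."""
    cfg = study.config
    wm_reg, vis_reg = task_regressors(study)

    preprocessed = {}
    for scan in study.scans:
        preprocessed[(scan.subject_id, scan.scan_id)] = detrend_and_percent(scan.bold)
    avg = group_average(preprocessed.values())

    decomp = spatial_ica(avg, n_comp=n_comp, seed=seed)
    labels = find_neural_components(decomp, wm_reg, vis_reg)
    pairs, masks = pair_components(decomp, labels, level=threshold_level)

    pair_index = {
        p.label: {"neural": p.neural_idx, "vascular": p.vascular_idx}
        for p in pairs if p.matched
    }
    scan_ts, regs_by_scan = {}, {}
    for scan in study.scans:
        sid = (scan.subject_id, scan.scan_id)
        scan_ts[sid] = dual_regression_timeseries(preprocessed[sid], decomp.maps)
        trace = baseline_normalize(scan.petco2)
        regs_by_scan[sid] = {
            "working_memory": wm_reg,
            "visual": vis_reg,
            "co2": vascular_regressor(trace, study.hrf, cfg.tr_s, cfg.n_vols),
        }
    table = normalized_r2_table(scan_ts, pair_index, regs_by_scan)
    report = paired_component_tests(table, alpha=alpha, m=bonferroni_m, seed=seed)
    return AnalysisResult(
        study=study, preprocessed=preprocessed, group_avg=avg, decomp=decomp,
        neural_labels=labels, pairs=pairs, masks=masks, wm_reg=wm_reg,
        vis_reg=vis_reg, regressors_by_scan=regs_by_scan, scan_ts=scan_ts,
        table=table, report=report,
    )


def run_replication(
    replication_study: Study,
    original: AnalysisResult,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Replication-mode analysis using the original maps (in-memory)."""
    wm_reg, vis_reg = task_regressors(replication_study)
    return replication_analysis(
        replication_study, original.decomp,
        [p for p in original.pairs if p.matched],
        wm_reg, vis_reg, level_alpha=alpha, seed=seed,
    )


# -- run-directory layer -----------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _scan_items(outdir: Path):
    with open(outdir / "study" / "manifest.json") as fh:
        manifest = json.load(fh)
    return manifest


def _pairs_to_csv(pairs, path) -> None:
    pd.DataFrame([{
        "label": p.label, "neural_idx": p.neural_idx,
        "vascular_idx": -1 if p.vascular_idx is None else p.vascular_idx,
        "dice": p.dice, "neural_corr": p.neural_corr, "matched": p.matched,
    } for p in pairs]).to_csv(path, index=False)


def _pairs_from_csv(path):
    df = pd.read_csv(path)
    return [ComponentPair(
        label=r.label, neural_idx=int(r.neural_idx),
        vascular_idx=None if r.vascular_idx < 0 else int(r.vascular_idx),
        dice=float(r.dice), neural_corr=float(r.neural_corr),
        matched=bool(r.matched),
    ) for r in df.itertuples()]


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> Study:
    study = simulate_study(cfg.study, master_seed=cfg.master_seed)
    write_study(study, outdir / "study")
    return study


def stage_extract_petco2(cfg: PipelineConfig, outdir: Path) -> None:
    """Raw gas traces → baseline-normalized, convolved CO2 regressors."""
    scfg = cfg.study
    hrf = canonical_hrf(0.1)
    rdir = outdir / "regressors"
    rdir.mkdir(exist_ok=True)
    from .paradigm import default_paradigms

    pars = default_paradigms(include_hypercapnia=(cfg.mode == "hypercapnia"))
    for nm, par in pars.items():
        save_regressor(
            convolve_to_regressor(par.timecourse, hrf, scfg.tr_s, scfg.n_vols,
                                  name=nm),
            rdir / f"{nm}.txt",
        )
    manifest = _scan_items(outdir)
    grid_t = np.arange(scfg.n_vols) * scfg.tr_s
    for item in manifest["scans"]:
        raw = load_raw_trace(outdir / "study" / item["co2_trace"])
        trace = baseline_normalize(extract_end_tidal(raw, grid_t_s=grid_t))
        reg = vascular_regressor(trace, hrf, scfg.tr_s, scfg.n_vols)
        stem = f"co2_sub-{item['subject_id']:02d}_scan-{item['scan_id']}"
        save_regressor(reg, rdir / f"{stem}.txt")


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    scfg = cfg.study
    pdir = outdir / "preproc"
    pdir.mkdir(exist_ok=True)
    manifest = _scan_items(outdir)
    processed = []
    for item in manifest["scans"]:
        ds = load_bold(outdir / "study" / item["bold"], tr_s=scfg.tr_s,
                       units="raw", mask_path=outdir / "study" / "mask.nii.gz")
        pct = detrend_and_percent(ds)
        stem = f"sub-{item['subject_id']:02d}_scan-{item['scan_id']}"
        save_bold(pct, pdir / f"{stem}_pct.nii.gz")
        processed.append(pct)
    avg = group_average(processed)
    save_bold(avg, pdir / "group_average.nii.gz",
              mask_path=pdir / "mask.nii.gz")


def stage_decompose(cfg: PipelineConfig, outdir: Path) -> None:
    scfg = cfg.study
    idir = outdir / "ica"
    idir.mkdir(exist_ok=True)
    avg = load_bold(outdir / "preproc" / "group_average.nii.gz",
                    tr_s=scfg.tr_s, units="percent_bold",
                    mask_path=outdir / "preproc" / "mask.nii.gz")
    decomp = spatial_ica(avg, n_comp=cfg.n_comp, seed=cfg.master_seed)
    save_decomposition(decomp, idir / "maps.nii.gz", idir / "timeseries.txt",
                       idir / "ica.json")


def _load_run_decomp(cfg: PipelineConfig, outdir: Path) -> ICADecomposition:
    import nibabel as nib

    mask = np.asarray(
        nib.load(str(outdir / "preproc" / "mask.nii.gz")).dataobj) > 0
    return load_decomposition(outdir / "ica" / "maps.nii.gz",
                              outdir / "ica" / "timeseries.txt",
                              outdir / "ica" / "ica.json", mask)


def stage_identify(cfg: PipelineConfig, outdir: Path) -> list:
    scfg = cfg.study
    decomp = _load_run_decomp(cfg, outdir)
    rdir = outdir / "regressors"
    wm = load_regressor(rdir / "working_memory.txt", scfg.tr_s, "working_memory")
    vis = load_regressor(rdir / "visual.txt", scfg.tr_s, "visual")
    labels = find_neural_components(decomp, wm, vis)
    pairs, _ = pair_components(decomp, labels, level=cfg.threshold_level)
    (outdir / "pairs").mkdir(exist_ok=True)
    _pairs_to_csv(pairs, outdir / "pairs" / "pairs.csv")
    return pairs


def stage_dualreg(cfg: PipelineConfig, outdir: Path) -> StatsReport:
    scfg = cfg.study
    decomp = _load_run_decomp(cfg, outdir)
    pairs = _pairs_from_csv(outdir / "pairs" / "pairs.csv")
    pair_index = {p.label: {"neural": p.neural_idx, "vascular": p.vascular_idx}
                  for p in pairs if p.matched}
    rdir = outdir / "regressors"
    wm = load_regressor(rdir / "working_memory.txt", scfg.tr_s, "working_memory")
    vis = load_regressor(rdir / "visual.txt", scfg.tr_s, "visual")
    manifest = _scan_items(outdir)
    scan_ts, regs_by_scan = {}, {}
    for item in manifest["scans"]:
        sid = (item["subject_id"], item["scan_id"])
        stem = f"sub-{item['subject_id']:02d}_scan-{item['scan_id']}"
        ds = load_bold(outdir / "preproc" / f"{stem}_pct.nii.gz",
                       tr_s=scfg.tr_s, units="percent_bold",
                       mask_path=outdir / "preproc" / "mask.nii.gz")
        scan_ts[sid] = dual_regression_timeseries(ds, decomp.maps)
        co2 = load_regressor(
            rdir / f"co2_sub-{item['subject_id']:02d}_scan-{item['scan_id']}.txt",
            scfg.tr_s, "co2")
        regs_by_scan[sid] = {"working_memory": wm, "visual": vis, "co2": co2}
    table = normalized_r2_table(scan_ts, pair_index, regs_by_scan)
    report = paired_component_tests(table, alpha=cfg.alpha, m=cfg.bonferroni_m,
                                    seed=cfg.master_seed)
    sdir = outdir / "stats"
    sdir.mkdir(exist_ok=True)
    table.to_csv(sdir / "normalized_r2.csv", index=False)
    report.table.to_csv(sdir / "stats_report.csv", index=False)
    return report


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    """Bar figure of normalized R² per pair and stimulus."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = pd.read_csv(outdir / "stats" / "normalized_r2.csv")
    stimuli = sorted(table["stimulus"].unique())
    labels = sorted(table["label"].unique())
    fig, axes = plt.subplots(len(stimuli), len(labels),
                             figsize=(3 * len(labels), 2.5 * len(stimuli)),
                             squeeze=False)
    for i, stim in enumerate(stimuli):
        for j, lab in enumerate(labels):
            sub = table[(table.stimulus == stim) & (table.label == lab)]
            g = sub.groupby("member")["normalized_r2"]
            means, sems = g.mean(), g.sem()
            ax = axes[i][j]
            order = ["neural", "vascular"]
            ax.bar(range(2), [means[m] for m in order],
                   yerr=[sems[m] for m in order],
                   color=["tab:blue", "tab:red"], capsize=3)
            ax.set_xticks(range(2), order)
            ax.set_ylim(0, 1)
            if i == 0:
                ax.set_title(lab)
            if j == 0:
                ax.set_ylabel(f"{stim}\nnormalized $R^2$")
    fig.tight_layout()
    fig.savefig(outdir / "stats" / "normalized_r2_bars.png", dpi=120)
    plt.close(fig)


def stage_replicate(cfg: PipelineConfig, outdir: Path,
                    original_dir: Path) -> dict:
    """Apply an original run's maps/pairs to this (replication) run's scans."""
    from .paradigm import default_paradigms
    from .synthetic import Scan, ellipsoid_mask

    scfg = cfg.study
    orig_cfg = PipelineConfig.from_yaml(Path(original_dir) / "config.yaml")
    decomp = _load_run_decomp(orig_cfg, Path(original_dir))
    pairs = _pairs_from_csv(Path(original_dir) / "pairs" / "pairs.csv")

    manifest = _scan_items(outdir)
    grid_t = np.arange(scfg.n_vols) * scfg.tr_s
    scans, preprocessed = [], {}
    for item in manifest["scans"]:
        sid = (item["subject_id"], item["scan_id"])
        stem = f"sub-{item['subject_id']:02d}_scan-{item['scan_id']}"
        ds = load_bold(outdir / "preproc" / f"{stem}_pct.nii.gz",
                       tr_s=scfg.tr_s, units="percent_bold",
                       mask_path=outdir / "preproc" / "mask.nii.gz")
        preprocessed[sid] = ds
        raw = load_raw_trace(outdir / "study" / item["co2_trace"])
        petco2 = extract_end_tidal(raw, grid_t_s=grid_t)
        scans.append(Scan(subject_id=item["subject_id"],
                          scan_id=item["scan_id"], bold=None, petco2=petco2,
                          raw_gas=raw, source_ts={}))
    study = Study(mode="replication", scans=scans,
                  paradigms=default_paradigms(include_hypercapnia=False),
                  hrf=canonical_hrf(0.1), ground_truth=None, config=scfg,
                  mask=ellipsoid_mask(scfg.grid))
    table, report, coupling = replication_analysis(
        study, decomp, [p for p in pairs if p.matched],
        load_regressor(outdir / "regressors" / "working_memory.txt",
                       scfg.tr_s, "working_memory"),
        load_regressor(outdir / "regressors" / "visual.txt", scfg.tr_s,
                       "visual"),
        level_alpha=cfg.alpha, seed=cfg.master_seed,
        preprocessed=preprocessed,
    )
    sdir = outdir / "stats"
    sdir.mkdir(exist_ok=True)
    table.to_csv(sdir / "normalized_r2.csv", index=False)
    report.table.to_csv(sdir / "stats_report.csv", index=False)
    with open(sdir / "coupling.json", "w") as fh:
        json.dump(coupling, fh, indent=2)
    return coupling


STAGES_HYPERCAPNIA = ["simulate", "extract-petco2", "preprocess", "decompose",
                      "identify", "dualreg", "report"]
STAGES_REPLICATION = ["simulate", "extract-petco2", "preprocess", "replicate",
                      "report"]


def run_pipeline(cfg: PipelineConfig, outdir, original_dir=None) -> dict:
    """Run every stage in order; returns the run manifest.

    Replication mode requires ``original_dir`` — the run directory of a
    completed hypercapnia analysis whose maps and pairs are re-applied.  A
    stage failure raises after logging the stage name; completed-stage
    outputs are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    if cfg.mode == "replication":
        if original_dir is None:
            raise ValidationError(
                "replication mode requires the original run directory"
            )
        stages = STAGES_REPLICATION
    else:
        stages = STAGES_HYPERCAPNIA
    funcs = {
        "simulate": stage_simulate,
        "extract-petco2": stage_extract_petco2,
        "preprocess": stage_preprocess,
        "decompose": stage_decompose,
        "identify": stage_identify,
        "dualreg": stage_dualreg,
        "replicate": lambda c, o: stage_replicate(c, o, Path(original_dir)),
        "report": stage_report,
    }
    manifest = {"mode": cfg.mode, "master_seed": cfg.master_seed, "stages": {}}
    for name in stages:
        log.info("running stage %s", name)
        try:
            funcs[name](cfg, outdir)
        except Exception:
            log.error("stage %s failed", name)
            raise
        manifest["stages"][name] = "ok"
    for rel in ["pairs/pairs.csv", "stats/normalized_r2.csv",
                "stats/stats_report.csv"]:
        p = outdir / rel
        if p.exists():
            manifest.setdefault("hashes", {})[rel] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
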