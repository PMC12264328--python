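"""End-to-end orchestration: simulate → uncertainty → masks → features →
stability → discrimination.

A :class:`RunConfig` bundles the cohort parameters, one or more named
stochastic-model profiles, the confidence levels to scan, the radiomics
settings and the seeds.  :func:`run_pipeline` executes every stage for
every profile and returns (and optionally writes) a report containing

* per-scan segmentation accuracy (3-D Dice of the mean-prediction mask
  against ground truth) and the KL uncertainty-separability metric;
* per-threshold stability class counts and the optimal confidence level
  th_opt per subject group;
* per-feature ICC tables and Wilcoxon comparisons of the ICC
  distributions against the uncertainty-blind baselines;
* the classification stage: selected features, scan-level out-of-fold
  predictions, AUC per method and DeLong p-values versus the baselines.

Re-running with the same config and seed reproduces all outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import discrim, radfeat, stability, uncmask
from .errors import RadstabError, UndefinedDivergenceError
from .synthcohort import (
    PROFILES,
    CohortParams,
    ModelProfile,
    ScanRecord,
    simulate_cohort,
    simulate_prob_stack,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

STAGES = ("simulate", "uncertainty", "features", "stability", "classify")


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    cohort: CohortParams = field(default_factory=CohortParams)
    profiles: Mapping[str, ModelProfile] = field(
        default_factory=lambda: dict(PROFILES)
    )
    T: int = 50
    thresholds: Tuple[float, ...] = uncmask.DEFAULT_THRESHOLDS
    radiomics: radfeat.RadiomicsConfig = field(default_factory=radfeat.RadiomicsConfig)
    icc_cutoff: float = 0.8
    n_boot: int = 500
    n_selected: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = {k: asdict(v) for k, v in self.profiles.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortParams(**d["cohort"])
        if "profiles" in d:
            d["profiles"] = {
                k: (v if isinstance(v, ModelProfile) else ModelProfile(**v))
                for k, v in d["profiles"].items()
            }
        if "radiomics" in d:
            rc = d["radiomics"]
            if not isinstance(rc, radfeat.RadiomicsConfig):
                rc = dict(rc)
                for key in ("target_spacing", "categories"):
                    if key in rc:
                        rc[key] = tuple(rc[key])
                d["radiomics"] = radfeat.RadiomicsConfig(**rc)
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """All artifacts of one run, in memory."""

    config: RunConfig
    scans: List[ScanRecord]
    accuracy: pd.DataFrame  # per (profile, scan): dsc, kl
    features: pd.DataFrame  # tidy feature table incl. profile column
    baseline: Dict[str, pd.DataFrame]  # per profile: GT/MP baseline ICCs
    scans_by_th: Dict[str, stability.ThresholdScan]  # per profile
    wilcoxon: pd.DataFrame
    classification: Dict[str, dict]
    manifest: dict


def _scan_masks(scans: Sequence[ScanRecord]) -> List[np.ndarray]:
    return [s.gt_mask for s in scans]


def _repeatable_features(
    scan: stability.ThresholdScan, groups: Sequence[str]
) -> Tuple[List[str], Dict[str, float]]:
    """Classes 1∪3 at each group's th_opt, intersected across groups."""
    sets = []
    for g in groups:
        th = scan.th_opt[g]
        sets.append(set(scan.features_in_classes(g, th, classes=(1, 3))))
    common = set.intersection(*sets) if sets else set()
    return sorted(common), dict(scan.th_opt)


def _baseline_repeatable(df: pd.DataFrame, method: str) -> List[str]:
    sub = df[(df["method"] == method) & df["stability_class"].isin([1, 3])]
    per_group = [set(g["feature"]) for _, g in sub.groupby("group")]
    return sorted(set.intersection(*per_group)) if per_group else []


def _classify_method(
    table: pd.DataFrame,
    source: str,
    repeatable: List[str],
    cfg: RunConfig,
    rng_seed: int,
) -> Optional[dict]:
    """Feature filtering + bootstrapped MRMR + LOPO logistic regression
    for one mask source; returns None when no usable features remain."""
    sub = table[table["mask_source"] == source].reset_index(drop=True)
    cols = [f for f in repeatable if f in sub.columns]
    if not cols:
        return None
    feats = discrim.filter_features(sub[cols]) if "shape_MeshVolume" in cols else sub[
        [c for c in cols if sub[c].std() > 0]
    ]
    if feats.shape[1] == 0:
        return None
    k = min(cfg.n_selected, feats.shape[1])
    selected = discrim.mrmr_bootstrap(
        feats, sub["group"], n_boot=cfg.n_boot, k=k, seed=rng_seed
    )
    report = discrim.fit_eval_lopo(sub, sub["group"], sub["subject_id"], selected)
    return {
        "source": source,
        "n_repeatable": len(cols),
        "n_candidates": int(feats.shape[1]),
        "selected_features": report.selected_features,
        "auc": report.auc,
        "y_true": report.y_true.tolist(),
        "y_prob": report.y_prob.tolist(),
        "skipped_folds": report.skipped_folds,
    }


def run_pipeline(
    config: RunConfig,
    outdir: Optional[Path] = None,
    stage: str = "classify",
    cache: bool = False,
) -> RunReport:
    """Run the pipeline up to ``stage`` (one of
    simulate/uncertainty/features/stability/classify) for every profile."""
    if stage not in STAGES:
        raise RadstabError(f"unknown stage {stage!r}; choose from {STAGES}")
    stage_idx = STAGES.index(stage)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    scans = simulate_cohort(config.cohort)
    groups = sorted({s.group for s in scans})
    accuracy_rows: List[dict] = []
    feat_frames: List[pd.DataFrame] = []
    baseline: Dict[str, pd.DataFrame] = {}
    scans_by_th: Dict[str, stability.ThresholdScan] = {}
    wilcoxon_rows: List[dict] = []
    classification: Dict[str, dict] = {}

    feature_cache = outdir / "features.csv" if outdir is not None else None
    gt_table: Optional[pd.DataFrame] = None
    cached = None
    if (
        cache
        and stage_idx >= 2
        and feature_cache is not None
        and feature_cache.exists()
    ):
        cached = pd.read_csv(feature_cache)

    if stage_idx >= 1:
        root = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 17])
        profile_seeds = root.spawn(len(config.profiles))
        mrmr_rng = np.random.default_rng(root.spawn(1)[0])
        if stage_idx >= 2 and cached is None:
            gt_table = radfeat.extract_feature_table(
                scans, {"GT": _scan_masks(scans)}, config.radiomics
            )
        for p_idx, (pname, profile) in enumerate(config.profiles.items()):
            scan_seeds = profile_seeds[p_idx].spawn(len(scans))
            mask_sources: Dict[str, List[np.ndarray]] = {"MP": []}
            for th in config.thresholds:
                mask_sources[f"CL_{th:g}"] = []
            for s_idx, scan in enumerate(scans):
                stack = simulate_prob_stack(
                    scan, profile, T=config.T, seed=scan_seeds[s_idx]
                )
                mp = uncmask.mean_prediction(stack)
                unc = uncmask.uncertainty_decompose(stack)
                cls = uncmask.confidence_masks(stack, config.thresholds)
                try:
                    kl = uncmask.kl_uncertainty_separability(
                        unc.predictive, mp.mp_mask, scan.gt_mask
                    )
                except UndefinedDivergenceError:
                    kl = float("nan")
                accuracy_rows.append(
                    {
                        "profile": pname,
                        "subject_id": scan.subject_id,
                        "group": scan.group,
                        "repeat_index": scan.repeat_index,
                        "dsc_3d": uncmask.dice_score(mp.mp_mask, scan.gt_mask),
                        "kl_divergence": kl,
                    }
                )
                mask_sources["MP"].append(mp.mp_mask)
                for th in config.thresholds:
                    mask_sources[f"CL_{th:g}"].append(cls[float(th)])

            if stage_idx < 2:
                continue
            if cached is not None:
                table = cached[cached["profile"] == pname].drop(columns="profile")
            else:
                table = radfeat.extract_feature_table(
                    scans, mask_sources, config.radiomics
                )
                table = pd.concat([gt_table, table], ignore_index=True)
            feat_frames.append(table.assign(profile=pname))

            if stage_idx < 3:
                continue
            base = stability.baseline_analysis(
                table, auto_source="MP", cutoff=config.icc_cutoff
            )
            baseline[pname] = base
            th_scan = stability.threshold_scan(
                table, config.thresholds, cutoff=config.icc_cutoff
            )
            scans_by_th[pname] = th_scan
            # ICC distributions of the uncertainty-informed method at each
            # group's th_opt, compared to the uncertainty-blind baselines
            for g in groups:
                th = th_scan.th_opt[g]
                sel = th_scan.icc[
                    (th_scan.icc["group"] == g) & (th_scan.icc["th"] == th)
                ].set_index("feature")
                for ref in ("GT", "MP"):
                    ref_icc = base[
                        (base["method"] == ref) & (base["group"] == g)
                    ].set_index("feature")
                    for metric in ("icc_s", "icc_a"):
                        stat, p = stability.wilcoxon_compare(
                            sel[metric].reindex(ref_icc.index),
                            ref_icc[metric],
                        )
                        wilcoxon_rows.append(
                            {
                                "profile": pname,
                                "group": g,
                                "reference": ref,
                                "metric": metric,
                                "th": th,
                                "statistic": stat,
                                "p_value": p,
                            }
                        )

            if stage_idx < 4:
                continue
            repeatable, th_opt = _repeatable_features(th_scan, groups)
            cl_sources = {g: f"CL_{th_opt[g]:g}" for g in groups}
            method_entry = {}
            res = _classify_method(
                table,
                cl_sources[groups[0]],
                repeatable,
                config,
                rng_seed=int(mrmr_rng.integers(2**31)),
            )
            if res is not None:
                res["th_opt"] = th_opt
                method_entry["uncertainty"] = res
            for ref in ("GT", "MP"):
                ref_rep = _baseline_repeatable(base, ref)
                ref_res = _classify_method(
                    table, ref, ref_rep, config,
                    rng_seed=int(mrmr_rng.integers(2**31)),
                )
                if ref_res is not None:
                    method_entry[ref] = ref_res
            if "uncertainty" in method_entry:
                for ref in ("GT", "MP"):
                    if ref in method_entry:
                        method_entry["uncertainty"][f"delong_p_vs_{ref}"] = (
                            discrim.delong_test(
                                method_entry["uncertainty"]["y_prob"],
                                method_entry[ref]["y_prob"],
                                method_entry["uncertainty"]["y_true"],
                            )
                        )
            classification[pname] = method_entry

    accuracy = pd.DataFrame(accuracy_rows)
    features = (
        pd.concat(feat_frames, ignore_index=True) if feat_frames else pd.DataFrame()
    )
    wilcoxon = pd.DataFrame(wilcoxon_rows)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage": stage,
        "n_scans": len(scans),
        "outputs": [],
    }
    report = RunReport(
        config=config,
        scans=scans,
        accuracy=accuracy,
        features=features,
        baseline=baseline,
        scans_by_th=scans_by_th,
        wilcoxon=wilcoxon,
        classification=classification,
        manifest=manifest,
    )
    if outdir is not None:
        _write_report(report, outdir, stage_idx)
    return report


def _write_report(report: RunReport, outdir: Path, stage_idx: int) -> None:
    written: List[str] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(name)

    def save_json(obj, name: str) -> None:
        (outdir / name).write_text(json.dumps(obj, indent=2, default=float))
        written.append(name)

    index = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "repeat_index": s.repeat_index,
                "n_voxels_gt": int(s.gt_mask.sum()),
            }
            for s in report.scans
        ]
    )
    save_df(index, "scan_index.csv")
    if stage_idx >= 1 and len(report.accuracy):
        save_df(report.accuracy, "accuracy.csv")
    if stage_idx >= 2 and len(report.features):
        save_df(report.features, "features.csv")
    if stage_idx >= 3:
        for pname, th_scan in report.scans_by_th.items():
            save_df(th_scan.icc, f"icc_{pname}.csv")
            counts = th_scan.class_counts.reset_index()
            save_df(counts, f"class_counts_{pname}.csv")
        save_json(
            {p: s.th_opt for p, s in report.scans_by_th.items()}, "th_opt.json"
        )
        if len(report.wilcoxon):
            save_df(report.wilcoxon, "wilcoxon.csv")
    if stage_idx >= 4 and report.classification:
        save_json(report.classification, "classification.json")
    report.manifest["outputs"] = written + ["manifest.json"]
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=float)
    )
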