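"""End-to-end study replica: simulate -> segment -> decompose -> featurize ->
assemble datasets -> balance -> evaluate -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import pandas as pd

from noduletex.contourlet import TransformConfig, contourlet_decompose, pad_to_admissible
from noduletex.evaluate import (
    KernelConfig,
    SmoteProfile,
    cross_validate,
    stratified_eval,
)
from noduletex.features import DEFAULT_OFFSETS, DEFAULT_LEVELS, extract_feature_vector, feature_names
from noduletex.segment import clean_roi
from noduletex.smote import Dataset
from noduletex.stats import cohort_tables, feature_screen, BINARY_VARIABLES, CONTINUOUS_VARIABLES
from noduletex.synthetic import CohortSpec, SyntheticCohort, generate_cohort, write_cohort

log = logging.getLogger("noduletex")

__all__ = ["RunConfig", "run_study", "make_fixtures", "featurize_cohort",
           "assemble_datasets", "derive_seed"]


def derive_seed(master: int, stage: str) -> int:
    """Counter-free deterministic per-stage seed from the global seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation_tolerance: float = 30.0
    segmentation_mode: str = "adaptive"
    transform: TransformConfig = field(default_factory=TransformConfig)
    quant_levels: int = DEFAULT_LEVELS
    offsets: Tuple[Tuple[int, int], ...] = DEFAULT_OFFSETS
    smote: SmoteProfile = field(default_factory=lambda: SmoteProfile(mode="off"))
    kernel: KernelConfig = field(default_factory=KernelConfig)
    folds: int = 10
    grouping: str = "roi"
    dataset: str = "both"  # info | texture | both
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cohort": asdict(self.cohort),
                "seg": [self.segmentation_tolerance, self.segmentation_mode],
                "transform": asdict(self.transform),
                "quant": [self.quant_levels, list(map(list, self.offsets))],
                "smote": asdict(self.smote),
                "kernel": asdict(self.kernel),
                "folds": self.folds,
                "grouping": self.grouping,
                "dataset": self.dataset,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def featurize_cohort(cohort: SyntheticCohort, cfg: RunConfig | None = None,
                     segment: bool = True) -> pd.DataFrame:
    """Segment each ROI, decompose it and extract the 672-entry feature row."""
    cfg = cfg or RunConfig()
    names = feature_names(cfg.transform)
    rows = []
    for roi in cohort.rois:
        r = roi
        if segment:
            r = clean_roi(roi, cfg.segmentation_tolerance,
                          mode=cfg.segmentation_mode)
        img, _ = pad_to_admissible(r.pixels, cfg.transform)
        sb = contourlet_decompose(img, cfg.transform)
        fv = extract_feature_vector(sb, cfg.quant_levels, cfg.offsets)
        row = {"roi_id": roi.roi_id, "patient_id": roi.patient_id,
               "label": roi.label, "diameter_mm": roi.diameter_mm}
        row.update(zip(names, fv.values))
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_datasets(features: pd.DataFrame, patients: pd.DataFrame,
                      which: str = "both") -> Dict[str, Dataset]:
    """Build the three dataset variants (info / texture / both), one row per
    ROI; patient-information columns repeat across a patient's ROIs."""
    info_cols = [c for c in list(BINARY_VARIABLES) + list(CONTINUOUS_VARIABLES)]
    tex_cols = [c for c in features.columns
                if c not in ("roi_id", "patient_id", "label", "diameter_mm")]
    merged = features.merge(patients[["patient_id"] + info_cols],
                            on="patient_id", how="left", validate="m:1")
    y = (merged["label"] == "malignant").astype(int).to_numpy()
    groups = merged["patient_id"].to_numpy()
    out = {}
    variants = {
        "info": info_cols,
        "texture": tex_cols,
        "both": tex_cols + info_cols,
    }
    wanted = list(variants) if which == "all" else [which]
    for name in wanted:
        cols = variants[name]
        out[name] = Dataset(X=merged[cols].to_numpy(dtype=float), y=y,
                            groups=groups, feature_names=list(cols))
    return out


def run_study(cfg: RunConfig, outdir: str | Path) -> Path:
    """Run the full replica and write feature CSVs, reports and logs.

    Produces the three-variant comparison (seven metrics for info / texture /
    combined datasets), a per-feature-family report and a diameter-stratified
    report, all stamped with the config hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    try:
        log.info("run %s", stamp)
        cohort_seed = derive_seed(cfg.seed, "cohort")
        spec = CohortSpec(**{**asdict(cfg.cohort), "seed": cohort_seed})
        cohort = generate_cohort(spec)
        log.info("cohort: %d patients, %d ROIs", len(cohort.patients),
                 len(cohort.rois))
        features = featurize_cohort(cohort, cfg)
        features.to_csv(outdir / "features.csv", index=False)
        cohort.patients.to_csv(outdir / "patients.csv", index=False)

        tables = cohort_tables(cohort.patients)
        (outdir / "cohort_tables.json").write_text(
            json.dumps({**stamp, "tables": tables}, indent=1, default=float))

        datasets = assemble_datasets(features, cohort.patients, which="all")
        if cfg.dataset != "both" and cfg.dataset not in datasets:
            raise ValueError(f"unknown dataset variant {cfg.dataset!r}")
        eval_seed = derive_seed(cfg.seed, "eval")
        kernel = KernelConfig(gamma=cfg.kernel.gamma, cost=cfg.kernel.cost,
                              seed=eval_seed)
        variant_reports = {}
        for name, ds in datasets.items():
            rep = cross_validate(ds, kernel, folds=cfg.folds,
                                 grouping=cfg.grouping, balance=cfg.smote)
            variant_reports[name] = rep.as_dict()
            log.info("variant %s: %s", name, variant_reports[name])
        (outdir / "variant_report.json").write_text(
            json.dumps({**stamp, "variants": variant_reports}, indent=1))

        screen = feature_screen(
            datasets["texture"].X, datasets["texture"].y,
            feature_names=datasets["texture"].feature_names)
        screen.to_csv(outdir / "feature_screen.csv")

        diam = features["diameter_mm"].to_numpy()
        strat = stratified_eval(datasets["texture"], diam, kernel,
                                folds=cfg.folds, grouping=cfg.grouping)
        (outdir / "size_report.json").write_text(json.dumps(
            {**stamp, "groups": {k: v.as_dict() for k, v in strat.items()}},
            indent=1))
        (outdir / "config.json").write_text(json.dumps(
            {**stamp, "config": cfg.config_hash()}, indent=1))
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()


_FIXTURE_SPECS = {
    "tiny": CohortSpec(n_benign_patients=4, n_malignant_patients=4,
                       rois_per_patient=(2, 3), image_size=64,
                       diameter_range_mm=(7.0, 25.0), seed=11),
    "small": CohortSpec(n_benign_patients=15, n_malignant_patients=45,
                        rois_per_patient=(3, 5), image_size=128,
                        diameter_range_mm=(7.0, 30.0), seed=12),
}


def make_fixtures(size: str, outdir: str | Path) -> Path:
    """Write a checksum-stable test cohort (tiny: 8 patients at 64 px;
    small: 60 patients at 128 px)."""
    if size not in _FIXTURE_SPECS:
        raise ValueError(f"unknown fixture size {size!r}")
    cohort = generate_cohort(_FIXTURE_SPECS[size])
    return write_cohort(cohort, Path(outdir))
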