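"""End-to-end pipeline orchestration.

``run_pipeline`` sequences preprocess -> rings -> habitat fit/apply ->
extraction -> imputation -> selection -> model fit -> evaluation on either a
case manifest (NIfTI volumes + masks + clinical CSV) or a seeded synthetic
cohort, writing every intermediate artifact with a config-hash provenance
sidecar so re-runs with the same configuration resume instead of
recomputing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import assemble_signature_table, default_panel, extract_region_features, knn_impute, small_panel
from .habitats import apply_template, fit_habitat_template, partition_superpixels, superpixel_feature_matrix
from .imaging import ImageVolume, RegionMask, bias_correct, normalize_intensity, read_mask, read_volume, resample_isotropic
from .models import fit_clinical_model, fit_combined_model, fit_signature_model, predict_prob, stratified_split
from .evaluate import evaluate_cohort, youden_threshold
from .rings import build_rings
from .selection import rad_score, run_cascade
from .synthetic import SyntheticCohort, generate_cohort

log = logging.getLogger("habitatrad")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    output_dir: str = "habitatrad_output"
    manifest: str | None = None           # case manifest CSV; None -> synthetic
    clinical_csv: str | None = None
    # synthetic cohort settings (used when manifest is None)
    n_cases: int = 60
    grid_size: int = 64
    # preprocessing
    target_spacing: float = 1.0
    apply_bias_correction: bool = False
    normalize: bool = True
    # rings
    ring_distances: tuple[int, ...] = (1, 3, 5)
    cumulative_rings: bool = False
    # habitat mapping
    n_superpixels: int = 100
    compactness: float = 0.1
    k_range: tuple[int, int] = (2, 10)
    # extraction
    panel: str = "small"                  # "default" (1,547/region) or "small"
    knn_k: int = 5
    # selection cascade
    alpha: float = 0.05
    correlation_threshold: float = 0.9
    mrmr_top: int = 32
    lasso_folds: int = 10
    # modeling
    algorithm: str = "linear-SVM"
    model_folds: int = 5
    split_ratio: float = 0.7
    entry_alpha: float = 0.05
    # evaluation
    hl_groups: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0,1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0,1]")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0,1]")
        if self.mrmr_top < 1 or self.n_superpixels < 1:
            raise ValueError("counts must be positive")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.panel not in ("default", "small"):
            raise ValueError("panel must be 'default' or 'small'")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (artifact paths excluded)."""
        obj = dataclasses.asdict(self)
        obj.pop("output_dir")
        blob = json.dumps(obj, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str, overrides: dict | None = None) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        obj.update(overrides or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**obj)
        for name in ("ring_distances", "k_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    template: object
    selection_reports: dict
    models: dict
    reports: dict          # cohort -> {signature -> EvaluationReport}
    aucs: dict             # cohort -> {signature -> auc}
    output_dir: Path


def _load_manifest_cases(cfg: PipelineConfig):
    manifest = pd.read_csv(cfg.manifest)
    clinical = pd.read_csv(cfg.clinical_csv).set_index("case_id") if cfg.clinical_csv else None
    cases = []
    for _, row in manifest.iterrows():
        vol = read_volume(row["image_path"])
        mask = read_mask(row["mask_path"])
        cases.append((str(row["case_id"]), vol, mask))
    labels = clinical["label"]
    return cases, clinical.drop(columns=["label"]), labels


def _preprocess(vol: ImageVolume, mask: RegionMask, cfg: PipelineConfig):
    """Resample -> (optional) N4 -> z-score within the tumor-plus-ring
    support, then build rings.  Normalizing over the support rather than the
    whole grid keeps the intensity scale comparable across cases regardless
    of tumor/background proportions."""
    if not np.allclose(vol.spacing, (cfg.target_spacing,) * 3):
        vol = resample_isotropic(vol, cfg.target_spacing)
        mask = resample_isotropic(mask, cfg.target_spacing)
    if cfg.apply_bias_correction:
        vol = bias_correct(vol)
    rs = build_rings(mask, list(cfg.ring_distances), cumulative=cfg.cumulative_rings)
    if cfg.normalize:
        support = mask.labels.copy()
        for ring in rs:
            support |= ring.labels
        vol = normalize_intensity(vol, RegionMask(support, name="support",
                                                  spacing=mask.spacing))
    return vol, mask, rs


def _cached_table(path: Path, cfg_hash: str):
    meta = path.with_suffix(".json")
    if path.exists() and meta.exists():
        with open(meta) as fh:
            if json.load(fh).get("config_hash") == cfg_hash:
                log.info("resuming: %s", path.name)
                return pd.read_csv(path, index_col=0)
    return None


def _store_table(df: pd.DataFrame, path: Path, cfg_hash: str, **extra) -> None:
    df.to_csv(path)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"config_hash": cfg_hash, "version": __version__, **extra}, fh)


def run_pipeline(cfg: PipelineConfig, cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Execute the full workflow and return fitted artifacts and reports.

    When ``cfg.manifest`` is None a synthetic cohort is generated from
    ``cfg.seed`` (or a pre-built one can be passed).  All randomness derives
    from configured seeds; identical config + seed reproduces identical
    artifacts, and completed extraction tables on disk are reused when their
    provenance hash matches.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)
    log.info("pipeline start: hash=%s version=%s", cfg_hash, __version__)

    # ---- stage: cohort -----------------------------------------------------
    if cfg.manifest is not None:
        cases, clinical, labels = _load_manifest_cases(cfg)
    else:
        if cohort is None:
            from .synthetic import PhantomSpec
            spec = PhantomSpec(grid_size=(cfg.grid_size,) * 3)
            cohort = generate_cohort(n=cfg.n_cases, base_spec=spec, seed=cfg.seed)
        cases = [(c.case_id, c.volume, c.tumor) for c in cohort.cases]
        clinical = cohort.clinical_table.drop(columns=["label"])
        labels = cohort.labels

    case_ids = [cid for cid, _, _ in cases]
    labels = labels.loc[case_ids]

    # ---- stage: preprocess + rings + superpixels ---------------------------
    prepped = {}
    ringsets = {}
    parts = {}
    spmats = {}
    for cid, vol, mask in cases:
        vol, mask, rs = _preprocess(vol, mask, cfg)
        part = partition_superpixels(vol, mask, cfg.n_superpixels, cfg.compactness)
        prepped[cid] = (vol, mask)
        ringsets[cid] = rs
        parts[cid] = part
        spmats[cid] = superpixel_feature_matrix(vol, part)

    # ---- stage: split + habitat template -----------------------------------
    split = stratified_split(case_ids, labels.to_numpy(), ratio=cfg.split_ratio, seed=cfg.seed)
    train_ids, val_ids = list(split.train_ids), list(split.validation_ids)
    template = fit_habitat_template([spmats[c] for c in train_ids],
                                    k_range=cfg.k_range, seed=cfg.seed)
    template.to_json(str(out / "habitat_template.json"))
    log.info("habitat template: K=%d", template.K)

    habitat_masks = {cid: apply_template(template, parts[cid], spmats[cid]) for cid in case_ids}

    # ---- stage: extraction --------------------------------------------------
    panel = default_panel() if cfg.panel == "default" else small_panel()
    region_lists: dict[str, dict[str, RegionMask]] = {}
    for cid in case_ids:
        vol, mask = prepped[cid]
        regions = {"tumor": mask}
        for ring in ringsets[cid]:
            regions[ring.name] = ring
        for h, hm in enumerate(habitat_masks[cid], start=1):
            hm = RegionMask(hm.labels, name=f"H{h}", spacing=mask.spacing)
            regions[f"H{h}"] = hm
        region_lists[cid] = regions

    region_tags = ["tumor"] + [f"ring{d}mm" for d in cfg.ring_distances] + [
        f"H{h}" for h in range(1, template.K + 1)]
    tables: dict[str, pd.DataFrame] = {}
    for tag in region_tags:
        path = out / f"features_{tag}.csv"
        cached = _cached_table(path, cfg_hash)
        if cached is not None and list(cached.index) == case_ids:
            tables[tag] = cached
            continue
        rows = []
        for cid in case_ids:
            vol, _ = prepped[cid]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append(extract_region_features(vol, region_lists[cid][tag], panel))
        tables[tag] = pd.DataFrame(rows, index=case_ids)
        _store_table(tables[tag], path, cfg_hash, region=tag, panel_len=len(panel))

    signatures = {
        "radiomics": assemble_signature_table({"tumor": tables["tumor"]}),
        "habitat": assemble_signature_table({f"H{h}": tables[f"H{h}"]
                                             for h in range(1, template.K + 1)}),
    }
    for d in cfg.ring_distances:
        signatures[f"peri{d}mm"] = assemble_signature_table({f"ring{d}mm": tables[f"ring{d}mm"]})

    # ---- stage: imputation + selection + signature models ------------------
    y_train = labels.loc[train_ids].to_numpy()
    y_val = labels.loc[val_ids].to_numpy()
    # small cohorts cannot sustain the full fold counts; scale down so every
    # fold keeps at least one case of each class
    min_class = int(min((y_train == 0).sum(), (y_train == 1).sum()))
    lasso_folds = max(2, min(cfg.lasso_folds, min_class))
    model_folds = max(2, min(cfg.model_folds, min_class))
    if lasso_folds < cfg.lasso_folds or model_folds < cfg.model_folds:
        log.info("reduced CV folds for small cohort: lasso=%d model=%d",
                 lasso_folds, model_folds)
    selection_reports = {}
    models = {}
    probs: dict[str, dict[str, np.ndarray]] = {"train": {}, "validation": {}}
    scores: dict[str, pd.Series] = {}
    for name, table in signatures.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = knn_impute(table, k=cfg.knn_k)
        # z-scoring inside selection/model uses training statistics only
        tr, va = table.loc[train_ids], table.loc[val_ids]
        report = run_cascade(tr, y_train, alpha=cfg.alpha,
                             correlation_threshold=cfg.correlation_threshold,
                             mrmr_top=cfg.mrmr_top, folds=lasso_folds, seed=cfg.seed)
        selection_reports[name] = report
        report.to_json(str(out / f"selection_{name}.json"))
        # models are fit on the final (LASSO-selected) features; if the
        # penalty kept nothing, fall back to the mRMR survivors
        selected = (report.stage_survivors["lasso"]
                    or report.stage_survivors["mrmr"] or list(tr.columns[:1]))
        model = fit_signature_model(tr[selected], y_train, algorithm=cfg.algorithm,
                                    folds=model_folds, seed=cfg.seed)
        models[name] = model
        probs["train"][name] = predict_prob(model, tr[selected])
        probs["validation"][name] = predict_prob(model, va[selected])
        scores[name] = pd.concat([rad_score(report, tr), rad_score(report, va)])

    # ---- stage: clinical + combined ----------------------------------------
    clin_model, screen = fit_clinical_model(clinical.loc[train_ids], y_train, alpha=cfg.alpha,
                                            seed=cfg.seed)
    screen.to_csv(out / "clinical_screen.csv")
    models["clinical"] = clin_model
    from .models import encode_clinical
    enc_all = encode_clinical(clinical.loc[case_ids])
    probs["train"]["clinical"] = predict_prob(clin_model, enc_all.loc[train_ids])
    probs["validation"]["clinical"] = predict_prob(clin_model, enc_all.loc[val_ids])

    candidates_train = {
        "habitat_score": scores["habitat"].loc[train_ids].to_numpy(),
        "peri1mm_score": scores[f"peri{cfg.ring_distances[0]}mm"].loc[train_ids].to_numpy(),
    }
    candidates_val = {
        "habitat_score": scores["habitat"].loc[val_ids].to_numpy(),
        "peri1mm_score": scores[f"peri{cfg.ring_distances[0]}mm"].loc[val_ids].to_numpy(),
    }
    for col in clin_model.feature_names:
        candidates_train[col] = enc_all.loc[train_ids, col].to_numpy()
        candidates_val[col] = enc_all.loc[val_ids, col].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        combined = fit_combined_model(candidates_train, y_train, entry_alpha=cfg.entry_alpha,
                                      seed=cfg.seed)
    models["combined"] = combined
    tr_frame = pd.DataFrame(candidates_train, index=train_ids)
    va_frame = pd.DataFrame(candidates_val, index=val_ids)
    probs["train"]["combined"] = predict_prob(combined, tr_frame)
    probs["validation"]["combined"] = predict_prob(combined, va_frame)
    combined.save(str(out / "model_combined.json"))

    # ---- stage: evaluation --------------------------------------------------
    reports = {"train": {}, "validation": {}}
    aucs = {"train": {}, "validation": {}}
    for sig in probs["train"]:
        t = youden_threshold(probs["train"][sig], y_train)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports["train"][sig] = evaluate_cohort(probs["train"][sig], y_train, "train",
                                                    threshold=t, hl_groups=cfg.hl_groups)
            reports["validation"][sig] = evaluate_cohort(probs["validation"][sig], y_val,
                                                         "validation", threshold=t,
                                                         hl_groups=cfg.hl_groups)
        aucs["train"][sig] = reports["train"][sig].auc
        aucs["validation"][sig] = reports["validation"][sig].auc
        for coh in ("train", "validation"):
            reports[coh][sig].to_json(str(out / f"evaluation_{sig}_{coh}.json"))

    summary = {
        "config_hash": cfg_hash,
        "version": __version__,
        "seed": cfg.seed,
        "K": template.K,
        "aucs": aucs,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("pipeline done: validation AUCs %s", aucs["validation"])
    return PipelineResult(cfg, template, selection_reports, models, reports, aucs, out)
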