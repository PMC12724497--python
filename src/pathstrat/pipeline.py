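"""End-to-end orchestration: data -> QC -> clustering -> MPIS -> statistics.

A single :class:`RunConfig` drives the full analysis: synthetic-cohort
generation (or CSV ingestion), quality control and global z-scoring, view
selection, SRVCC co-clustering (optionally with model selection over a
(Kr, Kc) grid and seed/bootstrap stability), MPIS computation with variants,
and the pathway-aware statistical evaluation. Clustering consumes imaging
features only: clinical columns are stripped from the clustering matrix
unless explicitly overridden, and clinical data are joined post hoc.

Every run writes its tables under an output directory and returns a
:class:`RunManifest` listing each artifact with a content hash, per-stage
wall time and collected warnings; runs are deterministic given the global
seed, which fans out to stage-specific seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema as schema_mod
from .features import (load_feature_table, select_view, strip_clinical,
                       zscore_columns)
from .pathways import (MPISVariantSpec, assign_pathway_bins, bin_report,
                       compute_mpis, mpis_variant_concordance)
from .srvcc import TrainConfig, train_srvcc
from .stability import bootstrap_stability, model_selection_grid, seed_stability
from .stats import (association_table, categorical_association, cliffs_delta,
                    concordance_permutation, adjusted_regression, kruskal_eta2,
                    bh_fdr, summarize_clusters)
from .synthetic import SyntheticConfig, generate_cohort, write_cohort

# fixed seed offsets so stages are independently reproducible
_OFFSETS = {"synthetic": 0, "train": 1, "selection": 2, "stability": 3,
            "mpis": 4, "stats": 5, "concordance": 6}


@dataclass
class RunConfig:
    seed: int
    outdir: str = "results/run"
    mode: str = "synthetic"                      # "synthetic" | "csv"
    synthetic: SyntheticConfig | None = None
    features_csv: str | None = None
    clinical_csv: str | None = None
    view: str = "V4"
    allow_clinical_in_clustering: bool = False
    kr: int = 5
    kc: int = 5
    selection_grid: list | None = None           # [(kr, kc), ...] or None
    seeds_per_cell: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)
    stability_seeds: int = 0                     # 0 disables
    bootstrap_B: int = 0                         # 0 disables
    bootstrap_frac: float = 0.8
    mpis_variants: tuple = ("primary", "icv_normalized", "pathway_weighted",
                            "nonsigned_md")
    outcomes: tuple = ("updrs3", "moca", "quip_sum")
    covariates: tuple = ("age", "sex", "education", "medication_status")
    fdr_q: float = 0.05
    assoc_bootstrap: int = 1000
    n_perm: int = 1000
    concordance: bool = True
    cluster_contrast: tuple = (0, 3)

    def __post_init__(self):
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv":
            for p in (self.features_csv, self.clinical_csv):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"csv mode requires existing input: {p}")
        elif self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed + _OFFSETS["synthetic"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "train" in raw and raw["train"] is not None:
            train = raw["train"]
            if "hidden" in train:
                train["hidden"] = tuple(train["hidden"])
            raw["train"] = TrainConfig(**train)
        for key in ("mpis_variants", "outcomes", "covariates", "cluster_contrast"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "selection_grid" in raw and raw["selection_grid"] is not None:
            raw["selection_grid"] = [tuple(cell) for cell in raw["selection_grid"]]
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    failed_stage: str | None = None
    selected: tuple | None = None

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["selected"] = list(self.selected) if self.selected else None
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Shared state while executing the stage sequence."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        from importlib.metadata import version as _v
        try:
            ver = _v("pathstrat")
        except Exception:  # not installed (e.g. direct source use)
            ver = "0+src"
        self.manifest = RunManifest(config=_config_dict(config), version=ver)

    def write(self, name: str, obj) -> Path:
        path = self.outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, default=str))
        self.manifest.outputs[str(path)] = _sha256(path)
        return path

    def register(self, path: Path) -> None:
        self.manifest.outputs[str(path)] = _sha256(Path(path))


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if isinstance(d.get("synthetic"), dict):
        syn = d["synthetic"]
        if isinstance(syn.get("mean_shift"), np.ndarray):
            syn["mean_shift"] = syn["mean_shift"].tolist()
    return d


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all configured stages; on stage failure the manifest records
    it and downstream stages are skipped."""
    run = _Run(config)
    stages = [
        ("ingest", _stage_ingest),
        ("qc_zscore", _stage_qc),
        ("cluster", _stage_cluster),
        ("stability", _stage_stability),
        ("mpis", _stage_mpis),
        ("stats", _stage_stats),
        ("concordance", _stage_concordance),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn(run)
            run.manifest.warnings += [f"{name}: {w.message}" for w in caught]
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            run.manifest.failed_stage = name
            run.manifest.warnings.append(f"{name} FAILED: {exc}")
            break
        finally:
            run.manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
    run.manifest.to_json(run.outdir / "manifest.json")
    run.register(run.outdir / "manifest.json")
    return run.manifest


# --- stages ----------------------------------------------------------------


def _stage_ingest(run: _Run) -> None:
    cfg = run.cfg
    if cfg.mode == "synthetic":
        fm_raw, clinical, truth = generate_cohort(cfg.synthetic)
        paths = write_cohort(fm_raw, clinical, truth, run.outdir / "cohort")
        for p in paths.values():
            run.register(p)
        run.truth = truth
        # round-trip through the CSV dialect so csv mode is bit-identical
        fm_raw, clinical = load_feature_table(
            paths["features"], paths["clinical"],
            view_map=schema_mod.canonical_view_map())
    else:
        fm_raw, clinical = load_feature_table(
            cfg.features_csv, cfg.clinical_csv,
            view_map=schema_mod.canonical_view_map())
        run.truth = None
    run.fm_raw, run.clinical = fm_raw, clinical.aligned_to(fm_raw)


def _stage_qc(run: _Run) -> None:
    cfg = run.cfg
    run.write("qc_ledger.csv", run.fm_raw.qc_ledger)
    fm_std = zscore_columns(run.fm_raw)
    run.fm_std = fm_std
    view = select_view(fm_std, cfg.view)
    run.fm_cluster = view if cfg.allow_clinical_in_clustering else strip_clinical(view)
    if run.fm_cluster.n_features < 2:
        raise ValueError(f"view {cfg.view} leaves <2 clustering features")
    # leakage guard: assert no clinical columns unless explicitly allowed
    if not cfg.allow_clinical_in_clustering:
        assert all(d.modality != "CLIN" for d in run.fm_cluster.descriptors)
    run.write("clustering_features.json",
              {"view": cfg.view, "n_features": run.fm_cluster.n_features,
               "clinical_included": bool(cfg.allow_clinical_in_clustering),
               "features": run.fm_cluster.feature_names})


def _stage_cluster(run: _Run) -> None:
    cfg = run.cfg
    from dataclasses import replace
    train = replace(cfg.train, seed=cfg.seed + _OFFSETS["train"])
    kr, kc = cfg.kr, cfg.kc
    if cfg.selection_grid:
        records, (kr, kc) = model_selection_grid(
            run.fm_cluster, grid=cfg.selection_grid,
            seeds_per_cell=cfg.seeds_per_cell,
            train_config=replace(train, seed=cfg.seed + _OFFSETS["selection"]))
        run.write("model_selection.csv", records)
        run.manifest.selected = (kr, kc)
    model, assignments, log = train_srvcc(run.fm_cluster, kr, kc, train)
    run.model, run.assignments = model, assignments
    run.kr, run.kc = kr, kc
    run.write("training_log.csv", log)
    run.write("row_clusters.csv", pd.DataFrame({
        "subject_id": run.fm_cluster.subject_ids,
        "cluster": assignments.hard_rows}))
    run.write("col_clusters.csv", pd.DataFrame({
        "feature": run.fm_cluster.feature_names,
        "cluster": assignments.hard_cols}))
    run.write("cluster_metrics.json", {
        "kr": kr, "kc": kc, "val_recon": model.val_recon,
        "mi_org": model.mi_org, "mi_red": model.mi_red,
        "mi_ratio_org_over_red": model.mi_ratio})


def _stage_stability(run: _Run) -> None:
    cfg = run.cfg
    from dataclasses import replace
    train = replace(cfg.train, seed=cfg.seed + _OFFSETS["stability"])
    reports = {}
    if cfg.stability_seeds > 1:
        reports["seed"] = seed_stability(run.fm_cluster, run.kr, run.kc,
                                         n_seeds=cfg.stability_seeds,
                                         train_config=train)
    if cfg.bootstrap_B > 0:
        reports["bootstrap"] = bootstrap_stability(
            run.fm_cluster, run.kr, run.kc, B=cfg.bootstrap_B,
            frac=cfg.bootstrap_frac, train_config=train,
            reference_labels=run.assignments.hard_rows)
    if reports:
        summary = pd.concat([r.summary() for r in reports.values()],
                            ignore_index=True)
        run.write("stability_summary.csv", summary)


def _stage_mpis(run: _Run) -> None:
    cfg = run.cfg
    bins = assign_pathway_bins(run.fm_std.descriptors, schema_mod.default_bin_spec())
    run.bins = bins
    run.write("pathway_bins.csv", bin_report(bins))
    tables = {}
    for vname in cfg.mpis_variants:
        spec = MPISVariantSpec(
            variant=vname,
            icv_column="ICV" if vname == "icv_normalized" else None)
        try:
            tables[vname] = compute_mpis(run.fm_std, bins, spec, raw_fm=run.fm_raw)
        except ValueError as exc:
            warnings.warn(f"MPIS variant {vname!r} skipped: {exc}")
    run.mpis = tables
    for vname, t in tables.items():
        out = t.scores.copy()
        out.insert(0, "subject_id", t.subject_ids)
        run.write(f"mpis_{vname}.csv", out)


def _stage_stats(run: _Run) -> None:
    cfg = run.cfg
    seed = cfg.seed + _OFFSETS["stats"]
    clinical = run.clinical.data
    labels = run.assignments.hard_rows

    assoc = {}
    for vname, t in run.mpis.items():
        assoc[vname] = association_table(t.scores, clinical, outcomes=cfg.outcomes,
                                         B=cfg.assoc_bootstrap, seed=seed)
    run.write("associations_primary.csv", assoc["primary"])

    # Kruskal-Wallis separation of each pathway MPIS across the row clusters
    primary = run.mpis["primary"].scores
    kw_rows = []
    for pathway in primary.columns:
        vals = primary[pathway].to_numpy()
        if np.unique(labels).size >= 2 and np.isfinite(vals).any():
            r = kruskal_eta2(vals, labels, variable=pathway)
            kw_rows.append(r.__dict__)
    kw = pd.DataFrame(kw_rows)
    if not kw.empty:
        kw["q"] = bh_fdr(kw["p"])
    run.write("kruskal_mpis.csv", kw)

    # pre-specified cluster contrast on each pathway MPIS
    a_id, b_id = cfg.cluster_contrast
    contrast_rows = []
    if a_id in labels and b_id in labels:
        for pathway in primary.columns:
            es = cliffs_delta(primary[pathway].to_numpy()[labels == a_id],
                              primary[pathway].to_numpy()[labels == b_id],
                              B=cfg.assoc_bootstrap, seed=seed,
                              contrast=(int(a_id), int(b_id)))
            contrast_rows.append({"pathway": pathway, "cluster_a": a_id,
                                  "cluster_b": b_id, "delta": es.delta,
                                  "ci_low": es.ci_low, "ci_high": es.ci_high})
    run.write("cluster_contrast.csv", pd.DataFrame(contrast_rows))

    # cluster composition and categorical association with diagnosis
    run.write("cluster_composition.csv", summarize_clusters(clinical, labels))
    ct = pd.crosstab(clinical["diagnosis"], labels)
    if ct.shape[0] > 1 and ct.shape[1] > 1:
        run.write("diagnosis_association.json", categorical_association(ct.to_numpy()))

    # covariate-adjusted regressions: outcome ~ MPIS + covariates
    reg_rows = []
    for outcome in cfg.outcomes:
        for pathway in primary.columns:
            try:
                r = adjusted_regression(
                    clinical[outcome], primary[pathway].rename(pathway).reset_index(drop=True),
                    covariates=clinical[list(cfg.covariates)],
                    outcome_name=outcome)
                reg_rows.append(r.__dict__)
            except ValueError as exc:
                warnings.warn(f"regression {outcome}~{pathway} skipped: {exc}")
    reg = pd.DataFrame(reg_rows)
    if not reg.empty:
        reg["covariates"] = [",".join(c) for c in reg["covariates"]]
        reg["q"] = bh_fdr(reg["p"])
    run.write("adjusted_regressions.csv", reg)

    # variant concordance with the primary MPIS
    others = [t for v, t in run.mpis.items() if v != "primary"]
    if others:
        report = mpis_variant_concordance(run.mpis["primary"], others,
                                          assoc_results=assoc)
        run.write("variant_concordance.csv", report["correlations"])
        if "association_agreement" in report:
            run.write("variant_agreement.csv", report["association_agreement"])


def _stage_concordance(run: _Run) -> None:
    cfg = run.cfg
    if not cfg.concordance:
        return
    from dataclasses import replace
    train = replace(cfg.train, seed=cfg.seed + _OFFSETS["concordance"])
    global_labels = run.assignments.hard_rows
    name_to_idx = {n: i for i, n in enumerate(run.fm_std.feature_names)}
    rows = []
    for b in run.bins:
        members = [f for feats in b.members.values() for f in feats
                   if f in name_to_idx]
        if len(members) < 2:
            warnings.warn(f"pathway {b.name} has <2 features; concordance skipped")
            continue
        sub = run.fm_std.values[:, [name_to_idx[f] for f in members]]
        kc = min(run.kc, sub.shape[1])
        _, asg, _ = train_srvcc(sub, run.kr, kc, train)
        res = concordance_permutation(asg.hard_rows, global_labels,
                                      n_perm=cfg.n_perm,
                                      seed=cfg.seed + _OFFSETS["concordance"],
                                      pathway=b.name)
        rows.append(res.__dict__)
    run.write("pathway_concordance.csv", pd.DataFrame(rows))


# ---------------------------------------------------------------------------


def ablation_views(config: RunConfig, views=("V2", "V3", "V4")) -> pd.DataFrame:
    """Re-run the clustering stage per feature view and report cross-view
    agreement of the hard row labels (pairwise ARI/NMI)."""
    from dataclasses import replace
    from .stability import ari, nmi

    run = _Run(config)
    _stage_ingest(run)
    fm_std = zscore_columns(run.fm_raw)
    train = replace(config.train, seed=config.seed + _OFFSETS["train"])
    labelings = {}
    for view in views:
        fm_v = select_view(fm_std, view)
        if not config.allow_clinical_in_clustering:
            fm_v = strip_clinical(fm_v)
        if fm_v.n_features < 2:
            warnings.warn(f"view {view} has <2 clustering features; skipped")
            continue
        _, asg, _ = train_srvcc(fm_v, config.kr, config.kc, train)
        labelings[view] = asg.hard_rows
    rows = []
    names = list(labelings)
    for i, va in enumerate(names):
        for vb in names[i + 1:]:
            rows.append({"view_a": va, "view_b": vb,
                         "ari": ari(labelings[va], labelings[vb]),
                         "nmi": nmi(labelings[va], labelings[vb])})
    out = pd.DataFrame(rows)
    run.write("view_ablation.csv", out)
    return out
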