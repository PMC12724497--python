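"""Pathway binning and the Multimodal Pathway Integrity Score (MPIS).

For pathway p with per-modality member sets F_p and z-scored features, the
score for subject i is

    MPIS_i(p) = Z( sum_{j in F_p^FA} w_FA z_ij - sum_{j in F_p^MD} w_MD z_ij
                   + sum_{j in F_p^VOL} w_VOL z_ij + sum_{j in F_p^SBR} w_SBR z_ij )

where Z standardizes the composite across subjects (sample SD). FA, volume
and SBR enter positively (higher = more intact) and MD negatively (higher MD
= degradation). Four variants probe the robustness of that construction:
equal weights (primary), ICV-normalized volumes, pathway-specific reweighting
(SBR upweighted in the nigrostriatal bin, volumes downweighted in the
microvascular bin), and a control with MD entering positively.

Asymmetry-index features are excluded from the sums by default: their sign
has no "higher = more intact" reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

VARIANTS = ("primary", "icv_normalized", "pathway_weighted", "nonsigned_md")

DEFAULT_SIGNS = {"FA": 1, "MD": -1, "VOL": 1, "SBR": 1}

#: pathway-specific weight overrides for the ``pathway_weighted`` variant
PATHWAY_WEIGHT_DEFAULTS = {
    "nigrostriatal": {"SBR": 2.0},
    "microvascular": {"VOL": 0.5},
}


class AlignmentError(ValueError):
    pass


@dataclass
class PathwayBin:
    """Feature membership of one pathway, by modality, with signs/weights."""

    name: str
    members: dict = field(default_factory=dict)   # modality -> list of feature names
    signs: dict = field(default_factory=lambda: dict(DEFAULT_SIGNS))
    weights: dict = field(default_factory=lambda: {m: 1.0 for m in DEFAULT_SIGNS})

    def __post_init__(self):
        seen: set = set()
        for mod, feats in self.members.items():
            dup = seen & set(feats)
            if dup:
                raise ValueError(f"bin {self.name}: features in two modalities: {sorted(dup)}")
            seen |= set(feats)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class MPISVariantSpec:
    variant: str = "primary"
    icv_column: str | None = None
    weight_overrides: dict | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown MPIS variant {self.variant!r}")
        if self.variant == "icv_normalized" and not self.icv_column:
            raise ValueError("icv_normalized variant requires icv_column")


@dataclass
class MPISTable:
    subject_ids: list
    scores: pd.DataFrame          # subjects x pathways, standardized columns
    variant: MPISVariantSpec


def assign_pathway_bins(descriptors, bin_spec: dict) -> list:
    """Materialize pathway bins from a spec of ROI/modality member groups.

    ``bin_spec`` maps pathway name to ``{"groups": [{"rois": [...],
    "modalities": [...]}, ...], "signs": {...}, "weights": {...}}``. A feature
    may land in several bins; a referenced ROI absent from the descriptors
    yields a warning, not an error.
    """
    by_roi: dict = {}
    for d in descriptors:
        if d.name.endswith("-std"):  # nuisance columns never enter a bin
            continue
        by_roi.setdefault(d.roi, []).append(d)
    bins = []
    for name, spec in bin_spec.items():
        members: dict = {}
        for group in spec.get("groups", []):
            for roi in group["rois"]:
                if roi not in by_roi:
                    warnings.warn(f"bin {name!r}: ROI {roi!r} not in feature table")
                    continue
                for d in by_roi[roi]:
                    if d.modality in group["modalities"] and d.hemisphere != "ASYM":
                        members.setdefault(d.modality, []).append(d.name)
        bins.append(PathwayBin(
            name=name,
            members=members,
            signs={**DEFAULT_SIGNS, **spec.get("signs", {})},
            weights={**{m: 1.0 for m in DEFAULT_SIGNS}, **spec.get("weights", {})},
        ))
    return bins


def bin_report(bins) -> pd.DataFrame:
    """Per-bin feature counts, total and by modality."""
    rows = []
    for b in bins:
        row = {"pathway": b.name, "n_features": b.size}
        for mod in DEFAULT_SIGNS:
            row[f"n_{mod}"] = len(b.members.get(mod, []))
        rows.append(row)
    return pd.DataFrame(rows)


def compute_mpis(fm: FeatureMatrix, bins, variant: MPISVariantSpec | None = None,
                 raw_fm: FeatureMatrix | None = None) -> MPISTable:
    """Compute standardized MPIS for every bin on a standardized matrix.

    For the ICV-normalized variant the *raw* matrix must be supplied: volumes
    are divided by the subject's ICV and re-z-scored before entering the
    composite. A bin with no members present yields a NaN column and a
    warning. Modalities with no members simply contribute nothing.
    """
    if variant is None:
        variant = MPISVariantSpec()
    if not fm.standardized:
        raise ValueError("compute_mpis expects a standardized FeatureMatrix")

    name_to_col = {n: i for i, n in enumerate(fm.feature_names)}
    values = fm.values

    icv_adjusted: dict = {}
    if variant.variant == "icv_normalized":
        if raw_fm is None:
            raise ValueError("icv_normalized variant requires the raw FeatureMatrix")
        if list(raw_fm.subject_ids) != list(fm.subject_ids):
            raise AlignmentError("raw and standardized matrices must share subjects")
        icv = raw_fm.column(variant.icv_column)
        if (icv == 0).any():
            raise ValueError("ICV column contains zeros")
        raw_names = {n: i for i, n in enumerate(raw_fm.feature_names)}
        for d in raw_fm.descriptors:
            if d.modality == "VOL" and d.name != variant.icv_column:
                adj = raw_fm.values[:, raw_names[d.name]] / icv
                sd = adj.std(ddof=1)
                if sd > 0:
                    icv_adjusted[d.name] = (adj - adj.mean()) / sd

    n = fm.n_subjects
    out = {}
    for b in bins:
        weights = dict(b.weights)
        signs = dict(b.signs)
        if variant.variant == "pathway_weighted":
            overrides = (variant.weight_overrides or PATHWAY_WEIGHT_DEFAULTS)
            weights.update(overrides.get(b.name, {}))
        if variant.variant == "nonsigned_md":
            signs["MD"] = 1

        composite = np.zeros(n)
        used = 0
        for mod, feats in b.members.items():
            cols = []
            for f in feats:
                if variant.variant == "icv_normalized" and f in icv_adjusted:
                    cols.append(icv_adjusted[f])
                elif f in name_to_col:
                    cols.append(values[:, name_to_col[f]])
            if not cols:
                continue
            used += len(cols)
            composite = composite + signs[mod] * weights[mod] * np.sum(cols, axis=0)
        if used == 0:
            warnings.warn(f"bin {b.name!r} has no members in the matrix; MPIS set to NaN")
            out[b.name] = np.full(n, np.nan)
            continue
        sd = composite.std(ddof=1)
        if sd == 0:
            warnings.warn(f"bin {b.name!r} composite is constant; MPIS set to NaN")
            out[b.name] = np.full(n, np.nan)
            continue
        out[b.name] = (composite - composite.mean()) / sd

    return MPISTable(
        subject_ids=list(fm.subject_ids),
        scores=pd.DataFrame(out, index=list(fm.subject_ids)),
        variant=variant,
    )


def mpis_variant_concordance(primary: MPISTable, others: list,
                             assoc_results: dict | None = None) -> dict:
    """Agreement between the primary MPIS and each variant.

    Returns per-pathway Pearson r and Spearman rho per variant, the median
    Pearson correlation per variant, and — when association tables are
    supplied (variant name -> tidy table with columns pathway, outcome, rho,
    q) — sign and FDR-significance agreement per pathway x outcome.
    """
    correlations = []
    for other in others:
        if list(other.subject_ids) != list(primary.subject_ids):
            raise AlignmentError("MPIS variants must share subjects")
        for pathway in primary.scores.columns:
            if pathway not in other.scores.columns:
                continue
            a = primary.scores[pathway].to_numpy()
            b = other.scores[pathway].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            correlations.append({
                "variant": other.variant.variant, "pathway": pathway,
                "pearson_r": float(np.corrcoef(a[ok], b[ok])[0, 1]),
                "spearman_rho": float(stats.spearmanr(a[ok], b[ok]).statistic),
            })
    corr_df = pd.DataFrame(correlations)
    report = {
        "correlations": corr_df,
        "median_pearson": corr_df.groupby("variant")["pearson_r"].median(),
    }
    if assoc_results is not None:
        primary_assoc = assoc_results["primary"].set_index(["pathway", "outcome"])
        rows = []
        for vname, table in assoc_results.items():
            if vname == "primary":
                continue
            t = table.set_index(["pathway", "outcome"])
            for key in primary_assoc.index:
                if key not in t.index:
                    continue
                p_rho, p_q = primary_assoc.loc[key, "rho"], primary_assoc.loc[key, "q"]
                v_rho, v_q = t.loc[key, "rho"], t.loc[key, "q"]
                rows.append({
                    "variant": vname, "pathway": key[0], "outcome": key[1],
                    "sign_agrees": bool(np.sign(p_rho) == np.sign(v_rho)),
                    "significance_agrees": bool((p_q < 0.05) == (v_q < 0.05)),
                })
        report["association_agreement"] = pd.DataFrame(rows)
    return report
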