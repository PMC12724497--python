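"""Canonical ROI-modality schema and default pathway bin specification.

The canonical schema emulates a wide multimodal metrics table for a
parkinsonian cohort: per-ROI T1 volumes, diffusion FA/MD, and striatal
DaT-SBR columns, four clinical score columns, an intracranial-volume column,
and optional ``-std`` nuisance columns. It is constructed so that

* the four nested feature views have 4 / 48 / 112 / 144 features
  (clinical; + 27 volumes + 17 SBR; + 64 diffusion; + 96 free-water-corrected
  diffusion) — the views are a curated subset of the full table, which is
  much wider, as a real metrics export would be;
* the six pathway bins contain (88, 128, 20, 80, 4, 112) features for
  nigrostriatal, frontostriatal, cerebello-thalamo-cortical, limbic,
  microvascular and sensory/visuospatial circuits respectively;
* bins are nearly disjoint — thalamus (VOL/FA/MD) and the dorsal striatal
  SBR columns are shared between the nigrostriatal and frontostriatal bins,
  reflecting their joint role in both circuits.

Each imaging column carries a *generating* pathway (the latent integrity
factor that drives it in the synthetic cohort); columns shared between two
bins are generated from the nigrostriatal latent.
"""

from __future__ import annotations

import pandas as pd

from .features import CLINICAL_FEATURES, ICV_COLUMN, FeatureDescriptor

PATHWAYS = (
    "nigrostriatal",
    "frontostriatal",
    "ctc",
    "limbic",
    "microvascular",
    "sensory",
)

OUTCOMES = ("updrs3", "moca", "quip_sum")

# --- pathway ROI groups ----------------------------------------------------
# Each entry: ROIs measured with VOL + FA + MD bilaterally (6 columns per ROI)
# unless noted otherwise.

_NIGRO_VOLFAMD = (
    "substantia_nigra", "putamen", "caudate", "pallidum", "thalamus",
    "precentral", "sma", "premotor", "midbrain", "red_nucleus",
    "subthalamic", "motor_wm",
)  # 12 ROIs x 6 = 72
_NIGRO_SBR = (
    "putamen", "caudate", "pallidum", "dorsal_putamen", "dorsal_caudate",
    "anterior_putamen", "posterior_putamen", "ventral_pallidum",
)  # 8 ROIs x 2 = 16  -> nigrostriatal total 88

_FRONTO_VOLFAMD_OWN = (
    "dlpfc", "rostral_middle_frontal", "caudal_middle_frontal",
    "superior_frontal", "frontal_pole", "lateral_ofc", "medial_ofc",
    "anterior_cingulate", "caudal_anterior_cingulate", "insula",
    "pars_opercularis", "pars_triangularis", "pars_orbitalis",
    "middle_frontal_wm", "anterior_corona_radiata", "external_capsule",
    "anterior_internal_capsule", "frontal_wm", "cingulum_anterior",
)  # 19 ROIs x 6 = 114
_FRONTO_SHARED_VOLFAMD = ("thalamus",)  # + 6 (generated by nigrostriatal latent)
_FRONTO_SHARED_SBR = ("putamen", "caudate", "pallidum", "dorsal_caudate")  # + 8
# frontostriatal total 114 + 6 + 8 = 128

_CTC_VOLFAMD = ("cerebellum_cortex", "cerebellum_wm", "dentate")  # 3 x 6 = 18
_CTC_FAMD_MIDLINE = ("vermis",)  # FA + MD, midline (B) -> + 2; CTC total 20

_LIMBIC_VOLFAMD = (
    "hippocampus", "amygdala", "accumbens", "entorhinal", "parahippocampal",
    "subgenual_cingulate", "posterior_cingulate", "isthmus_cingulate",
    "temporal_pole", "fornix", "cingulum_posterior", "uncinate_fasciculus",
    "mammillary_body",
)  # 13 x 6 = 78
_LIMBIC_SBR = ("accumbens",)  # ventral striatum SBR -> + 2; limbic total 80

_MICRO_ROI = "wm_hypointensities"  # VOL L/R + FA/MD midline -> 4 features

_SENSORY_VOLFAMD = (
    "lateral_occipital", "cuneus", "lingual", "pericalcarine",
    "superior_parietal", "inferior_parietal", "supramarginal", "precuneus",
    "superior_temporal", "middle_temporal", "inferior_temporal",
    "transverse_temporal", "banks_sts", "fusiform", "temporoparietal",
    "posterior_corona_radiata", "sagittal_stratum", "splenium",
)  # 18 x 6 = 108
_SENSORY_FAMD = ("optic_radiation",)  # FA/MD L/R -> + 4; sensory total 112

# --- curated view membership ----------------------------------------------

_V2_VOL_PAIR_ROIS = (
    "putamen", "caudate", "pallidum", "thalamus", "accumbens", "hippocampus",
    "amygdala", "dlpfc", "insula", "anterior_cingulate", "superior_frontal",
    "precuneus", "superior_parietal",
)  # 13 pairs = 26, + brainstem_VOL_B -> 27
_V2_SBR_PAIR_ROIS = (
    "putamen", "caudate", "pallidum", "dorsal_putamen", "dorsal_caudate",
    "anterior_putamen", "posterior_putamen", "accumbens",
)  # 8 pairs = 16, + striatum_SBR_B -> 17
_V3_DTI_ROIS = _V2_VOL_PAIR_ROIS + ("lateral_occipital", "superior_temporal",
                                    "cerebellum_wm")  # 16 ROIs x 4 = 64
_V4_DTI_ROIS = (
    "substantia_nigra", "precentral", "sma", "premotor", "midbrain",
    "red_nucleus", "subthalamic", "motor_wm",
    "rostral_middle_frontal", "caudal_middle_frontal", "frontal_pole",
    "lateral_ofc", "medial_ofc", "caudal_anterior_cingulate",
    "pars_opercularis", "pars_triangularis",
    "entorhinal", "parahippocampal", "posterior_cingulate", "temporal_pole",
    "cuneus", "lingual", "middle_temporal", "fusiform",
)  # 24 ROIs x 4 = 96

# default generator column-cluster labels by modality family
_COL_CLUSTER_BY_MODALITY = {"VOL": 0, "SBR": 1, "FA": 2, "MD": 2}


def _col(rows, roi, mod, hemi, pathway):
    rows.append({
        "name": f"{roi}_{mod}_{hemi}", "roi": roi, "modality": mod,
        "hemisphere": hemi, "pathway": pathway,
        "col_cluster": _COL_CLUSTER_BY_MODALITY[mod],
    })


def canonical_schema(include_std_columns: bool = True) -> pd.DataFrame:
    """Build the canonical schema table.

    One row per emitted CSV column, with fields ``name``, ``roi``,
    ``modality``, ``hemisphere``, ``pathway`` (generating latent; None for
    columns outside every bin), ``col_cluster`` (generating column-block
    label; -1 for non-imaging columns) and ``views`` (tuple of view tags).
    """
    rows: list[dict] = []
    for roi in _NIGRO_VOLFAMD:
        for mod in ("VOL", "FA", "MD"):
            for hemi in ("L", "R"):
                _col(rows, roi, mod, hemi, "nigrostriatal")
    for roi in _NIGRO_SBR:
        for hemi in ("L", "R"):
            _col(rows, roi, "SBR", hemi, "nigrostriatal")
    for roi in _FRONTO_VOLFAMD_OWN:
        for mod in ("VOL", "FA", "MD"):
            for hemi in ("L", "R"):
                _col(rows, roi, mod, hemi, "frontostriatal")
    for roi in _CTC_VOLFAMD:
        for mod in ("VOL", "FA", "MD"):
            for hemi in ("L", "R"):
                _col(rows, roi, mod, hemi, "ctc")
    for roi in _CTC_FAMD_MIDLINE:
        for mod in ("FA", "MD"):
            _col(rows, roi, mod, "B", "ctc")
    for roi in _LIMBIC_VOLFAMD:
        for mod in ("VOL", "FA", "MD"):
            for hemi in ("L", "R"):
                _col(rows, roi, mod, hemi, "limbic")
    for roi in _LIMBIC_SBR:
        for hemi in ("L", "R"):
            _col(rows, roi, "SBR", hemi, "limbic")
    for hemi in ("L", "R"):
        _col(rows, _MICRO_ROI, "VOL", hemi, "microvascular")
    for mod in ("FA", "MD"):
        _col(rows, _MICRO_ROI, mod, "B", "microvascular")
    for roi in _SENSORY_VOLFAMD:
        for mod in ("VOL", "FA", "MD"):
            for hemi in ("L", "R"):
                _col(rows, roi, mod, hemi, "sensory")
    for roi in _SENSORY_FAMD:
        for mod in ("FA", "MD"):
            for hemi in ("L", "R"):
                _col(rows, roi, mod, hemi, "sensory")
    # columns outside every bin: brainstem volume, whole-striatum SBR, ICV
    rows.append({"name": "brainstem_VOL_B", "roi": "brainstem", "modality": "VOL",
                 "hemisphere": "B", "pathway": None, "col_cluster": 0})
    rows.append({"name": "striatum_SBR_B", "roi": "striatum", "modality": "SBR",
                 "hemisphere": "B", "pathway": None, "col_cluster": 1})
    rows.append({"name": ICV_COLUMN, "roi": "intracranial", "modality": "VOL",
                 "hemisphere": "B", "pathway": None, "col_cluster": -1})
    for name in CLINICAL_FEATURES:
        rows.append({"name": name, "roi": "clinical", "modality": "CLIN",
                     "hemisphere": "B", "pathway": None, "col_cluster": -1})

    schema = pd.DataFrame(rows)
    if schema["name"].duplicated().any():
        raise AssertionError("schema produced duplicate column names")
    schema["views"] = [_views_for(r) for r in schema.itertuples()]

    if include_std_columns:
        std = schema[schema["modality"] == "SBR"].copy()
        std["name"] = std["name"] + "-std"
        std["pathway"] = None
        std["col_cluster"] = -1
        std["views"] = [() for _ in range(len(std))]
        schema = pd.concat([schema, std], ignore_index=True)
    return schema


def _views_for(row) -> tuple:
    name, roi, mod, hemi = row.name, row.roi, row.modality, row.hemisphere
    if mod == "CLIN":
        return ("V1", "V2", "V3", "V4")
    if name == "brainstem_VOL_B" or (
            mod == "VOL" and hemi in ("L", "R") and roi in _V2_VOL_PAIR_ROIS):
        return ("V2", "V3", "V4")
    if name == "striatum_SBR_B" or (
            mod == "SBR" and hemi in ("L", "R") and roi in _V2_SBR_PAIR_ROIS):
        return ("V2", "V3", "V4")
    if mod in ("FA", "MD") and hemi in ("L", "R"):
        if roi in _V3_DTI_ROIS:
            return ("V3",)
        if roi in _V4_DTI_ROIS:
            return ("V4",)
    return ()


def canonical_view_map(include_std_columns: bool = False) -> dict:
    """Column name -> curated view tags, for re-ingesting written CSVs."""
    schema = canonical_schema(include_std_columns=include_std_columns)
    return {r.name: frozenset(r.views) for r in schema.itertuples()}


def descriptors_from_schema(schema: pd.DataFrame) -> list:
    """FeatureDescriptors for the non-nuisance columns of a schema table."""
    out = []
    for r in schema.itertuples():
        if r.name.endswith("-std"):
            continue
        out.append(FeatureDescriptor(
            name=r.name, roi=r.roi, modality=r.modality,
            hemisphere=r.hemisphere, views=frozenset(r.views)))
    return out


def default_bin_spec() -> dict:
    """Pathway -> member groups (ROIs x allowed modalities), signs, weights.

    Signs default to +1 for FA/VOL/SBR and -1 for MD; weights default to 1.
    The ``pathway_weighted`` MPIS variant overrides nigrostriatal SBR weight
    to 2 and microvascular VOL weight to 0.5.
    """
    sign = {"FA": 1, "MD": -1, "VOL": 1, "SBR": 1}
    one = {"FA": 1.0, "MD": 1.0, "VOL": 1.0, "SBR": 1.0}
    return {
        "nigrostriatal": {
            "groups": [
                {"rois": list(_NIGRO_VOLFAMD), "modalities": ["VOL", "FA", "MD"]},
                {"rois": list(_NIGRO_SBR), "modalities": ["SBR"]},
            ],
            "signs": dict(sign), "weights": dict(one),
        },
        "frontostriatal": {
            "groups": [
                {"rois": list(_FRONTO_VOLFAMD_OWN + _FRONTO_SHARED_VOLFAMD),
                 "modalities": ["VOL", "FA", "MD"]},
                {"rois": list(_FRONTO_SHARED_SBR), "modalities": ["SBR"]},
            ],
            "signs": dict(sign), "weights": dict(one),
        },
        "ctc": {
            "groups": [
                {"rois": list(_CTC_VOLFAMD), "modalities": ["VOL", "FA", "MD"]},
                {"rois": list(_CTC_FAMD_MIDLINE), "modalities": ["FA", "MD"]},
            ],
            "signs": dict(sign), "weights": dict(one),
        },
        "limbic": {
            "groups": [
                {"rois": list(_LIMBIC_VOLFAMD), "modalities": ["VOL", "FA", "MD"]},
                {"rois": list(_LIMBIC_SBR), "modalities": ["SBR"]},
            ],
            "signs": dict(sign), "weights": dict(one),
        },
        "microvascular": {
            "groups": [
                {"rois": [_MICRO_ROI], "modalities": ["VOL", "FA", "MD"]},
            ],
            "signs": dict(sign), "weights": dict(one),
        },
        "sensory": {
            "groups": [
                {"rois": list(_SENSORY_VOLFAMD), "modalities": ["VOL", "FA", "MD"]},
                {"rois": list(_SENSORY_FAMD), "modalities": ["FA", "MD"]},
            ],
            "signs": dict(sign), "weights": dict(one),
        },
    }
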