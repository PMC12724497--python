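"""Synthetic multimodal cohort generator with plantable ground truth.

Emulates a baseline multimodal parkinsonian cohort (patients, healthy
controls and SWEDD participants) at the tabular-metrics level. Each
subject i carries a row-cluster label r_i and six latent pathway integrity
factors u_i^(p) (standard-normal, standardized per pathway). Each imaging
column j carries a column-block label c_j (by modality family) and a
generating pathway p(j). Raw values follow a block-plus-latent-factor model

    x_ij = M[r_i, c_j] + s(mod_j) * a_j * u_i^(p(j)) + eps_ij,

with eps ~ Normal(0, noise_sd^2) and s(MD) = -1, s(FA) = s(VOL) = s(SBR) = +1,
so that higher latent integrity lowers mean diffusivity. Within a (cluster,
latent) cell, features are conditionally independent.

Clinical outcomes are planted at target Spearman correlations with the
pathway latents through a Gaussian copula: a unit-variance Gaussian score is
drawn jointly with the latents at the Pearson correlation
``2 sin(pi * rho_s / 6)`` and then pushed through a monotone transform
(affine to the target mean/SD, integer rounding, range clipping), which
preserves rank correlations up to rounding ties.

Covariates (age, sex, education, scanner field strength) are generated
independently of imaging, matching a design in which clustering is
covariate-free and covariates enter only the post hoc statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .features import SUBJECT_ID, ClinicalTable, FeatureMatrix
from .schema import OUTCOMES, PATHWAYS, canonical_schema


class ConfigurationError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


def copula_pearson_from_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal with Spearman rho ``rho_s``.

    For a bivariate Gaussian the population Spearman correlation is
    ``(6/pi) * arcsin(rho_p / 2)``; inverting gives
    ``rho_p = 2 sin(pi * rho_s / 6)``.
    """
    rho_s = float(rho_s)
    if not abs(rho_s) < 1:
        raise ValueError(f"|rho_s| must be < 1, got {rho_s}")
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


#: Spearman targets replicating the reported pathway-outcome association
#: magnitudes (motor, cognition, impulsivity outcomes per pathway).
DEFAULT_PATHWAY_EFFECTS: dict = {
    "nigrostriatal": {"updrs3": -0.201, "moca": 0.019, "quip_sum": 0.037},
    "frontostriatal": {"updrs3": -0.191, "moca": 0.080, "quip_sum": 0.059},
    "ctc": {},
    "limbic": {"updrs3": -0.108, "moca": 0.119, "quip_sum": 0.062},
    "microvascular": {"updrs3": -0.043, "moca": -0.036, "quip_sum": 0.017},
    "sensory": {"updrs3": -0.097, "moca": 0.163, "quip_sum": 0.096},
}

#: outcome marginal targets: mean, SD, (min, max); integer-valued scales
DEFAULT_CLINICAL_MARGINALS: dict = {
    "updrs3": (21.7, 9.6, (0, 132)),
    "moca": (27.0, 2.2, (0, 30)),
    "quip_sum": (4.5, 1.7, (0, 28)),
}

# Default 4 x 3 block pattern. Rows are zero-mean and pairwise affinely
# distinct, so the planted row clusters stay distinguishable even after the
# per-row centering/scaling applied inside co-cluster training; columns are
# also pairwise distinct, so column blocks are recoverable.
_DEFAULT_BLOCK_SIGNS = np.array([
    [1, 0, -1],
    [-1, 0, 1],
    [0, 1, -1],
    [1, -1, 0],
], dtype=float)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_per_group: dict = field(default_factory=lambda: {"PD": 185, "HC": 72, "SWEDD": 37})
    include_std_columns: bool = True
    mixing_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    #: row-cluster x column-cluster mean shifts (block structure); the default
    #: is a +/- shift_scale checkerboard with distinct rows and columns
    mean_shift: np.ndarray | None = None
    shift_scale: float = 1.0
    pathway_effects: dict = field(default_factory=lambda: {
        p: dict(v) for p, v in DEFAULT_PATHWAY_EFFECTS.items()})
    noise_sd: float = 1.0
    #: feature loading on its pathway latent, per modality
    loadings: dict = field(default_factory=lambda: {
        "VOL": 1.0, "FA": 1.0, "MD": 1.0, "SBR": 1.0})
    clinical_marginals: dict = field(default_factory=lambda: {
        k: (m, s, tuple(r)) for k, (m, s, r) in DEFAULT_CLINICAL_MARGINALS.items()})
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.mixing_proportions, dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise ConfigurationError("mixing proportions must sum to 1")
        if (props < 0).any():
            raise ConfigurationError("mixing proportions must be nonnegative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.mean_shift is None:
            self.mean_shift = self.shift_scale * _DEFAULT_BLOCK_SIGNS
        self.mean_shift = np.asarray(self.mean_shift, dtype=float)
        if self.mean_shift.shape[0] != len(props):
            raise ConfigurationError("mean_shift rows must match mixing proportions")
        for pathway, effects in self.pathway_effects.items():
            if pathway not in PATHWAYS:
                raise ConfigurationError(f"unknown pathway {pathway!r}")
            for outcome, rho in effects.items():
                if outcome not in OUTCOMES:
                    raise ConfigurationError(f"unknown outcome {outcome!r}")
                if not abs(rho) < 1:
                    raise ConfigurationError(f"planted |rho| must be < 1 ({pathway}->{outcome})")
        for outcome in OUTCOMES:
            c2 = sum(copula_pearson_from_spearman(eff[outcome]) ** 2
                     for eff in self.pathway_effects.values() if outcome in eff)
            if c2 >= 1:
                raise ConfigurationError(
                    f"planted effects on {outcome} are jointly infeasible (sum c^2 >= 1)")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group.values()))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigurationError("config file must set a seed")
        if "mean_shift" in raw and raw["mean_shift"] is not None:
            raw["mean_shift"] = np.asarray(raw["mean_shift"], dtype=float)
        if "mixing_proportions" in raw:
            raw["mixing_proportions"] = tuple(raw["mixing_proportions"])
        if "clinical_marginals" in raw:
            raw["clinical_marginals"] = {
                k: (v[0], v[1], tuple(v[2])) for k, v in raw["clinical_marginals"].items()}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything that was planted: labels, latents and realized effects."""

    row_labels: np.ndarray
    col_labels: np.ndarray            # -1 for non-imaging columns
    pathway_latents: pd.DataFrame     # subjects x pathways, standardized
    planted_effects: pd.DataFrame     # pathway, outcome, target, realized

    def to_json(self, path) -> None:
        payload = {
            "row_labels": self.row_labels.tolist(),
            "col_labels": self.col_labels.tolist(),
            "pathway_latents": {
                "subject_id": list(self.pathway_latents.index),
                "columns": list(self.pathway_latents.columns),
                "values": self.pathway_latents.to_numpy().tolist(),
            },
            "planted_effects": self.planted_effects.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        lat = payload["pathway_latents"]
        return cls(
            row_labels=np.asarray(payload["row_labels"], dtype=int),
            col_labels=np.asarray(payload["col_labels"], dtype=int),
            pathway_latents=pd.DataFrame(
                lat["values"], index=lat["subject_id"], columns=lat["columns"]),
            planted_effects=pd.DataFrame(payload["planted_effects"]),
        )


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)


def _marginal_transform(z: np.ndarray, mean: float, sd: float, rng_: tuple) -> np.ndarray:
    lo, hi = rng_
    return np.clip(np.round(mean + sd * z), lo, hi)


def generate_cohort(config: SyntheticConfig):
    """Generate ``(FeatureMatrix_raw, ClinicalTable, GroundTruth)``.

    Deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    schema = canonical_schema(include_std_columns=config.include_std_columns)
    n = config.n_subjects
    kr, kc = config.mean_shift.shape

    diagnosis = np.concatenate([
        np.repeat(g, int(cnt)) for g, cnt in config.n_per_group.items()])
    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    row_labels = rng.choice(kr, size=n, p=np.asarray(config.mixing_proportions))

    # latent pathway integrity factors, exactly standardized per pathway
    latents = _standardize(rng.standard_normal((n, len(PATHWAYS))))
    lat_df = pd.DataFrame(latents, index=subject_ids, columns=list(PATHWAYS))

    # Gaussian outcome scores jointly with the latents via the copula map
    gauss_scores = {}
    for outcome in OUTCOMES:
        c = np.array([
            copula_pearson_from_spearman(config.pathway_effects.get(p, {}).get(outcome, 0.0))
            for p in PATHWAYS])
        resid_sd = float(np.sqrt(max(1.0 - (c ** 2).sum(), 0.0)))
        gauss_scores[outcome] = latents @ c + resid_sd * rng.standard_normal(n)

    outcomes = {}
    for outcome in OUTCOMES:
        mean, sd, rng_pair = config.clinical_marginals[outcome]
        outcomes[outcome] = _marginal_transform(gauss_scores[outcome], mean, sd, rng_pair)

    # imaging feature matrix
    pathway_index = {p: i for i, p in enumerate(PATHWAYS)}
    values = np.empty((n, len(schema)))
    col_labels = np.full(len(schema), -1, dtype=int)
    for j, row in enumerate(schema.itertuples()):
        name, mod, cclu, pathway = row.name, row.modality, row.col_cluster, row.pathway
        if name.endswith("-std"):
            values[:, j] = np.abs(rng.normal(0.0, config.noise_sd, size=n))
            continue
        if mod == "CLIN":
            if name == "NP3TOT":
                values[:, j] = outcomes["updrs3"]
            elif name == "NPTOT":
                values[:, j] = outcomes["updrs3"] + np.round(
                    np.abs(rng.normal(12.0, 5.0, size=n)))
            elif name == "MCATOT":
                values[:, j] = outcomes["moca"]
            else:  # QUIP_SUM
                values[:, j] = outcomes["quip_sum"]
            continue
        if name == "ICV":
            values[:, j] = rng.normal(1.45e6, 1.2e5, size=n)
            continue
        x = rng.normal(0.0, config.noise_sd, size=n)
        if cclu >= 0:
            x += config.mean_shift[row_labels, cclu % kc]
            col_labels[j] = cclu
        if pathway is not None and not (isinstance(pathway, float) and np.isnan(pathway)):
            s = -1.0 if mod == "MD" else 1.0
            x += s * config.loadings.get(mod, 1.0) * latents[:, pathway_index[pathway]]
        values[:, j] = x

    fm = FeatureMatrix(
        subject_ids=subject_ids,
        values=values,
        descriptors=_descriptors_with_std(schema),
        standardized=False,
    )

    clinical = ClinicalTable(pd.DataFrame({
        SUBJECT_ID: subject_ids,
        "diagnosis": diagnosis,
        "age": np.round(_group_normal(rng, diagnosis, {
            "PD": (64.2, 9.1), "HC": (61.8, 8.7), "SWEDD": (63.5, 8.9)}), 1),
        "sex": np.where(rng.random(n) < _group_value(diagnosis, {
            "PD": 0.389, "HC": 0.403, "SWEDD": 0.351}), "F", "M"),
        "education": np.clip(np.round(rng.normal(15.3, 3.0, size=n)), 5, 25),
        "disease_duration": np.where(
            diagnosis == "HC", np.nan,
            np.round(np.clip(rng.normal(1.9, 1.1, size=n), 0.0, None), 1)),
        "medication_status": np.where(
            diagnosis == "HC", "off",
            np.where(rng.random(n) < 0.52, "on", "off")),
        "field_strength": np.where(rng.random(n) < 0.8, "3T", "1.5T"),
        "updrs3": outcomes["updrs3"],
        "moca": outcomes["moca"],
        "quip_sum": outcomes["quip_sum"],
    }))

    planted = []
    for pathway, effects in config.pathway_effects.items():
        for outcome, target in effects.items():
            realized = stats.spearmanr(latents[:, pathway_index[pathway]],
                                       outcomes[outcome]).statistic
            planted.append({"pathway": pathway, "outcome": outcome,
                            "target": float(target), "realized": float(realized)})
    truth = GroundTruth(
        row_labels=row_labels,
        col_labels=col_labels,
        pathway_latents=lat_df,
        planted_effects=pd.DataFrame(
            planted, columns=["pathway", "outcome", "target", "realized"]),
    )
    return fm, clinical, truth


def _descriptors_with_std(schema: pd.DataFrame) -> list:
    """Descriptors for all columns, -std nuisance columns included (they are
    raw columns that row QC must see and column QC must then drop)."""
    from .features import FeatureDescriptor

    return [FeatureDescriptor(
        name=r.name, roi=r.roi, modality=r.modality, hemisphere=r.hemisphere,
        views=frozenset(r.views)) for r in schema.itertuples()]


def _group_normal(rng, diagnosis, params):
    out = np.empty(len(diagnosis))
    for g, (m, s) in params.items():
        mask = diagnosis == g
        out[mask] = rng.normal(m, s, size=mask.sum())
    return out


def _group_value(diagnosis, params):
    return np.array([params[g] for g in diagnosis])


def write_cohort(fm: FeatureMatrix, clinical: ClinicalTable, truth: GroundTruth,
                 outdir) -> dict:
    """Write features.csv / clinical.csv / truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": outdir / "features.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.json",
    }
    fm.to_frame().to_csv(paths["features"], index=False)
    clinical.data.to_csv(paths["clinical"], index=False)
    truth.to_json(paths["truth"])
    return paths


def verify_planting(fm: FeatureMatrix, clinical: ClinicalTable, truth: GroundTruth,
                    n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Realized vs target Spearman for every planted pathway-outcome pair.

    Reports a percentile bootstrap CI per pair and flags pairs whose CI
    excludes the planted target.
    """
    if len(clinical.data) != fm.n_subjects or len(truth.pathway_latents) != fm.n_subjects:
        raise AlignmentError("features, clinical table and truth must share subjects")
    rng = np.random.default_rng(seed)
    n = fm.n_subjects
    rows = []
    for rec in truth.planted_effects.itertuples():
        u = truth.pathway_latents[rec.pathway].to_numpy()
        y = clinical.data[rec.outcome].to_numpy(dtype=float)
        rho = stats.spearmanr(u, y).statistic
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                boot[b] = stats.spearmanr(u[idx], y[idx]).statistic
        boot = boot[np.isfinite(boot)]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({
            "pathway": rec.pathway, "outcome": rec.outcome,
            "target": rec.target, "realized": float(rho),
            "ci_low": float(lo), "ci_high": float(hi),
            "ci_excludes_target": bool(rec.target < lo or rec.target > hi),
        })
    return pd.DataFrame(rows, columns=[
        "pathway", "outcome", "target", "realized", "ci_low", "ci_high",
        "ci_excludes_target"])
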