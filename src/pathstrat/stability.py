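"""Model selection over (Kr, Kc) and cluster stability quantification.

Partition agreement uses the adjusted Rand index (permutation-model
expectation correction) and normalized mutual information (normalized by the
arithmetic mean of the two label entropies; identical constant labelings
score 1, a constant vs. a non-constant labeling scores 0).

Model selection scans a (Kr, Kc) grid with several random initializations
per cell and records the final objective, held-out reconstruction error and
the mutual-information ratio MI(T_org)/MI(T_red). The selected configuration
is the most parsimonious one — smallest Kr + Kc, ties broken by smaller
Kr — whose median final objective is within a tolerance (default 2%) of the
grid minimum: a reproducible formalization of "diminishing returns". The
objective, not held-out reconstruction, carries the cluster-count signal
here: an under-clustered prior pays a KL penalty for merged latent clusters
while the decoder still reconstructs from the encoder posterior.

Stability is measured two ways: retraining with different seeds (pairwise
ARI/NMI between hard row labels) and a nonparametric subject bootstrap
(0.8*N draws with replacement; refit labels compared with the full-sample
solution on the unique subjects present, first occurrence per duplicate).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .features import FeatureMatrix
from .srvcc import TrainConfig, train_srvcc

DEFAULT_GRID = tuple(itertools.product(range(3, 8), range(3, 8)))


def _check_pair(a, b, min_len: int = 1):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length ({len(a)} vs {len(b)})")
    if len(a) < min_len:
        raise ValueError(f"need at least {min_len} labels")
    return a, b


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index under the permutation null model."""
    a, b = _check_pair(labels_a, labels_b, min_len=2)
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """NMI with arithmetic-mean entropy normalization."""
    a, b = _check_pair(labels_a, labels_b, min_len=1)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


@dataclass
class SelectionRecord:
    kr: int
    kc: int
    seed: int
    final_loss: float
    val_recon: float
    mi_ratio: float
    failed: bool = False


@dataclass
class StabilityReport:
    """ARI/NMI distributions over seed pairs and/or bootstrap resamples."""

    pairwise_ari: np.ndarray = field(default_factory=lambda: np.array([]))
    pairwise_nmi: np.ndarray = field(default_factory=lambda: np.array([]))
    bootstrap_ari: np.ndarray = field(default_factory=lambda: np.array([]))
    bootstrap_nmi: np.ndarray = field(default_factory=lambda: np.array([]))
    n_skipped: int = 0

    @staticmethod
    def _summ(x: np.ndarray) -> dict:
        if len(x) == 0:
            return {"median": np.nan, "iqr": np.nan}
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "iqr": float(q3 - q1)}

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, x in (("seed_ari", self.pairwise_ari),
                        ("seed_nmi", self.pairwise_nmi),
                        ("bootstrap_ari", self.bootstrap_ari),
                        ("bootstrap_nmi", self.bootstrap_nmi)):
            if len(x):
                rows.append({"metric": name, "n": len(x), **self._summ(x)})
        return pd.DataFrame(rows)


def model_selection_grid(fm, grid=None, seeds_per_cell: int = 5,
                         train_config: TrainConfig | None = None,
                         select_tol: float = 0.02):
    """Scan the grid; returns (records DataFrame, (Kr*, Kc*)).

    Per cell the median over seeds of the final objective, validation
    reconstruction and MI ratio is computed; failed fits are recorded and
    excluded from selection.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    base = train_config or TrainConfig()
    records = []
    for kr, kc in grid:
        for s in range(seeds_per_cell):
            cfg = replace(base, seed=base.seed + 1000 * s)
            try:
                model, _, log = train_srvcc(fm, kr, kc, cfg)
                records.append(SelectionRecord(
                    kr=kr, kc=kc, seed=cfg.seed,
                    final_loss=float(log[log.phase == "joint"].iloc[-1]["total"]),
                    val_recon=float(model.val_recon),
                    mi_ratio=float(model.mi_ratio)))
            except Exception as exc:  # noqa: BLE001 - cell failures are data
                warnings.warn(f"cell (Kr={kr}, Kc={kc}, seed={cfg.seed}) failed: {exc}")
                records.append(SelectionRecord(
                    kr=kr, kc=kc, seed=cfg.seed, final_loss=np.nan,
                    val_recon=np.nan, mi_ratio=np.nan, failed=True))
    table = pd.DataFrame([r.__dict__ for r in records])

    ok = table[~table.failed]
    if ok.empty:
        raise RuntimeError("every grid cell failed to train")
    med = ok.groupby(["kr", "kc"], as_index=False).agg(
        final_loss=("final_loss", "median"),
        val_recon=("val_recon", "median"),
        mi_ratio=("mi_ratio", "median"))
    # parsimony rule on the full objective: under-clustered cells pay a KL
    # penalty for merged latent clusters, which held-out reconstruction alone
    # does not register (the decoder reads the encoder posterior, not the
    # cluster representative)
    best = med.final_loss.min()
    eligible = med[med.final_loss <= best * (1 + select_tol)].copy()
    eligible["order"] = eligible.kr + eligible.kc
    eligible = eligible.sort_values(["order", "kr", "kc"])
    sel = eligible.iloc[0]
    return table, (int(sel.kr), int(sel.kc))


def seed_stability(fm, kr: int, kc: int, n_seeds: int = 10,
                   train_config: TrainConfig | None = None) -> StabilityReport:
    """Pairwise ARI/NMI of hard row labels over ``n_seeds`` retrainings."""
    base = train_config or TrainConfig()
    labelings = []
    for s in range(n_seeds):
        cfg = replace(base, seed=base.seed + 1000 * s)
        _, asg, _ = train_srvcc(fm, kr, kc, cfg)
        labelings.append(asg.hard_rows)
    a_vals, n_vals = [], []
    for i, j in itertools.combinations(range(n_seeds), 2):
        a_vals.append(ari(labelings[i], labelings[j]))
        n_vals.append(nmi(labelings[i], labelings[j]))
    return StabilityReport(pairwise_ari=np.array(a_vals), pairwise_nmi=np.array(n_vals))


def bootstrap_stability(fm, kr: int, kc: int, B: int = 100, frac: float = 0.8,
                        train_config: TrainConfig | None = None,
                        reference_labels=None) -> StabilityReport:
    """Subject-bootstrap stability against the full-sample solution.

    Each resample draws ``round(frac * N)`` subjects with replacement, refits,
    and compares its hard row labels with the full-sample labels on the
    unique subjects present (first occurrence per duplicated subject).
    Resamples with fewer than Kr unique subjects are skipped.
    """
    base = train_config or TrainConfig()
    # normalize once on the full cohort; resamples inherit the full-sample scaling
    if isinstance(fm, FeatureMatrix):
        from .features import row_col_normalize
        x = row_col_normalize(fm).values
    else:
        x = np.asarray(fm, dtype=float)
    n = x.shape[0]
    if reference_labels is None:
        _, full_asg, _ = train_srvcc(x, kr, kc, base)
        reference_labels = full_asg.hard_rows
    reference_labels = np.asarray(reference_labels)

    rng = np.random.default_rng(base.seed + 77)
    a_vals, n_vals, skipped = [], [], 0
    for b in range(B):
        idx = rng.integers(0, n, size=int(round(frac * n)))
        uniq, first_pos = np.unique(idx, return_index=True)
        if len(uniq) < kr:
            warnings.warn(f"resample {b} collapsed to {len(uniq)} unique subjects; skipped")
            skipped += 1
            continue
        cfg = replace(base, seed=base.seed + 500_000 + b)
        try:
            _, asg, _ = train_srvcc(x[idx], kr, kc, cfg)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"resample {b} failed to train: {exc}")
            skipped += 1
            continue
        boot_labels = asg.hard_rows[first_pos]
        ref = reference_labels[uniq]
        a_vals.append(ari(ref, boot_labels))
        n_vals.append(nmi(ref, boot_labels))
    return StabilityReport(bootstrap_ari=np.array(a_vals),
                           bootstrap_nmi=np.array(n_vals), n_skipped=skipped)
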