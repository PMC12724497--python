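"""Variational co-clustering with Gaussian-mixture latent priors (SRVCC).

Two variational autoencoders are trained jointly: a *row* model on the
subject x feature matrix X (subjects as samples) and a *column* model on X^T
(features as samples). Each side has a learnable Gaussian-mixture prior

    p(z) = sum_k pi_k N(z | mu_k, diag sigma_k^2),

whose responsibilities gamma_ik give soft cluster assignments. The side loss
is reconstruction (squared error, summed over dimensions and averaged over
the batch) plus beta * KL(q(z|x) || p(z)), the KL estimated by a
single-sample reparameterized Monte Carlo estimator (it has no closed form
for a mixture prior). The two partitions are coupled through a
mutual-information term on the normalized data-weighted cross-tabulation

    T_org = Gamma_r^T W Gamma_c / sum(Gamma_r^T W Gamma_c),   W = |X~|,

against its hard-assignment reduction T_red:

    L_MI = lambda_mi * ln(1 + (1 - MI(T_red) / MI(T_org))),

which is zero exactly when hardening the soft partitions loses no
association. Training is staged: reconstruction-only pretraining, k-means
initialization of the mixture parameters on the encoder means, then joint
optimization with Adam under a linear KL warm-up (beta: 0 -> 1).

The trainable networks run on the package's own reverse-mode autodiff
engine (:mod:`pathstrat.autodiff`); all public scoring operations
(``gmm_log_density``, ``responsibilities``, ``mutual_information``, ...) are
plain numpy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp as _np_logsumexp
from sklearn.cluster import KMeans

from .autodiff import Adam, Tensor
from .features import FeatureMatrix, row_col_normalize

_LOG2PI = float(np.log(2.0 * np.pi))
_RATIO_CAP = 2.0 - 1e-6
_MI_EPS = 1e-8
# prior component variances are kept in [1e-4, 1]; an unbounded component can
# inflate to swallow neighboring clusters, and the bounded scale makes the KL
# term penalize under-clustered priors (merged clusters compress latents and
# cost reconstruction), which is what the validation-recon elbow relies on
_PRIOR_LOGVAR_MIN = float(np.log(1e-2))
_PRIOR_LOGVAR_MAX = 0.0


class TrainingDivergedError(RuntimeError):
    pass


class DegenerateWeightsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class GMMParams:
    """Mixture prior: log-weights (softmax -> pi), means, diagonal log-vars."""

    log_weights: np.ndarray
    means: np.ndarray
    log_vars: np.ndarray

    def __post_init__(self):
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.log_vars = np.atleast_2d(np.asarray(self.log_vars, dtype=float))
        if not (len(self.log_weights) == self.means.shape[0] == self.log_vars.shape[0]):
            raise ValueError("component count mismatch")

    @property
    def n_components(self) -> int:
        return len(self.log_weights)

    @property
    def weights(self) -> np.ndarray:
        w = self.log_weights - _np_logsumexp(self.log_weights)
        return np.exp(w)


@dataclass
class EncoderOutput:
    mu: np.ndarray
    log_var: np.ndarray


@dataclass
class TrainConfig:
    epochs: int = 100
    pretrain_epochs: int = 40
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    val_frac: float = 0.2
    beta_warmup_epochs: int = 30
    lambda_mi: float = 1.0
    latent_dim: int = 10
    hidden: tuple = (64, 32)


@dataclass
class AssignmentMatrices:
    gamma_rows: np.ndarray
    gamma_cols: np.ndarray

    def __post_init__(self):
        for g, side in ((self.gamma_rows, "row"), (self.gamma_cols, "column")):
            if np.any(g < -1e-9) or np.any(g > 1 + 1e-9):
                raise ValueError(f"{side} assignments outside [0, 1]")
            if not np.allclose(g.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"{side} assignments do not sum to 1")

    @property
    def hard_rows(self) -> np.ndarray:
        return hard_assign(self.gamma_rows)

    @property
    def hard_cols(self) -> np.ndarray:
        return hard_assign(self.gamma_cols)


@dataclass
class CrossTab:
    table: np.ndarray
    kind: str = "soft"  # "soft" (T_org) or "reduced" (T_red)

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if np.any(self.table < 0):
            raise ValueError("cross-tabulation entries must be nonnegative")
        if not np.isclose(self.table.sum(), 1.0, atol=1e-9):
            raise ValueError("cross-tabulation must sum to 1")


# ---------------------------------------------------------------------------
# public scoring operations (numpy)


def gmm_log_density(z, prior: GMMParams):
    """log p(z) under the mixture prior; stable log-sum-exp over components."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite latent input")
    single = z.ndim == 1
    z2 = np.atleast_2d(z)[:, None, :]                       # (n, 1, d)
    if z2.shape[-1] != prior.means.shape[1]:
        raise ValueError("latent dimension mismatch")
    log_pi = prior.log_weights - _np_logsumexp(prior.log_weights)
    comp = -0.5 * (_LOG2PI + prior.log_vars
                   + (z2 - prior.means) ** 2 / np.exp(prior.log_vars)).sum(axis=-1)
    out = _np_logsumexp(comp + log_pi, axis=1)
    return float(out[0]) if single else out


def responsibilities(z, prior: GMMParams):
    """Posterior component probabilities gamma_k(z), normalized in log-space."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite latent input")
    single = z.ndim == 1
    z2 = np.atleast_2d(z)[:, None, :]
    log_pi = prior.log_weights - _np_logsumexp(prior.log_weights)
    logits = log_pi - 0.5 * (_LOG2PI + prior.log_vars
                             + (z2 - prior.means) ** 2 / np.exp(prior.log_vars)).sum(axis=-1)
    gamma = np.exp(logits - _np_logsumexp(logits, axis=1, keepdims=True))
    return gamma[0] if single else gamma


def hard_assign(gamma) -> np.ndarray:
    """Arg-max cluster labels; ties break to the lowest index."""
    return np.argmax(np.asarray(gamma), axis=-1).astype(int)


def cross_tab(gamma_rows, gamma_cols, weight_matrix) -> CrossTab:
    """Normalized data-weighted cross-tabulation T = Gamma_r^T W Gamma_c."""
    w = np.asarray(weight_matrix, dtype=float)
    if np.any(w < 0):
        raise DegenerateWeightsError("weight matrix must be nonnegative")
    t = np.asarray(gamma_rows).T @ w @ np.asarray(gamma_cols)
    s = t.sum()
    if s <= 0:
        raise DegenerateWeightsError("weight matrix sums to zero")
    return CrossTab(t / s, kind="soft")


def mutual_information(t) -> float:
    """MI(T) = sum_ab T_ab ln(T_ab / (T_a. T_.b)), with 0 ln 0 = 0 (nats)."""
    table = t.table if isinstance(t, CrossTab) else np.asarray(t, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * (np.log(table) - np.log(rows) - np.log(cols))
    return float(np.nansum(terms))


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def reduced_cross_tab(gamma_rows, gamma_cols, weight_matrix) -> CrossTab:
    """T_red: the cross-tabulation of the hardened assignments."""
    gr = np.asarray(gamma_rows)
    gc = np.asarray(gamma_cols)
    t = cross_tab(_one_hot(hard_assign(gr), gr.shape[1]),
                  _one_hot(hard_assign(gc), gc.shape[1]), weight_matrix)
    return CrossTab(t.table, kind="reduced")


def mi_coupling_loss(gamma_rows, gamma_cols, weight_matrix, lambda_mi: float) -> float:
    """L_MI = lambda * ln(1 + (1 - MI(T_red)/MI(T_org))), ratio clamped."""
    if lambda_mi < 0:
        raise ValueError("lambda_mi must be nonnegative")
    if lambda_mi == 0:
        return 0.0
    mi_org = mutual_information(cross_tab(gamma_rows, gamma_cols, weight_matrix))
    if mi_org <= _MI_EPS:
        warnings.warn("MI(T_org) is ~0; coupling ratio treated as 1 (loss 0)")
        return 0.0
    mi_red = mutual_information(reduced_cross_tab(gamma_rows, gamma_cols, weight_matrix))
    ratio = np.clip(mi_red / mi_org, 0.0, _RATIO_CAP)
    return float(lambda_mi * np.log(1.0 + (1.0 - ratio)))


# ---------------------------------------------------------------------------
# networks


class SideModel:
    """One side (rows or columns): MLP encoder/decoder + mixture prior."""

    def __init__(self, input_dim: int, latent_dim: int, hidden: tuple, seed: int):
        self.input_dim = int(input_dim)
        self.latent_dim = int(latent_dim)
        self.hidden = tuple(hidden)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)
        h1, h2 = hidden
        init = self.rng.normal

        def layer(fan_in, fan_out):
            return Tensor(init(0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out)),
                          requires_grad=True)

        self.params = {
            "eW1": layer(input_dim, h1), "eb1": Tensor(np.zeros(h1), True),
            "eW2": layer(h1, h2), "eb2": Tensor(np.zeros(h2), True),
            "eWmu": layer(h2, latent_dim), "ebmu": Tensor(np.zeros(latent_dim), True),
            "eWlv": layer(h2, latent_dim), "eblv": Tensor(np.zeros(latent_dim), True),
            "dW1": layer(latent_dim, h2), "db1": Tensor(np.zeros(h2), True),
            "dW2": layer(h2, h1), "db2": Tensor(np.zeros(h1), True),
            "dW3": layer(h1, input_dim), "db3": Tensor(np.zeros(input_dim), True),
        }
        self.prior_params: dict | None = None  # set after k-means init

    # -- forward passes (autodiff tensors) -------------------------------
    def encode_t(self, x: Tensor):
        p = self.params
        h = ((x @ p["eW1"]) + p["eb1"]).tanh()
        h = ((h @ p["eW2"]) + p["eb2"]).tanh()
        mu = (h @ p["eWmu"]) + p["ebmu"]
        lv = (h @ p["eWlv"]) + p["eblv"]
        return mu, lv

    def decode_t(self, z: Tensor) -> Tensor:
        p = self.params
        h = ((z @ p["dW1"]) + p["db1"]).tanh()
        h = ((h @ p["dW2"]) + p["db2"]).tanh()
        return (h @ p["dW3"]) + p["db3"]

    def prior_log_pi_t(self) -> Tensor:
        lw = self.prior_params["log_weights"]
        return lw - lw.logsumexp(axis=0)

    def log_prior_t(self, z: Tensor) -> Tensor:
        """log p(z) for a (B, d) tensor under the trainable mixture prior."""
        pp = self.prior_params
        b = z.shape[0]
        k, d = pp["means"].shape
        z3 = z.reshape(b, 1, d)
        lv = pp["log_vars"]
        diff = z3 - pp["means"]
        comp = (-0.5) * ((diff * diff) / lv.exp() + lv + _LOG2PI)
        logits = comp.sum(axis=2) + self.prior_log_pi_t()
        return logits.logsumexp(axis=1)

    def responsibilities_t(self, z: Tensor) -> Tensor:
        pp = self.prior_params
        b = z.shape[0]
        k, d = pp["means"].shape
        z3 = z.reshape(b, 1, d)
        lv = pp["log_vars"]
        diff = z3 - pp["means"]
        logits = ((-0.5) * ((diff * diff) / lv.exp() + lv + _LOG2PI)).sum(axis=2) \
            + self.prior_log_pi_t()
        lse = logits.logsumexp(axis=1)
        return (logits - lse.reshape(b, 1)).exp()

    # -- numpy views ------------------------------------------------------
    def encode(self, x: np.ndarray) -> EncoderOutput:
        mu, lv = self.encode_t(Tensor(np.atleast_2d(x)))
        return EncoderOutput(mu=mu.data, log_var=lv.data)

    @property
    def prior(self) -> GMMParams | None:
        if self.prior_params is None:
            return None
        return GMMParams(
            log_weights=self.prior_params["log_weights"].data.copy(),
            means=self.prior_params["means"].data.copy(),
            log_vars=self.prior_params["log_vars"].data.copy(),
        )

    def init_prior(self, mu: np.ndarray, k: int, seed: int) -> None:
        """K-means on encoder means; variances kept in [1e-2, 1] (see module note)."""
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
        labels = km.fit_predict(mu)
        counts = np.bincount(labels, minlength=k).astype(float)
        weights = np.clip(counts, 1.0, None)
        variances = np.full((k, mu.shape[1]), 1.0)
        floor = np.exp(_PRIOR_LOGVAR_MIN)
        for j in range(k):
            members = mu[labels == j]
            if len(members) > 1:
                variances[j] = np.clip(members.var(axis=0), floor, 1.0)
            else:
                variances[j] = floor
        self.prior_params = {
            "log_weights": Tensor(np.log(weights / weights.sum()), True),
            "means": Tensor(km.cluster_centers_.copy(), True),
            "log_vars": Tensor(np.log(variances), True),
        }

    def clamp_prior(self) -> None:
        if self.prior_params is not None:
            np.clip(self.prior_params["log_vars"].data,
                    _PRIOR_LOGVAR_MIN, _PRIOR_LOGVAR_MAX,
                    out=self.prior_params["log_vars"].data)

    def trainable(self, include_prior: bool = True) -> list:
        out = list(self.params.values())
        if include_prior and self.prior_params is not None:
            out += list(self.prior_params.values())
        return out

    def elbo_t(self, xb: np.ndarray, beta: float, eps: np.ndarray | None = None):
        """(recon, kl, total) tensors for one batch; sum over dims, mean over batch."""
        x = Tensor(np.atleast_2d(xb))
        b = x.shape[0]
        mu, lv = self.encode_t(x)
        if eps is None:
            eps = self.rng.standard_normal((b, self.latent_dim))
        z = mu + Tensor(eps) * ((0.5 * lv).exp())
        xhat = self.decode_t(z)
        diff = x - xhat
        recon = (diff * diff).sum(axis=1).mean()
        if beta == 0 or self.prior_params is None:
            return recon, None, recon
        log_q = ((-0.5) * (_LOG2PI + lv + Tensor(eps) * Tensor(eps))).sum(axis=1)
        log_p = self.log_prior_t(z)
        kl = (log_q - log_p).mean()
        total = recon + beta * kl
        return recon, kl, total


def elbo_loss(batch, side_model: SideModel, beta: float, eps: np.ndarray | None = None):
    """Evaluate (recon_mse, kl_estimate, total) for a batch, as floats."""
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    recon, kl, total = side_model.elbo_t(np.asarray(batch, dtype=float), beta, eps=eps)
    return recon.item(), (kl.item() if kl is not None else 0.0), total.item()


# ---------------------------------------------------------------------------
# training


@dataclass
class CoClusterModel:
    row_side: SideModel
    col_side: SideModel
    kr: int
    kc: int
    config: TrainConfig
    lambda_mi: float
    val_recon: float = np.nan
    mi_org: float = np.nan
    mi_red: float = np.nan
    warnings_log: list = field(default_factory=list)

    @property
    def mi_ratio(self) -> float:
        """MI(T_org) / MI(T_red), the model-selection orientation."""
        return self.mi_org / self.mi_red if self.mi_red > 0 else np.nan

    def save(self, path) -> None:
        arrays = {}
        for side_name, side in (("row", self.row_side), ("col", self.col_side)):
            for k, v in side.params.items():
                arrays[f"{side_name}_{k}"] = v.data
            for k, v in (side.prior_params or {}).items():
                arrays[f"{side_name}_prior_{k}"] = v.data
        meta = {"kr": self.kr, "kc": self.kc, "lambda_mi": self.lambda_mi,
                "config": asdict(self.config),
                "row_input_dim": self.row_side.input_dim,
                "col_input_dim": self.col_side.input_dim,
                "val_recon": float(self.val_recon),
                "mi_org": float(self.mi_org), "mi_red": float(self.mi_red)}
        np.savez(path, __meta__=json.dumps(meta), **arrays)


def _minibatches(n: int, batch_size: int, rng, probs=None):
    if probs is not None:
        order = rng.choice(n, size=n, replace=True, p=probs)
    else:
        order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _beta_at(epoch: int, warmup: int) -> float:
    if warmup <= 0:
        return 1.0
    return float(min(1.0, (epoch + 1) / warmup))


def train_srvcc(fm, kr: int, kc: int, train_config: TrainConfig | None = None,
                cohort_labels=None):
    """Train the co-clustering model; returns (model, assignments, log).

    ``fm`` may be a FeatureMatrix (standardized or raw; per-row/per-column
    normalization is applied internally) or a plain array. ``cohort_labels``
    optionally enables inverse-frequency minibatch sampling on the row side
    to counter cohort imbalance; labels never enter the loss. Deterministic
    given the config seed.
    """
    cfg = train_config or TrainConfig()
    if isinstance(fm, FeatureMatrix):
        x = row_col_normalize(fm).values
    else:
        x = np.asarray(fm, dtype=float)
    n, d = x.shape
    if kr > n:
        warnings.warn(f"Kr={kr} capped to N={n}")
        kr = n
    if kc > d:
        warnings.warn(f"Kc={kc} capped to D={d}")
        kc = d

    rng = np.random.default_rng(cfg.seed)
    latent = min(cfg.latent_dim, d, n)
    row = SideModel(d, latent, cfg.hidden, seed=int(rng.integers(2**31)))
    col = SideModel(n, latent, cfg.hidden, seed=int(rng.integers(2**31)))

    # validation split (rows)
    n_val = int(round(cfg.val_frac * n))
    if n_val > 0 and n - n_val >= max(2, kr):
        perm = np.random.default_rng(cfg.seed + 1).permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, train_idx = np.array([], dtype=int), np.arange(n)
    x_train = x[train_idx]
    w_train = np.abs(x_train)

    probs = None
    if cohort_labels is not None:
        labels = np.asarray(cohort_labels)[train_idx]
        _, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
        p = 1.0 / counts[inv]
        probs = p / p.sum()

    batch = max(1, min(cfg.batch_size, len(train_idx)))
    log_rows = []

    # (1) reconstruction-only pretraining
    opt_r = Adam(row.trainable(include_prior=False), lr=cfg.learning_rate)
    opt_c = Adam(col.trainable(include_prior=False), lr=cfg.learning_rate)
    for epoch in range(cfg.pretrain_epochs):
        for idx in _minibatches(len(train_idx), batch, rng, probs):
            recon, _, total = row.elbo_t(x_train[idx], beta=0.0)
            opt_r.zero_grad()
            total.backward()
            opt_r.step()
        for idx in _minibatches(d, batch, rng):
            recon, _, total = col.elbo_t(x.T[idx], beta=0.0)
            opt_c.zero_grad()
            total.backward()
            opt_c.step()
        r_full = row.elbo_t(x_train, beta=0.0)[0].item()
        c_full = col.elbo_t(x.T, beta=0.0)[0].item()
        if not (np.isfinite(r_full) and np.isfinite(c_full)):
            raise TrainingDivergedError(f"non-finite pretrain loss at epoch {epoch}")
        log_rows.append({"phase": "pretrain", "epoch": epoch, "beta": 0.0,
                         "l_row": r_full, "l_col": c_full, "l_mi": 0.0,
                         "total": r_full + c_full})

    # (2) k-means initialization of both mixture priors
    row.init_prior(row.encode(x_train).mu, kr, seed=cfg.seed + 11)
    col.init_prior(col.encode(x.T).mu, kc, seed=cfg.seed + 12)

    # (3) joint optimization with KL warm-up and MI coupling
    opt = Adam(row.trainable() + col.trainable(), lr=cfg.learning_rate)
    w_tensor = Tensor(w_train)
    captured: list = []
    for epoch in range(cfg.epochs):
        beta = _beta_at(epoch, cfg.beta_warmup_epochs)
        for idx in _minibatches(len(train_idx), batch, rng, probs):
            _, _, total = row.elbo_t(x_train[idx], beta=beta)
            opt.zero_grad()
            total.backward()
            opt.step()
            row.clamp_prior()
        for idx in _minibatches(d, batch, rng):
            _, _, total = col.elbo_t(x.T[idx], beta=beta)
            opt.zero_grad()
            total.backward()
            opt.step()
            col.clamp_prior()

        if cfg.lambda_mi > 0:
            mi_loss_t = _mi_loss_tensor(row, col, x_train, x, w_tensor,
                                        cfg.lambda_mi, captured)
            if mi_loss_t is not None:
                opt.zero_grad()
                mi_loss_t.backward()
                opt.step()
                row.clamp_prior()
                col.clamp_prior()

        l_row = row.elbo_t(x_train, beta=beta)[2].item()
        l_col = col.elbo_t(x.T, beta=beta)[2].item()
        gr = responsibilities(row.encode(x_train).mu, row.prior)
        gc = responsibilities(col.encode(x.T).mu, col.prior)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            l_mi = mi_coupling_loss(gr, gc, w_train, cfg.lambda_mi)
        if not np.isfinite(l_row + l_col + l_mi):
            raise TrainingDivergedError(f"non-finite joint loss at epoch {epoch}")
        log_rows.append({"phase": "joint", "epoch": epoch, "beta": beta,
                         "l_row": l_row, "l_col": l_col, "l_mi": l_mi,
                         "total": l_row + l_col + l_mi})

    # final assignments from responsibilities of the encoder means (all data)
    gamma_rows = responsibilities(row.encode(x).mu, row.prior)
    gamma_cols = responsibilities(col.encode(x.T).mu, col.prior)
    assignments = AssignmentMatrices(gamma_rows=gamma_rows, gamma_cols=gamma_cols)

    w_all = np.abs(x)
    mi_org = mutual_information(cross_tab(gamma_rows, gamma_cols, w_all))
    mi_red = mutual_information(reduced_cross_tab(gamma_rows, gamma_cols, w_all))

    model = CoClusterModel(row_side=row, col_side=col, kr=kr, kc=kc, config=cfg,
                           lambda_mi=cfg.lambda_mi, mi_org=mi_org, mi_red=mi_red,
                           warnings_log=captured)
    if len(val_idx):
        recon, _, _ = elbo_loss(x[val_idx], row, beta=0.0,
                                eps=np.zeros((len(val_idx), latent)))
        model.val_recon = recon / d  # per-entry squared error
    # low-occupancy components are logged, not merged
    occupancy = gamma_rows.sum(axis=0)
    for k in np.nonzero(occupancy < 1e-3 * n)[0]:
        captured.append(f"row component {k} has responsibility mass {occupancy[k]:.2e}")

    return model, assignments, pd.DataFrame(log_rows)


def _mi_loss_tensor(row: SideModel, col: SideModel, x_train, x_full, w_tensor,
                    lambda_mi: float, captured: list):
    """Differentiable L_MI for the current parameters, or None if degenerate."""
    mu_r, _ = row.encode_t(Tensor(x_train))
    mu_c, _ = col.encode_t(Tensor(x_full.T))
    gr = row.responsibilities_t(mu_r)
    gc = col.responsibilities_t(mu_c)
    t_raw = gr.t() @ (w_tensor @ gc)
    t = t_raw / t_raw.sum()
    eps = Tensor(1e-12)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    mi_t = (t * ((t + eps).log() - (rows + eps).log() - (cols + eps).log())).sum()
    mi_org = mi_t.item()
    if mi_org <= _MI_EPS:
        captured.append("MI(T_org) ~ 0 during training; MI step skipped")
        return None
    mi_red = mutual_information(
        reduced_cross_tab(gr.data, gc.data, np.asarray(w_tensor.data)))
    ratio = mi_red / mi_org
    if not 0.0 <= ratio <= _RATIO_CAP:
        captured.append(f"MI ratio {ratio:.3f} outside clamp; MI step skipped")
        return None
    return Tensor(float(lambda_mi)) * (Tensor(1.0) + (Tensor(1.0) - Tensor(mi_red) / mi_t)).log()
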