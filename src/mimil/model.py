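"""The MI-MIL classifier, baselines, training and person-disjoint evaluation.

MI-MIL (modality-invariant multiple instance learning) classifies a 20 s
window of multimodal physiological features (a *bag* of 19 overlapping 2 s
*instances*) as CWS (children who stutter, label 1) vs. CWNS (label 0) while
only bag labels are ever observed.  Four blocks:

1. *Modality-specific embedding*: an MLP (ReLU between layers, linear output)
   maps each instance of each modality independently to a p-dim embedding.
2. *Modality-specific self-attention pooling*: per modality m the bag
   embedding is ``t_m = sum_i a_im e_im`` with
   ``a_im = softmax_i(w_m^T tanh(V_m e_im))`` — the gated-attention MIL
   pooling; the weights are non-negative and sum to 1.
3. *Modality fusion*: the four bag embeddings are concatenated to
   ``X in R^{4N}`` and a non-local (embedded-Gaussian) operator produces
   ``z_i = sum_j softmax_j(theta(x_i)^T phi(x_j)) g(x_j)`` where theta, phi, g
   are position-wise linear maps (1x1 convolutions over the 4N scalar
   positions), encoding pairwise and unary relations between all dimensions.
4. *Classifier*: two fully connected layers and a sigmoid give p(CWS).

Everything is plain numpy (float64) with hand-derived gradients; the backward
pass is verified against finite differences in the test suite.  Training is
Adam on bag-level binary cross-entropy with early stopping on validation F1.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .features import MODALITIES, FeatureBag, feature_names
from .preprocess import N_SEGMENTS


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    embedding_dim: int = 32  # p == M == N: instance and bag embedding size
    attention_hidden_dim: int = 16  # L
    embedding_hidden_dim: int = 32
    embedding_depth: int = 2
    classifier_hidden_dim: int = 32
    learning_rate: float = 3e-4
    epochs: int = 120
    batch_size: int = 32
    patience: int = 20
    #: independent initializations per training seed; the restart with the
    #: best validation F1 is kept (no test information is used)
    n_restarts: int = 3
    seeds: Tuple[int, ...] = (0, 1, 2)
    fusion: bool = True

    def __post_init__(self) -> None:
        if min(self.embedding_dim, self.attention_hidden_dim,
               self.classifier_hidden_dim, self.embedding_depth) < 1:
            raise ValueError("all network dimensions must be positive")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")


@dataclass
class Metrics:
    accuracy: float
    f1: float
    precision: float
    recall: float
    specificity: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
        }


@dataclass
class SplitSpec:
    """Person-disjoint partition; every window follows its participant."""

    train: List[str]
    validation: List[str]
    test: List[str]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if parts[i] & parts[j]:
                    raise ValueError(
                        f"participants shared between partitions: {parts[i] & parts[j]}"
                    )


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion-matrix metrics with CWS (label 1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("single-class test set; recall or specificity undefined")
    acc = (tp + tn) / max(1, len(y_true))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return Metrics(acc, f1, prec, rec, spec)


def bags_to_arrays(
    bags: Sequence[FeatureBag],
) -> Tuple[Dict[str, np.ndarray], np.ndarray, List[str]]:
    """Stack bags into per-modality (B, 19, d) arrays + labels + participant ids."""
    xs = {m: np.stack([b.matrices[m] for b in bags]) for m in MODALITIES}
    y = np.array([b.label for b in bags], dtype=float)
    pids = [b.participant_id for b in bags]
    return xs, y, pids


# ---------------------------------------------------------------------------
# functional blocks (single-bag; used directly by oracles and small tools)
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_pool(E: np.ndarray, V: np.ndarray, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Self-attention MIL pooling of one bag.

    ``E`` is (k, M) instance embeddings; returns ``(t, a)`` with
    ``a_i = softmax_i(w^T tanh(V e_i))`` and ``t = sum_i a_i e_i``.
    """
    E = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(E)):
        raise FloatingPointError("non-finite embeddings")
    logits = np.tanh(E @ V.T) @ w  # (k,)
    a = _softmax(logits, axis=0)
    t = a @ E
    return t, a


def fuse_modalities(
    t_eda: np.ndarray,
    t_hr: np.ndarray,
    t_rsp_amp: np.ndarray,
    t_rsp_rate: np.ndarray,
    w_theta: float,
    w_phi: float,
    w_g: float,
) -> np.ndarray:
    """Non-local embedded-Gaussian fusion of the four bag embeddings.

    The concatenation ``X`` (fixed modality order EDA, HR, RSP-amp, RSP-rate)
    is treated as 4N scalar positions; ``theta(x) = w_theta x``,
    ``phi(x) = w_phi x``, ``g(x) = w_g x`` are the position-wise linear maps,
    so the pairwise similarity is ``exp(w_theta w_phi x_i x_j)`` and
    ``z_i = sum_j softmax_j(...) g(x_j)``.  Z has the same dimension as X.
    """
    X = np.concatenate([t_eda, t_hr, t_rsp_amp, t_rsp_rate]).astype(float)
    c = w_theta * w_phi
    M = c * np.outer(X, X)
    S = _softmax(M, axis=1)
    return S @ (w_g * X)


def classify(Z: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2) -> float:
    """Two fully connected layers + sigmoid -> p(CWS) in (0, 1)."""
    h = np.maximum(Z @ W1 + b1, 0.0)
    logit = float(h @ W2 + b2)
    return 1.0 / (1.0 + np.exp(-logit))


# ---------------------------------------------------------------------------
# the trainable network (batched forward/backward)
# ---------------------------------------------------------------------------


class MILNet:
    """Shared machinery for MI-MIL and the attention-MIL baseline.

    MI-MIL uses all four modalities plus the fusion block; the attention-MIL
    baseline concatenates all modalities' features per instance into a single
    stream and omits fusion.
    """

    def __init__(
        self,
        input_dims: Dict[str, int],
        cfg: ModelConfig,
        fusion: Optional[bool] = None,
    ):
        self.modalities = list(input_dims)
        self.input_dims = dict(input_dims)
        self.cfg = cfg
        self.fusion = cfg.fusion if fusion is None else fusion
        self.z_dim = len(self.modalities) * cfg.embedding_dim

    # -- parameters ---------------------------------------------------------

    def init_params(self, seed: int) -> Dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        cfg = self.cfg
        p: Dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        for m in self.modalities:
            d = self.input_dims[m]
            dims = [d] + [cfg.embedding_hidden_dim] * (cfg.embedding_depth - 1) + [cfg.embedding_dim]
            for layer in range(cfg.embedding_depth):
                p[f"emb_{m}_W{layer}"] = he((dims[layer], dims[layer + 1]), dims[layer])
                p[f"emb_{m}_b{layer}"] = np.zeros(dims[layer + 1])
            p[f"att_{m}_V"] = he((cfg.attention_hidden_dim, cfg.embedding_dim), cfg.embedding_dim)
            p[f"att_{m}_w"] = he((cfg.attention_hidden_dim,), cfg.attention_hidden_dim)
        if self.fusion:
            p["fus_wtheta"] = np.array(rng.normal(0.0, 0.1))
            p["fus_wphi"] = np.array(rng.normal(0.0, 0.1))
            p["fus_wg"] = np.array(1.0 + rng.normal(0.0, 0.1))
        p["clf_W1"] = he((self.z_dim, cfg.classifier_hidden_dim), self.z_dim)
        p["clf_b1"] = np.zeros(cfg.classifier_hidden_dim)
        p["clf_W2"] = he((cfg.classifier_hidden_dim,), cfg.classifier_hidden_dim)
        p["clf_b2"] = np.zeros(())
        return p

    # -- forward ------------------------------------------------------------

    def forward(
        self, params: Dict[str, np.ndarray], xs: Dict[str, np.ndarray]
    ) -> Tuple[np.ndarray, dict]:
        """Batched forward pass; returns (logits (B,), cache)."""
        cfg = self.cfg
        cache: dict = {"emb": {}, "att": {}}
        ts = []
        for m in self.modalities:
            X = np.asarray(xs[m], dtype=float)  # (B, k, d)
            acts = [X]
            pre = []
            H = X
            for layer in range(cfg.embedding_depth):
                H = H @ params[f"emb_{m}_W{layer}"] + params[f"emb_{m}_b{layer}"]
                pre.append(H)
                if layer < cfg.embedding_depth - 1:
                    H = np.maximum(H, 0.0)
                acts.append(H)
            E = H  # (B, k, p); final layer linear
            T = np.tanh(E @ params[f"att_{m}_V"].T)  # (B, k, L)
            logits_a = T @ params[f"att_{m}_w"]  # (B, k)
            if not np.all(np.isfinite(logits_a)):
                raise FloatingPointError("non-finite attention logits")
            A = _softmax(logits_a, axis=1)
            t = np.einsum("bk,bkp->bp", A, E)
            cache["emb"][m] = (acts, pre)
            cache["att"][m] = (E, T, A)
            ts.append(t)
        X4 = np.concatenate(ts, axis=1)  # (B, 4N) or (B, p)
        cache["X4"] = X4
        if self.fusion:
            c = float(params["fus_wtheta"]) * float(params["fus_wphi"])
            Mm = c * X4[:, :, None] * X4[:, None, :]  # (B, D, D)
            S = _softmax(Mm, axis=2)
            G = float(params["fus_wg"]) * X4
            Z = np.einsum("bij,bj->bi", S, G)
            cache["fus"] = (S, G)
        else:
            Z = X4
        h_pre = Z @ params["clf_W1"] + params["clf_b1"]
        h = np.maximum(h_pre, 0.0)
        logit = h @ params["clf_W2"] + params["clf_b2"]
        cache["clf"] = (Z, h_pre, h)
        return logit, cache

    def predict_proba(self, params: Dict[str, np.ndarray], xs: Dict[str, np.ndarray]) -> np.ndarray:
        logit, _ = self.forward(params, xs)
        return 1.0 / (1.0 + np.exp(-logit))

    # -- loss and gradients -------------------------------------------------

    def loss_and_grads(
        self, params: Dict[str, np.ndarray], xs: Dict[str, np.ndarray], y: np.ndarray
    ) -> Tuple[float, Dict[str, np.ndarray]]:
        """Mean bag-level binary cross-entropy and its parameter gradients."""
        cfg = self.cfg
        logit, cache = self.forward(params, xs)
        y = np.asarray(y, dtype=float)
        B = len(y)
        # numerically stable BCE-with-logits
        loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))
        p_hat = 1.0 / (1.0 + np.exp(-logit))
        dlogit = (p_hat - y) / B  # (B,)

        g: Dict[str, np.ndarray] = {}
        Z, h_pre, h = cache["clf"]
        g["clf_W2"] = h.T @ dlogit
        g["clf_b2"] = np.array(dlogit.sum())
        dh = dlogit[:, None] * params["clf_W2"][None, :]
        dh_pre = dh * (h_pre > 0)
        g["clf_W1"] = Z.T @ dh_pre
        g["clf_b1"] = dh_pre.sum(axis=0)
        dZ = dh_pre @ params["clf_W1"].T  # (B, D)

        X4 = cache["X4"]
        if self.fusion:
            S, G = cache["fus"]
            c = float(params["fus_wtheta"]) * float(params["fus_wphi"])
            wg = float(params["fus_wg"])
            dS = dZ[:, :, None] * G[:, None, :]  # (B, D, D)
            dG = np.einsum("bij,bi->bj", S, dZ)
            g["fus_wg"] = np.array(np.sum(dG * X4))
            dX4 = wg * dG
            # softmax (row-wise over j) backward
            dM = S * (dS - np.sum(S * dS, axis=2, keepdims=True))
            xxT = X4[:, :, None] * X4[:, None, :]
            dc = float(np.sum(dM * xxT))
            g["fus_wtheta"] = np.array(dc * float(params["fus_wphi"]))
            g["fus_wphi"] = np.array(dc * float(params["fus_wtheta"]))
            dX4 = dX4 + c * (
                np.einsum("bij,bj->bi", dM, X4) + np.einsum("bji,bj->bi", dM, X4)
            )
        else:
            dX4 = dZ

        p_dim = cfg.embedding_dim
        for mi, m in enumerate(self.modalities):
            dt = dX4[:, mi * p_dim : (mi + 1) * p_dim]  # (B, p)
            E, T, A = cache["att"][m]
            dA = np.einsum("bp,bkp->bk", dt, E)
            dE = A[:, :, None] * dt[:, None, :]
            dlog_a = A * (dA - np.sum(A * dA, axis=1, keepdims=True))
            w_att = params[f"att_{m}_w"]
            dT = dlog_a[:, :, None] * w_att[None, None, :]
            g[f"att_{m}_w"] = np.einsum("bk,bkl->l", dlog_a, T)
            dpreT = dT * (1.0 - T**2)
            g[f"att_{m}_V"] = np.einsum("bkl,bkp->lp", dpreT, E)
            dE = dE + dpreT @ params[f"att_{m}_V"]

            acts, pre = cache["emb"][m]
            dH = dE
            for layer in reversed(range(cfg.embedding_depth)):
                if layer < cfg.embedding_depth - 1:
                    dH = dH * (pre[layer] > 0)
                inp = acts[layer]
                g[f"emb_{m}_W{layer}"] = np.einsum("bkd,bkh->dh", inp, dH)
                g[f"emb_{m}_b{layer}"] = dH.sum(axis=(0, 1))
                dH = dH @ params[f"emb_{m}_W{layer}"].T
        return loss, g


def _mimil_net(cfg: ModelConfig, representation: str = "raw") -> MILNet:
    d = 6 if representation == "raw" else 2
    return MILNet({m: d for m in MODALITIES}, cfg)


def _attention_mil_net(cfg: ModelConfig, representation: str = "raw") -> MILNet:
    d = (6 if representation == "raw" else 2) * len(MODALITIES)
    return MILNet({"all": d}, cfg, fusion=False)


def _concat_instances(xs: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Merge per-modality instance matrices into one stream (attention-MIL input)."""
    return {"all": np.concatenate([xs[m] for m in MODALITIES], axis=2)}


def _fit_norm(xs: Dict[str, np.ndarray]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-modality, per-feature mean/sd over all instances of the train set."""
    out = {}
    for m, X in xs.items():
        flat = X.reshape(-1, X.shape[-1])
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd[sd < 1e-12] = 1.0
        out[m] = (mu, sd)
    return out


def _normalize(
    xs: Dict[str, np.ndarray],
    norm: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]],
) -> Dict[str, np.ndarray]:
    if norm is None:
        return xs
    return {m: (X - norm[m][0]) / norm[m][1] for m, X in xs.items()}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    net: MILNet
    params: Dict[str, np.ndarray]
    config: ModelConfig
    seed: int
    representation: str
    kind: str  # "mimil" | "attention_mil"
    history: List[Tuple[int, float, float]] = field(default_factory=list)  # epoch, loss, val F1
    #: per-modality (mean, sd) of each instance feature, fit on the train set
    norm: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def _prep(self, xs: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        xs = _normalize(xs, self.norm)
        return _concat_instances(xs) if self.kind == "attention_mil" else xs

    def predict_proba(self, xs: Dict[str, np.ndarray]) -> np.ndarray:
        return self.net.predict_proba(self.params, self._prep(xs))

    def predict(self, xs: Dict[str, np.ndarray]) -> np.ndarray:
        return (self.predict_proba(xs) >= 0.5).astype(int)

    def attention_weights(self, xs: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        """Per modality (or 'all' for attention-MIL), the (B, k) pooling weights."""
        _, cache = self.net.forward(self.params, self._prep(xs))
        return {m: cache["att"][m][2] for m in self.net.modalities}


def forward(bag: FeatureBag, model: TrainedModel) -> float:
    """p(CWS) for a single bag; deterministic given parameters."""
    xs = {m: bag.matrices[m][None, :, :] for m in MODALITIES}
    return float(model.predict_proba(xs)[0])


class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            gk = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def train_model(
    train_xs: Dict[str, np.ndarray],
    train_y: np.ndarray,
    val_xs: Dict[str, np.ndarray],
    val_y: np.ndarray,
    cfg: ModelConfig,
    seed: int = 0,
    kind: str = "mimil",
    representation: str = "raw",
) -> TrainedModel:
    """Train one model with one seed; early stopping on validation F1.

    Fully deterministic: the same seed always yields the same parameters.
    """
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain both classes")
    if kind == "mimil":
        net = _mimil_net(cfg, representation)
        prep = lambda xs: xs
    elif kind == "attention_mil":
        net = _attention_mil_net(cfg, representation)
        prep = _concat_instances
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    norm = _fit_norm(train_xs)
    txs = prep(_normalize(train_xs, norm))
    vxs = prep(_normalize(val_xs, norm))

    def _train_once(init_seed: int):
        params = net.init_params(init_seed)
        opt = _Adam(params, cfg.learning_rate)
        rng = np.random.default_rng(init_seed + 1)
        n = len(train_y)
        best_f1, best_params, since_best = -1.0, copy.deepcopy(params), 0
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                batch = {m: X[idx] for m, X in txs.items()}
                loss, grads = net.loss_and_grads(params, batch, train_y[idx])
                opt.step(params, grads)
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            val_pred = (net.predict_proba(params, vxs) >= 0.5).astype(int)
            vf1 = _f1(val_y.astype(int), val_pred)
            history.append((epoch, epoch_loss, vf1))
            if vf1 > best_f1 + 1e-12:
                best_f1, best_params, since_best = vf1, copy.deepcopy(params), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        return best_f1, best_params, history

    # restarts: re-initialize and keep the restart with the best validation F1
    best_f1, best_params, history = -1.0, None, []
    for r in range(cfg.n_restarts):
        f1_r, params_r, hist_r = _train_once(seed + 10007 * r)
        if f1_r > best_f1 + 1e-12:
            best_f1, best_params, history = f1_r, params_r, hist_r
    return TrainedModel(
        net=net,
        params=best_params,
        config=cfg,
        seed=seed,
        representation=representation,
        kind=kind,
        history=history,
        norm=norm,
    )


def evaluate(models, test_xs: Dict[str, np.ndarray], test_y: np.ndarray) -> Metrics:
    """Confusion-matrix metrics on the test bags, averaged over seeds.

    ``models`` is one :class:`TrainedModel` or a list of them (one per seed);
    metric values are averaged across models, matching seed-averaged reporting.
    """
    if isinstance(models, TrainedModel):
        models = [models]
    per_seed = [compute_metrics(test_y.astype(int), m.predict(test_xs)) for m in models]
    vals = {
        k: float(np.mean([getattr(ms, k) for ms in per_seed]))
        for k in ("accuracy", "f1", "precision", "recall", "specificity")
    }
    return Metrics(**vals)


def person_disjoint_split(
    participants: Dict[str, str],
    seed: int = 0,
    n_test_per_group: int = 3,
    n_val_per_group: int = 3,
) -> SplitSpec:
    """Random person-disjoint train/validation/test split, balanced by group.

    ``participants`` maps participant_id -> group.  Test and validation each
    take ``n`` CWS + ``n`` CWNS participants; the remainder trains.
    """
    rng = np.random.default_rng(seed)
    by_group = {"CWS": [], "CWNS": []}
    for pid, grp in sorted(participants.items()):
        by_group[grp].append(pid)
    need = n_test_per_group + n_val_per_group
    for grp, ids in by_group.items():
        if len(ids) < need + 1:
            raise ValueError(f"group {grp} has {len(ids)} participants; need > {need}")
    test, val, train = [], [], []
    for grp, ids in by_group.items():
        ids = list(ids)
        rng.shuffle(ids)
        test += ids[:n_test_per_group]
        val += ids[n_test_per_group:need]
        train += ids[need:]
    return SplitSpec(train=sorted(train), validation=sorted(val), test=sorted(test))


def split_bags(
    bags: Sequence[FeatureBag], split: SplitSpec
) -> Tuple[List[FeatureBag], List[FeatureBag], List[FeatureBag]]:
    tr = [b for b in bags if b.participant_id in set(split.train)]
    va = [b for b in bags if b.participant_id in set(split.validation)]
    te = [b for b in bags if b.participant_id in set(split.test)]
    return tr, va, te


def save_model(model: TrainedModel, out_dir) -> None:
    """Checkpoint: parameters as .npz plus a JSON config sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    extra = {}
    if model.norm is not None:
        for m, (mu, sd) in model.norm.items():
            extra[f"__norm_{m}_mu"] = mu
            extra[f"__norm_{m}_sd"] = sd
    np.savez(out_dir / "params.npz", **model.params, **extra)
    cfg = asdict(model.config)
    cfg["seeds"] = list(cfg["seeds"])
    with open(out_dir / "model.json", "w") as fh:
        json.dump(
            {
                "config": cfg,
                "seed": model.seed,
                "kind": model.kind,
                "representation": model.representation,
                "input_dims": model.net.input_dims,
                "fusion": model.net.fusion,
            },
            fh,
            indent=1,
        )


def load_model(out_dir) -> TrainedModel:
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    with open(out_dir / "model.json") as fh:
        meta = json.load(fh)
    cfg_d = meta["config"]
    cfg_d["seeds"] = tuple(cfg_d["seeds"])
    cfg = ModelConfig(**cfg_d)
    net = MILNet(meta["input_dims"], cfg, fusion=meta["fusion"])
    with np.load(Path(out_dir) / "params.npz") as data:
        params = {k: data[k] for k in data.files if not k.startswith("__norm_")}
        norm = None
        mods = {k[len("__norm_"):-3] for k in data.files if k.startswith("__norm_") and k.endswith("_mu")}
        if mods:
            norm = {m: (data[f"__norm_{m}_mu"], data[f"__norm_{m}_sd"]) for m in mods}
    return TrainedModel(
        net=net,
        params=params,
        config=cfg,
        seed=meta["seed"],
        representation=meta["representation"],
        kind=meta["kind"],
        norm=norm,
    )


# ---------------------------------------------------------------------------
# baselines and feature ranking
# ---------------------------------------------------------------------------


def flat_supervised_baseline(
    train_bags: Sequence[FeatureBag],
    test_bags: Sequence[FeatureBag],
    seed: int = 0,
    hidden: Tuple[int, int] = (64, 32),
    val_bags: Optional[Sequence[FeatureBag]] = None,
    epochs: int = 120,
    patience: int = 20,
) -> Tuple[Metrics, MLPClassifier]:
    """Flat supervised reference: a 2-hidden-layer MLP on the flattened grid.

    Sees the whole 19x24 (or 19x8) window as one feature vector, so it must
    learn position-specific patterns — exactly what sparse random-onset
    witnesses deny it.  Trained under the same protocol as the MIL models:
    when ``val_bags`` is given, epochs run one at a time with early stopping
    and model selection on validation F1; otherwise it fits to convergence on
    the training bags alone.
    """
    Xtr = np.stack([b.flatten().ravel() for b in train_bags])
    ytr = np.array([b.label for b in train_bags])
    Xte = np.stack([b.flatten().ravel() for b in test_bags])
    yte = np.array([b.label for b in test_bags])
    scaler = StandardScaler().fit(Xtr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at fixed budget
        if val_bags is None:
            clf = MLPClassifier(
                hidden_layer_sizes=hidden, random_state=seed, max_iter=300, alpha=1e-3
            )
            clf.fit(scaler.transform(Xtr), ytr)
        else:
            Xva = scaler.transform(np.stack([b.flatten().ravel() for b in val_bags]))
            yva = np.array([b.label for b in val_bags])
            Xs = scaler.transform(Xtr)
            overall_best, clf = -1.0, None
            # same restart policy as the MIL models: best validation F1 wins
            for r in range(ModelConfig().n_restarts):
                cand = MLPClassifier(
                    hidden_layer_sizes=hidden, random_state=seed + 10007 * r,
                    max_iter=1, alpha=1e-3, warm_start=True,
                )
                best_f1, best_coefs, since = -1.0, None, 0
                for _ in range(epochs):
                    cand.fit(Xs, ytr)
                    vf1 = _f1(yva, cand.predict(Xva))
                    if vf1 > best_f1 + 1e-12:
                        best_f1 = vf1
                        best_coefs = (
                            [c.copy() for c in cand.coefs_],
                            [c.copy() for c in cand.intercepts_],
                        )
                        since = 0
                    else:
                        since += 1
                        if since >= patience:
                            break
                if best_coefs is not None:
                    cand.coefs_, cand.intercepts_ = best_coefs
                if best_f1 > overall_best:
                    overall_best, clf = best_f1, cand
    pred = clf.predict(scaler.transform(Xte))
    return compute_metrics(yte, pred), clf


def ridge_feature_ranking(
    bags: Sequence[FeatureBag], alpha: float = 1.0
) -> List[Tuple[str, float]]:
    """Rank the 24 HLD features by signed ridge coefficient (descending).

    Each window's 19 instances are averaged to one 24-vector, features are
    standardized, and a ridge regressor is fit against the bag labels; the
    squared-magnitude penalty shrinks uninformative coefficients toward 0.
    """
    X = np.stack([b.flatten().mean(axis=0) for b in bags])
    y = np.array([b.label for b in bags], dtype=float)
    X = StandardScaler().fit_transform(X)
    cond = np.linalg.cond(X.T @ X + alpha * np.eye(X.shape[1]))
    if cond > 1e10:
        warnings.warn(f"extreme condition number {cond:.2e} despite ridge penalty")
    model = Ridge(alpha=alpha).fit(X, y)
    names = feature_names(bags[0].representation)
    ranked = sorted(zip(names, model.coef_), key=lambda kv: kv[1], reverse=True)
    return [(n, float(c)) for n, c in ranked]
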