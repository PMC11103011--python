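"""Dual-stream deep risk model for matched case-control outcome data.

Architecture: temporal presence tokens are embedded (feature-id embedding
plus period-id embedding, combined by addition) and encoded by a transformer
encoder (two blocks by default, multi-head self-attention + feed-forward,
post-layer-norm, mean-pooled over real tokens); static covariates pass
through a residual multilayer perceptron; the two streams are combined by
element-wise addition and a fully connected sigmoid head produces a risk
score in (0, 1).  Training minimizes binary cross-entropy with Adam, monitors
the area under the ROC curve, keeps the best-validation-AUC weights, and
reports sensitivity/specificity at the operating threshold where the two are
closest to equal.

The interface follows the statsmodels convention: a model object is built
from data and configuration, ``fit()`` returns a results object carrying the
trained network, the training report and prediction/evaluation/summary
methods.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from ehrisk.autodiff import Adam, Parameter, Tensor
from ehrisk.encoding import EncodedDataset, EncodedPatient

__all__ = ["ModelConfig", "TrainReport", "SuicideRiskModel", "RiskModelResults",
           "roc_auc", "equal_error_threshold", "classification_metrics"]


@dataclass
class ModelConfig:
    embed_dim: int = 64
    n_heads: int = 4
    n_encoder_blocks: int = 2
    mlp_hidden: int = 128
    ffn_mult: int = 2
    dropout: float = 0.1
    weight_decay: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 30
    early_stop_patience: int = 5
    #: model selection on "val_loss" (proper scoring rule, calibration-aware)
    #: or "val_auc" (rank-based)
    early_stop_metric: str = "val_loss"
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encoder_blocks < 1:
            raise ValueError("n_encoder_blocks must be >= 1")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim ({self.embed_dim}) must be divisible by n_heads ({self.n_heads})")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


# --- metrics ----------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """AUC by the rank statistic (Mann-Whitney), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for a single-class label set")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classification_metrics(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) with positives called at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


def equal_error_threshold(scores, labels) -> float:
    """Threshold over unique scores where sensitivity and specificity are
    closest to equal (ties broken toward higher sensitivity + specificity)."""
    best_t, best_key = 0.5, (np.inf, -np.inf)
    for t in np.unique(np.asarray(scores, dtype=float)):
        sens, spec = classification_metrics(scores, labels, t)
        key = (abs(sens - spec), -(sens + spec))
        if key < best_key:
            best_key, best_t = key, float(t)
    return best_t


@dataclass
class TrainReport:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_train_auc: list[float] = field(default_factory=list)
    epoch_val_auc: list[float] = field(default_factory=list)
    epoch_val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    train_auc: float = float("nan")
    val_auc: float = float("nan")
    threshold: float = 0.5
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    n_parameters: int = 0


# --- network ----------------------------------------------------------------

class _RiskNetwork:
    """Parameter container and forward pass (internal)."""

    def __init__(self, config: ModelConfig, vocab_size: int, static_dim: int,
                 n_periods: int = 21, static_mean=None, static_std=None):
        if vocab_size < 0 or static_dim <= 0:
            raise ValueError("dimensions must be positive")
        self.config = config
        self.vocab_size = vocab_size
        self.static_dim = static_dim
        self.n_periods = n_periods
        self.static_mean = np.zeros(static_dim) if static_mean is None else np.asarray(static_mean, float)
        self.static_std = np.ones(static_dim) if static_std is None else np.asarray(static_std, float)
        rng = np.random.default_rng(config.seed)
        D, H, F = config.embed_dim, config.mlp_hidden, config.embed_dim * config.ffn_mult
        p: dict[str, Tensor] = {}

        def init(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Parameter(rng.normal(0.0, scale, size=shape))

        p["emb_feat"] = Parameter(rng.normal(0.0, 0.05, size=(vocab_size + 1, D)))
        p["emb_period"] = Parameter(rng.normal(0.0, 0.05, size=(n_periods + 1, D)))
        for b in range(config.n_encoder_blocks):
            for name in ("q", "k", "v", "o"):
                p[f"blk{b}_W{name}"] = init(D, D)
                p[f"blk{b}_b{name}"] = Parameter(np.zeros(D))
            p[f"blk{b}_ln1_g"] = Parameter(np.ones(D))
            p[f"blk{b}_ln1_b"] = Parameter(np.zeros(D))
            p[f"blk{b}_W1"] = init(D, F)
            p[f"blk{b}_b1"] = Parameter(np.zeros(F))
            p[f"blk{b}_W2"] = init(F, D)
            p[f"blk{b}_b2"] = Parameter(np.zeros(D))
            p[f"blk{b}_ln2_g"] = Parameter(np.ones(D))
            p[f"blk{b}_ln2_b"] = Parameter(np.zeros(D))
        p["Ws1"] = init(static_dim, H)
        p["bs1"] = Parameter(np.zeros(H))
        p["Ws2"] = init(H, H)
        p["bs2"] = Parameter(np.zeros(H))
        p["Ws3"] = init(H, D)
        p["bs3"] = Parameter(np.zeros(D))
        p["w_out"] = init(D, 1)
        p["b_out"] = Parameter(np.zeros(1))
        self.params = p
        self._drop_rng = np.random.default_rng(config.seed + 1)

    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.params.values()))

    def _dropout(self, x: Tensor, train: bool) -> Tensor:
        rate = self.config.dropout
        if not train or rate <= 0.0:
            return x
        mask = (self._drop_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * mask

    def forward(self, feat_ids: np.ndarray, per_ids: np.ndarray, mask: np.ndarray,
                static: np.ndarray, train: bool = False) -> Tensor:
        """Risk logits for a padded batch; ``mask`` is 1 on real tokens."""
        if feat_ids.size and feat_ids.max() > self.vocab_size:
            raise ValueError(
                f"token id {int(feat_ids.max())} outside vocabulary of size {self.vocab_size}")
        p = self.params
        cfg = self.config
        B, L = feat_ids.shape
        D, h = cfg.embed_dim, cfg.n_heads
        dh = D // h

        x = (p["emb_feat"].take_rows(feat_ids) + p["emb_period"].take_rows(per_ids))
        x = x * mask[:, :, None]
        attn_bias = (1.0 - mask)[:, None, None, :] * -1e9  # (B,1,1,L)
        for b in range(cfg.n_encoder_blocks):
            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

            q = heads(x @ p[f"blk{b}_Wq"] + p[f"blk{b}_bq"])
            k = heads(x @ p[f"blk{b}_Wk"] + p[f"blk{b}_bk"])
            v = heads(x @ p[f"blk{b}_Wv"] + p[f"blk{b}_bv"])
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + attn_bias
            att = scores.softmax()
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
            ctx = ctx @ p[f"blk{b}_Wo"] + p[f"blk{b}_bo"]
            x = (x + self._dropout(ctx, train)).layer_norm(p[f"blk{b}_ln1_g"], p[f"blk{b}_ln1_b"])
            ff = (x @ p[f"blk{b}_W1"] + p[f"blk{b}_b1"]).relu() @ p[f"blk{b}_W2"] + p[f"blk{b}_b2"]
            x = (x + self._dropout(ff, train)).layer_norm(p[f"blk{b}_ln2_g"], p[f"blk{b}_ln2_b"])

        # sum pooling (not mean): token contributions stay additive, so removing
        # one feature's tokens does not rescale the others' — mean pooling would
        # induce a spurious negative interaction between co-occurring features
        pooled = (x * mask[:, :, None]).sum(axis=1)  # empty sequence -> zeros

        s = (static - self.static_mean) / self.static_std
        h1 = (Tensor(s) @ p["Ws1"] + p["bs1"]).relu()
        h1 = self._dropout(h1, train)
        h2 = ((h1 @ p["Ws2"] + p["bs2"]).relu() + h1)  # residual connection
        sdm = h2 @ p["Ws3"] + p["bs3"]

        fused = pooled + sdm  # element-wise addition of the two streams
        logits = (fused @ p["w_out"] + p["b_out"]).reshape(B)
        return logits

    def predict_batch(self, feat_ids, per_ids, mask, static) -> np.ndarray:
        z = self.forward(feat_ids, per_ids, mask, static, train=False).data
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def state(self) -> dict[str, np.ndarray]:
        st = {k: t.data.copy() for k, t in self.params.items()}
        st["__static_mean"] = self.static_mean.copy()
        st["__static_std"] = self.static_std.copy()
        return st

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()
        self.static_mean = state["__static_mean"].copy()
        self.static_std = state["__static_std"].copy()


def _pack(patients: list[EncodedPatient]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of encoded patients into batch arrays."""
    B = len(patients)
    L = max((len(p.tokens) for p in patients), default=0) or 1
    feat = np.zeros((B, L), dtype=np.int64)
    per = np.zeros((B, L), dtype=np.int64)
    mask = np.zeros((B, L), dtype=np.float64)
    static = np.stack([p.static for p in patients])
    for i, p in enumerate(patients):
        for j, (fid, pid) in enumerate(p.tokens):
            feat[i, j] = fid
            per[i, j] = pid
            mask[i, j] = 1.0
    return feat, per, mask, static


# --- model / results --------------------------------------------------------

class SuicideRiskModel:
    """Dual-stream risk model bound to an encoded case-control dataset.

    Parameters
    ----------
    dataset : EncodedDataset
        Encoded patients with binary labels (1 = suicide death), produced by
        :mod:`ehrisk.encoding` — approximately balanced under the matched
        design.
    config : ModelConfig, optional
        Architecture and training hyperparameters.
    """

    def __init__(self, dataset: EncodedDataset, config: ModelConfig | None = None):
        self.dataset = dataset
        self.config = config or ModelConfig()
        labels = dataset.labels()
        if len(np.unique(labels)) < 2:
            raise ValueError("training data must contain both outcome classes")
        statics = np.stack([p.static for p in dataset.patients])
        mean = statics.mean(axis=0)
        std = statics.std(axis=0)
        std[std < 1e-8] = 1.0
        self.network = _RiskNetwork(self.config, vocab_size=len(dataset.vocabulary),
                                    static_dim=dataset.static_dim,
                                    n_periods=dataset.scheme.n_periods,
                                    static_mean=mean, static_std=std)

    def fit(self, verbose: bool = False) -> "RiskModelResults":
        """Train with BCE/Adam, early-stopping on validation AUC."""
        cfg = self.config
        net = self.network
        rng = np.random.default_rng(cfg.seed + 2)
        labels = self.dataset.labels()

        # stratified validation split
        idx_pos = np.flatnonzero(labels == 1)
        idx_neg = np.flatnonzero(labels == 0)
        rng.shuffle(idx_pos)
        rng.shuffle(idx_neg)
        nvp = max(1, int(round(len(idx_pos) * cfg.validation_fraction)))
        nvn = max(1, int(round(len(idx_neg) * cfg.validation_fraction)))
        val_idx = np.concatenate([idx_pos[:nvp], idx_neg[:nvn]])
        train_idx = np.concatenate([idx_pos[nvp:], idx_neg[nvn:]])
        train_set = [self.dataset.patients[i] for i in train_idx]
        val_set = [self.dataset.patients[i] for i in val_idx]
        y_train = labels[train_idx]
        y_val = labels[val_idx]

        opt = Adam(net.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        report = TrainReport(n_parameters=net.n_parameters)
        best_val, best_state, since_best = -np.inf, None, 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(train_set))
            total, count = 0.0, 0
            for lo in range(0, len(order), cfg.batch_size):
                sel = order[lo:lo + cfg.batch_size]
                batch = [train_set[i] for i in sel]
                y = y_train[sel]
                feat, per, mask, static = _pack(batch)
                logits = net.forward(feat, per, mask, static, train=True)
                # BCE with logits: softplus(z) - y*z, averaged
                loss = (logits.softplus() - logits * y).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(sel)
                count += len(sel)
            train_scores = self._scores(net, train_set)
            val_scores = self._scores(net, val_set)
            tr_auc = roc_auc(train_scores, y_train)
            va_auc = roc_auc(val_scores, y_val)
            eps = 1e-12
            val_nll = -float(np.mean(y_val * np.log(val_scores + eps)
                                     + (1 - y_val) * np.log(1 - val_scores + eps)))
            report.epoch_loss.append(total / count)
            report.epoch_train_auc.append(tr_auc)
            report.epoch_val_auc.append(va_auc)
            report.epoch_val_loss.append(val_nll)
            if verbose:
                print(f"epoch {epoch}: loss {total / count:.4f} "
                      f"train AUC {tr_auc:.4f} val AUC {va_auc:.4f} val NLL {val_nll:.4f}")
            criterion = -val_nll if cfg.early_stop_metric == "val_loss" else va_auc
            if criterion > best_val:
                best_val, best_state, since_best = criterion, net.state(), 0
                report.best_epoch = epoch
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
        if best_state is not None:
            net.load_state(best_state)

        val_scores = self._scores(net, val_set)
        train_scores = self._scores(net, train_set)
        report.train_auc = roc_auc(train_scores, y_train)
        report.val_auc = roc_auc(val_scores, y_val)
        report.threshold = equal_error_threshold(val_scores, y_val)
        report.sensitivity, report.specificity = classification_metrics(
            val_scores, y_val, report.threshold)
        return RiskModelResults(model=self, network=net, report=report)

    @staticmethod
    def _scores(net: _RiskNetwork, patients: list[EncodedPatient],
                batch_size: int = 512) -> np.ndarray:
        out = []
        for lo in range(0, len(patients), batch_size):
            out.append(net.predict_batch(*_pack(patients[lo:lo + batch_size])))
        return np.concatenate(out) if out else np.array([])


class RiskModelResults:
    """Fitted dual-stream risk model: predictions, metrics, persistence."""

    def __init__(self, model: SuicideRiskModel, network: _RiskNetwork, report: TrainReport):
        self.model = model
        self.network = network
        self.report = report

    # scorer contract used by ehrisk.explain
    def predict_proba(self, patients) -> np.ndarray:
        """Risk scores in (0, 1) for encoded patients (list or dataset)."""
        if isinstance(patients, EncodedDataset):
            patients = patients.patients
        if isinstance(patients, EncodedPatient):
            patients = [patients]
        return SuicideRiskModel._scores(self.network, list(patients))

    def evaluate(self, dataset: EncodedDataset, threshold: float | None = None) -> dict:
        """AUC plus sensitivity/specificity at the operating threshold."""
        scores = self.predict_proba(dataset)
        labels = dataset.labels().astype(int)
        t = self.report.threshold if threshold is None else threshold
        sens, spec = classification_metrics(scores, labels, t)
        return {"auc": roc_auc(scores, labels), "threshold": t,
                "sensitivity": sens, "specificity": spec, "n": len(dataset)}

    def summary(self) -> str:
        r = self.report
        cfg = self.model.config
        lines = [
            "Dual-Stream Suicide Risk Model Results",
            "=" * 54,
            f"{'No. observations:':<28}{len(self.model.dataset):>10d}",
            f"{'Vocabulary size:':<28}{self.network.vocab_size:>10d}",
            f"{'Static dimension:':<28}{self.network.static_dim:>10d}",
            f"{'Parameters:':<28}{r.n_parameters:>10d}",
            f"{'Encoder blocks / heads:':<28}{cfg.n_encoder_blocks:>6d} /{cfg.n_heads:>3d}",
            f"{'Embedding dim:':<28}{cfg.embed_dim:>10d}",
            f"{'Epochs run (best):':<28}{len(r.epoch_loss):>6d} ({r.best_epoch})",
            "-" * 54,
            f"{'Train AUC:':<28}{r.train_auc:>10.4f}",
            f"{'Validation AUC:':<28}{r.val_auc:>10.4f}",
            f"{'Operating threshold:':<28}{r.threshold:>10.4f}",
            f"{'Sensitivity:':<28}{r.sensitivity:>10.4f}",
            f"{'Specificity:':<28}{r.specificity:>10.4f}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.network.state())
        meta = {"config": asdict(self.model.config), "report": asdict(self.report),
                "vocab_size": self.network.vocab_size,
                "static_dim": self.network.static_dim,
                "n_periods": self.network.n_periods}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory, dataset: EncodedDataset) -> "RiskModelResults":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        config = ModelConfig(**meta["config"])
        model = SuicideRiskModel.__new__(SuicideRiskModel)
        model.dataset = dataset
        model.config = config
        net = _RiskNetwork(config, meta["vocab_size"], meta["static_dim"], meta["n_periods"])
        with np.load(directory / "weights.npz") as z:
            net.load_state({k: z[k] for k in z.files})
        model.network = net
        report = TrainReport(**meta["report"])
        return cls(model=model, network=net, report=report)
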