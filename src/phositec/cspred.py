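"""Bimodal classifier for critical phosphorylation sites (CSPred).

A critical phos-site is one whose phosphorylation enhances the host kinase's
catalytic activity.  The classifier fuses two views of a site: a sequence
embedding of the flanking region (dimension 1024 by convention, from a
protein language model or a surrogate) and an MS embedding from the
phospho-MS embedder (dimension d, default 128).  Sites with both views use
the plain concatenation (D = 1024 + d); sites without an MS embedding are
aligned to D by a learned linear layer trained jointly with the classifier.

The classifier is a 4-layer MLP whose first three layers halve the width
successively from D, with LayerNorm + ReLU + Dropout in between, trained
with a weighted binary cross-entropy in which sites outside the kinase
activation loop (A-loop) receive weight ``w_out`` >= 1.  Training follows a
3-round under-sampling protocol: positives are constant across rounds and
each round draws fresh negatives without replacement at a 10:1 ratio,
followed by a stratified 8:2 train/test split and 5-fold cross-validation on
the training portion with early stopping on fold-validation AUROC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .msio import PhosSiteID

__all__ = [
    "LabeledSite",
    "ClassifierConfig",
    "TrainingProtocol",
    "CSPredModel",
    "fuse_embeddings",
    "assign_loss_weights",
    "weighted_bce",
    "undersample_rounds",
    "fit_classifier",
    "train_cspred",
    "compute_metrics",
    "select_high_confidence",
]


@dataclass
class LabeledSite:
    site: PhosSiteID
    label: int
    in_aloop: bool = False
    weight: float = 1.0


@dataclass
class ClassifierConfig:
    seq_dim: int = 1024
    ms_dim: int = 128
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 5
    threshold: float = 0.5

    @property
    def fused_dim(self) -> int:
        return self.seq_dim + self.ms_dim

    @property
    def widths(self) -> list[int]:
        d = self.fused_dim
        return [d, d // 2, d // 4, d // 8, 1]


@dataclass
class TrainingProtocol:
    rounds: int = 3
    neg_pos_ratio: int = 10
    test_frac: float = 0.2  # 8:2 train/test
    cv_folds: int = 5
    w_out: float = 4.0  # weight for out-of-A-loop sites; 1 disables weighting
    seed: int = 0


class CSPredModel(nn.Module):
    """Alignment layer (sequence-only path) + 4-layer halving MLP classifier."""

    def __init__(self, cfg: ClassifierConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.align = nn.Linear(cfg.seq_dim, cfg.fused_dim, rng)
        self.mlp = nn.MLP(cfg.widths, rng, dropout=cfg.dropout)

    def fuse(self, seq_emb: nn.Tensor, ms_emb: nn.Tensor, has_ms: np.ndarray) -> nn.Tensor:
        """Row-wise fusion: concat when the MS view exists, aligned sequence otherwise."""
        both = nn.concat([seq_emb, ms_emb], axis=-1)
        only = self.align(seq_emb)
        ind = nn.Tensor(has_ms.astype(float)[:, None])
        return both * ind + only * (1.0 - ind)

    def forward(self, seq_emb, ms_emb, has_ms: np.ndarray) -> nn.Tensor:
        seq_emb = nn.Tensor._lift(seq_emb)
        ms_emb = nn.Tensor._lift(ms_emb)
        return self.mlp(self.fuse(seq_emb, ms_emb, has_ms)).reshape(-1)

    def predict_proba(self, seq_emb: np.ndarray, ms_emb: np.ndarray, has_ms: np.ndarray) -> np.ndarray:
        self.mlp.training = False
        with nn.set_grad_enabled(False):
            logits = self(seq_emb, ms_emb, has_ms)
            probs = nn.sigmoid(logits)
        self.mlp.training = True
        return probs.data


def fuse_embeddings(
    seq_emb: np.ndarray,
    ms_emb: np.ndarray | None,
    align_layer: nn.Linear,
    ms_dim: int | None = None,
) -> np.ndarray:
    """Fuse one site's embeddings: concatenation, or the aligned sequence embedding.

    Both paths return a vector of dimension D = seq_dim + ms_dim.
    """
    seq_emb = np.asarray(seq_emb, dtype=float)
    in_dim, out_dim = align_layer.weight.shape
    if seq_emb.shape != (in_dim,):
        raise ValueError(f"sequence embedding must have dimension {in_dim}")
    if ms_emb is None:
        with nn.set_grad_enabled(False):
            out = align_layer(nn.Tensor(seq_emb[None, :])).data[0]
        if out.shape[0] != out_dim:
            raise AssertionError
        return out
    ms_emb = np.asarray(ms_emb, dtype=float)
    if ms_dim is not None and ms_emb.shape != (ms_dim,):
        raise ValueError(f"MS embedding must have dimension {ms_dim}")
    if in_dim + ms_emb.shape[0] != out_dim:
        raise ValueError("align layer output dimension must equal seq_dim + ms_dim")
    return np.concatenate([seq_emb, ms_emb])


def assign_loss_weights(sites: Sequence[LabeledSite], w_out: float) -> list[LabeledSite]:
    """w_i = w_out for out-of-A-loop sites, 1 inside the A-loop."""
    if w_out < 1:
        raise ValueError("w_out must be >= 1")
    for s in sites:
        s.weight = 1.0 if s.in_aloop else float(w_out)
    return list(sites)


def weighted_bce(logits, labels, weights=None) -> float:
    """-(1/N) sum_i w_i [y_i log sigma(x_i) + (1 - y_i) log(1 - sigma(x_i))]."""
    x = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("logits, labels and weights must have equal shapes")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite logits")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    # numerically stable: log(1+exp(-|x|)) + max(x,0) - x*y
    per = w * (np.maximum(x, 0.0) - x * y + np.log1p(np.exp(-np.abs(x))))
    return float(per.mean())


def _bce_loss_tensor(logits: nn.Tensor, y: np.ndarray, w: np.ndarray) -> nn.Tensor:
    """Differentiable weighted BCE-with-logits (same formula as weighted_bce)."""
    x = logits
    maxed = nn.relu(x)
    absx = nn.relu(x) + nn.relu(-x)
    softplus = (1.0 + (-absx).exp()).log()
    per = (maxed - x * nn.Tensor(y) + softplus) * nn.Tensor(w)
    return per.mean()


def undersample_rounds(
    positives: Sequence,
    negative_pool: Sequence,
    ratio: int,
    rounds: int,
    rng: np.random.Generator,
) -> list[tuple[list, list]]:
    """Per-round (positives, negatives): positives constant, negatives disjoint.

    The pool is shuffled once and consumed sequentially; when it runs short the
    later rounds take the remainder (possibly empty) with a warning.
    """
    positives = list(positives)
    if not positives:
        raise ValueError("empty positive set")
    pool = list(negative_pool)
    perm = rng.permutation(len(pool))
    need = ratio * len(positives)
    out = []
    cursor = 0
    for r in range(rounds):
        take = perm[cursor : cursor + need]
        cursor += need
        if len(take) < need:
            warnings.warn(
                f"round {r + 1}: negative pool short ({len(take)}/{need})", stacklevel=2
            )
        out.append((positives, [pool[i] for i in take]))
    return out


def fit_classifier(
    model: CSPredModel,
    X_seq: np.ndarray,
    X_ms: np.ndarray,
    has_ms: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    val: tuple | None = None,
    seed: int = 0,
) -> float:
    """Adam training with early stopping on validation AUROC; returns best val AUROC.

    ``val`` is (X_seq, X_ms, has_ms, y); when omitted, training runs for
    ``max_epochs`` and the final weights are kept.
    """
    cfg = model.cfg
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    n = len(y)
    best_auc, best_state, stale = -np.inf, None, 0
    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            b = perm[start : start + cfg.batch_size]
            logits = model(X_seq[b], X_ms[b], has_ms[b])
            if not np.all(np.isfinite(logits.data)):
                raise FloatingPointError("non-finite logits during training")
            loss = _bce_loss_tensor(logits, y[b].astype(float), w[b])
            opt.zero_grad()
            loss.backward()
            opt.step()
        if val is not None:
            vs = model.predict_proba(val[0], val[1], val[2])
            auc = roc_auc_score(val[3], vs)
            if auc > best_auc:
                best_auc, best_state, stale = auc, model.state_dict(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return float(best_auc) if val is not None else float("nan")


def _stratified_split(y: np.ndarray, test_frac: float, seed: int) -> tuple:
    idx = np.arange(len(y))
    for attempt in range(5):
        tr, te = train_test_split(
            idx, test_size=test_frac, stratify=y, random_state=seed + attempt
        )
        if len(set(y[tr])) == 2 and len(set(y[te])) == 2:
            return tr, te
    raise ValueError("could not produce a two-class split in 5 attempts")


def train_cspred(
    X_seq: np.ndarray,
    X_ms: np.ndarray,
    has_ms: np.ndarray,
    sites: Sequence[LabeledSite],
    protocol: TrainingProtocol | None = None,
    cfg: ClassifierConfig | None = None,
) -> dict:
    """3-round under-sampling training; returns per-round models and metrics.

    Rows of ``X_seq``/``X_ms`` align with ``sites``.  Each round: fresh
    negatives, stratified 8:2 split, 5-fold CV on the training portion with
    early stopping on fold-validation AUROC; the fold model with the best
    validation AUROC is evaluated on the held-out test portion.
    """
    protocol = protocol or TrainingProtocol()
    cfg = cfg or ClassifierConfig()
    sites = list(sites)
    assign_loss_weights(sites, protocol.w_out)
    y_all = np.array([s.label for s in sites])
    w_all = np.array([s.weight for s in sites])
    pos_idx = np.flatnonzero(y_all == 1)
    neg_idx = np.flatnonzero(y_all == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(protocol.seed)
    rounds = undersample_rounds(
        pos_idx.tolist(), neg_idx.tolist(), protocol.neg_pos_ratio, protocol.rounds, rng
    )

    results: dict = {"rounds": [], "models": []}
    for r, (pos, neg) in enumerate(rounds):
        idx = np.array(pos + neg)
        y = y_all[idx]
        tr, te = _stratified_split(y, protocol.test_frac, protocol.seed * 101 + r)
        skf = StratifiedKFold(
            n_splits=protocol.cv_folds, shuffle=True, random_state=protocol.seed + r
        )
        best = (-np.inf, None)
        for f, (fit_i, val_i) in enumerate(skf.split(tr, y[tr])):
            fit_idx, val_idx = idx[tr[fit_i]], idx[tr[val_i]]
            model = CSPredModel(cfg, seed=protocol.seed * 1000 + r * 10 + f)
            auc = fit_classifier(
                model,
                X_seq[fit_idx], X_ms[fit_idx], has_ms[fit_idx],
                y_all[fit_idx], w_all[fit_idx],
                val=(X_seq[val_idx], X_ms[val_idx], has_ms[val_idx], y_all[val_idx]),
                seed=protocol.seed * 7 + r,
            )
            if auc > best[0]:
                best = (auc, model)
        model = best[1]
        te_idx = idx[te]
        scores = model.predict_proba(X_seq[te_idx], X_ms[te_idx], has_ms[te_idx])
        metrics = compute_metrics(y_all[te_idx], scores, threshold=cfg.threshold)
        metrics["val_auroc"] = best[0]
        results["rounds"].append(metrics)
        results["models"].append(model)

    for key in ("auroc", "auprc", "f1", "mcc"):
        vals = [r[key] for r in results["rounds"]]
        results[f"{key}_mean"] = float(np.mean(vals))
        results[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    best_round = int(np.argmax([r["auroc"] for r in results["rounds"]]))
    results["best_model"] = results["models"][best_round]
    return results


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """AUROC (tie-aware concordance), step-wise AUPRC, and F1/MCC at a threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("AUROC/AUPRC need both classes present")
    pred = (s >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(y, s)),
        "auprc": float(average_precision_score(y, s)),
        "f1": float(f1_score(y, pred, zero_division=0)),
        "mcc": float(matthews_corrcoef(y, pred)),
    }


def select_high_confidence(scores: dict, frac: float = 0.05) -> list:
    """Top ceil(frac * n) sites by descending score; ties break by site-ID order."""
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    items = list(scores.items())
    if not items:
        return []
    k = math.ceil(frac * len(items))
    items.sort(key=lambda kv: (-kv[1], str(kv[0])))
    return [site for site, _ in items[:k]]
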