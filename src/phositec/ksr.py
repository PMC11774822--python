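"""Kinase-substrate relation (KSR) prediction from phos-site embeddings.

A kinase is represented by the componentwise max over the embeddings of its
own phos-sites; a candidate relation is the concatenation of that pooled
kinase embedding with the substrate-site embedding, classified by a
two-linear-layer MLP (LayerNorm + ReLU + Dropout in between).  Negative
pairs are drawn uniformly from the kinase x substrate-site cross product
after excluding known pairs, pairs any external predictor scores above 0.7
(strict), and kinase self-pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from . import nn
from .cspred import compute_metrics
from .msio import PhosSiteID

__all__ = [
    "KSPair",
    "KSRConfig",
    "build_negative_pairs",
    "pool_kinase_embedding",
    "train_predict_ksr",
    "write_gmt",
]

SCORE_EXCLUSION_THRESHOLD = 0.7


@dataclass(frozen=True)
class KSPair:
    kinase: str
    substrate: PhosSiteID
    label: int  # 1 = known relation, 0 = sampled negative


def build_negative_pairs(
    kinases: Sequence[str],
    substrate_sites: Sequence[PhosSiteID],
    known_pairs: Sequence[KSPair],
    predicted_scores: Mapping | None,
    ratio: int,
    rng: np.random.Generator,
) -> list[KSPair]:
    """Uniform random negatives excluding known and high-scoring predicted pairs.

    ``predicted_scores`` maps (kinase, substrate) to an external prediction
    score; pairs scoring strictly above 0.7 are never sampled.  Count is
    ``ratio * len(known_pairs)``; self-pairs (substrate on the kinase itself)
    are excluded.
    """
    predicted_scores = predicted_scores or {}
    known = {(p.kinase, p.substrate) for p in known_pairs}
    eligible = [
        (k, s)
        for k in kinases
        for s in substrate_sites
        if (k, s) not in known
        and s.protein_accession != k
        and predicted_scores.get((k, s), 0.0) <= SCORE_EXCLUSION_THRESHOLD
    ]
    need = ratio * len(known_pairs)
    if len(eligible) < need:
        raise ValueError(
            f"only {len(eligible)} eligible negative pairs for a request of {need}"
        )
    take = rng.choice(len(eligible), size=need, replace=False)
    return [KSPair(*eligible[i], label=0) for i in sorted(take)]


def pool_kinase_embedding(site_embeddings: Sequence[np.ndarray]) -> np.ndarray:
    """Componentwise maximum over the kinase's own phos-site embeddings."""
    if len(site_embeddings) == 0:
        raise ValueError("kinase unobserved: no site embeddings to pool")
    return np.max(np.stack([np.asarray(e, float) for e in site_embeddings]), axis=0)


@dataclass
class KSRConfig:
    hidden: int = 256
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    threshold: float = 0.5
    seed: int = 0


class KSRModel(nn.Module):
    """Linear -> LayerNorm -> ReLU -> Dropout -> Linear -> single logit."""

    def __init__(self, in_dim: int, cfg: KSRConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(in_dim, cfg.hidden, rng)
        self.norm = nn.LayerNorm(cfg.hidden)
        self.drop = nn.Dropout(cfg.dropout, rng)
        self.fc2 = nn.Linear(cfg.hidden, 1, rng)

    def forward(self, x) -> nn.Tensor:
        x = nn.Tensor._lift(x)
        return self.fc2(self.drop(nn.relu(self.norm(self.fc1(x))))).reshape(-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.drop.training = False
        with nn.set_grad_enabled(False):
            probs = nn.sigmoid(self(x))
        self.drop.training = True
        return probs.data


def _pair_features(
    pairs: Sequence[KSPair],
    kinase_site_map: Mapping,
    site_embeddings: Mapping,
) -> np.ndarray:
    pooled = {
        k: pool_kinase_embedding([site_embeddings[s] for s in sites if s in site_embeddings])
        for k, sites in kinase_site_map.items()
    }
    return np.stack(
        [np.concatenate([pooled[p.kinase], site_embeddings[p.substrate]]) for p in pairs]
    )


def train_predict_ksr(
    pairs: Sequence[KSPair],
    kinase_site_map: Mapping,
    site_embeddings: Mapping,
    cfg: KSRConfig | None = None,
) -> dict:
    """Train on a 7:2:1 split with early stopping on validation AUROC.

    ``kinase_site_map`` maps each kinase accession to the phos-sites used for
    pooling its embedding; ``site_embeddings`` maps PhosSiteID to a vector.
    Returns the model plus AUROC/AUPRC/F1/MCC on the test portion.
    """
    cfg = cfg or KSRConfig()
    pairs = list(pairs)
    y = np.array([p.label for p in pairs])
    if len(set(y.tolist())) < 2:
        raise ValueError("both labels required")
    X = _pair_features(pairs, kinase_site_map, site_embeddings)
    idx = np.arange(len(pairs))
    tr, rest = train_test_split(idx, test_size=0.3, stratify=y, random_state=cfg.seed)
    va, te = train_test_split(rest, test_size=1 / 3, stratify=y[rest], random_state=cfg.seed)

    model = KSRModel(X.shape[1], cfg, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    from .cspred import _bce_loss_tensor

    best_auc, best_state, stale = -np.inf, None, 0
    w = np.ones(len(y))
    for _epoch in range(cfg.max_epochs):
        perm = rng.permutation(tr)
        for start in range(0, perm.size, cfg.batch_size):
            b = perm[start : start + cfg.batch_size]
            loss = _bce_loss_tensor(model(X[b]), y[b].astype(float), w[b])
            opt.zero_grad()
            loss.backward()
            opt.step()
        auc = roc_auc_score(y[va], model.predict_proba(X[va]))
        if auc > best_auc:
            best_auc, best_state, stale = auc, model.state_dict(), 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state_dict(best_state)
    scores = model.predict_proba(X[te])
    metrics = compute_metrics(y[te], scores, threshold=cfg.threshold)
    metrics["val_auroc"] = float(best_auc)
    return {"model": model, "metrics": metrics, "test_idx": te, "test_scores": scores}


def write_gmt(kinase_substrate_map: Mapping, path) -> None:
    """Export kinase -> substrate-site sets as a GMT gene-set file."""
    with open(path, "w") as fh:
        for kinase in sorted(kinase_substrate_map):
            members = sorted(str(s) for s in kinase_substrate_map[kinase])
            fh.write("\t".join([kinase, f"substrates of {kinase}", *members]) + "\n")
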