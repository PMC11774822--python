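"""Masked-autoencoding embedder for sparse phospho-MS matrices.

Each phos-site is a "sentence" whose tokens are the site's normalized values
across samples; sample identity plays the role of position.  Training hides
an equal number of nonzero and zero cells per site (equal counts, not equal
proportions — zeros dominate the matrix and proportional masking would let a
constant-zero predictor look good) and reconstructs them:

* embedding: a value embedding from an autodiscretization gate (soft mixture
  over learned anchor vectors) plus a learned per-sample identity embedding;
* encoder: multi-head attention over the observed (unmasked, nonzero) tokens
  only — realized by excluding all other positions as attention keys, which
  is exactly equivalent to compacting the sequence and padding;
* extension: the full-length token sequence is reassembled with the encoder
  output at observed positions, a learned mask embedding at masked positions
  and a learned zero embedding at unmasked-zero positions, then mapped by a
  position-wise linear layer;
* decoder: attention over all positions (exact softmax, or Performer-style
  positive-random-feature linear attention for long sample axes), followed by
  a linear projection to one reconstructed value per sample.

The loss is mean squared error at masked positions only.  Per-site embeddings
are the componentwise max over the encoder's contextual sample embeddings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .msio import NormalizedPhosMatrix, PhosSiteID

__all__ = [
    "MaskPlan",
    "ModelConfig",
    "PretrainConfig",
    "ReconstructionReport",
    "PhoSiteformer",
    "make_mask",
    "masked_mse",
    "pretrain",
    "extract_site_embeddings",
    "column_mean_baseline_mse",
]


@dataclass(frozen=True)
class MaskPlan:
    """Masked sample indices for one site row; equal nonzero and zero counts."""

    nonzero_masked: tuple
    zero_masked: tuple

    def __post_init__(self) -> None:
        if len(self.nonzero_masked) != len(self.zero_masked):
            raise ValueError("masked nonzero and zero counts must be equal")
        if set(self.nonzero_masked) & set(self.zero_masked):
            raise ValueError("masked sets must be disjoint")

    @property
    def all_masked(self) -> tuple:
        return self.nonzero_masked + self.zero_masked

    def indicator(self, n_samples: int) -> np.ndarray:
        out = np.zeros(n_samples, dtype=bool)
        out[list(self.all_masked)] = True
        return out


def make_mask(row: np.ndarray, mask_fraction: float, rng: np.random.Generator) -> MaskPlan:
    """Mask ``round(mask_fraction * #nonzero)`` nonzero cells and as many zero cells.

    The count is capped at min(#nonzero, #zero) so the equal-count rule always
    holds exactly.
    """
    row = np.asarray(row, dtype=float)
    nonzero = np.flatnonzero(row > 0)
    zero = np.flatnonzero(row == 0)
    if nonzero.size == 0:
        raise ValueError("all-zero row cannot be masked (should have been filtered)")
    n = int(round(mask_fraction * nonzero.size))
    n = min(n, nonzero.size, zero.size)
    if n == 0:
        return MaskPlan((), ())
    nz = rng.choice(nonzero, size=n, replace=False)
    zz = rng.choice(zero, size=n, replace=False)
    return MaskPlan(tuple(int(i) for i in nz), tuple(int(i) for i in zz))


@dataclass
class ModelConfig:
    d_model: int = 128
    n_heads: int = 4
    encoder_layers: int = 2
    decoder_layers: int = 2
    decoder_backend: str = "exact"  # or "performer"
    n_random_features: int = 128
    ffn_mult: int = 2
    dropout: float = 0.0
    autodis_anchors: int = 100
    autodis_hidden: int = 16

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass
class PretrainConfig:
    mask_fraction: float = 0.15
    batch_size: int = 32
    lr: float = 1e-3
    max_epochs: int = 20
    val_frac: float = 0.25  # site-wise 75:25 train/validation split
    patience: int = 5
    accuracy_tau: float = 0.1
    seed: int = 0


@dataclass
class ReconstructionReport:
    """Per-epoch masked-reconstruction quality; epoch 0 is the untrained model."""

    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    val_correlation: list = field(default_factory=list)
    best_epoch: int = 0
    val_site_idx: np.ndarray | None = None  # validation rows (for baselines)
    val_masked: np.ndarray | None = None  # their fixed validation masks


class AutoDisEmbedder(nn.Module):
    """Scalar value -> softmax gate over B learned anchor embeddings -> weighted sum."""

    def __init__(self, n_anchors: int, hidden: int, d_model: int, rng: np.random.Generator):
        self.w1 = nn.Parameter(rng.normal(0.0, 1.0, size=(1, hidden)))
        self.b1 = nn.Parameter(np.zeros(hidden))
        self.w2 = nn.Parameter(rng.normal(0.0, 1.0 / math.sqrt(hidden), size=(hidden, n_anchors)))
        self.b2 = nn.Parameter(np.zeros(n_anchors))
        self.anchors = nn.Parameter(rng.normal(0.0, 0.02, size=(n_anchors, d_model)))

    def forward(self, values: nn.Tensor) -> nn.Tensor:
        """values (..., 1) -> embeddings (..., d_model)."""
        h = nn.relu(values @ self.w1 + self.b1)
        weights = nn.softmax(h @ self.w2 + self.b2, axis=-1)
        return weights @ self.anchors

    def gate_weights(self, value: float) -> np.ndarray:
        with nn.set_grad_enabled(False):
            h = nn.relu(nn.Tensor([[value]]) @ self.w1 + self.b1)
            w = nn.softmax(h @ self.w2 + self.b2, axis=-1)
        return w.data[0]


def autodis_embed(value: float, emb: AutoDisEmbedder) -> np.ndarray:
    """Embedding of a single scalar value (deterministic given parameters)."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    with nn.set_grad_enabled(False):
        out = emb(nn.Tensor([[value]]))
    return out.data[0]


class PhoSiteformer(nn.Module):
    def __init__(self, n_samples: int, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_samples = n_samples
        d = cfg.d_model
        self.autodis = AutoDisEmbedder(cfg.autodis_anchors, cfg.autodis_hidden, d, rng)
        self.sample_table = nn.Parameter(rng.normal(0.0, 0.02, size=(n_samples, d)))
        self.mask_emb = nn.Parameter(rng.normal(0.0, 0.02, size=(d,)))
        self.zero_emb = nn.Parameter(rng.normal(0.0, 0.02, size=(d,)))
        self.encoder = [
            nn.TransformerBlock(d, cfg.n_heads, rng, cfg.ffn_mult, cfg.dropout)
            for _ in range(cfg.encoder_layers)
        ]
        self.bridge = nn.Linear(d, d, rng)
        self.decoder = [
            nn.TransformerBlock(
                d, cfg.n_heads, rng, cfg.ffn_mult, cfg.dropout,
                backend=cfg.decoder_backend, n_features=cfg.n_random_features,
            )
            for _ in range(cfg.decoder_layers)
        ]
        self.head = nn.Linear(d, 1, rng)
        self._drop_rng = rng

    def save(self, path) -> None:
        """Single-file checkpoint (NPZ) with the model config embedded."""
        import json

        from dataclasses import asdict

        np.savez(
            path,
            _config=np.frombuffer(
                json.dumps({"n_samples": self.n_samples, **asdict(self.cfg)}).encode(),
                dtype=np.uint8,
            ),
            **{f"p{i}": p.data for i, p in enumerate(self.parameters())},
        )

    @classmethod
    def load(cls, path) -> "PhoSiteformer":
        import json

        with np.load(path) as archive:
            meta = json.loads(bytes(archive["_config"].tobytes()).decode())
            n_samples = meta.pop("n_samples")
            model = cls(n_samples, ModelConfig(**meta))
            model.load_state_dict(
                [archive[f"p{i}"] for i in range(len(model.parameters()))]
            )
        return model

    # -- forward pieces ----------------------------------------------------
    def encode(self, values: np.ndarray, observed: np.ndarray) -> nn.Tensor:
        """Contextual embeddings (B, L, d) for observed tokens.

        ``observed`` marks unmasked nonzero tokens; everything else is
        excluded as attention keys, and values at non-observed positions are
        zeroed out before embedding so they cannot influence any output.
        """
        safe_values = np.where(observed, values, 0.0)
        v = nn.Tensor(safe_values[..., None])
        e = self.autodis(v)
        # sample-identity embeddings: same table for every site row
        s = self.sample_table.reshape(1, self.n_samples, self.cfg.d_model)
        x = e + s
        for block in self.encoder:
            x = block(x, key_mask=observed)
        return x

    def forward(
        self, values: np.ndarray, masked: np.ndarray, zero_mask: np.ndarray
    ) -> nn.Tensor:
        """Reconstruct all sample values for a batch of site rows.

        values (B, L) float; masked (B, L) bool; zero_mask (B, L) bool (cells
        that are zero in the *unmasked* matrix, i.e. originally missing).
        """
        observed = (~masked) & (~zero_mask)
        enc = self.encode(values, observed)
        obs = nn.Tensor(observed[..., None].astype(float))
        msk = nn.Tensor(masked[..., None].astype(float))
        zro = nn.Tensor((zero_mask & ~masked)[..., None].astype(float))
        assembled = enc * obs + self.mask_emb * msk + self.zero_emb * zro
        x = self.bridge(assembled)
        for block in self.decoder:
            x = block(x)
        pred = self.head(x)
        return pred.reshape(values.shape[0], values.shape[1])


def masked_mse(pred: np.ndarray, true: np.ndarray, masked: np.ndarray) -> float:
    """Mean squared error over masked positions only."""
    pred, true, masked = np.asarray(pred), np.asarray(true), np.asarray(masked, bool)
    if pred.shape != true.shape or pred.shape != masked.shape:
        raise ValueError("shape mismatch")
    if not masked.any():
        raise ValueError("empty mask")
    diff = pred[masked] - true[masked]
    return float(np.mean(diff**2))


def _batch_plans(
    values: np.ndarray, zero_mask: np.ndarray, frac: float, rng: np.random.Generator
) -> list[MaskPlan]:
    return [make_mask(row, frac, rng) for row in values]


def _plan_matrix(plans: Sequence[MaskPlan], n_samples: int) -> np.ndarray:
    return np.stack([p.indicator(n_samples) for p in plans])


def _eval_masked(
    model: PhoSiteformer,
    values: np.ndarray,
    zero_mask: np.ndarray,
    masked: np.ndarray,
    tau: float,
) -> tuple[float, float, float]:
    with nn.set_grad_enabled(False):
        pred = model(values, masked, zero_mask).data
    mse = masked_mse(pred, values, masked)
    err = np.abs(pred[masked] - values[masked])
    acc = float((err < tau).mean())
    p, t = pred[masked], values[masked]
    if p.size > 1 and p.std() > 0 and t.std() > 0:
        corr = float(np.corrcoef(p, t)[0, 1])
    else:
        corr = 0.0
    return mse, acc, corr


def pretrain(
    matrix: NormalizedPhosMatrix,
    mcfg: ModelConfig | None = None,
    pcfg: PretrainConfig | None = None,
) -> tuple[PhoSiteformer, ReconstructionReport]:
    """Pretrain on a normalized matrix with a site-wise 75:25 train/validation split.

    Fresh masks are drawn for the training sites every epoch; validation masks
    are drawn once so epochs are comparable.  Deterministic given the seed.
    """
    mcfg = mcfg or ModelConfig()
    pcfg = pcfg or PretrainConfig()
    if pcfg.mask_fraction <= 0:
        raise ValueError("mask_fraction must be positive (no training signal otherwise)")
    values = matrix.values
    zero_mask = matrix.zero_mask
    n_sites, n_samples = values.shape
    if n_sites < 2:
        raise ValueError("need >= 2 sites to split")
    rng = np.random.default_rng(pcfg.seed)
    order = rng.permutation(n_sites)
    n_val = max(1, int(round(pcfg.val_frac * n_sites)))
    val_idx, train_idx = order[:n_val], order[n_val:]

    model = PhoSiteformer(n_samples, mcfg, seed=pcfg.seed)
    opt = nn.Adam(model.parameters(), lr=pcfg.lr)
    report = ReconstructionReport()

    val_rng = np.random.default_rng(pcfg.seed + 1)
    val_masked = _plan_matrix(
        _batch_plans(values[val_idx], zero_mask[val_idx], pcfg.mask_fraction, val_rng),
        n_samples,
    )

    def val_metrics() -> tuple[float, float, float]:
        return _eval_masked(
            model, values[val_idx], zero_mask[val_idx], val_masked, pcfg.accuracy_tau
        )

    report.val_site_idx = val_idx
    report.val_masked = val_masked

    mse0, acc0, corr0 = val_metrics()
    report.val_mse.append(mse0)
    report.val_accuracy.append(acc0)
    report.val_correlation.append(corr0)
    report.train_mse.append(float("nan"))

    best = (mse0, model.state_dict(), 0)
    stale = 0
    for epoch in range(1, pcfg.max_epochs + 1):
        perm = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, perm.size, pcfg.batch_size):
            batch = perm[start : start + pcfg.batch_size]
            vb, zb = values[batch], zero_mask[batch]
            masked = _plan_matrix(
                _batch_plans(vb, zb, pcfg.mask_fraction, rng), n_samples
            )
            if not masked.any():
                continue
            pred = model(vb, masked, zb)
            ind = nn.Tensor(masked.astype(float))
            diff = (pred - nn.Tensor(vb)) * ind
            loss = (diff * diff).sum() * (1.0 / masked.sum())
            if not np.isfinite(loss.data):
                raise FloatingPointError("training diverged (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        vm, va, vc = val_metrics()
        report.train_mse.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        report.val_mse.append(vm)
        report.val_accuracy.append(va)
        report.val_correlation.append(vc)
        if vm < best[0]:
            best = (vm, model.state_dict(), epoch)
            stale = 0
        else:
            stale += 1
            if stale >= pcfg.patience:
                break
    model.load_state_dict(best[1])
    report.best_epoch = best[2]
    return model, report


def extract_site_embeddings(
    model: PhoSiteformer,
    matrix: NormalizedPhosMatrix,
    site_ids: Sequence[PhosSiteID] | None = None,
) -> dict:
    """Componentwise max over encoder contextual embeddings of nonzero tokens.

    Sites with no nonzero values are omitted (no MS embedding; such sites fall
    back to sequence-only fusion downstream).
    """
    site_ids = list(site_ids) if site_ids is not None else list(matrix.sites)
    index = matrix.site_index()
    out: dict = {}
    for site in site_ids:
        if site not in index:
            raise KeyError(f"site {site} not in matrix")
        row = matrix.values[index[site]][None, :]
        observed = row > 0
        if not observed.any():
            continue
        with nn.set_grad_enabled(False):
            ctx = model.encode(row, observed).data[0]
        out[site] = ctx[observed[0]].max(axis=0)
    return out


def column_mean_baseline_mse(
    matrix: NormalizedPhosMatrix,
    site_idx: np.ndarray,
    masked: np.ndarray,
) -> float:
    """Masked MSE of predicting each masked cell by its sample's observed column mean.

    The column mean is computed over unmasked cells of the evaluation rows,
    matching the information available to the model.
    """
    values = matrix.values[site_idx]
    avail = ~masked
    col_sum = (values * avail).sum(axis=0)
    col_n = avail.sum(axis=0)
    col_mean = np.divide(col_sum, np.maximum(col_n, 1))
    pred = np.broadcast_to(col_mean, values.shape)
    return masked_mse(pred, values, masked)
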