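"""Kinase-activity readout from substrate phosphorylation, plus survival-ready imputation.

For a kinase phos-site, samples are split into a phos-group (site level > 0)
and a non-phos-group (level == 0, i.e. not detected).  All sites are ranked
by the log2 fold change of their mean level between the two groups and the
kinase's substrate set is scored with the weighted Kolmogorov-Smirnov
enrichment statistic (GSEA-style running sum); the normalized enrichment
score (NES) scales the observed ES by the mean |ES| of same-sign
set-membership permutations.  A high NES for a site's substrates is the
matrix-level signature of the site enhancing kinase activity.

``downshift_impute`` provides the downshifted-Gaussian imputation
(mean mu0 + delta*sigma0, sd lambda*sigma0, defaults delta=-0.5,
lambda=0.5) applied to sites with fewer than 50% missing values before
survival modeling; the survival fit itself is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .msio import NormalizedPhosMatrix, PhosSiteID

__all__ = [
    "EnrichmentResult",
    "DownshiftConfig",
    "split_by_site_detection",
    "rank_by_foldchange",
    "enrichment_score",
    "normalized_enrichment",
    "downshift_impute",
    "bh_adjust",
]

FOLD_CHANGE_EPS = 1e-6


@dataclass
class EnrichmentResult:
    site: PhosSiteID | None
    es: float
    nes: float
    n_permutations: int
    defined: bool = True  # False when no same-sign permutation ES existed


@dataclass
class DownshiftConfig:
    delta: float = -0.5
    lam: float = 0.5
    max_missing_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def split_by_site_detection(
    matrix: NormalizedPhosMatrix, site: PhosSiteID
) -> tuple[list[str], list[str]]:
    """(phos-group, non-phos-group) sample IDs, split on site level > 0 vs == 0."""
    row = matrix.row(site)
    phos = [s for s, v in zip(matrix.samples, row) if v > 0]
    non = [s for s, v in zip(matrix.samples, row) if v == 0]
    return phos, non


def rank_by_foldchange(
    matrix: NormalizedPhosMatrix, groups: tuple[Sequence[str], Sequence[str]]
) -> list[tuple[PhosSiteID, float]]:
    """Sites ranked by log2((mean_phos + eps) / (mean_non + eps)), descending.

    Ties break by site-ID order for determinism.
    """
    phos, non = groups
    if not phos or not non:
        raise ValueError("both groups must be nonempty")
    col = {s: j for j, s in enumerate(matrix.samples)}
    pj = [col[s] for s in phos]
    nj = [col[s] for s in non]
    mp = matrix.values[:, pj].mean(axis=1)
    mn = matrix.values[:, nj].mean(axis=1)
    scores = np.log2((mp + FOLD_CHANGE_EPS) / (mn + FOLD_CHANGE_EPS))
    ranked = sorted(
        zip(matrix.sites, scores), key=lambda t: (-t[1], str(t[0]))
    )
    return [(s, float(v)) for s, v in ranked]


def enrichment_score(
    ranked: Sequence[tuple[PhosSiteID, float]],
    gene_set: set,
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment statistic of ``gene_set`` in a ranked, scored list.

    Hits advance the running sum by |score|^p normalized over hit scores;
    misses retreat by 1/(N - N_hits).  ES is the extremum of the walk.
    """
    sites = [s for s, _ in ranked]
    scores = np.array([v for _, v in ranked], dtype=float)
    hit = np.array([s in gene_set for s in sites], dtype=bool)
    n_hits = int(hit.sum())
    n = len(sites)
    if n_hits == 0:
        raise ValueError("gene set has empty intersection with the ranking")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranking (no misses)")
    hw = np.abs(scores) ** weight_p
    hit_total = hw[hit].sum()
    steps = np.where(hit, np.where(hit_total > 0, hw / max(hit_total, 1e-300), 0.0),
                     -1.0 / (n - n_hits))
    walk = np.cumsum(steps)
    es = walk[np.argmax(np.abs(walk))]
    return float(es), walk


def normalized_enrichment(
    ranked: Sequence[tuple[PhosSiteID, float]],
    gene_set: set,
    permutations: int = 1000,
    rng: np.random.Generator | None = None,
    weight_p: float = 1.0,
    site: PhosSiteID | None = None,
) -> EnrichmentResult:
    """NES = ES / mean(|ES_perm|) over same-sign set-membership permutations."""
    if permutations < 100:
        raise ValueError("use >= 100 permutations")
    rng = rng or np.random.default_rng(0)
    es, _ = enrichment_score(ranked, gene_set, weight_p)
    n_hits = len([s for s, _ in ranked if s in gene_set])
    all_sites = [s for s, _ in ranked]
    perm_es = np.empty(permutations)
    for i in range(permutations):
        take = rng.choice(len(all_sites), size=n_hits, replace=False)
        perm_set = {all_sites[j] for j in take}
        perm_es[i], _ = enrichment_score(ranked, perm_set, weight_p)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if same_sign.size == 0:
        return EnrichmentResult(site, es, float("nan"), permutations, defined=False)
    nes = es / np.abs(same_sign).mean()
    return EnrichmentResult(site, float(es), float(nes), permutations)


def downshift_impute(
    values: Sequence[float] | np.ndarray,
    cfg: DownshiftConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fill NaNs with draws from Normal(mu0 + delta*sigma0, (lambda*sigma0)^2).

    mu0 and sigma0 are the mean and sd of the observed values.  Sites with a
    missing fraction at or above ``max_missing_frac`` are rejected.
    """
    cfg = cfg or DownshiftConfig()
    rng = rng or np.random.default_rng(0)
    x = np.asarray(values, dtype=float).copy()
    missing = np.isnan(x)
    frac = missing.mean() if x.size else 1.0
    if frac >= cfg.max_missing_frac:
        raise ValueError(
            f"missing fraction {frac:.2f} >= {cfg.max_missing_frac:.2f}: site rejected"
        )
    obs = x[~missing]
    if obs.size < 2:
        raise ValueError("need >= 2 observed values")
    mu0 = obs.mean()
    sigma0 = obs.std(ddof=1)
    x[missing] = rng.normal(mu0 + cfg.delta * sigma0, cfg.lam * sigma0, size=missing.sum())
    return x


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (utility; no survival fitting here)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out
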