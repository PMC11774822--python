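"""Sequence features around phosphorylation sites.

Features are computed on the +/-7-residue window flanking a site (the window is
truncated, not padded, at protein termini): fractions of residues falling in
named physicochemical groups, and occurrence rates of k-mers from a sliding
window.  ``select_features`` implements the two-stage screen used to reduce a
candidate table to model inputs: a two-sided rank-sum test for ordinary
features, a frequency + log2-fold-change screen for 2-mers, then a greedy
correlation filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .msio import PhosSiteID

__all__ = [
    "FlankWindow",
    "AA_GROUPS",
    "FeatureSelectionConfig",
    "extract_flank",
    "group_composition",
    "kmer_rates",
    "feature_table",
    "select_features",
    "pca_select",
]

#: Named amino-acid groups; several groups overlap by design.
AA_GROUPS: Mapping[str, frozenset] = {
    "Asx": frozenset("DN"),
    "Glx": frozenset("EQ"),
    "Xle": frozenset("IL"),
    "Positively charged": frozenset("KRH"),
    "Negatively charged": frozenset("DE"),
    "Uncharged": frozenset("NCQSTY"),
    "Aromatic": frozenset("FWYH"),
    "Aliphatic": frozenset("VILM"),
    "Small": frozenset("PGAS"),
    "Hydrophilic": frozenset("STHNQEDKR"),
    "Hydrophobic": frozenset("VILFWYM"),
    "Polar": frozenset("RNDCQEHKSTY"),
    "Nonpolar": frozenset("AGILMFPWV"),
    "AHR": frozenset("ACQEHLKM"),  # common residues in alpha-helix motifs
    "BSR": frozenset("IFTWYV"),  # common residues in beta-sheet motifs
    "RTR": frozenset("NDGPS"),  # common residues in reverse-turn motifs
    "UFR": frozenset("GP"),  # residues promoting unfolded/distorted regions
}


@dataclass(frozen=True)
class FlankWindow:
    """A site-centered sequence window, truncated at protein termini.

    ``center_offset`` is the 1-based index of the phosphorylated residue
    within ``sequence_window``.
    """

    site: PhosSiteID | None
    sequence_window: str
    center_offset: int

    @property
    def effective_length(self) -> int:
        return len(self.sequence_window)

    @property
    def center_residue(self) -> str:
        return self.sequence_window[self.center_offset - 1]


def extract_flank(
    sequence: str, position: int, w: int, site: PhosSiteID | None = None
) -> FlankWindow:
    """Window ``sequence[position-w .. position+w]`` (1-based, inclusive, truncated)."""
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    lo = max(1, position - w)
    hi = min(len(sequence), position + w)
    return FlankWindow(site, sequence[lo - 1 : hi], position - lo + 1)


def group_composition(
    window: FlankWindow, scheme: Mapping[str, frozenset] = AA_GROUPS
) -> dict[str, float]:
    """Per group, the fraction of window residues (center included) in the group."""
    seq = window.sequence_window
    if not seq:
        raise ValueError("empty window")
    known = set().union(*scheme.values())
    unknown = sorted(set(seq) - known - set("ARNDCQEGHILKMFPSTWYV"))
    if unknown:
        warnings.warn(f"residues {unknown} belong to no group", stacklevel=2)
    n = len(seq)
    return {name: sum(c in members for c in seq) / n for name, members in scheme.items()}


def kmer_rates(window: FlankWindow, k: int) -> dict[str, float]:
    """Occurrence rate of each k-mer in a size-k sliding window; rates sum to 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = window.sequence_window
    n_windows = len(seq) - k + 1
    if n_windows <= 0:
        return {}
    counts: dict[str, int] = {}
    for i in range(n_windows):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return {kmer: c / n_windows for kmer, c in counts.items()}


def feature_table(
    windows: Sequence[FlankWindow],
    labels: Sequence[int] | None = None,
    k: int = 2,
    scheme: Mapping[str, frozenset] = AA_GROUPS,
) -> pd.DataFrame:
    """Assemble group-composition and k-mer features into one table (kmer_ prefix)."""
    rows = []
    for win in windows:
        feats = dict(group_composition(win, scheme))
        feats.update({f"kmer_{m}": r for m, r in kmer_rates(win, k).items()})
        rows.append(feats)
    df = pd.DataFrame(rows, index=[str(w.site) for w in windows]).fillna(0.0)
    if labels is not None:
        df.attrs["labels"] = np.asarray(labels, dtype=int)
    return df


@dataclass
class FeatureSelectionConfig:
    p_threshold: float = 0.05
    kmer_min_freq: float = 0.2
    kmer_min_log2fc: float = 1.5
    corr_threshold: float = 0.7
    kmer_prefix: str = "kmer_"


def _ranksum_p(pos: np.ndarray, neg: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small tie-free samples, else normal approx."""
    exact = len(pos) <= 8 and len(neg) <= 8 and len(np.unique(np.r_[pos, neg])) == len(
        pos
    ) + len(neg)
    method = "exact" if exact else "asymptotic"
    return float(
        stats.mannwhitneyu(pos, neg, alternative="two-sided", method=method).pvalue
    )


def select_features(
    table: pd.DataFrame,
    labels: Sequence[int] | None = None,
    config: FeatureSelectionConfig | None = None,
) -> list[str]:
    """Screen features against binary labels, then drop correlated ones greedily.

    Ordinary features pass with a two-sided rank-sum p below ``p_threshold``.
    2-mer features (columns with the k-mer prefix) pass when present in more
    than ``kmer_min_freq`` of positive windows with a positive/negative mean
    log2 fold change above ``kmer_min_log2fc`` (an all-zero negative mean counts
    as infinite fold change).  Survivors are ranked by significance and a later
    feature is dropped when |Pearson r| with an already-kept feature exceeds
    ``corr_threshold``.
    """
    config = config or FeatureSelectionConfig()
    if labels is None:
        labels = table.attrs.get("labels")
    if labels is None:
        raise ValueError("labels required for feature selection")
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != table.shape[0]:
        raise ValueError("labels length does not match table")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 samples per class")

    ranked: list[tuple[float, str]] = []  # (sort key, feature); lower = stronger
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        pos, neg = x[y == 1], x[y == 0]
        if np.ptp(x) == 0.0:
            warnings.warn(f"constant feature {name!r} excluded", stacklevel=2)
            continue
        if name.startswith(config.kmer_prefix):
            freq = float((pos > 0).mean())
            pos_mean, neg_mean = float(pos.mean()), float(neg.mean())
            if pos_mean <= 0:
                continue
            log2fc = math.inf if neg_mean == 0 else math.log2(pos_mean / neg_mean)
            if freq > config.kmer_min_freq and log2fc > config.kmer_min_log2fc:
                ranked.append((1.0 - min(log2fc, 1e6) * 1e-7, name))  # after p-ranked
        else:
            p = _ranksum_p(pos, neg)
            if p < config.p_threshold:
                ranked.append((p, name))

    ranked.sort(key=lambda t: (t[0], list(table.columns).index(t[1])))
    kept: list[str] = []
    for _, name in ranked:
        x = table[name].to_numpy(dtype=float)
        redundant = False
        for prev in kept:
            r = np.corrcoef(x, table[prev].to_numpy(dtype=float))[0, 1]
            if np.isfinite(r) and abs(r) > config.corr_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(name)
    return kept


def pca_select(
    matrix: np.ndarray | pd.DataFrame, var_frac: float = 0.95
) -> tuple[int, np.ndarray]:
    """Smallest k whose cumulative explained-variance ratio exceeds ``var_frac``.

    Returns ``(k, projection)`` where projection is the k-component PCA
    transform of the rows.
    """
    if not 0 < var_frac < 1:
        raise ValueError("var_frac must lie in (0, 1)")
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("matrix must be 2-D with >= 2 rows and columns")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("zero-variance matrix")
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, var_frac, side="right") + 1)
    k = min(k, proj.shape[1])
    return k, proj[:, :k]
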