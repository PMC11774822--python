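"""Reading, deduplication, filtering, imputation and normalization of phospho-MS matrices.

A phospho-MS intensity matrix is sites x samples, nonnegative, and heavily
missing: a site is only quantified in the samples where its phosphopeptide was
detected.  The preprocessing contract used throughout the package is

* duplicate samples collapse to the replicate with the fewest missing values,
* sites are kept when they sit on a kinase, are a (known or predicted)
  substrate site, or are detected in at least ``min_detect_frac`` of samples,
* missing cells are imputed as (global observed minimum - eps) and the whole
  matrix is min-max scaled to [0, 1], so that imputed cells land exactly on 0
  and the zero mask doubles as the missingness indicator downstream.

Scaling is global (whole matrix), not per sample or per site: only a global
scheme keeps "value == 0" equivalent to "originally missing".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhosSiteID",
    "PhosMatrix",
    "NormalizedPhosMatrix",
    "read_phos_matrix",
    "write_matrix",
    "read_normalized_matrix",
    "dedupe_samples",
    "filter_sites",
    "impute_and_normalize",
]

_RESIDUES = frozenset("STY")
_SITE_RE = re.compile(r"^(?P<acc>.+?)[:_](?P<res>[A-Za-z])(?P<pos>\d+)$")


@dataclass(frozen=True, order=True)
class PhosSiteID:
    """A phosphorylation site: protein accession + residue (S/T/Y) + 1-based position."""

    protein_accession: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in _RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.protein_accession}:{self.residue}{self.position}"

    @classmethod
    def parse(cls, text: str) -> "PhosSiteID":
        """Parse ``ACC:R<pos>`` (canonical) or ``ACC_R<pos>``."""
        m = _SITE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed phos-site ID: {text!r}")
        return cls(m.group("acc"), m.group("res").upper(), int(m.group("pos")))


@dataclass
class PhosMatrix:
    """Raw site x sample intensity matrix; missing cells are NaN."""

    sites: list[PhosSiteID]
    samples: list[str]
    values: np.ndarray  # float, shape (n_sites, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValueError("values shape does not match sites x samples")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site IDs in matrix")
        observed = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(observed)):
            raise ValueError("non-finite observed values in matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def site_index(self) -> dict[PhosSiteID, int]:
        return {s: i for i, s in enumerate(self.sites)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[str(s) for s in self.sites], columns=self.samples
        )


@dataclass
class NormalizedPhosMatrix:
    """Preprocessed matrix: values in [0, 1]; zero_mask marks originally-missing cells."""

    sites: list[PhosSiteID]
    samples: list[str]
    values: np.ndarray
    zero_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.zero_mask is None:
            self.zero_mask = self.values == 0.0
        self.zero_mask = np.asarray(self.zero_mask, dtype=bool)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValueError("values shape does not match sites x samples")
        if self.values.min(initial=0.0) < 0.0 or self.values.max(initial=0.0) > 1.0:
            raise ValueError("normalized values must lie in [0, 1]")
        if np.any(self.values[self.zero_mask] != 0.0):
            raise ValueError("zero_mask=True cells must hold value 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def site_index(self) -> dict[PhosSiteID, int]:
        return {s: i for i, s in enumerate(self.sites)}

    def row(self, site: PhosSiteID) -> np.ndarray:
        try:
            return self.values[self.site_index()[site]]
        except KeyError:
            raise KeyError(f"site {site} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[str(s) for s in self.sites], columns=self.samples
        )


_DEFAULT_NA = ("", "NA", "NaN", "nan")


def read_phos_matrix(path: str | Path, na_tokens: Sequence[str] = _DEFAULT_NA) -> PhosMatrix:
    """Read a TSV matrix: first column phos-site IDs, header row of sample IDs."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(na_tokens), keep_default_na=False
    )
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    sites = []
    for lineno, raw in enumerate(df.index.astype(str), start=2):
        try:
            sites.append(PhosSiteID.parse(raw))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
    if len(set(sites)) != len(sites):
        dup = pd.Index([str(s) for s in sites])
        dup = sorted(dup[dup.duplicated()].unique())
        raise ValueError(f"{path}: duplicate site IDs: {dup}")
    return PhosMatrix(sites, [str(c) for c in df.columns], df.to_numpy(dtype=float))


def write_matrix(m: PhosMatrix | NormalizedPhosMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with full float precision (round-trips to < 1e-9)."""
    m.to_frame().to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def read_normalized_matrix(path: str | Path) -> NormalizedPhosMatrix:
    """Read back a normalized matrix written by :func:`write_matrix`."""
    raw = read_phos_matrix(path)
    values = np.nan_to_num(raw.values, nan=0.0)
    return NormalizedPhosMatrix(raw.sites, raw.samples, values)


def dedupe_samples(m: PhosMatrix, duplicate_groups: Iterable[Sequence[str]]) -> PhosMatrix:
    """Collapse each duplicate group to the sample with the fewest missing values.

    Ties break toward the earliest occurrence in the matrix column order.
    Samples not named in any group are kept as-is.
    """
    col = {s: j for j, s in enumerate(m.samples)}
    missing = m.missing_mask().sum(axis=0)
    drop: set[str] = set()
    for group in duplicate_groups:
        if not group:
            raise ValueError("empty duplicate group")
        unknown = [s for s in group if s not in col]
        if unknown:
            raise ValueError(f"duplicate group references unknown samples: {unknown}")
        ordered = sorted(set(group), key=lambda s: col[s])
        keep = min(ordered, key=lambda s: (missing[col[s]], col[s]))
        drop.update(s for s in ordered if s != keep)
    kept = [j for j, s in enumerate(m.samples) if s not in drop]
    return PhosMatrix([*m.sites], [m.samples[j] for j in kept], m.values[:, kept])


def filter_sites(
    m: PhosMatrix,
    kinase_sites: set[PhosSiteID] = frozenset(),
    substrate_sites: set[PhosSiteID] = frozenset(),
    min_detect_frac: float = 0.10,
) -> PhosMatrix:
    """Keep kinase sites, substrate sites, and sites detected in >= min_detect_frac of samples."""
    if not 0 <= min_detect_frac <= 1:
        raise ValueError("min_detect_frac must lie in [0, 1]")
    n_samples = len(m.samples)
    detect_frac = (~m.missing_mask()).sum(axis=1) / max(n_samples, 1)
    keep = [
        i
        for i, s in enumerate(m.sites)
        if s in kinase_sites or s in substrate_sites or detect_frac[i] >= min_detect_frac
    ]
    return PhosMatrix([m.sites[i] for i in keep], [*m.samples], m.values[keep, :])


def impute_and_normalize(m: PhosMatrix, eps: float = 1e-4) -> NormalizedPhosMatrix:
    """Impute missing as (global observed min - eps), then min-max scale to [0, 1].

    Imputed cells map to exactly 0 and are recorded in ``zero_mask``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    missing = m.missing_mask()
    observed = m.values[~missing]
    if observed.size == 0:
        raise ValueError("all-missing matrix cannot be normalized")
    floor = observed.min() - eps if missing.any() else observed.min()
    vmax = observed.max()
    span = vmax - floor
    values = np.where(missing, floor, m.values)
    if span == 0.0:
        # constant matrix with no missing cells: every observed value maps to 1
        out = np.ones_like(values)
    else:
        out = (values - floor) / span
    out[missing] = 0.0  # exact zero regardless of rounding
    out = np.clip(out, 0.0, 1.0)
    return NormalizedPhosMatrix([*m.sites], [*m.samples], out, missing)
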