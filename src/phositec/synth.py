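"""Seeded synthetic fixtures emulating the pipeline's real inputs at desk scale.

The generators plant exactly the regularities the pipeline is built to
recover, so each stage's tests double as end-to-end recovery checks:

* a sparse nonnegative site x sample matrix in which every kinase has a
  latent per-sample activity; its critical site tracks that activity, its
  other sites are partially co-regulated with it, and its substrate sites
  follow ``clip(beta * activity + noise)`` (``beta=0`` severs the coupling);
* kinase sequences carrying one instance each of an ATP-binding-like
  signature (conserved K as last element) and an active-site-like signature
  (conserved D), an activation-loop interval downstream of the D, critical
  sites placed nearer the conserved K with flanks enriched in Y/C/G/W, and
  non-critical sites placed uniformly;
* class-separated Gaussian surrogate sequence embeddings (separation Delta
  along a random unit direction, unit covariance), standing in for protein
  language-model embeddings;
* toy Calpha-only helical traces (rise 1.5 A, 100 deg per residue, radius
  chosen for the canonical ~3.8 A Calpha spacing) so spatial distances are
  computable.

Missingness is intensity-dependent (left-censored): a cell's dropout
probability rises as its value falls, averaging to the configured sparsity.
This mirrors the detection behavior of phospho-MS and makes "site detected"
weakly informative about the underlying level, which the enrichment module's
phos/non-phos grouping relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import NormalizedPhosMatrix, PhosMatrix, PhosSiteID, impute_and_normalize
from .structfeat import RegionAnnotation

__all__ = [
    "SynthSpec",
    "ATP_BINDING_PATTERN",
    "ACTIVE_SITE_PATTERN",
    "gen_phos_matrix",
    "gen_kinase_sequences",
    "gen_site_embeddings",
    "gen_toy_structures",
]

#: Planted signature patterns (PROSITE syntax).  The ATP-binding-like pattern
#: ends on the conserved K; the active-site-like pattern holds the conserved D
#: at element index 2.
ATP_BINDING_PATTERN = "[LIV]-G-[EQ]-G-x-[FY]-G-x-V-K"
ACTIVE_SITE_PATTERN = "[HY]-R-D-[LIV]-K-x(2)-N"

_AA20 = "ARNDCQEGHILKMFPSTWYV"
_CRIT_FLANK = "YCGW"  # letters enriched around planted critical sites


@dataclass
class SynthSpec:
    n_kinases: int = 20
    sites_per_kinase: int = 5
    n_substrate_sites: int = 200
    n_samples: int = 60
    sparsity: float = 0.4
    critical_frac: float = 0.2
    beta: float = 2.0  # kinase->substrate coupling strength
    delta: float = 4.0  # class separation of surrogate embeddings
    seq_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sparsity", "critical_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.n_substrate_sites < self.n_kinases:
            raise ValueError("need at least one substrate site per kinase")


def _kinase_acc(i: int) -> str:
    return f"KIN{i + 1:03d}"


def gen_phos_matrix(spec: SynthSpec) -> tuple[NormalizedPhosMatrix, dict]:
    """Sparse normalized matrix with planted kinase->substrate value coupling.

    Returns (matrix, truth) where truth holds the critical-site set, the
    kinase -> substrate-site map, the kinase -> own-site map, and the latent
    activity matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n_crit = max(1, round(spec.critical_frac * spec.sites_per_kinase))
    sites: list[PhosSiteID] = []
    rows: list[np.ndarray] = []
    critical: set[PhosSiteID] = set()
    kinase_sites: dict[str, list[PhosSiteID]] = {}
    substrate_map: dict[str, list[PhosSiteID]] = {}
    activities = rng.uniform(size=(spec.n_kinases, spec.n_samples))

    for k in range(spec.n_kinases):
        acc = _kinase_acc(k)
        a = activities[k]
        own: list[PhosSiteID] = []
        for j in range(spec.sites_per_kinase):
            site = PhosSiteID(acc, "STY"[j % 3], 10 * (j + 1))
            own.append(site)
            sites.append(site)
            if j < n_crit:
                critical.add(site)
                row = np.clip(a + 0.05 * rng.normal(size=spec.n_samples), 0.0, 1.0)
            else:
                # partial co-regulation with the host kinase (shared protein level)
                row = np.clip(
                    0.5 * a + 0.5 * rng.uniform(size=spec.n_samples), 0.0, 1.0
                )
            rows.append(row)
        kinase_sites[acc] = own

    # substrates partitioned across kinases round-robin
    for m in range(spec.n_substrate_sites):
        k = m % spec.n_kinases
        acc = _kinase_acc(k)
        site = PhosSiteID(f"SUB{m + 1:04d}", "STY"[m % 3], 5)
        sites.append(site)
        substrate_map.setdefault(acc, []).append(site)
        noise = rng.normal(size=spec.n_samples)
        if spec.beta > 0:
            row = np.clip(spec.beta * activities[k] * 0.5 + 0.15 * noise, 0.0, 1.0)
        else:
            row = np.clip(0.5 + 0.25 * noise, 0.0, 1.0)
        rows.append(row)

    values = np.stack(rows)
    # strictly positive raw intensities so detection (nonzero) == not missing
    values = 0.05 + 0.95 * values
    # intensity-dependent missingness (low-abundance cells drop out more
    # often), matching the left-censored character of phospho-MS data; the
    # overall missing rate averages to `sparsity`
    p_missing = np.clip(spec.sparsity * (1.5 - values), 0.0, 1.0)
    missing = rng.random(values.shape) < p_missing
    # keep at least one observed value per site so preprocessing never degenerates
    for i in np.flatnonzero(missing.all(axis=1)):
        missing[i, rng.integers(values.shape[1])] = False
    raw = np.where(missing, np.nan, values)
    matrix = impute_and_normalize(PhosMatrix(sites, [f"S{j + 1:03d}" for j in range(spec.n_samples)], raw))
    truth = {
        "critical_sites": critical,
        "substrate_map": substrate_map,
        "kinase_sites": kinase_sites,
        "activities": activities,
    }
    return matrix, truth


def _instantiate(pattern_elements: str, rng: np.random.Generator) -> str:
    """A concrete residue string matching a planted pattern."""
    out = []
    for token in pattern_elements.split("-"):
        base, rep = token, 1
        if "(" in token:
            base = token[: token.index("(")]
            rep = int(token[token.index("(") + 1 : -1].split(",")[0])
        for _ in range(rep):
            if base == "x":
                out.append(rng.choice(list(_AA20)))
            elif base.startswith("["):
                out.append(rng.choice(list(base[1:-1])))
            elif base.startswith("{"):
                out.append(rng.choice([c for c in _AA20 if c not in base[1:-1]]))
            else:
                out.append(base)
    return "".join(out)


def gen_kinase_sequences(spec: SynthSpec) -> tuple[dict, dict, list]:
    """Sequences with planted signatures, A-loops, and annotated phos-sites.

    Returns (sequences, annotations, site_labels) where annotations maps
    accession -> RegionAnnotation and site_labels is a list of
    (PhosSiteID, is_critical).
    """
    rng = np.random.default_rng(spec.seed + 17)
    n_crit = max(1, round(spec.critical_frac * spec.sites_per_kinase))
    sequences: dict[str, str] = {}
    annotations: dict[str, RegionAnnotation] = {}
    site_labels: list[tuple[PhosSiteID, bool]] = []

    sig1 = _instantiate(ATP_BINDING_PATTERN, rng)
    sig2 = _instantiate(ACTIVE_SITE_PATTERN, rng)
    for k in range(spec.n_kinases):
        acc = _kinase_acc(k)
        L = spec.seq_length
        seq = list(rng.choice(list(_AA20.replace("K", "").replace("D", "")), size=L))
        p1 = int(rng.integers(30, 60))
        p2 = int(rng.integers(130, 160))
        seq[p1 - 1 : p1 - 1 + len(sig1)] = list(sig1)
        seq[p2 - 1 : p2 - 1 + len(sig2)] = list(sig2)
        k_pos = p1 + len(sig1) - 1  # conserved K: last signature element
        d_pos = p2 + 2  # conserved D: third element
        aloop = (p2 + len(sig2) + 5, min(L, p2 + len(sig2) + 35))
        reserved = set(range(p1, p1 + len(sig1))) | set(range(p2, p2 + len(sig2)))

        taken: set[int] = set()
        for j in range(spec.sites_per_kinase):
            crit = j < n_crit
            for _attempt in range(200):
                if crit:
                    offset = int(rng.integers(8, 30)) * (1 if rng.random() < 0.5 else -1)
                    pos = k_pos + offset
                else:
                    pos = int(rng.integers(10, L - 10))
                if 8 <= pos <= L - 8 and pos not in reserved and pos not in taken:
                    break
            taken.add(pos)
            residue = "STY"[int(rng.integers(3))]
            seq[pos - 1] = residue
            if crit:
                for off in (-3, -2, -1, 1, 2, 3):
                    fp = pos + off - 1
                    if 0 <= fp < L and (fp + 1) not in reserved and rng.random() < 0.7:
                        seq[fp] = str(rng.choice(list(_CRIT_FLANK)))
            site_labels.append((PhosSiteID(acc, residue, pos), crit))
        sequences[acc] = "".join(seq)
        annotations[acc] = RegionAnnotation(acc, [aloop], conserved_k=k_pos, conserved_d=d_pos)
    return sequences, annotations, site_labels


def gen_site_embeddings(
    sites: list,
    labels: list,
    dim: int = 1024,
    delta: float = 4.0,
    seed: int = 0,
    signal_mask: list | None = None,
) -> pd.DataFrame:
    """Class-conditional Gaussian embeddings with mean separation ``delta``.

    Means sit at +/-(delta/2) along one random unit direction; unit
    covariance.  ``signal_mask`` (optional, per site) turns the class signal
    off for selected sites — they are embedded as class 0 regardless of label,
    modeling a modality that misses part of the positive class.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=dim)
    u /= np.linalg.norm(u)
    labels = np.asarray(labels, dtype=int)
    effective = labels.copy()
    if signal_mask is not None:
        effective = np.where(np.asarray(signal_mask, bool), labels, 0)
    X = rng.normal(size=(len(sites), dim))
    X += np.outer(np.where(effective == 1, delta / 2, -delta / 2), u)
    return pd.DataFrame(X, index=[str(s) for s in sites])


_HELIX_RISE = 1.5  # angstrom per residue along the axis
_HELIX_TURN = math.radians(100.0)
_CA_SPACING = 3.8


def _helix_radius() -> float:
    chord2 = _CA_SPACING**2 - _HELIX_RISE**2
    return math.sqrt(chord2 / (2.0 * (1.0 - math.cos(_HELIX_TURN))))


def gen_toy_structures(sequences: dict, seed: int = 0, out_dir=None) -> dict:
    """Calpha-only helical PDB text per sequence; adjacent Calpha ~3.8 A apart."""
    from Bio.SeqUtils import seq3

    r = _helix_radius()
    out: dict[str, str] = {}
    for acc, seq in sequences.items():
        lines = []
        for i, aa in enumerate(seq, start=1):
            x = r * math.cos(i * _HELIX_TURN)
            y = r * math.sin(i * _HELIX_TURN)
            z = i * _HELIX_RISE
            res3 = seq3(aa).upper() if aa in _AA20 else "UNK"
            lines.append(
                f"ATOM  {i:5d}  CA  {res3:>3} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        text = "\n".join(lines) + "\n"
        out[acc] = text
        if out_dir is not None:
            from pathlib import Path

            Path(out_dir).mkdir(parents=True, exist_ok=True)
            (Path(out_dir) / f"{acc}.pdb").write_text(text)
    return out
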