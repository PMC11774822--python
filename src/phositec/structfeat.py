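"""Structural context of kinase phosphorylation sites.

Covers PROSITE-signature scanning (the kinase ATP-binding and active-site
signatures carry the conserved K and D residues that anchor distance
features), sequence and spatial (Calpha-Calpha) distances from a site to
those residues, activation-loop membership, PDB ingestion, and loading of
externally computed per-site structural feature tables (ASA/CX/DPX).

The PROSITE scanner is a direct backtracking matcher over parsed pattern
elements, so every match can report the sequence position of each element —
needed to pull out the conserved residue — and all distinct spans of
variable-length wildcards are enumerated.

Coordinates are 1-based inclusive throughout; PDB residue numbers are assumed
to equal sequence positions (AlphaFold-style single-chain models), with a
configurable offset for mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .msio import PhosSiteID

__all__ = [
    "PrositeElement",
    "PrositePattern",
    "PrositeMatch",
    "StructureModel",
    "RegionAnnotation",
    "SignatureAbsentError",
    "parse_prosite",
    "scan_prosite",
    "locate_conserved",
    "residue_distance",
    "read_structure",
    "load_structural_table",
    "in_aloop",
]

_AA20 = "ARNDCQEGHILKMFPSTWYV"


class SignatureAbsentError(LookupError):
    """Raised when a signature pattern has no match in a sequence."""


@dataclass(frozen=True)
class PrositeElement:
    """One pattern element: a residue set (or complement) repeated min..max times."""

    allowed: frozenset  # residues the element accepts
    min_rep: int = 1
    max_rep: int = 1

    def accepts(self, residue: str) -> bool:
        return residue in self.allowed


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple
    n_anchor: bool = False  # '<': match must start at position 1
    c_anchor: bool = False  # '>': match must end at the last residue


def parse_prosite(pattern_text: str) -> PrositePattern:
    """Parse PROSITE pattern syntax: ``A-[ST]-{P}-x(2,3)-K`` with optional ``<``/``>``."""
    text = pattern_text.strip().rstrip(".")
    if not text:
        raise ValueError("empty pattern")
    n_anchor = text.startswith("<")
    if n_anchor:
        text = text[1:]
    c_anchor = text.endswith(">")
    if c_anchor:
        text = text[:-1]
    elements = []
    for offset, token in _tokenize(text):
        base, rep = token, "1"
        if "(" in token:
            if not token.endswith(")"):
                raise ValueError(f"pattern syntax error at offset {offset}: {token!r}")
            base, rep = token[: token.index("(")], token[token.index("(") + 1 : -1]
        if base == "x":
            allowed = frozenset(_AA20)
        elif base.startswith("[") and base.endswith("]") and len(base) > 2:
            allowed = frozenset(base[1:-1])
        elif base.startswith("{") and base.endswith("}") and len(base) > 2:
            allowed = frozenset(_AA20) - frozenset(base[1:-1])
        elif len(base) == 1 and base.isalpha():
            allowed = frozenset(base.upper())
        else:
            raise ValueError(f"pattern syntax error at offset {offset}: {base!r}")
        parts = rep.split(",")
        try:
            lo = int(parts[0])
            hi = int(parts[1]) if len(parts) > 1 else lo
        except ValueError:
            raise ValueError(
                f"pattern syntax error at offset {offset}: bad repeat {rep!r}"
            ) from None
        if lo > hi or lo < 0 or len(parts) > 2:
            raise ValueError(f"pattern syntax error at offset {offset}: bad repeat {rep!r}")
        if lo == hi:
            # fixed repetition expands to individual elements so element
            # indices address single residues (x(2) counts as two elements)
            elements.extend(PrositeElement(allowed, 1, 1) for _ in range(lo))
        else:
            elements.append(PrositeElement(allowed, lo, hi))
    if not elements:
        raise ValueError("pattern has no elements")
    return PrositePattern(tuple(elements), n_anchor, c_anchor)


def _tokenize(text: str) -> Iterator[tuple[int, str]]:
    i = 0
    for token in text.split("-"):
        if not token:
            raise ValueError(f"pattern syntax error at offset {i}: empty element")
        yield i, token
        i += len(token) + 1


@dataclass(frozen=True)
class PrositeMatch:
    """A match span (1-based inclusive) plus the start position of every element.

    For a zero-length wildcard the recorded position is where the element
    would have started.
    """

    start: int
    end: int
    element_positions: tuple

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def scan_prosite(pattern_text: str | PrositePattern, sequence: str) -> list[PrositeMatch]:
    """All distinct match spans of a PROSITE pattern in a sequence.

    Variable-length wildcards are enumerated exhaustively; matches that land
    on the same (start, end) span are reported once (first enumeration kept).
    """
    pattern = (
        pattern_text if isinstance(pattern_text, PrositePattern) else parse_prosite(pattern_text)
    )
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n = len(seq)
    starts = [0] if pattern.n_anchor else range(n)
    out: list[PrositeMatch] = []
    seen: set[tuple[int, int]] = set()

    def backtrack(ei: int, pos: int, positions: list[int]) -> None:
        if ei == len(pattern.elements):
            if pattern.c_anchor and pos != n:
                return
            span = (positions[0] + 1, pos)  # 1-based inclusive; pos is exclusive 0-based end
            if span not in seen:
                seen.add(span)
                out.append(PrositeMatch(span[0], span[1], tuple(p + 1 for p in positions)))
            return
        el = pattern.elements[ei]
        for rep in range(el.min_rep, el.max_rep + 1):
            if pos + rep > n:
                break
            if all(el.accepts(seq[pos + j]) for j in range(rep)):
                backtrack(ei + 1, pos + rep, positions + [pos])
            elif rep > 0:
                break  # longer repetitions of the same set cannot match either

    for s in starts:
        backtrack(0, s, [])
    out.sort(key=lambda m: (m.start, m.end))
    return out


def locate_conserved(
    sequence: str, pattern_text: str | PrositePattern, element_index: int
) -> int:
    """1-based sequence position of the ``element_index``-th element in the first match.

    For the kinase ATP-binding signature the conserved K is the last element
    (``element_index=-1``); raises :class:`SignatureAbsentError` when the
    signature does not occur, so callers can drop distance features.
    """
    matches = scan_prosite(pattern_text, sequence)
    if not matches:
        raise SignatureAbsentError("signature absent from sequence")
    first = matches[0]
    return first.element_positions[element_index]


@dataclass
class StructureModel:
    """Per-residue Calpha coordinates (angstrom), keyed by (chain, residue number)."""

    coords: dict  # (chain, resnum) -> np.ndarray shape (3,)
    source_id: str = ""

    def ca(self, resnum: int, chain: str | None = None) -> np.ndarray:
        if chain is None:
            chain = next(iter(self.coords))[0]
        try:
            return self.coords[(chain, resnum)]
        except KeyError:
            raise KeyError(f"residue {chain}/{resnum} missing from structure") from None

    def __len__(self) -> int:
        return len(self.coords)


def read_structure(path: str | Path, source_id: str | None = None) -> StructureModel:
    """One Calpha coordinate per residue from a PDB file; first altloc kept."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(source_id or Path(path).stem, str(path))
    coords: dict = {}
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM / water
                continue
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]
            key = (chain.id, residue.id[1])
            if key not in coords:
                coords[key] = np.asarray(atom.coord, dtype=float)
    if not coords:
        raise ValueError(f"{path}: no CA atoms found")
    return StructureModel(coords, source_id or Path(path).stem)


def residue_distance(
    site: PhosSiteID,
    target_pos: int,
    mode: str = "sequence",
    structure: StructureModel | None = None,
    chain: str | None = None,
    resnum_offset: int = 0,
) -> float:
    """Distance from a phos-site to a target residue.

    ``sequence`` mode: |position difference| in residues.  ``spatial`` mode:
    Euclidean Calpha-Calpha distance in angstrom; residue numbers are sequence
    positions plus ``resnum_offset``.
    """
    if mode == "sequence":
        return float(abs(site.position - target_pos))
    if mode == "spatial":
        if structure is None:
            raise ValueError("spatial mode requires a structure")
        a = structure.ca(site.position + resnum_offset, chain)
        b = structure.ca(target_pos + resnum_offset, chain)
        return float(np.linalg.norm(a - b))
    raise ValueError(f"unknown mode {mode!r}")


_STRUCT_COLS = ("ASA_backbone_sum", "CX_total_mean", "DPX_total_mean")


def load_structural_table(path: str | Path) -> dict:
    """Per-site externally computed structural features (ASA/CX/DPX), keyed by site ID."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "site" not in df.columns:
        raise ValueError(f"{path}: missing 'site' column")
    missing = [c for c in _STRUCT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c != "site" and c not in _STRUCT_COLS]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    out: dict = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            site = PhosSiteID.parse(getattr(row, "site"))
            feats = {c: float(getattr(row, c)) for c in _STRUCT_COLS}
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {lineno}: {exc}") from None
        if site in out:
            raise ValueError(f"{path}, line {lineno}: duplicate site {site}")
        out[site] = feats
    return out


@dataclass
class RegionAnnotation:
    """Per-kinase A-loop intervals and conserved-residue positions."""

    kinase: str
    aloop_intervals: list = field(default_factory=list)  # [(start, end)] 1-based incl.
    conserved_k: int | None = None  # K of the ATP-binding signature
    conserved_d: int | None = None  # D of the active-site signature

    def __post_init__(self) -> None:
        for start, end in self.aloop_intervals:
            if start > end:
                raise ValueError(f"invalid A-loop interval [{start}, {end}]")


def in_aloop(site: PhosSiteID, ann: RegionAnnotation) -> bool:
    """True iff the site position lies in any A-loop interval (inclusive ends)."""
    if ann.kinase != site.protein_accession:
        raise KeyError(f"annotation is for {ann.kinase}, site is on {site.protein_accession}")
    return any(start <= site.position <= end for start, end in ann.aloop_intervals)
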