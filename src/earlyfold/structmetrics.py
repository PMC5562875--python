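"""Structure-derived residue metrics and distribution comparisons.

Two per-residue quantities link predicted early folding to the final fold:

* **RSA** — relative solvent accessibility: the DSSP accessible surface
  area divided by the residue type's maximum accessible area (Sander scale
  by default), 0 for fully buried residues.
* **Contact S²** — a rigidity estimate of the backbone amide from a
  contact model: exponentially weighted counts of heavy atoms near the
  amide proton of residue *i* and the carbonyl oxygen of residue *i−1*,

      S²(i) = tanh( b · [ Σ w·exp(−d_H/r0) + Σ exp(−d_O/r0) ] ) − c,

  summing over heavy atoms outside residues *i* and *i−1*.

Group comparisons use the two-sided Wilcoxon rank-sum test with
Benjamini–Hochberg correction, optionally after a per-amino-acid bias
correction that recentres each residue type's distribution on the global
median (so composition differences between groups do not masquerade as
signal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict, residue_max_acc
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Atom",
    "StructureModel",
    "DsspRecord",
    "ContactS2Params",
    "parse_pdb",
    "parse_dssp",
    "rsa",
    "contact_s2",
    "contact_s2_profile",
    "bias_correct",
    "wilcoxon_ranksum",
    "benjamini_hochberg",
    "significance_stars",
    "compare_groups",
    "GroupSummary",
    "PairComparison",
    "ComparisonReport",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_type: str  # three-letter code
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    """A flat atom list with per-residue lookup helpers."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        coords = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        object.__setattr__(self, "atoms", atoms)

    def residues(self, chain: str | None = None) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            if chain is None or a.chain == chain:
                seen.setdefault((a.chain, a.residue_number), None)
        return list(seen)

    def residue_atoms(self, chain: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.residue_number == residue_number
        ]

    def atom(self, chain: str, residue_number: int, name: str) -> Atom | None:
        for a in self.residue_atoms(chain, residue_number):
            if a.name == name:
                return a
        return None


def parse_pdb(path: str | Path, model_index: int = 0) -> StructureModel:
    """Read a PDB coordinate file into a :class:`StructureModel`."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = list(structure)[model_index]
    atoms = []
    for chain in model:
        for residue in chain:
            het, resnum, _icode = residue.id
            if het.strip():  # skip waters / heteroatoms
                continue
            for atom in residue:
                x, y, z = atom.coord
                atoms.append(
                    Atom(
                        chain=chain.id,
                        residue_number=resnum,
                        residue_type=residue.resname,
                        name=atom.get_name(),
                        element=(atom.element or "").upper(),
                        x=float(x),
                        y=float(y),
                        z=float(z),
                    )
                )
    return StructureModel(tuple(atoms))


@dataclass(frozen=True)
class DsspRecord:
    chain: str
    residue_number: int
    amino_acid: str  # one-letter code
    acc: float  # solvent-accessible area, A^2

    def __post_init__(self) -> None:
        if self.acc < 0:
            raise ValueError("ACC must be non-negative")


class DsspFormatError(ValueError):
    """Raised when a file is not in the classic DSSP column format."""


def parse_dssp(path: str | Path) -> list[DsspRecord]:
    """Parse a classic-format DSSP output file.

    Returns one record per residue line; chain-break lines (``!``) are
    skipped. A file without the DSSP residue-table header is a format
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if "  #  RESIDUE" not in path.read_text():
        raise DsspFormatError(f"{path}: missing DSSP residue-table header")
    dssp_dict, keys = make_dssp_dict(str(path))
    records = []
    for chain, res_id in keys:
        aa, _ss, acc = dssp_dict[(chain, res_id)][:3]
        if aa == "!":  # chain break
            continue
        records.append(
            DsspRecord(
                chain=chain,
                residue_number=int(res_id[1]),
                amino_acid=aa,
                acc=float(acc),
            )
        )
    return records


#: max-ASA normalisation scales available for RSA (from Bio.PDB.DSSP)
RSA_SCALES = tuple(residue_max_acc)


def rsa(acc: float, amino_acid: str, scale: str = "Sander") -> float:
    """Relative solvent accessibility: ACC / maxASA(residue type).

    ``amino_acid`` may be a one- or three-letter code. Values above 1
    (possible for unusual conformations) are flagged with a warning, not
    clipped.
    """
    if acc < 0:
        raise ValueError("ACC must be non-negative")
    aa3 = (
        amino_acid.upper()
        if len(amino_acid) == 3
        else _ONE_TO_THREE.get(amino_acid.upper(), amino_acid.upper())
    )
    try:
        max_asa = residue_max_acc[scale][aa3]
    except KeyError as exc:
        raise KeyError(
            f"unknown residue type {amino_acid!r} for max-ASA scale {scale!r}"
        ) from exc
    value = acc / max_asa
    if value > 1.0:
        warnings.warn(
            f"RSA {value:.2f} > 1 for {aa3} (ACC={acc}); not clipped",
            stacklevel=2,
        )
    return value


@dataclass(frozen=True)
class ContactS2Params:
    """Constants of the contact model; defaults follow the contact-model
    literature and are fully configurable."""

    b: float = 0.8  # overall scale inside tanh
    w: float = 0.8  # weight of the amide-proton contact path
    r0: float = 1.0  # exponential decay length, A
    c: float = 0.1  # constant offset

    def __post_init__(self) -> None:
        if self.b <= 0 or self.r0 <= 0:
            raise ValueError("b and r0 must be positive")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate geometry: zero-length bond vector")
    return v / n


def _amide_proton(
    structure: StructureModel, chain: str, resnum: int, prev_resnum: int
) -> np.ndarray | None:
    """The amide H coordinate: the H atom if present, else rebuilt from
    N(i), CA(i) and C'(i−1) (N–H 1.01 Å, opposite the N bond bisector)."""
    h = structure.atom(chain, resnum, "H")
    if h is not None:
        return h.coord
    n = structure.atom(chain, resnum, "N")
    ca = structure.atom(chain, resnum, "CA")
    c_prev = structure.atom(chain, prev_resnum, "C")
    if n is None or ca is None or c_prev is None:
        return None
    direction = _unit(
        _unit(n.coord - c_prev.coord) + _unit(n.coord - ca.coord)
    )
    return n.coord + 1.01 * direction


def contact_s2(
    structure: StructureModel,
    chain: str,
    residue_number: int,
    params: ContactS2Params = ContactS2Params(),
) -> float:
    """Contact-model S² for one residue; NaN where undefined.

    Undefined for the first residue of a chain, or when the amide proton
    (or the atoms needed to rebuild it) or the preceding carbonyl oxygen
    is missing.
    """
    residues = structure.residues(chain)
    numbers = [r[1] for r in residues]
    if residue_number not in numbers:
        raise KeyError(f"residue {chain}/{residue_number} not in structure")
    pos = numbers.index(residue_number)
    if pos == 0:
        return float("nan")
    prev_number = numbers[pos - 1]
    h_coord = _amide_proton(structure, chain, residue_number, prev_number)
    o_prev = structure.atom(chain, prev_number, "O")
    if h_coord is None or o_prev is None:
        return float("nan")
    excluded = {(chain, residue_number), (chain, prev_number)}
    total = 0.0
    for a in structure.atoms:
        if a.element == "H" or (a.chain, a.residue_number) in excluded:
            continue
        d_h = float(np.linalg.norm(a.coord - h_coord))
        d_o = float(np.linalg.norm(a.coord - o_prev.coord))
        total += params.w * math.exp(-d_h / params.r0) + math.exp(
            -d_o / params.r0
        )
    return math.tanh(params.b * total) - params.c


def contact_s2_profile(
    structure: StructureModel,
    chain: str,
    params: ContactS2Params = ContactS2Params(),
) -> dict[int, float]:
    """Contact S² for every residue of a chain (NaN where undefined)."""
    return {
        resnum: contact_s2(structure, chain, resnum, params)
        for _, resnum in structure.residues(chain)
    }


def bias_correct(
    values: Sequence[float], amino_acids: Sequence[str]
) -> np.ndarray:
    """Remove per-amino-acid composition bias from a value distribution.

    Subtracts each residue type's median and adds back the global median:
    ``v' = v − median(values of type) + median(all values)``. After
    correction every residue type has the same median (the global one),
    and the operation is idempotent.
    """
    v = np.asarray(values, dtype=float)
    aa = np.asarray(amino_acids)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != aa.shape:
        raise ValueError("values and amino_acids must align")
    global_median = np.median(v)
    out = np.empty_like(v)
    for t in np.unique(aa):
        mask = aa == t
        out[mask] = v[mask] - np.median(v[mask]) + global_median
    return out


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Uses the exact permutation distribution when the combined sample is
    small (n ≤ 20) and tie-free, and the normal approximation with
    continuity and tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else empty."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    #: half-width of the median notch, 1.57·IQR/sqrt(n)
    notch: float


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    pvalue: float
    pvalue_adjusted: float
    stars: str


@dataclass(frozen=True)
class ComparisonReport:
    summaries: tuple[GroupSummary, ...]
    pairs: tuple[PairComparison, ...]
    bias_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])

    def summaries_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    amino_acids_by_group: Mapping[str, Sequence[str]] | None = None,
    bias_correct_flag: bool = False,
) -> ComparisonReport:
    """Pairwise distribution comparisons across ≥ 2 groups.

    Each unordered pair of groups gets a two-sided Wilcoxon rank-sum
    p-value; all pairs are then Benjamini–Hochberg adjusted together and
    annotated with significance stars on the adjusted values. With
    ``bias_correct_flag`` the per-amino-acid bias correction is applied to
    the pooled values first (requires ``amino_acids_by_group``).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = {g: np.asarray(values_by_group[g], float) for g in names}
    for g, v in groups.items():
        if v.size < 1:
            raise ValueError(f"group {g!r} is empty")
    if bias_correct_flag:
        if amino_acids_by_group is None:
            raise ValueError("bias correction requires amino-acid types")
        pooled = np.concatenate([groups[g] for g in names])
        pooled_aa = np.concatenate(
            [np.asarray(amino_acids_by_group[g]) for g in names]
        )
        corrected = bias_correct(pooled, pooled_aa)
        offset = 0
        for g in names:
            n = groups[g].size
            groups[g] = corrected[offset : offset + n]
            offset += n

    summaries = tuple(
        GroupSummary(
            group=g,
            n=int(v.size),
            median=float(np.median(v)),
            q1=float(np.percentile(v, 25)),
            q3=float(np.percentile(v, 75)),
            mean=float(v.mean()),
            notch=float(
                1.57 * (np.percentile(v, 75) - np.percentile(v, 25))
                / math.sqrt(v.size)
            ),
        )
        for g, v in groups.items()
    )
    pair_names = list(combinations(names, 2))
    raw = [wilcoxon_ranksum(groups[a], groups[b]) for a, b in pair_names]
    adjusted = benjamini_hochberg(raw)
    pairs = tuple(
        PairComparison(
            group_a=a,
            group_b=b,
            pvalue=float(p),
            pvalue_adjusted=float(q),
            stars=significance_stars(float(q)),
        )
        for (a, b), p, q in zip(pair_names, raw, adjusted)
    )
    return ComparisonReport(
        summaries=summaries, pairs=pairs, bias_corrected=bias_correct_flag
    )
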