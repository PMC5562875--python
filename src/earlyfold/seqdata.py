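"""Sequence records, early-folding annotations, and score-table I/O.

Residue numbering is 1-based in every file format and 0-based in memory;
the conversion happens only inside the readers and writers in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: accepted but flagged; mapped to a neutral encoding during featurization
AMBIGUOUS_AA = "XBZ"

__all__ = [
    "CANONICAL_AA",
    "AMBIGUOUS_AA",
    "ProteinRecord",
    "Dataset",
    "FastaFormatError",
    "AnnotationError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_scores",
    "read_scores",
]


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input."""


class AnnotationError(ValueError):
    """Raised when an annotation row cannot be mapped onto a record."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein chain: identifier, sequence, optional per-residue labels.

    ``labels`` is a binary vector aligned 1:1 with ``sequence``; 1 marks a
    residue protected in the earliest phase of folding (EARLY), 0 everything
    else.
    """

    id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(CANONICAL_AA) - set(AMBIGUOUS_AA)
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue codes {sorted(bad)}"
            )
        if set(seq) & set(AMBIGUOUS_AA):
            warnings.warn(
                f"record {self.id!r} contains non-canonical residues "
                f"({sorted(set(seq) & set(AMBIGUOUS_AA))}); they receive a "
                "neutral feature encoding",
                stacklevel=3,
            )
        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=np.int8)
            if lab.shape != (len(seq),):
                raise ValueError(
                    f"record {self.id!r}: {lab.size} labels for "
                    f"{len(seq)} residues"
                )
            if not np.isin(lab, (0, 1)).all():
                raise ValueError(f"record {self.id!r}: labels must be 0/1")
            object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_labelled(self) -> bool:
        return self.labels is not None

    def with_labels(self, labels: Sequence[int]) -> "ProteinRecord":
        return replace(self, labels=np.asarray(labels, dtype=np.int8))


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: tuple[ProteinRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def n_positive(self) -> int:
        return int(sum(r.labels.sum() for r in self.records if r.is_labelled))

    @property
    def is_labelled(self) -> bool:
        return all(r.is_labelled for r in self.records)

    def label_vector(self) -> np.ndarray:
        """All labels concatenated in record order (requires labels)."""
        if not self.is_labelled:
            raise ValueError("dataset is not fully labelled")
        return np.concatenate([r.labels for r in self.records])


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased and whitespace-stripped; an empty sequence
    under a header is a format error naming that header.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise FastaFormatError(
                f"{path}: empty sequence under header {rec.id!r}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    out = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(out, Path(path), "fasta")


def _parse_annotation_rows(path: Path) -> Iterator[tuple[str, int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":  # optional header row
                continue
            if len(parts) != 3:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 3 tab-separated fields "
                    f"(protein_id, residue_number, label), got {len(parts)}"
                )
            pid, pos_s, label = parts
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: residue_number {pos_s!r} is not an "
                    "integer"
                ) from exc
            yield pid, pos, label


def read_annotations(path: str | Path, dataset: Dataset) -> Dataset:
    """Attach EARLY labels from a TSV to every record of ``dataset``.

    The file has tab-separated columns ``protein_id``, ``residue_number``
    (1-based) and ``label`` (currently only ``EARLY``). Residues listed are
    labelled positive; every unlisted residue is labelled negative, so an
    empty file yields all-zero labels.
    """
    path = Path(path)
    labels = {r.id: np.zeros(len(r), dtype=np.int8) for r in dataset}
    lengths = {r.id: len(r) for r in dataset}
    for pid, pos, label in _parse_annotation_rows(path):
        if pid not in labels:
            raise AnnotationError(
                f"{path}: unknown protein_id {pid!r} "
                f"(dataset has {sorted(lengths)})"
            )
        if label != "EARLY":
            raise AnnotationError(
                f"{path}: unsupported label {label!r} for {pid!r} "
                "(expected EARLY)"
            )
        if not 1 <= pos <= lengths[pid]:
            raise AnnotationError(
                f"{path}: residue_number {pos} out of range for {pid!r} "
                f"(length {lengths[pid]})"
            )
        labels[pid][pos - 1] = 1
    return Dataset(tuple(r.with_labels(labels[r.id]) for r in dataset))


#: decimal places written for probabilities; round-trips exactly via repr
SCORE_PRECISION = 6


def write_scores(
    dataset: Dataset,
    scores: Mapping[str, Sequence[float]],
    path: str | Path,
    threshold: float = 0.163,
) -> None:
    """Write per-residue probabilities and binary calls as a TSV.

    One data row per residue with columns ``protein_id``, ``residue_number``
    (1-based), ``amino_acid``, ``probability`` and ``binary_call``.
    ``binary_call`` is 1 iff probability >= threshold (inclusive).
    """
    path = Path(path)
    rows = ["protein_id\tresidue_number\tamino_acid\tprobability\tbinary_call"]
    for rec in dataset:
        s = np.asarray(scores[rec.id], dtype=float)
        if s.shape != (len(rec),):
            raise ValueError(
                f"record {rec.id!r}: {s.size} scores for {len(rec)} residues"
            )
        if ((s < 0) | (s > 1)).any():
            raise ValueError(f"record {rec.id!r}: scores outside [0, 1]")
        for i, (aa, p) in enumerate(zip(rec.sequence, s)):
            call = int(round(p, SCORE_PRECISION) >= threshold)
            rows.append(
                f"{rec.id}\t{i + 1}\t{aa}\t{p:.{SCORE_PRECISION}f}\t{call}"
            )
    path.write_text("\n".join(rows) + "\n")


def read_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Read a score TSV written by :func:`write_scores` back into arrays."""
    scores: dict[str, list[float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_id", "residue_number"]:
            raise ValueError(f"{path}: not a score table")
        for line in fh:
            pid, pos, _aa, prob, _call = line.rstrip("\n").split("\t")
            scores.setdefault(pid, [])
            if int(pos) != len(scores[pid]) + 1:
                raise ValueError(f"{path}: non-contiguous residue numbers")
            scores[pid].append(float(prob))
    return {pid: np.asarray(v) for pid, v in scores.items()}
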