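"""Protein records, dataset manifests, and FASTA/TSV input-output.

A dataset is a FASTA file of protein sequences plus a manifest assigning
each record a class label: ``positive`` (classically secreted, carries a
signal peptide), ``negative`` (non-secretory) or ``neutral``.  Records
shorter than a minimum length (default 40 residues, the shortest sequence
the downstream secretion predictor accepts) are filtered out before any
analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical 20-letter amino-acid alphabet
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: ambiguity / non-standard letters admitted but flagged
AMBIGUOUS_AA = set("BJOUXZ")

CLASS_LABELS = ("positive", "negative", "neutral")

DEFAULT_MIN_LENGTH = 40


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identity, class label and provenance."""

    id: str
    sequence: str
    class_label: str | None = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_AA - AMBIGUOUS_AA
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"record {self.id!r}: class_label must be one of {CLASS_LABELS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        """True if the sequence contains B/J/O/U/X/Z letters."""
        return bool(set(self.sequence) & AMBIGUOUS_AA)


@dataclass
class DatasetManifest:
    """Class-label assignment for a dataset: (record id, label, source tag)."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    min_length: int = DEFAULT_MIN_LENGTH

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rid, label, _tag in self.entries:
            if label not in CLASS_LABELS:
                raise ValueError(f"manifest entry {rid!r}: unknown label {label!r}")
            if rid in seen:
                raise ValueError(f"manifest lists id {rid!r} more than once")
            seen.add(rid)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _, _ in self.entries]

    def label_of(self, record_id: str) -> str:
        for rid, label, _ in self.entries:
            if rid == record_id:
                return label
        raise KeyError(record_id)


def _normalize_sequence(record_id: str, raw: str) -> str:
    seq = re.sub(r"\s+", "", raw).upper()
    # trailing stop codons are a common FASTA dialect artefact
    seq = seq.rstrip("*")
    if "*" in seq:
        raise FastaParseError(
            f"record {record_id!r}: internal stop symbol '*' in sequence"
        )
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, whitespace is removed and trailing ``*``
    stop symbols stripped.  Record order is preserved.  Duplicate ids and
    internal stop symbols raise :class:`FastaParseError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"{path}: FASTA entry with empty header")
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate FASTA header {entry.id!r}")
        seen.add(entry.id)
        seq = _normalize_sequence(entry.id, str(entry.seq))
        if not seq:
            raise FastaParseError(f"{path}: record {entry.id!r} has empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (stable output for byte-level diffing)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def filter_min_length(
    records: Sequence[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (kept, dropped) by ``len >= min_length``."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [r for r in records if len(r) >= min_length]
    dropped = [r for r in records if len(r) < min_length]
    for r in dropped:
        logger.info("dropped %s: length %d < %d", r.id, len(r), min_length)
    return kept, dropped


def apply_manifest(
    records: Sequence[ProteinRecord], manifest: DatasetManifest
) -> list[ProteinRecord]:
    """Attach manifest class labels; records absent from the manifest are
    excluded (and logged), manifest ids with no record are an error."""
    by_id = {r.id: r for r in records}
    missing = [rid for rid in manifest.ids if rid not in by_id]
    if missing:
        raise KeyError(f"manifest ids with no matching record: {missing}")
    labelled = [
        replace(by_id[rid], class_label=label, source_tag=tag)
        for rid, label, tag in manifest.entries
    ]
    excluded = set(by_id) - set(manifest.ids)
    if excluded:
        logger.info("%d records absent from manifest, excluded", len(excluded))
    if not manifest.entries:
        logger.warning("manifest is empty: no records labelled")
    return labelled


def read_manifest(path: str | Path, min_length: int = DEFAULT_MIN_LENGTH) -> DatasetManifest:
    """Read a 3-column TSV manifest (id, class_label, source_tag) with header."""
    path = Path(path)
    entries: list[tuple[str, str, str]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.lower().startswith("id"):
            raise ValueError(f"{path}: expected header starting with 'id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            rid, label = parts[0], parts[1]
            tag = parts[2] if len(parts) > 2 else ""
            entries.append((rid, label, tag))
    return DatasetManifest(entries=entries, min_length=min_length)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tclass_label\tsource_tag\n")
        for rid, label, tag in manifest.entries:
            fh.write(f"{rid}\t{label}\t{tag}\n")
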