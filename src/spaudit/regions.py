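"""Signal-peptide region resolution.

Every perturbation targeting the signal peptide (SP) needs to know, per
record, which N-terminal stretch to operate on.  Three sources exist:

* ``predicted`` — parsed from the short tabular output of an external SP
  predictor (the SignalP 4 dialect: one row per sequence with a Y/N
  decision and a cleavage position; cleavage "between L and L+1" means the
  SP is residues 1..L);
* ``fixed`` — a fixed N-terminal length (default 30) used for negative,
  non-secretory records, which have no SP to predict;
* ``annotated`` — ground-truth lengths, available for synthetic data.

The region is 1-based inclusive ``[1..L]`` and must leave a non-empty
mature sequence (``L < len(sequence)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .records import ProteinRecord

logger = logging.getLogger(__name__)

REGION_SOURCES = ("predicted", "fixed", "annotated")

DEFAULT_FIXED_LENGTH = 30

RESOLVE_POLICIES = ("predicted_then_drop", "annotated", "fixed")


@dataclass(frozen=True)
class SignalRegion:
    """The N-terminal region [1..L] an SP-targeted modification acts on."""

    record_id: str
    length: int
    source: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(
                f"region for {self.record_id!r}: length must be >= 1, got {self.length}"
            )
        if self.source not in REGION_SOURCES:
            raise ValueError(f"unknown region source {self.source!r}")

    def validate_for(self, record: ProteinRecord) -> None:
        """Check the region leaves a non-empty mature sequence."""
        if record.id != self.record_id:
            raise ValueError(f"region {self.record_id!r} applied to record {record.id!r}")
        if self.length >= len(record):
            raise ValueError(
                f"region for {self.record_id!r}: length {self.length} >= sequence "
                f"length {len(record)} (mature part would be empty)"
            )


def parse_sp_predictions(path: str | Path) -> list[SignalRegion]:
    """Parse an SP predictor's short tabular output into regions.

    Accepts the 12-column SignalP 4 "short" format (decision in the ``?``
    column, cleavage position in the ``Ymax pos`` column) or a minimal
    3-column dialect ``id  Y/N  cleavage_pos``.  Comment lines start with
    ``#``.  Rows with a negative decision yield no region.  The SP length
    is ``cleavage position - 1``.
    """
    path = Path(path)
    regions: list[SignalRegion] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= 12:  # SignalP 4 short format
                    rid, decision, cleavage = fields[0], fields[9], int(fields[4])
                elif len(fields) == 3:
                    rid, decision, cleavage = fields[0], fields[1], int(fields[2])
                else:
                    raise ValueError(f"unexpected field count {len(fields)}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if decision.upper() not in ("Y", "N"):
                raise ValueError(f"{path}:{lineno}: decision must be Y or N, got {decision!r}")
            if decision.upper() == "N":
                continue
            if cleavage < 2:
                raise ValueError(
                    f"{path}:{lineno}: cleavage position {cleavage} implies an "
                    f"empty SP (length {cleavage - 1})"
                )
            regions.append(SignalRegion(record_id=rid, length=cleavage - 1, source="predicted"))
    return regions


def fixed_region(
    records: Sequence[ProteinRecord], length: int = DEFAULT_FIXED_LENGTH
) -> list[SignalRegion]:
    """Assign every record a fixed N-terminal region of ``length`` residues.

    Used for negative records, mirroring the convention of modifying the
    first 30 residues of non-secretory proteins the same way as a real SP.
    """
    too_short = [r.id for r in records if len(r) <= length]
    if too_short:
        raise ValueError(
            f"records not longer than the fixed region length {length}: {too_short}"
        )
    return [SignalRegion(record_id=r.id, length=length, source="fixed") for r in records]


def read_truth_table(path: str | Path) -> dict[str, int]:
    """Read ground-truth SP lengths from a 2-column TSV (id, L) with header."""
    path = Path(path)
    truth: dict[str, int] = {}
    with path.open() as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            truth[parts[0]] = int(parts[1])
    return truth


def write_truth_table(truth: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\tsp_length\n")
        for rid, L in truth.items():
            fh.write(f"{rid}\t{L}\n")


def resolve_regions(
    records: Sequence[ProteinRecord],
    predicted: Sequence[SignalRegion] = (),
    truth: Mapping[str, int] | None = None,
    policy: str = "predicted_then_drop",
    fixed_length: int = DEFAULT_FIXED_LENGTH,
) -> dict[str, SignalRegion]:
    """Resolve one :class:`SignalRegion` per record according to ``policy``.

    ``predicted_then_drop``
        Positives use the predicted region; positives with no SP call are
        excluded from the perturbation analysis (logged).  Negatives and
        neutrals always receive the fixed region.
    ``annotated``
        Positives use ground-truth lengths (error if missing); negatives
        and neutrals receive the fixed region.
    ``fixed``
        Every record receives the fixed region.

    Regions that would leave an empty mature sequence raise.
    """
    if policy not in RESOLVE_POLICIES:
        raise ValueError(f"policy must be one of {RESOLVE_POLICIES}, got {policy!r}")
    predicted_by_id = {r.record_id: r for r in predicted}
    resolved: dict[str, SignalRegion] = {}
    excluded: list[str] = []
    for rec in records:
        region: SignalRegion | None = None
        if policy == "fixed":
            region = SignalRegion(rec.id, fixed_length, "fixed")
        elif rec.class_label == "positive":
            if policy == "predicted_then_drop":
                region = predicted_by_id.get(rec.id)
                if region is None:
                    excluded.append(rec.id)
                    continue
            else:  # annotated
                if truth is None or rec.id not in truth:
                    raise ValueError(
                        f"policy=annotated but no ground-truth SP length for {rec.id!r}"
                    )
                region = SignalRegion(rec.id, truth[rec.id], "annotated")
        else:
            region = SignalRegion(rec.id, fixed_length, "fixed")
        region.validate_for(rec)
        resolved[rec.id] = region
    if excluded:
        logger.info(
            "%d positive records without a predicted SP excluded: %s",
            len(excluded),
            excluded[:10],
        )
    return resolved
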