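"""Synthetic protein datasets with the class structure the audit assumes.

Positives carry a tripartite signal peptide — a short positively charged
n-region beginning with the initiator methionine, a hydrophobic h-region
of 7–13 residues, and a small/polar c-region — followed by a mature
region drawn from a background amino-acid composition close to the
average of curated protein databases.  Negatives are mature-only
sequences starting with M; a configurable fraction of them contain one
internal hydrophobic stretch (a transmembrane-segment look-alike), giving
any hydrophobicity-driven scorer a non-trivial false-positive channel.

Ground-truth SP lengths are recorded for every positive so the whole
pipeline can run with region policy ``annotated``, independent of any
external SP predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .records import ProteinRecord, DatasetManifest
from .regions import SignalRegion

#: average amino-acid composition of curated protein databases (fractions,
#: normalised to sum to 1)
BACKGROUND_FREQS: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}
_total = sum(BACKGROUND_FREQS.values())
BACKGROUND_FREQS = {aa: v / _total for aa, v in BACKGROUND_FREQS.items()}

#: strongly hydrophobic residues used for h-regions and decoy stretches
HYDROPHOBIC_AA = ("A", "I", "L", "F", "V", "M")
#: h-region composition, weighted toward leucine
HYDROPHOBIC_WEIGHTS = (0.13, 0.13, 0.35, 0.13, 0.13, 0.13)
#: small/polar residues of the c-region
C_REGION_AA = ("A", "G", "S", "T", "P", "N", "Q")
#: positively charged residues of the n-region
CHARGED_AA = ("K", "R")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic dataset.

    ``decoy_hydrophobic_rate`` is the probability a negative carries an
    internal 8–12 residue hydrophobic stretch.  The stretch is placed just
    past the fixed 30-residue pseudo-SP region but still inside the
    scorer's N-terminal scan, so SP-targeted perturbations leave it intact.
    """

    n_pos: int = 200
    n_neg: int = 200
    mature_length: tuple[int, int] = (80, 400)
    sp_n_region: tuple[int, int] = (1, 5)
    sp_h_region: tuple[int, int] = (7, 13)
    sp_c_region: tuple[int, int] = (3, 7)
    background_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(BACKGROUND_FREQS)
    )
    decoy_hydrophobic_rate: float = 0.2
    decoy_length: tuple[int, int] = (8, 12)
    decoy_start: tuple[int, int] = (32, 36)  # 1-based start position
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        total = sum(self.background_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background_freqs must sum to 1, got {total}")
        if not 0.0 <= self.decoy_hydrophobic_rate <= 1.0:
            raise ValueError("decoy_hydrophobic_rate must be in [0,1]")


def _sample_background(config: SyntheticConfig, n: int, rng: np.random.Generator) -> str:
    letters = list(config.background_freqs)
    probs = np.array([config.background_freqs[aa] for aa in letters])
    return "".join(rng.choice(letters, size=n, p=probs))


def _sample_signal_peptide(config: SyntheticConfig, rng: np.random.Generator) -> str:
    n_len = int(rng.integers(config.sp_n_region[0], config.sp_n_region[1] + 1))
    h_len = int(rng.integers(config.sp_h_region[0], config.sp_h_region[1] + 1))
    c_len = int(rng.integers(config.sp_c_region[0], config.sp_c_region[1] + 1))
    n_region = "M" + "".join(rng.choice(CHARGED_AA, size=n_len - 1))
    h_region = "".join(
        rng.choice(HYDROPHOBIC_AA, size=h_len, p=HYDROPHOBIC_WEIGHTS)
    )
    c_region = "".join(rng.choice(C_REGION_AA, size=c_len))
    return n_region + h_region + c_region


def generate_protein(
    config: SyntheticConfig,
    class_label: str,
    rng: np.random.Generator,
    record_id: str = "synthetic",
) -> tuple[ProteinRecord, SignalRegion | None]:
    """Draw one synthetic protein; positives return their true SP region."""
    lo, hi = config.mature_length
    if class_label == "positive":
        sp = _sample_signal_peptide(config, rng)
        mature = _sample_background(config, int(rng.integers(lo, hi + 1)), rng)
        record = ProteinRecord(
            id=record_id, sequence=sp + mature,
            class_label="positive", source_tag="synthetic",
        )
        return record, SignalRegion(record_id, len(sp), "annotated")
    # negative: mature-only chain starting with M
    length = int(rng.integers(lo, hi + 1))
    seq = list("M" + _sample_background(config, length - 1, rng))
    if rng.random() < config.decoy_hydrophobic_rate:
        d_len = int(rng.integers(config.decoy_length[0], config.decoy_length[1] + 1))
        start = int(rng.integers(config.decoy_start[0], config.decoy_start[1] + 1)) - 1
        decoy = rng.choice(HYDROPHOBIC_AA, size=d_len, p=HYDROPHOBIC_WEIGHTS)
        seq[start : start + d_len] = decoy
    record = ProteinRecord(
        id=record_id, sequence="".join(seq),
        class_label=class_label, source_tag="synthetic",
    )
    return record, None


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], dict[str, int], DatasetManifest]:
    """Generate the full labelled dataset.

    Returns ``(records, truth, manifest)`` where ``truth`` maps positive
    record ids to their ground-truth SP length.  The same seed always
    yields the identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    truth: dict[str, int] = {}
    for i in range(config.n_pos):
        rec, region = generate_protein(config, "positive", rng, f"pos_{i:04d}")
        records.append(rec)
        truth[rec.id] = region.length
    for i in range(config.n_neg):
        rec, _ = generate_protein(config, "negative", rng, f"neg_{i:04d}")
        records.append(rec)
    manifest = DatasetManifest(
        entries=[(r.id, r.class_label, r.source_tag) for r in records]
    )
    return records, truth, manifest
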