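"""The five sequence perturbations and their bootstrap replication.

Each original sequence spawns a family of derived sequences designed to
isolate the signal peptide's (SP) contribution to a predictor's score:

* ``reverse``   — the whole sequence in reverse order;
* ``sp_remove`` — the SP region [1..L] deleted (sequence gets shorter);
* ``sp_cterm``  — the SP moved from the N- to the C-terminus (length and
  composition preserved);
* ``sp_random`` — the SP residues uniformly shuffled in place, B bootstrap
  replicates;
* ``random``    — the entire sequence uniformly shuffled, B replicates.

With the default B=500 one input yields 1 + 1 + 1 + 500 + 500 = 1003
derived sequences.  Shuffles use a Fisher–Yates permutation seeded from a
stable hash of (global seed, origin id, kind, replicate), so any single
replicate is independently reproducible.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .records import ProteinRecord
from .regions import SignalRegion

MODIFICATION_KINDS = ("reverse", "sp_remove", "sp_cterm", "sp_random", "random")
#: kinds whose output depends on a random draw, hence bootstrap-replicated
STOCHASTIC_KINDS = ("sp_random", "random")
#: kinds that act on the SP region only
SP_TARGETED_KINDS = ("sp_remove", "sp_cterm", "sp_random")

ALL_KINDS = ("original",) + MODIFICATION_KINDS

DEFAULT_BOOTSTRAP = 500


@dataclass(frozen=True)
class ModifiedSequence:
    """One derived sequence, tagged with its provenance."""

    origin_id: str
    kind: str
    replicate: int  # 0 for deterministic kinds, 1..B for stochastic kinds
    seed: int  # derived seed actually used (0 for deterministic kinds)
    sequence: str

    @property
    def uid(self) -> str:
        return f"{self.origin_id}|{self.kind}|{self.replicate}"


def derive_seed(global_seed: int, origin_id: str, kind: str, replicate: int) -> int:
    """Stable per-replicate seed from (global seed, origin id, kind, replicate)."""
    key = f"{global_seed}|{origin_id}|{kind}|{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


def mod_reverse(sequence: str) -> str:
    """Reverse the amino-acid order of the entire sequence."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    return sequence[::-1]


def _check_region(sequence: str, length: int) -> None:
    if not 1 <= length < len(sequence):
        raise ValueError(
            f"SP length must satisfy 1 <= L < {len(sequence)}, got {length}"
        )


def mod_sp_remove(sequence: str, length: int) -> str:
    """Delete the SP region [1..L]; the mature sequence remains."""
    _check_region(sequence, length)
    return sequence[length:]


def mod_sp_cterm(sequence: str, length: int) -> str:
    """Move the SP region from the N-terminus to the C-terminus."""
    _check_region(sequence, length)
    return sequence[length:] + sequence[:length]


def mod_sp_random(sequence: str, length: int, rng: random.Random) -> str:
    """Uniformly shuffle the SP residues in place; mature part untouched."""
    _check_region(sequence, length)
    sp = list(sequence[:length])
    rng.shuffle(sp)
    return "".join(sp) + sequence[length:]


def mod_random(sequence: str, rng: random.Random) -> str:
    """Uniformly shuffle the entire sequence."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    chars = list(sequence)
    rng.shuffle(chars)
    return "".join(chars)


def generate_set(
    record: ProteinRecord,
    region: SignalRegion,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> Iterator[ModifiedSequence]:
    """Yield all 2B+3 derived sequences for one record.

    Deterministic kinds (reverse, sp_remove, sp_cterm) are emitted once as
    replicate 0; stochastic kinds (sp_random, random) as replicates 1..B.
    Output for a given (seed, record) is byte-identical across calls.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1 (stochastic kinds need a replicate)")
    region.validate_for(record)
    seq, L = record.sequence, region.length

    yield ModifiedSequence(record.id, "reverse", 0, 0, mod_reverse(seq))
    yield ModifiedSequence(record.id, "sp_remove", 0, 0, mod_sp_remove(seq, L))
    yield ModifiedSequence(record.id, "sp_cterm", 0, 0, mod_sp_cterm(seq, L))
    for kind in STOCHASTIC_KINDS:
        for b in range(1, n_bootstrap + 1):
            s = derive_seed(seed, record.id, kind, b)
            rng = random.Random(s)
            if kind == "sp_random":
                derived = mod_sp_random(seq, L, rng)
            else:
                derived = mod_random(seq, rng)
            yield ModifiedSequence(record.id, kind, b, s, derived)


def expected_set_size(n_bootstrap: int = DEFAULT_BOOTSTRAP) -> int:
    """Number of derived sequences per input: 2B + 3."""
    return 2 * n_bootstrap + 3


def write_modified_fasta(
    modified: Iterable[ModifiedSequence], path: str | Path, width: int = 60
) -> int:
    """Write derived sequences with structured headers ``origin|kind|replicate|seed``.

    Returns the number of sequences written.  Output is append-safe: the
    caller controls file mode via a path (always truncates here).
    """
    n = 0
    with Path(path).open("w") as fh:
        for m in modified:
            fh.write(f">{m.origin_id}|{m.kind}|{m.replicate}|{m.seed}\n")
            for i in range(0, len(m.sequence), width):
                fh.write(m.sequence[i : i + width] + "\n")
            n += 1
    return n


def parse_modified_header(header: str) -> tuple[str, str, int, int]:
    """Split a structured header back into (origin_id, kind, replicate, seed)."""
    parts = header.split("|")
    if len(parts) != 4:
        raise ValueError(f"malformed modified-sequence header {header!r}")
    origin, kind, replicate, seed = parts
    if kind not in ALL_KINDS:
        raise ValueError(f"unknown modification kind {kind!r} in header {header!r}")
    return origin, kind, int(replicate), int(seed)


def read_modified_fasta(path: str | Path) -> list[ModifiedSequence]:
    """Read back a modified-sequence FASTA written by :func:`write_modified_fasta`."""
    from Bio import SeqIO

    out: list[ModifiedSequence] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        origin, kind, replicate, seed = parse_modified_header(entry.id)
        out.append(ModifiedSequence(origin, kind, replicate, seed, str(entry.seq).upper()))
    return out
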