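"""Scorer contract, synthetic SP-sensitive scorer, and score aggregation.

A *scorer* maps an admissible amino-acid sequence to a secretion score in
[0, 1].  Real analyses wrap an external command-line predictor (see
:class:`ExternalCommandScorer`); tests and synthetic studies use
:class:`SyntheticScorer`, a fully specified stand-in whose score rises
with SP-like N-terminal hydrophobicity:

    H     = max over all windows of length ``w`` inside the first
            ``scan_depth`` residues of the mean Kyte–Doolittle hydropathy
    raw   = b0 + a * logistic(k * (H - h0))
    score = clamp_[0,1](raw + Normal(0, sigma))        (noise optional)

This emulates the behaviour attributed to common-feature secretion
predictors, whose score is elevated by any sufficiently hydrophobic
N-terminal stretch — a real signal peptide or a look-alike.

Per-protein scores for bootstrap-replicated modifications are aggregated
as the arithmetic mean over replicates.
"""

from __future__ import annotations

import logging
import math
import random
import hashlib
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .modifications import ModifiedSequence, STOCHASTIC_KINDS
from .records import ProteinRecord, AMBIGUOUS_AA

logger = logging.getLogger(__name__)

SCORE_POLICIES = ("skip_and_flag", "error")


class ScorerContractError(RuntimeError):
    """A scorer broke its contract (score outside [0,1], missing output...)."""


@runtime_checkable
class Scorer(Protocol):
    """Contract: a total function from admissible sequence to score in [0,1]."""

    name: str
    min_length: int

    def score(self, sequence: str, uid: str | None = None) -> float:  # pragma: no cover
        ...


@dataclass(frozen=True)
class SyntheticScorerParams:
    """Parameters of the synthetic hydropathy scorer.

    window
        sliding-window width in residues over which hydropathy is averaged.
    scan_depth
        how far into the N-terminus windows are scanned, in residues.
    midpoint, steepness
        logistic location/slope on the hydropathy axis (Kyte–Doolittle units).
    baseline, span
        score = baseline .. baseline+span as hydrophobicity goes low → high.
    noise_sd
        standard deviation of additive Gaussian score noise (0 disables).
    """

    window: int = 8
    scan_depth: int = 45
    midpoint: float = 1.6
    steepness: float = 2.5
    baseline: float = 0.45
    span: float = 0.35
    noise_sd: float = 0.05
    hydropathy_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.baseline + self.span > 1:
            raise ValueError("require 0 <= baseline and baseline + span <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.window <= self.scan_depth:
            raise ValueError("require 1 <= window <= scan_depth")


def max_window_hydropathy(
    sequence: str,
    window: int,
    scan_depth: int,
    scale: Mapping[str, float],
) -> tuple[float, bool]:
    """Maximum mean hydropathy over all ``window``-wide windows fully inside
    the first ``min(scan_depth, len)`` residues.

    Returns ``(H, has_ambiguous)``; ambiguous residues contribute 0
    (neutral) and are flagged.
    """
    if len(sequence) < window:
        raise ValueError(
            f"sequence length {len(sequence)} < window {window}: cannot score"
        )
    prefix = sequence[: min(scan_depth, len(sequence))]
    ambiguous = False
    values = []
    for aa in prefix:
        v = scale.get(aa)
        if v is None:
            ambiguous = True
            v = 0.0
        values.append(v)
    # running-sum sliding window
    s = sum(values[:window])
    best = s
    for i in range(window, len(values)):
        s += values[i] - values[i - window]
        if s > best:
            best = s
    return best / window, ambiguous


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


class SyntheticScorer:
    """SP-sensitive synthetic scorer (see module docstring for the model).

    ``seed=None`` or ``params.noise_sd == 0`` makes the scorer fully
    deterministic.  With a seed, the noise draw is keyed on the sequence's
    ``uid`` (or the sequence itself), so scores are independent of batch
    order and splitting.
    """

    def __init__(self, params: SyntheticScorerParams | None = None, seed: int | None = None):
        self.params = params or SyntheticScorerParams()
        self.seed = seed
        self.name = "synthetic"
        self.min_length = self.params.window

    def raw_score(self, sequence: str) -> tuple[float, bool]:
        """Noise-free score and ambiguity flag."""
        p = self.params
        H, ambiguous = max_window_hydropathy(
            sequence, p.window, p.scan_depth, p.hydropathy_scale
        )
        raw = p.baseline + p.span * _logistic(p.steepness * (H - p.midpoint))
        return raw, ambiguous

    def score(self, sequence: str, uid: str | None = None) -> float:
        raw, _ = self.raw_score(sequence)
        if self.seed is None or self.params.noise_sd == 0:
            return raw
        key = f"{self.seed}|noise|{uid if uid is not None else sequence}".encode()
        noise_seed = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
        noise = random.Random(noise_seed).gauss(0.0, self.params.noise_sd)
        return min(1.0, max(0.0, raw + noise))


class ExternalCommandScorer:
    """Adapter around an external command-line predictor.

    ``command_template`` must contain ``{input}`` (FASTA path written by
    the adapter) and may contain ``{output}`` (table path the command
    writes; otherwise stdout is parsed).  The parsed table is whitespace-
    delimited with comment lines starting with ``#``; ``id_column`` and
    ``score_column`` are 0-based indices.  Scores outside [0,1], missing
    ids, or non-numeric values raise :class:`ScorerContractError`.
    """

    def __init__(
        self,
        command_template: str,
        id_column: int = 0,
        score_column: int = 1,
        min_length: int = 40,
        name: str = "external",
    ):
        if "{input}" not in command_template:
            raise ValueError("command_template must contain an {input} placeholder")
        self.command_template = command_template
        self.id_column = id_column
        self.score_column = score_column
        self.min_length = min_length
        self.name = name
        self._cache: dict[str, float] = {}

    def _parse_table(self, text: str, expected_ids: list[str]) -> dict[str, float]:
        scores: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                rid = fields[self.id_column]
                value = float(fields[self.score_column])
            except (IndexError, ValueError) as exc:
                raise ScorerContractError(
                    f"{self.name}: cannot parse score row {line!r}: {exc}"
                ) from exc
            if not 0.0 <= value <= 1.0:
                raise ScorerContractError(
                    f"{self.name}: score {value} for {rid!r} outside [0,1]"
                )
            scores[rid] = value
        missing = [rid for rid in expected_ids if rid not in scores]
        if missing:
            raise ScorerContractError(
                f"{self.name}: no score returned for ids {missing[:10]}"
            )
        return scores

    def score_many(self, named_sequences: Sequence[tuple[str, str]]) -> dict[str, float]:
        """Score a batch of (uid, sequence) pairs in one external invocation."""
        from .records import write_fasta

        with tempfile.TemporaryDirectory(prefix="spaudit_scorer_") as tmp:
            fasta = Path(tmp) / "batch.fasta"
            out = Path(tmp) / "scores.txt"
            write_fasta(
                (ProteinRecord(id=uid, sequence=seq) for uid, seq in named_sequences),
                fasta,
            )
            cmd = self.command_template.format(input=fasta, output=out)
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise ScorerContractError(
                    f"{self.name}: command failed with exit {proc.returncode}; "
                    f"stderr: {proc.stderr[-500:]}"
                )
            text = out.read_text() if "{output}" in self.command_template else proc.stdout
        return self._parse_table(text, [uid for uid, _ in named_sequences])

    def score(self, sequence: str, uid: str | None = None) -> float:
        key = uid if uid is not None else sequence
        if key not in self._cache:
            self._cache.update(self.score_many([(key, sequence)]))
        return self._cache[key]


def aggregate_bootstrap(replicate_scores: Sequence[float]) -> float:
    """Arithmetic mean of bootstrap replicate scores."""
    arr = np.asarray(replicate_scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty replicate-score vector")
    return float(arr.mean())


@dataclass
class ScoreTable:
    """Aggregated scores keyed by (origin_id, kind).

    ``table`` columns: origin_id, kind, n_replicates, mean_score, flags
    (semicolon-joined, empty string if none).  ``replicate_scores`` holds
    the per-replicate vectors for stochastic kinds when retained.
    """

    table: pd.DataFrame
    replicate_scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    COLUMNS = ("origin_id", "kind", "n_replicates", "mean_score", "flags")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        finite = self.table["mean_score"].dropna()
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("aggregated scores must lie in [0,1]")

    def scores_for(self, kind: str, ids: Sequence[str] | None = None) -> pd.Series:
        """Mean scores of one modification kind, indexed by origin_id."""
        sub = self.table[self.table["kind"] == kind]
        series = sub.set_index("origin_id")["mean_score"]
        if ids is not None:
            series = series.reindex(ids)
        return series

    @property
    def kinds(self) -> list[str]:
        return sorted(self.table["kind"].unique())

    def to_tsv(self, path: str | Path) -> None:
        """Write the aggregated table; formatting is fixed for byte-stable output."""
        with Path(path).open("w") as fh:
            fh.write("\t".join(self.COLUMNS) + "\n")
            for row in self.table.itertuples(index=False):
                score = "NA" if pd.isna(row.mean_score) else f"{row.mean_score:.12g}"
                fh.write(
                    f"{row.origin_id}\t{row.kind}\t{row.n_replicates}\t{score}\t{row.flags}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(
            path, sep="\t", dtype={"origin_id": str, "kind": str, "flags": str},
            na_values=["NA"], keep_default_na=False,
        )
        df["flags"] = df["flags"].fillna("")
        return cls(table=df)


def score_batch(
    scorer: Scorer,
    sequences: Iterable[ModifiedSequence | ProteinRecord],
    policy: str = "skip_and_flag",
) -> pd.DataFrame:
    """Score a batch, one row per sequence.

    Returns a DataFrame (origin_id, kind, replicate, score, flags).
    Sequences shorter than ``scorer.min_length`` are skipped with a
    ``short`` flag (policy ``skip_and_flag``) or raise (policy ``error``);
    ambiguous residues are flagged.  Output depends only on the sequences,
    never on batch order or splitting.
    """
    if policy not in SCORE_POLICIES:
        raise ValueError(f"policy must be one of {SCORE_POLICIES}, got {policy!r}")
    rows = []
    for item in sequences:
        if isinstance(item, ProteinRecord):
            origin, kind, replicate, seq = item.id, "original", 0, item.sequence
            uid = f"{item.id}|original|0"
        else:
            origin, kind, replicate, seq = (
                item.origin_id, item.kind, item.replicate, item.sequence,
            )
            uid = item.uid
        flags = []
        if set(seq) & AMBIGUOUS_AA:
            flags.append("ambiguous_residues")
        if len(seq) < scorer.min_length:
            if policy == "error":
                raise ValueError(
                    f"sequence {uid} length {len(seq)} < scorer minimum "
                    f"{scorer.min_length}"
                )
            flags.append("short")
            rows.append((origin, kind, replicate, np.nan, ";".join(flags)))
            continue
        value = scorer.score(seq, uid=uid)
        if not 0.0 <= value <= 1.0:
            raise ScorerContractError(
                f"{scorer.name}: score {value} for {uid} outside [0,1]"
            )
        rows.append((origin, kind, replicate, value, ";".join(flags)))
    return pd.DataFrame(
        rows, columns=["origin_id", "kind", "replicate", "score", "flags"]
    )


def build_score_table(per_sequence: pd.DataFrame, keep_replicates: bool = False) -> ScoreTable:
    """Aggregate per-sequence scores into a :class:`ScoreTable`.

    Stochastic kinds are averaged over their bootstrap replicates;
    deterministic kinds pass through.  Flags are unioned.
    """
    agg_rows = []
    replicate_store: dict[tuple[str, str], np.ndarray] = {}
    grouped = per_sequence.groupby(["origin_id", "kind"], sort=True)
    for (origin, kind), grp in grouped:
        scores = grp["score"].to_numpy(dtype=float)
        valid = scores[~np.isnan(scores)]
        flags = sorted(set(f for fl in grp["flags"] if fl for f in fl.split(";")))
        if valid.size == 0:
            mean = np.nan
        else:
            mean = aggregate_bootstrap(valid)
        n_rep = int(valid.size)
        if keep_replicates and kind in STOCHASTIC_KINDS:
            replicate_store[(origin, kind)] = valid
        agg_rows.append((origin, kind, n_rep, mean, ";".join(flags)))
    table = pd.DataFrame(agg_rows, columns=list(ScoreTable.COLUMNS))
    return ScoreTable(table=table, replicate_scores=replicate_store)
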