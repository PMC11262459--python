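"""Sequence records, amino-acid-level tokenization, and FASTA/CSV input-output.

Every other module consumes :class:`SequenceRecord` collections produced here.
Metadata (organism, growth temperature, melting temperature, thermal class)
travels either in FASTA header ``key=value`` pairs or in a CSV sidecar table;
on conflict the CSV wins.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: 20 canonical residues, in the conventional alphabetical one-letter order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Rare / ambiguous one-letter symbols accepted on input.
RARE_AA = "BJOUXZ"

#: The accepted 25-letter IUPAC amino-acid alphabet.
ALPHABET = frozenset(CANONICAL_AA + RARE_AA)

THERMOPHILIC = "thermophilic"
NON_THERMOPHILIC = "non_thermophilic"
UNLABELED = "unlabeled"
THERMAL_CLASSES = (THERMOPHILIC, NON_THERMOPHILIC, UNLABELED)

# Tokenizer vocabulary: 5 special symbols + 25 amino-acid letters = 30,
# mirroring the protBERT convention (J has no token of its own; like the
# other rare symbols it collapses to X at encoding time, but B/O/U/X/Z
# keep their vocabulary slots).
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
VOCAB = SPECIAL_TOKENS + tuple(sorted(set(CANONICAL_AA + "BOUXZ")))
TOKEN_TO_ID = {tok: i for i, tok in enumerate(VOCAB)}
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = (TOKEN_TO_ID[t] for t in SPECIAL_TOKENS)

#: Symbols remapped to X before encoding (ambiguity / non-standard residues).
RARE_TO_X = {c: "X" for c in "BJOUZ"}

MAX_RESIDUE_TOKENS = 512


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid records."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with optional thermal metadata.

    Parameters
    ----------
    id:
        Unique identifier within a collection.
    sequence:
        Uppercase residues over the 25-letter IUPAC amino-acid alphabet.
    organism:
        Free-text organism tag ("" if unknown).
    growth_temp:
        Source-organism growth temperature in °C, or None.
    melting_temp:
        Experimental melting temperature in °C, or None.
    thermal_class:
        One of ``thermophilic`` / ``non_thermophilic`` / ``unlabeled``.
    """

    id: str
    sequence: str
    organism: str = ""
    growth_temp: float | None = None
    melting_temp: float | None = None
    thermal_class: str = UNLABELED

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        seq = self.sequence.upper()
        if seq != self.sequence:
            object.__setattr__(self, "sequence", seq)
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue symbols {sorted(bad)}"
            )
        for name in ("growth_temp", "melting_temp"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not math.isfinite(v):
                    raise ValueError(f"record {self.id!r}: {name} must be finite")
                object.__setattr__(self, name, v)
        if self.thermal_class not in THERMAL_CLASSES:
            raise ValueError(
                f"record {self.id!r}: unknown thermal class {self.thermal_class!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_(self, **kwargs) -> "SequenceRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TokenizedSequence:
    """Token ids plus the map from token index back to residue index."""

    token_ids: tuple[int, ...]
    residue_positions: Mapping[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.token_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_positions)


def _check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


_META_KEYS = ("organism", "growth_temp", "melting_temp", "class")


def _parse_header_meta(description: str) -> dict:
    """Parse ``key=value`` pairs trailing the id in a FASTA description."""
    meta: dict = {}
    for part in description.split()[1:]:
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        if key not in _META_KEYS:
            continue
        if key in ("growth_temp", "melting_temp"):
            try:
                meta[key] = float(value)
            except ValueError as exc:
                raise FastaParseError(
                    f"non-numeric {key}={value!r} in header {description!r}"
                ) from exc
        elif key == "class":
            meta["thermal_class"] = value
        else:
            meta[key] = value
    return meta


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into sequence records.

    Headers are parsed as ``id [key=value]*`` with optional ``organism``,
    ``growth_temp``, ``melting_temp`` and ``class`` keys.  Sequences are
    uppercased.  Duplicate ids and malformed entries raise errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with path.open() as handle:
        first = handle.read(1)
        if first not in (">", ""):
            raise FastaParseError(f"{path}: line 1: expected '>' header")
        handle.seek(0)
        for i, bio in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            seq = str(bio.seq).upper()
            if not seq:
                raise FastaParseError(f"{path}: entry {i} ({bio.id!r}): empty sequence")
            meta = _parse_header_meta(bio.description)
            try:
                records.append(SequenceRecord(id=bio.id, sequence=seq, **meta))
            except ValueError as exc:
                raise FastaParseError(f"{path}: entry {i}: {exc}") from exc
    try:
        _check_unique_ids(records)
    except ValueError as exc:
        raise FastaParseError(f"{path}: {exc}") from exc
    return records


def _format_header(record: SequenceRecord) -> str:
    parts = []
    if record.organism:
        parts.append(f"organism={record.organism}")
    if record.growth_temp is not None:
        parts.append(f"growth_temp={record.growth_temp!r}")
    if record.melting_temp is not None:
        parts.append(f"melting_temp={record.melting_temp!r}")
    if record.thermal_class != UNLABELED:
        parts.append(f"class={record.thermal_class}")
    return " ".join(parts)


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write records to FASTA (60-column wrap), metadata in the header.

    Round trip: ``read_fasta(write_fasta(R)) == R``.
    """
    _check_unique_ids(records)
    path = Path(path)
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=_format_header(r))
        for r in records
    ]
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(bio_records)
    return path


_CSV_COLUMNS = ("id", "organism", "growth_temp", "melting_temp", "class")


def write_sidecar_csv(records: Sequence[SequenceRecord], path: str | Path) -> Path:
    """Write the five-column metadata sidecar (id, organism, growth_temp,
    melting_temp, class)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.organism,
                    "" if r.growth_temp is None else repr(r.growth_temp),
                    "" if r.melting_temp is None else repr(r.melting_temp),
                    r.thermal_class,
                ]
            )
    return path


def apply_sidecar_csv(
    records: Sequence[SequenceRecord], path: str | Path
) -> list[SequenceRecord]:
    """Merge metadata from a CSV sidecar into records; CSV values win on
    conflict.  Rows whose id matches no record are ignored."""
    table: dict[str, dict] = {}
    with Path(path).open(newline="") as handle:
        reader = csv.DictReader(handle)
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"sidecar {path}: missing columns {sorted(missing)}")
        for row in reader:
            meta: dict = {}
            if row["organism"]:
                meta["organism"] = row["organism"]
            for key in ("growth_temp", "melting_temp"):
                if row[key] not in ("", None):
                    meta[key] = float(row[key])
            if row["class"]:
                meta["thermal_class"] = row["class"]
            table[row["id"]] = meta
    return [r.with_(**table[r.id]) if r.id in table else r for r in records]


def tokenize(sequence: str, max_len: int = MAX_RESIDUE_TOKENS) -> TokenizedSequence:
    """Encode a sequence as ``[CLS] r1 ... rn [SEP]`` token ids.

    Rare symbols ``B J O U Z`` are mapped to ``X`` before encoding; residues
    beyond ``max_len`` are dropped from the tail (the N-terminal prefix is
    kept).  Token count is always ``min(len(sequence), max_len) + 2``.
    """
    if max_len < 1:
        raise ValueError("max_len must be positive")
    sequence = sequence.upper()
    for pos, ch in enumerate(sequence):
        if ch not in ALPHABET:
            raise ValueError(f"invalid residue {ch!r} at position {pos}")
    kept = sequence[:max_len]
    ids = [CLS_ID]
    positions: dict[int, int] = {}
    for res_idx, ch in enumerate(kept):
        ch = RARE_TO_X.get(ch, ch)
        positions[len(ids)] = res_idx
        ids.append(TOKEN_TO_ID[ch])
    ids.append(SEP_ID)
    return TokenizedSequence(token_ids=tuple(ids), residue_positions=positions)
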