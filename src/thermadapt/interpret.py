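"""Attention-score interpretability: per-residue profiles, the
high-attention-score (HAS) Tukey-fence statistic, amino-acid enrichment,
model comparison, homolog conservation cross-tabs, column entropy and
attention-to-structure mapping.

A residue is a HAS when its aggregated attention score strictly exceeds
``Q3 + 1.5 * IQR`` of its own sequence's score distribution (Tukey's upper
fence; quartiles by linear interpolation at position ``(n-1)p``).  How the
(layers × heads × tokens × tokens) attention stack is reduced to one score
per residue is an explicit choice carried on every profile:

* ``received_mean`` (default) — mean attention *received* by the residue's
  token over all layers, heads and source positions, special tokens excised;
* ``received_last_layer`` — same, last layer only;
* ``cls_row_last_layer`` — attention paid by the class token to the
  residue, last layer, head-averaged.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from biotite.sequence.align import get_sequence_identity

from .curation import align_global
from .encoder import AttentionTensorSet, EncoderModel
from .seqio import CANONICAL_AA, SequenceRecord, tokenize

AGGREGATIONS = ("received_mean", "received_last_layer", "cls_row_last_layer")

CONSERVED = "conserved"
NON_CONSERVED = "non_conserved"
INSERTION = "insertion"


@dataclass(frozen=True)
class AttentionProfile:
    """One non-negative attention score per residue of a sequence."""

    sequence_id: str
    scores: np.ndarray
    aggregation: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty vector")
        if not np.all(np.isfinite(scores)) or np.any(scores < 0):
            raise ValueError("scores must be finite and non-negative")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class HASMask:
    """Indices whose score strictly exceeds the Tukey upper fence."""

    threshold: float
    positions: frozenset[int]


def residue_attention(
    model: EncoderModel,
    record: SequenceRecord,
    aggregation: str = "received_mean",
) -> AttentionProfile:
    """Aggregate the model's attention stack into a per-residue profile."""
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; one of {AGGREGATIONS}")
    tokens = tokenize(record.sequence)
    att = model.capture_attention(tokens)
    scores = aggregate_attention(att, aggregation)
    return AttentionProfile(sequence_id=record.id, scores=scores, aggregation=aggregation)


def aggregate_attention(att: AttentionTensorSet, aggregation: str) -> np.ndarray:
    """Reduce an (L, H, T, T) attention stack to per-residue scores."""
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; one of {AGGREGATIONS}")
    residue_tokens = sorted(att.tokens.residue_positions)  # token indices
    m = att.matrices
    if aggregation == "received_mean":
        sub = m[:, :, residue_tokens, :][:, :, :, residue_tokens]
        return sub.mean(axis=(0, 1, 2))
    if aggregation == "received_last_layer":
        sub = m[-1][:, residue_tokens, :][:, :, residue_tokens]
        return sub.mean(axis=(0, 1))
    # cls_row_last_layer: attention from the class token (position 0)
    return m[-1][:, 0, residue_tokens].mean(axis=0)


def has_threshold(scores: Sequence[float]) -> float:
    """Tukey upper fence ``Q3 + 1.5 * (Q3 - Q1)`` of the scores.

    Quartiles use linear interpolation on the ordered sample at position
    ``(n-1) * p``.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one score")
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # numpy default = linear, (n-1)p
    return float(q3 + 1.5 * (q3 - q1))


def has_mask(profile: AttentionProfile) -> HASMask:
    """Flag positions whose score strictly exceeds the fence."""
    thr = has_threshold(profile.scores)
    positions = frozenset(int(i) for i in np.flatnonzero(profile.scores > thr))
    return HASMask(threshold=thr, positions=positions)


# -- enrichment --------------------------------------------------------------


def _composition(counter: Counter) -> dict[str, float]:
    total = sum(counter.values())
    return {aa: counter[aa] / total for aa in counter} if total else {}


def enrichment(
    records: Sequence[SequenceRecord],
    masks: Mapping[str, HASMask],
    class_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-class amino-acid background vs HAS frequency table.

    Background = residue composition of all sequences in the class; HAS
    frequency = composition of the HAS-flagged residues.  Both sum to 1
    per class over the amino acids present.  Returns columns
    (thermal_class, amino_acid, background_freq, has_freq, difference,
    ratio); the ratio is NaN for classes with zero HAS residues of that
    amino acid type when the background is also zero-free.
    """
    class_labels = class_labels or {r.id: r.thermal_class for r in records}
    bg: dict[str, Counter] = {}
    has: dict[str, Counter] = {}
    for r in records:
        cls = class_labels[r.id]
        bg.setdefault(cls, Counter()).update(r.sequence)
        mask = masks.get(r.id)
        if mask is None:
            continue
        has.setdefault(cls, Counter()).update(r.sequence[i] for i in mask.positions)
    rows = []
    for cls in sorted(bg):
        bg_freq = _composition(bg[cls])
        has_freq = _composition(has.get(cls, Counter()))
        for aa in sorted(set(bg_freq) | set(has_freq)):
            b = bg_freq.get(aa, 0.0)
            h = has_freq.get(aa, 0.0)
            rows.append(
                {
                    "thermal_class": cls,
                    "amino_acid": aa,
                    "background_freq": b,
                    "has_freq": h,
                    "difference": h - b,
                    "ratio": h / b if b > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows)


def has_frequencies(
    model: EncoderModel,
    records: Sequence[SequenceRecord],
    aggregation: str = "received_mean",
) -> dict[str, float]:
    """Corpus-wide HAS amino-acid frequency (sums to 1) for one model."""
    counter: Counter = Counter()
    for r in records:
        profile = residue_attention(model, r, aggregation)
        mask = has_mask(profile)
        counter.update(r.sequence[i] for i in mask.positions)
    return _composition(counter)


def compare_models(
    model_a: EncoderModel,
    model_b: EncoderModel,
    records: Sequence[SequenceRecord],
    aggregation: str = "received_mean",
) -> pd.DataFrame:
    """Paired per-amino-acid HAS frequencies of two models over a corpus
    (e.g. pre-trained backbone vs fine-tuned)."""
    fa = has_frequencies(model_a, records, aggregation)
    fb = has_frequencies(model_b, records, aggregation)
    aas = sorted(set(fa) | set(fb))
    return pd.DataFrame(
        {
            "amino_acid": aas,
            "freq_a": [fa.get(aa, 0.0) for aa in aas],
            "freq_b": [fb.get(aa, 0.0) for aa in aas],
        }
    )


# -- homolog comparison ------------------------------------------------------


@dataclass(frozen=True)
class HomologColumn:
    """One alignment column of a homolog pair."""

    label: str                      # conserved / non_conserved / insertion
    pos_a: int | None               # residue index in sequence a (None = gap)
    pos_b: int | None
    has_a: bool
    has_b: bool


@dataclass(frozen=True)
class HomologComparison:
    """Aligned HAS cross-tab of a homolog pair."""

    columns: tuple[HomologColumn, ...]
    identity: float
    has_counts: Mapping[str, int] = field(default_factory=dict)


def compare_homologs(
    profile_a: AttentionProfile,
    profile_b: AttentionProfile,
    seq_a: str,
    seq_b: str,
) -> HomologComparison:
    """Globally align two homologs and cross-tab HAS against conservation.

    Columns are labeled ``conserved`` (identical residues), ``non_conserved``
    (aligned mismatch) or ``insertion`` (gap in exactly one partner); HAS
    flags of both partners are attached per column, and HAS occurrences are
    counted per label (a column counts once per flagged partner).
    """
    if len(profile_a) != len(seq_a) or len(profile_b) != len(seq_b):
        raise ValueError("profiles must match sequence lengths")
    ali = align_global(seq_a, seq_b)
    identity = float(get_sequence_identity(ali, mode="all"))
    mask_a = has_mask(profile_a).positions
    mask_b = has_mask(profile_b).positions
    columns: list[HomologColumn] = []
    counts = {CONSERVED: 0, NON_CONSERVED: 0, INSERTION: 0}
    for ia, ib in ali.trace:
        pa = int(ia) if ia != -1 else None
        pb = int(ib) if ib != -1 else None
        if pa is None or pb is None:
            label = INSERTION
        elif seq_a[pa] == seq_b[pb]:
            label = CONSERVED
        else:
            label = NON_CONSERVED
        ha = pa is not None and pa in mask_a
        hb = pb is not None and pb in mask_b
        counts[label] += int(ha) + int(hb)
        columns.append(HomologColumn(label, pa, pb, ha, hb))
    return HomologComparison(columns=tuple(columns), identity=identity, has_counts=counts)


def column_entropy(columns: Sequence[Sequence[str]]) -> list[float | None]:
    """Shannon entropy (bits) per alignment column over the 20 canonical
    residues; gaps ('-') are ignored; all-gap columns yield None."""
    out: list[float | None] = []
    canonical = set(CANONICAL_AA)
    for col in columns:
        symbols = [c for c in col if c in canonical]
        if not symbols:
            out.append(None)
            continue
        counts = np.array(list(Counter(symbols).values()), dtype=float)
        p = counts / counts.sum()
        out.append(float(-(p * np.log2(p)).sum()))
    return out


# -- structure mapping -------------------------------------------------------


def write_bfactor_pdb(
    structure_file: str | Path,
    chain: str,
    profile: AttentionProfile,
    profile_sequence: str,
    out_file: str | Path,
    min_identity_warn: float = 0.9,
) -> Path:
    """Write a copy of a PDB with attention scores in the B-factor column.

    The profile's sequence is globally aligned to the chain's observed
    residue sequence; mapped residues get their score min–max scaled to
    [0, 100] (a constant profile maps to 0), unmapped residues get 0.
    Coordinates and everything else are unchanged.  A low alignment
    identity (< ``min_identity_warn``) triggers a warning.
    """
    import biotite.structure as struc
    from biotite.sequence import ProteinSequence
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(structure_file))
    atoms = pdb.get_structure(model=1)
    chain_mask = atoms.chain_id == chain
    if not chain_mask.any():
        raise ValueError(f"chain {chain!r} not present in {structure_file}")
    chain_atoms = atoms[chain_mask]
    res_ids, res_names = struc.get_residues(chain_atoms)
    one = "".join(
        ProteinSequence.convert_letter_3to1(n.capitalize())
        if len(n) == 3 else "X"
        for n in res_names
    ).upper()
    if len(profile) != len(profile_sequence):
        raise ValueError("profile must match its sequence length")
    ali = align_global(profile_sequence, one)
    identity = float(get_sequence_identity(ali, mode="all"))
    if identity < min_identity_warn:
        warnings.warn(
            f"profile/chain alignment identity {identity:.2f} below "
            f"{min_identity_warn:.2f}; B-factor mapping may be unreliable",
            stacklevel=2,
        )
    lo = float(profile.scores.min())
    hi = float(profile.scores.max())
    scaled = (
        np.zeros_like(profile.scores)
        if hi == lo
        else (profile.scores - lo) / (hi - lo) * 100.0
    )
    b_by_res_id: dict[int, float] = {}
    for ip, ic in ali.trace:
        if ip != -1 and ic != -1:
            b_by_res_id[int(res_ids[ic])] = float(scaled[int(ip)])
    b = np.zeros(atoms.array_length())
    for i in range(atoms.array_length()):
        if chain_mask[i]:
            b[i] = b_by_res_id.get(int(atoms.res_id[i]), 0.0)
    atoms.set_annotation("b_factor", b)
    out = PDBFile()
    out.set_structure(atoms)
    out_file = Path(out_file)
    out.write(str(out_file))
    return out_file
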