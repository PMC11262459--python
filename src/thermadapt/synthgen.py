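"""Synthetic protein corpora with the statistical structure the pipeline
assumes, so every stage is testable without external downloads.

The generator emulates four features of real thermostability data:

* two sequence classes differing in amino-acid composition — thermophilic
  proteomes are enriched in charged/hydrophobic residues (R, E, L, A, I, V)
  and depleted in deamidation-prone and lysine-type residues (K, Q, N);
* a bimodal melting-temperature distribution with a gap between the
  non-thermophilic (around 50 °C) and thermophilic (around 85 °C) regimes;
* homolog pairs at controlled sequence identity (substitutions, optional
  single indel block);
* ground-truth "signal" positions (implanted motifs) against which
  attention-based interpretability can be scored.

Sequences are i.i.d. draws from a per-class residue composition — no
positional grammar, domain architecture, or organism structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import CANONICAL_AA, NON_THERMOPHILIC, THERMOPHILIC, SequenceRecord

#: Residues shifted up in the thermophilic composition.
SIGNAL_UP = tuple("RELAIV")
#: Residues shifted down in the thermophilic composition.
SIGNAL_DOWN = tuple("KQN")

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class CompositionSpec:
    """Per-class residue composition over the 20 canonical residues.

    The non-thermophilic background is uniform; the thermophilic vector
    multiplies the background by ``1 + shift`` for R/E/L/A/I/V and
    ``1 - shift`` for K/Q/N, then renormalizes.  ``shift`` in [0, 1) is the
    separability dial: 0 makes the classes indistinguishable.
    """

    shift: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift < 1.0:
            raise ValueError("shift must be in [0, 1)")

    def probabilities(self, thermal_class: str) -> np.ndarray:
        p = np.full(20, 1.0 / 20.0)
        if thermal_class == THERMOPHILIC:
            for aa in SIGNAL_UP:
                p[_AA_INDEX[aa]] *= 1.0 + self.shift
            for aa in SIGNAL_DOWN:
                p[_AA_INDEX[aa]] *= 1.0 - self.shift
            p = p / p.sum()
        return p

    def signal_fraction_mean(self, thermal_class: str) -> float:
        """Expected fraction of residues in the up-shifted signal set."""
        p = self.probabilities(thermal_class)
        return float(sum(p[_AA_INDEX[aa]] for aa in SIGNAL_UP))


@dataclass(frozen=True)
class TmModel:
    """Two-regime melting-temperature model.

    ``Tm = mu_class + beta * (signal_fraction - class_mean_signal_fraction)
    + Normal(0, sigma)`` with class means 50 °C (non-thermophilic) and
    85 °C (thermophilic), mirroring the bimodal shape with a gap between
    the two regimes.  ``beta`` couples Tm to composition so the regression
    has within-class signal; ``sigma`` is observation noise in °C.
    """

    mu_non: float = 50.0
    mu_thermo: float = 85.0
    beta: float = 40.0
    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mu_non >= self.mu_thermo:
            raise ValueError("mu_non must be below mu_thermo")


@dataclass(frozen=True)
class HomologPairSpec:
    """A parent/homolog pair at controlled identity."""

    parent_length: int = 80
    target_identity: float = 0.5
    indel_block: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError("target identity must be in (0, 1]")


def sample_sequences(
    n: int,
    thermal_class: str,
    length_range: tuple[int, int] = (60, 160),
    comp: CompositionSpec | None = None,
    seed: int = 0,
    id_prefix: str | None = None,
) -> list[SequenceRecord]:
    """Draw ``n`` labeled records with i.i.d. residues from the class
    composition; lengths uniform over ``length_range`` (min 30)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 30:
        raise ValueError("minimum length is 30")
    comp = comp or CompositionSpec()
    p = comp.probabilities(thermal_class)
    rng = np.random.default_rng(seed)
    prefix = id_prefix or ("t" if thermal_class == THERMOPHILIC else "n")
    letters = np.array(list(CANONICAL_AA))
    records = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=L, p=p))
        records.append(
            SequenceRecord(id=f"{prefix}{i:05d}", sequence=seq,
                           organism="synthetic", thermal_class=thermal_class)
        )
    return records


def implant_motif(
    record: SequenceRecord, motif: str, n_copies: int, seed: int = 0
) -> tuple[SequenceRecord, list[int]]:
    """Overwrite ``n_copies`` non-overlapping windows with ``motif``.

    Returns the modified record and the sorted list of 0-based residue
    positions covered by the implants (the ground truth for attention
    recovery).
    """
    L = len(record.sequence)
    m = len(motif)
    if m > L:
        raise ValueError("motif longer than sequence")
    if n_copies == 0:
        return record, []
    rng = np.random.default_rng(seed)
    starts: list[int] = []
    candidates = list(range(0, L - m + 1))
    rng.shuffle(candidates)
    for s in candidates:
        if all(s + m <= t or t + m <= s for t in starts):
            starts.append(s)
            if len(starts) == n_copies:
                break
    if len(starts) < n_copies:
        raise ValueError("sequence too short for requested motif copies")
    seq = list(record.sequence)
    positions: list[int] = []
    for s in starts:
        seq[s : s + m] = motif
        positions.extend(range(s, s + m))
    return record.with_(sequence="".join(seq)), sorted(positions)


def _signal_fraction(sequence: str) -> float:
    up = set(SIGNAL_UP)
    return sum(c in up for c in sequence) / len(sequence)


def sample_tm(
    record: SequenceRecord,
    model: TmModel | None = None,
    comp: CompositionSpec | None = None,
    seed: int = 0,
) -> float:
    """Draw a melting temperature for a class-labeled record."""
    model = model or TmModel()
    comp = comp or CompositionSpec()
    if record.thermal_class == THERMOPHILIC:
        mu = model.mu_thermo
    elif record.thermal_class == NON_THERMOPHILIC:
        mu = model.mu_non
    else:
        raise ValueError(f"record {record.id!r} has no thermal class")
    centred = _signal_fraction(record.sequence) - comp.signal_fraction_mean(
        record.thermal_class
    )
    rng = np.random.default_rng(seed)
    return float(mu + model.beta * centred + rng.normal(0.0, model.sigma))


def mutate_to_identity(
    parent: SequenceRecord,
    target_identity: float,
    seed: int = 0,
    indel_block: int = 0,
    new_id: str | None = None,
) -> SequenceRecord:
    """Create a homolog by substituting ``round((1 - target) * L)`` distinct
    positions to different residues, plus an optional single inserted block.

    Without an indel the ungapped identity to the parent is exactly the
    target (up to rounding of the substitution count).
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    seq = list(parent.sequence)
    L = len(seq)
    n_sub = round((1.0 - target_identity) * L)
    for pos in rng.choice(L, size=n_sub, replace=False):
        current = seq[pos]
        choices = [aa for aa in CANONICAL_AA if aa != current]
        seq[pos] = str(rng.choice(choices))
    if indel_block > 0:
        at = int(rng.integers(0, L + 1))
        block = "".join(rng.choice(list(CANONICAL_AA), size=indel_block))
        seq[at:at] = list(block)
    return parent.with_(
        id=new_id or f"{parent.id}_hom", sequence="".join(seq)
    )


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of a full synthetic corpus."""

    n_per_class: int = 200
    length_range: tuple[int, int] = (60, 160)
    comp: CompositionSpec = field(default_factory=CompositionSpec)
    tm: TmModel = field(default_factory=TmModel)
    n_families: int = 0           # 0 = fully independent sequences
    homolog_identities: tuple[float, ...] = (0.3, 0.5, 0.7, 0.85, 0.9)
    motif: str = "RRELV"
    motif_copies: int = 0


@dataclass
class Benchmark:
    """A generated corpus plus every piece of ground truth."""

    records: list[SequenceRecord]
    homolog_pairs: list[tuple[str, str, float]]   # (parent, homolog, identity)
    signal_positions: dict[str, list[int]]
    family_of: dict[str, str]
    manifest: dict

    def by_class(self, thermal_class: str) -> list[SequenceRecord]:
        return [r for r in self.records if r.thermal_class == thermal_class]


def make_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> Benchmark:
    """Generate a balanced two-class corpus with melting temperatures,
    optional family structure, homolog pairs and motif ground truth.

    With ``n_families > 0``, each class is organized into families: family
    founders are drawn independently and members are derived from their
    founder at 55–90% identity, giving the clustered structure real protein
    databases have.  Everything (records, Tm draws, pairs, manifest) is
    reproducible from the seed.
    """
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    signal_positions: dict[str, list[int]] = {}
    family_of: dict[str, str] = {}
    for cls in (NON_THERMOPHILIC, THERMOPHILIC):
        prefix = "t" if cls == THERMOPHILIC else "n"
        if config.n_families > 0:
            founders = sample_sequences(
                config.n_families, cls, config.length_range, config.comp,
                seed=int(rng.integers(2**31)), id_prefix=f"{prefix}fam",
            )
            members: list[SequenceRecord] = []
            i = 0
            while len(members) < config.n_per_class:
                founder = founders[i % len(founders)]
                if i < len(founders):
                    members.append(founder)
                    family_of[founder.id] = founder.id
                else:
                    ident = float(rng.uniform(0.55, 0.9))
                    hom = mutate_to_identity(
                        founder, ident, seed=int(rng.integers(2**31)),
                        new_id=f"{founder.id}m{i:05d}",
                    )
                    members.append(hom)
                    family_of[hom.id] = founder.id
                i += 1
            class_records = members
        else:
            class_records = sample_sequences(
                config.n_per_class, cls, config.length_range, config.comp,
                seed=int(rng.integers(2**31)), id_prefix=prefix,
            )
            for r in class_records:
                family_of[r.id] = r.id
        for r in class_records:
            if config.motif_copies > 0 and cls == THERMOPHILIC:
                r, pos = implant_motif(
                    r, config.motif, config.motif_copies,
                    seed=int(rng.integers(2**31)),
                )
                signal_positions[r.id] = pos
            tm = sample_tm(r, config.tm, config.comp, seed=int(rng.integers(2**31)))
            records.append(r.with_(melting_temp=tm))

    # homolog pairs at controlled identity: thermophilic parent, mutated
    # partner labeled non-thermophilic (the hard-negative construction)
    homolog_pairs: list[tuple[str, str, float]] = []
    thermo = [r for r in records if r.thermal_class == THERMOPHILIC]
    for j, ident in enumerate(config.homolog_identities):
        parent = thermo[j % len(thermo)]
        hom = mutate_to_identity(
            parent, ident, seed=int(rng.integers(2**31)),
            new_id=f"hom{j:03d}",
        ).with_(thermal_class=NON_THERMOPHILIC, melting_temp=None)
        records.append(hom)
        family_of[hom.id] = family_of.get(parent.id, parent.id)
        homolog_pairs.append((parent.id, hom.id, ident))

    manifest = {
        "seed": seed,
        "n_per_class": config.n_per_class,
        "length_range": list(config.length_range),
        "composition_shift": config.comp.shift,
        "tm_model": {
            "mu_non": config.tm.mu_non, "mu_thermo": config.tm.mu_thermo,
            "beta": config.tm.beta, "sigma": config.tm.sigma,
        },
        "n_families": config.n_families,
        "motif": config.motif,
        "motif_copies": config.motif_copies,
        "homolog_pairs": [
            {"parent": a, "homolog": b, "identity": c} for a, b, c in homolog_pairs
        ],
        "signal_positions": {k: v for k, v in sorted(signal_positions.items())},
        "family_of": {k: v for k, v in sorted(family_of.items())},
        "record_ids": [r.id for r in records],
    }
    return Benchmark(records, homolog_pairs, signal_positions, family_of, manifest)


def manifest_json(benchmark: Benchmark) -> str:
    """Canonical (byte-stable) JSON form of the manifest."""
    return json.dumps(benchmark.manifest, sort_keys=True, indent=2)
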