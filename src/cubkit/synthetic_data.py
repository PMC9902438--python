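"""Synthetic codon-usage tables and plasmid-like sequences with known truth.

Codon frequency vectors are compositional (64 entries summing to 1), so
class-conditional usage profiles are modeled as Dirichlet draws around a
class mean, with a concentration parameter controlling within-class
spread and a divergence knob controlling between-class separation.
Sequences are built from i.i.d. multinomial codon sampling: a pure
codon stream for null-model calibration, start/stop-framed coding
sequences, and plasmid-like constructs that embed coding sequences in
random background.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_core import CODON_ALPHABET, CODON_INDEX, CodonFrequencies, GeneticCode, STANDARD_CODE
from .io_formats import LabeledUsageTable, USAGE_META_COLUMNS

__all__ = [
    "ClassProfile",
    "SyntheticTruth",
    "base_distribution",
    "gen_class_profiles",
    "gen_usage_table",
    "gen_codon_sequence",
    "gen_coding_sequence",
    "gen_plasmid_like",
    "permuted_reference",
]

#: Default Dirichlet concentration: scales the class mean into Dirichlet
#: parameters; 500 gives within-class frequency jitter comparable to a
#: table of organisms sharing a usage profile while keeping classes tight.
DEFAULT_CONCENTRATION = 500.0


@dataclass(frozen=True)
class ClassProfile:
    """One class's mean codon usage and Dirichlet concentration."""

    label: str
    mean_frequencies: CodonFrequencies
    concentration: float = DEFAULT_CONCENTRATION

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class TrueORF:
    start: int
    stop: int
    source_id: str


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated artifact: embedded ORFs for sequences,
    generating profiles and row labels for tables."""

    orfs: tuple[TrueORF, ...] = ()
    profiles: tuple[ClassProfile, ...] = ()
    row_labels: tuple[str, ...] = ()


def base_distribution(seed: int = 0, jitter: float = 0.6) -> CodonFrequencies:
    """The shared base codon distribution: uniform 1/64 with a seeded
    log-normal multiplicative perturbation.

    The default ``jitter`` (log-scale sigma 0.6) gives roughly a 10-15x
    ratio between the rarest and commonest codon, matching the dynamic
    range of real per-organism usage tables; a flat vector would
    understate how biased real codon usage is.
    """
    rng = np.random.default_rng(seed)
    weights = np.exp(rng.normal(0.0, jitter, size=64))
    return CodonFrequencies(weights / weights.sum())


def gen_class_profiles(
    n_classes: int,
    divergence: float,
    seed: int = 0,
    concentration: float = DEFAULT_CONCENTRATION,
) -> list[ClassProfile]:
    """Class-conditional usage profiles with tunable separation.

    Each class mean is the convex combination
    ``(1 - divergence) * base + divergence * q_c`` with ``q_c`` an
    independent Dirichlet(0.5) draw, so pairwise total-variation
    distance between class means scales exactly linearly with
    ``divergence``: 0 gives identical profiles, 1 gives well-separated
    ones.
    """
    if not 2 <= n_classes <= 64:
        raise ValueError("n_classes must be in 2..64")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = base_distribution(seed).values
    profiles = []
    for c in range(n_classes):
        q = rng.dirichlet(np.full(64, 0.5))
        mean = (1.0 - divergence) * base + divergence * q
        profiles.append(
            ClassProfile(
                label=f"class{c}",
                mean_frequencies=CodonFrequencies(mean / mean.sum()),
                concentration=concentration,
            )
        )
    return profiles


def gen_usage_table(
    profiles: Sequence[ClassProfile],
    n_per_class: int,
    seed: int = 0,
) -> tuple[LabeledUsageTable, SyntheticTruth]:
    """A labeled usage table of Dirichlet draws around each profile mean.

    Row ``i`` of class ``c`` is a draw from
    ``Dirichlet(concentration * mean_c)``; labels go in the ``Kingdom``
    column (``DNAtype`` is 0 throughout).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for profile in profiles:
        alpha = profile.concentration * profile.mean_frequencies.values
        draws = rng.dirichlet(np.maximum(alpha, 1e-8), size=n_per_class)
        for j in range(n_per_class):
            rows.append(draws[j])
            labels.append(profile.label)
    X = np.asarray(rows)
    frame = pd.DataFrame(X, columns=list(CODON_ALPHABET))
    frame.insert(0, "Kingdom", labels)
    frame.insert(1, "DNAtype", 0)
    frame.insert(2, "SpeciesID", [str(100000 + i) for i in range(len(labels))])
    frame.insert(3, "Ncodons", rng.integers(10_000, 2_000_000, size=len(labels)))
    frame.insert(4, "SpeciesName", [f"synthetic organism {i}" for i in range(len(labels))])
    table = LabeledUsageTable(frame=frame[USAGE_META_COLUMNS + list(CODON_ALPHABET)])
    truth = SyntheticTruth(profiles=tuple(profiles), row_labels=tuple(labels))
    return table, truth


def gen_codon_sequence(
    reference: CodonFrequencies,
    n_codons: int,
    seed: int = 0,
) -> str:
    """A sequence of ``n_codons`` codons drawn i.i.d. from ``reference``.

    No start/stop structure is imposed — this is the exact multinomial
    null model of the goodness-of-fit test, used for Type-I calibration.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(64, size=n_codons, p=reference.values)
    return "".join(CODON_ALPHABET[i] for i in draws)


def gen_coding_sequence(
    reference: CodonFrequencies,
    n_codons: int,
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """A framed coding sequence: start codon, multinomial body, stop codon.

    The body's ``n_codons - 2`` codons are i.i.d. from ``reference``
    restricted to non-stop codons (renormalized); the final stop codon
    is sampled from the reference's stop-codon mass, or uniformly over
    stops when the reference gives stops zero mass.  Total length is
    ``3 * n_codons``.
    """
    if n_codons < 3:
        raise ValueError("n_codons must be >= 3")
    rng = np.random.default_rng(seed)
    stops = sorted(code.stop_codons)
    stop_idx = [CODON_INDEX[c] for c in stops]
    start = sorted(code.start_codons)[0]

    body_p = reference.values.copy()
    body_p[stop_idx] = 0.0
    if body_p.sum() <= 0:
        raise ValueError("reference has no mass on non-stop codons")
    body_p /= body_p.sum()
    body = rng.choice(64, size=n_codons - 2, p=body_p)

    stop_mass = reference.values[stop_idx]
    stop_p = stop_mass / stop_mass.sum() if stop_mass.sum() > 0 else np.full(len(stops), 1 / len(stops))
    stop = stops[rng.choice(len(stops), p=stop_p)]
    return start + "".join(CODON_ALPHABET[i] for i in body) + stop


def gen_plasmid_like(
    background_n: int,
    orfs: Sequence[tuple[CodonFrequencies, int]],
    seed: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[str, SyntheticTruth]:
    """Embed coding sequences at random offsets in uniform random background.

    ``orfs`` is a list of (reference distribution, n_codons) pairs; each
    generated coding sequence is inserted (never overwritten, so the
    embedded regions stay intact and non-overlapping) at a random
    offset into ``background_n`` bases of i.i.d. uniform background.
    The returned truth lists each embedded ORF's (start, stop)
    coordinates, which are guaranteed recoverable by enumeration.
    """
    if background_n < 0:
        raise ValueError("background_n must be >= 0")
    rng = np.random.default_rng(seed)
    pieces = [
        gen_coding_sequence(ref, n, seed=int(rng.integers(2**31)), code=code)
        for ref, n in orfs
    ]
    offsets = sorted(int(o) for o in rng.integers(0, background_n + 1, size=len(pieces)))
    background = "".join(rng.choice(list("ACGU"), size=background_n))
    seq_parts = []
    truth_orfs = []
    cursor = 0  # background consumed so far
    built_len = 0
    for i, (off, piece) in enumerate(zip(offsets, pieces)):
        seq_parts.append(background[cursor:off])
        built_len += off - cursor
        truth_orfs.append(TrueORF(start=built_len, stop=built_len + len(piece) - 3, source_id=f"orf{i}"))
        seq_parts.append(piece)
        built_len += len(piece)
        cursor = off
    seq_parts.append(background[cursor:])
    seq = "".join(seq_parts)
    assert len(seq) == background_n + sum(len(p) for p in pieces)
    for t in truth_orfs:  # embedded ORFs must be intact in the final sequence
        assert seq[t.start : t.start + 3] in code.start_codons
        assert seq[t.stop : t.stop + 3] in code.stop_codons
    return seq, SyntheticTruth(orfs=tuple(truth_orfs))


def permuted_reference(reference: CodonFrequencies, seed: int = 0) -> CodonFrequencies:
    """The reference with its frequencies randomly permuted across codons —
    a strongly divergent distribution with identical bin-value multiset,
    used as the alternative in power checks."""
    rng = np.random.default_rng(seed)
    return CodonFrequencies(rng.permutation(reference.values))


def save_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "orfs": [dict(start=t.start, stop=t.stop, source_id=t.source_id) for t in truth.orfs],
        "row_labels": list(truth.row_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
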