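"""Canonical codon alphabet, sequence normalization, and codon counting.

The internal nucleotide alphabet is RNA (``A``, ``C``, ``G``, ``U``);
DNA input is converted on normalization (``T`` -> ``U``).  All codon
frequency vectors in the package are laid out over a single fixed
alphabet of the 64 codons in lexicographic order with ``A < C < G < U``,
so that vector positions are stable everywhere (counting, goodness-of-fit
testing, feature ranking, classification).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

__all__ = [
    "RNA_BASES",
    "CODON_ALPHABET",
    "CODON_INDEX",
    "GeneticCode",
    "STANDARD_CODE",
    "CodonCounts",
    "CodonFrequencies",
    "normalize_sequence",
    "has_ambiguous",
    "count_codons",
    "to_frequencies",
    "codon_to_amino_acid",
]

RNA_BASES = ("A", "C", "G", "U")

#: The 64 codons in canonical (lexicographic, A<C<G<U) order.
CODON_ALPHABET: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(RNA_BASES, repeat=3)
)

#: Codon -> position in the canonical order.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODON_ALPHABET)}


def _standard_table() -> dict[str, str]:
    """Standard genetic code as codon -> three-letter amino acid / 'STOP'."""
    bio = CodonTable.unambiguous_rna_by_id[1]
    table = {}
    for codon in CODON_ALPHABET:
        if codon in bio.stop_codons:
            table[codon] = "STOP"
        else:
            table[codon] = seq3(bio.forward_table[codon])
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping with start/stop annotations.

    Parameters
    ----------
    table:
        Mapping from each of the 64 codons to an amino-acid symbol or
        ``"STOP"``.
    start_codons:
        Codons treated as translation starts (default ``{AUG}``).
    stop_codons:
        Codons treated as translation stops (default ``{UGA, UAG, UAA}``).

    Both sets are configurable because some organisms use alternative
    start codons or reassign stop codons.
    """

    table: Mapping[str, str] = field(default_factory=_standard_table)
    start_codons: frozenset[str] = frozenset({"AUG"})
    stop_codons: frozenset[str] = frozenset({"UGA", "UAG", "UAA"})

    def __post_init__(self) -> None:
        missing = set(CODON_ALPHABET) - set(self.table)
        if missing:
            raise ValueError(f"genetic code missing codons: {sorted(missing)}")
        if not self.start_codons or not self.stop_codons:
            raise ValueError("start and stop codon sets must be non-empty")
        if self.start_codons & self.stop_codons:
            raise ValueError("start and stop codon sets must be disjoint")
        object.__setattr__(self, "start_codons", frozenset(self.start_codons))
        object.__setattr__(self, "stop_codons", frozenset(self.stop_codons))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneticCode":
        """Load a code from JSON: ``[{codon, amino_acid, is_start, is_stop}, ...]``."""
        entries = json.loads(Path(path).read_text())
        table = {e["codon"]: e["amino_acid"] for e in entries}
        starts = frozenset(e["codon"] for e in entries if e.get("is_start"))
        stops = frozenset(e["codon"] for e in entries if e.get("is_stop"))
        return cls(table=table, start_codons=starts, stop_codons=stops)


#: The standard genetic code with AUG start and UGA/UAG/UAA stops.
STANDARD_CODE = GeneticCode()


def normalize_sequence(raw: str) -> str:
    """Uppercase a nucleotide string and convert DNA ``T`` to RNA ``U``.

    Characters outside ``{A, C, G, U}`` (IUPAC ambiguity codes, gaps)
    are preserved; use :func:`has_ambiguous` to flag them.  Idempotent.
    """
    if not raw:
        raise ValueError("empty sequence")
    return raw.upper().replace("T", "U")


def has_ambiguous(seq: str) -> bool:
    """True if the normalized sequence contains non-ACGU characters."""
    return any(ch not in "ACGU" for ch in seq)


@dataclass(frozen=True)
class CodonCounts:
    """Integer counts over the 64-codon alphabet.

    ``counts[i]`` is the count of ``CODON_ALPHABET[i]``; ``skipped``
    records in-frame triplets that contained ambiguous characters and
    were excluded from counting.
    """

    counts: np.ndarray
    skipped: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (64,):
            raise ValueError("counts must have length 64")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def total_n(self) -> int:
        return int(self.counts.sum())

    def as_dict(self, nonzero_only: bool = True) -> dict[str, int]:
        items = zip(CODON_ALPHABET, self.counts.tolist())
        return {c: n for c, n in items if n or not nonzero_only}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, int], skipped: int = 0) -> "CodonCounts":
        arr = np.zeros(64, dtype=np.int64)
        for codon, n in mapping.items():
            arr[CODON_INDEX[codon]] = n
        return cls(arr, skipped=skipped)


@dataclass(frozen=True)
class CodonFrequencies:
    """A length-64 frequency vector over the canonical codon order.

    Entries lie in [0, 1] and sum to 1 within 1e-6.  Restricted-subset
    vectors (frequencies renormalized over a codon subset, zeros
    elsewhere) also satisfy this: their retained entries sum to 1.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.shape != (64,):
            raise ValueError("frequency vector must have length 64")
        if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies sum to {arr.sum():.8f}, expected 1")
        object.__setattr__(self, "values", arr)

    def as_dict(self, nonzero_only: bool = True) -> dict[str, float]:
        items = zip(CODON_ALPHABET, self.values.tolist())
        return {c: f for c, f in items if f or not nonzero_only}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "CodonFrequencies":
        arr = np.zeros(64, dtype=np.float64)
        for codon, f in mapping.items():
            arr[CODON_INDEX[codon]] = f
        return cls(arr)

    def __getitem__(self, codon: str) -> float:
        return float(self.values[CODON_INDEX[codon]])


def count_codons(
    seq: str,
    include_stop: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> CodonCounts:
    """Count consecutive non-overlapping in-frame codons from position 0.

    The sequence length must be a multiple of 3.  Triplets containing
    ambiguous characters are skipped and tallied in ``skipped``.  With
    ``include_stop=False`` the final triplet is excluded when it is a
    stop codon of ``code``.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    triplets = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not include_stop and triplets and triplets[-1] in code.stop_codons:
        triplets = triplets[:-1]
    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    for t in triplets:
        idx = CODON_INDEX.get(t)
        if idx is None:
            skipped += 1
        else:
            counts[idx] += 1
    if counts.sum() == 0:
        raise ValueError("no countable codons")
    return CodonCounts(counts, skipped=skipped)


def to_frequencies(counts: CodonCounts) -> CodonFrequencies:
    """Frequencies = counts / total count."""
    n = counts.total_n
    if n == 0:
        raise ValueError("cannot compute frequencies of zero total count")
    return CodonFrequencies(counts.counts / n)


def codon_to_amino_acid(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Three-letter amino-acid symbol (or ``STOP``) for one codon."""
    if codon not in CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    return code.table[codon]


def frequencies_from_sequence(
    seq: str,
    include_stop: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[CodonFrequencies, int]:
    """Convenience: count codons then normalize; returns (frequencies, n)."""
    counts = count_codons(seq, include_stop=include_stop, code=code)
    return to_frequencies(counts), counts.total_n


def codons_of(indices: Iterable[int]) -> list[str]:
    """Map canonical-order indices back to codon strings."""
    return [CODON_ALPHABET[i] for i in indices]
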