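"""Potential-ORF enumeration and goodness-of-fit rejection.

A *potential ORF* is any (start codon, stop codon) index pair in the
same reading frame with the stop downstream of the start — deliberately
permissive: under the default ``all_pairs`` pairing, pairs that span
intermediate in-frame stops are kept, so the enumeration upper-bounds
every plausible coding region.  Each candidate's in-frame codon
frequencies are then tested against a reference (population) codon
usage distribution with a chi-square or Cressie–Read goodness-of-fit
test; candidates whose codon usage is implausible under the reference
are rejected.

The chi-square test needs counts, so observed counts are reconstructed
as ``frequency x n`` rounded by largest remainder (total preserved
exactly).  Codons with zero population frequency are removed from both
sides before testing (the expected-count denominator forbids zeros) and
the expected counts are rescaled to the retained observed total; the
Cressie–Read power-divergence statistic (lambda = 2/3) instead keeps
all 64 bins, since observed-zero bins contribute nothing and
expected-zero bins with observations force rejection.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import (
    CODON_ALPHABET,
    CODON_INDEX,
    CodonFrequencies,
    GeneticCode,
    STANDARD_CODE,
    count_codons,
    to_frequencies,
)

__all__ = [
    "PotentialORF",
    "GOFResult",
    "enumerate_potential_orfs",
    "orf_frequencies",
    "largest_remainder_counts",
    "chi_square_gof",
    "cressie_read_gof",
    "restrict_to_subset",
    "screen_orfs",
]

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGU", "UGCA")

CRESSIE_READ_LAMBDA = 2.0 / 3.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class PotentialORF:
    """A candidate coding region: 0-based first-base indices of its start
    and stop codons, in one reading frame.

    ``n_codons`` counts the in-frame codons from start through stop
    inclusive.  On the minus strand, coordinates refer to the reverse
    complement read left-to-right (``strand='-'``); for circular input,
    ``stop >= len(seq)`` marks an origin-crossing candidate on the
    unwrapped (doubled) coordinate line.
    """

    start: int
    stop: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("stop index must exceed start index")
        if (self.stop - self.start) % 3 != 0:
            raise ValueError("start and stop are not in the same frame")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")

    @property
    def n_codons(self) -> int:
        return (self.stop - self.start) // 3 + 1


def _scan_one_strand(
    seq: str,
    code: GeneticCode,
    pairing: str,
    min_codons: int,
    strand: str,
    max_span: int | None = None,
) -> list[PotentialORF]:
    n = len(seq)
    starts: list[list[int]] = [[], [], []]
    stops: list[list[int]] = [[], [], []]
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon in code.start_codons:
            starts[i % 3].append(i)
        elif codon in code.stop_codons:
            stops[i % 3].append(i)
    orfs: list[PotentialORF] = []
    for frame in range(3):
        frame_stops = stops[frame]
        for s in starts[frame]:
            j = bisect_right(frame_stops, s)
            candidates = frame_stops[j : j + 1] if pairing == "first_stop" else frame_stops[j:]
            for t in candidates:
                if max_span is not None and t + 3 - s > max_span:
                    break
                orf = PotentialORF(s, t, strand)
                if orf.n_codons >= min_codons:
                    orfs.append(orf)
    return orfs


def enumerate_potential_orfs(
    seq: str,
    code: GeneticCode = STANDARD_CODE,
    strand_mode: str = "forward",
    circular: bool = False,
    pairing: str = "all_pairs",
    min_codons: int = 0,
) -> list[PotentialORF]:
    """Enumerate all potential ORFs of a normalized sequence.

    Parameters
    ----------
    strand_mode:
        ``forward`` scans the given strand only; ``both`` also scans the
        reverse complement (reported with ``strand='-'`` in reverse-
        complement coordinates).
    circular:
        Additionally scan the doubled sequence for candidates crossing
        the origin (start inside the first copy, stop beyond it, span at
        most the sequence length).
    pairing:
        ``all_pairs`` records every downstream in-frame stop for each
        start (the permissive rule); ``first_stop`` keeps only each
        start's nearest in-frame stop.
    min_codons:
        Drop candidates with fewer in-frame codons (start and stop
        included) than this.

    Results are sorted by (strand, start, stop).
    """
    if pairing not in {"all_pairs", "first_stop"}:
        raise ValueError(f"unknown pairing {pairing!r}")
    if strand_mode not in {"forward", "both"}:
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    strands = [("+", seq)]
    if strand_mode == "both":
        strands.append(("-", reverse_complement(seq)))

    orfs: list[PotentialORF] = []
    n = len(seq)
    for strand, s in strands:
        orfs.extend(_scan_one_strand(s, code, pairing, min_codons, strand))
        if circular:
            doubled = s + s
            wrapped = [
                o
                for o in _scan_one_strand(doubled, code, pairing, min_codons, strand, max_span=n)
                if o.start < n and o.stop + 3 > n
            ]
            orfs.extend(wrapped)
    orfs.sort(key=lambda o: (o.strand, o.start, o.stop))
    return orfs


def orf_frequencies(
    seq: str,
    orf: PotentialORF,
    include_stop: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[CodonFrequencies, int]:
    """In-frame codon frequencies of one candidate; returns (freqs, n counted)."""
    source = seq if orf.strand == "+" else reverse_complement(seq)
    if orf.stop + 3 > len(source):  # origin-crossing candidate on circular input
        source = source + source
    sub = source[orf.start : orf.stop + 3]
    counts = count_codons(sub, include_stop=include_stop, code=code)
    return to_frequencies(counts), counts.total_n


def largest_remainder_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    """Integer counts ~ freqs*n with the total preserved exactly.

    Floors each product, then distributes the remaining units to the
    largest fractional remainders (ties: lower index first).
    """
    raw = np.asarray(freqs, dtype=np.float64) * n
    base = np.floor(raw).astype(np.int64)
    short = int(n - base.sum())
    if short:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


@dataclass(frozen=True)
class GOFResult:
    """Outcome of one goodness-of-fit test of sample vs. population codon usage."""

    method: str
    statistic: float
    df: int
    p_value: float
    retained_codons: tuple[str, ...]
    removed_codons: tuple[str, ...]
    rejected: bool
    alpha: float


def chi_square_gof(
    sample_freq: CodonFrequencies,
    sample_n: int,
    population_freq: CodonFrequencies,
    alpha: float = 0.05,
) -> GOFResult:
    """Pearson chi-square goodness of fit of a codon sample to a reference.

    Observed counts ``O_i`` are the sample frequencies times ``sample_n``
    (largest-remainder rounding); codons with zero population frequency
    are removed from both sides, and expected counts ``E_i`` are the
    retained population frequencies renormalized and scaled to the
    retained observed total.  The statistic is ``sum (O_i - E_i)^2 / E_i``
    with ``k - 1`` degrees of freedom over ``k`` retained codons; the
    null (the sample follows the reference distribution) is rejected
    when the statistic exceeds the upper-``alpha`` chi-square critical
    value, equivalently ``p < alpha``.
    """
    if sample_n <= 0:
        raise ValueError("sample_n must be positive")
    pop = population_freq.values
    if not pop.any():
        raise ValueError("all population frequencies are zero")
    observed = largest_remainder_counts(sample_freq.values, sample_n)
    mask = pop > 0
    k = int(mask.sum())
    if k < 2:
        raise ValueError("degenerate test: fewer than 2 retained codons")
    obs = observed[mask]
    n_ret = int(obs.sum())
    if n_ret == 0:
        raise ValueError("degenerate test: no observed counts on retained codons")
    expected = pop[mask] / pop[mask].sum() * n_ret
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return GOFResult(
        method="chi2",
        statistic=statistic,
        df=df,
        p_value=p,
        retained_codons=tuple(np.array(CODON_ALPHABET)[mask]),
        removed_codons=tuple(np.array(CODON_ALPHABET)[~mask]),
        rejected=bool(p < alpha),
        alpha=alpha,
    )


def cressie_read_gof(
    sample_freq: CodonFrequencies,
    sample_n: int,
    population_freq: CodonFrequencies,
    alpha: float = 0.05,
) -> GOFResult:
    """Cressie–Read power-divergence goodness of fit (lambda = 2/3).

    All 64 codon bins are retained.  The statistic is

        2 / (lambda (lambda + 1)) * sum O_i [ (O_i / E_i)^lambda - 1 ]

    with ``E_i = population_freq_i * sample_n``.  Bins with ``O_i = 0``
    contribute nothing, so zero-population bins are tolerated as long as
    they are unobserved; an observed count on a zero-expectation bin
    yields an infinite statistic (certain rejection).
    """
    if sample_n <= 0:
        raise ValueError("sample_n must be positive")
    pop = population_freq.values
    if not pop.any():
        raise ValueError("all population frequencies are zero")
    lam = CRESSIE_READ_LAMBDA
    observed = largest_remainder_counts(sample_freq.values, sample_n).astype(np.float64)
    expected = pop * sample_n
    pos = observed > 0
    if (expected[pos] == 0).any():
        statistic = float("inf")
    else:
        o, e = observed[pos], expected[pos]
        statistic = float(2.0 / (lam * (lam + 1.0)) * (o * ((o / e) ** lam - 1.0)).sum())
    df = 63
    p = float(stats.chi2.sf(statistic, df))
    return GOFResult(
        method="cressie_read",
        statistic=statistic,
        df=df,
        p_value=p,
        retained_codons=CODON_ALPHABET,
        removed_codons=(),
        rejected=bool(p < alpha),
        alpha=alpha,
    )


def restrict_to_subset(
    freqs: CodonFrequencies,
    n: int,
    subset: Sequence[str],
) -> tuple[CodonFrequencies | None, int, bool]:
    """Restrict a frequency vector to a codon subset and renormalize.

    Counts are reconstructed as ``freqs x n`` (largest remainder),
    non-subset codons dropped, and the rest renormalized; the effective
    n is the retained count total.  Returns ``(restricted, effective_n,
    untestable)`` — when the subset carries zero mass the vector is
    untestable (``None, 0, True``), which screening reports rather than
    raising.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = sorted(CODON_INDEX[c] for c in subset)
    counts = largest_remainder_counts(freqs.values, n)
    kept = np.zeros(64, dtype=np.int64)
    kept[idx] = counts[idx]
    eff_n = int(kept.sum())
    if eff_n == 0:
        return None, 0, True
    return CodonFrequencies(kept / eff_n), eff_n, False


_GOF_FUNCS = {"chi2": chi_square_gof, "cressie_read": cressie_read_gof}


def screen_orfs(
    seq: str,
    reference: CodonFrequencies,
    method: str = "chi2",
    alpha: float = 0.05,
    codon_subset: Sequence[str] | None = None,
    include_stop: bool = True,
    code: GeneticCode = STANDARD_CODE,
    strand_mode: str = "forward",
    circular: bool = False,
    pairing: str = "all_pairs",
    min_codons: int = 0,
) -> pd.DataFrame:
    """Enumerate the potential ORFs of ``seq`` and test each against ``reference``.

    Returns a DataFrame with one row per candidate, sorted by (strand,
    start, stop): columns ``start``, ``stop``, ``strand``, ``n_codons``,
    ``n_tested``, ``statistic``, ``df``, ``p_value``, ``rejected``,
    ``flag`` (empty, or ``untestable`` when a codon-subset restriction
    leaves no observed counts).  ``start``/``stop`` are 0-based first
    bases of the start/stop codons; ``end`` is the 0-based half-open end
    of the candidate (stop + 3).

    With ``codon_subset`` both the sample and the reference are
    restricted to the subset and renormalized before testing, mirroring
    screening with only the most phylogenetically influential codons.
    """
    if method not in _GOF_FUNCS:
        raise ValueError(f"unknown method {method!r}")
    gof = _GOF_FUNCS[method]

    ref = reference
    if codon_subset is not None:
        idx = [CODON_INDEX[c] for c in codon_subset]
        mass = reference.values[idx].sum()
        if mass <= 0:
            raise ValueError("reference has zero mass on the requested codon subset")
        vals = np.zeros(64)
        vals[idx] = reference.values[idx] / mass
        ref = CodonFrequencies(vals)

    orfs = enumerate_potential_orfs(
        seq, code=code, strand_mode=strand_mode, circular=circular,
        pairing=pairing, min_codons=min_codons,
    )
    rows = []
    n_rejected = n_untestable = 0
    for orf in orfs:
        freqs, n = orf_frequencies(seq, orf, include_stop=include_stop, code=code)
        flag = ""
        if codon_subset is not None:
            freqs, n, untestable = restrict_to_subset(freqs, n, codon_subset)
            if untestable:
                n_untestable += 1
                rows.append(
                    dict(start=orf.start, stop=orf.stop, end=orf.stop + 3,
                         strand=orf.strand, n_codons=orf.n_codons, n_tested=0,
                         statistic=np.nan, df=0, p_value=np.nan,
                         rejected=False, flag="untestable")
                )
                continue
        result = gof(freqs, n, ref, alpha=alpha)
        n_rejected += result.rejected
        rows.append(
            dict(start=orf.start, stop=orf.stop, end=orf.stop + 3,
                 strand=orf.strand, n_codons=orf.n_codons, n_tested=n,
                 statistic=result.statistic, df=result.df,
                 p_value=result.p_value, rejected=result.rejected, flag=flag)
        )
    logger.info(
        "screened %d potential ORFs: %d rejected at alpha=%g, %d untestable",
        len(rows), n_rejected, alpha, n_untestable,
    )
    columns = ["start", "stop", "end", "strand", "n_codons", "n_tested",
               "statistic", "df", "p_value", "rejected", "flag"]
    return pd.DataFrame(rows, columns=columns)
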