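"""Readers and writers: FASTA, labeled codon-usage tables, reference
frequency vectors, and screening/ranking reports.

The usage-table dialect is the CUTG-derived CSV used by public
per-organism codon-usage datasets: columns ``Kingdom``, ``DNAtype``,
``SpeciesID``, ``Ncodons``, ``SpeciesName`` and 64 codon-frequency
columns named by RNA codon spelling.  Deposited frequency values are
rounded, so row sums are accepted within 1e-3 on load and renormalized
to machine precision internally.

All coordinates written to reports are 0-based; ``end`` columns are
half-open.  Report headers state this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codon_core import CODON_ALPHABET, CodonFrequencies, has_ambiguous, normalize_sequence

__all__ = [
    "SequenceRecord",
    "KingdomGrouping",
    "default_kingdom_grouping",
    "LabeledUsageTable",
    "read_fasta",
    "write_fasta",
    "read_usage_table",
    "write_usage_table",
    "read_reference_frequencies",
    "write_report",
    "read_report",
    "load_published_kingdom_rankings",
]

logger = logging.getLogger(__name__)

USAGE_META_COLUMNS = ["Kingdom", "DNAtype", "SpeciesID", "Ncodons", "SpeciesName"]

#: Header comment stamped on every TSV report.
COORDINATE_NOTE = "# coordinates: 0-based; 'end' columns are half-open"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    sequence: str  # normalized RNA alphabet
    ambiguous: bool


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized (RNA-alphabet) sequence records."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, line {lineno} precedes any '>' header"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                sequence=seq,
                ambiguous=has_ambiguous(seq),
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.id == rec.description else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass(frozen=True)
class KingdomGrouping:
    """Mapping from source division codes to the 5-way kingdom scheme."""

    mapping: Mapping[str, str]

    LABELS = ("arc", "bct", "euk", "phg", "vrl")

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(self.LABELS)
        if bad:
            raise ValueError(f"grouping maps onto unknown labels: {sorted(bad)}")

    def __getitem__(self, code: str) -> str:
        return self.mapping[code]

    def __contains__(self, code: str) -> bool:
        return code in self.mapping

    @classmethod
    def from_json(cls, path: str | Path) -> "KingdomGrouping":
        data = json.loads(Path(path).read_text())
        return cls(mapping=data["mapping"] if "mapping" in data else data)


def default_kingdom_grouping() -> KingdomGrouping:
    """The shipped CUTG-division -> {arc,bct,euk,phg,vrl} collapse."""
    text = resources.files("cubkit.data").joinpath("kingdom_grouping.json").read_text()
    return KingdomGrouping(mapping=json.loads(text)["mapping"])


@dataclass
class LabeledUsageTable:
    """Organisms x 64 codon frequencies with kingdom and DNA-type labels.

    ``frame`` keeps the full table (meta columns + 64 codon columns in
    canonical order); ``X`` is the float matrix view used by ranking and
    classification.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in USAGE_META_COLUMNS + list(CODON_ALPHABET) if c not in self.frame]
        if missing:
            raise ValueError(f"usage table missing columns: {missing}")
        self.frame = self.frame[USAGE_META_COLUMNS + list(CODON_ALPHABET)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(CODON_ALPHABET)].to_numpy(dtype=np.float64)

    @property
    def kingdom(self) -> np.ndarray:
        return self.frame["Kingdom"].to_numpy()

    @property
    def dna_type(self) -> np.ndarray:
        return self.frame["DNAtype"].to_numpy(dtype=int)

    def labels(self, which: str) -> np.ndarray:
        if which == "kingdom":
            return self.kingdom
        if which == "dnatype":
            return self.dna_type.astype(str)
        raise ValueError(f"unknown label column {which!r}")

    def reference_for(self, species_id: str) -> CodonFrequencies:
        rows = self.frame[self.frame["SpeciesID"].astype(str) == str(species_id)]
        if rows.empty:
            raise KeyError(f"organism {species_id!r} not found in usage table")
        return CodonFrequencies(rows.iloc[0][list(CODON_ALPHABET)].to_numpy(dtype=np.float64))


def read_usage_table(
    path: str | Path,
    grouping: KingdomGrouping | None = None,
    strict: bool = False,
    sum_tolerance: float = 1e-3,
) -> LabeledUsageTable:
    """Load a CUTG-dialect labeled usage table.

    Rows whose frequency sum deviates from 1 by more than
    ``sum_tolerance``, whose ``DNAtype`` is outside 0..12, or whose
    kingdom code is absent from ``grouping`` are dropped (``strict=False``,
    with the drop count logged) or fatal (``strict=True``).  Retained
    rows are renormalized to sum to 1 exactly.

    When no row's kingdom code appears in the grouping at all (e.g. a
    synthetic table, or one already carrying grouped labels), labels
    pass through unchanged instead of every row being dropped.
    """
    if grouping is None:
        grouping = default_kingdom_grouping()
    df = pd.read_csv(path, dtype={"Kingdom": str, "SpeciesID": str, "SpeciesName": str})
    missing = [c for c in CODON_ALPHABET if c not in df.columns]
    if missing:
        raise ValueError(f"usage table is missing codon columns: {missing}")
    for col in USAGE_META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"usage table is missing column {col!r}")

    apply_grouping = bool(df["Kingdom"].isin(grouping.mapping).any())
    if not apply_grouping:
        logger.info("read_usage_table: no kingdom codes match the grouping; labels kept as-is")

    codon_cols = list(CODON_ALPHABET)
    freq = df[codon_cols].apply(pd.to_numeric, errors="coerce")
    sums = freq.sum(axis=1)
    ok = (
        freq.notna().all(axis=1)
        & ((sums - 1.0).abs() <= sum_tolerance)
        & (freq.ge(0).all(axis=1))
        & pd.to_numeric(df["DNAtype"], errors="coerce").between(0, 12)
    )
    if apply_grouping:
        ok &= df["Kingdom"].isin(grouping.mapping)
    n_dropped = int((~ok).sum())
    if n_dropped and strict:
        raise ValueError(f"{n_dropped} rows failed usage-table validation (strict mode)")
    if n_dropped:
        logger.info("read_usage_table: dropped %d invalid rows", n_dropped)
    df = df[ok].copy()
    freq = freq[ok]
    df[codon_cols] = freq.div(freq.sum(axis=1), axis=0)
    if apply_grouping:
        df["Kingdom"] = df["Kingdom"].map(grouping.mapping)
    df["DNAtype"] = pd.to_numeric(df["DNAtype"]).astype(int)
    df["Ncodons"] = pd.to_numeric(df["Ncodons"]).astype(int)
    return LabeledUsageTable(frame=df)


def write_usage_table(table: LabeledUsageTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.10g")


def read_reference_frequencies(
    source: str | Path | LabeledUsageTable,
    organism_id: str | None = None,
    sum_tolerance: float = 1e-3,
) -> CodonFrequencies:
    """Load a single 64-codon reference frequency vector.

    ``source`` may be a JSON file (``{codon: frequency}`` covering all
    64 codons), a single-row delimited file with the 64 codon columns,
    or a :class:`LabeledUsageTable` together with ``organism_id``.
    Vectors summing to 1 within ``sum_tolerance`` are renormalized;
    larger deviations are an error.
    """
    if isinstance(source, LabeledUsageTable):
        if organism_id is None:
            raise ValueError("organism_id is required with a usage table source")
        return source.reference_for(organism_id)
    path = Path(source)
    if path.suffix.lower() == ".json":
        mapping = json.loads(path.read_text())
        missing = set(CODON_ALPHABET) - set(mapping)
        if missing:
            raise ValueError(f"reference vector missing codons: {sorted(missing)}")
        values = np.array([float(mapping[c]) for c in CODON_ALPHABET])
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        missing = [c for c in CODON_ALPHABET if c not in df.columns]
        if missing:
            raise ValueError(f"reference vector missing codons: {missing}")
        if organism_id is not None and "SpeciesID" in df.columns:
            df = df[df["SpeciesID"].astype(str) == str(organism_id)]
            if df.empty:
                raise KeyError(f"organism {organism_id!r} not found")
        values = df.iloc[0][list(CODON_ALPHABET)].to_numpy(dtype=np.float64)
    total = values.sum()
    if abs(total - 1.0) > sum_tolerance:
        raise ValueError(f"reference frequencies sum to {total:.6f}; expected 1 within {sum_tolerance}")
    return CodonFrequencies(values / total)


def write_report(results: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a result table as TSV (with coordinate-convention header) or JSON."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(COORDINATE_NOTE + "\n")
            results.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    elif format == "json":
        payload = {"coordinates": "0-based; 'end' columns are half-open",
                   "rows": json.loads(results.to_json(orient="records", double_precision=10))}
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", comment="#")
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text())["rows"])
    raise ValueError(f"unknown report format {format!r}")


def load_published_kingdom_rankings() -> dict[str, list[str]]:
    """The shipped reference codon rankings (lasso path and RF importance)
    for five-way kingdom prediction; most influential first."""
    text = resources.files("cubkit.data").joinpath("kingdom_rankings.json").read_text()
    data = json.loads(text)
    return {"lasso": data["lasso"], "random_forest": data["random_forest"]}
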