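"""Shared domain types and file-format I/O.

The pipeline's on-disk surface is deliberately plain: GTF exon records for
transcript structure, TSV expression matrices (features x samples), FASTA for
transcript sequences, and a JSON run manifest next to every result set.
Coordinates are 0-based half-open internally; GTF's 1-based inclusive
convention is converted at the boundary and nowhere else.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("isoswitch")

#: IUPAC nucleotide codes accepted in FASTA input.
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PipelineError):
    """A file could not be parsed."""


class ValidationError(PipelineError):
    """An in-memory object violates its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's exon chain on the genome.

    Exons are 0-based half-open ``(start, end)`` intervals, sorted ascending
    by start regardless of strand, non-overlapping and non-empty.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"{self.transcript_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def length(self) -> int:
        """Total exonic length in bp (the mature-transcript length)."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; both sequences written 5'->3'.

    The reverse primer anneals to the sense strand's complement, i.e. its
    reverse complement is what appears in the sense-strand cDNA sequence.
    """

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < 10:
                raise ValidationError(f"{name} primer shorter than 10 nt")
            if not set(seq) <= set("ACGT"):
                raise ValidationError(f"{name} primer contains non-ACGT characters")


@dataclass
class SampleInfo:
    """Per-sample metadata: optional group label, tissue, pairing, survival."""

    sample_id: str
    group: str | None = None
    tissue: str | None = None
    pair_id: str | None = None
    survival_time: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        if self.group not in (None, "low", "high"):
            raise ValidationError(f"group must be low/high, got {self.group!r}")
        if self.tissue not in (None, "tumor", "normal"):
            raise ValidationError(f"tissue must be tumor/normal, got {self.tissue!r}")
        if (self.survival_time is None) != (self.event is None):
            raise ValidationError(
                f"{self.sample_id}: survival_time and event must be given together"
            )
        if self.survival_time is not None and self.survival_time < 0:
            raise ValidationError(f"{self.sample_id}: negative survival time")
        if self.event not in (None, 0, 1):
            raise ValidationError(f"{self.sample_id}: event must be 0 or 1")


VALID_UNITS = ("count", "TPM", "fraction")


@dataclass
class ExpressionMatrix:
    """A features x samples numeric table with a feature->gene mapping.

    ``values`` is a DataFrame indexed by feature id with sample-id columns.
    ``unit`` is one of ``count``, ``TPM`` or ``fraction``.  NaN entries are
    only allowed for ``fraction`` matrices, where they mark samples in which
    the gene was not expressed (fractions undefined).
    """

    values: pd.DataFrame
    unit: str
    feature_level: str = "transcript"
    gene_of: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.feature_level not in ("transcript", "gene"):
            raise ValidationError(f"unknown feature_level {self.feature_level!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicated feature id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicated sample id {dup!r}")
        if self.gene_of is None:
            self.gene_of = pd.Series(self.values.index, index=self.values.index)
        else:
            self.gene_of = self.gene_of.reindex(self.values.index)
            if self.gene_of.isna().any():
                missing = self.gene_of.index[self.gene_of.isna()][0]
                raise ValidationError(f"feature {missing!r} has no gene mapping")
        arr = self.values.to_numpy(dtype=float)
        if self.unit != "fraction" and np.isnan(arr).any():
            raise ValidationError("missing values are not allowed in this matrix")
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("expression values must be non-negative")
        if self.unit == "TPM":
            sums = np.asarray(arr.sum(axis=0))
            bad = (sums > 0) & ~np.isclose(sums, 1e6, rtol=1e-6)
            if bad.any():
                col = self.values.columns[np.flatnonzero(bad)[0]]
                raise ValidationError(
                    f"TPM column {col!r} sums to {sums[bad][0]:.6g}, expected 1e6"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def features_of_gene(self, gene_id: str) -> list[str]:
        return list(self.gene_of.index[self.gene_of == gene_id])

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", self.gene_of)
        out.index.name = (
            "transcript_id" if self.feature_level == "transcript" else "gene_id"
        )
        if self.feature_level == "gene":
            out = out.drop(columns="gene_id")
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a 9-column GTF file into transcript models.

    GTF's 1-based inclusive intervals become 0-based half-open internally.
    Transcript feature lines without any exon child are excluded with a
    logged warning; malformed lines raise :class:`ParseError` naming the
    line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # transcript -> (gene, chrom, strand)
    declared: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "transcript"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            attr = _parse_attributes(attrs)
            if "gene_id" not in attr or "transcript_id" not in attr:
                raise ParseError(
                    f"{path}: line {lineno}: missing gene_id or transcript_id attribute"
                )
            tid, gid = attr["transcript_id"], attr["gene_id"]
            if tid in meta and meta[tid] != (gid, chrom, strand):
                raise ParseError(f"{path}: line {lineno}: inconsistent records for {tid!r}")
            meta.setdefault(tid, (gid, chrom, strand))
            if tid not in declared:
                declared.append(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append((start - 1, end))
    models = []
    for tid in declared:
        gid, chrom, strand = meta[tid]
        if not exons.get(tid):
            logger.warning("transcript %s has zero exons; excluded", tid)
            continue
        models.append(
            TranscriptModel(gid, tid, chrom, strand, tuple(sorted(exons[tid])))
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{m.chrom}\tisoswitch\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path, unit: str, feature_level: str = "transcript"
) -> ExpressionMatrix:
    """Read a TSV expression table.

    Transcript-level tables carry ``transcript_id`` then ``gene_id`` as the
    first two columns; gene-level tables have only the id column.  Ragged
    rows, missing values, negatives and duplicate ids are all rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns.empty:
        raise ParseError(f"{path}: empty table")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    gene_of = None
    if feature_level == "transcript" and len(df.columns) and df.columns[0] == "gene_id":
        gene_of = df["gene_id"]
        df = df.drop(columns="gene_id")
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged rows or missing values")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value ({exc})") from exc
    return ExpressionMatrix(values, unit=unit, feature_level=feature_level, gene_of=gene_of)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ParseError(
                f"{path}: {record.id}: non-IUPAC characters {sorted(bad)}"
            )
        out[record.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    params: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write result tables as TSV plus a JSON run manifest.

    Each table is written as ``<name>.tsv`` with its columns in the order
    given.  The manifest records parameters, seed and library versions so a
    run can be reproduced exactly.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        written.append(p)
    manifest = {
        "parameters": dict(params or {}),
        "seed": seed,
        "tables": [p.name for p in written],
        "versions": {
            "isoswitch": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mp)
    return written


def sample_table(samples: Iterable[SampleInfo]) -> pd.DataFrame:
    """Tabulate SampleInfo records (fixed column order)."""
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "tissue": s.tissue,
            "pair_id": s.pair_id,
            "survival_time": s.survival_time,
            "event": s.event,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "tissue", "pair_id", "survival_time", "event"])
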