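"""Readers and writers for the genomic inputs every other stage consumes.

All coordinates are held 0-based, half-open ``[start, end)`` internally —
the native convention of BED/narrowPeak. GTF input (1-based, closed) is
converted once, on read. The TSS of a ``+`` gene is ``start``; for a ``-``
gene it is ``end - 1``, the last covered base, so the TSS always lies
inside the half-open span.

Chromosome names are matched by exact string equality throughout the
package; no ``chr`` prefix aliasing is attempted, and downstream
operations warn when peak chromosomes are absent from the annotation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "Peak",
    "PeakSet",
    "GeneSet",
    "DEGTable",
    "ParseError",
    "ValidationError",
    "read_annotation",
    "write_annotation",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_set",
    "write_gene_set",
    "read_deg_table",
    "write_deg_table",
]


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


def _tss_for(strand: str, start: int, end: int) -> int:
    return start if strand == "+" else end - 1


@dataclass(frozen=True)
class GeneRecord:
    """One gene: span ``[start, end)`` on ``chrom`` with a strand-aware TSS."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    tss: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.tss == -1:
            object.__setattr__(self, "tss", _tss_for(self.strand, self.start, self.end))
        expected = _tss_for(self.strand, self.start, self.end)
        if self.tss != expected:
            raise ValidationError(f"{self.gene_id}: tss {self.tss} inconsistent with strand/span (expected {expected})")


class GenomeAnnotation:
    """An ordered collection of :class:`GeneRecord` with unique gene ids."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        self._by_id: dict[str, GeneRecord] = {}
        for rec in self.records:
            if rec.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r} in annotation")
            self._by_id[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeAnnotation) and self.records == other.records

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def chroms(self) -> set[str]:
        return {r.chrom for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.gene_id, r.chrom, r.strand, r.start, r.end, r.tss) for r in self.records],
            columns=["gene_id", "chrom", "strand", "start", "end", "tss"],
        )


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_annotation(path: str | Path, format: str = "tss_tsv") -> GenomeAnnotation:
    """Read a gene annotation from a GTF (gene features only) or a 5-column TSV.

    The TSV carries ``gene_id, chrom, strand, start, end`` with a header and
    0-based half-open coordinates. GTF coordinates (1-based closed) are
    shifted on read; only ``gene`` feature lines are used.
    """
    path = Path(path)
    if format == "gtf":
        return _read_gtf(path)
    if format != "tss_tsv":
        raise ValueError(f"unknown annotation format {format!r}")
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        want = ["gene_id", "chrom", "strand", "start", "end"]
        if header[: len(want)] != want:
            raise ParseError(f"{path}: expected columns {want}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 columns, got {len(parts)}")
            try:
                rec = GeneRecord(parts[0], parts[1], parts[2], int(parts[3]), int(parts[4]))
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return GenomeAnnotation(records)


def _read_gtf(path: Path) -> GenomeAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            if parts[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(parts[8])
            if m is None:
                raise ParseError(f"{path}:{lineno}: no gene_id attribute")
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            # GTF is 1-based closed; internal convention is 0-based half-open.
            records.append(GeneRecord(m.group(1), parts[0], parts[6], start1 - 1, end1))
    return GenomeAnnotation(records)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Peak:
    """One narrowPeak row (BED6+4), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0  # -log10; -1 = absent
    q_value: float = -1.0
    summit_offset: int = -1  # bp from start; -1 = absent

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"peak {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.summit_offset != -1 and not (0 <= self.summit_offset < self.end - self.start):
            raise ValidationError(f"peak {self.name!r}: summit offset {self.summit_offset} outside peak")
        if self.signal_value < 0:
            raise ValidationError(f"peak {self.name!r}: signalValue must be >= 0")

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when the summit is absent."""
        if self.summit_offset == -1:
            return self.start + (self.end - self.start) // 2
        return self.start + self.summit_offset


@dataclass
class PeakSet:
    """All ChIP peaks of one TF, sorted by (chrom, start, end)."""

    tf_name: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def chroms(self) -> set[str]:
        return {p.chrom for p in self.peaks}


def read_narrowpeak(path: str | Path, tf_name: str) -> PeakSet:
    """Read a 10-column narrowPeak file into a :class:`PeakSet`."""
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 10:
                raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(parts)}")
            try:
                peak = Peak(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    name=parts[3],
                    score=int(parts[4]),
                    strand=parts[5],
                    signal_value=float(parts[6]),
                    p_value=float(parts[7]),
                    q_value=float(parts[8]),
                    summit_offset=int(parts[9]),
                )
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return PeakSet(tf_name=tf_name, peaks=peaks)


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peakset.peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}\t"
                f"{p.signal_value:g}\t{p.p_value:g}\t{p.q_value:g}\t{p.summit_offset}\n"
            )


@dataclass
class GeneSet:
    """A named gene set, optionally with subgroup labels on a subset of genes."""

    name: str
    genes: frozenset[str]
    subgroups: Mapping[str, str] = field(default_factory=dict)  # gene_id -> label

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        stray = set(self.subgroups) - self.genes
        if stray:
            raise ValidationError(f"gene set {self.name!r}: subgroup labels for genes outside the set: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set TSV (``gene_id`` column, optional ``subgroup``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'gene_id'")
    genes = frozenset(df["gene_id"])
    if len(genes) != len(df):
        raise ValidationError(f"{path}: duplicated gene ids in gene set")
    subgroups: dict[str, str] = {}
    if "subgroup" in df.columns:
        sub = df.dropna(subset=["subgroup"])
        subgroups = dict(zip(sub["gene_id"], sub["subgroup"]))
    return GeneSet(name=name or path.stem, genes=genes, subgroups=subgroups)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    rows = [(g, gene_set.subgroups.get(g, "")) for g in sorted(gene_set.genes)]
    pd.DataFrame(rows, columns=["gene_id", "subgroup"]).to_csv(path, sep="\t", index=False)


class DEGTable:
    """Per-gene differential-expression results: log2 fold change and FDR q."""

    COLUMNS = ["gene_id", "log2fc", "qvalue"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ParseError(f"DEG table missing columns: {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["log2fc"] = pd.to_numeric(frame["log2fc"], errors="raise")
        frame["qvalue"] = pd.to_numeric(frame["qvalue"], errors="raise")
        if frame["gene_id"].duplicated().any():
            dups = frame.loc[frame["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicated gene ids in DEG table: {dups[:5]}")
        bad_q = frame["qvalue"].dropna()
        if ((bad_q < 0) | (bad_q > 1)).any():
            raise ValidationError("DEG table q-values must lie in [0, 1]")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.frame["gene_id"])

    def __eq__(self, other) -> bool:
        return isinstance(other, DEGTable) and self.frame.equals(other.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()

    def lookup(self, gene_id: str) -> tuple[float, float] | None:
        """(log2fc, qvalue) for a gene, or None when absent."""
        sub = self.frame[self.frame["gene_id"] == gene_id]
        if sub.empty:
            return None
        row = sub.iloc[0]
        return float(row["log2fc"]), float(row["qvalue"])


def read_deg_table(path: str | Path) -> DEGTable:
    df = pd.read_csv(path, sep="\t")
    return DEGTable(df)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def check_chrom_overlap(peakset: PeakSet, annotation: GenomeAnnotation) -> set[str]:
    """Warn about peak chromosomes absent from the annotation; return them."""
    unmatched = peakset.chroms - annotation.chroms
    if unmatched:
        warnings.warn(
            f"{peakset.tf_name}: peak chromosomes not in annotation (exact-match policy): {sorted(unmatched)}",
            stacklevel=2,
        )
    return unmatched
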