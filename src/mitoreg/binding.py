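"""Peak-to-gene assignment, the TF x gene binding matrix, and coverage stats.

Promoter binding uses a window around the TSS (default 2 kb on each side,
configurable); a peak is assigned to a gene when the peak interval overlaps
the gene's window by at least one base. ``gene_region`` mode instead uses
the whole gene span extended upstream of the TSS, matching whole-gene
("genomic region") binding statements. Summits are used only for the
genomic-distribution and TSS-profile summaries, never for assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import (
    GeneRecord,
    GeneSet,
    GenomeAnnotation,
    PeakSet,
    ValidationError,
    check_chrom_overlap,
)

__all__ = [
    "PromoterWindow",
    "BindingMatrix",
    "CoverageReport",
    "promoter_window",
    "gene_region_window",
    "assign_peaks_to_genes",
    "build_binding_matrix",
    "coverage_stats",
    "genomic_distribution",
    "tss_profile",
]

DEFAULT_W_UP = 2000
DEFAULT_W_DOWN = 2000


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter interval [lo, hi) around a gene's TSS."""

    gene_id: str
    lo: int
    hi: int
    w_up: int
    w_down: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError(f"{self.gene_id}: empty promoter window [{self.lo}, {self.hi})")


def promoter_window(gene: GeneRecord, w_up: int = DEFAULT_W_UP, w_down: int = DEFAULT_W_DOWN) -> PromoterWindow:
    """Promoter window of a gene: w_up bp 5' of the TSS and w_down bp 3'.

    '+' strand: [tss - w_up, tss + w_down); '-' strand is its mirror image,
    [tss - w_down + 1, tss + w_up + 1). Clipped at zero; the TSS base is
    always inside the window.
    """
    if w_up < 0 or w_down < 0:
        raise ValueError("window extents must be non-negative")
    if w_up == 0 and w_down == 0:
        raise ValueError("promoter window cannot be empty on both sides")
    if gene.strand == "+":
        lo, hi = gene.tss - w_up, gene.tss + w_down
        if w_down == 0:
            hi = gene.tss + 1  # keep the TSS base covered
    else:
        lo, hi = gene.tss - w_down + 1, gene.tss + w_up + 1
        if w_down == 0:
            lo = gene.tss
    return PromoterWindow(gene.gene_id, max(lo, 0), hi, w_up, w_down)


def gene_region_window(gene: GeneRecord, w_up: int = DEFAULT_W_UP) -> PromoterWindow:
    """Whole gene span extended w_up bp upstream of the TSS (strand-aware)."""
    if gene.strand == "+":
        lo, hi = gene.tss - w_up, gene.end
    else:
        lo, hi = gene.start, gene.tss + w_up + 1
    return PromoterWindow(gene.gene_id, max(lo, 0), hi, w_up, 0)


def _windows(annotation: GenomeAnnotation, mode: str, w_up: int, w_down: int) -> dict[str, PromoterWindow]:
    if mode == "promoter":
        return {g.gene_id: promoter_window(g, w_up, w_down) for g in annotation}
    if mode == "gene_region":
        return {g.gene_id: gene_region_window(g, w_up) for g in annotation}
    raise ValueError(f"unknown assignment mode {mode!r}")


def assign_peaks_to_genes(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    mode: str = "promoter",
    w_up: int = DEFAULT_W_UP,
    w_down: int = DEFAULT_W_DOWN,
) -> dict[str, list[int]]:
    """Map gene_id -> indices of peaks overlapping the gene's window (>=1 bp).

    A peak may hit several genes; every hit is kept. Peak indices refer to
    the sorted order of ``peaks.peaks``.
    """
    check_chrom_overlap(peaks, annotation)
    windows = _windows(annotation, mode, w_up, w_down)
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        w = windows[gene.gene_id]
        trees.setdefault(gene.chrom, IntervalTree()).addi(w.lo, w.hi, gene.gene_id)
    hits: dict[str, list[int]] = {}
    for idx, peak in enumerate(peaks.peaks):
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(peak.start, peak.end):
            hits.setdefault(iv.data, []).append(idx)
    return {g: sorted(v) for g, v in sorted(hits.items())}


@dataclass
class BindingMatrix:
    """Boolean TF x gene incidence: bound[i, j] = TF i binds gene j."""

    tf_names: list[str]
    gene_ids: list[str]
    bound: np.ndarray
    mode: str = "promoter"
    support: dict[str, dict[str, list[int]]] = field(default_factory=dict)  # tf -> gene -> peak idx

    def __post_init__(self) -> None:
        self.bound = np.asarray(self.bound, dtype=bool)
        if self.bound.shape != (len(self.tf_names), len(self.gene_ids)):
            raise ValidationError(
                f"matrix shape {self.bound.shape} inconsistent with {len(self.tf_names)} TFs x {len(self.gene_ids)} genes"
            )
        if len(set(self.tf_names)) != len(self.tf_names):
            raise ValidationError("duplicate TF names in binding matrix")
        self._tf_index = {t: i for i, t in enumerate(self.tf_names)}
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    def is_bound(self, tf: str, gene_id: str) -> bool:
        j = self._gene_index.get(gene_id)
        if j is None:
            return False
        return bool(self.bound[self._tf_index[tf], j])

    def targets_of(self, tf: str) -> set[str]:
        row = self.bound[self._tf_index[tf]]
        return {self.gene_ids[j] for j in np.flatnonzero(row)}

    def binders_of(self, gene_id: str) -> set[str]:
        col = self.bound[:, self._gene_index[gene_id]]
        return {self.tf_names[i] for i in np.flatnonzero(col)}

    def to_frame(self) -> pd.DataFrame:
        """Genes x TFs 0/1 frame (the on-disk orientation)."""
        return pd.DataFrame(self.bound.T.astype(int), index=self.gene_ids, columns=self.tf_names)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path, mode: str = "promoter") -> "BindingMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(
            tf_names=list(df.columns),
            gene_ids=[str(g) for g in df.index],
            bound=df.to_numpy().T.astype(bool),
            mode=mode,
        )


def build_binding_matrix(
    assignments: Mapping[str, Mapping[str, Sequence[int]]],
    gene_universe: Sequence[str],
    mode: str = "promoter",
) -> BindingMatrix:
    """Assemble the TF x gene matrix from per-TF assignment maps.

    ``assignments`` maps tf_name -> (gene_id -> supporting peak indices).
    Assigned genes outside the universe are dropped (count retained in the
    matrix's ``support`` provenance only for in-universe genes).
    """
    tf_names = list(assignments)
    if len(set(tf_names)) != len(tf_names):
        raise ValidationError("duplicate TF name in assignments")
    gene_ids = list(gene_universe)
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    bound = np.zeros((len(tf_names), len(gene_ids)), dtype=bool)
    support: dict[str, dict[str, list[int]]] = {}
    n_dropped = 0
    for i, tf in enumerate(tf_names):
        kept: dict[str, list[int]] = {}
        for gene, peak_idx in assignments[tf].items():
            j = gene_index.get(gene)
            if j is None:
                n_dropped += 1
                continue
            bound[i, j] = True
            kept[gene] = list(peak_idx)
        support[tf] = kept
    matrix = BindingMatrix(tf_names=tf_names, gene_ids=gene_ids, bound=bound, mode=mode, support=support)
    matrix.n_dropped_genes = n_dropped  # type: ignore[attr-defined]
    return matrix


@dataclass
class CoverageReport:
    """How thoroughly a panel of TFs covers a target gene set."""

    set_name: str
    set_size: int  # |target set ∩ gene universe|
    per_tf_bound: dict[str, int]
    n_bound_ge1: int
    fraction_bound_ge1: float
    tfs_over_half: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [(tf, n, n / self.set_size, tf in self.tfs_over_half) for tf, n in sorted(self.per_tf_bound.items())]
        return pd.DataFrame(rows, columns=["tf", "n_bound_in_set", "fraction_of_set", "over_half"])


def coverage_stats(matrix: BindingMatrix, target_set: GeneSet) -> CoverageReport:
    """Per-TF coverage of a gene set and the union coverage by >=1 TF.

    Counts are on the intersection of the set with the matrix's gene
    universe; "over half" means strictly more than 0.5 x |set ∩ universe|.
    """
    in_universe = [g for g in matrix.gene_ids if g in target_set]
    if not in_universe:
        raise ValueError(f"gene set {target_set.name!r} does not intersect the matrix universe")
    cols = [matrix._gene_index[g] for g in in_universe]
    sub = matrix.bound[:, cols]
    per_tf = {tf: int(sub[i].sum()) for i, tf in enumerate(matrix.tf_names)}
    n_union = int(sub.any(axis=0).sum())
    half = 0.5 * len(in_universe)
    over_half = sorted(tf for tf, n in per_tf.items() if n > half)
    return CoverageReport(
        set_name=target_set.name,
        set_size=len(in_universe),
        per_tf_bound=per_tf,
        n_bound_ge1=n_union,
        fraction_bound_ge1=n_union / len(in_universe),
        tfs_over_half=over_half,
    )


def genomic_distribution(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    w_up: int = DEFAULT_W_UP,
    w_down: int = DEFAULT_W_DOWN,
) -> dict[str, float]:
    """Fractions of peaks whose summit lies in promoter / gene body / intergenic.

    Classification is by summit (midpoint when absent) with priority
    promoter > gene_body > intergenic; the three fractions sum to one.
    """
    if not len(peaks):
        return {"promoter": 0.0, "gene_body": 0.0, "intergenic": 0.0}
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        w = promoter_window(gene, w_up, w_down)
        prom_trees.setdefault(gene.chrom, IntervalTree()).addi(w.lo, w.hi, gene.gene_id)
        body_trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, gene.gene_id)
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    for peak in peaks:
        s = peak.summit
        if peak.chrom in prom_trees and prom_trees[peak.chrom].overlap(s, s + 1):
            counts["promoter"] += 1
        elif peak.chrom in body_trees and body_trees[peak.chrom].overlap(s, s + 1):
            counts["gene_body"] += 1
        else:
            counts["intergenic"] += 1
    n = len(peaks)
    return {k: v / n for k, v in counts.items()}


@dataclass
class TSSProfile:
    """Histogram of signed summit-to-nearest-TSS distances."""

    bin_edges: np.ndarray  # length n_bins + 1, from -flank to +flank
    counts: np.ndarray  # length n_bins
    n_within_flank: int
    n_total: int


def tss_profile(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    flank: int = 3000,
    bin: int = 100,
) -> TSSProfile:
    """Profile of peak summits around the nearest TSS.

    Distances are signed by the gene's strand (negative = upstream of the
    TSS). Summits farther than ``flank`` from every TSS are excluded from
    the histogram but counted in ``n_total``.
    """
    if bin <= 0 or (2 * flank) % bin != 0:
        raise ValueError("bin size must be positive and divide 2*flank")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene in annotation:
        by_chrom.setdefault(gene.chrom, []).append((gene.tss, gene.strand))
    for v in by_chrom.values():
        v.sort()
    edges = np.arange(-flank, flank + bin, bin)
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_within = 0
    for peak in peaks:
        tss_list = by_chrom.get(peak.chrom)
        if not tss_list:
            continue
        s = peak.summit
        positions = np.array([t for t, _ in tss_list])
        i = int(np.argmin(np.abs(positions - s)))
        tss, strand = tss_list[i]
        dist = s - tss if strand == "+" else tss - s
        if -flank <= dist < flank:
            counts[(dist + flank) // bin] += 1
            n_within += 1
    return TSSProfile(bin_edges=edges, counts=counts, n_within_flank=n_within, n_total=len(peaks))
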