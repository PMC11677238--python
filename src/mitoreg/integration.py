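"""Differential-expression classification and binding x DEG integration.

A gene is called *down* when ``log2fc < -lfc_min`` and ``qvalue < q_max``
(strict at both boundaries), *up* symmetrically, otherwise *ns*. The
defaults — FDR 0.05 and |log2 fold change| > 1, i.e. a more-than-two-fold
change — are the thresholds used throughout the reports. Genes missing
from the DEG table count as *ns* rather than being dropped, so fractions
stay on gene-inventory denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import DEGTable, GeneSet

__all__ = [
    "DEGClassParams",
    "TargetClassTable",
    "classify_deg",
    "classify_table",
    "intersect_binding_deg",
    "overlap_enrichment",
    "fold_change_summary",
]

DEG_CLASSES = ("down", "up", "ns")


@dataclass(frozen=True)
class DEGClassParams:
    """Thresholds for calling differential expression."""

    q_max: float = 0.05
    lfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.q_max <= 1):
            raise ValueError(f"q_max must lie in (0, 1], got {self.q_max}")
        if self.lfc_min < 0:
            raise ValueError(f"lfc_min must be >= 0, got {self.lfc_min}")


def classify_deg(log2fc: float, qvalue: float | None, params: DEGClassParams = DEGClassParams()) -> str:
    """Classify one gene as 'down', 'up' or 'ns' (strict inequalities)."""
    if qvalue is None or (isinstance(qvalue, float) and np.isnan(qvalue)):
        return "ns"
    if qvalue < params.q_max:
        if log2fc < -params.lfc_min:
            return "down"
        if log2fc > params.lfc_min:
            return "up"
    return "ns"


def classify_table(deg: DEGTable, params: DEGClassParams = DEGClassParams()) -> pd.Series:
    """Vectorised classification; index = gene_id, values in {down, up, ns}."""
    f = deg.frame
    sig = f["qvalue"] < params.q_max
    cls = np.where(
        sig & (f["log2fc"] < -params.lfc_min),
        "down",
        np.where(sig & (f["log2fc"] > params.lfc_min), "up", "ns"),
    )
    return pd.Series(cls, index=f["gene_id"].values, name="deg_class")


@dataclass
class TargetClassTable:
    """2x3 contingency of bound status against DEG class over a gene universe."""

    counts: pd.DataFrame  # index {bound, unbound}, columns {down, up, ns}
    n_universe: int
    n_bound: int
    fraction_target_bound: float | None
    fraction_bound_target_down: float | None
    n_bound_down: int
    n_bound_up: int
    flags: list[str] = field(default_factory=list)

    def cell(self, bound: bool, deg_class: str) -> int:
        return int(self.counts.loc["bound" if bound else "unbound", deg_class])


def intersect_binding_deg(
    bound_genes: Iterable[str],
    deg: DEGTable,
    params: DEGClassParams = DEGClassParams(),
    universe: Iterable[str] | None = None,
    target_set: GeneSet | None = None,
) -> TargetClassTable:
    """Tabulate binding against DEG class and compute the headline fractions.

    ``fraction_target_bound`` is |bound ∩ target| / |target ∩ universe| and
    ``fraction_bound_target_down`` is the down-regulated share of the bound
    target genes — the two denominators used when reporting how much of a
    gene inventory a TF binds and how much of that responds to its loss.
    """
    bound = set(bound_genes)
    if universe is None:
        universe_set = set(deg.gene_ids) | bound
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    if not bound <= universe_set:
        raise ValueError("bound genes must be a subset of the universe")

    classes = classify_table(deg, params)
    flags: list[str] = []
    counts = pd.DataFrame(0, index=["bound", "unbound"], columns=list(DEG_CLASSES))
    for gene in universe_set:
        cls = classes.get(gene, "ns")  # absent from DEG table -> ns
        counts.loc["bound" if gene in bound else "unbound", cls] += 1

    n_bound_down = int(counts.loc["bound", "down"])
    n_bound_up = int(counts.loc["bound", "up"])

    frac_target_bound = None
    frac_bound_target_down = None
    if target_set is not None:
        target_in_universe = target_set.genes & universe_set
        if not target_in_universe:
            raise ValueError("target set does not intersect the universe")
        bound_target = bound & target_in_universe
        frac_target_bound = len(bound_target) / len(target_in_universe)
        if bound_target:
            down_bt = sum(1 for g in bound_target if classes.get(g, "ns") == "down")
            frac_bound_target_down = down_bt / len(bound_target)
        else:
            flags.append("no_bound_target_genes")
    if not bound:
        flags.append("no_bound_genes")

    return TargetClassTable(
        counts=counts,
        n_universe=len(universe_set),
        n_bound=len(bound),
        fraction_target_bound=frac_target_bound,
        fraction_bound_target_down=frac_bound_target_down,
        n_bound_down=n_bound_down,
        n_bound_up=n_bound_up,
        flags=flags,
    )


def overlap_enrichment(n_universe: int, n_set_a: int, n_set_b: int, n_overlap: int) -> float:
    """Hypergeometric upper-tail probability of seeing >= n_overlap shared genes.

    p = P(X >= n_overlap) with X ~ Hypergeom(N=n_universe, K=n_set_a,
    n=n_set_b) — the standard one-sided gene-set overlap enrichment test.
    """
    if not (0 <= n_overlap <= min(n_set_a, n_set_b) <= max(n_set_a, n_set_b) <= n_universe):
        raise ValueError(
            f"inconsistent counts: universe={n_universe}, |A|={n_set_a}, |B|={n_set_b}, overlap={n_overlap}"
        )
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set_a, n_set_b))


def fold_change_summary(deg: DEGTable, partition: GeneSet) -> pd.DataFrame:
    """Median/quartile log2fc summaries for genes in vs out of a gene set.

    Partition genes absent from the DEG table are dropped (their count is
    reported in the ``n_missing`` column of the in-set row).
    """
    f = deg.frame
    in_mask = f["gene_id"].isin(partition.genes)
    n_missing = len(partition.genes - set(f["gene_id"]))
    rows = []
    for label, sub in (("in_set", f[in_mask]), ("out_of_set", f[~in_mask])):
        vals = sub["log2fc"].to_numpy()
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append((label, len(vals), med, q1, q3, n_missing if label == "in_set" else 0))
    return pd.DataFrame(rows, columns=["group", "n", "median_log2fc", "q1_log2fc", "q3_log2fc", "n_missing"])
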