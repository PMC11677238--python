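"""Synergy scoring for the two-arm eye modifier screen.

Each RNAi line is scored in two arms — RNAi alone, and RNAi combined with
mtDNA deficiency — on an ordinal 0-5 eye-size scale. The index of eye-size
reduction (Index-R) of an arm is the mean score normalised to the matched
control arm's mean. A line whose combined-arm Index-R falls below the
enhancer line of slope 0.75 through the origin (ir_combo < 0.75 * ir_rnai)
shows a synergistic interaction with the mtDNA deficiency; one above the
slope-1.5 line is a suppressor. Both comparisons are strict, so a point on
a threshold line is not a hit; the enhancer slope can be re-calibrated
from a reference gene's own ratio (the screen used the NRF-1 homolog ewg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GeneSet
from .integration import overlap_enrichment

__all__ = [
    "ARMS",
    "EyeScoreRecord",
    "IndexRPair",
    "ModifierCall",
    "DegenerateControlError",
    "compute_index_r",
    "call_modifier",
    "calibrate_enhancer_slope",
    "consolidate_gene_calls",
    "group_summary",
    "score_screen",
]

ARMS = ("rnai_only", "rnai_mitoxhoi")
ENHANCER_SLOPE = 0.75
SUPPRESSOR_SLOPE = 1.5
VALID_SCORES = frozenset(range(6))


class DegenerateControlError(ValueError):
    """The control arm's mean score is zero; Index-R is undefined."""


@dataclass
class EyeScoreRecord:
    """Ordinal eye scores (0-5) for one line in one arm."""

    line_id: str
    gene_id: str
    arm: str
    scores: list[int]
    lethal: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not self.scores:
            raise ValueError(f"{self.line_id}/{self.arm}: empty score list")
        bad = [s for s in self.scores if s not in VALID_SCORES]
        if bad:
            raise ValueError(f"{self.line_id}/{self.arm}: scores outside 0-5: {bad[:5]}")

    @property
    def mean(self) -> float:
        return sum(self.scores) / len(self.scores)


@dataclass(frozen=True)
class IndexRPair:
    """Per-gene (or per-line) Index-R in the two arms."""

    gene_id: str
    ir_rnai: float
    ir_combo: float

    def __post_init__(self) -> None:
        if self.ir_rnai < 0 or self.ir_combo < 0:
            raise ValueError(f"{self.gene_id}: Index-R must be non-negative")


@dataclass(frozen=True)
class ModifierCall:
    gene_id: str
    call: str  # 'enhancer' | 'suppressor' | 'none'
    ratio: float  # ir_combo / ir_rnai; nan when undefined
    flags: tuple[str, ...] = ()


def compute_index_r(scores: Sequence[float], control_scores: Sequence[float]) -> float:
    """Mean score normalised to the mean of the matched control arm."""
    if not len(scores) or not len(control_scores):
        raise ValueError("score lists must be non-empty")
    control_mean = sum(control_scores) / len(control_scores)
    if control_mean <= 0:
        raise DegenerateControlError("control arm mean score is zero")
    return (sum(scores) / len(scores)) / control_mean


def call_modifier(
    pair: IndexRPair,
    enhancer_slope: float = ENHANCER_SLOPE,
    suppressor_slope: float = SUPPRESSOR_SLOPE,
) -> ModifierCall:
    """Call a gene enhancer/suppressor/none from its Index-R pair.

    Strict inequalities: enhancer iff ir_combo < enhancer_slope * ir_rnai,
    suppressor iff ir_combo > suppressor_slope * ir_rnai. A zero RNAi-arm
    Index-R leaves the ratio undefined; the gene is flagged, not called.
    """
    if pair.ir_rnai == 0:
        return ModifierCall(pair.gene_id, "none", float("nan"), flags=("undefined_ratio",))
    # compare on the ratio so a point on a threshold line (e.g. the
    # calibration reference itself) is never a hit, exactly
    ratio = pair.ir_combo / pair.ir_rnai
    if ratio < enhancer_slope:
        return ModifierCall(pair.gene_id, "enhancer", ratio)
    if ratio > suppressor_slope:
        return ModifierCall(pair.gene_id, "suppressor", ratio)
    return ModifierCall(pair.gene_id, "none", ratio)


def calibrate_enhancer_slope(reference_pair: IndexRPair) -> float:
    """Enhancer slope implied by a reference gene's screen performance.

    Returns the reference gene's combo/RNAi ratio — the slope at or below
    which the reference itself sits on the calling boundary.
    """
    if reference_pair.ir_rnai == 0:
        raise DegenerateControlError(f"{reference_pair.gene_id}: reference RNAi-arm Index-R is zero")
    slope = reference_pair.ir_combo / reference_pair.ir_rnai
    if slope >= 1.0:
        warnings.warn(
            f"reference gene {reference_pair.gene_id} is not synergistic (ratio {slope:.3g} >= 1)",
            stacklevel=2,
        )
    return slope


def consolidate_gene_calls(line_calls: Sequence[ModifierCall]) -> ModifierCall:
    """Collapse per-line calls for one gene to a single gene-level call.

    Any line calling a direction scores the gene in that direction, taking
    the line with the extreme ratio (minimum for enhancers, maximum for
    suppressors). Lines disagreeing in direction conflict: the gene is
    called none and flagged.
    """
    if not line_calls:
        raise ValueError("need at least one line call")
    gene_id = line_calls[0].gene_id
    if any(c.gene_id != gene_id for c in line_calls):
        raise ValueError("line calls mix gene ids")
    flags = tuple(sorted({f for c in line_calls for f in c.flags}))
    enh = [c for c in line_calls if c.call == "enhancer"]
    sup = [c for c in line_calls if c.call == "suppressor"]
    if enh and sup:
        ratio = min(c.ratio for c in enh)
        return ModifierCall(gene_id, "none", ratio, flags=flags + ("conflict",))
    if enh:
        best = min(enh, key=lambda c: c.ratio)
        return ModifierCall(gene_id, "enhancer", best.ratio, flags=flags)
    if sup:
        best = max(sup, key=lambda c: c.ratio)
        return ModifierCall(gene_id, "suppressor", best.ratio, flags=flags)
    # no direction called: report the most extreme ratio (largest departure
    # from the diagonal) among defined ones
    defined = [c for c in line_calls if c.ratio == c.ratio]
    if defined:
        best = max(defined, key=lambda c: abs(c.ratio - 1.0))
        return ModifierCall(gene_id, "none", best.ratio, flags=flags)
    return ModifierCall(gene_id, "none", float("nan"), flags=flags)


def group_summary(
    calls: Mapping[str, ModifierCall] | Iterable[ModifierCall],
    groups: Sequence[GeneSet],
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Per-group enhancer counts/fractions with enrichment vs a reference group.

    Groups must be disjoint over the scored genes. The p-value is the
    hypergeometric upper tail for the group's enhancer count against the
    reference group (default: the first group), computed on the two groups'
    pooled genes. It is reported alongside the fractions and never feeds
    back into calling.
    """
    if not isinstance(calls, Mapping):
        calls = {c.gene_id: c for c in calls}
    scored = set(calls)
    seen: set[str] = set()
    for g in groups:
        overlap = (g.genes & scored) & seen
        if overlap:
            raise ValueError(f"groups are not disjoint over scored genes (e.g. {sorted(overlap)[:3]})")
        seen |= g.genes & scored

    stats_rows = []
    per_group: dict[str, tuple[int, int]] = {}
    for g in groups:
        members = sorted(g.genes & scored)
        if not members:
            warnings.warn(f"group {g.name!r} has no scored genes; skipped", stacklevel=2)
            continue
        n = len(members)
        n_enh = sum(1 for m in members if calls[m].call == "enhancer")
        per_group[g.name] = (n, n_enh)
        stats_rows.append([g.name, n, n_enh, n_enh / n])

    ref_name = reference_group if reference_group is not None else (stats_rows[0][0] if stats_rows else None)
    pvals = []
    for name, n, n_enh, _frac in stats_rows:
        if ref_name is None or name == ref_name or ref_name not in per_group:
            pvals.append(float("nan"))
            continue
        n_ref, k_ref = per_group[ref_name]
        # enrichment of the reference group relative to this one, on their pooled genes
        pvals.append(overlap_enrichment(n + n_ref, n_ref, k_ref + n_enh, k_ref))
    df = pd.DataFrame(stats_rows, columns=["group", "n", "n_enhancer", "fraction"])
    df["p_vs_reference"] = pvals
    return df


def _records_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], EyeScoreRecord]:
    """Aggregate a long score table (line_id, gene_id, arm, score[, lethal])."""
    required = {"line_id", "gene_id", "arm", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    records: dict[tuple[str, str], EyeScoreRecord] = {}
    for (line_id, gene_id, arm), sub in frame.groupby(["line_id", "gene_id", "arm"], sort=True):
        lethal = bool(sub["lethal"].any()) if "lethal" in sub.columns else False
        records[(str(line_id), str(arm))] = EyeScoreRecord(
            line_id=str(line_id),
            gene_id=str(gene_id),
            arm=str(arm),
            scores=[int(s) for s in sub["score"]],
            lethal=lethal,
        )
    return records


@dataclass
class ScreenResult:
    line_table: pd.DataFrame  # per line: ir_rnai, ir_combo, ratio, call, flags
    gene_calls: dict[str, ModifierCall] = field(default_factory=dict)

    @property
    def gene_table(self) -> pd.DataFrame:
        rows = [
            (g, c.call, c.ratio, ";".join(c.flags))
            for g, c in sorted(self.gene_calls.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "call", "ratio", "flags"])


def score_screen(
    frame: pd.DataFrame,
    control_rnai_line: str,
    control_combo_line: str | None = None,
    enhancer_slope: float = ENHANCER_SLOPE,
    suppressor_slope: float = SUPPRESSOR_SLOPE,
    calibrate_on: str | None = None,
) -> ScreenResult:
    """Score a whole screen from a long table of per-fly eye scores.

    Each arm of each line is normalised to the matched arm of the control
    line(s), called per line, then consolidated per gene. When
    ``calibrate_on`` names a gene, the enhancer slope is recomputed from
    that gene's consolidated Index-R pair before the final calling pass.
    """
    if control_combo_line is None:
        control_combo_line = control_rnai_line
    records = _records_from_frame(frame)
    ctrl_rnai = records.get((control_rnai_line, "rnai_only"))
    ctrl_combo = records.get((control_combo_line, "rnai_mitoxhoi"))
    if ctrl_rnai is None or ctrl_combo is None:
        raise ValueError("control line scores missing for one or both arms")

    pairs: dict[str, IndexRPair] = {}
    lethal_lines: set[str] = set()
    gene_of_line: dict[str, str] = {}
    for (line_id, arm), rec in records.items():
        gene_of_line[line_id] = rec.gene_id
        if rec.lethal:
            lethal_lines.add(line_id)
    line_ids = sorted({line_id for line_id, _arm in records})
    for line_id in line_ids:
        rnai = records.get((line_id, "rnai_only"))
        combo = records.get((line_id, "rnai_mitoxhoi"))
        if rnai is None or combo is None:
            warnings.warn(f"line {line_id}: missing one arm; skipped", stacklevel=2)
            continue
        pairs[line_id] = IndexRPair(
            gene_id=rnai.gene_id,
            ir_rnai=compute_index_r(rnai.scores, ctrl_rnai.scores),
            ir_combo=compute_index_r(combo.scores, ctrl_combo.scores),
        )

    if calibrate_on is not None:
        ref_lines = [p for p in pairs.values() if p.gene_id == calibrate_on]
        if not ref_lines:
            raise ValueError(f"calibration gene {calibrate_on!r} not in the screen")
        ref = min(ref_lines, key=lambda p: p.ir_combo / p.ir_rnai if p.ir_rnai else float("inf"))
        enhancer_slope = calibrate_enhancer_slope(ref)

    line_rows = []
    by_gene: dict[str, list[ModifierCall]] = {}
    for line_id in sorted(pairs):
        pair = pairs[line_id]
        call = call_modifier(pair, enhancer_slope, suppressor_slope)
        if line_id in lethal_lines:
            call = ModifierCall(call.gene_id, call.call, call.ratio, call.flags + ("lethal",))
        by_gene.setdefault(pair.gene_id, []).append(call)
        line_rows.append(
            (line_id, pair.gene_id, pair.ir_rnai, pair.ir_combo, call.ratio, call.call, ";".join(call.flags))
        )
    line_table = pd.DataFrame(
        line_rows, columns=["line_id", "gene_id", "ir_rnai", "ir_combo", "ratio", "call", "flags"]
    )
    gene_calls = {g: consolidate_gene_calls(cs) for g, cs in by_gene.items()}
    return ScreenResult(line_table=line_table, gene_calls=gene_calls)
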