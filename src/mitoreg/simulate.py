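"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the five inputs the pipeline consumes — a gene
annotation with labelled mitochondrial genes, per-TF narrowPeak files
planted from a known TF hierarchy, a knockout DEG table with direct and
indirect effects, and two-arm ordinal eye-score data with planted synergy
— while recording the ground truth (planted layers, target sets, DEG
classes, synergy genes) so recovery can be checked exactly.

Randomness is driven by one global seed; each stage draws from its own
substream (``numpy.random.SeedSequence(seed).spawn``), so stages can be
regenerated independently and identical configs emit byte-identical files.

With all noise parameters at zero (summit jitter, peak false-negative
rate, background peaks, DEG sigma, score SD) the full pipeline recovers
the ground truth exactly; the noisy defaults are used for robustness and
power checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    DEGTable,
    GeneRecord,
    GeneSet,
    GenomeAnnotation,
    Peak,
    PeakSet,
    write_annotation,
    write_deg_table,
    write_gene_set,
    write_narrowpeak,
)

__all__ = [
    "LayerSpec",
    "BindingSimParams",
    "DEGSimParams",
    "ScreenSimParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_hierarchy",
    "simulate_peaks",
    "simulate_deg",
    "simulate_screen",
    "simulate_all",
    "emit_bundle",
]

TSS_SPACING = 5000  # minimum TSS-to-TSS distance within a chromosome


@dataclass(frozen=True)
class LayerSpec:
    """Planted hierarchy shape: node counts per layer and SCC sizes in core."""

    n_top: int = 2
    n_core: int = 6
    n_bottom: int = 3
    n_isolated: int = 0
    scc_sizes: tuple[int, ...] = (3,)
    extra_edge_prob: float = 0.3

    @property
    def n_tf(self) -> int:
        return self.n_top + self.n_core + self.n_bottom + self.n_isolated

    def __post_init__(self) -> None:
        if sum(self.scc_sizes) > self.n_core:
            raise ValueError("SCC sizes exceed the core layer size")
        if any(s < 2 for s in self.scc_sizes):
            raise ValueError("planted SCCs need size >= 2")
        if self.n_core and (self.n_top == 0 or self.n_bottom == 0):
            raise ValueError("a non-empty core needs at least one top and one bottom node")
        if self.n_bottom and not (self.n_top or self.n_core):
            raise ValueError("bottom nodes need an upstream layer")
        if self.n_top and not (self.n_core or self.n_bottom):
            raise ValueError("top nodes need a downstream layer")


@dataclass(frozen=True)
class BindingSimParams:
    """Peak-planting parameters per TF."""

    targets_min: int = 10
    targets_max: int = 30
    frac_mito_targets: float = 0.6
    peak_width_min: int = 150
    peak_width_max: int = 400
    summit_jitter: float = 50.0  # SD (bp) of summit displacement from the TSS
    false_negative_rate: float = 0.05  # chance a true target loses its peak
    background_mean: float = 10.0  # Poisson mean background peaks per TF
    background_avoid_promoters: bool = False
    signal_true: tuple[float, float] = (8.0, 20.0)  # uniform range
    signal_background: tuple[float, float] = (1.0, 5.0)


@dataclass(frozen=True)
class DEGSimParams:
    """Knockout contrast: planted effect sizes on the log2 scale."""

    mu_direct: float = -2.0
    mu_indirect: float = -1.5
    sigma: float = 0.4
    q_affected_exp_range: tuple[float, float] = (3.0, 8.0)  # q = 10^-U(range)


@dataclass(frozen=True)
class ScreenSimParams:
    """Two-arm eye-score screen: latent eye size scored on the 0-5 scale."""

    flies_per_arm: int = 30
    control_rnai_mean: float = 5.0
    control_combo_mean: float = 4.5  # mtDNA deficiency alone mildly reduces eye size
    severity_min: float = 0.7
    severity_max: float = 1.0
    synergy_factor: float = 0.5  # extra combo-arm attenuation for true hits
    score_sd: float = 0.5
    frac_synergy: float = 0.3
    lines_per_gene: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 300
    n_chrom: int = 3
    frac_mito: float = 0.25
    layers: LayerSpec = field(default_factory=LayerSpec)
    binding: BindingSimParams = field(default_factory=BindingSimParams)
    deg: DEGSimParams = field(default_factory=DEGSimParams)
    screen: ScreenSimParams = field(default_factory=ScreenSimParams)

    def __post_init__(self) -> None:
        if self.n_genes < self.layers.n_tf:
            raise ValueError("need at least as many genes as TFs")
        if not (0 <= self.frac_mito <= 1):
            raise ValueError("frac_mito must lie in [0, 1]")

    def with_zero_noise(self) -> "SimulationConfig":
        """Copy with every stochastic corruption switched off."""
        return SimulationConfig(
            seed=self.seed,
            n_genes=self.n_genes,
            n_chrom=self.n_chrom,
            frac_mito=self.frac_mito,
            layers=self.layers,
            binding=BindingSimParams(
                targets_min=self.binding.targets_min,
                targets_max=self.binding.targets_max,
                frac_mito_targets=self.binding.frac_mito_targets,
                peak_width_min=self.binding.peak_width_min,
                peak_width_max=self.binding.peak_width_max,
                summit_jitter=0.0,
                false_negative_rate=0.0,
                background_mean=0.0,
            ),
            deg=DEGSimParams(
                mu_direct=self.deg.mu_direct,
                mu_indirect=self.deg.mu_indirect,
                sigma=0.0,
                q_affected_exp_range=self.deg.q_affected_exp_range,
            ),
            screen=ScreenSimParams(
                flies_per_arm=self.screen.flies_per_arm,
                control_rnai_mean=self.screen.control_rnai_mean,
                control_combo_mean=self.screen.control_combo_mean,
                severity_min=self.screen.severity_min,
                severity_max=self.screen.severity_max,
                synergy_factor=self.screen.synergy_factor,
                score_sd=0.0,
                frac_synergy=self.screen.frac_synergy,
                lines_per_gene=self.screen.lines_per_gene,
            ),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("layers", LayerSpec), ("binding", BindingSimParams), ("deg", DEGSimParams), ("screen", ScreenSimParams)):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                for tuple_field in ("scc_sizes", "signal_true", "signal_background", "q_affected_exp_range"):
                    if tuple_field in d and isinstance(d[tuple_field], list):
                        d[tuple_field] = tuple(d[tuple_field])
                raw[key] = sub(**d)
        return cls(**raw)


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact recovery checks."""

    graph: nx.DiGraph
    layers: dict[str, str]  # tf -> top/core/bottom/isolated
    scc_of: dict[str, int]
    tf_gene: dict[str, str]
    targets: dict[str, set[str]]  # tf -> true bound genes (promoter)
    retained_targets: dict[str, set[str]] = field(default_factory=dict)  # after false negatives
    mito_genes: set[str] = field(default_factory=set)
    deg_class: dict[str, str] = field(default_factory=dict)
    knockout_tf: str | None = None
    indirect: set[str] = field(default_factory=set)
    indirect_down: set[str] = field(default_factory=set)
    synergy_genes: set[str] = field(default_factory=set)
    severities: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "edges": sorted(self.graph.edges()),
            "layers": dict(sorted(self.layers.items())),
            "tf_gene": dict(sorted(self.tf_gene.items())),
            "targets": {t: sorted(v) for t, v in sorted(self.targets.items())},
            "retained_targets": {t: sorted(v) for t, v in sorted(self.retained_targets.items())},
            "mito_genes": sorted(self.mito_genes),
            "deg_class": dict(sorted(self.deg_class.items())),
            "knockout_tf": self.knockout_tf,
            "indirect": sorted(self.indirect),
            "indirect_down": sorted(self.indirect_down),
            "synergy_genes": sorted(self.synergy_genes),
            "severities": {g: round(s, 10) for g, s in sorted(self.severities.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(8)
    return np.random.default_rng(children[stage])


def simulate_annotation(config: SimulationConfig) -> tuple[GenomeAnnotation, GeneSet]:
    """Non-overlapping genes on n_chrom chromosomes, with mito labels.

    TSSs are spaced >= 5 kb apart so default promoter windows of adjacent
    genes never swallow each other's planted peaks.
    """
    rng = _stage_rng(config.seed, 0)
    n = config.n_genes
    per_chrom = [n // config.n_chrom + (1 if i < n % config.n_chrom else 0) for i in range(config.n_chrom)]
    records = []
    gid = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(TSS_SPACING, 2 * TSS_SPACING))
        for _ in range(n_on_chrom):
            length = int(rng.integers(500, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
            end = start + length
            records.append(GeneRecord(f"g{gid:04d}", chrom, strand, start, end))
            gid += 1
            pos = end + TSS_SPACING + int(rng.integers(0, TSS_SPACING))
    annotation = GenomeAnnotation(records)
    n_mito = int(round(config.frac_mito * n))
    mito_ids = sorted(rng.choice(annotation.gene_ids, size=n_mito, replace=False).tolist())
    subgroups = {g: ("Mito-EBR" if i % 2 == 0 else "other_mito") for i, g in enumerate(mito_ids)}
    return annotation, GeneSet(name="mito", genes=frozenset(mito_ids), subgroups=subgroups)


def simulate_hierarchy(config: SimulationConfig) -> tuple[nx.DiGraph, dict[str, str], dict[str, int]]:
    """Plant a TF network with known top/core/bottom/isolated layers and SCCs.

    Core SCCs are directed cycles (plus chance chords); all other edges run
    strictly downward (top -> core -> bottom, and forward within the core
    ordering), so planted tops are exactly the condensation sources and
    planted bottoms exactly the sinks.
    """
    rng = _stage_rng(config.seed, 1)
    spec = config.layers
    tops = [f"TF{i:02d}" for i in range(spec.n_top)]
    cores = [f"TF{i:02d}" for i in range(spec.n_top, spec.n_top + spec.n_core)]
    bottoms = [f"TF{i:02d}" for i in range(spec.n_top + spec.n_core, spec.n_top + spec.n_core + spec.n_bottom)]
    isolated = [f"TF{i:02d}" for i in range(spec.n_top + spec.n_core + spec.n_bottom, spec.n_tf)]
    graph = nx.DiGraph()
    graph.add_nodes_from(tops + cores + bottoms + isolated)
    layers = {t: "top" for t in tops}
    layers |= {c: "core" for c in cores}
    layers |= {b: "bottom" for b in bottoms}
    layers |= {i: "isolated" for i in isolated}

    # Core blocks: SCC cycles first, then singletons.
    blocks: list[list[str]] = []
    idx = 0
    for size in spec.scc_sizes:
        blocks.append(cores[idx : idx + size])
        idx += size
    blocks.extend([c] for c in cores[idx:])
    scc_of: dict[str, int] = {}
    for block in blocks:
        for node in block:
            if len(block) >= 2:
                scc_of[node] = blocks.index(block)
        if len(block) >= 2:
            for a, b in zip(block, block[1:] + block[:1]):
                graph.add_edge(a, b)
            for a in block:  # chance chords inside the cycle
                for b in block:
                    if a != b and not graph.has_edge(a, b) and rng.random() < spec.extra_edge_prob:
                        graph.add_edge(a, b)

    if cores:
        # every top seeds >= 1 core block; block 0 always has a top parent
        for t in tops:
            k = int(rng.integers(1, max(2, len(blocks) // 2 + 1)))
            chosen = rng.choice(len(blocks), size=min(k, len(blocks)), replace=False)
            for bi in chosen:
                graph.add_edge(t, rng.choice(blocks[bi]))
        first = blocks[0][0]
        if not any(graph.has_edge(t, m) for t in tops for m in blocks[0]):
            graph.add_edge(rng.choice(tops), first)
        # forward chain between consecutive blocks keeps the core connected
        for b1, b2 in zip(blocks, blocks[1:]):
            graph.add_edge(rng.choice(b1), rng.choice(b2))
            # singleton blocks after the first need an upstream edge; the chain provides it
        # every core node reaches a bottom
        for c in cores:
            graph.add_edge(c, rng.choice(bottoms))
        # extra strictly-forward edges
        for i, b1 in enumerate(blocks):
            for b2 in blocks[i + 1 :]:
                if rng.random() < spec.extra_edge_prob:
                    graph.add_edge(rng.choice(b1), rng.choice(b2))
        for t in tops:
            for b in bottoms:
                if rng.random() < spec.extra_edge_prob / 2:
                    graph.add_edge(t, b)
    else:
        for t in tops:
            graph.add_edge(t, rng.choice(bottoms))
    for b in bottoms:  # every bottom needs an upstream regulator
        if graph.in_degree(b) == 0:
            graph.add_edge(rng.choice(cores if cores else tops), b)
    return graph, layers, scc_of


def _assign_tf_genes(annotation: GenomeAnnotation, tf_names: list[str], mito: GeneSet, rng) -> dict[str, str]:
    # TF-encoding genes are drawn from non-mito genes so random mito targets
    # can never create unplanned TF-TF edges.
    pool = [g for g in annotation.gene_ids if g not in mito.genes]
    chosen = rng.choice(pool, size=len(tf_names), replace=False)
    return dict(zip(tf_names, chosen.tolist()))


def _plant_targets(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    mito: GeneSet,
    config: SimulationConfig,
    rng,
) -> None:
    tf_genes = set(truth.tf_gene.values())
    mito_pool = sorted(mito.genes - tf_genes)
    other_pool = sorted(set(annotation.gene_ids) - mito.genes - tf_genes)
    p = config.binding
    for tf in sorted(truth.graph.nodes):
        targets = {truth.tf_gene[v] for v in truth.graph.successors(tf)}
        n_extra = int(rng.integers(p.targets_min, p.targets_max + 1))
        n_mito = int(round(p.frac_mito_targets * n_extra))
        n_other = n_extra - n_mito
        targets |= set(rng.choice(mito_pool, size=min(n_mito, len(mito_pool)), replace=False).tolist())
        targets |= set(rng.choice(other_pool, size=min(n_other, len(other_pool)), replace=False).tolist())
        truth.targets[tf] = targets


def simulate_peaks(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> dict[str, PeakSet]:
    """One promoter peak per retained true target, plus Poisson background.

    True-target peaks have summits jittered around the TSS and higher
    signalValues than background peaks; targets are dropped at the false-
    negative rate and the retained sets are recorded in the ground truth.
    """
    rng = _stage_rng(config.seed, 2)
    p = config.binding
    chrom_len = {}
    for gene in annotation:
        chrom_len[gene.chrom] = max(chrom_len.get(gene.chrom, 0), gene.end + TSS_SPACING)
    promoter_spans: dict[str, list[tuple[int, int]]] = {}
    if p.background_avoid_promoters:
        from .binding import promoter_window

        for gene in annotation:
            w = promoter_window(gene)
            promoter_spans.setdefault(gene.chrom, []).append((w.lo, w.hi))

    peaksets: dict[str, PeakSet] = {}
    for tf in sorted(truth.graph.nodes):
        peaks = []
        retained = set()
        for gene_id in sorted(truth.targets[tf]):
            if p.false_negative_rate > 0 and rng.random() < p.false_negative_rate:
                continue
            retained.add(gene_id)
            gene = annotation[gene_id]
            summit = gene.tss + int(round(rng.normal(0.0, p.summit_jitter))) if p.summit_jitter > 0 else gene.tss
            width = int(rng.integers(p.peak_width_min, p.peak_width_max + 1))
            start = max(summit - width // 2, 0)
            end = start + width
            peaks.append(
                Peak(
                    chrom=gene.chrom,
                    start=start,
                    end=end,
                    name=f"{tf}_{gene_id}",
                    score=int(rng.integers(100, 1000)),
                    strand=".",
                    signal_value=float(rng.uniform(*p.signal_true)),
                    p_value=float(rng.uniform(5, 30)),
                    q_value=float(rng.uniform(3, 20)),
                    summit_offset=summit - start,
                )
            )
        n_bg = int(rng.poisson(p.background_mean)) if p.background_mean > 0 else 0
        chroms = sorted(chrom_len)
        for k in range(n_bg):
            for _attempt in range(100):
                chrom = chroms[int(rng.integers(len(chroms)))]
                width = int(rng.integers(p.peak_width_min, p.peak_width_max + 1))
                start = int(rng.integers(0, max(chrom_len[chrom] - width, 1)))
                end = start + width
                if p.background_avoid_promoters and any(
                    start < hi and lo < end for lo, hi in promoter_spans.get(chrom, [])
                ):
                    continue
                break
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=f"{tf}_bg{k}",
                    score=int(rng.integers(10, 200)),
                    strand=".",
                    signal_value=float(rng.uniform(*p.signal_background)),
                    p_value=float(rng.uniform(2, 8)),
                    q_value=float(rng.uniform(1, 5)),
                    summit_offset=width // 2,
                )
            )
        truth.retained_targets[tf] = retained
        peaksets[tf] = PeakSet(tf_name=tf, peaks=peaks)
    return peaksets


def _truth_indirect(truth: GroundTruth, knockout_tf: str) -> tuple[set[str], set[str]]:
    """Ground-truth bookkeeping mirror of the pipeline's indirect-target rule."""
    direct = truth.targets[knockout_tf]
    own = truth.tf_gene[knockout_tf]
    indirect: set[str] = set()
    for d in truth.graph.successors(knockout_tf):
        if d == knockout_tf:
            continue
        indirect |= truth.targets[d]
    indirect -= direct
    indirect.discard(own)
    return indirect, indirect & truth.mito_genes


def simulate_deg(
    truth: GroundTruth,
    knockout_tf: str,
    annotation: GenomeAnnotation,
    config: SimulationConfig,
) -> DEGTable:
    """Knockout-vs-control DEG table with planted direct/indirect effects.

    Direct targets draw log2fc ~ N(mu_direct, sigma), indirect targets
    (bound by downstream TFs, not by the knockout) ~ N(mu_indirect, sigma),
    the knocked-out gene itself mu_direct, and everything else N(0, sigma).
    Affected genes get small q-values (10^-U); null genes q ~ U(0, 1).
    """
    if knockout_tf not in truth.targets:
        raise KeyError(f"unknown knockout TF {knockout_tf!r}")
    rng = _stage_rng(config.seed, 3)
    p = config.deg
    direct = truth.targets[knockout_tf]
    indirect, _ = _truth_indirect(truth, knockout_tf)
    own = truth.tf_gene[knockout_tf]
    rows = []
    truth.deg_class = {}
    truth.knockout_tf = knockout_tf
    for gene in annotation.gene_ids:
        if gene in direct or gene == own:
            mu = p.mu_direct
        elif gene in indirect:
            mu = p.mu_indirect
        else:
            mu = 0.0
        lfc = mu + (rng.normal(0.0, p.sigma) if p.sigma > 0 else 0.0)
        if mu != 0.0:
            q = 10.0 ** (-rng.uniform(*p.q_affected_exp_range))
        else:
            q = float(rng.uniform(0.0, 1.0))
        rows.append((gene, lfc, q))
        truth.deg_class[gene] = "down" if mu != 0.0 else "ns"
    truth.indirect = indirect
    truth.indirect_down = {g for g in indirect if truth.deg_class[g] == "down"}
    return DEGTable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "qvalue"]))


def simulate_screen(
    truth: GroundTruth,
    config: SimulationConfig,
    screened_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Two-arm ordinal eye scores with planted synergy genes.

    Latent eye size is the control arm's mean scaled by a per-gene RNAi
    severity; synergy genes are additionally attenuated by the synergy
    factor in the combined arm. Scores are the latent value plus Gaussian
    noise, rounded and clamped to the ordinal 0-5 scale. The control line
    is emitted under gene id 'ctrl'.
    """
    rng = _stage_rng(config.seed, 4)
    p = config.screen
    if screened_genes is None:
        screened_genes = sorted(truth.tf_gene.values())
    n_syn = int(round(p.frac_synergy * len(screened_genes)))
    synergy = set(rng.choice(screened_genes, size=n_syn, replace=False).tolist())
    truth.synergy_genes = synergy
    severities = {g: float(rng.uniform(p.severity_min, p.severity_max)) for g in screened_genes}
    truth.severities = severities

    def scores(latent: float) -> list[int]:
        noise = rng.normal(0.0, p.score_sd, size=p.flies_per_arm) if p.score_sd > 0 else np.zeros(p.flies_per_arm)
        return np.clip(np.rint(latent + noise), 0, 5).astype(int).tolist()

    rows: list[tuple[str, str, str, int]] = []

    def emit(line_id: str, gene_id: str, latent_rnai: float, latent_combo: float) -> None:
        for s in scores(latent_rnai):
            rows.append((line_id, gene_id, "rnai_only", s))
        for s in scores(latent_combo):
            rows.append((line_id, gene_id, "rnai_mitoxhoi", s))

    emit("ctrl-1", "ctrl", p.control_rnai_mean, p.control_combo_mean)
    for gene in screened_genes:
        sev = severities[gene]
        factor = p.synergy_factor if gene in synergy else 1.0
        for li in range(1, p.lines_per_gene + 1):
            emit(f"{gene}-L{li}", gene, p.control_rnai_mean * sev, p.control_combo_mean * sev * factor)
    return pd.DataFrame(rows, columns=["line_id", "gene_id", "arm", "score"])


def _plain(obj):
    """Recursively convert tuples to lists for YAML emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class SimulationBundle:
    config: SimulationConfig
    annotation: GenomeAnnotation
    mito: GeneSet
    truth: GroundTruth
    peaksets: dict[str, PeakSet]
    deg: DEGTable
    screen_scores: pd.DataFrame


def simulate_all(config: SimulationConfig, knockout_tf: str | None = None) -> SimulationBundle:
    """Run every generator stage in order and return the bundle + truth."""
    annotation, mito = simulate_annotation(config)
    graph, layers, scc_of = simulate_hierarchy(config)
    rng_assign = _stage_rng(config.seed, 5)  # own substream for TF-gene mapping and target planting
    truth = GroundTruth(graph=graph, layers=layers, scc_of=scc_of, tf_gene={}, targets={}, mito_genes=set(mito.genes))
    truth.tf_gene = _assign_tf_genes(annotation, sorted(graph.nodes), mito, rng_assign)
    _plant_targets(truth, annotation, mito, config, rng_assign)
    peaksets = simulate_peaks(truth, annotation, config)
    if knockout_tf is None:
        core = [t for t, l in sorted(truth.layers.items()) if l == "core"]
        knockout_tf = core[0] if core else sorted(graph.nodes)[0]
    deg = simulate_deg(truth, knockout_tf, annotation, config)
    screen_scores = simulate_screen(truth, config)
    return SimulationBundle(
        config=config,
        annotation=annotation,
        mito=mito,
        truth=truth,
        peaksets=peaksets,
        deg=deg,
        screen_scores=screen_scores,
    )


def emit_bundle(bundle: SimulationBundle, out_dir) -> dict[str, str]:
    """Write every emitted file of a simulation; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_annotation(bundle.annotation, out / "annotation.tsv")
    paths["annotation"] = str(out / "annotation.tsv")
    write_gene_set(bundle.mito, out / "mito_genes.tsv")
    paths["mito_genes"] = str(out / "mito_genes.tsv")
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for tf, ps in sorted(bundle.peaksets.items()):
        write_narrowpeak(ps, peaks_dir / f"{tf}.narrowPeak")
    paths["peaks_dir"] = str(peaks_dir)
    write_deg_table(bundle.deg, out / "deg.tsv")
    paths["deg"] = str(out / "deg.tsv")
    bundle.screen_scores.to_csv(out / "screen_scores.tsv", sep="\t", index=False)
    paths["screen_scores"] = str(out / "screen_scores.tsv")
    tf_map = pd.DataFrame(sorted(bundle.truth.tf_gene.items()), columns=["tf", "gene_id"])
    tf_map.to_csv(out / "tf_gene_map.tsv", sep="\t", index=False)
    paths["tf_gene_map"] = str(out / "tf_gene_map.tsv")
    (out / "ground_truth.json").write_text(bundle.truth.to_json())
    paths["ground_truth"] = str(out / "ground_truth.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_plain(asdict(bundle.config)), fh, sort_keys=True)
    paths["config"] = str(out / "config.yaml")
    return paths
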