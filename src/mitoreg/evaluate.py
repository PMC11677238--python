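"""Benchmark experiments run on the synthetic generator.

Two standing experiments quantify how well the pipeline recovers planted
truth: exact recovery at zero noise across independent simulations, and
the power / false-positive rate of the screen's enhancer call under
score noise. Both are consumed by the test suite and by the acceptance
script; neither touches any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from . import binding, integration, network, screen
from .simulate import (
    GroundTruth,
    ScreenSimParams,
    SimulationConfig,
    simulate_all,
    simulate_screen,
)

__all__ = ["RecoveryResult", "zero_noise_recovery", "PowerResult", "screen_power", "wilson_interval"]


@dataclass
class RecoveryResult:
    n_seeds: int
    n_recovered: int
    component_failures: dict[str, int]

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_seeds


def _recover_one(seed: int, base: SimulationConfig | None = None) -> dict[str, bool]:
    config = (base or SimulationConfig()).with_zero_noise()
    config = replace(config, seed=seed)
    b = simulate_all(config)
    out: dict[str, bool] = {}

    assignments = {tf: binding.assign_peaks_to_genes(ps, b.annotation) for tf, ps in b.peaksets.items()}
    matrix = binding.build_binding_matrix(assignments, b.annotation.gene_ids)
    out["target_sets"] = all(matrix.targets_of(tf) == b.truth.targets[tf] for tf in b.truth.targets)

    graph = network.build_tf_network(matrix, b.truth.tf_gene)
    hierarchy = network.vertex_sort(graph)
    out["layers"] = hierarchy.layers() == b.truth.layers

    classes = integration.classify_table(b.deg)
    out["deg_classes"] = dict(classes.items()) == b.truth.deg_class

    ind = network.indirect_targets(
        b.truth.knockout_tf, graph, matrix, deg=b.deg, tf_gene_map=b.truth.tf_gene
    )
    out["indirect_targets"] = (
        ind.all_indirect == b.truth.indirect and ind.indirect_down == b.truth.indirect_down
    )

    result = screen.score_screen(b.screen_scores, control_rnai_line="ctrl-1")
    enhancers = {g for g, c in result.gene_calls.items() if c.call == "enhancer"}
    out["screen_calls"] = enhancers == b.truth.synergy_genes
    return out


def zero_noise_recovery(seeds: range | list[int], base: SimulationConfig | None = None) -> RecoveryResult:
    """Run the full pipeline on zero-noise simulations and compare to truth.

    A seed counts as recovered only when every component — per-TF target
    sets, hierarchy layers, DEG classes, indirect-target sets, and screen
    enhancer calls — matches the planted ground truth exactly.
    """
    failures: dict[str, int] = {}
    n_ok = 0
    seeds = list(seeds)
    for seed in seeds:
        comp = _recover_one(seed, base)
        if all(comp.values()):
            n_ok += 1
        for name, ok in comp.items():
            if not ok:
                failures[name] = failures.get(name, 0) + 1
    return RecoveryResult(n_seeds=len(seeds), n_recovered=n_ok, component_failures=failures)


def wilson_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    # clamp to [0, 1] and guarantee the point estimate is inside under rounding
    return (min(max(0.0, centre - half), p), max(min(1.0, centre + half), p))


@dataclass
class PowerResult:
    n_replicates: int
    n_synergy_genes: int
    n_null_genes: int
    power: float
    power_ci: tuple[float, float]
    false_positive_rate: float
    fpr_ci: tuple[float, float]


def screen_power(
    synergy_factor: float = 0.6,
    score_sd: float = 0.5,
    flies_per_arm: int = 30,
    n_replicates: int = 500,
    genes_per_replicate: int = 10,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power and type-I error of the enhancer call.

    Each replicate simulates a small screen (half its genes planted
    synergistic at the given factor, half null) and scores it with the
    default slope thresholds. Power is the fraction of synergy genes
    called enhancer; the false-positive rate is the fraction of null
    genes called enhancer. Wilson 95% intervals accompany both.
    """
    rep_seeds = (np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)).tolist()
    n_hit = n_syn = n_fp = n_null = 0
    for rep_seed in rep_seeds:
        params = ScreenSimParams(
            flies_per_arm=flies_per_arm,
            synergy_factor=synergy_factor,
            score_sd=score_sd,
            frac_synergy=0.5,
        )
        config = replace(SimulationConfig(seed=int(rep_seed)), screen=params)
        truth = GroundTruth(graph=nx.DiGraph(), layers={}, scc_of={}, tf_gene={}, targets={})
        genes = [f"gene{i:02d}" for i in range(genes_per_replicate)]
        scores = simulate_screen(truth, config, screened_genes=genes)
        result = screen.score_screen(scores, control_rnai_line="ctrl-1")
        for gene in genes:
            call = result.gene_calls[gene].call
            if gene in truth.synergy_genes:
                n_syn += 1
                n_hit += call == "enhancer"
            else:
                n_null += 1
                n_fp += call == "enhancer"
    return PowerResult(
        n_replicates=n_replicates,
        n_synergy_genes=n_syn,
        n_null_genes=n_null,
        power=n_hit / n_syn,
        power_ci=wilson_interval(n_hit, n_syn),
        false_positive_rate=n_fp / n_null,
        fpr_ci=wilson_interval(n_fp, n_null),
    )
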