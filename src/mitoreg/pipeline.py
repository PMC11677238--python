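"""Orchestration of the analysis stages behind one declarative config.

A pipeline config is a plain mapping (usually loaded from YAML) with one
section per stage; every stage parameter defaults to the values used
throughout the package (enhancer slope 0.75, suppressor slope 1.5, 2 kb
promoter windows, FDR 0.05, |log2FC| > 1). Stages run in dependency
order; a stage whose inputs are missing is skipped and the skip recorded
in the report, so partial runs are first-class. Every output table
carries a header comment with the config hash, and reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import binding as _binding
from . import genome_io as gio
from . import network as _network
from . import screen as _screen
from .integration import DEGClassParams, intersect_binding_deg, fold_change_summary

log = logging.getLogger("mitoreg")

DEFAULTS: dict[str, Any] = {
    "screen": {
        "scores": None,
        "control_rnai": None,
        "control_combo": None,
        "enhancer_slope": 0.75,
        "suppressor_slope": 1.5,
        "calibrate_on": None,
    },
    "bind": {
        "peaks_dir": None,
        "annotation": None,
        "annotation_format": "tss_tsv",
        "mode": "promoter",
        "w_up": 2000,
        "w_down": 2000,
        "universe": None,  # gene-set file restricting the matrix; default: all annotated genes
        "target_set": None,
    },
    "network": {
        "tf_gene_map": None,
        "focal_tf": None,
    },
    "integrate": {
        "deg": None,
        "q_max": 0.05,
        "lfc_min": 1.0,
        "focal_tf": None,
        "target_set": None,
    },
    "out_dir": "mitoreg_out",
}


def merge_config(user: Mapping[str, Any] | None) -> dict[str, Any]:
    """Defaults <- config file <- (CLI overrides applied by the caller)."""
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for key, value in (user or {}).items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    config: dict[str, Any]
    config_hash: str
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/skipped/failed: reason
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            path = out / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# mitoreg config_hash={self.config_hash}\n")
                table.to_csv(fh, sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(
                {"config_hash": self.config_hash, "stages": self.stages, "summary": self.summary},
                indent=1,
                sort_keys=True,
                default=str,
            )
        )


def _stage(report: ReportBundle, name: str):
    """Context wrapper logging stage outcome; validation failures abort the
    stage but never the run."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is None:
                report.stages.setdefault(name, "ok")
                log.info("stage=%s status=%s elapsed=%.2fs", name, report.stages[name], elapsed)
                return False
            report.stages[name] = f"failed: {exc}"
            log.error("stage=%s status=failed elapsed=%.2fs error=%s", name, elapsed, exc)
            return True  # swallow; later stages decide from report.stages

    return _Ctx()


def run_pipeline(config: Mapping[str, Any] | None = None) -> ReportBundle:
    """Execute all configured stages; see module docstring for semantics."""
    cfg = merge_config(config)
    report = ReportBundle(config=cfg, config_hash=config_hash(cfg))

    # --- screen ---
    scfg = cfg["screen"]
    if scfg.get("scores") and scfg.get("control_rnai"):
        with _stage(report, "screen"):
            frame = pd.read_csv(scfg["scores"], sep="\t")
            result = _screen.score_screen(
                frame,
                control_rnai_line=scfg["control_rnai"],
                control_combo_line=scfg.get("control_combo") or scfg["control_rnai"],
                enhancer_slope=scfg["enhancer_slope"],
                suppressor_slope=scfg["suppressor_slope"],
                calibrate_on=scfg.get("calibrate_on"),
            )
            report.tables["screen_lines"] = result.line_table
            report.tables["screen_genes"] = result.gene_table
            calls = result.gene_table["call"]
            report.summary["screen"] = {
                "n_genes": int(len(result.gene_calls)),
                "n_enhancer": int((calls == "enhancer").sum()),
                "n_suppressor": int((calls == "suppressor").sum()),
            }
    else:
        report.stages["screen"] = "skipped: no scores/control configured"

    # --- bind ---
    bcfg = cfg["bind"]
    matrix = None
    annotation = None
    target_set = None
    if bcfg.get("peaks_dir") and bcfg.get("annotation"):
        with _stage(report, "bind"):
            annotation = gio.read_annotation(bcfg["annotation"], format=bcfg.get("annotation_format", "tss_tsv"))
            universe = annotation.gene_ids
            if bcfg.get("universe"):
                universe = sorted(gio.read_gene_set(bcfg["universe"]).genes)
            assignments = {}
            for peak_file in sorted(Path(bcfg["peaks_dir"]).glob("*.narrowPeak")):
                tf = peak_file.stem
                peakset = gio.read_narrowpeak(peak_file, tf)
                assignments[tf] = _binding.assign_peaks_to_genes(
                    peakset, annotation, mode=bcfg["mode"], w_up=bcfg["w_up"], w_down=bcfg["w_down"]
                )
            if not assignments:
                raise FileNotFoundError(f"no .narrowPeak files under {bcfg['peaks_dir']}")
            matrix = _binding.build_binding_matrix(assignments, universe, mode=bcfg["mode"])
            report.tables["binding_matrix"] = matrix.to_frame().reset_index().rename(columns={"index": "gene_id"})
            pairs = [
                (tf, gene, ",".join(map(str, idx)))
                for tf, genes in sorted(matrix.support.items())
                for gene, idx in sorted(genes.items())
            ]
            report.tables["binding_pairs"] = pd.DataFrame(pairs, columns=["tf", "gene_id", "peak_indices"])
            if bcfg.get("target_set"):
                target_set = gio.read_gene_set(bcfg["target_set"])
                cov = _binding.coverage_stats(matrix, target_set)
                report.tables["coverage"] = cov.to_frame()
                report.summary["coverage"] = {
                    "set": cov.set_name,
                    "set_size": cov.set_size,
                    "n_bound_ge1": cov.n_bound_ge1,
                    "fraction_bound_ge1": cov.fraction_bound_ge1,
                    "tfs_over_half": cov.tfs_over_half,
                }
    else:
        report.stages["bind"] = "skipped: no peaks/annotation configured"

    # --- network ---
    ncfg = cfg["network"]
    graph = None
    tf_gene_map = None
    if matrix is not None and ncfg.get("tf_gene_map"):
        with _stage(report, "network"):
            map_df = pd.read_csv(ncfg["tf_gene_map"], sep="\t")
            tf_gene_map = dict(zip(map_df["tf"], map_df["gene_id"]))
            graph = _network.build_tf_network(matrix, tf_gene_map)
            hierarchy = _network.vertex_sort(graph)
            report.tables["hierarchy"] = hierarchy.to_frame()
            report.tables["edges"] = pd.DataFrame(sorted(graph.edges()), columns=["source", "target"])
            layer_counts = report.tables["hierarchy"]["layer"].value_counts().to_dict()
            report.summary["network"] = {"n_edges": graph.number_of_edges(), "layers": layer_counts}
    elif "network" not in report.stages:
        report.stages["network"] = "skipped: needs binding matrix and tf_gene_map"

    # --- integrate ---
    icfg = cfg["integrate"]
    if matrix is not None and icfg.get("deg"):
        with _stage(report, "integrate"):
            deg = gio.read_deg_table(icfg["deg"])
            params = DEGClassParams(q_max=icfg["q_max"], lfc_min=icfg["lfc_min"])
            focal = icfg.get("focal_tf") or ncfg.get("focal_tf")
            iset = target_set
            if icfg.get("target_set"):
                iset = gio.read_gene_set(icfg["target_set"])
            if focal is None:
                raise ValueError("integrate stage needs a focal_tf")
            table = intersect_binding_deg(
                matrix.targets_of(focal), deg, params, universe=matrix.gene_ids, target_set=iset
            )
            counts = table.counts.reset_index().rename(columns={"index": "bound_status"})
            report.tables["integration_counts"] = counts
            report.summary["integrate"] = {
                "focal_tf": focal,
                "n_bound": table.n_bound,
                "n_bound_down": table.n_bound_down,
                "n_bound_up": table.n_bound_up,
                "fraction_target_bound": table.fraction_target_bound,
                "fraction_bound_target_down": table.fraction_bound_target_down,
            }
            if iset is not None:
                report.tables["fold_change_summary"] = fold_change_summary(deg, iset)
            if graph is not None and tf_gene_map is not None:
                ind = _network.indirect_targets(
                    focal, graph, matrix, deg=deg, target_set=iset, tf_gene_map=tf_gene_map, params=params
                )
                report.summary["indirect"] = {
                    "n_downstream_tfs": len(ind.downstream_used),
                    "n_upstream_tfs": len(_network.upstream_tfs(focal, graph)),
                    "n_indirect": len(ind.all_indirect),
                    "n_indirect_down": len(ind.indirect_down),
                    "n_indirect_down_in_set": len(ind.indirect_down_in_set),
                }
    else:
        report.stages["integrate"] = "skipped: needs binding matrix and DEG table"

    return report


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
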