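"""End-to-end run driver: score → prioritize → benchmark → motifs.

A run is described by a YAML/dict config naming the input files and the
stage parameters; outputs are written to one directory together with a
JSON manifest (config echo, SHA-256 digests of the inputs, tool version,
seeds, per-stage row counts, timestamps) so a result can be traced back to
exactly the files and settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .benchmark import BenchmarkLabels, comparison_table, evaluate
from .core_model import load_id_list, load_inputs
from .domain_network import build_network, network_summary
from .hrc import CI_THRESHOLD, prioritize
from .motifs import motif_significance
from .wv_scoring import HWE_THRESHOLD, ClassCatalog, score_candidates

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "write_scores", "PipelineError"]

FLOAT_FMT = "%.6g"

SCORE_COLUMNS = [
    "protein",
    "gene_symbol",
    "best_domain",
    "n_partners",
    "raw_wv",
    "wv",
    "ci",
    "is_hwe",
    "is_hwec",
]


class PipelineError(RuntimeError):
    """A stage failed; ``exit_code`` distinguishes missing input (2) from
    validation failure (3)."""

    def __init__(self, message: str, exit_code: int = 1) -> None:
        super().__init__(message)
        self.exit_code = exit_code


def _fmt(value: Any) -> str:
    if isinstance(value, bool):
        return "Y" if value else "N"
    if isinstance(value, float):
        return FLOAT_FMT % value
    if value is None:
        return "-"
    return str(value)


def write_scores(candidates, path: str | Path) -> None:
    """Candidate score table, fixed column order, 6 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    _fmt(getattr(c, col)) for col in SCORE_COLUMNS
                )
                + "\n"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict:
    """Execute the full prioritization pipeline; returns the manifest.

    Config keys: ``inputs`` (edges, domain_protein_map, annotation, regions,
    class_a, class_b_processes, pfam2go, class_d, and optional
    benchmark_positives / benchmark_negatives), ``min_confidence``,
    ``aggregation``, ``normalization``, ``wv_threshold``, ``ci_threshold``,
    ``class_totals`` (optional 4-tuple), ``motifs`` (size, iterations,
    alpha, seed, or false to skip).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "domprior",
        "version": __version__,
        "format_version": 1,
        "started": datetime.now(timezone.utc).isoformat(),
        "config": json.loads(json.dumps(dict(config), default=str)),
        "stages": {},
    }

    def fail(stage: str, message: str, exit_code: int) -> PipelineError:
        manifest["failed_stage"] = stage
        manifest["error"] = message
        _write_manifest(manifest, outdir)
        return PipelineError(f"{stage}: {message}", exit_code)

    inputs = dict(config.get("inputs", {}))
    required = ("edges", "domain_protein_map", "annotation")
    for key in required:
        if key not in inputs:
            raise fail("load", f"missing required input {key!r}", 2)
    for key, path in inputs.items():
        if path and not Path(path).exists():
            raise fail("load", f"input file not found: {path}", 2)
    manifest["input_digests"] = {
        k: _sha256(Path(v)) for k, v in inputs.items() if v
    }

    try:
        bundle = load_inputs(
            edges=inputs["edges"],
            domain_protein_map=inputs["domain_protein_map"],
            annotation=inputs["annotation"],
            regions=inputs.get("regions"),
            class_a=inputs.get("class_a"),
            class_b_processes=inputs.get("class_b_processes"),
            pfam2go=inputs.get("pfam2go"),
            class_d=inputs.get("class_d"),
        )
    except Exception as exc:
        raise fail("load", str(exc), 3)

    # --- network -----------------------------------------------------------
    min_conf = float(config.get("min_confidence", 10.0))
    network = build_network(
        bundle.edges, min_conf, extra_nodes=bundle.dp_map.domains
    )
    summary = network_summary(network)
    manifest["stages"]["network"] = {
        "nodes": summary.node_count,
        "edges": summary.edge_count,
        "mean_degree": round(summary.mean_degree, 4),
        "mean_clustering": round(summary.mean_clustering, 4),
        "characteristic_path_length": round(
            summary.characteristic_path_length, 4
        ),
    }

    # --- scoring -----------------------------------------------------------
    totals = config.get("class_totals")
    catalog = ClassCatalog.from_members(
        bundle.class_a_domains,
        bundle.class_b_processes,
        bundle.pfam2go,
        bundle.regions,
        bundle.class_d_proteins,
        totals=tuple(totals) if totals else None,
    ).deduplicate_class_d(bundle.dp_map)
    try:
        candidates, excluded = score_candidates(
            network,
            catalog,
            bundle.dp_map,
            bundle.annotation,
            aggregation=config.get("aggregation", "sum"),
            normalization=config.get("normalization", "minmax"),
            cd_mode=config.get("cd_mode", "binary"),
        )
    except ValueError as exc:
        raise fail("score", str(exc), 3)

    # --- prioritization ----------------------------------------------------
    result = prioritize(
        candidates,
        wv_threshold=float(config.get("wv_threshold", HWE_THRESHOLD)),
        ci_threshold=float(config.get("ci_threshold", CI_THRESHOLD)),
    )
    write_scores(result.candidates, outdir / "scores.tsv")
    write_scores(result.hwec, outdir / "hwec.tsv")
    manifest["stages"]["score"] = {
        "candidates_in": len(bundle.annotation),
        "candidates_scored": len(result.candidates),
        "excluded_no_domain": len(excluded),
        "hwe": result.hwe_count,
        "hwec": result.hwec_count,
    }

    # --- benchmark (optional) ----------------------------------------------
    if inputs.get("benchmark_positives") and inputs.get("benchmark_negatives"):
        labels = BenchmarkLabels(
            positives=frozenset(load_id_list(inputs["benchmark_positives"])),
            negatives=frozenset(load_id_list(inputs["benchmark_negatives"])),
        )
        scores_map = {c.protein: c.wv for c in result.candidates}
        hwec_ids = {c.protein for c in result.hwec}
        hwe_ids = {c.protein for c in result.hwe}
        bench = evaluate(
            hwec_ids,
            labels,
            scores=scores_map,
            enrichment_def=config.get("enrichment_def", "density"),
        )
        table = comparison_table(
            {"Wv": hwe_ids, "Wv+HRC": hwec_ids}, labels
        )
        table.to_csv(outdir / "report.tsv", sep="\t")
        with open(outdir / "roc.tsv", "w") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for thr, fpr, tpr in bench.roc_points or []:
                fh.write(f"{_fmt(thr)}\t{_fmt(fpr)}\t{_fmt(tpr)}\n")
        manifest["stages"]["benchmark"] = {
            "tp": bench.matrix.tp,
            "fp": bench.matrix.fp,
            "tn": bench.matrix.tn,
            "fn": bench.matrix.fn,
            "sensitivity": _round(bench.sensitivity),
            "specificity": _round(bench.specificity),
            "accuracy": _round(bench.accuracy),
            "enrichment": _round(bench.enrichment),
            "auc": _round(bench.auc),
        }

    # --- motifs (optional) --------------------------------------------------
    motif_cfg = config.get("motifs", {})
    if motif_cfg is not False and motif_cfg is not None:
        motif_cfg = dict(motif_cfg) if isinstance(motif_cfg, Mapping) else {}
        results = motif_significance(
            network,
            size=int(motif_cfg.get("size", 3)),
            iterations=int(motif_cfg.get("iterations", 100)),
            alpha=float(motif_cfg.get("alpha", 0.01)),
            seed=int(motif_cfg.get("seed", config.get("seed", 0))),
        )
        with open(outdir / "motifs.tsv", "w") as fh:
            fh.write(
                "motif_id\tsize\treal_count\tnull_mean\tnull_sd\tz\tp\tsignificant\n"
            )
            for r in results:
                fh.write(
                    f"{r.motif.name}\t{r.motif.size}\t{r.real_count}\t"
                    f"{_fmt(r.null_mean)}\t{_fmt(r.null_sd)}\t"
                    f"{_fmt(r.z_score)}\t{_fmt(r.p_value)}\t"
                    f"{_fmt(r.significant)}\n"
                )
        manifest["stages"]["motifs"] = {
            "classes": len(results),
            "significant": sum(r.significant for r in results),
        }

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    _write_manifest(manifest, outdir)
    return manifest


def _round(value: float | None, digits: int = 4) -> float | None:
    return None if value is None else round(value, digits)


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=False)
        fh.write("\n")
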