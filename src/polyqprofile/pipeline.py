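"""End-to-end pipeline orchestration.

Composes the stages in analysis order — scan (L2G filter + sweep), shared-
trait network on the scan-retained catalog, prioritization (count-trait and
provenance filters + per-gene dedup), LD signal identification on the
prioritized records, and drug-target risk profiling — writing deterministic
TSV/JSON artifacts plus a run manifest. The manifest is the only output
carrying a timestamp, so all data artifacts are byte-reproducible.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from . import io as pio
from .ld import HaplotypeSignal, prune_catalog
from .network import build_network, export_network, isolated_genes
from .prioritize import prioritize_catalog, summarize_ancestry
from .risk import aggregate_scores, compare_gene_sets, verdict_frame
from .scan import filter_by_l2g, summarize_scan, threshold_sweep
from .types import ThresholdConfig

__all__ = ["PipelineInputs", "StageError", "run_pipeline", "write_haplotype_table"]

log = logging.getLogger("polyqprofile.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and preserves the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PipelineInputs:
    catalog: Path
    ld: Mapping[str, Path] = field(default_factory=dict)  # gene -> LD TSV
    features: Optional[Path] = None
    interactions: Optional[Path] = None
    omim: Optional[Path] = None
    compare_features: Optional[Path] = None
    compare_interactions: Optional[Path] = None

    def digests(self) -> dict[str, str]:
        out = {}
        for name, path in self._named_paths():
            out[name] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        return out

    def _named_paths(self):
        yield "catalog", self.catalog
        for gene, path in sorted(self.ld.items()):
            yield f"ld:{gene}", path
        for name in ("features", "interactions", "omim", "compare_features",
                     "compare_interactions"):
            path = getattr(self, name)
            if path is not None:
                yield name, path


def write_haplotype_table(haplotypes: Sequence[HaplotypeSignal], path) -> Path:
    path = Path(path)
    lines = ["gene_symbol\thaplotype_index\ttag_variant\tmember_variants\tn_traits\tn_distinct_traits"]
    for h in haplotypes:
        lines.append(
            f"{h.gene_symbol}\t{h.haplotype_index}\t{h.tag_variant}\t"
            f"{';'.join(h.member_variants)}\t{h.n_traits}\t{h.n_distinct_traits}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def run_pipeline(cfg: ThresholdConfig, inputs: PipelineInputs, outdir) -> Path:
    """Run every stage on the given inputs, writing artifacts under ``outdir``.

    Returns ``outdir``. Any stage failure raises :class:`StageError` after
    writing a manifest of the stages completed so far.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "polyqprofile",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": cfg.rng_seed,
        "config": json.loads(json.dumps({
            "l2g_cutoff": cfg.l2g_cutoff,
            "r2_cutoff": cfg.r2_cutoff,
            "pli_cutoff": cfg.pli_cutoff,
            "mi_cutoff": cfg.mi_cutoff,
            "partner_cutoff": cfg.partner_cutoff,
            "count_trait_patterns": list(cfg.count_trait_patterns),
            "sweep_grid": list(cfg.sweep_grid),
        })),
        "inputs": inputs.digests(),
        "stages": {},
    }

    def _finish_manifest():
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
        )

    try:
        stage = "scan"
        records = pio.read_association_table(inputs.catalog, cfg)
        retained = filter_by_l2g(records, cfg.l2g_cutoff)
        summary = summarize_scan(retained)
        sweep = threshold_sweep(records, cfg.sweep_grid)
        pio.write_association_table(retained, outdir / "scan_retained.tsv")
        (outdir / "scan_summary.json").write_text(
            json.dumps(
                {"summary": summary.to_dict(),
                 "sweep": {str(k): v for k, v in sweep.items()}},
                indent=2,
            ) + "\n",
            encoding="utf-8",
        )
        manifest["stages"]["scan"] = {"n_in": len(records), "n_retained": len(retained)}

        stage = "network"
        network = build_network(retained)
        export_network(network, outdir / "network_edges.tsv", "edge_list_tsv")
        export_network(network, outdir / "network.graphml", "graphml")
        isolated = isolated_genes(network, {r.gene_symbol for r in retained})
        manifest["stages"]["network"] = {
            "n_nodes": len(network.nodes),
            "n_edges": len(network.edges),
            "isolated_genes": sorted(isolated),
        }

        stage = "prioritize"
        prioritized, report = prioritize_catalog(retained, cfg.count_trait_patterns)
        pio.write_association_table(prioritized, outdir / "prioritized.tsv")
        payload = {"report": report.to_dict()}
        try:
            payload["ancestry"] = summarize_ancestry(prioritized).to_dict()
        except ValueError as exc:
            payload["ancestry"] = {"error": str(exc)}
        (outdir / "prioritization_report.json").write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )
        manifest["stages"]["prioritize"] = {
            "n_retained": report.n_retained,
            "n_unique_after_dedup": report.n_unique_after_dedup,
        }

        stage = "signals"
        if inputs.ld:
            ld = {gene: pio.read_ld_matrix(path) for gene, path in inputs.ld.items()}
            haplotypes = prune_catalog(prioritized, ld, cfg.r2_cutoff)
            write_haplotype_table(haplotypes, outdir / "haplotypes.tsv")
            manifest["stages"]["signals"] = {
                "n_haplotypes": len(haplotypes),
                "per_gene": {
                    g: sum(1 for h in haplotypes if h.gene_symbol == g)
                    for g in sorted({h.gene_symbol for h in haplotypes})
                },
            }

        stage = "profile"
        if inputs.features is not None:
            profiles = pio.read_profile_table(inputs.features, inputs.interactions)
            verdicts = aggregate_scores(profiles, cfg)
            frame = verdict_frame(verdicts)
            frame.to_csv(outdir / "verdicts.tsv", sep="\t", index=False, na_rep=".")
            scores = [v.safety_score for v in verdicts]
            profile_payload: dict = {
                "n_genes": len(scores),
                "mean_safety_score": round(sum(scores) / len(scores), 1) if scores else None,
            }
            if inputs.compare_features is not None:
                compare = pio.read_profile_table(
                    inputs.compare_features, inputs.compare_interactions
                )
                result, _, verdicts_b = compare_gene_sets(profiles, compare, cfg)
                profile_payload["comparison"] = result.to_dict()
                verdict_frame(verdicts_b).to_csv(
                    outdir / "verdicts_compare.tsv", sep="\t", index=False, na_rep="."
                )
            (outdir / "profile_summary.json").write_text(
                json.dumps(profile_payload, indent=2) + "\n", encoding="utf-8"
            )
            manifest["stages"]["profile"] = {
                "n_genes": len(scores),
                "mean_safety_score": profile_payload["mean_safety_score"],
            }

        stage = "omim"
        if inputs.omim is not None:
            from .prioritize import classify_omim_entries

            entries = pio.read_omim_table(inputs.omim)
            counts = classify_omim_entries(entries)
            (outdir / "omim_classes.json").write_text(
                json.dumps(counts, indent=2) + "\n", encoding="utf-8"
            )
            manifest["stages"]["omim"] = counts
    except Exception as exc:
        manifest["failed_stage"] = stage
        _finish_manifest()
        raise StageError(stage, exc) from exc

    _finish_manifest()
    log.info("pipeline complete: %s", outdir)
    return outdir
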