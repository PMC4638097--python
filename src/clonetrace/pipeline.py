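"""End-to-end patient analysis: filter -> partition -> tree -> contexts -> stats.

`run_pipeline` composes the library stages on one patient's inputs (a
multi-sample VCF, a reference FASTA, optional known-sites VCF and driver
gene list) and persists every intermediate table, a Newick tree with
bootstrap supports, and a JSON + Markdown report.  All numbers in the
report are re-derivable from the emitted TSVs; given a fixed seed, reruns
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pyfaidx
import pysam

from . import __version__
from .context import trinucleotide_context, tally_contexts, substitution_table
from .impact import classify_functional, driver_overlap, impact_summary, read_gene_list
from .phylo import (
    binary_distance, bionj, bootstrap_support, flag_normal_contamination,
    root_with_reference, tumour_monophyly, upgma,
)
from .sharing import SharingClass, partition_counts, partition_table
from .stats import compare_functional, compare_tpc
from .variant_matrix import (
    NORMAL, TUMOUR, add_reference_row, binarize, exclude_known_sites,
    filter_high_confidence, read_multisample_vcf,
)

logger = logging.getLogger(__name__)

VERDICT_CLONAL = "clonal origin"
VERDICT_FIELD = "not monophyletic / field-consistent"


@dataclass
class PipelineConfig:
    vcf: Path
    reference_fasta: Path
    normal: str
    tumours: Sequence[str]
    outdir: Path
    known: Optional[Path] = None
    drivers: Optional[Path] = None
    min_reads: int = 4
    depth_mode: str = "called"
    bootstrap_reps: int = 10_000
    seed: int = 17

    @property
    def roles(self) -> dict[str, str]:
        return {self.normal: NORMAL, **{t: TUMOUR for t in self.tumours}}


@dataclass
class PatientReport:
    config: PipelineConfig
    filter_stats: dict
    partition: dict
    newick: str
    monophyletic: bool
    tumour_clade_support: Optional[float]
    verdict: str
    contamination: dict
    functional: dict
    enrichment: dict  # named comparisons -> EnrichmentResult dicts
    context_excluded: int
    driver_rows: int = 0
    missense_tpc_fraction: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "clonetrace_version": __version__,
            "seed": self.config.seed,
            "parameters": {
                "min_reads": self.config.min_reads,
                "depth_mode": self.config.depth_mode,
                "bootstrap_reps": self.config.bootstrap_reps,
                "normal": self.config.normal,
                "tumours": list(self.config.tumours),
            },
            "filter_stats": self.filter_stats,
            "partition": self.partition,
            "tree_newick": self.newick,
            "monophyletic": self.monophyletic,
            "tumour_clade_support": self.tumour_clade_support,
            "verdict": self.verdict,
            "contamination": self.contamination,
            "functional": self.functional,
            "enrichment": self.enrichment,
            "context_unknown_excluded": self.context_excluded,
            "driver_rows": self.driver_rows,
            "missense_tpc_fraction": self.missense_tpc_fraction,
        }


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
    return wrap


def run_pipeline(cfg: PipelineConfig) -> PatientReport:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "clonetrace %s | seed=%d reps=%d min_reads=%d",
        __version__, cfg.seed, cfg.bootstrap_reps, cfg.min_reads,
    )

    # -- filter ---------------------------------------------------------
    stage = _stage("filter")
    header = pysam.VariantFile(str(cfg.vcf)).header
    samples = [s for s in header.samples if s in cfg.roles]
    records = stage(read_multisample_vcf, cfg.vcf, cfg.roles, cfg.depth_mode)
    stats: dict = {}
    records = stage(filter_high_confidence, records, cfg.min_reads, stats)
    if cfg.known is not None:
        records = stage(exclude_known_sites, records, cfg.known, stats)
    matrix = stage(binarize, records, samples, cfg.roles)
    matrix.to_tsv(out / "matrix.tsv")

    # -- partition ------------------------------------------------------
    stage = _stage("partition")
    partition = stage(partition_counts, matrix)
    partition_table(matrix, partition).to_csv(out / "partition.tsv", sep="\t", index=False)
    partition.to_json(out / "partition.json")

    # -- tree / bootstrap -----------------------------------------------
    stage = _stage("tree")
    ref_matrix = stage(add_reference_row, matrix)
    tree = stage(
        bootstrap_support, ref_matrix, reps=cfg.bootstrap_reps, seed=cfg.seed
    )
    rooted = stage(root_with_reference, tree)
    newick = rooted.newick()
    (out / "tree.nwk").write_text(newick + "\n")
    from .trees import bipartitions as _bipartitions

    split_rows = [
        {
            "bipartition": "|".join(sorted(split)),
            "support_pct": node.support,
            "edge_length": node.length,
        }
        for split, node in sorted(
            _bipartitions(tree).items(), key=lambda kv: sorted(kv[0])
        )
    ]
    pd.DataFrame(
        split_rows, columns=["bipartition", "support_pct", "edge_length"]
    ).to_csv(out / "bipartitions.tsv", sep="\t", index=False)
    upgma_tree = stage(upgma, binary_distance(ref_matrix))
    (out / "tree_upgma.nwk").write_text(upgma_tree.newick(include_support=False) + "\n")
    mono = stage(tumour_monophyly, tree, cfg.roles)
    contamination = stage(
        flag_normal_contamination, rooted, cfg.roles, partition, ref_matrix
    )
    verdict = VERDICT_CLONAL if mono.monophyletic else VERDICT_FIELD

    # -- mutation contexts ----------------------------------------------
    stage = _stage("context")
    genome = stage(pyfaidx.Fasta, str(cfg.reference_fasta))
    contexts = [
        stage(trinucleotide_context, genome, m.chrom, m.pos, m.ref, m.alt)
        if len(m.ref) == 1 and len(m.alt) == 1 and m.ref in "ACGT" and m.alt in "ACGT"
        else None
        for m in matrix.markers
    ]
    from .context import ContextLabel
    contexts = [c if c is not None else ContextLabel.UNKNOWN for c in contexts]
    groups = {
        cls.value: [
            i for i, a in enumerate(partition.assignments) if a.sharing == cls
        ]
        for cls in SharingClass
    }
    groups["TUMOUR_PRIVATE_POOLED"] = groups.pop(SharingClass.TUMOUR_PRIVATE.value)
    tallies = tally_contexts(contexts, groups)
    tallies.to_csv(out / "contexts.tsv", sep="\t", index=False)
    substitution_table(contexts, groups).to_csv(
        out / "substitutions.tsv", sep="\t", index=False
    )
    n_unknown = sum(1 for c in contexts if not c.valid)

    # -- stats ----------------------------------------------------------
    stage = _stage("stats")
    impacts = [stage(classify_functional, m.annotation) for m in matrix.markers]
    functional_flags = [c.functional for c in impacts]
    tpc_flags = [c.is_tpc if c.valid else None for c in contexts]
    trunk = groups[SharingClass.TUMOUR_SHARED.value]
    germline = groups[SharingClass.ALL_SHARED.value]
    private = groups["TUMOUR_PRIVATE_POOLED"]
    enrichment = {
        "functional_trunk_vs_germline": compare_functional(
            functional_flags, trunk, germline
        ),
        "tpc_trunk_vs_germline": compare_tpc(tpc_flags, trunk, germline),
        "tpc_trunk_vs_private": compare_tpc(
            tpc_flags, trunk, private, ("TUMOUR_SHARED", "TUMOUR_PRIVATE_POOLED")
        ),
    }
    for t in matrix.tumour_samples:  # per-tumour timing breakdown
        idx = [
            i for i, a in enumerate(partition.assignments)
            if a.sharing == SharingClass.TUMOUR_PRIVATE and a.private_sample == t
        ]
        if idx:
            enrichment[f"tpc_trunk_vs_private_{t}"] = compare_tpc(
                tpc_flags, trunk, idx, ("TUMOUR_SHARED", f"TUMOUR_PRIVATE_{t}")
            )
    enrich_rows = []
    for name, res in enrichment.items():
        d = res.to_dict()
        enrich_rows.append(
            {
                "comparison": name,
                "a": d["table"][0][0], "b": d["table"][0][1],
                "c": d["table"][1][0], "d": d["table"][1][1],
                "p_value": d["p_value"], "fold": d["fold"],
                "degenerate": d["degenerate"],
            }
        )
    pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # -- drivers --------------------------------------------------------
    driver_rows, missense_tpc = 0, None
    if cfg.drivers is not None:
        stage = _stage("drivers")
        genes = stage(read_gene_list, cfg.drivers)
        tumour_present = [
            any(matrix.row(t)[i] for t in matrix.tumour_samples)
            for i in range(matrix.n_markers)
        ]
        drv = stage(
            driver_overlap,
            matrix.markers, impacts, partition.assignments,
            tumour_present, [bool(f) for f in tpc_flags], genes,
        )
        drv.to_csv(out / "drivers.tsv", sep="\t", index=False)
        driver_rows = len(drv)
        missense_tpc = drv.attrs["missense_tpc_fraction"]

    report = PatientReport(
        config=cfg,
        filter_stats=stats,
        partition=partition.to_dict(),
        newick=newick,
        monophyletic=mono.monophyletic,
        tumour_clade_support=mono.support,
        verdict=verdict,
        contamination=contamination.to_dict(),
        functional=impact_summary(impacts),
        enrichment={k: v.to_dict() for k, v in enrichment.items()},
        context_excluded=n_unknown,
        driver_rows=driver_rows,
        missense_tpc_fraction=missense_tpc,
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    (out / "report.md").write_text(render_report_md(report))
    return report


def render_report_md(report: PatientReport) -> str:
    p = report.partition
    lines = [
        "# clonetrace patient report",
        "",
        f"- markers analysed: **{p['total']}**",
        f"- tumour-associated fraction: **{p['tumour_associated_fraction']:.3f}**",
        f"- verdict: **{report.verdict}** "
        f"(tumour clade support {report.tumour_clade_support:.1f} %)"
        if report.tumour_clade_support is not None
        else f"- verdict: **{report.verdict}**",
        f"- normal-contamination flag: **{report.contamination['flagged']}**",
        "",
        "## Sharing partition",
        "",
        "| class | count | fraction |",
        "| --- | --- | --- |",
    ]
    for cls in SharingClass:
        lines.append(
            f"| {cls.value} | {p['counts'][cls.value]} | {p['fractions'][cls.value]:.3f} |"
        )
    lines += ["", "## Enrichment", "", "| comparison | fold | p |", "| --- | --- | --- |"]
    for name, res in report.enrichment.items():
        fold = res["fold"]
        fold_s = f"{fold:.2f}" if fold == fold and fold != float("inf") else str(fold)
        lines.append(f"| {name} | {fold_s} | {res['p_value']:.3g} |")
    lines += ["", "## Tree", "", "```", report.newick, "```", ""]
    return "\n".join(lines)
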