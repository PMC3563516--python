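"""End-to-end orchestration: simulate -> clean -> map -> annotate ->
known profiling -> novel discovery -> differential expression -> qPCR.

`run_synthetic` drives the whole pipeline on the synthetic study and
writes every table the analysis produces; `validate_outputs` re-reads the
written tables and re-checks the cross-table conservation identities
(cleaning ledger, category partition, DE totals) so a results directory
can be audited after the fact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, diffexpr, io, known, mapping, novel, qpcr, simulate
from .config import PipelineConfig, SimulationConfig

log = logging.getLogger("bovmir")

LIBRARIES = ("fetal", "adult")


@dataclass
class PipelineResult:
    tag_counts: pd.DataFrame
    summaries: dict
    category_table: pd.DataFrame
    profiles: dict
    leftover: pd.DataFrame
    edits: list
    discovery: novel.DiscoveryResult
    de: pd.DataFrame
    totals: dict
    extras: dict = field(default_factory=dict)


def analyze(
    reads_per_library: dict,
    genome: dict,
    loci: list,
    matures: dict,
    hairpins: dict,
    families: dict,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the analysis stages on raw reads plus references."""
    cfg = config or PipelineConfig()
    libraries = list(reads_per_library)

    tags = {}
    summaries = {}
    for lib in libraries:
        tags[lib], summaries[lib] = cleaning.clean_library(reads_per_library[lib], cfg)
        log.info(
            "cleaned %s: %d high-quality -> %d clean reads, %d unique tags",
            lib, summaries[lib].high_quality, summaries[lib].clean_reads, len(tags[lib]),
        )
    tag_counts = cleaning.merge_tag_counts(tags)
    totals = {lib: summaries[lib].clean_reads for lib in libraries}

    index = mapping.GenomeIndex(genome, k=cfg.index_k)
    hits, unmatched = mapping.map_tags(tag_counts.index, index)
    log.info("mapped %d/%d unique tags to the genome", len(hits), len(tag_counts))
    assignment = mapping.annotate_tags(hits, loci, cfg)
    category_table = mapping.category_summary(assignment, tag_counts, cfg.annotation_priority)

    profiles, leftover = known.match_known(tag_counts, matures, hairpins, cfg)
    log.info(
        "known matching: %d tags left over of %d", len(leftover), len(tag_counts)
    )
    ref_weights = {mid: p.reads() for mid, p in profiles.items()}
    edits, unexplained = known.detect_base_edits(leftover, matures, hairpins, ref_weights)

    novel_input = unexplained.loc[
        [t for t in unexplained.index if assignment.get(t) == "unknown"]
    ]
    discovery = novel.discover_novel(novel_input, index, genome, cfg)
    log.info(
        "novel discovery: %d candidates evaluated, %d accepted",
        len(discovery.candidates), len(discovery.novel),
    )

    counts1 = {mid: p.total.get(libraries[0], 0) for mid, p in profiles.items()}
    counts2 = {mid: p.total.get(libraries[1], 0) for mid, p in profiles.items()}
    for n in discovery.novel:
        counts1[n.novel_id] = n.counts.get(libraries[0], 0)
        counts2[n.novel_id] = n.counts.get(libraries[1], 0)
    de = diffexpr.de_table(counts1, counts2, totals[libraries[0]], totals[libraries[1]], cfg)

    extras = {"novel_input": novel_input, "unmatched": unmatched, "assignment": assignment}
    return PipelineResult(
        tag_counts=tag_counts,
        summaries=summaries,
        category_table=category_table,
        profiles=profiles,
        leftover=leftover,
        edits=edits,
        discovery=discovery,
        de=de,
        totals=totals,
        extras=extras,
    )


def write_outputs(result: PipelineResult, outdir, matures, hairpins, families,
                  config: PipelineConfig | None = None) -> None:
    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    libraries = list(result.summaries)

    (out / "config.json").write_text(cfg.to_json())
    io.write_table(cleaning.summaries_to_table(result.summaries), out / "cleaning_summary.tsv")
    io.write_table(cleaning.length_distribution(result.tag_counts), out / "length_distribution.tsv")
    io.write_tags_tsv(result.tag_counts, out / "tags.tsv")
    io.write_table(result.category_table, out / "category_summary.tsv")
    pct = mapping.category_percentages(result.category_table, {
        f"{lib}_unique": int((result.tag_counts[lib] > 0).sum()) for lib in libraries
    } | {f"{lib}_reads": result.totals[lib] for lib in libraries})
    io.write_table(pct, out / "category_percentages.tsv")

    io.write_table(known.profile_table(result.profiles, libraries), out / "known_profiles.tsv")
    class_table = pd.DataFrame({lib: known.class_summary(result.profiles, lib) for lib in libraries})
    io.write_table(class_table, out / "known_class_summary.tsv")
    io.write_table(known.arm_usage(result.profiles), out / "arm_usage.tsv")
    io.write_table(known.nucleotide_bias(result.profiles), out / "nucleotide_bias.tsv")
    io.write_table(known.edits_table(result.edits, libraries), out / "base_edits.tsv", index=False)
    variants = known.catalog_end_variants(result.profiles, matures, hairpins)
    io.write_table(variants, out / "end_variants.tsv", index=False)
    fam_table, unassigned = known.assign_families(result.profiles, families)
    io.write_table(fam_table, out / "families.tsv")
    (out / "families_unassigned.txt").write_text("\n".join(unassigned) + "\n")

    io.write_table(novel.novel_table(result.discovery, libraries), out / "novel_mirnas.tsv", index=False)
    io.write_fasta(
        {n.novel_id: n.candidate.precursor for n in result.discovery.novel},
        out / "novel_precursors.fa",
    )
    with open(out / "novel_structures.txt", "w") as fh:
        for n in result.discovery.novel:
            fh.write(f">{n.novel_id}\n{n.candidate.precursor}\n{n.candidate.structure}\n")

    io.write_table(result.de, out / "de_table.tsv")
    io.write_table(diffexpr.de_summary(result.de).to_frame("count"), out / "de_summary.tsv")
    diffexpr.scatter_plot(result.de, out / "de_scatter.png")
    genome_matched = {
        lib: int(result.category_table[f"{lib}_reads"].sum()) for lib in libraries
    }
    totals_payload = {
        "totals": result.totals,
        "high_quality": {lib: result.summaries[lib].high_quality for lib in libraries},
        "genome_matched": genome_matched,
    }
    (out / "totals.json").write_text(json.dumps(totals_payload, indent=2))


def run_synthetic(
    sim_config: SimulationConfig | None = None,
    pipe_config: PipelineConfig | None = None,
    outdir=None,
):
    """Simulate the default study and analyse it; optionally write outputs.

    Returns (ground truth, pipeline result).
    """
    sim = sim_config or SimulationConfig()
    cfg = pipe_config or PipelineConfig(
        adapter3=sim.adapter3, adapter5=sim.adapter5, seed=sim.seed
    )
    genome, gt = simulate.generate_genome(sim)
    reads = simulate.simulate_reads(genome, gt, sim)
    matures = gt.mature_fasta()
    hairpins = gt.hairpin_fasta()
    families = gt.family_map()
    annotated = [l for l in gt.loci if l.klass != "novel_mirna"]
    result = analyze(reads.reads, genome, annotated, matures, hairpins, families, cfg)
    if outdir is not None:
        write_outputs(result, outdir, matures, hairpins, families, cfg)
    return gt, result


def write_simulation(sim_config: SimulationConfig, outdir) -> None:
    """Write the synthetic inputs (genome, annotation, references, reads,
    Ct table) as files, for running the pipeline from disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, gt = simulate.generate_genome(sim_config)
    reads = simulate.simulate_reads(genome, gt, sim_config)
    io.write_fasta(genome, out / "genome.fa")
    io.write_loci_gff3([l for l in gt.loci if l.klass != "novel_mirna"], out / "loci.gff3")
    io.write_fasta(gt.mature_fasta(), out / "mature.fa")
    io.write_fasta(gt.hairpin_fasta(), out / "hairpin.fa")
    io.write_family_file(gt.family_map(), out / "families.dat")
    reads.write_fastq({lib: out / f"reads_{lib}.fastq" for lib in reads.libraries})
    abundances = {
        "muscle_fetal": {"miR-demo": 8.0},
        "muscle_adult": {"miR-demo": 1.0},
    }
    ct = simulate.simulate_qpcr(abundances, sim_config)
    io.write_table(ct, out / "ct_table.tsv", index=False)
    truth = {
        "fold_changes": gt.fold_changes,
        "novel_precursors": {m.precursor_id: m.precursor for m in gt.novel},
        "novel_matures": {m.precursor_id: m.mature for m in gt.novel},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def validate_outputs(outdir) -> dict[str, bool]:
    """Re-check conservation identities from a written results directory."""
    out = Path(outdir)
    checks: dict[str, bool] = {}

    ledger = pd.read_csv(out / "cleaning_summary.tsv", sep="\t", index_col=0)
    for col in [c for c in ledger.columns if c.endswith("_count")]:
        s = ledger[col]
        filters = sum(int(s[name]) for name in cleaning.LEDGER_FILTERS)
        checks[f"ledger_identity_{col}"] = (
            int(s["clean_reads"]) == int(s["high_quality"]) - filters
        )

    tags = io.read_tags_tsv(out / "tags.tsv")
    totals = json.loads((out / "totals.json").read_text())["totals"]
    for lib in tags.columns:
        checks[f"tag_conservation_{lib}"] = int(tags[lib].sum()) == int(totals[lib])

    cats = pd.read_csv(out / "category_summary.tsv", sep="\t", index_col=0)
    genome_matched = json.loads((out / "totals.json").read_text())["genome_matched"]
    for col in cats.columns:
        lib, kind = col.rsplit("_", 1)
        if kind == "reads":
            checks[f"category_partition_{col}"] = (
                int(cats[col].sum()) == int(genome_matched[lib])
            )

    de = pd.read_csv(out / "de_table.tsv", sep="\t", index_col=0)
    de_sum = pd.read_csv(out / "de_summary.tsv", sep="\t", index_col=0)["count"]
    sig = de[de["significant"]]
    checks["de_totals"] = (
        int(de_sum["tested"]) == len(de)
        and int(de_sum["significant"]) == len(sig)
        and int(de_sum["up"]) == int((sig["class"] == "up").sum())
        and int(de_sum["down"]) == int((sig["class"] == "down").sum())
    )
    return checks
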