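"""End-to-end pipeline on a synthetic dataset.

Generates reads with planted features, classifies them, clusters the FLNC
inserts into a non-redundant transcript set, and runs the SSR, ORF,
lncRNA and alternative-splicing stages over it, writing deterministic
text reports.  Running twice with the same seed produces byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import flnc, lncrna, orf, report, splicing, ssr, synthetic
from .cluster import cluster_sequences, collapse_representatives, write_membership_tsv
from .io_formats import SeqRecord, write_gff3, write_sequences

__all__ = ["PipelineResult", "run_pipeline", "default_config"]


def default_config(seed: int, n_reads: int = 1000) -> synthetic.FixtureConfig:
    """Study conditions used by the worked example and the acceptance run."""
    return synthetic.FixtureConfig(
        seed=seed,
        n_reads=n_reads,
        ssr_plants=[
            synthetic.SsrPlantSpec(motif="AT", repeats=12, count=10),
            synthetic.SsrPlantSpec(motif="AAG", repeats=8, count=10),
            synthetic.SsrPlantSpec(motif="A", repeats=15, count=10),
        ],
        orf_plants=[synthetic.OrfPlantSpec(aa_length=300, count=20)],
    )


@dataclass
class PipelineResult:
    summary: dict
    truth: synthetic.TruthTable
    flnc_records: list
    transcripts: list[SeqRecord]
    as_events: list


def run_pipeline(
    config: synthetic.FixtureConfig,
    outdir: str | Path,
    as_pairs: int = 10,
    as_decoys: int = 50,
) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # 1. simulate reads + truth
    reads, truth = synthetic.make_reads(config)
    synthetic.write_fixture(reads, truth, outdir)

    # 2. FLNC classification and trimming
    primers = flnc.PrimerPair(five=config.primer_5, three=config.primer_3)
    classifications = flnc.classify_reads(reads, primers)
    flnc.write_classification_tsv(classifications, outdir / "flnc_classification.tsv")
    flnc_summary = flnc.write_summary_json(classifications, outdir / "flnc_summary.json")
    inserts = [
        SeqRecord(id=c.read_id, sequence=c.insert)
        for c in classifications
        if c.label == "FLNC"
    ]
    write_sequences(inserts, outdir / "flnc_inserts.fasta")

    # 3. cluster + collapse to a non-redundant transcript set
    clusters = cluster_sequences(inserts)
    write_membership_tsv(clusters, outdir / "clusters.tsv")
    transcripts = collapse_representatives(clusters, inserts)
    write_sequences(transcripts, outdir / "transcripts.fasta")

    # 4. SSR mining
    thresholds = ssr.SsrThresholds()
    hits_by_seq = {t.id: ssr.find_ssrs(t, thresholds) for t in transcripts}
    ssr_rep = ssr.ssr_report(hits_by_seq, transcripts)
    ssr.write_ssr_table_tsv(ssr_rep, outdir / "ssr_table.tsv")
    ssr.write_density_tsv(ssr_rep, outdir / "ssr_density.tsv")
    write_gff3(ssr.ssr_gff3_rows(hits_by_seq), outdir / "ssr.gff3")

    # 5. ORF prediction
    best_orfs = {}
    for t in transcripts:
        best = orf.find_best_orf(t, min_aa=100, strands="both")
        if best is not None:
            best_orfs[t.id] = best
    complete = [o for o in best_orfs.values() if o.completeness == "complete"]
    bin_rep = orf.orf_length_bins(complete)
    orf.write_bin_report_tsv(bin_rep, outdir / "orf_bins.tsv")
    ordered_orfs = [best_orfs[t.id] for t in transcripts if t.id in best_orfs]
    write_gff3(orf.orf_gff3_rows(ordered_orfs), outdir / "orf.gff3")
    with open(outdir / "peptides.fasta", "w") as fh:
        for o in ordered_orfs:
            fh.write(f">{o.transcript_id} {o.completeness}\n{o.peptide}\n")

    # 6. lncRNA consensus using the built-in coding-potential heuristic
    builtin = lncrna.MethodCalls(
        method="BUILTIN",
        noncoding_ids={
            t.id
            for t in transcripts
            if lncrna.builtin_noncoding_call(t, best_orfs.get(t.id))
        },
    )
    calls, venn = lncrna.consensus_lncrna(transcripts, [builtin])
    lncrna.write_votes_tsv(calls, outdir / "lncrna_votes.tsv")
    lncrna.write_venn_tsv(venn, outdir / "lncrna_venn.tsv")

    # 7. AS events on a planted pair set (separate transcript mixture)
    as_records, as_truth = synthetic.make_as_pair_set(
        n_pairs=as_pairs, n_decoys=as_decoys, seed=config.seed + 1
    )
    truth.as_pairs = as_truth.as_pairs
    events = splicing.scan_all_pairs(as_records)
    splicing.write_events_tsv(events, outdir / "as_events.tsv")

    # 8. dataset summary
    length_summary = report.summarize_lengths(reads)
    report.write_length_summary_tsv(length_summary, outdir / "read_lengths.tsv")
    n_flnc = flnc_summary["n_flnc"]
    summary = {
        "n_reads": len(reads),
        "mean_read_length": length_summary.mean,
        "n_flnc": n_flnc,
        "flnc_rate_pct": flnc_summary["flnc_rate_pct"],
        "n_clusters": len(clusters),
        "n_transcripts": len(transcripts),
        "n_ssrs": ssr_rep.n_ssrs,
        "n_orfs": len(best_orfs),
        "n_complete_orfs": len(complete),
        "n_lncrna_consensus": sum(1 for c in calls if c.consensus),
        "n_as_events": len(events),
    }
    with open(outdir / "pipeline_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        summary=summary, truth=truth, flnc_records=classifications,
        transcripts=transcripts, as_events=events,
    )
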