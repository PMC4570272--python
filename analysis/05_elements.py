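#!/usr/bin/env python
"""Scan the 51-nt window around each high-confidence summit for bipartite
UGUA(N)UA elements, deconvolute them into the five 8-12 nt length classes,
compare the CLIP length profile to the round-5 in-vitro selection profile,
build the per-class position weight matrices, score recovery against the
planted truth, and export the peak-to-length network."""

from pathlib import Path

import pandas as pd

import pufclip as pc
from pufclip import elements as el, peaks as pk, preprocess as pp, synth
from pufclip.genome import GenomeModel
from pufclip.pipeline import evaluate_recovery

SCRATCH = Path("scratch/clip_run")
RESULTS = Path("results")


def main() -> None:
    genome = GenomeModel.read(SCRATCH / "genome.fa", SCRATCH / "features.tsv")
    hc_table = pd.read_csv(RESULTS / "04_high_confidence_peaks.tsv", sep="\t")

    targets = []
    site_rows = []
    target_rows = []
    hc_peaks = []
    for _, row in hc_table.iterrows():
        gene = genome.gene(row["gene_id"])
        summit = int(row["summit"])
        window, _ = el.extract_window(genome, gene, summit)
        sites = el.scan_elements(window)
        pid = f"{row['gene_id']}:{summit}"
        t = el.classify_target(pid, row["gene_id"], sites)
        targets.append(t)
        for s in sites:
            site_rows.append(
                {
                    "peak_id": pid, "window_pos": s.start, "sequence": s.sequence,
                    "classes": ",".join(map(str, sorted(s.length_classes))),
                    "label": s.label,
                }
            )
        for L in sorted(t.length_classes):
            target_rows.append({"gene_id": row["gene_id"], "length_class": L})
        dummy = pk.Peak(
            gene_id=row["gene_id"], chrom=row["chrom"], strand=row["strand"],
            start=summit - 1, end=summit + 1, summit=summit,
            height=int(row["height_a"]), n_reads=int(row["n_reads_a"]),
            n_gapped_reads=int(row["gapped_a"]), kurtosis=float(row["kurtosis_a"]),
            modfdr=0.0, feature_class=row["feature_class"],
        )
        hc_peaks.append(pk.HighConfidencePeak(
            row["gene_id"], row["chrom"], row["strand"], summit, dummy, dummy
        ))

    pd.DataFrame(site_rows).to_csv(RESULTS / "05_element_sites.tsv", sep="\t", index=False)
    pd.DataFrame(target_rows).to_csv(RESULTS / "05_targets_by_class.tsv", sep="\t", index=False)

    kinds = pd.Series([t.kind for t in targets]).value_counts()
    print("peak classification:")
    print(kinds.to_string())
    n_with = sum(t.kind != "no-element" for t in targets)
    print(f"\n{n_with}/{len(targets)} high-confidence peaks contain >=1 element")

    clip_prof = el.length_distribution(targets, assay="CLIP")
    profiles = [clip_prof.to_frame()]
    seqrs_reads = [r.sequence for r in pp.read_fastq(SCRATCH / "seqrs_round5.fastq")]
    seqrs_prof = el.seqrs_length_profile(seqrs_reads, assay="SEQRS_round5")
    profiles.append(seqrs_prof.to_frame())
    prof_table = pd.concat(profiles, ignore_index=True)
    prof_table.to_csv(RESULTS / "05_length_profiles.tsv", sep="\t", index=False)
    print("\nlength profiles (enrichment relative to predominant class):")
    print(prof_table.to_string(index=False))

    # per-class PWMs over single-length sites
    pwm_frames = []
    for L in (8, 9, 10, 11, 12):
        seqs = [
            s.sequence for t in targets for s in t.sites
            if s.length_classes == frozenset({L})
        ]
        if seqs:
            pwm = pc.build_pwm(seqs)
            pwm.insert(0, "length_class", L)
            pwm.insert(1, "position", range(1, L + 1))
            pwm_frames.append(pwm)
    pd.concat(pwm_frames, ignore_index=True).to_csv(
        RESULTS / "05_pwms.tsv", sep="\t", index=False
    )

    el.export_network(
        targets, RESULTS / "05_network_edges.sif.tsv", RESULTS / "05_network_nodes.tsv"
    )

    truth_tab = pd.read_csv(SCRATCH / "element_truth.tsv", sep="\t")
    truth = [synth.PlantedElement(**row) for row in truth_tab.to_dict("records")]
    ev = evaluate_recovery(truth, hc_peaks, genome)
    ev.to_csv(RESULTS / "05_recovery.tsv", sep="\t", index=False)
    print("\nrecovery against planted truth:")
    print(ev.to_string(index=False))


if __name__ == "__main__":
    main()
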