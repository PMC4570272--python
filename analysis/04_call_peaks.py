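#!/usr/bin/env python
"""Call peaks per replicate with the permutation modFDR (alpha = 0.01,
1,000 uniform read placements per gene), annotate summits to
5'UTR/ORF/3'UTR, merge the replicates into high-confidence peaks (summits
within 10 nt, a gapped read and height > 10 in both), and report the
between-replicate correlation of normalized peak heights."""

from pathlib import Path

import pandas as pd

from pufclip import alignmap, peaks as pk
from pufclip.genome import GenomeModel

SCRATCH = Path("scratch/clip_run")
RESULTS = Path("results")
SEED = 1


def main() -> None:
    genome = GenomeModel.read(SCRATCH / "genome.fa", SCRATCH / "features.tsv")
    called = []
    for rep in (1, 2):
        alns = alignmap.read_sam(SCRATCH / f"clip_rep{rep}.sam")
        peaks = pk.call_peaks_all_genes(
            alns, genome, n_perm=1000, alpha=0.01, seed=SEED + 1000 * rep
        )
        pk.write_peaks(peaks, RESULTS / f"04_peaks_rep{rep}.tsv")
        called.append(peaks)

    hc = pk.merge_replicates(called[0], called[1])
    rows = [
        {
            "gene_id": m.gene_id, "chrom": m.chrom, "strand": m.strand,
            "summit": m.summit, "height_a": m.rep_a.height, "height_b": m.rep_b.height,
            "n_reads_a": m.rep_a.n_reads, "n_reads_b": m.rep_b.n_reads,
            "gapped_a": m.rep_a.n_gapped_reads, "gapped_b": m.rep_b.n_gapped_reads,
            "kurtosis_a": m.rep_a.kurtosis, "feature_class": m.feature_class,
        }
        for m in hc
    ]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "04_high_confidence_peaks.tsv", sep="\t", index=False)

    r = pk.replicate_correlation(hc)
    region = table["feature_class"].value_counts(normalize=True)
    print(f"peaks per replicate: {len(called[0])}, {len(called[1])}")
    print(f"high-confidence peaks: {len(hc)}")
    print(f"replicate correlation of log2 normalized reads/peak: r = {r:.2f}")
    print("\nsummit feature classes:")
    print(region.to_string())
    with open(RESULTS / "04_replicate_correlation.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"pearson_r_log2_reads_per_peak\t{r:.4f}\n")
        fh.write(f"n_high_confidence_peaks\t{len(hc)}\n")


if __name__ == "__main__":
    main()
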