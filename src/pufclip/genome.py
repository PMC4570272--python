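"""Toy genome model: chromosome sequences plus stranded gene features.

Coordinates are 0-based, half-open everywhere in memory. A gene is an ORF
interval extended by untranslated regions: by default 200 nt of 5'UTR and
300 nt of 3'UTR, mirroring the convention of treating the sequence 200 bases
upstream and 300 bases downstream of each yeast ORF as its UTRs. For a
minus-strand gene the 5'UTR lies on the higher-coordinate side of the ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UTR5_DEFAULT = 200
UTR3_DEFAULT = 300

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene: ORF interval plus UTR extensions, on one strand.

    ``orf_start``/``orf_end`` are 0-based half-open genomic coordinates.
    ``feature_type`` distinguishes mRNAs (which get UTR region classes)
    from non-coding RNAs (which pass through as their own class).
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    orf_start: int
    orf_end: int
    utr5_len: int = UTR5_DEFAULT
    utr3_len: int = UTR3_DEFAULT
    feature_type: str = "mRNA"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.orf_end <= self.orf_start:
            raise ValueError("orf_end must exceed orf_start")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError("UTR lengths must be >= 0")

    @property
    def start(self) -> int:
        """Genomic start of the extended footprint (UTRs included)."""
        up = self.utr5_len if self.strand == "+" else self.utr3_len
        return self.orf_start - up

    @property
    def end(self) -> int:
        """Genomic end of the extended footprint (UTRs included)."""
        down = self.utr3_len if self.strand == "+" else self.utr5_len
        return self.orf_end + down

    def region_interval(self, region: str) -> tuple[int, int]:
        """Genomic half-open interval of '5UTR', 'ORF' or '3UTR'."""
        if region == "ORF":
            return self.orf_start, self.orf_end
        if region == "5UTR":
            if self.strand == "+":
                return self.orf_start - self.utr5_len, self.orf_start
            return self.orf_end, self.orf_end + self.utr5_len
        if region == "3UTR":
            if self.strand == "+":
                return self.orf_end, self.orf_end + self.utr3_len
            return self.orf_start - self.utr3_len, self.orf_start
        raise ValueError(f"unknown region {region!r}")

    def classify_position(self, pos: int) -> str | None:
        """Feature class of a genomic position: 5UTR/ORF/3UTR, the
        feature type for non-mRNA genes, or None outside the footprint."""
        if not (self.start <= pos < self.end):
            return None
        if self.feature_type != "mRNA":
            return self.feature_type
        if self.orf_start <= pos < self.orf_end:
            return "ORF"
        lo5, hi5 = self.region_interval("5UTR")
        return "5UTR" if lo5 <= pos < hi5 else "3UTR"


@dataclass
class GenomeModel:
    """Chromosome sequences plus the gene feature table."""

    chrom_sequences: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)

    def validate(self) -> None:
        """Check the model's structural invariants; raise on violation."""
        by_chrom: dict[str, list[GeneFeature]] = {}
        for f in self.features:
            if f.chrom not in self.chrom_sequences:
                raise ValueError(f"{f.gene_id}: unknown chromosome {f.chrom}")
            clen = len(self.chrom_sequences[f.chrom])
            if f.start < 0 or f.end > clen:
                raise ValueError(f"{f.gene_id}: footprint outside chromosome")
            by_chrom.setdefault(f.chrom, []).append(f)
        for feats in by_chrom.values():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"extended footprints of {a.gene_id} and {b.gene_id} overlap"
                    )

    def gene(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def sense_sequence(self, feature: GeneFeature) -> str:
        """Sense-strand sequence of the extended gene footprint."""
        s = self.chrom_sequences[feature.chrom][feature.start : feature.end]
        return s if feature.strand == "+" else revcomp(s)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genomic slice, reverse-complemented for the minus strand.
        Coordinates are clipped to the chromosome."""
        seq = self.chrom_sequences[chrom]
        s = seq[max(0, start) : min(len(seq), end)]
        return s if strand == "+" else revcomp(s)

    # ---- I/O -------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in self.chrom_sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_features(self, path: str | Path) -> None:
        """BED-like TSV: chrom, start, end, gene_id, strand, orf_start,
        orf_end, utr5_len, utr3_len, feature_type (0-based half-open)."""
        with open(path, "w") as fh:
            fh.write(
                "chrom\tstart\tend\tgene_id\tstrand\torf_start\torf_end"
                "\tutr5_len\tutr3_len\tfeature_type\n"
            )
            for f in self.features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.gene_id}\t{f.strand}"
                    f"\t{f.orf_start}\t{f.orf_end}\t{f.utr5_len}\t{f.utr3_len}"
                    f"\t{f.feature_type}\n"
                )

    @classmethod
    def read(cls, fasta: str | Path, features_tsv: str | Path) -> "GenomeModel":
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        feats: list[GeneFeature] = []
        with open(features_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                c = line.rstrip("\n").split("\t")
                feats.append(
                    GeneFeature(
                        gene_id=c[idx["gene_id"]],
                        chrom=c[idx["chrom"]],
                        strand=c[idx["strand"]],
                        orf_start=int(c[idx["orf_start"]]),
                        orf_end=int(c[idx["orf_end"]]),
                        utr5_len=int(c[idx["utr5_len"]]),
                        utr3_len=int(c[idx["utr3_len"]]),
                        feature_type=c[idx["feature_type"]],
                    )
                )
        model = cls(chrom_sequences=chroms, features=feats)
        model.validate()
        return model


def genes_by_chrom(features: Iterable[GeneFeature]) -> dict[str, list[GeneFeature]]:
    out: dict[str, list[GeneFeature]] = {}
    for f in features:
        out.setdefault(f.chrom, []).append(f)
    for feats in out.values():
        feats.sort(key=lambda f: f.start)
    return out
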