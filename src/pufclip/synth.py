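"""Synthetic CLIP and in-vitro-selection data with known ground truth.

Builds a toy genome of non-overlapping stranded genes, plants bipartite
UGUA(N)UA binding elements (total length 8-12 nt) at known coordinates,
and simulates:

* two CLIP sequencing replicates: read pileups over planted elements,
  crosslink-induced 1-2 nt deletions, PCR duplicates, 5-nt random barcodes,
  the library's 3' adaptor, and Poisson background reads; and
* in-vitro selection (SEQRS-style) rounds over a randomized 20-mer library,
  where each round resamples sequences in proportion to the affinity of the
  best binding element they contain.

Every generator is deterministic for a fixed seed, and every simulated read
is recorded in a truth table so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GeneFeature, GenomeModel, revcomp

ADAPTOR_3P = "TGGAATTCTCGGGTGCCAAGG"
ADAPTOR_5P = "GTTCAGAGTTCTACAGTCCGACGATC"  # DNA form of the 5' RNA adaptor

#: spacer base probabilities (A-biased, G-depleted) for planted elements
SPACER_BASE_PROBS = {"A": 0.55, "C": 0.20, "G": 0.05, "T": 0.20}

#: default genomic region mix for planted elements (3'UTR-dominated,
#: matching the observed distribution of CLIP peaks over mRNA features)
REGION_WEIGHTS = {"3UTR": 0.68, "ORF": 0.28, "5UTR": 0.04}

LENGTH_CLASSES = (8, 9, 10, 11, 12)


class PlacementError(RuntimeError):
    """Raised when an element cannot be placed after bounded retries."""


@dataclass(frozen=True)
class PlantedElement:
    """Ground truth for one planted binding element.

    ``pos`` is the leftmost genomic coordinate of the element footprint
    (0-based); on minus-strand genes the sense-strand 5' end of the element
    is therefore at ``pos + length - 1``. ``sequence`` is always the
    sense-strand (RNA-sense, written as DNA) element.
    """

    element_id: str
    gene_id: str
    region: str  # 5UTR | ORF | 3UTR
    chrom: str
    strand: str
    pos: int
    sequence: str
    length_class: int
    relative_affinity: float = 1.0

    def __post_init__(self) -> None:
        L = self.length_class
        if L not in LENGTH_CLASSES:
            raise ValueError(f"length_class must be in {LENGTH_CLASSES}")
        s = self.sequence
        if len(s) != L or not s.startswith("TGTA") or not s.endswith("TA"):
            raise ValueError(f"sequence {s!r} is not a valid {L}-nt element")
        if self.relative_affinity <= 0:
            raise ValueError("relative_affinity must be positive")


def truth_to_frame(truth: list[PlantedElement]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truth])


def make_genome(
    n_genes: int,
    orf_len_range: tuple[int, int] = (300, 900),
    intergenic_len: int = 200,
    seed: int = 0,
    utr5_len: int = 200,
    utr3_len: int = 300,
    chrom: str = "chrS",
) -> GenomeModel:
    """Lay ``n_genes`` non-overlapping genes along one chromosome.

    ORF lengths are drawn uniformly from ``orf_len_range``; strands are
    random; extended footprints (ORF + UTRs) are separated by
    ``intergenic_len`` nt of random sequence, so no two footprints overlap.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if orf_len_range[0] < 30 or orf_len_range[1] < orf_len_range[0]:
        raise ValueError("orf_len_range must be an interval with min >= 30")
    if intergenic_len <= 0 or utr5_len < 0 or utr3_len < 0:
        raise ValueError("lengths must be positive (UTRs >= 0)")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    features: list[GeneFeature] = []
    pos = intergenic_len
    for i in range(n_genes):
        orf_len = int(rng.integers(orf_len_range[0], orf_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        up = utr5_len if strand == "+" else utr3_len
        orf_start = pos + up
        features.append(
            GeneFeature(
                gene_id=f"g{i+1:04d}",
                chrom=chrom,
                strand=strand,
                orf_start=orf_start,
                orf_end=orf_start + orf_len,
                utr5_len=utr5_len,
                utr3_len=utr3_len,
            )
        )
        pos += utr5_len + orf_len + utr3_len + intergenic_len
    seq = "".join(rng.choice(bases, size=pos)) if features else ""
    model = GenomeModel(chrom_sequences={chrom: seq}, features=features)
    model.validate()
    return model


def _draw_spacer(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    letters = list(probs)
    p = np.array([probs[b] for b in letters], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def plant_elements(
    genome: GenomeModel,
    length_weights: dict[int, float] | None = None,
    region_weights: dict[str, float] | None = None,
    seed: int = 0,
    n_elements: int | None = None,
    spacer_base_probs: dict[str, float] | None = None,
    affinity_by_length: dict[int, float] | None = None,
    affinity_range: tuple[float, float] = (0.6, 16.0),
    max_attempts: int = 100,
) -> list[PlantedElement]:
    """Write binding elements into gene regions; return the truth table.

    One element per gene by default (``n_elements`` overrides; genes are
    then cycled). The element sequence TGTA + spacer + TA is written on the
    gene's sense strand, so minus-strand genes receive its reverse
    complement on the reference. Spacer bases are A-biased and G-depleted
    by default. Elements never overlap one another.

    Each element gets a relative affinity: the value from
    ``affinity_by_length`` if given, otherwise drawn log-uniformly from
    ``affinity_range``. Affinity scales the expected CLIP read depth, so
    it is the shared biological signal that makes independent replicates
    correlate.
    """
    length_weights = length_weights or {L: 0.2 for L in LENGTH_CLASSES}
    region_weights = region_weights or dict(REGION_WEIGHTS)
    spacer_base_probs = spacer_base_probs or dict(SPACER_BASE_PROBS)
    for name, w in (("length", length_weights), ("region", region_weights)):
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name}_weights must sum to 1")
    if any(L not in LENGTH_CLASSES for L in length_weights):
        raise ValueError(f"length classes must be in {LENGTH_CLASSES}")

    rng = np.random.default_rng(seed)
    genes = list(genome.features)
    if not genes:
        return []
    n_elements = len(genes) if n_elements is None else n_elements

    lengths = sorted(length_weights)
    lp = np.array([length_weights[L] for L in lengths], dtype=float)
    regions = sorted(region_weights)
    rp = np.array([region_weights[r] for r in regions], dtype=float)

    chrom_seqs = {name: list(s) for name, s in genome.chrom_sequences.items()}
    occupied: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    truth: list[PlantedElement] = []
    for i in range(n_elements):
        gene = genes[i % len(genes)]
        placed = False
        for _ in range(max_attempts):
            L = int(rng.choice(lengths, p=lp))
            region = str(rng.choice(regions, p=rp))
            lo, hi = gene.region_interval(region)
            if hi - lo < L:
                continue
            pos = int(rng.integers(lo, hi - L + 1))
            if any(pos < e and s < pos + L for s, e in occupied[gene.gene_id]):
                continue
            element = "TGTA" + _draw_spacer(rng, L - 6, spacer_base_probs) + "TA"
            written = element if gene.strand == "+" else revcomp(element)
            chrom_seqs[gene.chrom][pos : pos + L] = list(written)
            occupied[gene.gene_id].append((pos, pos + L))
            if affinity_by_length is not None:
                affinity = affinity_by_length.get(L, 1.0)
            else:
                lo_a, hi_a = np.log(affinity_range[0]), np.log(affinity_range[1])
                affinity = float(np.exp(rng.uniform(lo_a, hi_a)))
            truth.append(
                PlantedElement(
                    element_id=f"e{len(truth)+1:05d}",
                    gene_id=gene.gene_id,
                    region=region,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    pos=pos,
                    sequence=element,
                    length_class=L,
                    relative_affinity=affinity,
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place an element in {gene.gene_id} after "
                f"{max_attempts} attempts"
            )
    genome.chrom_sequences = {name: "".join(s) for name, s in chrom_seqs.items()}
    return truth


def simulate_term_annotation(
    genome: GenomeModel,
    truth: list[PlantedElement],
    seed: int = 0,
    coverage: float = 0.9,
    noise: float = 0.05,
    n_unrelated_terms: int = 5,
) -> pd.DataFrame:
    """Synthetic gene -> functional-term table tied to element lengths.

    Each element length class gets a dedicated term assigned to a
    ``coverage`` fraction of the genes carrying that class plus a ``noise``
    fraction of all other genes, emulating functional categories that track
    binding-site length. ``n_unrelated_terms`` extra terms are assigned at
    random. Two-column frame (gene_id, term_id), writable as TSV.
    """
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in genome.features]
    by_class: dict[int, set[str]] = {}
    for t in truth:
        by_class.setdefault(t.length_class, set()).add(t.gene_id)
    rows = []
    for L, members in sorted(by_class.items()):
        term = f"TERM_len{L}"
        for g in genes:
            p = coverage if g in members else noise
            if rng.random() < p:
                rows.append({"gene_id": g, "term_id": term})
    for i in range(n_unrelated_terms):
        for g in genes:
            if rng.random() < 0.15:
                rows.append({"gene_id": g, "term_id": f"TERM_bg{i+1}"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


@dataclass
class ClipSimConfig:
    """Knobs of the CLIP read simulator.

    ``reads_per_element_mean``/``dispersion`` parameterize a negative
    binomial read count per element (dispersion is the NB size parameter;
    large values approach Poisson). ``background_rate_per_nt`` is a Poisson
    rate of non-specific reads per genic nucleotide. Deletions of 1-2 nt
    are placed uniformly within the element footprint +/- 3 nt, modelling
    reverse-transcriptase skips at crosslink sites.
    """

    reads_per_element_mean: float = 50.0
    reads_per_element_dispersion: float = 10.0
    background_rate_per_nt: float = 0.005
    crosslink_deletion_prob: float = 0.3
    max_deletion_length: int = 2
    pcr_duplication_rate: float = 0.3
    barcode_length: int = 5
    read_length: int = 50
    insert_len_range: tuple[int, int] = (28, 45)
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    adaptor_3p: str = ADAPTOR_3P
    seeds: tuple[int, ...] = (101, 102)

    def validate(self) -> None:
        if not 0 <= self.crosslink_deletion_prob <= 1:
            raise ValueError("crosslink_deletion_prob must be in [0,1]")
        if self.max_deletion_length not in (1, 2):
            raise ValueError("deletions are 1 or 2 nt")
        if self.read_length <= self.barcode_length:
            raise ValueError("read_length must exceed barcode_length")
        if not 0 <= self.pcr_duplication_rate <= 1:
            raise ValueError("pcr_duplication_rate must be in [0,1]")
        if self.insert_len_range[0] < 15:
            raise ValueError("minimum insert length must be >= 15")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClipSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "insert_len_range" in raw:
            raw["insert_len_range"] = tuple(raw["insert_len_range"])
        if "seeds" in raw:
            raw["seeds"] = tuple(raw["seeds"])
        return cls(**raw)


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


@dataclass
class ClipSimResult:
    """Reads per replicate plus the per-read truth table."""

    replicates: list[list[SimRead]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path, prefix: str = "clip") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, reads in enumerate(self.replicates, start=1):
            p = outdir / f"{prefix}_rep{i}.fastq"
            with open(p, "w") as fh:
                for r in reads:
                    fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
            paths.append(p)
        tpath = outdir / f"{prefix}_read_truth.tsv"
        self.truth.to_csv(tpath, sep="\t", index=False)
        paths.append(tpath)
        return paths


def _quality_string(rng: np.random.Generator, n: int, mean: float, sd: float) -> str:
    q = np.clip(np.rint(rng.normal(mean, sd, size=n)), 2, 40).astype(int)
    return "".join(chr(33 + v) for v in q)


def _finish_read(
    rng: np.random.Generator, insert: str, cfg: ClipSimConfig
) -> tuple[str, str]:
    barcode = "".join(rng.choice(list("ACGT"), size=cfg.barcode_length))
    seq = barcode + insert
    if len(seq) < cfg.read_length:
        seq = (seq + cfg.adaptor_3p)[: cfg.read_length]
    else:
        seq = seq[: cfg.read_length]
    qual = _quality_string(rng, len(seq), cfg.quality_mean, cfg.quality_sd)
    return seq, qual


def simulate_clip_reads(
    genome: GenomeModel,
    truth: list[PlantedElement],
    cfg: ClipSimConfig | None = None,
) -> ClipSimResult:
    """Simulate CLIP FASTQ replicates over planted elements.

    Element reads are genomic substrings containing the element; with
    probability ``crosslink_deletion_prob`` a read loses 1-2 nt at the
    crosslink site. Background reads are uniform over gene footprints.
    PCR duplicates are exact copies (same barcode, insert and quality).
    Reads from minus-strand genes are reverse-complemented, as cDNA
    sequencing reads would be.
    """
    cfg = cfg or ClipSimConfig()
    cfg.validate()
    if not truth and cfg.background_rate_per_nt <= 0:
        raise ValueError("need planted elements or a positive background rate")

    genes = {g.gene_id: g for g in genome.features}
    replicates: list[list[SimRead]] = []
    rows: list[dict] = []
    for rep_i, seed in enumerate(cfg.seeds, start=1):
        rng = np.random.default_rng(seed)
        reads: list[SimRead] = []
        primaries: list[tuple[SimRead, dict]] = []

        def add_primary(
            gene: GeneFeature,
            g_start: int,
            g_end: int,
            origin: str,
            element_id: str,
            del_len: int,
            del_pos: int,
        ) -> None:
            chrom = genome.chrom_sequences[gene.chrom]
            if del_len:
                ins = chrom[g_start:del_pos] + chrom[del_pos + del_len : g_end]
            else:
                ins = chrom[g_start:g_end]
            if gene.strand == "-":
                ins = revcomp(ins)
            seq, qual = _finish_read(rng, ins, cfg)
            rid = f"r{rep_i}_{len(primaries)+1:06d}"
            read = SimRead(rid, seq, qual)
            primaries.append(
                (
                    read,
                    {
                        "read_id": rid,
                        "replicate": rep_i,
                        "origin": origin,
                        "gene_id": gene.gene_id,
                        "element_id": element_id,
                        "has_deletion": bool(del_len),
                        "deletion_length": del_len,
                        "deletion_pos": del_pos if del_len else -1,
                        "is_duplicate": False,
                        "duplicate_of": "",
                    },
                )
            )

        disp = cfg.reads_per_element_dispersion
        for el in truth:
            gene = genes[el.gene_id]
            mean = cfg.reads_per_element_mean * el.relative_affinity
            n_reads = int(rng.negative_binomial(disp, disp / (disp + mean)))
            el_start, el_end = el.pos, el.pos + el.length_class
            for _ in range(n_reads):
                L = int(rng.integers(*cfg.insert_len_range))
                lo = max(gene.start, el_end - L)
                hi = min(el_start, gene.end - L)
                g_start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(
                    gene.start, min(el_start, gene.end - L)
                )
                del_len, del_pos = 0, -1
                if rng.random() < cfg.crosslink_deletion_prob:
                    del_len = int(rng.integers(1, cfg.max_deletion_length + 1))
                    dlo = max(g_start + 1, el_start - 3)
                    dhi = min(g_start + L - del_len - 1, el_end + 3 - del_len)
                    if dhi >= dlo:
                        del_pos = int(rng.integers(dlo, dhi + 1))
                    else:
                        del_len = 0
                add_primary(
                    gene, g_start, g_start + L + del_len, "element",
                    el.element_id, del_len, del_pos,
                )

        if cfg.background_rate_per_nt > 0 and genes:
            feats = list(genes.values())
            spans = np.array([g.end - g.start for g in feats], dtype=float)
            n_bg = int(rng.poisson(cfg.background_rate_per_nt * spans.sum()))
            p = spans / spans.sum()
            for gi in rng.choice(len(feats), size=n_bg, p=p):
                gene = feats[gi]
                L = int(rng.integers(*cfg.insert_len_range))
                if gene.end - gene.start <= L:
                    continue
                g_start = int(rng.integers(gene.start, gene.end - L))
                add_primary(gene, g_start, g_start + L, "background", "", 0, -1)

        for read, row in primaries:
            reads.append(read)
            rows.append(row)
            if rng.random() < cfg.pcr_duplication_rate:
                dup_id = read.read_id + "_dup"
                reads.append(SimRead(dup_id, read.sequence, read.quality))
                dup_row = dict(row)
                dup_row.update(
                    read_id=dup_id, is_duplicate=True, duplicate_of=read.read_id
                )
                rows.append(dup_row)
        replicates.append(reads)

    return ClipSimResult(replicates=replicates, truth=pd.DataFrame(rows))


def simulate_seqrs(
    affinity: dict[int, float],
    rounds: int = 5,
    library_size: int = 20000,
    read_depth: int = 20000,
    seed: int = 0,
) -> list[list[str]]:
    """Simulate selection rounds over a randomized 20-mer library.

    Round 0 is uniform random. Each later round resamples the library with
    replacement, weighting every sequence by the affinity of the best
    binding element it contains (1.0 if it contains none) — read counts
    across rounds thereby become a proxy for relative affinity. Returns
    ``rounds + 1`` lists of ``read_depth`` sequenced reads (round 0 first).
    """
    from .elements import scan_elements  # deferred: avoids import cycle at module load

    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not affinity:
        raise ValueError("affinity map must be non-empty")
    if any(a <= 0 for a in affinity.values()):
        raise ValueError("affinities must be positive")

    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, 4, size=(library_size, 20))
    letters = np.array(list("ACGT"))
    library = ["".join(row) for row in letters[base_idx]]

    def weight(seq: str) -> float:
        classes = set()
        for site in scan_elements(seq):
            classes.update(site.length_classes)
        if not classes:
            return 1.0
        return max(affinity.get(c, 1.0) for c in classes)

    sampled_rounds: list[list[str]] = []
    current = library
    for rnd in range(rounds + 1):
        if rnd > 0:
            w = np.array([weight(s) for s in current], dtype=float)
            idx = rng.choice(len(current), size=library_size, p=w / w.sum())
            current = [current[i] for i in idx]
        ridx = rng.integers(0, len(current), size=read_depth)
        sampled_rounds.append([current[i] for i in ridx])
    return sampled_rounds


def write_seqrs_fastq(rounds: list[list[str]], outdir: str | Path, prefix: str = "seqrs") -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rnd, reads in enumerate(rounds):
        p = outdir / f"{prefix}_round{rnd}.fastq"
        with open(p, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@{prefix}_r{rnd}_{i+1:06d}\n{seq}\n+\n{'I'*len(seq)}\n")
        paths.append(p)
    return paths
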