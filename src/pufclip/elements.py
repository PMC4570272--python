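"""Bipartite binding-element detection and length deconvolution.

A PUF binding element here is a 5'-UGUA anchor and a 3'-UA terminus with a
variable spacer in between, giving five total length classes of 8-12 nt
(UGUA + 2-6 N + UA). A single anchored site can admit several lengths (for
example UGUNNNUAUA reads as both an 8-nt and a 10-nt element depending on
which 3'-UA is used); such sites are grouped into one ``ElementSite`` whose
``length_classes`` holds every admissible length.

Sequences may be RNA or DNA; U and T are equivalent. Internally everything
is DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MIN_LEN = 8
MAX_LEN = 12
LENGTH_CLASSES = tuple(range(MIN_LEN, MAX_LEN + 1))

_RNA_TO_DNA = str.maketrans("Uu", "Tt")


def as_dna(seq: str) -> str:
    return seq.upper().translate(_RNA_TO_DNA)


@dataclass(frozen=True)
class ElementSite:
    """One anchored match: a 5' anchor plus every admissible 3'-UA."""

    start: int  # anchor position, 0-based within the scanned sequence
    sequence: str  # longest admissible element at this anchor (DNA)
    length_classes: frozenset[int]

    @property
    def label(self) -> str:
        """'9' for a single length, '8–10' for an overlapping site."""
        ls = sorted(self.length_classes)
        return str(ls[0]) if len(ls) == 1 else f"{ls[0]}–{ls[-1]}"

    @property
    def end(self) -> int:
        return self.start + max(self.length_classes)


def _anchor_matches(seq: str, i: int, anchor: str) -> bool:
    if i + len(anchor) > len(seq):
        return False
    return all(a == "N" or seq[i + j] == a for j, a in enumerate(anchor))


def scan_elements(
    seq: str,
    five_anchor: str = "UGUA",
    three_anchor: str = "UA",
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> list[ElementSite]:
    """Find all bipartite elements in ``seq``.

    Every occurrence of the 5' anchor (N = any base) is tested for the 3'
    anchor at each offset yielding a total element length in
    [min_len, max_len]; all admissible lengths at one anchor form a single
    site. Returns sites ordered by anchor position.
    """
    s = as_dna(seq)
    a5 = as_dna(five_anchor)
    a3 = as_dna(three_anchor)
    if min_len < len(a5) + len(a3):
        raise ValueError("min_len shorter than the two anchors combined")
    sites: list[ElementSite] = []
    for i in range(len(s) - min_len + 1):
        if not _anchor_matches(s, i, a5):
            continue
        lengths = [
            L
            for L in range(min_len, max_len + 1)
            if i + L <= len(s) and _anchor_matches(s, i + L - len(a3), a3)
        ]
        if lengths:
            sites.append(
                ElementSite(
                    start=i,
                    sequence=s[i : i + max(lengths)],
                    length_classes=frozenset(lengths),
                )
            )
    return sites


def extract_window(genome, gene, summit: int, flank: int = 25) -> tuple[str, int]:
    """Sense-strand sequence of summit-flank .. summit+flank (inclusive).

    Returns ``(window, window_start)`` where ``window_start`` is the
    genomic coordinate of the leftmost base of the window. Minus-strand
    genes yield the reverse complement. Truncated with a warning at
    chromosome ends.
    """
    chrom = genome.chrom_sequences[gene.chrom]
    lo, hi = summit - flank, summit + flank + 1
    if lo < 0 or hi > len(chrom):
        warnings.warn(
            f"window around summit {summit} truncated at chromosome edge",
            stacklevel=2,
        )
        lo, hi = max(0, lo), min(len(chrom), hi)
    return genome.fetch(gene.chrom, lo, hi, gene.strand), lo


@dataclass(frozen=True)
class TargetClass:
    """Element content of one peak window.

    ``kind`` is 'single' (one site, one length), 'overlapping' (one site,
    several lengths), 'multi' (several distinct sites) or 'no-element'.
    """

    peak_id: str
    gene_id: str
    kind: str
    sites: tuple[ElementSite, ...]

    @property
    def length_classes(self) -> frozenset[int]:
        out: set[int] = set()
        for s in self.sites:
            out.update(s.length_classes)
        return frozenset(out)

    @property
    def label(self) -> str:
        return ",".join(s.label for s in self.sites) if self.sites else "none"


def classify_target(peak_id: str, gene_id: str, sites: list[ElementSite]) -> TargetClass:
    """Classify a peak by the element sites found in its summit window."""
    if not sites:
        kind = "no-element"
    elif len(sites) > 1:
        kind = "multi"
    elif len(sites[0].length_classes) > 1:
        kind = "overlapping"
    else:
        kind = "single"
    return TargetClass(peak_id=peak_id, gene_id=gene_id, kind=kind, sites=tuple(sites))


def build_pwm(sequences: list[str], pseudocount: float = 0.5) -> pd.DataFrame:
    """Position probability matrix of equal-length element sequences.

    Rows are positions, columns A/C/G/T; each row sums to 1 (pseudocount
    added per base per position).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    seqs = [as_dna(s) for s in sequences]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have the same length")
    counts = np.full((L, 4), pseudocount, dtype=float)
    idx = {b: j for j, b in enumerate("ACGT")}
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, idx[b]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, columns=list("ACGT"))


@dataclass
class LengthProfile:
    """Counts per element length class with max-normalized enrichment."""

    assay: str
    counts: dict[int, int]

    @property
    def enrichment(self) -> dict[int, float]:
        mx = max(self.counts.values()) if self.counts else 0
        if mx == 0:
            return {L: 0.0 for L in self.counts}
        return {L: c / mx for L, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        enr = self.enrichment
        return pd.DataFrame(
            {
                "assay": self.assay,
                "length_class": list(self.counts),
                "count": list(self.counts.values()),
                "enrichment": [enr[L] for L in self.counts],
            }
        )


def length_distribution(
    targets: list[TargetClass],
    assay: str = "CLIP",
    mode: str = "per-class",
) -> LengthProfile:
    """Element length distribution across classified targets.

    ``mode='per-class'`` counts each site once for every length it admits
    (an overlapping 8-10 site contributes to both 8 and 10);
    ``mode='longest-only'`` counts only a site's longest reading.
    """
    if mode not in ("per-class", "longest-only"):
        raise ValueError("mode must be 'per-class' or 'longest-only'")
    counts = {L: 0 for L in LENGTH_CLASSES}
    any_element = False
    for t in targets:
        for site in t.sites:
            any_element = True
            classes = (
                site.length_classes
                if mode == "per-class"
                else {max(site.length_classes)}
            )
            for L in classes:
                counts[L] += 1
    if not any_element:
        warnings.warn("no elements found; length profile is all zero", stacklevel=2)
    return LengthProfile(assay=assay, counts=counts)


def seqrs_length_profile(
    reads: list[str], assay: str = "SEQRS", **scan_kwargs
) -> LengthProfile:
    """Length profile of a selection-round read set.

    Each read contributes once to every length class for which it contains
    at least one element of that class.
    """
    counts = {L: 0 for L in LENGTH_CLASSES}
    for read in reads:
        classes: set[int] = set()
        for site in scan_elements(read, **scan_kwargs):
            classes.update(site.length_classes)
        for L in classes:
            counts[L] += 1
    return LengthProfile(assay=assay, counts=counts)


def export_network(
    targets: list[TargetClass], edges_path: str | Path, nodes_path: str | Path
) -> pd.DataFrame:
    """Emit the peak-to-length-hub network.

    Edges (SIF-compatible TSV: source, interaction, target) connect each
    length hub ``L<class>`` to every peak whose window contains a site of
    that class; one edge per (peak, length class). The node attribute
    table lists every peak with its classification kind and overlap label
    (element-free peaks appear there with no edges).
    """
    edge_rows = []
    node_rows = []
    for t in targets:
        for L in sorted(t.length_classes):
            edge_rows.append({"source": f"L{L}", "interaction": "binds", "target": t.peak_id})
        node_rows.append(
            {
                "node": t.peak_id,
                "gene_id": t.gene_id,
                "kind": t.kind,
                "label": t.label,
            }
        )
    edges = pd.DataFrame(edge_rows, columns=["source", "interaction", "target"])
    nodes = pd.DataFrame(node_rows, columns=["node", "gene_id", "kind", "label"])
    edges.to_csv(edges_path, sep="\t", index=False)
    nodes.to_csv(nodes_path, sep="\t", index=False)
    return edges
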