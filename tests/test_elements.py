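"""Bipartite element scanning, classification, PWMs and length profiles."""

import re
import warnings

import numpy as np
import pytest

import pufclip as pc
from pufclip import elements as el
from pufclip.genome import GeneFeature, GenomeModel, revcomp


def regex_scan(seq: str) -> dict[int, set[int]]:
    """Independent enumeration oracle: anchor position -> length classes."""
    s = seq.upper().replace("U", "T")
    out: dict[int, set[int]] = {}
    for L in range(8, 13):
        pat = re.compile(rf"(?=(TGTA[ACGT]{{{L - 6}}}TA))")
        for m in pat.finditer(s):
            out.setdefault(m.start(), set()).add(L)
    return out


class TestScanElements:
    @pytest.mark.parametrize(
        "seq,classes",
        [
            ("UGUAAAUA", {8}),
            ("UGUAAAAUA", {9}),
            ("UGUAAAAAUA", {10}),
            ("UGUAAAAAAUA", {11}),
            ("UGUAAAAAAAUA", {12}),
        ],
    )
    def test_single_length_reference_rnas(self, seq, classes):
        sites = pc.scan_elements(seq)
        assert len(sites) == 1
        assert set(sites[0].length_classes) == classes

    def test_overlapping_site_admits_8_and_10(self):
        sites = pc.scan_elements("UGUAAAUAUA")
        assert len(sites) == 1
        assert set(sites[0].length_classes) == {8, 10}
        assert sites[0].label == "8–10"

    def test_mutated_anchor_yields_nothing(self):
        assert pc.scan_elements("ACAAAAUA") == []
        assert pc.scan_elements("ACAAAAAAAUA") == []

    def test_t_and_u_equivalent(self):
        assert pc.scan_elements("TGTAAATA")[0].length_classes == frozenset({8})

    def test_ugun_anchor_mode_relaxes_fourth_base(self):
        assert pc.scan_elements("UGUCAAUA") == []
        sites = pc.scan_elements("UGUCAAUA", five_anchor="UGUN")
        assert len(sites) == 1 and 8 in sites[0].length_classes

    def test_distinct_anchors_are_distinct_sites(self):
        sites = pc.scan_elements("UGUAAAUA" + "CCCC" + "UGUAAAAAUA")
        assert len(sites) == 2

    def test_agrees_with_regex_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            expected = regex_scan(seq)
            got = {s.start: set(s.length_classes) for s in pc.scan_elements(seq)}
            assert got == expected, seq


class TestExtractWindow:
    @pytest.fixture
    def genome(self):
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        gene = GeneFeature("g1", "c", "+", 500, 1500)
        return GenomeModel({"c": seq}, [gene])

    def test_default_window_is_51nt(self, genome):
        w, lo = el.extract_window(genome, genome.features[0], 1000)
        assert len(w) == 51 and lo == 975

    def test_truncated_at_chromosome_start_with_warning(self, genome):
        with pytest.warns(UserWarning):
            w, lo = el.extract_window(genome, genome.features[0], 10)
        assert len(w) == 36 and lo == 0

    def test_minus_strand_window_is_reverse_complement(self, genome):
        minus = GeneFeature("g2", "c", "-", 500, 1500)
        w_plus, _ = el.extract_window(genome, genome.features[0], 1000)
        w_minus, _ = el.extract_window(
            GenomeModel(genome.chrom_sequences, [minus]), minus, 1000
        )
        assert w_minus == revcomp(w_plus)


class TestClassifyTarget:
    def test_single_overlapping_multi_and_none(self):
        single = pc.classify_target("p", "g", pc.scan_elements("CCUGUAAAAUACC"))
        assert single.kind == "single" and single.label == "9"
        over = pc.classify_target("p", "g", pc.scan_elements("CCUGUAAAUAUACC"))
        assert over.kind == "overlapping" and over.label == "8–10"
        multi = pc.classify_target(
            "p", "g", pc.scan_elements("UGUAAAUA" + "CCCC" + "UGUAAAAAUA")
        )
        assert multi.kind == "multi" and multi.length_classes == frozenset({8, 10})
        none = pc.classify_target("p", "g", [])
        assert none.kind == "no-element" and none.label == "none"


class TestBuildPwm:
    def test_identical_sequences_concentrate_on_anchor(self):
        pwm = pc.build_pwm(["UGUAAAUA"] * 100)
        expected = 100.5 / 102  # pseudocount 0.5 per base
        for i, b in enumerate("TGTA"):
            assert pwm.iloc[i][b] == pytest.approx(expected)
        assert np.allclose(pwm.sum(axis=1), 1.0)

    def test_zero_pseudocount_single_sequence_is_one_hot(self):
        pwm = pc.build_pwm(["UGUAAAUA"], pseudocount=0.0)
        assert (pwm.max(axis=1) == 1.0).all()

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            pc.build_pwm(["UGUAAAUA", "UGUAAAAUA"])

    def test_spacer_composition_matches_configured_bias(self):
        genome = pc.make_genome(n_genes=100, seed=13)
        truth = pc.plant_elements(genome, length_weights={12: 1.0}, seed=14)
        spacers = "".join(t.sequence[4:-2] for t in truth)
        n = len(spacers)
        frac_a = spacers.count("A") / n
        sd = np.sqrt(0.55 * 0.45 / n)
        assert abs(frac_a - 0.55) < 3 * sd


class TestLengthDistribution:
    def _targets(self, counts):
        targets = []
        for L, n in counts.items():
            seq = "TGTA" + "A" * (L - 6) + "TA"
            for i in range(n):
                site = el.ElementSite(0, seq, frozenset({L}))
                targets.append(
                    el.TargetClass(f"p{L}_{i}", f"g{L}_{i}", "single", (site,))
                )
        return targets

    def test_enrichment_relative_to_predominant_class(self):
        prof = pc.length_distribution(
            self._targets({8: 5, 9: 50, 10: 45, 11: 10, 12: 5})
        )
        assert prof.enrichment[9] == 1.0
        assert prof.enrichment[10] == pytest.approx(0.9)
        assert prof.enrichment[8] == pytest.approx(0.1)

    def test_single_class_is_one_rest_zero(self):
        prof = pc.length_distribution(self._targets({10: 7}))
        assert prof.enrichment[10] == 1.0
        assert all(prof.enrichment[L] == 0 for L in (8, 9, 11, 12))

    def test_zero_elements_warns_and_is_all_zero(self):
        with pytest.warns(UserWarning):
            prof = pc.length_distribution([])
        assert set(prof.enrichment.values()) == {0.0}

    def test_overlapping_site_counts_once_per_class_by_default(self):
        site = el.ElementSite(0, "TGTAAATATA", frozenset({8, 10}))
        t = el.TargetClass("p", "g", "overlapping", (site,))
        per_class = pc.length_distribution([t]).counts
        assert per_class[8] == 1 and per_class[10] == 1
        longest = pc.length_distribution([t], mode="longest-only").counts
        assert longest[8] == 0 and longest[10] == 1

    def test_planted_uniform_lengths_recovered_flat(self, default_run):
        genome, truth, _, res = default_run
        prof = pc.length_distribution(res.targets)
        truth_counts = {L: 0 for L in (8, 9, 10, 11, 12)}
        for t in truth:
            truth_counts[t.length_class] += 1
        # every class planted at ~10 of 50 elements should be recovered
        # at comparable frequency: no class collapses or dominates
        for L, c in prof.counts.items():
            assert c >= 0.5 * truth_counts[L]


class TestSeqrsProfile:
    def test_pure_library_gives_single_class(self):
        reads = ["CCCCC" + "TGTAAAATA" + "CCCCCC"] * 50
        prof = pc.seqrs_length_profile(reads)
        assert prof.enrichment[9] == 1.0
        assert prof.counts[8] == 0

    def test_random_background_matches_analytic_match_probabilities(self):
        """In uniform random 20-mers the chance of containing a class-L
        element is ~(21-L)/4^6: shorter classes have more admissible
        positions, so the background profile decreases with spacer length."""
        rng = np.random.default_rng(17)
        n = 30000
        letters = np.array(list("ACGT"))
        reads = ["".join(row) for row in letters[rng.integers(0, 4, size=(n, 20))]]
        prof = pc.seqrs_length_profile(reads)
        q = 0.25**6
        for L in (8, 9, 10, 11, 12):
            mu = n * (1 - (1 - q) ** (21 - L))
            sd = np.sqrt(mu)
            assert abs(prof.counts[L] - mu) < 4 * sd, (L, prof.counts[L], mu)
        mus = [n * (1 - (1 - q) ** (21 - L)) for L in (8, 9, 10, 11, 12)]
        assert mus == sorted(mus, reverse=True)


class TestExportNetwork:
    def test_edges_and_nodes(self, tmp_path):
        s810 = el.ElementSite(0, "TGTAAATATA", frozenset({8, 10}))
        t1 = el.TargetClass("p1", "g1", "overlapping", (s810,))
        t2 = el.TargetClass("p2", "g2", "no-element", ())
        edges = el.export_network([t1, t2], tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert len(edges) == 2
        assert set(edges["source"]) == {"L8", "L10"}
        nodes = (tmp_path / "n.tsv").read_text().splitlines()
        assert any("p2" in ln and "no-element" in ln for ln in nodes)

    def test_one_peak_per_class_gives_five_hubs(self, tmp_path):
        targets = []
        for L in (8, 9, 10, 11, 12):
            site = el.ElementSite(0, "TGTA" + "A" * (L - 6) + "TA", frozenset({L}))
            targets.append(el.TargetClass(f"p{L}", f"g{L}", "single", (site,)))
        edges = el.export_network(targets, tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert len(edges) == 5 and edges["source"].nunique() == 5
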