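"""Intron harvesting, clustering, IE call merging/classification/location."""
import numpy as np
import pytest

from picoannot.core import ESTAlignment, Intron, oriented_est_introns
from picoannot.introner import (
    IECall,
    MotifGroup,
    classify_element,
    cluster_introns,
    donor_pfm,
    donor_pfms_by_class,
    harvest_introns,
    ie_family_stats,
    locate_elements,
    merge_hits,
)
from picoannot.motifs import MotifHit
from conftest import make_genome, make_model, random_dna

G1 = MotifGroup("D-IE1", ("m1", "m2", "m3", "m4"))
G2 = MotifGroup("D-IE2", ("n1", "n2", "n3"))
GROUPS = [G1, G2]


def intron(iv, strand="+", chrom="chr1", donor="GT"):
    return Intron(chrom, tuple(iv), strand, donor, "AG")


class TestHarvest:
    def test_length_filter(self):
        rng = np.random.default_rng(0)
        genome = make_genome(chr1=random_dna(rng, 2000))
        introns = [intron((0, 300)), intron((500, 1001))]
        kept = harvest_introns(introns, genome, max_len=500)
        assert [i.interval for i, _ in kept] == [(0, 300)]

    def test_exact_duplicates_collapsed(self):
        seq = "GT" + "ACGTACGT" * 9 + "AG"
        genome = make_genome(chr1=seq + "TTTT" + seq)
        i1 = intron((0, len(seq)))
        i2 = intron((len(seq) + 4, 2 * len(seq) + 4))
        kept = harvest_introns([i1, i2], genome)
        assert len(kept) == 1

    def test_undetermined_est_strand_excluded(self):
        # an EST whose gap matches neither strand contributes no introns
        seq = "A" * 10 + "TTTTTT" + "A" * 10
        genome = make_genome(chr1=seq)
        est = ESTAlignment("e/f", "forward", "chr1", ((0, 10), (16, 26)))
        kept_ests, est_introns = oriented_est_introns([est], genome)
        assert est_introns == []
        assert all(len(e.blocks) < 2 for e in kept_ests)


class TestClustering:
    def test_mutated_family_single_linkage(self):
        rng = np.random.default_rng(1)
        base = random_dna(rng, 150)
        family = []
        for _ in range(10):
            s = list(base)
            for i in range(len(s)):
                if rng.random() < 0.05:
                    s[i] = "ACGT"[rng.integers(0, 4)]
            family.append("".join(s))
        unrelated = [random_dna(rng, 200), random_dna(rng, 200)]
        clusters = cluster_introns(family + unrelated)
        assert sorted(len(c) for c in clusters) == [1, 1, 10]

    def test_random_pairs_are_singletons(self):
        rng = np.random.default_rng(2)
        seqs = [random_dna(rng, 200) for _ in range(5)]
        assert all(len(c) == 1 for c in cluster_introns(seqs))

    def test_short_fragment_fails_coverage(self):
        seq = random_dna(np.random.default_rng(3), 200)
        assert len(cluster_introns([seq, seq[:100]])) == 2

    def test_empty_input(self):
        assert cluster_introns([]) == []


def hit(motif, start, width=10, strand="+"):
    return MotifHit(motif, "chr1", (start, start + width), strand, 30.0, 1e-12)


def test_discover_family_motifs_from_clustered_introns():
    """A family of near-identical introns forms one cluster and yields a
    well-supported high-information motif; unrelated introns (singleton
    clusters below the size floor) contribute nothing."""
    from picoannot.introner import discover_family_motifs

    rng = np.random.default_rng(14)
    base = random_dna(rng, 160)
    fam_seqs = []
    for _ in range(12):
        s = list(base)
        for i in range(len(s)):
            if rng.random() < 0.03:
                s[i] = "ACGT"[rng.integers(0, 4)]
        fam_seqs.append("".join(s))
    others = [random_dna(rng, 170) for _ in range(4)]
    pairs = [
        (Intron("chr1", (i * 200, i * 200 + len(s)), "+", "GT", "AG"), s)
        for i, s in enumerate(fam_seqs + others)
    ]
    clusters = discover_family_motifs(
        pairs, min_cluster=10, n_motifs=1, min_sites=10, width=12,
    )
    assert len(clusters) == 1
    (pwm,) = clusters[0]
    assert pwm.nsites >= 10
    assert pwm.information_content() >= 1.0
    # the motif is a near-exact substring of the family's shared sequence
    best = max(
        sum(a == b for a, b in zip(pwm.consensus, base[i:i + 12]))
        for i in range(len(base) - 11)
    )
    assert best >= 10


class TestMergeHits:
    def test_gap_49_merges(self):
        calls = merge_hits([hit("m1", 90), hit("m2", 149)])
        assert len(calls) == 1 and calls[0].motifs_present == ("m1", "m2")

    def test_gap_55_does_not_merge(self):
        assert len(merge_hits([hit("m1", 90), hit("m2", 155)])) == 2

    def test_gap_50_boundary_does_not_merge(self):
        assert len(merge_hits([hit("m1", 90), hit("m2", 150)])) == 2

    def test_four_hits_transitive_merge(self):
        hits = [hit(f"m{i + 1}", 100 + i * 40) for i in range(4)]
        calls = merge_hits(hits)
        assert len(calls) == 1
        assert calls[0].motifs_present == ("m1", "m2", "m3", "m4")
        assert calls[0].interval == (100, 230)

    def test_minus_strand_motifs_in_transcription_order(self):
        hits = [hit("m1", 140, strand="-"), hit("m2", 100, strand="-")]
        calls = merge_hits(hits)
        assert calls[0].motifs_present == ("m1", "m2")

    def test_strands_not_merged_together(self):
        assert len(merge_hits([hit("m1", 90), hit("m2", 120, strand="-")])) == 2


def cand(motifs, strand="+"):
    return IECall("chr1", (0, 100), strand, "unclassified", "partial",
                  tuple(motifs), len(motifs))


class TestClassify:
    def test_complete_in_order(self):
        c = classify_element(cand(["m1", "m2", "m3", "m4"]), GROUPS)
        assert (c.family, c.completeness) == ("D-IE1", "complete")

    def test_single_motif_partial(self):
        c = classify_element(cand(["m1"]), GROUPS)
        assert (c.family, c.completeness, c.n_motifs) == ("D-IE1", "partial", 1)

    def test_internal_duplication(self):
        c = classify_element(
            cand(["m1", "m2", "m3", "m4", "m1", "m2", "m3", "m4"]), GROUPS
        )
        assert c.completeness == "complete_duplicated"

    def test_out_of_order_is_partial(self):
        c = classify_element(cand(["m2", "m1", "m3", "m4"]), GROUPS)
        assert c.completeness == "partial"

    def test_mixed_families(self):
        c = classify_element(cand(["m1", "n1"]), GROUPS)
        assert (c.family, c.completeness) == ("mixed", "partial")

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            classify_element(cand(["zz"]), GROUPS)

    def test_three_motif_family_complete(self):
        c = classify_element(cand(["n1", "n2", "n3"]), GROUPS)
        assert (c.family, c.completeness) == ("D-IE2", "complete")


class TestLocate:
    def _setup(self):
        seq = ("T" * 50                      # intergenic
               + "C" * 100                   # exon1 [50,150)
               + "GT" + "A" * 196 + "AG"     # intron [150,350)
               + "C" * 100                   # exon2 [350,450)
               + "T" * 200)                  # intergenic
        genome = make_genome(chr1=seq)
        m = make_model(exons=((50, 150), (350, 450)), cds=(50, 448))
        return genome, [m]

    def _call(self, iv, strand="+"):
        return IECall("chr1", iv, strand, "D-IE1", "complete",
                      ("m1", "m2", "m3", "m4"), 4)

    def test_intronic_same_strand_inherits_donor(self):
        genome, models = self._setup()
        (c,) = locate_elements([self._call((160, 340))], models, genome)
        assert c.location_class == "intronic_same_strand"
        assert c.donor_type == "GT"

    def test_intronic_opposite_strand(self):
        genome, models = self._setup()
        (c,) = locate_elements([self._call((160, 340), "-")], models, genome)
        assert c.location_class == "intronic_opposite_strand"

    def test_intergenic(self):
        genome, models = self._setup()
        (c,) = locate_elements([self._call((500, 600))], models, genome)
        assert c.location_class == "intergenic" and c.donor_type == "n/a"

    def test_exon_overlap_takes_precedence(self):
        genome, models = self._setup()
        (c,) = locate_elements([self._call((140, 200))], models, genome)
        assert c.location_class == "exon_overlap"


class TestFamilyStats:
    def test_gc_donor_percentage(self):
        calls = [
            IECall("chr1", (i * 1000, i * 1000 + 100), "+", "D-IE1",
                   "complete", ("m1", "m2", "m3", "m4"), 4,
                   "intronic_same_strand", "GC" if i < 4 else "GT")
            for i in range(10)
        ]
        df = ie_family_stats(calls)
        row = df[(df.family == "D-IE1") & (df.completeness == "complete")]
        assert int(row["count"].iloc[0]) == 10
        assert row.gc_donor_pct.iloc[0] == pytest.approx(40.0)

    def test_no_intronic_calls_gives_nan(self):
        calls = [
            IECall("chr1", (0, 100), "+", "D-IE1", "partial", ("m1",), 1,
                   "intergenic", "n/a")
        ]
        df = ie_family_stats(calls)
        assert np.isnan(df.gc_donor_pct.iloc[0])

    def test_partition_consistency(self):
        """completeness classes and location classes both tile the calls."""
        rng = np.random.default_rng(4)
        comps = ["complete", "complete_duplicated", "partial"]
        locs = ["intronic_same_strand", "intergenic", "exon_overlap"]
        calls = [
            IECall("chr1", (i * 500, i * 500 + 60), "+",
                   "D-IE1" if rng.random() < 0.8 else "mixed",
                   comps[rng.integers(0, 3)], ("m1",), 1,
                   locs[rng.integers(0, 3)], "GT")
            for i in range(40)
        ]
        df = ie_family_stats(calls)
        df = df[df.completeness != "all"]
        assert int(df["count"].sum()) == 40
        assert int((df.intronic + df.intergenic + df.exon_overlap).sum()) == 40


class TestDonorPFM:
    def test_uniform_donor_context_is_point_mass(self):
        seq = "GTAAGTAAAAAA" * 40
        genome = make_genome(chr1=seq)
        introns = [intron((i * 12, i * 12 + 12)) for i in range(30)]
        pfm = donor_pfm(introns, genome, window=6)
        assert pfm[0].argmax() == 2  # G
        assert pfm[1].argmax() == 3  # T
        assert pfm[0, 2] == pytest.approx(1.0)

    def test_subsample_deterministic(self):
        rng = np.random.default_rng(5)
        genome = make_genome(chr1=random_dna(rng, 20_000))
        introns = [intron((i * 30, i * 30 + 25)) for i in range(600)]
        a = donor_pfm(introns, genome, subsample=500, seed=9)
        b = donor_pfm(introns, genome, subsample=500, seed=9)
        assert np.array_equal(a, b)

    def test_conserved_ie_context_has_higher_information(self):
        rng = np.random.default_rng(6)
        conserved = "GTAAGTTCGGCA"
        block = "".join(
            conserved + random_dna(rng, 48) for _ in range(30)
        )
        tail = random_dna(rng, 3000)
        genome = make_genome(chr1=block + tail)
        ie_introns = [intron((i * 60, i * 60 + 55)) for i in range(30)]
        rsi_introns = [
            intron((len(block) + i * 80, len(block) + i * 80 + 60))
            for i in range(30)
        ]
        calls = [
            IECall(i.chrom, (i.interval[0] + 14, i.interval[0] + 40), "+",
                   "D-IE1", "partial", ("m1",), 1)
            for i in ie_introns
        ]
        pfms = donor_pfms_by_class(ie_introns + rsi_introns, calls, genome)

        def info(pfm):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = pfm * (np.log2(pfm) - np.log2(0.25))
            return np.nansum(t)

        assert info(pfms["IE-GT"]) > info(pfms["RSI-GT"])
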