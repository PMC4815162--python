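"""Evidence weights, locus grouping and exact per-locus selection."""
from fractions import Fraction

import numpy as np
import pytest

from picoannot.core import ESTAlignment, PeptidePlacement, SpliceJunction
from picoannot.scoring import (
    EvidenceBundle,
    ScoreBreakdown,
    default_conflict,
    group_loci,
    score_cdna,
    score_ie_bonus,
    score_intron_evidence,
    score_model,
    score_peptides,
    score_utrs,
    select_models,
)
from conftest import make_model


def _junc_keys(model, intervals):
    return {(model.chrom, s, e, model.strand) for s, e in intervals}


def three_intron_model():
    return make_model(
        exons=((0, 30), (60, 90), (120, 150), (180, 210)), cds=(0, 210)
    )


class TestIntronEvidence:
    def test_all_confirmed(self):
        m = three_intron_model()
        assert score_intron_evidence(m, _junc_keys(m, m.intron_intervals())) == 20

    def test_some_confirmed(self):
        m = three_intron_model()
        keys = _junc_keys(m, m.intron_intervals()[:1])
        assert score_intron_evidence(m, keys) == 5

    def test_none_confirmed(self):
        m = three_intron_model()
        assert score_intron_evidence(m, set()) == -5

    def test_single_exon_is_neutral(self):
        m = make_model(exons=((0, 30),), cds=(0, 30))
        assert score_intron_evidence(m, set()) == 0

    def test_wrong_strand_junction_does_not_confirm(self):
        m = three_intron_model()
        keys = {(m.chrom, s, e, "-") for s, e in m.intron_intervals()}
        assert score_intron_evidence(m, keys) == -5

    def test_est_intron_also_confirms(self):
        m = three_intron_model()
        est_keys = _junc_keys(m, m.intron_intervals())
        assert score_intron_evidence(m, set(), est_keys) == 20


class TestIEBonus:
    def test_two_of_four_introns(self):
        m = make_model(
            exons=((0, 30), (60, 90), (120, 150), (180, 210), (240, 270)),
            cds=(0, 270),
        )
        # introns are [30,60),[90,120),[150,180),[210,240); elements sit
        # in the first and last
        ies = {"chr1": [(35, 50), (215, 230)]}
        assert score_ie_bonus(m, ies) == 40

    def test_no_elements(self):
        assert score_ie_bonus(three_intron_model(), {}) == 0

    def test_one_intron_two_elements_counts_once(self):
        m = three_intron_model()
        s, e = m.intron_intervals()[0]
        ies = {"chr1": [(s, s + 5), (e - 5, e)]}
        assert score_ie_bonus(m, ies) == 20


class TestPeptides:
    def test_unique_locations(self):
        m = make_model()
        peps = [PeptidePlacement("PEPTIDE", "m1", 1) for _ in range(3)]
        assert score_peptides(m, peps) == 3

    def test_fractional_multimapper(self):
        m = make_model()
        assert score_peptides(m, [PeptidePlacement("PEPTIDE", "m1", 4)]) == \
            Fraction(1, 4)

    def test_no_peptides(self):
        assert score_peptides(make_model(), []) == 0


class TestCDNA:
    def test_full_clone(self):
        m = make_model(exons=((100, 400),), cds=(100, 400))
        ests = {
            "cl1": [
                ESTAlignment("cl1/f", "forward", "chr1", ((90, 200),), "+"),
                ESTAlignment("cl1/r", "reverse", "chr1", ((300, 420),), "+"),
            ]
        }
        assert score_cdna(m, ests) == 20

    def test_one_mate_only(self):
        m = make_model(exons=((100, 400),), cds=(100, 400))
        ests = {"cl1": [
            ESTAlignment("cl1/f", "forward", "chr1", ((90, 200),), "+"),
        ]}
        assert score_cdna(m, ests) == 0

    def test_flat_bonus_for_two_clones(self):
        m = make_model(exons=((100, 400),), cds=(100, 400))
        mk = lambda c: [
            ESTAlignment(f"{c}/f", "forward", "chr1", ((90, 200),), "+"),
            ESTAlignment(f"{c}/r", "reverse", "chr1", ((300, 420),), "+"),
        ]
        assert score_cdna(m, {"cl1": mk("cl1"), "cl2": mk("cl2")}) == 20


@pytest.mark.parametrize(
    "u5,u3,expected", [(True, True, 10), (True, False, 5), (False, False, 0)]
)
def test_score_utrs(u5, u3, expected):
    m = make_model(exons=((0, 30),), cds=(0, 30), utr_flags=False)
    from dataclasses import replace

    assert score_utrs(replace(m, utr5_present=u5, utr3_present=u3)) == expected


class TestScoreModel:
    def test_manual_model_bonus(self):
        m = make_model(source="manual")
        s = score_model(m, EvidenceBundle())
        assert s.manual_points == 10000 and s.total == 10000

    def test_component_sum_92(self):
        """All-confirmed 2-intron model, both introns over IEs, 2 unique
        peptides, a full cDNA and both UTRs: 20+40+2+20+10 = 92."""
        from dataclasses import replace

        m = make_model(exons=((0, 90), (150, 240), (300, 390)), cds=(6, 384))
        m = replace(m, utr5_present=True, utr3_present=True)
        ev = EvidenceBundle.build(
            junctions=[
                SpliceJunction("chr1", iv, "+", 12)
                for iv in m.intron_intervals()
            ],
            ie_intervals={"chr1": [(95, 140), (250, 260)]},
            peptides=[
                PeptidePlacement("AAAAAAK", "m1", 1),
                PeptidePlacement("CCCCCCR", "m1", 1),
            ],
            ests=[
                ESTAlignment("cl1/f", "forward", "chr1", ((0, 100),), "+"),
                ESTAlignment("cl1/r", "reverse", "chr1", ((300, 390),), "+"),
            ],
        )
        s = score_model(m, ev)
        assert (s.intron_points, s.ie_bonus_points, s.peptide_points,
                s.cdna_points, s.utr_points) == (20, 40, 2, 20, 10)
        assert s.total == 92

    def test_evidence_free_multiexon_penalty(self):
        m = three_intron_model()
        assert score_model(m, EvidenceBundle()).total == -5


class TestLoci:
    def test_simple_grouping(self):
        a = make_model("A", exons=((0, 100),), cds=(0, 99))
        b = make_model("B", exons=((50, 150),), cds=(51, 150))
        c = make_model("C", exons=((200, 300),), cds=(200, 300))
        loci = group_loci([a, b, c])
        members = sorted(tuple(sorted(l.member_model_ids)) for l in loci)
        assert members == [("A", "B"), ("C",)]

    def test_transitive_chain_single_locus(self):
        a = make_model("A", exons=((0, 100),), cds=(0, 99))
        b = make_model("B", exons=((90, 200),), cds=(90, 198))
        c = make_model("C", exons=((190, 300),), cds=(190, 298))
        loci = group_loci([a, b, c])
        assert len(loci) == 1
        assert sorted(loci[0].member_model_ids) == ["A", "B", "C"]

    def test_empty_input(self):
        assert group_loci([]) == []


def _scored(models, totals):
    return {
        m.model_id: ScoreBreakdown(m.model_id, 0, 0, Fraction(t), 0, 0, 0)
        for m, t in zip(models, totals)
    }


class TestSelection:
    def test_higher_score_wins(self):
        a = make_model("A", exons=((0, 100),), cds=(0, 99))
        b = make_model("B", exons=((50, 150),), cds=(51, 150))
        sel = select_models([a, b], _scored([a, b], [25, 10]))
        assert [m.model_id for m in sel] == ["A"]

    def test_chain_takes_outer_pair(self):
        a = make_model("A", exons=((0, 100),), cds=(0, 99))
        b = make_model("B", exons=((90, 200),), cds=(90, 198))
        c = make_model("C", exons=((190, 300),), cds=(190, 298))
        sel = select_models([a, b, c], _scored([a, b, c], [10, 15, 10]))
        assert sorted(m.model_id for m in sel) == ["A", "C"]

    def test_convergent_utr_overlap_pair_coexists(self):
        # opposite strands, spans overlap only in 3' UTRs: no conflict
        plus = make_model("P", exons=((0, 1000),), cds=(100, 700), strand="+")
        minus = make_model("M", exons=((900, 2000),), cds=(1200, 1800),
                           strand="-")
        assert not default_conflict(plus, minus)
        sel = select_models([plus, minus], _scored([plus, minus], [30, 30]))
        assert sorted(m.model_id for m in sel) == ["M", "P"]

    def test_opposite_strand_cds_overlap_conflicts(self):
        plus = make_model("P", exons=((0, 1000),), cds=(100, 700), strand="+")
        minus = make_model("M", exons=((500, 1500),), cds=(600, 1200),
                           strand="-")
        assert default_conflict(plus, minus)

    def test_all_negative_locus_selects_empty(self):
        a = make_model("A", exons=((0, 100),), cds=(0, 99))
        assert select_models([a], _scored([a], [-5])) == []
        assert select_models([a], _scored([a], [-5]), allow_empty=False) == [a]

    def test_monotone_in_added_evidence(self):
        """Adding a confirming junction, a peptide or a UTR flag never
        lowers a model's total."""
        from dataclasses import replace

        m = three_intron_model()
        base_ev = EvidenceBundle()
        base = score_model(m, base_ev).total
        with_junc = EvidenceBundle.build(
            junctions=[SpliceJunction(m.chrom, m.intron_intervals()[0], "+", 11)]
        )
        assert score_model(m, with_junc).total >= base
        with_pep = EvidenceBundle.build(
            peptides=[PeptidePlacement("AAAAAAK", m.model_id, 2)]
        )
        assert score_model(m, with_pep).total >= base
        assert score_model(
            replace(m, utr5_present=True), base_ev
        ).total >= base


from conftest import oracle_select, random_locus  # noqa: E402


def test_selection_matches_exhaustive_oracle_small():
    rng = np.random.default_rng(2024)
    for _ in range(60):
        models, scores = random_locus(rng, int(rng.integers(1, 9)))
        got = tuple(sorted(m.model_id for m in select_models(models, scores)))
        assert got == oracle_select(models, scores)


def test_selected_sets_are_maximal():
    """No conflict-free positive-score model can be added to a selection."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        models, scores = random_locus(rng, 8)
        sel = select_models(models, scores)
        chosen = {m.model_id for m in sel}
        for m in models:
            if m.model_id in chosen or scores[m.model_id].total <= 0:
                continue
            assert any(default_conflict(m, s) for s in sel), (
                f"{m.model_id} could have been added"
            )
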