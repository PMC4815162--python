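"""Evidence scoring and per-locus selection of gene models.

Every candidate model is scored with fixed evidence weights:

* intron evidence: +20 if all introns are confirmed by an EST intron or a
  splice junction (exact coordinates, same strand), +5 if some are, -5 if
  none are; single-exon models score 0 here,
* +20 for every intron overlapping an Introner Element,
* +1 per MS peptide placed in the model's ORF, or 1/n for a peptide
  mappable to n genomic locations,
* +10000 for previous manual annotation,
* +20 if both mates of a directional cDNA clone overlap the model,
* +5 per transcript-supported UTR.

Overlapping models are grouped into loci and the highest-scoring
combination of non-conflicting models per locus is selected exactly.
Peptide points are exact rationals (``fractions.Fraction``) so score
comparisons are order-independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

from .core import (
    ESTAlignment,
    GeneModel,
    Intron,
    PeptidePlacement,
    SpliceJunction,
)
from .intervals import Interval, overlaps
from .transfrags import Transfrag

MANUAL_BONUS = 10000
ALL_INTRONS_BONUS = 20
SOME_INTRONS_BONUS = 5
NO_INTRONS_PENALTY = -5
IE_INTRON_BONUS = 20
CDNA_BONUS = 20
UTR_BONUS = 5


@dataclass(frozen=True)
class ScoreBreakdown:
    model_id: str
    intron_points: int
    ie_bonus_points: int
    peptide_points: Fraction
    manual_points: int
    cdna_points: int
    utr_points: int

    @property
    def total(self) -> Fraction:
        return (
            self.intron_points + self.ie_bonus_points + self.peptide_points
            + self.manual_points + self.cdna_points + self.utr_points
        )

    @property
    def n_evidence_types(self) -> int:
        """How many evidence components contributed nonzero points."""
        return sum(
            1 for x in (
                self.intron_points, self.ie_bonus_points, self.peptide_points,
                self.manual_points, self.cdna_points, self.utr_points,
            ) if x != 0
        )


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chrom: str
    member_model_ids: tuple[str, ...]
    span: Interval


@dataclass
class EvidenceBundle:
    """Prepared evidence lookups shared by the per-model score functions."""

    junction_keys: set[tuple[str, int, int, str]] = field(default_factory=set)
    est_intron_keys: set[tuple[str, int, int, str]] = field(default_factory=set)
    ie_intervals: dict[str, list[Interval]] = field(default_factory=dict)
    peptides_by_model: dict[str, list[PeptidePlacement]] = field(default_factory=dict)
    ests_by_clone: dict[str, list[ESTAlignment]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        junctions: Iterable[SpliceJunction] = (),
        est_introns: Iterable[Intron] = (),
        ie_intervals: Mapping[str, Sequence[Interval]] = (),
        peptides: Iterable[PeptidePlacement] = (),
        ests: Iterable[ESTAlignment] = (),
    ) -> "EvidenceBundle":
        ev = cls()
        for j in junctions:
            ev.junction_keys.add(
                (j.chrom, j.intron_interval[0], j.intron_interval[1], j.strand)
            )
        for i in est_introns:
            ev.est_intron_keys.add((i.chrom, *i.interval, i.strand))
        ev.ie_intervals = {c: sorted(iv) for c, iv in dict(ie_intervals).items()}
        for p in peptides:
            ev.peptides_by_model.setdefault(p.model_id, []).append(p)
        for e in ests:
            if e.mate in ("forward", "reverse"):
                ev.ests_by_clone.setdefault(e.clone_id, []).append(e)
        return ev


# ---------------------------------------------------------------------------
# per-model components
# ---------------------------------------------------------------------------

def score_intron_evidence(
    model: GeneModel,
    junction_keys: set[tuple[str, int, int, str]],
    est_intron_keys: set[tuple[str, int, int, str]] = frozenset(),
) -> int:
    """+20 all confirmed / +5 some / -5 none; 0 for single-exon models."""
    introns = model.intron_intervals()
    if not introns:
        return 0
    confirmed = sum(
        (model.chrom, s, e, model.strand) in junction_keys
        or (model.chrom, s, e, model.strand) in est_intron_keys
        for s, e in introns
    )
    if confirmed == len(introns):
        return ALL_INTRONS_BONUS
    if confirmed:
        return SOME_INTRONS_BONUS
    return NO_INTRONS_PENALTY


def score_ie_bonus(
    model: GeneModel, ie_intervals: Mapping[str, Sequence[Interval]]
) -> int:
    """+20 per intron overlapping at least one Introner Element."""
    ies = ie_intervals.get(model.chrom, ())
    n = sum(
        any(overlaps(intron, ie) for ie in ies)
        for intron in model.intron_intervals()
    )
    return IE_INTRON_BONUS * n


def score_peptides(
    model: GeneModel, placements: Iterable[PeptidePlacement]
) -> Fraction:
    """Sum of 1/n_genomic_locations over this model's peptides."""
    total = Fraction(0)
    for p in placements:
        if p.model_id != model.model_id:
            continue
        total += Fraction(1, p.n_genomic_locations)
    return total


def score_cdna(
    model: GeneModel, ests_by_clone: Mapping[str, Sequence[ESTAlignment]]
) -> int:
    """Flat +20 if any clone has both mates overlapping the model span on
    its strand."""
    for alignments in ests_by_clone.values():
        mates_hit = set()
        for est in alignments:
            if (est.chrom == model.chrom
                    and est.inferred_strand in (model.strand, ".")
                    and overlaps(est.span, model.span)):
                mates_hit.add(est.mate)
        if {"forward", "reverse"} <= mates_hit:
            return CDNA_BONUS
    return 0


def score_utrs(model: GeneModel) -> int:
    return UTR_BONUS * (int(model.utr5_present) + int(model.utr3_present))


def score_model(model: GeneModel, evidence: EvidenceBundle) -> ScoreBreakdown:
    return ScoreBreakdown(
        model_id=model.model_id,
        intron_points=score_intron_evidence(
            model, evidence.junction_keys, evidence.est_intron_keys
        ),
        ie_bonus_points=score_ie_bonus(model, evidence.ie_intervals),
        peptide_points=score_peptides(
            model, evidence.peptides_by_model.get(model.model_id, ())
        ),
        manual_points=MANUAL_BONUS if model.source == "manual" else 0,
        cdna_points=score_cdna(model, evidence.ests_by_clone),
        utr_points=score_utrs(model),
    )


# ---------------------------------------------------------------------------
# loci and selection
# ---------------------------------------------------------------------------

def group_loci(models: Sequence[GeneModel]) -> list[Locus]:
    """Connected components of the any-strand genomic-span overlap graph.

    Interval-overlap connectivity is computed with a sweep: a new locus
    starts whenever a model begins past the furthest end seen so far.
    """
    loci: list[Locus] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    counter = 0
    for chrom in sorted(by_chrom):
        group: list[GeneModel] = []
        reach = -1
        for m in sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.model_id)):
            if group and m.start >= reach:
                counter += 1
                loci.append(_make_locus(counter, chrom, group))
                group = []
                reach = -1
            group.append(m)
            reach = max(reach, m.end)
        if group:
            counter += 1
            loci.append(_make_locus(counter, chrom, group))
    return loci


def _make_locus(n: int, chrom: str, members: list[GeneModel]) -> Locus:
    return Locus(
        locus_id=f"locus{n:05d}",
        chrom=chrom,
        member_model_ids=tuple(m.model_id for m in members),
        span=(min(m.start for m in members), max(m.end for m in members)),
    )


def default_conflict(a: GeneModel, b: GeneModel) -> bool:
    """Two models conflict if they overlap on the same strand, or their CDS
    intervals overlap on opposite strands (so convergent pairs whose only
    overlap is 3' UTR may co-exist)."""
    if a.chrom != b.chrom:
        return False
    if a.strand == b.strand:
        return overlaps(a.span, b.span)
    return overlaps(a.cds, b.cds)


def selection_key(
    chosen: Sequence[GeneModel], scores: Mapping[str, ScoreBreakdown]
) -> tuple:
    """Ordering key for candidate selections: higher total score, then
    fewer models (prefer unfragmented representations), longer summed CDS,
    more models with any nonzero evidence, then lexicographically smaller
    id tuple."""
    ids = tuple(sorted(m.model_id for m in chosen))
    return (
        sum((scores[m.model_id].total for m in chosen), Fraction(0)),
        -len(chosen),
        sum(m.cds_spliced_length for m in chosen),
        sum(1 for m in chosen if scores[m.model_id].n_evidence_types > 0),
        tuple(-ord(c) for mid in ids for c in mid + "\0"),
    )


def select_models(
    models: Sequence[GeneModel],
    scores: Mapping[str, ScoreBreakdown],
    conflict_rule: Callable[[GeneModel, GeneModel], bool] = default_conflict,
    allow_empty: bool = True,
) -> list[GeneModel]:
    """Exact highest-scoring conflict-free subset of one locus's members.

    Searches over independent sets of the conflict graph with a
    sum-of-positive-remaining bound; only positive-scoring models can
    enter the optimum, so others are pruned up front.  With
    ``allow_empty=False`` a locus whose best combination is empty instead
    keeps its single best-ranked model.
    """
    cands = sorted(
        (m for m in models if scores[m.model_id].total > 0),
        key=lambda m: (m.start, m.end, m.model_id),
    )
    n = len(cands)
    adj = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if conflict_rule(cands[i], cands[j]):
                adj[i] |= 1 << j
                adj[j] |= 1 << i
    weights = [scores[m.model_id].total for m in cands]
    suffix_pos = [Fraction(0)] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_pos[i] = suffix_pos[i + 1] + max(weights[i], Fraction(0))

    best: dict = {"key": selection_key((), scores), "set": ()}

    def visit(i: int, taken_mask: int, chosen: list[GeneModel],
              score: Fraction) -> None:
        if score + suffix_pos[i] < best["key"][0]:
            return
        if i == n:
            key = selection_key(chosen, scores)
            if key > best["key"]:
                best["key"] = key
                best["set"] = tuple(chosen)
            return
        if not (taken_mask & (1 << i)):
            chosen.append(cands[i])
            visit(i + 1, taken_mask | adj[i], chosen, score + weights[i])
            chosen.pop()
        visit(i + 1, taken_mask, chosen, score)

    visit(0, 0, [], Fraction(0))
    selected = list(best["set"])
    if not selected and not allow_empty and models:
        selected = [
            max(
                models,
                key=lambda m: (
                    scores[m.model_id].total,
                    m.cds_spliced_length,
                    scores[m.model_id].n_evidence_types,
                    tuple(-ord(c) for c in m.model_id),
                ),
            )
        ]
    return sorted(selected, key=lambda m: (m.start, m.model_id))


@dataclass
class SelectionResult:
    selected: list[GeneModel]
    scores: dict[str, ScoreBreakdown]
    loci: list[Locus]


def run_selection(
    models: Sequence[GeneModel],
    evidence: EvidenceBundle,
    conflict_rule: Callable[[GeneModel, GeneModel], bool] = default_conflict,
    allow_empty: bool = True,
) -> SelectionResult:
    """Score every model, group loci, and select per locus."""
    scores = {m.model_id: score_model(m, evidence) for m in models}
    by_id = {m.model_id: m for m in models}
    loci = group_loci(models)
    selected: list[GeneModel] = []
    for locus in loci:
        members = [by_id[i] for i in locus.member_model_ids]
        selected.extend(select_models(members, scores, conflict_rule, allow_empty))
    return SelectionResult(selected, scores, loci)


# ---------------------------------------------------------------------------
# curation flags (machine stand-in for the browser-based review pass)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationFlag:
    kind: str  # merge_candidate | break_candidate
    model_ids: tuple[str, ...]
    transfrag_span: Interval


def curation_flags(
    selected: Sequence[GeneModel], transfrags: Sequence[Transfrag]
) -> list[CurationFlag]:
    """Flag loci where a spliced transfrag spans >=2 selected same-strand
    models (merge candidates) or covers <50% of a selected model (break
    candidates)."""
    flags = []
    for t in transfrags:
        if not t.spliced:
            continue
        hit = [
            m for m in selected
            if m.chrom == t.chrom and m.strand == t.strand
            and overlaps(m.span, t.span)
        ]
        if len(hit) >= 2:
            flags.append(
                CurationFlag("merge_candidate",
                             tuple(sorted(m.model_id for m in hit)), t.span)
            )
    for m in selected:
        mine = [
            t for t in transfrags
            if t.chrom == m.chrom and t.strand == m.strand
            and overlaps(t.span, m.span)
        ]
        if not mine:
            continue
        best_cov = max(
            min(t.span[1], m.end) - max(t.span[0], m.start) for t in mine
        )
        if best_cov < 0.5 * (m.end - m.start):
            flags.append(
                CurationFlag("break_candidate", (m.model_id,),
                             max(mine, key=lambda t: t.span[1] - t.span[0]).span)
            )
    return flags


def scores_to_frame(scores: Mapping[str, ScoreBreakdown]):
    """Scores as a DataFrame (floats) for TSV output."""
    import pandas as pd

    rows = [
        {
            "model_id": s.model_id,
            "intron_points": s.intron_points,
            "ie_bonus_points": s.ie_bonus_points,
            "peptide_points": float(s.peptide_points),
            "manual_points": s.manual_points,
            "cdna_points": s.cdna_points,
            "utr_points": s.utr_points,
            "total": float(s.total),
        }
        for _, s in sorted(scores.items())
    ]
    return pd.DataFrame(rows)
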