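"""Discovery and classification of Introner Elements (IEs).

IEs are repetitive spliceosomal introns: families of near-identical
intron sequences scattered across the genome, recognizable as ordered
groups of sequence motifs separated by short (0-49 nt) gaps.  The
workflow mirrors intron-derived discovery followed by whole-genome
scanning:

1. harvest nonredundant reading-strand intron sequences (<=500 nt) from
   gene models or strand-oriented multi-exon ESTs,
2. cluster them by global-alignment identity (80% identity over 80% of
   the longer sequence, single linkage),
3. discover motifs per cluster under a ZOOPS model,
4. scan the genome with the motif PWMs at an exact p-value threshold
   (default 1e-10) on both strands,
5. concatenate same-strand hits within 50 nt into element candidates,
6. classify candidates by family and completeness, locate them against
   the gene set, and summarize per-family counts and splice-donor usage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomeSequence,
    Intron,
    classify_donor,
    extract_introns,
    intron_sequence,
)
from .intervals import Interval, UnionFind, contains, overlaps
from .motifs import PWM, MotifHit, discover_motifs_zoops, scan_genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifGroup:
    """An ordered family of motifs with inter-motif gap bounds."""

    family_id: str
    motif_ids: tuple[str, ...]
    min_gap: int = 0
    max_gap: int = 49


@dataclass(frozen=True)
class IECall:
    chrom: str
    interval: Interval
    strand: str
    family: str                 # D-IE1 | D-IE2 | ABC-IE | mixed | user id
    completeness: str           # complete | complete_duplicated | partial
    motifs_present: tuple[str, ...]
    n_motifs: int
    location_class: str = "unlocated"
    donor_type: str = "n/a"


# ---------------------------------------------------------------------------
# intron harvesting & clustering
# ---------------------------------------------------------------------------

def harvest_introns(
    introns: Iterable[Intron],
    genome: dict[str, GenomeSequence],
    max_len: int = 500,
) -> list[tuple[Intron, str]]:
    """Nonredundant (exact-duplicate-collapsed) reading-strand intron
    sequences of at most ``max_len`` nt; one representative per sequence."""
    seen: dict[str, Intron] = {}
    order: list[str] = []
    for intron in sorted(
        introns, key=lambda i: (i.chrom, i.interval, i.strand)
    ):
        if intron.length > max_len:
            continue
        seq = intron_sequence(intron, genome)
        if seq not in seen:
            seen[seq] = intron
            order.append(seq)
    return [(seen[s], s) for s in order]


def _alignment_identity(a: str, b: str, aligner) -> float:
    """Global-alignment matches divided by the longer sequence length."""
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / max(len(a), len(b))


def cluster_introns(
    seqs: Sequence[str],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
) -> list[list[int]]:
    """Single-linkage clusters of intron sequences, blastclust-style.

    Two sequences link when their global-alignment identity, measured
    over the longer sequence's length, reaches ``min_identity`` and the
    shorter sequence is at least ``min_coverage`` of the longer.
    Alignment scoring: match 1, mismatch -1, gap -2.  Clusters are
    returned as index lists, largest first.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-2,
    )
    n = len(seqs)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            la, lb = len(seqs[i]), len(seqs[j])
            if min(la, lb) < min_coverage * max(la, lb):
                continue
            # identity over the longer length is bounded by the shorter
            # length, so the coverage check above is also a cheap prefilter
            if _alignment_identity(seqs[i], seqs[j], aligner) >= min_identity:
                uf.union(i, j)
    clusters = sorted(
        uf.groups().values(), key=lambda g: (-len(g), g[0])
    )
    return [sorted(g) for g in clusters]


def discover_family_motifs(
    introns_and_seqs: Sequence[tuple[Intron, str]],
    min_cluster: int = 10,
    n_motifs: int = 6,
    min_sites: int = 10,
    seed: int = 0,
    **zoops_kwargs,
) -> list[list[PWM]]:
    """Cluster harvested introns and run ZOOPS discovery per cluster of at
    least ``min_cluster`` members (reading strand only)."""
    seqs = [s for _, s in introns_and_seqs]
    out = []
    for ci, cluster in enumerate(cluster_introns(seqs), 1):
        if len(cluster) < min_cluster:
            continue
        pwms = discover_motifs_zoops(
            [seqs[i] for i in cluster], n_motifs=n_motifs,
            min_sites=min_sites, seed=seed, **zoops_kwargs,
        )
        pwms = [replace(p, motif_id=f"c{ci}.{p.motif_id}") for p in pwms]
        if pwms:
            out.append(pwms)
    return out


# ---------------------------------------------------------------------------
# hit merging and classification
# ---------------------------------------------------------------------------

def merge_hits(hits: Sequence[MotifHit], max_gap: int = 50) -> list[IECall]:
    """Concatenate same-strand hits whose gap is strictly below
    ``max_gap`` (i.e. 0-49 nt apart at the default) into unclassified
    element candidates carrying the ordered motif multiset."""
    candidates: list[IECall] = []
    keyed: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        keyed.setdefault((h.chrom, h.strand), []).append(h)
    for (chrom, strand), group in sorted(keyed.items()):
        group.sort(key=lambda h: h.interval)
        run: list[MotifHit] = []
        for h in group:
            if run and h.interval[0] - run[-1].interval[1] >= max_gap:
                candidates.append(_candidate_from_run(chrom, strand, run))
                run = []
            run.append(h)
        if run:
            candidates.append(_candidate_from_run(chrom, strand, run))
    return sorted(candidates, key=lambda c: (c.chrom, c.interval, c.strand))


def _candidate_from_run(chrom: str, strand: str, run: list[MotifHit]) -> IECall:
    motifs = [h.motif_id for h in run]
    if strand == "-":  # transcription order is reversed genomic order
        motifs = motifs[::-1]
    return IECall(
        chrom=chrom,
        interval=(run[0].interval[0], run[-1].interval[1]),
        strand=strand,
        family="unclassified",
        completeness="partial",
        motifs_present=tuple(motifs),
        n_motifs=len(motifs),
    )


def _is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    it = iter(haystack)
    return all(x in it for x in needle)


def classify_element(
    candidate: IECall, groups: Sequence[MotifGroup]
) -> IECall:
    """Assign family and completeness from the candidate's ordered motifs.

    complete: every family motif present exactly once, in canonical order;
    complete_duplicated: all present with at least one repeat and the
    canonical order embedded; partial: anything else within one family;
    mixed: motifs from more than one family.
    """
    by_motif = {}
    for g in groups:
        for m in g.motif_ids:
            by_motif[m] = g
    fams = []
    for m in candidate.motifs_present:
        if m not in by_motif:
            raise ValueError(f"motif {m!r} is not in any motif group")
        fams.append(by_motif[m].family_id)
    if len(set(fams)) > 1:
        return replace(candidate, family="mixed", completeness="partial")
    group = by_motif[candidate.motifs_present[0]]
    motifs = candidate.motifs_present
    if motifs == group.motif_ids:
        completeness = "complete"
    elif (set(motifs) >= set(group.motif_ids)
          and len(motifs) > len(group.motif_ids)
          and _is_subsequence(group.motif_ids, motifs)):
        completeness = "complete_duplicated"
    else:
        completeness = "partial"
    return replace(candidate, family=group.family_id, completeness=completeness)


# ---------------------------------------------------------------------------
# location against the gene set
# ---------------------------------------------------------------------------

def locate_elements(
    calls: Sequence[IECall],
    models: Sequence[GeneModel],
    genome: dict[str, GenomeSequence],
) -> list[IECall]:
    """Label each call intronic (same/opposite strand, inheriting the
    containing intron's donor type), exon-overlapping, or intergenic.
    Exon overlap takes precedence over intron containment."""
    exons_by_chrom: dict[str, list[Interval]] = {}
    introns_by_chrom: dict[str, list[Intron]] = {}
    for m in models:
        exons_by_chrom.setdefault(m.chrom, []).extend(m.exons)
        introns_by_chrom.setdefault(m.chrom, []).extend(
            extract_introns(m, genome)
        )
    out = []
    for call in calls:
        exon_hit = any(
            overlaps(call.interval, ex)
            for ex in exons_by_chrom.get(call.chrom, ())
        )
        if exon_hit:
            out.append(replace(call, location_class="exon_overlap",
                               donor_type="n/a"))
            continue
        container = next(
            (
                i for i in introns_by_chrom.get(call.chrom, ())
                if contains(i.interval, call.interval)
            ),
            None,
        )
        if container is not None:
            loc = ("intronic_same_strand" if container.strand == call.strand
                   else "intronic_opposite_strand")
            out.append(replace(call, location_class=loc,
                               donor_type=classify_donor(container)))
        else:
            out.append(replace(call, location_class="intergenic",
                               donor_type="n/a"))
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def ie_family_stats(
    calls: Sequence[IECall], introns: Sequence[Intron] = ()
) -> pd.DataFrame:
    """Per family x completeness: counts, intronic/intergenic split and GC
    splice-donor percentage among containing introns; plus a genome-wide
    row comparing IE-containing introns with regular spliceosomal introns
    when the full intron set is supplied."""
    rows = []
    frame = pd.DataFrame(
        [
            {
                "family": c.family,
                "completeness": c.completeness,
                "location": c.location_class,
                "donor": c.donor_type,
            }
            for c in calls
        ]
    )
    if not frame.empty:
        for (fam, comp), g in frame.groupby(["family", "completeness"],
                                            sort=True):
            intronic = g.location.str.startswith("intronic")
            n_intronic = int(intronic.sum())
            donors = g.loc[intronic, "donor"]
            gc_pct = (
                round(100.0 * (donors == "GC").mean(), 2)
                if n_intronic else float("nan")
            )
            rows.append(
                {
                    "family": fam,
                    "completeness": comp,
                    "count": len(g),
                    "intronic": n_intronic,
                    "intergenic": int((g.location == "intergenic").sum()),
                    "exon_overlap": int((g.location == "exon_overlap").sum()),
                    "gc_donor_pct": gc_pct,
                }
            )
    if introns:
        ie_iv = {(c.chrom, c.strand): [] for c in calls}
        for c in calls:
            ie_iv[(c.chrom, c.strand)].append(c.interval)
        def has_ie(i: Intron) -> bool:
            return any(
                overlaps(i.interval, iv)
                for iv in ie_iv.get((i.chrom, i.strand), ())
            )
        flags = np.array([has_ie(i) for i in introns])
        gc = np.array([classify_donor(i) == "GC" for i in introns])
        for label, mask in (("IE-containing introns", flags),
                            ("regular spliceosomal introns", ~flags)):
            rows.append(
                {
                    "family": label,
                    "completeness": "all",
                    "count": int(mask.sum()),
                    "intronic": int(mask.sum()),
                    "intergenic": 0,
                    "exon_overlap": 0,
                    "gc_donor_pct": (
                        round(100.0 * gc[mask].mean(), 2)
                        if mask.any() else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def donor_pfm(
    introns: Sequence[Intron],
    genome: dict[str, GenomeSequence],
    window: int = 12,
    subsample: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Donor-anchored position-frequency matrix: base frequencies over the
    first ``window`` nt of the intron reading strand, from a seeded random
    subsample of at most ``subsample`` introns."""
    usable = [i for i in introns if i.length >= window]
    if len(usable) < 10:
        logger.warning("donor_pfm: only %d introns (low support)", len(usable))
    if not usable:
        return np.full((window, 4), np.nan)
    rng = np.random.default_rng(seed)
    if len(usable) > subsample:
        idx = sorted(rng.choice(len(usable), size=subsample, replace=False))
        usable = [usable[i] for i in idx]
    counts = np.zeros((window, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for intron in usable:
        seq = intron_sequence(intron, genome)[:window]
        for pos, base in enumerate(seq):
            if base in base_index:
                counts[pos, base_index[base]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def donor_pfms_by_class(
    introns: Sequence[Intron],
    ie_calls: Sequence[IECall],
    genome: dict[str, GenomeSequence],
    window: int = 12,
    subsample: int = 500,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """PFMs for the four donor classes RSI-GT, RSI-GC, IE-GT, IE-GC."""
    ie_iv: dict[tuple[str, str], list[Interval]] = {}
    for c in ie_calls:
        ie_iv.setdefault((c.chrom, c.strand), []).append(c.interval)
    classes: dict[str, list[Intron]] = {
        "RSI-GT": [], "RSI-GC": [], "IE-GT": [], "IE-GC": [],
    }
    for i in introns:
        donor = classify_donor(i)
        if donor not in ("GT", "GC"):
            continue
        is_ie = any(
            overlaps(i.interval, iv) for iv in ie_iv.get((i.chrom, i.strand), ())
        )
        classes[("IE-" if is_ie else "RSI-") + donor].append(i)
    return {
        name: donor_pfm(members, genome, window, subsample, seed)
        for name, members in classes.items()
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def find_introner_elements(
    genome: dict[str, GenomeSequence],
    pwms: Sequence[PWM],
    groups: Sequence[MotifGroup],
    models: Sequence[GeneModel] = (),
    p_threshold: float = 1e-10,
    max_gap: int = 50,
) -> list[IECall]:
    """Scan -> merge -> classify -> locate, returning located IE calls."""
    hits = scan_genome(genome, pwms, p_threshold=p_threshold)
    candidates = merge_hits(hits, max_gap=max_gap)
    calls = [classify_element(c, groups) for c in candidates]
    if models:
        calls = locate_elements(calls, models, genome)
    return calls


def calls_to_frame(calls: Sequence[IECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.interval[0],
                "end": c.interval[1],
                "strand": c.strand,
                "family": c.family,
                "completeness": c.completeness,
                "n_motifs": c.n_motifs,
                "motifs": ",".join(c.motifs_present),
                "location": c.location_class,
                "donor": c.donor_type,
            }
            for c in calls
        ]
    )
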