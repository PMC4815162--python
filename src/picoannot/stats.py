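"""Gene-set summary statistics, convergent overlapping pairs (COPs), and
GC-composition profiling.

The base partition tiles the genome: a base is exonic if inside any exon
of any model, else intronic if inside any intron, else intergenic, so
exonic + intronic + intergenic always equals genome length.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ESTAlignment,
    GeneModel,
    GenomeSequence,
    classify_donor,
    extract_introns,
)
from .intervals import Interval, merge_intervals, overlaps, total_length


@dataclass(frozen=True)
class GeneSetStats:
    n_genes: int
    mean_transcript_length: float   # spliced, introns removed (nt)
    mean_coding_length: float       # spliced CDS (nt)
    n_introns: int
    mean_intron_length: float
    n_exons: int
    mean_exon_length: float
    n_spliced_genes: int
    exons_per_multiexon_gene: float  # 0 when no spliced gene exists
    intergenic_mb: float
    exonic_mb: float
    intronic_mb: float
    gc_splice_donor_pct: float


def gene_set_stats(
    models: Sequence[GeneModel], genome: dict[str, GenomeSequence]
) -> GeneSetStats:
    n_genes = len(models)
    transcript_lengths = [m.transcript_length for m in models]
    coding_lengths = [m.cds_spliced_length for m in models]
    exon_lengths = [e - s for m in models for s, e in m.exons]
    intron_lengths = [e - s for m in models for s, e in m.intron_intervals()]
    spliced = [m for m in models if m.n_exons > 1]
    donors = [
        classify_donor(i) for m in models for i in extract_introns(m, genome)
    ]

    exonic = merge_intervals_by_chrom(
        (m.chrom, ex) for m in models for ex in m.exons
    )
    intronic_raw = merge_intervals_by_chrom(
        (m.chrom, iv) for m in models for iv in m.intron_intervals()
    )
    exonic_total = sum(total_length(ivs) for ivs in exonic.values())
    # exon takes precedence over intron across overlapping genes
    intronic_total = 0
    for chrom, ivs in intronic_raw.items():
        intronic_total += _subtract_total(ivs, exonic.get(chrom, []))
    genome_total = sum(g.length for g in genome.values())
    intergenic_total = genome_total - exonic_total - intronic_total

    mean = lambda xs: float(np.mean(xs)) if xs else 0.0
    return GeneSetStats(
        n_genes=n_genes,
        mean_transcript_length=mean(transcript_lengths),
        mean_coding_length=mean(coding_lengths),
        n_introns=len(intron_lengths),
        mean_intron_length=mean(intron_lengths),
        n_exons=len(exon_lengths),
        mean_exon_length=mean(exon_lengths),
        n_spliced_genes=len(spliced),
        exons_per_multiexon_gene=(
            mean([m.n_exons for m in spliced]) if spliced else 0.0
        ),
        intergenic_mb=intergenic_total / 1e6,
        exonic_mb=exonic_total / 1e6,
        intronic_mb=intronic_total / 1e6,
        gc_splice_donor_pct=(
            100.0 * sum(d == "GC" for d in donors) / len(donors)
            if donors else 0.0
        ),
    )


def merge_intervals_by_chrom(
    items: Iterable[tuple[str, Interval]]
) -> dict[str, list[Interval]]:
    grouped: dict[str, list[Interval]] = {}
    for chrom, iv in items:
        grouped.setdefault(chrom, []).append(iv)
    return {c: merge_intervals(ivs) for c, ivs in grouped.items()}


def _subtract_total(ivs: list[Interval], minus: list[Interval]) -> int:
    """Total bases of ``ivs`` not covered by ``minus`` (both merged)."""
    total = sum(e - s for s, e in ivs)
    overlap = 0
    j = 0
    for s, e in ivs:
        while j < len(minus) and minus[j][1] <= s:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < e:
            overlap += min(e, minus[k][1]) - max(s, minus[k][0])
            k += 1
    return total - overlap


# ---------------------------------------------------------------------------
# convergent overlapping pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class COPRecord:
    gene_a: str   # the + strand (leftward-3'-end) gene
    gene_b: str   # the - strand gene
    overlap: int  # nt
    est_validated: bool
    region: str = "other"  # LGC | other


def detect_cops(
    models: Sequence[GeneModel],
    ests: Sequence[ESTAlignment] = (),
    require_est: bool = True,
    lgc_segments: dict[str, list[Interval]] | None = None,
) -> tuple[list[COPRecord], list[COPRecord]]:
    """Find tail-to-tail convergent overlapping pairs.

    A COP is a + strand gene and a - strand gene whose spans overlap at
    their 3' ends (the + gene lies left of the - gene).  With
    ``require_est`` the overlap must be covered by correctly-stranded EST
    alignments for both genes; pairs failing that are reported separately
    in a relaxed list.  Returns ``(validated, relaxed)``.
    """
    validated, relaxed = [], []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.start, m.end))
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                if b.start >= a.end:
                    break
                if a.strand == b.strand:
                    continue
                plus, minus = (a, b) if a.strand == "+" else (b, a)
                # convergent (-> <-): + gene's 3' end inside the overlap,
                # i.e. the + gene starts first and ends inside/before the
                # - gene, whose 3' end (genomic start) lies inside the +
                if not (plus.start < minus.start and plus.end < minus.end):
                    continue
                ov = (minus.start, plus.end)
                est_ok = _est_covers(ov, chrom, "+", ests) and _est_covers(
                    ov, chrom, "-", ests
                )
                region = "other"
                if lgc_segments:
                    mid = (ov[0] + ov[1]) // 2
                    if any(
                        s <= mid < e for s, e in lgc_segments.get(chrom, ())
                    ):
                        region = "LGC"
                rec = COPRecord(plus.model_id, minus.model_id,
                                ov[1] - ov[0], est_ok, region)
                if est_ok or not require_est:
                    validated.append(rec)
                else:
                    relaxed.append(rec)
    return validated, relaxed


def _est_covers(
    region: Interval, chrom: str, strand: str, ests: Sequence[ESTAlignment]
) -> bool:
    return any(
        e.chrom == chrom and e.inferred_strand == strand
        and overlaps(e.span, region)
        for e in ests
    )


def intergenic_distance_stats(
    models: Sequence[GeneModel],
    region_segments: dict[str, list[Interval]] | None = None,
) -> dict[str, tuple[int, float, float]]:
    """Mean +/- sd of distances between consecutive gene spans, split by
    region class (inside vs outside the supplied segments, e.g. the LGC).
    Overlapping neighbors contribute distance 0.  Returns
    ``{region: (n, mean, sd)}`` with sample (ddof=1) sd."""
    dists: dict[str, list[int]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, ms in by_chrom.items():
        ms = sorted(ms, key=lambda m: (m.start, m.end))
        for prev, nxt in zip(ms, ms[1:]):
            d = max(0, nxt.start - prev.end)
            region = "other"
            if region_segments:
                mid = (prev.end + nxt.start) // 2
                if any(
                    s <= mid < e
                    for s, e in region_segments.get(chrom, ())
                ):
                    region = "LGC"
            dists.setdefault(region, []).append(d)
    return {
        region: (
            len(xs),
            float(np.mean(xs)),
            float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0,
        )
        for region, xs in sorted(dists.items())
    }


# ---------------------------------------------------------------------------
# GC profile and low-GC segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCWindow:
    chrom: str
    interval: Interval
    gc_fraction: float  # percent


@dataclass(frozen=True)
class LowGCSegment:
    chrom: str
    interval: Interval
    mean_gc: float  # percent


def gc_profile(
    genome: dict[str, GenomeSequence], window: int = 10_000, step: int = 5_000
) -> list[GCWindow]:
    """Sliding-window GC percentage; a window larger than the chromosome
    yields one whole-chromosome window."""
    out = []
    for chrom_id in sorted(genome):
        seq = genome[chrom_id].sequence
        is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        L = len(seq)
        if window >= L:
            out.append(GCWindow(chrom_id, (0, L), 100.0 * cum[-1] / max(L, 1)))
            continue
        for s in range(0, L - window + 1, step):
            e = s + window
            out.append(
                GCWindow(chrom_id, (s, e), 100.0 * (cum[e] - cum[s]) / window)
            )
    return out


def detect_low_gc(
    profile: Sequence[GCWindow],
    genome: dict[str, GenomeSequence],
    threshold: float,
) -> list[LowGCSegment]:
    """Merge maximal runs of below-threshold windows into segments; the
    reported mean GC is recomputed over the merged genomic interval."""
    below: dict[str, list[Interval]] = {}
    for w in profile:
        if w.gc_fraction < threshold:
            below.setdefault(w.chrom, []).append(w.interval)
    out = []
    for chrom in sorted(below):
        for s, e in merge_intervals(below[chrom]):
            seq = genome[chrom].sequence[s:e]
            gc = 100.0 * (seq.count("G") + seq.count("C")) / max(len(seq), 1)
            out.append(LowGCSegment(chrom, (s, e), gc))
    return out


def genome_gc_percent(genome: dict[str, GenomeSequence]) -> float:
    gc = total = 0
    for g in genome.values():
        gc += g.sequence.count("G") + g.sequence.count("C")
        total += g.length
    return 100.0 * gc / max(total, 1)
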