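"""Transfrag construction and transcript-evidence model extension.

Transcribed segments are maximal runs of per-base coverage at or above a
depth floor (default 10 reads); same-strand segments joined by a splice
junction become one spliced transfrag.  Gene models are 5'/3' extended to
overlapping transfrags, with the ORF repositioned on the extended spliced
sequence, for two rounds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .core import (
    AnnotationError,
    CoverageTrack,
    ESTAlignment,
    GeneModel,
    GenomeSequence,
    SpliceJunction,
    set_structural_utr_flags,
)
from .intervals import Interval, UnionFind, overlaps

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class Transfrag:
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    spliced: bool
    support_junction_ids: tuple[tuple[int, int], ...] = ()

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass(frozen=True)
class ExpressionRecord:
    model_id: str
    fragment_count: int
    fpkm: float
    expressed: bool


def call_transcribed_segments(
    coverage: CoverageTrack, min_depth: int = 10
) -> list[Interval]:
    """Maximal runs of positions with depth >= ``min_depth``."""
    if min_depth < 1:
        raise AnnotationError("min_depth must be >= 1")
    covered = coverage.depth >= min_depth
    if not covered.any():
        return []
    padded = np.concatenate([[False], covered, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def link_segments(
    segments: Sequence[Interval],
    junctions: Iterable[SpliceJunction],
    strand: str,
    chrom: str,
) -> list[Transfrag]:
    """Merge segments into spliced transfrags wherever a same-strand
    junction's ends fall inside two segments (attachment tolerance 0)."""
    segments = sorted(segments)
    starts = np.array([s for s, _ in segments] or [0])
    uf = UnionFind(len(segments))
    support: dict[int, list[Interval]] = {}

    def containing_segment(pos: int) -> int | None:
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and segments[i][0] <= pos < segments[i][1]:
            return i
        return None

    for j in junctions:
        if j.chrom != chrom:
            raise AnnotationError(
                f"junction on {j.chrom} cannot link segments on {chrom}"
            )
        if j.strand != strand:
            continue
        js, je = j.intron_interval
        a = containing_segment(js - 1)  # last transcribed base before intron
        b = containing_segment(je)      # first transcribed base after intron
        if a is not None and b is not None and a != b:
            uf.union(a, b)
            support.setdefault(uf.find(a), []).append((js, je))

    out = []
    for root, members in sorted(uf.groups().items()):
        blocks = tuple(segments[i] for i in sorted(members))
        juncs = tuple(sorted(set(support.get(uf.find(root), []))))
        out.append(
            Transfrag(chrom, strand, blocks, spliced=len(blocks) > 1,
                      support_junction_ids=juncs)
        )
    return sorted(out, key=lambda t: t.span)


def build_transfrags(
    tracks: dict[tuple[str, str], CoverageTrack],
    junctions: Iterable[SpliceJunction],
    min_depth: int = 10,
) -> list[Transfrag]:
    """Call segments and link them per (chromosome, strand)."""
    junctions = list(junctions)
    out: list[Transfrag] = []
    for (chrom, strand), track in sorted(tracks.items()):
        segs = call_transcribed_segments(track, min_depth)
        juncs = [j for j in junctions if j.chrom == chrom and j.strand == strand]
        out.extend(link_segments(segs, juncs, strand, chrom))
    return out


def compute_fpkm(
    model: GeneModel,
    fragment_count: int,
    total_assigned_fragments: int,
    threshold: float = 2000.0,
) -> ExpressionRecord:
    """FPKM over the spliced (exonic) transcript length; a model is called
    expressed at FPKM >= ``threshold`` (default 2000)."""
    if total_assigned_fragments < 1:
        raise AnnotationError("total_assigned_fragments must be >= 1")
    length = model.transcript_length
    if length < 1:
        raise AnnotationError(f"model {model.model_id}: zero-length transcript")
    fpkm = fragment_count / (length / 1e3) / (total_assigned_fragments / 1e6)
    return ExpressionRecord(model.model_id, fragment_count, fpkm, fpkm >= threshold)


# ---------------------------------------------------------------------------
# ORF machinery
# ---------------------------------------------------------------------------

def find_orfs(seq: str) -> list[tuple[int, int]]:
    """All ATG->stop ORFs (stop codon included) in the three forward
    frames of a spliced transcript, as half-open transcript intervals."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if codon == "ATG":
                open_starts.append(i)
            elif codon in STOP_CODONS:
                orfs.extend((s, i + 3) for s in open_starts)
                open_starts.clear()
    return orfs


def _transcript_cds_interval(model: GeneModel) -> tuple[int, int]:
    """The model's CDS as a half-open interval in transcript coordinates."""
    pos = model.genomic_positions()
    inside = np.flatnonzero((pos >= model.cds[0]) & (pos < model.cds[1]))
    return int(inside[0]), int(inside[-1]) + 1


def reposition_orf(
    model: GeneModel, genome: dict[str, GenomeSequence]
) -> GeneModel:
    """Move the CDS to the longest ORF on the model strand that overlaps
    the original CDS (ties: most 5' start); UTR flags follow."""
    seq = model.spliced_sequence(genome)
    t_cs, t_ce = _transcript_cds_interval(model)
    best: tuple[int, int] | None = None
    for s, e in find_orfs(seq):
        if s < t_ce and t_cs < e:  # transcript-coordinate overlap with old CDS
            if best is None or (e - s, -s) > (best[1] - best[0], -best[0]):
                best = (s, e)
    if best is None:
        return model
    pos = model.genomic_positions()
    gpos = pos[best[0]:best[1]]
    new_cds = (int(gpos.min()), int(gpos.max()) + 1)
    model = replace(model, cds=new_cds)
    return set_structural_utr_flags(model)


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def extend_model(
    model: GeneModel,
    transfrags: Sequence[Transfrag],
    genome: dict[str, GenomeSequence],
    neighbors: Sequence[GeneModel] = (),
) -> GeneModel:
    """Extend terminal exons to overlapping same-strand transfrags (never
    trimming), truncating at a same-strand neighbor's CDS, then reposition
    the ORF on the extended transcript."""
    hits = [
        t for t in transfrags
        if t.chrom == model.chrom and t.strand == model.strand
        and overlaps(t.span, model.span)
    ]
    if not hits:
        return model
    new_start = min(model.start, *(t.span[0] for t in hits))
    new_end = max(model.end, *(t.span[1] for t in hits))
    for nb in neighbors:
        if (nb.model_id == model.model_id or nb.chrom != model.chrom
                or nb.strand != model.strand):
            continue
        if nb.cds[1] <= model.start and new_start < nb.cds[1]:
            logger.info(
                "extension of %s truncated at CDS of neighbor %s",
                model.model_id, nb.model_id,
            )
            new_start = nb.cds[1]
        if nb.cds[0] >= model.end and new_end > nb.cds[0]:
            logger.info(
                "extension of %s truncated at CDS of neighbor %s",
                model.model_id, nb.model_id,
            )
            new_end = nb.cds[0]
    exons = list(model.exons)
    exons[0] = (new_start, exons[0][1])
    exons[-1] = (exons[-1][0], new_end)
    extended = replace(model, exons=tuple(exons))
    return reposition_orf(extended, genome)


def extend_two_rounds(
    models: Sequence[GeneModel],
    transfrags: Sequence[Transfrag],
    genome: dict[str, GenomeSequence],
) -> list[GeneModel]:
    """Two rounds of extension + ORF repositioning; logs if a third round
    would still change anything (fixed point not reached)."""
    round1 = [extend_model(m, transfrags, genome, neighbors=models) for m in models]
    round2 = [extend_model(m, transfrags, genome, neighbors=round1) for m in round1]
    round3 = [extend_model(m, transfrags, genome, neighbors=round2) for m in round2]
    if round3 != round2:
        changed = [a.model_id for a, b in zip(round2, round3) if a != b]
        logger.warning("extension not at fixed point after 2 rounds: %s", changed)
    return round2


def annotate_utrs(
    models: Sequence[GeneModel],
    transfrags: Sequence[Transfrag] = (),
    ests: Sequence[ESTAlignment] = (),
    min_utr: int = 10,
) -> list[GeneModel]:
    """Set UTR flags where at least ``min_utr`` nt of exon sequence lies
    outside the CDS *and* is covered by a same-strand transfrag or EST
    (transcript-derived UTRs)."""
    out = []
    for m in models:
        left = (m.start, m.cds[0])
        right = (m.cds[1], m.end)

        def supported(region: Interval) -> bool:
            if region[1] - region[0] < min_utr:
                return False
            for t in transfrags:
                if t.chrom == m.chrom and t.strand == m.strand and overlaps(t.span, region):
                    return True
            for e in ests:
                if (e.chrom == m.chrom and e.inferred_strand == m.strand
                        and overlaps(e.span, region)):
                    return True
            return False

        left_ok, right_ok = supported(left), supported(right)
        if m.strand == "+":
            out.append(replace(m, utr5_present=left_ok, utr3_present=right_ok))
        else:
            out.append(replace(m, utr5_present=right_ok, utr3_present=left_ok))
    return out


def write_transfrags_bed12(transfrags: Sequence[Transfrag], path) -> None:
    lines = []
    for i, t in enumerate(
        sorted(transfrags, key=lambda t: (t.chrom, t.span, t.strand)), 1
    ):
        s, e = t.span
        sizes = ",".join(str(b[1] - b[0]) for b in t.blocks)
        offsets = ",".join(str(b[0] - s) for b in t.blocks)
        lines.append(
            f"{t.chrom}\t{s}\t{e}\ttf{i:05d}\t0\t{t.strand}\t{s}\t{e}\t0\t"
            f"{len(t.blocks)}\t{sizes}\t{offsets}"
        )
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
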