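"""Domain types and standard-format I/O for the annotation pipeline.

Holds the genome, gene-model, intron and evidence containers that every
other module consumes, together with readers/writers for FASTA, GFF3,
BED12 EST alignments, bedGraph-style coverage, and the junction/peptide
TSV formats.

Conventions
-----------
* Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
  closed; BED is 0-based half-open.
* Splice donor/acceptor dinucleotides are always reported on the
  transcribed strand (reverse-complemented for minus-strand features).
* Non-ACGTN genome characters are coerced to N with a logged warning.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import Interval, intersect_len

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for invalid annotation inputs (bad models, malformed files)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/scaffold of an assembly, uppercase ACGTN."""

    chrom_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A stranded, exon-structured transcript with a CDS.

    ``exons`` are sorted, pairwise disjoint 0-based half-open genomic
    intervals on one chromosome.  ``cds`` is the genomic interval from the
    first to the last coding base (it may span introns); its spliced length
    must be a multiple of 3.
    """

    model_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Interval
    utr5_present: bool = False
    utr3_present: bool = False
    source: str = "allgenes"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        """Spliced (intron-free) transcript length."""
        return sum(e - s for s, e in self.exons)

    @property
    def cds_spliced_length(self) -> int:
        return sum(intersect_len(ex, self.cds) for ex in self.exons)

    def intron_intervals(self) -> list[Interval]:
        """Genomic intron intervals in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def validate(self, genome: dict[str, GenomeSequence] | None = None) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"model {self.model_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"model {self.model_id}: no exons")
        for i, (s, e) in enumerate(self.exons):
            if e <= s:
                raise AnnotationError(f"model {self.model_id}: empty exon {s}-{e}")
            if i and s < self.exons[i - 1][1]:
                raise AnnotationError(
                    f"model {self.model_id}: exons overlap or are unsorted"
                )
        cs, ce = self.cds
        if not (self.start <= cs < ce <= self.end):
            raise AnnotationError(f"model {self.model_id}: CDS outside exon span")
        if not any(s <= cs < e for s, e in self.exons) or not any(
            s < ce <= e for s, e in self.exons
        ):
            raise AnnotationError(f"model {self.model_id}: CDS ends not in exons")
        if self.cds_spliced_length % 3 != 0:
            raise AnnotationError(
                f"model {self.model_id}: CDS spliced length "
                f"{self.cds_spliced_length} not a multiple of 3"
            )
        if genome is not None:
            if self.chrom not in genome:
                raise AnnotationError(f"model {self.model_id}: unknown chrom {self.chrom}")
            if self.end > genome[self.chrom].length:
                raise AnnotationError(
                    f"model {self.model_id}: exon beyond end of {self.chrom}"
                )

    # -- transcript <-> genome coordinate maps ------------------------------

    def genomic_positions(self) -> np.ndarray:
        """Genomic positions of transcript bases, in transcript (5'->3') order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        return pos[::-1] if self.strand == "-" else pos

    def spliced_sequence(self, genome: dict[str, GenomeSequence]) -> str:
        chrom = genome[self.chrom].sequence
        seq = "".join(chrom[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class Intron:
    chrom: str
    interval: Interval
    strand: str
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    parent_model_id: str | None = None

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class SpliceJunction:
    chrom: str
    intron_interval: Interval
    strand: str
    read_support: int

    def __post_init__(self):
        if self.read_support < 1:
            raise AnnotationError("junction read_support must be >= 1")


@dataclass(frozen=True)
class PeptidePlacement:
    peptide_seq: str
    model_id: str
    n_genomic_locations: int

    def __post_init__(self):
        if self.n_genomic_locations < 1:
            raise AnnotationError("peptide n_genomic_locations must be >= 1")
        if len(self.peptide_seq) < 6:
            raise AnnotationError("peptides shorter than 6 aa are not accepted")


@dataclass(frozen=True)
class ESTAlignment:
    """A BLAT-style spliced EST alignment; mate labels pair directional
    cDNA clone reads (``est_id`` is ``<clone>/f`` or ``<clone>/r``)."""

    est_id: str
    mate: str  # forward | reverse | unpaired
    chrom: str
    blocks: tuple[Interval, ...]
    inferred_strand: str = "."  # + | - | . (undetermined)

    @property
    def clone_id(self) -> str:
        return self.est_id.rsplit("/", 1)[0]

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    def gap_intervals(self) -> list[Interval]:
        return [
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


@dataclass
class CoverageTrack:
    chrom: str
    strand: str
    depth: np.ndarray  # per-base read depth, length == chromosome length


# ---------------------------------------------------------------------------
# genome I/O
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a FASTA assembly; non-ACGTN characters become N (warned)."""
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise AnnotationError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            logger.warning(
                "%s: %d non-ACGTN characters in %s coerced to N", path, n_bad, rec.id
            )
            seq = _NON_ACGTN.sub("N", seq)
        out[rec.id] = GenomeSequence(rec.id, seq)
    if not out:
        raise AnnotationError(f"no FASTA records in {path}")
    return out


def write_genome(genome: dict[str, GenomeSequence], path: str | Path,
                 width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom_id in sorted(genome):
            fh.write(f">{chrom_id}\n")
            seq = genome[chrom_id].sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def read_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features).

    Models failing the structural invariants raise :class:`AnnotationError`
    naming the offending model.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    seen: set[str] = set()
    for mrna in db.features_of_type("mRNA"):
        if mrna.strand not in "+-":
            raise AnnotationError(f"model {mrna.id}: missing strand in GFF3")
        if mrna.id in seen:
            raise AnnotationError(f"duplicate model id {mrna.id!r}")
        seen.add(mrna.id)
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_parts = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds_parts:
            raise AnnotationError(f"model {mrna.id}: needs exon and CDS features")
        cds = (cds_parts[0][0], cds_parts[-1][1])
        model = GeneModel(
            model_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=tuple(exons),
            cds=cds,
            source=mrna.source or "allgenes",
        )
        model = set_structural_utr_flags(model)
        model.validate()
        models.append(model)
    return models


def set_structural_utr_flags(model: GeneModel) -> GeneModel:
    """Set UTR flags from exon extent beyond the CDS on each side."""
    left = model.start < model.cds[0]
    right = model.cds[1] < model.end
    if model.strand == "+":
        return replace(model, utr5_present=left, utr3_present=right)
    return replace(model, utr5_present=right, utr3_present=left)


def write_models_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.chrom, m.start, m.model_id)):
        gid = f"gene:{m.model_id}"
        attr = f"ID={gid}"
        lines.append(
            f"{m.chrom}\t{m.source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attr}"
        )
        lines.append(
            f"{m.chrom}\t{m.source}\tmRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
            f"ID={m.model_id};Parent={gid}"
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                f"{m.chrom}\t{m.source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.model_id}.exon{i};Parent={m.model_id}"
            )
        cds_parts = [
            (max(s, m.cds[0]), min(e, m.cds[1]))
            for s, e in m.exons
            if intersect_len((s, e), m.cds) > 0
        ]
        # phase: bases carried over from the previous CDS segment, in
        # transcript orientation
        ordered = cds_parts if m.strand == "+" else cds_parts[::-1]
        phases: dict[Interval, int] = {}
        carried = 0
        for s, e in ordered:
            phases[(s, e)] = (3 - carried % 3) % 3
            carried += e - s
        for i, (s, e) in enumerate(cds_parts, 1):
            lines.append(
                f"{m.chrom}\t{m.source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                f"{phases[(s, e)]}\tID={m.model_id}.cds{i};Parent={m.model_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# introns & splice donors
# ---------------------------------------------------------------------------

def extract_introns(
    model: GeneModel, genome: dict[str, GenomeSequence]
) -> list[Intron]:
    """Introns of a model in transcript (5'->3') order, with transcribed-
    strand donor/acceptor dinucleotides."""
    model.validate(genome)
    chrom = genome[model.chrom].sequence
    introns = []
    for s, e in model.intron_intervals():
        left = chrom[s:s + 2]
        right = chrom[e - 2:e]
        if model.strand == "+":
            donor, acceptor = left, right
        else:
            donor, acceptor = revcomp(right), revcomp(left)
        introns.append(
            Intron(model.chrom, (s, e), model.strand, donor, acceptor,
                   parent_model_id=model.model_id)
        )
    return introns[::-1] if model.strand == "-" else introns


def classify_donor(intron: Intron | str) -> str:
    """Donor class {GT, GC, AT, other} from the transcribed-strand 2-mer."""
    donor = intron if isinstance(intron, str) else intron.donor_dinucleotide
    return donor if donor in ("GT", "GC", "AT") else "other"


def intron_sequence(intron: Intron, genome: dict[str, GenomeSequence]) -> str:
    """Reading-strand (transcribed-strand) sequence of an intron."""
    s, e = intron.interval
    seq = genome[intron.chrom].sequence[s:e]
    return revcomp(seq) if intron.strand == "-" else seq


# ---------------------------------------------------------------------------
# EST orientation
# ---------------------------------------------------------------------------

def _gap_compatible_strands(left2: str, right2: str) -> set[str]:
    """Which transcribed strands a splice gap is consistent with, by the
    G[TC]/AG and AT/AN donor/acceptor rule."""
    ok = set()
    if (left2 in ("GT", "GC") and right2 == "AG") or (
        left2 == "AT" and right2[:1] == "A"
    ):
        ok.add("+")
    rc_donor, rc_acceptor = revcomp(right2), revcomp(left2)
    if (rc_donor in ("GT", "GC") and rc_acceptor == "AG") or (
        rc_donor == "AT" and rc_acceptor[:1] == "A"
    ):
        ok.add("-")
    return ok


def orient_est(
    est: ESTAlignment, genome: dict[str, GenomeSequence]
) -> str:
    """Infer the transcribed strand of a multi-exon EST from its splice
    gaps; returns '+', '-' or '.' (undetermined; caller discards)."""
    if len(est.blocks) < 2:
        return "."
    chrom = genome[est.chrom].sequence
    candidates = {"+", "-"}
    for gs, ge in est.gap_intervals():
        candidates &= _gap_compatible_strands(chrom[gs:gs + 2], chrom[ge - 2:ge])
        if not candidates:
            return "."
    if len(candidates) == 1:
        return candidates.pop()
    return "."


def oriented_est_introns(
    ests: Iterable[ESTAlignment], genome: dict[str, GenomeSequence]
) -> tuple[list[ESTAlignment], list[Intron]]:
    """Orient multi-exon ESTs and return (oriented ESTs, their introns).

    ESTs whose strand cannot be determined are discarded from the intron
    harvest; single-exon ESTs pass through with their supplied strand.
    """
    kept: list[ESTAlignment] = []
    introns: list[Intron] = []
    chromseqs = genome
    for est in ests:
        if len(est.blocks) < 2:
            kept.append(est)
            continue
        strand = orient_est(est, chromseqs)
        if strand == ".":
            continue
        est = replace(est, inferred_strand=strand)
        kept.append(est)
        chrom = genome[est.chrom].sequence
        for gs, ge in est.gap_intervals():
            left, right = chrom[gs:gs + 2], chrom[ge - 2:ge]
            if strand == "+":
                donor, acceptor = left, right
            else:
                donor, acceptor = revcomp(right), revcomp(left)
            introns.append(Intron(est.chrom, (gs, ge), strand, donor, acceptor))
    return kept, introns


# ---------------------------------------------------------------------------
# evidence-track I/O (TSV / bedGraph / BED12)
# ---------------------------------------------------------------------------

_JUNC_COLS = ["chrom", "start", "end", "strand", "reads"]


def read_junctions(path: str | Path) -> list[SpliceJunction]:
    df = pd.read_csv(path, sep="\t", names=_JUNC_COLS, comment="#")
    return [
        SpliceJunction(r.chrom, (int(r.start), int(r.end)), r.strand, int(r.reads))
        for r in df.itertuples()
    ]


def write_junctions(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    rows = sorted(
        (j.chrom, j.intron_interval[0], j.intron_interval[1], j.strand, j.read_support)
        for j in junctions
    )
    pd.DataFrame(rows, columns=_JUNC_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_peptides(path: str | Path) -> list[PeptidePlacement]:
    df = pd.read_csv(
        path, sep="\t", names=["peptide", "model_id", "n_locations"], comment="#"
    )
    return [
        PeptidePlacement(r.peptide, str(r.model_id), int(r.n_locations))
        for r in df.itertuples()
    ]


def write_peptides(placements: Iterable[PeptidePlacement], path: str | Path) -> None:
    rows = sorted(
        (p.peptide_seq, p.model_id, p.n_genomic_locations) for p in placements
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_coverage(
    path: str | Path, genome: dict[str, GenomeSequence], strand: str
) -> dict[str, CoverageTrack]:
    """Read a bedGraph-like per-base coverage file for one strand."""
    tracks = {
        c: CoverageTrack(c, strand, np.zeros(g.length, dtype=np.int64))
        for c, g in genome.items()
    }
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "depth"], comment="#"
    )
    for r in df.itertuples():
        tracks[r.chrom].depth[int(r.start):int(r.end)] += int(r.depth)
    return tracks


def write_coverage(tracks: dict[str, CoverageTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            depth = tracks[chrom].depth
            if len(depth) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(depth)]])
            for s, e in zip(starts, ends):
                d = depth[s]
                if d:
                    fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


_MATE_SUFFIX = {"f": "forward", "r": "reverse"}
_MATE_CODE = {"forward": "f", "reverse": "r", "unpaired": "u"}


def read_ests_bed12(path: str | Path) -> list[ESTAlignment]:
    """Read EST alignments from BED12; mate pairing is encoded in the name
    (``clone/f``, ``clone/r``; anything else is unpaired)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
            )
            suffix = name.rsplit("/", 1)[-1] if "/" in name else ""
            mate = _MATE_SUFFIX.get(suffix, "unpaired")
            out.append(
                ESTAlignment(name, mate, chrom, blocks,
                             strand if strand in "+-" else ".")
            )
    return out


def write_ests_bed12(ests: Iterable[ESTAlignment], path: str | Path) -> None:
    lines = []
    for est in sorted(ests, key=lambda e: (e.chrom, e.span[0], e.est_id)):
        s, e = est.span
        sizes = ",".join(str(b[1] - b[0]) for b in est.blocks)
        offsets = ",".join(str(b[0] - s) for b in est.blocks)
        strand = est.inferred_strand if est.inferred_strand in "+-" else "."
        lines.append(
            f"{est.chrom}\t{s}\t{e}\t{est.est_id}\t0\t{strand}\t{s}\t{e}\t0\t"
            f"{len(est.blocks)}\t{sizes}\t{offsets}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
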