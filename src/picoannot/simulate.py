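"""Synthetic genomes, annotations, Introner Element families and evidence
tracks with known ground truth.

The generator emulates a gene-dense picoeukaryote genome: short
intergenic spans, compact multi-exon genes (mean intron ~180 nt, ~3
exons per spliced gene), GC-rich background (66%) with an optional
low-GC block, repetitive intron families built from ordered motifs with
0-49 nt gaps and a configurable GC-donor fraction, and per-gene evidence
(splice junctions, stranded coverage, peptides, paired directional EST
clones).  Everything is driven by one seeded generator: identical config
and seed give byte-identical outputs.

The motif consensus strings below are synthetic stand-ins with the
length and ordered-group structure of real Introner Element families;
they are not genomic sequences.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    AnnotationError,
    CoverageTrack,
    ESTAlignment,
    GeneModel,
    GenomeSequence,
    PeptidePlacement,
    SpliceJunction,
    revcomp,
    set_structural_utr_flags,
    write_ests_bed12,
    write_genome,
    write_junctions,
    write_models_gff3,
    write_peptides,
    write_coverage,
)
from .intervals import Interval
from .motifs import PWM, write_meme_minimal

_DEC = bytes.maketrans(bytes([0, 1, 2, 3, 4]), b"ACGTN")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# synthetic motif consensus strings (ordered family structure only)
D_IE1_MOTIFS = (
    "CAGGTCACGTTCGAATGGCCTAGTCG",
    "TTCGACGGCATAAGCCGTTCAGGACA",
    "GCTTAGCAGTCCATGACGGTAACTGC",
    "ACGTTCAGCCTTGAGCGATACCGGTA",
)
D_IE2_MOTIFS = (
    "TGCAGTTCGGATCACGAGTTCCAGGT",
    "CATCGGTTAGCACGTGAGACTTGCAC",
    "GTAGCCTTACGAGCGATTCAGACGGT",
)
ABC_IE_MOTIFS = (
    "CTGAAGCGTTACCGGATCAGCTTGACGTAGCATCCGATTGGCAACGTCTG",
)


@dataclass(frozen=True)
class IEFamilySpec:
    family_id: str
    motifs: tuple[str, ...]
    mutation_rate: float = 0.02
    min_gap: int = 0
    max_gap: int = 49
    gc_donor_fraction: float = 0.46


DEFAULT_D_IE1 = IEFamilySpec("D-IE1", D_IE1_MOTIFS, gc_donor_fraction=0.46)
DEFAULT_D_IE2 = IEFamilySpec("D-IE2", D_IE2_MOTIFS, gc_donor_fraction=0.07)
DEFAULT_ABC_IE = IEFamilySpec("ABC-IE", ABC_IE_MOTIFS, gc_donor_fraction=0.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset; the seed is mandatory
    and every random draw flows from it."""

    seed: int
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    gc_content: float = 0.66
    lgc_block: tuple[int, int, int, float] | None = None  # chrom idx, start, end, GC
    n_genes: int = 200
    p_spliced: float = 0.57
    multiexon_extra_mean: float = 1.0   # exons = 2 + Poisson(mean)
    mean_intron_length: float = 180.0
    sd_intron_length: float = 40.0
    min_intron_length: int = 62
    cds_codons_range: tuple[int, int] = (300, 800)
    utr5_range: tuple[int, int] = (40, 150)
    utr3_range: tuple[int, int] = (80, 250)
    mean_intergenic: float = 230.0
    min_intergenic: int = 40
    rsi_gc_donor_fraction: float = 0.097
    p_cop: float = 0.0                  # convergent overlapping pair rate
    cop_overlap_range: tuple[int, int] = (40, 120)
    # evidence
    p_junction_confirm: float = 1.0
    junction_reads_range: tuple[int, int] = (11, 61)
    exon_depth: int = 25
    peptides_per_model_mean: float = 4.0
    peptide_len_range: tuple[int, int] = (8, 21)
    p_peptide_multimap: float = 0.1
    multimap_range: tuple[int, int] = (2, 6)
    p_est_clone: float = 1.0
    est_mate_span: int = 400
    # decoys
    p_split: float = 0.5
    p_merge: float = 0.2
    p_truncate: float = 0.5
    p_frameshift: float = 0.3

    def __post_init__(self):
        for name in ("p_spliced", "rsi_gc_donor_fraction", "p_junction_confirm",
                     "p_peptide_multimap", "p_est_clone", "p_split", "p_merge",
                     "p_truncate", "p_frameshift", "p_cop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PlantedIE:
    family: str
    chrom: str
    interval: Interval
    strand: str
    completeness: str
    motifs_present: tuple[str, ...]
    location_class: str
    donor_type: str
    intron_interval: Interval | None = None
    parent_model_id: str | None = None


@dataclass
class TruthTable:
    config: SimulationConfig
    genome_arrays: dict[str, np.ndarray]
    models: list[GeneModel]
    planted_ies: list[PlantedIE] = field(default_factory=list)
    pool: list[GeneModel] = field(default_factory=list)
    pool_ledger: dict[str, tuple[str, str]] = field(default_factory=dict)
    _ie_used_introns: set = field(default_factory=set)

    def genome(self) -> dict[str, GenomeSequence]:
        return {
            c: GenomeSequence(c, arr.tobytes().translate(_DEC).decode())
            for c, arr in self.genome_arrays.items()
        }


@dataclass
class EvidencePack:
    junctions: list[SpliceJunction]
    coverage: dict[tuple[str, str], CoverageTrack]
    peptides: list[PeptidePlacement]
    ests: list[ESTAlignment]


# ---------------------------------------------------------------------------
# genome + gene synthesis
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return _random_bases(rng, n, gc).tobytes().translate(_DEC).decode()


def _utr_without_atg(rng, n: int, gc: float) -> str:
    seq = _random_seq(rng, n, gc)
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[:i] + "C" + seq[i + 1:]
    return seq


_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng, n_codons: int, gc: float) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


@dataclass
class _GenePlan:
    """A gene laid out in local (pre-mRNA, plus-orientation) coordinates."""

    length: int
    sequence: str
    exons: list[Interval]
    cds: Interval


def _plan_gene(rng, cfg: SimulationConfig, force_strand: str | None = None
               ) -> tuple[_GenePlan, str]:
    strand = force_strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = 1
    if rng.random() < cfg.p_spliced:
        n_exons = 2 + int(rng.poisson(cfg.multiexon_extra_mean))
    utr5 = _utr_without_atg(rng, int(rng.integers(*cfg.utr5_range)), cfg.gc_content)
    cds = _random_cds(rng, int(rng.integers(*cfg.cds_codons_range)), cfg.gc_content)
    utr3 = _random_seq(rng, int(rng.integers(*cfg.utr3_range)), cfg.gc_content)
    transcript = utr5 + cds + utr3
    t_cs, t_ce = len(utr5), len(utr5) + len(cds)

    # intron insertion points inside the CDS (UTR introns are not modeled)
    cuts: list[int] = []
    lo, hi = t_cs + 12, t_ce - 12
    for _ in range(200):
        cand = sorted(int(rng.integers(lo, hi)) for _ in range(n_exons - 1))
        if all(b - a >= 25 for a, b in zip(cand, cand[1:])):
            cuts = cand
            break
    n_exons = len(cuts) + 1

    pieces, exons, pos, prev = [], [], 0, 0
    for cut in cuts + [len(transcript)]:
        exon_seq = transcript[prev:cut]
        pieces.append(exon_seq)
        exons.append((pos, pos + len(exon_seq)))
        pos += len(exon_seq)
        if cut != len(transcript):
            ilen = max(cfg.min_intron_length,
                       int(round(rng.normal(cfg.mean_intron_length,
                                            cfg.sd_intron_length))))
            donor = "GC" if rng.random() < cfg.rsi_gc_donor_fraction else "GT"
            intron = donor + _random_seq(rng, ilen - 4, cfg.gc_content) + "AG"
            pieces.append(intron)
            pos += ilen
        prev = cut

    seq = "".join(pieces)

    # local genomic position of a transcript coordinate
    def to_local(t: int) -> int:
        acc = 0
        for es, ee in exons:
            if t < acc + (ee - es):
                return es + (t - acc)
            acc += ee - es
        raise AssertionError

    cds_local = (to_local(t_cs), to_local(t_ce - 1) + 1)
    plan = _GenePlan(len(seq), seq, exons, cds_local)
    if strand == "-":
        G = plan.length
        plan = _GenePlan(
            G,
            revcomp(plan.sequence),
            sorted((G - e, G - s) for s, e in plan.exons),
            (G - plan.cds[1], G - plan.cds[0]),
        )
    return plan, strand


def simulate_genome(cfg: SimulationConfig) -> TruthTable:
    """Background genome with placed true genes; raises with a capacity
    report when the requested genes cannot be placed."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = cfg.genome_length // cfg.n_chromosomes
    arrays = {
        f"chr{i + 1}": _random_bases(rng, per_chrom, cfg.gc_content)
        for i in range(cfg.n_chromosomes)
    }
    if cfg.lgc_block is not None:
        ci, s, e, gc = cfg.lgc_block
        chrom = f"chr{ci + 1}"
        arrays[chrom][s:e] = _random_bases(rng, e - s, gc)

    models: list[GeneModel] = []
    chrom_ids = sorted(arrays)
    cursor = {c: 500 for c in chrom_ids}
    gi = 0
    while gi < cfg.n_genes:
        make_cop = cfg.p_cop > 0 and rng.random() < cfg.p_cop and gi + 1 < cfg.n_genes
        if make_cop:
            plan_a, _ = _plan_gene(rng, cfg, force_strand="+")
            plan_b, _ = _plan_gene(rng, cfg, force_strand="-")
            ov_hi = min(cfg.cop_overlap_range[1],
                        plan_a.length - plan_a.cds[1] - 5,
                        plan_b.cds[0] - 5)
            if ov_hi <= cfg.cop_overlap_range[0]:
                make_cop = False
            else:
                ov = int(rng.integers(cfg.cop_overlap_range[0], ov_hi))
                need = plan_a.length + plan_b.length - ov
                chrom = _chrom_with_room(arrays, cursor, need)
                start = cursor[chrom]
                _stamp(arrays[chrom], start, plan_a.sequence)
                b_start = start + plan_a.length - ov
                _stamp(arrays[chrom], b_start, plan_b.sequence)
                models.append(_to_model(f"g{gi:04d}", chrom, "+", plan_a, start))
                models.append(_to_model(f"g{gi + 1:04d}", chrom, "-", plan_b, b_start))
                gi += 2
                gap = cfg.min_intergenic + int(rng.exponential(
                    max(cfg.mean_intergenic - cfg.min_intergenic, 1)))
                cursor[chrom] = b_start + plan_b.length + gap
                continue
        plan, strand = _plan_gene(rng, cfg)
        chrom = _chrom_with_room(arrays, cursor, plan.length)
        start = cursor[chrom]
        _stamp(arrays[chrom], start, plan.sequence)
        models.append(_to_model(f"g{gi:04d}", chrom, strand, plan, start))
        gi += 1
        gap = cfg.min_intergenic + int(rng.exponential(
            max(cfg.mean_intergenic - cfg.min_intergenic, 1)))
        cursor[chrom] += plan.length + gap
    truth = TruthTable(cfg, arrays, models)
    genome = truth.genome()
    for m in models:
        m.validate(genome)
    return truth


def _chrom_with_room(arrays, cursor, need: int) -> str:
    options = [
        c for c in sorted(arrays)
        if cursor[c] + need + 500 <= len(arrays[c])
    ]
    if not options:
        placed = {c: cursor[c] for c in sorted(arrays)}
        raise AnnotationError(
            f"genome capacity exhausted placing a {need}-bp gene; "
            f"cursors={placed}, lengths="
            f"{ {c: len(a) for c, a in arrays.items()} }"
        )
    return min(options, key=lambda c: cursor[c])


def _stamp(arr: np.ndarray, start: int, seq: str) -> None:
    codes = np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.uint8,
    )
    arr[start:start + len(codes)] = codes


def _to_model(model_id: str, chrom: str, strand: str, plan: _GenePlan,
              offset: int) -> GeneModel:
    model = GeneModel(
        model_id=model_id,
        chrom=chrom,
        strand=strand,
        exons=tuple((s + offset, e + offset) for s, e in plan.exons),
        cds=(plan.cds[0] + offset, plan.cds[1] + offset),
        source="synthetic-truth",
    )
    return set_structural_utr_flags(model)


# ---------------------------------------------------------------------------
# IE planting
# ---------------------------------------------------------------------------

def _reading(arr: np.ndarray, iv: Interval, strand: str) -> str:
    seq = arr[iv[0]:iv[1]].tobytes().translate(_DEC).decode()
    return revcomp(seq) if strand == "-" else seq


def _write_reading(arr: np.ndarray, iv: Interval, strand: str, seq: str) -> None:
    _stamp(arr, iv[0], revcomp(seq) if strand == "-" else seq)


def _mutate(rng, motif: str, rate: float) -> str:
    out = list(motif)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = "ACGT"[(_BASE_INDEX[b] + 1 + rng.integers(3)) % 4]
    return "".join(out)


def plant_ie_family(
    truth: TruthTable,
    spec: IEFamilySpec,
    n_complete: int,
    n_partial: int = 0,
    n_intergenic: int = 0,
) -> TruthTable:
    """Write mutated, gap-separated motif instances into eligible introns
    (and optionally intergenic space), recording every planted element.

    Complete elements carry all family motifs in canonical order; partial
    ones a proper ordered subset.  Donors of IE-bearing introns are set
    to GC at the family's configured fraction.  An intron too short for a
    draw is skipped for a longer one; placement fails loudly when no
    intron fits.
    """
    import zlib

    rng = np.random.default_rng(
        (truth.config.seed * 1_000_003
         + zlib.crc32(spec.family_id.encode()) % 65_536) % (2**31)
    )
    candidates = []
    for m in truth.models:
        for iv in m.intron_intervals():
            key = (m.chrom, iv)
            if key not in truth._ie_used_introns:
                candidates.append((m, iv))
    order = rng.permutation(len(candidates))

    jobs = (["complete"] * n_complete) + (["partial"] * n_partial)
    ptr = 0
    for job in jobs:
        if job == "complete":
            motifs = list(spec.motifs)
        else:
            k = int(rng.integers(1, len(spec.motifs))) if len(spec.motifs) > 1 else 1
            if rng.random() < 0.5:
                motifs = list(spec.motifs[:k])
            else:
                picks = sorted(rng.choice(len(spec.motifs), size=k, replace=False))
                motifs = [spec.motifs[i] for i in picks]
        need = sum(len(mm) for mm in motifs) + 6
        placed = False
        while ptr < len(order):
            m, iv = candidates[order[ptr]]
            ptr += 1
            if iv[1] - iv[0] < need:
                continue  # draw a longer intron
            _plant_in_intron(truth, rng, spec, m, iv, motifs)
            placed = True
            break
        if not placed:
            raise AnnotationError(
                f"no intron long enough ({need} nt) remains for {spec.family_id}"
            )

    for _ in range(n_intergenic):
        motifs = list(spec.motifs)
        _plant_intergenic(truth, rng, spec, motifs)
    return truth


def _layout_element(rng, spec: IEFamilySpec, motifs: list[str],
                    room: int) -> tuple[int, list[tuple[int, str]]]:
    """Choose gaps and offset; returns (element length, [(offset, motif)])."""
    budget = room - sum(len(m) for m in motifs)
    placements = []
    off = 0
    for i, m in enumerate(motifs):
        if i > 0:
            gap_hi = min(spec.max_gap, budget)
            gap = int(rng.integers(spec.min_gap, gap_hi + 1)) if gap_hi > 0 else 0
            budget -= gap
            off += gap
        placements.append((off, m))
        off += len(m)
    return off, placements


def _plant_in_intron(truth, rng, spec, model, iv, motifs) -> None:
    arr = truth.genome_arrays[model.chrom]
    ilen = iv[1] - iv[0]
    reading = list(_reading(arr, iv, model.strand))
    elem_len, placements = _layout_element(rng, spec, motifs, ilen - 6)
    slack = ilen - 4 - elem_len
    anchor = 2 + int(rng.integers(0, max(slack - 2, 0) + 1))
    for off, motif in placements:
        inst = _mutate(rng, motif, spec.mutation_rate)
        reading[anchor + off:anchor + off + len(motif)] = inst
    donor = "GC" if rng.random() < spec.gc_donor_fraction else "GT"
    reading[0], reading[1] = donor[0], donor[1]
    reading[-2], reading[-1] = "A", "G"
    _write_reading(arr, iv, model.strand, "".join(reading))
    if model.strand == "+":
        interval = (iv[0] + anchor, iv[0] + anchor + elem_len)
    else:
        interval = (iv[1] - anchor - elem_len, iv[1] - anchor)
    truth._ie_used_introns.add((model.chrom, iv))
    truth.planted_ies.append(
        PlantedIE(
            family=spec.family_id,
            chrom=model.chrom,
            interval=interval,
            strand=model.strand,
            completeness=(
                "complete" if list(motifs) == list(spec.motifs) else "partial"
            ),
            motifs_present=tuple(motifs),
            location_class="intronic_same_strand",
            donor_type=donor,
            intron_interval=iv,
            parent_model_id=model.model_id,
        )
    )


def _plant_intergenic(truth, rng, spec, motifs) -> None:
    elem_len_max = sum(len(m) for m in motifs) + spec.max_gap * (len(motifs) - 1)
    spans = []
    for chrom in sorted(truth.genome_arrays):
        L = len(truth.genome_arrays[chrom])
        occupied = sorted(
            m.span for m in truth.models if m.chrom == chrom
        )
        prev = 0
        for s, e in occupied + [(L, L)]:
            if s - prev >= elem_len_max + 20:
                spans.append((chrom, prev, s))
            prev = max(prev, e)
    if not spans:
        raise AnnotationError("no intergenic room for an element")
    chrom, lo, hi = spans[int(rng.integers(len(spans)))]
    strand = "+" if rng.random() < 0.5 else "-"
    elem_len, placements = _layout_element(
        rng, spec, motifs, hi - lo - 20
    )
    start = lo + 10 + int(rng.integers(0, hi - lo - 20 - elem_len + 1))
    arr = truth.genome_arrays[chrom]
    reading = list(_reading(arr, (start, start + elem_len), strand))
    for off, motif in placements:
        reading[off:off + len(motif)] = _mutate(rng, motif, spec.mutation_rate)
    _write_reading(arr, (start, start + elem_len), strand, "".join(reading))
    truth.planted_ies.append(
        PlantedIE(
            family=spec.family_id,
            chrom=chrom,
            interval=(start, start + elem_len),
            strand=strand,
            completeness=(
                "complete" if list(motifs) == list(spec.motifs) else "partial"
            ),
            motifs_present=tuple(motifs),
            location_class="intergenic",
            donor_type="n/a",
        )
    )


def family_pwms(specs: Sequence[IEFamilySpec],
                background: np.ndarray | None = None) -> list[PWM]:
    """Scanning PWMs from the family consensus strings (match probability
    matching the per-base planting fidelity)."""
    out = []
    for spec in specs:
        for i, motif in enumerate(spec.motifs, 1):
            out.append(
                PWM.from_consensus(
                    motif, f"{spec.family_id}.m{i}",
                    match_p=1 - 3 * spec.mutation_rate / 2,
                    background=background,
                )
            )
    return out


def family_groups(specs: Sequence[IEFamilySpec]):
    from .introner import MotifGroup

    return [
        MotifGroup(
            s.family_id,
            tuple(f"{s.family_id}.m{i}" for i in range(1, len(s.motifs) + 1)),
            s.min_gap, s.max_gap,
        )
        for s in specs
    ]


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------

def _transcript_blocks(model: GeneModel, t0: int, t1: int) -> tuple[Interval, ...]:
    pos = np.sort(model.genomic_positions()[t0:t1])
    breaks = np.flatnonzero(np.diff(pos) > 1) + 1
    blocks = []
    for chunk in np.split(pos, breaks):
        blocks.append((int(chunk[0]), int(chunk[-1]) + 1))
    return tuple(blocks)


def simulate_evidence(truth: TruthTable, cfg: SimulationConfig | None = None
                      ) -> EvidencePack:
    """Evidence tracks from the truth models: one junction per confirmed
    intron, exon coverage above the transcription floor, tryptic-like
    peptides placed against the candidate pool with frame checking, and
    paired directional EST clones spanning each transcript's ends."""
    cfg = cfg or truth.config
    rng = np.random.default_rng((cfg.seed * 2_000_003 + 17) % (2**31))
    genome = truth.genome()

    junctions = []
    for m in truth.models:
        for iv in m.intron_intervals():
            if rng.random() < cfg.p_junction_confirm:
                junctions.append(
                    SpliceJunction(m.chrom, iv, m.strand,
                                   int(rng.integers(*cfg.junction_reads_range)))
                )

    coverage = {
        (c, strand): CoverageTrack(c, strand,
                                   np.zeros(genome[c].length, dtype=np.int64))
        for c in genome for strand in "+-"
    }
    for m in truth.models:
        track = coverage[(m.chrom, m.strand)].depth
        for s, e in m.exons:
            track[s:e] += cfg.exon_depth

    pool = truth.pool or truth.models
    index = {m.model_id: _cds_position_index(m) for m in pool}
    pool_by_chrom: dict[str, list[GeneModel]] = {}
    for m in pool:
        pool_by_chrom.setdefault(m.chrom, []).append(m)
    peptides: list[PeptidePlacement] = []
    for m in truth.models:
        seq = m.spliced_sequence(genome)
        t_cs = _transcript_cds_start(m)
        n_codons = m.cds_spliced_length // 3
        n_pep = int(rng.poisson(cfg.peptides_per_model_mean))
        for _ in range(n_pep):
            plen = int(rng.integers(*cfg.peptide_len_range))
            if n_codons - 1 - plen <= 1:
                continue
            c0 = int(rng.integers(1, n_codons - 1 - plen))
            nt = seq[t_cs + 3 * c0: t_cs + 3 * (c0 + plen)]
            aa = _translate(nt)
            gpos = m.genomic_positions()[t_cs + 3 * c0: t_cs + 3 * (c0 + plen)]
            n_loc = 1
            if rng.random() < cfg.p_peptide_multimap:
                n_loc = int(rng.integers(*cfg.multimap_range))
            g_lo, g_hi = int(gpos.min()), int(gpos.max()) + 1
            for target in pool_by_chrom.get(m.chrom, ()):
                if target.end <= g_lo or target.start >= g_hi:
                    continue
                if _placement_ok(gpos, index[target.model_id]):
                    peptides.append(PeptidePlacement(aa, target.model_id, n_loc))

    ests: list[ESTAlignment] = []
    for ci, m in enumerate(truth.models):
        if rng.random() >= cfg.p_est_clone:
            continue
        L = m.transcript_length
        span = min(cfg.est_mate_span, L)
        clone = f"cl{ci:05d}"
        ests.append(
            ESTAlignment(f"{clone}/f", "forward", m.chrom,
                         _transcript_blocks(m, 0, span), m.strand)
        )
        ests.append(
            ESTAlignment(f"{clone}/r", "reverse", m.chrom,
                         _transcript_blocks(m, L - span, L), m.strand)
        )
    return EvidencePack(junctions, coverage, peptides, ests)


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


def _transcript_cds_start(model: GeneModel) -> int:
    pos = model.genomic_positions()
    inside = np.flatnonzero((pos >= model.cds[0]) & (pos < model.cds[1]))
    return int(inside[0])


def _cds_position_index(model: GeneModel) -> dict[int, int]:
    """genomic position -> spliced CDS index (transcript order)."""
    pos = model.genomic_positions()
    inside = pos[(pos >= model.cds[0]) & (pos < model.cds[1])]
    return {int(g): i for i, g in enumerate(inside)}


def _placement_ok(gpos: np.ndarray, index: dict[int, int]) -> bool:
    """Peptide coding bases must map into the model CDS contiguously,
    starting on a codon boundary (same reading frame)."""
    first = index.get(int(gpos[0]))
    if first is None or first % 3 != 0:
        return False
    for k, g in enumerate(gpos):
        if index.get(int(g)) != first + k:
            return False
    return True


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def _trim_cds_to_exons(exons: tuple[Interval, ...], cds: Interval
                       ) -> Interval | None:
    """Clip a CDS interval into an exon chain, keeping endpoints inside
    exons and trimming bases from the genomic end so the spliced length
    is a multiple of 3.  None when fewer than 3 codons survive."""
    positions = [
        p for s, e in exons
        for p in range(max(s, cds[0]), min(e, cds[1]))
    ]
    if len(positions) < 9:
        return None
    n = len(positions) - (len(positions) % 3)
    positions = positions[:n]
    return (positions[0], positions[-1] + 1)


def make_decoys(truth: TruthTable, cfg: SimulationConfig | None = None
                ) -> TruthTable:
    """Build the allgenes-style candidate pool: truth models plus split,
    merge, truncate and frameshift decoys, with shuffled pool ids and a
    ledger mapping every pool entry to its origin."""
    cfg = cfg or truth.config
    rng = np.random.default_rng((cfg.seed * 3_000_017 + 29) % (2**31))
    genome = truth.genome()
    entries: list[tuple[GeneModel, str, str]] = [
        (m, "true", m.model_id) for m in truth.models
    ]
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in truth.models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda m: m.start)

    for m in truth.models:
        if m.n_exons >= 2 and rng.random() < cfg.p_split:
            k = int(rng.integers(0, m.n_exons - 1))
            for half in (m.exons[:k + 1], m.exons[k + 1:]):
                cds = _trim_cds_to_exons(half, m.cds)
                if cds is None:
                    continue
                d = replace(m, exons=half, cds=cds, source="decoy")
                _try_add(entries, d, genome, "split", m.model_id)
        if rng.random() < cfg.p_merge:
            sibs = by_chrom[m.chrom]
            i = sibs.index(m)
            if i + 1 < len(sibs):
                nxt = sibs[i + 1]
                if (nxt.strand == m.strand and nxt.start > m.end
                        and nxt.start - m.end < 600):
                    exons = m.exons + nxt.exons
                    cds = _trim_cds_to_exons(exons, (m.cds[0], nxt.cds[1]))
                    if cds is not None:
                        d = replace(m, exons=exons, cds=cds, source="decoy")
                        _try_add(entries, d, genome, "merge", m.model_id)
        if m.n_exons >= 2 and rng.random() < cfg.p_truncate:
            exons = m.exons[:-1] if m.strand == "+" else m.exons[1:]
            cds = _trim_cds_to_exons(exons, m.cds)
            if cds is not None:
                d = replace(m, exons=exons, cds=cds, source="decoy")
                _try_add(entries, d, genome, "truncate", m.model_id)
        if rng.random() < cfg.p_frameshift and m.cds_spliced_length >= 12:
            cds = _trim_cds_to_exons(m.exons, (m.cds[0] + 1, m.cds[1]))
            if cds is not None and cds != m.cds:
                d = replace(m, exons=m.exons, cds=cds, source="decoy")
                _try_add(entries, d, genome, "frameshift", m.model_id)

    order = rng.permutation(len(entries))
    pool, ledger = [], {}
    for new_i, old_i in enumerate(order):
        model, kind, parent = entries[old_i]
        pid = f"m{new_i:05d}"
        source = "allgenes" if kind == "true" else "decoy"
        pool.append(set_structural_utr_flags(
            replace(model, model_id=pid, source=source)))
        ledger[pid] = (kind, parent)
    truth.pool = sorted(pool, key=lambda m: (m.chrom, m.start, m.model_id))
    truth.pool_ledger = ledger
    return truth


def _try_add(entries, model: GeneModel, genome, kind: str, parent: str) -> None:
    try:
        model.validate(genome)
    except AnnotationError:
        return
    entries.append((model, kind, parent))


# ---------------------------------------------------------------------------
# whole-study convenience + file emission
# ---------------------------------------------------------------------------

def simulate_study(
    cfg: SimulationConfig,
    ie_plan: Sequence[tuple[IEFamilySpec, int, int, int]] = (),
) -> tuple[TruthTable, EvidencePack]:
    """Genome -> IE planting -> decoy pool -> evidence, in one seeded run.

    ``ie_plan`` rows are (family spec, n complete, n partial,
    n intergenic).
    """
    truth = simulate_genome(cfg)
    for spec, n_c, n_p, n_i in ie_plan:
        plant_ie_family(truth, spec, n_c, n_p, n_i)
    make_decoys(truth, cfg)
    evidence = simulate_evidence(truth, cfg)
    return truth, evidence


def emit_study(truth: TruthTable, evidence: EvidencePack, outdir: str | Path,
               ie_specs: Sequence[IEFamilySpec] = ()) -> None:
    """Write every output file of a simulated study (FASTA, GFF3s,
    evidence tracks, motif file, truth tables)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = truth.genome()
    write_genome(genome, out / "genome.fa")
    write_models_gff3(truth.models, out / "truth.gff3")
    write_models_gff3(truth.pool or truth.models, out / "allgenes.gff3")
    write_junctions(evidence.junctions, out / "junctions.tsv")
    write_coverage(
        {c: t for (c, s), t in evidence.coverage.items() if s == "+"},
        out / "coverage_plus.bedgraph",
    )
    write_coverage(
        {c: t for (c, s), t in evidence.coverage.items() if s == "-"},
        out / "coverage_minus.bedgraph",
    )
    write_peptides(evidence.peptides, out / "peptides.tsv")
    write_ests_bed12(evidence.ests, out / "ests.bed12")
    if ie_specs:
        write_meme_minimal(family_pwms(list(ie_specs)), out / "motifs.meme")
    import pandas as pd

    pd.DataFrame(
        [
            {
                "family": p.family, "chrom": p.chrom,
                "start": p.interval[0], "end": p.interval[1],
                "strand": p.strand, "completeness": p.completeness,
                "motifs": ",".join(p.motifs_present),
                "location": p.location_class, "donor": p.donor_type,
                "parent_model": p.parent_model_id or ".",
            }
            for p in truth.planted_ies
        ]
    ).to_csv(out / "planted_ies.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"pool_id": pid, "kind": kind, "parent": parent}
            for pid, (kind, parent) in sorted(truth.pool_ledger.items())
        ]
    ).to_csv(out / "pool_ledger.tsv", sep="\t", index=False)
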