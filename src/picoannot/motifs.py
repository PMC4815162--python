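"""Position-weight-matrix machinery for Introner Element detection.

Provides the PWM container with MEME-minimal-format I/O, exact p-values
for log-odds scores (dynamic-programming convolution over discretized
per-column score distributions), double-stranded genome scanning at a
p-value threshold, and ZOOPS (zero-or-one occurrence per sequence)
motif discovery by expectation-maximization.

Scores are log-odds in bits against a 0-order background and are
discretized to 1e-3-bit integer bins; the p-value DP and the scanner
share the same binning, so a hit's reported p-value is exactly the tail
probability of its binned score.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import Interval

logger = logging.getLogger(__name__)

BIN_BITS = 1e-3  # score discretization (bits per bin)
_N_CODE = 4
_BASES = "ACGT"
_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))

UNIFORM = np.full(4, 0.25)


def encode_seq(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_ENC), dtype=np.uint8)


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities over ACGT with a background model."""

    motif_id: str
    matrix: np.ndarray          # (width, 4) probabilities
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())
    nsites: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: columns must sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(width, 4) log2 odds vs background; zero probabilities map to
        a large negative score."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix) - np.log2(self.background)
        return np.where(np.isfinite(lo), lo, -1e4)

    def binned_scores(self) -> np.ndarray:
        return np.rint(self.log_odds() / BIN_BITS).astype(np.int64)

    def information_content(self) -> float:
        """Mean per-column relative entropy vs background, in bits."""
        with np.errstate(divide="ignore", invalid="ignore"):
            term = self.matrix * (np.log2(self.matrix) - np.log2(self.background))
        return float(np.nansum(term, axis=1).mean())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.nsites)

    def score_sequence(self, seq: str) -> float:
        """Log-odds score of an exact-width sequence, in bits."""
        codes = encode_seq(seq)
        if len(codes) != self.width or (codes == _N_CODE).any():
            raise ValueError("sequence must be motif width, ACGT only")
        return float(self.log_odds()[np.arange(self.width), codes].sum())

    @classmethod
    def from_consensus(
        cls, consensus: str, motif_id: str, match_p: float = 0.94,
        background: np.ndarray | None = None,
    ) -> "PWM":
        codes = encode_seq(consensus)
        m = np.full((len(codes), 4), (1 - match_p) / 3)
        m[np.arange(len(codes)), codes] = match_p
        return cls(motif_id, m, UNIFORM.copy() if background is None else background)

    @classmethod
    def from_sites(
        cls, sites: Sequence[str], motif_id: str, pseudocount: float = 0.1,
        background: np.ndarray | None = None,
    ) -> "PWM":
        bg = UNIFORM.copy() if background is None else np.asarray(background, float)
        w = len(sites[0])
        counts = np.zeros((w, 4))
        for s in sites:
            codes = encode_seq(s)
            if len(codes) != w:
                raise ValueError("sites must share one width")
            ok = codes != _N_CODE
            counts[np.flatnonzero(ok), codes[ok]] += 1
        counts += pseudocount * bg
        return cls(motif_id, counts / counts.sum(axis=1, keepdims=True), bg,
                   nsites=len(sites))


# ---------------------------------------------------------------------------
# exact p-values
# ---------------------------------------------------------------------------

class ScoreDistribution:
    """Exact distribution of a PWM's binned log-odds score under the
    background model, by convolution over positions."""

    def __init__(self, pwm: PWM):
        B = pwm.binned_scores()
        bg = pwm.background
        probs = np.array([1.0])
        lo = 0
        for col in B:
            cmin, cmax = int(col.min()), int(col.max())
            new = np.zeros(len(probs) + cmax - cmin)
            for b in range(4):
                shift = int(col[b]) - cmin
                new[shift:shift + len(probs)] += probs * bg[b]
            probs = new
            lo += cmin
        self.min_bin = lo
        self.max_bin = lo + len(probs) - 1
        # tail[k] = P(score_bin >= min_bin + k)
        self.tail = np.cumsum(probs[::-1])[::-1]

    def pvalue(self, score_bin: int) -> float:
        if score_bin <= self.min_bin:
            return 1.0
        if score_bin > self.max_bin:
            return 0.0
        return float(self.tail[score_bin - self.min_bin])

    def threshold_bin(self, p: float) -> int:
        """Smallest binned score whose tail probability is <= p (may be
        ``max_bin + 1`` when no attainable score is that significant)."""
        idx = np.searchsorted(-self.tail, -p, side="left")
        return self.min_bin + int(idx)


def pwm_pvalue(pwm: PWM, score_bits: float) -> float:
    """Exact tail probability P(score >= ``score_bits``) under the
    background, at the module's 1e-3-bit discretization."""
    dist = ScoreDistribution(pwm)
    return dist.pvalue(int(round(score_bits / BIN_BITS)))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    interval: Interval
    strand: str
    score_bits: float
    p_value: float


def _window_scores(codes: np.ndarray, binned: np.ndarray) -> np.ndarray:
    """Binned window scores at every start position; windows containing N
    score far below any threshold."""
    w = binned.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    ext = np.hstack([binned, np.full((w, 1), -(10 ** 7), dtype=np.int64)])
    total = np.zeros(n_win, dtype=np.int64)
    for j in range(w):
        total += ext[j, codes[j:j + n_win]]
    return total


def scan_genome(
    genome: dict, pwms: Sequence[PWM], p_threshold: float = 1e-10,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Report all motif occurrences with exact p-value <= threshold on
    both strands, sorted by position."""
    hits: list[MotifHit] = []
    for pwm in pwms:
        dist = ScoreDistribution(pwm)
        tbin = dist.threshold_bin(p_threshold)
        if tbin > dist.max_bin:
            logger.warning(
                "motif %s cannot reach p <= %g; no hits possible",
                pwm.motif_id, p_threshold,
            )
            continue
        strands = [("+", pwm.binned_scores())]
        if both_strands:
            strands.append(("-", pwm.reverse_complement().binned_scores()))
        for chrom_id, gseq in sorted(genome.items()):
            codes = encode_seq(gseq.sequence)
            for strand, binned in strands:
                scores = _window_scores(codes, binned)
                for i in np.flatnonzero(scores >= tbin):
                    sbin = int(scores[i])
                    hits.append(
                        MotifHit(
                            pwm.motif_id, chrom_id,
                            (int(i), int(i) + pwm.width), strand,
                            sbin * BIN_BITS, dist.pvalue(sbin),
                        )
                    )
    return sorted(hits, key=lambda h: (h.chrom, h.interval, h.strand, h.motif_id))


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def read_meme_minimal(path: str | Path) -> list[PWM]:
    """Read MEME minimal-format motifs, keeping the letter probabilities
    exactly as printed (no quantization through site counts)."""
    lines = Path(path).read_text().splitlines()
    bg = UNIFORM.copy()
    out: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            bg = np.array(
                [float(fields[fields.index(b) + 1]) for b in _BASES]
            )
            bg = bg / bg.sum()
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = dict(
                zip(*[iter(lines[i].split(":", 1)[1].split())] * 2)
            )
            w = int(header["w="]) if "w=" in header else int(header.get("w", 0))
            nsites = int(float(header.get("nsites=", header.get("nsites", 0))))
            rows = []
            i += 1
            while len(rows) < w:
                vals = lines[i].split()
                if vals:
                    rows.append([float(v) for v in vals[:4]])
                i += 1
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            out.append(PWM(name, mat, bg.copy(), nsites=nsites))
            continue
        i += 1
    return out


def write_meme_minimal(pwms: Sequence[PWM], path: str | Path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = pwms[0].background if pwms else UNIFORM
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg)))
    lines.append("")
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.motif_id}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {max(pwm.nsites, 1)} E= 0"
        )
        for row in pwm.matrix:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ZOOPS motif discovery
# ---------------------------------------------------------------------------

def _sequence_background(code_arrays: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)
    for codes in code_arrays:
        ok = codes != _N_CODE
        counts += np.bincount(codes[ok], minlength=4)[:4]
    return counts / counts.sum()


def _zoops_em(
    code_arrays: Sequence[np.ndarray], seed_kmer: np.ndarray,
    background: np.ndarray, max_iter: int, tol: float = 1e-5,
) -> tuple[float, np.ndarray, list[tuple[int, int]]]:
    """Run ZOOPS EM from one seed; returns (log-likelihood, probability
    matrix, site list as (sequence index, offset))."""
    w = len(seed_kmer)
    matrix = np.full((w, 4), 0.05)
    matrix[np.arange(w), seed_kmer] = 0.85
    gamma = 0.5
    lbg = np.log(background)
    n = len(code_arrays)
    prev_ll = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            lp = np.log(matrix)
        lp_ext = np.hstack([lp - lbg[None, :], np.full((w, 1), -1e9)])
        ll = 0.0
        z_all = []
        presence = np.zeros(n)
        for s, codes in enumerate(code_arrays):
            m = len(codes) - w + 1
            if m <= 0:
                z_all.append(np.zeros(0))
                continue
            llr = np.zeros(m)
            for j in range(w):
                llr += lp_ext[j, codes[j:j + m]]
            lik = np.exp(np.clip(llr, -700, 700))
            mix = (1 - gamma) + (gamma / m) * lik.sum()
            ll += math.log(max(mix, 1e-300))
            z = (gamma / m) * lik / mix
            z_all.append(z)
            presence[s] = z.sum()
        counts = np.zeros((w, 4))
        for codes, z in zip(code_arrays, z_all):
            m = len(z)
            if m == 0:
                continue
            active = np.flatnonzero(z > 1e-9)
            for i in active:
                window = codes[i:i + w]
                ok = window != _N_CODE
                counts[np.flatnonzero(ok), window[ok]] += z[i]
        counts += 0.25 * background
        matrix = counts / counts.sum(axis=1, keepdims=True)
        gamma = float(np.clip(presence.mean(), 1e-3, 0.999))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    sites = [
        (s, int(np.argmax(z)))
        for s, z in enumerate(z_all)
        if len(z) and presence[s] > 0.5
    ]
    return ll, matrix, sites


def _top_kmers(
    code_arrays: Sequence[np.ndarray], w: int, n_seeds: int
) -> list[np.ndarray]:
    counts: dict[bytes, int] = {}
    for codes in code_arrays:
        for i in range(len(codes) - w + 1):
            window = codes[i:i + w]
            if (window == _N_CODE).any():
                continue
            key = window.tobytes()
            counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [np.frombuffer(k, dtype=np.uint8) for k, _ in ranked[:n_seeds]]


def discover_motifs_zoops(
    sequences: Sequence[str],
    n_motifs: int = 6,
    min_sites: int = 10,
    width: int | None = None,
    widths: Sequence[int] = (8, 12, 16, 20),
    min_info: float = 1.0,
    n_seeds: int = 5,
    max_iter: int = 60,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Discover up to ``n_motifs`` PWMs under a zero-or-one-occurrence-
    per-sequence model.

    EM is seeded from the most over-represented words; after each motif
    its sites are masked before the next search.  Motifs supported by
    fewer than ``min_sites`` sequences, or below ``min_info`` bits of
    mean per-column information, are discarded and end the search.
    Deterministic given the input and seed.
    """
    if len(sequences) < min_sites:
        logger.warning(
            "ZOOPS: %d sequences < min_sites=%d; no motifs searched",
            len(sequences), min_sites,
        )
        return []
    rng = np.random.default_rng(seed)
    if len(sequences) > 600:
        keep = sorted(rng.choice(len(sequences), size=600, replace=False))
        sequences = [sequences[i] for i in keep]
    work = [encode_seq(s).copy() for s in sequences]
    bg = _sequence_background(work) if background is None else np.asarray(background)
    trial_widths = [width] if width else list(widths)

    found: list[PWM] = []
    for k in range(n_motifs):
        best = None
        for w in trial_widths:
            for seed_kmer in _top_kmers(work, w, n_seeds):
                ll, matrix, sites = _zoops_em(work, seed_kmer, bg, max_iter)
                if len(sites) < min_sites:
                    continue
                cand = PWM(f"motif{k + 1}", matrix, bg, nsites=len(sites))
                if cand.information_content() < min_info:
                    continue
                if best is None or ll > best[0]:
                    best = (ll, cand, sites, w)
        if best is None:
            break
        _, pwm, sites, w = best
        site_seqs = [
            "".join("ACGTN"[c] for c in work[s][i:i + w]) for s, i in sites
        ]
        found.append(
            PWM.from_sites(site_seqs, f"motif{k + 1}", background=bg)
        )
        for s, i in sites:  # mask so the next motif must be elsewhere
            work[s][i:i + w] = _N_CODE
    return found
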