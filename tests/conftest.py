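import numpy as np
import pytest

from picoannot.core import GeneModel, GenomeSequence, set_structural_utr_flags


def make_genome(**seqs: str) -> dict[str, GenomeSequence]:
    return {k: GenomeSequence(k, v.upper()) for k, v in seqs.items()}


def make_model(
    model_id="m1", chrom="chr1", strand="+", exons=((0, 30),), cds=None,
    source="allgenes", utr_flags=True,
):
    exons = tuple(tuple(e) for e in exons)
    if cds is None:
        span = (exons[0][0], exons[-1][1])
        spliced = sum(e - s for s, e in exons)
        cds = (span[0], span[0] + (spliced - spliced % 3))
        if cds[1] > span[1]:
            cds = (span[0], span[1] - (spliced % 3))
    m = GeneModel(model_id, chrom, strand, exons, tuple(cds), source=source)
    return set_structural_utr_flags(m) if utr_flags else m


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def random_locus(rng, n):
    """A random locus of n single-exon models with arbitrary evidence
    scores, for comparing selection against exhaustive enumeration."""
    from fractions import Fraction

    from picoannot.scoring import ScoreBreakdown

    models, scores = [], {}
    for i in range(n):
        start = int(rng.integers(0, 400))
        length = int(rng.integers(60, 400))
        cs = start + int(rng.integers(0, 20))
        n_codons = int(rng.integers(5, max((start + length - cs) // 3, 6)))
        ce = min(cs + 3 * n_codons, start + length)
        ce = cs + ((ce - cs) // 3) * 3
        if ce <= cs:
            ce = cs + 3
        m = make_model(
            f"m{i:02d}", strand="+" if rng.random() < 0.5 else "-",
            exons=((start, start + length),), cds=(cs, ce),
        )
        models.append(m)
        scores[m.model_id] = ScoreBreakdown(
            m.model_id,
            int(rng.choice([-5, 0, 5, 20])),
            20 * int(rng.integers(0, 3)),
            Fraction(int(rng.integers(0, 5)), int(rng.integers(1, 5))),
            0,
            int(rng.choice([0, 20])),
            5 * int(rng.integers(0, 3)),
        )
    return models, scores


def oracle_select(models, scores):
    """Independent exhaustive-subset selection oracle (empty set included),
    applying the same documented tie-break convention by its own code."""
    import itertools
    from fractions import Fraction

    from picoannot.scoring import default_conflict

    best_key, best = None, ()
    n = len(models)
    for mask in range(1 << n):
        chosen = [models[i] for i in range(n) if mask >> i & 1]
        if any(
            default_conflict(x, y)
            for x, y in itertools.combinations(chosen, 2)
        ):
            continue
        total = sum((scores[m.model_id].total for m in chosen), Fraction(0))
        ids = tuple(sorted(m.model_id for m in chosen))
        key = (
            total,
            -len(chosen),
            sum(m.cds_spliced_length for m in chosen),
            sum(1 for m in chosen if scores[m.model_id].n_evidence_types > 0),
            tuple(-ord(c) for mid in ids for c in mid + "\0"),
        )
        if best_key is None or key > best_key:
            best_key, best = key, ids
    return best


@pytest.fixture(scope="session")
def small_study():
    """A modest seeded study reused by scoring/pipeline tests."""
    from picoannot import simulate as sim

    cfg = sim.SimulationConfig(seed=11, genome_length=250_000, n_genes=40)
    truth, evidence = sim.simulate_study(cfg)
    return truth, evidence
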