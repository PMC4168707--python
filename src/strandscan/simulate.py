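"""Seeded generator of bacterial-like genomes, transcripts and stranded reads.

The generator emulates the features the model exploits: codon-biased genes
grouped into transcription units (operons) with short intra-operon gaps,
longer inter-unit gaps, both genome strands used, antisense transcripts
overlapping part of a single gene on the opposite strand, and stranded
paired-end reads with a configurable FR/RF orientation.

Coding sequence is emitted from exactly the parameterisation the model fits
(six periodic states, order-``coding_order`` context), so parameter recovery
is well-posed; ``coding_order=0`` provides a deliberately misspecified
generator for robustness checks.  The coding emission tables depend only on
``table_seed``, so corpora with different layout seeds share one codon-usage
model, like genomes from one community.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import AlignmentRecord
from .decode import Transcript
from .model import (
    BASES,
    BASE_INDEX,
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    contexts,
    reverse_complement,
)
from .seqio import Feature

SENSE_MATCH = ("M1", "M2", "M3", "M4", "M5", "M6")


@dataclass
class GeneratorConfig:
    seed: int
    table_seed: int = 7                     # shared codon-bias model
    genome_length: int = 100_000
    gc: float = 0.5
    mean_gene_codons: int = 180
    sd_gene_codons: int = 60
    min_gene_codons: int = 40
    operon_fraction: float = 0.5            # fraction of multi-gene units
    max_operon_size: int = 4
    intra_gap: tuple[int, int] = (5, 50)    # nt, inclusive bounds
    inter_gap: tuple[int, int] = (120, 400)
    utr_flank: tuple[int, int] = (20, 60)
    minus_fraction: float = 0.5
    antisense_fraction: float = 0.2         # relative to sense units
    antisense_overlap: tuple[float, float] = (0.3, 0.8)
    coding_order: int = 2
    coding_bias: float = 0.35               # Dirichlet concentration
    start_codon_freqs: dict = field(default_factory=lambda: {
        "ATG": 0.8, "GTG": 0.15, "TTG": 0.05})
    stop_codon_freqs: dict = field(default_factory=lambda: {
        "TAA": 0.5, "TAG": 0.2, "TGA": 0.3})
    max_genes: int | None = None
    read_length: int = 101
    insert_size: int = 300
    insert_sd: int = 30
    coverage: float = 30.0
    error_rate: float = 0.0
    library_type: str = "RF"


@dataclass
class TruthGene:
    start: int
    end: int
    strand: str
    unit_id: int


@dataclass
class TruthUnit:
    unit_id: int
    start: int
    end: int
    strand: str
    gene_indices: list


@dataclass
class TruthAntisense:
    start: int
    end: int
    strand: str            # strand the antisense RNA is transcribed from
    target_gene: int
    overlap_fraction: float


@dataclass
class SyntheticTruth:
    genome_id: str
    sequence: str
    genes: list = field(default_factory=list)
    units: list = field(default_factory=list)
    antisense: list = field(default_factory=list)
    config: GeneratorConfig | None = None
    coding_tables: dict = field(default_factory=dict)

    @property
    def gene_features(self) -> list:
        return [Feature(seqid=self.genome_id, start=g.start, end=g.end,
                        strand=g.strand,
                        attributes={"ID": f"gene{i}",
                                    "unit": str(g.unit_id)})
                for i, g in enumerate(self.genes)]


# ----------------------------------------------------------------------
# coding emission tables

def _ban_stop_completions(state: str, ctx: str, vec: np.ndarray,
                          stops) -> np.ndarray:
    """Zero third-codon-position entries that would complete a stop codon."""
    if state in ("M3", "M6") and len(ctx) == 2:
        for s in stops:
            if ctx == s[:2]:
                vec = vec.copy()
                vec[BASE_INDEX[s[2]]] = 0.0
    total = vec.sum()
    return vec / total if total > 0 else vec


def _tilt(v: np.ndarray, t: float) -> np.ndarray:
    w = v * np.exp(t * np.array([-1.0, 1.0, 1.0, -1.0]))
    return w / w.sum()


def _stationary_gc(tables: dict, k: int) -> float:
    """GC fraction of the coding chain's stationary base distribution.

    The chain's node is (periodic state to emit next, length-k context);
    power iteration over at most 6*4^k nodes.
    """
    ctxs = contexts(k)
    nodes = [(i, c) for i in range(6) for c in ctxs]
    idx = {n: j for j, n in enumerate(nodes)}
    pi = np.full(len(nodes), 1.0 / len(nodes))
    M = np.zeros((len(nodes), len(nodes)))
    for (i, c), j in idx.items():
        vec = tables[SENSE_MATCH[i]][c]
        for b, base in enumerate(BASES):
            nc = (c + base)[-k:] if k else ""
            M[j, idx[((i + 1) % 6, nc)]] += vec[b]
    for _ in range(300):
        pi = pi @ M
        pi /= pi.sum()
    gc = 0.0
    for (i, c), j in idx.items():
        vec = tables[SENSE_MATCH[i]][c]
        gc += pi[j] * (vec[1] + vec[2])
    return float(gc)


def _retilt_to_gc(tables: dict, target_gc: float, k: int) -> dict:
    """Exponentially retilt all vectors so the *visited* (stationary) GC of
    the coding chain hits the target, preserving the per-context bias
    pattern (bisection on a single tilt parameter)."""
    def tilted(t):
        return {s: {c: _tilt(v, t) for c, v in tab.items()}
                for s, tab in tables.items()}

    lo, hi = -6.0, 6.0
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if _stationary_gc(tilted(mid), k) < target_gc:
            lo = mid
        else:
            hi = mid
    return tilted((lo + hi) / 2.0)


def coding_tables(config: GeneratorConfig) -> dict:
    """Per-state, per-context coding emission tables drawn from table_seed."""
    rng = np.random.default_rng(config.table_seed)
    k = config.coding_order
    stops = tuple(config.stop_codon_freqs)
    tables = {}
    for state in SENSE_MATCH:
        tables[state] = {}
        for ctx in contexts(k):
            vec = rng.dirichlet([config.coding_bias] * 4)
            vec = np.clip(vec, 1e-4, None)
            vec = vec / vec.sum()
            tables[state][ctx] = _ban_stop_completions(state, ctx, vec, stops)
    return _retilt_to_gc(tables, config.gc, k)


# ----------------------------------------------------------------------
# genome generation

def _sample_codon(rng, freqs: dict) -> str:
    codons = sorted(freqs)
    probs = np.array([freqs[c] for c in codons])
    return codons[rng.choice(len(codons), p=probs / probs.sum())]


def _sample_gene(rng, tables: dict, config: GeneratorConfig) -> str:
    codons = max(config.min_gene_codons,
                 int(round(rng.normal(config.mean_gene_codons,
                                      config.sd_gene_codons))))
    k = config.coding_order
    stops = set(config.stop_codon_freqs)
    seq = _sample_codon(rng, config.start_codon_freqs)
    for ci in range(codons):
        phase = ci % 2
        while True:
            codon = ""
            for within in range(3):
                state = SENSE_MATCH[phase * 3 + within]
                ctx = (seq + codon)[-k:] if k else ""
                vec = tables[state][ctx]
                codon += BASES[rng.choice(4, p=vec)]
            if codon not in stops:
                break
        seq += codon
    seq += _sample_codon(rng, config.stop_codon_freqs)
    return seq


def _background(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def generate_genome(config: GeneratorConfig,
                    genome_id: str | None = None) -> SyntheticTruth:
    """Plant codon-biased transcription units in a background genome."""
    rng = np.random.default_rng([config.seed, 0])
    tables = coding_tables(config)
    gid = genome_id or f"synth{config.seed}"
    L = config.genome_length

    genes: list[TruthGene] = []
    units: list[TruthUnit] = []
    chunks: list[str] = []
    pos = 0

    def gap(bounds):
        return int(rng.integers(bounds[0], bounds[1] + 1))

    lead = gap(config.inter_gap)
    chunks.append(_background(rng, lead, config.gc))
    pos += lead
    unit_id = 0
    while True:
        size = 1
        if rng.random() < config.operon_fraction:
            size = int(rng.integers(2, config.max_operon_size + 1))
        strand = "-" if rng.random() < config.minus_fraction else "+"
        gene_seqs = [_sample_gene(rng, tables, config) for _ in range(size)]
        gaps = [gap(config.intra_gap) for _ in range(size - 1)]
        local = []          # gene intervals within the unit, sense orientation
        cursor = 0
        useq = ""
        for i, gs in enumerate(gene_seqs):
            local.append((cursor, cursor + len(gs)))
            useq += gs
            cursor += len(gs)
            if i < size - 1:
                useq += _background(rng, gaps[i], config.gc)
                cursor += gaps[i]
        trailing = gap(config.inter_gap)
        if pos + len(useq) + trailing > L:
            break
        if config.max_genes is not None and \
                len(genes) + size > config.max_genes:
            break
        gidx = []
        if strand == "+":
            chunks.append(useq)
            for a, b in local:
                gidx.append(len(genes))
                genes.append(TruthGene(pos + a, pos + b, "+", unit_id))
        else:
            chunks.append(reverse_complement(useq))
            ulen = len(useq)
            for a, b in reversed(local):
                gidx.append(len(genes))
                genes.append(TruthGene(pos + ulen - b, pos + ulen - a,
                                       "-", unit_id))
        units.append(TruthUnit(unit_id, pos, pos + len(useq), strand, gidx))
        pos += len(useq)
        chunks.append(_background(rng, trailing, config.gc))
        pos += trailing
        unit_id += 1
    if pos < L:
        chunks.append(_background(rng, L - pos, config.gc))
    sequence = "".join(chunks)[:L]
    if not units:
        raise ValueError("genome too short for a single transcription unit")
    return SyntheticTruth(genome_id=gid, sequence=sequence, genes=genes,
                          units=units, config=config, coding_tables=tables)


# ----------------------------------------------------------------------
# transcripts

def simulate_transcription(truth: SyntheticTruth,
                           config: GeneratorConfig | None = None
                           ) -> list[Transcript]:
    """Sense transcripts (unit spans plus UTR flanks) and antisense
    transcripts overlapping part of one opposite-strand gene."""
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    L = len(truth.sequence)
    truth.antisense = []        # regenerated deterministically on each call
    transcripts: list[Transcript] = []

    spans = sorted((u.start, u.end) for u in truth.units)

    def clearance(pos, left=True):
        """Distance from pos to the nearest unit span boundary."""
        best = pos if left else L - pos
        for s, e in spans:
            if left and e <= pos:
                best = min(best, pos - e)
            if not left and s >= pos:
                best = min(best, s - pos)
        return max(0, best)

    def flank(bound):
        return int(rng.integers(config.utr_flank[0], config.utr_flank[1] + 1))

    for n, unit in enumerate(truth.units):
        f5 = min(flank(None), clearance(unit.start, left=True))
        f3 = min(flank(None), clearance(unit.end, left=False))
        s, e = unit.start - f5, unit.end + f3
        seq = truth.sequence[s:e]
        if unit.strand == "-":
            seq = reverse_complement(seq)
        if len(seq) < 120:
            continue
        transcripts.append(Transcript(
            id=f"{truth.genome_id}|t{n}",
            sequence=seq,
            provenance={"reference": truth.genome_id, "start": s, "end": e,
                        "strand": unit.strand, "kind": "sense",
                        "unit": unit.unit_id}))

    n_anti = int(round(config.antisense_fraction * len(truth.units)))
    candidates = list(rng.permutation(len(truth.genes)))
    made = 0
    for gi in candidates:
        if made >= n_anti:
            break
        g = truth.genes[gi]
        frac = float(rng.uniform(*config.antisense_overlap))
        ov = max(120, int(round(frac * (g.end - g.start))))
        if ov > g.end - g.start:
            continue
        # cover the fraction anchored at the gene's 3' end and extend into
        # the downstream intergenic region
        if g.strand == "+":
            s = g.end - ov
            ext = min(int(rng.integers(10, 80)), clearance(g.end, left=False))
            e = g.end + ext
        else:
            e = g.start + ov
            ext = min(int(rng.integers(10, 80)), clearance(g.start, left=True))
            s = g.start - ext
        if s < 0 or e > L or e - s < 120:
            continue
        # keep the construction clean: no other gene may intrude
        if any(i != gi and gg.start < e and gg.end > s
               for i, gg in enumerate(truth.genes)):
            continue
        anti_strand = "-" if g.strand == "+" else "+"
        seq = truth.sequence[s:e]
        if anti_strand == "-":
            seq = reverse_complement(seq)
        real_frac = (min(e, g.end) - max(s, g.start)) / (g.end - g.start)
        truth.antisense.append(TruthAntisense(
            start=s, end=e, strand=anti_strand, target_gene=int(gi),
            overlap_fraction=real_frac))
        transcripts.append(Transcript(
            id=f"{truth.genome_id}|as{made}",
            sequence=seq,
            provenance={"reference": truth.genome_id, "start": s, "end": e,
                        "strand": anti_strand, "kind": "antisense",
                        "target_gene": int(gi)}))
        made += 1
    return transcripts


def project_annotations(truth: SyntheticTruth, transcripts) -> list[Feature]:
    """Project the truth genes onto each transcript's coordinate frame.

    Coordinates may fall outside [0, len(transcript)) when the transcript
    truncates the gene; strand is '+' when the gene reads along the
    transcript's forward strand.
    """
    out = []
    for tr in transcripts:
        p = tr.provenance
        s, e, strand = p["start"], p["end"], p["strand"]
        for gi, g in enumerate(truth.genes):
            if g.end <= s or g.start >= e:
                continue
            if strand == "+":
                a, b = g.start - s, g.end - s
            else:
                a, b = e - g.end, e - g.start
            out.append(Feature(
                seqid=tr.id, start=a, end=b,
                strand="+" if g.strand == strand else "-",
                attributes={"ID": f"gene{gi}"}))
    return out


# ----------------------------------------------------------------------
# reads

def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = BASES[(BASE_INDEX.get(out[i], 0) + int(rng.integers(1, 4)))
                       % 4]
    return "".join(out)


@dataclass
class SimulatedRead:
    read_id: str
    mate: int
    sequence: str
    true_strand: str        # genome strand of the source transcript


def simulate_reads(transcripts, config: GeneratorConfig):
    """Uniform fragment sampling with fixed read length.

    Returns (reads, alignment_records, truth) where truth maps read_id to the
    genome strand of the originating transcript.  Transcripts shorter than
    the insert size are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = np.random.default_rng([config.seed, 2])
    rl = config.read_length
    reads: list[SimulatedRead] = []
    alignments: list[AlignmentRecord] = []
    truth: dict[str, str] = {}
    for tr in transcripts:
        L = len(tr.sequence)
        p = tr.provenance
        if L < config.insert_size:
            logger.warning("%s: length %d < insert size %d, skipped",
                           tr.id, L, config.insert_size)
            continue
        n_pairs = rng.poisson(config.coverage * L / (2.0 * rl))
        for i in range(int(n_pairs)):
            frag = int(np.clip(round(rng.normal(config.insert_size,
                                                config.insert_sd)), rl, L))
            start = int(rng.integers(0, L - frag + 1))
            fwd = tr.sequence[start:start + rl]
            rev = reverse_complement(tr.sequence[start + frag - rl:
                                                 start + frag])
            if config.library_type == "FR":
                r1, r2 = fwd, rev
                r1_interval = (start, start + rl)
                r2_interval = (start + frag - rl, start + frag)
                r1_fwd_on_tr, r2_fwd_on_tr = True, False
            else:
                r1, r2 = rev, fwd
                r1_interval = (start + frag - rl, start + frag)
                r2_interval = (start, start + rl)
                r1_fwd_on_tr, r2_fwd_on_tr = False, True
            rid = f"{tr.id}.p{i}"
            truth[rid] = p["strand"]
            for mate, seq, (a, b), fwd_on_tr in (
                    (1, r1, r1_interval, r1_fwd_on_tr),
                    (2, r2, r2_interval, r2_fwd_on_tr)):
                reads.append(SimulatedRead(
                    read_id=rid, mate=mate,
                    sequence=_mutate(rng, seq, config.error_rate),
                    true_strand=p["strand"]))
                if p["strand"] == "+":
                    g_pos = p["start"] + a
                    is_rev = not fwd_on_tr
                else:
                    g_pos = p["end"] - b
                    is_rev = fwd_on_tr
                alignments.append(AlignmentRecord(
                    read_id=rid, mate=mate, reference=p["reference"],
                    position=g_pos, length=rl, is_reverse=is_rev))
    return reads, alignments, truth


# ----------------------------------------------------------------------
# convenience

def training_corpus_from_truth(truths) -> "TrainingCorpus":
    """Transcript-shaped training records (unit spans + flanks) from one or
    more synthetic truths, genes rotated into sense orientation."""
    from .training import GeneInterval, TrainingCorpus, TrainingRecord

    records = []
    for truth in ([truths] if isinstance(truths, SyntheticTruth) else truths):
        transcripts = simulate_transcription(truth)
        for tr in transcripts:
            if tr.provenance.get("kind") != "sense":
                continue
            genes = []
            p = tr.provenance
            for g in truth.genes:
                if g.start >= p["start"] and g.end <= p["end"]:
                    if p["strand"] == "+":
                        a, b = g.start - p["start"], g.end - p["start"]
                    else:
                        a, b = p["end"] - g.end, p["end"] - g.start
                    genes.append(GeneInterval(start=a, end=b, strand="+"))
            records.append(TrainingRecord(id=tr.id, sequence=tr.sequence,
                                          genes=genes))
    return TrainingCorpus(records=records)
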