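"""Estimation of model parameters from annotated sequence.

A :class:`TrainingCorpus` is a set of records (sequence + gene intervals with
strand).  Genes are rotated into sense orientation before counting; genes
that do not start with a configured start codon, do not end with a configured
stop codon, or whose length is not a multiple of 3 are skipped with a warning
and counted.

Estimators:

* match emissions — periodic di-codon counts conditioned on the ``k``
  preceding bases (Laplace pseudocounts).  Start and stop codons are modelled
  by the signal states and excluded from match counts; the first body codon
  maps to M1–M3, the second to M4–M6, alternating.
* signal models — joint codon frequencies over the configured codon sets plus
  a descriptive position-weight matrix over a window of 6 nt of flank on
  either side of the codon.
* transitions — geometric rates: the UTR self-loop from intergenic
  (post-stop) gap lengths, so the mean modelled gap is 1/(1 - q); the coding
  self-continuation from gene body lengths in codons.

:func:`train` assembles a GC-binned :class:`~strandscan.model.ParameterLibrary`
from these, mirroring the sense estimates into the antisense module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    BASE_INDEX,
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    PWM_FLANK,
    PWM_WIDTH,
    ModelParameters,
    ParameterLibrary,
    contexts,
    gc_fraction,
    mirror_parameters,
    reverse_complement,
)
from . import seqio

logger = logging.getLogger(__name__)

SENSE_MATCH = ("M1", "M2", "M3", "M4", "M5", "M6")


@dataclass
class GeneInterval:
    start: int          # 0-based half-open on the record
    end: int
    strand: str = "+"   # "+" or "-"


@dataclass
class TrainingRecord:
    id: str
    sequence: str
    genes: list = field(default_factory=list)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)

    def gene_sequence(self, g: GeneInterval) -> str:
        s = self.sequence[g.start:g.end]
        return s if g.strand == "+" else reverse_complement(s)


@dataclass
class TrainingCorpus:
    records: list = field(default_factory=list)
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    stop_codons: tuple[str, ...] = DEFAULT_STOP_CODONS
    n_skipped: int = 0

    def __post_init__(self):
        self._filter_genes()

    def _filter_genes(self):
        for rec in self.records:
            kept = []
            for g in rec.genes:
                seq = rec.gene_sequence(g)
                ok = (len(seq) % 3 == 0 and len(seq) >= 9
                      and seq[:3] in self.start_codons
                      and seq[-3:] in self.stop_codons
                      and set(seq) <= set("ACGT"))
                if ok:
                    kept.append(g)
                else:
                    self.n_skipped += 1
                    logger.warning("%s: gene %d-%d (%s) fails start/stop/"
                                   "length rules, skipped", rec.id, g.start,
                                   g.end, g.strand)
            rec.genes = kept

    @property
    def n_genes(self) -> int:
        return sum(len(r.genes) for r in self.records)

    @classmethod
    def from_files(cls, fasta_path, gff3_path, feature_types=("CDS",),
                   **kw) -> "TrainingCorpus":
        """Build from a genome FASTA and its GFF3 annotation."""
        seqs = dict(seqio.read_fasta(fasta_path))
        feats = seqio.read_gff3(gff3_path, feature_types=feature_types)
        genes_by_seq: dict[str, list] = {sid: [] for sid in seqs}
        for f in feats:
            if f.seqid not in seqs:
                raise ValueError(
                    f"{gff3_path}: feature on unknown sequence {f.seqid!r}")
            genes_by_seq[f.seqid].append(
                GeneInterval(start=f.start, end=f.end, strand=f.strand))
        records = [TrainingRecord(id=sid, sequence=seq,
                                  genes=sorted(genes_by_seq[sid],
                                               key=lambda g: g.start))
                   for sid, seq in seqs.items()]
        return cls(records=records, **kw)


# ----------------------------------------------------------------------
# estimators

def _normalise_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    total = counts.sum() + 4 * pseudocount
    if total == 0:
        return np.full(4, 0.25)
    return (counts + pseudocount) / total


def estimate_emissions(corpus: TrainingCorpus, k: int = 2,
                       pseudocount: float = 1.0) -> dict:
    """Periodic match-state emission tables P(base | Mi, context).

    Returns ``{"M1": {ctx: p(4)}, ...}`` with contexts of length ``k`` drawn
    from the bases preceding each body position (the start codon provides the
    context of the first body bases).
    """
    if corpus.n_genes == 0 and pseudocount <= 0:
        raise ValueError("empty corpus and zero pseudocount")
    ctxs = contexts(k)
    counts = {s: {c: np.zeros(4) for c in ctxs} for s in SENSE_MATCH}
    for rec in corpus.records:
        for g in rec.genes:
            seq = rec.gene_sequence(g)
            body = seq[3:-3]
            for p, base in enumerate(body):
                codon_i, within = divmod(p, 3)
                state = SENSE_MATCH[(codon_i % 2) * 3 + within]
                ctx = seq[3 + p - k:3 + p]
                counts[state][ctx][BASE_INDEX[base]] += 1
    tables = {s: {c: _normalise_counts(v, pseudocount) for c, v in t.items()}
              for s, t in counts.items()}
    if k == 2:
        # coding states may never complete an in-frame stop codon: with the
        # full di-nucleotide context the third-position states can see the
        # codon's first two bases, so the ban is exact
        banned: dict[str, set] = {}
        for stop in corpus.stop_codons:
            banned.setdefault(stop[:2], set()).add(BASE_INDEX[stop[2]])
        for state in ("M3", "M6"):
            for ctx, bad in banned.items():
                vec = tables[state][ctx].copy()
                vec[list(bad)] = 0.0
                total = vec.sum()
                if total > 0:
                    tables[state][ctx] = vec / total
                else:
                    vec = np.ones(4)
                    vec[list(bad)] = 0.0
                    tables[state][ctx] = vec / vec.sum()
    return tables


def estimate_utr_emission(corpus: TrainingCorpus,
                          pseudocount: float = 1.0) -> np.ndarray:
    """Base composition of the non-genic portions of the records."""
    counts = np.zeros(4)
    for rec in corpus.records:
        genic = np.zeros(len(rec.sequence), dtype=bool)
        for g in rec.genes:
            genic[g.start:g.end] = True
        for i, base in enumerate(rec.sequence):
            if not genic[i] and base in BASE_INDEX:
                counts[BASE_INDEX[base]] += 1
    if counts.sum() == 0 and pseudocount <= 0:
        return np.full(4, 0.25)
    return _normalise_counts(counts, pseudocount)


def build_signal_pwm(windows, pseudocount: float = 1.0) -> np.ndarray:
    """Column-wise base frequencies (+ pseudocount) of aligned windows."""
    windows = list(windows)
    if not windows:
        if pseudocount <= 0:
            raise ValueError("no windows and zero pseudocount")
        return np.full((PWM_WIDTH, 4), 0.25)
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("signal windows have unequal lengths")
    counts = np.zeros((width, 4))
    for w in windows:
        for j, base in enumerate(w.upper()):
            if base in BASE_INDEX:
                counts[j, BASE_INDEX[base]] += 1
    return np.stack([_normalise_counts(counts[j], pseudocount)
                     for j in range(width)])


def _codon_frequencies(codons, allowed, pseudocount: float) -> dict:
    counts = {c: 0.0 for c in allowed}
    for c in codons:
        if c in counts:
            counts[c] += 1.0
    total = sum(counts.values()) + pseudocount * len(allowed)
    if total == 0:
        return {c: 1.0 / len(allowed) for c in allowed}
    return {c: (n + pseudocount) / total for c, n in counts.items()}


def _signal_windows(rec: TrainingRecord, g: GeneInterval, at_start: bool):
    """15 nt window around the start (or stop) codon, sense orientation."""
    if g.strand == "+":
        pos = g.start if at_start else g.end - 3
        lo, hi = pos - PWM_FLANK, pos + 3 + PWM_FLANK
        if lo < 0 or hi > len(rec.sequence):
            return None
        return rec.sequence[lo:hi]
    pos = g.end - 3 if at_start else g.start
    lo, hi = pos - PWM_FLANK, pos + 3 + PWM_FLANK
    if lo < 0 or hi > len(rec.sequence):
        return None
    return reverse_complement(rec.sequence[lo:hi])


def estimate_transitions(corpus: TrainingCorpus, pseudocount: float = 1.0,
                         ) -> dict:
    """Geometric transition rates of the sense module (plus the fixed
    initiation row); the antisense rows are produced later by mirroring.

    The UTR self-loop is estimated from intergenic gaps between consecutive
    same-strand genes (a gap of g nt contributes g-1 self-loops and one exit),
    so a corpus of single-gene records with zero pseudocount yields an
    operon re-entry probability of exactly 0.
    """
    gap_self = gap_exit = 0.0
    cont = exit_ = 0.0
    for rec in corpus.records:
        for strand in "+-":
            genes = sorted((g for g in rec.genes if g.strand == strand),
                           key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                gap = b.start - a.end
                if gap >= 1:
                    gap_self += gap - 1
                    gap_exit += 1
        for g in rec.genes:
            body_codons = (g.end - g.start) // 3 - 2
            if body_codons >= 1:
                cont += body_codons - 1
                exit_ += 1
    gap_self += pseudocount
    gap_exit += pseudocount
    q = 1.0 if gap_self + gap_exit == 0 else gap_self / (gap_self + gap_exit)
    cont += pseudocount
    exit_ += pseudocount
    p = 0.5 if cont + exit_ == 0 else cont / (cont + exit_)

    idle = {"UTR_S": 0.5}
    from .model import ANTISENSE_STATES
    for s in ANTISENSE_STATES:
        idle[s] = 0.5 / len(ANTISENSE_STATES)
    return {
        "IDLE": idle,
        "UTR_S": {"UTR_S": q, "START_S": 1.0 - q},
        "START_S": {"M1": 1.0},
        "M1": {"M2": 1.0}, "M2": {"M3": 1.0},
        "M3": {"M4": p, "STOP_S": 1.0 - p},
        "M4": {"M5": 1.0}, "M5": {"M6": 1.0},
        "M6": {"M1": p, "STOP_S": 1.0 - p},
        "STOP_S": {"UTR_S": 1.0},
    }


def estimate_parameters(corpus: TrainingCorpus, gc_bin: int = 50, *,
                        k: int = 2, pseudocount: float = 1.0,
                        restrict_antisense: bool = True) -> ModelParameters:
    """All sense-module estimates for one corpus, antisense filled by mirror."""
    params = ModelParameters(
        gc_bin=gc_bin, k=k, pseudocount=pseudocount,
        start_codons=corpus.start_codons, stop_codons=corpus.stop_codons,
        restrict_antisense=restrict_antisense)
    params.match_sense = estimate_emissions(corpus, k=k,
                                            pseudocount=pseudocount)
    params.utr_emission = {"UTR_S": estimate_utr_emission(corpus,
                                                          pseudocount)}
    starts, stops = [], []
    start_windows, stop_windows = [], []
    for rec in corpus.records:
        for g in rec.genes:
            seq = rec.gene_sequence(g)
            starts.append(seq[:3])
            stops.append(seq[-3:])
            w = _signal_windows(rec, g, at_start=True)
            if w is not None:
                start_windows.append(w)
            w = _signal_windows(rec, g, at_start=False)
            if w is not None:
                stop_windows.append(w)
    params.start_codon_probs = _codon_frequencies(
        starts, corpus.start_codons, pseudocount)
    params.stop_codon_probs = _codon_frequencies(
        stops, corpus.stop_codons, pseudocount)
    params.start_pwm = _pwm_with_codon_columns(
        build_signal_pwm(start_windows, pseudocount),
        params.start_codon_probs)
    params.stop_pwm = _pwm_with_codon_columns(
        build_signal_pwm(stop_windows, pseudocount),
        params.stop_codon_probs)
    params.transition = estimate_transitions(corpus, pseudocount)
    return mirror_parameters(params)


def _pwm_with_codon_columns(pwm: np.ndarray, codon_probs: dict) -> np.ndarray:
    """Replace the codon columns by the joint codon model's marginals so the
    PWM's support matches the decoder's (configured codons only)."""
    out = pwm.copy()
    for j in range(3):
        col = np.zeros(4)
        for codon, p in codon_probs.items():
            col[BASE_INDEX[codon[j]]] += p
        out[PWM_FLANK + j] = col
    return out


# ----------------------------------------------------------------------
# library assembly

def train(source, *, k: int = 2, pseudocount: float = 1.0,
          bin_width: int = 1, gc_range: tuple[int, int] = (26, 70),
          bin_smoothing: int = 1,
          start_codons=DEFAULT_START_CODONS,
          stop_codons=DEFAULT_STOP_CODONS,
          restrict_antisense: bool = True) -> ParameterLibrary:
    """Train a GC-binned parameter library.

    ``source`` is a TrainingCorpus or an iterable of (fasta, gff3) path
    pairs.  Records are grouped by rounded GC percent; each populated bin is
    estimated from its records plus those within ``bin_smoothing`` percent;
    unpopulated bins inside ``gc_range`` borrow the nearest populated bin's
    parameters so the library tiles the range without gaps.  Deterministic:
    identical inputs give byte-identical model files.
    """
    if isinstance(source, TrainingCorpus):
        corpus = source
    else:
        corpora = [TrainingCorpus.from_files(f, g,
                                             start_codons=tuple(start_codons),
                                             stop_codons=tuple(stop_codons))
                   for f, g in source]
        corpus = TrainingCorpus(
            records=[r for c in corpora for r in c.records],
            start_codons=tuple(start_codons), stop_codons=tuple(stop_codons))
    if corpus.n_genes == 0:
        raise ValueError("no usable genes in the training input")

    by_bin: dict[int, list] = {}
    for rec in corpus.records:
        if not rec.genes:
            continue
        b = int(round(100.0 * rec.gc))
        by_bin.setdefault(b, []).append(rec)

    populated: dict[int, ModelParameters] = {}
    for b in sorted(by_bin):
        recs = []
        for bb in range(b - bin_smoothing, b + bin_smoothing + 1):
            recs.extend(by_bin.get(bb, []))
        sub = TrainingCorpus(records=[TrainingRecord(r.id, r.sequence,
                                                     list(r.genes))
                                      for r in recs],
                             start_codons=corpus.start_codons,
                             stop_codons=corpus.stop_codons)
        populated[b] = estimate_parameters(
            sub, gc_bin=b, k=k, pseudocount=pseudocount,
            restrict_antisense=restrict_antisense)

    lo, hi = gc_range
    bins = {}
    from dataclasses import replace
    for b in range(lo, hi + 1, bin_width):
        if b in populated:
            bins[b] = populated[b]
        else:
            src = min(populated, key=lambda x: (abs(x - b), x))
            bins[b] = replace(populated[src], gc_bin=b)
    library = ParameterLibrary(bins=bins, bin_width=bin_width,
                               gc_range=(lo, hi))
    report = library.validate()
    if not report.ok:
        raise RuntimeError("trained library failed validation: "
                           + "; ".join(report.issues[:5]))
    return library
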