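"""Viterbi decoding of transcripts and extraction of gene calls.

The decoder expands the 20 atomic model states into 27 dynamic-programming
states: each 3-base signal state (start/stop codon, both modules) becomes
three phase states traversed with forced transitions, so the recursion stays
strictly per-position.  Signal codons are scored jointly at phase 0 (the
phase-1/2 emissions are then 1), which pins gene boundaries to the configured
start/stop codon sets.

All arithmetic is in natural-log space with ``-inf`` for impossible events.
Ties are broken deterministically by the fixed state order (sense states
before antisense, lower index first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ANTISENSE_CODING,
    BASES,
    ModelParameters,
    ParameterLibrary,
    SENSE_CODING,
    build_state_space,
    gc_fraction,
    reverse_complement,
    select_parameters,
)
from .seqio import translate_cds

logger = logging.getLogger(__name__)

LOG_QUARTER = float(np.log(0.25))
NEG_INF = float("-inf")

#: decoding states: atomic states with signal states expanded into 3 phases
DP_STATES = (
    "UTR_S",
    "START_S/0", "START_S/1", "START_S/2",
    "M1", "M2", "M3", "M4", "M5", "M6",
    "STOP_S/0", "STOP_S/1", "STOP_S/2",
    "UTR3_A",
    "STOP_A/0", "STOP_A/1", "STOP_A/2",
    "M1A", "M2A", "M3A", "M4A", "M5A", "M6A",
    "START_A/0", "START_A/1", "START_A/2",
    "UTR5_A",
)
DP_INDEX = {s: i for i, s in enumerate(DP_STATES)}
N_DP = len(DP_STATES)

#: atomic label of each dp state
DP_ATOMIC = tuple(s.split("/")[0] for s in DP_STATES)

_SIGNALS = ("START_S", "STOP_S", "STOP_A", "START_A")


def _entry_dp(state: str) -> int:
    return DP_INDEX[state + "/0"] if state in _SIGNALS else DP_INDEX[state]


def _exit_dp(state: str) -> int:
    return DP_INDEX[state + "/2"] if state in _SIGNALS else DP_INDEX[state]


@dataclass
class Transcript:
    """A strand-oriented assembled RNA sequence (the observation sequence)."""

    id: str
    sequence: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {self.id}: invalid symbols {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class StatePath:
    """Per-position atomic state labelling with its total log score."""

    states: tuple[str, ...]
    score: float
    dp_states: np.ndarray | None = None
    emission_logs: np.ndarray | None = None


@dataclass
class GeneCall:
    transcript_id: str
    start: int          # transcript-forward, 0-based half-open
    end: int
    strand: str         # "sense" | "antisense"
    has_start: bool
    has_stop: bool
    frame: int
    score: float
    nucleotide: str = ""
    protein: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def gff_strand(self) -> str:
        return "+" if self.strand == "sense" else "-"


@dataclass
class TranscriptAnnotation:
    transcript_id: str
    verdict: str                     # sense_coding | sense_noncoding | antisense
    genes: list = field(default_factory=list)
    partial: list = field(default_factory=list)
    gc: float = 0.0
    length: int = 0


# ----------------------------------------------------------------------
# scoring tables

def _log(x: float) -> float:
    return float(np.log(x)) if x > 0 else NEG_INF


def build_transition_matrix(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """(initial log vector, dp transition log matrix) from atomic rates."""
    space = build_state_space(params.restrict_antisense)
    T = np.full((N_DP, N_DP), NEG_INF)
    init = np.full(N_DP, NEG_INF)
    for src, row in params.transition.items():
        for dst, p in row.items():
            if (src, dst) not in space.allowed_transitions:
                raise ValueError(f"transition {src}->{dst} not in topology")
            if src == "IDLE":
                init[_entry_dp(dst)] = _log(p)
            else:
                T[_exit_dp(src), _entry_dp(dst)] = _log(p)
    for sig in _SIGNALS:
        T[DP_INDEX[sig + "/0"], DP_INDEX[sig + "/1"]] = 0.0
        T[DP_INDEX[sig + "/1"], DP_INDEX[sig + "/2"]] = 0.0
    return init, T


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def _codon_lump_logs(seq: str, codes: np.ndarray, probs: dict) -> np.ndarray:
    """log P(codon starting at t) under a joint codon model.

    N positions (and positions running past the sequence end) contribute a
    uniform 1/4 per ambiguous base, marginalised over compatible codons.
    """
    L = len(seq)
    out = np.full(L, NEG_INF)
    plain = {}
    for codon, p in probs.items():
        plain[codon] = plain.get(codon, 0.0) + p
    for t in range(L):
        codon = seq[t:t + 3]
        if len(codon) == 3 and "N" not in codon:
            out[t] = _log(plain.get(codon, 0.0))
        else:
            codon = (codon + "NNN")[:3]
            n_amb = codon.count("N")
            total = sum(p for c, p in plain.items()
                        if all(a in ("N", b) for a, b in zip(codon, c)))
            out[t] = _log(total * 0.25 ** n_amb)
    return out


def _match_emission_column(table: dict, marginal: np.ndarray,
                           codes: np.ndarray, k: int,
                           following: bool) -> np.ndarray:
    """Per-position log emission for one match state."""
    L = len(codes)
    probs = np.empty(L)
    log_marg = np.log(np.clip(marginal, 1e-300, None))
    # dense (4^k, 4) table in lexicographic context order
    idx_of = {ctx: i for i, ctx in enumerate(sorted(table))}
    dense = np.empty((len(table), 4))
    for ctx, vec in table.items():
        dense[idx_of[ctx]] = vec
    log_dense = np.log(np.clip(dense, 1e-300, None))

    ctx_idx = np.zeros(L, dtype=np.int64)
    valid = np.ones(L, dtype=bool)
    for j in range(1, k + 1):
        off = j if following else -j
        shifted = np.full(L, 4, dtype=np.int64)
        if off > 0:
            shifted[:L - off] = codes[off:]
        else:
            shifted[-off:] = codes[:L + off]
        valid &= shifted < 4
        # axis-order context string: nearest base is most significant when
        # reading left-to-right from the key start
        if following:
            ctx_idx = ctx_idx + shifted.clip(max=3) * 4 ** (k - j)
        else:
            ctx_idx = ctx_idx * 1 + shifted.clip(max=3) * 4 ** (j - 1)
    base_ok = codes < 4
    safe_base = codes.clip(max=3)
    probs = np.where(valid, log_dense[ctx_idx, safe_base],
                     log_marg[safe_base])
    probs = np.where(base_ok, probs, LOG_QUARTER)
    return probs


def build_emission_matrix(transcript_seq: str,
                          params: ModelParameters) -> np.ndarray:
    """(L, 27) matrix of per-position log emissions for every dp state."""
    seq = transcript_seq.upper()
    L = len(seq)
    codes = _encode(seq)
    E = np.zeros((L, N_DP))

    for state in ("UTR_S", "UTR3_A", "UTR5_A"):
        logs = np.log(np.clip(params.utr_emission[state], 1e-300, None))
        col = np.where(codes < 4, logs[codes.clip(max=3)], LOG_QUARTER)
        E[:, DP_INDEX[state]] = col

    k = params.k
    for i, state in enumerate(("M1", "M2", "M3", "M4", "M5", "M6")):
        E[:, DP_INDEX[state]] = _match_emission_column(
            params.match_sense[state], params.match_marginal(state),
            codes, k, following=False)
    for state in ("M1A", "M2A", "M3A", "M4A", "M5A", "M6A"):
        E[:, DP_INDEX[state]] = _match_emission_column(
            params.match_antisense[state], params.match_marginal(state),
            codes, k, following=True)

    E[:, DP_INDEX["START_S/0"]] = _codon_lump_logs(
        seq, codes, params.start_codon_probs)
    E[:, DP_INDEX["STOP_S/0"]] = _codon_lump_logs(
        seq, codes, params.stop_codon_probs)
    E[:, DP_INDEX["STOP_A/0"]] = _codon_lump_logs(
        seq, codes, params.antisense_stop_codon_probs())
    E[:, DP_INDEX["START_A/0"]] = _codon_lump_logs(
        seq, codes, params.antisense_start_codon_probs())
    # phase 1/2 columns stay 0 (the codon is scored in full at phase 0)
    return E


# ----------------------------------------------------------------------
# decoding

def viterbi(transcript: Transcript | str,
            params: ModelParameters) -> StatePath:
    """Most probable topology-valid state path for one transcript.

    Ties are resolved toward the lowest dp-state index (sense before
    antisense), making the output deterministic.
    """
    if isinstance(transcript, str):
        transcript = Transcript(id="seq", sequence=transcript)
    seq = transcript.sequence
    if not seq:
        raise ValueError("empty sequence")
    init, T = build_transition_matrix(params)
    E = build_emission_matrix(seq, params)
    L = len(seq)

    ptr = np.zeros((L, N_DP), dtype=np.int8)
    v = init + E[0]
    for t in range(1, L):
        cand = v[:, None] + T
        ptr[t] = np.argmax(cand, axis=0)
        v = cand[ptr[t], np.arange(N_DP)] + E[t]

    best = int(np.argmax(v))
    score = float(v[best])
    dp_path = np.empty(L, dtype=np.int64)
    dp_path[-1] = best
    for t in range(L - 1, 0, -1):
        dp_path[t - 1] = ptr[t, dp_path[t]]
    labels = tuple(DP_ATOMIC[i] for i in dp_path)
    emis = E[np.arange(L), dp_path]
    return StatePath(states=labels, score=score, dp_states=dp_path,
                     emission_logs=emis)


# ----------------------------------------------------------------------
# gene extraction

@dataclass
class ExtractionResult:
    genes: list
    partial: list
    n_dropped_short: int = 0
    n_dropped_antisense: int = 0


def _null_logs(seq: str, params: ModelParameters, state: str) -> float:
    logs = np.log(np.clip(params.utr_emission[state], 1e-300, None))
    total = 0.0
    for b in seq:
        total += LOG_QUARTER if b == "N" else float(logs["ACGT".index(b)])
    return total


def extract_genes(path: StatePath, transcript: Transcript,
                  params: ModelParameters | None = None,
                  min_gene_length: int = 120,
                  max_antisense: int | None = 1) -> ExtractionResult:
    """Turn a decoded path into gene calls.

    Complete ORFs (start and stop signals fully inside the path) of at least
    ``min_gene_length`` nt — the length includes the stop codon — become
    gene calls.  Runs truncated at a transcript edge go to the ``partial``
    channel; short runs are dropped (counted).  If more than
    ``max_antisense`` complete antisense ORFs survive (possible only with the
    single-antisense restriction disabled), the highest-scoring are kept.
    """
    seq = transcript.sequence
    L = len(seq)
    if len(path.states) != L:
        raise ValueError("state path and transcript lengths differ")

    genes: list[GeneCall] = []
    partial: list[GeneCall] = []
    n_short = 0

    def emission_score(a: int, b: int, null_state: str) -> float:
        if path.emission_logs is None or params is None:
            return float("nan")
        return float(path.emission_logs[a:b].sum()
                     - _null_logs(seq[a:b], params, null_state))

    t = 0
    while t < L:
        label = path.states[t]
        if label in SENSE_CODING or label in ANTISENSE_CODING:
            sense = label in SENSE_CODING
            group = SENSE_CODING if sense else ANTISENSE_CODING
            a = t
            while t < L and path.states[t] in group:
                t += 1
            b = t
            dp = path.dp_states
            if sense:
                has_start = dp is not None and dp[a] == DP_INDEX["START_S/0"] \
                    and b - a >= 3
                has_stop = dp is not None and dp[b - 1] == DP_INDEX["STOP_S/2"]
                frame = a % 3
                nt = seq[a:b]
                null_state = "UTR_S"
            else:
                has_stop = dp is not None and dp[a] == DP_INDEX["STOP_A/0"] \
                    and b - a >= 3
                has_start = dp is not None and dp[b - 1] == DP_INDEX["START_A/2"]
                frame = (L - b) % 3
                nt = reverse_complement(seq[a:b])
                null_state = "UTR3_A"
            call = GeneCall(
                transcript_id=transcript.id, start=a, end=b,
                strand="sense" if sense else "antisense",
                has_start=bool(has_start), has_stop=bool(has_stop),
                frame=frame, score=emission_score(a, b, null_state),
                nucleotide=nt, protein=translate_cds(nt))
            if b - a < min_gene_length:
                n_short += 1
            elif has_start and has_stop:
                genes.append(call)
            elif a == 0 or b == L:
                partial.append(call)
            else:
                # unreachable under the topology: incomplete internal run
                n_short += 1
        else:
            t += 1

    n_dropped_anti = 0
    if max_antisense is not None:
        anti = [g for g in genes if g.strand == "antisense"]
        if len(anti) > max_antisense:
            anti.sort(key=lambda g: (-(g.score if g.score == g.score else 0.0),
                                     g.start))
            keep = set(id(g) for g in anti[:max_antisense])
            n_dropped_anti = len(anti) - max_antisense
            genes = [g for g in genes
                     if g.strand == "sense" or id(g) in keep]
    if n_short or n_dropped_anti:
        logger.debug("%s: dropped %d short runs, %d extra antisense",
                     transcript.id, n_short, n_dropped_anti)
    return ExtractionResult(genes=genes, partial=partial,
                            n_dropped_short=n_short,
                            n_dropped_antisense=n_dropped_anti)


def classify_transcript(transcript: Transcript,
                        result: ExtractionResult | list) -> TranscriptAnnotation:
    """Transcript-level verdict from its gene calls."""
    if isinstance(result, ExtractionResult):
        genes, partial = result.genes, result.partial
    else:
        genes, partial = list(result), []
    sense = [g for g in genes if g.strand == "sense"]
    anti = [g for g in genes if g.strand == "antisense"]
    if sense and anti:
        raise RuntimeError(
            f"{transcript.id}: mixed sense and antisense calls from one path "
            "(violates the model topology)")
    if anti:
        verdict = "antisense"
    elif sense:
        verdict = "sense_coding"
    else:
        verdict = "sense_noncoding"
    return TranscriptAnnotation(
        transcript_id=transcript.id, verdict=verdict, genes=genes,
        partial=partial, gc=transcript.gc, length=len(transcript))


# ----------------------------------------------------------------------
# end-to-end driver

def annotate_transcript(transcript: Transcript,
                        library: ParameterLibrary | ModelParameters,
                        min_gene_length: int = 120) -> TranscriptAnnotation:
    if isinstance(library, ParameterLibrary):
        params = select_parameters(transcript.gc, library)
    else:
        params = library
    path = viterbi(transcript, params)
    result = extract_genes(path, transcript, params,
                           min_gene_length=min_gene_length)
    return classify_transcript(transcript, result)


def predict(transcripts, library: ParameterLibrary | ModelParameters,
            out_dir=None, *, min_transcript_length: int = 120,
            min_gene_length: int = 120) -> list[TranscriptAnnotation]:
    """Annotate many transcripts; optionally write the standard outputs.

    ``transcripts`` may be a FASTA path or an iterable of (id, sequence)
    pairs / Transcript objects.  Records shorter than
    ``min_transcript_length`` are skipped with a warning; per-record failures
    are logged and processing continues.
    """
    from .seqio import read_fasta  # local import to avoid cycles

    if isinstance(transcripts, (str, bytes)) or hasattr(transcripts, "__fspath__"):
        records = read_fasta(transcripts)
    else:
        records = [(t.id, t.sequence) if isinstance(t, Transcript) else tuple(t)
                   for t in transcripts]

    annotations = []
    n_failed = 0
    for rid, seq in records:
        try:
            if len(seq) < min_transcript_length:
                logger.warning("%s: length %d < %d, skipped", rid, len(seq),
                               min_transcript_length)
                continue
            tr = Transcript(id=rid, sequence=seq)
            annotations.append(
                annotate_transcript(tr, library, min_gene_length))
        except Exception:
            n_failed += 1
            logger.exception("failed to annotate %s", rid)
    if records and n_failed == len(records):
        raise RuntimeError("all transcript records failed to annotate")

    if out_dir is not None:
        write_outputs(annotations, out_dir)
    return annotations


def write_outputs(annotations, out_dir) -> None:
    """GFF3 + protein/nucleotide FASTA + per-transcript TSV under out_dir."""
    from pathlib import Path

    import pandas as pd

    from .seqio import Feature, write_fasta, write_gff3

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def feature(ann, g, idx, channel):
        return Feature(
            seqid=ann.transcript_id, start=g.start, end=g.end,
            strand=g.gff_strand, score=g.score,
            attributes={
                "ID": f"{ann.transcript_id}.{channel}{idx}",
                "has_start": str(g.has_start).lower(),
                "has_stop": str(g.has_stop).lower(),
                "verdict": ann.verdict,
            })

    main, part, faa, fna = [], [], [], []
    rows = []
    for ann in annotations:
        for i, g in enumerate(ann.genes, 1):
            f = feature(ann, g, i, "gene")
            main.append(f)
            faa.append((f.attributes["ID"], g.protein))
            fna.append((f.attributes["ID"], g.nucleotide))
        for i, g in enumerate(ann.partial, 1):
            part.append(feature(ann, g, i, "partial"))
        rows.append({"transcript_id": ann.transcript_id,
                     "verdict": ann.verdict, "n_genes": len(ann.genes),
                     "gc": round(ann.gc, 4), "length": ann.length})
    write_gff3(main, out / "genes.gff3")
    write_gff3(part, out / "genes_partial.gff3")
    write_fasta(faa, out / "genes.faa")
    write_fasta(fna, out / "genes.fna")
    pd.DataFrame(rows, columns=["transcript_id", "verdict", "n_genes",
                                "gc", "length"]
                 ).to_csv(out / "transcripts.tsv", sep="\t", index=False)
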