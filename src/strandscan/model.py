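"""Strand-specific HMM for gene finding in stranded transcripts.

The model annotates an assembled transcript (forward strand = transcription
strand) with one of two mutually exclusive modules:

* a **sense** module — untranslated sequence, a start-codon signal, a
  six-periodic cycle of match states M1..M6 modelling di-codon composition,
  and a stop-codon signal.  The stop state re-enters the UTR, so a single
  transcript may carry several genes (an operon).
* an **antisense** module — the mirror image, modelling a single ORF encoded
  on the reverse complement of the transcript.  On the transcript-forward
  axis an antisense gene reads stop-mirror first, so the traversal order is
  UTR3_A -> STOP_A -> M1A..M6A -> START_A -> UTR5_A, and UTR5_A is absorbing
  so a path can contain at most one antisense gene.

An idle start state initiates paths either in the sense UTR or anywhere in
the antisense module; no transition connects the two modules.

Parameters (transition probabilities, periodic context-conditioned match
emissions, UTR composition, and start/stop signal models) are held per GC
bin in a :class:`ParameterLibrary`; the bin is selected from the GC fraction
of each input transcript, so no per-dataset training is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np

MODEL_FORMAT_VERSION = "strandscan-model/1"

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = (3, 2, 1, 0)  # A<->T, C<->G in ACGT order

_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")

#: columns flanking the codon in a signal position-weight matrix
PWM_FLANK = 6
PWM_WIDTH = 2 * PWM_FLANK + 3

IDLE = "IDLE"
SENSE_STATES = ("UTR_S", "START_S", "M1", "M2", "M3", "M4", "M5", "M6", "STOP_S")
#: antisense states in transcript-forward (axis) traversal order
ANTISENSE_STATES = (
    "UTR3_A", "STOP_A", "M1A", "M2A", "M3A", "M4A", "M5A", "M6A",
    "START_A", "UTR5_A",
)
#: fixed state order used for deterministic tie-breaking
ALL_STATES = (IDLE,) + SENSE_STATES + ANTISENSE_STATES

SENSE_MATCH = ("M1", "M2", "M3", "M4", "M5", "M6")
ANTISENSE_MATCH = ("M1A", "M2A", "M3A", "M4A", "M5A", "M6A")
UTR_STATES = ("UTR_S", "UTR3_A", "UTR5_A")
SENSE_CODING = ("START_S",) + SENSE_MATCH + ("STOP_S",)
ANTISENSE_CODING = ("STOP_A",) + ANTISENSE_MATCH + ("START_A",)


def complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over unambiguous bases (N ignored); 0.0 for empty."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass(frozen=True)
class StateSpace:
    """The fixed 20-state topology of the two-module HMM."""

    states: tuple[str, ...]
    allowed_transitions: frozenset[tuple[str, str]]
    restrict_antisense: bool = True

    def successors(self, state: str) -> tuple[str, ...]:
        return tuple(d for (s, d) in sorted(self.allowed_transitions,
                                            key=_edge_order)
                     if s == state)


def _edge_order(edge):
    return (ALL_STATES.index(edge[0]), ALL_STATES.index(edge[1]))


def build_state_space(restrict_antisense: bool = True) -> StateSpace:
    """Construct the model topology.

    With ``restrict_antisense=True`` (the default) UTR5_A is absorbing, so at
    most one antisense ORF fits on any path.  Setting it ``False`` adds the
    edge UTR5_A -> STOP_A, making the antisense module cyclic like the sense
    one; this is used only for symmetry testing.
    """
    edges: set[tuple[str, str]] = set()
    edges.add((IDLE, "UTR_S"))
    for s in ANTISENSE_STATES:
        edges.add((IDLE, s))
    # sense module
    edges.update([
        ("UTR_S", "UTR_S"), ("UTR_S", "START_S"), ("START_S", "M1"),
        ("M1", "M2"), ("M2", "M3"), ("M3", "M4"), ("M3", "STOP_S"),
        ("M4", "M5"), ("M5", "M6"), ("M6", "M1"), ("M6", "STOP_S"),
        ("STOP_S", "UTR_S"),
    ])
    # antisense module, transcript-forward traversal order
    edges.update([
        ("UTR3_A", "UTR3_A"), ("UTR3_A", "STOP_A"),
        ("STOP_A", "M1A"), ("STOP_A", "M4A"),
        ("M1A", "M2A"), ("M2A", "M3A"), ("M3A", "M4A"), ("M3A", "START_A"),
        ("M4A", "M5A"), ("M5A", "M6A"), ("M6A", "M1A"), ("M6A", "START_A"),
        ("START_A", "UTR5_A"), ("UTR5_A", "UTR5_A"),
    ])
    if not restrict_antisense:
        edges.add(("UTR5_A", "STOP_A"))
    return StateSpace(states=ALL_STATES, allowed_transitions=frozenset(edges),
                      restrict_antisense=restrict_antisense)


def contexts(k: int) -> list[str]:
    """All length-k context strings over ACGT ('' for k = 0)."""
    return ["".join(p) for p in product(BASES, repeat=k)]


@dataclass
class ModelParameters:
    """All probabilities of the HMM for one GC bin.

    Match emissions are conditional on observed context: sense states condition
    on the ``k`` *preceding* axis bases, antisense states (mirrored) on the
    ``k`` *following* axis bases, stored in axis order.  Signal codons are
    modelled jointly (distribution over the configured codon set); the wider
    position-weight matrices around them are kept as trained descriptive
    objects with the codon columns equal to the joint model's marginals.
    """

    gc_bin: int = 50
    k: int = 2
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    stop_codons: tuple[str, ...] = DEFAULT_STOP_CODONS
    pseudocount: float = 1.0
    # transition[src][dst] -> probability, over allowed edges only
    transition: dict = field(default_factory=dict)
    # match_sense["M1"][ctx] -> length-4 array over ACGT
    match_sense: dict = field(default_factory=dict)
    match_antisense: dict = field(default_factory=dict)
    # utr_emission[state] -> length-4 array
    utr_emission: dict = field(default_factory=dict)
    start_codon_probs: dict = field(default_factory=dict)
    stop_codon_probs: dict = field(default_factory=dict)
    # descriptive 15x4 PWMs (axis orientation for the antisense pair)
    start_pwm: np.ndarray | None = None
    stop_pwm: np.ndarray | None = None
    start_pwm_antisense: np.ndarray | None = None
    stop_pwm_antisense: np.ndarray | None = None
    restrict_antisense: bool = True

    # ------------------------------------------------------------------
    @classmethod
    def uniform(cls, gc_bin: int = 50, k: int = 2,
                start_codons: tuple[str, ...] = DEFAULT_START_CODONS,
                stop_codons: tuple[str, ...] = DEFAULT_STOP_CODONS,
                restrict_antisense: bool = True) -> "ModelParameters":
        """Uniform distributions over every allowed edge / symbol."""
        space = build_state_space(restrict_antisense)
        p = cls(gc_bin=gc_bin, k=k, start_codons=tuple(start_codons),
                stop_codons=tuple(stop_codons),
                restrict_antisense=restrict_antisense)
        for s in ALL_STATES:
            succ = space.successors(s)
            if succ:
                p.transition[s] = {d: 1.0 / len(succ) for d in succ}
        u = np.full(4, 0.25)
        for s in SENSE_MATCH:
            p.match_sense[s] = {c: u.copy() for c in contexts(k)}
        for s in ANTISENSE_MATCH:
            p.match_antisense[s] = {c: u.copy() for c in contexts(k)}
        for s in UTR_STATES:
            p.utr_emission[s] = u.copy()
        p.start_codon_probs = {c: 1.0 / len(start_codons) for c in start_codons}
        p.stop_codon_probs = {c: 1.0 / len(stop_codons) for c in stop_codons}
        p.start_pwm = _pwm_from_codon_probs(p.start_codon_probs)
        p.stop_pwm = _pwm_from_codon_probs(p.stop_codon_probs)
        return mirror_parameters(p)

    @classmethod
    def default(cls, gc_bin: int = 50, k: int = 2,
                utr_self: float = 0.98, coding_continue: float = 0.995,
                **kw) -> "ModelParameters":
        """Uniform emissions with realistic default transition rates
        (mean UTR run 50 nt, mean gene body 200 codons)."""
        p = cls.uniform(gc_bin=gc_bin, k=k, **kw)
        idle = {"UTR_S": 0.5}
        for s in ANTISENSE_STATES:
            idle[s] = 0.5 / len(ANTISENSE_STATES)
        q, pc = utr_self, coding_continue
        p.transition.update({
            "IDLE": idle,
            "UTR_S": {"UTR_S": q, "START_S": 1.0 - q},
            "M3": {"M4": pc, "STOP_S": 1.0 - pc},
            "M6": {"M1": pc, "STOP_S": 1.0 - pc},
        })
        return mirror_parameters(p)

    # derived lookup tables -------------------------------------------
    def match_marginal(self, state: str) -> np.ndarray:
        """Context-averaged emission for a match state (N-context fallback)."""
        table = (self.match_sense if state in SENSE_MATCH
                 else self.match_antisense)[state]
        return np.mean([v for v in table.values()], axis=0)

    def antisense_start_codon_probs(self) -> dict:
        """Axis-orientation codon model for START_A (revcomp of starts)."""
        return {reverse_complement(c): p
                for c, p in self.start_codon_probs.items()}

    def antisense_stop_codon_probs(self) -> dict:
        return {reverse_complement(c): p
                for c, p in self.stop_codon_probs.items()}


def _pwm_from_codon_probs(codon_probs: dict, flank: np.ndarray | None = None
                          ) -> np.ndarray:
    """15x4 PWM with uniform (or given) flank columns and codon marginals."""
    pwm = np.full((PWM_WIDTH, 4), 0.25)
    if flank is not None:
        pwm[:] = flank
    for j in range(3):
        col = np.zeros(4)
        for codon, p in codon_probs.items():
            col[BASE_INDEX[codon[j]]] += p
        pwm[PWM_FLANK + j] = col
    return pwm


# ----------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:  # truthy when valid
        return self.ok


def _check_dist(report, name, vec, tol=1e-9):
    arr = np.asarray(vec, dtype=float)
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        report.issues.append(f"{name}: probability outside [0,1]")
    if abs(arr.sum() - 1.0) > tol:
        report.issues.append(f"{name}: sums to {arr.sum():.12g}, not 1")


def validate_parameters(params: ModelParameters,
                        space: StateSpace | None = None,
                        tol: float = 1e-9) -> ValidationReport:
    """Report every distribution off unit mass, out-of-range probability,
    or transition outside the allowed topology.  Empty report <=> valid."""
    if space is None:
        space = build_state_space(params.restrict_antisense)
    report = ValidationReport()
    for src, row in params.transition.items():
        for dst in row:
            if (src, dst) not in space.allowed_transitions:
                report.issues.append(f"transition {src}->{dst} not allowed")
        _check_dist(report, f"transition row {src}", list(row.values()), tol)
    for state in SENSE_MATCH:
        for ctx, vec in params.match_sense.get(state, {}).items():
            _check_dist(report, f"match {state}|{ctx or '-'}", vec, tol)
    for state in ANTISENSE_MATCH:
        for ctx, vec in params.match_antisense.get(state, {}).items():
            _check_dist(report, f"match {state}|{ctx or '-'}", vec, tol)
    for state, vec in params.utr_emission.items():
        _check_dist(report, f"utr {state}", vec, tol)
    _check_dist(report, "start codon model",
                list(params.start_codon_probs.values()), tol)
    _check_dist(report, "stop codon model",
                list(params.stop_codon_probs.values()), tol)
    for codon in params.start_codon_probs:
        if codon not in params.start_codons:
            report.issues.append(f"start codon model has mass on {codon}")
    for codon in params.stop_codon_probs:
        if codon not in params.stop_codons:
            report.issues.append(f"stop codon model has mass on {codon}")
    _validate_pwm(report, "start_pwm", params.start_pwm,
                  params.start_codons, tol)
    _validate_pwm(report, "stop_pwm", params.stop_pwm,
                  params.stop_codons, tol)
    _validate_pwm(report, "start_pwm_antisense", params.start_pwm_antisense,
                  tuple(reverse_complement(c) for c in params.start_codons),
                  tol)
    _validate_pwm(report, "stop_pwm_antisense", params.stop_pwm_antisense,
                  tuple(reverse_complement(c) for c in params.stop_codons),
                  tol)
    return report


def _validate_pwm(report, name, pwm, codons, tol):
    if pwm is None:
        return
    if pwm.shape != (PWM_WIDTH, 4):
        report.issues.append(f"{name}: shape {pwm.shape} != ({PWM_WIDTH}, 4)")
        return
    for j in range(PWM_WIDTH):
        _check_dist(report, f"{name} column {j}", pwm[j], tol)
    # codon columns carry mass only on the bases the codon set uses
    for j in range(3):
        allowed = {BASE_INDEX[c[j]] for c in codons}
        col = pwm[PWM_FLANK + j]
        for b in range(4):
            if b not in allowed and col[b] > tol:
                report.issues.append(
                    f"{name}: codon column {j} has mass on {BASES[b]}")


# ----------------------------------------------------------------------
# mirroring

def _mirror_vec(vec: np.ndarray) -> np.ndarray:
    return np.asarray(vec)[list(COMPLEMENT_INDEX)].copy()


def mirror_parameters(params: ModelParameters) -> ModelParameters:
    """Fill the antisense half by reverse-complement symmetry.

    Axis match state ``MiA`` takes the emission of sense ``M(7-i)`` with
    complemented bases; because the antisense states condition on *following*
    axis bases, the context key is the reverse complement of the sense
    (preceding-bases) context.  Signal PWMs are reversed and complemented into
    axis orientation.  Idempotent: applying it twice changes nothing.
    """
    out = replace(params,
                  transition={s: dict(r) for s, r in params.transition.items()},
                  match_sense={s: {c: np.asarray(v).copy() for c, v in t.items()}
                               for s, t in params.match_sense.items()},
                  match_antisense={},
                  utr_emission=dict(params.utr_emission),
                  start_codon_probs=dict(params.start_codon_probs),
                  stop_codon_probs=dict(params.stop_codon_probs))
    for i in range(1, 7):
        src = f"M{7 - i}"
        table = params.match_sense[src]
        out.match_antisense[f"M{i}A"] = {
            reverse_complement(ctx): _mirror_vec(vec)
            for ctx, vec in table.items()
        }
    utr = np.asarray(params.utr_emission["UTR_S"])
    out.utr_emission["UTR3_A"] = _mirror_vec(utr)
    out.utr_emission["UTR5_A"] = _mirror_vec(utr)
    if params.start_pwm is not None:
        out.start_pwm_antisense = _mirror_pwm(params.start_pwm)
    if params.stop_pwm is not None:
        out.stop_pwm_antisense = _mirror_pwm(params.stop_pwm)
    # mirror the sense transition rates onto the antisense module
    t = out.transition
    if "UTR_S" in t:
        q = t["UTR_S"].get("UTR_S", 0.0)
        t["UTR3_A"] = {"UTR3_A": q, "STOP_A": 1.0 - q}
        if not params.restrict_antisense:
            t["UTR5_A"] = {"UTR5_A": q, "STOP_A": 1.0 - q}
        else:
            t["UTR5_A"] = {"UTR5_A": 1.0}
    if "M6" in t:
        p = t["M6"].get("M1", 0.0)
        t["M3A"] = {"M4A": p, "START_A": 1.0 - p}
        t["M6A"] = {"M1A": p, "START_A": 1.0 - p}
    t.setdefault("STOP_A", {"M1A": 0.5, "M4A": 0.5})
    t.setdefault("START_A", {"UTR5_A": 1.0})
    for s, r in [("M1A", {"M2A": 1.0}), ("M2A", {"M3A": 1.0}),
                 ("M4A", {"M5A": 1.0}), ("M5A", {"M6A": 1.0})]:
        t.setdefault(s, r)
    return out


def _mirror_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1][:, list(COMPLEMENT_INDEX)].copy()


# ----------------------------------------------------------------------
# GC-binned parameter library

@dataclass
class ParameterLibrary:
    """ModelParameters per integer GC percent bin, tiling ``gc_range``."""

    bins: dict = field(default_factory=dict)  # int percent -> ModelParameters
    bin_width: int = 1
    gc_range: tuple[int, int] = (26, 70)

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        lo, hi = self.gc_range
        for b in range(lo, hi + 1, self.bin_width):
            if b not in self.bins:
                report.issues.append(f"gc bin {b} missing from library")
        for b, params in sorted(self.bins.items()):
            sub = validate_parameters(params)
            report.issues.extend(f"bin {b}: {i}" for i in sub.issues)
        return report


def select_parameters(gc: float, library: ParameterLibrary) -> ModelParameters:
    """Pick the library bin containing round(100*gc), clamped to gc_range."""
    if not library.bins:
        raise ValueError("parameter library is empty")
    lo, hi = library.gc_range
    label = min(max(int(round(100.0 * gc)), lo), hi)
    # snap to the bin grid
    label = lo + ((label - lo) // library.bin_width) * library.bin_width
    if label in library.bins:
        return library.bins[label]
    # defensive: nearest populated bin (libraries are built fully tiled)
    nearest = min(library.bins, key=lambda b: (abs(b - label), b))
    return library.bins[nearest]


# ----------------------------------------------------------------------
# serialisation (canonical JSON; byte-exact round trips)

def _params_to_dict(p: ModelParameters) -> dict:
    return {
        "gc_bin": p.gc_bin,
        "k": p.k,
        "start_codons": list(p.start_codons),
        "stop_codons": list(p.stop_codons),
        "pseudocount": p.pseudocount,
        "restrict_antisense": p.restrict_antisense,
        "transition": {s: dict(sorted(r.items()))
                       for s, r in sorted(p.transition.items())},
        "match_sense": {s: {c: list(map(float, v)) for c, v in sorted(t.items())}
                        for s, t in sorted(p.match_sense.items())},
        "match_antisense": {s: {c: list(map(float, v))
                                for c, v in sorted(t.items())}
                            for s, t in sorted(p.match_antisense.items())},
        "utr_emission": {s: list(map(float, v))
                         for s, v in sorted(p.utr_emission.items())},
        "start_codon_probs": dict(sorted(p.start_codon_probs.items())),
        "stop_codon_probs": dict(sorted(p.stop_codon_probs.items())),
        "start_pwm": None if p.start_pwm is None else p.start_pwm.tolist(),
        "stop_pwm": None if p.stop_pwm is None else p.stop_pwm.tolist(),
        "start_pwm_antisense": (None if p.start_pwm_antisense is None
                                else p.start_pwm_antisense.tolist()),
        "stop_pwm_antisense": (None if p.stop_pwm_antisense is None
                               else p.stop_pwm_antisense.tolist()),
    }


def _params_from_dict(d: dict) -> ModelParameters:
    def arr(x):
        return None if x is None else np.asarray(x, dtype=float)

    return ModelParameters(
        gc_bin=d["gc_bin"], k=d["k"],
        start_codons=tuple(d["start_codons"]),
        stop_codons=tuple(d["stop_codons"]),
        pseudocount=d["pseudocount"],
        restrict_antisense=d["restrict_antisense"],
        transition={s: dict(r) for s, r in d["transition"].items()},
        match_sense={s: {c: np.asarray(v, dtype=float) for c, v in t.items()}
                     for s, t in d["match_sense"].items()},
        match_antisense={s: {c: np.asarray(v, dtype=float)
                             for c, v in t.items()}
                         for s, t in d["match_antisense"].items()},
        utr_emission={s: np.asarray(v, dtype=float)
                      for s, v in d["utr_emission"].items()},
        start_codon_probs=dict(d["start_codon_probs"]),
        stop_codon_probs=dict(d["stop_codon_probs"]),
        start_pwm=arr(d["start_pwm"]), stop_pwm=arr(d["stop_pwm"]),
        start_pwm_antisense=arr(d["start_pwm_antisense"]),
        stop_pwm_antisense=arr(d["stop_pwm_antisense"]),
    )


def save_library(library: ParameterLibrary, path: str | Path) -> None:
    doc = {
        "format": MODEL_FORMAT_VERSION,
        "bin_width": library.bin_width,
        "gc_range": list(library.gc_range),
        "bins": {str(b): _params_to_dict(p)
                 for b, p in sorted(library.bins.items())},
    }
    text = json.dumps(doc, sort_keys=True, indent=1) + "\n"
    Path(path).write_text(text)


def load_library(path: str | Path) -> ParameterLibrary:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file format: {doc.get('format')!r}")
    return ParameterLibrary(
        bins={int(b): _params_from_dict(d) for b, d in doc["bins"].items()},
        bin_width=doc["bin_width"],
        gc_range=tuple(doc["gc_range"]),
    )
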