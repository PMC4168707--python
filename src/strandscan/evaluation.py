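"""Sensitivity / precision / F-score evaluation of gene predictions, plus
operon and antisense-transcript comparison statistics.

Gene matching works on transcript coordinates.  An annotated gene counts
toward the sensitivity denominator only when it is fully contained in a
transcript.  A prediction is a true positive under mode ``complete`` when it
covers all of an annotated gene in the same frame and strand, and under mode
``overlap80`` when the shared length is at least 80% of the annotated gene's
length.  Predictions whose stop codon matches an annotated gene in frame but
whose start lies mid-gene because the transcript truncates the gene's 5' end
are excluded from the evaluation entirely.  False positives are the
remaining predictions that fail even the 80% criterion; precision in either
mode is TP / (TP + FP) with that shared FP set, which is what reconciles the
per-mode precision with the total prediction count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import Feature

MODES = ("complete", "overlap80")


def f_score(sn: float, pr: float) -> float:
    """Harmonic mean of sensitivity and precision (percent in, percent out);
    defined as 0 when both are 0."""
    if not (0 <= sn <= 100 and 0 <= pr <= 100):
        raise ValueError(f"Sn/Pr must be percentages in [0,100], "
                         f"got {sn}, {pr}")
    if sn == 0 and pr == 0:
        return 0.0
    return 2.0 * pr * sn / (pr + sn)


@dataclass
class EvaluationReport:
    mode: str
    tp: int
    fp: int
    fn: int
    excluded: int
    annotated_covered: int
    sn: float
    pr: float
    f: float
    pr_defined: bool = True


@dataclass
class GeneRecord:
    """Normalised view of a prediction or annotation on a transcript."""

    transcript_id: str
    start: int
    end: int
    strand: str   # "+" along the transcript, "-" antisense


def _normalise(items) -> list[GeneRecord]:
    out = []
    for it in items:
        if isinstance(it, GeneRecord):
            out.append(it)
        elif isinstance(it, Feature):
            out.append(GeneRecord(it.seqid, it.start, it.end, it.strand))
        elif hasattr(it, "transcript_id"):  # decode.GeneCall
            out.append(GeneRecord(it.transcript_id, it.start, it.end,
                                  it.gff_strand))
        else:
            tid, s, e, strand = it
            out.append(GeneRecord(tid, s, e, strand))
    return out


def _in_frame(pred: GeneRecord, ann: GeneRecord) -> bool:
    if pred.strand != ann.strand:
        return False
    if pred.strand == "+":
        return (pred.start - ann.start) % 3 == 0
    return (pred.end - ann.end) % 3 == 0


def _overlap_fraction(pred: GeneRecord, ann: GeneRecord) -> float:
    shared = min(pred.end, ann.end) - max(pred.start, ann.start)
    return max(0, shared) / (ann.end - ann.start)


def _is_excluded(pred: GeneRecord, anns, length: int) -> bool:
    """Partial 5'-end call: correct in-frame stop on a gene whose 5' end the
    transcript does not cover, start picked mid-gene."""
    for a in anns:
        if pred.strand != a.strand or not _in_frame(pred, a):
            continue
        if a.strand == "+" and a.start < 0 and pred.end == a.end \
                and pred.start > a.start:
            return True
        if a.strand == "-" and a.end > length and pred.start == a.start \
                and pred.end < a.end:
            return True
    return False


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    excluded: int
    annotated_covered: int
    matched_ann_ids: list = field(default_factory=list)


def match_genes(predicted, annotated, transcript_lengths: dict,
                mode: str = "overlap80") -> MatchResult:
    """Count TP/FP/FN/excluded for one overlap mode.

    ``transcript_lengths`` maps transcript id to length; annotations may
    extend outside [0, length) to signal genes truncated by the transcript.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    threshold = 1.0 if mode == "complete" else 0.8
    preds = _normalise(predicted)
    anns = _normalise(annotated)

    ann_by_t: dict[str, list] = {}
    for a in anns:
        ann_by_t.setdefault(a.transcript_id, []).append(a)

    tp = fp = fn = excluded = covered_total = 0
    matched = []
    seen_t = set()
    for tid in sorted(set(list(ann_by_t) + [p.transcript_id for p in preds])):
        if tid in seen_t:
            continue
        seen_t.add(tid)
        length = transcript_lengths.get(tid, 0)
        t_anns = ann_by_t.get(tid, [])
        t_preds = [p for p in preds if p.transcript_id == tid]
        covered = [a for a in t_anns if a.start >= 0 and a.end <= length]
        covered_total += len(covered)

        usable = []
        for p in t_preds:
            if _is_excluded(p, t_anns, length):
                excluded += 1
            else:
                usable.append(p)
        for a in covered:
            hit = any(_in_frame(p, a)
                      and _overlap_fraction(p, a) >= threshold
                      for p in usable)
            if hit:
                tp += 1
                matched.append(a)
            else:
                fn += 1
        # false positives are judged at the 80% level regardless of mode
        for p in usable:
            if not any(_in_frame(p, a) and _overlap_fraction(p, a) >= 0.8
                       for a in covered):
                fp += 1
    return MatchResult(tp=tp, fp=fp, fn=fn, excluded=excluded,
                       annotated_covered=covered_total, matched_ann_ids=matched)


def evaluate(predicted, annotated, transcript_lengths: dict) -> dict:
    """Both overlap modes as EvaluationReports keyed by mode name."""
    reports = {}
    for mode in MODES:
        m = match_genes(predicted, annotated, transcript_lengths, mode)
        sn = 100.0 * m.tp / m.annotated_covered if m.annotated_covered else 0.0
        denom = m.tp + m.fp
        pr = 100.0 * m.tp / denom if denom else 0.0
        reports[mode] = EvaluationReport(
            mode=mode, tp=m.tp, fp=m.fp, fn=m.fn, excluded=m.excluded,
            annotated_covered=m.annotated_covered,
            sn=sn, pr=pr, f=f_score(sn, pr), pr_defined=denom > 0)
    return reports


# ----------------------------------------------------------------------
# operons

@dataclass
class OperonComparison:
    n_predicted: int
    n_matched_80: int
    n_complete: int
    n_contained: int
    n_spanning: int


def _check_operon(genes) -> list:
    ordered = sorted((tuple(g) for g in genes))
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if e1 > s2:
            raise ValueError("operon gene intervals overlap or are unsorted")
        if s1 >= e1 or s2 >= e2:
            raise ValueError("empty gene interval in operon")
    return ordered


def compare_operons(predicted_operons, known_operons) -> OperonComparison:
    """Predicted vs curated operons on a shared genome coordinate frame.

    Each operon is a list of (start, end) member gene intervals.  A
    prediction matches completely when its gene set is identical to a known
    operon's; it matches at 80% when its genomic span shares at least 80% of
    its own length with some known operon's span; 'contained' predictions sit
    strictly inside a known span without matching completely; 'spanning'
    predictions overlap two or more known operons.
    """
    pred = [_check_operon(p) for p in predicted_operons]
    known = [_check_operon(ko) for ko in known_operons]
    known_sets = [tuple(ko) for ko in known]
    spans = [(ko[0][0], ko[-1][1]) for ko in known]

    n_complete = n_80 = n_contained = n_spanning = 0
    for p in pred:
        span = (p[0][0], p[-1][1])
        plen = span[1] - span[0]
        complete = tuple(p) in known_sets
        overlaps = []
        for ks, ke in spans:
            shared = min(span[1], ke) - max(span[0], ks)
            if shared > 0:
                overlaps.append(shared)
        if complete:
            n_complete += 1
        if overlaps and max(overlaps) / plen >= 0.8:
            n_80 += 1
        if not complete:
            if any(span[0] >= ks and span[1] <= ke
                   and (span[0] > ks or span[1] < ke)
                   for ks, ke in spans):
                n_contained += 1
            elif len(overlaps) >= 2:
                n_spanning += 1
    return OperonComparison(n_predicted=len(pred), n_matched_80=n_80,
                            n_complete=n_complete, n_contained=n_contained,
                            n_spanning=n_spanning)


# ----------------------------------------------------------------------
# antisense transcripts

def antisense_stats(antisense_transcripts, reference_genes) -> dict:
    """Classify predicted antisense transcripts against annotated genes.

    Inputs are (start, end, strand) tuples on the genome: the transcript's
    strand is the strand it was transcribed from.  Classes:

    * ``partial_single_opposite`` — overlaps part of exactly one gene on the
      opposite strand and no gene on its own strand (likely a real asRNA);
    * ``contains_gene`` — fully contains an annotated gene (likely an mRNA
      mis-called as antisense);
    * ``other``.
    """
    genes = [g if isinstance(g, tuple) else (g.start, g.end, g.strand)
             for g in reference_genes]
    counts = {"partial_single_opposite": 0, "contains_gene": 0, "other": 0}
    for t in antisense_transcripts:
        s, e, strand = t if isinstance(t, tuple) else (t.start, t.end,
                                                       t.strand)
        contains = [g for g in genes if s <= g[0] and g[1] <= e]
        if contains:
            counts["contains_gene"] += 1
            continue
        opp_partial = [g for g in genes
                       if g[2] != strand and min(e, g[1]) > max(s, g[0])]
        same = [g for g in genes
                if g[2] == strand and min(e, g[1]) > max(s, g[0])]
        if len(opp_partial) == 1 and not same:
            counts["partial_single_opposite"] += 1
        else:
            counts["other"] += 1
    return counts
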