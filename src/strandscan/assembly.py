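"""Reference-based transcript extraction from stranded paired-end alignments.

The pipeline mirrors how stranded RNA-seq is condensed into transcript
sequences without a de novo assembler: partition properly-paired reads into
positively- and negatively-transcribed sets by mate orientation, mark every
reference base supported by at least one read of a set, and emit contiguous
marked regions of at least 120 nt as transcripts (negative-class regions
reverse-complemented so the transcript's forward strand is the transcription
strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .decode import Transcript
from .model import reverse_complement

logger = logging.getLogger(__name__)

LIBRARY_TYPES = ("FR", "RF")


@dataclass
class AlignmentRecord:
    """One aligned mate of a paired-end read."""

    read_id: str
    mate: int                 # 1 or 2
    reference: str
    position: int             # 0-based leftmost reference coordinate
    length: int               # aligned reference length
    is_reverse: bool
    is_proper_pair: bool = True
    is_mapped: bool = True

    @property
    def end(self) -> int:
        return self.position + self.length


@dataclass
class CoverageMask:
    """Sorted, disjoint, half-open marked intervals for one strand class."""

    reference: str
    strand_class: str                     # "+" or "-"
    intervals: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(e - s for s, e in self.intervals)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse SAM/BAM into alignment records (primary alignments only)."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                mate=1 if aln.is_read1 or not aln.is_paired else 2,
                reference=aln.reference_name or "",
                position=aln.reference_start if not aln.is_unmapped else -1,
                length=aln.reference_length or 0,
                is_reverse=aln.is_reverse,
                is_proper_pair=aln.is_proper_pair,
                is_mapped=not aln.is_unmapped,
            ))
    return records


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """6+-column tabular form: read_id, mate, reference, position, length,
    strand(+/-) [, proper(0/1)]."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            records.append(AlignmentRecord(
                read_id=parts[0], mate=int(parts[1]), reference=parts[2],
                position=int(parts[3]), length=int(parts[4]),
                is_reverse=parts[5] == "-",
                is_proper_pair=len(parts) < 7 or parts[6] == "1",
            ))
    return records


def partition_reads(records, library_type: str = "RF"):
    """Split paired records into (positively, negatively) transcribed sets.

    For an FR library a pair whose mate 1 aligns forward comes from a
    transcript on the reference's plus strand; RF is the opposite.  Pairs
    with an unmapped mate or not properly paired are discarded (counted).
    Returns (positive_records, negative_records, n_discarded).
    """
    if library_type not in LIBRARY_TYPES:
        raise ValueError(f"unknown library_type {library_type!r}")
    pairs: dict[str, list] = {}
    n_discarded = 0
    for r in records:
        pairs.setdefault(r.read_id, []).append(r)
    positive, negative = [], []
    for rid in sorted(pairs):
        group = pairs[rid]
        mates = {r.mate: r for r in group}
        ok = (len(group) == 2 and set(mates) == {1, 2}
              and all(r.is_mapped and r.is_proper_pair for r in group)
              and len({r.reference for r in group}) == 1)
        if not ok:
            n_discarded += len(group)
            continue
        mate1_forward = not mates[1].is_reverse
        plus = mate1_forward if library_type == "FR" else not mate1_forward
        (positive if plus else negative).extend(sorted(group,
                                                       key=lambda r: r.mate))
    if n_discarded:
        logger.info("discarded %d unpaired/improper records", n_discarded)
    return positive, negative, n_discarded


def coverage_mask(records, reference_length: int, reference: str = "",
                  strand_class: str = "+") -> CoverageMask:
    """Union of aligned intervals of one strand class on one reference.

    Overlapping or abutting intervals merge; gaps of >= 1 nt split.
    """
    raw = []
    for r in records:
        if r.position < 0 or r.end > reference_length:
            raise ValueError(
                f"read {r.read_id}/{r.mate} interval [{r.position},{r.end}) "
                f"outside reference of length {reference_length}")
        if reference and r.reference != reference:
            raise ValueError(f"read {r.read_id} on {r.reference}, "
                             f"expected {reference}")
        raw.append((r.position, r.end))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:          # overlap or abutting
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return CoverageMask(reference=reference or
                        (records[0].reference if raw else ""),
                        strand_class=strand_class, intervals=merged)


def extract_transcripts(masks, reference_seqs: dict,
                        min_length: int = 120) -> list[Transcript]:
    """One transcript per surviving (>= min_length) interval.

    Negative-class transcripts are reverse-complemented so that their forward
    strand is the transcription strand; provenance is recorded in the id as
    ``ref:start-end:strand`` (0-based half-open).
    """
    out = []
    for mask in ([masks] if isinstance(masks, CoverageMask) else masks):
        if mask.reference not in reference_seqs:
            raise KeyError(f"reference {mask.reference!r} not in FASTA")
        ref = reference_seqs[mask.reference]
        for s, e in mask.intervals:
            if e - s < min_length:
                continue
            seq = ref[s:e]
            if mask.strand_class == "-":
                seq = reverse_complement(seq)
            out.append(Transcript(
                id=f"{mask.reference}:{s}-{e}:{mask.strand_class}",
                sequence=seq,
                provenance={"reference": mask.reference, "start": s,
                            "end": e, "strand": mask.strand_class}))
    return out


def assemble(records, reference_seqs: dict, library_type: str = "RF",
             min_length: int = 120) -> list[Transcript]:
    """Full partition -> mask -> extraction pipeline over all references."""
    positive, negative, _ = partition_reads(records, library_type)
    transcripts = []
    for strand, recs in (("+", positive), ("-", negative)):
        by_ref: dict[str, list] = {}
        for r in recs:
            by_ref.setdefault(r.reference, []).append(r)
        for ref in sorted(by_ref):
            mask = coverage_mask(by_ref[ref], len(reference_seqs[ref]),
                                 reference=ref, strand_class=strand)
            transcripts.extend(
                extract_transcripts(mask, reference_seqs, min_length))
    return transcripts
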