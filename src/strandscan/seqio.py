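"""Shared readers/writers: FASTA, FASTQ, GFF3, TSV.

Internal coordinates are 0-based half-open everywhere; conversion to GFF3's
1-based inclusive convention happens only in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
import gffutils

GFF3_VERSION_LINE = "##gff-version 3"

_GFF3_ATTR_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
                      "%": "%25", "\t": "%09", "\n": "%0A"}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercase sequence) pairs.

    Multi-line records and CRLF endings are accepted; the id is the header
    token up to the first whitespace.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty id")
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records, path: str | Path, width: int = 60,
                descriptions: dict | None = None) -> None:
    """Write (id, seq) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            desc = (descriptions or {}).get(rid, "")
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(records, path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate a coding sequence (bacterial table 11), trimming a trailing
    stop; incomplete trailing codons are dropped."""
    nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(table=table))
    return aa[:-1] if aa.endswith("*") else aa


def gff3_escape(value) -> str:
    out = str(value)
    out = out.replace("%", "%25")
    for ch, rep in _GFF3_ATTR_ESCAPES.items():
        if ch != "%":
            out = out.replace(ch, rep)
    return out


@dataclass
class Feature:
    """One GFF3 feature with 0-based half-open coordinates."""

    seqid: str
    start: int
    end: int
    strand: str = "+"
    type: str = "CDS"
    source: str = "strandscan"
    score: float | None = None
    phase: int | None = 0
    attributes: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def write_gff3(features, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GFF3_VERSION_LINE + "\n")
        for f in features:
            attrs = ";".join(f"{gff3_escape(k)}={gff3_escape(v)}"
                             for k, v in f.attributes.items()) or "."
            score = "." if f.score is None else f"{f.score:.3f}"
            phase = "." if f.phase is None else str(f.phase)
            fh.write("\t".join([
                f.seqid, f.source, f.type, str(f.start + 1), str(f.end),
                score, f.strand, phase, attrs,
            ]) + "\n")


def read_gff3(path: str | Path, feature_types=("CDS",)) -> list[Feature]:
    """Read selected feature types from GFF3 (via gffutils)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for ftype in feature_types:
        for f in db.features_of_type(ftype, order_by=("seqid", "start")):
            try:
                score = float(f.score)
            except (TypeError, ValueError):
                score = None
            phase = int(f.frame) if f.frame not in (None, ".") else None
            out.append(Feature(
                seqid=f.seqid, start=f.start - 1, end=f.end,
                strand=f.strand or "+", type=f.featuretype,
                source=f.source or ".", score=score, phase=phase,
                attributes={k: v[0] if len(v) == 1 else list(v)
                            for k, v in f.attributes.items()},
            ))
    return out
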