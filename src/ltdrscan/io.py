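"""File formats: FASTA, GFF3, BED6 and TSV.

FASTA goes through Biopython's SeqIO (wrapped at 60 columns on output;
lowercase input is uppercased and IUPAC ambiguity codes collapse to N).
GFF3 output is 1-based inclusive per the standard; everything in memory
stays 0-based half-open.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ltdrscan.core import GenomeSequence, Interval
from ltdrscan.errors import IOFormatError

_AMBIGUITY = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().translate(_AMBIGUITY)
        records.append(GenomeSequence(contig_id=rec.id, seq=seq))
    if not records:
        raise IOFormatError(f"{path}: no FASTA records")
    ids = [r.contig_id for r in records]
    if len(set(ids)) != len(ids):
        raise IOFormatError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.contig_id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def write_bed6(
    rows: Sequence[tuple[Interval, str, float]], path: str | Path
) -> None:
    """Write (interval, name, score_fraction) rows as BED6.

    The BED score column is round(1000 * score_fraction), clipped to
    [0, 1000] per the BED convention.
    """
    with open(path, "w") as fh:
        for interval, name, frac in rows:
            score = max(0, min(1000, round(1000 * frac)))
            fh.write(
                f"{interval.contig_id}\t{interval.start}\t{interval.end}"
                f"\t{name}\t{score}\t{interval.strand}\n"
            )


_GFF_ESCAPE = {";": "%3B", "=": "%3D", "\t": "%09", "\n": "%0A", "%": "%25"}


def _gff_escape(value: str) -> str:
    return "".join(_GFF_ESCAPE.get(c, c) for c in value)


def _gff_unescape(value: str) -> str:
    return re.sub(
        "%25|%3B|%3D|%2C|%09|%0A",
        lambda m: {"%25": "%", "%3B": ";", "%3D": "=", "%2C": ",", "%09": "\t", "%0A": "\n"}[m.group(0)],
        value,
    )


class Gff3Feature:
    """One GFF3 feature line (coordinates 0-based half-open in memory)."""

    __slots__ = ("contig_id", "source", "ftype", "start", "end", "score", "strand", "attributes")

    def __init__(self, contig_id, source, ftype, start, end, score, strand, attributes):
        self.contig_id = contig_id
        self.source = source
        self.ftype = ftype
        self.start = start
        self.end = end
        self.score = score
        self.strand = strand
        self.attributes = dict(attributes)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={_gff_escape(str(v))}" for k, v in self.attributes.items())
        score = "." if self.score is None else f"{self.score:.3f}"
        return (
            f"{self.contig_id}\t{self.source}\t{self.ftype}\t{self.start + 1}\t{self.end}"
            f"\t{score}\t{self.strand}\t.\t{attrs}"
        )


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.to_line() + "\n")


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise IOFormatError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = {}
            for item in fields[8].split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attrs[key] = _gff_unescape(value)
            features.append(
                Gff3Feature(
                    contig_id=fields[0],
                    source=fields[1],
                    ftype=fields[2],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    score=None if fields[5] == "." else float(fields[5]),
                    strand=fields[6],
                    attributes=attrs,
                )
            )
    return features
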