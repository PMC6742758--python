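"""Sequence I/O and read quality control for virome libraries.

Containers for raw reads plus the three standard pre-processing steps a
virome library goes through before assembly:

* :func:`qc_filter` -- end-trimming at Phred 30, removal of low
  complexity (homopolymer) reads, length-range and ambiguity filters;
* :func:`screen_contamination` -- low-stringency mapping of the surviving
  reads against a decoy (host / bacterial) sequence set, flagging a
  library as contaminated when more than 10% of reads map;
* :func:`read_hit_table` -- import of 12-column tabular alignment output
  (the BLAST ``outfmt 6`` dialect) so an external aligner can replace the
  built-in search engine.

FASTQ quality strings use the Sanger Phred+33 convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import homology

__all__ = [
    "Read",
    "ReadSet",
    "QCReport",
    "ScreenResult",
    "TabularHit",
    "qc_filter",
    "screen_contamination",
    "read_hit_table",
    "write_hit_table",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]

_QC_CATEGORIES = (
    "quality_trim_to_empty",
    "homopolymer",
    "too_short",
    "too_long",
    "ambiguous",
    "host_like",
)


@dataclass
class Read:
    read_id: str
    sequence: str
    quality: Sequence[int]
    source_id: Optional[str] = None  # true origin (virus id or "contaminant")

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class ReadSet:
    sample_id: str
    reads: List[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class QCReport:
    """Accounting of a QC pass; counts always reconcile exactly."""

    input_reads: int
    surviving_reads: int
    removed_by: Dict[str, int]

    def __post_init__(self) -> None:
        for key in _QC_CATEGORIES:
            self.removed_by.setdefault(key, 0)
        if any(v < 0 for v in self.removed_by.values()) or self.surviving_reads < 0:
            raise ValueError("negative counts in QC report")
        if self.surviving_reads + sum(self.removed_by.values()) != self.input_reads:
            raise ValueError("QC report counts do not reconcile")


@dataclass
class ScreenResult:
    mapped_fraction: float
    decision: str  # "pass" | "contaminated"
    threshold: float = 0.10

    def __post_init__(self) -> None:
        expect = "contaminated" if self.mapped_fraction > self.threshold else "pass"
        if self.decision != expect:
            raise ValueError("decision inconsistent with mapped_fraction/threshold")


def _trim_ends(seq: str, qual: Sequence[int], phred_min: int) -> Tuple[str, Sequence[int]]:
    lo, hi = 0, len(seq)
    while lo < hi and qual[lo] < phred_min:
        lo += 1
    while hi > lo and qual[hi - 1] < phred_min:
        hi -= 1
    return seq[lo:hi], qual[lo:hi]


def _max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def qc_filter(
    reads: ReadSet,
    phred_min: int = 30,
    homopolymer_max_run: int = 7,
    length_min: int = 50,
    length_max: int = 300,
    trim: bool = True,
) -> Tuple[ReadSet, QCReport]:
    """Quality-filter a read set; returns surviving reads and a report.

    Order of operations (length is judged after trimming): end-trim both
    ends inward until the terminal base quality reaches ``phred_min``;
    drop reads containing a homopolymer run longer than
    ``homopolymer_max_run`` (i.e. >= 8 identical bases at the default);
    drop reads whose trimmed length falls outside
    [``length_min``, ``length_max``]; drop reads with non-ACGT characters.

    The operation is idempotent: re-filtering its output is a no-op.
    """
    removed = {k: 0 for k in _QC_CATEGORIES}
    kept: List[Read] = []
    for r in reads:
        if trim:
            if len(r.quality) != len(r.sequence):
                raise ValueError(f"read {r.read_id} lacks per-base qualities")
            seq, qual = _trim_ends(r.sequence, r.quality, phred_min)
        else:
            seq, qual = r.sequence, r.quality
        if len(seq) == 0:
            removed["quality_trim_to_empty"] += 1
            continue
        if _max_homopolymer_run(seq) > homopolymer_max_run:
            removed["homopolymer"] += 1
            continue
        if len(seq) < length_min:
            removed["too_short"] += 1
            continue
        if len(seq) > length_max:
            removed["too_long"] += 1
            continue
        if any(ch not in "ACGT" for ch in seq):
            removed["ambiguous"] += 1
            continue
        kept.append(Read(r.read_id, seq, list(qual), r.source_id))
    report = QCReport(
        input_reads=len(reads.reads), surviving_reads=len(kept), removed_by=removed
    )
    return ReadSet(reads.sample_id, kept), report


def screen_contamination(
    reads: ReadSet,
    decoy: Mapping[str, str],
    min_identity: float = 0.80,
    min_read_coverage: float = 0.20,
    contaminated_if_over: float = 0.10,
    seed_k: int = 11,
) -> ScreenResult:
    """Low-stringency screen of reads against decoy genomes.

    A read counts as mapped when any local match against the decoy set
    has identity >= ``min_identity`` over at least ``min_read_coverage``
    of the read length.  The library is called contaminated when the
    mapped fraction exceeds ``contaminated_if_over``.
    """
    if not decoy:
        raise ValueError("decoy sequence set must be non-empty")
    if len(reads.reads) == 0:
        raise ValueError("cannot screen an empty read set")
    qdict = {r.read_id: r.sequence for r in reads}
    hits = homology.find_hits(
        qdict, dict(decoy), seed_k=seed_k, evalue_max=float("inf")
    )
    lengths = {r.read_id: len(r.sequence) for r in reads}
    mapped = set()
    for h in hits:
        if h.identity >= min_identity and (
            h.align_length / lengths[h.query_id] >= min_read_coverage
        ):
            mapped.add(h.query_id)
    frac = len(mapped) / len(reads.reads)
    decision = "contaminated" if frac > contaminated_if_over else "pass"
    return ScreenResult(frac, decision, threshold=contaminated_if_over)


@dataclass
class TabularHit:
    """One row of a 12-column tabular alignment file.

    Coordinates are stored 0-based half-open on entry (converted from
    the file's 1-based inclusive convention).
    """

    query_id: str
    subject_id: str
    identity: float  # proportion in [0, 1]
    align_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float

    def to_homology_hit(
        self, query_length: int, subject_length: int
    ) -> homology.HomologyHit:
        shorter = min(query_length, subject_length)
        strand = "+" if self.subject_end >= self.subject_start else "-"
        return homology.HomologyHit(
            query_id=self.query_id,
            subject_id=self.subject_id,
            identity=self.identity,
            align_length=self.align_length,
            evalue=self.evalue,
            coverage_of_shorter=min(1.0, self.align_length / shorter),
            raw_score=int(round(self.bit_score)),
            strand=strand,
        )


def read_hit_table(path) -> List[TabularHit]:
    """Parse a 12-column tabular hit file (BLAST ``outfmt 6`` dialect).

    Identity percentages are converted to proportions and 1-based
    inclusive coordinates to the 0-based half-open convention, so a file
    interval (1, 100) becomes (0, 100).  Malformed rows raise with their
    line number.  An empty file yields an empty list.
    """
    hits: List[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                hits.append(
                    TabularHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        identity=float(fields[2]) / 100.0,
                        align_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        query_start=qs - 1,
                        query_end=qe,
                        subject_start=ss - 1 if ss <= se else ss,
                        subject_end=se if ss <= se else se - 1,
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
    return hits


def write_hit_table(path, hits: Iterable[homology.HomologyHit]) -> None:
    """Write engine hits in the 12-column tabular dialect.

    The built-in engine does not track coordinates, so query/subject
    intervals are emitted as (1, align_length); raw score stands in for
    the bit score column.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity * 100:.2f}",
                        str(h.align_length),
                        str(h.align_length - round(h.identity * h.align_length)),
                        "0",
                        "1",
                        str(h.align_length),
                        "1",
                        str(h.align_length),
                        f"{h.evalue:.3g}",
                        f"{h.raw_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str], descriptions: Optional[Mapping[str, str]] = None) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=name,
            description=(descriptions or {}).get(name, ""),
        )
        for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path, sample_id: Optional[str] = None) -> ReadSet:
    reads = [
        Read(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(sample_id or Path(str(path)).stem, reads)


def write_fastq(path, reads: ReadSet) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description=r.source_id or "")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
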