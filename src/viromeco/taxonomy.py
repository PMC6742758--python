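"""Taxonomic bucketing of contigs from precomputed best-hit tables.

No live database search happens here: the module consumes annotation
hits (from an external BLASTX/TBLASTX run, or from the synthetic
generator's ground truth) and applies the study's two E-value regimes --
1e-5 to call a contig viral/bacterial/unknown, and the stricter 1e-20 to
accept a virus-family assignment from the best hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd

from .assembly import ContigSet

__all__ = [
    "AnnotationHit",
    "classify_contigs",
    "assign_family",
    "composition_table",
    "read_annotation_table",
    "write_annotation_table",
]

TARGET_CLASSES = ("virus", "bacterium", "other")


@dataclass
class AnnotationHit:
    contig_id: str
    target_class: str  # virus | bacterium | other
    family: Optional[str] = None
    evalue: float = 1.0
    gene_function: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target_class {self.target_class!r}")
        if self.family is not None and self.target_class != "virus":
            raise ValueError("family may only be set on virus hits")


def classify_contigs(
    hits: Iterable[AnnotationHit],
    evalue_max: float = 1e-5,
    contig_ids: Optional[Iterable[str]] = None,
) -> Dict[str, str]:
    """Bucket contigs as viral / bacterial / unknown by best qualifying hit.

    The lowest E-value wins regardless of class; equal E-values break
    alphabetically on the class name (a documented, arbitrary rule).
    Contigs in ``contig_ids`` with no qualifying hit are "unknown".
    """
    best: Dict[str, AnnotationHit] = {}
    for h in hits:
        if h.evalue > evalue_max:
            continue
        cur = best.get(h.contig_id)
        if cur is None or (h.evalue, h.target_class) < (cur.evalue, cur.target_class):
            best[h.contig_id] = h
    buckets = {
        cid: {"virus": "viral", "bacterium": "bacterial", "other": "unknown"}[
            h.target_class
        ]
        for cid, h in best.items()
    }
    for cid in contig_ids or ():
        buckets.setdefault(cid, "unknown")
    return buckets


def assign_family(
    hits: Iterable[AnnotationHit],
    evalue_max: float = 1e-20,
    contig_ids: Optional[Iterable[str]] = None,
) -> Dict[str, str]:
    """Assign a virus family per contig from its best hit under E < 1e-20.

    Only virus-class hits are considered; ties on E break alphabetically
    on family name.  Contigs with no qualifying hit are "unclassified".
    """
    best: Dict[str, AnnotationHit] = {}
    for h in hits:
        if h.target_class != "virus" or h.family is None:
            continue
        if h.evalue >= evalue_max:
            continue
        cur = best.get(h.contig_id)
        if cur is None or (h.evalue, h.family) < (cur.evalue, cur.family):
            best[h.contig_id] = h
    families = {cid: h.family for cid, h in best.items()}
    for cid in contig_ids or ():
        families.setdefault(cid, "unclassified")
    return families


def composition_table(
    assignments: Mapping[str, str],
    contigs: Mapping[str, ContigSet],
    weighting: str = "reads",
) -> pd.DataFrame:
    """Per-sample category proportions (rows = samples, columns = categories).

    ``weighting="reads"`` weights each contig by its read count (the
    convention of the family-composition figures); ``"contigs"`` counts
    each contig once.  Every contig must have an assignment.  Rows sum
    to 1 within 1e-9.
    """
    if weighting not in ("reads", "contigs"):
        raise ValueError("weighting must be 'reads' or 'contigs'")
    rows: Dict[str, Dict[str, float]] = {}
    for sample_id, cset in contigs.items():
        acc: Dict[str, float] = {}
        for c in cset:
            try:
                cat = assignments[c.contig_id]
            except KeyError:
                raise KeyError(f"contig {c.contig_id} has no assignment") from None
            w = c.read_count if weighting == "reads" else 1
            acc[cat] = acc.get(cat, 0.0) + w
        total = sum(acc.values())
        rows[sample_id] = {k: v / total for k, v in acc.items()} if total else {}
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table.reindex(sorted(table.columns), axis=1)
    table.index.name = "sample_id"
    table.attrs["weighting"] = weighting
    return table


def read_annotation_table(path) -> List[AnnotationHit]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    hits = []
    for row in df.itertuples(index=False):
        family = getattr(row, "family", None)
        if pd.isna(family):
            family = None
        func = getattr(row, "gene_function", None)
        if pd.isna(func):
            func = None
        hits.append(
            AnnotationHit(
                contig_id=row.contig_id,
                target_class=row.target_class,
                family=family,
                evalue=float(row.evalue),
                gene_function=func,
            )
        )
    return hits


def write_annotation_table(path, hits: Iterable[AnnotationHit]) -> None:
    hits = list(hits)
    pd.DataFrame(
        {
            "contig_id": [h.contig_id for h in hits],
            "target_class": [h.target_class for h in hits],
            "family": [h.family for h in hits],
            "evalue": [h.evalue for h in hits],
            "gene_function": [h.gene_function for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)
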