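"""Pairwise nucleotide similarity search for contig networks.

A deliberately small, self-contained search engine: exact k-mer seeds,
ungapped extension along the seed diagonal (optimal maximum-scoring
segment on that diagonal, which subsumes x-drop extension for
substitution-only data), and Karlin-Altschul E-values with the published
ungapped +1/-2 parameters (lambda = 1.33, K = 0.621).

Two threshold regimes are exposed on top of the raw hits:

* :func:`hvdi_edges` -- the strict intra-sample regime used to join
  contigs that belong to the same virus (E < 1e-20, alignment spanning
  at least half of the shorter contig and at least 75 bp);
* :func:`sharing_hits` -- the permissive inter-sample regime used to
  score virus sharing between specimens (E < 1e-10).

Real aligner output (12-column tabular hits) can be substituted for this
engine via :func:`viromeco.seqio_qc.read_hit_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "EvalueModel",
    "HomologyHit",
    "find_hits",
    "hvdi_edges",
    "sharing_hits",
    "encode_seq",
    "revcomp",
]

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EvalueModel:
    """Karlin-Altschul statistics for ungapped +1/-2 nucleotide scoring.

    E = K * m * n * exp(-lambda * S), with m and n the summed lengths of
    the query and subject sets (the search space) and S the raw score.
    """

    match_score: int = 1
    mismatch_score: int = -2
    lam: float = 1.33
    K: float = 0.621

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return self.K * float(m) * float(n) * math.exp(-self.lam * raw_score)


DEFAULT_MODEL = EvalueModel()


@dataclass
class HomologyHit:
    """Best ungapped local match for one ordered (query, subject) pair."""

    query_id: str
    subject_id: str
    identity: float
    align_length: int
    evalue: float
    coverage_of_shorter: float
    raw_score: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _as_seq_dict(seqs) -> Dict[str, str]:
    """Normalise contig containers to an ordered {id: sequence} mapping."""
    if isinstance(seqs, Mapping):
        return dict(seqs)
    if hasattr(seqs, "contigs"):  # a ContigSet
        return {c.contig_id: c.consensus for c in seqs.contigs}
    out = {}
    for item in seqs:
        if hasattr(item, "contig_id"):
            out[item.contig_id] = item.consensus
        else:
            cid, seq = item
            out[cid] = seq
    return out


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; positions touching non-ACGT get code -1."""
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    a = arr.astype(np.int64)
    for i in range(k):
        codes = codes * 4 + a[i : i + n]
        bad |= arr[i : i + n] >= 4
    codes[bad] = -1
    return codes


def _best_segment_on_diagonal(
    qa: np.ndarray, sa: np.ndarray, diag: int, match: int, mismatch: int
) -> Tuple[int, int, int]:
    """Optimal maximum-scoring ungapped segment on one diagonal.

    Returns (raw_score, align_length, n_matches); (0, 0, 0) if nothing
    scores positively.  diag is subject_pos - query_pos.
    """
    lq, ls = qa.shape[0], sa.shape[0]
    qstart = max(0, -diag)
    qend = min(lq, ls - diag)
    if qend - qstart < 1:
        return 0, 0, 0
    q = qa[qstart:qend]
    s = sa[qstart + diag : qend + diag]
    ok = (q < 4) & (s < 4)
    is_match = (q == s) & ok
    scores = np.where(is_match, match, mismatch).astype(np.int64)
    scores[~ok] = -(10 ** 6)  # ambiguous columns break alignments
    prefix = np.concatenate(([0], np.cumsum(scores)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    score = int(gains[end])
    if score <= 0:
        return 0, 0, 0
    start = int(np.argmin(prefix[: end + 1]))
    length = end - start + 1
    n_match = int(np.count_nonzero(is_match[start : end + 1]))
    return score, length, n_match


def _collect_diagonals(
    q_codes: np.ndarray,
    sorted_codes: np.ndarray,
    order_pos: np.ndarray,
    order_subj: np.ndarray,
    min_diag_seeds: int,
) -> Dict[int, List[int]]:
    """Map subject index -> list of candidate diagonals with enough seeds."""
    valid = np.nonzero(q_codes >= 0)[0]
    if valid.size == 0:
        return {}
    lo = np.searchsorted(sorted_codes, q_codes[valid], side="left")
    hi = np.searchsorted(sorted_codes, q_codes[valid], side="right")
    counts = hi - lo
    hit_rows = np.nonzero(counts)[0]
    if hit_rows.size == 0:
        return {}
    subj_list: List[np.ndarray] = []
    diag_list: List[np.ndarray] = []
    for r in hit_rows:
        sl = slice(lo[r], hi[r])
        subj_list.append(order_subj[sl])
        diag_list.append(order_pos[sl] - valid[r])
    subj = np.concatenate(subj_list)
    diag = np.concatenate(diag_list)
    # one combined key so np.unique groups (subject, diagonal) pairs
    key = subj.astype(np.int64) * (1 << 32) + (diag + (1 << 31))
    uniq, cnt = np.unique(key, return_counts=True)
    keep = uniq[cnt >= min_diag_seeds]
    out: Dict[int, List[int]] = {}
    for k in keep:
        si = int(k >> 32)
        d = int((k & 0xFFFFFFFF) - (1 << 31))
        out.setdefault(si, []).append(d)
    return out


def find_hits(
    queries,
    subjects,
    seed_k: int = 11,
    model: EvalueModel = DEFAULT_MODEL,
    evalue_max: float = 10.0,
    min_diag_seeds: int = 2,
    search_reverse_strand: bool = True,
) -> List[HomologyHit]:
    """All-vs-all best-hit search between two contig collections.

    Exact ``seed_k``-mer matches nominate (subject, diagonal) candidates;
    each candidate diagonal is scored by its optimal ungapped segment.
    The best-scoring segment per ordered (query, subject) pair and strand
    is kept, and the best strand wins.  ``min_diag_seeds`` (default 2)
    suppresses the background of single chance k-mer matches between
    unrelated contigs; set it to 1 for exhaustive small searches.

    Self pairs (identical ids) are skipped, so a set can be searched
    against itself to build intra-sample networks.
    """
    if seed_k < 4:
        raise ValueError("seed_k must be >= 4")
    qdict = _as_seq_dict(queries)
    sdict = _as_seq_dict(subjects)
    if not qdict or not sdict:
        raise ValueError("find_hits requires non-empty query and subject sets")

    s_ids = list(sdict)
    s_arrs = [encode_seq(sdict[i]) for i in s_ids]
    m_total = sum(len(s) for s in qdict.values())
    n_total = sum(len(s) for s in sdict.values())

    # flat sorted index of subject k-mers
    code_parts, pos_parts, subj_parts = [], [], []
    for si, arr in enumerate(s_arrs):
        codes = _kmer_codes(arr, seed_k)
        keep = codes >= 0
        code_parts.append(codes[keep])
        pos_parts.append(np.nonzero(keep)[0].astype(np.int64))
        subj_parts.append(np.full(int(keep.sum()), si, dtype=np.int64))
    all_codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.int64)
    all_pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
    all_subj = np.concatenate(subj_parts) if subj_parts else np.empty(0, np.int64)
    order = np.argsort(all_codes, kind="stable")
    sorted_codes = all_codes[order]
    order_pos = all_pos[order]
    order_subj = all_subj[order]

    hits: List[HomologyHit] = []
    strands = ["+", "-"] if search_reverse_strand else ["+"]
    for qid, qseq in qdict.items():
        best: Dict[int, Tuple[int, int, int, str]] = {}
        for strand in strands:
            seq = qseq if strand == "+" else revcomp(qseq)
            qa = encode_seq(seq)
            q_codes = _kmer_codes(qa, seed_k)
            cand = _collect_diagonals(
                q_codes, sorted_codes, order_pos, order_subj, min_diag_seeds
            )
            for si, diags in cand.items():
                if s_ids[si] == qid:
                    continue
                for d in diags:
                    score, length, n_match = _best_segment_on_diagonal(
                        qa, s_arrs[si], d, model.match_score, model.mismatch_score
                    )
                    if score <= 0:
                        continue
                    prev = best.get(si)
                    if prev is None or score > prev[0]:
                        best[si] = (score, length, n_match, strand)
        for si, (score, length, n_match, strand) in sorted(best.items()):
            ev = model.evalue(score, m_total, n_total)
            if ev > evalue_max:
                continue
            shorter = min(len(qdict[qid]), len(sdict[s_ids[si]]))
            hits.append(
                HomologyHit(
                    query_id=qid,
                    subject_id=s_ids[si],
                    identity=n_match / length,
                    align_length=length,
                    evalue=ev,
                    coverage_of_shorter=min(1.0, length / shorter),
                    raw_score=score,
                    strand=strand,
                )
            )
    return hits


def hvdi_edges(
    hits: Iterable[HomologyHit],
    evalue_max: float = 1e-20,
    min_coverage_of_shorter: float = 0.50,
    min_align_length: int = 75,
) -> List[Tuple[str, str]]:
    """Strict intra-virome edges joining contigs of one putative virus.

    A hit becomes an undirected edge when E < ``evalue_max``, the
    alignment spans at least ``min_coverage_of_shorter`` of the shorter
    contig, and is at least ``min_align_length`` bp long.  Self hits are
    excluded and duplicate orientations collapsed.
    """
    edges = set()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue >= evalue_max:
            continue
        if h.coverage_of_shorter < min_coverage_of_shorter:
            continue
        if h.align_length < min_align_length:
            continue
        a, b = sorted((h.query_id, h.subject_id))
        edges.add((a, b))
    return sorted(edges)


def sharing_hits(
    hits: Iterable[HomologyHit], evalue_max: float = 1e-10
) -> List[HomologyHit]:
    """Permissive inter-virome regime: keep hits with E < ``evalue_max``."""
    return [h for h in hits if h.evalue < evalue_max]
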