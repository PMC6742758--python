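"""Cross-virome beta diversity and virus-sharing attribution.

The feature table behind beta diversity is the *homology profile*: cell
(i, j) is the read-weighted fraction of sample i's contigs that have at
least one permissive-regime hit (E < 1e-10) among sample j's contigs,
with the diagonal fixed at 1.  Profile rows feed Bray-Curtis
dissimilarities, metric ordination (PCoA via Gower double-centering),
and a one-way PERMANOVA with a permutation p-value.

"Co-assembly" sharing attribution is realised as connected components
of the pooled cross-sample homology network (deterministic and
equivalent in what it measures to re-assembling pooled reads): each
component records which specimen types and subjects contributed, giving
the sharing-percentage matrix and the subject-membership spectrum.

The within/between specimen-type permutation test draws, per iteration,
a random cross-type sample pair and a fixed number of random contigs,
and refers a single same-type draw of the same form to that null; with
the +1 convention the p-value is exact under exchangeability and never
zero.

Pooled contig ids use the ``"sample|contig"`` convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

from .assembly import ContigSet
from .homology import HomologyHit

__all__ = [
    "SampleMeta",
    "SharingComponent",
    "PermanovaResult",
    "PermTestResult",
    "OrdinationResult",
    "pooled_sequences",
    "pooled_sample_of",
    "homology_profile",
    "bray_curtis",
    "pcoa",
    "permanova",
    "coassembly_components",
    "sharing_matrix",
    "subject_membership_spectrum",
    "within_between_test",
]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    specimen_type: str
    subject_id: str


def pooled_sequences(contig_sets: Mapping[str, ContigSet]) -> Dict[str, str]:
    """Globalise contig ids as ``"sample|contig"`` for a pooled search."""
    out: Dict[str, str] = {}
    for sample_id, cset in contig_sets.items():
        if "|" in sample_id:
            raise ValueError("sample ids must not contain '|'")
        for c in cset:
            out[f"{sample_id}|{c.contig_id}"] = c.consensus
    return out


def pooled_sample_of(pooled_id: str) -> str:
    return pooled_id.split("|", 1)[0]


def homology_profile(
    contig_sets: Mapping[str, ContigSet],
    cross_hits: Iterable[HomologyHit],
) -> pd.DataFrame:
    """Read-weighted sharing profile over all ordered sample pairs.

    cell(i, j) = (reads on sample i's contigs with >= 1 qualifying hit
    against sample j) / (total reads of sample i); diagonal = 1.
    ``cross_hits`` must already be filtered to the permissive sharing
    regime and use pooled ``"sample|contig"`` ids.
    """
    samples = list(contig_sets)
    hit_contigs: Dict[Tuple[str, str], Set[str]] = {}
    for h in cross_hits:
        qs = pooled_sample_of(h.query_id)
        ss = pooled_sample_of(h.subject_id)
        if qs == ss:
            continue
        hit_contigs.setdefault((qs, ss), set()).add(h.query_id)
    mat = np.eye(len(samples))
    for a, sample_a in enumerate(samples):
        total = contig_sets[sample_a].total_reads
        if total == 0:
            raise ValueError(f"sample {sample_a} has no reads")
        reads = {
            f"{sample_a}|{c.contig_id}": c.read_count
            for c in contig_sets[sample_a]
        }
        for b, sample_b in enumerate(samples):
            if a == b:
                continue
            hitset = hit_contigs.get((sample_a, sample_b), set())
            mat[a, b] = sum(reads[cid] for cid in hitset if cid in reads) / total
    return pd.DataFrame(mat, index=samples, columns=samples)


def bray_curtis(profile: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between profile rows.

    BC_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); symmetric, zero
    diagonal, entries in [0, 1] for nonnegative rows.
    """
    x = profile.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _braycurtis(x[i], x[j])
    return pd.DataFrame(d, index=profile.index, columns=profile.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over retained (positive) axes


def pcoa(dist: pd.DataFrame, tol: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Gower double-centering of -d^2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are reported but their axes are
    dropped.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    pos_sum = vals[keep].sum()
    prop = vals[keep] / pos_sum if pos_sum > 0 else vals[keep]
    frame = pd.DataFrame(
        coords,
        index=dist.index,
        columns=[f"PC{i + 1}" for i in range(int(keep.sum()))],
    )
    return OrdinationResult(frame, vals, prop)


@dataclass
class PermanovaResult:
    F: float
    R2: float
    p: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.R2 <= 1.0 + 1e-12):
            raise ValueError("R2 must be in [0, 1]")
        lo = 1.0 / (self.n_permutations + 1)
        if not (lo - 1e-12 <= self.p <= 1.0 + 1e-12):
            raise ValueError("p outside permutation support")


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> Tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.nonzero(codes == g)[0]
        if members.size == 0:
            raise ValueError("every group must have at least one sample")
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += float(np.triu(sub, k=1).sum()) / members.size
    return ss_total, ss_within


def permanova(
    dist: pd.DataFrame,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (pseudo-F on a distance matrix).

    SS_total = (1/N) sum_{i<j} d_ij^2, SS_within the analogous per-group
    sums, F = (SS_between / (a - 1)) / (SS_within / (N - a)).  The
    p-value permutes labels ``n_permutations`` times, counting ties as
    extreme with the +1 convention, so p >= 1 / (n_permutations + 1).
    """
    labels = list(labels)
    n = dist.shape[0]
    if len(labels) != n:
        raise ValueError("one label per sample required")
    uniq = sorted(set(labels))
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least two groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    codes = np.array([uniq.index(l) for l in labels])
    d2 = dist.to_numpy(dtype=float) ** 2

    ss_total, ss_within = _permanova_ss(d2, codes, a)
    ss_between = ss_total - ss_within
    if ss_within <= 0 or n - a <= 0:
        f_obs = math.inf if ss_between > 0 else 0.0
    else:
        f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        _, ssw = _permanova_ss(d2, perm, a)
        ssb = ss_total - ssw
        if ssw <= 0:
            f_perm = math.inf if ssb > 0 else 0.0
        else:
            f_perm = (ssb / (a - 1)) / (ssw / (n - a))
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(F=f_obs, R2=min(1.0, max(0.0, r2)), p=p, n_permutations=n_permutations)


@dataclass
class SharingComponent:
    """A pooled homology component with its contributing samples."""

    component_id: str
    members: List[Tuple[str, str]]  # (pooled contig id, sample_id)
    types_present: Set[str]
    subjects_present: Set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a sharing component needs >= 1 member")


def coassembly_components(
    contig_sets: Mapping[str, ContigSet],
    cross_hits: Iterable[HomologyHit],
    sample_meta: Mapping[str, SampleMeta],
    evalue_max: float = 1e-10,
    min_coverage_of_shorter: float = 0.50,
    min_align_length: int = 75,
) -> List[SharingComponent]:
    """Connected components of the pooled sharing network.

    Edges are hits passing the permissive E-value plus the same coverage
    rules used for intra-sample virus networks, applied to the pooled
    contig set; every pooled contig is a node, so contigs without edges
    form single-sample components.
    """
    nodes = [
        f"{sample_id}|{c.contig_id}"
        for sample_id, cset in contig_sets.items()
        for c in cset
    ]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for h in cross_hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue >= evalue_max:
            continue
        if h.coverage_of_shorter < min_coverage_of_shorter:
            continue
        if h.align_length < min_align_length:
            continue
        g.add_edge(h.query_id, h.subject_id)
    comps = []
    for i, members in enumerate(
        sorted(nx.connected_components(g), key=lambda ns: min(ns))
    ):
        pairs = sorted((cid, pooled_sample_of(cid)) for cid in members)
        samples = {s for _, s in pairs}
        comps.append(
            SharingComponent(
                component_id=f"share{i:05d}",
                members=pairs,
                types_present={sample_meta[s].specimen_type for s in samples},
                subjects_present={sample_meta[s].subject_id for s in samples},
            )
        )
    return comps


def sharing_matrix(
    components: Iterable[SharingComponent],
    specimen_types: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Type-by-type sharing percentages.

    cell(X, Y) = 100 * (#components containing X that also contain Y) /
    (#components containing X); the diagonal is 100 and the matrix need
    not be symmetric.
    """
    components = list(components)
    types = (
        list(specimen_types)
        if specimen_types is not None
        else sorted({t for c in components for t in c.types_present})
    )
    mat = np.zeros((len(types), len(types)))
    for xi, x in enumerate(types):
        with_x = [c for c in components if x in c.types_present]
        for yi, y in enumerate(types):
            if not with_x:
                mat[xi, yi] = float("nan")
            else:
                mat[xi, yi] = 100.0 * sum(
                    1 for c in with_x if y in c.types_present
                ) / len(with_x)
    return pd.DataFrame(mat, index=types, columns=types)


def subject_membership_spectrum(
    components: Iterable[SharingComponent], n_subjects: int
) -> Tuple[Dict[int, int], float]:
    """Histogram of components by contributing-subject count, plus the
    fraction of components derived from every subject."""
    components = list(components)
    if not components:
        return {}, 0.0
    hist: Dict[int, int] = {}
    universal = 0
    for c in components:
        k = len(c.subjects_present)
        hist[k] = hist.get(k, 0) + 1
        if k == n_subjects:
            universal += 1
    return dict(sorted(hist.items())), universal / len(components)


@dataclass
class PermTestResult:
    specimen_type: str
    observed_within: float  # mean over ordered same-type pairs, full contigs
    observed_between: float  # mean over ordered cross-type pairs from this type
    statistic: float  # single subsampled same-type draw referred to the null
    null_draws: np.ndarray
    p: float
    n_iterations: int

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_iterations + 1)
        if not (lo - 1e-12 <= self.p <= 1.0 + 1e-12):
            raise ValueError("p outside permutation support")


def _pair_tables(
    contig_sets: Mapping[str, ContigSet],
    cross_hits: Iterable[HomologyHit],
):
    """Per-sample contig read vectors and per-ordered-pair hit masks."""
    reads: Dict[str, np.ndarray] = {}
    index: Dict[str, Dict[str, int]] = {}
    for sample_id, cset in contig_sets.items():
        ids = [f"{sample_id}|{c.contig_id}" for c in cset]
        index[sample_id] = {cid: i for i, cid in enumerate(ids)}
        reads[sample_id] = np.array([c.read_count for c in cset], dtype=float)
    masks: Dict[Tuple[str, str], np.ndarray] = {}
    for h in cross_hits:
        qs = pooled_sample_of(h.query_id)
        ss = pooled_sample_of(h.subject_id)
        if qs == ss or qs not in index or ss not in index:
            continue
        key = (qs, ss)
        if key not in masks:
            masks[key] = np.zeros(len(index[qs]), dtype=bool)
        pos = index[qs].get(h.query_id)
        if pos is not None:
            masks[key][pos] = True
    return reads, masks


def _pair_fraction(
    reads_i: np.ndarray, mask: Optional[np.ndarray]
) -> float:
    if mask is None:
        return 0.0
    total = reads_i.sum()
    return float(reads_i[mask].sum() / total) if total > 0 else 0.0


def _subsampled_fraction(
    reads_i: np.ndarray,
    mask: Optional[np.ndarray],
    contigs_per_draw: int,
    rng: np.random.Generator,
) -> float:
    n = reads_i.shape[0]
    if contigs_per_draw >= n:
        idx = rng.integers(0, n, size=contigs_per_draw)  # with replacement
    else:
        idx = rng.choice(n, size=contigs_per_draw, replace=False)
    r = reads_i[idx]
    hit = mask[idx] if mask is not None else np.zeros(idx.shape[0], dtype=bool)
    total = r.sum()
    return float(r[hit].sum() / total) if total > 0 else 0.0


def within_between_test(
    contig_sets: Mapping[str, ContigSet],
    cross_hits: Iterable[HomologyHit],
    sample_meta: Mapping[str, SampleMeta],
    n_iterations: int = 10_000,
    contigs_per_draw: int = 1000,
    seed: int = 0,
) -> Dict[str, PermTestResult]:
    """Per-specimen-type permutation test of within- vs between-type sharing.

    For type T the reported ``observed_within`` is the mean read-weighted
    shared fraction over ordered same-type sample pairs, and
    ``observed_between`` the analogous cross-type mean.  The p-value is
    computed by referring one randomly drawn same-type pair statistic
    (``contigs_per_draw`` random contigs, with replacement when a sample
    has fewer) to a null of ``n_iterations`` equally constructed draws
    over random cross-type pairs with the source sample in T:
    p = (1 + #{null >= statistic}) / (n_iterations + 1).  Observed draw
    and null draws are exchangeable when sharing carries no type signal,
    making the p-value exactly calibrated.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if contigs_per_draw < 1:
        raise ValueError("contigs_per_draw must be >= 1")
    samples = list(contig_sets)
    types = sorted({sample_meta[s].specimen_type for s in samples})
    if len(types) < 2:
        raise ValueError("need at least two specimen types")
    by_type: Dict[str, List[str]] = {t: [] for t in types}
    for s in samples:
        by_type[sample_meta[s].specimen_type].append(s)
    reads, masks = _pair_tables(contig_sets, cross_hits)

    results: Dict[str, PermTestResult] = {}
    rng = np.random.default_rng(seed)
    for t in types:
        members = by_type[t]
        if len(members) < 2:
            raise ValueError(
                f"specimen type {t!r} has {len(members)} sample(s); the "
                "within-type statistic needs at least two"
            )
        others = [s for s in samples if sample_meta[s].specimen_type != t]
        within_pairs = [(i, j) for i in members for j in members if i != j]
        between_pairs = [(i, j) for i in members for j in others]
        obs_within = float(
            np.mean([_pair_fraction(reads[i], masks.get((i, j))) for i, j in within_pairs])
        )
        obs_between = (
            float(
                np.mean(
                    [_pair_fraction(reads[i], masks.get((i, j))) for i, j in between_pairs]
                )
            )
            if between_pairs
            else 0.0
        )
        wi, wj = within_pairs[rng.integers(0, len(within_pairs))]
        statistic = _subsampled_fraction(
            reads[wi], masks.get((wi, wj)), contigs_per_draw, rng
        )
        null = np.empty(n_iterations)
        for it in range(n_iterations):
            bi, bj = between_pairs[rng.integers(0, len(between_pairs))]
            null[it] = _subsampled_fraction(
                reads[bi], masks.get((bi, bj)), contigs_per_draw, rng
            )
        p = (1 + int(np.count_nonzero(null >= statistic))) / (n_iterations + 1)
        results[t] = PermTestResult(
            specimen_type=t,
            observed_within=obs_within,
            observed_between=obs_between,
            statistic=statistic,
            null_draws=null,
            p=p,
            n_iterations=n_iterations,
        )
    return results
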