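"""Synthetic virome communities with known ground truth.

Every downstream stage of the package (QC, assembly, homology networks,
diversity, sharing) is exercised on communities built here, because the
raw viromes this kind of study sequences are rarely deposited.  The
generator plants the ecological structure the analyses are meant to
recover:

* a panel of random virus "genomes" carrying family labels;
* two diversity clusters of specimen types -- a *high* cluster
  (feces / saliva / urine-like, many viruses per sample) and a *low*
  cluster (CSF / plasma / body-fluid / milk-like, few viruses) -- with
  controlled virus sharing within and between the clusters;
* per-sample reads (substitution errors only, forward strand) or, as a
  fast path that bypasses assembly, per-sample contigs cut from the
  genomes as overlapping windows so that the homology network can
  re-join them.

All generators are pure functions of their parameters and seed, and the
planted truth (membership, abundances, per-contig source virus) is
always emitted alongside the sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import Contig, ContigSet
from .homology import HomologyHit
from .seqio_qc import Read, ReadSet
from .taxonomy import AnnotationHit

__all__ = [
    "FAMILIES",
    "DEFAULT_FAMILY_WEIGHTS",
    "Virus",
    "VirusPanel",
    "SampleSpec",
    "SampleCommunity",
    "CommunityDesign",
    "generate_panel",
    "default_sample_plan",
    "generate_communities",
    "decoy_genome",
    "generate_reads",
    "fragment_to_contigs",
    "truth_annotation_hits",
    "truth_hits",
]

FAMILIES = (
    "Myoviridae",
    "Siphoviridae",
    "Podoviridae",
    "Microviridae",
    "Inoviridae",
    "other-dsDNA",
    "eukaryotic-virus",
)

# phage-dominated mixture typical of body-fluid viromes
DEFAULT_FAMILY_WEIGHTS = {
    "Myoviridae": 0.24,
    "Siphoviridae": 0.28,
    "Podoviridae": 0.18,
    "Microviridae": 0.10,
    "Inoviridae": 0.08,
    "other-dsDNA": 0.08,
    "eukaryotic-virus": 0.04,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Virus:
    virus_id: str
    genome: str
    family: str
    lifestyle: str  # lytic | temperate


@dataclass
class VirusPanel:
    viruses: List[Virus]

    def __post_init__(self) -> None:
        ids = [v.virus_id for v in self.viruses]
        if len(set(ids)) != len(ids):
            raise ValueError("virus ids must be unique")
        for v in self.viruses:
            if set(v.genome) - set("ACGT"):
                raise ValueError(f"{v.virus_id}: genome alphabet must be ACGT")

    def __len__(self) -> int:
        return len(self.viruses)

    def __iter__(self):
        return iter(self.viruses)

    def by_id(self, virus_id: str) -> Virus:
        return self._index()[virus_id]

    def _index(self) -> Dict[str, Virus]:
        if not hasattr(self, "_idx"):
            object.__setattr__(self, "_idx", {v.virus_id: v for v in self.viruses})
        return self._idx

    def family_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for v in self.viruses:
            out[v.family] = out.get(v.family, 0) + 1
        return out


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_panel(
    n_viruses: int,
    length_range: Tuple[int, int] = (2000, 6000),
    family_weights: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> VirusPanel:
    """Random virus panel: i.i.d. genomes, multinomial family labels.

    Genomes are uniform random nucleotide strings, which makes distinct
    panel viruses effectively unrelated -- exactly the property the
    homology stages rely on to separate planted structure from noise.
    Siphovirus-like entries are biased toward temperate lifestyles.
    """
    if n_viruses < 1:
        raise ValueError("n_viruses must be >= 1")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("invalid genome length range")
    weights = dict(family_weights or DEFAULT_FAMILY_WEIGHTS)
    unknown = set(weights) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families in weights: {sorted(unknown)}")
    w = np.array([float(weights.get(f, 0.0)) for f in FAMILIES])
    if (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("family weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    fams = rng.choice(len(FAMILIES), size=n_viruses, p=w / w.sum())
    lengths = rng.integers(lo, hi + 1, size=n_viruses)
    viruses = []
    for i in range(n_viruses):
        family = FAMILIES[fams[i]]
        p_temperate = 0.7 if family == "Siphoviridae" else 0.3
        viruses.append(
            Virus(
                virus_id=f"virus_{i:04d}",
                genome=_random_genome(rng, int(lengths[i])),
                family=family,
                lifestyle="temperate" if rng.random() < p_temperate else "lytic",
            )
        )
    return VirusPanel(viruses)


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    specimen_type: str
    diversity_cluster: str  # high | low
    subject_id: str


HIGH_TYPES = ("feces", "saliva", "urine", "skin")
LOW_TYPES = ("csf", "plasma", "body_fluid", "milk")


def default_sample_plan(
    samples_per_type: int = 3,
    high_types: Sequence[str] = HIGH_TYPES,
    low_types: Sequence[str] = LOW_TYPES,
) -> List[SampleSpec]:
    """Two-cluster study layout: each specimen type contributes
    ``samples_per_type`` samples, one subject per sample."""
    plan, subject = [], 0
    for cluster, types in (("high", high_types), ("low", low_types)):
        for t in types:
            for i in range(samples_per_type):
                subject += 1
                plan.append(
                    SampleSpec(f"{t}_{i + 1}", t, cluster, f"S{subject:03d}")
                )
    return plan


@dataclass
class SampleCommunity:
    sample_id: str
    specimen_type: str
    diversity_cluster: str
    subject_id: str
    virus_ids: List[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        if len(self.virus_ids) != len(self.abundances):
            raise ValueError("abundance vector length mismatch")
        if abs(float(np.sum(self.abundances)) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def richness(self) -> int:
        return len(self.virus_ids)


@dataclass
class CommunityDesign:
    samples: List[SampleCommunity]
    within_sharing: float
    between_sharing: float
    seed: int

    def __iter__(self):
        return iter(self.samples)

    def membership(self) -> Dict[str, frozenset]:
        return {s.sample_id: frozenset(s.virus_ids) for s in self.samples}

    def true_richness(self) -> Dict[str, int]:
        return {s.sample_id: s.richness for s in self.samples}

    def mean_jaccard(self, within_cluster: bool) -> float:
        vals = []
        for i, a in enumerate(self.samples):
            for b in self.samples[i + 1 :]:
                same = a.diversity_cluster == b.diversity_cluster
                if same != within_cluster:
                    continue
                sa, sb = set(a.virus_ids), set(b.virus_ids)
                vals.append(len(sa & sb) / len(sa | sb))
        return float(np.mean(vals)) if vals else float("nan")


def generate_communities(
    panel: VirusPanel,
    plan: Optional[Sequence[SampleSpec]] = None,
    n_viruses_high: int = 40,
    n_viruses_low: int = 8,
    within_sharing: float = 0.7,
    between_sharing: float = 0.1,
    abundance_exponent: float = 1.0,
    pool_factor: float = 3.0,
    seed: int = 0,
) -> CommunityDesign:
    """Plant two-cluster community structure over a virus panel.

    Each cluster owns a deterministic *core* of ``ceil(within_sharing *
    richness)`` viruses present in every sample of the cluster; the
    remaining slots per sample are drawn without replacement from a
    cluster-private pool.  A *bridge* set of ``round(between_sharing *
    min(richness))`` viruses is shared by both cluster cores, so
    ``between_sharing = 0`` guarantees that no virus occurs in both
    clusters, and ``within_sharing = 1`` makes all samples of a cluster
    identical.  High-cluster samples always carry strictly more viruses
    than low-cluster samples (``n_viruses_high > n_viruses_low`` is
    enforced).  Per-sample relative abundances follow a power law with
    exponent ``abundance_exponent`` over a random virus order, mimicking
    the uneven populations seen in real body-fluid viromes.
    """
    for name, p in (("within_sharing", within_sharing), ("between_sharing", between_sharing)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if n_viruses_high <= n_viruses_low:
        raise ValueError("n_viruses_high must exceed n_viruses_low")
    if n_viruses_low < 1:
        raise ValueError("cluster richness must be >= 1")
    plan = list(plan) if plan is not None else default_sample_plan()
    if len({s.specimen_type for s in plan}) < 2:
        raise ValueError("need at least two specimen types")

    richness = {"high": n_viruses_high, "low": n_viruses_low}
    core_size = {c: math.ceil(within_sharing * n) for c, n in richness.items()}
    n_bridge = min(
        int(round(between_sharing * min(richness.values()))), *core_size.values()
    )
    free = {c: richness[c] - core_size[c] for c in richness}
    pool_size = {c: int(math.ceil(pool_factor * free[c])) if free[c] else 0 for c in free}

    need = (
        n_bridge
        + sum(core_size[c] - n_bridge for c in richness)
        + sum(pool_size.values())
    )
    ids = [v.virus_id for v in panel]
    if need > len(ids):
        raise ValueError(f"panel too small: need {need} viruses, have {len(ids)}")

    cursor = 0

    def take(n: int) -> List[str]:
        nonlocal cursor
        out = ids[cursor : cursor + n]
        cursor += n
        return out

    bridge = take(n_bridge)
    core = {c: bridge + take(core_size[c] - n_bridge) for c in ("high", "low")}
    pool = {c: take(pool_size[c]) for c in ("high", "low")}

    rng = np.random.default_rng(seed)
    samples = []
    for spec in plan:
        c = spec.diversity_cluster
        if c not in richness:
            raise ValueError(f"unknown diversity cluster {c!r}")
        extras = (
            sorted(rng.choice(pool[c], size=free[c], replace=False).tolist())
            if free[c]
            else []
        )
        virus_ids = core[c] + extras
        ranks = rng.permutation(len(virus_ids)) + 1.0
        weights = ranks ** (-abundance_exponent)
        samples.append(
            SampleCommunity(
                sample_id=spec.sample_id,
                specimen_type=spec.specimen_type,
                diversity_cluster=c,
                subject_id=spec.subject_id,
                virus_ids=virus_ids,
                abundances=weights / weights.sum(),
            )
        )
    return CommunityDesign(samples, within_sharing, between_sharing, seed)


def decoy_genome(seed: int, length: int = 100_000) -> str:
    """Synthetic "bacterial" decoy genome used for the contamination screen."""
    rng = np.random.default_rng([int(seed) % (2**31), 222])
    return _random_genome(rng, length)


def generate_reads(
    design: CommunityDesign,
    panel: VirusPanel,
    depth: int = 2000,
    read_length_mean: int = 150,
    read_length_sd: int = 10,
    error_rate: float = 0.0,
    contaminant_fraction: float = 0.0,
    seed: int = 0,
) -> Dict[str, ReadSet]:
    """Simulate shotgun reads per sample.

    Reads are forward-strand substrings of the source genomes, virus
    chosen by planted abundance, with i.i.d. substitution errors at
    ``error_rate`` and constant per-base qualities consistent with that
    rate (Q = -10 log10(error_rate), capped at Q40).  A
    ``contaminant_fraction`` of reads is drawn from the synthetic decoy
    genome instead and tagged ``"contaminant"``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 <= error_rate <= 0.2):
        raise ValueError("error_rate must be in [0, 0.2]")
    if not (0.0 <= contaminant_fraction <= 1.0):
        raise ValueError("contaminant_fraction must be in [0, 1]")
    if not design.samples:
        raise ValueError("community design has no samples")
    qual = 40 if error_rate <= 0 else int(np.clip(round(-10 * math.log10(error_rate)), 2, 40))
    decoy = decoy_genome(seed)
    rng = np.random.default_rng(seed)
    out: Dict[str, ReadSet] = {}
    for sample in design:
        genomes = [panel.by_id(v).genome for v in sample.virus_ids]
        reads: List[Read] = []
        contam = rng.random(depth) < contaminant_fraction
        choices = rng.choice(len(genomes), size=depth, p=sample.abundances)
        lengths = np.clip(
            np.rint(rng.normal(read_length_mean, read_length_sd, size=depth)),
            60,
            290,
        ).astype(int)
        for i in range(depth):
            if contam[i]:
                src, source_id = decoy, "contaminant"
            else:
                src, source_id = genomes[choices[i]], sample.virus_ids[choices[i]]
            L = min(int(lengths[i]), len(src))
            start = int(rng.integers(0, len(src) - L + 1))
            frag = src[start : start + L]
            if error_rate > 0:
                arr = np.frombuffer(frag.encode(), dtype=np.uint8).copy()
                errs = np.nonzero(rng.random(L) < error_rate)[0]
                for pos in errs:
                    base = "ACGT".replace(chr(arr[pos]), "")
                    arr[pos] = ord(base[rng.integers(0, 3)])
                frag = arr.tobytes().decode()
            reads.append(
                Read(
                    read_id=f"{sample.sample_id}_r{i:06d}",
                    sequence=frag,
                    quality=[qual] * L,
                    source_id=source_id,
                )
            )
        out[sample.sample_id] = ReadSet(sample.sample_id, reads)
    return out


def _windows(genome_len: int, k: int, overlap_fraction: float) -> List[Tuple[int, int]]:
    """k equal-length windows covering the genome, consecutive windows
    overlapping by ``overlap_fraction`` of the window length."""
    if k == 1:
        return [(0, genome_len)]
    W = math.ceil(genome_len / (k * (1 - overlap_fraction) + overlap_fraction))
    W = min(W, genome_len)
    step = max(1, int(W * (1 - overlap_fraction)))
    starts = [min(i * step, genome_len - W) for i in range(k)]
    starts[-1] = genome_len - W
    return [(s, s + W) for s in starts]


def fragment_to_contigs(
    design: CommunityDesign,
    panel: VirusPanel,
    fragmentation: float = 2.0,
    overlap_fraction: float = 0.6,
    reads_per_virus: int = 50,
    split_exponent: float = 1.5,
    seed: int = 0,
) -> Tuple[Dict[str, ContigSet], pd.DataFrame]:
    """Fast path to per-sample contigs, bypassing read-level assembly.

    Each virus present in a sample is cut into ``round(fragmentation)``
    equal windows; consecutive windows overlap by ``overlap_fraction``
    of their length so that the strict homology regime (E < 1e-20 over
    >= 50% of the shorter contig) can chain them back into one network
    component -- the situation HVDI is designed to correct.  Per-virus
    read totals follow the planted abundances (``reads_per_virus`` x
    richness reads per sample) and are split across the virus's windows
    by power-law weights with ``split_exponent``, every window keeping
    at least one read.

    Returns the per-sample contig sets and a tidy ground-truth table
    (sample_id, contig_id, true_virus_id, read_count, family).
    """
    if fragmentation < 1:
        raise ValueError("fragmentation must be >= 1")
    if not (0.0 < overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in (0, 1)")
    k = max(1, int(round(fragmentation)))
    rng = np.random.default_rng(seed)
    contig_sets: Dict[str, ContigSet] = {}
    truth_rows = []
    for sample in design:
        total_reads = reads_per_virus * sample.richness
        contigs: List[Contig] = []
        idx = 0
        for v_id, p in zip(sample.virus_ids, sample.abundances):
            virus = panel.by_id(v_id)
            wins = _windows(len(virus.genome), k, overlap_fraction)
            n_v = max(1, int(round(p * total_reads)))
            if n_v >= len(wins):
                w = (rng.permutation(len(wins)) + 1.0) ** (-split_exponent)
                counts = 1 + rng.multinomial(n_v - len(wins), w / w.sum())
            else:
                counts = np.ones(len(wins), dtype=int)
            for (s, e), cnt in zip(wins, counts):
                # globally unique id: annotation tables are keyed by contig id
                cid = f"{sample.sample_id}.g{idx:05d}"
                idx += 1
                contigs.append(
                    Contig(
                        contig_id=cid,
                        consensus=virus.genome[s:e],
                        read_count=int(cnt),
                        member_read_ids=[],
                        sample_id=sample.sample_id,
                        true_virus_id=v_id,
                    )
                )
                truth_rows.append(
                    (sample.sample_id, cid, v_id, int(cnt), virus.family)
                )
        contig_sets[sample.sample_id] = ContigSet(sample.sample_id, contigs)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "contig_id", "true_virus_id", "read_count", "family"],
    )
    return contig_sets, truth


def truth_annotation_hits(
    truth: pd.DataFrame,
    weak_fraction: float = 0.0,
    seed: int = 0,
) -> List[AnnotationHit]:
    """Annotation hits derived from planted truth.

    Each contig gets a virus-class best hit labelled with its source
    family at a strong E-value (below every threshold); a
    ``weak_fraction`` of contigs instead receive an E-value between the
    classification (1e-5) and family (1e-20) cutoffs, ending up viral
    but family-unclassified.  Contigs tagged ``contaminant`` get
    bacterial hits.
    """
    rng = np.random.default_rng(seed)
    hits = []
    for row in truth.itertuples(index=False):
        if row.true_virus_id == "contaminant":
            hits.append(
                AnnotationHit(row.contig_id, "bacterium", None, 1e-40, "16S-like")
            )
            continue
        weak = rng.random() < weak_fraction
        ev = 10.0 ** (-rng.uniform(8, 18)) if weak else 10.0 ** (-rng.uniform(25, 60))
        hits.append(
            AnnotationHit(
                contig_id=row.contig_id,
                target_class="virus",
                family=row.family,
                evalue=float(ev),
                gene_function="structural",
            )
        )
    return hits


def truth_hits(
    contig_sets: Mapping[str, ContigSet],
    evalue: float = 1e-30,
    include_within_sample: bool = True,
) -> List[HomologyHit]:
    """Idealised homology hits: one hit per ordered pair of pooled
    contigs that share a ``true_virus_id``.

    Contig ids are globalised as ``"sample|contig"`` to match the pooled
    convention in :mod:`viromeco.beta_sharing`.  Useful as an oracle for
    sharing-attribution tests and as a fast stand-in for the search
    engine in calibration studies.
    """
    by_virus: Dict[str, List[Tuple[str, str, int]]] = {}
    for sample_id, cset in contig_sets.items():
        for c in cset:
            if c.true_virus_id is None:
                continue
            by_virus.setdefault(c.true_virus_id, []).append(
                (f"{sample_id}|{c.contig_id}", sample_id, len(c))
            )
    hits: List[HomologyHit] = []
    for members in by_virus.values():
        for qid, qsample, qlen in members:
            for sid, ssample, slen in members:
                if qid == sid:
                    continue
                if not include_within_sample and qsample == ssample:
                    continue
                length = min(qlen, slen)
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=sid,
                        identity=1.0,
                        align_length=length,
                        evalue=evalue,
                        coverage_of_shorter=1.0,
                        raw_score=length,
                    )
                )
    return hits
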