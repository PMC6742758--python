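"""End-to-end orchestration: simulate -> (QC/assemble) -> homology ->
HVDI -> beta/sharing/permutation -> taxonomy -> report.

A run is a pure function of (config, seed): per-stage seeds are derived
from the global seed by hashing the stage name, and the manifest records
a checksum of every output so reruns can be verified byte-for-byte.

Two simulation modes are supported.  ``contigs`` (the default) cuts
virus genomes directly into overlapping contig windows -- the fast path
that preserves exactly the contig-spectrum structure the diversity
stages consume.  ``reads`` simulates shotgun reads and exercises the QC
and assembly stages as well; it is intended for small depths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import alpha_hvdi, assembly, beta_sharing, homology, seqio_qc, simgen, taxonomy

__all__ = ["PipelineConfig", "RunManifest", "stage_seed", "run_pipeline", "make_report"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults reproduce the study parameters."""

    seed: int = 0
    mode: str = "contigs"  # contigs | reads

    # virus panel
    n_viruses: int = 200
    genome_length_min: int = 2000
    genome_length_max: int = 6000

    # community design
    samples_per_type: int = 3
    n_viruses_high: int = 40
    n_viruses_low: int = 8
    within_sharing: float = 0.7
    between_sharing: float = 0.1
    abundance_exponent: float = 1.0

    # contig fast path
    fragmentation: float = 2.0
    overlap_fraction: float = 0.6
    reads_per_virus: int = 50
    split_exponent: float = 1.5

    # reads mode
    depth: int = 400
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0

    # QC
    phred_min: int = 30
    homopolymer_max_run: int = 7
    length_min: int = 50
    length_max: int = 300

    # assembly
    assembly_min_identity: float = 0.98
    assembly_min_overlap_fraction: float = 0.50

    # homology
    seed_k: int = 11
    hvdi_evalue_max: float = 1e-20
    sharing_evalue_max: float = 1e-10
    min_coverage_of_shorter: float = 0.50
    min_align_length: int = 75

    # beta / permutation test
    n_permutations: int = 999
    permtest_iterations: int = 10_000
    contigs_per_draw: int = 1000

    # rarefaction
    rarefaction_fractions: Tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    rarefaction_replicates: int = 5
    run_rarefaction: bool = True

    # taxonomy
    annotation_weak_fraction: float = 0.1

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["rarefaction_fractions"] = list(self.rarefaction_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rarefaction_fractions" in data:
            data["rarefaction_fractions"] = tuple(data["rarefaction_fractions"])
        return cls(**data)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["rarefaction_fractions"] = list(self.rarefaction_fractions)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: Dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _strip(pooled_id: str) -> str:
    return pooled_id.split("|", 1)[1]


STAGE_FILES = {
    "simulate": ["truth.tsv", "design.tsv"],
    "hvdi": ["hvdi.tsv"],
    "beta": ["profile.tsv", "bray_curtis.tsv", "pcoa_coordinates.tsv", "permanova.tsv"],
    "share": ["sharing_matrix.tsv", "subject_spectrum.tsv"],
    "permtest": ["table1_analog.tsv"],
    "taxonomy": ["composition_reads.tsv", "composition_contigs.tsv"],
}


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- simulate ---------------------------------------------------------
    panel = simgen.generate_panel(
        config.n_viruses,
        (config.genome_length_min, config.genome_length_max),
        seed=stage_seed(seed, "panel"),
    )
    design = simgen.generate_communities(
        panel,
        simgen.default_sample_plan(config.samples_per_type),
        n_viruses_high=config.n_viruses_high,
        n_viruses_low=config.n_viruses_low,
        within_sharing=config.within_sharing,
        between_sharing=config.between_sharing,
        abundance_exponent=config.abundance_exponent,
        seed=stage_seed(seed, "community"),
    )
    meta = {
        s.sample_id: beta_sharing.SampleMeta(s.sample_id, s.specimen_type, s.subject_id)
        for s in design
    }
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "specimen_type": [s.specimen_type for s in design],
            "diversity_cluster": [s.diversity_cluster for s in design],
            "subject_id": [s.subject_id for s in design],
            "true_richness": [s.richness for s in design],
        }
    ).to_csv(out / "design.tsv", sep="\t", index=False)

    if config.mode == "contigs":
        contig_sets, truth = simgen.fragment_to_contigs(
            design,
            panel,
            fragmentation=config.fragmentation,
            overlap_fraction=config.overlap_fraction,
            reads_per_virus=config.reads_per_virus,
            split_exponent=config.split_exponent,
            seed=stage_seed(seed, "fragments"),
        )
    elif config.mode == "reads":
        contig_sets, truth = _reads_mode(config, design, panel, out)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    contig_dir = out / "contigs"
    contig_dir.mkdir(exist_ok=True)
    for sample_id, cset in contig_sets.items():
        seqio_qc.write_fasta(
            contig_dir / f"{sample_id}.fasta",
            {c.contig_id: c.consensus for c in cset},
            descriptions={c.contig_id: f"read_count={c.read_count}" for c in cset},
        )

    # --- homology ---------------------------------------------------------
    pooled = beta_sharing.pooled_sequences(contig_sets)
    hits = homology.find_hits(
        pooled, pooled, seed_k=config.seed_k, evalue_max=config.sharing_evalue_max
    )
    seqio_qc.write_hit_table(out / "hits.tsv", hits)

    # --- HVDI -------------------------------------------------------------
    hvdi_rows = []
    raref_frames = []
    for s in design:
        cset = contig_sets[s.sample_id]
        own = [
            h
            for h in hits
            if beta_sharing.pooled_sample_of(h.query_id) == s.sample_id
            and beta_sharing.pooled_sample_of(h.subject_id) == s.sample_id
        ]
        local_hits = [
            dataclasses.replace(h, query_id=_strip(h.query_id), subject_id=_strip(h.subject_id))
            for h in own
        ]
        edges = homology.hvdi_edges(
            local_hits,
            evalue_max=config.hvdi_evalue_max,
            min_coverage_of_shorter=config.min_coverage_of_shorter,
            min_align_length=config.min_align_length,
        )
        raw_spec = assembly.contig_spectrum(cset)
        _, coll_spec = alpha_hvdi.collapse(cset, edges)
        est = alpha_hvdi.estimate_diversity(coll_spec)
        hvdi_rows.append(
            {
                "sample_id": s.sample_id,
                "specimen_type": s.specimen_type,
                "diversity_cluster": s.diversity_cluster,
                "true_richness": s.richness,
                "S_obs_raw": raw_spec.S_obs,
                "chao1_raw": alpha_hvdi.chao1(raw_spec),
                "S_obs_hvdi": coll_spec.S_obs,
                "chao1_hvdi": est.chao1,
                "shannon_hvdi": est.shannon,
            }
        )
        if config.run_rarefaction:
            total = cset.total_reads
            depths = sorted(
                {max(1, int(round(f * total))) for f in config.rarefaction_fractions}
            )
            curve = alpha_hvdi.hvdi_rarefaction(
                cset,
                edges,
                depths,
                replicates=config.rarefaction_replicates,
                seed=stage_seed(seed, f"rarefaction:{s.sample_id}"),
            )
            curve.insert(0, "sample_id", s.sample_id)
            raref_frames.append(curve)
    pd.DataFrame(hvdi_rows).to_csv(out / "hvdi.tsv", sep="\t", index=False)
    if raref_frames:
        pd.concat(raref_frames).to_csv(out / "rarefaction.tsv", sep="\t", index=False)

    # --- beta diversity ---------------------------------------------------
    shits = homology.sharing_hits(hits, evalue_max=config.sharing_evalue_max)
    profile = beta_sharing.homology_profile(contig_sets, shits)
    profile.to_csv(out / "profile.tsv", sep="\t")
    dist = beta_sharing.bray_curtis(profile)
    dist.to_csv(out / "bray_curtis.tsv", sep="\t")
    ordination = beta_sharing.pcoa(dist)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    labels = [meta[s].specimen_type for s in profile.index]
    perm = beta_sharing.permanova(
        dist, labels, n_permutations=config.n_permutations, seed=stage_seed(seed, "permanova")
    )
    pd.DataFrame(
        [
            {
                "F": perm.F,
                "R2": perm.R2,
                "p": perm.p,
                "n_permutations": perm.n_permutations,
            }
        ]
    ).to_csv(out / "permanova.tsv", sep="\t", index=False)

    # --- sharing attribution ---------------------------------------------
    comps = beta_sharing.coassembly_components(
        contig_sets,
        shits,
        meta,
        evalue_max=config.sharing_evalue_max,
        min_coverage_of_shorter=config.min_coverage_of_shorter,
        min_align_length=config.min_align_length,
    )
    beta_sharing.sharing_matrix(comps).to_csv(out / "sharing_matrix.tsv", sep="\t")
    n_subjects = len({m.subject_id for m in meta.values()})
    hist, universal = beta_sharing.subject_membership_spectrum(comps, n_subjects)
    pd.DataFrame(
        {"n_subjects": list(hist), "n_components": list(hist.values())}
    ).assign(universal_fraction=universal).to_csv(
        out / "subject_spectrum.tsv", sep="\t", index=False
    )

    # --- permutation sharing test -----------------------------------------
    permtest = beta_sharing.within_between_test(
        contig_sets,
        shits,
        meta,
        n_iterations=config.permtest_iterations,
        contigs_per_draw=config.contigs_per_draw,
        seed=stage_seed(seed, "permtest"),
    )
    pd.DataFrame(
        [
            {
                "specimen_type": r.specimen_type,
                "pct_homologous_within": 100 * r.observed_within,
                "pct_homologous_between": 100 * r.observed_between,
                "p": r.p,
            }
            for r in permtest.values()
        ]
    ).to_csv(out / "table1_analog.tsv", sep="\t", index=False)

    # --- taxonomy ---------------------------------------------------------
    ann = simgen.truth_annotation_hits(
        truth,
        weak_fraction=config.annotation_weak_fraction,
        seed=stage_seed(seed, "annotation"),
    )
    taxonomy.write_annotation_table(out / "annotation_hits.tsv", ann)
    families = taxonomy.assign_family(
        ann, contig_ids=[c.contig_id for cs in contig_sets.values() for c in cs]
    )
    for weighting in ("reads", "contigs"):
        taxonomy.composition_table(families, contig_sets, weighting).to_csv(
            out / f"composition_{weighting}.tsv", sep="\t"
        )

    # --- manifest ---------------------------------------------------------
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=seed,
        version=__version__,
        checksums=checksums,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _reads_mode(
    config: PipelineConfig,
    design: simgen.CommunityDesign,
    panel: simgen.VirusPanel,
    out: Path,
) -> Tuple[Dict[str, assembly.ContigSet], pd.DataFrame]:
    """Read-level path: simulate reads, QC, screen, assemble."""
    readsets = simgen.generate_reads(
        design,
        panel,
        depth=config.depth,
        error_rate=config.error_rate,
        contaminant_fraction=config.contaminant_fraction,
        seed=stage_seed(config.seed, "reads"),
    )
    decoy = {"decoy": simgen.decoy_genome(stage_seed(config.seed, "reads"))}
    virus_family = {v.virus_id: v.family for v in panel}
    qc_rows = []
    contig_sets: Dict[str, assembly.ContigSet] = {}
    truth_rows = []
    for sample_id, rs in readsets.items():
        filtered, report = seqio_qc.qc_filter(
            rs,
            phred_min=config.phred_min,
            homopolymer_max_run=config.homopolymer_max_run,
            length_min=config.length_min,
            length_max=config.length_max,
        )
        screen = seqio_qc.screen_contamination(filtered, decoy)
        qc_rows.append(
            {
                "sample_id": sample_id,
                "input_reads": report.input_reads,
                "surviving_reads": report.surviving_reads,
                **{f"removed_{k}": v for k, v in sorted(report.removed_by.items())},
                "decoy_mapped_fraction": screen.mapped_fraction,
                "screen_decision": screen.decision,
            }
        )
        cset = assembly.assemble(
            filtered,
            min_identity=config.assembly_min_identity,
            min_overlap_fraction=config.assembly_min_overlap_fraction,
        )
        source_of = {r.read_id: r.source_id for r in rs}
        for c in cset:
            c.contig_id = f"{sample_id}.{c.contig_id}"  # globally unique
            sources = Counter(source_of.get(rid) for rid in c.member_read_ids)
            c.true_virus_id = sources.most_common(1)[0][0]
            truth_rows.append(
                (
                    sample_id,
                    c.contig_id,
                    c.true_virus_id,
                    c.read_count,
                    virus_family.get(c.true_virus_id, "unclassified"),
                )
            )
        contig_sets[sample_id] = cset
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "contig_id", "true_virus_id", "read_count", "family"],
    )
    return contig_sets, truth


def make_report(outdir) -> str:
    """Deterministic human-readable summary of a completed run.

    Raises FileNotFoundError naming the missing stage when outputs are
    incomplete.  Writes ``report.txt`` in the output directory and
    returns its content.
    """
    out = Path(outdir)
    for stage, files in STAGE_FILES.items():
        for fname in files:
            if not (out / fname).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} output missing: {fname}"
                )
    lines: List[str] = ["virome community ecology run summary", "=" * 38, ""]
    hvdi = pd.read_csv(out / "hvdi.tsv", sep="\t")
    lines.append("Per-sample diversity (HVDI = Chao1 on the collapsed spectrum):")
    lines.append(
        hvdi.to_string(
            index=False,
            float_format=lambda v: f"{v:.2f}",
            columns=[
                "sample_id",
                "specimen_type",
                "diversity_cluster",
                "true_richness",
                "chao1_raw",
                "chao1_hvdi",
                "shannon_hvdi",
            ],
        )
    )
    cluster_means = hvdi.groupby("diversity_cluster")["chao1_hvdi"].mean()
    lines.append("")
    for cluster, value in cluster_means.items():
        lines.append(f"mean HVDI ({cluster} cluster): {value:.2f}")
    perm = pd.read_csv(out / "permanova.tsv", sep="\t").iloc[0]
    lines.append("")
    lines.append(
        "PERMANOVA on Bray-Curtis of homology profiles: "
        f"F = {perm.F:.2f}, R2 = {perm.R2:.3f}, p = {perm.p:.4g} "
        f"({int(perm.n_permutations)} permutations)"
    )
    lines.append("")
    lines.append("Sharing matrix (% of components containing row type that also contain column type):")
    share = pd.read_csv(out / "sharing_matrix.tsv", sep="\t", index_col=0)
    lines.append(share.to_string(float_format=lambda v: f"{v:.1f}"))
    lines.append("")
    lines.append("Within/between specimen-type sharing (permutation test):")
    table1 = pd.read_csv(out / "table1_analog.tsv", sep="\t")
    lines.append(table1.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    subj = pd.read_csv(out / "subject_spectrum.tsv", sep="\t")
    if len(subj):
        lines.append("")
        lines.append(
            "fraction of sharing components touching every subject: "
            f"{subj['universal_fraction'].iloc[0]:.4f}"
        )
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
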