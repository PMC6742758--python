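# Methods

`viromeco` implements the analysis track a desk-scale virome ecology
study follows once sequencing is done: read QC, assembly into contigs,
intra-sample homology networks for alpha diversity, inter-sample
homology for beta diversity and virus sharing, and a permutation test of
within- versus between-specimen-type sharing.  Because raw viromes of
this kind are rarely deposited, the package ships a synthetic community
generator that plants every structure the analyses are meant to recover,
so each stage can be validated against ground truth.

## The model

**Contig spectrum.** Assembly of a virome library yields classes
(contigs) with occupancy counts; the spectrum F maps occupancy *i*
(reads per class) to the number of classes F_i.  Richness estimation
runs on F with no contig length cutoff, because singleton counts (reads
that never co-assembled) carry most of the signal.

**HVDI.** Assemblers split most viruses across several contigs, so the
raw spectrum overstates virus richness roughly by the fragmentation
factor.  The Homologous Virus Diversity Index corrects this by treating
contigs as nodes and connecting pairs with strong intra-sample homology
(E < 1e-20, alignment covering at least 50% of the shorter contig and at
least 75 bp).  Each connected component is one putative virus whose
abundance is the summed read count of its members; the collapsed
spectrum feeds Chao1,

    classic:         S_chao1 = S_obs + F1^2 / (2 F2)
    bias-corrected:  S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1))

with the bias-corrected form as the default because collapsed virome
spectra frequently have F2 = 0, where the classic form is undefined.
Shannon entropy H = -Σ p ln p (nats) is reported alongside.

**Beta diversity.** The feature table is the *homology profile*: cell
(i, j) is the read-weighted fraction of sample i's contigs with at least
one permissive hit (E < 1e-10) among sample j's contigs, diagonal fixed
at 1.  The source protocol never states its feature table explicitly;
the read-weighted sharing profile is our documented interpretation, and
a binary variant can be derived by thresholding.  Profile rows feed
Bray-Curtis dissimilarity, PCoA (Gower double-centering +
eigendecomposition; negative eigenvalues are reported and their axes
dropped), and a one-way PERMANOVA with

    SS_total = (1/N) Σ_{i<j} d²_ij,   F = (SS_between/(a-1)) / (SS_within/(N-a))

and a label-permutation p-value using the +1 convention (ties count as
extreme; p is never 0).

**Sharing attribution.** "Co-assembly" across specimen types is realised
as connected components of the pooled cross-sample homology network
(permissive E-value plus the same coverage rules), which is
deterministic and measures the same thing as re-assembling pooled reads:
shared sequence membership.  Each component records contributing
specimen types and subjects, yielding the type-by-type sharing
percentage matrix (cell(X, Y) = % of components containing X that also
contain Y; not symmetric) and the histogram of components by
contributing-subject count.

**Within/between permutation test.** For each specimen type T the
package reports the mean read-weighted shared fraction over ordered
same-type sample pairs (within) and over cross-type pairs (between).
The p-value refers a single same-type draw — one random same-type pair
scored on `contigs_per_draw` (default 1000) random contigs, drawn with
replacement when a sample has fewer — to a null of `n_iterations`
(default 10,000) identically constructed cross-type draws.  Observed and
null draws are exchangeable when sharing carries no type signal, so the
p-value is exactly calibrated (uniform under the null) and equals
1/(n_iterations + 1) under complete separation.  Referring a *mean* of
within-pair statistics to single-pair null draws — a tempting
alternative reading of the protocol — is not calibrated (the mean has
smaller variance than a single draw, concentrating p near 0.5), which is
why the single-draw statistic was chosen.

## The homology engine

A self-contained substitute for a production aligner, adequate for
substitution-only synthetic data: exact k-mer seeds (default k = 11)
nominate (subject, diagonal) candidates, and each candidate diagonal is
scored by its optimal maximum-scoring ungapped segment (+1 match, -2
mismatch), which subsumes x-drop extension.  E-values follow
Karlin-Altschul statistics with the published ungapped +1/-2 parameters
λ = 1.33, K = 0.621 and search space m·n taken as the product of the
summed query and subject lengths.  Both strands are searched and the
best strand kept; one best hit is retained per ordered (query, subject)
pair.  By default a diagonal needs at least two seed matches before
scoring, which suppresses the O(L²/4^k) background of chance 11-mer
matches on pooled megabase searches while keeping every alignment of
biological interest (a 35-bp exact match already carries 25 seeds);
`min_diag_seeds=1` restores exhaustive behaviour for small searches.
Real aligner output in the 12-column tabular dialect can replace the
engine at every stage.

Gapped alignment and translated search are out of scope: the synthetic
error model is substitution-only, and users with real data are expected
to import hit tables from a production aligner.

## The assembler

A greedy overlap assembler reproduces the behavioural contract of the
commercial workbench used for real viromes: merge the pair with the
longest overlap whose identity is ≥ 98%, consensus per column by
majority rule (ties resolved alphabetically A < C < G < T), unmerged
reads kept as one-read contigs.  The minimum-overlap rule is anchored to
*read* length: an overlap qualifies when it spans at least
`min_overlap_fraction` (default 0.5, with 0.8 as the stricter preset) of
min(shorter sequence, shortest member read of either side).  For
read-read merges this is exactly "50% of the shorter read"; anchoring to
read length matters because a rule phrased as a fraction of the growing
contig stalls as soon as contigs exceed twice the read length, and the
protocol's own gloss ("minimum tolerable overlap was approximately 75
nucleotides" for 150-nt reads) is a read-length statement.  Candidate
overlaps come from exact 15-mer anchors; merging is longest-overlap
first with lexicographic tie-breaking, so assembly is deterministic.
Equivalence to the commercial tool is contract-level, not bit-level.

## The synthetic generator

`simgen` emulates the study conditions end to end:

* **Panel** — `n_viruses` (default 200) i.i.d. random genomes of
  2–6 kb carrying family labels drawn from a phage-dominated mixture
  (Myoviridae 0.24, Siphoviridae 0.28, Podoviridae 0.18, Microviridae
  0.10, Inoviridae 0.08, other-dsDNA 0.08, eukaryotic viruses 0.04).
  Random genomes make distinct viruses effectively unrelated, which is
  exactly what the homology thresholds assume.
* **Communities** — two diversity clusters: four high-diversity specimen
  types (feces-, saliva-, urine-, skin-like) at 40 viruses per sample
  and four low-diversity types (CSF-, plasma-, body-fluid-, milk-like)
  at 8, three samples per type, one subject per sample.  Each cluster
  has a deterministic core of ceil(within_sharing × richness) viruses
  (default within_sharing = 0.7) present in every sample of the cluster;
  remaining slots are drawn from a cluster-private pool.  A bridge of
  round(between_sharing × min richness) viruses (default
  between_sharing = 0.1, i.e. one virus) sits in both cores — the analog
  of a virus recoverable from every subject.  Per-sample abundances
  follow a power law (exponent 1.0), mimicking the uneven populations
  seen in real body-fluid viromes.
* **Reads** — forward-strand substrings, lengths ~N(150, 10), i.i.d.
  substitution errors, constant per-base qualities consistent with the
  error rate; a configurable fraction of reads comes from a synthetic
  100-kb "bacterial" decoy genome and is tagged, to exercise the
  contamination screen without shipping real genomes.
* **Contig fast path** — each virus in a sample is cut into
  round(fragmentation) equal windows (default 2) with consecutive
  windows overlapping by 60% of their length.  The overlap is deliberate:
  the strict homology regime demands coverage of at least half of the
  shorter contig, so zero-overlap fragments could never be re-joined and
  HVDI would have nothing to correct.  Per-virus read totals follow the
  planted abundances (`reads_per_virus` × richness per sample, default
  50 — enough that even the rarest virus collects several reads and
  spurious singletons are rare), split across windows by power-law
  weights (exponent 1.5), minimum one read per window.

What the generator does *not* emulate: real phage genome architecture
(repeats, mosaicism, conserved modules shared between genuinely distinct
viruses), indels and chimeric MDA artefacts, strand mixture, and
uneven per-base coverage.  Passing tests therefore demonstrate that the
estimators recover planted structure under the stated error model, not
that they are robust to every failure mode of real viromes — in real
data, conserved modules can bridge distinct viruses into one HVDI
component, biasing richness downward.

## Numerical and design choices

* All randomness flows through `numpy` Generators seeded from explicit
  arguments; the pipeline derives per-stage seeds by hashing the stage
  name with the global seed, so stages are independently reproducible.
* Chao1 on an empty spectrum returns 0; the classic variant raises with
  guidance when F2 = 0 and F1 > 0.
* Rarefaction subsamples reads without replacement (multivariate
  hypergeometric) and rebuilds components per replicate; homology edges
  are depth-independent, so the edge list is reused restricted to
  surviving contigs.  Rarefying reads before network reconstruction is
  our documented choice; the alternative order is not implemented.
* PCoA drops axes with eigenvalues below 1e-10; coordinates reproduce
  Euclidean-embeddable inputs to well below 1e-9.
* Consensus ties, family-assignment E-value ties, and equal-best
  annotation classes all break alphabetically; greedy merges break ties
  lexicographically on contig id.  Every tie rule is arbitrary but
  deterministic.
* Collapse abundance is summed member reads per component; a
  contig-count weighting is available in the taxonomy composition tables
  (`weighting="contigs"`), reflecting a genuine ambiguity in how such
  studies weight abundance.

## Problem sizes

Default study: 24 samples (8 types × 3), 200-virus panel, fragmentation
2, 50 reads per virus — roughly 1,900 contigs and 3.5 Mb of pooled
sequence, which the engine searches all-vs-all in about a minute on one
core.  The recovery experiment spans 20 samples at richness 5–100 and
fragmentation 1–4.  These sizes were chosen so the estimators operate in
the regime the method targets (hundreds of contigs per sample) while a
full run of the test suite and acceptance script stays well under half
an hour.

## Known limitations

* The engine is ungapped; a single indel truncates an alignment.
* The assembler is O(n²) in reads and intended for ≤ a few thousand
  reads per sample.
* PERMANOVA is one-way only (no strata, no covariates).
* The permutation test's single-draw statistic is exactly calibrated but
  has the variance of one pair comparison; with strong planted signal it
  is decisive, with weak signal individual p-values are noisy by design.
* E-values from the built-in engine use a fixed ungapped parameter set;
  imported aligner E-values are taken at face value.
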