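# Methods

`flocprofiler` implements the downstream, rule-based half of a genome-centric
metagenome workflow for flocculated-aggregate (biofloc) microbial
communities.  Everything upstream — assembly, binning, dereplication,
CheckM-style quality estimation, GTDB classification, gene annotation, read
mapping, protein alignment — is assumed done; the package consumes the
derived tables those tools emit and applies the community- and
function-level classification rules reproducibly.

## Quality scoring and tiers

Per genome, completeness `C` and contamination `X` are CheckM2-style percent
estimates.  The quality score is

    QS = C − 5·X

Tiers: **high** requires `C ≥ 90` and `X ≤ 5`; **medium** requires `C ≥ 50`
and `X < 10`; everything else **fails**.  High is tested first, so the tiers
partition the genome set.  The two source conventions for the medium bound
(`>50 / <10` vs `≥50 / ≤10`) disagree at the exact boundary; the default
(`C ≥ 50`, `X < 10`) splits the difference in the direction of the MIMAG
convention and both bounds are configurable (`TierThresholds`).  The MIMAG
high-quality flag additionally requires all three rRNA genes (5S, 16S, 23S)
and `trna_count ≥ 18`; the standard's "≥ 18" is the default even though some
write-ups say "more than 18" (`mimag_min_trna` switches it).

## Core microbiota

Relative abundance is `100 · mapped / total` against each sample's **total**
PE read count (not the mapped total), so per-sample RA values sum to the
mapping rate, not to 100%.  Detection in a sample means RA strictly above a
threshold (default 0, i.e. one mapped read suffices); the threshold exists
because "present" is otherwise undefined for count data.  A genome is MfA
when detected in a strict majority of samples (`floor(n/2)+1`; 6 of 11),
else LfA.  Core = MfA **and** mean RA > 0.01%, with the mean taken over all
samples including zeros — the plainest reading of "average relative
abundance"; `mean_over_detected_only` gives the alternative.  Upstream
mapping provenance (10 M-read subsampling, rRNA/tRNA masking, the
min-length-50 / identity-95 / aligned-fraction-50 alignment filters) belongs
to the mapping tool and is treated as pass-through metadata.

## Pathway rule engine

A pathway definition is an ordered list of steps; each step lists
alternative complexes; a complex is a set of subunit symbols that must all
be present.  A step is satisfied when any alternative is complete, and
completeness is the unweighted fraction of satisfied steps (weights were
considered and rejected for transparency: every published count the engine
reproduces is a presence/absence rule, not a weighted score).  Monotonicity
holds by construction: adding a gene can only satisfy more steps.

Shipped definitions: denitrification (napAB | narGHI → nirS | nirK → norBC
→ nosZ), DNRA (napAB | narGHI → nirBD | nrfAH), assimilatory nitrate
reduction (nas → nirA), autotrophic nitrification (amoABC → hao → nxr),
anammox (hzs → hdh), nitrogen fixation (nif), GS-GOGAT (glnA → gltB+gltD),
GDH (gdh), sox (soxXAYZBCD as one seven-subunit complex), rdsr (dsrAB,
oxidative orientation required), and reductive sulfate reduction (sat →
aprAB → dsrAB, reductive orientation).  `nas`, `nirA`, `hao`, `nxr`, `hzs`,
`hdh`, `nif` and `gdh` are collapsed single symbols because annotation
tools disagree on their subunit granularity; the vocabulary file is where
subunit symbols are mapped onto them.  A "complete denitrifier" needs every
step with *either* nitrate reductase — requiring both napAB and narGHI
would contradict the enzymology (they are alternative entry points).

Markers are deliberately separate from completeness: nirS **or** nirK marks
a denitrifier, nirB **and** nirD mark DNRA, soxB marks sulfur oxidizers.
napAB-complete genomes are aerobic-capable denitrifiers; narGHI-complete
without napAB are anaerobic-only.

## dsrAB orientation and direction gating

dsrAB runs reductively in sulfate reducers and oxidatively (reverse dsrAB)
in many sulfur oxidizers.  In place of phylogenetic placement the package
assigns each query the label of its highest-identity labelled reference
from a similarity table, calling **ambiguous** when the best reductive and
oxidative hits lie within a margin (default 2.0 percentage points) or when
no labelled hit exists.  The rdsr pathway is only credited to oxidative
genomes and the dsrAB step of sulfate reduction only to reductive ones;
sox+rdsr co-occurrence therefore requires a complete sox cluster *and*
oxidative dsrAB.

## HN-AD screening

Heterotrophic nitrification–aerobic denitrification is screened through
best-hit identities against the four marker proteins DnfA/DnfB/DnfC/POD: a
genome is positive when all three Dnf subunits, or POD alone, exceed both
an identity threshold (default 60%) and an alignment-length coverage
threshold (default 70% of the reference protein).  The defaults are
package choices — the published precedent is an expert negative call from
similarity heatmaps, with no printed cutoff — and both are exposed in
config.  Per-marker identities are always reported so the decision is
reproducible from stored values alone.

## 16S novelty

Best-identity thresholds 94.5% (genus) and 98.7% (species) partition
[0, 100] into novel genus (< 94.5), novel species (94.5 ≤ id < 98.7) and
known species (≥ 98.7).  Boundaries are strict-less-than; the bands are
disjoint so genus- and species-level novelty counts never overlap.
Queries are assumed length-filtered (> 1,000 nt) upstream.

## CAZymes

Family strings `<class><family>[_<subfamily>]` map to the six classes GH,
GT, PL, CE, AA, CBM; subfamily suffixes collapse into their family.  Counts
are conserved: the total over any class×taxon or family×taxon table equals
the number of CAZy-annotated genes regardless of rank, with genomes
unclassified at the chosen rank pooled under an `unclassified` sentinel.

## Pathway × sample z-scores

For per-sample bulk (metagenome-contig) annotations, the raw cell is the
count of genes whose symbol lies in the pathway's symbol union; each row is
transformed to `(x − mean) / sd` with the population SD.  Constant rows map
to all-zero and are flagged rather than dividing by zero; with fewer than
two samples z-scoring is refused and raw counts are returned.

## Synthetic community generator

The generator emulates the *derived tables*, not reads, at the study
conditions: 11 metagenomes of 10 million PE reads each.  Mechanisms:

* **Taxa** draw a lineage from a pool of families recurrent in biofloc/
  aggregate communities and a pathway endowment by independent Bernoulli
  draws; default endowment probabilities approximate observed per-genome
  prevalence (≈25% denitrifiers, 28% GS-GOGAT, 10% sox, 6% DNRA, rare
  oxidative dsrAB, essentially no anammox or autotrophic nitrification).
  A genome's dsrAB is given one orientation only.
* **Quality**: completeness ~ Beta(5, 2) scaled to [50, 100] (most genomes
  good, a tail near the medium bound); contamination ~ Exponential(scale 2)
  truncated to [0, 10).
* **Gene dropout**: each endowed gene is emitted independently with
  probability C/100 — the simplest mechanism consistent with incomplete
  genomes.  A correlated variant (`block_dropout`) drops one contiguous arc
  of the gene order instead; it is off by default.
* **Contamination**: foreign genes drawn from other taxa's endowments are
  injected at 0.5 genes per contamination percentage point, so contamination
  produces spurious pathway calls — the failure mode the X ≤ 5 / X < 10
  bounds guard against.
* **Abundance**: presence is Bernoulli(0.7) per genome × sample; weights are
  log-normal(0, 2); counts are one multinomial draw of the 10 M reads over
  present genomes plus a background bin absorbing 40% (echoing the ~60%
  mapping rates seen for well-recovered genome compendia, without claiming
  to reproduce them).
* **Similarity tables** plant dsrAB orientations at a clear identity margin,
  uniformly weak (20–40%) HN-AD marker hits, and 16S best identities mixed
  ≈50/37/13 across the novel-genus/novel-species/known bands.

What the generator does **not** emulate: assembly chimerism, binning
cross-contamination structure, strain heterogeneity, compositional coupling
between samples, or annotation error beyond symbol dropout.  Passing
recovery tests therefore demonstrates the correctness of the rules and
their implementations under the stated noise model, not robustness to real
annotation pipelines.

Determinism: every draw comes from one `numpy.random.default_rng(seed)`
stream in fixed order, so equal seeds give byte-identical output tables.

## Problem sizes

The shipped checks use a 200-genome community at the study conditions for
the end-to-end run, a 60-genome noiseless community (C ≡ 100, X ≡ 0) for
exact recovery, 2,000 genomes at C ≡ 80 for the dropout calibration of the
7-gene sox cluster (expected complete-call rate 0.8⁷ ≈ 0.21, checked within
three binomial standard errors), and 10,000 random gene subsets for
engine-vs-oracle equivalence.  All run in seconds.

## Degenerate inputs and tie-breaks

Empty gene tables yield zero completeness everywhere and a successful run;
all-zero abundance rows are LfA with detection frequency 0; equal best
reductive/oxidative identities are ambiguous at any margin ≥ 0; a taxonomy
rank labelled below an unclassified rank is rejected at parse time (GTDB
strings are prefix-closed); `.` is the missing value in every TSV.

## Known limitations

* The dsrAB nearest-reference rule is a stand-in for phylogenetic
  placement; queries equidistant from both clades are only caught by the
  ambiguity margin.
* Pathway completeness weights all steps equally; a missing terminal
  oxidase counts the same as a missing entry enzyme.
* The HN-AD thresholds are pragmatic defaults, not community standards.
* The vocabulary-file approach pushes annotation-dialect reconciliation
  (e.g. KOfam vs UniRef90 disagreements) out of the engine; it documents
  rather than resolves them.
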