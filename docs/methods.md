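# Methods

This note documents the models, rules and numerical choices behind
`httscan`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the method left room.

## TE-transcript identification

The classifier is a deterministic rule over hit tables. For each
transcript:

1. **Domain evidence.** At least one conserved-domain (blastx-style) hit
   must be to a subject flagged TE-related. The flagging is an input
   mapping, decoupled from any database snapshot; the helper
   `te_flags_from_descriptions` builds it from a description table by
   case-insensitive substring match on "transposon".
2. **Repeat-library dominance.** The top repeat-library (tblastx-style)
   hit must satisfy *E* < `e_te_candidate` (default 1e-5) **and**
   *E* < the top conserved-domain hit's *E*, both strict. This rejects
   single-copy genes that happen to carry a TE-like domain (the classic
   case: an elongation-factor mRNA containing a TetM-like domain, a
   family typically found on mobile elements).

"Top hit" is always the minimum of (*E*, −bitscore, subject id), a total
order, so every assignment is invariant under permutation of hit rows.
All E-value thresholds are strict inequalities, following the "lower
than" reading.

Superfamily is copied from the top repeat-library hit's annotation and
mapped to a TE group (DNA / LTR / Non-LTR) through a packaged
superfamily→group table. Family assignment requires the top repeat blastn
hit to (a) be a catalogued focal-species family consensus and (b) clear
`e_family` (default 1e-20); family/superfamily discordance (possible with
nested TE insertions) is recorded, not repaired.

## HTT calling by top-hit phylogenetic incongruence

Nucleotide hits at *E* ≥ `e_nt_hit` (default 1e-5) are dropped. Each
surviving hit's lineage is mapped through an ordered rule scheme: the
first rule whose include term appears in the lineage, and none of whose
exclude terms do, supplies the taxon label. The focal shrimp family
(Penaeidae) is an *excluded* label — placed first and removed from all
tallies — because penaeid shrimps are too close to the focal species for
a top hit to carry any transfer signal. "Arthropoda minus Penaeidae" is
therefore realized by rule order plus an exclusion term, and no penaeid
hit can ever reach a tally.

A transcript is HTT when its surviving top-hit taxon is defined and is
not Arthropoda. When no hit survives (none significant, or all penaeid)
the result is a **no-call**, reported as such; conflating no-calls with
negatives would corrupt every margin downstream.

The packaged 17-taxon scheme drives the superfamily-by-taxon contingency
table; the packaged ecological scheme (shrimp / amphibians / aquatic
animals / aquatic plants / arthropods / land animals / land plants /
microorganisms / parasites) drives tree-neighbor coloring. The ecological
scheme reproduces its source term table verbatim, including taxonomic
oddities such as Testudines and Annelida under "amphibians": fidelity to
the printed grouping was preferred over taxonomic correctness, since the
scheme's purpose is to reproduce the published reading of the trees.

Genome-homologue screening keeps the best chromosome/HTGS hit below
`e_genome_hit` (default 1e-10) per family, or records "no significant
hit". Protein-homologue filtering for tree building drops hits with query
coverage below `min_protein_coverage` (default 0.60), keeps one best hit
per organism, and returns them best-first.

### Query coverage

Coverage is stored as a fraction in [0, 1]. When a hit table lacks an
explicit coverage column it is recomputed as (merged non-overlapping HSP
query spans of the query/subject pair) / (query length) — the
conservative reading in which a region covered by several HSPs counts
once. Coordinates follow the BLAST convention (1-based, inclusive).

## Tree neighbors

Tree inference is out of scope; trees arrive as Newick. "Closest
relative" is computed two ways and reported side by side, because a
visual reading of a published tree admits both:

* **patristic** — tips minimizing path-length distance to the focal tip
  (computed via dendropy's distance matrix; all ties returned; invariant
  under re-rooting);
* **sister-clade** — all tips of the focal tip's sibling subtree, a
  rooting-dependent topological notion.

The neighbor set's majority ecological label is reported; label ties are
flagged ambiguous rather than broken arbitrarily. Support values are
carried for display (default display threshold 0.9) but never used for
filtering, since the published neighbor judgments show no evidence of
support-based pruning.

## Expression screen

**TMM normalization** is implemented from scratch rather than delegated,
and cross-checked in the test suite against both an independent rank-trim
oracle and Bioconductor edgeR (`calcNormFactors`, unweighted). The
reference sample is the one whose upper-quartile of library-scaled counts
is closest to the mean upper-quartile. For each other sample, log2
expression ratios (M) and average abundances (A) are computed over genes
positive in both samples; the extreme 30 % of M and 5 % of A (each tail)
are trimmed; the factor is 2^(mean of surviving M). Factors are rescaled
to geometric mean 1, and normalized counts are raw counts divided by
(factor × relative library size). Precision weighting is available in
edgeR but off here (trim fractions dominate in practice; the edgeR
cross-check test uses the unweighted mode).

Two properties worth stating precisely: (i) on depth-only-scaled matrices
all factors are 1 to 1e-6 and normalized columns coincide; (ii) a single
strongly differential gene leaves the normalization *applied to every
other gene* unchanged to within the trim noise — the raw factor itself
shifts by the outlier's library-size share, which is exactly the
composition bias TMM exists to absorb.

**Max fold change (MFC)** of a transcript is max/min of its per-group
summary counts, where the group summary is the mean of normalized counts
over the group's samples (the method's source is silent on replicate
handling; means are the natural reading of "average read counts"). A zero
minimum takes a pseudocount of one — applied to the minimum only, since
applying it to both sides would change values; an all-zero transcript
scores exactly 1. MFC ≥ 1 always, so threshold sweeps over 1..40 start at
proportion 1.0 and are non-increasing. Sweeps can run on raw counts via a
flag; normalized is the default.

**Grouped ANOVA.** For transcripts above an MFC threshold, each group's
observations are the per-transcript group summary counts; a one-way
fixed-effects F is computed from between/within sums of squares with the
p-value from the F distribution, plus pairwise comparisons marked * (p <
0.05) and ** (p < 0.01). Transcripts are the observational unit,
matching grouped "average read counts of transcripts" summaries.

## One-class expression-pattern matching

The detector asks which non-TE transcripts behave like HTT transcripts
across experimental groups.

* **Profiles.** log2(1 + normalized group mean) per group, then centered
  per transcript (per-gene centering, as in expression heatmap
  clustering). Centering makes the boundary abundance-invariant: two
  transcripts with the same relative response have the same profile. The
  uncentered variant is available (`center=False`). Per-group means were
  chosen over per-sample vectors: the pattern of interest is a group
  response, and group means are the lower-noise estimate of it.
* **Training set.** HTT transcripts with MFC strictly above 4 in at least
  one experiment — a cut chosen to keep training sets above ~50 profiles;
  smaller sets trigger a warning because one-class boundaries on tiny
  samples are unstable.
* **Model.** RBF one-class SVM, nu = 0.1, after per-feature
  standardization learned on the training set (required by any
  scale-sensitive kernel). The kernel width default is the median
  heuristic, gamma = 1/(2 · median‖xi − xj‖²) over the standardized
  training set: matching the kernel scale to the typical point spacing
  keeps the boundary smooth enough to generalize from 50–100 training
  profiles, where the per-feature-variance default produces a boundary
  that hugs the sample and under-covers fresh draws from the same
  distribution. The variance-scaled default remains available
  (`gamma="scale"`).
* **Numerics.** The SVM is fitted at solver tolerance 1e-9 and decision
  values within 1e-6 of zero count as on-boundary (inlier). Margin
  support vectors sit at exactly zero in exact arithmetic; the default
  solver tolerance (1e-3) leaves them ~1e-4 below it, which would
  spuriously violate the nu bound, while genuine outliers score orders of
  magnitude lower — the band cannot flip a real verdict.
* **Two experiments.** Per-experiment models are fitted and their
  positive sets intersected: a candidate must look HTT-like in both.
  Intersection can only shrink or preserve the positive set.

With nu = 0.1 roughly 10 % of genuinely in-distribution candidates fall
outside any correctly calibrated boundary; recovery rates for planted
look-alikes should be read against that ceiling.

## Synthetic worlds

`WorldSpec`/`generate_world` fabricate hit tables, lineages, count
matrices and truth labels as a pure function of the spec (which includes
the seed); identical specs give byte-identical outputs.

* **Hit structure.** Planted TE transcripts draw a repeat-library E-value
  strictly below both the candidate cutoff and their conserved-domain
  E-value, so they satisfy the two-step rule by construction; decoys get
  a TE-flagged domain but a repeat hit above one of the bounds; planted
  HTT transcripts get their best nucleotide hit from a planted
  non-arthropod donor, a worse arthropod hit, and (half the time) an even
  better shrimp-family hit that the exclusion rule must discard.
* **Counts.** Negative binomial (variance = μ + 0.1 μ²; dispersion 0.1 is
  typical biological-replicate noise), per-transcript base abundance
  lognormal with mean 200 and log-sd 0.8, four experimental groups ×
  three replicates emulating a stimulation design (blank / control /
  single / successive), and an eight-fold down-regulation planted on HTT
  and mimic transcripts in the final group — a strong responder profile,
  comfortably above the MFC > 4 training rule. The default HTT fraction
  of the TE set is 40 %, mirroring the observed study proportion (157 HTT
  calls among 395 TE transcripts) and keeping novelty training sets above
  50 profiles.
* **What it does not emulate.** No nucleotide sequences are simulated (no
  pipeline stage needs them); hit E-values are log-uniform rather than
  score-derived; real libraries have unequal depths, batch structure and
  gene-length effects absent here. Passing tests therefore demonstrate
  the *rules and estimators* behave as specified on data with the assumed
  statistical structure — not that the biological conclusions of any
  particular study are correct.

## Packaged fixtures

The study's per-transcript data are not public, but its printed tables
pin the classification tally (395 TE transcripts; 230 carrying one of 31
named families), the top-hit margins (244 transcripts with a significant
nucleotide hit; 87 arthropod vs 157 non-arthropod; 30 virus top hits, all
on one Penelope family), the HTT roll-up (16 families, 83 transcripts)
and the genome best-hit table. `httscan.fixtures` reconstructs a
per-transcript table satisfying every one of those marginals; cells the
source leaves undetermined (e.g. which particular non-arthropod taxon a
given reconstructed transcript hits) are filled deterministically and
flagged `reconstructed` in a provenance column, with prose-anchored cells
flagged `prose`. Fixture construction is pure code and fully
deterministic.

## Known limitations

* HTT calling is single-evidence (top-hit incongruence); it estimates
  neither transfer direction, age nor donor identity, and offers no
  synteny or flanking-sequence corroboration.
* The taxon schemes match lineage terms exactly; organisms absent from
  the supplied lineage tables fall through to the fallback label.
* TMM assumes most genes are not differential; normalization of matrices
  where the majority of genes shift will be biased, as in any
  composition-based method.
* The one-class detector's positive set is threshold-sensitive near the
  boundary; candidates with decision values near zero deserve manual
  inspection rather than mechanical acceptance.
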