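# httscan

Horizontal transposon transfer (HTT) screening for transcriptomes, built
around the analysis of the Pacific white shrimp (*Litopenaeus vannamei*)
transcriptome: rule-based identification of transposable-element (TE)
transcripts from homology hit tables, HTT calling by top-hit phylogenetic
incongruence, ecological classification of tree neighbors, and a
max-fold-change expression screen with one-class pattern matching.

## Who this is for

Researchers who have assembled a transcriptome for a non-model (typically
aquatic) animal, run BLAST-style searches against conserved-domain, repeat,
nucleotide, genome and protein databases, counted reads from one or more
expression experiments — and now want a reproducible, testable pipeline for
the downstream inference: *which transcripts are TEs, which of those look
horizontally transferred, and how do they behave transcriptionally?*
The pipeline consumes hit tables, Newick trees and count matrices; it never
runs BLAST, aligners or tree programs itself.

## The method

**TE identification (two-step rule).** A transcript is TE-derived iff
(1) at least one of its conserved-domain (blastx-style) hits is to a
TE-related domain, and (2) its top repeat-library (tblastx-style) hit has
*E* < 1e-5 **and** *E* strictly below the top conserved-domain hit's *E*.
Step 2 rejects single-copy genes that merely contain a TE-like domain.
Superfamily follows the top repeat-library hit; a named family is assigned
only when the top repeat blastn hit comes from the focal species at
*E* < 1e-20.

**HTT calling (top-hit incongruence).** Nucleotide-database hits at
*E* < 1e-5 are screened; hits from the focal shrimp family (Penaeidae) are
excluded, and the surviving top hit's organism is mapped to one of 17 taxa
through an ordered rule scheme. A transcript whose top-hit taxon is not
Arthropoda is called HTT; a transcript with no surviving hit is a no-call,
kept distinct from a negative.

**Tree neighbors.** Given an externally built tree per TE family, the
focal sequence's closest relatives are found under both a patristic
(path-length) and a sister-clade definition and labeled by ecological
group (aquatic animals, arthropods, parasites, microorganisms, ...).

**Expression screen.** Counts are TMM-normalized (trimmed mean of
M-values, re-implemented; trim 30 % on M, 5 % on A), summarized per
experimental group, and scored with

```
max fold change (MFC) = maximum group count / minimum group count
```

with a pseudocount of one replacing a zero minimum. Threshold sweeps
report the proportion of each transcript set (overall / TE / HTT) at or
above MFC thresholds 1..40; grouped means are compared by one-way ANOVA.
A one-class SVM (RBF kernel, nu = 0.1) trained on the expression profiles
of HTT transcripts with MFC > 4 flags non-TE transcripts with HTT-like
expression patterns; with two experiments, per-experiment positives are
intersected.

**Synthetic worlds.** `httscan.synth` generates every pipeline input with
planted ground truth — TE transcripts that satisfy the two-step rule by
construction, decoys that fail it, HTT transcripts with planted donor
taxa, negative-binomial count matrices with planted group effects and
HTT-mimicking profiles — so every stage can be scored against truth.

## Worked example

```python
>>> from httscan import (WorldSpec, generate_world, classify_te_transcripts,
...                      call_htt_table, load_taxa17_scheme)
>>> world = generate_world(WorldSpec(n_transcripts=1000, n_te=500,
...                                  n_htt=50, seed=0))
>>> te = classify_te_transcripts(world.hit_tables["cdd"],
...                              world.hit_tables["repeat_lib"],
...                              world.te_domain_flags)
>>> len(te)
500
>>> calls = call_htt_table(world.hit_tables["nt"], te, load_taxa17_scheme())
>>> sum(1 for c in calls if c.is_htt)
50
```

All 500 planted TE transcripts are recovered (the decoys with TE-like
domains but weak repeat hits are rejected by step 2), and the 50 planted
HTT events are called with perfect precision: every call's top surviving
nucleotide hit comes from its planted non-arthropod donor.

The same stages run from the shell:

```
httscan run-all --mode fixtures --outdir out/
```

which prints, among other numbers, `"n_te_transcripts": 395`,
`"n_htt": 157`, `"n_htt_families": 16`, `"n_htt_family_transcripts": 83`
and `"n_virus_top": 30` — the classification and top-hit tallies of the
packaged shrimp study fixtures (see below).

## Layout

| module | role |
| --- | --- |
| `httscan.io` | hit tables (extended outfmt-6), count matrices, Newick |
| `httscan.config` | pipeline thresholds, YAML round trip |
| `httscan.te` | two-step TE call, superfamily/family assignment, tallies |
| `httscan.htt` | taxon schemes, top-hit selection, HTT calls, roll-ups |
| `httscan.trees` | patristic / sister-clade neighbor classification |
| `httscan.expression` | TMM, max fold change, sweeps, grouped ANOVA |
| `httscan.novelty` | one-class SVM expression-pattern matching |
| `httscan.synth` | synthetic worlds with planted ground truth |
| `httscan.fixtures` | packaged study tables as per-transcript fixtures |
| `httscan.cli` | `httscan` command-line interface |
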