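"""Synthetic worlds with known ground truth for every pipeline stage.

Real inputs to the pipeline are BLAST-style hit tables, taxonomy lineages
and RNA-seq count matrices; this module fabricates all of them from a
:class:`WorldSpec` so that detection operations can be scored against
planted truth:

* planted TE transcripts receive a TE-flagged conserved-domain hit and a
  repeat-library hit whose E-value is drawn strictly below both the
  candidate cutoff and the conserved-domain E — they satisfy the two-step
  criterion by construction;
* "EF2-like" decoys carry a TE-flagged domain but a weak repeat hit, the
  single-copy-gene failure mode the second step exists to reject;
* planted HTT transcripts get their best nucleotide hit from a chosen
  non-arthropod donor taxon, with a worse arthropod hit and (sometimes) an
  even better shrimp-family hit that the taxon filter must discard;
* count matrices are negative-binomial (the standard RNA-seq noise model)
  with a multiplicative group effect planted on HTT transcripts and on a
  set of non-TE "mimic" transcripts that the novelty detector should find.

Generation is a pure function of the spec (which includes the seed): the
same spec yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, HitRecord
from .te import load_family_catalog

FOCAL_SPECIES = "Litopenaeus vannamei"
FOCAL_LINEAGE = ("Eukaryota", "Metazoa", "Ecdysozoa", "Arthropoda",
                 "Crustacea", "Decapoda", "Penaeidae", "Litopenaeus")

#: Representative organism and root-to-leaf lineage per taxon label.
ORGANISMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "Arthropoda": ("Drosophila melanogaster",
                   ("Eukaryota", "Metazoa", "Ecdysozoa", "Arthropoda",
                    "Insecta", "Diptera")),
    "Penaeidae": ("Penaeus monodon",
                  ("Eukaryota", "Metazoa", "Ecdysozoa", "Arthropoda",
                   "Crustacea", "Decapoda", "Penaeidae")),
    "Actinopterygii": ("Danio rerio",
                       ("Eukaryota", "Metazoa", "Chordata",
                        "Actinopterygii", "Cypriniformes")),
    "Mollusca": ("Crassostrea gigas",
                 ("Eukaryota", "Metazoa", "Lophotrochozoa", "Mollusca",
                  "Bivalvia")),
    "Echinodermata": ("Strongylocentrotus purpuratus",
                      ("Eukaryota", "Metazoa", "Echinodermata",
                       "Echinoidea")),
    "Brachiopoda": ("Lingula anatina",
                    ("Eukaryota", "Metazoa", "Lophotrochozoa",
                     "Brachiopoda", "Lingulata")),
    "Enteropneusta": ("Saccoglossus kowalevskii",
                      ("Eukaryota", "Metazoa", "Hemichordata",
                       "Enteropneusta")),
    "Annelida": ("Capitella teleta",
                 ("Eukaryota", "Metazoa", "Lophotrochozoa", "Annelida",
                  "Polychaeta")),
    "Alveolata": ("Perkinsus marinus",
                  ("Eukaryota", "Sar", "Alveolata", "Perkinsozoa")),
    "Cyclostomata": ("Petromyzon marinus",
                     ("Eukaryota", "Metazoa", "Chordata", "Cyclostomata",
                      "Petromyzontiformes")),
    "Cnidaria": ("Hydra vulgaris",
                 ("Eukaryota", "Metazoa", "Cnidaria", "Hydrozoa")),
    "Nematoda": ("Trichinella spiralis",
                 ("Eukaryota", "Metazoa", "Ecdysozoa", "Nematoda",
                  "Enoplea")),
    "Platyhelminthes": ("Schistosoma mansoni",
                        ("Eukaryota", "Metazoa", "Lophotrochozoa",
                         "Platyhelminthes", "Trematoda")),
    "Bacteria": ("Vibrio parahaemolyticus",
                 ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                  "Vibrionales")),
    "Viruses": ("White spot syndrome virus",
                ("Viruses", "Naldaviricetes", "Nimaviridae", "Whispovirus")),
    "Embryophyta": ("Vigna radiata",
                    ("Eukaryota", "Viridiplantae", "Streptophyta",
                     "Embryophyta", "Fabales")),
    "Mammalia": ("Homo sapiens",
                 ("Eukaryota", "Metazoa", "Chordata", "Mammalia",
                  "Primates")),
    "Aves": ("Gallus gallus",
             ("Eukaryota", "Metazoa", "Chordata", "Aves", "Galliformes")),
}

DEFAULT_DONOR_TAXA = ("Actinopterygii", "Mollusca", "Echinodermata",
                      "Cnidaria", "Nematoda", "Viruses", "Brachiopoda",
                      "Platyhelminthes")


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world.

    Count-matrix defaults emulate the four-group haemocyte stimulation
    design (blank / control / single / successive injections, three
    replicates each) with negative-binomial noise at dispersion 0.1 and a
    planted eight-fold down-regulation of HTT and mimic transcripts in the
    final group — a strong responder profile, comfortably above the
    MFC > 4 training rule.  The default HTT fraction of the TE set (40 %)
    mirrors the observed study proportion (157 HTT calls among 395 TE
    transcripts) and keeps novelty training sets well above 50 profiles.
    """

    n_transcripts: int = 1000
    n_te: int = 400
    n_htt: int = 160
    n_decoys: int = 30
    n_mimics: int = 20
    p_family: float = 0.6           # TE transcripts given a known family
    p_no_nt_hit: float = 0.15       # TE transcripts left without nt hits
    donor_taxa: tuple[str, ...] = DEFAULT_DONOR_TAXA
    groups: tuple[str, ...] = ("blank", "control", "single_vp28",
                               "successive_vp28")
    replicates: int = 3
    base_mean: float = 200.0
    base_sigma: float = 0.8         # lognormal sigma of per-transcript mean
    dispersion: float = 0.1         # NB: var = mu + disp * mu^2
    htt_effect: float = 8.0         # fold-change planted on HTT + mimics
    projects: tuple[str, ...] = ("project_a", "project_b")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_htt <= self.n_te <= self.n_transcripts:
            raise ValueError("need n_htt <= n_te <= n_transcripts")
        if self.n_decoys + self.n_mimics > self.n_transcripts - self.n_te:
            raise ValueError("decoys + mimics exceed non-TE transcripts")
        if not 0 <= self.p_family <= 1 or not 0 <= self.p_no_nt_hit <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.htt_effect < 1:
            raise ValueError("htt_effect must be >= 1")
        unknown = set(self.donor_taxa) - set(ORGANISMS)
        if unknown or "Arthropoda" in self.donor_taxa \
                or "Penaeidae" in self.donor_taxa:
            raise ValueError(f"invalid donor taxa: "
                             f"{sorted(unknown) or list(self.donor_taxa)}")


@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, plus the planted truth."""

    spec: WorldSpec
    hit_tables: dict[str, list[HitRecord]]      # keyed by database_tag
    te_domain_flags: dict[str, bool]
    domain_descriptions: dict[str, str]
    repeat_annotation: dict[str, tuple[str, str]]
    count_matrices: dict[str, CountMatrix]      # keyed by project
    truth: pd.DataFrame
    lineages: dict[str, tuple[str, ...]]        # organism -> lineage

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.truth.index)


def _loguniform_e(rng: np.random.Generator, lo: float, hi: float) -> float:
    """E-value drawn log10-uniformly on [10^lo, 10^hi]."""
    return float(10.0 ** rng.uniform(lo, hi))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mu, dtype=float))
    return rng.negative_binomial(size, p)


def generate_world(spec: WorldSpec) -> SyntheticWorld:
    """Generate hit tables, count matrices and truth labels for *spec*."""
    rng = np.random.default_rng(spec.seed)
    catalog = load_family_catalog()
    families = sorted(catalog.entries)

    n = spec.n_transcripts
    ids = [f"SYN{i:05d}" for i in range(1, n + 1)]
    order = rng.permutation(n)
    te_idx = set(order[:spec.n_te].tolist())
    htt_idx = set(order[:spec.n_htt].tolist())        # HTT within TE
    non_te = [i for i in range(n) if i not in te_idx]
    decoy_idx = set(non_te[:spec.n_decoys])
    mimic_idx = set(non_te[spec.n_decoys:spec.n_decoys + spec.n_mimics])

    cdd_hits: list[HitRecord] = []
    repeat_hits: list[HitRecord] = []
    blastn_hits: list[HitRecord] = []
    nt_hits: list[HitRecord] = []
    te_domain_flags: dict[str, bool] = {}
    descriptions: dict[str, str] = {}
    repeat_annotation: dict[str, tuple[str, str]] = {}
    rows = []

    def cdd_record(tid: str, subject: str, e: float) -> HitRecord:
        return HitRecord(
            query_id=tid, subject_id=subject, subject_organism="consensus",
            subject_lineage=("cellular organisms",), e_value=e,
            bitscore=round(60 - 2 * np.log10(e + 1e-300), 1),
            query_coverage=float(rng.uniform(0.3, 1.0)), program="blastx",
            database_tag="cdd", q_start=1, q_end=300)

    def repeat_record(tid: str, subject: str, e: float,
                      program: str = "tblastx",
                      organism: str = "repeat consensus") -> HitRecord:
        return HitRecord(
            query_id=tid, subject_id=subject, subject_organism=organism,
            subject_lineage=FOCAL_LINEAGE if organism == FOCAL_SPECIES
            else ("artificial",), e_value=e,
            bitscore=round(60 - 2 * np.log10(e + 1e-300), 1),
            query_coverage=float(rng.uniform(0.3, 1.0)), program=program,
            database_tag="repeat_lib", q_start=1, q_end=300)

    def nt_record(tid: str, taxon: str, e: float) -> HitRecord:
        organism, lineage = ORGANISMS[taxon]
        return HitRecord(
            query_id=tid, subject_id=f"acc_{taxon}_{tid}",
            subject_organism=organism, subject_lineage=lineage, e_value=e,
            bitscore=round(60 - 2 * np.log10(e + 1e-300), 1),
            query_coverage=float(rng.uniform(0.2, 1.0)), program="blastn",
            database_tag="nt", q_start=1, q_end=500)

    for i, tid in enumerate(ids):
        is_te = i in te_idx
        is_htt = i in htt_idx
        is_decoy = i in decoy_idx
        is_mimic = i in mimic_idx
        family = None
        superfamily = None
        donor = None
        has_nt = False

        if is_te:
            family = families[int(rng.integers(len(families)))] \
                if rng.random() < spec.p_family else None
            superfamily = catalog.superfamily(family) if family else \
                rng.choice(["Gypsy", "RTE", "Penelope", "Nimb", "BEL"])
            # TE-flagged domain plus a repeat hit strictly better than both
            # the candidate cutoff and the domain hit
            dom = f"cd_sim_{i:05d}"
            te_domain_flags[dom] = True
            descriptions[dom] = "reverse transcriptase, transposon-related"
            e_cdd = _loguniform_e(rng, -40, -8)
            cdd_hits.append(cdd_record(tid, dom, e_cdd))
            ceiling = min(np.log10(e_cdd), -5.0)
            e_rep = _loguniform_e(rng, ceiling - 20, ceiling - 1)
            consensus = family or f"{superfamily}-sim_consensus"
            repeat_annotation[consensus] = (str(superfamily), "")
            repeat_hits.append(repeat_record(tid, consensus, e_rep))
            if family:
                blastn_hits.append(repeat_record(
                    tid, family, _loguniform_e(rng, -60, -21),
                    program="blastn", organism=FOCAL_SPECIES))
            # nucleotide hits: planted donor (HTT) or arthropod top hit
            if is_htt:
                has_nt = True
                donor = spec.donor_taxa[int(rng.integers(
                    len(spec.donor_taxa)))]
                e_top = _loguniform_e(rng, -60, -30)
                nt_hits.append(nt_record(tid, donor, e_top))
                nt_hits.append(nt_record(
                    tid, "Arthropoda", e_top * 10 ** rng.uniform(5, 15)))
                if rng.random() < 0.5:   # shrimp hit the filter must drop
                    nt_hits.append(nt_record(tid, "Penaeidae", e_top * 1e-10))
            elif rng.random() >= spec.p_no_nt_hit:
                has_nt = True
                e_top = _loguniform_e(rng, -60, -30)
                nt_hits.append(nt_record(tid, "Arthropoda", e_top))
                donor_decoy = spec.donor_taxa[int(rng.integers(
                    len(spec.donor_taxa)))]
                nt_hits.append(nt_record(
                    tid, donor_decoy, e_top * 10 ** rng.uniform(5, 15)))
        elif is_decoy:
            # TE-like domain on a single-copy gene: weak repeat hit only
            dom = f"cd_sim_{i:05d}"
            te_domain_flags[dom] = True
            descriptions[dom] = "TetM-like domain found on transposons"
            e_cdd = _loguniform_e(rng, -30, -10)
            cdd_hits.append(cdd_record(tid, dom, e_cdd))
            e_rep = e_cdd * 10 ** rng.uniform(1, 8)
            repeat_hits.append(repeat_record(tid, "weak_consensus", e_rep))
        else:
            dom = f"cd_host_{i:05d}"
            te_domain_flags[dom] = False
            descriptions[dom] = "housekeeping domain"
            cdd_hits.append(cdd_record(tid, dom,
                                       _loguniform_e(rng, -60, -5)))

        rows.append(dict(
            transcript_id=tid, is_te=is_te, is_htt=is_htt,
            is_decoy=is_decoy, is_mimic=is_mimic,
            superfamily=superfamily, family=family, donor_taxon=donor,
            has_nt_hit=has_nt))

    truth = pd.DataFrame(rows).set_index("transcript_id")

    # ---- count matrices: NB noise, planted effect on HTT + mimics --------
    n_groups = len(spec.groups)
    pattern_on = truth["is_htt"] | truth["is_mimic"]
    multipliers = np.ones((n, n_groups))
    multipliers[pattern_on.to_numpy(), -1] = 1.0 / spec.htt_effect

    matrices: dict[str, CountMatrix] = {}
    for project in spec.projects:
        base = rng.lognormal(
            mean=np.log(spec.base_mean) - spec.base_sigma ** 2 / 2,
            sigma=spec.base_sigma, size=n)
        cols = {}
        groups_map = {}
        for gi, group in enumerate(spec.groups):
            mu = base * multipliers[:, gi]
            for r in range(1, spec.replicates + 1):
                sample = f"{project}_{group}_r{r}"
                cols[sample] = _nb_draw(rng, mu, spec.dispersion)
                groups_map[sample] = group
        counts = pd.DataFrame(cols, index=ids)
        matrices[project] = CountMatrix(
            counts=counts, groups=pd.Series(groups_map), project=project)

    lineages = {org: lin for org, lin in ORGANISMS.values()}
    lineages[FOCAL_SPECIES] = FOCAL_LINEAGE
    return SyntheticWorld(
        spec=spec,
        hit_tables={"cdd": cdd_hits, "repeat_lib": repeat_hits,
                    "repeat_blastn": blastn_hits, "nt": nt_hits},
        te_domain_flags=te_domain_flags,
        domain_descriptions=descriptions,
        repeat_annotation=repeat_annotation,
        count_matrices=matrices, truth=truth, lineages=lineages)
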