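"""HTT calling by top-hit phylogenetic incongruence.

A transcript's nucleotide-database hits are screened at E < 1e-5, hits from
the focal shrimp family (Penaeidae) are removed — close penaeid relatives
would otherwise trivially dominate — and the surviving top hit's organism
is mapped to a coarse taxon through an ordered rule scheme.  A transcript
whose top hit falls outside Arthropoda is called horizontally transferred
(HTT); a transcript with no surviving significant hit is a *no-call*,
reported distinctly from a negative call so that contingency-table margins
stay honest.

Two rule schemes ship with the package: the 17-taxon scheme used for the
top-hit contingency table, and the ecological-habit scheme (shrimp /
aquatic animals / arthropods / parasites / ...) used to color tree
neighbors.  Rules are ordered; the first rule whose include term appears in
the lineage and none of whose exclude terms do supplies the label, so
"Arthropoda minus Penaeidae" is expressed by an exclusion and by placing
the Penaeidae rule first.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import HitRecord, hit_sort_key
from .te import TEClassification, FamilyCatalog


@dataclass(frozen=True)
class TaxonRule:
    label: str
    include_terms: tuple[str, ...]
    exclude_terms: tuple[str, ...] = ()

    def matches(self, lineage: Sequence[str]) -> bool:
        terms = set(lineage)
        if any(t in terms for t in self.exclude_terms):
            return False
        if "*" in self.include_terms:
            return True
        return any(t in terms for t in self.include_terms)


@dataclass(frozen=True)
class TaxonScheme:
    """Ordered first-match-wins lineage->label rules with a fallback.

    ``excluded_labels`` marks labels (e.g. the focal shrimp family) whose
    hits are dropped from all tallies rather than counted.
    """

    name: str
    rules: tuple[TaxonRule, ...]
    fallback: str
    excluded_labels: frozenset[str] = frozenset()

    @property
    def labels(self) -> list[str]:
        out = [r.label for r in self.rules]
        if self.fallback not in out:
            out.append(self.fallback)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None
                 ) -> "TaxonScheme":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        df = df.sort_values("priority")
        rules: list[TaxonRule] = []
        fallback = "Other"
        excluded: set[str] = set()
        for r in df.itertuples():
            include = tuple(t.strip() for t in str(r.include_terms).split(",")
                            if t.strip())
            exclude = tuple(t.strip() for t in str(r.exclude_terms).split(",")
                            if t.strip())
            if include == ("*",):
                fallback = r.label
                continue
            rules.append(TaxonRule(r.label, include, exclude))
            if int(r.excluded):
                excluded.add(r.label)
        return cls(name=name or Path(path).stem, rules=tuple(rules),
                   fallback=fallback, excluded_labels=frozenset(excluded))


def _packaged_scheme(fname: str, name: str) -> TaxonScheme:
    ref = resources.files("httscan.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return TaxonScheme.from_tsv(p, name=name)


def load_taxa17_scheme() -> TaxonScheme:
    """The 17-taxon top-hit scheme (Penaeidae excluded from Arthropoda)."""
    return _packaged_scheme("taxa17.tsv", "taxa17")


def load_ecology_scheme() -> TaxonScheme:
    """The ecological-habit scheme used for tree-neighbor coloring.

    Reproduces the published term table verbatim, including its taxonomic
    oddities (Testudines and Annelida grouped under 'amphibians').
    """
    return _packaged_scheme("table5_ecology.tsv", "ecology")


def map_taxon(lineage: Sequence[str], scheme: TaxonScheme) -> str:
    """Label of the first rule matching *lineage*; fallback when none does."""
    if not lineage:
        raise ValueError("empty lineage cannot be mapped to a taxon")
    for rule in scheme.rules:
        if rule.matches(lineage):
            return rule.label
    return scheme.fallback


@dataclass(frozen=True)
class HTTCall:
    """Per-transcript HTT verdict.  ``is_htt`` is None when no significant
    non-excluded hit survives (a no-call, distinct from a negative)."""

    transcript_id: str
    top_hit_taxon: str | None
    top_hit_organism: str | None
    is_htt: bool | None

    def __post_init__(self) -> None:
        if (self.is_htt is None) != (self.top_hit_taxon is None):
            raise ValueError(
                f"{self.transcript_id}: is_htt defined iff taxon defined")


def select_top_hit(nt_hits: Iterable[HitRecord], scheme: TaxonScheme,
                   e_nt_hit: float = 1e-5
                   ) -> tuple[str, str] | None:
    """(organism, taxon) of the best surviving nucleotide hit, or None.

    Hits at E >= ``e_nt_hit`` and hits mapping to an excluded label are
    dropped before the top hit is taken.
    """
    survivors = []
    for h in nt_hits:
        if h.e_value >= e_nt_hit:
            continue
        taxon = map_taxon(h.subject_lineage, scheme)
        if taxon in scheme.excluded_labels:
            continue
        survivors.append((h, taxon))
    if not survivors:
        return None
    best, taxon = min(survivors, key=lambda ht: hit_sort_key(ht[0]))
    return best.subject_organism, taxon


def call_htt(transcript_id: str, top: tuple[str, str] | None,
             arthropod_label: str = "Arthropoda") -> HTTCall:
    """HTT iff the top-hit taxon is defined and is not the arthropod label."""
    if top is None:
        return HTTCall(transcript_id, None, None, None)
    organism, taxon = top
    return HTTCall(transcript_id, taxon, organism,
                   is_htt=(taxon != arthropod_label))


def call_htt_table(nt_hits: Iterable[HitRecord], transcript_ids: Iterable[str],
                   scheme: TaxonScheme, e_nt_hit: float = 1e-5,
                   arthropod_label: str = "Arthropoda") -> list[HTTCall]:
    """Vectorized convenience: one :class:`HTTCall` per transcript id."""
    by_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in nt_hits:
        by_query[h.query_id].append(h)
    return [call_htt(tid, select_top_hit(by_query.get(tid, ()), scheme,
                                         e_nt_hit), arthropod_label)
            for tid in sorted(set(transcript_ids))]


def tally_taxa(calls: Iterable[HTTCall],
               classifications: Iterable[TEClassification]) -> pd.DataFrame:
    """Superfamily x taxon contingency table of defined-taxon calls,
    with 'Total' margins.  Calls whose transcript id is missing from the
    classifications raise ``KeyError``."""
    sf_by_id = {c.transcript_id: c.superfamily for c in classifications}
    rows = []
    for call in calls:
        if call.top_hit_taxon is None:
            continue
        if call.transcript_id not in sf_by_id:
            raise KeyError(
                f"call for unknown transcript {call.transcript_id!r}")
        rows.append((sf_by_id[call.transcript_id], call.top_hit_taxon))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["superfamily", "taxon"])
    table = pd.crosstab(df["superfamily"], df["taxon"], margins=True,
                        margins_name="Total")
    return table


def htt_family_rollup(calls: Iterable[HTTCall],
                      classifications: Iterable[TEClassification],
                      focal_species: str = "Litopenaeus vannamei",
                      catalog: FamilyCatalog | None = None
                      ) -> tuple[set[str], int]:
    """(families with >=1 HTT transcript, number of HTT transcripts carrying
    a family label).  When a catalog is given, only families recorded for
    *focal_species* count."""
    fam_by_id = {c.transcript_id: c.family for c in classifications}
    families: set[str] = set()
    n = 0
    for call in calls:
        if not call.is_htt:
            continue
        family = fam_by_id.get(call.transcript_id)
        if family is None:
            continue
        if catalog is not None and (
                family not in catalog
                or catalog.species(family) != focal_species):
            continue
        families.add(family)
        n += 1
    return families, n


def best_genome_hit(genome_hits: Iterable[HitRecord],
                    e_genome_hit: float = 1e-10) -> HitRecord | None:
    """Best chromosome/HTGS hit below the significance ceiling, else None
    ('no significant hit')."""
    survivors = [h for h in genome_hits if h.e_value < e_genome_hit]
    if not survivors:
        return None
    return min(survivors, key=hit_sort_key)


def filter_homologue_hits(protein_hits: Iterable[HitRecord],
                          min_protein_coverage: float = 0.60
                          ) -> list[HitRecord]:
    """Protein-hit redundancy filter feeding the phylogenies: drop hits with
    query coverage below the floor, keep only the best hit per organism,
    return sorted best-first."""
    survivors = [h for h in protein_hits
                 if h.query_coverage >= min_protein_coverage]
    best: dict[str, HitRecord] = {}
    for h in survivors:
        prev = best.get(h.subject_organism)
        if prev is None or hit_sort_key(h) < hit_sort_key(prev):
            best[h.subject_organism] = h
    return sorted(best.values(), key=hit_sort_key)
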