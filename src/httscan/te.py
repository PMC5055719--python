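"""TE-transcript identification and superfamily/family classification.

The screen works entirely from homology hit tables:

1. *Prefilter*: transcripts are kept only when they resemble already-known
   nucleotide sequences of the focal species (blastn self-hits below the
   nucleotide E-value cutoff); the remainder are treated as possible
   assembly artifacts or contamination.
2. *Two-step TE call*: a transcript is TE-derived iff (step 1) at least one
   of its conserved-domain (blastx-style) hits is to a TE-related domain,
   and (step 2) its top repeat-library (tblastx-style) hit has E-value
   strictly below the candidate cutoff **and** strictly below the E-value of
   its top conserved-domain hit.  Step 2 exists to reject single-copy genes
   that merely contain a TE-like domain (the classic counter-example being
   an elongation-factor transcript carrying a TetM-like domain).
3. *Superfamily*: that of the top repeat-library hit; *family*: the top
   repeat-library nucleotide (blastn-style) hit, accepted only when it comes
   from the focal species and clears a stringent E-value cutoff.

"Top hit" everywhere means lowest E-value with ties broken by highest
bitscore then lexicographic subject id, so every assignment is invariant
under permutation of hit-table rows.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import HitRecord, top_hit

logger = logging.getLogger(__name__)

GROUPS = ("DNA transposon", "LTR retrotransposon",
          "Non-LTR retrotransposon", "Unknown")


@dataclass(frozen=True)
class TEClassification:
    """Per-transcript TE verdict and its nested classification."""

    transcript_id: str
    is_te: bool
    group: str = "Unknown"
    superfamily: str = "Unknown"
    family: str | None = None
    family_superfamily_consistent: bool | None = None

    def __post_init__(self) -> None:
        if self.family is not None and not self.is_te:
            raise ValueError(
                f"{self.transcript_id}: family set on a non-TE transcript")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class FamilyCatalog:
    """Known TE families: name -> (source species, canonical superfamily,
    canonical group)."""

    entries: Mapping[str, tuple[str, str, str]]

    def __contains__(self, family: str) -> bool:
        return family in self.entries

    def species(self, family: str) -> str:
        return self.entries[family][0]

    def superfamily(self, family: str) -> str:
        return self.entries[family][1]

    def group(self, family: str) -> str:
        return self.entries[family][2]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyCatalog":
        df = pd.read_csv(path, sep="\t")
        if df["family"].duplicated().any():
            raise ValueError("family names must be unique")
        return cls(entries={
            r.family: (r.source_species, r.canonical_superfamily,
                       r.canonical_group)
            for r in df.itertuples()})


def _packaged(name: str):
    return resources.files("httscan.data").joinpath(name)


def load_superfamily_groups() -> dict[str, str]:
    """Packaged superfamily -> TE group table."""
    with resources.as_file(_packaged("superfamily_groups.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["superfamily"], df["group"]))


def load_family_catalog() -> FamilyCatalog:
    """Packaged catalog of the focal species' known TE families."""
    with resources.as_file(_packaged("family_catalog.tsv")) as p:
        return FamilyCatalog.from_tsv(p)


def te_flags_from_descriptions(descriptions: Mapping[str, str],
                               marker: str = "transposon") -> dict[str, bool]:
    """Build the subject->TE-related mapping from a description table.

    A conserved-domain subject is TE-related when its description contains
    *marker* (case-insensitive).  Kept as a helper so the classifier itself
    is decoupled from any database snapshot's wording.
    """
    marker = marker.lower()
    return {sid: marker in (desc or "").lower()
            for sid, desc in descriptions.items()}


def _by_query(hits: Iterable[HitRecord]) -> dict[str, list[HitRecord]]:
    out: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        out[h.query_id].append(h)
    return out


def prefilter_known_species(transcript_ids: Iterable[str],
                            self_hits: Iterable[HitRecord],
                            e_nt_hit: float = 1e-5) -> set[str]:
    """Retain transcripts with at least one self-species blastn hit below
    ``e_nt_hit``; the rest are dropped as possible artifacts/contamination."""
    by_query = _by_query(self_hits)
    return {tid for tid in transcript_ids
            if any(h.e_value < e_nt_hit for h in by_query.get(tid, ()))}


def classify_te_transcripts(cdd_hits: Iterable[HitRecord],
                            repeat_hits: Iterable[HitRecord],
                            te_domain_flags: Mapping[str, bool],
                            e_te_candidate: float = 1e-5) -> set[str]:
    """Two-step TE call; returns the set of TE transcript ids.

    Step 1: >=1 conserved-domain hit whose subject is flagged TE-related.
    Step 2: top repeat-library hit E strictly below ``e_te_candidate`` and
    strictly below the top conserved-domain hit's E.
    """
    cdd_by_query = _by_query(cdd_hits)
    repeat_by_query = _by_query(repeat_hits)
    te_ids: set[str] = set()
    for tid, chits in cdd_by_query.items():
        if not any(te_domain_flags.get(h.subject_id, False) for h in chits):
            continue
        rtop = top_hit(repeat_by_query.get(tid, ()))
        if rtop is None:
            continue
        ctop = top_hit(chits)
        if rtop.e_value < e_te_candidate and rtop.e_value < ctop.e_value:
            te_ids.add(tid)
    return te_ids


def assign_superfamily(repeat_hits: Iterable[HitRecord],
                       repeat_annotation: Mapping[str, tuple[str, str]],
                       transcript_ids: Iterable[str] | None = None,
                       ) -> dict[str, tuple[str, str]]:
    """Superfamily/group of each transcript = that of its top repeat-library
    hit; transcripts with no annotated top hit get ("Unknown", "Unknown")."""
    by_query = _by_query(repeat_hits)
    ids = set(transcript_ids) if transcript_ids is not None \
        else set(by_query)
    groups = load_superfamily_groups()
    out: dict[str, tuple[str, str]] = {}
    for tid in ids:
        hit = top_hit(by_query.get(tid, ()))
        if hit is None or hit.subject_id not in repeat_annotation:
            out[tid] = ("Unknown", "Unknown")
            continue
        superfamily, group = repeat_annotation[hit.subject_id]
        if not group:
            group = groups.get(superfamily, "Unknown")
        out[tid] = (superfamily, group)
    return out


def assign_family(blastn_hits: Iterable[HitRecord],
                  catalog: FamilyCatalog,
                  focal_species: str,
                  e_family: float = 1e-20) -> dict[str, str | None]:
    """Family = the overall top blastn hit's subject, accepted only when it
    is a focal-species family below ``e_family``; otherwise None."""
    out: dict[str, str | None] = {}
    for tid, hits in _by_query(blastn_hits).items():
        hit = top_hit(hits)
        out[tid] = None
        if hit is None or hit.e_value >= e_family:
            continue
        if hit.subject_id not in catalog:
            logger.warning("top blastn hit %r of %s absent from catalog",
                           hit.subject_id, tid)
            continue
        if catalog.species(hit.subject_id) == focal_species:
            out[tid] = hit.subject_id
    return out


def build_classifications(te_ids: Iterable[str],
                          superfamilies: Mapping[str, tuple[str, str]],
                          families: Mapping[str, str | None],
                          catalog: FamilyCatalog) -> list[TEClassification]:
    """Assemble per-transcript classifications, marking family/superfamily
    concordance against the catalog's canonical superfamily."""
    out = []
    for tid in sorted(te_ids):
        superfamily, group = superfamilies.get(tid, ("Unknown", "Unknown"))
        family = families.get(tid)
        consistent: bool | None = None
        if family is not None and family in catalog:
            consistent = catalog.superfamily(family) == superfamily
        out.append(TEClassification(
            transcript_id=tid, is_te=True, group=group,
            superfamily=superfamily, family=family,
            family_superfamily_consistent=consistent))
    return out


def check_family_consistency(classifications: Iterable[TEClassification],
                             catalog: FamilyCatalog) -> list[str]:
    """Families whose canonical superfamily disagrees with the assigned
    superfamily of at least one carrying transcript, each reported once,
    sorted."""
    discordant: set[str] = set()
    for c in classifications:
        if c.family is None or c.family not in catalog:
            continue
        if catalog.superfamily(c.family) != c.superfamily:
            discordant.add(c.family)
    return sorted(discordant)


def tabulate_classifications(classifications: Iterable[TEClassification]
                             ) -> dict[str, dict[str, dict]]:
    """Nested tally group -> superfamily -> {'count', 'families'}.

    Counts are conserved: summing 'count' over the tally equals the number
    of input classifications; family counts sum to the number of
    family-assigned transcripts.
    """
    tally: dict[str, dict[str, dict]] = {}
    for c in classifications:
        cell = tally.setdefault(c.group, {}).setdefault(
            c.superfamily, {"count": 0, "families": defaultdict(int)})
        cell["count"] += 1
        if c.family is not None:
            cell["families"][c.family] += 1
    for group in tally.values():
        for cell in group.values():
            cell["families"] = dict(cell["families"])
    return tally


def tally_totals(tally: Mapping[str, Mapping[str, Mapping]]) -> dict:
    """Convenience margins over a :func:`tabulate_classifications` tally."""
    per_group = {g: sum(c["count"] for c in sfs.values())
                 for g, sfs in tally.items()}
    families: dict[str, int] = defaultdict(int)
    for sfs in tally.values():
        for cell in sfs.values():
            for fam, n in cell["families"].items():
                families[fam] += n
    return {
        "total": sum(per_group.values()),
        "per_group": per_group,
        "n_family_assigned": sum(families.values()),
        "n_distinct_families": len(families),
        "per_family": dict(families),
    }
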