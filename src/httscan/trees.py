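"""Closest-relative classification on externally built trees.

Trees come from ML programs run outside this package; here each focal
(shrimp) sequence's closest relatives are found and labeled by ecological
group.  "Closest" is deliberately implemented two ways, reported side by
side, since a visual reading of a figure admits both:

* ``patristic`` — tips minimizing path-length distance to the focal tip
  (re-rooting invariant; all ties returned);
* ``sister-clade`` — every tip of the focal tip's sibling subtree (a
  topological notion that depends on the rooting shown).

The majority ecological label of the neighbor set is reported; label ties
are flagged ambiguous rather than broken arbitrarily.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

MODES = ("patristic", "sister-clade")


@dataclass
class AnnotatedTree:
    """A tree plus tip->organism and organism->ecological-label mappings.

    ``support_display_threshold`` only governs reporting (figures print
    support values at or above it); no filtering is done with it.
    """

    tree: dendropy.Tree
    tip_organism: Mapping[str, str]
    organism_label: Mapping[str, str]
    focal_tip: str
    name: str = ""
    support_display_threshold: float = 0.9

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        if self.focal_tip not in tips:
            raise ValueError(f"focal tip {self.focal_tip!r} absent from tree")
        missing = tips - set(self.tip_organism)
        if missing:
            raise ValueError(f"tips without organism mapping: "
                             f"{sorted(missing)}")

    def label_of_tip(self, tip: str) -> str:
        return self.organism_label.get(self.tip_organism[tip], "other")


@dataclass(frozen=True)
class NeighborResult:
    neighbor_tips: tuple[str, ...]
    label: str | None       # None when ambiguous
    ambiguous: bool

    @property
    def display_label(self) -> str:
        return "ambiguous" if self.ambiguous else (self.label or "none")


def _patristic_neighbors(tree: dendropy.Tree, focal: str) -> list[str]:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    focal_taxon = taxa[focal]
    dists = {label: pdm.patristic_distance(focal_taxon, t)
             for label, t in taxa.items() if label != focal}
    if not dists:
        return []
    dmin = min(dists.values())
    eps = 1e-9 * max(dmin, 1.0)
    return sorted(l for l, d in dists.items() if d <= dmin + eps)


def _sister_clade_neighbors(tree: dendropy.Tree, focal: str) -> list[str]:
    focal_leaf = next(l for l in tree.leaf_node_iter()
                      if l.taxon.label == focal)
    parent = focal_leaf.parent_node
    if parent is None:
        return []
    siblings = [c for c in parent.child_nodes() if c is not focal_leaf]
    tips: list[str] = []
    for sib in siblings:
        tips.extend(l.taxon.label for l in sib.leaf_iter())
    return sorted(tips)


def nearest_neighbor_class(atree: AnnotatedTree,
                           mode: str = "patristic") -> NeighborResult:
    """Closest relatives of the focal tip and their majority ecological
    label (ties -> ambiguous)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if sum(1 for _ in atree.tree.leaf_node_iter()) < 2:
        raise ValueError("tree needs at least 2 tips")
    if mode == "patristic":
        tips = _patristic_neighbors(atree.tree, atree.focal_tip)
    else:
        tips = _sister_clade_neighbors(atree.tree, atree.focal_tip)
    if not tips:
        return NeighborResult((), None, ambiguous=False)
    counts = Counter(atree.label_of_tip(t) for t in tips)
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return NeighborResult(tuple(tips), None, ambiguous=True)
    return NeighborResult(tuple(tips), ranked[0][0], ambiguous=False)


def neighbor_class_report(atrees: list[AnnotatedTree]) -> pd.DataFrame:
    """One row per tree: neighbor label under each mode plus an agreement
    flag (the two modes standing in for two tree programs' topologies)."""
    rows = []
    for atree in atrees:
        res = {mode: nearest_neighbor_class(atree, mode) for mode in MODES}
        rows.append({
            "family": atree.name or atree.focal_tip,
            "patristic_label": res["patristic"].display_label,
            "patristic_neighbors": ",".join(res["patristic"].neighbor_tips),
            "sister_clade_label": res["sister-clade"].display_label,
            "sister_clade_neighbors":
                ",".join(res["sister-clade"].neighbor_tips),
            "modes_agree": (res["patristic"].display_label
                            == res["sister-clade"].display_label),
        })
    return pd.DataFrame(
        rows, columns=["family", "patristic_label", "patristic_neighbors",
                       "sister_clade_label", "sister_clade_neighbors",
                       "modes_agree"])
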