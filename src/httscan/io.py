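"""Readers and writers for the pipeline's external formats.

Everything downstream of this module works on in-memory domain objects:
:class:`HitRecord` lists, :class:`CountMatrix`, and dendropy trees.  The hit
table dialect is BLAST ``outfmt 6`` (tab-separated, 1-based inclusive query
coordinates) extended with two mandatory taxonomy columns —
``subject_organism`` and a semicolon-joined root-to-leaf ``subject_lineage``
— plus optional ``program``, ``query_length`` and ``query_coverage``
columns.  When ``query_coverage`` is absent it is recomputed as the merged
(non-overlapping) HSP query span of the query/subject pair divided by
``query_length``: the conservative reading in which repeated coverage of
the same region counts once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

PROGRAMS = ("blastx", "tblastx", "blastn", "blastp")
DATABASE_TAGS = ("cdd", "repeat_lib", "nt", "chromosome", "htgs", "protein")

#: Search program conventionally producing hits against each database.
DEFAULT_PROGRAM = {
    "cdd": "blastx",
    "repeat_lib": "tblastx",
    "nt": "blastn",
    "chromosome": "blastn",
    "htgs": "blastn",
    "protein": "blastp",
}

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value",
    "bit_score", "subject_organism", "subject_lineage",
]
OPTIONAL_HIT_COLUMNS = ["program", "query_length", "query_coverage"]


class HitTableFormatError(ValueError):
    """A hit table violated the documented dialect."""


class CountMatrixFormatError(ValueError):
    """A count matrix or design table violated its contract."""


@dataclass(frozen=True)
class HitRecord:
    """One homology hit of a query transcript against a database subject."""

    query_id: str
    subject_id: str
    subject_organism: str
    subject_lineage: tuple[str, ...]
    e_value: float
    bitscore: float
    query_coverage: float
    program: str
    database_tag: str
    q_start: int = 0
    q_end: int = 0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError(
                f"query_coverage must be in [0, 1], got {self.query_coverage}")
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown program {self.program!r}")
        if self.database_tag not in DATABASE_TAGS:
            raise ValueError(f"unknown database_tag {self.database_tag!r}")


def hit_sort_key(hit: HitRecord) -> tuple:
    """Total order defining the 'top hit': lowest E-value first, ties broken
    by highest bitscore, then lexicographic subject id."""
    return (hit.e_value, -hit.bitscore, hit.subject_id)


def top_hit(hits: Iterable[HitRecord]) -> HitRecord | None:
    hits = list(hits)
    if not hits:
        return None
    return min(hits, key=hit_sort_key)


def _merged_span_length(spans: Iterable[tuple[int, int]]) -> int:
    """Total length covered by 1-based inclusive intervals, overlaps merged."""
    ordered = sorted((min(a, b), max(a, b)) for a, b in spans)
    total = 0
    cur_start, cur_end = None, None
    for start, end in ordered:
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def read_hit_table(path: str | Path, database_tag: str) -> list[HitRecord]:
    """Read an extended-outfmt-6 hit table into :class:`HitRecord` objects.

    Raises :class:`HitTableFormatError` naming the offending column or the
    1-based data row on any violation (missing mandatory column, unparsable
    E-value, out-of-range coverage, ...).
    """
    if database_tag not in DATABASE_TAGS:
        raise ValueError(f"unknown database_tag {database_tag!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in HIT_COLUMNS:
            if col not in header:
                raise HitTableFormatError(
                    f"{path.name}: missing mandatory column {col!r}")
        rows = list(reader)

    records: list[HitRecord] = []
    # first pass: parse raw fields, remember HSP spans per (query, subject)
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    parsed: list[dict] = []
    for i, row in enumerate(rows, start=1):
        def fail(msg: str) -> None:
            raise HitTableFormatError(f"{path.name}: row {i}: {msg}")

        try:
            e_value = float(row["e_value"])
        except (TypeError, ValueError):
            fail(f"unparsable e_value {row.get('e_value')!r}")
        if e_value < 0:
            fail(f"negative e_value {e_value}")
        try:
            bitscore = float(row["bit_score"])
            q_start = int(row["q_start"])
            q_end = int(row["q_end"])
        except (TypeError, ValueError):
            fail("unparsable numeric field (bit_score/q_start/q_end)")
        lineage = tuple(
            t.strip() for t in (row["subject_lineage"] or "").split(";")
            if t.strip())
        program = (row.get("program") or "").strip() or \
            DEFAULT_PROGRAM[database_tag]
        if program not in PROGRAMS:
            fail(f"unknown program {program!r}")

        coverage_raw = (row.get("query_coverage") or "").strip()
        qlen_raw = (row.get("query_length") or "").strip()
        coverage = None
        if coverage_raw:
            try:
                coverage = float(coverage_raw)
            except ValueError:
                fail(f"unparsable query_coverage {coverage_raw!r}")
            if not 0 <= coverage <= 1:
                fail(f"query_coverage {coverage} outside [0, 1]")
        parsed.append(dict(
            row=i, query_id=row["query_id"], subject_id=row["subject_id"],
            subject_organism=row["subject_organism"], lineage=lineage,
            e_value=e_value, bitscore=bitscore, q_start=q_start, q_end=q_end,
            coverage=coverage, qlen=int(qlen_raw) if qlen_raw else None,
            program=program))
        spans.setdefault((row["query_id"], row["subject_id"]), []).append(
            (q_start, q_end))

    for p in parsed:
        coverage = p["coverage"]
        if coverage is None:
            if p["qlen"] is None:
                raise HitTableFormatError(
                    f"{path.name}: row {p['row']}: neither query_coverage "
                    "nor query_length given; coverage cannot be determined")
            merged = _merged_span_length(spans[(p["query_id"], p["subject_id"])])
            coverage = min(1.0, merged / p["qlen"])
        records.append(HitRecord(
            query_id=p["query_id"], subject_id=p["subject_id"],
            subject_organism=p["subject_organism"],
            subject_lineage=p["lineage"], e_value=p["e_value"],
            bitscore=p["bitscore"], query_coverage=coverage,
            program=p["program"], database_tag=database_tag,
            q_start=p["q_start"], q_end=p["q_end"]))
    return records


def write_hit_table(records: Sequence[HitRecord], path: str | Path) -> None:
    """Write records in the extended dialect; round-trips with
    :func:`read_hit_table`."""
    cols = HIT_COLUMNS + ["program", "query_coverage"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            writer.writerow([
                r.query_id, r.subject_id, "", r.q_end - r.q_start + 1
                if r.q_end else "", "", "", r.q_start, r.q_end, "", "",
                repr(float(r.e_value)), repr(float(r.bitscore)),
                r.subject_organism, ";".join(r.subject_lineage), r.program,
                repr(float(r.query_coverage))])


@dataclass
class CountMatrix:
    """Read counts per transcript (rows) and sample (columns) plus the
    sample-to-experimental-group design."""

    counts: pd.DataFrame          # transcripts x samples, non-negative int
    groups: pd.Series             # sample -> group label
    project: str = ""

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise CountMatrixFormatError("no transcripts")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise CountMatrixFormatError(
                f"duplicate transcript ids: {sorted(set(dupes))}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise CountMatrixFormatError(
                f"samples missing from design: {missing}")
        absent = [s for s in self.groups.index if s not in self.counts.columns]
        if absent:
            raise CountMatrixFormatError(
                f"design references absent samples: {absent}")
        if (self.counts.values < 0).any():
            raise CountMatrixFormatError("negative counts present")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def group_order(self) -> list[str]:
        """Group labels in first-appearance (design) order."""
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


def read_count_matrix(path: str | Path,
                      design_path: str | Path,
                      project: str = "") -> CountMatrix:
    """Read a transcripts-x-samples integer TSV plus a two-column design
    TSV (``sample<TAB>group``)."""
    path, design_path = Path(path), Path(design_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.shape[0] == 0:
        raise CountMatrixFormatError(f"{path.name}: no transcripts")
    for col in raw.columns:
        series = raw[col]
        bad = series[(series != series.round()) | (series < 0) |
                     series.isna()]
        if len(bad):
            tid = bad.index[0]
            raise CountMatrixFormatError(
                f"{path.name}: non-integer or negative count at "
                f"transcript {tid!r}, sample {col!r}: {bad.iloc[0]!r}")
    design = pd.read_csv(design_path, sep="\t")
    if not {"sample", "group"} <= set(design.columns):
        raise CountMatrixFormatError(
            f"{design_path.name}: needs 'sample' and 'group' columns")
    groups = design.set_index("sample")["group"]
    if groups.index.duplicated().any():
        raise CountMatrixFormatError(
            f"{design_path.name}: duplicate sample rows")
    return CountMatrix(counts=raw.astype(int), groups=groups, project=project)


def write_count_matrix(matrix: CountMatrix, path: str | Path,
                       design_path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="transcript_id")
    pd.DataFrame({"sample": matrix.groups.index,
                  "group": matrix.groups.values}).to_csv(
        design_path, sep="\t", index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; absent branch lengths default to 1.

    Duplicate tip labels raise ``ValueError`` (downstream tip->organism
    mapping needs unique labels).
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.\
            NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicated tip labels in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicated tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
    return tree
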