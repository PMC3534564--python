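"""Spreadsheet-style table editing and the multi-level merge engine.

The merge engine joins two experiment tables through an *ordered* list
of key relations.  A left row is matched at the earliest relation whose
key connects it to any right row and is excluded from later relations,
so the per-level match counts partition the left table exactly.  A
relation may translate the left key through the identifier
cross-reference tables first (e.g. Entrez → gene symbol), which is how
rows that share no direct identifier still find each other.

Duplicate keys expand cartesianly (every matching right row produces an
output row); :func:`dedupe_rows` is the explicit alternative when a
first-match semantic is wanted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import idmap
from .datastore import NA, Snapshot


def _read_tsv_skip_comments(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        start += 1
    from io import StringIO

    return pd.read_csv(StringIO("".join(lines[start:])), sep="\t", dtype=str, keep_default_na=False)


class ExperimentTable:
    """A named-column table with stable row ids assigned at load.

    Cells are strings with ``"NA"`` as the missing token; numeric
    interpretation is deferred to the consumer (e.g. clustering).
    Row ids survive edits, so provenance of a row is traceable through
    dedup/split/merge chains.
    """

    def __init__(self, df: pd.DataFrame, row_ids: list[int] | None = None):
        cols = list(df.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate column name(s): {dupes}")
        self.df = df.copy()
        self.df.index = pd.Index(
            row_ids if row_ids is not None else range(len(df)), name="row_id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExperimentTable":
        return cls(_read_tsv_skip_comments(Path(path)))

    def to_tsv(self, path: str | Path, header_lines: tuple[str, ...] = ()) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def __len__(self) -> int:
        return len(self.df)

    def require_columns(self, names: list[str]) -> None:
        missing = [c for c in names if c not in self.df.columns]
        if missing:
            raise ValueError(f"column(s) {missing} not present in table (has {self.columns})")


@dataclass(frozen=True)
class MergeRelation:
    """One level of a merge plan.

    ``translation``, when given, is ``(from_ns, to_ns, species)`` applied
    to the LEFT key through the cross-reference tables before comparison.
    ``namespace`` declares the namespace of the compared key so the
    matching case rule follows identifier conventions (symbols fold
    case, everything else is exact); the translated namespace takes
    precedence when a translation is set.
    """

    left_column: str
    right_column: str
    translation: tuple[str, str, str] | None = None
    namespace: str | None = None

    def fold_case(self) -> bool:
        ns = self.translation[1] if self.translation else self.namespace
        return ns == "gene_symbol"


@dataclass(frozen=True)
class MergePlan:
    relations: tuple[MergeRelation, ...]
    mode: str = "intersection"
    output_columns: tuple[str, ...] | None = None

    def __post_init__(self):
        if not self.relations:
            raise ValueError("a merge plan needs at least one relation")
        if self.mode not in ("intersection", "union"):
            raise ValueError(f"mode must be 'intersection' or 'union', got {self.mode!r}")


@dataclass
class MergeReport:
    """Per-level accounting of a multi-level merge.

    ``matched_by_level[i]`` counts LEFT rows first matched at relation
    ``i+1``; these sum to ``matched_total`` and, with
    ``left_unmatched``, partition the left table.  ``matched_pairs`` is
    the number of matched output rows (>= ``matched_total`` under
    one-to-many expansion).
    """

    matched_by_level: list[int] = field(default_factory=list)
    matched_total: int = 0
    left_unmatched: int = 0
    right_unmatched: int = 0
    matched_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": i + 1, "left_rows_matched": n}
            for i, n in enumerate(self.matched_by_level)
        ]
        rows.append({"level": "total_matched", "left_rows_matched": self.matched_total})
        rows.append({"level": "left_unmatched", "left_rows_matched": self.left_unmatched})
        rows.append({"level": "right_unmatched", "left_rows_matched": self.right_unmatched})
        rows.append({"level": "matched_output_rows", "left_rows_matched": self.matched_pairs})
        return pd.DataFrame(rows, columns=["level", "left_rows_matched"])


def _suffix_columns(left_cols: list[str], right_cols: list[str]) -> tuple[dict, dict]:
    shared = set(left_cols) & set(right_cols)
    lmap = {c: (f"{c}_left" if c in shared else c) for c in left_cols}
    rmap = {c: (f"{c}_right" if c in shared else c) for c in right_cols}
    return lmap, rmap


def merge_datasets(
    left: ExperimentTable,
    right: ExperimentTable,
    plan: MergePlan,
    snapshot: Snapshot | None = None,
) -> tuple[ExperimentTable, MergeReport]:
    """Apply an ordered multi-level merge plan.

    Relations are applied in plan order; a left row matched at level *i*
    never participates in levels > *i*.  ``"NA"`` keys never match.
    Intersection mode keeps only matched rows; union mode appends the
    unmatched left then unmatched right rows with NA fill.  Shared
    column names get ``_left``/``_right`` suffixes.
    """
    for rel in plan.relations:
        left.require_columns([rel.left_column])
        right.require_columns([rel.right_column])
        if rel.translation is not None:
            from_ns, to_ns, _species = rel.translation
            idmap.check_namespace(from_ns)
            idmap.check_namespace(to_ns)
            if snapshot is None:
                raise ValueError("a snapshot is required for translated merge relations")

    remaining = list(left.df.index)
    right_matched: set[int] = set()
    matches: list[tuple[int, int]] = []  # (left_row_id, right_row_id)
    report = MergeReport()

    for rel in plan.relations:
        fold = rel.fold_case()

        def norm(v: str) -> str:
            return v.casefold() if fold else v

        right_index: dict[str, list[int]] = {}
        for rid, value in zip(right.df.index, right.df[rel.right_column].astype(str)):
            if value != NA and value != "":
                right_index.setdefault(norm(value), []).append(rid)

        # left key -> list of comparable values (several after translation)
        left_values = left.df[rel.left_column].astype(str)
        if rel.translation is not None:
            from_ns, to_ns, species = rel.translation
            distinct = sorted({v for v in left_values[remaining] if v not in (NA, "")})
            translated: dict[str, list[str]] = {v: [] for v in distinct}
            if distinct:
                mapping = idmap.xref(distinct, from_ns, to_ns, species, snapshot)
                for row in mapping.itertuples(index=False):
                    if row.matched:
                        translated[row.input_id].append(row.output_id)

            def keys_for(v: str) -> list[str]:
                return translated.get(v, [])

        else:

            def keys_for(v: str) -> list[str]:
                return [] if v in (NA, "") else [v]

        matched_here = 0
        still_remaining = []
        for lid in remaining:
            hit_rids: list[int] = []
            seen: set[int] = set()
            for key in keys_for(left_values.at[lid]):
                for rid in right_index.get(norm(key), []):
                    if rid not in seen:
                        seen.add(rid)
                        hit_rids.append(rid)
            if hit_rids:
                matched_here += 1
                for rid in sorted(hit_rids):
                    matches.append((lid, rid))
                right_matched.update(hit_rids)
            else:
                still_remaining.append(lid)
        remaining = still_remaining
        report.matched_by_level.append(matched_here)

    report.matched_total = sum(report.matched_by_level)
    report.left_unmatched = len(remaining)
    report.right_unmatched = len(right.df) - len(right_matched)
    report.matched_pairs = len(matches)

    lmap, rmap = _suffix_columns(left.columns, right.columns)
    out_columns = [lmap[c] for c in left.columns] + [rmap[c] for c in right.columns]

    matches.sort()
    out_rows = []
    for lid, rid in matches:
        out_rows.append(list(left.df.loc[lid].astype(str)) + list(right.df.loc[rid].astype(str)))
    if plan.mode == "union":
        for lid in remaining:
            out_rows.append(list(left.df.loc[lid].astype(str)) + [NA] * len(right.columns))
        for rid in right.df.index:
            if rid not in right_matched:
                out_rows.append([NA] * len(left.columns) + list(right.df.loc[rid].astype(str)))

    merged_df = pd.DataFrame(out_rows, columns=out_columns)
    if plan.output_columns is not None:
        missing = [c for c in plan.output_columns if c not in merged_df.columns]
        if missing:
            raise ValueError(f"output column(s) {missing} not present after merge")
        merged_df = merged_df[list(plan.output_columns)]
    return ExperimentTable(merged_df), report


def dedupe_rows(t: ExperimentTable, key_columns: list[str]) -> ExperimentTable:
    """Keep the first occurrence (by row id) of each key combination."""
    if not key_columns:
        raise ValueError("key_columns must not be empty")
    t.require_columns(key_columns)
    keep_mask = ~t.df.duplicated(subset=key_columns, keep="first")
    removed = int((~keep_mask).sum())
    out = ExperimentTable(t.df[keep_mask], row_ids=list(t.df.index[keep_mask]))
    out.df.attrs["n_removed"] = removed
    if removed:
        warnings.warn(f"dedupe_rows removed {removed} duplicate row(s)", UserWarning, stacklevel=2)
    return out


def split_column(t: ExperimentTable, column: str, delimiter: str) -> ExperimentTable:
    """Split a delimited column into ``column_1 .. column_N`` part columns.

    N is the largest part count observed; rows with fewer parts are
    padded with NA.  The original column is kept.
    """
    if delimiter == "":
        raise ValueError("delimiter must not be empty")
    t.require_columns([column])
    parts = [str(v).split(delimiter) for v in t.df[column]]
    n = max((len(p) for p in parts), default=1)
    df = t.df.copy()
    for i in range(n):
        df[f"{column}_{i + 1}"] = [p[i] if i < len(p) else NA for p in parts]
    return ExperimentTable(df, row_ids=list(t.df.index))


def merge_columns(
    t: ExperimentTable, columns: list[str], joiner: str, new_column: str | None = None
) -> ExperimentTable:
    """Concatenate columns with *joiner*, skipping NA cells."""
    if not columns:
        raise ValueError("columns must not be empty")
    t.require_columns(columns)
    name = new_column or "_".join(columns)
    df = t.df.copy()
    merged = []
    for _, row in df[columns].iterrows():
        vals = [str(v) for v in row if str(v) != NA]
        merged.append(joiner.join(vals) if vals else NA)
    df[name] = merged
    return ExperimentTable(df, row_ids=list(t.df.index))


#: Patterns for identifiers commonly embedded in free-text columns.
ID_PATTERNS: dict[str, str] = {
    "genbank": r"\b(?:NM|NR|XM|XR|NP|XP)_\d+(?:\.\d+)?",
    "ensembl_gene": r"\bENS[A-Z]{0,4}G\d{6,}",
    "ensembl_transcript": r"\bENS[A-Z]{0,4}T\d{6,}",
    "entrez": r"\b\d+\b",
    "go_term": r"\bGO:\d{7}",
}


def extract_ids(
    t: ExperimentTable, column: str, pattern: str, new_column: str | None = None
) -> ExperimentTable:
    """Extract the first embedded identifier match from each cell.

    *pattern* is a preset name from :data:`ID_PATTERNS` or a custom
    regular expression; cells without a match get NA.
    """
    t.require_columns([column])
    regex_src = ID_PATTERNS.get(pattern, pattern)
    try:
        regex = re.compile(regex_src)
    except re.error as exc:
        raise ValueError(f"invalid pattern {pattern!r}: {exc}") from exc
    name = new_column or f"{column}_{pattern if pattern in ID_PATTERNS else 'extracted'}"
    df = t.df.copy()
    out = []
    for v in df[column]:
        m = regex.search(str(v))
        out.append(m.group(0) if m else NA)
    df[name] = out
    return ExperimentTable(df, row_ids=list(t.df.index))
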