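"""Local reference snapshot: loading, validation and indexing.

A *snapshot* is a plain directory of tab-separated tables plus a
``manifest.tsv`` naming them.  It stands in for a mirrored copy of the
public miRNA-target, identifier cross-reference, ortholog and annotation
databases, so that every retrieval in this package runs offline and is
reproducible against a frozen data version.

Conventions shared by all tables:

* UTF-8, tab-separated, exactly one header row;
* the literal string ``"NA"`` is the missing-value token (cells are kept
  as strings on load, never coerced to floats);
* species are coded ``hsa``/``mmu``/``rno``/``dre``/``mml``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NA = "NA"

SPECIES_CODES = frozenset({"hsa", "mmu", "rno", "dre", "mml"})

#: The three miRNA target-prediction sources and their snapshot tables.
SOURCES = ("targetscan", "microcosm", "mirnaorg")
TARGET_TABLES = {s: f"targets_{s}" for s in SOURCES}

TARGET_COLUMNS = ["species", "mirna_id", "gene_symbol", "entrez_id", "ensembl_transcript"]

TABLE_COLUMNS: dict[str, list[str]] = {
    "targets_targetscan": TARGET_COLUMNS,
    "targets_microcosm": TARGET_COLUMNS,
    "targets_mirnaorg": TARGET_COLUMNS,
    "mirna_metadata": ["species", "mirna_id", "mature_accession", "mature_sequence"],
    "xref": ["species", "gene_key", "namespace", "value"],
    "orthologs": [
        "src_species",
        "src_ensembl_gene",
        "dst_species",
        "dst_ensembl_gene",
        "pct_identity_src",
        "pct_identity_dst",
    ],
    "annotations_go": ["species", "gene_symbol", "term_id", "term_name", "category"],
    "annotations_kegg": ["species", "gene_symbol", "term_id", "term_name", "category"],
}

#: Default hard cap on retrieval result size, mirroring the server-side
#: subset limit of the original tool.
DEFAULT_MAX_ROWS = 500_000


class SnapshotError(Exception):
    """Fatal problem with a snapshot directory or one of its tables."""


@dataclass(frozen=True)
class RetrievalCap:
    """Upper bound on rows returned by a single retrieval.

    Retrievals exceeding ``max_rows`` are truncated; truncation always
    emits a :class:`UserWarning` and sets ``attrs["truncated"]`` on the
    result frame so provenance is never silent.
    """

    max_rows: int = DEFAULT_MAX_ROWS

    def __post_init__(self) -> None:
        if self.max_rows <= 0:
            raise ValueError("max_rows must be a positive integer")

    def apply(self, df: pd.DataFrame, what: str = "retrieval") -> pd.DataFrame:
        if len(df) > self.max_rows:
            warnings.warn(
                f"{what} returned {len(df)} rows; truncated to {self.max_rows}",
                UserWarning,
                stacklevel=2,
            )
            df = df.head(self.max_rows).copy()
            df.attrs["truncated"] = True
        else:
            df.attrs.setdefault("truncated", False)
        return df


@dataclass
class ValidationReport:
    """Deterministic per-table accounting for a loaded snapshot."""

    row_counts: dict[str, int] = field(default_factory=dict)
    duplicate_rows: dict[str, int] = field(default_factory=dict)
    dangling_mirna_refs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "table": t,
                "rows": self.row_counts[t],
                "duplicate_rows": self.duplicate_rows.get(t, 0),
            }
            for t in sorted(self.row_counts)
        ]
        return pd.DataFrame(rows, columns=["table", "rows", "duplicate_rows"])


@dataclass
class Snapshot:
    """An indexed, read-only view of a snapshot directory."""

    root_path: Path
    version_tag: str
    tables: dict[str, pd.DataFrame]
    absent_tables: list[str] = field(default_factory=list)
    validation: ValidationReport | None = None

    def has(self, name: str) -> bool:
        return name in self.tables

    def table(self, name: str) -> pd.DataFrame:
        if name not in self.tables:
            raise SnapshotError(
                f"snapshot at {self.root_path} has no table {name!r} "
                f"(absent: {sorted(self.absent_tables)})"
            )
        return self.tables[name]

    def orthologs_bidirectional(self) -> pd.DataFrame:
        """Ortholog pairs materialized in both directions.

        The table is stored directionally; queries must never miss a pair
        because it was recorded the other way round, so the reverse rows
        (fields and percent identities swapped) are appended here.
        """
        fwd = self.table("orthologs")
        rev = fwd.rename(
            columns={
                "src_species": "dst_species",
                "dst_species": "src_species",
                "src_ensembl_gene": "dst_ensembl_gene",
                "dst_ensembl_gene": "src_ensembl_gene",
                "pct_identity_src": "pct_identity_dst",
                "pct_identity_dst": "pct_identity_src",
            }
        )[fwd.columns]
        both = pd.concat([fwd, rev], ignore_index=True)
        return both.drop_duplicates(ignore_index=True)


def read_table(path: Path) -> pd.DataFrame:
    """Read one snapshot TSV with all cells kept as strings."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_snapshot(root_path: str | Path) -> Snapshot:
    """Load and index the snapshot rooted at *root_path*.

    The manifest (``manifest.tsv``, columns ``table_name``/``file_name``)
    is the source of truth for which tables exist.  A file named in the
    manifest but missing on disk, or a table whose header deviates from
    the declared schema, is fatal; a known table simply absent from the
    manifest is recorded in ``absent_tables``.  Referential problems
    (e.g. a target row whose miRNA is missing from the metadata table)
    are warnings in the attached :class:`ValidationReport`, not errors.
    """
    root = Path(root_path)
    manifest_path = root / "manifest.tsv"
    if not manifest_path.is_file():
        raise SnapshotError(f"manifest not found: {manifest_path}")
    manifest = read_table(manifest_path)
    for col in ("table_name", "file_name"):
        if col not in manifest.columns:
            raise SnapshotError(f"malformed manifest {manifest_path}: missing column {col!r}")

    tables: dict[str, pd.DataFrame] = {}
    for row in manifest.itertuples(index=False):
        name, fname = row.table_name, row.file_name
        path = root / fname
        if not path.is_file():
            raise SnapshotError(f"table file missing: {path} (declared as {name!r})")
        df = read_table(path)
        expected = TABLE_COLUMNS.get(name)
        if expected is not None and list(df.columns) != expected:
            missing = [c for c in expected if c not in df.columns]
            raise SnapshotError(
                f"malformed header in {path}: expected columns {expected}, "
                f"got {list(df.columns)} (missing {missing})"
            )
        tables[name] = df

    version_path = root / "version.txt"
    version_tag = version_path.read_text().strip() if version_path.is_file() else "unversioned"

    absent = sorted(set(TABLE_COLUMNS) - set(tables))
    snap = Snapshot(root_path=root, version_tag=version_tag, tables=tables, absent_tables=absent)
    snap.validation = validate_snapshot(snap)
    return snap


def validate_snapshot(s: Snapshot) -> ValidationReport:
    """Recount rows, exact-duplicate rows and dangling miRNA references.

    Purely reporting: the same snapshot always yields the same report.
    """
    report = ValidationReport()
    for name, df in s.tables.items():
        report.row_counts[name] = len(df)
        n_dup = len(df) - len(df.drop_duplicates())
        report.duplicate_rows[name] = n_dup
        if n_dup:
            report.warnings.append(f"{name}: {n_dup} exactly duplicated row(s)")

    if s.has("mirna_metadata"):
        meta = s.table("mirna_metadata")
        known = set(zip(meta["species"], meta["mirna_id"]))
        for src, tname in TARGET_TABLES.items():
            if not s.has(tname):
                continue
            tdf = s.table(tname)
            seen = set(zip(tdf["species"], tdf["mirna_id"]))
            for species, mirna in sorted(seen - known):
                msg = f"{tname}: miRNA {mirna!r} ({species}) absent from mirna_metadata"
                report.dangling_mirna_refs.append(msg)
                report.warnings.append(msg)
    return report
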