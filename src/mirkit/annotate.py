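"""Batch annotation joins against the snapshot's GO / KEGG / gene tables.

Annotation either appends a multi-valued column to the experiment table
("wide", terms joined by ``"; "`` in term-id order) or emits one row per
(gene, term) ("long", the precursor of a GMT gene-set file).  For
sparsely annotated species, :func:`annotate_via_ortholog` bridges each
gene to an ortholog in a better-annotated species, annotates there and
carries the terms back keyed by the original identifier.
"""

from __future__ import annotations

import pandas as pd

from . import idmap
from .datastore import NA, Snapshot
from .tableops import ExperimentTable

ANNOTATION_SOURCES = ("go", "kegg", "gene")

_SOURCE_TABLE = {"go": "annotations_go", "kegg": "annotations_kegg"}


def _symbols_for_ids(
    ids: list[str], id_type: str, species: str, s: Snapshot
) -> dict[str, list[str]]:
    """Map each input id to its gene symbols (identity for symbol input)."""
    unique, _ = idmap.dedupe_preserving_order(ids)
    if id_type == "gene_symbol":
        return {i: [i] for i in unique}
    mapping = idmap.xref(unique, id_type, "gene_symbol", species, s)
    out: dict[str, list[str]] = {i: [] for i in unique}
    for row in mapping.itertuples(index=False):
        if row.matched:
            out[row.input_id].append(row.output_id)
    return out


def _term_index(source: str, species: str, s: Snapshot) -> dict[str, list[tuple[str, str, str]]]:
    """Folded gene symbol -> sorted [(term_id, term_name, category)]."""
    table = s.table(_SOURCE_TABLE[source])
    table = table[table["species"] == species]
    index: dict[str, set[tuple[str, str, str]]] = {}
    for row in table.itertuples(index=False):
        index.setdefault(row.gene_symbol.casefold(), set()).add(
            (row.term_id, row.term_name, row.category)
        )
    return {k: sorted(v) for k, v in index.items()}


def _format_terms(terms: list[tuple[str, str, str]]) -> str:
    if not terms:
        return NA
    return "; ".join(f"{tid} ({tname})" for tid, tname, _cat in terms)


def annotate(
    t: ExperimentTable,
    id_column: str,
    id_type: str,
    source: str,
    species: str,
    s: Snapshot,
    layout: str = "wide",
) -> ExperimentTable:
    """Attach GO/KEGG terms (or gene identifier columns) to a table.

    Wide layout overwrites its appended column on re-run, so the
    operation is idempotent.  Long layout repeats each input row once
    per term; unannotated rows appear once with NA term fields.
    """
    if source not in ANNOTATION_SOURCES:
        raise ValueError(f"unknown annotation source {source!r}; expected one of {ANNOTATION_SOURCES}")
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    t.require_columns([id_column])
    idmap.check_namespace(id_type)

    ids = [str(v) for v in t.df[id_column]]

    if source == "gene":
        # identifier enrichment: append the other core namespaces via xref
        df = t.df.copy()
        for ns in ("gene_symbol", "entrez", "ensembl_gene"):
            if ns == id_type:
                continue
            mapping = idmap.xref(sorted(set(ids)), id_type, ns, species, s)
            values: dict[str, list[str]] = {}
            for row in mapping.itertuples(index=False):
                if row.matched:
                    values.setdefault(row.input_id, []).append(row.output_id)
            df[ns] = ["; ".join(sorted(values.get(v, []))) or NA for v in ids]
        return ExperimentTable(df, row_ids=list(t.df.index))

    symbols = _symbols_for_ids(ids, id_type, species, s)
    index = _term_index(source, species, s)

    def terms_for(input_id: str) -> list[tuple[str, str, str]]:
        collected: set[tuple[str, str, str]] = set()
        for sym in symbols.get(input_id, []):
            collected.update(index.get(sym.casefold(), []))
        return sorted(collected)

    if layout == "wide":
        df = t.df.copy()
        df[f"{source}_terms"] = [_format_terms(terms_for(v)) for v in ids]
        return ExperimentTable(df, row_ids=list(t.df.index))

    rows = []
    row_ids = []
    for rid, v in zip(t.df.index, ids):
        terms = terms_for(v) or [(NA, NA, NA)]
        for tid, tname, cat in terms:
            rows.append(list(t.df.loc[rid].astype(str)) + [tid, tname, cat])
            row_ids.append(rid)
    long_df = pd.DataFrame(rows, columns=t.columns + ["term_id", "term_name", "category"])
    return ExperimentTable(long_df)


def annotate_via_ortholog(
    t: ExperimentTable,
    id_column: str,
    src: str,
    bridge: str,
    source: str,
    s: Snapshot,
    id_type: str = "ensembl_gene",
    layout: str = "wide",
) -> ExperimentTable:
    """Annotate through an ortholog in the *bridge* species.

    Ids are converted to Ensembl gene ids if needed, mapped
    src → bridge through the ortholog table, annotated in the bridge
    species and the terms carried back keyed by the original id.  A
    provenance column records the bridge gene(s) used; genes with no
    ortholog get NA.
    """
    t.require_columns([id_column])
    ids = [str(v) for v in t.df[id_column]]
    unique, _ = idmap.dedupe_preserving_order(ids)

    if id_type == "ensembl_gene":
        ensembl_by_input = {i: [i] for i in unique}
    else:
        mapping = idmap.xref(unique, id_type, "ensembl_gene", src, s)
        ensembl_by_input = {i: [] for i in unique}
        for row in mapping.itertuples(index=False):
            if row.matched:
                ensembl_by_input[row.input_id].append(row.output_id)

    all_ens = sorted({e for v in ensembl_by_input.values() for e in v})
    bridge_by_ens: dict[str, list[str]] = {e: [] for e in all_ens}
    if all_ens:
        pairs = idmap.map_orthologs(all_ens, src, bridge, s)
        for row in pairs.itertuples(index=False):
            if row.dst_ensembl_gene != NA:
                bridge_by_ens[row.src_ensembl_gene].append(row.dst_ensembl_gene)

    bridge_genes = sorted({b for v in bridge_by_ens.values() for b in v})
    sym_by_bridge: dict[str, list[str]] = {b: [] for b in bridge_genes}
    if bridge_genes:
        mapping = idmap.xref(bridge_genes, "ensembl_gene", "gene_symbol", bridge, s)
        for row in mapping.itertuples(index=False):
            if row.matched:
                sym_by_bridge[row.input_id].append(row.output_id)

    index = _term_index(source, bridge, s)

    def bridge_info(input_id: str) -> tuple[list[str], list[tuple[str, str, str]]]:
        bridges: list[str] = []
        terms: set[tuple[str, str, str]] = set()
        for ens in ensembl_by_input.get(input_id, []):
            for b in bridge_by_ens.get(ens, []):
                bridges.append(b)
                for sym in sym_by_bridge.get(b, []):
                    terms.update(index.get(sym.casefold(), []))
        return sorted(set(bridges)), sorted(terms)

    df = t.df.copy()
    term_cells = []
    bridge_cells = []
    for v in ids:
        bridges, terms = bridge_info(v)
        term_cells.append(_format_terms(terms))
        bridge_cells.append("; ".join(bridges) if bridges else NA)
    df[f"{source}_terms_{bridge}"] = term_cells
    df[f"{source}_bridge_gene"] = bridge_cells
    return ExperimentTable(df, row_ids=list(t.df.index))


def parse_term_cell(cell: str) -> set[str]:
    """Term ids from a wide-layout annotation cell."""
    if cell == NA:
        return set()
    return {part.split(" (")[0] for part in cell.split("; ")}


def write_gmt(long_table: pd.DataFrame, path) -> None:
    """Write a long (gene, term) table as a standard GMT gene-set file."""
    groups: dict[tuple[str, str], list[str]] = {}
    for row in long_table.itertuples(index=False):
        if row.term_id == NA:
            continue
        gene = getattr(row, "gene_symbol", None) or row[0]
        groups.setdefault((row.term_id, row.term_name), []).append(str(gene))
    with open(path, "w", encoding="utf-8") as fh:
        for (tid, tname), members in sorted(groups.items()):
            uniq = sorted(set(members))
            fh.write("\t".join([tid, tname, *uniq]) + "\n")
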