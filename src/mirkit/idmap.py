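"""Identifier cross-referencing and cross-species ortholog mapping.

Within a species, gene identifiers live in one of six namespaces
(symbol, Entrez, Ensembl gene/transcript, GenBank, UniProt) tied
together by an internal gene key.  Across species, Ensembl gene IDs are
the mapping currency, with the percent identity of the alignment carried
in both directions.

Matching rules: gene symbols are compared case-insensitively (zebrafish
symbols are conventionally lower-case where human are upper-case); every
other namespace is matched exactly.  One-to-many mappings expand to one
output row per value so downstream merges always join on atomic keys.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .datastore import NA, Snapshot, SnapshotError

NAMESPACES = (
    "gene_symbol",
    "entrez",
    "ensembl_gene",
    "ensembl_transcript",
    "genbank",
    "uniprot",
)

XREF_COLUMNS = ["input_id", "output_id", "matched"]
ORTHOLOG_COLUMNS = [
    "src_species",
    "src_ensembl_gene",
    "dst_species",
    "dst_ensembl_gene",
    "pct_identity_src",
    "pct_identity_dst",
]


def check_namespace(ns: str) -> str:
    if ns not in NAMESPACES:
        raise ValueError(f"unknown namespace {ns!r}; expected one of {NAMESPACES}")
    return ns


def normalize_key(value: str, namespace: str) -> str:
    """Fold case for symbol comparison; leave all other namespaces verbatim."""
    return value.casefold() if namespace == "gene_symbol" else value


def dedupe_preserving_order(ids: list[str]) -> tuple[list[str], int]:
    seen: dict[str, None] = {}
    for i in ids:
        seen.setdefault(i, None)
    return list(seen), len(ids) - len(seen)


def xref(
    ids: list[str],
    from_ns: str,
    to_ns: str,
    species: str,
    s: Snapshot,
) -> pd.DataFrame:
    """Map identifiers from one namespace to another within a species.

    Returns one row per (input id, distinct output value), in input
    order with output values sorted; unmapped inputs appear exactly once
    with ``output_id == "NA"`` and ``matched == False``.  Duplicate
    inputs are collapsed before the query (the number removed is in
    ``attrs["n_input_duplicates"]``).
    """
    check_namespace(from_ns)
    check_namespace(to_ns)
    if from_ns == to_ns:
        raise ValueError("from_ns and to_ns must differ")

    unique_ids, n_dup = dedupe_preserving_order(list(ids))
    xt = s.table("xref")
    xt = xt[xt["species"] == species]

    src = xt[xt["namespace"] == from_ns]
    key_by_value: dict[str, set[str]] = {}
    for value, gene_key in zip(src["value"], src["gene_key"]):
        key_by_value.setdefault(normalize_key(value, from_ns), set()).add(gene_key)

    dst = xt[xt["namespace"] == to_ns]
    values_by_key: dict[str, set[str]] = {}
    for value, gene_key in zip(dst["value"], dst["gene_key"]):
        values_by_key.setdefault(gene_key, set()).add(value)

    rows: list[tuple[str, str, bool]] = []
    for input_id in unique_ids:
        keys = key_by_value.get(normalize_key(input_id, from_ns), set())
        outputs: set[str] = set()
        for k in keys:
            outputs |= values_by_key.get(k, set())
        if outputs:
            rows.extend((input_id, out, True) for out in sorted(outputs))
        else:
            rows.append((input_id, NA, False))

    result = pd.DataFrame(rows, columns=XREF_COLUMNS)
    result.attrs["n_input_duplicates"] = n_dup
    if n_dup:
        warnings.warn(f"xref: collapsed {n_dup} duplicate input id(s)", UserWarning, stacklevel=2)
    return result


def map_orthologs(
    genes: list[str],
    src: str,
    dst: str,
    s: Snapshot,
) -> pd.DataFrame:
    """Return every stored ortholog pair whose source side is a queried gene.

    Input ids are Ensembl gene IDs of species *src*.  Pairs are looked
    up in both storage directions.  A gene with no ortholog appears once
    with an ``NA`` partner and ``NA`` percent identities, so every
    queried gene occurs at least once in the output.
    """
    if src == dst:
        raise ValueError("source and destination species must differ")
    both = s.orthologs_bidirectional()
    pair_rows = both[(both["src_species"] == src) & (both["dst_species"] == dst)]
    if pair_rows.empty:
        raise SnapshotError(f"no ortholog data for species pair {src!r} -> {dst!r}")

    unique_genes, _ = dedupe_preserving_order(list(genes))
    by_gene: dict[str, list[tuple[str, str, str]]] = {}
    for row in pair_rows.itertuples(index=False):
        by_gene.setdefault(row.src_ensembl_gene, []).append(
            (row.dst_ensembl_gene, row.pct_identity_src, row.pct_identity_dst)
        )

    rows = []
    for g in unique_genes:
        hits = sorted(by_gene.get(g, []))
        if not hits:
            rows.append((src, g, dst, NA, NA, NA))
        else:
            rows.extend((src, g, dst, d, ps, pd_) for d, ps, pd_ in hits)
    return pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
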