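"""miRNA retrievals: consensus targets, reverse lookup, metadata, homology.

Target predictions come from three precomputed sources (TargetScan-style,
microCosm/miRBase-style, miRNA.org-style).  Because any single prediction
algorithm carries false positives, the central operation here is
*consensus* prediction: keep only (miRNA, gene) pairs — or genes —
predicted by at least ``min_agreement`` of the selected sources.

Cross-species homology filtering compares the mature sequences of two
miRNAs (e.g. a zebrafish miRNA and its candidate human homolog): the
pair passes when the total mismatch count is within a budget *and* the
seed region (positions 2–8 from the 5′ end, the primary determinant of
target recognition) is identical.  Sequences are compared aligned at the
5′ end, since mature 3′ ends are heterogeneous while the 5′ end anchors
the seed; a length difference contributes its full amount to the
mismatch count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from . import idmap
from .datastore import NA, RetrievalCap, Snapshot, SOURCES, TARGET_TABLES

#: 0-based python slice of the seed region (mature positions 2-8, 1-based).
SEED_SLICE = slice(1, 8)

RNA_ALPHABET = frozenset("ACGU")

#: Mature-length range outside which a warning (not an error) is raised.
TYPICAL_MATURE_LENGTH = (18, 26)


@dataclass(frozen=True)
class MiRNARecord:
    species: str
    mirna_id: str
    mature_accession: str
    mature_sequence: str


def normalize_sequence(seq: str, record_name: str = "sequence") -> str:
    """Uppercase, convert DNA T to RNA U, and validate the alphabet."""
    norm = seq.strip().upper().replace("T", "U")
    if not norm:
        raise ValueError(f"{record_name}: empty mature sequence")
    bad = set(norm) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"{record_name}: non-ACGU character(s) {sorted(bad)} in sequence {seq!r}"
        )
    lo, hi = TYPICAL_MATURE_LENGTH
    if not lo <= len(norm) <= hi:
        warnings.warn(
            f"{record_name}: mature sequence length {len(norm)} outside {lo}-{hi}",
            UserWarning,
            stacklevel=2,
        )
    return norm


def compare_mature_sequences(seq_a: str, seq_b: str) -> tuple[int, bool, int]:
    """5′-aligned comparison of two normalized mature sequences.

    Returns ``(n_mismatch, seed_identical, overlap_length)`` where
    ``n_mismatch`` is the Hamming distance over the overlap plus the
    absolute length difference, and ``seed_identical`` is True iff
    positions 2–8 of both sequences agree.
    """
    overlap = min(len(seq_a), len(seq_b))
    n_mismatch = sum(a != b for a, b in zip(seq_a[:overlap], seq_b[:overlap]))
    n_mismatch += abs(len(seq_a) - len(seq_b))
    seed_identical = seq_a[SEED_SLICE] == seq_b[SEED_SLICE]
    return n_mismatch, seed_identical, overlap


def homology_filter(
    pairs: list[tuple[MiRNARecord, MiRNARecord]],
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Score miRNA sequence pairs and flag those passing the homology rule.

    ``pass`` is True iff ``n_mismatch <= max_mismatch`` AND the seed
    regions are identical: a single seed-position difference fails the
    pair even when the total mismatch budget would allow it.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    rows = []
    for rec_a, rec_b in pairs:
        seq_a = normalize_sequence(rec_a.mature_sequence, rec_a.mirna_id)
        seq_b = normalize_sequence(rec_b.mature_sequence, rec_b.mirna_id)
        n_mismatch, seed_identical, overlap = compare_mature_sequences(seq_a, seq_b)
        rows.append(
            {
                "mirna_a": rec_a.mirna_id,
                "species_a": rec_a.species,
                "mirna_b": rec_b.mirna_id,
                "species_b": rec_b.species,
                "n_mismatch": n_mismatch,
                "seed_identical": seed_identical,
                "overlap_length": overlap,
                "pass": n_mismatch <= max_mismatch and seed_identical,
            }
        )
    columns = [
        "mirna_a",
        "species_a",
        "mirna_b",
        "species_b",
        "n_mismatch",
        "seed_identical",
        "overlap_length",
        "pass",
    ]
    return pd.DataFrame(rows, columns=columns)


def _source_frames(
    species: str, sources: tuple[str, ...], s: Snapshot
) -> dict[str, pd.DataFrame]:
    frames = {}
    for src in sources:
        tname = TARGET_TABLES[src]
        if s.has(tname):
            df = s.table(tname)
            frames[src] = df[df["species"] == species]
    return frames


def _check_sources(sources, min_agreement) -> tuple[str, ...]:
    sources = tuple(sources)
    unknown = [x for x in sources if x not in SOURCES]
    if unknown:
        raise ValueError(f"unknown source(s) {unknown}; expected subset of {SOURCES}")
    if not sources:
        raise ValueError("at least one source required")
    if not 1 <= min_agreement <= len(sources):
        raise ValueError(
            f"min_agreement={min_agreement} must be between 1 and the "
            f"number of selected sources ({len(sources)})"
        )
    return sources


def predict_targets(
    mirnas: list[str],
    species: str,
    sources: tuple[str, ...] = SOURCES,
    min_agreement: int = 2,
    level: str = "pair",
    s: Snapshot = None,
    cap: RetrievalCap | None = None,
) -> pd.DataFrame:
    """Consensus target prediction across the selected sources.

    At ``level="pair"`` each output row is a (miRNA, gene) pair with one
    presence flag per source; at ``level="gene"`` rows are unique gene
    symbols and a source flag is set when *any* queried miRNA targets
    the gene in that source.  ``agreement_count`` is the number of true
    flags and rows below ``min_agreement`` are dropped.  Output is
    sorted by (agreement descending, key ascending) and obeys the
    retrieval cap.
    """
    sources = _check_sources(sources, min_agreement)
    if level not in ("pair", "gene"):
        raise ValueError(f"level must be 'pair' or 'gene', got {level!r}")
    frames = _source_frames(species, sources, s)
    if not frames:
        raise ValueError(f"no target table available for species {species!r}")

    queried, _ = idmap.dedupe_preserving_order(list(mirnas))
    queried_set = set(queried)

    pair_sets: dict[str, set[tuple[str, str]]] = {}
    entrez_by_gene: dict[str, str] = {}
    for src, df in frames.items():
        sub = df[df["mirna_id"].isin(queried_set)]
        pair_sets[src] = set(zip(sub["mirna_id"], sub["gene_symbol"]))
        for gene, entrez in zip(sub["gene_symbol"], sub["entrez_id"]):
            if entrez != NA:
                prev = entrez_by_gene.get(gene)
                if prev is None or entrez < prev:
                    entrez_by_gene[gene] = entrez

    for m in queried:
        if not any((m in {p[0] for p in pair_sets[src]}) for src in frames):
            warnings.warn(
                f"miRNA {m!r} absent from every selected source for {species}",
                UserWarning,
                stacklevel=2,
            )

    flag_cols = [f"in_{src}" for src in SOURCES]
    rows = []
    if level == "pair":
        all_pairs = set().union(*pair_sets.values()) if pair_sets else set()
        for mirna, gene in all_pairs:
            flags = {f"in_{src}": (mirna, gene) in pair_sets.get(src, set()) for src in SOURCES}
            agreement = sum(flags[f"in_{src}"] for src in sources)
            if agreement >= min_agreement:
                rows.append(
                    {
                        "mirna_id": mirna,
                        "gene_symbol": gene,
                        "entrez_id": entrez_by_gene.get(gene, NA),
                        **flags,
                        "agreement_count": agreement,
                    }
                )
        columns = ["mirna_id", "gene_symbol", "entrez_id", *flag_cols, "agreement_count"]
        sort_keys = ["mirna_id", "gene_symbol"]
    else:
        gene_sets = {src: {g for _, g in pairs} for src, pairs in pair_sets.items()}
        for gene in set().union(*gene_sets.values()) if gene_sets else set():
            flags = {f"in_{src}": gene in gene_sets.get(src, set()) for src in SOURCES}
            agreement = sum(flags[f"in_{src}"] for src in sources)
            if agreement >= min_agreement:
                rows.append(
                    {
                        "gene_symbol": gene,
                        "entrez_id": entrez_by_gene.get(gene, NA),
                        **flags,
                        "agreement_count": agreement,
                    }
                )
        columns = ["gene_symbol", "entrez_id", *flag_cols, "agreement_count"]
        sort_keys = ["gene_symbol"]

    result = pd.DataFrame(rows, columns=columns)
    if not result.empty:
        result = result.sort_values(
            ["agreement_count", *sort_keys], ascending=[False] + [True] * len(sort_keys)
        ).reset_index(drop=True)
    cap = cap or RetrievalCap()
    return cap.apply(result, "predict_targets")


def regulatory_mirnas(
    genes: list[str],
    id_type: str,
    species: str,
    sources: tuple[str, ...] = SOURCES,
    s: Snapshot = None,
) -> pd.DataFrame:
    """All predicted regulator miRNAs for each queried gene.

    Non-symbol inputs are first translated to gene symbols through the
    cross-reference tables; untranslatable ids yield an NA row with a
    warning rather than failing the batch.  One row per
    (gene, miRNA, source) triple; genes with no predicted regulator
    appear once with NA fields.
    """
    idmap.check_namespace(id_type)
    sources = _check_sources(sources, 1)
    frames = _source_frames(species, sources, s)

    queried, _ = idmap.dedupe_preserving_order(list(genes))
    if id_type == "gene_symbol":
        symbols_by_input = {g: [g] for g in queried}
    else:
        mapping = idmap.xref(queried, id_type, "gene_symbol", species, s)
        symbols_by_input = {g: [] for g in queried}
        for row in mapping.itertuples(index=False):
            if row.matched:
                symbols_by_input[row.input_id].append(row.output_id)
        for g in queried:
            if not symbols_by_input[g]:
                warnings.warn(
                    f"input id {g!r} could not be translated to a gene symbol",
                    UserWarning,
                    stacklevel=2,
                )

    # index: folded symbol -> [(mirna, source)]
    regulators: dict[str, list[tuple[str, str]]] = {}
    for src, df in frames.items():
        for mirna, gene in zip(df["mirna_id"], df["gene_symbol"]):
            regulators.setdefault(gene.casefold(), []).append((mirna, src))

    rows = []
    for g in queried:
        hits: set[tuple[str, str]] = set()
        for sym in symbols_by_input[g]:
            hits.update(regulators.get(sym.casefold(), []))
        if hits:
            rows.extend((g, mirna, src) for mirna, src in sorted(hits))
        else:
            rows.append((g, NA, NA))
    return pd.DataFrame(rows, columns=["gene", "mirna_id", "source"])


def get_metadata(mirnas: list[str], species: str, s: Snapshot) -> pd.DataFrame:
    """Mature accession and sequence for each distinct input miRNA.

    Sequences are normalized to uppercase RNA (T→U).  Unknown ids are
    returned with NA fields and ``matched=False`` so batch queries never
    silently drop inputs.
    """
    meta = s.table("mirna_metadata")
    meta = meta[meta["species"] == species]
    by_id = {row.mirna_id: row for row in meta.itertuples(index=False)}
    queried, _ = idmap.dedupe_preserving_order(list(mirnas))
    rows = []
    for m in queried:
        rec = by_id.get(m)
        if rec is None:
            rows.append((species, m, NA, NA, False))
        else:
            seq = normalize_sequence(rec.mature_sequence, m)
            rows.append((species, m, rec.mature_accession, seq, True))
    return pd.DataFrame(
        rows, columns=["species", "mirna_id", "mature_accession", "mature_sequence", "matched"]
    )


def metadata_records(df: pd.DataFrame) -> list[MiRNARecord]:
    """Matched rows of a :func:`get_metadata` result as records."""
    return [
        MiRNARecord(r.species, r.mirna_id, r.mature_accession, r.mature_sequence)
        for r in df.itertuples(index=False)
        if r.matched
    ]
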