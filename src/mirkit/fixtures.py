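"""Deterministic synthetic snapshot and experiment generator.

Everything the other modules query can be generated here with *planted,
recountable structure*: a fixed number of (miRNA, gene) pairs present in
all three target sources, single-source background predictions, ortholog
pairs with bidirectional percent identities, per-gene annotation terms
including one deliberately over-represented term on the conserved target
genes, and cross-species mature-sequence pairs with a controlled
mismatch profile (edits placed inside or outside the seed).  Every
planted fact is also written to a plain-TSV ground-truth ledger so tests
can recount it independently of the query code.

Generation is a pure function of (spec, seed): the same spec written
twice produces byte-identical directories.

The default spec mirrors the shape of a developmental miRNA/mRNA
microarray study in zebrafish bridged to human: 42 significant miRNAs
of which 33 survive the homology filter (≤1 mismatch with an intact
seed), and 100 significant mRNAs of which a planted fraction are true
targets of the significant miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datastore import NA, Snapshot, load_snapshot

_BASES = "ACGU"

#: Mismatch-profile categories and whether a pair passes the default
#: homology rule (n_mismatch <= 1 and seed identical).
CATEGORY_PASSES = {
    "exact": True,       # identical sequences
    "one_nonseed": True,  # one edit outside positions 2-8
    "one_seed": False,    # one edit inside the seed
    "two_nonseed": False,  # two edits outside the seed (budget exceeded)
}
CATEGORY_MISMATCHES = {"exact": 0, "one_nonseed": 1, "one_seed": 1, "two_nonseed": 2}

_ENSEMBL_GENE_PREFIX = {
    "hsa": "ENSG",
    "mmu": "ENSMUSG",
    "rno": "ENSRNOG",
    "dre": "ENSDARG",
    "mml": "ENSMMUG",
}
_ENSEMBL_TX_PREFIX = {k: v[:-1] + "T" for k, v in _ENSEMBL_GENE_PREFIX.items()}
_SPECIES_OFFSET = {"hsa": 2, "mmu": 3, "rno": 4, "dre": 1, "mml": 5}


def gene_symbol(i: int, species: str) -> str:
    """Synthetic symbol; human-style upper case, other species lower."""
    base = f"g{i:06d}"
    return base.upper() if species == "hsa" else base


def entrez_id(i: int, species: str) -> str:
    return str(_SPECIES_OFFSET[species] * 100000 + i)


def ensembl_gene(i: int, species: str) -> str:
    return f"{_ENSEMBL_GENE_PREFIX[species]}{i:011d}"


def ensembl_transcript(i: int, species: str) -> str:
    return f"{_ENSEMBL_TX_PREFIX[species]}{i:011d}"


def genbank_id(i: int, species: str) -> str:
    return f"NM_{_SPECIES_OFFSET[species] * 100000 + i:06d}"


def uniprot_id(i: int, species: str) -> str:
    return f"{'QPABC'[_SPECIES_OFFSET[species] - 1]}{i:05d}"


def mirna_id(i: int, species: str) -> str:
    return f"{species}-miR-{i}"


def mature_accession(i: int, species: str) -> str:
    return f"MIMAT{_SPECIES_OFFSET[species] * 100000 + i:07d}"


def default_mismatch_profile(n_mirnas: int) -> dict[str, int]:
    """Profile proportional to the 42-miRNA default (33 passing)."""
    fractions = {"exact": 20 / 42, "one_nonseed": 13 / 42, "one_seed": 5 / 42, "two_nonseed": 4 / 42}
    counts = {k: int(np.floor(v * n_mirnas)) for k, v in fractions.items()}
    remainder = n_mirnas - sum(counts.values())
    for k in ("exact", "one_nonseed", "one_seed", "two_nonseed"):
        if remainder <= 0:
            break
        counts[k] += 1
        remainder -= 1
    return counts


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted synthetic study.

    ``background_rate`` is the per-source probability that a
    (miRNA, gene) pair outside the conserved set is predicted by that
    source *alone*; background pairs are therefore never multi-source,
    so any pair reaching two-source agreement is a planted one.
    """

    seed: int = 11
    n_genes: int = 200
    n_mirnas: int = 42
    species_pair: tuple[str, str] = ("dre", "hsa")
    background_rate: float = 0.01
    n_conserved_pairs: int = 25
    ortholog_fraction: float = 0.8
    mean_terms_per_gene: float = 3.0
    n_terms: int = 30
    n_sig_mirnas: int = 42
    n_sig_genes: int = 100
    target_enrichment: float = 0.4
    mismatch_profile: dict[str, int] = field(
        default_factory=lambda: {"exact": 20, "one_nonseed": 13, "one_seed": 5, "two_nonseed": 4}
    )

    def __post_init__(self):
        if not 0.0 <= self.background_rate <= 1 / 3:
            raise ValueError("background_rate must be in [0, 1/3] (three disjoint sources)")
        for name in ("ortholog_fraction", "target_enrichment"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_genes", "n_mirnas", "n_conserved_pairs", "n_terms", "n_sig_mirnas", "n_sig_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if set(self.mismatch_profile) - set(CATEGORY_PASSES):
            raise ValueError(f"unknown mismatch categories: {set(self.mismatch_profile) - set(CATEGORY_PASSES)}")
        if sum(self.mismatch_profile.values()) != self.n_mirnas:
            raise ValueError(
                f"mismatch_profile counts sum to {sum(self.mismatch_profile.values())}, "
                f"expected n_mirnas={self.n_mirnas}"
            )
        if self.n_sig_mirnas > self.n_mirnas:
            raise ValueError("n_sig_mirnas cannot exceed n_mirnas")
        if self.n_conserved_pairs > self.n_genes:
            raise ValueError("n_conserved_pairs cannot exceed n_genes (one pair per gene)")

    @property
    def n_passing(self) -> int:
        return sum(n for cat, n in self.mismatch_profile.items() if CATEGORY_PASSES[cat])


@dataclass
class SnapshotFixture:
    out_dir: Path
    spec: FixtureSpec
    conserved: pd.DataFrame       # planted all-three-source pairs
    homology: pd.DataFrame        # per-miRNA cross-species sequence plan
    background: pd.DataFrame      # planted single-source pairs

    def load(self) -> Snapshot:
        return load_snapshot(self.out_dir)


@dataclass
class ExperimentFixture:
    out_dir: Path
    mirna_table: Path
    mrna_table: Path
    ledger: pd.DataFrame          # per significant gene: planted target or not


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _edit(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = _BASES.index(seq[pos])
    new = (old + int(rng.integers(1, 4))) % 4
    return seq[:pos] + _BASES[new] + seq[pos + 1 :]


_NONSEED_POSITIONS = [0] + list(range(8, 22))  # 0-based; seed is 1..7
_SEED_POSITIONS = list(range(1, 8))


def generate_snapshot(spec: FixtureSpec, out_dir: str | Path) -> SnapshotFixture:
    """Write a complete snapshot directory plus ground-truth ledgers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    src_sp, dst_sp = spec.species_pair
    gene_idx = list(range(1, spec.n_genes + 1))
    mirna_idx = list(range(1, spec.n_mirnas + 1))

    # --- cross-species mature sequences with planted mismatch profile ---
    categories: list[str] = []
    for cat in ("exact", "one_nonseed", "one_seed", "two_nonseed"):
        categories.extend([cat] * spec.mismatch_profile.get(cat, 0))
    categories = [categories[i] for i in rng.permutation(spec.n_mirnas)]

    homology_rows = []
    seq_src: dict[int, str] = {}
    seq_dst: dict[int, str] = {}
    for i, cat in zip(mirna_idx, categories):
        s_seq = _random_sequence(rng)
        d_seq = s_seq
        if cat == "one_nonseed":
            d_seq = _edit(d_seq, int(rng.choice(_NONSEED_POSITIONS)), rng)
        elif cat == "one_seed":
            d_seq = _edit(d_seq, int(rng.choice(_SEED_POSITIONS)), rng)
        elif cat == "two_nonseed":
            p1, p2 = rng.choice(_NONSEED_POSITIONS, size=2, replace=False)
            d_seq = _edit(_edit(d_seq, int(p1), rng), int(p2), rng)
        seq_src[i], seq_dst[i] = s_seq, d_seq
        homology_rows.append(
            {
                "mirna_index": i,
                "src_mirna_id": mirna_id(i, src_sp),
                "dst_mirna_id": mirna_id(i, dst_sp),
                "category": cat,
                "n_mismatch": CATEGORY_MISMATCHES[cat],
                "passes": CATEGORY_PASSES[cat],
            }
        )
    homology = pd.DataFrame(homology_rows)

    meta_rows = []
    for sp, seqs in ((src_sp, seq_src), (dst_sp, seq_dst)):
        for i in mirna_idx:
            meta_rows.append(
                {
                    "species": sp,
                    "mirna_id": mirna_id(i, sp),
                    "mature_accession": mature_accession(i, sp),
                    "mature_sequence": seqs[i],
                }
            )
    metadata = pd.DataFrame(meta_rows, columns=["species", "mirna_id", "mature_accession", "mature_sequence"])

    # --- conserved pairs: one distinct gene each, cycling over miRNAs that
    # are both significant (index <= n_sig_mirnas) and homology-passing, so
    # the planted structure is reachable through the bridged workflow ---
    passing_sig = [
        int(r.mirna_index)
        for r in homology.itertuples(index=False)
        if r.passes and r.mirna_index <= spec.n_sig_mirnas
    ]
    if spec.n_conserved_pairs > 0 and not passing_sig:
        raise ValueError("cannot plant conserved pairs: no significant homology-passing miRNA")
    conserved_genes = sorted(
        int(g) for g in rng.choice(gene_idx, size=spec.n_conserved_pairs, replace=False)
    ) if spec.n_conserved_pairs else []
    conserved_rows = []
    for j, g in enumerate(conserved_genes):
        m = passing_sig[j % len(passing_sig)]
        conserved_rows.append(
            {
                "mirna_index": m,
                "gene_index": g,
                "src_mirna_id": mirna_id(m, src_sp),
                "src_gene_symbol": gene_symbol(g, src_sp),
                "dst_mirna_id": mirna_id(m, dst_sp),
                "dst_gene_symbol": gene_symbol(g, dst_sp),
            }
        )
    conserved = pd.DataFrame(
        conserved_rows,
        columns=["mirna_index", "gene_index", "src_mirna_id", "src_gene_symbol", "dst_mirna_id", "dst_gene_symbol"],
    )
    conserved_cells = {(r["mirna_index"], r["gene_index"]) for r in conserved_rows}

    # --- single-source background pairs (never multi-source) ---
    sources = ("targetscan", "microcosm", "mirnaorg")
    background_rows = []
    draws = rng.random(size=(spec.n_mirnas, spec.n_genes))
    for mi, m in enumerate(mirna_idx):
        for gi, g in enumerate(gene_idx):
            if (m, g) in conserved_cells:
                continue
            r = draws[mi, gi]
            if spec.background_rate > 0 and r < 3 * spec.background_rate:
                src = sources[int(r // spec.background_rate)]
                background_rows.append(
                    {"source": src, "species": dst_sp, "mirna_index": m, "gene_index": g}
                )
    # background for the source species (single-source tool only)
    draws_src = rng.random(size=(spec.n_mirnas, spec.n_genes))
    for mi, m in enumerate(mirna_idx):
        for gi, g in enumerate(gene_idx):
            if (m, g) in conserved_cells:
                continue
            if spec.background_rate > 0 and draws_src[mi, gi] < spec.background_rate:
                background_rows.append(
                    {"source": "microcosm", "species": src_sp, "mirna_index": m, "gene_index": g}
                )
    background = pd.DataFrame(
        background_rows, columns=["source", "species", "mirna_index", "gene_index"]
    )

    def target_row(sp: str, m: int, g: int) -> dict:
        return {
            "species": sp,
            "mirna_id": mirna_id(m, sp),
            "gene_symbol": gene_symbol(g, sp),
            "entrez_id": entrez_id(g, sp),
            "ensembl_transcript": ensembl_transcript(g, sp),
        }

    target_tables: dict[str, list[dict]] = {s: [] for s in sources}
    for r in conserved_rows:
        for s in sources:
            target_tables[s].append(target_row(dst_sp, r["mirna_index"], r["gene_index"]))
        # conserved structure mirrored into the source species' only tool
        target_tables["microcosm"].append(target_row(src_sp, r["mirna_index"], r["gene_index"]))
    for r in background_rows:
        target_tables[r["source"]].append(target_row(r["species"], r["mirna_index"], r["gene_index"]))

    # --- identifier cross-references for both species ---
    xref_rows = []
    for sp in (src_sp, dst_sp):
        for g in gene_idx:
            key = f"{sp}:{g:06d}"
            for ns, value in (
                ("gene_symbol", gene_symbol(g, sp)),
                ("entrez", entrez_id(g, sp)),
                ("ensembl_gene", ensembl_gene(g, sp)),
                ("ensembl_transcript", ensembl_transcript(g, sp)),
                ("genbank", genbank_id(g, sp)),
                ("uniprot", uniprot_id(g, sp)),
            ):
                xref_rows.append({"species": sp, "gene_key": key, "namespace": ns, "value": value})
    xref = pd.DataFrame(xref_rows, columns=["species", "gene_key", "namespace", "value"])

    # --- orthologs (stored directionally src -> dst) ---
    n_orth = int(round(spec.ortholog_fraction * spec.n_genes))
    orth_genes = sorted(int(g) for g in rng.choice(gene_idx, size=n_orth, replace=False))
    orth_rows = []
    for g in orth_genes:
        orth_rows.append(
            {
                "src_species": src_sp,
                "src_ensembl_gene": ensembl_gene(g, src_sp),
                "dst_species": dst_sp,
                "dst_ensembl_gene": ensembl_gene(g, dst_sp),
                "pct_identity_src": f"{rng.uniform(60, 95):.1f}",
                "pct_identity_dst": f"{rng.uniform(60, 95):.1f}",
            }
        )
    orthologs = pd.DataFrame(
        orth_rows,
        columns=["src_species", "src_ensembl_gene", "dst_species", "dst_ensembl_gene", "pct_identity_src", "pct_identity_dst"],
    )

    # --- annotations: one planted over-represented GO term on every
    # conserved target gene, plus random background terms per gene ---
    planted_term = ("GO:0000001", "planted process", "BP")
    go_rows = []
    for sp in (src_sp, dst_sp):
        for g in conserved_genes:
            go_rows.append(
                {
                    "species": sp,
                    "gene_symbol": gene_symbol(g, sp),
                    "term_id": planted_term[0],
                    "term_name": planted_term[1],
                    "category": planted_term[2],
                }
            )
        for g in gene_idx:
            n_t = min(int(rng.poisson(spec.mean_terms_per_gene)), max(spec.n_terms - 1, 0))
            if n_t == 0:
                continue
            picks = rng.choice(range(2, spec.n_terms + 1), size=n_t, replace=False)
            for t in sorted(int(x) for x in picks):
                go_rows.append(
                    {
                        "species": sp,
                        "gene_symbol": gene_symbol(g, sp),
                        "term_id": f"GO:{t:07d}",
                        "term_name": f"process {t:04d}",
                        "category": "BP",
                    }
                )
    annotations_go = pd.DataFrame(
        go_rows, columns=["species", "gene_symbol", "term_id", "term_name", "category"]
    )

    kegg_rows = []
    for sp in (src_sp, dst_sp):
        for g in gene_idx:
            n_p = int(rng.integers(0, 3))
            if n_p == 0:
                continue
            picks = rng.choice(range(1, 11), size=n_p, replace=False)
            for p in sorted(int(x) for x in picks):
                kegg_rows.append(
                    {
                        "species": sp,
                        "gene_symbol": gene_symbol(g, sp),
                        "term_id": f"ko{p:05d}",
                        "term_name": f"pathway {p:02d}",
                        "category": "pathway",
                    }
                )
    annotations_kegg = pd.DataFrame(
        kegg_rows, columns=["species", "gene_symbol", "term_id", "term_name", "category"]
    )

    # --- write everything ---
    files = {
        "targets_targetscan": pd.DataFrame(target_tables["targetscan"], columns=["species", "mirna_id", "gene_symbol", "entrez_id", "ensembl_transcript"]),
        "targets_microcosm": pd.DataFrame(target_tables["microcosm"], columns=["species", "mirna_id", "gene_symbol", "entrez_id", "ensembl_transcript"]),
        "targets_mirnaorg": pd.DataFrame(target_tables["mirnaorg"], columns=["species", "mirna_id", "gene_symbol", "entrez_id", "ensembl_transcript"]),
        "mirna_metadata": metadata,
        "xref": xref,
        "orthologs": orthologs,
        "annotations_go": annotations_go,
        "annotations_kegg": annotations_kegg,
    }
    manifest_rows = []
    for name, df in files.items():
        fname = f"{name}.tsv"
        _write(df, out / fname)
        manifest_rows.append({"table_name": name, "file_name": fname})
    _write(pd.DataFrame(manifest_rows, columns=["table_name", "file_name"]), out / "manifest.tsv")
    (out / "version.txt").write_text(f"fixture-seed{spec.seed}\n")

    # ground-truth ledgers (plain TSV, diffable)
    _write(conserved, out / "ledger_conserved.tsv")
    _write(homology, out / "ledger_homology.tsv")
    bg_ledger = background.copy()
    if not bg_ledger.empty:
        bg_ledger["mirna_id"] = [mirna_id(m, sp) for m, sp in zip(bg_ledger["mirna_index"], bg_ledger["species"])]
        bg_ledger["gene_symbol"] = [gene_symbol(g, sp) for g, sp in zip(bg_ledger["gene_index"], bg_ledger["species"])]
    else:
        bg_ledger["mirna_id"] = []
        bg_ledger["gene_symbol"] = []
    _write(bg_ledger, out / "ledger_background.tsv")

    return SnapshotFixture(out_dir=out, spec=spec, conserved=conserved, homology=homology, background=bg_ledger)


def generate_experiment(
    spec: FixtureSpec, snapshot_dir: str | Path, out_dir: str | Path
) -> ExperimentFixture:
    """Emit significant-miRNA and significant-mRNA experiment tables.

    Exactly ``round(target_enrichment * n_sig_genes)`` mRNA rows are
    planted conserved-target genes of the significant, homology-passing
    miRNAs; the remainder are genes with no target prediction at all,
    so the planted count is exactly recoverable by the merge.
    """
    snap_dir = Path(snapshot_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conserved_path = snap_dir / "ledger_conserved.tsv"
    if not conserved_path.is_file():
        raise ValueError(
            f"snapshot at {snap_dir} has no ground-truth ledger; "
            "generate it with generate_snapshot from the same spec"
        )
    conserved = pd.read_csv(conserved_path, sep="\t", dtype=str, keep_default_na=False)
    background = pd.read_csv(snap_dir / "ledger_background.tsv", sep="\t", dtype=str, keep_default_na=False)
    homology = pd.read_csv(snap_dir / "ledger_homology.tsv", sep="\t", dtype=str, keep_default_na=False)

    rng = np.random.default_rng([spec.seed, 104729])
    src_sp, _dst_sp = spec.species_pair

    passing_sig = {
        int(r.mirna_index)
        for r in homology.itertuples(index=False)
        if r.passes == "True" and int(r.mirna_index) <= spec.n_sig_mirnas
    }
    target_pool = sorted(
        {
            int(r.gene_index)
            for r in conserved.itertuples(index=False)
            if int(r.mirna_index) in passing_sig
        }
    )
    targeted_any = {int(g) for g in conserved["gene_index"]} | {
        int(g) for g in background["gene_index"]
    }
    clean_pool = sorted(set(range(1, spec.n_genes + 1)) - targeted_any)

    n_target = int(round(spec.target_enrichment * spec.n_sig_genes))
    n_clean = spec.n_sig_genes - n_target
    if n_target > len(target_pool):
        raise ValueError(
            f"spec asks for {n_target} planted target genes but only "
            f"{len(target_pool)} conserved target genes are reachable"
        )
    if n_clean > len(clean_pool):
        raise ValueError(
            f"spec asks for {n_clean} untargeted genes but only {len(clean_pool)} exist; "
            "increase n_genes or lower background_rate"
        )
    chosen_targets = sorted(int(g) for g in rng.choice(target_pool, size=n_target, replace=False))
    chosen_clean = sorted(int(g) for g in rng.choice(clean_pool, size=n_clean, replace=False))

    timepoints = ("logFC_24hpf", "logFC_36hpf", "logFC_48hpf")

    def expression_row(sign: int) -> dict:
        return {
            tp: f"{sign * rng.uniform(0.8, 2.5):.3f}" for tp in timepoints
        } | {"p_value": f"{rng.uniform(0.0001, 0.0499):.4f}"}

    mirna_rows = []
    for i in range(1, spec.n_sig_mirnas + 1):
        sign = int(rng.choice([-1, 1]))
        mirna_rows.append({"mirna_id": mirna_id(i, src_sp)} | expression_row(sign))
    mirna_df = pd.DataFrame(mirna_rows, columns=["mirna_id", *timepoints, "p_value"])

    gene_rows = []
    for g, planted in [(g, True) for g in chosen_targets] + [(g, False) for g in chosen_clean]:
        # planted targets trend down (repression), the rest either way
        sign = -1 if planted else int(rng.choice([-1, 1]))
        gene_rows.append(
            {
                "gene_symbol": gene_symbol(g, src_sp),
                "entrez_id": entrez_id(g, src_sp),
                "planted_target": planted,
            }
            | expression_row(sign)
        )
    order = rng.permutation(len(gene_rows))
    gene_rows = [gene_rows[i] for i in order]
    ledger = pd.DataFrame(gene_rows, columns=["gene_symbol", "entrez_id", "planted_target", *timepoints, "p_value"])
    mrna_df = ledger.drop(columns=["planted_target"])

    mirna_path = out / "mirna_significant.tsv"
    mrna_path = out / "mrna_significant.tsv"
    _write(mirna_df, mirna_path)
    _write(mrna_df, mrna_path)
    _write(ledger[["gene_symbol", "entrez_id", "planted_target"]], out / "ledger_experiment.tsv")
    return ExperimentFixture(out_dir=out, mirna_table=mirna_path, mrna_table=mrna_path, ledger=ledger)
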