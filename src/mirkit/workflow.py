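"""The three-step integration pipeline, wired end-to-end.

Step 1 — target prediction: the significant miRNA list is (optionally)
bridged to a better-covered species through mature-sequence homology
filtering (≤ ``max_mismatch`` total mismatches with an identical seed),
then consensus targets are retrieved at the configured source agreement.

Step 2 — integration: the consensus target table is merged with the
significant-mRNA table through an ordered multi-level plan (by default
gene symbol, then Entrez, then Entrez translated to symbol), with full
per-level match accounting.

Step 3 — interpretation: hypergeometric GO enrichment of the merged
gene list against the platform background, and centroid-linkage
hierarchical clustering of the merged expression profiles.

Every artifact is persisted with a provenance header (config hash,
snapshot version, timestamp) so a run is reproducible and auditable;
re-running an identical config on an identical snapshot reproduces the
outputs byte-for-byte apart from the timestamp line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import analysis, mirna
from .datastore import NA, SOURCES, Snapshot, load_snapshot
from .tableops import ExperimentTable, MergePlan, MergeRelation, MergeReport, merge_datasets


def default_merge_plan(
    species: str,
    bridge: str | None,
    mode: str = "intersection",
) -> MergePlan:
    """Symbol first, then Entrez, then Entrez translated to symbol.

    The translation level maps the left (target-table) Entrez id to a
    gene symbol in the species the targets were predicted in, catching
    rows whose symbols were missing at level one.
    """
    translate_species = bridge or species
    return MergePlan(
        relations=(
            MergeRelation("gene_symbol", "gene_symbol", namespace="gene_symbol"),
            MergeRelation("entrez_id", "entrez_id", namespace="entrez"),
            MergeRelation(
                "entrez_id",
                "gene_symbol",
                translation=("entrez", "gene_symbol", translate_species),
            ),
        ),
        mode=mode,
    )


@dataclass
class WorkflowConfig:
    snapshot_dir: str
    mirna_table: str
    mrna_table: str
    out_dir: str
    species: str = "dre"
    bridge_species: str | None = "hsa"
    sources: tuple[str, ...] = SOURCES
    min_agreement: int = 2
    level: str = "gene"
    max_mismatch: int = 1
    merge_mode: str = "intersection"
    merge_plan: MergePlan | None = None
    mirna_id_column: str = "mirna_id"
    gene_symbol_column: str = "gene_symbol"
    expression_prefix: str = "logFC"
    annotation_source: str = "go"
    annotation_category: str | None = "BP"
    alpha: float = 0.05
    anti_correlated: bool = False

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # location of outputs is not part of the analysis
        payload["merge_plan"] = repr(self.merge_plan)
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode())
        return digest.hexdigest()[:12]


@dataclass
class WorkflowResult:
    config: WorkflowConfig
    consensus: pd.DataFrame
    homology: pd.DataFrame | None
    merged: ExperimentTable
    merge_report: MergeReport
    enrichment: pd.DataFrame
    dendrogram: analysis.Dendrogram | None
    n_query_mirnas: int
    n_passing_mirnas: int
    paths: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _bridge_suffix(mid: str, species: str) -> str:
    prefix = f"{species}-"
    return mid[len(prefix):] if mid.startswith(prefix) else mid


def _homology_bridge(
    mirna_ids: list[str], cfg: WorkflowConfig, snap: Snapshot, log: list[str]
) -> tuple[list[str], pd.DataFrame]:
    """Map source-species miRNAs to homologs in the bridge species.

    Candidate homologs share the mature name suffix (e.g. ``miR-21``);
    all candidates of a query are scored and every passing pair is kept,
    with multiplicity logged.
    """
    src_meta = mirna.get_metadata(mirna_ids, cfg.species, snap)
    src_records = {r.mirna_id: r for r in mirna.metadata_records(src_meta)}
    bridge_table = snap.table("mirna_metadata")
    bridge_table = bridge_table[bridge_table["species"] == cfg.bridge_species]
    by_suffix: dict[str, list[mirna.MiRNARecord]] = {}
    for row in bridge_table.itertuples(index=False):
        rec = mirna.MiRNARecord(
            row.species, row.mirna_id, row.mature_accession,
            mirna.normalize_sequence(row.mature_sequence, row.mirna_id),
        )
        by_suffix.setdefault(_bridge_suffix(row.mirna_id, cfg.bridge_species), []).append(rec)

    pairs = []
    n_multi = 0
    for mid in mirna_ids:
        rec = src_records.get(mid)
        if rec is None:
            log.append(f"step1: no metadata for {mid}; skipped from homology filter")
            continue
        candidates = by_suffix.get(_bridge_suffix(mid, cfg.species), [])
        if not candidates:
            log.append(f"step1: no {cfg.bridge_species} homolog candidate for {mid}")
            continue
        if len(candidates) > 1:
            n_multi += 1
        for cand in candidates:
            pairs.append((rec, cand))
    scored = mirna.homology_filter(pairs, max_mismatch=cfg.max_mismatch)
    passing = sorted(set(scored.loc[scored["pass"], "mirna_b"]))
    log.append(
        f"step1: {len(mirna_ids)} query miRNAs, {len(pairs)} homolog pairs scored, "
        f"{int(scored['pass'].sum())} pairs passed (max_mismatch={cfg.max_mismatch}), "
        f"{len(passing)} distinct {cfg.bridge_species} miRNAs retained"
    )
    if n_multi:
        log.append(f"step1: {n_multi} miRNA(s) had multiple homolog candidates; all pairs kept")
    return passing, scored


def _write_artifact(path: Path, df: pd.DataFrame, header: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_workflow(cfg: WorkflowConfig) -> WorkflowResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap = load_snapshot(cfg.snapshot_dir)
    log: list[str] = []
    chash = cfg.config_hash()
    header = [
        "mirkit workflow artifact",
        f"config_hash={chash}",
        f"snapshot_version={snap.version_tag}",
        f"generated: {datetime.now(timezone.utc).isoformat()}",
    ]

    mirna_in = ExperimentTable.from_tsv(cfg.mirna_table)
    mrna_in = ExperimentTable.from_tsv(cfg.mrna_table)
    mirna_in.require_columns([cfg.mirna_id_column])
    query_mirnas = [str(v) for v in mirna_in.df[cfg.mirna_id_column]]
    log.append(f"inputs: {len(query_mirnas)} significant miRNAs, {len(mrna_in)} significant mRNAs")

    # ---- Step 1: (bridged) consensus target prediction ----
    homology_scores: pd.DataFrame | None = None
    if cfg.bridge_species:
        predict_ids, homology_scores = _homology_bridge(query_mirnas, cfg, snap, log)
        predict_species = cfg.bridge_species
    else:
        predict_ids = query_mirnas
        predict_species = cfg.species

    def predict(ids: list[str]) -> pd.DataFrame:
        if not ids:
            cols = (["mirna_id"] if cfg.level == "pair" else []) + [
                "gene_symbol", "entrez_id",
                *[f"in_{s}" for s in SOURCES], "agreement_count",
            ]
            return pd.DataFrame(columns=cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return mirna.predict_targets(
                ids, predict_species, cfg.sources, cfg.min_agreement, cfg.level, snap
            )

    mrna_table = mrna_in

    if cfg.anti_correlated:
        expr_cols = [c for c in mirna_in.columns if c.startswith(cfg.expression_prefix)]
        signs = mirna_in.df[expr_cols].astype(float).mean(axis=1)
        up_ids = [m for m, sg in zip(query_mirnas, signs) if sg > 0]
        down_ids = [m for m, sg in zip(query_mirnas, signs) if sg <= 0]
        if cfg.bridge_species:
            up_set = {
                _bridge_suffix(m, cfg.species) for m in up_ids
            }
            up_pred = [m for m in predict_ids if _bridge_suffix(m, cfg.bridge_species) in up_set]
            down_pred = [m for m in predict_ids if _bridge_suffix(m, cfg.bridge_species) not in up_set]
        else:
            up_pred, down_pred = up_ids, down_ids
        consensus_up = predict(up_pred)
        consensus_down = predict(down_pred)
        log.append(
            f"step1: anti-correlation split: {len(up_pred)} up / {len(down_pred)} down miRNAs"
        )
        consensus = pd.concat([consensus_up, consensus_down], ignore_index=True).drop_duplicates(ignore_index=True)
    else:
        consensus = predict(predict_ids)
    log.append(
        f"step1: {len(consensus)} consensus rows at level={cfg.level}, "
        f"min_agreement={cfg.min_agreement}, species={predict_species}"
    )

    # ---- Step 2: multi-level merge with the mRNA table ----
    plan = cfg.merge_plan or default_merge_plan(cfg.species, cfg.bridge_species, cfg.merge_mode)
    left = ExperimentTable(consensus.astype(str))

    if cfg.anti_correlated:
        expr_cols_m = [c for c in mrna_in.columns if c.startswith(cfg.expression_prefix)]
        mrna_signs = mrna_in.df[expr_cols_m].astype(float).mean(axis=1)
        merged_parts = []
        reports = []
        for pred_df, keep_sign in ((consensus_up, -1), (consensus_down, 1)):
            sub_rows = mrna_in.df[(mrna_signs * keep_sign) > 0]
            sub = ExperimentTable(sub_rows, row_ids=list(sub_rows.index))
            m_part, r_part = merge_datasets(ExperimentTable(pred_df.astype(str)), sub, plan, snap)
            merged_parts.append(m_part.df)
            reports.append(r_part)
        merged_df = pd.concat(merged_parts, ignore_index=True).drop_duplicates(ignore_index=True)
        merged = ExperimentTable(merged_df)
        report = MergeReport(
            matched_by_level=[sum(r.matched_by_level[i] for r in reports) for i in range(len(plan.relations))],
            matched_total=sum(r.matched_total for r in reports),
            left_unmatched=sum(r.left_unmatched for r in reports),
            right_unmatched=sum(r.right_unmatched for r in reports),
            matched_pairs=sum(r.matched_pairs for r in reports),
        )
    else:
        merged, report = merge_datasets(left, mrna_table, plan, snap)
    log.append(
        f"step2: matched_total={report.matched_total} "
        f"(by level: {report.matched_by_level}), left_unmatched={report.left_unmatched}, "
        f"right_unmatched={report.right_unmatched}, merged rows={len(merged)}"
    )

    # ---- Step 3: enrichment + clustering ----
    sym_col = cfg.gene_symbol_column
    right_sym = sym_col if sym_col in merged.columns else f"{sym_col}_right"
    merged_genes = (
        [v for v in merged.df[right_sym] if v != NA] if right_sym in merged.columns else []
    )
    if merged_genes:
        gsc = analysis.GeneSetCollection.from_annotations(
            snap, cfg.species, source=cfg.annotation_source, category=cfg.annotation_category
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            enrichment = analysis.enrich(merged_genes, gsc, alpha=cfg.alpha)
        n_sig = int(enrichment["significant_raw"].sum()) if len(enrichment) else 0
        log.append(f"step3: {len(enrichment)} gene sets tested, {n_sig} at p<={cfg.alpha}")
    else:
        enrichment = pd.DataFrame(columns=analysis.ENRICH_COLUMNS)
        log.append("step3: merged gene list empty; enrichment skipped")

    expr_cols = [c for c in merged.columns if c.startswith(cfg.expression_prefix)]
    dendrogram = None
    if len(merged) >= 2 and expr_cols:
        matrix = merged.df[expr_cols].astype(float)
        dendrogram = analysis.hcluster(matrix, labels=[str(v) for v in merged.df[right_sym]])
        log.append(
            f"step3: clustered {len(matrix)} profiles over {len(expr_cols)} columns"
            + ("; height inversions present" if dendrogram.has_inversions else "")
        )
    else:
        log.append("step3: fewer than 2 merged rows; clustering skipped")

    # ---- persist artifacts ----
    paths = {
        "consensus_targets": out / "consensus_targets.tsv",
        "merged": out / "merged.tsv",
        "merge_report": out / "merge_report.tsv",
        "enrichment": out / "enrichment.tsv",
        "tree": out / "tree.nwk",
        "cluster_merges": out / "cluster_merges.tsv",
        "run_log": out / "run.log",
    }
    _write_artifact(paths["consensus_targets"], consensus, header)
    if homology_scores is not None:
        paths["homology"] = out / "homology_filter.tsv"
        _write_artifact(paths["homology"], homology_scores, header)
    _write_artifact(paths["merged"], merged.df, header)
    _write_artifact(paths["merge_report"], report.to_frame(), header)
    _write_artifact(paths["enrichment"], enrichment, header)
    if dendrogram is not None:
        paths["tree"].write_text(dendrogram.to_newick() + "\n")
        _write_artifact(paths["cluster_merges"], dendrogram.merge_table(), header)
    else:
        paths["tree"].write_text("")
        _write_artifact(paths["cluster_merges"], pd.DataFrame(columns=["node_a", "node_b", "height", "new_node", "size"]), header)
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for line in log:
            fh.write(line + "\n")

    n_passing = len(predict_ids) if cfg.bridge_species else len(query_mirnas)
    return WorkflowResult(
        config=cfg,
        consensus=consensus,
        homology=homology_scores,
        merged=merged,
        merge_report=report,
        enrichment=enrichment,
        dendrogram=dendrogram,
        n_query_mirnas=len(query_mirnas),
        n_passing_mirnas=n_passing,
        paths=paths,
        log=log,
    )
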