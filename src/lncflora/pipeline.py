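"""End-to-end orchestration: classify -> filter -> DE -> conservation -> targets.

A run starts from a bundle directory (a ``manifest.yaml`` naming the inputs,
as written by the synthetic generator or assembled by hand from real data)
and writes every stage's table plus a JSON summary report.  Reruns with the
same config and seed are byte-identical.  The report's accounting
identities — category counts partition the lncRNA total, up + down = total
DE per feature type, highly-conserved <= conserved per species — are
asserted on every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .annotate_classify import chromosome_density, classify_all
from .coding_potential import (
    Thresholds,
    background_hexamer_model,
    score_transcripts,
    train_hexamer_model,
    verdicts_to_frame,
)
from .conservation import (
    best_hit_per_query,
    conservation_summary,
    filter_hits,
    reciprocal_best_hits,
    sharing_matrix,
)
from .expression_de import de_analysis, fpkm
from .io_formats import ExpressionMatrix, TranscriptModel
from .lncrna_filter import (
    FilterParams,
    categorize_and_name,
    filter_candidates,
    records_to_frame,
)
from .regulatory_targets import (
    cis_targets,
    enrich,
    export_network,
    read_term_map,
    trans_targets,
)

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SummaryReport",
    "run_pipeline",
    "summarize_characteristics",
    "ddct",
    "verify_accounting",
]


@dataclass(frozen=True)
class RunConfig:
    """All paths and thresholds of one pipeline run."""

    bundle_dir: Path
    outdir: Path
    seed: int = 1
    filter_params: FilterParams = field(default_factory=FilterParams)
    coding_thresholds: Thresholds = field(default_factory=Thresholds)
    lfc_threshold: float = 1.0
    q_threshold: float = 0.05
    max_evalue: float = 1e-10
    min_coverage: float = 0.30
    cis_window: int = 100_000
    min_abs_r: float = 0.95
    trans_alpha: float = 0.05
    density_bin: int = 1_000_000


@dataclass
class SummaryReport:
    """Per-stage counts and characteristics of one run."""

    counts: dict
    characteristics: dict
    thresholds: dict

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "characteristics": self.characteristics,
            "thresholds": self.thresholds,
        }


def verify_accounting(summary: Mapping) -> pd.DataFrame:
    """Check the partition identities a consistent census must satisfy.

    ``summary`` is a mapping with (any of) the keys:

    * ``total_lncrnas`` and ``category_counts`` (dict category -> n),
    * ``de_lncrna`` / ``de_pcg``: dicts with ``up``, ``down``, ``total``,
    * ``de_by_category``: dict category -> n of DE lncRNAs (vs de_lncrna total),
    * ``conservation``: list of dicts with ``species``, ``n_conserved``,
      ``n_highly_conserved``.

    Returns a DataFrame (identity, lhs, rhs, holds) and raises
    ``AssertionError`` if any identity fails.
    """
    rows = []

    def check(name: str, lhs: float, rhs: float, op: str = "==") -> None:
        holds = (lhs == rhs) if op == "==" else (lhs <= rhs)
        rows.append({"identity": name, "lhs": lhs, "rhs": rhs, "holds": holds})

    if "category_counts" in summary:
        check(
            "sum(category) == total lncRNAs",
            sum(summary["category_counts"].values()),
            summary["total_lncrnas"],
        )
    for key in ("de_lncrna", "de_pcg"):
        if key in summary:
            d = summary[key]
            check(f"{key}: up + down == total", d["up"] + d["down"], d["total"])
    if "de_by_category" in summary and "de_lncrna" in summary:
        check(
            "sum(DE by category) == total DE lncRNAs",
            sum(summary["de_by_category"].values()),
            summary["de_lncrna"]["total"],
        )
    for entry in summary.get("conservation", []):
        check(
            f"{entry['species']}: highly conserved <= conserved",
            entry["n_highly_conserved"],
            entry["n_conserved"],
            op="<=",
        )
    df = pd.DataFrame(rows, columns=["identity", "lhs", "rhs", "holds"])
    bad = df[~df["holds"]]
    if len(bad):
        raise AssertionError(f"accounting identities violated:\n{bad}")
    return df


def summarize_characteristics(
    lncrnas: Sequence[TranscriptModel], mrnas: Sequence[TranscriptModel]
) -> dict:
    """Length / exon-count summaries contrasting lncRNAs with mRNAs."""

    def one(models: Sequence[TranscriptModel]) -> dict:
        if not models:
            raise ValueError("empty transcript set")
        lengths = np.array([t.length for t in models])
        exons = np.array([t.n_exons for t in models])
        n = len(models)
        fractions = {
            "le_200": float((lengths <= 200).sum() / n),
            "201_1000": float(((lengths > 200) & (lengths <= 1000)).sum() / n),
            "gt_1000": float((lengths > 1000).sum() / n),
        }
        hist = {int(k): int(v) for k, v in zip(*np.unique(exons, return_counts=True))}
        return {
            "n": n,
            "mean_length": float(lengths.mean()),
            "median_length": float(np.median(lengths)),
            "length_fractions": fractions,
            "mean_exons": float(exons.mean()),
            "exon_histogram": hist,
        }

    return {"lncRNA": one(lncrnas), "mRNA": one(mrnas)}


def ddct(
    ct_table: pd.DataFrame,
    target_id: str,
    reference_id: str,
    control_group: str,
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct_table`` is long-format with columns sample, group, gene, ct.
    dCt = Ct(target) - Ct(reference) per sample; ddCt subtracts the control
    group's mean dCt; relative expression is 2^-ddCt (so the control group
    averages 1 on the ddCt scale).
    """
    pivot = ct_table.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for gene in (target_id, reference_id):
        if gene not in pivot.columns or pivot[gene].isna().any():
            missing = (
                pivot.index.get_level_values("sample").tolist()
                if gene not in pivot.columns
                else pivot.index[pivot[gene].isna()].get_level_values("sample").tolist()
            )
            raise ValueError(f"missing Ct for {gene} in samples {missing}")
    dct = pivot[target_id] - pivot[reference_id]
    groups = dct.index.get_level_values("group")
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} absent from table")
    control_mean = dct[groups == control_group].mean()
    ddct_vals = dct - control_mean
    out = pd.DataFrame(
        {
            "sample": dct.index.get_level_values("sample"),
            "group": groups,
            "delta_ct": dct.values,
            "delta_delta_ct": ddct_vals.values,
            "relative_expression": np.power(2.0, -ddct_vals.values),
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# the run itself


def _load_bundle_inputs(bundle_dir: Path) -> dict:
    with open(bundle_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    p = lambda key: bundle_dir / manifest[key]  # noqa: E731
    ref = iof.read_gtf(p("reference_gtf"))
    novel = iof.read_gtf(p("novel_gtf"))
    ref_seqs = iof.read_fasta(p("ref_fasta"))
    novel_seqs = iof.read_fasta(p("novel_fasta"))
    libs, groups = iof.read_samples_sheet(p("samples"))
    matrix = iof.read_counts(p("counts"), library_sizes=libs, group_labels=groups)
    chrom_sizes = {}
    with open(p("chrom_sizes")) as fh:
        for line in fh:
            chrom, size = line.split("\t")
            chrom_sizes[chrom] = int(size)
    term_map, term_names = read_term_map(p("terms"))
    homology = {}
    hdir = bundle_dir / manifest["homology_dir"]
    for sp in manifest["species"]:
        sp_seqs = iof.read_fasta(hdir / f"{sp}.fasta")
        fwd = iof.read_blast_tab(
            hdir / f"{sp}_forward.tsv",
            {tid: len(s) for tid, s in novel_seqs.items()},
        )
        rev = iof.read_blast_tab(
            hdir / f"{sp}_reverse.tsv", {sid: len(s) for sid, s in sp_seqs.items()}
        )
        homology[sp] = (fwd, rev)
    return {
        "manifest": manifest,
        "reference": ref,
        "novel": novel,
        "ref_seqs": ref_seqs,
        "novel_seqs": novel_seqs,
        "matrix": matrix,
        "chrom_sizes": chrom_sizes,
        "term_map": term_map,
        "term_names": term_names,
        "homology": homology,
    }


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Execute every stage in order and write all outputs under ``outdir``."""
    bundle_dir = Path(config.bundle_dir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_bundle_inputs(bundle_dir)
    reference: list[TranscriptModel] = inputs["reference"]
    novel: list[TranscriptModel] = inputs["novel"]
    matrix: ExpressionMatrix = inputs["matrix"]
    group_a, group_b = inputs["manifest"]["group_labels"]

    # 1. positional classification
    class_codes = classify_all(novel, reference)
    codes_df = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in novel],
            "class_code": [class_codes[t.transcript_id].code for t in novel],
            "subject_gene_id": [
                class_codes[t.transcript_id].subject_gene_id for t in novel
            ],
        }
    )
    codes_df.to_csv(outdir / "class_codes.tsv", sep="\t", index=False)

    # 2. coding potential (hexamer model trained on the annotated mRNAs
    #    against their zero-order compositional background)
    coding_model = train_hexamer_model(inputs["ref_seqs"].values())
    noncoding_model = background_hexamer_model(inputs["ref_seqs"].values())
    verdicts = score_transcripts(
        inputs["novel_seqs"], coding_model, noncoding_model, config.coding_thresholds
    )
    verdicts_to_frame(verdicts).to_csv(
        outdir / "coding_verdicts.tsv", sep="\t", float_format="%.6g"
    )

    # 3. FPKM
    lengths = pd.Series(
        {
            **{t.gene_id: t.length for t in reference},
            **{t.transcript_id: t.length for t in novel},
        }
    )
    fpkm_df = fpkm(matrix.counts, lengths, matrix.library_sizes)
    fpkm_df.to_csv(
        outdir / "fpkm.tsv", sep="\t", index_label="feature_id", float_format="%.6g"
    )

    # 4. filter cascade and naming
    records, audit = filter_candidates(
        novel, class_codes, fpkm_df, verdicts, config.filter_params
    )
    records = categorize_and_name(records)
    audit.to_frame().to_csv(outdir / "filter_audit.tsv", sep="\t", index=False)
    rec_df = records_to_frame(records)
    rec_df.to_csv(outdir / "lncrnas.tsv", sep="\t", index=False)
    iof.write_gtf([r.transcript for r in records], outdir / "lncrnas.gtf")
    category_counts = {
        cat: int((rec_df["category"] == cat).sum()) if len(rec_df) else 0
        for cat in ("lincRNA", "antisense", "sense", "intronic")
    }
    lnc_ids = list(rec_df["transcript_id"]) if len(rec_df) else []
    category_by_tid = (
        dict(zip(rec_df["transcript_id"], rec_df["category"])) if len(rec_df) else {}
    )

    # 5. differential expression, lncRNAs and PCGs separately
    pcg_ids = [t.gene_id for t in reference]
    expressed_pcgs = [
        g
        for g in pcg_ids
        if float(fpkm_df.loc[g].max()) >= config.filter_params.min_fpkm
    ]

    def _sub_de(ids: list[str]) -> pd.DataFrame:
        sub = ExpressionMatrix(
            matrix.counts.loc[ids], matrix.library_sizes, matrix.group_labels
        )
        return de_analysis(
            sub, group_a, group_b, config.lfc_threshold, config.q_threshold
        )

    de_lnc = _sub_de(lnc_ids)
    de_pcg = _sub_de(pcg_ids)
    de_lnc.to_csv(
        outdir / "de_lncrna.tsv", sep="\t", index_label="feature_id",
        float_format="%.6g",
    )
    de_pcg.to_csv(
        outdir / "de_pcg.tsv", sep="\t", index_label="feature_id", float_format="%.6g"
    )

    def _updown(df: pd.DataFrame) -> dict:
        up = int((df["status"] == "up").sum()) if len(df) else 0
        down = int((df["status"] == "down").sum()) if len(df) else 0
        return {"up": up, "down": down, "total": up + down}

    de_lnc_counts = _updown(de_lnc)
    de_pcg_counts = _updown(de_pcg)
    de_lnc_ids = (
        list(de_lnc.index[de_lnc["status"] != "ns"]) if len(de_lnc) else []
    )
    de_by_category = {
        cat: sum(1 for tid in de_lnc_ids if category_by_tid.get(tid) == cat)
        for cat in ("lincRNA", "antisense", "sense", "intronic")
    }

    # 6. conservation
    kept_fwd, rbh_by_sp = {}, {}
    for sp, (fwd, rev) in inputs["homology"].items():
        kf = filter_hits(fwd, config.max_evalue, config.min_coverage)
        kr = filter_hits(rev, config.max_evalue, config.min_coverage)
        kept_fwd[sp] = kf
        rbh_by_sp[sp] = reciprocal_best_hits(
            best_hit_per_query(kf), best_hit_per_query(kr), sp
        )
    cons_table, membership = conservation_summary(kept_fwd, rbh_by_sp)
    cons_table.to_csv(outdir / "conservation_summary.tsv", sep="\t", index=False)
    sharing_matrix(membership, sorted(kept_fwd)).to_csv(
        outdir / "conservation_sharing.tsv", sep="\t", index_label="query_id"
    )
    rbh_rows = [
        {"species": p.species, "query_id": p.query_id, "subject_id": p.subject_id}
        for sp in sorted(rbh_by_sp)
        for p in rbh_by_sp[sp]
    ]
    pd.DataFrame(rbh_rows, columns=["species", "query_id", "subject_id"]).to_csv(
        outdir / "rbh_pairs.tsv", sep="\t", index=False
    )

    # 7. cis / trans targets of the DE lncRNAs
    tx_by_id = {t.transcript_id: t for t in novel}
    de_lnc_models = [tx_by_id[tid] for tid in de_lnc_ids]
    cis_pairs = cis_targets(de_lnc_models, reference, config.cis_window)
    lnc_expr = fpkm_df.loc[de_lnc_ids] if de_lnc_ids else fpkm_df.iloc[:0]
    gene_expr = fpkm_df.loc[expressed_pcgs] if expressed_pcgs else fpkm_df.iloc[:0]
    trans_pairs = (
        trans_targets(lnc_expr, gene_expr, config.min_abs_r, config.trans_alpha)
        if len(lnc_expr) and len(gene_expr)
        else []
    )
    pd.DataFrame(
        [
            {"lncrna_id": p.lncrna_id, "gene_id": p.gene_id, "distance": p.distance}
            for p in cis_pairs
        ],
        columns=["lncrna_id", "gene_id", "distance"],
    ).to_csv(outdir / "cis_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "gene_id": p.gene_id,
                "r": p.r,
                "r_pvalue": p.r_pvalue,
            }
            for p in trans_pairs
        ],
        columns=["lncrna_id", "gene_id", "r", "r_pvalue"],
    ).to_csv(outdir / "trans_pairs.tsv", sep="\t", index=False, float_format="%.6g")

    # 8. enrichment of target sets against the expressed-PCG universe
    universe = set(expressed_pcgs)
    results = {}
    for mode, pairs in (("cis", cis_pairs), ("trans", trans_pairs)):
        selected = {p.gene_id for p in pairs} & universe
        res = enrich(selected, universe, inputs["term_map"])
        results[mode] = res
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "term_name": inputs["term_names"].get(r.term_id, r.term_id),
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "N": r.N,
                    "pvalue": r.pvalue,
                    "qvalue": r.qvalue,
                    "significant": r.significant,
                }
                for r in res
            ],
            columns=[
                "term_id", "term_name", "k", "K", "n", "N",
                "pvalue", "qvalue", "significant",
            ],
        ).to_csv(
            outdir / f"enrichment_{mode}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    # 9. network export
    de_status = {}
    for df in (de_lnc, de_pcg):
        for fid, row in df.iterrows():
            de_status[str(fid)] = row["status"]
    export_network(cis_pairs + trans_pairs, de_status, outdir / "network_edges.tsv")

    # 10. density + characteristics
    density = chromosome_density(
        [r.transcript.span for r in records], inputs["chrom_sizes"], config.density_bin
    )
    density.to_csv(outdir / "lncrna_density.tsv", sep="\t", index=False)
    characteristics: dict = {}
    if records:
        characteristics = summarize_characteristics(
            [r.transcript for r in records], reference
        )

    counts = {
        "novel_transcripts": len(novel),
        "class_code_counts": {
            c: int((codes_df["class_code"] == c).sum()) for c in ("=", "u", "x", "i", "o")
        },
        "total_lncrnas": len(records),
        "category_counts": category_counts,
        "de_lncrna": de_lnc_counts,
        "de_pcg": de_pcg_counts,
        "de_by_category": de_by_category,
        "conservation": cons_table.to_dict(orient="records"),
        "n_cis_pairs": len(cis_pairs),
        "n_trans_pairs": len(trans_pairs),
        "n_significant_terms": {
            mode: sum(r.significant for r in res) for mode, res in results.items()
        },
        "filter_audit": audit.to_frame().to_dict(orient="records"),
    }
    thresholds = {
        "filter_params": dataclasses.asdict(config.filter_params),
        "coding_thresholds": dataclasses.asdict(config.coding_thresholds),
        "lfc_threshold": config.lfc_threshold,
        "q_threshold": config.q_threshold,
        "max_evalue": config.max_evalue,
        "min_coverage": config.min_coverage,
        "cis_window": config.cis_window,
        "min_abs_r": config.min_abs_r,
        "trans_alpha": config.trans_alpha,
        "seed": config.seed,
    }
    report = SummaryReport(counts=counts, characteristics=characteristics,
                           thresholds=thresholds)
    verify_accounting(counts)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
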