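"""End-to-end orchestration: scan -> replicate -> express -> report.

The pipeline mirrors a two-stage meQTL study.  Discovery hits are the
probes with a region-adjusted p below threshold in the all-samples pass;
loci whose significant CpGs show a disease-group methylation difference
(NOF controls differing from OA) have the NOF samples excluded from their
replication test, replication uses duplicate-QC'd pyrosequencing data with
Kruskal-Wallis + Bonferroni, and expression integration correlates
2^-dCt relative expression with methylation and genotype at each hit
locus.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .discovery import (
    DEFAULT_PASSES,
    group_methylation_comparison,
    run_strata,
)
from .expression import correlate_locus, expression_table
from .replication import fraction_percent, run_replication
from .simulate import SimConfig, StudyData, simulate_study


@dataclass
class PipelineParams:
    """Tunable analysis settings shared by the CLI and the library."""

    default_span: int = 1_000_000
    step: int = 500_000
    threshold: float = 0.05
    passes: Sequence[str] = DEFAULT_PASSES
    bonferroni_k: Optional[int] = None  # default: CpGs tested in the batch
    duplicate_tolerance: float = 5.0
    trend_tolerance: float = 0.5
    grubbs_alpha: float = 0.05
    eqtl_test: str = "kruskal_wallis"
    #: exclude NOF controls from replication at loci whose discovery CpGs
    #: show a disease-group methylation difference (p < threshold)
    auto_exclude_nof: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class ReportBundle:
    """All tables from one run plus metadata sufficient to reproduce it."""

    scan_results: pd.DataFrame
    scan_flags: pd.DataFrame
    replication_results: pd.DataFrame
    replication_qc_log: pd.DataFrame
    expression_results: pd.DataFrame
    locus_summary: pd.DataFrame
    metadata: dict
    summary_text: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scan_results.to_csv(out / "scan_results.tsv", sep="\t",
                                 index=False)
        self.scan_flags.to_csv(out / "scan_flags.tsv", sep="\t", index=False)
        self.replication_results.to_csv(
            out / "replication_results.tsv", sep="\t", index=False
        )
        self.replication_qc_log.to_csv(
            out / "replication_qc_log.tsv", sep="\t", index=False
        )
        self.expression_results.to_csv(
            out / "expression_results.tsv", sep="\t", index=False
        )
        self.locus_summary.to_csv(out / "locus_summary.tsv", sep="\t",
                                  index=False)
        (out / "summary.txt").write_text(self.summary_text)
        (out / "metadata.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True) + "\n"
        )

    def report_hash(self) -> str:
        """Digest over every result table, for determinism checks."""
        h = hashlib.sha256()
        for df in (self.scan_results, self.scan_flags,
                   self.replication_results, self.replication_qc_log,
                   self.expression_results, self.locus_summary):
            h.update(df.round(12).to_csv(index=False).encode())
        return h.hexdigest()


def _config_hash(params: PipelineParams, seed: Optional[int]) -> str:
    blob = json.dumps(
        {"params": {k: list(v) if isinstance(v, tuple) else v
                    for k, v in asdict(params).items()},
         "seed": seed},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _parent_cpg(cpg_id: str) -> str:
    """Assay CpGs named '<probe>+Nbp'/'<probe>-Nbp' inherit the discovery
    probe's locus and direction."""
    for sep in ("+", "-"):
        head, _, tail = cpg_id.partition(sep)
        if tail.endswith("bp") and head.startswith("cg"):
            return head
    return cpg_id


def run_from_study(
    study: StudyData,
    params: Optional[PipelineParams] = None,
    seed: Optional[int] = None,
) -> ReportBundle:
    """Run the full analysis over an assembled study dataset."""
    params = params or PipelineParams()
    cohort = study.cohort

    scan_results, scan_flags = run_strata(
        cohort, study.loci, study.manifest,
        default_span=params.default_span, step=params.step,
        passes=params.passes, threshold=params.threshold,
    )
    all_pass = scan_results.loc[scan_results["stratum"] == "all"]
    hits = all_pass.loc[all_pass["significant"]]

    # disease-group methylation comparison at each hit CpG; loci with a
    # group difference lose their NOF controls in replication
    group_rows = []
    exclude_nof_snps: set[str] = set()
    nof_ids = list(
        study.pyro_samples.index[study.pyro_samples["status"] == "NOF"]
    )
    for row in hits.itertuples(index=False):
        try:
            cmp = group_methylation_comparison(
                cohort.betas[row.probe_id], cohort.samples
            )
        except ValueError:
            continue
        group_rows.append(
            {"locus_id": row.locus_id, "snp_id": row.snp_id,
             "probe_id": row.probe_id, "p": cmp["p"],
             **{f"mean_{k}": v for k, v in cmp["means"].items()}}
        )
        if params.auto_exclude_nof and cmp["p"] < params.threshold:
            exclude_nof_snps.add(row.snp_id)

    # ---- replication
    hit_dir = dict(zip(hits["probe_id"], hits["direction_vs_risk"]))
    hit_snp = dict(zip(hits["probe_id"], hits["snp_id"]))
    risk_is_minor = {l.snp_id: l.risk_is_minor for l in study.loci}
    cpg_to_snp: dict[str, str] = {}
    direction: dict[str, str] = {}
    for cpg in pd.unique(study.pyro["cpg_id"]) if len(study.pyro) else []:
        parent = _parent_cpg(cpg)
        if parent in hit_snp:
            cpg_to_snp[cpg] = hit_snp[parent]
            direction[cpg] = hit_dir[parent]
    if cpg_to_snp:
        replication, qc_log = run_replication(
            study.pyro, study.pyro_dosages, cpg_to_snp, direction,
            risk_is_minor,
            k=params.bonferroni_k,
            exclude_samples={s: nof_ids for s in exclude_nof_snps},
            duplicate_tolerance=params.duplicate_tolerance,
            trend_tolerance=params.trend_tolerance,
            threshold=params.threshold,
        )
    else:
        replication = pd.DataFrame(
            columns=["cpg_id", "snp_id", "n_used", "group_sizes", "H",
                     "p_raw", "p_adj", "direction", "direction_match",
                     "replicated", "status"]
        )
        qc_log = pd.DataFrame(columns=["sample_id", "cpg_id", "rep1", "rep2"])

    # ---- expression integration at hit loci
    expr_tables = []
    if len(study.ct):
        expr = expression_table(study.ct)
        for gene, locus_id in study.gene_to_locus.items():
            locus_hits = hits.loc[hits["locus_id"] == locus_id]
            if locus_hits.empty:
                continue
            expr_tables.append(
                correlate_locus(
                    expr, cohort.betas, cohort.dosages, gene,
                    list(locus_hits["probe_id"]),
                    locus_hits["snp_id"].iloc[0],
                    alpha=params.threshold,
                    grubbs_alpha=params.grubbs_alpha,
                    eqtl_test=params.eqtl_test,
                )
            )
    expression = (
        pd.concat(expr_tables, ignore_index=True)
        if expr_tables
        else pd.DataFrame(
            columns=["gene", "test", "target", "statistic", "p_raw",
                     "p_adj", "significant", "n_outliers_removed"]
        )
    )

    # ---- per-locus summary
    snp_replicated = (
        replication.loc[replication["replicated"] == True]  # noqa: E712
        .groupby("snp_id").size().to_dict()
        if len(replication)
        else {}
    )
    summary_rows = []
    for locus in study.loci:
        sub = all_pass.loc[all_pass["locus_id"] == locus.locus_id]
        sig = sub.loc[sub["significant"]]
        summary_rows.append(
            {
                "locus_id": locus.locus_id,
                "snp_id": locus.snp_id,
                "stratum": locus.stratum,
                "m_probes": len(sub),
                "n_significant_cpgs": len(sig),
                "min_p_adj": sig["p_adj"].min() if len(sig) else np.nan,
                "direction_vs_risk": (
                    sig["direction_vs_risk"].mode().iloc[0]
                    if len(sig) else "."
                ),
                "max_pct_var_explained": (
                    sig["pct_var_explained"].max() if len(sig) else np.nan
                ),
                "nof_excluded_in_replication": locus.snp_id
                in exclude_nof_snps,
                "n_replicated_cpgs": snp_replicated.get(locus.snp_id, 0),
                "replicated": snp_replicated.get(locus.snp_id, 0) > 0,
            }
        )
    locus_summary = pd.DataFrame(summary_rows)

    n_loci = len(study.loci)
    n_meqtl = int((locus_summary["n_significant_cpgs"] > 0).sum())
    n_repl = int(locus_summary["replicated"].sum())
    lines = [
        f"cis-meQTL scan of {n_loci} loci, "
        f"{len(cohort.samples)} discovery samples",
        f"meQTL loci (>=1 region-adjusted p < {params.threshold}): "
        f"{n_meqtl}",
        f"replicated loci: {n_repl} of {n_loci} "
        f"({fraction_percent(n_repl, n_loci)}%)",
        "",
        f"{'locus':<10}{'SNP':<12}{'sig CpGs':>9}{'min adj p':>12}"
        f"{'direction':>11}{'max %var':>10}{'replicated':>12}",
    ]
    for r in summary_rows:
        if r["n_significant_cpgs"] == 0:
            continue
        lines.append(
            f"{r['locus_id']:<10}{r['snp_id']:<12}"
            f"{r['n_significant_cpgs']:>9}"
            f"{r['min_p_adj']:>12.3g}{r['direction_vs_risk']:>11}"
            f"{r['max_pct_var_explained']:>10.1f}"
            f"{str(r['replicated']):>12}"
        )
    summary_text = "\n".join(lines) + "\n"

    metadata = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(params, seed),
        "n_loci": n_loci,
        "n_discovery_samples": int(len(cohort.samples)),
        "n_meqtl_loci": n_meqtl,
        "n_replicated_loci": n_repl,
        "nof_excluded_snps": sorted(exclude_nof_snps),
        "group_comparison": group_rows,
    }
    return ReportBundle(
        scan_results=scan_results,
        scan_flags=scan_flags,
        replication_results=replication,
        replication_qc_log=qc_log,
        expression_results=expression,
        locus_summary=locus_summary,
        metadata=metadata,
        summary_text=summary_text,
    )


def run_synthetic(
    seed: int,
    sim_config: Optional[SimConfig] = None,
    params: Optional[PipelineParams] = None,
) -> tuple[StudyData, ReportBundle]:
    """Simulate a study under the default conditions and analyse it."""
    study = simulate_study(sim_config or SimConfig(), seed)
    return study, run_from_study(study, params, seed=seed)
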