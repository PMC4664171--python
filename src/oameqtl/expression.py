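"""Gene-expression integration for meQTL loci.

Relative expression from qPCR cycle thresholds via the 2^-dCt method
(target Ct minus the mean of three housekeeping genes), Grubbs outlier
removal, Spearman correlation of expression with CpG methylation, and an
eQTL pass testing expression differences across genotype groups
(Kruskal-Wallis by default, t-test on the extreme genotype groups as an
alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for one sample and target gene.

    ``ct_housekeeping`` holds the three housekeeping-gene Cts (18S, GAPDH
    and HPRT1 roles); NaN marks a failed housekeeping assay.
    """

    sample_id: str
    gene: str
    ct_target: float
    ct_housekeeping: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_target) and self.ct_target > 0):
            raise ValueError(
                f"{self.sample_id}/{self.gene}: target Ct must be finite > 0"
            )
        for v in self.ct_housekeeping:
            if np.isfinite(v) and v <= 0:
                raise ValueError(
                    f"{self.sample_id}/{self.gene}: housekeeping Ct <= 0"
                )


def relative_expression(
    ct: CtRecord, missing_policy: str = "mean_available"
) -> float:
    """Relative expression 2^-(Ct_target - mean housekeeping Ct).

    With ``missing_policy="mean_available"`` a missing housekeeping value
    is tolerated as long as at least two remain; ``"strict"`` rejects any
    missing value.  Adding a constant to all four Cts leaves the result
    unchanged (the measure is scale-free in cycle units).
    """
    hk = np.asarray(ct.ct_housekeeping, dtype=float)
    finite = hk[np.isfinite(hk)]
    if missing_policy == "strict":
        if finite.size != hk.size:
            raise ValueError(
                f"{ct.sample_id}/{ct.gene}: missing housekeeping Ct"
            )
    elif missing_policy == "mean_available":
        if finite.size < 2:
            raise ValueError(
                f"{ct.sample_id}/{ct.gene}: fewer than two housekeeping Cts"
            )
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return float(2.0 ** -(ct.ct_target - finite.mean()))


def expression_table(
    ct: pd.DataFrame, missing_policy: str = "mean_available"
) -> pd.DataFrame:
    """2^-dCt for a Ct table (sample_id, gene, ct_target, ct_18s, ct_gapdh,
    ct_hprt1), returning sample_id, gene, rel_expr."""
    rows = []
    for rec in ct.itertuples(index=False):
        r = relative_expression(
            CtRecord(
                rec.sample_id,
                rec.gene,
                float(rec.ct_target),
                (float(rec.ct_18s), float(rec.ct_gapdh), float(rec.ct_hprt1)),
            ),
            missing_policy=missing_policy,
        )
        rows.append(
            {"sample_id": rec.sample_id, "gene": rec.gene, "rel_expr": r}
        )
    return pd.DataFrame(rows)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at ``alpha``."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal.

    At each step the single most extreme value (largest |x - mean| / sd) is
    removed if its G statistic exceeds the critical value; iteration stops
    when no value exceeds it, fewer than three values remain, or the spread
    is zero.  Removal depends only on the value multiset, never on input
    order.  Returns (kept, removed) with kept in original input order.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return v.copy(), np.array([])
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    keep = np.ones(v.size, dtype=bool)
    removed: list[float] = []
    while keep.sum() >= 3:
        x = v[keep]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        g = dev.max() / sd
        if g <= grubbs_critical(int(keep.sum()), alpha):
            break
        # most extreme value; ties broken toward the larger value so the
        # outcome is a function of the multiset only
        worst_val = max(x[dev == dev.max()])
        idx = np.flatnonzero(keep & (v == worst_val))[0]
        keep[idx] = False
        removed.append(worst_val)
    return v[keep], np.asarray(removed)


def methylation_expression_correlation(
    rel_expr: Sequence[float], beta: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p) of expression with
    methylation, pairwise-complete.

    Requires >= 4 complete pairs; a constant input has no defined rank
    correlation and is rejected.
    """
    e = np.asarray(rel_expr, dtype=float)
    b = np.asarray(beta, dtype=float)
    if e.shape != b.shape:
        raise ValueError("vectors must have the same length")
    ok = np.isfinite(e) & np.isfinite(b)
    e, b = e[ok], b[ok]
    if e.size < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.ptp(e) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = stats.spearmanr(e, b)
    return float(rho), float(p)


def expression_by_genotype(
    rel_expr: Sequence[float],
    dosage: Sequence[float],
    test: str = "kruskal_wallis",
    min_group: int = 2,
    equal_var: bool = False,
) -> Optional[float]:
    """p-value for expression differences across genotype groups.

    ``kruskal_wallis`` uses all dosage groups of size >= ``min_group``;
    ``t_test`` compares the two extreme eligible genotype groups (Welch by
    default, pooled with ``equal_var=True``).  Returns None when fewer than
    two eligible groups remain.
    """
    e = np.asarray(rel_expr, dtype=float)
    d = np.asarray(dosage, dtype=float)
    ok = np.isfinite(e) & np.isfinite(d)
    e, d = e[ok], d[ok]
    groups = [
        e[d == g] for g in sorted(np.unique(d)) if (d == g).sum() >= min_group
    ]
    if len(groups) < 2:
        return None
    if test == "kruskal_wallis":
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            return 1.0
        _, p = stats.kruskal(*groups)
        return float(p)
    if test == "t_test":
        _, p = stats.ttest_ind(groups[0], groups[-1], equal_var=equal_var)
        return float(p)
    raise ValueError(f"unknown test {test!r}")


def correlate_locus(
    expr: pd.DataFrame,
    betas: pd.DataFrame,
    dosages: pd.DataFrame,
    gene: str,
    probe_ids: Sequence[str],
    snp_id: str,
    alpha: float = 0.05,
    grubbs_alpha: float = 0.05,
    eqtl_test: str = "kruskal_wallis",
) -> pd.DataFrame:
    """Expression integration for one gene at one meQTL locus.

    Grubbs-filters the gene's relative expression, then (a) Spearman-
    correlates it against methylation at each discovery CpG and (b) tests
    expression across genotype groups at the index SNP.  Within-locus
    Bonferroni over the CpG correlations.  Returns one row per test.
    """
    sub = expr.loc[expr["gene"] == gene].set_index("sample_id")["rel_expr"]
    kept, removed = grubbs_filter(sub.to_numpy(), alpha=grubbs_alpha)
    keep_mask = ~sub.isin(removed)
    sub = sub[keep_mask]

    rows = []
    k = max(len(probe_ids), 1)
    for probe in probe_ids:
        b = betas[probe].reindex(sub.index)
        try:
            rho, p = methylation_expression_correlation(
                sub.to_numpy(), b.to_numpy()
            )
            p_adj = min(1.0, k * p)
            rows.append(
                {
                    "gene": gene, "test": "spearman_methylation",
                    "target": probe, "statistic": rho, "p_raw": p,
                    "p_adj": p_adj, "significant": p_adj < alpha,
                    "n_outliers_removed": int(removed.size),
                }
            )
        except ValueError:
            rows.append(
                {
                    "gene": gene, "test": "spearman_methylation",
                    "target": probe, "statistic": np.nan, "p_raw": np.nan,
                    "p_adj": np.nan, "significant": False,
                    "n_outliers_removed": int(removed.size),
                }
            )
    d = dosages[snp_id].reindex(sub.index)
    p = expression_by_genotype(sub.to_numpy(), d.to_numpy(), test=eqtl_test)
    rows.append(
        {
            "gene": gene, "test": f"eqtl_{eqtl_test}", "target": snp_id,
            "statistic": np.nan,
            "p_raw": np.nan if p is None else p,
            "p_adj": np.nan if p is None else p,
            "significant": bool(p is not None and p < alpha),
            "n_outliers_removed": int(removed.size),
        }
    )
    return pd.DataFrame(rows)
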