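"""Replication of discovery meQTLs on pyrosequencing percent methylation.

Pyrosequencing runs each PCR in duplicate; a sample is excluded at a CpG
when the duplicates differ by more than 5 percentage points, otherwise the
duplicate mean is carried forward.  Genotype association is then tested per
CpG with a Kruskal-Wallis test across dosage groups, Bonferroni-corrected
for the number of CpGs in the batch, and a CpG replicates when the
corrected p is below threshold AND the genotype trend runs in the same
direction as in discovery.

This module works on the percent scale [0, 100]; discovery betas convert at
the boundary via beta = pct / 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import risk_dosage

DUPLICATE_TOLERANCE_PCT = 5.0  # max |rep1 - rep2| retained
TREND_TOLERANCE_PCT = 0.5  # extreme-group mean gap below which trend is flat


def qc_duplicates(
    rep1: float, rep2: float, tolerance: float = DUPLICATE_TOLERANCE_PCT
) -> Optional[float]:
    """Duplicate mean, or None when the replicates disagree by > tolerance.

    A difference of exactly ``tolerance`` is retained (the exclusion rule
    is strictly "differed by more than"). Values outside [0, 100] are
    invalid measurements.
    """
    for v in (rep1, rep2):
        if not np.isfinite(v) or not 0.0 <= v <= 100.0:
            raise ValueError(f"percent methylation outside [0, 100]: {v}")
    if abs(rep1 - rep2) > tolerance:
        return None
    return (rep1 + rep2) / 2.0


def qc_table(
    pyro: pd.DataFrame, tolerance: float = DUPLICATE_TOLERANCE_PCT
) -> pd.DataFrame:
    """Vectorized duplicate QC over a (sample_id, cpg_id, rep1, rep2) table.

    Adds ``mean_pct`` (NaN when excluded) and ``qc_pass``.
    """
    out = pyro.copy()
    r1 = out["rep1"].to_numpy(dtype=float)
    r2 = out["rep2"].to_numpy(dtype=float)
    bad = ~(
        np.isfinite(r1) & np.isfinite(r2)
        & (r1 >= 0) & (r1 <= 100) & (r2 >= 0) & (r2 <= 100)
    )
    if bad.any():
        i = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"percent methylation outside [0, 100] at row {out.index[i]} "
            f"(sample {out.iloc[i]['sample_id']!r}, cpg "
            f"{out.iloc[i]['cpg_id']!r})"
        )
    keep = np.abs(r1 - r2) <= tolerance
    out["qc_pass"] = keep
    out["mean_pct"] = np.where(keep, (r1 + r2) / 2.0, np.nan)
    return out


def kruskal_wallis_by_genotype(
    values: Sequence[float],
    dosage: Sequence[float],
    min_group: int = 2,
) -> tuple[Optional[float], Optional[float], dict[int, int]]:
    """Kruskal-Wallis H and p across genotype (dosage) groups.

    Pairs with a missing value are dropped; groups smaller than
    ``min_group`` are excluded.  Returns (H, p, group sizes); (None, None)
    when fewer than two eligible groups remain ("not testable").  Identical
    values throughout give H = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if v.shape != d.shape:
        raise ValueError("values and dosage must have the same length")
    ok = np.isfinite(v) & np.isfinite(d)
    v, d = v[ok], d[ok]
    groups = []
    sizes: dict[int, int] = {}
    for g in sorted(np.unique(d)):
        vals = v[d == g]
        if vals.size >= min_group:
            groups.append(vals)
            sizes[int(g)] = int(vals.size)
    if len(groups) < 2:
        return None, None, sizes
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, sizes
    h, p = stats.kruskal(*groups)
    return float(h), float(p), sizes


def bonferroni(p_raw: float, k: int) -> float:
    """Bonferroni correction for ``k`` CpGs tested: min(1, k * p)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, k * p_raw)


def trend_direction(
    group_means: Mapping[int, float],
    tolerance: float = TREND_TOLERANCE_PCT,
) -> str:
    """Direction of methylation across risk-allele dosage groups.

    Compares the two extreme dosage groups: "lower" when the high-dosage
    mean falls below the low-dosage mean by more than ``tolerance``
    percentage points, "higher" for the reverse, "flat" otherwise.
    """
    if len(group_means) < 2:
        raise ValueError("need means for at least two genotype groups")
    lo = min(group_means)
    hi = max(group_means)
    delta = group_means[hi] - group_means[lo]
    if abs(delta) <= tolerance:
        return "flat"
    return "lower" if delta < 0 else "higher"


def direction_consistency(
    discovery_direction: str,
    group_means: Mapping[int, float],
    tolerance: float = TREND_TOLERANCE_PCT,
) -> bool:
    """True iff the replication trend matches the discovery direction.

    ``group_means`` are keyed by risk-allele dosage.  A flat replication
    trend (extreme-group gap within tolerance) never counts as a match.
    """
    if discovery_direction not in ("lower", "higher"):
        raise ValueError(
            f"discovery direction must be lower/higher, got "
            f"{discovery_direction!r}"
        )
    return trend_direction(group_means, tolerance) == discovery_direction


def run_replication(
    pyro: pd.DataFrame,
    dosages: pd.DataFrame,
    cpg_to_snp: Mapping[str, str],
    discovery_direction: Mapping[str, str],
    risk_is_minor: Mapping[str, bool],
    k: Optional[int] = None,
    exclude_samples: Optional[Mapping[str, Sequence[str]]] = None,
    duplicate_tolerance: float = DUPLICATE_TOLERANCE_PCT,
    trend_tolerance: float = TREND_TOLERANCE_PCT,
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full replication pass over a duplicate pyrosequencing table.

    Parameters
    ----------
    pyro : table with columns sample_id, cpg_id, rep1, rep2.
    dosages : samples x SNPs minor-allele dosage table.
    cpg_to_snp : maps each CpG (discovery probe or "+Nbp" assay CpG) to the
        index SNP whose genotype stratifies it.
    discovery_direction : discovery trend ("lower"/"higher" vs risk allele)
        per CpG; additional assay CpGs inherit their discovery CpG's
        direction.
    risk_is_minor : per SNP, whether the risk allele is the minor allele.
    k : Bonferroni denominator; defaults to the number of CpGs tested in
        this batch.
    exclude_samples : per-SNP sample ids to drop (e.g. NOF controls at loci
        with disease-group methylation differences).

    Returns (results, qc_log): one result row per CpG, and the QC log of
    excluded duplicate measurements.
    """
    qc = qc_table(pyro, tolerance=duplicate_tolerance)
    qc_log = qc.loc[~qc["qc_pass"],
                    ["sample_id", "cpg_id", "rep1", "rep2"]].copy()
    kept = qc.loc[qc["qc_pass"]]

    cpgs = [c for c in pd.unique(pyro["cpg_id"]) if c in cpg_to_snp]
    if k is None:
        k = len(cpgs)
    rows = []
    for cpg in cpgs:
        snp = cpg_to_snp[cpg]
        sub = kept.loc[kept["cpg_id"] == cpg]
        if exclude_samples and snp in exclude_samples:
            sub = sub.loc[~sub["sample_id"].isin(exclude_samples[snp])]
        d = dosages.reindex(sub["sample_id"])[snp].to_numpy(dtype=float)
        d_risk = risk_dosage(d, risk_is_minor[snp])
        v = sub["mean_pct"].to_numpy(dtype=float)
        h, p_raw, sizes = kruskal_wallis_by_genotype(v, d_risk)
        row: dict = {
            "cpg_id": cpg,
            "snp_id": snp,
            "n_used": int(sum(sizes.values())),
            "group_sizes": "/".join(
                f"{g}:{n}" for g, n in sorted(sizes.items())
            ),
            "H": h,
            "p_raw": p_raw,
        }
        if p_raw is None:
            row.update(
                p_adj=None, direction="not_testable", direction_match=False,
                replicated=False, status="not_testable",
            )
        else:
            ok = np.isfinite(v) & np.isfinite(d_risk)
            means = {
                int(g): float(v[ok][d_risk[ok] == g].mean())
                for g in sizes
            }
            direction = trend_direction(means, trend_tolerance)
            match = direction == discovery_direction.get(cpg)
            p_adj = bonferroni(p_raw, k)
            row.update(
                p_adj=p_adj,
                direction=direction,
                direction_match=bool(match),
                replicated=bool(p_adj < threshold and match),
                status="ok",
            )
        rows.append(row)
    return pd.DataFrame(rows), qc_log


def fraction_percent(count: int, total: int, decimals: int = 1) -> float:
    """Fraction as a percentage truncated to ``decimals`` places.

    Truncation (not rounding) matches the convention of summary statements
    such as 3 replicated loci of 16 = 18.7%.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    scale = 10 ** decimals
    return np.floor(100.0 * count / total * scale) / scale
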