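"""Discovery-stage cis-meQTL scan.

Methylation beta-values (fraction methylated, in [0, 1]) at every CpG probe
inside a locus window are regressed on minor-allele dosage (0/1/2) by
ordinary least squares; the two-sided p-value for slope = 0 is corrected
per region with the Benjamini-Hochberg step-up procedure, with the
denominator fixed at the number of probes in the tested region.  The scan
is repeated over sample strata (all, OA only, NOF only, OA knee, OA hip,
males, females), each pass corrected independently.

Degenerate situations — a SNP monomorphic within a stratum, fewer than
three complete genotype/methylation pairs — yield flagged records rather
than exceptions so a multi-locus run always completes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import (
    CpGProbe,
    GenomicInterval,
    Locus,
    ProbeManifest,
    build_window,
    select_probes,
)

SIGNIFICANCE_THRESHOLD = 0.05

#: Analysis passes, in the order they are run.  Each maps a pass label to a
#: predicate over the sample sheet.
STRATA: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "all": lambda s: pd.Series(True, index=s.index),
    "OA": lambda s: s["status"] == "OA",
    "NOF": lambda s: s["status"] == "NOF",
    "OA_knee": lambda s: (s["status"] == "OA") & (s["joint"] == "knee"),
    "OA_hip": lambda s: (s["status"] == "OA") & (s["joint"] == "hip"),
    "males": lambda s: s["sex"] == "male",
    "females": lambda s: s["sex"] == "female",
}

DEFAULT_PASSES = tuple(STRATA)


@dataclass(frozen=True)
class SampleRecord:
    """One patient: disease status (OA or NOF fracture control), joint, sex."""

    sample_id: str
    status: str
    joint: str
    sex: str

    def __post_init__(self) -> None:
        if self.status not in ("OA", "NOF"):
            raise ValueError(f"{self.sample_id}: status must be OA or NOF")
        if self.joint not in ("knee", "hip", "none"):
            raise ValueError(f"{self.sample_id}: joint must be knee/hip/none")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.sample_id}: sex must be male/female")
        if self.status == "NOF" and self.joint == "knee":
            raise ValueError(
                f"{self.sample_id}: NOF (fracture control) samples are free "
                "of OA and cannot carry joint='knee'"
            )


@dataclass
class CohortData:
    """Sample sheet, genotype dosages and methylation betas, joined on id.

    ``samples`` is indexed by sample_id with columns status/joint/sex;
    ``dosages`` is samples x SNPs with values in {0, 1, 2} or NaN;
    ``betas`` is samples x probes with values in [0, 1] or NaN.
    """

    samples: pd.DataFrame
    dosages: pd.DataFrame
    betas: pd.DataFrame

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        for name, table in (("dosages", self.dosages), ("betas", self.betas)):
            missing = table.index.difference(self.samples.index)
            if len(missing):
                raise ValueError(
                    f"{name} rows not in sample sheet: {sorted(missing)[:10]}"
                )
        b = self.betas.to_numpy(dtype=float)
        bad = np.isfinite(b) & ((b < 0) | (b > 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                "beta out of [0, 1] at sample "
                f"{self.betas.index[r]!r}, probe {self.betas.columns[c]!r} "
                f"(value {b[r, c]})"
            )
        d = self.dosages.to_numpy(dtype=float)
        bad = np.isfinite(d) & ~np.isin(d, (0.0, 1.0, 2.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                "dosage not in {0, 1, 2} at sample "
                f"{self.dosages.index[r]!r}, SNP {self.dosages.columns[c]!r} "
                f"(value {d[r, c]})"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index


@dataclass(frozen=True)
class RegressionResult:
    """OLS of beta on dosage for one probe.

    ``status`` is "ok", "monomorphic" (single dosage value among complete
    pairs) or "insufficient" (< 3 complete pairs); the statistics are NaN
    for non-ok records.
    """

    n_used: int
    slope: float
    intercept: float
    p_raw: float
    r_squared: float
    status: str = "ok"


def _regress_matrix(
    dosage: np.ndarray, betas: np.ndarray
) -> dict[str, np.ndarray]:
    """Column-wise OLS of ``betas`` (n x m, NaN allowed) on ``dosage`` (n,).

    Missing entries are dropped pairwise per column.  Returns per-column
    slope, intercept, two-sided p for slope = 0, r^2, n and a status code
    (0 ok, 1 insufficient data, 2 monomorphic dosage).
    """
    d = np.asarray(dosage, dtype=float)[:, None]
    b = np.asarray(betas, dtype=float)
    if b.ndim != 2 or b.shape[0] != d.shape[0]:
        raise ValueError("betas must be (n_samples, n_probes)")
    valid = np.isfinite(b) & np.isfinite(d)
    n = valid.sum(axis=0).astype(float)
    d0 = np.where(valid, d, 0.0)
    b0 = np.where(valid, b, 0.0)
    sd = d0.sum(axis=0)
    sb = b0.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = (d0 * d0).sum(axis=0) - sd * sd / n
        syy = (b0 * b0).sum(axis=0) - sb * sb / n
        sxy = (d0 * b0).sum(axis=0) - sd * sb / n
        # negative round-off from catastrophic cancellation -> clamp
        sxx = np.maximum(sxx, 0.0)
        syy = np.maximum(syy, 0.0)
        slope = sxy / sxx
        intercept = (sb - slope * sd) / n
        rss = np.maximum(syy - sxy * sxy / sxx, 0.0)
        df = n - 2
        se2 = rss / (df * sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slope / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)

    status = np.zeros(b.shape[1], dtype=int)
    status[n < 3] = 1
    status[(n >= 3) & (sxx <= 0)] = 2
    ok = status == 0

    # constant beta: zero covariance -> slope exactly 0, p = 1
    flat = ok & (syy <= 0)
    slope[flat] = 0.0
    p[flat] = 1.0
    # perfect fit with nonzero slope: se = 0 -> p = 0
    exact = ok & (syy > 0) & (rss <= 0)
    p[exact] = 0.0

    for arr in (slope, intercept, p, r2):
        arr[~ok] = np.nan
    return {
        "slope": slope,
        "intercept": intercept,
        "p_raw": p,
        "r_squared": np.clip(r2, 0.0, 1.0),
        "n_used": n.astype(int),
        "status": status,
    }


_STATUS_LABELS = {0: "ok", 1: "insufficient", 2: "monomorphic"}


def dosage_regression(
    beta: Sequence[float], dosage: Sequence[float]
) -> RegressionResult:
    """OLS of methylation beta on minor-allele dosage for a single probe.

    Pairs with a missing value on either side are dropped.  A stratum in
    which the SNP is monomorphic, or with fewer than three complete pairs,
    yields a flagged result rather than an exception.
    """
    beta = np.asarray(beta, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if beta.shape != dosage.shape:
        raise ValueError("beta and dosage must have the same length")
    out = _regress_matrix(dosage, beta[:, None])
    return RegressionResult(
        n_used=int(out["n_used"][0]),
        slope=float(out["slope"][0]),
        intercept=float(out["intercept"][0]),
        p_raw=float(out["p_raw"][0]),
        r_squared=float(out["r_squared"][0]),
        status=_STATUS_LABELS[int(out["status"][0])],
    )


def variance_explained(
    beta: Sequence[float], dosage: Sequence[float]
) -> float:
    """Percent of methylation variability accounted for by genotype.

    100 x r^2 of the univariate dosage model (equivalently 100 x the
    squared Pearson correlation of beta with dosage).
    """
    res = dosage_regression(beta, dosage)
    if res.status != "ok":
        return float("nan")
    return 100.0 * res.r_squared


def bh_adjust(
    p_values: Sequence[float], m: Optional[int] = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with region denominator ``m``.

    ``m`` defaults to the number of p-values and may exceed it when some of
    the m region probes produced no testable p (those implicitly count as
    p = 1, which cannot change the step-up minimum below the cap).  Output
    preserves input order, is monotone in the sorted order and is capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    k = p.size
    if k == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"denominator m={m} smaller than number of tests {k}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adj = np.empty(k)
    adj[order] = adj_sorted
    return adj


@dataclass
class LocusScan:
    """Scan outcome for one locus in one pass.

    ``status``: "ok", "empty_stratum", "monomorphic", "no_genotypes" or
    "no_probes".  ``results`` has one row per region probe (empty for
    locus-level failures).
    """

    locus_id: str
    stratum: str
    status: str
    n_samples: int
    m_probes: int
    results: pd.DataFrame


_RESULT_COLUMNS = [
    "locus_id",
    "snp_id",
    "probe_id",
    "stratum",
    "n_used",
    "slope",
    "intercept",
    "p_raw",
    "p_adj",
    "significant",
    "direction_vs_risk",
    "pct_var_explained",
    "status",
]


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(columns=_RESULT_COLUMNS)


def scan_locus(
    cohort: CohortData,
    locus: Locus,
    probes: Sequence[CpGProbe],
    stratum: str = "all",
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> LocusScan:
    """Regress every region probe on dosage within one sample stratum.

    The BH denominator is the full region probe count m, so probes that are
    individually untestable still count toward the correction.  Direction
    is re-expressed per risk-allele copy: "lower" means methylation falls
    as risk-allele count rises.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    mask = STRATA[stratum](cohort.samples)
    ids = cohort.samples.index[mask]
    m = len(probes)
    if m == 0:
        return LocusScan(locus.locus_id, stratum, "no_probes", len(ids), 0,
                         _empty_results())
    if len(ids) < 3:
        return LocusScan(locus.locus_id, stratum, "empty_stratum", len(ids),
                         m, _empty_results())
    if locus.snp_id not in cohort.dosages.columns:
        return LocusScan(locus.locus_id, stratum, "no_genotypes", len(ids),
                         m, _empty_results())

    d = cohort.dosages.loc[ids, locus.snp_id].to_numpy(dtype=float)
    finite_d = d[np.isfinite(d)]
    if finite_d.size < 3 or np.unique(finite_d).size < 2:
        return LocusScan(locus.locus_id, stratum, "monomorphic", len(ids),
                         m, _empty_results())

    probe_ids = [p.probe_id for p in probes]
    missing_probes = [p for p in probe_ids if p not in cohort.betas.columns]
    if missing_probes:
        raise KeyError(
            f"{locus.locus_id}: probes absent from beta matrix: "
            f"{missing_probes[:5]}"
        )
    b = cohort.betas.loc[ids, probe_ids].to_numpy(dtype=float)
    out = _regress_matrix(d, b)

    p_raw = out["p_raw"]
    testable = np.isfinite(p_raw)
    p_adj = np.full(m, np.nan)
    if testable.any():
        p_adj[testable] = bh_adjust(p_raw[testable], m=m)

    sign = np.sign(out["slope"])
    if not locus.risk_is_minor:
        sign = -sign
    direction = np.select(
        [sign < 0, sign > 0], ["lower", "higher"], default="flat"
    )
    direction = np.where(out["status"] == 0, direction, "flat")

    res = pd.DataFrame(
        {
            "locus_id": locus.locus_id,
            "snp_id": locus.snp_id,
            "probe_id": probe_ids,
            "stratum": stratum,
            "n_used": out["n_used"],
            "slope": out["slope"],
            "intercept": out["intercept"],
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": np.where(
                np.isfinite(p_adj), p_adj < threshold, False
            ).astype(bool),
            "direction_vs_risk": direction,
            "pct_var_explained": 100.0 * out["r_squared"],
            "status": [_STATUS_LABELS[s] for s in out["status"]],
        },
        columns=_RESULT_COLUMNS,
    )
    return LocusScan(locus.locus_id, stratum, "ok", len(ids), m, res)


def run_strata(
    cohort: CohortData,
    loci: Sequence[Locus],
    manifest: ProbeManifest | Iterable[CpGProbe],
    default_span: int = 1_000_000,
    step: int = 500_000,
    passes: Sequence[str] = DEFAULT_PASSES,
    threshold: float = SIGNIFICANCE_THRESHOLD,
    exclude_polymorphic: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every locus in every analysis pass.

    Each pass is BH-corrected independently per region.  Returns the
    concatenated per-probe result table and a per-locus x pass flag table
    (status, samples used, region probe count m).
    """
    manifest = list(manifest)
    tables: list[pd.DataFrame] = []
    flags: list[dict] = []
    for locus in loci:
        window = build_window(locus, default_span=default_span, step=step)
        probes = select_probes(
            manifest, window, exclude_polymorphic=exclude_polymorphic
        )
        for label in passes:
            scan = scan_locus(cohort, locus, probes, label, threshold)
            flags.append(
                {
                    "locus_id": locus.locus_id,
                    "snp_id": locus.snp_id,
                    "stratum": label,
                    "status": scan.status,
                    "n_samples": scan.n_samples,
                    "m_probes": scan.m_probes,
                    "window_start": window.start,
                    "window_end": window.end,
                }
            )
            if not scan.results.empty:
                tables.append(scan.results)
    results = (
        pd.concat(tables, ignore_index=True) if tables else _empty_results()
    )
    return results, pd.DataFrame(flags)


def group_methylation_comparison(
    beta: pd.Series,
    samples: pd.DataFrame,
    min_group: int = 2,
) -> dict:
    """Compare one probe's methylation across OA-knee / OA-hip / NOF groups.

    Groups with fewer than ``min_group`` non-missing values are dropped
    (reported under "dropped").  The across-group test is Kruskal-Wallis;
    identical values in every group give H = 0, p = 1.
    """
    groups = {
        "OA_knee": (samples["status"] == "OA") & (samples["joint"] == "knee"),
        "OA_hip": (samples["status"] == "OA") & (samples["joint"] == "hip"),
        "NOF": samples["status"] == "NOF",
    }
    values: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, mask in groups.items():
        ids = samples.index[mask]
        v = beta.reindex(ids).dropna().to_numpy(dtype=float)
        if v.size >= min_group:
            values[name] = v
        else:
            dropped.append(name)
    if len(values) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    means = {name: float(v.mean()) for name, v in values.items()}
    pooled = np.concatenate(list(values.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values.values())
    return {
        "means": means,
        "n": {name: int(v.size) for name, v in values.items()},
        "H": float(h),
        "p": float(p),
        "dropped": dropped,
    }
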