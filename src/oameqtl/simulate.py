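"""Synthetic cohort generator with a planted-effect truth ledger.

Emulates the statistical structure of a cartilage meQTL study: ~100
patients (OA knee / OA hip / NOF fracture controls), 16 loci with region
CpG probe counts on the order of a 450k-array scan, Hardy-Weinberg
genotypes, additive allelic effects on methylation at a minority of loci,
disease-group and sex offsets at some probes, bounded (0, 1) methylation,
duplicate pyrosequencing measurements for replication, and qPCR Ct tables
for expression integration.

Methylation is simulated on the logit scale and mapped through the inverse
logit, because additive generation directly on the beta scale can escape
[0, 1].  The truth ledger reports each planted effect both in logit units
and as the population least-squares slope on the beta scale (the quantity
the discovery regression estimates), so parameter-recovery tests have an
exact target.

A single root seed derives named substreams per component, so each stage
can be regenerated independently and a full run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .discovery import CohortData
from .regions import CpGProbe, GenomicInterval, Locus, ProbeManifest

_HERMGAUSS_NODES = 64


@dataclass(frozen=True)
class LocusSim:
    """Simulation parameters for one locus.

    ``planted`` maps probe ordinals (0-based, within the locus region) to
    allelic effects in logit units per risk-allele copy.  ``nof_offsets``
    and ``male_offsets`` are additive logit shifts applied to NOF / male
    samples at the given probe ordinals, independent of genotype.
    """

    locus_id: str
    maf: float
    n_probes: int
    risk_is_minor: bool = True
    planted: Mapping[int, float] = field(default_factory=dict)
    nof_offsets: Mapping[int, float] = field(default_factory=dict)
    male_offsets: Mapping[int, float] = field(default_factory=dict)
    stratum: str = "knees_and_hips"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"{self.locus_id}: MAF must be in (0, 1)")
        if self.n_probes < 1:
            raise ValueError(f"{self.locus_id}: need >= 1 region probe")
        for idx in (*self.planted, *self.nof_offsets, *self.male_offsets):
            if not 0 <= idx < self.n_probes:
                raise ValueError(
                    f"{self.locus_id}: probe ordinal {idx} outside region"
                )


def _default_loci() -> tuple[LocusSim, ...]:
    # Region probe counts mirror a 450k scan of 16 OA loci; four loci carry
    # planted effects of graded strength (the weakest mimics a signal that
    # replicates in direction but not significance).  Two planted loci have
    # risk = minor allele, two risk = major, exercising the sign flip.
    counts = [431, 76, 197, 157, 135, 57, 123, 190,
              655, 32, 385, 91, 92, 135, 71, 270]
    mafs = [0.33, 0.21, 0.38, 0.27, 0.45, 0.19, 0.31, 0.24,
            0.41, 0.29, 0.36, 0.22, 0.40, 0.26, 0.18, 0.35]
    strata = ["knees_and_hips", "female_knees", "males", "hips", "knees",
              "female_hips", "hips", "hips", "knees_and_hips", "hips",
              "knees_and_hips", "hands", "females", "male_hips", "hips",
              "knees_and_hips"]
    loci = []
    for i, (m, c, s) in enumerate(zip(mafs, counts, strata), start=1):
        lid = f"locus{i:02d}"
        planted: dict[int, float] = {}
        nof: dict[int, float] = {}
        male: dict[int, float] = {}
        risk_minor = True
        mid = c // 2
        if i == 1:
            planted = {mid - 1: -0.5, mid: -0.5, mid + 1: -0.5}
            nof = {j: -0.2 for j in planted}
        elif i == 3:
            planted = {mid - 1: -0.6, mid: -0.6, mid + 1: -0.6, mid + 2: -0.6}
            nof = {j: -0.2 for j in planted}
            male = {mid - 1: -0.15, mid + 1: -0.15, mid + 2: -0.15}
        elif i == 12:
            planted = {mid: -0.55}
            risk_minor = False
        elif i == 16:
            planted = {mid: -0.25}
            risk_minor = False
        loci.append(
            LocusSim(lid, m, c, risk_minor, planted, nof, male, s)
        )
    return tuple(loci)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: a 99-sample discovery cohort
    (63 OA knee / 17 OA hip / 19 NOF), 16 loci, logit-scale methylation
    noise, a replication cohort of 40 OA + 5 NOF with duplicate
    pyrosequencing, and a 29-sample OA-knee qPCR expression panel.
    """

    n_oa_knee: int = 63
    n_oa_hip: int = 17
    n_nof: int = 19
    loci: Sequence[LocusSim] = field(default_factory=_default_loci)
    noise_sd_logit: float = 0.15
    baseline_logit_range: tuple[float, float] = (-1.5, 1.5)
    polymorphic_every: int = 40  # every k-th non-planted probe flagged
    pyro_replicate_sd: float = 1.5  # percentage points per PCR replicate
    n_replication_oa: int = 40
    n_replication_nof: int = 5
    n_expression: int = 29
    expression_link_ct_per_beta: float = 0.0  # target-Ct shift per beta unit
    expression_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd_logit < 0 or self.pyro_replicate_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def null(cls) -> "SimConfig":
        """Study conditions with every planted effect and offset removed
        (for false-discovery-rate calibration runs)."""
        cfg = cls()
        cfg.loci = tuple(
            replace(l, planted={}, nof_offsets={}, male_offsets={})
            for l in cfg.loci
        )
        return cfg


_STREAMS = (
    "genotypes", "baselines", "methylation", "sex",
    "replication", "pyro", "expression",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {
        name: np.random.default_rng(s)
        for name, s in zip(_STREAMS, children)
    }


def simulate_genotypes(
    n: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    """Minor-allele dosages under Hardy-Weinberg: Binomial(2, maf) draws."""
    if not 0.0 < maf < 1.0:
        raise ValueError("MAF must be in (0, 1)")
    return rng.binomial(2, maf, size=n)


def simulate_methylation(
    dosage_risk: np.ndarray,
    baseline_logit: float,
    effect_logit: float,
    offsets: Optional[np.ndarray],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Beta values from an additive logit model, mapped into (0, 1)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    d = np.asarray(dosage_risk, dtype=float)
    z = baseline_logit + effect_logit * d
    if offsets is not None:
        z = z + np.asarray(offsets, dtype=float)
    z = z + rng.normal(0.0, noise_sd, size=d.shape)
    return expit(z)


def simulate_pyro(
    beta_true: np.ndarray, replicate_sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate percent-methylation measurements, truncated to [0, 100]."""
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    center = 100.0 * np.asarray(beta_true, dtype=float)
    rep1 = rng.normal(center, replicate_sd)
    rep2 = rng.normal(center, replicate_sd)
    return np.clip(rep1, 0.0, 100.0), np.clip(rep2, 0.0, 100.0)


def simulate_expression(
    predictor: np.ndarray,
    link_slope: float,
    noise_sd: float,
    rng: np.random.Generator,
    baseline_ct: float = 26.0,
    housekeeping_means: tuple[float, float, float] = (10.0, 18.0, 24.0),
    housekeeping_sd: float = 0.2,
) -> pd.DataFrame:
    """qPCR Ct draws whose 2^-dCt carries the planted association.

    Target Ct = baseline + link_slope * predictor + noise; a positive link
    between methylation and Ct therefore yields a negative methylation-
    expression correlation.  Housekeeping Cts sit around fixed means (18S,
    GAPDH, HPRT1 roles).
    """
    x = np.asarray(predictor, dtype=float)
    n = x.size
    ct_target = baseline_ct + link_slope * x + rng.normal(0, noise_sd, n)
    hk = {
        name: rng.normal(mu, housekeeping_sd, n)
        for name, mu in zip(("ct_18s", "ct_gapdh", "ct_hprt1"),
                            housekeeping_means)
    }
    return pd.DataFrame({"ct_target": ct_target, **hk})


def expected_beta(logit_mean: float, noise_sd: float) -> float:
    """E[inverse-logit(mu + eps)], eps ~ N(0, sd), by Gauss-Hermite."""
    if noise_sd == 0:
        return float(expit(logit_mean))
    nodes, weights = np.polynomial.hermite.hermgauss(_HERMGAUSS_NODES)
    vals = expit(logit_mean + np.sqrt(2.0) * noise_sd * nodes)
    return float((weights * vals).sum() / np.sqrt(np.pi))


def beta_scale_effect(
    baseline_logit: float,
    effect_logit: float,
    maf: float,
    risk_is_minor: bool,
    noise_sd: float,
) -> float:
    """Population beta-scale slope per risk-allele copy.

    The least-squares slope of E[beta | risk dosage] on risk dosage under
    Hardy-Weinberg genotype frequencies; this is the target the discovery
    OLS slope estimates under the logit generator.
    """
    p = maf if risk_is_minor else 1.0 - maf
    w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    d = np.array([0.0, 1.0, 2.0])
    y = np.array(
        [expected_beta(baseline_logit + effect_logit * di, noise_sd)
         for di in d]
    )
    dbar = (w * d).sum()
    ybar = (w * y).sum()
    return float(
        (w * (d - dbar) * (y - ybar)).sum() / (w * (d - dbar) ** 2).sum()
    )


@dataclass
class SimTruth:
    """Ledger of planted effects for parameter-recovery tests."""

    table: pd.DataFrame  # one row per planted locus x probe
    seed: int

    def planted_probes(self) -> list[str]:
        return list(self.table["probe_id"])

    def lookup(self, probe_id: str) -> pd.Series:
        hit = self.table.loc[self.table["probe_id"] == probe_id]
        if hit.empty:
            raise KeyError(probe_id)
        return hit.iloc[0]


@dataclass
class StudyData:
    """Everything a full pipeline run consumes, plus the truth ledger."""

    cohort: CohortData
    loci: list[Locus]
    manifest: ProbeManifest
    truth: SimTruth
    pyro: pd.DataFrame  # sample_id, cpg_id, rep1, rep2
    pyro_samples: pd.DataFrame  # replication sample sheet
    pyro_dosages: pd.DataFrame  # replication samples x SNPs
    ct: pd.DataFrame  # sample_id, gene, ct_target, ct_18s, ct_gapdh, ct_hprt1
    gene_to_locus: dict[str, str]


def _locus_geometry(i: int, spec: LocusSim) -> tuple[Locus, list[CpGProbe]]:
    """Deterministic genomic layout for simulated locus ``i`` (1-based).

    The SNP sits at 50 Mb on its own chromosome; the LD block spans +/-200
    kb; region probes are evenly spaced across the 1 Mb default window so
    centrally planted probes fall inside the block.
    """
    chrom = f"chr{i}"
    pos = 50_000_000
    block = GenomicInterval(chrom, pos - 200_000, pos + 200_000)
    snp_id = f"rs{900000 + i}"
    risk = "minor" if spec.risk_is_minor else "major"
    locus = Locus(
        locus_id=spec.locus_id,
        snp_id=snp_id,
        chromosome=chrom,
        position=pos,
        major_allele="A",
        minor_allele="G",
        risk_allele="G" if spec.risk_is_minor else "A",
        ld_block=block,
        stratum=spec.stratum,
    )
    positions = np.linspace(
        pos - 499_000, pos + 499_000, spec.n_probes
    ).astype(int)
    probes = [
        CpGProbe(f"cg_{spec.locus_id}_{j:04d}", chrom, int(p), False)
        for j, p in enumerate(positions)
    ]
    return locus, probes


def simulate_cohort(
    config: SimConfig, seed: int
) -> tuple[CohortData, list[Locus], ProbeManifest, SimTruth]:
    """Discovery-stage dataset: sample sheet, dosages, betas, manifest.

    Planted effects act per risk-allele copy; NOF and male offsets act on
    the flagged probes regardless of genotype.  Every planted probe is
    guaranteed to exist in the manifest, lie inside its locus LD block and
    be non-polymorphic.
    """
    rngs = _rngs(seed)
    n = config.n_oa_knee + config.n_oa_hip + config.n_nof
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    status = (["OA"] * (config.n_oa_knee + config.n_oa_hip)
              + ["NOF"] * config.n_nof)
    joint = (["knee"] * config.n_oa_knee + ["hip"] * config.n_oa_hip
             + ["none"] * config.n_nof)
    sex = np.where(
        rngs["sex"].random(n) < 0.5, "male", "female"
    )
    samples = pd.DataFrame(
        {"status": status, "joint": joint, "sex": sex},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    is_nof = (samples["status"] == "NOF").to_numpy()
    is_male = (samples["sex"] == "male").to_numpy()

    dosage_cols: dict[str, np.ndarray] = {}
    beta_blocks: list[np.ndarray] = []
    probe_ids: list[str] = []
    manifest_probes: list[CpGProbe] = []
    loci: list[Locus] = []
    truth_rows: list[dict] = []

    for i, spec in enumerate(config.loci, start=1):
        locus, probes = _locus_geometry(i, spec)
        # flag every k-th non-planted probe as polymorphic
        flagged = []
        for j, p in enumerate(probes):
            poly = (
                config.polymorphic_every > 0
                and j % config.polymorphic_every == config.polymorphic_every - 1
                and j not in spec.planted
            )
            flagged.append(replace(p, polymorphic=poly) if poly else p)
        probes = flagged
        loci.append(locus)
        manifest_probes.extend(probes)

        d = simulate_genotypes(n, spec.maf, rngs["genotypes"])
        dosage_cols[locus.snp_id] = d
        d_risk = d if spec.risk_is_minor else 2 - d

        lo, hi = config.baseline_logit_range
        baselines = rngs["baselines"].uniform(lo, hi, spec.n_probes)
        effects = np.zeros(spec.n_probes)
        for j, e in spec.planted.items():
            effects[j] = e
        nof_off = np.zeros(spec.n_probes)
        for j, e in spec.nof_offsets.items():
            nof_off[j] = e
        male_off = np.zeros(spec.n_probes)
        for j, e in spec.male_offsets.items():
            male_off[j] = e

        z = (
            baselines[None, :]
            + effects[None, :] * d_risk[:, None]
            + nof_off[None, :] * is_nof[:, None]
            + male_off[None, :] * is_male[:, None]
            + rngs["methylation"].normal(0, config.noise_sd_logit,
                                         (n, spec.n_probes))
        )
        beta_blocks.append(expit(z))
        probe_ids.extend(p.probe_id for p in probes)

        for j, e in spec.planted.items():
            probe = probes[j]
            assert not probe.polymorphic
            assert locus.ld_block.contains(probe.chromosome, probe.position)
            truth_rows.append(
                {
                    "locus_id": spec.locus_id,
                    "snp_id": locus.snp_id,
                    "probe_id": probe.probe_id,
                    "maf": spec.maf,
                    "risk_is_minor": spec.risk_is_minor,
                    "baseline_logit": baselines[j],
                    "effect_logit": e,
                    "beta_effect": beta_scale_effect(
                        baselines[j], e, spec.maf, spec.risk_is_minor,
                        config.noise_sd_logit,
                    ),
                    "nof_offset_logit": nof_off[j],
                    "male_offset_logit": male_off[j],
                }
            )

    betas = pd.DataFrame(
        np.hstack(beta_blocks), index=samples.index, columns=probe_ids
    )
    dosages = pd.DataFrame(dosage_cols, index=samples.index, dtype=float)
    cohort = CohortData(samples=samples, dosages=dosages, betas=betas)
    truth_cols = ["locus_id", "snp_id", "probe_id", "maf", "risk_is_minor",
                  "baseline_logit", "effect_logit", "beta_effect",
                  "nof_offset_logit", "male_offset_logit"]
    truth = SimTruth(
        pd.DataFrame(truth_rows, columns=truth_cols), seed
    )
    return cohort, loci, ProbeManifest(manifest_probes), truth


def simulate_study(config: SimConfig, seed: int) -> StudyData:
    """Full synthetic study: discovery cohort, replication pyro data, Ct
    table for expression, and the truth ledger."""
    cohort, loci, manifest, truth = simulate_cohort(config, seed)
    rngs = _rngs(seed)
    rng_rep = rngs["replication"]
    rng_pyro = rngs["pyro"]
    rng_expr = rngs["expression"]
    spec_by_id = {s.locus_id: s for s in config.loci}
    locus_by_id = {l.locus_id: l for l in loci}

    # ---- replication cohort: fresh OA + NOF samples, planted CpGs only
    n_rep = config.n_replication_oa + config.n_replication_nof
    rep_ids = [f"R{i:03d}" for i in range(1, n_rep + 1)]
    n_knee = int(round(config.n_replication_oa * 26 / 40))
    rep_samples = pd.DataFrame(
        {
            "status": ["OA"] * config.n_replication_oa
            + ["NOF"] * config.n_replication_nof,
            "joint": ["knee"] * n_knee
            + ["hip"] * (config.n_replication_oa - n_knee)
            + ["none"] * config.n_replication_nof,
            "sex": np.where(rng_rep.random(n_rep) < 0.5, "male", "female"),
        },
        index=pd.Index(rep_ids, name="sample_id"),
    )
    rep_is_nof = (rep_samples["status"] == "NOF").to_numpy()
    rep_is_male = (rep_samples["sex"] == "male").to_numpy()

    rep_dosages: dict[str, np.ndarray] = {}
    pyro_rows: list[pd.DataFrame] = []
    for row in truth.table.itertuples(index=False):
        spec = spec_by_id[row.locus_id]
        snp = row.snp_id
        if snp not in rep_dosages:
            rep_dosages[snp] = simulate_genotypes(n_rep, spec.maf, rng_rep)
        d = rep_dosages[snp]
        d_risk = d if spec.risk_is_minor else 2 - d
        offsets = (row.nof_offset_logit * rep_is_nof
                   + row.male_offset_logit * rep_is_male)
        beta_true = simulate_methylation(
            d_risk, row.baseline_logit, row.effect_logit, offsets,
            config.noise_sd_logit, rng_rep,
        )
        rep1, rep2 = simulate_pyro(
            beta_true, config.pyro_replicate_sd, rng_pyro
        )
        pyro_rows.append(
            pd.DataFrame(
                {
                    "sample_id": rep_ids,
                    "cpg_id": row.probe_id,
                    "rep1": rep1,
                    "rep2": rep2,
                }
            )
        )
    pyro = (
        pd.concat(pyro_rows, ignore_index=True)
        if pyro_rows
        else pd.DataFrame(columns=["sample_id", "cpg_id", "rep1", "rep2"])
    )
    pyro_dosages = pd.DataFrame(
        rep_dosages, index=rep_samples.index, dtype=float
    )

    # ---- expression panel: OA knee subset of the discovery cohort
    knee_ids = cohort.samples.index[
        (cohort.samples["status"] == "OA")
        & (cohort.samples["joint"] == "knee")
    ][: config.n_expression]
    ct_rows: list[pd.DataFrame] = []
    gene_to_locus: dict[str, str] = {}
    for locus_id in pd.unique(truth.table["locus_id"]):
        gene = f"gene_{locus_id}"
        gene_to_locus[gene] = locus_id
        probe = truth.table.loc[
            truth.table["locus_id"] == locus_id, "probe_id"
        ].iloc[0]
        predictor = cohort.betas.loc[knee_ids, probe].to_numpy()
        tab = simulate_expression(
            predictor,
            config.expression_link_ct_per_beta,
            config.expression_noise_sd,
            rng_expr,
        )
        tab.insert(0, "gene", gene)
        tab.insert(0, "sample_id", list(knee_ids))
        ct_rows.append(tab)
    ct = (
        pd.concat(ct_rows, ignore_index=True)
        if ct_rows
        else pd.DataFrame(
            columns=["sample_id", "gene", "ct_target", "ct_18s",
                     "ct_gapdh", "ct_hprt1"]
        )
    )
    return StudyData(
        cohort=cohort,
        loci=loci,
        manifest=manifest,
        truth=truth,
        pyro=pyro,
        pyro_samples=rep_samples,
        pyro_dosages=pyro_dosages,
        ct=ct,
        gene_to_locus=gene_to_locus,
    )
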