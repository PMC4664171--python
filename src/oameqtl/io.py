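"""Tab-separated readers/writers and packaged reference tables.

All tabular I/O is TSV with a header row.  The packaged reference tables
describe the 16 OA association signals (index SNP, alleles, risk allele,
LD block where published, stratum, proxy SNP) and the nine discovery CpGs
with their published region-adjusted p-values, both on hg19 coordinates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .discovery import CohortData
from .regions import CpGProbe, GenomicInterval, Locus, ProbeManifest

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."])
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------- loci


def read_loci(path: PathLike) -> list[Locus]:
    """Load a locus definition table.

    Columns: locus_id, snp_id, chromosome, position, major_allele,
    minor_allele, risk_allele, ld_start, ld_end, stratum, proxy_snp,
    proxy_r2.  "." marks a missing value; a locus without published LD
    bounds gets the degenerate block [position, position], so the window
    rule falls back to the default span.
    """
    df = _read_tsv(
        path,
        ["locus_id", "snp_id", "chromosome", "position", "major_allele",
         "minor_allele", "risk_allele", "ld_start", "ld_end", "stratum",
         "proxy_snp", "proxy_r2"],
    )
    loci = []
    for row in df.itertuples(index=False):
        pos = int(row.position)
        if pd.isna(row.ld_start) or pd.isna(row.ld_end):
            block = GenomicInterval(str(row.chromosome), pos, pos)
        else:
            block = GenomicInterval(
                str(row.chromosome), int(row.ld_start), int(row.ld_end)
            )
        loci.append(
            Locus(
                locus_id=str(row.locus_id),
                snp_id=str(row.snp_id),
                chromosome=str(row.chromosome),
                position=pos,
                major_allele=str(row.major_allele),
                minor_allele=str(row.minor_allele),
                risk_allele=str(row.risk_allele),
                ld_block=block,
                stratum=str(row.stratum),
                proxy_snp=None if pd.isna(row.proxy_snp) else str(row.proxy_snp),
                proxy_r2=None if pd.isna(row.proxy_r2) else float(row.proxy_r2),
            )
        )
    return loci


def write_loci(loci: Iterable[Locus], path: PathLike) -> None:
    rows = []
    for l in loci:
        degenerate = (
            l.ld_block.start == l.ld_block.end == l.position
        )
        rows.append(
            {
                "locus_id": l.locus_id,
                "snp_id": l.snp_id,
                "chromosome": l.chromosome,
                "position": l.position,
                "major_allele": l.major_allele,
                "minor_allele": l.minor_allele,
                "risk_allele": l.risk_allele,
                "ld_start": "." if degenerate else l.ld_block.start,
                "ld_end": "." if degenerate else l.ld_block.end,
                "stratum": l.stratum,
                "proxy_snp": l.proxy_snp or ".",
                "proxy_r2": "." if l.proxy_r2 is None else l.proxy_r2,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ manifest


def read_manifest(path: PathLike) -> ProbeManifest:
    """Probe manifest TSV: probe_id, chromosome, position, polymorphic."""
    df = _read_tsv(path, ["probe_id", "chromosome", "position", "polymorphic"])
    return ProbeManifest(
        [
            CpGProbe(
                str(r.probe_id), str(r.chromosome), int(r.position),
                bool(int(r.polymorphic)),
            )
            for r in df.itertuples(index=False)
        ]
    )


def write_manifest(manifest: ProbeManifest, path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "chromosome": p.chromosome,
                "position": p.position,
                "polymorphic": int(p.polymorphic),
            }
            for p in manifest
        ]
    ).to_csv(path, sep="\t", index=False)


def manifest_to_bed(manifest: ProbeManifest, path: PathLike) -> None:
    """BED export (0-based half-open) of probe positions."""
    with open(path, "w") as fh:
        for p in manifest:
            fh.write(f"{p.chromosome}\t{p.position - 1}\t{p.position}"
                     f"\t{p.probe_id}\n")


def intervals_to_bed(
    intervals: Iterable[tuple[str, GenomicInterval]], path: PathLike
) -> None:
    """BED export of named intervals (windows, LD blocks)."""
    with open(path, "w") as fh:
        for name, iv in intervals:
            chrom, start, end = iv.to_bed()
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# -------------------------------------------------------------- cohort


def read_cohort(
    sample_path: PathLike,
    dosage_path: PathLike,
    beta_path: PathLike,
    beta_orientation: str = "samples_by_probes",
) -> CohortData:
    """Assemble a validated cohort from three TSVs.

    The sample sheet needs sample_id/status/joint/sex; the dosage and beta
    matrices are indexed by sample_id (betas may be stored probes-by-
    samples; declare with ``beta_orientation="probes_by_samples"``).
    Out-of-range betas or dosages and duplicated or mismatched sample ids
    are rejected with row/column coordinates.
    """
    samples = _read_tsv(sample_path, ["sample_id", "status", "joint", "sex"])
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[
            samples["sample_id"].duplicated(), "sample_id"
        ].tolist()
        raise ValueError(f"duplicate sample ids in sample sheet: {dups}")
    samples = samples.set_index("sample_id")

    dosages = pd.read_csv(dosage_path, sep="\t", index_col="sample_id")
    betas = pd.read_csv(beta_path, sep="\t", index_col=0)
    if beta_orientation == "probes_by_samples":
        betas = betas.T
        betas.index.name = "sample_id"
    elif beta_orientation != "samples_by_probes":
        raise ValueError(f"unknown beta orientation {beta_orientation!r}")

    for name, table in (("dosage", dosages), ("beta", betas)):
        extra = table.index.difference(samples.index)
        if len(extra):
            raise ValueError(
                f"{name} matrix contains sample ids absent from the sample "
                f"sheet: {sorted(extra)[:10]}"
            )
    return CohortData(
        samples=samples,
        dosages=dosages.astype(float),
        betas=betas.astype(float),
    )


def write_cohort(
    cohort: CohortData,
    sample_path: PathLike,
    dosage_path: PathLike,
    beta_path: PathLike,
) -> None:
    cohort.samples.reset_index().to_csv(sample_path, sep="\t", index=False)
    cohort.dosages.to_csv(dosage_path, sep="\t", index_label="sample_id")
    cohort.betas.to_csv(beta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------- pyro & expression


def read_pyro(path: PathLike) -> pd.DataFrame:
    """Duplicate pyrosequencing table: sample_id, cpg_id, rep1, rep2."""
    df = _read_tsv(path, ["sample_id", "cpg_id", "rep1", "rep2"])
    df["rep1"] = df["rep1"].astype(float)
    df["rep2"] = df["rep2"].astype(float)
    return df


def read_ct(path: PathLike) -> pd.DataFrame:
    """qPCR Ct table: sample_id, gene, ct_target, ct_18s, ct_gapdh,
    ct_hprt1."""
    df = _read_tsv(
        path,
        ["sample_id", "gene", "ct_target", "ct_18s", "ct_gapdh", "ct_hprt1"],
    )
    for col in ("ct_target", "ct_18s", "ct_gapdh", "ct_hprt1"):
        df[col] = df[col].astype(float)
    return df


# ----------------------------------------------------- reference tables


def _data_path(name: str):
    return resources.files("oameqtl").joinpath("data", name)


def load_reference_loci() -> list[Locus]:
    """The 16 published OA association signals (hg19)."""
    with resources.as_file(_data_path("loci_hg19.tsv")) as p:
        return read_loci(p)


def load_discovery_cpgs() -> pd.DataFrame:
    """The nine published discovery CpGs with region-adjusted p-values."""
    with resources.as_file(_data_path("discovery_cpgs.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df
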