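"""Genomic regions for cis-meQTL scans.

Loci are osteoarthritis association signals: an index SNP, its alleles, the
linkage-disequilibrium (LD) block it tags (r^2 > 0.8 interval) and the
joint/sex stratum the genetic association was reported in.  The analysis
window around each SNP is symmetric and is widened in fixed steps until the
LD block is fully covered, so a 1 Mb default suffices for most loci while a
locus with a wide block gets 1.5 Mb.

Coordinates are hg19, 1-based and inclusive at both ends.  BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} exceeds end {self.end}"
            )

    @property
    def span_bp(self) -> int:
        """Number of bases covered (inclusive)."""
        return self.end - self.start + 1

    def contains(self, chromosome: str, position: int) -> bool:
        return (
            str(chromosome) == self.chromosome
            and self.start <= position <= self.end
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.chromosome == self.chromosome
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_bed(self) -> tuple[str, int, int]:
        """(chrom, start, end) in BED's 0-based half-open convention."""
        return (self.chromosome, self.start - 1, self.end)


@dataclass(frozen=True)
class Locus:
    """An OA association signal and its LD context.

    ``risk_allele`` is the allele associated with increased OA
    susceptibility and must be one of the two listed alleles.  A proxy SNP
    (used when the index SNP is not on the genotyping array) carries the
    r^2 of the proxy with the index SNP.
    """

    locus_id: str
    snp_id: str
    chromosome: str
    position: int
    major_allele: str
    minor_allele: str
    risk_allele: str
    ld_block: GenomicInterval
    stratum: str = "all"
    proxy_snp: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.risk_allele not in (self.major_allele, self.minor_allele):
            raise ValueError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is neither "
                f"major {self.major_allele!r} nor minor {self.minor_allele!r}"
            )
        if (self.proxy_snp is None) != (self.proxy_r2 is None):
            raise ValueError(
                f"{self.snp_id}: proxy_snp and proxy_r2 must be given together"
            )
        if self.proxy_r2 is not None and not 0.0 <= self.proxy_r2 <= 1.0:
            raise ValueError(f"{self.snp_id}: proxy r2 must be in [0, 1]")

    @property
    def risk_is_minor(self) -> bool:
        return self.risk_allele == self.minor_allele


@dataclass(frozen=True)
class CpGProbe:
    """A methylation-array CpG probe.

    ``polymorphic`` flags CpG sites created/destroyed by a SNP; these are
    excluded from scans because their apparent methylation tracks genotype
    trivially.
    """

    probe_id: str
    chromosome: str
    position: int
    polymorphic: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.probe_id}: position must be >= 1")


@dataclass
class ProbeManifest:
    """Collection of CpG probes, unique by probe id."""

    probes: list[CpGProbe] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate probe ids in manifest: {dups}")

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def get(self, probe_id: str) -> CpGProbe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)


def build_window(
    locus: Locus,
    default_span: int = 1_000_000,
    step: int = 500_000,
) -> GenomicInterval:
    """Symmetric analysis window centred on the index SNP.

    The window starts at ``default_span`` and is enlarged in multiples of
    ``step`` until it fully contains the locus LD block, so the whole LD
    region is always scanned.  The start is clipped at base 1.
    """
    if default_span <= 0 or step <= 0:
        raise ValueError("default_span and step must be positive")
    if locus.ld_block.chromosome != locus.chromosome:
        raise ValueError(
            f"{locus.snp_id}: LD block on chromosome "
            f"{locus.ld_block.chromosome}, SNP on {locus.chromosome}"
        )
    span = default_span
    while True:
        half = span // 2
        start = locus.position - half
        end = locus.position + half
        if start <= locus.ld_block.start and end >= locus.ld_block.end:
            break
        span += step
    return GenomicInterval(locus.chromosome, max(1, start), end)


def select_probes(
    manifest: ProbeManifest | Iterable[CpGProbe],
    window: GenomicInterval,
    exclude_polymorphic: bool = True,
) -> list[CpGProbe]:
    """Probes inside ``window`` (inclusive bounds), sorted by position.

    The length of the returned list is the multiplicity denominator m used
    for the region-wise Benjamini-Hochberg correction.  Polymorphic probes
    are dropped when ``exclude_polymorphic`` is set.  An empty result is
    allowed (m = 0).
    """
    kept = [
        p
        for p in manifest
        if window.contains(p.chromosome, p.position)
        and not (exclude_polymorphic and p.polymorphic)
    ]
    kept.sort(key=lambda p: (p.position, p.probe_id))
    return kept


def distance_kb(pos_a: int, pos_b: int, rounding: str = "floor") -> int:
    """SNP-CpG distance in whole kilobases.

    ``floor`` truncates (the convention behind printed annotations such as
    "107 kb from the SNP"); ``nearest`` rounds half away from zero.
    Symmetric and non-negative.
    """
    if pos_a < 1 or pos_b < 1:
        raise ValueError("positions must be >= 1")
    d = abs(pos_a - pos_b)
    if rounding == "floor":
        return d // 1000
    if rounding == "nearest":
        return int(math.floor(d / 1000 + 0.5))
    raise ValueError(f"unknown rounding {rounding!r}")


def within_ld_block(probe: CpGProbe, block: GenomicInterval) -> bool:
    """True iff the probe lies inside the LD block (inclusive bounds)."""
    return block.contains(probe.chromosome, probe.position)


def risk_dosage(dosage, risk_is_minor: bool):
    """Re-express a minor-allele dosage as copies of the risk allele.

    When the risk allele is the major allele the count flips to 2 - dosage;
    slopes re-expressed this way flip sign accordingly.  Accepts scalars or
    numpy arrays (NaN passes through).
    """
    return dosage if risk_is_minor else 2 - dosage
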