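"""Selection of informative SNP markers for single-side linkage phasing.

A marker is informative when it is heterozygous in exactly one parent and
homozygous in the other: the allele an embryo received from the
heterozygous parent can then be read off directly, after subtracting the
obligate allele contributed by the homozygous parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .loci import MutationLocus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SNPSite:
    """A biallelic SNP on hg19."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"pos must be positive, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(
                f"alleles must be non-empty and distinct, got "
                f"{self.ref!r}/{self.alt!r}")


@dataclass(frozen=True)
class InformativeSNP:
    """A phase-informative marker, oriented by which parent is heterozygous.

    ``het_alleles`` is the unordered allele pair of the heterozygous parent
    and ``hom_allele`` the single allele of the homozygous parent.
    ``location`` is upstream/downstream/intragenic relative to the disease
    region on forward-strand hg19 coordinates.
    """

    site: SNPSite
    side: str                      # "maternal" | "paternal"
    het_alleles: frozenset[str]
    hom_allele: str
    location: str

    def __post_init__(self) -> None:
        if self.side not in ("maternal", "paternal"):
            raise ValueError(f"side must be maternal/paternal, got {self.side!r}")
        if len(self.het_alleles) != 2:
            raise ValueError("het_alleles must be two distinct alleles")
        if self.location not in ("upstream", "downstream", "intragenic"):
            raise ValueError(f"unknown location {self.location!r}")

    @property
    def pos(self) -> int:
        return self.site.pos

    def other_het_allele(self, allele: str) -> str:
        (other,) = self.het_alleles - {allele}
        return other


def _parse_gt(gt: str) -> tuple[str, ...] | None:
    """Split a genotype string like ``"A/C"``; None for missing."""
    if gt is None or not isinstance(gt, str):
        return None
    alleles = tuple(a for a in gt.replace("|", "/").split("/") if a)
    if len(alleles) != 2 or any(a in (".", "N") for a in alleles):
        return None
    return alleles


def select_informative(
    parents: pd.DataFrame,
    locus: MutationLocus,
    window_upstream_bp: int | None = None,
    window_downstream_bp: int | None = None,
) -> list[InformativeSNP]:
    """Select the markers heterozygous in one parent, homozygous in the other.

    Parameters
    ----------
    parents
        Table with columns ``chrom, pos, ref, alt, mother, father``;
        genotypes as allele strings (``"A/C"``).
    locus
        Disease locus defining the upstream/downstream boundary.
    window_upstream_bp, window_downstream_bp
        Optional window limits measured from the region boundaries; sites
        beyond them are excluded. ``None`` means unlimited.

    Doubly heterozygous, doubly homozygous, off-contig and multi-allelic
    sites are excluded; sites with a missing parental genotype are excluded
    with a logged count rather than an error.
    """
    out: list[InformativeSNP] = []
    n_missing = 0
    n_multiallelic = 0
    for row in parents.itertuples(index=False):
        if row.chrom != locus.region.chrom:
            continue
        m = _parse_gt(row.mother)
        f = _parse_gt(row.father)
        if m is None or f is None:
            n_missing += 1
            continue
        site_alleles = {row.ref, row.alt}
        if not (set(m) | set(f)) <= site_alleles:
            n_multiallelic += 1
            continue
        location = locus.location_of(row.pos)
        if location == "upstream" and window_upstream_bp is not None:
            if row.pos < locus.region.start - window_upstream_bp:
                continue
        if location == "downstream" and window_downstream_bp is not None:
            if row.pos > locus.region.end + window_downstream_bp:
                continue
        m_het = m[0] != m[1]
        f_het = f[0] != f[1]
        if m_het == f_het:
            continue  # doubly het or doubly hom: uninformative
        site = SNPSite(row.chrom, int(row.pos), row.ref, row.alt)
        if m_het:
            out.append(InformativeSNP(
                site=site, side="maternal", het_alleles=frozenset(m),
                hom_allele=f[0], location=location))
        else:
            out.append(InformativeSNP(
                site=site, side="paternal", het_alleles=frozenset(f),
                hom_allele=m[0], location=location))
    if n_missing:
        logger.info("excluded %d sites with missing parental genotypes", n_missing)
    if n_multiallelic:
        logger.info("excluded %d sites with out-of-panel alleles", n_multiallelic)
    return out


def count_by_side_and_location(
    panel: list[InformativeSNP],
) -> dict[tuple[str, str], int]:
    """Tally informative markers by (side, location); sums to ``len(panel)``."""
    counts: dict[tuple[str, str], int] = {
        (side, loc): 0
        for side in ("maternal", "paternal")
        for loc in ("upstream", "downstream", "intragenic")
    }
    for snp in panel:
        counts[(snp.side, snp.location)] += 1
    return counts


def panel_to_frame(panel: list[InformativeSNP]) -> pd.DataFrame:
    """Serialize a selected panel as a table (TSV-ready)."""
    rows = [
        (s.site.chrom, s.site.pos, s.site.ref, s.site.alt, s.side,
         "/".join(sorted(s.het_alleles)), s.hom_allele, s.location)
        for s in panel
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "side", "het_alleles", "hom_allele",
        "location"])
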