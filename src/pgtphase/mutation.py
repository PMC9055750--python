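"""Direct mutation detection per embryo.

Two assay styles:

* Large deletions (the --SEA allele): the deleted interval fails to
  amplify on deleted copies, so the embryo's mean read depth inside the
  region, normalized by the flanking depth, collapses towards zero for a
  homozygote, towards one half for a heterozygote, and stays near one for
  a wild type.
* Small indels (HBB CD41-42, -AAAG): allele-specific read counts at the
  mutation site give the mutant-allele fraction directly.

Thresholds are configurable; the defaults separate the three copy states
with wide margins at the >30X depth the assay is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loci import MutationLocus
from .sim import EmbryoObservation


@dataclass(frozen=True)
class DeletionThresholds:
    """Depth-ratio bands for deletion genotyping (ratio = region/flank)."""

    t_hom: float = 0.10        # below: homozygous deletion (2 disease alleles)
    t_het_lo: float = 0.30     # het band
    t_het_hi: float = 0.70
    t_wt: float = 0.80         # above: no deletion
    min_flank_depth: float = 30.0
    min_flank_sites: int = 5


@dataclass(frozen=True)
class IndelThresholds:
    """Mutant-fraction bands for small-indel genotyping."""

    min_depth: float = 30.0
    het_lo: float = 0.25
    het_hi: float = 0.75
    hom_frac: float = 0.90


@dataclass(frozen=True)
class DepthCall:
    """Direct mutation-dosage call for one embryo."""

    embryo: str
    copies_or_genotype: int | None   # disease-allele count 0/1/2; None if ambiguous
    in_region_mean_depth: float
    flank_mean_depth: float
    ratio: float | None
    confidence: str                  # "pass" | "low_depth" | "ambiguous"

    @property
    def is_affected(self) -> bool:
        return self.copies_or_genotype == 2 and self.confidence == "pass"


def call_deletion_state(
    observation: EmbryoObservation,
    locus: MutationLocus,
    thresholds: DeletionThresholds | None = None,
) -> DepthCall:
    """Genotype a large deletion from the region/flank depth ratio."""
    if locus.kind != "large_deletion":
        raise ValueError(f"locus {locus.name} is not a large deletion")
    th = thresholds or DeletionThresholds()
    probes = observation.locus_probes
    region = probes[probes["kind"] == "region"]
    flank = probes[probes["kind"] == "flank"]
    if len(region) == 0:
        raise ValueError(f"no depth probes inside locus {locus.name}")
    if len(flank) < th.min_flank_sites:
        raise ValueError(
            f"need >= {th.min_flank_sites} flank probes for locus {locus.name}, "
            f"got {len(flank)}")
    region_depth = float(
        (region["ref_depth"] + region["alt_depth"]).mean())
    # zero-depth flank probes are amplification failures, not signal, and
    # would deflate the baseline; in-region zeros are kept (deletion signal)
    flank_totals = (flank["ref_depth"] + flank["alt_depth"]).to_numpy()
    amplified_flank = flank_totals[flank_totals > 0]
    if amplified_flank.size < th.min_flank_sites:
        raise ValueError(
            f"fewer than {th.min_flank_sites} amplified flank probes for "
            f"locus {locus.name}")
    flank_depth = float(amplified_flank.mean())
    ratio = region_depth / flank_depth
    if flank_depth < th.min_flank_depth:
        return DepthCall(observation.embryo, None, region_depth, flank_depth,
                         ratio, "low_depth")
    if ratio < th.t_hom:
        genotype = 2
    elif th.t_het_lo <= ratio <= th.t_het_hi:
        genotype = 1
    elif ratio > th.t_wt:
        genotype = 0
    else:
        return DepthCall(observation.embryo, None, region_depth, flank_depth,
                         ratio, "ambiguous")
    return DepthCall(observation.embryo, genotype, region_depth, flank_depth,
                     ratio, "pass")


def call_indel_genotype(
    observation: EmbryoObservation,
    locus: MutationLocus,
    thresholds: IndelThresholds | None = None,
) -> DepthCall:
    """Genotype a small indel from allele-specific counts at its site."""
    if locus.kind != "small_indel":
        raise ValueError(f"locus {locus.name} is not a small indel")
    th = thresholds or IndelThresholds()
    probes = observation.locus_probes
    site = probes[probes["kind"] == "site"]
    if len(site) == 0:
        raise ValueError(f"no allele counts at the {locus.name} site")
    ref_depth = float(site["ref_depth"].sum())
    alt_depth = float(site["alt_depth"].sum())
    flank = probes[probes["kind"] == "flank"]
    flank_depth = float(
        (flank["ref_depth"] + flank["alt_depth"]).mean()) if len(flank) else np.nan
    total = ref_depth + alt_depth
    if total < th.min_depth:
        return DepthCall(observation.embryo, None, total, flank_depth, None,
                         "low_depth")
    frac = alt_depth / total
    if frac >= th.hom_frac:
        genotype = 2
    elif th.het_lo <= frac <= th.het_hi:
        genotype = 1
    elif frac <= 1.0 - th.hom_frac:
        genotype = 0
    else:
        return DepthCall(observation.embryo, None, total, flank_depth, frac,
                         "ambiguous")
    return DepthCall(observation.embryo, genotype, total, flank_depth, frac,
                     "pass")


def call_mutation(
    observation: EmbryoObservation,
    locus: MutationLocus,
    deletion_thresholds: DeletionThresholds | None = None,
    indel_thresholds: IndelThresholds | None = None,
) -> DepthCall:
    """Dispatch to the depth- or allele-count-based caller by locus kind."""
    if locus.kind == "large_deletion":
        return call_deletion_state(observation, locus, deletion_thresholds)
    return call_indel_genotype(observation, locus, indel_thresholds)


def identify_affected_embryos(calls: dict[str, DepthCall]) -> set[str]:
    """Embryos confidently called homozygous for the disease allele.

    These are the in-cohort phasing references; an empty set means the
    family cannot be phased from this cycle's embryos.
    """
    return {label for label, call in calls.items() if call.is_affected}
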