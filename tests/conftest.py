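"""Shared fixtures: hand-built worked-example families.

Two small families mirror the published clinical narratives: an
alpha-thalassemia family of nine embryos genotyped through the SEA
deletion's depth collapse, and a beta-thalassemia family of six embryos
genotyped through CD41-42 allele counts. Both are constructed noise-free
from the known inheritance pattern so every stage has an exact expected
answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from pgtphase import EmbryoObservation, hbb_cd41_42, sea_deletion
from pgtphase.loci import MutationLocus


@dataclass
class WorkedFamily:
    parents: pd.DataFrame
    observations: list[EmbryoObservation]
    locus: MutationLocus
    maternal_h0_embryos: set[str]
    paternal_h0_embryos: set[str]
    affected: set[str]
    expected_status: dict[str, str]
    m0: dict[int, str]  # position -> disease-linked maternal allele
    f0: dict[int, str]


def _snp_row(chrom, pos, ref, alt):
    return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}


def _depths_for(alleles: tuple[str, ...], ref: str, alt: str,
                depth: float) -> tuple[int, int]:
    """Noise-free allele depths: depth/2 per copy."""
    rd = ad = 0
    per_copy = depth / 2
    for a in alleles:
        if a == ref:
            rd += per_copy
        elif a == alt:
            ad += per_copy
    return int(rd), int(ad)


def build_worked_family(
    locus: MutationLocus,
    maternal_sites: list[tuple[int, str, str, str, str, str]],
    paternal_sites: list[tuple[int, str, str, str, str, str]],
    maternal_h0: set[str],
    paternal_h0: set[str],
    embryos: list[str],
    depth: float = 100.0,
) -> WorkedFamily:
    """Assemble a noise-free family from per-site phase definitions.

    Site tuples are (pos, ref, alt, h0_allele, h1_allele, hom_allele):
    for maternal sites the mother is h0/h1 het and the father hom.
    """
    chrom = locus.region.chrom
    panel_rows, m0, f0 = [], {}, {}
    site_info = []
    for pos, ref, alt, h0, h1, hom in maternal_sites:
        panel_rows.append({**_snp_row(chrom, pos, ref, alt),
                           "mother": "/".join(sorted((h0, h1))),
                           "father": f"{hom}/{hom}"})
        m0[pos] = h0
        site_info.append(("maternal", pos, ref, alt, h0, h1, hom))
    for pos, ref, alt, h0, h1, hom in paternal_sites:
        panel_rows.append({**_snp_row(chrom, pos, ref, alt),
                           "mother": f"{hom}/{hom}",
                           "father": "/".join(sorted((h0, h1)))})
        f0[pos] = h0
        site_info.append(("paternal", pos, ref, alt, h0, h1, hom))
    parents = pd.DataFrame(panel_rows).sort_values("pos").reset_index(drop=True)

    observations = []
    expected_status = {}
    for emb in embryos:
        dose = int(emb in maternal_h0) + int(emb in paternal_h0)
        expected_status[emb] = {0: "noncarrier", 1: "carrier",
                                2: "affected"}[dose]
        rows = []
        for side, pos, ref, alt, h0, h1, hom in site_info:
            inherited_h0 = emb in (maternal_h0 if side == "maternal"
                                   else paternal_h0)
            het_allele = h0 if inherited_h0 else h1
            alleles = (het_allele, hom)
            if locus.kind == "large_deletion" and locus.region.contains(pos):
                alleles = ()  # markers inside the deletion vanish with it
            rd, ad = _depths_for(alleles, ref, alt, depth)
            rows.append({**_snp_row(chrom, pos, ref, alt),
                         "ref_depth": rd, "alt_depth": ad})
        snps = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)

        probe_rows = []
        if locus.kind == "large_deletion":
            copies = 2 - dose
            region_depth = depth * copies / 2 if copies else 1
            for p in np.linspace(locus.region.start, locus.region.end, 8):
                probe_rows.append((chrom, int(p), "region",
                                   int(region_depth), 0))
        else:
            rd = int(depth / 2 * (2 - dose))
            ad = int(depth / 2 * dose)
            probe_rows.append((chrom, locus.site_pos, "site", rd, ad))
        for flank in locus.flank_regions:
            for p in np.linspace(flank.start, flank.end, 5):
                probe_rows.append((chrom, int(p), "flank", int(depth), 0))
        probes = pd.DataFrame(probe_rows, columns=[
            "chrom", "pos", "kind", "ref_depth", "alt_depth"])
        observations.append(EmbryoObservation(emb, snps, probes))

    affected = {e for e in embryos
                if e in maternal_h0 and e in paternal_h0}
    return WorkedFamily(parents, observations, locus, maternal_h0,
                        paternal_h0, affected, expected_status, m0, f0)


@pytest.fixture
def family13() -> WorkedFamily:
    """Alpha-thalassemia family: 9 embryos, SEA deletion.

    Includes the two published marker examples: the mother heterozygous
    A/C against a homozygous A/A father at position 119,006 (disease
    allele A), and the father heterozygous C/T against a homozygous C/C
    mother at position 207,611 (disease allele C).
    """
    maternal = [
        (119_006, "A", "C", "A", "C", "A"),   # the published maternal marker
        (150_000, "G", "T", "T", "G", "G"),
        (155_000, "C", "G", "G", "C", "C"),
        (300_000, "A", "G", "G", "A", "A"),
        (350_000, "C", "T", "C", "T", "T"),
    ]
    paternal = [
        (207_611, "C", "T", "C", "T", "C"),   # the published paternal marker
        (160_000, "A", "T", "A", "T", "T"),
        (310_000, "C", "G", "G", "C", "C"),
        (360_000, "A", "G", "A", "G", "G"),
    ]
    return build_worked_family(
        sea_deletion(), maternal, paternal,
        maternal_h0={"E1", "E5", "E7"},
        paternal_h0={"E2", "E3", "E4", "E5", "E7"},
        embryos=[f"E{i}" for i in range(1, 10)])


@pytest.fixture
def family30() -> WorkedFamily:
    """Beta-thalassemia family: 6 embryos, CD41-42 (-AAAG) indel."""
    maternal = [
        (5_100_000, "A", "C", "A", "C", "C"),
        (5_200_000, "G", "T", "T", "G", "G"),
        (5_300_000, "A", "G", "G", "A", "A"),
        (5_400_000, "C", "T", "C", "T", "T"),
    ]
    paternal = [
        (5_120_000, "C", "T", "C", "T", "C"),
        (5_220_000, "A", "T", "A", "T", "T"),
        (5_320_000, "C", "G", "G", "C", "C"),
        (5_420_000, "A", "G", "A", "G", "G"),
    ]
    return build_worked_family(
        hbb_cd41_42(), maternal, paternal,
        maternal_h0={"E1", "E4", "E5", "E6"},
        paternal_h0={"E2", "E4", "E6"},
        embryos=[f"E{i}" for i in range(1, 7)])


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-family Mendelian cohort (8 embryos each) with a small panel.

    Shared across tests that only need transmission statistics, so the
    expensive full-size panels are not regenerated repeatedly.
    """
    from pgtphase import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_families=400, embryos_per_family=8, n_snps_upstream=10,
        n_snps_downstream=10, n_fragments=5_000, aneuploidy_rate=0.0,
        seed=123)
    return simulate_cohort(cfg)
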