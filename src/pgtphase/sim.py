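"""Synthetic IVF-cohort simulator.

Generates families of two thalassemia-carrier parents plus N biopsied
embryos, with full ground truth, so the phasing/genotyping pipeline can be
exercised and validated without patient data. The generative model:

* A biallelic SNP panel flanking the disease locus (default 138 markers
  within 1 Mb upstream and 132 within 2 Mb downstream for the alpha locus).
* Each parent carries exactly one disease allele; by construction parental
  haplotype 0 is the disease-linked one (the M0/F0 convention).
* Embryos inherit one haplotype per side by Mendelian transmission, with
  crossovers as a Poisson process along the marker map.
* Whole-genome amplification artifacts: each site fails entirely with
  probability 1 - amplification_rate (default 0.9471 amplified), and each
  heterozygous site loses one allele (ADO) with probability ado_rate
  (default 0.0426).
* Read depth: Poisson(mean_depth / 2) per amplified haplotype copy, so a
  clean heterozygote shows two ~mean_depth/2 allele columns and a
  homozygote one ~mean_depth column. Sites inside a homozygous deletion
  amplify only at a background level, Poisson(0.02 * mean_depth).
* Aneuploidy: whole-chromosome gains/losses and mosaics, expressed in the
  binned read-count profile used for CNV screening (about 1.5 million
  fragments per biopsy).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loci import AUTOSOMES, DISEASE_LOCI, HG19_CHROM_LENGTHS, MutationLocus

_BACKGROUND_DEPTH_FRAC = 0.02  # residual WGA signal inside a homozygous deletion

_ALLELES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the study conditions: 36 families, alpha-thalassemia
    SEA panel sizes and windows, amplification rate 94.71%, ADO rate 4.26%,
    mean depth 100X, recombination ~1 cM/Mb.
    """

    n_families: int = 36
    embryos_per_family: int | tuple[int, int] = 6
    disease: str = "alpha_SEA"
    n_snps_upstream: int = 138
    n_snps_downstream: int = 132
    n_snps_intragenic: int = 0
    window_upstream_bp: int = 1_000_000
    window_downstream_bp: int = 2_000_000
    ado_rate: float = 0.0426
    amplification_rate: float = 0.9471
    mean_depth: float = 100.0
    recombination_rate: float = 1e-8
    aneuploidy_rate: float = 0.30
    mosaic_rate: float = 0.35
    mosaic_fraction_range: tuple[float, float] = (0.2, 0.8)
    allele_freq: float = 0.5
    n_fragments: int = 1_500_000
    bin_size_bp: int = 1_000_000
    min_affected_per_family: int = 0
    min_informative_per_quadrant: int = 0
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first offending field."""
        for name in ("ado_rate", "amplification_rate", "recombination_rate",
                     "aneuploidy_rate", "mosaic_rate", "allele_freq"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.window_upstream_bp <= 0:
            raise ValueError(
                f"window_upstream_bp must be > 0, got {self.window_upstream_bp}")
        if self.window_downstream_bp <= 0:
            raise ValueError(
                f"window_downstream_bp must be > 0, got {self.window_downstream_bp}")
        lo, hi = self.mosaic_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"mosaic_fraction_range must be an ordered subinterval of [0, 1], "
                f"got {self.mosaic_fraction_range}")
        if self.disease not in DISEASE_LOCI:
            raise ValueError(
                f"disease must be one of {sorted(DISEASE_LOCI)}, got {self.disease!r}")
        for name in ("n_families", "n_snps_upstream", "n_snps_downstream",
                     "n_snps_intragenic", "n_fragments", "bin_size_bp"):
            value = getattr(self, name)
            if value < 0 or (name in ("n_families", "n_fragments", "bin_size_bp")
                             and value == 0):
                raise ValueError(f"{name} must be positive, got {value}")
        emb = self.embryos_per_family
        if isinstance(emb, int):
            if emb <= 0:
                raise ValueError(f"embryos_per_family must be > 0, got {emb}")
        else:
            lo, hi = emb
            if not (0 < lo <= hi):
                raise ValueError(
                    f"embryos_per_family range must satisfy 0 < lo <= hi, got {emb}")

    def locus(self) -> MutationLocus:
        return DISEASE_LOCI[self.disease]()


def beta_preset(**overrides) -> SimConfig:
    """Config preset for the beta locus: 85 markers within 1 Mb either side.

    A wider preset (95 markers within 2 Mb) is available via
    ``beta_preset(n_snps_upstream=48, n_snps_downstream=47,
    window_upstream_bp=2_000_000, window_downstream_bp=2_000_000)``.
    """
    base = dict(
        disease="beta_CD41_42",
        n_snps_upstream=43,
        n_snps_downstream=42,
        window_upstream_bp=1_000_000,
        window_downstream_bp=1_000_000,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class Karyotype:
    """Whole-chromosome copy state of one embryo biopsy."""

    chrom: str | None = None      # None => euploid
    copies: int = 2               # 1 (monosomy) or 3 (trisomy) when aberrant
    mosaic_fraction: float | None = None  # None => whole-chromosome event

    @property
    def status(self) -> str:
        if self.chrom is None:
            return "euploid"
        kind = "trisomy" if self.copies == 3 else "monosomy"
        if self.mosaic_fraction is not None:
            return f"mosaic_{kind}"
        return kind

    @property
    def mean_copies(self) -> dict[str, float]:
        """Expected copy number per affected chromosome."""
        if self.chrom is None:
            return {}
        if self.mosaic_fraction is None:
            return {self.chrom: float(self.copies)}
        f = self.mosaic_fraction
        return {self.chrom: 2.0 * (1 - f) + self.copies * f}


@dataclass
class EmbryoTruth:
    embryo: str
    maternal_hap: np.ndarray      # 0/1 transmitted maternal haplotype per panel site
    paternal_hap: np.ndarray
    maternal_at_locus: int        # transmitted maternal haplotype at the mutation
    paternal_at_locus: int
    mutation_genotype: int        # number of disease alleles, 0/1/2
    karyotype: Karyotype
    crossovers: list[tuple[str, int]]  # (side, 1-based position after which the switch occurs)


@dataclass
class TruthRecord:
    """Ground truth for one simulated family."""

    family: str
    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    parent_haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]  # side -> (hap0, hap1)
    embryos: list[EmbryoTruth]

    def true_genotype(self, embryo_idx: int) -> list[tuple[str, str]]:
        """Per-site (maternal allele, paternal allele) of one embryo."""
        emb = self.embryos[embryo_idx]
        m0, m1 = self.parent_haplotypes["mother"]
        f0, f1 = self.parent_haplotypes["father"]
        mat = np.where(emb.maternal_hap == 0, m0, m1)
        pat = np.where(emb.paternal_hap == 0, f0, f1)
        return list(zip(mat.tolist(), pat.tolist()))

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(f"not serializable: {type(obj)}")
        return json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)


# ---------------------------------------------------------------------------
# observation containers
# ---------------------------------------------------------------------------

@dataclass
class EmbryoObservation:
    """What sequencing sees for one embryo biopsy.

    ``snps`` holds allele-specific read depths over the SNP panel
    (chrom, pos, ref, alt, ref_depth, alt_depth). ``locus_probes`` holds the
    depth profile over the mutation region and its flanks (column ``kind``
    is ``region``, ``flank`` or ``site``; ``site`` rows carry the
    allele-specific counts of a small indel).
    """

    embryo: str
    snps: pd.DataFrame
    locus_probes: pd.DataFrame
    wga_status: np.ndarray | None = None  # per-site 'ok' | 'ado' | 'failed' (truth annotation)

    def observed_alleles(self, idx: int) -> tuple[str, ...]:
        """Alleles with nonzero depth at panel row ``idx``."""
        row = self.snps.iloc[idx]
        out = []
        if row.ref_depth > 0:
            out.append(row.ref)
        if row.alt_depth > 0:
            out.append(row.alt)
        return tuple(out)

    def median_panel_depth(self) -> float:
        """Median total depth over amplified panel sites (full-copy reference)."""
        total = (self.snps["ref_depth"] + self.snps["alt_depth"]).to_numpy()
        amplified = total[total > 0]
        if amplified.size == 0:
            return 0.0
        return float(np.median(amplified))


# ---------------------------------------------------------------------------
# WGA artifact model
# ---------------------------------------------------------------------------

def apply_wga(
    true_genotypes: list[tuple[str, str]],
    ado_rate: float,
    amplification_rate: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, ...]], np.ndarray]:
    """Apply amplification failure and allele dropout to true genotypes.

    Each site fails entirely with probability ``1 - amplification_rate``;
    each heterozygous amplified site loses one allele (chosen with equal
    probability) with probability ``ado_rate``. Homozygous sites cannot
    exhibit detectable dropout.

    Returns the observed allele tuple per site (empty tuple for a failed
    site) and a per-site status annotation (``ok``/``ado``/``failed``)
    retained as ground truth for estimator validation.
    """
    if not 0.0 <= ado_rate <= 1.0:
        raise ValueError(f"ado_rate must be in [0, 1], got {ado_rate}")
    if not 0.0 <= amplification_rate <= 1.0:
        raise ValueError(
            f"amplification_rate must be in [0, 1], got {amplification_rate}")
    n = len(true_genotypes)
    failed = rng.random(n) >= amplification_rate
    ado_draw = rng.random(n) < ado_rate
    which = rng.integers(0, 2, size=n)
    observed: list[tuple[str, ...]] = []
    status = np.full(n, "ok", dtype=object)
    for i, (a, b) in enumerate(true_genotypes):
        if failed[i]:
            observed.append(())
            status[i] = "failed"
            continue
        if a != b and ado_draw[i]:
            kept = a if which[i] == 0 else b
            observed.append((kept,))
            status[i] = "ado"
        else:
            observed.append((a, b) if a != b else (a, a))
    return observed, status


def simulate_depths(
    observed_genotypes: list[tuple[str, ...]],
    mutation_genotype: int,
    mean_depth: float,
    rng: np.random.Generator,
    *,
    locus: MutationLocus,
    panel: pd.DataFrame,
    embryo: str = "E1",
    wga_status: np.ndarray | None = None,
    ado_rate: float = 0.0,
    amplification_rate: float = 1.0,
    maternal_hap: np.ndarray | None = None,
    paternal_hap: np.ndarray | None = None,
    true_genotypes: list[tuple[str, str]] | None = None,
) -> EmbryoObservation:
    """Draw allele-specific read depths for one embryo.

    Depth is Poisson(mean_depth/2) per amplified haplotype copy. Panel
    sites inside a large deletion lose the copies carried on deleted
    haplotypes; with zero remaining copies only background noise
    (Poisson(0.02 * mean_depth)) is emitted. The mutation locus itself is
    observed through dedicated probes: total depth over the deleted
    interval and its flanks for a large deletion, or allele-specific
    counts at the mutation site for a small indel.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be > 0, got {mean_depth}")
    n = len(panel)
    ref = panel["ref"].to_numpy()
    alt = panel["alt"].to_numpy()
    pos = panel["pos"].to_numpy()
    ref_depth = np.zeros(n, dtype=int)
    alt_depth = np.zeros(n, dtype=int)

    in_region = (panel["chrom"].to_numpy() == locus.region.chrom) & (
        pos >= locus.region.start) & (pos <= locus.region.end)
    deletion = locus.kind == "large_deletion"

    for i, alleles in enumerate(observed_genotypes):
        if deletion and in_region[i]:
            # intra-deletion markers: copies on deleted (haplotype 0) sides
            # are physically absent, so only the non-deleted transmissions
            # amplify; with none left, emit WGA background only.
            surviving: list[str] = []
            if (maternal_hap is not None and paternal_hap is not None
                    and true_genotypes is not None):
                if maternal_hap[i] != 0:
                    surviving.append(true_genotypes[i][0])
                if paternal_hap[i] != 0:
                    surviving.append(true_genotypes[i][1])
            else:
                surviving = list(alleles)[: max(0, 2 - mutation_genotype)]
            if not surviving:
                ref_depth[i] = rng.poisson(_BACKGROUND_DEPTH_FRAC * mean_depth)
                continue
            for allele in surviving:
                if rng.random() >= amplification_rate:
                    continue
                d = rng.poisson(mean_depth / 2.0)
                if allele == ref[i]:
                    ref_depth[i] += d
                elif allele == alt[i]:
                    alt_depth[i] += d
            continue
        for allele in alleles:
            d = rng.poisson(mean_depth / 2.0)
            if allele == ref[i]:
                ref_depth[i] += d
            elif allele == alt[i]:
                alt_depth[i] += d
    snps = panel[["chrom", "pos", "ref", "alt"]].copy()
    snps["sample"] = embryo
    snps["ref_depth"] = ref_depth
    snps["alt_depth"] = alt_depth

    probes = _locus_probes(
        locus, mutation_genotype, mean_depth, rng,
        ado_rate=ado_rate, amplification_rate=amplification_rate)
    return EmbryoObservation(
        embryo=embryo, snps=snps, locus_probes=probes, wga_status=wga_status)


def _locus_probes(
    locus: MutationLocus,
    mutation_genotype: int,
    mean_depth: float,
    rng: np.random.Generator,
    *,
    n_region: int = 12,
    n_flank: int = 8,
    ado_rate: float = 0.0,
    amplification_rate: float = 1.0,
) -> pd.DataFrame:
    rows = []
    g = mutation_genotype
    if locus.kind == "large_deletion":
        copies = 2 - g
        region_pos = np.linspace(
            locus.region.start, locus.region.end, n_region).astype(int)
        for p in region_pos:
            if rng.random() >= amplification_rate:
                depth = 0
            elif copies == 0:
                depth = int(rng.poisson(_BACKGROUND_DEPTH_FRAC * mean_depth))
            else:
                depth = int(rng.poisson(mean_depth * copies / 2.0))
            rows.append((locus.region.chrom, int(p), "region", depth, 0))
    else:
        # allele-specific counts at the indel site, subject to ADO when het
        ref_copies, alt_copies = 2 - g, g
        if g == 1 and rng.random() < ado_rate:
            if rng.integers(0, 2) == 0:
                ref_copies = 0
            else:
                alt_copies = 0
        if rng.random() >= amplification_rate:
            ref_copies = alt_copies = 0
        rd = int(rng.poisson(mean_depth * ref_copies / 2.0))
        ad = int(rng.poisson(mean_depth * alt_copies / 2.0))
        rows.append((locus.region.chrom, int(locus.site_pos), "site", rd, ad))
    for flank in locus.flank_regions:
        flank_pos = np.linspace(flank.start, flank.end, n_flank).astype(int)
        for p in flank_pos:
            if rng.random() >= amplification_rate:
                depth = 0
            else:
                depth = int(rng.poisson(mean_depth))
            rows.append((flank.chrom, int(p), "flank", depth, 0))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "kind", "ref_depth", "alt_depth"])


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

@dataclass
class FamilyData:
    """One simulated family: ground truth, parental table, observations."""

    family: str
    locus: MutationLocus
    truth: TruthRecord
    parents: pd.DataFrame         # chrom, pos, ref, alt, mother, father
    observations: list[EmbryoObservation]
    cnv_profiles: dict[str, pd.DataFrame] = field(default_factory=dict)


def _draw_panel(config: SimConfig, locus: MutationLocus,
                rng: np.random.Generator) -> pd.DataFrame:
    """Draw SNP positions uniformly within the configured windows."""
    region = locus.region
    lo_up = max(1, region.start - config.window_upstream_bp)
    pools = [
        (lo_up, region.start - 1, config.n_snps_upstream),
        (region.end + 1, region.end + config.window_downstream_bp,
         config.n_snps_downstream),
        (region.start, region.end, config.n_snps_intragenic),
    ]
    positions: list[int] = []
    for lo, hi, n in pools:
        if n == 0:
            continue
        pos = rng.choice(np.arange(lo, hi + 1), size=n, replace=False)
        positions.extend(int(p) for p in pos)
    positions = sorted(set(positions))
    n = len(positions)
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    ref = _ALLELES[ref_idx]
    alt = _ALLELES[(ref_idx + alt_shift) % 4]
    return pd.DataFrame({
        "chrom": region.chrom, "pos": positions, "ref": ref, "alt": alt})


def _draw_parent_haplotypes(
    panel: pd.DataFrame, allele_freq: float, rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    n = len(panel)
    ref = panel["ref"].to_numpy()
    alt = panel["alt"].to_numpy()
    out = {}
    for side in ("mother", "father"):
        haps = []
        for _ in range(2):
            take_alt = rng.random(n) < allele_freq
            haps.append(np.where(take_alt, alt, ref))
        out[side] = (haps[0], haps[1])
    return out


def _informative_quadrant_counts(
    panel: pd.DataFrame,
    parent_haps: dict[str, tuple[np.ndarray, np.ndarray]],
    locus: MutationLocus,
) -> dict[tuple[str, str], int]:
    counts = {(s, l): 0 for s in ("maternal", "paternal")
              for l in ("upstream", "downstream")}
    m_het = parent_haps["mother"][0] != parent_haps["mother"][1]
    f_het = parent_haps["father"][0] != parent_haps["father"][1]
    pos = panel["pos"].to_numpy()
    for i in range(len(panel)):
        loc = locus.location_of(int(pos[i]))
        if loc == "intragenic":
            continue
        if m_het[i] and not f_het[i]:
            counts[("maternal", loc)] += 1
        elif f_het[i] and not m_het[i]:
            counts[("paternal", loc)] += 1
    return counts


def _transmit(
    positions: np.ndarray,
    anchor_pos: int,
    recombination_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, list[int]]:
    """Walk along the marker map, switching haplotypes at crossovers.

    Returns the haplotype label per site, the label at the locus anchor,
    and the positions after which a switch occurred.
    """
    walk_pos = np.concatenate([positions, [anchor_pos]])
    walk_order = np.argsort(walk_pos, kind="stable")
    hap = int(rng.integers(0, 2))
    labels = np.empty(len(walk_pos), dtype=int)
    crossovers: list[int] = []
    prev = None
    for idx in walk_order:
        p = walk_pos[idx]
        if prev is not None:
            d = p - prev
            if d > 0 and rng.random() < -np.expm1(-recombination_rate * d):
                hap = 1 - hap
                crossovers.append(int(prev))
        labels[idx] = hap
        prev = p
    return labels[:-1], int(labels[-1]), crossovers


def simulate_family(
    config: SimConfig,
    family_id: str,
    rng: np.random.Generator | None = None,
) -> FamilyData:
    """Simulate one carrier x carrier family with biopsied embryos.

    Both parents carry exactly one disease allele, phase-linked to their
    haplotype 0 (the M0/F0 convention). Embryo observations are produced
    by :func:`apply_wga` followed by :func:`simulate_depths`.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    locus = config.locus()

    panel = _draw_panel(config, locus, rng)
    parent_haps = _draw_parent_haplotypes(panel, config.allele_freq, rng)
    if config.min_informative_per_quadrant > 0:
        for _ in range(1000):
            counts = _informative_quadrant_counts(panel, parent_haps, locus)
            if min(counts.values()) >= config.min_informative_per_quadrant:
                break
            parent_haps = _draw_parent_haplotypes(panel, config.allele_freq, rng)
        else:  # pragma: no cover - panel too small for the requested floor
            raise RuntimeError(
                "could not draw parental genotypes meeting "
                f"min_informative_per_quadrant={config.min_informative_per_quadrant}")

    emb_spec = config.embryos_per_family
    if isinstance(emb_spec, int):
        n_embryos = emb_spec
    else:
        n_embryos = int(rng.integers(emb_spec[0], emb_spec[1] + 1))

    anchor = (locus.region.start + locus.region.end) // 2
    positions = panel["pos"].to_numpy()

    def draw_embryos() -> list[EmbryoTruth]:
        embryos = []
        for j in range(n_embryos):
            mat, mat_locus, mat_x = _transmit(
                positions, anchor, config.recombination_rate, rng)
            pat, pat_locus, pat_x = _transmit(
                positions, anchor, config.recombination_rate, rng)
            g = int(mat_locus == 0) + int(pat_locus == 0)
            kary = _draw_karyotype(config, rng)
            embryos.append(EmbryoTruth(
                embryo=f"E{j + 1}",
                maternal_hap=mat, paternal_hap=pat,
                maternal_at_locus=mat_locus, paternal_at_locus=pat_locus,
                mutation_genotype=g, karyotype=kary,
                crossovers=[("maternal", p) for p in mat_x]
                + [("paternal", p) for p in pat_x]))
        return embryos

    embryos = draw_embryos()
    if config.min_affected_per_family > 0:
        for _ in range(10_000):
            n_aff = sum(e.mutation_genotype == 2 for e in embryos)
            if n_aff >= config.min_affected_per_family:
                break
            embryos = draw_embryos()
        else:  # pragma: no cover
            raise RuntimeError("could not satisfy min_affected_per_family")

    truth = TruthRecord(
        family=family_id, chrom=locus.region.chrom,
        positions=positions, ref=panel["ref"].to_numpy(),
        alt=panel["alt"].to_numpy(),
        parent_haplotypes=parent_haps, embryos=embryos)

    parents = panel.copy()
    for side in ("mother", "father"):
        h0, h1 = parent_haps[side]
        parents[side] = ["/".join(sorted((a, b))) for a, b in zip(h0, h1)]

    observations = []
    cnv_profiles = {}
    for j, emb in enumerate(embryos):
        true_gt = truth.true_genotype(j)
        observed, status = apply_wga(
            true_gt, config.ado_rate, config.amplification_rate, rng)
        obs = simulate_depths(
            observed, emb.mutation_genotype, config.mean_depth, rng,
            locus=locus, panel=panel, embryo=emb.embryo, wga_status=status,
            ado_rate=config.ado_rate,
            amplification_rate=config.amplification_rate,
            maternal_hap=emb.maternal_hap, paternal_hap=emb.paternal_hap,
            true_genotypes=true_gt)
        observations.append(obs)
        cnv_profiles[emb.embryo] = simulate_cnv_profile(
            emb.karyotype, config.n_fragments, config.bin_size_bp, rng)

    return FamilyData(
        family=family_id, locus=locus, truth=truth, parents=parents,
        observations=observations, cnv_profiles=cnv_profiles)


def _draw_karyotype(config: SimConfig, rng: np.random.Generator) -> Karyotype:
    if rng.random() >= config.aneuploidy_rate:
        return Karyotype()
    chrom = AUTOSOMES[int(rng.integers(0, len(AUTOSOMES)))]
    copies = 3 if rng.random() < 0.5 else 1
    if rng.random() < config.mosaic_rate:
        lo, hi = config.mosaic_fraction_range
        frac = float(rng.uniform(lo, hi))
        return Karyotype(chrom=chrom, copies=copies, mosaic_fraction=frac)
    return Karyotype(chrom=chrom, copies=copies)


def simulate_cohort(config: SimConfig) -> list[FamilyData]:
    """Simulate ``config.n_families`` families with independent seeded RNGs.

    Child RNGs are spawned from ``config.seed`` so the cohort is
    byte-identical for a fixed seed regardless of how many families are
    consumed downstream.
    """
    config.validate()
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_families)
    return [
        simulate_family(config, f"F{i + 1}", np.random.default_rng(children[i]))
        for i in range(config.n_families)
    ]


# ---------------------------------------------------------------------------
# CNV profile simulation
# ---------------------------------------------------------------------------

def genome_bins(bin_size: int = 1_000_000) -> pd.DataFrame:
    """Fixed hg19 1-based bin coordinates (chrom, start, end, length)."""
    rows = []
    for chrom, length in HG19_CHROM_LENGTHS.items():
        start = 1
        while start <= length:
            end = min(start + bin_size - 1, length)
            rows.append((chrom, start, end, end - start + 1))
            start = end + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])


def simulate_cnv_profile(
    karyotype: Karyotype,
    n_fragments: int,
    bin_size: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Allocate sequencing fragments to genome bins by multinomial sampling.

    Bin weights are proportional to bin length times copy state / 2; a
    mosaic chromosome contributes the mixture expectation
    2(1 - f) + copies * f.
    """
    if n_fragments <= 0:
        raise ValueError(f"n_fragments must be > 0, got {n_fragments}")
    bins = genome_bins(bin_size)
    copy = np.full(len(bins), 2.0)
    for chrom, mean_copies in karyotype.mean_copies.items():
        copy[bins["chrom"] == chrom] = mean_copies
    weights = bins["length"].to_numpy() * copy / 2.0
    p = weights / weights.sum()
    counts = rng.multinomial(n_fragments, p)
    out = bins[["chrom", "start", "end"]].copy()
    out["count"] = counts
    return out


def euploid_reference(n_fragments: int = 1_500_000,
                      bin_size: int = 1_000_000) -> pd.DataFrame:
    """Noise-free expected euploid profile (the normalization reference)."""
    bins = genome_bins(bin_size)
    weights = bins["length"].to_numpy().astype(float)
    out = bins[["chrom", "start", "end"]].copy()
    out["count"] = weights / weights.sum() * n_fragments
    return out
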