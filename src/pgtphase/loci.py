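"""Disease-locus definitions and hg19 reference constants.

The two thalassemia loci handled by this package are the Southeast-Asian
(--SEA) deletion removing both alpha-globin genes (HBA1/HBA2) on chr16, and
the 4-bp frameshift deletion in HBB codons 41-42 (CD41-42, -AAAG) on chr11.
Coordinates are 1-based inclusive on hg19.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: hg19 chromosome lengths (bp), used for CNV binning.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class MutationLocus:
    """A disease mutation assayed directly, plus flanks for depth baselines.

    Parameters
    ----------
    name
        Human-readable mutation name (e.g. ``"SEA"``, ``"CD41-42delAAAG"``).
    kind
        ``"large_deletion"`` (genotyped by read-depth collapse over the
        deleted interval) or ``"small_indel"`` (genotyped by allele-specific
        read counts at the mutation site).
    region
        The deleted interval (large deletion) or the gene interval holding
        the mutation (small indel).
    flank_regions
        Two intervals outside ``region`` used as the amplification-depth
        baseline for depth-ratio genotyping.
    site_pos
        For small indels, the mutation's base position inside ``region``.
    """

    name: str
    kind: str
    region: Region
    flank_regions: tuple[Region, Region]
    site_pos: int | None = None
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self) -> None:
        if self.kind not in ("large_deletion", "small_indel"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        for flank in self.flank_regions:
            if flank.chrom != self.region.chrom:
                raise ValueError("flank on a different contig than the region")
            if flank.start <= self.region.end and flank.end >= self.region.start:
                raise ValueError("flank overlaps the mutation region")
        if self.kind == "small_indel" and self.site_pos is None:
            raise ValueError("small_indel locus requires site_pos")

    def location_of(self, pos: int) -> str:
        """Classify a coordinate as upstream/intragenic/downstream.

        Upstream means lower hg19 coordinate than the region start on the
        forward strand; downstream means higher than the region end.
        """
        if pos < self.region.start:
            return "upstream"
        if pos > self.region.end:
            return "downstream"
        return "intragenic"


def sea_deletion() -> MutationLocus:
    """The --SEA alpha-globin deletion, chr16:215,400-234,700 (hg19)."""
    region = Region("chr16", 215_400, 234_700)
    flanks = (
        Region("chr16", 165_400, 215_399),
        Region("chr16", 234_701, 284_700),
    )
    return MutationLocus(
        name="SEA", kind="large_deletion", region=region, flank_regions=flanks
    )


def hbb_cd41_42() -> MutationLocus:
    """The HBB CD41-42 (-AAAG) deletion inside chr11:5,246,696-5,248,301.

    The 4-bp deletion is represented at a fixed position inside the HBB
    gene interval; linkage and depth logic depend only on the position
    lying inside the gene region.
    """
    region = Region("chr11", 5_246_696, 5_248_301)
    flanks = (
        Region("chr11", 5_196_696, 5_246_695),
        Region("chr11", 5_248_302, 5_298_301),
    )
    return MutationLocus(
        name="CD41-42delAAAG",
        kind="small_indel",
        region=region,
        flank_regions=flanks,
        site_pos=5_248_000,
        ref_allele="CAAAG",
        alt_allele="C",
    )


#: Disease presets keyed by the simulator's ``disease`` enum.
DISEASE_LOCI = {
    "alpha_SEA": sea_deletion,
    "beta_CD41_42": hbb_cd41_42,
}
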