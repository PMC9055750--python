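"""On-disk formats: parental VCF, embryo depth TSVs, BED regions, truth JSON.

All TSVs carry a versioned ``# pgtphase-format`` header line. Parental
genotypes are exchanged as a two-sample VCF (GT only, hg19 contigs);
embryo observations as a long-format allele-depth table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .loci import HG19_CHROM_LENGTHS, MutationLocus
from .sim import EmbryoObservation, FamilyData

FORMAT_HEADER = "# pgtphase-format v1"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_parental_vcf(parents: pd.DataFrame, path: str | Path) -> None:
    """Write the two-sample (MOTHER, FATHER) parental genotype VCF."""
    path = Path(path)
    chroms = parents["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgtphase\n")
        fh.write("##reference=hg19\n")
        for c in chroms:
            length = HG19_CHROM_LENGTHS.get(c, 0)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "MOTHER\tFATHER\n")
        for row in parents.sort_values("pos").itertuples(index=False):
            alleles = {row.ref: "0", row.alt: "1"}

            def gt(s: str) -> str:
                return "/".join(sorted(alleles.get(a, ".") for a in s.split("/")))

            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t"
                     f"PASS\t.\tGT\t{gt(row.mother)}\t{gt(row.father)}\n")


def read_parental_vcf(path: str | Path) -> pd.DataFrame:
    """Read a two-sample parental VCF back into the genotype table."""
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parental VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise ValueError(
            f"expected two samples (mother, father) in {path}, got {samples}")
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        alleles = [var.REF, var.ALT[0]]

        def decode(gt_idx) -> str:
            a = [alleles[i] if i is not None and i >= 0 else "." for i in gt_idx[:2]]
            return "/".join(sorted(a))

        gts = var.genotypes  # [[a0, a1, phased], ...]
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     decode(gts[0]), decode(gts[1])))
    vcf.close()
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "mother", "father"])


# ---------------------------------------------------------------------------
# embryo observations
# ---------------------------------------------------------------------------

def write_embryo_observations(
    observations: list[EmbryoObservation], snp_path: str | Path,
    probe_path: str | Path,
) -> None:
    """Write SNP allele depths and locus depth probes for all embryos."""
    snp_frames = []
    probe_frames = []
    for obs in observations:
        df = obs.snps.copy()
        df["sample"] = obs.embryo
        snp_frames.append(df[["chrom", "pos", "ref", "alt", "sample",
                              "ref_depth", "alt_depth"]])
        p = obs.locus_probes.copy()
        p["sample"] = obs.embryo
        probe_frames.append(p[["chrom", "pos", "kind", "sample",
                               "ref_depth", "alt_depth"]])
    for frames, path in ((snp_frames, snp_path), (probe_frames, probe_path)):
        with open(path, "w") as fh:
            fh.write(FORMAT_HEADER + "\n")
            pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_embryo_observations(
    snp_path: str | Path, probe_path: str | Path,
) -> list[EmbryoObservation]:
    snps = pd.read_csv(snp_path, sep="\t", comment="#")
    probes = pd.read_csv(probe_path, sep="\t", comment="#")
    out = []
    for sample, grp in snps.groupby("sample", sort=True):
        p = probes[probes["sample"] == sample]
        out.append(EmbryoObservation(
            embryo=str(sample),
            snps=grp.drop(columns=["sample"]).reset_index(drop=True),
            locus_probes=p.drop(columns=["sample"]).reset_index(drop=True)))
    return out


# ---------------------------------------------------------------------------
# regions, truth, CNV
# ---------------------------------------------------------------------------

def write_locus_bed(locus: MutationLocus, path: str | Path,
                    sidecar_path: str | Path | None = None) -> None:
    """Mutation and flank regions as 0-based half-open BED.

    When ``sidecar_path`` is given, the non-positional attributes (assay
    kind, indel site and alleles) are written alongside as JSON so the
    locus can be reconstructed with :func:`read_locus_bed`.
    """
    with open(path, "w") as fh:
        region = locus.region
        fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\t"
                 f"{locus.name}\n")
        for i, flank in enumerate(locus.flank_regions):
            fh.write(f"{flank.chrom}\t{flank.start - 1}\t{flank.end}\t"
                     f"{locus.name}_flank{i + 1}\n")
    if sidecar_path is not None:
        write_json({
            "name": locus.name, "kind": locus.kind,
            "site_pos": locus.site_pos, "ref_allele": locus.ref_allele,
            "alt_allele": locus.alt_allele}, sidecar_path)


def read_locus_bed(path: str | Path, sidecar_path: str | Path) -> MutationLocus:
    """Reconstruct a :class:`MutationLocus` from BED + JSON sidecar.

    The BED must hold the mutation region (named as in the sidecar) and
    its two flank regions (suffix ``_flank1``/``_flank2``); the sidecar
    carries the assay kind and, for small indels, the site and alleles.
    """
    from .loci import Region

    meta = json.loads(Path(sidecar_path).read_text())
    regions: dict[str, Region] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            regions[name] = Region(chrom, int(start) + 1, int(end))
    name = meta["name"]
    try:
        region = regions[name]
        flanks = (regions[f"{name}_flank1"], regions[f"{name}_flank2"])
    except KeyError as exc:
        raise ValueError(
            f"BED {path} lacks required interval {exc.args[0]!r}") from None
    return MutationLocus(
        name=name, kind=meta["kind"], region=region, flank_regions=flanks,
        site_pos=meta.get("site_pos"),
        ref_allele=meta.get("ref_allele", "N"),
        alt_allele=meta.get("alt_allele", "N"))


def write_cnv_counts(profiles: dict[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for embryo, df in sorted(profiles.items()):
        d = df.copy()
        d["sample"] = embryo
        frames.append(d)
    with open(path, "w") as fh:
        fh.write(FORMAT_HEADER + "\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_cnv_counts(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(s): g.drop(columns=["sample"]).reset_index(drop=True)
        for s, g in df.groupby("sample", sort=True)
    }


def write_family(family: FamilyData, out_dir: str | Path) -> None:
    """Write one simulated family's artifacts into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_parental_vcf(family.parents, out / "parents.vcf")
    write_embryo_observations(
        family.observations, out / "embryo_snps.tsv",
        out / "embryo_locus_probes.tsv")
    write_locus_bed(family.locus, out / "locus.bed", out / "locus.json")
    (out / "truth.json").write_text(family.truth.to_json() + "\n")
    if family.cnv_profiles:
        write_cnv_counts(family.cnv_profiles, out / "cnv_counts.tsv")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
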