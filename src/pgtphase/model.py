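"""Model/Results interface tying the pipeline stages together.

``PGTLinkage`` is built from one family's data (parental genotypes, embryo
observations, the disease locus) and ``fit()`` runs the full proband-free
workflow: informative-marker selection, direct mutation calls, affected-
embryo identification, haplotype phasing, linkage genotyping of every
sibling embryo, WGA artifact-rate estimation and (when binned read counts
are supplied) aneuploidy screening with transfer decisions. The returned
``PGTLinkageResults`` carries the estimates and diagnostics and renders a
clinic-style ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import calling, cnv as cnv_mod, informative, mutation, phasing, report
from .loci import MutationLocus
from .mutation import DeletionThresholds, IndelThresholds
from .calling import VoteThresholds
from .sim import EmbryoObservation, FamilyData, euploid_reference


class PGTLinkage:
    """Proband-free PGT-M model for one carrier x carrier family.

    Parameters
    ----------
    parents
        Genotype table (chrom, pos, ref, alt, mother, father) with
        genotypes as allele strings, e.g. ``"A/C"``.
    observations
        One :class:`~pgtphase.sim.EmbryoObservation` per biopsied embryo.
    locus
        The disease mutation being tested.
    cnv_counts
        Optional per-embryo binned read counts for aneuploidy screening.
    window_upstream_bp, window_downstream_bp
        Marker windows around the locus (``None`` = use every site).
    """

    def __init__(
        self,
        parents: pd.DataFrame,
        observations: list[EmbryoObservation],
        locus: MutationLocus,
        *,
        cnv_counts: dict[str, pd.DataFrame] | None = None,
        cnv_reference: pd.DataFrame | None = None,
        window_upstream_bp: int | None = None,
        window_downstream_bp: int | None = None,
        family: str = "family",
        min_cohort: int = 3,
        min_flank_resolved: int = 2,
        deletion_thresholds: DeletionThresholds | None = None,
        indel_thresholds: IndelThresholds | None = None,
        vote_thresholds: VoteThresholds | None = None,
        cnv_bands: cnv_mod.CNVBands | None = None,
        conflict_policy: str = "unanimous",
    ) -> None:
        self.parents = parents
        self.observations = observations
        self.locus = locus
        self.cnv_counts = cnv_counts or {}
        self.cnv_reference = cnv_reference
        self.window_upstream_bp = window_upstream_bp
        self.window_downstream_bp = window_downstream_bp
        self.family = family
        self.min_cohort = min_cohort
        self.min_flank_resolved = min_flank_resolved
        self.deletion_thresholds = deletion_thresholds
        self.indel_thresholds = indel_thresholds
        self.vote_thresholds = vote_thresholds or VoteThresholds()
        self.cnv_bands = cnv_bands
        self.conflict_policy = conflict_policy

    @classmethod
    def from_family(cls, family: FamilyData, **kwargs) -> "PGTLinkage":
        """Build the model from a simulated family."""
        kwargs.setdefault("family", family.family)
        kwargs.setdefault("cnv_counts", family.cnv_profiles)
        return cls(family.parents, family.observations, family.locus, **kwargs)

    @classmethod
    def from_files(
        cls, vcf_path, snp_tsv, probe_tsv, locus: MutationLocus, **kwargs,
    ) -> "PGTLinkage":
        from .io import read_embryo_observations, read_parental_vcf

        parents = read_parental_vcf(vcf_path)
        observations = read_embryo_observations(snp_tsv, probe_tsv)
        return cls(parents, observations, locus, **kwargs)

    def fit(self) -> "PGTLinkageResults":
        """Run selection → direct calls → phasing → linkage genotyping."""
        panel = informative.select_informative(
            self.parents, self.locus,
            self.window_upstream_bp, self.window_downstream_bp)
        direct = {
            obs.embryo: mutation.call_mutation(
                obs, self.locus, self.deletion_thresholds,
                self.indel_thresholds)
            for obs in self.observations
        }
        affected = mutation.identify_affected_embryos(direct)
        exclude_intragenic = self.locus.kind == "large_deletion"
        haplotypes = phasing.build_haplotypes(
            panel, affected, self.observations,
            min_cohort=self.min_cohort,
            min_flank_resolved=self.min_flank_resolved,
            exclude_intragenic=exclude_intragenic,
            ado_depth_frac=self.vote_thresholds.ado_depth_frac,
            conflict_policy=self.conflict_policy)
        calls = []
        for obs in self.observations:
            mat = calling.assign_side(
                obs, haplotypes, "maternal", self.locus, self.vote_thresholds)
            pat = calling.assign_side(
                obs, haplotypes, "paternal", self.locus, self.vote_thresholds)
            calls.append(calling.classify_embryo(mat, pat, direct[obs.embryo]))
        try:
            wga = calling.estimate_wga_metrics(
                self.observations, self.parents, self.locus)
        except ValueError:
            # panel may lack obligate-heterozygous markers; artifact rates
            # are then not estimable for this family
            wga = None

        cnv_profiles: dict[str, cnv_mod.CNVProfile] = {}
        transferable: dict[str, bool] = {}
        if self.cnv_counts:
            reference = self.cnv_reference
            if reference is None:
                any_profile = next(iter(self.cnv_counts.values()))
                reference = euploid_reference(
                    n_fragments=int(any_profile["count"].sum()) or 1,
                    bin_size=int(any_profile["end"].iloc[0]
                                 - any_profile["start"].iloc[0] + 1))
            for embryo, counts in self.cnv_counts.items():
                cnv_profiles[embryo] = cnv_mod.screen_embryo(
                    counts, reference, embryo, self.cnv_bands)
            transferable = report.decide_transferable(calls, cnv_profiles)

        return PGTLinkageResults(
            model=self, panel=panel, direct_calls=direct, affected=affected,
            haplotypes=haplotypes, calls=calls, wga_metrics=wga,
            cnv_profiles=cnv_profiles, transferable=transferable)


@dataclass
class PGTLinkageResults:
    """Fitted results: phased haplotypes, embryo calls, diagnostics."""

    model: PGTLinkage
    panel: list
    direct_calls: dict[str, mutation.DepthCall]
    affected: set[str]
    haplotypes: phasing.PhasedParentalHaplotypes
    calls: list[calling.EmbryoCall]
    wga_metrics: dict[str, float] | None
    cnv_profiles: dict[str, cnv_mod.CNVProfile] = field(default_factory=dict)
    transferable: dict[str, bool] = field(default_factory=dict)

    @property
    def calls_frame(self) -> pd.DataFrame:
        return calling.calls_to_frame(self.calls)

    @property
    def panel_counts(self) -> dict[tuple[str, str], int]:
        return informative.count_by_side_and_location(self.panel)

    def status_of(self, embryo: str) -> str:
        for c in self.calls:
            if c.embryo == embryo:
                return c.final_status
        raise KeyError(embryo)

    @property
    def n_conclusive(self) -> int:
        return sum(1 for c in self.calls if c.final_status != "inconclusive")

    def concordance_with_truth(self, truth) -> float:
        """Fraction of conclusive calls matching a simulation TruthRecord."""
        by_label = {e.embryo: e.mutation_genotype for e in truth.embryos}
        status_by_dose = {0: "noncarrier", 1: "carrier", 2: "affected"}
        ok = total = 0
        for c in self.calls:
            if c.final_status == "inconclusive":
                continue
            total += 1
            if status_by_dose[by_label[c.embryo]] == c.final_status:
                ok += 1
        return ok / total if total else float("nan")

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        counts = self.panel_counts
        hap_counts = self.haplotypes.counts()
        lines = [
            f"PGT-M linkage results — {m.family} ({m.locus.name}, {m.locus.kind})",
            "=" * 64,
            f"embryos: {len(m.observations)}   affected references: "
            f"{sorted(self.affected) or 'none'}",
            f"informative markers: "
            f"maternal {counts[('maternal', 'upstream')]}u/"
            f"{counts[('maternal', 'downstream')]}d, "
            f"paternal {counts[('paternal', 'upstream')]}u/"
            f"{counts[('paternal', 'downstream')]}d",
            f"phased sites: {hap_counts['resolved']} resolved, "
            f"{hap_counts['unresolved_ADO']} ADO, "
            f"{hap_counts['conflict']} conflict",
            (f"WGA: amplification "
             f"{100 * self.wga_metrics['amplification_rate']:.2f}%,"
             f" ADO {100 * self.wga_metrics['ado_rate']:.2f}%"
             if self.wga_metrics is not None
             else "WGA: not estimable (no obligate-heterozygous markers)"),
            "-" * 64,
            f"{'embryo':<8}{'maternal':<12}{'paternal':<12}{'direct':<8}"
            f"{'status':<14}{'transfer':<9}",
        ]
        for c in self.calls:
            direct = c.direct_call
            d = str(direct.copies_or_genotype) if direct and \
                direct.copies_or_genotype is not None else "?"
            transfer = ""
            if self.transferable:
                transfer = "yes" if self.transferable.get(c.embryo) else "no"
            lines.append(
                f"{c.embryo:<8}{c.maternal.assignment:<12}"
                f"{c.paternal.assignment:<12}{d:<8}{c.final_status:<14}"
                f"{transfer:<9}")
        return "\n".join(lines)
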