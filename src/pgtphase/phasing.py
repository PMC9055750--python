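"""Parental haplotype phasing from affected embryos.

With two carrier parents and no proband, an embryo called homozygous for
the disease mutation must have inherited the disease-linked haplotype from
both parents. At every informative marker, subtracting the obligate allele
contributed by the homozygous parent from such an embryo's genotype leaves
the heterozygous parent's transmitted allele — which is, by construction,
the allele riding the disease haplotype (M0 on the maternal side, F0 on
the paternal side). The complementary allele is M1/F1.

Allele dropout (ADO) complicates the subtraction: a single-allele
observation may be a true homozygote or a heterozygote that lost one
allele during whole-genome amplification. Dropout halves the expected
read depth (one amplified copy instead of two), so single-allele
observations are only trusted as homozygous when their depth is
consistent with two copies; otherwise the site is left unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .informative import InformativeSNP
from .sim import EmbryoObservation

#: A single-allele observation is treated as a two-copy homozygote only if
#: its total depth is at least this fraction of the embryo's median
#: amplified-site depth; below it, dropout of the other allele is suspected.
ADO_DEPTH_FRAC = 0.7


# ---------------------------------------------------------------------------
# shared genotype-subtraction logic
# ---------------------------------------------------------------------------

def transmitted_allele(
    alleles: tuple[str, ...],
    total_depth: float,
    full_depth: float,
    snp: InformativeSNP,
    ado_depth_frac: float = ADO_DEPTH_FRAC,
) -> tuple[str | None, str]:
    """Infer which allele the heterozygous parent transmitted to an embryo.

    Parameters
    ----------
    alleles
        Alleles observed with nonzero depth at the site.
    total_depth
        Total read depth at the site.
    full_depth
        The embryo's two-copy depth reference (median amplified-site depth).
    snp
        The informative marker (defines het pair and obligate allele).

    Returns
    -------
    (allele, reason)
        ``allele`` is the transmitted allele of the het parent, or ``None``
        when the observation cannot disambiguate; ``reason`` explains the
        outcome (``resolved``, ``resolved_hom``, ``no_amplification``,
        ``ado``, ``mendelian_inconsistent``).
    """
    obs = set(alleles)
    if not obs:
        return None, "no_amplification"
    hom = snp.hom_allele
    legal = set(snp.het_alleles) | {hom}
    if not obs <= legal:
        return None, "mendelian_inconsistent"
    non_obligate = obs - {hom}
    if len(non_obligate) > 1:
        return None, "mendelian_inconsistent"
    if len(non_obligate) == 1:
        (allele,) = non_obligate
        return allele, "resolved"
    # only the obligate allele was seen
    if hom not in snp.het_alleles:
        # the het parent's contribution dropped out entirely
        return None, "ado"
    # shared allele: genuine homozygote vs dropout of the other het allele,
    # separated by depth (two amplified copies vs one)
    if full_depth > 0 and total_depth >= ado_depth_frac * full_depth:
        return hom, "resolved_hom"
    return None, "ado"


@dataclass
class _SiteEvidence:
    """One embryo's observation at one marker, with its depth context."""

    embryo: str
    alleles: tuple[str, ...]
    total_depth: float
    full_depth: float


def _collect_evidence(
    panel: list[InformativeSNP],
    observations: list[EmbryoObservation],
) -> dict[int, list[_SiteEvidence]]:
    """Index observations by marker position."""
    evidence: dict[int, list[_SiteEvidence]] = {snp.pos: [] for snp in panel}
    for obs in observations:
        med = obs.median_panel_depth()
        pos_arr = obs.snps["pos"].to_numpy()
        ref = obs.snps["ref"].to_numpy()
        alt = obs.snps["alt"].to_numpy()
        rd = obs.snps["ref_depth"].to_numpy()
        ad = obs.snps["alt_depth"].to_numpy()
        by_pos = {int(p): i for i, p in enumerate(pos_arr)}
        for snp in panel:
            i = by_pos.get(snp.pos)
            if i is None:
                continue
            alleles = tuple(
                a for a, d in ((ref[i], rd[i]), (alt[i], ad[i])) if d > 0)
            evidence[snp.pos].append(_SiteEvidence(
                obs.embryo, alleles, float(rd[i] + ad[i]), med))
    return evidence


# ---------------------------------------------------------------------------
# phased haplotype container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasedSite:
    snp: InformativeSNP
    status: str                  # "resolved" | "unresolved_ADO" | "conflict"
    h0_allele: str | None        # disease-linked allele of the het parent
    h1_allele: str | None
    n_support: int = 0           # affected embryos backing the call


@dataclass
class PhasedParentalHaplotypes:
    """M0/M1 and F0/F1 allele vectors over the informative panel.

    Index 0 is disease-associated by construction: it is the haplotype the
    affected reference embryos inherited.
    """

    sites: list[PhasedSite]
    n_affected_used: int
    notes: dict = field(default_factory=dict)

    def side_sites(self, side: str, resolved_only: bool = False) -> list[PhasedSite]:
        out = [s for s in self.sites if s.snp.side == side]
        if resolved_only:
            out = [s for s in out if s.status == "resolved"]
        return out

    def counts(self) -> dict[str, int]:
        out = {"resolved": 0, "unresolved_ADO": 0, "conflict": 0}
        for s in self.sites:
            out[s.status] += 1
        return out

    def allele_vectors(self, side: str) -> tuple[list, list]:
        """(H0, H1) allele lists over that side's markers (None if unresolved)."""
        sites = self.side_sites(side)
        return ([s.h0_allele for s in sites], [s.h1_allele for s in sites])

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.sites:
            label0 = "M0" if s.snp.side == "maternal" else "F0"
            label1 = "M1" if s.snp.side == "maternal" else "F1"
            rows.append((s.snp.site.chrom, s.snp.pos, s.snp.side,
                         s.snp.location, s.status,
                         s.h0_allele or ".", s.h1_allele or ".",
                         label0, label1, s.n_support))
        return pd.DataFrame(rows, columns=[
            "chrom", "pos", "side", "location", "status", "h0_allele",
            "h1_allele", "h0_label", "h1_label", "n_support"])


# ---------------------------------------------------------------------------
# phase deduction
# ---------------------------------------------------------------------------

def deduce_site_phase(
    snp: InformativeSNP,
    affected_evidence: list[_SiteEvidence],
    ado_depth_frac: float = ADO_DEPTH_FRAC,
    conflict_policy: str = "unanimous",
) -> PhasedSite:
    """Resolve the disease-linked allele at one marker from affected embryos.

    Every affected embryo votes with its inferred transmitted allele;
    unanimity resolves the site, disagreement marks it ``conflict``
    (or resolves by majority under ``conflict_policy="majority"``), and
    no usable observation leaves it ``unresolved_ADO``.
    """
    if not affected_evidence:
        raise ValueError("phasing reference unavailable: no affected embryos")
    votes: list[str] = []
    for ev in affected_evidence:
        allele, _ = transmitted_allele(
            ev.alleles, ev.total_depth, ev.full_depth, snp, ado_depth_frac)
        if allele is not None:
            votes.append(allele)
    if not votes:
        return PhasedSite(snp, "unresolved_ADO", None, None, 0)
    unique = set(votes)
    if len(unique) == 1:
        h0 = votes[0]
        return PhasedSite(snp, "resolved", h0, snp.other_het_allele(h0),
                          len(votes))
    if conflict_policy == "majority":
        best = max(unique, key=lambda a: (votes.count(a), a))
        counts = sorted((votes.count(a) for a in unique), reverse=True)
        if counts[0] > counts[1]:
            return PhasedSite(snp, "resolved", best,
                              snp.other_het_allele(best), votes.count(best))
    return PhasedSite(snp, "conflict", None, None, len(votes))


def build_haplotypes(
    panel: list[InformativeSNP],
    affected: set[str],
    observations: list[EmbryoObservation],
    *,
    min_cohort: int = 3,
    min_flank_resolved: int = 2,
    exclude_intragenic: bool = False,
    ado_depth_frac: float = ADO_DEPTH_FRAC,
    conflict_policy: str = "unanimous",
    enforce_flank_minimum: bool = True,
) -> PhasedParentalHaplotypes:
    """Phase both parents' disease haplotypes over the informative panel.

    Raises if no affected reference embryo is supplied, if the cohort is
    smaller than ``min_cohort`` (clinical floor for attempting phasing), or
    if fewer than ``min_flank_resolved`` markers resolve upstream or
    downstream on either side.
    """
    if not panel:
        raise ValueError("informative panel is empty")
    if not affected:
        raise ValueError("phasing reference unavailable: no affected embryos")
    if len(observations) < min_cohort:
        raise ValueError(
            f"cohort of {len(observations)} embryos is below the phasing "
            f"floor of {min_cohort}")
    if exclude_intragenic:
        panel = [s for s in panel if s.location != "intragenic"]
    affected_obs = [o for o in observations if o.embryo in affected]
    if not affected_obs:
        raise ValueError(
            "phasing reference unavailable: affected embryos not among "
            "observations")
    evidence = _collect_evidence(panel, affected_obs)
    sites = [
        deduce_site_phase(snp, evidence[snp.pos], ado_depth_frac,
                          conflict_policy)
        for snp in sorted(panel, key=lambda s: s.pos)
    ]
    phased = PhasedParentalHaplotypes(
        sites=sites, n_affected_used=len(affected_obs))
    if enforce_flank_minimum:
        for side in ("maternal", "paternal"):
            for loc in ("upstream", "downstream"):
                n = sum(1 for s in phased.sites
                        if s.status == "resolved" and s.snp.side == side
                        and s.snp.location == loc)
                if n < min_flank_resolved:
                    raise ValueError(
                        f"insufficient resolved {side} {loc} markers: "
                        f"{n} < {min_flank_resolved}")
    phased.notes["counts"] = phased.counts()
    return phased


# ---------------------------------------------------------------------------
# independent oracle (tests only)
# ---------------------------------------------------------------------------

def phase_oracle(
    panel: list[InformativeSNP],
    affected: set[str],
    observations: list[EmbryoObservation],
    *,
    exclude_intragenic: bool = False,
) -> PhasedParentalHaplotypes:
    """Exhaustive per-site hypothesis scoring, independent of the subtraction
    route in :func:`build_haplotypes`.

    For each marker, both candidate disease alleles of the heterozygous
    parent are scored against every affected embryo's observation: a
    hypothesis is eliminated if the observation is Mendelian-impossible
    under it, and earns a point when the observation equals the full
    no-dropout expectation. The higher-scoring surviving hypothesis wins;
    a tie (including both eliminated) is declared ambiguous.
    """
    if not affected:
        raise ValueError("phasing reference unavailable: no affected embryos")
    if exclude_intragenic:
        panel = [s for s in panel if s.location != "intragenic"]
    affected_obs = [o for o in observations if o.embryo in affected]
    evidence = _collect_evidence(panel, affected_obs)
    sites: list[PhasedSite] = []
    for snp in sorted(panel, key=lambda s: s.pos):
        scores: dict[str, float] = {}
        for h in sorted(snp.het_alleles):
            expected = {h, snp.hom_allele}
            score: float = 0.0
            for ev in evidence[snp.pos]:
                obs = set(ev.alleles)
                if not obs:
                    continue
                if not obs <= expected:
                    score = float("-inf")
                    break
                if obs == expected:
                    # count full observations; depth-confirmed single-allele
                    # homozygotes count as full evidence too
                    if len(expected) == 1:
                        if ev.full_depth > 0 and (
                                ev.total_depth
                                >= ADO_DEPTH_FRAC * ev.full_depth):
                            score += 1.0
                    else:
                        score += 1.0
            scores[h] = score
        alive = {h: s for h, s in scores.items() if s != float("-inf")}
        if not alive:
            sites.append(PhasedSite(snp, "conflict", None, None, 0))
        elif len(alive) == 1:
            (best, best_score), = alive.items()
            sites.append(PhasedSite(
                snp, "resolved", best, snp.other_het_allele(best),
                int(max(best_score, 0))))
        else:
            ranked = sorted(alive.items(), key=lambda kv: (-kv[1], kv[0]))
            (best, best_score), (_, second_score) = ranked
            if best_score > second_score:
                sites.append(PhasedSite(
                    snp, "resolved", best, snp.other_het_allele(best),
                    int(best_score)))
            else:
                sites.append(PhasedSite(snp, "unresolved_ADO", None, None, 0))
    return PhasedParentalHaplotypes(
        sites=sites, n_affected_used=len(affected_obs))
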