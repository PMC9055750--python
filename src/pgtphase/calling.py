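"""Per-embryo linkage genotyping with ADO and recombination safeguards.

Every sibling embryo is assigned the maternal and paternal haplotype it
inherited by letting each resolved informative marker vote H0 (disease) or
H1 (normal) according to the allele received from the heterozygous parent.
A call requires at least two concordant markers upstream AND two
downstream of the gene (the clinic's closely-linked-flanking-marker rule)
plus a 0.8 supermajority of non-abstaining votes, so a single corrupted
marker cannot flip an assignment. A clean positional switch in the vote
sequence is treated as a suspected crossover, and only the gene-side
segment of markers is used.

The final disease status combines the two haplotype assignments with the
direct mutation call: linkage rescues dropout at the mutation site, while
a hard contradiction between the two routes withholds the diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .informative import InformativeSNP
from .loci import MutationLocus
from .mutation import DepthCall
from .phasing import ADO_DEPTH_FRAC, PhasedParentalHaplotypes, transmitted_allele
from .sim import EmbryoObservation


@dataclass(frozen=True)
class VoteThresholds:
    min_flank_votes: int = 2      # concordant winners required per flank
    winner_frac: float = 0.8      # supermajority of non-abstaining votes
    ado_depth_frac: float = ADO_DEPTH_FRAC


@dataclass
class SideAssignment:
    """Haplotype assignment for one parental side of one embryo."""

    embryo: str
    side: str
    assignment: str               # "H0" | "H1" | "inconclusive"
    n_h0_upstream: int = 0
    n_h0_downstream: int = 0
    n_h1_upstream: int = 0
    n_h1_downstream: int = 0
    n_abstain: int = 0
    flags: set[str] = field(default_factory=set)

    @property
    def n_h0(self) -> int:
        return self.n_h0_upstream + self.n_h0_downstream

    @property
    def n_h1(self) -> int:
        return self.n_h1_upstream + self.n_h1_downstream


@dataclass
class EmbryoCall:
    """Final per-embryo diagnosis."""

    embryo: str
    maternal: SideAssignment
    paternal: SideAssignment
    direct_call: DepthCall | None
    final_status: str             # affected | carrier | noncarrier | inconclusive
    flags: set[str] = field(default_factory=set)


def _vote_at_site(
    phased_site,
    obs_alleles: tuple[str, ...],
    total_depth: float,
    full_depth: float,
    ado_depth_frac: float,
) -> str | None:
    allele, _ = transmitted_allele(
        obs_alleles, total_depth, full_depth, phased_site.snp, ado_depth_frac)
    if allele is None:
        return None
    if allele == phased_site.h0_allele:
        return "H0"
    if allele == phased_site.h1_allele:
        return "H1"
    return None  # allele outside the phased pair: treat as abstention


def assign_side(
    observation: EmbryoObservation,
    phased: PhasedParentalHaplotypes,
    side: str,
    locus: MutationLocus,
    thresholds: VoteThresholds | None = None,
) -> SideAssignment:
    """Vote one embryo's inherited haplotype on one parental side.

    Only sites phased as ``resolved`` vote; conflict and unresolved sites
    never enter the count. Dropout-ambiguous observations abstain.
    """
    th = thresholds or VoteThresholds()
    sites = phased.side_sites(side, resolved_only=True)
    med = observation.median_panel_depth()
    snps = observation.snps
    by_pos = {int(p): i for i, p in enumerate(snps["pos"].to_numpy())}
    ref = snps["ref"].to_numpy()
    alt = snps["alt"].to_numpy()
    rd = snps["ref_depth"].to_numpy()
    ad = snps["alt_depth"].to_numpy()

    votes: list[tuple[int, str, str]] = []  # (pos, location, H0/H1)
    n_abstain = 0
    for ps in sorted(sites, key=lambda s: s.snp.pos):
        i = by_pos.get(ps.snp.pos)
        if i is None:
            continue
        alleles = tuple(a for a, d in ((ref[i], rd[i]), (alt[i], ad[i])) if d > 0)
        v = _vote_at_site(ps, alleles, float(rd[i] + ad[i]), med,
                          th.ado_depth_frac)
        if v is None:
            n_abstain += 1
        else:
            votes.append((ps.snp.pos, ps.snp.location, v))

    out = SideAssignment(observation.embryo, side, "inconclusive",
                         n_abstain=n_abstain)
    for pos, loc, v in votes:
        key = f"n_{v.lower()}_{loc}" if loc in ("upstream", "downstream") else None
        if key is not None:
            setattr(out, key, getattr(out, key) + 1)

    if not votes:
        return out

    labels = [v for _, _, v in votes]
    switches = [k for k in range(1, len(labels)) if labels[k] != labels[k - 1]]
    used = votes
    if len(switches) == 1 and len(set(labels)) == 2:
        # one clean positional changepoint: suspected crossover; keep the
        # gene-side segment (markers are position-sorted, the gene sits
        # between the upstream and downstream blocks)
        out.flags.add("recombination_suspected")
        k = switches[0]
        left, right = votes[:k], votes[k:]
        split_pos = right[0][0]
        if split_pos <= locus.region.start:
            used = right  # crossover upstream of the gene: distal block is left
        else:
            used = left
    n_h0 = sum(1 for _, _, v in used if v == "H0")
    n_h1 = sum(1 for _, _, v in used if v == "H1")
    if n_h0 == n_h1:
        return out
    winner = "H0" if n_h0 > n_h1 else "H1"
    n_win, n_total = max(n_h0, n_h1), n_h0 + n_h1
    win_up = sum(1 for _, loc, v in used if v == winner and loc == "upstream")
    win_down = sum(1 for _, loc, v in used if v == winner and loc == "downstream")
    if (win_up >= th.min_flank_votes and win_down >= th.min_flank_votes
            and n_win / n_total >= th.winner_frac):
        out.assignment = winner
    return out


_STATUS_BY_DOSE = {0: "noncarrier", 1: "carrier", 2: "affected"}


def classify_embryo(
    maternal: SideAssignment,
    paternal: SideAssignment,
    direct_call: DepthCall | None,
) -> EmbryoCall:
    """Combine linkage assignments with the direct mutation call.

    Linkage is primary: H0+H0 is affected, one H0 a carrier, H1+H1 a
    noncarrier. A passing direct call that agrees confirms the result; an
    ambiguous or low-depth direct call leaves the linkage result standing
    with an ``ADO_at_mutation_site`` flag; a hard contradiction withholds
    the diagnosis (``discordant_direct_vs_linkage``).
    """
    flags = set(maternal.flags) | set(paternal.flags)
    if maternal.assignment == "inconclusive" or paternal.assignment == "inconclusive":
        status = "inconclusive"
    else:
        dose = int(maternal.assignment == "H0") + int(paternal.assignment == "H0")
        status = _STATUS_BY_DOSE[dose]
    if status != "inconclusive" and direct_call is not None:
        if direct_call.confidence != "pass":
            flags.add("ADO_at_mutation_site")
        elif _STATUS_BY_DOSE[direct_call.copies_or_genotype] != status:
            flags.add("discordant_direct_vs_linkage")
            status = "inconclusive"
    return EmbryoCall(
        embryo=maternal.embryo, maternal=maternal, paternal=paternal,
        direct_call=direct_call, final_status=status, flags=flags)


def calls_to_frame(calls: list[EmbryoCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append((
            c.embryo, c.final_status,
            c.maternal.assignment, c.maternal.n_h0, c.maternal.n_h1,
            c.paternal.assignment, c.paternal.n_h0, c.paternal.n_h1,
            c.direct_call.copies_or_genotype if c.direct_call else None,
            c.direct_call.confidence if c.direct_call else None,
            ";".join(sorted(c.flags)) or "."))
    return pd.DataFrame(rows, columns=[
        "embryo", "final_status", "maternal_assignment", "maternal_h0",
        "maternal_h1", "paternal_assignment", "paternal_h0", "paternal_h1",
        "direct_genotype", "direct_confidence", "flags"])


# ---------------------------------------------------------------------------
# WGA artifact-rate estimation
# ---------------------------------------------------------------------------

def estimate_wga_metrics(
    observations: list[EmbryoObservation],
    parents: pd.DataFrame,
    locus: MutationLocus | None = None,
) -> dict[str, float]:
    """Estimate amplification and allele-dropout rates from embryo data.

    The amplification rate is the fraction of attempted panel site-calls
    with any reads. ADO is only observable where the embryo is an obligate
    heterozygote — both parents homozygous for different alleles — where a
    single-allele observation must be a dropout; the ADO rate is the
    fraction of amplified obligate-heterozygous site-calls observed with
    one allele. Sites inside a large-deletion region are excluded (missing
    copies there are genotype, not artifact).
    """
    mother = parents["mother"].to_numpy()
    father = parents["father"].to_numpy()
    pos = parents["pos"].to_numpy()

    def hom_allele(gt: str) -> str | None:
        a = gt.split("/")
        return a[0] if a[0] == a[1] else None

    obligate = np.zeros(len(parents), dtype=bool)
    for i in range(len(parents)):
        ma, fa = hom_allele(mother[i]), hom_allele(father[i])
        if ma is not None and fa is not None and ma != fa:
            obligate[i] = True
    usable = np.ones(len(parents), dtype=bool)
    if locus is not None and locus.kind == "large_deletion":
        usable &= ~np.array(
            [locus.region.contains(int(p)) for p in pos])

    n_attempted = 0
    n_amplified = 0
    n_obl_amplified = 0
    n_dropout = 0
    for obs in observations:
        snps = obs.snps
        by_pos = {int(p): i for i, p in enumerate(snps["pos"].to_numpy())}
        rd = snps["ref_depth"].to_numpy()
        ad = snps["alt_depth"].to_numpy()
        for j in range(len(parents)):
            if not usable[j]:
                continue
            i = by_pos.get(int(pos[j]))
            if i is None:
                continue
            n_attempted += 1
            amplified = rd[i] + ad[i] > 0
            if amplified:
                n_amplified += 1
                if obligate[j]:
                    n_obl_amplified += 1
                    if rd[i] == 0 or ad[i] == 0:
                        n_dropout += 1
    if n_attempted == 0:
        raise ValueError("no attempted site-calls")
    if n_obl_amplified == 0:
        raise ValueError(
            "no amplified obligate-heterozygous sites: ADO rate undefined")
    return {
        "amplification_rate": n_amplified / n_attempted,
        "ado_rate": n_dropout / n_obl_amplified,
        "n_attempted": n_attempted,
        "n_obligate_het": n_obl_amplified,
    }
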