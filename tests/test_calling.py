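"""Linkage voting, final classification, and WGA-metric estimation."""

import numpy as np
import pandas as pd
import pytest

from pgtphase import (
    PGTLinkage,
    SimConfig,
    VoteThresholds,
    assign_side,
    build_haplotypes,
    classify_embryo,
    estimate_wga_metrics,
    select_informative,
    simulate_family,
)
from pgtphase.mutation import DepthCall

from conftest import build_worked_family


def _phased(worked):
    panel = select_informative(worked.parents, worked.locus)
    return build_haplotypes(panel, worked.affected, worked.observations)


def test_worked_family_haplotype_assignments(family13):
    """The published partition: embryos 1, 5, 7 carry the maternal disease
    haplotype; 2, 3, 4, 5, 7 the paternal one."""
    phased = _phased(family13)
    mat_h0 = {o.embryo for o in family13.observations
              if assign_side(o, phased, "maternal",
                             family13.locus).assignment == "H0"}
    pat_h0 = {o.embryo for o in family13.observations
              if assign_side(o, phased, "paternal",
                             family13.locus).assignment == "H0"}
    assert mat_h0 == {"E1", "E5", "E7"}
    assert pat_h0 == {"E2", "E3", "E4", "E5", "E7"}


@pytest.mark.parametrize("family_fixture,expected", [
    ("family13", {"affected": {"E5", "E7"},
                  "carrier": {"E1", "E2", "E3", "E4"},
                  "noncarrier": {"E6", "E8", "E9"}}),
    ("family30", {"affected": {"E4", "E6"},
                  "carrier": {"E1", "E2", "E5"},
                  "noncarrier": {"E3"}}),
])
def test_full_model_reproduces_published_partitions(
        family_fixture, expected, request):
    worked = request.getfixturevalue(family_fixture)
    results = PGTLinkage(worked.parents, worked.observations,
                         worked.locus).fit()
    partition = {"affected": set(), "carrier": set(), "noncarrier": set()}
    for call in results.calls:
        partition[call.final_status].add(call.embryo)
    assert partition == expected


def test_votes_recorded_by_flank(family13):
    phased = _phased(family13)
    e5 = next(o for o in family13.observations if o.embryo == "E5")
    mat = assign_side(e5, phased, "maternal", family13.locus)
    assert mat.assignment == "H0"
    assert mat.n_h0_upstream >= 2 and mat.n_h0_downstream >= 2
    assert mat.n_h1 == 0


def test_crossover_splits_votes_and_flags_recombination():
    """All-H0 upstream against all-H1 downstream is a suspected crossover
    between the flanks; the gene-side haplotype is undecidable and the
    call is withheld."""
    from pgtphase import sea_deletion

    maternal = [
        (100_000, "A", "C", "A", "C", "C"),
        (150_000, "G", "T", "T", "G", "G"),
        (160_000, "A", "G", "G", "A", "A"),
        (300_000, "A", "G", "G", "A", "A"),
        (350_000, "C", "T", "C", "T", "T"),
        (360_000, "A", "T", "A", "T", "T"),
    ]
    paternal = [
        (110_000, "C", "T", "C", "T", "C"),
        (165_000, "A", "T", "A", "T", "T"),
        (310_000, "C", "G", "G", "C", "C"),
        (365_000, "A", "G", "A", "G", "G"),
    ]
    worked = build_worked_family(
        sea_deletion(), maternal, paternal,
        maternal_h0={"E1", "E2"}, paternal_h0={"E1", "E2"},
        embryos=["E1", "E2", "E3", "E4"])
    phased = _phased(worked)
    # craft a recombinant: upstream maternal markers H0, downstream H1
    e3 = next(o for o in worked.observations if o.embryo == "E3")
    snps = e3.snps.copy()
    for pos, ref, alt, h0, h1, hom in maternal:
        i = snps.index[snps["pos"] == pos][0]
        allele = h0 if pos < 215_400 else h1
        rd = 50 * ((allele == ref) + (hom == ref))
        ad = 50 * ((allele == alt) + (hom == alt))
        snps.loc[i, ["ref_depth", "alt_depth"]] = [rd, ad]
    recombinant = type(e3)("E3", snps, e3.locus_probes)
    call = assign_side(recombinant, phased, "maternal", worked.locus)
    assert call.assignment == "inconclusive"
    assert "recombination_suspected" in call.flags


def test_distal_crossover_still_called_with_flag():
    """A crossover beyond the proximal markers leaves the gene-side block
    intact: the assignment survives with the recombination flag."""
    from pgtphase import sea_deletion

    maternal = [
        (50_000, "A", "C", "A", "C", "C"),
        (100_000, "G", "T", "T", "G", "G"),
        (150_000, "A", "G", "G", "A", "A"),
        (160_000, "C", "T", "C", "T", "T"),
        (300_000, "A", "G", "G", "A", "A"),
        (350_000, "C", "T", "C", "T", "T"),
    ]
    paternal = [
        (110_000, "C", "T", "C", "T", "C"),
        (165_000, "A", "T", "A", "T", "T"),
        (310_000, "C", "G", "G", "C", "C"),
        (365_000, "A", "G", "A", "G", "G"),
    ]
    worked = build_worked_family(
        sea_deletion(), maternal, paternal,
        maternal_h0={"E1", "E2"}, paternal_h0={"E1", "E2"},
        embryos=["E1", "E2", "E3", "E4"])
    phased = _phased(worked)
    e3 = next(o for o in worked.observations if o.embryo == "E3")
    snps = e3.snps.copy()
    for pos, ref, alt, h0, h1, hom in maternal:
        i = snps.index[snps["pos"] == pos][0]
        allele = h1 if pos <= 50_000 else h0  # switch distal to the gene
        rd = 50 * ((allele == ref) + (hom == ref))
        ad = 50 * ((allele == alt) + (hom == alt))
        snps.loc[i, ["ref_depth", "alt_depth"]] = [rd, ad]
    recombinant = type(e3)("E3", snps, e3.locus_probes)
    call = assign_side(recombinant, phased, "maternal", worked.locus)
    assert call.assignment == "H0"
    assert "recombination_suspected" in call.flags


def test_classification_matrix():
    def side(label):
        from pgtphase.calling import SideAssignment
        return SideAssignment("E1", "maternal", label,
                              n_h0_upstream=2, n_h0_downstream=2)

    direct_pass = DepthCall("E1", 2, 1, 100, 0.01, "pass")
    assert classify_embryo(side("H0"), side("H0"),
                           direct_pass).final_status == "affected"
    assert classify_embryo(side("H0"), side("H1"), None
                           ).final_status == "carrier"
    assert classify_embryo(side("H1"), side("H1"), None
                           ).final_status == "noncarrier"
    both_inconclusive = classify_embryo(side("inconclusive"),
                                        side("inconclusive"), direct_pass)
    assert both_inconclusive.final_status == "inconclusive"


def test_direct_linkage_discordance_withholds_diagnosis():
    from pgtphase.calling import SideAssignment

    def side(label):
        return SideAssignment("E1", "maternal", label)

    direct_hom = DepthCall("E1", 2, 1, 100, 0.01, "pass")
    call = classify_embryo(side("H1"), side("H1"), direct_hom)
    assert call.final_status == "inconclusive"
    assert "discordant_direct_vs_linkage" in call.flags

    direct_ambiguous = DepthCall("E1", None, 20, 100, 0.2, "ambiguous")
    call = classify_embryo(side("H0"), side("H0"), direct_ambiguous)
    assert call.final_status == "affected"
    assert "ADO_at_mutation_site" in call.flags


def test_vote_invariance_and_threshold_monotonicity(family13):
    """Votes do not depend on marker order, and a stricter flank floor can
    only lose conclusive calls, never gain them."""
    phased = _phased(family13)
    lax = VoteThresholds(min_flank_votes=2)
    strict = VoteThresholds(min_flank_votes=3)
    for obs in family13.observations:
        shuffled = type(obs)(
            obs.embryo, obs.snps.sample(frac=1, random_state=3)
            .reset_index(drop=True), obs.locus_probes)
        for side in ("maternal", "paternal"):
            a = assign_side(obs, phased, side, family13.locus, lax)
            b = assign_side(shuffled, phased, side, family13.locus, lax)
            assert a.assignment == b.assignment
            s = assign_side(obs, phased, side, family13.locus, strict)
            if a.assignment == "inconclusive":
                assert s.assignment == "inconclusive"


def test_simulated_cohort_truth_concordance():
    """At the published artifact rates with no recombination, every
    conclusive linkage call matches the simulated truth."""
    n_embryos = 0
    for seed in range(8):
        cfg = SimConfig(
            embryos_per_family=16, ado_rate=0.0426,
            amplification_rate=0.9471, recombination_rate=0.0,
            aneuploidy_rate=0.0, n_fragments=5_000,
            min_affected_per_family=1, min_informative_per_quadrant=5,
            seed=900 + seed)
        fam = simulate_family(cfg, f"F{seed}")
        results = PGTLinkage.from_family(fam).fit()
        assert results.concordance_with_truth(fam.truth) == 1.0
        n_embryos += len(results.calls)
    assert n_embryos >= 100


# ---------------------------------------------------------------------------
# WGA metric estimation
# ---------------------------------------------------------------------------

def _obligate_family(n_sites, ado, amp, seed, n_embryos=2):
    """All panel sites obligate-heterozygous (A/A mother x C/C father)."""
    from pgtphase import EmbryoObservation, apply_wga, sea_deletion, simulate_depths

    locus = sea_deletion()
    pos = np.arange(100_000, 100_000 + n_sites)
    panel = pd.DataFrame({"chrom": "chr16", "pos": pos,
                          "ref": "A", "alt": "C"})
    parents = panel.copy()
    parents["mother"] = "A/A"
    parents["father"] = "C/C"
    rng = np.random.default_rng(seed)
    observations = []
    for j in range(n_embryos):
        observed, status = apply_wga([("A", "C")] * n_sites, ado, amp, rng)
        obs = simulate_depths(observed, 0, 100.0, rng, locus=locus,
                              panel=panel, embryo=f"E{j + 1}",
                              wga_status=status)
        observations.append(obs)
    return observations, parents, locus


def test_wga_metrics_zero_noise_limit():
    observations, parents, locus = _obligate_family(200, 0.0, 1.0, seed=0)
    metrics = estimate_wga_metrics(observations, parents, locus)
    assert metrics["amplification_rate"] == 1.0
    assert metrics["ado_rate"] == 0.0


def test_wga_metrics_recover_published_rates_within_3_se():
    n_sites = 30_000
    observations, parents, locus = _obligate_family(
        n_sites, 0.0426, 0.9471, seed=41)
    metrics = estimate_wga_metrics(observations, parents, locus)
    n_att = metrics["n_attempted"]
    n_obl = metrics["n_obligate_het"]
    se_amp = np.sqrt(0.9471 * (1 - 0.9471) / n_att)
    se_ado = np.sqrt(0.0426 * (1 - 0.0426) / n_obl)
    assert abs(metrics["amplification_rate"] - 0.9471) < 3 * se_amp
    assert abs(metrics["ado_rate"] - 0.0426) < 3 * se_ado


def test_wga_metrics_error_cases():
    observations, parents, locus = _obligate_family(50, 0.0, 0.0, seed=1)
    with pytest.raises(ValueError, match="obligate"):
        estimate_wga_metrics(observations, parents, locus)
    # no obligate-het sites at all: both parents het
    observations2, parents2, locus2 = _obligate_family(50, 0.0, 1.0, seed=2)
    parents2["mother"] = "A/C"
    with pytest.raises(ValueError, match="obligate"):
        estimate_wga_metrics(observations2, parents2, locus2)
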