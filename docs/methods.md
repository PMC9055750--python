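# Methods

## The problem

Couples in which both partners carry a recessive thalassemia allele
(α-thalassemia: the ~20 kb Southeast-Asian deletion removing HBA1/HBA2;
β-thalassemia: e.g. the CD41–42 −AAAG frameshift in HBB) can avoid an
affected pregnancy through preimplantation genetic testing for monogenic
disease (PGT-M). Reliable single-embryo genotyping requires linkage
analysis over SNPs flanking the mutation, because whole-genome
amplification (WGA) of a ~5-cell trophectoderm biopsy suffers allele
dropout (ADO): a direct mutation assay alone misdiagnoses when one allele
fails to amplify. Linkage, in turn, requires knowing which parental
haplotype carries the mutation — ordinarily established from a proband or
pedigree, which many couples lack.

This package implements the proband-free alternative: embryos of the same
IVF cohort that are *homozygous* for the mutation (detected by a direct
depth assay that ADO cannot mimic for a biallelic deletion) must carry
the disease haplotype from **both** parents, and therefore serve as the
phasing reference for their siblings.

## The phasing rule

A marker is *informative* when it is heterozygous in exactly one parent
and homozygous in the other. For a maternal-informative site (mother
a₁/a₂, father b/b), any embryo receives the obligate b from the father;
subtracting it from an affected embryo's observed genotype leaves the
maternal transmitted allele, which by construction lies on the maternal
disease haplotype M0. The complementary allele is M1. Paternal sites
yield F0/F1 symmetrically.

Dropout handling follows the allele identities and read depths:

* observed {x, b} with x ≠ b → maternal allele x (resolved);
* observed {x} with x ≠ b → the paternal copy dropped; still resolved x;
* observed {b} with b ∉ {a₁, a₂} → the maternal copy dropped and its
  identity is unknowable → `unresolved_ADO`;
* observed {b} with b ∈ {a₁, a₂} → either a genuine homozygote (two
  amplified copies, ≈ full depth) or dropout of the other maternal allele
  (one copy, ≈ half depth). The site resolves to b only when its total
  depth is at least `ado_depth_frac` (default 0.7) of the embryo's median
  amplified-site depth; otherwise `unresolved_ADO`.

The depth gate matters: under the package's Poisson depth model
(mean_depth/2 per amplified copy) a one-copy site at 100X reads ~50 ± 7
and a two-copy site ~100 ± 10, so the 0.7 gate misclassifies either with
probability < 0.5%. With several affected references, sites resolve only
on unanimity (default) — any disagreement marks the site `conflict` and
removes it from all downstream voting; a majority policy is available.

Phasing is attempted only for cohorts of ≥ 3 embryos (the clinical floor;
one affected embryo is mathematically sufficient and the floor is
configurable) and fails loudly when fewer than 2 markers resolve upstream
or downstream on either side. Markers inside a large deletion are
excluded from phasing (affected embryos carry no DNA there); for a small
indel they participate normally.

## Embryo genotyping

Each resolved marker votes H0 or H1 for each sibling embryo by the same
subtraction-plus-depth rule; ambiguous observations abstain. An
assignment requires ≥ 2 concordant winning votes upstream AND ≥ 2
downstream (the closely-linked flanking-marker rule) and a winner
fraction ≥ 0.8 of non-abstaining votes, so a single corrupted marker
cannot flip a call backed by many. The 0.8 supermajority and the
abstention rule are this package's reinforcement of the ≥2+≥2 floor.

A single clean positional changepoint in the vote sequence (an all-H0
block meeting an all-H1 block) is treated as a suspected crossover: the
marker block on the gene's side of the changepoint is used alone if it
still satisfies both flank minima, otherwise the call is withheld with a
`recombination_suspected` flag. A changepoint exactly between the flanks
leaves the gene-side haplotype genuinely undecidable and the call is
withheld.

Final status: H0+H0 → affected, one H0 → carrier, H1+H1 → noncarrier.
The direct mutation call cross-validates: agreement confirms; a low-depth
or ambiguous direct call leaves the linkage result standing with an
`ADO_at_mutation_site` flag; a hard contradiction (e.g. direct homozygote
vs linkage noncarrier) withholds the diagnosis — a deliberate
prefer-no-answer-over-wrong-answer policy.

## Direct mutation assays

* **Large deletion** — mean read depth over probes tiling the deleted
  interval, normalized by the mean over amplified flank probes. Bands:
  ratio < 0.10 → two deletion alleles; 0.30–0.70 → one; > 0.80 → zero;
  gaps → ambiguous; flank depth < 30X → low_depth. Zero-depth flank
  probes are excluded from the baseline (they are amplification failures,
  not signal), while in-region zeros are retained because there they are
  the deletion signal. These thresholds are this package's
  reconstruction — the source assay reports only "very low read counts"
  for homozygotes — and are configurable.
* **Small indel** — mutant-allele read fraction at the site: ≥ 0.90 → two
  alleles; 0.25–0.75 → one; ≤ 0.10 → zero; total depth < 30 → low_depth.

## The synthetic cohort generator

The simulator emulates the study conditions so every stage is testable
without patient data. Defaults (all configurable in `SimConfig`):

| parameter | default | origin |
|---|---|---|
| families / embryos per family | 36 / 6 | cohort size; ~6 biopsied blastocysts per couple |
| α panel | 138 SNPs ≤ 1 Mb upstream, 132 ≤ 2 Mb downstream of chr16:215,400–234,700 | assay design |
| β panel preset | 85 SNPs within 1 Mb (alternate: 95 within 2 Mb) of chr11:5,246,696–5,248,301 | assay design (both published counts offered) |
| amplification rate | 0.9471 per site | cohort-measured |
| ADO rate | 0.0426 per heterozygous site | cohort-measured |
| mean depth | 100X (Poisson per copy) | "> 30X" with margin |
| recombination | 10⁻⁸ /bp (≈ 1 cM/Mb) | genome-average prior; unreported |
| aneuploidy / mosaic share / mosaic fraction | 0.30 / 0.35 / U(0.2, 0.8) | 70.0% of unaffected euploid; 10.6% of biopsies mosaic |
| CNV fragments / bins | 1.5 M / 1 Mb hg19 bins | sequencing design |
| population allele frequency | 0.5 | makes ~half the panel informative |

Mechanics: parental haplotype 0 carries the mutation by construction;
embryos inherit one haplotype per side with crossovers as a Poisson
process along the marker map; WGA applies per-site amplification failure
then per-heterozygous-site single-allele dropout; depth is
Poisson(mean/2) per surviving copy; sites inside a homozygous deletion
emit background only, Poisson(0.02 × mean) — near zero but not zero, as
real WGA background is. The mutation region is observed through 12
in-region probes and 8 per flank: the amplicon count is an assay-design
parameter (the source assay tiles the region with many primer pairs) and
is set so the carrier depth-ratio band is separated by > 4 SD at 100X.
One seeded generator (numpy `SeedSequence`, per-family spawns) drives
everything; a fixed seed reproduces the cohort byte-identically.

What the generator does **not** emulate: read-level errors and alignment,
GC and amplicon-efficiency bias (flat amplification/ADO rates across
sites and embryos), linkage disequilibrium between markers, segmental
aneuploidy, trisomy-distorted SNP depths (karyotype affects only the
binned CNV counts), and consanguinity-driven marker scarcity. Passing
tests therefore demonstrate the logic of phasing, voting and screening
under the stated artifact rates — not robustness to structured bias in
real amplicon data.

## Aneuploidy screening

Binned counts are converted to ratios against a reference profile
(observed fraction / reference fraction), rescaled to a genome-wide
median of 1; a chromosome's median bin ratio estimates copy state (1.5
trisomy, 0.5 monosomy, 1 ± f/2 for a mosaic of fraction f, estimated as
2·|ratio − 1|). Bands: euploid [0.9, 1.1]; mosaic gain (1.15, 1.35];
full gain > 1.35; mirrored losses; gap zones take the nearest band and
are flagged borderline. The bands follow common PGT-A practice — the
clinical center's thresholds are unpublished. GC correction is omitted
(the simulator has no GC bias); the normalization hook accepts any
reference profile. An embryo is transferable iff unaffected (carrier or
noncarrier) and euploid; mosaics are withheld.

## WGA artifact estimation

Amplification rate = site-calls with any reads / attempted. ADO is only
*observable* where an embryo is an obligate heterozygote (parents
homozygous for different alleles), where a single-allele observation must
be dropout: ADO rate = single-allele observations / amplified
obligate-heterozygous site-calls. Sites inside a large-deletion region
are excluded (missing copies there are genotype). Both estimators are
binomial proportions; tests require recovery within 3 standard errors.

## Verification design

* An independent per-site **phase oracle** scores both candidate disease
  alleles of the het parent against every affected observation
  (elimination on Mendelian impossibility, points for full-observation
  matches, ties ambiguous) — a different route from the subtraction rule;
  property tests require agreement on all sites both methods resolve.
* The worked-example families are reconstructed from the published
  narratives (marker 119,006 A/C × A/A resolving M0=A; 207,611 C/C × C/T
  resolving F0=C; the {E5,E7} / {E1–E4} / {E6,E8,E9} and {E4,E6} /
  {E1,E2,E5} / {E3} partitions) and must reproduce exactly.
* The packaged outcomes table is checked against the cohort's printed
  aggregates (217 biopsied; 73.7% unaffected; 70.0% euploid of
  unaffected; 6.0 and 3.1 per-couple means). One row's digits are
  ambiguous in the available transcription; it is reconstructed from the
  column totals, which all match the printed aggregates exactly.
* Problem sizes used by the default test run: 36-family pipeline cohorts,
  500-family oracle-agreement sweeps with reduced (12+12 marker) panels,
  1,000 + 1,000 CNV profiles at full 1.5 M-fragment scale, and ≥ 50,000
  obligate-heterozygous site-calls for estimator recovery.

## Known limitations

* Thresholds for depth genotyping and mosaic bands are reconstructions;
  on real data they would need calibration against controls.
* The recombination handler assumes at most one crossover per side within
  the panel window; double crossovers between flanks fall back to the
  supermajority rule.
* Carrier-vs-wild-type separation by depth ratio presumes a stable
  amplification baseline; without flank normalization (e.g. failed
  biopsy-wide amplification) the direct call degrades to low_depth and
  diagnosis rests on linkage alone.
* X/Y chromosomes are simulated as disomic; sex-chromosome aneuploidy
  calling is untested.
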