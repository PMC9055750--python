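# pgtphase

Proband-free preimplantation genetic testing (PGT-M) for recessive
thalassemia, with a bundled synthetic-cohort simulator.

When both partners carry a recessive thalassemia allele — the
Southeast-Asian (--SEA) deletion removing both α-globin genes, or a small
HBB indel such as CD41–42 (−AAAG) — embryos from IVF can be genotyped
before transfer. Reliable genotyping needs linkage analysis over
informative SNPs flanking the mutation, because whole-genome
amplification of a few-cell biopsy drops alleles (ADO) and a direct assay
alone can misdiagnose. Linkage needs the parental *phase*: which allele
at each marker rides the disease chromosome. Families without an affected
child or informative pedigree cannot be phased the usual way.

`pgtphase` implements the in-cohort alternative: embryos called
**homozygous** for the mutation by a direct depth assay (near-zero read
depth across a deletion; mutant-allele read fraction for an indel) must
carry the disease haplotype from *both* parents. They become the phasing
reference for their siblings.

## Core model

For an informative marker — heterozygous in one parent (a₁/a₂), homozygous
in the other (b/b) — an affected embryo's genotype minus the obligate b
reveals the transmitted allele of the heterozygous parent, which by
construction lies on that parent's disease haplotype (M0 maternally, F0
paternally; M1/F1 are the complements). Every sibling embryo is then
genotyped by letting each resolved marker vote H0/H1 for the allele it
received from the heterozygous parent; a call needs ≥ 2 concordant
markers upstream **and** ≥ 2 downstream of the gene plus an 0.8
supermajority, with dropout-ambiguous sites abstaining (single-allele
observations are trusted as homozygous only at two-copy read depth).
Final status — affected (H0+H0), carrier, noncarrier — is cross-validated
against the direct mutation call; contradictions withhold the diagnosis.
Aneuploidy is screened separately from ~1.5 M binned read counts
(per-chromosome median ratio: 1.5 trisomy, 0.5 monosomy, 1 ± f/2 for a
mosaic of fraction f); transferable = unaffected AND euploid.

The package is organised statsmodels-style: `PGTLinkage` is built from
one family's data and `fit()` returns a `PGTLinkageResults` with the
phased haplotypes, per-embryo calls, WGA artifact-rate estimates,
aneuploidy screens, transfer decisions and a `summary()` table. The
underlying stages live in `informative`, `mutation`, `phasing`,
`calling`, `cnv`, `report`, and `sim` (the simulator).

## Worked example

```python
from pgtphase import PGTLinkage, SimConfig, simulate_family

cfg = SimConfig(embryos_per_family=9, min_affected_per_family=1,
                min_informative_per_quadrant=10, seed=13)
family = simulate_family(cfg, "demo")          # two SEA carriers, 9 embryos
results = PGTLinkage.from_family(family).fit()
print(results.summary())
```

prints

```
PGT-M linkage results — demo (SEA, large_deletion)
================================================================
embryos: 9   affected references: ['E1', 'E3', 'E7']
informative markers: maternal 34u/35d, paternal 37u/30d
phased sites: 136 resolved, 0 ADO, 0 conflict
WGA: amplification 94.24%, ADO 2.29%
----------------------------------------------------------------
embryo  maternal    paternal    direct  status        transfer
E1      H0          H0          2       affected      no
E2      H1          H0          1       carrier       yes
E3      H0          H0          2       affected      no
E4      H0          H1          1       carrier       yes
E5      H1          H1          0       noncarrier    no
E6      H1          H0          1       carrier       yes
E7      H0          H0          2       affected      no
E8      H0          H1          1       carrier       yes
E9      H0          H1          1       carrier       no
```

Reading it: three embryos failed to amplify across the deletion (direct
dose 2) and served as the phasing reference; 136 informative markers
resolved without conflict; the estimated amplification and dropout rates
are this family's realisation of the configured artifact process. E1, E3
and E7 are affected and never transferable; E5 is a noncarrier and E9 a
carrier but both failed the aneuploidy screen (`transfer no`); the four
transferable embryos are unaffected carriers with euploid profiles.
`results.concordance_with_truth(family.truth)` returns 1.0 — every call
matches the simulated ground truth.

The same workflow runs from the shell:

```
pgtphase simulate --out cohort --seed 7
pgtphase phase    --family-dir cohort/F1 --out cohort/F1/phased.tsv
pgtphase genotype --family-dir cohort/F1 --out cohort/F1/calls
pgtphase cnv      --counts cohort/F1/cnv_counts.tsv --out cohort/F1/cnv.tsv
pgtphase report   --out cohort_summary.json
pgtphase pipeline --out full_run --seed 7       # all stages end to end
```

`pgtphase report` also reproduces the packaged 36-family clinical
outcomes table: 217 biopsied blastocysts, 73.7% unaffected, 70.0% of
unaffected euploid, 6.0 biopsied and 3.1 transferable blastocysts per
couple — and the counseling probability that an n-embryo cohort contains
no affected reference, (3/4)ⁿ (≈ 10% at n = 8, `p_none_affected(8)`).

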