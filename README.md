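# pedsieve

Family-based exome variant prioritization for rare Mendelian disease.

Given an annotated multi-sample VCF for a single family, a pedigree, and a
handful of auxiliary tables (known-gene panel, local population frequencies,
gene-level priors, case/control carrier counts), `pedsieve` narrows tens of
thousands of exome variants down to a ranked shortlist of candidate causal
alleles for an autosomal-dominant trait. It was built around the analysis
design used in family studies of kidney stone disease — an 8-member,
two-generation family with four affected members — but every stage is
configurable and pedigree-agnostic.

The pipeline:

1. **Known-variant exclusion** — drop exact matches to a known-pathogenic
   panel; novel alleles in panel genes are kept and flagged.
2. **Dominant segregation filter** — keep variants heterozygous in *every*
   affected member and absent from *every* unaffected member.
3. **Consequence filter** — keep protein-altering and splice classes.
4. **Rarity filters** — population MAF < 0.01, local-database frequency < 0.01.
5. **Pathogenicity consensus** — damaging by ≥2 of {SIFT, PolyPhen-2, REVEL};
   score-less records bypass.
6. **Segregation LOD** — exact two-point parametric LOD per variant.
7. **Cohort screening & ranking** — carrier frequencies in case/control
   cohorts, common-polymorphism demotion, and a weighted evidence ranking.

A gene-dropping simulator generates full synthetic datasets (VCF + PED +
tables) with a planted causal variant and per-stage decoy classes, so the
whole pipeline is testable end to end without any private patient data.

## The LOD model

For a bi-allelic marker observed in a pedigree and a postulated disease
locus at recombination fraction θ, the likelihood is computed by exact
enumeration of phased two-locus configurations:

```
L(θ) = Σ_configs  Π_founders P(haplotypes | HWE, linkage equilibrium)
                × Π_children P(transmission | θ)
                × Π_members  P(phenotype | disease genotype)
```

with penetrances (f₀, f₁, f₂) = (0, 1, 1) and rare allele frequencies
(10⁻⁴) by default — the convention for a fully penetrant rare dominant
trait. The score is `LOD = log10 L(θ) − log10 L(0.5)`. Founder phase is
unknown and marginalized, so a family with one doubly heterozygous carrier
parent and n fully informative non-recombinant meioses attains the
classical phase-unknown maximum `(n−1)·log10 2`: 1.505 for n = 6, printed
as **1.50** under the truncation convention. Enumeration is exact and
auditable; pedigrees up to 12 members are supported.

## Worked example

```bash
pedsieve simulate --out sim --seed 7
pedsieve run-all --vcf sim/dataset.vcf --ped sim/family.ped \
    --cohort sim/cohort.tsv --panel-genes sim/panel_genes.txt \
    --panel-variants sim/panel_variants.tsv --local-db sim/local_af.tsv \
    --annotations sim/gene_annotations.tsv --out results
```

prints the funnel and the winner:

```
INFO stage exclude_known      61 ->     51
INFO stage ad_segregation     51 ->     41
INFO stage consequence        41 ->     31
INFO stage maf                31 ->     21
INFO stage local_db           21 ->     21
INFO stage consensus          21 ->     11
top candidate: HSPG2 1:500000:C:G (LOD 1.50, total 62.4211)
```

Each stage removes exactly the ten decoys built to fail it; the eleven
survivors are the planted causal variant plus ten cohort-polymorphism
decoys, which the screening stage then demotes (control carrier frequency
> 1%). The planted variant wins with LOD 1.50 — co-segregation in all four
affected members over six informative meioses — zero cohort carriers, and
the prior disease association of its gene. `results/` contains the funnel
counts (TSV/JSON), per-variant LOD results, the screen, the ranking, and a
summary table whose cells print carrier counts as `count (frequency)` with
frequencies truncated to three decimals (e.g. `8/179 → 0.044`).

The same steps are available as library calls; see `examples/` for short
scripts covering simulation, filtering, LOD scoring, consensus
categorization, and ranking.

## Layout

- `src/pedsieve/ped_io.py` — pedigree model, PED reader/writer
- `src/pedsieve/variant_io.py` — annotated VCF reader (cyvcf2), VCF writer,
  auxiliary tables
- `src/pedsieve/funnel.py` — the ordered filtering funnel and its report
- `src/pedsieve/pathogenicity.py` — score categorization, k-of-3 consensus
- `src/pedsieve/lod.py` — exact two-point parametric LOD engine
- `src/pedsieve/screening.py` — cohort screening, frequency dialects, ranking
- `src/pedsieve/simulate.py` — gene-dropping dataset generator
- `src/pedsieve/cli.py` — `pedsieve` command-line front end

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
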