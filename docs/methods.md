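# Methods

## Scope and data model

`pedsieve` prioritizes candidate causal variants for a fully penetrant
autosomal-dominant trait in a single small family. It consumes an
*already annotated* multi-sample VCF — gene symbol, collapsed consequence
class, population allele frequency and SIFT/PolyPhen-2/REVEL scores in
INFO fields whose names are configurable — and never re-annotates.
Coordinates are 1-based VCF positions throughout; records are normalized
to bi-allelic on read (multi-allelic sites split per ALT, dosages
re-expressed against each ALT). Missing annotations stay missing: absence
of evidence is represented as `None`, never as a default value.

`pop_af` is the **maximum** over the configured population-frequency
fields. When several databases are consulted, the maximum is the
conservative aggregation for a rarity filter: a variant common in any one
database is not a novel-disease candidate.

## The filtering funnel

Stages are pure conjunctive predicates applied in a fixed order
(known-variant exclusion → dominant segregation → consequence → population
MAF → local database → pathogenicity consensus). Because each stage is a
per-record predicate, the final survivor set is invariant under stage
permutation; only the per-stage counts depend on order. The shipped order
follows the narrative order such analyses are usually reported in, and a
test asserts the permutation invariance.

Decisions where the design was genuinely open:

- **Missing genotypes.** A missing call in an *affected* member excludes
  the variant: a causal dominant allele must be observable in every
  affected carrier. A missing call in an *unaffected* member also excludes
  by default — "absent in unaffected" is unverifiable on a missing call —
  but a `lenient_unaffected` switch tolerates it, for sparse call sets.
- **Hom-alt calls.** Any homozygous-ALT call anywhere excludes: under a
  rare fully penetrant dominant model the causal allele is heterozygous in
  carriers and absent elsewhere.
- **Missing population AF is treated as rare** (kept): novel variants
  absent from the databases are precisely the discovery target.
- **Consequence set.** The default retained set is the union of the
  protein-altering classes (missense, stop gain/loss, indel) and the
  splice classes (splice region, splice site); it is configurable because
  reasonable analyses differ on whether splice-region records belong in
  the first-pass set.
- **Panel semantics.** Only exact (chrom, pos, ref, alt) matches to the
  known-pathogenic list are excluded. A novel allele inside a panel gene is
  retained and flagged `panel_gene=True` — known disease genes harbouring
  new alleles are candidates, not exclusions.

## Pathogenicity consensus

The consensus rule is "damaging by at least k of the n tools with a
score" with k = 2 of 3. Raw scores are kept in each tool's native
orientation (SIFT low = deleterious) and categorized only at evaluation:
SIFT < 0.05 → D; PolyPhen-2 ≥ 0.446 → possibly damaging (P), ≥ 0.908 →
probably damaging (PD); REVEL ≥ 0.5 → damaging. These are the tools'
published conventions; they reproduce the category letters of the
reference score profiles the test suite carries. Two switches matter:

- `polyphen_strict` — count only "probably damaging" toward the consensus
  (default off: P counts too, since published tables rarely distinguish).
- Records with fewer than `evaluable_min` scores **bypass** the consensus
  (default: retained). Splice-region and intronic records typically carry
  no missense predictor scores; failing them for score absence would
  silently delete a whole consequence class.

A known tension, reported rather than resolved: a candidate missense
variant damaging by PolyPhen alone (letters N/T/PD) *fails* the strict
2-of-3 rule. The funnel applies the rule as stated; recovering such a
variant requires an explicit, logged override (`--no-consensus` or
`--consensus-k 1`), never a silent exception. One published summary table
this package's tests mirror prints "D" where its other rows print "PD" for
PolyPhen probabilities ≥ 0.908; both abbreviations denote "probably
damaging" and the categorizer emits "PD".

## Two-point parametric LOD

The likelihood is computed by exact enumeration of phased two-locus
diplotypes (haplotype = disease allele × marker allele), with founder
priors from Hardy–Weinberg and linkage equilibrium, transmission
probabilities with recombination fraction θ, and penetrance terms
(f₀, f₁, f₂) on disease-genotype copies. Implementation notes:

- **Constraint propagation, not peeling.** Children's haplotypes are
  restricted to parental transmissions; members without offspring are
  summed out analytically at their parents' node. In-scope pedigrees are
  ≤ 12 members (hard capacity error beyond), where an exact, auditable
  enumeration is worth more than Elston–Stewart scalability. An
  independent flat-product oracle in the test suite verifies both the
  likelihood and the count of positive-probability configurations.
- **Founder phase is marginalized** (both phases weighted by their
  haplotype priors). This is what makes six informative meioses yield
  (6−1)·log10 2 = 1.505 rather than 6·log10 2 = 1.806.
- **Defaults**: θ = 0, disease and marker allele frequencies 10⁻⁴,
  penetrance (0, 1, 1). No penetrance or frequency model is usually stated
  alongside a quoted family LOD; the fully penetrant rare-dominant
  convention is the one that makes a 6-meiosis family print 1.50. All four
  parameters are configuration.
- **Untyped members** are marginalized by the summation; an untyped
  *affected* member additionally logs a warning, since it silently costs
  an informative meiosis.
- **Obligate recombinants**: if L(θ=0) = 0, the numerator is maximized
  over the grid θ ∈ {0.01, 0.05, 0.1, 0.2, 0.3, 0.4} and the grid point is
  recorded in the result.
- **Reporting**: the LOD is truncated (not rounded) to two decimals in
  human-readable reports — the convention under which an exact 1.505
  prints as 1.50 — with full precision retained in JSON output.
- LOD(θ = 0.5) is exactly 0 by construction (numerator and denominator are
  the same computation), and the suite asserts this identity on random
  pedigrees.

## Cohort screening and ranking

Carrier (heterozygote) frequency — the fraction of *individuals* carrying
the allele, not the fraction of chromosomes — is formatted by **truncation**
to three decimals, the dialect that reproduces reference cells such as
8/179 → 0.044 (rounding would give 0.045); the computation uses exact
integer arithmetic, and the mode is switchable. Database allele
frequencies are *rounded* at the database's printed precision (8/140282 at
six decimals → 0.000057). A variant is a common polymorphism when its
exact control carrier fraction strictly exceeds 1%.

Ranking uses a weighted evidence total over six components — segregation
(weight 32), zero cohort carriers (16), prior disease association (8),
predictor consensus (4), kidney expression (2), and an externally supplied
gene-prioritization score scaled to ≤ 1 — so the binary components order
candidates lexicographically. Polymorphisms are demoted below all
non-polymorphisms regardless of total: common-in-controls is treated as a
veto on causality, not one more weighted vote, because a polymorphism in a
well-annotated disease gene would otherwise outscore a rare segregating
variant in an unannotated one. Ties break on (chrom, pos, ref, alt), so
ranking is a deterministic function of its inputs. External gene scores
are consumed as inputs and never recomputed — they derive from database
snapshots that are not reproducible. A per-variant `validated: false`
override removes wet-lab false positives before ranking.

## The simulator

`simulate` emulates the statistical structure the funnel assumes, not
sequencing itself. Gene dropping places a single heterozygous founder
allele and transmits it down the pedigree with independent fair meioses;
every emitted genotype configuration is Mendelian-consistent by
construction and checked by an independent validator in the tests. The
default pedigree is the 8-member study structure (2 founders, 6 offspring,
4 affected), so a planted causal variant reproduces the 1.50 LOD
end-to-end from generated files. Default cohort sizes are 180 controls and
179 cases, the screening design the package mirrors.

Decoy classes map one-to-one onto funnel stages (non-segregating, common
MAF, excluded consequence, benign consensus, known panel variant), plus
cohort polymorphisms (survive the funnel, demoted at screening) and
optional pass-all decoys. Every drawn score or frequency keeps a guard
band of 0.005 from the nearest threshold so no outcome depends on
tie-breaking at a boundary; generation is verified post hoc — each decoy
must fail exactly its designated stage in isolation — and a violation
raises instead of shipping a broken dataset. One seeded integer RNG stream
drives all draws and floats are quantized before writing, so a fixed seed
yields byte-identical files.

What the simulator does **not** model — and hence what passing tests do
not show about real data: sequencing error and genotype miscalls, linkage
disequilibrium between sites, transcript-dependent annotation ambiguity,
genome-scale variant counts (tens of decoys, not 57,000 exome variants —
correctness of the predicates, not scale, is what the synthetic data can
establish), population structure in the cohorts, and phenocopies or
reduced penetrance in the family.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by design: exact
LOD enumeration on pedigrees of ≤ 8 members (oracle comparisons at ≤ 6),
funnels of ~50–60 records across 10 seeds, 10,000 gene drops for the
per-offspring carrier-rate check and 100,000 for the exact-pattern
frequency check (expected rate (1/2)⁶, asserted within three binomial
standard errors). The whole suite completes in seconds.

## Known limitations

- Only the autosomal-dominant model is implemented; recessive,
  compound-heterozygous and X-linked modes are out of scope (the CLI
  reserves no behavior for them).
- Single-family analysis; no multi-family or association statistics
  (no odds ratios or exact tests on the cohort counts).
- Two-point LOD only — no multipoint linkage, liability classes, or
  simulation-based empirical p-values.
- The PED dialect is single-family, six mandatory columns; loops beyond
  the acyclicity check (e.g. consanguinity) are not modeled.
- Phase from the VCF is ignored (phased separators read as unphased):
  the LOD model marginalizes phase, and no other stage uses it.
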