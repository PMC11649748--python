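"""Gene-dropping simulator for family exome datasets.

Generates, for a configurable pedigree, an annotated multi-sample VCF with
one planted causal variant plus decoy variants engineered to fail exactly
one designated funnel stage each, together with the PED file, case/control
carrier-count table, known-gene panel, local frequency table, gene
annotations, a truth table labelling every record with its class, and a
manifest recording the configuration and seed.

The default pedigree is the study structure: two founders, six offspring,
four affected members (the father and three offspring) — so a planted
variant heterozygous in exactly the affected members yields the classical
phase-unknown dominant LOD of (6−1)·log10 2 ≈ 1.505.

Determinism: one integer-seeded RNG stream drives everything; genotype
draws use integer draws only and every float annotation is quantized before
being written, so a fixed seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._errors import ConfigError
from .funnel import (
    FunnelConfig,
    ad_segregation_filter,
    consequence_filter,
    consensus_filter,
    exclude_known,
    local_db_filter,
    maf_filter,
)
from .pathogenicity import ConsensusRule
from .ped_io import Affection, Individual, Pedigree, Sex, write_ped
from .screening import CohortScreen, write_cohort_screens
from .variant_io import (
    Consequence,
    GenotypeCall,
    LocalFrequencyTable,
    PanelSet,
    ScoreBundle,
    VariantRecord,
    write_vcf,
)

__all__ = [
    "DECOY_CLASSES",
    "SimConfig",
    "default_pedigree",
    "gene_drop",
    "gene_drop_many",
    "plant_causal_variant",
    "generate_dataset",
]

DECOY_CLASSES = (
    "non_segregating",
    "common_maf",
    "excluded_consequence",
    "benign_consensus",
    "known_panel_variant",
    "cohort_polymorphism",
    "pass_all_decoy",
)
#: classes removed by a funnel stage (the rest survive to screening/ranking)
FUNNEL_FAILING_CLASSES = frozenset(
    {
        "non_segregating",
        "common_maf",
        "excluded_consequence",
        "benign_consensus",
        "known_panel_variant",
    }
)

#: margin kept between any drawn score/frequency and the nearest threshold,
#: so no test outcome depends on tie-breaking at a boundary
GUARD_BAND = 0.005


def default_pedigree() -> Pedigree:
    """Two-generation family: affected father, unaffected mother, six
    offspring of whom three are affected."""
    members = [
        Individual("I:1", sex=Sex.MALE, affection=Affection.AFFECTED),
        Individual("I:2", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
    ]
    affected_children = {"II:1", "II:3", "II:4"}
    sexes = {
        "II:1": Sex.MALE,
        "II:2": Sex.MALE,
        "II:3": Sex.FEMALE,
        "II:4": Sex.FEMALE,
        "II:5": Sex.MALE,
        "II:6": Sex.MALE,
    }
    for i in range(1, 7):
        iid = f"II:{i}"
        members.append(
            Individual(
                iid,
                father_id="I:1",
                mother_id="I:2",
                sex=sexes[iid],
                affection=(
                    Affection.AFFECTED
                    if iid in affected_children
                    else Affection.UNAFFECTED
                ),
            )
        )
    return Pedigree("FAM1", members)


@dataclass
class SimConfig:
    """Study-condition parameters for one generated dataset."""

    pedigree: Pedigree = field(default_factory=default_pedigree)
    founder_carrier: str = "I:1"
    n_decoys_per_class: int = 10
    decoy_classes: tuple[str, ...] = DECOY_CLASSES[:6]  # all but pass_all_decoy
    n_controls: int = 180
    n_cases: int = 179
    seed: int = 0
    published_profile: bool = False
    causal_gene: str = "HSPG2"
    funnel_config: FunnelConfig = field(default_factory=FunnelConfig)
    consensus_rule: ConsensusRule = field(default_factory=ConsensusRule)

    def __post_init__(self) -> None:
        unknown = set(self.decoy_classes) - set(DECOY_CLASSES)
        if unknown:
            raise ConfigError(f"unknown decoy classes: {sorted(unknown)}")
        if not self.decoy_classes:
            raise ConfigError("decoy_classes must be non-empty")
        if self.n_decoys_per_class < 0:
            raise ConfigError("n_decoys_per_class must be >= 0")
        if (
            "benign_consensus" in self.decoy_classes
            and not self.funnel_config.apply_consensus
        ):
            raise ConfigError(
                "benign_consensus decoys are unsatisfiable with the consensus "
                "stage disabled (funnel_config.apply_consensus=False)"
            )


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def gene_drop_many(
    ped: Pedigree,
    founder_carrier: str,
    n: int,
    rng: np.random.Generator | int,
) -> tuple[list[str], np.ndarray]:
    """Drop a single heterozygous founder allele down the pedigree n times.

    Returns (sample order, (n, n_members) array of ALT dosages). The carrier
    founder is het, other founders hom-ref, and every meiosis transmits one
    of the parent's two alleles with equal probability, independently.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    carrier = ped.member(founder_carrier)
    if not carrier.is_founder:
        raise ConfigError(f"{founder_carrier!r} is not a founder")
    order = ped.founders_first()
    # two allele arrays per individual, shape (n,)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    zeros = np.zeros(n, dtype=np.int8)
    ones = np.ones(n, dtype=np.int8)
    for m in order:
        if m.is_founder:
            if m.individual_id == founder_carrier:
                alleles[m.individual_id] = (ones, zeros)
            else:
                alleles[m.individual_id] = (zeros, zeros)
        else:
            pa0, pa1 = alleles[m.father_id]
            ma0, ma1 = alleles[m.mother_id]
            cp = rng.integers(0, 2, size=n)
            cm = rng.integers(0, 2, size=n)
            alleles[m.individual_id] = (
                np.where(cp == 1, pa1, pa0),
                np.where(cm == 1, ma1, ma0),
            )
    samples = [m.individual_id for m in ped.members]
    dosages = np.stack(
        [alleles[s][0] + alleles[s][1] for s in samples], axis=1
    ).astype(np.int8)
    return samples, dosages


def gene_drop(
    ped: Pedigree, founder_carrier: str, rng: np.random.Generator | int
) -> dict[str, int]:
    """One gene drop: map sample id → ALT dosage (Mendelian-consistent)."""
    samples, dosages = gene_drop_many(ped, founder_carrier, 1, rng)
    return {s: int(d) for s, d in zip(samples, dosages[0])}


# ---------------------------------------------------------------------------
# record construction
# ---------------------------------------------------------------------------


def _genotypes_from_pattern(
    ped: Pedigree, dosages: dict[str, int]
) -> tuple[GenotypeCall, ...]:
    return tuple(
        GenotypeCall(s, dosages.get(s, 0)) for s in ped.sample_ids
    )


def _segregating_pattern(ped: Pedigree) -> dict[str, int]:
    return {s: 1 for s in ped.affected_ids}


def plant_causal_variant(
    ped: Pedigree,
    published_profile: bool = False,
    gene: str = "HSPG2",
    chrom: str = "1",
    pos: int = 500_000,
) -> VariantRecord:
    """The planted causal record: het in exactly the affected members,
    hom-ref elsewhere; missense; absent from population databases.

    Default scores pass the 2-of-3 consensus. With ``published_profile`` the
    scores mirror the published candidate's profile — damaging by PolyPhen
    only (letters N, T, PD) — so the record survives the funnel only when
    the consensus stage is bypassed or relaxed.
    """
    if ped.n_affected < 1:
        raise ConfigError("pedigree has no affected members")
    scores = (
        ScoreBundle(sift=0.171, polyphen=0.997, revel=0.478)
        if published_profile
        else ScoreBundle(sift=0.01, polyphen=0.99, revel=0.8)
    )
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="C",
        alt="G",
        gene=gene,
        consequence=Consequence.MISSENSE,
        pop_af=None,  # novel with respect to the population databases
        scores=scores,
        genotypes=_genotypes_from_pattern(ped, _segregating_pattern(ped)),
    )


_REF_ALT = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def _rand_unit(rng: np.random.Generator, lo: float, hi: float, decimals: int) -> float:
    return round(float(rng.uniform(lo, hi)), decimals)


def _make_decoy(
    cls: str,
    idx: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    pos: int,
) -> VariantRecord:
    ped = cfg.pedigree
    rule = cfg.consensus_rule
    fc = cfg.funnel_config
    ref, alt = _REF_ALT[idx % len(_REF_ALT)]
    gene = f"DEC{idx:03d}{cls[:4].upper()}"

    # perfect baseline: segregates, retained consequence, rare, damaging scores
    pattern = _segregating_pattern(ped)
    consequence = Consequence.MISSENSE
    pop_af = _rand_unit(rng, 0.0, cfg.funnel_config.maf_threshold - GUARD_BAND, 4)
    scores = ScoreBundle(
        sift=_rand_unit(rng, 0.0, max(rule.sift_deleterious_max - GUARD_BAND, 0.0), 3),
        polyphen=_rand_unit(rng, rule.polyphen_probably_min + GUARD_BAND, 1.0, 3),
        revel=_rand_unit(rng, rule.revel_damaging_min + GUARD_BAND, 1.0, 3),
    )

    if cls == "non_segregating":
        # realistic Mendelian pattern that is not the affected-only pattern
        target = {s: pattern.get(s, 0) for s in ped.sample_ids}
        while True:
            drop = gene_drop(ped, cfg.founder_carrier, rng)
            if drop != target:
                pattern = drop
                break
    elif cls == "common_maf":
        pop_af = _rand_unit(rng, fc.maf_threshold + GUARD_BAND, 0.5, 4)
    elif cls == "excluded_consequence":
        consequence = (
            Consequence.SYNONYMOUS if idx % 2 == 0 else Consequence.INTRONIC
        )
        scores = ScoreBundle()  # no predictor scores, as for non-coding records
    elif cls == "benign_consensus":
        scores = ScoreBundle(
            sift=_rand_unit(rng, rule.sift_deleterious_max + GUARD_BAND, 1.0, 3),
            polyphen=_rand_unit(
                rng, 0.0, max(rule.polyphen_damaging_min - GUARD_BAND, 0.0), 3
            ),
            revel=_rand_unit(
                rng, 0.0, max(rule.revel_damaging_min - GUARD_BAND, 0.0), 3
            ),
        )
    elif cls in ("known_panel_variant", "cohort_polymorphism", "pass_all_decoy"):
        pass  # baseline already correct; panel/cohort handled by the caller
    else:  # pragma: no cover
        raise ConfigError(f"unknown decoy class {cls!r}")

    return VariantRecord(
        chrom="1",
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        pop_af=pop_af,
        scores=scores,
        genotypes=_genotypes_from_pattern(ped, pattern),
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset; return a map of output paths.

    Every decoy is verified post hoc to fail exactly its designated funnel
    stage (and no other) when stages are applied in isolation; a violation
    raises rather than silently shipping a broken fixture.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ped = cfg.pedigree

    causal = plant_causal_variant(
        ped, published_profile=cfg.published_profile, gene=cfg.causal_gene
    )
    records: list[VariantRecord] = [causal]
    truth: list[tuple[VariantRecord, str]] = [(causal, "causal")]
    panel = PanelSet()
    local_freqs: dict[tuple, float] = {}
    screens: dict[tuple, CohortScreen] = {}

    pos = 1_000_000
    for cls in cfg.decoy_classes:
        for i in range(cfg.n_decoys_per_class):
            v = _make_decoy(cls, len(records), cfg, rng, pos)
            pos += 997
            if cls == "known_panel_variant":
                panel.known_variants.add(v.key)
                panel.genes.add(v.gene)
            records.append(v)
            truth.append((v, cls))

    # cohort carrier counts: polymorphism decoys common in controls, the
    # causal variant and everything else absent from both cohorts
    for v, cls in truth:
        if cls == "cohort_polymorphism":
            het_controls = int(rng.integers(4, 20))  # >= 4/180 ≈ 0.022 > 1%
            het_cases = int(rng.integers(0, 12))
        else:
            het_controls = het_cases = 0
        screens[v.key] = CohortScreen(
            key=v.key,
            n_controls=cfg.n_controls,
            n_cases=cfg.n_cases,
            het_controls=het_controls,
            het_cases=het_cases,
        )

    # local frequency table: sub-threshold entries for a few decoys so the
    # lookup path is exercised without changing any stage outcome
    for v, cls in truth:
        if cls in ("cohort_polymorphism", "pass_all_decoy"):
            local_freqs[v.key] = _rand_unit(
                rng, 0.0, cfg.funnel_config.local_af_threshold - GUARD_BAND, 4
            )

    _verify_classes(records, truth, cfg, panel, LocalFrequencyTable(dict(local_freqs)))

    paths = {
        "vcf": outdir / "dataset.vcf",
        "ped": outdir / "family.ped",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "truth.tsv",
        "panel_genes": outdir / "panel_genes.txt",
        "panel_variants": outdir / "panel_variants.tsv",
        "local_af": outdir / "local_af.tsv",
        "annotations": outdir / "gene_annotations.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(records, paths["vcf"], samples=ped.sample_ids)
    write_ped(ped, paths["ped"])
    write_cohort_screens(screens, paths["cohort"])

    truth_lines = ["chrom\tpos\tref\talt\tgene\tclass"]
    truth_lines += [
        f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t{cls}" for v, cls in truth
    ]
    paths["truth"].write_text("\n".join(truth_lines) + "\n")

    paths["panel_genes"].write_text(
        "\n".join(sorted(panel.genes)) + ("\n" if panel.genes else "")
    )
    pv_lines = ["chrom\tpos\tref\talt"]
    pv_lines += ["\t".join(map(str, k)) for k in sorted(panel.known_variants)]
    paths["panel_variants"].write_text("\n".join(pv_lines) + "\n")

    la_lines = ["chrom\tpos\tref\talt\tfreq"]
    la_lines += [
        "\t".join(map(str, [*k, f])) for k, f in sorted(local_freqs.items())
    ]
    paths["local_af"].write_text("\n".join(la_lines) + "\n")

    ann_lines = ["gene\tkidney_expressed\tprior_association\tprior_score"]
    ann_lines.append(f"{cfg.causal_gene}\t1\t1\t29.6")
    for v, cls in truth[1:]:
        kidney = int(rng.integers(0, 2))
        score = round(float(rng.uniform(0, 80)), 1)
        ann_lines.append(f"{v.gene}\t{kidney}\t0\t{score}")
    paths["annotations"].write_text("\n".join(ann_lines) + "\n")

    manifest = {
        "seed": cfg.seed,
        "pedigree": {
            "family_id": ped.family_id,
            "n_members": ped.n_members,
            "n_affected": ped.n_affected,
        },
        "founder_carrier": cfg.founder_carrier,
        "n_decoys_per_class": cfg.n_decoys_per_class,
        "decoy_classes": list(cfg.decoy_classes),
        "n_controls": cfg.n_controls,
        "n_cases": cfg.n_cases,
        "published_profile": cfg.published_profile,
        "causal_gene": cfg.causal_gene,
        "n_records": len(records),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def _verify_classes(
    records: list[VariantRecord],
    truth: list[tuple[VariantRecord, str]],
    cfg: SimConfig,
    panel: PanelSet,
    local: LocalFrequencyTable,
) -> None:
    """Assert each decoy fails its designated stage in isolation and passes
    every other stage."""
    ped = cfg.pedigree
    fc = cfg.funnel_config
    rule = cfg.consensus_rule
    stage_of = {
        "known_panel_variant": "exclude_known",
        "non_segregating": "ad_segregation",
        "excluded_consequence": "consequence",
        "common_maf": "maf",
        "benign_consensus": "consensus",
    }
    stages = {
        "exclude_known": lambda vs: exclude_known(vs, panel),
        "ad_segregation": lambda vs: ad_segregation_filter(
            vs, ped, fc.lenient_unaffected
        ),
        "consequence": lambda vs: consequence_filter(vs, fc),
        "maf": lambda vs: maf_filter(vs, fc),
        "local_db": lambda vs: local_db_filter(vs, local, fc),
    }
    if fc.apply_consensus:
        stages["consensus"] = lambda vs: consensus_filter(vs, rule)
    for v, cls in truth:
        failing_stage = stage_of.get(cls)
        for name, fn in stages.items():
            survived = bool(fn([v]))
            expect_survive = name != failing_stage
            if cls == "causal" and cfg.published_profile and name == "consensus":
                expect_survive = False  # published 1-of-3 profile fails k=2
            if survived != expect_survive:
                raise AssertionError(
                    f"{cls} decoy {v.key_str} {'passed' if survived else 'failed'} "
                    f"stage {name!r} unexpectedly"
                )
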