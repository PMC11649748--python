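"""Filtering-funnel stages: unit examples, exhaustive oracles, invariants."""

from __future__ import annotations

import itertools
import random

import pytest

from pedsieve._errors import ConfigError
from pedsieve.funnel import (
    FunnelConfig,
    ad_segregation_filter,
    consequence_filter,
    consensus_filter,
    exclude_known,
    local_db_filter,
    maf_filter,
    run_funnel,
)
from pedsieve.pathogenicity import ConsensusRule, consensus_pass
from pedsieve.simulate import SimConfig, generate_dataset
from pedsieve.variant_io import (
    Consequence,
    LocalFrequencyTable,
    PanelSet,
    ScoreBundle,
    read_annotated_vcf,
    read_local_frequency_table,
    read_panel,
)
from tests.conftest import make_variant


@pytest.fixture
def seg_pattern(family8):
    return {s: 1 for s in family8.affected_ids}


class TestExcludeKnown:
    def test_exact_match_removed(self, family8, seg_pattern):
        vs = [make_variant(family8, seg_pattern, pos=p) for p in (10, 20, 30)]
        panel = PanelSet(known_variants={vs[1].key})
        out = exclude_known(vs, panel)
        assert [v.pos for v in out] == [10, 30]

    def test_empty_panel_is_identity(self, family8, seg_pattern):
        vs = [make_variant(family8, seg_pattern)]
        assert exclude_known(vs, PanelSet()) == vs

    def test_panel_gene_without_coordinate_match_is_flagged_not_dropped(
        self, family8, seg_pattern
    ):
        v = make_variant(family8, seg_pattern, gene="HSPG2")
        (out,) = exclude_known([v], PanelSet(genes={"HSPG2"}))
        assert out.panel_gene is True


class TestAdSegregation:
    def test_affected_het_unaffected_ref_is_kept(self, family8, seg_pattern):
        v = make_variant(family8, seg_pattern)
        assert ad_segregation_filter([v], family8) == [v]

    def test_het_in_everyone_is_excluded(self, family8):
        v = make_variant(family8, {s: 1 for s in family8.sample_ids})
        assert ad_segregation_filter([v], family8) == []

    def test_hom_alt_anywhere_excludes(self, family8, seg_pattern):
        pattern = dict(seg_pattern, **{"I:1": 2})
        v = make_variant(family8, pattern)
        assert ad_segregation_filter([v], family8) == []

    def test_missing_call_in_affected_excludes(self, family8, seg_pattern):
        v = make_variant(family8, dict(seg_pattern, **{"II:1": None}))
        assert ad_segregation_filter([v], family8) == []

    def test_missing_in_unaffected_strict_vs_lenient(self, family8, seg_pattern):
        v = make_variant(family8, dict(seg_pattern, **{"II:2": None}))
        assert ad_segregation_filter([v], family8) == []
        assert ad_segregation_filter([v], family8, lenient_unaffected=True) == [v]

    def test_exhaustive_hom_ref_het_patterns_keep_exactly_one(self, family8):
        """Over all 2^8 hom-ref/het patterns only the affected-exclusive one
        survives (exhaustive enumeration oracle)."""
        affected = set(family8.affected_ids)
        kept = []
        for bits in itertools.product((0, 1), repeat=8):
            pattern = dict(zip(family8.sample_ids, bits))
            v = make_variant(family8, pattern)
            if ad_segregation_filter([v], family8):
                kept.append(pattern)
        assert len(kept) == 1
        assert {s for s, d in kept[0].items() if d == 1} == affected

    def test_pedigree_vcf_sample_mismatch_is_config_error(self, family8, seg_pattern):
        v = make_variant(family8, seg_pattern)
        v = v.with_flags(genotypes=v.genotypes[:-1])  # drop II:6's column
        with pytest.raises(ConfigError, match="II:6"):
            ad_segregation_filter([v], family8)


class TestConsequenceMafLocal:
    def test_splice_region_kept_synonymous_excluded(self, family8, seg_pattern):
        keep = make_variant(
            family8, seg_pattern, consequence=Consequence.SPLICE_REGION
        )
        drop = make_variant(
            family8, seg_pattern, pos=2, consequence=Consequence.SYNONYMOUS
        )
        assert consequence_filter([keep, drop]) == [keep]

    def test_missing_consequence_excluded(self, family8, seg_pattern):
        v = make_variant(family8, seg_pattern, consequence=None)
        assert consequence_filter([v]) == []

    def test_retained_class_count_by_construction(self, family8, seg_pattern):
        classes = [
            Consequence.MISSENSE,
            Consequence.STOP_GAIN,
            Consequence.SPLICE_SITE,
            Consequence.INDEL,
            Consequence.SYNONYMOUS,
            Consequence.INTRONIC,
            Consequence.OTHER,
            Consequence.SYNONYMOUS,
            Consequence.INTRONIC,
            Consequence.OTHER,
        ]
        vs = [
            make_variant(family8, seg_pattern, pos=i + 1, consequence=c)
            for i, c in enumerate(classes)
        ]
        assert len(consequence_filter(vs)) == 4

    @pytest.mark.parametrize(
        "af,kept",
        [(0.00008, True), (0.5, False), (0.01, False), (None, True), (0.0099, True)],
    )
    def test_maf_strict_threshold(self, family8, seg_pattern, af, kept):
        v = make_variant(family8, seg_pattern, pop_af=af)
        assert bool(maf_filter([v])) is kept

    def test_local_db_filter(self, family8, seg_pattern):
        vs = [make_variant(family8, seg_pattern, pos=p) for p in range(1, 7)]
        local = LocalFrequencyTable(
            {vs[0].key: 0.02, vs[1].key: 0.15, vs[2].key: 0.001}
        )
        out = local_db_filter(vs, local)
        assert len(out) == 4  # two listed above threshold removed
        assert vs[2] in out  # below-threshold entry retained


def _predicates(ped, panel, local, cfg, rule):
    """Brute-force per-record conjunction of the stage predicates."""

    def ok(v):
        if v.key in panel.known_variants:
            return False
        if not ad_segregation_filter([v], ped, cfg.lenient_unaffected):
            return False
        if v.consequence is None or v.consequence not in cfg.retained_consequences:
            return False
        if v.pop_af is not None and v.pop_af >= cfg.maf_threshold:
            return False
        f = local.get(v.key)
        if f is not None and f >= cfg.local_af_threshold:
            return False
        if cfg.apply_consensus and not consensus_pass(v.scores, rule)[2]:
            return False
        return True

    return ok


class TestRunFunnel:
    @pytest.fixture()
    def dataset(self, tmp_path):
        cfg = SimConfig(seed=11, n_decoys_per_class=10)
        paths = generate_dataset(cfg, tmp_path / "sim")
        return cfg, paths

    def test_synthetic_dataset_keeps_planted_plus_passalls(self, dataset):
        cfg, paths = dataset
        variants = read_annotated_vcf(paths["vcf"])
        panel = read_panel(paths["panel_genes"], paths["panel_variants"])
        local = read_local_frequency_table(paths["local_af"])
        survivors, report = run_funnel(variants, cfg.pedigree, panel, local)
        genes = {v.gene for v in survivors}
        assert cfg.causal_gene in genes
        # survivors = planted + cohort_polymorphism decoys (screened out later)
        assert len(survivors) == 1 + cfg.n_decoys_per_class
        # per-stage counts match the construction: each funnel-failing class
        # is removed exactly at its stage
        assert [(s, i, o) for s, i, o in report.stages] == [
            ("exclude_known", 61, 51),
            ("ad_segregation", 51, 41),
            ("consequence", 41, 31),
            ("maf", 31, 21),
            ("local_db", 21, 21),
            ("consensus", 21, 11),
        ]

    def test_empty_input_gives_zero_report(self, family8):
        survivors, report = run_funnel([], family8)
        assert survivors == []
        assert all(i == 0 and o == 0 for _, i, o in report.stages)

    def test_consensus_ablation_matches_first_five_stages(self, dataset):
        cfg, paths = dataset
        variants = read_annotated_vcf(paths["vcf"])
        panel = read_panel(paths["panel_genes"], paths["panel_variants"])
        local = read_local_frequency_table(paths["local_af"])
        no_consensus = FunnelConfig(apply_consensus=False)
        survivors_off, report_off = run_funnel(
            variants, cfg.pedigree, panel, local, no_consensus
        )
        _, report_on = run_funnel(variants, cfg.pedigree, panel, local)
        assert [s for s, _, _ in report_off.stages] == [
            s for s, _, _ in report_on.stages[:-1]
        ]
        # the ablated run reproduces the survivor set entering the consensus stage
        assert len(survivors_off) == report_on.stages[-1][1]
        survivors_on, _ = run_funnel(variants, cfg.pedigree, panel, local)
        assert {v.key for v in survivors_on} == {
            v.key
            for v in survivors_off
            if consensus_pass(v.scores, ConsensusRule())[2]
        }

    def test_funnel_matches_brute_force_predicates(self, dataset):
        cfg, paths = dataset
        variants = read_annotated_vcf(paths["vcf"])[:12]
        panel = read_panel(paths["panel_genes"], paths["panel_variants"])
        local = read_local_frequency_table(paths["local_af"])
        fc, rule = FunnelConfig(), ConsensusRule()
        ok = _predicates(cfg.pedigree, panel, local, fc, rule)
        survivors, _ = run_funnel(variants, cfg.pedigree, panel, local, fc, rule)
        assert {v.key for v in survivors} == {v.key for v in variants if ok(v)}

    def test_stage_permutation_leaves_survivor_set_unchanged(self, dataset):
        cfg, paths = dataset
        variants = read_annotated_vcf(paths["vcf"])
        panel = read_panel(paths["panel_genes"], paths["panel_variants"])
        local = read_local_frequency_table(paths["local_af"])
        fc, rule = FunnelConfig(), ConsensusRule()
        stages = [
            lambda vs: exclude_known(vs, panel),
            lambda vs: ad_segregation_filter(vs, cfg.pedigree),
            lambda vs: consequence_filter(vs, fc),
            lambda vs: maf_filter(vs, fc),
            lambda vs: local_db_filter(vs, local, fc),
            lambda vs: consensus_filter(vs, rule),
        ]
        baseline, _ = run_funnel(variants, cfg.pedigree, panel, local, fc, rule)
        baseline_keys = {v.key for v in baseline}
        rng = random.Random(5)
        for _ in range(5):
            order = stages[:]
            rng.shuffle(order)
            out = variants
            for stage in order:
                out = stage(out)
            assert {v.key for v in out} == baseline_keys

    def test_each_filter_is_idempotent(self, dataset):
        cfg, paths = dataset
        variants = read_annotated_vcf(paths["vcf"])
        panel = read_panel(paths["panel_genes"], paths["panel_variants"])
        local = read_local_frequency_table(paths["local_af"])
        fc, rule = FunnelConfig(), ConsensusRule()
        for stage in (
            lambda vs: exclude_known(vs, panel),
            lambda vs: ad_segregation_filter(vs, cfg.pedigree),
            lambda vs: consequence_filter(vs, fc),
            lambda vs: maf_filter(vs, fc),
            lambda vs: local_db_filter(vs, local, fc),
            lambda vs: consensus_filter(vs, rule),
        ):
            once = stage(variants)
            assert stage(once) == once

    def test_report_monotone_and_chained(self, dataset):
        cfg, paths = dataset
        variants = read_annotated_vcf(paths["vcf"])
        _, report = run_funnel(variants, cfg.pedigree)
        for (_, n_in, n_out), (_, next_in, _) in zip(
            report.stages, report.stages[1:]
        ):
            assert n_out <= n_in
            assert next_in == n_out


class TestFunnelConfig:
    def test_threshold_bounds(self):
        with pytest.raises(ConfigError):
            FunnelConfig(maf_threshold=0.0)
        with pytest.raises(ConfigError):
            FunnelConfig(local_af_threshold=1.5)
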