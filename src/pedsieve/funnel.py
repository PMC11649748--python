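"""The ordered variant-filtering funnel for autosomal-dominant families.

Stages, applied in order:

1. ``exclude_known``   — drop variants already listed in the known-pathogenic
   panel (exact coordinate match); variants merely lying in a panel gene are
   kept and flagged.
2. ``ad_segregation``  — keep variants heterozygous in every affected member
   and absent from every unaffected member.
3. ``consequence``     — keep protein-altering / splice classes.
4. ``maf``             — keep variants rare (< threshold) in the population
   databases; unseen variants are treated as rare.
5. ``local_db``        — drop variants common in the local population table.
6. ``consensus``       — k-of-3 predictor consensus; records with no scores
   bypass.

Every stage is a pure conjunctive predicate, so the final survivor set is
invariant under stage permutation even though the per-stage counts are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from ._errors import ConfigError
from .ped_io import Affection, Pedigree
from .pathogenicity import ConsensusRule, consensus_pass
from .variant_io import (
    Consequence,
    LocalFrequencyTable,
    PanelSet,
    VariantRecord,
)

__all__ = [
    "FunnelConfig",
    "FunnelReport",
    "DEFAULT_RETAINED_CONSEQUENCES",
    "exclude_known",
    "ad_segregation_filter",
    "consequence_filter",
    "maf_filter",
    "local_db_filter",
    "run_funnel",
]

#: Union of the protein-altering classes and the splice classes.
DEFAULT_RETAINED_CONSEQUENCES: frozenset[Consequence] = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
        Consequence.INDEL,
        Consequence.SPLICE_REGION,
        Consequence.SPLICE_SITE,
    }
)


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds and switches for the funnel stages."""

    maf_threshold: float = 0.01
    retained_consequences: frozenset[Consequence] = DEFAULT_RETAINED_CONSEQUENCES
    local_af_threshold: float = 0.01
    lenient_unaffected: bool = False  # True: missing calls in unaffected tolerated
    apply_consensus: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "local_af_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if not self.retained_consequences:
            raise ConfigError("retained_consequences must be non-empty")


@dataclass
class FunnelReport:
    """Ordered per-stage (name, n_in, n_out) counts."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: n_out {n_out} > n_in {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(
                f"stage {name}: n_in {n_in} != previous n_out {self.stages[-1][2]}"
            )
        self.stages.append((name, n_in, n_out))

    def to_dict(self) -> list[dict]:
        return [
            {"stage": s, "n_in": i, "n_out": o} for s, i, o in self.stages
        ]

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        lines = ["stage\tn_in\tn_out"]
        lines += [f"{s}\t{i}\t{o}" for s, i, o in self.stages]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------


def exclude_known(
    variants: Sequence[VariantRecord], panel: PanelSet
) -> list[VariantRecord]:
    """Remove exact matches to known pathogenic variants; flag panel-gene hits.

    A variant inside a panel gene whose coordinates are NOT in the known list
    is novel with respect to the panel and is retained (flagged
    ``panel_gene=True``) — known genes harbouring new alleles are discovery
    targets, not exclusions.
    """
    out = []
    for v in variants:
        if v.key in panel.known_variants:
            continue
        if v.gene is not None and v.gene.upper() in panel.genes:
            v = v.with_flags(panel_gene=True)
        out.append(v)
    return out


def check_sample_coverage(
    variants: Sequence[VariantRecord], ped: Pedigree
) -> None:
    """Every pedigree member must have a genotype column in every record."""
    for v in variants:
        missing = [s for s in ped.sample_ids if s not in v.sample_ids]
        if missing:
            raise ConfigError(
                f"{v.key_str}: pedigree members without genotype column: {missing}"
            )


def _segregates_ad(
    v: VariantRecord, ped: Pedigree, lenient_unaffected: bool
) -> bool:
    dosages = {g.sample_id: g.alt_dosage for g in v.genotypes}
    # a causal dominant allele is heterozygous here; any hom-alt call anywhere
    # is inconsistent with the rare-dominant model
    if any(
        dosages.get(m.individual_id) == 2 for m in ped.members
    ):
        return False
    for m in ped.members:
        d = dosages.get(m.individual_id)
        if m.affection is Affection.AFFECTED:
            if d != 1:  # missing or non-het in an affected member excludes
                return False
        elif m.affection is Affection.UNAFFECTED:
            if d is None:
                if not lenient_unaffected:
                    return False
            elif d != 0:
                return False
    return True


def ad_segregation_filter(
    variants: Sequence[VariantRecord],
    ped: Pedigree,
    lenient_unaffected: bool = False,
) -> list[VariantRecord]:
    """Keep variants het in all affected and hom-ref in all unaffected members.

    Missing calls in affected members exclude (the causal allele must be
    observable in every affected); missing calls in unaffected members
    exclude unless ``lenient_unaffected`` is set, since "absent in
    unaffected" cannot be verified on a missing call.
    """
    check_sample_coverage(variants, ped)
    return [v for v in variants if _segregates_ad(v, ped, lenient_unaffected)]


def consequence_filter(
    variants: Sequence[VariantRecord], cfg: FunnelConfig | None = None
) -> list[VariantRecord]:
    """Keep variants whose consequence class is in the retained set."""
    cfg = cfg or FunnelConfig()
    return [
        v
        for v in variants
        if v.consequence is not None and v.consequence in cfg.retained_consequences
    ]


def maf_filter(
    variants: Sequence[VariantRecord], cfg: FunnelConfig | None = None
) -> list[VariantRecord]:
    """Keep variants with population AF strictly below threshold; missing AF = rare."""
    cfg = cfg or FunnelConfig()
    return [
        v
        for v in variants
        if v.pop_af is None or v.pop_af < cfg.maf_threshold
    ]


def local_db_filter(
    variants: Sequence[VariantRecord],
    local: LocalFrequencyTable,
    cfg: FunnelConfig | None = None,
) -> list[VariantRecord]:
    """Drop variants at or above the local-population frequency threshold."""
    cfg = cfg or FunnelConfig()
    out = []
    for v in variants:
        f = local.get(v.key)
        if f is not None and f >= cfg.local_af_threshold:
            continue
        out.append(v)
    return out


def consensus_filter(
    variants: Sequence[VariantRecord], rule: ConsensusRule | None = None
) -> list[VariantRecord]:
    """Keep variants passing the k-of-3 consensus (score-less records bypass)."""
    rule = rule or ConsensusRule()
    return [v for v in variants if consensus_pass(v.scores, rule)[2]]


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------


def run_funnel(
    variants: Sequence[VariantRecord],
    ped: Pedigree,
    panel: PanelSet | None = None,
    local: LocalFrequencyTable | None = None,
    cfg: FunnelConfig | None = None,
    consensus_rule: ConsensusRule | None = None,
) -> tuple[list[VariantRecord], FunnelReport]:
    """Apply the full ordered funnel; return survivors and per-stage counts."""
    cfg = cfg or FunnelConfig()
    panel = panel or PanelSet()
    local = local or LocalFrequencyTable()
    consensus_rule = consensus_rule or ConsensusRule()

    stages: list[tuple[str, Callable[[list[VariantRecord]], list[VariantRecord]]]] = [
        ("exclude_known", lambda vs: exclude_known(vs, panel)),
        (
            "ad_segregation",
            lambda vs: ad_segregation_filter(vs, ped, cfg.lenient_unaffected),
        ),
        ("consequence", lambda vs: consequence_filter(vs, cfg)),
        ("maf", lambda vs: maf_filter(vs, cfg)),
        ("local_db", lambda vs: local_db_filter(vs, local, cfg)),
    ]
    if cfg.apply_consensus:
        stages.append(("consensus", lambda vs: consensus_filter(vs, consensus_rule)))

    report = FunnelReport()
    current = list(variants)
    for name, fn in stages:
        n_in = len(current)
        current = fn(current)
        report.add(name, n_in, len(current))
    return current, report
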