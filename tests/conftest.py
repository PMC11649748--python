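"""Shared fixtures: the 8-member study-structure family, genotype patterns,
and reference missense score profiles used by several suites."""

from __future__ import annotations

import random

import pytest

from pedsieve.ped_io import Affection, Individual, Pedigree, Sex
from pedsieve.simulate import default_pedigree
from pedsieve.variant_io import (
    Consequence,
    GenotypeCall,
    ScoreBundle,
    VariantRecord,
)

# Reference missense score profiles (REVEL, SIFT, PolyPhen-2) with the
# category letters a report prints for them, and whether the 2-of-3
# damaging consensus passes. One profile is damaging by PolyPhen alone and
# fails the strict 2-of-3 rule.
MISSENSE_SCORE_ROWS = [
    # (label, revel, sift, polyphen, revel_cat, sift_cat, polyphen_cat, k2_pass)
    ("HSPG2:p.Asp775Glu", 0.478, 0.171, 0.997, "N", "T", "PD", False),
    ("ARHGEF10L:p.Arg523Leu", 0.364, 0.008, 0.979, "N", "D", "PD", True),
    ("CNKSR1:p.Ser141Leu", 0.337, 0.0, 0.998, "N", "D", "PD", True),
    ("CDK11B:p.Lys101Arg", 0.146, 0.0, 0.99, "N", "D", "PD", True),
    ("HSPG2:p.Val3123Met", 0.448, 0.03, 0.999, "N", "D", "PD", True),
]


@pytest.fixture
def family8() -> Pedigree:
    """Two founders, six offspring; father and three offspring affected."""
    return default_pedigree()


@pytest.fixture
def affected_pattern(family8) -> dict[str, int]:
    """Marker dosages: het in exactly the affected members, hom-ref elsewhere."""
    affected = set(family8.affected_ids)
    return {
        s: (1 if s in affected else 0) for s in family8.sample_ids
    }


def make_variant(
    ped: Pedigree,
    pattern: dict[str, int | None],
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    gene: str = "GENE1",
    consequence: Consequence = Consequence.MISSENSE,
    pop_af: float | None = None,
    scores: ScoreBundle | None = None,
) -> VariantRecord:
    """Build a VariantRecord with genotypes for every pedigree member."""
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        pop_af=pop_af,
        scores=scores or ScoreBundle(sift=0.01, polyphen=0.99, revel=0.8),
        genotypes=tuple(
            GenotypeCall(s, pattern.get(s, 0)) for s in ped.sample_ids
        ),
    )


def random_pedigree(rng: random.Random, max_members: int = 8) -> Pedigree:
    """A random nuclear or three-generation pedigree with 3..max_members
    members, at least one affected."""
    n_children = rng.randint(1, max(1, max_members - 2 - 2))
    members = [
        Individual("F", sex=Sex.MALE, affection=Affection.AFFECTED),
        Individual("M", sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
    ]
    for i in range(n_children):
        members.append(
            Individual(
                f"C{i}",
                father_id="F",
                mother_id="M",
                sex=rng.choice([Sex.MALE, Sex.FEMALE]),
                affection=rng.choice(
                    [Affection.AFFECTED, Affection.UNAFFECTED]
                ),
            )
        )
    if len(members) + 2 <= max_members and rng.random() < 0.5:
        # extend to a third generation below the first child
        child_is_male = members[2].sex is Sex.MALE
        spouse_sex = Sex.FEMALE if child_is_male else Sex.MALE
        members.append(
            Individual("S0", sex=spouse_sex, affection=Affection.UNAFFECTED)
        )
        father, mother = ("C0", "S0") if child_is_male else ("S0", "C0")
        members.append(
            Individual(
                "G0",
                father_id=father,
                mother_id=mother,
                affection=rng.choice([Affection.AFFECTED, Affection.UNAFFECTED]),
            )
        )
    return Pedigree("RND", members)
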