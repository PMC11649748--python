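"""Exact two-point parametric LOD scores for small pedigrees.

The likelihood of a pedigree at recombination fraction θ between an
(unobserved) disease locus and an observed bi-allelic marker is computed by
full enumeration of phased two-locus genotype configurations:

    L(θ) = Σ_configs  Π_founders  hap-freq priors (HWE, linkage equilibrium)
                    × Π_non-founders  transmission probabilities (recombination θ)
                    × Π_members  penetrance term given disease-allele copies

A configuration assigns every member an ordered pair of haplotypes, each
haplotype a (disease allele, marker allele) pair. Configurations
inconsistent with an observed marker dosage contribute nothing; untyped
members are marginalized. Founder phase is unknown and marginalized — for a
single doubly heterozygous carrier parent with n fully informative
non-recombinant meioses this yields the classical phase-unknown LOD
(n−1)·log10 2, e.g. 1.505 for n = 6.

The LOD is log10 L(θ) − log10 L(0.5). Enumeration uses constraint
propagation (children's haplotypes restricted to parental transmissions,
members without offspring summed out analytically) and is exact; the
pedigree size bound is 12 members.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Mapping

from ._errors import CapacityError, ConfigError, DataError
from .ped_io import Affection, Individual, Pedigree
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LodModel",
    "LodResult",
    "ModelError",
    "pedigree_likelihood",
    "compute_lod",
    "compute_lod_for_variant",
    "lod_closed_form_phase_unknown",
    "truncate",
    "MAX_ENUM_MEMBERS",
    "THETA_GRID",
]

MAX_ENUM_MEMBERS = 12
#: fallback grid when the requested θ gives zero likelihood (obligate recombinant)
THETA_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4)

#: haplotype = (disease allele, marker allele), each 0/1
_HAPS = tuple(product((0, 1), (0, 1)))


class ModelError(DataError):
    """The phenotype data are impossible under the disease model."""


@dataclass(frozen=True)
class LodModel:
    """Two-locus parametric model: θ, allele frequencies, penetrances.

    Defaults encode the convention for a rare fully penetrant autosomal
    dominant trait: disease and marker allele frequencies 1e-4, penetrance
    (0, 1, 1) for 0/1/2 copies of the disease allele, no phenocopies.
    """

    theta: float = 0.0
    disease_allele_freq: float = 1e-4
    marker_allele_freq: float = 1e-4
    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 0.5):
            raise ConfigError(f"theta={self.theta} outside [0, 0.5]")
        for name, v in (
            ("disease_allele_freq", self.disease_allele_freq),
            ("marker_allele_freq", self.marker_allele_freq),
        ):
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name}={v} outside (0, 1)")
        if len(self.penetrance) != 3 or any(
            not (0.0 <= f <= 1.0) for f in self.penetrance
        ):
            raise ConfigError(f"penetrance {self.penetrance} invalid")


@dataclass(frozen=True)
class LodResult:
    """An evaluated LOD with the θ used for the numerator."""

    lod: float
    theta_eval: float
    n_configs: int

    @property
    def printed(self) -> str:
        """The reporting convention: truncated (not rounded) to 2 decimals."""
        return f"{truncate(self.lod, 2):.2f}"


def truncate(x: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (1.505 → 1.50)."""
    scale = 10**decimals
    return math.trunc(x * scale) / scale


def lod_closed_form_phase_unknown(n_informative: int) -> float:
    """θ=0 LOD for one phase-unknown doubly het parent, n informative
    non-recombinant meioses: (n−1)·log10 2. One meiosis alone carries no
    linkage information when phase is unknown."""
    if n_informative < 1:
        raise ConfigError(f"n_informative={n_informative} must be >= 1")
    return (n_informative - 1) * math.log10(2.0)


# ---------------------------------------------------------------------------
# enumeration engine
# ---------------------------------------------------------------------------


def _hap_freqs(model: LodModel) -> dict[tuple[int, int], float]:
    pd_, pm = model.disease_allele_freq, model.marker_allele_freq
    return {
        (d, m): (pd_ if d else 1.0 - pd_) * (pm if m else 1.0 - pm)
        for d, m in _HAPS
    }


def _penetrance_factor(member: Individual, n_disease: int, model: LodModel) -> float:
    f = model.penetrance[n_disease]
    if member.affection is Affection.AFFECTED:
        return f
    if member.affection is Affection.UNAFFECTED:
        return 1.0 - f
    return 1.0


def _transmission_probs(
    dip: tuple[tuple[int, int], tuple[int, int]], theta: float
) -> dict[tuple[int, int], float]:
    """P(transmitted haplotype | parent diplotype) at recombination θ.

    Strand choices: pick the strand contributing the disease allele and the
    strand contributing the marker allele; same strand w.p. (1−θ)/2 each,
    opposite strands w.p. θ/2 each. Identical resulting haplotypes are
    aggregated.
    """
    out: dict[tuple[int, int], float] = {}
    for a, b in product((0, 1), (0, 1)):
        hap = (dip[a][0], dip[b][1])
        w = (1.0 - theta) / 2.0 if a == b else theta / 2.0
        out[hap] = out.get(hap, 0.0) + w
    return out


def _member_candidates(
    member: Individual,
    dosage: int | None,
    model: LodModel,
    theta: float,
    hap_freqs: dict,
    parent_dips: tuple | None,
) -> list[tuple[tuple, float]]:
    """Ordered diplotypes consistent with the observed marker dosage, with
    their prior (founder) or transmission (non-founder) weight times the
    penetrance factor. Zero-weight candidates are dropped."""
    cands = []
    if parent_dips is None:
        for h1, h2 in product(_HAPS, _HAPS):
            if dosage is not None and h1[1] + h2[1] != dosage:
                continue
            w = hap_freqs[h1] * hap_freqs[h2]
            w *= _penetrance_factor(member, h1[0] + h2[0], model)
            if w > 0.0:
                cands.append(((h1, h2), w))
    else:
        pat = _transmission_probs(parent_dips[0], theta)
        mat = _transmission_probs(parent_dips[1], theta)
        for h1, wp in pat.items():
            for h2, wm in mat.items():
                if dosage is not None and h1[1] + h2[1] != dosage:
                    continue
                w = wp * wm * _penetrance_factor(member, h1[0] + h2[0], model)
                if w > 0.0:
                    cands.append(((h1, h2), w))
    return cands


def pedigree_likelihood(
    ped: Pedigree,
    marker_genotypes: Mapping[str, int | None],
    model: LodModel,
    theta: float,
) -> float:
    """L(θ): total probability of phenotypes and observed marker dosages."""
    return _enumerate(ped, marker_genotypes, model, theta)[0]


def _enumerate(
    ped: Pedigree,
    marker_genotypes: Mapping[str, int | None],
    model: LodModel,
    theta: float,
) -> tuple[float, int]:
    """Return (likelihood, count of positive-probability phased configurations)."""
    if ped.n_members > MAX_ENUM_MEMBERS:
        raise CapacityError(
            f"pedigree has {ped.n_members} members; exact enumeration is "
            f"bounded at {MAX_ENUM_MEMBERS}"
        )
    for m in ped.members:
        if (
            m.affection is Affection.AFFECTED
            and marker_genotypes.get(m.individual_id) is None
        ):
            logger.warning(
                "affected member %s untyped at the marker; marginalized",
                m.individual_id,
            )

    hap_freqs = _hap_freqs(model)
    order = ped.founders_first()
    has_children = {
        m.individual_id: bool(ped.offspring_of(m.individual_id)) for m in order
    }
    # members whose diplotype other members depend on must be branched over;
    # childless members are summed out analytically at their parents' node
    branch = [m for m in order if has_children[m.individual_id]]
    leaves = [m for m in order if not has_children[m.individual_id]]

    def candidates(member: Individual, assignment: dict) -> list[tuple[tuple, float]]:
        if member.is_founder:
            parent_dips = None
        else:
            parent_dips = (
                assignment[member.father_id],
                assignment[member.mother_id],
            )
        return _member_candidates(
            member,
            marker_genotypes.get(member.individual_id),
            model,
            theta,
            hap_freqs,
            parent_dips,
        )

    total = 0.0
    n_configs = 0
    assignment: dict[str, tuple] = {}

    def leaf_factor(assignment: dict) -> tuple[float, int]:
        factor, count = 1.0, 1
        for leaf in leaves:
            cands = candidates(leaf, assignment)
            if not cands:
                return 0.0, 0
            factor *= sum(w for _, w in cands)
            count *= len(cands)
        return factor, count

    def rec(i: int, weight: float) -> None:
        nonlocal total, n_configs
        if i == len(branch):
            factor, count = leaf_factor(assignment)
            if factor > 0.0:
                total += weight * factor
                n_configs += count
            return
        member = branch[i]
        for dip, w in candidates(member, assignment):
            assignment[member.individual_id] = dip
            rec(i + 1, weight * w)
        assignment.pop(member.individual_id, None)

    rec(0, 1.0)
    return total, n_configs


def compute_lod(
    ped: Pedigree,
    marker_genotypes: Mapping[str, int | None],
    model: LodModel | None = None,
) -> LodResult:
    """Two-point LOD: log10 L(θ) − log10 L(0.5).

    When L(model.theta) is zero (an obligate recombinant at θ=0), the
    numerator is maximized over the fallback θ grid and ``theta_eval``
    records the grid point used.
    """
    model = model or LodModel()
    l_half, _ = _enumerate(ped, marker_genotypes, model, 0.5)
    if l_half <= 0.0:
        raise ModelError(
            "phenotypes impossible under the disease model (zero likelihood "
            "at every theta)"
        )
    l_num, n_configs = _enumerate(ped, marker_genotypes, model, model.theta)
    if l_num > 0.0:
        return LodResult(
            lod=math.log10(l_num) - math.log10(l_half),
            theta_eval=model.theta,
            n_configs=n_configs,
        )
    best: LodResult | None = None
    for theta in THETA_GRID:
        l_t, n_c = _enumerate(ped, marker_genotypes, model, theta)
        if l_t <= 0.0:
            continue
        lod = math.log10(l_t) - math.log10(l_half)
        if best is None or lod > best.lod:
            best = LodResult(lod=lod, theta_eval=theta, n_configs=n_c)
    if best is None:  # pragma: no cover - impossible once L(0.5) > 0
        raise ModelError("zero likelihood at every theta on the fallback grid")
    return best


def compute_lod_for_variant(
    ped: Pedigree, variant: VariantRecord, model: LodModel | None = None
) -> LodResult:
    """LOD treating the variant's per-sample ALT dosages as the marker."""
    genotypes = {
        g.sample_id: g.alt_dosage
        for g in variant.genotypes
        if g.sample_id in set(ped.sample_ids)
    }
    return compute_lod(ped, genotypes, model)
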