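"""Case/control carrier screening, frequency dialects and candidate ranking.

Carrier frequency is the fraction of *individuals* heterozygous for a
variant (distinct from allele frequency, which counts chromosomes). The
summary-table dialect truncates — not rounds — carrier frequencies to three
decimals (8/179 prints as 0.044, not 0.045); allele frequencies quoted from
population databases are rounded at the database's printed precision.

A variant whose control carrier frequency exceeds 1% is a common
polymorphism and is ruled out as causative regardless of its prediction
scores; ranking therefore places all non-polymorphisms ahead of all
polymorphisms and orders within each tier by a weighted evidence sum whose
default weights (32, 16, 8, 4, 2, ≤1) make the binary components strictly
lexicographic: segregation first, absence from the screening cohorts second,
a prior disease association third, then predictor consensus, kidney
expression, and finally the scaled external gene-prioritization score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._errors import ConfigError, ParseError
from .lod import LodResult, truncate
from .pathogenicity import ConsensusRule, categorize, consensus_pass
from .variant_io import GeneAnnotation, VariantRecord, _parse_site_rows

__all__ = [
    "CohortScreen",
    "CandidateScore",
    "DEFAULT_WEIGHTS",
    "carrier_frequency",
    "allele_frequency",
    "classify_polymorphism",
    "read_cohort_screens",
    "write_cohort_screens",
    "rank_candidates",
    "build_summary_table",
    "write_markdown",
    "parse_frequency_cell",
]

VariantKey = tuple[str, int, str, str]


def carrier_frequency(
    het_count: int, n: int, decimals: int = 3, mode: str = "truncate"
) -> float:
    """Carrier (heterozygote) frequency het_count/n at the table's precision.

    ``truncate`` (the default dialect) floors at ``decimals`` places using
    exact integer arithmetic; ``round`` uses ordinary rounding.
    """
    if n < 1:
        raise ValueError(f"cohort size n={n} must be >= 1")
    if not (0 <= het_count <= n):
        raise ValueError(f"het_count={het_count} outside 0..{n}")
    if mode == "truncate":
        return (het_count * 10**decimals // n) / 10**decimals
    if mode == "round":
        return round(het_count / n, decimals)
    raise ConfigError(f"unknown frequency mode {mode!r}")


def allele_frequency(allele_count: int, allele_number: int, decimals: int) -> float:
    """Allele frequency ac/an rounded to ``decimals`` places."""
    if allele_number < 1:
        raise ValueError(f"allele_number={allele_number} must be >= 1")
    if not (0 <= allele_count <= allele_number):
        raise ValueError(
            f"allele_count={allele_count} outside 0..{allele_number}"
        )
    return round(allele_count / allele_number, decimals)


@dataclass(frozen=True)
class CohortScreen:
    """Carrier counts for one variant in the screening cohorts."""

    key: VariantKey
    n_controls: int
    n_cases: int
    het_controls: int
    het_cases: int

    def __post_init__(self) -> None:
        for label, h, n in (
            ("controls", self.het_controls, self.n_controls),
            ("cases", self.het_cases, self.n_cases),
        ):
            if n < 1:
                raise ValueError(f"{label}: cohort size {n} must be >= 1")
            if not (0 <= h <= n):
                raise ValueError(f"{label}: het count {h} outside 0..{n}")

    @property
    def freq_controls(self) -> float:
        return carrier_frequency(self.het_controls, self.n_controls)

    @property
    def freq_cases(self) -> float:
        return carrier_frequency(self.het_cases, self.n_cases)

    @property
    def is_polymorphism(self) -> bool:
        return classify_polymorphism(self)


def classify_polymorphism(screen: CohortScreen, threshold: float = 0.01) -> bool:
    """True iff the unformatted control carrier fraction strictly exceeds
    ``threshold`` (exact rational comparison, no float division)."""
    return Fraction(screen.het_controls, screen.n_controls) > threshold


def read_cohort_screens(path: str | Path) -> dict[VariantKey, CohortScreen]:
    """Read a screen TSV: chrom, pos, ref, alt, het_controls, het_cases,
    n_controls, n_cases."""
    out: dict[VariantKey, CohortScreen] = {}
    for lineno, chrom, pos, ref, alt, extras in _parse_site_rows(path, n_extra=4):
        try:
            hc, ha, nc, na = (int(x) for x in extras)
        except ValueError:
            raise ParseError(
                f"{Path(path).name}:{lineno}: counts must be integers: {extras}"
            ) from None
        key = (chrom, pos, ref, alt)
        out[key] = CohortScreen(
            key=key, n_controls=nc, n_cases=na, het_controls=hc, het_cases=ha
        )
    return out


def write_cohort_screens(
    screens: Mapping[VariantKey, CohortScreen], path: str | Path
) -> None:
    lines = ["chrom\tpos\tref\talt\thet_controls\thet_cases\tn_controls\tn_cases"]
    for key in sorted(screens):
        s = screens[key]
        lines.append(
            "\t".join(
                map(
                    str,
                    [*key, s.het_controls, s.het_cases, s.n_controls, s.n_cases],
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

DEFAULT_WEIGHTS: dict[str, float] = {
    "segregates": 32.0,
    "zero_cohort_carriers": 16.0,
    "prior_association": 8.0,
    "consensus_pass": 4.0,
    "kidney_expressed": 2.0,
    "prior_score_scaled": 1.0,
}


@dataclass(frozen=True)
class CandidateScore:
    """Evidence components, their weighted total, and the resulting rank."""

    key: VariantKey
    gene: str | None
    components: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    rank: int = 0
    is_polymorphism: bool = False


def rank_candidates(
    survivors: Sequence[VariantRecord],
    screens: Mapping[VariantKey, CohortScreen],
    lod_results: Mapping[VariantKey, LodResult],
    annotations: Mapping[str, GeneAnnotation],
    weights: Mapping[str, float] | None = None,
    consensus_rule: ConsensusRule | None = None,
    validated: Mapping[VariantKey, bool] | None = None,
) -> list[CandidateScore]:
    """Score and rank funnel survivors.

    Variants with a ``validated=False`` override (wet-lab false positives)
    are removed before ranking. Ranking is deterministic: polymorphism tier,
    then descending weighted total, then (chrom, pos, ref, alt).
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        unknown = set(weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ConfigError(f"unknown ranking weight keys: {sorted(unknown)}")
        w.update(weights)
    rule = consensus_rule or ConsensusRule()
    validated = validated or {}

    pool = [v for v in survivors if validated.get(v.key, True)]
    for v in pool:
        if v.key not in screens:
            raise ConfigError(f"no cohort screen for survivor {v.key_str}")
        if v.key not in lod_results:
            raise ConfigError(f"no LOD result for survivor {v.key_str}")

    genes = {v.gene.upper() for v in pool if v.gene}
    max_prior = max(
        (annotations[g].prior_score for g in genes if g in annotations),
        default=0.0,
    )

    scored: list[CandidateScore] = []
    for v in pool:
        screen = screens[v.key]
        lod = lod_results[v.key]
        ann = annotations.get(v.gene.upper()) if v.gene else None
        prior_scaled = (
            min(ann.prior_score / max_prior, 1.0) if ann and max_prior > 0 else 0.0
        )
        components = {
            "segregates": 1.0 if lod.lod > 0 else 0.0,
            "zero_cohort_carriers": (
                1.0 if screen.het_controls == 0 and screen.het_cases == 0 else 0.0
            ),
            "prior_association": (
                1.0 if ann and ann.prior_disease_association else 0.0
            ),
            "consensus_pass": 1.0 if consensus_pass(v.scores, rule)[2] else 0.0,
            "kidney_expressed": 1.0 if ann and ann.kidney_expressed else 0.0,
            "prior_score_scaled": prior_scaled,
        }
        total = sum(w[k] * c for k, c in components.items())
        scored.append(
            CandidateScore(
                key=v.key,
                gene=v.gene,
                components=components,
                weights=dict(w),
                total=total,
                is_polymorphism=screen.is_polymorphism,
            )
        )

    scored.sort(key=lambda c: (c.is_polymorphism, -c.total, c.key))
    return [
        CandidateScore(
            key=c.key,
            gene=c.gene,
            components=c.components,
            weights=c.weights,
            total=c.total,
            rank=i + 1,
            is_polymorphism=c.is_polymorphism,
        )
        for i, c in enumerate(scored)
    ]


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

_CELL_RE = re.compile(r"^(\d+)(?:\s*\(([0-9.]+)\))?$")


def format_frequency_cell(het_count: int, n: int) -> str:
    """Table cell dialect: ``"6 (0.033)"``; a zero count prints as ``"0"``."""
    if het_count == 0:
        return "0"
    return f"{het_count} ({carrier_frequency(het_count, n):.3f})"


def parse_frequency_cell(cell: str) -> int:
    """Recover the carrier count from a formatted frequency cell."""
    m = _CELL_RE.match(cell.strip())
    if not m:
        raise ParseError(f"unparseable frequency cell {cell!r}")
    return int(m.group(1))


def build_summary_table(
    survivors: Sequence[VariantRecord],
    screens: Mapping[VariantKey, CohortScreen],
    lods: Mapping[VariantKey, LodResult],
    consensus_rule: ConsensusRule | None = None,
    annotations: Mapping[str, GeneAnnotation] | None = None,
) -> pd.DataFrame:
    """One row per variant mirroring the published summary-table layout:
    segregation call with truncated LOD, score letters, prior score, and
    ``"count (freq)"`` cohort cells."""
    rule = consensus_rule or ConsensusRule()
    annotations = annotations or {}
    rows = []
    for v in survivors:
        screen = screens.get(v.key)
        lod = lods.get(v.key)
        cats = categorize(v.scores, rule)
        ann = annotations.get(v.gene.upper()) if v.gene else None
        segregates = lod is not None and lod.lod > 0
        poly = screen.is_polymorphism if screen else False
        rows.append(
            {
                "gene": v.gene or "NA",
                "variant": v.key_str,
                "consequence": v.consequence.value if v.consequence else "NA",
                "segregation": (
                    f"{'Yes' if segregates else 'No'} ({truncate(lod.lod, 2):.2f})"
                    if lod
                    else "NA"
                ),
                "revel": "NA" if v.scores.revel is None else v.scores.revel,
                "revel_cat": cats.revel,
                "sift": "NA" if v.scores.sift is None else v.scores.sift,
                "sift_cat": cats.sift,
                "polyphen": "NA" if v.scores.polyphen is None else v.scores.polyphen,
                "polyphen_cat": cats.polyphen,
                "prior_score": ann.prior_score if ann else "NA",
                "controls": (
                    format_frequency_cell(screen.het_controls, screen.n_controls)
                    if screen
                    else "ND"
                ),
                "cases": (
                    format_frequency_cell(screen.het_cases, screen.n_cases)
                    if screen
                    else "ND"
                ),
                "causative": "Yes" if segregates and not poly else "No",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "variant",
            "consequence",
            "segregation",
            "revel",
            "revel_cat",
            "sift",
            "sift_cat",
            "polyphen",
            "polyphen_cat",
            "prior_score",
            "controls",
            "cases",
            "causative",
        ],
    )


def write_markdown(table: pd.DataFrame, path: str | Path) -> None:
    """Write the summary table as a GitHub-flavored Markdown table."""
    cols = list(table.columns)
    lines = [
        "| " + " | ".join(cols) + " |",
        "| " + " | ".join("---" for _ in cols) + " |",
    ]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    Path(path).write_text("\n".join(lines) + "\n")
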