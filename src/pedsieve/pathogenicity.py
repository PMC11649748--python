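"""Predictor-score categorization and the k-of-n damaging consensus.

Each variant carries up to three predictor scores — SIFT (low score means
deleterious), PolyPhen-2 (high probability means damaging) and REVEL (high
score means damaging). The funnel retains a variant when at least
``min_damaging`` of the tools with a score call it damaging; variants with
too few evaluable scores (splice-region/intronic records typically carry
none) bypass the consensus rather than failing it.

Default thresholds follow each tool's published convention: SIFT < 0.05 is
deleterious ("D", else tolerated "T"); PolyPhen-2 >= 0.446 is possibly
damaging ("P") and >= 0.908 probably damaging ("PD"), below is benign ("B");
REVEL >= 0.5 is damaging, else neutral ("N"). All thresholds are
configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._errors import ConfigError
from .variant_io import ScoreBundle

__all__ = ["ConsensusRule", "Categories", "categorize", "consensus_pass"]

NA = "NA"


@dataclass(frozen=True)
class ConsensusRule:
    """Thresholds and the k-of-n rule for the damaging consensus."""

    sift_deleterious_max: float = 0.05  # score < threshold => deleterious
    polyphen_damaging_min: float = 0.446  # score >= threshold => damaging
    polyphen_probably_min: float = 0.908  # reported as "PD" above this
    revel_damaging_min: float = 0.5
    min_damaging: int = 2
    evaluable_min: int = 1
    polyphen_strict: bool = False  # True: only "probably damaging" counts
    bypass_when_unevaluable: bool = True

    def __post_init__(self) -> None:
        for name in (
            "sift_deleterious_max",
            "polyphen_damaging_min",
            "polyphen_probably_min",
            "revel_damaging_min",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not (0 <= self.min_damaging <= 3):
            raise ConfigError(f"min_damaging={self.min_damaging} outside 0..3")
        if self.evaluable_min < 0:
            raise ConfigError("evaluable_min must be >= 0")


@dataclass(frozen=True)
class Categories:
    """Per-tool category letters as a variant report prints them."""

    sift: str  # "D" | "T" | "NA"
    polyphen: str  # "PD" | "P" | "B" | "NA"
    revel: str  # "D" | "N" | "NA"

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.sift, self.polyphen, self.revel)


def categorize(scores: ScoreBundle, rule: ConsensusRule | None = None) -> Categories:
    """Map raw scores to category letters under the rule's thresholds."""
    rule = rule or ConsensusRule()
    if scores.sift is None:
        sift = NA
    else:
        sift = "D" if scores.sift < rule.sift_deleterious_max else "T"
    if scores.polyphen is None:
        polyphen = NA
    elif scores.polyphen >= rule.polyphen_probably_min:
        polyphen = "PD"
    elif scores.polyphen >= rule.polyphen_damaging_min:
        polyphen = "P"
    else:
        polyphen = "B"
    if scores.revel is None:
        revel = NA
    else:
        revel = "D" if scores.revel >= rule.revel_damaging_min else "N"
    return Categories(sift=sift, polyphen=polyphen, revel=revel)


def consensus_pass(
    scores: ScoreBundle, rule: ConsensusRule | None = None
) -> tuple[int, int, bool]:
    """Evaluate the k-of-n consensus.

    Returns ``(damaging_count, evaluable_count, passes)``. When fewer than
    ``evaluable_min`` scores are present the verdict is the configured
    bypass (default True): a record with no usable predictions is retained
    rather than silently dropped.
    """
    rule = rule or ConsensusRule()
    cats = categorize(scores, rule)
    evaluable = scores.n_present
    polyphen_damaging = (
        cats.polyphen == "PD" if rule.polyphen_strict else cats.polyphen in ("PD", "P")
    )
    damaging = sum(
        [cats.sift == "D", polyphen_damaging, cats.revel == "D"]
    )
    if evaluable < rule.evaluable_min:
        return damaging, evaluable, rule.bypass_when_unevaluable
    return damaging, evaluable, damaging >= rule.min_damaging
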