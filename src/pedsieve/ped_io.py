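"""Pedigree data model and PLINK-style PED input/output.

A pedigree is the unit over which segregation filtering and parametric LOD
scores are computed. The model is deliberately small: individuals with
optional parent links, a sex code that is carried but unused by the autosomal
analyses, and a three-valued affection status.

PED dialect: whitespace-delimited, six mandatory columns
``FID IID PAT MAT SEX PHENO``; extra columns are ignored with a warning.
Phenotype codes ``1`` = unaffected, ``2`` = affected, ``0``/``-9`` = unknown.
Parent id ``0`` means founder; a founder has both parent ids absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from ._errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Affection",
    "Individual",
    "Pedigree",
    "read_ped",
    "write_ped",
    "informative_meioses",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {
    "1": Affection.UNAFFECTED,
    "2": Affection.AFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {
    Affection.UNAFFECTED: "1",
    Affection.AFFECTED: "2",
    Affection.UNKNOWN: "0",
}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both set (non-founder) or both
    ``None`` (founder); this is enforced by :class:`Pedigree` validation.
    """

    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family: ordered members with validated parent links."""

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------

    def __iter__(self) -> Iterable[Individual]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def member(self, individual_id: str) -> Individual:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(
                f"individual {individual_id!r} not in family {self.family_id!r}"
            ) from None

    @property
    def sample_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def offspring_of(self, individual_id: str) -> list[Individual]:
        self.member(individual_id)  # raise on unknown id
        return [
            m
            for m in self.members
            if individual_id in (m.father_id, m.mother_id)
        ]

    # -- counts ----------------------------------------------------------

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_affected(self) -> int:
        return sum(m.affection is Affection.AFFECTED for m in self.members)

    @property
    def n_unaffected(self) -> int:
        return sum(m.affection is Affection.UNAFFECTED for m in self.members)

    @property
    def n_unknown(self) -> int:
        return sum(m.affection is Affection.UNKNOWN for m in self.members)

    @property
    def n_founders(self) -> int:
        return sum(m.is_founder for m in self.members)

    @property
    def affected_ids(self) -> list[str]:
        return [
            m.individual_id
            for m in self.members
            if m.affection is Affection.AFFECTED
        ]

    @property
    def unaffected_ids(self) -> list[str]:
        return [
            m.individual_id
            for m in self.members
            if m.affection is Affection.UNAFFECTED
        ]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"duplicate individual id(s) in family {self.family_id!r}: {dupes}"
            )
        self._index = {m.individual_id: m for m in self.members}
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise ValidationError(
                    f"{m.individual_id}: parents must be both present or both absent"
                )
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is not None and pid not in self._index:
                    raise ValidationError(
                        f"{m.individual_id}: {role} {pid!r} not in pedigree"
                    )
            if m.father_id is not None:
                fa = self._index[m.father_id]
                mo = self._index[m.mother_id]
                if fa.sex is mo.sex and fa.sex is not Sex.UNKNOWN:
                    logger.warning(
                        "%s: parents %s and %s share sex %s (ignored by the "
                        "autosomal model)",
                        m.individual_id,
                        m.father_id,
                        m.mother_id,
                        fa.sex.value,
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # depth-first ancestor walk; a back edge means someone is their own ancestor
        state: dict[str, int] = {}  # 0 in progress, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValidationError(
                    f"pedigree cycle involving {iid!r}: {' -> '.join(stack + [iid])}"
                )
            state[iid] = 0
            m = self._index[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1

        for m in self.members:
            visit(m.individual_id, [])

    def founders_first(self) -> list[Individual]:
        """Members in topological order (every parent before its children)."""
        ordered: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.members)
        while pending:
            progressed = False
            rest = []
            for m in pending:
                parents_ok = all(
                    pid is None or pid in placed
                    for pid in (m.father_id, m.mother_id)
                )
                if parents_ok:
                    ordered.append(m)
                    placed.add(m.individual_id)
                    progressed = True
                else:
                    rest.append(m)
            pending = rest
            if not progressed:  # pragma: no cover - acyclicity already enforced
                raise ValidationError("pedigree ordering failed (cycle?)")
        return ordered


def read_ped(path: str | Path) -> Pedigree:
    """Read a single-family, 6-column PED file into a validated Pedigree.

    Raises :class:`ParseError` naming the line number on malformed rows and
    :class:`ValidationError` on broken parent references or cycles. Extra
    columns beyond the sixth are ignored with a logged warning. Input order
    of members is preserved.
    """
    path = Path(path)
    members: list[Individual] = []
    family_id: str | None = None
    warned_extra = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=6 columns, got {len(cols)}"
                )
            if len(cols) > 6 and not warned_extra:
                logger.warning(
                    "%s:%d: ignoring %d extra column(s) beyond the 6 mandatory",
                    path.name,
                    lineno,
                    len(cols) - 6,
                )
                warned_extra = True
            fid, iid, pat, mat, sex, pheno = cols[:6]
            if family_id is None:
                family_id = fid
            elif fid != family_id:
                raise ParseError(
                    f"{path.name}:{lineno}: multiple family ids "
                    f"({family_id!r} and {fid!r}); one family per file"
                )
            if pheno not in _PHENO_CODES:
                raise ParseError(
                    f"{path.name}:{lineno}: phenotype code {pheno!r} "
                    "(expected 1, 2, 0 or -9)"
                )
            members.append(
                Individual(
                    individual_id=iid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    affection=_PHENO_CODES[pheno],
                )
            )
    if family_id is None:
        raise ParseError(f"{path.name}: no pedigree rows found")
    return Pedigree(family_id=family_id, members=members)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Write the pedigree in the same 6-column dialect read_ped accepts."""
    with open(path, "w") as fh:
        for m in ped.members:
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_OUT[m.sex],
                        _PHENO_OUT[m.affection],
                    ]
                )
                + "\n"
            )


def informative_meioses(ped: Pedigree, carrier_parent: str) -> int:
    """Number of offspring of ``carrier_parent`` with known affection status.

    For a fully penetrant dominant marker pattern this is the number of
    meioses that contribute linkage information; it feeds the closed-form
    phase-unknown LOD oracle.
    """
    return sum(
        child.affection is not Affection.UNKNOWN
        for child in ped.offspring_of(carrier_parent)
    )
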