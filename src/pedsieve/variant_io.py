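"""Annotated variant records and the readers/writers that move them.

The pipeline consumes a multi-sample VCF that has already been annotated
upstream (gene symbol, consequence class, population allele frequency and
the SIFT/PolyPhen/REVEL predictor scores live in INFO fields whose names
are supplied through a :class:`VcfFieldMap`). Records are normalized to
bi-allelic on read: a multi-allelic site becomes one record per ALT with
per-sample dosages re-expressed against that ALT.

Coordinates are 1-based VCF positions everywhere in the pipeline; there are
no 0-based conversions. ``pop_af`` is the maximum over the configured
population-frequency INFO keys — the conservative aggregation when several
databases are consulted. Missing annotations stay missing (``None``), never
defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

from ._errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "GenotypeCall",
    "ScoreBundle",
    "VariantRecord",
    "PanelSet",
    "LocalFrequencyTable",
    "GeneAnnotation",
    "VcfFieldMap",
    "read_annotated_vcf",
    "write_vcf",
    "read_panel",
    "read_local_frequency_table",
    "read_gene_annotations",
]


class Consequence(str, Enum):
    """Collapsed consequence classes used by the filtering funnel."""

    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    INDEL = "inframe_or_frameshift_indel"
    SPLICE_REGION = "splice_region"
    SPLICE_SITE = "splice_site"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Sequence-Ontology style terms mapped onto the collapsed classes; the
#: collapsed class names themselves are accepted verbatim.
SO_TERM_MAP: dict[str, Consequence] = {
    "missense_variant": Consequence.MISSENSE,
    "stop_gained": Consequence.STOP_GAIN,
    "stop_lost": Consequence.STOP_LOSS,
    "frameshift_variant": Consequence.INDEL,
    "inframe_insertion": Consequence.INDEL,
    "inframe_deletion": Consequence.INDEL,
    "disruptive_inframe_deletion": Consequence.INDEL,
    "splice_region_variant": Consequence.SPLICE_REGION,
    "splice_acceptor_variant": Consequence.SPLICE_SITE,
    "splice_donor_variant": Consequence.SPLICE_SITE,
    "intron_variant": Consequence.INTRONIC,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "stop_retained_variant": Consequence.SYNONYMOUS,
}
SO_TERM_MAP.update({c.value: c for c in Consequence})


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample ALT dosage: 0, 1, 2, or None when the call is missing."""

    sample_id: str
    alt_dosage: int | None

    def __post_init__(self) -> None:
        if self.alt_dosage is not None and self.alt_dosage not in (0, 1, 2):
            raise ValidationError(
                f"{self.sample_id}: alt dosage {self.alt_dosage!r} not in {{0,1,2}}"
            )


def _check_unit(name: str, v: float | None) -> None:
    if v is not None and not (0.0 <= v <= 1.0):
        raise ValidationError(f"{name} score {v!r} outside [0, 1]")


@dataclass(frozen=True)
class ScoreBundle:
    """Raw predictor scores; SIFT keeps its native orientation (low = deleterious)."""

    sift: float | None = None
    polyphen: float | None = None
    revel: float | None = None

    def __post_init__(self) -> None:
        _check_unit("SIFT", self.sift)
        _check_unit("PolyPhen", self.polyphen)
        _check_unit("REVEL", self.revel)

    @property
    def n_present(self) -> int:
        return sum(v is not None for v in (self.sift, self.polyphen, self.revel))


@dataclass(frozen=True)
class VariantRecord:
    """One bi-allelic annotated variant with per-sample genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    consequence: Consequence | None = None
    pop_af: float | None = None
    scores: ScoreBundle = field(default_factory=ScoreBundle)
    genotypes: tuple[GenotypeCall, ...] = ()
    panel_gene: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} < 1 (coordinates are 1-based)")
        if self.ref == self.alt:
            raise ValidationError(f"{self.key_str}: ref == alt")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValidationError(f"{self.key_str}: pop_af {self.pop_af} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def dosage(self, sample_id: str) -> int | None:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g.alt_dosage
        raise KeyError(f"sample {sample_id!r} not genotyped for {self.key_str}")

    @property
    def sample_ids(self) -> list[str]:
        return [g.sample_id for g in self.genotypes]

    def with_flags(self, **kw) -> "VariantRecord":
        return replace(self, **kw)


@dataclass
class PanelSet:
    """Known disease genes and known pathogenic variants (panel + ClinVar stand-in)."""

    genes: set[str] = field(default_factory=set)
    known_variants: set[tuple[str, int, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = {g.upper() for g in self.genes}


@dataclass
class LocalFrequencyTable:
    """Site → allele frequency observed in the local population databases."""

    freqs: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.freqs.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"local frequency {v} for {k} outside [0,1]")

    def get(self, key: tuple[str, int, str, str]) -> float | None:
        return self.freqs.get(key)


@dataclass(frozen=True)
class GeneAnnotation:
    """Externally supplied gene-level priors (expression, prior association, score)."""

    gene: str
    kidney_expressed: bool = False
    prior_disease_association: bool = False
    prior_score: float = 0.0

    def __post_init__(self) -> None:
        if self.prior_score < 0:
            raise ValidationError(f"{self.gene}: prior_score must be >= 0")


@dataclass
class VcfFieldMap:
    """Names of the INFO keys carrying each annotation.

    ``af_keys`` may list several population sources; ``pop_af`` becomes the
    maximum over those present. ``samples`` restricts genotype extraction to
    a subset (None = all samples in the file).
    """

    gene_key: str = "GENE"
    consequence_key: str = "CSQCLASS"
    af_keys: tuple[str, ...] = ("AF_POP",)
    sift_key: str = "SIFT"
    polyphen_key: str = "PPH2"
    revel_key: str = "REVEL"
    samples: tuple[str, ...] | None = None


def _to_float(value, alt_index: int) -> float | None:
    """Coerce a cyvcf2 INFO value (scalar, tuple per-ALT, str, np.float32) to float.

    np.float32 goes through its shortest decimal repr so that values written
    with few decimals survive a write/read round trip exactly.
    """
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if alt_index >= len(value):
            return None
        value = value[alt_index]
        if value is None:
            return None
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, str):
        value = value.split(",")[alt_index] if "," in value else value
        if value in (".", ""):
            return None
        return float(value)
    if isinstance(value, (float, np.floating)):
        # VCF Float fields come back through float32; its shortest decimal
        # repr recovers the value as written (0.171, not 0.17100000381...)
        return float(str(np.float32(value)))
    return float(value)


def _to_str(value, alt_index: int) -> str | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if alt_index >= len(value):
            return None
        value = value[alt_index]
    if isinstance(value, bytes):
        value = value.decode()
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        value = parts[alt_index] if alt_index < len(parts) else parts[0]
    return None if value in (None, ".", "") else str(value)


def read_annotated_vcf(
    path: str | Path, field_map: VcfFieldMap | None = None
) -> list[VariantRecord]:
    """Read an annotated multi-sample VCF into VariantRecords.

    Multi-allelic sites are split: one record per ALT, per-sample dosage
    re-expressed as the count of that ALT allele in the genotype. A genotype
    containing any missing allele becomes a missing call. Annotations absent
    from INFO stay ``None``.
    """
    fm = field_map or VcfFieldMap()
    path = str(path)
    vcf = VCF(path, gts012=False)
    file_samples = list(vcf.samples)
    if fm.samples is not None:
        keep = [s for s in file_samples if s in fm.samples]
        missing = [s for s in fm.samples if s not in file_samples]
        if missing:
            logger.warning("samples in field map absent from VCF: %s", missing)
    else:
        keep = file_samples
    keep_idx = [(s, file_samples.index(s)) for s in keep]

    records: list[VariantRecord] = []
    for v in vcf:
        alts = v.ALT
        gts = v.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(alts):
            allele_code = k + 1
            calls = []
            for sample, i in keep_idx:
                gt = gts[i]
                alleles = [a for a in gt[:-1] if a is not None]
                if not alleles or any(a < 0 for a in alleles):
                    dosage = None
                else:
                    dosage = sum(a == allele_code for a in alleles)
                calls.append(GenotypeCall(sample, dosage))
            csq_raw = _to_str(v.INFO.get(fm.consequence_key), k)
            consequence = None
            if csq_raw is not None:
                consequence = SO_TERM_MAP.get(csq_raw, Consequence.OTHER)
            afs = [
                _to_float(v.INFO.get(key), k)
                for key in fm.af_keys
            ]
            afs = [a for a in afs if a is not None]
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    gene=_to_str(v.INFO.get(fm.gene_key), k),
                    consequence=consequence,
                    pop_af=max(afs) if afs else None,
                    scores=ScoreBundle(
                        sift=_to_float(v.INFO.get(fm.sift_key), k),
                        polyphen=_to_float(v.INFO.get(fm.polyphen_key), k),
                        revel=_to_float(v.INFO.get(fm.revel_key), k),
                    ),
                    genotypes=tuple(calls),
                )
            )
    vcf.close()
    return records


_GT_OUT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def _fmt_float(x: float) -> str:
    return repr(round(float(x), 10))


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str] | None = None,
    field_map: VcfFieldMap | None = None,
) -> None:
    """Write bi-allelic VariantRecords as a sorted VCF 4.2 text file.

    The inverse of :func:`read_annotated_vcf` on the modeled field set.
    All records must carry genotypes for the same sample list.
    """
    fm = field_map or VcfFieldMap()
    if samples is None:
        samples = records[0].sample_ids if records else []

    def chrom_key(chrom: str):
        c = chrom.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    contigs = sorted({r.chrom for r in records}, key=chrom_key)
    header = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        f'##INFO=<ID={fm.gene_key},Number=1,Type=String,Description="Gene symbol">',
        f'##INFO=<ID={fm.consequence_key},Number=1,Type=String,Description="Consequence class">',
        f'##INFO=<ID={fm.af_keys[0]},Number=1,Type=Float,Description="Max population allele frequency">',
        f'##INFO=<ID={fm.sift_key},Number=1,Type=Float,Description="SIFT score (low=deleterious)">',
        f'##INFO=<ID={fm.polyphen_key},Number=1,Type=Float,Description="PolyPhen-2 probability">',
        f'##INFO=<ID={fm.revel_key},Number=1,Type=Float,Description="REVEL score">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]

    def sort_key(r: VariantRecord):
        chrom = r.chrom.removeprefix("chr")
        return (0, int(chrom)) if chrom.isdigit() else (1, chrom), r.pos, r.ref, r.alt

    lines = []
    for r in sorted(records, key=sort_key):
        info = []
        if r.gene is not None:
            info.append(f"{fm.gene_key}={r.gene}")
        if r.consequence is not None:
            info.append(f"{fm.consequence_key}={r.consequence.value}")
        if r.pop_af is not None:
            info.append(f"{fm.af_keys[0]}={_fmt_float(r.pop_af)}")
        for key, val in (
            (fm.sift_key, r.scores.sift),
            (fm.polyphen_key, r.scores.polyphen),
            (fm.revel_key, r.scores.revel),
        ):
            if val is not None:
                info.append(f"{key}={_fmt_float(val)}")
        gt_cols = "\t".join(_GT_OUT[r.dosage(s)] for s in samples)
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
            f"{';'.join(info) or '.'}\tGT\t{gt_cols}"
        )
    Path(path).write_text("\n".join(header + lines) + "\n")


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    import gzip

    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_site_rows(path: str | Path, n_extra: int = 0):
    """Yield (lineno, chrom, pos, ref, alt, extras) from a site TSV.

    Accepts an optional header line (detected by a non-integer second field
    on the first row) and '#' comments.
    """
    path = Path(path)
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4 + n_extra:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >={4 + n_extra} columns, "
                    f"got {len(cols)}"
                )
            try:
                pos = int(cols[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(
                    f"{path.name}:{lineno}: position {cols[1]!r} is not an integer"
                ) from None
            yield lineno, cols[0], pos, cols[2], cols[3], cols[4 : 4 + n_extra]


def read_panel(gene_path: str | Path, variant_path: str | Path) -> PanelSet:
    """Read the known-gene list and known-variant TSV into a PanelSet."""
    genes: set[str] = set()
    with _open_text(gene_path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(line.split()[0].upper())
    known = {
        (chrom, pos, ref, alt)
        for _, chrom, pos, ref, alt, _ in _parse_site_rows(variant_path)
    }
    return PanelSet(genes=genes, known_variants=known)


def read_local_frequency_table(path: str | Path) -> LocalFrequencyTable:
    """Read a TSV of chrom, pos, ref, alt, frequency."""
    freqs: dict[tuple[str, int, str, str], float] = {}
    for lineno, chrom, pos, ref, alt, (freq,) in _parse_site_rows(path, n_extra=1):
        try:
            f = float(freq)
        except ValueError:
            raise ParseError(
                f"{Path(path).name}:{lineno}: frequency {freq!r} is not a number"
            ) from None
        freqs[(chrom, pos, ref, alt)] = f
    return LocalFrequencyTable(freqs=freqs)


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_bool(s: str, where: str) -> bool:
    low = s.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ParseError(f"{where}: boolean flag {s!r} not understood")


def read_gene_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read the gene-annotation TSV: gene, kidney_expressed, prior_association, prior_score."""
    path = Path(path)
    out: dict[str, GeneAnnotation] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 4 columns, got {len(cols)}"
                )
            gene, kidney, assoc, score = cols[:4]
            if lineno == 1 and gene.lower() in {"gene", "symbol"}:
                continue
            where = f"{path.name}:{lineno}"
            try:
                prior = float(score)
            except ValueError:
                raise ParseError(f"{where}: prior_score {score!r} is not a number") from None
            g = gene.upper()
            out[g] = GeneAnnotation(
                gene=g,
                kidney_expressed=_parse_bool(kidney, where),
                prior_disease_association=_parse_bool(assoc, where),
                prior_score=prior,
            )
    return out
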