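"""Annotated variant tables: reading, validation, filtering, inheritance.

Variants arrive pre-annotated (gene symbol, HGVS, population frequency and
precomputed CADD / VIPUR deleteriousness scores) either as a TSV table or as a
VCF whose INFO field carries ``CADD`` and ``VIPUR`` floats. This module never
computes scores; it validates, filters by population frequency and by a
candidate-gene panel, and summarizes parental inheritance of the variants that
survive stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AnnotatedVariant",
    "GenePanel",
    "InheritanceSummary",
    "read_variant_table",
    "write_variant_table",
    "filter_by_maf",
    "filter_by_panel",
    "summarize_inheritance",
    "default_mma_panel",
    "INHERITANCE_STATES",
    "PHENOTYPE_LABELS",
]

INHERITANCE_STATES = {
    "de_novo",
    "maternal",
    "paternal",
    "biparental_unknown",
    "not_established",
}
PHENOTYPE_LABELS = {"MMA", "aortic", "other_arteriopathy", "this_study"}

_TSV_COLUMNS = [
    "variant_id", "gene", "hgvs_p", "chrom", "pos", "ref", "alt",
    "global_maf", "cadd", "vipur", "inheritance", "phenotype_label",
    "carrier_ids",
]


class VariantValidationError(ValueError):
    """A variant record violates a field contract."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One scored missense (or small indel) variant.

    ``cadd`` is a phred-scaled deleteriousness score (>= 0, higher = more
    deleterious); ``vipur`` is a structure-based deleteriousness probability
    in [0, 1]. Either may be missing (``None``) — missingness is meaningful
    (e.g. no structural model available) and is never coerced to 0.
    """

    variant_id: str
    gene: str
    hgvs_p: str = ""
    chrom: str = ""
    pos: Optional[int] = None
    ref: str = ""
    alt: str = ""
    global_maf: Optional[float] = None
    cadd: Optional[float] = None
    vipur: Optional[float] = None
    inheritance: str = "not_established"
    phenotype_label: Optional[str] = None
    carrier_ids: tuple[str, ...] = ()
    true_component: Optional[str] = None  # synthetic ground truth, if any

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise VariantValidationError("variant_id must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise VariantValidationError(
                f"{self.variant_id}: pos must be >= 1 (1-based), got {self.pos}"
            )
        if self.global_maf is not None and not 0.0 <= self.global_maf <= 1.0:
            raise VariantValidationError(
                f"{self.variant_id}: global_maf {self.global_maf} outside [0, 1]"
            )
        if self.vipur is not None and not 0.0 <= self.vipur <= 1.0:
            raise VariantValidationError(
                f"{self.variant_id}: vipur {self.vipur} outside [0, 1]"
            )
        if self.cadd is not None and self.cadd < 0:
            raise VariantValidationError(
                f"{self.variant_id}: cadd {self.cadd} must be >= 0"
            )
        if self.inheritance not in INHERITANCE_STATES:
            raise VariantValidationError(
                f"{self.variant_id}: unknown inheritance {self.inheritance!r}"
            )
        if self.phenotype_label is not None and self.phenotype_label not in PHENOTYPE_LABELS:
            raise VariantValidationError(
                f"{self.variant_id}: unknown phenotype_label {self.phenotype_label!r}"
            )

    @property
    def n_occurrences(self) -> int:
        """Occurrences = variant x carrier; a record without carrier list counts once."""
        return max(1, len(self.carrier_ids))


@dataclass(frozen=True)
class GenePanel:
    """A named set of candidate-gene HGNC symbols (e.g. the MMA panel)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        object.__setattr__(
            self, "genes", frozenset(g.strip().upper() for g in self.genes)
        )

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.genes

    @classmethod
    def from_file(cls, path: str | Path, name: Optional[str] = None) -> "GenePanel":
        path = Path(path)
        symbols = [
            line.strip() for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(name=name or path.stem, genes=frozenset(symbols))


@dataclass(frozen=True)
class InheritanceSummary:
    """Occurrence-level inheritance counts for (possibly) deleterious variants."""

    n_occurrences: int
    n_established: int
    n_de_novo: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_de_novo <= self.n_established <= self.n_occurrences):
            raise ValueError("require n_de_novo <= n_established <= n_occurrences")

    @property
    def de_novo_fraction(self) -> Optional[int]:
        """Percent de novo among established occurrences, half-away-from-zero.

        Undefined (None) when no occurrence has established inheritance.
        """
        if self.n_established == 0:
            return None
        return int(math.floor(100.0 * self.n_de_novo / self.n_established + 0.5))


def _parse_missing(cell: object) -> Optional[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    return None if s in ("", ".", "NA", "nan") else s


def _parse_float(cell: object, line_no: int, col: str) -> Optional[float]:
    s = _parse_missing(cell)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise VariantValidationError(f"line {line_no}: bad {col} value {s!r}") from exc


def read_variant_table(path: str | Path, format: str = "tsv") -> list[AnnotatedVariant]:
    """Read an annotated variant table from TSV or VCF.

    TSV dialect: tab-separated, UTF-8, header row; ``.`` or empty cell means
    missing; ``carrier_ids`` is a comma-separated list. VCF: standard 4.2 with
    scores in INFO keys ``CADD`` and ``VIPUR``; one record is emitted per ALT
    allele. Missing score cells become missing values, never 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"variant_id", "gene", "cadd"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise VariantValidationError(
            f"{path}: missing required columns {sorted(missing_cols)}"
        )
    out: list[AnnotatedVariant] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            carriers = _parse_missing(row.get("carrier_ids"))
            pos = _parse_missing(row.get("pos"))
            out.append(AnnotatedVariant(
                variant_id=str(row["variant_id"]).strip(),
                gene=str(row["gene"]).strip(),
                hgvs_p=_parse_missing(row.get("hgvs_p")) or "",
                chrom=_parse_missing(row.get("chrom")) or "",
                pos=int(pos) if pos is not None else None,
                ref=_parse_missing(row.get("ref")) or "",
                alt=_parse_missing(row.get("alt")) or "",
                global_maf=_parse_float(row.get("global_maf"), line_no, "global_maf"),
                cadd=_parse_float(row.get("cadd"), line_no, "cadd"),
                vipur=_parse_float(row.get("vipur"), line_no, "vipur"),
                inheritance=_parse_missing(row.get("inheritance")) or "not_established",
                phenotype_label=_parse_missing(row.get("phenotype_label")),
                carrier_ids=tuple(c.strip() for c in carriers.split(",")) if carriers else (),
            ))
        except VariantValidationError as exc:
            raise VariantValidationError(f"{path} line {line_no}: {exc}") from exc
        except (ValueError, TypeError) as exc:
            raise VariantValidationError(f"{path} line {line_no}: {exc}") from exc
    return out


def _read_vcf(path: Path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    out: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    for rec in vcf:
        cadd = rec.INFO.get("CADD")
        vipur = rec.INFO.get("VIPUR")
        maf = rec.INFO.get("MAF")
        gene = rec.INFO.get("GENE") or ""
        for i, alt in enumerate(rec.ALT):
            vid = rec.ID or f"{rec.CHROM}-{rec.POS}-{rec.REF}-{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}-alt{i + 1}"
            out.append(AnnotatedVariant(
                variant_id=vid,
                gene=str(gene),
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref=str(rec.REF),
                alt=str(alt),
                global_maf=float(maf) if maf is not None else None,
                cadd=float(cadd) if cadd is not None else None,
                vipur=float(vipur) if vipur is not None else None,
            ))
    vcf.close()
    return out


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write variants to the package TSV dialect ('.' for missing cells)."""
    rows = []
    for v in variants:
        rows.append({
            "variant_id": v.variant_id,
            "gene": v.gene,
            "hgvs_p": v.hgvs_p or ".",
            "chrom": v.chrom or ".",
            "pos": v.pos if v.pos is not None else ".",
            "ref": v.ref or ".",
            "alt": v.alt or ".",
            "global_maf": repr(v.global_maf) if v.global_maf is not None else ".",
            "cadd": repr(v.cadd) if v.cadd is not None else ".",
            "vipur": repr(v.vipur) if v.vipur is not None else ".",
            "inheritance": v.inheritance,
            "phenotype_label": v.phenotype_label or ".",
            "carrier_ids": ",".join(v.carrier_ids) or ".",
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_by_maf(
    variants: Iterable[AnnotatedVariant], maf_max: float = 0.02
) -> list[AnnotatedVariant]:
    """Keep variants rarer than ``maf_max`` in the population.

    Comparison is strict (< maf_max). A missing frequency is retained: absence
    from population databases is itself evidence of rarity. Order preserved.
    """
    if not 0.0 < maf_max <= 1.0:
        raise ValueError("maf_max must be in (0, 1]")
    return [v for v in variants if v.global_maf is None or v.global_maf < maf_max]


def filter_by_panel(
    variants: Iterable[AnnotatedVariant], panel: GenePanel
) -> list[AnnotatedVariant]:
    """Keep variants whose gene is on the panel (case-insensitive symbol match)."""
    return [v for v in variants if v.gene in panel]


def summarize_inheritance(variants: Iterable[AnnotatedVariant]) -> InheritanceSummary:
    """Occurrence-level inheritance summary.

    The counting unit is the variant *occurrence* (variant x carrier): a
    variant carried by two patients contributes two occurrences, each with the
    record's inheritance status. "Established" covers every state except
    ``not_established`` (a de novo call requires both parents, so de novo
    occurrences are established ones).
    """
    n_occ = n_est = n_dn = 0
    for v in variants:
        k = v.n_occurrences
        n_occ += k
        if v.inheritance != "not_established":
            n_est += k
            if v.inheritance == "de_novo":
                n_dn += k
    return InheritanceSummary(n_occurrences=n_occ, n_established=n_est, n_de_novo=n_dn)


def default_mma_panel() -> GenePanel:
    """The bundled candidate-gene panel for Moyamoya-associated genes.

    A stand-in list of genes reported with Moyamoya angiopathy; replace with a
    curated 87-gene panel file via :meth:`GenePanel.from_file` for real use.
    """
    text = resources.files("moyastrat.data").joinpath("mma_panel.txt").read_text()
    symbols = [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return GenePanel(name="mma_panel", genes=frozenset(symbols))
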