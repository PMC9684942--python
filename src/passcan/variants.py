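"""Per-line variant sets and line-specific SNV derivation.

The two divergently selected lines (Fat, Lean) each contribute one VCF;
*line-specific* variants are those present in one line's set and absent
from the other's, keyed by (chrom, pos, ref, alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional

__all__ = ["Variant", "LineVariantSet", "read_variants", "line_specific"]

VariantKey = tuple[str, int, str, str]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    variant_id: Optional[str] = None
    genotype: Optional[str] = None  # "hom_ref" | "het" | "hom_alt" | None

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele) <= _BASES:
                raise ValueError(f"bad allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class LineVariantSet:
    """Variants attributed to one selection line, keyed by (chrom,pos,ref,alt)."""

    line_label: str
    variants: dict[VariantKey, Variant] = field(default_factory=dict)

    def add(self, variant: Variant) -> None:
        if variant.key in self.variants:
            raise ValueError(f"duplicate variant key: {variant.key}")
        self.variants[variant.key] = variant

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants


def _classify_gt(gt_type: int) -> Optional[str]:
    # cyvcf2 gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
    return {0: "hom_ref", 1: "het", 3: "hom_alt"}.get(gt_type)


def read_variants(
    path: str | Path,
    line_label: str,
    sample: Optional[str] = None,
    snv_only: bool = True,
) -> LineVariantSet:
    """Read a VCF into a LineVariantSet.

    Multi-allelic records are split into biallelic variants (one per alt).
    Symbolic alleles are rejected; indels are dropped when ``snv_only``.
    When ``sample`` is given, only records with a non-reference genotype for
    that sample are kept.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such VCF: {path}")
    vcf = VCF(str(path))
    sample_idx: Optional[int] = None
    if sample is not None:
        if sample not in vcf.samples:
            raise ValueError(f"sample {sample!r} not in VCF ({vcf.samples})")
        sample_idx = vcf.samples.index(sample)

    out = LineVariantSet(line_label)
    for record in vcf:
        genotype = None
        if sample_idx is not None:
            genotype = _classify_gt(int(record.gt_types[sample_idx]))
            if genotype in (None, "hom_ref"):
                continue
        for alt in record.ALT:
            if alt.startswith("<") or "*" in alt or "." in alt:
                raise ValueError(
                    f"symbolic/unsupported allele {alt!r} at "
                    f"{record.CHROM}:{record.POS}"
                )
            variant = Variant(
                chrom=record.CHROM,
                pos=record.POS,
                ref_allele=record.REF.upper(),
                alt_allele=alt.upper(),
                variant_id=record.ID,
                genotype=genotype,
            )
            if snv_only and not variant.is_snv:
                continue
            out.add(variant)
    return out


def line_specific(
    a: LineVariantSet,
    b: LineVariantSet,
    rule: Literal["presence", "hom_fixed"] = "presence",
) -> tuple[LineVariantSet, LineVariantSet]:
    """Split two line sets into their line-specific halves.

    ``presence``: a variant is a-specific when its key is absent from b
    (and symmetrically).  ``hom_fixed`` additionally requires the owning
    line's genotype to be homozygous-alternate (genotype information must
    be present; the other line is already non-carrying by key absence).
    """
    def specific(own: LineVariantSet, other: LineVariantSet) -> LineVariantSet:
        out = LineVariantSet(own.line_label)
        for variant in own:
            if variant.key in other:
                continue
            if rule == "hom_fixed":
                if variant.genotype is None:
                    raise ValueError(
                        "hom_fixed rule requires genotype information "
                        f"(variant {variant.key} has none)"
                    )
                if variant.genotype != "hom_alt":
                    continue
            out.add(variant)
        return out

    if rule not in ("presence", "hom_fixed"):
        raise ValueError(f"unknown line-specificity rule: {rule}")
    return specific(a, b), specific(b, a)
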