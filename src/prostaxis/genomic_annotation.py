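"""Printed variant-retention and copy-number classification rules.

These are the downstream filtering rules applied to externally produced
somatic calls: germline-subtracted variants are retained only when they
pass the caller's filter, meet depth/allele-fraction floors (DP >= 10,
VD >= 3, AF >= 0.02, all inclusive) and are nonsynonymous coding changes;
copy-number log-ratios map to five ordered categories at the cutpoints
-1.1 / -0.4 / 0.3 / 1.1; samples need at least 15% tumor content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "CopyNumberCall",
    "filter_variants",
    "variant_retention_reason",
    "classify_copy_number",
    "tumor_content_gate",
    "CN_CATEGORIES",
]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str
    dp: int
    vd: int
    af: float
    coding: bool
    synonymous: bool
    present_in_matched_germline: bool = False

    def __post_init__(self) -> None:
        if self.vd > self.dp:
            raise ValueError(
                f"variant depth {self.vd} exceeds total depth {self.dp} "
                f"at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele fraction {self.af} outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_retention_reason(v: VariantRecord) -> str | None:
    """None if the variant is retained, else the first failed criterion."""
    if v.present_in_matched_germline:
        return "germline"
    if v.filter_status != "PASS":
        return "FILTER"
    if v.dp < 10:
        return "DP"
    if v.vd < 3:
        return "VD"
    if v.af < 0.02:
        return "AF"
    if not v.coding:
        return "noncoding"
    if v.synonymous:
        return "synonymous"
    return None


def filter_variants(records) -> list[VariantRecord]:
    """Retain germline-subtracted, PASS, DP>=10, VD>=3, AF>=0.02
    nonsynonymous coding variants; order-preserving and idempotent.

    Dropped records are logged with the criterion that failed.
    """
    kept: list[VariantRecord] = []
    for v in records:
        reason = variant_retention_reason(v)
        if reason is None:
            kept.append(v)
        else:
            logger.info(
                "dropped %s:%s %s>%s (%s)", v.chrom, v.pos, v.ref, v.alt, reason
            )
    return kept


CN_CATEGORIES = (
    "deep_deletion",
    "deletion",
    "copy_neutral",
    "gain",
    "amplification",
)


@dataclass(frozen=True)
class CopyNumberCall:
    gene: str
    log_ratio: float
    category: str


def classify_copy_number(log_ratio: float) -> str:
    """Map a copy-number log-ratio to its category.

    Cutpoints -1.1, -0.4, 0.3 and 1.1; a value sitting exactly on a shared
    boundary is assigned to the less extreme category, so the extreme
    classes are open at their boundary ("below -1.1", "above 1.1").
    """
    if not math.isfinite(log_ratio):
        raise ValueError(f"log ratio must be finite, got {log_ratio}")
    if log_ratio < -1.1:
        return "deep_deletion"
    if log_ratio < -0.4:
        return "deletion"
    if log_ratio <= 0.3:
        return "copy_neutral"
    if log_ratio <= 1.1:
        return "gain"
    return "amplification"


def tumor_content_gate(purity: float) -> bool:
    """Keep samples with at least 15% tumor content (boundary inclusive)."""
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity {purity} outside [0, 1]")
    return purity >= 0.15
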