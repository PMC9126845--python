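"""The two rare-variant filter cascades and consequence classification.

Candidate-gene branch (applied to the concatenated multi-caller call set):
drop synonymous/intronic/intergenic/UTR calls, then require QUAL > 40,
DP >= 20, GQ >= 60 when any of GATK-UG / GATK-HC / Freebayes made the call,
and support from more than one caller (a Sanger spot-check of single-caller
calls found them all artifactual).  Survivors are filtered against a ranked
common-variant list (top half removed), a gnomAD MAF cutoff (0.01 for
heterozygous analysis, 0.05 for homozygous), and a platform filter removing
variants carried by more than 40% of samples.

Binomial (burden) branch: VQSR pass, DP >= 8, GQ >= 20, MQ >= 40, at least
three alt-supporting reads, outside low-complexity regions; then MAF at or
below a chosen threshold (1e-5 / 1e-4 / 1e-3) in every one of ExAC, 1000
Genomes and ESP, absent values counting as 0 (novel).

Consequence classes: LoF (stop-gain, stop-loss, frameshift indel, splice
site, start-loss) and D-Mis (missense called deleterious by MetaSVM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import (
    GQ_SENSITIVE_CALLERS,
    LOF_CONSEQUENCES,
    NONCODING_CONSEQUENCES,
    RARE_MAF_SOURCES,
    VariantRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterDecision:
    """Keep/drop outcome with the first failed rule as the reason code."""

    keep: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.keep


def candidate_qc_filter(v: VariantRecord) -> FilterDecision:
    """Candidate-branch QC; drop reason is the first failed rule in order
    QUAL, DP, GQ, caller-count, consequence."""
    if v.qual is None or v.dp is None:
        raise ValueError(f"variant {v.key} missing mandatory QUAL/DP")
    if not v.qual > 40:
        return FilterDecision(False, "QUAL")
    if not v.dp >= 20:
        return FilterDecision(False, "DP")
    if v.callers & GQ_SENSITIVE_CALLERS:
        if v.gq is None or not v.gq >= 60:
            return FilterDecision(False, "GQ")
    if len(v.callers) <= 1:
        return FilterDecision(False, "caller-count")
    if v.consequence in NONCODING_CONSEQUENCES:
        return FilterDecision(False, "consequence")
    return FilterDecision(True)


def common_variant_filter(
    variants: Iterable[VariantRecord], ranked_common_list: Sequence[str]
) -> list[VariantRecord]:
    """Remove variants in the top half (rounded up) of a ranked common list.

    The list is ordered most- to least-common (e.g. a vendor-supplied common
    variant catalogue); an empty list is the identity.
    """
    if not ranked_common_list:
        return list(variants)
    n_top = math.ceil(len(ranked_common_list) / 2)
    top = set(ranked_common_list[:n_top])
    return [v for v in variants if v.key not in top]


def maf_filter(
    v: VariantRecord, het_cutoff: float = 0.01, hom_cutoff: float = 0.05
) -> tuple[bool, bool]:
    """(keep-for-het, keep-for-hom) by gnomAD MAF.

    Kept for heterozygous analysis iff MAF <= het_cutoff; for homozygous
    analysis iff MAF <= hom_cutoff and at least one homozygous genotype
    exists.  A missing gnomAD value is treated as 0 (novel variant).
    """
    maf = v.pop_mafs.get("gnomAD") or 0.0
    keep_het = maf <= het_cutoff
    keep_hom = maf <= hom_cutoff and v.n_hom > 0
    return keep_het, keep_hom


def platform_filter(
    variants: Iterable[VariantRecord], n_samples: int, share_cutoff: float = 0.40
) -> list[VariantRecord]:
    """Drop variants carried (het or hom) by > share_cutoff of the cohort.

    Removes platform/capture artifacts that recur across samples far above
    any plausible population frequency.
    """
    if n_samples <= 0:
        raise ValueError(f"n_samples must be positive, got {n_samples}")
    limit = share_cutoff * n_samples
    return [v for v in variants if v.n_carriers <= limit]


def burden_qc_filter(v: VariantRecord) -> FilterDecision:
    """Burden-branch QC; reason order VQSR, DP, GQ, MQ, supporting-reads, LCR.

    All numeric thresholds are inclusive (DP >= 8, GQ >= 20, MQ >= 40,
    alt reads >= 3).
    """
    if not v.vqsr_pass:
        return FilterDecision(False, "VQSR")
    if v.dp is None or not v.dp >= 8:
        return FilterDecision(False, "DP")
    if v.gq is None or not v.gq >= 20:
        return FilterDecision(False, "GQ")
    if v.mq is None or not v.mq >= 40:
        return FilterDecision(False, "MQ")
    if v.alt_reads is None or not v.alt_reads >= 3:
        return FilterDecision(False, "supporting-reads")
    if v.lcr:
        return FilterDecision(False, "LCR")
    return FilterDecision(True)


def rare_filter(v: VariantRecord, threshold: float) -> bool:
    """Keep iff MAF <= threshold in every one of ExAC, 1000G and ESP.

    An absent source value counts as 0: novel variants are by definition
    rare.
    """
    for source in RARE_MAF_SOURCES:
        maf = v.pop_mafs.get(source) or 0.0
        if maf > threshold:
            return False
    return True


def consequence_class(v: VariantRecord) -> str:
    """Classify as ``LoF``, ``D-Mis`` or ``other``.

    LoF: stop-gain, stop-loss, frameshift indel, splice site, start-loss.
    D-Mis: missense with a deleterious MetaSVM call.  Unknown labels fall to
    ``other`` with a logged warning.
    """
    c = v.consequence
    if c in LOF_CONSEQUENCES:
        return "LoF"
    if c == "missense":
        return "D-Mis" if v.metasvm == "deleterious" else "other"
    if c is None or c not in NONCODING_CONSEQUENCES and c not in (
        "missense",
        "other-indel",
    ):
        if c is not None:
            logger.warning("unknown consequence label %r at %s; classed other", c, v.key)
    return "other"


def cohort_maf(n_het: int, n_hom: int, n_samples: int) -> float:
    """Within-cohort minor allele frequency (n_het + 2*n_hom) / (2*n_samples)."""
    if n_samples <= 0:
        raise ValueError(f"n_samples must be positive, got {n_samples}")
    if n_het < 0 or n_hom < 0 or n_het + n_hom > n_samples:
        raise ValueError(
            f"invalid genotype counts: {n_het} het + {n_hom} hom of {n_samples}"
        )
    return (n_het + 2 * n_hom) / (2 * n_samples)


def apply_candidate_cascade(
    variants: Sequence[VariantRecord],
    n_samples: int,
    ranked_common_list: Sequence[str] = (),
    het_maf_cutoff: float = 0.01,
    hom_maf_cutoff: float = 0.05,
    share_cutoff: float = 0.40,
) -> tuple[list[VariantRecord], list[VariantRecord], dict[str, int]]:
    """Full candidate-gene cascade; returns (het set, hom set, stage tally).

    The tally maps stage name to record count after that stage, so stage-wise
    accounting can be reported alongside results.
    """
    tally = {"input": len(variants)}
    kept = [v for v in variants if candidate_qc_filter(v)]
    tally["qc"] = len(kept)
    kept = common_variant_filter(kept, ranked_common_list)
    tally["common-list"] = len(kept)
    kept = platform_filter(kept, n_samples, share_cutoff)
    tally["platform"] = len(kept)
    het_set, hom_set = [], []
    for v in kept:
        keep_het, keep_hom = maf_filter(v, het_maf_cutoff, hom_maf_cutoff)
        if keep_het:
            het_set.append(v)
        if keep_hom:
            hom_set.append(v)
    tally["maf-het"] = len(het_set)
    tally["maf-hom"] = len(hom_set)
    return het_set, hom_set, tally


def apply_burden_cascade(
    variants: Sequence[VariantRecord], threshold: float
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Burden-branch cascade: QC, rarity, damaging class; returns survivors
    (LoF or D-Mis only) and the per-stage tally."""
    tally = {"input": len(variants)}
    kept = [v for v in variants if burden_qc_filter(v)]
    tally["qc"] = len(kept)
    kept = [v for v in kept if rare_filter(v, threshold)]
    tally["rare"] = len(kept)
    kept = [v for v in kept if consequence_class(v) in ("LoF", "D-Mis")]
    tally["damaging"] = len(kept)
    return kept, tally
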