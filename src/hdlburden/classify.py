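"""Consensus deleteriousness classification over ten prediction tools.

Instead of a full ACMG engine, each variant gets a consensus damaging vote
count over ten impact predictors (SIFT, PolyPhen-HVAR, MutationTaster,
MutationAssessor, FATHMM, PROVEAN, MetaSVM, MetaLR, M-CAP, FATHMM-MKL): a
damaging call scores 1, an equivocal call 0.5, tolerated and missing 0.  The
counts are ranked within the assessed set (mid-rank percentiles) and mapped to
four classes:

    >= 80th percentile                      probably_damaging
    in [50th, 80th)                         undetermined
    <  50th percentile                      likely_benign
    >  50th + unequivocal ClinVar entry     pathogenic (overrides the above)

"Unequivocal" means a ClinVar label containing pathogenic/likely pathogenic
with no benign, conflicting or uncertain token; sub-50th-percentile variants
stay likely_benign regardless of ClinVar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .records import PREDICTION_TOOLS, VOTE_VALUES, Participant, VariantRecord
from .selection import compare_distributions

logger = logging.getLogger(__name__)

DAMAGING_CLASSES = frozenset({"pathogenic", "probably_damaging"})

_VOTE_SCORE = {"damaging": 1.0, "equivocal": 0.5, "tolerated": 0.0, "missing": 0.0}


@dataclass
class DamageAssessment:
    """Consensus assessment for one variant."""

    key: str
    vote_count: float
    percentile: Optional[float] = None
    klass: Optional[str] = None


def damage_vote_count(votes: Mapping[str, str]) -> float:
    """Consensus score in [0, 10]: damaging 1, equivocal 0.5, else 0.

    Requires exactly the ten configured tools; an unconfigured tool name is
    an error.  Missing calls contribute 0 (the 0-10 scale is fixed, not
    renormalized) and are counted in a logged warning.
    """
    extra = set(votes) - set(PREDICTION_TOOLS)
    if extra:
        raise ValueError(f"votes from unconfigured tools: {sorted(extra)}")
    missing_tools = set(PREDICTION_TOOLS) - set(votes)
    if missing_tools:
        raise ValueError(f"votes absent for tools: {sorted(missing_tools)}")
    n_missing = 0
    total = 0.0
    for tool in PREDICTION_TOOLS:
        call = votes[tool]
        if call not in VOTE_VALUES:
            raise ValueError(f"invalid vote {call!r} from {tool}")
        if call == "missing":
            n_missing += 1
        total += _VOTE_SCORE[call]
    if n_missing == len(PREDICTION_TOOLS):
        logger.warning("all %d tool calls missing; vote count is 0", n_missing)
    elif n_missing:
        logger.debug("%d of %d tool calls missing", n_missing, len(PREDICTION_TOOLS))
    return total


def is_unequivocal_pathogenic(label: Optional[str]) -> bool:
    """True for ClinVar labels asserting (likely) pathogenic with no
    benign/conflicting/uncertain qualifier."""
    if not label:
        return False
    text = label.lower()
    if "pathogenic" not in text:
        return False
    for token in ("benign", "conflict", "uncertain"):
        if token in text:
            return False
    return True


def percentile_classify(
    assessments: Sequence[DamageAssessment],
    clinvar: Mapping[str, Optional[str]],
    upper: float = 0.80,
    lower: float = 0.50,
) -> list[DamageAssessment]:
    """Assign percentile ranks and four-way classes in place; returns input.

    Percentile rank of a variant is the fraction of the assessed set with a
    strictly smaller vote count plus half the ties (mid-rank), so it is
    invariant under duplication of the set.  Classes follow the module
    docstring with configurable upper/lower boundaries.
    """
    if not assessments:
        raise ValueError("cannot compute percentiles over an empty assessed set")
    counts = np.array([a.vote_count for a in assessments], dtype=float)
    n = len(counts)
    order = np.sort(counts)
    below = np.searchsorted(order, counts, side="left")
    upto = np.searchsorted(order, counts, side="right")
    percentiles = (below + 0.5 * (upto - below)) / n
    for a, pct in zip(assessments, percentiles):
        a.percentile = float(pct)
        label = clinvar.get(a.key)
        if pct > lower and is_unequivocal_pathogenic(label):
            a.klass = "pathogenic"
        elif pct >= upper:
            a.klass = "probably_damaging"
        elif pct >= lower:
            a.klass = "undetermined"
        else:
            a.klass = "likely_benign"
    return list(assessments)


def assess_variants(
    variants: Sequence[VariantRecord], upper: float = 0.80, lower: float = 0.50
) -> dict[str, DamageAssessment]:
    """Vote-count and classify a whole variant set; returns key -> assessment.

    The percentile reference population is exactly the supplied set (normally
    all variants surviving the candidate-branch cascade in the current run).
    """
    assessments = [
        DamageAssessment(key=v.key, vote_count=damage_vote_count(v.votes))
        for v in variants
    ]
    clinvar = {v.key: v.clinvar for v in variants}
    percentile_classify(assessments, clinvar, upper=upper, lower=lower)
    return {a.key: a for a in assessments}


def _damaging_variants(
    variants: Iterable[VariantRecord],
    assessments: Mapping[str, DamageAssessment],
    genes: Optional[frozenset[str]] = None,
) -> list[VariantRecord]:
    out = []
    for v in variants:
        a = assessments.get(v.key)
        if a is None or a.klass not in DAMAGING_CLASSES:
            continue
        if genes is not None and v.gene not in genes:
            continue
        out.append(v)
    return out


def per_gene_damaging_counts(
    variants: Sequence[VariantRecord],
    assessments: Mapping[str, DamageAssessment],
    gene_list: Iterable[str],
) -> dict[str, int]:
    """Carrier-occurrences of damaging variants per candidate gene.

    An occurrence is one (carrier, variant) pair; homozygous carriage counts
    once.  Only pathogenic / probably_damaging variants in listed genes
    contribute; genes with zero occurrences are omitted.
    """
    genes = frozenset(gene_list)
    counts: dict[str, int] = {}
    for v in _damaging_variants(variants, assessments, genes):
        counts[v.gene] = counts.get(v.gene, 0) + v.n_carriers
    return counts


def per_person_damaging_histogram(
    variants: Sequence[VariantRecord],
    assessments: Mapping[str, DamageAssessment],
    gene_list: Iterable[str],
    cohort_ids: Iterable[str],
) -> dict[int, int]:
    """Histogram k -> number of participants with exactly k damaging
    candidate-gene variants (variants, not genes, are counted); includes
    k = 0, so the histogram sums to the cohort size."""
    genes = frozenset(gene_list)
    per_person = {pid: 0 for pid in cohort_ids}
    for v in _damaging_variants(variants, assessments, genes):
        for pid in v.genotypes:
            if pid in per_person:
                per_person[pid] += 1
    hist: dict[int, int] = {}
    for k in per_person.values():
        hist[k] = hist.get(k, 0) + 1
    return hist


def damaging_carrier_ids(
    variants: Sequence[VariantRecord],
    assessments: Mapping[str, DamageAssessment],
    gene_list: Iterable[str],
) -> set[str]:
    """Participants carrying >= 1 damaging variant in the listed genes."""
    genes = frozenset(gene_list)
    carriers: set[str] = set()
    for v in _damaging_variants(variants, assessments, genes):
        carriers.update(v.genotypes)
    return carriers


def group_carrier_percentages(
    participants: Sequence[Participant], carrier_ids: set[str]
) -> dict[int, float]:
    """Percent of each subphenotype group carrying a damaging variant
    (1 decimal place); groups with no members are omitted."""
    out: dict[int, float] = {}
    for g in (1, 2, 3, 4):
        members = [p for p in participants if p.group == g]
        if members:
            n_car = sum(1 for p in members if p.pid in carrier_ids)
            out[g] = round(100.0 * n_car / len(members), 1)
    return out


@dataclass
class CarrierComparison:
    carrier_mean: float
    carrier_sd: float
    noncarrier_mean: float
    noncarrier_sd: float
    n_carriers: int
    n_noncarriers: int
    p_value: float


def carrier_association(
    variants: Sequence[VariantRecord],
    assessments: Mapping[str, DamageAssessment],
    gene_set: Iterable[str],
    participants: Sequence[Participant],
    variable: str,
    transform: str = "none",
) -> CarrierComparison:
    """Compare a lipid variable between carriers and noncarriers.

    Carriers hold >= 1 pathogenic / probably_damaging variant in the gene
    set; the test is the same transform-then-Welch-t used for group
    summaries.  Raises if either side of the partition is empty or has fewer
    than two observations.
    """
    genes = frozenset(gene_set)
    carrier_ids: set[str] = set()
    for v in _damaging_variants(variants, assessments, genes):
        carrier_ids.update(v.genotypes)
    carriers, noncarriers = [], []
    for p in participants:
        value = getattr(p, variable)
        if value is None:
            continue
        (carriers if p.pid in carrier_ids else noncarriers).append(float(value))
    for side, sample in (("carrier", carriers), ("noncarrier", noncarriers)):
        if len(sample) < 2:
            raise ValueError(
                f"{side} side has {len(sample)} usable observations; need >= 2"
            )
    p_value = compare_distributions(carriers, noncarriers, transform)
    return CarrierComparison(
        carrier_mean=float(np.mean(carriers)),
        carrier_sd=float(np.std(carriers, ddof=1)),
        noncarrier_mean=float(np.mean(noncarriers)),
        noncarrier_sd=float(np.std(noncarriers, ddof=1)),
        n_carriers=len(carriers),
        n_noncarriers=len(noncarriers),
        p_value=p_value,
    )
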