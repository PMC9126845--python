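"""Mutability-calibrated binomial gene-burden test and gene-set enrichment.

The burden test asks whether a gene carries more rare damaging heterozygous
variants than expected from its de novo mutability.  Per-gene mutability is
summed from trinucleotide-context substitution rates over every possible
single-nucleotide change in the coding sequence, split by coding consequence
(LoF / missense / synonymous), with additive frameshift+splice terms and a
base-pair coverage adjustment.  With N total damaging variants across genes,

    p_i        = Mutability_i / sum_j Mutability_j
    Expected_i = N * p_i

and the per-gene p-value is the one-sided binomial tail P(X >= observed) for
X ~ Binomial(N, p_i).  Genome-wide significance uses alpha divided by the
number of genes tested.  Gene-set over-representation uses a one-sided Fisher
exact test with Benjamini-Hochberg FDR across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import GeneSet, VariantRecord

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

ContextKey = tuple[str, str, str, str]  # (5' base, ref, 3' base, alt)

# standard genetic code as a flat codon -> amino-acid map ('*' for stop)
_STANDARD_CODE = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA: dict[str, str] = dict(_STANDARD_CODE.forward_table)
for _stop in _STANDARD_CODE.stop_codons:
    _CODON_AA[_stop] = "*"


def _revcomp_key(key: ContextKey) -> ContextKey:
    five, ref, three, alt = key
    return (
        _COMPLEMENT[three],
        _COMPLEMENT[ref],
        _COMPLEMENT[five],
        _COMPLEMENT[alt],
    )


class MutationRateTable:
    """Trinucleotide-context substitution rates, strand-symmetrized.

    Maps (5' base, ref base, 3' base, alt base) to a per-site per-generation
    rate.  The closure requires exactly 64 contexts x 3 alternate bases = 192
    entries; a table supplied only for pyrimidine-centered contexts (96 rows)
    is expanded by reverse complement.  Conflicting duplicate rows and
    non-positive rates are errors.
    """

    def __init__(self, rates: Mapping[ContextKey, float]):
        table: dict[ContextKey, float] = {}
        for key, rate in rates.items():
            five, ref, three, alt = key
            for base in key:
                if base not in BASES:
                    raise ValueError(f"invalid base {base!r} in context {key}")
            if alt == ref:
                raise ValueError(f"alt equals ref in context {key}")
            if not rate > 0:
                raise ValueError(f"rate must be > 0, got {rate} for {key}")
            if key in table and not np.isclose(table[key], rate, rtol=1e-9):
                raise ValueError(
                    f"conflicting rates for context {key}: {table[key]} vs {rate}"
                )
            table[key] = float(rate)
        # strand symmetry: a substitution and its reverse complement share a rate
        for key, rate in list(table.items()):
            rc = _revcomp_key(key)
            if rc in table:
                if not np.isclose(table[rc], rate, rtol=1e-9):
                    raise ValueError(
                        f"strand-asymmetric rates for {key} / {rc}: "
                        f"{rate} vs {table[rc]}"
                    )
            else:
                table[rc] = rate
        missing = [
            (f, r, t, a)
            for f in BASES
            for r in BASES
            for t in BASES
            for a in BASES
            if a != r and (f, r, t, a) not in table
        ]
        if missing:
            preview = ", ".join("".join(k) for k in missing[:8])
            raise ValueError(
                f"rate table incomplete: {len(missing)} of 192 contexts missing "
                f"(e.g. {preview})"
            )
        self._table = table

    def __len__(self) -> int:
        return len(self._table)

    def __getitem__(self, key: ContextKey) -> float:
        return self._table[key]

    def items(self):
        return self._table.items()


def _classify_substitution(
    cds: str, idx: int, alt: str
) -> str:
    """Coding consequence of substituting ``alt`` at 0-based CDS index ``idx``
    (frame from position 1): LoF / missense / synonymous."""
    codon_idx = idx // 3
    start = codon_idx * 3
    old_codon = cds[start : start + 3]
    offset = idx - start
    new_codon = old_codon[:offset] + alt + old_codon[offset + 1 :]
    if codon_idx == 0 and old_codon == "ATG":
        return "LoF"  # start-loss
    old_aa = _CODON_AA[old_codon]
    new_aa = _CODON_AA[new_codon]
    if old_aa == "*" and new_aa != "*":
        return "LoF"  # stop-loss
    if new_aa == "*" and old_aa != "*":
        return "LoF"  # stop-gain
    if old_aa == new_aa:
        return "synonymous"
    return "missense"


def snv_mutability_classes(
    cds_with_flanks: str, rates: MutationRateTable
) -> dict[str, float]:
    """Per-class SNV mutability of a coding sequence.

    ``cds_with_flanks`` is the CDS with one flanking base on each side (so
    every coding position has a trinucleotide context).  Sums the context
    rate of all 3L possible single-nucleotide substitutions, split by coding
    consequence; returns {"LoF", "missense", "synonymous", "total"}.
    """
    seq = cds_with_flanks.upper()
    if len(seq) < 5 or (len(seq) - 2) % 3 != 0:
        raise ValueError(
            f"need a CDS of length divisible by 3 plus one flanking base each "
            f"side; got total length {len(seq)}"
        )
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"ambiguity codes not supported: {sorted(bad)}")
    cds = seq[1:-1]
    out = {"LoF": 0.0, "missense": 0.0, "synonymous": 0.0, "total": 0.0}
    for i, ref in enumerate(cds):
        five = seq[i]
        three = seq[i + 2]
        for alt in BASES:
            if alt == ref:
                continue
            rate = rates[(five, ref, three, alt)]
            out["total"] += rate
            out[_classify_substitution(cds, i, alt)] += rate
    return out


def snv_mutability_from_cds(
    cds_with_flanks: str, rates: MutationRateTable, klass: str
) -> float:
    """SNV mutability of one consequence class (LoF / missense / synonymous)."""
    classes = snv_mutability_classes(cds_with_flanks, rates)
    if klass not in ("LoF", "missense", "synonymous"):
        raise ValueError(f"unknown mutability class {klass!r}")
    return classes[klass]


@dataclass
class GeneMutability:
    """Per-gene, per-class de novo mutation probability.

    ``lof`` includes the enumerated SNV LoF mutability plus the additive
    frameshift/splice term; ``dmis`` is the damaging-missense share of the
    missense mutability.  ``coverage_factor`` scales both (fraction of coding
    bases adequately covered in the cohort).
    """

    gene: str
    lof: float
    dmis: float
    coverage_factor: float = 1.0
    coding_length: int = 0

    def __post_init__(self) -> None:
        if self.lof < 0 or self.dmis < 0:
            raise ValueError(f"mutabilities must be >= 0 for {self.gene}")
        if not 0.0 <= self.coverage_factor <= 1.0:
            raise ValueError(
                f"coverage factor must be in [0,1], got {self.coverage_factor}"
            )

    @property
    def damaging(self) -> float:
        return self.lof + self.dmis

    @property
    def adjusted_damaging(self) -> float:
        return self.damaging * self.coverage_factor


def gene_mutability_from_cds(
    gene: str,
    cds_with_flanks: str,
    rates: MutationRateTable,
    dmis_fraction: float = 0.35,
    indel_splice_factor: float = 1.25,
    coverage_factor: float = 1.0,
) -> GeneMutability:
    """Build a gene's mutability model from its coding sequence.

    Frameshift/splice mutability is not derivable from the SNV context model;
    it enters as an additive term defaulting to ``indel_splice_factor`` times
    the enumerated SNV LoF mutability.  ``dmis_fraction`` is the share of
    missense mutability expected to be called deleterious by the
    meta-predictor.
    """
    if not 0.0 <= dmis_fraction <= 1.0:
        raise ValueError(f"dmis_fraction must be in [0,1], got {dmis_fraction}")
    classes = snv_mutability_classes(cds_with_flanks, rates)
    lof_snv = classes["LoF"]
    return GeneMutability(
        gene=gene,
        lof=lof_snv * (1.0 + indel_splice_factor),
        dmis=dmis_fraction * classes["missense"],
        coverage_factor=coverage_factor,
        coding_length=len(cds_with_flanks) - 2,
    )


def coverage_adjust(m: GeneMutability, covered_fraction: float) -> GeneMutability:
    """Return a copy with the coverage factor set to ``covered_fraction``."""
    if not 0.0 <= covered_fraction <= 1.0:
        raise ValueError(f"covered fraction must be in [0,1], got {covered_fraction}")
    if covered_fraction == 0.0:
        logger.warning("gene %s has zero coverage; it will be excluded from testing", m.gene)
    return GeneMutability(
        gene=m.gene,
        lof=m.lof,
        dmis=m.dmis,
        coverage_factor=covered_fraction,
        coding_length=m.coding_length,
    )


def expected_counts(
    N: int, genes: Sequence[GeneMutability]
) -> dict[str, tuple[float, float]]:
    """Per-gene (p_i, expected count) with sum(expected) = N exactly.

    p_i is the gene's adjusted damaging mutability over the total across
    genes; expected_i = N * p_i.  Genes with zero adjusted mutability get
    (0, 0); all-zero mutability is an error.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    weights = np.array([g.adjusted_damaging for g in genes], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all gene mutabilities are zero; expectations undefined")
    p = weights / total
    return {g.gene: (float(pi), float(N * pi)) for g, pi in zip(genes, p)}


def binomial_burden(observed: int, N: int, p_i: float) -> float:
    """One-sided binomial tail P(X >= observed), X ~ Binomial(N, p_i).

    Computed through the regularized-incomplete-beta survival function, which
    stays accurate for small p_i and large N where naive term summation
    underflows.
    """
    if not 0 <= observed <= N:
        raise ValueError(f"need 0 <= observed <= N, got observed={observed}, N={N}")
    if not 0.0 <= p_i <= 1.0:
        raise ValueError(f"p_i must be in [0,1], got {p_i}")
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, N, p_i))


@dataclass
class BurdenResult:
    gene: str
    observed: int
    expected: float
    p_i: float
    p_value: float
    significant: bool


def run_burden(
    variants: Sequence[VariantRecord],
    genes: Sequence[GeneMutability],
    alpha: float = 0.05,
) -> list[BurdenResult]:
    """Gene-burden test over filtered damaging heterozygous variants.

    ``variants`` must already have passed the burden-branch cascade (QC,
    rarity, LoF/D-Mis class).  Each heterozygous carriage of a retained
    variant counts one occurrence; N is the total across tested genes (those
    with positive adjusted mutability).  Significance is flagged at
    alpha / (number of genes tested); results are sorted ascending by p.
    """
    tested = [g for g in genes if g.adjusted_damaging > 0]
    if not tested:
        raise ValueError("no genes with positive adjusted mutability")
    gene_names = {g.gene for g in tested}
    observed: dict[str, int] = {g.gene: 0 for g in tested}
    for v in variants:
        if v.gene in gene_names:
            observed[v.gene] += v.n_het
    N = sum(observed.values())
    if N == 0:
        logger.warning("no retained damaging heterozygous variants; empty burden result")
        return []
    expectations = expected_counts(N, tested)
    cutoff = alpha / len(tested)
    results = []
    for g in tested:
        p_i, expected = expectations[g.gene]
        obs = observed[g.gene]
        p = binomial_burden(obs, N, p_i)
        results.append(
            BurdenResult(
                gene=g.gene,
                observed=obs,
                expected=expected,
                p_i=p_i,
                p_value=p,
                significant=p < cutoff,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results


def qq_points(pvalues: Sequence[float]) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a Q-Q plot.

    Observed p-values are sorted ascending; the expected quantile for rank i
    of n is i/(n+1) (uniform order-statistic mean).  p = 0 is clamped to the
    smallest positive double with a logged warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values supplied")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("clamping %d zero p-values", int(np.sum(p == 0)))
        p = np.where(p == 0, np.nextafter(0, 1), p)
    obs = np.sort(p)
    n = len(obs)
    exp = np.arange(1, n + 1) / (n + 1)
    return np.column_stack((-np.log10(exp), -np.log10(obs)))


@dataclass
class GeneSetEnrichment:
    set_id: str
    set_size: int
    hits: int
    expected: float
    fold: float
    p_value: float
    q_value: float
    hit_genes: tuple[str, ...] = field(default_factory=tuple)


def overrepresentation(
    hit_list: Iterable[str],
    sets: Sequence[GeneSet],
    universe: int,
) -> list[GeneSetEnrichment]:
    """Gene-set over-representation: one-sided Fisher exact + BH FDR.

    For each set the 2x2 table is (hits, list non-hits; set non-list,
    remainder) over a gene universe of the given size; expected hits are
    set_size * |hit list| / universe and fold enrichment their ratio.
    Results are sorted by q then p.
    """
    hit_genes = frozenset(hit_list)
    n_list = len(hit_genes)
    if universe < n_list:
        raise ValueError(f"universe ({universe}) smaller than hit list ({n_list})")
    raw = []
    for s in sets:
        size = len(s.members)
        if size > universe:
            raise ValueError(f"gene set {s.name!r} ({size}) larger than universe ({universe})")
        overlap = tuple(sorted(hit_genes & s.members))
        hits = len(overlap)
        expected = size * n_list / universe
        table = [
            [hits, n_list - hits],
            [size - hits, universe - size - n_list + hits],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        raw.append((s, hits, expected, overlap, float(p)))
    pvals = [r[4] for r in raw]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        GeneSetEnrichment(
            set_id=s.name,
            set_size=len(s.members),
            hits=hits,
            expected=expected,
            fold=hits / expected if expected > 0 else float("nan"),
            p_value=p,
            q_value=float(q),
            hit_genes=overlap,
        )
        for (s, hits, expected, overlap, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_id))
    return results
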