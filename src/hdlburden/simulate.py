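"""Synthetic low-HDL-C cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline can be exercised end-to-end and its calibration and power
measured against known ground truth:

* lipid panels with the hyperbolic inverse TG-HDL-C relationship
  (HDL-C = m1 + m2*m3/(m2 + TG) + noise) and TC built as LDL + HDL + TG/5 so
  the Friedewald estimate is exact below 400 mg/dl TG;
* a gene roster of random open reading frames whose per-gene damaging-variant
  counts are Poisson with mean proportional to trinucleotide-context
  mutability, times a planted enrichment multiplier (>= 1) for chosen genes;
* per-variant QC fields, caller sets, population MAFs, ten prediction-tool
  votes drawn from configurable operating points, MetaSVM calls, occasional
  ClinVar labels, and mostly-heterozygous genotypes;
* a truth table (per-variant damaging flag, per-gene multiplier,
  per-participant latent lipids) for recovery tests.

All randomness flows from the design seed through one NumPy generator in a
fixed stage order, so runs are bit-reproducible.  The m1/m2/m3 defaults are
synthetic round numbers, not any study's fitted isopleth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .burden import GeneMutability, MutationRateTable, gene_mutability_from_cds
from .records import CALLERS, PREDICTION_TOOLS, Participant, VariantRecord

_NON_STOP_CODONS = None  # built lazily

ETHNICITIES = (
    ("White European", 0.765),
    ("Mexican", 0.108),
    ("East Asian", 0.039),
    ("Indian", 0.029),
    ("African American", 0.015),
    ("Mixed, other", 0.044),
)

FLAG_PREVALENCE = {
    "CAD": 0.086,
    "MI": 0.055,
    "diabetes": 0.059,
    "hypertension": 0.287,
    "smoker": 0.086,
}


@dataclass
class SimulationDesign:
    """Study conditions for the synthetic cohort.

    Cohort size and demographic rates mirror a 204-person low-HDL-C exome
    cohort (34.3% female, lipid-clinic age structure).  The damaging-count
    law is Poisson per (participant, gene) with mean proportional to the
    gene's context mutability times its enrichment multiplier, aggregated
    here per gene; ``total_expected_damaging`` sets the cohort-wide null
    total.  Tool operating points are P(damaging vote | truly damaging) and
    P(damaging vote | benign).
    """

    n_participants: int = 204
    female_fraction: float = 0.343
    # lipids (mg/dl); TG is lognormal on the natural scale
    tg_log_mean: float = math.log(120.0)
    tg_log_sd: float = 0.6
    m1: float = 20.0
    m2: float = 100.0
    m3: float = 45.0
    hdl_noise_sd: float = 10.0
    ldl_mean: float = 130.0
    ldl_sd: float = 35.0
    # gene roster
    n_genes: int = 200
    gene_length_log_mean: float = math.log(1500.0)
    gene_length_log_sd: float = 0.45
    enrichment: dict[str, float] = field(default_factory=dict)
    # variant load: simulated total chosen so that after QC and rarity
    # thinning about 400 damaging occurrences are retained (~2 per gene in a
    # 200-gene run), the scale of a ~200-exome rare-variant study
    total_expected_damaging: float = 480.0
    background_per_damaging: float = 3.0
    hom_fraction: float = 0.02
    # prediction-tool operating points
    tool_sensitivity: float = 0.90
    tool_false_positive: float = 0.15
    tool_equivocal_prob: float = 0.04
    tool_missing_prob: float = 0.02
    # mutability model shares
    dmis_fraction: float = 0.35
    indel_splice_factor: float = 1.25
    # QC realism
    qc_fail_rate: float = 0.02
    single_caller_rate: float = 0.03
    platform_artifact_rate: float = 0.01
    # population MAF sampling
    novel_fraction: float = 0.5
    not_rare_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError(f"n_participants must be positive, got {self.n_participants}")
        if self.m2 <= 0:
            raise ValueError(f"m2 must be positive, got {self.m2}")
        for gene, mult in self.enrichment.items():
            if mult < 1.0:
                raise ValueError(f"enrichment multiplier for {gene} must be >= 1, got {mult}")
        for name in (
            "female_fraction",
            "tool_sensitivity",
            "tool_false_positive",
            "tool_equivocal_prob",
            "tool_missing_prob",
            "hom_fraction",
            "dmis_fraction",
            "qc_fail_rate",
            "single_caller_rate",
            "platform_artifact_rate",
            "novel_fraction",
            "not_rare_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort.

    ``damaging`` flags every simulated variant exactly once; ``multipliers``
    records the planted per-gene enrichment; ``latent_lipids`` holds each
    participant's (TG, noise-free HDL-C) before measurement noise.
    """

    damaging: dict[str, bool] = field(default_factory=dict)
    multipliers: dict[str, float] = field(default_factory=dict)
    latent_lipids: dict[str, tuple[float, float]] = field(default_factory=dict)


def default_rate_table() -> MutationRateTable:
    """A plausible trinucleotide substitution-rate table.

    Transitions run ~3x transversions around a 1.2e-8 per-site per-generation
    base rate, with a 10x boost for CpG transitions (C->T in a CG context) --
    the canonical features of human de novo SNV rates.  Rates are specified
    for pyrimidine-centered contexts and strand-symmetrized on construction.
    """
    base = 1.2e-8
    transitions = {("C", "T"), ("T", "C")}
    rows: dict[tuple[str, str, str, str], float] = {}
    for five in "ACGT":
        for ref in "CT":  # pyrimidine-centered half
            for three in "ACGT":
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    rate = base * (3.0 if (ref, alt) in transitions else 1.0)
                    if ref == "C" and three == "G" and alt == "T":
                        rate *= 10.0
                    rows[(five, ref, three, alt)] = rate
    return MutationRateTable(rows)


def _non_stop_codons() -> list[str]:
    global _NON_STOP_CODONS
    if _NON_STOP_CODONS is None:
        stops = {"TAA", "TAG", "TGA"}
        _NON_STOP_CODONS = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in stops
        ]
    return _NON_STOP_CODONS


def make_gene_roster(
    design: SimulationDesign,
    rates: MutationRateTable,
    rng: np.random.Generator,
) -> tuple[list[GeneMutability], dict[str, str], dict[str, tuple[str, int]]]:
    """Random gene roster: (mutability models, CDS with flanks, loci).

    Each gene is an open reading frame (ATG, random non-stop codons, TAA)
    with lognormal coding length, placed at a unique locus.  Mutability
    models come from the same enumeration the burden test uses, so the
    generator and the test share one expectation model by construction.
    """
    if design.n_genes <= 0:
        raise ValueError("gene roster must be non-empty")
    codons = _non_stop_codons()
    genes: list[GeneMutability] = []
    cds_map: dict[str, str] = {}
    loci: dict[str, tuple[str, int]] = {}
    for g in range(design.n_genes):
        name = f"G{g + 1:04d}"
        length = float(rng.lognormal(design.gene_length_log_mean, design.gene_length_log_sd))
        n_codons = max(100, int(round(length / 3.0)))
        body = rng.choice(len(codons), size=n_codons - 2)
        cds = "ATG" + "".join(codons[i] for i in body) + "TAA"
        flank5, flank3 = (str(b) for b in rng.choice(list("ACGT"), size=2))
        cds_with_flanks = flank5 + cds + flank3
        genes.append(
            gene_mutability_from_cds(
                name,
                cds_with_flanks,
                rates,
                dmis_fraction=design.dmis_fraction,
                indel_splice_factor=design.indel_splice_factor,
            )
        )
        cds_map[name] = cds_with_flanks
        loci[name] = (str(1 + g % 22), 1_000_000 + 5_000_000 * (g // 22) + 100_000 * (g % 22))
    return genes, cds_map, loci


def simulate_lipids(
    design: SimulationDesign,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Participant], dict[str, tuple[float, float]]]:
    """Draw participants with lipid panels; returns (participants, latent).

    TG is lognormal; noise-free HDL-C sits on the truth hyperbola
    m1 + m2*m3/(m2 + TG), with centered Gaussian noise added and a 1 mg/dl
    floor.  TC = LDL + HDL + TG/5 by construction, so the Friedewald LDL
    estimate is exact on records with TG < 400.  ``latent`` maps participant
    id to (TG, noise-free HDL-C).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if n is None:
        n = design.n_participants
    if n <= 0:
        raise ValueError(f"participant count must be positive, got {n}")
    eth_labels = [e[0] for e in ETHNICITIES]
    eth_probs = np.array([e[1] for e in ETHNICITIES])
    eth_probs = eth_probs / eth_probs.sum()
    participants: list[Participant] = []
    latent: dict[str, tuple[float, float]] = {}
    for i in range(n):
        pid = f"P{i + 1:05d}"
        tg = float(rng.lognormal(design.tg_log_mean, design.tg_log_sd))
        hdl_true = design.m1 + design.m2 * design.m3 / (design.m2 + tg)
        hdl = max(hdl_true + float(rng.normal(0.0, design.hdl_noise_sd)), 1.0)
        ldl = max(float(rng.normal(design.ldl_mean, design.ldl_sd)), 1.0)
        tc = ldl + hdl + tg / 5.0
        sex = "F" if rng.random() < design.female_fraction else "M"
        age = float(np.clip(rng.normal(50.0, 15.7), 8.0, 86.0))
        flags = {
            k: ("yes" if rng.random() < p else "no") for k, p in FLAG_PREVALENCE.items()
        }
        participants.append(
            Participant(
                pid=pid,
                sex=sex,
                age=age,
                ethnicity=eth_labels[int(rng.choice(len(eth_labels), p=eth_probs))],
                tc=tc,
                tg=tg,
                hdl=hdl,
                ldl=ldl,
                prebeta_hdl=max(float(rng.normal(4.3, 1.3)), 0.5),
                bmi=float(rng.lognormal(math.log(28.0), 0.18)),
                flags=flags,
            )
        )
        latent[pid] = (tg, hdl_true)
    return participants, latent


def _draw_votes(rng: np.random.Generator, design: SimulationDesign, damaging: bool) -> dict[str, str]:
    p_dmg = design.tool_sensitivity if damaging else design.tool_false_positive
    votes = {}
    for tool in PREDICTION_TOOLS:
        u = rng.random()
        if u < design.tool_missing_prob:
            votes[tool] = "missing"
        elif u < design.tool_missing_prob + design.tool_equivocal_prob:
            votes[tool] = "equivocal"
        elif rng.random() < p_dmg:
            votes[tool] = "damaging"
        else:
            votes[tool] = "tolerated"
    return votes


def _draw_qc(rng: np.random.Generator, design: SimulationDesign) -> dict:
    fail = design.qc_fail_rate
    qual = float(rng.gamma(6.0, 100.0))
    if rng.random() < fail:
        qual = float(rng.uniform(5.0, 40.0))
    dp = int(rng.poisson(60)) + 1
    if rng.random() < fail:
        dp = int(rng.integers(1, 8))
    u = rng.random()
    if u < 0.90:
        gq = 99.0
    elif u < 0.95:
        gq = float(rng.uniform(60.0, 99.0))
    elif u < 0.98:
        gq = float(rng.uniform(20.0, 60.0))
    else:
        gq = float(rng.uniform(0.0, 20.0))
    mq = 60.0 if rng.random() > fail else float(rng.uniform(20.0, 40.0))
    alt_reads = int(rng.binomial(dp, 0.5))
    alt_reads = min(max(alt_reads, 1), dp)
    if rng.random() < fail:
        alt_reads = min(dp, int(rng.integers(1, 3)))
    u = rng.random()
    if u < design.single_caller_rate:
        callers = frozenset({CALLERS[int(rng.integers(len(CALLERS)))]})
    elif u < design.single_caller_rate + 0.07:
        k = int(rng.integers(2, 4))
        idx = rng.choice(len(CALLERS), size=k, replace=False)
        callers = frozenset(CALLERS[i] for i in idx)
    else:
        callers = frozenset(CALLERS)
    return {
        "qual": qual,
        "dp": dp,
        "gq": gq,
        "mq": mq,
        "alt_reads": alt_reads,
        "callers": callers,
        "lcr": rng.random() < 0.01,
        "vqsr_pass": rng.random() > 0.02,
    }


def _rare_mafs(rng: np.random.Generator, design: SimulationDesign) -> dict[str, Optional[float]]:
    if rng.random() < design.novel_fraction:
        return {s: None for s in ("gnomAD", "ExAC", "1000G", "ESP")}
    if rng.random() < design.not_rare_fraction:
        lo, hi = -3.0, -2.0  # rare-threshold violators
    else:
        lo, hi = -8.0, -3.5
    return {
        s: float(10 ** rng.uniform(lo, hi)) for s in ("gnomAD", "ExAC", "1000G", "ESP")
    }


def _benign_mafs(rng: np.random.Generator, common: bool) -> dict[str, Optional[float]]:
    lo, hi = (-1.5, -0.8) if common else (-5.0, -1.8)
    return {
        s: float(10 ** rng.uniform(lo, hi)) for s in ("gnomAD", "ExAC", "1000G", "ESP")
    }


def _draw_clinvar(rng: np.random.Generator, damaging: bool) -> Optional[str]:
    u = rng.random()
    if damaging:
        if u < 0.05:
            return "Pathogenic"
        if u < 0.09:
            return "Likely pathogenic"
        if u < 0.14:
            return "Uncertain significance"
        return None
    if u < 0.04:
        return "Benign"
    if u < 0.08:
        return "Likely benign"
    if u < 0.10:
        return "Conflicting interpretations of pathogenicity"
    return None


_LOF_SUBTYPES = ("stop-gain", "frameshift-indel", "splice-site", "start-loss", "stop-loss")
_LOF_WEIGHTS = np.array([0.35, 0.30, 0.20, 0.08, 0.07])


def simulate_variants(
    design: SimulationDesign,
    participants: Sequence[Participant],
    genes: Optional[Sequence[GeneMutability]] = None,
    loci: Optional[dict[str, tuple[str, int]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantRecord], TruthTable]:
    """Simulate annotated variant calls for a cohort.

    Per gene the damaging occurrence count is Poisson with mean
    ``total_expected_damaging * p_g * multiplier_g`` where p_g is the gene's
    share of adjusted damaging mutability -- exactly the burden test's
    expectation model, so the null and planted alternatives are realizable.
    Each occurrence is a singleton variant (rare-variant regime) carried
    heterozygously except for a ``hom_fraction`` of carriers.  Benign
    background variants (synonymous/missense/noncoding) are added with more
    carriers and higher population MAFs, including occasional platform-like
    artifacts carried by over 40% of samples.
    """
    if not participants:
        raise ValueError("participant collection is empty")
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    if genes is None:
        rates = default_rate_table()
        genes, _, loci = make_gene_roster(design, rates, rng)
    if loci is None:
        loci = {
            g.gene: (str(1 + i % 22), 1_000_000 + 100_000 * i)
            for i, g in enumerate(genes)
        }
    if not genes:
        raise ValueError("gene roster is empty")
    pids = [p.pid for p in participants]

    weights = np.array([g.adjusted_damaging for g in genes], dtype=float)
    p_g = weights / weights.sum()
    multipliers = {g.gene: design.enrichment.get(g.gene, 1.0) for g in genes}

    truth = TruthTable(multipliers=dict(multipliers))
    variants: list[VariantRecord] = []
    offset: dict[str, int] = {g.gene: 0 for g in genes}

    def next_pos(gene: str) -> tuple[str, int]:
        chrom, start = loci[gene]
        offset[gene] += 1
        return chrom, start + 7 * offset[gene]

    bases = "ACGT"

    def snv_alleles() -> tuple[str, str]:
        ref = bases[int(rng.integers(4))]
        alt = bases[int(rng.integers(4))]
        while alt == ref:
            alt = bases[int(rng.integers(4))]
        return ref, alt

    # --- damaging variants, gene by gene ---
    for g, share in zip(genes, p_g):
        lam = design.total_expected_damaging * share * multipliers[g.gene]
        k = int(rng.poisson(lam))
        lof_share = g.lof / g.damaging if g.damaging > 0 else 0.0
        for _ in range(k):
            chrom, pos = next_pos(g.gene)
            is_lof = rng.random() < lof_share
            if is_lof:
                consequence = _LOF_SUBTYPES[
                    int(rng.choice(len(_LOF_SUBTYPES), p=_LOF_WEIGHTS / _LOF_WEIGHTS.sum()))
                ]
            else:
                consequence = "missense"
            if consequence == "frameshift-indel":
                b1, b2 = bases[int(rng.integers(4))], bases[int(rng.integers(4))]
                ref, alt = b1 + b2, b1
            else:
                ref, alt = snv_alleles()
            carrier = pids[int(rng.integers(len(pids)))]
            genotype = "hom" if rng.random() < design.hom_fraction else "het"
            qc = _draw_qc(rng, design)
            v = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=g.gene,
                consequence=consequence,
                pop_mafs=_rare_mafs(rng, design),
                votes=_draw_votes(rng, design, damaging=True),
                metasvm="deleterious" if consequence == "missense" else "missing",
                clinvar=_draw_clinvar(rng, damaging=True),
                genotypes={carrier: genotype},
                **qc,
            )
            variants.append(v)
            truth.damaging[v.key] = True

    # --- benign background ---
    totals = np.array([g.lof / (1 + design.indel_splice_factor) + g.dmis / max(design.dmis_fraction, 1e-12) for g in genes])
    bg_share = totals / totals.sum()
    n_background = design.background_per_damaging * design.total_expected_damaging
    for g, share in zip(genes, bg_share):
        k = int(rng.poisson(n_background * share))
        for _ in range(k):
            chrom, pos = next_pos(g.gene)
            u = rng.random()
            if u < 0.15:
                consequence = str(rng.choice(["intronic", "UTR", "synonymous"]))
            elif u < 0.55:
                consequence = "missense"
            else:
                consequence = "synonymous"
            ref, alt = snv_alleles()
            is_platform = rng.random() < design.platform_artifact_rate
            common = is_platform or rng.random() < 0.08
            if is_platform:
                n_car = int(rng.uniform(0.45, 0.70) * len(pids))
            else:
                n_car = min(1 + int(rng.poisson(1.5)), len(pids))
            carriers = rng.choice(len(pids), size=n_car, replace=False)
            genotypes = {
                pids[c]: ("hom" if rng.random() < design.hom_fraction else "het")
                for c in carriers
            }
            qc = _draw_qc(rng, design)
            v = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=g.gene,
                consequence=consequence,
                pop_mafs=_benign_mafs(rng, common),
                votes=_draw_votes(rng, design, damaging=False),
                metasvm="tolerated" if consequence == "missense" else "missing",
                clinvar=_draw_clinvar(rng, damaging=False),
                genotypes=genotypes,
                **qc,
            )
            variants.append(v)
            truth.damaging[v.key] = False

    return variants, truth


def simulate_planted_cohort(
    design: SimulationDesign, multiplier: float
) -> tuple[list[VariantRecord], TruthTable, list[GeneMutability], str]:
    """Simulate a cohort with one gene planted at ``multiplier`` its null rate.

    The planted gene is the roster member whose damaging-mutability share is
    closest to the roster mean, so its null expected count is
    ``total_expected_damaging / n_genes`` -- the canonical power-study
    condition of an average-sized gene.  Returns (variants, truth, gene
    models, planted gene symbol).
    """
    rng = np.random.default_rng(design.seed)
    participants, latent = simulate_lipids(design, rng=rng)
    rates = default_rate_table()
    genes, _, loci = make_gene_roster(design, rates, rng)
    weights = np.array([g.adjusted_damaging for g in genes])
    shares = weights / weights.sum()
    target = genes[int(np.argmin(np.abs(shares - 1.0 / len(genes))))].gene
    planted = replace(design, enrichment={target: multiplier})
    variants, truth = simulate_variants(planted, participants, genes, loci, rng=rng)
    truth.latent_lipids = latent
    return variants, truth, genes, target


@dataclass
class SyntheticCohort:
    """One complete simulated study: inputs plus ground truth."""

    design: SimulationDesign
    participants: list[Participant]
    variants: list[VariantRecord]
    truth: TruthTable
    genes: list[GeneMutability]
    rate_table: MutationRateTable
    common_list: list[str]
    candidate_genes: list[str]


def simulate_cohort(design: SimulationDesign) -> SyntheticCohort:
    """Generate a full synthetic study from one seed.

    Stage order (lipids, roster, variants, common list) is fixed, so a design
    and seed fully determine the output.  The ranked common-variant list is
    the background variants ordered by carrier count (a stand-in for a
    vendor common-variant catalogue); the candidate gene list is a random
    quarter of the roster plus every enriched gene.
    """
    rng = np.random.default_rng(design.seed)
    participants, latent = simulate_lipids(design, rng=rng)
    rates = default_rate_table()
    genes, _, loci = make_gene_roster(design, rates, rng)
    variants, truth = simulate_variants(design, participants, genes, loci, rng=rng)
    truth.latent_lipids = latent

    benign = [v for v in variants if not truth.damaging[v.key]]
    benign.sort(key=lambda v: (-v.n_carriers, v.key))
    common_list = [v.key for v in benign[:40]]

    n_candidates = max(1, len(genes) // 4)
    picked = rng.choice(len(genes), size=n_candidates, replace=False)
    candidate_genes = sorted(
        {genes[i].gene for i in picked} | set(design.enrichment)
    )
    return SyntheticCohort(
        design=design,
        participants=participants,
        variants=variants,
        truth=truth,
        genes=genes,
        rate_table=rates,
        common_list=common_list,
        candidate_genes=candidate_genes,
    )
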