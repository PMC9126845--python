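"""Domain types shared across the pipeline.

A low-HDL-C exome study handles two kinds of records: participants with a
fasting lipid panel, and called variants carrying QC metrics, functional
annotation, population frequencies, deleteriousness-tool calls and per-sample
genotypes.  Both are plain dataclasses; tabular I/O lives in
:mod:`hdlburden.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# The ten deleteriousness prediction tools whose calls are consumed as
# annotation.  The consensus vote count is defined over exactly this roster.
PREDICTION_TOOLS: tuple[str, ...] = (
    "SIFT",
    "PolyPhen_HVAR",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
    "MCAP",
    "FATHMM_MKL",
)

VOTE_VALUES = frozenset({"damaging", "tolerated", "equivocal", "missing"})

CALLERS: tuple[str, ...] = ("GATK-UG", "GATK-HC", "Freebayes", "Samtools", "VarDict")
# Callers for which the GQ >= 60 rule of the candidate-branch QC applies.
GQ_SENSITIVE_CALLERS = frozenset({"GATK-UG", "GATK-HC", "Freebayes"})

MAF_SOURCES: tuple[str, ...] = ("gnomAD", "ExAC", "1000G", "ESP")
# Sources consulted by the burden-branch rare-variant filter.
RARE_MAF_SOURCES: tuple[str, ...] = ("ExAC", "1000G", "ESP")

CONSEQUENCES = frozenset(
    {
        "missense",
        "stop-gain",
        "stop-loss",
        "frameshift-indel",
        "splice-site",
        "start-loss",
        "synonymous",
        "intronic",
        "intergenic",
        "UTR",
        "other-indel",
    }
)
# Loss-of-function consequence labels.
LOF_CONSEQUENCES = frozenset(
    {"stop-gain", "stop-loss", "frameshift-indel", "splice-site", "start-loss"}
)
# Consequences removed outright by the candidate-branch cascade.
NONCODING_CONSEQUENCES = frozenset({"synonymous", "intronic", "intergenic", "UTR"})


@dataclass
class Participant:
    """One study participant: demographics, lipid panel, clinical flags.

    Lipids are mg/dl.  ``ldl`` may be ``None`` (triglycerides too high for the
    Friedewald estimate and no direct measurement).  Clinical flags are
    tri-state: ``"yes"``, ``"no"`` or ``"unknown"``.  ``group`` is the
    dyslipidemia subphenotype (1-4) once assigned.
    """

    pid: str
    sex: str  # "F" / "M"
    age: float
    ethnicity: str = "unknown"
    tc: Optional[float] = None
    tg: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    prebeta_hdl: Optional[float] = None
    bmi: Optional[float] = None
    flags: dict[str, str] = field(default_factory=dict)  # CAD/MI/diabetes/...
    group: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("tc", "tg", "hdl", "ldl", "prebeta_hdl", "bmi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v} for {self.pid}")


@dataclass
class VariantRecord:
    """A single alternate allele at a site, with its annotation payload.

    Multi-allelic sites are decomposed on read, so ``(chrom, pos, ref, alt)``
    identifies the record.  Coordinates are 1-based as in VCF.  ``genotypes``
    maps participant id to ``"het"`` or ``"hom"``; reference-genotype samples
    are omitted.  ``annotated`` is False for variants with no sidecar
    annotation row; such records carry explicit ``None`` markers, never silent
    defaults.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequence: Optional[str] = None
    qual: Optional[float] = None
    dp: Optional[int] = None
    gq: Optional[float] = None
    mq: Optional[float] = None
    alt_reads: Optional[int] = None
    callers: frozenset[str] = frozenset()
    lcr: bool = False
    vqsr_pass: bool = True
    pop_mafs: dict[str, Optional[float]] = field(default_factory=dict)
    votes: dict[str, str] = field(default_factory=dict)
    metasvm: str = "missing"  # "deleterious" / "tolerated" / "missing"
    clinvar: Optional[str] = None
    genotypes: dict[str, str] = field(default_factory=dict)
    annotated: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.dp is not None and self.alt_reads is not None and self.alt_reads > self.dp:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds DP ({self.dp}) at {self.key}"
            )
        for src, maf in self.pop_mafs.items():
            if maf is not None and not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF for {src} outside [0,1]: {maf}")
        for gt in self.genotypes.values():
            if gt not in ("het", "hom"):
                raise ValueError(f"genotype must be het/hom, got {gt!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def n_carriers(self) -> int:
        return len(self.genotypes)

    @property
    def n_het(self) -> int:
        return sum(1 for g in self.genotypes.values() if g == "het")

    @property
    def n_hom(self) -> int:
        return sum(1 for g in self.genotypes.values() if g == "hom")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line); members are deduplicated symbols."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
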