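"""Readers and writers for every external format the pipeline touches.

Genotypes travel in VCF v4.2 (GT per sample; QUAL; INFO DP/MQ/AC) through
pysam; the annotation payload (gene, consequence, QC extras, caller set,
population MAFs, the ten tool calls, MetaSVM, ClinVar) travels in a sidecar
tab-delimited table keyed by ``chrom:pos:ref:alt``.  Multi-allelic sites are
decomposed into one record per alternate allele on read.  Coordinates are
1-based throughout, as in VCF.

QUAL and MQ are written rounded to two decimals (VCF stores them as 32-bit
floats) and read back at that precision, so write-then-read round-trips are
exact for values carrying at most two decimals.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .burden import GeneMutability, MutationRateTable
from .records import (
    MAF_SOURCES,
    PREDICTION_TOOLS,
    GeneSet,
    Participant,
    VariantRecord,
)


class ParseError(ValueError):
    """Malformed input file."""


_ANN_COLUMNS = (
    ["key", "gene", "consequence", "gq", "callers", "alt_reads", "lcr_flag", "vqsr_pass"]
    + [f"maf_{s}" for s in MAF_SOURCES]
    + [f"tool_{t}" for t in PREDICTION_TOOLS]
    + ["metasvm", "clinvar"]
)

_GT_CODE = {None: (0, 0), "het": (0, 1), "hom": (1, 1)}


def write_variants(
    variants: Sequence[VariantRecord],
    vcf_path: str | Path,
    annotation_path: str | Path,
    sample_ids: Sequence[str],
) -> None:
    """Write a cohort as VCF v4.2 plus the annotation sidecar TSV."""
    header = pysam.VariantHeader()
    contigs = sorted({v.chrom for v in variants}, key=_contig_sort_key)
    for chrom in contigs:
        header.contigs.add(chrom, length=300_000_000)
    header.info.add("DP", "1", "Integer", "Read depth")
    header.info.add("MQ", "1", "Float", "Mapping quality")
    header.info.add("AC", "A", "Integer", "Alternate allele count")
    header.formats.add("GT", "1", "String", "Genotype")
    for sid in sample_ids:
        header.add_sample(sid)
    ordered = sorted(variants, key=lambda v: (_contig_sort_key(v.chrom), v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.qual is not None:
                rec.qual = round(v.qual, 2)
            if v.dp is not None:
                rec.info["DP"] = v.dp
            if v.mq is not None:
                rec.info["MQ"] = round(v.mq, 2)
            ac = sum(2 if g == "hom" else 1 for g in v.genotypes.values())
            rec.info["AC"] = (ac,)
            for sid in sample_ids:
                rec.samples[sid]["GT"] = _GT_CODE[v.genotypes.get(sid)]
            out.write(rec)

    rows = []
    for v in ordered:
        row: dict[str, object] = {
            "key": v.key,
            "gene": v.gene or "",
            "consequence": v.consequence or "",
            "gq": "" if v.gq is None else repr(float(v.gq)),
            "callers": ",".join(sorted(v.callers)),
            "alt_reads": "" if v.alt_reads is None else v.alt_reads,
            "lcr_flag": int(v.lcr),
            "vqsr_pass": int(v.vqsr_pass),
        }
        for s in MAF_SOURCES:
            maf = v.pop_mafs.get(s)
            row[f"maf_{s}"] = "" if maf is None else repr(float(maf))
        for t in PREDICTION_TOOLS:
            row[f"tool_{t}"] = v.votes.get(t, "missing")
        row["metasvm"] = v.metasvm
        row["clinvar"] = v.clinvar or ""
        rows.append(row)
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(
        annotation_path, sep="\t", index=False
    )


def _contig_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def _read_annotations(annotation_path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(_ANN_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(
            f"annotation table missing columns: {sorted(missing_cols)}"
        )
    annotations: dict[str, dict] = {}
    for _, row in df.iterrows():
        key = row["key"]
        if key in annotations:
            raise ParseError(f"duplicate annotation key: {key}")
        annotations[key] = row.to_dict()
    return annotations


def read_variants(
    vcf_path: str | Path, annotation_path: str | Path
) -> list[VariantRecord]:
    """Read VCF + annotation sidecar into decomposed variant records.

    One record per alternate allele.  Variants lacking an annotation row are
    returned with ``annotated=False`` and ``None`` annotation fields, never
    silent defaults.  A duplicate annotation key or malformed VCF header is a
    parse error.
    """
    with open(vcf_path) as fh:
        first = fh.readline()
    if not first.startswith("##fileformat=VCF"):
        raise ParseError(
            f"{vcf_path}: line 1: expected '##fileformat=VCFv4.2' header, got {first.strip()!r}"
        )
    annotations = _read_annotations(annotation_path)
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for allele_idx, alt in enumerate(alts, start=1):
                genotypes: dict[str, str] = {}
                for sid in samples:
                    gt = rec.samples[sid].get("GT")
                    if gt is None:
                        continue
                    n_alt = sum(1 for a in gt if a == allele_idx)
                    if n_alt == 1:
                        genotypes[sid] = "het"
                    elif n_alt >= 2:
                        genotypes[sid] = "hom"
                key = f"{rec.contig}:{rec.pos}:{rec.ref}:{alt}"
                ann = annotations.get(key)
                dp = rec.info.get("DP") if "DP" in rec.header.info else None
                mq = rec.info.get("MQ") if "MQ" in rec.header.info else None
                base = dict(
                    chrom=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    qual=None if rec.qual is None else round(float(rec.qual), 2),
                    dp=dp,
                    mq=None if mq is None else round(float(mq), 2),
                    genotypes=genotypes,
                )
                if ann is None:
                    records.append(VariantRecord(annotated=False, **base))
                    continue
                records.append(
                    VariantRecord(
                        gene=ann["gene"] or None,
                        consequence=ann["consequence"] or None,
                        gq=float(ann["gq"]) if ann["gq"] else None,
                        callers=frozenset(
                            c for c in ann["callers"].split(",") if c
                        ),
                        alt_reads=int(ann["alt_reads"]) if ann["alt_reads"] else None,
                        lcr=bool(int(ann["lcr_flag"])),
                        vqsr_pass=bool(int(ann["vqsr_pass"])),
                        pop_mafs={
                            s: (float(ann[f"maf_{s}"]) if ann[f"maf_{s}"] else None)
                            for s in MAF_SOURCES
                        },
                        votes={t: ann[f"tool_{t}"] for t in PREDICTION_TOOLS},
                        metasvm=ann["metasvm"] or "missing",
                        clinvar=ann["clinvar"] or None,
                        annotated=True,
                        **base,
                    )
                )
    return records


def read_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Read a GMT file (set name, description, member symbols, tab-separated).

    Duplicate members within one set are deduplicated; a line with fewer than
    three columns is a parse error naming the line; an empty file yields an
    empty collection.
    """
    sets: list[GeneSet] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{gmt_path}: line {lineno}: GMT needs >= 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{gmt_path}: line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, description=description, members=frozenset(members)))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain gene list, one symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_rate_table(path: str | Path) -> MutationRateTable:
    """Read a trinucleotide substitution-rate TSV.

    Rows are (5' base, ref base, 3' base, alt base, rate per site per
    generation); a header row is optional.  Strand symmetrization expands a
    pyrimidine-centered 96-row table to the full 192 entries; a duplicate
    context with a conflicting rate, a negative rate, or a missing context
    after closure is an error.
    """
    rows: dict[tuple[str, str, str, str], float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, fields in enumerate(reader, start=1):
            if not fields or not "".join(fields).strip():
                continue
            if lineno == 1 and fields[-1].lower() in ("rate", "mu"):
                continue  # header
            if len(fields) != 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(fields)}"
                )
            five, ref, three, alt = (f.strip().upper() for f in fields[:4])
            try:
                rate = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad rate {fields[4]!r}") from exc
            if rate <= 0:
                raise ParseError(f"{path}: line {lineno}: rate must be > 0, got {rate}")
            key = (five, ref, three, alt)
            if key in rows and rows[key] != rate:
                raise ParseError(
                    f"{path}: line {lineno}: conflicting duplicate for context "
                    f"{''.join(key)}: {rows[key]} vs {rate}"
                )
            rows[key] = rate
    return MutationRateTable(rows)


def write_rate_table(rates: MutationRateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("five\tref\tthree\talt\trate\n")
        for (five, ref, three, alt), rate in sorted(rates.items()):
            fh.write(f"{five}\t{ref}\t{three}\t{alt}\t{rate!r}\n")


_PARTICIPANT_COLUMNS = [
    "pid", "sex", "age", "ethnicity", "tc", "tg", "hdl", "ldl",
    "prebeta_hdl", "bmi", "CAD", "MI", "diabetes", "hypertension",
    "smoker", "group",
]


def write_participants(participants: Sequence[Participant], path: str | Path) -> None:
    rows = []
    for p in participants:
        row = {
            "pid": p.pid, "sex": p.sex, "age": p.age, "ethnicity": p.ethnicity,
            "tc": p.tc, "tg": p.tg, "hdl": p.hdl, "ldl": p.ldl,
            "prebeta_hdl": p.prebeta_hdl, "bmi": p.bmi,
            "group": p.group,
        }
        for flag in ("CAD", "MI", "diabetes", "hypertension", "smoker"):
            row[flag] = p.flags.get(flag, "unknown")
        rows.append(row)
    pd.DataFrame(rows, columns=_PARTICIPANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_participants(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, sep="\t")
    participants = []
    for _, row in df.iterrows():
        def opt(col: str) -> Optional[float]:
            v = row.get(col)
            return None if pd.isna(v) else float(v)

        flags = {
            flag: (row[flag] if isinstance(row.get(flag), str) else "unknown")
            for flag in ("CAD", "MI", "diabetes", "hypertension", "smoker")
        }
        group = row.get("group")
        participants.append(
            Participant(
                pid=str(row["pid"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                ethnicity=str(row.get("ethnicity", "unknown")),
                tc=opt("tc"), tg=opt("tg"), hdl=opt("hdl"), ldl=opt("ldl"),
                prebeta_hdl=opt("prebeta_hdl"), bmi=opt("bmi"),
                flags=flags,
                group=None if pd.isna(group) else int(group),
            )
        )
    return participants


def write_gene_models(genes: Sequence[GeneMutability], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": g.gene,
                "lof": g.lof,
                "dmis": g.dmis,
                "coverage_factor": g.coverage_factor,
                "coding_length": g.coding_length,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneMutability]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneMutability(
            gene=str(row["gene"]),
            lof=float(row["lof"]),
            dmis=float(row["dmis"]),
            coverage_factor=float(row["coverage_factor"]),
            coding_length=int(row["coding_length"]),
        )
        for _, row in df.iterrows()
    ]
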