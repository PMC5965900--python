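"""Tab-delimited and VCF input/output for the analysis modules.

Variant tables travel as TSV with one row per call; the same columns can be
pulled from a VCF whose INFO field carries the caller QC annotations
(QD/MQ/FS/HS/MQRS/RPRS) and the functional annotations (GENE, EFFECT,
PPH2_HDIV, PPH2_HVAR).  Artifact blacklists are plain chrom-pos-ref-alt
text files.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import pandas as pd

from .variants import AnnotatedVariant

_QC_COLUMNS = ["QUAL", "GQ", "QD", "MQ", "FS", "HS", "MQRS", "RPRS", "depth", "alt_depth"]


def _variant_row(individual: Optional[str], v: AnnotatedVariant) -> dict:
    row = {
        "individual": individual,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "gene": v.gene,
        "effect": v.effect,
        "polyphen_humdiv": v.polyphen_humdiv,
        "polyphen_humvar": v.polyphen_humvar,
        "evs_freq": v.pop_freq.get("EVS"),
        "exac_freq": v.pop_freq.get("ExAC"),
        "cohort_allele_count": v.cohort_allele_count,
        "cohort_maf": v.cohort_maf,
        "is_indel": int(v.is_indel),
        "vqsr_pass": int(bool(v.qc.get("vqsr_pass", False))),
    }
    for name in _QC_COLUMNS:
        row[name] = v.qc.get(name)
    return row


def write_denovo_tsv(calls, path) -> None:
    """Write de novo calls (``TrioDenovo`` records) to TSV."""
    rows = [_variant_row(c.individual, c.variant) for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _row_to_variant(row) -> AnnotatedVariant:
    def val(name, default=None):
        x = row.get(name, default)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return default
        return x

    qc = {name: val(name) for name in _QC_COLUMNS if val(name) is not None}
    qc["vqsr_pass"] = bool(int(val("vqsr_pass", 0)))
    pop_freq = {}
    if val("evs_freq") is not None:
        pop_freq["EVS"] = float(val("evs_freq"))
    if val("exac_freq") is not None:
        pop_freq["ExAC"] = float(val("exac_freq"))
    return AnnotatedVariant(
        chrom=str(val("chrom")),
        pos=int(val("pos")),
        ref=str(val("ref")),
        alt=str(val("alt")),
        gene=str(val("gene")),
        effect=str(val("effect")),
        polyphen_humdiv=val("polyphen_humdiv"),
        polyphen_humvar=val("polyphen_humvar"),
        qc=qc,
        pop_freq=pop_freq,
        cohort_allele_count=int(val("cohort_allele_count", 0)),
        cohort_maf=val("cohort_maf"),
        is_indel=bool(int(val("is_indel", 0))),
    )


def read_denovo_tsv(path):
    """Read de novo calls written by :func:`write_denovo_tsv`."""
    from .simulate import TrioDenovo

    frame = pd.read_csv(path, sep="\t")
    return [
        TrioDenovo(str(row["individual"]), _row_to_variant(row))
        for _, row in frame.iterrows()
    ]


def read_variants_vcf(path) -> list[AnnotatedVariant]:
    """Read annotated variants from a VCF via pysam.

    INFO keys consumed: GENE, EFFECT, PPH2_HDIV, PPH2_HVAR, QD, MQ, FS, HS,
    MQRS, RPRS, EVS_AF, EXAC_AF; the FILTER column supplies the VQSR pass
    flag and the first sample's FORMAT fields supply DP/AD/GQ.
    """
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            qc = {"QUAL": rec.qual if rec.qual is not None else None}
            for key in ("QD", "MQ", "FS", "HS", "MQRS", "RPRS"):
                if key in info:
                    qc[key] = float(info[key])
            qc["vqsr_pass"] = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
            if rec.samples:
                sample = rec.samples[0]
                if sample.get("DP") is not None:
                    qc["depth"] = int(sample["DP"])
                if sample.get("GQ") is not None:
                    qc["GQ"] = float(sample["GQ"])
                ad = sample.get("AD")
                if ad is not None and len(ad) > 1 and ad[1] is not None:
                    qc["alt_depth"] = int(ad[1])
            pop_freq = {}
            if "EVS_AF" in info:
                pop_freq["EVS"] = float(info["EVS_AF"])
            if "EXAC_AF" in info:
                pop_freq["ExAC"] = float(info["EXAC_AF"])
            alt = rec.alts[0] if rec.alts else "N"
            out.append(
                AnnotatedVariant(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    gene=str(info.get("GENE", "")),
                    effect=str(info.get("EFFECT", "other")),
                    polyphen_humdiv=float(info["PPH2_HDIV"]) if "PPH2_HDIV" in info else None,
                    polyphen_humvar=float(info["PPH2_HVAR"]) if "PPH2_HVAR" in info else None,
                    qc={k: v for k, v in qc.items() if v is not None},
                    pop_freq=pop_freq,
                    is_indel=len(rec.ref) != len(alt),
                )
            )
    return out


def read_blacklist(path) -> frozenset:
    """Read an artifact blacklist of whitespace-separated chrom pos ref alt."""
    entries = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split()[:4]
            entries.add((chrom, int(pos), ref, alt))
    return frozenset(entries)


def read_gene_annotations(path) -> pd.DataFrame:
    """Gene annotation TSV with at least ``gene`` and ``rvis_percentile``."""
    frame = pd.read_csv(path, sep="\t")
    if not {"gene", "rvis_percentile"} <= set(frame.columns):
        raise ValueError("gene annotation table needs gene and rvis_percentile")
    return frame


def write_expression(dataset, matrix_path, samples_path) -> None:
    dataset.expression.to_csv(matrix_path, sep="\t")
    dataset.samples.to_csv(samples_path, sep="\t", index=False)


def read_expression(matrix_path, samples_path, name="dataset"):
    from .coexpression import ExpressionDataset

    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return ExpressionDataset(expr, samples, name)
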