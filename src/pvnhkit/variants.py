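"""Core variant data types, QC filters, and qualifying-variant logic.

Every analysis in this package — the trio de novo pipeline, the hot-zone
enrichment test, and the gene-level collapsing association — consumes
annotated variant calls through the types and predicates defined here.
Variants are represented at the level a downstream statistical analysis
needs: genomic coordinates, effect class, PolyPhen-2 deleteriousness
scores, caller QC metrics, and population-database allele frequencies.
Alignment, genotype calling and functional annotation are upstream of this
package and are consumed as columns.

Coordinates are 1-based and fully closed, matching VCF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AnnotatedVariant",
    "GeneAnnotation",
    "SiteGenotype",
    "TrioGenotypes",
    "BiallelicGenotype",
    "MissingAnnotationError",
    "LOF_EFFECTS",
    "EFFECT_CLASSES",
    "PROBABLY_DAMAGING_HUMDIV",
    "qc_pass_denovo",
    "qc_pass_collapsing",
    "is_qualifying_dominant",
    "is_qualifying_biallelic_site",
    "list_trio_biallelic_genotypes",
]

#: Sub-consequences collapsed into the ``lof`` effect class: stop gained,
#: frameshift, splice acceptor/donor, start lost, exon deleted.
LOF_EFFECTS = frozenset(
    {
        "stop_gained",
        "frameshift",
        "splice_acceptor",
        "splice_donor",
        "start_lost",
        "exon_deleted",
    }
)

EFFECT_CLASSES = ("synonymous", "missense", "lof", "other")

#: PolyPhen-2 HumDiv score at and above which a missense variant carries the
#: "probably damaging" label.  The study defines qualifying missense variants
#: by the label; this is PolyPhen-2's published numeric cut for it.
PROBABLY_DAMAGING_HUMDIV = 0.957

GENOTYPE_STATES = ("hom_ref", "het", "hom_alt", "hemi", "missing")

DOMINANT_MODELS = ("lof_only", "lof_plus_probably_damaging")


class MissingAnnotationError(KeyError):
    """A QC metric or score required by a filter is absent from the record."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant with the annotations the analyses consume.

    ``qc`` holds caller metrics keyed by their conventional short names
    (QUAL, GQ, QD, MQ, FS, HS, MQRS, RPRS, depth, alt_depth, vqsr_pass).
    ``pop_freq`` maps population database name (``"EVS"``, ``"ExAC"``) to
    observed allele frequency; a database key that is present with value 0.0
    means the variant was looked up and not found, a missing key means the
    database was not consulted.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    polyphen_humdiv: Optional[float] = None
    polyphen_humvar: Optional[float] = None
    qc: Mapping[str, float] = field(default_factory=dict)
    pop_freq: Mapping[str, float] = field(default_factory=dict)
    cohort_allele_count: int = 0
    cohort_maf: Optional[float] = None
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        for score in (self.polyphen_humdiv, self.polyphen_humvar):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"PolyPhen score out of [0, 1]: {score}")
        depth = self.qc.get("depth")
        alt_depth = self.qc.get("alt_depth")
        if depth is not None and alt_depth is not None and alt_depth > depth:
            raise ValueError("alt_depth exceeds depth")

    @property
    def key(self) -> tuple:
        """(chrom, pos, ref, alt) identity used for blacklists and joins."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level annotation: intolerance percentile and CDS length.

    A gene is *intolerant* when its Residual Variation Intolerance Score
    (RVIS) percentile is in the lowest quartile of the genome.
    """

    gene: str
    rvis_percentile: float
    cds_length: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rvis_percentile <= 1.0):
            raise ValueError("rvis_percentile must lie in [0, 1]")

    @property
    def intolerant(self) -> bool:
        return self.rvis_percentile <= 0.25


def _qc(v: AnnotatedVariant, name: str, absent_fields: Iterable[str] = ()):
    """Fetch a QC metric, raising unless the field was declared absent."""
    value = v.qc.get(name)
    if value is None:
        if name in absent_fields:
            return None
        raise MissingAnnotationError(
            f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} lacks QC field {name!r}"
        )
    return value


# QC metrics consulted by the de novo hard filters, per variant class.
_DENOVO_SNV_FAIL = (
    ("QD", lambda x: x < 2.0),
    ("MQ", lambda x: x < 40.0),
    ("FS", lambda x: x > 60.0),
    ("HS", lambda x: x > 13.0),
    ("MQRS", lambda x: x < -12.5),
    ("RPRS", lambda x: x < -8.0),
)
_DENOVO_INDEL_FAIL = (
    ("QD", lambda x: x < 2.0),
    ("RPRS", lambda x: x < -20.0),
    ("FS", lambda x: x > 200.0),
)


def qc_pass_denovo(v: AnnotatedVariant, absent_fields: Iterable[str] = ()) -> bool:
    """Hard-filter gate for candidate de novo calls.

    SNVs fail on any of QD < 2, MQ < 40, FS > 60, HS > 13, MQRS < -12.5,
    RPRS < -8; indels fail on QD < 2, RPRS < -20, or FS > 200.  All
    inequalities are strict, so a metric sitting exactly at its threshold
    passes.  A metric missing from the record raises
    :class:`MissingAnnotationError` unless its name is listed in
    ``absent_fields`` (for callers that do not emit it, e.g. HaplotypeScore),
    in which case that sub-check is waived.
    """
    rules = _DENOVO_INDEL_FAIL if v.is_indel else _DENOVO_SNV_FAIL
    for name, fails in rules:
        value = _qc(v, name, absent_fields)
        if value is not None and fails(value):
            return False
    return True


def qc_pass_collapsing(
    v: AnnotatedVariant,
    genotype: str,
    blacklist: frozenset = frozenset(),
    absent_fields: Iterable[str] = (),
) -> bool:
    """Site/genotype QC gate for the case-control collapsing analysis.

    Requires depth >= 10, QUAL >= 30, GQ >= 20, QD >= 2, MQ >= 40,
    RPRS > -3, MQRS > -6, FS <= 200 for indels, a passing VQSR tranche, the
    site not on the artifact blacklist, and for heterozygous genotypes an
    alternate allele ratio >= 25%.
    """
    if genotype not in GENOTYPE_STATES:
        raise ValueError(f"unknown genotype state {genotype!r}")
    if v.key in blacklist:
        return False
    checks = (
        ("depth", lambda x: x >= 10),
        ("QUAL", lambda x: x >= 30),
        ("GQ", lambda x: x >= 20),
        ("QD", lambda x: x >= 2),
        ("MQ", lambda x: x >= 40),
        ("RPRS", lambda x: x > -3),
        ("MQRS", lambda x: x > -6),
    )
    for name, ok in checks:
        value = _qc(v, name, absent_fields)
        if value is not None and not ok(value):
            return False
    if v.is_indel:
        fs = _qc(v, "FS", absent_fields)
        if fs is not None and fs > 200:
            return False
    if not v.qc.get("vqsr_pass", False):
        return False
    if genotype == "het":
        depth = _qc(v, "depth", absent_fields)
        alt_depth = _qc(v, "alt_depth", absent_fields)
        if depth is not None and alt_depth is not None:
            if depth == 0 or alt_depth / depth < 0.25:
                return False
    return True


def _absent_from(v: AnnotatedVariant, database: str) -> bool:
    return v.pop_freq.get(database, 0.0) == 0.0


def _functional_class_qualifies(v: AnnotatedVariant, include_missense: bool) -> bool:
    if v.effect == "lof":
        return True
    if include_missense and v.effect == "missense":
        if v.polyphen_humdiv is None:
            raise MissingAnnotationError(
                f"missense variant {v.chrom}:{v.pos} lacks a HumDiv score"
            )
        return v.polyphen_humdiv >= PROBABLY_DAMAGING_HUMDIV
    return False


def is_qualifying_dominant(v: AnnotatedVariant, model: str) -> bool:
    """Dominant-model qualifying status.

    A variant qualifies when it is absent from EVS and ExAC, has at most 4
    copies of the variant allele across the combined case-control cohort,
    and is loss-of-function (``lof_only``) or loss-of-function / "probably
    damaging" missense (``lof_plus_probably_damaging``).
    """
    if model not in DOMINANT_MODELS:
        raise ValueError(f"unknown dominant model {model!r}; use one of {DOMINANT_MODELS}")
    if not (_absent_from(v, "EVS") and _absent_from(v, "ExAC")):
        return False
    if v.cohort_allele_count > 4:
        return False
    return _functional_class_qualifies(v, include_missense=(model == "lof_plus_probably_damaging"))


def is_qualifying_biallelic_site(v: AnnotatedVariant) -> bool:
    """Biallelic-model qualifying status for a single site.

    Qualifies when the effect is loss-of-function or probably-damaging
    missense and the minor allele frequency is below 0.001 in EVS, ExAC and
    the combined case-control cohort.
    """
    if not _functional_class_qualifies(v, include_missense=True):
        return False
    if v.cohort_maf is None:
        raise MissingAnnotationError(
            f"variant {v.chrom}:{v.pos} lacks a cohort allele frequency"
        )
    for freq in (v.pop_freq.get("EVS", 0.0), v.pop_freq.get("ExAC", 0.0), v.cohort_maf):
        if freq >= 0.001:
            return False
    return True


@dataclass(frozen=True)
class SiteGenotype:
    """Trio genotype calls at one variant site."""

    proband: str
    mother: str
    father: str
    qual: float = math.inf
    proband_gq: float = math.inf
    proband_depth: int = 10**6
    mother_depth: int = 10**6
    father_depth: int = 10**6

    def __post_init__(self) -> None:
        for g in (self.proband, self.mother, self.father):
            if g not in GENOTYPE_STATES:
                raise ValueError(f"invalid genotype state {g!r}")
        for d in (self.proband_depth, self.mother_depth, self.father_depth):
            if d < 0:
                raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotypes of a proband and both parents, aligned to a variant list."""

    sites: Sequence[SiteGenotype]
    proband_sex: str = "female"  # hemizygous logic applies to males only

    def __post_init__(self) -> None:
        if self.proband_sex not in ("male", "female"):
            raise ValueError("proband_sex must be 'male' or 'female'")


@dataclass(frozen=True)
class BiallelicGenotype:
    """A recessive-model genotype found in a proband.

    ``kind`` is ``"hom"`` (newly homozygous), ``"comphet"`` (two distinct
    qualifying het sites in one gene, unphased) or ``"hemi"`` (newly
    hemizygous, male X).  ``same_parent`` is set on compound hets where both
    contributing alleles are traceable to a single parent (a cis
    configuration that downstream filtering may drop); ``inconsistent`` marks
    records whose child allele is absent from both parents where inheritance
    was expected.
    """

    kind: str
    gene: str
    variant_indices: tuple
    same_parent: bool = False
    inconsistent: bool = False


_PARENT_CARRIES = {"het", "hom_alt", "hemi"}


def _genotype_ok(site: SiteGenotype) -> bool:
    """Proband genotype-level QC for recessive listing: QUAL>=30, GQ>=20."""
    return site.qual >= 30 and site.proband_gq >= 20


def _parent_ref_usable(genotype: str, depth: int) -> bool:
    # A homozygous-reference call is only trusted at >=10x coverage.
    return genotype != "hom_ref" or depth >= 10


def list_trio_biallelic_genotypes(
    trio: TrioGenotypes,
    variants: Sequence[AnnotatedVariant],
    known_hom_sites: frozenset = frozenset(),
    max_maf: float = 0.01,
) -> list[BiallelicGenotype]:
    """List newly homozygous, compound-het, and newly hemizygous genotypes.

    Scans a proband's genotypes across the trio and reports recessive-model
    genotypes built from qualifying sites (LoF or probably-damaging missense,
    see :func:`is_qualifying_biallelic_site`).  A contributing variant with a
    minor allele frequency above ``max_maf`` (default 1%) in any consulted
    source excludes the genotype, as does a homozygous/hemizygous observation
    of the same site in controls or the population databases
    (``known_hom_sites``, keyed by (chrom, pos, alt)).  Proband genotypes
    require QUAL >= 30 and GQ >= 20; a parental homozygous-reference call is
    usable only with at least 10-fold coverage.  Compound hets are unphased:
    two distinct qualifying het sites in one gene suffice, with a
    ``same_parent`` flag emitted when trio data trace both alleles to one
    parent.  Mendelian-inconsistent records are flagged, not dropped.
    """
    if len(trio.sites) != len(variants):
        raise ValueError("trio genotypes are not aligned to the variant list")

    def maf_ok(v: AnnotatedVariant) -> bool:
        freqs = [v.pop_freq.get("EVS", 0.0), v.pop_freq.get("ExAC", 0.0)]
        if v.cohort_maf is not None:
            freqs.append(v.cohort_maf)
        return all(f <= max_maf for f in freqs)

    records: list[BiallelicGenotype] = []
    het_by_gene: dict[str, list[int]] = {}

    for i, (v, site) in enumerate(zip(variants, trio.sites)):
        if not _genotype_ok(site):
            continue
        if not is_qualifying_biallelic_site(v) or not maf_ok(v):
            continue
        if (v.chrom, v.pos, v.alt) in known_hom_sites:
            continue

        if site.proband == "hom_alt":
            # Newly homozygous: neither parent already homozygous.
            if site.mother == "hom_alt" or site.father == "hom_alt":
                continue
            inconsistent = not (
                site.mother in _PARENT_CARRIES and site.father in _PARENT_CARRIES
            ) and not (site.mother == "missing" or site.father == "missing")
            if not _parent_ref_usable(site.mother, site.mother_depth):
                continue
            if not _parent_ref_usable(site.father, site.father_depth):
                continue
            records.append(
                BiallelicGenotype("hom", v.gene, (i,), inconsistent=inconsistent)
            )
        elif site.proband == "hemi":
            if trio.proband_sex != "male" or v.chrom not in ("X", "chrX"):
                continue
            if site.mother == "hom_alt" or site.father == "hemi":
                continue
            inconsistent = (
                site.mother not in _PARENT_CARRIES and site.mother != "missing"
            )
            records.append(
                BiallelicGenotype("hemi", v.gene, (i,), inconsistent=inconsistent)
            )
        elif site.proband == "het":
            het_by_gene.setdefault(v.gene, []).append(i)

    for gene, idx in sorted(het_by_gene.items()):
        if len(idx) < 2:
            continue
        # Unphased compound het: all qualifying het sites in the gene form
        # one record.  Trace parental origin where the trio allows it.
        origins = set()
        inconsistent = False
        for i in idx:
            site = trio.sites[i]
            m = site.mother in _PARENT_CARRIES
            f = site.father in _PARENT_CARRIES
            if m and not f:
                origins.add("mother")
            elif f and not m:
                origins.add("father")
            elif not m and not f:
                if site.mother != "missing" and site.father != "missing":
                    inconsistent = True  # de novo or genotyping error
                origins.add("unknown")
            else:
                origins.add("ambiguous")
        same_parent = origins in ({"mother"}, {"father"})
        records.append(
            BiallelicGenotype(
                "comphet",
                gene,
                tuple(idx),
                same_parent=same_parent,
                inconsistent=inconsistent,
            )
        )
    return records
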