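"""Hot-zone analysis of the most damaging de novo variant per individual.

Each de novo single-nucleotide substitution is placed on a plane whose
x-axis is a variant-level deleteriousness score (synonymous 0, LoF 1,
missense = PolyPhen-2 HumVar) and whose y-axis is the gene-level RVIS
intolerance percentile.  For each individual only the single most damaging
variant — the one with the shortest Euclidean distance to the most-damaging
corner (x=1, y=0) — is kept, and case/control enrichment in the "hot zone"
(score >= 0.95 and RVIS percentile <= 0.25) is tested with a two-tailed
Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .collapsing import fisher_two_tailed
from .variants import AnnotatedVariant, GeneAnnotation, MissingAnnotationError

__all__ = [
    "DamagePoint",
    "damage_score",
    "make_point",
    "most_damaging_per_individual",
    "HotZoneModel",
    "HotZoneResults",
    "hotzone_test",
]

POLYPHEN_CUT = 0.95
RVIS_CUT = 0.25


@dataclass(frozen=True)
class DamagePoint:
    """One individual's de novo variant on the damage/intolerance plane."""

    individual: str
    variant: AnnotatedVariant
    x: float  # variant deleteriousness in [0, 1]
    y: float  # gene RVIS percentile in [0, 1]

    @property
    def distance(self) -> float:
        """Euclidean distance to the most-damaging corner (1, 0)."""
        return math.hypot(1.0 - self.x, self.y)

    def in_hot_zone(self, polyphen_cut: float = POLYPHEN_CUT, rvis_cut: float = RVIS_CUT) -> bool:
        return self.x >= polyphen_cut and self.y <= rvis_cut


def damage_score(v: AnnotatedVariant) -> float:
    """Variant-level deleteriousness: synonymous 0, LoF 1, missense HumVar."""
    if v.effect == "synonymous":
        return 0.0
    if v.effect == "lof":
        return 1.0
    if v.effect == "missense":
        if v.polyphen_humvar is None:
            raise MissingAnnotationError(
                f"missense variant {v.chrom}:{v.pos} lacks a HumVar score"
            )
        return float(v.polyphen_humvar)
    raise ValueError(f"effect {v.effect!r} has no damage score")


def make_point(individual: str, v: AnnotatedVariant, annotation: GeneAnnotation) -> DamagePoint:
    return DamagePoint(individual, v, damage_score(v), annotation.rvis_percentile)


def most_damaging_per_individual(points: Sequence[DamagePoint]) -> Optional[DamagePoint]:
    """The point minimizing distance to (1, 0); ``None`` for empty input.

    Exact distance ties are broken by lowest (chrom, pos, alt) so the choice
    is deterministic.  All points must belong to one individual.
    """
    if not points:
        return None
    if len({p.individual for p in points}) > 1:
        raise ValueError("points from more than one individual")
    return min(
        points,
        key=lambda p: (p.distance, p.variant.chrom, p.variant.pos, p.variant.alt),
    )


class HotZoneModel:
    """Case/control enrichment test of hot-zone membership.

    ``cases`` and ``controls`` are per-individual most-damaging points
    (one per individual; indel de novos are excluded upstream since only
    single-nucleotide substitutions are scored).
    """

    def __init__(
        self,
        cases: Sequence[DamagePoint],
        controls: Sequence[DamagePoint],
        polyphen_cut: float = POLYPHEN_CUT,
        rvis_cut: float = RVIS_CUT,
    ):
        for group in (cases, controls):
            ids = [p.individual for p in group]
            if len(set(ids)) != len(ids):
                raise ValueError("an individual is represented more than once")
        self.cases = list(cases)
        self.controls = list(controls)
        self.polyphen_cut = polyphen_cut
        self.rvis_cut = rvis_cut

    def fit(self) -> "HotZoneResults":
        in_hz = lambda p: p.in_hot_zone(self.polyphen_cut, self.rvis_cut)
        a = sum(map(in_hz, self.cases))
        b = len(self.cases) - a
        c = sum(map(in_hz, self.controls))
        d = len(self.controls) - c
        return HotZoneResults(self, *hotzone_test_counts(a, b, c, d))


def hotzone_test_counts(a: int, b: int, c: int, d: int):
    """Fisher test + conditional-MLE odds ratio on a hot-zone 2x2 table."""
    p = fisher_two_tailed(a, b, c, d)
    res = odds_ratio([[a, b], [c, d]])  # conditional MLE
    ci = res.confidence_interval(0.95)
    return (np.array([[a, b], [c, d]]), float(res.statistic), (float(ci.low), float(ci.high)), p)


def hotzone_test(cases: Sequence[DamagePoint], controls: Sequence[DamagePoint], **kwargs):
    """Functional form of :class:`HotZoneModel`: returns its fitted results."""
    return HotZoneModel(cases, controls, **kwargs).fit()


@dataclass
class HotZoneResults:
    model: Optional[HotZoneModel]
    table: np.ndarray
    oddsratio: float
    oddsratio_ci: tuple
    p: float

    @property
    def case_fraction(self) -> float:
        a, b = self.table[0]
        return a / (a + b) if a + b else float("nan")

    @property
    def control_fraction(self) -> float:
        c, d = self.table[1]
        return c / (c + d) if c + d else float("nan")

    def summary(self) -> str:
        (a, b), (c, d) = self.table
        return "\n".join(
            [
                "Hot-zone enrichment (most damaging de novo per individual)",
                f"  cases:    {a}/{a + b} in hot zone ({100 * self.case_fraction:.1f}%)",
                f"  controls: {c}/{c + d} in hot zone ({100 * self.control_fraction:.1f}%)",
                f"  odds ratio (conditional MLE): {self.oddsratio:.3g} "
                f"(95% CI {self.oddsratio_ci[0]:.3g}-{self.oddsratio_ci[1]:.3g})",
                f"  two-tailed Fisher p: {self.p:.3g}",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.table,
            index=["case", "control"],
            columns=["hot_zone", "not_hot_zone"],
        )
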