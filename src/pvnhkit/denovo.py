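"""Trio de novo pipeline: candidates, expected counts, score calibration.

The de novo arm of the study calls candidate variants permissively in each
trio and then separates true events from artifacts with a supervised
probability score.  The acceptance threshold on that score is not chosen by
eye: it is calibrated so that the number of accepted variants matches the
number *expected* from the per-trio synonymous mutation rate, computed by
summing trinucleotide-context mutation rates over the coding sequence and
doubling for the two chromosomes.  This module implements that machinery:

* :class:`MutationRateTable` — per-gene per-haploid expected de novo rates,
  with the cohort-level expectation ``lambda_g = 2 * n_trios * mu_g``;
* :func:`identify_candidates` — proband-het / parents-hom-ref candidates
  passing the hard QC filters, restricted to coding sequence +/- 2 bp;
* :func:`expected_synonymous_count` — the calibration anchor;
* :func:`calibrate_threshold` — the largest score threshold at which the
  accepted count (Sanger-confirmed plus untested-above-threshold) reaches
  the expectation;
* :func:`fit_score_model` — a pluggable supervised probability scorer;
* :func:`poisson_gene_enrichment` — a plain upper-tail Poisson test for
  per-gene de novo excess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import AnnotatedVariant, TrioGenotypes, qc_pass_denovo

__all__ = [
    "MutationRateTable",
    "ScoredCandidate",
    "CalibrationResult",
    "identify_candidates",
    "expected_synonymous_count",
    "calibrate_threshold",
    "fit_score_model",
    "poisson_gene_enrichment",
]


@dataclass(frozen=True)
class MutationRateTable:
    """Per-gene expected de novo mutation rates.

    ``table`` has one row per gene with columns ``gene``, ``syn_rate`` and
    ``nonsyn_rate``, each an expected number of de novo variants per haploid
    genome per generation (the sum of trinucleotide-context rates over the
    gene's coding sequence).  Cohort-level expectations double the rate for
    the two chromosomes: ``lambda_g = 2 * n_trios * mu_g``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "syn_rate", "nonsyn_rate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"rate table lacks columns {sorted(missing)}")
        rates = self.table[["syn_rate", "nonsyn_rate"]].to_numpy()
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("mutation rates must be finite and >= 0")
        if self.table["gene"].duplicated().any():
            raise ValueError("duplicate gene in rate table")

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    def lam(self, n_trios: int, kind: str = "nonsyn") -> np.ndarray:
        """Cohort expectation ``2 * n_trios * mu_g`` per gene."""
        if kind not in ("syn", "nonsyn"):
            raise ValueError("kind must be 'syn' or 'nonsyn'")
        return 2.0 * n_trios * self.table[f"{kind}_rate"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ScoredCandidate:
    """A candidate de novo call with its model probability score.

    ``sanger_status`` records orthogonal validation: ``confirmed`` calls are
    accepted regardless of score, ``refuted`` calls rejected regardless, and
    ``untested`` calls stand or fall by the calibrated threshold.
    """

    variant: AnnotatedVariant
    probability_score: float
    sanger_status: str = "untested"

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability_score <= 1.0):
            raise ValueError("probability_score must lie in [0, 1]")
        if self.sanger_status not in ("confirmed", "refuted", "untested"):
            raise ValueError(f"unknown sanger_status {self.sanger_status!r}")


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    n_accepted: int
    expected_count: float
    n_confirmed: int = 0


def identify_candidates(
    trio: TrioGenotypes,
    variants: Sequence[AnnotatedVariant],
    coding_intervals: Optional[Sequence[tuple]] = None,
    flank: int = 2,
    absent_fields: Sequence[str] = (),
) -> list[AnnotatedVariant]:
    """Candidate de novo variants in one trio.

    A site is a candidate when the proband is het (or hemi) while both
    parents are homozygous reference, the call passes
    :func:`~pvnhkit.variants.qc_pass_denovo`, and the position lies within a
    coding interval extended by ``flank`` bp on each side (splice sites).
    ``coding_intervals`` is a sequence of 1-based closed ``(chrom, start,
    end)`` tuples; ``None`` disables the positional filter.  Sites with a
    missing parental genotype are excluded (inheritance cannot be ruled
    out), never promoted.
    """
    if len(trio.sites) != len(variants):
        raise ValueError("trio genotypes are not aligned to the variant list")

    def in_coding(v: AnnotatedVariant) -> bool:
        if coding_intervals is None:
            return True
        return any(
            chrom == v.chrom and start - flank <= v.pos <= end + flank
            for chrom, start, end in coding_intervals
        )

    out = []
    for v, site in zip(variants, trio.sites):
        if site.proband not in ("het", "hemi"):
            continue
        if site.mother != "hom_ref" or site.father != "hom_ref":
            continue
        if not in_coding(v):
            continue
        if not qc_pass_denovo(v, absent_fields):
            continue
        out.append(v)
    return out


def expected_synonymous_count(rates: MutationRateTable, n_trios: int) -> tuple[float, float]:
    """Expected cohort-wide synonymous de novo count and the per-trio rate.

    Returns ``(2 * n_trios * sum_g mu_g_syn, 2 * sum_g mu_g_syn)``.  The
    table must already be restricted to autosomal genes; the expectation is
    reported as a real number and rounded only at presentation.
    """
    if len(rates.table) == 0:
        raise ValueError("empty mutation rate table")
    per_trio = 2.0 * float(rates.table["syn_rate"].sum())
    return per_trio * n_trios, per_trio


def calibrate_threshold(
    candidates: Sequence[ScoredCandidate], expected_count: float
) -> CalibrationResult:
    """Calibrate the probability-score acceptance threshold.

    Finds the largest threshold ``t`` such that the Sanger-confirmed
    candidates plus the untested candidates with score >= ``t`` together
    reach the expected count.  Confirmed candidates are always accepted and
    refuted ones always rejected, whatever their scores.  When several
    untested candidates tie exactly at the threshold score, all of them are
    accepted, so ``n_accepted`` may exceed the expectation by the tie size;
    this keeps the procedure deterministic without a random tie-break.
    """
    confirmed = sum(1 for c in candidates if c.sanger_status == "confirmed")
    target = int(round(expected_count))
    if target < confirmed:
        raise ValueError(
            f"expected_count {expected_count} is below the {confirmed} "
            "Sanger-confirmed candidates; calibration is infeasible"
        )
    scores = sorted(
        (c.probability_score for c in candidates if c.sanger_status == "untested"),
        reverse=True,
    )
    budget = target - confirmed
    if budget == 0 or not scores:
        # No untested calls may be accepted: threshold just above any score.
        threshold = math.nextafter(1.0, 2.0)
        return CalibrationResult(threshold, confirmed, expected_count, confirmed)
    k = min(budget, len(scores))
    threshold = scores[k - 1]
    n_accepted = confirmed + sum(1 for s in scores if s >= threshold)
    return CalibrationResult(threshold, n_accepted, expected_count, confirmed)


def fit_score_model(
    features: pd.DataFrame,
    labels: Sequence[int],
    classifier=None,
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[Callable[[pd.DataFrame], np.ndarray], dict]:
    """Fit a supervised probability scorer for de novo calls.

    The scorer is a pluggable contract: any probabilistic classifier with the
    scikit-learn API may be passed via ``classifier``; the default is
    gradient-boosted trees.  Features are caller-supplied columns
    (variant-level, individual-level and genomic); labels are 1 for a
    validated de novo and 0 for a refuted call.  Returns ``(score_fn,
    metrics)`` where ``score_fn`` maps a feature table to probabilities and
    ``metrics`` carries stratified cross-validated sensitivity and
    specificity.
    """
    from sklearn.base import clone
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = features.to_numpy(dtype=float)
    if classifier is None:
        classifier = GradientBoostingClassifier(random_state=seed)

    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for train, test in cv.split(X, y):
        model = clone(classifier)
        model.fit(X[train], y[train])
        pred = (model.predict_proba(X[test])[:, 1] >= 0.5).astype(int)
        tp += int(np.sum((pred == 1) & (y[test] == 1)))
        fn += int(np.sum((pred == 0) & (y[test] == 1)))
        tn += int(np.sum((pred == 0) & (y[test] == 0)))
        fp += int(np.sum((pred == 1) & (y[test] == 0)))
    metrics = {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(y),
    }
    classifier.fit(X, y)

    def score_fn(table: pd.DataFrame) -> np.ndarray:
        return classifier.predict_proba(table.to_numpy(dtype=float))[:, 1]

    return score_fn, metrics


def poisson_gene_enrichment(observed: int, lam: float) -> float:
    """Upper-tail Poisson probability ``P(X >= observed)`` at mean ``lam``.

    A deliberately simple per-gene de novo enrichment utility.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if lam <= 0:
        raise ValueError("expected count must be > 0")
    return float(stats.poisson.sf(observed - 1, lam))
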