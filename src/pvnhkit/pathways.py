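"""Higher-criticism pathway testing on gene-level collapsing p-values.

A pathway may carry association signal spread thinly over many genes, none
of which is individually significant.  The higher-criticism (HC) statistic
detects such sparse signal by maximizing, over the lower tail of the sorted
gene-level p-values, the standardized gap between the observed empirical
CDF and the uniform CDF expected under a global null:

    HC = max_{1 <= i <= ceil(alpha0 m)}
         sqrt(m) * (i/m - p_(i)) / sqrt(p_(i) (1 - p_(i)))

Gene-level p-values come from a 1-df chi-square test on the carrier 2x2
table (a cheap stand-in for Fisher's exact test — the null distribution is
obtained by permutation anyway, so the marginal test only needs to be a
reasonable ranking statistic).  Pathway significance is assessed against
case/control label permutations, with a step-down min-p family-wise
adjustment computed on the *same* permutation matrix so correlation between
overlapping pathways is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .collapsing import CollapsingMatrix

__all__ = [
    "PathwayDefinition",
    "PathwayResult",
    "gene_level_chisq",
    "chisq_p_vector",
    "hc_statistic",
    "PathwayHCModel",
    "pathway_test",
    "read_gmt",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA0 = 0.5


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set, optionally with positive per-gene weights."""

    name: str
    genes: tuple
    weights: Optional[tuple] = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("pathway must contain at least one gene")
        if self.weights is not None:
            if len(self.weights) != len(self.genes):
                raise ValueError("weights must align with genes")
            if any(w <= 0 for w in self.weights):
                raise ValueError("weights must be positive")


@dataclass(frozen=True)
class PathwayResult:
    name: str
    n_genes_tested: int
    hc: float
    hc_weighted: Optional[float]
    p: float
    p_adjusted: float


def read_gmt(path) -> list[PathwayDefinition]:
    """Read gene sets from a GMT file (name, description, members...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(PathwayDefinition(parts[0], tuple(g for g in parts[2:] if g)))
    return out


def gene_level_chisq(a: int, b: int, c: int, d: int) -> float:
    """1-df chi-square p (no continuity correction) on a 2x2 carrier table.

    Closed form: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  A zero
    margin makes the test undefined and returns p = 1.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(stats.chi2.sf(chi2, df=1))


def chisq_p_vector(case_carriers, total_carriers, n_cases, n_total) -> np.ndarray:
    """Vectorized :func:`gene_level_chisq` for genes sharing sample margins."""
    a = np.asarray(case_carriers, dtype=float)
    k = np.asarray(total_carriers, dtype=float)
    b = n_cases - a
    c = k - a
    d = n_total - n_cases - c
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n_total * (a * d - b * c) ** 2 / denom
    p = stats.chi2.sf(chi2, df=1)
    return np.where(denom == 0, 1.0, p)


def hc_statistic(
    pvalues: Sequence[float],
    alpha0: float = DEFAULT_ALPHA0,
    weights: Optional[Sequence[float]] = None,
    clamp_b: int = 1000,
) -> float:
    """Higher-criticism statistic over a vector of p-values.

    The maximization runs over the smallest ``ceil(alpha0 * m)`` sorted
    p-values (at least one).  With ``weights``, the empirical CDF term
    ``i/m`` is replaced by the weighted ECDF at ``p_(i)`` and ``m`` by the
    effective sample size ``(sum w)^2 / sum w^2``.  p-values of exactly 0 or
    1 are clamped into ``[1/(2 m clamp_b), 1 - 1/(2 m clamp_b)]`` with a
    warning, since the standardization is undefined at the endpoints.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if not (0.0 < alpha0 <= 1.0):
        raise ValueError("alpha0 must lie in (0, 1]")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    eps = 1.0 / (2.0 * m * clamp_b)
    if np.any((p == 0) | (p == 1)):
        warnings.warn("p-values at 0 or 1 clamped for HC standardization")
        p = np.where(p == 0, eps, np.where(p == 1, 1.0 - eps, p))

    if weights is None:
        order = np.sort(p)
        i = np.arange(1, m + 1)
        ecdf = i / m
        m_eff = float(m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights must align with pvalues")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        idx = np.argsort(p, kind="mergesort")
        order = p[idx]
        ecdf = np.cumsum(w[idx]) / w.sum()
        m_eff = float(w.sum() ** 2 / np.sum(w**2))
    k = max(1, int(np.ceil(alpha0 * m)))
    hc = np.sqrt(m_eff) * (ecdf - order) / np.sqrt(order * (1.0 - order))
    return float(hc[:k].max())


class PathwayHCModel:
    """Permutation-calibrated HC tests over a collection of pathways.

    All pathways share one permutation matrix, which both defines each
    pathway's null HC distribution and drives the step-down min-p
    family-wise adjustment (preserving inter-pathway correlation).
    ``gene_weights`` maps gene -> positive weight for the weighted HC
    variant; a natural default for intolerance weighting is
    ``1 - rvis_percentile``.
    """

    def __init__(
        self,
        pathways: Sequence[PathwayDefinition],
        matrix: CollapsingMatrix,
        gene_weights: Optional[Mapping[str, float]] = None,
        alpha0: float = DEFAULT_ALPHA0,
    ):
        self.pathways = list(pathways)
        self.matrix = matrix
        self.gene_weights = dict(gene_weights) if gene_weights else None
        self.alpha0 = alpha0

    def _tested_gene_index(self) -> dict:
        ind = self.matrix.indicators
        total = ind.sum(axis=1)
        return {
            g: i for i, g in enumerate(self.matrix.genes) if total[i] > 0
        }

    def fit(self, permutations: int = 1000, seed: int = 0) -> "PathwayHCResults":
        m = self.matrix
        ind = m.indicators
        total = ind.sum(axis=1)
        n = len(m.individuals)
        n_cases = m.n_cases
        gene_idx = self._tested_gene_index()

        member_idx: list[np.ndarray] = []
        member_weights: list[Optional[np.ndarray]] = []
        kept: list[PathwayDefinition] = []
        for pw in self.pathways:
            pairs = [
                (gene_idx[g], w)
                for g, w in zip(
                    pw.genes,
                    pw.weights if pw.weights is not None else [None] * len(pw.genes),
                )
                if g in gene_idx
            ]
            if not pairs:
                logger.info("pathway %s has no tested genes; skipped", pw.name)
                continue
            kept.append(pw)
            member_idx.append(np.array([i for i, _ in pairs]))
            if pw.weights is not None:
                member_weights.append(np.array([w for _, w in pairs], dtype=float))
            elif self.gene_weights is not None:
                member_weights.append(
                    np.array(
                        [self.gene_weights.get(m.genes[i], 1.0) for i, _ in pairs]
                    )
                )
            else:
                member_weights.append(None)

        def hc_all(pvec: np.ndarray, weighted: bool) -> np.ndarray:
            out = np.empty(len(kept))
            for j, idx in enumerate(member_idx):
                w = member_weights[j] if weighted else None
                out[j] = hc_statistic(pvec[idx], self.alpha0, w, clamp_b=permutations)
            return out

        a_obs = ind[:, m.is_case].sum(axis=1)
        p_obs = chisq_p_vector(a_obs, total, n_cases, n)
        hc_obs = hc_all(p_obs, weighted=False)
        any_weighted = any(w is not None for w in member_weights)
        hc_obs_w = hc_all(p_obs, weighted=True) if any_weighted else None

        rng = np.random.default_rng(seed)
        null_hc = np.empty((permutations, len(kept)))
        for b in range(permutations):
            case_idx = rng.choice(n, size=n_cases, replace=False)
            a = ind[:, case_idx].sum(axis=1)
            null_hc[b] = hc_all(chisq_p_vector(a, total, n_cases, n), weighted=False)

        raw_p = (1.0 + (null_hc >= hc_obs[None, :]).sum(axis=0)) / (permutations + 1.0)
        adj_p = _stepdown_minp(hc_obs, null_hc, raw_p)

        results = [
            PathwayResult(
                pw.name,
                len(member_idx[j]),
                float(hc_obs[j]),
                float(hc_obs_w[j]) if hc_obs_w is not None else None,
                float(raw_p[j]),
                float(adj_p[j]),
            )
            for j, pw in enumerate(kept)
        ]
        return PathwayHCResults(self, results, null_hc)


def _stepdown_minp(hc_obs, null_hc, raw_p) -> np.ndarray:
    """Step-down min-p adjustment over the shared permutation matrix.

    Per-permutation pathway p-values are ranks of each permuted HC within
    its own null column; the step-down walks pathways from most to least
    significant, comparing each raw p against the distribution of minima
    over the not-yet-rejected set, then enforces monotonicity.
    """
    B, J = null_hc.shape
    # null p-value of permutation b for pathway j, computed within column j
    null_p = np.empty_like(null_hc)
    for j in range(J):
        col = null_hc[:, j]
        # count of permutations with HC >= value (ties share the count)
        sorted_col = np.sort(col)
        ge_counts = B - np.searchsorted(sorted_col, col, side="left")
        null_p[:, j] = (1.0 + ge_counts) / (B + 1.0)

    order = np.argsort(raw_p, kind="mergesort")
    adj = np.empty(J)
    # walk from least significant to most, accumulating column minima
    running_min = np.full(B, np.inf)
    adj_sorted = np.empty(J)
    for pos in range(J - 1, -1, -1):
        j = order[pos]
        running_min = np.minimum(running_min, null_p[:, j])
        adj_sorted[pos] = (1.0 + np.sum(running_min <= raw_p[order[pos]])) / (B + 1.0)
    # enforce step-down monotonicity (non-decreasing along the ordering)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj[order] = adj_sorted
    return np.maximum(adj, raw_p)


def pathway_test(
    pathways: Sequence[PathwayDefinition],
    matrix: CollapsingMatrix,
    permutations: int = 1000,
    seed: int = 0,
    **kwargs,
) -> list[PathwayResult]:
    """Functional wrapper over :class:`PathwayHCModel`."""
    return PathwayHCModel(pathways, matrix, **kwargs).fit(permutations, seed).results


@dataclass
class PathwayHCResults:
    model: PathwayHCModel
    results: list
    null_hc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def summary(self, top: int = 10) -> str:
        frame = self.to_frame().sort_values("p").head(top)
        n_sig = int((self.to_frame()["p_adjusted"] < 0.05).sum())
        return "\n".join(
            [
                "Pathway higher-criticism tests",
                f"  pathways tested: {len(self.results)}  "
                f"family-wise significant (adj p < 0.05): {n_sig}",
                "",
                frame.to_string(index=False),
            ]
        )
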