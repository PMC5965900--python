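"""Gene-level case-control collapsing association.

Rare-variant burden is tested gene by gene by collapsing each individual's
qualifying variants into a 0/1 carrier indicator and comparing carrier
proportions between cases and controls with a two-tailed Fisher's exact
test.  Genome-wide significance uses a Bonferroni correction across all
genes and all inheritance models tested.  Because qualifying variants are
ultra-rare, p-values under the null are far from uniform; the expected
quantile-quantile curve is therefore estimated empirically by permuting the
case/control labels and averaging order statistics of the permuted
p-values rank by rank.

The model object follows the estimator/results convention:

>>> model = CollapsingModel(matrix)
>>> res = model.fit(permutations=1000, seed=1)
>>> res.gene_results        # per-gene carrier counts, p, rank
>>> res.qq_expectation      # rank-wise mean permuted order statistics
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CollapsingMatrix",
    "CollapsingModel",
    "CollapsingResults",
    "build_matrix",
    "fisher_two_tailed",
    "genome_wide_threshold",
    "permutation_qq",
    "rank_genes",
]

MODEL_TAGS = (
    "dominant_lof_only",
    "dominant_lof_plus_probably_damaging",
    "biallelic_lof_only",
    "biallelic_lof_plus_probably_damaging",
)


@dataclass(frozen=True)
class CollapsingMatrix:
    """Gene x individual qualifying-variant indicator matrix.

    ``indicators`` is a 0/1 array of shape (n_genes, n_individuals);
    ``is_case`` is a boolean array over individuals.  ``model`` tags which
    qualifying-variant definition produced the matrix.
    """

    genes: Sequence[str]
    individuals: Sequence[str]
    indicators: np.ndarray
    is_case: np.ndarray
    model: str = "dominant_lof_only"

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicators)
        if ind.shape != (len(self.genes), len(self.individuals)):
            raise ValueError("indicator matrix shape does not match labels")
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if len(self.is_case) != len(self.individuals):
            raise ValueError("phenotype labels incomplete")
        object.__setattr__(self, "indicators", ind.astype(np.int8))
        object.__setattr__(self, "is_case", np.asarray(self.is_case, dtype=bool))

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def to_tsv(self, matrix_path, phenotype_path) -> None:
        pd.DataFrame(
            self.indicators, index=pd.Index(self.genes, name="gene"), columns=self.individuals
        ).to_csv(matrix_path, sep="\t")
        pd.DataFrame(
            {"individual": self.individuals, "is_case": self.is_case.astype(int)}
        ).to_csv(phenotype_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, phenotype_path, model="dominant_lof_only") -> "CollapsingMatrix":
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        pheno = pd.read_csv(phenotype_path, sep="\t").set_index("individual")
        is_case = pheno.loc[list(mat.columns), "is_case"].to_numpy().astype(bool)
        return cls(list(mat.index), list(mat.columns), mat.to_numpy(), is_case, model)


def build_matrix(
    carriers: Mapping[str, Mapping[str, int]],
    individuals: Sequence[str],
    is_case: Sequence[bool],
    model: str = "dominant_lof_only",
) -> CollapsingMatrix:
    """Assemble a collapsing matrix from per-gene carrier maps.

    ``carriers`` maps gene -> {individual -> count of qualifying variants or
    genotypes}.  Collapsing semantics: any positive count yields indicator 1.
    For biallelic models the caller supplies counts of qualifying *genotypes*
    (homozygous or unphased compound-het), so a single qualifying het never
    reaches this function with a positive count.
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}")
    if len(set(individuals)) != len(individuals):
        raise ValueError("duplicate individual ids")
    col = {ind: j for j, ind in enumerate(individuals)}
    genes = sorted(carriers)
    mat = np.zeros((len(genes), len(individuals)), dtype=np.int8)
    for i, g in enumerate(genes):
        for ind, count in carriers[g].items():
            if count > 0:
                mat[i, col[ind]] = 1
    return CollapsingMatrix(genes, list(individuals), mat, np.asarray(is_case, bool), model)


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Uses the point-probability rule: with margins fixed, the p-value sums the
    hypergeometric probabilities of every table at most as probable as the
    observed one.  Degenerate margins give p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def genome_wide_threshold(n_genes: int, n_models: int, alpha: float = 0.05) -> float:
    """Bonferroni genome-wide significance level ``alpha / (genes * models)``."""
    if n_genes <= 0 or n_models <= 0:
        raise ValueError("gene and model counts must be positive")
    return alpha / (n_genes * n_models)


def _fisher_p_vector(case_carriers, total_carriers, n_cases, n_total, cache):
    """Two-tailed Fisher p for many genes sharing the same sample margins."""
    out = np.ones(len(case_carriers))
    for i, (a, k) in enumerate(zip(case_carriers, total_carriers)):
        key = (int(a), int(k))
        p = cache.get(key)
        if p is None:
            b = n_cases - a
            c = k - a
            d = n_total - n_cases - c
            p = fisher_two_tailed(int(a), int(b), int(c), int(d))
            cache[key] = p
        out[i] = p
    return out


def permutation_qq(
    matrix: CollapsingMatrix, permutations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Permutation-derived expected order statistics of gene p-values.

    Randomly permutes the case/control labels (preserving the case count),
    recomputes every gene's Fisher p per permutation, sorts, and averages
    rank by rank: the mean 1st order statistic, mean 2nd, and so on.  Genes
    with zero qualifying carriers overall have no defined test and are
    excluded from the ranking.  Returns a frame with columns ``rank`` and
    ``expected_p``; empty when no gene has any carrier.
    """
    if permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    ind = matrix.indicators
    total = ind.sum(axis=1)
    tested = total > 0
    if not tested.any():
        return pd.DataFrame({"rank": [], "expected_p": []})
    ind = ind[tested]
    total = total[tested]
    n = len(matrix.individuals)
    n_cases = matrix.n_cases
    cache: dict = {}
    sums = np.zeros(ind.shape[0])
    for _ in range(permutations):
        case_idx = rng.choice(n, size=n_cases, replace=False)
        a = ind[:, case_idx].sum(axis=1)
        p = _fisher_p_vector(a, total, n_cases, n, cache)
        sums += np.sort(p)
    expected = sums / permutations
    return pd.DataFrame({"rank": np.arange(1, len(expected) + 1), "expected_p": expected})


def rank_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Rank gene results by ascending p; ties share the minimum rank.

    Secondary ordering of rows within a tie is by gene name, keeping output
    deterministic.  Expects columns ``gene`` and ``p``.
    """
    out = results.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    out["rank"] = out["p"].rank(method="min").astype(int)
    return out


class CollapsingModel:
    """Gene-level collapsing association model for one indicator matrix."""

    def __init__(self, matrix: CollapsingMatrix):
        self.matrix = matrix

    def fit(
        self, permutations: int = 0, seed: int = 0, n_genes_genome: Optional[int] = None,
        n_models: int = 4, alpha: float = 0.05,
    ) -> "CollapsingResults":
        """Test every gene and (optionally) build the permutation QQ curve.

        ``n_genes_genome`` sets the Bonferroni denominator; by default the
        number of genes in the matrix is used.
        """
        m = self.matrix
        ind = m.indicators
        a = ind[:, m.is_case].sum(axis=1)
        c = ind[:, ~m.is_case].sum(axis=1)
        n_cases, n_controls = m.n_cases, m.n_controls
        cache: dict = {}
        p = _fisher_p_vector(a, a + c, n_cases, n_cases + n_controls, cache)
        frame = pd.DataFrame(
            {
                "gene": list(m.genes),
                "case_carriers": a,
                "case_noncarriers": n_cases - a,
                "control_carriers": c,
                "control_noncarriers": n_controls - c,
                "case_pct": 100.0 * a / n_cases,
                "control_pct": 100.0 * c / n_controls,
                "p": p,
            }
        )
        ranked = rank_genes(frame)
        qq = None
        if permutations > 0:
            qq = permutation_qq(m, permutations, seed)
        threshold = genome_wide_threshold(
            n_genes_genome or len(m.genes), n_models, alpha
        )
        return CollapsingResults(self, ranked, qq, threshold)


@dataclass
class CollapsingResults:
    """Fitted collapsing association results."""

    model: CollapsingModel
    gene_results: pd.DataFrame
    qq_expectation: Optional[pd.DataFrame]
    genome_wide_threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.gene_results[self.gene_results["p"] <= self.genome_wide_threshold]

    def observed_qq(self) -> pd.DataFrame:
        """Sorted observed p-values for genes with at least one carrier."""
        g = self.gene_results
        tested = g[(g["case_carriers"] + g["control_carriers"]) > 0]
        obs = np.sort(tested["p"].to_numpy())
        return pd.DataFrame({"rank": np.arange(1, len(obs) + 1), "observed_p": obs})

    def summary(self, top: int = 10) -> str:
        m = self.model.matrix
        lines = [
            "Gene-level collapsing association",
            f"  model: {m.model}",
            f"  cases: {m.n_cases}  controls: {m.n_controls}  genes: {len(m.genes)}",
            f"  genome-wide threshold: {self.genome_wide_threshold:.3g}",
            f"  genome-wide significant genes: {len(self.significant)}",
            "",
            self.gene_results.head(top).to_string(index=False),
        ]
        return "\n".join(lines)
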