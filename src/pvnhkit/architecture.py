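"""De novo mutational-architecture likelihood model.

The question: across a cohort of trios, how many intolerant genes confer
disease risk, and how strongly?  The model summarizes the architecture with
two parameters — pi, the fraction of (intolerant) genes that confer risk,
and gamma, the relative-risk multiplier on the de novo rate contribution of
those genes among affected probands.  Each gene g is independently a risk
gene with prior probability pi; its cohort-wide nonsynonymous de novo count
x_g is Poisson with mean lambda_g (from the mutation-rate table,
lambda_g = 2 * n_trios * mu_g) in non-risk genes and gamma * lambda_g in
risk genes.  The marginal log-likelihood is therefore a per-gene
two-component Poisson mixture:

    l(pi, gamma) = sum_g log[(1 - pi) Pois(x_g; lambda_g)
                             + pi Pois(x_g; gamma * lambda_g)]

The likelihood is evaluated on a (pi, gamma) grid; a shift away from the
null expectation is tested with the likelihood ratio Lambda =
2 (l_max - l_{gamma=1}), whose null distribution is obtained by parametric
simulation under gamma = 1 rather than a chi-square approximation (gamma
sits on a boundary and pi is unidentified there).  See docs/methods.md for
the provenance and caveats of this likelihood form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "ArchitectureParams",
    "DeNovoCounts",
    "ArchitectureModel",
    "ArchitectureResults",
    "log_likelihood",
    "default_pi_grid",
    "default_gamma_grid",
]


@dataclass(frozen=True)
class ArchitectureParams:
    """(pi, gamma): risk-gene fraction and relative-risk multiplier."""

    pi: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError("pi must lie in [0, 1]")
        if self.gamma < 1.0:
            raise ValueError("gamma must be >= 1")


@dataclass(frozen=True)
class DeNovoCounts:
    """Observed per-gene cohort de novo counts with their null expectations.

    ``counts[g]`` is the observed nonsynonymous de novo count in gene g
    summed over the cohort; ``lam[g]`` the matching null expectation
    ``2 * n_trios * mu_g``.  The analysis conventionally restricts to
    intolerant genes (RVIS lowest quartile) — that restriction is applied by
    the caller when assembling this object.
    """

    genes: Sequence[str]
    counts: np.ndarray
    lam: np.ndarray
    n_trios: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        lam = np.asarray(self.lam, dtype=float)
        if counts.shape != lam.shape or counts.ndim != 1:
            raise ValueError("counts and lam must be matching 1-d arrays")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if np.any(lam < 0) or not np.all(np.isfinite(lam)):
            raise ValueError("lam must be finite and >= 0")
        if np.any((lam == 0) & (counts > 0)):
            raise ValueError("a gene with observed counts has zero expectation")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "lam", lam)


def default_pi_grid(n: int = 50) -> np.ndarray:
    """Log-spaced risk-fraction grid, 1e-4 .. 1."""
    return np.geomspace(1e-4, 1.0, n)


def default_gamma_grid(n: int = 60) -> np.ndarray:
    """Log-spaced relative-risk grid, 1 .. 1e5 (estimates can exceed 1e3)."""
    return np.geomspace(1.0, 1e5, n)


def _poisson_logpmf(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x * np.log(mu) - mu - gammaln(x + 1.0)
    # mu == 0 contributes 0 log-probability iff x == 0
    out = np.where(mu == 0, np.where(x == 0, 0.0, -np.inf), out)
    return out


def log_likelihood(params: ArchitectureParams, data: DeNovoCounts) -> float:
    """Mixture log-likelihood at a single (pi, gamma) point."""
    lp_null = _poisson_logpmf(data.counts, data.lam)
    lp_risk = _poisson_logpmf(data.counts, params.gamma * data.lam)
    with np.errstate(divide="ignore"):
        terms = np.logaddexp(np.log1p(-params.pi) + lp_null, np.log(params.pi) + lp_risk)
    return float(terms.sum())


class ArchitectureModel:
    """Grid-based fit of the two-parameter de novo architecture model."""

    def __init__(
        self,
        data: DeNovoCounts,
        pi_grid: Optional[np.ndarray] = None,
        gamma_grid: Optional[np.ndarray] = None,
    ):
        self.data = data
        self.pi_grid = np.asarray(pi_grid if pi_grid is not None else default_pi_grid())
        self.gamma_grid = np.asarray(
            gamma_grid if gamma_grid is not None else default_gamma_grid()
        )
        if not np.any(np.isclose(self.gamma_grid, 1.0)):
            raise ValueError("gamma grid must include the null value 1")

    # -- likelihood evaluation -------------------------------------------

    def loglik_surface(self, counts: Optional[np.ndarray] = None) -> np.ndarray:
        """Log-likelihood on the (pi, gamma) grid; shape (len(pi), len(gamma))."""
        x = self.data.counts if counts is None else np.asarray(counts)
        lam = self.data.lam
        lp_null = _poisson_logpmf(x, lam)
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.pi_grid)[:, None]
            log_1mpi = np.log1p(-self.pi_grid)[:, None]
        out = np.empty((len(self.pi_grid), len(self.gamma_grid)))
        for j, gamma in enumerate(self.gamma_grid):
            lp_risk = _poisson_logpmf(x, gamma * lam)
            terms = np.logaddexp(log_1mpi + lp_null[None, :], log_pi + lp_risk[None, :])
            out[:, j] = terms.sum(axis=1)
        return out

    def _lrt_from_surface(self, surface: np.ndarray, counts: np.ndarray) -> float:
        null_ll = float(_poisson_logpmf(counts, self.data.lam).sum())
        return max(0.0, 2.0 * (float(surface.max()) - null_ll))

    def simulate_null_lrt(self, n_sims: int, seed: int = 0) -> np.ndarray:
        """Parametric-bootstrap LRT statistics under gamma = 1."""
        rng = np.random.default_rng(seed)
        stats_out = np.empty(n_sims)
        for b in range(n_sims):
            x = rng.poisson(self.data.lam)
            stats_out[b] = self._lrt_from_surface(self.loglik_surface(x), x)
        return stats_out

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        null_sims: int = 10000,
        seed: int = 0,
        null_stats: Optional[np.ndarray] = None,
        level: float = 0.95,
    ) -> "ArchitectureResults":
        """Evaluate the surface, locate the MLE, and test the null shift.

        ``null_stats`` lets a caller reuse a precomputed null LRT sample
        (the null distribution depends only on the lambda vector, not the
        observed counts); otherwise ``null_sims`` parametric simulations are
        run under gamma = 1.  Set ``null_sims=0`` to skip the p-value.
        """
        data = self.data
        surface = self.loglik_surface()
        if data.counts.sum() == 0:
            import warnings

            warnings.warn("all-zero de novo counts: surface is null-equivalent")
        i, j = np.unravel_index(np.argmax(surface), surface.shape)
        mle = ArchitectureParams(float(self.pi_grid[i]), float(self.gamma_grid[j]))
        lrt = self._lrt_from_surface(surface, data.counts)

        p_value = None
        if null_stats is None and null_sims > 0:
            null_stats = self.simulate_null_lrt(null_sims, seed)
        if null_stats is not None:
            null_stats = np.asarray(null_stats)
            p_value = (1.0 + np.sum(null_stats >= lrt)) / (len(null_stats) + 1.0)

        return ArchitectureResults(self, surface, mle, lrt, p_value, level, null_stats)


@dataclass
class ArchitectureResults:
    """Fitted likelihood surface with MLE, LRT and confidence machinery."""

    model: ArchitectureModel
    surface: np.ndarray
    mle: ArchitectureParams
    lrt: float
    p_value: Optional[float]
    level: float = 0.95
    null_stats: Optional[np.ndarray] = None

    # joint confidence region: points within chi2(2) / 2 of the maximum
    def _joint_cut(self) -> float:
        return float(self.surface.max()) - stats.chi2.ppf(self.level, df=2) / 2.0

    def in_confidence_region(self, params: ArchitectureParams) -> bool:
        """Whether (pi, gamma) lies in the joint profile-likelihood region.

        Evaluates the likelihood at the exact point (not a grid lookup), so
        true parameter values off the grid are handled correctly.
        """
        return log_likelihood(params, self.model.data) >= self._joint_cut()

    def confidence_region(self) -> np.ndarray:
        """Boolean mask over the grid marking the joint confidence region."""
        return self.surface >= self._joint_cut()

    def profile_interval(self, param: str) -> tuple[float, float]:
        """Profile-likelihood interval for ``'pi'`` or ``'gamma'`` (df=1 cut)."""
        cut = float(self.surface.max()) - stats.chi2.ppf(self.level, df=1) / 2.0
        profile = self.surface.max(axis=1 if param == "pi" else 0)
        grid = self.model.pi_grid if param == "pi" else self.model.gamma_grid
        inside = np.flatnonzero(profile >= cut)
        if len(inside) == 0:
            raise ValueError("profile interval is empty; grid too coarse?")
        # the cut crossing lies between the outermost inside point and its
        # neighbour, so bracket by one grid step on each side (conservative)
        lo = grid[max(inside.min() - 1, 0)]
        hi = grid[min(inside.max() + 1, len(grid) - 1)]
        return float(lo), float(hi)

    def surface_frame(self) -> pd.DataFrame:
        """Long-format (pi, gamma, loglik) table of the full surface."""
        pi, gamma = np.meshgrid(
            self.model.pi_grid, self.model.gamma_grid, indexing="ij"
        )
        return pd.DataFrame(
            {"pi": pi.ravel(), "gamma": gamma.ravel(), "loglik": self.surface.ravel()}
        )

    def summary(self) -> str:
        ci_pi = self.profile_interval("pi")
        ci_gamma = self.profile_interval("gamma")
        lines = [
            "De novo architecture model (two-component Poisson mixture)",
            f"  genes: {len(self.model.data.genes)}  "
            f"total de novo count: {int(self.model.data.counts.sum())}",
            f"  MLE: pi = {self.mle.pi:.3g}, gamma = {self.mle.gamma:.3g}",
            f"  {100 * self.level:.0f}% profile CI pi:    [{ci_pi[0]:.3g}, {ci_pi[1]:.3g}]",
            f"  {100 * self.level:.0f}% profile CI gamma: [{ci_gamma[0]:.3g}, {ci_gamma[1]:.3g}]",
            f"  LRT vs gamma = 1: {self.lrt:.3f}",
        ]
        if self.p_value is not None:
            lines.append(f"  parametric-simulation p: {self.p_value:.3g}")
        return "\n".join(lines)
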