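"""Synthetic-cohort generators with known ground truth.

The raw cohort behind a rare-disease exome study is protected, so every
input the analysis pipeline consumes can be generated here instead: a
per-gene mutation-rate table, trio de novo variant calls under a
two-parameter risk architecture, case/control qualifying-variant carrier
matrices with spiked risk genes, and developmental brain expression with a
planted co-expression module.  Each generator is driven by a single
:class:`SimulationConfig` and returns the ground truth alongside the data,
which is what makes parameter-recovery and calibration tests possible.

Default cohort dimensions mirror the reference study design: 535 trios for
the de novo arm, 196 cases against 13,151 controls for the collapsing arm,
an autosomal synonymous de novo expectation of 0.303 per trio, and a
14-gene query module for the expression arm.

Randomness: every generator call builds its own ``numpy`` Generator from
``config.seed`` (plus a fixed per-generator stream tag), so a fixed config
is bit-reproducible and the four generators are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .architecture import DeNovoCounts
from .collapsing import CollapsingMatrix
from .coexpression import ExpressionDataset
from .denovo import MutationRateTable
from .variants import AnnotatedVariant

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TrioDenovo",
    "simulate_mutation_rate_table",
    "simulate_trio_denovos",
    "simulate_case_control_matrix",
    "simulate_expression",
    "aggregate_nonsyn_counts",
]

# fraction of nonsynonymous de novo events that are LoF (vs missense)
_LOF_FRACTION = 0.2
# exome-wide nonsynonymous : synonymous de novo rate ratio; with a
# synonymous rate of 0.303/trio this gives ~1.1 de novo variants per trio
_NONSYN_SYN_RATIO = 2.64


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for all synthetic generators.

    ``spiked_genes`` lists ``(gene_id, case_carrier_prob, control_carrier_prob)``
    triples; a spiked gene receives an exact carrier count of
    ``round(prob * n)`` in each arm (emulating a printed carrier
    configuration), while unspiked genes draw Bernoulli carriers at
    ``background_carrier_rate`` in cases and controls alike.
    """

    n_trios: int = 535
    n_cases: int = 196
    n_controls: int = 13151
    n_genes: int = 2000
    risk_fraction: float = 0.01
    relative_risk: float = 50.0
    per_trio_syn_rate: float = 0.303
    spiked_genes: tuple = ()
    background_carrier_rate: float = 0.002
    expression_module_size: int = 14
    module_loading: float = 0.9
    n_expression_samples: int = 300
    n_donors: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trios", "n_cases", "n_controls", "n_genes",
                     "expression_module_size", "n_expression_samples", "n_donors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.risk_fraction <= 1.0):
            raise ValueError("risk_fraction must lie in [0, 1]")
        if self.relative_risk < 1.0:
            raise ValueError("relative_risk must be >= 1")
        if self.per_trio_syn_rate <= 0:
            raise ValueError("per_trio_syn_rate must be > 0")
        if not (0.0 <= self.background_carrier_rate <= 1.0):
            raise ValueError("background_carrier_rate must lie in [0, 1]")
        if not (0.0 <= self.module_loading <= 1.0):
            raise ValueError("module_loading must lie in [0, 1]")
        for gene, p_case, p_ctrl in self.spiked_genes:
            if not (0.0 <= p_case <= 1.0 and 0.0 <= p_ctrl <= 1.0):
                raise ValueError(f"spiked gene {gene}: probabilities must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "spiked_genes" in raw:
            raw["spiked_genes"] = tuple(tuple(s) for s in raw["spiked_genes"])
        return cls(**raw)

    def gene_ids(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure behind one generator call."""

    risk_gene_ids: frozenset = frozenset()
    module_gene_ids: frozenset = frozenset()
    spiked_gene_ids: frozenset = frozenset()


@dataclass(frozen=True)
class TrioDenovo:
    """A de novo call attributed to one proband."""

    individual: str
    variant: AnnotatedVariant


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_mutation_rate_table(config: SimulationConfig) -> MutationRateTable:
    """Per-gene synonymous and nonsynonymous per-haploid mutation rates.

    Gene-to-gene rate heterogeneity is log-normal (mimicking coding-sequence
    length variation); rates are scaled so the diploid synonymous
    expectation summed over genes equals ``per_trio_syn_rate`` exactly.
    """
    if config.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = _rng(config, 1)
    weights = rng.lognormal(mean=0.0, sigma=0.7, size=config.n_genes)
    syn = weights / weights.sum() * (config.per_trio_syn_rate / 2.0)
    ratio = _NONSYN_SYN_RATIO * rng.lognormal(mean=0.0, sigma=0.1, size=config.n_genes)
    table = pd.DataFrame(
        {"gene": config.gene_ids(), "syn_rate": syn, "nonsyn_rate": syn * ratio}
    )
    return MutationRateTable(table)


def _draw_risk_genes(config: SimulationConfig, rng: np.random.Generator) -> frozenset:
    genes = config.gene_ids()
    excluded = {g for g, _, _ in config.spiked_genes}
    excluded |= set(genes[-config.expression_module_size:])
    risk = {
        g
        for g in genes
        if g not in excluded and rng.random() < config.risk_fraction
    }
    return frozenset(risk)


def _simulated_qc(rng: np.random.Generator) -> dict:
    depth = int(rng.poisson(60) + 10)
    return {
        "QUAL": float(rng.uniform(200, 3000)),
        "GQ": 99.0,
        "QD": float(rng.normal(15, 3)),
        "MQ": float(rng.normal(60, 1)),
        "FS": float(rng.exponential(5)),
        "HS": float(rng.exponential(2)),
        "MQRS": float(rng.normal(0, 1)),
        "RPRS": float(rng.normal(0, 1)),
        "depth": depth,
        "alt_depth": int(rng.binomial(depth, 0.5)),
        "vqsr_pass": True,
    }


def simulate_trio_denovos(
    config: SimulationConfig, rates: MutationRateTable
) -> tuple[list[TrioDenovo], GroundTruth]:
    """Trio de novo calls under the two-parameter risk architecture.

    Each gene is independently a risk gene with probability
    ``risk_fraction``; cohort-wide nonsynonymous counts are Poisson with
    mean ``2 * n_trios * mu_g`` multiplied by ``relative_risk`` in risk
    genes, while synonymous counts are untouched by the architecture.
    Events are attributed to uniformly random trios and carry simulated QC
    fields and PolyPhen-like scores (LoF and synonymous variants carry no
    PolyPhen score; missense scores are Beta(0.5, 0.5), populating both the
    benign and damaging tails around the hot-zone boundary).
    """
    rng = _rng(config, 2)
    genes = rates.genes
    risk = _draw_risk_genes(config, rng)
    is_risk = np.isin(genes, sorted(risk))

    lam_syn = rates.lam(config.n_trios, "syn")
    lam_nonsyn = rates.lam(config.n_trios, "nonsyn") * np.where(
        is_risk, config.relative_risk, 1.0
    )
    syn_counts = rng.poisson(lam_syn)
    nonsyn_counts = rng.poisson(lam_nonsyn)

    chroms = [str(1 + i % 22) for i in range(len(genes))]
    calls: list[TrioDenovo] = []
    for gi, gene in enumerate(genes):
        for kind, count in (("synonymous", syn_counts[gi]), ("nonsyn", nonsyn_counts[gi])):
            for _ in range(int(count)):
                trio = f"trio{rng.integers(config.n_trios):05d}"
                pos = int(gi * 100_000 + rng.integers(1, 50_000))
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                if kind == "synonymous":
                    effect, humdiv, humvar = "synonymous", None, None
                elif rng.random() < _LOF_FRACTION:
                    effect, humdiv, humvar = "lof", None, None
                else:
                    effect = "missense"
                    humdiv = float(rng.beta(0.5, 0.5))
                    humvar = float(rng.beta(0.5, 0.5))
                calls.append(
                    TrioDenovo(
                        trio,
                        AnnotatedVariant(
                            chrom=chroms[gi],
                            pos=pos,
                            ref=str(ref),
                            alt=str(alt),
                            gene=gene,
                            effect=effect,
                            polyphen_humdiv=humdiv,
                            polyphen_humvar=humvar,
                            qc=_simulated_qc(rng),
                            pop_freq={"EVS": 0.0, "ExAC": 0.0},
                        ),
                    )
                )
    return calls, GroundTruth(risk_gene_ids=risk)


def aggregate_nonsyn_counts(
    calls: Sequence[TrioDenovo], rates: MutationRateTable, n_trios: int
) -> DeNovoCounts:
    """Cohort nonsynonymous de novo counts per gene, for the architecture fit."""
    counts = pd.Series(0, index=pd.Index(rates.genes, name="gene"), dtype=np.int64)
    for call in calls:
        if call.variant.effect in ("missense", "lof"):
            counts[call.variant.gene] += 1
    return DeNovoCounts(
        list(rates.genes), counts.to_numpy(), rates.lam(n_trios, "nonsyn"), n_trios
    )


def simulate_case_control_matrix(
    config: SimulationConfig,
) -> tuple[CollapsingMatrix, GroundTruth]:
    """Qualifying-variant carrier matrix for cases and controls.

    Unspiked genes draw independent Bernoulli carrier indicators at the
    shared background rate in both arms; each spiked gene places an exact
    ``round(prob * n)`` carriers uniformly at random within the arm.
    """
    rng = _rng(config, 3)
    genes = config.gene_ids()
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    individuals = [f"case{i:05d}" for i in range(n_cases)] + [
        f"ctrl{i:05d}" for i in range(n_controls)
    ]
    is_case = np.arange(n) < n_cases

    mat = np.zeros((len(genes), n), dtype=np.int8)
    rate = config.background_carrier_rate
    if rate > 0:
        # chunked draws keep the transient random matrix small
        chunk = max(1, int(5e7 // max(n, 1)))
        for start in range(0, len(genes), chunk):
            stop = min(start + chunk, len(genes))
            mat[start:stop] = (
                rng.random((stop - start, n), dtype=np.float32) < rate
            ).astype(np.int8)

    gene_row = {g: i for i, g in enumerate(genes)}
    spiked = set()
    for gene, p_case, p_ctrl in config.spiked_genes:
        if gene not in gene_row:
            raise ValueError(f"spiked gene {gene!r} not in the gene universe")
        row = np.zeros(n, dtype=np.int8)
        k_case = int(round(p_case * n_cases))
        k_ctrl = int(round(p_ctrl * n_controls))
        row[rng.choice(n_cases, size=k_case, replace=False)] = 1
        row[n_cases + rng.choice(n_controls, size=k_ctrl, replace=False)] = 1
        mat[gene_row[gene]] = row
        spiked.add(gene)

    matrix = CollapsingMatrix(genes, individuals, mat, is_case)
    return matrix, GroundTruth(spiked_gene_ids=frozenset(spiked))


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Developmental expression with a planted co-expression module.

    The last ``expression_module_size`` genes of the universe load on a
    shared latent factor with coefficient ``module_loading`` (unit marginal
    variance), background genes are independent noise, donors contribute
    unequal sample counts (Dirichlet-skewed), and sample ages span the 4-38
    weeks-post-conception window.
    """
    if config.expression_module_size < 2:
        raise ValueError("expression_module_size must be >= 2")
    rng = _rng(config, 4)
    genes = config.gene_ids()
    module = genes[-config.expression_module_size:]
    n_s = config.n_expression_samples

    donor_probs = rng.dirichlet(np.full(config.n_donors, 0.8))
    donors = rng.choice(config.n_donors, size=n_s, p=donor_probs)
    ages = rng.uniform(4.0, 38.0, size=n_s)
    samples = pd.DataFrame(
        {
            "sample": [f"s{i:04d}" for i in range(n_s)],
            "donor": [f"donor{d:03d}" for d in donors],
            "age": np.round(ages, 2),
        }
    )

    latent = rng.normal(size=n_s)
    expr = rng.normal(size=(len(genes), n_s))
    loading = config.module_loading
    resid = np.sqrt(max(0.0, 1.0 - loading**2))
    module_rows = np.arange(len(genes) - len(module), len(genes))
    expr[module_rows] = loading * latent + resid * expr[module_rows]

    dataset = ExpressionDataset(
        pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples["sample"]),
        samples,
        name="synthetic",
    )
    return dataset, GroundTruth(module_gene_ids=frozenset(module))
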