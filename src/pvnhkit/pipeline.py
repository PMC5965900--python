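"""End-to-end pipeline orchestration over the synthetic cohort.

Chains the generators and the analysis engines in dependency order from a
single YAML config: simulate inputs, calibrate the de novo score threshold,
run the hot-zone test, fit the architecture likelihood, run the collapsing
association with its permutation QQ expectation, test pathways, and
prioritize candidates by co-expression.  Every output directory carries the
config hash and master seed so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as pio
from .architecture import ArchitectureModel
from .coexpression import CoexpressionPrioritizer, QueryGeneSet, query_set_cohesion
from .collapsing import CollapsingModel
from .denovo import ScoredCandidate, calibrate_threshold, expected_synonymous_count
from .hotzone import HotZoneModel, make_point, most_damaging_per_individual
from .pathways import PathwayDefinition, PathwayHCModel
from .simulate import (
    SimulationConfig,
    aggregate_nonsyn_counts,
    simulate_case_control_matrix,
    simulate_expression,
    simulate_mutation_rate_table,
    simulate_trio_denovos,
)
from .variants import AnnotatedVariant, GeneAnnotation

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "denovo", "hotzone", "architecture", "collapse", "pathways", "coexpress")


class PipelineConfigError(ValueError):
    """Raised when a pipeline config fails validation before any stage runs."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int
    stages: tuple = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    permutations: int = 200
    null_sims: int = 200
    coexpression_sets: int = 200
    gmt_path: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise PipelineConfigError("config must set a seed (stochastic stages)")
        if "outdir" not in raw:
            raise PipelineConfigError("config must set an output directory")
        sim_raw = raw.get("simulation", {})
        sim_raw.setdefault("seed", raw["seed"])
        if "spiked_genes" in sim_raw:
            sim_raw["spiked_genes"] = tuple(tuple(s) for s in sim_raw["spiked_genes"])
        stages = tuple(raw.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages {sorted(unknown)}")
        gmt = raw.get("gmt_path")
        if gmt is not None and not Path(gmt).exists():
            raise PipelineConfigError(f"gmt_path {gmt} does not exist")
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw["seed"]),
            stages=stages,
            simulation=SimulationConfig(**sim_raw),
            permutations=int(raw.get("permutations", 200)),
            null_sims=int(raw.get("null_sims", 200)),
            coexpression_sets=int(raw.get("coexpression_sets", 200)),
            gmt_path=Path(gmt) if gmt else None,
        )

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}
    sim = config.simulation
    stages = set(config.stages)

    current = "simulate"
    try:
        rates = simulate_mutation_rate_table(sim)
        calls, truth = simulate_trio_denovos(sim, rates)
        matrix, cc_truth = simulate_case_control_matrix(sim)
        if "simulate" in stages:
            rates.to_tsv(out / "mutation_rates.tsv")
            pio.write_denovo_tsv(calls, out / "denovo_calls.tsv")
            matrix.to_tsv(out / "collapsing_matrix.tsv", out / "phenotypes.tsv")
            report["stages"]["simulate"] = {
                "n_denovo_calls": len(calls),
                "n_risk_genes": len(truth.risk_gene_ids),
                "n_spiked_genes": len(cc_truth.spiked_gene_ids),
            }
            logger.info("simulate: %d de novo calls, %d risk genes", len(calls), len(truth.risk_gene_ids))

        # simulated gene-level intolerance percentiles shared by stages
        rvis = {g: float(p) for g, p in zip(rates.genes, rng.random(len(rates.genes)))}

        if "denovo" in stages:
            current = "denovo"
            expected, per_trio = expected_synonymous_count(rates, sim.n_trios)
            n_true = len(calls)
            scores_true = rng.beta(9, 1, size=n_true)
            scores_false = rng.beta(1, 9, size=n_true)
            candidates = [
                ScoredCandidate(c.variant, float(s)) for c, s in zip(calls, scores_true)
            ] + [
                ScoredCandidate(calls[i % n_true].variant, float(s))
                for i, s in enumerate(scores_false)
            ]
            cal = calibrate_threshold(candidates, expected_count=round(expected))
            report["stages"]["denovo"] = {
                "expected_synonymous": expected,
                "per_trio_synonymous_rate": per_trio,
                "calibrated_threshold": cal.threshold,
                "n_accepted": cal.n_accepted,
            }

        if "hotzone" in stages:
            current = "hotzone"
            control_sim = SimulationConfig(
                **{**sim.__dict__, "relative_risk": 1.0, "seed": sim.seed + 1}
            )
            control_calls, _ = simulate_trio_denovos(control_sim, rates)

            def points(call_list):
                by_ind: dict = {}
                for c in call_list:
                    if c.variant.is_indel or c.variant.effect == "other":
                        continue
                    ann = GeneAnnotation(c.variant.gene, rvis[c.variant.gene])
                    by_ind.setdefault(c.individual, []).append(
                        make_point(c.individual, c.variant, ann)
                    )
                return [most_damaging_per_individual(v) for v in by_ind.values()]

            hz = HotZoneModel(points(calls), points(control_calls)).fit()
            (out / "hotzone.json").write_text(
                json.dumps(
                    {
                        "table": hz.table.tolist(),
                        "odds_ratio": hz.oddsratio,
                        "ci": hz.oddsratio_ci,
                        "p": hz.p,
                    },
                    default=float,
                )
            )
            report["stages"]["hotzone"] = {
                "case_fraction": hz.case_fraction,
                "control_fraction": hz.control_fraction,
                "p": hz.p,
            }

        if "architecture" in stages:
            current = "architecture"
            counts = aggregate_nonsyn_counts(calls, rates, sim.n_trios)
            res = ArchitectureModel(counts).fit(null_sims=config.null_sims, seed=config.seed)
            res.surface_frame().to_csv(out / "architecture_surface.tsv", sep="\t", index=False)
            report["stages"]["architecture"] = {
                "pi_mle": res.mle.pi,
                "gamma_mle": res.mle.gamma,
                "lrt": res.lrt,
                "p": res.p_value,
            }

        if "collapse" in stages:
            current = "collapse"
            res = CollapsingModel(matrix).fit(
                permutations=config.permutations, seed=config.seed
            )
            res.gene_results.to_csv(out / "collapsing_results.tsv", sep="\t", index=False)
            if res.qq_expectation is not None:
                res.qq_expectation.to_csv(out / "qq_expected.tsv", sep="\t", index=False)
            report["stages"]["collapse"] = {
                "n_genes": len(res.gene_results),
                "min_p": float(res.gene_results["p"].min()),
                "top_gene": res.gene_results.iloc[0]["gene"],
                "genome_wide_threshold": res.genome_wide_threshold,
            }

        if "pathways" in stages:
            current = "pathways"
            if config.gmt_path is not None:
                pathways = pio.read_gmt(config.gmt_path)
            else:
                genes = list(matrix.genes)
                pathways = [
                    PathwayDefinition(f"demo_set_{i}", tuple(genes[i * 25 : (i + 1) * 25]))
                    for i in range(min(20, len(genes) // 25))
                ]
            weights = {g: 1.0 - rvis[g] for g in rvis}
            res = PathwayHCModel(pathways, matrix, gene_weights=weights).fit(
                permutations=config.permutations, seed=config.seed
            )
            res.to_frame().to_csv(out / "pathway_results.tsv", sep="\t", index=False)
            frame = res.to_frame()
            report["stages"]["pathways"] = {
                "n_pathways": len(frame),
                "n_significant_adjusted": int((frame["p_adjusted"] < 0.05).sum()),
            }

        if "coexpress" in stages:
            current = "coexpress"
            dataset, expr_truth = simulate_expression(sim)
            module = sorted(expr_truth.module_gene_ids)
            query = QueryGeneSet(tuple(module))
            background = [g for g in dataset.genes if g not in expr_truth.module_gene_ids]
            candidates = list(rng.choice(background, size=min(30, len(background)), replace=False))
            model = CoexpressionPrioritizer([dataset], query)
            fitted = model.fit(
                candidates, n_sets=config.coexpression_sets, seed=config.seed
            )
            fitted.table.to_csv(out / "prioritization.tsv", sep="\t")
            cohesion = query_set_cohesion(query, dataset, n_random=config.coexpression_sets, seed=config.seed)
            report["stages"]["coexpress"] = {
                "n_prioritized": len(fitted.prioritized),
                "thresholds": fitted.thresholds,
                "query_cohesion_percentile": cohesion["percentile"],
            }
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
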