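"""Scenario orchestration: simulate, estimate, build matrices, predict,
evaluate -- the two-step pipeline behind all result tables.

A scenario is the standard design (h2 = 0.5, 50 QTL) with at most one
factor altered (heritability sweep, QTL-count sweep). Each replicate
draws an independent genome, population and trait from a child seed of
the master seed, so scenarios are reproducible end to end and single
replicates can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import (
    BayesBConfig,
    MarkerEffects,
    RidgeSolver,
    VarianceComponents,
    estimate_bayesb,
    estimate_rrblup,
)
from .evaluate import ScenarioResult, accuracy, rank_correlation, regression_bias
from .genome_sim import SimulationConfig, simulate_dataset
from .mme import MMEProblem, gebv_from_effects, solve_mme_gauss_seidel
from .relmat import build_relationship, scheme_adhoc, scheme_g, scheme_tab, scheme_tap

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ExperimentPlan",
    "run_replicate",
    "run_scenario",
    "compare_methods",
    "scaled",
]

#: methods that require RRBLUP / BayesB marker-effect estimates
_NEEDS_RRBLUP = {"rrblup", "tap", "tap_adhoc"}
_NEEDS_BAYESB = {"bayesb", "tab", "tab_adhoc"}
_MME_METHODS = {"gblup", "tab", "tap", "tab_adhoc", "tap_adhoc"}
KNOWN_METHODS = _NEEDS_RRBLUP | _NEEDS_BAYESB | {"gblup"}


@dataclass
class ScenarioConfig:
    """One cell of the experiment grid.

    ``method_generations`` optionally restricts the generations a
    method is evaluated in (default 2..6); MME-based methods include
    generation 1 plus exactly the generations they are evaluated in,
    which leaves their predictions unchanged (BLUP is invariant to
    dropping unphenotyped individuals) while keeping the matrix small.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    methods: tuple[str, ...] = ("bayesb", "rrblup", "gblup", "tab", "tap")
    bayesb: BayesBConfig | None = None  # None -> paper chain, pi_in = n_qtl/N
    method_generations: dict[str, tuple[int, ...]] | None = None
    mme_tol: float = 1e-8
    mme_max_iter: int = 10_000
    mme_jitter: float = 0.0  # diagonal ridge for deliberately tiny panels
    #: evaluate each candidate generation on a random subset of this size
    #: (None = all 1,000); the estimated correlation targets the same
    #: population quantity, only with more sampling noise, while the
    #: per-generation MME shrinks accordingly.
    candidate_subsample: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.methods) - KNOWN_METHODS
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def generations_for(self, method: str) -> tuple[int, ...]:
        default = tuple(range(2, self.sim.n_validation_generations + 1))
        if self.method_generations is None:
            return default
        return tuple(self.method_generations.get(method, default))

    def bayesb_config(self, n_markers: int) -> BayesBConfig:
        if self.bayesb is not None:
            return self.bayesb
        return BayesBConfig(pi_in=self.sim.n_qtl / n_markers)


@dataclass
class ExperimentPlan:
    """A grid of scenarios sharing replicate count and master seed."""

    scenarios: dict[str, ScenarioConfig]
    n_replicates: int = 10
    master_seed: int = 0

    def run(self) -> dict[str, ScenarioResult]:
        return {
            name: run_scenario(cfg, self.n_replicates, self.master_seed)
            for name, cfg in self.scenarios.items()
        }


def scaled(cfg: ScenarioConfig, factor: float) -> ScenarioConfig:
    """Jointly shrink marker count, historical depth and chain length.

    One multiplier keeps desk-scale runs internally consistent; the
    full-scale defaults are recovered at factor 1.
    """
    if not 0 < factor <= 1:
        raise ValueError("scale factor must be in (0, 1]")
    sim = dataclasses.replace(
        cfg.sim,
        markers_per_chromosome=max(2, round(cfg.sim.markers_per_chromosome * factor)),
        n_historical_generations=max(1, round(cfg.sim.n_historical_generations * factor)),
    )
    bb = cfg.bayesb or BayesBConfig()
    bb = dataclasses.replace(
        bb,
        n_cycles=max(10, round(bb.n_cycles * factor)),
        burn_in=max(1, round(bb.burn_in * factor)),
    )
    return dataclasses.replace(cfg, sim=sim, bayesb=bb)


def run_replicate(
    scenario: ScenarioConfig,
    seed: int | np.random.SeedSequence,
    return_artifacts: bool = False,
):
    """Run one replicate and return tidy metric records.

    With ``return_artifacts=True`` also returns the dataset, the
    estimated marker effects and the per-method GEBV vectors (indexed
    like the population), for diagnostics and equivalence checks.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_sim, s_mcmc, s_eval = ss.spawn(3)
    data = simulate_dataset(scenario.sim, s_sim)
    pop = data.pop
    Z = data.Z
    vc = VarianceComponents(scenario.sim.sigma_A2, scenario.sim.sigma_e2)
    train = pop.rows_of(1)
    y = pop.phenotypes[train]

    # evaluation rows per generation, shared across methods
    eval_rng = np.random.default_rng(s_eval)
    all_gens = sorted({g for m in scenario.methods for g in scenario.generations_for(m)})
    eval_rows: dict[int, np.ndarray] = {}
    for g in all_gens:
        rows_g = pop.rows_of(g)
        k = scenario.candidate_subsample
        if k is not None and g != 1 and k < rows_g.size:
            rows_g = np.sort(eval_rng.choice(rows_g, size=k, replace=False))
        eval_rows[g] = rows_g

    effects: dict[str, MarkerEffects] = {}
    if _NEEDS_RRBLUP & set(scenario.methods):
        solver = RidgeSolver(Z[train], vc)
        effects["rrblup"] = estimate_rrblup(y, Z[train], vc, solver=solver)
    if _NEEDS_BAYESB & set(scenario.methods):
        cfg = scenario.bayesb_config(Z.shape[1])
        effects["bayesb"] = estimate_bayesb(
            y, Z[train], vc, cfg, np.random.default_rng(s_mcmc)
        )

    rows_out: list[dict] = []
    gebvs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _evaluate(method: str, g: int, tbv: np.ndarray, gebv: np.ndarray) -> None:
        for metric, fn in (
            ("correlation", accuracy),
            ("rank_correlation", rank_correlation),
            ("regression", regression_bias),
        ):
            rows_out.append(
                {"method": method, "generation": g, "metric": metric,
                 "value": fn(tbv, gebv)}
            )

    def _scheme(method: str):
        if method == "gblup":
            return scheme_g()
        if method == "tap":
            return scheme_tap(effects["rrblup"])
        if method == "tab":
            return scheme_tab(effects["bayesb"])
        if method == "tap_adhoc":
            return scheme_adhoc(effects["rrblup"])
        return scheme_adhoc(effects["bayesb"])

    for method in scenario.methods:
        gens = scenario.generations_for(method)
        if method in ("rrblup", "bayesb"):
            rows = np.concatenate([eval_rows[g] for g in gens])
            res = gebv_from_effects(Z[rows], effects[method])
            for g in gens:
                mask = pop.generation[rows] == g
                _evaluate(method, g, pop.tbv[rows][mask], res.gebv[mask])
            gebvs[method] = (rows, res.gebv)
        else:
            # One MME per candidate generation (training + candidates).
            # BLUP predictions are invariant to dropping unphenotyped
            # individuals, and the weighted-IBS matrix has rank at most
            # n_markers + 1, so small systems keep it invertible.
            scheme = _scheme(method)
            parts_rows, parts_gebv = [], []
            for g in gens:
                rows = train if g == 1 else np.concatenate([train, eval_rows[g]])
                rm = build_relationship(
                    data.X[rows], scheme,
                    jitter=scenario.mme_jitter, ids=pop.ids[rows],
                )
                local_train = np.arange(train.size)
                problem = MMEProblem(y, local_train, rm, vc)
                res, _mu = solve_mme_gauss_seidel(
                    problem, tol=scenario.mme_tol, max_iter=scenario.mme_max_iter
                )
                mask = pop.generation[rows] == g
                _evaluate(method, g, pop.tbv[rows][mask], res.gebv[mask])
                parts_rows.append(rows[mask])
                parts_gebv.append(res.gebv[mask])
            gebvs[method] = (np.concatenate(parts_rows), np.concatenate(parts_gebv))

    records = pd.DataFrame(rows_out)
    if return_artifacts:
        return records, {"data": data, "effects": effects, "gebvs": gebvs}
    return records


def run_scenario(
    scenario: ScenarioConfig,
    n_replicates: int,
    master_seed: int | np.random.SeedSequence,
) -> ScenarioResult:
    """Run ``n_replicates`` independent replicates and pool the metrics.

    A failing replicate is logged with its cause and skipped; the
    remaining replicates still produce a result.
    """
    ss = (
        master_seed
        if isinstance(master_seed, np.random.SeedSequence)
        else np.random.SeedSequence(master_seed)
    )
    frames = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        try:
            rec = run_replicate(scenario, child)
        except Exception:  # noqa: BLE001 - isolate replicate failures
            logger.exception("replicate %d failed; continuing", rep)
            continue
        rec.insert(0, "replicate", rep)
        frames.append(rec)
    if not frames:
        raise RuntimeError("every replicate failed")
    return ScenarioResult(
        records=pd.concat(frames, ignore_index=True),
        scenario={"config": scenario, "n_replicates": n_replicates},
    )


def compare_methods(table: pd.DataFrame) -> dict:
    """Derived contrasts from a method x metric accuracy table.

    ``table`` is indexed by method with at least a ``correlation``
    column (a ``rank_correlation`` column enables the Pearson-minus-
    rank gap). Returns pairwise accuracy differences and the mean gap.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least two methods to compare")
    methods = list(table.index)
    acc = table["correlation"]
    diffs = {
        (m1, m2): float(acc[m1] - acc[m2])
        for i, m1 in enumerate(methods)
        for m2 in methods[i + 1 :]
    }
    out = {"accuracy_difference": diffs}
    if "rank_correlation" in table.columns:
        gap = table["correlation"] - table["rank_correlation"]
        out["pearson_minus_rank"] = gap.to_dict()
        out["pearson_minus_rank_mean"] = float(gap.mean())
    return out
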