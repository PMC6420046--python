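"""Replicated-simulation engine for nonresponse bias indices.

For an estimator w_hat of a target w the bias index is r = E(w_hat)/w,
estimated by averaging over independent replicates of the survey on one
fixed finite population (the design-based frame conditions on U, so the
truth is the population mean, not the superpopulation mean).  The
variance analogue is r_V = E(V_hat) / V_MC, the mean of the variance
estimates over the Monte Carlo variance of the point estimates.

Reproducibility contract: every replicate draws from a dedicated PCG64
stream seeded by SeedSequence(entropy=master_seed, spawn_key=(1,
cell_index, replicate_index)); the population uses spawn_key=(0,).
Identical (config, seed) therefore give bit-identical result tables.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import PhasePlan
from .errors import ConfigError, DomainError
from .estimators import (
    PhaseData,
    eb_estimate,
    hh_variance_estimate,
    impute_last_phase_nulls,
)
from .nonresponse import NonresponsePlan, run_survey
from .superpop import FinitePopulation, SuperpopulationModel, generate_population

__all__ = [
    "ScenarioConfig",
    "BiasIndexResult",
    "bias_index",
    "variance_bias_index",
    "run_scenario",
    "population_for",
    "parse_grid",
]


def parse_grid(spec) -> tuple[float, ...]:
    """Parse a grid given as list/tuple or as 'start(step)end' notation."""
    if isinstance(spec, str):
        m = re.fullmatch(r"\s*([\d.eE+-]+)\(([\d.eE+-]+)\)([\d.eE+-]+)\s*", spec)
        if not m:
            raise ConfigError(f"cannot parse grid spec {spec!r}")
        start, step, end = (float(g) for g in m.groups())
        if step <= 0:
            raise ConfigError("grid step must be positive")
        n = int(round((end - start) / step))
        return tuple(round(start + k * step, 12) for k in range(n + 1))
    if np.isscalar(spec):
        return (float(spec),)
    return tuple(float(v) for v in spec)


@dataclass(frozen=True)
class ScenarioConfig:
    """One Monte Carlo experiment: a fixed population, a design grid, and
    nonresponse propensities.

    Grid cells are the Cartesian product of ``L_grid`` x ``nu_grid`` x
    ``pi_z_grid`` x ``pi_m_last_grid``; within a cell the first L-1
    phases share ``pi_m_early`` and the last phase uses the grid value
    (for L = 1 the single phase uses the grid value directly).  ``nu``
    applies to every phase of the design (nu = nu_m, the setting of all
    the source experiments).
    """

    name: str = "scenario"
    N: int = 10_000
    p: float = 0.955
    lam: float = 7.0
    replicates: int = 1000
    seed: int = 0
    L_grid: tuple[int, ...] = (2,)
    nu_grid: tuple[float, ...] = (0.5,)
    pi_z_grid: tuple[float, ...] = (0.2,)
    pi_m_last_grid: tuple[float, ...] = (0.0,)
    pi_m_early: float = 0.85
    compute_variance: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "L_grid", tuple(int(v) for v in parse_grid(self.L_grid)))
        object.__setattr__(self, "nu_grid", parse_grid(self.nu_grid))
        object.__setattr__(self, "pi_z_grid", parse_grid(self.pi_z_grid))
        object.__setattr__(self, "pi_m_last_grid", parse_grid(self.pi_m_last_grid))
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.L_grid or not self.nu_grid or not self.pi_z_grid or not self.pi_m_last_grid:
            raise ConfigError("grids must be nonempty")
        for L in self.L_grid:
            if L < 1:
                raise ConfigError(f"L must be >= 1, got {L}")


@dataclass(frozen=True)
class BiasIndexResult:
    """A bias index with its Monte Carlo uncertainty."""

    estimator: str
    r: float
    se: float
    replicates: int
    truth: float
    clip_events: int = 0
    dropped: int = 0
    coords: dict = field(default_factory=dict)


def bias_index(estimates: Sequence[float], truth: float, estimator: str = "",
               **coords) -> BiasIndexResult:
    """Bias index r = mean(estimates)/truth with its MC standard error."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise DomainError("need at least one estimate")
    if truth == 0:
        raise DomainError("bias index undefined for a zero target")
    r = float(est.mean()) / truth
    if est.size >= 2:
        se = float(est.std(ddof=1)) / math.sqrt(est.size) / abs(truth)
    else:
        se = float("nan")
    return BiasIndexResult(
        estimator=estimator, r=r, se=se, replicates=int(est.size), truth=truth,
        coords=coords,
    )


def variance_bias_index(
    variance_estimates: Sequence[float], point_estimates: Sequence[float]
) -> tuple[float, float]:
    """r_V = mean(V_hat) / V_MC with a delta-method standard error.

    ``V_MC`` is the empirical (ddof=1) variance of the point estimates.
    The SE accounts for noise in both numerator and denominator,
    including their covariance across replicates.
    """
    v = np.asarray(variance_estimates, dtype=float)
    x = np.asarray(point_estimates, dtype=float)
    if v.size < 2 or x.size < 2:
        raise DomainError("need at least two replicates")
    v_mc = float(x.var(ddof=1))
    if v_mc == 0.0:
        raise DomainError("zero Monte Carlo variance of the point estimates")
    r_v = float(v.mean()) / v_mc
    # delta method on the ratio of means of (v_i, d_i=(x_i - xbar)^2)
    n = x.size
    d = (x - x.mean()) ** 2
    vbar, dbar = v.mean(), d.mean()
    var_v = v.var(ddof=1)
    var_d = d.var(ddof=1)
    cov_vd = float(np.cov(v, d, ddof=1)[0, 1])
    se2 = (var_v / dbar**2 + vbar**2 * var_d / dbar**4
           - 2.0 * vbar * cov_vd / dbar**3) / n
    return r_v, math.sqrt(max(se2, 0.0))


def population_for(config: ScenarioConfig) -> FinitePopulation:
    """The scenario's fixed finite population (spawn_key=(0,) stream)."""
    model = SuperpopulationModel(p=config.p, lam=config.lam)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    return generate_population(config.N, model, rng)


def _rep_rng(seed: int, cell: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, cell, rep))
    )


def _empty_phase(i: int) -> PhaseData:
    return PhaseData(i=i, n_s=0, n_r=0, n_m=0, y_r=np.empty(0))


def simulate_cell(
    pop: FinitePopulation,
    L: int,
    nu: float,
    pi_m_last: float,
    pi_z: float,
    pi_m_early: float,
    replicates: int,
    seed: int,
    cell_index: int,
    compute_variance: bool = False,
) -> dict:
    """Run one grid cell: replicate point (and optional variance) estimates.

    Returns raw per-replicate arrays plus the clip/drop counters so
    callers can form any bias index.
    """
    plan = PhasePlan.uniform(nu, L)
    if L == 1:
        pi_m = (pi_m_last,)
    else:
        pi_m = (pi_m_early,) * (L - 1) + (pi_m_last,)
    nrplan = NonresponsePlan(pi_m=pi_m, pi_z=(pi_z,) * L)

    points = np.empty(replicates)
    variances = np.empty(replicates) if compute_variance else None
    clip_events = 0
    dropped = 0
    for rep in range(replicates):
        rng = _rep_rng(seed, cell_index, rep)
        real = run_survey(pop, plan, nrplan, rng)
        clip_events += 1 if real.clip_events else 0
        pd_list = real.phase_data()
        if L == 1:
            ph = pd_list[0]
            point = ph.ybar_r if ph.n_r else float("nan")
            var = float("nan")
        elif len(pd_list) == 1:
            # nonrespondents exhausted at phase 1: SRSWOR with full response
            point = pd_list[0].ybar_r
            var = (
                hh_variance_estimate(pd_list[0], _empty_phase(2), pop.N)
                if compute_variance
                else float("nan")
            )
        else:
            # the study convention: final-phase nonrespondents are scored
            # as null harvest (the formulas assume n_rL = n_sL)
            if len(pd_list) == L:
                pd_list[-1] = impute_last_phase_nulls(pd_list[-1])
            res = eb_estimate(pd_list, pop.N, with_variance=False)
            point = res.mean_hat
            if compute_variance:
                if L == 2:
                    p2 = pd_list[1] if len(pd_list) > 1 else _empty_phase(2)
                    var = hh_variance_estimate(pd_list[0], p2, pop.N)
                else:
                    from .estimators import eb_variance_estimate

                    var = eb_variance_estimate(pd_list, pop.N) / pop.N**2
            else:
                var = float("nan")
        if math.isnan(point):
            dropped += 1
        points[rep] = point
        if compute_variance:
            variances[rep] = var
    return {
        "points": points,
        "variances": variances,
        "clip_events": clip_events,
        "dropped": dropped,
    }


def run_scenario(config: ScenarioConfig) -> pd.DataFrame:
    """Run the full grid of a scenario and tabulate bias indices.

    One row per grid cell, long format; when ``compute_variance`` is set
    the r_V columns are filled for L >= 2 cells.
    """
    pop = population_for(config)
    truth = pop.ybar
    rows = []
    cells = list(
        itertools.product(
            config.L_grid, config.nu_grid, config.pi_z_grid, config.pi_m_last_grid
        )
    )
    for cell_index, (L, nu, pi_z, pi_m_last) in enumerate(cells):
        out = simulate_cell(
            pop,
            L,
            nu,
            pi_m_last,
            pi_z,
            config.pi_m_early,
            config.replicates,
            config.seed,
            cell_index,
            compute_variance=config.compute_variance and L >= 2,
        )
        pts = out["points"]
        ok = ~np.isnan(pts)
        name = "ybar_r" if L == 1 else ("ybar_HH" if L == 2 else "ybar_EB")
        res = bias_index(pts[ok], truth, estimator=name)
        row = {
            "scenario": config.name,
            "L": L,
            "nu": nu,
            "pi_z": pi_z,
            "pi_m_last": pi_m_last,
            "pi_m_early": config.pi_m_early if L > 1 else float("nan"),
            "estimator": name,
            "r": res.r,
            "se": res.se,
            "replicates": int(ok.sum()),
            "dropped": out["dropped"],
            "clip_events": out["clip_events"],
            "truth_mean": truth,
            "seed": config.seed,
        }
        if out["variances"] is not None:
            var = out["variances"]
            good = ~np.isnan(var) & ok
            if good.sum() >= 2:
                r_v, se_v = variance_bias_index(var[good], pts[good])
                row["r_V"] = r_v
                row["se_rV"] = se_v
                row["V_MC"] = float(pts[good].var(ddof=1))
                row["mean_Vhat"] = float(var[good].mean())
        rows.append(row)
    return pd.DataFrame(rows)
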