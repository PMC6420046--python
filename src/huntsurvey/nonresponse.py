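"""Null-harvest nonresponse mechanism and the multiphase survey driver.

The mechanism models the dominant, nonignorable cause of nonresponse in
hunting-bag surveys: hunters with a null bag are disproportionately
likely not to return the questionnaire.  Two propensities drive it:
``pi_m``, the overall propensity to nonrespond, and ``pi_z``, the
propensity among nonrespondents to nonrespond *because* the bag was
zero.  For each pool the mechanism realizes a respondent set R and a
nonrespondent set M containing a subset Z of zero-bag units:

1. draw N_M with E(N_M) = n*pi_m (randomized rounding),
2. N_R = n - N_M,
3. draw N_Z with E(N_Z) = n*pi_z*pi_m, clipped to min(N_M, #zero bags),
4. Z = SRSWOR of the pool's zero-bag units, size N_Z,
5-6. R = SRSWOR of size N_R from C = pool - Z,
7. M = pool - R  (so Z is always inside M).

Undercovering the zero-bag stratum in R inflates the respondent mean;
with pi_z = 0 the mechanism is MCAR and ignorable.  The multiphase
driver applies the mechanism afresh at every phase, sampling each wave
from the previous wave's nonrespondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .designs import PhasePlan, randomized_round, srswor
from .errors import ConfigError, DomainError
from .estimators import PhaseData
from .superpop import FinitePopulation

__all__ = [
    "NonresponsePlan",
    "PartitionRealization",
    "SurveyRealization",
    "partition_pool",
    "apply_sample",
    "run_survey",
    "write_survey_tables",
]


@dataclass(frozen=True)
class NonresponsePlan:
    """Per-phase nonresponse propensities.

    ``pi_m[i]`` is the nonresponse propensity at phase i+1; ``pi_z`` is
    shared by all phases unless given per phase.
    """

    pi_m: tuple[float, ...]
    pi_z: tuple[float, ...]

    def __post_init__(self) -> None:
        pi_m = tuple(float(v) for v in self.pi_m)
        pi_z = tuple(float(v) for v in self.pi_z)
        if len(pi_z) == 1 and len(pi_m) > 1:
            pi_z = pi_z * len(pi_m)
        if len(pi_z) != len(pi_m):
            raise DomainError(
                f"{len(pi_m)} pi_m values but {len(pi_z)} pi_z values"
            )
        for v in pi_m:
            if not 0.0 <= v < 1.0:
                raise DomainError(f"pi_m must lie in [0, 1), got {v}")
        for v in pi_z:
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"pi_z must lie in [0, 1], got {v}")
        object.__setattr__(self, "pi_m", pi_m)
        object.__setattr__(self, "pi_z", pi_z)

    @property
    def L(self) -> int:
        return len(self.pi_m)

    @classmethod
    def constant(cls, pi_m: Sequence[float] | float, pi_z: float, L: int | None = None
                 ) -> "NonresponsePlan":
        if np.isscalar(pi_m):
            if L is None:
                raise ConfigError("L is required when pi_m is scalar")
            pi_m = (float(pi_m),) * L
        return cls(pi_m=tuple(pi_m), pi_z=(float(pi_z),))


@dataclass(frozen=True)
class PartitionRealization:
    """One realization of the respondent/nonrespondent split of a pool."""

    R: np.ndarray
    M: np.ndarray
    Z: np.ndarray
    n_clipped: int  # amount removed from N_Z by the feasibility clip
    _R_mask: np.ndarray = field(repr=False)
    _Z_mask: np.ndarray = field(repr=False)

    @property
    def N_R(self) -> int:
        return int(self.R.size)

    @property
    def N_M(self) -> int:
        return int(self.M.size)

    @property
    def N_Z(self) -> int:
        return int(self.Z.size)


@dataclass(frozen=True)
class SamplePhase:
    """A sampled phase: the drawn sample and its response partition."""

    s: np.ndarray
    r: np.ndarray
    m: np.ndarray
    z: np.ndarray


@dataclass(frozen=True)
class SurveyRealization:
    """Per-phase survey outcome of one multiphase replicate."""

    pop: FinitePopulation
    plan: PhasePlan
    nrplan: NonresponsePlan
    phases: tuple[SamplePhase, ...]
    clip_events: int

    def phase_data(self) -> list[PhaseData]:
        """Assemble the estimator-facing records (sizes + respondent bags)."""
        y = self.pop.y
        out = []
        for i, ph in enumerate(self.phases, start=1):
            out.append(
                PhaseData(
                    i=i,
                    n_s=ph.s.size,
                    n_r=ph.r.size,
                    n_m=ph.m.size,
                    y_r=y[ph.r].astype(float),
                )
            )
        return out


def partition_pool(
    pool: np.ndarray,
    y: np.ndarray,
    pi_m: float,
    pi_z: float,
    rng: np.random.Generator,
) -> PartitionRealization:
    """Realize the respondent/nonrespondent partition of ``pool``.

    ``y`` is the full population bag array (indexed by the unit ids in
    ``pool``).  Infeasible N_Z draws are clipped to min(N_M, #zero-bag
    units) and the clipped amount is reported.
    """
    pool = np.asarray(pool)
    n = pool.size
    if n == 0:
        raise DomainError("cannot partition an empty pool")
    n_m = randomized_round(n * pi_m, rng)
    n_r = n - n_m
    n_z = randomized_round(n * pi_z * pi_m, rng)
    zero_pool = pool[y[pool] == 0]
    n_z_feasible = min(n_z, n_m, zero_pool.size)
    clipped = n_z - n_z_feasible

    size = y.size
    z = srswor(zero_pool, n_z_feasible, rng)
    z_mask = np.zeros(size, dtype=bool)
    z_mask[z] = True
    c = pool[~z_mask[pool]]
    r = srswor(c, n_r, rng)
    r_mask = np.zeros(size, dtype=bool)
    r_mask[r] = True
    m = pool[~r_mask[pool]]
    return PartitionRealization(
        R=r, M=m, Z=z, n_clipped=clipped, _R_mask=r_mask, _Z_mask=z_mask
    )


def apply_sample(
    pool: np.ndarray,
    partition: PartitionRealization,
    n_s: int,
    rng: np.random.Generator,
) -> SamplePhase:
    """Draw the phase sample and intersect it with the partition."""
    s = srswor(np.asarray(pool), n_s, rng)
    in_r = partition._R_mask[s]
    r = s[in_r]
    m = s[~in_r]
    z = s[partition._Z_mask[s]]
    return SamplePhase(s=s, r=r, m=m, z=z)


def run_survey(
    pop: FinitePopulation,
    plan: PhasePlan,
    nrplan: NonresponsePlan,
    rng: np.random.Generator,
) -> SurveyRealization:
    """Simulate one replicate of the L-phase survey on a fixed population.

    Phase i samples the nonrespondents of phase i-1 (phase 1 samples U)
    with target size ``|pool| * nu_i`` materialized by randomized
    rounding; the nonresponse mechanism is redrawn independently on each
    pool.  Phases whose pool is exhausted are simply absent.
    """
    if plan.L != nrplan.L:
        raise ConfigError(
            f"phase plan has L={plan.L} but nonresponse plan has L={nrplan.L}"
        )
    y = pop.y
    pool = np.arange(pop.N)
    phases: list[SamplePhase] = []
    clip_events = 0
    for i in range(plan.L):
        if pool.size == 0:
            break
        part = partition_pool(pool, y, nrplan.pi_m[i], nrplan.pi_z[i], rng)
        if part.n_clipped:
            clip_events += 1
        n_s = randomized_round(pool.size * plan.nu[i], rng)
        phase = apply_sample(pool, part, n_s, rng)
        phases.append(phase)
        pool = phase.m
    return SurveyRealization(
        pop=pop, plan=plan, nrplan=nrplan, phases=tuple(phases), clip_events=clip_events
    )


def write_survey_tables(
    realization: SurveyRealization, respondents_path: str | Path, summary_path: str | Path
) -> None:
    """Export a realization in the delimited format the estimators read.

    ``respondents_path``: columns (phase, unit_id, bag) for every
    respondent; ``summary_path``: columns (phase, n_s, n_r, n_m).
    """
    y = realization.pop.y
    rows = []
    for i, ph in enumerate(realization.phases, start=1):
        for k in ph.r:
            rows.append((i, int(k), int(y[k])))
    pd.DataFrame(rows, columns=["phase", "unit_id", "bag"]).to_csv(
        respondents_path, index=False
    )
    summary = pd.DataFrame(
        [
            (i, ph.s.size, ph.r.size, ph.m.size)
            for i, ph in enumerate(realization.phases, start=1)
        ],
        columns=["phase", "n_s", "n_r", "n_m"],
    )
    summary.to_csv(summary_path, index=False)
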