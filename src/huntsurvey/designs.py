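"""Equal-probability sampling primitives.

Two building blocks recur through the multiphase strategy: simple random
sampling without replacement (SRSWOR) and the randomized rounding of
non-integer expected sample sizes.  Each wave samples a fraction nu_i of
the previous wave's nonrespondents, so the target size n_si = n_m(i-1)*nu_i
is generally non-integer; drawing the realized size from the two-point
distribution on {floor, floor+1} keeps its expectation exactly on target,
which matters for the unbiasedness of the replicated simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SizeError

__all__ = ["PhasePlan", "randomized_round", "srswor"]


@dataclass(frozen=True)
class PhasePlan:
    """Per-phase sampling fractions nu_1..nu_L of a multiphase design.

    ``nu[0]`` applies to the whole population; ``nu[i]`` (i >= 1) applies
    to the nonrespondents of wave i.  ``L = 1`` is plain uni-phase SRSWOR;
    otherwise the design has ``ell = L - 1`` mailing waves followed by a
    final interview phase.
    """

    nu: tuple[float, ...]

    def __post_init__(self) -> None:
        nu = tuple(float(v) for v in self.nu)
        if len(nu) < 1:
            raise DomainError("a phase plan needs at least one sampling fraction")
        for v in nu:
            if not 0.0 < v <= 1.0:
                raise DomainError(f"sampling fractions must lie in (0, 1], got {v}")
        object.__setattr__(self, "nu", nu)

    @property
    def L(self) -> int:
        return len(self.nu)

    @property
    def ell(self) -> int:
        """Number of mailing waves (L - 1 for multiphase, 0 for uni-phase)."""
        return self.L - 1

    @classmethod
    def uniform(cls, nu: float, L: int) -> "PhasePlan":
        """Same fraction at every phase (the common simulation setting)."""
        return cls(nu=(nu,) * L)


def randomized_round(alpha: float, rng: np.random.Generator) -> int:
    """Round a non-negative expected size to an integer without bias.

    Returns ``floor(alpha) + 1`` with probability ``omega = alpha -
    floor(alpha)`` and ``floor(alpha)`` otherwise, so the result has mean
    ``alpha`` and variance ``omega * (1 - omega)``.
    """
    if alpha < 0:
        raise DomainError(f"expected size must be non-negative, got {alpha}")
    base = math.floor(alpha)
    omega = alpha - base
    if omega == 0.0:
        return base
    return base + int(rng.random() < omega)


def srswor(pool: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniformly random n-subset of ``pool`` (unit indices).

    Every unit's inclusion probability is ``n / len(pool)``.
    """
    pool = np.asarray(pool)
    if not 0 <= n <= pool.size:
        raise SizeError(f"cannot draw {n} units from a pool of {pool.size}")
    if n == pool.size:
        return pool.copy()
    if n == 0:
        return pool[:0].copy()
    return rng.choice(pool, size=n, replace=False, shuffle=False)
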