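"""Hurdle-at-zero Poisson superpopulation model and finite-population generator.

Individual hunting bags are counts with a large excess of zeros: most
licence holders harvest nothing for a given species while the active,
successful minority follows a Poisson-like distribution. The hurdle model
puts a point mass ``p`` at zero and rescales a Poisson(lambda) over the
positive counts:

    Pr(Y = 0) = p
    Pr(Y = y) = phi * exp(-lambda) * lambda**y / y!   for y = 1, 2, ...

with hurdle factor ``phi = (1 - p) / (1 - exp(-lambda))``.  Mean and
variance are ``mu = phi*lambda`` and ``mu2 = phi*lambda*(1+lambda) -
(phi*lambda)**2``.  ``phi = 1`` (i.e. ``p = exp(-lambda)``) recovers the
plain Poisson.

A finite population of N hunters is obtained by i.i.d. sampling from the
model; all design-based quantities downstream condition on that fixed
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize, special, stats

from .errors import DomainError

__all__ = [
    "SuperpopulationModel",
    "FinitePopulation",
    "solve_lambda",
    "hurdle_pmf",
    "hurdle_moments",
    "generate_population",
]


@dataclass(frozen=True)
class SuperpopulationModel:
    """Hurdle-at-zero Poisson model with null-bag probability ``p`` and
    positive-part Poisson rate ``lam``."""

    p: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DomainError(f"p must lie in [0, 1], got {self.p}")
        if self.lam <= 0.0:
            raise DomainError(f"lam must be positive, got {self.lam}")

    @property
    def phi(self) -> float:
        """Hurdle factor (1 - p) / (1 - exp(-lam))."""
        return (1.0 - self.p) / (-np.expm1(-self.lam))

    @property
    def mu(self) -> float:
        """Model mean phi * lam."""
        return self.phi * self.lam

    @property
    def mu2(self) -> float:
        """Model variance phi*lam*(1 + lam) - (phi*lam)**2."""
        phi_lam = self.phi * self.lam
        return phi_lam * (1.0 + self.lam) - phi_lam * phi_lam

    @classmethod
    def from_mean(cls, mu: float, p: float) -> "SuperpopulationModel":
        """Build the model from its mean, inverting mu = phi*lam for lam."""
        return cls(p=p, lam=solve_lambda(mu, p))

    def pmf(self, y) -> np.ndarray | float:
        return hurdle_pmf(y, self)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` i.i.d. bags.

        Zeros occur with probability ``p``; positive bags come from the
        zero-truncated Poisson via exact inverse-CDF transform.
        """
        u = rng.random(size)
        y = np.zeros(size, dtype=np.int64)
        pos = u >= self.p
        n_pos = int(pos.sum())
        if n_pos:
            e = np.exp(-self.lam)
            v = rng.random(n_pos)
            # map v uniformly onto the Poisson CDF above the zero atom
            y[pos] = stats.poisson.ppf(e + v * (1.0 - e), self.lam).astype(np.int64)
        return y


def solve_lambda(mu: float, p: float) -> float:
    """Recover the Poisson rate lambda from the model mean.

    Inverts the transcendental equation ``mu = lam*(1-p)/(1-exp(-lam))``
    through the closed form ``lam = W0(D*exp(D)) - D`` with
    ``D = mu/(p-1)`` and W0 the upper Lambert branch.  A Brent bisection
    on the original equation backs the closed form up whenever the W
    evaluation is numerically borderline; the two must agree to 1e-8.

    Raises
    ------
    DomainError
        If ``p`` is not interior to (0, 1), ``mu`` is not positive, or
        ``mu <= 1 - p`` (no positive root exists: the mean of the hurdle
        model is bounded below by 1 - p since every positive bag is >= 1).
    """
    if not 0.0 < p < 1.0:
        raise DomainError(f"p must lie in (0, 1) to solve for lambda, got {p}")
    if mu <= 0.0:
        raise DomainError(f"mu must be positive, got {mu}")
    if mu <= 1.0 - p:
        raise DomainError(
            f"mu={mu} is infeasible for p={p}: the hurdle mean exceeds 1-p={1.0 - p} "
            "for every positive lambda"
        )
    d = mu / (p - 1.0)  # d < -1 on the feasible domain
    w = special.lambertw(d * np.exp(d), k=0)
    lam = float(np.real(w)) - d

    def residual(la: float) -> float:
        return la * (1.0 - p) / (-np.expm1(-la)) - mu

    if not np.isfinite(lam) or lam <= 0.0 or abs(residual(lam)) > 1e-10 * mu:
        # bracket: mean is increasing in lambda, lower bound just above 0
        hi = max(2.0 * mu / (1.0 - p), 1.0)
        while residual(hi) < 0.0:
            hi *= 2.0
        lam_bis = optimize.brentq(residual, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
        if np.isfinite(lam) and lam > 0.0 and abs(lam - lam_bis) > 1e-8 * max(1.0, lam_bis):
            raise DomainError(
                f"Lambert-W and bisection solutions disagree: {lam} vs {lam_bis}"
            )
        lam = lam_bis
    return lam


def hurdle_pmf(y, model: SuperpopulationModel) -> np.ndarray | float:
    """Probability mass of the hurdle model at the count(s) ``y``."""
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.issubdtype(y_arr.dtype, np.integer) and np.any(
        y_arr != np.floor(y_arr)
    ):
        raise DomainError("bag counts must be non-negative integers")
    out = np.where(
        y_arr == 0,
        model.p,
        model.phi * stats.poisson.pmf(y_arr, model.lam),
    )
    return float(out) if np.isscalar(y) else out


def hurdle_moments(model: SuperpopulationModel) -> tuple[float, float]:
    """Return the model mean and variance ``(mu, mu2)``."""
    return model.mu, model.mu2


@dataclass(frozen=True)
class FinitePopulation:
    """A fixed population of N integer bag counts with derived summaries."""

    y: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int64)
        if y.ndim != 1 or y.size < 1:
            raise DomainError("population must be a non-empty 1-d array of counts")
        if np.any(y < 0):
            raise DomainError("bag counts must be non-negative")
        object.__setattr__(self, "y", y)

    @property
    def N(self) -> int:
        return int(self.y.size)

    @property
    def N0(self) -> int:
        """Number of hunters with a null bag."""
        return int(np.count_nonzero(self.y == 0))

    @property
    def W0(self) -> float:
        return self.N0 / self.N

    @property
    def ybar(self) -> float:
        return float(self.y.mean())

    @property
    def total(self) -> int:
        return int(self.y.sum())

    @property
    def S2(self) -> float:
        """Population dispersion with the 1/(N-1) convention."""
        if self.N < 2:
            return float("nan")
        return float(self.y.var(ddof=1))

    # -- serialization: one bag per line + key-value sidecar ---------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.y, fmt="%d")
        sidecar = {"N": self.N, **self.meta}
        Path(str(path) + ".meta.yaml").write_text(
            yaml.safe_dump(sidecar, sort_keys=False)
        )

    @classmethod
    def load(cls, path: str | Path) -> "FinitePopulation":
        path = Path(path)
        y = np.loadtxt(path, dtype=np.int64, ndmin=1)
        meta_path = Path(str(path) + ".meta.yaml")
        meta = {}
        if meta_path.exists():
            meta = yaml.safe_load(meta_path.read_text()) or {}
            meta.pop("N", None)
        return cls(y=y, meta=meta)


def generate_population(
    N: int, model: SuperpopulationModel, rng: np.random.Generator
) -> FinitePopulation:
    """Draw one finite population of ``N`` i.i.d. bags from ``model``."""
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    y = model.rvs(N, rng)
    return FinitePopulation(y=y, meta={"p": model.p, "lam": model.lam})
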