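"""Design-based estimation for nonrespondent-subsampling designs.

Two-phase design (Hansen & Hurwitz): a first SRSWOR sample s1 splits into
respondents r1 and nonrespondents m1; an SRSWOR subsample s2 of m1 is
followed up by interview.  The population mean is estimated by

    ybar_HH = (n_r1 * ybar_r1 + n_m1 * ybar_r2) / n_s1

which weights each respondent group by the estimated size of the stratum
it represents.  The general L-phase (El-Badry) design iterates the
subsampling over ell mailing waves plus a final interview phase; the
estimator in sample-size form is

    t_EB = sum_{i=1}^{ell} n_ri * ybar_ri * prod_{j<=i} (n_m(j-1)/n_sj)
           + n_mell * ybar_rL * prod_{j<=ell} (n_m(j-1)/n_sj)

with n_m0 = N.  Both are design-unbiased exactly when the response rate
at the last phase is 100%.

Three distinct products all written "Pi_i" in the source literature are
kept apart here:

* forward-fraction product  prod_{j<=i} nu_j          (stratum weights),
* inverse-fraction product  prod_{j<i} 1/nu_j         (theoretical variance),
* size-ratio products       prod (n_m(j-1)*(n_m(j-1)-1))/(n_sj*(n_sj-1))
                            and prod n_m(j-1)/n_sj    (variance estimator /
                                                       point estimator).

Variance formulas use the 1/(N-1) dispersion convention throughout.
Degenerate sizes (a dispersion term with fewer than two contributing
units) make the variance estimate undefined: NaN is returned with a
DegenerateSizeWarning, never a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .designs import PhasePlan
from .errors import (
    ConsistencyError,
    DegenerateSizeWarning,
    DomainError,
    EstimationError,
)

__all__ = [
    "PhaseData",
    "EstimateResult",
    "StrataSummary",
    "impute_last_phase_nulls",
    "read_survey_tables",
    "write_estimate_record",
    "hh_estimate",
    "hh_variance_true",
    "hh_variance_estimate",
    "eb_estimate",
    "eb_variance_true",
    "eb_variance_estimate",
    "nrbias_theoretical",
    "nrbias_index_theoretical",
]


@dataclass(frozen=True)
class PhaseData:
    """Observed outcome of one survey phase: sizes and respondent bags."""

    i: int
    n_s: int
    n_r: int
    n_m: int
    y_r: np.ndarray

    def __post_init__(self) -> None:
        y_r = np.asarray(self.y_r, dtype=float)
        object.__setattr__(self, "y_r", y_r)
        if self.n_s != self.n_r + self.n_m:
            raise ConsistencyError(
                f"phase {self.i}: n_s={self.n_s} != n_r+n_m={self.n_r + self.n_m}"
            )
        if y_r.size != self.n_r:
            raise ConsistencyError(
                f"phase {self.i}: {y_r.size} respondent bags for n_r={self.n_r}"
            )
        if np.any(y_r < 0):
            raise DomainError(f"phase {self.i}: negative bag counts")

    @property
    def ybar_r(self) -> float:
        """Respondent mean; NaN when there are no respondents."""
        return float(self.y_r.mean()) if self.n_r else float("nan")

    @property
    def s2_r(self) -> float:
        """Respondent dispersion, 1/(n_r - 1) convention; NaN if n_r < 2."""
        return float(self.y_r.var(ddof=1)) if self.n_r >= 2 else float("nan")


@dataclass(frozen=True)
class EstimateResult:
    """Point and variance estimates with per-phase bookkeeping."""

    mean_hat: float
    total_hat: float
    var_hat_total: float
    var_hat_mean: float
    phase_weights: tuple[float, ...]
    N: int
    L: int

    @property
    def se_total(self) -> float:
        return float(np.sqrt(self.var_hat_total))

    @property
    def se_mean(self) -> float:
        return float(np.sqrt(self.var_hat_mean))

    def to_record(self) -> dict:
        rec = {
            "N": self.N,
            "L": self.L,
            "mean_hat": self.mean_hat,
            "total_hat": self.total_hat,
            "var_hat_mean": self.var_hat_mean,
            "var_hat_total": self.var_hat_total,
            "se_mean": self.se_mean,
            "se_total": self.se_total,
        }
        for i, w in enumerate(self.phase_weights, start=1):
            rec[f"W_hat_R{i}"] = w
        return rec


@dataclass(frozen=True)
class StrataSummary:
    """Population-level summaries of the nested nonrespondent strata.

    ``M_0 = U`` and ``M_i`` nests inside ``M_(i-1)``; index ``i`` of each
    array refers to stratum ``M_i``.  Used only in simulation, where the
    would-be response strata are known.
    """

    N_M: tuple[int, ...]
    ybar_M: tuple[float, ...]
    S2_M: tuple[float, ...]

    @property
    def N(self) -> int:
        return self.N_M[0]

    @property
    def W_M(self) -> tuple[float, ...]:
        return tuple(n / self.N for n in self.N_M)

    @classmethod
    def from_nested_strata(
        cls, y: np.ndarray, M_sets: Sequence[np.ndarray]
    ) -> "StrataSummary":
        """Build from the full bag array and index sets M_0=U, M_1, ..."""
        y = np.asarray(y, dtype=float)
        N_M, ybar, s2 = [], [], []
        for m in M_sets:
            ym = y[np.asarray(m)]
            N_M.append(int(ym.size))
            ybar.append(float(ym.mean()) if ym.size else float("nan"))
            s2.append(float(ym.var(ddof=1)) if ym.size >= 2 else float("nan"))
        return cls(N_M=tuple(N_M), ybar_M=tuple(ybar), S2_M=tuple(s2))


def _check_nesting(phases: Sequence[PhaseData]) -> None:
    for a, b in zip(phases, phases[1:]):
        if b.n_s > a.n_m:
            raise ConsistencyError(
                f"phase {b.i}: sample of {b.n_s} drawn from only {a.n_m} "
                f"nonrespondents of phase {a.i}"
            )


# ---------------------------------------------------------------------------
# Two-phase (Hansen-Hurwitz)
# ---------------------------------------------------------------------------


def hh_estimate(phase1: PhaseData, phase2: PhaseData, N: int) -> EstimateResult:
    """Hansen-Hurwitz mean/total estimate for the two-phase design."""
    if phase1.n_s < 1:
        raise EstimationError("empty first-phase sample")
    _check_nesting([phase1, phase2])
    term_r = phase1.n_r * phase1.ybar_r if phase1.n_r else 0.0
    term_m = phase1.n_m * phase2.ybar_r if phase1.n_m else 0.0
    if phase1.n_m and phase2.n_r == 0:
        term_m = 0.0  # no follow-up data: the stratum term cannot be evaluated
    mean_hat = (term_r + term_m) / phase1.n_s
    var_mean = hh_variance_estimate(phase1, phase2, N)
    w_r = phase1.n_r / phase1.n_s
    w_m = phase1.n_m / phase1.n_s
    return EstimateResult(
        mean_hat=mean_hat,
        total_hat=N * mean_hat,
        var_hat_mean=var_mean,
        var_hat_total=N * N * var_mean,
        phase_weights=(w_r, w_m),
        N=N,
        L=2,
    )


def hh_variance_true(
    strata: StrataSummary, S2: float, n_s1: int, N: int, nu_m: float
) -> float:
    """Theoretical sampling variance of the HH mean estimator.

    ``(1/n_s1 - 1/N) S^2 + (1/n_s1) (1/nu_m - 1) W_M S_M^2`` where the
    nonrespondent stratum M is ``M_1`` of ``strata``.  Simulation use
    only (requires the full-population strata).
    """
    if not 0.0 < nu_m <= 1.0:
        raise DomainError(f"nu_m must lie in (0, 1], got {nu_m}")
    w_m = strata.W_M[1]
    s2_m = strata.S2_M[1] if w_m > 0 else 0.0
    return (1.0 / n_s1 - 1.0 / N) * S2 + (1.0 / n_s1) * (1.0 / nu_m - 1.0) * w_m * s2_m


def hh_variance_estimate(phase1: PhaseData, phase2: PhaseData, N: int) -> float:
    """Unbiased estimator of the sampling variance of the HH mean.

    Nonnegative, and unbiased when the follow-up phase has full response.
    Requires n_s1 >= 2 and at least two units behind each dispersion term
    actually used; otherwise NaN with a DegenerateSizeWarning.
    """
    n_s1, n_r1, n_m1 = phase1.n_s, phase1.n_r, phase1.n_m
    n_r2 = phase2.n_r
    if n_s1 < 2:
        warnings.warn(
            f"variance estimate undefined: n_s1={n_s1} < 2", DegenerateSizeWarning
        )
        return float("nan")
    if n_r1 == 0 or (n_m1 > 0 and n_r2 == 0):
        warnings.warn(
            "variance estimate undefined: a stratum mean has no respondents",
            DegenerateSizeWarning,
        )
        return float("nan")
    w_r = n_r1 / n_s1
    w_m = n_m1 / n_s1
    mean_hat = (
        n_r1 * phase1.ybar_r + (n_m1 * phase2.ybar_r if n_m1 else 0.0)
    ) / n_s1

    # within-r1 dispersion term
    if n_r1 >= 2:
        s2_r1 = phase1.s2_r
    elif n_r1 == 1:
        warnings.warn(
            "variance estimate undefined: single respondent at phase 1",
            DegenerateSizeWarning,
        )
        return float("nan")
    else:
        s2_r1 = 0.0
    term1 = (n_r1 - 1) * (N - n_s1) / (N * (n_s1 - 1) * n_s1) * s2_r1

    # subsampling dispersion term (absent under full first-wave response)
    if n_m1 == 0:
        term2 = 0.0
        term3_m = 0.0
    else:
        if n_r2 < 2:
            warnings.warn(
                "variance estimate undefined: fewer than two follow-up respondents",
                DegenerateSizeWarning,
            )
            return float("nan")
        s2_r2 = phase2.s2_r
        term2 = (
            (N - 1)
            / N
            * ((n_m1 - 1) / (n_s1 - 1) - (n_r2 - 1) / (N - 1))
            * w_m
            / n_r2
            * s2_r2
        )
        term3_m = w_m * (phase2.ybar_r - mean_hat) ** 2

    term3 = (
        (N - n_s1)
        / (N * (n_s1 - 1))
        * (w_r * (phase1.ybar_r - mean_hat) ** 2 + term3_m)
    )
    return term1 + term2 + term3


# ---------------------------------------------------------------------------
# L-phase (El-Badry)
# ---------------------------------------------------------------------------


def eb_estimate(
    phases: Sequence[PhaseData], N: int, with_variance: bool = True
) -> EstimateResult:
    """El-Badry mean/total estimate for the general L-phase design.

    Uses the sample-size form of the estimator, in which the design
    fractions nu_j are replaced by the realized ratios n_sj / n_m(j-1)
    (with n_m0 = N).  With L = 2 it coincides with the Hansen-Hurwitz
    estimate to machine precision.  If some wave exhausts the
    nonrespondents (n_mi = 0), later phases are vacuous and only realized
    terms are summed.
    """
    phases = list(phases)
    L = len(phases)
    if L < 2:
        raise EstimationError("the multiphase estimator needs at least two phases")
    if phases[0].n_s < 1:
        raise EstimationError("empty first-phase sample")
    _check_nesting(phases)

    total = 0.0
    weights: list[float] = []
    g = 1.0  # running product of n_m(j-1)/n_sj
    n_m_prev = N
    ell = L - 1
    for i, ph in enumerate(phases, start=1):
        if n_m_prev == 0:
            # chain exhausted: no nonrespondents left to represent
            weights.append(0.0)
            continue
        if ph.n_s == 0:
            raise EstimationError(
                f"phase {i}: no sample drawn although {n_m_prev} nonrespondents remain"
            )
        if i <= ell:
            g *= n_m_prev / ph.n_s
            weights.append(g * ph.n_r / N)
            if ph.n_r:
                total += g * ph.n_r * ph.ybar_r
            n_m_prev = ph.n_m
        else:
            # last phase represents the whole not-yet-responded stratum
            # M_ell; the product stops at wave ell (Pi_ell, not Pi_L)
            weights.append(g * n_m_prev / N)
            if ph.n_r:
                total += g * n_m_prev * ph.ybar_r
    var_total = eb_variance_estimate(phases, N) if with_variance else float("nan")
    return EstimateResult(
        mean_hat=total / N,
        total_hat=total,
        var_hat_mean=var_total / (N * N),
        var_hat_total=var_total,
        phase_weights=tuple(weights),
        N=N,
        L=L,
    )


def eb_estimate_nu_form(
    phases: Sequence[PhaseData], N: int, plan: PhasePlan
) -> float:
    """Design-fraction form of the El-Badry total, for cross-checking.

    Equals the sample-size form only when every realized size matches the
    design size exactly (integer n_m(i-1)*nu_i); kept as a test oracle.
    """
    phases = list(phases)
    L = len(phases)
    total = 0.0
    fwd = 1.0  # forward-fraction product prod_{j<=i} nu_j
    for i, ph in enumerate(phases, start=1):
        fwd *= plan.nu[i - 1]
        if i <= L - 1:
            if ph.n_r:
                total += ph.n_r / fwd * ph.ybar_r
        else:
            prev_m = phases[i - 2].n_m if i >= 2 else N
            fwd_ell = fwd / plan.nu[i - 1]
            if ph.n_r:
                total += prev_m / fwd_ell * ph.ybar_r
    return total


def eb_variance_true(
    strata: StrataSummary, plan: PhasePlan, N: int
) -> tuple[float, float]:
    """Theoretical sampling variance of the EB estimator (mean, total).

    Compact form: V(ybar_EB) = (1/N) * sum_{i=1}^{L} P_i (1/nu_i - 1)
    W_M(i-1) S2_M(i-1), with inverse-fraction products P_1 = 1 and
    P_i = prod_{j<i} 1/nu_j.  Simulation use only.
    """
    L = plan.L
    if len(strata.N_M) < L:
        raise DomainError(
            f"strata summary covers {len(strata.N_M)} strata M_0..M_{len(strata.N_M)-1}; "
            f"need M_0..M_{L-1} for an L={L} design"
        )
    v = 0.0
    inv = 1.0
    for i in range(1, L + 1):
        if i > 1:
            inv /= plan.nu[i - 2]
        w = strata.W_M[i - 1]
        s2 = strata.S2_M[i - 1]
        if w > 0 and strata.N_M[i - 1] >= 2:
            v += inv * (1.0 / plan.nu[i - 1] - 1.0) * w * s2
    v_mean = v / N
    return v_mean, N * N * v_mean


def eb_variance_estimate(phases: Sequence[PhaseData], N: int) -> float:
    """Unbiased estimator of the sampling variance of the EB *total*.

    General form for any number of phases, built on backward recursions

        t_L = sum_{rL} y,  t_i = sum_{ri} y + (n_mi / n_s(i+1)) t_(i+1)
        z_L = sum_{rL} y^2, z_i analogous,

    and size-ratio products P_1 = 1, P_i = prod_{j<i}
    n_m(j-1)(n_m(j-1)-1) / (n_sj(n_sj-1)):

        V_hat = sum_{i=1}^{ell} P_i [n_m(i-1)(n_m(i-1)-n_si)/(n_si(n_si-1))]
                                 (z_i - t_i^2/n_si)
                + P_L [n_mell^2 (1/n_sL - 1/n_mell) S2_rL]

    Divide by N^2 for the mean.  Unbiased under full last-phase response.
    """
    phases = list(phases)
    L = len(phases)
    if L < 2:
        raise EstimationError("the multiphase variance estimator needs >= 2 phases")
    _check_nesting(phases)
    ell = L - 1

    # trim vacuous phases after an exhausted chain
    n_m_prev = N
    active: list[PhaseData] = []
    for ph in phases:
        if n_m_prev == 0:
            break
        active.append(ph)
        n_m_prev = ph.n_m
    if len(active) < L:
        # chain ended early: the realized design is an (len(active))-phase one
        # with full coverage of the nonrespondents; if it ended at a wave with
        # n_m = 0 the last realized phase plays the role of phase L.
        phases = active
        L = len(phases)
        ell = L - 1
        if L < 2:
            # the chain collapsed at phase 1 (full response): the general
            # formula's last term with ell=0 is the SRSWOR estimator
            ph = phases[0]
            if ph.n_r < 2:
                warnings.warn(
                    "variance estimate undefined: fewer than two respondents",
                    DegenerateSizeWarning,
                )
                return float("nan")
            return N * N * (1.0 / ph.n_s - 1.0 / N) * ph.s2_r

    n_s = [ph.n_s for ph in phases]
    n_m = [ph.n_m for ph in phases]
    n_m_prev = [N] + n_m[:-1]  # n_m(i-1) for phase i (1-based index i-1)

    for i in range(ell):
        if n_s[i] < 2:
            warnings.warn(
                f"variance estimate undefined: n_s{i+1}={n_s[i]} < 2",
                DegenerateSizeWarning,
            )
            return float("nan")

    # backward recursions on respondent sums
    t_next = 0.0
    z_next = 0.0
    t_arr = [0.0] * L
    z_arr = [0.0] * L
    for i in range(L - 1, -1, -1):
        y = phases[i].y_r
        t_i = float(y.sum())
        z_i = float((y * y).sum())
        if i < L - 1:
            if n_s[i + 1] == 0:
                warnings.warn(
                    f"variance estimate undefined: n_s{i+2}=0 with nonrespondents left",
                    DegenerateSizeWarning,
                )
                return float("nan")
            t_i += n_m[i] / n_s[i + 1] * t_next
            z_i += n_m[i] / n_s[i + 1] * z_next
        t_arr[i], z_arr[i] = t_i, z_i
        t_next, z_next = t_i, z_i

    v = 0.0
    P = 1.0  # size-ratio product
    for i in range(1, ell + 1):
        if i > 1:
            nmp, ns = n_m_prev[i - 2], n_s[i - 2]
            P *= nmp * (nmp - 1) / (ns * (ns - 1))
        nmp, ns = n_m_prev[i - 1], n_s[i - 1]
        v += P * (nmp * (nmp - ns) / (ns * (ns - 1))) * (
            z_arr[i - 1] - t_arr[i - 1] ** 2 / ns
        )

    # last-phase term
    last = phases[-1]
    n_m_ell = n_m_prev[L - 1]
    if n_m_ell > 0:
        if last.n_s == 0 or last.n_r < 2:
            warnings.warn(
                "variance estimate undefined: fewer than two last-phase respondents",
                DegenerateSizeWarning,
            )
            return float("nan")
        nmp, ns = n_m_prev[ell - 1], n_s[ell - 1]
        P_L = P * nmp * (nmp - 1) / (ns * (ns - 1))
        v += P_L * n_m_ell**2 * (1.0 / last.n_s - 1.0 / n_m_ell) * last.s2_r
    return v


def impute_last_phase_nulls(phase: PhaseData) -> PhaseData:
    """Score last-phase nonrespondents as null harvest.

    The HH/EB formulas assume a 100% response rate at the final interview
    phase (n_rL = n_sL).  When some interviewees still do not respond,
    the field-realistic fallback — consistent with nonresponse being
    driven by null bags — is to record their harvest as zero; the
    last-phase mean then becomes the respondent total divided by the full
    sample size n_sL.  A no-op under full response.
    """
    if phase.n_m == 0:
        return phase
    y_full = np.concatenate([phase.y_r, np.zeros(phase.n_m)])
    return PhaseData(i=phase.i, n_s=phase.n_s, n_r=phase.n_s, n_m=0, y_r=y_full)


# ---------------------------------------------------------------------------
# Nonresponse-bias theory
# ---------------------------------------------------------------------------


def nrbias_theoretical(
    pi_m: float, pi_z: float, expected_respondent_mean: float
) -> float:
    """Theoretical nonresponse bias of the respondent mean.

    Under the null-harvest mechanism the bias of ybar_r is
    ``pi_z * pi_m * E(ybar_r)``: nonresponse removes null bags from the
    respondents in proportion pi_z*pi_m, inflating their mean.
    """
    if not 0.0 <= pi_m < 1.0:
        raise DomainError(f"pi_m must lie in [0, 1), got {pi_m}")
    if not 0.0 <= pi_z <= 1.0:
        raise DomainError(f"pi_z must lie in [0, 1], got {pi_z}")
    return pi_z * pi_m * expected_respondent_mean


def nrbias_index_theoretical(pi_m: float, pi_z: float) -> float:
    """Implied bias index r = E(ybar_r)/ybar = 1 / (1 - pi_z*pi_m).

    Solves ybar = E(ybar_r) - pi_z*pi_m*E(ybar_r) for the ratio.
    """
    nrbias_theoretical(pi_m, pi_z, 0.0)  # domain validation
    return 1.0 / (1.0 - pi_z * pi_m)


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------


def read_survey_tables(respondents_path, summary_path) -> list[PhaseData]:
    """Read per-phase survey tables into estimator-facing records.

    ``respondents_path``: delimited table with columns (phase, unit_id,
    bag), one row per responding unit; ``summary_path``: table with
    columns (phase, n_s, n_r, n_m).  Phases are matched by the phase
    column and must be consecutive starting at 1.
    """
    import pandas as pd

    from .errors import DataFormatError

    try:
        resp = pd.read_csv(respondents_path)
        summ = pd.read_csv(summary_path)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise DataFormatError(f"cannot parse survey tables: {exc}") from exc
    for col in ("phase", "unit_id", "bag"):
        if col not in resp.columns:
            raise DataFormatError(f"respondents table lacks column '{col}'")
    for col in ("phase", "n_s", "n_r", "n_m"):
        if col not in summ.columns:
            raise DataFormatError(f"summary table lacks column '{col}'")
    summ = summ.sort_values("phase")
    if list(summ["phase"]) != list(range(1, len(summ) + 1)):
        raise DataFormatError("phase column must run 1..L without gaps")
    phases = []
    for row in summ.itertuples(index=False):
        bags = resp.loc[resp["phase"] == row.phase, "bag"].to_numpy(dtype=float)
        try:
            phases.append(
                PhaseData(
                    i=int(row.phase),
                    n_s=int(row.n_s),
                    n_r=int(row.n_r),
                    n_m=int(row.n_m),
                    y_r=bags,
                )
            )
        except (ConsistencyError, DomainError):
            raise
    return phases


def write_estimate_record(result: EstimateResult, path) -> None:
    """Write an estimate as a flat ``key: value`` text record."""
    lines = [f"{k}: {v}" for k, v in result.to_record().items()]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
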