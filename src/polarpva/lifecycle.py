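"""Expected-value form of the three-year polar bear reproduction cycle.

The population state tracks independent bears by sex and whole-year age,
and family units (a mother with her dependent litter) by mother age,
litter age (0 = cubs-of-year, 1 = yearlings, 2 = two-year-olds) and
litter composition (number of female and male young, 1-3 cubs).  The
annual cycle is: survival (a dead mother's litter is lost with her, and
a female whose whole litter dies becomes available the following year)
-> aging (two-year-olds disperse and the mother returns to the breeding
pool) -> reproduction by available females.  Harvest belongs to the
stochastic engine and does not appear here.

The deterministic projection is the expectation of that cycle; its
asymptotic growth rate equals the dominant eigenvalue of the expanded
state-transition matrix, which :func:`build_projection_matrix` exposes
for cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rates import DISPERSAL_AGE, VitalRates, age_class

__all__ = [
    "COMPS",
    "PopulationState",
    "AgeSexDistribution",
    "ConvergenceError",
    "expected_step",
    "deterministic_project",
    "stable_age_distribution",
    "deterministic_lambda",
    "build_projection_matrix",
]

#: Litter compositions (n female young, n male young), 1-3 cubs.
COMPS = [(1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]
COMP_INDEX = {c: i for i, c in enumerate(COMPS)}
N_COMPS = len(COMPS)
N_YOUNG_AGES = DISPERSAL_AGE + 1
COMP_KF = np.array([c[0] for c in COMPS])
COMP_KM = np.array([c[1] for c in COMPS])
COMP_SIZE = COMP_KF + COMP_KM


class ConvergenceError(RuntimeError):
    """Raised when power iteration fails to converge (degenerate rates)."""


@dataclass
class PopulationState:
    """Counts of bears by sex, age and reproductive status.

    ``f_avail``/``males`` are indexed by age; ``mothers`` has shape
    (n_ages, 3, 9): mother age x litter age x litter composition.
    Dependent young are implied by their mother's cell.
    """

    f_avail: np.ndarray
    males: np.ndarray
    mothers: np.ndarray
    year: int = 0

    @classmethod
    def empty(cls, n_ages: int, year: int = 0) -> "PopulationState":
        return cls(
            np.zeros(n_ages),
            np.zeros(n_ages),
            np.zeros((n_ages, N_YOUNG_AGES, N_COMPS)),
            year,
        )

    @classmethod
    def single_cohort(
        cls, n_ages: int, n: float, sex: str = "f", age: int = 10, year: int = 0
    ) -> "PopulationState":
        """All-independent cohort of one sex and age (testing convenience)."""
        state = cls.empty(n_ages, year)
        (state.f_avail if sex == "f" else state.males)[age] = n
        return state

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.f_avail.copy(), self.males.copy(), self.mothers.copy(), self.year
        )

    def total(self) -> float:
        """Total N including dependent young."""
        return float(
            self.f_avail.sum()
            + self.males.sum()
            + (self.mothers * (1.0 + COMP_SIZE)).sum()
        )

    def validate(self):
        for arr in (self.f_avail, self.males, self.mothers):
            if (arr < 0).any():
                raise ValueError("negative count in population state")

    # flattening used by the matrix oracle -------------------------------

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.f_avail, self.males, self.mothers.ravel()]
        )

    @classmethod
    def unflatten(cls, vec: np.ndarray, n_ages: int, year: int = 0):
        a = n_ages
        return cls(
            vec[:a].copy(),
            vec[a : 2 * a].copy(),
            vec[2 * a :].reshape(a, N_YOUNG_AGES, N_COMPS).copy(),
            year,
        )


@dataclass
class AgeSexDistribution:
    """A population state normalized so that total N (bears) is 1."""

    state: PopulationState
    growth_rate: float | None = None

    def proportions(self) -> dict:
        """Fractions of individuals by (sex, age, status); sums to 1."""
        out: dict = {}
        s = self.state
        for a in range(len(s.f_avail)):
            if s.f_avail[a] > 0:
                out[("f", a, "available")] = out.get(("f", a, "available"), 0.0) + float(
                    s.f_avail[a]
                )
            if s.males[a] > 0:
                out[("m", a, "available")] = out.get(("m", a, "available"), 0.0) + float(
                    s.males[a]
                )
        status_names = {0: "with_coy", 1: "with_yearlings", 2: "with_two_year_olds"}
        for a in range(s.mothers.shape[0]):
            for y in range(N_YOUNG_AGES):
                for ci, (kf, km) in enumerate(COMPS):
                    w = float(s.mothers[a, y, ci])
                    if w == 0:
                        continue
                    key = ("f", a, status_names[y])
                    out[key] = out.get(key, 0.0) + w
                    if kf:
                        kkey = ("f", y, "dependent")
                        out[kkey] = out.get(kkey, 0.0) + w * kf
                    if km:
                        kkey = ("m", y, "dependent")
                        out[kkey] = out.get(kkey, 0.0) + w * km
        return out


def _binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1.0 - p) ** (n - k)


def comp_transition_matrix(qf: float, qm: float) -> np.ndarray:
    """Litter-composition transition under independent per-cub survival.

    Returns shape (9, 10): columns 0-8 are surviving compositions, column
    9 is whole-litter loss.
    """
    T = np.zeros((N_COMPS, N_COMPS + 1))
    for i, (kf, km) in enumerate(COMPS):
        for sf in range(kf + 1):
            for sm in range(km + 1):
                p = _binom_pmf(sf, kf, qf) * _binom_pmf(sm, km, qm)
                if sf + sm == 0:
                    T[i, N_COMPS] += p
                else:
                    T[i, COMP_INDEX[(sf, sm)]] += p
    return T


def litter_size_pmf(mean: float) -> np.ndarray:
    """Two-point litter-size distribution on {1,2,3} with the given mean.

    Mass sits on the two integers bracketing the mean, the minimal
    support consistent with a mean in [1, 3].
    """
    m = min(3.0, max(1.0, mean))
    pmf = np.zeros(3)
    if m <= 2.0:
        pmf[0] = 2.0 - m
        pmf[1] = m - 1.0
    else:
        pmf[1] = 3.0 - m
        pmf[2] = m - 2.0
    return pmf


def birth_comp_dist(litter_mean: float, p_female: float) -> np.ndarray:
    """Distribution over litter compositions at birth, shape (9,)."""
    pmf = litter_size_pmf(litter_mean)
    B = np.zeros(N_COMPS)
    for ci, (kf, km) in enumerate(COMPS):
        s = kf + km
        B[ci] = pmf[s - 1] * _binom_pmf(kf, s, p_female)
    return B


def _age_up(v: np.ndarray) -> np.ndarray:
    """Advance ages one year; the terminal class is absorbing."""
    out = np.zeros_like(v)
    out[1:] = v[:-1]
    out[-1] += v[-1]
    return out


class CycleContext:
    """Precomputed per-year quantities of the annual cycle for one rate set."""

    def __init__(
        self,
        sF: np.ndarray,
        sM: np.ndarray,
        lpr: np.ndarray,
        litter_mean: float,
        cub_sex_ratio: float,
    ):
        self.sF = sF
        self.sM = sM
        self.lpr = lpr
        # dependent young of age y carry their own class survival
        self.young_T = [
            comp_transition_matrix(sF[y], sM[y]) for y in range(N_YOUNG_AGES)
        ]
        self.birth = birth_comp_dist(litter_mean, cub_sex_ratio)

    @classmethod
    def from_rates(cls, rates: VitalRates) -> "CycleContext":
        return cls(
            rates.survival_means("f"),
            rates.survival_means("m"),
            rates.lpr_means(),
            rates.litter_size.mean,
            rates.cub_sex_ratio,
        )


def expected_step(state: PopulationState, ctx: CycleContext) -> PopulationState:
    """One expected-value year: survival, litter fate, aging/dispersal,
    reproduction.  Linear in the state."""
    sF, sM, lpr = ctx.sF, ctx.sM, ctx.lpr
    A = len(state.f_avail)

    # survival
    f_av = state.f_avail * sF
    males = state.males * sM
    moth = state.mothers * sF[:, None, None]

    # dependent-young fate (orphans of a dead mother are already gone
    # because the whole family cell was scaled by the mother's survival)
    moth_surv = np.empty_like(moth)
    f_lost = np.zeros(A)
    for y in range(N_YOUNG_AGES):
        res = moth[:, y, :] @ ctx.young_T[y]  # (A, 10)
        moth_surv[:, y, :] = res[:, :N_COMPS]
        f_lost += res[:, N_COMPS]

    # aging; two-year-olds disperse, newly independent at age 3
    f_av = _age_up(f_av)
    males = _age_up(males)
    f_lost = _age_up(f_lost)
    moth_aged = np.zeros_like(moth)
    for y in range(N_YOUNG_AGES - 1):
        moth_aged[1:, y + 1, :] = moth_surv[:-1, y, :]
        moth_aged[-1, y + 1, :] += moth_surv[-1, y, :]
    disp = moth_surv[:, DISPERSAL_AGE, :]  # (A, 9), mothers by pre-aging age
    f_disp = _age_up(disp.sum(axis=1))
    f_av[DISPERSAL_AGE + 1] += float((disp * COMP_KF).sum())
    males[DISPERSAL_AGE + 1] += float((disp * COMP_KM).sum())

    # reproduction: lone survivors and mothers of dispersing young breed;
    # females that lost a whole litter this year wait until next year
    eligible = f_av + f_disp
    litters = eligible * lpr
    moth_aged[:, 0, :] += litters[:, None] * ctx.birth[None, :]
    f_av_next = eligible * (1.0 - lpr) + f_lost

    return PopulationState(f_av_next, males, moth_aged, state.year + 1)


def deterministic_project(
    rates: VitalRates, init: PopulationState, horizon: int
) -> np.ndarray:
    """Expected total N per year, length horizon+1 (no stochastic draws)."""
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    ctx = CycleContext.from_rates(rates)
    out = np.empty(horizon + 1)
    state = init.copy()
    out[0] = state.total()
    for t in range(horizon):
        state = expected_step(state, ctx)
        out[t + 1] = state.total()
    return out


def stable_age_distribution(
    rates: VitalRates, tol: float = 1e-10, max_iter: int = 10_000
) -> AgeSexDistribution:
    """Long-run proportional composition under the expected-value cycle.

    Power iteration on the annual map; at the fixed point one projection
    year multiplies every cell by the deterministic growth rate.

    Raises
    ------
    ConvergenceError
        If iteration does not converge within ``max_iter`` (degenerate
        rates, e.g. all-zero survival).
    """
    ctx = CycleContext.from_rates(rates)
    A = rates.n_ages
    state = PopulationState.empty(A)
    state.f_avail[:] = 1.0
    state.males[:] = 1.0
    state.mothers[5:, :, :] = 1.0 / N_COMPS
    total = state.total()
    _scale(state, 1.0 / total)

    lam = np.nan
    for _ in range(max_iter):
        new = expected_step(state, ctx)
        total = new.total()
        if total <= 0 or not np.isfinite(total):
            raise ConvergenceError(
                "population vanished during power iteration; degenerate rates"
            )
        _scale(new, 1.0 / total)
        delta = (
            np.abs(new.f_avail - state.f_avail).sum()
            + np.abs(new.males - state.males).sum()
            + np.abs(new.mothers - state.mothers).sum()
        )
        state = new
        lam = total
        if delta < tol:
            return AgeSexDistribution(state, growth_rate=float(lam))
    raise ConvergenceError(f"no convergence after {max_iter} iterations")


def _scale(state: PopulationState, factor: float):
    state.f_avail *= factor
    state.males *= factor
    state.mothers *= factor


def deterministic_lambda(rates: VitalRates, **kwargs) -> float:
    """Asymptotic annual growth rate of the expected-value cycle."""
    return float(stable_age_distribution(rates, **kwargs).growth_rate)


def build_projection_matrix(rates: VitalRates) -> np.ndarray:
    """Dense expanded state-transition matrix of the annual cycle.

    Column j is the image of unit state j under one expected-value year.
    Its dominant eigenvalue equals :func:`deterministic_lambda`; intended
    as an independent cross-check, not for production projection.
    """
    ctx = CycleContext.from_rates(rates)
    A = rates.n_ages
    n = 2 * A + A * N_YOUNG_AGES * N_COMPS
    M = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        state = PopulationState.unflatten(e, A)
        M[:, j] = expected_step(state, ctx).flatten()
    return M
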