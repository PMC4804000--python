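"""Monte Carlo individual-based realization of the harvested life cycle.

Uncertainty model
-----------------
Each vital rate with a standard error is realized as

    mean + sqrt(param_fraction) * se * z_run + sqrt(env_fraction) * se * z_year

where ``z_run`` is drawn once per Monte Carlo iteration (parameter
uncertainty: how wrong the estimated mean may be) and ``z_year`` is
redrawn every simulated year (environmental variation).  Under
correlation mode ``R1`` a single standard-normal deviate is shared by
all parameters at each level; under ``R0`` deviates are independent per
parameter.  Probabilities are clipped to [0, 1] and litter size to
[1, 3]; clip events are tallied so truncation bias is observable.

Demographic stochasticity uses per-class binomial/multinomial draws,
distributionally identical to per-individual Bernoulli trials.  Harvest
removes a fixed annual number of bears split into a female and a male
share; a run is truncated (N set to 0 onward) when the initial normal
deviate for N0 is nonpositive, when the population hits zero, or when
either sex can no longer supply its share of the removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lifecycle import (
    COMPS,
    COMP_INDEX,
    COMP_KF,
    COMP_KM,
    COMP_SIZE,
    N_COMPS,
    N_YOUNG_AGES,
    DISPERSAL_AGE,
    AgeSexDistribution,
    PopulationState,
    birth_comp_dist,
    comp_transition_matrix,
)
from .rates import AGE_CLASSES, VitalRates, age_class

__all__ = [
    "SimulationConfig",
    "HarvestInterval",
    "HarvestSchedule",
    "RunResult",
    "EnsembleResult",
    "RateSampler",
    "simulate_run",
    "simulate_ensemble",
    "allocate_initial_state",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings.

    ``param_fraction``/``env_fraction`` partition each rate's total
    variance into parameter (per-run) and environmental (per-year)
    components and must sum to 1.  ``correlation_mode`` is "R0"
    (independent deviates) or "R1" (one shared deviate per level).
    """

    n_iterations: int = 5000
    horizon: int = 20
    param_fraction: float = 0.75
    env_fraction: float = 0.25
    correlation_mode: str = "R0"
    seed: int = 0
    record_trajectories: bool = True
    record_final_state: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        for f in (self.param_fraction, self.env_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("variance fractions must lie in [0,1]")
        if abs(self.param_fraction + self.env_fraction - 1.0) > 1e-9:
            raise ValueError("param_fraction + env_fraction must equal 1")
        if self.correlation_mode not in ("R0", "R1"):
            raise ValueError("correlation_mode must be 'R0' or 'R1'")


@dataclass(frozen=True)
class HarvestInterval:
    start: int  # first harvest season (inclusive)
    end: int  # last season boundary (exclusive)
    removals: float  # bears per year, may be fractional (multi-year mean)
    prop_female: float = 0.5

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        if self.removals < 0:
            raise ValueError("removals must be nonnegative")
        if not (0.0 <= self.prop_female <= 1.0):
            raise ValueError("prop_female must lie in [0,1]")


@dataclass
class HarvestSchedule:
    """Annual removals by calendar-year interval, with a female fraction.

    Intervals are half-open ``[start, end)`` on the year a simulation
    step begins; gaps carry zero harvest.  Allocation within each sex is
    proportional to standing numbers (``selectivity`` optionally maps
    (sex, age_class) to a relative vulnerability).  By default family
    groups are protected — mothers and their dependent young are not
    harvested, mirroring standard polar bear harvest regulation; with
    ``protect_family_groups=False`` all bears of age >= 1 are
    vulnerable (cubs-of-year never are) and a harvested mother's
    dependent young die as orphans.
    """

    intervals: list = field(default_factory=list)
    selectivity: dict | None = None
    protect_family_groups: bool = True

    def __post_init__(self):
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping harvest intervals {a.start}-{a.end} and {b.start}-{b.end}"
                )
        self.intervals = ivs

    @classmethod
    def none(cls) -> "HarvestSchedule":
        return cls([])

    @classmethod
    def constant(
        cls, removals: float, prop_female: float = 0.5, start: int = 0, end: int = 10_000
    ) -> "HarvestSchedule":
        if removals == 0:
            return cls.none()
        return cls([HarvestInterval(start, end, removals, prop_female)])

    def removals_at(self, year: int):
        """(removals, prop_female) for the step starting in ``year``."""
        for iv in self.intervals:
            if iv.start <= year < iv.end:
                return iv.removals, iv.prop_female
        return 0.0, 0.0

    @property
    def is_zero(self) -> bool:
        return all(iv.removals == 0 for iv in self.intervals)


@dataclass
class RunResult:
    initial_N: int
    trajectory: np.ndarray  # length horizon+1; zeros after truncation
    truncated: bool
    truncation_cause: str  # initial_deviate | extinction | harvest_infeasible | none
    truncation_year: int | None
    clip_events: int = 0
    final_state: PopulationState | None = None


@dataclass
class EnsembleResult:
    """Raw Monte Carlo output; summary statistics live in :mod:`.metrics`."""

    runs: list
    config: SimulationConfig

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def trajectories(self) -> np.ndarray:
        return np.stack([r.trajectory for r in self.runs])

    @property
    def truncation_proportion(self) -> float:
        return sum(r.truncated for r in self.runs) / self.n_runs

    def truncation_causes(self) -> dict:
        out: dict = {}
        for r in self.runs:
            if r.truncated:
                out[r.truncation_cause] = out.get(r.truncation_cause, 0) + 1
        return out


# ---------------------------------------------------------------------------
# rate realization


class RateSampler:
    """Draws realized rate sets under the variance-partition model."""

    def __init__(self, rates: VitalRates, config: SimulationConfig):
        self.rates = rates
        self.config = config
        params = rates.parameters()
        self.names = [p[0] for p in params]
        self.means = np.array([p[1] for p in params])
        self.ses = np.array([p[2] for p in params])
        self.lo = np.array([p[3] for p in params])
        self.hi = np.array([p[4] for p in params])
        self.sd_run = np.sqrt(config.param_fraction) * self.ses
        self.sd_year = np.sqrt(config.env_fraction) * self.ses
        self.shared = config.correlation_mode == "R1"
        self.clip_events = 0
        self._run_offset = np.zeros_like(self.means)
        # index map: params order is survival f (4 classes), survival m,
        # lpr ages sorted, litter size — see VitalRates.parameters()
        self._lpr_ages = sorted(rates.litter_production)
        self._n_ages = rates.n_ages
        cls_index = {c: i for i, c in enumerate(AGE_CLASSES)}
        self._ages_cls = np.array(
            [cls_index[age_class(a)] for a in range(self._n_ages)]
        )

    def _deviate(self, rng, sd: np.ndarray) -> np.ndarray:
        if self.shared:
            return float(rng.standard_normal()) * sd
        return rng.standard_normal(len(sd)) * sd

    def draw_run(self, rng):
        """Fix the per-iteration (parameter-uncertainty) component."""
        self._run_offset = self._deviate(rng, self.sd_run)

    def draw_year(self, rng) -> np.ndarray:
        """Realized parameter vector for one simulated year."""
        vals = self.means + self._run_offset + self._deviate(rng, self.sd_year)
        clipped = np.clip(vals, self.lo, self.hi)
        self.clip_events += int((clipped != vals).sum())
        return clipped

    def realized_arrays(self, vals: np.ndarray):
        """Map a parameter vector to (sF, sM, lpr, litter_mean) arrays."""
        A = self._n_ages
        sF = vals[0:4][self._ages_cls]
        sM = vals[4:8][self._ages_cls]
        lpr = np.zeros(A)
        for i, a in enumerate(self._lpr_ages):
            if 0 <= a < A:
                lpr[a] = vals[8 + i]
        litter_mean = vals[-1]
        return sF, sM, lpr, litter_mean


class _YearContext:
    """Per-year realized transition structures."""

    __slots__ = ("sF", "sM", "lpr", "young_T", "birth")

    def __init__(self, sF, sM, lpr, litter_mean, cub_sex_ratio):
        self.sF = sF
        self.sM = sM
        self.lpr = lpr
        T = np.empty((N_YOUNG_AGES, N_COMPS, N_COMPS + 1))
        for y in range(N_YOUNG_AGES):
            T[y] = comp_transition_matrix(sF[y], sM[y])
        # guard against floating drift for the multinomial sampler
        T /= T.sum(axis=-1, keepdims=True)
        self.young_T = T
        b = birth_comp_dist(litter_mean, cub_sex_ratio)
        s = b.sum()
        self.birth = b / s if s > 0 else b

# ---------------------------------------------------------------------------
# initial allocation


def allocate_initial_state(
    n: int, dist: AgeSexDistribution, rng, year: int = 0
) -> PopulationState:
    """Allocate ``n`` bears to state cells following ``dist``.

    Family units (mother plus litter) are drawn whole, then the total is
    balanced to exactly ``n`` individuals by adding or removing single
    independent bears.
    """
    ref = dist.state
    A = len(ref.f_avail)
    w_f = ref.f_avail.clip(min=0)
    w_m = ref.males.clip(min=0)
    w_moth = ref.mothers.clip(min=0)
    unit_w = np.concatenate([w_f, w_m, w_moth.ravel()])
    if unit_w.sum() <= 0:
        raise ValueError("initial distribution has no mass")
    unit_ind = np.concatenate(
        [np.ones(A), np.ones(A), np.tile(1.0 + COMP_SIZE, A * N_YOUNG_AGES).reshape(A, N_YOUNG_AGES, N_COMPS).ravel()]
    )
    p = unit_w / unit_w.sum()
    ibar = float((p * unit_ind).sum())
    n_units = max(1, int(round(n / ibar)))
    counts = rng.multinomial(n_units, p)
    state = PopulationState(
        counts[:A].astype(np.int64),
        counts[A : 2 * A].astype(np.int64),
        counts[2 * A :].reshape(A, N_YOUNG_AGES, N_COMPS).astype(np.int64),
        year,
    )
    # balance to exactly n individuals using single independent bears
    p_single = np.concatenate([w_f, w_m])
    p_single = (
        p_single / p_single.sum() if p_single.sum() > 0 else np.full(2 * A, 1 / (2 * A))
    )
    for _ in range(100):
        diff = n - int(round(state.total()))
        if diff == 0:
            break
        if diff > 0:
            add = rng.multinomial(diff, p_single)
            state.f_avail += add[:A]
            state.males += add[A:]
        else:
            singles = np.concatenate([state.f_avail, state.males])
            take = min(-diff, int(singles.sum()))
            if take > 0:
                rem = rng.multivariate_hypergeometric(singles, take)
                state.f_avail -= rem[:A]
                state.males -= rem[A:]
            if take < -diff:
                # not enough singles: drop family units until at or below n
                flat = state.mothers.ravel()
                nz = np.flatnonzero(flat)
                if len(nz) == 0:
                    break
                j = nz[rng.integers(len(nz))]
                flat[j] -= 1
    return state


# ---------------------------------------------------------------------------
# annual stochastic step


def _age_up_int(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v)
    out[1:] = v[:-1]
    out[-1] += v[-1]
    return out


def _stochastic_step(state: PopulationState, ctx: _YearContext, rng) -> PopulationState:
    A = len(state.f_avail)

    # survival
    f_av = rng.binomial(state.f_avail, ctx.sF)
    males = rng.binomial(state.males, ctx.sM)
    moth = rng.binomial(state.mothers, ctx.sF[:, None, None])

    # dependent-young fate within surviving families
    n_by = np.transpose(moth, (1, 2, 0))  # (3, 9, A)
    out = rng.multinomial(n_by, ctx.young_T[:, :, None, :])  # (3, 9, A, 10)
    surv = out[..., :N_COMPS].sum(axis=1)  # (3, A, 10->9): sum over source comp
    moth_surv = np.transpose(surv, (1, 0, 2))  # (A, 3, 9)
    f_lost = out[..., N_COMPS].sum(axis=(0, 1))  # (A,) whole-litter losses

    # aging and dispersal
    f_av = _age_up_int(f_av)
    males = _age_up_int(males)
    f_lost = _age_up_int(f_lost)
    moth_aged = np.zeros_like(moth)
    for y in range(N_YOUNG_AGES - 1):
        moth_aged[1:, y + 1, :] = moth_surv[:-1, y, :]
        moth_aged[-1, y + 1, :] += moth_surv[-1, y, :]
    disp = moth_surv[:, DISPERSAL_AGE, :]
    f_disp = _age_up_int(disp.sum(axis=1))
    f_av[DISPERSAL_AGE + 1] += int((disp * COMP_KF).sum())
    males[DISPERSAL_AGE + 1] += int((disp * COMP_KM).sum())

    # reproduction
    eligible = f_av + f_disp
    litters = rng.binomial(eligible, ctx.lpr)
    new_comps = rng.multinomial(litters, ctx.birth)  # (A, 9)
    moth_aged[:, 0, :] += new_comps
    f_av_next = eligible - litters + f_lost

    return PopulationState(f_av_next, males, moth_aged, state.year + 1)


# ---------------------------------------------------------------------------
# harvest


def _sex_categories(state: PopulationState, sex: str, protect: bool):
    """Harvestable category counts for one sex as a flat int vector.

    With family-group protection only independent bears of age >= 1 are
    vulnerable; otherwise mothers and their dependent yearlings and
    two-year-olds join the pool (cubs-of-year never do).
    """
    indep = state.f_avail if sex == "f" else state.males
    cats = [indep[1:]]  # independents age >= 1
    if not protect:
        if sex == "f":
            cats.append(state.mothers.ravel())  # the mothers themselves
        kvec = COMP_KF if sex == "f" else COMP_KM
        for y in (1, 2):  # dependent yearlings and two-year-olds
            cats.append((state.mothers[:, y, :] * kvec).ravel())
    return np.concatenate(cats).astype(np.int64)


def _selectivity_weights(state: PopulationState, sex: str, selectivity: dict,
                         protect: bool):
    A = len(state.f_avail)
    w_age = np.array(
        [selectivity.get((sex, age_class(a)), 1.0) for a in range(A)], dtype=float
    )
    parts = [w_age[1:]]
    if not protect:
        if sex == "f":
            parts.append(np.repeat(w_age, N_YOUNG_AGES * N_COMPS))
        for y in (1, 2):
            parts.append(
                np.full(A * N_COMPS, selectivity.get((sex, age_class(y)), 1.0))
            )
    return np.concatenate(parts)


def _remove_from_categories(state: PopulationState, sex: str, removals: np.ndarray,
                            protect: bool):
    """Apply per-category removal counts back onto the state arrays."""
    A = len(state.f_avail)
    idx = 0
    indep = state.f_avail if sex == "f" else state.males
    indep[1:] -= removals[idx : idx + A - 1]
    idx += A - 1
    if protect:
        return
    if sex == "f":
        moth_rem = removals[idx : idx + A * N_YOUNG_AGES * N_COMPS].reshape(
            A, N_YOUNG_AGES, N_COMPS
        )
        # a harvested mother's dependent young are orphaned and die
        state.mothers -= moth_rem
        idx += A * N_YOUNG_AGES * N_COMPS
    kvec = COMP_KF if sex == "f" else COMP_KM
    for y in (1, 2):
        young_rem = removals[idx : idx + A * N_COMPS].reshape(A, N_COMPS)
        idx += A * N_COMPS
        for a in np.flatnonzero(young_rem.sum(axis=1)):
            for ci in np.flatnonzero(young_rem[a]):
                _remove_young(state, a, y, ci, int(young_rem[a, ci]), sex)


def _remove_young(state: PopulationState, a: int, y: int, ci: int, k: int, sex: str):
    """Remove k dependent young of one sex from families in cell (a,y,ci),
    cascading through downgraded compositions when k exceeds the number
    of families."""
    while k > 0:
        kf, km = COMPS[ci]
        avail_fams = int(state.mothers[a, y, ci])
        if avail_fams <= 0 or (sex == "f" and kf == 0) or (sex == "m" and km == 0):
            # young were removed from this cell concurrently (mother harvest);
            # drop the remainder silently — counts stay consistent
            return
        take = min(k, avail_fams)
        state.mothers[a, y, ci] -= take
        new = (kf - 1, km) if sex == "f" else (kf, km - 1)
        if new[0] + new[1] == 0:
            # whole litter gone: mother returns to the breeding pool
            state.f_avail[a] += take
        else:
            state.mothers[a, y, COMP_INDEX[new]] += take
        k -= take
        if k > 0 and new[0] + new[1] > 0:
            ci = COMP_INDEX[new]


def apply_harvest(
    state: PopulationState,
    removals: float,
    prop_female: float,
    selectivity: dict | None,
    rng,
    protect_family_groups: bool = True,
) -> bool:
    """Remove the year's quota; returns False when infeasible.

    Fractional quotas are realized unbiasedly: the integer part is
    removed and the remainder is removed with matching probability.  The
    total is split into a female share (binomial with the observed
    female proportion) and a male share.
    """
    k_int = int(removals)
    frac = removals - k_int
    k_total = k_int + (1 if (frac > 0 and rng.random() < frac) else 0)
    if k_total == 0:
        return True
    k_f = int(rng.binomial(k_total, prop_female))
    k_m = k_total - k_f
    for sex, k in (("f", k_f), ("m", k_m)):
        if k == 0:
            continue
        counts = _sex_categories(state, sex, protect_family_groups)
        if counts.sum() < k:
            return False
        if selectivity is None:
            removals_vec = rng.multivariate_hypergeometric(counts, k)
        else:
            removals_vec = _weighted_without_replacement(
                counts,
                _selectivity_weights(state, sex, selectivity, protect_family_groups),
                k,
                rng,
            )
        _remove_from_categories(state, sex, removals_vec, protect_family_groups)
    return True


def _weighted_without_replacement(counts, weights, k, rng):
    taken = np.zeros_like(counts)
    remaining = counts.astype(np.int64).copy()
    while k > 0:
        w = remaining * weights
        tot = w.sum()
        if tot <= 0:
            w = remaining.astype(float)
            tot = w.sum()
        draw = rng.multinomial(k, w / tot)
        draw = np.minimum(draw, remaining)
        taken += draw
        remaining -= draw
        k -= int(draw.sum())
    return taken


# ---------------------------------------------------------------------------
# run and ensemble


def simulate_run(
    rates: VitalRates,
    init_estimate,
    init_distribution: AgeSexDistribution,
    harvest: HarvestSchedule,
    config: SimulationConfig,
    rng,
    start_year: int = 0,
) -> RunResult:
    """One Monte Carlo trajectory of the harvested life cycle.

    ``init_estimate`` is a ``(N, SE)`` pair; the initial abundance is a
    rounded normal deviate (exact when SE = 0) allocated to state cells
    by ``init_distribution``.
    """
    n_hat, se = float(init_estimate[0]), float(init_estimate[1])
    horizon = config.horizon
    traj = np.zeros(horizon + 1, dtype=np.int64)

    n0 = int(round(rng.normal(n_hat, se))) if se > 0 else int(round(n_hat))
    if n0 <= 0:
        return RunResult(n0, traj, True, "initial_deviate", 0)

    sampler = RateSampler(rates, config)
    sampler.draw_run(rng)
    state = allocate_initial_state(n0, init_distribution, rng, year=start_year)
    traj[0] = int(state.total())

    truncated = False
    cause = "none"
    t_year = None
    for t in range(1, horizon + 1):
        vals = sampler.draw_year(rng)
        sF, sM, lpr, litter_mean = sampler.realized_arrays(vals)
        ctx = _YearContext(sF, sM, lpr, litter_mean, rates.cub_sex_ratio)
        state = _stochastic_step(state, ctx, rng)
        kill, pf = harvest.removals_at(start_year + t - 1)
        if kill > 0:
            ok = apply_harvest(state, kill, pf, harvest.selectivity, rng,
                               harvest.protect_family_groups)
            if not ok:
                truncated, cause, t_year = True, "harvest_infeasible", t
                break
        n_t = int(state.total())
        traj[t] = n_t
        if n_t <= 0:
            truncated, cause, t_year = True, "extinction", t
            break

    if truncated:
        traj[t_year:] = 0
    final = state if (config.record_final_state and not truncated) else None
    return RunResult(
        traj[0], traj, truncated, cause, t_year, sampler.clip_events, final
    )


def simulate_ensemble(
    rates: VitalRates,
    init_estimate,
    init_distribution: AgeSexDistribution,
    harvest: HarvestSchedule,
    config: SimulationConfig,
    start_year: int = 0,
) -> EnsembleResult:
    """``config.n_iterations`` independent runs on per-iteration
    substreams spawned from ``config.seed``; identical seeds give
    bitwise-identical ensembles."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    runs = [
        simulate_run(
            rates,
            init_estimate,
            init_distribution,
            harvest,
            config,
            np.random.default_rng(s),
            start_year,
        )
        for s in streams
    ]
    return EnsembleResult(runs, config)
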