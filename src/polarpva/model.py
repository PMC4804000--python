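"""Model/Results interface for subpopulation viability analysis.

:class:`SubpopulationPVA` is constructed from data — a vital-rate table,
an abundance estimate and a removals schedule — and ``fit()`` runs the
deterministic and Monte Carlo projections, returning a
:class:`PVAResults` that carries the growth-rate estimators, the
probability of decline, truncation diagnostics and a ``summary()``
table.  Convenience constructors cover the two standard experiment
designs: the zero-harvest viability run from a stable-age distribution,
and the forward projection of a published estimate under observed
removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import EnsembleResult, HarvestSchedule, SimulationConfig, simulate_ensemble
from .lifecycle import AgeSexDistribution, stable_age_distribution
from .metrics import (
    VIABILITY_HORIZON,
    VIABILITY_N0,
    AbundanceEstimate,
    growth_estimates,
    probability_of_decline,
)
from .rates import VitalRates

__all__ = ["SubpopulationPVA", "PVAResults"]


class SubpopulationPVA:
    """Population viability model for one subpopulation.

    Parameters
    ----------
    rates : VitalRates
        Survival and recruitment parameters with standard errors.
    abundance : AbundanceEstimate
        Initial abundance with sampling error and estimate year.
    harvest : HarvestSchedule, optional
        Annual removals; omitted means a zero-harvest scenario.
    init_distribution : AgeSexDistribution, optional
        Starting composition; defaults to the stable-age distribution of
        ``rates``.
    """

    def __init__(
        self,
        rates: VitalRates,
        abundance: AbundanceEstimate,
        harvest: HarvestSchedule | None = None,
        init_distribution: AgeSexDistribution | None = None,
    ):
        self.rates = rates
        self.abundance = abundance
        self.harvest = harvest or HarvestSchedule.none()
        self._init_distribution = init_distribution

    @classmethod
    def viability(
        cls, rates: VitalRates, n0: float = VIABILITY_N0
    ) -> "SubpopulationPVA":
        """Zero-harvest viability design: stable-age start, N known
        exactly."""
        return cls(rates, AbundanceEstimate(n0, 0.0, 0, "simulated"))

    @classmethod
    def from_tables(
        cls,
        survival_df,
        recruitment_df,
        subpop: str,
        abundance: AbundanceEstimate,
        harvest_df=None,
        variant: str = "natural",
    ) -> "SubpopulationPVA":
        """Build from the CSV-schema DataFrames (see :mod:`.io`)."""
        from . import io as _io

        rates = _io.rates_from_frames(survival_df, recruitment_df, subpop, variant)
        harvest = (
            _io.harvest_from_frame(harvest_df, subpop) if harvest_df is not None else None
        )
        return cls(rates, abundance, harvest)

    @property
    def init_distribution(self) -> AgeSexDistribution:
        if self._init_distribution is None:
            self._init_distribution = stable_age_distribution(self.rates)
        return self._init_distribution

    def fit(
        self,
        n_iterations: int = 5000,
        horizon: int = VIABILITY_HORIZON,
        seed: int = 0,
        param_fraction: float = 0.75,
        correlation_mode: str = "R0",
    ) -> "PVAResults":
        """Run deterministic and Monte Carlo projections."""
        config = SimulationConfig(
            n_iterations=n_iterations,
            horizon=horizon,
            param_fraction=param_fraction,
            env_fraction=1.0 - param_fraction,
            correlation_mode=correlation_mode,
            seed=seed,
        )
        sad = self.init_distribution
        lam_det = (
            sad.growth_rate
            if sad.growth_rate is not None
            else stable_age_distribution(self.rates).growth_rate
        )
        ens = simulate_ensemble(
            self.rates,
            (self.abundance.N, self.abundance.se),
            sad,
            self.harvest,
            config,
            start_year=self.abundance.year,
        )
        return PVAResults(self, config, ens, float(lam_det))


@dataclass
class PVAResults:
    """Fitted PVA quantities for one scenario."""

    model: SubpopulationPVA
    config: SimulationConfig
    ensemble: EnsembleResult
    deterministic_lambda: float
    _growth: object = field(default=None, repr=False)

    def __post_init__(self):
        self._growth = growth_estimates(self.ensemble)
        p, se = probability_of_decline(self.ensemble)
        self.p_decline = p
        self.p_decline_se = se

    @property
    def lambda_mc(self):
        return self._growth.lambda_mc

    @property
    def lambda_nbased(self):
        return self._growth.lambda_nbased

    @property
    def lambda_se(self):
        return self._growth.se

    @property
    def growth_valid(self) -> bool:
        return self._growth.valid

    @property
    def truncation_proportion(self) -> float:
        return self.ensemble.truncation_proportion

    @property
    def final_abundance(self) -> AbundanceEstimate:
        finals = self.ensemble.trajectories[:, -1].astype(float)
        sd = float(finals.std(ddof=1)) if len(finals) > 1 else 0.0
        return AbundanceEstimate(
            float(finals.mean()),
            sd,
            self.model.abundance.year + self.config.horizon,
            "simulated",
        )

    def row(self) -> dict:
        fin = self.final_abundance
        return {
            "subpop": self.model.rates.subpop_id,
            "variant": self.model.rates.rate_variant,
            "lambda_det": self.deterministic_lambda,
            "lambda_mc": self.lambda_mc,
            "lambda_nbased": self.lambda_nbased,
            "lambda_se": self.lambda_se,
            "p_decline": self.p_decline,
            "p_decline_se": self.p_decline_se,
            "trunc_prop": self.truncation_proportion,
            "N_ref": fin.N,
            "N_ref_sd": fin.se,
        }

    def summary(self) -> str:
        """Plain-text results table."""
        m = self.model
        fin = self.final_abundance
        causes = self.ensemble.truncation_causes()
        lines = [
            "Population Viability Analysis Results",
            "=" * 53,
            f"Subpopulation:        {m.rates.subpop_id} ({m.rates.rate_variant} survival)",
            f"Initial N (SE):       {m.abundance.N:.1f} ({m.abundance.se:.1f})"
            f"   year {m.abundance.year}",
            f"Harvest:              "
            + ("none" if m.harvest.is_zero else f"{len(m.harvest.intervals)} interval(s)"),
            f"Iterations / horizon: {self.config.n_iterations} / {self.config.horizon} yr",
            f"Variance partition:   {self.config.param_fraction:.0%} parameter / "
            f"{self.config.env_fraction:.0%} environmental "
            f"({self.config.correlation_mode})",
            "-" * 53,
            f"Deterministic lambda: {self.deterministic_lambda:.4f}",
        ]
        if self.growth_valid:
            lines += [
                f"Stochastic lambda_G:  {self.lambda_mc:.4f} (SE {self.lambda_se:.4f})",
                f"N-based lambda:       {self.lambda_nbased:.4f}",
            ]
        else:
            lines += ["Stochastic lambda_G:  withheld (truncated runs present)"]
        lines += [
            f"p(decline):           {self.p_decline:.4f} (SE {self.p_decline_se:.4f})",
            f"Truncated runs:       {self.truncation_proportion:.4f}"
            + (f"  {causes}" if causes else ""),
            f"Final N mean (SD):    {fin.N:.1f} ({fin.se:.1f})   year {fin.year}",
            "=" * 53,
        ]
        return "\n".join(lines)

    def plot_trajectories(self, ax=None, max_runs: int = 200, **kwargs):
        """Spaghetti plot of Monte Carlo trajectories with the ensemble
        mean overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.ensemble.trajectories
        years = self.model.abundance.year + np.arange(traj.shape[1])
        for row in traj[:max_runs]:
            ax.plot(years, row, color="steelblue", alpha=0.08, lw=0.6)
        ax.plot(years, traj.mean(axis=0), color="crimson", lw=2, label="ensemble mean")
        ax.set_xlabel("year")
        ax.set_ylabel("N")
        ax.legend()
        return ax
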