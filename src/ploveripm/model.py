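"""Model/Results surface for the integrated population model.

``PloverIPM`` wraps an :class:`~ploveripm.data.ObservationBundle` the way a
statsmodels model wraps its endog/exog: construct it from data (CSV files,
record lists, or a synthetic scenario), then ``fit()`` to obtain an
:class:`IPMResults` carrying posterior draws, credible intervals,
convergence diagnostics and the post-fit analyses.

Example
-------
>>> from ploveripm import PloverIPM, SimulationScenario, MCMCConfig
>>> scenario = SimulationScenario(seed=1)
>>> model, truth = PloverIPM.from_scenario(scenario)
>>> res = model.fit(MCMCConfig(n_chains=2, n_iter=2000, n_burn=500, thin=3))
>>> print(res.summary().head())
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics
from .data import (ObservationBundle, SurveyDesign, build_bundle, read_stream)
from .likelihood import (LatentState, ModelOptions, ModelParams,
                         joint_log_posterior)
from .sampler import MCMCConfig, PosteriorSummary, run_mcmc
from .simulate import SimulationScenario, simulate_bundle

__all__ = ["PloverIPM", "IPMResults"]


class PloverIPM:
    """Integrated population model for three plover populations.

    Parameters
    ----------
    bundle:
        The aligned data streams and availability masks.
    universal_slopes:
        Share demographic regression intercepts/slopes across regions
        (the default, information-borrowing variant) or estimate them per
        region.
    cohort_specific_sigma:
        One survival process SD per cohort (default) or a single shared SD.
    """

    def __init__(self, bundle: ObservationBundle, *,
                 universal_slopes: bool = True,
                 cohort_specific_sigma: bool = True):
        self.bundle = bundle
        self.options = ModelOptions(universal_slopes=universal_slopes,
                                    cohort_specific_sigma=cohort_specific_sigma)

    @classmethod
    def from_csv(cls, *, survey=None, grid=None, distance=None, nest=None,
                 cmr=None, covariates=None, design: SurveyDesign | None = None,
                 **options) -> "PloverIPM":
        """Build the model from CSV files in the archival dialects.

        ``survey``/``grid``/``distance``/``covariates`` may be a single path
        (with a region column) or a mapping region -> path for per-region
        files without one.
        """
        design = design or SurveyDesign()

        def load(source, kind):
            if source is None:
                return []
            if isinstance(source, dict):
                out = []
                for region, path in source.items():
                    out.extend(read_stream(path, kind, region=region,
                                           design=design))
                return out
            return read_stream(source, kind, design=design)

        bundle = build_bundle(
            design,
            counts=load(survey, "survey"),
            grid_counts=load(grid, "grid"),
            distances=load(distance, "distance"),
            nests=load(nest, "nest"),
            encounters=load(cmr, "cmr"),
            covariates=load(covariates, "covariates"),
        )
        return cls(bundle, **options)

    @classmethod
    def from_scenario(cls, scenario: SimulationScenario, **options
                      ) -> tuple["PloverIPM", dict]:
        """Simulate a bundle and return (model, truth) for recovery studies."""
        bundle, state, demog = simulate_bundle(scenario)
        truth = {"params": scenario.true_params, "state": state,
                 "demography": demog}
        return cls(bundle, **options), truth

    def loglike(self, params: ModelParams, state: LatentState) -> float:
        """Joint log density of parameters, latent state and the data."""
        return joint_log_posterior(params, state, self.bundle, self.options)

    def fit(self, config: MCMCConfig | None = None, *,
            n_latent_draws: int = 200, progress: bool = False) -> "IPMResults":
        posterior = run_mcmc(self.bundle, self.options, config,
                             n_latent_draws=n_latent_draws, progress=progress)
        return IPMResults(self, posterior)


@dataclass
class IPMResults:
    """Fitted-model container: draws, summaries, diagnostics, reports."""

    model: PloverIPM
    posterior: PosteriorSummary

    def summary(self, level: float = 0.8) -> pd.DataFrame:
        """Per-parameter posterior mean, credible interval and R-hat."""
        return self.posterior.summary(level)

    @property
    def params(self) -> pd.Series:
        return self.summary()["mean"]

    def max_rhat(self, exclude: tuple[str, ...] = ("N[",)) -> float:
        return self.posterior.max_rhat(exclude)

    def population_estimates(self, level: float = 0.8) -> pd.DataFrame:
        """Posterior N with credible intervals, region by year."""
        d = self.model.bundle.design
        summ = self.summary(level)
        rows = []
        for region in d.regions:
            for year in d.years:
                lab = f"N[{region},{year}]"
                m, lo, hi = summ.loc[lab, ["mean", "ci_low", "ci_high"]]
                rows.append((region, year, m, lo, hi))
        return pd.DataFrame(rows, columns=["region", "year", "mean",
                                           "ci_low", "ci_high"])

    def ppc(self, seed: int = 0) -> dict[str, diagnostics.PPCResult]:
        """Posterior predictive checks per data stream."""
        return diagnostics.posterior_predictive_check(
            self.posterior, self.model.bundle, seed=seed)

    def partition(self) -> diagnostics.PartitionResult:
        """Hierarchical partitioning of demographic contributions to
        growth."""
        return diagnostics.partition_over_posterior(self.posterior,
                                                    self.model.bundle)

    def ses_table(self, level: float = 0.8) -> pd.DataFrame:
        """Standardized effect sizes for every covariate slope."""
        return diagnostics.ses_table(self.posterior, level)

    def plot_population(self, ax=None):
        """Posterior population trajectories with credible bands."""
        import matplotlib.pyplot as plt

        est = self.population_estimates()
        regions = est["region"].unique()
        if ax is None:
            _, axes = plt.subplots(1, len(regions), figsize=(4 * len(regions),
                                                             3), squeeze=False)
            axes = axes[0]
        else:
            axes = np.atleast_1d(ax)
        for a, region in zip(axes, regions):
            sub = est[est["region"] == region]
            a.plot(sub["year"], sub["mean"], color="goldenrod")
            a.fill_between(sub["year"], sub["ci_low"], sub["ci_high"],
                           alpha=0.3, color="purple")
            a.set_title(region)
            a.set_xlabel("year")
            a.set_ylabel("N")
        return axes

    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write tidy draws and the summary table to CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {"draws": directory / "draws.csv",
                 "summary": directory / "summary.csv"}
        self.posterior.to_tidy().to_csv(paths["draws"], index=False)
        self.summary().to_csv(paths["summary"])
        return paths
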