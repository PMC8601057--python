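"""Post-fit analyses: predictive checks, growth partitioning, effect sizes.

Three procedures summarise a fitted IPM:

* posterior predictive checks — Chi-square discrepancies for the count and
  distance-sampling streams, Freeman-Tukey discrepancies for clutch size,
  clutch fate and the encounter data, with the Bayesian p-value defined as
  the proportion of posterior draws whose replicated-data discrepancy
  exceeds the observed-data one (0.5 indicates a well-fitting model);
* hierarchical partitioning — the explained variance of a linear regression
  of annual population growth N_t / N_{t-1} on the six demographic rates is
  decomposed into independent contributions per rate by averaging the R^2
  gain of each predictor over all entry orders (all-subset enumeration),
  repeated over posterior draws;
* standardized effect sizes — |posterior mean| divided by the width of the
  80% credible interval, classified strong (> 0.6), moderate (0.3-0.6) or
  little-to-none (< 0.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .data import ObservationBundle
from .likelihood import (LatentState, ModelParams, combined_detection,
                         derive_demography, detection_at_distance,
                         eps_groups)
from .sampler import PosteriorSummary, summarize

logger = logging.getLogger(__name__)

SES_STRONG = 0.6
SES_MODERATE = 0.3

PARTITION_PREDICTORS = ("gamma", "pi", "phi_AF", "phi_AM", "phi_JF", "phi_JM")

__all__ = [
    "chi_square_discrepancy", "freeman_tukey_discrepancy",
    "posterior_predictive_pvalue", "replicate_data",
    "posterior_predictive_check", "hierarchical_partitioning",
    "partition_over_posterior", "standardized_effect_size",
    "ses_table", "PPCResult", "PartitionResult", "SESResult",
]


def chi_square_discrepancy(observed, expected) -> float:
    """Sum of (o - e)^2 / e; expected values must be strictly positive."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(e <= 0):
        raise ValueError("expected values must be positive")
    return float(np.sum((o - e) ** 2 / e))


def freeman_tukey_discrepancy(observed, expected) -> float:
    """Sum of (sqrt(o) - sqrt(e))^2; inputs must be non-negative."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(o < 0) or np.any(e < 0):
        raise ValueError("inputs must be non-negative")
    return float(np.sum((np.sqrt(o) - np.sqrt(e)) ** 2))


def posterior_predictive_pvalue(d_obs, d_rep) -> float:
    """Proportion of draws with replicated discrepancy strictly larger."""
    d_obs = np.asarray(d_obs, dtype=float)
    d_rep = np.asarray(d_rep, dtype=float)
    if d_obs.size == 0 or d_obs.shape != d_rep.shape:
        raise ValueError("need equal-length non-empty discrepancy vectors")
    return float(np.mean(d_rep > d_obs))


@dataclass
class PPCResult:
    stream: str
    discrepancy_observed: np.ndarray
    discrepancy_replicated: np.ndarray

    @property
    def p_value(self) -> float:
        return posterior_predictive_pvalue(self.discrepancy_observed,
                                           self.discrepancy_replicated)


def _count_rates(params: ModelParams, state: LatentState,
                 bundle: ObservationBundle):
    """Per count/grid/distance row: observed count, base rate N * p / div
    (local deviation excluded), and the row's deviation-group index."""
    d = bundle.design
    p_count = detection_at_distance(params.xi, d.median_distance)
    out = {}
    for stream, divisor in (("survey", 1.0), ("grid", d.n_grids),
                            ("distance", d.n_grids)):
        records = bundle.stream_records(stream)
        if not records:
            continue
        gidx, n_groups = eps_groups(bundle, stream)
        base = np.empty(len(records))
        ys = np.empty(len(records))
        for k, rec in enumerate(records):
            i, t = d.region_index(rec.region), d.year_index(rec.year)
            p = (detection_at_distance(params.xi, rec.distance)
                 if stream == "distance" else p_count)
            base[k] = np.exp(state.log_n[i, t]) / divisor * p
            ys[k] = rec.count
        out[stream] = (ys, base, gidx, n_groups)
    return out


def replicate_data(params: ModelParams, state: LatentState,
                   bundle: ObservationBundle, rng: np.random.Generator,
                   z: np.ndarray | None = None) -> dict:
    """One replicated dataset from the fitted observation models.

    Replicates are aligned with the observed availability pattern: one
    Poisson count per observed count row (with the lake/grid-level local
    deviation redrawn from its population distribution), one clutch size /
    fate pair per observed nest, and one detection record per alive
    occasion of each marked bird (``z`` is the alive-state matrix of the
    same posterior draw).  Returns arrays keyed by stream.
    """
    d = bundle.design
    X = bundle.covariate_matrix()
    demog = derive_demography(params, X, state)
    rep: dict[str, np.ndarray] = {}
    for stream, (_, base, gidx, n_groups) in _count_rates(
            params, state, bundle).items():
        eps_rep = rng.normal(0.0, params.sigma_y, n_groups)
        rep[stream] = rng.poisson(base * np.exp(eps_rep[gidx]))
    if bundle.nests:
        sizes = np.empty(len(bundle.nests), dtype=int)
        fates = np.empty(len(bundle.nests), dtype=int)
        for k, rec in enumerate(bundle.nests):
            i, t = d.region_index(rec.region), d.year_index(rec.year)
            sizes[k] = rng.choice(3, p=demog.omega[i, t]) + 1
            fates[k] = rng.random() < demog.pi[i, t]
        rep["nest_size"] = sizes
        rep["nest_fate"] = fates
    if bundle.encounters and z is not None:
        p_star = combined_detection(params.p_rec, params.p_res)
        T = d.n_years
        f = np.array([h.first_year - h.start_year for h in bundle.encounters])
        eligible = z & (np.arange(T)[None, :] > f[:, None])
        rep["encounter"] = (eligible
                            & (rng.random(z.shape) < p_star)).astype(int)
        rep["encounter_eligible"] = eligible
    return rep


def posterior_predictive_check(posterior: PosteriorSummary,
                               bundle: ObservationBundle,
                               seed: int = 0) -> dict[str, PPCResult]:
    """Stream-wise predictive checks over the stored latent draws.

    Count and distance rows are pooled into one Chi-square statistic (as the
    population-survey check); clutch size, clutch fate and encounter data
    each get a Freeman-Tukey statistic.  The encounter discrepancy compares
    per-occasion detection totals with their expectation given the alive
    states, a documented construction since the aggregation is not part of
    the model definition.
    """
    if not posterior.latent_draws:
        raise ValueError("posterior carries no stored latent draws")
    rng = np.random.default_rng(seed)
    d = bundle.design
    X = bundle.covariate_matrix()
    n_draw = len(posterior.latent_draws)

    acc: dict[str, tuple[list, list]] = {}

    def push(key, obs, rep_):
        acc.setdefault(key, ([], []))
        acc[key][0].append(obs)
        acc[key][1].append(rep_)

    nest_cells = {}
    for k, rec in enumerate(bundle.nests):
        nest_cells.setdefault((rec.region, rec.year), []).append(k)
    obs_sizes = np.array([r.clutch_size for r in bundle.nests], int)
    obs_fates = np.array([r.fate for r in bundle.nests], int)
    if bundle.encounters:
        f_arr = np.array([h.first_year - h.start_year
                          for h in bundle.encounters])
        Y = np.array([h.detections for h in bundle.encounters], int)

    for params, state, z in posterior.latent_draws:
        demog = derive_demography(params, X, state)
        rep = replicate_data(params, state, bundle, rng, z)
        rates = _count_rates(params, state, bundle)
        if rates:
            ys = np.concatenate([v[0] for v in rates.values()])
            # marginal expectation over the local deviations: the check
            # replicates the deviations, so observed and replicated data
            # are exchangeable under a well-specified model
            lam = np.concatenate([v[1] for v in rates.values()]) \
                * np.exp(0.5 * params.sigma_y ** 2)
            y_rep = np.concatenate([rep[s] for s in rates])
            lam = np.maximum(lam, 1e-12)
            push("counts", chi_square_discrepancy(ys, lam),
                 chi_square_discrepancy(y_rep, lam))
        if bundle.nests:
            d_obs_s = d_rep_s = 0.0
            d_obs_f = d_rep_f = 0.0
            for (region, year), idx in nest_cells.items():
                i, t = d.region_index(region), d.year_index(year)
                n_cell = len(idx)
                exp_sizes = n_cell * demog.omega[i, t]
                cnt = np.bincount(obs_sizes[idx] - 1, minlength=3)
                cnt_rep = np.bincount(rep["nest_size"][idx] - 1, minlength=3)
                d_obs_s += freeman_tukey_discrepancy(cnt, exp_sizes)
                d_rep_s += freeman_tukey_discrepancy(cnt_rep, exp_sizes)
                exp_f = n_cell * demog.pi[i, t]
                obs_f = float(obs_fates[idx].sum())
                rep_f = float(rep["nest_fate"][idx].sum())
                d_obs_f += freeman_tukey_discrepancy(
                    [obs_f, n_cell - obs_f], [exp_f, n_cell - exp_f])
                d_rep_f += freeman_tukey_discrepancy(
                    [rep_f, n_cell - rep_f], [exp_f, n_cell - exp_f])
            push("clutch_size", d_obs_s, d_rep_s)
            push("clutch_fate", d_obs_f, d_rep_f)
        if bundle.encounters:
            p_star = combined_detection(params.p_rec, params.p_res)
            eligible = rep["encounter_eligible"]
            expected = eligible.sum(axis=0) * p_star
            obs_tot = (Y.astype(bool) & eligible).sum(axis=0)
            rep_tot = rep["encounter"].sum(axis=0)
            keep = expected > 0
            push("encounter",
                 freeman_tukey_discrepancy(obs_tot[keep], expected[keep]),
                 freeman_tukey_discrepancy(rep_tot[keep], expected[keep]))

    return {key: PPCResult(key, np.array(v[0]), np.array(v[1]))
            for key, v in acc.items()}


# ---------------------------------------------------------------------------
# Hierarchical partitioning


def _subset_r2(y: np.ndarray, X: np.ndarray, names) -> dict[frozenset, float]:
    """R^2 of the OLS fit (with intercept) for every predictor subset."""
    n, k = X.shape
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("response has zero variance")
    Xc = X - X.mean(axis=0)
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            Xs = Xc[:, subset]
            rank = np.linalg.matrix_rank(Xs)
            if rank < len(subset):
                bad = tuple(names[j] for j in subset)
                raise ValueError(f"singular design for predictor subset {bad}")
            beta, _, _, _ = np.linalg.lstsq(Xs, yc, rcond=None)
            rss = float(np.sum((yc - Xs @ beta) ** 2))
            r2[frozenset(subset)] = 1.0 - rss / tss
    return r2


def hierarchical_partitioning(growth, predictors, names=None,
                              ) -> np.ndarray:
    """Independent contribution of each predictor, as % of explained variance.

    Implements the average-over-hierarchies decomposition: the independent
    contribution of predictor j is the average, over all orderings of the
    predictors, of the R^2 increase when j enters the regression.  Computed
    from the R^2 of all 2^k subset regressions with the combinatorial
    weights (|S|! (k-|S|-1)!) / k!.  Negative contributions (possible with
    suppressor predictors) are floored at zero before renormalising to
    100%, with a logged warning.
    """
    y = np.asarray(growth, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2:
        raise ValueError("predictors must be 2-d (observations x predictors)")
    n, k = X.shape
    if k > 6:
        raise ValueError("at most 6 predictors supported")
    if n < k + 2:
        raise ValueError("need at least k + 2 complete cases")
    if y.shape != (n,):
        raise ValueError("growth and predictors disagree on sample size")
    names = list(names) if names is not None else [f"x{j}" for j in range(k)]
    # constant predictors explain nothing; partition over the varying ones
    sds = X.std(axis=0)
    active = [j for j in range(k) if sds[j] > 1e-12]
    if not active:
        raise ValueError("all predictors are constant")
    r2 = _subset_r2(y, X[:, active], [names[j] for j in active])
    ka = len(active)
    indep = np.zeros(k)
    from math import factorial
    for pos, j in enumerate(active):
        others = [m for m in range(ka) if m != pos]
        total = 0.0
        for size in range(0, ka):
            w = factorial(size) * factorial(ka - size - 1) / factorial(ka)
            for subset in combinations(others, size):
                s = frozenset(subset)
                total += w * (r2[s | {pos}] - r2[s])
        indep[j] = total
    if np.any(indep < -1e-12):
        logger.warning("negative independent contributions floored at zero "
                       "(suppressor predictors): %s",
                       {names[j]: indep[j] for j in np.where(indep < 0)[0]})
    indep = np.maximum(indep, 0.0)
    s = indep.sum()
    if s == 0:
        raise ValueError("no explained variance to partition")
    return 100.0 * indep / s


@dataclass
class PartitionResult:
    predictors: tuple[str, ...]
    contributions: np.ndarray  # (n_draws, k) percentages

    def summary(self, level: float = 0.8) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.predictors):
            mean, lo, hi = summarize(self.contributions[:, j], level)
            rows.append((name, mean, lo, hi))
        return pd.DataFrame(rows, columns=["predictor", "mean", "ci_low",
                                           "ci_high"]).set_index("predictor")


def partition_over_posterior(posterior: PosteriorSummary,
                             bundle: ObservationBundle) -> PartitionResult:
    """Demographic contributions to growth, over the stored latent draws.

    Per draw, the response is the pooled vector of annual growth ratios
    N_t / N_{t-1} across regions, and the predictors are the matching
    average clutch size, clutch fate and the four cohort survivals.
    """
    if not posterior.latent_draws:
        raise ValueError("posterior carries no stored latent draws")
    X = bundle.covariate_matrix()
    out = []
    for params, state, _ in posterior.latent_draws:
        demog = derive_demography(params, X, state)
        N = np.exp(state.log_n)
        growth = (N[:, 1:] / N[:, :-1]).ravel()
        preds = np.column_stack([
            demog.gamma[:, :-1].ravel(), demog.pi[:, :-1].ravel(),
            demog.phi[0].ravel(), demog.phi[1].ravel(),
            demog.phi[2].ravel(), demog.phi[3].ravel()])
        out.append(hierarchical_partitioning(growth, preds,
                                             PARTITION_PREDICTORS))
    return PartitionResult(PARTITION_PREDICTORS, np.array(out))


# ---------------------------------------------------------------------------
# Standardized effect sizes


@dataclass
class SESResult:
    mean: float
    ci_low: float
    ci_high: float

    @property
    def ses(self) -> float:
        return abs(self.mean) / (self.ci_high - self.ci_low)

    @property
    def category(self) -> str:
        s = self.ses
        if s > SES_STRONG:
            return "strong"
        if s >= SES_MODERATE:
            return "moderate"
        return "little_to_none"


def standardized_effect_size(mean: float, ci_low: float,
                             ci_high: float) -> SESResult:
    """|posterior mean| over the 80% credible-interval width.

    Boundary values 0.3 and 0.6 both classify as moderate.
    """
    if not ci_high > ci_low:
        raise ValueError("ci_high must exceed ci_low")
    return SESResult(float(mean), float(ci_low), float(ci_high))


def ses_table(posterior: PosteriorSummary, level: float = 0.8,
              ) -> pd.DataFrame:
    """SES and category for every covariate slope in the posterior."""
    rows = []
    summ = posterior.summary(level)
    for label in summ.index:
        if not label.startswith("beta"):
            continue
        mean, lo, hi = summ.loc[label, ["mean", "ci_low", "ci_high"]]
        res = standardized_effect_size(mean, lo, hi)
        rows.append((label, mean, lo, hi, res.ses, res.category))
    return pd.DataFrame(rows, columns=["parameter", "mean", "ci_low",
                                       "ci_high", "ses", "category"]
                        ).set_index("parameter")
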