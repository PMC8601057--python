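"""Deterministic model mathematics and log-likelihood components of the IPM.

The integrated population model couples three sub-models around a latent
log-Normal abundance process N[region, year]:

* population sub-model — counts are Poisson with rate N * exp(eps) * p,
  where p is a constant transect detection probability tied to an
  exponential distance-decay exp(-xi * d) evaluated at the 30 m median
  distance; Oklahoma grid counts use N / n_grids in place of N.
* productivity sub-model — clutch size (1-3 eggs) follows a multinomial
  logistic regression on drought index, minimum temperature and wind, with
  baseline category 1; clutch fate (success) is a logistic regression on
  the same covariates.
* survival sub-model — apparent survival of each age-sex cohort (AF, AM,
  JF, JM) follows a logistic regression on the same covariates; encounter
  histories contribute a Cormack-Jolly-Seber likelihood with combined
  recapture/resight detection.

Every function here is pure; the sampler and the tests both consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .data import COHORTS, EncounterHistory, ObservationBundle, SurveyDesign

LINPRED_CLIP = 35.0  # guard before exponentiation
INITIAL_LOGN_SD = 0.1  # SD of log N in the first study year
PRIOR_COEF_SD = 10.0  # Normal(0, var 100) on intercepts/slopes
PRIOR_GAMMA_SHAPE = 0.01  # Gamma(0.01, 0.01) on precisions and on xi
PRIOR_GAMMA_RATE = 0.01

__all__ = [
    "ModelParams", "LatentState", "DerivedDemography", "ModelOptions",
    "expected_next_population", "clutch_theta", "clutch_size_probs",
    "average_clutch_size", "inv_logit_regression", "detection_at_distance",
    "combined_detection", "count_loglik", "population_process_logdensity",
    "encounter_history_loglik", "derive_demography", "joint_log_posterior",
]


@dataclass
class ModelOptions:
    """Structural switches of the model.

    universal_slopes ties the demographic regressions across regions (one
    intercept and slope set shared by Texas, New Mexico and Oklahoma); the
    region-specific variant frees them per region.  cohort_specific_sigma
    gives each survival cohort its own process SD.
    """

    universal_slopes: bool = True
    cohort_specific_sigma: bool = True


@dataclass
class ModelParams:
    """Every estimated quantity of the IPM.

    Regression blocks may be scalar/1-d (universal across regions) or carry a
    leading region axis (region-specific variant).  ``sigma_*`` are process /
    observation SDs, ``xi`` the per-metre detection decay, ``p_rec``/``p_res``
    the recapture and resight probabilities, and ``mu0`` the per-region mean
    of log N in the first year.
    """

    alpha2: np.ndarray  # () or (R,)
    alpha3: np.ndarray
    alpha_f: np.ndarray
    alpha_C: np.ndarray  # (4,) or (4, R)
    beta2: np.ndarray  # (3,) or (R, 3)
    beta3: np.ndarray
    beta_f: np.ndarray
    beta_C: np.ndarray  # (4, 3) or (4, R, 3)
    sigma_N: float
    sigma_y: float
    sigma_2: float
    sigma_3: float
    sigma_f: float
    sigma_C: np.ndarray  # (4,)
    xi: float
    p_rec: float
    p_res: float
    mu0: np.ndarray  # (R,)

    def __post_init__(self) -> None:
        for name in ("alpha2", "alpha3", "alpha_f", "alpha_C", "beta2",
                     "beta3", "beta_f", "beta_C", "sigma_C", "mu0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("sigma_N", "sigma_y", "sigma_2", "sigma_3", "sigma_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(self.sigma_C <= 0):
            raise ValueError("sigma_C must be positive")
        if self.xi < 0:
            raise ValueError("xi must be non-negative")
        for name in ("p_rec", "p_res"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def region_specific(self) -> bool:
        return self.beta2.ndim == 2

    def linpred_blocks(self, n_regions: int):
        """Intercepts/slopes broadcast to (R,) and (R, 3) per target."""
        def a(x):
            return np.broadcast_to(np.asarray(x, float), (n_regions,))

        def b(x):
            return np.broadcast_to(np.asarray(x, float), (n_regions, 3))

        aC = np.asarray(self.alpha_C, float)
        bC = np.asarray(self.beta_C, float)
        aC = np.broadcast_to(aC[:, None] if aC.ndim == 1 else aC,
                             (4, n_regions))
        bC = np.broadcast_to(bC[:, None, :] if bC.ndim == 2 else bC,
                             (4, n_regions, 3))
        return (a(self.alpha2), b(self.beta2), a(self.alpha3), b(self.beta3),
                a(self.alpha_f), b(self.beta_f), aC, bC)


@dataclass
class LatentState:
    """Latent abundances and process-error draws.

    ``log_n`` is (R, T); eps_2/eps_3/eps_f are (R, T); eps_C is (4, R, T-1)
    with interval s covering (year s, year s+1); eps_y holds one draw per
    count/grid/distance row in bundle record order.
    """

    log_n: np.ndarray
    eps_2: np.ndarray
    eps_3: np.ndarray
    eps_f: np.ndarray
    eps_C: np.ndarray
    eps_y: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n(self) -> np.ndarray:
        return np.exp(self.log_n)


@dataclass
class DerivedDemography:
    """Per region-year demographic rates implied by params + process errors."""

    omega: np.ndarray  # (R, T, 3) clutch-size probabilities
    gamma: np.ndarray  # (R, T) average clutch size
    pi: np.ndarray  # (R, T) clutch fate (success probability)
    phi: np.ndarray  # (4, R, T-1) apparent survival per cohort & interval


# ---------------------------------------------------------------------------
# Elementary model functions


def expected_next_population(n_prev, phi_am, phi_af, phi_jm, phi_jf,
                             gamma, pi):
    """Deterministic skeleton of the state equation (process error zero).

    Half the birds are male and half female; surviving adults carry over,
    and each female's expected successful clutch contributes half sons and
    half daughters surviving their first year.
    """
    n_prev = np.asarray(n_prev, dtype=float)
    if np.any(n_prev <= 0):
        raise ValueError("n_prev must be positive")
    recruits = n_prev * 0.5 * np.asarray(gamma) * np.asarray(pi) * 0.5
    return (n_prev * 0.5 * np.asarray(phi_am)
            + n_prev * 0.5 * np.asarray(phi_af)
            + recruits * np.asarray(phi_jm)
            + recruits * np.asarray(phi_jf))


def clutch_theta(alpha, betas, covariates, eps):
    """exp of the clutch-size linear predictor (baseline category = 1 egg)."""
    lp = (np.asarray(alpha, float)
          + np.asarray(betas, float) @ np.asarray(covariates, float)
          + np.asarray(eps, float))
    return np.exp(np.clip(lp, -LINPRED_CLIP, LINPRED_CLIP))


def clutch_size_probs(theta2, theta3):
    """Multinomial clutch-size probabilities with theta1 fixed at 1."""
    theta2 = np.asarray(theta2, dtype=float)
    theta3 = np.asarray(theta3, dtype=float)
    if np.any(theta2 <= 0) or np.any(theta3 <= 0):
        raise ValueError("theta values must be positive")
    denom = 1.0 + theta2 + theta3
    return np.stack([np.ones_like(denom) / denom, theta2 / denom,
                     theta3 / denom], axis=-1)


def average_clutch_size(omega):
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(omega.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("omega must sum to 1")
    return omega @ np.array([1.0, 2.0, 3.0])


def inv_logit_regression(alpha, betas, covariates, eps):
    """Inverse-logit of a linear predictor; clutch fate and survival links."""
    lp = (np.asarray(alpha, float)
          + np.asarray(betas, float) @ np.asarray(covariates, float)
          + np.asarray(eps, float))
    return expit(np.clip(lp, -LINPRED_CLIP, LINPRED_CLIP))


def detection_at_distance(xi, d):
    """Exponential distance decay of detection, exp(-xi * d)."""
    xi = np.asarray(xi, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(xi < 0) or np.any(d < 0):
        raise ValueError("xi and d must be non-negative")
    return np.exp(-xi * d)


def combined_detection(p_rec, p_res):
    """Per-occasion detection: recaptured OR resighted."""
    return 1.0 - (1.0 - p_rec) * (1.0 - p_res)


def count_loglik(y, n, eps, p, divisor=1.0):
    """Poisson log-pmf of a count at rate (N / divisor) * exp(eps) * p.

    ``divisor`` is 1 for whole-population transect counts and the number of
    grid cells for Oklahoma grid-level streams.  A zero rate gives 0 for
    y = 0 and -inf otherwise.
    """
    y = np.asarray(y)
    if np.any(y < 0) or np.any(np.asarray(y) != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    rate = np.asarray(n, float) / divisor * np.exp(np.asarray(eps, float)) \
        * np.asarray(p, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rate > 0,
                       y * np.log(np.where(rate > 0, rate, 1.0)) - rate
                       - gammaln(np.asarray(y, float) + 1.0),
                       np.where(y == 0, 0.0, -np.inf))
    return out if out.ndim else float(out)


def population_process_logdensity(n_now, n_expected, sigma_n):
    """Normal log-density of log(N_now) around log(N_expected)."""
    n_now = np.asarray(n_now, dtype=float)
    n_expected = np.asarray(n_expected, dtype=float)
    if np.any(n_now <= 0) or np.any(n_expected <= 0) or sigma_n <= 0:
        raise ValueError("abundances and sigma_n must be positive")
    z = (np.log(n_now) - np.log(n_expected)) / sigma_n
    out = -0.5 * z ** 2 - np.log(sigma_n) - 0.5 * np.log(2.0 * np.pi)
    return out if out.ndim else float(out)


def _normal_logpdf(x, mu, sd):
    z = (np.asarray(x, float) - mu) / sd
    return -0.5 * z ** 2 - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Encounter histories (Cormack-Jolly-Seber, conditioned on first capture)


def encounter_history_loglik(history: EncounterHistory,
                             phi_schedule: np.ndarray,
                             p_rec: float, p_res: float) -> float:
    """CJS log-likelihood of one encounter history.

    ``phi_schedule[s]`` is the survival probability of this individual over
    the interval (occasion s, occasion s+1), already resolved by cohort, sex,
    region and year (a bird marked as a juvenile uses juvenile survival for
    its first interval, then adult survival of the same sex).  Detection per
    occasion combines recapture and resight, p* = 1 - (1-p_rec)(1-p_res).
    The closed-form chi recursion marginalises the alive/dead path: chi_t is
    the probability of never being seen after occasion t given alive at t.
    """
    det = np.asarray(history.detections)
    n_occ = det.size
    f = history.first_year - history.start_year
    if np.any(det[:f]):
        raise ValueError("detection before first capture")
    phi_schedule = np.asarray(phi_schedule, dtype=float)
    if phi_schedule.size < n_occ - 1:
        raise ValueError("phi_schedule does not cover the design span")
    p_star = combined_detection(p_rec, p_res)
    last = int(np.max(np.nonzero(det)[0]))
    ll = 0.0
    for t in range(f + 1, last + 1):
        ll += np.log(phi_schedule[t - 1])
        ll += np.log(p_star) if det[t] else np.log1p(-p_star)
    # chi recursion from the final occasion back to the last detection
    chi = 1.0
    for t in range(n_occ - 2, last - 1, -1):
        chi = (1.0 - phi_schedule[t]) + phi_schedule[t] * (1.0 - p_star) * chi
    return float(ll + np.log(chi))


def _cohort_schedule_index(history: EncounterHistory) -> np.ndarray:
    """Effective cohort (index into COHORTS) for each interval s -> s+1."""
    f = history.first_year - history.start_year
    n_int = len(history.detections) - 1
    sex_is_male = history.cohort in ("AM", "JM")
    adult = 1 if sex_is_male else 0  # AM / AF
    idx = np.full(n_int, adult)
    if history.cohort in ("JF", "JM") and f < n_int:
        idx[f] = 3 if sex_is_male else 2  # JM / JF for the first interval
    return idx


def phi_schedule_for(history: EncounterHistory, phi: np.ndarray,
                     design: SurveyDesign) -> np.ndarray:
    """Resolve an individual's per-interval survival from phi (4, R, T-1)."""
    i = design.region_index(history.region)
    cls = _cohort_schedule_index(history)
    return phi[cls, i, np.arange(phi.shape[2])]


# ---------------------------------------------------------------------------
# Demography and the joint density


def eps_groups(bundle: ObservationBundle, stream: str) -> tuple[np.ndarray, int]:
    """Map count rows to local-abundance error terms.

    Shoreline survey counts get one eps per lake-date row; Oklahoma grid and
    distance streams share one eps per grid-year (the grid-level deviation
    persists across visits within a season).  Returns the per-row group index
    and the number of groups, with groups ordered by first appearance.
    """
    records = bundle.stream_records(stream)
    if stream == "survey":
        return np.arange(len(records)), len(records)
    keys: dict[tuple, int] = {}
    idx = np.empty(len(records), dtype=int)
    for k, rec in enumerate(records):
        key = (rec.region, rec.year, rec.grid)
        idx[k] = keys.setdefault(key, len(keys))
    return idx, len(keys)


def derive_demography(params: ModelParams, X: np.ndarray,
                      state: LatentState) -> DerivedDemography:
    """Demographic rates for all region-years from regressions + errors.

    ``X`` is the (R, T, 3) standardized covariate array.  Survival over the
    interval (t, t+1) uses the covariates of year t+1, following the model's
    indexing of survival regressions.
    """
    n_regions = X.shape[0]
    a2, b2, a3, b3, af, bf, aC, bC = params.linpred_blocks(n_regions)
    lp2 = a2[:, None] + np.einsum("rtk,rk->rt", X, b2) + state.eps_2
    lp3 = a3[:, None] + np.einsum("rtk,rk->rt", X, b3) + state.eps_3
    theta2 = np.exp(np.clip(lp2, -LINPRED_CLIP, LINPRED_CLIP))
    theta3 = np.exp(np.clip(lp3, -LINPRED_CLIP, LINPRED_CLIP))
    omega = clutch_size_probs(theta2, theta3)
    gamma = omega @ np.array([1.0, 2.0, 3.0])
    lpf = af[:, None] + np.einsum("rtk,rk->rt", X, bf) + state.eps_f
    pi = expit(np.clip(lpf, -LINPRED_CLIP, LINPRED_CLIP))
    # survival: interval s -> covariates of year s + 1
    Xs = X[:, 1:, :]  # (R, T-1, 3)
    lpC = (aC[:, :, None]
           + np.einsum("rtk,crk->crt", Xs, bC)
           + state.eps_C)
    phi = expit(np.clip(lpC, -LINPRED_CLIP, LINPRED_CLIP))
    return DerivedDemography(omega=omega, gamma=gamma, pi=pi, phi=phi)


def process_means(log_n: np.ndarray, demog: DerivedDemography) -> np.ndarray:
    """Expected log N for years 2..T given year-before states and rates."""
    n_prev = np.exp(log_n[:, :-1])
    phi = demog.phi  # (4, R, T-1); interval s = (year s, year s+1)
    expected = expected_next_population(
        n_prev, phi[1], phi[0], phi[3], phi[2],
        demog.gamma[:, :-1], demog.pi[:, :-1])
    return np.log(expected)


def _log_gamma_pdf(x, shape, rate):
    return (shape * np.log(rate) - gammaln(shape)
            + (shape - 1.0) * np.log(x) - rate * x)


def log_prior(params: ModelParams, options: ModelOptions) -> float:
    """Log prior density over ModelParams.

    Normal(0, var 100) on every intercept and slope; Gamma(0.01, 0.01) on
    each precision 1/sigma^2 (with the Jacobian to the sigma scale) and on
    the detection decay xi; Uniform(0, 1) on recapture/resight probabilities.
    mu0 is a data-derived constant, not sampled, and carries no prior term.
    """
    lp = 0.0
    for block in (params.alpha2, params.alpha3, params.alpha_f,
                  params.alpha_C, params.beta2, params.beta3, params.beta_f,
                  params.beta_C):
        lp += float(np.sum(_normal_logpdf(block, 0.0, PRIOR_COEF_SD)))
    sigmas = [params.sigma_N, params.sigma_y, params.sigma_2, params.sigma_3,
              params.sigma_f]
    if options.cohort_specific_sigma:
        sigmas.extend(params.sigma_C.tolist())
    else:
        sigmas.append(float(params.sigma_C[0]))
    for s in sigmas:
        tau = 1.0 / s ** 2
        lp += float(_log_gamma_pdf(tau, PRIOR_GAMMA_SHAPE, PRIOR_GAMMA_RATE)
                    + np.log(2.0 / s ** 3))
    if params.xi > 0:
        lp += float(_log_gamma_pdf(params.xi, PRIOR_GAMMA_SHAPE,
                                   PRIOR_GAMMA_RATE))
    else:
        lp = -np.inf
    # Uniform(0,1) on p_rec / p_res contributes 0 inside the unit interval
    return lp


def joint_log_posterior(params: ModelParams, state: LatentState,
                        bundle: ObservationBundle,
                        options: ModelOptions | None = None) -> float:
    """Unnormalised joint log density of parameters, latent state and data.

    Sums the initial-state density, the state-process densities, every
    observation likelihood present in the bundle (absent streams contribute
    nothing), the process-error densities, and the log prior.
    """
    options = options or ModelOptions()
    design = bundle.design
    R, T = design.n_regions, design.n_years
    if state.log_n.shape != (R, T):
        raise ValueError("log_n shape does not match the design")
    if state.eps_C.shape != (4, R, T - 1):
        raise ValueError("eps_C shape does not match the design")
    X = bundle.covariate_matrix()
    demog = derive_demography(params, X, state)

    lp = float(np.sum(_normal_logpdf(state.log_n[:, 0], params.mu0,
                                     INITIAL_LOGN_SD)))
    means = process_means(state.log_n, demog)
    lp += float(np.sum(_normal_logpdf(state.log_n[:, 1:], means,
                                      params.sigma_N)))

    p_count = detection_at_distance(params.xi, design.median_distance)
    for stream, divisor in (("survey", 1.0), ("grid", design.n_grids),
                            ("distance", design.n_grids)):
        records = bundle.stream_records(stream)
        if not records:
            continue
        group_idx, n_groups = eps_groups(bundle, stream)
        eps = state.eps_y.get(stream)
        if eps is None or len(eps) != n_groups:
            raise ValueError(f"eps_y[{stream!r}] does not match group count")
        for k, rec in enumerate(records):
            i = design.region_index(rec.region)
            t = design.year_index(rec.year)
            p = (detection_at_distance(params.xi, rec.distance)
                 if stream == "distance" else p_count)
            lp += count_loglik(rec.count, np.exp(state.log_n[i, t]),
                               eps[group_idx[k]], p, divisor=divisor)
        lp += float(np.sum(_normal_logpdf(np.asarray(eps), 0.0,
                                          params.sigma_y)))

    for rec in bundle.nests:
        i = design.region_index(rec.region)
        t = design.year_index(rec.year)
        lp += float(np.log(demog.omega[i, t, rec.clutch_size - 1]))
        pi = demog.pi[i, t]
        lp += float(np.log(pi) if rec.fate else np.log1p(-pi))

    for hist in bundle.encounters:
        sched = phi_schedule_for(hist, demog.phi, design)
        lp += encounter_history_loglik(hist, sched, params.p_rec,
                                       params.p_res)

    lp += float(np.sum(_normal_logpdf(state.eps_2, 0.0, params.sigma_2)))
    lp += float(np.sum(_normal_logpdf(state.eps_3, 0.0, params.sigma_3)))
    lp += float(np.sum(_normal_logpdf(state.eps_f, 0.0, params.sigma_f)))
    lp += float(np.sum(_normal_logpdf(
        state.eps_C, 0.0, params.sigma_C.reshape(4, 1, 1))))

    lp += log_prior(params, options)
    return lp
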