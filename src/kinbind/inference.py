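"""Simulation-based inference for the binding model.

Two complementary routes fit the free parameters to per-condition mean
binding times:

* :func:`fit_point_estimate` — squared loss over condition means,
  minimized by a derivative-free global optimizer (differential
  evolution) in log-parameter space with a fixed evaluation budget.  The
  loss uses common random numbers (a fixed simulation seed) so the
  optimizer sees a deterministic, if slightly biased, objective.
* :func:`abc_smc` — sequential Monte Carlo approximate Bayesian
  computation.  Particles are filtered through a decreasing schedule of
  relative-error thresholds (1.8 down to 0.2 in steps of 0.2 by default);
  later generations resample by weight, perturb with a Gaussian kernel in
  log-parameter space, and re-weight by

      w_i = pi(theta_i) / sum_j w_j K(theta_i | theta_j),

  the standard importance correction against the prior.

Priors are lognormal per parameter, parameterized by their natural-scale
mean and standard deviation; sampling, perturbation and densities all
live on the log scale, where the prior is Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import ExperimentCondition, ParameterVector, PhysicalParams
from .simulate import simulate_event

__all__ = ["PriorSpec", "FitResult", "PosteriorSample", "loss",
           "fit_point_estimate", "relative_error", "abc_smc",
           "posterior_summary", "default_abc_subset",
           "DEFAULT_PRIOR_HYPERPARAMS"]

#: Lognormal prior hyperparameters (natural-scale mean, sd) per parameter.
DEFAULT_PRIOR_HYPERPARAMS = {
    "k_off_adp": (1e-2, 0.001),
    "k_on_adp": (1e3, 100.0),
    "k_off_adp_fast": (10 ** 0.3, 1.0),
    "k_on_mt": (10 ** 1.7, 100.0),
    "k_off_mt": (1e-1, 0.01),
    "D_m": (10 ** 3.3, 100.0),
    "kappa_w": (10 ** -2.7, 0.001),
}


class PriorSpec:
    """Independent lognormal priors.

    ``hyperparams`` maps parameter name to (mean, sd) on the natural
    scale.  Internally each prior is the normal distribution of the log
    parameter with

        sigma^2 = log(1 + sd^2/mean^2),   mu = log(mean) - sigma^2/2.
    """

    def __init__(self, hyperparams: dict | None = None):
        hp = dict(hyperparams or DEFAULT_PRIOR_HYPERPARAMS)
        self.names = list(hp)
        self.mean = np.array([hp[n][0] for n in self.names], dtype=float)
        self.sd = np.array([hp[n][1] for n in self.names], dtype=float)
        if np.any(self.mean <= 0) or np.any(self.sd <= 0):
            raise ValueError("lognormal means and sds must be positive")
        self.sigma = np.sqrt(np.log1p((self.sd / self.mean) ** 2))
        self.mu = np.log(self.mean) - 0.5 * self.sigma ** 2

    def __len__(self) -> int:
        return len(self.names)

    def sample_log(self, rng, size: int = 1) -> np.ndarray:
        """Draw log-parameter vectors, shape (size, n_params)."""
        return rng.normal(self.mu, self.sigma, size=(size, len(self)))

    def logpdf_log(self, log_theta: np.ndarray) -> float:
        """Log density of a log-parameter vector under the prior."""
        return float(np.sum(stats.norm.logpdf(log_theta, self.mu,
                                              self.sigma)))

    def pdf_log(self, log_theta: np.ndarray) -> float:
        return math.exp(self.logpdf_log(log_theta))

    def central_interval(self, name: str, level: float = 0.5):
        """Central probability interval of the prior, natural scale."""
        i = self.names.index(name)
        z = stats.norm.ppf(0.5 + level / 2)
        return (math.exp(self.mu[i] - z * self.sigma[i]),
                math.exp(self.mu[i] + z * self.sigma[i]))


@dataclass
class FitResult:
    """Point estimate with its optimization trace."""

    params: ParameterVector
    best_loss: float
    loss_trace: list
    n_evals: int
    budget: int
    S: int
    seed: int
    free_names: list


@dataclass
class PosteriorSample:
    """One ABC-SMC generation of weighted particles (natural scale)."""

    particles: np.ndarray        # (n, n_params), natural scale
    log_particles: np.ndarray
    weights: np.ndarray          # normalized
    names: list
    generation: int
    epsilon: float
    n_draws: int
    stalled: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.particles, columns=self.names)
        df["weight"] = self.weights
        df["generation"] = self.generation
        df["epsilon"] = self.epsilon
        return df


def _conditions_of(dataset: pd.DataFrame):
    return [ExperimentCondition(motor_length=row.length_nm, gap=row.gap_nm)
            for row in dataset.itertuples()]


def simulate_condition_means(params: ParameterVector, dataset: pd.DataFrame,
                             S: int, seed: int,
                             p: PhysicalParams | None = None,
                             max_time: float = 100.0,
                             max_restarts: int = 2,
                             abort_mean: float | None = None) -> np.ndarray:
    """Simulated mean binding time for each dataset row, S events each.

    The estimand is the mean binding time conditional on success within
    the ``max_time`` screen — the same quantity the assay reports.
    Because attempts are i.i.d., averaging only the events that complete
    within ``max_restarts`` censoring restarts is unbiased for that
    conditional mean while keeping the per-proposal cost bounded (the
    routine feeds parameter-search loops that visit arbitrary, sometimes
    never-binding, proposals).  A condition where fewer than a quarter of
    events complete — binding far slower than anything in the data —
    scores ``max_time``.  With ``abort_mean`` set, a condition whose
    running mean (incomplete events counted at ``max_time``) already
    exceeds that bound after a handful of events is scored by the partial
    mean: proposals that far overshoot the data need no precise mean.
    """
    out = np.empty(len(dataset))
    probe = 5
    for i, cond in enumerate(_conditions_of(dataset)):
        # seeds keyed by the condition itself, not the row index, so the
        # result is invariant to condition ordering
        ev_ss = np.random.SeedSequence(
            (int(seed), int(round(cond.motor_length * 1000)),
             int(round(cond.gap * 1000))))
        child = ev_ss.generate_state(S, dtype=np.uint32)
        times = []
        dead = 0
        aborted = False
        for j in range(S):
            e = simulate_event(cond, params, p=p, rng=int(child[j]),
                               max_time=max_time, max_restarts=max_restarts)
            if e.completed:
                times.append(e.binding_time)
            else:
                dead += 1
            if j + 1 >= probe:
                if dead == j + 1:
                    break  # nothing binds: score at max_time
                if abort_mean is not None:
                    partial = ((sum(times) + dead * max_time)
                               / (len(times) + dead))
                    if partial > abort_mean:
                        aborted = True
                        break
        n_seen = dead + len(times)
        if not times or (not aborted and len(times) < max(1, n_seen // 4)):
            out[i] = max_time
        elif aborted:
            out[i] = (sum(times) + dead * max_time) / n_seen
        else:
            out[i] = float(np.mean(times))
    return out


def loss(params: ParameterVector, dataset: pd.DataFrame, S: int = 1000,
         seed: int = 0, p: PhysicalParams | None = None,
         max_time: float = 100.0,
         abort_mean: float | None = None,
         max_restarts: int = 2,
         weights=None) -> float:
    """Squared distance between simulated and observed condition means.

    Sum over conditions of (simulated mean over S events - observed
    mean)^2; distributional information beyond the means is deliberately
    ignored.  ``abort_mean`` is forwarded to
    :func:`simulate_condition_means` for bounded-cost use inside
    optimizers.

    ``weights`` rescales the per-condition squared residuals: ``None``
    (default) is the unweighted form; ``"sem"`` uses inverse squared
    reported SEMs (weighted least squares), which keeps the fast, precise
    conditions visible next to the slow, noisy ones at small simulation
    budgets; or an explicit array of per-condition weights.
    """
    if len(dataset) == 0:
        raise ValueError("dataset has no conditions")
    obs = dataset["mean_time_s"].to_numpy(dtype=float)
    if np.any(np.isnan(obs)):
        raise ValueError("dataset has missing mean_time_s values")
    if weights is None:
        w = np.ones_like(obs)
    elif isinstance(weights, str) and weights == "sem":
        sem = dataset["sem_s"].to_numpy(dtype=float)
        w = 1.0 / np.clip(np.nan_to_num(sem, nan=1.0), 1e-3, None) ** 2
    else:
        w = np.asarray(weights, dtype=float)
    sim = simulate_condition_means(params, dataset, S, seed, p=p,
                                   max_time=max_time, abort_mean=abort_mean,
                                   max_restarts=max_restarts)
    return float(np.sum(w * (sim - obs) ** 2))


def _build_params(base: ParameterVector, names, values) -> ParameterVector:
    return base.replace_values(**dict(zip(names, values)))


def fit_point_estimate(dataset: pd.DataFrame, bounds: dict,
                       budget: int = 200, S: int = 1000, seed: int = 0,
                       base_params: ParameterVector | None = None,
                       p: PhysicalParams | None = None,
                       max_time: float = 100.0,
                       x0: ParameterVector | None = None,
                       local_only: bool = False,
                       loss_weights="sem") -> FitResult:
    """Global derivative-free point estimate of the free parameters.

    ``bounds`` maps each fitted parameter name to (low, high) on the
    natural scale; optimization runs over log10-parameters with
    differential evolution.  ``budget`` caps the number of loss
    evaluations; the best-so-far parameters are always returned.  The
    loss uses a fixed simulation seed derived from ``seed`` (common
    random numbers), so the objective is deterministic given ``seed``.
    ``x0`` warm-starts the search (seeded into the initial population),
    e.g. from a previous full-data fit.

    The search has two stages within the one budget: a global
    differential-evolution stage, then a Nelder-Mead refinement started
    from the best point found.  With ``local_only`` (requires ``x0``)
    the global stage is skipped and the whole budget refines ``x0`` —
    the cheap mode for warm-started per-fold refits.
    """
    base = base_params or ParameterVector.fitted_adp()
    names = list(bounds)
    lo = np.log10([bounds[n][0] for n in names])
    hi = np.log10([bounds[n][1] for n in names])
    dim = len(names)
    pop = max(5, min(15, budget // (2 * dim)))
    if not local_only and budget < pop * dim:
        raise ValueError(
            f"budget {budget} is below the initial design size {pop * dim}")
    loss_seed = int(np.random.SeedSequence(seed).generate_state(1)[0]
                    % (2 ** 31))
    trace: list = []
    evals = [0]
    best = [math.inf, None]

    guard = 3.0 * float(dataset["mean_time_s"].max()) + 10.0

    def objective(x):
        evals[0] += 1
        pv = _build_params(base, names, 10.0 ** np.asarray(x))
        val = loss(pv, dataset, S=S, seed=loss_seed, p=p, max_time=max_time,
                   abort_mean=guard, max_restarts=0, weights=loss_weights)
        if val < best[0]:
            best[0] = val
            best[1] = np.asarray(x).copy()
        trace.append(best[0])
        return val

    start = None
    if x0 is not None:
        start = np.log10(np.clip([getattr(x0, n) for n in names],
                                 10.0 ** lo, 10.0 ** hi))
    if local_only:
        if start is None:
            raise ValueError("local_only refinement requires x0")
        objective(start)
    else:
        de_budget = max(pop * dim, int(0.6 * budget))
        maxiter = max(0, de_budget // (pop * dim) - 1)
        de_kwargs = {"x0": start} if start is not None else {}
        optimize.differential_evolution(
            objective, bounds=list(zip(lo, hi)), maxiter=maxiter,
            popsize=pop, tol=0.0, seed=seed, polish=False,
            init="latinhypercube", updating="immediate", **de_kwargs)
    remaining = budget - evals[0]
    if remaining > dim + 1:
        optimize.minimize(
            objective, x0=best[1], method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": remaining, "xatol": 1e-3, "fatol": 0.0})
    est = _build_params(base, names, 10.0 ** best[1])
    return FitResult(params=est, best_loss=best[0], loss_trace=trace,
                     n_evals=evals[0], budget=budget, S=S, seed=seed,
                     free_names=names)


def relative_error(sim_means, obs_means, agg: str = "sum") -> float:
    """Summed (default) or mean per-condition absolute relative error."""
    sim = np.asarray(sim_means, dtype=float)
    obs = np.asarray(obs_means, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("sim and obs means must be matched per condition")
    if np.any(obs <= 0):
        raise ValueError("observed means must be positive")
    rel = np.abs(sim - obs) / obs
    if agg == "sum":
        return float(rel.sum())
    if agg == "mean":
        return float(rel.mean())
    raise ValueError(f"unknown aggregation {agg!r}")


def default_abc_subset(summary: pd.DataFrame) -> pd.DataFrame:
    """The three-condition ABC fitting subset: shortest motor at the
    smallest gap, mid-length motor at the middle gap, longest motor at the
    largest gap."""
    lengths = sorted(summary["length_nm"].unique())
    gaps = sorted(summary["gap_nm"].unique())
    picks = [(lengths[0], gaps[0]),
             (lengths[len(lengths) // 2], gaps[len(gaps) // 2]),
             (lengths[-1], gaps[-1])]
    rows = [summary[(summary.length_nm == L) & (summary.gap_nm == g)]
            for L, g in picks]
    return pd.concat(rows, ignore_index=True)


def abc_smc(dataset: pd.DataFrame, priors: PriorSpec | None = None,
            n_particles: int = 100, schedule=None, S: int = 100,
            seed: int = 0, base_params: ParameterVector | None = None,
            p: PhysicalParams | None = None, max_time: float = 100.0,
            max_draws_per_generation: int | None = None,
            kernel_scale: float = 2.0) -> list:
    """Sequential ABC over the lognormal priors.

    Generation 1 accepts prior draws whose summed relative error over the
    dataset conditions falls below the first threshold; each later
    generation resamples the previous particles by weight, perturbs them
    with a diagonal Gaussian kernel in log space (variance =
    ``kernel_scale`` x the weighted sample variance), and re-weights.
    If a generation cannot fill its quota within
    ``max_draws_per_generation`` proposal draws, the partial generation
    is returned with ``stalled=True`` and the schedule stops — a
    prior-data conflict is reported, not silently looped.
    """
    priors = priors or PriorSpec()
    base = base_params or ParameterVector.fitted_adp()
    if schedule is None:
        schedule = [round(1.8 - 0.2 * i, 10) for i in range(9)]
    schedule = list(schedule)
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("threshold schedule must be strictly decreasing")
    if max_draws_per_generation is None:
        max_draws_per_generation = 200 * n_particles
    obs = dataset["mean_time_s"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    guard = 3.0 * float(np.max(obs)) + 10.0

    def distance(log_theta) -> float:
        pv = _build_params(base, priors.names, np.exp(log_theta))
        sim_seed = int(rng.integers(2 ** 31))
        sim = simulate_condition_means(pv, dataset, S, sim_seed, p=p,
                                       max_time=max_time, abort_mean=guard,
                                       max_restarts=0)
        return relative_error(sim, obs)

    generations: list[PosteriorSample] = []
    prev: PosteriorSample | None = None
    for gen_idx, eps in enumerate(schedule, start=1):
        accepted = np.empty((n_particles, len(priors)))
        weights = np.empty(n_particles)
        if prev is not None:
            kern_sd = np.sqrt(kernel_scale * _weighted_var(
                prev.log_particles, prev.weights))
            kern_sd = np.maximum(kern_sd, 1e-8)
        n_acc = 0
        n_draws = 0
        stalled = False
        while n_acc < n_particles:
            if n_draws >= max_draws_per_generation:
                stalled = True
                break
            n_draws += 1
            if prev is None:
                log_theta = priors.sample_log(rng)[0]
            else:
                j = rng.choice(n_particles, p=prev.weights)
                log_theta = rng.normal(prev.log_particles[j], kern_sd)
            if not math.isfinite(eps) or distance(log_theta) < eps:
                accepted[n_acc] = log_theta
                if prev is None:
                    weights[n_acc] = 1.0
                else:
                    kern = np.exp(
                        -0.5 * ((log_theta - prev.log_particles)
                                / kern_sd) ** 2
                    ) / (kern_sd * math.sqrt(2 * math.pi))
                    denom = float(np.dot(prev.weights,
                                         np.prod(kern, axis=1)))
                    weights[n_acc] = (priors.pdf_log(log_theta)
                                      / max(denom, 1e-300))
                n_acc += 1
        accepted = accepted[:n_acc]
        weights = weights[:n_acc]
        if n_acc > 0:
            weights = weights / weights.sum()
        sample = PosteriorSample(particles=np.exp(accepted),
                                 log_particles=accepted, weights=weights,
                                 names=list(priors.names),
                                 generation=gen_idx, epsilon=float(eps),
                                 n_draws=n_draws, stalled=stalled)
        generations.append(sample)
        if stalled:
            break
        prev = sample
    return generations


def _weighted_var(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    mean = np.average(x, axis=0, weights=w)
    return np.average((x - mean) ** 2, axis=0, weights=w)


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def posterior_summary(samples, grid_size: int = 512) -> dict:
    """Weighted kernel density estimates and MAP per parameter.

    ``samples`` is a :class:`PosteriorSample` or the list returned by
    :func:`abc_smc` (the final generation is summarized).  Densities are
    estimated on the log scale; the MAP is the density argmax mapped back
    to the natural scale.
    """
    if isinstance(samples, list):
        samples = samples[-1]
    if len(samples.particles) < 2:
        raise ValueError("need at least 2 particles to summarize")
    out = {}
    for i, name in enumerate(samples.names):
        x = samples.log_particles[:, i]
        w = samples.weights
        if np.ptp(x) < 1e-12:
            raise ValueError(
                f"degenerate (all-identical) particles for {name!r}")
        kde = stats.gaussian_kde(x, weights=w)
        lo = x.min() - 3 * x.std()
        hi = x.max() + 3 * x.std()
        grid = np.linspace(lo, hi, grid_size)
        dens = kde(grid)
        out[name] = {
            "map": float(np.exp(grid[np.argmax(dens)])),
            "median": float(np.exp(_weighted_quantile(x, w, 0.5))),
            "q25": float(np.exp(_weighted_quantile(x, w, 0.25))),
            "q75": float(np.exp(_weighted_quantile(x, w, 0.75))),
            "kde_grid_log": grid,
            "kde_density_log": dens,
        }
    return out
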