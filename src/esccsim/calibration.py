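"""Likelihood-based calibration of the free transition parameters.

Each calibration target (an age-specific lesion prevalence, an ESCC
incidence converted to a per-person-year proportion, or a TNM-stage share
at diagnosis) is treated as an independent binomial observation of the
model's corresponding output. The goodness-of-fit score of a parameter set
is GOF = -2 * sum of binomial log-likelihoods over all targets (lower is
better). The search is a genetic algorithm with fitness-proportional parent
selection, single-point crossover and uniform-in-bounds gene mutation;
posterior uncertainty around the best fit is approximated by sampling
importance resampling (SIR).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from importlib import resources
from scipy import stats

from .errors import UndefinedResultError, ValidationError
from .life_table import LifeTable
from .natural_history import incidence, prevalence, run_cohort, stage_distribution
from .parameters import FREE_PARAMETERS, ModelParameters
from .states import UNDETECTED, HealthState

_EPS = 1e-12

_PREVALENCE_STATES = {
    "bch_md": (HealthState.BCH_MD,),
    "md": (HealthState.MD,),
    "sd": (HealthState.SD,),
    "undetected_escc": UNDETECTED,
}


@dataclass(frozen=True)
class CalibrationTarget:
    """One observed quantity the model is scored against.

    ``value`` is the observation on its printed scale (percent for
    prevalence and stage shares, per 100,000 person-years for incidence);
    ``proportion`` is the normalized per-trial probability used in the
    binomial likelihood. ``n_eff`` is the effective number of binomial
    trials (persons, or person-years for incidence).
    """

    kind: str            # prevalence | incidence | stage_proportion
    label: str
    age_lo: int
    age_hi: int
    value: float
    n_eff: float

    def __post_init__(self) -> None:
        if self.kind not in ("prevalence", "incidence", "stage_proportion"):
            raise ValidationError(f"unknown target kind {self.kind!r}")
        if self.value < 0:
            raise ValidationError("target value must be >= 0")
        if self.n_eff <= 0:
            raise ValidationError("n_eff must be positive")
        if self.proportion > 1:
            raise ValidationError("target proportion above 1 after "
                                  "unit normalization")

    @property
    def proportion(self) -> float:
        scale = 1e5 if self.kind == "incidence" else 100.0
        return self.value / scale

    @property
    def successes(self) -> int:
        return int(round(self.proportion * self.n_eff))


def load_targets(path) -> list[CalibrationTarget]:
    df = pd.read_csv(path, comment="#")
    return [CalibrationTarget(kind=r.kind, label=r.label,
                              age_lo=int(r.age_lo), age_hi=int(r.age_hi),
                              value=float(r.value), n_eff=float(r.n_eff))
            for r in df.itertuples()]


def save_targets(targets: Sequence[CalibrationTarget], path) -> None:
    pd.DataFrame([t.__dict__ for t in targets]).to_csv(
        path, index=False, float_format="%.10g")


def packaged_targets(which: str = "all") -> list[CalibrationTarget]:
    """Packaged target sets.

    ``table2``: the 30 printed age-specific prevalence and incidence
    targets. ``stage``: 4 TNM-stage-at-diagnosis shares (synthetic
    placeholder values; the cohort source is not printed, so these are
    editable stand-ins). ``all``: both (34 targets).
    """
    out: list[CalibrationTarget] = []
    if which in ("table2", "all"):
        with resources.files("esccsim.data").joinpath(
                "table2_targets.csv").open() as fh:
            out += load_targets(fh)
    if which in ("stage", "all"):
        with resources.files("esccsim.data").joinpath(
                "stage_targets_synthetic.csv").open() as fh:
            out += load_targets(fh)
    if not out:
        raise ValidationError(f"unknown target set {which!r}")
    return out


# -- scoring -----------------------------------------------------------------

def model_outputs(params: ModelParameters, life_table: LifeTable,
                  targets: Sequence[CalibrationTarget]) -> np.ndarray:
    """Model analogue of every target, as per-trial proportions.

    One deterministic cohort run serves all targets.
    """
    traj = run_cohort(params, life_table)
    stage_cache: dict[tuple[int, int], np.ndarray] = {}
    out = np.empty(len(targets))
    for i, t in enumerate(targets):
        if t.kind == "prevalence":
            out[i] = prevalence(traj, _PREVALENCE_STATES[t.label],
                                t.age_lo, t.age_hi)
        elif t.kind == "incidence":
            out[i] = incidence(traj, t.age_lo, t.age_hi) / 1e5
        else:
            key = (t.age_lo, t.age_hi)
            if key not in stage_cache:
                stage_cache[key] = stage_distribution(traj, t.age_lo, t.age_hi)
            out[i] = stage_cache[key][int(t.label[-1]) - 1]
    return out


def binomial_loglik(target: CalibrationTarget, model_value: float) -> float:
    """Binomial log-likelihood of the target given a model proportion."""
    if target.n_eff <= 0:
        raise ValidationError("n_eff must be positive")
    p = float(np.clip(model_value, _EPS, 1.0 - _EPS))
    n = int(round(target.n_eff))
    return float(stats.binom.logpmf(target.successes, n, p))


@dataclass(frozen=True)
class GOFResult:
    """A scored parameter set."""

    params: ModelParameters | np.ndarray
    per_target_loglik: np.ndarray | None
    gof: float


def gof(params: ModelParameters, targets: Sequence[CalibrationTarget],
        life_table: LifeTable) -> GOFResult:
    """Goodness of fit: -2 * sum of per-target binomial log-likelihoods."""
    if not targets:
        raise ValidationError("targets must be non-empty")
    try:
        outputs = model_outputs(params, life_table, targets)
    except UndefinedResultError as err:
        raise UndefinedResultError(
            f"model output undefined while scoring targets: {err}") from err
    ll = np.array([binomial_loglik(t, m) for t, m in zip(targets, outputs)])
    return GOFResult(params=params, per_target_loglik=ll, gof=-2.0 * ll.sum())


# -- parameter bounds --------------------------------------------------------

@dataclass(frozen=True)
class ParameterBounds:
    """Box bounds on the free parameters, on their natural scales."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...] = FREE_PARAMETERS

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != hi.shape or lo.shape != (len(self.names),):
            raise ValidationError("bounds shape does not match names")
        if np.any(lo >= hi):
            raise ValidationError("each lower bound must be below its upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterBounds":
        names = tuple(d)
        lo = np.array([d[n][0] for n in names], float)
        hi = np.array([d[n][1] for n in names], float)
        return cls(lower=lo, upper=hi, names=names)

    def to_dict(self) -> dict:
        return {n: [float(l), float(u)] for n, l, u
                in zip(self.names, self.lower, self.upper)}

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper,
                           size=(n, len(self.names)))

    def contains(self, vector) -> bool:
        v = np.asarray(vector, float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))


def default_bounds() -> ParameterBounds:
    """Widely inclusive boxes around the published point estimates.

    Hazard parameters with a published SD get +/- 5 SD (covering any
    reported confidence interval several times over); the annual rates,
    whose uncertainty is not published, get a factor of four in either
    direction, capped to [0.001, 0.9]. beta2 was fixed in the original
    calibration (SD 0) and keeps a narrow non-negative box.
    """
    sds = {"beta0": 0.461, "beta1": 0.01815, "beta3": 0.00134,
           "alpha0": 0.171, "alpha1": 0.0095}
    points = {"beta0": -8.96, "beta1": 0.20481, "beta3": 0.00836,
              "alpha0": -3.359, "alpha1": 0.03668}
    box = {name: (points[name] - 5 * sd, points[name] + 5 * sd)
           for name, sd in sds.items()}
    box["alpha1"] = (0.0, box["alpha1"][1])  # duration slope stays >= 0
    box["beta2"] = (0.0, 0.01)
    rates = {"p_md_to_sd": 0.1538, "p_u1_u2": 0.1538, "p_u2_u3": 0.2094,
             "p_u3_u4": 0.4665, "det1": 0.5487, "det2": 0.3231,
             "det3": 0.0386, "det4": 0.3432}
    box |= {name: (max(0.001, v / 4), min(0.9, v * 4))
            for name, v in rates.items()}
    return ParameterBounds.from_dict(
        {name: box[name] for name in FREE_PARAMETERS})


# -- genetic-algorithm search ------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    crossover_prob: float = 0.80
    mutation_prob: float = 0.25
    iterations: int = 100_000     # offspring objective evaluations
    elitism: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValidationError("GA probabilities must be in [0, 1]")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")


@dataclass(frozen=True)
class GAResult:
    """Outcome of one GA run."""

    results: list[GOFResult]      # every evaluated set, ranked by GOF
    best_trace: np.ndarray        # best GOF in population, per generation

    @property
    def best(self) -> GOFResult:
        return self.results[0]


def _selection_probs(scores: np.ndarray) -> np.ndarray:
    """Fitness ∝ proportional difference from the worst GOF in population."""
    worst = scores.max()
    w = worst - scores
    total = w.sum()
    if total <= 0:  # degenerate population, fall back to uniform
        return np.full(scores.shape, 1.0 / scores.size)
    return w / total


def ga_search(bounds: ParameterBounds, config: GAConfig,
              targets: Sequence[CalibrationTarget] | None = None,
              life_table: LifeTable | None = None,
              base_params: ModelParameters | None = None,
              objective: Callable[[np.ndarray], float] | None = None
              ) -> GAResult:
    """Genetic-algorithm minimization of the GOF score.

    The population evolves by mu+lambda replacement: an offspring
    population is bred (parents chosen with probability proportional to
    their GOF's distance from the worst in the population, single-point
    crossover with ``crossover_prob``, and with ``mutation_prob`` per
    offspring one randomly chosen gene is changed — half the time redrawn
    uniformly in bounds, half the time jittered locally) and the next
    generation keeps the
    best ``population_size`` of parents plus offspring (pure generational
    replacement when elitism is off). ``iterations`` counts offspring
    evaluations: generations = iterations // population_size, so
    ``iterations=0`` scores the initial population only.

    ``objective`` replaces the GOF evaluation (surrogate-objective testing);
    otherwise ``targets`` and ``life_table`` are required and scoring runs
    the cohort model.
    """
    if objective is None:
        if targets is None or life_table is None:
            raise ValidationError("targets and life_table are required "
                                  "without a surrogate objective")
        base = base_params if base_params is not None else ModelParameters.table1()

        def evaluate(vec: np.ndarray) -> GOFResult:
            r = gof(base.with_vector(vec, bounds.names), targets, life_table)
            return GOFResult(params=vec.copy(),
                             per_target_loglik=r.per_target_loglik, gof=r.gof)
    else:
        def evaluate(vec: np.ndarray) -> GOFResult:
            return GOFResult(params=vec.copy(), per_target_loglik=None,
                             gof=float(objective(vec)))

    rng = np.random.default_rng(config.seed)
    d = len(bounds.names)
    pop = bounds.sample(rng, config.population_size)
    evaluated = [evaluate(v) for v in pop]
    scores = np.array([r.gof for r in evaluated])
    all_results = list(evaluated)
    trace = [scores.min()]

    n_generations = config.iterations // config.population_size
    for _ in range(n_generations):
        probs = _selection_probs(scores)
        children: list[np.ndarray] = []
        while len(children) < config.population_size:
            i, j = rng.choice(config.population_size, size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if d > 1 and rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, d))
                a[cut:], b[cut:] = pop[j][cut:].copy(), pop[i][cut:].copy()
            for child in (a, b):
                if rng.random() < config.mutation_prob:
                    g = int(rng.integers(d))
                    width = bounds.upper[g] - bounds.lower[g]
                    if rng.random() < 0.5:  # exploratory redraw
                        child[g] = rng.uniform(bounds.lower[g],
                                               bounds.upper[g])
                    else:  # local refinement
                        child[g] = np.clip(
                            child[g] + rng.normal(0.0, 0.05 * width),
                            bounds.lower[g], bounds.upper[g])
                children.append(child)
        children = children[:config.population_size]
        child_results = [evaluate(v) for v in children]
        all_results.extend(child_results)
        child_scores = np.array([r.gof for r in child_results])
        if config.elitism:
            comb = np.vstack([pop, children])
            comb_scores = np.concatenate([scores, child_scores])
            keep = np.argsort(comb_scores, kind="stable")[:config.population_size]
            pop, scores = comb[keep], comb_scores[keep]
        else:
            pop = np.asarray(children)
            scores = child_scores
        trace.append(scores.min())

    order = np.argsort([r.gof for r in all_results], kind="stable")
    ranked = [all_results[i] for i in order]
    return GAResult(results=ranked, best_trace=np.array(trace))


def select_good_fitting(results: Sequence[GOFResult],
                        delta: float | None = None,
                        n_targets: int | None = None) -> list[GOFResult]:
    """Subset with GOF within ``delta`` of the best.

    By default ``delta`` is the 95th percentile of a chi-squared
    distribution with one degree of freedom per target (the selection rule
    is a configurable convention; no canonical rule is published).
    """
    if not results:
        raise ValidationError("results must be non-empty")
    if delta is None:
        if n_targets is None:
            first = next(r for r in results if r.per_target_loglik is not None)
            n_targets = len(first.per_target_loglik)
        delta = float(stats.chi2.ppf(0.95, df=n_targets))
    best = min(r.gof for r in results)
    return [r for r in results if r.gof <= best + delta]


# -- sampling importance resampling -----------------------------------------

def sample_proposal(center: np.ndarray, sds: np.ndarray,
                    bounds: ParameterBounds, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Independent normals around ``center``, truncated to the bounds.

    A parameter with SD zero stays fixed at its center value.
    """
    center = np.asarray(center, float)
    sds = np.asarray(sds, float)
    out = np.tile(center, (n, 1))
    for k, sd in enumerate(sds):
        if sd > 0:
            a = (bounds.lower[k] - center[k]) / sd
            b = (bounds.upper[k] - center[k]) / sd
            out[:, k] = stats.truncnorm.rvs(a, b, loc=center[k], scale=sd,
                                            size=n, random_state=rng)
    return out


def sir_resample(samples: np.ndarray, loglikelihoods: np.ndarray,
                 n_resample: int, seed: int | np.random.Generator | None = None
                 ) -> tuple[np.ndarray, int]:
    """Likelihood-weighted resample with replacement.

    Weights are the likelihoods, computed overflow-safely by exponentiating
    log-likelihoods after subtracting their maximum. Returns the resampled
    parameter sets and the number of unique sets retained (the 'unique
    weighted sample size').
    """
    samples = np.asarray(samples, float)
    ll = np.asarray(loglikelihoods, float)
    if samples.shape[0] != ll.shape[0]:
        raise ValidationError("samples and loglikelihoods length mismatch")
    w = np.exp(ll - ll.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValidationError("all importance weights underflowed; rescale "
                              "the log-likelihoods before resampling")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.choice(samples.shape[0], size=n_resample, replace=True,
                     p=w / total)
    return samples[idx], int(np.unique(idx).size)
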