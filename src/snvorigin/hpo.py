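"""Gaussian-process Bayesian hyperparameter search.

Sequential model-based minimization: an initial random design, then a
Matern-5/2 Gaussian process fitted to all evaluations proposes the next
point by maximizing expected improvement over a random candidate pool.
Continuous dimensions may be log-uniform (learning rate, L2 penalty),
integers are searched on their lattice, and categoricals (activation) are
one-hot encoded for the GP.

The study design evaluates 200 combinations per model; the desk-scale
default here is 25 calls, with the full budget reachable through
``n_calls``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .net import ACTIVATION_SET, Hyperparams, IntegrationSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    prior: str = "uniform"  # or "log-uniform"

    def sample(self, rng: np.random.Generator):
        if self.prior == "log-uniform":
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def encode(self, x) -> list[float]:
        if self.prior == "log-uniform":
            return [(np.log(x) - np.log(self.low)) / (np.log(self.high) - np.log(self.low))]
        return [(x - self.low) / (self.high - self.low)]


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int

    def sample(self, rng: np.random.Generator):
        return int(rng.integers(self.low, self.high + 1))

    def encode(self, x) -> list[float]:
        return [(x - self.low) / max(self.high - self.low, 1)]


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(len(self.choices)))]

    def encode(self, x) -> list[float]:
        return [1.0 if c == x else 0.0 for c in self.choices]


Dimension = Real | Integer | Categorical


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        for d in self.dimensions:
            if isinstance(d, Categorical) and not d.choices:
                raise ValueError(f"{d.name}: empty categorical")
            if isinstance(d, (Real, Integer)) and not np.isfinite([d.low, d.high]).all():
                raise ValueError(f"{d.name}: bounds must be finite")

    def sample(self, rng: np.random.Generator) -> dict:
        return {d.name: d.sample(rng) for d in self.dimensions}

    def encode(self, params: dict) -> np.ndarray:
        out: list[float] = []
        for d in self.dimensions:
            out.extend(d.encode(params[d.name]))
        return np.asarray(out)


def default_search_space() -> SearchSpace:
    """Documented default bounds for the classifier hyperparameters."""
    return SearchSpace((
        Real("learning_rate", 1e-5, 1e-2, prior="log-uniform"),
        Real("l2_penalty", 1e-6, 1e-2, prior="log-uniform"),
        Real("dropout", 0.0, 0.5),
        Integer("n_layers", 1, 4),
        Integer("n_nodes", 32, 512),
        Categorical("activation", tuple(ACTIVATION_SET)),
    ))


@dataclass
class SearchResult:
    best_params: dict
    best_value: float
    trace: list[tuple[dict, float, int]] = field(default_factory=list)


def search(space: SearchSpace, objective, n_calls: int, seed: int = 0,
           n_initial: int = 10, n_candidates: int = 512) -> SearchResult:
    """Minimize ``objective`` (e.g. negated validation accuracy) over ``space``.

    The trace has exactly ``n_calls`` entries; a raising objective is
    recorded at the worst value seen so far and the search continues.
    Deterministic for a fixed seed.
    """
    if n_calls < n_initial:
        raise ValueError(f"n_calls must be >= {n_initial} (initial random design)")
    rng = np.random.default_rng(seed)
    evaluated: list[dict] = []
    values: list[float] = []
    trace: list[tuple[dict, float, int]] = []

    def evaluate(params: dict, iteration: int) -> None:
        try:
            val = float(objective(params))
            if not np.isfinite(val):
                raise ValueError(f"objective returned {val}")
        except Exception as exc:  # noqa: BLE001 - any failure counts as worst-seen
            val = max(values) if values else 0.0
            log.warning("objective failed at iteration %d (%s); recorded %.4g",
                        iteration, exc, val)
        evaluated.append(params)
        values.append(val)
        trace.append((params, val, iteration))

    for i in range(min(n_initial, n_calls)):
        evaluate(space.sample(rng), i)

    kernel = 1.0 * Matern(length_scale=1.0, nu=2.5)
    for i in range(len(trace), n_calls):
        X = np.vstack([space.encode(p) for p in evaluated])
        y = np.asarray(values)
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6, normalize_y=True,
                                      n_restarts_optimizer=1, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP convergence chatter on tiny designs
            gp.fit(X, y)
            candidates = [space.sample(rng) for _ in range(n_candidates)]
            Xc = np.vstack([space.encode(p) for p in candidates])
            mu, sigma = gp.predict(Xc, return_std=True)
        best = y.min()
        sigma = np.maximum(sigma, 1e-12)
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        evaluate(candidates[int(np.argmax(ei))], i)

    best_idx = int(np.argmin(values))
    return SearchResult(best_params=evaluated[best_idx], best_value=values[best_idx],
                        trace=trace)


def tune_per_entry_point(architecture: str, spaces: list[SearchSpace],
                         objective_builder, n_calls: int = 25, seed: int = 0,
                         feature_order: list[str] | None = None,
                         ) -> tuple[IntegrationSpec, list[SearchResult]]:
    """Tune each architecture entry point with its own GP search.

    ``early`` has a single entry point; ``multi_branch`` and ``consecutive``
    get one search per feature set, run sequentially with earlier winners
    frozen. ``objective_builder(entry_index, current_hyperparams)`` must
    return a callable mapping a params dict to the objective value.
    """
    feature_order = feature_order or ["bins", "tri", "drivers"]
    n_entry = 1 if architecture == "early" else len(feature_order)
    if len(spaces) != n_entry:
        raise ValueError(f"{architecture} needs {n_entry} search spaces, got {len(spaces)}")
    current = [Hyperparams() for _ in range(n_entry)]
    results = []
    for i in range(n_entry):
        objective = objective_builder(i, [Hyperparams(**vars(h)) for h in current])
        res = search(spaces[i], objective, n_calls=n_calls, seed=seed + i)
        current[i] = Hyperparams(**res.best_params)
        results.append(res)
    return IntegrationSpec(architecture, current, feature_order=feature_order), results


def cumulative_best(trace: list[tuple[dict, float, int]]) -> list[float]:
    """Running minimum of the trace values (monotone non-increasing)."""
    out, best = [], np.inf
    for _, v, _ in trace:
        best = min(best, v)
        out.append(best)
    return out
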