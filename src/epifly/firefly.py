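"""Wrapper feature selection by a chaos-seeded firefly algorithm with
simulated-annealing offspring refinement.

Each firefly is a point in [0,1]^D; thresholding its coordinates at 0.5
yields a candidate feature mask.  Brightness is the wrapper fitness

    f = w1 · acc + w2 · (1 − |S|/D)

where ``acc`` is the stratified inner-CV accuracy of a small random forest
on the masked table and the second term rewards parsimony (w1 = 0.9,
w2 = 0.1 by default).  The search augments the classical firefly movement
(attractiveness β0·e^(−γ r²) toward brighter neighbours) with:

* chaotic logistic-map initialisation and a chaotic factor C_k in the
  movement step, to diversify the swarm;
* a second leader S_best — the fittest firefly lying farther from g_best
  than the median pairwise distance — so two distinct regions lead;
* a simulated-annealing refinement of the leaders' midpoint producing the
  guide g_best′ (worse moves accepted with p = exp(Δf/T) under a linear
  cooling schedule);
* per-bit mask mutation and repositioning of the worst firefly around the
  leaders' midpoint.

The best mask ever evaluated is returned, so the fitness history is
non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = ["SelectionConfig", "SelectionResult", "logistic_map_sequence",
           "distance", "attractiveness", "fitness", "sa_offspring",
           "move_firefly", "reposition_worst", "select_features"]


@dataclass(frozen=True)
class SelectionConfig:
    population: int = 20
    iterations: int = 100
    beta0: float = 1.0
    gamma: float = 0.1          # light absorption
    alpha_step: float = 0.5     # initial random-walk step, decayed linearly
    alpha_step_final: float = 0.05
    w1: float = 0.9             # weight of wrapped-classifier accuracy
    w2: float = 0.1             # weight of the parsimony term
    mutation_p: float = 0.01    # per-bit mask mutation probability
    sa_t0: float = 1.0          # initial SA temperature
    sa_t_final: float = 0.01    # linear cooling endpoint
    sa_iterations: int = 8
    sa_sigma: float = 0.6       # SA single-coordinate perturbation scale
    neighbor_sigma: float = 0.1  # Gaussian jitter on the brighter neighbour (sigma1)
    binarization_threshold: float = 0.5
    rng_seed: int = 0
    inner_cv_folds: int = 2
    inner_trees: int = 10

    def __post_init__(self):
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")
        if abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ValueError("w1 + w2 must equal 1")
        for name in ("mutation_p", "binarization_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SelectionResult:
    selected_indices: list[int]
    selected_names: list[str]
    best_fitness: float
    history: list[float]
    g_best: np.ndarray
    s_best: np.ndarray
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "selected_indices": list(map(int, self.selected_indices)),
            "selected_names": list(self.selected_names),
            "best_fitness": float(self.best_fitness),
            "history": list(map(float, self.history)),
            "n_evaluations": int(self.n_evaluations),
        }


_LOGISTIC_DEGENERATE = (0.0, 0.25, 0.5, 0.75, 1.0)


def logistic_map_sequence(x0: float, n: int) -> np.ndarray:
    """Fully chaotic logistic map x_{k+1} = 4 x_k (1 − x_k).

    ``x0`` must avoid the fixed points and short cycles
    {0, 0.25, 0.5, 0.75, 1}.
    """
    if any(abs(x0 - v) < 1e-12 for v in _LOGISTIC_DEGENERATE) or not 0 < x0 < 1:
        raise ValueError(
            f"x0 must lie in (0,1) excluding {_LOGISTIC_DEGENERATE}, got {x0!r}")
    out = np.empty(n)
    x = float(x0)
    for i in range(n):
        x = 4.0 * x * (1.0 - x)
        out[i] = x
    return out


def distance(xi, xj) -> float:
    """Euclidean distance between two firefly positions."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"dimension mismatch: {xi.shape} vs {xj.shape}")
    return float(np.sqrt(np.sum((xi - xj) ** 2)))


def attractiveness(r: float, beta0: float, gamma: float) -> float:
    """Distance-attenuated attractiveness β(r) = β0 · exp(−γ r²)."""
    if r < 0:
        raise ValueError("distance must be >= 0")
    return float(beta0 * np.exp(-gamma * r * r))


class _FitnessCache:
    """Mask-keyed wrapper fitness with inner stratified-CV accuracy."""

    def __init__(self, table, labels, config: SelectionConfig):
        if isinstance(table, pd.DataFrame):
            self.x = table.to_numpy(dtype=float)
            self.names = list(map(str, table.columns))
        else:
            self.x = np.asarray(table, dtype=float)
            self.names = [f"f{i}" for i in range(self.x.shape[1])]
        self.y = np.asarray(labels)
        self.config = config
        self.cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    @property
    def dim(self) -> int:
        return self.x.shape[1]

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        if key in self.cache:
            return self.cache[key]
        val = fitness(mask, self.x, self.y, w1=self.config.w1, w2=self.config.w2,
                      inner_cv_folds=self.config.inner_cv_folds,
                      rng_seed=self.config.rng_seed,
                      n_trees=self.config.inner_trees)
        self.cache[key] = val
        self.n_evaluations += 1
        return val


def fitness(mask, table, labels, w1: float = 0.9, w2: float = 0.1,
            inner_cv_folds: int = 3, rng_seed: int = 0, n_trees: int = 25) -> float:
    """Wrapper fitness f = w1·acc + w2·(1 − |S|/D); −inf for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("-inf")
    x = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    y = np.asarray(labels)
    xs = x[:, mask]
    skf = StratifiedKFold(n_splits=inner_cv_folds, shuffle=True, random_state=rng_seed)
    correct = 0
    for train_idx, test_idx in skf.split(xs, y):
        clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                     random_state=rng_seed)
        clf.fit(xs[train_idx], y[train_idx])
        correct += int(np.sum(clf.predict(xs[test_idx]) == y[test_idx]))
    acc = correct / len(y)
    return float(w1 * acc + w2 * (1.0 - mask.sum() / mask.size))


def _binarize(position: np.ndarray, threshold: float) -> np.ndarray:
    return position >= threshold


def sa_offspring(g_best, s_best, evaluate, rng: np.random.Generator,
                 config: SelectionConfig) -> tuple[np.ndarray, float]:
    """Simulated-annealing refinement of the leaders' midpoint.

    Starts from mean(g_best, S_best) plus a Gaussian draw on one coordinate
    and iterates single-coordinate Gaussian perturbations (local moves that
    toggle roughly one mask bit at a time); better candidates are always
    accepted, worse ones with probability exp(Δf/T) under a linear cooling
    schedule from ``sa_t0`` down to ``sa_t_final``.  Returns the best
    position visited and its fitness.
    """
    g_best = np.asarray(g_best, dtype=float)
    s_best = np.asarray(s_best, dtype=float)
    thr = config.binarization_threshold
    d = len(g_best)

    def perturb(pos: np.ndarray) -> np.ndarray:
        cand = pos.copy()
        j = rng.integers(d)
        cand[j] = np.clip(cand[j] + config.sa_sigma * rng.standard_normal(), 0, 1)
        return cand

    current = 0.5 * (g_best + s_best)
    if config.sa_iterations > 0:
        current = perturb(current)
    f_current = evaluate(_binarize(current, thr))
    best, f_best = current.copy(), f_current
    n_it = config.sa_iterations
    for k in range(n_it):
        t_c = config.sa_t0 + (config.sa_t_final - config.sa_t0) * (k / max(1, n_it - 1))
        cand = perturb(current)
        f_cand = evaluate(_binarize(cand, thr))
        delta = f_cand - f_current
        if delta >= 0 or rng.random() < np.exp(delta / t_c):
            current, f_current = cand, f_cand
            if f_current > f_best:
                best, f_best = current.copy(), f_current
    return best, f_best


def move_firefly(xi, xj_prime, g_best_prime, c_k: float, alpha_step: float,
                 beta0: float, rng: np.random.Generator,
                 epsilon: float | None = None) -> np.ndarray:
    """One movement step of a dim firefly.

    x ← x + β0·C_k·(x_j′ − x) + C_k·ε·(g_best′ − x) + α′·sign(rand − 0.5),
    with ε uniform in [−0.5, 0.5] unless given, then clipped to [0,1]^D.
    """
    xi = np.asarray(xi, dtype=float)
    xj_prime = np.asarray(xj_prime, dtype=float)
    g_best_prime = np.asarray(g_best_prime, dtype=float)
    if not xi.shape == xj_prime.shape == g_best_prime.shape:
        raise ValueError("position dimension mismatch")
    eps = rng.uniform(-0.5, 0.5) if epsilon is None else epsilon
    step = (beta0 * c_k * (xj_prime - xi)
            + c_k * eps * (g_best_prime - xi)
            + alpha_step * np.sign(rng.random(len(xi)) - 0.5))
    return np.clip(xi + step, 0.0, 1.0)


def reposition_worst(x_worst, g_best, s_best, sigma: float) -> np.ndarray:
    """Contract the worst firefly toward the leaders' midpoint:
    m + σ·(x_worst − m), clipped to [0,1]^D."""
    x_worst = np.asarray(x_worst, dtype=float)
    m = 0.5 * (np.asarray(g_best, dtype=float) + np.asarray(s_best, dtype=float))
    return np.clip(m + sigma * (x_worst - m), 0.0, 1.0)


def _pick_s_best(positions: np.ndarray, fits: np.ndarray, best_idx: int) -> int:
    """Fittest firefly farther from g_best than the median pairwise distance;
    falls back to the runner-up when no firefly is that remote."""
    n = len(positions)
    diffs = positions[:, None, :] - positions[None, :, :]
    dmat = np.sqrt(np.sum(diffs ** 2, axis=2))
    median_d = float(np.median(dmat[np.triu_indices(n, k=1)]))
    order = np.argsort(-fits)
    for idx in order:
        if idx != best_idx and dmat[idx, best_idx] > median_d:
            return int(idx)
    for idx in order:
        if idx != best_idx:
            return int(idx)
    return best_idx


def select_features(table, labels, config: SelectionConfig | None = None) -> SelectionResult:
    """Run the full selection loop and return the best mask ever evaluated.

    The population is initialised from one chaotic logistic-map stream; each
    iteration ranks the swarm, refines the two leaders' midpoint by
    simulated annealing, moves every dimmer firefly toward its nearest
    brighter neighbour and the refined guide, mutates mask bits, and
    repositions the worst firefly around the leaders' midpoint.
    """
    config = config or SelectionConfig()
    evaluate = _FitnessCache(table, labels, config)
    d = evaluate.dim
    if d < 2:
        raise ValueError("need at least 2 features to select from")
    if len(np.unique(evaluate.y)) < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(config.rng_seed)
    thr = config.binarization_threshold
    n = config.population

    # chaotic initialisation: one logistic stream, burn-in discarded
    x0 = float(rng.uniform(0.05, 0.45))
    while any(abs(x0 - v) < 1e-6 for v in _LOGISTIC_DEGENERATE):
        x0 = float(rng.uniform(0.05, 0.45))
    stream = logistic_map_sequence(x0, 100 + n * d)[100:]
    positions = stream.reshape(n, d).copy()
    fits = np.array([evaluate(_binarize(p, thr)) for p in positions])

    # chaotic factor C_k driven by its own logistic stream
    c_k = float(rng.uniform(0.05, 0.45))

    best_idx = int(np.argmax(fits))
    g_best_pos = positions[best_idx].copy()
    best_mask = _binarize(g_best_pos, thr).copy()
    best_fit = float(fits[best_idx])
    history = [best_fit]
    s_best_pos = g_best_pos.copy()

    for it in range(config.iterations):
        frac = it / max(1, config.iterations - 1)
        alpha_step = config.alpha_step + (config.alpha_step_final - config.alpha_step) * frac
        c_k = 4.0 * c_k * (1.0 - c_k)

        order = np.argsort(-fits)
        best_idx = int(order[0])
        worst_idx = int(order[-1])
        g_best_pos = positions[best_idx].copy()
        s_idx = _pick_s_best(positions, fits, best_idx)
        s_best_pos = positions[s_idx].copy()

        # SA refinement of the leaders' midpoint -> movement guide
        g_prime, f_prime = sa_offspring(g_best_pos, s_best_pos, evaluate, rng, config)
        if f_prime > best_fit:
            best_fit = f_prime
            best_mask = _binarize(g_prime, thr).copy()

        # move every firefly dimmer than the leader
        diffs = positions[:, None, :] - positions[None, :, :]
        dmat = np.sqrt(np.sum(diffs ** 2, axis=2))
        for i in range(n):
            if i == best_idx:
                continue
            brighter = np.flatnonzero(fits > fits[i])
            j = best_idx if len(brighter) == 0 else int(brighter[np.argmin(dmat[i, brighter])])
            xj_prime = np.clip(
                positions[j] + config.neighbor_sigma * rng.standard_normal(d), 0, 1)
            positions[i] = move_firefly(positions[i], xj_prime, g_prime, c_k,
                                        alpha_step, config.beta0, rng)
            # per-bit mutation: reflect the coordinate across the threshold
            flip = rng.random(d) < config.mutation_p
            if flip.any():
                positions[i][flip] = np.clip(2 * thr - positions[i][flip], 0, 1)
            fits[i] = evaluate(_binarize(positions[i], thr))

        # population diversity: contract the worst firefly toward the leaders
        sigma = float(rng.standard_normal())
        positions[worst_idx] = reposition_worst(positions[worst_idx], g_best_pos,
                                                s_best_pos, sigma)
        fits[worst_idx] = evaluate(_binarize(positions[worst_idx], thr))

        it_best = int(np.argmax(fits))
        if fits[it_best] > best_fit:
            best_fit = float(fits[it_best])
            best_mask = _binarize(positions[it_best], thr).copy()
        history.append(best_fit)

    if not best_mask.any():
        # no informative signal anywhere: fall back to the single first feature
        best_mask = np.zeros(d, dtype=bool)
        best_mask[0] = True
    selected = np.flatnonzero(best_mask)
    return SelectionResult(
        selected_indices=[int(i) for i in selected],
        selected_names=[evaluate.names[i] for i in selected],
        best_fitness=best_fit,
        history=history,
        g_best=g_best_pos,
        s_best=s_best_pos,
        n_evaluations=evaluate.n_evaluations,
    )
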