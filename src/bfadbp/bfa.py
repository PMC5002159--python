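"""Improved binary firefly algorithm (BFA).

A firefly is a fixed-length bit string; its brightness is the objective
value.  Each iteration every firefly flies towards every brighter one:
bits on which the pair already agrees are kept, each differing bit adopts
the brighter firefly's value with probability

    beta = beta0 * exp(-gamma * r^2),

where r is the normalized Hamming SIMILARITY of the pair (1 minus the
fraction of differing bits) — dissimilar pairs therefore take the larger
strides.  After each attraction the mover is mutated: every bit flips
independently with probability alpha, which decays linearly from 0.5 to 0
over the run so the search shifts from exploration to convergence.  A
firefly with no brighter neighbour undergoes mutation only.  The global
best bit string is archived outside the population (elitism), making the
best-so-far trace monotone without shielding any individual from mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

BitArray = np.ndarray  # 1-D uint8 array over {0, 1}


class ContractError(ValueError):
    """A caller violated an interface contract."""


@dataclass(frozen=True)
class BFAConfig:
    """Search settings.

    Defaults follow the reference protocol for this method: 30 fireflies,
    light absorption gamma_fa = 1, 500 iterations.  ``gamma_fa`` is the
    firefly absorption coefficient — unrelated to the SVM kernel width
    optimised elsewhere in this package.
    """

    population_size: int = 30
    max_iterations: int = 500
    gamma_fa: float = 1.0
    beta0: float = 1.0
    rng_seed: int = 0
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ContractError("population_size must be >= 1")
        if self.max_iterations < 1:
            raise ContractError("max_iterations must be >= 1")
        if self.gamma_fa < 0:
            raise ContractError("gamma_fa must be >= 0")
        if not 0.0 < self.beta0 <= 1.0:
            raise ContractError("beta0 must lie in (0, 1]")


@dataclass
class BFAResult:
    """Outcome of one optimization run."""

    best_bits: BitArray
    best_brightness: float
    trace: list[float]  # best-so-far brightness after each iteration
    n_evaluations: int  # objective calls (cache misses)
    seed: int


def _as_bits(x) -> BitArray:
    arr = np.asarray(x, dtype=np.uint8)
    if arr.ndim != 1 or not np.all((arr == 0) | (arr == 1)):
        raise ContractError("bits must be a 1-D array over {0, 1}")
    return arr


def bits_from_string(s: str) -> BitArray:
    """Convenience: '1001' -> array([1, 0, 0, 1])."""
    return _as_bits([int(c) for c in s])


def similarity(a, b) -> float:
    """Normalized Hamming similarity r = 1 - (differing bits)/n, in [0, 1]."""
    a, b = _as_bits(a), _as_bits(b)
    if a.shape != b.shape:
        raise ContractError(f"length mismatch: {a.size} vs {b.size}")
    return 1.0 - float(np.count_nonzero(a != b)) / a.size


def attractiveness(r: float, cfg: BFAConfig) -> float:
    """beta = beta0 * exp(-gamma_fa * r^2); at r = 0, beta equals beta0."""
    return cfg.beta0 * float(np.exp(-cfg.gamma_fa * r * r))


def attract(
    mover: BitArray, brighter: BitArray, beta: float, rng: np.random.Generator
) -> BitArray:
    """Move ``mover`` towards ``brighter``.

    Agreeing bits are preserved; each differing bit independently adopts
    the brighter firefly's value with probability ``beta``.  The Hamming
    distance to ``brighter`` can therefore only shrink or stay.
    """
    mover, brighter = _as_bits(mover), _as_bits(brighter)
    if mover.shape != brighter.shape:
        raise ContractError("length mismatch")
    differs = mover != brighter
    adopt = differs & (rng.random(mover.size) < beta)
    out = mover.copy()
    out[adopt] = brighter[adopt]
    return out


def mutate(bits: BitArray, alpha: float, rng: np.random.Generator) -> BitArray:
    """Flip every bit independently with probability ``alpha``."""
    bits = _as_bits(bits)
    flip = rng.random(bits.size) < alpha
    return np.where(flip, 1 - bits, bits).astype(np.uint8)


def alpha_schedule(iteration: int, max_iterations: int) -> float:
    """Linear decay alpha = 0.5 - 0.5 * iteration / max_iterations."""
    if not 0 <= iteration <= max_iterations:
        raise ContractError(
            f"iteration {iteration} outside [0, {max_iterations}]"
        )
    return 0.5 - 0.5 * iteration / max_iterations


@dataclass
class _Evaluator:
    """Objective wrapper with a bit-string-keyed cache and call counting."""

    objective: Callable[[BitArray], float]
    cache: dict[bytes, float] = field(default_factory=dict)
    n_calls: int = 0

    def __call__(self, bits: BitArray, context: str = "") -> float:
        key = bits.tobytes()
        if key not in self.cache:
            try:
                self.cache[key] = float(self.objective(bits))
            except Exception as exc:
                raise RuntimeError(
                    f"objective failed {context} on bits "
                    f"{''.join(map(str, bits.tolist()))}"
                ) from exc
            self.n_calls += 1
        return self.cache[key]


def move_firefly(
    x: BitArray,
    brighter: Sequence[BitArray],
    alpha: float,
    cfg: BFAConfig,
    randoms: np.ndarray,
) -> BitArray:
    """One full inner sweep of a firefly: attract-then-mutate per neighbour.

    ``randoms`` is a (len(brighter), 2, n_bits) block of uniforms; row
    ``[k, 0]`` drives the attraction towards the k-th brighter firefly and
    row ``[k, 1]`` the subsequent mutation.  This is exactly the
    composition of :func:`attract` and :func:`mutate` fed those same
    uniforms, written with lean XOR arithmetic so the main loop stays
    cheap; a unit test pins the equivalence.
    """
    inv = 1.0 / x.size
    for k, xj in enumerate(brighter):
        differ = x ^ xj
        r = 1.0 - float(differ.sum()) * inv
        beta = cfg.beta0 * math.exp(-cfg.gamma_fa * r * r)
        x = x ^ (differ & (randoms[k, 0] < beta))
        x = (x ^ (randoms[k, 1] < alpha)).astype(np.uint8)
    return x


def optimize(
    objective: Callable[[BitArray], float],
    n_bits: int,
    cfg: BFAConfig | None = None,
    log: Callable[[str], None] | None = None,
) -> BFAResult:
    """Run the BFA main loop against ``objective`` (higher is better).

    The population is initialised uniformly at random from the seeded
    generator.  Each iteration sweeps the population: firefly i is moved
    once towards every firefly j that is currently strictly brighter
    (attract with beta(r_ij), then mutate with the iteration's alpha), and
    is re-evaluated after its full inner sweep; a firefly with no brighter
    neighbour is mutated only.  Runs are bit-reproducible for a fixed
    (config seed, objective).
    """
    cfg = cfg if cfg is not None else BFAConfig()
    if n_bits < 1:
        raise ContractError("n_bits must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed)
    evaluate = _Evaluator(objective)

    pop = rng.integers(0, 2, size=(cfg.population_size, n_bits), dtype=np.uint8)
    bright = np.array(
        [evaluate(pop[i], "during initialisation") for i in range(cfg.population_size)]
    )

    best_idx = int(np.argmax(bright))
    best_bits = pop[best_idx].copy()
    best_brightness = float(bright[best_idx])
    trace: list[float] = []

    for iteration in range(cfg.max_iterations):
        alpha = alpha_schedule(iteration, cfg.max_iterations)
        for i in range(cfg.population_size):
            js = np.flatnonzero(bright > bright[i])
            if js.size:
                randoms = rng.random((js.size, 2, n_bits))
                pop[i] = move_firefly(
                    pop[i], [pop[j] for j in js], alpha, cfg, randoms
                )
            else:
                pop[i] = mutate(pop[i], alpha, rng)
            bright[i] = evaluate(pop[i], f"at iteration {iteration}, firefly {i}")

        iter_best = int(np.argmax(bright))
        if cfg.elitism:
            if bright[iter_best] > best_brightness:
                best_brightness = float(bright[iter_best])
                best_bits = pop[iter_best].copy()
        else:
            best_brightness = float(bright[iter_best])
            best_bits = pop[iter_best].copy()
        trace.append(best_brightness)
        if log is not None:
            log(
                f"iter={iteration + 1} best_I={best_brightness:.6f} "
                f"mean_I={bright.mean():.6f} alpha={alpha:.4f}"
            )

    return BFAResult(
        best_bits=best_bits,
        best_brightness=best_brightness,
        trace=trace,
        n_evaluations=evaluate.n_calls,
        seed=cfg.rng_seed,
    )
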