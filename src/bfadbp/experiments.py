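"""Reference experiments: oracle checks, operator laws, planted recovery.

These are the package's benchmark computations, shared by the test suite
and by ``scripts/acceptance.py``.  Every experiment takes explicit seeds
and returns plain dataclasses of numbers; nothing here reads files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC
from sklearn.model_selection import train_test_split

from . import bfa
from .bfa import BFAConfig, attract, mutate
from .pipeline import FireflyLayout, _pooled_counts, metrics, decode, make_objective, train_model
from .synthetic import PlantedDatasetSpec, gen_planted_dataset, mask_recovery


def exhaustive_optimum(objective, n_bits: int) -> float:
    """Brute-force enumeration of all 2^n bit strings (independent oracle)."""
    best = -np.inf
    for combo in itertools.product((0, 1), repeat=n_bits):
        best = max(best, objective(np.array(combo, dtype=np.uint8)))
    return best


@dataclass
class OracleCheck:
    """Fraction of seeded BFA runs matching the exhaustive optimum."""

    landscape: str
    n_bits: int
    n_seeds: int
    match_fraction: float


def onemax_oracle_check(n_bits: int = 12, seeds=range(20), cfg: BFAConfig | None = None) -> OracleCheck:
    """BFA vs brute force on OneMax (brightness = popcount)."""

    def objective(bits):
        return float(bits.sum())

    target = exhaustive_optimum(objective, n_bits)
    hits = 0
    seeds = list(seeds)
    base = cfg if cfg is not None else BFAConfig()
    for seed in seeds:
        run_cfg = BFAConfig(
            population_size=base.population_size,
            max_iterations=base.max_iterations,
            gamma_fa=base.gamma_fa,
            beta0=base.beta0,
            rng_seed=seed,
            elitism=base.elitism,
        )
        result = bfa.optimize(objective, n_bits, run_cfg)
        hits += result.best_brightness == target
    return OracleCheck("onemax", n_bits, len(seeds), hits / len(seeds))


def random_landscape_oracle_check(
    n_bits: int = 12, seeds=range(20), landscape_seed: int = 12345, cfg: BFAConfig | None = None
) -> OracleCheck:
    """BFA vs brute force on a random landscape with a unique optimum.

    The landscape assigns each of the 2^n bit strings a distinct value (a
    seeded permutation), so the global optimum is unique and the search
    gets no gradient structure to lean on.
    """
    values = np.random.default_rng(landscape_seed).permutation(1 << n_bits).astype(float)
    weights = 1 << np.arange(n_bits)[::-1]

    def objective(bits):
        return float(values[int(np.dot(bits, weights))])

    target = float(values.max())
    hits = 0
    seeds = list(seeds)
    for seed in seeds:
        base = cfg if cfg is not None else BFAConfig()
        run_cfg = BFAConfig(
            population_size=base.population_size,
            max_iterations=base.max_iterations,
            gamma_fa=base.gamma_fa,
            beta0=base.beta0,
            rng_seed=seed,
            elitism=base.elitism,
        )
        result = bfa.optimize(objective, n_bits, run_cfg)
        hits += result.best_brightness == target
    return OracleCheck("random-unique-optimum", n_bits, len(seeds), hits / len(seeds))


@dataclass
class OperatorLawStats:
    """Monte-Carlo statistics of the attraction and mutation operators."""

    n_trials: int
    n_bits: int
    beta: float
    alpha: float
    attract_mean_flips: float  # over differing bits, expect beta * d
    attract_expected: float
    attract_z: float  # deviation in binomial sigmas
    mutate_mean_flips: float  # expect alpha * n
    mutate_expected: float
    mutate_z: float


def operator_law_stats(
    n_trials: int = 10_000,
    n_bits: int = 32,
    beta: float = 0.3,
    alpha: float = 0.2,
    seed: int = 0,
) -> OperatorLawStats:
    """Check flip counts against their binomial laws over seeded trials.

    ``attract`` flips each of the d differing bits independently with
    probability beta, so flips ~ Binomial(d, beta); ``mutate`` flips each
    of the n bits with probability alpha, so flips ~ Binomial(n, alpha).
    """
    rng = np.random.default_rng(seed)
    mover = rng.integers(0, 2, n_bits).astype(np.uint8)
    brighter = 1 - mover  # all bits differ: d = n_bits
    a_flips = np.empty(n_trials)
    m_flips = np.empty(n_trials)
    for trial in range(n_trials):
        moved = attract(mover, brighter, beta, rng)
        a_flips[trial] = np.count_nonzero(moved != mover)
        mutated = mutate(mover, alpha, rng)
        m_flips[trial] = np.count_nonzero(mutated != mover)

    d = n_bits
    a_mean, a_exp = float(a_flips.mean()), beta * d
    a_sigma = np.sqrt(d * beta * (1 - beta) / n_trials)
    m_mean, m_exp = float(m_flips.mean()), alpha * n_bits
    m_sigma = np.sqrt(n_bits * alpha * (1 - alpha) / n_trials)
    return OperatorLawStats(
        n_trials=n_trials,
        n_bits=n_bits,
        beta=beta,
        alpha=alpha,
        attract_mean_flips=a_mean,
        attract_expected=a_exp,
        attract_z=(a_mean - a_exp) / a_sigma,
        mutate_mean_flips=m_mean,
        mutate_expected=m_exp,
        mutate_z=(m_mean - m_exp) / m_sigma,
    )


@dataclass
class RecoverySeedResult:
    seed: int
    n_selected: int
    precision: float
    recall: float
    test_mcc: float
    baseline_mcc: float
    best_intensity: float


@dataclass
class RecoverySummary:
    """Planted-feature recovery across seeds.

    ``union_recall`` is the recall of the union of all selected masks —
    how much of the planted set any run ever found.
    """

    per_seed: list[RecoverySeedResult]
    mean_recall: float
    mean_precision: float
    union_recall: float
    beats_baseline_fraction: float
    mean_test_mcc: float
    mean_baseline_mcc: float


def planted_recovery_experiment(
    seeds=range(1, 11),
    n_features: int = 30,
    n_informative: int = 5,
    delta_sep: float = 2.0,
    n_per_class: int = 100,
    population_size: int = 15,
    max_iterations: int = 100,
    train_fraction: float = 355.0 / 455.0,
    omega: float = 0.55,
) -> RecoverySummary:
    """End-to-end wrapper selection on data with known informative features.

    Per seed: generate the planted dataset, hold out a stratified test
    split, run the BFA search (reduced budget) on the training part, refit
    the decoded model, and score mask recovery plus held-out MCC against
    an all-features RBF-SVM at library defaults.
    """
    layout = FireflyLayout(w=n_features)
    per_seed: list[RecoverySeedResult] = []
    union = np.zeros(n_features, dtype=bool)
    truth = None
    for seed in seeds:
        spec = PlantedDatasetSpec(
            n_per_class=n_per_class,
            n_features=n_features,
            informative=tuple(range(n_informative)),
            delta_sep=delta_sep,
            seed=seed,
        )
        truth = spec.truth_mask
        X, y = gen_planted_dataset(spec)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_fraction, stratify=y, random_state=seed
        )
        cfg = BFAConfig(
            population_size=population_size,
            max_iterations=max_iterations,
            rng_seed=seed,
        )
        objective = make_objective(X_tr, y_tr, layout, omega=omega, eval_seed=seed)
        result = bfa.optimize(objective, layout.n, cfg)
        params, mask = decode(result.best_bits, layout)
        precision, recall = mask_recovery(mask, truth)
        union |= mask

        model = train_model(X_tr, y_tr, params, mask, layout=layout)
        pred, _ = model.predict(X_te)
        test_m = metrics(_pooled_counts(y_te, pred))
        baseline = SVC(C=1.0, gamma="scale", kernel="rbf").fit(X_tr, y_tr)
        base_m = metrics(_pooled_counts(y_te, baseline.predict(X_te)))
        per_seed.append(
            RecoverySeedResult(
                seed=seed,
                n_selected=int(mask.sum()),
                precision=precision,
                recall=recall,
                test_mcc=test_m.mcc,
                baseline_mcc=base_m.mcc,
                best_intensity=result.best_brightness,
            )
        )

    recalls = np.array([r.recall for r in per_seed])
    precisions = np.array([r.precision for r in per_seed])
    test_mccs = np.array([r.test_mcc for r in per_seed])
    base_mccs = np.array([r.baseline_mcc for r in per_seed])
    _, union_recall = mask_recovery(union, truth)
    return RecoverySummary(
        per_seed=per_seed,
        mean_recall=float(recalls.mean()),
        mean_precision=float(precisions.mean()),
        union_recall=union_recall,
        beats_baseline_fraction=float((test_mccs >= base_mccs).mean()),
        mean_test_mcc=float(test_mccs.mean()),
        mean_baseline_mcc=float(base_mccs.mean()),
    )


def random_mask_comparison(
    seeds=range(20),
    n_features: int = 30,
    delta_sep: float = 2.0,
    n_per_class: int = 100,
    population_size: int = 15,
    max_iterations: int = 60,
    omega: float = 0.55,
) -> tuple[float, float]:
    """Mean best intensity of BFA vs random masks of equal cardinality.

    For each seed the BFA best intensity is compared against a random
    firefly whose mask has the same number of selected features (parameter
    fields drawn at random), evaluated under the same objective.
    """
    layout = FireflyLayout(w=n_features)
    bfa_scores, random_scores = [], []
    for seed in seeds:
        spec = PlantedDatasetSpec(
            n_per_class=n_per_class,
            n_features=n_features,
            delta_sep=delta_sep,
            seed=seed,
        )
        X, y = gen_planted_dataset(spec)
        objective = make_objective(X, y, layout, omega=omega, eval_seed=seed)
        cfg = BFAConfig(
            population_size=population_size, max_iterations=max_iterations, rng_seed=seed
        )
        result = bfa.optimize(objective, layout.n, cfg)
        _, mask = decode(result.best_bits, layout)
        rng = np.random.default_rng(seed + 10_000)
        rand_bits = rng.integers(0, 2, layout.n).astype(np.uint8)
        rand_mask = np.zeros(n_features, dtype=np.uint8)
        rand_mask[rng.choice(n_features, size=max(int(mask.sum()), 1), replace=False)] = 1
        rand_bits[layout.mask_slice] = rand_mask
        bfa_scores.append(result.best_brightness)
        random_scores.append(objective(rand_bits))
    return float(np.mean(bfa_scores)), float(np.mean(random_scores))
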