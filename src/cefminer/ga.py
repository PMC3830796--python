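"""Genetic-algorithm search over the herb-subset space.

Candidate formulae are binary chromosomes, one gene per herb.  The fitness
of a chromosome is its effectiveness value (EV) when the coreness
constraints hold — support at the configured confidence level at least
``s_set`` and at least ``n_set`` herbs — and ``EV - R`` otherwise, with a
penalty constant ``R`` chosen larger than any attainable |EV| so that every
infeasible candidate ranks below every feasible one.

The generational loop is the classic evaluate → tournament-select →
multipoint-crossover → mutate cycle.  Mutation defaults to a three-gene
cyclic swap (a random 3-cycle of gene values, preserving the herb count);
a per-gene bit-flip alternative is available.  The returned candidates are
the final generation's positive-fitness chromosomes, deduplicated and
sorted by fitness.

Fitness evaluation is vectorised across the whole population: coverage of
every record by every chromosome is one integer matrix product, from which
supports and group effective proportions follow by column reductions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .metrics import (
    REPORT_LEVELS,
    CEFCandidate,
    patient_based_support,
)
from .records import AnalysisTable, ValidationError

__all__ = [
    "FitnessConfig",
    "GAConfig",
    "Individual",
    "CEFResult",
    "init_population",
    "evaluate_population",
    "fitness",
    "tournament_select",
    "multipoint_crossover",
    "three_gene_swap",
    "bit_flip",
    "run_ga",
]


@dataclass(frozen=True)
class FitnessConfig:
    """Constraint and penalty parameters of the fitness function.

    R : penalty subtracted from EV for infeasible candidates (study value 200).
    n_set : minimum number of herbs in a candidate (study range 8–11).
    level : confidence level used for both the support constraint and the
        CEF/non-CEF group split (study value 1).
    s_set : minimum support at that level (study values 2–10 %).
    """

    R: float = 200.0
    n_set: int = 8
    level: float = 1.0
    s_set: float = 0.02

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValidationError("penalty R must be positive")
        if self.n_set < 1:
            raise ValidationError("n_set must be >= 1")
        if not 0.0 < self.level <= 1.0:
            raise ValidationError("level must be in (0, 1]")
        if not 0.0 < self.s_set < 1.0:
            raise ValidationError("s_set must be in (0, 1)")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm run parameters.

    Defaults follow the study configuration: population 1000, 200
    generations, crossover probability 0.7, tournament size 15, and initial
    gene probability ``p_init = k * n_set / m`` with ``k = 1``.
    """

    pop_size: int = 1000
    generations: int = 200
    k: float = 1.0
    p_crossover: float = 0.7
    tournament_size: int = 15
    crossover_points: int = 2
    mutation: str = "swap3"  # or "bitflip"
    mutation_rate: float = 1.0  # swaps per offspring, or per-gene flip prob
    elitism: bool = False
    n_elite: int = 1  # individuals retained per generation when elitism is on
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValidationError("pop_size must be >= 2")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if not 0.0 <= self.p_crossover <= 1.0:
            raise ValidationError("p_crossover must be in [0, 1]")
        if not 1 <= self.tournament_size <= self.pop_size:
            raise ValidationError("tournament_size must be in [1, pop_size]")
        if self.crossover_points < 1:
            raise ValidationError("crossover_points must be >= 1")
        if self.mutation not in ("swap3", "bitflip"):
            raise ValidationError(f"unknown mutation operator: {self.mutation!r}")
        if not 1 <= self.n_elite < self.pop_size:
            raise ValidationError("n_elite must be in [1, pop_size)")

    def p_init(self, m: int, n_set: int) -> float:
        """Initial per-gene probability of a 1, ``k * n_set / m``."""
        p = self.k * n_set / m
        if not 0.0 < p < 1.0:
            raise ValidationError(
                f"p_init = k*n_set/m = {p:.3f} outside (0, 1); "
                "large k filters out feasible solutions"
            )
        return p


@dataclass
class Individual:
    """One chromosome with a cached fitness value."""

    chromosome: np.ndarray
    fitness: float | None = None


@dataclass(frozen=True)
class CEFResult:
    """A positive-fitness candidate annotated with its coreness report."""

    candidate: CEFCandidate
    fitness: float
    ev: float
    alpha: float
    support_at: dict[float, float]
    pbs: float

    @property
    def n_herbs(self) -> int:
        return self.candidate.N


def init_population(
    ga_cfg: GAConfig, m: int, n_set: int, rng: np.random.Generator
) -> np.ndarray:
    """Random initial population: each gene independently 1 with ``p_init``."""
    p = ga_cfg.p_init(m, n_set)
    return (rng.random((ga_cfg.pop_size, m)) < p).astype(np.uint8)


def evaluate_population(
    pop: np.ndarray, table: AnalysisTable, f_cfg: FitnessConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness and EV of every chromosome in one vectorised pass.

    Returns ``(fitness, ev)`` arrays.  Chromosomes whose EV is undefined
    (empty chromosome, empty group, or zero pooled spread) take the penalty
    sentinel ``-R`` as fitness with ``ev`` reported as ``nan``.
    """
    X = table.X.astype(np.float32)
    y = table.outcome.astype(np.float32)
    n = X.shape[0]
    K = float(y.sum())

    N = pop.sum(axis=1).astype(np.int64)
    # coverage >= level  <=>  |CEF ∩ x| >= ceil(level * N); counts are exact
    # small integers in float32, so the comparison is float-safe
    counts = X @ pop.T.astype(np.float32)  # (n, pop)
    thr = np.ceil(f_cfg.level * N - 1e-9)
    in_cef = counts >= np.maximum(thr, 1.0)
    sup = in_cef.mean(axis=0)
    n1 = in_cef.sum(axis=0)
    k1 = (y @ in_cef).astype(np.float64)
    n0 = n - n1
    k0 = K - k1

    with np.errstate(divide="ignore", invalid="ignore"):
        ep1 = np.where(n1 > 0, k1 / np.maximum(n1, 1), np.nan)
        ep0 = np.where(n0 > 0, k0 / np.maximum(n0, 1), np.nan)
        pooled = (k1 + k0) / n
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n0, 1)))
        ev = (ep1 - ep0) / se

    defined = (N >= 1) & (n1 > 0) & (n0 > 0) & (se > 0)
    ev = np.where(defined, ev, np.nan)

    feasible = defined & (sup >= f_cfg.s_set) & (N >= f_cfg.n_set)
    fit = np.where(
        feasible,
        np.nan_to_num(ev),
        np.where(defined, np.nan_to_num(ev) - f_cfg.R, -f_cfg.R),
    )
    return fit, ev


def fitness(ind: Individual, table: AnalysisTable, f_cfg: FitnessConfig) -> float:
    """Fitness of one chromosome; caches the value on the individual."""
    fit, _ = evaluate_population(ind.chromosome[None, :], table, f_cfg)
    ind.fitness = float(fit[0])
    return ind.fitness


def tournament_select(
    fit: np.ndarray, tournament_size: int, rng: np.random.Generator, n_winners: int
) -> np.ndarray:
    """Indices of ``n_winners`` tournament winners (draws with replacement).

    Each tournament draws ``tournament_size`` entrants uniformly with
    replacement and keeps the fittest; ties are broken uniformly at random.
    """
    pop_size = len(fit)
    entrants = rng.integers(0, pop_size, size=(n_winners, tournament_size))
    f = fit[entrants]
    best = f.max(axis=1, keepdims=True)
    tied = f == best
    # random tie-break: maximise a random key restricted to the tied entrants
    key = rng.random(f.shape)
    pick = np.argmax(np.where(tied, key, -1.0), axis=1)
    return entrants[np.arange(n_winners), pick]


def multipoint_crossover(
    a: np.ndarray,
    b: np.ndarray,
    crossover_points: int,
    p_crossover: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Multipoint crossover of two equal-length chromosomes.

    With probability ``p_crossover``, ``crossover_points`` distinct cut
    points are drawn from the m-1 internal boundaries and the children
    alternate parental segments; otherwise the children are copies.  At
    every locus the child pair carries exactly the parents' gene multiset.
    """
    m = len(a)
    if len(b) != m:
        raise ValidationError("parent chromosomes differ in length")
    if crossover_points >= m:
        raise ValidationError("crossover_points must be < chromosome length")
    if rng.random() >= p_crossover:
        return a.copy(), b.copy()
    cuts = rng.choice(m - 1, size=crossover_points, replace=False) + 1
    swap = np.zeros(m, dtype=bool)
    for c in np.sort(cuts):
        swap[c:] = ~swap[c:]
    c1 = np.where(swap, b, a).astype(a.dtype)
    c2 = np.where(swap, a, b).astype(a.dtype)
    return c1, c2


def three_gene_swap(chrom: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cyclic 3-permutation of three randomly chosen genes.

    Values move locus1 → locus2 → locus3 → locus1; the herb count is
    preserved for every draw.
    """
    m = len(chrom)
    if m < 3:
        raise ValidationError("three-gene swap needs >= 3 genes")
    loci = rng.choice(m, size=3, replace=False)
    out = chrom.copy()
    out[loci[1]] = chrom[loci[0]]
    out[loci[2]] = chrom[loci[1]]
    out[loci[0]] = chrom[loci[2]]
    return out


def bit_flip(chrom: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-gene flips with probability ``rate``."""
    flips = rng.random(len(chrom)) < rate
    return np.where(flips, 1 - chrom, chrom).astype(chrom.dtype)


def _crossover_all(
    parents: np.ndarray, ga_cfg: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised multipoint crossover over consecutive parent pairs."""
    n, m = parents.shape
    n_pairs = n // 2
    a = parents[0 : 2 * n_pairs : 2]
    b = parents[1 : 2 * n_pairs : 2]
    k = ga_cfg.crossover_points
    # k distinct cut points per pair among the m-1 internal boundaries
    keys = rng.random((n_pairs, m - 1))
    cuts = np.argpartition(keys, k - 1, axis=1)[:, :k] + 1
    ind = np.zeros((n_pairs, m), dtype=np.int8)
    np.put_along_axis(ind, cuts, 1, axis=1)
    swap = np.cumsum(ind, axis=1) % 2 == 1
    apply = rng.random(n_pairs) < ga_cfg.p_crossover
    swap &= apply[:, None]
    children = parents.copy()
    children[0 : 2 * n_pairs : 2] = np.where(swap, b, a)
    children[1 : 2 * n_pairs : 2] = np.where(swap, a, b)
    return children


def _mutate_all(pop: np.ndarray, ga_cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the configured mutation to every offspring, vectorised."""
    n, m = pop.shape
    if ga_cfg.mutation == "bitflip":
        rate = min(ga_cfg.mutation_rate, 1.0) if ga_cfg.mutation_rate < 1.0 else 1.0 / m
        flips = rng.random(pop.shape) < rate
        return np.where(flips, 1 - pop, pop).astype(np.uint8)
    # swap3: mutation_rate = expected number of swaps per offspring
    out = pop.copy()
    n_rounds = int(math.ceil(ga_cfg.mutation_rate))
    p_apply = ga_cfg.mutation_rate / n_rounds
    for _ in range(n_rounds):
        apply = rng.random(n) < p_apply
        # three distinct loci per row via partial argsort of random keys
        keys = rng.random((n, m))
        loci = np.argpartition(keys, 3, axis=1)[:, :3]
        rows = np.arange(n)
        v0 = out[rows, loci[:, 0]].copy()
        v1 = out[rows, loci[:, 1]].copy()
        v2 = out[rows, loci[:, 2]].copy()
        nv1 = np.where(apply, v0, v1)
        nv2 = np.where(apply, v1, v2)
        nv0 = np.where(apply, v2, v0)
        out[rows, loci[:, 1]] = nv1
        out[rows, loci[:, 2]] = nv2
        out[rows, loci[:, 0]] = nv0
    return out


@dataclass
class GARunLog:
    """Per-generation best and mean fitness, for convergence diagnostics."""

    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)


def run_ga(
    table: AnalysisTable,
    ga_cfg: GAConfig,
    f_cfg: FitnessConfig,
    rng: np.random.Generator | None = None,
    log: GARunLog | None = None,
) -> list[CEFResult]:
    """Run the generational GA and return deduplicated positive-fitness CEF.

    The final generation's chromosomes with fitness > 0 are deduplicated by
    exact chromosome equality, annotated with their coreness report
    (average confidence, supports at 0.7/0.8/0.9/1, patient-based support)
    and EV, and returned sorted by fitness descending.  An empty list is a
    legal outcome (no feasible candidate found).
    """
    if rng is None:
        rng = np.random.default_rng(ga_cfg.seed)
    m = table.m
    pop = init_population(ga_cfg, m, f_cfg.n_set, rng)
    fit, _ = evaluate_population(pop, table, f_cfg)

    for _ in range(ga_cfg.generations):
        if log is not None:
            log.best.append(float(fit.max()))
            log.mean.append(float(fit.mean()))
        winners = tournament_select(fit, ga_cfg.tournament_size, rng, ga_cfg.pop_size)
        parents = pop[winners]
        children = _crossover_all(parents, ga_cfg, rng)
        children = _mutate_all(children, ga_cfg, rng)
        if ga_cfg.elitism:
            k = ga_cfg.n_elite
            elite = np.argsort(fit)[::-1][:k]
            children[:k] = pop[elite]
        pop = children
        fit, _ = evaluate_population(pop, table, f_cfg)

    if log is not None:
        log.best.append(float(fit.max()))
        log.mean.append(float(fit.mean()))

    positive = np.flatnonzero(fit > 0)
    unique: dict[bytes, int] = {}
    for i in positive:
        key = pop[i].tobytes()
        if key not in unique:
            unique[key] = i
    order = sorted(unique.values(), key=lambda i: -fit[i])

    results: list[CEFResult] = []
    _, ev = evaluate_population(pop[order], table, f_cfg) if order else (None, None)
    for rank, i in enumerate(order):
        cand = CEFCandidate(pop[i])
        cov = (table.X.astype(np.int64) @ cand.herb_bits.astype(np.int64)) / cand.N
        results.append(
            CEFResult(
                candidate=cand,
                fitness=float(fit[i]),
                ev=float(ev[rank]),
                alpha=float(cov.mean()),
                support_at={lv: float((cov >= lv).mean()) for lv in REPORT_LEVELS},
                pbs=patient_based_support(cand, table, level=f_cfg.level),
            )
        )
    return results
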