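"""Synthetic longitudinal prescription cohorts with plantable formulae.

The generator emulates the shape of an inpatient herbal-therapy cohort:
150 patients by default, 1–9 visits each (mean near 4), prescriptions of
9–36 herbs (mean 23) drawn without replacement from a 230-herb vocabulary
under a long-tailed (Zipf–Mandelbrot) popularity law calibrated so the most
popular herb appears in roughly two thirds of prescriptions, and a baseline
effective proportion of 0.22.

Outcomes are controlled at generation time: for every consecutive visit
pair an effectiveness flag is drawn (elevated probability when the
prescription fully contains a planted formula, baseline otherwise) and the
next visit's symptom scores are constructed so that the symptom change
value crosses the 30 % threshold exactly when the flag is set.  This
inversion makes every downstream metric testable against known ground
truth without modelling disease dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import (
    AnalysisTable,
    HerbVocabulary,
    ValidationError,
    VisitRecord,
    build_analysis_table,
)

__all__ = [
    "PlantedCEF",
    "SyntheticConfig",
    "tiny_config",
    "study_config",
    "generate_cohort",
    "generate_analysis_table",
    "make_symptom_trajectory",
    "zipf_weights",
]

N_SYMPTOMS_DEFAULT = 15
VISIT_RANGE = (1, 9)
PRESC_SIZE_RANGE = (9, 36)


@dataclass(frozen=True)
class PlantedCEF:
    """A formula planted into the cohort with known support and effect.

    ``support`` is the target fraction of analysis records fully containing
    the formula; ``group_ep`` the outcome-1 probability of those records.
    """

    herb_indices: tuple[int, ...]
    support: float
    group_ep: float

    def __post_init__(self) -> None:
        if not 0.0 < self.support < 1.0:
            raise ValidationError("planted support must be in (0, 1)")
        if not 0.0 <= self.group_ep <= 1.0:
            raise ValidationError("planted group_ep must be in [0, 1]")
        object.__setattr__(self, "herb_indices", tuple(sorted(set(self.herb_indices))))


def zipf_weights(m: int, s: float = 1.0, q: float = 6.0) -> np.ndarray:
    """Zipf–Mandelbrot popularity weights ``w_j ∝ 1 / (j + 1 + q)^s``.

    The defaults put roughly two thirds of prescriptions on the top herb
    when 23 herbs are sampled without replacement from 230.
    """
    ranks = np.arange(1, m + 1, dtype=float)
    w = (ranks + q) ** (-s)
    return w / w.sum()


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-shape parameters; defaults mirror the emulated study cohort."""

    n_patients: int = 150
    m: int = 230
    n_symptoms: int = N_SYMPTOMS_DEFAULT
    visit_mean: float = 4.0  # mean of 1 + Poisson(visit_mean - 1), truncated to <= 9
    presc_size_mean: float = 23.0
    presc_size_range: tuple[int, int] = PRESC_SIZE_RANGE
    herb_popularity: np.ndarray | None = None
    baseline_ep: float = 0.22
    planted_cefs: tuple[PlantedCEF, ...] = ()
    n_templates: int = 0  # optional shared base formulas (0 = pure popularity)
    template_size: int = 15
    template_adherence: float = 0.8  # per-herb retention of the base formula
    persistence: float = 0.8  # per-herb retention between a patient's visits
    p_remission: float = 0.03  # chance an effective step clears all symptoms
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.m < 2:
            raise ValidationError("need >= 1 patient and >= 2 herbs")
        if not 0.0 <= self.baseline_ep <= 1.0:
            raise ValidationError("baseline_ep must be in [0, 1]")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValidationError("persistence must be in [0, 1]")
        if self.n_templates < 0 or not 0.0 <= self.template_adherence <= 1.0:
            raise ValidationError("invalid template parameters")
        if self.n_templates > 0 and not 1 <= self.template_size <= self.m:
            raise ValidationError("template_size must be in [1, m]")
        lo, hi = self.presc_size_range
        if not 1 <= lo <= hi:
            raise ValidationError("invalid prescription-size range")
        if not lo <= self.presc_size_mean <= min(hi, self.m):
            raise ValidationError("presc_size_mean outside the prescription-size range")
        for cef in self.planted_cefs:
            if max(cef.herb_indices, default=0) >= self.m:
                raise ValidationError("planted herb index outside vocabulary")
            if len(cef.herb_indices) > min(hi, self.m):
                raise ValidationError(
                    "planted formula larger than the maximum prescription size"
                )
        if self.herb_popularity is not None:
            w = np.asarray(self.herb_popularity, dtype=float)
            if w.shape != (self.m,) or (w < 0).any() or w.sum() <= 0:
                raise ValidationError("herb_popularity must be m non-negative weights")
            object.__setattr__(self, "herb_popularity", w / w.sum())

    def weights(self) -> np.ndarray:
        if self.herb_popularity is not None:
            return self.herb_popularity
        return zipf_weights(self.m)

    def vocabulary(self) -> HerbVocabulary:
        width = len(str(self.m))
        return HerbVocabulary(tuple(f"herb_{j + 1:0{width}d}" for j in range(self.m)))


def tiny_config(seed: int | None = None, **overrides) -> SyntheticConfig:
    """Small fixture: 8 patients, 12 herbs — sized for exhaustive oracles."""
    defaults = dict(
        n_patients=8, m=12, presc_size_mean=6.0, presc_size_range=(3, 9),
        visit_mean=4.0, seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def study_config(seed: int | None = None, **overrides) -> SyntheticConfig:
    """Study-shaped cohort: 150 patients, 230 herbs, baseline EP 0.22."""
    return SyntheticConfig(seed=seed, **overrides)


def _draw_visit_counts(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lam = max(cfg.visit_mean - 1.0, 0.1)
    counts = 1 + rng.poisson(lam, size=cfg.n_patients)
    return np.clip(counts, *VISIT_RANGE)


def _draw_presc_size(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    lo = cfg.presc_size_range[0]
    hi = min(cfg.presc_size_range[1], cfg.m)
    if hi <= lo:
        return hi
    span = hi - lo
    p = (cfg.presc_size_mean - lo) / span
    return int(lo + rng.binomial(span, p))


def _sample_prescription(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    weights: np.ndarray,
    forced: Sequence[int] = (),
    template: Sequence[int] = (),
    previous: frozenset[int] | None = None,
) -> frozenset[int]:
    """One prescription: forced herbs, base formula, carry-over, then fill.

    Composition mirrors clinical prescribing: any planted (forced) herbs
    come first; each herb of the patient's base formula (template) is kept
    with probability ``cfg.template_adherence``; each herb of the previous
    visit's prescription is retained with probability ``cfg.persistence``
    (the incremental add/remove adaptation between consecutive visits); the
    remainder is drawn by popularity-weighted sampling without replacement.
    """
    size = max(_draw_presc_size(cfg, rng), len(forced))
    chosen = set(forced)
    kept = [h for h in template if rng.random() < cfg.template_adherence]
    rng.shuffle(kept)
    if previous is not None and cfg.persistence > 0.0:
        carried = [h for h in previous if rng.random() < cfg.persistence]
        rng.shuffle(carried)
        kept += carried
    for h in kept:
        if len(chosen) >= size:
            break
        chosen.add(int(h))
    if len(chosen) < size:
        remaining = np.setdiff1d(np.arange(cfg.m), np.fromiter(chosen, dtype=int, count=len(chosen)))
        w = weights[remaining]
        extra = rng.choice(remaining, size=size - len(chosen), replace=False, p=w / w.sum())
        chosen.update(int(j) for j in extra)
    return frozenset(chosen)


def _scores_from_total(total: int, n_symptoms: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Random split of a total into n per-symptom scores, each at most 3."""
    capacity = 3 * n_symptoms
    if not 0 <= total <= capacity:
        raise ValidationError(f"total {total} outside [0, {capacity}]")
    if total == 0:
        return (0,) * n_symptoms
    slots = rng.choice(capacity, size=total, replace=False)
    counts = np.bincount(slots // 3, minlength=n_symptoms)
    return tuple(int(c) for c in counts)


def _next_total(
    prev: int, effective: bool, cap: int, p_remission: float, rng: np.random.Generator
) -> int:
    """Next-visit symptom total realizing (or not) a >= 30 % reduction."""
    if effective:
        hi = math.floor(0.7 * prev)  # (prev - next)/prev >= 0.3  <=>  next <= 0.7 prev
        if hi < 1 or rng.random() < p_remission:
            return 0
        return int(rng.integers(1, hi + 1))
    lo = math.floor(0.7 * prev) + 1  # smallest total with SCV < 0.3
    hi = min(cap, prev + 6)
    if lo > hi:
        lo = hi
    return int(rng.integers(lo, hi + 1))


def make_symptom_trajectory(
    effective: int, rng: np.random.Generator, n_symptoms: int = N_SYMPTOMS_DEFAULT
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """One consecutive-visit score pair with the requested outcome.

    The previous total is always positive, so the symptom change value is
    defined; it crosses the 30 % threshold exactly when ``effective`` is 1.
    """
    prev_total = int(rng.integers(10, 31))
    next_total = _next_total(prev_total, bool(effective), 3 * n_symptoms, 0.0, rng)
    return (
        _scores_from_total(prev_total, n_symptoms, rng),
        _scores_from_total(next_total, n_symptoms, rng),
    )


def generate_cohort(cfg: SyntheticConfig) -> list[VisitRecord]:
    """Generate a full synthetic visit list; reproducible given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    weights = cfg.weights()
    herb_names = cfg.vocabulary().herbs
    visits: list[VisitRecord] = []
    id_width = len(str(cfg.n_patients))
    visit_counts = _draw_visit_counts(cfg, rng)

    planted_sets = [set(c.herb_indices) for c in cfg.planted_cefs]
    templates: list[np.ndarray] = [
        rng.choice(cfg.m, size=min(cfg.template_size, cfg.m), replace=False, p=weights)
        for _ in range(cfg.n_templates)
    ]

    for p in range(cfg.n_patients):
        pid = f"P{p + 1:0{id_width}d}"
        k = int(visit_counts[p])
        template: Sequence[int] = (
            templates[int(rng.integers(cfg.n_templates))] if templates else ()
        )

        prescriptions: list[frozenset[int]] = []
        for j in range(k):
            forced: Sequence[int] = ()
            if j < k - 1 and cfg.planted_cefs:  # only evaluable visits can carry
                for cef in cfg.planted_cefs:
                    if rng.random() < cef.support:
                        forced = cef.herb_indices
                        break
            prev = prescriptions[-1] if prescriptions else None
            prescriptions.append(
                _sample_prescription(cfg, rng, weights, forced,
                                     template=template, previous=prev)
            )

        totals = [int(rng.integers(10, 31))]
        for j in range(k - 1):
            if totals[j] == 0:
                # outcome unobservable; continue the trajectory arbitrarily
                totals.append(int(rng.integers(5, 20)))
                continue
            ep = cfg.baseline_ep
            for cef, cef_set in zip(cfg.planted_cefs, planted_sets):
                if cef_set <= prescriptions[j]:
                    ep = cef.group_ep
                    break
            effective = rng.random() < ep
            totals.append(
                _next_total(totals[j], effective, 3 * cfg.n_symptoms,
                            cfg.p_remission, rng)
            )

        for j in range(k):
            visits.append(
                VisitRecord(
                    patient_id=pid,
                    visit_index=j + 1,
                    symptom_scores=_scores_from_total(totals[j], cfg.n_symptoms, rng),
                    herbs=frozenset(herb_names[h] for h in prescriptions[j]),
                )
            )
    return visits


def generate_analysis_table(cfg: SyntheticConfig) -> AnalysisTable:
    """Generate a cohort and preprocess it into the binary analysis table."""
    vocab = cfg.vocabulary()
    return build_analysis_table(generate_cohort(cfg), vocab)
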