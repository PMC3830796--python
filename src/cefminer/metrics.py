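"""Coreness and effectiveness metrics for candidate herb formulae.

A candidate core effective formula (CEF) is a subset of the herb vocabulary,
encoded as a binary vector.  Its *coreness* is measured by how completely it
is embedded in the prescriptions of a cohort:

* coverage of a record — fraction of the candidate's herbs present in that
  prescription;
* average confidence ``alpha`` — mean coverage over all records;
* support ``S_level`` — fraction of records whose coverage reaches ``level``
  (at level 1 this is classic itemset support);
* patient-based support (PBS) — fraction of patients with at least one
  qualifying record, guarding against one frequently-returning patient
  inflating record-based support.

Its *effectiveness* is measured by splitting records into a CEF group
(coverage >= level) and a non-CEF group and standardising the difference in
effective proportions by the pooled standard error — the effectiveness value
(EV) that the genetic algorithm maximises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import AnalysisTable, HerbVocabulary, ValidationError

__all__ = [
    "UndefinedEVError",
    "CEFCandidate",
    "CoverageProfile",
    "GroupSplit",
    "coverage",
    "coverage_vector",
    "average_confidence",
    "support",
    "patient_based_support",
    "coverage_profile",
    "split_groups",
    "effectiveness_value",
]

#: Support levels conventionally reported alongside a candidate formula.
REPORT_LEVELS = (0.7, 0.8, 0.9, 1.0)


class UndefinedEVError(ValueError):
    """An effectiveness value cannot be computed (empty group or zero spread)."""


@dataclass(frozen=True)
class CEFCandidate:
    """A candidate formula: one bit per herb of the vocabulary."""

    herb_bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.herb_bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValidationError("herb_bits must be a 1-D binary vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValidationError("herb_bits must be binary")
        if bits.sum() < 1:
            raise ValidationError("a candidate formula needs at least one herb")
        object.__setattr__(self, "herb_bits", bits)

    @property
    def N(self) -> int:
        """Number of herbs in the candidate."""
        return int(self.herb_bits.sum())

    def herb_indices(self) -> np.ndarray:
        return np.flatnonzero(self.herb_bits)

    def herb_names(self, vocab: HerbVocabulary) -> tuple[str, ...]:
        return tuple(vocab.herbs[j] for j in self.herb_indices())

    @classmethod
    def from_indices(cls, indices: Iterable[int], m: int) -> "CEFCandidate":
        bits = np.zeros(m, dtype=np.uint8)
        bits[list(indices)] = 1
        return cls(bits)

    @classmethod
    def from_names(cls, names: Iterable[str], vocab: HerbVocabulary) -> "CEFCandidate":
        return cls.from_indices([vocab.index(n) for n in names], vocab.m)


@dataclass(frozen=True)
class CoverageProfile:
    """Per-record coverages of a candidate plus derived coreness summaries."""

    coverages: np.ndarray
    alpha: float
    support_at: Mapping[float, float]


@dataclass(frozen=True)
class GroupSplit:
    """Partition of analysis records into CEF and non-CEF groups.

    ``ep1``/``ep0`` are the effective proportions of the two groups
    (``nan`` for an empty group).
    """

    cef_indices: np.ndarray
    noncef_indices: np.ndarray
    n1: int
    k1: int
    n0: int
    k0: int

    @property
    def ep1(self) -> float:
        return self.k1 / self.n1 if self.n1 > 0 else math.nan

    @property
    def ep0(self) -> float:
        return self.k0 / self.n0 if self.n0 > 0 else math.nan


def _as_matrix(data) -> np.ndarray:
    X = data.X if isinstance(data, AnalysisTable) else np.asarray(data)
    if X.ndim != 2:
        raise ValidationError("prescriptions must form a 2-D binary matrix")
    return X


def coverage(cef: CEFCandidate, prescription: Sequence[int]) -> float:
    """Fraction of the candidate's herbs present in one prescription."""
    p = np.asarray(prescription, dtype=np.uint8)
    if p.shape != cef.herb_bits.shape:
        raise ValidationError("prescription and candidate lengths differ")
    return float((p & cef.herb_bits).sum() / cef.N)


def coverage_vector(cef: CEFCandidate, data) -> np.ndarray:
    """Coverages of every record; vectorised ``X @ bits / N``."""
    X = _as_matrix(data)
    if X.shape[0] == 0:
        raise ValidationError("empty dataset")
    if X.shape[1] != cef.herb_bits.shape[0]:
        raise ValidationError("matrix width and candidate length differ")
    return (X @ cef.herb_bits.astype(np.int64)) / cef.N


def average_confidence(cef: CEFCandidate, data) -> float:
    """Mean coverage over all records (``alpha``); 1 iff every prescription
    carries the complete candidate formula."""
    return float(coverage_vector(cef, data).mean())


def support(cef: CEFCandidate, data, level: float) -> float:
    """Fraction of records covering the candidate at the given confidence level."""
    if not 0.0 <= level <= 1.0:
        raise ValidationError(f"level must be in [0, 1], got {level}")
    cov = coverage_vector(cef, data)
    return float((cov >= level).mean())


def patient_based_support(
    cef: CEFCandidate, table: AnalysisTable, level: float = 1.0
) -> float:
    """Fraction of distinct patients with >= 1 record covering the candidate."""
    if table.n == 0:
        raise ValidationError("empty dataset")
    cov = coverage_vector(cef, table)
    qualifying = np.unique(table.patient_ids[cov >= level])
    return len(qualifying) / table.n_patients


def coverage_profile(
    cef: CEFCandidate, data, levels: Sequence[float] = REPORT_LEVELS
) -> CoverageProfile:
    """Coverages, average confidence, and supports at the reporting levels."""
    cov = coverage_vector(cef, data)
    return CoverageProfile(
        coverages=cov,
        alpha=float(cov.mean()),
        support_at={lv: float((cov >= lv).mean()) for lv in levels},
    )


def split_groups(cef: CEFCandidate, table: AnalysisTable, level: float = 1.0) -> GroupSplit:
    """Partition records by coverage: CEF group (coverage >= level) vs rest."""
    if not 0.0 < level <= 1.0:
        raise ValidationError(f"level must be in (0, 1], got {level}")
    cov = coverage_vector(cef, table)
    in_cef = cov >= level
    y = table.outcome
    return GroupSplit(
        cef_indices=np.flatnonzero(in_cef),
        noncef_indices=np.flatnonzero(~in_cef),
        n1=int(in_cef.sum()),
        k1=int(y[in_cef].sum()),
        n0=int((~in_cef).sum()),
        k0=int(y[~in_cef].sum()),
    )


def effectiveness_value(split: GroupSplit) -> float:
    """Standardised difference in effective proportions between the groups.

    ``EV = (ep1 - ep0) / SE`` with the pooled standard error
    ``SE = sqrt(p(1-p)(1/n1 + 1/n0))`` where ``p`` is the pooled effective
    proportion.  The sign follows ``ep1 - ep0``; larger is better.
    """
    if split.n1 == 0 or split.n0 == 0:
        raise UndefinedEVError("both groups must be non-empty")
    pooled = (split.k1 + split.k0) / (split.n1 + split.n0)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / split.n1 + 1.0 / split.n0))
    if se == 0.0:
        raise UndefinedEVError("all outcomes identical: zero pooled standard error")
    return (split.ep1 - split.ep0) / se
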