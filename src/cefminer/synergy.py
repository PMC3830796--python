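"""Pairwise herb synergy: stratified effective proportions and synergy index.

For a herb pair (a, b) the records are stratified into co-use (both herbs
present), a-without-b and b-without-a.  ``E11``, ``E01`` and ``E10`` are the
effective proportions of these strata and the synergy index is

    SI = E11 / max(E01, E10).

SI = 1 means co-prescription offers no advantage over the better herb used
without the other; SI > 1 suggests synergy.  Significance is assessed by
permuting the outcome labels across all records (prescriptions fixed) and
recomputing SI; the one-sided P value uses add-one smoothing,
``p = (1 + #{SI_perm >= SI_obs}) / (B + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .records import AnalysisTable, HerbVocabulary, ValidationError

__all__ = [
    "UndefinedSIError",
    "PairStrata",
    "PairSynergy",
    "pair_ep",
    "synergy_index",
    "permutation_test_si",
    "screen_pairs",
]


class UndefinedSIError(ValueError):
    """The synergy index is undefined (empty stratum or zero denominator)."""


@dataclass(frozen=True)
class PairStrata:
    """Effective proportions and sizes of the three pair strata."""

    e11: float
    e01: float
    e10: float
    n11: int
    n01: int
    n10: int

    @property
    def defined(self) -> bool:
        return min(self.n11, self.n01, self.n10) > 0


@dataclass(frozen=True)
class PairSynergy:
    """Synergy screening result for one herb pair."""

    herb_a: int
    herb_b: int
    e11: float
    e01: float
    e10: float
    si: float
    p_perm: float
    n11: int
    n01: int
    n10: int


def _xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, AnalysisTable):
        return data.X, np.asarray(data.outcome)
    raise ValidationError("expected an AnalysisTable")


def pair_ep(data: AnalysisTable, a: int, b: int) -> PairStrata:
    """Stratum effective proportions for a herb pair.

    An empty stratum leaves its proportion as ``nan`` and marks the pair
    undefined (it is excluded from synergy screening).
    """
    if a == b:
        raise ValidationError("pair requires two distinct herbs")
    X, y = _xy(data)
    ha, hb = X[:, a] > 0, X[:, b] > 0
    m11, m01, m10 = ha & hb, ha & ~hb, hb & ~ha

    def ep(mask: np.ndarray) -> float:
        return float(y[mask].mean()) if mask.any() else math.nan

    return PairStrata(
        e11=ep(m11), e01=ep(m01), e10=ep(m10),
        n11=int(m11.sum()), n01=int(m01.sum()), n10=int(m10.sum()),
    )


def synergy_index(e11: float, e01: float, e10: float) -> float:
    """``SI = E11 / max(E01, E10)``; raises when the denominator is not positive."""
    denom = max(e01, e10)
    if math.isnan(e11) or math.isnan(denom) or denom <= 0.0:
        raise UndefinedSIError("max(E01, E10) must be positive")
    return e11 / denom


def _si_from_counts(k11, n11, k01, n01, k10, n10):
    """Vectorised SI from stratum positive counts; nan where undefined."""
    e11 = k11 / n11
    denom = np.maximum(k01 / n01, k10 / n10)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.where(denom > 0, e11 / denom, np.nan)
    return si


def permutation_test_si(
    data: AnalysisTable,
    a: int,
    b: int,
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
    max_rounds: int = 50,
) -> float:
    """One-sided permutation P value for the synergy index of a pair.

    Outcome labels are permuted uniformly across all records with the
    prescriptions fixed; permutations yielding an undefined SI (the better
    solo stratum has no positives) are redrawn, so the null distribution is
    conditional on SI being defined.  ``p = (1 + #{SI >= SI_obs}) / (n_perm + 1)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    strata = pair_ep(data, a, b)
    if not strata.defined:
        raise UndefinedSIError("a stratum is empty: observed SI undefined")
    si_obs = synergy_index(strata.e11, strata.e01, strata.e10)

    X, y = _xy(data)
    ha, hb = X[:, a] > 0, X[:, b] > 0
    m11, m01, m10 = ha & hb, ha & ~hb, hb & ~ha
    y = y.astype(np.int64)

    collected: list[np.ndarray] = []
    n_have = 0
    for _ in range(max_rounds):
        need = n_perm - n_have
        if need <= 0:
            break
        # draw permutations as row-wise shuffles of the outcome vector
        keys = rng.random((need, len(y)))
        order = np.argsort(keys, axis=1)
        Y = y[order]
        si = _si_from_counts(
            Y[:, m11].sum(axis=1), strata.n11,
            Y[:, m01].sum(axis=1), strata.n01,
            Y[:, m10].sum(axis=1), strata.n10,
        )
        ok = ~np.isnan(si)
        collected.append(si[ok])
        n_have += int(ok.sum())
    else:
        raise UndefinedSIError(
            f"could not draw {n_perm} defined-SI permutations for pair "
            f"({a}, {b}): solo strata too sparse"
        )
    si_perm = np.concatenate(collected)[:n_perm]
    return float((1 + int((si_perm >= si_obs).sum())) / (n_perm + 1))


def screen_pairs(
    data: AnalysisTable,
    herbs: Iterable[int],
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    vocab: HerbVocabulary | None = None,
) -> pd.DataFrame:
    """Synergy screening of every unordered pair among the given herbs.

    Pairs with an undefined SI (an empty stratum or a zero denominator) are
    dropped.  The result is sorted by SI descending with a ``significant``
    flag at the given level.
    """
    herbs = sorted(set(herbs))
    if len(herbs) < 2:
        raise ValidationError("need at least two herbs to screen pairs")
    if rng is None:
        rng = np.random.default_rng()
    if vocab is None and isinstance(data, AnalysisTable):
        vocab = data.vocab
    rows = []
    for i, a in enumerate(herbs):
        for b in herbs[i + 1:]:
            strata = pair_ep(data, a, b)
            if not strata.defined:
                continue
            try:
                si = synergy_index(strata.e11, strata.e01, strata.e10)
                p = permutation_test_si(data, a, b, n_perm=n_perm, rng=rng)
            except UndefinedSIError:
                continue
            rows.append(
                {
                    "herb_a": vocab.herbs[a] if vocab is not None else a,
                    "herb_b": vocab.herbs[b] if vocab is not None else b,
                    "e11": strata.e11,
                    "e01": strata.e01,
                    "e10": strata.e10,
                    "si": si,
                    "p_perm": p,
                    "n11": strata.n11,
                    "n01": strata.n01,
                    "n10": strata.n10,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "herb_a", "herb_b", "e11", "e01", "e10",
            "si", "p_perm", "n11", "n01", "n10",
        ],
    )
    if len(df):
        df = df.sort_values("si", ascending=False).reset_index(drop=True)
    df["significant"] = df["p_perm"] < alpha if len(df) else pd.Series(dtype=bool)
    return df
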