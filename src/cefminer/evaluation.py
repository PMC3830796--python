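"""Statistical evaluation of candidate formulae.

Effectiveness is tested with a two-proportion Z-test between the CEF and
non-CEF groups (unpooled standard error by default, two-sided normal P),
robustness with a leave-one-patient-out (LOPO) resampling that removes each
patient in turn, and coreness through the herb co-occurrence network:
herbs that are both high-degree network nodes and high-frequency
prescription members are core herbs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .metrics import CEFCandidate, split_groups
from .records import AnalysisTable, HerbVocabulary, ValidationError

__all__ = [
    "UndefinedTestError",
    "ZTestResult",
    "LOPOSummary",
    "two_proportion_ztest",
    "neglog10",
    "leave_one_patient_out",
    "build_herb_network",
    "rank_herbs",
    "reconstruct_group_counts",
]


class UndefinedTestError(ValueError):
    """The test statistic is undefined (zero standard error)."""


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p_two_sided: float


def two_proportion_ztest(
    k1: int, n1: int, k0: int, n0: int, pooled: bool = False
) -> ZTestResult:
    """Two-sided Z-test for the difference of two proportions.

    By default the standard error is the unpooled (Wald) form
    ``sqrt(p1(1-p1)/n1 + p0(1-p0)/n0)``; ``pooled=True`` switches to the
    pooled-proportion form.  No continuity correction is applied.
    """
    if n1 < 1 or n0 < 1:
        raise ValidationError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k0 <= n0):
        raise ValidationError("positive counts must lie within group sizes")
    p1, p0 = k1 / n1, k0 / n0
    if pooled:
        p = (k1 + k0) / (n1 + n0)
        se = math.sqrt(p * (1.0 - p) * (1.0 / n1 + 1.0 / n0))
    else:
        se = math.sqrt(p1 * (1.0 - p1) / n1 + p0 * (1.0 - p0) / n0)
    if se == 0.0:
        raise UndefinedTestError("zero standard error: degenerate proportions")
    z = (p1 - p0) / se
    return ZTestResult(z=z, p_two_sided=float(2.0 * norm.sf(abs(z))))


def neglog10(p: float, cap: float = 16.0) -> float:
    """``-log10(p)``; values above ``-log10(0.05) = 1.301`` mean P < 0.05.

    ``p = 0`` is capped at ``cap`` with a warning rather than returning inf.
    """
    if p < 0.0 or p > 1.0:
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if p == 0.0:
        warnings.warn("p = 0 capped in -log10 transform", RuntimeWarning, stacklevel=2)
        return cap
    return -math.log10(p)


@dataclass(frozen=True)
class LOPOSummary:
    """Leave-one-patient-out robustness summary for one candidate.

    ``table`` holds one row per holdout (patient removed) with columns
    patient_id, ep0, ep1, p, neglog_p; undefined holdouts (the removal
    empties a group or degenerates the test) are excluded from the summary
    statistics and counted in ``n_undefined``.
    """

    table: pd.DataFrame
    n_undefined: int

    def _col(self, name: str) -> pd.Series:
        return self.table.loc[self.table["defined"], name]

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {"n_holdouts": float(len(self.table)),
                                 "n_undefined": float(self.n_undefined)}
        for col in ("ep0", "ep1", "neglog_p"):
            vals = self._col(col)
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_min"] = float(vals.min())
            out[f"{col}_max"] = float(vals.max())
        return out


def leave_one_patient_out(
    table: AnalysisTable,
    cef: CEFCandidate,
    level: float = 1.0,
    pooled: bool = False,
) -> LOPOSummary:
    """Remove each patient in turn and re-test the candidate's effectiveness.

    One holdout per distinct patient; each recomputes the group split and the
    two-proportion Z-test on the remaining records.
    """
    patients = np.unique(table.patient_ids)
    if len(patients) < 2:
        raise ValidationError("leave-one-patient-out needs >= 2 patients")
    rows = []
    n_undefined = 0
    for pid in patients:
        keep = table.patient_ids != pid
        sub = AnalysisTable(
            patient_ids=table.patient_ids[keep],
            X=table.X[keep],
            scv=table.scv[keep],
            outcome=table.outcome[keep],
            vocab=table.vocab,
        )
        split = split_groups(cef, sub, level=level)
        row = {"patient_id": pid, "ep0": split.ep0, "ep1": split.ep1}
        try:
            if split.n1 == 0 or split.n0 == 0:
                raise UndefinedTestError("empty group after holdout")
            zt = two_proportion_ztest(split.k1, split.n1, split.k0, split.n0, pooled=pooled)
            row.update(p=zt.p_two_sided, neglog_p=neglog10(zt.p_two_sided), defined=True)
        except (UndefinedTestError, ValidationError):
            n_undefined += 1
            row.update(p=math.nan, neglog_p=math.nan, defined=False)
        rows.append(row)
    return LOPOSummary(table=pd.DataFrame(rows), n_undefined=n_undefined)


def build_herb_network(
    data, patient_ids: np.ndarray | None = None, threshold: int = 1
) -> nx.Graph:
    """Herb co-occurrence network from a binary prescription matrix.

    Nodes are herb indices carrying ``record_freq`` (and ``patient_freq``
    when patient ids are given); an edge joins two herbs co-occurring in at
    least ``threshold`` prescriptions, weighted by the co-occurrence count.
    """
    X = data.X if isinstance(data, AnalysisTable) else np.asarray(data)
    if patient_ids is None and isinstance(data, AnalysisTable):
        patient_ids = data.patient_ids
    if X.shape[0] == 0:
        raise ValidationError("need at least one prescription")
    Xi = X.astype(np.int64)
    counts = Xi.T @ Xi  # (m, m); diagonal = record frequencies
    record_freq = np.diag(counts)

    G = nx.Graph()
    for j in range(X.shape[1]):
        G.add_node(j, record_freq=int(record_freq[j]))
    if patient_ids is not None:
        for j in range(X.shape[1]):
            G.nodes[j]["patient_freq"] = int(
                len(np.unique(np.asarray(patient_ids)[X[:, j] > 0]))
            )
    iu, ju = np.triu_indices(X.shape[1], k=1)
    mask = counts[iu, ju] >= threshold
    for u, v, w in zip(iu[mask], ju[mask], counts[iu, ju][mask]):
        G.add_edge(int(u), int(v), weight=int(w))
    return G


def rank_herbs(G: nx.Graph, vocab: HerbVocabulary | None = None) -> pd.DataFrame:
    """Rank herbs by network degree and by prescription frequency.

    Ranks are 1..n, descending in the ranked value; ties are broken by
    descending record frequency and then lexicographic herb name, so the
    rank columns are permutations.  Isolated (zero-frequency) herbs are
    included.
    """
    if G.number_of_nodes() == 0:
        raise ValidationError("empty network")
    rows = []
    for j, attrs in G.nodes(data=True):
        rows.append(
            {
                "herb": vocab.herbs[j] if vocab is not None else str(j),
                "degree": G.degree(j),
                "record_freq": attrs.get("record_freq", 0),
                "patient_freq": attrs.get("patient_freq", 0),
            }
        )
    df = pd.DataFrame(rows)

    def dense_order(df: pd.DataFrame, col: str) -> pd.Series:
        ordered = df.sort_values(
            by=[col, "record_freq", "herb"], ascending=[False, False, True]
        )
        ranks = pd.Series(range(1, len(df) + 1), index=ordered.index)
        return ranks

    df["degree_rank"] = dense_order(df, "degree")
    df["record_freq_rank"] = dense_order(df, "record_freq")
    df["patient_freq_rank"] = dense_order(df, "patient_freq")
    return (
        df.sort_values("degree_rank")
        .reset_index(drop=True)[
            [
                "herb",
                "degree",
                "degree_rank",
                "record_freq",
                "record_freq_rank",
                "patient_freq",
                "patient_freq_rank",
            ]
        ]
    )


def reconstruct_group_counts(
    s1: float,
    ep_cef: float,
    ep_noncef: float,
    n_total: int,
    total_positives: int | None = None,
) -> tuple[int, int, int, int]:
    """Recover integer group counts from printed support and proportions.

    Returns ``(k1, n1, k0, n0)`` with ``n1 = round(s1 * n_total)``,
    ``k1 = round(ep_cef * n1)``, ``n0 = n_total - n1`` and
    ``k0 = round(ep_noncef * n0)``.  When ``total_positives`` is given, the
    reconstruction is checked for consistency (``k1 + k0`` must match).
    """
    n1 = round(s1 * n_total)
    n0 = n_total - n1
    k1 = round(ep_cef * n1)
    k0 = round(ep_noncef * n0)
    if total_positives is not None and k1 + k0 != total_positives:
        raise ValidationError(
            f"reconstructed positives {k1} + {k0} != expected {total_positives}"
        )
    return k1, n1, k0, n0
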