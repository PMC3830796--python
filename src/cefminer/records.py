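"""Clinical visit records, symptom change values and the binary analysis table.

The unit of analysis is a prescription paired with its observed outcome.
A patient contributes one analysis record per visit except the last: the
prescription given at visit *j* is judged by the symptom change observed at
visit *j + 1*.  The symptom change value (SCV) is the relative reduction in
the summed symptom-severity score between the two visits; a reduction of at
least 30 % marks the prescription as effective (outcome 1).

Records with an undefined SCV (previous symptom score of zero) are removed,
and patients with a single visit contribute nothing, mirroring the exclusion
rules used in longitudinal herbal-prescription cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "HerbVocabulary",
    "VisitRecord",
    "AnalysisTable",
    "EFFECTIVENESS_THRESHOLD",
    "symptom_score",
    "scv",
    "binarize_outcome",
    "build_analysis_table",
    "encode_prescriptions",
    "read_visits_csv",
    "write_visits_csv",
    "write_analysis_csv",
]

#: Minimum relative symptom reduction for a prescription to count as effective.
EFFECTIVENESS_THRESHOLD = 0.30

SYMPTOM_SCALE_MAX = 3


class ValidationError(ValueError):
    """Raised when input clinical data violates the expected format."""


@dataclass(frozen=True)
class HerbVocabulary:
    """Ordered, immutable list of herb names defining the chromosome layout.

    Herb *j* of the vocabulary maps to bit *j* of every prescription vector;
    the mapping is stable for the lifetime of an analysis.
    """

    herbs: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        herbs = tuple(h.strip() for h in self.herbs)
        if any(not h for h in herbs):
            raise ValidationError("herb names must be non-empty")
        if len(set(herbs)) != len(herbs):
            dupes = sorted({h for h in herbs if herbs.count(h) > 1})
            raise ValidationError(f"duplicate herb names: {dupes}")
        if len(herbs) < 2:
            raise ValidationError("a vocabulary needs at least two herbs")
        object.__setattr__(self, "herbs", herbs)
        object.__setattr__(self, "_index", {h: j for j, h in enumerate(herbs)})

    def __len__(self) -> int:
        return len(self.herbs)

    @property
    def m(self) -> int:
        return len(self.herbs)

    def index(self, name: str) -> int:
        try:
            return self._index[name.strip()]
        except KeyError:
            raise ValidationError(f"herb not in vocabulary: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name.strip() in self._index

    @classmethod
    def from_visits(cls, visits: Iterable["VisitRecord"]) -> "HerbVocabulary":
        """Collect every herb name appearing in *visits*, in sorted order."""
        names = sorted({h for v in visits for h in v.herbs})
        return cls(tuple(names))


@dataclass(frozen=True)
class VisitRecord:
    """One clinical encounter: patient, visit order, symptom severities, herbs.

    ``symptom_scores`` holds one integer per recorded symptom on the 4-point
    scale (0 not at all … 3 very much); ``herbs`` is the prescribed herb set
    by name.
    """

    patient_id: str
    visit_index: int
    symptom_scores: tuple[int, ...]
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        if self.visit_index < 1:
            raise ValidationError(
                f"visit_index must be >= 1, got {self.visit_index}"
            )
        if not self.herbs:
            raise ValidationError(
                f"empty prescription for patient {self.patient_id!r} "
                f"visit {self.visit_index}"
            )
        object.__setattr__(self, "symptom_scores", tuple(int(s) for s in self.symptom_scores))
        object.__setattr__(self, "herbs", frozenset(h.strip() for h in self.herbs))
        symptom_score(self.symptom_scores)  # validates the scale


def symptom_score(scores: Sequence[int]) -> int:
    """Total symptom burden at one visit: the sum of per-symptom severities.

    Each entry must lie on the 4-point scale {0, 1, 2, 3}.
    """
    total = 0
    for i, s in enumerate(scores):
        s = int(s)
        if not 0 <= s <= SYMPTOM_SCALE_MAX:
            raise ValidationError(
                f"symptom {i + 1} has score {s}, outside the 0..3 scale"
            )
        total += s
    return total


def scv(prev_score: int, next_score: int) -> float | None:
    """Symptom change value: relative score reduction between visits.

    Returns ``(prev - next) / prev``, or ``None`` when the previous score is
    zero (the ratio is undefined and the record is treated as missing).
    Negative values indicate worsening symptoms.
    """
    if prev_score < 0 or next_score < 0:
        raise ValidationError("symptom scores cannot be negative")
    if prev_score == 0:
        return None
    return (prev_score - next_score) / prev_score


def binarize_outcome(scv_value: float) -> int:
    """1 when the symptom change value reaches the 30 % threshold, else 0."""
    return 1 if scv_value >= EFFECTIVENESS_THRESHOLD else 0


@dataclass
class AnalysisTable:
    """Binary prescription-outcome table: the input of every downstream metric.

    Attributes
    ----------
    patient_ids : array of str, shape (n,)
        Patient owning each record (a patient typically owns several).
    X : uint8 array, shape (n, m)
        Prescription incidence matrix; bit (i, j) set iff herb j of the
        vocabulary was in prescription i.
    scv : float array, shape (n,)
        Symptom change value of each record (never missing here).
    outcome : int8 array, shape (n,)
        Binary effectiveness outcome, 1 iff scv >= 0.30.
    vocab : HerbVocabulary
    n_missing_removed : int
        Number of prescription/outcome pairs dropped for undefined SCV.
    """

    patient_ids: np.ndarray
    X: np.ndarray
    scv: np.ndarray
    outcome: np.ndarray
    vocab: HerbVocabulary
    n_missing_removed: int = 0

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def m(self) -> int:
        return self.vocab.m

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.patient_ids))

    @property
    def effective_proportion(self) -> float:
        """Fraction of records with a positive outcome."""
        if self.n == 0:
            raise ValidationError("empty analysis table has no effective proportion")
        return float(self.outcome.mean())

    def __len__(self) -> int:
        return self.n


def build_analysis_table(
    visits: Sequence[VisitRecord], vocab: HerbVocabulary
) -> AnalysisTable:
    """Pair each non-final prescription with the SCV observed at the next visit.

    Patients with a single visit are dropped; the last visit of each patient
    yields no record (its outcome is never observed); records whose SCV is
    undefined (previous symptom score 0) are removed.  The resulting count
    satisfies::

        n = (visits of multi-visit patients) - (multi-visit patients) - (missing)
    """
    seen: set[tuple[str, int]] = set()
    for v in visits:
        key = (v.patient_id, v.visit_index)
        if key in seen:
            raise ValidationError(f"duplicate (patient, visit_index): {key}")
        seen.add(key)
        for h in v.herbs:
            if h not in vocab:
                raise ValidationError(
                    f"herb not in vocabulary: {h!r} "
                    f"(patient {v.patient_id!r} visit {v.visit_index})"
                )

    ordered = sorted(visits, key=lambda v: (str(v.patient_id), v.visit_index))

    pids: list[str] = []
    rows: list[frozenset[str]] = []
    scvs: list[float] = []
    n_missing = 0
    for pid, group in itertools.groupby(ordered, key=lambda v: v.patient_id):
        pvisits = list(group)
        if len(pvisits) < 2:
            continue
        totals = [symptom_score(v.symptom_scores) for v in pvisits]
        for j in range(len(pvisits) - 1):
            value = scv(totals[j], totals[j + 1])
            if value is None:
                n_missing += 1
                continue
            pids.append(str(pid))
            rows.append(pvisits[j].herbs)
            scvs.append(value)

    X = np.zeros((len(rows), vocab.m), dtype=np.uint8)
    for i, herbs in enumerate(rows):
        for h in herbs:
            X[i, vocab.index(h)] = 1

    scv_arr = np.asarray(scvs, dtype=float)
    outcome = np.fromiter(
        (binarize_outcome(v) for v in scvs), dtype=np.int8, count=len(scvs)
    )
    return AnalysisTable(
        patient_ids=np.asarray(pids, dtype=object),
        X=X,
        scv=scv_arr,
        outcome=outcome,
        vocab=vocab,
        n_missing_removed=n_missing,
    )


def encode_prescriptions(
    prescriptions: Iterable[Iterable[str]], vocab: HerbVocabulary
) -> np.ndarray:
    """Encode herb-name sets as rows of a binary incidence matrix (n x m)."""
    rows = list(prescriptions)
    X = np.zeros((len(rows), vocab.m), dtype=np.uint8)
    for i, herbs in enumerate(rows):
        for h in herbs:
            X[i, vocab.index(h)] = 1
    return X


# ---------------------------------------------------------------------------
# CSV interchange


def read_visits_csv(
    path,
    n_symptoms: int = 15,
    herb_columns: str = "list",
    herb_sep: str = ";",
) -> list[VisitRecord]:
    """Read visit-level clinical data from CSV.

    Expected columns: ``patient_id``, ``visit_index``, ``s1``..``s<k>`` and
    either a single ``herbs`` column of ``herb_sep``-delimited names
    (``herb_columns="list"``, the default) or one 0/1 column per herb name
    (``herb_columns="wide"``; every column beyond the id/visit/symptom block
    is taken as a herb).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    score_cols = [f"s{i}" for i in range(1, n_symptoms + 1)]
    required = ["patient_id", "visit_index", *score_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns in visits CSV: {missing}")

    visits: list[VisitRecord] = []
    if herb_columns == "list":
        if "herbs" not in df.columns:
            raise ValidationError("missing 'herbs' column in visits CSV")
        for row in df.itertuples(index=False):
            d = row._asdict()
            herbs = frozenset(
                h.strip() for h in str(d["herbs"]).split(herb_sep) if h.strip()
            )
            visits.append(
                VisitRecord(
                    patient_id=str(d["patient_id"]),
                    visit_index=int(d["visit_index"]),
                    symptom_scores=tuple(int(d[c]) for c in score_cols),
                    herbs=herbs,
                )
            )
    elif herb_columns == "wide":
        herb_names = [c for c in df.columns if c not in required]
        if not herb_names:
            raise ValidationError("no herb indicator columns found in wide CSV")
        for _, d in df.iterrows():
            herbs = frozenset(h for h in herb_names if int(d[h]) == 1)
            visits.append(
                VisitRecord(
                    patient_id=str(d["patient_id"]),
                    visit_index=int(d["visit_index"]),
                    symptom_scores=tuple(int(d[c]) for c in score_cols),
                    herbs=herbs,
                )
            )
    else:
        raise ValidationError(f"unknown herb_columns mode: {herb_columns!r}")
    return visits


def write_visits_csv(visits: Sequence[VisitRecord], path, herb_sep: str = ";") -> None:
    """Write visit records in the list-column CSV dialect read back by
    :func:`read_visits_csv`."""
    if not visits:
        raise ValidationError("no visits to write")
    n_symptoms = len(visits[0].symptom_scores)
    rows = []
    for v in sorted(visits, key=lambda v: (str(v.patient_id), v.visit_index)):
        row = {"patient_id": v.patient_id, "visit_index": v.visit_index}
        for i, s in enumerate(v.symptom_scores, start=1):
            row[f"s{i}"] = s
        row["herbs"] = herb_sep.join(sorted(v.herbs))
        rows.append(row)
    cols = ["patient_id", "visit_index", *(f"s{i}" for i in range(1, n_symptoms + 1)), "herbs"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_analysis_csv(table: AnalysisTable, path) -> None:
    """Write the analysis table: patient_id, scv, outcome, one bit column per herb."""
    df = pd.DataFrame(
        {
            "patient_id": table.patient_ids,
            "scv": table.scv,
            "outcome": table.outcome,
        }
    )
    bits = pd.DataFrame(table.X, columns=list(table.vocab.herbs))
    pd.concat([df, bits], axis=1).to_csv(path, index=False)
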