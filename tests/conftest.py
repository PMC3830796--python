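import numpy as np
import pytest

import cefminer as cm
from cefminer.records import AnalysisTable, HerbVocabulary, VisitRecord


@pytest.fixture(scope="session")
def vocab4():
    return HerbVocabulary(("ginger", "licorice", "peony", "astragalus"))


@pytest.fixture(scope="session")
def multi_patient_visits():
    """Four patients with 1, 2, 3 and 4 visits (10 visits total).

    No zero symptom totals, so pairing yields (2-1)+(3-1)+(4-1) = 6 records.
    """
    def v(pid, idx, total_pattern, herbs):
        return VisitRecord(pid, idx, total_pattern, frozenset(herbs))

    s_hi = (2, 1, 1) + (0,) * 12   # total 4
    s_lo = (1, 0, 0) + (0,) * 12   # total 1
    return [
        v("A", 1, s_hi, {"ginger"}),
        v("B", 1, s_hi, {"ginger", "licorice"}),
        v("B", 2, s_lo, {"licorice"}),
        v("C", 1, s_hi, {"peony"}),
        v("C", 2, s_lo, {"peony", "ginger"}),
        v("C", 3, s_hi, {"peony"}),
        v("D", 1, s_hi, {"astragalus"}),
        v("D", 2, s_hi, {"astragalus", "peony"}),
        v("D", 3, s_lo, {"astragalus"}),
        v("D", 4, s_hi, {"astragalus"}),
    ]


@pytest.fixture(scope="session")
def vocab15():
    return HerbVocabulary(tuple(f"h{i}" for i in range(15)))


def make_table(X, outcome, patient_ids=None, vocab=None):
    """Assemble an AnalysisTable directly from a bit matrix and outcomes."""
    X = np.asarray(X, dtype=np.uint8)
    outcome = np.asarray(outcome, dtype=np.int8)
    n, m = X.shape
    if patient_ids is None:
        patient_ids = [f"p{i}" for i in range(n)]
    if vocab is None:
        vocab = HerbVocabulary(tuple(f"h{j}" for j in range(m)))
    scv = np.where(outcome == 1, 0.5, 0.0)
    return AnalysisTable(
        patient_ids=np.asarray(patient_ids, dtype=object),
        X=X,
        scv=scv,
        outcome=outcome,
        vocab=vocab,
    )


@pytest.fixture(scope="session")
def tiny_planted_table():
    """Small planted cohort for GA oracle tests: 15 patients, 12 herbs."""
    cfg = cm.tiny_config(
        seed=5, n_patients=15,
        planted_cefs=(cm.PlantedCEF((1, 2, 3), 0.3, 0.7),),
    )
    return cm.generate_analysis_table(cfg)


@pytest.fixture(scope="session")
def study_planted_table():
    """Study-shaped cohort with a planted 8-herb formula at 5% support."""
    cfg = cm.study_config(
        seed=0,
        planted_cefs=(cm.PlantedCEF(tuple(range(2, 10)), 0.05, 0.6),),
    )
    return cm.generate_analysis_table(cfg)
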