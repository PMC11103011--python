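import numpy as np
import pandas as pd
import pytest

from ehrisk.encoding import EncodedDataset, EncodedPatient, FeatureVocabulary, StaticCodec
from ehrisk.simulate import OutcomeModel, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,500-patient simulated cohort with known outcome coefficients."""
    config = SimulationConfig(
        n_patients=1500,
        seed=7,
        outcome_model=OutcomeModel(
            intercept=-2.0,
            main={"depression": 1.0, "suicidal_ideation": 2.0, "marital_status=Married": -0.5},
            interactions={("lgbt=Yes", "marital_status=Married"): 0.5},
            age_per_decade=-0.2,
        ),
    )
    patients, events, notes = simulate_cohort(config)
    return config, patients, events, notes


def make_patients(rows):
    """Build a patients frame from compact per-patient dicts."""
    defaults = {
        "birth_date": "1955-01-01", "sex": "Male", "race_ethnicity": "Non-Hispanic White",
        "marital_status": "Married", "religion": "Catholic", "enrollment_date": "2011-01-01",
        "death_date": None, "underlying_cause": "", "suicide_death": False,
        "lgbt_status": "Unknown", "endpoint_date": "2015-01-01",
        "true_linear_predictor": 0.0, "true_probability": 0.5,
    }
    recs = []
    for row in rows:
        rec = {**defaults, **row}
        recs.append(rec)
    df = pd.DataFrame(recs)
    for col in ("birth_date", "enrollment_date", "death_date", "endpoint_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_events(rows):
    """Build an events frame from (patient_id, feature_code, date) triples."""
    df = pd.DataFrame(rows, columns=["patient_id", "feature_code", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


@pytest.fixture
def stub_dataset():
    """Tiny hand-built encoded dataset for closed-form explainability checks.

    Static layout: [age, sex=Female, lgbt_status=No, lgbt_status=Yes].
    """
    vocab = FeatureVocabulary(code_to_id={"depression": 1, "anxiety": 2, "pain": 3})
    codec = StaticCodec(levels={"sex": ["Male", "Female"],
                                "lgbt_status": ["Unknown", "No", "Yes"]})

    def mk(i, age, female, lgbt_no, lgbt_yes, tokens, label=0):
        return EncodedPatient(f"P{i}", label,
                              np.array([age, female, lgbt_no, lgbt_yes], dtype=float),
                              tokens)

    patients = [
        mk(0, 71.6, 1, 0, 1, [(1, 3), (1, 5), (2, 1)]),
        mk(1, 61.6, 0, 0, 0, [(1, 2)], label=1),
        mk(2, 50.0, 0, 1, 0, [(2, 4), (3, 21)]),
        mk(3, 45.0, 1, 0, 1, [(1, 1), (2, 2), (3, 3)], label=1),
        mk(4, 80.0, 0, 0, 0, []),
    ]
    return EncodedDataset(patients, vocab, codec)
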