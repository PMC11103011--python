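"""Synthetic longitudinal EHR cohorts with a known logit outcome model.

The simulator emulates the inputs of a large healthcare-system suicide
mortality study: a patient table (demographics, enrollment, death), an event
table of dated coded features (diagnoses, prescription fills, firearm-access
mentions, homelessness indicators, hospitalizations, prior suicidal behavior,
outpatient visits), and a table of free-text note snippets carrying disclosed
LGBT status.  The suicide-death outcome is drawn from an explicit
additive-plus-interaction logistic model

    P(suicide) = sigmoid(b0 + sum_j b_j x_j + sum_{jk} g_jk x_j x_k
                         + b_age * (age - age_ref) / 10)

where ``x_j`` is presence of feature ``j`` in the patient's history (or a
static-level indicator), so the true per-patient linear predictor is known and
is retained in the output for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "OutcomeModel",
    "ConfigurationError",
    "CohortReadError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


class ConfigurationError(ValueError):
    """A simulation config references undeclared features or invalid probabilities."""


class CohortReadError(ValueError):
    """A cohort file on disk is malformed."""


# Static covariate distributions loosely shaped like a veteran healthcare
# population (predominantly male, older).  Values are sampling probabilities.
DEFAULT_STATIC_SPEC: dict[str, dict[str, float]] = {
    "sex": {"Male": 0.93, "Female": 0.07},
    "race_ethnicity": {
        "Non-Hispanic White": 0.69,
        "Non-Hispanic Black": 0.16,
        "Hispanic": 0.06,
        "Other": 0.07,
        "Unknown": 0.02,
    },
    "marital_status": {
        "Married": 0.55,
        "Divorced": 0.22,
        "Single": 0.12,
        "Widowed": 0.07,
        "Separated": 0.03,
        "Unknown": 0.01,
    },
    "religion": {
        "Other-Protestant": 0.28,
        "Catholic": 0.21,
        "None-Unknown": 0.21,
        "Baptist": 0.18,
        "Christian": 0.06,
        "Other-Religion": 0.06,
    },
}

# Disclosed-status prevalence: ~2.3% affirmed, ~5% disclosed-negative, the
# rest undocumented.
DEFAULT_STATUS_SPEC: dict[str, float] = {"Yes": 0.023, "No": 0.05, "Unknown": 0.927}

# Per-180-day-period incidence of each temporal feature family.
DEFAULT_FEATURE_SPEC: dict[str, float] = {
    "depression": 0.020,
    "anxiety": 0.020,
    "ptsd": 0.015,
    "substance_abuse": 0.010,
    "sleep_disorder": 0.010,
    "pain": 0.030,
    "diabetes": 0.020,
    "suicidal_ideation": 0.004,
    "firearm_access": 0.002,
    "homelessness": 0.003,
    "hospitalization": 0.008,
    "antidepressant_fill": 0.025,
}

SUICIDE_CAUSE_CODES = ("X60", "X64", "X70", "X72", "X74", "X80", "U03", "Y87.0")
OTHER_CAUSE_CODES = ("I21.9", "C34.90", "J44.9", "I50.9", "W19", "X85")

#: Days-prior span sampled for the open-ended remote-history period (~15 y cap).
REMOTE_PERIOD_SPAN = (3607, 5407)

PATIENT_COLUMNS = [
    "id", "birth_date", "sex", "race_ethnicity", "marital_status", "religion",
    "enrollment_date", "death_date", "underlying_cause", "suicide_death",
    "lgbt_status", "endpoint_date", "true_linear_predictor", "true_probability",
]
EVENT_COLUMNS = ["patient_id", "feature_code", "event_date"]
NOTE_COLUMNS = ["patient_id", "note_date", "text"]


@dataclass
class OutcomeModel:
    """Additive-plus-interaction logistic outcome model.

    Coefficient keys name either a temporal feature family (e.g.
    ``"depression"``) or a static level as ``"variable=Level"`` (e.g.
    ``"marital_status=Married"``, ``"lgbt=Yes"``).  ``age_per_decade`` is the
    log-odds change per 10 years of age relative to ``reference_age``.
    ``recency_weights``, when given, must have one weight per lookback period
    (most-recent first); a present feature then contributes
    ``beta * weight[most recent period with an event]`` instead of ``beta``.
    """

    intercept: float = -4.0
    main: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    age_per_decade: float = 0.0
    reference_age: float = 61.6
    recency_weights: list[float] | None = None


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    #: possible outpatient-visit dates (fiscal years 2010-2017 by default)
    date_window: tuple[date, date] = (date(2009, 10, 1), date(2017, 9, 30))
    death_observation_end: date = date(2018, 12, 31)
    birth_year_range: tuple[int, int] = (1930, 1990)
    static_spec: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STATIC_SPEC.items()})
    feature_spec: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEATURE_SPEC))
    status_spec: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STATUS_SPEC))
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    visit_rate_per_year: float = 2.0
    #: probability of a non-suicide death during observation
    other_death_prob: float = 0.15
    n_periods: int = 21
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        if self.date_window[0] >= self.date_window[1]:
            raise ConfigurationError("date_window start must precede end")
        for fam, p in self.feature_spec.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"incidence for {fam!r} outside [0, 1]: {p}")
        for var, levels in self.static_spec.items():
            total = sum(levels.values())
            if not np.isclose(total, 1.0):
                raise ConfigurationError(f"probabilities for {var!r} sum to {total}, not 1")
        if not np.isclose(sum(self.status_spec.values()), 1.0):
            raise ConfigurationError("status_spec probabilities must sum to 1")
        om = self.outcome_model
        keys = list(om.main) + [k for pair in om.interactions for k in pair]
        for key in keys:
            if not self._key_declared(key):
                raise ConfigurationError(f"outcome coefficient references undeclared feature {key!r}")
        if om.recency_weights is not None and len(om.recency_weights) != self.n_periods:
            raise ConfigurationError("recency_weights must have one entry per period")

    def _key_declared(self, key: str) -> bool:
        if key in self.feature_spec:
            return True
        if "=" in key:
            var, level = key.split("=", 1)
            if var == "lgbt":
                return level in self.status_spec
            return var in self.static_spec and level in self.static_spec[var]
        return False


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _sample_categorical(rng: np.random.Generator, spec: dict[str, float], n: int) -> np.ndarray:
    levels = np.array(list(spec), dtype=object)
    probs = np.array([spec[lv] for lv in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def _period_days_prior_bounds(period: int) -> tuple[int, int]:
    # inclusive [lo, hi] days-prior range sampled for events in this period
    if period <= 20:
        lo = 7 + 180 * (period - 1)
        return lo, lo + 179
    return REMOTE_PERIOD_SPAN


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, events, notes) tables under ``config``.

    Each patient receives at least one outpatient visit inside the configured
    date window (the earliest is the enrollment date), per-period Bernoulli
    temporal events tiled backwards from an endpoint-candidate date, and a
    suicide-death outcome drawn from the configured logit model.  The true
    linear predictor and sampling probability are retained per patient.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return (pd.DataFrame(columns=PATIENT_COLUMNS),
                pd.DataFrame(columns=EVENT_COLUMNS),
                pd.DataFrame(columns=NOTE_COLUMNS))

    win_start = pd.Timestamp(config.date_window[0])
    win_end = pd.Timestamp(config.date_window[1])
    obs_end = pd.Timestamp(config.death_observation_end)
    window_days = (win_end - win_start).days

    ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    y0, y1 = config.birth_year_range
    birth_year = rng.integers(y0, y1 + 1, size=n)
    birth_doy = rng.integers(0, 365, size=n)
    birth = pd.to_datetime({"year": birth_year, "month": 1, "day": 1}) + pd.to_timedelta(birth_doy, unit="D")

    statics = {var: _sample_categorical(rng, spec, n) for var, spec in config.static_spec.items()}
    lgbt = _sample_categorical(rng, config.status_spec, n)

    # enrollment = first outpatient visit in the window
    enroll_off = rng.integers(0, window_days + 1, size=n)
    enrollment = pd.Series(win_start + pd.to_timedelta(enroll_off, unit="D"))

    # endpoint candidate strictly after enrollment, within the observation span;
    # becomes the death date when the suicide outcome fires
    span = (obs_end - enrollment).dt.days.to_numpy()
    endpoint = enrollment + pd.to_timedelta(1 + rng.integers(0, np.maximum(span, 1)), unit="D")

    # extra outpatient visits after enrollment
    years_left = np.maximum((win_end - enrollment).dt.days.to_numpy(), 0) / 365.25
    n_extra = rng.poisson(config.visit_rate_per_year * years_left)
    rep = np.repeat(np.arange(n), n_extra)
    visit_frames = []
    if rep.size:
        lo = enroll_off[rep]
        offs = lo + rng.integers(0, np.maximum(window_days - lo, 0) + 1)
        visit_frames.append(pd.DataFrame({
            "patient_id": ids[rep],
            "feature_code": "outpatient_visit",
            "event_date": win_start + pd.to_timedelta(offs, unit="D"),
        }))
    visit_frames.append(pd.DataFrame({
        "patient_id": ids, "feature_code": "outpatient_visit", "event_date": enrollment,
    }))

    # temporal events: Bernoulli presence per (patient, family, period), dated
    # uniformly within the period's days-prior range behind the endpoint
    families = list(config.feature_spec)
    presence = {}
    event_frames = list(visit_frames)
    endpoint_np = endpoint.to_numpy()
    birth_np = birth.to_numpy()
    for fam in families:
        p = config.feature_spec[fam]
        hits = rng.random((n, config.n_periods)) < p
        pat_idx, per_idx = np.nonzero(hits)
        if pat_idx.size:
            lo = np.empty(pat_idx.size, dtype=int)
            hi = np.empty(pat_idx.size, dtype=int)
            for k in range(config.n_periods):
                m = per_idx == k
                lo[m], hi[m] = _period_days_prior_bounds(k + 1)
            days_prior = lo + rng.integers(0, hi - lo + 1)
            dates = endpoint_np[pat_idx] - days_prior.astype("timedelta64[D]")
            keep = dates > birth_np[pat_idx]  # drop pre-birth history
            pat_idx, per_idx, dates = pat_idx[keep], per_idx[keep], dates[keep]
            if pat_idx.size:
                event_frames.append(pd.DataFrame({
                    "patient_id": ids[pat_idx], "feature_code": fam, "event_date": dates,
                }))
        pres = np.zeros(n, dtype=float)
        if pat_idx.size:
            if config.outcome_model.recency_weights is not None:
                # weight of the most recent (smallest-index) period with an event
                w = np.asarray(config.outcome_model.recency_weights, dtype=float)
                first = np.full(n, config.n_periods, dtype=int)
                np.minimum.at(first, pat_idx, per_idx)
                carrier = first < config.n_periods
                pres[carrier] = w[first[carrier]]
            else:
                pres[np.unique(pat_idx)] = 1.0
        presence[fam] = pres

    events = pd.concat(event_frames, ignore_index=True)
    events = events.sort_values(["patient_id", "event_date", "feature_code"], kind="stable").reset_index(drop=True)

    # linear predictor from retained presences and static indicators
    om = config.outcome_model

    def indicator(key: str) -> np.ndarray:
        if key in presence:
            return presence[key]
        var, level = key.split("=", 1)
        col = lgbt if var == "lgbt" else statics[var]
        return (col == level).astype(float)

    lp = np.full(n, om.intercept, dtype=float)
    for key, beta in om.main.items():
        lp += beta * indicator(key)
    for (ka, kb), gamma in om.interactions.items():
        lp += gamma * indicator(ka) * indicator(kb)
    if om.age_per_decade:
        age = (endpoint - birth).dt.days.to_numpy() / 365.25
        lp += om.age_per_decade * (age - om.reference_age) / 10.0

    prob = _sigmoid(lp)
    suicide = rng.random(n) < prob

    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    cause = np.full(n, "", dtype=object)
    death_date[suicide] = endpoint[suicide]
    cause[suicide] = rng.choice(np.array(SUICIDE_CAUSE_CODES, dtype=object), size=int(suicide.sum()))
    other = (~suicide) & (rng.random(n) < config.other_death_prob)
    if other.any():
        sp = np.maximum((obs_end - enrollment[other]).dt.days.to_numpy(), 1)
        death_date[other] = enrollment[other] + pd.to_timedelta(1 + rng.integers(0, sp), unit="D")
        cause[other] = rng.choice(np.array(OTHER_CAUSE_CODES, dtype=object), size=int(other.sum()))

    patients = pd.DataFrame({
        "id": ids,
        "birth_date": birth,
        "sex": statics["sex"] if "sex" in statics else "Unknown",
        "race_ethnicity": statics.get("race_ethnicity", np.full(n, "Unknown", dtype=object)),
        "marital_status": statics.get("marital_status", np.full(n, "Unknown", dtype=object)),
        "religion": statics.get("religion", np.full(n, "Unknown", dtype=object)),
        "enrollment_date": enrollment,
        "death_date": death_date,
        "underlying_cause": cause,
        "suicide_death": suicide,
        "lgbt_status": lgbt,
        "endpoint_date": endpoint,
        "true_linear_predictor": lp,
        "true_probability": prob,
    })

    notes = _generate_notes(rng, patients)
    return patients, events, notes


# --- note snippets ----------------------------------------------------------

STATUS_KEYWORDS = ("gay", "lesbian", "bisexual", "transgender")

AFFIRMATIVE_TEMPLATES = (
    "patient identifies as {kw}",
    "veteran self-identifies as {kw}",
    "patient reports being {kw}",
    "patient is openly {kw} and comfortable discussing it",
    "pt came out as {kw} to family last year",
    "discussed stressors related to being {kw}",
)
NEGATED_TEMPLATES = (
    "patient denies being {kw}",
    "pt denies {kw} identity",
    "patient does not identify as {kw}",
    "denied being {kw} when asked during intake",
    "patient states he is not {kw}",
    "no report of {kw} identity on review",
)
IRRELEVANT_TEMPLATES = (
    "follow-up scheduled at gaylord street clinic",
    "routine follow-up, no acute distress",
    "medication refill requested at front desk",
    "discussed diet and exercise goals",
)


def _generate_notes(rng: np.random.Generator, patients: pd.DataFrame) -> pd.DataFrame:
    """Template notes realising each patient's planted status.

    Disclosed-Yes patients get >=1 affirmative note, disclosed-No patients
    >=1 negated note (and no affirmative), Unknown patients only ever get
    status-free snippets.
    """
    rows: list[dict] = []
    enroll = patients["enrollment_date"].to_numpy()
    endpoint = patients["endpoint_date"].to_numpy()
    status = patients["lgbt_status"].to_numpy()
    ids = patients["id"].to_numpy()
    n = len(patients)
    span = np.maximum((endpoint - enroll).astype("timedelta64[D]").astype(int), 1)
    for i in range(n):
        def stamp():
            return pd.Timestamp(enroll[i]) + pd.Timedelta(days=int(rng.integers(0, span[i])))
        if status[i] == "Yes":
            kw = str(rng.choice(STATUS_KEYWORDS))
            tpl = str(rng.choice(AFFIRMATIVE_TEMPLATES))
            rows.append({"patient_id": ids[i], "note_date": stamp(), "text": tpl.format(kw=kw)})
        elif status[i] == "No":
            kw = str(rng.choice(STATUS_KEYWORDS))
            tpl = str(rng.choice(NEGATED_TEMPLATES))
            rows.append({"patient_id": ids[i], "note_date": stamp(), "text": tpl.format(kw=kw)})
        if rng.random() < 0.3:  # irrelevant snippets for anyone
            tpl = str(rng.choice(IRRELEVANT_TEMPLATES))
            rows.append({"patient_id": ids[i], "note_date": stamp(), "text": tpl})
    if not rows:
        return pd.DataFrame(columns=NOTE_COLUMNS)
    notes = pd.DataFrame(rows, columns=NOTE_COLUMNS)
    notes["note_date"] = pd.to_datetime(notes["note_date"])
    return notes.sort_values(["patient_id", "note_date"], kind="stable").reset_index(drop=True)


# --- persistence ------------------------------------------------------------

_DATE_COLS = {"birth_date", "enrollment_date", "death_date", "endpoint_date", "event_date", "note_date"}


def write_cohort(patients: pd.DataFrame, events: pd.DataFrame, notes: pd.DataFrame, directory) -> dict[str, str]:
    """Write patients.csv, events.csv and notes.jsonl under ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = patients.copy()
    for col in p.columns:
        if col in _DATE_COLS:
            p[col] = pd.to_datetime(p[col]).dt.strftime("%Y-%m-%d")
    p.to_csv(directory / "patients.csv", index=False)
    e = events.copy()
    e["event_date"] = pd.to_datetime(e["event_date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(directory / "events.csv", index=False)
    with open(directory / "notes.jsonl", "w") as fh:
        for _, row in notes.iterrows():
            fh.write(json.dumps({
                "patient_id": row["patient_id"],
                "note_date": pd.Timestamp(row["note_date"]).strftime("%Y-%m-%d"),
                "text": row["text"],
            }) + "\n")
    return {"patients": str(directory / "patients.csv"),
            "events": str(directory / "events.csv"),
            "notes": str(directory / "notes.jsonl")}


def read_cohort(directory) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`; inverse round trip.

    Raises :class:`CohortReadError` naming any unknown column or the offending
    line of a malformed notes file.
    """
    from pathlib import Path

    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv", dtype={"id": str, "underlying_cause": str},
                           keep_default_na=False)
    extra = [c for c in patients.columns if c not in PATIENT_COLUMNS]
    if extra:
        raise CohortReadError(f"unknown column(s) in patients.csv: {', '.join(extra)}")
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise CohortReadError(f"missing column(s) in patients.csv: {', '.join(missing)}")
    for col in ("birth_date", "enrollment_date", "endpoint_date"):
        patients[col] = pd.to_datetime(patients[col])
    patients["death_date"] = pd.to_datetime(patients["death_date"].replace("", pd.NaT))
    patients["suicide_death"] = patients["suicide_death"].astype(str).str.lower().isin(("true", "1"))
    for col in ("true_linear_predictor", "true_probability"):
        patients[col] = pd.to_numeric(patients[col])

    events = pd.read_csv(directory / "events.csv", dtype={"patient_id": str, "feature_code": str})
    extra = [c for c in events.columns if c not in EVENT_COLUMNS]
    if extra:
        raise CohortReadError(f"unknown column(s) in events.csv: {', '.join(extra)}")
    events["event_date"] = pd.to_datetime(events["event_date"])

    rows = []
    with open(directory / "notes.jsonl") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise CohortReadError(f"notes.jsonl line {lineno}: invalid JSON ({err.msg})") from err
            if set(obj) != set(NOTE_COLUMNS):
                raise CohortReadError(f"notes.jsonl line {lineno}: unexpected keys {sorted(obj)}")
            obj["note_date"] = pd.Timestamp(obj["note_date"])
            rows.append(obj)
    notes = pd.DataFrame(rows, columns=NOTE_COLUMNS)
    if rows:
        notes["note_date"] = pd.to_datetime(notes["note_date"])
    return patients, events, notes
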