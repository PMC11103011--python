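"""Static and temporal feature encoding for the dual-stream risk model.

Static covariates become a vector of age at the index date plus n-1 dummy
indicators per categorical (reference level = most frequent).  Temporal
history becomes a sequence of presence tokens ``(feature_id, period_id)``
over a 21-period lookback: behind a 7-day buffer that excludes data on the
event itself sit twenty contiguous 180-day slides, and everything at ten
years prior and beyond is grouped into one open-ended remote-history period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimePeriodScheme", "StaticCodec", "FeatureVocabulary", "EncodedPatient",
    "EncodedDataset", "period_of", "age_at", "build_vocabulary", "build_static_codec",
    "encode_static", "encode_temporal", "encode_dataset", "encode_pairs",
    "LookbackError", "EncodingError",
]

STATIC_VARIABLES = ["sex", "race_ethnicity", "marital_status", "religion", "lgbt_status"]


class LookbackError(ValueError):
    """An event dated after its index date."""


class EncodingError(ValueError):
    """A value outside the fitted category maps or vocabulary."""


@dataclass(frozen=True)
class TimePeriodScheme:
    n_periods: int = 21
    slide_length_days: int = 180
    buffer_days: int = 7

    @property
    def n_slides(self) -> int:
        return self.n_periods - 1

    @property
    def remote_start_days(self) -> int:
        # first days-prior value belonging to the open-ended remote period
        return self.buffer_days + self.n_slides * self.slide_length_days


def period_of(event_date, index_date, scheme: TimePeriodScheme | None = None) -> int | None:
    """Lookback period of an event relative to an index date.

    Returns ``None`` for events inside the buffer (days prior < 7), period
    1..20 for the 180-day slides, and 21 for remote history.  Events after the
    index date violate the lookback and raise :class:`LookbackError`.
    """
    scheme = scheme or TimePeriodScheme()
    days_prior = (pd.Timestamp(index_date) - pd.Timestamp(event_date)).days
    if days_prior < 0:
        raise LookbackError(f"event {event_date} is after index date {index_date}")
    if days_prior < scheme.buffer_days:
        return None
    if days_prior < scheme.remote_start_days:
        return 1 + (days_prior - scheme.buffer_days) // scheme.slide_length_days
    return scheme.n_periods


def age_at(birth_date, index_date) -> float:
    """Calendar-exact fractional age in years at the index date."""
    b = pd.Timestamp(birth_date)
    d = pd.Timestamp(index_date)

    def anniversary(year: int) -> pd.Timestamp:
        try:
            return b.replace(year=year)
        except ValueError:  # Feb 29 in a non-leap year
            return b.replace(year=year, month=3, day=1)

    years = d.year - b.year
    last = anniversary(b.year + years)
    if last > d:
        years -= 1
        last = anniversary(b.year + years)
    nxt = anniversary(b.year + years + 1)
    frac = (d - last).days / (nxt - last).days
    return years + frac


@dataclass
class StaticCodec:
    """n-1 dummy coding maps fitted on a cohort.

    ``levels[var]`` lists the observed levels most-frequent-first; the first
    entry is the reference and emits all zeros.  The encoded vector is
    ``[age] + dummies``, with one indicator column per non-reference level in
    a deterministic order.
    """

    levels: dict[str, list[str]]

    @property
    def columns(self) -> list[str]:
        cols = ["age"]
        for var in self.levels:
            cols.extend(f"{var}={lv}" for lv in self.levels[var][1:])
        return cols

    def block(self, var: str) -> tuple[int, int]:
        """Half-open column range of a variable's indicator block."""
        start = 1
        for v in self.levels:
            width = len(self.levels[v]) - 1
            if v == var:
                return start, start + width
            start += width
        raise KeyError(var)

    def decode(self, var: str, vector: np.ndarray) -> str:
        """Recover the category value from its indicator block."""
        lo, hi = self.block(var)
        blk = vector[lo:hi]
        nz = np.nonzero(blk)[0]
        if nz.size == 0:
            return self.levels[var][0]
        return self.levels[var][1 + int(nz[0])]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"levels": self.levels}, indent=2))

    @classmethod
    def from_json(cls, path) -> "StaticCodec":
        return cls(levels=json.loads(Path(path).read_text())["levels"])


def build_static_codec(patients: pd.DataFrame,
                       variables: list[str] | None = None) -> StaticCodec:
    """Fit category maps: levels ordered by frequency (ties alphabetical)."""
    variables = variables or [v for v in STATIC_VARIABLES if v in patients.columns]
    levels = {}
    for var in variables:
        counts = patients[var].astype(str).value_counts()
        ordered = sorted(counts.index, key=lambda lv: (-counts[lv], lv))
        levels[var] = ordered
    return StaticCodec(levels=levels)


def encode_static(patient_row, index_date, codec: StaticCodec) -> np.ndarray:
    """``[age, dummies...]`` for one patient at one index date."""
    vec = np.zeros(len(codec.columns), dtype=float)
    vec[0] = age_at(patient_row["birth_date"], index_date)
    for var, lvls in codec.levels.items():
        value = str(patient_row[var])
        if value not in lvls:
            raise EncodingError(f"unseen category for {var!r}: {value!r}")
        pos = lvls.index(value)
        if pos > 0:
            lo, _ = codec.block(var)
            vec[lo + pos - 1] = 1.0
    return vec


@dataclass
class FeatureVocabulary:
    """Temporal feature-code <-> integer-id map with cohort prevalences.

    Ids are 1-based; 0 is reserved for sequence padding.  Drug-category codes
    below the prevalence floor are dropped at build time.
    """

    code_to_id: dict[str, int]
    prevalence: dict[str, float] = field(default_factory=dict)

    @property
    def id_to_code(self) -> dict[int, str]:
        return {i: c for c, i in self.code_to_id.items()}

    def __len__(self) -> int:
        return len(self.code_to_id)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "feature_id": list(self.code_to_id.values()),
            "code": list(self.code_to_id.keys()),
            "prevalence": [self.prevalence.get(c, np.nan) for c in self.code_to_id],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureVocabulary":
        df = pd.read_csv(path, dtype={"code": str})
        return cls(code_to_id=dict(zip(df["code"], df["feature_id"].astype(int))),
                   prevalence=dict(zip(df["code"], df["prevalence"])))


def build_vocabulary(events: pd.DataFrame, cohort_ids,
                     drug_features: set[str] | frozenset[str] = frozenset(),
                     min_drug_prevalence: float = 0.005,
                     exclude: set[str] = frozenset({"outpatient_visit"})) -> FeatureVocabulary:
    """Feature vocabulary over a cohort.

    Prevalence of a code is the fraction of cohort members with at least one
    event of that code.  Drug-category codes (``drug_features``) below
    ``min_drug_prevalence`` are dropped — the threshold is inclusive, a drug
    at exactly the floor stays — while all other families are kept at any
    prevalence.
    """
    cohort_ids = list(cohort_ids)
    if not cohort_ids:
        raise EncodingError("cannot build a vocabulary on an empty cohort")
    n = len(cohort_ids)
    ev = events[events["patient_id"].isin(cohort_ids)]
    ev = ev[~ev["feature_code"].isin(exclude)]
    carriers = ev.groupby("feature_code")["patient_id"].nunique()
    prevalence = (carriers / n).to_dict()
    kept = []
    for code in sorted(prevalence):
        if code in drug_features and prevalence[code] < min_drug_prevalence:
            continue
        kept.append(code)
    return FeatureVocabulary(code_to_id={c: i + 1 for i, c in enumerate(kept)},
                             prevalence=prevalence)


def encode_temporal(events_for_patient: pd.DataFrame, index_date,
                    vocabulary: FeatureVocabulary,
                    scheme: TimePeriodScheme | None = None,
                    max_tokens: int = 512) -> list[tuple[int, int]]:
    """Distinct ``(feature_id, period_id)`` presence tokens, most recent first.

    One token per (feature, period) with at least one event; sorted by
    ``(period_id, feature_id)``; buffered and out-of-vocabulary events are
    skipped; sequences above ``max_tokens`` drop the oldest periods.
    """
    scheme = scheme or TimePeriodScheme()
    seen: set[tuple[int, int]] = set()
    for code, edate in zip(events_for_patient["feature_code"], events_for_patient["event_date"]):
        fid = vocabulary.code_to_id.get(code)
        if fid is None:
            continue
        period = period_of(edate, index_date, scheme)
        if period is not None:
            seen.add((period, fid))
    ordered = sorted(seen)[:max_tokens]
    return [(fid, period) for period, fid in ordered]


@dataclass
class EncodedPatient:
    patient_id: str
    label: int
    static: np.ndarray
    tokens: list[tuple[int, int]]  # (feature_id, period_id)


@dataclass
class EncodedDataset:
    patients: list[EncodedPatient]
    vocabulary: FeatureVocabulary
    codec: StaticCodec
    scheme: TimePeriodScheme = field(default_factory=TimePeriodScheme)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def static_dim(self) -> int:
        return len(self.codec.columns)

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=float)

    def subset(self, indices) -> "EncodedDataset":
        return EncodedDataset([self.patients[i] for i in indices],
                              self.vocabulary, self.codec, self.scheme)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.patients:
                fh.write(json.dumps({
                    "id": p.patient_id, "label": p.label,
                    "static": [round(float(x), 10) for x in p.static],
                    "tokens": [list(t) for t in p.tokens],
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path, vocabulary: FeatureVocabulary, codec: StaticCodec,
                   scheme: TimePeriodScheme | None = None) -> "EncodedDataset":
        patients = []
        with open(path) as fh:
            for line in fh:
                obj = json.loads(line)
                patients.append(EncodedPatient(
                    patient_id=obj["id"], label=int(obj["label"]),
                    static=np.asarray(obj["static"], dtype=float),
                    tokens=[tuple(t) for t in obj["tokens"]]))
        return cls(patients, vocabulary, codec, scheme or TimePeriodScheme())

    def save(self, directory) -> None:
        """Persist the dataset with its vocabulary and category maps."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_jsonl(directory / "encoded.jsonl")
        self.vocabulary.to_csv(directory / "vocabulary.csv")
        self.codec.to_json(directory / "codec.json")

    @classmethod
    def load(cls, directory) -> "EncodedDataset":
        directory = Path(directory)
        return cls.from_jsonl(directory / "encoded.jsonl",
                              FeatureVocabulary.from_csv(directory / "vocabulary.csv"),
                              StaticCodec.from_json(directory / "codec.json"))


def encode_dataset(patients: pd.DataFrame, events: pd.DataFrame, index_dates: dict[str, object],
                   labels: dict[str, int], vocabulary: FeatureVocabulary, codec: StaticCodec,
                   scheme: TimePeriodScheme | None = None, max_tokens: int = 512) -> EncodedDataset:
    """Encode every patient in ``index_dates`` at its index date.

    ``index_dates`` and ``labels`` map patient id to index date / binary
    outcome; in the matched design these come from the case-control pairs
    (death date for cases, matched first visit for controls).
    """
    scheme = scheme or TimePeriodScheme()
    rows = patients.set_index("id")
    ev_by_pid = dict(tuple(events.groupby("patient_id")))
    empty = events.iloc[0:0]
    encoded = []
    for pid, index_date in index_dates.items():
        row = rows.loc[pid]
        pe = ev_by_pid.get(pid, empty)
        pe = pe[pe["event_date"] <= pd.Timestamp(index_date)]
        encoded.append(EncodedPatient(
            patient_id=pid,
            label=int(labels[pid]),
            static=encode_static(row, index_date, codec),
            tokens=encode_temporal(pe, index_date, vocabulary, scheme, max_tokens)))
    return EncodedDataset(encoded, vocabulary, codec, scheme)


def encode_pairs(pairs: pd.DataFrame, patients: pd.DataFrame, events: pd.DataFrame,
                 vocabulary: FeatureVocabulary, codec: StaticCodec,
                 scheme: TimePeriodScheme | None = None, max_tokens: int = 512) -> EncodedDataset:
    """Encode a matched case-control pair table (label 1 = case)."""
    index_dates: dict[str, object] = {}
    labels: dict[str, int] = {}
    for _, r in pairs.iterrows():
        index_dates[r["case_id"]] = r["case_index_date"]
        labels[r["case_id"]] = 1
        index_dates[r["control_id"]] = r["control_index_date"]
        labels[r["control_id"]] = 0
    return encode_dataset(patients, events, index_dates, labels, vocabulary, codec,
                          scheme, max_tokens)
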