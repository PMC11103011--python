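"""Rule-based extraction of disclosed LGBT status from clinical note text.

A note is scanned for status keywords ("gay", "lesbian", "bisexual",
"transgender", ...) and then matched against positive and negative regular
expression patterns carrying a keyword slot.  A negative match (e.g. "denies
being gay") takes precedence over a positive one by default.  Notes with no
keyword, or with a keyword but no matching pattern, abstain; in the original
hybrid pipeline those documents fall through to a machine-learned classifier,
which this rule-only stage deliberately replaces with Abstain.

Patient-level status aggregates note-level calls: Yes if any note affirms,
else No if any note negates, else Unknown (no status-bearing documentation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

import pandas as pd
import yaml

__all__ = ["StatusRuleSet", "classify_note", "assign_patient_status", "assign_statuses"]

DEFAULT_KEYWORDS = ["gay", "lesbian", "bisexual", "transgender", "lgbt"]

# {kw} is the keyword slot; patterns are applied case-insensitively.
DEFAULT_POSITIVE_PATTERNS = [
    r"identifies as (?:a |an )?{kw}\b",
    r"self-identifies as (?:a |an )?{kw}\b",
    r"reports being (?:a |an )?{kw}\b",
    r"is openly {kw}\b",
    r"came out as (?:a |an )?{kw}\b",
    r"being {kw}\b",
    r"\b{kw} identity\b",
]
DEFAULT_NEGATIVE_PATTERNS = [
    r"denies being (?:a |an )?{kw}\b",
    r"denies (?:a |an )?{kw}\b",
    r"denied being (?:a |an )?{kw}\b",
    r"does not identify as (?:a |an )?{kw}\b",
    r"is not (?:a |an )?{kw}\b",
    r"no report of (?:a |an )?{kw}\b",
    r"not {kw}\b",
]


@dataclass
class StatusRuleSet:
    keywords: list[str] = field(default_factory=lambda: list(DEFAULT_KEYWORDS))
    positive_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_POSITIVE_PATTERNS))
    negative_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATIVE_PATTERNS))
    #: when both polarities match, the negative call wins
    negative_over_positive: bool = True

    def __post_init__(self) -> None:
        for tpl in self.positive_patterns + self.negative_patterns:
            if "{kw}" not in tpl:
                raise ValueError(f"pattern missing keyword slot {{kw}}: {tpl!r}")
            re.compile(tpl.format(kw="x"))  # must compile once instantiated

    @cached_property
    def _keyword_re(self) -> re.Pattern:
        alt = "|".join(re.escape(k) for k in self.keywords)
        return re.compile(rf"\b(?:{alt})\b", re.IGNORECASE)

    @cached_property
    def _positive_res(self) -> list[re.Pattern]:
        return self._compile(self.positive_patterns)

    @cached_property
    def _negative_res(self) -> list[re.Pattern]:
        return self._compile(self.negative_patterns)

    def _compile(self, templates: list[str]) -> list[re.Pattern]:
        alt = "|".join(re.escape(k) for k in self.keywords)
        return [re.compile(tpl.format(kw=f"(?:{alt})"), re.IGNORECASE) for tpl in templates]

    @classmethod
    def from_yaml(cls, path) -> "StatusRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "keywords": self.keywords,
                "positive_patterns": self.positive_patterns,
                "negative_patterns": self.negative_patterns,
                "negative_over_positive": self.negative_over_positive,
            }, fh, sort_keys=False)


def classify_note(text: str, rules: StatusRuleSet | None = None) -> str:
    """Classify one note as ``"Yes"``, ``"No"`` or ``"Abstain"``.

    Keywords are matched on word boundaries and case-insensitively, so e.g.
    "gaylord street clinic" contains no status keyword and abstains.
    """
    rules = rules or StatusRuleSet()
    if not rules._keyword_re.search(text):
        return "Abstain"
    neg = any(rx.search(text) for rx in rules._negative_res)
    pos = any(rx.search(text) for rx in rules._positive_res)
    if neg and (rules.negative_over_positive or not pos):
        return "No"
    if pos:
        return "Yes"
    if neg:
        return "No"
    return "Abstain"


def assign_patient_status(notes_for_patient, rules: StatusRuleSet | None = None,
                          policy: str = "any_positive") -> str:
    """Aggregate a patient's note-level calls into Yes/No/Unknown.

    ``notes_for_patient`` is an iterable of note texts, or a DataFrame with
    ``text`` (and ``note_date`` when ``policy="most_recent"``).  The default
    ``any_positive`` policy reflects disclosure-once semantics: a single
    affirmed note outweighs any number of negations.
    """
    rules = rules or StatusRuleSet()
    if isinstance(notes_for_patient, pd.DataFrame):
        if policy == "most_recent":
            notes_for_patient = notes_for_patient.sort_values("note_date")
        texts = notes_for_patient["text"].tolist()
    else:
        texts = list(notes_for_patient)
    calls = [classify_note(t, rules) for t in texts]
    if policy == "most_recent":
        decided = [c for c in calls if c != "Abstain"]
        return decided[-1] if decided else "Unknown"
    if "Yes" in calls:
        return "Yes"
    if "No" in calls:
        return "No"
    return "Unknown"


def assign_statuses(notes: pd.DataFrame, patient_ids, rules: StatusRuleSet | None = None,
                    policy: str = "any_positive") -> pd.DataFrame:
    """Patient-level status for every id in ``patient_ids``.

    Patients with no notes at all are Unknown.  Returns a frame with columns
    ``patient_id`` and ``lgbt_status``.
    """
    rules = rules or StatusRuleSet()
    out = {pid: "Unknown" for pid in patient_ids}
    if len(notes):
        for pid, group in notes.groupby("patient_id"):
            if pid in out:
                out[pid] = assign_patient_status(group, rules, policy=policy)
    return pd.DataFrame({"patient_id": list(out), "lgbt_status": list(out.values())})
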