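"""Model-agnostic logit-mutation explainability.

For any scorer exposing ``predict_proba(encoded_patients) -> probabilities``,
the impact of a feature on one patient is the logit difference between the
score at the current feature value and the score after mutating the feature
to a reference value:

    impact       = logit(p_cur) - logit(p_ref)
    impact score = impact / (current - reference)

A positive impact means the current value raises risk relative to the
reference.  Binary and temporal features use 0/absence as the reference, so
impact and impact score coincide; age uses the cohort reference age (61.6
years by default) and is measured per 10-year change.  The pairwise
interaction of two features compares the impact of mutating both with the
impacts of mutating each separately; the residual — the excess of the pair's
joint effect over the sum of its solo effects, measured from the
double-reference baseline — is the interaction.  It is exactly zero for any
scorer additive in the logit, equals the product-term weight for a scorer
with one, and is positive when the combined risk exceeds the sum of the two
separate risks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ehrisk.encoding import EncodedDataset, EncodedPatient

__all__ = [
    "MutationSpec", "ImpactResult", "InteractionResult", "NullMutationError",
    "OverlappingMutationError", "impact", "interaction", "aggregate_impacts",
    "rank_interactions", "AdditiveLogitScorer", "REFERENCE_AGE",
]

#: cohort average age used as the reference for age mutations (years)
REFERENCE_AGE = 61.6

CLAMP_EPS = 1e-12


class NullMutationError(ValueError):
    """Mutating an absent temporal feature to absence is a no-op."""


class OverlappingMutationError(ValueError):
    """Two mutations touching the same encoding slot."""


@dataclass(frozen=True)
class MutationSpec:
    """What to mutate and toward which reference.

    ``kind`` is ``"temporal"`` (target = feature code; mutation removes every
    token of the family across all periods), ``"static"`` (target =
    ``"variable=Level"``; mutation sends the patient to the variable's
    reference level) or ``"age"`` (target ignored; mutation sets age to
    ``reference``).
    """

    kind: str
    target: str = ""
    reference: float = 0.0
    #: restrict a temporal mutation to these period ids (None = all 21)
    periods: tuple[int, ...] | None = None

    @staticmethod
    def temporal(code: str, periods=None) -> "MutationSpec":
        return MutationSpec(kind="temporal", target=code,
                            periods=None if periods is None else tuple(periods))

    @staticmethod
    def static(column: str) -> "MutationSpec":
        return MutationSpec(kind="static", target=column)

    @staticmethod
    def age(reference: float = REFERENCE_AGE) -> "MutationSpec":
        return MutationSpec(kind="age", reference=reference)

    @property
    def label(self) -> str:
        return self.target if self.kind != "age" else "age"


@dataclass
class ImpactResult:
    patient_id: str
    feature: str
    p_cur: float
    p_ref: float
    impact: float
    impact_score: float
    current_value: float
    reference_value: float


@dataclass
class InteractionResult:
    feature_a: str
    feature_b: str
    patient_id: str
    impact_a: float
    impact_b: float
    joint_impact: float
    interaction: float


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return np.log(p) - np.log1p(-p)


def _current_value(patient: EncodedPatient, mutation: MutationSpec,
                   dataset: EncodedDataset) -> float:
    if mutation.kind == "temporal":
        fid = dataset.vocabulary.code_to_id[mutation.target]
        hit = any(f == fid and (mutation.periods is None or p in mutation.periods)
                  for f, p in patient.tokens)
        return 1.0 if hit else 0.0
    if mutation.kind == "static":
        cols = dataset.codec.columns
        if mutation.target not in cols:
            raise KeyError(f"unknown static column {mutation.target!r}")
        return float(patient.static[cols.index(mutation.target)])
    if mutation.kind == "age":
        return float(patient.static[0])
    raise ValueError(f"unknown mutation kind {mutation.kind!r}")


def _slots(mutation: MutationSpec, dataset: EncodedDataset) -> set:
    """Encoding slots a mutation writes (to detect overlap)."""
    if mutation.kind == "temporal":
        return {("temporal", mutation.target)}
    if mutation.kind == "static":
        var = mutation.target.split("=", 1)[0]
        return {("static", var)}
    return {("age",)}


def apply_mutation(patient: EncodedPatient, mutation: MutationSpec,
                   dataset: EncodedDataset) -> EncodedPatient:
    """Return a mutated copy; the original encoding is never modified."""
    if mutation.kind == "temporal":
        fid = dataset.vocabulary.code_to_id[mutation.target]
        tokens = [t for t in patient.tokens
                  if not (t[0] == fid and (mutation.periods is None or t[1] in mutation.periods))]
        return replace(patient, tokens=tokens, static=patient.static.copy())
    static = patient.static.copy()
    if mutation.kind == "static":
        var = mutation.target.split("=", 1)[0]
        lo, hi = dataset.codec.block(var)
        static[lo:hi] = 0.0  # reference level emits all zeros
        return replace(patient, static=static, tokens=list(patient.tokens))
    if mutation.kind == "age":
        static[0] = mutation.reference
        return replace(patient, static=static, tokens=list(patient.tokens))
    raise ValueError(f"unknown mutation kind {mutation.kind!r}")


def _denominator(mutation: MutationSpec, current: float, reference: float) -> float:
    if mutation.kind == "age":
        return (current - reference) / 10.0  # impact score per decade of age
    return current - reference


def impact(scorer, patient: EncodedPatient, mutation: MutationSpec,
           dataset: EncodedDataset) -> ImpactResult:
    """Impact and impact score of one mutation on one patient."""
    current = _current_value(patient, mutation, dataset)
    reference = mutation.reference
    if mutation.kind == "temporal" and current == 0.0:
        raise NullMutationError(
            f"feature {mutation.target!r} absent and reference is absence: null mutation")
    p_cur = float(scorer.predict_proba([patient])[0])
    if current == reference:
        p_ref, imp = p_cur, 0.0
    else:
        mutated = apply_mutation(patient, mutation, dataset)
        p_ref = float(scorer.predict_proba([mutated])[0])
        imp = float(_logit(p_cur) - _logit(p_ref))
    denom = _denominator(mutation, current, reference)
    score = imp / denom if denom != 0 else 0.0
    return ImpactResult(patient_id=patient.patient_id, feature=mutation.label,
                        p_cur=p_cur, p_ref=p_ref, impact=imp, impact_score=score,
                        current_value=current, reference_value=reference)


def interaction(scorer, patient: EncodedPatient, mutation_a: MutationSpec,
                mutation_b: MutationSpec, dataset: EncodedDataset) -> InteractionResult:
    """Pairwise interaction: residual of the joint mutation against the two singles.

    Positive values mean the combined risk exceeds the sum of the separate
    risks in the logit; symmetric in the two mutations.
    """
    if _slots(mutation_a, dataset) & _slots(mutation_b, dataset):
        raise OverlappingMutationError(
            f"mutations {mutation_a.label!r} and {mutation_b.label!r} share an encoding slot")
    res_a = impact(scorer, patient, mutation_a, dataset)
    res_b = impact(scorer, patient, mutation_b, dataset)
    joint = apply_mutation(apply_mutation(patient, mutation_a, dataset), mutation_b, dataset)
    p_joint = float(scorer.predict_proba([joint])[0])
    joint_imp = float(_logit(res_a.p_cur) - _logit(p_joint))
    # iA + iB - joint equals the excess of the pair's joint effect over the sum
    # of its solo effects measured from the double-reference baseline, so a
    # planted product term gamma comes out as +gamma
    return InteractionResult(
        feature_a=mutation_a.label, feature_b=mutation_b.label,
        patient_id=patient.patient_id, impact_a=res_a.impact, impact_b=res_b.impact,
        joint_impact=joint_imp, interaction=res_a.impact + res_b.impact - joint_imp)


def _carriers(dataset: EncodedDataset, mutation: MutationSpec) -> list[int]:
    out = []
    for i, p in enumerate(dataset.patients):
        cur = _current_value(p, mutation, dataset)
        if cur != mutation.reference:
            out.append(i)
    return out


def aggregate_impacts(scorer, dataset: EncodedDataset, mutation: MutationSpec) -> dict:
    """Mean impact/impact score over patients carrying a non-reference value.

    Returns ``{feature, n, mean_impact, sd_impact, mean_impact_score,
    direction}``; ``n`` is 0 with a flag when no patient is eligible.
    """
    idx = _carriers(dataset, mutation)
    if not idx:
        return {"feature": mutation.label, "n": 0, "mean_impact": np.nan,
                "sd_impact": np.nan, "mean_impact_score": np.nan,
                "direction": "", "empty": True}
    originals = [dataset.patients[i] for i in idx]
    mutated = [apply_mutation(p, mutation, dataset) for p in originals]
    p_cur = np.asarray(scorer.predict_proba(originals), dtype=float)
    p_ref = np.asarray(scorer.predict_proba(mutated), dtype=float)
    imps = _logit(p_cur) - _logit(p_ref)
    denoms = np.array([_denominator(mutation, _current_value(p, mutation, dataset),
                                    mutation.reference) for p in originals])
    scores = imps / denoms
    mean = float(imps.mean())
    return {"feature": mutation.label, "n": len(idx), "mean_impact": mean,
            "sd_impact": float(imps.std(ddof=1)) if len(idx) > 1 else 0.0,
            "mean_impact_score": float(scores.mean()),
            "direction": "+" if mean >= 0 else "-", "empty": False}


def impact_table(scorer, dataset: EncodedDataset,
                 mutations: list[MutationSpec]) -> pd.DataFrame:
    """Aggregated impact summary for many features, ranked by |mean impact|."""
    rows = [aggregate_impacts(scorer, dataset, m) for m in mutations]
    df = pd.DataFrame(rows)
    return df.sort_values("mean_impact", key=lambda s: s.abs(), ascending=False,
                          kind="stable").reset_index(drop=True)


def rank_interactions(scorer, dataset: EncodedDataset, anchor: MutationSpec,
                      candidates: list[MutationSpec]) -> pd.DataFrame:
    """Mean interaction of each candidate feature with the anchor.

    Averaged over patients carrying both features; the anchor itself (or any
    candidate sharing its encoding slot) is excluded; sorted by absolute mean
    interaction, descending.
    """
    anchor_slots = _slots(anchor, dataset)
    anchor_idx = set(_carriers(dataset, anchor))
    rows = []
    for cand in candidates:
        if _slots(cand, dataset) & anchor_slots:
            continue
        both = [i for i in _carriers(dataset, cand) if i in anchor_idx]
        if not both:
            rows.append({"feature": cand.label, "n": 0, "mean_interaction": np.nan})
            continue
        pats = [dataset.patients[i] for i in both]
        p_cur = np.asarray(scorer.predict_proba(pats), dtype=float)
        m_a = [apply_mutation(p, anchor, dataset) for p in pats]
        m_b = [apply_mutation(p, cand, dataset) for p in pats]
        m_ab = [apply_mutation(p, cand, dataset) for p in m_a]
        p_a = np.asarray(scorer.predict_proba(m_a), dtype=float)
        p_b = np.asarray(scorer.predict_proba(m_b), dtype=float)
        p_ab = np.asarray(scorer.predict_proba(m_ab), dtype=float)
        lc = _logit(p_cur)
        inter = (lc - _logit(p_a)) + (lc - _logit(p_b)) - (lc - _logit(p_ab))
        rows.append({"feature": cand.label, "n": len(both),
                     "mean_interaction": float(inter.mean())})
    df = pd.DataFrame(rows, columns=["feature", "n", "mean_interaction"])
    return df.sort_values("mean_interaction", key=lambda s: s.abs(),
                          ascending=False, na_position="last",
                          kind="stable").reset_index(drop=True)


class AdditiveLogitScorer:
    """Reference scorer: sigmoid of a linear (optionally product-term) logit.

    Useful both as an interpretable baseline and as a closed-form oracle for
    the mutation statistics: binary-feature impact equals the feature's
    weight exactly, and pairwise interactions equal the product-term weight
    (zero when absent).

    ``temporal_weights`` maps feature codes to weights on presence;
    ``static_weights`` maps static columns (e.g. ``"marital_status=Married"``)
    to weights on the encoded value; ``age_per_decade`` weights
    ``(age - reference_age)/10``; ``product_terms`` maps key pairs to weights
    on the product of the two resolved values (keys as above, or ``"age"``).
    """

    def __init__(self, bias: float = 0.0,
                 temporal_weights: dict[str, float] | None = None,
                 static_weights: dict[str, float] | None = None,
                 age_per_decade: float = 0.0,
                 product_terms: dict[tuple[str, str], float] | None = None,
                 dataset: EncodedDataset | None = None,
                 reference_age: float = REFERENCE_AGE):
        self.bias = bias
        self.temporal_weights = temporal_weights or {}
        self.static_weights = static_weights or {}
        self.age_per_decade = age_per_decade
        self.product_terms = product_terms or {}
        self.dataset = dataset
        self.reference_age = reference_age

    def _value(self, patient: EncodedPatient, key: str) -> float:
        if key == "age":
            return (float(patient.static[0]) - self.reference_age) / 10.0
        vocab = self.dataset.vocabulary
        if key in vocab.code_to_id:
            fid = vocab.code_to_id[key]
            return 1.0 if any(f == fid for f, _ in patient.tokens) else 0.0
        cols = self.dataset.codec.columns
        return float(patient.static[cols.index(key)])

    def logit(self, patient: EncodedPatient) -> float:
        z = self.bias
        for code, w in self.temporal_weights.items():
            z += w * self._value(patient, code)
        for col, w in self.static_weights.items():
            z += w * self._value(patient, col)
        if self.age_per_decade:
            z += self.age_per_decade * self._value(patient, "age")
        for (a, b), w in self.product_terms.items():
            z += w * self._value(patient, a) * self._value(patient, b)
        return z

    def predict_proba(self, patients) -> np.ndarray:
        if isinstance(patients, EncodedDataset):
            patients = patients.patients
        if isinstance(patients, EncodedPatient):
            patients = [patients]
        z = np.array([self.logit(p) for p in patients], dtype=float)
        return 0.5 * (1.0 + np.tanh(0.5 * z))
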