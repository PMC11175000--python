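"""MEDOC combined Mediterranean/Western adherence scoring engine.

Each of the 22 score rows awards a base point of +1 when the respondent's
aggregated weekly servings (or categorical behavior answer) fall in the
Mediterranean-recommended branch and -1 otherwise.  Seven rows carry a
behavior modifier worth an extra +0.5 on the favorable branch when the
matching behavior is Mediterranean (e.g. seasonal produce, local-producer
meat) and an extra -0.5 penalty on the unfavorable branch when it is not, so
per-row points lie in {-1.5, -1, +1, +1.5}.  The Mediterranean-diet (MD)
subscore sums the positive points, the Western-diet (WD) subscore the
negative ones, and the raw total (their sum) is rescaled linearly onto the
published -20 (full WD) .. +20 (full MD) axis.

Rule kinds
----------
frequency_range
    The pooled weekly servings of the mapped items must fall in a favorable
    interval; daily cut-offs are stored pre-converted (x7) to weekly servings.
comparison
    Compares the raw weekly frequencies of two items (loaf vs fresh bread).
categorical
    Scored directly from a behavior answer (olive-oil use, nibbling, ...).

A rule may also carry a *gate*: the breakfast row treats "no breakfast" as an
unfavorable answer regardless of the reported croissant-breakfast frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .errors import DomainError, ScoringError, SchemaError
from .ffq import QuestionnaireSchema, ResponseProfile

BASE_POINT = 1.0
MODIFIER_DELTA = 0.5
NORMALIZED_MAX = 20.0

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"


@dataclass(frozen=True)
class Interval:
    """A frequency interval with explicit open/closed ends (weekly servings)."""

    lo: float | None
    hi: float | None
    lo_closed: bool = True
    hi_closed: bool = True

    def contains(self, x: float) -> bool:
        if self.lo is not None:
            if x < self.lo or (x == self.lo and not self.lo_closed):
                return False
        if self.hi is not None:
            if x > self.hi or (x == self.hi and not self.hi_closed):
                return False
        return True


@dataclass(frozen=True)
class Modifier:
    behavior: str
    favorable_answer: str
    unfavorable_answer: str


@dataclass(frozen=True)
class Gate:
    """A behavior answer that forces the unfavorable branch (breakfast row)."""

    behavior: str
    unfavorable_answer: str


@dataclass(frozen=True)
class ScoringRule:
    row_id: str
    kind: str  # frequency_range | comparison | categorical
    label: str = ""
    unit: str = "per_week"
    favorable: Interval | None = None
    modifier: Modifier | None = None
    gate: Gate | None = None
    # comparison rules
    left_item: str | None = None
    right_item: str | None = None
    # categorical rules
    behavior: str | None = None
    favorable_answer: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "frequency_range" and self.favorable is None:
            raise SchemaError(f"rule {self.row_id!r}: frequency rule needs an interval")
        if self.kind == "comparison" and not (self.left_item and self.right_item):
            raise SchemaError(f"rule {self.row_id!r}: comparison rule needs two items")
        if self.kind == "categorical" and not (self.behavior and self.favorable_answer):
            raise SchemaError(
                f"rule {self.row_id!r}: categorical rule needs a behavior and answer"
            )

    def point_values(self) -> tuple[float, ...]:
        """All point values this rule can emit, ascending."""
        vals = [-BASE_POINT, BASE_POINT]
        if self.modifier is not None:
            vals = [-BASE_POINT - MODIFIER_DELTA, -BASE_POINT, BASE_POINT, BASE_POINT + MODIFIER_DELTA]
        return tuple(vals)


@dataclass(frozen=True)
class ScoringMatrix:
    name: str
    rules: tuple[ScoringRule, ...]

    def __post_init__(self) -> None:
        ids = [r.row_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate score-row ids in matrix")

    @property
    def raw_max(self) -> float:
        return matrix_extrema(self)[1]

    @property
    def raw_min(self) -> float:
        return matrix_extrema(self)[0]

    def rule(self, row_id: str) -> ScoringRule:
        for r in self.rules:
            if r.row_id == row_id:
                return r
        raise SchemaError(f"unknown score row {row_id!r}")


@dataclass(frozen=True)
class ItemScore:
    row_id: str
    branch: str  # favorable | unfavorable
    base: float
    modifier_delta: float
    servings: float | None = None
    behavior_answer: str | None = None

    @property
    def points(self) -> float:
        return self.base + self.modifier_delta


@dataclass
class MedocScoreCard:
    respondent_id: str
    administration: str
    item_scores: list[ItemScore]
    raw_max: float
    warnings: list[str] = field(default_factory=list)

    @property
    def md_subscore(self) -> float:
        return sum(s.points for s in self.item_scores if s.points > 0)

    @property
    def wd_subscore(self) -> float:
        return sum(s.points for s in self.item_scores if s.points < 0)

    @property
    def raw_total(self) -> float:
        return self.md_subscore + self.wd_subscore

    @property
    def normalized_total(self) -> float:
        if self.raw_max == 0:
            return 0.0
        return self.raw_total * NORMALIZED_MAX / self.raw_max


# ---------------------------------------------------------------------------
# matrix loading
# ---------------------------------------------------------------------------

def _interval_from_dict(d: Mapping) -> Interval:
    return Interval(
        lo=None if d.get("lo") is None else float(d["lo"]),
        hi=None if d.get("hi") is None else float(d["hi"]),
        lo_closed=bool(d.get("lo_closed", True)),
        hi_closed=bool(d.get("hi_closed", True)),
    )


def load_matrix(path: str | Path = "builtin") -> ScoringMatrix:
    """Load the scoring matrix from JSON, or the builtin 22-row default."""
    if path == "builtin":
        raw = json.loads(
            resources.files("dietscore.data").joinpath("matrix.json").read_text()
        )
    else:
        try:
            raw = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"matrix file {path} is not valid JSON: {exc}") from exc
    rules = []
    for d in raw["rules"]:
        mod = d.get("modifier")
        gate = d.get("gate")
        rules.append(
            ScoringRule(
                row_id=str(d["row_id"]),
                kind=str(d["kind"]),
                label=str(d.get("label", d["row_id"])),
                unit=str(d.get("unit", "per_week")),
                favorable=_interval_from_dict(d["favorable"]) if d.get("favorable") else None,
                modifier=Modifier(
                    behavior=str(mod["behavior"]),
                    favorable_answer=str(mod["favorable_answer"]),
                    unfavorable_answer=str(mod["unfavorable_answer"]),
                )
                if mod
                else None,
                gate=Gate(
                    behavior=str(gate["behavior"]),
                    unfavorable_answer=str(gate["unfavorable_answer"]),
                )
                if gate
                else None,
                left_item=d.get("left_item"),
                right_item=d.get("right_item"),
                behavior=d.get("behavior"),
                favorable_answer=d.get("favorable_answer"),
            )
        )
    return ScoringMatrix(name=str(raw.get("name", "matrix")), rules=tuple(rules))


def validate_matrix(matrix: ScoringMatrix, schema: QuestionnaireSchema) -> None:
    """Cross-check matrix and schema: every frequency row must be fed by the
    aggregation map, and every aggregation row must exist in the matrix."""
    row_ids = {r.row_id for r in matrix.rules}
    for row in schema.aggregation_map:
        if row not in row_ids:
            raise SchemaError(f"aggregation map references unknown score row {row!r}")
    for r in matrix.rules:
        if r.kind == "frequency_range" and r.row_id not in schema.aggregation_map:
            raise SchemaError(f"score row {r.row_id!r} has no mapped items")
        if r.kind == "comparison":
            for iid in (r.left_item, r.right_item):
                if iid not in schema.item_ids:
                    raise SchemaError(
                        f"comparison row {r.row_id!r} references unknown item {iid!r}"
                    )


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------

def servings_per_week(frequency: float, portion_multiplier: float = 1.0) -> float:
    """Combine a weekly frequency count with a portion multiplier."""
    if frequency < 0 or not math.isfinite(frequency):
        raise DomainError(f"weekly frequency must be >= 0, got {frequency}")
    if portion_multiplier <= 0:
        raise DomainError(f"portion multiplier must be > 0, got {portion_multiplier}")
    return frequency * portion_multiplier


def _modifier_delta(
    rule: ScoringRule, favorable: bool, behavior_answer: str | None
) -> float:
    if rule.modifier is None or behavior_answer is None:
        return 0.0
    mod = rule.modifier
    if behavior_answer not in (mod.favorable_answer, mod.unfavorable_answer):
        raise DomainError(
            f"rule {rule.row_id!r}: behavior answer {behavior_answer!r} outside domain"
        )
    if favorable and behavior_answer == mod.favorable_answer:
        return MODIFIER_DELTA
    if not favorable and behavior_answer == mod.unfavorable_answer:
        return -MODIFIER_DELTA
    return 0.0


def score_item(
    rule: ScoringRule,
    servings: float | None = None,
    behavior_answer: str | None = None,
    gate_answer: str | None = None,
    comparison: tuple[float, float] | None = None,
) -> ItemScore:
    """Score a single rule.

    ``servings`` are aggregated weekly servings (frequency rules);
    ``behavior_answer`` is the modifier answer for frequency rules with a
    modifier, or the branch-selecting answer for categorical rules;
    ``comparison`` supplies the (left, right) weekly frequencies for
    comparison rules; ``gate_answer`` the gating behavior answer, if any.
    """
    if rule.kind == "frequency_range":
        if servings is None:
            raise ScoringError(f"rule {rule.row_id!r}: no frequency data")
        if servings < 0:
            raise DomainError(f"rule {rule.row_id!r}: negative servings {servings}")
        favorable = rule.favorable.contains(servings)
        if rule.gate is not None and gate_answer == rule.gate.unfavorable_answer:
            favorable = False
    elif rule.kind == "comparison":
        if comparison is None:
            raise ScoringError(f"rule {rule.row_id!r}: no comparison data")
        favorable = comparison[0] <= comparison[1]
    elif rule.kind == "categorical":
        if behavior_answer is None:
            raise ScoringError(f"rule {rule.row_id!r}: missing behavior answer")
        favorable = behavior_answer == rule.favorable_answer
    else:
        raise SchemaError(f"rule {rule.row_id!r}: unknown kind {rule.kind!r}")

    base = BASE_POINT if favorable else -BASE_POINT
    delta = _modifier_delta(rule, favorable, behavior_answer) if rule.kind != "categorical" else 0.0
    return ItemScore(
        row_id=rule.row_id,
        branch=FAVORABLE if favorable else UNFAVORABLE,
        base=base,
        modifier_delta=delta,
        servings=servings,
        behavior_answer=behavior_answer,
    )


def _aggregate_servings(
    profile: ResponseProfile,
    schema: QuestionnaireSchema,
    row_id: str,
    warnings: list[str],
) -> float:
    items = schema.aggregation_map.get(row_id)
    if not items:
        raise ScoringError(f"score row {row_id!r} has no mapped items")
    present = [i for i in items if i in profile.frequencies]
    if not present:
        raise ScoringError(f"score row {row_id!r}: no frequency data for mapped items")
    total = 0.0
    for item in present:
        label = profile.portions.get(item)
        if label is None and schema.item(item).has_portion_question:
            warnings.append(f"{row_id}: missing portion for {item}, assuming standard")
        total += servings_per_week(
            profile.frequencies[item], schema.portion_multiplier(label)
        )
    return total


def score_profile(
    profile: ResponseProfile,
    matrix: ScoringMatrix | None = None,
    schema: QuestionnaireSchema | None = None,
) -> MedocScoreCard:
    """Score one respondent against the full matrix."""
    from .ffq import load_schema  # local to avoid import cycle at module load

    if matrix is None:
        matrix = load_matrix()
    if schema is None:
        schema = load_schema()

    warnings: list[str] = []
    item_scores: list[ItemScore] = []
    _, raw_max = matrix_extrema(matrix)
    for rule in matrix.rules:
        if rule.kind == "frequency_range":
            servings = _aggregate_servings(profile, schema, rule.row_id, warnings)
            mod_answer = (
                profile.behaviors.get(rule.modifier.behavior)
                if rule.modifier is not None
                else None
            )
            gate_answer = (
                profile.behaviors.get(rule.gate.behavior)
                if rule.gate is not None
                else None
            )
            item_scores.append(
                score_item(rule, servings=servings, behavior_answer=mod_answer,
                           gate_answer=gate_answer)
            )
        elif rule.kind == "comparison":
            try:
                left = profile.frequencies[rule.left_item]
                right = profile.frequencies[rule.right_item]
            except KeyError as exc:
                raise ScoringError(
                    f"score row {rule.row_id!r}: missing frequency for {exc.args[0]!r}"
                ) from exc
            item_scores.append(score_item(rule, comparison=(left, right)))
        else:  # categorical
            answer = profile.behaviors.get(rule.behavior)
            if answer is None:
                raise ScoringError(
                    f"score row {rule.row_id!r}: missing behavior answer "
                    f"{rule.behavior!r}"
                )
            item_scores.append(score_item(rule, behavior_answer=answer))

    return MedocScoreCard(
        respondent_id=profile.respondent_id,
        administration=profile.administration,
        item_scores=item_scores,
        raw_max=raw_max,
        warnings=warnings,
    )


def matrix_extrema(matrix: ScoringMatrix) -> tuple[float, float]:
    """Raw score range attainable under the matrix, by per-rule enumeration.

    Rules are evaluated independently, so the extrema of the sum are the sums
    of per-rule extrema over each rule's attainable point values.
    """
    lo = sum(min(r.point_values()) for r in matrix.rules)
    hi = sum(max(r.point_values()) for r in matrix.rules)
    return (lo, hi)


def normalize_score(raw: float, matrix: ScoringMatrix) -> float:
    """Map a raw total linearly onto the -20..+20 published scale."""
    lo, hi = matrix_extrema(matrix)
    if raw < lo or raw > hi:
        raise DomainError(f"raw score {raw} outside matrix range [{lo}, {hi}]")
    if hi == 0:
        return 0.0
    return raw * NORMALIZED_MAX / hi


# ---------------------------------------------------------------------------
# extremal profile construction
# ---------------------------------------------------------------------------

def _point_in_interval(iv: Interval) -> float:
    x = 0.0
    while x <= 2000.0:
        if iv.contains(x):
            return x
        x += 0.5
    raise ScoringError("no attainable point found inside favorable interval")


def _point_outside_interval(iv: Interval) -> float:
    x = 0.0
    while x <= 2000.0:
        if not iv.contains(x):
            return x
        x += 0.5
    raise ScoringError("favorable interval covers all non-negative frequencies")


def extremal_profile(
    schema: QuestionnaireSchema,
    matrix: ScoringMatrix,
    favorable: bool = True,
    respondent_id: str | None = None,
) -> ResponseProfile:
    """Construct the profile that hits every rule's favorable (or unfavorable)
    branch together with the matching modifier answer.

    Aggregated rows place their whole target quantity on the first mapped
    item at the standard portion, so the pooled servings equal the chosen
    branch point exactly.
    """
    freq = {item: 0.0 for item in schema.item_ids}
    portions = {
        item: "standard"
        for item in schema.item_ids
        if schema.item(item).has_portion_question
    }
    behaviors: dict[str, str] = {}

    for rule in matrix.rules:
        if rule.kind == "frequency_range":
            target = (
                _point_in_interval(rule.favorable)
                if favorable
                else _point_outside_interval(rule.favorable)
            )
            first = schema.aggregation_map[rule.row_id][0]
            freq[first] = target
            for other in schema.aggregation_map[rule.row_id][1:]:
                freq[other] = 0.0
            if rule.gate is not None:
                gate_domain = schema.behavior(rule.gate.behavior).answers
                behaviors[rule.gate.behavior] = (
                    next(a for a in gate_domain if a != rule.gate.unfavorable_answer)
                    if favorable
                    else rule.gate.unfavorable_answer
                )
        elif rule.kind == "comparison":
            if favorable:
                freq[rule.left_item] = min(
                    freq.get(rule.left_item, 0.0), freq.get(rule.right_item, 0.0)
                )
            else:
                freq[rule.left_item] = freq.get(rule.right_item, 0.0) + 1.0
        else:  # categorical
            domain = schema.behavior(rule.behavior).answers
            behaviors[rule.behavior] = (
                rule.favorable_answer
                if favorable
                else next(a for a in domain if a != rule.favorable_answer)
            )
        if rule.modifier is not None:
            behaviors[rule.modifier.behavior] = (
                rule.modifier.favorable_answer
                if favorable
                else rule.modifier.unfavorable_answer
            )

    if respondent_id is None:
        respondent_id = "extremal-md" if favorable else "extremal-wd"
    return ResponseProfile(
        respondent_id=respondent_id,
        age_years=40.0,
        sex="F",
        frequencies=freq,
        portions=portions,
        behaviors=behaviors,
    )
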