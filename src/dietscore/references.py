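"""Reference Mediterranean-diet adherence scorers and the validity workflow.

Two established instruments are re-implemented on the same respondent data
model so that scores computed from the combined questionnaire can be
validated against them:

MedDietScore (MDS)
    Eleven components each scored 0..5, total 0..55.  Pro-Mediterranean
    components (non-refined cereals, fruit, vegetables, legumes, fish) score
    higher with higher intake; meat, poultry and full-fat dairy are reversed;
    potatoes peak at the recommended 3-4 servings/week; alcohol peaks below
    3 wine glasses/day and falls to 0 above 7; olive oil is scored from the
    use-frequency behavior answer.

MEDILITE
    Nine food groups each scored 0/1/2 from three ordered consumption levels:
    Mediterranean-typical groups award 2 to the highest level, non-typical
    groups award 2 to the lowest, and alcohol awards 2 to the middle level.

Both rule sets live in JSON data files, so bins and cut points are
configurable without code changes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, SchemaError, ScoringError
from .ffq import QuestionnaireSchema, ResponseProfile
from .medoc import servings_per_week

MDS_MAX_COMPONENT = 5
MEDILITE_POINTS = {
    "md_typical": {"lowest": 0, "middle": 1, "highest": 2},
    "non_md": {"lowest": 2, "middle": 1, "highest": 0},
    "alcohol": {"lowest": 1, "middle": 2, "highest": 0},
}
DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class Bin:
    """A half-open (or closed) upper-bounded frequency bin mapping to a score."""

    max: float | None
    score: int
    closed: bool = False  # True: intake <= max; False: intake < max

    def matches(self, x: float) -> bool:
        if self.max is None:
            return True
        return x <= self.max if self.closed else x < self.max


@dataclass(frozen=True)
class MdsComponentRule:
    component_id: str
    direction: str  # pro | anti | special_potato | special_alcohol
    unit: str  # monthly_servings | weekly_servings | glasses_per_day | behavior
    items: tuple[str, ...] = ()
    bins: tuple[Bin, ...] = ()
    behavior: str | None = None
    behavior_scores: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.unit == "behavior":
            if not self.behavior or not self.behavior_scores:
                raise SchemaError(
                    f"component {self.component_id!r}: behavior rule needs scores"
                )
            bad = [s for s in self.behavior_scores.values() if not 0 <= s <= 5]
        else:
            if not self.bins or self.bins[-1].max is not None:
                raise SchemaError(
                    f"component {self.component_id!r}: bins must end with a "
                    "catch-all (max = null)"
                )
            bad = [b.score for b in self.bins if not 0 <= b.score <= 5]
        if bad:
            raise SchemaError(
                f"component {self.component_id!r}: scores outside 0..5: {bad}"
            )


@dataclass
class MdsResult:
    respondent_id: str
    component_scores: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.component_scores.values())


@dataclass(frozen=True)
class MediliteRule:
    group_id: str
    group_class: str  # md_typical | non_md | alcohol
    unit: str  # weekly_servings | units_per_day | behavior
    items: tuple[str, ...] = ()
    cuts: tuple[float, float] | None = None
    behavior: str | None = None
    behavior_levels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.group_class not in MEDILITE_POINTS:
            raise SchemaError(
                f"group {self.group_id!r}: unknown class {self.group_class!r}"
            )
        if self.unit == "behavior":
            if not self.behavior or not self.behavior_levels:
                raise SchemaError(
                    f"group {self.group_id!r}: behavior rule needs level mapping"
                )
        elif self.cuts is None or not self.cuts[0] < self.cuts[1]:
            raise SchemaError(
                f"group {self.group_id!r}: needs two increasing cut points"
            )


@dataclass
class MediliteResult:
    respondent_id: str
    group_points: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.group_points.values())


@dataclass
class ValidityReport:
    stratum: str
    statistic: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# rule loading
# ---------------------------------------------------------------------------

def load_mds_rules(path: str | Path = "builtin") -> tuple[MdsComponentRule, ...]:
    if path == "builtin":
        raw = json.loads(
            resources.files("dietscore.data").joinpath("mds_rules.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    rules = []
    for d in raw["components"]:
        rules.append(
            MdsComponentRule(
                component_id=str(d["component_id"]),
                direction=str(d["direction"]),
                unit=str(d["unit"]),
                items=tuple(d.get("items", ())),
                bins=tuple(
                    Bin(
                        max=None if b.get("max") is None else float(b["max"]),
                        score=int(b["score"]),
                        closed=bool(b.get("closed", False)),
                    )
                    for b in d.get("bins", ())
                ),
                behavior=d.get("behavior"),
                behavior_scores=d.get("behavior_scores"),
            )
        )
    if len(rules) != 11:
        raise SchemaError(f"expected 11 MDS components, got {len(rules)}")
    return tuple(rules)


def load_medilite_rules(path: str | Path = "builtin") -> tuple[MediliteRule, ...]:
    if path == "builtin":
        raw = json.loads(
            resources.files("dietscore.data").joinpath("medilite_rules.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    rules = []
    for d in raw["groups"]:
        rules.append(
            MediliteRule(
                group_id=str(d["group_id"]),
                group_class=str(d["group_class"]),
                unit=str(d["unit"]),
                items=tuple(d.get("items", ())),
                cuts=tuple(float(c) for c in d["cuts"]) if d.get("cuts") else None,
                behavior=d.get("behavior"),
                behavior_levels=d.get("behavior_levels"),
            )
        )
    if len(rules) != 9:
        raise SchemaError(f"expected 9 MEDILITE groups, got {len(rules)}")
    return tuple(rules)


# ---------------------------------------------------------------------------
# MDS scoring
# ---------------------------------------------------------------------------

def mds_component(rule: MdsComponentRule, intake: float) -> int:
    """Score one component from intake in the rule's own unit
    (monthly servings, weekly servings for potatoes, glasses/day for alcohol)."""
    if intake < 0 or not math.isfinite(intake):
        raise ScoringError(
            f"component {rule.component_id!r}: invalid intake {intake}"
        )
    if rule.unit == "behavior":
        raise ScoringError(
            f"component {rule.component_id!r} is behavior-scored; "
            "use mds_behavior_component"
        )
    for b in rule.bins:
        if b.matches(intake):
            return b.score
    raise ScoringError(f"component {rule.component_id!r}: no bin matched {intake}")


def mds_behavior_component(rule: MdsComponentRule, answer: str) -> int:
    try:
        return int(rule.behavior_scores[answer])
    except (KeyError, TypeError) as exc:
        raise ScoringError(
            f"component {rule.component_id!r}: answer {answer!r} has no score"
        ) from exc


def _component_intake(
    profile: ResponseProfile,
    schema: QuestionnaireSchema,
    items: Sequence[str],
    unit: str,
    weekly_to_monthly: float = 4.0,
    label: str = "",
) -> float:
    present = [i for i in items if i in profile.frequencies]
    if not present:
        raise ScoringError(f"{label}: no frequency data for mapped items")
    weekly = sum(
        servings_per_week(
            profile.frequencies[i],
            schema.portion_multiplier(profile.portions.get(i)),
        )
        for i in present
    )
    if unit == "monthly_servings":
        return weekly * weekly_to_monthly
    if unit in ("glasses_per_day", "units_per_day"):
        return weekly / DAYS_PER_WEEK
    return weekly


def mds_total(
    profile: ResponseProfile,
    rules: Sequence[MdsComponentRule] | None = None,
    schema: QuestionnaireSchema | None = None,
) -> MdsResult:
    """Component-wise MDS scoring and summation (total in 0..55)."""
    from .ffq import load_schema

    if rules is None:
        rules = load_mds_rules()
    if schema is None:
        schema = load_schema()
    scores: dict[str, int] = {}
    for rule in rules:
        if rule.unit == "behavior":
            answer = profile.behaviors.get(rule.behavior)
            if answer is None:
                raise ScoringError(
                    f"component {rule.component_id!r}: missing behavior answer"
                )
            scores[rule.component_id] = mds_behavior_component(rule, answer)
        else:
            intake = _component_intake(
                profile, schema, rule.items, rule.unit, label=rule.component_id
            )
            scores[rule.component_id] = mds_component(rule, intake)
    return MdsResult(respondent_id=profile.respondent_id, component_scores=scores)


def mds_extremal_profile(
    schema: QuestionnaireSchema | None = None,
    rules: Sequence[MdsComponentRule] | None = None,
) -> ResponseProfile:
    """A fully Mediterranean-adherent respondent sitting in the top-scoring
    bin of every MDS component: daily pro-MD foods, no meat, poultry or dairy,
    3 potato servings/week and about one wine glass/day."""
    from .ffq import load_schema

    if schema is None:
        schema = load_schema()
    if rules is None:
        rules = load_mds_rules()
    freq = {item: 0.0 for item in schema.item_ids}
    behaviors: dict[str, str] = {}
    for rule in rules:
        if rule.unit == "behavior":
            best = max(rule.behavior_scores, key=rule.behavior_scores.__getitem__)
            behaviors[rule.behavior] = best
            continue
        if rule.direction == "pro":
            # daily consumption of the first mapped item clears the top bin
            freq[rule.items[0]] = 7.0
        elif rule.direction == "anti":
            for item in rule.items:
                freq[item] = 0.0
        elif rule.direction == "special_potato":
            freq[rule.items[0]] = 3.0
        elif rule.direction == "special_alcohol":
            freq[rule.items[0]] = 7.0  # one glass a day, well under three
    portions = {
        item: "standard"
        for item in schema.item_ids
        if schema.item(item).has_portion_question
    }
    return ResponseProfile(
        respondent_id="mds-extremal",
        age_years=40.0,
        frequencies=freq,
        portions=portions,
        behaviors=behaviors,
    )


# ---------------------------------------------------------------------------
# MEDILITE scoring
# ---------------------------------------------------------------------------

def consumption_level(rule: MediliteRule, intake: float) -> str:
    """Assign lowest/middle/highest from the rule's two cut points:
    lowest below c1, middle in [c1, c2], highest above c2."""
    c1, c2 = rule.cuts
    if intake < c1:
        return "lowest"
    if intake <= c2:
        return "middle"
    return "highest"


def medilite_component(rule: MediliteRule, level: str) -> int:
    """Points for a consumption level under the rule's group class."""
    try:
        return MEDILITE_POINTS[rule.group_class][level]
    except KeyError as exc:
        raise ScoringError(
            f"group {rule.group_id!r}: unknown consumption level {level!r}"
        ) from exc


def medilite_total(
    profile: ResponseProfile,
    rules: Sequence[MediliteRule] | None = None,
    schema: QuestionnaireSchema | None = None,
) -> MediliteResult:
    """Per-group level assignment from cut points, then pointwise summation."""
    from .ffq import load_schema

    if rules is None:
        rules = load_medilite_rules()
    if schema is None:
        schema = load_schema()
    points: dict[str, int] = {}
    for rule in rules:
        if rule.unit == "behavior":
            answer = profile.behaviors.get(rule.behavior)
            if answer is None:
                raise ScoringError(
                    f"group {rule.group_id!r}: missing behavior answer"
                )
            level = rule.behavior_levels.get(answer)
            if level is None:
                raise ScoringError(
                    f"group {rule.group_id!r}: answer {answer!r} has no level"
                )
        else:
            intake = _component_intake(
                profile, schema, rule.items, rule.unit, label=rule.group_id
            )
            level = consumption_level(rule, intake)
        points[rule.group_id] = medilite_component(rule, level)
    return MediliteResult(respondent_id=profile.respondent_id, group_points=points)


# ---------------------------------------------------------------------------
# validity workflow
# ---------------------------------------------------------------------------

def scoring_table(
    profiles: Sequence[ResponseProfile],
    schema: QuestionnaireSchema | None = None,
    matrix=None,
    mds_rules: Sequence[MdsComponentRule] | None = None,
    medilite_rules: Sequence[MediliteRule] | None = None,
) -> pd.DataFrame:
    """Score a cohort with all three instruments; one row per profile."""
    from .ffq import load_schema
    from .medoc import load_matrix, score_profile

    if schema is None:
        schema = load_schema()
    if matrix is None:
        matrix = load_matrix()
    if mds_rules is None:
        mds_rules = load_mds_rules()
    if medilite_rules is None:
        medilite_rules = load_medilite_rules()
    rows = []
    for p in profiles:
        card = score_profile(p, matrix, schema)
        mds = mds_total(p, mds_rules, schema)
        medi = medilite_total(p, medilite_rules, schema)
        rows.append(
            {
                "respondent_id": p.respondent_id,
                "administration": p.administration,
                "age_years": p.age_years,
                "stratum": p.stratum,
                "md_subscore": card.md_subscore,
                "wd_subscore": card.wd_subscore,
                "raw_total": card.raw_total,
                "normalized_total": card.normalized_total,
                "mds_total": mds.total,
                "medilite_total": medi.total,
            }
        )
    return pd.DataFrame(rows)


def _pearson_fisher(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 observations per stratum")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("correlation undefined on a constant score vector")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(len(x) - 3)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return r, float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)), p


def validity_report(
    table: pd.DataFrame,
    stratify_by_age: bool = True,
    pairs: Sequence[tuple[str, str, str]] = (
        ("medoc_vs_mds", "md_subscore", "mds_total"),
        ("medoc_vs_medilite", "normalized_total", "medilite_total"),
    ),
) -> list[ValidityReport]:
    """Pearson correlations (Fisher-z 95% CIs) between the combined score and
    each reference instrument, optionally per age stratum."""
    reports: list[ValidityReport] = []
    if stratify_by_age:
        groups = [(s, g) for s, g in table.groupby("stratum")]
    else:
        groups = [("all", table)]
    for stratum, g in groups:
        for name, xcol, ycol in pairs:
            r, lo, hi, p = _pearson_fisher(
                g[xcol].to_numpy(float), g[ycol].to_numpy(float)
            )
            reports.append(
                ValidityReport(
                    stratum=stratum,
                    statistic=name,
                    r=float(r),
                    ci_low=lo,
                    ci_high=hi,
                    p_value=float(p),
                    n=len(g),
                )
            )
    return reports
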