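"""Questionnaire schema, respondent data model, validation and file I/O.

The default (builtin) schema describes a 39-item semi-quantitative food
frequency questionnaire: weekly consumption counts per food item, an ordered
portion-size category per item where a portion question exists, and a set of
categorical eating-behavior questions (seasonality, provenance, breakfast
habits, ...).  The schema also owns the aggregation map that pools individual
food items into the score rows consumed by the scoring engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ReadError, SchemaError

ITEM_CATEGORIES = (
    "vegetables_fruits",
    "cereals",
    "dairy",
    "meat_fish",
    "drinks",
    "unhealthy",
)

#: Age (years) at or below which a respondent belongs to the young-adults stratum.
YOUNG_ADULT_MAX_AGE = 30.0

YOUNG_ADULTS = "young_adults"
ADULTS_ELDERLY = "adults_elderly"

_DEMOGRAPHIC_COLUMNS = (
    "respondent_id",
    "administration",
    "age_years",
    "sex",
    "height_cm",
    "weight_kg",
)


def age_stratum(age_years: float) -> str:
    """Return the age stratum label: young adults iff age <= 30 years."""
    return YOUNG_ADULTS if age_years <= YOUNG_ADULT_MAX_AGE else ADULTS_ELDERLY


@dataclass(frozen=True)
class ItemDef:
    """One weekly-frequency food item."""

    id: str
    label: str
    category: str
    has_portion_question: bool = True


@dataclass(frozen=True)
class BehaviorDef:
    """One categorical eating-behavior question with an enumerated answer domain."""

    id: str
    label: str
    answers: tuple[str, ...]


@dataclass(frozen=True)
class PortionLevel:
    label: str
    multiplier: float


@dataclass(frozen=True)
class QuestionnaireSchema:
    """Immutable description of the questionnaire.

    ``aggregation_map`` maps a score-row id to the food items whose weekly
    servings are pooled when that row is evaluated; every item appears in at
    most one row, and items outside the map are informative only.
    """

    name: str
    items: tuple[ItemDef, ...]
    behavior_questions: tuple[BehaviorDef, ...]
    aggregation_map: Mapping[str, tuple[str, ...]]
    portion_levels: tuple[PortionLevel, ...]

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item id(s): {', '.join(dupes)}")
        for it in self.items:
            if it.category not in ITEM_CATEGORIES:
                raise SchemaError(
                    f"item {it.id!r}: unknown category {it.category!r}"
                )
        for b in self.behavior_questions:
            if not b.answers:
                raise SchemaError(f"behavior {b.id!r}: empty answer domain")
        mults = [p.multiplier for p in self.portion_levels]
        if any(m <= 0 for m in mults):
            raise SchemaError("portion multipliers must be strictly positive")
        if mults != sorted(mults):
            raise SchemaError("portion multipliers must be ordered with their labels")
        seen: set[str] = set()
        item_ids = set(ids)
        for row, row_items in self.aggregation_map.items():
            for iid in row_items:
                if iid not in item_ids:
                    raise SchemaError(
                        f"aggregation row {row!r} references unknown item {iid!r}"
                    )
                if iid in seen:
                    raise SchemaError(
                        f"item {iid!r} mapped to more than one score row"
                    )
                seen.add(iid)

    # -- convenience lookups -------------------------------------------------

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    @property
    def n_frequency_items(self) -> int:
        return len(self.items)

    @property
    def portion_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.portion_levels)

    def portion_multiplier(self, label: str | None) -> float:
        """Serving multiplier for a portion label; a missing answer counts as 1.0."""
        if label is None:
            return 1.0
        for p in self.portion_levels:
            if p.label == label:
                return p.multiplier
        raise SchemaError(f"unknown portion label {label!r}")

    def behavior(self, behavior_id: str) -> BehaviorDef:
        for b in self.behavior_questions:
            if b.id == behavior_id:
                return b
        raise SchemaError(f"unknown behavior id {behavior_id!r}")

    def item(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.id == item_id:
                return it
        raise SchemaError(f"unknown item id {item_id!r}")

    def section_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in ITEM_CATEGORIES}
        for it in self.items:
            counts[it.category] += 1
        return counts


@dataclass
class ResponseProfile:
    """One respondent-administration of the questionnaire."""

    respondent_id: str
    age_years: float
    sex: str = "F"
    height_cm: float | None = None
    weight_kg: float | None = None
    frequencies: dict[str, float] = field(default_factory=dict)
    portions: dict[str, str] = field(default_factory=dict)
    behaviors: dict[str, str] = field(default_factory=dict)
    administration: str = "T0"

    @property
    def stratum(self) -> str:
        return age_stratum(self.age_years)

    def to_dict(self) -> dict:
        return {
            "respondent_id": self.respondent_id,
            "age_years": self.age_years,
            "sex": self.sex,
            "height_cm": self.height_cm,
            "weight_kg": self.weight_kg,
            "frequencies": dict(sorted(self.frequencies.items())),
            "portions": dict(sorted(self.portions.items())),
            "behaviors": dict(sorted(self.behaviors.items())),
            "administration": self.administration,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResponseProfile":
        return cls(
            respondent_id=str(d["respondent_id"]),
            age_years=float(d["age_years"]),
            sex=str(d.get("sex", "F")),
            height_cm=None if d.get("height_cm") is None else float(d["height_cm"]),
            weight_kg=None if d.get("weight_kg") is None else float(d["weight_kg"]),
            frequencies={k: float(v) for k, v in dict(d.get("frequencies", {})).items()},
            portions={k: str(v) for k, v in dict(d.get("portions", {})).items()},
            behaviors={k: str(v) for k, v in dict(d.get("behaviors", {})).items()},
            administration=str(d.get("administration", "T0")),
        )


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    n_valid: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def merge(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)
        self.n_valid += other.n_valid


# ---------------------------------------------------------------------------
# schema loading
# ---------------------------------------------------------------------------

def _schema_from_dict(raw: Mapping, name_hint: str = "schema") -> QuestionnaireSchema:
    try:
        items = tuple(
            ItemDef(
                id=str(d["id"]),
                label=str(d.get("label", d["id"])),
                category=str(d["category"]),
                has_portion_question=bool(d.get("has_portion_question", True)),
            )
            for d in raw["items"]
        )
        behaviors = tuple(
            BehaviorDef(
                id=str(d["id"]),
                label=str(d.get("label", d["id"])),
                answers=tuple(str(a) for a in d["answers"]),
            )
            for d in raw.get("behavior_questions", [])
        )
        levels = tuple(
            PortionLevel(label=str(d["label"]), multiplier=float(d["multiplier"]))
            for d in raw.get(
                "portion_levels",
                [
                    {"label": "small", "multiplier": 0.5},
                    {"label": "standard", "multiplier": 1.0},
                    {"label": "large", "multiplier": 1.5},
                ],
            )
        )
        agg = {
            str(k): tuple(str(i) for i in v)
            for k, v in raw.get("aggregation_map", {}).items()
        }
    except KeyError as exc:  # name the offending key
        raise SchemaError(f"{name_hint}: missing required key {exc.args[0]!r}") from exc
    return QuestionnaireSchema(
        name=str(raw.get("name", name_hint)),
        items=items,
        behavior_questions=behaviors,
        aggregation_map=agg,
        portion_levels=levels,
    )


def load_schema(path: str | Path = "builtin") -> QuestionnaireSchema:
    """Load a questionnaire schema from a JSON file, or the builtin default.

    The builtin schema carries the 39 weekly-frequency items (sections:
    vegetables and fruits, cereals, dairy, meat and fish, drinks, unhealthy
    foods), the thirteen behavior questions, the three portion levels and the
    default item-to-score-row aggregation map.
    """
    if path == "builtin":
        raw = json.loads(
            resources.files("dietscore.data").joinpath("schema.json").read_text()
        )
        return _schema_from_dict(raw, "builtin")
    p = Path(path)
    try:
        raw = json.loads(p.read_text())
    except OSError as exc:
        raise ReadError(f"cannot read schema file {p}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise SchemaError(f"schema file {p} is not valid JSON: {exc}") from exc
    return _schema_from_dict(raw, str(p))


# ---------------------------------------------------------------------------
# profile validation
# ---------------------------------------------------------------------------

def validate_profile(
    profile: ResponseProfile, schema: QuestionnaireSchema
) -> ValidationReport:
    """Check one profile against the schema; breaches are data, not exceptions."""
    rep = ValidationReport()
    rid = profile.respondent_id
    item_ids = set(schema.item_ids)
    behavior_ids = {b.id for b in schema.behavior_questions}

    if profile.age_years < 0 or not math.isfinite(profile.age_years):
        rep.errors.append((rid, "age_years", f"invalid age {profile.age_years}"))
    for fld in ("height_cm", "weight_kg"):
        val = getattr(profile, fld)
        if val is not None and val <= 0:
            rep.errors.append((rid, fld, f"must be positive, got {val}"))
    if profile.administration not in ("T0", "T1"):
        rep.errors.append(
            (rid, "administration", f"must be T0 or T1, got {profile.administration!r}")
        )

    for item, freq in profile.frequencies.items():
        if item not in item_ids:
            rep.errors.append((rid, f"freq.{item}", "unknown item"))
        elif freq < 0 or not math.isfinite(freq):
            rep.errors.append(
                (rid, f"freq.{item}", f"weekly frequency must be >= 0, got {freq}")
            )
    for item, label in profile.portions.items():
        if item not in item_ids:
            rep.errors.append((rid, f"portion.{item}", "unknown item"))
        elif label not in schema.portion_labels:
            rep.errors.append(
                (rid, f"portion.{item}", f"unknown portion label {label!r}")
            )
        elif item in item_ids and not schema.item(item).has_portion_question:
            rep.warnings.append(
                (rid, f"portion.{item}", "item has no portion question; answer ignored")
            )
    for bid, answer in profile.behaviors.items():
        if bid not in behavior_ids:
            rep.errors.append((rid, f"behavior.{bid}", "unknown behavior"))
        elif answer not in schema.behavior(bid).answers:
            rep.errors.append(
                (rid, f"behavior.{bid}", f"answer {answer!r} outside domain")
            )
    for item in item_ids - set(profile.frequencies):
        rep.warnings.append((rid, f"freq.{item}", "missing frequency answer"))

    rep.n_valid = 1 if rep.ok else 0
    return rep


def validate_profiles(
    profiles: Iterable[ResponseProfile], schema: QuestionnaireSchema
) -> ValidationReport:
    total = ValidationReport()
    for p in profiles:
        total.merge(validate_profile(p, schema))
    return total


# ---------------------------------------------------------------------------
# response file I/O
# ---------------------------------------------------------------------------

def _profile_to_row(profile: ResponseProfile) -> dict:
    row: dict = {
        "respondent_id": profile.respondent_id,
        "administration": profile.administration,
        "age_years": profile.age_years,
        "sex": profile.sex,
        "height_cm": profile.height_cm,
        "weight_kg": profile.weight_kg,
    }
    for item, freq in profile.frequencies.items():
        row[f"freq.{item}"] = freq
    for item, label in profile.portions.items():
        row[f"portion.{item}"] = label
    for bid, answer in profile.behaviors.items():
        row[f"behavior.{bid}"] = answer
    return row


def _row_to_profile(row: Mapping, schema: QuestionnaireSchema) -> ResponseProfile:
    def _present(v) -> bool:
        return v is not None and v == v and v != ""

    frequencies, portions, behaviors = {}, {}, {}
    unknown: list[str] = []
    for col, val in row.items():
        if col in _DEMOGRAPHIC_COLUMNS:
            continue
        if col.startswith("freq."):
            item = col[5:]
            if item not in schema.item_ids:
                unknown.append(item)
            elif _present(val):
                frequencies[item] = float(val)
        elif col.startswith("portion."):
            item = col[8:]
            if item not in schema.item_ids:
                unknown.append(item)
            elif _present(val):
                portions[item] = str(val)
        elif col.startswith("behavior."):
            bid = col[9:]
            if bid not in {b.id for b in schema.behavior_questions}:
                unknown.append(bid)
            elif _present(val):
                behaviors[bid] = str(val)
        else:
            unknown.append(col)
    if unknown:
        raise ReadError(
            "unmatched column name(s): " + ", ".join(sorted(set(unknown)))
        )
    return ResponseProfile(
        respondent_id=str(row["respondent_id"]),
        age_years=float(row["age_years"]),
        sex=str(row.get("sex", "F")) if _present(row.get("sex")) else "F",
        height_cm=float(row["height_cm"]) if _present(row.get("height_cm")) else None,
        weight_kg=float(row["weight_kg"]) if _present(row.get("weight_kg")) else None,
        frequencies=frequencies,
        portions=portions,
        behaviors=behaviors,
        administration=str(row.get("administration", "T0"))
        if _present(row.get("administration"))
        else "T0",
    )


def read_responses(
    path: str | Path, schema: QuestionnaireSchema
) -> list[ResponseProfile]:
    """Read respondent profiles from a CSV (one row per administration) or a
    JSON array of profile objects.  Missing optional cells are recorded as
    absent, never imputed."""
    p = Path(path)
    if not p.exists():
        raise ReadError(f"response file not found: {p}")
    if p.suffix.lower() == ".json":
        try:
            raw = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise ReadError(f"{p} is not valid JSON: {exc}") from exc
        if not isinstance(raw, list):
            raise ReadError(f"{p}: expected a JSON array of profiles")
        return [ResponseProfile.from_dict(d) for d in raw]
    try:
        df = pd.read_csv(p, dtype={"respondent_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ReadError(f"cannot read CSV {p}: {exc}") from exc
    if "respondent_id" not in df.columns or "age_years" not in df.columns:
        raise ReadError(f"{p}: header must include respondent_id and age_years")
    return [_row_to_profile(rec, schema) for rec in df.to_dict(orient="records")]


def write_responses(
    profiles: Sequence[ResponseProfile],
    path: str | Path,
    schema: QuestionnaireSchema | None = None,
) -> None:
    """Write profiles to CSV or JSON (by suffix) with canonical column order.

    Canonical ordering (demographics, then frequency, portion and behavior
    columns in schema order; rows sorted by respondent_id and administration)
    makes write->read->write byte-stable.
    """
    p = Path(path)
    ordered = sorted(profiles, key=lambda pr: (pr.respondent_id, pr.administration))
    if p.suffix.lower() == ".json":
        p.write_text(
            json.dumps([pr.to_dict() for pr in ordered], indent=1, sort_keys=False)
            + "\n"
        )
        return
    rows = [_profile_to_row(pr) for pr in ordered]
    df = pd.DataFrame(rows)
    if schema is not None:
        cols = list(_DEMOGRAPHIC_COLUMNS)
        cols += [f"freq.{i}" for i in schema.item_ids]
        cols += [f"portion.{i}" for i in schema.item_ids if schema.item(i).has_portion_question]
        cols += [f"behavior.{b.id}" for b in schema.behavior_questions]
        df = df.reindex(columns=[c for c in cols if c in df.columns or c in _DEMOGRAPHIC_COLUMNS])
    df.to_csv(p, index=False)
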