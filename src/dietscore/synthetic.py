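"""Synthetic FFQ respondents spanning the Western-to-Mediterranean axis.

The generator emulates the validation-study design with no real data: a
cohort of respondents drawn from diet archetypes (``md``, ``wd``, or a
``mixed`` interpolation) completes the questionnaire twice, two weeks apart.
Weekly frequencies are negative-binomial counts on a half-serving lattice
(FFQ count data are over-dispersed: variance grows roughly quadratically in
the mean); portions and behaviors are categorical draws.  The second
administration is derived from the first by multiplicative lognormal jitter
on frequencies, adjacent-category portion switches and behavior flips, so
item-level test-retest reliability is controlled analytically.

For a latent intake X with mean mu and variance sigma^2 and a mean-one
lognormal multiplier with log-sd tau, corr(X, X*M) is exactly
``1 / sqrt(1 + v * (1 + mu^2/sigma^2))`` with ``v = exp(tau^2) - 1``, which
:func:`expected_retest_correlation` and :func:`tau_for_target_correlation`
expose for calibration and testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import DomainError
from .ffq import QuestionnaireSchema, ResponseProfile, load_schema
from .reliability import TestRetestPair

_HALF = 0.5


def _round_half(x: float) -> float:
    return round(x * 2.0) / 2.0


def _load_defaults() -> dict:
    return json.loads(
        resources.files("dietscore.data").joinpath("archetypes.json").read_text()
    )


@dataclass(frozen=True)
class ArchetypeParams:
    """Generator parameters for one diet archetype."""

    name: str
    item_means: Mapping[str, float]
    dispersion: float
    portion_probs: Mapping[str, float]
    behavior_favorable: Mapping[str, str]
    behavior_favorable_p: float

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise DomainError("dispersion must be >= 0")
        if any(m < 0 for m in self.item_means.values()):
            raise DomainError("item means must be >= 0")
        total = sum(self.portion_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise DomainError("portion probabilities must sum to 1")
        if not 0.0 <= self.behavior_favorable_p <= 1.0:
            raise DomainError("behavior probability must lie in [0, 1]")


def load_archetype(name: str, mixed_lambda: float = 0.5) -> ArchetypeParams:
    """Builtin archetypes: ``md``, ``wd`` or ``mixed`` (lambda in [0, 1]
    interpolates item means and behavior probabilities linearly, with
    lambda = 1 the Mediterranean pole)."""
    raw = _load_defaults()
    if name in ("md", "wd"):
        return ArchetypeParams(
            name=name,
            item_means={k: v[name] for k, v in raw["item_means"].items()},
            dispersion=float(raw["dispersion"]),
            portion_probs=raw["portion_probs"][name],
            behavior_favorable=raw["behavior_favorable"],
            behavior_favorable_p=float(raw["behavior_favorable_p"][name]),
        )
    if name == "mixed":
        lam = float(mixed_lambda)
        if not 0.0 <= lam <= 1.0:
            raise DomainError("mixed lambda must lie in [0, 1]")
        md = load_archetype("md")
        wd = load_archetype("wd")
        return ArchetypeParams(
            name=f"mixed({lam:g})",
            item_means={
                k: lam * md.item_means[k] + (1 - lam) * wd.item_means[k]
                for k in md.item_means
            },
            dispersion=md.dispersion,
            portion_probs={
                k: lam * md.portion_probs[k] + (1 - lam) * wd.portion_probs[k]
                for k in md.portion_probs
            },
            behavior_favorable=md.behavior_favorable,
            behavior_favorable_p=lam * md.behavior_favorable_p
            + (1 - lam) * wd.behavior_favorable_p,
        )
    raise DomainError(f"unknown archetype {name!r}")


@dataclass(frozen=True)
class RetestNoise:
    """Perturbation applied to derive the second administration."""

    tau: float = 0.8
    portion_switch_p: float = 0.25
    behavior_flip_p: float = 0.15

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise DomainError("tau must be >= 0")
        for p in (self.portion_switch_p, self.behavior_flip_p):
            if not 0.0 <= p <= 1.0:
                raise DomainError("switch/flip probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic test-retest cohort.

    Defaults mirror the validation study's composition: 213 respondents with
    age strata weighted 145:68 (young adults: normal age 22.9 +/- 2.3 years;
    adults-elderly: 56.3 +/- 17.4), 70% female, and the older stratum tilted
    toward the Mediterranean archetype (the nutrition-transition direction).
    """

    n: int = 213
    seed: int = 0
    mixture: Mapping[str, float] | None = None  # overrides per-stratum mixtures
    mixed_lambda: float = 0.5
    retest: RetestNoise = field(default_factory=RetestNoise)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DomainError("cohort size must be positive")
        if self.mixture is not None:
            total = sum(self.mixture.values())
            if total <= 0:
                raise DomainError("mixture weights must have a positive sum")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_frequency(rng: np.random.Generator, mean: float, dispersion: float) -> float:
    """Negative-binomial weekly count on a half-serving lattice with
    Var = mean + dispersion * mean^2; dispersion 0 is a point mass at the mean."""
    if dispersion == 0.0 or mean == 0.0:
        return _round_half(mean)
    shape = 1.0 / dispersion
    doubled = 2.0 * mean
    p = shape / (shape + doubled)
    return rng.negative_binomial(shape, p) / 2.0


def generate_profile(
    params: ArchetypeParams,
    rng: np.random.Generator,
    schema: QuestionnaireSchema | None = None,
    respondent_id: str = "synthetic",
    age_years: float = 25.0,
    sex: str = "F",
) -> ResponseProfile:
    """Draw one questionnaire administration from an archetype."""
    if schema is None:
        schema = load_schema()
    frequencies = {
        item: _draw_frequency(rng, float(params.item_means.get(item, 0.0)), params.dispersion)
        for item in schema.item_ids
    }
    labels = list(params.portion_probs.keys())
    probs = np.array([params.portion_probs[l] for l in labels], float)
    portions = {
        item: labels[rng.choice(len(labels), p=probs)]
        for item in schema.item_ids
        if schema.item(item).has_portion_question
    }
    behaviors = {}
    for b in schema.behavior_questions:
        fav = params.behavior_favorable.get(b.id, b.answers[0])
        others = [a for a in b.answers if a != fav]
        if rng.random() < params.behavior_favorable_p or not others:
            behaviors[b.id] = fav
        else:
            behaviors[b.id] = others[int(rng.integers(len(others)))]
    return ResponseProfile(
        respondent_id=respondent_id,
        age_years=age_years,
        sex=sex,
        frequencies=frequencies,
        portions=portions,
        behaviors=behaviors,
        administration="T0",
    )


def retest_replicate(
    profile: ResponseProfile,
    noise: RetestNoise,
    rng: np.random.Generator,
    schema: QuestionnaireSchema | None = None,
) -> ResponseProfile:
    """Second administration: multiplicative lognormal frequency jitter
    (mean-one, log-sd tau, on the half-serving lattice), adjacent-category
    portion switches, and behavior flips; the respondent id is preserved."""
    if schema is None:
        schema = load_schema()
    tau = noise.tau
    frequencies = {}
    for item, f in profile.frequencies.items():
        if tau == 0.0:
            frequencies[item] = f
        else:
            mult = math.exp(rng.normal(-0.5 * tau * tau, tau))
            frequencies[item] = max(0.0, _round_half(f * mult))
    levels = list(schema.portion_labels)
    portions = {}
    for item, label in profile.portions.items():
        if rng.random() < noise.portion_switch_p and len(levels) > 1:
            i = levels.index(label)
            if i == 0:
                i = 1
            elif i == len(levels) - 1:
                i -= 1
            else:
                i += 1 if rng.random() < 0.5 else -1
            portions[item] = levels[i]
        else:
            portions[item] = label
    behaviors = {}
    for bid, answer in profile.behaviors.items():
        domain = schema.behavior(bid).answers
        others = [a for a in domain if a != answer]
        if others and rng.random() < noise.behavior_flip_p:
            behaviors[bid] = others[int(rng.integers(len(others)))]
        else:
            behaviors[bid] = answer
    return replace(
        profile,
        frequencies=frequencies,
        portions=portions,
        behaviors=behaviors,
        administration="T1",
    )


def _draw_age(rng: np.random.Generator, strata: Mapping) -> tuple[str, float]:
    names = list(strata.keys())
    weights = np.array([strata[s]["weight"] for s in names], float)
    weights = weights / weights.sum()
    name = names[rng.choice(len(names), p=weights)]
    s = strata[name]
    age = float(np.clip(rng.normal(s["mean"], s["sd"]), s["min"], s["max"]))
    return name, age


def generate_cohort(
    spec: CohortSpec, schema: QuestionnaireSchema | None = None
) -> list[TestRetestPair]:
    """Generate ``spec.n`` paired test-retest administrations."""
    if schema is None:
        schema = load_schema()
    raw = _load_defaults()
    rng = np.random.default_rng(spec.seed)
    archetypes = {
        "md": load_archetype("md"),
        "wd": load_archetype("wd"),
        "mixed": load_archetype("mixed", spec.mixed_lambda),
    }
    sex_labels = list(raw["sex_probs"].keys())
    sex_p = np.array([raw["sex_probs"][s] for s in sex_labels], float)

    pairs: list[TestRetestPair] = []
    for i in range(spec.n):
        stratum, age = _draw_age(rng, raw["age_strata"])
        if spec.mixture is not None:
            mix = spec.mixture
        else:
            mix = raw["stratum_mixtures"][stratum]
        names = list(mix.keys())
        p = np.array([mix[k] for k in names], float)
        p = p / p.sum()
        arch = archetypes[names[rng.choice(len(names), p=p)]]
        sex = sex_labels[rng.choice(len(sex_labels), p=sex_p)]
        rid = f"S{i + 1:04d}"
        t0 = generate_profile(arch, rng, schema, respondent_id=rid, age_years=age, sex=sex)
        t1 = retest_replicate(t0, spec.retest, rng, schema)
        pairs.append(TestRetestPair(rid, t0, t1))
    return pairs


# ---------------------------------------------------------------------------
# analytic retest attenuation
# ---------------------------------------------------------------------------

def expected_retest_correlation(mu: float, sigma: float, tau: float) -> float:
    """Exact corr(X, X*M) for any X >= 0 with mean mu and sd sigma > 0 and an
    independent mean-one lognormal multiplier with log-sd tau."""
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    v = math.expm1(tau * tau)
    return 1.0 / math.sqrt(1.0 + v * (1.0 + (mu / sigma) ** 2))


def tau_for_target_correlation(mu: float, sigma: float, rho: float) -> float:
    """Log-sd tau for which the multiplicative retest jitter attenuates the
    item-level test-retest correlation to ``rho``."""
    if not 0.0 < rho <= 1.0:
        raise DomainError("target correlation must lie in (0, 1]")
    if sigma <= 0:
        raise DomainError("sigma must be > 0")
    v = (1.0 / (rho * rho) - 1.0) / (1.0 + (mu / sigma) ** 2)
    return math.sqrt(math.log1p(v))
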