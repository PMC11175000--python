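"""Test-retest reliability statistics and interpretation bands.

Implements the agreement toolkit used to assess a questionnaire administered
twice, two weeks apart: Pearson and Spearman correlations with Fisher-z 95%
confidence intervals, the two-way random-effects absolute-agreement
single-measure intraclass correlation ICC(2,1), and Cohen's kappa (simple,
linear- and quadratic-weighted) with seeded bootstrap confidence intervals.
Each estimate can be labelled with a conventional interpretation band
(reliability scale, Landis-Koch kappa scale, or the 0.5-0.7 acceptability
range proposed for FFQ reproducibility trials).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError
from .ffq import QuestionnaireSchema, ResponseProfile, age_stratum


@dataclass(frozen=True)
class ReliabilityEstimate:
    statistic: str  # pearson_r | spearman_r | icc | kappa_simple | kappa_weighted
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    band: str | None = None


@dataclass(frozen=True)
class BandScale:
    """Ordered interpretation bands over [-1, 1]: intervals are closed on the
    left and open on the right, with the top band closed."""

    name: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise DomainError(f"band scale {self.name!r}: cuts must strictly increase")
        if len(self.labels) != len(self.cuts) + 1:
            raise DomainError(
                f"band scale {self.name!r}: need {len(self.cuts) + 1} labels"
            )


CORRELATION_SCALE = BandScale(
    name="correlation-scale",
    cuts=(0.4, 0.6, 0.8),
    labels=("poor", "moderate", "substantial", "optimal"),
)

LANDIS_KOCH = BandScale(
    name="landis-koch",
    cuts=(0.4, 0.6, 0.8),
    labels=("suboptimal", "moderate", "substantial", "almost perfect"),
)

CADE_RANGE = BandScale(
    name="cade-range",
    cuts=(0.5, 0.7),
    labels=("below acceptable", "acceptable", "above acceptable"),
)

BAND_SCALES = {s.name: s for s in (CORRELATION_SCALE, LANDIS_KOCH, CADE_RANGE)}


def classify_band(value: float, scale: BandScale) -> str:
    """Label a statistic in [-1, 1] on an interpretation scale."""
    if not -1.0 <= value <= 1.0:
        raise DomainError(f"band value {value} outside [-1, 1]")
    for cut, label in zip(scale.cuts, scale.labels):
        if value < cut:
            return label
    return scale.labels[-1]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _check_vectors(x: np.ndarray, y: np.ndarray, min_n: int = 4) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-d vectors")
    if len(x) < min_n:
        raise DomainError(f"need at least {min_n} observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("correlation undefined on a constant vector")


def _fisher_ci(r: float, n: int, alpha: float) -> tuple[float, float]:
    if abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return (math.tanh(z - zc * se), math.tanh(z + zc * se))


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> ReliabilityEstimate:
    """Product-moment correlation with a Fisher-z confidence interval."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    _check_vectors(xa, ya)
    r = float(stats.pearsonr(xa, ya).statistic)
    lo, hi = _fisher_ci(r, len(xa), alpha)
    return ReliabilityEstimate("pearson_r", r, lo, hi, len(xa))


def spearman(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> ReliabilityEstimate:
    """Rank correlation (Pearson on mid-ranks) with a Fisher-z interval."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    _check_vectors(xa, ya)
    r = float(stats.spearmanr(xa, ya).statistic)
    lo, hi = _fisher_ci(r, len(xa), alpha)
    return ReliabilityEstimate("spearman_r", r, lo, hi, len(xa))


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc(pairs: Sequence[Sequence[float]] | np.ndarray, alpha: float = 0.05) -> ReliabilityEstimate:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``pairs`` is an (n_subjects x 2) matrix of first/second administration
    values; the estimate and its F-based confidence interval come from the
    standard repeated-measures ANOVA decomposition.
    """
    import pingouin as pg

    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("expected an (n x 2) matrix of paired administrations")
    n = arr.shape[0]
    if n < 5:
        raise DomainError(f"need at least 5 subjects, got {n}")
    if np.ptp(arr) == 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "administration": np.tile(["T0", "T1"], n),
            "value": arr.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="administration", ratings="value"
        )
    # two-way random, absolute agreement, single measure (labelling varies
    # across pingouin versions: "ICC2" vs "ICC(A,1)")
    row = res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    est = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if not math.isfinite(est):
        raise DegenerateDataError("ICC undefined on this data")
    return ReliabilityEstimate("icc", est, lo, hi, n)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

def _weight_matrix(k: int, weights: str | None) -> np.ndarray:
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    if weights is None or weights == "none":
        return (dist > 0).astype(float)
    if k == 1:
        return np.zeros((1, 1))
    if weights == "linear":
        return dist / (k - 1)
    if weights == "quadratic":
        return (dist / (k - 1)) ** 2
    raise DomainError(f"unknown kappa weighting {weights!r}")


def _kappa_from_codes(a: np.ndarray, b: np.ndarray, w: np.ndarray, k: int) -> float:
    obs = np.bincount(a * k + b, minlength=k * k).reshape(k, k) / len(a)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    den = float((w * exp).sum())
    if den == 0.0:
        raise DegenerateDataError("kappa undefined: no expected disagreement")
    return 1.0 - float((w * obs).sum()) / den


def cohen_kappa(
    a: Sequence,
    b: Sequence,
    weights: str | None = None,
    categories: Sequence | None = None,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> ReliabilityEstimate:
    """Chance-corrected agreement between two ratings of the same subjects.

    ``weights=None`` gives simple kappa; "linear" and "quadratic" penalize
    disagreements by (squared) inter-category distance on the shared ordered
    ``categories`` domain (inferred from the data when omitted).  The
    confidence interval is a seeded nonparametric percentile bootstrap, which
    remains usable when some categories are sparse; ``n_boot=0`` skips it.
    """
    av, bv = list(a), list(b)
    if len(av) != len(bv) or not av:
        raise DomainError("ratings must be two equal-length non-empty vectors")
    if categories is None:
        categories = sorted(set(av) | set(bv))
    cat_index = {c: i for i, c in enumerate(categories)}
    try:
        ac = np.array([cat_index[v] for v in av])
        bc = np.array([cat_index[v] for v in bv])
    except KeyError as exc:
        raise DomainError(f"rating {exc.args[0]!r} outside the category domain") from exc
    k = len(categories)
    w = _weight_matrix(k, weights)
    est = _kappa_from_codes(ac, bc, w, k)

    name = "kappa_simple" if weights in (None, "none") else "kappa_weighted"
    if n_boot <= 0:
        return ReliabilityEstimate(name, est, float("nan"), float("nan"), len(av))
    rng = np.random.default_rng(seed)
    n = len(av)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boots[i] = _kappa_from_codes(ac[idx], bc[idx], w, k)
        except DegenerateDataError:
            boots[i] = 1.0  # resample with perfect expected agreement
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return ReliabilityEstimate(name, est, float(lo), float(hi), n)


# ---------------------------------------------------------------------------
# test-retest report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestRetestPair:
    __test__ = False  # not a test class, despite the name

    respondent_id: str
    t0: ResponseProfile
    t1: ResponseProfile

    def __post_init__(self) -> None:
        if self.t0.respondent_id != self.t1.respondent_id:
            raise DomainError("paired administrations must share a respondent id")


@dataclass
class ReliabilityTables:
    """Per-item frequency reliability (Pearson/Spearman + ICC) and portion
    reliability (weighted kappa), each row labelled with a band."""

    frequency: pd.DataFrame
    portion: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def pair_profiles(
    t0: Iterable[ResponseProfile], t1: Iterable[ResponseProfile]
) -> list[TestRetestPair]:
    """Match administrations by respondent id; respondents missing either
    administration are excluded."""
    t0_map = {p.respondent_id: p for p in t0}
    t1_map = {p.respondent_id: p for p in t1}
    return [
        TestRetestPair(rid, t0_map[rid], t1_map[rid])
        for rid in sorted(t0_map.keys() & t1_map.keys())
    ]


def reliability_report(
    pairs: Sequence[TestRetestPair],
    schema: QuestionnaireSchema,
    stratify_by_age: bool = True,
    min_n: int = 5,
    kappa_weights: str | None = "linear",
    n_boot: int = 2000,
    seed: int = 0,
) -> ReliabilityTables:
    """Item-wise test-retest report for a paired cohort.

    For every item, the frequency table carries T0/T1 summary statistics,
    Pearson r with its Fisher-z 95% CI, Spearman r, ICC(2,1) and the
    acceptability band of the Pearson coefficient; the portion table carries
    Cohen's kappa (weighted by default, since the portion scale is ordered)
    with a bootstrap CI and its Landis-Koch band.
    """
    warnings: list[str] = []
    if stratify_by_age:
        strata: dict[str, list[TestRetestPair]] = {}
        for p in pairs:
            strata.setdefault(age_stratum(p.t0.age_years), []).append(p)
    else:
        strata = {"all": list(pairs)}

    freq_rows, portion_rows = [], []
    for stratum, members in sorted(strata.items()):
        if len(members) < min_n:
            warnings.append(
                f"stratum {stratum!r} skipped: only {len(members)} complete pairs"
            )
            continue
        for item in schema.item_ids:
            x, y = [], []
            for p in members:
                if item in p.t0.frequencies and item in p.t1.frequencies:
                    x.append(p.t0.frequencies[item])
                    y.append(p.t1.frequencies[item])
            row = {
                "stratum": stratum,
                "item": item,
                "n": len(x),
                "t0_mean": np.mean(x) if x else np.nan,
                "t0_sd": np.std(x, ddof=1) if len(x) > 1 else np.nan,
                "t1_mean": np.mean(y) if y else np.nan,
                "t1_sd": np.std(y, ddof=1) if len(y) > 1 else np.nan,
            }
            try:
                if len(x) < min_n:
                    raise DegenerateDataError(f"fewer than {min_n} complete answers")
                pe = pearson_with_ci(x, y)
                sp = spearman(x, y)
                ic = icc(np.column_stack([x, y]))
                row.update(
                    pearson_r=pe.estimate,
                    pearson_ci_low=pe.ci_low,
                    pearson_ci_high=pe.ci_high,
                    spearman_r=sp.estimate,
                    icc=ic.estimate,
                    band=classify_band(
                        float(np.clip(pe.estimate, -1, 1)), CADE_RANGE
                    ),
                )
            except (DegenerateDataError, DomainError) as exc:
                warnings.append(f"{stratum}/{item}: frequency reliability skipped ({exc})")
                row.update(
                    pearson_r=np.nan, pearson_ci_low=np.nan, pearson_ci_high=np.nan,
                    spearman_r=np.nan, icc=np.nan, band="undefined",
                )
            freq_rows.append(row)

            if not schema.item(item).has_portion_question:
                continue
            pa, pb = [], []
            for p in members:
                if item in p.t0.portions and item in p.t1.portions:
                    pa.append(p.t0.portions[item])
                    pb.append(p.t1.portions[item])
            prow = {"stratum": stratum, "item": item, "n": len(pa)}
            try:
                if len(pa) < min_n:
                    raise DegenerateDataError(f"fewer than {min_n} complete answers")
                ka = cohen_kappa(
                    pa, pb, weights=kappa_weights,
                    categories=schema.portion_labels, n_boot=n_boot, seed=seed,
                )
                prow.update(
                    kappa=ka.estimate,
                    kappa_ci_low=ka.ci_low,
                    kappa_ci_high=ka.ci_high,
                    weighting=ka.statistic,
                    band=classify_band(float(np.clip(ka.estimate, -1, 1)), LANDIS_KOCH),
                )
            except (DegenerateDataError, DomainError) as exc:
                warnings.append(f"{stratum}/{item}: portion kappa skipped ({exc})")
                prow.update(
                    kappa=np.nan, kappa_ci_low=np.nan, kappa_ci_high=np.nan,
                    weighting="none", band="undefined",
                )
            portion_rows.append(prow)

    return ReliabilityTables(
        frequency=pd.DataFrame(freq_rows),
        portion=pd.DataFrame(portion_rows),
        warnings=warnings,
    )
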