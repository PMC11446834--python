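"""Between-day (test–retest) agreement statistics.

Binary flow-limitation calls are compared across two visits with Cohen's
κ, classified on the McHugh bands; continuous quantities (EFL magnitude,
ventilatory parameters) with the intraclass correlation coefficient,
classified on the Koo & Li bands, and with the within-subject
between-day coefficient of variation.  Group shifts between visits are
screened with Student's paired t-test (continuous) and Fisher's exact
test (counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementTable2x2",
    "KappaResult",
    "IccResult",
    "RepeatabilityReport",
    "cohens_kappa",
    "kappa_class",
    "icc",
    "icc_class",
    "between_day_cv",
    "paired_t",
    "fisher_exact",
]


@dataclass
class AgreementTable2x2:
    """2×2 agreement counts for a binary trait across two visits.

    ``a``: positive on both visits; ``b``: visit-1 only; ``c``: visit-2
    only; ``d``: negative on both.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("agreement counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty agreement table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_pairs(cls, pairs: list[tuple[bool, bool]]) -> "AgreementTable2x2":
        a = sum(1 for x, y in pairs if x and y)
        b = sum(1 for x, y in pairs if x and not y)
        c = sum(1 for x, y in pairs if not x and y)
        d = sum(1 for x, y in pairs if not x and not y)
        return cls(a, b, c, d)


@dataclass
class KappaResult:
    kappa: float
    p: float
    undefined: bool = False


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    form: str = "ICC2"
    undefined: bool = False


def cohens_kappa(t: AgreementTable2x2) -> KappaResult:
    """Cohen's κ for a 2×2 table, with a large-sample test of κ = 0.

    κ = (po − pe)/(1 − pe) with po the observed and pe the chance
    agreement from the marginals.  The p-value is the two-sided normal
    test using the standard error under H₀: SE₀ = √(pe/(n(1 − pe))).
    A constant rater (pe = 1) leaves κ undefined: the result is flagged,
    not raised.
    """
    n = t.n
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe >= 1.0 - 1e-15:
        return KappaResult(kappa=math.nan, p=math.nan, undefined=True)
    kappa = (po - pe) / (1.0 - pe)
    se0 = math.sqrt(pe / (n * (1.0 - pe)))
    z = kappa / se0
    p = 2.0 * stats.norm.sf(abs(z))
    return KappaResult(kappa=kappa, p=float(p))


#: McHugh agreement bands (closed printed intervals; an exact shared
#: endpoint goes to the lower-named band).
_KAPPA_BANDS = [
    (0.20, "none"),
    (0.39, "minimal"),
    (0.59, "weak"),
    (0.79, "moderate"),
    (0.90, "strong"),
]


def kappa_class(kappa: float) -> str:
    """McHugh label for a κ value (κ < 0 → "none", κ > 0.90 → "almost perfect")."""
    if not math.isfinite(kappa):
        raise ValueError("kappa must be finite")
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect"


def icc(
    pairs: list[tuple[float, float]] | np.ndarray, form: str = "ICC2"
) -> IccResult:
    """Single-measure intraclass correlation for a two-visit design.

    ``form`` selects the ANOVA model: ``"ICC2"`` — two-way random
    effects, absolute agreement, ICC(2,1), the default for a
    repeatability design where visit is a random factor; ``"ICC3"`` —
    two-way mixed effects, consistency, ICC(3,1).  Point estimate, 95%
    CI and the F-test p-value come from pingouin's ANOVA-mean-squares
    implementation.  Zero total variance is returned flagged undefined.
    """
    import pingouin as pg

    if form not in ("ICC2", "ICC3"):
        raise ValueError(f"unsupported ICC form {form!r}")
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array-like")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 complete pairs for ICC")
    if np.ptp(arr) == 0:
        return IccResult(math.nan, (math.nan, math.nan), math.nan, form, True)
    n = arr.shape[0]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "visit": np.tile([1, 2], n),
            "score": arr.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="visit", ratings="score"
        )
    # pingouin labels the forms in McGraw-Wong notation:
    # ICC(A,1) = two-way random, absolute agreement = ICC(2,1)
    # ICC(C,1) = two-way mixed, consistency = ICC(3,1)
    label = {"ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)"}[form]
    res = res.set_index("Type")
    if label not in res.index:  # pragma: no cover - older label scheme
        label = form
    row = res.loc[label]
    val = float(row["ICC"])
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    ci = tuple(float(x) for x in row[ci_col])
    p = float(row["pval"])
    if not math.isfinite(val):
        return IccResult(math.nan, (math.nan, math.nan), math.nan, form, True)
    return IccResult(icc=val, ci95=ci, p=p, form=form)


#: Koo & Li bands; boundaries 0.50/0.75/0.90 go to the lower-named band.
_ICC_BANDS = [(0.50, "poor"), (0.75, "moderate"), (0.90, "good")]


def icc_class(value: float) -> str:
    """Koo & Li label for an ICC ("poor" < 0.50 ... "excellent" > 0.90)."""
    if not math.isfinite(value):
        raise ValueError("ICC must be finite")
    if value < 0.50:
        return "poor"
    for upper, label in _ICC_BANDS[1:]:
        if value <= upper + 1e-12:
            return label
    return "excellent"


def between_day_cv(pairs: list[tuple[float, float]] | np.ndarray) -> float:
    """Within-subject between-day coefficient of variation, %.

    Per pair, the within-subject SD is sᵢ = |x₁ − x₂|/√2; the CV is
    100·√(mean sᵢ²) / grand mean.  Requires a positive grand mean.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be a non-empty (n, 2) array-like")
    grand = float(np.mean(arr))
    if grand <= 0:
        raise ValueError("grand mean must be positive for a CV")
    s2 = (arr[:, 0] - arr[:, 1]) ** 2 / 2.0
    return 100.0 * math.sqrt(float(np.mean(s2))) / grand


def paired_t(pairs: list[tuple[float, float]] | np.ndarray) -> tuple[float, float]:
    """Student's paired t-test; returns (t, two-sided p).

    Zero variance of the differences is flagged as (0, 1) when the
    differences are all zero, else (±inf, 0).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return float(t), float(p)


def fisher_exact(
    pos1: int, neg1: int, pos2: int, neg2: int
) -> float:
    """Two-sided Fisher's exact p for visit-1 vs visit-2 counts.

    The table compares e.g. (flow-limited, not flow-limited) counts on
    each visit; p is the exact two-sided hypergeometric probability.
    """
    if min(pos1, neg1, pos2, neg2) < 0:
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact([[pos1, neg1], [pos2, neg2]])
    return float(p)


@dataclass
class RepeatabilityReport:
    """κ/ICC/CV summary for one binary trait and its continuous magnitude."""

    n_pairs: int
    kappa: float
    kappa_p: float
    kappa_class: str | None
    icc: float
    icc_ci95: tuple[float, float]
    icc_p: float
    icc_class: str | None
    icc_form: str
    cv_pct: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "kappa": self.kappa,
            "kappa_p": self.kappa_p,
            "kappa_class": self.kappa_class,
            "icc": self.icc,
            "icc_ci95": list(self.icc_ci95),
            "icc_p": self.icc_p,
            "icc_class": self.icc_class,
            "icc_form": self.icc_form,
            "cv_pct": self.cv_pct,
            **self.extras,
        }
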