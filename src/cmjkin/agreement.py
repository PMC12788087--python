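"""Method-comparison statistics for reliability and validity studies.

Given an ``n_subjects × k_methods`` matrix of one jump variable, the
battery computes:

* **ICC(3,1)** — two-way mixed, single-measure, *consistency* intraclass
  correlation from the two-way ANOVA decomposition,
  ``ICC = (MS_S − MS_E) / (MS_S + (k−1)·MS_E)``, with the F-based 95 %
  confidence interval for this form (Shrout & Fleiss);
* **CV%** — mean over subjects of the within-subject SD as a percentage
  of the absolute within-subject mean (an alternative, SEM relative to
  the grand mean, is available behind a flag);
* **SEM** — absolute measurement error, ``SD_pooled·√(1 − ICC)``;
* **MD** — mean difference between two methods (second label minus
  first);
* **Pearson r** with two-sided p and a Hinkle magnitude grade
  (negligible / low / moderate / high / very high at |r| cut-points
  0.30 / 0.50 / 0.70 / 0.90, boundaries to the upper band);
* **Bland–Altman** bias and 95 % limits of agreement, bias ± 1.96·SD of
  the paired differences, plus the inverse map from printed limits back
  to (bias, SD);
* the **correlation sample size** for testing H0: ρ = 0 via the Fisher-z
  approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_LOA = 1.96  # 95% limits of agreement


class DegenerateTableError(ValueError):
    """Agreement statistic undefined for this table (e.g. no subject variance)."""


@dataclass
class MeasurementTable:
    """``n_subjects × k_methods`` matrix of one variable."""

    values: np.ndarray
    subjects: Optional[Sequence[str]] = None
    methods: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects × methods)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 methods")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed")
        if self.subjects is None:
            self.subjects = [f"S{i + 1}" for i in range(n)]
        if self.methods is None:
            self.methods = [f"M{j + 1}" for j in range(k)]
        if len(self.subjects) != n or len(self.methods) != k:
            raise ValueError("label lengths do not match the matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class AgreementReport:
    icc: float
    ci_low: float
    ci_high: float
    cv_pct: float
    sem: float
    md: Optional[float] = None


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float = field(init=False)
    loa_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.loa_low = self.bias - Z_LOA * self.sd_diff
        self.loa_high = self.bias + Z_LOA * self.sd_diff


@dataclass
class CorrelationResult:
    r: float
    p: float
    magnitude: str


@dataclass
class PowerQuery:
    """Inputs of the correlation sample-size computation."""

    rho: float = 0.8
    alpha: float = 0.05
    power: float = 0.8
    tails: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# ICC(3,1)
# ---------------------------------------------------------------------------

def _anova_mean_squares(x: np.ndarray) -> tuple[float, float]:
    """MS_subjects and MS_error of the two-way (subjects × methods) ANOVA."""
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_meth = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_meth
    return ss_subj / (n - 1), ss_err / ((n - 1) * (k - 1))


def icc_3_1(table: MeasurementTable, ci: float = 0.95
            ) -> tuple[float, float, float]:
    """ICC(3,1) with its F-based confidence interval.

    Raises :class:`DegenerateTableError` when there is no between-subject
    variance (the coefficient is undefined).
    """
    x = table.values
    n, k = x.shape
    ms_s, ms_e = _anova_mean_squares(x)
    if ms_s <= 0 or (ms_s == 0 and ms_e == 0):
        raise DegenerateTableError("zero between-subject variance")
    if ms_e == 0:
        return 1.0, 1.0, 1.0
    icc = (ms_s - ms_e) / (ms_s + (k - 1) * ms_e)

    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_s / ms_e
    alpha = 1.0 - ci
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return float(icc), float(ci_low), float(ci_high)


# ---------------------------------------------------------------------------
# CV%, SEM, MD
# ---------------------------------------------------------------------------

def cv_percent(table: MeasurementTable, method: str = "within_subject"
               ) -> float:
    """Coefficient of variation in percent.

    ``within_subject`` (default): mean over subjects of
    100·SD_i/|mean_i| with the n−1 SD. ``sem_ratio``: 100·SEM/|grand
    mean| (flagged alternative). Raises for a subject mean of zero.
    """
    x = table.values
    if method == "within_subject":
        means = x.mean(axis=1)
        if np.any(means == 0):
            raise DegenerateTableError("a subject mean is zero: CV undefined")
        sds = x.std(axis=1, ddof=1)
        return float(np.mean(100.0 * sds / np.abs(means)))
    if method == "sem_ratio":
        grand = x.mean()
        if grand == 0:
            raise DegenerateTableError("grand mean is zero: CV undefined")
        icc, _, _ = icc_3_1(table)
        return float(100.0 * sem_abs(table, icc) / abs(grand))
    raise ValueError(f"unknown CV method {method!r}")


def sem_abs(table: MeasurementTable, icc: float) -> float:
    """Standard error of measurement, SD_pooled·√(1 − ICC)."""
    if icc > 1:
        raise ValueError("icc must be <= 1")
    sd = table.values.std(ddof=1)
    return float(sd * math.sqrt(max(1.0 - icc, 0.0)))


def mean_difference(table: MeasurementTable) -> float:
    """Mean difference for k = 2 tables, oriented second − first label."""
    if table.k != 2:
        raise ValueError("mean difference requires exactly two methods")
    return float((table.values[:, 1] - table.values[:, 0]).mean())


# ---------------------------------------------------------------------------
# Pearson with Hinkle grades
# ---------------------------------------------------------------------------

HINKLE_BANDS = ((0.90, "very high"), (0.70, "high"), (0.50, "moderate"),
                (0.30, "low"), (0.0, "negligible"))


def hinkle_magnitude(r: float) -> str:
    """Magnitude label for |r|; boundary values go to the upper band."""
    a = abs(r)
    for cut, label in HINKLE_BANDS:
        if a >= cut:
            return label
    return "negligible"


def pearson_graded(x: Sequence[float], y: Sequence[float]
                   ) -> CorrelationResult:
    """Pearson r, two-sided p (t transform) and Hinkle grade."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateTableError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             magnitude=hinkle_magnitude(res.statistic))


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------

def bland_altman(x: Sequence[float], y: Sequence[float]
                 ) -> BlandAltmanResult:
    """Bias and 95 % limits of agreement of paired differences x − y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples with n >= 2")
    d = x - y
    return BlandAltmanResult(bias=float(d.mean()),
                             sd_diff=float(d.std(ddof=1)))


def ba_from_summary(loa_low: float, loa_high: float
                    ) -> tuple[float, float]:
    """Invert printed limits of agreement back to (bias, sd_diff)."""
    if not loa_high > loa_low:
        raise ValueError("degenerate limits of agreement")
    bias = (loa_low + loa_high) / 2.0
    sd_diff = (loa_high - loa_low) / (2.0 * Z_LOA)
    return bias, sd_diff


# ---------------------------------------------------------------------------
# sample size for a correlation test
# ---------------------------------------------------------------------------

def sample_size_correlation(q: PowerQuery | None = None) -> int:
    """Smallest n detecting ρ ≠ 0 at the requested power (Fisher z).

    ``n = ceil(((z_{1−α[/2]} + z_{power}) / arctanh(ρ))² + 3)``.
    """
    q = q or PowerQuery()
    alpha = q.alpha / 2.0 if q.tails == "two" else q.alpha
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(q.power)
    n = ((z_a + z_b) / math.atanh(q.rho)) ** 2 + 3.0
    return int(math.ceil(n - 1e-12))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def agreement_report(table: MeasurementTable) -> AgreementReport:
    """Full ICC/CV/SEM(/MD) battery for one variable table."""
    icc, lo, hi = icc_3_1(table)
    return AgreementReport(
        icc=icc, ci_low=lo, ci_high=hi,
        cv_pct=cv_percent(table),
        sem=sem_abs(table, icc),
        md=mean_difference(table) if table.k == 2 else None)


def build_tables(variables: pd.DataFrame, label_a: str, label_b: str,
                 *, average_trials: bool = True, with_pearson: bool = False,
                 variable_names: Sequence[str] = ("dt_ecc", "dt_PP",
                                                  "dt_take_off", "h_Z_min",
                                                  "h_Z_max"),
                 ) -> pd.DataFrame:
    """Reliability/validity report rows (marker × variable).

    ``variables`` is the canonical long variables table with a
    ``label`` column (``mocap`` / ``video:A`` / ``video:B``). For each
    marker × variable the two methods' per-participant values (trials
    averaged by default, else pooled per trial) feed the ICC/CV/SEM/MD
    battery, optionally plus Pearson r with its Hinkle grade and
    Bland–Altman limits. MD and bias are oriented ``label_b − label_a``.
    """
    df = variables.copy()
    if "label" not in df.columns:
        df["label"] = np.where(df["source"].eq("mocap"), "mocap",
                               "video:" + df["rater"].astype(str))
    rows = []
    for marker, grp in df.groupby("marker", sort=True):
        for var in variable_names:
            keys = ["participant"] if average_trials else ["participant",
                                                           "trial"]
            wide = (grp.pivot_table(index=keys, columns="label", values=var,
                                    aggfunc="mean")
                    .dropna(subset=[label_a, label_b]))
            table = MeasurementTable(
                wide[[label_a, label_b]].to_numpy(),
                subjects=[str(i) for i in wide.index],
                methods=[label_a, label_b])
            rep = agreement_report(table)
            ba = bland_altman(table.values[:, 1], table.values[:, 0])
            row = {"marker": marker, "variable": var, "icc": rep.icc,
                   "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                   "cv_pct": rep.cv_pct, "sem": rep.sem, "md": rep.md,
                   "ba_bias": ba.bias, "ba_loa_low": ba.loa_low,
                   "ba_loa_high": ba.loa_high, "n": table.n}
            if with_pearson:
                cor = pearson_graded(table.values[:, 0], table.values[:, 1])
                row |= {"r": cor.r, "p": cor.p, "magnitude": cor.magnitude}
            rows.append(row)
    return pd.DataFrame(rows)
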