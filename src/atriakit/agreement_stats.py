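"""Method-agreement and diagnostic statistics.

The battery used to compare two cine techniques and two readers on the same
subjects: Mann-Whitney U, coefficient of determination R^2, intraclass
correlation (two-way, absolute agreement), Bland-Altman bias and limits of
agreement, Fleiss kappa for categorical ratings, empirical ROC/AUC with a
Youden-optimal operating point, the DeLong test for paired AUCs, and a
Kolmogorov-Smirnov normality gate for choosing between mean +- SD and
median/IQR reporting.

Difference orientation is fixed as (condition A - condition B), i.e.
conventional minus CS throughout the pipeline. All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats import inter_rater as smir

from .core import AtriakitError

__all__ = [
    "AgreementSummary",
    "RocSummary",
    "mann_whitney_u",
    "icc_absolute",
    "bland_altman",
    "r_squared",
    "fleiss_kappa",
    "kappa_band",
    "roc_auc",
    "delong_test",
    "ks_normality",
]


@dataclass
class AgreementSummary:
    """Bland-Altman bias and 95 % limits of agreement (units of the input)."""

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


@dataclass
class RocSummary:
    auc: float
    sensitivity: float  # percent, at the Youden-optimal cutoff
    specificity: float  # percent
    cutoff: float
    direction: int      # +1: higher values indicate the positive class


def _clean(x, name, min_n=1):
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise AtriakitError(f"{name}: need at least {min_n} values, got {x.size}")
    if np.any(~np.isfinite(x)):
        raise AtriakitError(f"{name}: non-finite values")
    return x


def mann_whitney_u(group_x, group_y) -> tuple[float, float]:
    """Mann-Whitney U (of ``group_x``) with a two-sided p-value.

    Exact p by enumeration for small, tie-free samples (nx + ny <= 12),
    otherwise the tie-corrected normal approximation with continuity
    correction. Degenerate data with zero rank variance gives p = 1.
    """
    x = _clean(group_x, "group_x")
    y = _clean(group_y, "group_y")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(res.pvalue)
    if not np.isfinite(p):  # all-tied ranks under the asymptotic path
        p = 1.0
    return float(res.statistic), min(p, 1.0)


def _two_way_anova(matrix: np.ndarray):
    """Mean squares of the two-way (subjects x raters) decomposition."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise AtriakitError("expected a subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise AtriakitError("need >= 2 subjects and >= 2 raters")
    if np.any(~np.isfinite(m)):
        raise AtriakitError("missing or non-finite cells (no imputation)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc_absolute(matrix, measure: str = "single") -> float:
    """Two-way, absolute-agreement intraclass correlation.

    ``measure="single"`` gives ICC(A,1) =
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)); ``"average"`` gives
    ICC(A,k). Absolute agreement penalises systematic rater bias, unlike the
    consistency form. A matrix of identical columns returns exactly 1.
    """
    n, k, msr, msc, mse = _two_way_anova(matrix)
    if measure == "single":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif measure == "average":
        denom = msr + (msc - mse) * k / n
    else:
        raise AtriakitError("measure must be 'single' or 'average'")
    if denom == 0:
        raise AtriakitError("degenerate matrix: zero total dispersion")
    return float((msr - mse) / denom)


def bland_altman(a, b) -> AgreementSummary:
    """Bland-Altman analysis of paired measurements, differences A - B.

    bias = mean difference; LoA = bias +- 1.96 * SD (sample SD, n-1); the
    limits are symmetric about the bias by construction.
    """
    a = _clean(a, "a", min_n=2)
    b = _clean(b, "b", min_n=2)
    if a.size != b.size:
        raise AtriakitError("paired measurements must have equal length")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    out = AgreementSummary(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=d.size,
    )
    assert np.isclose(out.loa_upper - out.bias, out.bias - out.loa_lower)
    return out


def r_squared(a, b) -> float:
    """Squared Pearson correlation of two paired series."""
    a = _clean(a, "a", min_n=3)
    b = _clean(b, "b", min_n=3)
    if a.size != b.size:
        raise AtriakitError("paired measurements must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AtriakitError("zero variance: R^2 undefined")
    r = sps.pearsonr(a, b).statistic
    return float(r * r)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a Fleiss kappa value."""
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost excellent"


def fleiss_kappa(ratings, n_categories: int | None = None) -> tuple[float, str]:
    """Fleiss kappa for an items x raters table of categorical ratings.

    Every item must be rated by the same number of raters. Returns the
    kappa and its qualitative band. If all raters always use one single
    category the chance agreement is 1 and kappa is undefined.
    """
    r = np.asarray(ratings)
    if r.ndim != 2 or r.shape[0] < 1 or r.shape[1] < 2:
        raise AtriakitError("expected an items x raters table with >= 2 raters")
    if np.any(~np.isfinite(np.asarray(r, dtype=float))):
        raise AtriakitError("unequal rater counts per item are not supported")
    counts, _ = smir.aggregate_raters(r)
    if n_categories is not None and counts.shape[1] < n_categories:
        counts = np.hstack(
            [counts, np.zeros((counts.shape[0], n_categories - counts.shape[1]), int)]
        )
    p_j = counts.sum(axis=0) / counts.sum()
    if np.sum(p_j**2) >= 1.0:
        raise AtriakitError("degenerate ratings: a single category is always used")
    kappa = float(smir.fleiss_kappa(counts, method="fleiss"))
    return kappa, kappa_band(kappa)


def _midrank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity with midrank tie handling."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(values, labels, expected_direction: int = +1) -> RocSummary:
    """Empirical ROC analysis of one continuous marker.

    ``labels`` are boolean (True = positive class, e.g. HFrEF);
    ``expected_direction`` is +1 when higher marker values indicate the
    positive class (atrial volumes) and -1 when lower values do (emptying
    fractions). The reported operating point maximises the Youden index
    J = sensitivity + specificity - 1, taking the lowest cutoff on ties.
    """
    v = _clean(values, "values")
    y = np.asarray(labels, dtype=bool).ravel()
    if y.size != v.size:
        raise AtriakitError("values and labels must have equal length")
    if y.all() or (~y).all():
        raise AtriakitError("both classes must be present")
    if expected_direction not in (+1, -1):
        raise AtriakitError("expected_direction must be +1 or -1")
    s = v * expected_direction
    auc = _midrank_auc(s[y], s[~y])
    # candidate cutoffs: halfway between consecutive distinct scores, plus
    # the extremes (classify-none / classify-all)
    u = np.unique(s)
    cand = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    sens = np.array([(s[y] > c).mean() for c in cand])
    spec = np.array([(s[~y] <= c).mean() for c in cand])
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[0]  # lowest cutoff on ties
    return RocSummary(
        auc=auc,
        sensitivity=100.0 * float(sens[best]),
        specificity=100.0 * float(spec[best]),
        cutoff=float(cand[best]) * expected_direction,
        direction=expected_direction,
    )


def _delong_components(values: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    x = values[labels]  # positives
    y = values[~labels]
    psi = (x[:, None] > y[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_test(values_a, values_b, labels):
    """DeLong comparison of two paired (same-subject) AUCs.

    Returns ``(z, p, auc_a, auc_b)``; the variance of the AUC difference is
    estimated from the empirical covariance of the structural components.
    Identical predictors (zero difference variance) give p = 1.
    """
    va = _clean(values_a, "values_a")
    vb = _clean(values_b, "values_b")
    y = np.asarray(labels, dtype=bool).ravel()
    if not (va.size == vb.size == y.size):
        raise AtriakitError("paired predictors and labels must align")
    if y.all() or (~y).all():
        raise AtriakitError("both classes must be present")
    v10_a, v01_a = _delong_components(va, y)
    v10_b, v01_b = _delong_components(vb, y)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0, auc_a, auc_b
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0)), auc_a, auc_b


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Used only to choose between mean +- SD and median/IQR reporting. Note
    the Lilliefors caveat: estimating the parameters from the sample makes
    the asymptotic p conservative-leaning, mirroring common SPSS usage.
    """
    v = _clean(values, "values", min_n=5)
    sd = v.std(ddof=1)
    if sd == 0:
        raise AtriakitError("degenerate (constant) sample")
    res = sps.kstest(v, "norm", args=(v.mean(), sd))
    return float(res.statistic), float(res.pvalue)
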