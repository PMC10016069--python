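"""Cohort-level statistics for FI metrics.

Covers the analysis battery run over a cohort of parcellated subjects:
threshold optimization by skewness minimization, test–retest
reliability (ICC and CoV from a one-way variance decomposition), twin
heritability via Falconer's formula H2b = 2 (r_MZ - r_DZ) on
double-entry sibling correlations, group comparisons, standardized
multiple regression with Tukey outlier exclusion and Benjamini–
Hochberg FDR correction, Bayesian information criterion deltas, and
population probability maps.

The ICC is computed as (sigma_between - sigma_within) / (sigma_between
+ sigma_within), where the sigmas are the between- and within-subject
mean squares of a one-way decomposition; with two sessions per subject
this coincides exactly with the classical one-way ICC(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mesh import vertex_adjacency
from .parcellation import (
    DIRECTION_FOR_PARAM,
    RestrictionMask,
    SmoothingConfig,
    laplacian_smooth,
    largest_component,
    mode_filter,
    threshold_mask,
)
from .types import VertexMorphometry, VertexScalarMap

DEFAULT_THRESHOLDS = np.round(np.arange(0, 41) * 0.025, 3)  # 0..1 step 0.025


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------


def skewness(x: np.ndarray) -> float:
    """Adjusted Fisher–Pearson sample skewness; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.std(x) < 1e-12:
        return np.nan
    return float(sps.skew(x, bias=False))


@dataclass
class SweepResult:
    thresholds: np.ndarray          # (T,)
    volumes: np.ndarray             # (n_subjects, T) mm^3
    skewness: np.ndarray            # (T,), NaN where undefined


def sweep_thresholds(
    maps: list[VertexScalarMap],
    triangles: np.ndarray,
    restriction: RestrictionMask | np.ndarray,
    morphometry: VertexMorphometry,
    parameter: str = "odi",
    direction: str | None = None,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    smoothing: SmoothingConfig | None = None,
    mode_iterations: int = 1,
) -> SweepResult:
    """Run the full parcellation chain per subject per candidate threshold
    and record the cohort FI-volume distribution and its skewness."""
    if len(maps) < 3:
        raise ValueError("threshold sweep requires at least 3 subjects")
    if direction is None:
        direction = DIRECTION_FOR_PARAM[parameter]
    n = maps[0].n_vertices
    adj = vertex_adjacency(triangles, n)
    if isinstance(restriction, RestrictionMask):
        restriction = restriction.as_bool(n)
    thresholds = np.asarray(thresholds, dtype=float)
    volumes = np.zeros((len(maps), thresholds.size))
    for i, vmap in enumerate(maps):
        smoothed = laplacian_smooth(vmap, adj, smoothing)
        for j, t in enumerate(thresholds):
            mask = threshold_mask(smoothed, t, direction, restriction)
            mask = mode_filter(mask, adj, iterations=mode_iterations)
            mask &= restriction
            mask = largest_component(mask, adj, vertex_area=morphometry.area)
            volumes[i, j] = morphometry.volume[mask].sum()
    skew = np.array([skewness(volumes[:, j]) for j in range(thresholds.size)])
    return SweepResult(thresholds=thresholds, volumes=volumes, skewness=skew)


def select_threshold(sweep: SweepResult) -> float:
    """Threshold minimizing |skewness|; ties resolve to the lower value."""
    defined = np.isfinite(sweep.skewness)
    if not defined.any():
        raise ValueError("skewness undefined at every threshold")
    a = np.where(defined, np.abs(sweep.skewness), np.inf)
    return float(sweep.thresholds[int(np.argmin(a))])


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityResult:
    icc: float
    cov: float
    mu: float
    sigma_within: float      # within-subject mean square
    sigma_between: float     # between-subject mean square
    defined: bool = True


def reliability(test: np.ndarray, retest: np.ndarray) -> ReliabilityResult:
    """Test–retest ICC and CoV from a one-way variance decomposition.

    ICC = (MS_between - MS_within) / (MS_between + MS_within), which
    for two sessions equals the one-way random-effects ICC(1);
    CoV = sqrt(MS_within) / mean.
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("reliability requires at least 3 subjects")
    gm = x.mean()
    m = x.mean(axis=1)
    msb = k * np.sum((m - gm) ** 2) / (n - 1)
    msw = np.sum((x - m[:, None]) ** 2) / (n * (k - 1))
    total = msb + msw
    if total < 1e-24:
        return ReliabilityResult(np.nan, np.nan, gm, msw, msb, defined=False)
    icc = (msb - msw) / total
    cov = np.sqrt(msw) / gm if gm != 0 else np.nan
    return ReliabilityResult(float(icc), float(cov), float(gm),
                             float(msw), float(msb))


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def pair_correlation(pairs: np.ndarray) -> float:
    """Double-entry intraclass correlation of sibling pairs.

    Each pair is entered in both orders, making the estimate invariant
    to within-pair ordering.  Returns NaN on zero variance.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (n_pairs, 2)")
    if pairs.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    a = np.concatenate([pairs[:, 0], pairs[:, 1]])
    b = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.std(a) < 1e-15 or np.std(b) < 1e-15:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def falconer(r_mz: float, r_dz: float) -> float:
    """Broad-sense heritability H2b = 2 (r_MZ - r_DZ)."""
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    return 2.0 * (r_mz - r_dz)


def sibling_pairs(
    cohort: pd.DataFrame, value_col: str = "value"
) -> dict[str, np.ndarray]:
    """Extract sibling pair values by zygosity group.

    Pairs are matched on both parent IDs; sibships with more than two
    members contribute every unordered pair.
    """
    out: dict[str, list] = {}
    for (_, _, group), rows in cohort.groupby(
        ["mother_id", "father_id", "group"], sort=True
    ):
        if group == "SINGLE":
            continue
        vals = rows[value_col].to_numpy()
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                out.setdefault(group, []).append((vals[i], vals[j]))
    return {g: np.asarray(v) for g, v in out.items()}


@dataclass
class HeritabilityResult:
    r_mz: float
    r_dz: float
    r_nt: float
    h2b: float


def heritability(cohort: pd.DataFrame, value_col: str = "value") -> HeritabilityResult:
    """Falconer heritability from a cohort table with family structure."""
    pairs = sibling_pairs(cohort, value_col)
    r_mz = pair_correlation(pairs["MZ"]) if "MZ" in pairs else np.nan
    r_dz = pair_correlation(pairs["DZ"]) if "DZ" in pairs else np.nan
    r_nt = pair_correlation(pairs["NT"]) if "NT" in pairs else np.nan
    h2b = falconer(r_mz, r_dz) if np.isfinite(r_mz) and np.isfinite(r_dz) else np.nan
    return HeritabilityResult(r_mz, r_dz, r_nt, h2b)


# ---------------------------------------------------------------------------
# group comparison / outlier exclusion
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    t: float
    p: float
    defined: bool = True


def compare_groups(
    a: np.ndarray, b: np.ndarray, paired: bool = False, welch: bool = True
) -> GroupComparison:
    """Student's t-test: paired for within-subject (left–right) contrasts,
    unpaired (Welch by default) for between-group (male–female) ones."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        d = a - b
        if np.std(d) < 1e-15:
            if np.allclose(d, 0):
                return GroupComparison(0.0, 1.0, defined=False)
            # constant nonzero difference: direction is certain, p underflows
            return GroupComparison(np.sign(d.mean()) * np.inf, 0.0, defined=False)
        t, p = sps.ttest_rel(a, b)
    else:
        if np.std(a) < 1e-15 and np.std(b) < 1e-15:
            return GroupComparison(np.nan, np.nan, defined=False)
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(float(t), float(p))


def tukey_filter(values: np.ndarray) -> np.ndarray:
    """Retention mask for Tukey's fences: [Q1 - 1.5 IQR, Q3 + 1.5 IQR],
    quartiles by linear interpolation.  NaNs are never retained."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise ValueError("Tukey fences require at least 4 values")
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    with np.errstate(invalid="ignore"):
        return np.isfinite(values) & (values >= lo) & (values <= hi)


# ---------------------------------------------------------------------------
# standardized regression with BIC
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    r2: float
    std_beta: float
    se: float
    t_value: float
    p_value: float
    delta_bic: float
    q_value: float = np.nan
    n_used: int = 0


def _bic(rss: float, n: int, k: int) -> float:
    return n * np.log(rss / n) + k * np.log(n)


def regress_behavior(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
    tukey: bool = True,
) -> RegressionResult:
    """OLS of a standardized outcome on a standardized predictor plus
    covariates.

    Continuous variables are z-scored (so the predictor coefficient is
    a standardized beta); two-level categorical covariates are coded
    0/1.  Tukey fences — computed on the full cohort per variable —
    exclude outlier rows before fitting.  Reports R², standardized
    beta, SE, t, p for the predictor, and ΔBIC = BIC(model without
    predictor) − BIC(model with predictor) with
    BIC = n ln(RSS/n) + k ln(n); positive ΔBIC favours keeping the
    predictor.
    """
    cols = [outcome, predictor, *covariates]
    df = table[cols].copy()

    numeric = [c for c in cols if pd.api.types.is_numeric_dtype(df[c])]
    keep = np.ones(len(df), dtype=bool)
    if tukey:
        for c in numeric:
            keep &= tukey_filter(df[c].to_numpy())
    df = df[keep].dropna()
    n = len(df)
    if n < len(cols) + 2:
        raise ValueError("too few complete cases after outlier exclusion")

    def encode(c: str) -> np.ndarray:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd < 1e-15:
                raise ValueError(f"column {c!r} is constant")
            return (v - v.mean()) / sd
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise ValueError(f"categorical column {c!r} must have 2 levels")
        return (col == levels[1]).to_numpy(dtype=float)

    y = encode(outcome)
    x_pred = encode(predictor)
    x_cov = [encode(c) for c in covariates]
    X_full = np.column_stack([np.ones(n), x_pred, *x_cov])
    cond = np.linalg.cond(X_full)
    if cond > 1e10:
        raise ValueError(f"collinear design (condition number {cond:.2e})")

    import statsmodels.api as sm

    fit = sm.OLS(y, X_full).fit()
    rss_full = float(np.sum(fit.resid**2))
    X_red = np.column_stack([np.ones(n), *x_cov]) if x_cov else np.ones((n, 1))
    fit_red = sm.OLS(y, X_red).fit()
    rss_red = float(np.sum(fit_red.resid**2))
    delta_bic = _bic(rss_red, n, X_red.shape[1]) - _bic(rss_full, n, X_full.shape[1])
    return RegressionResult(
        r2=float(fit.rsquared),
        std_beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_value=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        delta_bic=float(delta_bic),
        n_used=n,
    )


def fdr_bh(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (monotone q-values, rejections)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


# ---------------------------------------------------------------------------
# population probability map
# ---------------------------------------------------------------------------


def probability_map(masks: list[np.ndarray]) -> np.ndarray:
    """Per-vertex fraction of subjects whose parcel includes the vertex."""
    if not masks:
        raise ValueError("no parcels supplied")
    arr = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        if np.asarray(m).shape != arr.shape:
            raise ValueError("parcel topologies differ")
    stack = np.stack([np.asarray(m, dtype=float) for m in masks])
    return stack.mean(axis=0)
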