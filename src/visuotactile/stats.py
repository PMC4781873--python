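"""Within-subject inference machinery.

Implements the analysis chain used throughout the experiment: a normality
gate (Shapiro-Wilk on cell-centered residuals, natural-log transform on
failure), one- and two-factor repeated-measures ANOVA with Mauchly's
sphericity test and the Greenhouse-Geisser degrees-of-freedom correction,
paired and one-sample t-tests, and Holm-Bonferroni multiplicity control.

Conventions
-----------
* Data enter as a complete, balanced subjects x cells matrix (one value per
  subject per cell — typically a per-subject median or mean).
* Sphericity diagnostics are computed from the sample covariance (n-1
  divisor) of orthonormal within-factor contrasts; for a main effect the
  data are first collapsed (averaged) over the other factor, for the
  interaction the Kronecker product of the factor contrasts is used.
* The Greenhouse-Geisser correction is applied per effect only when that
  effect's Mauchly test rejects at the gate alpha; two-level effects are
  spherical by construction (epsilon = W = 1) and bypass testing.
* All tests are two-sided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Zero-variance or otherwise degenerate input to a test."""


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def normality_gate(values, alpha: float = 0.05):
    """Shapiro-Wilk gate with natural-log fallback.

    ``values`` is a subjects x cells array. Residuals are the values minus
    their cell means, pooled across cells. If the Shapiro-Wilk test rejects
    at ``alpha`` the values are replaced by their natural logarithm (they
    must then be strictly positive) and the flag is True.

    Returns ``(values, transformed_flag)``.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a subjects x cells matrix")
    resid = X - X.mean(axis=0, keepdims=True)
    if np.allclose(resid, 0.0):
        logger.warning("normality_gate: residuals all zero (degenerate); no transform")
        return X, False
    _, p = sps.shapiro(resid.ravel())
    if p >= alpha:
        return X, False
    if np.any(X <= 0.0):
        raise ValueError(
            "normality violated but values are not strictly positive; "
            "add an offset before log-transforming or analyze untransformed"
        )
    return np.log(X), True


# ---------------------------------------------------------------------------
# Sphericity: contrasts, Mauchly's W, Greenhouse-Geisser epsilon
# ---------------------------------------------------------------------------

def orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (normalized Helmert rows)."""
    if k < 2:
        raise ValueError("need at least two levels")
    C = np.zeros((k - 1, k))
    for i in range(1, k):
        C[i - 1, :i] = 1.0
        C[i - 1, i] = -i
        C[i - 1] /= np.sqrt(i * (i + 1))
    return C


def _contrast_cov(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    Y = X @ C.T  # n x (k-1) contrast scores
    return np.cov(Y, rowvar=False, ddof=1).reshape(C.shape[0], C.shape[0])


def mauchly_from_cov(S: np.ndarray, n: int):
    """Mauchly's W and its chi-square approximation p from a d x d contrast
    covariance estimated on n subjects."""
    d = S.shape[0]
    if d == 1:
        return 1.0, 1.0
    det = np.linalg.det(S)
    tr = np.trace(S)
    if det <= 0 or tr <= 0:
        raise DegenerateDataError("singular contrast covariance in Mauchly's test")
    W = float(det / (tr / d) ** d)
    if not np.isfinite(W) or W < 1e-12:
        raise DegenerateDataError("numerically singular contrast covariance in Mauchly's test")
    # chi-square approximation with the standard second-order term
    k = d + 1
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1))
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    chi2 = -(n - 1) * f * np.log(W)
    df = d * (d + 1) // 2 - 1
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return W, p


def mauchly_test(values):
    """Mauchly's sphericity test on a subjects x k within-factor matrix."""
    X = np.asarray(values, dtype=float)
    n, k = X.shape
    if k == 2:
        return 1.0, 1.0
    return mauchly_from_cov(_contrast_cov(X, orthonormal_contrasts(k)), n)


def gg_epsilon_from_cov(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon-hat from a d x d contrast covariance,
    clipped to [1/d, 1]."""
    d = S.shape[0]
    eps = np.trace(S) ** 2 / (d * np.trace(S @ S))
    return float(np.clip(eps, 1.0 / d, 1.0))


def gg_epsilon(values) -> float:
    """Greenhouse-Geisser epsilon-hat for a subjects x k within-factor matrix."""
    X = np.asarray(values, dtype=float)
    k = X.shape[1]
    if k == 2:
        return 1.0
    return gg_epsilon_from_cov(_contrast_cov(X, orthonormal_contrasts(k)))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test; raises on constant differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length samples of size >= 2")
    d = x - y
    scale = max(1.0, float(np.abs(d).max()))
    if np.var(d, ddof=1) <= (1e-9 * scale) ** 2:
        raise DegenerateDataError(
            f"differences are constant (mean {d.mean():g}); t undefined"
        )
    res = sps.ttest_rel(x, y)
    return TTestResult(float(res.statistic), x.size - 1, float(res.pvalue),
                       float(d.mean()))


def one_sample_t(x, mu: float) -> TTestResult:
    """Two-sided one-sample t-test against ``mu``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("one_sample_t needs n >= 2")
    scale = max(1.0, float(np.abs(x).max()))
    if np.var(x, ddof=1) <= (1e-9 * scale) ** 2:
        raise DegenerateDataError("sample is constant; t undefined")
    res = sps.ttest_1samp(x, mu)
    return TTestResult(float(res.statistic), x.size - 1, float(res.pvalue),
                       float(x.mean() - mu))


# ---------------------------------------------------------------------------
# Holm-Bonferroni
# ---------------------------------------------------------------------------

def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm-corrected p-values, in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _effect_row(name, ss_eff, df_eff, ss_err, df_err, eff_data=None, cov=None,
                n=None, alpha=0.05):
    """Assemble one ANOVA table row with sphericity handling.

    ``eff_data`` (subjects x levels, for main effects) or ``cov`` (contrast
    covariance, for the interaction) feeds Mauchly/epsilon when the effect
    has more than one numerator df.
    """
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff, df_err))
    if df_eff == 1:
        W, mp, eps = 1.0, 1.0, 1.0
    elif cov is not None:
        W, mp = mauchly_from_cov(cov, n)
        eps = gg_epsilon_from_cov(cov)
    else:
        W, mp = mauchly_test(eff_data)
        eps = gg_epsilon(eff_data)
    df1c, df2c = eps * df_eff, eps * df_err
    p_gg = float(sps.f.sf(F, df1c, df2c))
    corrected = bool(mp < alpha and df_eff > 1)
    return {
        "effect": name, "ss": ss_eff, "ss_error": ss_err,
        "df_num": df_eff, "df_den": df_err, "F": float(F), "p": p,
        "mauchly_W": W, "mauchly_p": mp, "gg_epsilon": eps,
        "corrected_df_num": df1c, "corrected_df_den": df2c, "corrected_p": p_gg,
        "sphericity_corrected": corrected,
        "p_final": p_gg if corrected else p,
    }


def rm_anova(values, factors, alpha: float = 0.05,
             apply_normality_gate: bool = True) -> pd.DataFrame:
    """Repeated-measures ANOVA with one or two within-subject factors.

    Parameters
    ----------
    values : subjects x cells matrix (or DataFrame). For two factors the
        cells must be ordered with the second factor varying fastest, i.e.
        (A1B1, A1B2, ..., A2B1, ...).
    factors : list of ``(name, n_levels)``; one or two entries whose level
        product equals the number of cells.
    alpha : gate level for both the normality gate and the per-effect
        Mauchly test that triggers the Greenhouse-Geisser correction.
    apply_normality_gate : when True (default), the Shapiro-Wilk /
        log-transform gate runs first; requires strictly positive values if
        it triggers.

    Returns one row per effect with raw and sphericity-corrected statistics
    (``p_final`` is the Greenhouse-Geisser p when that effect's Mauchly test
    rejected, the raw p otherwise) plus a ``transform_applied`` column.
    """
    if isinstance(values, pd.DataFrame):
        subject_ids = list(values.index)
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
        subject_ids = list(range(1, X.shape[0] + 1))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("values must be a subjects x cells matrix with >= 2 subjects")
    bad = [subject_ids[i] for i in np.where(np.isnan(X).any(axis=1))[0]]
    if bad:
        raise ValueError(f"incomplete cells for subject(s) {bad}")
    if len(factors) not in (1, 2):
        raise ValueError("one or two within-subject factors supported")
    levels = [int(k) for _, k in factors]
    if int(np.prod(levels)) != X.shape[1]:
        raise ValueError("product of factor levels must equal the number of cells")

    transformed = False
    if apply_normality_gate:
        X, transformed = normality_gate(X, alpha)

    n = X.shape[0]
    grand = X.mean()
    rows = []
    if len(factors) == 1:
        name, k = factors[0]
        ms = X.mean(axis=1)  # subject means
        mc = X.mean(axis=0)  # cell means
        ss_eff = n * np.sum((mc - grand) ** 2)
        ss_err = np.sum((X - ms[:, None] - mc[None, :] + grand) ** 2)
        rows.append(_effect_row(name, ss_eff, k - 1, ss_err, (k - 1) * (n - 1),
                                eff_data=X, alpha=alpha))
    else:
        (na_, a), (nb_, b) = factors
        Y = X.reshape(n, a, b)
        ms = Y.mean(axis=(1, 2))
        ma = Y.mean(axis=(0, 2))
        mb = Y.mean(axis=(0, 1))
        msa = Y.mean(axis=2)  # n x a
        msb = Y.mean(axis=1)  # n x b
        mab = Y.mean(axis=0)  # a x b

        ss_a = n * b * np.sum((ma - grand) ** 2)
        ss_as = b * np.sum((msa - ms[:, None] - ma[None, :] + grand) ** 2)
        rows.append(_effect_row(na_, ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                                eff_data=msa, alpha=alpha))

        ss_b = n * a * np.sum((mb - grand) ** 2)
        ss_bs = a * np.sum((msb - ms[:, None] - mb[None, :] + grand) ** 2)
        rows.append(_effect_row(nb_, ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
                                eff_data=msb, alpha=alpha))

        ss_ab = n * np.sum((mab - ma[:, None] - mb[None, :] + grand) ** 2)
        resid = (Y - msa[:, :, None] - msb[:, None, :] - mab[None, :, :]
                 + ms[:, None, None] + ma[None, :, None] + mb[None, None, :] - grand)
        ss_abs = np.sum(resid ** 2)
        d_ab = (a - 1) * (b - 1)
        C_ab = np.kron(orthonormal_contrasts(a), orthonormal_contrasts(b))
        cov_ab = _contrast_cov(X, C_ab) if d_ab > 1 else None
        rows.append(_effect_row(f"{na_} x {nb_}", ss_ab, d_ab, ss_abs,
                                d_ab * (n - 1),
                                eff_data=None if d_ab > 1 else X,
                                cov=cov_ab, n=n, alpha=alpha))

    out = pd.DataFrame(rows)
    out["transform_applied"] = transformed
    return out


def posthoc_pairwise(values: pd.DataFrame, pairs=None) -> pd.DataFrame:
    """Holm-corrected paired t-tests between columns of a subjects x levels
    frame. ``pairs`` defaults to all column pairs; each call is one Holm
    family (the set of comparisons reported together)."""
    cols = list(values.columns)
    if pairs is None:
        pairs = [(cols[i], cols[j]) for i in range(len(cols))
                 for j in range(i + 1, len(cols))]
    rows = []
    for x, y in pairs:
        res = paired_t(values[x].to_numpy(), values[y].to_numpy())
        rows.append({"comparison": f"{x} vs {y}", "mean_diff": res.mean_diff,
                     "t": res.t, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(out["p"].to_numpy())
    return out
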