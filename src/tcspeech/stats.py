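"""Keyword scoring, the RAU transform, and intelligibility inference.

Proportion-correct scores are variance-unstable near the floor and
ceiling, so post-hoc testing runs on rationalized arcsine units (RAU),
a linearly rescaled arcsine transform that is near-linear between ~20%
and ~80% correct and maps [0, 100]% onto roughly [-23, 123] RAU.

The inferential battery mirrors standard psychoacoustic practice:

* Welch two-sample t (Satterthwaite degrees of freedom), plus a paired
  variant for within-subject contrasts;
* a fully-within-subjects repeated-measures ANOVA for balanced designs
  with any number of crossed within factors, reporting per-effect F,
  generalized eta-squared, Mauchly's sphericity test, and the
  Greenhouse-Geisser correction applied when sphericity is rejected;
* Bonferroni-corrected pairwise post-hocs on RAU scores;
* the repackaging-benefit contrast (silence minus no-silence per
  subject and spectral condition, averaged over test/retest).

The ANOVA is computed from first principles (balanced-design
sums-of-squares projections and contrast-covariance epsilon); the test
suite cross-checks it against independent implementations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.linalg import helmert

__all__ = [
    "TrialScore",
    "score_keywords",
    "rau",
    "welch_t",
    "paired_t",
    "rm_anova",
    "posthoc_pairwise",
    "repackaging_benefit",
    "normality_check",
]


@dataclass(frozen=True)
class TrialScore:
    """Keywords presented and correctly recalled on one list."""

    n_keywords: int
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_keywords < 1:
            raise ValueError("n_keywords must be >= 1")
        if not 0 <= self.n_correct <= self.n_keywords:
            raise ValueError("n_correct must lie in [0, n_keywords]")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_correct / self.n_keywords

    @property
    def rau(self) -> float:
        return rau(self.n_correct, self.n_keywords)


_PUNCT = str.maketrans("", "", r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~""")


def _normalize_token(token: str) -> str:
    return token.casefold().translate(_PUNCT)


def score_keywords(response_tokens: list[str], keyword_tokens: list[str]) -> TrialScore:
    """Count keywords present in the response (case- and punctuation-insensitive).

    Each keyword is credited at most once; repeated response tokens can
    credit repeated keywords but not the same keyword twice.
    """
    if not keyword_tokens:
        raise ValueError("keyword list must be non-empty")
    available: dict[str, int] = {}
    for tok in response_tokens:
        norm = _normalize_token(tok)
        available[norm] = available.get(norm, 0) + 1
    n_correct = 0
    for kw in keyword_tokens:
        norm = _normalize_token(kw)
        if available.get(norm, 0) > 0:
            available[norm] -= 1
            n_correct += 1
    return TrialScore(n_keywords=len(keyword_tokens), n_correct=n_correct)


def rau(n_correct, n_keywords=None) -> float:
    """Rationalized arcsine units of ``n_correct`` out of ``n_keywords``.

    theta = asin(sqrt(X / (N + 1))) + asin(sqrt((X + 1) / (N + 1))),
    RAU = (146 / pi) * theta - 23.

    Defined at both endpoints: 0/N maps near -15 RAU (N = 33 gives
    -15.0) and N/N near +115 RAU.  Also accepts a single
    :class:`TrialScore` argument.
    """
    if n_keywords is None:
        if not isinstance(n_correct, TrialScore):
            raise TypeError("pass (n_correct, n_keywords) or a TrialScore")
        x, n = n_correct.n_correct, n_correct.n_keywords
    else:
        x, n = int(n_correct), int(n_keywords)
    TrialScore(n, x)  # validates
    theta = np.arcsin(np.sqrt(x / (n + 1.0))) + np.arcsin(np.sqrt((x + 1.0) / (n + 1.0)))
    return float(146.0 / np.pi * theta - 23.0)


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Returns ``(t, df, p)``.  The fractional df reduces to ``2n - 2``
    when the two samples have equal size and equal variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0 and np.mean(a) == np.mean(b):
        raise ValueError("zero variance in both groups with equal means: t undefined")
    res = sst.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t(values_a, values_b) -> tuple[float, float, float]:
    """Paired t-test; returns ``(t, df, p)``.

    Identical samples (every difference zero) report ``t = 0, p = 1`` by
    convention rather than the 0/0 form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.var(d, ddof=1) == 0.0 and np.mean(d) == 0.0:
        return 0.0, float(a.size - 1), 1.0
    res = sst.ttest_rel(a, b)
    return float(res.statistic), float(a.size - 1), float(res.pvalue)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA for balanced fully-within designs
# ---------------------------------------------------------------------------


def _effect_sum_squares(Y: np.ndarray, axes: tuple[int, ...]) -> tuple[float, float]:
    """Sum of squares and df of the effect spanned by ``axes``.

    Uses the balanced-design projection: the effect term is the
    inclusion-exclusion alternating sum of marginal means over all
    subsets of ``axes``, and its SS is the squared term summed over the
    full data array.
    """
    all_axes = tuple(range(Y.ndim))
    term = np.zeros_like(Y)
    for r in range(len(axes) + 1):
        sign = (-1.0) ** (len(axes) - r)
        for sub in itertools.combinations(axes, r):
            reduce_over = tuple(a for a in all_axes if a not in sub)
            m = Y.mean(axis=reduce_over, keepdims=True) if reduce_over else Y
            term = term + sign * m
    ss = float(np.sum(np.broadcast_to(term, Y.shape) ** 2))
    df = 1.0
    for a in axes:
        df *= Y.shape[a] - 1
    return ss, df


def _effect_contrast(Y: np.ndarray, factor_axes: tuple[int, ...]) -> np.ndarray:
    """Per-subject contrast scores for a within effect.

    Builds the Kronecker product over factor axes of orthonormal
    contrasts (for factors in the effect) and averaging rows (for
    factors not in it), applied to each subject's cell vector.
    """
    mats = []
    for axis in range(1, Y.ndim):
        levels = Y.shape[axis]
        if axis in factor_axes:
            mats.append(helmert(levels, full=False))
        else:
            mats.append(np.full((1, levels), 1.0 / levels))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    cells = Y.reshape(Y.shape[0], -1)  # row-major matches kron order
    return cells @ C.T


def _gg_epsilon(Z: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast scores (subjects x d)."""
    d = Z.shape[1]
    if d <= 1:
        return 1.0
    sigma = np.cov(Z, rowvar=False, ddof=1)
    tr = float(np.trace(sigma))
    denom = d * float(np.sum(sigma * sigma))
    if denom <= 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / d, 1.0))


def _mauchly(Z: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on contrast scores; returns (W, p).

    Returns ``(nan, nan)`` when the covariance is rank-deficient (too
    few subjects for the number of contrasts).
    """
    n, d = Z.shape
    if d <= 1:
        return 1.0, 1.0
    if n - 1 < d:
        return float("nan"), float("nan")
    sigma = np.cov(Z, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(sigma)
    if np.any(eig <= 0):
        return float("nan"), float("nan")
    W = float(np.prod(eig) / np.mean(eig) ** d)
    f = (2.0 * d * d + d + 2.0) / (6.0 * d)
    chi2 = -(n - 1.0 - f) * np.log(W)
    df = d * (d + 1.0) / 2.0 - 1.0
    return W, float(sst.chi2.sf(chi2, df))


def rm_anova(
    table: pd.DataFrame,
    dv: str = "percent",
    within: list[str] | tuple[str, ...] = (),
    subject: str = "subject",
    sphericity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeated-measures ANOVA for a balanced fully-within design.

    Replicate rows (e.g. per-sentence scores) are averaged within each
    subject x cell first; every subject must then hold every cell
    exactly once, otherwise a structural error is raised (no
    imputation).

    For every main effect and interaction the returned frame holds the
    F statistic with its uncorrected degrees of freedom, the
    uncorrected and Greenhouse-Geisser-corrected p values, generalized
    eta-squared (``ges``), the GG epsilon, and Mauchly's W and p.  The
    ``p`` column applies the study rule: the GG-corrected p is reported
    whenever the effect has more than one numerator df and Mauchly's
    test rejects sphericity at ``sphericity_alpha`` (or cannot be
    computed); otherwise the uncorrected p is reported.
    """
    within = list(within)
    if not within:
        raise ValueError("within must name at least one factor column")
    missing = [c for c in [subject, dv, *within] if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")

    cellmeans = table.groupby([subject, *within], as_index=False, observed=True)[dv].mean()
    subjects = sorted(cellmeans[subject].unique().tolist())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    levels = {f: sorted(cellmeans[f].unique().tolist()) for f in within}

    n_cells = int(np.prod([len(levels[f]) for f in within]))
    counts = cellmeans.groupby(subject, observed=True).size()
    if not (counts == n_cells).all() or len(cellmeans) != len(subjects) * n_cells:
        raise ValueError("unbalanced design: every subject must hold every within cell")

    order = [subject, *within]
    cm = cellmeans.copy()
    for col, lv in [(subject, subjects), *[(f, levels[f]) for f in within]]:
        cm[col] = pd.Categorical(cm[col], categories=lv, ordered=True)
    cm = cm.sort_values(order)
    shape = (len(subjects), *[len(levels[f]) for f in within])
    Y = cm[dv].to_numpy(dtype=float).reshape(shape)

    n_subj = shape[0]
    factor_axes = {f: i + 1 for i, f in enumerate(within)}

    # All sums of squares needed for F and generalized eta-squared.
    ss_subject, _ = _effect_sum_squares(Y, (0,))
    effects = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            effects.append(combo)
    ss_err_total = 0.0
    ss_cache: dict[tuple[str, ...], tuple[float, float, float, float]] = {}
    for combo in effects:
        axes = tuple(factor_axes[f] for f in combo)
        ss, df = _effect_sum_squares(Y, axes)
        ss_err, df_err = _effect_sum_squares(Y, (0, *axes))
        ss_cache[combo] = (ss, df, ss_err, df_err)
        ss_err_total += ss_err

    rows = []
    for combo in effects:
        ss, df, ss_err, df_err = ss_cache[combo]
        F = (ss / df) / (ss_err / df_err)
        p_unc = float(sst.f.sf(F, df, df_err))
        ges = ss / (ss + ss_subject + ss_err_total)
        axes = tuple(factor_axes[f] for f in combo)
        Z = _effect_contrast(Y, axes)
        eps = _gg_epsilon(Z)
        W, p_sph = _mauchly(Z)
        p_gg = float(sst.f.sf(F, eps * df, eps * df_err))
        gg_applied = df > 1 and (np.isnan(p_sph) or p_sph < sphericity_alpha)
        rows.append(
            {
                "effect": " * ".join(combo),
                "SS": ss,
                "SS_error": ss_err,
                "df_num": df,
                "df_den": df_err,
                "F": F,
                "p_unc": p_unc,
                "epsilon": eps,
                "sphericity_W": W,
                "sphericity_p": p_sph,
                "df_num_gg": eps * df,
                "df_den_gg": eps * df_err,
                "p_gg": p_gg,
                "gg_applied": bool(gg_applied),
                "p": p_gg if gg_applied else p_unc,
                "ges": ges,
                "n_subjects": n_subj,
            }
        )
    return pd.DataFrame(rows)


def posthoc_pairwise(
    table: pd.DataFrame,
    contrast: str,
    dv: str = "rau",
    subject: str = "subject",
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Paired t-tests between all level pairs of ``contrast``.

    Scores are averaged per subject within each level (collapsing any
    other factors, e.g. test/retest) and compared with paired t-tests;
    p values are Bonferroni-multiplied by the number of comparisons and
    capped at 1.
    """
    if contrast not in table.columns:
        raise ValueError(f"contrast factor {contrast!r} not in table")
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    means = table.groupby([subject, contrast], as_index=False, observed=True)[dv].mean()
    wide = means.pivot(index=subject, columns=contrast, values=dv)
    if wide.isna().any().any():
        raise ValueError("every subject must hold every level of the contrast factor")
    level_names = sorted(wide.columns.tolist())
    pairs = list(itertools.combinations(level_names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, df, p = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": t,
                "df": df,
                "p_unc": p,
                "p_adjusted": min(1.0, p * m),
                "n_comparisons": m,
            }
        )
    return pd.DataFrame(rows)


def repackaging_benefit(
    table: pd.DataFrame,
    subject: str = "subject",
    spectral: str = "spectral_content",
    silence: str = "silence_added",
) -> pd.DataFrame:
    """Per-subject intelligibility benefit of restoring the syllabic rhythm.

    benefit = score(silence added) - score(no silence), computed per
    subject and spectral condition with test/retest (and any other
    remaining factors) averaged first.  Returned in both percent and
    RAU.
    """
    for col in (subject, spectral, silence, "percent", "rau"):
        if col not in table.columns:
            raise ValueError(f"table is missing column {col!r}")
    means = table.groupby([subject, spectral, silence], as_index=False, observed=True)[
        ["percent", "rau"]
    ].mean()
    rows = []
    for (subj, spec), grp in means.groupby([subject, spectral], observed=True):
        with_sil = grp[grp[silence].astype(bool)]
        without = grp[~grp[silence].astype(bool)]
        if len(with_sil) != 1 or len(without) != 1:
            raise ValueError(
                f"subject {subj!r}, spectral condition {spec!r}: need exactly one "
                "silence and one no-silence cell"
            )
        rows.append(
            {
                subject: subj,
                spectral: spec,
                "benefit_percent": float(with_sil["percent"].iloc[0] - without["percent"].iloc[0]),
                "benefit_rau": float(with_sil["rau"].iloc[0] - without["rau"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk test; returns ``(W, p)``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(arr) == 0.0:
        raise ValueError("constant input: normality test undefined")
    res = sst.shapiro(arr)
    return float(res.statistic), float(res.pvalue)
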