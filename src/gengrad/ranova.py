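"""Split-plot repeated-measures ANOVA with sphericity diagnostics.

One between-subject factor (a group, typically from a median split of a
continuous trait) crossed with one within-subject factor (the stimulus
dimension).  Complete, balanced-within data is required: every subject
must have a response at every stimulus level.

Sphericity — equality of the variances of all pairwise difference scores
between stimulus levels — is what the uncorrected within-stratum F tests
assume.  The module provides Mauchly's W test, the Greenhouse-Geisser,
Huynh-Feldt and lower-bound epsilon estimates, and epsilon-corrected
p-values.  All sphericity quantities are computed on the orthonormal
contrast transform of the pooled within-group covariance matrix (error
df ``n - g``), so the group structure is respected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "WideResponses",
    "SphericityResult",
    "EpsilonEstimates",
    "EffectRow",
    "RanovaResult",
    "median_split",
    "pivot_wide",
    "split_plot_anova",
    "mauchly_test",
    "epsilon_estimates",
    "corrected_tests",
    "ranova",
]


@dataclass(frozen=True)
class WideResponses:
    """Responses in subjects x stimuli layout plus optional group labels."""

    matrix: np.ndarray            #: (n_subjects, k) responses, columns in d order
    d_values: np.ndarray          #: (k,) stimulus codes, ascending
    subjects: np.ndarray          #: (n_subjects,) subject identifiers
    group: np.ndarray | None = None  #: (n_subjects,) labels, or None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("matrix must be 2-D with at least 2 stimulus levels")
        if not np.all(np.isfinite(m)):
            raise ValueError("responses must be complete (no missing cells)")
        object.__setattr__(self, "matrix", m)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_groups(self) -> int:
        return 1 if self.group is None else len(np.unique(self.group))


@dataclass(frozen=True)
class SphericityResult:
    """Mauchly's test of sphericity on the contrast covariance."""

    W: float
    chi2: float
    df: int
    p_value: float
    trivially_spherical: bool = False  #: True when k == 2


@dataclass(frozen=True)
class EpsilonEstimates:
    """Degrees-of-freedom deflation factors for sphericity corrections."""

    gg: float           #: Greenhouse-Geisser epsilon-hat
    hf: float           #: Huynh-Feldt epsilon-tilde, capped at 1
    lower_bound: float  #: 1 / (k - 1), the maximal correction


@dataclass(frozen=True)
class EffectRow:
    """One line of the ANOVA table."""

    ss: float
    df: float
    ms: float
    F: float | None = None       #: None for error strata or undefined F
    p: float | None = None
    defined: bool = True         #: False when the error MS is zero


@dataclass
class RanovaResult:
    """Split-plot ANOVA table plus sphericity diagnostics and corrections."""

    effects: dict[str, EffectRow]
    sphericity: SphericityResult | None = None
    epsilons: EpsilonEstimates | None = None
    #: corrected p-values per within effect: {"Stimulus": {"gg": .., "hf": ..,
    #: "lower_bound": ..}, "Stimulus:Group": {...}}
    corrected_p: dict[str, dict[str, float]] = field(default_factory=dict)
    between_test_omitted: bool = False

    @property
    def ss_total(self) -> float:
        return sum(e.ss for e in self.effects.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append({"effect": name, "SS": e.ss, "df": e.df, "MS": e.ms,
                         "F": e.F, "p": e.p})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# median splits

def median_split(u, convention: str = "low_strict") -> np.ndarray:
    """Dichotomize per-subject scores at the sample median.

    Two tie-handling conventions exist and genuinely differ when scores
    equal the median:

    - ``low_strict``:    low iff u_i <  median(u)   (ties go high)
    - ``low_inclusive``: low iff u_i <= median(u)   (ties go low)

    The median is the usual midpoint-of-order-statistics sample median.
    Both conventions coincide whenever no score equals the median.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or len(u) < 2:
        raise ValueError("need at least 2 subjects to split")
    med = np.median(u)
    if convention == "low_strict":
        low = u < med
    elif convention == "low_inclusive":
        low = u <= med
    else:
        raise ValueError(f"unknown convention {convention!r}")
    labels = np.where(low, "low", "high")
    if len(np.unique(labels)) == 1:
        warnings.warn("median split produced a single group (all scores on "
                      "one side of the median); downstream group analyses "
                      "will be unavailable", stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# reshaping

def pivot_wide(data: pd.DataFrame, group=None) -> WideResponses:
    """Pivot a long-format gradient dataset to subjects x stimuli.

    Requires complete balanced data: every subject must have exactly one
    row per stimulus level.  ``group`` may be a per-subject array (in
    subject order) or a mapping from subject id to label.
    """
    piv = data.pivot_table(index="subject", columns="d", values="y",
                           aggfunc="first", dropna=False)
    if piv.isna().any().any():
        bad = piv.index[piv.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete data: subjects {bad} are missing one or "
                         "more stimulus levels (rANOVA needs complete cases)")
    counts = data.groupby("subject")["d"].count()
    if (counts != piv.shape[1]).any():
        bad = counts.index[counts != piv.shape[1]].tolist()
        raise ValueError(f"unbalanced data: subjects {bad} do not have exactly "
                         "one row per stimulus level")
    subjects = piv.index.to_numpy()
    if group is None:
        glab = None
    elif isinstance(group, dict):
        glab = np.array([group[s] for s in subjects])
    else:
        glab = np.asarray(group)
        if len(glab) != len(subjects):
            raise ValueError("group labels must be one per subject")
    return WideResponses(matrix=piv.to_numpy(dtype=float),
                         d_values=piv.columns.to_numpy(dtype=float),
                         subjects=subjects, group=glab)


# ---------------------------------------------------------------------------
# the split-plot decomposition

def split_plot_anova(wide: WideResponses) -> RanovaResult:
    """Classical balanced split-plot (mixed between/within) decomposition.

    Between-subject stratum: Group (df g-1) against subjects-within-groups
    (df n-g).  Within stratum: Stimulus (df k-1) and Stimulus:Group
    (df (k-1)(g-1)) against the within error (df (n-g)(k-1)).  Every
    subject contributes a complete row, so cell frequencies are
    proportional and the decomposition is orthogonal even with unequal
    group sizes.
    """
    y = wide.matrix
    n, k = y.shape
    if wide.group is None:
        groups = np.zeros(n, dtype=int)
    else:
        _, groups = np.unique(wide.group, return_inverse=True)
    g = groups.max() + 1
    single_group = g == 1
    if not single_group:
        sizes = np.bincount(groups)
        if sizes.min() < 2:
            raise ValueError("each group needs at least 2 subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)                       # (n,)
    stim_means = y.mean(axis=0)                       # (k,)
    group_means = np.array([subj_means[groups == a].mean() for a in range(g)])
    cell_means = np.array([y[groups == a].mean(axis=0) for a in range(g)])  # (g, k)
    sizes = np.bincount(groups)

    ss_group = k * float(np.sum(sizes * (group_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - group_means[groups]) ** 2))
    ss_stim = n * float(np.sum((stim_means - grand) ** 2))
    inter = cell_means - group_means[:, None] - stim_means[None, :] + grand
    ss_inter = float(np.sum(sizes[:, None] * inter ** 2))
    ss_within_total = float(np.sum((y - subj_means[:, None]) ** 2))
    ss_err = ss_within_total - ss_stim - ss_inter

    df_group = g - 1
    df_subj = n - g
    df_stim = k - 1
    df_inter = (k - 1) * (g - 1)
    df_err = (n - g) * (k - 1)

    def row(ss, df, ms_err, df_err_):
        ms = ss / df if df > 0 else 0.0
        if df == 0:
            return EffectRow(ss=ss, df=df, ms=ms, defined=False)
        if ms_err is None:
            return EffectRow(ss=ss, df=df, ms=ms)
        if ms_err <= 0:
            return EffectRow(ss=ss, df=df, ms=ms, defined=False)
        F = ms / ms_err
        p = float(stats.f.sf(F, df, df_err_))
        return EffectRow(ss=ss, df=df, ms=ms, F=F, p=p)

    ms_subj = ss_subj / df_subj if df_subj > 0 else 0.0
    ms_err = ss_err / df_err if df_err > 0 else 0.0

    effects = {
        "Group": row(ss_group, df_group, ms_subj, df_subj),
        "Subjects(Group)": EffectRow(ss=ss_subj, df=df_subj, ms=ms_subj),
        "Stimulus": row(ss_stim, df_stim, ms_err, df_err),
        "Stimulus:Group": row(ss_inter, df_inter, ms_err, df_err),
        "Within error": EffectRow(ss=ss_err, df=df_err, ms=ms_err),
    }
    return RanovaResult(effects=effects, between_test_omitted=single_group)


# ---------------------------------------------------------------------------
# sphericity

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    return linalg.helmert(k, full=False)


def _pooled_contrast_cov(wide: WideResponses,
                         contrasts: np.ndarray | None = None
                         ) -> tuple[np.ndarray, int]:
    """Contrast-transformed pooled within-group covariance and its df."""
    y = wide.matrix
    n, k = y.shape
    if wide.group is None:
        groups = np.zeros(n, dtype=int)
    else:
        _, groups = np.unique(wide.group, return_inverse=True)
    g = groups.max() + 1
    n_e = n - g
    if n_e < k - 1:
        raise ValueError(
            f"error df {n_e} < {k - 1} within-subject contrasts: the contrast "
            "covariance is singular; more subjects than stimulus levels are "
            "needed")
    centered = y - np.array([y[groups == a].mean(axis=0) for a in range(g)])[groups]
    pooled = centered.T @ centered / n_e
    C = _orthonormal_contrasts(k) if contrasts is None else np.asarray(contrasts)
    return C @ pooled @ C.T, n_e


def mauchly_test(wide: WideResponses,
                 contrasts: np.ndarray | None = None) -> SphericityResult:
    """Mauchly's W test of sphericity.

    W = det(S) / (tr(S)/p)^p on the contrast covariance S (p = k-1),
    referred to chi-square with f = p(p+1)/2 - 1 df via the Bartlett-type
    factor n_e - (2p^2+p+2)/(6p).  The p-value includes Box's
    second-order series term, Pr(chi2_f > z) + w2 (Pr(chi2_{f+4} > z) -
    Pr(chi2_f > z)), matching the convention of standard statistical
    software.  With k = 2 there is a single difference score, sphericity
    holds trivially, and W = 1 with df 0.
    """
    k = wide.k
    if k == 2:
        return SphericityResult(W=1.0, chi2=0.0, df=0, p_value=1.0,
                                trivially_spherical=True)
    S, n_e = _pooled_contrast_cov(wide, contrasts)
    p = k - 1
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("singular contrast covariance; more subjects than "
                         "stimulus levels are required")
    logW = logdet - p * np.log(np.trace(S) / p)
    W = float(np.exp(logW))
    rho = 1.0 - (2 * p ** 2 + p + 2) / (6.0 * p * n_e)
    chi2 = float(-n_e * rho * logW)
    df = p * (p + 1) // 2 - 1
    # the 3k+2 term (k = levels, not contrasts) matches the reference
    # implementations in standard statistical software
    w2 = ((p + 2) * (p - 1) * (p - 2) * (2 * p ** 3 + 6 * p ** 2 + 3 * k + 2)
          / (288.0 * (n_e * p * rho) ** 2))
    pr1 = stats.chi2.sf(chi2, df)
    pr2 = stats.chi2.sf(chi2, df + 4)
    pval = float(min(max(pr1 + w2 * (pr2 - pr1), 0.0), 1.0))
    return SphericityResult(W=W, chi2=chi2, df=df, p_value=pval)


def epsilon_estimates(wide: WideResponses,
                      contrasts: np.ndarray | None = None) -> EpsilonEstimates:
    """Greenhouse-Geisser, Huynh-Feldt and lower-bound epsilons.

    GG: (tr S)^2 / (p tr S^2).  HF (split-plot form, error df n_e = n-g):
    ((n_e + 1) p gg - 2) / (p (n_e - p gg)), capped at 1.  Lower bound:
    1/p, the most severe correction possible with k levels.
    """
    k = wide.k
    p = k - 1
    lb = 1.0 / p
    if k == 2:
        return EpsilonEstimates(gg=1.0, hf=1.0, lower_bound=1.0)
    S, n_e = _pooled_contrast_cov(wide, contrasts)
    tr = np.trace(S)
    gg = float(tr ** 2 / (p * np.sum(S * S.T)))
    hf = float(((n_e + 1) * p * gg - 2) / (p * (n_e - p * gg)))
    return EpsilonEstimates(gg=gg, hf=min(hf, 1.0), lower_bound=lb)


def corrected_tests(result: RanovaResult, epsilon: float) -> dict[str, float]:
    """Recompute within-stratum p-values with both df scaled by epsilon.

    The F statistic is unchanged; only the reference distribution's
    degrees of freedom shrink, which raises the p-value whenever
    epsilon < 1 (for F in the upper tail).
    """
    k = result.effects["Stimulus"].df + 1
    lb = 1.0 / (k - 1)
    if not (lb - 1e-12 <= epsilon <= 1.0 + 1e-12):
        raise ValueError(f"epsilon must lie in [1/(k-1), 1] = [{lb:.4g}, 1]")
    df_err = result.effects["Within error"].df
    out = {}
    for name in ("Stimulus", "Stimulus:Group"):
        e = result.effects[name]
        if not e.defined or e.F is None:
            out[name] = float("nan")
        else:
            out[name] = float(stats.f.sf(e.F, e.df * epsilon, df_err * epsilon))
    return out


# ---------------------------------------------------------------------------
# convenience front end

def ranova(data: pd.DataFrame, split: str = "low_strict") -> RanovaResult:
    """Full split-plot analysis of a long-format gradient dataset.

    Median-splits ``u`` with the given convention, pivots to wide form,
    runs the split-plot ANOVA, Mauchly's test and the epsilon estimates,
    and attaches GG / HF / lower-bound corrected p-values for the two
    within-stratum effects.
    """
    u_per_subject = data.groupby("subject")["u"].first()
    labels = median_split(u_per_subject.to_numpy(), convention=split)
    wide = pivot_wide(data, group=dict(zip(u_per_subject.index, labels)))
    res = split_plot_anova(wide)
    res.sphericity = mauchly_test(wide)
    eps = epsilon_estimates(wide)
    res.epsilons = eps
    gg = corrected_tests(res, eps.gg)
    hf = corrected_tests(res, eps.hf)
    lb = corrected_tests(res, eps.lower_bound)
    for name in ("Stimulus", "Stimulus:Group"):
        res.corrected_p[name] = {"gg": gg[name], "hf": hf[name],
                                 "lower_bound": lb[name]}
    return res
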