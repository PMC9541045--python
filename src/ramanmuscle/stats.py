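"""Final statistical inference on discriminant scores.

Two operations, mirroring the analysis of a hierarchical design where
several spectra are recorded per animal:

* :func:`nested_ttest` — group comparison with spectra nested within
  subjects, implemented as a one-way nested ANOVA with subject as the
  random factor: the between-group mean square is tested against the
  between-subject-within-group mean square on (1, S-2) degrees of freedom
  (S subjects in total).  With a balanced design this is numerically
  identical to a two-sample t-test on per-subject mean scores (t^2 = F).
* :func:`correlate_covariate` — Pearson correlation and least-squares line
  between per-subject mean scores and a continuous per-subject covariate
  (distance run, km).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["NestedTestResult", "CorrelationResult", "nested_ttest", "correlate_covariate"]


@dataclass
class NestedTestResult:
    """Nested ANOVA of scores: spectra nested in subjects nested in groups."""

    subject_means: dict[str, float]
    group_means: dict[str, float]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    icc: float  # intraclass correlation of spectra within subject (nan if df=0)


@dataclass
class CorrelationResult:
    """Pearson correlation of per-subject mean scores with a covariate."""

    r: float
    r2: float
    p_value: float
    slope: float
    intercept: float
    n_subjects: int


def _per_subject(
    scores: np.ndarray, subject_ids: np.ndarray, groups: np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    subjects = list(dict.fromkeys(subject_ids.tolist()))
    means = np.empty(len(subjects))
    counts = np.empty(len(subjects))
    subj_group: list[str] = []
    for i, s in enumerate(subjects):
        mask = subject_ids == s
        g = set(groups[mask].tolist())
        if len(g) != 1:
            raise ValueError(f"subject {s!r} appears in more than one group")
        subj_group.append(g.pop())
        means[i] = scores[mask].mean()
        counts[i] = mask.sum()
    return subjects, means, counts, subj_group


def nested_ttest(
    scores: Sequence[float],
    subject_ids: Sequence[str],
    groups: Sequence[str],
) -> NestedTestResult:
    """Nested t-test of scores with spectra nested within subjects.

    Sums of squares are taken at the spectrum level, so unbalanced designs
    (missing acquisitions) are handled by the general nested-ANOVA path
    rather than by collapsing to subject means.
    """
    y = np.asarray(scores, dtype=float)
    subj = np.asarray(subject_ids)
    grp = np.asarray(groups)
    if not (y.size == subj.size == grp.size):
        raise ValueError("scores, subject_ids and groups must align")
    labels = list(dict.fromkeys(grp.tolist()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    subjects, s_means, s_counts, s_group = _per_subject(y, subj, grp)
    s_group_arr = np.asarray(s_group)
    for lab in labels:
        if (s_group_arr == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 subjects")
    grand = y.mean()
    group_means = {lab: y[grp == lab].mean() for lab in labels}
    n_g = {lab: (grp == lab).sum() for lab in labels}
    ss_group = sum(n_g[lab] * (group_means[lab] - grand) ** 2 for lab in labels)
    ss_subj = 0.0
    for mean, count, lab in zip(s_means, s_counts, s_group):
        ss_subj += count * (mean - group_means[lab]) ** 2
    S = len(subjects)
    df_between, df_within = 1, S - 2
    ms_group = ss_group / df_between
    ms_subj = ss_subj / df_within if df_within > 0 else np.nan
    if ms_subj == 0:
        f = 0.0 if ss_group == 0 else np.inf
    else:
        f = float(ms_group / ms_subj)
    p = float(sps.f.sf(f, df_between, df_within))
    # residual (spectrum-within-subject) level, for the ICC estimate
    resid = y.copy().astype(float)
    for s, mean in zip(subjects, s_means):
        resid[subj == s] -= mean
    df_err = int(y.size - S)
    if df_err > 0:
        ms_err = float((resid**2).sum() / df_err)
        N = y.size
        n0 = (N - float((s_counts**2).sum()) / N) / (S - len(labels))
        var_subj = max((ms_subj - ms_err) / n0, 0.0) if np.isfinite(ms_subj) else np.nan
        denom = var_subj + ms_err
        icc = float(var_subj / denom) if denom > 0 else np.nan
    else:
        icc = float("nan")
    return NestedTestResult(
        subject_means=dict(zip(subjects, s_means.tolist())),
        group_means=group_means,
        f_statistic=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        icc=icc,
    )


def correlate_covariate(
    scores: Sequence[float],
    subject_ids: Sequence[str],
    covariate: Mapping[str, float] | Sequence[float],
) -> CorrelationResult:
    """Correlate per-subject mean scores with a per-subject covariate.

    ``covariate`` is either a mapping subject id -> value or a sequence
    aligned with ``scores`` that is constant within each subject.  Subjects
    without a covariate value are dropped; at least 3 must remain.
    """
    y = np.asarray(scores, dtype=float)
    subj = np.asarray(subject_ids)
    if y.size != subj.size:
        raise ValueError("scores and subject_ids must align")
    if isinstance(covariate, Mapping):
        cov_of = dict(covariate)
    else:
        cov_arr = np.asarray(
            [np.nan if c is None else float(c) for c in covariate], dtype=float
        )
        if cov_arr.size != y.size:
            raise ValueError("per-acquisition covariate must align with scores")
        cov_of = {}
        for s in dict.fromkeys(subj.tolist()):
            vals = cov_arr[subj == s]
            finite = vals[np.isfinite(vals)]
            if finite.size and not np.allclose(finite, finite[0]):
                raise ValueError(f"covariate varies within subject {s!r}")
            cov_of[s] = float(finite[0]) if finite.size else None
    subjects = [s for s in dict.fromkeys(subj.tolist())]
    means, xs = [], []
    for s in subjects:
        c = cov_of.get(s)
        if c is None or (isinstance(c, float) and np.isnan(c)):
            continue
        means.append(y[subj == s].mean())
        xs.append(float(c))
    if len(xs) < 3:
        raise ValueError("fewer than 3 subjects with covariate")
    x = np.asarray(xs)
    m = np.asarray(means)
    fit = sps.linregress(x, m)
    r = float(fit.rvalue)
    p = float(fit.pvalue)
    if abs(r) >= 1.0 - 1e-15:
        p = min(p, 1e-12)  # perfect correlation: below representable threshold
    return CorrelationResult(
        r=r,
        r2=r * r,
        p_value=p,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_subjects=len(xs),
    )
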