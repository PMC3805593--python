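"""Group-level factorial statistics.

Mixed repeated-measures ANOVA (one between-subjects factor, any number
of within-subjects factors) via the classical univariate sums-of-squares
decomposition on a balanced design: each within effect and its
group interaction are tested against the corresponding
effect-by-subject(group) error term, and the between effect against the
subject(group) term.  Uncorrected degrees of freedom are reported
(no sphericity correction by default).  Post-hoc two-sample t-tests and
Benjamini-Hochberg FDR round out the toolbox.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["rm_anova", "posthoc_t", "fdr_bh", "FdrResult", "drop_incomplete_subjects"]

logger = logging.getLogger(__name__)


def drop_incomplete_subjects(table: pd.DataFrame, within: list[str],
                             subject: str = "subject",
                             dv: str = "value") -> pd.DataFrame:
    """Remove subjects missing any within-factor cell (with a warning).

    A repeated-measures ANOVA needs one value per subject per cell;
    imputation would invent data, so incomplete subjects are excluded.
    """
    levels = {w: sorted(table[w].unique()) for w in within}
    n_cells = int(np.prod([len(v) for v in levels.values()]))
    counts = table.groupby(subject, observed=True)[dv].count()
    complete = counts[counts >= n_cells].index
    dropped = sorted(set(table[subject]) - set(complete))
    if dropped:
        logger.warning("dropping %d incomplete subject(s): %s", len(dropped), dropped)
    return table[table[subject].isin(complete)]


def _design_arrays(table: pd.DataFrame, dv: str, subject: str,
                   between: str, within: list[str]):
    """Validate balance and pivot to (subjects x cells) with metadata."""
    levels = {w: sorted(table[w].unique()) for w in within}
    cells = list(product(*levels.values()))
    pivot = table.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="mean", observed=True)
    count = table.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="count", observed=True)
    if pivot.isna().any().any():
        missing = [(s, c) for s in pivot.index for c in pivot.columns
                   if pd.isna(pivot.loc[s, c])]
        raise ValueError(f"unbalanced design; missing cells: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    if (count > 1).any().any():
        logger.warning("rm_anova: duplicate records per cell averaged")
    # align column order with the cartesian cell list
    if len(within) == 1:
        pivot = pivot[[c[0] for c in cells]]
    else:
        pivot = pivot[cells]
    group_of = (table[[subject, between]].drop_duplicates()
                .set_index(subject)[between])
    if group_of.index.duplicated().any():
        raise ValueError("a subject appears in more than one group")
    groups = sorted(group_of.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    g_codes = group_of.loc[pivot.index].map({g: i for i, g in enumerate(groups)})
    return pivot.to_numpy(float), np.asarray(g_codes), levels, cells, groups


def rm_anova(table: pd.DataFrame, dv: str = "value", subject: str = "subject",
             between: str = "group", within: list[str] | None = None,
             ) -> pd.DataFrame:
    """Mixed-design ANOVA: ``between`` factor plus within-subject factors.

    Reports the between main effect, each within main effect, and each
    between-by-within interaction, in a fixed column order
    ``(effect, df1, df2, F, p)``.  Requires a complete (balanced)
    within-subject design; missing cells raise with an explicit list.
    Zero-variance error terms yield NaN F (logged), never an exception.
    """
    if not within:
        raise ValueError("at least one within factor is required")
    y, g, levels, cells, groups = _design_arrays(table, dv, subject, between, within)
    n_subj, n_cells = y.shape
    n_groups = len(groups)
    group_sizes = np.bincount(g, minlength=n_groups)
    if (group_sizes < 2).any():
        raise ValueError("need >= 2 subjects per group")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[g == gi].mean() for gi in range(n_groups)])

    rows = []

    def f_test(ss_eff, df_eff, ss_err, df_err, name):
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if not np.isfinite(ms_err) or ms_err <= 0:
            logger.warning("rm_anova: zero-variance error term for %s", name)
            rows.append((name, df_eff, df_err, np.nan, np.nan))
            return
        f = (ss_eff / df_eff) / ms_err
        p = float(sps.f.sf(f, df_eff, df_err))
        rows.append((name, df_eff, df_err, float(f), p))

    # between effect, error = subjects within groups
    ss_between = n_cells * float(
        (group_sizes * (group_means - grand) ** 2).sum())
    ss_subj = n_cells * float(
        ((subj_means - group_means[g]) ** 2).sum())
    f_test(ss_between, n_groups - 1, ss_subj, n_subj - n_groups, between.upper())

    # each within factor: collapse over the others
    cell_levels = np.array(cells, dtype=object)  # (n_cells, n_within)
    for wi, w in enumerate(within):
        lv = levels[w]
        n_lv = len(lv)
        scale = n_cells // n_lv  # observations per (subject, level) mean
        # subject x level means
        a = np.empty((n_subj, n_lv))
        for li, lev in enumerate(lv):
            mask = np.array([c == lev for c in cell_levels[:, wi]])
            a[:, li] = y[:, mask].mean(axis=1)
        lv_means = a.mean(axis=0)
        ag = np.array([a[g == gi].mean(axis=0) for gi in range(n_groups)])

        ss_w = scale * n_subj * float(((lv_means - grand) ** 2).sum())
        resid_gw = (ag - ag.mean(axis=1, keepdims=True)
                    - lv_means[None, :] + grand)
        ss_gw = scale * float((group_sizes[:, None] * resid_gw ** 2).sum())
        resid_err = (a - subj_means[:, None] - ag[g]
                     + group_means[g][:, None])
        ss_err = scale * float((resid_err ** 2).sum())
        df_w = n_lv - 1
        df_err = df_w * (n_subj - n_groups)
        f_test(ss_w, df_w, ss_err, df_err, w.upper())
        f_test(ss_gw, (n_groups - 1) * df_w, ss_err, df_err,
               f"{between.upper()} x {w.upper()}")

    return pd.DataFrame(rows, columns=["effect", "df1", "df2", "F", "p"])


def posthoc_t(table: pd.DataFrame, by: str, dv: str = "value",
              between: str = "group", equal_var: bool = True) -> pd.DataFrame:
    """Two-sample two-sided t-test per level of ``by``.

    Returns one row per key with ``(by, t, p, n1, n2)``; Welch's variant
    via ``equal_var=False``.  Degenerate (zero-variance) comparisons
    yield NaN p and a warning.
    """
    groups = sorted(table[between].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    rows = []
    for key, sub in table.groupby(by, observed=True):
        x = sub.loc[sub[between] == groups[0], dv].to_numpy(float)
        y = sub.loc[sub[between] == groups[1], dv].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"key {key!r}: need >= 2 observations per group")
        if np.var(x) == 0 and np.var(y) == 0:
            if np.mean(x) == np.mean(y):
                logger.warning("posthoc_t: degenerate zero-variance key %r", key)
                rows.append((key, np.nan, np.nan, len(x), len(y)))
                continue
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        rows.append((key, float(res.statistic), float(res.pvalue), len(x), len(y)))
    return pd.DataFrame(rows, columns=[by, "t", "p", "n1", "n2"])


@dataclass
class FdrResult:
    """Benjamini-Hochberg step-up outcome at level ``q``."""

    pvalues: np.ndarray
    q: float
    reject: np.ndarray
    cutoff: float  # largest p-value rejected; 0.0 when none


def fdr_bh(pvalues, q: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up procedure.

    Sort the m p-values ascending, find the largest i with
    ``p_(i) <= (i / m) q``, and reject every p-value at or below it.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(sorted_p <= thresh)[0]
    if passing.size == 0:
        return FdrResult(pvalues=p, q=q, reject=np.zeros(m, dtype=bool), cutoff=0.0)
    cutoff = float(sorted_p[passing[-1]])
    return FdrResult(pvalues=p, q=q, reject=p <= cutoff, cutoff=cutoff)
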