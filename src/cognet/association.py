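"""Group comparisons and metric-component correlations with FDR control.

Two families of univariate analyses surround the multivariate models:

* patient-vs-control t-tests of every global network measure (one family of
  12 = 2 networks x 3 measures x 2 components' worth of comparisons) and of
  nodal measures (corrected across nodes, per network and metric);
* Pearson correlations, in patients, of each network measure against each
  cognitive component, crossing corresponding and non-corresponding
  network-component pairs. Global correlations form one 12-test family;
  nodal correlations are corrected across nodes within each
  network x metric x component family.

All p-values are Benjamini-Hochberg adjusted within their family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def group_compare(
    metric_table: pd.DataFrame,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-tests of every measure between controls and patients.

    Expects the long-format metric table (columns subject_id, group, network,
    scope, node, metric, value) with groups 'control' and 'patient'. The t
    statistic is control minus patient, so a positive t means controls score
    higher. FDR families: all global measures together; nodal measures per
    network x metric across nodes. Measures with zero variance in both groups
    are flagged (statistic NaN) and excluded from their family.

    Parameters
    ----------
    equal_var : bool
        Pooled-variance t-test (default); False gives Welch.
    """
    rows = []
    key_cols = ["network", "scope", "node", "metric"]
    for keys, sub in metric_table.groupby(key_cols, sort=True):
        ctrl = sub.loc[sub["group"] == "control", "value"].to_numpy(float)
        pat = sub.loc[sub["group"] == "patient", "value"].to_numpy(float)
        if ctrl.size < 2 or pat.size < 2:
            raise ValueError("need at least two subjects per group")
        if ctrl.var() == 0 and pat.var() == 0:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(ctrl, pat, equal_var=equal_var)
        rows.append(dict(zip(key_cols, keys), statistic=t, p=p))
    out = pd.DataFrame(rows)
    out["family"] = np.where(
        out["scope"] == "global",
        "global",
        out["network"] + ":" + out["metric"] + ":nodes",
    )
    out["q"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        ok = out.loc[idx, "p"].notna()
        sel = idx[ok]
        if len(sel):
            out.loc[sel, "q"] = fdr_adjust(out.loc[sel, "p"].to_numpy())
    out["direction"] = np.sign(out["statistic"])
    return out


def correlate_metrics_components(
    metric_table: pd.DataFrame,
    component_scores: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate every network measure with every cognitive component.

    ``metric_table`` should contain patients only; ``component_scores`` is a
    subject-indexed frame with one column per component (e.g. 'wm', 'rsn').
    All network x component pairings are computed, including the
    non-corresponding ones. FDR families: the 12 global correlations
    together; nodal correlations across nodes per network x metric x
    component.

    Parameters
    ----------
    method : {'pearson', 'spearman'}
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    key_cols = ["network", "scope", "node", "metric"]
    for keys, sub in metric_table.groupby(key_cols, sort=True):
        sub = sub.set_index("subject_id")
        for comp in component_scores.columns:
            joined = pd.concat(
                [sub["value"], component_scores[comp]], axis=1, join="inner"
            ).dropna()
            if len(joined) < 4:
                raise ValueError("need at least 4 paired observations")
            x = joined.iloc[:, 0].to_numpy(float)
            y = joined.iloc[:, 1].to_numpy(float)
            if x.var() == 0 or y.var() == 0:
                r = p = np.nan
            else:
                r, p = corr(x, y)
            rows.append(dict(zip(key_cols, keys), component=comp, statistic=r, p=p))
    out = pd.DataFrame(rows)
    out["family"] = np.where(
        out["scope"] == "global",
        "global",
        out["network"] + ":" + out["metric"] + ":" + out["component"] + ":nodes",
    )
    out["q"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        ok = out.loc[idx, "p"].notna()
        sel = idx[ok]
        if len(sel):
            out.loc[sel, "q"] = fdr_adjust(out.loc[sel, "p"].to_numpy())
    out["direction"] = np.sign(out["statistic"])
    return out
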