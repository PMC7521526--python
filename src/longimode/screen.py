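"""Mass-univariate Pearson screening between variable blocks.

Every (x, y) variable pair is correlated over its own complete pairs
(rows where both variables are observed), producing one record with r,
the complete-pair count, a two-sided p-value from the exact t reference
t = r * sqrt(df / (1 - r^2)), and -log10 p.  Degrees of freedom are
n_pairs - 2 minus, by default, the five deconfounding parameters, a
conservative accounting for the variance already removed by the
nuisance regression.

Multiplicity is controlled two ways over each analysis set: Bonferroni
(familywise error) and Benjamini-Hochberg step-up (false discovery
rate).  The extreme-group validation split re-runs the screen within
each recruitment group, so that associations driven purely by
between-group mean differences (Simpson's paradox) become visible as
pooled-only effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import SubjectMatrix
from .registry import VariableRegistry

MIN_PAIRS = 5  # records with fewer complete pairs are flagged invalid
N_CONFOUNDS = 5

RECORD_COLUMNS = ["id_x", "id_y", "r", "n_pairs", "p", "neg_log10_p",
                  "analysis_set", "valid"]


def pairwise_pearson(X: SubjectMatrix, Y: SubjectMatrix, set_label: str,
                     df_adjust: int = N_CONFOUNDS,
                     check_provenance: bool = True) -> pd.DataFrame:
    """Pearson correlation of every column of ``X`` with every column of ``Y``.

    Complete-case per pair: each correlation uses exactly the rows where
    both variables are observed.  Pairs with fewer than ``MIN_PAIRS``
    complete pairs, or zero variance over their complete pairs, are
    emitted with ``valid=False`` (r as NaN for degenerate variance) and
    excluded from multiplicity thresholds.

    Returns a DataFrame with one row per pair (columns
    ``RECORD_COLUMNS``), enumerated x-major in registry/matrix order.
    """
    if check_provenance:
        X.require_provenance("deconfounded", "imputed")
        Y.require_provenance("deconfounded", "imputed")
    if list(X.subjects) != list(Y.subjects):
        raise ValueError("blocks must cover the same subjects")

    Mx = (~X.mask).astype(float)
    My = (~Y.mask).astype(float)
    Xv = np.where(X.mask, 0.0, X.values)
    Yv = np.where(Y.mask, 0.0, Y.values)

    # pairwise sums over complete pairs, all (p_x x p_y) at once
    n = Mx.T @ My
    sx = Xv.T @ My
    sy = Mx.T @ Yv
    sxx = (Xv**2).T @ My
    syy = Mx.T @ (Yv**2)
    sxy = Xv.T @ Yv

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        r = cov / np.sqrt(varx * vary)
    degenerate = (varx <= 1e-12 * np.maximum(sxx, 1.0)) | \
                 (vary <= 1e-12 * np.maximum(syy, 1.0))
    r = np.clip(r, -1.0, 1.0)

    df = n - 2 - df_adjust
    valid = (n >= MIN_PAIRS) & (df >= 1) & ~degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    r = np.where(degenerate, np.nan, r)
    p = np.where(valid, p, np.nan)

    px, py = len(X.variables), len(Y.variables)
    rec = pd.DataFrame({
        "id_x": np.repeat(X.variables, py),
        "id_y": np.tile(Y.variables, px),
        "r": r.ravel(),
        "n_pairs": n.astype(int).ravel(),
        "p": p.ravel(),
        "neg_log10_p": -np.log10(p.ravel()),
        "analysis_set": set_label,
        "valid": valid.ravel(),
    })
    return rec


@dataclass
class ThresholdSet:
    """Multiplicity control summary over one analysis set."""

    m_tests: int
    alpha: float
    bonferroni_p: float
    bh_p: float
    n_discoveries_fwe: int
    n_discoveries_fdr: int


def benjamini_hochberg_cutoff(p_values, alpha):
    """Largest p(i) satisfying the step-up condition p(i) <= i*alpha/m,
    or 0.0 when no discovery exists."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = len(p)
    crit = (np.arange(1, m + 1) / m) * alpha
    ok = np.flatnonzero(p <= crit)
    return float(p[ok[-1]]) if len(ok) else 0.0


def correct_multiplicity(records: pd.DataFrame, alpha: float = 0.05) -> ThresholdSet:
    """Bonferroni and Benjamini-Hochberg control over the valid records."""
    p = records.loc[records["valid"], "p"].to_numpy()
    m = len(p)
    if m < 1:
        raise ValueError("need at least one valid record")
    bonf = alpha / m
    bh = benjamini_hochberg_cutoff(p, alpha)
    return ThresholdSet(
        m_tests=m,
        alpha=alpha,
        bonferroni_p=bonf,
        bh_p=bh,
        n_discoveries_fwe=int((p <= bonf).sum()),
        n_discoveries_fdr=int((p <= bh).sum()) if bh > 0 else 0,
    )


def manhattan_export(records: pd.DataFrame, registry: VariableRegistry,
                     alpha: float = 0.05,
                     override_lines: dict = None) -> pd.DataFrame:
    """Plot-ready table for a Manhattan display of one analysis set.

    Rows are ordered by the registry's behavioural/cognitive ordering of
    ``id_y`` (the x-axis of the plot), annotated with the subdomain
    colour key of ``id_x`` and both multiplicity threshold lines.
    ``override_lines`` may supply externally chosen ``{"fwe": p, "fdr": p}``
    lines, which are surfaced in extra columns next to the computed ones.
    """
    sets = records["analysis_set"].unique()
    if len(sets) > 1:
        raise ValueError(f"records mix analysis sets: {sets}")
    out = records.copy()
    if len(out):
        order = {vid: i for i, vid in enumerate(_order_ids(registry))}
        out["_ky"] = out["id_y"].map(lambda v: order.get(v, len(order)))
        out["_kx"] = out["id_x"].map(lambda v: order.get(v, len(order)))
        out = out.sort_values(["_ky", "_kx"], kind="stable").drop(columns=["_kx", "_ky"])
        out["subdomain_x"] = [
            registry[v].subdomain if v in registry else "" for v in out["id_x"]
        ]
        out["subdomain_y"] = [
            registry[v].subdomain if v in registry else "" for v in out["id_y"]
        ]
        thr = correct_multiplicity(records, alpha)
        out["line_fwe_p"] = thr.bonferroni_p
        out["line_fdr_p"] = thr.bh_p
    else:
        out = records.copy()
        for c in ("subdomain_x", "subdomain_y", "line_fwe_p", "line_fdr_p"):
            out[c] = pd.Series(dtype=float if c.startswith("line") else str)
    if override_lines:
        for key, val in override_lines.items():
            out[f"line_{key}_override_p"] = val
    return out.reset_index(drop=True)


def _order_ids(registry):
    out = []
    for v in registry.variables:
        out.append(v.id)
    return out


def split_group_screen(X: SubjectMatrix, Y: SubjectMatrix, labels,
                       set_label: str = "longitudinal", **kwargs):
    """Within-group screens plus the pooled screen (EGD validation).

    ``labels`` assigns each subject to one of two groups.  Returns a dict
    of record tables ``{group_a, group_b, pooled}`` with identical pair
    enumeration and a comparison table of pooled vs within-group r per
    pair — the Simpson's-paradox diagnostic: a pair whose pooled |r| far
    exceeds both within-group |r| is driven by the group mean difference.
    """
    labels = np.asarray(labels)
    if len(labels) != len(X.subjects):
        raise ValueError("labels must cover all subjects")
    names = pd.unique(labels)
    if len(names) > 2:
        raise ValueError(f"expected at most two groups, got {list(names)}")
    groups = {}
    for name in names:
        sel = [s for s, l in zip(X.subjects, labels) if l == name]
        if len(sel) < 10:
            import warnings
            warnings.warn(f"group {name!r} has only {len(sel)} subjects")
        groups[name] = (X.select_subjects(sel), Y.select_subjects(sel))

    result = {"pooled": pairwise_pearson(X, Y, set_label, **kwargs)}
    for name, (Xg, Yg) in groups.items():
        result[str(name)] = pairwise_pearson(Xg, Yg, set_label, **kwargs)

    comp = result["pooled"][["id_x", "id_y"]].copy()
    comp["r_pooled"] = result["pooled"]["r"].to_numpy()
    for name in names:
        comp[f"r_{name}"] = result[str(name)]["r"].to_numpy()
    if len(names) == 2:
        within = np.fmax(np.abs(comp[f"r_{names[0]}"].to_numpy()),
                         np.abs(comp[f"r_{names[1]}"].to_numpy()))
        comp["pooled_excess"] = np.abs(comp["r_pooled"].to_numpy()) - within
    result["comparison"] = comp
    return result
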