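"""Longitudinal feature construction.

Repeated measurements are represented by their raw difference
(W63 - W57) and raw average ((W63 + W57)/2) scores.  Raw change is used
instead of residualized change because residualized change is biased
when the sample consists of pre-existing groups, and instead of
baseline as a companion regressor because raw change is negatively
correlated with baseline by construction; the average is the natural
orthogonal companion.

Behavioural variables where lower raw values mean better function
(reaction times, error counts, depression scores) are sign-inverted at
the wave level, before score construction, so that every behavioural
score is oriented "higher = better".  Brain measures are left
untouched: assigning a good/bad direction to a structural change is
not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import SubjectMatrix
from .registry import VariableRegistry


def invert_bad_direction(m: SubjectMatrix, registry: VariableRegistry) -> SubjectMatrix:
    """Negate behavioural columns whose trait polarity is lower-is-better.

    Operates on wave-level (or analysis-level) matrices; columns are
    matched to the registry by analysis id or source id.  IDP columns are
    always passed through unchanged.  The operation is an involution.
    """
    out = m.copy()
    by_source = {}
    for v in registry.variables:
        by_source.setdefault(v.source, v)
    for j, col in enumerate(out.variables):
        v = registry[col] if col in registry else by_source.get(col)
        if v is None:
            raise KeyError(f"variable {col!r} not in registry")
        if v.block != "behavioural":
            continue
        if v.trait_polarity == "lower_is_better":
            out.values[:, j] = -out.values[:, j]
    return out


def make_longitudinal(m57: SubjectMatrix, m63: SubjectMatrix,
                      registry: VariableRegistry, block: str) -> SubjectMatrix:
    """Assemble the longitudinal analysis matrix for one block.

    Output columns follow the registry: change and average scores are
    computed from the two wave matrices (masked wherever either wave is
    missing); single and cross-sectional variables pass through from the
    wave that carries them.
    """
    if list(m57.subjects) != list(m63.subjects):
        raise ValueError("wave matrices must cover the same subjects")
    n = len(m57.subjects)
    ids = registry.ids(block=block)
    vals = np.zeros((n, len(ids)))
    mask = np.zeros((n, len(ids)), dtype=bool)
    for j, vid in enumerate(ids):
        v = registry[vid]
        if v.score_kind in ("change", "average"):
            x57, k57 = m57.column(v.source)
            x63, k63 = m63.column(v.source)
            mask[:, j] = k57 | k63
            if v.score_kind == "change":
                vals[:, j] = np.where(mask[:, j], 0.0, x63 - x57)
            else:
                vals[:, j] = np.where(mask[:, j], 0.0, (x63 + x57) / 2.0)
        else:
            if "W63" in v.waves_present:
                src = m63
            elif "W57" in v.waves_present:
                src = m57
            else:
                raise ValueError(f"{vid}: no wave carries this variable")
            x, k = src.column(v.source)
            vals[:, j], mask[:, j] = x, k
    return SubjectMatrix(list(m57.subjects), ids, vals, mask, "raw")


@dataclass
class BlandAltmanSummary:
    """Agreement between two paired measurements.

    ``bias`` is the mean difference, the limits of agreement are
    ``bias +/- 1.96 * sd(diff)`` (sd with n-1 denominator), and
    ``structure_r`` is the correlation between per-subject means and
    differences — nonzero structure indicates that the size of change
    depends on the underlying level.
    """

    bias: float
    loa_low: float
    loa_high: float
    structure_r: float
    degenerate: bool
    means: np.ndarray
    diffs: np.ndarray
    n: int


def bland_altman(x_a, x_b, mask_a=None, mask_b=None) -> BlandAltmanSummary:
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    keep = np.ones(len(x_a), dtype=bool)
    if mask_a is not None:
        keep &= ~np.asarray(mask_a, dtype=bool)
    if mask_b is not None:
        keep &= ~np.asarray(mask_b, dtype=bool)
    keep &= ~np.isnan(x_a) & ~np.isnan(x_b)
    a, b = x_a[keep], x_b[keep]
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    d = b - a
    means = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0 or means.std(ddof=1) == 0
    if degenerate:
        structure_r = 0.0
    else:
        structure_r = float(np.corrcoef(means, d)[0, 1])
    return BlandAltmanSummary(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        structure_r=structure_r,
        degenerate=degenerate,
        means=means,
        diffs=d,
        n=n,
    )
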