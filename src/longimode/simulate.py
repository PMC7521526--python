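"""Synthetic two-wave cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so
every downstream stage is testable without access to cohort data:

* a recruitment pool (default 1,985 subjects) with youth and
  late-midlife IQ scores tied together by a latent general ability;
* extreme-group-design (EGD) subsampling on the standardized residual
  of late IQ regressed on youth IQ (default 66 "improvers" + 57
  "decliners" = 123 subjects, trimming |z| > 3);
* two late-midlife measurement waves of every imaging-derived
  phenotype (IDP) and behavioural variable, with one planted
  cross-block covariation mode: latent factors U0 and
  V0 = rho_star*U0 + sqrt(1-rho_star^2)*eps load on the behavioural
  and IDP change components respectively;
* linear confound contamination from five nuisance variables;
* missing-completely-at-random cell masking with a re-draw rule that
  never empties a row or column.

All randomness flows from a single seed through named per-stage
substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import ConfoundSet, SubjectMatrix
from .registry import VariableRegistry, build_default_registry

_STAGE_KEYS = {"iq": 1, "mode": 2, "levels": 3, "waves": 4,
               "confounds": 5, "missing": 6}


def _stage_rng(seed, stage):
    return np.random.default_rng([int(seed) % (2**31), _STAGE_KEYS[stage]])


@dataclass
class CohortConfig:
    """All generator parameters.

    ``loadings_idp`` / ``loadings_beh`` may be scalars (broadcast to every
    variable of the block) or per-variable arrays in [0, 1].
    """

    n_pool: int = 1985
    n_select: int = 123
    group_sizes: tuple = (66, 57)
    residual_z_cut: float = 3.0
    rho_star: float = 0.92
    loadings_idp: object = 0.9
    loadings_beh: object = 0.9
    confound_effect: float = 0.3
    noise_sd: float = 0.3
    missing_rate: float = 0.05
    seed: int = 0
    profile: str = "full"
    #: number of planted cross-block modes (rank of the shared structure)
    n_modes: int = 1
    #: correlate confounds with the planted mode (leakage study switch)
    confound_mode_corr: float = 0.0

    def __post_init__(self):
        if not (0 <= self.rho_star < 1):
            raise ValueError("rho_star must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(self.group_sizes) != self.n_select:
            raise ValueError(
                f"group_sizes {self.group_sizes} must sum to n_select={self.n_select}"
            )
        if self.n_select > self.n_pool:
            raise ValueError("n_select exceeds n_pool")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")


@dataclass
class GeneratedCohort:
    config: CohortConfig
    registry: VariableRegistry
    pool_subjects: list
    iq: dict                     # iq_11/iq_20/iq_57/iq_63 over the pool
    selected_subjects: list
    group_labels: np.ndarray     # "improver"/"decliner" per selected subject
    residual_z: np.ndarray       # standardized residual per pool subject
    idp_w57: SubjectMatrix
    idp_w63: SubjectMatrix
    beh_w57: SubjectMatrix
    beh_w63: SubjectMatrix
    confounds: ConfoundSet
    truth: dict                  # U0, V0 (selected subjects x n_modes), loadings


def _as_loadings(value, n, name):
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def simulate_pool(config: CohortConfig) -> GeneratedCohort:
    """Draw the full recruitment pool with both waves of every variable.

    IQ model (standardized scale): a latent general ability g gives the
    youth scores; the late score regresses on the youth score with
    population slope 0.71 (R^2 ~ 50%) plus an independent change factor,
    mirroring the calibration the EGD selection is built on.
    """
    cfg = config
    registry = build_default_registry(cfg.profile)
    n = cfg.n_pool
    subjects = [f"S{i + 1:05d}" for i in range(n)]

    rng = _stage_rng(cfg.seed, "iq")
    g = rng.standard_normal(n)
    iq_11 = 0.80 * g + np.sqrt(1 - 0.80**2) * rng.standard_normal(n)
    iq_20 = 0.85 * g + np.sqrt(1 - 0.85**2) * rng.standard_normal(n)
    d = rng.standard_normal(n)  # latent change in ability, youth -> late midlife
    iq_57 = 0.71 * iq_20 + 0.50 * d + np.sqrt(1 - 0.71**2 - 0.50**2) * rng.standard_normal(n)
    iq_63 = 0.90 * iq_57 + 0.30 * d + np.sqrt(1 - 0.90**2 - 0.30**2) * rng.standard_normal(n)
    iq = {"iq_11": iq_11, "iq_20": iq_20, "iq_57": iq_57, "iq_63": iq_63}

    # planted cross-block mode(s): corr(U0_k, V0_k) = rho_star
    rng = _stage_rng(cfg.seed, "mode")
    k = cfg.n_modes
    U0 = rng.standard_normal((n, k))
    V0 = cfg.rho_star * U0 + np.sqrt(1 - cfg.rho_star**2) * rng.standard_normal((n, k))

    idp_sources = registry.source_ids("IDP", "W63")        # includes PBVC
    beh_sources_57 = registry.source_ids("behavioural", "W57")
    beh_sources_63 = registry.source_ids("behavioural", "W63")
    beh_all = list(dict.fromkeys(beh_sources_57 + beh_sources_63))

    load_idp = _as_loadings(cfg.loadings_idp, len(idp_sources), "loadings_idp")
    load_beh = _as_loadings(cfg.loadings_beh, len(beh_all), "loadings_beh")

    # stable per-variable levels: cognitive levels share g, others are
    # independent traits
    rng = _stage_rng(cfg.seed, "levels")
    lev_idp = {s: rng.standard_normal(n) for s in idp_sources}
    lev_beh = {}
    for s in beh_all:
        if s.startswith("cog_test"):
            lev_beh[s] = 0.6 * g + 0.8 * rng.standard_normal(n)
        else:
            lev_beh[s] = rng.standard_normal(n)

    # confounds and their per-variable contamination weights
    rng = _stage_rng(cfg.seed, "confounds")
    C = rng.standard_normal((n, 5))
    if cfg.confound_mode_corr:
        C[:, 0] = cfg.confound_mode_corr * U0[:, 0] + \
            np.sqrt(1 - cfg.confound_mode_corr**2) * C[:, 0]
    w_conf = {s: rng.standard_normal(5) / np.sqrt(5)
              for s in idp_sources + beh_all}
    contamination = {s: cfg.confound_effect * (C @ w_conf[s]) for s in w_conf}

    rng = _stage_rng(cfg.seed, "waves")

    def waves_for(source, level, loading, factor):
        e57 = cfg.noise_sd * rng.standard_normal(n)
        e63 = cfg.noise_sd * rng.standard_normal(n)
        w57 = level + contamination[source] + e57
        w63 = level + loading * factor + contamination[source] + e63
        return w57, w63

    mode_w = rng.standard_normal(k) if k > 1 else np.ones(1)
    mode_w /= np.linalg.norm(mode_w)
    u_factor = U0 @ mode_w
    v_factor = V0 @ mode_w

    idp57, idp63 = {}, {}
    for s, lo in zip(idp_sources, load_idp):
        if s.startswith("idp_siena_pbvc"):
            idp63[s] = lo * v_factor + contamination[s] + cfg.noise_sd * rng.standard_normal(n)
        else:
            idp57[s], idp63[s] = waves_for(s, lev_idp[s], lo, v_factor)

    beh57, beh63 = {}, {}
    for s, lo in zip(beh_all, load_beh):
        v = registry[s] if s in registry else None
        both = s in beh_sources_57 and s in beh_sources_63
        if s in iq:
            continue  # IQ handled from the pool model below
        if both:
            beh57[s], beh63[s] = waves_for(s, lev_beh[s], lo, u_factor)
        else:
            val = lev_beh[s] + lo * u_factor + contamination[s] \
                + cfg.noise_sd * rng.standard_normal(n)
            if s in beh_sources_57:
                beh57[s] = val
            else:
                beh63[s] = val
    for name in ("iq_11", "iq_20", "iq_57"):
        if name in beh_sources_57:
            beh57[name] = iq[name]
    if "iq_63" in beh_sources_63:
        beh63["iq_63"] = iq["iq_63"]

    # trait polarity: lower_is_better variables are stored negatively
    # oriented, as raw instruments would report them
    for d_ in (beh57, beh63):
        for s in d_:
            pol = _source_polarity(registry, s)
            if pol == "lower_is_better":
                d_[s] = -d_[s]

    def to_matrix(data, order):
        cols = [c for c in order if c in data]
        vals = np.column_stack([data[c] for c in cols])
        return SubjectMatrix(list(subjects), cols, vals)

    cohort = GeneratedCohort(
        config=cfg,
        registry=registry,
        pool_subjects=subjects,
        iq=iq,
        selected_subjects=[],
        group_labels=np.array([]),
        residual_z=np.array([]),
        idp_w57=to_matrix(idp57, registry.source_ids("IDP", "W57")),
        idp_w63=to_matrix(idp63, idp_sources),
        beh_w57=to_matrix(beh57, beh_sources_57),
        beh_w63=to_matrix(beh63, beh_sources_63),
        confounds=ConfoundSet(list(subjects), C),
        truth={"U0": U0, "V0": V0, "mode_weights": mode_w,
               "loadings_idp": load_idp, "loadings_beh": load_beh},
    )
    return cohort


def _source_polarity(registry, source):
    for v in registry.variables:
        if v.source == source:
            return v.trait_polarity
    return "neutral"


def egd_select(iq20, iq57, config: CohortConfig):
    """Extreme-group selection on change in IQ.

    Fits the least-squares regression of late IQ on youth IQ, standardizes
    the residuals by their root-mean-square (n-2 denominator), drops
    subjects beyond ``residual_z_cut``, and labels the largest residuals
    "improver" and the smallest "decliner" (ties broken by subject index).

    Returns
    -------
    labels : array of "improver" / "decliner" / "" per pool subject
    z : standardized residual per pool subject
    """
    iq20 = np.asarray(iq20, dtype=float)
    iq57 = np.asarray(iq57, dtype=float)
    n = len(iq20)
    if n < 10 or len(iq57) != n:
        raise ValueError("need paired vectors of length >= 10")
    if np.var(iq20) == 0:
        raise ValueError("zero variance in youth IQ")
    slope, intercept = np.polyfit(iq20, iq57, 1)
    resid = iq57 - (slope * iq20 + intercept)
    dof = max(n - 2, 1)
    s = np.sqrt((resid**2).sum() / dof)
    # exact fit: residuals are numerical noise, everyone is a tie
    tol = 1e-10 * max(1.0, float(np.std(iq57)))
    z = resid / s if s > tol else np.zeros(n)

    eligible = np.flatnonzero(np.abs(z) <= config.residual_z_cut)
    n_imp, n_dec = config.group_sizes
    if len(eligible) < n_imp + n_dec:
        raise ValueError(
            f"only {len(eligible)} eligible subjects for "
            f"{n_imp + n_dec} requested"
        )
    # stable sort => ties broken by subject index
    order = eligible[np.argsort(z[eligible], kind="stable")]
    labels = np.array([""] * n, dtype=object)
    labels[order[-n_imp:]] = "improver"
    labels[order[:n_dec]] = "decliner"
    return labels, z


def apply_missingness(m: SubjectMatrix, rate: float, seed: int) -> SubjectMatrix:
    """Mask cells independently with probability ``rate`` (MCAR).

    A re-draw rule unmasks cells as needed so that every column keeps at
    least two observed values and every row at least one.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate > 0.95:
        raise ValueError("rate too high for the re-draw rule to terminate")
    out = m.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng([int(seed) % (2**31), _STAGE_KEYS["missing"]])
    new = rng.random(out.values.shape) < rate
    mask = out.mask | new
    # column rule: keep >= 2 observed per column
    for j in range(mask.shape[1]):
        short = 2 - int((~mask[:, j]).sum())
        if short > 0:
            hidden = np.flatnonzero(mask[:, j] & ~m.mask[:, j])
            keep = rng.choice(hidden, size=short, replace=False)
            mask[keep, j] = False
    # row rule: keep >= 1 observed per row
    for i in range(mask.shape[0]):
        if mask[i].all():
            hidden = np.flatnonzero(~m.mask[i])
            mask[i, rng.choice(hidden)] = False
    out.mask = mask
    out.values = np.where(mask, 0.0, out.values)
    return out


def generate_cohort(config: CohortConfig) -> GeneratedCohort:
    """Pool simulation + EGD selection + MCAR missingness, in one call."""
    cohort = simulate_pool(config)
    labels, z = egd_select(cohort.iq["iq_20"], cohort.iq["iq_57"], config)
    sel = np.flatnonzero(labels != "")
    cohort.residual_z = z
    cohort.group_labels = labels[sel]
    cohort.selected_subjects = [cohort.pool_subjects[i] for i in sel]

    for attr in ("idp_w57", "idp_w63", "beh_w57", "beh_w63"):
        m = getattr(cohort, attr).select_subjects(cohort.selected_subjects)
        m = apply_missingness(m, config.missing_rate,
                              config.seed + _STAGE_KEYS["missing"] * 10007
                              + sum(map(ord, attr)))
        setattr(cohort, attr, m)
    cohort.confounds = cohort.confounds.select_subjects(cohort.selected_subjects)
    cohort.truth = {**cohort.truth,
                    "U0": cohort.truth["U0"][sel],
                    "V0": cohort.truth["V0"][sel]}
    return cohort
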