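"""End-to-end orchestration: simulate -> scores -> preprocess -> screen -> cca.

Stage outputs are plain tab-separated files on disk rather than an
in-memory pipeline, so any stage can be rerun or replaced (the
univariate and multivariate branches share the conditioning stages but
are otherwise independent).  A run manifest records the resolved
configuration, a config hash, per-stage seeds and wall-clock times;
re-running with the same manifest reproduces every numeric output
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import preprocess, scores, screen
from .cca import (cca as run_cca, debias_canonical_correlation,
                  orient_modes, pca_reduce, permutation_inference,
                  structure_correlations, subdomain_importance)
from .matrix import (ConfoundSet, SubjectMatrix, load_confounds, load_dataset,
                     write_confounds, write_dataset)
from .registry import VariableRegistry, build_default_registry
from .simulate import CohortConfig, generate_cohort


@dataclass
class RunConfig:
    """Run configuration: cohort generation plus analysis parameters."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_components: int = 30
    n_perm: int = 10000
    alpha: float = 0.05
    impute_lambda: object = "auto"
    impute_tol: float = 1e-6
    impute_max_iter: int = 500
    df_adjust: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        if "group_sizes" in cohort_raw:
            cohort_raw["group_sizes"] = tuple(cohort_raw["group_sizes"])
        known = {f for f in cls.__dataclass_fields__ if f != "cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        try:
            cohort = CohortConfig(**cohort_raw)
        except TypeError as err:
            raise ValueError(f"cohort config: {err}") from None
        cfg = cls(cohort=cohort, **raw)
        cfg.cohort.seed = cfg.cohort.seed or cfg.seed
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cohort"]["group_sizes"] = list(d["cohort"]["group_sizes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def toy(cls, seed=0) -> "RunConfig":
        """Small end-to-end profile: 60 subjects, 40 IDPs, 20 behavioural
        variables, 5 components, 999 permutations."""
        cohort = CohortConfig(n_pool=400, n_select=60, group_sizes=(32, 28),
                              profile="toy", seed=seed)
        return cls(cohort=cohort, n_components=5, n_perm=999, seed=seed)


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)   # name -> {seconds, outputs, seed}

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages},
                      fh, indent=2)


def _hash_config(cfg: RunConfig) -> str:
    d = asdict(cfg)
    d["cohort"]["group_sizes"] = list(d["cohort"]["group_sizes"])
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg.cohort)
    reg = cohort.registry
    reg.write_tsv(outdir / "registry.tsv")
    for name in ("idp_w57", "idp_w63", "beh_w57", "beh_w63"):
        write_dataset(getattr(cohort, name), outdir / f"{name}.tsv")
    write_confounds(cohort.confounds, outdir / "confounds.tsv")
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("subject\tgroup\tresidual_z\n")
        zsel = {s: cohort.residual_z[i] for i, s in enumerate(cohort.pool_subjects)}
        for s, g in zip(cohort.selected_subjects, cohort.group_labels):
            fh.write(f"{s}\t{g}\t{zsel[s]!r}\n")
    truth = cohort.truth
    with open(outdir / "truth.tsv", "w") as fh:
        k = truth["U0"].shape[1]
        head = [f"U0_{i+1}" for i in range(k)] + [f"V0_{i+1}" for i in range(k)]
        fh.write("subject\t" + "\t".join(head) + "\n")
        for i, s in enumerate(cohort.selected_subjects):
            row = list(truth["U0"][i]) + list(truth["V0"][i])
            fh.write(s + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
    cfg.to_yaml(outdir / "config_resolved.yaml")
    return {"outputs": sorted(p.name for p in outdir.iterdir()),
            "seed": cfg.cohort.seed}


def stage_scores(indir, outdir) -> dict:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = VariableRegistry.read_tsv(indir / "registry.tsv")
    mats = {n: load_dataset(indir / f"{n}.tsv", reg) for n in
            ("idp_w57", "idp_w63", "beh_w57", "beh_w63")}
    beh57 = scores.invert_bad_direction(mats["beh_w57"], reg)
    beh63 = scores.invert_bad_direction(mats["beh_w63"], reg)
    idp_long = scores.make_longitudinal(mats["idp_w57"], mats["idp_w63"], reg, "IDP")
    beh_long = scores.make_longitudinal(beh57, beh63, reg, "behavioural")
    write_dataset(idp_long, outdir / "idp_long.tsv")
    write_dataset(beh_long, outdir / "beh_long.tsv")
    # Bland-Altman agreement for the late-midlife IQ pair when present
    if "iq_57" in beh_long.variables and "iq_63" in beh_long.variables:
        x57, k57 = beh_long.column("iq_57")
        x63, k63 = beh_long.column("iq_63")
        ba = scores.bland_altman(x57, x63, k57, k63)
        with open(outdir / "bland_altman_iq.tsv", "w") as fh:
            fh.write("mean\tdiff\tbias\tloa_low\tloa_high\tstructure_r\n")
            for mth, dfi in zip(ba.means, ba.diffs):
                fh.write(f"{mth!r}\t{dfi!r}\t{ba.bias!r}\t{ba.loa_low!r}"
                         f"\t{ba.loa_high!r}\t{ba.structure_r!r}\n")
    return {"outputs": sorted(p.name for p in outdir.iterdir())}


def stage_preprocess(sim_dir, scores_dir, outdir, cfg: RunConfig) -> dict:
    sim_dir, scores_dir, outdir = Path(sim_dir), Path(scores_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = VariableRegistry.read_tsv(sim_dir / "registry.tsv")
    conf = preprocess.normalize_confounds(load_confounds(sim_dir / "confounds.tsv"))
    report = []
    for name in ("idp_long", "beh_long"):
        m = load_dataset(scores_dir / f"{name}.tsv", reg, provenance="raw")
        norm = preprocess.quantile_normalize(m)
        dec, model = preprocess.regress_out(norm, conf)
        write_dataset(dec, outdir / f"{name}_deconfounded.tsv")
        imp, state = preprocess.soft_impute(
            dec, lam=cfg.impute_lambda, tol=cfg.impute_tol,
            max_iter=cfg.impute_max_iter, rank_target=cfg.n_components)
        write_dataset(imp, outdir / f"{name}_imputed.tsv")
        report.append({
            "block": name,
            "n_variables": len(dec.variables),
            "dropped_constant": sorted(set(m.variables) - set(norm.variables)),
            "flagged_deconfound": model.flagged,
            "impute_lambda": state.lambda_,
            "impute_iterations": state.n_iter,
            "impute_converged": state.converged,
        })
    with open(outdir / "preprocess_report.jsonl", "w") as fh:
        for rec in report:
            fh.write(json.dumps(rec) + "\n")
    return {"outputs": sorted(p.name for p in outdir.iterdir())}


def stage_screen(sim_dir, pre_dir, outdir, cfg: RunConfig) -> dict:
    sim_dir, pre_dir, outdir = Path(sim_dir), Path(pre_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = VariableRegistry.read_tsv(sim_dir / "registry.tsv")
    X = load_dataset(pre_dir / "idp_long_deconfounded.tsv", reg,
                     provenance="deconfounded")
    Y = load_dataset(pre_dir / "beh_long_deconfounded.tsv", reg,
                     provenance="deconfounded")
    rec = screen.pairwise_pearson(X, Y, "longitudinal", df_adjust=cfg.df_adjust)
    rec.to_csv(outdir / "records_longitudinal.tsv", sep="\t", index=False)
    thr = screen.correct_multiplicity(rec, cfg.alpha)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump(asdict(thr), fh, indent=2)
    man = screen.manhattan_export(rec, reg, cfg.alpha)
    man.to_csv(outdir / "manhattan_longitudinal.tsv", sep="\t", index=False)

    import pandas as pd
    groups = pd.read_csv(sim_dir / "groups.tsv", sep="\t", index_col=0)
    labels = groups.loc[[str(s) for s in X.subjects], "group"].to_numpy()
    split = screen.split_group_screen(X, Y, labels, "longitudinal",
                                      df_adjust=cfg.df_adjust)
    split["comparison"].to_csv(outdir / "egd_comparison.tsv", sep="\t", index=False)
    return {"outputs": sorted(p.name for p in outdir.iterdir()),
            "n_records": len(rec)}


def stage_cca(sim_dir, pre_dir, outdir, cfg: RunConfig) -> dict:
    sim_dir, pre_dir, outdir = Path(sim_dir), Path(pre_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reg = VariableRegistry.read_tsv(sim_dir / "registry.tsv")
    Xi = load_dataset(pre_dir / "idp_long_imputed.tsv", reg, provenance="imputed")
    Yi = load_dataset(pre_dir / "beh_long_imputed.tsv", reg, provenance="imputed")
    Yd = load_dataset(pre_dir / "beh_long_deconfounded.tsv", reg,
                      provenance="deconfounded")
    px = pca_reduce(Xi, cfg.n_components)
    py = pca_reduce(Yi, cfg.n_components)
    result = orient_modes(run_cca(px.scores, py.scores), Yd)
    conf = preprocess.normalize_confounds(load_confounds(sim_dir / "confounds.tsv"))
    inference = permutation_inference(px.scores, py.scores,
                                      n_perm=cfg.n_perm, seed=cfg.seed,
                                      confounds=conf.values)

    import pandas as pd
    modes = pd.DataFrame({
        "mode": np.arange(1, result.n_modes + 1),
        "r": result.correlations,
        "p_fwe": inference.p_fwe,
        "r_debiased": [debias_canonical_correlation(
            r, len(Xi.subjects), px.k, py.k) for r in result.correlations],
    })
    modes.to_csv(outdir / "modes.tsv", sep="\t", index=False)
    pd.DataFrame({"null_max": inference.null_max}).to_csv(
        outdir / "null_max.tsv", sep="\t", index=False)

    groups = pd.read_csv(sim_dir / "groups.tsv", sep="\t", index_col=0)
    variates = pd.DataFrame(
        {"subject": Xi.subjects,
         "group": groups.loc[[str(s) for s in Xi.subjects], "group"].to_numpy()})
    for i in range(min(3, result.n_modes)):
        variates[f"U_{i+1}"] = result.U[:, i]
        variates[f"V_{i+1}"] = result.V[:, i]
    variates.to_csv(outdir / "variates.tsv", sep="\t", index=False)

    Xd = load_dataset(pre_dir / "idp_long_deconfounded.tsv", reg,
                      provenance="deconfounded")
    sc_idp = structure_correlations(result, 0, Xd, reg, "IDP")
    sc_beh = structure_correlations(result, 0, Yd, reg, "behavioural")
    full = pd.concat([sc_idp.table, sc_beh.table], ignore_index=True)
    full.to_csv(outdir / "structure_correlations.tsv", sep="\t", index=False)
    full[full["reported"]].to_csv(outdir / "structure_correlations_reported.tsv",
                                  sep="\t", index=False)
    imp = pd.concat([subdomain_importance(sc_idp, reg),
                     subdomain_importance(sc_beh, reg)], ignore_index=True)
    imp.to_csv(outdir / "subdomain_importance.tsv", sep="\t", index=False)
    with open(outdir / "cca_config.json", "w") as fh:
        json.dump({"n_components": [int(px.k), int(py.k)],
                   "cumulative_variance": [float(px.cumulative_variance[-1]),
                                           float(py.cumulative_variance[-1])],
                   "n_perm": cfg.n_perm, "seed": cfg.seed}, fh, indent=2)
    return {"outputs": sorted(p.name for p in outdir.iterdir()),
            "mode1_r": float(result.correlations[0]),
            "mode1_p_fwe": float(inference.p_fwe[0])}


def analyze_cohort(cohort, cfg: RunConfig = None, n_perm: int = None,
                   seed: int = None) -> dict:
    """In-memory analysis of a generated cohort (no file round-trips).

    Runs scores -> normalize -> deconfound -> impute -> PCA -> CCA and,
    when ``n_perm`` is given, the max-statistic permutation test.
    Returns a dict with the conditioned matrices, PCA reductions, the
    :class:`~longimode.cca.CCAResult`, the debiased mode-1 strength and
    (optionally) the :class:`~longimode.cca.PermutationInference`.

    Intended for simulation studies and examples; the file-based stages
    remain the canonical pipeline.
    """
    cfg = cfg or RunConfig()
    reg = cohort.registry
    beh57 = scores.invert_bad_direction(cohort.beh_w57, reg)
    beh63 = scores.invert_bad_direction(cohort.beh_w63, reg)
    idp_long = scores.make_longitudinal(cohort.idp_w57, cohort.idp_w63, reg, "IDP")
    beh_long = scores.make_longitudinal(beh57, beh63, reg, "behavioural")
    conf = preprocess.normalize_confounds(cohort.confounds)
    out = {}
    for key, m in (("idp", idp_long), ("beh", beh_long)):
        norm = preprocess.quantile_normalize(m)
        dec, _ = preprocess.regress_out(norm, conf)
        imp, state = preprocess.soft_impute(
            dec, lam=cfg.impute_lambda, tol=cfg.impute_tol,
            max_iter=cfg.impute_max_iter, rank_target=cfg.n_components)
        out[f"{key}_deconfounded"] = dec
        out[f"{key}_imputed"] = imp
        out[f"{key}_impute_state"] = state
    px = pca_reduce(out["idp_imputed"], cfg.n_components)
    py = pca_reduce(out["beh_imputed"], cfg.n_components)
    result = orient_modes(run_cca(px.scores, py.scores), out["beh_deconfounded"])
    out.update(pca_idp=px, pca_beh=py, cca=result)
    n = len(cohort.selected_subjects) or cohort.idp_w63.shape[0]
    out["mode1_r"] = float(result.correlations[0])
    out["mode1_r_debiased"] = debias_canonical_correlation(
        result.correlations[0], n, px.k, py.k)
    if n_perm:
        out["inference"] = permutation_inference(
            px.scores, py.scores, n_perm=n_perm,
            seed=cfg.seed if seed is None else seed,
            confounds=conf.values)
    return out


def run_all(cfg: RunConfig, outdir) -> RunManifest:
    """Execute all stages in order under ``outdir``; any failure halts
    with the failing stage named."""
    outdir = Path(outdir)
    manifest = RunManifest(_hash_config(cfg))
    plan = [
        ("simulate", lambda: stage_simulate(cfg, outdir / "simulate")),
        ("scores", lambda: stage_scores(outdir / "simulate", outdir / "scores")),
        ("preprocess", lambda: stage_preprocess(outdir / "simulate",
                                                outdir / "scores",
                                                outdir / "preprocess", cfg)),
        ("screen", lambda: stage_screen(outdir / "simulate",
                                        outdir / "preprocess",
                                        outdir / "screen", cfg)),
        ("cca", lambda: stage_cca(outdir / "simulate", outdir / "preprocess",
                                  outdir / "cca", cfg)),
    ]
    for name, fn in plan:
        t0 = time.perf_counter()
        try:
            info = fn()
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest.stages[name] = info
    manifest.write(outdir / "manifest.json")
    return manifest
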