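"""Pipeline orchestration: simulate -> qc -> pcovr -> interpret -> sgxe.

Each stage reads the previous stage's on-disk artifacts, writes its own,
and records input/output hashes in a run manifest so reruns with the
same config and seed are reproducible and any stage can be resumed.
A single root seed fans out to per-stage seeds through a counter-based
scheme (SeedSequence spawn keys), so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .growth import fit_lgcm_sgxe, simple_slopes
from .interpret import (
    classify_loadings,
    component_betas,
    gene_summary,
    ld_mirror_diagnostic,
    stratification_diagnostic,
)
from .pcovr import alpha_sweep, coarse_alpha_grid, fine_alpha_grid, fit_pcovr, select_alpha
from .rotation import rotate_quartimin
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["run_pipeline", "study_scale_preset", "RunManifest", "STAGES"]

STAGES = ("simulate", "qc", "pcovr", "interpret", "sgxe")


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict
    version: str
    hashes: dict = dataclasses.field(default_factory=dict)
    timestamps: dict = dataclasses.field(default_factory=dict)
    warnings: list = dataclasses.field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(root_seed: int) -> dict:
    # counter-based fan-out; each stage gets an independent 31-bit seed
    ss = np.random.SeedSequence(int(root_seed) & 0x7FFFFFFF)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for stage, child in zip(STAGES, children)
    }


def study_scale_preset() -> dict:
    """Preset config at the target study scale: ~1000 subjects, 223 SNPs in
    14 gene blocks, 3 waves x 3 informants, R = 5 components, two-stage
    alpha grid (0-1 by 0.10, then 0.70-1.00 by 0.01)."""
    sim = SimulationConfig(
        effect_intercept_g=0.25,
        effect_intercept_e=0.15,
        effect_intercept_gxe=0.10,
        effect_slope_g=-0.05,
        effect_slope_gxe=-0.04,
        n_subpops=2,
        fst=0.01,
    )
    return {
        "stages": list(STAGES),
        "simulate": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(sim).items()
            if k not in ("causal_weights", "seed")
        },
        "qc": dataclasses.asdict(qc_mod.QcThresholds()),
        "pcovr": {
            "n_components": 5,
            "alpha": "auto",
            "coarse_grid": [float(a) for a in coarse_alpha_grid()],
            "fine_grid": {"lo": 0.70, "hi": 1.00, "step": 0.01},
            "tau": 0.10,
        },
        "interpret": {"loading_threshold": 0.15, "n_permutations": 199},
        "sgxe": {"focal": "C1", "time_codes": [0, 1, 2]},
    }


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Execute the configured stages in order, writing artifacts and a
    manifest under ``out_dir``.  Raises on the first failing stage, after
    saving a partial manifest."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    _check_dependencies(stages)

    from . import __version__

    manifest = RunManifest(
        config=config,
        seed=int(seed),
        stage_seeds=_stage_seeds(seed),
        version=__version__,
    )
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            runner = globals()[f"_stage_{stage}"]
            outputs = runner(config.get(stage, {}), state, out, manifest.stage_seeds[stage])
            manifest.timestamps[stage] = round(time.time() - t0, 3)
            manifest.hashes[stage] = {
                name: _hash_file(path) for name, path in outputs.items()
            }
    finally:
        manifest.save(out / "manifest.json")
    return manifest


def _check_dependencies(stages: list[str]) -> None:
    deps = {"qc": "simulate", "pcovr": "qc", "interpret": "pcovr", "sgxe": "pcovr"}
    for stage in stages:
        need = deps.get(stage)
        if need and need not in stages:
            raise ValueError(f"stage {stage!r} requires stage {need!r} which is not configured")


def _stage_simulate(cfg: dict, state: dict, out: Path, seed: int) -> dict:
    cfg = dict(cfg)
    for key in ("block_sizes",):
        if key in cfg:
            cfg[key] = list(cfg[key])
    for key in ("maf_range", "growth_means", "growth_sds", "parenting_loadings", "parenting_residual_sds"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    sim_config = SimulationConfig(**cfg, seed=seed)
    genotypes, table, truth = simulate_cohort(sim_config)
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    qc_mod.write_tsv_dosage(genotypes, d / "genotypes.tsv")
    qc_mod.write_vcf(genotypes, d / "genotypes.vcf")
    genotypes.annotation.to_csv(d / "annotation.tsv", sep="\t", index=False)
    table.to_csv(d / "cohort.tsv", sep="\t", index=False, na_rep="NA")
    truth.as_frame(genotypes.subject_ids).to_csv(d / "truth.tsv", sep="\t", index=False)
    (d / "config.yaml").write_text(yaml.safe_dump({**cfg, "seed": seed}))
    state["genotypes"] = genotypes
    state["table"] = table
    state["truth"] = truth
    return {name: d / name for name in
            ("genotypes.tsv", "genotypes.vcf", "annotation.tsv", "cohort.tsv", "truth.tsv")}


def _stage_qc(cfg: dict, state: dict, out: Path, seed: int) -> dict:
    d = out / "qc"
    d.mkdir(exist_ok=True)
    genotypes = state.get("genotypes")
    if genotypes is None:
        sim_dir = out / "simulate"
        annotation = pd.read_csv(sim_dir / "annotation.tsv", sep="\t")
        genotypes = qc_mod.read_genotypes(sim_dir / "genotypes.tsv", "tsv_dosage", annotation)
    thresholds = qc_mod.QcThresholds(**cfg) if cfg else qc_mod.QcThresholds()
    filtered, report = qc_mod.apply_qc(genotypes, thresholds)
    z, scale = qc_mod.impute_and_standardize(filtered)
    std = pd.DataFrame(z, columns=filtered.snp_ids)
    std.insert(0, "subject_id", filtered.subject_ids)
    std.to_csv(d / "standardized.tsv", sep="\t", index=False, float_format="%.10g")
    scale.to_csv(d / "scale.tsv", sep="\t", index=False)
    report.removed_snps.to_csv(d / "removed_snps.tsv", sep="\t", index=False)
    (d / "qc_report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    state["geno_std"] = z
    state["geno_filtered"] = filtered
    return {name: d / name for name in ("standardized.tsv", "scale.tsv", "qc_report.json")}


def _stage_pcovr(cfg: dict, state: dict, out: Path, seed: int) -> dict:
    d = out / "pcovr"
    d.mkdir(exist_ok=True)
    X = state["geno_std"]
    table = state["table"]
    subj = state["geno_filtered"].subject_ids
    table = table.set_index("subject_id").loc[subj].reset_index()
    y = table["y_w1"].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    X, y = X[ok], y[ok]
    state["analysis_rows"] = ok
    state["analysis_table"] = table.loc[ok].reset_index(drop=True)

    R = int(cfg.get("n_components", 5))
    coarse = alpha_sweep(X, y, R, np.asarray(cfg.get("coarse_grid", coarse_alpha_grid())))
    fg = cfg.get("fine_grid", {"lo": 0.70, "hi": 1.00, "step": 0.01})
    fine = alpha_sweep(X, y, R, fine_alpha_grid(fg["lo"], fg["hi"], fg["step"]))
    alpha_cfg = cfg.get("alpha", "auto")
    if alpha_cfg == "auto":
        alpha, trace = select_alpha(fine, tau=float(cfg.get("tau", 0.10)))
    else:
        alpha, trace = select_alpha(fine, manual=float(alpha_cfg))
    solution = fit_pcovr(X, y, n_components=R, alpha=alpha)

    pd.DataFrame(coarse.as_records()).to_csv(d / "sweep_coarse.tsv", sep="\t", index=False)
    pd.DataFrame(fine.as_records()).to_csv(d / "sweep_fine.tsv", sep="\t", index=False)
    snp_ids = state["geno_filtered"].snp_ids
    comp_cols = [f"C{r + 1}" for r in range(R)]
    pd.DataFrame(solution.weights, index=snp_ids, columns=comp_cols).to_csv(
        d / "weights.tsv", sep="\t", index_label="snp_id"
    )
    pd.DataFrame(solution.x_loadings, index=snp_ids, columns=comp_cols).to_csv(
        d / "x_loadings.tsv", sep="\t", index_label="snp_id"
    )
    (d / "selection.json").write_text(
        json.dumps(
            {
                "alpha": alpha,
                "n_components": R,
                "r2_x": solution.r2_x,
                "r2_y": solution.r2_y,
                "trace": trace,
            },
            indent=2,
        )
    )
    _plot_sweep(fine, alpha, d / "sweep.png")
    state["pcovr_solution"] = solution
    state["pcovr_y"] = y
    state["pcovr_X"] = X
    state["alpha"] = alpha
    return {name: d / name for name in
            ("sweep_coarse.tsv", "sweep_fine.tsv", "weights.tsv", "x_loadings.tsv", "selection.json")}


def _plot_sweep(sweep, alpha: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.alphas, sweep.r2_x, "o-", label="$R^2_X$ (reduction)")
    ax.plot(sweep.alphas, sweep.r2_y, "s-", label="$R^2_y$ (prediction)")
    ax.axvline(alpha, color="grey", ls="--", label=f"selected $\\alpha$ = {alpha:g}")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel("explained variance fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_interpret(cfg: dict, state: dict, out: Path, seed: int) -> dict:
    d = out / "interpret"
    d.mkdir(exist_ok=True)
    solution = state["pcovr_solution"]
    y = state["pcovr_y"]
    rotated = rotate_quartimin(solution, seed=seed)
    betas = component_betas(rotated.scores, y)
    annotation = state["geno_filtered"].annotation
    threshold = float(cfg.get("loading_threshold", 0.15))
    classes = classify_loadings(rotated.loadings, threshold=threshold)
    genes = gene_summary(rotated.loadings, annotation, threshold=threshold)
    blocks = annotation["gene"].to_numpy()
    ld = ld_mirror_diagnostic(rotated.loadings, state["pcovr_X"], blocks=blocks)
    truth = state.get("truth")
    strat = None
    if truth is not None:
        # map subpopulation labels through subject ids (QC may drop subjects)
        all_ids = state["genotypes"].subject_ids
        labels_by_id = pd.Series(truth.subpop_labels, index=all_ids)
        labels = labels_by_id.loc[state["analysis_table"]["subject_id"]].to_numpy()
        strat = stratification_diagnostic(
            rotated.scores, labels, n_permutations=int(cfg.get("n_permutations", 199)), seed=seed
        )

    comp_cols = [f"C{r + 1}" for r in range(rotated.loadings.shape[1])]
    snp_ids = state["geno_filtered"].snp_ids
    load_df = pd.DataFrame(rotated.loadings, index=snp_ids, columns=comp_cols)
    load_df.to_csv(d / "rotated_loadings.tsv", sep="\t", index_label="snp_id")
    pd.DataFrame(classes, index=snp_ids, columns=comp_cols).to_csv(
        d / "loading_classes.tsv", sep="\t", index_label="snp_id"
    )
    betas.to_csv(d / "component_betas.tsv", sep="\t", index=False)
    genes.to_csv(d / "gene_summary.tsv", sep="\t", index=False)
    ld.to_csv(d / "ld_diagnostic.tsv", sep="\t", index=False)
    if strat is not None:
        strat.to_csv(d / "stratification.tsv", sep="\t", index=False)
    pd.DataFrame(rotated.phi, index=comp_cols, columns=comp_cols).to_csv(
        d / "component_correlations.tsv", sep="\t", index_label="component"
    )
    state["rotated"] = rotated
    outputs = ("rotated_loadings.tsv", "loading_classes.tsv", "component_betas.tsv",
               "gene_summary.tsv", "ld_diagnostic.tsv", "component_correlations.tsv")
    return {name: d / name for name in outputs}


def _stage_sgxe(cfg: dict, state: dict, out: Path, seed: int) -> dict:
    d = out / "sgxe"
    d.mkdir(exist_ok=True)
    rotated = state["rotated"]
    table = state["analysis_table"].copy()
    comp_cols = [f"C{r + 1}" for r in range(rotated.scores.shape[1])]
    for i, c in enumerate(comp_cols):
        table[c] = rotated.scores[:, i]
    focal = cfg.get("focal", "C1")
    if focal == "auto":
        # focal = component most associated with the wave-1 outcome
        betas = component_betas(rotated.scores, state["pcovr_y"])
        focal = betas.loc[betas["beta"].abs().idxmax(), "component"]
    fit = fit_lgcm_sgxe(
        table, focal=focal, time_codes=tuple(cfg.get("time_codes", (0, 1, 2)))
    )
    fit.coefficients.to_csv(d / "coefficients.tsv", sep="\t", index=False, float_format="%.6g")
    fit.rge.to_csv(d / "rge.tsv", sep="\t", index=False)
    traj = simple_slopes(fit)
    traj.to_csv(d / "simple_slopes.tsv", sep="\t", index=False)
    _plot_slopes(traj, d / "simple_slopes.png")
    record = {
        "focal": focal,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_subjects": fit.n_subjects,
        "growth_means": fit.growth_means.tolist(),
        "growth_disturbance_cov": fit.growth_disturbance_cov.tolist(),
        "residual_variances": fit.residual_variances.tolist(),
    }
    (d / "fit.json").write_text(json.dumps(record, indent=2))
    state["sgxe_fit"] = fit
    return {name: d / name for name in ("coefficients.tsv", "rge.tsv", "simple_slopes.tsv", "fit.json")}


def _plot_slopes(traj: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (g, e), sub in traj.groupby(["component_level", "parenting_level"]):
        label = f"G {'+1' if g > 0 else '-1'} SD, E {'+1' if e > 0 else '-1'} SD"
        ax.plot(sub["wave"], sub["predicted"], "o-", label=label)
    ax.set_xlabel("wave")
    ax.set_ylabel("predicted outcome")
    ax.set_xticks(sorted(traj["wave"].unique()))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
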