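"""Interpretation and stress-testing of polygenic components.

Covers: per-component outcome regressions with normal-theory intervals,
effect-size classification of loadings (medium at |lambda| >= 0.15, small
at 0.10), per-gene loading aggregates, diagnostics flagging components
that merely mirror LD block structure or population stratification,
random-SNP-deletion robustness (Tucker congruence of refit components),
and outcome-specificity comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pcovr import PCovR, fit_pcovr
from .rotation import congruence_match, rotate_quartimin

__all__ = [
    "component_betas",
    "classify_loadings",
    "gene_summary",
    "ld_mirror_diagnostic",
    "stratification_diagnostic",
    "deletion_robustness",
    "specificity_check",
    "RobustnessResult",
]

MEDIUM_LOADING = 0.15  # |loading| at or above: "medium+" effect size
SMALL_LOADING = 0.10  # our documented small/negligible cut


def component_betas(scores: np.ndarray, y: np.ndarray, level: float = 0.95) -> pd.DataFrame:
    """Simultaneous least-squares regression of standardized y on all
    standardized component scores; normal-theory CIs.

    Returns a frame with columns component, beta, se, ci_low, ci_high, p.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    zs = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    zy = (y - y.mean()) / y.std()
    cond = np.linalg.cond(zs.T @ zs / len(zy))
    if cond > 1e8:
        raise ValueError(f"component scores are collinear (condition number {cond:.3g})")
    model = sm.OLS(zy, sm.add_constant(zs)).fit()
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for r in range(zs.shape[1]):
        b = model.params[r + 1]
        se = model.bse[r + 1]
        rows.append(
            {
                "component": f"C{r + 1}",
                "beta": b,
                "se": se,
                "ci_low": b - z * se,
                "ci_high": b + z * se,
                "p": 2 * stats.norm.sf(abs(b / se)),
            }
        )
    return pd.DataFrame(rows)


def classify_loadings(loadings: np.ndarray, threshold: float = MEDIUM_LOADING) -> np.ndarray:
    """Classify each loading: "medium+" iff |l| >= threshold, "small" iff
    0.10 <= |l| < threshold, else "negligible"."""
    L = np.abs(np.asarray(loadings, dtype=float))
    if not np.isfinite(L).all():
        raise ValueError("loadings must be finite")
    out = np.full(L.shape, "negligible", dtype=object)
    out[L >= SMALL_LOADING] = "small"
    out[L >= threshold] = "medium+"
    return out


def gene_summary(
    loadings: np.ndarray, annotation: pd.DataFrame, threshold: float = MEDIUM_LOADING
) -> pd.DataFrame:
    """Per-gene, per-component aggregates of |loading|, sorted by the gene's
    max |loading|; SNPs without a gene label fall in "unannotated"."""
    L = np.asarray(loadings, dtype=float)
    genes = annotation["gene"].fillna("unannotated").replace("", "unannotated")
    rows = []
    for r in range(L.shape[1]):
        a = np.abs(L[:, r])
        df = pd.DataFrame({"gene": genes.values, "absload": a})
        agg = df.groupby("gene")["absload"].agg(["mean", "max", "count"])
        medium = df[df["absload"] >= threshold].groupby("gene").size()
        for gene, row in agg.iterrows():
            rows.append(
                {
                    "component": f"C{r + 1}",
                    "gene": gene,
                    "mean_abs_loading": row["mean"],
                    "max_abs_loading": row["max"],
                    "n_snps": int(row["count"]),
                    "n_medium": int(medium.get(gene, 0)),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["component", "max_abs_loading"], ascending=[True, False]
    ).reset_index(drop=True)


def ld_mirror_diagnostic(
    loadings: np.ndarray,
    genotypes: np.ndarray,
    blocks: np.ndarray | None = None,
    corr_cut: float = 0.5,
    top_decile: float = 0.90,
    max_blocks: int = 2,
) -> pd.DataFrame:
    """Flag components that mainly mirror the LD structure.

    For each component, the score is the correlation between the pairwise
    loading-similarity pattern |l_j * l_k| and the pairwise genotype r^2.
    A component is flagged when its top-decile |loadings| concentrate in at
    most ``max_blocks`` annotated blocks AND the similarity/r^2 correlation
    exceeds ``corr_cut``.  Without block annotation only the correlation
    rule applies.
    """
    L = np.asarray(loadings, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    r2 = np.corrcoef(G, rowvar=False) ** 2
    iu = np.triu_indices(L.shape[0], k=1)
    r2_vec = r2[iu]
    rows = []
    for r in range(L.shape[1]):
        a = np.abs(L[:, r])
        sim = np.outer(a, a)[iu]
        if sim.std() == 0 or r2_vec.std() == 0:
            score = 0.0
        else:
            score = float(np.corrcoef(sim, r2_vec)[0, 1])
        concentrated = True
        n_blocks_top = 0
        if blocks is not None:
            cut = np.quantile(a, top_decile)
            top = a >= cut
            n_blocks_top = len(np.unique(np.asarray(blocks)[top]))
            concentrated = n_blocks_top <= max_blocks
        rows.append(
            {
                "component": f"C{r + 1}",
                "ld_score": score,
                "n_blocks_top_decile": n_blocks_top if blocks is not None else np.nan,
                "flagged": bool(score > corr_cut and concentrated),
            }
        )
    return pd.DataFrame(rows)


def stratification_diagnostic(
    scores: np.ndarray,
    subpop_labels: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-component between-subpopulation variance fraction (eta^2) with a
    permutation p-value."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(subpop_labels)
    rng = np.random.default_rng(seed)
    groups = np.unique(labels)
    rows = []
    for r in range(scores.shape[1]):
        v = scores[:, r]
        if len(groups) < 2:
            rows.append({"component": f"C{r + 1}", "eta2": 0.0, "p": 1.0})
            continue
        obs = _eta2(v, labels, groups)
        count = 0
        for _ in range(n_permutations):
            if _eta2(v, rng.permutation(labels), groups) >= obs:
                count += 1
        rows.append(
            {
                "component": f"C{r + 1}",
                "eta2": obs,
                "p": (count + 1) / (n_permutations + 1),
            }
        )
    return pd.DataFrame(rows)


def _eta2(v: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    grand = v.mean()
    ss_tot = ((v - grand) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    ss_b = sum(len(v[labels == g]) * (v[labels == g].mean() - grand) ** 2 for g in groups)
    return float(ss_b / ss_tot)


@dataclass
class RobustnessResult:
    records: pd.DataFrame  # fraction, replicate, component, congruence, delta_beta, n_deleted
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summarize(self) -> pd.DataFrame:
        if self.records.empty:
            self.summary = pd.DataFrame(
                columns=["fraction", "component", "mean_congruence",
                         "sd_congruence", "mean_abs_delta_beta"]
            )
            return self.summary
        g = self.records.groupby(["fraction", "component"])
        self.summary = g.agg(
            mean_congruence=("congruence", "mean"),
            sd_congruence=("congruence", "std"),
            mean_abs_delta_beta=("delta_beta", lambda s: s.abs().mean()),
        ).reset_index()
        return self.summary


def deletion_count(n_snps: int, fraction: float) -> int:
    """Round-to-nearest count of SNPs to delete (223 -> 2/11/22 at 1/5/10%)."""
    return int(round(fraction * n_snps))


def deletion_robustness(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_components: int,
    fractions=(0.01, 0.05, 0.10),
    replicates: int = 20,
    seed: int = 0,
) -> RobustnessResult:
    """Refit PCovR + quartimin after deleting a random fraction of SNPs and
    record per-component Tucker congruence with the full-panel components
    (greedy congruence matching) and the change in outcome beta."""
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    J = X.shape[1]
    full = rotate_quartimin(fit_pcovr(X, y, n_components=n_components, alpha=alpha))
    full_betas = component_betas(full.scores, y)["beta"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not 0 <= f < 1:
            raise ValueError(f"fraction {f} outside [0, 1)")
        k = deletion_count(J, f)
        if f > 0 and k == 0:
            warnings.warn(f"fraction {f} deletes 0 of {J} SNPs; skipped", UserWarning)
            continue
        for rep in range(replicates):
            keep = np.ones(J, dtype=bool)
            if k:
                keep[rng.choice(J, size=k, replace=False)] = False
            rot = rotate_quartimin(
                fit_pcovr(X[:, keep], y, n_components=n_components, alpha=alpha)
            )
            # match on the shared SNPs of the full-panel loadings
            perm, signs, cong = congruence_match(full.loadings[keep], rot.loadings)
            betas = component_betas(rot.scores, y)["beta"].to_numpy()
            for r in range(n_components):
                rows.append(
                    {
                        "fraction": f,
                        "replicate": rep,
                        "component": f"C{r + 1}",
                        "congruence": cong[r],
                        "delta_beta": signs[r] * betas[perm[r]] - full_betas[r],
                        "n_deleted": k,
                    }
                )
    result = RobustnessResult(records=pd.DataFrame(rows))
    result.summarize()
    return result


def specificity_check(
    scores: np.ndarray, outcomes: dict[str, np.ndarray], level: float = 0.95
) -> pd.DataFrame:
    """Component-outcome beta table across a focal outcome and alternatives."""
    frames = []
    n = np.asarray(scores).shape[0]
    for name, y in outcomes.items():
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != n:
            raise ValueError(f"outcome {name!r} length {y.shape[0]} != {n}")
        tab = component_betas(scores, y, level=level)
        tab.insert(0, "outcome", name)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out["abs_beta"] = out["beta"].abs()
    return out
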