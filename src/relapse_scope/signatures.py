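"""Weighted gene-signature scoring (LSC17) and cell-cycle phase assignment.

The LSC17 leukemic-stem-cell score is the Ng et al. (2016) 17-gene weighted
sum, applied per cell to log-normalized expression.  Cell-cycle scoring
follows the Tirosh et al. (2016) module-score scheme used by Seurat's
``CellCycleScoring``: for each phase gene set, genes are binned by average
expression and an expression-matched control set is sampled; the score is
mean(set) - mean(control) per cell, and the phase is G1 when both the S and
G2M scores are negative, otherwise the argmax phase.

The weight table and the S/G2M gene lists ship as editable data files
(``data/lsc17.tsv``, ``data/cc_s_genes.txt``, ``data/cc_g2m_genes.txt``)
reproducing the published lists.
"""

from __future__ import annotations

import warnings
from importlib import resources
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats


def _data_path(name: str):
    return resources.files("relapse_scope.data").joinpath(name)


def load_signature(path) -> dict[str, float]:
    """Read a two-column (gene, weight) TSV into an ordered mapping."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("signature file needs columns: gene, weight")
    genes = df.iloc[:, 0].astype(str)
    if genes.duplicated().any():
        raise ValueError("duplicate gene ids in signature file")
    return dict(zip(genes, df.iloc[:, 1].astype(float)))


def load_lsc17() -> dict[str, float]:
    """The bundled 17-gene LSC signature weights (Ng et al. 2016)."""
    with resources.as_file(_data_path("lsc17.tsv")) as p:
        return load_signature(p)


def load_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def load_cell_cycle_genes() -> tuple[list[str], list[str]]:
    """Bundled S-phase and G2/M gene lists (Tirosh et al. 2016)."""
    with resources.as_file(_data_path("cc_s_genes.txt")) as p:
        s = load_gene_list(p)
    with resources.as_file(_data_path("cc_g2m_genes.txt")) as p:
        g2m = load_gene_list(p)
    return s, g2m


def _matrix(adata_or_df) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(adata_or_df, ad.AnnData):
        X = np.asarray(adata_or_df.X)
        return X, list(adata_or_df.obs_names), list(adata_or_df.var_names)
    df = adata_or_df  # cells x genes DataFrame
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def score_weighted_signature(norm, signature: dict[str, float]) -> pd.Series:
    """Per-cell weighted sum of normalized expression over signature genes.

    Genes absent from the matrix are imputed as zero expression (with a
    warning) rather than renormalizing the weights, preserving cross-sample
    comparability of the score scale.
    """
    if not signature:
        raise ValueError("empty signature")
    X, cells, genes = _matrix(norm)
    col = {g: i for i, g in enumerate(genes)}
    present = [g for g in signature if g in col]
    if not present:
        raise ValueError("no signature genes present in the matrix")
    missing = [g for g in signature if g not in col]
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent, imputed as 0: {missing}",
            stacklevel=2,
        )
    weights = np.array([signature[g] for g in present])
    scores = X[:, [col[g] for g in present]] @ weights
    return pd.Series(scores, index=pd.Index(cells, name="cell"), name="score")


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for thr, s in _STAR_LEVELS:
        if p < thr:
            return s
    return ""


def compare_scores_by_group(
    scores: pd.Series, groups: pd.Series, equal_var: bool = True
) -> pd.DataFrame:
    """Pairwise two-sample t-tests of per-cell scores between groups.

    ``equal_var=True`` is the classical Student's t-test; set False for
    Welch.  Returns one row per group pair with the t statistic, p-value
    and a star annotation (* p<0.05, ** p<0.01, *** p<0.001).
    """
    groups = groups.reindex(scores.index)
    levels = [g for g in pd.unique(groups.dropna())]
    rows = []
    for a, b in combinations(levels, 2):
        xa = scores[groups == a].to_numpy()
        xb = scores[groups == b].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a if len(xa) < 2 else b} has fewer than 2 cells")
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        rows.append(
            {
                "group_a": a, "group_b": b,
                "mean_a": xa.mean(), "mean_b": xb.mean(),
                "n_a": len(xa), "n_b": len(xb),
                "t": float(t), "p": float(p), "stars": stars(float(p)),
            }
        )
    return pd.DataFrame(rows)


def _module_score(
    X: np.ndarray,
    genes: list[str],
    gene_set: list[str],
    n_bins: int,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    col = {g: i for i, g in enumerate(genes)}
    set_cols = [col[g] for g in gene_set if g in col]
    if not set_cols:
        raise ValueError("gene set empty after intersection with the matrix")
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(genes), dtype=int)
    # equal-size bins of the average-expression ranking
    bin_of[order] = np.minimum((np.arange(len(genes)) * n_bins) // len(genes), n_bins - 1)
    set_mask = np.zeros(len(genes), bool)
    set_mask[set_cols] = True
    ctrl_cols: list[int] = []
    for c in set_cols:
        pool = np.flatnonzero((bin_of == bin_of[c]) & ~set_mask)
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl_cols.extend(rng.choice(pool, size=take, replace=False))
    ctrl_cols = sorted(set(ctrl_cols))
    if not ctrl_cols:
        raise ValueError("no control genes available for module score")
    return X[:, set_cols].mean(axis=1) - X[:, ctrl_cols].mean(axis=1)


def assign_phase(s_score: np.ndarray, g2m_score: np.ndarray) -> np.ndarray:
    """G1 iff both scores are negative, else the argmax of (S, G2M)."""
    phase = np.where(s_score >= g2m_score, "S", "G2M")
    phase[(s_score < 0) & (g2m_score < 0)] = "G1"
    return phase


def cell_cycle_score(
    norm,
    s_genes: list[str] | None = None,
    g2m_genes: list[str] | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Tirosh-style S and G2/M module scores and cell-cycle phase per cell.

    Control-gene sampling is seeded and therefore reproducible.  Returns a
    frame with ``s_score``, ``g2m_score`` and ``phase`` (G1/S/G2M).
    """
    if s_genes is None or g2m_genes is None:
        s_def, g2m_def = load_cell_cycle_genes()
        s_genes = s_genes or s_def
        g2m_genes = g2m_genes or g2m_def
    overlap = set(s_genes) & set(g2m_genes)
    if overlap:
        warnings.warn(f"S and G2M gene sets overlap: {sorted(overlap)}", stacklevel=2)
    X, cells, genes = _matrix(norm)
    rng = np.random.default_rng(seed)
    s_score = _module_score(X, genes, s_genes, n_bins, n_ctrl, rng)
    g2m_score = _module_score(X, genes, g2m_genes, n_bins, n_ctrl, rng)
    return pd.DataFrame(
        {
            "s_score": s_score,
            "g2m_score": g2m_score,
            "phase": assign_phase(s_score, g2m_score),
        },
        index=pd.Index(cells, name="cell"),
    )
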