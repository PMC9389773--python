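"""Marker-gene and differential-expression detection (Wilcoxon rank-sum).

Genes are compared between two cell groups (e.g. Dx vs Re) or one-vs-rest
across cluster labels with the two-sided Wilcoxon rank-sum / Mann-Whitney U
test, after Seurat-style pre-filtering on detection fraction and fold
change; surviving genes are BH-adjusted.  Fold changes are computed on
de-logged normalized means with a pseudocount:
``log2fc = log2((mean_in + eps) / (mean_out + eps))``.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .clonal import bh_adjust

EXACT_MAX_N = 12  # exact enumeration branch for tiny samples


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled
    values (valid with ties; 2 * min tail probability, capped at 1)."""
    from itertools import combinations as _comb

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    idx = range(len(pooled))
    obs = ranks[:n_a].sum()
    stats_all = np.array([ranks[list(c)].sum() for c in _comb(idx, n_a)])
    p_le = np.mean(stats_all <= obs + 1e-12)
    p_ge = np.mean(stats_all >= obs - 1e-12)
    return float(min(1.0, 2 * min(p_le, p_ge)))


def rank_sum_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the tie-corrected normal approximation with continuity correction;
    for very small samples (n_a + n_b <= 12) the exact null distribution is
    enumerated instead.  Returns 1.0 when all pooled values are tied.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if a.size + b.size <= EXACT_MAX_N:
        return _rank_sum_exact(a, b)

    n1, n2 = a.size, b.size
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)  # continuity-corrected
    return float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))


def _expr(norm) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(norm, ad.AnnData):
        return np.asarray(norm.X, dtype=float), norm.obs_names, norm.var_names
    return norm.to_numpy(dtype=float), norm.index, norm.columns


def _group_stats(X, in_mask, out_mask, eps):
    mean_in = np.expm1(X[in_mask]).mean(axis=0)
    mean_out = np.expm1(X[out_mask]).mean(axis=0)
    log2fc = np.log2((mean_in + eps) / (mean_out + eps))
    pct_in = (X[in_mask] > 0).mean(axis=0)
    pct_out = (X[out_mask] > 0).mean(axis=0)
    return log2fc, pct_in, pct_out


def find_markers(
    norm,
    labels: pd.Series,
    group=None,
    reference="rest",
    min_pct: float = 0.1,
    min_abs_log2fc: float = 0.25,
    alpha: float = 0.05,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Marker genes per group (one-vs-rest) or for a single contrast.

    With ``group=None`` every label is contrasted against the rest; with
    ``group`` (and optionally ``reference``) only that contrast is run.
    Genes detected in >= ``min_pct`` of either side form the testing family:
    they are tested with the rank-sum test and BH-adjusted per group.  The
    fold-change cut (|log2fc| >= ``min_abs_log2fc``) is applied to the
    *reported* rows only, after adjustment — filtering the testing family on
    observed effect size would select noise-extreme genes and inflate the
    false-discovery rate beyond the nominal level.  Rows are ranked by
    (q, -|log2fc|, gene).  ``alpha`` is carried in the output as the
    significance cut used by downstream consumers.
    """
    X, cells, genes = _expr(norm)
    labels = labels.reindex(cells)
    if labels.isna().any():
        raise ValueError("labels must cover all cells")
    targets = [group] if group is not None else list(pd.unique(labels))
    frames = []
    n_tested: dict = {}
    for g in targets:
        in_mask = (labels == g).to_numpy()
        out_mask = (
            (labels == reference).to_numpy() if reference != "rest" else ~in_mask
        )
        if in_mask.sum() < 3 or out_mask.sum() < 3:
            warnings.warn(f"group {g!r} or its reference has <3 cells; skipped", stacklevel=2)
            continue
        log2fc, pct_in, pct_out = _group_stats(X, in_mask, out_mask, eps)
        tested = np.maximum(pct_in, pct_out) >= min_pct
        cols = np.flatnonzero(tested)
        n_tested[g] = int(cols.size)
        if cols.size == 0:
            continue
        p = np.array(
            [rank_sum_test(X[in_mask, j], X[out_mask, j]) for j in cols]
        )
        q = bh_adjust(p)
        df = pd.DataFrame(
            {
                "gene": np.asarray(genes)[cols],
                "group": g,
                "log2fc": log2fc[cols],
                "pct_in": pct_in[cols],
                "pct_out": pct_out[cols],
                "p": p,
                "q": q,
            }
        )
        df = df[df["log2fc"].abs() >= min_abs_log2fc]
        df["abs_lfc"] = df["log2fc"].abs()
        df = df.sort_values(["q", "abs_lfc", "gene"], ascending=[True, False, True])
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df.drop(columns="abs_lfc"))
    if not frames:
        out = pd.DataFrame(
            columns=["gene", "group", "log2fc", "pct_in", "pct_out", "p", "q", "rank"]
        )
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["alpha"] = alpha
    out.attrs["n_tested"] = n_tested
    return out


def top_markers(results: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Top-n rows per group by the deterministic (q, |log2fc|, gene) rank."""
    return results.groupby("group", sort=False, group_keys=False).head(n)


def signature_contrast(
    norm,
    gene_set,
    labels: pd.Series,
    group_a,
    group_b,
    fc_thr: float = 1.5,
    p_thr: float = 0.05,
    eps: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene fold change and rank-sum p for a named gene set between two
    sample groups, plus a set-level summary (genes passing FC and p cuts).

    Genes absent from the matrix are reported as missing and excluded from
    the summary.
    """
    X, cells, genes = _expr(norm)
    labels = labels.reindex(cells)
    col = {g: i for i, g in enumerate(genes)}
    a_mask = (labels == group_a).to_numpy()
    b_mask = (labels == group_b).to_numpy()
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("both groups need at least 3 cells")
    rows, missing = [], []
    for g in gene_set:
        if g not in col:
            missing.append(g)
            continue
        j = col[g]
        mean_a = float(np.expm1(X[a_mask, j]).mean())
        mean_b = float(np.expm1(X[b_mask, j]).mean())
        fc = (mean_a + eps) / (mean_b + eps)
        p = rank_sum_test(X[a_mask, j], X[b_mask, j])
        rows.append({"gene": g, "mean_a": mean_a, "mean_b": mean_b, "fc": fc, "p": p})
    df = pd.DataFrame(rows)
    summary = {
        "n_genes": len(df),
        "n_missing": len(missing),
        "missing": missing,
        "n_passing": int(((df["fc"] > fc_thr) & (df["p"] < p_thr)).sum()) if len(df) else 0,
    }
    return df, summary


def compare_deg_sets(deg_sets: dict[str, set]) -> dict[str, int]:
    """Inclusion-exclusion partition counts over named DEG sets (Venn input).

    Keys are '&'-joined sorted member names; each count is the number of
    genes belonging to exactly that combination of sets.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least two DEG sets")
    names = sorted(deg_sets)
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(deg_sets[n]) for n in combo))
            outside = set.union(
                *(set(deg_sets[n]) for n in names if n not in combo), set()
            )
            out["&".join(combo)] = len(inside - outside)
    return out
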