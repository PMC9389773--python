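"""Per-cell quality control and library-size normalization.

QC follows the four-rule filter used for plate-based SORT-seq libraries: a
cell is discarded when genes detected < ``min_genes``, or total UMI count >
``max_umi``, or mitochondrial UMI fraction > ``max_mito_frac``, or ERCC
spike-in read fraction > ``max_ercc_frac``.  Boundary semantics are strict
inequalities: a cell sitting exactly on a threshold passes.

ERCC spike-ins are not transcriptome, so they are excluded from the detected
gene count, the UMI total and the mitochondrial denominator; the ERCC
fraction itself is computed against the grand total including spike-ins.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

MITO_PREFIX = "MT-"
ERCC_PREFIX = "ERCC-"


@dataclass(frozen=True)
class QCThresholds:
    """Cut-offs of the four-rule cell filter (strict inequalities)."""

    min_genes: int = 500
    max_umi: int = 12_000
    max_mito_frac: float = 0.30
    max_ercc_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValueError(f"min_genes must be >= 0, got {self.min_genes}")
        if self.max_umi <= 0:
            raise ValueError(f"max_umi must be > 0, got {self.max_umi}")
        for name in ("max_mito_frac", "max_ercc_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


DEFAULT_THRESHOLDS = QCThresholds()


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X)


def _feature_masks(adata: ad.AnnData) -> tuple[np.ndarray, np.ndarray]:
    names = pd.Index(adata.var_names.astype(str))
    mito = names.str.startswith(MITO_PREFIX)
    ercc = names.str.startswith(ERCC_PREFIX)
    return np.asarray(mito), np.asarray(ercc)


def compute_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC metrics (detected genes, UMI total, mito/ERCC fractions).

    Returns a frame indexed by cell with columns ``n_genes_detected``,
    ``n_umi``, ``mito_frac``, ``ercc_frac`` and the four per-rule failure
    flags plus the overall ``pass`` flag (default thresholds; ``qc_filter``
    re-evaluates against caller thresholds).
    """
    if adata.n_obs == 0:
        raise ValueError("count matrix has no cells")
    if adata.n_vars == 0:
        raise ValueError("count matrix has no features")
    X = _dense(adata.X)
    mito, ercc = _feature_masks(adata)
    nonercc = ~ercc

    n_umi = X[:, nonercc].sum(axis=1)
    n_genes = (X[:, nonercc] > 0).sum(axis=1)
    mito_umi = X[:, mito].sum(axis=1)
    ercc_umi = X[:, ercc].sum(axis=1)
    grand = n_umi + ercc_umi

    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
        ercc_frac = np.where(grand > 0, ercc_umi / np.maximum(grand, 1), 0.0)

    df = pd.DataFrame(
        {
            "n_genes_detected": n_genes.astype(int),
            "n_umi": n_umi.astype(int),
            "mito_frac": mito_frac,
            "ercc_frac": ercc_frac,
        },
        index=adata.obs_names,
    )
    _apply_rules(df, DEFAULT_THRESHOLDS)
    return df


def _apply_rules(metrics: pd.DataFrame, thr: QCThresholds) -> None:
    metrics["fail_genes"] = metrics["n_genes_detected"] < thr.min_genes
    metrics["fail_umi"] = metrics["n_umi"] > thr.max_umi
    metrics["fail_mito"] = metrics["mito_frac"] > thr.max_mito_frac
    metrics["fail_ercc"] = metrics["ercc_frac"] > thr.max_ercc_frac
    metrics["pass"] = ~(
        metrics["fail_genes"]
        | metrics["fail_umi"]
        | metrics["fail_mito"]
        | metrics["fail_ercc"]
    )


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, dict]:
    """Drop failing cells; return the surviving matrix and a failure report.

    The report counts cells failing each rule (cells can fail several) and
    records the thresholds applied.  Raises if no cell survives.
    """
    thr = thresholds or DEFAULT_THRESHOLDS
    metrics = compute_qc_metrics(adata)
    _apply_rules(metrics, thr)
    keep = metrics["pass"].to_numpy()
    if not keep.any():
        raise ValueError("no cells survive QC filtering")
    report = {
        "n_cells_in": int(adata.n_obs),
        "n_cells_out": int(keep.sum()),
        "n_fail_genes": int(metrics["fail_genes"].sum()),
        "n_fail_umi": int(metrics["fail_umi"].sum()),
        "n_fail_mito": int(metrics["fail_mito"].sum()),
        "n_fail_ercc": int(metrics["fail_ercc"].sum()),
        "thresholds": {
            "min_genes": thr.min_genes,
            "max_umi": thr.max_umi,
            "max_mito_frac": thr.max_mito_frac,
            "max_ercc_frac": thr.max_ercc_frac,
        },
    }
    out = adata[keep].copy()
    qc_cols = ["n_genes_detected", "n_umi", "mito_frac", "ercc_frac"]
    out.obs = pd.concat(
        [out.obs.drop(columns=qc_cols, errors="ignore"), metrics.loc[keep, qc_cols]],
        axis=1,
    )
    return out, report


def normalize(
    adata: ad.AnnData, scale_factor: float = 10_000.0
) -> ad.AnnData:
    """Library-size normalize: ``log1p(count / cell_total * scale_factor)``.

    ERCC spike-ins are removed from both the cell totals and the output; the
    raw counts are preserved in ``layers['counts']``.
    """
    _, ercc = _feature_masks(adata)
    sub = adata[:, ~ercc]
    X = _dense(sub.X).astype(np.float64)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = list(np.asarray(sub.obs_names)[totals <= 0][:5])
        raise ValueError(f"cells with zero total count cannot be normalized: {bad}")
    norm = np.log1p(X / totals[:, None] * scale_factor)
    out = ad.AnnData(
        X=norm, obs=sub.obs.copy(), var=sub.var.copy(), uns=dict(sub.uns)
    )
    out.layers["counts"] = X
    out.uns["scale_factor"] = scale_factor
    return out
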