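"""Clonal variant-allele-frequency dynamics between diagnosis and relapse.

Each somatic variant carries REF/ALT read depths at the two timepoints.  A
variant is *detected* at a timepoint when it has at least ``min_alt`` ALT
reads and VAF >= ``min_vaf`` (defaults 5 reads, 0.05).  A Dx/Re shift is
tested with a two-sided Fisher's exact test on the 2x2 ALT/REF table and
adjusted across the panel with Benjamini-Hochberg; a shift is *reportable*
when the larger of the two VAFs is >= ``report_vaf`` (default 0.2) and the
raw p-value is below ``alpha`` (default 0.05).  Both the raw p and the BH q
are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

_REL_EPS = 1e-7  # relative slack when comparing hypergeometric point masses


def compute_vaf(alt: int, ref: int) -> float:
    """ALT / (ALT + REF); NaN (missing) when the site has zero depth."""
    if alt < 0 or ref < 0:
        raise ValueError(f"negative read counts: alt={alt}, ref={ref}")
    depth = alt + ref
    if depth == 0:
        return float("nan")
    return alt / depth


def detect_variant(alt: int, ref: int, min_alt: int = 5, min_vaf: float = 0.05) -> bool:
    """Detection rule: at least ``min_alt`` ALT reads and VAF >= ``min_vaf``."""
    if alt < min_alt:
        return False
    vaf = compute_vaf(alt, ref)
    return bool(not np.isnan(vaf) and vaf >= min_vaf)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Probability-ordering definition: sum of hypergeometric point
    probabilities not exceeding that of the observed table (with a small
    relative slack against floating-point ties), over all tables with the
    observed margins.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    n = int(t.sum())
    if n == 0:
        warnings.warn("all-zero 2x2 table; p-value set to 1", stacklevel=2)
        return 1.0
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    # hypergeometric log-pmf over the support (fixed margins)
    logpmf = (
        _lchoose(r1, support)
        + _lchoose(n - r1, c1 - support)
        - _lchoose(n, c1)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[support == t[0, 0]][0]
    p = float(pmf[pmf <= p_obs * (1 + _REL_EPS)].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def _lchoose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_vaf_shifts(
    variants: pd.DataFrame,
    min_alt: int = 5,
    min_vaf: float = 0.05,
    report_vaf: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher/BH screen for VAF shifts between Dx and Re across a panel.

    ``variants`` needs columns ``variant_id, ref_dx, alt_dx, ref_re,
    alt_re``.  Variants undetected at both timepoints are excluded before
    testing (no information).  Returns per-variant VAFs, detection flags,
    raw p, BH q, the shift direction and the ``reportable`` flag
    (max(VAF) >= ``report_vaf`` and p < ``alpha``).
    """
    if variants.empty:
        raise ValueError("variant table is empty")
    if variants["variant_id"].duplicated().any():
        dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids: {dup}")

    df = variants.copy()
    df["vaf_dx"] = [compute_vaf(a, r) for a, r in zip(df["alt_dx"], df["ref_dx"])]
    df["vaf_re"] = [compute_vaf(a, r) for a, r in zip(df["alt_re"], df["ref_re"])]
    df["detected_dx"] = [
        detect_variant(a, r, min_alt, min_vaf) for a, r in zip(df["alt_dx"], df["ref_dx"])
    ]
    df["detected_re"] = [
        detect_variant(a, r, min_alt, min_vaf) for a, r in zip(df["alt_re"], df["ref_re"])
    ]
    tested = df["detected_dx"] | df["detected_re"]
    df = df.loc[tested].reset_index(drop=True)
    if df.empty:
        return df.assign(p=[], q=[], direction=[], reportable=[])

    df["p"] = [
        fisher_exact_2x2([[a_dx, r_dx], [a_re, r_re]])
        for a_dx, r_dx, a_re, r_re in zip(
            df["alt_dx"], df["ref_dx"], df["alt_re"], df["ref_re"]
        )
    ]
    df["q"] = bh_adjust(df["p"].to_numpy())
    max_vaf = df[["vaf_dx", "vaf_re"]].max(axis=1)
    df["reportable"] = (max_vaf >= report_vaf) & (df["p"] < alpha)
    direction = np.where(df["vaf_dx"] > df["vaf_re"], "Dx-enriched", "Re-enriched")
    df["direction"] = np.where(df["reportable"], direction, "none")
    return df
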