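"""Synthetic paired diagnosis/relapse (Dx/Re) datasets with planted truth.

The generator emulates the structure of a plate-based (CEL-Seq2/SORT-seq)
AML study: UMI counts with ERCC spike-ins and mitochondrial genes, two
timepoints per patient, planted expression subpopulations with marker genes,
multi-megabase copy-number gains/losses and copy-neutral LOH, LSC-like
G1-enriched cells, and exome-like clonal variant depths whose clones expand
or disappear between Dx and Re.  Every planted structure is recorded in a
:class:`GroundTruth` so each downstream stage can be scored against it.

Count model: per-gene negative binomial with a shared dispersion
(gamma-Poisson mixture), gene means scaled per cell to a lognormal library
size.  Copy-number events act multiplicatively on expected expression;
copy-neutral LOH leaves expression untouched and only skews allele
fractions.  Haplotype phase is unknown, so the skewed allele fraction of a
loss/LOH SNP is 0 or 1 (gain: 1/3 or 2/3) with equal probability, fixed per
SNP per event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

from . import qc as _qc
from .signatures import load_cell_cycle_genes, load_lsc17

_MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

_LOWQ_MODES = ("low_genes", "high_umi", "high_mito", "high_ercc")


@dataclass(frozen=True)
class CnvEvent:
    """A planted copy-number (or copy-neutral LOH) event.

    ``copy_ratio`` multiplies expected expression of genes inside
    ``[start, end)`` in carrier cells (1.5 = single-copy gain of diploid,
    0.5 = single-copy loss); ``copy_ratio == 1.0`` with ``loh=True`` models
    copy-neutral loss of heterozygosity (expression unchanged, allele
    fractions pushed to 0/1).
    """

    chrom: str
    start: int
    end: int
    copy_ratio: float = 1.0
    timepoint: str = "Re"  # "Dx" | "Re" | "both"
    cell_fraction: float = 1.0
    loh: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError(f"copy_ratio must be > 0, got {self.copy_ratio}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if not 0.0 < self.cell_fraction <= 1.0:
            raise ValueError(f"cell_fraction must be in (0, 1], got {self.cell_fraction}")
        if self.timepoint not in ("Dx", "Re", "both"):
            raise ValueError(f"timepoint must be Dx/Re/both, got {self.timepoint!r}")
        if not self.name:
            object.__setattr__(
                self, "name",
                f"{'loh' if self.loh and self.copy_ratio == 1.0 else ('gain' if self.copy_ratio > 1 else 'loss')}"
                f"_{self.chrom}_{self.start // 1_000_000}M",
            )

    @property
    def kind(self) -> str:
        if self.loh and self.copy_ratio == 1.0:
            return "loh"
        return "gain" if self.copy_ratio > 1.0 else "loss"


@dataclass(frozen=True)
class VariantSpec:
    """True variant allele fractions of one somatic variant at Dx and Re."""

    id: str
    vaf_dx: float
    vaf_re: float

    def __post_init__(self) -> None:
        for name in ("vaf_dx", "vaf_re"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def default_cnv_events() -> list[CnvEvent]:
    """Relapse-specific 30 Mb gain and loss plus a copy-neutral LOH arm."""
    return [
        CnvEvent("chr2", 9_000_000, 39_000_000, copy_ratio=1.5, timepoint="Re"),
        CnvEvent("chr1", 21_000_000, 51_000_000, copy_ratio=0.5, timepoint="Re"),
        CnvEvent("chr3", 27_000_000, 57_000_000, copy_ratio=1.0, loh=True, timepoint="Re"),
    ]


def default_variant_specs() -> list[VariantSpec]:
    """Clonal dynamics panel: Dx-enriched, Re-enriched and stable variants."""
    return [
        VariantSpec("NPM1", 0.60, 0.10),
        VariantSpec("NRAS", 0.087, 0.0),
        VariantSpec("FLT3-ITD1", 0.40, 0.0),
        VariantSpec("FLT3-ITD2", 0.30, 0.45),
        VariantSpec("KIT1", 0.325, 0.05),
        VariantSpec("KIT2", 0.138, 0.01),
        VariantSpec("FAT3", 0.0, 0.238),
        VariantSpec("ITGB7", 0.0, 0.165),
        VariantSpec("UBA2", 0.0, 0.117),
        VariantSpec("SLC4A3", 0.0, 0.135),
        VariantSpec("DNMT3A", 0.45, 0.45),
        VariantSpec("WT1", 0.35, 0.35),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired Dx/Re generator (defaults = study conditions)."""

    n_genes: int = 1200
    n_cells_dx: int = 220
    n_cells_re: int = 220
    n_chromosomes: int = 4
    chrom_length_bp: int = 60_000_000
    mean_depth_umi: float = 4500.0
    depth_cv: float = 0.25
    nb_dispersion: float = 2.0
    n_clusters: int = 3
    marker_genes_per_cluster: int = 10
    marker_logfc: float = 2.0
    cnv_events: tuple[CnvEvent, ...] = field(default_factory=lambda: tuple(default_cnv_events()))
    lsc_fraction: float = 0.12
    lsc_upshift: float = 2.0
    variant_specs: tuple[VariantSpec, ...] = field(
        default_factory=lambda: tuple(default_variant_specs())
    )
    n_het_snps: int = 300
    wes_depth_mean: float = 250.0
    snp_read_rate: float = 1.0
    mito_fraction_mean: float = 0.10
    ercc_fraction_mean: float = 0.05
    phase_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)  # G1, S, G2M
    phase_marker_logfc: float = 2.0
    quiescent_downshift: float = 0.5  # cycle-gene factor in G1 cells
    lowq_cell_fraction: float = 0.10
    n_mito_genes: int = 13
    n_ercc: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells_dx", "n_cells_re", "n_chromosomes",
                     "chrom_length_bp", "n_clusters", "n_het_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("lsc_fraction", "mito_fraction_mean", "ercc_fraction_mean",
                     "lowq_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not math.isclose(sum(self.phase_fractions), 1.0, abs_tol=1e-9):
            raise ValueError(f"phase_fractions must sum to 1, got {self.phase_fractions}")
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        object.__setattr__(self, "cnv_events", tuple(self.cnv_events))
        object.__setattr__(self, "variant_specs", tuple(self.variant_specs))
        self._validate_events()

    def _validate_events(self) -> None:
        for ev in self.cnv_events:
            if ev.chrom not in self.chrom_names:
                raise ValueError(f"cnv_events: unknown chromosome {ev.chrom!r}")
            if ev.end > self.chrom_length_bp:
                raise ValueError(
                    f"cnv_events: event {ev.name} exceeds chromosome length "
                    f"{self.chrom_length_bp}"
                )
        for tp in ("Dx", "Re"):
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for ev in self.cnv_events:
                if ev.timepoint in (tp, "both"):
                    per_chrom.setdefault(ev.chrom, []).append((ev.start, ev.end))
            for chrom, spans in per_chrom.items():
                spans.sort()
                for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"cnv_events: overlapping events on {chrom} at timepoint {tp}"
                        )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


@dataclass
class GroundTruth:
    """Planted truth: per-cell labels/flags, gene annotation, event table."""

    cells: pd.DataFrame          # cluster, lsc, phase, clean, per-event carrier flags
    genes: pd.DataFrame          # chrom/start/end/strand/feature_type + planting flags
    events: pd.DataFrame         # one row per CnvEvent
    cluster_markers: dict[int, list[str]]
    variant_truth: pd.DataFrame  # true VAFs per variant


def _stream(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(abs(int(seed)) % (2**31), k)))


def _beta_params(mean: float, conc: float = 60.0) -> tuple[float, float]:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return mean * conc, (1 - mean) * conc


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu^2 / theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 0.0) / theta)
    return rng.poisson(lam)


def _build_gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    sig_genes = list(load_lsc17().keys())
    s_genes, g2m_genes = load_cell_cycle_genes()
    named = list(dict.fromkeys(sig_genes + s_genes + g2m_genes))
    if config.n_genes < len(named) + config.n_clusters * config.marker_genes_per_cluster:
        raise ValueError(
            "n_genes too small: need at least "
            f"{len(named) + config.n_clusters * config.marker_genes_per_cluster}"
        )
    n_plain = config.n_genes - len(named)
    names = named + [f"GENE{i:04d}" for i in range(n_plain)]

    chroms = rng.choice(config.chrom_names, size=config.n_genes)
    starts = rng.integers(0, config.chrom_length_bp - 200_000, size=config.n_genes)
    lengths = rng.integers(2_000, 150_000, size=config.n_genes)
    rows = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": rng.choice(["+", "-"], size=config.n_genes),
            "feature_type": "gene",
        },
        index=pd.Index(names, name="gene"),
    )

    mito = pd.DataFrame(
        {
            "chrom": "chrM",
            "start": np.arange(config.n_mito_genes) * 1000,
            "end": np.arange(config.n_mito_genes) * 1000 + 900,
            "strand": "+",
            "feature_type": "mito",
        },
        index=pd.Index(_MITO_GENES[: config.n_mito_genes], name="gene"),
    )
    ercc = pd.DataFrame(
        {
            "chrom": "ERCC",
            "start": np.arange(config.n_ercc) * 1000,
            "end": np.arange(config.n_ercc) * 1000 + 900,
            "strand": "+",
            "feature_type": "ercc",
        },
        index=pd.Index([f"ERCC-{i + 1:05d}" for i in range(config.n_ercc)], name="gene"),
    )
    return pd.concat([rows, mito, ercc])


def _gene_midpoints(genes: pd.DataFrame) -> np.ndarray:
    return ((genes["start"].to_numpy() + genes["end"].to_numpy()) // 2).astype(np.int64)


def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw the paired Dx/Re UMI count matrix and its ground truth.

    Deterministic under a fixed ``config.seed``.  After sampling, clean cells
    are nudged (deterministically, from the same RNG stream) to guarantee
    they satisfy the four default QC rules, and deliberately low-quality
    cells are verified to violate the rule they were assigned; the
    clean/low-quality split is recorded in the truth so the QC stage can be
    scored exactly.
    """
    rng = _stream(config.seed, 0)
    genes = _build_gene_table(config, rng)
    nuclear = genes["feature_type"].to_numpy() == "gene"
    mito_mask = genes["feature_type"].to_numpy() == "mito"
    ercc_mask = genes["feature_type"].to_numpy() == "ercc"
    n_feat = len(genes)
    gene_names = genes.index.to_numpy()

    # --- baseline relative abundances -----------------------------------
    w = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    lsc17 = load_lsc17()
    s_genes, g2m_genes = load_cell_cycle_genes()
    name_to_col = {g: i for i, g in enumerate(gene_names)}
    # fixed iteration order: set iteration is hash-seed dependent
    planted_list = list(dict.fromkeys(list(lsc17) + s_genes + g2m_genes))
    planted = set(planted_list)
    # signature genes get mid/high baseline expression so scores are informative
    for g in planted_list:
        w[name_to_col[g]] = rng.lognormal(mean=0.7, sigma=0.5)
    w = w / w.sum()

    mito_w = rng.lognormal(0.0, 0.8, size=config.n_mito_genes)
    mito_w /= mito_w.sum()
    ercc_w = rng.lognormal(0.0, 1.0, size=config.n_ercc)
    ercc_w /= ercc_w.sum()

    # --- cell table -----------------------------------------------------
    n_cells = config.n_cells_dx + config.n_cells_re
    timepoint = np.array(["Dx"] * config.n_cells_dx + ["Re"] * config.n_cells_re)
    cell_ids = np.array(
        [f"Dx_{i:04d}" for i in range(config.n_cells_dx)]
        + [f"Re_{i:04d}" for i in range(config.n_cells_re)]
    )
    cluster = rng.integers(0, config.n_clusters, size=n_cells)
    lsc = rng.random(n_cells) < config.lsc_fraction
    phase = rng.choice(["G1", "S", "G2M"], size=n_cells, p=list(config.phase_fractions))
    phase[lsc] = "G1"  # planted LSC-like cells are quiescent

    n_lowq = int(round(config.lowq_cell_fraction * n_cells))
    lowq_idx = rng.choice(n_cells, size=n_lowq, replace=False) if n_lowq else np.array([], int)
    lowq_mode = np.array([""] * n_cells, dtype=object)
    for j, idx in enumerate(np.sort(lowq_idx)):
        lowq_mode[idx] = _LOWQ_MODES[j % len(_LOWQ_MODES)]
    clean = lowq_mode == ""

    carriers = {}
    mid = _gene_midpoints(genes)
    for ev in config.cnv_events:
        in_tp = (timepoint == ev.timepoint) if ev.timepoint != "both" else np.ones(n_cells, bool)
        carry = in_tp & (rng.random(n_cells) < ev.cell_fraction)
        carriers[ev.name] = carry

    # --- cluster marker assignment --------------------------------------
    plain = [g for g in gene_names[nuclear] if g not in planted]
    marker_map: dict[int, list[str]] = {}
    cursor = 0
    for c in range(config.n_clusters):
        marker_map[c] = plain[cursor : cursor + config.marker_genes_per_cluster]
        cursor += config.marker_genes_per_cluster

    # --- expected means --------------------------------------------------
    sigma = math.sqrt(math.log(1 + config.depth_cv**2))
    depth = rng.lognormal(math.log(config.mean_depth_umi) - sigma**2 / 2, sigma, n_cells)
    a, b = _beta_params(config.ercc_fraction_mean)
    ercc_frac = rng.beta(a, b, size=n_cells)
    a, b = _beta_params(config.mito_fraction_mean)
    mito_frac = rng.beta(a, b, size=n_cells)

    restrict_genes: dict[int, np.ndarray] = {}
    for i in np.flatnonzero(~clean):
        mode = lowq_mode[i]
        if mode == "low_genes":
            depth[i] = 1500.0
            restrict_genes[i] = rng.choice(config.n_genes, size=150, replace=False)
        elif mode == "high_umi":
            depth[i] = 1.5 * _qc.DEFAULT_THRESHOLDS.max_umi / (1 - ercc_frac[i])
        elif mode == "high_mito":
            mito_frac[i] = 0.5
        elif mode == "high_ercc":
            ercc_frac[i] = 0.4

    mod = np.ones((n_cells, config.n_genes))
    marker_fc = 2.0**config.marker_logfc
    for c, genes_c in marker_map.items():
        cols = [name_to_col[g] for g in genes_c]
        mod[np.ix_(cluster == c, cols)] *= marker_fc
    phase_fc = 2.0**config.phase_marker_logfc
    s_cols = [name_to_col[g] for g in s_genes]
    g2m_cols = [name_to_col[g] for g in g2m_genes]
    mod[np.ix_(phase == "S", s_cols)] *= phase_fc
    mod[np.ix_(phase == "G2M", g2m_cols)] *= phase_fc
    # quiescent cells transcribe replication/mitosis programs below the
    # population mean, not at it
    cycle_cols = sorted(set(s_cols) | set(g2m_cols))
    mod[np.ix_(phase == "G1", cycle_cols)] *= config.quiescent_downshift
    pos_lsc_cols = [name_to_col[g] for g, wt in lsc17.items() if wt > 0]
    mod[np.ix_(lsc, pos_lsc_cols)] *= config.lsc_upshift
    for ev in config.cnv_events:
        if ev.loh and ev.copy_ratio == 1.0:
            continue  # copy-neutral: expression untouched
        in_ev = nuclear & (genes["chrom"].to_numpy() == ev.chrom) & \
            (mid >= ev.start) & (mid < ev.end)
        cols = np.flatnonzero(in_ev[: config.n_genes])
        mod[np.ix_(carriers[ev.name], cols)] *= ev.copy_ratio

    nuclear_total = depth * (1 - ercc_frac) * (1 - mito_frac)
    mu = nuclear_total[:, None] * (w[None, :] * mod)
    for i, cols in restrict_genes.items():
        keep = np.zeros(config.n_genes, bool)
        keep[cols] = True
        mu[i, ~keep] = 0.0
        mu[i, keep] *= 1.0 / (w[cols].sum())  # keep expected depth after restriction

    X = np.zeros((n_cells, n_feat), dtype=np.int64)
    X[:, : config.n_genes] = _nb_sample(rng, mu, config.nb_dispersion)
    mito_mu = (depth * (1 - ercc_frac) * mito_frac)[:, None] * mito_w[None, :]
    X[:, mito_mask] = rng.poisson(mito_mu)
    ercc_mu = (depth * ercc_frac)[:, None] * ercc_w[None, :]
    X[:, ercc_mask] = rng.poisson(ercc_mu)

    _enforce_qc_outcomes(X, clean, lowq_mode, nuclear, mito_mask, ercc_mask, rng)

    obs = pd.DataFrame(
        {
            "sample": np.where(timepoint == "Dx", "patient_Dx", "patient_Re"),
            "timepoint": timepoint,
            "cluster": cluster,
            "lsc": lsc,
            "phase": phase,
            "clean": clean,
            "lowq_mode": lowq_mode,
        },
        index=pd.Index(cell_ids, name="cell"),
    )
    for name, carry in carriers.items():
        obs[f"cnv_{name}"] = carry

    adata = ad.AnnData(X=X.astype(np.int32), obs=obs, var=genes.copy())
    adata.uns["chrom_lengths"] = {**config.chrom_lengths, "chrM": 16_569, "ERCC": config.n_ercc * 1000}

    events = pd.DataFrame(
        [
            {
                "name": ev.name, "chrom": ev.chrom, "start": ev.start, "end": ev.end,
                "copy_ratio": ev.copy_ratio, "timepoint": ev.timepoint,
                "cell_fraction": ev.cell_fraction, "loh": ev.loh, "kind": ev.kind,
            }
            for ev in config.cnv_events
        ]
    )
    gt_genes = genes.copy()
    gt_genes["is_marker"] = [
        g in {m for ms in marker_map.values() for m in ms} for g in gene_names
    ]
    truth = GroundTruth(
        cells=obs.copy(),
        genes=gt_genes,
        events=events,
        cluster_markers=marker_map,
        variant_truth=pd.DataFrame(
            [{"variant_id": v.id, "vaf_dx": v.vaf_dx, "vaf_re": v.vaf_re}
             for v in config.variant_specs]
        ),
    )
    return adata, truth


def _enforce_qc_outcomes(
    X: np.ndarray,
    clean: np.ndarray,
    lowq_mode: np.ndarray,
    nuclear: np.ndarray,
    mito_mask: np.ndarray,
    ercc_mask: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Deterministically pin each cell to its intended side of the QC filter.

    Clean cells are adjusted into a safety margin inside all four rules;
    low-quality cells are pushed across their assigned rule if sampling noise
    left them passing.  Operates in place on the count matrix.
    """
    thr = _qc.DEFAULT_THRESHOLDS
    nonercc = ~ercc_mask
    n_nuc = int(nuclear.sum())

    for i in range(X.shape[0]):
        row = X[i]
        if clean[i]:
            for _ in range(4):
                numi = int(row[nonercc].sum())
                if numi > thr.max_umi - 600:  # thin to 80% of the cap
                    p = (0.8 * thr.max_umi) / numi
                    row[nonercc] = rng.binomial(row[nonercc], p)
                detected = int((row[nonercc] > 0).sum())
                if detected < thr.min_genes + 20:
                    zero = np.flatnonzero((row == 0) & nuclear)
                    need = thr.min_genes + 20 - detected
                    add = rng.choice(zero, size=min(need, zero.size), replace=False)
                    row[add] = 1
                numi = int(row[nonercc].sum())
                mito = int(row[mito_mask].sum())
                if numi > 0 and mito / numi > thr.max_mito_frac - 0.02:
                    target = int((thr.max_mito_frac - 0.05) * (numi - mito) / (1 - (thr.max_mito_frac - 0.05)))
                    row[mito_mask] = _scale_down(row[mito_mask], target)
                numi = int(row[nonercc].sum())
                ercc = int(row[ercc_mask].sum())
                if ercc / max(ercc + numi, 1) > thr.max_ercc_frac - 0.02:
                    target = int((thr.max_ercc_frac - 0.05) * numi / (1 - (thr.max_ercc_frac - 0.05)))
                    row[ercc_mask] = _scale_down(row[ercc_mask], target)
                if _passes(row, nonercc, mito_mask, ercc_mask, thr, margin=True):
                    break
        else:
            mode = lowq_mode[i]
            numi = int(row[nonercc].sum())
            if mode == "low_genes":
                detected = int((row[nonercc] > 0).sum())
                if detected >= thr.min_genes:  # keep only the top expressed genes
                    order = np.argsort(row * nonercc)[::-1]
                    row[order[thr.min_genes - 100:]] = np.where(
                        nonercc[order[thr.min_genes - 100:]], 0, row[order[thr.min_genes - 100:]]
                    )
            elif mode == "high_umi" and numi <= thr.max_umi:
                top = np.argmax(row * nuclear)
                row[top] += thr.max_umi - numi + 500
            elif mode == "high_mito":
                mito = int(row[mito_mask].sum())
                while mito <= thr.max_mito_frac * int(row[nonercc].sum()) + 1:
                    row[mito_mask] = row[mito_mask] * 2 + 1
                    mito = int(row[mito_mask].sum())
            elif mode == "high_ercc":
                while int(row[ercc_mask].sum()) <= thr.max_ercc_frac * int(row[nonercc].sum() + row[ercc_mask].sum()) + 1:
                    row[ercc_mask] = row[ercc_mask] * 2 + 1
    assert n_nuc > 0


def _scale_down(counts: np.ndarray, target_total: int) -> np.ndarray:
    total = counts.sum()
    if total <= target_total or total == 0:
        return counts
    scaled = np.floor(counts * (target_total / total)).astype(counts.dtype)
    return scaled


def _passes(row, nonercc, mito_mask, ercc_mask, thr, margin: bool = False) -> bool:
    numi = int(row[nonercc].sum())
    detected = int((row[nonercc] > 0).sum())
    mito = int(row[mito_mask].sum())
    ercc = int(row[ercc_mask].sum())
    m = 0.01 if margin else 0.0
    return (
        detected >= thr.min_genes
        and numi <= thr.max_umi
        and (numi == 0 or mito / numi <= thr.max_mito_frac - m)
        and ercc / max(ercc + numi, 1) <= thr.max_ercc_frac - m
    )


def simulate_variants(config: SimConfig) -> pd.DataFrame:
    """Exome-like allelic depths per variant and timepoint.

    Depth per timepoint is Poisson(``wes_depth_mean``); the ALT count is
    binomial at the true VAF.  Returns one row per variant with columns
    ``variant_id, chrom, pos, gene, ref_dx, alt_dx, ref_re, alt_re`` plus the
    true VAFs.
    """
    if not config.variant_specs:
        raise ValueError("variant_specs is empty")
    rng = _stream(config.seed, 1)
    rows = []
    for spec in config.variant_specs:
        chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
        pos = int(rng.integers(config.chrom_length_bp))
        d_dx = int(rng.poisson(config.wes_depth_mean))
        d_re = int(rng.poisson(config.wes_depth_mean))
        alt_dx = int(rng.binomial(d_dx, spec.vaf_dx)) if d_dx else 0
        alt_re = int(rng.binomial(d_re, spec.vaf_re)) if d_re else 0
        rows.append(
            {
                "variant_id": spec.id, "chrom": chrom, "pos": pos,
                "gene": spec.id.rstrip("0123456789").rstrip("-"),
                "ref_dx": d_dx - alt_dx, "alt_dx": alt_dx,
                "ref_re": d_re - alt_re, "alt_re": alt_re,
                "true_vaf_dx": spec.vaf_dx, "true_vaf_re": spec.vaf_re,
            }
        )
    return pd.DataFrame(rows)


def simulate_allele_counts(
    config: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell ref/alt read counts at heterozygous SNPs.

    SNPs are placed uniformly across the synthetic genome.  Reads per cell
    and SNP are Poisson(``snp_read_rate``); alt reads are binomial at an
    allele fraction of 0.5 in diploid cells, 0 or 1 (fixed per SNP per
    event) in single-copy-loss or copy-neutral-LOH carriers, and 1/3 or 2/3
    in single-copy-gain carriers.

    Returns ``(allele_counts, snps)``: the long-format nonzero counts and
    the SNP table with its planted per-event allele fractions.
    """
    rng = _stream(config.seed, 2)
    n_cells = len(truth.cells)
    chroms = np.asarray(rng.choice(config.chrom_names, size=config.n_het_snps))
    pos = rng.integers(0, config.chrom_length_bp, size=config.n_het_snps)
    if (pos >= config.chrom_length_bp).any():
        raise ValueError("SNP placed outside the annotated genome")
    snp_ids = np.array([f"snp{i:04d}" for i in range(config.n_het_snps)])

    f = np.full((n_cells, config.n_het_snps), 0.5)
    snp_event_f = np.full(config.n_het_snps, np.nan)
    snp_event = np.array([""] * config.n_het_snps, dtype=object)
    for _, ev in truth.events.iterrows():
        in_ev = (chroms == ev["chrom"]) & (pos >= ev["start"]) & (pos < ev["end"])
        if not in_ev.any():
            continue
        carry = truth.cells[f"cnv_{ev['name']}"].to_numpy()
        for j in np.flatnonzero(in_ev):
            if ev["kind"] in ("loss", "loh"):
                fj = float(rng.choice([0.0, 1.0]))
            elif ev["kind"] == "gain":
                fj = float(rng.choice([1.0 / 3.0, 2.0 / 3.0]))
            else:
                continue
            f[carry, j] = fj
            snp_event_f[j] = fj
            snp_event[j] = ev["name"]

    reads = rng.poisson(config.snp_read_rate, size=(n_cells, config.n_het_snps))
    alt = rng.binomial(reads, f)
    cell_idx, snp_idx = np.nonzero(reads)
    out = pd.DataFrame(
        {
            "cell": truth.cells.index.to_numpy()[cell_idx],
            "snp_id": snp_ids[snp_idx],
            "chrom": chroms[snp_idx],
            "pos": pos[snp_idx],
            "ref_count": (reads - alt)[cell_idx, snp_idx],
            "alt_count": alt[cell_idx, snp_idx],
        }
    )
    snps = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": chroms, "pos": pos,
         "event": snp_event, "event_f": snp_event_f}
    )
    return out, snps


def small_config(**overrides) -> SimConfig:
    """A scaled-down config for fast tests; same structure, fewer cells/genes."""
    base = dict(
        n_genes=750, n_cells_dx=120, n_cells_re=120, mean_depth_umi=3500.0,
        n_het_snps=120, lowq_cell_fraction=0.1, marker_genes_per_cluster=8,
    )
    base.update(overrides)
    return SimConfig(**base)
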