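"""Expression-tile CNV inference (iCNV) and B-allele-fraction confirmation.

Large copy-number events leave a dosage footprint in scRNA-seq: relative to
a reference cell group, carrier cells over- or under-express whole genomic
segments.  The genome is partitioned into fixed 3 Mb tiles; per cell and
tile the signal is

    log2( (pooled normalized expression of the tile's genes)
          / (reference-cell mean of the same pool) )

median-centered across tiles within the cell (which also absorbs the
library-size inflation a large gain causes), clipped, and smoothed with a
centered moving average along each chromosome.  Segments are called from
cell-consensus runs of supra-threshold tiles and their boundaries refined on
the unsmoothed group-mean signal.

Copy-neutral LOH is invisible to this expression signal by construction and
is instead confirmed from pooled alt-read fractions at heterozygous SNPs:
the folded deviation |f - 0.5| approaches 0.5 in carriers (alleles at 0 or
1) while staying near binomial noise in diploid cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

TILE_SIZE = 3_000_000


@dataclass
class TileIndex:
    """Fixed-width genomic tiles with the gene-to-tile assignment."""

    tiles: pd.DataFrame            # tile_id, chrom, start, end
    gene_tile: pd.Series           # gene -> tile_id (midpoint assignment)
    tile_size: int = TILE_SIZE

    def genes_in(self, tile_id: str) -> list[str]:
        return list(self.gene_tile.index[self.gene_tile == tile_id])


@dataclass
class TileMatrix:
    """Per-cell iCNV signal over tiles (smoothed + raw, log2 units)."""

    signal: pd.DataFrame           # cells x tiles, clipped + smoothed (calling scale)
    raw: pd.DataFrame              # cells x tiles, unclipped + unsmoothed (diagnostic)
    tiles: pd.DataFrame
    reference_cells: list[str]


@dataclass
class SegmentCall:
    chrom: str
    start: int
    end: int
    state: str                     # "gain" | "loss"
    tile_ids: list[str]
    mean_signal: float
    affected_fraction: float
    affected_cells: list[str] = field(default_factory=list)


@dataclass
class BafSummary:
    """Per-SNP pooled alt fractions and the segment-level folded deviation."""

    per_snp: pd.DataFrame          # snp_id, f_target, f_reference, depths, deviations
    target_deviation: float
    reference_deviation: float
    n_snps: int
    status: str                    # "confirmed" | "not_confirmed" | "unconfirmable"

    @property
    def confirmed(self) -> bool:
        return self.status == "confirmed"


def build_tiles(
    annotation: pd.DataFrame,
    chrom_lengths: dict[str, int],
    tile_size: int = TILE_SIZE,
) -> TileIndex:
    """Partition each chromosome into fixed tiles from position 0.

    Genes are assigned to the single tile containing their midpoint
    ``floor((start + end) / 2)`` (0-based, half-open tiles).  Raises for a
    gene on an undeclared chromosome or beyond its declared length.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        n_tiles = int(np.ceil(length / tile_size))
        for k in range(n_tiles):
            rows.append(
                {
                    "tile_id": f"{chrom}:{k}",
                    "chrom": chrom,
                    "start": k * tile_size,
                    "end": min((k + 1) * tile_size, length),
                }
            )
    tiles = pd.DataFrame(rows).set_index("tile_id", drop=False)

    mid = (annotation["start"].to_numpy() + annotation["end"].to_numpy()) // 2
    assignments = []
    for gene, chrom, m in zip(annotation.index, annotation["chrom"], mid):
        if chrom not in chrom_lengths:
            raise ValueError(f"gene {gene!r} on undeclared chromosome {chrom!r}")
        if m >= chrom_lengths[chrom]:
            raise ValueError(
                f"gene {gene!r} midpoint {m} beyond {chrom} length {chrom_lengths[chrom]}"
            )
        assignments.append(f"{chrom}:{m // tile_size}")
    gene_tile = pd.Series(assignments, index=annotation.index, name="tile_id")
    return TileIndex(tiles=tiles, gene_tile=gene_tile, tile_size=tile_size)


def _lin_expr(norm) -> tuple[np.ndarray, list[str], list[str]]:
    """De-logged normalized expression (cells x genes, linear scale)."""
    if isinstance(norm, ad.AnnData):
        X = np.asarray(norm.X, dtype=float)
        return np.expm1(X), list(norm.obs_names), list(norm.var_names)
    return np.expm1(norm.to_numpy(dtype=float)), list(norm.index), list(norm.columns)


def icnv_signal(
    norm,
    tiles: TileIndex,
    reference_cells,
    min_genes_per_tile: int = 5,
    clip: float = 1.5,
    smooth_window: int = 3,
    eps: float = 1.0,
) -> TileMatrix:
    """Per-cell log2 tile signal relative to the reference cell group.

    Tiles with fewer than ``min_genes_per_tile`` member genes are excluded
    (with a warning).  ``eps`` is a pseudo-expression stabilizer on the
    pooled tile expression (normalized scale).  Reference cells average to
    ~0 per tile by construction.
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("reference_cells must be non-empty")
    X, cells, genes = _lin_expr(norm)
    cell_pos = {c: i for i, c in enumerate(cells)}
    ref_idx = [cell_pos[c] for c in reference_cells]

    usable = [g for g in genes if g in tiles.gene_tile.index]
    tile_of = tiles.gene_tile.loc[usable]
    tile_order = [t for t in tiles.tiles["tile_id"] if t in set(tile_of)]
    kept, pooled = [], []
    gene_idx = {g: i for i, g in enumerate(genes)}
    for t in tile_order:
        members = [gene_idx[g] for g in tile_of.index[tile_of == t]]
        if len(members) < min_genes_per_tile:
            warnings.warn(f"tile {t} has <{min_genes_per_tile} genes; excluded", stacklevel=2)
            continue
        kept.append(t)
        pooled.append(X[:, members].sum(axis=1))
    if not kept:
        raise ValueError("no usable tiles")
    P = np.column_stack(pooled)                      # cells x tiles
    ref_mean = P[ref_idx].mean(axis=0)
    sig = np.log2((P + eps) / (ref_mean[None, :] + eps))
    sig = sig - sig[ref_idx].mean(axis=0)            # exact per-tile ref centering
    sig = sig - np.median(sig, axis=1, keepdims=True)  # per-cell re-centering

    tiles_kept = tiles.tiles.loc[kept]
    raw = pd.DataFrame(sig, index=pd.Index(cells, name="cell"), columns=kept)
    smoothed = pd.DataFrame(
        np.clip(sig, -clip, clip), index=raw.index, columns=raw.columns
    )
    if smooth_window > 1:
        for chrom, sub in tiles_kept.groupby("chrom", sort=False):
            cols = list(sub["tile_id"])
            block = smoothed[cols].to_numpy()
            smoothed[cols] = _moving_average(block, smooth_window)
    return TileMatrix(signal=smoothed, raw=raw, tiles=tiles_kept, reference_cells=reference_cells)


def _moving_average(block: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows."""
    n = block.shape[1]
    half = w // 2
    out = np.empty_like(block)
    csum = np.cumsum(np.pad(block, ((0, 0), (1, 0))), axis=1)
    for j in range(n):
        lo, hi = max(0, j - half), min(n, j + half + 1)
        out[:, j] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def call_segments(
    tilemat: TileMatrix,
    target_cells,
    gain_thr: float = 0.15,
    loss_thr: float = -0.15,
    min_tiles: int = 2,
    min_cell_frac: float = 0.5,
) -> list[SegmentCall]:
    """Consensus segment calls over the target cell group.

    A tile is called when the per-cell smoothed signal exceeds the threshold
    in at least ``min_cell_frac`` of target cells; maximal same-state runs of
    at least ``min_tiles`` adjacent tiles become segments.  Segment edges are
    then trimmed to tiles whose unsmoothed target-mean signal also exceeds
    the threshold, and the reported mean signal and per-cell affected flags
    use the unsmoothed signal (smoothing spreads signal across boundaries).
    """
    if gain_thr <= loss_thr:
        raise ValueError(f"gain_thr ({gain_thr}) must exceed loss_thr ({loss_thr})")
    target_cells = list(target_cells)
    if not target_cells:
        raise ValueError("target_cells must be non-empty")
    S = tilemat.signal.loc[target_cells]
    R = tilemat.raw.loc[target_cells]
    frac_gain = (S > gain_thr).mean(axis=0)
    frac_loss = (S < loss_thr).mean(axis=0)
    state = pd.Series("neutral", index=S.columns)
    state[frac_gain >= min_cell_frac] = "gain"
    state[frac_loss >= min_cell_frac] = "loss"

    calls: list[SegmentCall] = []
    tiles = tilemat.tiles
    for chrom, sub in tiles.groupby("chrom", sort=False):
        cols = list(sub["tile_id"])
        run: list[str] = []
        run_state = "neutral"
        for t in cols + ["__end__"]:
            s = state[t] if t != "__end__" else "neutral"
            if s == run_state and s != "neutral":
                run.append(t)
                continue
            if run_state != "neutral":
                seg = _finalize_run(run, run_state, tiles, R, gain_thr, loss_thr, min_tiles)
                if seg is not None:
                    calls.append(seg)
            run = [t] if s != "neutral" else []
            run_state = s
    return calls


def _finalize_run(run, run_state, tiles, R, gain_thr, loss_thr, min_tiles):
    thr = gain_thr if run_state == "gain" else loss_thr
    mean_sig = R[run].mean(axis=0)
    beyond = mean_sig > thr if run_state == "gain" else mean_sig < thr
    # trim edge tiles not supported by the unsmoothed group mean
    lo, hi = 0, len(run)
    while lo < hi and not beyond.iloc[lo]:
        lo += 1
    while hi > lo and not beyond.iloc[hi - 1]:
        hi -= 1
    run = run[lo:hi]
    if len(run) < min_tiles:
        return None
    seg_mean = R[run].to_numpy().mean(axis=1)
    affected = seg_mean > thr if run_state == "gain" else seg_mean < thr
    return SegmentCall(
        chrom=tiles.loc[run[0], "chrom"],
        start=int(tiles.loc[run[0], "start"]),
        end=int(tiles.loc[run[-1], "end"]),
        state=run_state,
        tile_ids=list(run),
        mean_signal=float(R[run].to_numpy().mean()),
        affected_fraction=float(affected.mean()),
        affected_cells=list(R.index[affected]),
    )


def baf_confirm(
    allele_counts: pd.DataFrame,
    region: tuple[str, int, int],
    target_cells,
    reference_cells,
    min_snps: int = 3,
    min_reads: int = 20,
    dev_threshold: float = 0.1,
) -> BafSummary:
    """Confirm an allelic imbalance over ``region`` from pooled SNP counts.

    Reads are pooled (cell-summed) per SNP within each group; the segment
    statistic is the mean folded deviation |f - 0.5| over SNPs with pooled
    depth >= ``min_reads`` in both groups.  The call is ``confirmed`` when
    the target deviation exceeds the reference deviation by more than
    ``dev_threshold``, and ``unconfirmable`` when fewer than ``min_snps``
    SNPs are usable.
    """
    chrom, start, end = region
    target_cells, reference_cells = set(target_cells), set(reference_cells)
    ac = allele_counts
    in_reg = (ac["chrom"] == chrom) & (ac["pos"] >= start) & (ac["pos"] < end)
    sub = ac.loc[in_reg]

    def pooled(cells: set) -> pd.DataFrame:
        g = sub[sub["cell"].isin(cells)].groupby("snp_id")[["ref_count", "alt_count"]].sum()
        g["depth"] = g["ref_count"] + g["alt_count"]
        g["f"] = np.where(g["depth"] > 0, g["alt_count"] / g["depth"].clip(lower=1), np.nan)
        return g

    tg, rg = pooled(target_cells), pooled(reference_cells)
    snps = tg.join(rg, lsuffix="_target", rsuffix="_reference", how="inner")
    usable = snps[(snps["depth_target"] >= min_reads) & (snps["depth_reference"] >= min_reads)].copy()
    usable["dev_target"] = (usable["f_target"] - 0.5).abs()
    usable["dev_reference"] = (usable["f_reference"] - 0.5).abs()

    if len(usable) < min_snps:
        return BafSummary(
            per_snp=usable.reset_index(), target_deviation=float("nan"),
            reference_deviation=float("nan"), n_snps=len(usable), status="unconfirmable",
        )
    tdev = float(usable["dev_target"].mean())
    rdev = float(usable["dev_reference"].mean())
    status = "confirmed" if tdev - rdev > dev_threshold else "not_confirmed"
    return BafSummary(
        per_snp=usable.reset_index(), target_deviation=tdev,
        reference_deviation=rdev, n_snps=len(usable), status=status,
    )


def degs_in_segments(
    markers: pd.DataFrame,
    segments: list[SegmentCall],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count significant DEGs whose gene midpoint falls inside each segment.

    ``markers`` needs columns ``gene``, ``log2fc`` and ``q``; coordinates
    are joined from ``annotation`` (genes missing there are warned about and
    skipped).  Direction consistency (gain => up in the target group,
    loss => down) is reported per segment.
    """
    sig = markers[markers["q"] < alpha]
    missing = [g for g in sig["gene"] if g not in annotation.index]
    if missing:
        warnings.warn(f"{len(missing)} DEG(s) lack coordinates; skipped", stacklevel=2)
    sig = sig[sig["gene"].isin(annotation.index)]
    mid = (annotation["start"] + annotation["end"]) // 2
    rows = []
    for k, seg in enumerate(segments):
        genes, consistent = [], 0
        for _, row in sig.iterrows():
            g = row["gene"]
            if annotation.loc[g, "chrom"] == seg.chrom and seg.start <= mid[g] < seg.end:
                genes.append(g)
                up = row["log2fc"] > 0
                if (seg.state == "gain") == up:
                    consistent += 1
        rows.append(
            {
                "segment": f"{seg.chrom}:{seg.start}-{seg.end}",
                "state": seg.state,
                "n_degs": len(genes),
                "n_direction_consistent": consistent,
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(rows)
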