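"""End-to-end orchestration: simulate -> qc -> clonal -> icnv -> score -> markers.

One YAML config drives every stage; the global seed propagates to each
stochastic step, all artifacts live in a plain directory layout with a
manifest of SHA-256 checksums, and re-running with an identical config
reproduces byte-identical artifacts.  Stage failures are re-raised with the
stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clonal, cnv, markers, qc, signatures, simulate
from . import io as rsio


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "qc": {},
    "clonal": {"min_alt": 5, "min_vaf": 0.05, "report_vaf": 0.2, "alpha": 0.05},
    "icnv": {
        "tile_size": cnv.TILE_SIZE, "clip": 1.5, "smooth_window": 3,
        "gain_thr": 0.15, "loss_thr": -0.15, "min_tiles": 2, "min_cell_frac": 0.5,
        "min_genes_per_tile": 5, "target": "Re", "reference": "Dx",
    },
    "signatures": {"n_bins": 24, "n_ctrl": 100},
    "markers": {"min_pct": 0.1, "min_abs_log2fc": 0.25, "alpha": 0.05},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sim_config(cfg: dict) -> simulate.SimConfig:
    block = dict(cfg.get("simulate") or {})
    events = block.pop("cnv_events", None)
    specs = block.pop("variant_specs", None)
    kwargs = dict(block)
    if events is not None:
        kwargs["cnv_events"] = tuple(
            ev if isinstance(ev, simulate.CnvEvent) else simulate.CnvEvent(**ev)
            for ev in events
        )
    if specs is not None:
        kwargs["variant_specs"] = tuple(
            s if isinstance(s, simulate.VariantSpec) else simulate.VariantSpec(**s)
            for s in specs
        )
    kwargs.setdefault("seed", cfg.get("seed", 0))
    kwargs["seed"] = int(kwargs["seed"])
    return simulate.SimConfig(**kwargs)


def run_pipeline(config, outdir) -> dict:
    """Run every configured stage in dependency order; return the RunReport.

    Artifacts land under ``outdir/<stage>/``; the report (parameter echo,
    per-stage input/output summaries, seed, version) is written to
    ``outdir/report.json`` and a checksum manifest to ``outdir/manifest.json``.
    """
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {"version": __version__, "seed": seed, "stages": {}, "config": cfg}

    # --- simulate -------------------------------------------------------
    try:
        sim_cfg = _sim_config(cfg)
        adata, truth = simulate.simulate_counts(sim_cfg)
        rsio.write_counts_dir(adata, out / "simulate")
        rsio.write_tsv(truth.events, out / "simulate" / "truth_events.tsv")
        allele_counts, snps = simulate.simulate_allele_counts(sim_cfg, truth)
        rsio.write_tsv(allele_counts, out / "simulate" / "allele_counts.tsv")
        rsio.write_tsv(snps, out / "simulate" / "snps.tsv")
        have_variants = bool(sim_cfg.variant_specs)
        if have_variants:
            variants = simulate.simulate_variants(sim_cfg)
            rsio.write_tsv(variants, out / "simulate" / "variants.tsv")
        report["stages"]["simulate"] = {
            "n_cells": int(adata.n_obs), "n_features": int(adata.n_vars),
            "n_clean_cells": int(truth.cells["clean"].sum()),
            "n_cnv_events": len(truth.events),
            "n_variants": len(sim_cfg.variant_specs),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # --- qc -------------------------------------------------------------
    try:
        thr = qc.QCThresholds(**(cfg.get("qc") or {}))
        filtered, qc_report = qc.qc_filter(adata, thr)
        metrics = qc.compute_qc_metrics(adata)
        rsio.write_tsv(metrics.reset_index(), out / "qc" / "qc_metrics.tsv")
        rsio.write_json(qc_report, out / "qc" / "qc_report.json")
        norm = qc.normalize(filtered)
        norm_df = pd.DataFrame(norm.X, index=norm.obs_names, columns=norm.var_names)
        rsio.write_tsv(norm_df.reset_index(), out / "qc" / "normalized.tsv")
        report["stages"]["qc"] = qc_report
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e

    # --- clonal ---------------------------------------------------------
    if have_variants:
        try:
            cl = cfg["clonal"]
            results = clonal.test_vaf_shifts(
                variants, min_alt=cl["min_alt"], min_vaf=cl["min_vaf"],
                report_vaf=cl["report_vaf"], alpha=cl["alpha"],
            )
            rsio.write_tsv(results, out / "clonal" / "vaf_tests.tsv")
            onco = variants[["variant_id"]].copy()
            for tp in ("dx", "re"):
                onco[f"status_{tp}"] = [
                    "square" if clonal.detect_variant(a, r, cl["min_alt"], cl["min_vaf"])
                    else "triangle"
                    for a, r in zip(variants[f"alt_{tp}"], variants[f"ref_{tp}"])
                ]
            rsio.write_tsv(onco, out / "clonal" / "oncoplot_status.tsv")
            report["stages"]["clonal"] = {
                "n_variants_in": len(variants),
                "n_tested": len(results),
                "n_reportable": int(results["reportable"].sum()) if len(results) else 0,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("clonal", e) from e
    else:
        report["stages"]["clonal"] = {"skipped": "no variant_specs configured"}

    # --- icnv -----------------------------------------------------------
    try:
        ic = cfg["icnv"]
        nuclear = norm.var["feature_type"] == "gene"
        ann = norm.var.loc[nuclear, ["chrom", "start", "end"]]
        chrom_lengths = {
            k: v for k, v in adata.uns["chrom_lengths"].items()
            if k not in ("chrM", "ERCC")
        }
        tiles = cnv.build_tiles(ann, chrom_lengths, tile_size=ic["tile_size"])
        tp = norm.obs["timepoint"]
        target_cells = list(norm.obs_names[tp == ic["target"]])
        reference_cells = list(norm.obs_names[tp == ic["reference"]])
        nuclear_df = pd.DataFrame(
            norm.X[:, nuclear.to_numpy()], index=norm.obs_names,
            columns=norm.var_names[nuclear.to_numpy()],
        )
        tm = cnv.icnv_signal(
            nuclear_df, tiles, reference_cells,
            min_genes_per_tile=ic["min_genes_per_tile"],
            clip=ic["clip"], smooth_window=ic["smooth_window"],
        )
        segs = cnv.call_segments(
            tm, target_cells, gain_thr=ic["gain_thr"], loss_thr=ic["loss_thr"],
            min_tiles=ic["min_tiles"], min_cell_frac=ic["min_cell_frac"],
        )
        rsio.write_segments_bed(segs, out / "icnv" / "segments.bed")
        rsio.write_tsv(
            tm.signal.T.reset_index().rename(columns={"index": "tile_id"}),
            out / "icnv" / "tile_signal.tsv",
        )
        baf_rows = []
        for seg in segs:
            baf = cnv.baf_confirm(
                allele_counts, (seg.chrom, seg.start, seg.end),
                target_cells, reference_cells,
            )
            baf_rows.append(
                {
                    "segment": f"{seg.chrom}:{seg.start}-{seg.end}", "state": seg.state,
                    "n_snps": baf.n_snps, "target_deviation": baf.target_deviation,
                    "reference_deviation": baf.reference_deviation, "status": baf.status,
                }
            )
        rsio.write_tsv(pd.DataFrame(baf_rows), out / "icnv" / "baf_confirmation.tsv")
        report["stages"]["icnv"] = {
            "n_tiles": len(tm.tiles), "n_segments": len(segs),
            "n_confirmed": sum(r["status"] == "confirmed" for r in baf_rows),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("icnv", e) from e

    # --- score ----------------------------------------------------------
    try:
        sg = cfg["signatures"]
        sig = (
            signatures.load_signature(sg["signature_file"])
            if sg.get("signature_file")
            else signatures.load_lsc17()
        )
        lsc_scores = signatures.score_weighted_signature(norm, sig)
        cc = signatures.cell_cycle_score(
            norm, n_bins=sg["n_bins"], n_ctrl=sg["n_ctrl"], seed=seed
        )
        scores = pd.DataFrame({"lsc17": lsc_scores}).join(cc)
        rsio.write_tsv(scores.reset_index(), out / "score" / "signature_scores.tsv")
        cluster = norm.obs["cluster"].astype(str)
        ttab = signatures.compare_scores_by_group(lsc_scores, cluster)
        rsio.write_tsv(ttab, out / "score" / "lsc17_by_cluster.tsv")
        report["stages"]["score"] = {
            "n_cells": len(scores),
            "phase_counts": scores["phase"].value_counts().to_dict(),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("score", e) from e

    # --- markers --------------------------------------------------------
    try:
        mk = cfg["markers"]
        de = markers.find_markers(
            norm, norm.obs["timepoint"], group=ic["target"],
            reference=ic["reference"], min_pct=mk["min_pct"],
            min_abs_log2fc=mk["min_abs_log2fc"], alpha=mk["alpha"],
        )
        rsio.write_tsv(de, out / "markers" / "dx_vs_re.tsv")
        cl_markers = markers.find_markers(
            norm, norm.obs["cluster"].astype(str), min_pct=mk["min_pct"],
            min_abs_log2fc=mk["min_abs_log2fc"], alpha=mk["alpha"],
        )
        rsio.write_tsv(cl_markers, out / "markers" / "cluster_markers.tsv")
        seg_degs = cnv.degs_in_segments(de, segs, ann, alpha=mk["alpha"])
        rsio.write_tsv(seg_degs, out / "markers" / "degs_in_segments.tsv")
        report["stages"]["markers"] = {
            "n_de_dx_re": int((de["q"] < mk["alpha"]).sum()) if len(de) else 0,
            "n_cluster_marker_rows": len(cl_markers),
            "degs_in_segments": {
                row["segment"]: int(row["n_degs"]) for _, row in seg_degs.iterrows()
            },
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("markers", e) from e

    rsio.write_json(report, out / "report.json")
    rsio.write_json(manifest(out), out / "manifest.json")
    return report


def manifest(outdir) -> dict:
    """SHA-256 checksums of every artifact under ``outdir`` (sans manifest)."""
    out = Path(outdir)
    sums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            sums[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return sums


def config_template() -> str:
    """YAML text of the full default configuration."""
    cfg = load_config({})
    cfg["simulate"] = {
        f.name: getattr(simulate.SimConfig(), f.name)
        for f in dataclasses.fields(simulate.SimConfig)
        if f.name not in ("cnv_events", "variant_specs")
    }
    cfg["simulate"]["cnv_events"] = [
        dataclasses.asdict(ev) for ev in simulate.default_cnv_events()
    ]
    cfg["simulate"]["variant_specs"] = [
        dataclasses.asdict(v) for v in simulate.default_variant_specs()
    ]
    return yaml.safe_dump(cfg, sort_keys=False)
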