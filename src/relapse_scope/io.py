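"""Disk formats: MatrixMarket counts directory, variant TSV/VCF, allele TSVs.

The counts directory layout mirrors common gene x cell exchange formats:
``matrix.mtx`` (genes x cells, integer), ``genes.tsv`` (id, chrom, start,
end, strand, feature_type), ``barcodes.tsv`` and ``cell_metadata.tsv``.
All writers are deterministic (no timestamps, fixed float formatting) so
identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse


def write_counts_dir(adata: ad.AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(np.asarray(adata.X).T)  # genes x cells
    sio.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    genes = adata.var.reset_index()
    genes.columns = ["gene"] + list(genes.columns[1:])
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.reset_index().rename(columns={"index": "cell"}).to_csv(
        outdir / "cell_metadata.tsv", sep="\t", index=False
    )
    if "chrom_lengths" in adata.uns:
        with open(outdir / "chrom_lengths.json", "w") as fh:
            json.dump({k: int(v) for k, v in adata.uns["chrom_lengths"].items()}, fh,
                      sort_keys=True, indent=0)


def read_counts_dir(indir) -> ad.AnnData:
    indir = Path(indir)
    X = np.asarray(sio.mmread(indir / "matrix.mtx").todense()).T  # cells x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    adata = ad.AnnData(
        X=X.astype(np.int32),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell")),
        var=genes,
    )
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell")
        adata.obs = meta.reindex(adata.obs_names)
    cl = indir / "chrom_lengths.json"
    if cl.exists():
        with open(cl) as fh:
            adata.uns["chrom_lengths"] = json.load(fh)
    return adata


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants_vcf(variants: pd.DataFrame, path, timepoint: str) -> None:
    """Minimal single-sample VCF with the AD FORMAT field for one timepoint."""
    tp = timepoint.lower()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for _, row in variants.iterrows():
            ref, alt = int(row[f"ref_{tp}"]), int(row[f"alt_{tp}"])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['variant_id']}\t"
                f"N\tA\t.\tPASS\t.\tAD\t{ref},{alt}\n"
            )


def read_variants_vcf_pair(dx_path, re_path) -> pd.DataFrame:
    """Merge Dx and Re single-sample VCFs (AD field) into the variant table.

    The first AD value is the REF depth, the remainder are summed as ALT.
    Records are matched by variant ID when present, else by chrom:pos.
    """
    import pysam

    def load(path, tp):
        rows = {}
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                sample = rec.samples[list(rec.samples)[0]]
                ad_field = sample.get("AD")
                if ad_field is None:
                    continue
                key = rec.id or f"{rec.chrom}:{rec.pos}"
                rows[key] = {
                    "variant_id": key, "chrom": rec.chrom, "pos": rec.pos - 1,
                    f"ref_{tp}": int(ad_field[0]),
                    f"alt_{tp}": int(sum(ad_field[1:])),
                }
        return rows

    dx, re_ = load(dx_path, "dx"), load(re_path, "re")
    keys = sorted(set(dx) | set(re_))
    rows = []
    for k in keys:
        row = {"variant_id": k, "ref_dx": 0, "alt_dx": 0, "ref_re": 0, "alt_re": 0}
        row.update(dx.get(k, {}))
        row.update(re_.get(k, {}))
        rows.append(row)
    return pd.DataFrame(rows)


def write_segments_bed(segments, path) -> None:
    """Segments as BED: chrom, start, end, name=state, score=mean signal."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.state}\t"
                f"{seg.mean_signal:.4f}\t.\n"
            )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
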