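import warnings

import pandas as pd
import pytest

from relapse_scope import cnv, qc
from relapse_scope.simulate import SimConfig, simulate_allele_counts, simulate_counts

# tile/BAF warnings from small tiles are expected noise in fixtures
warnings.filterwarnings("ignore", message="tile .* has <")


@pytest.fixture(scope="session")
def default_sim():
    """One full-size paired Dx/Re simulation shared across the suite."""
    config = SimConfig(seed=11)
    adata, truth = simulate_counts(config)
    return config, adata, truth


@pytest.fixture(scope="session")
def normalized(default_sim):
    """QC-filtered, log-normalized view of the shared simulation."""
    _, adata, _ = default_sim
    filtered, _ = qc.qc_filter(adata)
    return qc.normalize(filtered)


@pytest.fixture(scope="session")
def allele_counts(default_sim):
    config, _, truth = default_sim
    return simulate_allele_counts(config, truth)


@pytest.fixture(scope="session")
def tile_matrix(default_sim, normalized):
    """iCNV signal of the shared simulation (Re scanned against Dx)."""
    _, adata, _ = default_sim
    norm = normalized
    nuclear = (norm.var["feature_type"] == "gene").to_numpy()
    annotation = norm.var.loc[nuclear, ["chrom", "start", "end"]]
    chrom_lengths = {
        k: v for k, v in adata.uns["chrom_lengths"].items() if k not in ("chrM", "ERCC")
    }
    tiles = cnv.build_tiles(annotation, chrom_lengths)
    expr = pd.DataFrame(
        norm.X[:, nuclear], index=norm.obs_names, columns=norm.var_names[nuclear]
    )
    reference = list(norm.obs_names[norm.obs["timepoint"] == "Dx"])
    target = list(norm.obs_names[norm.obs["timepoint"] == "Re"])
    tm = cnv.icnv_signal(expr, tiles, reference)
    return tm, target, reference, annotation
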