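"""Tile construction, iCNV signal recovery, segment calls, BAF confirmation."""

import numpy as np
import pandas as pd
import pytest

from relapse_scope import cnv, markers, qc
from relapse_scope.simulate import simulate_counts, small_config


def _annotation(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end"],
        index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene"),
    )


class TestBuildTiles:
    def test_midpoint_half_open_assignment(self):
        ann = _annotation(
            [("chr1", 2_999_998, 3_000_000),  # midpoint 2,999,999 -> tile 0
             ("chr1", 3_000_000, 3_000_000 + 2)]  # midpoint 3,000,000 -> tile 1
        )
        idx = cnv.build_tiles(ann, {"chr1": 10_000_000})
        assert idx.gene_tile["g0"] == "chr1:0"
        assert idx.gene_tile["g1"] == "chr1:1"

    def test_last_tile_truncated_to_chromosome(self):
        idx = cnv.build_tiles(_annotation([("chr1", 0, 2)]), {"chr1": 10_000_000})
        widths = (idx.tiles["end"] - idx.tiles["start"]).tolist()
        assert widths == [3_000_000, 3_000_000, 3_000_000, 1_000_000]

    def test_gene_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="undeclared chromosome"):
            cnv.build_tiles(_annotation([("chrX", 0, 2)]), {"chr1": 10_000_000})
        with pytest.raises(ValueError, match="beyond"):
            cnv.build_tiles(
                _annotation([("chr1", 9_999_999, 10_000_005)]), {"chr1": 10_000_000}
            )


class TestICnvSignal:
    def test_reference_cells_center_near_zero(self, tile_matrix):
        tm, _, reference, _ = tile_matrix
        ref_means = tm.raw.loc[reference].mean(axis=0)
        assert ref_means.abs().max() < 0.05

    @pytest.mark.parametrize("kind, expected", [("gain", np.log2(1.5)), ("loss", -1.0)])
    def test_planted_event_signal_matches_log2_ratio(
        self, default_sim, tile_matrix, kind, expected
    ):
        _, _, truth = default_sim
        tm, target, _, _ = tile_matrix
        ev = truth.events[truth.events["kind"] == kind].iloc[0]
        in_ev = [
            t for t in tm.tiles["tile_id"]
            if tm.tiles.loc[t, "chrom"] == ev["chrom"]
            and tm.tiles.loc[t, "start"] >= ev["start"]
            and tm.tiles.loc[t, "end"] <= ev["end"]
        ]
        per_cell = tm.raw.loc[target, in_ev].mean(axis=1)
        sem = per_cell.std(ddof=1) / np.sqrt(len(per_cell))
        assert abs(per_cell.mean() - expected) < 3 * sem

    def test_depth_scaling_leaves_signal_unchanged(self, tile_matrix, normalized):
        """Library-size normalization makes the tile signal depth-invariant."""
        tm, _, reference, _ = tile_matrix
        norm = normalized
        nuclear = (norm.var["feature_type"] == "gene").to_numpy()
        counts = norm.layers["counts"]  # all non-ERCC features
        tripled = np.log1p(
            3 * counts / (3 * counts.sum(axis=1, keepdims=True)) * 10_000
        )[:, nuclear]
        expr = pd.DataFrame(tripled, index=norm.obs_names, columns=norm.var_names[nuclear])
        chrom_lengths = {f"chr{i+1}": 60_000_000 for i in range(4)}
        tiles = cnv.build_tiles(
            norm.var.loc[nuclear, ["chrom", "start", "end"]], chrom_lengths
        )
        tm2 = cnv.icnv_signal(expr, tiles, reference)
        np.testing.assert_allclose(tm2.raw.to_numpy(), tm.raw.to_numpy(), atol=1e-9)

    def test_empty_reference_rejected(self, normalized):
        with pytest.raises(ValueError, match="reference_cells"):
            cnv.icnv_signal(pd.DataFrame(np.ones((2, 2))), None, [])


class TestCallSegments:
    def test_all_zero_signal_yields_no_calls(self):
        tiles = pd.DataFrame(
            {"tile_id": [f"chr1:{i}" for i in range(10)], "chrom": "chr1",
             "start": np.arange(10) * 3_000_000, "end": (np.arange(10) + 1) * 3_000_000}
        ).set_index("tile_id", drop=False)
        zeros = pd.DataFrame(
            np.zeros((5, 10)), index=[f"c{i}" for i in range(5)], columns=tiles.index
        )
        tm = cnv.TileMatrix(signal=zeros, raw=zeros, tiles=tiles, reference_cells=[])
        assert cnv.call_segments(tm, [f"c{i}" for i in range(5)]) == []

    def test_bad_thresholds_rejected(self, tile_matrix):
        tm, target, _, _ = tile_matrix
        with pytest.raises(ValueError, match="gain_thr"):
            cnv.call_segments(tm, target, gain_thr=-0.2, loss_thr=0.2)

    def test_planted_events_called_within_one_tile(self, default_sim, tile_matrix):
        _, _, truth = default_sim
        tm, target, _, _ = tile_matrix
        segs = cnv.call_segments(tm, target)
        by_state = {s.state: s for s in segs}
        assert set(by_state) == {"gain", "loss"}
        for kind in ("gain", "loss"):
            ev = truth.events[truth.events["kind"] == kind].iloc[0]
            seg = by_state[kind]
            assert seg.chrom == ev["chrom"]
            assert abs(seg.start - ev["start"]) <= cnv.TILE_SIZE
            assert abs(seg.end - ev["end"]) <= cnv.TILE_SIZE
            assert seg.affected_fraction >= 0.95

    def test_copy_neutral_loh_is_expression_silent(self, default_sim, tile_matrix):
        """No iCNV segment may be called on the LOH chromosome: dosage is
        unchanged, only allele fractions shift."""
        _, _, truth = default_sim
        tm, target, _, _ = tile_matrix
        loh = truth.events[truth.events["kind"] == "loh"].iloc[0]
        segs = cnv.call_segments(tm, target)
        assert all(s.chrom != loh["chrom"] for s in segs)

    def test_target_reference_swap_negates_segment_signal(self, default_sim, normalized):
        _, adata, truth = default_sim
        norm = normalized
        nuclear = (norm.var["feature_type"] == "gene").to_numpy()
        expr = pd.DataFrame(
            norm.X[:, nuclear], index=norm.obs_names, columns=norm.var_names[nuclear]
        )
        chrom_lengths = {
            k: v for k, v in adata.uns["chrom_lengths"].items()
            if k not in ("chrM", "ERCC")
        }
        tiles = cnv.build_tiles(norm.var.loc[nuclear, ["chrom", "start", "end"]], chrom_lengths)
        dx = list(norm.obs_names[norm.obs["timepoint"] == "Dx"])
        re_ = list(norm.obs_names[norm.obs["timepoint"] == "Re"])
        fwd = cnv.icnv_signal(expr, tiles, reference_cells=dx)
        rev = cnv.icnv_signal(expr, tiles, reference_cells=re_)
        ev = truth.events[truth.events["kind"] == "gain"].iloc[0]
        in_ev = [
            t for t in fwd.tiles["tile_id"]
            if fwd.tiles.loc[t, "chrom"] == ev["chrom"]
            and fwd.tiles.loc[t, "start"] >= ev["start"]
            and fwd.tiles.loc[t, "end"] <= ev["end"]
        ]
        s_fwd = fwd.raw.loc[re_, in_ev].to_numpy().mean()
        s_rev = rev.raw.loc[dx, in_ev].to_numpy().mean()
        assert s_fwd > 0.4 and s_rev < -0.4
        assert abs(s_fwd + s_rev) < 0.2


class TestBafConfirm:
    def test_diploid_region_not_confirmed(self, default_sim, allele_counts):
        _, _, truth = default_sim
        ac, _ = allele_counts
        cells = truth.cells.index
        dx = cells[truth.cells["timepoint"] == "Dx"]
        re_ = cells[truth.cells["timepoint"] == "Re"]
        baf = cnv.baf_confirm(ac, ("chr4", 0, 60_000_000), re_, dx)
        assert baf.status == "not_confirmed"
        assert baf.target_deviation < 0.1

    @pytest.mark.parametrize("kind, expected_dev", [("loss", 0.5), ("loh", 0.5),
                                                    ("gain", 1 / 6)])
    def test_planted_imbalance_confirmed_with_expected_deviation(
        self, default_sim, allele_counts, kind, expected_dev
    ):
        _, _, truth = default_sim
        ac, _ = allele_counts
        ev = truth.events[truth.events["kind"] == kind].iloc[0]
        carriers = truth.cells.index[truth.cells[f"cnv_{ev['name']}"]]
        dx = truth.cells.index[truth.cells["timepoint"] == "Dx"]
        baf = cnv.baf_confirm(ac, (ev["chrom"], ev["start"], ev["end"]), carriers, dx)
        assert baf.status == "confirmed"
        assert baf.target_deviation == pytest.approx(expected_dev, abs=0.06)
        assert baf.reference_deviation < 0.1

    def test_insufficient_snps_is_unconfirmable_not_false(self, default_sim, allele_counts):
        _, _, truth = default_sim
        ac, _ = allele_counts
        cells = truth.cells.index
        baf = cnv.baf_confirm(ac, ("chr1", 0, 1000), cells, cells)
        assert baf.status == "unconfirmable"
        assert not baf.confirmed

    def test_folded_deviation_is_phase_invariant(self, default_sim, allele_counts):
        """Swapping ref/alt (haplotype relabeling) leaves |f - 0.5| fixed."""
        _, _, truth = default_sim
        ac, _ = allele_counts
        ev = truth.events[truth.events["kind"] == "loh"].iloc[0]
        carriers = truth.cells.index[truth.cells[f"cnv_{ev['name']}"]]
        dx = truth.cells.index[truth.cells["timepoint"] == "Dx"]
        flipped = ac.rename(columns={"ref_count": "alt_count", "alt_count": "ref_count"})
        b1 = cnv.baf_confirm(ac, (ev["chrom"], ev["start"], ev["end"]), carriers, dx)
        b2 = cnv.baf_confirm(flipped, (ev["chrom"], ev["start"], ev["end"]), carriers, dx)
        assert b1.target_deviation == pytest.approx(b2.target_deviation, abs=1e-12)


class TestDegsInSegments:
    def test_no_segments_empty(self):
        out = cnv.degs_in_segments(
            pd.DataFrame(columns=["gene", "log2fc", "q"]), [], _annotation([])
        )
        assert out.empty

    def test_deg_outside_segments_never_counted(self):
        ann = _annotation([("chr1", 0, 100), ("chr2", 0, 100)])
        seg = cnv.SegmentCall("chr1", 0, 3_000_000, "gain", ["chr1:0"], 0.6, 1.0)
        mk = pd.DataFrame(
            {"gene": ["g0", "g1"], "log2fc": [1.0, 1.0], "q": [0.001, 0.001]}
        )
        out = cnv.degs_in_segments(mk, [seg], ann)
        assert out.loc[0, "n_degs"] == 1
        assert out.loc[0, "genes"] == "g0"

    def test_planted_gain_genes_recovered_as_up_degs(self, default_sim, normalized, tile_matrix):
        """Most expressed genes inside the planted gain come out as Re-up DEGs."""
        _, _, truth = default_sim
        norm = normalized
        tm, target, _, ann = tile_matrix
        segs = cnv.call_segments(tm, target)
        gain = [s for s in segs if s.state == "gain"][0]
        de = markers.find_markers(
            norm, norm.obs["timepoint"], group="Re", reference="Dx"
        )
        out = cnv.degs_in_segments(de, [gain], ann)
        genes = truth.genes
        mid = (genes["start"] + genes["end"]) // 2
        member = genes[
            (genes["feature_type"] == "gene")
            & (genes["chrom"] == gain.chrom)
            & (mid >= gain.start) & (mid < gain.end)
        ].index
        counts = norm.layers["counts"]
        expressed = [
            g for g in member
            if counts[:, list(norm.var_names).index(g)].mean() >= 0.5
        ]
        hit = set(out.loc[0, "genes"].split(","))
        up_hits = de[(de["gene"].isin(hit)) & (de["log2fc"] > 0)]["gene"]
        recovered = np.mean([g in set(up_hits) for g in expressed])
        assert recovered >= 0.8
        assert out.loc[0, "n_direction_consistent"] >= 0.8 * out.loc[0, "n_degs"]
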