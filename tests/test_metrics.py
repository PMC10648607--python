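"""Tests for degree-of-splicing counting, the constrained variant, overall
splicing and binned abundance distributions, each against an independent
brute-force oracle."""

import warnings

import numpy as np
import pandas as pd
import pytest

from splicedegree import (
    BinSpec,
    IsoformAbundanceMatrix,
    bin_distribution,
    degree_of_splicing,
    make_log_bins,
    overall_splicing,
    restrict_nonzero,
)

from conftest import random_tpm_matrix


def brute_force_ds(matrix: IsoformAbundanceMatrix, thr: float) -> pd.DataFrame:
    """Double loop over genes and samples (oracle)."""
    genes = sorted(matrix.gene_of.unique())
    out = pd.DataFrame(0, index=genes, columns=matrix.sample_ids, dtype=int)
    for tx in matrix.transcript_ids:
        g = matrix.gene_of[tx]
        for s in matrix.sample_ids:
            if matrix.tpm.loc[tx, s] > thr:
                out.loc[g, s] += 1
    return out


class TestDegreeOfSplicing:
    def test_strict_threshold_hand_example(self):
        """Isoform TPMs [12, 0.5, 0.2]: one isoform above 10, three above
        0.1 (strict inequality)."""
        tpm = pd.DataFrame({"s": [12.0, 0.5, 0.2]},
                           index=pd.Index(["a", "b", "c"], name="transcript_id"))
        t2g = pd.DataFrame({"gene_id": ["g"] * 3, "biotype": ["protein_coding"] * 3},
                           index=tpm.index)
        m = IsoformAbundanceMatrix(tpm, t2g)
        assert degree_of_splicing(m, 10).ds.loc["g", "s"] == 1
        assert degree_of_splicing(m, 0.1).ds.loc["g", "s"] == 3
        # a value exactly at the threshold does not count
        assert degree_of_splicing(m, 12).ds.loc["g", "s"] == 0

    def test_all_zero_column_gives_zero_ds(self, tiny_matrix):
        ds = degree_of_splicing(tiny_matrix, 0.1)
        assert ds.ds.loc["gA", "s2"] == 0

    def test_matches_brute_force_and_is_threshold_monotone(self):
        rng = np.random.default_rng(2024)
        m = random_tpm_matrix(rng, n_genes=200, n_samples=11)
        previous = None
        for thr in (10.0, 1.0, 0.1):
            ds = degree_of_splicing(m, thr)
            pd.testing.assert_frame_equal(
                ds.ds, brute_force_ds(m, thr), check_names=False
            )
            if previous is not None:
                assert (ds.ds.to_numpy() >= previous).all()
            previous = ds.ds.to_numpy()

    def test_all_zero_gene_rows_retained(self, tiny_matrix):
        ds = degree_of_splicing(tiny_matrix, 1e9)
        assert set(ds.ds.index) == {"gA", "gB"}
        assert (ds.ds.to_numpy() == 0).all()


class TestRestrictNonzero:
    def test_gene_with_any_zero_excluded(self, tiny_matrix):
        ds = degree_of_splicing(tiny_matrix, 0.1)  # gA zero in s2
        kept = restrict_nonzero(ds)
        assert list(kept.ds.index) == ["gB"]

    def test_identity_when_all_positive(self, tiny_matrix):
        ds = degree_of_splicing(tiny_matrix, 0.1)
        sub = restrict_nonzero(ds)
        pd.testing.assert_frame_equal(restrict_nonzero(sub).ds, sub.ds)

    def test_matches_row_min_scan_on_random_matrix(self):
        rng = np.random.default_rng(7)
        m = random_tpm_matrix(rng, n_genes=150, n_samples=11)
        ds = degree_of_splicing(m, 1.0)
        expected = [g for g in ds.ds.index if min(ds.ds.loc[g]) > 0]
        assert list(restrict_nonzero(ds).ds.index) == expected

    def test_empty_result_warns_not_raises(self, tiny_matrix):
        ds = degree_of_splicing(tiny_matrix, 1e9)
        with pytest.warns(UserWarning, match="empty"):
            out = restrict_nonzero(ds)
        assert out.ds.empty


class TestOverallSplicing:
    def test_single_sample_hand_example(self):
        """Gene A with isoforms [50, 30], gene B with [20]: 3 isoforms over
        2 expressing genes = 1.5."""
        tpm = pd.DataFrame({"s": [50.0, 30.0, 20.0]},
                           index=pd.Index(["a1", "a2", "b1"], name="transcript_id"))
        t2g = pd.DataFrame({"gene_id": ["gA", "gA", "gB"],
                            "biotype": ["protein_coding"] * 3}, index=tpm.index)
        m = IsoformAbundanceMatrix(tpm, t2g)
        meta = pd.DataFrame({"sample_id": ["s"], "type": ["x"]})
        assert overall_splicing(m, meta, 0.1)["x"] == pytest.approx(1.5)

    def test_lower_bound_one_when_single_isoform_genes(self):
        tpm = pd.DataFrame({"s1": [5.0, 5.0], "s2": [5.0, 5.0]},
                           index=pd.Index(["a1", "b1"], name="transcript_id"))
        t2g = pd.DataFrame({"gene_id": ["gA", "gB"],
                            "biotype": ["protein_coding"] * 2}, index=tpm.index)
        m = IsoformAbundanceMatrix(tpm, t2g)
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "type": ["x", "x"]})
        assert overall_splicing(m, meta, 0.1)["x"] == pytest.approx(1.0)

    def test_matches_brute_force_on_scene(self, small_matrix, small_scene):
        result = overall_splicing(small_matrix, small_scene.metadata, 1.0)
        for type_label, group in small_scene.metadata.groupby("type"):
            iso, genes = [], []
            for s in group["sample_id"]:
                above = small_matrix.tpm[s] > 1.0
                iso.append(int(above.sum()))
                genes.append(small_matrix.gene_of[above].nunique())
            expected = np.mean(iso) / np.mean(genes)
            assert result[type_label] == pytest.approx(expected)
            assert result[type_label] >= 1.0

    def test_undefined_type_yields_nan_with_warning(self, tiny_matrix):
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "type": ["x", "y"]})
        with pytest.warns(UserWarning, match="undefined"):
            out = overall_splicing(tiny_matrix, meta, 1e9)
        assert np.isnan(out["x"]) and np.isnan(out["y"])


class TestBins:
    def test_default_first_bin_matches_printed_convention(self):
        spec = make_log_bins(0.1, 10 ** 0.5, 1e3)
        assert spec.edges[0] == pytest.approx(0.1)
        assert spec.edges[1] == pytest.approx(0.31622776, rel=1e-6)
        assert spec.labels()[0] == "(0.1, 0.316]"

    def test_stop_just_above_start_gives_two_edges(self):
        spec = make_log_bins(0.1, 10 ** 0.5, 0.11)
        assert spec.edges.size == 2

    def test_edges_strictly_increasing(self):
        spec = make_log_bins(0.5, 2.0, 100.0)
        assert (np.diff(spec.edges) > 0).all()
        assert spec.edges[-1] >= 100.0

    @pytest.mark.parametrize("args", [(0, 2, 10), (1, 1, 10), (1, 2, 0.5)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            make_log_bins(*args)


class TestBinDistribution:
    @staticmethod
    def _matrix_and_meta():
        tpm = pd.DataFrame(
            {"s1": [0.2, 5.0, 40.0, 0.05], "s2": [0.25, 6.0, 35.0, 0.0]},
            index=pd.Index(["a", "b", "c", "d"], name="transcript_id"),
        )
        t2g = pd.DataFrame({"gene_id": ["g1", "g1", "g2", "g2"],
                            "biotype": ["protein_coding"] * 4}, index=tpm.index)
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "type": ["x", "x"]})
        return IsoformAbundanceMatrix(tpm, t2g), meta

    def test_left_open_right_closed_assignment(self):
        """TPM 0.2 falls in (0.1, 0.316]; TPM 0.05 is below the first edge
        and excluded; a value equal to an edge belongs to the bin it
        closes."""
        m, meta = self._matrix_and_meta()
        spec = make_log_bins(0.1, 10 ** 0.5, 100.0)
        out = bin_distribution(m, meta, spec, mode="per_sample")
        first = out[out["bin"] == "(0.1, 0.316]"]
        assert first["mean_count"].iloc[0] == pytest.approx(1.0)
        edge_val = BinSpec(np.array([1.0, 2.0, 4.0]))
        counts = bin_distribution(
            m, meta, edge_val, mode="per_sample"
        )
        # isoform b: 5.0 and 6.0 are above the last edge -> excluded
        assert counts["mean_count"].sum() == 0

    def test_identical_samples_give_zero_width_ci(self):
        tpm = pd.DataFrame({"s1": [5.0, 0.2], "s2": [5.0, 0.2]},
                           index=pd.Index(["a", "b"], name="transcript_id"))
        t2g = pd.DataFrame({"gene_id": ["g", "g"],
                            "biotype": ["protein_coding"] * 2}, index=tpm.index)
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "type": ["x", "x"]})
        out = bin_distribution(IsoformAbundanceMatrix(tpm, t2g), meta,
                               make_log_bins(0.1, 10 ** 0.5, 100.0))
        assert (out["ci95_high"] - out["ci95_low"]).abs().max() == pytest.approx(0.0)

    def test_count_conservation_per_sample(self, small_matrix, small_scene):
        """Binned counts plus the below-first-edge and above-last-edge
        exclusions account for every detected isoform."""
        spec = make_log_bins(0.1, 10 ** 0.5, 1e7)
        meta = small_scene.metadata
        out = bin_distribution(small_matrix, meta, spec, mode="per_sample")
        for type_label, group in meta.groupby("type"):
            mean_total = out.loc[out["type"] == type_label, "mean_count"].sum()
            totals = []
            for s in group["sample_id"]:
                v = small_matrix.tpm[s].to_numpy()
                detected = (v > 0).sum()
                below = ((v > 0) & (v <= spec.edges[0])).sum()
                above = (v > spec.edges[-1]).sum()
                totals.append(detected - below - above)
            assert mean_total == pytest.approx(np.mean(totals))

    def test_per_isoform_mean_includes_zeros_in_the_mean(self):
        m, meta = self._matrix_and_meta()
        spec = BinSpec(np.array([0.01, 0.04, 0.1]))
        out = bin_distribution(m, meta, spec, mode="per_isoform_mean")
        # isoform d: mean of (0.05, 0.0) = 0.025 -> bin (0.01, 0.04]
        assert out.loc[out["bin"] == "(0.01, 0.04]", "mean_count"].iloc[0] == 1.0

    def test_modes_agree_when_samples_identical_within_type(self):
        tpm = pd.DataFrame({"s1": [5.0, 0.2, 50.0], "s2": [5.0, 0.2, 50.0]},
                           index=pd.Index(["a", "b", "c"], name="transcript_id"))
        t2g = pd.DataFrame({"gene_id": ["g"] * 3,
                            "biotype": ["protein_coding"] * 3}, index=tpm.index)
        m = IsoformAbundanceMatrix(tpm, t2g)
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "type": ["x", "x"]})
        spec = make_log_bins(0.1, 10 ** 0.5, 1e3)
        a = bin_distribution(m, meta, spec, mode="per_sample")
        b = bin_distribution(m, meta, spec, mode="per_isoform_mean")
        np.testing.assert_allclose(a["mean_count"], b["mean_count"])

    def test_single_sample_type_warns_and_reports_point_value(self):
        m, _ = self._matrix_and_meta()
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "type": ["x", "y"]})
        with pytest.warns(UserWarning, match="single sample"):
            out = bin_distribution(m, meta, make_log_bins(0.1, 10 ** 0.5, 100.0))
        assert (out["ci95_low"] == out["mean_count"]).all()
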