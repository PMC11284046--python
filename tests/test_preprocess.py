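"""I/O, standardization, concatenation, and splitting contracts."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caemgbdt.preprocess import (
    LabelVector,
    OmicsMatrix,
    OmicsValidationError,
    SampleStandardizer,
    concat_omics,
    load_labels,
    load_omics,
    split_samples,
    standardize,
)

from conftest import write_tsv


def _toy_matrix(n_features=3, n_samples=2, omics_type="gene_expression", prefix="f"):
    vals = np.arange(n_features * n_samples, dtype=float).reshape(n_features, n_samples)
    return OmicsMatrix(vals, [f"{prefix}{i}" for i in range(n_features)],
                       [f"s{j}" for j in range(n_samples)], omics_type)


class TestLoadOmics:
    def test_parses_feature_by_sample_tsv(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv", ["g1", "g2", "g3"], ["s1", "s2"],
                         [[1, 2], [3, 4], [5, 6]])
        mat = load_omics(path, "gene_expression")
        assert (mat.n_features, mat.n_samples) == (3, 2)
        assert mat.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(mat.values, [[1, 2], [3, 4], [5, 6]])

    def test_transposed_orientation_gives_identical_matrix(self, tmp_path):
        a = write_tsv(tmp_path / "a.tsv", ["g1", "g2", "g3"], ["s1", "s2"],
                      [[1, 2], [3, 4], [5, 6]])
        b = write_tsv(tmp_path / "b.tsv", ["s1", "s2"], ["g1", "g2", "g3"],
                      [[1, 3, 5], [2, 4, 6]])
        ma = load_omics(a, "gene_expression")
        mb = load_omics(b, "gene_expression", orientation="samples_by_features")
        np.testing.assert_array_equal(ma.values, mb.values)
        assert ma.feature_ids == mb.feature_ids
        assert ma.sample_ids == mb.sample_ids

    def test_na_cell_names_the_offender(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv", ["g1", "g2"], ["s1", "s2"],
                         [[1, 2], ["NA", 4]])
        with pytest.raises(OmicsValidationError, match="g2.*s1"):
            load_omics(path)

    def test_csv_and_gzip_dialects(self, tmp_path):
        csv = write_tsv(tmp_path / "m.csv", ["g1", "g2"], ["s1", "s2"],
                        [[1, 2], [3, 4]], sep=",")
        assert load_omics(csv).n_features == 2
        gz = tmp_path / "m.tsv.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write("id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\n")
        np.testing.assert_array_equal(load_omics(gz).values, [[1, 2], [3, 4]])

    def test_duplicate_ids_rejected(self, tmp_path):
        path = write_tsv(tmp_path / "m.tsv", ["g1", "g1"], ["s1", "s2"],
                         [[1, 2], [3, 4]])
        with pytest.raises(OmicsValidationError, match="duplicate"):
            load_omics(path)


class TestConcat:
    def test_feature_dims_add_up(self):
        blocks = [_toy_matrix(5, 3, "gene_expression", "g"),
                  _toy_matrix(2, 3, "mirna_expression", "m"),
                  _toy_matrix(4, 3, "dna_methylation", "c")]
        merged = concat_omics(blocks)
        assert merged.n_features == 11
        assert [r for _, r in merged.blocks] == [(0, 5), (5, 7), (7, 11)]

    def test_single_block_identity(self):
        blk = _toy_matrix()
        assert concat_omics([blk]) is blk

    def test_sample_order_follows_first_block(self):
        a = _toy_matrix(2, 3, "gene_expression", "g")
        vals = np.array([[9.0, 7.0, 8.0]])
        b = OmicsMatrix(vals, ["m0"], ["s2", "s0", "s1"], "mirna_expression")
        merged = concat_omics([a, b])
        assert merged.sample_ids == ["s0", "s1", "s2"]
        np.testing.assert_array_equal(merged.values[2], [7.0, 8.0, 9.0])

    def test_disjoint_samples_raise_with_symmetric_difference(self):
        a = _toy_matrix(2, 2, "gene_expression", "g")
        b = OmicsMatrix(np.ones((1, 2)), ["m0"], ["x0", "x1"], "mirna_expression")
        with pytest.raises(OmicsValidationError, match="symmetric difference"):
            concat_omics([a, b])

    def test_slicing_recorded_ranges_recovers_blocks(self, tiny_dataset):
        blocks, _, _ = tiny_dataset
        merged = concat_omics(blocks)
        for blk, (otype, (lo, hi)) in zip(blocks, merged.blocks):
            assert otype == blk.omics_type
            np.testing.assert_array_equal(merged.values[lo:hi], blk.values)


class TestStandardize:
    def test_row_123(self):
        out = standardize(np.array([[1.0, 2.0, 3.0]])).values
        np.testing.assert_allclose(out, [[-1.224745, 0.0, 1.224745]], atol=1e-6)

    def test_population_denominator_not_sample(self):
        # sigma with denominator n is sqrt(2/3); the n-1 variant (sqrt(1))
        # would give +-1.0 at the endpoints and must NOT be produced
        out = standardize(np.array([[1.0, 2.0, 3.0]])).values
        assert abs(out[0, 2] - 1.224745) < 1e-6
        assert abs(out[0, 2] - 1.0) > 0.2

    def test_constant_row_maps_to_zeros(self):
        out = standardize(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])).values
        np.testing.assert_array_equal(out[0], 0.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=40))
    def test_rows_have_zero_mean_unit_sd_and_idempotence(self, row):
        X = np.array([row])
        out = standardize(X).values
        sd = np.std(row)
        if sd == 0:
            np.testing.assert_array_equal(out, 0.0)
        elif sd > 1e-7:  # away from catastrophic-cancellation territory
            assert abs(out.mean()) < 1e-9
            assert abs(out.std(ddof=0) - 1.0) < 1e-6
            np.testing.assert_allclose(standardize(out).values, out, atol=1e-9)

    def test_per_feature_option(self):
        X = np.array([[1.0, 10.0], [3.0, 30.0]])
        scaler = SampleStandardizer(per_feature=True).fit(X)
        out = scaler.transform(X)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-12)


class TestSplits:
    def _labels(self, n, k=2, seed=0):
        rng = np.random.default_rng(seed)
        reps = np.repeat(np.arange(k), -(-n // k))[:n]
        y = reps[rng.permutation(n)]
        return LabelVector([f"s{i}" for i in range(n)], y,
                           [f"c{j}" for j in range(k)])

    def test_five_fold_partitions_evenly(self):
        labels = self._labels(10)
        folds = split_samples(10, labels, "five_fold", seed=3)
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [2, 2, 2, 2, 2]
        all_test = np.sort(np.concatenate([te for _, te in folds]))
        np.testing.assert_array_equal(all_test, np.arange(10))

    def test_five_fold_disjoint_for_any_seed(self):
        labels = self._labels(23, k=3)
        for seed in (0, 1, 7):
            folds = split_samples(23, labels, "five_fold", seed=seed)
            covered = np.concatenate([te for _, te in folds])
            assert len(covered) == 23 and len(set(covered.tolist())) == 23
            sizes = [len(te) for _, te in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_ratio_3_1_test_size(self):
        labels = self._labels(104, k=4)
        ((tr, te),) = split_samples(104, labels, "ratio_3_1", seed=0)
        assert len(te) == 26
        assert len(tr) == 78

    def test_same_seed_reproduces_split(self):
        labels = self._labels(40, k=4)
        a = split_samples(40, labels, "five_fold", seed=11)
        b = split_samples(40, labels, "five_fold", seed=11)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)
            np.testing.assert_array_equal(tra, trb)

    def test_stratification_keeps_class_balance(self):
        labels = self._labels(100, k=4, seed=5)
        folds = split_samples(100, labels, "five_fold", seed=1)
        for _, te in folds:
            counts = np.bincount(labels.labels[te], minlength=4)
            assert counts.min() >= 4  # 5 per class expected, allow 1 slack


def test_load_labels_roundtrip(tmp_path):
    path = tmp_path / "labels.tsv"
    path.write_text("sample_id\tsubtype\ns0\tlumA\ns1\tbasal\ns2\tlumA\n")
    lv = load_labels(path)
    assert lv.class_names == ["basal", "lumA"]
    np.testing.assert_array_equal(lv.labels, [1, 0, 1])
    reordered = lv.reorder(["s2", "s0", "s1"])
    np.testing.assert_array_equal(reordered.labels, [1, 1, 0])
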