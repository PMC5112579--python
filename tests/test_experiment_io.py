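"""Container semantics, subsetting alignment, and on-disk round trips."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from scworkflow import (
    IdMapping,
    build_experiment,
    load_bundle,
    map_ids,
    read_counts,
    save_bundle,
    write_counts,
    write_table,
)


class TestBuild:
    def test_hand_matrix_dims(self):
        exp = build_experiment(np.arange(6).reshape(3, 2))
        assert exp.dims == (3, 2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_experiment(np.array([[1, -1], [0, 2]]))

    def test_empty_cell_set_rejected(self):
        with pytest.raises(ValueError):
            build_experiment(np.zeros((3, 0)))

    def test_metadata_dimension_mismatch(self):
        with pytest.raises(ValueError, match="metadata"):
            build_experiment(np.ones((3, 2)), feature_meta=["a", "b"])

    def test_duplicate_feature_ids_warn(self):
        with pytest.warns(UserWarning, match="duplicate"):
            build_experiment(np.ones((2, 2)), feature_meta=["a", "a"])


class TestSpikeSets:
    def test_declare_and_mask(self, spiked_exp):
        assert spiked_exp.spike_sets == {"ERCC": False}
        assert spiked_exp.spike_mask().sum() == 5
        assert spiked_exp.endogenous_mask.sum() == 20

    def test_unknown_set_rejected(self, spiked_exp):
        with pytest.raises(KeyError, match="unknown"):
            spiked_exp.declare_spike_set("nope")

    def test_overlapping_spike_sets_rejected(self, spiked_exp):
        mask = np.zeros(25, dtype=bool)
        mask[22] = True  # already in ERCC
        spiked_exp.control_sets["other"] = mask
        with pytest.raises(ValueError, match="overlap"):
            spiked_exp.declare_spike_set("other")


class TestSubset:
    def test_cell_subset_aligns_all_slots(self, spiked_exp):
        spiked_exp.size_factors = np.linspace(0.5, 1.5, 30)
        keep = np.arange(30) < 10
        sub = spiked_exp.subset(cell_mask=keep)
        assert sub.dims == (25, 10)
        assert len(sub.cell_table) == 10
        np.testing.assert_array_equal(sub.size_factors, spiked_exp.size_factors[:10])
        # factors carried as-is, not re-centred
        assert sub.size_factors.mean() != pytest.approx(1.0)

    def test_identity_mask(self, tiny_exp):
        sub = tiny_exp.subset(cell_mask=np.ones(2, dtype=bool))
        np.testing.assert_array_equal(sub.dense_counts(), tiny_exp.dense_counts())

    def test_feature_mask_removes_low_spikes_too(self, spiked_exp):
        keep = np.ones(25, dtype=bool)
        keep[21] = False  # drop one spike row like a mean filter would
        sub = spiked_exp.subset(feature_mask=keep)
        assert sub.n_features == 24
        assert sub.spike_mask().sum() == 4

    def test_all_false_mask_rejected(self, tiny_exp):
        with pytest.raises(ValueError):
            tiny_exp.subset(cell_mask=np.zeros(2, dtype=bool))

    @given(
        m1=st.lists(st.booleans(), min_size=8, max_size=8),
        m2=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    def test_subset_composition(self, m1, m2):
        """subset(subset(e, m1), m2) equals subset(e, composed mask)."""
        m1, m2 = np.array(m1), np.array(m2)
        composed = np.zeros(8, dtype=bool)
        if m1.any():
            composed[np.flatnonzero(m1)[m2[: m1.sum()]]] = True
        if not composed.any():
            return
        rng = np.random.default_rng(0)
        exp = build_experiment(rng.poisson(3, size=(5, 8)))
        step = exp.subset(cell_mask=m1).subset(cell_mask=m2[: m1.sum()])
        direct = exp.subset(cell_mask=composed)
        np.testing.assert_array_equal(step.dense_counts(), direct.dense_counts())


class TestIO:
    @pytest.mark.parametrize("fname", ["m.mtx", "m.tsv", "m.csv"])
    def test_integer_round_trip(self, tmp_path, rng, fname):
        mat = rng.integers(0, 50, size=(50, 20))
        path = tmp_path / fname
        write_counts(mat, [f"g{i}" for i in range(50)], [f"c{i}" for i in range(20)], path)
        back, fids, cids = read_counts(path)
        np.testing.assert_array_equal(np.asarray(back.todense()), mat)
        assert fids == [f"g{i}" for i in range(50)]
        assert cids == [f"c{i}" for i in range(20)]

    def test_delimited_excludes_label_row_and_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("\tcellA\tcellB\ngene1\t1\t2\ngene2\t3\t4\n")
        mat, fids, cids = read_counts(path)
        np.testing.assert_array_equal(np.asarray(mat.todense()), [[1, 2], [3, 4]])
        assert fids == ["gene1", "gene2"] and cids == ["cellA", "cellB"]

    def test_matrixmarket_explicit_zeros(self, tmp_path):
        path = tmp_path / "z.mtx"
        path.write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "3 2 3\n1 1 5\n2 2 0\n3 1 7\n"
        )
        mat, _, _ = read_counts(path)
        dense_oracle = np.array([[5, 0], [0, 0], [7, 0]])
        np.testing.assert_array_equal(np.asarray(mat.todense()), dense_oracle)

    def test_nonnumeric_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\tc1\ng1\tx\n")
        with pytest.raises(ValueError):
            read_counts(path)

    def test_write_table_empty_is_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_table(pd.DataFrame(columns=["gene1", "gene2", "rho"]), path)
        assert path.read_text().strip() == "gene1\tgene2\trho"

    def test_bundle_round_trip(self, tmp_path, spiked_exp):
        spiked_exp.size_factors = np.linspace(0.5, 1.5, 30)
        spiked_exp.spike_size_factors["ERCC"] = np.linspace(0.9, 1.1, 30)
        spiked_exp.log_exprs = np.log1p(spiked_exp.dense_counts().astype(float))
        save_bundle(spiked_exp, tmp_path / "bundle")
        back = load_bundle(tmp_path / "bundle")
        np.testing.assert_array_equal(back.dense_counts(), spiked_exp.dense_counts())
        assert back.spike_sets == {"ERCC": False}
        np.testing.assert_allclose(back.size_factors, spiked_exp.size_factors)
        np.testing.assert_allclose(back.spike_size_factors["ERCC"], spiked_exp.spike_size_factors["ERCC"])
        np.testing.assert_allclose(back.log_exprs, spiked_exp.log_exprs)


class TestMapIds:
    def test_first_match_wins(self):
        m = IdMapping([("ENS1", "Alpha"), ("ENS1", "Beta"), ("ENS2", "Gamma")])
        assert map_ids(["ENS1", "ENS2"], m) == ["Alpha", "Gamma"]

    def test_unmapped_is_missing(self):
        m = IdMapping([("ENS1", "Alpha")])
        assert map_ids(["ENSX"], m) == [None]

    def test_empty_input(self):
        assert map_ids([], IdMapping([])) == []
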