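"""Containers, transformations, design construction and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbmm import (ModelSpec, SampleMeta, TaxaTable, arcsine_sqrt_transform,
                  build_design, log2_transform, nonzero_proportions,
                  read_results_table, read_taxa_table, write_results_table)
from mbmm.data import IntegrityError, SpecificationError


class TestTaxaTableIO:
    def _write(self, tmp_path, frame, name="t.tsv"):
        path = tmp_path / name
        frame.to_csv(path, sep="\t")
        return path

    def test_orientation_transpose(self, tmp_path):
        frame = pd.DataFrame(np.arange(12).reshape(3, 4),
                             index=["taxA", "taxB", "taxC"],
                             columns=[f"s{i}" for i in range(4)])
        path = self._write(tmp_path, frame)
        tab = read_taxa_table(path, orientation="taxa_by_samples")
        assert tab.counts.shape == (4, 3)
        assert tab.taxon_ids == ["taxA", "taxB", "taxC"]
        np.testing.assert_array_equal(tab.counts, frame.values.T)

    def test_negative_entry_rejected(self, tmp_path):
        frame = pd.DataFrame([[1.0, -2.0]], index=["s0"], columns=["a", "b"])
        path = self._write(tmp_path, frame)
        with pytest.raises(IntegrityError):
            read_taxa_table(path)

    def test_scale_applied(self, tmp_path):
        frame = pd.DataFrame([[0.42]], index=["s0"], columns=["a"])
        path = self._write(tmp_path, frame)
        tab = read_taxa_table(path, scale=100, is_proportion=True)
        assert tab.counts[0, 0] == pytest.approx(42.0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(IntegrityError):
            TaxaTable(np.ones((2, 2)), ["a", "a"], ["s0", "s1"])

    def test_results_roundtrip_12_digits(self, tmp_path):
        table = pd.DataFrame({
            "taxon": ["t1", "t2"], "term": ["g", "g"], "part": ["count"] * 2,
            "estimate": [0.123456789012345, -3.9876543210987e-7],
            "se": [1.5e-3, 2.0], "pvalue": [0.049999999, 1.0],
        })
        path = tmp_path / "res.tsv"
        write_results_table(table, path)
        back = read_results_table(path)
        for col in ("estimate", "se", "pvalue"):
            np.testing.assert_allclose(back[col], table[col], rtol=1e-11)


class TestTransforms:
    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (7.0, 3.0), (1.0, 1.0)])
    def test_log2_values(self, x, expected):
        assert log2_transform([x])[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("c, t, expected", [
        (0.0, 10.0, 0.0),
        (10.0, 10.0, np.pi / 2),
        (5.0, 10.0, np.pi / 4),
    ])
    def test_arcsine_sqrt_values(self, c, t, expected):
        assert arcsine_sqrt_transform([c], [t])[0] == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            log2_transform([-1.0])
        with pytest.raises(ValueError):
            arcsine_sqrt_transform([11.0], [10.0])

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_log2_monotone_and_zero_fixed(self, xs):
        xs = np.sort(np.asarray(xs))
        out = log2_transform(xs)
        assert np.all(np.diff(out) >= 0)
        assert log2_transform([0.0])[0] == 0.0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_arcsine_monotone_bounded(self, fracs):
        fracs = np.sort(np.asarray(fracs))
        out = arcsine_sqrt_transform(fracs, np.ones_like(fracs))
        assert np.all(np.diff(out) >= -1e-15)
        assert np.all((out >= 0) & (out <= np.pi / 2 + 1e-12))


class TestNonzeroProportions:
    def test_counting(self):
        tab = TaxaTable(np.array([[0, 2], [0, 3], [0, 0], [1, 1]], float),
                        ["a", "b"], [f"s{i}" for i in range(4)])
        props = nonzero_proportions(tab)
        assert props["a"] == pytest.approx(0.25)
        assert props["b"] == pytest.approx(0.75)

    def test_all_zero_taxon(self):
        tab = TaxaTable(np.zeros((3, 1)), ["a"], ["s0", "s1", "s2"])
        assert nonzero_proportions(tab)["a"] == 0.0

    def test_permutation_invariance(self, rng):
        counts = rng.poisson(1.0, size=(20, 5)).astype(float)
        tab = TaxaTable(counts, [f"t{j}" for j in range(5)],
                        [f"s{i}" for i in range(20)])
        perm = rng.permutation(20)
        tab2 = TaxaTable(counts[perm], tab.taxon_ids,
                         [tab.sample_ids[i] for i in perm])
        pd.testing.assert_series_equal(nonzero_proportions(tab),
                                       nonzero_proportions(tab2))


class TestBuildDesign:
    def test_offset_log_total_reads(self, small_meta):
        spec = ModelSpec(fixed_formula="group", method="nb",
                         offset_policy="log_total_reads")
        y = np.ones(12)
        d = build_design(small_meta, spec, y)
        totals = small_meta.data["total_reads"].values[d.row_index]
        np.testing.assert_allclose(d.offset, np.log(totals))

    def test_offset_none_is_zero(self, small_meta):
        spec = ModelSpec(fixed_formula="group", method="nb", offset_policy="none")
        d = build_design(small_meta, spec, np.ones(12))
        np.testing.assert_array_equal(d.offset, np.zeros(12))

    def test_missing_variable_raises(self, small_meta):
        spec = ModelSpec(fixed_formula="group + bmi", method="nb")
        with pytest.raises(SpecificationError):
            build_design(small_meta, spec, np.ones(12))

    def test_missing_rows_dropped(self, small_meta):
        meta = SampleMeta(small_meta.data.copy())
        meta.data.iloc[3, meta.data.columns.get_loc("age")] = np.nan
        spec = ModelSpec(fixed_formula="group + age", method="nb")
        d = build_design(meta, spec, np.ones(12))
        assert d.n_obs == 11 and d.n_dropped == 1

    def test_subjects_contiguous_and_time_ordered(self, small_meta):
        # shuffle rows; ar1 designs must come back subject-blocked, time-sorted
        perm = np.random.default_rng(3).permutation(12)
        meta = SampleMeta(small_meta.data.iloc[perm])
        spec = ModelSpec(fixed_formula="group", method="nb", correlation="ar1")
        d = build_design(meta, spec, np.ones(12))
        subj = np.asarray(d.groups)
        changes = np.flatnonzero(np.diff(subj) != 0)
        assert len(changes) == d.n_subjects - 1  # each subject one block
        times = meta.data["time"].values[d.row_index]
        for g in np.unique(subj):
            assert np.all(np.diff(times[subj == g]) >= 0)

    def test_zero_part_matrices_only_for_zi_methods(self, small_meta):
        spec = ModelSpec(fixed_formula="group", method="zinb",
                         zi_fixed_formula="group")
        d = build_design(small_meta, spec, np.ones(12))
        assert d.zi_X is not None and d.zi_X.shape[1] == 2
        with pytest.raises(SpecificationError):
            ModelSpec(fixed_formula="group", method="nb", zi_fixed_formula="group")
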