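"""Many-taxa screening: filtering, fault isolation, result tables, BH."""

import numpy as np
import pandas as pd
import pytest

from mbmm import (ModelSpec, SampleMeta, SimTruth, TaxaTable, adjust_pvalues,
                  fixed_table, get_fixed, screen, simulate_nbmm)


def _engineered_table(rng, n_samples=40, props=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5,
                                                0.6, 0.7, 0.8, 0.9)):
    """Taxa with exact nonzero proportions by construction."""
    cols = []
    for p in props:
        k = int(round(p * n_samples))
        col = np.zeros(n_samples)
        col[:k] = rng.poisson(20.0, k) + 1.0
        cols.append(col)
    counts = np.column_stack(cols)
    return TaxaTable(counts, [f"tax{i}" for i in range(len(props))],
                     [f"s{i}" for i in range(n_samples)])


@pytest.fixture
def screen_inputs():
    ds = simulate_nbmm(SimTruth(n_subjects=8, samples_per_subject=(5, 5),
                                n_taxa=1, seed=55))
    rng = np.random.default_rng(0)
    table = _engineered_table(rng, n_samples=len(ds.meta.sample_ids))
    table.sample_ids = list(ds.meta.sample_ids)
    return table, ds.meta


class TestFiltering:
    def test_min_p_strict_threshold(self, screen_inputs):
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group + time", random_formula="1 | subject",
                         method="nb")
        res = screen(table, meta, spec, min_p=0.2)
        filtered = [t for t, r in res.skipped.items() if r == "filtered"]
        # proportions 0.0, 0.1, 0.2 fail "> 0.2"; 7 retained
        assert len(filtered) == 3
        assert set(filtered) == {"tax0", "tax1", "tax2"}
        assert res.n_fitted + len(res.skipped) == table.n_taxa

    def test_min_p_zero_keeps_any_nonzero(self, screen_inputs):
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group", random_formula="1 | subject",
                         method="nb")
        res = screen(table, meta, spec, min_p=0.0)
        assert "tax0" in res.skipped        # all-zero taxon
        assert res.n_fitted == table.n_taxa - 1

    def test_min_p_one_skips_everything(self, screen_inputs):
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group", random_formula="1 | subject",
                         method="nb")
        with pytest.warns(UserWarning):
            res = screen(table, meta, spec, min_p=1.0)
        assert res.n_fitted == 0
        assert len(res.skipped) == table.n_taxa

    def test_sort_decreasing_nonzero(self, screen_inputs):
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group", random_formula="1 | subject",
                         method="nb")
        res = screen(table, meta, spec, min_p=0.2, sort=True)
        assert res.order[0] == "tax9"
        assert res.order[-1] == "tax0"


class TestFaultIsolation:
    def test_failure_leaves_others_byte_identical(self, screen_inputs):
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group + time", random_formula="1 | subject",
                         method="nb")
        res1 = screen(table, meta, spec, min_p=0.2)
        # poison one retained taxon: all zeros except one NaN-free tiny value
        counts2 = table.counts.copy()
        counts2[:, 5] = 0.0
        counts2[0, 5] = 1.0  # nonzero proportion 1/40 -> still > 0? no: 0.025
        table2 = TaxaTable(counts2, table.taxon_ids, table.sample_ids)
        res2 = screen(table2, meta, spec, min_p=0.2)
        assert "tax5" in res2.skipped
        t1 = fixed_table(res1)
        t2 = fixed_table(res2)
        t1 = t1[t1["taxon"] != "tax5"].reset_index(drop=True)
        t2 = t2[t2["taxon"] != "tax5"].reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, t2)

    def test_injected_exception_recorded_as_failed(self, screen_inputs,
                                                   monkeypatch):
        """A fitter blowing up on one taxon is recorded and contained."""
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group + time", random_formula="1 | subject",
                         method="nb")
        baseline = fixed_table(screen(table, meta, spec, min_p=0.2))

        import importlib
        scr = importlib.import_module("mbmm.screen")
        real = scr.fit_nbmm
        calls = {"n": 0}

        def flaky(y, design, control=None, **kw):
            calls["n"] += 1
            if calls["n"] == 3:
                raise RuntimeError("numerical collapse (injected)")
            return real(y, design, control, **kw)

        monkeypatch.setattr(scr, "fit_nbmm", flaky)
        res = screen(table, meta, spec, min_p=0.2)
        failed = [t for t, r in res.skipped.items() if r.startswith("failed")]
        assert len(failed) == 1
        got = fixed_table(res)
        keep = baseline["taxon"] != failed[0]
        pd.testing.assert_frame_equal(
            baseline[keep].reset_index(drop=True),
            got[got["taxon"] != failed[0]].reset_index(drop=True),
            check_exact=True)

    def test_determinism(self, screen_inputs):
        table, meta = screen_inputs
        spec = ModelSpec(fixed_formula="group + time", random_formula="1 | subject",
                         method="nb")
        t1 = fixed_table(screen(table, meta, spec, min_p=0.2))
        t2 = fixed_table(screen(table, meta, spec, min_p=0.2))
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)


class TestResultTables:
    @pytest.fixture
    def nb_screen(self):
        ds = simulate_nbmm(SimTruth(n_subjects=15, n_taxa=3, seed=77))
        spec = ModelSpec(fixed_formula="group + time",
                         random_formula="1 | subject", method="nb")
        return screen(ds.table, ds.meta, spec)

    def test_fixed_table_cardinality(self, nb_screen):
        tab = fixed_table(nb_screen)
        # 3 taxa x 3 fixed terms (Intercept, group, time), count part only
        assert len(tab) == 9
        assert set(tab["part"]) == {"count"}

    def test_get_fixed_slice(self, nb_screen):
        sl = get_fixed(nb_screen, "group")
        assert len(sl) == 3
        assert {"estimate", "se", "pvalue"} <= set(sl.columns)

    def test_get_fixed_unknown_term_lists_candidates(self, nb_screen):
        with pytest.raises(KeyError, match="group"):
            get_fixed(nb_screen, "pregnant")

    def test_zinb_adds_zero_rows(self):
        ds = simulate_nbmm(SimTruth(n_subjects=15, n_taxa=2,
                                    beta=(-1.0, 0.5),
                                    total_reads_range=(5, 50), seed=78))
        spec = ModelSpec(fixed_formula="group", random_formula="1 | subject",
                         method="zinb")
        res = screen(ds.table, ds.meta, spec)
        tab = fixed_table(res)
        zero_rows = tab[tab["part"] == "zero"]
        with_zero_part = sum(f.has_zero_part for f in res.fits.values())
        assert with_zero_part >= 1
        assert len(zero_rows) == with_zero_part  # intercept-only zero part


class TestAdjustPvalues:
    def test_bh_step_up_hand_computed(self):
        tab = pd.DataFrame({"taxon": ["a", "b", "c"], "term": ["g"] * 3,
                            "part": ["count"] * 3,
                            "pvalue": [0.01, 0.02, 0.03]})
        out = adjust_pvalues(tab, method="BH")
        np.testing.assert_allclose(out["adjusted"], [0.03, 0.03, 0.03])

    def test_none_copies_raw(self):
        tab = pd.DataFrame({"taxon": ["a"], "term": ["g"], "part": ["count"],
                            "pvalue": [0.2]})
        out = adjust_pvalues(tab, method="none")
        assert out["adjusted"][0] == 0.2

    def test_bh_within_term_not_across(self):
        tab = pd.DataFrame({
            "taxon": ["a", "b", "a", "b"],
            "term": ["g", "g", "t", "t"],
            "part": ["count"] * 4,
            "pvalue": [0.01, 0.04, 0.5, 1.0],
        })
        out = adjust_pvalues(tab, method="BH")
        g = out[out["term"] == "g"]["adjusted"].values
        np.testing.assert_allclose(g, [0.02, 0.04])
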