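"""Lineage cultures: partitioning, scheduling, pedigrees, reproducibility."""

import numpy as np
import pytest

import yeastcycle as yc
from yeastcycle.culture import (
    CultureConfig,
    divide_cell,
    extant_population,
    run_culture,
)
from conftest import steady_frame


class TestDivideCell:
    def test_glucose_split_of_ten(self):
        (m, mv), (d, dv) = divide_cell(np.array([10]), 60.0, 0.4)
        assert d[0] == 4 and m[0] == 6
        assert mv == pytest.approx(36.0) and dv == pytest.approx(24.0)

    def test_zero_molecules(self):
        (m, _), (d, _) = divide_cell(np.array([0]), 60.0, 0.4)
        assert m[0] == 0 and d[0] == 0

    def test_conservation_both_modes(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 5000, 40)
        for mode in ("proportional", "binomial"):
            (m, mv), (d, dv) = divide_cell(counts, 77.0, 0.4, mode, rng)
            np.testing.assert_array_equal(m + d, counts)
            assert mv + dv == pytest.approx(77.0)
            assert (m >= 0).all() and (d >= 0).all()

    def test_binomial_moments(self):
        # daughter share of N=100 at f=0.4: mean 40, variance 24
        rng = np.random.default_rng(7)
        counts = np.full(1, 100)
        draws = np.array([divide_cell(counts, 50.0, 0.4, "binomial",
                                      rng)[1][0][0]
                          for _ in range(20_000)])
        assert draws.mean() == pytest.approx(40.0, abs=0.25)
        assert draws.var() == pytest.approx(24.0, rel=0.06)

    def test_cln3_partition_25_75(self):
        counts = np.array([1000, 1000])
        (m, _), (d, _) = divide_cell(counts, 60.0, 0.4,
                                     cln3_idx=np.array([1]))
        assert d[0] == 400 and d[1] == 250
        assert m[1] == 750

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            divide_cell(np.array([10]), 60.0, 1.2)


class TestRunCulture:
    def test_single_cell_culture(self, wt_glucose_network):
        table = run_culture(wt_glucose_network,
                            CultureConfig(master_seed=5, max_cells=1))
        assert len(table) == 1
        assert table.records[0].parent_id == -1

    def test_reproducible_given_master_seed(self, wt_glucose_network):
        cfg = CultureConfig(master_seed=42, max_cells=3)
        a = run_culture(wt_glucose_network, cfg).to_frame()
        b = run_culture(wt_glucose_network, cfg).to_frame()
        assert a.equals(b)

    def test_pedigree_is_binary_tree(self, wt_culture):
        # every parent has at most two recorded children (the scheduler may
        # stop before a division's second child is simulated), and each
        # complete sibling pair is one mother + one daughter
        df = wt_culture.to_frame()
        children = df[df.parent_id >= 0].groupby("parent_id")
        assert (children.size() <= 2).all()
        complete = [g for _, g in children if len(g) == 2]
        assert complete, "expected at least one complete division"
        for g in complete:
            assert set(g.md_label) == {"mother", "daughter"}

    def test_tree_accounting_identity(self, wt_culture):
        # final cell count = divisions + 1 (each division adds one cell)
        grid = np.array([wt_culture.to_frame().t_birth.max() + 1e-6])
        n_div = sum(1 for r in wt_culture.records
                    if r.arrest == "none" and np.isfinite(r.t_div)
                    and r.t_birth + r.t_div <= grid[0])
        assert wt_culture.count_series(grid)[0] == n_div + 1

    def test_daughters_born_smaller_and_wait_longer(self, wt_culture):
        df = steady_frame(wt_culture)
        d = df[df.md_label == "daughter"]
        m = df[df.md_label == "mother"]
        assert d.V_bir.mean() < m.V_bir.mean()
        assert d.T_unbud.mean() > m.T_unbud.mean()

    def test_duration_identities(self, wt_culture):
        # T_div = T_unbud + T_bud = T_g1 + T_sg2m for every divided cell
        for r in wt_culture.divided():
            if np.isfinite(r.t_unbud):
                assert r.t_div == pytest.approx(r.t_unbud + r.t_bud_dur)
            if np.isfinite(r.t_g1):
                assert r.t_div == pytest.approx(r.t_g1 + r.t_sg2m)

    def test_volume_conserved_at_division(self, wt_culture):
        df = wt_culture.to_frame()
        kids = df[df.parent_id >= 0]
        parents = df.set_index("cell_id")
        for pid, group in kids.groupby("parent_id"):
            if len(group) == 2 and pid in parents.index and np.isfinite(
                    parents.loc[pid, "V_div"]):
                assert group.V_bir.sum() == pytest.approx(
                    parents.loc[pid, "V_div"], rel=1e-9)


class TestExtantPopulation:
    def test_before_first_division_only_founder(self, wt_culture):
        first_div = min(r.t_div for r in wt_culture.divided()
                        if r.cell_id == 0)
        ext = extant_population(wt_culture, first_div / 2)
        assert [r.cell_id for r in ext] == [0]

    def test_each_lineage_contributes_exactly_one_cell(self, wt_culture):
        df = wt_culture.to_frame()
        # pick a time well inside the simulated horizon
        t_stop = np.percentile(df.t_birth, 60)
        ext = extant_population(wt_culture, t_stop)
        assert len(ext) >= 2
        # extant cells' lifetimes cover t_stop and never overlap within a
        # lineage: no extant cell is an ancestor of another extant cell
        ids = {r.cell_id for r in ext}
        parent = dict(zip(df.cell_id, df.parent_id))
        for r in ext:
            p = parent.get(r.cell_id, -1)
            while p >= 0:
                assert p not in ids
                p = parent.get(p, -1)

    def test_too_early_stop_empty(self, wt_culture):
        assert extant_population(wt_culture, -1.0) == []
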