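"""Stochastic engine contracts: propensities, exactness, reproducibility."""

import numpy as np
import pytest
from scipy.stats import chisquare

from yeastcycle import CellState, ReactionDef, ReactionNetwork, simulate_cell
from yeastcycle.compiled import compile_network
from yeastcycle.fixtures import STATIC, fixture_network
from yeastcycle.network import Medium
from yeastcycle.ode import derivatives
from yeastcycle.ssa import propensity


def _sample_stationary(net, t_burn, t_end, spacing, seed, species="m"):
    # fixed-volume fixtures tolerate a coarse clock interval
    tr = simulate_cell(net, t_end=t_end, seed=seed, sample_dt=spacing,
                       dt_null=5.0)
    j = tr.species.index(species)
    keep = tr.t >= t_burn
    return tr.counts[keep, j]


class TestPropensity:
    def test_bimolecular_with_zero_reactant_is_zero(self):
        net = ReactionNetwork(
            species=["A", "B", "C"],
            reactions=[ReactionDef(("A", "B"), ("C",), 1.0, "bimolecular")],
            params={}, medium=STATIC, initial_counts={"A": 0, "B": 50})
        a = propensity(net, [0, 50, 0], 30.0)
        assert a[0] == 0.0

    def test_cln3_translation_scales_with_v_squared(self, wt_glucose_network):
        cn = compile_network(wt_glucose_network)
        counts = np.zeros(cn.n_species, dtype=np.int64)
        for g in ("CLN3", "WHI5"):
            counts[cn.index[f"m_{g}"]] = 10
        a1 = propensity(cn, counts, 50.0)
        a2 = propensity(cn, counts, 100.0)
        jc = next(i for i, r in enumerate(wt_glucose_network.reactions)
                  if r.tag == "translation:CLN3")
        jw = next(i for i, r in enumerate(wt_glucose_network.reactions)
                  if r.tag == "translation:WHI5")
        # doubling V doubles the CLN3 propensity relative to ordinary
        # translation at the same mRNA count
        assert (a2[jc] / a1[jc]) / (a2[jw] / a1[jw]) == pytest.approx(2.0)

    def test_negative_count_rejected(self):
        net, _ = fixture_network("decay_only")
        with pytest.raises(ValueError):
            propensity(net, [-1], 30.0)

    def test_mean_field_matches_ode_derivatives(self):
        """Sum of stoichiometry-weighted propensities == ODE RHS exactly."""
        net = ReactionNetwork(
            species=["A", "B", "C"],
            reactions=[
                ReactionDef((), ("A",), 2.0, "synthesis"),
                ReactionDef(("A",), (), 0.1, "unimolecular"),
                ReactionDef(("A", "B"), ("C",), 0.05, "bimolecular"),
                ReactionDef(("C",), ("A", "B"), 0.3, "unimolecular"),
            ],
            params={}, medium=STATIC,
            initial_counts={"A": 17, "B": 23, "C": 5})
        cn = compile_network(net)
        counts = np.array([17, 23, 5])
        a = propensity(cn, counts, 42.0)
        dn, _ = derivatives(cn, counts, 42.0)
        expected = cn.stoich.T.astype(float) @ a
        np.testing.assert_allclose(dn, expected, atol=1e-9)


class TestExactness:
    def test_zero_reaction_network_only_grows(self):
        net = ReactionNetwork(
            species=["A"], reactions=[], params={},
            medium=Medium("fast", 0.01, 0.4), initial_counts={"A": 7})
        tr = simulate_cell(net, init=CellState(0.0, 30.0,
                                               np.array([7], np.int64)),
                          t_end=100.0, seed=1, sample_dt=10.0)
        assert (tr.counts[:, 0] == 7).all()
        np.testing.assert_allclose(tr.volume, 30.0 * np.exp(0.01 * tr.t),
                                   rtol=1e-9)

    def test_constitutive_gene_is_poisson(self):
        """Birth-death mRNA: stationary law Poisson(k_t/k_d), chi-square GOF.

        k_t = 1/min, half-life 6.93 min (k_d = 0.1) => Poisson(10).
        """
        net, oracle = fixture_network("constitutive_gene", k_t=1.0, k_d=0.1)
        samples = _sample_stationary(net, 200.0, 500_000.0, 25.0, seed=4)
        assert len(samples) >= 19000
        kmax = len(oracle["pmf"]) - 1
        obs = np.bincount(np.clip(samples, 0, kmax), minlength=kmax + 1)
        exp = oracle["pmf"] * obs.sum()
        # pool tail bins with expected < 5 for a valid chi-square
        keep = exp >= 5
        obs_p = np.append(obs[keep], obs[~keep].sum())
        exp_p = np.append(exp[keep], exp[~keep].sum())
        stat, p = chisquare(obs_p, exp_p * obs_p.sum() / exp_p.sum())
        assert p > 0.01
        assert samples.mean() == pytest.approx(10.0, rel=0.03)

    def test_two_state_promoter_matches_cme(self):
        """Full count distribution vs truncated master-equation solve."""
        net, oracle = fixture_network("two_state_promoter")
        samples = _sample_stationary(net, 200.0, 400_000.0, 20.0, seed=8)
        kmax = len(oracle["pmf"]) - 1
        obs = np.bincount(np.clip(samples, 0, kmax), minlength=kmax + 1)
        emp = obs / obs.sum()
        tv = 0.5 * np.abs(emp - oracle["pmf"]).sum()
        assert tv < 0.02
        # bursty expression: variance exceeds the Poisson value
        assert samples.var() > 1.3 * samples.mean()

    def test_decay_half_life(self):
        net, oracle = fixture_network("decay_only", k_d=0.1, n0=40000)
        tr = simulate_cell(net, t_end=25.0, seed=3, sample_dt=0.5)
        n = tr.counts[:, 0].astype(float)
        slope = np.polyfit(tr.t[n > 2000], np.log(n[n > 2000]), 1)[0]
        assert -np.log(2) / slope == pytest.approx(oracle["half_life"],
                                                   rel=0.05)

    def test_dimerization_conserves_monomer_equivalents(self):
        net, oracle = fixture_network("dimerization", n0=200)
        tr = simulate_cell(net, t_end=50.0, seed=5, sample_dt=1.0)
        total = tr.counts[:, 0] + 2 * tr.counts[:, 1]
        assert (total == oracle["n0"]).all()


class TestMeanFieldConvergence:
    def test_ssa_mean_approaches_ode_with_system_size(self):
        """Relative deviation of SSA means from the ODE shrinks as the
        volume (hence molecule numbers) is scaled up 10x and 100x."""
        from yeastcycle.ode import simulate_deterministic

        k_syn, k_dec, k_f, k_b = 5.0, 0.05, 0.02, 0.5
        devs = []
        for scale in (1.0, 10.0, 100.0):
            v = 10.0 * scale
            net = ReactionNetwork(
                species=["A", "A2"],
                reactions=[
                    ReactionDef((), ("A",), k_syn, "synthesis"),
                    ReactionDef(("A",), (), k_dec, "unimolecular"),
                    ReactionDef(("A", "A"), ("A2",), k_f, "bimolecular"),
                    ReactionDef(("A2",), ("A", "A"), k_b, "unimolecular"),
                ],
                params={}, medium=STATIC, initial_counts={"A": 0, "A2": 0})
            ode = simulate_deterministic(net, 60.0, v0=v,
                                         init_counts=[0.0, 0.0],
                                         sample_dt=60.0)
            means = np.zeros(2)
            reps = 24
            for s in range(reps):
                tr = simulate_cell(
                    net, init=CellState(0.0, v, np.zeros(2, np.int64)),
                    t_end=60.0, seed=1000 + s, sample_dt=0.0)
                means += tr.final_state.counts / reps
            ref = ode.counts[-1]
            devs.append(np.max(np.abs(means - ref) / ref))
        assert devs[2] < devs[0]
        assert devs[2] < 0.05


class TestReproducibility:
    def test_same_seed_bit_identical(self, wt_glucose_network):
        a = simulate_cell(wt_glucose_network, t_end=12.0, seed=123,
                          sample_dt=1.0)
        b = simulate_cell(wt_glucose_network, t_end=12.0, seed=123,
                          sample_dt=1.0)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert a.events == b.events
        c = simulate_cell(wt_glucose_network, t_end=12.0, seed=124,
                          sample_dt=1.0)
        assert (a.counts != c.counts).any()
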