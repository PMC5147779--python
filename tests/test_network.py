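"""Network construction: phospho-chains, the APC ladder, genotype edits."""

import numpy as np
import pytest
from scipy.linalg import expm

from yeastcycle import (
    MutantSpec,
    PhosphoChainDef,
    apc_affinity_factor,
    apply_mutant,
    build_wildtype,
    expand_phospho_chain,
)
from yeastcycle.model import mutant_catalog


def chain(n, mode="ordered", rule=("le", 0), kin=(("K", 1.0),),
          pho=(("P", 1.0),)):
    return PhosphoChainDef(protein="X", n_sites=n, active_rule=rule,
                           order_mode=mode, kinases=tuple(kin),
                           phosphatases=tuple(pho))


class TestPhosphoChain:
    def test_whi5_chain_has_11_forms_and_3_active(self):
        c = chain(10, rule=("le", 2))
        species, rxns, mask = expand_phospho_chain(c)
        assert len(species) == 11
        assert mask == [True, True, True] + [False] * 8

    def test_smallest_chain(self):
        species, rxns, _ = expand_phospho_chain(chain(1))
        assert len(species) == 2
        assert len(rxns) == 2

    def test_reaction_count_scales_with_enzymes(self):
        c = chain(5, kin=(("K1", 1.0), ("K2", 2.0)), pho=(("P", 1.0),))
        _, rxns, _ = expand_phospho_chain(c)
        assert len(rxns) == 2 * 5 + 5

    def test_chain_conserves_protein(self):
        # every (de)phosphorylation step moves one molecule between forms
        species, rxns, _ = expand_phospho_chain(chain(4, mode="disordered"))
        for r in rxns:
            net = r.net_stoich()
            assert sum(v for s, v in net.items() if s in species) == 0

    def test_invalid_defs_rejected(self):
        with pytest.raises(ValueError):
            chain(0)
        with pytest.raises(ValueError):
            chain(3, rule=("le", 3))  # m must be < n

    @pytest.mark.parametrize("n", [2, 3])
    def test_disordered_marginal_matches_site_resolved_cme(self, n):
        """Count-resolved disordered chain == site-resolved CME marginal.

        With site-symmetric rates, a brute-force master equation over the
        2^n site-resolved states, marginalised to the phospho-count, must
        match the (n+1)-state count-resolved chain — as full dynamics, not
        just stationarily.
        """
        u, v = 0.7, 0.4   # per-site phosphorylation/dephosphorylation
        # site-resolved generator over 2^n states
        ns = 2 ** n
        gen = np.zeros((ns, ns))
        for s in range(ns):
            for site in range(n):
                flip = s ^ (1 << site)
                rate = u if not (s >> site) & 1 else v
                gen[flip, s] += rate
                gen[s, s] -= rate
        # count-resolved generator with multiplicities (n-k) up, k down
        gc = np.zeros((n + 1, n + 1))
        for k in range(n):
            gc[k + 1, k] += u * (n - k)
            gc[k, k] -= u * (n - k)
        for k in range(1, n + 1):
            gc[k - 1, k] += v * k
            gc[k, k] -= v * k
        p0_site = np.zeros(ns)
        p0_site[0] = 1.0
        p0_count = np.zeros(n + 1)
        p0_count[0] = 1.0
        for t in (0.3, 1.0, 4.0, 20.0):
            p_site = expm(gen * t) @ p0_site
            marginal = np.zeros(n + 1)
            for s in range(ns):
                marginal[bin(s).count("1")] += p_site[s]
            p_count = expm(gc * t) @ p0_count
            np.testing.assert_allclose(marginal, p_count, atol=1e-10)


class TestApcLadder:
    def test_fully_phosphorylated_factor_is_one(self):
        assert apc_affinity_factor(11) == pytest.approx(1.0)

    def test_one_phosphate_short_gives_beta(self):
        assert apc_affinity_factor(10) == pytest.approx(0.525)

    def test_unphosphorylated_is_beta_to_the_n(self):
        assert apc_affinity_factor(0) == pytest.approx(0.525 ** 11)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apc_affinity_factor(12)
        with pytest.raises(ValueError):
            apc_affinity_factor(-1)


class TestWildtypeNetwork:
    def test_structure(self, wt_glucose_network):
        net = wt_glucose_network
        mrnas = [s for s in net.species if s.startswith("m_")]
        assert len(mrnas) == 17
        # one promoter group per gene, summing to the haploid copy number
        for g, gd in net.genes.items():
            if gd.regulated:
                total = (net.initial_counts.get(f"Goff_{g}", 0)
                         + net.initial_counts.get(f"Gon_{g}", 0))
            else:
                total = net.initial_counts.get(f"G_{g}", 0)
            assert total == 1, g
        assert 400 < net.n_reactions < 900

    def test_every_reaction_at_most_two_reactants(self, wt_glucose_network):
        assert all(len(r.reactants) <= 2
                   for r in wt_glucose_network.reactions)

    def test_regulated_and_constitutive_gene_lists(self, wt_glucose_network):
        reg = {g for g, d in wt_glucose_network.genes.items() if d.regulated}
        assert reg == {"CLN1", "CLN2", "CLB5", "CLB2", "SIC1", "SWI5",
                       "CDC20"}

    def test_cln3_translation_scales_with_v_squared(self, wt_glucose_network):
        tl = [r for r in wt_glucose_network.reactions
              if r.tag == "translation:CLN3"]
        assert len(tl) == 1 and tl[0].vol_exp == 2
        others = [r for r in wt_glucose_network.reactions
                  if r.tag.startswith("translation:")
                  and r.tag != "translation:CLN3"]
        assert all(r.vol_exp == 1 for r in others)

    def test_tsv_export_roundtrips_reaction_count(self, wt_glucose_network):
        text = wt_glucose_network.to_tsv()
        assert len(text.strip().splitlines()) == \
            wt_glucose_network.n_reactions + 1


class TestApplyMutant:
    def test_double_cln_deletion_removes_only_transcription(
            self, wt_glucose_network):
        net = wt_glucose_network
        mut = apply_mutant(net, mutant_catalog()["cln1 cln2"])
        gone = [r for r in net.reactions
                if r.tag in ("transcription:CLN1", "transcription:CLN2")]
        assert len(mut.reactions) == len(net.reactions) - len(gone)
        assert not any(r.tag.startswith("transcription:CLN1")
                       for r in mut.reactions)

    def test_scale_identity_is_noop(self, wt_glucose_network):
        net = wt_glucose_network
        mut = apply_mutant(net, MutantSpec(
            "id", (("scale", "k_cln1_whi5", 1.0),)))
        assert [r.rate for r in mut.reactions] == \
            [r.rate for r in net.reactions]

    def test_clb2_db_removes_regulated_degradation_only(
            self, wt_glucose_network):
        net = wt_glucose_network
        mut = apply_mutant(net, mutant_catalog()["CLB2-db"])
        assert len(mut.reactions) < len(net.reactions)
        tags = {r.tag for r in mut.reactions}
        assert "deg:Clb2:cdc20" not in tags
        assert "deg:Clb2:cdh1" not in tags
        assert "deg:Clb2:basal" in tags

    def test_delete_is_idempotent(self, wt_glucose_network):
        once = apply_mutant(wt_glucose_network,
                            MutantSpec("d", (("delete", "CLN1"),)))
        with pytest.raises(ValueError):
            # second deletion has nothing left to remove
            apply_mutant(once, MutantSpec("d", (("delete", "CLN1"),)))

    def test_disjoint_edits_commute(self, wt_glucose_network):
        a = MutantSpec("a", (("delete", "CLN1"), ("scale", "k_clb2_sbf", 2.0)))
        b = MutantSpec("b", (("scale", "k_clb2_sbf", 2.0), ("delete", "CLN1")))
        na = apply_mutant(wt_glucose_network, a)
        nb = apply_mutant(wt_glucose_network, b)
        assert sorted((r.reactants, r.products, r.rate) for r in na.reactions) \
            == sorted((r.reactants, r.products, r.rate) for r in nb.reactions)

    def test_unknown_gene_rejected(self, wt_glucose_network):
        with pytest.raises(ValueError, match="CLB9"):
            apply_mutant(wt_glucose_network,
                         MutantSpec("x", (("delete", "CLB9"),)))

    def test_gal_allele_inactive_in_glucose(self, wt_glucose_network):
        mut = apply_mutant(wt_glucose_network, mutant_catalog()["GAL-SIC1"])
        assert len(mut.reactions) == len(wt_glucose_network.reactions)
        gal = build_wildtype("galactose")
        mut_gal = apply_mutant(gal, mutant_catalog()["GAL-SIC1"])
        assert len(mut_gal.reactions) == len(gal.reactions) + 1
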