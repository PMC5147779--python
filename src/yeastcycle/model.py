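"""Construction of the wild-type cell-cycle reaction network.

The network couples gene expression (two-state promoters, mRNA, translation),
eight multisite-phosphorylation switches, stoichiometric-inhibitor complexes
(Whi5:SBF, Sic1:Clb5, Sic1:Clb2, Net1:Cdc14), the phospho-graded Cdc20:APC
ubiquitin ligase, and regulated proteolysis (Cdc20:APC and APC:Cdh1 routes,
SCF-mediated destruction of multiply phosphorylated Sic1).

Species naming:
  ``G_<GENE>`` constitutive promoter (always active, copy number 1);
  ``Goff_<GENE>``/``Gon_<GENE>`` two-state regulated promoter;
  ``m_<GENE>`` mRNA; ``<Prot>:<k>`` k-fold phosphorylated protein;
  ``<A>:<k>|<B>`` complex of phospho-form k of A with B.
Proteins without a phospho-chain (cyclins, Cdc20, Cdc14, Ht1, Hbf) use their
bare name.
"""

from __future__ import annotations

from .network import (
    GeneDef,
    Medium,
    MutantSpec,
    PhosphoChainDef,
    ReactionDef,
    ReactionNetwork,
    apc_affinity_factor,
    expand_phospho_chain,
    medium_growth,
)
from .params import (
    APC_SITES,
    CHAIN_TABLE,
    CLB2_MEDIUM_FACTOR,
    GENE_TABLE,
    V_BIRTH,
    V_REF,
    default_params,
)
from .units import conc_to_count

#: proteins represented by a single (unphosphorylated) species
PLAIN_PROTEINS = ("Cln1", "Cln2", "Cln3", "Clb5", "Clb2",
                  "Cdc20", "Cdc14", "Ht1", "Hbf")

GENE_TO_PROTEIN = {
    "CLN1": "Cln1", "CLN2": "Cln2", "CLN3": "Cln3", "CLB5": "Clb5",
    "CLB2": "Clb2", "CDC20": "Cdc20", "CDC14": "Cdc14", "HT1": "Ht1",
    "HBF": "Hbf", "WHI5": "Whi5", "SBF": "SBF", "FKH2": "Fkh2",
    "NET1": "Net1", "CDH1": "Cdh1", "SWI5": "Swi5", "SIC1": "Sic1",
    "APC": "APC",
}

#: species name of the active form of each transcription factor
TF_ACTIVE = {"SBF": "SBF:0", "FKH2": "Fkh2:2", "SWI5": "Swi5:0"}


def _chain_defs(params: dict) -> dict[str, PhosphoChainDef]:
    chains = {}
    for prot, row in CHAIN_TABLE.items():
        kin = tuple((k, params[f"k_{k.lower()}_{prot.lower()}"])
                    for k, _ in row["kin"])
        pho = tuple((k, params[f"k_{k.lower()}_{prot.lower()}"])
                    for k, _ in row["pho"])
        chains[prot] = PhosphoChainDef(
            protein=prot, n_sites=row["n"], active_rule=row["rule"],
            order_mode=row["mode"], kinases=kin, phosphatases=pho)
    return chains


def build_wildtype(medium: Medium | str = "glucose",
                   params: dict | None = None) -> ReactionNetwork:
    """Assemble the full wild-type network for one growth medium."""
    if isinstance(medium, str):
        medium = medium_growth(medium)
    p = default_params()
    if params:
        p.update(params)

    species: list[str] = []
    roles: dict[str, str] = {}
    rxns: list[ReactionDef] = []
    genes: dict[str, GeneDef] = {}

    def add_species(name: str, role: str) -> None:
        if name not in roles:
            species.append(name)
            roles[name] = role

    # ---- gene expression --------------------------------------------------
    for g, row in GENE_TABLE.items():
        missing = [k for k in (f"kt_{g}", f"kdm_{g}", f"ktl_{g}", f"kdp_{g}")
                   if k not in p]
        if missing:
            raise ValueError(f"missing parameter(s) {missing} for gene {g}")
        prot = GENE_TO_PROTEIN[g]
        prot0 = prot if prot in PLAIN_PROTEINS else f"{prot}:0"
        mrna = f"m_{g}"
        add_species(mrna, "mRNA")
        vexp = row.get("vexp", 1)
        kt = p[f"kt_{g}"]
        if g == "CLB2":
            kt = kt * CLB2_MEDIUM_FACTOR[medium.name]
        if row["reg"]:
            tf = TF_ACTIVE[row["tf"]]
            goff, gon = f"Goff_{g}", f"Gon_{g}"
            add_species(goff, "promoter-state")
            add_species(gon, "promoter-state")
            rxns.append(ReactionDef((goff, tf), (gon, tf), p[f"kon_{g}"],
                                    "bimolecular", param=f"kon_{g}",
                                    tag=f"promoter:{g}"))
            rxns.append(ReactionDef((gon,), (goff,), p[f"koff_{g}"],
                                    "unimolecular", param=f"koff_{g}",
                                    tag=f"promoter:{g}"))
            rxns.append(ReactionDef((gon,), (gon, mrna), kt,
                                    "unimolecular", param=f"kt_{g}",
                                    tag=f"transcription:{g}"))
        else:
            gname = f"G_{g}"
            add_species(gname, "promoter-state")
            rxns.append(ReactionDef((gname,), (gname, mrna), kt,
                                    "unimolecular", param=f"kt_{g}",
                                    tag=f"transcription:{g}"))
        rxns.append(ReactionDef((mrna,), (), p[f"kdm_{g}"], "unimolecular",
                                param=f"kdm_{g}", tag=f"deg:m_{g}"))
        genes[g] = GeneDef(
            name=g, regulated=row["reg"],
            transcription_factors=((row["tf"], 1.0),) if row["reg"] else (),
            mrna_half_life=row["thm"], transcription_rate=kt,
            translation_rate=p[f"ktl_{g}"], translation_volume_exponent=vexp)

    # RAD27 reporter promoter (G1/S regulon readout; activity only)
    add_species("Goff_RAD27", "promoter-state")
    add_species("Gon_RAD27", "promoter-state")
    for act, key in (("Cln1", "kon_rad27_cln1"), ("Cln2", "kon_rad27_cln2"),
                     ("Cln3", "kon_rad27_cln3"), ("Clb5", "kon_rad27_clb5")):
        rxns.append(ReactionDef(("Goff_RAD27", act), ("Gon_RAD27", act),
                                p[key], "bimolecular", param=key,
                                tag="promoter:RAD27"))
    rxns.append(ReactionDef(("Gon_RAD27",), ("Goff_RAD27",), p["koff_RAD27"],
                            "unimolecular", param="koff_RAD27",
                            tag="promoter:RAD27"))

    # ---- proteins and phospho-chains --------------------------------------
    for prot in PLAIN_PROTEINS:
        add_species(prot, "protein")
    chains = _chain_defs(p)
    chain_species: dict[str, list[str]] = {}
    for prot, chain in chains.items():
        sp, chain_rxns, _ = expand_phospho_chain(chain)
        for s in sp:
            add_species(s, "protein phospho-form")
        chain_species[prot] = sp
        rxns.extend(chain_rxns)

    # translation (after chains so the :0 species exist)
    for g, row in GENE_TABLE.items():
        prot = GENE_TO_PROTEIN[g]
        prot0 = prot if prot in PLAIN_PROTEINS else f"{prot}:0"
        mrna = f"m_{g}"
        rxns.append(ReactionDef((mrna,), (mrna, prot0), p[f"ktl_{g}"],
                                "translation", vol_exp=row.get("vexp", 1),
                                param=f"ktl_{g}", tag=f"translation:{g}"))

    # basal degradation of every free protein form
    for g, row in GENE_TABLE.items():
        prot = GENE_TO_PROTEIN[g]
        forms = [prot] if prot in PLAIN_PROTEINS else chain_species[prot]
        for s in forms:
            rxns.append(ReactionDef((s,), (), p[f"kdp_{g}"], "unimolecular",
                                    param=f"kdp_{g}", tag=f"deg:{prot}:basal"))

    # ---- Whi5:SBF complex (nuclear Whi5 with <=2 phosphates binds SBF) ----
    kon, koff = p["kon_whi5_sbf"], p["koff_whi5_sbf"]
    for k in range(3):
        c = f"Whi5:{k}|SBF"
        add_species(c, "complex")
        rxns.append(ReactionDef((f"Whi5:{k}", "SBF:0"), (c,), kon,
                                "bimolecular", param="kon_whi5_sbf",
                                tag="bind:Whi5:SBF"))
        rxns.append(ReactionDef((c,), (f"Whi5:{k}", "SBF:0"), koff,
                                "unimolecular", param="koff_whi5_sbf",
                                tag="unbind:Whi5:SBF"))
    # in-complex Whi5 (de)phosphorylation; the k=2 -> 3 step ejects Whi5
    for kin, rate in chains["Whi5"].kinases:
        pname = f"k_{kin.lower()}_whi5"
        for k in range(2):
            rxns.append(ReactionDef((kin, f"Whi5:{k}|SBF"),
                                    (kin, f"Whi5:{k + 1}|SBF"), rate,
                                    "bimolecular", param=pname,
                                    tag="phos:Whi5"))
        rxns.append(ReactionDef((kin, "Whi5:2|SBF"),
                                (kin, "Whi5:3", "SBF:0"), rate,
                                "bimolecular", param=pname, tag="phos:Whi5"))
    for pho, rate in chains["Whi5"].phosphatases:
        pname = f"k_{pho.lower()}_whi5"
        for k in range(1, 3):
            rxns.append(ReactionDef((pho, f"Whi5:{k}|SBF"),
                                    (pho, f"Whi5:{k - 1}|SBF"), rate,
                                    "bimolecular", param=pname,
                                    tag="dephos:Whi5"))

    # ---- Sic1 complexes with Clb5 and Clb2 --------------------------------
    n_sic = chains["Sic1"].n_sites
    for clb, onk, offk in (("Clb5", "kon_sic1_clb5", "koff_sic1_clb5"),
                           ("Clb2", "kon_sic1_clb2", "koff_sic1_clb2")):
        for k in range(n_sic + 1):
            add_species(f"Sic1:{k}|{clb}", "complex")
        for k in range(6):   # only active (k<=5) Sic1 binds cyclin
            c = f"Sic1:{k}|{clb}"
            rxns.append(ReactionDef((f"Sic1:{k}", clb), (c,), p[onk],
                                    "bimolecular", param=onk,
                                    tag=f"bind:Sic1:{clb}"))
            rxns.append(ReactionDef((c,), (f"Sic1:{k}", clb), p[offk],
                                    "unimolecular", param=offk,
                                    tag=f"unbind:Sic1:{clb}"))
        # in-complex Sic1 (de)phosphorylation, disordered multiplicities
        for kin, rate in chains["Sic1"].kinases:
            pname = f"k_{kin.lower()}_sic1"
            for k in range(n_sic):
                rxns.append(ReactionDef(
                    (kin, f"Sic1:{k}|{clb}"), (kin, f"Sic1:{k + 1}|{clb}"),
                    rate * (n_sic - k), "bimolecular", param=pname,
                    tag="phos:Sic1"))
        for pho, rate in chains["Sic1"].phosphatases:
            pname = f"k_{pho.lower()}_sic1"
            for k in range(1, n_sic + 1):
                rxns.append(ReactionDef(
                    (pho, f"Sic1:{k}|{clb}"), (pho, f"Sic1:{k - 1}|{clb}"),
                    rate * k, "bimolecular", param=pname, tag="dephos:Sic1"))
        # SCF destruction of multiply phosphorylated Sic1 frees the cyclin
        for k in range(6, n_sic + 1):
            rxns.append(ReactionDef((f"Sic1:{k}|{clb}",), (clb,),
                                    p["k_deg_sic1p"], "unimolecular",
                                    param="k_deg_sic1p", tag="deg:Sic1:scf"))
    for k in range(6, n_sic + 1):
        rxns.append(ReactionDef((f"Sic1:{k}",), (), p["k_deg_sic1p"],
                                "unimolecular", param="k_deg_sic1p",
                                tag="deg:Sic1:scf"))

    # ---- RENT complex: Net1 (k<=3) sequesters Cdc14 -----------------------
    for k in range(4):
        c = f"Net1:{k}|Cdc14"
        add_species(c, "complex")
        rxns.append(ReactionDef((f"Net1:{k}", "Cdc14"), (c,),
                                p["kon_net1_cdc14"], "bimolecular",
                                param="kon_net1_cdc14", tag="bind:RENT"))
        rxns.append(ReactionDef((c,), (f"Net1:{k}", "Cdc14"),
                                p["koff_net1_cdc14"], "unimolecular",
                                param="koff_net1_cdc14", tag="unbind:RENT"))
    for kin, rate in chains["Net1"].kinases:
        pname = f"k_{kin.lower()}_net1"
        for k in range(3):
            rxns.append(ReactionDef((kin, f"Net1:{k}|Cdc14"),
                                    (kin, f"Net1:{k + 1}|Cdc14"), rate,
                                    "bimolecular", param=pname,
                                    tag="phos:Net1"))
        # the 3 -> 4 phosphorylation releases Cdc14
        rxns.append(ReactionDef((kin, "Net1:3|Cdc14"),
                                (kin, "Net1:4", "Cdc14"), rate,
                                "bimolecular", param=pname, tag="phos:Net1"))
    for pho, rate in chains["Net1"].phosphatases:
        pname = f"k_{pho.lower()}_net1"
        for k in range(1, 4):
            rxns.append(ReactionDef((pho, f"Net1:{k}|Cdc14"),
                                    (pho, f"Net1:{k - 1}|Cdc14"), rate,
                                    "bimolecular", param=pname,
                                    tag="dephos:Net1"))

    # ---- Cdc20:APC with the beta^(n-k) affinity ladder --------------------
    beta = p["beta_apc"]
    for k in range(APC_SITES + 1):
        c = f"APC:{k}|Cdc20"
        add_species(c, "complex")
        rxns.append(ReactionDef(
            (f"APC:{k}", "Cdc20"), (c,),
            p["kon_apc_cdc20"] * apc_affinity_factor(k, beta, APC_SITES),
            "bimolecular", param="kon_apc_cdc20", tag="bind:APC:Cdc20"))
        rxns.append(ReactionDef((c,), (f"APC:{k}", "Cdc20"),
                                p["koff_apc_cdc20"], "unimolecular",
                                param="koff_apc_cdc20",
                                tag="unbind:APC:Cdc20"))
        # every Cdc20:APC form has equal catalytic potency
        for sub, key in (("Clb2", "k_c20a_clb2"), ("Clb5", "k_c20a_clb5"),
                         ("Ht1", "k_c20a_ht1")):
            rxns.append(ReactionDef((sub, c), (c,), p[key], "bimolecular",
                                    param=key, tag=f"deg:{sub}:cdc20"))

    # ---- APC:Cdh1 route (active, unphosphorylated Cdh1) -------------------
    rxns.append(ReactionDef(("Clb2", "Cdh1:0"), ("Cdh1:0",),
                            p["k_cdh1_clb2"], "bimolecular",
                            param="k_cdh1_clb2", tag="deg:Clb2:cdh1"))
    rxns.append(ReactionDef(("Cdc20", "Cdh1:0"), ("Cdh1:0",),
                            p["k_cdh1_cdc20"], "bimolecular",
                            param="k_cdh1_cdc20", tag="deg:Cdc20:cdh1"))

    # ---- initial state: newborn daughter in G1 at V = 30 fL ---------------
    v0 = V_BIRTH
    cc = lambda nm: conc_to_count(nm, v0)
    init: dict[str, int] = {}
    for g, row in GENE_TABLE.items():
        if row["reg"]:
            init[f"Goff_{g}"] = 1
            init[f"Gon_{g}"] = 0
        else:
            init[f"G_{g}"] = 1
    init["Gon_SIC1"] = 1          # Swi5 is active in G1
    init["Goff_SIC1"] = 0
    init["Goff_RAD27"] = 1
    for g, row in GENE_TABLE.items():
        if row["reg"]:
            init[f"m_{g}"] = {"SIC1": 6, "SWI5": 3, "CDC20": 1,
                              "CLB2": 1}.get(g, 0)
        else:
            init[f"m_{g}"] = int(round(row["m"]))
    init["Whi5:0"] = cc(150.0)
    init["Whi5:0|SBF"] = cc(150.0)        # SBF fully sequestered at birth
    init["Sic1:0"] = cc(150.0)
    init["Cdh1:0"] = cc(100.0)
    init["Net1:0"] = cc(80.0)
    init["Net1:0|Cdc14"] = cc(160.0)      # Cdc14 fully in RENT
    init["Swi5:0"] = cc(100.0)
    init["Fkh2:0"] = cc(100.0)
    init["APC:0"] = cc(100.0)
    init["Hbf"] = cc(100.0)
    init["Ht1"] = cc(80.0)
    init["Cln3"] = cc(25.0 * (v0 / V_REF) ** 2)
    init["Cdc20"] = cc(3.0)

    net = ReactionNetwork(
        species=species, reactions=rxns, params=p, medium=medium,
        initial_counts=init, roles=roles, genes=genes, chains=chains,
        v_ref=V_REF, name="wild-type",
        annotations=_annotations(p, chain_species),
    )
    return net


def _annotations(p: dict, chain_species: dict[str, list[str]]) -> dict:
    """Engine-facing metadata: indicator weights, event species, thresholds."""
    bud_w = {"Cln1": p["eff_bud_Cln1"], "Cln2": p["eff_bud_Cln2"],
             "Cln3": p["eff_bud_Cln3"], "Clb5": p["eff_bud_Clb5"],
             "Clb2": p["eff_bud_Clb2"]}
    dna_w = {"Clb5": p["eff_dna_Clb5"], "Clb2": p["eff_dna_Clb2"]}
    whi5_nuclear = [f"Whi5:{k}" for k in range(3)] + \
                   [f"Whi5:{k}|SBF" for k in range(3)]
    return {
        "bud_weights": bud_w,
        "dna_weights": dna_w,
        "indicator_rates": {"ks_bud": p["ks_bud"], "kd_bud": p["kd_bud"],
                            "ks_dna": p["ks_dna"], "kd_dna": p["kd_dna"]},
        "division_species": "Clb2",       # free mitotic cyclin concentration
        "whi5_nuclear_species": whi5_nuclear,
        # gene "activity" is the promoter occupancy probability
        # r_on/(r_on + k_off) with r_on = sum(kon_i * [activator_i]); the
        # continuous activity variable of the deterministic formulation is
        # recovered this way in the stochastic engine.
        "reporter_activity": {
            "CLN2": ({"SBF:0": p["kon_CLN2"]}, p["koff_CLN2"]),
            "RAD27": ({"Cln1": p["kon_rad27_cln1"],
                       "Cln2": p["kon_rad27_cln2"],
                       "Cln3": p["kon_rad27_cln3"],
                       "Clb5": p["kon_rad27_clb5"]}, p["koff_RAD27"]),
            "CLB2": ({"Fkh2:2": p["kon_CLB2"]}, p["koff_CLB2"]),
        },
        "cln3_species": ["Cln3"],         # 25/75 daughter/mother partition
        "sic1_total_species": [s for s in chain_species["Sic1"]] +
                              [f"Sic1:{k}|{c}" for k in range(10)
                               for c in ("Clb5", "Clb2")],
        "thresholds": {k[len("thr_"):]: v for k, v in p.items()
                       if k.startswith("thr_")},
    }


def species_groups(net: ReactionNetwork) -> dict[str, dict[str, list[int]]]:
    """Index groups for population snapshots.

    Returns ``{"mrna": {gene: [idx]}, "protein": {protein: [idxs]}}`` where a
    protein group sums every form of that protein — free, phosphorylated to
    any degree, and bound in complexes — the way an antibody blind to
    phospho-epitopes would count it.
    """
    idx = net.species_index()
    mrna = {g: [idx[f"m_{g}"]] for g in net.genes}
    protein: dict[str, list[int]] = {}
    for s, i in idx.items():
        if s.startswith(("G_", "Gon_", "Goff_", "m_")):
            continue
        base = s.split(":")[0]
        protein.setdefault(base, []).append(i)
        if "|" in s:  # complexes count toward the partner too
            partner = s.split("|")[1]
            protein.setdefault(partner, []).append(i)
    return {"mrna": mrna, "protein": protein}


# ---------------------------------------------------------------------------
# mutant catalog
# ---------------------------------------------------------------------------

def mutant_catalog() -> dict[str, MutantSpec]:
    """Named genotype edits for the simulated strains.

    ``clb5`` deletes only the CLB5 half of the composite Clb5,6 variable
    (transcription halved); ``clb5 clb6`` removes it entirely.
    """
    m = {
        "WT": MutantSpec("WT", ()),
        "cln1": MutantSpec("cln1", (("delete", "CLN1"),)),
        "cln2": MutantSpec("cln2", (("delete", "CLN2"),)),
        "cln1 cln2": MutantSpec("cln1 cln2",
                                (("delete", "CLN1"), ("delete", "CLN2"))),
        "clb5": MutantSpec("clb5", (("multicopy", "CLB5", 0.5),)),
        "clb5 clb6": MutantSpec("clb5 clb6", (("delete", "CLB5"),)),
        "sic1": MutantSpec("sic1", (("delete", "SIC1"),)),
        "swi5": MutantSpec("swi5", (("delete", "SWI5"),)),
        "cdh1": MutantSpec("cdh1", (("delete", "CDH1"),)),
        "cln1 cln2 sic1": MutantSpec(
            "cln1 cln2 sic1",
            (("delete", "CLN1"), ("delete", "CLN2"), ("delete", "SIC1"))),
        "swi5 cdh1": MutantSpec("swi5 cdh1",
                                (("delete", "SWI5"), ("delete", "CDH1"))),
        "GAL-CLB2": MutantSpec("GAL-CLB2", (("overexpress", "CLB2", 2.0),)),
        "GAL-CLB5": MutantSpec("GAL-CLB5", (("overexpress", "CLB5", 2.0),)),
        "GAL-SIC1": MutantSpec("GAL-SIC1", (("overexpress", "SIC1", 1.5),)),
        "GAL-NET1": MutantSpec("GAL-NET1", (("overexpress", "NET1", 1.2),)),
        "CLB2-db": MutantSpec("CLB2-db", (("stabilize", "deg:Clb2:cdc20"),
                                          ("stabilize", "deg:Clb2:cdh1"))),
        "CLB2-db clb5": MutantSpec(
            "CLB2-db clb5",
            (("stabilize", "deg:Clb2:cdc20"), ("stabilize", "deg:Clb2:cdh1"),
             ("delete", "CLB5"))),
        "CLB2-db GAL-SIC1": MutantSpec(
            "CLB2-db GAL-SIC1",
            (("stabilize", "deg:Clb2:cdc20"), ("stabilize", "deg:Clb2:cdh1"),
             ("overexpress", "SIC1", 1.5))),
        "swi5 cdh1 GAL-SIC1": MutantSpec(
            "swi5 cdh1 GAL-SIC1",
            (("delete", "SWI5"), ("delete", "CDH1"),
             ("overexpress", "SIC1", 1.5))),
    }
    return m
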