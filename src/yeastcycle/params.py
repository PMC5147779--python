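"""Default rate constants, gene table and thresholds for the wild-type model.

The supplement-level rate table is not shipped with this package; the values
below were calibrated by the package's own helper (:func:`gene_rates`) to the
published population-level anchors:

* mRNA means of 5–10 copies per cell, mRNA half-lives of 5–10 min for most
  genes and 3 min for *CLN1*, *CLN2* and *CLB5*;
* protein copy numbers of roughly 500–9000 per cell (concentrations of
  25–300 nM at the 50-fL reference volume);
* mass doubling times of 99/148/174 min for glucose/galactose/
  glycerol-ethanol;
* the event thresholds: division at [Clb2] = 12.5 nM, budding at
  bud_ss = 25 nM, DNA-synthesis onset at dna_ss = 30 nM, Whi5 nuclear exit
  below 200 nM, gene-activity thresholds 0.15 (CLN2) / 0.2 (CLB2, RAD27).

Units: time min, concentration nM, volume fL.  First-order constants min⁻¹,
second-order constants nM⁻¹·min⁻¹.
"""

from __future__ import annotations

import math

LN2 = math.log(2.0)

V_REF = 50.0          # fL; volume at which concentration-based rates were set
V_BIRTH = 30.0        # fL; founder daughter-cell birth volume

BETA_APC = 0.525      # Cdc20 affinity ladder base
APC_SITES = 11

#: event thresholds (nM except activities, which are occupancy fractions)
THRESHOLDS = {
    "division_clb2": 12.5,
    "division_arm": 25.0,     # Clb2 must first exceed this to arm division
    "bud": 25.0,
    "dna": 30.0,
    "whi5_nuclear": 200.0,
    "act_CLN2": 0.15,
    "act_CLB2": 0.20,
    "act_RAD27": 0.20,
    "act_window": 1.0,        # min; gene-activity smoothing window
    "arrest_window": 500.0,   # min without division => arrested
}

#: CLB2 transcription multiplier per medium (Clb2 synthesis tracks growth
#: rate: poorer media accumulate less Clb2 in M phase)
CLB2_MEDIUM_FACTOR = {
    "glucose": 1.00,
    "galactose": 0.80,
    "glycerol-ethanol": 0.72,
}


MU_CALIBRATION = 0.007   # min^-1; growth rate at which rates were calibrated


def gene_rates(mrna_mean: float, mrna_half_life: float,
               protein_conc: float, protein_half_life: float,
               duty: float = 1.0, mu: float = MU_CALIBRATION) -> dict[str, float]:
    """Back out transcription/translation rates from target stationary levels.

    mRNA numbers obey dM/dt = k_t·duty − δ_m·M (transcription per gene copy
    does not scale with volume), so M = k_t·duty/δ_m.  Protein numbers obey
    dN/dt = k_tl·M·(V/V_ref) − δ_p·N in a volume growing as e^{μt}; on the
    balanced-growth path N tracks volume and the stationary concentration is
    1.67·k_tl·M/(V_ref·(δ_p + μ)) — growth dilution enters through μ, which
    is why k_tl carries the (δ_p + μ) factor.
    """
    k_dm = LN2 / mrna_half_life
    k_dp = LN2 / protein_half_life
    p_count = protein_conc * V_REF / 1.67
    k_t = mrna_mean * k_dm / duty
    k_tl = p_count * (k_dp + mu) / mrna_mean
    return {"k_t": k_t, "k_dm": k_dm, "k_tl": k_tl, "k_dp": k_dp}


# gene table: (regulated?, TF, mRNA mean, mRNA t1/2, protein conc nM at V_ref,
#              protein t1/2, duty, translation volume exponent)
GENE_TABLE: dict[str, dict] = {
    # regulated by SBF (G1/S regulon)
    "CLN1": dict(reg=True, tf="SBF", m=8.0, thm=3.0, p=130.0, thp=6.0, duty=0.8),
    "CLN2": dict(reg=True, tf="SBF", m=8.0, thm=3.0, p=130.0, thp=6.0, duty=0.8),
    "CLB5": dict(reg=True, tf="SBF", m=6.0, thm=3.0, p=100.0, thp=15.0, duty=0.8),
    # regulated by Fkh2 (G2/M cluster)
    "CLB2": dict(reg=True, tf="FKH2", m=8.0, thm=5.0, p=300.0, thp=30.0, duty=0.8),
    "CDC20": dict(reg=True, tf="FKH2", m=6.0, thm=7.0, p=100.0, thp=15.0, duty=0.8),
    "SWI5": dict(reg=True, tf="FKH2", m=5.0, thm=7.0, p=100.0, thp=30.0, duty=0.8),
    # regulated by Swi5
    "SIC1": dict(reg=True, tf="SWI5", m=6.0, thm=7.0, p=150.0, thp=20.0, duty=0.8),
    # constitutive
    "CLN3": dict(reg=False, m=6.0, thm=7.0, p=25.0, thp=10.0, vexp=2),
    "WHI5": dict(reg=False, m=6.0, thm=7.0, p=300.0, thp=60.0),
    "SBF": dict(reg=False, m=5.0, thm=7.0, p=150.0, thp=60.0),
    "FKH2": dict(reg=False, m=5.0, thm=7.0, p=100.0, thp=60.0),
    "APC": dict(reg=False, m=5.0, thm=7.0, p=100.0, thp=60.0),
    "NET1": dict(reg=False, m=6.0, thm=7.0, p=240.0, thp=60.0),
    "CDH1": dict(reg=False, m=6.0, thm=7.0, p=100.0, thp=60.0),
    "CDC14": dict(reg=False, m=6.0, thm=7.0, p=160.0, thp=60.0),
    "HBF": dict(reg=False, m=6.0, thm=7.0, p=100.0, thp=60.0),
    "HT1": dict(reg=False, m=5.0, thm=7.0, p=80.0, thp=30.0),
}

# multisite phosphorylation chains: n sites, activity rule, order mode,
# kinases and phosphatases with second-order rate constants
CHAIN_TABLE: dict[str, dict] = {
    "Whi5": dict(n=10, rule=("le", 2), mode="ordered",
                 kin=[("Cln3", 0.026), ("Cln1", 0.012), ("Cln2", 0.012)],
                 pho=[("Hbf", 0.0095), ("Cdc14", 0.030)]),
    "SBF": dict(n=4, rule=("le", 0), mode="ordered",
                kin=[("Clb2", 0.030)],
                pho=[("Hbf", 0.0040)]),
    "Sic1": dict(n=9, rule=("le", 5), mode="disordered",
                 kin=[("Cln1", 0.010), ("Cln2", 0.010),
                      ("Clb5", 0.010), ("Clb2", 0.004)],
                 pho=[("Cdc14", 0.010), ("Hbf", 0.002)]),
    "Cdh1": dict(n=11, rule=("le", 0), mode="ordered",
                 kin=[("Cln1", 0.003), ("Cln2", 0.003),
                      ("Clb5", 0.005), ("Clb2", 0.012)],
                 pho=[("Cdc14", 0.020), ("Hbf", 0.002)]),
    "Net1": dict(n=8, rule=("le", 3), mode="ordered",
                 kin=[("Clb2", 0.004)],
                 pho=[("Ht1", 0.020), ("Hbf", 0.001)]),
    "Swi5": dict(n=3, rule=("le", 0), mode="ordered",
                 kin=[("Clb2", 0.010)],
                 pho=[("Cdc14", 0.020), ("Hbf", 0.002)]),
    "Fkh2": dict(n=2, rule=("eq", 2), mode="ordered",
                 kin=[("Cln1", 0.0008), ("Cln2", 0.0008), ("Cln3", 0.0003),
                      ("Clb5", 0.0015), ("Clb2", 0.010)],
                 pho=[("Hbf", 0.0075)]),
    # APC activity is graded through the beta ladder, not an on/off rule;
    # the "active" rule below is only used for bookkeeping.
    "APC": dict(n=11, rule=("eq", 11), mode="ordered",
                kin=[("Clb2", 0.0022)],
                pho=[("Hbf", 0.0050)]),
}

#: hand-calibrated departures from the simple birth-death back-calculation;
#: mitotic-cyclin synthesis must overshoot its stationary level to build the
#: M-phase Clb2 peak within ~25 min, and Cdc20 accumulation is slowed so the
#: Cdc20:APC ligase forms with a delay after Clb2 rises.
RATE_OVERRIDES = {
    "ktl_CLB2": 100.0,
    "ktl_CDC20": 8.0,
}


def default_params() -> dict[str, float]:
    """Named rate constants for the wild-type network (complete set)."""
    p: dict[str, float] = {"beta_apc": BETA_APC, "v_ref": V_REF}

    # gene expression
    for g, row in GENE_TABLE.items():
        r = gene_rates(row["m"], row["thm"], row["p"], row["thp"],
                       row.get("duty", 1.0))
        p[f"kt_{g}"] = r["k_t"]
        p[f"kdm_{g}"] = r["k_dm"]
        p[f"ktl_{g}"] = r["k_tl"]
        p[f"kdp_{g}"] = r["k_dp"]
        if row["reg"]:
            p[f"kon_{g}"] = 0.08    # promoter activation per nM of active TF
            p[f"koff_{g}"] = 2.0    # promoter deactivation

    # RAD27 reporter promoter (G1/S regulon member, no mRNA/protein tracked)
    p["kon_rad27_cln1"] = 0.010
    p["kon_rad27_cln2"] = 0.010
    p["kon_rad27_cln3"] = 0.0008
    p["kon_rad27_clb5"] = 0.010
    p["koff_RAD27"] = 2.0

    # chain kinase/phosphatase constants, exposed under scan-friendly names
    for prot, row in CHAIN_TABLE.items():
        for kin, rate in row["kin"]:
            p[f"k_{kin.lower()}_{prot.lower()}"] = rate
        for pho, rate in row["pho"]:
            p[f"k_{pho.lower()}_{prot.lower()}"] = rate

    # complex association/dissociation
    p["kon_whi5_sbf"] = 0.10
    p["koff_whi5_sbf"] = 0.01
    p["kon_sic1_clb5"] = 0.05
    p["koff_sic1_clb5"] = 0.05
    p["kon_sic1_clb2"] = 0.05
    p["koff_sic1_clb2"] = 0.05
    p["kon_net1_cdc14"] = 0.05
    p["koff_net1_cdc14"] = 0.01
    p["kon_apc_cdc20"] = 0.05     # scaled by beta^(11-k) per phospho-form
    p["koff_apc_cdc20"] = 0.10

    # regulated degradation routes
    p["k_c20a_clb2"] = 0.020      # Cdc20:APC-mediated Clb2 degradation
    p["k_c20a_clb5"] = 0.020
    p["k_c20a_ht1"] = 0.050
    p["k_cdh1_clb2"] = 0.020      # APC:Cdh1-mediated
    p["k_cdh1_cdc20"] = 0.010
    p["k_deg_sic1p"] = 1.0        # SCF route for Sic1 with >= 6 phosphates

    # event indicators: first-order relaxation toward efficiency-weighted
    # cyclin concentrations
    p["ks_bud"] = 0.2
    p["kd_bud"] = 0.2
    p["ks_dna"] = 0.2
    p["kd_dna"] = 0.2
    p["eff_bud_Cln1"] = 0.40
    p["eff_bud_Cln2"] = 0.40
    p["eff_bud_Cln3"] = 0.10
    p["eff_bud_Clb5"] = 0.20
    p["eff_bud_Clb2"] = 0.05
    p["eff_dna_Clb5"] = 0.80
    p["eff_dna_Clb2"] = 0.30

    p.update(RATE_OVERRIDES)
    p.update({f"thr_{k}": v for k, v in THRESHOLDS.items()})
    return p
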