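"""Flat array representation of a ReactionNetwork shared by both engines.

The SSA kernel and the ODE right-hand side evaluate propensities from the
same arrays, which is what guarantees the mean-field consistency between the
two engines (a unit mismatch in either one breaks the shared-rate oracle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork
from .units import NM_PER_MOLECULE_FL

# propensity kinds (must match the kernel dispatch)
K_SYNTHESIS = 0       # a = k * V / 1.67           (zero order, conc rate)
K_CONSTANT = 1        # a = k                      (zero order, number rate)
K_UNI = 2             # a = k * N1
K_BI = 3              # a = k * N1 * N2 * 1.67 / V
K_BI_HOMO = 4         # a = k * N1 (N1-1)/2 * 1.67 / V
K_TRANSLATION = 5     # a = k * N1 * (V/V_ref)**vexp

_KIND_CODE = {
    "synthesis": K_SYNTHESIS,
    "constant": K_CONSTANT,
    "unimolecular": K_UNI,
    "bimolecular": K_BI,
    "bimolecular_homo": K_BI_HOMO,
    "translation": K_TRANSLATION,
}


@dataclass
class CompiledNetwork:
    species: list[str]
    index: dict[str, int]
    rate: np.ndarray        # float64 (n_rxn,)
    kind: np.ndarray        # int8
    r1: np.ndarray          # int32, -1 if absent
    r2: np.ndarray          # int32, -1 if absent
    vexp: np.ndarray        # int8
    stoich: np.ndarray      # int8 (n_rxn, n_species) net stoichiometry
    v_ref: float
    mu: float

    # event/indicator metadata (zero-filled when the network has none)
    bud_w: np.ndarray       # per-species efficiency weights (conc basis)
    dna_w: np.ndarray
    whi5_mask: np.ndarray   # 1.0 for nuclear-Whi5 species
    sic1_mask: np.ndarray   # 1.0 for total-Sic1 species
    div_idx: int            # species index of free Clb2 (-1: no division)
    rep_w: np.ndarray       # (3, n_species) kon weights for gene activity
    rep_koff: np.ndarray    # (3,) promoter deactivation rates
    ks_bud: float = 0.0
    kd_bud: float = 0.0
    ks_dna: float = 0.0
    kd_dna: float = 0.0
    thr_div: float = np.inf
    thr_arm: float = np.inf
    thr_bud: float = np.inf
    thr_dna: float = np.inf
    thr_whi5: float = 0.0
    thr_act: np.ndarray = None  # activity thresholds for the 3 reporters
    act_window: float = 5.0     # min; promoter-activity smoothing window

    # sparse structure for the SSA kernel: which species each reaction
    # changes, and which reactions each species' count feeds into
    chg_ptr: np.ndarray = None   # int32 (n_rxn+1,)
    chg_sp: np.ndarray = None    # int32
    chg_d: np.ndarray = None     # int8
    dep_ptr: np.ndarray = None   # int32 (n_species+1,)
    dep_rxn: np.ndarray = None   # int32

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.rate)


def compile_network(net: ReactionNetwork) -> CompiledNetwork:
    idx = net.species_index()
    n_rxn = net.n_reactions
    n_sp = net.n_species
    rate = np.zeros(n_rxn)
    kind = np.zeros(n_rxn, dtype=np.int8)
    r1 = np.full(n_rxn, -1, dtype=np.int32)
    r2 = np.full(n_rxn, -1, dtype=np.int32)
    vexp = np.ones(n_rxn, dtype=np.int8)
    stoich = np.zeros((n_rxn, n_sp), dtype=np.int8)
    for j, r in enumerate(net.reactions):
        rate[j] = r.rate
        vexp[j] = r.vol_exp
        reactants = list(r.reactants)
        if len(reactants) == 2 and reactants[0] == reactants[1]:
            kind[j] = K_BI_HOMO if r.kind == "bimolecular" else _KIND_CODE[r.kind]
            r1[j] = idx[reactants[0]]
        else:
            kind[j] = _KIND_CODE[r.kind]
            if reactants:
                r1[j] = idx[reactants[0]]
            if len(reactants) == 2:
                r2[j] = idx[reactants[1]]
        for s, v in r.net_stoich().items():
            stoich[j, idx[s]] = v

    # sparse change lists (CSR over reactions)
    chg_ptr = np.zeros(n_rxn + 1, dtype=np.int32)
    chg_sp_l: list[int] = []
    chg_d_l: list[int] = []
    for j in range(n_rxn):
        nz = np.nonzero(stoich[j])[0]
        chg_ptr[j + 1] = chg_ptr[j] + len(nz)
        chg_sp_l.extend(nz.tolist())
        chg_d_l.extend(stoich[j, nz].tolist())
    chg_sp = np.array(chg_sp_l, dtype=np.int32)
    chg_d = np.array(chg_d_l, dtype=np.int8)

    # dependency lists: reactions whose propensity reads species i
    deps: list[list[int]] = [[] for _ in range(n_sp)]
    for j in range(n_rxn):
        if r1[j] >= 0:
            deps[r1[j]].append(j)
        if r2[j] >= 0 and r2[j] != r1[j]:
            deps[r2[j]].append(j)
    dep_ptr = np.zeros(n_sp + 1, dtype=np.int32)
    dep_l: list[int] = []
    for i in range(n_sp):
        dep_ptr[i + 1] = dep_ptr[i] + len(deps[i])
        dep_l.extend(deps[i])
    dep_rxn = np.array(dep_l, dtype=np.int32)

    ann = net.annotations
    bud_w = np.zeros(n_sp)
    dna_w = np.zeros(n_sp)
    whi5_mask = np.zeros(n_sp)
    sic1_mask = np.zeros(n_sp)
    rep_w = np.zeros((3, n_sp))
    rep_koff = np.zeros(3)
    div_idx = -1
    ks_bud = kd_bud = ks_dna = kd_dna = 0.0
    thr = {}
    if ann:
        for s, w in ann.get("bud_weights", {}).items():
            bud_w[idx[s]] = w
        for s, w in ann.get("dna_weights", {}).items():
            dna_w[idx[s]] = w
        for s in ann.get("whi5_nuclear_species", []):
            whi5_mask[idx[s]] = 1.0
        for s in ann.get("sic1_total_species", []):
            sic1_mask[idx[s]] = 1.0
        div = ann.get("division_species")
        if div is not None:
            div_idx = idx[div]
        rep = ann.get("reporter_activity", {})
        for i, g in enumerate(("CLN2", "RAD27", "CLB2")):
            if g in rep:
                weights, koff = rep[g]
                for s, w in weights.items():
                    rep_w[i, idx[s]] = w
                rep_koff[i] = koff
        rates = ann.get("indicator_rates", {})
        ks_bud = rates.get("ks_bud", 0.0)
        kd_bud = rates.get("kd_bud", 0.0)
        ks_dna = rates.get("ks_dna", 0.0)
        kd_dna = rates.get("kd_dna", 0.0)
        thr = ann.get("thresholds", {})

    return CompiledNetwork(
        species=list(net.species), index=idx,
        rate=rate, kind=kind, r1=r1, r2=r2, vexp=vexp, stoich=stoich,
        v_ref=net.v_ref, mu=net.medium.mu,
        bud_w=bud_w, dna_w=dna_w, whi5_mask=whi5_mask, sic1_mask=sic1_mask,
        div_idx=div_idx, rep_w=rep_w, rep_koff=rep_koff,
        ks_bud=ks_bud, kd_bud=kd_bud, ks_dna=ks_dna, kd_dna=kd_dna,
        thr_div=thr.get("division_clb2", np.inf),
        thr_arm=thr.get("division_arm", np.inf),
        thr_bud=thr.get("bud", np.inf),
        thr_dna=thr.get("dna", np.inf),
        thr_whi5=thr.get("whi5_nuclear", 0.0),
        thr_act=np.array([thr.get("act_CLN2", 2.0), thr.get("act_RAD27", 2.0),
                          thr.get("act_CLB2", 2.0)]),
        act_window=thr.get("act_window", 5.0),
        chg_ptr=chg_ptr, chg_sp=chg_sp, chg_d=chg_d,
        dep_ptr=dep_ptr, dep_rxn=dep_rxn,
    )


def propensities(cn: CompiledNetwork, counts: np.ndarray, volume: float) -> np.ndarray:
    """Vectorized propensity evaluation (used by the ODE engine and tests).

    Evaluates the same formulas as the SSA kernel, accepting non-integer
    states so the ODE engine can reuse it as its mean-field rate vector.
    """
    n = np.asarray(counts, dtype=float)
    conv = NM_PER_MOLECULE_FL / volume
    n1 = np.where(cn.r1 >= 0, n[np.maximum(cn.r1, 0)], 1.0)
    n2 = np.where(cn.r2 >= 0, n[np.maximum(cn.r2, 0)], 1.0)
    a = np.empty(cn.n_reactions)
    k = cn.kind
    a[k == K_SYNTHESIS] = cn.rate[k == K_SYNTHESIS] * volume / NM_PER_MOLECULE_FL
    a[k == K_CONSTANT] = cn.rate[k == K_CONSTANT]
    m = k == K_UNI
    a[m] = cn.rate[m] * n1[m]
    m = k == K_BI
    a[m] = cn.rate[m] * n1[m] * n2[m] * conv
    m = k == K_BI_HOMO
    a[m] = cn.rate[m] * n1[m] * (n1[m] - 1.0) * 0.5 * conv
    m = k == K_TRANSLATION
    a[m] = cn.rate[m] * n1[m] * (volume / cn.v_ref) ** cn.vexp[m].astype(float)
    return a
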