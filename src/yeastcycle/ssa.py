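"""Exact stochastic simulation of one cell in an exponentially growing volume.

The engine is Gillespie's direct method over the network's elementary
reactions.  Cell volume grows as V(t) = V(0)·e^{μt} and is treated as
constant between forced clock boundaries every ``dt_null`` minutes, at which
propensities are refreshed, the continuous indicator variables (bud_ss,
dna_ss) are advanced, and threshold events are scored.  Identical
(network, initial state, horizon, seed) inputs give bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .compiled import CompiledNetwork, compile_network, propensities
from .network import ReactionNetwork
from .units import NM_PER_MOLECULE_FL, omega

DT_NULL = 0.1   # min between forced volume/indicator updates


@dataclass
class CellState:
    """Instantaneous state of one simulated cell."""

    t: float                       # absolute time, min
    volume: float                  # fL
    counts: np.ndarray             # integer copy numbers per species
    bud_ss: float = 0.0            # budding indicator, nM
    dna_ss: float = 0.0            # DNA-synthesis indicator, nM

    def copy(self) -> "CellState":
        return CellState(self.t, self.volume, self.counts.copy(),
                         self.bud_ss, self.dna_ss)


@dataclass
class Trajectory:
    """Sampled single-cell trajectory plus its event log.

    ``events`` maps event name -> age since birth (min); events that never
    occurred are absent.  ``status`` is "divided" or "horizon".
    """

    species: list[str]
    t: np.ndarray
    volume: np.ndarray
    counts: np.ndarray             # (n_samples, n_species)
    bud_ss: np.ndarray
    dna_ss: np.ndarray
    events: dict = field(default_factory=dict)
    status: str = "horizon"
    final_state: CellState | None = None
    n_reactions_fired: int = 0

    def conc(self, species: str) -> np.ndarray:
        """Concentration time series (nM) for one species."""
        j = self.species.index(species)
        return NM_PER_MOLECULE_FL * self.counts[:, j] / self.volume

    def to_frame(self):
        import pandas as pd
        data = {"t": self.t, "V": self.volume,
                "bud_ss": self.bud_ss, "dna_ss": self.dna_ss}
        for j, s in enumerate(self.species):
            data[s] = self.counts[:, j]
        return pd.DataFrame(data)


def propensity(cn: CompiledNetwork | ReactionNetwork, counts, volume: float):
    """Propensity vector (events·min⁻¹) at the given state.

    Zero-order synthesis scales with Ω(V) = V/1.67, unimolecular reactions
    with N, bimolecular with N₁N₂/Ω (N(N−1)/2Ω for homodimerization), and
    translation with N_mRNA·(V/V_ref)^e, e = 1 (2 for CLN3).
    """
    if isinstance(cn, ReactionNetwork):
        cn = compile_network(cn)
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative species count")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return propensities(cn, counts, volume)


_EVENT_NAMES = ("t_bud", "t_dna", "t_whi5_exit",
                "t_act_CLN2", "t_act_RAD27", "t_act_CLB2")


def run_cell_cycle(cn: CompiledNetwork, counts: np.ndarray, v0: float,
                   horizon: float, seed: int,
                   sample_dt: float = 0.0,
                   dt_null: float = DT_NULL):
    """Low-level driver: one birth-to-division (or horizon) kernel run.

    Returns (status, age_end, v_end, events dict, trajectory arrays or None,
    n_fired).  ``counts`` is modified in place and holds the final state.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if cn.n_reactions == 0:
        # nothing can fire: counts constant, volume grows exponentially
        if sample_dt > 0:
            t_s = np.arange(0.0, horizon + 1e-9, sample_dt)
        else:
            t_s = np.array([0.0, horizon])
        v_s = v0 * np.exp(cn.mu * t_s)
        counts_s = np.tile(counts, (len(t_s), 1))
        zeros = np.zeros_like(t_s)
        return (0, horizon, float(v_s[-1]), {},
                (t_s, v_s, zeros, zeros, counts_s), 0)
    stride = 0
    n_max = 2
    if sample_dt > 0:
        stride = max(1, int(round(sample_dt / dt_null)))
        n_max = int(np.ceil(horizon / (stride * dt_null))) + 2
    samp_t = np.zeros(n_max)
    samp_v = np.zeros(n_max)
    samp_bud = np.zeros(n_max)
    samp_dna = np.zeros(n_max)
    samp_counts = np.zeros((n_max if stride else 1, cn.n_species),
                           dtype=np.int64)
    status, age, v_end, ev, n_samp, n_fired = _kernel.run_cycle(
        counts, v0, horizon, cn.mu,
        cn.rate, cn.kind, cn.r1, cn.r2, cn.vexp,
        cn.chg_ptr, cn.chg_sp, cn.chg_d, cn.dep_ptr, cn.dep_rxn,
        cn.v_ref, dt_null,
        cn.bud_w, cn.dna_w, cn.whi5_mask,
        cn.div_idx, cn.rep_w, cn.rep_koff,
        cn.ks_bud, cn.kd_bud, cn.ks_dna, cn.kd_dna,
        cn.thr_div, cn.thr_arm, cn.thr_bud, cn.thr_dna, cn.thr_whi5,
        cn.thr_act, cn.act_window,
        stride, samp_t, samp_v, samp_bud, samp_dna, samp_counts,
        int(seed) & 0x7FFFFFFF,
    )
    events = {name: float(ev[i]) for i, name in enumerate(_EVENT_NAMES)
              if ev[i] >= 0.0}
    traj = None
    if stride:
        traj = (samp_t[:n_samp], samp_v[:n_samp], samp_bud[:n_samp],
                samp_dna[:n_samp], samp_counts[:n_samp])
    return status, age, v_end, events, traj, n_fired


def simulate_cell(net: ReactionNetwork | CompiledNetwork,
                  init: CellState | None = None,
                  t_end: float = 100.0,
                  seed: int = 0,
                  sample_dt: float = 1.0,
                  dt_null: float = DT_NULL,
                  stop_at_division: bool = False) -> Trajectory:
    """Simulate one cell with the exact SSA and return its trajectory.

    By default the run continues to ``t_end`` even if a division event is
    scored (the event is logged); with ``stop_at_division`` the trajectory
    ends at the division time, as used by the culture scheduler.
    """
    if isinstance(net, ReactionNetwork):
        cn = compile_network(net)
        if init is None:
            init = CellState(
                t=0.0, volume=getattr(net, "annotations", {}).get(
                    "v_birth", 30.0),
                counts=np.array(net.initial_state_vector(), dtype=np.int64))
    else:
        cn = net
        if init is None:
            raise ValueError("an initial CellState is required for a "
                             "compiled network")
    if t_end <= init.t:
        raise ValueError("t_end must exceed the initial time")

    counts = init.counts.astype(np.int64).copy()
    if np.any(counts < 0):
        raise ValueError("negative initial count")
    horizon = t_end - init.t
    cn_run = cn
    if not stop_at_division and cn.div_idx >= 0:
        # disable the terminal division check but keep event scoring
        import copy as _copy
        cn_run = _copy.copy(cn)
        cn_run.thr_div = -np.inf
    status, age, v_end, events, traj, n_fired = run_cell_cycle(
        cn_run, counts, init.volume, horizon, seed, sample_dt, dt_null)
    if traj is None:
        traj = (np.array([0.0, age]), np.array([init.volume, v_end]),
                np.zeros(2), np.zeros(2),
                np.vstack([init.counts, counts]))
    t_s, v_s, bud_s, dna_s, counts_s = traj
    out = Trajectory(
        species=list(cn.species),
        t=init.t + t_s, volume=v_s, counts=counts_s,
        bud_ss=bud_s, dna_ss=dna_s,
        events=events,
        status="divided" if status == 1 else "horizon",
        final_state=CellState(init.t + age, v_end, counts,
                              float(bud_s[-1]), float(dna_s[-1])),
        n_reactions_fired=n_fired,
    )
    if status == 1:
        out.events["t_div"] = age
    return out
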