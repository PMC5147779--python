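"""Deterministic (mass-action ODE) engine over the same rate table as the SSA.

The state is integrated in molecule-number units, so growth enters only
through the volume scaling of the shared propensity formulas — there is no
separate dilution term, and the right-hand side is exactly the
stoichiometry-weighted sum of SSA propensities.  Division is symmetric: when
the free Clb2 concentration, having first risen above the arming level,
falls through the division threshold, cell volume and all molecular species
(not gene copies) are halved and the indicators reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .compiled import CompiledNetwork, compile_network, propensities
from .network import ReactionNetwork
from .units import NM_PER_MOLECULE_FL


@dataclass
class OdeTrajectory:
    species: list[str]
    t: np.ndarray
    volume: np.ndarray
    counts: np.ndarray           # (n_t, n_species), float molecule numbers
    bud_ss: np.ndarray
    dna_ss: np.ndarray
    division_times: list[float] = field(default_factory=list)
    events: dict = field(default_factory=dict)

    def conc(self, species: str) -> np.ndarray:
        j = self.species.index(species)
        return NM_PER_MOLECULE_FL * self.counts[:, j] / self.volume

    def periods(self) -> np.ndarray:
        """Division-to-division cycle lengths."""
        return np.diff(np.asarray(self.division_times))

    def to_frame(self):
        import pandas as pd
        data = {"t": self.t, "V": self.volume,
                "bud_ss": self.bud_ss, "dna_ss": self.dna_ss}
        for j, s in enumerate(self.species):
            data[s] = self.counts[:, j]
        return pd.DataFrame(data)


def derivatives(net: ReactionNetwork | CompiledNetwork, counts, volume: float):
    """Mass-action right-hand side dN/dt (molecules·min⁻¹) plus dV/dt.

    Identical to the stoichiometry-weighted propensity sum of the stochastic
    engine at the same state; returns ``(dN, dV)``.
    """
    cn = compile_network(net) if isinstance(net, ReactionNetwork) else net
    n = np.asarray(counts, dtype=float)
    if np.any(n < 0):
        raise ValueError("negative species count")
    a = propensities(cn, n, volume)
    dn = cn.stoich.T.astype(float) @ a
    return dn, cn.mu * volume


def simulate_deterministic(net: ReactionNetwork | CompiledNetwork,
                           t_end: float,
                           init_counts=None,
                           v0: float | None = None,
                           rtol: float = 1e-6,
                           atol: float = 1e-6,
                           sample_dt: float = 0.5,
                           method: str = "LSODA") -> OdeTrajectory:
    """Integrate the network deterministically with symmetric divisions.

    Divisions require arming: free Clb2 must exceed the arming level before a
    downward crossing of the division threshold fires; newborn (symmetric)
    cells therefore do not re-trigger on their low initial Clb2.
    """
    if isinstance(net, ReactionNetwork):
        cn = compile_network(net)
        if init_counts is None:
            init_counts = np.array(net.initial_state_vector(), dtype=float)
        if v0 is None:
            v0 = 30.0
    else:
        cn = net
        if init_counts is None:
            raise ValueError("init_counts required for a compiled network")
        if v0 is None:
            raise ValueError("v0 required for a compiled network")

    n_sp = cn.n_species
    promoter_mask = np.array(
        [1.0 if s.startswith(("G_", "Gon_", "Goff_")) else 0.5
         for s in cn.species])   # multiply by this at division
    st = cn.stoich.T.astype(float)
    conv = NM_PER_MOLECULE_FL

    def rhs(t, y):
        n = np.maximum(y[:n_sp], 0.0)
        xb, xd, vol = y[n_sp], y[n_sp + 1], y[n_sp + 2]
        a = propensities(cn, n, vol)
        dn = st @ a
        out = np.empty(n_sp + 3)
        out[:n_sp] = dn
        wb = cn.bud_w @ n * conv / vol
        wd = cn.dna_w @ n * conv / vol
        out[n_sp] = cn.ks_bud * wb - cn.kd_bud * xb
        out[n_sp + 1] = cn.ks_dna * wd - cn.kd_dna * xd
        out[n_sp + 2] = cn.mu * vol
        return out

    def clb2_conc(y):
        if cn.div_idx < 0:
            return -1.0
        return y[cn.div_idx] * conv / y[n_sp + 2]

    def arm_event(t, y):
        return clb2_conc(y) - cn.thr_arm
    arm_event.terminal = True
    arm_event.direction = 1

    def div_event(t, y):
        return clb2_conc(y) - cn.thr_div
    div_event.terminal = True
    div_event.direction = -1

    y = np.concatenate([np.asarray(init_counts, float), [0.0, 0.0, v0]])
    t = 0.0
    armed = False
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    div_times: list[float] = []
    do_events = cn.div_idx >= 0 and np.isfinite(cn.thr_div)

    while t < t_end:
        grid = np.arange(t, t_end + 1e-9, sample_dt)
        if grid[-1] < t_end:
            grid = np.append(grid, t_end)
        ev = ([arm_event] if not armed else [div_event]) if do_events else []
        sol = solve_ivp(rhs, (t, t_end), y, method=method, rtol=rtol,
                        atol=atol, t_eval=grid[grid >= t], events=ev,
                        max_step=5.0)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed at t={t}: "
                               f"{sol.message}")
        ts.append(sol.t)
        ys.append(sol.y.T)
        if sol.status == 1 and ev:   # event fired
            t = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            if not armed:
                armed = True
            else:
                div_times.append(t)
                y[:n_sp] *= promoter_mask
                y[n_sp] = 0.0
                y[n_sp + 1] = 0.0
                y[n_sp + 2] /= 2.0
                armed = False
        else:
            break

    tt = np.concatenate(ts)
    yy = np.vstack(ys)
    return OdeTrajectory(
        species=list(cn.species), t=tt, volume=yy[:, n_sp + 2],
        counts=yy[:, :n_sp], bud_ss=yy[:, n_sp], dna_ss=yy[:, n_sp + 1],
        division_times=div_times)
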