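"""Numba kernel for the exact SSA with exponentially growing volume.

Direct-method Gillespie with volume held piecewise-constant between forced
"clock" boundaries every ``dt_null`` minutes (default 0.1 min; with
mu ~ 0.007 min^-1 the per-interval volume error is < 0.1%).  Between
boundaries, propensities are maintained incrementally through a species ->
reaction dependency graph, and the next reaction is selected from 32-wide
partial sums; the full propensity vector is recomputed at every boundary so
floating-point drift cannot accumulate.  Indicator variables (bud_ss,
dna_ss) are deterministic first-order relaxations updated exactly at each
boundary; gene activity is the promoter occupancy probability
r_on/(r_on + k_off) computed from active-TF concentrations and smoothed
over ``act_window`` minutes before threshold comparison.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# event-vector layout returned by run_cycle
EV_BUD = 0
EV_DNA = 1
EV_WHI5 = 2
EV_ACT_CLN2 = 3
EV_ACT_RAD27 = 4
EV_ACT_CLB2 = 5
N_EV = 6

NM = 1.67  # nM per molecule per fL

GROUP_SHIFT = 5  # 32 reactions per selection group


@njit(cache=True, inline="always")
def _one_propensity(j, counts, conv, vol_over_nm, vr, rate, kind, r1, r2,
                    vexp):
    # conv = 1.67/V, vol_over_nm = V/1.67, vr = V/V_ref
    k = kind[j]
    if k == 3:
        return rate[j] * counts[r1[j]] * counts[r2[j]] * conv
    elif k == 2:
        return rate[j] * counts[r1[j]]
    elif k == 5:
        if vexp[j] == 1:
            return rate[j] * counts[r1[j]] * vr
        return rate[j] * counts[r1[j]] * vr * vr
    elif k == 4:
        n = counts[r1[j]]
        return rate[j] * n * (n - 1) * 0.5 * conv
    elif k == 1:
        return rate[j]
    else:
        return rate[j] * vol_over_nm


@njit(cache=True)
def _refresh(counts, volume, v_ref, rate, kind, r1, r2, vexp, a, gsum):
    conv = NM / volume
    vol_over_nm = volume / NM
    vr = volume / v_ref
    gsum[:] = 0.0
    total = 0.0
    for j in range(rate.shape[0]):
        aj = _one_propensity(j, counts, conv, vol_over_nm, vr, rate, kind,
                             r1, r2, vexp)
        a[j] = aj
        gsum[j >> GROUP_SHIFT] += aj
        total += aj
    return total


@njit(cache=True)
def run_cycle(counts, v0, horizon, mu,
              rate, kind, r1, r2, vexp,
              chg_ptr, chg_sp, chg_d, dep_ptr, dep_rxn,
              v_ref, dt_null,
              bud_w, dna_w, whi5_mask,
              div_idx, rep_w, rep_koff,
              ks_bud, kd_bud, ks_dna, kd_dna,
              thr_div, thr_arm, thr_bud, thr_dna, thr_whi5, thr_act,
              act_window,
              sample_stride, samp_t, samp_v, samp_bud, samp_dna, samp_counts,
              seed):
    """Simulate one cell from birth (age 0) to division or ``horizon``.

    Mutates ``counts`` in place.  Returns
    (status, age_end, V_end, events, n_samples, n_events_fired) where status
    is 1 if the cell divided and 0 if the horizon was reached first.
    Sampling rows are written into the pre-allocated ``samp_*`` arrays every
    ``sample_stride`` boundaries (0 disables sampling).
    """
    np.random.seed(seed)
    n_rxn = rate.shape[0]
    n_sp = counts.shape[0]
    n_grp = (n_rxn + (1 << GROUP_SHIFT) - 1) >> GROUP_SHIFT
    a = np.empty(n_rxn)
    gsum = np.empty(n_grp)
    stamp = np.full(n_rxn, -1, dtype=np.int64)
    ev = np.full(N_EV, -1.0)

    t = 0.0
    volume = v0
    t_next = dt_null
    boundary = 1
    x_bud = 0.0
    x_dna = 0.0
    armed = False
    divided = False
    n_fired = 0
    n_samp = 0

    # promoter-occupancy moving-average ring (act_window / dt_null slots)
    win = max(1, int(round(act_window / dt_null)))
    occ = np.zeros((3, win))
    occ_pos = 0
    occ_filled = 0

    whi5_prev = 0.0
    for i in range(n_sp):
        whi5_prev += whi5_mask[i] * counts[i]
    whi5_prev *= NM / volume

    conv = NM / volume
    vol_over_nm = volume / NM
    vr = volume / v_ref
    a0 = _refresh(counts, volume, v_ref, rate, kind, r1, r2, vexp, a, gsum)

    if sample_stride > 0:
        samp_t[0] = 0.0
        samp_v[0] = volume
        samp_bud[0] = x_bud
        samp_dna[0] = x_dna
        for i in range(n_sp):
            samp_counts[0, i] = counts[i]
        n_samp = 1

    while t < horizon:
        tau = np.inf
        if a0 > 1e-12:
            tau = np.random.exponential(1.0 / a0)
        if t + tau >= t_next:
            # advance to the clock boundary: update volume & indicators,
            # score events, refresh propensities.  Indicators were last
            # updated at the previous boundary, so they advance by dt_null.
            dt = dt_null
            t = t_next
            volume = v0 * math.exp(mu * t)

            # indicator relaxation with frozen inputs over the interval
            if kd_bud > 0.0:
                s = 0.0
                for i in range(n_sp):
                    s += bud_w[i] * counts[i]
                target = ks_bud / kd_bud * (s * NM / volume)
                x_bud = target + (x_bud - target) * math.exp(-kd_bud * dt)
            if kd_dna > 0.0:
                s = 0.0
                for i in range(n_sp):
                    s += dna_w[i] * counts[i]
                target = ks_dna / kd_dna * (s * NM / volume)
                x_dna = target + (x_dna - target) * math.exp(-kd_dna * dt)

            if ev[EV_BUD] < 0.0 and x_bud >= thr_bud:
                ev[EV_BUD] = t
            if ev[EV_DNA] < 0.0 and x_dna >= thr_dna:
                ev[EV_DNA] = t

            if thr_whi5 > 0.0:
                w = 0.0
                for i in range(n_sp):
                    w += whi5_mask[i] * counts[i]
                w *= NM / volume
                if ev[EV_WHI5] < 0.0 and whi5_prev >= thr_whi5 > w:
                    ev[EV_WHI5] = t
                whi5_prev = w

            # gene activity = promoter occupancy probability
            # r_on/(r_on + koff), r_on from active-TF concentrations;
            # smoothed over the activity window before threshold comparison
            for g in range(3):
                if rep_koff[g] > 0.0:
                    r_on = 0.0
                    for i in range(n_sp):
                        if rep_w[g, i] != 0.0:
                            r_on += rep_w[g, i] * counts[i]
                    r_on *= NM / volume
                    occ[g, occ_pos] = r_on / (r_on + rep_koff[g])
            occ_pos = (occ_pos + 1) % win
            if occ_filled < win:
                occ_filled += 1
            if occ_filled == win:
                for g in range(3):
                    if rep_koff[g] > 0.0 and ev[EV_ACT_CLN2 + g] < 0.0:
                        m = 0.0
                        for q in range(win):
                            m += occ[g, q]
                        m /= win
                        if m >= thr_act[g]:
                            ev[EV_ACT_CLN2 + g] = t

            # armed division on downward [Clb2] crossing
            if div_idx >= 0:
                clb2 = counts[div_idx] * NM / volume
                if not armed and clb2 >= thr_arm:
                    armed = True
                if armed and clb2 < thr_div:
                    divided = True

            if sample_stride > 0 and boundary % sample_stride == 0:
                samp_t[n_samp] = t
                samp_v[n_samp] = volume
                samp_bud[n_samp] = x_bud
                samp_dna[n_samp] = x_dna
                for i in range(n_sp):
                    samp_counts[n_samp, i] = counts[i]
                n_samp += 1

            if divided:
                break
            boundary += 1
            t_next += dt_null
            conv = NM / volume
            vol_over_nm = volume / NM
            vr = volume / v_ref
            a0 = _refresh(counts, volume, v_ref, rate, kind, r1, r2, vexp,
                          a, gsum)
        else:
            # fire one reaction: select from group sums, apply stoichiometry,
            # refresh only the propensities that read a changed species
            t += tau
            u = np.random.random() * a0
            g = 0
            acc = 0.0
            while g < n_grp - 1 and acc + gsum[g] < u:
                acc += gsum[g]
                g += 1
            j = g << GROUP_SHIFT
            jmax = min(n_rxn, (g + 1) << GROUP_SHIFT) - 1
            while j < jmax and acc + a[j] < u:
                acc += a[j]
                j += 1

            for q in range(chg_ptr[j], chg_ptr[j + 1]):
                counts[chg_sp[q]] += chg_d[q]
            n_fired += 1

            for q in range(chg_ptr[j], chg_ptr[j + 1]):
                sp = chg_sp[q]
                for d in range(dep_ptr[sp], dep_ptr[sp + 1]):
                    rj = dep_rxn[d]
                    if stamp[rj] != n_fired:
                        stamp[rj] = n_fired
                        old = a[rj]
                        new = _one_propensity(rj, counts, conv, vol_over_nm,
                                              vr, rate, kind, r1, r2, vexp)
                        a[rj] = new
                        diff = new - old
                        a0 += diff
                        gsum[rj >> GROUP_SHIFT] += diff

    status = 1 if divided else 0
    return status, t, volume, ev, n_samp, n_fired
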