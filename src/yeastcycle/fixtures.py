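"""Small reference networks with independent oracles.

These fixtures exercise every propensity kind of the engines on problems
with closed-form or numerically exact (truncated master equation) answers,
so the SSA and ODE contracts can be validated without the full cell-cycle
model.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space
from scipy.stats import poisson

from .network import Medium, ReactionDef, ReactionNetwork

#: a non-growing "medium" for fixed-volume fixtures (mu tiny but positive)
STATIC = Medium("static", 1e-12, 0.4)

FIXTURE_KINDS = ("constitutive_gene", "two_state_promoter", "decay_only",
                 "dimerization")


def fixture_network(kind: str, **kw) -> tuple[ReactionNetwork, dict]:
    """Return (network, oracle) for one of the named fixture kinds.

    The oracle dict carries closed-form expectations: a stationary
    distribution over copy number, a mean, or a half-life, depending on the
    fixture.
    """
    if kind == "constitutive_gene":
        k_t = kw.get("k_t", 1.0)       # mRNA/min (number-based zero order)
        k_d = kw.get("k_d", 0.1)       # 1/min
        net = ReactionNetwork(
            species=["m"],
            reactions=[
                ReactionDef((), ("m",), k_t, "constant", param="k_t"),
                ReactionDef(("m",), (), k_d, "unimolecular", param="k_d"),
            ],
            params={"k_t": k_t, "k_d": k_d},
            medium=STATIC, initial_counts={"m": 0}, name=kind)
        lam = k_t / k_d
        kmax = int(lam + 12 * np.sqrt(lam) + 20)
        return net, {"mean": lam,
                     "pmf": poisson.pmf(np.arange(kmax + 1), lam),
                     "distribution": "poisson"}

    if kind == "two_state_promoter":
        k_on = kw.get("k_on", 0.1)     # 1/min
        k_off = kw.get("k_off", 0.2)
        k_t = kw.get("k_t", 2.0)       # mRNA/min from the on state
        k_d = kw.get("k_d", 0.1)
        net = ReactionNetwork(
            species=["Goff", "Gon", "m"],
            reactions=[
                ReactionDef(("Goff",), ("Gon",), k_on, "unimolecular",
                            param="k_on"),
                ReactionDef(("Gon",), ("Goff",), k_off, "unimolecular",
                            param="k_off"),
                ReactionDef(("Gon",), ("Gon", "m"), k_t, "unimolecular",
                            param="k_t"),
                ReactionDef(("m",), (), k_d, "unimolecular", param="k_d"),
            ],
            params=dict(k_on=k_on, k_off=k_off, k_t=k_t, k_d=k_d),
            medium=STATIC, initial_counts={"Goff": 1, "m": 0}, name=kind)
        pmf = _two_state_cme_pmf(k_on, k_off, k_t, k_d)
        mean = k_t / k_d * k_on / (k_on + k_off)
        return net, {"mean": mean, "pmf": pmf, "distribution": "cme"}

    if kind == "decay_only":
        k_d = kw.get("k_d", 0.1)
        n0 = kw.get("n0", 1000)
        net = ReactionNetwork(
            species=["x"],
            reactions=[ReactionDef(("x",), (), k_d, "unimolecular",
                                   param="k_d")],
            params={"k_d": k_d}, medium=STATIC,
            initial_counts={"x": n0}, name=kind)
        return net, {"half_life": np.log(2.0) / k_d, "n0": n0}

    if kind == "dimerization":
        k_f = kw.get("k_f", 0.01)      # nM^-1 min^-1
        k_b = kw.get("k_b", 1.0)       # 1/min
        n0 = kw.get("n0", 200)
        v = kw.get("volume", 50.0)
        net = ReactionNetwork(
            species=["A", "A2"],
            reactions=[
                ReactionDef(("A", "A"), ("A2",), k_f, "bimolecular",
                            param="k_f"),
                ReactionDef(("A2",), ("A", "A"), k_b, "unimolecular",
                            param="k_b"),
            ],
            params={"k_f": k_f, "k_b": k_b}, medium=STATIC,
            initial_counts={"A": n0, "A2": 0}, name=kind)
        return net, {"n0": n0, "volume": v,
                     "conserved": "A + 2*A2"}

    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"known kinds: {FIXTURE_KINDS}")


def _two_state_cme_pmf(k_on, k_off, k_t, k_d, nmax: int | None = None):
    """Stationary mRNA pmf of the two-state promoter by linear CME solve.

    State space {off, on} × {0..nmax} with nmax at mean + 10 sd; the
    stationary vector is the null space of the truncated generator,
    marginalised over the promoter state.
    """
    mean = k_t / k_d * k_on / (k_on + k_off)
    var_guess = mean + mean ** 2  # generous bound for truncation
    if nmax is None:
        nmax = int(mean + 10 * np.sqrt(var_guess) + 20)
    n_states = 2 * (nmax + 1)

    def idx(g, n):
        return g * (nmax + 1) + n

    gen = np.zeros((n_states, n_states))
    for n in range(nmax + 1):
        # promoter switching
        gen[idx(1, n), idx(0, n)] += k_on
        gen[idx(0, n), idx(0, n)] -= k_on
        gen[idx(0, n), idx(1, n)] += k_off
        gen[idx(1, n), idx(1, n)] -= k_off
        # transcription from the on state
        if n < nmax:
            gen[idx(1, n + 1), idx(1, n)] += k_t
            gen[idx(1, n), idx(1, n)] -= k_t
        # decay
        if n > 0:
            for g in (0, 1):
                gen[idx(g, n - 1), idx(g, n)] += k_d * n
                gen[idx(g, n), idx(g, n)] -= k_d * n
    ns = null_space(gen)
    if ns.shape[1] == 0:
        # fall back to the eigenvector of the smallest-magnitude eigenvalue
        w, v = np.linalg.eig(gen)
        ns = v[:, [int(np.argmin(np.abs(w)))]].real
    pi = np.abs(ns[:, 0])
    pi /= pi.sum()
    return pi[: nmax + 1] + pi[nmax + 1:]
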