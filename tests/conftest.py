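"""Shared fixtures: compiled toy networks and cached culture runs.

Full-model cultures are expensive (each cell cycle is millions of SSA
events), so they are simulated once per session at deliberately small sizes
and shared by every test that needs population statistics.
"""

from __future__ import annotations

import numpy as np
import pytest

import yeastcycle as yc
from yeastcycle.culture import CultureConfig, run_culture
from yeastcycle.model import mutant_catalog
from yeastcycle.network import apply_mutant


@pytest.fixture(scope="session")
def wt_glucose_network():
    return yc.build_wildtype("glucose")


@pytest.fixture(scope="session")
def culture_cache(wt_glucose_network):
    """Lazily-built cache of small cultures keyed by (strain, medium, n)."""
    cache: dict = {}
    catalog = mutant_catalog()

    def get(strain: str = "WT", medium: str = "glucose", n: int = 24,
            seed: int = 11, keep_traj: bool = False, window: float = 400.0):
        key = (strain, medium, n, seed, keep_traj)
        if key not in cache:
            if medium == "glucose" and strain == "WT":
                net = wt_glucose_network
            else:
                net = yc.build_wildtype(medium)
            if strain.startswith("scan:whi5_feedback_"):
                fac = float(strain.rsplit("_", 1)[1])
                net = apply_mutant(net, yc.MutantSpec(
                    strain, (("scale", "k_cln1_whi5", fac),
                             ("scale", "k_cln2_whi5", fac))))
            elif strain != "WT":
                net = apply_mutant(net, catalog[strain])
            cfg = CultureConfig(master_seed=seed, max_cells=n,
                                arrest_window=window,
                                sample_dt=1.0 if keep_traj else 0.0)
            cache[key] = run_culture(net, cfg, strain=strain,
                                     keep_trajectories=keep_traj)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def wt_culture(culture_cache):
    """The workhorse wild-type glucose culture, shared across tests
    (pedigree checks, duration identities, size control, Sic1 lifetimes,
    feedback baseline, variability structure)."""
    return culture_cache("WT", "glucose", 24, seed=31, keep_traj=True)


def steady_frame(table, drop: int = 8):
    """Divided-cell records with the founder transient removed."""
    df = table.to_frame()
    return df[(df.arrest == "none") & (df.cell_id >= drop)]
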