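"""Computational cultures: birth-ordered scheduling of dividing cells.

A culture starts from one founder cell.  Each cell is simulated from birth
to division (or to the arrest window); at division the volume is split
(1−f):f between mother and daughter and every molecular species is
partitioned by the same fraction — except Cln3, of which the daughter
receives only 25% — either deterministically (proportional mode, the
default) or binomially (an extrinsic-noise variant).  Progeny are appended
to a queue ordered by birth time and the earliest-born cell is always
simulated next, exactly reproducing a culture expanding in real time.
Pedigrees, per-cell event records and the cell-count series are retained.

Per-cell randomness comes from counter-based streams derived from
(master seed, cell id), so cultures are bit-reproducible regardless of how
the schedule interleaves cells.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .compiled import CompiledNetwork, compile_network
from .events import EventRecord, record_from_kernel
from .network import ReactionNetwork
from .params import V_BIRTH
from .ssa import run_cell_cycle

F_CLN3_DAUGHTER = 0.25   # daughters inherit ~3-fold less Cln3


@dataclass
class CultureConfig:
    """Run settings for one computational culture."""

    master_seed: int = 0
    max_cells: int = 100             # cells to simulate (founder included)
    t_stop: float = np.inf           # do not start cells born after this
    partition_mode: str = "proportional"   # or "binomial"
    f_cv: float = 0.0                # Gaussian noise on f (0 disables)
    arrest_window: float = 500.0     # min without division => arrested
    sample_dt: float = 0.0           # per-cell trajectory cadence (0: none)
    v_birth: float = V_BIRTH         # founder birth volume, fL

    def __post_init__(self):
        if self.max_cells < 1:
            raise ValueError("max_cells must be at least 1")
        if self.partition_mode not in ("proportional", "binomial"):
            raise ValueError(f"unknown partition mode {self.partition_mode!r}")
        if not 0 <= self.f_cv < 1:
            raise ValueError("f_cv must lie in [0, 1)")


@dataclass
class LineageTable:
    """Pedigree-complete per-cell records for one culture."""

    records: list[EventRecord] = field(default_factory=list)
    medium_name: str = ""
    strain: str = ""
    mdt: float = np.nan

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self):
        import pandas as pd
        rows = []
        for r in self.records:
            rows.append(dict(
                cell_id=r.cell_id, parent_id=r.parent_id, md_label=r.md_label,
                t_birth=r.t_birth, V_bir=r.v_bir, V_bud=r.v_bud,
                V_div=r.v_div, T_div=r.t_div, T_unbud=r.t_unbud, T_g1=r.t_g1,
                T_bud=r.t_bud_dur, T_sg2m=r.t_sg2m, T_whi5=r.t_whi5,
                act_CLN2=r.act_cln2, act_RAD27=r.act_rad27,
                act_CLB2=r.act_clb2, arrest=r.arrest))
        return pd.DataFrame(rows)

    def divided(self) -> list[EventRecord]:
        return [r for r in self.records if r.arrest == "none"
                and np.isfinite(r.t_div)]

    def arrested(self) -> list[EventRecord]:
        return [r for r in self.records if r.arrest != "none"]

    def arrest_fractions(self) -> dict[str, float]:
        n = len(self.records)
        out = {"unbudded": 0.0, "unreplicated": 0.0, "m_phase": 0.0,
               "none": 0.0}
        for r in self.records:
            out[r.arrest] += 1.0 / n
        return out

    def count_series(self, grid: np.ndarray) -> np.ndarray:
        """Number of cells alive at each grid time (divisions add one)."""
        div_times = np.sort([r.t_birth + r.t_div for r in self.divided()])
        return 1 + np.searchsorted(div_times, grid, side="right")


def divide_cell(counts: np.ndarray, volume: float, f: float,
                mode: str = "proportional",
                rng: np.random.Generator | None = None,
                promoter_mask: np.ndarray | None = None,
                cln3_idx: np.ndarray | None = None,
                f_cln3: float = F_CLN3_DAUGHTER):
    """Partition a dividing cell into (mother, daughter) states.

    The daughter receives volume f·V and, per species, either
    round-half-up(f·N) (proportional) or a Binomial(N, f) draw; the mother
    keeps the remainder, so totals are conserved exactly.  Cln3 uses the
    daughter fraction ``f_cln3`` instead of f.  Gene-copy (promoter-state)
    species are duplicated into both progeny.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("daughter volume fraction f must lie in (0, 1)")
    counts = np.asarray(counts, dtype=np.int64)
    frac = np.full(counts.shape, f)
    if cln3_idx is not None:
        frac[cln3_idx] = f_cln3
    if mode == "proportional":
        daughter = np.floor(frac * counts + 0.5).astype(np.int64)
    elif mode == "binomial":
        if rng is None:
            raise ValueError("binomial partitioning needs an rng")
        daughter = rng.binomial(counts, frac).astype(np.int64)
    else:
        raise ValueError(f"unknown partition mode {mode!r}")
    mother = counts - daughter
    if promoter_mask is not None:
        daughter[promoter_mask] = counts[promoter_mask]
        mother[promoter_mask] = counts[promoter_mask]
    return (mother, (1.0 - f) * volume), (daughter, f * volume)


def _cell_seed(master_seed: int, cell_id: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(cell_id),))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def run_culture(net: ReactionNetwork | CompiledNetwork,
                config: CultureConfig,
                f_daughter: float | None = None,
                strain: str = "",
                keep_trajectories: bool = False) -> LineageTable:
    """Grow one computational culture and return its lineage table."""
    if isinstance(net, ReactionNetwork):
        cn = compile_network(net)
        founder_counts = np.array(net.initial_state_vector(), dtype=np.int64)
        medium = net.medium
        strain = strain or net.name
        ann = net.annotations
    else:
        raise TypeError("run_culture needs a ReactionNetwork (for initial "
                        "state and medium)")
    if f_daughter is None:
        f_daughter = medium.f_daughter

    promoter_mask = np.array([s.startswith(("G_", "Gon_", "Goff_"))
                              for s in cn.species])
    cln3_idx = np.array([cn.index[s] for s in ann.get("cln3_species", [])],
                        dtype=np.int64)

    table = LineageTable(medium_name=medium.name, strain=strain,
                         mdt=medium.mdt)
    # the partition rng stream is independent of the per-cell SSA streams
    part_rng = np.random.Generator(np.random.Philox(
        np.random.SeedSequence(entropy=int(config.master_seed),
                               spawn_key=(0xD151DE,))))

    heap: list[tuple[float, int, int, str, np.ndarray, float]] = []
    heapq.heappush(heap, (0.0, 0, -1, "daughter", founder_counts,
                          config.v_birth))
    next_id = 1
    processed = 0
    while heap and processed < config.max_cells:
        t_birth, cell_id, parent_id, label, counts, v0 = heapq.heappop(heap)
        if t_birth > config.t_stop:
            break
        seed = _cell_seed(config.master_seed, cell_id)
        counts = counts.copy()
        status, age, v_end, events, traj, _ = run_cell_cycle(
            cn, counts, v0, config.arrest_window, seed,
            sample_dt=config.sample_dt)
        rec = record_from_kernel(cell_id, parent_id, label, t_birth, v0,
                                 status, age, v_end, events,
                                 config.arrest_window, cn.mu)
        if keep_trajectories and traj is not None:
            rec.extra["trajectory"] = traj
        table.records.append(rec)
        processed += 1

        if status == 1:
            f = f_daughter
            if config.f_cv > 0:
                # truncated Gaussian noise on the division fraction
                while True:
                    f = part_rng.normal(f_daughter, config.f_cv * f_daughter)
                    if 0.05 < f < 0.95:
                        break
            (m_counts, m_v), (d_counts, d_v) = divide_cell(
                counts, v_end, f, config.partition_mode, part_rng,
                promoter_mask, cln3_idx)
            t_next = t_birth + age
            heapq.heappush(heap, (t_next, next_id, cell_id, "mother",
                                  m_counts, m_v))
            heapq.heappush(heap, (t_next, next_id + 1, cell_id, "daughter",
                                  d_counts, d_v))
            next_id += 2
    return table


def extant_population(table: LineageTable, t_stop: float,
                      include_arrested: bool = False) -> list[EventRecord]:
    """Cells alive at ``t_stop``, each with its complete single-cycle record.

    A divided cell is extant iff t_birth < t_stop < t_birth + T_div.
    Arrested cells (no division) are included only on request, while their
    arrest window still covers t_stop.
    """
    out = []
    for r in table.records:
        if r.arrest == "none" and np.isfinite(r.t_div):
            if r.t_birth < t_stop < r.t_birth + r.t_div:
                out.append(r)
        elif include_arrested and r.arrest != "none" and r.t_birth < t_stop:
            out.append(r)
    return out
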