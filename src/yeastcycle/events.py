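"""Scoring of cell-cycle milestones from trajectories and cell records.

Budding and the onset of DNA synthesis are scored through two continuous
"indicator" variables, bud_ss and dna_ss, that relax toward
efficiency-weighted sums of cyclin concentrations (all G1 and S cyclins
contribute to budding; only B-type cyclins drive DNA-synthesis onset) and
trigger at fixed thresholds (25 nM and 30 nM).  Division fires on a downward
crossing of the free Clb2 concentration through 12.5 nM, but only after
Clb2 has exceeded an arming level (twice the threshold) since the last
division, so newborn G1 cells with low Clb2 cannot re-trigger.  Whi5 is
"nuclear" while the summed concentration of all Whi5 species carrying at
most two phosphates (free or SBF-bound) exceeds 200 nM.  A cell that fails
to reach a milestone within the arrest window (500 min) is classified as
arrested in the corresponding phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import count_to_conc


@dataclass(frozen=True)
class Thresholds:
    """Event thresholds (nM for concentrations, fractions for activities)."""

    clb2_division: float = 12.5
    division_arm: float = 25.0
    bud: float = 25.0
    dna: float = 30.0
    whi5_nuclear: float = 200.0
    act_cln2: float = 0.15
    act_clb2: float = 0.20
    act_rad27: float = 0.20
    arrest_window: float = 500.0

    def __post_init__(self):
        for name in ("clb2_division", "division_arm", "bud", "dna",
                     "whi5_nuclear", "arrest_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class EventRecord:
    """One cell's complete single-cycle record.

    Ages are minutes since the cell's own birth.  ``arrest`` is "none" for a
    divided cell, else one of "unbudded" / "unreplicated" / "m_phase".
    """

    cell_id: int
    parent_id: int = -1
    md_label: str = "daughter"       # was this cell the mother or daughter
    t_birth: float = 0.0             # absolute culture time
    v_bir: float = np.nan
    v_bud: float = np.nan
    v_div: float = np.nan
    t_div: float = np.nan            # cycle duration T_div
    t_unbud: float = np.nan
    t_g1: float = np.nan             # age at onset of DNA synthesis
    t_bud_dur: float = np.nan        # T_bud = T_div - T_unbud
    t_sg2m: float = np.nan           # T_sg2m = T_div - T_g1
    t_whi5: float = np.nan           # age of Whi5 nuclear exit
    act_cln2: float = np.nan
    act_rad27: float = np.nan
    act_clb2: float = np.nan
    arrest: str = "none"
    extra: dict = field(default_factory=dict)

    def finalize(self) -> None:
        """Fill the derived durations from the primary event ages."""
        if np.isfinite(self.t_div):
            if np.isfinite(self.t_unbud):
                self.t_bud_dur = self.t_div - self.t_unbud
            if np.isfinite(self.t_g1):
                self.t_sg2m = self.t_div - self.t_g1


def update_indicators(bud_ss: float, dna_ss: float,
                      bud_input: float, dna_input: float,
                      rates: dict, dt: float) -> tuple[float, float]:
    """Advance the two indicators by ``dt`` with frozen cyclin inputs.

    Each indicator obeys dx/dt = ks·c − kd·x for an efficiency-weighted
    cyclin concentration c, integrated exactly over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = []
    for x, c, ks, kd in ((bud_ss, bud_input, rates["ks_bud"], rates["kd_bud"]),
                         (dna_ss, dna_input, rates["ks_dna"], rates["kd_dna"])):
        target = ks / kd * c
        out.append(target + (x - target) * np.exp(-kd * dt))
    return out[0], out[1]


def detect_division(t: np.ndarray, clb2_conc: np.ndarray,
                    thresholds: Thresholds = Thresholds()) -> list[float]:
    """Division times from a [Clb2] series with the arming rule.

    A division fires on a downward crossing of the division threshold only
    when Clb2 has previously exceeded the arming level since the last
    division (or since the start of the series); each firing disarms.
    """
    t = np.asarray(t, float)
    c = np.asarray(clb2_conc, float)
    armed = c[0] >= thresholds.division_arm
    out: list[float] = []
    for i in range(1, len(c)):
        if not armed and c[i] >= thresholds.division_arm:
            armed = True
        elif armed and c[i - 1] >= thresholds.clb2_division > c[i]:
            # linear interpolation of the crossing time
            f = (thresholds.clb2_division - c[i - 1]) / (c[i] - c[i - 1])
            out.append(float(t[i - 1] + f * (t[i] - t[i - 1])))
            armed = False
    return out


def whi5_nuclear_conc(counts, volume: float, species: list[str]) -> float:
    """Total concentration (nM) of nuclear (SBF-binding-competent) Whi5.

    Sums free and SBF-bound Whi5 forms with phosphocount <= 2.
    """
    counts = np.asarray(counts)
    total = 0
    for i, s in enumerate(species):
        if s.startswith("Whi5:"):
            k = int(s.split(":")[1].split("|")[0])
            if k <= 2:
                total += counts[i]
    return count_to_conc(total, volume)


def gene_activation_time(t: np.ndarray, activity: np.ndarray,
                         threshold: float) -> float | None:
    """Age of the first upward crossing of a gene-activity series."""
    act = np.asarray(activity, float)
    above = act >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    return float(t[i])


def classify_arrest(budded: bool, replicated: bool, divided: bool,
                    elapsed: float,
                    window: float = 500.0) -> str:
    """Arrest phase for a cell that failed to divide within the window.

    Returns "none" for divided cells; otherwise exactly one of the three
    phase labels, so arrest labels partition non-dividing cells.
    """
    if divided:
        return "none"
    if elapsed < window:
        return "none"
    if not budded:
        return "unbudded"
    if not replicated:
        return "unreplicated"
    return "m_phase"


def record_from_kernel(cell_id: int, parent_id: int, md_label: str,
                       t_birth: float, v_bir: float,
                       status: int, age_end: float, v_end: float,
                       events: dict, window: float,
                       mu: float) -> EventRecord:
    """Assemble an EventRecord from a kernel run's outputs."""
    rec = EventRecord(cell_id=cell_id, parent_id=parent_id,
                      md_label=md_label, t_birth=t_birth, v_bir=v_bir)
    rec.t_unbud = events.get("t_bud", np.nan)
    rec.t_g1 = events.get("t_dna", np.nan)
    rec.t_whi5 = events.get("t_whi5_exit", np.nan)
    rec.act_cln2 = events.get("t_act_CLN2", np.nan)
    rec.act_rad27 = events.get("t_act_RAD27", np.nan)
    rec.act_clb2 = events.get("t_act_CLB2", np.nan)
    if np.isfinite(rec.t_unbud):
        rec.v_bud = v_bir * np.exp(mu * rec.t_unbud)
    if status == 1:
        rec.t_div = age_end
        rec.v_div = v_end
        rec.arrest = "none"
    else:
        rec.arrest = classify_arrest(
            budded=np.isfinite(rec.t_unbud),
            replicated=np.isfinite(rec.t_g1),
            divided=False, elapsed=age_end, window=window)
    rec.finalize()
    return rec
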