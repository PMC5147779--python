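"""Count/concentration conversions for a single yeast cell.

A haploid yeast cell of volume V (fL) holding N molecules of a species has
concentration C = 1.67 N / V in nM (1 molecule in 1 fL is 1.67 nM, i.e. the
reciprocal of Avogadro's number times 1 fL expressed in nanomolar).
"""

from __future__ import annotations

NM_PER_MOLECULE_FL = 1.67
"""Concentration (nM) of one molecule in a 1-fL volume."""


def count_to_conc(n: float, volume_fl: float) -> float:
    """Concentration in nM of ``n`` molecules in a cell of ``volume_fl`` fL."""
    if volume_fl <= 0:
        raise ValueError(f"cell volume must be positive, got {volume_fl}")
    if n < 0:
        raise ValueError(f"molecule count must be non-negative, got {n}")
    return NM_PER_MOLECULE_FL * n / volume_fl


def conc_to_count(conc_nm: float, volume_fl: float) -> int:
    """Molecule count (nearest integer) for a concentration in nM."""
    if volume_fl <= 0:
        raise ValueError(f"cell volume must be positive, got {volume_fl}")
    return int(round(conc_nm * volume_fl / NM_PER_MOLECULE_FL))


def omega(volume_fl: float) -> float:
    """System size Ω(V): molecules per nM of concentration, = V / 1.67."""
    return volume_fl / NM_PER_MOLECULE_FL
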