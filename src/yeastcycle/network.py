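"""Reaction-network data model for the budding-yeast cell-cycle control system.

Everything here is engine-independent data: species, elementary mass-action
reactions, growth media, gene definitions, multisite phosphorylation chains,
and genotype edits.  Both the stochastic (SSA) and deterministic (ODE) engines
consume the same :class:`ReactionNetwork`, so a single rate table drives both.

Volume-scaling semantics of a reaction's propensity (V in fL, Ω = V/1.67
molecules per nM, rate constants in concentration units):

======================  =====================================================
kind                    propensity
======================  =====================================================
``synthesis``           k · Ω(V)                (zero-order, k in nM·min⁻¹)
``constant``            k                       (number-based zero order)
``unimolecular``        k · N₁                  (k in min⁻¹)
``bimolecular``         k · N₁ · N₂ / Ω(V)      (k in nM⁻¹·min⁻¹)
``bimolecular_homo``    k · N₁(N₁−1) / (2Ω(V))
``translation``         k · N_mRNA · (V/V_ref)^e   e = 1, or 2 for CLN3
======================  =====================================================

Transcription from a promoter copy is ``unimolecular`` in the promoter
species and carries no volume factor, so mRNA numbers (not concentrations)
are stationary for constitutively expressed genes.  Ordinary translation is
proportional to cell volume (ribosome content) and CLN3 translation to V²,
which makes the Cln3 concentration grow with cell size — the model's size
sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .units import NM_PER_MOLECULE_FL

LN2 = math.log(2.0)

REACTION_KINDS = (
    "synthesis",
    "constant",
    "unimolecular",
    "bimolecular",
    "bimolecular_homo",
    "translation",
)


# ---------------------------------------------------------------------------
# growth media
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medium:
    """Growth condition: specific growth rate and division asymmetry.

    ``mu`` is the specific growth rate (min⁻¹) of exponential volume growth
    V(t) = V(0)·e^{μt}; the mass doubling time is ln2/μ.  ``f_daughter`` is
    the volume fraction handed to the daughter cell at division.
    """

    name: str
    mu: float
    f_daughter: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("growth rate mu must be positive")
        if not 0.0 < self.f_daughter < 0.5:
            raise ValueError("daughter volume fraction must lie in (0, 0.5)")

    @property
    def mdt(self) -> float:
        """Mass doubling time ln(2)/μ in minutes."""
        return LN2 / self.mu


#: growth rates and mother:daughter volume splits for the three carbon sources
MEDIA: dict[str, Medium] = {
    "glucose": Medium("glucose", 0.00700, 0.40),
    "galactose": Medium("galactose", 0.00467, 0.36),
    "glycerol-ethanol": Medium("glycerol-ethanol", 0.00398, 0.35),
}


def medium_growth(name: str) -> Medium:
    """Return the :class:`Medium` for a named carbon source."""
    try:
        return MEDIA[name]
    except KeyError:
        raise ValueError(
            f"unknown medium {name!r}; known media: {sorted(MEDIA)}"
        ) from None


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionDef:
    """One elementary mass-action reaction (at most two reactants).

    ``param`` names the rate constant the reaction was built from so genotype
    edits (``scale``) can find it; ``tag`` labels degradation routes so edits
    (``stabilize``) can remove them.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float
    kind: str = "unimolecular"
    vol_exp: int = 1
    param: str = ""
    tag: str = ""

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise ValueError(f"at most two reactants allowed: {self.reactants}")
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate constant must be non-negative")

    def net_stoich(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.reactants:
            out[s] = out.get(s, 0) - 1
        for s in self.products:
            out[s] = out.get(s, 0) + 1
        return {s: v for s, v in out.items() if v != 0}


# ---------------------------------------------------------------------------
# genes and phospho-chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDef:
    """Transcription/translation description of one (haploid) gene."""

    name: str
    regulated: bool
    transcription_factors: tuple[tuple[str, float], ...] = ()
    mrna_half_life: float = 7.0          # min
    transcription_rate: float = 0.5      # mRNA·min⁻¹ per active copy
    translation_rate: float = 10.0       # protein·min⁻¹ per mRNA at V_ref
    translation_volume_exponent: int = 1
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.copy_number != 1:
            raise ValueError("model is haploid: copy_number must be 1")
        if self.translation_volume_exponent not in (1, 2):
            raise ValueError("translation volume exponent must be 1 or 2")
        if self.mrna_half_life <= 0:
            raise ValueError("mRNA half-life must be positive")

    @property
    def mrna_decay_rate(self) -> float:
        return LN2 / self.mrna_half_life


@dataclass(frozen=True)
class PhosphoChainDef:
    """A distributive multisite phosphorylation chain on one protein.

    ``active_rule`` decides which phospho-count states retain activity:
    ``("le", m)`` — active iff k ≤ m (inactivation by phosphorylation);
    ``("eq", n)`` — active iff k = n (activation by full phosphorylation).
    ``order_mode`` is ``ordered`` (single path through k) or ``disordered``
    (site-symmetric random order; the count-resolved chain then carries
    combinatorial multiplicity n−k on phosphorylation out of state k and k on
    dephosphorylation).
    """

    protein: str
    n_sites: int
    active_rule: tuple[str, int]
    order_mode: str = "ordered"
    kinases: tuple[tuple[str, float], ...] = ()
    phosphatases: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("a phospho-chain needs at least one site")
        if self.order_mode not in ("ordered", "disordered"):
            raise ValueError(f"unknown order mode {self.order_mode!r}")
        rule, val = self.active_rule
        if rule == "le":
            if not 0 <= val < self.n_sites:
                raise ValueError("inactivation rule needs 0 <= m < n")
        elif rule == "eq":
            if not 0 <= val <= self.n_sites:
                raise ValueError("activation rule value out of range")
        else:
            raise ValueError(f"unknown activity rule {rule!r}")

    def species(self) -> list[str]:
        return [f"{self.protein}:{k}" for k in range(self.n_sites + 1)]

    def is_active(self, k: int) -> bool:
        rule, val = self.active_rule
        return k <= val if rule == "le" else k == val

    def active_species(self) -> list[str]:
        return [s for k, s in enumerate(self.species()) if self.is_active(k)]


def expand_phospho_chain(
    chain: PhosphoChainDef,
) -> tuple[list[str], list[ReactionDef], list[bool]]:
    """Expand a chain into count-resolved species, reactions and activity mask.

    Returns ``(species, reactions, active_mask)`` where ``species[k]`` is the
    k-fold phosphorylated form.  Each kinase contributes n phosphorylation
    reactions (bimolecular, catalyst preserved) and each phosphatase n
    dephosphorylation reactions.  Disordered chains pick up the combinatorial
    multiplicity in the effective rate.
    """
    if chain.n_sites == 0 and chain.kinases:
        raise ValueError("chain with zero sites cannot have kinases")
    species = chain.species()
    disordered = chain.order_mode == "disordered"
    rxns: list[ReactionDef] = []
    n = chain.n_sites
    for kin, rate in chain.kinases:
        pname = f"k_{kin.lower()}_{chain.protein.lower()}"
        for k in range(n):
            mult = (n - k) if disordered else 1
            rxns.append(ReactionDef(
                reactants=(kin, species[k]),
                products=(kin, species[k + 1]),
                rate=rate * mult,
                kind="bimolecular",
                param=pname,
                tag=f"phos:{chain.protein}",
            ))
    for pho, rate in chain.phosphatases:
        pname = f"k_{pho.lower()}_{chain.protein.lower()}"
        for k in range(1, n + 1):
            mult = k if disordered else 1
            rxns.append(ReactionDef(
                reactants=(pho, species[k]),
                products=(pho, species[k - 1]),
                rate=rate * mult,
                kind="bimolecular",
                param=pname,
                tag=f"dephos:{chain.protein}",
            ))
    mask = [chain.is_active(k) for k in range(n + 1)]
    return species, rxns, mask


def apc_affinity_factor(k: int, beta: float = 0.525, n_sites: int = 11) -> float:
    """Cdc20 association multiplier β^(n−k) for APC phospho-form k.

    Unphosphorylated APC binds Cdc20 weakly; every added phosphate raises the
    association rate by 1/β, so the fully phosphorylated form has factor 1.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    if not 0 <= k <= n_sites:
        raise ValueError(f"phospho count k={k} outside [0, {n_sites}]")
    return beta ** (n_sites - k)


# ---------------------------------------------------------------------------
# genotype edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutantSpec:
    """A genotype as a list of declarative edits to the wild-type network.

    Edit forms (tuples):
      ``("delete", gene)``                      remove transcription of a gene
      ``("overexpress", gene, rate)``           add a constitutive promoter
                                                (GAL allele: only active when
                                                the medium is galactose)
      ``("multicopy", gene, factor)``           scale transcription rate
      ``("stabilize", tag)``                    remove a degradation route
      ``("scale", param, factor)``              scale one named rate constant
    """

    name: str
    edits: tuple[tuple, ...] = ()


# ---------------------------------------------------------------------------
# the network container
# ---------------------------------------------------------------------------

@dataclass
class ReactionNetwork:
    """Complete description of one strain in one medium."""

    species: list[str]
    reactions: list[ReactionDef]
    params: dict[str, float]
    medium: Medium
    initial_counts: dict[str, int]
    roles: dict[str, str] = field(default_factory=dict)
    genes: dict[str, GeneDef] = field(default_factory=dict)
    chains: dict[str, PhosphoChainDef] = field(default_factory=dict)
    v_ref: float = 50.0
    name: str = "wild-type"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        declared = set(self.species)
        for r in self.reactions:
            for s in (*r.reactants, *r.products):
                if s not in declared:
                    raise ValueError(
                        f"reaction references undeclared species {s!r}: {r}"
                    )
        for s in self.initial_counts:
            if s not in declared:
                raise ValueError(f"initial count for undeclared species {s!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def initial_state_vector(self) -> list[int]:
        return [self.initial_counts.get(s, 0) for s in self.species]

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            params=dict(self.params),
            medium=self.medium,
            initial_counts=dict(self.initial_counts),
            roles=dict(self.roles),
            genes=dict(self.genes),
            chains=dict(self.chains),
            v_ref=self.v_ref,
            name=self.name,
            annotations=dict(self.annotations),
        )

    # -- export ------------------------------------------------------------

    def to_tsv(self) -> str:
        """Expanded elementary-reaction list as TSV for auditability."""
        lines = ["rxn_id\treactants\tproducts\trate\tkind\tvol_exp\tparam\ttag"]
        for i, r in enumerate(self.reactions):
            lines.append(
                f"{i}\t{'+'.join(r.reactants) or '-'}\t"
                f"{'+'.join(r.products) or '-'}\t{r.rate:.8g}\t{r.kind}\t"
                f"{r.vol_exp}\t{r.param}\t{r.tag}"
            )
        return "\n".join(lines) + "\n"


def apply_mutant(net: ReactionNetwork, spec: MutantSpec) -> ReactionNetwork:
    """Return an edited copy of ``net`` implementing the genotype ``spec``.

    Edits are validated against the wild-type network; referencing an absent
    gene, route or parameter raises ``ValueError``.
    """
    out = net.copy()
    out.name = spec.name
    for edit in spec.edits:
        op = edit[0]
        if op == "delete":
            gene = edit[1]
            if gene not in out.genes:
                raise ValueError(f"cannot delete unknown gene {gene!r}")
            before = len(out.reactions)
            out.reactions = [
                r for r in out.reactions if r.tag != f"transcription:{gene}"
            ]
            if len(out.reactions) == before:
                raise ValueError(f"gene {gene!r} has no transcription to delete")
        elif op == "overexpress":
            gene, rate = edit[1], edit[2]
            if gene not in out.genes:
                raise ValueError(f"cannot overexpress unknown gene {gene!r}")
            if out.medium.name == "galactose":
                out.reactions.append(ReactionDef(
                    reactants=(), products=(f"m_{gene}",), rate=rate,
                    kind="constant", param=f"k_gal_{gene.lower()}",
                    tag=f"transcription:{gene}:GAL",
                ))
        elif op == "multicopy":
            gene, factor = edit[1], edit[2]
            if gene not in out.genes:
                raise ValueError(f"unknown gene {gene!r}")
            hit = False
            new = []
            for r in out.reactions:
                if r.tag.startswith(f"transcription:{gene}"):
                    new.append(replace(r, rate=r.rate * factor))
                    hit = True
                else:
                    new.append(r)
            if not hit:
                raise ValueError(f"gene {gene!r} has no transcription reactions")
            out.reactions = new
        elif op == "stabilize":
            tag = edit[1]
            before = len(out.reactions)
            out.reactions = [r for r in out.reactions if r.tag != tag]
            if len(out.reactions) == before:
                raise ValueError(f"no degradation route tagged {tag!r}")
        elif op == "scale":
            param, factor = edit[1], edit[2]
            hit = False
            new = []
            for r in out.reactions:
                if r.param == param:
                    new.append(replace(r, rate=r.rate * factor))
                    hit = True
                else:
                    new.append(r)
            if not hit:
                raise ValueError(f"no reaction uses parameter {param!r}")
            out.reactions = new
            if param in out.params:
                out.params[param] = out.params[param] * factor
        else:
            raise ValueError(f"unknown edit operation {op!r}")
    out.validate()
    return out
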