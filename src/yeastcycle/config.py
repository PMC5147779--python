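"""Plain-text configuration: media, genotype edits, parameter overrides.

The format is INI-style with flat ``key = value`` pairs:

.. code-block:: ini

    [run]
    medium = glucose
    mutant = WT
    seed = 1
    max_cells = 50

    [params]
    k_cln1_whi5 = 0.006        ; any named rate constant

    [genes]
    CLN1 = m=8 thm=3 p=130 thp=8     ; override gene-table entries

    [phospho]
    Whi5.kin.Cln3 = 0.02             ; chain kinase/phosphatase rates

    [medium:raffinose]
    mu = 0.00462
    f_daughter = 0.36

    [mutant:my-strain]
    delete = CLN1, CLN2
    scale = k_cln1_whi5 * 0.5

Model content (gene table, chains, parameters) and run settings live in
separate sections so one network description can serve many runs.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field

from .network import Medium, MutantSpec, medium_growth


@dataclass
class RunSettings:
    medium: str = "glucose"
    mutant: str = "WT"
    seed: int = 0
    max_cells: int = 50
    t_stop: float = float("inf")
    t_end: float = 500.0
    partition_mode: str = "proportional"
    f_cv: float = 0.0
    sample_dt: float = 0.0
    out_dir: str = "."


@dataclass
class LoadedConfig:
    run: RunSettings = field(default_factory=RunSettings)
    params: dict = field(default_factory=dict)
    gene_overrides: dict = field(default_factory=dict)
    chain_overrides: dict = field(default_factory=dict)
    media: dict = field(default_factory=dict)
    mutants: dict = field(default_factory=dict)
    sha: str = ""

    def medium(self, name: str | None = None) -> Medium:
        name = name or self.run.medium
        if name in self.media:
            return self.media[name]
        return medium_growth(name)


def _parse_number(s: str):
    try:
        return int(s)
    except ValueError:
        return float(s)


def load_config(path: str) -> LoadedConfig:
    """Parse a configuration file; malformed keys raise with their name."""
    text = open(path).read()
    cp = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    cp.read_string(text)
    out = LoadedConfig(sha=hashlib.sha256(text.encode()).hexdigest()[:16])

    if cp.has_section("run"):
        rs = out.run
        for key, val in cp.items("run"):
            if not hasattr(rs, key):
                raise ValueError(f"unknown [run] key {key!r}")
            cur = getattr(rs, key)
            if isinstance(cur, bool):
                setattr(rs, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int):
                setattr(rs, key, int(val))
            elif isinstance(cur, float):
                setattr(rs, key, float(val))
            else:
                setattr(rs, key, val)

    if cp.has_section("params"):
        for key, val in cp.items("params"):
            try:
                out.params[key] = float(val)
            except ValueError:
                raise ValueError(f"[params] {key} is not numeric: {val!r}")

    if cp.has_section("genes"):
        for gene, spec in cp.items("genes"):
            row = {}
            for tok in spec.split():
                if "=" not in tok:
                    raise ValueError(f"[genes] {gene}: bad token {tok!r}")
                k, v = tok.split("=", 1)
                row[k] = _parse_number(v)
            out.gene_overrides[gene.upper()] = row

    if cp.has_section("phospho"):
        for key, val in cp.items("phospho"):
            parts = key.split(".")
            if len(parts) != 3 or parts[1] not in ("kin", "pho"):
                raise ValueError(f"[phospho] bad key {key!r}; expected "
                                 "Protein.kin.Enzyme or Protein.pho.Enzyme")
            out.chain_overrides[(parts[0].capitalize(), parts[1],
                                 parts[2].capitalize())] = float(val)

    for section in cp.sections():
        if section.startswith("medium:"):
            name = section.split(":", 1)[1]
            mu = cp.getfloat(section, "mu")
            f = cp.getfloat(section, "f_daughter")
            out.media[name] = Medium(name, mu, f)
        elif section.startswith("mutant:"):
            name = section.split(":", 1)[1]
            edits: list[tuple] = []
            for key, val in cp.items(section):
                if key == "delete":
                    edits += [("delete", g.strip()) for g in val.split(",")]
                elif key == "overexpress":
                    g, r = val.split("@")
                    edits.append(("overexpress", g.strip(), float(r)))
                elif key == "multicopy":
                    g, fct = val.split("*")
                    edits.append(("multicopy", g.strip(), float(fct)))
                elif key == "stabilize":
                    edits += [("stabilize", tag.strip())
                              for tag in val.split(",")]
                elif key == "scale":
                    pname, fct = val.split("*")
                    edits.append(("scale", pname.strip(), float(fct)))
                else:
                    raise ValueError(f"[{section}] unknown edit {key!r}")
            out.mutants[name] = MutantSpec(name, tuple(edits))
    return out


def apply_overrides(cfg: LoadedConfig) -> dict:
    """Materialise parameter overrides (including gene/chain sections)."""
    from .params import CHAIN_TABLE, GENE_TABLE, gene_rates

    params = dict(cfg.params)
    for gene, row in cfg.gene_overrides.items():
        if gene not in GENE_TABLE:
            raise ValueError(f"[genes] unknown gene {gene!r}")
        merged = {**GENE_TABLE[gene], **row}
        r = gene_rates(merged["m"], merged["thm"], merged["p"],
                       merged["thp"], merged.get("duty", 1.0))
        params.setdefault(f"kt_{gene}", r["k_t"])
        params.setdefault(f"kdm_{gene}", r["k_dm"])
        params.setdefault(f"ktl_{gene}", r["k_tl"])
        params.setdefault(f"kdp_{gene}", r["k_dp"])
    for (prot, _kind, enzyme), rate in cfg.chain_overrides.items():
        if prot not in CHAIN_TABLE:
            raise ValueError(f"[phospho] unknown chain {prot!r}")
        params[f"k_{enzyme.lower()}_{prot.lower()}"] = rate
    return params
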