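"""Silylation chemistry: amenability detection, derivative mass arithmetic,
diagnostic marker-ion series, derivative-name parsing, and the REACH-based
eligibility rule for contaminants of emerging concern (CEC).

Silylation replaces an active hydrogen — an H bound to O, N or S in a
carboxyl, hydroxyl, amine, thiol or sulfonamide group — by a silyl group:
trimethylsilyl (TMS, net gain C3H8Si ≈ 72.04 amu per group) or
tert-butyldimethylsilyl (TBDMS, net gain C6H14Si ≈ 114.09 amu per group).
Electron-impact spectra of silylated derivatives carry diagnostic fragment
ions: m/z 73, 147, 221, 295 for one to four TMS groups and m/z 115, 230,
345 for one to three TBDMS groups.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import yaml
from pyteomics import mass as _pmass
from rdkit import Chem, RDLogger

from .core import parse_formula

RDLogger.DisableLog("rdApp.*")  # rdkit warnings are noise at library scale

__all__ = [
    "SilylationSite",
    "CecProperties",
    "PatternTable",
    "load_pattern_table",
    "find_silylation_sites",
    "is_amenable",
    "silyl_mass_increment",
    "silyl_average_increment",
    "SILYL_NET_FORMULA",
    "derivative_exact_mass",
    "derivative_mw",
    "derivative_formula",
    "marker_series",
    "parse_group_count",
    "cec_eligibility",
]

DERIV_TYPES = ("TMS", "TBDMS")

#: net elemental gain when one active H is replaced by the silyl group
#: (TMS adds Si(CH3)3 and removes H; TBDMS adds Si(CH3)2C(CH3)3 and removes H)
SILYL_NET_FORMULA = {"TMS": "C3H8Si", "TBDMS": "C6H14Si"}


@dataclass(frozen=True)
class SilylationSite:
    group_kind: str
    atom_index: int


@dataclass(frozen=True)
class PatternTable:
    version: int
    patterns: tuple[tuple[str, str, int], ...]  # (kind, smarts, site_atom)


def _compile(table: PatternTable):
    return [(kind, Chem.MolFromSmarts(smarts), site_atom)
            for kind, smarts, site_atom in table.patterns]


@lru_cache(maxsize=4)
def load_pattern_table(include_optional: bool = False) -> PatternTable:
    """Load the packaged SMARTS pattern table (versioned YAML)."""
    text = resources.files("silylib.data").joinpath("silylation_patterns.yaml").read_text("utf-8")
    doc = yaml.safe_load(text)
    pats = [(p["kind"], p["smarts"], int(p.get("site_atom", 0)))
            for p in doc["patterns"]]
    if include_optional:
        pats += [(p["kind"], p["smarts"], int(p.get("site_atom", 0)))
                 for p in doc.get("optional_patterns", [])]
    return PatternTable(version=int(doc["version"]), patterns=tuple(pats))


def _mol_from_structure(structure: str) -> Chem.Mol:
    text = structure.strip()
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"unparsable molecular structure: {structure!r}")
    return mol


def find_silylation_sites(structure: str,
                          table: Optional[PatternTable] = None) -> list[SilylationSite]:
    """All heteroatoms bearing an active hydrogen in an amenable group.

    Each heteroatom is counted once even if it carries two hydrogens; sites
    are ordered by atom index, ties broken by first matching pattern.
    """
    mol = _mol_from_structure(structure)
    table = table or load_pattern_table()
    seen: set[int] = set()
    sites: list[SilylationSite] = []
    for kind, patt, site_atom in _compile(table):
        for match in mol.GetSubstructMatches(patt):
            idx = match[site_atom]
            if idx not in seen:
                seen.add(idx)
                sites.append(SilylationSite(group_kind=kind, atom_index=idx))
    sites.sort(key=lambda s: s.atom_index)
    return sites


def is_amenable(structure: str, table: Optional[PatternTable] = None) -> bool:
    """True iff the structure carries at least one silylation site."""
    return len(find_silylation_sites(structure, table)) >= 1


# ---------------------------------------------------------------------------
# mass arithmetic (standard atomic masses via pyteomics tables, no literals)
# ---------------------------------------------------------------------------

def silyl_mass_increment(deriv_type: str) -> float:
    """Monoisotopic mass gained per silyl group (amu)."""
    if deriv_type not in DERIV_TYPES:
        raise ValueError(f"unknown derivative type: {deriv_type!r}")
    return _pmass.calculate_mass(formula=SILYL_NET_FORMULA[deriv_type])


def silyl_average_increment(deriv_type: str) -> float:
    """Average (molecular-weight) mass gained per silyl group (amu)."""
    if deriv_type not in DERIV_TYPES:
        raise ValueError(f"unknown derivative type: {deriv_type!r}")
    return _pmass.calculate_mass(formula=SILYL_NET_FORMULA[deriv_type], average=True)


def derivative_exact_mass(parent_exact_mass: float, n_groups: int, deriv_type: str) -> float:
    if n_groups < 0:
        raise ValueError("number of silyl groups cannot be negative")
    return parent_exact_mass + n_groups * silyl_mass_increment(deriv_type)


def derivative_mw(parent_mw: float, n_groups: int, deriv_type: str) -> float:
    if n_groups < 0:
        raise ValueError("number of silyl groups cannot be negative")
    return parent_mw + n_groups * silyl_average_increment(deriv_type)


def derivative_formula(parent_formula: str, n_groups: int, deriv_type: str) -> str:
    """Hill-ordered formula of the parent plus n silyl-group net gains."""
    if n_groups < 0:
        raise ValueError("number of silyl groups cannot be negative")
    counts = parse_formula(parent_formula)
    for el, n in parse_formula(SILYL_NET_FORMULA[deriv_type]).items():
        counts[el] = counts.get(el, 0) + n * n_groups
    ordered = []
    for el in ("C", "H"):
        if el in counts:
            ordered.append((el, counts.pop(el)))
    ordered.extend(sorted(counts.items()))
    return "".join(f"{el}{n if n > 1 else ''}" for el, n in ordered)


def marker_series(deriv_type: str, max_groups: int) -> list[int]:
    """Diagnostic silyl fragment ions for 1..max_groups groups (nominal m/z).

    TMS: 73, 147, 221, 295, … (73 + 74·(k−1)); TBDMS: 115, 230, 345, … (115·k).
    """
    if max_groups < 1:
        raise ValueError("max_groups must be at least 1")
    if deriv_type == "TMS":
        return [73 + 74 * (k - 1) for k in range(1, max_groups + 1)]
    if deriv_type == "TBDMS":
        return [115 * k for k in range(1, max_groups + 1)]
    raise ValueError(f"unknown derivative type: {deriv_type!r}")


# ---------------------------------------------------------------------------
# derivative-name parsing ("estriol 3TMS", "salicylic acid-bis TMS")
# ---------------------------------------------------------------------------

_NAME_TOKEN = re.compile(
    r"(?:(?P<count>\d+)\s*|(?P<bis>\bbis)[\s-]*)?(?P<type>TBDMS|TMS)\b")


def parse_group_count(derivative_name: str) -> tuple[str, str, int]:
    """Split a derivative name into (base name, deriv_type, n_groups).

    A leading integer gives the count ("2TMS" → 2), a "bis" prefix means 2,
    a bare token means 1.  The base name is what remains, trimmed of
    separator characters.
    """
    m = _NAME_TOKEN.search(derivative_name)
    if not m:
        raise ValueError(f"no TMS/TBDMS token in derivative name: {derivative_name!r}")
    if m.group("count"):
        n = int(m.group("count"))
    elif m.group("bis"):
        n = 2
    else:
        n = 1
    base = (derivative_name[:m.start()] + derivative_name[m.end():]).strip()
    base = base.strip(" -_,").strip()
    return base, m.group("type"), n


# ---------------------------------------------------------------------------
# CEC eligibility (REACH Annex III-style screening, 3-of-5 rule)
# ---------------------------------------------------------------------------

@dataclass
class CecProperties:
    """Environmental-fate properties feeding the five selection criteria.

    Absent values simply fail their criterion; the bioaccumulation criterion
    falls back from BAF/BCF to logKow only when BAF/BCF data are absent.
    """

    in_ccd: bool = False
    half_life_days: Optional[float] = None
    baf_bcf: Optional[float] = None
    log_kow: Optional[float] = None
    water_solubility_mg_l: Optional[float] = None
    log_koc: Optional[float] = None
    noec_mg_l: Optional[float] = None


def cec_eligibility(props: CecProperties) -> tuple[int, bool]:
    """Count how many of the five criteria hold; eligible iff at least three.

    1. Positioning — listed in the US EPA CompTox Chemistry Dashboard.
    2. Persistence — half-life in fresh/estuarine water > 40 days.
    3. Bioaccumulation — BAF/BCF > 2000; in absence of such data logKow ≥ 5.
    4. Mobility — water solubility ≥ 0.15 mg/L and −10.0 ≤ logKoc ≤ 4.0.
    5. EcoToxicity — long-term NOEC < 0.01 mg/L.
    """
    met = 0
    if props.in_ccd:
        met += 1
    if props.half_life_days is not None and props.half_life_days > 40:
        met += 1
    if props.baf_bcf is not None:
        if props.baf_bcf > 2000:
            met += 1
    elif props.log_kow is not None and props.log_kow >= 5.0:
        met += 1
    if (props.water_solubility_mg_l is not None and props.log_koc is not None
            and props.water_solubility_mg_l >= 0.15
            and -10.0 <= props.log_koc <= 4.0):
        met += 1
    if props.noec_mg_l is not None and props.noec_mg_l < 0.01:
        met += 1
    return met, met >= 3
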