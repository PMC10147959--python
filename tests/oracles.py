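"""Independent brute-force re-evaluation of the curation rules.

Deliberately written as plain per-record loops with its own constants and
its own amenability rule (an atom walk over N/O/S atoms carrying hydrogens)
so that pipeline tests compare two separate implementations.
"""
import re

from pyteomics import mass as pmass
from rdkit import Chem

INCHIKEY = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
MARKERS = {"TMS": [73, 147, 221, 295], "TBDMS": [115, 230, 345]}


def nominal_mass(formula):
    comp = pmass.Composition(formula=formula)
    return sum(round(pmass.nist_mass[el][0][0]) * int(n) for el, n in comp.items())


def atom_walk_amenable(smiles):
    """Any N, O or S atom carrying at least one hydrogen."""
    mol = Chem.MolFromSmiles(smiles)
    return any(a.GetSymbol() in {"N", "O", "S"} and a.GetTotalNumHs() > 0
               for a in mol.GetAtoms())


def record_kept(spectrum, deriv_type, parent_smiles):
    """True iff the record survives every rule, evaluated independently."""
    peaks = [(p.mz, p.intensity) for p in spectrum.peaks if p.intensity > 0]
    # step 0: metadata
    if deriv_type not in spectrum.name:
        return False
    if not spectrum.formula or not re.search(r"Si(?![a-z])", spectrum.formula):
        return False
    if not (spectrum.inchikey and INCHIKEY.match(spectrum.inchikey)):
        return False
    if spectrum.mw is not None and abs(nominal_mass(spectrum.formula) - spectrum.mw) > 1:
        return False
    # step 1: chemistry (skip when the parent structure is unknown)
    if parent_smiles is not None and not atom_walk_amenable(parent_smiles):
        return False
    # step 2: mass cutoff
    mass = spectrum.mw if spectrum.mw is not None else spectrum.exact_mass
    if mass is not None and mass >= 1000:
        return False
    # step 3: quality
    mw = spectrum.mw
    if mw is None:
        return False
    if spectrum.acquisition_upper_mz is not None:
        if spectrum.acquisition_upper_mz < mw + 10:
            return False
    elif not any(mz >= mw - 0.5 for mz, _ in peaks):
        return False
    if not any(abs(mz - mw) <= 0.5 for mz, _ in peaks):
        return False
    if not any(abs(mz - (mw + d)) <= 0.5 for mz, _ in peaks for d in (1, 2)):
        return False
    if not any(abs(mz - mk) <= 0.5 for mz, _ in peaks for mk in MARKERS[deriv_type]):
        return False
    if len(peaks) < 5:
        return False
    return True


def kept_names(library, deriv_type, registry):
    lookup = {}
    for rec in registry:
        lookup.setdefault(rec.inchikey.split("-")[0], rec.smiles)
    out = []
    for sp in library.records:
        block = sp.inchikey.split("-")[0] if sp.inchikey else None
        if record_kept(sp, deriv_type, lookup.get(block)):
            out.append(sp.name)
    return out
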