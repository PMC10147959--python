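"""Synthetic spectral libraries with known filter outcomes, and the packaged
compound/derivative registry.

The generator builds minimal electron-ionization-like spectra that are
*controlled*, not realistic: each spectrum contains exactly the features the
curation rules test (molecular ion, isotope satellite, diagnostic silyl
marker, a handful of filler fragments) so that a library assembled from a
:class:`GenerationSpec` has a curation report that must match the
generator's bookkeeping exactly.  Filler fragments are drawn away from the
marker and molecular-ion windows; intensities are log-uniform on [1, 999];
fragmentation realism is deliberately out of scope.

The registry packages the derivatization study's inventory: 104 parent
contaminants of emerging concern (21 in the TMS datasets only, 2 in the
TBDMS datasets only, 81 in both), 106 TMS derivatives of the 102
TMS-dataset compounds (four compounds yield two TMS derivatives: salicylic
acid, stanolone, sulfanilamide and 5-androstene-3β,17β-diol) and 85 TBDMS
derivatives of the 83 TBDMS-dataset compounds (two each for sulfanilamide
and L-serine), with retention times attached from the published tables.
"""
from __future__ import annotations

import csv
import hashlib
import json
import math
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .chem import (DERIV_TYPES, derivative_exact_mass, derivative_formula,
                   derivative_mw, marker_series, silyl_average_increment)
from .core import (CompoundRecord, DerivativeRecord, FilterConfig, Peak,
                   Spectrum, formula_monoisotopic_mass)
from .filters import FailureCode
from .io import LibraryFile

__all__ = [
    "GenerationSpec",
    "GroundTruth",
    "generate_passing_spectrum",
    "generate_failing_spectrum",
    "generate_library",
    "build_test_registry",
    "RegistryError",
    "synthetic_inchikey",
]


# ---------------------------------------------------------------------------
# synthetic spectra
# ---------------------------------------------------------------------------

@dataclass
class GenerationSpec:
    """Recipe for a library with known per-rule failure counts."""

    n_pass: int = 0
    n_fail_metadata: int = 0
    n_fail_chemistry: int = 0
    n_fail_mass: int = 0
    n_fail_range: int = 0
    n_fail_molion: int = 0
    n_fail_isotope: int = 0
    n_fail_marker: int = 0
    n_fail_minpeaks: int = 0
    deriv_type: str = "TMS"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_pass, self.n_fail_metadata, self.n_fail_chemistry,
                  self.n_fail_mass, self.n_fail_range, self.n_fail_molion,
                  self.n_fail_isotope, self.n_fail_marker, self.n_fail_minpeaks)
        if any(c < 0 for c in counts):
            raise ValueError("all generation counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("generation spec is empty")

    @property
    def total(self) -> int:
        return (self.n_pass + self.n_fail_metadata + self.n_fail_chemistry
                + self.n_fail_mass + self.n_fail_range + self.n_fail_molion
                + self.n_fail_isotope + self.n_fail_marker + self.n_fail_minpeaks)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_pass", "n_fail_metadata", "n_fail_chemistry", "n_fail_mass",
            "n_fail_range", "n_fail_molion", "n_fail_isotope", "n_fail_marker",
            "n_fail_minpeaks", "deriv_type", "seed")}

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationSpec":
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact bookkeeping the curation report must reproduce."""

    step0_metadata: int = 0
    step1_chemistry: int = 0
    step2_mass: int = 0
    step3_quality: int = 0
    retained: int = 0
    code_counts: dict[str, int] = field(default_factory=dict)
    expected_codes: dict[str, list[str]] = field(default_factory=dict)
    #: synthetic parent registry needed to run step 1 on the library
    registry: list[CompoundRecord] = field(default_factory=list)


def synthetic_inchikey(name: str, parent: bool = False) -> str:
    """Deterministic well-formed 14-10-1 key derived from the record name.

    Purely synthetic (not a structure hash); the parent key shares the first
    block with the derivative key so that the registry join on the
    connectivity block succeeds.
    """
    salt = "parent:" if parent else "derivative:"
    digest = hashlib.sha256((salt + name).encode("utf-8")).digest()
    letters = [chr(65 + b % 26) for b in digest]
    return "".join(letters[:14]) + "-" + "".join(letters[14:24]) + "-N"


def _synthetic_formula(nominal_mw: int, n_si: int) -> str:
    """A CxHyO2Siz formula whose nominal mass equals ``nominal_mw``."""
    rem = nominal_mw - 28 * n_si - 32  # Si=28, O2=32
    if rem < 16:
        raise ValueError(f"target Mw {nominal_mw} infeasible for {n_si} Si")
    c = rem // 13
    h = rem - 12 * c
    if h == 0:
        c, h = c - 1, 12
    si = f"Si{n_si}" if n_si > 1 else ("Si" if n_si == 1 else "")
    return f"C{c}H{h}O2{si}"


def _safe_mw(rng: random.Random, lo: int, hi: int) -> int:
    """Draw a nominal Mw whose molecular-ion/isotope region (Mw−2 … Mw+3)
    stays clear of every marker window, so that single-rule peak surgery in
    the failing-spectrum generators cannot touch two rules at once."""
    forbidden: set[int] = set()
    for t in DERIV_TYPES:
        for m in marker_series(t, 6):
            forbidden.update(range(m - 3, m + 3))
    while True:
        mw = rng.randint(lo, hi)
        if mw not in forbidden:
            return mw


def _filler_mzs(rng: random.Random, count: int, mw: int,
                deriv_type: str, config: FilterConfig) -> list[int]:
    """Fragment m/z values clear of every tested window (both marker series,
    molecular-ion and isotope region)."""
    forbidden: set[int] = set()
    for t in ("TMS", "TBDMS"):
        for m in marker_series(t, 6):
            forbidden.update(range(m - 2, m + 3))
    forbidden.update(range(mw - 3, mw + 4))
    lo = int(config.scan_lower) + 2
    hi = max(lo + 10, mw - 15)
    pool = [m for m in range(lo, hi) if m not in forbidden]
    return rng.sample(pool, count)


def _intensity(rng: random.Random) -> float:
    # log-uniform on [1, 999]
    return float(round(math.exp(rng.uniform(0.0, math.log(999.0))), 1))


def generate_passing_spectrum(deriv_type: str, mw: float, rng: random.Random,
                              config: Optional[FilterConfig] = None,
                              index: int = 0, n_groups: Optional[int] = None,
                              ) -> Spectrum:
    """A spectrum passing every curation rule at the given nominal Mw."""
    config = config or FilterConfig()
    mw = int(round(mw))
    if not (config.scan_lower + config.acquisition_margin < mw):
        raise ValueError(f"target Mw {mw} too low for a plausible spectrum")
    n_groups = n_groups if n_groups is not None else rng.randint(1, 3)
    name = f"synthetic compound {index:04d} {n_groups}{deriv_type}"
    marker = marker_series(deriv_type, config.marker_max_groups(deriv_type))[0]

    n_filler = config.min_peaks + rng.randint(1, 4)
    peaks = [Peak(float(mw), _intensity(rng)),
             Peak(float(mw + 1), round(_intensity(rng) * 0.3 + 1, 1)),
             Peak(float(marker), _intensity(rng))]
    peaks += [Peak(float(m), _intensity(rng))
              for m in _filler_mzs(rng, n_filler, mw, deriv_type, config)]
    formula = _synthetic_formula(mw, n_groups)
    return Spectrum(
        peaks=tuple(peaks),
        name=name,
        inchikey=synthetic_inchikey(name),
        formula=formula,
        mw=float(mw),
        exact_mass=round(formula_monoisotopic_mass(formula), 4),
        acquisition_upper_mz=float(mw) + config.acquisition_margin,
        annotations={"synthetic": True},
    )


_META_CYCLE = (FailureCode.META_NAME_MISMATCH, FailureCode.META_FORMULA_NO_SI,
               FailureCode.META_BAD_INCHIKEY, FailureCode.META_MASS_INCONSISTENT)


def generate_failing_spectrum(deriv_type: str, failure: FailureCode,
                              rng: random.Random,
                              config: Optional[FilterConfig] = None,
                              index: int = 0) -> Spectrum:
    """A spectrum failing exactly the requested rule.

    For the step-3 codes the spectrum passes every other quality check; for
    earlier-step codes the pipeline's short-circuiting makes later checks
    moot, but the record is still kept internally consistent.
    """
    config = config or FilterConfig()
    mw = _safe_mw(rng, 250, int(min(config.scan_upper(deriv_type),
                                    config.mass_cutoff)) - 60)
    if failure == FailureCode.MASS_CUTOFF:
        mw = _safe_mw(rng, int(config.mass_cutoff), int(config.mass_cutoff) + 150)
    s = generate_passing_spectrum(deriv_type, mw, rng, config, index=index)

    if failure == FailureCode.META_NAME_MISMATCH:
        s.name = s.name.replace(f"{deriv_type}", "underivatized")
        s.inchikey = synthetic_inchikey(s.name)
    elif failure == FailureCode.META_FORMULA_NO_SI:
        # swap each Si (nominal 28) for C2H4 so the nominal mass still matches
        counts = dict(_parse_simple_formula(s.formula))
        n_si = counts.pop("Si", 0)
        counts["C"] += 2 * n_si
        counts["H"] += 4 * n_si
        s.formula = "".join(f"{el}{n if n > 1 else ''}"
                            for el, n in (("C", counts["C"]), ("H", counts["H"]),
                                          ("O", counts["O"])))
    elif failure == FailureCode.META_BAD_INCHIKEY:
        s.inchikey = "NOTAKEY"
    elif failure == FailureCode.META_MASS_INCONSISTENT:
        s.mw = s.mw + 3.0
        s.acquisition_upper_mz = s.mw + config.acquisition_margin
    elif failure == FailureCode.CHEM_NOT_AMENABLE:
        s.annotations["parent_amenable"] = False
    elif failure == FailureCode.MASS_CUTOFF:
        pass  # mw chosen at or above the cutoff already
    elif failure == FailureCode.QUAL_RANGE:
        s.acquisition_upper_mz = s.mw + config.acquisition_margin - rng.randint(1, 5)
    elif failure == FailureCode.QUAL_MOLION:
        kept = [p for p in s.peaks if abs(p.mz - s.mw) > config.mz_tolerance]
        kept.append(Peak(float(_filler_mzs(rng, 1, int(s.mw), deriv_type, config)[0]),
                         _intensity(rng)))
        s.peaks = tuple(kept)
        s.__post_init__()
    elif failure == FailureCode.QUAL_ISOTOPE:
        kept = [p for p in s.peaks
                if not any(abs(p.mz - (s.mw + d)) <= config.mz_tolerance
                           for d in config.isotope_offsets)]
        kept.append(Peak(float(_filler_mzs(rng, 1, int(s.mw), deriv_type, config)[0]),
                         _intensity(rng)))
        s.peaks = tuple(kept)
        s.__post_init__()
    elif failure == FailureCode.QUAL_MARKER:
        series = marker_series(deriv_type, config.marker_max_groups(deriv_type))
        kept = [p for p in s.peaks
                if not any(abs(p.mz - m) <= config.mz_tolerance for m in series)]
        kept.append(Peak(float(_filler_mzs(rng, 1, int(s.mw), deriv_type, config)[0]),
                         _intensity(rng)))
        s.peaks = tuple(kept)
        s.__post_init__()
    elif failure == FailureCode.QUAL_MIN_PEAKS:
        # molecular ion + isotope + marker are 3 distinct peaks, so a
        # (min_peaks-1)-peak spectrum can pass all other checks
        target = max(3, config.min_peaks - 1)
        special = [p for p in s.peaks
                   if abs(p.mz - s.mw) <= config.mz_tolerance
                   or any(abs(p.mz - (s.mw + d)) <= config.mz_tolerance
                          for d in config.isotope_offsets)
                   or any(abs(p.mz - m) <= config.mz_tolerance
                          for m in marker_series(deriv_type,
                                                 config.marker_max_groups(deriv_type)))]
        filler = [p for p in s.peaks if p not in special]
        s.peaks = tuple(special + filler[:target - len(special)])
        s.__post_init__()
    else:
        raise ValueError(f"cannot generate a single-rule failure for {failure}")
    return s


def _parse_simple_formula(formula: str) -> dict[str, int]:
    import re
    return {el: int(n) if n else 1
            for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", formula) if el}


_AMENABLE_PARENT_SMILES = "Oc1cccc(O)c1"       # resorcinol-like: two sites
_INERT_PARENT_SMILES = "c1ccc2ccccc2c1"        # naphthalene: no active H


def _parent_record(s: Spectrum, amenable: bool) -> CompoundRecord:
    smiles = _AMENABLE_PARENT_SMILES if amenable else _INERT_PARENT_SMILES
    formula = "C6H6O2" if amenable else "C10H8"
    exact = formula_monoisotopic_mass(formula)
    # share the first (connectivity) block with the derivative record so the
    # step-1 registry join resolves; the tail marks it as a distinct molecule
    block1 = (s.inchikey or synthetic_inchikey(s.name)).split("-")[0]
    tail = synthetic_inchikey("parent:" + s.name, parent=True).split("-", 1)[1]
    return CompoundRecord(
        iupac_name=f"parent of {s.name}",
        inchikey=f"{block1}-{tail}",
        formula=formula,
        exact_mass=exact,
        mw=round(exact + 0.4, 2),
        smiles=smiles,
        flags=("synthetic",),
        note="synthetic stand-in parent structure",
    )


_FAILURE_FIELDS = (
    ("n_fail_chemistry", FailureCode.CHEM_NOT_AMENABLE),
    ("n_fail_mass", FailureCode.MASS_CUTOFF),
    ("n_fail_range", FailureCode.QUAL_RANGE),
    ("n_fail_molion", FailureCode.QUAL_MOLION),
    ("n_fail_isotope", FailureCode.QUAL_ISOTOPE),
    ("n_fail_marker", FailureCode.QUAL_MARKER),
    ("n_fail_minpeaks", FailureCode.QUAL_MIN_PEAKS),
)

_STEP_OF_CODE = {FailureCode.CHEM_NOT_AMENABLE: 1, FailureCode.MASS_CUTOFF: 2,
                 FailureCode.QUAL_RANGE: 3, FailureCode.QUAL_MOLION: 3,
                 FailureCode.QUAL_ISOTOPE: 3, FailureCode.QUAL_MARKER: 3,
                 FailureCode.QUAL_MIN_PEAKS: 3}


def generate_library(spec: GenerationSpec,
                     config: Optional[FilterConfig] = None,
                     ) -> tuple[LibraryFile, GroundTruth]:
    """Build a shuffled library whose curation report is known in advance."""
    config = config or FilterConfig()
    rng = random.Random(spec.seed)
    truth = GroundTruth()
    records: list[Spectrum] = []
    idx = 0

    def mw_target() -> int:
        return _safe_mw(rng, 250, int(min(config.scan_upper(spec.deriv_type),
                                          config.mass_cutoff)) - 60)

    for _ in range(spec.n_pass):
        s = generate_passing_spectrum(spec.deriv_type, mw_target(), rng, config,
                                      index=idx)
        idx += 1
        records.append(s)
        truth.registry.append(_parent_record(s, amenable=True))
    truth.retained = spec.n_pass

    for i in range(spec.n_fail_metadata):
        code = _META_CYCLE[i % len(_META_CYCLE)]
        s = generate_failing_spectrum(spec.deriv_type, code, rng, config, index=idx)
        idx += 1
        records.append(s)
        truth.registry.append(_parent_record(s, amenable=True))
        truth.step0_metadata += 1
        truth.code_counts[str(code)] = truth.code_counts.get(str(code), 0) + 1
        truth.expected_codes[s.name] = [str(code)]

    for fld, code in _FAILURE_FIELDS:
        for _ in range(getattr(spec, fld)):
            s = generate_failing_spectrum(spec.deriv_type, code, rng, config, index=idx)
            idx += 1
            records.append(s)
            amenable = code != FailureCode.CHEM_NOT_AMENABLE
            truth.registry.append(_parent_record(s, amenable=amenable))
            step = _STEP_OF_CODE[code]
            if step == 1:
                truth.step1_chemistry += 1
            elif step == 2:
                truth.step2_mass += 1
            else:
                truth.step3_quality += 1
            truth.code_counts[str(code)] = truth.code_counts.get(str(code), 0) + 1
            truth.expected_codes[s.name] = [str(code)]

    rng.shuffle(records)
    lib = LibraryFile(format="MSP", records=records,
                      source_path=f"<synthetic seed={spec.seed}>")
    return lib, truth


# ---------------------------------------------------------------------------
# packaged registry (compound + derivative tables)
# ---------------------------------------------------------------------------

class RegistryError(RuntimeError):
    """Packaged transcription files are missing or corrupted."""


#: compounds yielding two derivatives of the same silyl type
TWO_DERIVATIVE_TMS = ("salicylic acid", "stanolone", "sulfanilamide",
                      "5-androstene-3β,17β-diol")
TWO_DERIVATIVE_TBDMS = ("sulfanilamide", "L-serine")

#: group count of the second derivative where the tables do not list it
_SECOND_GROUPS = {("salicylic acid", "TMS"): 1, ("sulfanilamide", "TMS"): 1,
                  ("sulfanilamide", "TBDMS"): 2, ("L-serine", "TBDMS"): 2}


def _read_packaged_tsv(filename: str, manifest: dict) -> list[dict]:
    root = resources.files("silylib.data")
    try:
        raw = root.joinpath(filename).read_bytes()
    except FileNotFoundError as exc:
        raise RegistryError(f"packaged table {filename} missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if manifest.get(filename) != digest:
        raise RegistryError(f"packaged table {filename} failed its checksum")
    reader = csv.DictReader(raw.decode("utf-8").splitlines(), delimiter="\t")
    return list(reader)


def _load_tables() -> tuple[list[dict], list[dict], list[dict]]:
    root = resources.files("silylib.data")
    manifest = json.loads(root.joinpath("manifest.json").read_text("utf-8"))
    return (_read_packaged_tsv("compounds.tsv", manifest),
            _read_packaged_tsv("tms_derivatives.tsv", manifest),
            _read_packaged_tsv("tbdms_derivatives.tsv", manifest))


def _compound_from_row(row: dict) -> CompoundRecord:
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdMolDescriptors

    mol = Chem.MolFromSmiles(row["smiles"])
    if mol is None:
        raise RegistryError(f"unparsable SMILES for {row['name']!r}")
    flags = tuple(f for f in row.get("flags", "").split(",") if f)
    return CompoundRecord(
        iupac_name=row["name"],
        inchikey=Chem.MolToInchiKey(mol),
        inchi=Chem.MolToInchi(mol),
        smiles=row["smiles"],
        formula=rdMolDescriptors.CalcMolFormula(mol),
        exact_mass=round(Descriptors.ExactMolWt(mol), 4),
        mw=round(Descriptors.MolWt(mol), 2),
        flags=flags,
        note=row.get("note", ""),
    )


def _derivative(parent: CompoundRecord, deriv_type: str, n_groups: int,
                rt: Optional[float], method: Optional[str],
                flags: tuple[str, ...] = (), note: str = "") -> DerivativeRecord:
    return DerivativeRecord(
        parent=parent,
        deriv_type=deriv_type,
        n_groups=n_groups,
        derivative_formula=derivative_formula(parent.formula, n_groups, deriv_type),
        derivative_exact_mass=round(
            derivative_exact_mass(parent.exact_mass, n_groups, deriv_type), 4),
        derivative_mw=round(derivative_mw(parent.mw, n_groups, deriv_type), 2),
        retention_time_min=rt,
        acquisition_method=method,
        flags=flags,
        note=note,
    )


def _build_derivatives(deriv_type: str, compounds: dict[str, CompoundRecord],
                       dataset_names: list[str], rows: list[dict],
                       two_derivative: Sequence[str]) -> list[DerivativeRecord]:
    by_compound: dict[str, list[dict]] = {}
    for row in rows:
        cname = row["compound"]
        flags = set(f for f in row.get("flags", "").split(",") if f)
        if not cname or cname not in compounds:
            continue
        if flags & {"duplicate", "extra_row"}:
            continue
        if cname not in dataset_names:
            continue  # e.g. a TMS-only compound printed in the TBDMS table
        by_compound.setdefault(cname, []).append(row)

    out: list[DerivativeRecord] = []
    for cname in dataset_names:
        parent = compounds[cname]
        crows = by_compound.get(cname, [])
        wanted = 2 if cname in two_derivative else 1
        used = 0
        seen_groups: set[int] = set()
        for row in crows:
            if used >= wanted:
                break
            n = int(row["n_groups"])
            if n in seen_groups:
                continue
            seen_groups.add(n)
            flags = tuple(f for f in row.get("flags", "").split(",") if f)
            out.append(_derivative(
                parent, deriv_type, n,
                rt=float(row["rt_min"]) if row.get("rt_min") else None,
                method=row.get("method") or None,
                flags=flags, note=row.get("note", "")))
            used += 1
        while used < wanted:
            if used == 0:
                out.append(_derivative(parent, deriv_type, 1, rt=None, method=None,
                                       flags=("no_table_rt",),
                                       note="no retention-time table entry"))
            else:
                n2 = _SECOND_GROUPS.get((cname, deriv_type), 2)
                if n2 in seen_groups:
                    n2 = max(seen_groups) + 1
                out.append(_derivative(
                    parent, deriv_type, n2, rt=None, method=None,
                    flags=("inferred_groups",),
                    note="second derivative; group count not listed in the tables"))
            used += 1
    return out


def build_test_registry() -> tuple[list[CompoundRecord], list[DerivativeRecord],
                                   list[DerivativeRecord]]:
    """Build (compounds, TMS derivatives, TBDMS derivatives) from the packaged
    transcription tables, verifying their checksums first."""
    comp_rows, tms_rows, tbdms_rows = _load_tables()
    compounds = {row["name"]: _compound_from_row(row) for row in comp_rows}

    tms_names = [r["name"] for r in comp_rows if r["datasets"] in ("tms_only", "both")]
    tbdms_names = [r["name"] for r in comp_rows if r["datasets"] in ("tbdms_only", "both")]

    tms = _build_derivatives("TMS", compounds, tms_names, tms_rows, TWO_DERIVATIVE_TMS)
    tbdms = _build_derivatives("TBDMS", compounds, tbdms_names, tbdms_rows,
                               TWO_DERIVATIVE_TBDMS)
    return list(compounds.values()), tms, tbdms
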