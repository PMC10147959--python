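"""The step-0 … step-3 curation pipeline over a spectral library.

Spectra are first cleaned of zero-intensity ions, then filtered in fixed
order with short-circuit attribution (a record failing steps 1 and 3 is
charged to step 1):

* step 0 — metadata validation: the record name carries the expected silyl
  token, the molecular formula contains Si, the InChIKey is well formed and
  the formula's nominal mass agrees with the recorded Mw within 1 amu;
* step 1 — chemical amenability of the parent structure (resolved through a
  compound registry joined on the first InChIKey block);
* step 2 — derivative molecular mass below the instrument cutoff
  (exclusion at mass ≥ 1000 by default);
* step 3 — spectral quality: acquisition range reaches Mw + 10 amu, the
  molecular ion and an isotope satellite are both present, at least one
  silyl marker ion is present, and at least five nonzero peaks remain.

The per-step retained/excluded counts mirror the dataset-version lineage
_0.1 → _1.3 → _2.3 → _3.3.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .chem import is_amenable, marker_series
from .core import (CompoundRecord, CurationReport, FilterConfig, Spectrum,
                   formula_nominal_mass, is_valid_inchikey, parse_formula,
                   strip_zero_intensity)
from .io import LibraryFile

__all__ = [
    "FailureCode",
    "Finding",
    "CheckResult",
    "validate_metadata",
    "check_acquisition_range",
    "check_molecular_ion_and_isotope",
    "check_silyl_markers",
    "check_min_peaks",
    "apply_step",
    "curate",
    "CurationResult",
    "annotate_background",
    "DEFAULT_BACKGROUND_IONS",
]


class FailureCode(str, enum.Enum):
    """Closed set of exclusion reasons, one per curation rule."""

    META_NAME_MISMATCH = "META_NAME_MISMATCH"
    META_FORMULA_NO_SI = "META_FORMULA_NO_SI"
    META_BAD_INCHIKEY = "META_BAD_INCHIKEY"
    META_MASS_INCONSISTENT = "META_MASS_INCONSISTENT"
    CHEM_NOT_AMENABLE = "CHEM_NOT_AMENABLE"
    MASS_CUTOFF = "MASS_CUTOFF"
    QUAL_RANGE = "QUAL_RANGE"
    QUAL_MOLION = "QUAL_MOLION"
    QUAL_ISOTOPE = "QUAL_ISOTOPE"
    QUAL_MARKER = "QUAL_MARKER"
    QUAL_MIN_PEAKS = "QUAL_MIN_PEAKS"

    def __str__(self) -> str:  # report serialization uses bare code names
        return self.value


#: which pipeline step each code belongs to
CODE_STEP = {
    FailureCode.META_NAME_MISMATCH: 0,
    FailureCode.META_FORMULA_NO_SI: 0,
    FailureCode.META_BAD_INCHIKEY: 0,
    FailureCode.META_MASS_INCONSISTENT: 0,
    FailureCode.CHEM_NOT_AMENABLE: 1,
    FailureCode.MASS_CUTOFF: 2,
    FailureCode.QUAL_RANGE: 3,
    FailureCode.QUAL_MOLION: 3,
    FailureCode.QUAL_ISOTOPE: 3,
    FailureCode.QUAL_MARKER: 3,
    FailureCode.QUAL_MIN_PEAKS: 3,
}


@dataclass(frozen=True)
class Finding:
    code: FailureCode
    detail: str = ""


@dataclass(frozen=True)
class CheckResult:
    """Boolean-like outcome of one quality check, carrying its finding."""

    passed: bool
    finding: Optional[Finding] = None
    used_proxy: bool = False

    def __bool__(self) -> bool:
        return self.passed


# ---------------------------------------------------------------------------
# step 0 — metadata validation
# ---------------------------------------------------------------------------

def validate_metadata(spectrum: Spectrum, deriv_type: str) -> list[Finding]:
    """All metadata findings for one record (empty sequence = consistent)."""
    findings: list[Finding] = []
    if deriv_type not in spectrum.name:
        findings.append(Finding(
            FailureCode.META_NAME_MISMATCH,
            f"name {spectrum.name!r} lacks the {deriv_type} token"))
    si_count = 0
    formula_ok = False
    if spectrum.formula:
        try:
            si_count = parse_formula(spectrum.formula).get("Si", 0)
            formula_ok = True
        except Exception:
            formula_ok = False
    if si_count < 1:
        detail = ("formula missing" if not spectrum.formula
                  else f"formula {spectrum.formula} contains no Si"
                  if formula_ok else f"formula {spectrum.formula!r} unparsable")
        findings.append(Finding(FailureCode.META_FORMULA_NO_SI, detail))
    if not is_valid_inchikey(spectrum.inchikey):
        findings.append(Finding(
            FailureCode.META_BAD_INCHIKEY,
            f"InChIKey {spectrum.inchikey!r} is not a 14-10-1 key"))
    if formula_ok and spectrum.mw is not None:
        nominal = formula_nominal_mass(spectrum.formula)
        if abs(nominal - spectrum.mw) > 1.0:
            findings.append(Finding(
                FailureCode.META_MASS_INCONSISTENT,
                f"formula nominal mass {nominal} vs MW {spectrum.mw}"))
    return findings


# ---------------------------------------------------------------------------
# step 3 — the four spectral-quality checks
# ---------------------------------------------------------------------------

def check_acquisition_range(spectrum: Spectrum, config: FilterConfig) -> CheckResult:
    """Acquisition must reach at least Mw of the derivative + margin.

    When the record carries no acquisition upper limit, a proxy is used:
    the spectrum passes iff any peak reaches the molecular-ion region
    (the molecular ion could be, and was, observed); the proxy use is
    reported in the result.
    """
    if spectrum.mw is None:
        return CheckResult(False, Finding(FailureCode.QUAL_RANGE, "Mw unknown"))
    if spectrum.acquisition_upper_mz is not None:
        if spectrum.acquisition_upper_mz >= spectrum.mw + config.acquisition_margin:
            return CheckResult(True)
        return CheckResult(False, Finding(
            FailureCode.QUAL_RANGE,
            f"acquired to m/z {spectrum.acquisition_upper_mz}, below "
            f"Mw {spectrum.mw} + {config.acquisition_margin}"))
    threshold = spectrum.mw - config.mz_tolerance
    if any(p.mz >= threshold for p in spectrum.peaks):
        return CheckResult(True, used_proxy=True)
    return CheckResult(False, Finding(
        FailureCode.QUAL_RANGE,
        f"no acquisition metadata and no peak at or above m/z {threshold}"),
        used_proxy=True)


def check_molecular_ion_and_isotope(spectrum: Spectrum, config: FilterConfig) -> CheckResult:
    """Both the molecular ion [M]+ and an isotope satellite must be present.

    The satellite may sit at any offset in ``config.isotope_offsets``
    (M+1 from 13C, M+1/M+2 from 29Si/30Si), within the m/z tolerance.
    """
    if spectrum.mw is None:
        return CheckResult(False, Finding(FailureCode.QUAL_MOLION, "Mw unknown"))
    tol = config.mz_tolerance
    mw = spectrum.mw

    def present(target: float) -> bool:
        return any(abs(p.mz - target) <= tol and p.intensity > 0
                   for p in spectrum.peaks)

    if not present(mw):
        return CheckResult(False, Finding(
            FailureCode.QUAL_MOLION, f"no molecular-ion peak near m/z {mw}"))
    if not any(present(mw + d) for d in config.isotope_offsets):
        return CheckResult(False, Finding(
            FailureCode.QUAL_ISOTOPE,
            f"no isotope peak near m/z {mw} + {set(config.isotope_offsets)}"))
    return CheckResult(True)


def check_silyl_markers(spectrum: Spectrum, deriv_type: str,
                        config: FilterConfig) -> CheckResult:
    """At least one diagnostic silyl fragment of the derivative's own series."""
    series = marker_series(deriv_type, config.marker_max_groups(deriv_type))
    tol = config.mz_tolerance
    for p in spectrum.peaks:
        if any(abs(p.mz - m) <= tol for m in series):
            return CheckResult(True)
    return CheckResult(False, Finding(
        FailureCode.QUAL_MARKER,
        f"no peak within {tol} of the {deriv_type} series {series}"))


def check_min_peaks(spectrum: Spectrum, config: FilterConfig) -> CheckResult:
    """At least ``min_peaks`` fragment-ion peaks (molecular ion included)."""
    if spectrum.num_peaks >= config.min_peaks:
        return CheckResult(True)
    return CheckResult(False, Finding(
        FailureCode.QUAL_MIN_PEAKS,
        f"{spectrum.num_peaks} peaks, need {config.min_peaks}"))


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def _registry_index(registry: Sequence[CompoundRecord]) -> dict[str, CompoundRecord]:
    index: dict[str, CompoundRecord] = {}
    for rec in registry:
        index.setdefault(rec.inchikey_block1, rec)
    return index


def _derivative_mass(spectrum: Spectrum) -> Optional[float]:
    # the instrument cutoff is stated for "molecular mass" without choosing a
    # convention; use nominal Mw when present, else the exact mass
    return spectrum.mw if spectrum.mw is not None else spectrum.exact_mass


def apply_step(records: Sequence[Spectrum], step_id: int, config: FilterConfig,
               deriv_type: str,
               registry: Sequence[CompoundRecord] = (),
               warnings: Optional[list[str]] = None,
               ) -> tuple[list[Spectrum], list[tuple[Spectrum, list[Finding]]]]:
    """Run one pipeline step; return (kept, excluded-with-findings)."""
    if step_id not in (0, 1, 2, 3):
        raise ValueError(f"unknown curation step: {step_id}")
    warnings = warnings if warnings is not None else []
    kept: list[Spectrum] = []
    excluded: list[tuple[Spectrum, list[Finding]]] = []
    index = _registry_index(registry) if step_id == 1 else {}

    for s in records:
        findings: list[Finding] = []
        if step_id == 0:
            findings = validate_metadata(s, deriv_type)
        elif step_id == 1:
            parent = None
            if s.inchikey:
                parent = index.get(s.inchikey.split("-")[0])
            if parent is None or not parent.smiles:
                if config.unresolved_structure == "exclude":
                    findings = [Finding(FailureCode.CHEM_NOT_AMENABLE,
                                        "parent structure unresolved")]
                else:
                    warnings.append(
                        f"step 1: parent structure unresolved for {s.name!r}; kept")
            elif not is_amenable(parent.smiles):
                findings = [Finding(
                    FailureCode.CHEM_NOT_AMENABLE,
                    f"parent {parent.iupac_name!r} has no silylation site")]
        elif step_id == 2:
            mass = _derivative_mass(s)
            if mass is None:
                warnings.append(f"step 2: no molecular mass for {s.name!r}; kept")
            elif mass >= config.mass_cutoff:
                findings = [Finding(
                    FailureCode.MASS_CUTOFF,
                    f"molecular mass {mass} >= {config.mass_cutoff}")]
        else:
            for result in (check_acquisition_range(s, config),
                           check_molecular_ion_and_isotope(s, config),
                           check_silyl_markers(s, deriv_type, config),
                           check_min_peaks(s, config)):
                if not result.passed:
                    findings.append(result.finding)
        if findings:
            excluded.append((s, findings))
        else:
            kept.append(s)
    return kept, excluded


def _spectrum_key(s: Spectrum, position: int) -> str:
    if s.nist_number is not None:
        return f"NIST#{s.nist_number}"
    if s.id_number is not None:
        return f"ID#{s.id_number}"
    return f"record{position:05d}:{s.name}"


@dataclass
class CurationResult:
    """Curated library, per-step report, and the intermediate snapshots."""

    curated: LibraryFile
    report: CurationReport
    snapshots: dict[str, LibraryFile] = field(default_factory=dict)


def curate(library: LibraryFile, deriv_type: str,
           registry: Sequence[CompoundRecord] = (),
           config: Optional[FilterConfig] = None,
           keep_snapshots: bool = False) -> CurationResult:
    """Run the full pipeline: zero-intensity strip, then steps 0→1→2→3.

    Filters short-circuit in that order, so each excluded record carries the
    findings of the first step that rejected it.  Steps listed in
    ``config.skip_steps`` are passed through.  Snapshots of the surviving
    library after extraction and after each step are labelled with the
    dataset-version suffixes (_0.1, _1.3, _2.3, _3.3).
    """
    config = config or FilterConfig()
    warnings: list[str] = []
    stripped = [strip_zero_intensity(s) for s in library.records]
    positions = {id(s): i for i, s in enumerate(stripped)}

    reasons: dict[str, list[str]] = {}
    step_excluded_counts = {0: 0, 1: 0, 2: 0, 3: 0}
    current = stripped
    prefix = f"{deriv_type}"
    snapshots: dict[str, LibraryFile] = {}
    if keep_snapshots:
        snapshots[prefix + "_0.1"] = LibraryFile(
            format=library.format, records=list(current),
            source_path=library.source_path)
    step_labels = {1: "_1.3", 2: "_2.3", 3: "_3.3"}

    for step in (0, 1, 2, 3):
        if step in config.skip_steps:
            kept, excluded = list(current), []
        else:
            kept, excluded = apply_step(current, step, config, deriv_type,
                                        registry=registry, warnings=warnings)
        for s, findings in excluded:
            key = _spectrum_key(s, positions[id(s)])
            reasons[key] = [str(f.code) for f in findings]
        step_excluded_counts[step] = len(excluded)
        current = kept
        if keep_snapshots and step in step_labels:
            snapshots[prefix + step_labels[step]] = LibraryFile(
                format=library.format, records=list(current),
                source_path=library.source_path)

    report = CurationReport(
        input_count=len(stripped),
        step0_metadata_excluded=step_excluded_counts[0],
        step1_chemistry_excluded=step_excluded_counts[1],
        step2_mass_excluded=step_excluded_counts[2],
        step3_quality_excluded=step_excluded_counts[3],
        retained=len(current),
        per_spectrum_reasons=reasons,
        warnings=warnings,
    )
    curated = LibraryFile(format=library.format, records=list(current),
                          source_path=library.source_path)
    return CurationResult(curated=curated, report=report, snapshots=snapshots)


# ---------------------------------------------------------------------------
# background-ion annotation
# ---------------------------------------------------------------------------

#: constantly present background signals at unit resolution: phthalate
#: interference, fatty-acid ions, and polysiloxane ions from column bleed
DEFAULT_BACKGROUND_IONS = {
    149.0: "phthalate",
    256.0: "palmitic acid",
    282.0: "oleic acid",
    284.0: "stearic acid",
    207.0: "polysiloxane",
    281.0: "polysiloxane",
    327.0: "polysiloxane",
}


def annotate_background(spectrum: Spectrum,
                        ions: Optional[dict[float, str]] = None,
                        tolerance: float = 0.5,
                        subtract: bool = False) -> Spectrum:
    """Flag (or with ``subtract=True`` remove) known background ions.

    Annotation is the default because at library level removal is lossy:
    a genuine fragment can sit on a background m/z.
    """
    ions = DEFAULT_BACKGROUND_IONS if ions is None else ions
    hits = []
    flagged = set()
    for p in spectrum.peaks:
        for mz, label in ions.items():
            if abs(p.mz - mz) <= tolerance:
                hits.append({"mz": p.mz, "background_mz": mz, "label": label})
                flagged.add(p.mz)
                break
    if subtract:
        out = spectrum.with_peaks(p for p in spectrum.peaks if p.mz not in flagged)
    else:
        out = spectrum.with_peaks(spectrum.peaks)
    if hits:
        out.annotations = dict(out.annotations)
        out.annotations["background"] = hits
        if subtract:
            out.annotations["background_subtracted"] = True
    return out
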