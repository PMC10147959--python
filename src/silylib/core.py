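"""Domain types and elementary spectrum manipulations.

The unit everything operates on is a :class:`Spectrum` — an ordered peak list
(m/z, intensity) plus the record metadata a NIST-style library entry carries
(name, InChIKey, molecular formula, nominal and exact mass, CAS and library
identifiers).  Compound/derivative identity lives in :class:`CompoundRecord`
and :class:`DerivativeRecord`; every tunable threshold of the curation
pipeline is a field of :class:`FilterConfig`.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "Peak",
    "Spectrum",
    "CompoundRecord",
    "DerivativeRecord",
    "FilterConfig",
    "CurationReport",
    "INCHIKEY_PATTERN",
    "is_valid_inchikey",
    "canonical_peaks",
    "strip_zero_intensity",
    "clip_mz_range",
    "parse_formula",
    "formula_monoisotopic_mass",
    "formula_average_mass",
    "formula_nominal_mass",
]

#: 14-10-1 block pattern of a standard InChIKey, e.g. YGSDEFSMJLZEOE-UHFFFAOYSA-N
INCHIKEY_PATTERN = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def is_valid_inchikey(key: Optional[str]) -> bool:
    return key is not None and bool(INCHIKEY_PATTERN.match(key))


@dataclass(frozen=True)
class Peak:
    """One ion: m/z in amu (> 0) and abundance in arbitrary units (>= 0)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


def canonical_peaks(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
    """Sort ascending by m/z and merge exact-duplicate m/z by summing intensity."""
    merged: dict[float, float] = {}
    for p in peaks:
        merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
    return tuple(Peak(mz, inten) for mz, inten in sorted(merged.items()))


@dataclass
class Spectrum:
    """A single library record: canonically ordered peaks plus metadata.

    ``peaks`` are kept strictly ascending in m/z; readers canonicalize on
    construction.  Optional metadata fields are ``None`` when the source
    record did not carry them.  ``annotations`` holds provenance flags
    (imputed Mw, proxy acquisition check, background-ion labels) and is never
    serialized by the format writers.
    """

    peaks: tuple[Peak, ...] = ()
    name: str = ""
    inchikey: Optional[str] = None
    cas: Optional[str] = None
    formula: Optional[str] = None
    mw: Optional[float] = None
    exact_mass: Optional[float] = None
    nist_number: Optional[int] = None
    id_number: Optional[int] = None
    acquisition_upper_mz: Optional[float] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = canonical_peaks(self.peaks)

    @property
    def num_peaks(self) -> int:
        return len(self.peaks)

    @property
    def max_mz(self) -> Optional[float]:
        return self.peaks[-1].mz if self.peaks else None

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        return replace(self, peaks=tuple(peaks), annotations=dict(self.annotations))


def strip_zero_intensity(spectrum: Spectrum) -> Spectrum:
    """Drop every peak with intensity 0; metadata and order are untouched."""
    return spectrum.with_peaks(p for p in spectrum.peaks if p.intensity > 0)


def clip_mz_range(spectrum: Spectrum, lower: float, upper: float) -> Spectrum:
    """Keep only peaks with lower <= m/z <= upper (both bounds inclusive)."""
    if lower >= upper:
        raise ValueError(f"invalid m/z window: lower={lower} >= upper={upper}")
    return spectrum.with_peaks(p for p in spectrum.peaks if lower <= p.mz <= upper)


# ---------------------------------------------------------------------------
# molecular-formula helpers (element bookkeeping via pyteomics mass tables)
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into positive element counts."""
    comp = _pmass.Composition(formula=formula)
    counts = {el: int(n) for el, n in comp.items() if n}
    if not counts:
        raise ValueError(f"empty molecular formula: {formula!r}")
    if any(n < 0 for n in counts.values()):
        raise ValueError(f"negative element count in formula: {formula!r}")
    return counts


def formula_monoisotopic_mass(formula: str) -> float:
    return _pmass.calculate_mass(formula=formula)


def formula_average_mass(formula: str) -> float:
    return _pmass.calculate_mass(formula=formula, average=True)


def formula_nominal_mass(formula: str) -> int:
    """Nominal (integer) mass: sum of rounded principal-isotope masses."""
    total = 0
    for el, n in parse_formula(formula).items():
        mono = _pmass.nist_mass[el][0][0]
        total += round(mono) * n
    return total


@dataclass
class CompoundRecord:
    """Identity of a parent contaminant of emerging concern (CEC)."""

    iupac_name: str
    inchikey: str
    formula: str
    exact_mass: float
    mw: float
    cas: Optional[str] = None
    inchi: Optional[str] = None
    smiles: Optional[str] = None
    pubchem_id: Optional[int] = None
    in_training_overlap: Optional[bool] = None
    flags: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        # monoisotopic mass never sits far above the average mass for
        # CHNOPS-Si molecules of this size
        if self.exact_mass > self.mw + 1.0:
            raise ValueError(
                f"{self.iupac_name}: exact mass {self.exact_mass} exceeds Mw {self.mw} + 1"
            )
        parse_formula(self.formula)

    @property
    def inchikey_block1(self) -> str:
        return self.inchikey.split("-")[0]


@dataclass
class DerivativeRecord:
    """A TMS or TBDMS derivative of a parent compound."""

    parent: CompoundRecord
    deriv_type: str  # "TMS" | "TBDMS"
    n_groups: int
    derivative_formula: str
    derivative_exact_mass: float
    derivative_mw: float
    retention_time_min: Optional[float] = None
    acquisition_method: Optional[str] = None
    flags: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.deriv_type not in ("TMS", "TBDMS"):
            raise ValueError(f"unknown derivative type: {self.deriv_type!r}")
        if self.n_groups < 1:
            raise ValueError("a derivative carries at least one silyl group")
        if not self.derivative_exact_mass > self.parent.exact_mass:
            raise ValueError(
                f"{self.parent.iupac_name}: derivative mass must exceed parent mass"
            )


_DERIV_SPECIFIC = {"TMS": {"marker_max_groups": 4, "scan_upper": 800.0},
                   "TBDMS": {"marker_max_groups": 3, "scan_upper": 1000.0}}


@dataclass
class FilterConfig:
    """All thresholds of the curation pipeline.

    Defaults reflect unit-resolution quadrupole GC-EI-MS data: spectra are
    nominal-mass peak lists, hence the ±0.5 amu matching tolerance, and the
    acquisition ranges are m/z 50–800 (TMS) and 50–1000 (TBDMS).
    """

    mass_cutoff: float = 1000.0
    min_peaks: int = 5
    mz_tolerance: float = 0.5
    acquisition_margin: float = 10.0
    marker_max_groups_tms: int = 4
    marker_max_groups_tbdms: int = 3
    scan_lower: float = 50.0
    scan_upper_tms: float = 800.0
    scan_upper_tbdms: float = 1000.0
    isotope_offsets: tuple[float, ...] = (1.0, 2.0)
    #: disposition for spectra whose parent structure cannot be resolved in
    #: step 1: "keep" (retain, warn) or "exclude"
    unresolved_structure: str = "keep"
    skip_steps: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("mass_cutoff", "min_peaks", "mz_tolerance", "acquisition_margin",
                     "marker_max_groups_tms", "marker_max_groups_tbdms",
                     "scan_lower", "scan_upper_tms", "scan_upper_tbdms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        if not self.mz_tolerance < 1.0:
            raise ValueError("mz_tolerance must be below 1 amu (unit resolution)")
        if self.unresolved_structure not in ("keep", "exclude"):
            raise ValueError("unresolved_structure must be 'keep' or 'exclude'")

    def marker_max_groups(self, deriv_type: str) -> int:
        return {"TMS": self.marker_max_groups_tms,
                "TBDMS": self.marker_max_groups_tbdms}[deriv_type]

    def scan_upper(self, deriv_type: str) -> float:
        return {"TMS": self.scan_upper_tms, "TBDMS": self.scan_upper_tbdms}[deriv_type]

    def to_dict(self) -> dict:
        return {
            "mass_cutoff": self.mass_cutoff,
            "min_peaks": self.min_peaks,
            "mz_tolerance": self.mz_tolerance,
            "acquisition_margin": self.acquisition_margin,
            "marker_max_groups_tms": self.marker_max_groups_tms,
            "marker_max_groups_tbdms": self.marker_max_groups_tbdms,
            "scan_lower": self.scan_lower,
            "scan_upper_tms": self.scan_upper_tms,
            "scan_upper_tbdms": self.scan_upper_tbdms,
            "isotope_offsets": list(self.isotope_offsets),
            "unresolved_structure": self.unresolved_structure,
            "skip_steps": list(self.skip_steps),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        kwargs = dict(d)
        if "isotope_offsets" in kwargs:
            kwargs["isotope_offsets"] = tuple(kwargs["isotope_offsets"])
        if "skip_steps" in kwargs:
            kwargs["skip_steps"] = tuple(kwargs["skip_steps"])
        return cls(**kwargs)


#: dataset-version suffixes after the initial extraction and each filter step
VERSION_LABELS = ("_0.1", "_1.3", "_2.3", "_3.3")


@dataclass
class CurationReport:
    """Per-step retained/excluded bookkeeping for one curation run."""

    input_count: int
    step0_metadata_excluded: int
    step1_chemistry_excluded: int
    step2_mass_excluded: int
    step3_quality_excluded: int
    retained: int
    per_spectrum_reasons: dict[str, list[str]] = field(default_factory=dict)
    version_labels: tuple[str, ...] = VERSION_LABELS
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (self.step0_metadata_excluded + self.step1_chemistry_excluded
                 + self.step2_mass_excluded + self.step3_quality_excluded
                 + self.retained)
        if total != self.input_count:
            raise ValueError(
                f"report does not conserve records: input {self.input_count}, "
                f"accounted {total}"
            )

    @property
    def excluded(self) -> int:
        return self.input_count - self.retained

    def step_counts(self) -> dict[str, int]:
        return {
            "step0_metadata": self.step0_metadata_excluded,
            "step1_chemistry": self.step1_chemistry_excluded,
            "step2_mass": self.step2_mass_excluded,
            "step3_quality": self.step3_quality_excluded,
        }

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "step0_metadata_excluded": self.step0_metadata_excluded,
            "step1_chemistry_excluded": self.step1_chemistry_excluded,
            "step2_mass_excluded": self.step2_mass_excluded,
            "step3_quality_excluded": self.step3_quality_excluded,
            "retained": self.retained,
            "version_labels": list(self.version_labels),
            "per_spectrum_reasons": {k: list(v) for k, v in self.per_spectrum_reasons.items()},
            "warnings": list(self.warnings),
        }
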