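# Methods

## The curation model

A spectral-library record of a silylated derivative is judged on four
orthogonal grounds, applied in a fixed order with short-circuit
attribution (a record failing several stages is charged to the earliest):

**Stage 0 — metadata validation.** A derivative record must look like what
it claims to be: the record name carries the derivative-type token
(`TMS`/`TBDMS`), the molecular formula contains at least one Si atom, the
InChIKey matches the 14–10–1 uppercase block pattern, and the nominal mass
of the formula agrees with the recorded molecular weight within 1 amu.
Each violation is a separate failure code so a report can distinguish a
typo from a wholesale metadata swap.

**Stage 1 — chemical amenability.** Silylation replaces an active hydrogen
— H on O, N or S in a carboxyl, hydroxyl (including phenol), amine, thiol
or sulfonamide group.  A record whose *parent* structure carries no such
site cannot be a genuine silyl derivative.  Sites are detected with a
versioned SMARTS pattern table (`data/silylation_patterns.yaml`); each
heteroatom counts once, however many hydrogens it bears (–NH₂ is one
site).  Two deliberate boundary choices: carboxamide N–H is *not* amenable
by default (it is outside the carboxyl/hydroxyl/amine/thiol set; an
optional pattern enables it), but urea-type N–H — whose carbonyl carbon
bears no carbon substituent — *is* counted, since urea itself forms a
bis-TMS derivative.  Sulfonamide N–H is counted as its own kind
(sulfanilamide forms a 2TMS derivative).  Parents are resolved by joining
the spectrum's InChIKey first block against a compound registry;
unresolved records are kept with a warning by default (configurable to
exclude), because an absent registry row is ignorance, not evidence.

**Stage 2 — mass cutoff.** Derivatives with molecular mass ≥ *m/z* 1000
sit above the working linear range of the quadrupole GC-MS instruments the
libraries come from and are excluded.  The rule is stated for "molecular
mass" without fixing a convention, so the filter uses the record's nominal
Mw when present and falls back to the exact mass; at a 1000 amu threshold
the two differ by well under the 1-amu granularity of the sweep used to
verify the boundary.

**Stage 3 — spectral quality.** Four conjunctive checks at the matching
tolerance (±0.5 amu by default, unit-resolution data):

* *acquisition range*: the scan must extend to at least Mw + 10 amu.  When
  the record carries an explicit acquisition upper limit the check is
  direct; otherwise a proxy is used — some peak must reach the
  molecular-ion region — and the proxy use is recorded in the result,
  since absence of high-mass peaks then conflates "not acquired" with
  "not ionized".
* *molecular ion and isotope*: a peak at Mw **and** a satellite at Mw+1 or
  Mw+2.  The offset set {+1, +2} is wider than ¹³C alone because silicon's
  ²⁹Si/³⁰Si isotopes make M+1/M+2 abundant for silylated species.
* *marker ions*: at least one diagnostic silyl fragment of the record's own
  series — 73 + 74·(k−1) for k = 1…4 TMS groups, 115·k for k = 1…3 TBDMS
  groups.  The series extend beyond the printed terms by their constant
  increments (74 and 115) if a configuration asks for more groups.
* *minimum peaks*: at least five nonzero peaks, molecular ion included —
  the rule speaks of "fragment ion peaks" without defining "fragment", so
  all surviving ions count; this is the more conservative reading and is
  stated here prominently.

Zero-intensity ions are removed before any stage; they are export
artifacts, not measurements.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `mass_cutoff` | 1000 | amu | instrument linear range |
| `min_peaks` | 5 | count | informativeness floor |
| `mz_tolerance` | 0.5 | amu | unit-resolution (nominal-mass) peak lists |
| `acquisition_margin` | 10 | amu | molecular ion must sit inside the scan |
| `marker_max_groups` | 4 (TMS) / 3 (TBDMS) | count | printed series lengths |
| `scan_lower` | 50 | amu | acquisition lower bound |
| `scan_upper` | 800 (TMS) / 1000 (TBDMS) | amu | acquisition upper bounds |
| `isotope_offsets` | {+1, +2} | amu | ¹³C and ²⁹Si/³⁰Si satellites |

The retained *m/z* window upper bound is Mw + 10; the source convention is
written once as "± 10" and once as "+ 10", and the clip uses + 10 (a peak
*above* the molecular ion plus margin would be an artifact anyway, and the
acquisition rule is unambiguous).

## Mass arithmetic

Silyl increments are computed from standard monoisotopic atomic masses
(pyteomics element tables), never hard-coded: TMS = C₃H₈Si = 72.03953 amu,
TBDMS = C₆H₁₄Si = 114.08648 amu, their difference the mass of propene.
Derivative exact mass is parent + n·increment (additive in n); derivative
molecular weight uses average atomic masses the same way.  Benzoic acid
(122.03678 amu) + 1 TMS = 194.076 amu, the value that appears on the MGF
`MASS=` line.

## Format dialects

The three dialects are written deterministically (fixed key order, one
newline convention, shortest round-trip decimal serialization) so that
byte-identical inputs give byte-identical outputs and `msp→msp` conversion
is an idempotent canonicalization.  Readers are liberal where vendor
exports differ: MSP key synonyms (`CASNO:`, `MW=`), `PEPMASS=` as an MGF
alias of `MASS=`, whitespace-tolerant TITLE parsing (the fixed layout is
`TITLE= InChIKey: <key> Name: <name>`; a TITLE without the `InChIKey:`
token still yields the name plus a recorded warning), and UTF-8 with a
Latin-1 fallback because compound names carry Greek letters and primes
(17β-estradiol, 4,4′-biphenol).  Duplicate m/z values within one record
are merged at read time by summing intensities — the filters are defined
on distinct ions — and peaks are canonically sorted ascending.  The TXT
dialect additionally round-trips `ExactMass:` when present so a
txt→mgf conversion has the mass the MGF header requires.

## Synthetic data: what it emulates and what it does not

The generator builds *controlled* spectra, not realistic ones: each
contains a molecular ion at the target nominal Mw, an isotope satellite at
Mw+1, the first marker ion of the correct series, and filler fragments
drawn uniformly away from every tested window (both marker series ± 2 amu
and the molecular-ion region), with log-uniform intensities on [1, 999].
Failure variants are produced by single-rule surgery on a passing spectrum
(e.g. removing the marker peaks and adding one safe filler), so each
failing record violates exactly one rule.  Target Mw values are drawn so
that the Mw−2…Mw+3 region never overlaps a marker window — otherwise
removing a marker could also remove the isotope satellite and a
single-rule spectrum would fail two rules.  Records are named
`synthetic compound NNNN kTMS`, carry deterministic well-formed synthetic
InChIKeys (hash-derived, flagged as synthetic) and CxHyO₂Siz formulas
whose nominal mass equals the stated Mw.  All randomness flows through one
seeded generator; the same seed reproduces the same library byte for
byte.

What passing tests on these libraries show: the pipeline's bookkeeping,
boundary behavior, attribution and conservation are exact.  What they do
not show: performance on real EI fragmentation patterns, intensity
distributions, or noisy real-world metadata beyond the modeled error
classes.

The packaged registry transcribes the reference inventory: 104 parent
compounds (21 TMS-only, 2 TBDMS-only, 81 in both datasets) with curated
SMILES, and derivative lists of 106 TMS (102 compounds, four with two
derivatives each) and 85 TBDMS (83 compounds, two with two derivatives)
records with retention times where the published tables list them.
Formulas, exact masses, molecular weights and InChIKeys are computed from
the SMILES with RDKit at build time; the transcription files are
checksum-verified on load.  Table rows that could not be attributed with
certainty (a misprinted name, a compound listed in the wrong dataset, a
row with no resolvable identity) are kept verbatim with an `uncertain`
flag and attach to no derivative record rather than being silently
guessed.  Two table entries (`estrone 2TMS`, `stanolone 2TMS`) carry one
more silyl group than the parent has active-H sites: these are enol-TMS
ethers of ring ketones, real derivatization chemistry outside the
closed functional-group set; they are flagged `enol` and exempted from the
sites-bound invariant.  Group counts for second derivatives the tables do
not disambiguate are recorded with an `inferred_groups` flag.

## Numerical and degenerate-input choices

* All m/z window comparisons are closed (≤ tolerance), and the mass cutoff
  excludes at exactly ≥ 1000 — boundary records are excluded, not kept.
* A spectrum without Mw cannot be quality-checked and fails stage 3 with an
  explicit "Mw unknown" detail; a spectrum without any mass is passed
  through stage 2 with a warning (the filter cannot fire on ignorance).
* Empty libraries, empty spectra and zero-record conversions are all legal
  at the I/O layer; filters, not parsers, reject them.
* Report keys prefer NIST#/ID# identifiers and fall back to a
  position-qualified name, so duplicate names cannot collide.

## Problem sizes

The test suite exercises ground-truth recovery on twenty 210-record
synthetic libraries (alternating TMS/TBDMS), brute-force oracle
equivalence on 50-record libraries, and round-trip closure on a 10-record
fixture library carrying real registry metadata; the whole suite runs in
well under a minute on one CPU.

## Known limitations

* Amenability is binary; the package does not predict which of several
  sites actually derivatizes under given reaction conditions, nor partial
  derivatization kinetics.
* EI fragmentation is not modeled beyond the diagnostic marker series.
* The registry's SMILES are curated from compound names; four entries are
  flagged uncertain where the printed identity is ambiguous.
* mzML/mzXML emission is out of scope (standard converters read the MGF
  output).
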