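# silylib

Curation toolkit for GC-EI-MS spectral libraries of **trimethylsilyl (TMS)**
and ***tert*-butyldimethylsilyl (TBDMS)** derivatives.

Semi-polar environmental contaminants (phenols, acids, amines — the
"contaminants of emerging concern", CEC) must be silylated before gas
chromatography–mass spectrometry with electron ionization: an active
hydrogen on O, N or S is replaced by –Si(CH₃)₃ (net gain C₃H₈Si,
+72.0395 amu per group) or –Si(CH₃)₂C(CH₃)₃ (net gain C₆H₁₄Si,
+114.0865 amu).  Reference libraries of such derivatives are scarce and
noisy; before they can train or evaluate compound-identification models they
need systematic curation.  `silylib` implements that desk workflow for
analytical chemists and cheminformaticians:

* **Format I/O** — deterministic, round-trip-exact readers/writers for
  NIST-style `.msp`, Mascot generic `.mgf` (`BEGIN IONS` / `MASS=` /
  `CHARGE=1+` / `TITLE= InChIKey: … Name: …`) and two-column `.txt`
  peak-list dialects, plus conversion among them.
* **Silylation chemistry** — SMARTS-based detection of silylation-amenable
  groups (carboxyl, hydroxyl/phenol, amine, thiol, sulfonamide N–H) on a
  parent SMILES/InChI; derivative formula and mass arithmetic from standard
  atomic masses; the diagnostic marker-ion series *m/z* 73, 147, 221, 295
  (1–4 TMS groups) and 115, 230, 345 (1–3 TBDMS groups); parsing of table
  names like `estriol 3TMS` or `salicylic acid-bis TMS`; the REACH-style
  3-of-5 eligibility rule for CEC selection.
* **Curation pipeline** — after removal of zero-intensity ions, four
  short-circuiting stages mirroring the dataset-version lineage
  `_0.1 → _1.3 → _2.3 → _3.3`:
  0. metadata validation (silyl token in the name, Si in the formula,
     well-formed InChIKey, formula/Mw agreement within 1 amu);
  1. chemical amenability of the parent structure;
  2. instrument mass cutoff (exclusion at molecular mass ≥ *m/z* 1000);
  3. spectral quality — acquisition range ≥ Mw + 10 amu, molecular ion
     [M]⁺ **and** an isotope satellite (M+1/M+2) present, ≥ 1 diagnostic
     marker ion, ≥ 5 fragment-ion peaks.
  Every excluded spectrum carries an explicit failure code; the report
  conserves records exactly.
* **Synthetic libraries** — a generator that builds libraries with known
  per-rule failure counts (exact ground truth for the report) and a packaged
  registry of the 104 reference contaminants with their 106 TMS and 85
  TBDMS derivatives, including retention times.

## Worked example

```python
import silylib as s

compounds, tms, tbdms = s.build_test_registry()
print(f"{len(compounds)} compounds, {len(tms)} TMS / {len(tbdms)} TBDMS derivatives")

benzoic = next(c for c in compounds if c.iupac_name == "benzoic acid")
mass = s.derivative_exact_mass(benzoic.exact_mass, 1, "TMS")
print(f"benzoic acid + 1 TMS: {mass:.3f} amu")
print("TMS markers:", s.marker_series("TMS", 4))

spec = s.GenerationSpec(n_pass=10, n_fail_marker=2, n_fail_mass=1,
                        deriv_type="TMS", seed=42)
library, truth = s.generate_library(spec)
result = s.curate(library, "TMS", registry=truth.registry)
r = result.report
print(f"input {r.input_count} -> retained {r.retained} "
      f"(step2: {r.step2_mass_excluded}, step3: {r.step3_quality_excluded})")
```

prints

```
104 compounds, 106 TMS / 85 TBDMS derivatives
benzoic acid + 1 TMS: 194.076 amu
TMS markers: [73, 147, 221, 295]
input 13 -> retained 10 (step2: 1, step3: 2)
```

The registry holds the full reference inventory (104 parents; four
compounds give two TMS derivatives, two give two TBDMS derivatives).
194.076 amu is the monoisotopic mass of the benzoic acid mono-TMS ester —
the value written on the `MASS=` line of the MGF dialect.  The synthetic
13-record library was built with one mass-cutoff and two marker failures;
the curation report recovers exactly those exclusions and retains the ten
clean spectra.

The same workflow is available from the shell:

```bash
silylib synth --spec spec.yaml --out lib.msp --truth truth.json --registry-out parents.tsv
silylib curate --in lib.msp --deriv-type TMS --registry parents.tsv \
               --out curated.msp --report report.json --snapshots snaps/
silylib convert --from msp --to mgf --in curated.msp --out curated.mgf
silylib background --in curated.msp --out flagged.msp
silylib fixtures --out registry_dump/
```

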