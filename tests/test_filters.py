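import random

import pytest

import silylib as s
from silylib import (FailureCode, FilterConfig, Peak, Spectrum,
                     annotate_background, apply_step, check_acquisition_range,
                     check_min_peaks, check_molecular_ion_and_isotope,
                     check_silyl_markers, curate, validate_metadata)
from silylib.io import LibraryFile

import oracles


def spectrum(pairs, **meta):
    return Spectrum(peaks=tuple(Peak(m, i) for m, i in pairs), **meta)


GOOD_KEY = "AAAAAAAAAAAAAA-BBBBBBBBBB-N"


class TestValidateMetadata:
    def consistent(self):
        return spectrum([(73, 1)], name="benzoic acid TMS", formula="C10H14O2Si",
                        inchikey=GOOD_KEY, mw=194.0)

    def test_consistent_record_yields_no_findings(self):
        assert validate_metadata(self.consistent(), "TMS") == []

    def test_formula_without_silicon(self):
        sp = self.consistent()
        sp.formula = "C12H18O2"  # same nominal mass, Si swapped for C2H4
        codes = [f.code for f in validate_metadata(sp, "TMS")]
        assert codes == [FailureCode.META_FORMULA_NO_SI]

    def test_malformed_inchikey(self):
        sp = self.consistent()
        sp.inchikey = "NOTAKEY"
        codes = [f.code for f in validate_metadata(sp, "TMS")]
        assert codes == [FailureCode.META_BAD_INCHIKEY]

    def test_name_must_carry_the_silyl_token(self):
        sp = self.consistent()
        sp.name = "benzoic acid"
        assert [f.code for f in validate_metadata(sp, "TMS")] == \
               [FailureCode.META_NAME_MISMATCH]
        # a TBDMS run expects the TBDMS token
        assert FailureCode.META_NAME_MISMATCH in \
               [f.code for f in validate_metadata(self.consistent(), "TBDMS")]

    def test_formula_mass_consistency_window_is_one_amu(self):
        sp = self.consistent()
        sp.mw = 194.9  # nominal mass of C10H14O2Si is 194
        assert validate_metadata(sp, "TMS") == []
        sp.mw = 196.0
        assert [f.code for f in validate_metadata(sp, "TMS")] == \
               [FailureCode.META_MASS_INCONSISTENT]

    def test_multiple_findings_accumulate(self):
        sp = spectrum([(73, 1)], name="benzoic acid", formula="C7H6O2",
                      inchikey="NOTAKEY", mw=122.0)
        codes = {f.code for f in validate_metadata(sp, "TMS")}
        assert codes == {FailureCode.META_NAME_MISMATCH,
                         FailureCode.META_FORMULA_NO_SI,
                         FailureCode.META_BAD_INCHIKEY}


class TestAcquisitionRange:
    def test_upper_mz_below_mw_plus_margin_fails(self, default_config):
        sp = spectrum([(100, 1)], mw=400.0, acquisition_upper_mz=405.0)
        assert not check_acquisition_range(sp, default_config)

    def test_boundary_is_inclusive(self, default_config):
        sp = spectrum([(100, 1)], mw=400.0, acquisition_upper_mz=410.0)
        assert check_acquisition_range(sp, default_config)

    def test_proxy_mode_uses_highest_observed_peak(self, default_config):
        sp = spectrum([(100, 1), (400.0, 2)], mw=400.0)
        result = check_acquisition_range(sp, default_config)
        assert result.passed and result.used_proxy
        low = spectrum([(100, 1), (380, 2)], mw=400.0)
        result = check_acquisition_range(low, default_config)
        assert not result.passed and result.used_proxy

    def test_missing_mw_fails_with_detail(self, default_config):
        result = check_acquisition_range(spectrum([(100, 1)]), default_config)
        assert not result.passed
        assert "Mw unknown" in result.finding.detail


class TestMolecularIonAndIsotope:
    def test_molecular_ion_plus_c13_passes(self, default_config):
        assert check_molecular_ion_and_isotope(
            spectrum([(416, 10), (417, 3)], mw=416.0), default_config)

    def test_molecular_ion_alone_fails_on_isotope_clause(self, default_config):
        result = check_molecular_ion_and_isotope(
            spectrum([(416, 10)], mw=416.0), default_config)
        assert not result.passed
        assert result.finding.code == FailureCode.QUAL_ISOTOPE

    def test_m_plus_two_satellite_accepted(self, default_config):
        assert check_molecular_ion_and_isotope(
            spectrum([(416, 10), (418, 1)], mw=416.0), default_config)

    def test_missing_molecular_ion_fails_first_clause(self, default_config):
        result = check_molecular_ion_and_isotope(
            spectrum([(100, 10), (417, 3)], mw=416.0), default_config)
        assert result.finding.code == FailureCode.QUAL_MOLION


class TestSilylMarkers:
    def test_tms_spectrum_with_73_passes(self, default_config):
        assert check_silyl_markers(spectrum([(73, 5)]), "TMS", default_config)

    def test_tbdms_marker_does_not_rescue_a_tms_spectrum(self, default_config):
        assert not check_silyl_markers(spectrum([(115, 5)]), "TMS", default_config)
        assert check_silyl_markers(spectrum([(115, 5)]), "TBDMS", default_config)

    def test_tolerance_window_is_half_amu(self, default_config):
        assert check_silyl_markers(spectrum([(147.4, 1)]), "TMS", default_config)
        assert not check_silyl_markers(spectrum([(147.6, 1)]), "TMS", default_config)


class TestMinPeaks:
    @pytest.mark.parametrize("n,passes", [(5, True), (4, False), (0, False)])
    def test_five_peak_floor(self, n, passes, default_config):
        sp = spectrum([(60 + i, 1) for i in range(n)])
        assert bool(check_min_peaks(sp, default_config)) is passes


class TestApplySteps:
    def test_step2_excludes_at_exactly_the_cutoff(self, default_config):
        records = [spectrum([(73, 1)], name=f"m{m} TMS", mw=m)
                   for m in (999.9, 1000.0, 650.0)]
        kept, excluded = apply_step(records, 2, default_config, "TMS")
        assert [r.mw for r in kept] == [999.9, 650.0]
        assert [r.mw for r, _ in excluded] == [1000.0]
        assert excluded[0][1][0].code == FailureCode.MASS_CUTOFF

    def test_step3_single_cause_attribution(self, default_config):
        sp = spectrum([(416, 10), (417, 2), (60, 1), (61, 1), (62, 1)],
                      mw=416.0, acquisition_upper_mz=426.0)
        kept, excluded = apply_step([sp], 3, default_config, "TMS")
        assert kept == []
        assert [f.code for f in excluded[0][1]] == [FailureCode.QUAL_MARKER]

    def test_empty_input(self, default_config):
        assert apply_step([], 1, default_config, "TMS") == ([], [])

    def test_unknown_step_rejected(self, default_config):
        with pytest.raises(ValueError):
            apply_step([], 4, default_config, "TMS")

    def test_step1_unresolved_parent_kept_with_warning(self, default_config):
        sp = spectrum([(73, 1)], name="orphan TMS", inchikey=GOOD_KEY)
        warnings = []
        kept, excluded = apply_step([sp], 1, default_config, "TMS",
                                    registry=[], warnings=warnings)
        assert kept == [sp] and excluded == []
        assert warnings and "unresolved" in warnings[0]

    def test_step1_unresolved_parent_excluded_when_configured(self):
        config = FilterConfig(unresolved_structure="exclude")
        sp = spectrum([(73, 1)], name="orphan TMS", inchikey=GOOD_KEY)
        kept, excluded = apply_step([sp], 1, config, "TMS", registry=[])
        assert kept == []
        assert excluded[0][1][0].code == FailureCode.CHEM_NOT_AMENABLE


def library_with_known_failures(seed=5, deriv_type="TMS"):
    spec = s.GenerationSpec(n_pass=12, n_fail_metadata=4, n_fail_chemistry=3,
                            n_fail_mass=2, n_fail_range=3, n_fail_molion=2,
                            n_fail_isotope=2, n_fail_marker=3, n_fail_minpeaks=2,
                            deriv_type=deriv_type, seed=seed)
    return s.generate_library(spec)


class TestCurate:
    def test_already_clean_library_is_a_fixed_point(self):
        spec = s.GenerationSpec(n_pass=8, deriv_type="TMS", seed=2)
        lib, truth = s.generate_library(spec)
        result = curate(lib, "TMS", registry=truth.registry)
        assert result.report.excluded == 0
        assert [r.name for r in result.curated.records] == \
               [r.name for r in lib.records]

    def test_report_equals_generator_ground_truth(self):
        lib, truth = library_with_known_failures()
        report = curate(lib, "TMS", registry=truth.registry).report
        assert report.step0_metadata_excluded == truth.step0_metadata
        assert report.step1_chemistry_excluded == truth.step1_chemistry
        assert report.step2_mass_excluded == truth.step2_mass
        assert report.step3_quality_excluded == truth.step3_quality
        assert report.retained == truth.retained

    def test_every_excluded_record_carries_the_expected_code(self):
        lib, truth = library_with_known_failures(seed=6)
        report = curate(lib, "TMS", registry=truth.registry).report
        got = {key.split(":", 1)[-1]: codes
               for key, codes in report.per_spectrum_reasons.items()}
        assert got == truth.expected_codes

    def test_curation_is_idempotent(self):
        lib, truth = library_with_known_failures(seed=7)
        first = curate(lib, "TMS", registry=truth.registry)
        second = curate(first.curated, "TMS", registry=truth.registry)
        assert second.report.excluded == 0
        assert second.report.retained == first.report.retained

    def test_conservation_every_record_kept_or_explained(self):
        lib, truth = library_with_known_failures(seed=8)
        result = curate(lib, "TMS", registry=truth.registry)
        assert (len(result.curated.records)
                + len(result.report.per_spectrum_reasons)) == len(lib.records)

    def test_short_circuit_attributes_to_the_earliest_failing_step(self):
        # a chemistry failure whose marker peak is also missing is charged
        # to step 1 only
        rng = random.Random(3)
        sp = s.generate_failing_spectrum("TMS", FailureCode.QUAL_MARKER, rng)
        sp.annotations["parent_amenable"] = False
        from silylib.synth import _parent_record
        registry = [_parent_record(sp, amenable=False)]
        lib = LibraryFile(format="MSP", records=[sp])
        report = curate(lib, "TMS", registry=registry).report
        codes = list(report.per_spectrum_reasons.values())
        assert codes == [["CHEM_NOT_AMENABLE"]]
        assert report.step3_quality_excluded == 0

    def test_skip_steps_pass_records_through(self):
        lib, truth = library_with_known_failures(seed=9)
        config = FilterConfig(skip_steps=(1,))
        report = curate(lib, "TMS", registry=truth.registry, config=config).report
        assert report.step1_chemistry_excluded == 0
        assert report.retained == truth.retained + truth.step1_chemistry

    def test_snapshots_mirror_the_dataset_version_lineage(self):
        lib, truth = library_with_known_failures(seed=10)
        result = curate(lib, "TMS", registry=truth.registry, keep_snapshots=True)
        rep = result.report
        sizes = {label: len(libf.records) for label, libf in result.snapshots.items()}
        after_step1 = (rep.input_count - rep.step0_metadata_excluded
                       - rep.step1_chemistry_excluded)
        assert sizes == {"TMS_0.1": rep.input_count,
                         "TMS_1.3": after_step1,
                         "TMS_2.3": after_step1 - rep.step2_mass_excluded,
                         "TMS_3.3": rep.retained}

    @pytest.mark.parametrize("loosen", [
        dict(min_peaks=3), dict(mass_cutoff=1500.0), dict(mz_tolerance=0.9),
        dict(acquisition_margin=5.0)])
    def test_loosening_thresholds_never_decreases_retention(self, loosen):
        lib, truth = library_with_known_failures(seed=11)
        base = curate(lib, "TMS", registry=truth.registry).report.retained
        loosened = curate(lib, "TMS", registry=truth.registry,
                          config=FilterConfig(**loosen)).report.retained
        assert loosened >= base

    @pytest.mark.parametrize("deriv_type,seed", [("TMS", 21), ("TBDMS", 22)])
    def test_pipeline_agrees_with_brute_force_rules(self, deriv_type, seed):
        lib, truth = library_with_known_failures(seed=seed, deriv_type=deriv_type)
        assert len(lib.records) <= 50
        result = curate(lib, deriv_type, registry=truth.registry)
        expected = oracles.kept_names(lib, deriv_type, truth.registry)
        assert [r.name for r in result.curated.records] == expected


class TestBackgroundAnnotation:
    def test_polysiloxane_ion_flagged(self):
        sp = spectrum([(207, 10), (100, 1)])
        out = annotate_background(sp)
        assert out.annotations["background"][0]["label"] == "polysiloxane"
        assert out.num_peaks == 2  # annotation never deletes

    def test_clean_spectrum_unchanged(self):
        sp = spectrum([(101, 1), (313, 2)])
        out = annotate_background(sp)
        assert "background" not in out.annotations
        assert out.peaks == sp.peaks

    def test_subtract_mode_can_drop_below_the_min_peak_floor(self, default_config):
        sp = spectrum([(149, 1), (207, 1), (60, 1), (61, 1), (62, 1)])
        assert check_min_peaks(sp, default_config)
        out = annotate_background(sp, subtract=True)
        assert out.num_peaks == 3
        assert not check_min_peaks(out, default_config)
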