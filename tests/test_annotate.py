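"""Annotation engine: decomposition, fragment explanation, UV rule, reports."""

import itertools

import numpy as np
import pytest

from anthonet.annotate import (
    AnnotationParams,
    Spectrum,
    UVRecord,
    annotate_dataset,
    annotate_spectrum,
    classify_uv,
    decompose_precursor,
    detect_aglycone,
    explain_fragments,
)
from anthonet.masscalc import cation_mass, compose, loss_mass
from anthonet.reference import REFERENCE_PEAKS, reference_spectra


def brute_force_decompositions(mz, library, params):
    """Independent exhaustive enumeration over the bounded composition lattice.

    Uses the package's block masses (separately validated against an
    independent elemental-mass table) but its own enumeration and filtering
    logic, written before the production bisect-based search.
    """
    glycosyls = sorted(b.id for b in library.glycosyls())
    acyls = sorted(b.id for b in library.acyls())
    hits = set()
    for aglycone in library.aglycones():
        for n_gly in range(params.max_glycosyl + 1):
            for gly in itertools.combinations_with_replacement(glycosyls, n_gly):
                for n_acyl in range(params.max_acyl + 1):
                    for acyl in itertools.combinations_with_replacement(acyls, n_acyl):
                        total = aglycone.residue_mass + sum(
                            library[b].residue_mass for b in gly + acyl
                        )
                        theoretical = total - 0.00054857990907
                        if abs(theoretical - mz) <= mz * params.precursor_tol_ppm * 1e-6:
                            hits.add((aglycone.id, tuple(sorted(gly + acyl))))
    return hits


class TestDecomposePrecursor:
    def test_diglucoside_has_one_pelargonidin_candidate(self, library, params):
        candidates = decompose_precursor(595.16516, library, params)
        pel = [c for c in candidates if c.aglycone_id == "pelargonidin"]
        assert len(pel) == 1
        assert pel[0].decorations == ("hexose", "hexose")

    def test_aglycone_mass_yields_bare_pelargonidin(self, library, params):
        candidates = decompose_precursor(271.06008, library, params)
        assert [c.sort_key() for c in candidates] == [("pelargonidin", ())]

    def test_below_any_aglycone_mass_is_empty(self, library, params):
        assert decompose_precursor(100.0, library, params) == []

    def test_matches_brute_force_oracle_on_random_masses(self, library, params):
        rng = np.random.default_rng(7)
        for mz in rng.uniform(250.0, 1200.0, size=200):
            got = {(c.aglycone_id, c.decorations)
                   for c in decompose_precursor(mz, library, params)}
            assert got == brute_force_decompositions(mz, library, params), mz

    def test_every_candidate_is_sound(self, library, params):
        rng = np.random.default_rng(11)
        for mz in rng.uniform(250.0, 1200.0, size=50):
            for c in decompose_precursor(mz, library, params):
                assert abs(c.cation_mz - mz) / mz * 1e6 <= params.precursor_tol_ppm

    def test_widening_tolerance_never_removes_candidates(self, library):
        rng = np.random.default_rng(3)
        for mz in rng.uniform(250.0, 1200.0, size=30):
            tight = decompose_precursor(mz, library, AnnotationParams(precursor_tol_ppm=3))
            loose = decompose_precursor(mz, library, AnnotationParams(precursor_tol_ppm=12))
            assert {c.sort_key() for c in tight} <= {c.sort_key() for c in loose}

    def test_deterministic_order(self, library, params):
        a = decompose_precursor(595.16516, library, params)
        b = decompose_precursor(595.16516, library, params)
        assert [c.sort_key() for c in a] == [c.sort_key() for c in b]


class TestExplainFragments:
    def test_published_triglycoside_walkthrough(self, library, params):
        # precursor 741.22180 -> losses: one hexose; hexose+deoxyhexose
        # (rutinoside-scale loss); all decorations (aglycone ion).
        comp = compose("pelargonidin", ["hexose", "hexose", "deoxyhexose"], library)
        expl = explain_fragments(
            comp, (579.16992, 433.11237, 271.05966), library, params
        )
        assert [e.kind for e in expl] == ["loss", "loss", "loss"]
        assert expl[0].loss == ("hexose",)
        assert expl[1].loss == ("deoxyhexose", "hexose")
        assert expl[2].loss == ("deoxyhexose", "hexose", "hexose")

    def test_free_deoxyhexose_residue_ion(self, library, params):
        comp = compose("pelargonidin", ["hexose", "deoxyhexose"], library)
        expl = explain_fragments(comp, (146.05790,), library, params)
        assert expl[0].kind == "residue_ion"
        assert expl[0].residue_id == "deoxyhexose"

    def test_undecorated_composition_explains_nothing_but_itself(self, library, params):
        comp = compose("pelargonidin", [], library)
        expl = explain_fragments(comp, (100.0, 200.0), library, params)
        assert all(e.kind == "unexplained" for e in expl)


class TestDetectAglycone:
    @pytest.mark.parametrize(
        "fragments, expected",
        [
            ((271.05972,), "pelargonidin"),
            ((287.0550,), "cyanidin"),  # cyanidin cation, one more oxygen
            ((100.0, 200.0), None),
        ],
    )
    def test_diagnostic_ion(self, library, params, fragments, expected):
        assert detect_aglycone(fragments, library, params) == expected

    def test_closest_aglycone_wins(self, library, params):
        # both pelargonidin and cyanidin ions present; cyanidin closer
        result = detect_aglycone((271.0650, 287.0550), library, params)
        assert result == "cyanidin"


class TestClassifyUV:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(52.0, "3-glycoside"), (25.0, "3,5-glycoside"), (35.0, "ambiguous")],
    )
    def test_published_exemplars_and_ambiguous_band(self, ratio, expected):
        assert classify_uv(UVRecord(lambda_max=(498.0,), e440_over_emax=ratio)) == expected

    def test_missing_record_is_absent(self):
        assert classify_uv(None) == "absent"
        assert classify_uv(UVRecord(lambda_max=(498.0,))) == "absent"

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            UVRecord(lambda_max=(498.0,), e440_over_emax=120.0)

    def test_out_of_range_wavelength_rejected(self):
        with pytest.raises(ValueError, match="lambda_max"):
            UVRecord(lambda_max=(150.0,))


class TestAnnotateSpectrum:
    def test_diglucoside_spectrum_fully_explained(self, library, params):
        spectrum = Spectrum(
            "peak2", 595.16516, ((433.11273, 100.0), (271.05972, 90.0)),
            uv=UVRecord(lambda_max=(282.0, 497.0), e440_over_emax=25.0),
        )
        ann = annotate_spectrum(spectrum, library, params)
        top = ann.top_candidate
        assert top.composition.aglycone_id == "pelargonidin"
        assert top.composition.decorations == ("hexose", "hexose")
        assert top.fragments_explained_fraction == 1.0
        assert ann.aglycone_detected == "pelargonidin"
        assert ann.uv_class == "3,5-glycoside"

    def test_inconsistent_precursor_falls_back_to_class_only(self, library, params):
        # published peak 5: precursor ~1 Da off its own formula
        spectrum = Spectrum(
            "peak5", 1094.29358,
            tuple((mz, 50.0) for mz in (932.23883, 771.21368, 433.11273, 271.06000)),
        )
        ann = annotate_spectrum(spectrum, library, params)
        assert ann.candidates == ()
        assert ann.aglycone_detected == "pelargonidin"
        assert ann.is_class_only

    def test_bare_aglycone_precursor_without_fragments(self, library, params):
        mz = cation_mass(compose("pelargonidin", [], library).total_formula)
        ann = annotate_spectrum(Spectrum("agl", mz), library, params)
        top = ann.top_candidate
        assert top.composition.decorations == ()
        assert top.fragments_explained_fraction == 1.0


class TestAnnotateDataset:
    def test_all_reference_peaks_are_pelargonidin_type(self, library, params):
        annotations, summary = annotate_dataset(reference_spectra(), library, params)
        assert summary.n_spectra == len(REFERENCE_PEAKS) == 11
        assert summary.per_aglycone == {"pelargonidin": 11}
        assert all(a.aglycone_detected == "pelargonidin" for a in annotations)
        assert summary.n_unidentified == 0

    def test_inconsistent_reference_peaks_are_class_only(self, library, params):
        annotations, summary = annotate_dataset(reference_spectra(), library, params)
        by_id = {a.spectrum_id: a for a in annotations}
        for peak in REFERENCE_PEAKS:
            ann = by_id[f"peak{peak.peak}"]
            if peak.decomposable:
                assert ann.top_candidate is not None, peak.peak
            else:
                assert ann.is_class_only, peak.peak
        assert summary.n_class_only == sum(
            1 for p in REFERENCE_PEAKS if not p.decomposable
        )

    def test_empty_input(self, library, params):
        annotations, summary = annotate_dataset([], library, params)
        assert annotations == [] and summary.n_spectra == 0

    def test_duplicate_ids_rejected(self, library, params):
        spectra = [Spectrum("a", 300.0), Spectrum("a", 400.0)]
        with pytest.raises(ValueError, match="duplicate"):
            annotate_dataset(spectra, library, params)


class TestSpectrumInvariants:
    def test_fragment_above_precursor_rejected(self):
        with pytest.raises(ValueError, match="exceeds precursor"):
            Spectrum("s", 300.0, ((301.0, 1.0),))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            Spectrum("s", 300.0, ((200.0, -1.0),))
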