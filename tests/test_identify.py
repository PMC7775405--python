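"""Precursor matching at ppm tolerance and diagnostic-ion validation."""

import numpy as np
import pytest

from glycoprofiler.glycans import (
    Peptide,
    build_candidate_table,
    glycoform_catalog,
)
from glycoprofiler.identify import (
    GLCNAC_OXONIUM_PANEL,
    NEU5AC_REPORTER_PANEL,
    SearchConfig,
    match_precursors,
    ppm_error,
    search_spectra,
    validate_diagnostics,
)
from glycoprofiler.simulate import (
    FIXTURES,
    NoiseModel,
    generate_glyco_run,
    reporter_glycopeptides,
)
from glycoprofiler.spectra import Ms2Spectrum


def brute_force_matches(spectra, candidates, config):
    """Independent O(n*m) oracle: exhaustive pairwise ppm comparison."""
    found = set()
    for s in spectra:
        charges = (s.precursor_charge,) if s.precursor_charge else config.charges
        for ci, cand in enumerate(candidates):
            for z in charges:
                if abs(ppm_error(s.precursor_mz, cand.mz(z))) <= config.precursor_tolerance_ppm:
                    found.add((s.raw_file, s.scan, ci, z))
        # candidate identity by index to keep the oracle free of package types
    return found


def _ms2(mz_list, precursor, charge=2, scan=1, intensities=None):
    mz = np.array(mz_list, dtype=float)
    inten = np.asarray(intensities, dtype=float) if intensities is not None \
        else np.full(len(mz), 100.0)
    return Ms2Spectrum("run", scan, 10.0 * scan, precursor, charge, mz, inten)


@pytest.fixture(scope="module")
def small_candidates():
    return build_candidate_table(
        [Peptide("LNDTFSAK"), Peptide("VVNHTEFLK")], glycoform_catalog()
    )


class TestPpmError:
    def test_zero_when_equal(self):
        assert ppm_error(1000.0, 1000.0) == 0.0

    def test_signed_values(self):
        assert ppm_error(1000.005, 1000.0) == pytest.approx(5.0)
        assert ppm_error(999.990, 1000.0) == pytest.approx(-10.0)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(1000.0, 0.0)


class TestMatchPrecursors:
    def test_exact_hit_single_match(self, small_candidates):
        cand = small_candidates[0]
        spec = _ms2([204.087], cand.mz(2), charge=2)
        matches = match_precursors([spec], small_candidates)
        assert len(matches) == 1
        assert matches[0].mass_error_ppm == 0.0
        assert matches[0].candidate.glycoform.code == cand.glycoform.code

    def test_ten_ppm_away_not_matched(self, small_candidates):
        cand = small_candidates[0]
        spec = _ms2([204.087], cand.mz(2) * (1 + 10e-6), charge=2)
        assert match_precursors([spec], small_candidates) == []

    def test_unknown_charge_tries_configured_range(self, small_candidates):
        cand = small_candidates[0]
        spec = _ms2([204.087], cand.mz(3), charge=None)
        matches = match_precursors([spec], small_candidates)
        assert {m.charge for m in matches} == {3}

    def test_empty_candidate_table_rejected(self):
        with pytest.raises(ValueError):
            match_precursors([], [])

    def test_equivalence_with_brute_force_oracle(self, small_candidates):
        rng = np.random.default_rng(42)
        mz_pool = np.array([c.mz(z) for c in small_candidates for z in (2, 3, 4)])
        spectra = []
        for i in range(200):
            if rng.random() < 0.5:
                base = float(rng.choice(mz_pool))
                prec = base * (1 + rng.normal(0, 4e-6))  # near a candidate
            else:
                prec = float(rng.uniform(400, 2500))
            charge = int(rng.choice([0, 2, 3, 4]))
            spectra.append(_ms2([204.087], prec, charge or None, scan=i + 1))
        config = SearchConfig()
        fast = {
            (m.raw_file, m.scan, small_candidates.index(m.candidate), m.charge)
            for m in match_precursors(spectra, small_candidates, config)
        }
        assert fast == brute_force_matches(spectra, small_candidates, config)

    def test_tolerance_monotonicity(self, small_candidates):
        rng = np.random.default_rng(3)
        spectra = [
            _ms2([204.087], c.mz(2) * (1 + rng.normal(0, 6e-6)), 2, scan=i + 1)
            for i, c in enumerate(small_candidates[:40])
        ]
        tight = match_precursors(spectra, small_candidates,
                                 SearchConfig(precursor_tolerance_ppm=5))
        loose = match_precursors(spectra, small_candidates,
                                 SearchConfig(precursor_tolerance_ppm=10))
        key = lambda m: (m.scan, m.candidate.glycoform.code,
                         m.candidate.peptide.sequence, m.charge)
        assert {key(m) for m in tight} <= {key(m) for m in loose}


class TestValidateDiagnostics:
    def _match(self, candidates, code, spec):
        cand = next(c for c in candidates if c.glycoform.code == code)
        [m] = match_precursors([spec], [cand])
        return m

    def test_two_diagnostics_validate_neutral_glycoform(self, small_candidates):
        cand = next(c for c in small_candidates if c.glycoform.code == "GnGn")
        spec = _ms2([204.087, 366.139], cand.mz(2))
        m = validate_diagnostics(self._match(small_candidates, "GnGn", spec), spec)
        assert m.status == "validated"
        assert len(m.matched_ions) == 2

    def test_no_diagnostics_rejected(self, small_candidates):
        cand = next(c for c in small_candidates if c.glycoform.code == "GnGn")
        spec = _ms2([500.0, 600.0], cand.mz(2))
        m = validate_diagnostics(self._match(small_candidates, "GnGn", spec), spec)
        assert m.status == "rejected"
        assert "diagnostic" in m.rejection_reason

    def test_sialylated_requires_both_reporters(self, small_candidates):
        cand = next(c for c in small_candidates if c.glycoform.code == "NaM")
        spec = _ms2([204.087, 366.139, 292.103], cand.mz(2))  # 274.092 absent
        m = validate_diagnostics(self._match(small_candidates, "NaM", spec), spec)
        assert m.status == "rejected"
        spec_ok = _ms2([204.087, 366.139, 292.103, 274.092], cand.mz(2))
        m_ok = validate_diagnostics(self._match(small_candidates, "NaM", spec_ok), spec_ok)
        assert m_ok.status == "validated"

    def test_single_reporter_allowed_when_configured(self, small_candidates):
        config = SearchConfig(require_both_neu5ac_reporters=False)
        cand = next(c for c in small_candidates if c.glycoform.code == "NaM")
        spec = _ms2([204.087, 366.139, 292.103], cand.mz(2))
        m = validate_diagnostics(self._match(small_candidates, "NaM", spec), spec, config)
        assert m.status == "validated"

    def test_fragment_tolerance_boundary(self, small_candidates):
        cand = next(c for c in small_candidates if c.glycoform.code == "GnGn")
        spec = _ms2([204.087 + 0.019, 366.139 + 0.019], cand.mz(2))
        m = validate_diagnostics(self._match(small_candidates, "GnGn", spec), spec)
        assert m.status == "validated"
        spec_far = _ms2([204.087 + 0.03, 366.139 + 0.03], cand.mz(2))
        m2 = validate_diagnostics(self._match(small_candidates, "GnGn", spec_far), spec_far)
        assert m2.status == "rejected"


class TestSearchEndToEnd:
    def test_empty_input(self, small_candidates):
        matches, audit = search_spectra([], small_candidates)
        assert matches == [] and audit == []

    def test_zero_noise_run_full_recovery(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        candidates = build_candidate_table(reporter_glycopeptides(), glycoform_catalog())
        validated, audit = search_spectra(run.spectra, candidates)
        got = {(m.candidate.peptide.sequence, m.candidate.glycoform.code, m.scan)
               for m in validated}
        expected = {(r.peptide, r.glycoform, r.scan)
                    for r in run.truth.itertuples()}
        assert got == expected  # every planted glycopeptide, nothing else
        assert audit == []

    def test_decoy_spectra_all_rejected_or_unmatched(self):
        run = generate_glyco_run(
            FIXTURES["ftst78"],
            noise=NoiseModel(decoy_spectra=100),
            seed=11,
        )
        candidates = build_candidate_table(reporter_glycopeptides(), glycoform_catalog())
        validated, _ = search_spectra(run.spectra, candidates)
        planted_scans = set(run.truth["scan"])
        assert all(m.scan in planted_scans for m in validated)

    def test_no_validated_sialylated_match_without_both_reporters(
        self, ftst78_noisy_run
    ):
        candidates = build_candidate_table(reporter_glycopeptides(), glycoform_catalog())
        validated, _ = search_spectra(ftst78_noisy_run.spectra, candidates)
        by_scan = {s.scan: s for s in ftst78_noisy_run.spectra}
        sialylated = [m for m in validated if m.candidate.glycoform.is_sialylated]
        assert sialylated  # the fixture plants NaM and NaGn
        for m in sialylated:
            spec = by_scan[m.scan]
            for reporter in NEU5AC_REPORTER_PANEL:
                assert spec.has_peak_near(reporter, 0.02)
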