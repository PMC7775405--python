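"""EIC quantification, intensity-table joins and relative glycoform profiles."""

import math

import numpy as np
import pandas as pd
import pytest

from glycoprofiler.glycans import Peptide, build_candidate_table, parse_code
from glycoprofiler.identify import SearchConfig, search_spectra
from glycoprofiler.pipeline import profile_glyco_run
from glycoprofiler.quantify import (
    join_intensities,
    quantify_by_eic,
    relative_profile,
)
from glycoprofiler.simulate import (
    FIXTURES,
    GroundTruthProfile,
    NoiseModel,
    generate_glyco_run,
    reporter_glycopeptides,
)


def _areas(rows):
    return pd.DataFrame(rows, columns=["peptide", "glycoform", "area"])


class TestRelativeProfile:
    def test_two_equal_glycoforms_split_fifty_fifty(self):
        prof = relative_profile(_areas([("P1", "AM", 5.0), ("P1", "GnGn", 5.0)]))
        assert prof.percentage("AM") == 50.0
        assert prof.percentage("GnGn") == 50.0
        assert prof.n_glycopeptides == 1
        assert np.isnan(prof.summary["sd"]).all()  # SD undefined for n=1

    def test_single_glycoform_is_hundred(self):
        prof = relative_profile(_areas([("P1", "AM", 3.0)]))
        assert prof.percentage("AM") == 100.0

    def test_pooled_mean_and_sd_of_two_peptides(self):
        # equal totals; glycoform shares 10% and 20% -> pooled 15%, SD 7.07
        areas = _areas(
            [
                ("P1", "NaM", 10.0),
                ("P1", "GnGn", 90.0),
                ("P2", "NaM", 20.0),
                ("P2", "GnGn", 80.0),
            ]
        )
        prof = relative_profile(areas)
        assert prof.percentage("NaM") == pytest.approx(15.0)
        sd = float(prof.summary.loc[prof.summary.glycoform == "NaM", "sd"].iloc[0])
        assert round(sd, 2) == 7.07

    def test_area_weighted_pooling_with_unequal_totals(self):
        areas = _areas(
            [
                ("P1", "NaM", 10.0),
                ("P1", "GnGn", 90.0),
                ("P2", "NaM", 60.0),
                ("P2", "GnGn", 240.0),
            ]
        )
        prof = relative_profile(areas)
        # grand-total ratio: (10+60)/400, not mean of 10% and 20%
        assert prof.percentage("NaM") == pytest.approx(17.5)

    def test_closure_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"P{i}", code, float(rng.uniform(0.1, 100)))
            for i in range(3)
            for code in ["MM", "GnGn", "AM", "NaM"]
        ]
        prof = relative_profile(_areas(rows))
        assert math.isclose(prof.summary["percentage"].sum(), 100.0, abs_tol=1e-9)
        scaled = relative_profile(
            _areas([(p, g, 17.3 * a) for p, g, a in rows])
        )
        pd.testing.assert_frame_equal(
            prof.summary.drop(columns="area"), scaled.summary.drop(columns="area")
        )

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            relative_profile(_areas([("P1", "AM", 0.0)]))


class TestQuantifyByEic:
    def test_zero_noise_recovery_matches_planted_ratios(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        prof = profile_glyco_run(run)
        for code, frac in run.profile.fractions.items():
            assert prof.percentage(code) == pytest.approx(100 * frac, abs=1e-6)

    def test_default_noise_recovery_within_one_percent_area(self):
        run = generate_glyco_run(FIXTURES["gmc_gt"], noise=NoiseModel(), seed=19)
        candidates = build_candidate_table(
            reporter_glycopeptides(), [parse_code(c) for c in run.profile.fractions]
        )
        validated, _ = search_spectra(run.spectra, candidates)
        areas = quantify_by_eic(run.run, validated)
        merged = areas.merge(run.truth, on=["peptide", "glycoform"])
        # recovered area / planted area constant across peaks to ~1% (the 5%
        # threshold truncates every Gaussian identically)
        ratio = merged["area_x"] / merged["area_y"]
        assert np.all(np.abs(ratio / ratio.mean() - 1) < 0.01)

    def test_two_charges_of_one_candidate_sum(self):
        profile = GroundTruthProfile("two", {"AM": 0.6, "GnGn": 0.4})
        run = generate_glyco_run(
            profile, noise=NoiseModel.zero(), seed=0, charges=(2, 3)
        )
        candidates = build_candidate_table(reporter_glycopeptides(),
                                           [parse_code("AM"), parse_code("GnGn")])
        validated, _ = search_spectra(run.spectra, candidates)
        assert {m.charge for m in validated} == {2, 3}
        areas = quantify_by_eic(run.run, validated)
        truth_sum = run.truth.groupby(["peptide", "glycoform"])["area"].sum().reset_index()
        merged = areas.merge(truth_sum, on=["peptide", "glycoform"])
        # both charge states contribute to one per-candidate area
        np.testing.assert_allclose(
            merged["area_x"], merged["area_y"] * (merged["area_x"] / merged["area_y"]).mean()
        )
        prof = relative_profile(areas)
        assert prof.percentage("AM") == pytest.approx(60.0, abs=1e-6)

    def test_unvalidated_matches_rejected(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        candidates = build_candidate_table(reporter_glycopeptides(),
                                           [parse_code("GnGn")])
        from glycoprofiler.identify import match_precursors

        raw = match_precursors(run.spectra, candidates)
        with pytest.raises(ValueError):
            quantify_by_eic(run.run, raw)


class TestJoinIntensities:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["Raw file", "Mass", "MS/MS scan number", "Intensity"]
        )

    def _validated(self, run, codes=None):
        from glycoprofiler.glycans import glycoform_catalog

        catalog = [parse_code(c) for c in codes] if codes else glycoform_catalog()
        candidates = build_candidate_table(reporter_glycopeptides(), catalog)
        validated, _ = search_spectra(run.spectra, candidates)
        return validated

    def test_exact_triple_match_returns_intensity(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        validated = self._validated(run, ["GnGn"])
        match = validated[0]
        table = self._table(
            [(match.raw_file, match.candidate.neutral_mass, match.scan, 1234.5)]
        )
        areas, unmatched = join_intensities([match], table)
        assert areas["area"].iloc[0] == 1234.5
        assert unmatched == []

    def test_mass_disagreement_unmatched(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        match = self._validated(run, ["GnGn"])[0]
        off_mass = match.candidate.neutral_mass * (1 + 50e-6)
        table = self._table([(match.raw_file, off_mass, match.scan, 1234.5)])
        areas, unmatched = join_intensities([match], table, mass_tolerance_ppm=10)
        assert len(areas) == 0 and unmatched == [match]

    def test_empty_table_all_unmatched(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        validated = self._validated(run, ["GnGn", "AM"])
        areas, unmatched = join_intensities(validated, self._table([]))
        assert len(areas) == 0 and len(unmatched) == len(validated)

    def test_duplicate_key_rejected(self, ftst78_zero_noise_run):
        match = self._validated(ftst78_zero_noise_run, ["GnGn"])[0]
        table = self._table(
            [
                (match.raw_file, match.candidate.neutral_mass, match.scan, 1.0),
                (match.raw_file, match.candidate.neutral_mass, match.scan, 2.0),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            join_intensities([match], table)

    def test_join_backend_reproduces_truth_profile(self, ftst78_zero_noise_run):
        run = ftst78_zero_noise_run
        validated = self._validated(run)
        table = self._table(
            [
                (run.run.raw_file,
                 row.mz * row.charge - row.charge * 1.007276,
                 row.scan,
                 row.area)
                for row in run.truth.itertuples()
            ]
        )
        areas, unmatched = join_intensities(validated, table)
        assert unmatched == []
        prof = relative_profile(areas)
        for code, frac in run.profile.fractions.items():
            assert prof.percentage(code) == pytest.approx(100 * frac, abs=1e-9)
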