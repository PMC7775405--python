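"""End-to-end composition: identify MS2 spectra, quantify EIC areas, profile."""

from __future__ import annotations

from .glycans import Peptide, build_candidate_table, glycoform_catalog
from .identify import SearchConfig, search_spectra
from .quantify import GlycoformProfile, quantify_by_eic, relative_profile
from .simulate import GlycoRun

__all__ = ["profile_glyco_run"]


def profile_glyco_run(
    glyco_run: GlycoRun,
    peptides: list[Peptide] | None = None,
    config: SearchConfig = SearchConfig(),
) -> GlycoformProfile:
    """Run the full identify -> quantify -> profile pipeline on one run.

    Candidates are built from the full glycoform catalog (not just the
    glycoforms present in the run), so the search is a genuine lookup, not a
    restatement of the generator's plan.
    """
    if peptides is None:
        from .simulate import reporter_glycopeptides

        peptides = reporter_glycopeptides()
    candidates = build_candidate_table(peptides, glycoform_catalog(), config.charges)
    validated, _ = search_spectra(glyco_run.spectra, candidates, config)
    areas = quantify_by_eic(glyco_run.run, validated, config)
    return relative_profile(areas)
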