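"""Glycopeptide identification: ppm precursor matching + diagnostic-ion validation.

The search mirrors the custom post-processing applied downstream of a standard
database search: theoretical glycopeptide precursor m/z values are matched to
MS2 precursors within +-5 ppm, and each precursor match is then validated on
the MS2 level (fragment tolerance 0.02 Da) by the presence of diagnostic
low-mass ions — the GlcNAc oxonium ladder (204.087 and its neutral-loss
satellites), the glycan fragments [GlcNAcHex]+ / [GlcNAcHex2]+, and, for
sialylated candidates, the Neu5Ac reporter pair 292.103 / 274.092.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chem import ElementalComposition, oxonium_mz
from .glycans import GlycopeptideCandidate
from .spectra import Ms2Spectrum, read_mgf

__all__ = [
    "SearchConfig",
    "GlycopeptideMatch",
    "ppm_error",
    "match_precursors",
    "validate_diagnostics",
    "search_run",
    "GLCNAC_OXONIUM_PANEL",
    "GLYCAN_FRAGMENT_PANEL",
    "NEU5AC_REPORTER_PANEL",
]


def _glcnac_panel() -> tuple[float, ...]:
    """The six GlcNAc-derived diagnostic oxonium ions (computed, not transcribed)."""
    hexnac = ["HexNAc"]
    return (
        oxonium_mz(hexnac),                                                     # 204.087
        oxonium_mz(hexnac, water_losses=1),                                     # 186.076
        oxonium_mz(hexnac, water_losses=2),                                     # 168.066
        oxonium_mz(hexnac, neutral_loss=ElementalComposition(C=2, H=4, O=2)),   # 144.065
        oxonium_mz(hexnac, neutral_loss=ElementalComposition(C=1, H=6, O=3)),   # 138.055
        oxonium_mz(hexnac, neutral_loss=ElementalComposition(C=2, H=6, O=3)),   # 126.055
    )


GLCNAC_OXONIUM_PANEL: tuple[float, ...] = _glcnac_panel()
GLYCAN_FRAGMENT_PANEL: tuple[float, ...] = (
    oxonium_mz(["HexNAc", "Hex"]),          # 366.139
    oxonium_mz(["HexNAc", "Hex", "Hex"]),   # 528.192
)
NEU5AC_REPORTER_PANEL: tuple[float, ...] = (
    oxonium_mz(["Neu5Ac"]),                 # 292.103
    oxonium_mz(["Neu5Ac"], water_losses=1), # 274.092
)


@dataclass(frozen=True)
class SearchConfig:
    """Tolerances and validation rules for the glycopeptide search."""

    precursor_tolerance_ppm: float = 5.0
    fragment_tolerance_da: float = 0.02
    glcnac_panel: tuple[float, ...] = GLCNAC_OXONIUM_PANEL
    glycan_fragment_panel: tuple[float, ...] = GLYCAN_FRAGMENT_PANEL
    neu5ac_panel: tuple[float, ...] = NEU5AC_REPORTER_PANEL
    min_diagnostic_hits: int = 2
    require_both_neu5ac_reporters: bool = True
    charges: tuple[int, ...] = (2, 3, 4)

    def __post_init__(self) -> None:
        if self.precursor_tolerance_ppm <= 0 or self.fragment_tolerance_da <= 0:
            raise ValueError("tolerances must be > 0")
        if self.min_diagnostic_hits < 1:
            raise ValueError("minimum diagnostic hits must be >= 1")


@dataclass(frozen=True)
class GlycopeptideMatch:
    """One (spectrum, candidate, charge) assignment with its validation state."""

    candidate: GlycopeptideCandidate
    charge: int
    raw_file: str
    scan: int
    rt: float
    observed_mz: float
    mass_error_ppm: float
    status: str = "precursor-only"  # {precursor-only, validated, rejected}
    matched_ions: tuple[tuple[float, float, float], ...] = ()  # (panel mz, obs mz, intensity)
    rejection_reason: str = ""
    ambiguous: bool = False


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def match_precursors(
    spectra: list[Ms2Spectrum],
    candidates: list[GlycopeptideCandidate],
    config: SearchConfig = SearchConfig(),
) -> list[GlycopeptideMatch]:
    """All (candidate, charge) pairs within the precursor tolerance of each spectrum.

    When a spectrum declares a precursor charge only that charge is tried;
    otherwise every charge in ``config.charges`` is considered. Implemented as
    a window lookup on per-charge sorted m/z tables — contractually identical
    to exhaustive pairwise comparison. Spectra matching more than one candidate
    are flagged ambiguous; disambiguation is left to quantification review.
    """
    if not candidates:
        raise ValueError("empty candidate table")
    tables = {}
    for z in set(config.charges) | {s.precursor_charge for s in spectra if s.precursor_charge}:
        mzs = np.array([c.mz(z) for c in candidates])
        order = np.argsort(mzs)
        tables[z] = (mzs[order], order)
    tol = config.precursor_tolerance_ppm * 1e-6
    matches: list[GlycopeptideMatch] = []
    for spectrum in spectra:
        charges = (
            (spectrum.precursor_charge,)
            if spectrum.precursor_charge
            else config.charges
        )
        found: list[GlycopeptideMatch] = []
        for z in charges:
            mzs, order = tables[z]
            # |obs - theo| <= tol * theo  <=>  theo in [obs/(1+tol), obs/(1-tol)]
            lo = np.searchsorted(mzs, spectrum.precursor_mz / (1 + tol), side="left")
            hi = np.searchsorted(mzs, spectrum.precursor_mz / (1 - tol), side="right")
            for k in range(lo, hi):
                cand = candidates[order[k]]
                found.append(
                    GlycopeptideMatch(
                        candidate=cand,
                        charge=z,
                        raw_file=spectrum.raw_file,
                        scan=spectrum.scan,
                        rt=spectrum.rt,
                        observed_mz=spectrum.precursor_mz,
                        mass_error_ppm=ppm_error(spectrum.precursor_mz, cand.mz(z)),
                    )
                )
        if len(found) > 1:
            found = [replace(m, ambiguous=True) for m in found]
        matches.extend(found)
    return matches


def _panel_hits(
    spectrum: Ms2Spectrum, panel: tuple[float, ...], tol_da: float
) -> list[tuple[float, float, float]]:
    hits = []
    for target in panel:
        diffs = np.abs(spectrum.mz - target)
        if len(diffs) and diffs.min() <= tol_da:
            j = int(np.argmin(diffs))
            hits.append((target, float(spectrum.mz[j]), float(spectrum.intensity[j])))
    return hits


def validate_diagnostics(
    match: GlycopeptideMatch,
    spectrum: Ms2Spectrum,
    config: SearchConfig = SearchConfig(),
) -> GlycopeptideMatch:
    """Validate or reject a precursor-only match on its MS2 diagnostic ions.

    Validated iff the union of GlcNAc-oxonium and glycan-fragment hits reaches
    ``min_diagnostic_hits`` and, for Neu5Ac-containing candidates, the Neu5Ac
    reporter rule holds (both reporters by default).
    """
    tol = config.fragment_tolerance_da
    general = _panel_hits(spectrum, config.glcnac_panel, tol) + _panel_hits(
        spectrum, config.glycan_fragment_panel, tol
    )
    sialo_hits = _panel_hits(spectrum, config.neu5ac_panel, tol)
    reason = ""
    if len(general) < config.min_diagnostic_hits:
        reason = (
            f"only {len(general)} diagnostic ions "
            f"(minimum {config.min_diagnostic_hits})"
        )
    elif match.candidate.glycoform.is_sialylated:
        needed = (
            len(config.neu5ac_panel) if config.require_both_neu5ac_reporters else 1
        )
        if len(sialo_hits) < needed:
            reason = (
                f"sialylated candidate lacks Neu5Ac reporters "
                f"({len(sialo_hits)}/{needed} present)"
            )
    status = "validated" if not reason else "rejected"
    return replace(
        match,
        status=status,
        matched_ions=tuple(general + sialo_hits),
        rejection_reason=reason,
    )


def search_run(
    mgf_path: str | Path,
    candidates: list[GlycopeptideCandidate],
    config: SearchConfig = SearchConfig(),
) -> tuple[list[GlycopeptideMatch], list[dict]]:
    """End-to-end search of one MGF: read, match precursors, validate.

    Returns validated matches sorted by (raw file, scan) and an audit log with
    one entry per rejection (reason included).
    """
    spectra = read_mgf(mgf_path)
    return search_spectra(spectra, candidates, config)


def search_spectra(
    spectra: list[Ms2Spectrum],
    candidates: list[GlycopeptideCandidate],
    config: SearchConfig = SearchConfig(),
) -> tuple[list[GlycopeptideMatch], list[dict]]:
    """As :func:`search_run` but on already-parsed spectra."""
    if not spectra:
        return [], []
    by_key = {(s.raw_file, s.scan): s for s in spectra}
    validated: list[GlycopeptideMatch] = []
    audit: list[dict] = []
    for match in match_precursors(spectra, candidates, config):
        checked = validate_diagnostics(match, by_key[(match.raw_file, match.scan)], config)
        if checked.status == "validated":
            validated.append(checked)
        else:
            audit.append(
                {
                    "raw_file": checked.raw_file,
                    "scan": checked.scan,
                    "peptide": checked.candidate.peptide.sequence,
                    "glycoform": checked.candidate.glycoform.code,
                    "charge": checked.charge,
                    "reason": checked.rejection_reason,
                }
            )
    validated.sort(key=lambda m: (m.raw_file, m.scan))
    return validated, audit
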