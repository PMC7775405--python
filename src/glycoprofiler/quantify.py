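"""Composition-resolved relative quantification of validated glycopeptides.

For each MS2-validated (candidate, charge) the MS1 extracted ion chromatogram
at the theoretical precursor m/z (+-5 ppm) is integrated over an automatic
window around the triggering MS2 retention time; areas of the same candidate
across charges are summed. Per glycopeptide, each glycoform's share of that
peptide's total area is computed; the pooled profile is area-weighted (total
glycoform area over the grand total), and the spread between glycopeptides is
reported as the sample standard deviation of the per-peptide percentages.

An alternative backend joins a search-engine intensity table (MaxQuant
allPeptides layout) on (raw file, MS2 scan, precursor mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .identify import GlycopeptideMatch, SearchConfig, ppm_error
from .spectra import Eic, Ms1Run, extract_eic, integrate_area, peak_window

__all__ = [
    "GlycoformProfile",
    "quantify_by_eic",
    "join_intensities",
    "relative_profile",
    "plot_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class GlycoformProfile:
    """Pooled relative glycoform percentages with inter-glycopeptide SD."""

    summary: pd.DataFrame        # glycoform, area, percentage, sd, n_peptides
    per_peptide: pd.DataFrame    # peptide x glycoform percentage matrix
    n_glycopeptides: int

    def percentage(self, glycoform_code: str) -> float:
        sel = self.summary.loc[self.summary["glycoform"] == glycoform_code, "percentage"]
        return float(sel.iloc[0]) if len(sel) else 0.0

    def family_percentage(self, glycoform_codes: list[str]) -> float:
        return float(
            self.summary.loc[
                self.summary["glycoform"].isin(glycoform_codes), "percentage"
            ].sum()
        )

    def sialylated_percentage(self) -> float:
        mask = self.summary["glycoform"].str.contains("Na")
        return float(self.summary.loc[mask, "percentage"].sum())


def quantify_by_eic(
    run: Ms1Run,
    matches: list[GlycopeptideMatch],
    config: SearchConfig = SearchConfig(),
    search_halfwidth: float = 30.0,
) -> pd.DataFrame:
    """Integrated EIC area per validated match, summed over charges.

    Returns a table with one row per (peptide, glycoform) and its summed area.
    A match whose MS2 retention time lies outside the run span contributes 0
    with a logged warning. Duplicate MS2 triggers of the same (candidate,
    charge) are integrated once (same chromatographic peak).
    """
    if any(m.status != "validated" for m in matches):
        raise ValueError("quantify_by_eic expects validated matches only")
    lo, hi = run.rt_span
    areas: dict[tuple[str, str], float] = {}
    seen: set[tuple[str, str, str, int]] = set()
    for match in matches:
        key = (
            match.candidate.peptide.sequence,
            match.candidate.glycoform.code,
            match.raw_file,
            match.charge,
        )
        if key in seen:
            continue
        seen.add(key)
        pep_gf = key[:2]
        if not (lo <= match.rt <= hi):
            logger.warning(
                "match RT %.1f s outside run span [%.1f, %.1f]; area set to 0",
                match.rt, lo, hi,
            )
            areas.setdefault(pep_gf, 0.0)
            continue
        eic = extract_eic(
            run,
            match.candidate.mz(match.charge),
            tolerance_ppm=config.precursor_tolerance_ppm,
        )
        start, end = peak_window(eic, around_rt=match.rt, search_halfwidth=search_halfwidth)
        area = integrate_area(eic, start, end + 1e-9)
        areas[pep_gf] = areas.get(pep_gf, 0.0) + area
    return pd.DataFrame(
        [(p, g, a) for (p, g), a in areas.items()],
        columns=["peptide", "glycoform", "area"],
    )


def join_intensities(
    matches: list[GlycopeptideMatch],
    table: pd.DataFrame,
    mass_tolerance_ppm: float = 10.0,
) -> tuple[pd.DataFrame, list[GlycopeptideMatch]]:
    """Intensity lookup by (raw file, MS2 scan, precursor mass) triple.

    ``table`` uses the MaxQuant allPeptides column names: "Raw file", "Mass",
    "MS/MS scan number", "Intensity". Returns the per-(peptide, glycoform)
    intensity table and the list of unmatched matches.
    """
    cols = {"Raw file", "Mass", "MS/MS scan number", "Intensity"}
    if not cols.issubset(table.columns):
        raise ValueError(f"intensity table must have columns {sorted(cols)}")
    keyed = table.set_index(["Raw file", "MS/MS scan number"], verify_integrity=False)
    if keyed.index.has_duplicates:
        raise ValueError("duplicate (raw file, scan) rows in intensity table")
    areas: dict[tuple[str, str], float] = {}
    unmatched: list[GlycopeptideMatch] = []
    for match in matches:
        key = (match.raw_file, match.scan)
        if key not in keyed.index:
            unmatched.append(match)
            continue
        row = keyed.loc[key]
        if abs(ppm_error(float(row["Mass"]), match.candidate.neutral_mass)) > mass_tolerance_ppm:
            unmatched.append(match)
            continue
        pep_gf = (match.candidate.peptide.sequence, match.candidate.glycoform.code)
        areas[pep_gf] = areas.get(pep_gf, 0.0) + float(row["Intensity"])
    frame = pd.DataFrame(
        [(p, g, a) for (p, g), a in areas.items()],
        columns=["peptide", "glycoform", "area"],
    )
    return frame, unmatched


def relative_profile(areas: pd.DataFrame) -> GlycoformProfile:
    """Relative glycoform percentages from per-(peptide, glycoform) areas.

    Per peptide, a glycoform's share is its area over that peptide's total
    (x100); the pooled percentage is area-weighted (glycoform total over grand
    total); the SD is the sample standard deviation (ddof=1) of the
    per-peptide percentages, defined only for >= 2 glycopeptides. Percentages
    sum to 100 exactly and are invariant to a common scaling of all areas.
    """
    required = {"peptide", "glycoform", "area"}
    if not required.issubset(areas.columns):
        raise ValueError(f"areas table must have columns {sorted(required)}")
    if areas.empty or not (areas["area"] > 0).any():
        raise ValueError("no positive areas to profile")
    if (areas["area"] < 0).any():
        raise ValueError("negative areas")
    matrix = (
        areas.pivot_table(index="peptide", columns="glycoform", values="area",
                          aggfunc="sum", fill_value=0.0)
    )
    totals = matrix.sum(axis=1)
    matrix = matrix.loc[totals > 0]
    per_pct = matrix.div(matrix.sum(axis=1), axis=0) * 100.0
    pooled = matrix.sum(axis=0) / matrix.to_numpy().sum() * 100.0
    n = len(matrix)
    sd = per_pct.std(axis=0, ddof=1) if n >= 2 else pd.Series(np.nan, index=pooled.index)
    summary = pd.DataFrame(
        {
            "glycoform": pooled.index,
            "area": matrix.sum(axis=0).to_numpy(),
            "percentage": pooled.to_numpy(),
            "sd": sd.to_numpy(),
            "n_peptides": n,
        }
    ).sort_values("percentage", ascending=False, ignore_index=True)
    return GlycoformProfile(summary=summary, per_peptide=per_pct, n_glycopeptides=n)


def plot_profile(profile: GlycoformProfile, ax=None, title: str = ""):
    """Bar chart of the pooled percentages with inter-peptide SD error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    s = profile.summary
    yerr = np.nan_to_num(s["sd"].to_numpy()) if profile.n_glycopeptides >= 2 else None
    ax.bar(s["glycoform"], s["percentage"], yerr=yerr, capsize=3, color="#4878a8")
    ax.set_ylabel("relative abundance (%)")
    ax.set_title(title)
    ax.tick_params(axis="x", rotation=45)
    return ax
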