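"""Seeded generators for every input the pipeline consumes.

No raw instrument data accompany the study design this package implements, so
each analysis stage is validated by parameter recovery: a generator plants a
known ground truth (glycoform area fractions, tissue concentrations, expression
ratios) into synthetic instrument files, and the corresponding pipeline stage
must recover it. All generators are deterministic for a given seed.

The chromatographic model is deliberately simple: monoisotopic centroids only,
Gaussian elution peaks (sigma 4 s) sampled on a fixed 1 s scan grid, no isotope
envelopes and no proteome background — the identification and EIC rules under
test operate on monoisotopic m/z, so nothing coarser is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, WATER_MASS, peptide_mass, AA_RESIDUES, monoisotopic_mass
from .glycans import (
    Glycoform,
    Peptide,
    build_candidate_table,
    glycoform_catalog,
    parse_code,
    tryptic_digest,
    REPORTER_SEQUENCE,
)
from .identify import (
    GLCNAC_OXONIUM_PANEL,
    GLYCAN_FRAGMENT_PANEL,
    NEU5AC_REPORTER_PANEL,
)
from .sialo import CMP_FRAGMENT_MZ, CMP_NEU5AC_MZ, CmpSampleInfo, HplcSampleInfo, TissueSample
from .spectra import Ms1Run, Ms2Spectrum, write_mgf, write_ms1_tsv

__all__ = [
    "GroundTruthProfile",
    "NoiseModel",
    "GlycoRun",
    "FIXTURES",
    "reporter_glycopeptides",
    "generate_glyco_run",
    "generate_cmp_pair",
    "generate_colorimetric_plate",
    "generate_ct_table",
]


@dataclass(frozen=True)
class GroundTruthProfile:
    """Glycoform code -> true fractional abundance (sums to 1)."""

    name: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.fractions.values()))
        if (vals < 0).any():
            raise ValueError("fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {vals.sum()}, not 1")
        for code in self.fractions:
            gf = parse_code(code)
            if gf.is_sialylated and gf.pent > 0:
                raise ValueError(f"{code}: pentoses never occur on sialylated glycans")

    @property
    def glycoforms(self) -> list[Glycoform]:
        return [parse_code(code) for code in self.fractions]

    def sialylated_fraction(self) -> float:
        return sum(f for c, f in self.fractions.items()
                   if parse_code(c).is_sialylated)


#: Packaged ground-truth fixtures.
#:
#: "ftst78" encodes the headline profile of a strongly sialyltransferase-
#: expressing line: 6.0% NaM + 0.3% NaGn (6.3% sialylated), 70.8% AM family,
#: 0.8% AGn, 11.3% biantennary galactosylation (AA), with the GnGn filler
#: (10.8%) being the derived complement of the stated shares. The intra-AM
#: pentose split 50/35/15 (none/one/two pentoses) is a package convention for
#: "almost half decorated with one or two pentoses".
#:
#: "gmc_gt" encodes a galactosylated-but-unsialylated line: GnGn-dominant
#: remainder, ~55% galactosylation, ~8% biantennary.
FIXTURES: dict[str, GroundTruthProfile] = {
    "ftst78": GroundTruthProfile(
        "ftst78",
        {
            "NaM": 0.060,
            "NaGn": 0.003,
            "AM": 0.3540,
            "AM+P": 0.2478,
            "AM+2P": 0.1062,
            "AGn": 0.008,
            "AA": 0.113,
            "GnGn": 0.108,
        },
    ),
    "gmc_gt": GroundTruthProfile(
        "gmc_gt",
        {
            "GnGn": 0.40,
            "GnM": 0.03,
            "MM": 0.02,
            "AM": 0.22,
            "AM+P": 0.15,
            "AM+2P": 0.07,
            "AGn": 0.03,
            "AA": 0.05,
            "AA+P": 0.03,
        },
    ),
}


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters for the synthetic instrument model.

    ``area_cv`` perturbs each planted peak area multiplicatively;
    ``mz_jitter_ppm`` shifts each planted precursor m/z; ``decoy_spectra``
    adds MS2 spectra with random precursors and no diagnostic ions. Identical
    seeds yield identical outputs.
    """

    peak_sigma_s: float = 4.0
    area_cv: float = 0.02
    mz_jitter_ppm: float = 1.0
    decoy_spectra: int = 0
    decoy_peaks: int = 8
    response_cv: float = 0.01  # plate/chromatogram detector noise
    ct_sigma: float = 0.2

    def __post_init__(self) -> None:
        if min(self.peak_sigma_s, self.area_cv, self.mz_jitter_ppm,
               self.response_cv, self.ct_sigma) < 0:
            raise ValueError("dispersions must be >= 0")

    @classmethod
    def zero(cls, peak_sigma_s: float = 4.0, decoy_spectra: int = 0) -> "NoiseModel":
        return cls(peak_sigma_s=peak_sigma_s, area_cv=0.0, mz_jitter_ppm=0.0,
                   decoy_spectra=decoy_spectra, response_cv=0.0, ct_sigma=0.0)


def reporter_glycopeptides() -> list[Peptide]:
    """The three sequon-bearing tryptic peptides of the packaged reporter."""
    return [p for p in tryptic_digest(REPORTER_SEQUENCE) if p.sequons]


@dataclass
class GlycoRun:
    """A synthetic glycopeptide LC-MS run with its ground-truth sidecar."""

    run: Ms1Run
    spectra: list[Ms2Spectrum]
    truth: pd.DataFrame
    profile: GroundTruthProfile

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mgf": out / f"{self.run.raw_file}.mgf",
            "ms1": out / f"{self.run.raw_file}.ms1.tsv",
            "truth": out / f"{self.run.raw_file}.truth.tsv",
        }
        write_mgf(self.spectra, paths["mgf"])
        write_ms1_tsv(self.run, paths["ms1"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
        return paths


def _backbone_ions(sequence: str) -> tuple[float, float]:
    """A b2 and a y2 fragment m/z, planted as confirmatory backbone ions."""
    b2 = sum(monoisotopic_mass(AA_RESIDUES[a]) for a in sequence[:2]) + PROTON_MASS
    y2 = sum(monoisotopic_mass(AA_RESIDUES[a]) for a in sequence[-2:]) + WATER_MASS + PROTON_MASS
    return b2, y2


def generate_glyco_run(
    profile: GroundTruthProfile,
    peptides: list[Peptide] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    charges: tuple[int, ...] = (2,),
    raw_file: str | None = None,
    peptide_weights: tuple[float, ...] | None = None,
    base_area: float = 1.0e8,
    peak_spacing_s: float = 30.0,
) -> GlycoRun:
    """Plant one LC peak + MS2 spectrum per (glycopeptide, glycoform, charge).

    Peak areas follow the profile's fractions (scaled per peptide by
    ``peptide_weights`` so that peptide totals differ, as in real digests);
    each MS2 spectrum carries the full GlcNAc oxonium panel, [GlcNAcHex]+,
    the Neu5Ac reporter pair iff the glycoform is sialylated, two peptide
    backbone ions, and random non-diagnostic noise peaks. The truth sidecar
    records every planted (realized) area.
    """
    rng = np.random.default_rng(seed)
    if peptides is None:
        peptides = reporter_glycopeptides()
    if not all(p.sequons for p in peptides):
        raise ValueError("all peptides must carry a sequon")
    if peptide_weights is None:
        peptide_weights = tuple(1.0 + 0.2 * i for i in range(len(peptides)))
    if len(peptide_weights) != len(peptides):
        raise ValueError("one weight per peptide required")
    raw_file = raw_file or f"{profile.name}_run"

    glycoforms = profile.glycoforms
    plan = []  # (peptide_idx, glycoform, charge, mz, rt, area)
    slot = 0
    for pi, pep in enumerate(peptides):
        pep_mass = pep.mass
        for gf in glycoforms:
            rt = 100.0 + peak_spacing_s * slot
            slot += 1
            frac = profile.fractions[gf.code]
            total = base_area * peptide_weights[pi] * frac
            for z in charges:
                theo = (pep_mass + gf.mass + z * PROTON_MASS) / z
                mz = theo * (1.0 + rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6) \
                    if noise.mz_jitter_ppm > 0 else theo
                area = total / len(charges)
                if noise.area_cv > 0:
                    area *= max(1.0 + rng.normal(0.0, noise.area_cv), 0.05)
                plan.append((pi, gf, z, mz, rt, area))

    rt_max = 100.0 + peak_spacing_s * slot + 60.0
    rts = np.arange(0.0, rt_max, 1.0)
    sigma = noise.peak_sigma_s
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    peaks: list[tuple[np.ndarray, np.ndarray]] = [
        (np.empty(0), np.empty(0)) for _ in rts
    ]
    scan_lists: dict[int, list[tuple[float, float]]] = {}
    for _, _, _, mz, rt, area in plan:
        lo = int(max(0, np.floor(rt - 5 * sigma)))
        hi = int(min(len(rts) - 1, np.ceil(rt + 5 * sigma)))
        for i in range(lo, hi + 1):
            inten = area * norm * np.exp(-0.5 * ((rts[i] - rt) / sigma) ** 2)
            scan_lists.setdefault(i, []).append((mz, inten))
    for i, centroids in scan_lists.items():
        arr = np.array(centroids)
        peaks[i] = (arr[:, 0], arr[:, 1])
    run = Ms1Run(raw_file=raw_file, rts=rts, peaks=peaks)

    spectra: list[Ms2Spectrum] = []
    scan_no = 1
    truth_rows = []
    for pi, gf, z, mz, rt, area in plan:
        pep = peptides[pi]
        frag_mz = list(GLCNAC_OXONIUM_PANEL) + [GLYCAN_FRAGMENT_PANEL[0]]
        frag_int = [1000.0, 400.0, 300.0, 200.0, 150.0, 120.0, 500.0]
        if gf.galactoses >= 2:
            frag_mz.append(GLYCAN_FRAGMENT_PANEL[1])
            frag_int.append(180.0)
        if gf.is_sialylated:
            frag_mz.extend(NEU5AC_REPORTER_PANEL)
            frag_int.extend([600.0, 250.0])
        frag_mz.extend(_backbone_ions(pep.sequence))
        frag_int.extend([80.0, 90.0])
        for _ in range(noise.decoy_peaks):
            frag_mz.append(_nondiagnostic_mz(rng))
            frag_int.append(float(rng.uniform(5.0, 60.0)))
        spectra.append(
            Ms2Spectrum(
                raw_file=raw_file,
                scan=scan_no,
                rt=rt,
                precursor_mz=mz,
                precursor_charge=z,
                mz=np.array(frag_mz),
                intensity=np.array(frag_int),
            )
        )
        truth_rows.append(
            {
                "peptide": pep.sequence,
                "glycoform": gf.code,
                "charge": z,
                "mz": mz,
                "rt": rt,
                "area": area,
                "fraction": profile.fractions[gf.code],
                "scan": scan_no,
            }
        )
        scan_no += 1

    all_mz = np.array([row[3] for row in plan])
    for _ in range(noise.decoy_spectra):
        prec = _decoy_precursor(rng, all_mz)
        decoy_mz = np.array([_nondiagnostic_mz(rng) for _ in range(12)])
        spectra.append(
            Ms2Spectrum(
                raw_file=raw_file,
                scan=scan_no,
                rt=float(rng.uniform(rts[0], rts[-1])),
                precursor_mz=prec,
                precursor_charge=2,
                mz=decoy_mz,
                intensity=rng.uniform(5.0, 80.0, size=len(decoy_mz)),
            )
        )
        scan_no += 1

    truth = pd.DataFrame(truth_rows)
    return GlycoRun(run=run, spectra=spectra, truth=truth, profile=profile)


_DIAGNOSTIC_MZ = np.array(
    GLCNAC_OXONIUM_PANEL + GLYCAN_FRAGMENT_PANEL + NEU5AC_REPORTER_PANEL
)


def _nondiagnostic_mz(rng: np.random.Generator) -> float:
    """Random fragment m/z at least 0.05 Da away from every diagnostic ion."""
    while True:
        mz = float(rng.uniform(120.0, 1300.0))
        if np.min(np.abs(_DIAGNOSTIC_MZ - mz)) > 0.05:
            return mz


def _decoy_precursor(rng: np.random.Generator, candidate_mz: np.ndarray) -> float:
    """Random precursor at least 20 ppm away from every planted precursor."""
    while True:
        mz = float(rng.uniform(400.0, 1800.0))
        if np.min(np.abs(candidate_mz - mz)) / mz > 20e-6:
            return mz


# --- CMP-Neu5Ac paired runs -------------------------------------------------

#: Tissue metadata of the packaged CMP-Neu5Ac fixture (a strongly producing
#: line assayed from a 5 ml protonema culture): values chosen as realistic for
#: the assay scale, not stated by the emulated study.
GMC5_CMP_SAMPLE = CmpSampleInfo(dry_weight_g=0.005, injected_fraction=0.5)
GMC5_TRUE_NMOL_PER_G_DW = 58.0


def generate_cmp_pair(
    true_nmol_per_g_dw: float = GMC5_TRUE_NMOL_PER_G_DW,
    standard_pmol: float = 70.0,
    sample_info: CmpSampleInfo = GMC5_CMP_SAMPLE,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict:
    """Paired sample/standard LC-MS runs for the CMP-Neu5Ac quantifier.

    Both runs show a Gaussian EIC peak at the CMP-Neu5Ac [M-H]- m/z with
    areas in the ratio implied by the true concentration and metadata; the
    sample MS2 inside the peak carries the CMP fragment. A zero concentration
    produces a sample run without the target peak.
    """
    if true_nmol_per_g_dw < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)
    area_per_pmol = 2.0e4
    injected_pmol = (
        true_nmol_per_g_dw * 1000.0 * sample_info.dry_weight_g
        * sample_info.injected_fraction
    )

    def make_run(name: str, pmol: float, apex_rt: float) -> tuple[Ms1Run, list[Ms2Spectrum]]:
        rts = np.arange(0.0, 600.0, 1.0)
        sigma = noise.peak_sigma_s
        area = pmol * area_per_pmol
        if noise.area_cv > 0 and area > 0:
            area *= max(1.0 + rng.normal(0.0, noise.area_cv), 0.05)
        mz = CMP_NEU5AC_MZ * (
            1.0 + (rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6 if noise.mz_jitter_ppm > 0 else 0.0)
        )
        peaks = []
        for rt in rts:
            if area > 0 and abs(rt - apex_rt) <= 5 * sigma:
                inten = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
                    -0.5 * ((rt - apex_rt) / sigma) ** 2
                )
                peaks.append((np.array([mz]), np.array([inten])))
            else:
                peaks.append((np.empty(0), np.empty(0)))
        run = Ms1Run(raw_file=name, rts=rts, peaks=peaks)
        ms2 = []
        if area > 0:
            ms2.append(
                Ms2Spectrum(
                    raw_file=name,
                    scan=1,
                    rt=apex_rt,
                    precursor_mz=mz,
                    precursor_charge=1,
                    mz=np.array([CMP_FRAGMENT_MZ, 211.0, 97.0]),
                    intensity=np.array([1000.0, 50.0, 30.0]),
                )
            )
        return run, ms2

    sample_run, sample_ms2 = make_run("cmp_sample", injected_pmol, 300.0)
    standard_run, standard_ms2 = make_run("cmp_standard", standard_pmol, 300.0)
    return {
        "sample_run": sample_run,
        "sample_ms2": sample_ms2,
        "standard_run": standard_run,
        "standard_ms2": standard_ms2,
        "standard_pmol": standard_pmol,
        "sample_info": sample_info,
        "truth": {
            "nmol_per_g_dw": true_nmol_per_g_dw,
            "injected_pmol": injected_pmol,
        },
    }


# --- colorimetric plate ------------------------------------------------------

GNN_TISSUE = TissueSample(fresh_weight_g=0.15)


def generate_colorimetric_plate(
    true_umol_per_g_fw: float,
    sample: TissueSample = GNN_TISSUE,
    curve_slope: float = 0.02,   # A595 per nmol
    curve_intercept: float = 0.05,
    standard_levels_nmol: tuple[float, ...] = (1, 2, 5, 10, 20, 30, 40),
    dilution_factors: tuple[int, ...] = (2, 4, 8, 16, 32),
    duplicates: int = 2,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict:
    """Synthetic periodate-resorcinol plate with a linear standard row.

    Sample wells follow the same line at the amounts implied by the true
    concentration and the dilution series; responses beyond the top standard
    saturate (and are thus excluded as out-of-range by the quantifier).
    """
    if true_umol_per_g_fw < 0:
        raise ValueError("concentration must be >= 0")
    rng = np.random.default_rng(seed)

    def respond(amount_nmol: float) -> float:
        resp = curve_slope * min(amount_nmol, 1.2 * max(standard_levels_nmol)) + curve_intercept
        if noise.response_cv > 0:
            resp *= 1.0 + rng.normal(0.0, noise.response_cv)
        return resp

    rows = []
    for i, level in enumerate(standard_levels_nmol):
        rows.append(("A%d" % (i + 1), "standard", float(level), respond(level)))
    conc_nmol_per_ul = (
        true_umol_per_g_fw * 1000.0 * sample.fresh_weight_g / sample.buffer_volume_ul
    )
    for rep in range(duplicates):
        for j, d in enumerate(dilution_factors):
            assayed = conc_nmol_per_ul / d * sample.assay_volume_ul
            rows.append((f"{'BC'[rep]}{j + 1}", "sample", float(d), respond(assayed)))
    plate = pd.DataFrame(rows, columns=["well", "role", "level", "absorbance"])
    return {
        "plate": plate,
        "sample": sample,
        "truth": {"umol_per_g_fw": true_umol_per_g_fw},
    }


# --- HPLC-FLD chromatogram pair ---------------------------------------------

#: Injection metadata of the packaged HPLC fixture (best free-Neu5Ac line).
GNN2_HPLC_SAMPLE = HplcSampleInfo(
    dry_weight_g=0.010, extract_volume_ul=500.0, injected_volume_ul=5.0
)
GNN2_TRUE_UMOL_PER_G_DW = 85.0


def generate_hplc_pair(
    true_umol_per_g_dw: float = GNN2_TRUE_UMOL_PER_G_DW,
    sample_info: HplcSampleInfo = GNN2_HPLC_SAMPLE,
    standard_amount_nmol: float = 2.0,
    apex_rt_min: float = 7.5,
    peak_sigma_min: float = 0.05,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict:
    """Paired DMB-Neu5Ac fluorescence chromatograms (sample + standard)."""
    from .sialo import Chromatogram

    rng = np.random.default_rng(seed)
    rts = np.arange(0.0, 12.0, 0.01)

    def trace(amount_nmol: float, apex: float) -> np.ndarray:
        area = amount_nmol * 1.0e4
        if noise.area_cv > 0 and area > 0:
            area *= max(1.0 + rng.normal(0.0, noise.area_cv), 0.05)
        sig = area / (peak_sigma_min * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((rts - apex) / peak_sigma_min) ** 2
        )
        if noise.response_cv > 0:
            sig = sig * (1.0 + rng.normal(0.0, noise.response_cv, size=sig.shape))
        return sig

    injected_nmol = (
        true_umol_per_g_dw * 1000.0 * sample_info.dry_weight_g
        * sample_info.injected_volume_ul / sample_info.extract_volume_ul
    )
    sample = Chromatogram(rts.copy(), trace(injected_nmol, apex_rt_min))
    standard = Chromatogram(rts.copy(), trace(standard_amount_nmol, apex_rt_min))
    return {
        "sample": sample,
        "standard": standard,
        "standard_amount_nmol": standard_amount_nmol,
        "sample_info": sample_info,
        "truth": {"umol_per_g_dw": true_umol_per_g_dw,
                  "injected_nmol": injected_nmol},
    }


# --- qPCR CT tables ----------------------------------------------------------

def generate_ct_table(
    true_ratios: dict[str, dict[str, float]],
    control_cts: dict[str, float] | None = None,
    n_replicates: int = 3,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict:
    """Triplicate CT table from true expression ratios per line and gene.

    Target CT = (mean control CT) - log2(ratio) + Gaussian noise; control
    wells carry the same CT noise. ``true_ratios`` maps line -> gene -> ratio.
    """
    if control_cts is None:
        control_cts = {"EF1a": 19.5, "L21": 20.5}
    if any(r <= 0 for genes in true_ratios.values() for r in genes.values()):
        raise ValueError("expression ratios must be > 0")
    rng = np.random.default_rng(seed)
    mean_control = float(np.mean(list(control_cts.values())))
    rows = []
    for line, genes in true_ratios.items():
        for gene, ct0 in control_cts.items():
            for rep in range(1, n_replicates + 1):
                ct = ct0 + (rng.normal(0.0, noise.ct_sigma) if noise.ct_sigma > 0 else 0.0)
                rows.append((gene, line, rep, ct))
        for gene, ratio in genes.items():
            base = mean_control - np.log2(ratio)
            for rep in range(1, n_replicates + 1):
                ct = base + (rng.normal(0.0, noise.ct_sigma) if noise.ct_sigma > 0 else 0.0)
                rows.append((gene, line, rep, ct))
    table = pd.DataFrame(rows, columns=["gene", "line", "replicate", "ct"])
    return {"table": table, "truth": true_ratios, "control_genes": tuple(control_cts)}
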