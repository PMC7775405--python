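# Methods

This note documents the models, conventions and design choices behind
`glycoprofiler`, in the order data flow through the package.

## Mass engine

All m/z arithmetic is monoisotopic, built from integer elemental compositions
over C/H/N/O/P/S and IUPAC atomic masses. Charged species use the proton-mass
convention m_p = 1.007276 Da (H minus one electron) with no separate electron
bookkeeping: positive mode (M + z·m_p)/z, negative mode (M − z·m_p)/z. This
reproduces every reference ion value at its printed precision. Two reference
values differ from residue-mass addition by one unit in the last printed
digit ([GlcNAcHex₂]⁺ 528.191 vs computed 528.192; [GlcNAc − C₂H₄O₂]⁺ 144.065
vs computed 144.0655): the engine always reports the computed value and the
validator's 0.02 Da fragment tolerance makes the difference irrelevant in
practice. Monosaccharide residues are glycosidically bound (free sugar minus
water): Hex 162.0528, HexNAc 203.0794, Neu5Ac 291.0954, Pent 132.0423 Da.
Display rounding is half-away-from-zero; internal values stay at double
precision. Average masses, isotope envelopes and adducts other than ±H are
out of scope.

## Glycoform catalog and candidate table

Glycoforms are identified at composition level only — linkage isomers such as
AM/MA are one entry — mirroring how composition-level MS data are reported.
Codes name the two antennae on the HexNAc₂Hex₃ core, canonicalized heavier
antenna first (Na > A > Gn > M); antenna increments are M: nothing,
Gn: +HexNAc, A: +HexNAc+Hex, Na: +HexNAc+Hex+Neu5Ac. Pentose variants
(+P/+2P) are generated only for galactosylated, non-sialylated forms, because
pentoses are empirically never observed together with sialylation; the
catalog optionally includes plant-typical xylose/core-fucose decorations as
negative controls for engineered Δxt/ft backgrounds. NaA is kept in the
combinatorial catalog even though it is rarely observed; fixtures simply
assign it zero abundance.

Tryptic digestion cleaves C-terminal to K/R except before P, with
configurable missed cleavages; glycosites are N-X-S/T sequons with X ≠ P.
Cysteines carry fixed carbamidomethylation (+57.02146 Da). The reporter
glycoprotein of the emulated workflow is not public, so the package ships a
synthetic reporter sequence (labelled as such) whose digest yields exactly
three sequon-bearing peptides; any FASTA can be substituted. The candidate
table is the Cartesian product of sequon-bearing peptides and the catalog,
with per-charge m/z for charges 2–4 (typical tryptic glycopeptide charges;
configurable).

## Spectra, EICs and peak areas

MS² spectra travel as Mascot-dialect MGF (via pyteomics) with a RAWFILE
annotation carrying the raw-file name needed for joins; MS¹ runs are
centroided long-format TSV tables. Retention times are seconds. An EIC sums,
per scan, all centroid intensities within the m/z window (absolute Da or
ppm); areas are trapezoidal integrals of the piecewise-linear trace clipped
at the window bounds, which makes areas exactly additive over adjacent
windows. Automatic integration bounds — nowhere standardized for this
workflow — are the contiguous region around the apex where intensity is at
least 5% of the apex; with a common peak shape this truncates every peak by
the same factor, so relative profiles are unaffected.

## Identification

Precursor matching finds all (candidate, charge) pairs with
|observed − theoretical| ≤ 5 ppm · theoretical, using a sorted-table window
lookup that is contractually identical to the exhaustive pairwise scan (and
tested against one). A spectrum with a declared charge is only tried at that
charge; otherwise all configured charges are tried. Validation then requires
at least 2 hits (default; configurable to 1) from the union of the GlcNAc
oxonium and glycan-fragment panels within 0.02 Da — one ion would be too
easily produced by noise — and, for Neu5Ac-containing candidates, both
Neu5Ac reporters (the pair is always reported together in practice;
configurable). Spectra matching several candidates are all reported and
flagged ambiguous rather than arbitrated; disambiguation belongs to
quantification review. Peptide-backbone fragments are planted by the
generator as confirmatory ions but are not scored.

## Relative quantification

The pooled profile is area-weighted: per glycoform, total confirmed area over
the grand total. The alternative (simple mean of per-peptide percentages) is
derivable from the emitted per-peptide matrix; area weighting is the default
because summing all confirmed peak areas before forming percentages is the
natural reading of the summation rule, and both coincide when peptide totals
are equal. The SD across glycopeptides uses ddof = 1 and is undefined for a
single glycopeptide. The intensity-table backend joins on exact
(raw file, scan) and precursor mass within 10 ppm (no tolerance is
standardized for this join; 10 ppm comfortably covers a 5 ppm precursor
match) and errors on duplicate keys.

## Small-molecule quantification

*Colorimetric.* The standard curve is unweighted OLS of A₅₉₅ on nmol
(R² < 0.98 warns); a sample dilution is in range when its response lies
between the smallest and largest standard responses inclusive. Each in-range
dilution is back-calculated, multiplied by its dilution factor and converted
through the extraction ratio (4 ml buffer per g tissue) and the 120 μl assay
volume to μmol/g FW; in-range dilutions are averaged and their SD reported.
Saturated dilutions are excluded and listed; a blank whose responses all fall
below the lowest standard reports 0 with a below-detection flag.

*DMB-HPLC-FLD.* The sample peak is accepted only if its apex co-elutes with
the standard apex within 0.2 min; the amount is the standard amount times the
area ratio, normalized through injection metadata (extract volume, injected
volume, dry weight) to μmol/g DW. The FW:DW ratio of 5:1 converts dry- to
fresh-weight values for cross-checking against the colorimetric assay.

*CMP-Neu5Ac LC-MS.* EICs at the computed [M−H]⁻ of CMP-Neu5Ac (613.140,
printed 613.1) ± 0.1 Da in sample and standard runs; the sample peak counts
only if an MS² spectrum within the peak's RT bounds contains the CMP fragment
within 0.02 Da. The confirmation targets the computed CMP [M−H]⁻ (322.045):
the printed 322.0 is instrument display precision, and a literal ±0.02 Da
window around 322.0 would reject the true fragment. A single-point standard
is the default (matching practice at these analyte levels); a multi-level
standard table fits through the same OLS machinery.

## qRT-PCR

Relative expression is 2^(−ΔCT) assuming primer efficiency 2, with the
control CT the arithmetic mean of the control genes' replicate-mean CTs
(EF1α and L21 by default). How the two housekeepers are combined is not
standardized; the mean is the default and per-control normalizations are also
returned. The SD is computed on the ratio scale (matching how such error bars
are drawn), over the replicate 2^(−ΔCT) values. Primer efficiency regresses
CT on log₂(dilution factor); constant CTs are degenerate and raise.

## Synthetic data and what it does(n't) show

Generators are seeded (`numpy.random.default_rng`) and byte-deterministic.
The chromatographic model is Gaussian peaks (σ = 4 s) on a 1 s scan grid,
30 s apart, with per-peak area CV (default 2%), precursor m/z jitter
(default 1 ppm), optional decoy MS² spectra (random precursors kept ≥ 20 ppm
from any candidate; fragment peaks kept ≥ 0.05 Da from every diagnostic ion)
and non-diagnostic noise peaks inside genuine spectra. Peptide totals differ
(weights 1.0/1.2/1.4) so area-weighted pooling is actually exercised.

The packaged profile fixtures encode the headline study conditions:
"ftst78" with 6.0% NaM, 0.3% NaGn, 70.8% AM family (split 50/35/15 over
0/1/2 pentoses — a convention for "about half decorated"), 0.8% AGn, 11.3%
AA and the derived GnGn complement of 10.8%; "gmc_gt" a GnGn-dominant,
galactosylated-but-unsialylated profile (~55% galactosylation, ~8%
biantennary). Tissue fixtures: CMP-Neu5Ac 58 nmol/g DW measured against a
70 pmol standard (5 mg DW, half the extract injected), free Neu5Ac
85 μmol/g DW by HPLC (10 mg DW, 5 of 500 μl injected) and 16.5 μmol/g FW
colorimetrically (150 mg FW, fourfold extraction volume). The normalization
metadata are package choices at realistic assay scales; generator and
quantifier share only this metadata, never the answer.

What passing recovery tests shows: the search, validation, integration and
normalization rules are implemented self-consistently and invert the
generators' forward models exactly at zero noise and stably under the modeled
noise. What they do not show: robustness to isotope envelopes, co-eluting
isobaric interference, chromatographic tailing, matrix effects or detector
saturation — none of which the generators emulate.

## Problem sizes and numerical choices

Synthetic profiling runs contain 24 glycopeptide peaks (3 peptides × 8
glycoforms) plus up to 100 decoy spectra over a ~14 min gradient; the
precursor-matching equivalence check runs 10³ spectra against 10³ candidates;
qPCR recovery uses 100 seeded replicates at CT noise σ = 0.2. These sizes
exercise every code path while keeping the whole suite in seconds. Ties in
`argmax` resolve to the first index (numpy convention); half-open RT windows
are evaluated on the clipped piecewise-linear trace; degenerate inputs
(empty runs, all-zero areas, zero slopes, charge 0) raise `ValueError` with
specific messages rather than propagating NaNs.
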