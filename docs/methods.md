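# Methods

## Scope and data model

The package analyses phantom acquisitions made under automatic exposure
control (AEC) on three mammography units — a GE Senographe Pristina
(Mo/Rh anode tracks, CsI flat-panel detector, 100-µm pitch, 9-projection
25° DBT with grid) and two Hologic Selenia units (W anode, a-Se detector,
70-µm pitch, 15-projection 15° DBT without grid; the Dimensions bins 2×2
in DBT, and only the 3Dimensions offers CEM). The phantom is a stack of
semicircular PMMA slabs, 20–70 mm in 5-mm steps, with a 15 × 15 mm,
0.2-mm-thick aluminum square on top of the first 20 mm. The full design —
every available AEC mode per modality, eleven thicknesses, triplicates —
comprises 363 studies: 165 DM, 132 DBT and 66 CEM (LE+HE pairs). A CEM
study is one LE+HE series and a DBT study one scan; projection- and
energy-level rows appear only inside the long-format `StudyTable`.

All stages exchange that table (CSV-serializable), so the statistics run
identically on synthetic data, on extracted DICOM trees, or on an external
factor table without pixel data (image metrics are then flagged
unavailable, dose and exposure statistics still run).

## Dosimetry

Mean glandular dose is recomputed from the entrance air kerma with the
Dance factor model,

    MGD = K · g(HVL, T) · c(HVL, glandularity) · s(anode/filter) · t(θ),

never taken from vendor organ-dose tags (those are carried as metadata
only, since vendors compute them under differing assumptions). The
PMMA→breast equivalence ladder (20 mm → 21 mm breast at 97 % glandularity
… 70 mm → 90 mm at 4 %), the g- and c-tables on the (HVL, thickness /
glandularity) grid, per-track s-factors and the small-angle tomosynthesis
t(θ) table are shipped as plain-text resources transcribed from the
standard published compilations at typical published values; the resource
version is recorded in every result's provenance. Lookups are linear
(bilinear on 2-D grids) and exact at grid nodes, which makes brute-force
table-indexing oracles decisive in the tests. Coordinates outside a grid
clamp to the edge with a provenance warning — by design this is how the
Cu-filtered high-energy CEM spectra (HVL ≈ 2.5–3 mm Al, far beyond the
classic tabulations) are handled; all HE doses therefore carry the
hardest-spectrum factors, a stated approximation.

Entrance kerma comes from the DICOM entrance-dose attribute when present;
otherwise a configurable tube-output model K = Y₀·(kVp/28)³·mAs scaled by
the inverse-square distance to the phantom surface reconstructs it (the
synthetic generator uses this same model forward). DBT scan dose is the
sum of per-projection MGDs, with MGD-per-projection = total/n as the FOM
basis; CEM series dose is the LE+HE sum.

## Image quality

CNR = |MPV_Al − MPV_PMMA| / SD_PMMA. The signal ROI is a 10-mm square
centred in the insert (2.5-mm guard against edge blur); the background is
a rectangular frame starting 2.5 mm outside the insert footprint and 5 mm
wide. SD is the sample standard deviation (n−1) of the background band; a
pooled insert+band variant exists behind a configuration switch (default
off) since both noise-region conventions circulate in QC practice. The
absolute difference makes the definition orientation-free ("for
processing" images are darker under aluminum). Geometry is specified in
mm and converted through the effective pixel pitch (doubled under 2×2 DBT
binning) to half-open pixel intervals, rounding toward the ROI interior.
FOM = CNR²/MGD; for DBT the CNR comes exclusively from the 0° projection
and the dose basis is the per-projection MGD. Insert position defaults to
laterally centred with the inner edge 60 mm from the chest-wall side and
is configurable.

## Statistics

Repeatability over the triplicates uses the maximum half-dispersion
(max − min)/2, divided by the mean for the relative error; per-mode
summaries report the worst thickness. A zero mean with nonzero dispersion
is flagged undefined and excluded from maxima rather than propagated.
Pooled per-modality summaries use medians and quartiles (linear
interpolation between order statistics, the "type 7" rule, recorded in
output metadata) because none of the distributions is normal; DBT
exposure and dose pool as scan totals, CEM separately per energy.
Intermodality ratios divide each modality's cell-mean dose (DBT total,
CEM LE+HE total) and CNR by the DM values at the same thickness on the
same unit, with AOP/STD as the GE reference on both sides; means over the
thickness range summarize each comparison. Ratios with a missing
numerator cell are omitted and logged; a missing DM reference is an
error. Mode-vs-mode percent differences are computed as means of
per-thickness percents, with ratio-of-means available via a flag, since
either convention is defensible. Outputs are CSV tables plus a JSON
report with provenance; plotting is left to the caller.

## Synthetic generator

The generator defines the study conditions under which the pipeline is
validated. Spectrum selection implements the observed decision rules
exactly (GE binary switch at 35 mm; Hologic monotone kVp ramps on W/Rh in
DM and W/Al in DBT; Cu-filtered HE at 49 kVp on GE and 45/49 kVp on
Hologic; GE CEM-LE identical to DM AOP/STD). Exposure follows
mas(t) = mas₄₅ · 2^((t−45)/12) (HE images use a flatter 25-mm doubling),
with per-mode scalings taken from the reported average dose shifts
between GE modes (+32.5 % STD+, −24.0 % DOSE in DM; +33.4 % STD+ in DBT)
and base values placed so dose magnitudes land in the clinically typical
range; vendors publish no per-thickness mAs tables, so these ramps are
illustrative stand-ins with the correct structure. mAs jitter is
lognormal at 1.2 % relative SD, the scale at which AEC triplicates vary
in practice; spectrum choices carry no jitter.

Rendering targets only the statistics the pipeline measures: a uniform
background proportional to the kerma reaching the detector (effective
exponential PMMA attenuation, gain 15 000 DN/mGy), the insert at
background·(1 − contrast) with contrast ∝ (26/kVp)², and stationary
Gaussian noise with quantum scaling σ = √(background·k), k = 0.033 for
the CsI detector and 0.33 for a-Se (divided by 4 under 2×2 binning). The
default detector window is 90 × 60 mm — enough to contain the insert and
both ROIs — rather than a full-field detector, since nothing outside the
ROIs is measured. Each image's planted CNR, background·contrast/σ_eff
with σ_eff² = σ² + 1/12 (integer-rounding variance), is reported for
ground-truth comparisons. This model deliberately omits scatter, detector
MTF, heel effect and spectral physics: passing tests demonstrate the
pipeline's correctness and statistical calibration, not vendor-accurate
dose or CNR predictions for real systems.

Technical factors are quantized on write (mAs to 1 µAs, kerma to
10⁻⁶ mGy) so DICOM decimal-string tags round-trip exactly. One master
seed expands through SeedSequence(master, entry_index, stream) to every
draw; studies regenerate bit-identically.

## Problem sizes and limitations

The shipped campaign is the full 363-study design (1 881 exposure rows;
429 rendered images for IQ), generated in seconds; the planted-CNR
recovery check uses 50 seeded renders of a reference cell. Known
limitations: headline dose values depend entirely on the configured HVL
model and factor-table edition (both recorded in provenance); HE-CEM
factors are edge-clamped extrapolations; CNR is the only IQ metric
(no MTF/NPS/detectability); and synthetic magnitudes — as opposed to
structure — should not be read as vendor measurements.
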