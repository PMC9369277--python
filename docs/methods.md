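# Methods

`adenoquant` re-implements, as a tested and reusable pipeline, the way
multiplex-immunohistochemistry studies of the uterus quantify vasculature:
blood-vessel density (BVD) from CD31, lymph-vessel density (LVD) from
podoplanin, vessel maturity from CD31/α-SMA double staining, and VEGF
expression as an immunohistochemical score (IHS) — followed by the standard
nonparametric group comparisons. Because clinical specimens are not
publicly available, the package ships a synthetic-tissue generator with
exact ground truth; every quantitative claim the test suite makes is a
recovery statement about planted quantities.

## The measurement model

**Binary layers.** Each marker channel is thresholded into a binary layer
(Otsu per channel per field by default, with a fixed-threshold override;
the threshold used is recorded in every mask for audit), morphologically
closed, and filtered for objects smaller than a minimum size. Two guards
handle degenerate planes: a constant plane cannot be Otsu-thresholded and
raises (or, inside the pipeline, falls back to a fixed mid-range cut of
128/255, so a uniformly stained plane reads as all-foreground and a blank
one as all-background); a plane whose two Otsu classes differ by less than
`min_class_separation` (default 32 of 255) has no real contrast — Otsu
would split pure noise in half — and falls back to the same mid-range cut.

**Compartments.** The endometrial stroma is the cleaned CD10 layer; glands
are the DAPI-lined, CD10-negative regions enclosed by stroma; small
enclosed holes without nuclei (vessel lumina, staining dropouts) are merged
back into stroma; the myometrium is the cleaned α-SMA layer outside
endometrial tissue, with stroma taking precedence on overlap so that
vascular α-SMA rings inside the stroma never count as myometrium. The four
masks provably partition every field (asserted at construction).

**Vessels.** Connected CD31 clusters (8-connectivity by default, so ring
walls do not fragment at diagonals) of at least `min_area_um2` (default
5 µm², about the smallest capillary cross-section) become vessel objects.
A cluster is lymphatic when at least half of its pixels are
podoplanin-positive; podoplanin clusters without CD31 are additional
lymphatics. Each vessel is assigned to the compartment holding the
majority of its pixels; majority-background or majority-gland objects are
dropped. BVD and LVD are exact count-over-area ratios per compartment
(vessels per mm² of CD10-stained stroma, or of α-SMA-stained myometrium).
The percent CD31- and podoplanin-positive area per compartment is carried
as the consistency metric alongside the counts.

**Maturity.** A blood vessel is mature when the ring of pixels gained by
dilating its footprint by `maturity_dilation_um` (default 3.5 µm) contains
at least `maturity_overlap_cut` (default 0.1) α-SMA-positive pixels. The
dilation reach is configured in micrometres and converted to pixels,
because a pixel-fixed default breaks when the resolution changes; 3.5 µm
spans the ~1 µm gap between endothelium and the mural layer plus most of
the mural wall. The cut is deliberately low: even partial mural coverage
reads as double staining. The mature:total ratio is computed in the stroma
only — every myometrial vessel is wrapped in smooth muscle, so the ratio
is uninformative there and is reported as undefined.

**Specimen aggregation.** Field records pool per specimen and compartment
as total count over total area (and area-weighted means for percent
areas), not as means of per-field densities; this is robust to unequal
compartment areas across the five fields of a sample.

**IHS.** Cells are proxied by DAPI local maxima. A cell is immunoreactive
when the mean VEGF intensity in a disk of `cell_radius_um` (default 3 µm)
around its seed reaches `vegf_threshold` (default 25/255). The percentage
of immunoreactive cells is binned on the continuum as [1,10] → 1,
(10,50] → 2, (50,80] → 3, (80,100] → 4, below 1% → 0 (the printed bins do
not define sub-1% staining; scoring it 0 matches the intensity scale's
inclusion of 0). Staining intensity is the mean, over positive cells, of
the local VEGF maximum, binned against four ascending calibration
cutpoints (default 25/75/125/175 — quarters of the 8-bit dynamic range).
The local maximum, not the disk mean, represents a cell's staining level:
at coarse pixel sizes the stained footprint underfills the sampling disk
and a blanket mean would systematically underestimate the level. IHS is
the product of the two scores (0–16). Compartments with no detected cells
are flagged as undefined, never scored 0. Glands and stroma are scored
separately; the specimen-level IHS pools cells across fields before
rebinning.

**Statistics.** Outcomes are summarized as median (range) per group.
Endometrial tissue groups (control, eutopic, ectopic endometrium) are
compared per cycle-phase stratum with a Kruskal–Wallis omnibus
(tie-corrected H, chi-squared approximation; all-tied data return H = 0,
p = 1 with a warning) and pairwise Mann–Whitney U post hoc; the
myometrium is a two-group comparison. Mann–Whitney switches automatically
to the exact null distribution when both groups have at most 8
observations and the pooled data are tie-free (enumeration cost at most
C(16,8)), otherwise it uses the tie-corrected normal approximation with
continuity correction; exact two-tailed p is twice the smaller tail,
capped at 1. Pairwise flags are significant at two-tailed α = 0.05 and are
*not* gated on the omnibus: the source analyses report omnibus and
pairwise p side by side, and gating would make the pairwise flag's type-I
rate uninterpretable. No multiple-testing correction is applied by default
(mirroring the original analysis style); a Holm adjustment is available
behind a flag. The medication subgroup comparison pools both phases and
compares native-endometrium BVD and LVD between specimens with and without
antiangiogenic-profile medication.

## What the generator emulates — and what it does not

Each tissue sample is rendered as `n_fields` (default 5) multispectral
fields of 0.9 × 0.7 mm (the ×200 field of the emulated acquisition), at a
configurable pixel size (default 0.5 µm/px, a realistic sub-micron scan;
the recovery tests run at 1 µm/px and the cohort end-to-end check at
2 µm/px with 2 fields per sample, chosen so the full suite stays
desk-scale). Endometrial fields are CD10 stroma perforated by elliptical
glands (~16 glands/mm², semi-axes 25–70 µm, epithelial nuclei lining the
rim); myometrial fields are solid α-SMA tissue; ectopic fields embed 2–4
CD10 islands with small glands in an α-SMA background. Vessels are annuli
(outer radius uniform in 4–15 µm, wall 2–3 µm); mature blood vessels get a
concentric α-SMA ring 1–3 µm outside the endothelium. Vessel centres are
placed uniformly inside the eroded compartment with non-overlap enforced
by rejection sampling (bounded retries; an impossible request fails loudly
naming the field). Nuclei sit on a jittered grid (12 µm spacing); VEGF is
painted as 4 µm disks on a planted fraction of each compartment's nuclei
at intensity `level × 50`. Noise is additive: constant background
(default 10), Gaussian read noise (default σ = 5), and an optional
spectral bleed-through fraction into the neighbouring channel (default 0).
Everything is deterministic in (seed, specimen id, field index); cohort
specimen seeds derive from the master seed via a CRC-based seed sequence.

The cohort preset mirrors the emulated study's structure: 19 adenomyosis
patients (eutopic + ectopic endometrium + myometrium samples, lesion
depths drawn 3–8 mm, classified against the strict 2.5 mm invasion
threshold) and 19 controls (endometrium + myometrium), phase split 7/12
and 6/13 (proliferative/secretory), and 4 vs 5 patients on
antiangiogenic-profile medication. The sources report no numeric group
medians (box plots only), so the planted medians are chosen once as
realistic values carrying the reported effect directions: control
endometrial BVD 22 (proliferative) / 29 (secretory) vessels/mm², ectopic
BVD at 2× control, myometrial BVD 14; LVD 8 with eutopic proliferative
LVD at 16; maturity fraction 0.60 (control) vs 0.35 (adenomyosis); VEGF
plans giving median IHS 1 (stroma), 3 (glands), 4 (myometrium).
Between-specimen variation is lognormal with σ = 0.2 (CV ≈ 20%) for
densities, Gaussian sd 0.06 for the maturity fraction, and proportional
CV 0.2 for VEGF fractions — typical biological spread for such cohorts.

The generator deliberately does **not** model: spectral unmixing or raw
multispectral stacks, chromogenic staining, 3-D tissue, realistic nucleus
texture or density gradients, vessel tortuosity or branching,
partial-volume/point-spread blur, or hotspot field selection (supported as
placement density, but the default is uniform). Passing recovery tests
therefore demonstrate that the measurement chain is correct and unbiased
under its own imaging model, not that it is robust to every artefact of
real multiplex scans — real-data use should revisit the thresholds and
calibration, which is why every threshold is logged and configurable.

## Numerical choices and degenerate inputs

- Image planes are 8-bit; write/read round trips through OME-TIFF are
  bit-exact, and reruns with identical config and seed produce
  byte-identical CSV/JSON artifacts.
- Densities are reported to 2 decimals in CSVs; medians and tests are
  computed on unrounded values in memory.
- Coordinates are 0-based row/col pixel indices, origin top-left; report
  columns carry physical units in their names (mm², vessels/mm², %,
  score).
- Zero-area compartments suppress their density record with a logged
  warning; zero-cell compartments flag the IHS as undefined.
- A specimen with a single field aggregates to that field's values; a
  stratum with fewer than two nonempty groups emits its report with tests
  omitted and a warning.
- The adenomyosis classifier is strictly greater-than: a lesion exactly at
  the threshold depth is not adenomyosis.

## Known limitations

- Whether CD31⁺/podoplanin⁺ vessels should count toward BVD is ambiguous
  in the emulated protocol; here they count as lymphatics only
  (`lymph_overlap_cut = 0.5`), and the generator's default lymphatics are
  podoplanin-only, so the choice does not affect the shipped benchmarks.
- The intensity calibration is a convention (quarters of the dynamic
  range); absolute IHS values on real data depend on acquisition settings
  and would need per-batch calibration.
- Statistical power statements in the tests are properties of the planted
  effect sizes and variability above, not of any particular clinical
  population.
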