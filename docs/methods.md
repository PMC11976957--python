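# Methods

`memphys` re-implements, as a tested library, the quantitative chain by
which raw membrane-biology measurements become physiological claims:
shotgun-lipidomics identification and quantification, lipidome summary
metrics, membrane-order readouts (generalized polarization and DPH
anisotropy), cryo-EM bilayer-thickness profiling, and growth/permeability
kinetics. Every stage has a seeded synthetic generator that produces its
inputs with known ground truth, so the whole chain is testable without
instrument data.

## Lipid model

Species are handled at sum-composition resolution — a class plus total
fatty-acyl (and long-chain-base) carbons `c`, double bonds `d` and, for
sphingolipids, hydroxyls `h` — written `CLASS(c:d)` / `CLASS(c:d:h)`.
Per-chain labels with deuterium tags (`PC(15:0/18:1-d7)`,
`CL(tetra14:1)`, `Cer(t18:0/16:0)`, where `d`/`t` long-chain-base
prefixes denote 2 and 3 hydroxyls) collapse to the same representation
with the deuterium count retained.

Elemental formulas follow

    formula(class, c, d, h) = base(class) + c·CH2 − d·H2 + h·O

with per-class base formulas at the (0:0) reference composition shipped
in `data/chemistry.yaml`. The bases were derived from the structural
chemistry of each class (backbone + acyls + headgroup minus waters of
esterification) and validated against reference compounds (DPPC
C40H80NO8P, dioleoyl-PA C39H73O8P, tetraoleoyl cardiolipin C81H150O17P2,
LPC 16:0 C24H50NO7P, d18:1/16:0 ceramide C34H67NO3, tripalmitin
C51H98O6). Monoisotopic masses come from a fixed IUPAC atomic-mass table
(≥ 6 decimal places), so results are bit-reproducible with no external
services. Adduct m/z is `(M + Δm)/|z|` with the electron mass folded
into Δm; the shipped adduct table covers protonation and ammonium gain
(positive mode, matching an ammonium-chloride additive) and
deprotonation and chloride gain (negative mode). Which adducts an
instrument actually produced per class is not recoverable from a method
description; the shipped table is a documented assumption and fully
user-editable.

## Identification and quantification

Peak assignment works at a ppm tolerance (default 3 ppm): a peak may be
assigned to a library entry iff `|mz_p − mz_e|/mz_e·1e6 ≤ tol`, each
peak goes to its nearest entry in ppm, each entry keeps its most intense
matching peak, and two *different* species within tolerance of one peak
are reported as ambiguous rather than silently resolved. The in-silico
library is restricted to the 350–1200 Th acquisition window.

Quantification is single-point internal-standard ratioing:

    pmol(species) = I(species) / I(class standard) × pmol(class standard)

with the spiked mix (35 pmol PC, 24 PE, 20 PI, 11 PS, 4 PG, 4 PA, 2 CL,
5 Cer, 5 DG, 7 TG, 9 sterol-ester standard) as default. No
isotope-overlap correction is applied — a stated limitation of the
single-point design. Classes without their own standard (lyso classes,
methylated PE, IPC/MIPC) borrow a chemically related class's standard
(lyso → parent, MMPE/DMPE → PE, IPC/MIPC → Cer); this mapping is a
documented assumption and configurable.

Mol% normalizes to the polar-lipid total: all measured lipids except the
storage classes DG, TG and sterol esters. Storage species keep a mol%
relative to the same polar denominator but are flagged non-polar, so
polar mol% always sums to exactly 100.

GC-MS triterpenoid quantification inverts a linear 6-point calibration
of analyte/internal-standard response ratios (unweighted least squares
by default, 1/x weighting available; the weighting used upstream is not
stated). Responses below the intercept return a negative concentration
with a below-range flag rather than silent clipping.

Sample-level exclusion regresses lipid content on culture OD per group
and drops samples whose absolute externally studentized (leave-one-out)
residual exceeds 2.5, then refits once. Externally studentized residuals
are used deliberately: internally studentized residuals are bounded by
√(n−p), so at the small group sizes this filter targets (n ≈ 5–6) a
gross outlier could never cross a 2.5 threshold. With fewer than 4
samples or a zero-variance predictor the filter is skipped with a
warning. The upstream exclusion rule is qualitative ("anomalous lipid
levels"); the 2.5 cutoff is explicit and configurable here.

## Lipidome metrics

All metrics take mol%-of-polar-lipids profiles.

- DBI = Σ(d·[GPLᵢ])/Σ[GPLᵢ] and average chain length =
  Σ(c·[GPLᵢ])/Σ[GPLᵢ], mol%-weighted means over a class set defaulting
  to {PC, PI, PE, PS}; the set is configurable for per-class variants.
- PE/(PC+PI): class-summed mol% ratio of the non-bilayer-prone PE
  against the bilayer formers.
- SoamD = Σᵢ |mol%ₛ(i) − mol%ᵣ(i)| over the union of polar species
  (missing species at 0), a total-variation-style lipidome-remodeling
  score with range [0, 200]. The species universe (all polar species,
  storage lipids excluded) is a documented choice. When the reference is
  a replicate group, the group's mean mol% profile is used.

## Membrane order

Generalized polarization is GP = (I_B − I_R)/(I_B + I_R) with blue/red
defaults of 442 and 496 nm. Spectral stacks use the 32-channel geometry
(415 nm start, 8.9 nm spacing, covering 415–691 nm); a wavelength maps
to the channel with the nearest center — no spectral interpolation, as
none is specified upstream (442 nm → center 441.7, 496 nm → 495.1).
Two-band mode (420–460 / 470–510 nm) averages the channels inside each
band rather than summing them, so bands holding different channel counts
stay comparable and two-band GP reduces exactly to single-channel GP on
band-flat spectra. Pixels whose summed intensity falls below a floor
(default 1% of the 99th-percentile sum) are masked background; optional
flat background subtraction exists but is off by default, since the
upstream plug-in's behavior is unspecified. Region masks are inputs, not
auto-segmented, matching the outlined-region workflow.

DPH steady-state anisotropy is r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with
the grating factor G = I_HV/I_HH computed from the reading or supplied.
Both GP and r are ratiometric, hence invariant to detector gain; these
invariances are property-tested.

Liquid-disordered (Ld) domain area on equatorial GUV images: the dye
partitions into Ld, so bright ring arcs are Ld. The ring is located by
an algebraic (Kåsa) circle fit to above-background pixels — an
intensity-weighted centroid would be dragged toward the bright arc —
ring pixels are binned by polar angle, each bin summarized by its radial
peak intensity (insensitive to how pixel radii distribute inside the
annulus), and bins split bright/dark at the midpoint of the profile's
robust (2nd/98th percentile) extremes, a threshold suited to the
two-level profile of a phase-separated ring. Angular modulation below a
contrast floor (default 30% of the bright level) is called single-phase.
This reproducible rule replaces a manual outlining procedure; on
synthetic rings it recovers arc fractions to well within ±0.02.

## Bilayer thickness (cryo-EM)

A bilayer imaged edge-on shows two intensity troughs at the
electron-rich head-group layers; their separation D_TT proxies membrane
thickness. Profiles are sampled along local normals of a membrane trace
by bilinear interpolation, min-max normalized, Gaussian-smoothed with
σ = 2 px (the common Fiji blur convention for "2-point" filtering;
configurable), and the two troughs located with 3-point parabolic
sub-pixel refinement. A trough qualifies if its prominence exceeds 10%
of the dynamic range *and* it descends at least half the range below the
brightest point — head-group troughs are the darkest features of a
crossing, which excludes shallow undulations of the bright background
that prominence alone admits. Any count other than exactly two
qualifying troughs is a no-call carrying the count found. D_TT is
reported in Å and nm (internal unit Å at the 1.99 Å reference pixel
size; no silent unit rewriting of user data).

Aggregation is hierarchical: per-liposome site means first, then mean ±
SD across liposomes (the sampling design is 10 sites on each of 20
liposomes), with the pooled site distribution kept for plotting.
Thick/thin domain calls use exact 1-D two-means (all threshold splits of
the sorted site values enumerated); a class-mean gap under 2 Å falls
back to single-phase.

## Kinetics

Growth curves (hourly OD readings) are fit to the logistic model
N(t) = K/(1 + ((K−N0)/N0)e^(−rt)) by least squares, initialized from the
data (K ← max OD, N0 ← first positive OD, r ← early log-slope);
Tmid = ln((K−N0)/N0)/r is reported from the closed form, so
N(Tmid) = K/2 holds identically for accepted fits. Non-growing or
non-converging curves are flagged failed with no parameters. Turbidity
traces (osmotic vesicle swelling, 6-minute window) are fit to
A(t) = A∞ + (A0−A∞)e^(−kt); the rate constant k is reported as the
water-permeability proxy — converting k to a coefficient in cm/s
requires vesicle geometry and an osmotic model that are out of scope
here. The two-group helper is an unpaired two-tailed t-test, Welch by
default (equal-variance Student's available), since the variance
assumption is not stated upstream.

## Synthetic data

Each generator inverts one analysis stage; noise-free round trips are
exact and are tested as such.

- **Lipidome tables**: a fission-yeast-like panel of 23 species —
  asymmetric-saturated-rich PC/PE/PI/PS plus minor GPL, lyso,
  sphingolipid and storage species — with class fractions roughly 30/22/
  18/8% for the four major GPL classes. Standard rows sit at their
  nominal pmol; analyte intensities are exact inverses of the
  quantification rule times log-normal multiplicative noise (default
  CV 5%; the replicate design defaults to 6 = 3 biological × 2
  technical). Compositions were chosen to avoid mass degeneracy (e.g.
  MMPE(c:d) is exactly isobaric with PE(c+1:d), so methylated PE is
  excluded from the default panel).
- **Peak lists**: one peak per species at its class-default adduct m/z
  with uniform(−j, +j) ppm jitter, plus uniform decoys re-drawn to stay
  ≥ 10 ppm from any library entry so decoys test specificity without
  stealing true assignments.
- **GP stacks**: two Gaussian emission components (ordered ~445 nm,
  disordered ~495 nm, bracketing the blue-shifted ordered-phase
  emission) mixed per region with the weight that hits the target GP at
  the 442/496 nm channels; Poisson noise scaled so the brightest channel
  holds SNR² expected counts.
- **Liposome images**: a circular membrane whose radial profile carries
  two inverted-Gaussian troughs of physical width 6 Å (SD) separated by
  the true D_TT; optional two-arc construction for domain tests;
  additive Gaussian noise as a fraction of dip depth. Because trough
  width is physical, recovered D_TT in Å is invariant to pixel size.
- **Growth/turbidity**: model curves with multiplicative (CV 2%) and
  additive (1% of A0) noise respectively, at the acquisition cadences of
  the assays (60-min OD sampling; 2-s turbidity sampling over 6 min).
- **Genetic cross**: two-locus tetrad segregation at 1:1:1:1 (no
  linkage), genotype-dependent viability (default: 68% baseline from the
  observed germination of non-double progeny, 0 for the double mutant).
  The expected double-mutant count among n spores is ⌊n/4⌋ — 47 of 189.

What the generators do *not* emulate: isotopologue envelopes, in-source
fragmentation and chromatographic effects in MS; spectral bleed-through
and photobleaching in imaging; CTF, ice and dose effects in cryo-EM;
lag/diauxic phases in growth. Passing recovery tests therefore shows the
*estimators* are correct and calibrated under the stated noise models,
not that real instrument artifacts are handled. Replicate SDs in real
designs mix biological and technical variance; the generators expose a
single CV and the default apportionment is a stated guess.

## Numerical choices and degenerate inputs

- Matching tolerance comparisons use ≤, so a peak exactly at tolerance
  matches; ties broken by nearest ppm, then intensity.
- mol% conservation holds to 1e-9; metric oracles agree to 1e-12.
- Trough refinement falls back to the integer sample when the parabola
  degenerates (non-positive curvature or edge minima).
- Flat extracted profiles (relative span ≤ 1e-9) are skipped as
  degenerate with a warning; windows leaving the image likewise.
- The logistic fit bounds all parameters positive; fits violating
  K > N0 > 0 or r > 0 are reported failed rather than clamped.
- Zero-variance groups in the t-test raise, except identical constant
  groups which return (t = 0, p = 1).

## Problem sizes in the test suite

Recovery suites use 100 simulated instances per condition (growth
curves, bilayer profiles per true separation), 1,000 random profiles for
oracle-equivalence checks, 10,000 null simulations for the type-I-error
calibration, and 6-replicate lipidome designs — sizes at which the
statistical assertions (3·SE bands, a [0.04, 0.06] rejection window)
have comfortable power while the full suite stays fast.

## Known limitations

- Single-point quantification ignores isotope overlap and response-
  factor differences within a class.
- The adduct-per-class table is an assumption; instruments differing
  from it need a custom chemistry config.
- Ld-domain segmentation assumes one vesicle per image with a roughly
  circular equatorial ring.
- D_TT no-calls are by design conservative (exactly two qualifying
  troughs); heavily overlapping domains on one normal produce no-calls
  rather than averages.
- The permeability proxy is a rate constant, not a permeability
  coefficient in physical units.
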