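# Methods

This note documents the models and procedures behind `oligoscreen`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions.

## Mass arithmetic

All identification rests on exact-mass arithmetic over elemental formulas.
Atomic masses are pinned in `formula.py`: monoisotopic masses from the
AME2020/CODATA evaluation (C = 12 exactly, H = 1.00782503, N = 14.00307400,
O = 15.99491462, Na = 22.98976928 Da), the electron mass
mₑ = 0.00054858 Da, and IUPAC 2021 standard atomic weights for average
masses.  Nothing is fetched at run time.

A positive adduct ion's m/z is `(M + k·m(delta) − z·mₑ)/z`: the ion carries
the adduct atoms but is z electrons short.  At Orbitrap accuracy the
electron term (~0.55 mDa per charge) is resolvable — the reference value
858.3907 for the [M+NH₄]⁺ adduct of C44H56O16 is reproduced only with the
correction.  Supported adducts are [M+H]⁺, [M+NH₄]⁺, [M+Na]⁺ and
[M+2NH₄]²⁺ (ammonium dominates for oligoesters in ammonium-acetate mobile
phase; doubly charged di-ammonium adducts appear for species with roughly
six or more repeat units).  Negative mode is out of scope: these analytes
do not ionise usefully there.

Display convention: masses to 5 decimals, m/z to 4–5 decimals; all internal
computation at full double precision.

## The predicted structure database

Species are multisets of the four repeat units plus a topology/end-group:
cyclic (no end group; mass is exactly the integer combination of repeat
masses), linear free (+H₂O), methyl-capped (+CH₄O) or butanediol-capped
(+C4H10O2).  Canonical labels list families in the fixed order AA-BD,
TA-BD, SeA-BD, LA, so deduplication is string-stable.

The default enumeration (267 species) mirrors the component ranges observed
in a commercial PLA/PBAT film: homopolymer cyclics [LA]₂–₁₂ (lactide is the
smallest lactate ring; single-unit diacid-diol rings exist), [AA-BD]₁–₆,
[TA-BD]₂–₃, [SeA-BD]₁–₄; mixed cyclics up to 9 units for the two copolymer
pairs the material contains (AA-BD/TA-BD from PBAT, TA-BD/SeA-BD from
PBSeT); methyl-capped PLA oligomers to 20 lactate units, optionally
carrying AA-BD units; and free/BD-capped linear PBAT species to 7 units.

Unrestricted four-family mixing is deliberately excluded because repeat
masses satisfy exact integer relations — one SeA-BD plus two LA equals two
AA-BD atom-for-atom (both C20H32O8) — and a database containing both sides
of such an identity cannot be matched unambiguously at any tolerance.  With
the default grammar the minimum mass gap between any two database entries
is 27 mDa, comfortably above the 1 mDa matching tolerance.  A
100 000-species safety cap guards against runaway bounds.

Correctness of the formula algebra is cross-checked in the tests against an
independent oracle that sums free monomer masses and subtracts condensation
waters, and enumeration counts are checked against the closed-form multiset
count.

## Direct-infusion sequence extraction

Pipeline: intensity threshold (default 1 × 10⁴, boundary inclusive) →
ladder detection → database assignment → isotopologue flagging → component
deduplication.

**Ladders.** For each repeat family and charge, chains of peaks spaced by
repeat/z within ±0.001 Da (absolute, as appropriate for per-step spacing
comparisons) are grown greedily from each peak with no in-tolerance
predecessor, choosing at every step the candidate closest to the expected
m/z (ties: higher intensity).  Chains contained in a longer chain of the
same family/charge are dropped; minimum reported length is 2 ions.
Isolated peaks can optionally be matched directly against the database
(singly charged hypotheses only — a lone peak carries no evidence for its
charge state).

**Charge disambiguation.** The m/z of [M+2NH₄]²⁺ for a composition X₂ is
numerically identical to [M+NH₄]⁺ of X, so spacing alone cannot fix the
charge.  As an analyst would, the package reads isotope spacing: a peak
whose spectrum contains a ¹³C companion at +1.00335/z supports charge z,
and peaks only join ladders of a supported charge (peaks with no satellite
remain usable at any charge).  Spacing alone is used for this test — no
intensity-ratio condition — because beyond ~91 carbons the one-¹³C
isotopologue is genuinely more intense than the monoisotopic peak.

**Assignment.** The lowest-m/z ion is inverted to a neutral mass under each
adduct hypothesis at the ladder's charge and matched against the database
within ±0.001 Da; the smallest absolute error wins, ties broken by the
adduct priority NH₄⁺ > H⁺ > Na⁺.  Successive members are the anchor species
plus one repeat per step, with theoretical m/z recomputed from theory (so
error does not accumulate along long ladders).  Two guards: (i) if the
first ion matches nothing, the anchor slides to later members and earlier
ions stay formula-only; (ii) extension may only produce repeat-family
combinations the database grammar itself contains — otherwise the exact
mass identities above would let a lactide peak and an [AA-BD]₂ peak
masquerade as a two-member "SeA-BD ladder".  Assigned components carry
formula-plus-ladder evidence only, i.e. confidence level 3.

**Isotopologues.** Peaks at parent +1.00335/z (¹³C) or +2.00425/z (¹⁸O)
within tolerance and strictly weaker than the parent are flagged and
excluded from component summaries; satellites of consecutive members are
themselves repeat-spaced, so whole satellite ladders disappear this way.

**Components.** One row per unique species label across all ladders,
adducts and charges, with supporting ion/sequence counts and the mass-error
distribution.

## LC-MS/MS annotation

Tolerances at this stage are relative (default 5 ppm); the instrument's
3 ppm dynamic-exclusion setting is stored as metadata only.  EIC peaks are
local intensity maxima over the features inside the m/z window, merged when
closer than 0.05 min (observed isomer spacings are ≥0.25 min); the module
reports multiplicity and apex retention times but makes no attempt to say
*which* structural or stereoisomer elutes where — that is unresolved
experimentally.  Precursors are annotated with the same
hypothesis-ranking logic as direct infusion; unmatched precursors fall back
to a bounded CHNO formula search at 3 ppm (H ≤ 2C+2+N, RDBE ≥ 0).

The diagnostic-fragment generator is deliberately conservative: protonated
sub-oligomers of the candidate's repeat multiset, their water losses,
the same with one free diacid attached (the diacid acylium is exactly
[acid+H−H₂O]⁺, e.g. C8H5O3⁺ at 149.02332 for terephthalate), double water
losses of acid-bearing forms, and end-group-bearing sub-oligomers for
linear species (e.g. protonated methyl lactate at 105.05462).  Every
HPLC-MS/MS characteristic ion listed for cyclic species in the packaged
catalogue falls within 1 mDa of a generated ion — a regression test
enforces this.  Confidence levels are a pure function of evidence:
1 with a reference standard, 2 with ≥1 matched diagnostic fragment,
3 formula-only.

## NMR quantification

mol%ᵢ = (Iᵢ/mᵢ)/Σⱼ(Iⱼ/mⱼ) × 100 over one assigned signal per polymer;
wt% additionally weights by the repeat-unit molecular weight.  Average
(not monoisotopic) weights are used — the sample is the full isotopic
mixture — and end-group mass is neglected (flagged in the output), which is
the standard approximation for high polymer.  Results sum to exactly 100
before display rounding and are invariant to rescaling all integrals.

Under multiplicative integral noise the ratio estimator has a second-order
bias of order σ²·p points (≈10⁻⁶ at σ = 1%), far below the Monte-Carlo
standard error at 1000 replicates; the noise-recovery test therefore checks
consistency with zero bias using a per-component band widened to 3.5
standard errors for the four simultaneous comparisons, plus an absolute
0.05-point cap.

## GC quantification

RF = (area_ref/conc_ref)/(area_IS/conc_IS) — response per unit
concentration relative to the internal standard (invert if your convention
differs).  Concentration in film: (area/area_IS)·m_IS/(RF·m_sample).
Surrogate-RF values stay flagged through every output, mirroring the
reporting convention of italicising surrogate-quantified concentrations.
Replicates are summarised as mean ± sd.  Recovery is 100·measured/spiked.

## Synthetic data

The spectrum generator plants series at theoretical adduct m/z plus
Gaussian jitter truncated at ±2.5σ (default σ = 0.2 mDa, so deviations stay
within half the extraction tolerance and pairwise spacings within the full
tolerance), geometric intensity decay along each series (as observed for
real oligoester distributions), optional one-¹³C satellites at 1.1% per
carbon, and uniform-random noise peaks kept outside a ±5 mDa guard band
around planted peaks so ground-truth scoring is unambiguous.  Members
outside the m/z 150–2000 acquisition window are clipped (noted in the
spectrum metadata); the random-plan sampler only emits series that fit the
window.  All generators are deterministic under a fixed seed.

Not emulated: electrospray ionisation efficiency and suppression, full
isotope patterns (only the one-¹³C satellite), adduct coexistence for a
single species, profile peak shapes, and retention-time behaviour beyond
simple Gaussian bumps.  Passing the recovery tests therefore demonstrates
the correctness of the extraction logic under realistic spacing/jitter/
noise structure, not instrument-level performance on real extracts.

NMR and GC generators invert their quantification equations exactly, with
multiplicative Gaussian noise on integrals/areas (including the
internal-standard area).

Test problem sizes — 20 series per direct-infusion run, 1000 NMR and 500 GC
noise replicates — keep each property test under a minute while leaving the
Monte-Carlo standard errors small against the tested tolerances.

## Known limitations

- Identification tops out at level 2 (probable structure): spectral-library
  search and reference-standard logic beyond a boolean flag are out of
  scope, as are stereo/sequence isomers within a composition.
- The default database grammar is a reconstruction of plausible enumeration
  bounds from the observed component ranges, not a copy of any instrument
  workflow's private database; counts of enumerated species are therefore
  a design choice, documented above.
- Ladder extraction trusts the threshold filter to remove noise; peaks
  above threshold that are neither analytes nor satellites (e.g. solvent
  clusters) would enter chains and surface as unassigned sequences.
- mzML support covers centroided spectra with 64/32-bit float arrays and
  zlib/no compression — the encodings produced by common converters —
  and rejects profile data rather than attempting centroiding.
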