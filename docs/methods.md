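# Methods

## Measurement concept

A cochlear-implant electrode array can stimulate the facial nerve in its
labyrinthine portion, which runs close to the upper basal turn of the
cochlea. The evoked CMAP amplitude recorded over the orbicularis oculi
(periocular channel) and orbicularis oris (perioral channel) depends on the
distance between the stimulating contact and the nerve. Two procedures
exploit this:

1. **Stepwise insertion.** The array is advanced two contacts at a time;
   at each pause the most apical contact (contact 1) stimulates at a fixed
   subject-specific current. The amplitude-vs-steps profile rises to a
   *passage peak* where the tip is closest to the nerve and falls after
   passing it. Under a constant step size, the tip's final contact-slot
   position is estimated as `P = 12 − N_inserted`, where `N_inserted` is
   the number of contacts inserted at the peak. `P = 0` (peak at full
   insertion) is reported but flagged as outside the contact range.
2. **Post-insertion sweep.** Every contact of the fully inserted array
   stimulates in turn. Per channel, the per-contact amplitudes are min–max
   normalized (0 = lowest, 1 = highest response); contacts at or above a
   0.75 normalized threshold are *peaks* and are compared with the contact
   of shortest radiological electrode–facial-nerve distance (EFND):
   *exact* if the peak set contains it, *neighbor* if a contact ±1 away is
   in the set, *none* otherwise. Neighbor matching is array-topological,
   motivated by the even step size: odd contact slots are unreachable by
   `P` when stepping by two.

## Cochlear geometry

The CT "cochlear view" is a 2-D axial reorientation; all distances are
planar by construction. The cochlea is modelled as a logarithmic spiral
`r(θ) = a·e^(−cθ)` with the round window at θ = 0. Parameterizing by the
asymptotic arc length `K = (a/c)·√(1+c²)` makes depth↔angle closed form:

    s(θ) = K(1 − e^(−cθ)),    θ(s) = −ln(1 − s/K)/c.

Defaults `K = 30.0 mm`, `c = 0.195 rad⁻¹` (basal radius ≈ 5.6 mm, duct
domain capped at 29.5 mm) were calibrated against two angular anchors —
the basal turn spans about 200° and a full long-array insertion reaches
the mid turn beyond 540° — and against the qualitative EFND structure
described below. With these defaults, 14.8 mm of arc lie within the first
200° (covering the basal half, contacts 7–12, of a fully inserted long
array) and the FLEX28 tip at 25.55 mm depth sits at ≈ 561°.

Contact `k` of an array with inter-contact spacing `Δ` sits at arc depth
`tip_offset + (N_inserted − k)·Δ`. The tip offset (array tip to contact 1)
defaults to half the inactive length, `(array_length − active_length)/2`,
since the catalogue gives only total and active lengths; it is
configurable.

The facial-nerve canal centre is a point in the plane, placed on the
outward radial ray through the spiral point at arc depth 16.10 mm, offset
1.00 mm beyond the lateral wall (`FACIAL_NERVE_ARC_ANCHOR_MM`,
`FACIAL_NERVE_RADIAL_OFFSET_MM` in `cifns.geometry`). This single
calibration reproduces, at full insertion:

* shortest EFND at contact 6 for Standard, FLEXsoft and FLEX28 (margins
  ≥ 0.25 mm over the runner-up contact),
* shortest EFND at contact 4 for the short FLEX24,
* a second local EFND minimum at the apical end of long arrays (the tip
  re-approaching the nerve in the second turn), absent for FLEX24.

The per-subject duct length and true facial-nerve coordinates of real
anatomies are unknown; this calibration reproduces the *qualitative*
distance structure, not subject-level millimetre values. Real EFND tables
measured from CT can be supplied as CSV (`contact,efnd_mm`) wherever a
profile is consumed.

## Charge arithmetic

Charge per phase in manufacturer charge units: `QU = CU × phase_µs /
1000`; with the protocol's 150 µs phases this is the ×0.15 factor verified
against all 17 recorded current/charge pairs (to ≤ 0.001 QU). The scaling
constant is empirical, not datasheet-sourced, and whether 1 CU is exactly
1 µA is not established — only the CU→QU ratio is used. Printed values are
half-up roundings to 3 decimals of exact decimal products; the package
rounds in decimal arithmetic (`display_round`) because binary-float
rounding turns e.g. 46.7775 into 46.777.

## Forward model (synthetic EMG)

The generator emulates the statistical structure the analysis relies on;
it is not a volume-conduction model.

* **Strength–distance law**: `I_th(d) = I₀(1 + (d/d₀)²)`, the classic
  quadratic threshold model. Defaults `I₀ = 300 CU`, `d₀ = 3.0 mm`. The
  distance scale keeps the tip's second-turn approach (≈ 2× the first-turn
  minimum distance under the default geometry) inside the dynamic range,
  so long-array simulations show the terminal amplitude re-rise.
* **Recruitment**: `A(I,d) = A_max·σ(k(I − I_th)/I_th)` with steepness
  `k = 6`; at threshold the amplitude is `A_max/2`, and for `d → ∞` it
  floors at `A_max·σ(−k)` (≈ 0.25 % of `A_max`), not exactly zero.
* **Channel asymmetry**: perioral CMAP scale 500 µV vs periocular 100 µV
  (×5); periocular stimulation artifact 2000 µV vs perioral 200 µV (×10).
* **Waveform**: each pulse epoch holds a decaying-exponential artifact at
  onset (τ = 0.15 ms, so the tail at the 1.5 ms blanking boundary is
  ≤ 10⁻⁴ of the artifact) and a zero-mean biphasic wavelet (Gaussian first
  derivative) centred at 3 ms latency with 5 ms nominal duration,
  normalized to the requested peak-to-peak amplitude. Latency and duration
  are plausible placeholders for facial muscles, not fitted values; the
  wavelet shape is cosmetic.
* **Noise**: additive white Gaussian, SD 5 µV, independent per channel;
  all draws come from a caller-supplied seed/generator and are bit
  reproducible.
* **Trace layout**: sampling 38.4 kHz; each of the (default 2) pulses gets
  its own 20 ms epoch and epochs are stored back-to-back in one TSV trace
  with a JSON sidecar. The protocol's 100 pps inter-pulse interval (10 ms)
  is metadata on the `StimulusSpec`; cutting stored epochs at the protocol
  spacing would truncate the 15 ms response window, so storage epochs are
  protocol-independent by design.

What the generator does **not** emulate: conduction paths of
heterogeneous tissue (the multiple-peak profiles seen in some real
subjects), the response "breakdown" at too-high stimulation beyond simple
recruitment saturation, electrode impedance variation, muscle fatigue, or
3-D nerve trajectory. Passing tests therefore demonstrate that the
analysis recovers positions when amplitude is a monotone proxy of planar
distance — the method's premise — not that real anatomy satisfies it.

## Amplitude extraction and detection

The response metric is the peak-to-peak voltage of the pulse-averaged
epoch within a 1.5–15 ms post-onset window, after excluding a 0–1.5 ms
blanking window (the amplitude metric of the original recordings is not
specified; peak-to-peak is this package's choice and is recorded in
outputs). The noise floor is the sample SD of the trailing 15 % of the
epoch. The automated stand-in for "just visually discernable from
background noise" flags a response when its peak-to-peak exceeds 8× the
noise-floor SD: the peak-to-peak of ~500 Gaussian samples concentrates
near 6.2 SD, so the conventional 3-SD criterion would flag pure noise;
8 SD leaves headroom of roughly two noise SDs.

Normalization is `(a − min)/(max − min)` per channel across a run.
All-equal profiles raise `DegenerateProfileError` rather than silently
emitting zeros. Ties at the maximum keep every tied contact in the peak
set; ties in the passage-peak search resolve to the earliest step (the
conservative, shallower depth estimate).

A terminal re-rise is flagged when, after the pre-final peak and a
decline, the final step exceeds the post-peak minimum by ≥ 0.2 normalized
units (the separation of passage peak and second approach is narrative in
the source material; the margin is this package's rule). When the global
maximum sits on the final step *and* the re-rise test fires, the final
step is excluded from the passage-peak search.

## Statistics

Spearman rank correlation with average ranks for ties (scipy), two-sided
p-value from the t approximation with df = n − 2. Pooled analysis stacks
one (EFND, normalized amplitude) point per contact, channel and subject; a
least-squares slope is reported descriptively. The published real-data
correlations are not desk-reproducible because subject-level amplitudes
are unavailable; the synthetic cohort instead verifies the sign and the
noise-free limit (ρ ≤ −0.9).

## Problem sizes and reproducibility

The default verification workloads are: a nine-subject synthetic cohort
(seven long arrays, two FLEX24, per-subject facial-nerve jitter within
arc 16.00–16.20 mm and offset 0.85–1.15 mm), and 200 seeded
parameter-recovery runs with facial-nerve placements drawn from arc
15.0–17.0 mm and offset 0.7–1.4 mm at 472.5 CU, the modal recorded
insertion level. Every stochastic path takes an explicit seed; identical
seeds give bit-identical traces, tracks and reports, and output bundles
are tagged with the config hash and seed.

## Known limitations

* 2-D geometry only; EFND is a planar estimate of a 3-D distance.
* One fixed facial-nerve point; no bone-density or conductivity fields.
* The `P = 12 − N` estimator inherits the ambiguity of whether contact 12
  sits inside or at the entrance of the cochlea at "full insertion"; the
  formula is implemented as stated.
* Fixture note: the recorded per-subject ages average 52.56, while the
  summary mean printed alongside them is 53.67; the ages are stored
  verbatim and no mean is asserted.
* Multiple stimulation levels per subject are reduced by a documented
  proxy (lowest level with above-noise responses on every contact); the
  original "best spatial differentiation" rule is not formalized.
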