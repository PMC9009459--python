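# Methods

## Scope and frame conventions

`ivims` couples a parametric synthetic beamline to the vertex-imaging
reconstruction chain it is meant to exercise. The lab frame puts the
origin at the isocenter (center of the head phantom) with the beam along
+Z; with the default 180.5-mm phantom depth the entrance face is at
Z = −90.25 mm. Depth markers are stored internally as absolute depth
(mm from the entrance face); center-relative reporting is a display
convention only. All lengths are mm, times integer ns.

## Synthetic beamline

The generator replaces particle-transport physics with the minimal
stochastic structure the analysis relies on. Per primary:

* **Beam line** — transverse anchor from independent Gaussians
  (σ_X = 1.3 mm, σ_Y = 1.6 mm at isocenter) plus the configured steering
  shifts; direction exactly +Z (divergence off by default). The spot
  monitor (SPM) records the crossing of a virtual plane 100 mm upstream.
  The SPM's ±25 mm aperture is referenced to the steered beam axis — the
  diagnostics sit downstream of the steering dipoles, so a scanned spot
  stays inside the active area even for centimetre shifts.
* **Fragmentation** — per species, a Bernoulli trial with the species
  yield decides whether a fragment is emitted. In-field vertex depth
  follows density ∝ exp(−depth/λ) truncated at the per-event range
  R ~ Normal(nominal_range, straggling σ = 1 mm); λ = 250 mm is the order
  of the carbon nuclear mean free path in water. Production past the
  stopping point is exactly zero — this sharp cutoff is what the erfc
  fall-off fit measures.
* **Emission** — polar angle |Normal(0, σ_ang)| about +Z with uniform
  azimuth; the apparent emission point is displaced laterally by a
  Gaussian whose σ scales with the square root of the remaining path
  (exit scattering). Secondary-origin vertices (a configurable fraction;
  0.5 for H, 0.1 for He) get an extra isotropic 5-mm smear so their
  back-projection is biased, and 30% of He vertices are placed upstream
  in the nozzle region (out-of-field component). These fractions emulate
  the composition of the fragment field, not its microscopic physics.
* **Detection** — each fragment ray is intersected with the front and
  back planes of a 5×5 cm², 55-µm-pitch stack (planes 50 mm apart, front
  plane 140 mm from isocenter at 30° to the beam). Hits are quantized to
  pixel centers (0-based, half-open bins) and written as list-mode rows
  (event ID, timestamp, pixel, lab coordinates). A mirrored −30° second
  stack is available for dual-stack coincidence studies.

All randomness flows from one root seed through deterministically spawned
child generators; reruns are byte-identical.

### Generator calibration

The defaults are calibrated once, against the emulation targets the
analysis chain assumes, and then frozen:

| parameter | H | He | why |
|---|---|---|---|
| yield / primary | 0.36 | 0.21 | front-tracker hit fraction ≈ 1.6% of primaries |
| angular σ (rad) | 0.80 | 0.55 | see below |
| exit scatter (mm·mm^−1/2) | 0.15 | 0.08 | H scatters more than He |
| primary-vertex fraction | 0.5 | 0.9 | fragment-field composition |
| out-of-field fraction | 0 | 0.3 | nozzle-interaction background |

The angular widths matter most. The polar angle needed to reach the
tracker grows from ≈18° for entrance vertices to ≈47° for the deepest
ones; with narrow cones the geometric acceptance collapses with depth,
and the apparent profile fall-off reflects acceptance rather than the
production cutoff — the Z50–range relation then saturates at large
ranges instead of staying linear. Secondary H/He at therapeutic energies
are in reality broadly distributed in angle, so widths of 0.80/0.55 rad
are physically reasonable; they keep the acceptance gradient gentle
enough that Z50 tracks the range linearly (calibration χ²/ndf ≈ 2)
while preserving forward peaking. With these defaults the intrastack
coincidence efficiency comes out near 0.5.

### What the generator does not emulate

No energy loss or stopping-power physics, no dose scoring, no neutron or
photon field, no detector charge sharing, dead pixels or material
response, no nozzle optics, no tissue heterogeneity or motion. Fragment
lines are exactly straight between emission and detection. Passing tests
therefore demonstrate that the *reconstruction and marker chain* recovers
what the generator encodes under realistic statistics and geometry — not
that a physical detector would reach the same accuracy on a patient.

## Reconstruction chain

* **Event building** — a track needs exactly one front and one back hit
  with the same event ID within a symmetric |Δt| ≤ 10 ns gate (the gate
  is configurable; the acquisition only promises "a preset window").
  Events with ≥2 hits on either plane are rejected as pile-up rather
  than best-pair matched: multiplicity leaves the pairing ambiguous.
  Matched + pile-up + unmatched exactly partition the front-registered
  events.
* **Beam correlation** — inner join with the SPM stream on event ID; the
  beam line is the SPM (x, y) with +Z direction. Duplicate SPM records
  drop the event.
* **PCA solve** — closed-form 3×3 least squares per pair (vectorized);
  pairs with |cos angle| > 1 − 10⁻⁶ are flagged degenerate and counted,
  never silently dropped. No miss-distance cut is applied by default,
  and the finite beam-spot size is deliberately not deconvolved; a cut
  flag exists because real data would need one.

## Markers and fits

* **Depth profile** — 1-mm bins (the phantom voxel), window
  [entrance − 40 mm, exit + 40 mm].
* **erfc fit** — weighted (1/√N) nonlinear least squares of
  f(z) = p0·erfc((z − p3)/p2) + p1 via Levenberg–Marquardt (lmfit).
  Initialization is data-driven: p3 from the smoothed raw-histogram
  distal half-max, p2 = 5 mm, p0 = half the plateau, p1 = tail median.
  The default fit window is [h − 35, h + 55] mm around the raw distal
  half-max h: the erfc model has a flat plateau, and fitting the whole
  slowly decaying production plateau lets the edge tilt (p2 inflates,
  p3 biases proximally). The window is configurable.
* **Z50** — solved by bisection on the fitted curve for the distal
  crossing of half the curve's maximum height (the proximal supremum
  2p0 + p1). Background-free, Z50 = p3 identically; positive background
  shifts Z50 distally. Its uncertainty uses the delta method on the
  closed form z50 = p3 + p2·erfcinv(1 − p1/(2p0)) with the fit
  covariance (a resampling propagation was tried first and is
  numerically fragile when the covariance is marginal).
* **Range calibration** — weighted linear least squares of true range on
  Z50. Abscissa errors are mapped to ordinate errors through a
  preliminary unweighted slope, so equal σ reduce exactly to ordinary
  least squares. Coefficients are always re-derived per setup — they
  depend on geometry, yields and acceptance and are outputs, never
  constants. Prediction propagates the parameter covariance plus the
  measured Z50 uncertainty; extrapolation beyond the calibrated span
  warns.
* **Boundaries** — plateau level is the median of bins above half the
  histogram maximum; entrance/exit are the interpolated crossings of
  0.5× that level. Profiles without crossings on both sides (monotone
  ramps) raise.
* **Lateral/vertical fits** — Gaussian fit of the 1-mm-binned transverse
  projection. The vertical (X) profile is heavier-tailed (scattering
  sensitivity), so X fits are restricted to the ±2 sample-sd core.
* **Spot verification** — per shift setting, Δ = SPM mean − fitted
  vertex mean; a line is fitted to Δ versus shift, and the overall
  accuracy is reported conservatively as max |Δ| across settings.
* **Reference range** — on a depth-dose curve, the distal crossing of
  72.5% of the Bragg-peak maximum (midpoint of the 70–75% definition
  band, configurable within it), reported at the center of the
  containing voxel.

## Problem sizes and numerical choices

The verification protocols use 2×10⁵ primaries per scanned spot
(≈1700–1800 reconstructed vertices), six calibration ranges spanning
42.2–147.2 mm, three held-out validation ranges, shift sweeps of
{5, 10, 20, 25} mm on both axes, and six ranges between 50 and 145 mm in
a 150-mm water-like phantom for the inflection-bias study. At this size a
full spot (simulate + reconstruct + fit) takes about one second on one
CPU, and the whole verification study runs in seconds, which makes the
protocols practical to rerun wholesale whenever the generator or the
chain changes.

Degenerate inputs are handled explicitly: near-parallel PCA pairs are
flagged, empty vertex clouds and monotone profiles raise, non-converged
erfc fits refuse to yield Z50, and lateral fits below 100 vertices are
rejected (and excluded-but-counted inside spot verification).

## Known limitations

* The linearity of the Z50–range relation depends on the acceptance
  gradient of the single 30° stack; very narrow emission models or much
  deeper phantoms would re-introduce curvature that a linear calibration
  cannot absorb.
* The erfc fall-off width p2 conflates range straggling, pixelation,
  back-projection smearing and the secondary-vertex smear; it should not
  be interpreted as a physical straggling width.
* Out-of-field and upstream-artifact vertices are modeled only as far as
  they affect the profile and its fits, not as a faithful nozzle model.
* The dual-stack (±30°) mode reproduces the qualitative result that
  interstack coincidence is far less efficient than intrastack; absolute
  dual-stack efficiencies are not calibrated to anything.
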