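# ivims — interaction-vertex imaging and monitoring for carbon-ion therapy

Carbon-ion radiation therapy (CIRT) delivers dose with a sharp Bragg-peak
fall-off, which makes it both precise and unforgiving: a few millimetres of
range error moves the high-dose region into healthy tissue. `ivims` is a
self-contained simulation and analysis package for *interaction vertex
imaging* (IVI), a monitoring technique that watches the secondary charged
fragments (mostly H and He) produced by nuclear fragmentation of the ¹²C
beam in tissue. Fragment trajectories, measured by a small two-plane
pixelated tracker placed downstream of the patient at 30° to the beam, are
approximated by straight lines and back-projected onto the beam axis; the
point of closest approach (PCA) between a fragment line and the beam line
is the reconstructed reaction vertex. Because fragment production stops
where the primary ions stop, the vertex depth distribution carries the
beam range, and its transverse projections carry the beam-spot position.

The package is aimed at medical-physics researchers prototyping IVI
monitoring chains: it provides a parametric synthetic beamline (pencil-beam
spot, fragmentation vertices, forward-peaked emission, detector pixelation,
list-mode readout with event IDs and timestamps), the full reconstruction
chain, and the derived monitoring markers.

## Model and markers

For a (fragment, beam) line pair with unit directions **d**ᵢ and anchors
**a**ᵢ, the vertex is the point **P** minimizing
Σᵢ d²(**P**, line ᵢ), the closed-form solution of
Σᵢ (I − **d**ᵢ**d**ᵢᵀ) **P** = Σᵢ (I − **d**ᵢ**d**ᵢᵀ) **a**ᵢ.

The binned vertex-depth histogram is fitted with a four-parameter
complementary-error-function model

    f(z) = p0 · erfc((z − p3) / p2) + p1

where z is depth in the phantom, p3 the inflection point of the fall-off,
p2 its width and p1 a flat background. Derived markers:

* **Z50** — distal depth at 50% of the fitted curve's maximum height;
  linearly related to the beam range and calibrated per setup with a
  weighted linear fit (range = intercept + slope·Z50).
* **Target boundaries** — threshold crossings of the profile plateau.
* **Spot position** — Gaussian means of the lateral (Y) and vertical (X)
  vertex projections, compared per run with the beam-spot-monitor (SPM)
  mean: Δ = beam − vertex.

## Worked example

Simulate one scanned spot (2×10⁵ primaries, 105.2 mm nominal range),
build tracks, reconstruct vertices and extract markers:

```
$ cat run.yaml
beam:
  n_primaries: 200000
  nominal_range: 105.2
seed: 7

$ ims simulate --config run.yaml --out demo
{"n_hits": 5050, "n_spm": 200000, "front_hit_fraction": 0.01601, ...}

$ ims reconstruct --config run.yaml --hits demo/hits.imslm.tsv \
      --spm demo/beam.spm.tsv --out demo
$ ims analyze --config run.yaml --vertices demo/vertices.tsv
```

Key lines of the analysis report (abridged):

```
"n_vertices": 1784,
"erfc": {"p0": 7.40, "p1": 0.13, "p2": 3.76, "p3": 103.88, ...},
"z50_mm": 103.91,
"z50_err_mm": 0.47,
"lateral_y": {"mean_mm": 0.125, "mean_err_mm": 0.065, "sigma_mm": 1.60, ...}
```

Reading: 1.6% of primaries left a front-tracker hit; the front–back
coincidence builder matched 1784 tracks (intrastack efficiency ≈ 0.56,
pile-up events rejected); the fitted fall-off inflection sits at
103.9 mm versus the true 105.2 mm range, and the Z50 marker (103.9 ±
0.5 mm) is what the linear range calibration consumes. The lateral vertex
mean (0.13 ± 0.07 mm) agrees with the unshifted beam, with a fitted width
of 1.6 mm matching the pencil-beam spot sigma.

Calibration and verification workflows:

```
ims calibrate    --config run.yaml --out calibration.yaml
ims verify-range --config run.yaml --calibration calibration.yaml
ims verify-spot  --config run.yaml --shifts="-5,-10,-20,-25" --axis y
```

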