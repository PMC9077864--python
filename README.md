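# clodscan

Flatbed-scanner dosimetry analysis for **curved contact-lens-type ocular
dosimeters (CLODs)** — wearable radiochromic dosimeters that measure the dose
delivered to the eye lens during radiotherapy.

A CLOD darkens with dose like a Gafchromic film, but unlike a flat film its
curved surface leaves a thin air gap against the scanner glass, so scans carry
**Newton's-ring interference fringes** that corrupt the readout. Spreading an
index-matching *compensating material* (optical grease, soft silicones) in
the gap suppresses the rings. This package implements the complete scanning
and analysis methodology for quantifying that effect, together with a
physics-based synthetic scan generator so every stage is testable without a
scanner:

- **Synthetic scans** (`clodscan.synthetic`): 16-bit RGB TIFF renderings with
  a power-law dose response in the red channel, mode-dependent gain, Fresnel
  fringe visibility, a sphere-on-flat gap profile `t(r) = r²/2R`, the
  reflected-light ring law `1 − V·cos(4πn·t/λ)`, and per-material Gaussian
  pixel noise.
- **Image/ROI I/O** (`clodscan.scan_io`): TIFF reading with dpi tags, channel
  selection, physical-units ROI windows (3.5 mm ≈ 41 px at 300 dpi), ROI
  statistics.
- **Net optical density** (`clodscan.netod`):
  `netOD = log₁₀((M_unexp − M_bkg)/(M_exp − M_bkg))` with first-order
  uncertainty propagation of the three pixel-value SDs.
- **Calibration** (`clodscan.calibration`): nonlinear least-squares fits of
  the dose response `netOD = a·D + b·Dⁿ`, its inverse calibration curve
  `D = a·netOD + b·netODⁿ`, and the analytic sensitivity
  `S(D) = a + n·b·Dⁿ⁻¹`.
- **Uncertainty budget** (`clodscan.uncertainty`): the Devic-style
  decomposition of the relative dose uncertainty into experimental and fit
  components,
  `σ_D,exp(%) = |b + n·c·netODⁿ⁻¹|·σ_netOD / D_fit × 100`,
  `σ_D,fit(%) = √(netOD²σ_b² + netOD²ⁿσ_c²) / D_fit × 100`,
  combined in quadrature.
- **Comparison metrics** (`clodscan.metrics`): dose-difference accuracy,
  sensitivity increase versus a bare air gap, the reflective/transmission
  sensitivity ratio, and scan-uniformity CV.
- **Study orchestration** (`clodscan.pipeline` and the `clodscan` CLI): the
  end-to-end study — render, read out, fit, decompose, rank — as one
  deterministic, seeded run.

## Worked example

`examples/04_full_study.py` runs the default synthetic study (doses
0–100 cGy in triplicate, four materials × two scan modes, accuracy checks at
25 and 70 cGy) and prints:

```
average dose difference (%, over 25/70 cGy and both modes):
  air:  4.28
   DS:  0.33
   SC:  0.27
   OG:  0.12

scan-uniformity CV (reflective mode):
  air: 0.3178
   DS: 0.0495
   SC: 0.0477
   OG: 0.0335

reflective/transmission sensitivity ratio per material:
  air: 2.451
   DS: 2.495
   SC: 2.502
   OG: 2.501

material ranking by accuracy (best first): ['OG', 'SC', 'DS', 'air']
```

Reading the numbers: the *average dose difference* is the accuracy of a
calibrated readout (|measured − delivered|/delivered); the bare air gap is
worst because its strong Newton's rings shift between scans, while optical
grease (OG) nearly index-matches the glass and lens. The *CV* is the
pixel-level uniformity of one ROI; the *sensitivity ratio* recovers the 2.5×
reflective-mode gain built into the generator. The other example scripts
(`examples/01…05`) each exercise one stage — rendering, netOD and fitting,
the uncertainty budget, and the published-benchmark desk check.

The same pipeline is scriptable from a shell:

```sh
clodscan simulate --doses 0,10,25,50,70,100 --material OG --mode reflective \
    --seed 1 --out exposed.tiff
clodscan report --seed 42 --out study_output/
clodscan reproduce-table1
```

## Scope

The package analyzes scans; it does not model dosimeter fabrication or
chemistry, beam delivery, reference dosimetry protocols, or treatment
planning. See `docs/methods.md` for the model, its assumptions, parameter
defaults, and known limitations.
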