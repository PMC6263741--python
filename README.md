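# dlpr — dictionary-learning phase retrieval from noisy coded diffraction patterns

Optical sensors record photon counts, not fields: the measurement of a
complex-valued object wavefront `x = a ⊙ exp(jψ)` is the intensity of its
far-field diffraction pattern, and the phase `ψ` — which carries most of the
structural information in microscopy, X-ray phase-contrast imaging, and MRI
interferometry — is lost at the detector. **Phase retrieval** reconstructs
`x` from `S` coded diffraction patterns

    z_s ≈ |A_s x|²,   A_s = F M_s,   s = 1..S,

where each `M_s` is a known random quaternary phase mask (values in
{0, ±π/2, π}) and `F` is the unitary 2-D DFT. This package implements a
solver for the *photon-limited* regime, where the counts follow
`z_s ~ Poisson(|A_s x|² · χ)` with χ as low as 10⁻⁵ photons per unit
intensity (global SNR ≈ −7 dB), or the Gaussian-noise analogue
`z_s = |A_s x|² + σε`.

## The algorithm

The solver alternates between the planes of the optical system:

1. **Forward propagation** `v_s = A_s x`.
2. **Sensor filtering** — each magnitude `|v_s[l]|` is replaced by the exact
   proximity operator of the noise negative log-likelihood: a closed-form
   positive quadratic root for Poisson counts, the nonnegative root of the
   depressed cubic `b³ + (σ²/2γ − z) b − (σ²/2γ)|v| = 0` for Gaussian noise,
   and plain magnitude substitution `√z` for exact data. Phases are kept.
3. **Backpropagation** `x_half = (1/S) Σ_s A_sᴴ u_s`.
4. **Object-plane sparse modeling** — all overlapping `w×w` patches of
   `x_half` are sparse-coded in the complex domain by orthogonal matching
   pursuit against a dictionary `D` of unit-ball atoms. The pursuit
   tolerance is calibrated statistically,
   `δ = (σ_x²/2)·F⁻¹_{χ²(2w²)}(0.96)`, from a robust estimate `σ_x` of the
   iterate's noise level. The dictionary is learned *online from the iterate
   itself* (complex-domain online dictionary learning: ℓ1 coding by
   ADMM + projected block-coordinate atom updates), or plugged in
   pre-trained on clean images of the same class.
5. **Object update** — the closed-form solution of the quadratic subproblem
   `x = (βγ Σ A_sᴴu_s + Σ R_iᴴ D α_i) / (S βγ + μ)`, an elementwise division
   because both operators have diagonal normal matrices (`μ` is the
   per-pixel patch multiplicity).

Three variants: `dlpr` (in-loop dictionary learning), `prior_plugged`
(fixed class dictionary) and `gsf` (the ablation that skips steps 4–5 —
a Gerchberg–Saxton loop with sensor filtering only).

## Worked example

```python
from dlpr import make_test_suite, simulate_and_retrieve

# constant-amplitude scene with an octant-truncated Gaussian phase surface
scene = make_test_suite((100, 100), seed=0)[0]
for variant in ("gsf", "dlpr"):
    rmse, estimate, history = simulate_and_retrieve(
        scene, noise_model="poisson", level=1e-5, variant=variant,
        seed=0, iterations=20, S=12,
    )
    print(f"{variant:5s} wrapped-phase RMSE: {rmse:.3f} rad")
```

prints

```
gsf   wrapped-phase RMSE: 1.119 rad
dlpr  wrapped-phase RMSE: 0.217 rad
```

At χ = 10⁻⁵ the 12 diffraction patterns together contain roughly one photon
per ten pixels. The sensor-filtered alternating-projection baseline (`gsf`)
retains almost no phase structure (an RMSE of π/√3 ≈ 1.81 rad corresponds to
a useless uniform phase error), while the dictionary-filtered solver
recovers the fringe pattern to ~0.22 rad. `estimate` is the aligned complex
field and `history` holds per-iteration diagnostics.

The same pipeline is available from the shell:

```bash
dlpr simulate --scene-kind truncated_gaussian --noise poisson --level 1e-5 \
     --out obs.npz --scene-out truth.tif
dlpr run --obs obs.npz --variant dlpr --truth truth.tif --out estimate
dlpr evaluate --estimate estimate.npz --truth truth.tif
```

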