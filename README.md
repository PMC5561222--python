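# trxss — time-resolved X-ray solution scattering analysis

`trxss` is a tested, reusable pipeline for analysing pump-probe
time-resolved X-ray solution scattering (TR-XSS) of a photoactivated
sensor histidine kinase: a homodimeric receptor whose LOV photosensor
domains, coiled-coil linker, and DHp/CA kinase module transduce a
blue-light signal through left-handed supercoiling of the linker
helices.  It is written for structural biologists and beamline users who
want to go from difference scattering curves ΔI(q, t) to kinetic
parameters and rigid-body structural descriptors without the original
beamline data or molecular-dynamics infrastructure: a first-class
synthetic-data module generates toy dimer structures, conformer pools,
and noisy time-resolved datasets with known ground truth.

## The model

**Kinetics.**  The difference data are a linear combination of two
time-independent basis spectra weighted by sequentially populated
states,

    q ΔI(q, t) = BS(q) · C(t),

where an intermediate state rises with time constant τ₁ and converts to
a final state with time constant τ₂:

    C₁(t) = τ₂/(τ₁−τ₂) (e^(−t/τ₁) − e^(−t/τ₂))
    C₂(t) = 1 + (τ₂ e^(−t/τ₂) − τ₁ e^(−t/τ₁))/(τ₁−τ₂)

so that C₁ + C₂ = 1 − e^(−t/τ₁) exactly.  Fitting uses variable
projection: for trial (τ₁, τ₂) the basis spectra are the exact linear
least-squares solution, and the q-weighted residual is minimized over a
log-spaced grid with Nelder–Mead refinement.

**Structure.**  Candidate dark/light conformer pairs are scored against
an experimental difference curve with a bounded-scale L1 R factor,

    R = Σ_q |ΔI_exp − c ΔI_theory| / Σ_q |ΔI_exp|,   0.35 ≤ c ≤ 1.6,

minimized exactly over c (weighted median of breakpoints).  Theoretical
curves come from an exact coarse-grained Debye sum over Cα sites,
optionally smeared by a polychromatic undulator spectrum.  Accepted
pairs are quantified by the bend angle χ (centre-of-mass angle over
residues 11–127 / 146–156 / 170–200), the supercoiling dihedral ψ
(centres of mass of the LOV and CA domains of the two chains; positive
Δψ = left-handed rotation), per-residue mean Cα displacement fields, and
Cα double distance difference matrices.

## Worked example

```python
import numpy as np
from trxss import synthetic_data, kinetics, geometry

# ground truth: a toy LOV-kinase dimer, photocycle tau1 = 2 us,
# tau2 = 250 ms, 70% turnover, rotations of 11/12 degrees
truth, base, light_int, light_fin = synthetic_data.make_truth(seed=0)

times = np.logspace(-7, np.log10(5.0), 25)          # 100 ns ... 5 s
data = synthetic_data.generate_dataset(truth, times, noise_sigma=0.02, seed=1)
decomp = kinetics.fit_decomposition(data)
print(f"tau1 = {decomp.model.tau1*1e6:.2f} us")
print(f"tau2 = {decomp.model.tau2*1e3:.1f} ms")

psi_dark = geometry.psi_dihedral(base)
psi_fin = geometry.psi_dihedral(light_fin)
print(f"delta psi (dark -> final) = {psi_fin - psi_dark:+.2f} deg")
```

prints

```
tau1 = 1.93 us
tau2 = 255.5 ms
delta psi (dark -> final) = +11.98 deg
```

The fitted rise times recover the generating photocycle constants from
a 2%-noise dataset, and the final photoproduct state is rotated
left-handedly by ~12° relative to the dark state — the supercoiling
motion the ψ descriptor is designed to report.

A full run (simulate → reduce → fit-kinetics → fit-ensemble → geometry)
is driven by one TOML config:

```
trxss run config.toml --outdir out --seed 7
```

and the individual stages are available as `trxss simulate`, `trxss
reduce`, `trxss fit-kinetics`, `trxss calc-scattering`,
`trxss fit-ensemble`.

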