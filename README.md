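# airdmd

Reduced-order reconstruction of pulsatile airway flow and inhaled-aerosol
deposition statistics via exact dynamic mode decomposition (DMD), with
parametric blending of reduced propagators between breathing flow rates.

The package implements a three-phase analysis pipeline:

1. **Trajectory phase** — fit a DMD model to deposited-particle
   trajectory decks, reconstruct the trajectories, and compare radial
   deposition distributions (uniform bins of width `0.01 R` around a
   carina-like reference point) through the Bhattacharyya overlap
   coefficient.
2. **Fluid phase** — fit and reconstruct velocity-field snapshot decks
   and tabulate per-frame relative L2 errors (mean, maximum,
   region-restricted on wall/inlet/outlet node subsets).
3. **Parametric phase** — blend the reduced operators, truncated bases
   and amplitudes of two models trained at bracketing flow rates
   (`theta = (v_theta - v2)/(v1 - v2)`), eigendecompose the blend, and
   reconstruct the flow at an untrained rate.

Because the reference CFD decks are not publicly available, a
`synthetic` module generates desk-scale stand-ins with the same
statistical structure: a 2.4 s sinusoidal breathing cycle sampled at
`dt = 0.015 s` (160 frames, trimmed to 144 by a trailing low-energy
discard rule), a parametric family of velocity decks on an analytic
Y-bifurcation point cloud whose mode amplitudes are linear in the peak
flow rate (40/50/55/60 L/min), log-normal aerosol ensembles (median
0.42 µm, GSD 3.5, 4390 kg/m³) advected to wall deposition, and exact
linear-propagator fixtures whose spectra serve as analytic oracles.

## Layout

| module | contents |
| --- | --- |
| `airdmd.snapshots` | `SnapshotSet` tensor container, flatten/lagged-shifted matrix arrangement, trailing-frame discard, region views, CSV/VTK/bundle I/O |
| `airdmd.synthetic` | waveform, toy geometry, parametric field family, aerosol sampling, tracer advection, linear fixtures |
| `airdmd.dmd` | exact-DMD fit (SVD, rank truncation, reduced operator, eigenpairs, modes, amplitudes) and reconstruction |
| `airdmd.parametric` | mode alignment, operator/basis/amplitude blending, interpolated reconstruction |
| `airdmd.deposition` | deposited-particle filtering, radial PDFs, Bhattacharyya overlap, trajectory-phase pipeline |
| `airdmd.evaluation` | per-frame relative errors, MRE / max error, region error tables |
| `airdmd.cli` | `airdmd` command-line interface |

## CLI

```sh
# generate synthetic decks for three flow rates
airdmd simulate --flow-rate 40 --flow-rate 50 --flow-rate 60 --seed 1 --out decks/

# fit a model (trailing low-energy frames trimmed by default)
airdmd fit --deck decks/deck_50.csv --out model50/

# reconstruct and evaluate
airdmd reconstruct --model model50/ --frames 144 --out recon.csv
airdmd evaluate --truth decks/deck_50.csv --recon recon.csv --out report/

# blend two trained models at an untrained rate
airdmd interpolate --model model40/ --model model60/ --flow-rate 50 \
    --frames 144 --out interp/

# end-to-end phase drivers (synthetic inputs, fully seeded)
airdmd phase1 --seed 1 --out p1/   # trajectories + deposition PDFs
airdmd phase2 --seed 1 --out p2/   # fluid reconstruction errors
airdmd phase3 --seed 1 --out p3/   # parametric interpolation errors
```

All commands accept `--config config.yml` (YAML, validated against
`airdmd.cli.RunConfig`) to override the waveform, aerosol, flow rates,
rank rule and seeds.

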