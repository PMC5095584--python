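# flimp

Pairwise-separation inference for single-molecule photobleaching microscopy,
with the companion analyses used to characterize receptor oligomers on cell
surfaces: Rician mixture decomposition of separation distributions, a linear
stacked-dimer chain model of oligomer geometry, plane-FRET estimation of the
distance of closest approach to the membrane, and MSD-based mobility
analysis. A synthetic-data module generates every input with known ground
truth, so the whole pipeline can be exercised and validated without
microscope data.

## The problem and the method

Two ligands bound to one receptor complex sit closer together than the
diffraction limit, so a single fluorescent spot hides their separation.
Single-step photobleaching breaks the degeneracy: the intensity trace of a
two-fluorophore spot drops in two discrete steps, and the frames between the
two bleaches show the surviving fluorophore alone. Fitting the mean image of
the two-emitter segment (a sum of two pixel-integrated Gaussians) jointly
with the mean image of the one-emitter segment, sharing the PSF width —
seven free parameters {x₁, y₁, I₁, x₂, y₂, I₂, FWHM} — recovers both
positions and hence the pair separation *d* with nanometre precision.

A measured distance between two noisy positions follows a Rice distribution
around the true separation *r*:

    p(d | r, σ) = (d/σ²) · exp(−(d² + r²)/(2σ²)) · I₀(dr/σ²),

where σ is the combined pair localization error. Under a uniform prior the
posterior over *r* is asymmetric — mass piles against *r* = 0 when *d* ≲ σ —
so each measurement is summarized by a 69% highest-posterior-density
interval, and only measurements whose interval is narrower than the target
resolution (4.8–7 nm) are pooled. The pooled point estimates {dᵢ, σᵢ} are
decomposed into K Rician peaks by expectation–maximization, with K chosen by
BIC = (2K−1)·ln n − 2·log L. Peaks whose position interval reaches into the
bias region (0–6.5 nm, comparable to the resolution) are reported
interval-only, because the Rice noise floor biases fitted positions there.

Peak positions are interpreted with a linear chain model: ligand-bound
back-to-back dimers stack through a face-to-face interface, so an oligomer
binds two ligands whose separation grows linearly — 18.5 nm for a tetramer
plus 7.5 nm per additional dimer (26, 33.5, 41 nm for hexamer, octamer,
decamer), plus a fixed 1.1 nm dye/linker contribution (19.6 nm for the
dye-corrected tetramer; the lone dimer's 12.5 nm is an independent
constant). Species population fractions are estimated by the
interval-overlap rule with 1,000-fold bootstrap errors.

The companion analyses: FRET efficiencies E = 1 − τ_DA/τ_D from donor
lifetimes, fitted against a Monte Carlo model of a donor at height *h* above
a plane of acceptors (rate S = Σ (R₀/rᵢ)⁶, E = S/(1+S)) to estimate the
distance of closest approach; and MSD(ΔT) = ⟨|r(T+ΔT) − r(T)|²⟩ with
D = m/4 from a two-point fit and a triple bootstrap (pairs within tracks,
tracks within data sets, data sets; 200 replicates).

## Worked example

The chain-model prediction table, from the command line:

```sh
$ flimp predict --n-max 5
n_dimers  oligomer  ligand_nm  dye_corrected_nm
2         tetramer  18.5       19.6
3         hexamer   26         27.1
4         octamer   33.5       34.6
5         decamer   41         42.1
```

Each row is the predicted separation between the two ligands of a stacked
chain of n dimers, and the same distance after the dye/linker correction —
the positions at which peaks are expected in a measured separation
distribution.

One separation measurement, from the library:

```python
>>> import flimp
>>> m = flimp.separation_posterior(d_nm=20.4, sigma_nm=1.3)
>>> m.mode_nm, (m.ci_low_nm, m.ci_high_nm)
(20.4, (19.0, 21.7))
>>> flimp.passes_resolution_filter(m, 4.8)
True
```

The posterior mode sits at 20.4 nm with a 69% interval of width 2.6 nm, so
this measurement would be retained at the 4.8 nm resolution threshold and is
consistent with the dye-corrected tetramer at 19.6 ± 0.5 nm.

A full synthetic run — generate two-emitter bleaching stacks for the default
five-species (dimer…decamer) mixture, localize, infer, decompose and
estimate fractions:

```sh
flimp run --seed 11 --n 150 --out report.json
```

prints `K = 6` with peak positions near 12.2, 18.9, 26.7, 34.7 and 42.9 nm
(the generator's species sit at 12.5, 19.6, 27.1, 34.6 and 42.1 nm), and the
JSON report carries positions, weights, the BIC table, the bias-region
report and dimer/tetramer fractions with bootstrap errors. Subcommands
`simulate`, `localize`, `infer`/`decompose`, `fractions`, `doca` and `msd`
expose the individual stages; every stage takes an explicit `--seed`.

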