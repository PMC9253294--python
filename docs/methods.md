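# Methods

## The gating model

The analysis assumes a channel in rapid equilibrium among three states —
unliganded closed (C0), ligand-bound closed (C1) and open (O) — with a
single ligand-binding step of dissociation constant Kd (µM) and a final
closed→open equilibrium constant L (dimensionless).  The relative
occupancies 1 : c/Kd : (c/Kd)·L give

    Po(c) = L·c / (Kd + c·(1 + L)),

which is exactly a Hill curve with unit slope, half-maximal at
EC50 = Kd/(1 + L) and saturating at Po_max = L/(1 + L).  These identities
are the backbone of the package: a fixed-slope Hill fit yields EC50, an
independent Po_max estimate yields L = Po_max/(1 − Po_max), and
Kd = EC50·(1 + L) separates binding from gating.  The model deliberately
excludes multi-ligand binding (Hill slope ≠ 1), kinetics (rates), and
explicit voltage dependence — each holding potential is analyzed
independently with its own (Kd, L).

## Estimation chain

1. **Steady state.**  Each 350 ms voltage-step sweep is reduced to the mean
   and unbiased (n−1) variance of its final 40 ms, where the current is
   stationary.  The cell's own zero-concentration sweep provides the
   baseline (subtracted before taking magnitudes) and, optionally, the
   additive-noise floor.  Inward sweeps at negative voltages are collapsed
   to magnitudes, so both polarities analyze identically.
2. **Hill fits.**  Per-concentration means are fitted with
   I(c) = Imax·c/(c + EC50) by deterministic multi-start least squares:
   EC50 started at every observed concentration, Imax at the maximal
   response, best residual sum of squares wins, exact ties broken toward
   the smaller EC50.  A free-slope mode exists as a diagnostic.  Parameter
   standard errors come from the local curvature (covariance of the fit).
3. **Po_max anchors.**  The wild-type/reference corner uses the externally
   measured single-channel constant `po_max_ref` (default 0.8).  **This
   constant rescales every derived L and Kd** — see the sensitivity note
   below.  Mutant constructs are anchored by stationary noise analysis of
   their saturating reference-ligand sweeps: N = I²/(|i|·I − σ²),
   Po = I/(|i|·N), averaged across cells, then divided by the saturation
   fraction c_top/(c_top + EC50) from the corner's own fit (the top ladder
   concentration does not reach Po_max exactly).  Alternative-ligand
   corners get Po_max by per-cell normalization: each cell's responses are
   divided by the same cell's saturating reference-ligand sweep, which
   cancels the cell-to-cell channel-count jitter exactly; the fitted
   normalized Imax times the construct anchor times the reference
   saturation fraction is the corner's Po_max.
4. **Mutant cycle.**  LnΩ = ln(Kd₁·Kd₄/(Kd₂·Kd₃)) over the four corners;
   the reported coupling energy is the magnitude |LnΩ| on the kT scale
   (the signed LnΩ is kept in the result).  Classification uses a strict
   threshold, default 1.5 kT; a kcal/mol column (×0.593 at 298 K) appears
   in reports only.

Corners whose ligand does not activate the channel are detected before
fitting: the largest per-concentration mean response must exceed
max(1 pA, 6 standard errors of the windowed mean given the zero-sweep
noise).  Such corners yield a cycle with status
`incomplete(no activation: <corner>)` and no classification — never a
spurious Kd.

## Uncertainty

Corner s.e.m.s are propagated by the delta method: on Po_max → L
(dL = dp/(1−p)²), on (EC50, Po_max) → Kd, and on the four corner Kds →
LnΩ as the quadrature sum of relative errors, sem = √Σ(semₖ/Kdₖ)².  A
replicate bootstrap (cells resampled with replacement per corner, fits
warm-started at the full-sample estimates) is provided as an alternative.
The two disagree by construction in one important way: both mutant corners
share the noise-analysis anchor, and an anchor error moves ln Kd₂ and
ln Kd₄ by exactly the same amount, cancelling in LnΩ.  The bootstrap sees
this cancellation and tracks the realized study-to-study spread; the
independent-corner quadrature formula does not, and is therefore
conservative (larger).  Reports carry the quadrature value, matching how
such errors are conventionally quoted; use the bootstrap when a realistic
interval matters.

## Synthetic data

Every sample of a simulated sweep is an independent draw of

    baseline + i_single · Binomial(N, Po(c)) + Normal(0, noise_sd),

so the stationary mean is baseline + N·i·Po and the variance
N·i²·Po(1−Po) + noise_sd² — the exact moments the noise analysis inverts.
Temporal correlation (Markov kinetics), capacitive transients, series
resistance, desensitization and rundown are deliberately absent: the
downstream analysis is a stationary moment method and never uses them.
Consequently, passing tests demonstrate correctness of the estimation
chain under its own assumptions; they do not probe robustness to kinetic
correlations, rundown or seal instability in real recordings.

A four-corner study simulates `replicates` cells per corner, each with its
own channel count drawn uniformly within ±20% of nominal (expression
variability), a zero-concentration sweep, the full ladder, and — for
alternative-ligand cells — a saturating reference-ligand sweep on the same
cell.  Child seeds are SHA-256 hashes of (master seed, role, cell id,
voltage, concentration index), so studies are bit-reproducible across
platforms; reusing a master seed across voltages reuses the same cells
(same N), as the real ±80 mV protocol does, while all gating draws stay
independent.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| ladder | 10, 30, 100, 300, 1000, 2000 µM | spans EC50s of interest; 2 mM is the saturating reference |
| reference corner | EC50 62.64 µM, Po_max 0.8 → Kd 313.2 µM, L 4 | wild-type reference-ligand behaviour at +80 mV |
| alternative ligand (WT) | Kd ×1.5, Po_max 0.7 | modest chemical perturbation |
| mutant corners | Kd ×e^±1.5, Po_max 0.6 | splits a 3.0 kT coupling so all EC50s stay inside the ladder |
| cells per corner | 6 | within the 4–9 cells typical of such datasets |
| N channels | 200 ± 20% per cell | patch of moderate expression |
| i_single | +1.0 pA (+80 mV), −0.8 pA (−80 mV) | outward-rectifying single-channel current |
| baseline | +20 pA (+80 mV), 0 (−80 mV) | small standing current at positive potentials only |
| noise_sd | 10% of the corner's saturating current | dominant recording noise, stressing the noise-floor correction |
| samples/sweep | 20 000 (350 ms) | ≈2300 samples in the 40 ms window |

The cell-replicate structure (one ladder per cell, one reference sweep per
alternative-ligand cell) is an assumption; real experiments may pool
sweeps differently.

## Numerical choices

- Variance uses the same last-40-ms window as the mean; per-sweep
  computation, replicate averaging downstream.
- The additive-noise correction of the noise analysis is **off by
  default**; the pipeline configuration built from a simulated study's
  manifest turns on the `zero_sweep` mode, which subtracts the variance of
  the cell's own ligand-free sweep.  At the default noise level (10% of
  saturating current) the additive variance exceeds the binomial bound and
  the uncorrected estimator is undefined, so quantitative work at high
  noise requires either this correction or quieter recordings.
- The noise anchor needs a few hundred samples in the analysis window to
  estimate σ² usefully; below ≈300 window samples its Po_max estimate
  becomes unstable (the estimator is unbiased, but its spread grows as
  √(2/n_window)).  The CLI demo therefore analyzes at full resolution
  (20 000 samples/sweep) in memory.
- `channel_count` clamps a noise-corrected variance below zero to zero
  (the Po→1 limit); a variance above the binomial bound raises an
  estimation error rather than returning a negative or infinite N.
- Po estimates in (1, 1.05] from sampling error on saturated patches are
  returned as computed; anything larger, or ≤ 0, is an error.  Nothing is
  silently clipped into range.
- Degenerate dose-response data (all responses equal, or none positive)
  raise fit errors; an EC50 outside [min(c)/10, max(c)·10] is flagged
  `extrapolated`.

## Sensitivity to the reference Po_max

`po_max_ref` is not estimated from the data; it rescales all L values
(and, through Kd = EC50·(1+L), all Kd values) coherently.
`gatecycle.validation.po_max_ref_sensitivity` re-runs an analysis over a
grid of assumed values; coupling energies are far less sensitive than the
individual L values because coherent rescalings largely cancel in LnΩ.

## Problem sizes

The recovery experiment behind `analysis/03_parameter_recovery.py`,
`scripts/acceptance.py` and the acceptance test uses 100 seeded studies
per design (null and 3.0 kT coupled) at the default study conditions
above.  The test-suite fixtures use 3–6 cells and 400–2000 samples per
sweep, chosen so each test exercises its property at the smallest size
where the property holds.

## Known limitations

- Po_max ≥ 1 after normalization (a test ligand apparently stronger than
  the saturating reference) is an error, not a clamp; such corners need a
  better reference or a noise-analysis anchor.
- The quadrature coupling s.e.m. ignores the anchor-induced correlation
  between mutant corners (see Uncertainty) and overstates the spread.
- Single-channel current i is an input per (construct, voltage), as
  measured experimentally; no variance–mean parabola fitting is attempted.
- Nonstationary (ensemble) noise analysis, single-channel idealization,
  global fits across constructs and kinetic modelling are out of scope.
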