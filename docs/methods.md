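# Methods

## Two-compartment chamber model

The simulator treats an Ussing chamber as two well-stirred compartments
separated by tissue of area `A` (cm²) and apparent permeability `P_app`
(cm·s⁻¹). The apical (donor) concentration `C_a` is clamped: at
`P_app ~ 10⁻⁵ cm·s⁻¹` over one hour the donor loses well under 1% of its
tracer, so the sink-condition assumption implicit in `P_app = J/c_a` is
satisfied and donor depletion is deliberately not modelled. The receiver
obeys

    dC_b/dt = P_app · A · (C_a − C_b) / V_K

Integration is explicit (forward) stepping at `dt_internal` (default 1 s).
The ODE is linear and non-stiff; at the default step the relative
discrepancy from the closed-form solution `C_a(1 − e^{−kt})`,
`k = P_app·A/V_K`, is below 10⁻⁴, far under every tolerance used
downstream, so an adaptive solver would add nothing. A step coarser than
1/100 of the sampling interval is rejected. Non-finite state aborts the run
with the offending interval and step named.

At each sampling time the state is read out, additive Gaussian
"plate-reader" noise of SD `noise_sd` is applied (readings truncated at 0,
photometric detection cannot go negative), and the receiver is diluted by
`(V_K − V_s)/V_K` — withdrawal of the sample and replacement with fresh
buffer. The basolateral concentration starts at 0 at `t = 0`: the baseline
sample marks the end of the preincubation period, which is carried as
metadata only. The simulator's mass bookkeeping is exact by construction:
cumulative transported mass equals receiver content plus everything
withdrawn, which the tests assert to 10⁻¹² relative.

## Chamber defaults

| parameter | default | unit | why |
|---|---|---|---|
| `chamber_volume` (V_K) | 10 | mL | typical conventional Ussing half-chamber; not fixed by the protocol, configurable |
| `exposed_area` (A) | 0.95 | cm² | standard insert aperture (95 mm²) |
| `apical_concentration` (c_a) | 100 | μmol·L⁻¹ | conventional fluorescein dose |
| `sample_volume` (V_s) | 0.5 | mL | typical plate-reader aliquot; not fixed by the protocol, configurable |
| `sampling_interval` (Δt) | 30 | min | serial-sampling protocol |
| `n_samples` | 3 | — | baseline + two intervals over 60 min |
| `preincubation` | 45 | min | equilibration before t = 0 (metadata) |

## Dilution correction: verbatim vs recursive

The conventional correction uses the previous *measured* concentration:
`c = (c_{t−1}·V_s + c_t·V_K)/V_K`. This is the package default
(`mode="verbatim"`). For runs with three or more intervals it undercorrects,
because the withdrawal at interval `j` keeps depressing every later
measurement and a single-step add-back cannot see that history. The
`mode="recursive"` variant feeds the previous *corrected* value back into
the formula, partially compounding the history; analysis (mirrored by a grid
property test over `V_s ∈ {0.3, 0.5, 1} mL × Δt ∈ {15, 30} min` at 5
samples) shows both forms undercorrect in the linear regime but the
recursive one is strictly closer to truth whenever `V_s > 0`. At the default
3-sample protocol the two coincide (the baseline is zero), which is why the
default remains the conventional form.

Flux uses the *corrected* series — the correction would be purposeless
otherwise — and `P_app` divides the arithmetic mean flux over **all**
intervals by `c_a` (whether a single final interval would be preferable is
not decidable from the protocol; the choice is recorded in the output as
`papp_from`). Reporting units are μmol·h⁻¹·cm⁻² for J and cm·s⁻¹ for
P_app; a units round-trip test pins the conversion to 10⁻¹² relative.

TER input is accepted as already area-normalized (Ω·cm²); raw
voltage/current clamp processing is out of scope. Summaries are plain means
over a recording window (default 0–60 min, inclusive endpoints).

## Morphometric surface correction

Three steps: (i) the follicle area is the **rectangular** product
width × length — the reference arithmetic for this geometry
(0.71 × 0.86 = 0.6106) is a plain product, so that is the default, with an
elliptical option (`π·w·l/4`) available; the circle-equivalent diameter
plus the inter-follicle distance defines a circular packing unit, and the
aperture divided by the unit area gives the follicle count
(round-half-to-even; 95/0.77 → 123). (ii) The FAE and interfollicular
area fractions weight the two linear cell densities into a combined
density. (iii) The factor is the pure-VE density over the combined density.

Two rounding policies are reported side by side. The `verbatim` chain
rounds every intermediate to conventional reporting precision (areas and
diameters 2 decimals, counts and combined density integers, fractions whole
percent) before the next step and is the default reporting surface — it
yields exactly 0.6106 / 0.88 / 0.99 / 0.77 / 123 / 75.10 / 19.90 /
79%:21% / 52 / 2.3 on the default geometry. The `full` chain carries full
precision and lands at 2.307 — the difference (<1%) bounds the rounding
sensitivity. The cell-density length unit cancels in the ratio, so
densities may be entered per 100 of any length unit as long as both groups
use the same one.

Degenerate geometry is handled explicitly: zero follicles (aperture smaller
than one packing unit) gives a pure-VE partition and factor exactly 1;
follicles overfilling the aperture are clipped to full coverage with a
warning; a VE density below the FAE density is allowed but warned about as
biologically implausible.

## Expression normalization

Densitometry: `ratio = band/β-actin` per sample, the reference (VE) group
mean anchored to 100%. Two SEM conventions for the anchor group:
`ve_sem_mode="zero"` reports the reference as 100 ± 0% (within-blot
anchoring, the default for report parity with the field's convention) and
`"propagate"` reports the reference group's own rescaled scatter.

qPCR: per-sample `ΔCt = Ct_target − Ct_ref`, `ΔΔCt` against the reference
group's mean ΔCt, `fold = E^−ΔΔCt` with efficiency `E = 2` (configurable).
Ct values outside (0, 45) or missing are rejected with the sample named.

Surface correction multiplies each non-reference sample value by the factor
**before** group statistics are recomputed (per-sample form). It commutes
with averaging at the mean level, keeps the SEM coherent, and is the
statistically defensible default; a mean-level variant exists for
comparison with summary-only workflows. For qPCR the factor is applied to
folds (not to ΔΔCt), the multiplicative scale on which the correction is
defined.

## Statistics

Classical pooled-variance Student's t (df = n₁ + n₂ − 2), two-sided, via
scipy; Welch and paired variants are options (tissue pairs from the same
animal would argue for pairing, but unpaired is the default absent an
explicit design statement). Zero pooled variance with equal means returns
t = 0, p = 1 by convention. Stars use strict thresholds (*p < 0.05,
**p < 0.01, ***p < 0.001; p = 0.05 is "ns"). A seeded null simulation
(10⁴ comparisons, n = 7 per group) checks that the empirical type-I error
at α = 0.05 stays within [0.04, 0.06].

## Synthetic generators: what they emulate, and what not

* `generate_ter_groups` draws each group from Normal(mean, sem·√n), so a
  simulated group of n animals has the target SEM in expectation. It
  emulates group-structured TER scatter only — no drift, no paired
  animal structure, no viability failures.
* `generate_expression_data` encodes the premise that whole-tissue signal
  scales with epithelial cell content: the test group's raw normalized
  ratio is `true_per_cell_ratio / density_ratio`, under mean-one lognormal
  intensity noise of CV `noise_cv` (Ct values get the additive equivalent,
  σ/ln 2 cycles). With both ratios 2.3 the raw ratios cancel to 100% and
  only surface correction reveals the 230% per-cell signal — the exact
  cancellation the correction exists to undo. Not emulated: blot
  saturation, loading gradients, inter-blot batch effects, reference-gene
  instability.
* The chamber simulator does not model electrodiffusion, TER–permeability
  coupling, apical depletion, or secretagogue (theophylline) responses.

Passing tests therefore demonstrate that the computational chain is
correct and self-consistent under these idealizations — not that any
particular biological value is reproduced; real-data group values depend on
per-animal raw measurements that are not part of this package.

## Problem sizes and determinism

Test-suite and acceptance-script simulations use the study-scale sizes
throughout: 3 sampling points per chamber (5 for the correction-variant
grid), 7 chambers or animals per group, 5 samples per expression group, and
10⁴ replicates for the null-calibration experiment. Every stochastic path
takes a single integer seed; per-chamber streams are spawned via
`numpy.random.SeedSequence`, and identical (parameters, seed) yield
bit-identical outputs.
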