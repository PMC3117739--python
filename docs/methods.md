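# Methods

This note records the models implemented, the conventions chosen where the
underlying formalism leaves freedom, and what the synthetic data do and do
not establish.

## Linear-quadratic isoeffect model

All schedule arithmetic rests on the linear-quadratic (LQ) cell-survival
model without repopulation:

    ln sf = −α·D·(1 + d/(α/β)),    BED = D·(1 + d/(α/β)).

Assumptions: complete sublethal-damage repair between fractions and no
proliferation during treatment. This is adequate for late-responding normal
tissue; for acutely responding tissue and tumors, schedules differing in
overall treatment time are compared only approximately. No time factor is
implemented.

Given a target BED and a fraction number `n` fixed by the reference target,
the isoeffective dose per fraction is the positive root of the quadratic
`n·d²/(α/β) + n·d − BED = 0`,

    d = (α/β)/2 · (−1 + √(1 + 4·BED/(n·α/β))).

The negative root is unphysical and never returned. `BED = 0` returns
`d = 0` (degenerate, allowed). Doses per fraction above 18 Gy trigger a
warning — the LQ model's validity at extreme hypofractionation is debated —
but never an error; the number is still computed. Fraction numbers are
integers throughout; solved doses per fraction are real numbers and are not
rounded to "nice" values (clinical prescriptions such as 2.12 Gy/fx are
themselves non-integral).

Parameters and units: `alpha_beta` (Gy) is the fractionation-sensitivity
ratio — low (≈1.5–3 Gy) for late-responding tissue and prostate tumor,
≈10 Gy for most other tumors; `alpha` (1/Gy) and the clonogen number `N*`
(dimensionless) are needed only for TCP. The LKB volume exponent is named
`volume_exponent` everywhere to avoid the classical collision with the
fraction number `n_fractions`.

## NTD2 (EQD2) conversion

A dose `D` delivered at `d` Gy per fraction maps to the isoeffective total
dose at 2 Gy per fraction:

    NTD2 = D·(α/β + d)/(α/β + 2).

For DVHs, every bin dose uses its own per-bin fraction dose `d_i = D_i/n`
with the schedule's single fraction number `n`; volumes are untouched. The
map is strictly increasing in `D`, so cumulative/differential shape
invariants survive.

## DVH conventions

- Cumulative point `(D, V)`: volume receiving **at least** `D` (left-closed).
- Differential bin: volume between consecutive cumulative grid points,
  carried at the interval midpoint; volume still present at the last grid
  point becomes a terminal bin at the maximum dose, so total volume is
  conserved exactly (to float round-off) by construction.
- Statistics: mean is the volume-weighted bin mean; **median** is the
  volume-weighted 50 % quantile with mass-midpoint interpolation (each bin's
  volume treated as centred on its bin dose) — on two equal bins at 20 and
  40 Gy this gives 30 Gy, and it converges to the cumulative 50 %-crossing
  as the grid refines; **modal** dose is the largest differential bin,
  ties broken toward the lowest dose; min/max ignore bins at or below a
  volume floor of 1e-6 (in the curve's own volume unit). These
  interpolation/tie-break rules are conventions of this package; grid-snapped
  alternatives would be grid-dependent.
- Plan comparison resamples cumulative curves onto the union dose grid by
  linear interpolation (volume 0 beyond a curve's last point). More than
  five plans are processed with a warning (the classical comparison display
  held five).

## File formats

The canonical DVH format (`#radbed-dvh v1`) is plain UTF-8 text: plan-level
`key: value` lines, then per-structure blocks (`structure:`, `volume_cc:`,
`kind:`, `dose_unit:`, `volume_unit:`) followed by two tab-separated
columns. Floats are written in shortest-exact form, so
write → read → write is a byte fixpoint.

The three non-canonical dialects (`eclipse_like`, `pinnacle_like`,
`brainscan_like`) are **synthetic emulations** of typical header-block
planning-system exports, not vendor grammars (those are unpublished and
version-dependent). The deliverable is the pluggable parser registry keyed
by sniffed header signatures — detection never uses the file extension —
plus unit handling (cGy columns are converted to Gy at parse time).
Cumulative curves whose first volume deviates from 100 % (or the stated
absolute volume) by at most 0.5 % are renormalised (export rounding is
common); larger deviations are rejected rather than silently rescaled.
Files are read in place; nothing is copied.

## TCP

Poisson model: `TCP = exp(−N*·sf)` for uniform dose. For heterogeneous
dose the clonogens are partitioned in proportion to bin volumes (uniform
clonogen density):

    TCP = exp(−N*·Σᵢ vᵢ·sfᵢ),    ln sfᵢ = −α·NTD2ᵢ·(1 + 2/(α/β)),

evaluated on the NTD2-converted differential DVH (each NTD2 bin is by
construction at 2 Gy per fraction). This bin-wise partition is the standard
Poisson-LQ extension and collapses exactly to the uniform-dose formula for
a single-bin DVH. Whether a given legacy implementation partitions
clonogens this way is generally not documentable; the choice is isolated in
`tcp_poisson`.

## NTCP (Lyman-Kutcher-Burman, effective-volume reduction)

The DVH (converted to NTD2) is reduced to a single value with the
effective-volume scheme:

    v_eff = Σᵢ vᵢ·(NTD2ᵢ/NTD2max)^(1/n),

`NTD2max` being the largest bin dose with strictly positive volume. Then

    TD50(v_eff) = TD50(1)·v_eff^(−n),
    NTCP = Φ((NTD2max − TD50(v_eff)) / (m·TD50(v_eff))),

with Φ the standard normal CDF (computed via the error function; no series
approximation). The exponent convention is `1/n` inside the reduction and
`−n` in the tolerance-dose power law, with `n ∈ (0, 1]`: `n → 0` is the
serial-organ limit, `n = 1` the parallel limit. `n = 0` itself is rejected
(division by zero in `1/n`); use a small positive value (e.g. 0.01) for
effectively serial organs. Exact fixed points used as tests:
NTCP = 0.5 whenever NTD2max = TD50(v_eff), and v_eff = 1 for uniform
whole-organ irradiation.

## Therapeutic gain

The combination of TCP and the per-OAR NTCPs is not standardised; this
package implements two forms, isolated in `therapeutic_gain`:

- `product` (default): `P+ = TCP·∏ⱼ(1 − NTCPⱼ)` — probability of control
  with no complication under independence; always in [0, 1].
- `difference`: `TCP − Σⱼ NTCPⱼ`, clamped to [0, 1] — the classical
  uncomplicated-control difference score.

Dose-response scans multiply every structure's dose axis by a scale factor
with the fraction number held fixed (dose per fraction scales with the
prescription, as in SIB practice where `n` is locked by the reference
target), recompute NTD2 at each scale, and report TCP, each NTCP and P+
against the prescribed dose `s·D_ref`. The reported optimum is the grid
argmax of P+ (first point on ties); use a finer grid near the peak if the
location matters to better than one grid step.

## Constraint conversion

DV-constraints are stored at 2 Gy per fraction. Conversion to a new
fraction count is BED-preserving **at the constraint's own dose level**:
the limit's BED is re-delivered in `n_new` fractions at the isoeffective
dose per fraction (`d_c = limit_new/n_new` solves the isoeffect quadratic).
Converting at the prescription's dose per fraction instead would couple
constraints to the target prescription and break per-point independence.
The conversion is a bijection: converting back at the original count
recovers the limit to 1e-9.

The shipped database values are illustrative, literature-style placeholders
(Emami/Burman-type ranges) marked non-clinical in the file header; the file
format (tab-separated, commentable, unknown columns preserved) is the
deliverable, and users are expected to replace the numbers with their
institute's data.

## Synthetic data

Targets get cumulative sigmoid DVHs placed so that ≥95 % of the volume
receives the prescription dose (the usual plan-acceptance goal), with
optional small hot/cold-spot admixtures; OARs get stretched-exponential
low-dose tails with an optional higher-dose shoulder emulating overlap with
the target, and a soft terminal cutoff so no volume lingers at
unphysically high doses. Generation is pure given the spec (including its
seed).

What this emulates: the qualitative shapes real plans produce, on realistic
dose grids, with controlled randomness. What it does not: anatomical
realism, dose-matrix physics, planning-system artefacts (coarse rebinning,
truncation at V > 0). Passing tests therefore establish the correctness of
the radiobiological arithmetic and the robustness of the I/O and transforms
to shape variation — not clinical validity on real exports.

The three worked cases (prostate 80 Gy/40 fx reference with 50 Gy nodes at
α/β 1.5; head & neck 69.96/59.36/53 Gy all at 2.12 Gy/fx with a 33-fraction
reference; lung boost 50 Gy/5 fx reference with a 40 Gy/4 fx PTV at
α/β 10) use the printed prescriptions exactly; their matched plans are
synthetic stand-ins for the unpublished patient DVHs. Tumor α/β for the
head & neck and lung cases defaults to 10 Gy (the conventional tumor
value), as no case-specific value is standard.

## Numerical choices

- Isoeffect solve: closed form; cross-checked against bisection to 1e-7 Gy
  over 1000 random draws in the test suite.
- Probabilities: `scipy.special.ndtr`; no clipping is needed except in the
  difference form of P+.
- Validation tolerances: schedule consistency 1e-9 relative; cumulative
  monotonicity and start-at-full-volume 1e-6; differential percent sum
  0.1 after parser normalisation.
- Whole-pipeline cross-validation: every probability from the composed
  operations matches an independently coded, deliberately naive
  straight-line evaluation (plain Python `math`, no shared code) to 1e-9 on
  200 random synthetic DVHs — the software analogue of validating against a
  hand-built spreadsheet. Problem sizes in the test suite and acceptance
  script (200 DVHs, 1000 oracle draws, ~150-point dose grids) keep the full
  run within seconds while exercising every code path.

## Known limitations

- No repopulation/overall-time correction (by design; see above).
- LQ validity above ~18 Gy per fraction is debated; the package warns and
  proceeds.
- The LKB reduction uses NTD2max from the DVH grid; extremely coarse grids
  bias NTD2max low. Import at the planning system's native resolution.
- Only the effective-volume reduction and probit NTCP are implemented (no
  relative seriality, no EUD-based reduction); no confidence intervals on
  TCP/NTCP parameters.
- Dialect parsers are emulations; real vendor exports will generally need a
  small new parser registered via `radbed.io.register_dialect`.
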