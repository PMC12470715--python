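# Methods

## Model structure

`vasosim` simulates lower-limit (threshold-triggered) vasopressor control
of systolic blood pressure as two coupled discrete-time modules.

The *blood-pressure generation* module is purely linear: every milligram
of drug entering at minute `s` — whether as a bolus or as one minute's
worth of infusion — launches a kernel-shaped elevation waveform
`f(t − s)`, and waveforms add. Linearity is a deliberate simplification:
over a 100-minute window drug accumulation, metabolite effects and the
saturating upper part of a sigmoidal dose–response curve are unlikely to
dominate, and the rising limb of such curves is commonly approximated
linearly in practice. No receptor or compartment pharmacokinetics are
modeled, and no drug-specific salt/base equivalence is applied; doses are
in reference-drug units.

The *vasopressor administration* module observes the generated sBP only
at measurement minutes (every 5 minutes, minute 0 included — the NIBP
premise), so the control loop has an intrinsic sampling delay on top of
the kernel's onset delay. Within a measurement minute the order is:
measure first (the reading includes every dose placed at earlier
minutes), then command; a commanded bolus contributes from that same
minute through `f(0)` (zero for the reference kernel, giving an implicit
onset delay).

## Reference kernel

The true unit-dose response curve of any particular vasopressor must be
measured; the package ships a documented stand-in with the qualitative
features that matter for closed-loop behaviour — delayed onset, early
peak, minutes-scale washout, finite support:

    f(t) = peak_effect · t / t_peak                     t ≤ t_peak
    f(t) = peak_effect · exp(−λ (t − t_peak))           t_peak < t ≤ t_support
    f(t) = 0                                            t > t_support

with `λ = ln(1/tail_fraction)/(t_support − t_peak)`, so the curve decays
to `tail_fraction` (default 5 %) of its peak before truncation. Defaults:
`t_peak = 2` min, `t_support = 10` min, `peak_effect = 0.4` mmHg/mg. The
default full bolus is `M = 40` mg, making a single bolus peak at 16 mmHg
— a clinically plausible pressor response. All four parameters and `M`
are configuration-exposed, and a measured kernel can be loaded from CSV.

## Baseline profile

The generator emulates the intended clinical scenario — induction
hypotension, a transient hypertensive response to surgical stimulation,
sustained hypotension — as a monotone-cubic (PCHIP) interpolation through
phase control points. The default phase parameters (plateau 66.5 mmHg,
stimulation peak 110 mmHg at minute 32 within a 24–60 min window) were
calibrated once so the noise-free default profile reproduces the
reference untreated-baseline summary statistics (PTBT 77.2 %,
MVBT ≈ 12.9 mmHg, average sBP ≈ 75.3 mmHg); they then stay fixed. The
profile is deterministic; per-run variability enters as an independent
uniform ±5 mmHg offset at each minute. The ±5 % effect noise is likewise
uniform: both sources are described only as bounded random fluctuation,
and a bounded uniform draw is the least-committal distribution consistent
with that. Noise is applied multiplicatively to the per-minute *total*
ΔBP after superposition, not per waveform.

## Controller details

All four algorithms trigger on readings strictly below 85 mmHg
("drops below"), while the PTBT metric counts samples at or below the
threshold (inclusive, per its formula). The two conventions are kept
independently; they are not reconciled.

For C and D the initial infusion rate is `C0 = M/Δt` with `Δt` the
interval between the first two boluses — the rate that would have
delivered the second bolus continuously over the waiting time. The
titration rule afterwards is: raise the rate by ×1.25 on any
sub-threshold reading, hold it inside [85, 105], hold (C) or suspend (D)
above 105, capped at `4·C0` to prevent wind-up. Once started the infusion
never stops in C; in D a suspension stores the current rate and resumes
it unchanged on the first reading back at or below 105 (least-surprise
policy; only "suspended" is specified). Boluses continue per B's rule in
both. Suspension decisions use the 5-minute readings only, consistent
with intermittent monitoring.

## Run design and seeding

Defaults: 100-minute window, 1-minute steps, 10 runs per batch, metric
threshold 85 mmHg, provisional MDPE/MDAPE targets {85, 90, 95, 100, 110}.
A run seed spawns two independent substreams (baseline noise, effect
noise) via `numpy` `SeedSequence`, so disabling one noise source leaves
the other stream unchanged; batch run `i` uses seed `base_seed + i`.
Generated sBP is never clamped; metrics operate on whatever positive
values the loop produces.

## Numerical choices

- The "observation period" denominator in PTBT, MVBT, average sBP and
  average excess is the sample count (101 on the default grid), applied
  identically so the identity
  `average excess = average sBP + MVBT − threshold` holds to machine
  precision (it is then an exact algebraic identity:
  `max(x−T,0) = x + max(T−x,0) − T` summed over samples).
- Superposition is evaluated as a discrete convolution
  (`numpy.convolve`) and is tested against a brute-force double loop to
  1e−12 relative error.
- Medians of even-length samples are the mean of the central order
  statistics; cross-run SDs use the sample (n−1) denominator.
- Per-run MDPE equals `100·(median(sBP)/T − 1)` because PE is a strictly
  increasing affine transform of sBP; this closed form is used as an
  independent cross-check, not as the implementation.

## What the synthetic conditions do and do not show

The shipped defaults define a single stylized scenario: one baseline
shape, bounded uniform noise, a stand-in kernel, and a simple titration
rule. Under them the simulator reproduces the expected qualitative
physiology — untreated baseline worst on PTBT/MVBT, half-dose-only
dosing (B) weakest among the active strategies, full boluses (A)
intermediate, continuous infusion (C, D) best on hypotension metrics but
highest on average excess, and D ≈ C on time below threshold.

Two quantitative caveats. First, absolute metric values depend strongly
on the kernel, bolus size and titration rule, none of which correspond
to a specific measured drug; only orderings and identities are meaningful
claims here. Second, with this parameterization the infusion settles
~5–10 mmHg above the trigger threshold, so readings rarely exceed
105 mmHg outside the stimulation phase; D's suspensions are therefore
infrequent, and the expected small MVBT penalty of suspension (rebound
dips while the infusion rebuilds) is near the resolution of a 30-run
Monte-Carlo comparison — D and C are statistically close on MVBT rather
than cleanly separated. Real data would add features the generator
omits: autocorrelated measurement error, drifting baselines between
runs, inter-patient response heterogeneity, and co-interventions such as
fluid therapy. Passing tests therefore validate the mechanics and the
metric algebra, not clinical performance.

## Problem sizes

All shipped experiments use the full 100-minute grid. Test batches use
10 runs; the ordering checks aggregate 3 batches (30 runs) per
condition, enough to separate every ordering that is not a documented
near-tie. The acceptance script runs 10 runs per condition.
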