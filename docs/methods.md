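# Methods

This note documents the model equations as implemented, the default
parameterization and why it looks the way it does, the numerical choices,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Pharmacokinetic component

Drug amounts (µg) evolve in a well-mixed compartment network.  Every flow
uses one saturable primitive (`il21pkpd.pk.saturating_rate`),

    rate(x) = w·x / (1 + α·x),

applied per enabled transition (constants w, α) and per degrading
compartment (constants d, β).  α = β = 0 gives linear kinetics; large β
approaches zero-order elimination.  The primitive is a single pluggable
function: passing an alternative callable to `pk_rhs` changes the kinetic
law everywhere without touching the solver (the compiled fast path covers
the default form only).

Topology is data, not code.  The IV system has 4 compartments — plasma
exchanging bidirectionally with three secondary tissues, all of which may
degrade drug.  The SC/IP system has 8: a depot chained through three
absorption compartments into plasma, plus a depot→plasma shortcut
(non-sequential absorption), plus the same secondary tissues.  Validation
enforces reachability from the dosed compartment.  A `strict`-off escape
hatch is not provided: alternative structures for comparison are built as
connectivity variants at the fixed compartment counts.

Directional flows are parameterized independently: "reverse" transport is
simply a second enabled transition (j→i) with its own constants.  The
forward rate depends on the source amount only.

The target tissue is not a compartment.  Tissue concentration is slaved to
plasma concentration through a dimensionless blood:tissue ratio s,
u = x₀/(V_plasma·s), so the PD side reads drug levels without removing
mass from the PK system.  s is route-specific, constrained to the
physiologically plausible band [1, 100], and deliberately the last
parameter estimated (see Calibration).

State is augmented with a cumulative-degradation tally integrated by the
same RK4 step, which makes the mass balance (injected = in-system +
degraded) checkable to machine precision at any time.

## Pharmacodynamic / disease component

Six states at the tumor site: NK cells N, CTLs C, per-cell cytotoxic
proteins p_N and p_C, a memory factor Mem, tumor cells T.  With
sat(u; h) = u/(h+u):

    dN/dt   = a_N − µ_N·N − i_N·sat(u; h_N)·N
    dMem/dt = a_M·sat(u; h_M) − µ_M·Mem
    dC/dt   = a_C + σ·Mem·C·(1 − C/D_max) − µ_C·C
    dp_N/dt = µ_pN·(g_N·sat(u; h_pN) − p_N)
    dp_C/dt = µ_pC·(g_C·sat(u; h_pC) − p_C)
    dT/dt   = r·T·(1 − T/K) − (k₁·N·p_N + k₂·C·p_C)·T

Each drug effect saturates with its own half-saturation constant.  Two
structural choices deserve comment:

* **Cytotoxic proteins are purely drug-induced** (zero baseline).  Without
  drug the effectors carry no armed payload, so the PBS control is an
  *exact* logistic curve in T and the baseline immune states are an exact
  fixed point.  This keeps the growth stage of calibration clean (r, K are
  identified from controls without a baseline-kill confounder) and matches
  the biology the model encodes: IL-21's contribution is the arming of
  effectors, not their homeostasis.  `drug_free_logistic` still handles a
  nonzero baseline kill κ₀ analytically (effective rate r−κ₀, capacity
  K·(1−κ₀/r)) for user-modified parameter sets.
* **Peak-sensing vs coverage-sensing.**  NK inhibition has a high
  half-saturation (h_N = 0.05 µg/ml, near the tissue peak after a 50 µg
  dose), so NK losses track dose *magnitude*; memory accumulation has a low
  one (h_M = 0.002 µg/ml), so CTL drive tracks the *time* tissue levels
  stay above threshold.  This separation is what lets the model produce
  both a 5–50 µg/day efficacy plateau (extra dose buys CTL drive but costs
  NK availability) and a genuine fractionation benefit (splitting a dose
  extends coverage without deepening NK loss).

## Default preset ("calibrated-style")

`presets.py` is the single source of the default parameterization and the
ground truth behind the synthetic-data generator.  No murine measurements
ship with the package, so the preset is a plausible-range parameter set
constructed once to exhibit the documented systemic-IL-21 phenomenology,
and then frozen:

* serum kinetics: terminal plasma half-life ≈ 1–2 h (clearance ~16/day),
  SC/IP peaks of ~4 µg/ml after 50 µg, IV peak 25 µg/ml (= 50 µg / 2 ml);
  mild saturation on SC absorption (α = 0.01 1/µg) and on secondary-tissue
  degradation (β = 0.05 1/µg), with the IP route linear;
* immunology: baseline NK pool 10⁷ cells suppressed to ~12% of baseline
  under the standard regimen; CTL ceiling D_max = 10⁶ (B16,
  non-immunogenic) or 2×10⁶ (RenCa, moderately immunogenic) reached after
  roughly a week of daily dosing; CTL-dominant killing k₂ = 10·k₁;
* growth: r per tumor × onset preset (0.52/day for B16-early), K = 3×10⁹
  cells; PBS controls pass ~1000 mm³ between days 17 and 20.

Under this preset the day-20 endpoints give: a 29% lower tumor mass for
25 µg q12h vs 50 µg q24h at the same 800 µg total, with < 2% further
change below the 12-h interval; a 21% gain for day-1 vs day-3 onset and a
2.1× burden for day-10 onset; a 14% spread across the 5–50 µg/day plateau
with clear dose-response outside it; and no eradication anywhere.  These
are the package's own numbers, recomputed by `scripts/acceptance.py`.

Route-specific defaults for s are 30 (SC), 20 (IP), 25 (IV).

## Numerics

* Fixed-step classical RK4, default dt = 0.002 day (~3 min of model time),
  compiled with numba.  Dose events are snapped to the nearest grid point
  and applied as instantaneous state increments; the stored state at an
  event time is post-bolus.  Doses scheduled beyond the simulation horizon
  are not administered (common-endpoint scans rely on this).
* Convergence: on the drug-free logistic benchmark the global error decays
  at fourth order; halving dt from the default changes day-20 volumes by
  < 0.1% (tested).  Mass balance holds to ~1e-14 relative.
* Negative states beyond a small tolerance raise `IntegrationError`
  advising a smaller step; tiny negative excursions are clamped to zero
  inside rate evaluations only.
* Calibration objectives integrate at dt = 0.01 day for speed (error well
  below data noise); scans in the test-suite run at dt = 0.004, headline
  reports at dt = 0.002.

## Calibration

Stage order is strict — (1) PK per route, (2) k₁ from T-cell-neutralized
arms with k₂ = 0 and then k₂ from NK-neutralized arms with k₁ = 0, (3)
(r, K) from PBS controls, (4) s per route from early-onset treated arms,
bounded to [1, 100] — each stage freezing earlier results.  Residuals are
raw squared differences by default with a 1/SEM² weighting switch; the
recovery experiments use the weighted form because tumor variance is
strongly proportional and late time points otherwise dominate.

Stage 2 needs a tissue coupling that only stage 4 estimates.  The protocol
therefore runs a provisional s (geometric mid-range, 10) through the first
pass, then repeats stages 2→3→4 in damped Gauss–Seidel sweeps (the s
update is geometrically interpolated with its previous value).  Because
affinities and s trade off along a soft ridge — the same ridge that makes
model predictions robust to two-fold s changes — the protocol ends with a
*joint polish*: a multi-start Hooke–Jeeves refinement of
(log k₁, log k₂, log s per route) against all tumor arms simultaneously,
seeded at the staged solution.  Staged per-stage results remain in the
report; the polish supplies the final point estimate.

The optimizer is a classical Hooke–Jeeves pattern search (exploratory
coordinate probes, pattern extrapolation moves, step halving on failure,
monotone descent, bound clipping) restarted from seeded Latin-hypercube
draws; rates are searched in log10 space.  Every fit retains its full
ensemble (default ten sets).  An ensemble is *accepted* when, across probe
regimens (50 µg daily, 25 µg twice daily, 12 µg daily, 50 µg 3×/week), the
relative spread of its members' predictions stays within 10% — the
unified-predictions criterion.  The tolerance is configurable; 10% is a
package default, chosen as "differences an experimentalist could not
distinguish at cohort SEMs".

`compare_structures` fits alternative topologies to the same profile,
ranks by SSE with near-ties (within 5%) broken toward fewer compartments,
and marks the best accepted structure as selected.

## Synthetic data

The generator emulates the study design, not any particular dataset:
single 50 µg SC/IP/IV serum profiles on a dense first-day schedule; tumor
cohorts measured ~3×/week (default B16-early days 3–20), n = 6–10 mice;
PBS, treated, NK-neutralized (k₁ = 0) and T-cell-neutralized (k₂ = 0)
arms; euthanasia censoring at 1000 mm³ (an animal's crossing measurement
is its last; later cohort means and SEM = SD/√n use survivors only).

Noise has two documented levels, chosen as generator defaults because the
source cohorts report only means±SEM: a lognormal animal-level scale
factor (CV 15% by default; 10% in the recovery experiments) multiplying
the arm's model trajectory, and proportional per-reading noise (CV 10%
default; 5% in the recovery experiments).  Per-animal trajectories are
scaled copies of one arm-level simulation — between-animal differences in
*shape* (growth-rate heterogeneity, immune variability) are not emulated,
so passing recovery tests demonstrates pipeline correctness under the
stated noise model, not robustness to real biological heterogeneity.
Assay detection limits and immunogenicity-driven PK drift are likewise out
of scope.

A manifest (seeds, cohort sizes, noise, every ground-truth value) is
emitted with each training bundle and regenerates it bit-for-bit.

## Recovery and validation experiments

`recovery_experiment` draws seeded bundles at 5% measurement noise, runs
the full staged calibration (template initialized at the preset: immune
constants are treated as known, as in staged experimental practice, while
k₁, k₂, r, K and s are re-estimated from the data), and reports the pooled
median relative error of (r, K, k₁, k₂, s) plus R² on the held-out
late-onset and low-dose arms.  Three bundles keep the experiment inside a
few minutes; growth parameters recover to well under 5%, affinities to
roughly 5–20%, and s — the weakly identifiable direction of the ridge —
anywhere from a few percent to ~2×, with validation R² ≥ 0.93 throughout.
That pattern is the point: predictions are pinned down much harder than
the (k, s) decomposition, which is exactly what the two-fold-s sensitivity
check (`s_sensitivity_check`, R² ≥ 0.99) quantifies.

## Known limitations

* The PD structure is one faithful realization of the documented
  qualitative constraints; the exact published supplementary equations may
  differ in detail.  The RHS is a single replaceable function.
* The tissue coupling collapses biodistribution into one ratio s; anything
  with tissue-specific kinetics (e.g., depot-proximal tumors) is outside
  the model.
* No toxicity model: the low-dose findings speak to efficacy only.
* Deterministic mean-trajectory disease model — no per-animal stochastic
  dynamics, no spatial structure, no angiogenesis or regulatory-T-cell
  effects.
* The fractionation benefit size depends on the preset's clearance and
  half-saturation constants; the robust claims are the orderings and the
  plateau, not the exact percentages.
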