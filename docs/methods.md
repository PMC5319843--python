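# Methods

## Model and assumptions

The package integrates a three-variable piecewise-smooth ODE system for a
population split into nomads $n_1$, colonists $n_2$ and a dynamic
carrying capacity $K$:

$$
\dot n_1 = -r_1 n_1 + s_{12} n_2 - s_{21} n_1,\qquad
\dot n_2 = r_2 n_2\Big(\tfrac{n_2}{\min(A,K)}-1\Big)\Big(1-\tfrac{n_2}{K}\Big)
          + s_{21} n_1 - s_{12} n_2,
$$

$$
\dot K = 1 - n_2 \quad\text{(unbounded habitat)}\qquad\text{or}\qquad
\dot K = (1-n_2)(1-K/K_{\max}).
$$

Assumptions baked into this form:

* **Reduced units.** The habitat regeneration rate and the per-colonist
  destruction rate are scaled to 1, so the long-term carrying capacity
  (the colonist density at which the habitat is stationary) is exactly 1,
  and $r_1, r_2, r_s$ are ratios to the habitat-change rate. The general
  two-parameter habitat law is not exposed: every published result uses
  the reduced form, and the scaling is lossless.
* **Deterministic continuum.** Populations are large enough that
  demographic noise is ignored; "extinction" in finite time never happens
  literally, which is why classification uses an explicit floor (below).
* **Switching is conservative.** The switching terms move organisms
  between sub-populations at rate $r_s$ without birth or death; they
  cancel exactly in $\dot n_1 + \dot n_2$ (a tested invariant).
* **The Allee clause.** $\min(A, K)$ is evaluated pointwise with no
  smoothing, so colonial growth can never be positive once $K \le A$.

## Parameters

| symbol | meaning | units | typical |
|---|---|---|---|
| $r_1$ | nomadic decay constant | 1 / scaled time | 1–100 |
| $r_2$ | colonial growth constant | 1 / scaled time | 10–1000, $\gg r_1$ |
| $r_s$ | switching constant | 1 / scaled time | $10^3$–$10^5$, $\gg r_2$ |
| $A$ | Allee critical capacity | population (units of $n^*=1$) | 1.001 for the paradox regimes; $<1$ for viable pure colonies |
| $K_{\max}$ | habitat cap (optional) | capacity | 7.5–20 |
| $L_1, L_2$ | switching levels | capacity | bracketed by the theory bounds |

The time-scale ordering $r_s \gg r_2 \gg r_1 \sim 1$ is what makes the
alternation argument work: switching is effectively instantaneous on the
growth time scale, and growth is fast on the habitat time scale.

## Survival theory

For $A > 1$, recolonization succeeds only if the nomadic population at
the end of a nomadic phase exceeds a critical level $B$ with

$$A = B - (1-B)\,W_0\!\big(\tfrac{B}{1-B} e^{B/(1-B)}\big),$$

inverted here by bracketed Brent root finding (tolerance $10^{-10}$,
expanding bracket), which is safe because the forward map is monotone.
Two facts about this map matter in practice:

* **Saturation.** $A(B) \to 2$ from below as $B \to \infty$
  (asymptotically $A \approx 2 - \tfrac{2}{3(B-1)}$), so the inverse
  exists only for $A \in (1, 2)$; `critical_from_allee` raises beyond it.
  For $B \ge 10^4$ the forward map itself switches to this series, because
  the direct Lambert-W evaluation near its branch point loses
  $\mathcal{O}(\sqrt{\varepsilon})$ precision that the $(B-1)$ prefactor
  amplifies.
* **Finite-rate correction.** $B$ is exact only in the limit
  $r_s \to \infty$. At finite $r_s$ the nomad-to-colonist conversion takes
  $\mathcal{O}(1/r_s)$ time, during which the incoming colony sits below
  $A$ and bleeds the integrated Allee deficit plus the decay of the
  yet-unswitched nomads:

  $$\Delta B \approx \frac{r_1 B + \tfrac{1}{2} r_2 B^2}{r_s}.$$

  An adaptive policy triggered exactly at $B$ therefore arrives *below*
  the Allee level and dies — at $r_s/r_2 = 100$ the deficit
  ($\approx 0.006$) exceeds the margin $A - 1 = 0.001$ of the standard
  growth scenario. The engine's default adaptive entry level is
  $B + \Delta B$ (`corrected_critical_level`); the correction is derived
  from the conversion dynamics, vanishes as $r_s \to \infty$, and restores
  all the idealized rule's qualitative behavior. The downstream results
  are insensitive to its exact size: the long-run plateau onset moves by
  only a few percent when the entry margin is varied several-fold.

The switching-level bounds $L_1 > Be^B/(e^B-1)$ and
$L_2 < L_1 + \tfrac1{r_1}\ln\frac{L_1+W_0(-L_1e^{-L_1})}{B}$ are strict;
equality cases are classified as not guaranteed to survive. For
$L_1 \le 1$ the second bound's logarithm argument collapses to zero
(principal-branch identity $W_0(-L_1e^{-L_1}) = -L_1$) and no admissible
$L_2$ exists, reported as `None`.

## Integration

* Adaptive explicit Runge–Kutta (scipy `RK45` by default) with relative
  and absolute tolerances $10^{-9}$.
* The right-hand side is discontinuous at threshold crossings, so the
  solver runs segment by segment: terminal events locate each crossing,
  the switching branch (and, for the adaptive rule, the thresholds
  themselves) is updated at the event time, and integration restarts.
  Within a segment the switching rates are constants and the system is
  smooth except for the mild $\min(A,K)$ kink.
* Event directions: fixed-rule crossings are armed in the direction that
  can actually occur next (K oscillates through $L_1$ during a switch-out,
  so both directions arise over a cycle); adaptive-rule crossings are
  direction-filtered — $n_2 - K$ rising, $n_1 - B$ falling — matching the
  derivative conditions of the optimal rule. Threshold reassignments that
  land the state exactly on a threshold rely on the event machinery's
  sign convention to fire the follow-up crossing immediately.
* Simultaneous events (within $10^{-10}$ relative) are processed with
  policy reassignments before branch re-evaluations; any fixed order is
  consistent, this one keeps thresholds current.
* Rate evaluation clamps $n_1, n_2$ at 0 (solvers probe slightly negative
  values near extinct states) and floors $K$ at $10^{-9}$ where $1/K$
  appears, since the colonial law is singular at $K=0$ and the model does
  not define behavior there. Reported trajectories clamp populations at 0.
* $L_2 = \infty$ (adaptive rule between exit and re-entry) is a sentinel:
  the corresponding event is simply not armed, no infinity enters the RHS.
* Accuracy gate: refining both tolerances tenfold moves every shipped
  scenario's final state by well under 1% (tested), the standard
  self-consistency check for this kind of run.

## Classification and cycle statistics

* **Extinction floor** $10^{-6}$ at the end of the horizon, with horizons
  at least 5 decay times $1/r_1$. The continuum model never reaches zero;
  the floor makes outcomes testable. All thresholds live in `SimOptions`.
* **Cycles** are anchored at colonial-entry events ($K$ rising through
  $L_2$, or the adaptive $n_1 = B$ trigger) — an unambiguous marker under
  both policies. Per-cycle maxima of $n_1$, $n_2$, $K$ come from the
  solver's natural output points, which cluster at events.
* **Growth vs. periodic survival**: a surviving switching run counts as
  long-term growth when the per-cycle peak $K$ still rises by more than
  0.1% per cycle across the last three cycles (the trailing partial cycle
  participates; its running peak can only underestimate). The 0.1%
  epsilon separates genuine growth (~10%/cycle) from integration jitter
  (~10⁻⁶) with three orders of margin on either side.
* **Plateau onset**: the start time of the first cycle after which the
  per-cycle peak $K$ changes by less than 1% at every subsequent cycle
  (1% mirrors the tolerance-refinement criterion). For the adaptive
  standard scenario run to $t=1000$ this lands at $t \approx 656$.
* `classify_regime` returns an explicit `undetermined` label when no
  pattern fits, never a silent default.

## Scenarios

Ten bundled scenario files transcribe the published parameter sets,
including the paradox pair (fixed thresholds $L_2 = 4$ surviving vs.
$L_2 = 4.5$ extinct), the adaptive growth runs, and the bounded-capacity
variants. Two caption gaps are filled by convention and flagged in the
files' `assumed` lists: the Allee capacity 1.001 where a caption omits it
(the value used by every other supercritical scenario) and the initial
state $(2, 2, 5)$ for the slow-habitat scenarios. Horizons are chosen to
cover the claimed behavior at interactive run times (the $t=1000$
adaptive run takes a few seconds; everything else well under that).

## Limitations

* No demographic noise, spatial structure, age structure, or alternative
  Allee formulations; no evolutionary-stability analysis.
* The $L_2$ bound is used as a sufficient condition; its sharpness is
  checked only empirically (the simulated survival boundary sits just
  below it, consistent with the finite-$r_s$ entry loss).
* Very aggressive parameter ratios ($r_s/r_2 < \sim 10$) erode the
  time-scale separation the theory assumes; the corrected entry level is
  first-order in $1/r_s$ and will not rescue such regimes.
* The event machinery guards against chattering with a segment budget and
  raises a diagnostic error (carrying the last valid state) rather than
  looping silently.
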