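# Methods

## Model summary

`stingsim` simulates the evolution of a honeybee colony's collective
stinging response with an ensemble of Projective Simulation (PS) agents.
The design commitments are:

* **Two-layer memory, shared by the colony.**  Each bee's decision process
  is a percept→action weight matrix `h` (P×2, all entries ≥ 1).  Because
  genetic mixing transmits average responses, every bee in a colony uses
  the *same* matrix, and the learning update is applied once per trial to
  the shared matrix.  The learning process is read as an evolutionary
  history, not individual learning: the reward is selection strength, the
  forgetting rate `γ` is imperfect selection/drift.
* **Collective glow as counts.**  The glow matrix `g` stores how many
  agents traversed each percept→action edge during the trial (so its
  entries sum to `N`), not a binary traversal flag.  Reinforcement is
  `g·R`: responses used by many bees in a successful trial are credited
  proportionally.
* **Single combined update.**  `h ← h − γ(h − h⁰) + g·R` is applied as one
  assignment reading the pre-update `h` once.  With `h⁰ = 1`, `R ∈ [0,1]`
  and `0 ≤ γ < 1` every weight stays ≥ 1 and the all-ones matrix is a fixed
  point; under constant `(g, R)` the weights converge geometrically to
  `h⁰ + gR/γ`.  Weights are kept in double precision and never
  renormalised.

## The defensive event

Time is discrete and agent index equals step index (0-based); a trial has
exactly `N` steps and every agent decides exactly once.  Agent `t` perceives
the concentration `c = (number of stings among agents 0..t−1)`, encoded
logarithmically: percept 0 for `c = 0`, percept `b` for
`c ∈ [2^(b−1), 2^b − 1]` (`1 ≤ b ≤ 8`, top bin open-ended).  Powers of two
give single-unit resolution at low concentrations — Weber-Fechner-like
sensing — and leave percepts 7–8 effectively unreached at `N = 100`, while
still resolving the concentrations a 200-bee colony can produce.  The bin
count is configurable (`n_pheromone_bins`).

Threshold bookkeeping uses one boundary: `t_stop` is the first step at
whose *start* the cumulative sting count is ≥ `s_th` (`N` if never).  The
predator kills `k` bees per step over `[t_att, t_stop)` — it kills during
the step it arrives in, and never kills once deterred; if the threshold is
met before `t_att` it never kills at all.  The escape percept is active for
agents at steps `t ≥ t_stop + dt_v` and overrides olfaction;
`dt_v = inf` disables it.  This single convention reproduces both anchor
cases exactly: with forced stinging, `N=10`, `s_th=3`, `k=1`, `dt_v=0` the
trial gives stings at steps 0–2, kills at steps 0–2 and escape suppression
from step 3 (`s=3, q=3, a=4, R=0.4`); and a false alarm (`s_th=0`) has
`t_stop=0`, an empty kill window (`q=0`) and the disturbance visibly gone
from step `dt_v`.

Two deliberate simplifications: bees killed by the predator still act
(deaths are end-of-trial bookkeeping), and bees that sting after the escape
percept still count as stingers and pheromone sources.  `q` is capped at
`N − s`, so `s + q + a = N` always and the reward `R = a/N` is well defined
even when the predator could nominally kill more bees than exist.

The false-alarm convention deserves a note.  A false alarm is encoded as
`s_th = 0`; mechanically the event then runs with an always-satisfied
threshold, so the escape percept activates for all agents from step `dt_v`
on.  We also explored the alternative in which predator-free events never
show an escape cue.  Under that alternative, colonies facing many false
alarms (`r_f = 0.6`) expose percept 0 to the full colony on every false
alarm, and ensembles bifurcate into defended and never-sting attractors —
replicate spread an order of magnitude wider than the reference ensembles
report, and escape-percept probabilities far off the reference values.
The literal `s_th = 0` rule matches the reference behaviour closely (e.g.
converged escape-percept probability ≈ 0.026 vs 0.024 reported for the
`r_f = 0.6` process, ≈ 0.095 vs 0.09 for the European-bee configuration)
and is what the package implements.

## Parameters and defaults

| parameter | meaning | default | units |
|---|---|---|---|
| `N` (`n_bees`) | colony size = steps per trial | 100 | bees |
| `s_th` | predator sting resistance | uniform on (16, 40) | stings |
| `k` | killing rate while attacking | 1 | bees/step |
| `t_att` | attack start (detection lead) | 0 | steps |
| `dt_v` | escape-visibility delay | 10 | steps |
| `r_f` | false-alarm probability | 0 | — |
| `γ` (`gamma`) | forgetting rate | 0.003 | per trial |
| `n_trials` | learning length | 80 000 | trials |
| `n_replicates` | independent colonies | 50 (5 at desk scale) | — |
| `window` | trailing trials for visit counts / running stats | 500 | trials |

The defaults are the reference environment of the figure-4-style ensembles.
`γ` is only stated explicitly for the N=200 case study; we use 0.003
throughout (the reported robustness sweep supports a broad range).  The
mixture environment weights weak predators (16, 26) 4:1 against strong ones
(27, 40).  The European/African configurations differ from each other only
in `r_f` (0.6 vs 0.3) and the `s_th` range ((15, 25) vs (15, 70)), at
`N=200` and 10⁵ trials.

## Evaluation modes

Converged strategies are summarised by the per-percept stinging
probabilities of the final memory, aggregated as mean ± sd across replicate
colonies (sample sd, `ddof=1`).  Dose-response curves drop percepts with
zero visits in the trailing window and place markers at each bin's upper
concentration edge.  Performance curves come in two modes:

* **frozen** (default): the final memories face a grid of fixed `s_th`
  values with learning off and false alarms disabled — a clean measurement
  of the converged strategy (`evaluate_performance`);
* **windowed**: statistics are taken from the last `window` trials of
  training itself, reproducing the running-measurement protocol
  (`windowed_performance`).

The frozen survivor percentages are reported next to the analytic optimum
`100·(N − s_th − k·max(0, s_th − t_att))/N`, the best any strategy could do
(one sting per step from step 0), and the over-stinging bound
`s_th + dt_v`, the most stings possible before the escape percept fires.

## Numerical and implementation choices

* Sequential trials are simulated in a tight scalar loop over pre-drawn
  per-trial uniforms (~20 µs per 100-agent trial), so a full 80 000-trial
  learning process runs in under two seconds; no compiled extension is
  needed.
* Randomness uses `numpy.random.Generator` throughout.  Replicate seeds are
  spawned from one master `SeedSequence` (counter-based), making ensembles
  reproducible and replicates independent; a fixed seed reproduces a run
  bit for bit.  Encounter thresholds for a whole learning process are drawn
  vectorised up front.
* Memory snapshots serialise to CSV/JSON with hexadecimal floats alongside
  decimal values, so round-trips are bit-exact; result tables are re-read
  with `float_precision="round_trip"`.
* Degenerate inputs are valid by construction: `k=0` leaves `q=0`;
  `s_th > N` means the predator is never deterred (`t_stop = N`);
  `n_trials = 0` returns the initial memory with every probability exactly
  0.5.

## Desk-scale ensembles

Reference-grade ensembles use 50 replicates; the test-suite and the
acceptance script use 5 replicates per configuration (3 is the floor for
the case study) with the full trial budgets (80 000 or 100 000 trials).
Converged means are compared within three reference standard deviations,
which absorbs the extra ensemble error of the smaller replicate count.
Statistical ordering claims (false alarms lower baseline stinging; a longer
escape delay lowers high-concentration stinging; a small territory wins
against weak predators and loses against resistant ones) are asserted as
one-sided Welch tests or sign comparisons across replicates.

## What the generator does and does not emulate

Trials emulate the *structure* of a defensive event — sequential decisions,
immediate pheromone accumulation (one unit per sting), deterministic
kill/stop rules, a single parametric predator.  They do not model spatial
structure, predator movement, simultaneous predators, guard/soldier castes,
pheromone decay or dispersal, or heterogeneity between bees (one shared
memory is the point of the collective-inheritance assumption).  Passing
tests therefore validate the learning dynamics and the qualitative
orderings under these idealisations; they do not by themselves establish
how real colonies weigh visual against olfactory stop signals, and the
interpretation of `p_s` (per-bee probability vs population threshold
distribution) is observationally equivalent here.

## Known limitations

* With large `r_f` the learning dynamics are bistable-ish; replicate spread
  of the escape-percept probability is large (the reference values show the
  same), so single replicates are not meaningful — always use ensembles.
* Convergence is not formally tested; trial budgets follow the reference
  protocol and the reward trajectory's first-vs-last comparison is the only
  built-in convergence check.
* The one-sting-one-unit pheromone model makes concentration equal to the
  sting count; rescaling to physical concentrations is up to the user.
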