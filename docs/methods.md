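# Methods

## Model

The network is a discrete-time recurrent layer of binary threshold neurons
— `N^E` excitatory and `N^I = round(0.2 N^E)` inhibitory — plus a readout
layer with one excitatory output neuron per task symbol.  A neuron emits a
spike whenever its summed input reaches its threshold (Heaviside step with
`Θ(0) = 1`), and all populations update synchronously:

    s^e(t+1) = Θ( W^EE s^e(t) − W^EI s^in(t) + u(t) − θ^e )
    s^in(t+1) = Θ( W^IE s^e(t) − θ^in )
    ψ^o(t+1) = W^OE s^e(t+1) − θ^o

Excitatory-to-excitatory connections are sparse, recorded by a binary mask
`c_ee` with zero diagonal; E↔I projections and the readout are full.  All
afferent weight vectors are drawn uniform on [0, 1] and normalized to sum
to 1.  There are no I→I connections.

Input symbols are encoded by disjoint subsets of `n_input_subset`
excitatory neurons (default: 5% of `N^E`, at least 10); presenting a
symbol adds a unit drive to its subset.  The subset scales with network
size because the input code's strength is relative: with a fixed
10-neuron subset a 400-neuron network receives proportionally half the
drive of a 200-neuron one, its entrained orbit turns marginal, and deep
counting (n = 12) becomes seed-lottery — proportional subsets restore
reliable entrainment.  With thresholds initialised below 1 the driven subset fires,
and the rest of the layer forms a recurrent "halo" whose composition
depends on the recent past — that halo is the working memory the readout
taps.

### Pipeline timing of the readout

Within a cycle the recurrent update runs first and the output layer reads
the excitatory state that has already absorbed the current symbol; the
emitted prediction is scored against the next symbol.  This keeps the
state on which predictions are scored identical to the state that earns
the plasticity credit.  A strictly simultaneous reading (output computed
from the previous excitatory state) would score the readout on a state it
was never trained to decode, one symbol out of phase.

### Winner-take-all emission

The emitted symbol is the output neuron with maximal potential `ψ^o`
(ties: lowest index).  For the *learning* pathway, that winner is treated
as the single active output: the readout eligibility trace and output
intrinsic plasticity see a one-hot emission vector rather than the
per-neuron thresholded states.  With literal per-neuron spiking, an
output neuron that happens to co-spike with a wrong winner is *depressed*
at exactly the states where its symbol is the target; the readout then
locks into predicting the majority symbol forever (we observed this
directly: a frozen 2/3-accuracy plateau on the counting task).  With
winner-take-all credit the rule behaves like a reward-modulated
perceptron and converges.  The per-neuron thresholded output states and
raw potentials remain available through `step_output`.

## Plasticity rules

**Reward-modulated STDP.**  Each plastic synapse accumulates an
eligibility trace (forward-Euler, unit step):

    e' = e·(1 − 1/τ_e) + s_post(t)·s_pre(t−1) − f·s_post(t−1)·s_pre(t)

with `f = 1` for `W^EE` and `f = 0.01` for `W^OE`.  Weights change only
when the reward deviates from its baseline: `W ← W + η·(R − b)·e`,
floored at 0, followed by row normalization.  The baseline `b` is an
exponential moving average of the reward (`α = 0.05`); it makes the
neuromodulation factor `M = R − b` a *surprise* signal, so a converged
network stops changing (errors still produce strongly negative `M`).

**Synaptic normalization.**  After every weight change each afferent row
with positive sum is rescaled to sum to 1.  Besides stabilising activity
this is the erosion mechanism behind synapse death: any potentiation in a
row multiplicatively shrinks its other synapses.

**Intrinsic plasticity.**  `θ ← θ + η_ip (s − μ_ip)`.  Recurrent
excitatory neurons share a scalar target `μ_ip` (default 0.1, admissible
range [0.05, 0.25]); each output neuron's target is the occurrence
probability of its symbol in the task stream, which both calibrates
emission rates and supplies the exploration pressure that breaks
fixed-point strategies.  Inhibitory thresholds never adapt.

**Structural plasticity** (recurrent E-E only).  Existing connections
with weight below `w_th` are pruned; each nonexistent off-diagonal pair
grows with probability `p_sp` per application, at weight `w_new = 0.001`.
Growth is applied to the post-prune mask and a pair pruned in a call may
not regrow in that call.  Eligibility traces of pruned pairs are zeroed;
newborn pairs start with zero trace.

## Two-stage training

Each alternation runs a short stage one (default 100 steps) with *all*
rules active on `W^EE` and `W^OE`, then a long stage two (default 20,000
steps) with the recurrent layer — weights, mask and excitatory
thresholds — frozen, fine-tuning only the readout weights and output
thresholds.  The published schedule repeats this 200 times.  For the
generation task the model's own read-out symbol is fed back as the next
input throughout training; the reward is the partial-credit match of the
recent output window against the target cycle (longest suffix of the
window that is a contiguous run of the repeated cycle, divided by the
cycle length).

Inference runs the frozen dynamics with every rule off: prediction tasks
stream the true sequence from a random phase offset and score read-outs
after a warmup (default 120 steps, extended to the next subsequence
boundary); generation seeds one start symbol and feeds read-outs back.

## Parameter defaults and how they were set

The tunable rates are not dictated by the model structure, and we set
them by pilot calibration on the counting task, then froze them:

| parameter | default | role / rationale |
|---|---|---|
| `eta` | 0.02 | R-STDP rate on `W^EE`.  Stage one is only 100 steps per alternation; the recurrent layer must reorganize fast.  This rate also powers the weight turnover that the connection-fraction equilibrium needs. |
| `eta_output` | 0.002 | R-STDP rate on `W^OE`.  The readout fine-tunes over ~10^5 steps; rates above ~0.005 leave a constant-step jitter around the separating solution and cost the last few percent. |
| `tau_e` | 1.2 | Rewards here are immediate (every step scores the current prediction), so the trace needs only ~1 step of memory; long traces smear credit across whole subsequence periods and empirically block phase discrimination. |
| `eta_ip` | 5e-5 | Recurrent threshold adaptation is exposed only during stage one (~0.5% of steps).  Its *total* drift must stay well below the threshold scale: at equilibrium-seeking rates the frozen-threshold inference orbit loses the marginal neurons and dies.  The small rate keeps every neuron mildly active (which structural turnover needs) without marginalising the input code. |
| `eta_ip_output` | 5e-4 | Output thresholds adapt every step of both stages; they must track the readout's drifting potentials but not oscillate. |
| `p_sp` | 2e-6 | Growth pressure, calibrated so births balance deaths with the trained connection fraction settling near 0.015 from a 0.01 start (and near 0.011 from 0.002) on the counting grid. |
| `w_th` | 6e-4 | Pruning threshold just below `w_new`: most newborn synapses that fail to win potentiation are eroded below it by normalization within a few hundred steps, matching the observed high turnover of new cortical synapses. |
| `p_c` | 0.05 (N≤200), 0.0125 (N=400) | Best-performing initial densities per network size (`experiments.default_p_c`). |
| `mu_ip` | 0.1 | Mid-range sparse activity target. |
| thresholds | θ^e, θ^o ~ U(0, 0.5]; θ^in ~ U(0, 1] | With unit input drive, excitatory thresholds below 1 guarantee the input subsets can fire. |

Reduced schedule: routine runs and the acceptance script use 100
alternations of 100 + 1,500 steps (and 60 alternations for the quickly
converging motion tasks).  These sizes were chosen because pilot runs
showed the per-alternation reward and the connection fraction have
plateaued by then at these learning rates; the full published schedule is
available as `experiments.full_protocol()`.

## What the synthetic tasks do and do not probe

All inputs are exactly periodic symbol streams, so "train/test" differ
only by phase, and a network that locks onto the cycle can reach 100%.
The tasks probe (i) whether the recurrent layer maintains a phase code
deep into a run of identical symbols (counting), (ii) whether a readout
trained only through scalar reward can decode it (all tasks), and
(iii) whether the loop is stable under output-to-input feedback
(generation).  They do not probe stochastic sequences, noise robustness,
or generalisation beyond the trained cycle; passing them says nothing
about such settings.

## Numerical choices and degenerate inputs

* `Θ(0) = 1`: a neuron exactly at threshold fires.
* Read-out ties resolve to the lowest neuron index (deterministic).
* All-zero afferent rows are left unnormalized (no division by zero).
* Weights are clipped at 0 after a reward update; a clipped-to-zero
  recurrent weight is below any `w_th` and is pruned at the next
  structural step.
* The eligibility decay factor `1 − 1/τ_e` requires `τ_e > 1`;
  configurations violating this (or `w_th ≥ w_new`, or `μ_ip` outside
  [0.05, 0.25], or `N^I ≠ round(0.2 N^E)`) are rejected at construction.
* Every random draw in an experiment derives from the single configured
  seed; fixed-seed runs are bit-reproducible, and run archives store the
  RNG state so resumed runs continue identically.

## Analysis conventions

Weight-distribution fits are maximum-likelihood (lognormal: moments of
log-weights; KS distance against the fitted CDF).  Lifetime fits use the
discrete power-law MLE (Hurwitz-zeta likelihood) with the lower cutoff
chosen by KS minimisation; right-censored lifetimes (connections still
alive at the horizon) are excluded from fitting.  Survival-by-strength
uses five weight-quantile bins and reports a Spearman rank association.
These statistics describe the trained model's synapse population; no
formal model comparison against alternative distributions is attempted.

## Known limitations

* Performance at large `n` (≥ 16 on N=200) degrades, consistent with the
  reference behaviour of this model family; the scaled schedule shows the
  same qualitative fall-off earlier.
* The connection-fraction equilibrium is calibrated at N=200 on the
  counting grid; other tasks/sizes equilibrate at nearby but not
  identical densities.
* Single-CPU, dense-array implementation; practical up to a few thousand
  excitatory neurons.
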