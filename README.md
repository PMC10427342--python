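# rsrnsp

A self-organizing recurrent network of binary spiking neurons that learns
symbol sequences through reward-modulated spike-timing-dependent
plasticity (R-STDP), homeostatic plasticity, and structural plasticity —
for computational neuroscientists studying how multiple plasticity rules
interact to shape a recurrent circuit, and what connection statistics
that interaction produces.

## The model in brief

A recurrent layer of `N^E` excitatory and `N^I = 0.2 N^E` inhibitory
binary threshold neurons evolves synchronously,

    s^e(t+1) = Θ( W^EE s^e(t) − W^EI s^in(t) + u(t) − θ^e ),
    s^in(t+1) = Θ( W^IE s^e(t) − θ^in ),

and a readout layer emits the symbol of the output neuron with maximal
potential `ψ^o = W^OE s^e − θ^o`.  Four rules shape the two plastic
matrices `W^EE` and `W^OE`:

* **R-STDP** — spike-timing coincidences accumulate in an eligibility
  trace `e` (decay `1 − 1/τ_e`); weights move only when the reward `R`
  deviates from its moving-average baseline `b`:
  `W ← W + η (R − b) e`.
* **Synaptic normalization** — every neuron's afferent weights are
  rescaled to sum to 1, creating competition on each dendrite.
* **Intrinsic plasticity** — thresholds track target firing rates:
  `θ ← θ + η_ip (s − μ_ip)`.
* **Structural plasticity** — E-E connections with weight below `w^th`
  are pruned; absent pairs grow with probability `p_sp` at weight 0.001.

Training alternates a short stage with all rules active and a long stage
with the recurrent layer frozen and only the readout fine-tuned.  The
benchmark suites are periodic symbol streams: *counting*
(`a b…b c` with `n` repeats — predicting the end flag requires counting),
*motion prediction* (`1 2 … n` cyclically), and *motion generation* (the
same cycle produced autonomously, outputs fed back as inputs).

The trained network reproduces hallmark cortical synapse statistics:
lognormal-like weights, power-law-like lifetimes of new connections, and
an initial-density-independent equilibrium connection fraction.

## Worked example

```python
from rsrnsp import NetworkConfig, Model, train, infer, report_from_inference
from rsrnsp.experiments import reduced_protocol
from rsrnsp.tasks import make_counting_sequence

seq = make_counting_sequence(n=4, m=500)        # a bbbb c, repeated
cfg = NetworkConfig(n_excitatory=200, p_c=0.05, seed=0)
model = Model.for_task(cfg, seq)                # 3 output neurons: a, b, c
history = train(model, reduced_protocol(), seq)
report = report_from_inference(
    infer(model, seq, steps=600, warmup=120), N=200, seed=0)
print(f"overall  {100 * report.overall:.2f}%")
print(f"counting {100 * report.counting:.2f}%")
print(f"final connection fraction {model.connection_fraction():.4f}")
```

Output of this exact script:

```
overall  100.00%
counting 100.00%
final connection fraction 0.0457
```

`overall` is the fraction of correctly predicted next symbols; `counting`
is the fraction of subsequences whose decisive end-flag transition (the
prediction made at the fourth `b`, whose correct answer is `c`) is right —
the one prediction that requires having counted.  The connection fraction
is the trained density of the E-E mask, which structural plasticity moved
from the initial 0.05 toward its attractor.

The same workflow is available from the shell:

```sh
rsrnsp train --task counting --n 4 -N 200 --pc 0.05 --seed 0 --out run.npz
rsrnsp eval run.npz --task counting --n 4
rsrnsp analyze run.npz --events run.events.tsv
rsrnsp reproduce-table table2 --reduced
```

`train` writes a checkpoint archive, a structural-event log (TSV of
birth/death events) and a JSON manifest; `analyze` fits the weight and
lifetime distributions.

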