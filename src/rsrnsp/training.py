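"""Two-stage alternating training and the inference loop.

Stage one runs every plasticity rule — reward-modulated STDP on both the
recurrent and readout matrices, synaptic normalization, intrinsic
plasticity, and structural growth/pruning of E-E connections.  Stage two
freezes the recurrent layer (weights, mask and excitatory thresholds) and
fine-tunes only the readout weights and output thresholds.  The two stages
alternate; inference runs the frozen dynamics with all plasticity off.

Per-step order: state update -> eligibility update -> reward -> baseline
update -> reward-gated weight update -> row normalization -> intrinsic
plasticity -> structural plasticity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .config import NetworkConfig, PlasticityToggles, TrainProtocol
from .network import (InputMap, NetworkState, WeightMatrices, init_network,
                      readout_symbol)
from .plasticity import (apply_reward, normalize_rows,
                         intrinsic_update, structural_step,
                         update_baseline, update_eligibility)
from .tasks import (MOTION_GENERATION, SymbolSequence,
                    generation_reward, prediction_reward)


class Model:
    """A network instance bundling config, weights, state and RNG.

    The construction RNG stream is kept on the model and continues to feed
    structural-plasticity draws and evaluation phase offsets, so a fixed
    seed makes an entire experiment bit-reproducible.
    """

    def __init__(self, config: NetworkConfig, symbols=None):
        self.config = config
        weights, state, input_map = init_network(config, symbols)
        self.weights: WeightMatrices = weights
        self.state: NetworkState = state
        self.input_map: InputMap = input_map
        self.symbols = input_map.symbols
        self.rng = np.random.default_rng((config.seed, 0x5F))
        if config.mu_ip_output is not None:
            self.mu_out = np.asarray(config.mu_ip_output, dtype=float)
        else:
            self.mu_out = np.full(config.n_output, config.mu_ip)

    @classmethod
    def for_task(cls, config: NetworkConfig, seq: SymbolSequence) -> "Model":
        """Build a model sized and targeted for a task sequence.

        One output neuron per alphabet symbol; per-output intrinsic targets
        equal to each symbol's occurrence probability in the stream.
        """
        freqs = seq.symbol_frequencies()
        cfg = config.replace(
            n_output=len(seq.alphabet),
            mu_ip_output=tuple(freqs[a] for a in seq.alphabet),
        )
        return cls(cfg, seq.alphabet)

    def connection_fraction(self) -> float:
        n = self.config.n_excitatory
        return float(self.weights.c_ee.sum()) / (n * (n - 1))


@dataclass
class TrainHistory:
    """Per-step and per-alternation records of one training run."""

    reward_chunks: list = field(default_factory=list)
    baseline_chunks: list = field(default_factory=list)
    events: list = field(default_factory=list)
    p_c: list = field(default_factory=list)
    alternation_rewards: list = field(default_factory=list)
    initial_mask: np.ndarray | None = None
    steps: int = 0

    @property
    def rewards(self) -> np.ndarray:
        if not self.reward_chunks:
            return np.empty(0, np.float32)
        return np.concatenate(self.reward_chunks)

    @property
    def baselines(self) -> np.ndarray:
        if not self.baseline_chunks:
            return np.empty(0, np.float32)
        return np.concatenate(self.baseline_chunks)


class TaskRunner:
    """Feeds task inputs and computes per-step rewards.

    In prediction mode the true sequence is streamed and the reward is 1
    for a correct next-element prediction.  In feedback (generation) mode
    the model's previous read-out is the next input and the reward is the
    partial-credit match of the recent output window against the target
    cycle.
    """

    def __init__(self, seq: SymbolSequence, reward_incorrect: float = 0.0,
                 feedback: bool = False, start_pos: int = 0):
        self.seq = seq
        self.length = len(seq)
        self.pos = start_pos
        self.feedback = feedback
        self.reward_incorrect = reward_incorrect
        self.cycle = seq.cycle
        self.window: deque = deque([None] * len(self.cycle),
                                   maxlen=len(self.cycle))
        self.last_output = None

    def next_input(self):
        if self.feedback:
            if self.last_output is None:
                return self.seq.symbols[0]  # seed the loop once
            return self.last_output
        return self.seq.symbols[self.pos % self.length]

    def reward(self, predicted) -> float:
        if self.feedback:
            self.window.append(predicted)
            return generation_reward(self.window, self.cycle)
        target = self.seq.symbols[(self.pos + 1) % self.length]
        return prediction_reward(predicted, target, self.reward_incorrect)

    def advance(self, predicted) -> None:
        self.pos += 1
        if self.feedback:
            self.last_output = predicted


def _run(model: Model, runner: TaskRunner, steps: int, stage: int,
         toggles: PlasticityToggles, history: TrainHistory) -> None:
    """Execute ``steps`` task-driven steps with stage-appropriate plasticity."""
    cfg = model.config
    W = model.weights
    S = model.state
    symbols = model.symbols
    ee_plastic = stage == 1 and toggles.rstdp_ee
    oe_plastic = toggles.rstdp_oe
    ip_e = stage == 1 and toggles.intrinsic
    ip_o = toggles.intrinsic
    sp = stage == 1 and toggles.structural
    norm = toggles.normalization
    mu_out = model.mu_out
    rewards = np.empty(steps, np.float32)
    baselines = np.empty(steps, np.float32)

    for k in range(steps):
        u = model.input_map.drive(runner.next_input())
        s_e_old, s_in_old, s_o_old = S.s_e, S.s_in, S.s_o
        psi_e = W.w_ee @ s_e_old - W.w_ei @ s_in_old + u - S.theta_e
        s_e = (psi_e >= 0.0).astype(float)
        s_in = (W.w_ie @ s_e_old - S.theta_in >= 0.0).astype(float)
        psi_o = W.w_oe @ s_e - S.theta_o
        # Emission is winner-take-all: the read-out symbol's neuron is the
        # single active output, and that emission state is what the output
        # eligibility trace and output intrinsic plasticity see.
        winner = int(np.argmax(psi_o))
        s_o = np.zeros(len(symbols))
        s_o[winner] = 1.0
        predicted = symbols[winner]
        r = runner.reward(predicted)

        if ee_plastic:
            S.e_ee = update_eligibility(S.e_ee, s_e, s_e_old, s_e, s_e_old,
                                        cfg.tau_e, cfg.f_ee, W.c_ee)
        if oe_plastic:
            # The readout spike is driven by the excitatory state computed
            # one propagation step earlier in the same cycle.
            S.e_oe = update_eligibility(S.e_oe, s_o, s_o_old, s_e, s_e,
                                        cfg.tau_e, cfg.f_oe)
        m = r - S.baseline_b
        S.baseline_b = update_baseline(S.baseline_b, r, cfg.baseline_alpha)
        if m != 0.0:
            if ee_plastic:
                w = apply_reward(W.w_ee, S.e_ee, m, cfg.eta, W.c_ee)
                W.w_ee = normalize_rows(w, W.c_ee) if norm else w
            if oe_plastic:
                w = apply_reward(W.w_oe, S.e_oe, m, cfg.eta_output)
                W.w_oe = normalize_rows(w) if norm else w
        if ip_e:
            S.theta_e = intrinsic_update(S.theta_e, s_e, cfg.mu_ip,
                                         cfg.eta_ip)
        if ip_o:
            S.theta_o = intrinsic_update(S.theta_o, s_o, mu_out,
                                         cfg.eta_ip_output)
        if sp:
            W.c_ee, W.w_ee, events = structural_step(
                W.c_ee, W.w_ee, cfg.p_sp, cfg.w_th, cfg.w_new,
                model.rng, S.t + 1)
            if events:
                S.e_ee = S.e_ee * W.c_ee
                history.events.extend(events)

        S.s_e, S.s_in, S.s_o = s_e, s_in, s_o
        S.t += 1
        rewards[k] = r
        baselines[k] = S.baseline_b
        runner.advance(predicted)

    history.reward_chunks.append(rewards)
    history.baseline_chunks.append(baselines)
    history.steps += steps


def run_stage_one(model: Model, runner: TaskRunner, steps: int,
                  toggles: PlasticityToggles | None = None,
                  history: TrainHistory | None = None) -> Model:
    """Stage one: all plasticity rules active on W^EE and W^OE."""
    _run(model, runner, steps, 1, toggles or PlasticityToggles(),
         history if history is not None else TrainHistory())
    return model


def run_stage_two(model: Model, runner: TaskRunner, steps: int,
                  toggles: PlasticityToggles | None = None,
                  history: TrainHistory | None = None) -> Model:
    """Stage two: recurrent layer frozen, readout fine-tuned only."""
    _run(model, runner, steps, 2, toggles or PlasticityToggles(),
         history if history is not None else TrainHistory())
    return model


def train(model: Model, protocol: TrainProtocol,
          seq: SymbolSequence) -> TrainHistory:
    """Alternate stage one and stage two over the task stream.

    For the generation task the model's read-out symbol is fed back as the
    next input throughout training (no external teaching signal beyond the
    reward).
    """
    if list(seq.alphabet) != list(model.symbols):
        raise ValueError(
            f"model symbols {model.symbols} do not match the task alphabet "
            f"{seq.alphabet}; build the model with Model.for_task"
        )
    history = TrainHistory(initial_mask=model.weights.c_ee.copy())
    runner = TaskRunner(seq, model.config.reward_incorrect,
                        feedback=(seq.task_kind == MOTION_GENERATION))
    per_alt = protocol.stage1_steps + protocol.stage2_steps
    for _ in range(protocol.alternations):
        run_stage_one(model, runner, protocol.stage1_steps,
                      protocol.toggles, history)
        run_stage_two(model, runner, protocol.stage2_steps,
                      protocol.toggles, history)
        history.p_c.append(model.connection_fraction())
        if per_alt:
            recent = history.rewards[-per_alt:]
            history.alternation_rewards.append(float(recent.mean()))
    return history


def infer(model: Model, seq: SymbolSequence, steps: int,
          warmup: int = 50, offset: int | None = None) -> SimpleNamespace:
    """Run the frozen network on a task and collect its read-out stream.

    All plasticity is disabled.  For prediction tasks the true sequence is
    streamed from a random phase offset and predictions are recorded for
    ``steps`` positions (rounded down to whole subsequences) after a warmup
    long enough to wash out the phase transient; for the generation task
    see :func:`infer_generation`.

    Returns a namespace with ``predicted``, ``targets``, ``boundaries``
    (subsequence index pairs within the scored region), ``task_kind`` and
    ``n``.
    """
    if seq.task_kind == MOTION_GENERATION:
        return infer_generation(model, seq, steps, warmup)
    period = seq.period
    length = len(seq)
    if offset is None:
        offset = int(model.rng.integers(length))
    n_scored = (steps // period) * period
    if n_scored == 0:
        raise ValueError(f"steps={steps} shorter than one period ({period})")
    # extend warmup so scoring starts exactly at a subsequence boundary
    t0 = warmup
    while (offset + t0) % period != 0:
        t0 += 1
    predicted, targets = [], []
    W, S = model.weights, model.state
    for t in range(t0 + n_scored):
        sym = seq.symbols[(offset + t) % length]
        u = model.input_map.drive(sym)
        psi_e = W.w_ee @ S.s_e - W.w_ei @ S.s_in + u - S.theta_e
        s_e = (psi_e >= 0.0).astype(float)
        s_in = (W.w_ie @ S.s_e - S.theta_in >= 0.0).astype(float)
        psi_o = W.w_oe @ s_e - S.theta_o
        s_o = (psi_o >= 0.0).astype(float)
        if t >= t0:
            predicted.append(symbols_at(model, psi_o))
            targets.append(seq.symbols[(offset + t + 1) % length])
        S.s_e, S.s_in, S.s_o = s_e, s_in, s_o
        S.t += 1
    boundaries = [(k * period, (k + 1) * period)
                  for k in range(n_scored // period)]
    return SimpleNamespace(predicted=predicted, targets=targets,
                           boundaries=boundaries, task_kind=seq.task_kind,
                           n=seq.n)


def symbols_at(model: Model, psi_o: np.ndarray):
    return readout_symbol(psi_o, model.symbols)


def infer_generation(model: Model, seq: SymbolSequence, steps: int,
                     warmup: int = 50) -> SimpleNamespace:
    """Autonomous generation: seed one start symbol, feed read-outs back.

    Returns a namespace with the scored ``generated`` stream, the symbol
    immediately preceding it (``previous``), the target ``cycle``,
    ``task_kind`` and ``n``.
    """
    cycle = seq.cycle
    seed_symbol = cycle[0]
    W, S = model.weights, model.state
    last = seed_symbol
    generated: list = []
    previous = seed_symbol
    for t in range(warmup + steps):
        u = model.input_map.drive(last)
        psi_e = W.w_ee @ S.s_e - W.w_ei @ S.s_in + u - S.theta_e
        s_e = (psi_e >= 0.0).astype(float)
        s_in = (W.w_ie @ S.s_e - S.theta_in >= 0.0).astype(float)
        psi_o = W.w_oe @ s_e - S.theta_o
        out = symbols_at(model, psi_o)
        if t >= warmup:
            generated.append(out)
        elif t == warmup - 1:
            previous = out
        S.s_e, S.s_in, S.s_o = s_e, s_in, (psi_o >= 0.0).astype(float)
        S.t += 1
        last = out
    return SimpleNamespace(generated=generated, previous=previous,
                           cycle=cycle, task_kind=seq.task_kind, n=seq.n)
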