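"""Experiment configuration.

:class:`NetworkConfig` gathers every hyperparameter of the network and its
plasticity rules; :class:`TrainProtocol` describes the two-stage training
schedule.  Both are plain dataclasses validated on construction so that an
inconsistent experiment fails before any simulation time is spent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model constraint."""


# Ratio of inhibitory to excitatory neurons in the recurrent layer.
INHIBITORY_RATIO = 0.2

# Admissible range for the excitatory target firing rate.
MU_IP_RANGE = (0.05, 0.25)


@dataclass
class NetworkConfig:
    """All hyperparameters and seeds for one network instance.

    Parameters
    ----------
    n_excitatory : int
        Number of excitatory neurons ``N^E`` in the recurrent layer.
    n_output : int
        Number of output neurons; one per task symbol.
    n_inhibitory : int, optional
        Number of inhibitory neurons.  Fixed by the architecture to
        ``round(0.2 * n_excitatory)``; passing any other value is an error.
    p_c : float
        Initial excitatory-to-excitatory connection fraction (off-diagonal
        pairs connected, in expectation).
    n_input_subset : int, optional
        Number of excitatory neurons driven by each input symbol.
        Defaults to 5% of ``n_excitatory`` (at least 10), so the input
        code keeps the same relative strength as the network grows.
    mu_ip : float
        Target firing rate of recurrent excitatory neurons for intrinsic
        plasticity; must lie in ``[0.05, 0.25]``.
    mu_ip_output : tuple of float, optional
        Per-output-neuron target rates (the expected occurrence probability
        of the symbol each neuron represents).  Usually derived from the
        task by the training layer; ``None`` until then.
    eta : float
        Learning rate of reward-modulated STDP on the recurrent matrix
        ``W^EE``.  Stage one is short and the recurrent layer must
        reorganize quickly, so this rate is deliberately aggressive.
    eta_output : float, optional
        R-STDP learning rate for the readout matrix ``W^OE``; pass
        ``None`` to share ``eta``.  The readout fine-tunes over the long
        second stage and needs a much smaller, stable rate.
    eta_ip : float
        Learning rate of intrinsic plasticity (threshold adaptation) in
        the recurrent layer.
    eta_ip_output : float, optional
        Intrinsic-plasticity rate for output thresholds; pass ``None`` to
        share ``eta_ip``.  The readout adapts every step of both training
        stages, whereas recurrent thresholds adapt only during stage one,
        so the two rates play different roles.
    tau_e : float
        Eligibility-trace time constant in steps; must exceed 1 so the
        per-step decay factor ``1 - 1/tau_e`` stays positive.
    f_ee, f_oe : float
        Dimensionless depression factors in the STDP bracket, for the
        recurrent (``f = 1``) and output (``f = 0.01``) plastic matrices.
    p_sp : float
        Per-pair growth probability of structural plasticity.
    w_th : float
        Pruning threshold; connections with weight below it are removed.
    w_new : float
        Weight assigned to a newly grown connection (must exceed ``w_th``).
    reward_incorrect : float
        Reward for an incorrect prediction: 0 or -1.
    baseline_alpha : float
        Coefficient of the exponential moving-average reward baseline.
    theta_e_range, theta_in_range, theta_o_range : (float, float)
        Uniform initialisation intervals for excitatory, inhibitory and
        output thresholds.
    seed : int
        Seed for every source of randomness in this network.
    """

    n_excitatory: int = 200
    n_output: int = 3
    n_inhibitory: int | None = None
    p_c: float = 0.05
    n_input_subset: int | None = None
    mu_ip: float = 0.1
    mu_ip_output: tuple[float, ...] | None = None
    eta: float = 0.02
    eta_output: float | None = 0.002
    eta_ip: float = 5e-5
    eta_ip_output: float | None = 5e-4
    tau_e: float = 1.2
    f_ee: float = 1.0
    f_oe: float = 0.01
    p_sp: float = 2e-6
    w_th: float = 6e-4
    w_new: float = 1e-3
    reward_incorrect: float = 0.0
    baseline_alpha: float = 0.05
    theta_e_range: tuple[float, float] = (0.0, 0.5)
    theta_in_range: tuple[float, float] = (0.0, 1.0)
    theta_o_range: tuple[float, float] = (0.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_excitatory < 1:
            raise ConfigurationError("n_excitatory must be a positive integer")
        expected_ni = round(INHIBITORY_RATIO * self.n_excitatory)
        if self.n_inhibitory is None:
            self.n_inhibitory = expected_ni
        elif self.n_inhibitory != expected_ni:
            raise ConfigurationError(
                f"n_inhibitory must equal round(0.2 * n_excitatory) = "
                f"{expected_ni}, got {self.n_inhibitory}"
            )
        if self.n_output < 1:
            raise ConfigurationError("n_output must be a positive integer")
        if not 0.0 < self.p_c < 1.0:
            raise ConfigurationError("p_c must lie in (0, 1)")
        if self.n_input_subset is None:
            self.n_input_subset = max(10, self.n_excitatory // 20)
        if self.n_input_subset < 1:
            raise ConfigurationError("n_input_subset must be positive")
        lo, hi = MU_IP_RANGE
        if not lo <= self.mu_ip <= hi:
            raise ConfigurationError(
                f"mu_ip must lie in [{lo}, {hi}], got {self.mu_ip}"
            )
        if self.mu_ip_output is not None:
            self.mu_ip_output = tuple(float(x) for x in self.mu_ip_output)
            if len(self.mu_ip_output) != self.n_output:
                raise ConfigurationError(
                    "mu_ip_output must have one entry per output neuron"
                )
        if self.eta <= 0:
            raise ConfigurationError("eta must be positive")
        if self.eta_output is None:
            self.eta_output = self.eta
        elif self.eta_output <= 0:
            raise ConfigurationError("eta_output must be positive")
        if self.eta_ip <= 0:
            raise ConfigurationError("eta_ip must be positive")
        if self.eta_ip_output is None:
            self.eta_ip_output = self.eta_ip
        elif self.eta_ip_output <= 0:
            raise ConfigurationError("eta_ip_output must be positive")
        if self.tau_e <= 1:
            raise ConfigurationError(
                "tau_e must exceed 1 (per-step decay 1 - 1/tau_e would be <= 0)"
            )
        if not 0.0 < self.p_sp < 1.0:
            raise ConfigurationError("p_sp must lie in (0, 1)")
        if not 0.0 < self.w_th < 1.0:
            raise ConfigurationError("w_th must lie in (0, 1)")
        if self.w_th >= self.w_new:
            raise ConfigurationError(
                "w_th must be smaller than w_new (newly grown connections "
                "would be pruned immediately)"
            )
        if self.reward_incorrect not in (0, -1, 0.0, -1.0):
            raise ConfigurationError("reward_incorrect must be 0 or -1")
        if not 0.0 < self.baseline_alpha < 1.0:
            raise ConfigurationError("baseline_alpha must lie in (0, 1)")
        for name in ("theta_e_range", "theta_in_range", "theta_o_range"):
            lo_hi = getattr(self, name)
            if len(lo_hi) != 2 or not lo_hi[0] < lo_hi[1]:
                raise ConfigurationError(f"{name} must be an increasing pair")
        n_in_needed = self.n_output * self.n_input_subset
        if n_in_needed > self.n_excitatory:
            raise ConfigurationError(
                f"n_output * n_input_subset = {n_in_needed} exceeds "
                f"n_excitatory = {self.n_excitatory}"
            )

    def replace(self, **changes) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown NetworkConfig keys: {sorted(unknown)}"
            )
        d = dict(d)
        for key in ("theta_e_range", "theta_in_range", "theta_o_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("mu_ip_output") is not None:
            d["mu_ip_output"] = tuple(d["mu_ip_output"])
        return cls(**d)


@dataclass
class PlasticityToggles:
    """Per-rule on/off switches, mainly for ablation experiments."""

    rstdp_ee: bool = True
    rstdp_oe: bool = True
    normalization: bool = True
    intrinsic: bool = True
    structural: bool = True

    @classmethod
    def all_off(cls) -> "PlasticityToggles":
        return cls(False, False, False, False, False)


@dataclass
class TrainProtocol:
    """Two-stage alternating training schedule.

    Stage one runs all plasticity rules on the recurrent and output layers;
    stage two freezes the recurrent layer and fine-tunes only the readout.
    The stages alternate ``alternations`` times.
    """

    stage1_steps: int = 100
    stage2_steps: int = 20000
    alternations: int = 200
    eval_steps: int = 2000
    eval_warmup: int = 50
    toggles: PlasticityToggles = field(default_factory=PlasticityToggles)

    def __post_init__(self) -> None:
        for name in ("stage1_steps", "stage2_steps", "alternations",
                     "eval_steps"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.eval_warmup < 0:
            raise ConfigurationError("eval_warmup must be nonnegative")
        if isinstance(self.toggles, dict):
            self.toggles = PlasticityToggles(**self.toggles)

    def replace(self, **changes) -> "TrainProtocol":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainProtocol":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown TrainProtocol keys: {sorted(unknown)}"
            )
        return cls(**d)
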