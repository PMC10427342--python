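"""The four plasticity rules.

* reward-modulated STDP: spike-timing coincidences accumulate in a decaying
  eligibility trace; weights change only when the reward deviates from its
  moving-average baseline (three-factor rule).
* synaptic normalization: afferent weights of each neuron are rescaled to
  sum to 1, inducing competition among synapses on the same dendrite.
* intrinsic plasticity: thresholds track a target firing rate.
* structural plasticity: sub-threshold connections are pruned, new
  connections grow stochastically between unconnected excitatory pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError
from .network import ContractError


@dataclass
class RewardSignal:
    """Reward ``r``, baseline ``b`` and neuromodulation factor ``m = r - b``."""

    r: float
    b: float

    @property
    def m(self) -> float:
        return self.r - self.b


@dataclass
class StructuralEvent:
    """One birth (growth) or death (pruning) of an E-E connection."""

    kind: str          # "birth" | "death"
    i: int             # post-synaptic index
    j: int             # pre-synaptic index
    t: int             # simulation step
    weight: float = 0.0  # weight at death (w_new at birth)


def update_eligibility(e: np.ndarray,
                       s_post_now: np.ndarray, s_post_prev: np.ndarray,
                       s_pre_now: np.ndarray, s_pre_prev: np.ndarray,
                       tau_e: float, f: float,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Forward-Euler step of the eligibility-trace dynamics (unit step).

    ``e'_ij = e_ij (1 - 1/tau_e) + post_i(t) pre_j(t-1)
              - f post_i(t-1) pre_j(t)``

    with ``i`` post-synaptic and ``j`` pre-synaptic.  The causal term
    (pre fired one step before post) potentiates; the anti-causal term
    depresses, scaled by ``f``.  When ``mask`` is given the trace is
    restricted to existing connections.
    """
    if tau_e <= 1:
        raise ConfigurationError("tau_e must exceed 1")
    decay = 1.0 - 1.0 / tau_e
    out = e * decay
    out += np.outer(s_post_now, s_pre_prev)
    out -= f * np.outer(s_post_prev, s_pre_now)
    if mask is not None:
        out *= mask
    return out


def apply_reward(w: np.ndarray, e: np.ndarray, reward,
                 eta: float, mask: np.ndarray | None = None) -> np.ndarray:
    """Reward-gated weight update ``w' = w + eta * m * e``, floored at 0.

    ``reward`` may be a :class:`RewardSignal` or the bare neuromodulation
    factor ``m``.  Entries off ``mask`` stay exactly zero.  With ``m = 0``
    the update is the identity.
    """
    m = reward.m if isinstance(reward, RewardSignal) else float(reward)
    if w.shape != e.shape:
        raise ContractError("weight/eligibility shape mismatch")
    if m == 0.0:
        return w.copy()
    out = w + (eta * m) * e
    np.maximum(out, 0.0, out=out)
    if mask is not None:
        out *= mask
    return out


def normalize_rows(w: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Scale each row with positive sum so it sums to 1.

    All-zero rows are left untouched (a neuron with no afferents).  Rows
    must be nonnegative.
    """
    if np.any(w < 0):
        raise ContractError("normalize_rows requires nonnegative weights")
    out = w.copy()
    sums = out.sum(axis=1)
    nz = sums > 0
    out[nz] /= sums[nz, None]
    if mask is not None:
        out *= mask
    return out


def intrinsic_update(theta: np.ndarray, s: np.ndarray,
                     mu_ip, eta_ip: float) -> np.ndarray:
    """Homeostatic threshold step ``theta' = theta + eta_ip (s - mu_ip)``.

    The threshold of a neuron firing above its target rate rises, pushing
    the rate down, and vice versa.  ``mu_ip`` may be a scalar (recurrent
    excitatory neurons) or a per-neuron vector (output neurons).
    """
    if theta.shape != s.shape:
        raise ContractError("theta/state shape mismatch")
    return theta + eta_ip * (s - np.asarray(mu_ip))


def structural_step(mask: np.ndarray, w: np.ndarray, p_sp: float,
                    w_th: float, w_new: float,
                    rng: np.random.Generator, t: int = 0
                    ) -> tuple[np.ndarray, np.ndarray, list]:
    """One application of structural plasticity to the E-E matrix.

    Pruning first: every existing connection with weight below ``w_th`` is
    removed.  Growth second, on the post-prune mask: every nonexistent
    off-diagonal pair independently becomes a connection with probability
    ``p_sp`` and weight ``w_new``; a pair pruned in this call cannot regrow
    in the same call.  Returns the new mask, new weights and the list of
    :class:`StructuralEvent` records.
    """
    if w_th >= w_new:
        raise ConfigurationError("w_th must be smaller than w_new")
    if mask.shape[0] != mask.shape[1] or np.any(np.diagonal(mask)):
        raise ContractError("mask must be square with zero diagonal")
    events: list[StructuralEvent] = []

    prune = mask & (w < w_th)
    pi, pj = np.nonzero(prune)
    new_mask = mask & ~prune
    new_w = w * new_mask
    for i, j in zip(pi.tolist(), pj.tolist()):
        events.append(StructuralEvent("death", i, j, t, float(w[i, j])))

    vacant = ~new_mask & ~prune  # pairs pruned this call may not regrow
    np.fill_diagonal(vacant, False)
    vi, vj = np.nonzero(vacant)
    n_vacant = vi.size
    if n_vacant:
        # Binomial count + uniform choice of distinct pairs is equivalent
        # to independent per-pair Bernoulli(p_sp) draws.
        n_births = rng.binomial(n_vacant, p_sp)
        if n_births:
            pick = rng.choice(n_vacant, size=n_births, replace=False)
            bi, bj = vi[pick], vj[pick]
            new_mask[bi, bj] = True
            new_w[bi, bj] = w_new
            for i, j in zip(bi.tolist(), bj.tolist()):
                events.append(StructuralEvent("birth", i, j, t, w_new))
    return new_mask, new_w, events


def update_baseline(b: float, r: float, alpha: float) -> float:
    """Exponential moving average of the reward: ``b' = (1-a) b + a r``."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    return (1.0 - alpha) * b + alpha * r
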