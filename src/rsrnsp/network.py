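"""Binary-neuron recurrent network: construction, encoding, one-step dynamics.

The recurrent layer holds ``N^E`` excitatory and ``N^I = 0.2 N^E``
inhibitory binary threshold neurons.  Excitatory-to-excitatory connections
are sparse (mask ``c_ee``); excitatory/inhibitory cross-connections and the
readout projection are full.  A neuron spikes when its summed input reaches
its threshold (Heaviside step with ``Theta(0) = 1``), and all populations
update synchronously from the previous time step's values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ConfigurationError, NetworkConfig


class ContractError(ValueError):
    """Raised when operation inputs violate a dimensional or value contract."""


@dataclass
class WeightMatrices:
    """The four weight matrices and the E-E connectivity mask.

    ``w_ee`` (``N^E x N^E``) and ``w_oe`` (``n_output x N^E``) are plastic;
    ``w_ei`` (``N^E x N^I``) and ``w_ie`` (``N^I x N^E``) are fixed after
    initialisation.  ``c_ee`` is a binary mask with zero diagonal; no
    inhibitory-to-inhibitory weights exist anywhere in the model.
    Row ``i`` of each matrix holds the afferent weights of neuron ``i``
    (``w[i, j]`` is the connection from ``j`` to ``i``).
    """

    w_ee: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray
    w_oe: np.ndarray
    c_ee: np.ndarray

    def copy(self) -> "WeightMatrices":
        return WeightMatrices(self.w_ee.copy(), self.w_ei.copy(),
                              self.w_ie.copy(), self.w_oe.copy(),
                              self.c_ee.copy())


@dataclass
class NetworkState:
    """Dynamic variables of the network at one time step."""

    s_e: np.ndarray
    s_in: np.ndarray
    s_o: np.ndarray
    theta_e: np.ndarray
    theta_in: np.ndarray
    theta_o: np.ndarray
    e_ee: np.ndarray
    e_oe: np.ndarray
    baseline_b: float = 0.0
    t: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(self.s_e.copy(), self.s_in.copy(),
                            self.s_o.copy(), self.theta_e.copy(),
                            self.theta_in.copy(), self.theta_o.copy(),
                            self.e_ee.copy(), self.e_oe.copy(),
                            self.baseline_b, self.t)


class InputMap:
    """Mapping from task symbols to disjoint excitatory input subsets.

    Symbol ``k`` of the alphabet drives the contiguous index block
    ``[k * n_input_subset, (k + 1) * n_input_subset)``; a ``None`` symbol
    (no-input step) yields an all-zero drive.
    """

    def __init__(self, symbols, n_input_subset: int, n_excitatory: int):
        symbols = list(symbols)
        if len(symbols) * n_input_subset > n_excitatory:
            raise ConfigurationError(
                "input subsets do not fit into the excitatory population"
            )
        self.n_excitatory = int(n_excitatory)
        self.n_input_subset = int(n_input_subset)
        self.symbols = symbols
        self.subsets = {
            s: np.arange(k * n_input_subset, (k + 1) * n_input_subset)
            for k, s in enumerate(symbols)
        }
        # Pre-built drive vectors; encode_input returns copies of these.
        self._drives = {}
        for s, idx in self.subsets.items():
            u = np.zeros(n_excitatory)
            u[idx] = 1.0
            self._drives[s] = u
        self._silence = np.zeros(n_excitatory)

    def drive(self, symbol) -> np.ndarray:
        """Drive vector for ``symbol`` (shared read-only buffer)."""
        if symbol is None:
            return self._silence
        try:
            return self._drives[symbol]
        except KeyError:
            raise KeyError(f"unknown input symbol: {symbol!r}") from None


def encode_input(symbol, input_map: InputMap,
                 n_excitatory: int | None = None) -> np.ndarray:
    """External drive ``u``: 1 on the symbol's subset, 0 elsewhere.

    ``symbol=None`` encodes a silent (no-input) step, as used while warming
    up the generation task.
    """
    if n_excitatory is not None and n_excitatory != input_map.n_excitatory:
        raise ContractError("n_excitatory does not match the input map")
    return input_map.drive(symbol).copy()


def init_network(config: NetworkConfig, symbols=None
                 ) -> tuple[WeightMatrices, NetworkState, InputMap]:
    """Construct weights, state and input map from a validated config.

    All weights are drawn uniformly on [0, 1] and row-normalized so every
    neuron's afferent weights sum to 1; the E-E mask is drawn so each
    off-diagonal pair is connected independently with probability ``p_c``;
    thresholds are uniform on their configured ranges.  All randomness
    derives from ``config.seed``.
    """
    ne, ni, no = config.n_excitatory, config.n_inhibitory, config.n_output
    if symbols is None:
        symbols = list(range(no))
    symbols = list(symbols)
    if len(symbols) != no:
        raise ConfigurationError(
            f"got {len(symbols)} symbols for {no} output neurons"
        )
    rng = np.random.default_rng(config.seed)

    c_ee = rng.random((ne, ne)) < config.p_c
    np.fill_diagonal(c_ee, False)

    w_ee = rng.random((ne, ne)) * c_ee
    w_ei = rng.random((ne, ni))
    w_ie = rng.random((ni, ne))
    w_oe = rng.random((no, ne))
    for w in (w_ee, w_ei, w_ie, w_oe):
        _normalize_rows_inplace(w)

    lo, hi = config.theta_e_range
    theta_e = rng.uniform(lo, hi, ne)
    lo, hi = config.theta_in_range
    theta_in = rng.uniform(lo, hi, ni)
    lo, hi = config.theta_o_range
    theta_o = rng.uniform(lo, hi, no)

    state = NetworkState(
        s_e=np.zeros(ne), s_in=np.zeros(ni), s_o=np.zeros(no),
        theta_e=theta_e, theta_in=theta_in, theta_o=theta_o,
        e_ee=np.zeros((ne, ne)), e_oe=np.zeros((no, ne)),
        baseline_b=0.0, t=0,
    )
    weights = WeightMatrices(w_ee, w_ei, w_ie, w_oe, c_ee)
    input_map = InputMap(symbols, config.n_input_subset, ne)
    return weights, state, input_map


def _normalize_rows_inplace(w: np.ndarray) -> None:
    sums = w.sum(axis=1)
    nz = sums > 0
    w[nz] /= sums[nz, None]


def step_recurrent(state: NetworkState, weights: WeightMatrices,
                   u: np.ndarray) -> NetworkState:
    """One synchronous update of the recurrent layer.

    The new excitatory state is computed from the old excitatory and
    inhibitory states plus the external drive; the new inhibitory state
    from the old excitatory state.  ``Theta(0) = 1``: a neuron at exactly
    threshold fires.
    """
    ne = weights.w_ee.shape[0]
    if u.shape != (ne,) or state.s_e.shape != (ne,):
        raise ContractError("drive/state length does not match N^E")
    psi_e = (weights.w_ee @ state.s_e - weights.w_ei @ state.s_in
             + u - state.theta_e)
    s_e = (psi_e >= 0.0).astype(float)
    psi_in = weights.w_ie @ state.s_e - state.theta_in
    s_in = (psi_in >= 0.0).astype(float)
    new = replace(state, s_e=s_e, s_in=s_in, t=state.t + 1)
    return new


def step_output(state: NetworkState, weights: WeightMatrices
                ) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the readout layer against the state's excitatory vector.

    Returns the binary output states and the raw potentials
    ``psi^o = W^OE s^e - theta^o`` (the potentials drive symbol readout).
    """
    if weights.w_oe.shape[1] != state.s_e.shape[0]:
        raise ContractError("output weights do not match N^E")
    psi_o = weights.w_oe @ state.s_e - state.theta_o
    s_o = (psi_o >= 0.0).astype(float)
    return s_o, psi_o


def readout_symbol(output_potentials: np.ndarray, symbols):
    """Symbol of the output neuron with maximal potential.

    Ties resolve to the lowest neuron index, so the readout is
    deterministic.
    """
    potentials = np.asarray(output_potentials)
    if potentials.size == 0:
        raise ContractError("empty potentials vector")
    if potentials.size != len(symbols):
        raise ContractError("potentials/symbols length mismatch")
    return symbols[int(np.argmax(potentials))]
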