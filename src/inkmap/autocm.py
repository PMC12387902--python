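"""Auto Contractive Map (AutoCM) association learning.

The AutoCM is a three-layer unsupervised network with one unit per
variable in each layer.  Writing ``s`` for a scaled input record in
[0, 1]^N, ``C`` for the contraction constant, ``v`` for the N
input->hidden mono-connection weights and ``w`` for the N x N
hidden->output weight matrix, a forward pass computes

    h_i   = s_i * (1 - v_i / C)                (contracted hidden signal)
    net_i = sum_j h_j * (1 - w_ij / C)         (aggregate input to output i)
    o_i   = h_i * (1 - net_i / C)              (output signal)

and the weight updates are

    dv_i  = (s_i - h_i) * (1 - v_i / C)
    dw_ij = (h_i - o_i) * (1 - w_ij / C) * h_j

applied online (after every record) with a learning coefficient.  The
mono-connections saturate monotonically toward C, shutting the hidden
signals down; training stops when every v_i is within tolerance of C.
The frozen w matrix then encodes pairwise variable associations: pairs
of variables that were strongly and jointly active accumulated large
weights before the signal died out.  Note that ``net`` can transiently
exceed C, driving ``o`` negative; this is part of the dynamics, and
weights are clipped to [0, C] purely as a numerical safeguard.

Symmetrizing and dividing by C yields an association matrix in [0, 1]
whose strongest entries are the "connection values" drawn on the
variable graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import ScaledMatrix


@dataclass
class AutoCMConfig:
    """Hyperparameters of the contractive map.

    The learning coefficient defaults to 0.01: small enough that no
    update overshoots the contraction bound C on desk-scale tables
    (keeping the top of the association scale un-flattened) and that the
    learned associations are insensitive to record order, while still
    converging in a few thousand epochs.
    """

    contraction: float = 1.0  # C
    learning_rate: float = 0.01  # lambda
    init_weight: float = 0.01  # epsilon_0, as a fraction of C: w, v start at this
    tolerance: float = 1e-6  # convergence: max_i (C - v_i) <= tolerance * C
    max_epochs: int = 10_000
    seed: int = 0  # record presentation order

    def __post_init__(self) -> None:
        if self.contraction <= 0:
            raise ValueError("contraction constant C must be positive")
        if not (0 < self.init_weight < self.contraction):
            raise ValueError("init_weight must lie in (0, C)")
        if self.learning_rate <= 0 or self.tolerance <= 0:
            raise ValueError("learning_rate and tolerance must be positive")


@dataclass
class AutoCMState:
    v: np.ndarray  # (N,) mono-connection weights
    w: np.ndarray  # (N, N) hidden->output weights
    config: AutoCMConfig
    variable_names: list[str] = field(default_factory=list)
    epochs: int = 0
    converged: bool = False

    @property
    def saturation_gap(self) -> float:
        """max_i (C - v_i), the distance from full mono-weight saturation."""
        return float((self.config.contraction - self.v).max())


def initial_state(n_variables: int, config: AutoCMConfig,
                  variable_names: list[str] | None = None) -> AutoCMState:
    eps = config.init_weight
    return AutoCMState(
        v=np.full(n_variables, eps, dtype=float),
        w=np.full((n_variables, n_variables), eps, dtype=float),
        config=config,
        variable_names=list(variable_names or []),
    )


def autocm_forward(s: np.ndarray, state: AutoCMState):
    """One forward pass; returns (h, net, o)."""
    s = np.asarray(s, dtype=float)
    if s.shape != state.v.shape:
        raise ValueError("record dimension does not match state")
    if not np.isfinite(s).all():
        raise ValueError("non-finite input record")
    C = state.config.contraction
    h = s * (1.0 - state.v / C)
    net = (1.0 - state.w / C) @ h
    o = h * (1.0 - net / C)
    return h, net, o


def autocm_update(s: np.ndarray, state: AutoCMState) -> AutoCMState:
    """Apply one online update for record ``s`` (mutates and returns state)."""
    C = state.config.contraction
    lam = state.config.learning_rate
    s = np.asarray(s, dtype=float)
    h, net, o = autocm_forward(s, state)
    dv = (s - h) * (1.0 - state.v / C)
    dw = (h - o)[:, None] * (1.0 - state.w / C) * h[None, :]
    state.v = np.clip(state.v + lam * dv, 0.0, C)
    state.w = np.clip(state.w + lam * dw, 0.0, C)
    return state


def train_autocm(scaled: ScaledMatrix, config: AutoCMConfig | None = None) -> AutoCMState:
    """Online training until mono-weight saturation or the epoch cap.

    Records are presented in a freshly seeded shuffled order every
    epoch.  At the default learning rate the learned associations agree
    across different orderings to well under 0.01, so the seed is a
    reproducibility knob rather than a result knob.  If some variable
    never carries signal (an all-zero column) its mono-weight cannot
    saturate; training then runs to ``max_epochs`` and the state is
    returned with ``converged=False`` and a warning.
    """
    cfg = config or AutoCMConfig()
    X = np.asarray(scaled.values, dtype=float)
    n, N = X.shape
    if n < 1 or N < 2:
        raise ValueError("training needs at least 1 record and 2 variables")
    rng = np.random.default_rng(cfg.seed)
    state = initial_state(N, cfg, scaled.variable_names)
    tol = cfg.tolerance * cfg.contraction
    for epoch in range(cfg.max_epochs):
        for i in rng.permutation(n):
            autocm_update(X[i], state)
        state.epochs = epoch + 1
        if state.saturation_gap <= tol:
            state.converged = True
            break
    if not state.converged:
        warnings.warn(
            f"AutoCM did not reach saturation in {cfg.max_epochs} epochs "
            f"(gap {state.saturation_gap:.3g})",
            stacklevel=2,
        )
    return state


@dataclass
class AssociationMatrix:
    """Symmetric variable-variable association strengths in [0, 1]."""

    variable_names: list[str]
    values: np.ndarray  # (N, N), symmetric, unit diagonal

    def entry(self, u: str, v: str) -> float:
        i = self.variable_names.index(u)
        j = self.variable_names.index(v)
        return float(self.values[i, j])

    def top_edges(self, k: int | None = None) -> list[tuple[str, str, float]]:
        """All (u, v, strength) pairs sorted by decreasing strength
        (ties lexicographic), optionally truncated to the first k."""
        N = len(self.variable_names)
        edges = []
        for i in range(N):
            for j in range(i + 1, N):
                u, v = sorted([self.variable_names[i], self.variable_names[j]])
                edges.append((u, v, float(self.values[i, j])))
        edges.sort(key=lambda e: (-e[2], e[0], e[1]))
        return edges if k is None else edges[:k]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.variable_names,
                            columns=self.variable_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def normalized_associations(state: AutoCMState,
                            variable_names: list[str] | None = None) -> AssociationMatrix:
    """Symmetrize w by arithmetic mean, normalize by C, clip to [0, 1].

    The diagonal is defined as 1 (a variable is maximally associated
    with itself).
    """
    names = list(variable_names or state.variable_names)
    C = state.config.contraction
    a = np.clip((state.w + state.w.T) / (2.0 * C), 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    if len(names) != a.shape[0]:
        raise ValueError("variable names do not match weight matrix size")
    return AssociationMatrix(names, a)
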