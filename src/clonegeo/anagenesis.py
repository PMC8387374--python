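"""Along-branch (anagenetic) range evolution: dispersal and extinction.

Range evolution along a phylogenetic branch is a continuous-time Markov
chain on the range state space.  A lineage expands its range by adding one
area at rate *d* per candidate area (dispersal), and contracts it by losing
one occupied area at rate *e* (local extinction).  Because the null range is
removed from the state space, singleton ranges cannot contract: a clone is
always present in at least one site, so Q rows sum to zero and P(t) is
stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .range_space import RangeSpace, RangeState


@dataclass(frozen=True)
class AnageneticParams:
    """Anagenetic rates, per unit branch length.

    d : rate of range expansion by one area (dispersal).
    e : rate of local range loss (extinction).
    """

    d: float
    e: float

    def __post_init__(self) -> None:
        for name in ("d", "e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")


@dataclass
class RateMatrix:
    Q: np.ndarray
    space: RangeSpace


def build_rate_matrix(params: AnageneticParams, space: RangeSpace) -> RateMatrix:
    """Instantaneous rate matrix over the range space.

    Off-diagonal rate d for each one-area expansion (respecting the maximum
    range size), rate e for each one-area contraction of a range of size
    >= 2.  Diagonals make rows sum to zero.
    """
    n = len(space)
    Q = np.zeros((n, n))
    for i, st in enumerate(space.states):
        if st.size < space.max_range_size:
            for a in range(space.n_areas):
                if a not in st:
                    Q[i, space.index_of(st.with_area(a))] += params.d
        if st.size >= 2:
            for a in st.areas:
                Q[i, space.index_of(st.without_area(a))] += params.e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q=Q, space=space)


def transition_probabilities(rate_matrix: RateMatrix, t: float) -> np.ndarray:
    """Branch transition matrix P = exp(Qt)."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    if t == 0:
        return np.eye(rate_matrix.Q.shape[0])
    return expm(rate_matrix.Q * t)


class BranchPropagator:
    """Computes P(t) for many branch lengths with one spectral decomposition.

    Falls back to a dense matrix exponential per branch when Q is too close
    to defective for the eigendecomposition to be reliable.
    """

    def __init__(self, rate_matrix: RateMatrix) -> None:
        self.rate_matrix = rate_matrix
        Q = rate_matrix.Q
        self._spectral = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            err = np.max(np.abs((V * w) @ Vinv - Q))
            scale = max(1.0, np.max(np.abs(Q)))
            if err < 1e-10 * scale:
                self._w, self._V, self._Vinv = w, V, Vinv
                self._spectral = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        n = self.rate_matrix.Q.shape[0]
        if t == 0:
            return np.eye(n)
        if self._spectral:
            P = np.real((self._V * np.exp(self._w * t)) @ self._Vinv)
            np.clip(P, 0.0, 1.0, out=P)
            return P
        return expm(self.rate_matrix.Q * t)
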