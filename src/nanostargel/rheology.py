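"""Virial stress, multiple-tau stress autocorrelation and Green–Kubo viscosity.

The zero-shear viscosity follows from the Green–Kubo relation: the shear
relaxation modulus is the equilibrium autocorrelation of the off-diagonal
virial stress,

    G(t) = (V / 3 k_B T) Σ_{αβ ∈ {xy, xz, yz}} 〈P_αβ(0) P_αβ(t)〉,

and η = ∫₀^∞ G(t) dt.  The correlation is accumulated with the multiple-tau
(hierarchical block-averaging) scheme: level 0 stores raw samples, level k
stores m-fold block averages of level k−1, giving quasi-logarithmic lags at
streaming cost.  With overdamped dynamics the stress has no kinetic part;
P_αβ = (1/V) Σ_pairs r_α F_β over all interacting bead pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "stress_tensor",
    "MultipleTauCorrelator",
    "ViscosityResult",
    "green_kubo",
]


def stress_tensor(state, ff) -> np.ndarray:
    """Off-diagonal virial stress (P_xy, P_xz, P_yz) of a configuration, ε/σ³."""
    from .potentials import compute_forces

    res = compute_forces(state, ff)
    V = state.box_L**3
    w = res.virial
    return np.array([w[0, 1], w[0, 2], w[1, 2]]) / V


class MultipleTauCorrelator:
    """Streaming multiple-tau autocorrelator for one or more channels.

    Parameters
    ----------
    p:
        Points per level (lags 0..p−1 at level 0; p/m..p−1 at higher levels).
    m:
        Block-averaging factor between levels.
    n_channels:
        Number of simultaneously correlated series (e.g. 3 stress components).

    The lag-0 accumulator equals the second moment of the pushed series, so
    ``values()[0]`` is 〈x²〉 exactly (up to floating-point accumulation).
    """

    def __init__(self, p: int = 16, m: int = 2, n_channels: int = 1, n_levels: int = 32):
        if p % m:
            raise ValueError("p must be a multiple of m")
        self.p = p
        self.m = m
        self.n_channels = n_channels
        self.n_levels = n_levels
        self._shift = np.zeros((n_levels, p, n_channels))
        self._filled = np.zeros((n_levels, p), dtype=bool)
        self._corr = np.zeros((n_levels, p, n_channels))
        self._count = np.zeros((n_levels, p), dtype=np.int64)
        self._accum = np.zeros((n_levels, n_channels))
        self._naccum = np.zeros(n_levels, dtype=np.int64)
        self.n_pushed = 0

    def push(self, sample) -> None:
        """Add one sample (scalar or length-``n_channels``)."""
        x = np.atleast_1d(np.asarray(sample, dtype=float))
        if x.shape != (self.n_channels,):
            raise ValueError(f"expected {self.n_channels} channel(s), got {x.shape}")
        self.n_pushed += 1
        self._push_level(0, x)

    def _push_level(self, level: int, x: np.ndarray) -> None:
        if level >= self.n_levels:
            return
        shift = self._shift[level]
        shift[1:] = shift[:-1]
        shift[0] = x
        filled = self._filled[level]
        filled[1:] = filled[:-1].copy()
        filled[0] = True
        lag0 = 0 if level == 0 else self.p // self.m
        for lag in range(lag0, self.p):
            if filled[lag]:
                self._corr[level, lag] += x * shift[lag]
                self._count[level, lag] += 1
        self._accum[level] += x
        self._naccum[level] += 1
        if self._naccum[level] == self.m:
            self._push_level(level + 1, self._accum[level] / self.m)
            self._accum[level] = 0.0
            self._naccum[level] = 0

    def lags(self, dt_sample: float = 1.0) -> np.ndarray:
        """Lag times of :meth:`values`, in units of the sampling interval."""
        out = []
        for level in range(self.n_levels):
            lag0 = 0 if level == 0 else self.p // self.m
            block = self.m**level
            for lag in range(lag0, self.p):
                if self._count[level, lag] > 0:
                    out.append(lag * block * dt_sample)
        return np.asarray(out)

    def values(self) -> np.ndarray:
        """Autocorrelation 〈x(0)x(t)〉 per channel at :meth:`lags`, shape (n_lags, n_channels)."""
        out = []
        for level in range(self.n_levels):
            lag0 = 0 if level == 0 else self.p // self.m
            for lag in range(lag0, self.p):
                if self._count[level, lag] > 0:
                    out.append(self._corr[level, lag] / self._count[level, lag])
        return np.asarray(out)


@dataclass
class ViscosityResult:
    """G(t) and its Green–Kubo integral."""

    lags: np.ndarray           #: τ_Br
    G_of_t: np.ndarray         #: shear relaxation modulus, ε/σ³
    eta: float                 #: viscosity, k_BT·τ_Br/σ³
    cutoff: float              #: integration cutoff, τ_Br
    eta_err: float             #: quadrature/noise-floor error estimate
    lower_bound: bool          #: True when G(t) had not decayed by the run end


def green_kubo(
    correlator,
    V: float,
    T: float,
    dt_sample: float,
    cutoff: float | None = None,
) -> ViscosityResult:
    """Viscosity from the stress autocorrelation accumulated in ``correlator``.

    G(t) = (V/3k_BT)·Σ_αβ C_αβ(t) with the three off-diagonal channels
    averaged; η is the trapezoidal integral of G up to ``cutoff`` (default:
    the first lag where G reaches the noise floor, taken as its first
    non-positive value).  If G never reaches the floor within the available
    lags, η is a lower bound and is flagged as such.

    ``correlator`` is either a :class:`MultipleTauCorrelator` or a pair
    ``(lags, C)`` of precomputed per-channel autocorrelations (in units of
    the sampling interval and stress², respectively).
    """
    if isinstance(correlator, tuple):
        lags, C = correlator
        lags = np.asarray(lags, dtype=float) * dt_sample
        C = np.asarray(C, dtype=float)
    else:
        lags = correlator.lags(dt_sample)
        C = correlator.values()
    if C.ndim == 1:
        C = C[:, None]
    G = V / (3.0 * T) * C.sum(axis=1)
    order = np.argsort(lags)
    lags, G = lags[order], G[order]
    lower = False
    if cutoff is None:
        nonpos = np.flatnonzero(G <= 0)
        if len(nonpos) and nonpos[0] > 0:
            cutoff = float(lags[nonpos[0]])
        else:
            cutoff = float(lags[-1])
            lower = True
    mask = lags <= cutoff
    eta = float(np.trapezoid(G[mask], lags[mask]))
    # error estimate: sensitivity of the integral to the last decade of lags
    tail = mask & (lags > cutoff / 2)
    eta_err = float(abs(np.trapezoid(G[tail], lags[tail]))) if tail.sum() > 1 else 0.0
    return ViscosityResult(
        lags=lags, G_of_t=G, eta=eta, cutoff=cutoff, eta_err=eta_err, lower_bound=lower
    )
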