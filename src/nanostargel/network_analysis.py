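"""Trajectory analysis: contacts, melting, relaxation, MSD, RDF, graphs, ϕ.

The nanostar-level network is a graph whose vertices are stars and whose
edges are patch–patch bonds; from it follow the contact count N_c, the
bonded fraction θ = 2N_c/(Nf), the melting curve 〈θ〉(T) with its midpoint
T_m, the degree histogram and the largest-component fraction c_s.  Dynamic
observables are the relaxation time τ_c of the N_c(t) autocorrelation (with
an Arrhenius fit across temperatures), the centre-of-mass MSD and the
core–core radial distribution function g(r).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy import optimize

from .geometry import N_ARMS, NanostarTemplate, bending_angle_axes, quat_to_matrix

__all__ = [
    "ContactGraph",
    "find_contacts",
    "contacts_from_state",
    "theta",
    "MeltingPoint",
    "melting_curve",
    "RelaxationTime",
    "relaxation_time",
    "ArrheniusFit",
    "arrhenius_fit",
    "msd",
    "rdf",
    "GraphMetrics",
    "graph_metrics",
    "collect_bending_angles",
    "phi_distribution",
]


@dataclass
class ContactGraph:
    """Nanostar-level bond network.

    ``graph`` is a :class:`networkx.MultiGraph` on the star indices 0..N−1
    (two stars may be doubly bonded through two arm pairs, as in the box-like
    motifs of non-planar gels); each edge carries the bonded arm indices
    ``arm_a``/``arm_b`` (for the lower/higher star index) and the patch
    separation ``dist``.  Every patch participates in at most one edge: when
    several partners lie within range only the nearest is kept.
    """

    graph: nx.MultiGraph
    n_stars: int
    multi_partner_patches: int = 0  #: patches that had ≥2 candidates in range

    @property
    def n_contacts(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(i) for i in range(self.n_stars)])

    def theta(self, f: int = N_ARMS) -> float:
        return theta(self.n_contacts, self.n_stars, f)


def find_contacts(
    patch_positions: np.ndarray, box_L: float, r_bond: float
) -> ContactGraph:
    """Bond network from patch coordinates.

    Parameters
    ----------
    patch_positions:
        (N, f, 3) world positions of every patch site (star, arm).
    r_bond:
        Bond criterion: patches closer than this (minimum image) are bonded,
        with a nearest-partner tie-break so each patch bonds at most once.
    """
    n, f, _ = patch_positions.shape
    flat = np.mod(patch_positions.reshape(n * f, 3), box_L)
    tree = cKDTree(flat, boxsize=box_L)
    candidate = tree.query_pairs(r_bond, output_type="ndarray")
    g = nx.MultiGraph()
    g.add_nodes_from(range(n))
    if len(candidate) == 0:
        return ContactGraph(graph=g, n_stars=n)
    star = candidate // f
    keep = star[:, 0] != star[:, 1]  # a star cannot bond to itself
    candidate = candidate[keep]
    if len(candidate) == 0:
        return ContactGraph(graph=g, n_stars=n)
    d = flat[candidate[:, 0]] - flat[candidate[:, 1]]
    d -= box_L * np.round(d / box_L)
    dist = np.linalg.norm(d, axis=1)
    order = np.argsort(dist)
    used = np.zeros(n * f, dtype=bool)
    seen = np.zeros(n * f, dtype=np.int64)
    for k in order:
        i, j = candidate[k]
        seen[i] += 1
        seen[j] += 1
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        a, b = (i, j) if i // f < j // f else (j, i)
        g.add_edge(
            int(a // f),
            int(b // f),
            arm_a=int(a % f),
            arm_b=int(b % f),
            dist=float(dist[k]),
        )
    multi = int(np.sum(seen > 1))
    return ContactGraph(graph=g, n_stars=n, multi_partner_patches=multi)


def contacts_from_state(state, ff) -> ContactGraph:
    """Bond network of a live simulation state (r_bond = the patch cutoff)."""
    return find_contacts(state.patch_positions(), state.box_L, ff.r_cut_patch)


def theta(n_c: int, N: int, f: int = N_ARMS) -> float:
    """Fraction of bonded patches θ = 2 N_c / (N f), clipped to [0, 1]."""
    if N <= 0 or f <= 0:
        raise ValueError("N and f must be positive")
    return float(np.clip(2.0 * n_c / (N * f), 0.0, 1.0))


@dataclass
class MeltingPoint:
    """Melting curve 〈θ〉(T) and its midpoint T_m (where 〈θ〉 = 0.5)."""

    temperatures: np.ndarray
    theta_mean: np.ndarray
    theta_err: np.ndarray
    T_m: float


def melting_curve(
    temperatures, theta_means, theta_errs=None
) -> MeltingPoint:
    """T_m by monotone linear interpolation of 〈θ〉(T) at the 0.5 crossing.

    Raises
    ------
    ValueError
        If the observed 〈θ〉 values do not bracket 0.5.
    """
    T = np.asarray(temperatures, dtype=float)
    th = np.asarray(theta_means, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least two temperatures")
    order = np.argsort(T)
    T, th = T[order], th[order]
    err = (
        np.asarray(theta_errs, dtype=float)[order]
        if theta_errs is not None
        else np.zeros_like(th)
    )
    if not (th.max() >= 0.5 >= th.min()):
        raise ValueError(
            f"melting curve does not bracket theta = 0.5 "
            f"(observed range [{th.min():.3f}, {th.max():.3f}])"
        )
    # theta decreases with T: interpolate T as a function of decreasing theta
    T_m = float(np.interp(0.5, th[::-1], T[::-1]))
    return MeltingPoint(temperatures=T, theta_mean=th, theta_err=err, T_m=T_m)


@dataclass
class RelaxationTime:
    """τ_c from an exponential fit to the N_c(t) fluctuation autocorrelation."""

    tau: float                 #: τ_Br; a lower bound if ``lower_bound``
    lower_bound: bool
    lags: np.ndarray
    acf: np.ndarray


def _acf(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    var = np.dot(x, x) / n
    if var == 0:
        return np.ones(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    c = np.fft.irfft(f * np.conj(f), nfft)[:n]
    return c / (var * n) * (n / (n - np.arange(n)))


def relaxation_time(
    n_c_series: np.ndarray, dt_sample: float, fit_floor: float = 0.05
) -> RelaxationTime:
    """Relaxation time of a stationary N_c(t) segment.

    Computes the normalised fluctuation autocorrelation
    C(t) = 〈δN_c(t₀)δN_c(t₀+t)〉/〈δN_c²〉 and least-squares fits
    exp(−t/τ_c) over the window C ∈ [``fit_floor``, 1].  If C never decays
    below ``fit_floor`` within half the series (a frozen network) the fit is
    still performed on the available window and the result is flagged as a
    lower bound.
    """
    x = np.asarray(n_c_series, dtype=float)
    if len(x) < 8:
        raise ValueError("series too short for an autocorrelation estimate")
    c = _acf(x)
    nmax = len(x) // 2
    c = c[:nmax]
    lags = np.arange(nmax) * dt_sample
    below = np.flatnonzero(c < fit_floor)
    if len(below):
        end = max(int(below[0]), 2)
        lower = False
    else:
        end = nmax
        lower = True
    tfit, cfit = lags[1:end], c[1:end]
    pos = cfit > 0
    if pos.sum() >= 2:
        slope = -np.polyfit(tfit[pos], np.log(cfit[pos]), 1, w=np.sqrt(cfit[pos]))[0]
        tau0 = 1.0 / slope if slope > 0 else lags[min(end, nmax - 1)]
    else:
        tau0 = dt_sample
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda t, tau: np.exp(-t / tau), tfit, cfit, p0=[max(tau0, dt_sample)]
            )
        tau = float(abs(popt[0]))
    except RuntimeError:
        tau = float(max(tau0, dt_sample))
    if tau <= dt_sample * 1.5 and not lower:
        # decorrelated within one sampling interval: resolution-limited
        tau = float(max(tau, dt_sample))
    return RelaxationTime(tau=tau, lower_bound=lower, lags=lags, acf=c)


@dataclass
class ArrheniusFit:
    """τ_c(T) = a · exp(E_a / k_B T)."""

    a: float                   #: prefactor, τ_Br
    E_a: float                 #: activation energy, k_BT units
    cov: np.ndarray            #: covariance of (ln a, E_a)


def arrhenius_fit(temperatures, taus) -> ArrheniusFit:
    """Linear regression of ln τ_c on 1/T (≥ 3 temperatures)."""
    T = np.asarray(temperatures, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if len(T) < 3:
        raise ValueError("Arrhenius fit needs at least 3 temperatures")
    x = 1.0 / T
    y = np.log(tau)
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    E_a, ln_a = coeffs
    return ArrheniusFit(a=float(np.exp(ln_a)), E_a=float(E_a), cov=cov)


def msd(
    unwrapped: np.ndarray,
    times: np.ndarray,
    box_L: float | None = None,
    n_lags: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Time- and ensemble-averaged mean squared displacement.

    ``unwrapped`` is (n_frames, N, 3) of *unwrapped* centre positions at the
    equally spaced ``times``.  Lags are log-spaced.  If ``box_L`` is given,
    frame-to-frame jumps larger than L/2 raise (wrapped input detector).
    """
    r = np.asarray(unwrapped, dtype=float)
    t = np.asarray(times, dtype=float)
    if r.ndim != 3 or len(t) != r.shape[0]:
        raise ValueError("unwrapped must be (n_frames, N, 3) matching times")
    if box_L is not None:
        jumps = np.abs(np.diff(r, axis=0)).max() if len(r) > 1 else 0.0
        if jumps > box_L / 2:
            raise ValueError(
                "input looks wrapped: a frame-to-frame jump exceeds L/2; "
                "pass unwrapped coordinates (image flags applied)"
            )
    nf = r.shape[0]
    lags = np.unique(
        np.clip(np.round(np.logspace(0, np.log10(nf - 1), n_lags)).astype(int), 1, nf - 1)
    )
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = r[lag:] - r[:-lag]
        out[k] = np.mean(np.sum(d * d, axis=-1))
    return lags * (t[1] - t[0]), out


def rdf(
    frames: np.ndarray, box_L: float, r_max: float, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function of core positions, averaged over frames.

    Standard pair-count normalisation against the ideal-gas shell count in
    the periodic cubic box.  ``frames`` is (n_frames, N, 3); r_max ≤ L/2.
    Returns (bin centres, g(r)).
    """
    if r_max > box_L / 2:
        raise ValueError(f"r_max={r_max} exceeds half the box L/2={box_L / 2}")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    nf, n, _ = frames.shape
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for f in range(nf):
        pos = np.mod(frames[f], box_L)
        tree = cKDTree(pos, boxsize=box_L)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs) == 0:
            continue
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d -= box_L * np.round(d / box_L)
        counts += np.histogram(np.linalg.norm(d, axis=1), bins=edges)[0]
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    density = n / box_L**3
    ideal = 0.5 * n * density * shell  # expected pair count per frame
    g = counts / (nf * ideal)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


@dataclass
class GraphMetrics:
    """Degree histogram, component sizes and largest-component fraction."""

    degree_hist: dict
    component_sizes: list
    c_s: float

    @property
    def mean_degree(self) -> float:
        tot = sum(self.degree_hist.values())
        return sum(k * v for k, v in self.degree_hist.items()) / tot


def graph_metrics(contact_graph: ContactGraph) -> GraphMetrics:
    """Connectivity summary of a bond network."""
    deg = contact_graph.degrees
    hist = {k: int(np.sum(deg == k)) for k in range(N_ARMS + 1)}
    comps = sorted(
        (len(c) for c in nx.connected_components(contact_graph.graph)), reverse=True
    )
    c_s = comps[0] / contact_graph.n_stars if comps else 0.0
    return GraphMetrics(degree_hist=hist, component_sizes=comps, c_s=float(c_s))


def collect_bending_angles(
    frames_centers: np.ndarray,
    frames_quats: np.ndarray,
    graphs: list[ContactGraph],
    template: NanostarTemplate,
) -> np.ndarray:
    """Pool the bending angle ϕ over every bond of every frame (degrees).

    ϕ is the angle between one bonded arm axis and the reverse of its
    partner's axis (0° = perfectly aligned end-to-end hybridisation).
    """
    angles = []
    for centers, quats, cg in zip(frames_centers, frames_quats, graphs):
        rots = np.array([quat_to_matrix(q) for q in quats])
        world_axes = np.einsum("nab,mb->nma", rots, template.arm_axes)
        for i, j, data in cg.graph.edges(data=True):
            ax_a = world_axes[i, data["arm_a"]]
            ax_b = world_axes[j, data["arm_b"]]
            angles.append(bending_angle_axes(ax_a, ax_b))
    return np.asarray(angles)


def phi_distribution(angles: np.ndarray, bin_width: float = 5.0):
    """Histogram of bending angles with ``bin_width``-degree bins.

    Returns (bin centres, probability density per degree).
    """
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.asarray(angles), bins=edges, density=True)
    return 0.5 * (edges[1:] + edges[:-1]), counts
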