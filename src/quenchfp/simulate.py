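"""Exact stochastic simulators of the physical models.

All models here are linear Langevin systems: the tagged observable is a
sum of independent Ornstein-Uhlenbeck modes, so trajectories can be
sampled *exactly* on arbitrary (in particular geometric) time grids by
the OU transition density -- there is no time-step error.  The model is

    da_k = -lambda_k a_k dt + sqrt(2 T0) dW_k,      T0 = 1,

with the system prepared at t = 0 in equilibrium at temperature T
(a_k(0) ~ N(0, T/lambda_k)); the tagged coordinate is
x(t) = sum_k c_k a_k(t), observed as the displacement x(t) - x(0).

Supported mode systems:

* Edwards-Wilkinson (z = 2) and Mullins-Herring (z = 4) interfaces --
  tagged-point height, Hurst exponents H = 1/4 and 3/8;
* Rouse chains (tagged monomer, H = 1/4) and bead-spring networks with
  Vicsek-fractal connectivity (f = 4: H ~= 0.203), via Laplacian
  eigenmodes;
* arbitrary Gaussian processes given by a covariance matrix (fractional
  Brownian motion, quenched fBM, conditioned fBM), via Cholesky
  factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CovarianceSpec, ConditionalModel

__all__ = [
    "ModeSystem",
    "NetworkModel",
    "TrajectoryEnsemble",
    "interface_modes",
    "rouse_chain",
    "vicsek_network",
    "network_modes",
    "sample_tagged",
    "sample_gaussian",
    "msd_from_modes",
    "cov_from_modes",
    "hurst_fit",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ModeSystem:
    """Eigenmodes of a linear Langevin model seen by a tagged coordinate.

    ``eigenvalues`` are the mode relaxation rates (ascending),
    ``couplings`` the projections of the tagged coordinate on each mode;
    the zero mode (free center-of-mass diffusion), when present in the
    underlying model, is excluded from the observable by default.
    """

    eigenvalues: np.ndarray
    couplings: np.ndarray
    T: float = 1.0
    d: int = 1
    zero_mode_excluded: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        order = np.argsort(self.eigenvalues)
        self.eigenvalues = self.eigenvalues[order]
        self.couplings = self.couplings[order]
        if np.any(self.eigenvalues <= 0):
            raise ValueError("mode eigenvalues must be positive "
                             "(the zero mode is excluded from sampling)")


@dataclass
class NetworkModel:
    """Bead-spring network defined by its (unit-spring) Laplacian."""

    laplacian: np.ndarray
    tagged: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        Lp = np.asarray(self.laplacian, dtype=float)
        if not np.allclose(Lp, Lp.T):
            raise ValueError("Laplacian must be symmetric")
        if not np.allclose(Lp.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("Laplacian rows must sum to zero")
        self.laplacian = Lp

    @property
    def n_beads(self) -> int:
        return self.laplacian.shape[0]


@dataclass
class TrajectoryEnsemble:
    """n_traj x n_times x d displacements relative to each start point."""

    times: np.ndarray
    positions: np.ndarray
    seed: int | None = None
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.positions.ndim == 2:
            self.positions = self.positions[:, :, None]

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[2]


# ---------------------------------------------------------------------------
# mode systems
# ---------------------------------------------------------------------------


def interface_modes(model: str, L: float = 256.0, M: int | None = None,
                    T: float = 1.0, d: int = 1) -> ModeSystem:
    """Fourier modes of a periodic linear interface of size L.

    ``model`` is "EW" (Edwards-Wilkinson, relaxation q^2, tagged-point
    H = 1/4) or "MH" (Mullins-Herring, q^4, H = 3/8).  The tagged
    observable is the height at one point relative to the spatially
    averaged height; cosine modes at the tagged point x0 = 0 carry
    coupling sqrt(2/L), sine modes do not couple.
    """
    z = {"EW": 2, "MH": 4}.get(model.upper())
    if z is None:
        raise ValueError(f"unknown interface model {model!r}; use EW or MH")
    if M is None:
        M = int(L) // 2
    q = 2.0 * np.pi * np.arange(1, M + 1) / L
    lam = q**z
    c = np.full(M, np.sqrt(2.0 / L))
    return ModeSystem(lam, c, T=T, d=d,
                      meta={"model": model.upper(), "L": L, "z": z,
                            "H": 0.25 if z == 2 else 0.375})


def rouse_chain(N: int, tagged: int | None = None) -> NetworkModel:
    """Flexible bead-spring chain (free ends); tagged middle monomer."""
    if N < 2:
        raise ValueError("a chain needs at least two beads")
    Lp = np.zeros((N, N))
    idx = np.arange(N - 1)
    Lp[idx, idx + 1] = Lp[idx + 1, idx] = -1.0
    Lp[np.diag_indices(N)] = -Lp.sum(axis=1)
    return NetworkModel(Lp, tagged=N // 2 if tagged is None else tagged,
                        meta={"model": "rouse", "N": N, "H": 0.25})


def _vicsek_cells(g: int) -> set[tuple[int, int]]:
    """Occupied cells of the two-dimensional (f = 4) Vicsek fractal of
    generation g on a 3^g x 3^g grid (plus-sign recursion)."""
    cells = {(0, 0)}
    size = 1
    for _ in range(g):
        shifts = [(1, 1), (0, 1), (2, 1), (1, 0), (1, 2)]
        cells = {(x + sx * size, y + sy * size)
                 for (x, y) in cells for (sx, sy) in shifts}
        size *= 3
    return cells


def vicsek_network(f: int = 4, g: int = 2) -> NetworkModel:
    """Bead-spring network with Vicsek-fractal connectivity.

    For f = 4 the construction is geometric: the generation-g fractal is
    the plus-sign subset of the 3^g grid, beads on occupied cells and unit
    springs between nearest neighbors (N = 5^g beads).  For other f an
    abstract arm recursion is used: f copies are attached to a central
    copy through designated port beads.  The tagged bead is the central
    one.  The spectral dimension d_s = 2 ln(f+1) / ln(3f+3) sets the
    tagged-monomer Hurst exponent H = (1 - d_s/2) / 2 (H ~= 0.203 at
    f = 4), which the test suite verifies through the mode-sum MSD.
    """
    if f < 3 or g < 1:
        raise ValueError("need functionality f >= 3 and generation g >= 1")
    if f == 4:
        cells = sorted(_vicsek_cells(g))
        index = {c: i for i, c in enumerate(cells)}
        N = len(cells)
        Lp = np.zeros((N, N))
        for (x, y) in cells:
            for (dx, dy) in ((1, 0), (0, 1)):
                nb = (x + dx, y + dy)
                if nb in index:
                    i, j = index[(x, y)], index[nb]
                    Lp[i, j] = Lp[j, i] = -1.0
        Lp[np.diag_indices(N)] = -Lp.sum(axis=1)
        mid = (3**g - 1) // 2
        tagged = index[(mid, mid)]
    else:
        # abstract recursion: ports are the outward arm ends; copy i is
        # attached through its port opposite(i) = i + ceil(f/2) mod f
        edges = [(0, k) for k in range(1, f + 1)]
        ports = list(range(1, f + 1))
        n_beads = f + 1
        tagged = 0
        for _ in range(g - 1):
            all_edges = list(edges)
            new_ports = []
            for i in range(f):
                off = (i + 1) * n_beads
                all_edges += [(a + off, b + off) for (a, b) in edges]
                opp = (i + (f + 1) // 2) % f
                all_edges.append((ports[i], ports[opp] + off))
                new_ports.append(ports[i] + off)
            edges = all_edges
            ports = new_ports
            n_beads *= f + 1
        Lp = np.zeros((n_beads, n_beads))
        for a, b in edges:
            Lp[a, b] = Lp[b, a] = -1.0
        Lp[np.diag_indices(n_beads)] = -Lp.sum(axis=1)
    ds = 2.0 * np.log(f + 1.0) / np.log(3.0 * f + 3.0)
    return NetworkModel(Lp, tagged=tagged,
                        meta={"model": "vicsek", "f": f, "g": g,
                              "spectral_dimension": ds,
                              "H": 0.5 * (1.0 - ds / 2.0)})


def network_modes(net: NetworkModel, T: float = 1.0, d: int = 1,
                  drop_zero_mode: bool = True) -> ModeSystem:
    """Eigendecomposition of the network Laplacian seen by the tagged bead.

    The zero mode (center-of-mass diffusion) is excluded from the tagged
    observable by default; system sizes should be chosen so that the
    slowest internal relaxation time exceeds the observation window.
    """
    lam, phi = np.linalg.eigh(net.laplacian)
    n_zero = int(np.sum(lam < 1e-10 * lam[-1]))
    if n_zero != 1:
        raise ValueError(f"network must be connected (found {n_zero} "
                         "zero modes)")
    if not drop_zero_mode:
        raise NotImplementedError("free center-of-mass diffusion is not "
                                  "part of the tagged observable")
    c = phi[net.tagged, n_zero:]
    return ModeSystem(lam[n_zero:], c, T=T, d=d, meta=dict(net.meta))


# ---------------------------------------------------------------------------
# deterministic mode sums
# ---------------------------------------------------------------------------


def msd_from_modes(ms: ModeSystem, times) -> np.ndarray:
    """Exact MSD of the tagged displacement per component:

    Var[x(t) - x(0)] = sum_k c_k^2 [ T (1 - e^{-lam t})^2
                                     + 1 - e^{-2 lam t} ] / lam.
    """
    t = np.asarray(times, dtype=float)[:, None]
    lam = ms.eigenvalues[None, :]
    c2 = ms.couplings[None, :] ** 2
    e = np.exp(-lam * t)
    return np.sum(c2 * (ms.T * (1 - e) ** 2 + (1 - e**2)) / lam, axis=1)


def cov_from_modes(ms: ModeSystem, t, tp) -> np.ndarray:
    """Exact two-time covariance of the tagged displacement,
    Cov[x(t)-x(0), x(t')-x(0)], broadcasting over t, t'."""
    t = np.asarray(t, dtype=float)[..., None]
    tp = np.asarray(tp, dtype=float)[..., None]
    lam = ms.eigenvalues
    c2 = ms.couplings**2
    et, ep = np.exp(-lam * t), np.exp(-lam * tp)
    edif = np.exp(-lam * np.abs(t - tp))
    return np.sum(c2 * (ms.T * (1 - et) * (1 - ep)
                        + edif - et * ep) / lam, axis=-1)


def hurst_fit(times, msd, window: tuple | None = None):
    """Hurst exponent as half the log-log MSD slope.

    Returns (H, err) where err is a window-sensitivity estimate: the
    spread of the fit over the two halves of the window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(msd, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    if len(t) < 8:
        raise ValueError("too few points in the fit window")
    lt, ly = np.log(t), np.log(y)
    slope = np.polyfit(lt, ly, 1)[0]
    half = len(t) // 2
    s1 = np.polyfit(lt[:half], ly[:half], 1)[0]
    s2 = np.polyfit(lt[half:], ly[half:], 1)[0]
    return 0.5 * slope, 0.25 * abs(s1 - s2) + 1e-3


def scaling_window(ms: ModeSystem, pad: float = 10.0) -> tuple:
    """Time window [pad/lam_max, 1/(pad*lam_min)] between the mode
    crossovers, inside which the MSD shows the anomalous exponent."""
    return (pad / ms.eigenvalues[-1], 1.0 / (pad * ms.eigenvalues[0]))


# ---------------------------------------------------------------------------
# exact sampling
# ---------------------------------------------------------------------------


def sample_tagged(ms: ModeSystem, grid, n: int, seed: int | None = None,
                  chunk: int = 256) -> TrajectoryEnsemble:
    """Sample tagged-coordinate displacement trajectories exactly.

    Every mode follows its Ornstein-Uhlenbeck transition density between
    consecutive grid times, so the sampling is exact on any strictly
    increasing grid.  Modes are processed in chunks to bound memory.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("grid must be strictly increasing and positive")
    rng = np.random.default_rng(seed)
    nt = len(grid)
    lam_all = ms.eigenvalues
    c_all = ms.couplings
    out = np.zeros((n, nt, ms.d))
    dts = np.diff(np.concatenate([[0.0], grid]))
    for k0 in range(0, len(lam_all), chunk):
        lam = lam_all[k0:k0 + chunk][None, :, None]
        c = c_all[k0:k0 + chunk][None, :, None]
        nm = lam.shape[1]
        a = rng.standard_normal((n, nm, ms.d)) * np.sqrt(ms.T / lam)
        a0 = a.copy()
        for j, dt in enumerate(dts):
            decay = np.exp(-lam[0, :, 0] * dt)[None, :, None]
            sd = np.sqrt((1.0 - decay**2) / lam)
            a = a * decay + sd * rng.standard_normal((n, nm, ms.d))
            out[:, j, :] += np.sum(c * (a - a0), axis=1)
    return TrajectoryEnsemble(grid, out, seed=seed,
                              model={**ms.meta, "T": ms.T, "kind": "modes"})


def sample_gaussian(cov, grid=None, n: int = 1000, seed: int | None = None,
                    jitter: float = 1e-10) -> TrajectoryEnsemble:
    """Exact factorization-based sampling of a Gaussian process.

    ``cov`` is a CovarianceSpec (sampled on ``grid``; d independent
    components) or a ConditionalModel (future times fixed; the conditional
    mean is added to every trajectory).
    """
    rng = np.random.default_rng(seed)
    if isinstance(cov, ConditionalModel):
        grid = cov.future_times
        C = cov.cov
        mean = cov.mean
        d = 1
        model = {"kind": "conditioned-fbm", "H": cov.H}
    else:
        if grid is None:
            raise ValueError("a time grid is required for a CovarianceSpec")
        grid = np.asarray(grid, dtype=float)
        C = cov.matrix(grid)
        mean = None
        d = cov.d
        model = cov.to_dict()
        model.pop("scaling_table", None)
        model["kind"] = f"gaussian-{cov.kind}"
    nt = len(grid)
    eps = jitter * np.trace(C) / nt
    for attempt in range(6):
        try:
            Lc = np.linalg.cholesky(C + (eps * (attempt > 0)) * np.eye(nt))
            if attempt > 0:
                model["jitter"] = eps
            break
        except np.linalg.LinAlgError:
            eps *= 100.0
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("covariance factorization failed")
    x = np.einsum("ij,njd->nid", Lc, rng.standard_normal((n, nt, d)))
    if mean is not None:
        x = x + mean[None, :, None]
    return TrajectoryEnsemble(grid, x, seed=seed, model=model)
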