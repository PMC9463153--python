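"""Two-time covariance models of transiently aging Gaussian processes.

A scale-invariant Gaussian process x(t) with Hurst exponent H is described
here by its covariance sigma(t, t') = max(t, t')^{2H} G(min/max), normalized
so that the mean-square displacement is sigma(t, t) = t^{2H} (G(1) = 1).
Three families are provided:

* ``quench``  -- the process starts from an equilibrium state at temperature
  T and evolves at temperature 1 for t > 0.  The covariance is

      sigma(t, t') = [T (t^{2H} + t'^{2H}) + (1 - T) (t + t')^{2H}
                      - |t - t'|^{2H}] / (2 T + 2^{2H} (1 - T)),

  which is exactly scale free.  T = 1 reduces to fractional Brownian
  motion (stationary increments at all times); T != 1 produces transient
  aging: the increments become stationary only as t -> infinity.

* ``stationary`` -- fractional Brownian motion itself,
  sigma(t, t') = (t^{2H} + t'^{2H} - |t - t'|^{2H}) / 2.

* ``conditioned`` -- the deviation of a two-sided fBM from its mean future
  trajectory predicted from an observed past; the covariance is the Schur
  complement of the past block and is tabulated numerically.

All families share the increment-stationary limit

    sigma_s(tau, tau') = s_amp (tau^{2H} + tau'^{2H} - |tau - tau'|^{2H}),

with an amplitude ``s_amp`` fixed by the normalization of sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.interpolate import PchipInterpolator

__all__ = [
    "CovarianceSpec",
    "StationaryCovariance",
    "PastObservation",
    "ConditionalModel",
    "sigma_quench",
    "sigma_stationary",
    "scaling_function",
    "condition_on_past",
    "conditioned_spec",
    "fbm_two_sided_cov",
]


def _check_H(H: float) -> None:
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst exponent must lie in (0, 1), got {H}")


def quench_norm(H: float, T: float) -> float:
    """Divisor making the quench covariance satisfy sigma(t, t) = t^{2H}."""
    return 2.0 * T + 2.0 ** (2.0 * H) * (1.0 - T)


def sigma_quench(t, tp, H: float, T: float):
    """Normalized post-quench covariance (pre-quench temperature T).

    Vectorized over ``t`` and ``tp``.  Satisfies sigma(t, t) = t^{2H},
    sigma(t, 0) = 0 and, at H = 1/2, reduces to min(t, t') for every T.
    """
    _check_H(H)
    if T < 0:
        raise ValueError(f"temperature must be >= 0, got {T}")
    t = np.asarray(t, dtype=float)
    tp = np.asarray(tp, dtype=float)
    if np.any(t < 0) or np.any(tp < 0):
        raise ValueError("times must be non-negative")
    h2 = 2.0 * H
    raw = T * (t**h2 + tp**h2) + (1.0 - T) * (t + tp) ** h2 - np.abs(t - tp) ** h2
    return raw / quench_norm(H, T)


def sigma_stationary(tau, taup, H: float, amp: float = 0.5):
    """Stationary-increment covariance s_amp (tau^{2H}+tau'^{2H}-|tau-tau'|^{2H}).

    ``amp`` is the normalization constant of the owning covariance family
    (1 / (2T + 2^{2H}(1-T)) for the quench family; 1/2 for plain fBM).
    """
    _check_H(H)
    tau = np.asarray(tau, dtype=float)
    taup = np.asarray(taup, dtype=float)
    if np.any(tau < 0) or np.any(taup < 0):
        raise ValueError("lags must be non-negative")
    h2 = 2.0 * H
    return amp * (tau**h2 + taup**h2 - np.abs(tau - taup) ** h2)


@dataclass(frozen=True)
class StationaryCovariance:
    """Increment-stationary limit of a covariance family."""

    H: float
    amp: float

    def __call__(self, tau, taup):
        return sigma_stationary(tau, taup, self.H, self.amp)


@dataclass
class CovarianceSpec:
    """A normalized two-time covariance sigma(t,t') = max^{2H} G(min/max).

    Parameters
    ----------
    H : Hurst exponent, 0 < H < 1.
    kind : "quench", "stationary", "conditioned" or "user".
    T : pre-quench temperature (quench kind only; dynamics temperature is 1).
    d : spatial dimension; components are independent and identical, each
        carrying this one-dimensional covariance.
    scaling_table : (u, G) arrays for tabulated kinds ("conditioned"/"user").
    s_amp : amplitude of the stationary-increment limit, in the same
        normalization as sigma.  Computed automatically for the closed-form
        kinds.
    """

    H: float
    kind: str = "quench"
    T: float = 1.0
    d: int = 1
    scaling_table: tuple | None = None
    s_amp: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        _check_H(self.H)
        if self.d < 1 or int(self.d) != self.d:
            raise ValueError(f"dimension must be a positive integer, got {self.d}")
        if self.kind not in ("quench", "stationary", "conditioned", "user"):
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if self.kind == "quench":
            if self.T < 0:
                raise ValueError("temperature must be >= 0")
            self.s_amp = 1.0 / quench_norm(self.H, self.T)
        elif self.kind == "stationary":
            self.s_amp = 0.5
        else:
            if self.scaling_table is None:
                raise ValueError(f"kind={self.kind!r} requires a scaling_table")
            if self.s_amp is None:
                raise ValueError(f"kind={self.kind!r} requires s_amp")
            u, g = self.scaling_table
            u = np.asarray(u, dtype=float)
            g = np.asarray(g, dtype=float)
            if u.ndim != 1 or u.shape != g.shape or not np.all(np.diff(u) > 0):
                raise ValueError("scaling_table must be (increasing u, G(u))")
            # interpolate in log u; extrapolate below the table by a power law
            # fitted on the smallest tabulated decade
            self._logu = np.log(u)
            self._g_interp = PchipInterpolator(self._logu, g, extrapolate=False)
            lo = u <= u[0] * 10.0
            slope, inter = np.polyfit(np.log(u[lo]), np.log(np.abs(g[lo]) + 1e-300), 1)
            self._ext_slope = slope
            self._ext_amp = np.exp(inter)
            self.scaling_table = (u, g)

    # -- scaling function -------------------------------------------------

    def G(self, u):
        """Scaling function G(u) = sigma(t, u t) / t^{2H}, u in (0, 1]."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1.0 + 1e-12):
            raise ValueError("scaling argument must lie in [0, 1]")
        h2 = 2.0 * self.H
        if self.kind == "quench":
            n = quench_norm(self.H, self.T)
            return (self.T * (1.0 + u**h2) + (1.0 - self.T) * (1.0 + u) ** h2
                    - (1.0 - u) ** h2) / n
        if self.kind == "stationary":
            return 0.5 * (1.0 + u**h2 - (1.0 - u) ** h2)
        out = np.empty_like(u)
        with np.errstate(divide="ignore"):
            logu = np.log(np.maximum(u, 1e-300))
        inside = logu >= self._logu[0]
        out[inside] = self._g_interp(np.minimum(logu[inside], self._logu[-1]))
        out[~inside] = self._ext_amp * np.exp(self._ext_slope * logu[~inside])
        return out

    def G_smooth(self, u):
        """G with the short-scale non-analytic part s_amp (1-u)^{2H} added back."""
        u = np.asarray(u, dtype=float)
        return self.G(u) + self.s_amp * (1.0 - u) ** (2.0 * self.H)

    def G_smooth_m1(self, u):
        """G_smooth(u) - 1, evaluated without cancellation near u = 1.

        The smooth part of G tends to 1 as u -> 1; the solver needs the
        deviation to relative precision at 1 - u down to ~1e-12."""
        u = np.asarray(u, dtype=float)
        h2 = 2.0 * self.H
        with np.errstate(divide="ignore"):
            lu = np.log(np.maximum(u, 1e-300))
        if self.kind == "quench":
            n = quench_norm(self.H, self.T)
            return (self.T * np.expm1(h2 * lu)
                    + (1.0 - self.T) * 2.0**h2
                    * np.expm1(h2 * np.log1p((u - 1.0) / 2.0))) / n
        if self.kind == "stationary":
            return 0.5 * np.expm1(h2 * lu)
        return self.G_smooth(u) - 1.0

    @property
    def g1(self) -> float:
        """Derivative of the smooth part of G at u = 1 (equals H for the
        quench family and for fBM; computed by finite differences for
        tabulated kinds)."""
        if self.kind in ("quench", "stationary"):
            return self.H
        eps = 1e-5
        return float((self.G_smooth(1.0) - self.G_smooth(1.0 - eps)) / eps)

    # -- covariances ------------------------------------------------------

    def sigma(self, t, tp):
        """sigma(t, t') = max^{2H} G(min/max) (exact for the closed-form
        kinds, long-time scaling form for tabulated kinds)."""
        t = np.asarray(t, dtype=float)
        tp = np.asarray(tp, dtype=float)
        hi = np.maximum(t, tp)
        lo = np.minimum(t, tp)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 1.0)
        return np.where(hi > 0, hi ** (2.0 * self.H) * self.G(u), 0.0)

    @property
    def sigma_s(self) -> StationaryCovariance:
        return StationaryCovariance(self.H, self.s_amp)

    def matrix(self, times) -> np.ndarray:
        """Covariance matrix of one component on a time grid."""
        times = np.asarray(times, dtype=float)
        return self.sigma(times[:, None], times[None, :])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        out = {"H": self.H, "kind": self.kind, "T": self.T, "d": self.d,
               "s_amp": self.s_amp, "meta": dict(self.meta)}
        if self.scaling_table is not None:
            u, g = self.scaling_table
            out["scaling_table"] = {"u": list(map(float, u)),
                                    "G": list(map(float, g))}
        return out

    @classmethod
    def from_dict(cls, cfg: dict) -> "CovarianceSpec":
        table = cfg.get("scaling_table")
        if table is not None:
            table = (np.asarray(table["u"]), np.asarray(table["G"]))
        return cls(H=cfg["H"], kind=cfg.get("kind", "quench"),
                   T=cfg.get("T", 1.0), d=cfg.get("d", 1),
                   scaling_table=table, s_amp=cfg.get("s_amp"),
                   meta=cfg.get("meta", {}))


def scaling_function(spec: CovarianceSpec, u, t_ref: float = 1024.0,
                     rtol: float = 1e-6):
    """Empirical scaling function sigma(t_ref, u t_ref) / t_ref^{2H}.

    Convergence to the self-similar form is checked by doubling t_ref; a
    warning carries both values if they disagree beyond ``rtol``.  For the
    exactly scale-free kinds this is independent of t_ref.
    """
    u = np.asarray(u, dtype=float)
    g1 = spec.sigma(t_ref, u * t_ref) / t_ref ** (2 * spec.H)
    g2 = spec.sigma(2 * t_ref, u * 2 * t_ref) / (2 * t_ref) ** (2 * spec.H)
    err = np.max(np.abs(g1 - g2) / (np.max(np.abs(g1)) + 1e-300))
    if err > rtol:
        warnings.warn(
            f"scaling form not converged at t_ref={t_ref}: relative change "
            f"{err:.3g} on doubling (values {g1} vs {g2})")
    return g2


# ---------------------------------------------------------------------------
# Type II: conditioning on an observed past
# ---------------------------------------------------------------------------


def fbm_two_sided_cov(s, t, H: float):
    """Covariance of two-sided fBM pinned at x(0)=0:
    Cov(x(s), x(t)) = (|s|^{2H} + |t|^{2H} - |s - t|^{2H}) / 2,  s, t in R."""
    _check_H(H)
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    h2 = 2.0 * H
    return 0.5 * (np.abs(s) ** h2 + np.abs(t) ** h2 - np.abs(s - t) ** h2)


@dataclass
class PastObservation:
    """A trajectory observed on a grid of past times.

    ``times`` is strictly increasing on [-T_past, 0] and must contain 0;
    the process is pinned at x(0) = 0, so the position at time 0 is dropped
    from the conditioning data (it carries no information).
    """

    times: np.ndarray
    positions: np.ndarray
    H: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        _check_H(self.H)
        if self.times.shape != self.positions.shape or self.times.ndim != 1:
            raise ValueError("times and positions must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times > 0):
            raise ValueError("past times must be <= 0")
        if self.times[-1] != 0.0:
            raise ValueError("the past grid must contain t = 0")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @classmethod
    def from_tsv(cls, path, H: float) -> "PastObservation":
        data = np.loadtxt(path)
        return cls(times=data[:, 0], positions=data[:, 1], H=H)

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.positions]),
                   fmt="%.17g", delimiter="\t", header="time\tposition")

    @classmethod
    def geometric(cls, H: float, T_past: float = 1e3, n: int = 200,
                  t_min: float = 1e-3, seed: int | None = None,
                  positions: np.ndarray | None = None) -> "PastObservation":
        """A geometric past grid on [-T_past, 0]; positions are either given
        or sampled from the two-sided fBM pinned at the origin."""
        t = -np.geomspace(T_past, t_min, n)
        t = np.append(t, 0.0)
        if positions is None:
            cov = fbm_two_sided_cov(t[:-1, None], t[None, :-1], H)
            rng = np.random.default_rng(seed)
            w = np.linalg.cholesky(cov + 1e-12 * np.eye(len(t) - 1)
                                   * np.trace(cov) / len(t))
            x = np.append(w @ rng.standard_normal(len(t) - 1), 0.0)
        else:
            x = np.asarray(positions, dtype=float)
        return cls(times=t, positions=x, H=H)


@dataclass
class ConditionalModel:
    """Gaussian law of the future of a two-sided fBM given its observed past.

    The conditional mean is exactly linear in the past positions,
    mean = weights @ positions, and the conditional covariance (a Schur
    complement) does not depend on the realization of the past.
    """

    future_times: np.ndarray
    weights: np.ndarray        # (n_future, n_past)
    cov: np.ndarray            # (n_future, n_future)
    H: float
    past: PastObservation
    jitter: float = 0.0

    @property
    def mean(self) -> np.ndarray:
        return self.weights @ self.past.positions[self.past.times < 0]


def condition_on_past(past: PastObservation, future_times) -> ConditionalModel:
    """Condition the two-sided fBM on an observed past trajectory.

    Returns predictor weights for the mean future trajectory and the
    Schur-complement covariance of the deviation from it.  Near-singular
    past covariances are regularized by a reported diagonal jitter.
    """
    fut = np.asarray(future_times, dtype=float)
    if np.any(fut <= 0):
        raise ValueError("future times must be > 0")
    H = past.H
    tp = past.times[past.times < 0]
    Sff = fbm_two_sided_cov(fut[:, None], fut[None, :], H)
    if tp.size == 0:
        return ConditionalModel(fut, np.zeros((fut.size, 0)), Sff, H, past)
    Spp = fbm_two_sided_cov(tp[:, None], tp[None, :], H)
    Sfp = fbm_two_sided_cov(fut[:, None], tp[None, :], H)
    jitter = 0.0
    for attempt in range(6):
        try:
            cf = cho_factor(Spp + jitter * np.eye(tp.size), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 100.0, 1e-10 * np.trace(Spp) / tp.size)
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("past covariance could not be factorized")
    W = cho_solve(cf, Sfp.T).T
    cov = Sff - W @ Sfp.T
    cov = 0.5 * (cov + cov.T)
    return ConditionalModel(fut, W, cov, H, past, jitter=jitter)


def conditioned_spec(H: float, d: int = 1, n_per_decade: int = 24,
                     past_decades: tuple[float, float] = (-8.0, 6.0),
                     u_min: float = 1e-8) -> CovarianceSpec:
    """Covariance spec of the deviation-from-prediction process (type II).

    The past observation grid is geometric on [-10^{p1}, -10^{p0}] with
    ``n_per_decade`` points per decade; the conditional covariance is
    evaluated at future times (u, 1) for u on a logarithmic grid, normalized
    so that sigma(t, t) = t^{2H}, and wrapped as a tabulated scaling
    function.  The stationary-increment amplitude is 1 / (2 c_inf) where
    c_inf is the raw conditional variance at t = 1 (far-future increments
    of the conditioned process recover plain fBM increments; this is
    verified numerically in the test suite).
    """
    _check_H(H)
    p0, p1 = past_decades
    n = int(round(n_per_decade * (p1 - p0)))
    tp = -np.geomspace(10.0**p1, 10.0**p0, n)
    past = PastObservation(np.append(tp, 0.0), np.zeros(n + 1), H)
    u = np.geomspace(u_min, 1.0, int(round(8 * -np.log10(u_min))) + 1)
    cm = condition_on_past(past, u)  # future times are exactly the u grid
    c_inf = cm.cov[-1, -1]  # conditional variance at t = 1
    g = cm.cov[-1, :] / c_inf
    # enforce exact endpoint G(1) = 1
    g[-1] = 1.0
    return CovarianceSpec(H=H, kind="conditioned", d=d,
                          scaling_table=(u, g), s_amp=0.5 / c_inf,
                          meta={"c_inf": float(c_inf),
                                "past_decades": list(past_decades),
                                "n_per_decade": n_per_decade})
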