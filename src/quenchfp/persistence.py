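"""Survival curves, persistence exponents, and post-first-passage statistics.

The persistence S(t) is the probability that a trajectory has not reached
a threshold (d = 1) or a target ball (d > 1, compact case dH < 1) up to
time t; at long times S(t) ~ t^{-theta}.  This module estimates S from
trajectory ensembles, fits theta with bootstrap errors, and measures the
statistics of trajectories in the future of the first-passage time:
their covariance excess rho = sigma_pi - sigma_0 grows as t^{2H-theta},
which provides an independent estimate of theta and an empirical scaling
function z(u) comparable with the collocation solver's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .covariance import CovarianceSpec, PastObservation, condition_on_past
from .simulate import TrajectoryEnsemble, sample_gaussian

__all__ = [
    "TargetSpec",
    "SurvivalCurve",
    "SigmaPiEstimate",
    "first_passage",
    "survival",
    "fit_theta",
    "post_fpt_statistics",
    "empirical_z",
    "conditional_persistence",
]


@dataclass
class TargetSpec:
    """First-passage target: a threshold level b in d = 1 (relative to the
    trajectory start), or a ball of radius a around the origin with the
    walker starting at distance x0 in d > 1."""

    d: int = 1
    b: float = 0.3
    a: float = 0.1
    x0: float = 1.0

    def __post_init__(self):
        if self.d > 1 and (self.a <= 0 or self.x0 <= self.a):
            raise ValueError("need target radius a > 0 and start x0 > a")
        if self.d == 1 and self.b == 0:
            raise ValueError("a zero threshold at the start point is "
                             "ill-posed for a process pinned at 0")


@dataclass
class SurvivalCurve:
    times: np.ndarray
    S: np.ndarray
    n_at_risk: np.ndarray
    censor_time: float

    def __post_init__(self):
        if np.any(np.diff(self.S) > 1e-12) or self.S[0] > 1.0 + 1e-12:
            raise ValueError("survival must be non-increasing and <= 1")

    def to_tsv(self, path):
        np.savetxt(path, np.column_stack([self.times, self.S,
                                          self.n_at_risk]),
                   delimiter="\t", header="t\tS\tn_at_risk")


@dataclass
class SigmaPiEstimate:
    """Mean and covariance of y(t) = x(t + FPT) over uncensored paths."""

    times: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    counts: np.ndarray
    H: float


# ---------------------------------------------------------------------------
# first passage
# ---------------------------------------------------------------------------


def first_passage(ens: TrajectoryEnsemble, target: TargetSpec,
                  bridge: bool = True, seed: int | None = None):
    """First-passage times with sub-grid crossing detection.

    Crossings between grid points are detected two ways: linear
    interpolation when the sampled path straddles the level, and (for
    d = 1, ``bridge=True``) a Brownian-bridge correction for excursions
    that cross and return between samples, with the local increment
    variance estimated from the ensemble itself.  Without the correction
    the missed-crossing (undershoot) bias inflates the survival curve of
    rough (small-H) paths at late times.

    Returns (fpt, censored); censored trajectories carry fpt = horizon.
    """
    t = ens.times
    if target.d != ens.d:
        raise ValueError(f"target dimension {target.d} != ensemble {ens.d}")
    if target.d == 1:
        sig = ens.positions[:, :, 0] - target.b
        if target.b < 0:
            sig = -sig
    else:
        start = np.zeros(ens.d)
        start[0] = target.x0
        r = np.linalg.norm(ens.positions + start[None, None, :], axis=2)
        sig = target.a - r            # crossing when r drops below a
    n, nt = sig.shape
    fpt = np.full(n, t[-1])
    done = np.zeros(n, dtype=bool)
    hit0 = sig[:, 0] >= 0
    fpt[hit0] = t[0]
    done |= hit0
    use_bridge = bridge
    if use_bridge:
        # the monitored signal is the signed distance to the level
        # (d = 1) or to the target ball (d > 1, radial crossing == entry);
        # its per-interval variance is estimated from the ensemble itself
        rng = np.random.default_rng(seed)
        dvar = np.var(np.diff(sig, axis=1), axis=0)
        dvar = np.maximum(dvar, 1e-300)
        # the exp(-2ab/var) law is exact for Brownian bridges; for fBM the
        # within-interval excursion is rescaled so that the conditional
        # midpoint variance matches (factor 1 at H = 1/2)
        Hloc = ens.model.get("H", 0.5)
        if Hloc is None or not np.isfinite(Hloc):
            Hloc = 0.5
        dvar = dvar * (2.0 ** (2.0 - 2.0 * Hloc) - 1.0)
    for j in range(1, nt):
        s0, s1 = sig[:, j - 1], sig[:, j]
        act = ~done
        hit = act & (s1 >= 0)
        if np.any(hit):
            frac = np.where(s1 != s0, -s0 / np.where(s1 != s0, s1 - s0, 1.0),
                            1.0)
            fpt[hit] = t[j - 1] + frac[hit] * (t[j] - t[j - 1])
            done |= hit
        if use_bridge:
            act = ~done
            if not np.any(act):
                break
            # P(bridge from s0 to s1 (< 0) touches 0) = exp(-2 s0 s1 / var)
            p = np.exp(-2.0 * s0 * s1 / dvar[j - 1])
            fire = act & (rng.random(n) < p)
            if np.any(fire):
                fpt[fire] = 0.5 * (t[j - 1] + t[j])
                done |= fire
    if not done.any():
        raise RuntimeError("all trajectories censored; increase t_max "
                           "(compactness requires dH < 1)")
    return fpt, ~done


def survival(fpt, censored, times=None) -> SurvivalCurve:
    """Empirical survival S(t) = P(FPT > t) with right censoring at the
    common horizon (with a single censor time this equals the
    Kaplan-Meier estimate)."""
    fpt = np.asarray(fpt, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    horizon = fpt.max()
    if times is None:
        times = np.geomspace(max(fpt.min(), 1e-12), horizon, 200)
    times = np.asarray(times, dtype=float)
    events = np.sort(fpt[~censored])
    n = len(fpt)
    n_events = np.searchsorted(events, times, side="right")
    S = 1.0 - n_events / n
    return SurvivalCurve(times=times, S=S,
                         n_at_risk=(n - n_events).astype(int),
                         censor_time=horizon)


def _auto_window(curve: SurvivalCurve, slope_tol: float = 0.05,
                 t_min: float | None = None):
    """Longest span of stable local log-slope, excluding the last
    half-decade before the censoring horizon and, when ``t_min`` is given,
    the early pre-asymptotic regime."""
    t, S = curve.times, curve.S
    keep = (S > 0) & (t < curve.censor_time / np.sqrt(10.0))
    if t_min is not None:
        keep &= t >= t_min
    t, S = t[keep], S[keep]
    if len(t) < 16:
        return t[0], t[-1]
    lt, lS = np.log(t), np.log(S)
    k = max(4, len(t) // 16)
    slope = np.gradient(lS, lt)
    sm = np.convolve(slope, np.ones(k) / k, mode="same")
    ref = np.median(sm[len(sm) // 2:])
    ok = np.abs(sm - ref) < slope_tol * max(abs(ref), 0.2)
    best_lo = best_hi = 0
    lo = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and lo is None:
            lo = i
        elif not flag and lo is not None:
            if i - lo > best_hi - best_lo:
                best_lo, best_hi = lo, i
            lo = None
    if best_hi - best_lo < 8:
        best_lo, best_hi = len(t) // 3, len(t) - 1
    return t[best_lo], t[best_hi - 1]


def fit_theta(curve: SurvivalCurve, window=None, n_boot: int = 200,
              seed: int | None = None, fpt=None, censored=None):
    """Power-law fit S ~ t^{-theta} on a log-log window.

    The error is a trajectory bootstrap when the raw (fpt, censored)
    sample is given, otherwise a window-sensitivity estimate.  Returns
    (theta, err, window).
    """
    if window is None:
        # predictable default: start well past the bulk of the FPT mass,
        # stop half a decade before the censoring horizon
        t_hi = curve.censor_time / np.sqrt(10.0)
        if fpt is not None:
            ev = np.asarray(fpt)[~np.asarray(censored)]
            t_lo = min(20.0 * np.median(ev), t_hi / 10.0)
        else:
            t_lo = t_hi / 100.0
        window = (t_lo, t_hi)
    elif window == "auto":
        t_min = None
        if fpt is not None:
            ev = np.asarray(fpt)[~np.asarray(censored)]
            t_min = 10.0 * np.median(ev)
        window = _auto_window(curve, t_min=t_min)
    t, S = curve.times, curve.S
    keep = (t >= window[0]) & (t <= window[1]) & (S > 0)
    if keep.sum() < 8:
        raise ValueError(f"fit window {window} contains too few points")
    lt, lS = np.log(t[keep]), np.log(S[keep])
    theta = -np.polyfit(lt, lS, 1)[0]
    if curve.n_at_risk[keep][-1] < 50:
        import warnings
        warnings.warn("fewer than 50 surviving trajectories at the window "
                      "end; the fitted exponent error may be underestimated")
    if fpt is not None:
        rng = np.random.default_rng(seed)
        fpt = np.asarray(fpt)
        censored = np.asarray(censored)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(fpt), len(fpt))
            cb = survival(fpt[idx], censored[idx], times=t[keep])
            good = cb.S > 0
            if good.sum() < 4:
                continue
            boots.append(-np.polyfit(np.log(cb.times[good]),
                                     np.log(cb.S[good]), 1)[0])
        err = float(np.std(boots)) if boots else np.nan
    else:
        half = keep.sum() // 2
        s1 = -np.polyfit(lt[:half], lS[:half], 1)[0]
        s2 = -np.polyfit(lt[half:], lS[half:], 1)[0]
        err = 0.5 * abs(s1 - s2)
    return float(theta), float(err), window


# ---------------------------------------------------------------------------
# statistics after the first passage
# ---------------------------------------------------------------------------


def post_fpt_statistics(ens: TrajectoryEnsemble, fpt, censored,
                        times=None) -> SigmaPiEstimate:
    """Mean and covariance of y(t) = x(t + FPT) - x(FPT) (d = 1).

    Trajectories are aligned at their (interpolated) first-passage time;
    y is read off by linear interpolation of the stored path.  Only
    uncensored trajectories whose window [FPT, FPT + t_max_post] fits in
    the simulated horizon contribute.
    """
    if ens.d != 1:
        raise NotImplementedError("post-FPT statistics implemented in d=1")
    t = ens.times
    fpt = np.asarray(fpt)
    censored = np.asarray(censored)
    if times is None:
        times = np.geomspace(t[0], t[-1] / 8.0, 48)
    times = np.asarray(times, dtype=float)
    ys = []
    for i in np.nonzero(~censored)[0]:
        if fpt[i] + times[-1] > t[-1]:
            continue
        x = ens.positions[i, :, 0]
        y = np.interp(fpt[i] + times, t, x) - np.interp(fpt[i], t, x)
        ys.append(y)
    if len(ys) < 100:
        raise RuntimeError(f"only {len(ys)} usable post-FPT paths; "
                           "increase the horizon or the ensemble size")
    Y = np.array(ys)
    mu = Y.mean(axis=0)
    cov = np.cov(Y.T)
    H = ens.model.get("H", np.nan)
    return SigmaPiEstimate(times=times, mean=mu, cov=cov,
                           counts=np.full(len(times), len(ys)), H=H)


def empirical_z(est: SigmaPiEstimate, spec: CovarianceSpec, theta: float):
    """Empirical scaling function from the post-FPT covariance excess.

    rho_hat(t, t') = sigma_pi_hat - sigma_0 is rescaled by the ansatz
    rho = min^{2H-theta} z(min/max); the diagonal additionally gives an
    independent theta estimate from d ln rho_hat(t,t) / d ln t = 2H - theta.
    Returns (u, z_hat, theta_pi).
    """
    t = est.times
    sig0 = spec.matrix(t)
    rho = est.cov - sig0
    h2 = 2.0 * spec.H
    diag = np.diag(rho)
    good = diag > 0
    if good.sum() >= 8:
        slope = np.polyfit(np.log(t[good]), np.log(diag[good]), 1)[0]
        theta_pi = h2 - slope
    else:
        theta_pi = np.nan
    lo = t[None, :].repeat(len(t), 0)
    lo = np.minimum(lo, lo.T)
    hi = np.maximum(t[None, :], t[:, None])
    u = (lo / hi).ravel()
    z = (rho / lo ** (h2 - theta)).ravel()
    order = np.argsort(u)
    return u[order], z[order], float(theta_pi)


def conditional_persistence(past: PastObservation, grid, n: int,
                            offset: float = 0.3, seed: int | None = None,
                            n_boot: int = 100):
    """Persistence of the deviation from the predicted mean trajectory.

    Futures consistent with the observed past are sampled from the
    conditional law; the first crossing of the conditional mean plus
    ``offset`` is recorded and theta is fitted from the survival curve.
    Returns (theta_hat, err, curve).
    """
    cm = condition_on_past(past, grid)
    ens = sample_gaussian(cm, n=n, seed=seed)
    dev = TrajectoryEnsemble(ens.times,
                             ens.positions[:, :, 0] - cm.mean[None, :],
                             seed=ens.seed, model={"H": past.H})
    fpt, cen = first_passage(dev, TargetSpec(d=1, b=offset), seed=seed)
    curve = survival(fpt, cen)
    theta, err, _ = fit_theta(curve, fpt=fpt, censored=cen,
                              n_boot=n_boot, seed=seed)
    return theta, err, curve
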