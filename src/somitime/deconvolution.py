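"""Maximum-entropy deconvolution of bulk profiles to phase profiles.

A bulk sample mixes cells across a window of cycle phases; the mixing is
encoded by a row-stochastic kernel K (samples x phase bins). Given observed
per-sample values g and per-sample noise sd sigma, the single-phase profile
f >= 0 is reconstructed as the maximizer of the Shannon entropy
S(f) = -sum_b p_b ln p_b (p = f / sum f) subject to the discrepancy
constraint chi2(f) = sum_j (g_j - (K f)_j)^2 / sigma_j^2 <= n_samples
(Morozov principle). The constrained problem is solved by minimising
chi2 - mu * S for a chain of entropy weights mu, with mu bisected until the
chi-squared constraint binds to within 1%.

Peak calling, Monte Carlo timing errors, and the high-confidence timeline
selection operate on the reconstructed profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import circstd

from .staging import TWO_PI

logger = logging.getLogger(__name__)

F_FLOOR = 1e-12


@dataclass
class PhaseProfile:
    """Deconvolved non-negative expression versus phase bin."""

    probe_id: str
    f: np.ndarray
    chi2: float
    entropy: float
    converged: bool
    mu: float = 0.0  # entropy weight at the returned solution
    n_iter: int = 0


@dataclass
class PeakCall:
    probe_id: str
    peak_bins: list[int]
    peak_phases: list[float]
    peak_times: list[float]
    heights: list[float]
    regularity: float
    timing_error_minutes: list[float] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_bins)


def _entropy(f: np.ndarray) -> float:
    total = f.sum()
    p = f / total
    return float(-np.sum(p * np.log(p)))


def _objective_log(u, g, K, inv_var, mu):
    # optimise in u = ln f: unconstrained and far better conditioned for the
    # entropy term than working in f directly
    f = np.exp(u)
    resid = g - K @ f
    chi2 = float(np.sum(resid**2 * inv_var))
    total = f.sum()
    p = f / total
    logp = u - np.log(total)
    S = float(-np.sum(p * logp))
    val = chi2 - mu * S
    grad_chi2_f = -2.0 * (K.T @ (resid * inv_var))
    grad_S_f = -(logp + S) / total
    grad_u = f * (grad_chi2_f - mu * grad_S_f)
    return val, grad_u


def _solve_mu(g, K, inv_var, mu, f0, max_iter):
    u0 = np.log(np.clip(f0, F_FLOOR, None))
    hi = np.log(max(np.abs(g).max(), 1.0)) + 30.0
    res = optimize.minimize(
        _objective_log,
        u0,
        args=(g, K, inv_var, mu),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(F_FLOOR), hi)] * u0.size,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8, "maxcor": 40},
    )
    f = np.exp(np.clip(res.x, np.log(F_FLOOR), hi))
    resid = g - K @ f
    chi2 = float(np.sum(resid**2 * inv_var))
    return f, chi2, res.nit


def maxent_deconvolve(
    g,
    K,
    sigma,
    target_chi2: float | None = None,
    chi2_rtol: float = 0.01,
    max_iter: int = 2_000,
    max_bisect: int = 40,
    probe_id: str = "",
) -> PhaseProfile:
    """Reconstruct the phase profile of one probe.

    Parameters
    ----------
    g : array (n_samples,)
        Observed per-sample values on the linear scale.
    K : KernelMatrix or array (n_samples, n_bins)
        Row-stochastic phase-mixing kernel.
    sigma : float or array
        Per-sample noise sd (> 0).
    target_chi2 : float, optional
        Discrepancy target; defaults to n_samples.

    Returns the entropy-maximal feasible profile; when even a flat profile
    satisfies the constraint the flat profile is returned directly.
    """
    weights = getattr(K, "weights", K)
    weights = np.asarray(weights, dtype=float)
    if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("kernel rows must sum to 1")
    g = np.asarray(g, dtype=float)
    if g.size != weights.shape[0]:
        raise ValueError("len(g) must equal the number of kernel rows")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), g.shape).copy()
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    n, B = weights.shape
    target = float(target_chi2) if target_chi2 is not None else float(n)
    inv_var = 1.0 / sigma**2

    # Flat candidate: rows sum to 1, so a constant profile predicts a
    # constant; the best constant is the precision-weighted mean of g.
    c = float(np.sum(g * inv_var) / np.sum(inv_var))
    chi2_flat = float(np.sum((g - c) ** 2 * inv_var))
    scale = max(c, 1.0)
    if chi2_flat <= target:
        f = np.full(B, max(c, F_FLOOR))
        return PhaseProfile(probe_id, f, chi2_flat, _entropy(f), True, mu=np.inf)

    f0 = np.full(B, max(c, F_FLOOR))
    # Bracket mu: chi2(f_mu) grows with mu, from the least-squares floor
    # (mu -> 0) to chi2_flat (mu -> inf). mu trades chi2 (scale chi2_flat)
    # against entropy (scale ln B), so chi2_flat is a natural starting point.
    mu_lo, mu_hi = None, None
    mu = max(chi2_flat, 1e-12)
    f_lo = f_hi = None
    nit_total = 0
    for _ in range(60):
        f, chi2, nit = _solve_mu(g, weights, inv_var, mu, f0, max_iter)
        nit_total += nit
        f0 = f
        if chi2 < target:
            mu_lo, f_lo, chi2_lo = mu, f, chi2
            mu *= 30.0
        else:
            mu_hi, f_hi, chi2_hi = mu, f, chi2
            mu /= 30.0
        if mu_lo is not None and mu_hi is not None:
            break
    if mu_lo is None:
        # even the near-least-squares solution cannot reach the target
        logger.warning(
            "maxent_deconvolve(%s): infeasible constraint (chi2 %.3g > %.3g)",
            probe_id,
            chi2,
            target,
        )
        return PhaseProfile(
            probe_id, f_hi, chi2_hi, _entropy(f_hi), False, mu=mu_hi, n_iter=nit_total
        )
    if mu_hi is None:
        return PhaseProfile(
            probe_id, f_lo, chi2_lo, _entropy(f_lo), True, mu=mu_lo, n_iter=nit_total
        )

    best = (f_hi, chi2_hi, mu_hi)
    for _ in range(max_bisect):
        # chi2(mu) is close to a power law, so secant in log-log space
        # converges much faster than plain geometric bisection
        llo, lhi = np.log(mu_lo), np.log(mu_hi)
        clo, chi = np.log(max(chi2_lo, 1e-300)), np.log(chi2_hi)
        if chi > clo + 1e-12:
            frac = (np.log(target) - clo) / (chi - clo)
            frac = min(max(frac, 0.1), 0.9)
        else:
            frac = 0.5
        mu_mid = float(np.exp(llo + frac * (lhi - llo)))
        f, chi2, nit = _solve_mu(g, weights, inv_var, mu_mid, f0, max_iter)
        nit_total += nit
        f0 = f
        if chi2 >= target:
            best = (f, chi2, mu_mid)
        if abs(chi2 - target) <= chi2_rtol * target:
            best = (f, chi2, mu_mid)
            break
        if chi2 < target:
            mu_lo, chi2_lo = mu_mid, chi2
        else:
            mu_hi, chi2_hi = mu_mid, chi2
    f, chi2, mu = best
    converged = abs(chi2 - target) <= chi2_rtol * target or chi2 <= target
    if not converged:
        logger.warning(
            "maxent_deconvolve(%s): chi2 %.4g vs target %.4g after bisection",
            probe_id,
            chi2,
            target,
        )
    return PhaseProfile(probe_id, f, chi2, _entropy(f), converged, mu, nit_total)


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def _circular_smooth3(f: np.ndarray) -> np.ndarray:
    return (np.roll(f, 1) + f + np.roll(f, -1)) / 3.0


def _plateau_peaks(fs: np.ndarray):
    """Circular local maxima of fs, plateaus collapsed to their centre bin."""
    B = fs.size
    peaks = []
    i = 0
    visited = 0
    # walk runs of equal value circularly
    while visited < B:
        j = i
        while np.isclose(fs[(j + 1) % B], fs[i], rtol=0, atol=1e-15):
            j += 1
            if j - i >= B:  # fully flat
                return []
        left = fs[(i - 1) % B]
        right = fs[(j + 1) % B]
        if fs[i] > left and fs[i] > right:
            peaks.append(((i + (j - i) // 2) % B, fs[i]))
        visited += j - i + 1
        i = (j + 1) % B
    return peaks


def profile_regularity(f: np.ndarray) -> float:
    """Fraction of (non-DC) profile variance captured by harmonics 1-2."""
    F = np.fft.rfft(np.asarray(f, dtype=float))
    power = np.abs(F[1:]) ** 2
    if f.size % 2 == 0:
        power = power.copy()
        power[-1] /= 2.0  # Nyquist counted once
    total = power.sum()
    if total == 0:
        return 0.0
    return float(power[:2].sum() / total)


def _harmonic_refine(f: np.ndarray, b0: int, n_harm: int = 2, window: float = 2.5):
    """Continuous peak position near bin b0: local maximum of the 1..n_harm
    Fourier reconstruction of f, searched within ``window`` bins of b0.

    Exact for symmetric profiles (delta, von Mises, two equidistant bumps);
    suppresses bin-level jitter of the raw argmax."""
    B = f.size
    F = np.fft.rfft(f)
    fine = np.arange(B * 16) / (B * 16.0)
    rec = np.full(fine.size, F[0].real / B)
    for k in range(1, min(n_harm, F.size - 1) + 1):
        rec += (2.0 / B) * (
            F[k].real * np.cos(TWO_PI * k * fine) - F[k].imag * np.sin(TWO_PI * k * fine)
        )
    dist = np.abs(fine * B - b0)
    dist = np.minimum(dist, B - dist)
    cand = np.nonzero(dist <= window)[0]
    j = cand[np.argmax(rec[cand])]
    return float(fine[j])


def call_peaks(
    pf: PhaseProfile,
    period_minutes: float,
    expect_bimodal: bool = False,
    prominence_frac: float = 0.2,
) -> PeakCall:
    """Call 1 (or, if bimodal expected, up to 2) peaks on a profile.

    Candidate peaks are circular local maxima of the 3-bin circularly
    smoothed profile; a second peak is kept only when its height clears
    ``prominence_frac`` of the smoothed profile's range above the minimum.
    Each peak's position is then refined to the local maximum of the
    two-harmonic reconstruction of the profile. Bin b maps to phase b/B,
    so times are phase * period."""
    f = np.asarray(pf.f, dtype=float)
    B = f.size
    if np.ptp(f) <= 1e-12 * max(1.0, float(np.max(np.abs(f)))):
        return PeakCall(pf.probe_id, [], [], [], [], profile_regularity(f))
    fs = _circular_smooth3(f)
    cands = _plateau_peaks(fs)
    if not cands:
        cands = [(int(np.argmax(fs)), float(np.max(fs)))]
    cands.sort(key=lambda bh: -bh[1])
    kept = [cands[0]]
    if expect_bimodal and len(cands) > 1:
        lo, hi = float(fs.min()), float(fs.max())
        b, h = cands[1]
        if h - lo >= prominence_frac * (hi - lo):
            kept.append((b, h))
    kept.sort(key=lambda bh: bh[0])
    bins = [int(b) for b, _ in kept]
    phases = [_harmonic_refine(f, b) for b in bins]
    times = [p * period_minutes for p in phases]
    heights = [float(f[b]) for b in bins]
    return PeakCall(pf.probe_id, bins, phases, times, heights, profile_regularity(f))


def estimate_sigma(g, phases, robust: bool = False) -> float:
    """Per-probe noise sd: residual sd of the two-harmonic fit to g.

    With ``robust`` the MAD-based scale (1.4826 * MAD) is used instead."""
    y = np.asarray(g, dtype=float)
    t = np.asarray(phases, dtype=float)
    X = np.column_stack(
        [
            np.ones_like(t),
            np.cos(TWO_PI * t),
            np.sin(TWO_PI * t),
            np.cos(2 * TWO_PI * t),
            np.sin(2 * TWO_PI * t),
        ]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    if robust:
        return float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    dof = max(y.size - X.shape[1], 1)
    return float(np.sqrt(np.sum(resid**2) / dof))


def timing_error_mc(
    g,
    K,
    sigma,
    R: int = 50,
    seed: int = 0,
    period_minutes: float = 90.0,
    expect_bimodal: bool = False,
    fast_replicates: bool = True,
    **deconv_opts,
) -> list[float]:
    """Monte Carlo timing error per peak, in minutes.

    Gaussian noise of sd ``sigma`` is added to g, the profile re-deconvolved
    and peaks re-called R times; each original peak is matched to the nearest
    replicate peak by circular distance and the circular sd of its times is
    reported. With ``fast_replicates`` each replicate is re-solved at the
    base solution's entropy weight (warm-started) instead of re-bisecting
    the discrepancy constraint, which changes chi2 by at most the noise
    perturbation itself."""
    if R < 50:
        raise ValueError("use at least 50 Monte Carlo replicates")
    g = np.asarray(g, dtype=float)
    base = maxent_deconvolve(g, K, sigma, **deconv_opts)
    call0 = call_peaks(base, period_minutes, expect_bimodal)
    if call0.n_peaks == 0:
        return []
    rng = np.random.default_rng(seed)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), g.shape)
    weights = getattr(K, "weights", K)
    weights = np.asarray(weights, dtype=float)
    inv_var = 1.0 / np.broadcast_to(np.asarray(sigma, dtype=float), g.shape) ** 2
    times: list[list[float]] = [[] for _ in call0.peak_times]
    for _ in range(R):
        grep = g + rng.normal(0.0, sig)
        if fast_replicates and np.isfinite(base.mu):
            f, chi2, _ = _solve_mu(grep, weights, inv_var, base.mu, base.f, 2000)
            pf = PhaseProfile(base.probe_id, f, chi2, _entropy(f), True, base.mu)
        else:
            pf = maxent_deconvolve(grep, K, sigma, **deconv_opts)
        call = call_peaks(pf, period_minutes, expect_bimodal)
        if call.n_peaks == 0:
            continue
        for k, t0 in enumerate(call0.peak_times):
            deltas = [
                min(abs(t - t0), period_minutes - abs(t - t0)) for t in call.peak_times
            ]
            times[k].append(call.peak_times[int(np.argmin(deltas))])
    errors = []
    for k, tlist in enumerate(times):
        if len(tlist) < 2:
            errors.append(float("inf"))
            continue
        errors.append(float(circstd(np.asarray(tlist), high=period_minutes, low=0.0)))
    return errors


def select_candidates(calls, detection: pd.DataFrame, cfg) -> pd.DataFrame:
    """High-confidence timeline: peak calls with every per-peak timing error
    below the species ceiling and a regular profile, sorted by LS p-value.

    ``calls`` is a sequence of PeakCall; ``detection`` the detect_cyclic
    table providing p-values. Output columns: probe_id, n_peaks,
    peak_times_minutes, timing_errors_minutes, regularity, p_value."""
    pmap = detection.set_index("probe_id")["p_value"].to_dict()
    rows = []
    for call in calls:
        if call.n_peaks == 0 or not call.timing_error_minutes:
            continue
        if max(call.timing_error_minutes) >= cfg.thresholds.max_timing_error_minutes:
            continue
        if call.regularity < cfg.thresholds.regularity_min:
            continue
        rows.append(
            {
                "probe_id": call.probe_id,
                "n_peaks": call.n_peaks,
                "peak_times_minutes": list(call.peak_times),
                "timing_errors_minutes": list(call.timing_error_minutes),
                "regularity": call.regularity,
                "p_value": pmap.get(call.probe_id, float("nan")),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "n_peaks",
            "peak_times_minutes",
            "timing_errors_minutes",
            "regularity",
            "p_value",
        ],
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
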