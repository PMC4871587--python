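"""Lomb-Scargle rhythm detection at base and double frequency.

Probes are scored with the classical normalized Lomb-Scargle periodogram at
one cycle per cycle (one peak) and at two cycles per cycle (two peaks per
somite cycle). Significance comes from a seeded permutation test, and the
family of probes is gated jointly by a p-value ceiling and a
Benjamini-Hochberg false-discovery-rate ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

TWO_PI = 2.0 * np.pi


@dataclass
class PeriodogramResult:
    probe_id: str
    frequency_multiple: int
    power: float
    amplitude: float
    p_value: float
    q_value: float


def _ls_vectors(phases: np.ndarray, frequency_multiple: int):
    """Unit-time-per-cycle LS basis with the standard per-frequency offset
    tau, which orthogonalises the cosine and sine columns."""
    omega = TWO_PI * frequency_multiple
    t = np.asarray(phases, dtype=float)
    tau = np.arctan2(np.sum(np.sin(2 * omega * t)), np.sum(np.cos(2 * omega * t))) / (
        2 * omega
    )
    c = np.cos(omega * (t - tau))
    s = np.sin(omega * (t - tau))
    return c, s


def lomb_scargle_power(series, phases, frequency_multiple: int = 1):
    """Classical normalized LS power and best-fit sinusoid amplitude.

    The power is the harmonic regression sum of squares divided by
    2 * Var(y) (variance with n-1 denominator); a constant series scores 0.
    Requires at least 5 samples."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(phases, dtype=float)
    if y.size < 5:
        raise ValueError("Lomb-Scargle requires at least 5 samples")
    yc = y - y.mean()
    ss = float(np.sum(yc**2))
    if ss == 0.0:
        return 0.0, 0.0
    c, s = _ls_vectors(t, frequency_multiple)
    scc = float(np.sum(c**2))
    sss = float(np.sum(s**2))
    yc_c = float(np.sum(yc * c))
    yc_s = float(np.sum(yc * s))
    bc = yc_c / scc if scc > 0 else 0.0
    bs = yc_s / sss if sss > 0 else 0.0
    ess = (yc_c**2 / scc if scc > 0 else 0.0) + (yc_s**2 / sss if sss > 0 else 0.0)
    sigma2 = ss / (y.size - 1)
    power = float(ess / (2.0 * sigma2))
    amplitude = float(np.hypot(bc, bs))
    return power, amplitude


def ls_pvalue(
    series,
    phases,
    frequency_multiple: int = 1,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> float:
    """Significance of the LS power.

    ``permutation`` (default): shuffle the series over the samples;
    p = (1 + #{permuted power >= observed}) / (n_permutations + 1).
    ``analytic``: the single-frequency exponential tail exp(-P), quick but
    approximate for small n."""
    power, _ = lomb_scargle_power(series, phases, frequency_multiple)
    if method == "analytic":
        return float(np.exp(-power))
    if n_permutations < 999:
        raise ValueError("use at least 999 permutations")
    y = np.asarray(series, dtype=float)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_permutations)])
    pp = _powers_matrix(perms, np.asarray(phases, dtype=float), frequency_multiple)
    return float((1 + np.sum(pp >= power - 1e-12)) / (n_permutations + 1))


def _powers_matrix(Y: np.ndarray, phases: np.ndarray, frequency_multiple: int):
    """LS powers for every row of Y at once (shared design)."""
    c, s = _ls_vectors(phases, frequency_multiple)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ss = np.sum(Yc**2, axis=1)
    scc = float(np.sum(c**2))
    sss = float(np.sum(s**2))
    ess = np.zeros(Y.shape[0])
    if scc > 0:
        ess += (Yc @ c) ** 2 / scc
    if sss > 0:
        ess += (Yc @ s) ** 2 / sss
    n = Y.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        power = np.where(ss > 0, ess * (n - 1) / (2.0 * ss), 0.0)
    return power


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values (monotone-adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    return q


def detect_cyclic(
    m,
    staging,
    cfg,
    frequency_multiple: int = 1,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Score every probe at the requested frequency multiple and keep those
    passing the species' p-value and FDR gates, ranked by p.

    Returns a DataFrame (probe_id, power, amplitude, p_value, q_value,
    passed) containing all probes; the ``passed`` column marks detections.
    Gates: p < p_max and q < fdr_max (unimodal or bimodal ceiling according
    to ``frequency_multiple``)."""
    Y = m.values.to_numpy(dtype=float)
    phases = np.asarray(staging.phases, dtype=float)
    powers = _powers_matrix(Y, phases, frequency_multiple)
    amps = np.zeros_like(powers)
    for i in range(Y.shape[0]):
        _, amps[i] = lomb_scargle_power(Y[i], phases, frequency_multiple)
    if method == "analytic":
        pvals = np.exp(-powers)
    else:
        rng = np.random.default_rng(seed)
        # one shared pool of permutations for the whole family
        idx = np.array(
            [rng.permutation(phases.size) for _ in range(n_permutations)]
        )
        pvals = np.empty(Y.shape[0])
        for i in range(Y.shape[0]):
            pp = _powers_matrix(Y[i][idx], phases, frequency_multiple)
            pvals[i] = (1 + np.sum(pp >= powers[i] - 1e-12)) / (n_permutations + 1)
    qvals = benjamini_hochberg(pvals)
    fdr_max = (
        cfg.thresholds.fdr_max_unimodal
        if frequency_multiple == 1
        else cfg.thresholds.fdr_max_bimodal
    )
    passed = (pvals < cfg.thresholds.p_max) & (qvals < fdr_max)
    out = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "frequency_multiple": frequency_multiple,
            "power": powers,
            "amplitude": amps,
            "p_value": pvals,
            "q_value": qvals,
            "passed": passed,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
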