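"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, direct least squares,
O(L^2) scanning) and shares no code with the package internals."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def ls_power_direct(y, t, k):
    """LS power via direct least squares: project the mean-subtracted series
    on [cos(2 pi k t), sin(2 pi k t)] and normalise the explained sum of
    squares by 2 * Var(y)."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    yc = y - y.mean()
    X = np.column_stack([np.cos(2 * np.pi * k * t), np.sin(2 * np.pi * k * t)])
    beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
    ess = float(np.sum((X @ beta) ** 2))
    ss = float(np.sum(yc**2))
    if ss == 0:
        return 0.0
    return ess * (len(y) - 1) / (2.0 * ss)


def fisher_two_sided_enum(k_in, n_in, k_bg, n_bg):
    """Two-sided Fisher p by exhaustive enumeration over all tables with the
    observed margins: sum of hypergeometric point probabilities <= observed."""
    row1 = n_in
    col1 = k_in + k_bg
    total = n_in + n_bg

    def point(a):
        return comb(row1, a) * comb(total - row1, col1 - a) / comb(total, col1)

    p_obs = point(k_in)
    amin = max(0, col1 - (total - row1))
    amax = min(row1, col1)
    return sum(point(a) for a in range(amin, amax + 1) if point(a) <= p_obs * (1 + 1e-9))


def g4_scan_naive(seq, min_run=3, n_runs=4, loop_min=1, loop_max=7):
    """Naive per-position greedy G4 matcher: at each start, walk maximal
    runs and minimal loops character by character. Returns the same greedy
    left-to-right non-overlapping match set as the package scanner."""
    out = []
    for base in "GC":
        i = 0
        L = len(seq)
        matches = []
        while i < L:
            end = _match_at(seq, i, base, min_run, n_runs, loop_min, loop_max)
            if end is not None:
                matches.append((i, end, base))
                i = end
            else:
                i += 1
        out.extend(matches)
    return sorted(out)


def _match_at(seq, i, base, min_run, n_runs, loop_min, loop_max):
    L = len(seq)
    pos = i
    # first run: maximal, from exactly position i
    run_len = 0
    while pos < L and seq[pos] == base:
        pos += 1
        run_len += 1
    if run_len < min_run:
        return None
    for _ in range(n_runs - 1):
        # earliest next run start within the loop bounds
        found = None
        for gap in range(loop_min, loop_max + 1):
            start = pos + gap
            if start >= L:
                break
            loop = seq[pos:start]
            if "N" in loop or "n" in loop:
                break
            run_len = 0
            q = start
            while q < L and seq[q] == base:
                q += 1
                run_len += 1
            if run_len >= min_run and seq[start - 1] != base:
                found = q
                break
        if found is None:
            return None
        pos = found
    return pos


def pwm_null_tail_enum(int_matrix, background, threshold):
    """P(site lattice score >= threshold) by enumerating all 4^W words."""
    W = int_matrix.shape[0]
    p = 0.0
    for word in itertools.product(range(4), repeat=W):
        score = sum(int_matrix[i, b] for i, b in enumerate(word))
        if score >= threshold:
            p += float(np.prod([background[b] for b in word]))
    return p


def classify_rule_table(w, n, f):
    """Direct restatement of the one/two/three-pathway rules."""
    fr = {"Wnt": w, "Notch": n, "Fgf": f}
    ge = {k for k, v in fr.items() if v >= 0.6}
    lt = {k for k, v in fr.items() if v < 0.2}
    if len(ge) == 3:
        return "three-pathway"
    if len(ge) == 2 and len(lt) == 1:
        return "two-pathway"
    if len(ge) == 1 and len(lt) == 2:
        return "one-pathway"
    return "unclassified"


def bh_by_hand(pvals):
    """Step-up BH adjusted p-values computed from the definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def kernel_mc_histogram(d, alpha, t, n_bins, region=(0.0, 0.5), n_draws=1_000_000, seed=0):
    """Monte Carlo version of one kernel row: sample x uniformly over the
    harvested interval, map to phase, histogram."""
    rng = np.random.default_rng(seed)
    lo, hi = region
    x = rng.uniform(lo, hi, n_draws)
    phi = np.mod((x / (1.0 - d)) ** alpha - t, 1.0)
    counts, _ = np.histogram(phi, bins=np.arange(n_bins + 1) / n_bins)
    return counts / n_draws
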