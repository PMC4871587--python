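"""Stage bulk samples on the somite cycle.

Each embryo (microarray sample) sits at an unknown phase of the somite
cycle. Phases are recovered by making a panel of known cyclic reference
genes as periodic as possible: for candidate phases t_j we fit each
reference series with a low-order harmonic wave (one harmonic for the
global search, two for the final polish and ranking) and maximise the
summed fraction of variance explained. The objective is
invariant under a global rotation of all phases and under reversal of
direction; these two gauge freedoms are fixed afterwards by anchoring the
cycle start on the anchor gene's peak and by the configured ordering of two
reference genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class SampleStaging:
    """Assignment of each sample to a cycle phase in [0, 1)."""

    sample_ids: list[str]
    phases: np.ndarray  # shape (n,), in [0, 1)
    objective_value: float = 0.0
    provenance: str = "given"
    seed: int | None = None
    restarts: int = 0
    anchored: bool = False

    def __post_init__(self) -> None:
        self.phases = np.mod(np.asarray(self.phases, dtype=float), 1.0)
        if len(self.sample_ids) != self.phases.size:
            raise ValueError("sample_ids and phases length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sample_ids, self.phases.tolist()))

    def rotated(self, delta: float) -> "SampleStaging":
        out = SampleStaging(
            self.sample_ids,
            np.mod(self.phases + delta, 1.0),
            self.objective_value,
            self.provenance,
            self.seed,
            self.restarts,
            self.anchored,
        )
        return out

    def reflected(self) -> "SampleStaging":
        return SampleStaging(
            self.sample_ids,
            np.mod(-self.phases, 1.0),
            self.objective_value,
            self.provenance,
            self.seed,
            self.restarts,
            self.anchored,
        )


def harmonic_fit(series: np.ndarray, phases: np.ndarray):
    """Least-squares fit of a + b*cos(2 pi t) + c*sin(2 pi t).

    Returns (a, b, c). Requires >= 4 samples."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(phases, dtype=float)
    if y.size < 4:
        raise ValueError("harmonic fit requires at least 4 samples")
    X = np.column_stack([np.ones_like(t), np.cos(TWO_PI * t), np.sin(TWO_PI * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def harmonic_amplitude(series, phases) -> tuple[float, float]:
    """Amplitude sqrt(b^2 + c^2) and fraction of variance explained of the
    best-fit single harmonic. A constant series has amplitude 0."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(phases, dtype=float)
    a, b, c = harmonic_fit(y, t)
    amplitude = float(np.hypot(b, c))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0, 0.0
    fitted = a + b * np.cos(TWO_PI * t) + c * np.sin(TWO_PI * t)
    ssr = float(np.sum((y - fitted) ** 2))
    fvar = max(0.0, min(1.0, 1.0 - ssr / sst))
    return amplitude, fvar


def harmonic_peak_phase(series, phases) -> float:
    """Phase (cycle fraction) at which the fitted harmonic peaks."""
    _, b, c = harmonic_fit(series, phases)
    return float(np.mod(np.arctan2(c, b) / TWO_PI, 1.0))


def _design(phases: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(phases)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(TWO_PI * k * phases))
        cols.append(np.sin(TWO_PI * k * phases))
    return np.stack(cols, axis=1)


def _objective_components(
    Y: np.ndarray, phases: np.ndarray, n_harmonics: int = 2
) -> np.ndarray:
    """Fraction of variance explained per reference gene (rows of Y)."""
    X = _design(phases, n_harmonics)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    ssr = np.sum(resid**2, axis=0)
    sst = np.sum((Y.T - Y.T.mean(axis=0)) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fvar = np.where(sst > 0, 1.0 - ssr / sst, 0.0)
    return np.clip(fvar, 0.0, 1.0)


def staging_objective(
    Y: np.ndarray, phases: np.ndarray, n_harmonics: int = 2
) -> float:
    """Summed fraction of variance explained over reference genes.

    The harmonic fit uses one or two harmonics; two is the staging default
    (bulk profiles of peaky reference genes carry substantial
    second-harmonic content, which sharpens phase identifiability)."""
    return float(np.sum(_objective_components(Y, phases, n_harmonics)))


def _sweep(Y, phases, grid, yty, sst, n_harmonics):
    """One coordinate-ascent sweep: re-optimise each sample's phase on the
    grid with all others held fixed. Vectorised over grid candidates via
    rank-1 updates of the normal equations."""
    n = phases.size
    U = _design(grid, n_harmonics)  # (C, K)
    K = U.shape[1]
    ridge = 1e-10 * np.eye(K)
    improved = False
    cur = staging_objective(Y, phases, n_harmonics)
    for j in range(n):
        u_all = _design(phases, n_harmonics)  # (n, K)
        base_M = u_all.T @ u_all - np.outer(u_all[j], u_all[j])
        base_R = u_all.T @ Y.T - np.outer(u_all[j], Y[:, j])  # (K, G)
        M = base_M[None, :, :] + U[:, :, None] * U[:, None, :] + ridge
        R = base_R[None, :, :] + U[:, :, None] * Y[None, :, j]  # (C, K, G)
        beta = np.linalg.solve(M, R)
        ssr = yty[None, :] - np.einsum("ckg,ckg->cg", beta, R)
        with np.errstate(invalid="ignore", divide="ignore"):
            fvar = np.where(sst > 0, 1.0 - ssr / sst[None, :], 0.0)
        obj = np.clip(fvar, 0.0, 1.0).sum(axis=1)  # (C,)
        best = int(np.argmax(obj))
        if obj[best] > cur + 1e-12:
            phases[j] = grid[best]
            cur = obj[best]
            improved = True
    return improved


def _ascend(Y, phases, grid, yty, sst, n_harmonics, max_sweeps, tol):
    prev = staging_objective(Y, phases, n_harmonics)
    for _ in range(max_sweeps):
        if not _sweep(Y, phases, grid, yty, sst, n_harmonics):
            break
        cur = staging_objective(Y, phases, n_harmonics)
        if cur - prev <= tol:
            break
        prev = cur
    return phases


def optimize_phases(
    m,
    annotation,
    reference_genes,
    restarts: int = 20,
    seed: int = 0,
    grid_size: int = 256,
    max_sweeps: int = 60,
    tol: float = 1e-9,
    initial: SampleStaging | None = None,
) -> SampleStaging:
    """Recover sample phases by coordinate ascent on the staging objective.

    Parameters
    ----------
    m : ExpressionMatrix
        Filtered expression matrix.
    annotation : ProbeAnnotation
        Maps probes to gene symbols; every reference gene must map to at
        least one retained probe.
    reference_genes : sequence of str
        Known cyclic genes used as the staging panel.
    restarts : int
        Number of random restarts (uniform random initial phases, seeded).
    initial : SampleStaging, optional
        Extra starting point included alongside the random restarts; the
        returned staging never scores below it.

    The result is defined up to global rotation and reflection; use
    :func:`anchor_cycle_start` / :func:`orient` to fix the gauge.
    """
    probes: list[str] = []
    for gene in reference_genes:
        found = [p for p in annotation.probes_for_gene(gene) if p in m.values.index]
        probes.extend(found)
    if not probes:
        raise ValueError("no reference-gene probes present in the matrix")
    Y = m.values.loc[probes].to_numpy(dtype=float)
    if np.allclose(Y.std(axis=1), 0.0):
        raise ValueError("all reference probes are constant; cannot stage")
    n = Y.shape[1]
    if n < 5:
        raise ValueError("staging requires at least 5 samples")
    yty = np.sum(Y**2, axis=1)
    sst = np.sum((Y - Y.mean(axis=1)[:, None]) ** 2, axis=1)
    grid = np.arange(grid_size) / grid_size

    rng = np.random.default_rng(seed)
    starts = [rng.uniform(0.0, 1.0, size=n) for _ in range(restarts)]
    if initial is not None:
        starts.append(np.asarray(initial.phases, dtype=float).copy())
    best_phases = None
    best_obj = -np.inf

    def consider(phases):
        nonlocal best_phases, best_obj
        obj = staging_objective(Y, phases)
        if obj > best_obj:
            best_obj = obj
            best_phases = phases.copy()

    for start in starts:
        # stage 1: single-harmonic ascent finds the global arrangement;
        # stage 2: two-harmonic polish sharpens individual phases. Each
        # restart is ranked by the (default, two-harmonic) objective.
        phases = np.mod(start, 1.0)
        _ascend(Y, phases, grid, yty, sst, 1, max_sweeps, tol)
        _ascend(Y, phases, grid, yty, sst, 2, max_sweeps, tol)
        consider(phases)
    if initial is not None:
        # polish the supplied staging in place as well, so the result never
        # scores below it (ascent is monotone in the ranking objective)
        phases = np.mod(np.asarray(initial.phases, dtype=float).copy(), 1.0)
        _ascend(Y, phases, grid, yty, sst, 2, max_sweeps, tol)
        consider(phases)
    logger.info("optimize_phases: objective %.6f over %d restarts", best_obj, restarts)
    return SampleStaging(
        m.sample_ids,
        best_phases,
        objective_value=best_obj,
        provenance="optimized",
        seed=seed,
        restarts=restarts,
    )


def anchor_cycle_start(
    st: SampleStaging,
    profile_peak_phase: float,
    anchor_value: float,
    confident: bool = True,
) -> SampleStaging:
    """Rotate all phases so the anchor gene's peak sits at ``anchor_value``.

    If the anchor peak is not confident the staging is returned unrotated
    with a warning."""
    if not confident:
        logger.warning("anchor_cycle_start: no confident anchor peak; not rotated")
        return st
    delta = (anchor_value - profile_peak_phase) % 1.0
    out = st.rotated(delta)
    out.anchored = True
    return out


def orient(
    st: SampleStaging,
    m,
    annotation,
    first_gene: str,
    second_gene: str,
) -> SampleStaging:
    """Resolve the reflection gauge: reflect the staging if ``first_gene``'s
    harmonic peak does not precede ``second_gene``'s within the cycle."""
    def peak(gene, staging):
        probes = [p for p in annotation.probes_for_gene(gene) if p in m.values.index]
        if not probes:
            raise ValueError(f"orientation gene {gene!r} not in matrix")
        y = m.values.loc[probes].to_numpy(dtype=float).mean(axis=0)
        return harmonic_peak_phase(y, staging.phases)

    if peak(first_gene, st) <= peak(second_gene, st):
        return st
    return st.reflected()


def align_to_truth(est: np.ndarray, truth: np.ndarray):
    """Best global rotation/reflection aligning estimated phases to truth.

    Returns (aligned_phases, circular_rms, reflect, rotation); the rms is in
    cycle fraction. Used by recovery tests; the rotation is found by
    maximising the mean resultant of the phase differences. Any phase
    quantity in the estimated gauge (for example a gene's peak phase) maps
    to the true gauge as ``(phase + rotation) mod 1`` or, with reflection,
    ``(-phase + rotation) mod 1``."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    best = None
    for reflect in (False, True):
        cand = np.mod(-est, 1.0) if reflect else est
        diff = TWO_PI * (truth - cand)
        rot = np.angle(np.mean(np.exp(1j * diff))) / TWO_PI
        aligned = np.mod(cand + rot, 1.0)
        delta = np.mod(aligned - truth + 0.5, 1.0) - 0.5
        rms = float(np.sqrt(np.mean(delta**2)))
        if best is None or rms < best[1]:
            best = (aligned, rms, reflect, float(rot))
    return best
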