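# Methods

## Model

A somite forms once per clock cycle of period *P* (120 / 90 / 30 minutes
for mouse, chicken, zebrafish). Each cell of the presomitic mesoderm (PSM)
oscillates with a phase that depends on its position: the expression band
of a reference gene sits at normalized position

x(φ, t) = (1 − d) (φ + t)^(1/α),   0 ≤ d < 1,  α > 0,

with x = 0 the posterior tip, x = 1 the anterior PSM end, t the embryo's
cycle phase and φ the cell's phase offset. α captures the deceleration of
the wave (large α: the wave crosses the posterior PSM in a small fraction
of the cycle), d the geometry of the system. The inverse,
φ = ((x/(1−d))^α − t) mod 1, is exact on x ∈ [0, 1−d].

A bulk sample harvests the posterior half of the PSM, x ∈ [0, 0.5]. Its
measured value for a gene with single-cell phase profile f is
g_t = ∫ f(φ(x, t)) dx. Discretising φ into B = 64 half-open bins
[b/B, (b+1)/B) and integrating x with a 2048-point midpoint rule yields a
row-stochastic kernel K (samples × bins) with g ≈ K f. Bin b represents
the grid phase b/B; peak times are phase × P.

The width of the kernel row is (0.5/(1−d))^α cycles: ≈ 0.10 for chicken,
0.28 for mouse, 0.37 for zebrafish. Chicken bulk samples are therefore
nearly single-phase (sharp but coverage-limited), zebrafish samples average
over a third of a cycle (smooth but attenuated) — this trade-off drives
most of the recovery behaviour quoted below.

## Staging

Sample phases are unknown. They are recovered by maximising, over the
phases t_j, the summed fraction of variance of a panel of known cyclic
reference genes explained by a low-order harmonic wave. The optimizer is
coordinate ascent on one sample's phase at a time over a 256-point grid,
multi-started (20 random restarts by default, seeded). Each restart first
ascends the single-harmonic objective, which has a smooth landscape and
finds the global arrangement, and is then polished under a two-harmonic
objective; restarts are ranked by the two-harmonic objective. The polish
matters because bulk reference profiles are not sinusoids — through the
narrow chicken kernel they retain strong second-harmonic content, and the
single-harmonic objective alone exhibits spurious optima that score above
the true staging while scrambling phases. On synthetic chick-like data
(18 samples, reference amplitude 0.5, noise sd 0.1 log2 units) the
two-stage scheme recovers phases with median circular RMS ≈ 0.03 cycle
(single-stage: ≈ 0.06).

The objective is invariant under global rotation and reflection of all
phases. The gauge is fixed by rotating the anchor gene's fitted peak to its
configured phase (`anchor_cycle_start`; chicken anchors LFNG at 78/90 of
the cycle, the time its first band appears) and by requiring a configured
ordering of two reference genes (`orient`).

## Rhythm detection

Probes are scored with the classical normalized Lomb–Scargle power at k = 1
and k = 2 cycles per cycle; the k = 2 periodogram flags genes with two
peaks per cycle. The per-frequency offset τ makes the power equal to the
explained sum of squares of a direct two-column least-squares sinusoid fit
divided by 2·Var(y) — the equivalence is tested to 1e-8 against an
independent implementation. Significance is by permutation (999 shuffles,
seeded, p = (1 + #{perm ≥ obs})/(1000)); an analytic exp(−P) mode exists
behind a flag for speed. The family is gated by p < 0.05 and
Benjamini–Hochberg q below a per-species ceiling (chicken 0.10 both
frequencies; zebrafish 0.15 unimodal, 0.10 bimodal), with BH computed by
statsmodels.

## Maximum-entropy deconvolution

Given g, K and per-sample noise sd σ, the phase profile solves

max S(f) = −Σ p_b ln p_b  (p = f/Σf)   s.t.  χ²(f) = Σ (g−Kf)²/σ² ≤ n.

The discrepancy target n (Morozov principle) is hit by minimising
χ² − μS for a chain of entropy weights μ: the inner problem is solved by
L-BFGS-B in u = ln f (unconstrained and far better conditioned than f
itself; bounds keep f ≥ 1e-12), warm-started along the chain, and μ is
bracketed and then refined by log-log secant until χ² is within 1% of the
target. If even a flat profile satisfies the constraint the flat profile is
returned (entropy maximum); if the constraint is infeasible the near-least-
squares solution is returned flagged unconverged. σ per gene is the
residual sd of a two-harmonic fit to g (MAD variant behind a flag); note
this over-estimates σ for very peaky profiles, which errs on the side of
smoother reconstructions.

Peak calling smooths the profile with a circular 3-bin mean, takes circular
local maxima (plateaus collapse to their centre), keeps the top peak (and
the second if bimodality is expected and it clears 20% prominence of the
smoothed range), and refines each position to the local maximum of the
profile's two-harmonic Fourier reconstruction — exact for symmetric
profiles and much less jittery than a raw argmax. Timing errors are
circular standard deviations of peak times over ≥ 50 noise-injected
replicates, re-solved at the base solution's entropy weight (warm-started);
peaks are matched across replicates by nearest circular distance. The
high-confidence timeline keeps calls with every per-peak error below the
species ceiling (10 min chicken, 5 min zebrafish) and regularity ≥ 0.6
(fraction of profile variance in harmonics 1–2).

## Cross-species comparison

Peak times are converted to cycle fractions and compared within HomoloGene
groups; two species are in phase when the circular difference is ≤ 0.1
cycle (an explicit, reported tolerance — "in phase" is otherwise
qualitative). Genes whose timing error exceeds the gate are carried as
"unresolved", never as evidence against conservation.

## Promoter analysis

Motifs are position probability matrices; consensus strings convert with
pseudocount 0.01. Two motifs are similar when the best ungapped alignment
(either orientation) has Pearson r > 0.6 over the flattened aligned columns
and covers ≥ 60% of the shorter motif; these two self-contained gates
replace any external tool's composite E-value. Scanning uses log2-odds
against a 0-order background estimated from the promoter set; site
significance is exact, from the null score distribution computed by dynamic
programming on a 1/1000-bit integer lattice (verified against full 4^W
enumeration for W ≤ 8), with a per-site ceiling of 1e-4 by default.
Pathway classification follows the presence rules: one-pathway = present in
≥ 60% of one pathway's known cyclic genes and < 20% of each other pathway;
two-pathway = ≥ 60% in two and < 20% of the third; three-pathway = ≥ 60%
in all three; anything else unclassified.

G-quadruplex prediction is quadparser-style: four maximal runs of ≥ 3 G
(or C, marking the opposite strand) separated by loops of 1–7 nt, matched
greedily left-to-right without overlap; N never participates. Promoter
presence tables report genes / genes-with-G4 / nearest-integer percentage
per group, and enrichment of a gene set against the genome background uses
the two-sided Fisher exact test (scipy), cross-checked against exhaustive
hypergeometric enumeration.

## Synthetic data

The generator emulates the study design: sample phases uniform on the
cycle; single-cell profiles with one or two von Mises bumps (κ = 8 —
roughly the width of one expression band); bulk values log2(K f) plus
Gaussian noise; present flags Bernoulli(0.95). The single-cell exponent is
calibrated per gene so the bulk log2 half-amplitude equals the requested
`amplitude`, making SNR = amplitude/noise_sd exact on the measurement
scale. Reference-panel probes carry their own amplitude (default 0.5) —
staging panels are strong, well-characterised oscillators — independent of
the test genes' amplitude. Defaults: noise sd 0.1 log2 units (typical
microarray replicate noise), amplitude 0.5, 18–21 samples matching the
chick/zebrafish designs.

What the generator does not emulate: probe-level cross-hybridisation,
intensity-dependent noise variance, correlated noise between co-hybridised
probes, and biological amplitude variation across genes. Passing recovery
tests therefore demonstrate correctness of the inference chain under the
stated noise model, not performance on real arrays.

## Resolution limits

Peak-time recovery through the full chain is information-limited. With 18–21
samples at uniform random phases and SNR 3, even a maximum-likelihood
estimator given the true generative model locates a one-peak gene's phase
only to ~1–2 bins of 64 (the chicken kernel additionally leaves ~16% of
phase bins covered by no sample); the pipeline's maxent-plus-peak-call
chain tracks that bound when staging is known, and estimated staging adds
its own ~2-bin RMS error. Consequently timing is reported with explicit
Monte Carlo errors rather than as exact bins, and the high-confidence
timeline gates on those errors. Problem sizes used by the test suite and
the acceptance script (10–300 genes, 18–21 samples, 5–50 replicate seeds,
B = 64) are chosen to exercise these regimes at a few minutes of runtime.

## Numerical choices

Filters: present-fraction boundary inclusive (≥ half); peak-to-trough on
the linear scale, 2^(max−min) of log2 values. Kernel: 2048-point midpoint
quadrature (8192 where cross-checked against 10^6-draw Monte Carlo within
total variation 0.01). Staging convergence: no single-sample grid move
improving the objective by > 1e-9. Deconvolution: χ² within 1% of target,
inner iteration cap 2000, profile floor 1e-12. Wave-parameter fitting:
least-squares quantile matching of sorted band positions against
(1−d)q^(1/α) at plotting positions (i−½)/n, Nelder–Mead multi-start with a
log-regression initialisation; bootstrap spread flags wide confidence
regions for small n. Degenerate inputs (constant series, empty matrices,
flat profiles, zero-margin contingency tables) return the documented
neutral values rather than raising, except where the contract demands an
error (duplicate probe ids, ragged tables, non-stochastic kernels).
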