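"""PWM handling: similarity gates, promoter scanning, pathway classification.

Motifs are position probability matrices over {A, C, G, T}. Two motifs are
deemed similar when, over the best ungapped alignment (either orientation),
the Pearson correlation of aligned column probabilities exceeds 0.6 and the
alignment covers at least 60% of the shorter motif. Promoters are scanned
with a log-odds score against a 0-order background estimated from the
promoter set itself; site significance uses the exact null score
distribution computed by dynamic programming on an integer score lattice.
Motifs found in the promoters of the known cyclic genes of the Wnt, Notch
and Fgf pathways are classified as one-, two- or three-pathway motifs by
presence fractions (>= 60% of a pathway's genes, < 20% of the others).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G
SCORE_SCALE = 1000  # integer lattice resolution for exact score p-values


@dataclass
class Pwm:
    """Position probability matrix (width x 4, columns ordered A, C, G, T)."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each column must sum to 1")
        self.probs = p

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name + "_rc", self.probs[::-1, _COMPLEMENT_IDX])

    @classmethod
    def from_consensus(cls, name: str, consensus: str, pseudocount: float = 0.01):
        """Near-deterministic PWM from a consensus string."""
        consensus = consensus.upper()
        probs = np.full((len(consensus), 4), pseudocount)
        for i, base in enumerate(consensus):
            if base not in _BASE_INDEX:
                raise ValueError(f"consensus base {base!r} not in {BASES}")
            probs[i, _BASE_INDEX[base]] = 1.0 - 3 * pseudocount
        return cls(name, probs)


def read_meme(path) -> list[Pwm]:
    """Parse motifs from MEME minimal text format."""
    motifs = []
    name = None
    rows: list[list[float]] = []
    expect = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            elif line.startswith("letter-probability matrix"):
                rows = []
                expect = 0
                # width is announced as "w= N"
                tokens = line.split()
                for i, tok in enumerate(tokens):
                    if tok == "w=" and i + 1 < len(tokens):
                        expect = int(tokens[i + 1])
            elif name is not None and line and line[0].isdigit() or (
                name is not None and line.startswith("0.")
            ):
                vals = [float(v) for v in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
                if expect and len(rows) == expect:
                    motifs.append(Pwm(name, np.array(rows)))
                    name, rows, expect = None, [], 0
    if name is not None and rows:
        motifs.append(Pwm(name, np.array(rows)))
    return motifs


def write_meme(motifs, path, background=None) -> None:
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.3f}" for b, p in zip(BASES, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityResult:
    best_r: float
    overlap_fraction: float
    offset: int
    orientation: str  # "+" or "-"
    meets_overlap: bool


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pwm_similarity(
    a: Pwm, b: Pwm, overlap_min: float = 0.6, include_revcomp: bool = True
) -> SimilarityResult:
    """Best ungapped alignment of b (either orientation) against a.

    The Pearson correlation is computed on the flattened aligned column
    probabilities; overlap_fraction is aligned columns / min(width_a,
    width_b). Among alignments meeting the overlap floor the one with the
    highest r wins; if none does, the best over all offsets is returned
    flagged with ``meets_overlap=False``."""
    wa, wb = a.width, b.width
    wmin = min(wa, wb)
    orientations = [("+", b.probs)]
    if include_revcomp:
        orientations.append(("-", b.reverse_complement().probs))
    best_ok = None
    best_any = None
    for strand, bp in orientations:
        for offset in range(-(wb - 1), wa):
            lo_a = max(0, offset)
            hi_a = min(wa, offset + wb)
            n_aligned = hi_a - lo_a
            if n_aligned < 2:
                continue
            seg_a = a.probs[lo_a:hi_a]
            seg_b = bp[lo_a - offset : hi_a - offset]
            r = _pearson(seg_a, seg_b)
            overlap = n_aligned / wmin
            entry = (r, overlap, offset, strand)
            if best_any is None or r > best_any[0]:
                best_any = entry
            if overlap >= overlap_min and (best_ok is None or r > best_ok[0]):
                best_ok = entry
    chosen = best_ok if best_ok is not None else best_any
    return SimilarityResult(
        best_r=chosen[0],
        overlap_fraction=chosen[1],
        offset=chosen[2],
        orientation=chosen[3],
        meets_overlap=best_ok is not None,
    )


def match_to_reference(
    motif: Pwm,
    reference: list[Pwm],
    r_min: float = 0.6,
    overlap_min: float = 0.6,
) -> tuple[Pwm | None, SimilarityResult | None]:
    """Best reference motif passing both similarity gates (r > r_min and
    overlap >= overlap_min), or (None, None). Ties break toward higher r,
    then earlier reference order."""
    if not reference:
        raise ValueError("reference list must be nonempty")
    best = None
    for ref in reference:
        sim = pwm_similarity(motif, ref, overlap_min=overlap_min)
        if sim.meets_overlap and sim.best_r > r_min:
            if best is None or sim.best_r > best[1].best_r:
                best = (ref, sim)
    if best is None:
        return None, None
    return best


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def estimate_background(promoters: dict) -> np.ndarray:
    """0-order background frequencies over the promoter set (N ignored)."""
    counts = np.zeros(4)
    for seq in promoters.values():
        arr = _encode(seq)
        valid = arr >= 0
        counts += np.bincount(arr[valid], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    freqs = counts / counts.sum()
    return np.clip(freqs, 1e-6, None) / np.clip(freqs, 1e-6, None).sum()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        lut[ord(base)] = i
        lut[ord(base.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def integer_log_odds(pwm: Pwm, background: np.ndarray) -> np.ndarray:
    """Log2-odds matrix rounded to the integer score lattice."""
    p = np.clip(pwm.probs, 1e-4, None)
    lom = np.log2(p / background[None, :])
    return np.rint(lom * SCORE_SCALE).astype(np.int64)


def score_distribution(int_matrix: np.ndarray, background: np.ndarray):
    """Exact null distribution of the total lattice score of one site drawn
    from the 0-order background, by positionwise convolution.

    Returns (offset, probs) so that probs[k] = P(score == offset + k);
    the probabilities sum to 1."""
    dist = np.array([1.0])
    offset = 0
    for row in int_matrix:
        rmin = int(row.min())
        rmax = int(row.max())
        new = np.zeros(dist.size + (rmax - rmin))
        for b in range(4):
            shift = int(row[b]) - rmin
            new[shift : shift + dist.size] += background[b] * dist
        dist = new
        offset += rmin
    return offset, dist


def score_threshold(int_matrix: np.ndarray, background: np.ndarray, p_max: float):
    """Smallest lattice score whose exact null tail probability is <= p_max."""
    offset, dist = score_distribution(int_matrix, background)
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.nonzero(tail <= p_max)[0]
    if ok.size == 0:
        return None  # no achievable score is that significant
    return offset + int(ok[0])


def site_pvalue(score: int, offset: int, dist: np.ndarray) -> float:
    """Exact null P(lattice score >= score)."""
    k = score - offset
    if k <= 0:
        return 1.0
    if k >= dist.size:
        return 0.0
    return float(dist[k:].sum())


def scan_promoters(
    pwm: Pwm,
    promoters: dict,
    score_p_max: float = 1e-4,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every promoter on both strands for significant motif sites.

    A position is a hit when its lattice log-odds score has exact null
    p-value <= ``score_p_max``. Positions are 0-based starts on the forward
    strand; minus-strand hits are matches of the reverse complement.
    Sequences with more than 50% N are skipped with a warning. Returns a
    DataFrame (gene, position, strand, score) where score is the log2-odds
    in bits."""
    if background is None:
        background = estimate_background(promoters)
    fwd = integer_log_odds(pwm, background)
    rev = integer_log_odds(pwm.reverse_complement(), background)
    thr = score_threshold(fwd, background, score_p_max)
    rows = []
    W = pwm.width
    for gene, seq in promoters.items():
        if len(seq) < W:
            raise ValueError(f"promoter {gene!r} shorter than motif width {W}")
        arr = _encode(seq)
        if np.mean(arr < 0) > 0.5:
            logger.warning("scan_promoters: skipping %s (>50%% N)", gene)
            continue
        if thr is None:
            continue
        L = arr.size
        for strand, mat in (("+", fwd), ("-", rev)):
            scores = np.zeros(L - W + 1, dtype=np.int64)
            valid = np.ones(L - W + 1, dtype=bool)
            for k in range(W):
                col = arr[k : k + L - W + 1]
                bad = col < 0
                valid &= ~bad
                scores += np.where(bad, 0, mat[k, np.clip(col, 0, 3)])
            hit = valid & (scores >= thr)
            for pos in np.nonzero(hit)[0]:
                rows.append(
                    {
                        "gene": gene,
                        "position": int(pos),
                        "strand": strand,
                        "score": scores[pos] / SCORE_SCALE,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "position", "strand", "score"])


def genes_with_motif(hits: pd.DataFrame) -> set:
    return set(hits["gene"]) if len(hits) else set()


# ---------------------------------------------------------------------------
# Pathway classification
# ---------------------------------------------------------------------------

PATHWAYS = ("Wnt", "Notch", "Fgf")


@dataclass
class PathwayClassification:
    motif: str
    presence: dict
    label: str  # one-pathway | two-pathway | three-pathway | unclassified
    pathways: tuple = ()


def classify_pathway_motif(presence: dict, motif_name: str = "") -> PathwayClassification:
    """Apply the one/two/three-pathway presence rules.

    one-pathway: present in >= 60% of one pathway's known cyclic genes and
    < 20% of each of the others; two-pathway: >= 60% in each of two and
    < 20% of the third; three-pathway: >= 60% in all three. Anything else is
    unclassified."""
    fracs = {p: float(presence[p]) for p in PATHWAYS}
    for v in fracs.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("presence fractions must lie in [0, 1]")
    high = [p for p in PATHWAYS if fracs[p] >= 0.6]
    low = [p for p in PATHWAYS if fracs[p] < 0.2]
    if len(high) == 3:
        label, members = "three-pathway", tuple(PATHWAYS)
    elif len(high) == 2 and len(low) == 1:
        label, members = "two-pathway", tuple(high)
    elif len(high) == 1 and len(low) == 2:
        label, members = "one-pathway", tuple(high)
    else:
        label, members = "unclassified", ()
    return PathwayClassification(motif_name, fracs, label, members)


def presence_fractions(
    pwm: Pwm,
    pathway_promoters: dict,
    score_p_max: float = 1e-4,
    background: np.ndarray | None = None,
) -> dict:
    """Fraction of each pathway's genes whose promoter contains the motif."""
    if background is None:
        pooled = {
            f"{p}:{g}": s
            for p, proms in pathway_promoters.items()
            for g, s in proms.items()
        }
        background = estimate_background(pooled)
    out = {}
    for pathway, proms in pathway_promoters.items():
        if not proms:
            out[pathway] = 0.0
            continue
        hits = scan_promoters(pwm, proms, score_p_max, background)
        out[pathway] = len(genes_with_motif(hits)) / len(proms)
    return out


def candidate_enrichment(
    candidates,
    reference: list[Pwm],
    promoters: dict,
    score_p_max: float = 1e-4,
) -> dict:
    """Per-reference-motif gene counts among candidate cyclic genes.

    Returns a dict with per-motif counts and hit-gene lists, the set of
    candidates containing at least one reference motif, and the candidates
    lacking a promoter sequence (excluded from denominators)."""
    missing = [g for g in candidates if g not in promoters]
    avail = {g: promoters[g] for g in candidates if g in promoters}
    background = estimate_background(avail) if avail else np.full(4, 0.25)
    per_motif = {}
    union: set = set()
    for pwm in reference:
        if not avail:
            per_motif[pwm.name] = {"count": 0, "genes": []}
            continue
        hits = scan_promoters(pwm, avail, score_p_max, background)
        genes = sorted(genes_with_motif(hits))
        per_motif[pwm.name] = {"count": len(genes), "genes": genes}
        union.update(genes)
    return {
        "per_motif": per_motif,
        "genes_with_any_motif": sorted(union),
        "n_with_any_motif": len(union),
        "n_candidates_scanned": len(avail),
        "missing_promoters": missing,
    }
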