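"""Synthetic data with the statistical structure the pipeline assumes.

The expression generator emulates staged bulk microarray samples: each gene
has a single-cell phase profile with one or two von Mises bumps per cycle,
bulk samples mix single-cell phases through the posterior-half-PSM wave
kernel, and observations are log2 intensities with additive Gaussian noise.
Sample phases are uniform on the cycle, a configurable fraction of genes is
non-oscillating, and present/absent flags are Bernoulli. Promoter and
homolog-table generators plant motif instances / G4 runs and write the
flat-file dialects the readers consume. All generators are pure functions
of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, ProbeAnnotation
from .staging import SampleStaging
from .wave import KernelMatrix, WaveModel, build_kernel

TWO_PI = 2.0 * np.pi


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic expression dataset.

    Per gene: oscillation status, number of peaks, peak phases, log2
    half-amplitude, baseline and noise sd; per sample: the true cycle
    phase. SNR is amplitude / noise_sd on the log2 scale."""

    genes: pd.DataFrame  # is_cyclic, n_peaks, peak_phases, amplitude, baseline, noise_sd
    sample_phases: np.ndarray
    seed: int
    kernel: KernelMatrix | None = None

    def snr(self) -> pd.Series:
        amp = self.genes["amplitude"]
        sd = self.genes["noise_sd"].replace(0.0, np.nan)
        return amp / sd


def _von_mises_profile(phases: np.ndarray, peak_phases, kappa: float) -> np.ndarray:
    """Sum of von Mises bumps (unnormalised density) over grid phases."""
    prof = np.zeros_like(phases)
    for mu in peak_phases:
        prof += np.exp(kappa * (np.cos(TWO_PI * (phases - mu)) - 1.0))
    return prof


def make_expression_dataset(
    cfg,
    n_genes: int = 300,
    n_samples: int = 18,
    frac_cyclic: float = 0.1,
    frac_bimodal: float = 0.2,
    amplitude: float = 0.5,
    ref_amplitude: float = 0.5,
    noise_sd: float = 0.1,
    baseline: float = 7.0,
    kappa: float = 8.0,
    present_prob: float = 0.95,
    n_bins: int = 64,
    seed: int = 0,
    reference_peak_phases: dict | None = None,
    sample_phases: np.ndarray | None = None,
):
    """Generate (ExpressionMatrix, ProbeAnnotation, SyntheticTruth).

    Cyclic genes carry one von Mises bump per cycle (or two, for a
    ``frac_bimodal`` share of the cyclic genes); the single-cell profile is
    mixed through the species' wave kernel, its exponent calibrated so the
    bulk log2 signal has half-amplitude ``amplitude`` exactly, and Gaussian
    noise of sd ``noise_sd`` is added on the log2 scale. The
    species' reference genes are always included as cyclic single-peak
    probes (ids ``ref_<gene>``) so the staging stage is exercisable; they
    carry ``ref_amplitude`` (staging panels are picked from strong,
    well-characterised oscillators) and ``reference_peak_phases`` overrides
    their peak phases (default: spread evenly over the cycle)."""
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    for frac in (frac_cyclic, frac_bimodal):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if sample_phases is None:
        sample_phases = rng.uniform(0.0, 1.0, size=n_samples)
    else:
        sample_phases = np.mod(np.asarray(sample_phases, dtype=float), 1.0)
        n_samples = sample_phases.size
    sample_ids = [f"s{j:02d}" for j in range(n_samples)]
    staging = SampleStaging(sample_ids, sample_phases)
    wave = WaveModel(cfg.d, cfg.alpha)
    kernel = build_kernel(wave, staging, n_bins=n_bins)
    grid = np.arange(n_bins) / n_bins

    refs = list(cfg.reference_genes)
    if reference_peak_phases is None:
        reference_peak_phases = {
            g: (i / max(len(refs), 1)) % 1.0 for i, g in enumerate(refs)
        }

    probe_ids, genes_rows, values = [], [], []
    anno_rows = []

    def bulk_series(peak_phases, amp):
        # single-cell log2 profile: baseline + a * s(phi) with s scaled to
        # [-1, 1]; the exponent a is calibrated so the bulk (kernel-mixed)
        # log2 signal has half-amplitude exactly `amp`, making
        # SNR = amplitude / noise_sd exact on the log2 scale.
        prof = _von_mises_profile(grid, peak_phases, kappa)
        s = 2.0 * (prof - prof.min()) / max(np.ptp(prof), 1e-12) - 1.0
        a = amp
        logm = None
        for _ in range(40):
            f_lin = 2.0 ** (a * s)
            logm = np.log2(kernel.weights @ f_lin)
            half = 0.5 * np.ptp(logm)
            if half <= 1e-12:
                return np.zeros(kernel.weights.shape[0])
            if abs(half - amp) < 1e-9:
                break
            a *= amp / half
        return logm - logm.mean()

    # reference probes first
    for gene in refs:
        mu = reference_peak_phases[gene]
        probe_ids.append(f"ref_{gene}")
        anno_rows.append((f"ref_{gene}", gene, "none", cfg.tax_id))
        values.append(baseline + bulk_series([mu], ref_amplitude))
        genes_rows.append(
            dict(
                probe_id=f"ref_{gene}",
                gene=gene,
                is_cyclic=True,
                n_peaks=1,
                peak_phases=(mu,),
                amplitude=ref_amplitude,
                baseline=baseline,
                noise_sd=noise_sd,
            )
        )

    n_cyclic = int(round(frac_cyclic * n_genes))
    for i in range(n_genes):
        pid = f"g{i:04d}"
        probe_ids.append(pid)
        anno_rows.append((pid, f"GENE{i:04d}", "none", cfg.tax_id))
        cyclic = i < n_cyclic
        if cyclic:
            bimodal = rng.uniform() < frac_bimodal
            if bimodal:
                mu1 = rng.uniform()
                mu2 = (mu1 + rng.uniform(0.35, 0.65)) % 1.0
                peaks = (mu1, mu2)
            else:
                peaks = (rng.uniform(),)
            values.append(baseline + bulk_series(list(peaks), amplitude))
            genes_rows.append(
                dict(
                    probe_id=pid,
                    gene=f"GENE{i:04d}",
                    is_cyclic=True,
                    n_peaks=len(peaks),
                    peak_phases=peaks,
                    amplitude=amplitude,
                    baseline=baseline,
                    noise_sd=noise_sd,
                )
            )
        else:
            values.append(np.full(n_samples, baseline))
            genes_rows.append(
                dict(
                    probe_id=pid,
                    gene=f"GENE{i:04d}",
                    is_cyclic=False,
                    n_peaks=0,
                    peak_phases=(),
                    amplitude=0.0,
                    baseline=baseline,
                    noise_sd=noise_sd,
                )
            )

    V = np.asarray(values)
    if noise_sd > 0:
        V = V + rng.normal(0.0, noise_sd, size=V.shape)
    present = rng.uniform(size=V.shape) < present_prob
    values_df = pd.DataFrame(V, index=probe_ids, columns=sample_ids)
    present_df = pd.DataFrame(present, index=probe_ids, columns=sample_ids)
    matrix = ExpressionMatrix(values_df, present_df)
    annotation = ProbeAnnotation(
        pd.DataFrame(
            anno_rows, columns=["probe_id", "gene_symbol", "pathway", "tax_id"]
        ).set_index("probe_id")
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(genes_rows).set_index("probe_id"),
        sample_phases=sample_phases,
        seed=seed,
        kernel=kernel,
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def make_promoters(
    n: int,
    length: int = 2000,
    gc: float = 0.5,
    planted: dict | None = None,
    seed: int = 0,
    name_prefix: str = "gene",
):
    """I.i.d.-background promoters with exact planted substrings.

    ``planted`` maps promoter index -> list of (position, substring); the
    substrings are written verbatim at the recorded positions. Overlapping
    planted instances raise an error. Returns ({name: seq}, truth table
    DataFrame with columns promoter, position, insert)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    planted = planted or {}
    promoters = {}
    truth_rows = []
    for i in range(n):
        seq = rng.choice(bases, size=length, p=probs)
        placements = sorted(planted.get(i, []))
        occupied = []
        for pos, ins in placements:
            if pos < 0 or pos + len(ins) > length:
                raise ValueError(f"planted instance does not fit: {(pos, ins)}")
            for s, e in occupied:
                if pos < e and s < pos + len(ins):
                    raise ValueError(
                        f"overlapping planted instances in promoter {i}: "
                        f"[{s},{e}) and [{pos},{pos + len(ins)})"
                    )
            occupied.append((pos, pos + len(ins)))
            seq[pos : pos + len(ins)] = list(ins.upper())
            truth_rows.append(
                {"promoter": f"{name_prefix}{i:04d}", "position": pos, "insert": ins}
            )
        promoters[f"{name_prefix}{i:04d}"] = "".join(seq)
    truth = pd.DataFrame(truth_rows, columns=["promoter", "position", "insert"])
    return promoters, truth


def write_fasta(promoters: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in promoters.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Homolog tables
# ---------------------------------------------------------------------------

def make_homolog_table(groups: list, path=None, seed: int = 0):
    """Write a homologene-dialect flat file from a group specification.

    ``groups`` is a list of dicts {tax_id: gene_symbol or (gene_id, symbol)}.
    Gene ids default to deterministic consecutive integers. Returns the
    lines (and writes them to ``path`` if given) plus a truth DataFrame."""
    rng = np.random.default_rng(seed)
    lines = []
    truth_rows = []
    gid = 1000
    for group_id, group in enumerate(groups, start=1):
        for tax, entry in sorted(group.items()):
            if isinstance(entry, tuple):
                gene_id, symbol = entry
            else:
                gene_id, symbol = gid, entry
                gid += 1
            prot_gi = int(rng.integers(10_000, 99_999))
            lines.append(
                f"{group_id}\t{tax}\t{gene_id}\t{symbol}\t{prot_gi}\tNP_{prot_gi}.1"
            )
            truth_rows.append(
                {
                    "group_id": group_id,
                    "tax_id": tax,
                    "gene_id": gene_id,
                    "gene_symbol": symbol,
                }
            )
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text, pd.DataFrame(
        truth_rows, columns=["group_id", "tax_id", "gene_id", "gene_symbol"]
    )
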