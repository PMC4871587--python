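"""End-to-end orchestration: filter -> stage -> kernel -> detect ->
deconvolve -> peak calling -> timeline -> reports.

Each stage writes TSV artifacts into the output directory and the run ends
with a JSON manifest recording seeds, thresholds and the probe counts at
every gate, so a rerun with the same configuration is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _config
from .datamodel import (
    ExpressionMatrix,
    apply_filters,
    read_expression_table,
    read_probe_annotation,
)
from .deconvolution import (
    call_peaks,
    estimate_sigma,
    maxent_deconvolve,
    select_candidates,
    timing_error_mc,
)
from .rhythm import detect_cyclic
from .staging import anchor_cycle_start, harmonic_peak_phase, optimize_phases
from .synthetic import make_expression_dataset
from .wave import WaveModel, build_kernel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Plain configuration for one pipeline run."""

    species: str = "chicken"
    outdir: str = "somitime_out"
    expression_path: str | None = None
    present_path: str | None = None
    annotation_path: str | None = None
    seed: int = 0
    n_bins: int = 64
    restarts: int = 20
    n_permutations: int = 999
    mc_replicates: int = 50
    detection_method: str = "permutation"
    # synthetic-input block, used when no expression_path is given
    n_genes: int = 120
    n_samples: int = 18
    frac_cyclic: float = 0.15
    frac_bimodal: float = 0.2
    noise_sd: float = 0.1
    amplitude: float = 0.5

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain-text ``key = value`` configuration file."""
        kwargs = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key not in cls.__dataclass_fields__:
                    raise KeyError(f"unknown configuration key {key!r}")
                current = getattr(cls(), key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in {"1", "true", "yes"}
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value if value.lower() != "none" else None
        return cls(**kwargs)


def format_timeline(timeline: pd.DataFrame, annotation=None) -> pd.DataFrame:
    """Table-style timeline: probe, gene, ``time±error`` in whole minutes
    per peak, LS p-value; sorted by p."""
    rows = []
    for _, row in timeline.iterrows():
        gene = ""
        if annotation is not None and row["probe_id"] in annotation.table.index:
            gene = str(annotation.table.loc[row["probe_id"], "gene_symbol"])
        times = row["peak_times_minutes"]
        errs = row["timing_errors_minutes"]
        formatted = "; ".join(
            f"{int(round(t))}±{int(round(e))}" for t, e in zip(times, errs)
        )
        rows.append(
            {
                "probe_id": row["probe_id"],
                "gene": gene,
                "time_min": formatted,
                "p_value": row["p_value"],
            }
        )
    out = pd.DataFrame(rows, columns=["probe_id", "gene", "time_min", "p_value"])
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the manifest dict (also written as JSON)."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = _config.get_species(cfg.species)
    manifest: dict = {
        "species": species.name,
        "seed": cfg.seed,
        "thresholds": asdict(species.thresholds),
        "n_bins": cfg.n_bins,
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return manifest["stages"][name]

    try:
        rec = stage("load")
        if cfg.expression_path:
            matrix = read_expression_table(cfg.expression_path, cfg.present_path)
            if not cfg.annotation_path:
                raise ValueError("annotation_path is required with expression_path")
            annotation = read_probe_annotation(cfg.annotation_path)
            truth = None
        else:
            matrix, annotation, truth = make_expression_dataset(
                species,
                n_genes=cfg.n_genes,
                n_samples=cfg.n_samples,
                frac_cyclic=cfg.frac_cyclic,
                frac_bimodal=cfg.frac_bimodal,
                amplitude=cfg.amplitude,
                noise_sd=cfg.noise_sd,
                n_bins=cfg.n_bins,
                seed=cfg.seed,
            )
        rec["n_probes"], rec["n_samples"] = matrix.shape

        rec = stage("filter")
        filtered = apply_filters(
            matrix,
            species.thresholds.present_fraction_min,
            species.thresholds.peak_to_trough_min,
        )
        rec["n_retained"] = filtered.shape[0]
        filtered.values.to_csv(outdir / "filtered_expression.tsv", sep="\t")

        rec = stage("stage")
        refs = [
            g
            for g in species.reference_genes
            if any(p in filtered.values.index for p in annotation.probes_for_gene(g))
        ]
        if not refs:
            raise ValueError("no reference genes retained; check reference_genes")
        staging = optimize_phases(
            filtered, annotation, refs, restarts=cfg.restarts, seed=cfg.seed
        )
        anchor_probes = [
            p
            for p in annotation.probes_for_gene(species.anchor_gene)
            if p in filtered.values.index
        ]
        if anchor_probes:
            y = filtered.values.loc[anchor_probes].to_numpy(float).mean(axis=0)
            peak = harmonic_peak_phase(y, staging.phases)
            staging = anchor_cycle_start(staging, peak, species.anchor_value)
        rec["objective"] = staging.objective_value
        pd.DataFrame(
            {"sample_id": staging.sample_ids, "phase": staging.phases}
        ).to_csv(outdir / "staging.tsv", sep="\t", index=False)

        rec = stage("kernel")
        kernel = build_kernel(
            WaveModel(species.d, species.alpha), staging, n_bins=cfg.n_bins
        )
        np.savetxt(outdir / "kernel.tsv", kernel.weights, delimiter="\t")

        detections = {}
        for k in (1, 2):
            rec = stage(f"detect_k{k}")
            det = detect_cyclic(
                filtered,
                staging,
                species,
                frequency_multiple=k,
                n_permutations=cfg.n_permutations,
                seed=cfg.seed + k,
                method=cfg.detection_method,
            )
            det.to_csv(outdir / f"detection_k{k}.tsv", sep="\t", index=False)
            detections[k] = det
            rec["n_passed"] = int(det["passed"].sum())

        rec = stage("deconvolve")
        calls = []
        passed1 = set(detections[1].loc[detections[1]["passed"], "probe_id"])
        passed2 = set(detections[2].loc[detections[2]["passed"], "probe_id"])
        for probe in sorted(passed1 | passed2):
            g_log = filtered.values.loc[probe].to_numpy(float)
            g_lin = 2.0**g_log
            sigma = max(estimate_sigma(g_lin, staging.phases), 1e-6)
            pf = maxent_deconvolve(g_lin, kernel, sigma, probe_id=probe)
            bimodal = probe in passed2 and probe not in passed1
            call = call_peaks(pf, species.period_minutes, expect_bimodal=bimodal)
            call.timing_error_minutes = timing_error_mc(
                g_lin,
                kernel,
                sigma,
                R=cfg.mc_replicates,
                seed=cfg.seed,
                period_minutes=species.period_minutes,
                expect_bimodal=bimodal,
            )
            calls.append(call)
        rec["n_profiles"] = len(calls)

        rec = stage("select")
        det_all = pd.concat([detections[1], detections[2]], ignore_index=True)
        det_best = (
            det_all.sort_values("p_value", kind="stable")
            .drop_duplicates("probe_id")
            .reset_index(drop=True)
        )
        timeline = select_candidates(calls, det_best, species)
        timeline.to_csv(outdir / "timeline.tsv", sep="\t", index=False)
        formatted = format_timeline(timeline, annotation)
        formatted.to_csv(outdir / "timeline_formatted.tsv", sep="\t", index=False)
        rec["n_selected"] = len(timeline)

        manifest["elapsed_seconds"] = round(time.time() - t0, 2)
        manifest["ok"] = True
    except Exception as exc:  # persist partial outputs, then re-raise
        manifest["ok"] = False
        manifest["failed_stage"] = list(manifest["stages"])[-1] if manifest["stages"] else None
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
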