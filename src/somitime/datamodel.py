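"""Expression-matrix container, TSV I/O, and probe pre-filters.

The expression matrix holds log2-scale intensities (probes x staged samples)
together with per-cell present/absent detection flags. Two filters are applied
before rhythm detection: a present-fraction filter (probe must be called
present on at least half the arrays by default) and a peak-to-trough filter
(linear fold change across present samples must reach 1.7 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Log2 intensities with present/absent flags.

    ``values`` and ``present`` are aligned DataFrames indexed by probe id with
    sample-id columns. Values must be finite wherever ``present`` is True.
    """

    values: pd.DataFrame
    present: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if self.present.shape != self.values.shape:
            raise FormatError(
                f"present table shape {self.present.shape} != values shape "
                f"{self.values.shape}"
            )
        self.present = self.present.astype(bool)
        self.present.index = self.values.index
        self.present.columns = self.values.columns
        masked = self.values.to_numpy(dtype=float)[self.present.to_numpy()]
        if not np.all(np.isfinite(masked)):
            raise FormatError("non-finite value in a present cell")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[probes], self.present.loc[probes])


@dataclass
class ProbeAnnotation:
    """probe_id -> (gene_symbol, pathway, tax_id) mapping."""

    table: pd.DataFrame  # columns: gene_symbol, pathway, tax_id; index probe_id

    PATHWAYS = ("Wnt", "Notch", "Fgf", "none")

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise FormatError("duplicate probe id in annotation")
        bad = set(self.table["pathway"]) - set(self.PATHWAYS)
        if bad:
            raise FormatError(f"unknown pathway label(s): {sorted(bad)}")

    def genes_for(self, probes) -> pd.Series:
        return self.table.loc[probes, "gene_symbol"]

    def probes_for_gene(self, gene: str) -> list[str]:
        hit = self.table.index[self.table["gene_symbol"] == gene]
        return list(hit)


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return df


def read_expression_table(path, present_path=None) -> ExpressionMatrix:
    """Read a probes x samples TSV (header row of sample ids, first column
    probe ids), plus an optional parallel present/absent table (same shape,
    entries P/A/M or true/false/1/0). Without a present table all entries are
    treated as present."""
    raw = _read_tsv(path)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for i, (probe, row) in enumerate(raw.iterrows(), start=2):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at line {i} "
                        f"(probe {probe!r})"
                    ) from exc
        raise FormatError(f"{path}: {exc}") from exc
    if present_path is None:
        present = pd.DataFrame(True, index=values.index, columns=values.columns)
    else:
        flags = _read_tsv(present_path)
        if flags.shape != values.shape:
            raise FormatError(
                f"{present_path}: shape {flags.shape} != expression shape "
                f"{values.shape}"
            )
        present = flags.map(_parse_flag)
    return ExpressionMatrix(values, present)


def _parse_flag(cell: str) -> bool:
    s = str(cell).strip().lower()
    if s in {"p", "true", "1", "present"}:
        return True
    if s in {"a", "m", "false", "0", "absent", "marginal"}:
        return False
    raise FormatError(f"unrecognised present/absent flag {cell!r}")


def write_expression_table(m: ExpressionMatrix, path, present_path=None) -> None:
    m.values.to_csv(path, sep="\t")
    if present_path is not None:
        m.present.replace({True: "P", False: "A"}).to_csv(present_path, sep="\t")


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read a TSV with columns probe_id, gene_symbol, pathway, tax_id."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_symbol": str})
    required = {"probe_id", "gene_symbol", "pathway", "tax_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return ProbeAnnotation(df.set_index("probe_id"))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_present(m: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Retain probes called present on at least ``min_fraction`` of samples.

    The boundary is inclusive: a probe present on exactly half of the arrays
    survives at the default threshold.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    if m.shape[0] == 0 or m.shape[1] == 0:
        logger.warning("filter_present: empty expression matrix")
        return m
    frac = m.present.to_numpy().mean(axis=1)
    keep = frac >= min_fraction
    dropped = np.asarray(m.probe_ids)[~keep]
    for probe in dropped:
        logger.debug("filter_present: dropped %s (reason=low_present_fraction)", probe)
    logger.info("filter_present: retained %d of %d probes", int(keep.sum()), len(keep))
    return m.subset(np.asarray(m.probe_ids)[keep])


def filter_peak_to_trough(
    m: ExpressionMatrix, min_ratio: float = 1.7
) -> ExpressionMatrix:
    """Retain probes whose linear fold change over present samples reaches
    ``min_ratio``; intensities are log2, so the ratio is ``2**(max - min)``.
    Probes with fewer than two present samples are removed."""
    if min_ratio < 1.0:
        raise ValueError("min_ratio must be >= 1")
    vals = m.values.to_numpy(dtype=float)
    pres = m.present.to_numpy()
    keep = np.zeros(len(m.probe_ids), dtype=bool)
    for i in range(vals.shape[0]):
        x = vals[i, pres[i]]
        if x.size < 2:
            logger.debug(
                "filter_peak_to_trough: dropped %s (reason=lt2_present)",
                m.probe_ids[i],
            )
            continue
        ratio = 2.0 ** (float(x.max()) - float(x.min()))
        if ratio >= min_ratio:
            keep[i] = True
        else:
            logger.debug(
                "filter_peak_to_trough: dropped %s (reason=flat ratio=%.3f)",
                m.probe_ids[i],
                ratio,
            )
    logger.info(
        "filter_peak_to_trough: retained %d of %d probes", int(keep.sum()), len(keep)
    )
    return m.subset(np.asarray(m.probe_ids)[keep])


def apply_filters(
    m: ExpressionMatrix,
    present_fraction_min: float = 0.5,
    peak_to_trough_min: float = 1.7,
) -> ExpressionMatrix:
    """Pipeline default composition: present filter, then peak-to-trough."""
    return filter_peak_to_trough(
        filter_present(m, present_fraction_min), peak_to_trough_min
    )
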