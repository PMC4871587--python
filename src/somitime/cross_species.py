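"""Ortholog mapping and cross-species phase comparison.

Peak times are only comparable across species after conversion to cycle
fractions (minutes / period). Two orthologous peaks are "in phase" when
their circular phase difference min(|a-b|, 1-|a-b|) is within a stated
tolerance (0.1 cycle by default). Genes whose timing could not be resolved
are labelled unresolved rather than not conserved: absence of evidence for
conserved regulation is not evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .datamodel import FormatError

HOMOLOGENE_COLUMNS = (
    "group_id",
    "tax_id",
    "gene_id",
    "gene_symbol",
    "protein_gi",
    "protein_accession",
)


@dataclass
class HomologTable:
    """Parsed homologene-dialect flat file."""

    table: pd.DataFrame  # columns as HOMOLOGENE_COLUMNS

    def groups(self):
        return self.table.groupby("group_id", sort=True)

    def __len__(self) -> int:
        return self.table["group_id"].nunique()


@dataclass
class ConservationCall:
    group_id: int
    genes: dict  # species/tax -> gene symbol
    peak_phases: dict  # species/tax -> phase (cycle fraction)
    phase_difference: float  # max pairwise circular difference
    in_phase: bool
    conserved_cyclic: bool
    unresolved: tuple = ()


def read_homologene(path) -> HomologTable:
    """Read the tab-delimited homologene dialect: group id, tax id, gene id,
    symbol, protein gi, protein accession. Extra columns are ignored; short
    rows raise a format error naming the line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=6 tab-delimited columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts[:6])
    df = pd.DataFrame(rows, columns=HOMOLOGENE_COLUMNS)
    if len(df):
        df["group_id"] = df["group_id"].astype(int)
        df["tax_id"] = df["tax_id"].astype(int)
        df["gene_id"] = df["gene_id"].astype(int)
        dup = df.duplicated(subset=["group_id", "tax_id", "gene_id"])
        if dup.any():
            raise FormatError(
                f"{path}: duplicate (tax_id, gene_id) within group "
                f"{df.loc[dup, 'group_id'].iloc[0]}"
            )
    return HomologTable(df)


def map_homologs(tbl: HomologTable, symbol_or_id, from_tax: int, to_tax: int):
    """All genes of ``to_tax`` sharing a homology group with the query gene
    of ``from_tax``; the query may be a symbol or an Entrez gene id. Returns
    an empty list when nothing matches (which is not evidence of absence of
    regulation). Order is deterministic by gene id."""
    df = tbl.table
    if isinstance(symbol_or_id, int) or str(symbol_or_id).isdigit():
        src = df[(df["tax_id"] == from_tax) & (df["gene_id"] == int(symbol_or_id))]
    else:
        src = df[(df["tax_id"] == from_tax) & (df["gene_symbol"] == symbol_or_id)]
    if src.empty:
        return []
    groups = set(src["group_id"])
    hits = df[(df["group_id"].isin(groups)) & (df["tax_id"] == to_tax)]
    return list(hits.sort_values("gene_id")["gene_symbol"])


def circular_phase_difference(a: float, b: float) -> float:
    """Circular distance on the unit cycle, in [0, 0.5]."""
    d = abs((a % 1.0) - (b % 1.0))
    return min(d, 1.0 - d)


def compare_timing(
    timelines: dict,
    tbl: HomologTable,
    species_tax: dict,
    species_period: dict,
    in_phase_tolerance: float = 0.1,
) -> list[ConservationCall]:
    """Cross-species conservation calls for every homology group with
    confident peaks in at least two species.

    ``timelines`` maps species name -> DataFrame with columns ``gene`` and
    ``peak_time_minutes`` (confident single-peak calls); ``species_tax`` and
    ``species_period`` map species name -> tax id / period in minutes.
    An optional ``unresolved`` boolean column marks genes whose timing error
    exceeded the species gate; they are carried as unresolved, never counted
    against conservation."""
    phase_of = {}
    unresolved_of = {}
    for sp, df in timelines.items():
        period = species_period[sp]
        for _, row in df.iterrows():
            key = (sp, str(row["gene"]))
            if bool(row.get("unresolved", False)):
                unresolved_of[key] = True
            else:
                phase_of[key] = (float(row["peak_time_minutes"]) / period) % 1.0

    calls = []
    for group_id, group in tbl.groups():
        present: dict[str, str] = {}
        unresolved = []
        for sp, tax in species_tax.items():
            members = group[group["tax_id"] == tax]
            for sym in members["gene_symbol"]:
                if (sp, sym) in phase_of:
                    present[sp] = sym
                    break
                if unresolved_of.get((sp, sym)):
                    unresolved.append((sp, sym))
        if len(present) < 2:
            continue
        phases = {sp: phase_of[(sp, sym)] for sp, sym in present.items()}
        diffs = [
            circular_phase_difference(phases[a], phases[b])
            for a, b in combinations(phases, 2)
        ]
        dmax = max(diffs)
        calls.append(
            ConservationCall(
                group_id=int(group_id),
                genes=dict(present),
                peak_phases=phases,
                phase_difference=dmax,
                in_phase=dmax <= in_phase_tolerance,
                conserved_cyclic=True,
                unresolved=tuple(unresolved),
            )
        )
    return calls
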