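"""Species-level configuration for segmentation-clock analyses.

Each vertebrate species carries a somite-cycle period, the two wave-geometry
parameters (``d``, ``alpha``) of the clock-and-wavefront readout
``x(phi, t) = (1 - d) * (phi + t) ** (1 / alpha)``, the reference cyclic genes
used for staging embryos on the cycle, and the statistical thresholds applied
when calling cyclic transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class Thresholds:
    """Detection and selection gates for cyclic-transcript calling.

    Attributes
    ----------
    p_max : float
        Maximum Lomb-Scargle p-value for a probe to count as rhythmic.
    fdr_max_unimodal, fdr_max_bimodal : float
        Benjamini-Hochberg q-value ceilings for the base-frequency
        (one peak per cycle) and double-frequency (two peaks) tests.
    max_timing_error_minutes : float
        Maximum Monte Carlo timing error for a peak call to enter the
        high-confidence timeline.
    peak_to_trough_min : float
        Minimum linear-scale fold change (computed as ``2**(max - min)`` of
        log2 intensities) for a probe to survive pre-filtering.
    present_fraction_min : float
        Minimum fraction of arrays on which the probe must be called present.
    regularity_min : float
        Minimum fraction of deconvolved-profile variance captured by the
        first two harmonics for the profile to count as regular.
    in_phase_tolerance : float
        Circular phase difference (cycle fraction) below which peaks in two
        species are called in phase.
    """

    p_max: float = 0.05
    fdr_max_unimodal: float = 0.10
    fdr_max_bimodal: float = 0.10
    max_timing_error_minutes: float = 10.0
    peak_to_trough_min: float = 1.7
    present_fraction_min: float = 0.5
    regularity_min: float = 0.6
    in_phase_tolerance: float = 0.1


@dataclass(frozen=True)
class SpeciesConfig:
    """One species' clock geometry, staging genes, and gates.

    ``period_minutes`` is the length of one somite cycle; phases are cycle
    fractions in [0, 1) and convert to minutes as ``phase * period_minutes``.
    ``d`` (0 <= d < 1) and ``alpha`` (> 0) parameterise the expression-wave
    trajectory along the presomitic mesoderm. ``anchor_gene`` defines the
    cycle start: its first expression band anchors phase ``anchor_value``.
    """

    name: str
    period_minutes: float
    d: float
    alpha: float
    reference_genes: tuple[str, ...]
    anchor_gene: str
    anchor_value: float = 0.0
    tax_id: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if self.period_minutes <= 0:
            raise ValueError("period_minutes must be positive")
        if not 0.0 <= self.d < 1.0:
            raise ValueError("wave parameter d must satisfy 0 <= d < 1")
        if self.alpha <= 0:
            raise ValueError("wave parameter alpha must be positive")

    def with_thresholds(self, **kwargs) -> "SpeciesConfig":
        return replace(self, thresholds=replace(self.thresholds, **kwargs))


# Built-in species: somite-cycle periods of 120 / 90 / 30 minutes for mouse,
# chicken and zebrafish, with wave-geometry parameters fitted under the
# uniform-phase-at-sacrifice assumption.
MOUSE = SpeciesConfig(
    name="mouse",
    period_minutes=120.0,
    d=0.022,
    alpha=1.900,
    reference_genes=("Hes1", "Hes5", "Lfng", "Axin2", "Nkd1", "Hey1", "Dact1"),
    anchor_gene="Lfng",
    tax_id=10090,
)

CHICKEN = SpeciesConfig(
    name="chicken",
    period_minutes=90.0,
    d=0.110,
    alpha=4.040,
    reference_genes=("T", "LFNG", "HES5", "HES1", "NKD1", "HEY1", "DACT1"),
    anchor_gene="LFNG",
    # The first LFNG band defines the cycle start; its bulk peak sits late in
    # the cycle (78 of 90 minutes).
    anchor_value=78.0 / 90.0,
    tax_id=9031,
)

ZEBRAFISH = SpeciesConfig(
    name="zebrafish",
    period_minutes=30.0,
    d=0.140,
    alpha=1.850,
    reference_genes=("her1", "her7", "dlc", "tbx16"),
    anchor_gene="her7",
    anchor_value=24.0 / 30.0,
    tax_id=7955,
    thresholds=Thresholds(
        fdr_max_unimodal=0.15,
        fdr_max_bimodal=0.10,
        max_timing_error_minutes=5.0,
    ),
)

SPECIES = {c.name: c for c in (MOUSE, CHICKEN, ZEBRAFISH)}


def get_species(name: str) -> SpeciesConfig:
    """Look up a built-in species configuration by name."""
    try:
        return SPECIES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; built-ins: {sorted(SPECIES)}"
        ) from None
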