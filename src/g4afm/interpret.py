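"""Structural interpretation of measured geometry.

Converts pipeline measurements into the quantities a structural biologist
reads off them: number of stacked G-quartets per axial repeat (adjacent
quartets stack at ~3.4 A), single-stranded-nucleotide equivalents of a
contour length, and the effective solution concentration implied by surface
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "QuartetEstimate",
    "ConcentrationEstimate",
    "quartet_count",
    "nucleotide_count",
    "nucleotide_range",
    "surface_concentration",
    "QUARTET_SPACING_NM",
    "SSRNA_RISE_NM",
]

AVOGADRO = 6.02214076e23

#: Axial spacing between stacked G-quartets (0.34 nm = 3.4 A).
QUARTET_SPACING_NM = 0.34

#: Default per-nucleotide rise of single-stranded RNA, back-derived from the
#: 50 nm -> 74 nt / 100 nm -> 148 nt correspondence (50/74 = 100/148 = 0.676).
SSRNA_RISE_NM = 0.676


@dataclass
class QuartetEstimate:
    """Stacked-quartet count for an axial repeat distance."""

    n_quartets: int
    n_uncertainty: int | None
    spacing_nm: float

    def __post_init__(self) -> None:
        if self.n_quartets < 1:
            raise ValueError("quartet count must be >= 1")


@dataclass
class ConcentrationEstimate:
    """Surface-coverage-derived effective solution molarity."""

    molarity: float
    n_molecules: float
    assumptions: dict = field(default_factory=dict)


def quartet_count(
    separation_nm: float,
    separation_sd_nm: float | None = None,
    spacing_nm: float = QUARTET_SPACING_NM,
) -> QuartetEstimate:
    """Convert an axial repeat distance into stacked G-quartets.

    ``n = round(separation / spacing)``; an uncertainty (SD of the repeat
    distribution) propagates the same way.  Scale-invariant: scaling both
    inputs by k leaves the count unchanged.
    """
    if separation_nm <= 0 or spacing_nm <= 0:
        raise ValueError("separation and spacing must be > 0")
    n = int(round(separation_nm / spacing_nm))
    unc = None
    if separation_sd_nm is not None:
        if separation_sd_nm < 0:
            raise ValueError("separation_sd_nm must be >= 0")
        unc = int(round(separation_sd_nm / spacing_nm))
    return QuartetEstimate(max(n, 1), unc, spacing_nm)


def nucleotide_count(contour_nm: float, rise_nm_per_nt: float = SSRNA_RISE_NM) -> int:
    """Number of single-stranded nucleotides spanning a contour length."""
    if contour_nm <= 0 or rise_nm_per_nt <= 0:
        raise ValueError("contour and rise must be > 0")
    return int(round(contour_nm / rise_nm_per_nt))


def nucleotide_range(
    contour_range_nm: tuple[float, float], rise_nm_per_nt: float = SSRNA_RISE_NM
) -> tuple[int, int]:
    """Nucleotide counts for a (low, high) contour-length range, endpoints
    converted independently."""
    lo, hi = contour_range_nm
    return (nucleotide_count(lo, rise_nm_per_nt), nucleotide_count(hi, rise_nm_per_nt))


def surface_concentration(
    coverage_fraction: float,
    substrate_area_nm2: float,
    gmp_footprint_nm2: float,
    solution_volume_l: float,
    stacking_multiplier: float = 1.0,
) -> ConcentrationEstimate:
    """Effective molarity of surface-bound monomers relative to the solution.

    ``n = coverage * area / footprint * stacking_multiplier`` monomers
    (the multiplier accounts for the layers stacked within a filament's
    height), divided by Avogadro's number and the imaging-solution volume.
    Linear in coverage and inverse-linear in volume.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in [0, 1]")
    if substrate_area_nm2 <= 0 or gmp_footprint_nm2 <= 0:
        raise ValueError("areas must be > 0")
    if solution_volume_l <= 0:
        raise ValueError("solution volume must be > 0")
    if stacking_multiplier <= 0:
        raise ValueError("stacking_multiplier must be > 0")
    n = coverage_fraction * substrate_area_nm2 / gmp_footprint_nm2 * stacking_multiplier
    molarity = n / (AVOGADRO * solution_volume_l)
    return ConcentrationEstimate(
        molarity=molarity,
        n_molecules=n,
        assumptions={
            "coverage_fraction": coverage_fraction,
            "substrate_area_nm2": substrate_area_nm2,
            "gmp_footprint_nm2": gmp_footprint_nm2,
            "solution_volume_l": solution_volume_l,
            "stacking_multiplier": stacking_multiplier,
            "note": "assumes homogeneous distribution across the substrate",
        },
    )
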