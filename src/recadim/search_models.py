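"""Closed-form models of RecA homology search in a cylindrical nucleoid.

The central model treats the RecA--ssDNA filament as a thin absorbing rod on
the axis of a cylindrical nucleoid (radius ``R``, length ``2L``). Because some
segment of the stretched filament is homologous to the chromosomal dsDNA
segment at every axial position, capture depends only on radial diffusion of
the dsDNA locus: the search is effectively two-dimensional. The alternative
("naive") model is the standard diffusion-limited bimolecular reaction of the
locus with a point-like filament segment anywhere in the nucleoid volume, and
a parallelised variant subdivides the homologous dsDNA into independently
searching segments.

Times are in seconds, lengths in µm, rates in µm³/s throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Literal

from . import constants


@dataclass(frozen=True)
class NucleoidGeometry:
    """Cylindrical nucleoid: half-length L, radius R, reaction radius r (µm)."""

    half_length: float = constants.HALF_LENGTH_UM
    nucleoid_radius: float = constants.NUCLEOID_RADIUS_UM
    reaction_radius: float = constants.REACTION_RADIUS_UM

    def __post_init__(self) -> None:
        if self.half_length <= 0:
            raise ValueError("half_length must be positive")
        if not 0 < self.reaction_radius < self.nucleoid_radius:
            raise ValueError("need 0 < reaction_radius < nucleoid_radius")

    def volume(self) -> float:
        """Nucleoid volume V = 2·L·π·R² (µm³)."""
        return 2.0 * self.half_length * math.pi * self.nucleoid_radius**2

    def concentration(self) -> float:
        """Concentration of the single searching dsDNA segment, c = 1/V."""
        return 1.0 / self.volume()


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Scale-dependent locus diffusivity (µm²/s).

    Chromosomal loci are subdiffusive, so the effective diffusion coefficient
    depends on the distance over which displacement is measured: ``D_R`` at
    the nucleoid-radius scale and the slower ``D_L`` at the cell-length scale.
    """

    D_R: float = constants.D_R_UM2_S
    D_L: float = constants.D_L_UM2_S

    def __post_init__(self) -> None:
        if self.D_R <= 0 or self.D_L <= 0:
            raise ValueError("diffusivities must be positive")
        if self.D_R < self.D_L:
            raise ValueError("D_R must be >= D_L (short-range diffusion is faster)")


@dataclass(frozen=True)
class ProbingBudget:
    """Budget for sequence probing by the filament.

    G bp of dsDNA in the cell must be interrogated by the F bp of ssDNA held
    in the filament, in n-bp segments, within ``available_time`` seconds.
    """

    genome_dsDNA_bp: float = constants.GENOME_DSDNA_BP
    filament_ssDNA_bp: float = constants.FILAMENT_SSDNA_BP
    probe_segment_bp: float = 10.0
    available_time: float = constants.AVAILABLE_TIME_S

    def __post_init__(self) -> None:
        if not self.genome_dsDNA_bp >= self.filament_ssDNA_bp > 0:
            raise ValueError("need genome_dsDNA_bp >= filament_ssDNA_bp > 0")
        if self.probe_segment_bp <= 0:
            raise ValueError("probe_segment_bp must be positive")
        if self.available_time <= 0:
            raise ValueError("available_time must be positive")


@dataclass
class ModelPrediction:
    """One row of the model-comparison table."""

    model_name: str
    search_time: float | None
    capture_rate: float | None
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


Convention = Literal["formula", "printed"]


def capture_rate_2d(geom: NucleoidGeometry, diff: DiffusionCoefficients) -> float:
    """Diffusion-limited rate onto an absorbing axial rod, k = 2π(2L)·D_R/ln(R/r)."""
    g = geom
    return 2.0 * math.pi * (2.0 * g.half_length) * diff.D_R / math.log(
        g.nucleoid_radius / g.reaction_radius
    )


def search_time_2d(
    geom: NucleoidGeometry,
    diff: DiffusionCoefficients,
    convention: Convention = "formula",
) -> float:
    """Mean association time of the reduced-dimensionality (2D) search.

    ``convention="formula"`` evaluates T = V/k = R²·ln(R/r)/(2·D_R).
    ``convention="printed"`` evaluates R²·ln(R/r)/D_R, i.e. the same
    expression without the factor ½ — the numeric substitution that yields
    the headline 300 s. The discrepancy between the two is deliberate and
    documented; the symbolic form is the default. Independent of L either way.
    """
    g = geom
    t = g.nucleoid_radius**2 * math.log(g.nucleoid_radius / g.reaction_radius) / diff.D_R
    if convention == "formula":
        return t / 2.0
    if convention == "printed":
        return t
    raise ValueError(f"unknown convention {convention!r}")


def capture_rate_3d(geom: NucleoidGeometry, diff: DiffusionCoefficients) -> float:
    """Smoluchowski rate onto a static point target, k = 4π·r·D_L."""
    return 4.0 * math.pi * geom.reaction_radius * diff.D_L


def search_time_3d(geom: NucleoidGeometry, diff: DiffusionCoefficients) -> float:
    """Naive 3D search time T = V/k = L·R²/(2·r·D_L); linear in L."""
    return geom.volume() / capture_rate_3d(geom, diff)


def model_speed_ratio(geom: NucleoidGeometry, diff: DiffusionCoefficients) -> float:
    """Fold speed-up of 2D over naive 3D search, (L/(r·D_L))/(ln(R/r)/D_R)."""
    g = geom
    return (g.half_length / (g.reaction_radius * diff.D_L)) / (
        math.log(g.nucleoid_radius / g.reaction_radius) / diff.D_R
    )


def parallel_speedup(filament_bp: float, segment_bp: float) -> float:
    """Speed-up from subdividing the filament into independently searching segments."""
    if not 0 < segment_bp <= filament_bp:
        raise ValueError("need 0 < segment_bp <= filament_bp")
    return filament_bp / segment_bp


def probing_tests_per_segment(budget: ProbingBudget) -> float:
    """Number of dsDNA segments each filament segment must test, (G/n)/(F/n) = G/F.

    The probing-segment length n cancels exactly.
    """
    return budget.genome_dsDNA_bp / budget.filament_ssDNA_bp


def max_probe_time(budget: ProbingBudget) -> float:
    """Upper bound on the time per probing test (s), available_time/(G/F)."""
    return budget.available_time / probing_tests_per_segment(budget)


def repair_success_fraction(
    repaired: int = constants.REPAIRED_CELLS,
    total: int = constants.CELLS_WITH_TEMPLATE,
) -> float:
    """Percentage of template-retaining cells that repaired the break and divided."""
    if total <= 0 or repaired < 0 or repaired > total:
        raise ValueError("need 0 <= repaired <= total, total > 0")
    return 100.0 * repaired / total


def predict_all(
    geom: NucleoidGeometry | None = None,
    diff: DiffusionCoefficients | None = None,
    budget: ProbingBudget | None = None,
) -> list[ModelPrediction]:
    """Model-comparison table at the given (or default) parameters."""
    geom = geom if geom is not None else NucleoidGeometry()
    diff = diff if diff is not None else DiffusionCoefficients()
    budget = budget if budget is not None else ProbingBudget()
    ratio_geom = NucleoidGeometry(
        half_length=geom.half_length,
        nucleoid_radius=constants.NUCLEOID_RADIUS_RATIO_UM
        if geom.nucleoid_radius == constants.NUCLEOID_RADIUS_UM
        else geom.nucleoid_radius,
        reaction_radius=geom.reaction_radius,
    )
    params = {
        "L_um": geom.half_length,
        "R_um": geom.nucleoid_radius,
        "r_um": geom.reaction_radius,
        "D_R_um2_s": diff.D_R,
        "D_L_um2_s": diff.D_L,
    }
    rows = [
        ModelPrediction(
            "reduced_2d",
            search_time_2d(geom, diff, "formula"),
            capture_rate_2d(geom, diff),
            {**params, "search_time_printed_s": search_time_2d(geom, diff, "printed")},
        ),
        ModelPrediction(
            "naive_3d",
            search_time_3d(geom, diff),
            capture_rate_3d(geom, diff),
            params,
        ),
        ModelPrediction(
            "parallel_naive",
            search_time_3d(geom, diff)
            / parallel_speedup(
                constants.PARALLEL_FILAMENT_BASES, constants.PARALLEL_SEGMENT_BASES
            ),
            None,
            {
                **params,
                "speedup_fold": parallel_speedup(
                    constants.PARALLEL_FILAMENT_BASES, constants.PARALLEL_SEGMENT_BASES
                ),
            },
        ),
    ]
    rows.append(
        ModelPrediction(
            "summary",
            None,
            None,
            {
                "speed_ratio_2d_over_3d": model_speed_ratio(ratio_geom, diff),
                "probing_tests_per_segment": probing_tests_per_segment(budget),
                "max_probe_time_s": max_probe_time(budget),
                "repair_success_percent": repair_success_fraction(),
            },
        )
    )
    return rows


def predictions_to_json(rows: list[ModelPrediction]) -> str:
    return json.dumps([r.to_dict() for r in rows], indent=2)


def predictions_from_json(text: str) -> list[ModelPrediction]:
    return [ModelPrediction(**row) for row in json.loads(text)]
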