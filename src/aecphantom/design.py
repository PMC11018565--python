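"""Experimental design: systems, phantom, and acquisition-plan enumeration.

Encodes the three mammography units under comparison (one GE Senographe
Pristina and two Hologic Selenia units), the stacked-PMMA phantom with its
0.2-mm aluminum contrast square, and the full factorial plan
(system x modality x AEC mode x PMMA thickness x repeat) that every later
stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SystemModel",
    "PhantomSpec",
    "PlanEntry",
    "GE_PRISTINA",
    "HOLOGIC_DIMENSIONS",
    "HOLOGIC_3DIMENSIONS",
    "DEFAULT_SYSTEMS",
    "THICKNESSES_MM",
    "MODALITIES",
    "enumerate_plan",
    "plan_counts",
    "plan_to_frame",
]

MODALITIES = ("DM", "DBT", "CEM")

#: PMMA thickness ladder of the study design: 20-70 mm in 5-mm steps.
THICKNESSES_MM: tuple[float, ...] = tuple(float(t) for t in range(20, 75, 5))


@dataclass(frozen=True)
class SystemModel:
    """Static descriptor of one mammography unit.

    ``aec_modes`` maps modality label (``DM``/``DBT``/``CEM``) to the ordered
    AEC-mode labels available on that unit for that modality; a modality
    absent from the map is not available on the unit.
    """

    name: str
    detector_kind: str  # "scintillator" (CsI FPD) or "photoconductor" (a-Se FPD)
    pixel_pitch_um: float
    dbt_binning: bool  # 2x2 detector binning in DBT mode
    anode_tracks: frozenset[str]
    filter_tracks: frozenset[str]
    dbt_n_projections: int
    dbt_angular_range_deg: float  # total angular span of the DBT sweep
    dbt_geometry: str
    dbt_grid: bool
    aec_modes: Mapping[str, tuple[str, ...]]
    cem_capable: bool

    def __post_init__(self) -> None:
        if self.dbt_n_projections not in (9, 15):
            raise ValueError(
                f"{self.name}: dbt_n_projections must be 9 or 15, "
                f"got {self.dbt_n_projections}"
            )
        if self.dbt_angular_range_deg not in (25.0, 15.0):
            raise ValueError(
                f"{self.name}: dbt_angular_range_deg must be 25 or 15 deg, "
                f"got {self.dbt_angular_range_deg}"
            )
        # 9-projection sweeps pair with the 25-degree span, 15 with 15 deg
        expected_span = 25.0 if self.dbt_n_projections == 9 else 15.0
        if self.dbt_angular_range_deg != expected_span:
            raise ValueError(
                f"{self.name}: {self.dbt_n_projections} projections imply a "
                f"{expected_span} deg span, got {self.dbt_angular_range_deg}"
            )
        if self.cem_capable != ("CEM" in self.aec_modes):
            raise ValueError(
                f"{self.name}: cem_capable inconsistent with aec_modes keys"
            )
        for modality in self.aec_modes:
            if modality not in MODALITIES:
                raise ValueError(f"{self.name}: unknown modality {modality!r}")

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.aec_modes)

    def modes_for(self, modality: str) -> tuple[str, ...]:
        return tuple(self.aec_modes.get(modality, ()))

    def dbt_projection_angles(self) -> tuple[float, ...]:
        """Evenly spaced projection angles spanning +/- half the sweep."""
        n = self.dbt_n_projections
        half = self.dbt_angular_range_deg / 2.0
        step = self.dbt_angular_range_deg / (n - 1)
        return tuple(round(-half + i * step, 6) for i in range(n))

    def effective_pixel_pitch_um(self, modality: str) -> float:
        """Pixel pitch as sampled in a given modality (DBT may bin 2x2)."""
        if modality == "DBT" and self.dbt_binning:
            return 2.0 * self.pixel_pitch_um
        return self.pixel_pitch_um


@dataclass(frozen=True)
class PhantomSpec:
    """Stacked-PMMA phantom with an aluminum contrast square on top.

    ``insert_offset_mm`` is the (depth, lateral) position of the insert
    centre measured from the midpoint of the chest-wall edge; the default
    places the square centred laterally with its inner edge 60 mm from the
    chest-wall side.
    """

    pmma_thickness_mm: float
    insert_material: str = "Al"
    insert_side_mm: float = 15.0
    insert_thickness_mm: float = 0.2
    insert_offset_mm: tuple[float, float] = (67.5, 0.0)

    def __post_init__(self) -> None:
        if self.pmma_thickness_mm <= 0:
            raise ValueError("pmma_thickness_mm must be positive")
        if self.insert_side_mm <= 0 or self.insert_thickness_mm <= 0:
            raise ValueError("insert dimensions must be positive")


@dataclass(frozen=True)
class PlanEntry:
    """One study cell repeat: a planned DM image, DBT scan or CEM LE+HE pair."""

    system: SystemModel
    modality: str
    aec_mode: str
    phantom: PhantomSpec
    repeat_index: int

    @property
    def pmma_mm(self) -> float:
        return self.phantom.pmma_thickness_mm

    @property
    def cell(self) -> tuple[str, str, str, float]:
        return (self.system.name, self.modality, self.aec_mode, self.pmma_mm)


GE_PRISTINA = SystemModel(
    name="GE Pristina",
    detector_kind="scintillator",
    pixel_pitch_um=100.0,
    dbt_binning=False,
    anode_tracks=frozenset({"Mo", "Rh"}),
    filter_tracks=frozenset({"Mo", "Ag", "Cu"}),
    dbt_n_projections=9,
    dbt_angular_range_deg=25.0,
    dbt_geometry="partial isocentric",
    dbt_grid=True,
    aec_modes={
        "DM": ("AOP/STD", "AOP/STD+", "AOP/DOSE"),
        "DBT": ("AOP/STD", "AOP/STD+"),
        "CEM": ("AOP/STD",),
    },
    cem_capable=True,
)

HOLOGIC_DIMENSIONS = SystemModel(
    name="Hologic Dimensions",
    detector_kind="photoconductor",
    pixel_pitch_um=70.0,
    dbt_binning=True,
    anode_tracks=frozenset({"W"}),
    filter_tracks=frozenset({"Rh", "Ag", "Al"}),
    dbt_n_projections=15,
    dbt_angular_range_deg=15.0,
    dbt_geometry="full isocentric",
    dbt_grid=False,
    aec_modes={
        "DM": ("AutoFilter",),
        "DBT": ("AutoFilter",),
    },
    cem_capable=False,
)

HOLOGIC_3DIMENSIONS = SystemModel(
    name="Hologic 3Dimensions",
    detector_kind="photoconductor",
    pixel_pitch_um=70.0,
    dbt_binning=False,
    anode_tracks=frozenset({"W"}),
    filter_tracks=frozenset({"Rh", "Ag", "Al", "Cu"}),
    dbt_n_projections=15,
    dbt_angular_range_deg=15.0,
    dbt_geometry="full isocentric",
    dbt_grid=False,
    aec_modes={
        "DM": ("AutoFilter",),
        "DBT": ("AutoFilter",),
        "CEM": ("AutoFilter",),
    },
    cem_capable=True,
)

DEFAULT_SYSTEMS: tuple[SystemModel, ...] = (
    GE_PRISTINA,
    HOLOGIC_DIMENSIONS,
    HOLOGIC_3DIMENSIONS,
)


def enumerate_plan(
    systems: Sequence[SystemModel] = DEFAULT_SYSTEMS,
    thicknesses: Sequence[float] = THICKNESSES_MM,
    repeats: int = 3,
    modalities: Sequence[str] | None = None,
    phantom_template: PhantomSpec | None = None,
) -> list[PlanEntry]:
    """Enumerate the acquisition plan in deterministic order.

    One entry per (system, available modality, available AEC mode, thickness,
    repeat); modalities a system lacks are silently skipped.  Ordering is
    (system, modality, mode, thickness, repeat) as configured.
    """
    thicknesses = list(thicknesses)
    if not thicknesses:
        raise ValueError("thickness list must be non-empty")
    if any(b <= a for a, b in zip(thicknesses, thicknesses[1:])):
        raise ValueError("thicknesses must be strictly increasing")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    wanted = tuple(modalities) if modalities is not None else MODALITIES
    for m in wanted:
        if m not in MODALITIES:
            raise ValueError(f"unknown modality {m!r}")

    plan: list[PlanEntry] = []
    for system in systems:
        for modality in system.modalities:
            if modality not in wanted:
                continue
            for mode in system.modes_for(modality):
                for t in thicknesses:
                    if phantom_template is None:
                        phantom = PhantomSpec(pmma_thickness_mm=float(t))
                    else:
                        phantom = replace(
                            phantom_template, pmma_thickness_mm=float(t)
                        )
                    for r in range(1, repeats + 1):
                        plan.append(
                            PlanEntry(system, modality, mode, phantom, r)
                        )
    return plan


def plan_counts(plan: Iterable[PlanEntry]) -> dict[str, int]:
    """Study counts per modality; absent modalities report zero."""
    counts = {m: 0 for m in MODALITIES}
    for entry in plan:
        counts[entry.modality] += 1
    return counts


def plan_to_frame(plan: Iterable[PlanEntry]) -> pd.DataFrame:
    """Plan as a long-format table (CSV-exportable)."""
    rows = [
        {
            "system": e.system.name,
            "modality": e.modality,
            "aec_mode": e.aec_mode,
            "pmma_mm": e.pmma_mm,
            "repeat": e.repeat_index,
        }
        for e in plan
    ]
    return pd.DataFrame(
        rows, columns=["system", "modality", "aec_mode", "pmma_mm", "repeat"]
    )
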