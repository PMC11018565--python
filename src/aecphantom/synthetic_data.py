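"""Synthetic study generator: AEC decisions, exposures, kerma and images.

Emulates the acquisition campaign end to end so every pipeline stage is
testable without real data:

* **AEC rules** reproduce the qualitative decision logic observed on the
  three units: the GE unit switches binarily between Mo/Mo @ 26 kVp below
  35 mm PMMA and Rh/Ag @ 34 kVp at or above, with exposure the only factor
  differing between its AOP modes (STD+ up, DOSE down); the Hologic units
  ramp both kVp and mAs with thickness on a single W/Rh (DM) or W/Al (DBT)
  track; high-energy CEM images use a Cu filter at 49 kVp (GE) or 45/49 kVp
  (Hologic).  Exposure grows exponentially with thickness (doubling every
  12 mm PMMA), with magnitudes placed in the clinically typical range.
  Per-thickness mAs tables are not published by the vendors; the ramps here
  are illustrative stand-ins with the correct monotone structure.
* **Jitter** perturbs mAs multiplicatively (lognormal, ~1% relative SD by
  default), the scale at which AEC triplicates actually vary; spectrum
  choices are perfectly repeatable, as observed.
* **Rendering** produces flat "for processing" images: uniform background
  proportional to the kerma reaching the detector, a planted darker square
  where the Al insert sits, and stationary Gaussian noise with a quantum
  (square-root) exposure scaling.  The planted CNR is reported alongside
  each image so measured CNR can be checked against ground truth; it
  accounts for the variance added by integer quantization.

All randomness flows from one master seed through a counter scheme
(SeedSequence(master, entry_index, stream)), so a study regenerates
bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_SYSTEMS,
    THICKNESSES_MM,
    PhantomSpec,
    PlanEntry,
    SystemModel,
    enumerate_plan,
)
from .dicom_io import Acquisition, acquisition_to_row, write_synthetic_dicom
from .dosimetry import SpectrumKey, TubeOutputModel
from .image_metrics import RoiConfig, measure_iq, place_rois, measure_rois, compute_cnr

__all__ = [
    "AecRule",
    "JitterModel",
    "RenderModel",
    "RenderResult",
    "StudyConfig",
    "default_rules",
    "default_tube_output",
    "simulate_aec",
    "render_image",
    "generate_study",
]


# --------------------------------------------------------------------------
# AEC decision rules

@dataclass(frozen=True)
class AecRule:
    """AEC behaviour for one (system, modality, mode).

    ``spectrum_rule`` maps PMMA thickness to (anode, filter, kVp) and is
    piecewise constant; ``mas_at_45mm`` and ``doubling_mm`` define the
    strictly increasing exposure ramp mas(t) = mas45 * 2**((t-45)/doubling),
    scaled by ``mode_scaling`` (e.g. STD+ above 1, DOSE below 1).
    """

    system: str
    modality: str
    aec_mode: str
    spectrum_rule: Callable[[float], tuple[str, str, float]]
    mas_at_45mm: float
    doubling_mm: float = 12.0
    mode_scaling: float = 1.0

    def spectrum(self, pmma_mm: float) -> tuple[str, str, float]:
        return self.spectrum_rule(pmma_mm)

    def mas(self, pmma_mm: float) -> float:
        return (
            self.mas_at_45mm
            * self.mode_scaling
            * 2.0 ** ((pmma_mm - 45.0) / self.doubling_mm)
        )


def _ge_low_energy(pmma_mm: float) -> tuple[str, str, float]:
    # binary spectrum switch at 35 mm PMMA
    return ("Mo", "Mo", 26.0) if pmma_mm < 35.0 else ("Rh", "Ag", 34.0)


_HOLOGIC_DM_KVP = {20: 25, 25: 26, 30: 27, 35: 28, 40: 29, 45: 30,
                   50: 31, 55: 32, 60: 33, 65: 34, 70: 34}
_HOLOGIC_DBT_KVP = {20: 26, 25: 27, 30: 28, 35: 29, 40: 30, 45: 31,
                    50: 32, 55: 33, 60: 34, 65: 36, 70: 38}


def _step_kvp(table: Mapping[int, int], pmma_mm: float) -> float:
    nodes = sorted(table)
    chosen = nodes[0]
    for t in nodes:
        if pmma_mm >= t:
            chosen = t
    return float(table[chosen])


def _hologic_dm(pmma_mm: float) -> tuple[str, str, float]:
    return ("W", "Rh", _step_kvp(_HOLOGIC_DM_KVP, pmma_mm))


def _hologic_dbt(pmma_mm: float) -> tuple[str, str, float]:
    return ("W", "Al", _step_kvp(_HOLOGIC_DBT_KVP, pmma_mm))


def _ge_he(pmma_mm: float) -> tuple[str, str, float]:
    return ("Rh", "Cu", 49.0)


def _hologic_he(pmma_mm: float) -> tuple[str, str, float]:
    return ("W", "Cu", 45.0 if pmma_mm < 45.0 else 49.0)


def default_rules() -> dict[tuple[str, str, str], AecRule | tuple[AecRule, AecRule]]:
    """Rule set for the three units; CEM entries hold an (LE, HE) pair.

    GE mode scalings use the reported average MGD shifts between AOP modes
    (+32.5% for STD+, -24.0% for DOSE in DM; +33.4% for STD+ in DBT).
    """
    rules: dict = {}
    ge = "GE Pristina"
    for mode, scale in (("AOP/STD", 1.0), ("AOP/STD+", 1.325), ("AOP/DOSE", 0.76)):
        rules[(ge, "DM", mode)] = AecRule(ge, "DM", mode, _ge_low_energy, 50.0,
                                          mode_scaling=scale)
    for mode, scale in (("AOP/STD", 1.0), ("AOP/STD+", 1.334)):
        rules[(ge, "DBT", mode)] = AecRule(ge, "DBT", mode, _ge_low_energy, 48.5,
                                           mode_scaling=scale)
    rules[(ge, "CEM", "AOP/STD")] = (
        AecRule(ge, "CEM", "AOP/STD", _ge_low_energy, 50.0),  # LE = DM AOP/STD
        AecRule(ge, "CEM", "AOP/STD", _ge_he, 100.0, doubling_mm=25.0),
    )
    for holo in ("Hologic Dimensions", "Hologic 3Dimensions"):
        rules[(holo, "DM", "AutoFilter")] = AecRule(
            holo, "DM", "AutoFilter", _hologic_dm, 46.0)
        rules[(holo, "DBT", "AutoFilter")] = AecRule(
            holo, "DBT", "AutoFilter", _hologic_dbt, 58.0)
    h3 = "Hologic 3Dimensions"
    rules[(h3, "CEM", "AutoFilter")] = (
        AecRule(h3, "CEM", "AutoFilter", _hologic_dm, 60.0),  # LE: DM track, more dose
        AecRule(h3, "CEM", "AutoFilter", _hologic_he, 100.0, doubling_mm=25.0),
    )
    return rules


def default_tube_output() -> TubeOutputModel:
    """Typical specific tube outputs (mGy/mAs at the reference distance)."""
    return TubeOutputModel(
        y0_mgy_per_mas={
            ("Mo", "Mo"): 0.045,
            ("Rh", "Ag"): 0.060,
            ("W", "Rh"): 0.055,
            ("W", "Al"): 0.055,
            ("Rh", "Cu"): 0.0027,
            ("W", "Cu"): 0.0027,
        }
    )


# --------------------------------------------------------------------------
# Jitter and simulation

@dataclass(frozen=True)
class JitterModel:
    """Multiplicative lognormal mAs jitter; ~1% relative SD keeps triplicate
    max relative errors safely below the 5% repeatability bound."""

    mas_rel_sd: float = 0.012

    def draw(self, rng: np.random.Generator) -> float:
        if self.mas_rel_sd == 0:
            return 1.0
        sigma = math.sqrt(math.log(1.0 + self.mas_rel_sd**2))
        return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def _quantize(value: float, decimals: int) -> float:
    return float(round(value, decimals))


def simulate_aec(
    entry: PlanEntry,
    rules: Mapping | None = None,
    jitter: JitterModel | None = None,
    tube_output: TubeOutputModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[Acquisition]:
    """Simulate the AEC for one plan entry.

    Returns one acquisition for DM, the full projection list for a DBT scan
    (total mAs split equally across projections), and the LE+HE pair for a
    CEM series.  Exposure carries the lognormal jitter; spectrum selection
    is deterministic.  Entrance kerma comes from the tube-output model and
    is quantized (6 decimals, as is mAs to 1 uAs) so DICOM round-trips are
    exact.
    """
    rules = rules if rules is not None else default_rules()
    jitter = jitter or JitterModel()
    tube_output = tube_output or default_tube_output()
    key = (entry.system.name, entry.modality, entry.aec_mode)
    try:
        rule = rules[key]
    except KeyError:
        raise KeyError(f"no AEC rule for {key}") from None
    rng = np.random.default_rng(seed)
    pmma = entry.pmma_mm

    def build(rule: AecRule, sub_kind: str, angle: float, mas: float) -> Acquisition:
        anode, filt, kvp = rule.spectrum(pmma)
        skey = SpectrumKey(anode=anode, filter=filt, kvp=kvp)
        mas = _quantize(mas, 3)
        kerma = _quantize(tube_output.entrance_kerma(skey, mas, pmma), 6)
        return Acquisition(
            sub_kind=sub_kind,
            anode=anode,
            filter=filt,
            kvp=kvp,
            mas=mas,
            pmma_mm=pmma,
            plan_key=(entry.system.name, entry.modality, entry.aec_mode,
                      pmma, entry.repeat_index),
            projection_angle_deg=angle,
            entrance_kerma_mgy=kerma,
            pixel_pitch_um=entry.system.effective_pixel_pitch_um(entry.modality),
        )

    if entry.modality == "DM":
        mas = rule.mas(pmma) * jitter.draw(rng)
        return [build(rule, "DM", 0.0, mas)]
    if entry.modality == "DBT":
        total = rule.mas(pmma) * jitter.draw(rng)
        angles = entry.system.dbt_projection_angles()
        per = total / len(angles)
        return [build(rule, "DBT_PROJECTION", a, per) for a in angles]
    if entry.modality == "CEM":
        le_rule, he_rule = rule
        le = build(le_rule, "CEM_LE", 0.0, le_rule.mas(pmma) * jitter.draw(rng))
        he = build(he_rule, "CEM_HE", 0.0, he_rule.mas(pmma) * jitter.draw(rng))
        return [le, he]
    raise ValueError(f"unknown modality {entry.modality!r}")


# --------------------------------------------------------------------------
# Image rendering

@dataclass(frozen=True)
class RenderModel:
    """Flat-field renderer targeting only the statistics the pipeline
    measures (no scatter, MTF or heel effect).

    Background = gain * kerma-at-detector, with the detector kerma obtained
    from the entrance kerma through an effective exponential PMMA
    attenuation; noise is stationary Gaussian with quantum scaling
    sigma = sqrt(background * noise_const); the insert sits at
    background * (1 - contrast) with contrast falling off as (26/kVp)^2.
    The photoconductor (a-Se) units carry a larger noise constant than the
    scintillator (CsI) unit, and 2x2 DBT binning divides it by 4.
    """

    detector_size_mm: tuple[float, float] = (90.0, 60.0)
    gain_dn_per_mgy: float = 15000.0
    mu_ref_per_mm: float = 0.08  # effective PMMA attenuation at 28 kVp
    mu_kvp_exponent: float = 1.5
    contrast_ref: float = 0.08  # Al-square contrast at 26 kVp
    noise_const: Mapping[str, float] = field(
        default_factory=lambda: {"scintillator": 0.033, "photoconductor": 0.33}
    )

    def mu(self, kvp: float) -> float:
        return self.mu_ref_per_mm * (28.0 / kvp) ** self.mu_kvp_exponent

    def contrast(self, kvp: float) -> float:
        return self.contrast_ref * (26.0 / kvp) ** 2

    def background(self, acq: Acquisition) -> float:
        if acq.entrance_kerma_mgy is None:
            raise ValueError("acquisition lacks entrance kerma; cannot render")
        det_kerma = acq.entrance_kerma_mgy * math.exp(-self.mu(acq.kvp) * acq.pmma_mm)
        return self.gain_dn_per_mgy * det_kerma

    def noise_sd(self, background: float, system: SystemModel, binned: bool) -> float:
        k = self.noise_const[system.detector_kind]
        if binned:
            k /= 4.0
        return math.sqrt(background * k)


@dataclass(frozen=True)
class RenderResult:
    image: np.ndarray  # uint16
    planted_cnr: float
    background: float
    noise_sd: float
    contrast: float


def render_image(
    acq: Acquisition,
    phantom: PhantomSpec,
    system: SystemModel,
    model: RenderModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> RenderResult:
    """Render one flat phantom image with the planted Al square.

    Deterministic under a fixed seed.  ``planted_cnr`` is the ground-truth
    contrast-to-noise of the emitted integer image,
    background * contrast / sqrt(sigma^2 + 1/12), the 1/12 term being the
    variance added by rounding to integers.
    """
    model = model or RenderModel()
    pitch_mm = acq.pixel_pitch_um / 1000.0
    n_rows = int(round(model.detector_size_mm[0] / pitch_mm))
    n_cols = int(round(model.detector_size_mm[1] / pitch_mm))

    depth_mm, lateral_mm = phantom.insert_offset_mm
    half = phantom.insert_side_mm / 2.0
    r0 = depth_mm - half
    r1 = depth_mm + half
    if r0 < 0 or r1 * 1.0 > model.detector_size_mm[0] or (
        abs(lateral_mm) + half > model.detector_size_mm[1] / 2.0
    ):
        raise ValueError("insert footprint outside detector area")

    bg = model.background(acq)
    binned = system.dbt_binning and acq.sub_kind == "DBT_PROJECTION"
    sigma = model.noise_sd(bg, system, binned)
    contrast = model.contrast(acq.kvp)

    rng = np.random.default_rng(seed)
    img = np.full((n_rows, n_cols), bg, dtype=np.float64)
    ri0 = int(round(r0 / pitch_mm))
    ri1 = int(round(r1 / pitch_mm))
    ci0 = int(round(n_cols / 2.0 + (lateral_mm - half) / pitch_mm))
    ci1 = int(round(n_cols / 2.0 + (lateral_mm + half) / pitch_mm))
    img[ri0:ri1, ci0:ci1] *= 1.0 - contrast
    if sigma > 0:
        img += rng.normal(0.0, sigma, size=img.shape)
    image = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    sigma_eff = math.sqrt(sigma**2 + 1.0 / 12.0)
    return RenderResult(
        image=image,
        planted_cnr=bg * contrast / sigma_eff,
        background=bg,
        noise_sd=sigma,
        contrast=contrast,
    )


# --------------------------------------------------------------------------
# Whole-study generation

@dataclass
class StudyConfig:
    """Configuration of a synthetic acquisition campaign.

    Defaults reproduce the study design: three systems, the 20-70 mm PMMA
    ladder in 5-mm steps, triplicate acquisitions (363 studies in total).
    """

    systems: Sequence[SystemModel] = DEFAULT_SYSTEMS
    thicknesses: Sequence[float] = THICKNESSES_MM
    repeats: int = 3
    modalities: Sequence[str] | None = None
    seed: int = 0
    jitter: JitterModel = field(default_factory=JitterModel)
    render: RenderModel = field(default_factory=RenderModel)
    roi: RoiConfig = field(default_factory=RoiConfig)
    rules: Mapping | None = None
    tube_output: TubeOutputModel | None = None
    measure_images: bool = True  # render + measure CNR on measurable exposures


def _measurable(acq: Acquisition) -> bool:
    # IQ is measured on DM images, the 0-degree DBT projection, and CEM LE/HE
    if acq.sub_kind == "DBT_PROJECTION":
        return acq.projection_angle_deg == 0.0
    return True


def generate_study(config: StudyConfig | None = None):
    """Generate a complete synthetic study as a StudyTable.

    Realizes the full acquisition plan; each entry's exposures, kerma and
    (optionally) ROI measurements are appended as long-format rows.  Fully
    deterministic for a fixed ``config.seed``.
    """
    from .aec_stats import StudyTable

    config = config or StudyConfig()
    rules = config.rules if config.rules is not None else default_rules()
    tube_output = config.tube_output or default_tube_output()
    plan = enumerate_plan(
        systems=config.systems,
        thicknesses=config.thicknesses,
        repeats=config.repeats,
        modalities=config.modalities,
    )
    rows: list[dict] = []
    for i, entry in enumerate(plan):
        acqs = simulate_aec(
            entry, rules=rules, jitter=config.jitter, tube_output=tube_output,
            seed=np.random.SeedSequence((config.seed, i, 0)),
        )
        for j, acq in enumerate(acqs):
            row = acquisition_to_row(acq)
            if config.measure_images and _measurable(acq):
                res = render_image(
                    acq, entry.phantom, entry.system, model=config.render,
                    seed=np.random.SeedSequence((config.seed, i, 1 + j)),
                )
                geom = place_rois(res.image, entry.phantom, acq.pixel_pitch_um,
                                  config=config.roi)
                stats = measure_rois(res.image, geom)
                row.update(
                    mpv_al=stats.mpv_al,
                    mpv_pmma=stats.mpv_pmma,
                    sd_pmma=stats.sd_pmma,
                    cnr=compute_cnr(stats),
                    planted_cnr=res.planted_cnr,
                )
            rows.append(row)
    return StudyTable(pd.DataFrame(rows))


def write_study_dicom(
    config: StudyConfig,
    out_dir: str | Path,
) -> Path:
    """Write a synthetic study as a DICOM tree plus manifest.json.

    Every planned exposure (including all DBT projections) becomes one
    "for processing" file; intended for small configurations.
    """
    import json

    config = config or StudyConfig()
    rules = config.rules if config.rules is not None else default_rules()
    tube_output = config.tube_output or default_tube_output()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = enumerate_plan(
        systems=config.systems,
        thicknesses=config.thicknesses,
        repeats=config.repeats,
        modalities=config.modalities,
    )
    manifest: dict[str, dict] = {}
    for i, entry in enumerate(plan):
        acqs = simulate_aec(
            entry, rules=rules, jitter=config.jitter, tube_output=tube_output,
            seed=np.random.SeedSequence((config.seed, i, 0)),
        )
        for j, acq in enumerate(acqs):
            res = render_image(
                acq, entry.phantom, entry.system, model=config.render,
                seed=np.random.SeedSequence((config.seed, i, 1 + j)),
            )
            name = f"acq_{i:04d}_{j:02d}.dcm"
            write_synthetic_dicom(acq, res.image, out_dir / name)
            system, modality, mode, pmma, repeat = acq.plan_key
            manifest[name] = {
                "system": system, "modality": modality, "aec_mode": mode,
                "pmma_mm": pmma, "repeat": repeat, "sub_kind": acq.sub_kind,
                "angle_deg": acq.projection_angle_deg,
                "planted_cnr": res.planted_cnr,
            }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
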