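"""Mean glandular dose with the Dance model.

MGD = K * g * c * s (* t per tomosynthesis projection), where K is the
incident air kerma at the phantom entrance surface, g converts kerma to dose
for a 50%-glandular breast, c corrects for the actual glandularity of the
PMMA-equivalent breast, s corrects for the anode/filter spectrum, and t is
the per-projection tomosynthesis factor (1 for 2-D and CEM exposures).

The g/c/s/t tables, the PMMA-to-breast equivalence ladder and a default HVL
model ship as plain-text resources (``aecphantom/data``); all table lookups
are linear (bilinear on two-dimensional grids) and exact at grid nodes.
Coordinates outside a grid clamp to the edge and are flagged in provenance —
relevant for the Cu-filtered high-energy CEM spectra, whose HVLs lie beyond
the classic tabulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import PhantomSpec, SystemModel

__all__ = [
    "SpectrumKey",
    "HvlModel",
    "TubeOutputModel",
    "DanceFactors",
    "DoseResult",
    "ScanDose",
    "DanceTables",
    "load_tables",
    "lookup_hvl",
    "pmma_to_breast",
    "dance_factors",
    "compute_mgd",
    "scan_mgd",
    "cem_total_mgd",
    "apply_dosimetry",
]

log = logging.getLogger(__name__)

TABLE_VERSION = "aecphantom-dance-tables-1"

_warned_clamps: set[tuple] = set()


def _warn_once(key: tuple, message: str, *args) -> None:
    # provenance warnings repeat per exposure; emit once per unique coordinate
    if key not in _warned_clamps:
        _warned_clamps.add(key)
        log.warning(message, *args)


def _read_resource(name: str) -> pd.DataFrame:
    with resources.files("aecphantom.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class SpectrumKey:
    """Anode/filter/kVp triple identifying an x-ray spectrum."""

    anode: str
    filter: str
    kvp: float
    filter_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.kvp <= 0:
            raise ValueError("kvp must be positive")


class HvlModel:
    """HVL (mm Al) per anode/filter track, linearly interpolated in kVp."""

    def __init__(self, table: pd.DataFrame):
        required = {"anode", "filter", "kvp", "hvl_mm_al"}
        if not required.issubset(table.columns):
            raise ValueError(f"HVL table needs columns {sorted(required)}")
        self._tracks: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (anode, filt), grp in table.groupby(["anode", "filter"]):
            grp = grp.sort_values("kvp")
            kvps = grp["kvp"].to_numpy(float)
            hvls = grp["hvl_mm_al"].to_numpy(float)
            if np.any(hvls <= 0):
                raise ValueError(f"non-positive HVL for {anode}/{filt}")
            if np.any(np.diff(hvls) < 0):
                raise ValueError(f"HVL not monotone in kVp for {anode}/{filt}")
            self._tracks[(str(anode), str(filt))] = (kvps, hvls)

    @classmethod
    def default(cls) -> "HvlModel":
        return cls(_read_resource("hvl_defaults.csv"))

    def lookup(self, key: SpectrumKey) -> tuple[float, bool]:
        """Return (HVL, clamped?). Exact at grid nodes, linear between."""
        track = self._tracks.get((key.anode, key.filter))
        if track is None:
            raise KeyError(
                f"no HVL data for anode/filter {key.anode}/{key.filter}"
            )
        kvps, hvls = track
        clamped = bool(key.kvp < kvps[0] or key.kvp > kvps[-1])
        hvl = float(np.interp(key.kvp, kvps, hvls))
        return hvl, clamped


def lookup_hvl(key: SpectrumKey, model: HvlModel) -> float:
    """HVL for a spectrum; clamped edge values log a provenance warning."""
    hvl, clamped = model.lookup(key)
    if clamped:
        _warn_once(
            ("hvl", key.anode, key.filter, round(key.kvp, 1)),
            "HVL lookup clamped to grid edge for %s/%s @ %.1f kVp -> %.3f mm Al",
            key.anode, key.filter, key.kvp, hvl,
        )
    return hvl


@dataclass(frozen=True)
class TubeOutputModel:
    """Fallback entrance-kerma model K = Y0*(kVp/kvp_ref)^n * mAs * inv-square.

    Used only when an acquisition carries no DICOM-reported entrance dose.
    ``y0_mgy_per_mas`` is the specific output per anode/filter at the
    reference kVp, already referred to the reference distance.
    """

    y0_mgy_per_mas: dict[tuple[str, str], float]
    kvp_ref: float = 28.0
    kvp_exponent: float = 3.0
    source_detector_mm: float = 660.0
    reference_distance_mm: float = 660.0

    def entrance_kerma(self, key: SpectrumKey, mas: float, pmma_mm: float) -> float:
        y0 = self.y0_mgy_per_mas.get((key.anode, key.filter))
        if y0 is None:
            raise KeyError(
                f"no tube output for anode/filter {key.anode}/{key.filter}"
            )
        d_surface = self.source_detector_mm - pmma_mm
        inv_sq = (self.reference_distance_mm / d_surface) ** 2
        return y0 * (key.kvp / self.kvp_ref) ** self.kvp_exponent * mas * inv_sq


class _Grid2D:
    """Rectangular table with bilinear interpolation and edge clamping."""

    def __init__(self, rows: np.ndarray, cols: np.ndarray, values: np.ndarray):
        self.rows = np.asarray(rows, float)
        self.cols = np.asarray(cols, float)
        self.values = np.asarray(values, float)
        if self.values.shape != (self.rows.size, self.cols.size):
            raise ValueError("grid shape mismatch")

    def __call__(self, r: float, c: float) -> tuple[float, bool]:
        clamped = bool(
            r < self.rows[0] or r > self.rows[-1]
            or c < self.cols[0] or c > self.cols[-1]
        )
        r = float(np.clip(r, self.rows[0], self.rows[-1]))
        c = float(np.clip(c, self.cols[0], self.cols[-1]))
        i = int(np.clip(np.searchsorted(self.rows, r) - 1, 0, self.rows.size - 2))
        j = int(np.clip(np.searchsorted(self.cols, c) - 1, 0, self.cols.size - 2))
        r0, r1 = self.rows[i], self.rows[i + 1]
        c0, c1 = self.cols[j], self.cols[j + 1]
        fr = 0.0 if r1 == r0 else (r - r0) / (r1 - r0)
        fc = 0.0 if c1 == c0 else (c - c0) / (c1 - c0)
        v = self.values
        val = (
            v[i, j] * (1 - fr) * (1 - fc)
            + v[i + 1, j] * fr * (1 - fc)
            + v[i, j + 1] * (1 - fr) * fc
            + v[i + 1, j + 1] * fr * fc
        )
        return float(val), clamped


@dataclass
class DanceTables:
    """The embedded factor tables backing the dose model."""

    g: _Grid2D  # (equivalent breast mm, HVL mm Al)
    c: _Grid2D  # (glandularity fraction, HVL mm Al)
    s: dict[tuple[str, str], float]
    t_angles: np.ndarray
    t_values: np.ndarray
    equivalence: pd.DataFrame  # pmma_mm, breast_mm, glandularity
    version: str = TABLE_VERSION

    def t_factor(self, angle_deg: float) -> float:
        a = abs(float(angle_deg))
        if a > self.t_angles[-1]:
            raise ValueError(
                f"projection angle {angle_deg} deg outside t-table "
                f"(max {self.t_angles[-1]} deg)"
            )
        return float(np.interp(a, self.t_angles, self.t_values))


_TABLES: DanceTables | None = None


def load_tables() -> DanceTables:
    """Load (and cache) the embedded factor tables."""
    global _TABLES
    if _TABLES is not None:
        return _TABLES
    g_df = _read_resource("g_factors.csv")
    g = _Grid2D(
        g_df["breast_mm"].to_numpy(float),
        np.array([float(h) for h in g_df.columns[1:]]),
        g_df.iloc[:, 1:].to_numpy(float),
    )
    c_df = _read_resource("c_factors.csv")
    c = _Grid2D(
        c_df["glandularity"].to_numpy(float),
        np.array([float(h) for h in c_df.columns[1:]]),
        c_df.iloc[:, 1:].to_numpy(float),
    )
    s_df = _read_resource("s_factors.csv")
    s = {
        (row.anode, row.filter): float(row.s)
        for row in s_df.itertuples(index=False)
    }
    t_df = _read_resource("t_factors.csv")
    eq = _read_resource("pmma_equivalence.csv")
    _TABLES = DanceTables(
        g=g,
        c=c,
        s=s,
        t_angles=t_df["angle_deg"].to_numpy(float),
        t_values=t_df["t"].to_numpy(float),
        equivalence=eq,
    )
    return _TABLES


def pmma_to_breast(pmma_mm: float) -> tuple[float, float]:
    """Equivalent breast thickness (mm) and glandularity for a PMMA stack.

    Linear interpolation on the embedded equivalence ladder; the 70-mm stack
    maps to a 90-mm, 4%-glandular breast.
    """
    eq = load_tables().equivalence
    lo, hi = eq["pmma_mm"].iloc[0], eq["pmma_mm"].iloc[-1]
    if not (lo <= pmma_mm <= hi):
        raise ValueError(
            f"PMMA thickness {pmma_mm} mm outside equivalence range "
            f"[{lo}, {hi}] mm"
        )
    breast = float(np.interp(pmma_mm, eq["pmma_mm"], eq["breast_mm"]))
    gland = float(np.interp(pmma_mm, eq["pmma_mm"], eq["glandularity"]))
    return breast, gland


@dataclass(frozen=True)
class DanceFactors:
    g: float
    c: float
    s: float
    t: float
    hvl_used: float
    breast_mm: float
    glandularity: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if min(self.g, self.c, self.s) <= 0 or not (0 < self.t <= 1.0):
            raise ValueError("Dance factors out of physical range")

    @property
    def product(self) -> float:
        return self.g * self.c * self.s * self.t


def dance_factors(
    key: SpectrumKey,
    pmma_mm: float,
    hvl: float,
    projection_angle_deg: float = 0.0,
    is_tomo_projection: bool = False,
) -> DanceFactors:
    """Look up g, c, s and t for one exposure.

    g and c are bilinear in (HVL, equivalent breast thickness /
    glandularity); s is per anode/filter track; t is 1 for 2-D and CEM
    exposures and the angle-interpolated tomo factor for DBT projections.
    """
    tables = load_tables()
    breast_mm, gland = pmma_to_breast(pmma_mm)
    g, g_clamped = tables.g(breast_mm, hvl)
    c, c_clamped = tables.c(gland, hvl)
    s = tables.s.get((key.anode, key.filter))
    if s is None:
        raise KeyError(f"no s-factor for anode/filter {key.anode}/{key.filter}")
    t = tables.t_factor(projection_angle_deg) if is_tomo_projection else 1.0
    clamped = g_clamped or c_clamped
    if clamped:
        _warn_once(
            ("gc", round(hvl, 3), round(breast_mm, 1)),
            "Dance factor lookup clamped to table edge "
            "(HVL %.3f mm Al, breast %.1f mm)", hvl, breast_mm,
        )
    return DanceFactors(
        g=g, c=c, s=s, t=t,
        hvl_used=hvl, breast_mm=breast_mm, glandularity=gland,
        clamped=clamped,
    )


@dataclass(frozen=True)
class DoseResult:
    """MGD for one exposure plus the factors and provenance behind it."""

    mgd_mgy: float
    factors: DanceFactors
    entrance_kerma_mgy: float
    kerma_source: str  # "dicom" or "tube-output-model"
    table_version: str = TABLE_VERSION
    scan_key: tuple | None = None  # identifies the parent DBT scan / CEM series


def compute_mgd(
    acq,
    phantom: PhantomSpec,
    system: SystemModel | None = None,
    hvl_model: HvlModel | None = None,
    tube_output: TubeOutputModel | None = None,
) -> DoseResult:
    """MGD = K * g * c * s * t for one acquisition.

    Entrance kerma is taken from the acquisition metadata when present;
    otherwise it is reconstructed from the tube-output model (an error if
    neither is available).
    """
    if acq.kvp is None or acq.mas is None:
        raise ValueError("acquisition lacks kVp or mAs; cannot compute MGD")
    key = SpectrumKey(anode=acq.anode, filter=acq.filter, kvp=acq.kvp)
    hvl_model = hvl_model or HvlModel.default()
    hvl = lookup_hvl(key, hvl_model)
    is_tomo = acq.sub_kind == "DBT_PROJECTION"
    factors = dance_factors(
        key,
        phantom.pmma_thickness_mm,
        hvl,
        projection_angle_deg=acq.projection_angle_deg,
        is_tomo_projection=is_tomo,
    )
    if acq.entrance_kerma_mgy is not None:
        kerma = acq.entrance_kerma_mgy
        source = "dicom"
    elif tube_output is not None:
        kerma = tube_output.entrance_kerma(key, acq.mas, phantom.pmma_thickness_mm)
        source = "tube-output-model"
    else:
        raise ValueError(
            "no entrance kerma in metadata and no tube-output model configured"
        )
    if kerma < 0:
        raise ValueError("entrance kerma must be non-negative")
    return DoseResult(
        mgd_mgy=kerma * factors.product,
        factors=factors,
        entrance_kerma_mgy=kerma,
        kerma_source=source,
        scan_key=getattr(acq, "scan_key", None),
    )


@dataclass(frozen=True)
class ScanDose:
    """Cumulative dose of one DBT scan."""

    total_mgy: float
    per_projection_mgy: float
    n_projections: int


def scan_mgd(projections: Sequence[DoseResult]) -> ScanDose:
    """Total MGD of a DBT scan (sum over projections) and the per-projection
    value total/n used as the FOM dose basis."""
    if not projections:
        raise ValueError("empty projection list")
    keys = {p.scan_key for p in projections}
    if len(keys) > 1:
        raise ValueError(f"projections from multiple scans: {sorted(map(str, keys))}")
    total = float(sum(p.mgd_mgy for p in projections))
    n = len(projections)
    return ScanDose(total_mgy=total, per_projection_mgy=total / n, n_projections=n)


def cem_total_mgd(le: DoseResult, he: DoseResult) -> float:
    """Total CEM MGD: sum of the low- and high-energy image MGDs."""
    if le.scan_key is not None and he.scan_key is not None:
        if le.scan_key != he.scan_key:
            raise ValueError(
                f"LE/HE from different series: {le.scan_key} vs {he.scan_key}"
            )
    return le.mgd_mgy + he.mgd_mgy


def apply_dosimetry(
    table,
    hvl_model: HvlModel | None = None,
    tube_output: TubeOutputModel | None = None,
) -> None:
    """Append dose columns (mgd_mgy, g, c, s, t, hvl_mm_al, breast_equiv_mm,
    glandularity, kerma_source) to a StudyTable in place."""
    hvl_model = hvl_model or HvlModel.default()
    df = table.df
    cols: dict[str, list] = {k: [] for k in (
        "mgd_mgy", "g", "c", "s", "t", "hvl_mm_al",
        "breast_equiv_mm", "glandularity", "kerma_source",
    )}
    for row in df.itertuples(index=False):
        acq = _RowAcq(row)
        phantom = PhantomSpec(pmma_thickness_mm=float(row.pmma_mm))
        res = compute_mgd(acq, phantom, hvl_model=hvl_model, tube_output=tube_output)
        cols["mgd_mgy"].append(res.mgd_mgy)
        cols["g"].append(res.factors.g)
        cols["c"].append(res.factors.c)
        cols["s"].append(res.factors.s)
        cols["t"].append(res.factors.t)
        cols["hvl_mm_al"].append(res.factors.hvl_used)
        cols["breast_equiv_mm"].append(res.factors.breast_mm)
        cols["glandularity"].append(res.factors.glandularity)
        cols["kerma_source"].append(res.kerma_source)
    for name, values in cols.items():
        df[name] = values


class _RowAcq:
    """Adapter presenting a StudyTable row with the Acquisition interface."""

    def __init__(self, row):
        self.anode = row.anode
        self.filter = row.filter
        self.kvp = float(row.kvp)
        self.mas = float(row.mas)
        self.sub_kind = row.sub_kind
        self.projection_angle_deg = float(getattr(row, "angle_deg", 0.0) or 0.0)
        kerma = getattr(row, "entrance_kerma_mgy", None)
        self.entrance_kerma_mgy = None if kerma is None or pd.isna(kerma) else float(kerma)
        self.scan_key = None
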