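"""Study-level statistics: AEC repeatability, pooled medians/IQRs,
per-thickness curves and intermodality dose/CNR ratios.

All operations consume a :class:`StudyTable` — a long-format table with one
row per exposure (DM image, DBT projection, CEM LE or HE image).  They first
reduce it to *study level*: one row per acquired study and energy, where DBT
exposure and MGD become the per-scan cumulative totals, the DBT CNR/FOM
refer to the 0-degree projection (FOM on the per-projection dose basis), and
CEM keeps LE and HE rows separate with the series total MGD alongside.

Repeatability follows the maximum-half-dispersion convention for small
repeat series: error = (max - min)/2 over the triplicate, and the relative
error divides that by the triplicate mean.  Pooled summaries use medians and
quartiles (linear interpolation between order statistics, the "type 7"
rule), since none of these quantities is normally distributed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StudyTable",
    "study_level",
    "repeatability",
    "repeatability_maxima",
    "modality_summaries",
    "thickness_curves",
    "intermodality_ratios",
]

log = logging.getLogger(__name__)

#: columns every StudyTable must carry (dose/IQ columns are appended later)
REQUIRED_COLUMNS = (
    "system", "modality", "aec_mode", "pmma_mm", "repeat", "sub_kind",
    "angle_deg", "anode", "filter", "kvp", "mas",
)

CELL_KEY = ["system", "modality", "aec_mode", "pmma_mm"]

#: parameters tracked in repeatability and summary outputs
PARAMETERS = ("kvp", "mas", "mgd", "cnr")


class StudyTable:
    """Long-format collection of per-exposure records.

    One row per exposure event; DBT scans contribute one row per projection
    and CEM series one row per energy.  Indexable by the study cell
    (system, modality, aec_mode, pmma_mm).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"StudyTable missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.unmatched: list[str] = []

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def has_dose(self) -> bool:
        return "mgd_mgy" in self.df.columns

    @property
    def has_iq(self) -> bool:
        return "cnr" in self.df.columns and bool(self.df["cnr"].notna().any())

    def n_studies(self) -> int:
        """Number of acquired studies (plan entries): one per cell repeat."""
        return len(self.df.groupby(CELL_KEY + ["repeat"]))

    def check_complete(self, expected_repeats: int = 3) -> None:
        counts = self.df.groupby(CELL_KEY)["repeat"].nunique()
        bad = counts[counts != expected_repeats]
        if not bad.empty:
            raise ValueError(
                f"{len(bad)} cell(s) without exactly {expected_repeats} "
                f"repeats, e.g. {bad.index[0]}"
            )


def study_level(table: StudyTable) -> pd.DataFrame:
    """Reduce per-exposure rows to one row per study (and CEM energy).

    Output columns: system, sub_label (DM | DBT | CEM_LE | CEM_HE),
    aec_mode, pmma_mm, repeat, kvp, mas, mgd, cnr, fom, mgd_basis,
    cem_total_mgd.  DBT mas/mgd are scan totals; mgd_basis is the full MGD
    for DM/CEM rows and the per-projection MGD for DBT.
    """
    df = table.df
    have_dose = table.has_dose
    have_iq = "cnr" in df.columns
    rows: list[dict] = []

    for (system, modality, mode, pmma, repeat), grp in df.groupby(
        CELL_KEY + ["repeat"], sort=True
    ):
        if modality == "DBT":
            central = grp[np.isclose(grp["angle_deg"].astype(float), 0.0)]
            kvp = float(grp["kvp"].iloc[0])
            mas_total = float(grp["mas"].sum())
            mgd_total = float(grp["mgd_mgy"].sum()) if have_dose else np.nan
            n_proj = len(grp)
            per_proj = mgd_total / n_proj if have_dose else np.nan
            cnr = (
                float(central["cnr"].iloc[0])
                if have_iq and len(central) and pd.notna(central["cnr"].iloc[0])
                else np.nan
            )
            fom = cnr * cnr / per_proj if np.isfinite(cnr) and per_proj > 0 else np.nan
            rows.append(dict(
                system=system, sub_label="DBT", aec_mode=mode, pmma_mm=pmma,
                repeat=repeat, kvp=kvp, mas=mas_total, mgd=mgd_total,
                cnr=cnr, fom=fom, mgd_basis=per_proj, cem_total_mgd=np.nan,
                n_projections=n_proj,
            ))
        elif modality == "CEM":
            le = grp[grp["sub_kind"] == "CEM_LE"]
            he = grp[grp["sub_kind"] == "CEM_HE"]
            if len(le) != 1 or len(he) != 1:
                raise ValueError(
                    f"CEM series {(system, mode, pmma, repeat)} must have one "
                    f"LE and one HE image, got {len(le)}/{len(he)}"
                )
            mgd_le = float(le["mgd_mgy"].iloc[0]) if have_dose else np.nan
            mgd_he = float(he["mgd_mgy"].iloc[0]) if have_dose else np.nan
            total = mgd_le + mgd_he
            for sub_label, part, mgd in (
                ("CEM_LE", le, mgd_le), ("CEM_HE", he, mgd_he)
            ):
                cnr = (
                    float(part["cnr"].iloc[0])
                    if have_iq and pd.notna(part["cnr"].iloc[0])
                    else np.nan
                )
                fom = cnr * cnr / mgd if np.isfinite(cnr) and mgd > 0 else np.nan
                rows.append(dict(
                    system=system, sub_label=sub_label, aec_mode=mode,
                    pmma_mm=pmma, repeat=repeat,
                    kvp=float(part["kvp"].iloc[0]),
                    mas=float(part["mas"].iloc[0]),
                    mgd=mgd, cnr=cnr, fom=fom, mgd_basis=mgd,
                    cem_total_mgd=total, n_projections=1,
                ))
        else:  # DM
            if len(grp) != 1:
                raise ValueError(
                    f"DM cell repeat {(system, mode, pmma, repeat)} has "
                    f"{len(grp)} rows, expected 1"
                )
            row = grp.iloc[0]
            mgd = float(row["mgd_mgy"]) if have_dose else np.nan
            cnr = float(row["cnr"]) if have_iq and pd.notna(row["cnr"]) else np.nan
            fom = cnr * cnr / mgd if np.isfinite(cnr) and mgd > 0 else np.nan
            rows.append(dict(
                system=system, sub_label="DM", aec_mode=mode, pmma_mm=pmma,
                repeat=repeat, kvp=float(row["kvp"]), mas=float(row["mas"]),
                mgd=mgd, cnr=cnr, fom=fom, mgd_basis=mgd,
                cem_total_mgd=np.nan, n_projections=1,
            ))
    return pd.DataFrame(rows)


_GROUP = ["system", "sub_label", "aec_mode", "pmma_mm"]


def repeatability(
    table: StudyTable, parameters: tuple[str, ...] = PARAMETERS
) -> pd.DataFrame:
    """Per-cell repeatability: mean, maximum half-dispersion (max-min)/2 over
    repeats, and their ratio as the relative error.

    Cells with fewer than two repeats raise; a zero mean with nonzero
    dispersion is flagged undefined and excluded from maxima.
    """
    sl = study_level(table)
    rows = []
    for key, grp in sl.groupby(_GROUP, sort=True):
        for param in parameters:
            vals = grp[param].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            if vals.size < 2:
                raise ValueError(
                    f"cell {key}: parameter {param!r} has <2 repeats"
                )
            mean = float(vals.mean())
            half = float((vals.max() - vals.min()) / 2.0)
            undefined = mean == 0.0 and half > 0.0
            rel = np.nan if undefined else (0.0 if half == 0 else half / mean)
            rows.append(dict(
                zip(_GROUP, key),
                parameter=param, mean=mean, half_dispersion=half,
                relative_error=rel, undefined=undefined,
            ))
    return pd.DataFrame(rows)


def repeatability_maxima(table: StudyTable) -> pd.DataFrame:
    """Highest relative error per (system, modality, mode, parameter) across
    the phantom-thickness range — the per-mode repeatability summary."""
    rep = repeatability(table)
    rep = rep[~rep["undefined"]]
    out = (
        rep.groupby(["system", "sub_label", "aec_mode", "parameter"])  # noqa: PD010
        ["relative_error"].max().reset_index()
        .rename(columns={"relative_error": "max_relative_error"})
    )
    return out


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics ("type 7")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def modality_summaries(table: StudyTable) -> pd.DataFrame:
    """Pooled median and IQR per modality and parameter, over all systems,
    AEC modes and thicknesses; CEM summarized separately for LE and HE, DBT
    exposure/MGD as scan totals and CNR/FOM on the 0-degree basis."""
    sl = study_level(table)
    rows = []
    for sub_label, grp in sl.groupby("sub_label", sort=True):
        for param in ("kvp", "mas", "mgd", "cnr", "fom"):
            vals = grp[param].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                log.warning("empty group %s/%s omitted from summaries",
                            sub_label, param)
                continue
            q1, med, q3 = _quartiles(vals)
            rows.append(dict(
                modality=sub_label, parameter=param,
                median=med, q1=q1, q3=q3, n=int(vals.size),
            ))
    return pd.DataFrame(rows)


def thickness_curves(
    table: StudyTable, parameters: tuple[str, ...] = ("kvp", "mas", "mgd", "cnr", "fom")
) -> pd.DataFrame:
    """Mean and half-dispersion of each parameter vs PMMA thickness, one
    series per (system, modality, AEC mode); DBT uses scan totals."""
    sl = study_level(table)
    rows = []
    for key, grp in sl.groupby(_GROUP, sort=True):
        for param in parameters:
            vals = grp[param].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append(dict(
                zip(_GROUP, key),
                parameter=param,
                mean=float(vals.mean()),
                half_dispersion=float((vals.max() - vals.min()) / 2.0),
            ))
    return pd.DataFrame(rows)


#: AEC mode used as reference/numerator per system when several exist
REFERENCE_MODE = {"GE Pristina": "AOP/STD"}


def _cell_means(sl: pd.DataFrame, sub_label: str, system: str, mode: str) -> pd.DataFrame:
    sel = sl[
        (sl["sub_label"] == sub_label)
        & (sl["system"] == system)
        & (sl["aec_mode"] == mode)
    ]
    return sel.groupby("pmma_mm")[["mgd", "cnr", "cem_total_mgd"]].mean()


def intermodality_ratios(table: StudyTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-thickness DBT/DM and CEM/DM dose and CNR ratios and their means.

    Ratios divide the cell-mean MGD (scan total for DBT, LE+HE total for
    CEM) and CNR of each modality by the DM values at the same thickness on
    the same system; on the GE unit the AOP/STD mode is the reference in
    both numerator and denominator.  A missing DM reference raises, naming
    the cell; ratios with a missing numerator cell are omitted and logged.
    """
    sl = study_level(table)
    records: list[dict] = []
    for system in sorted(sl["system"].unique()):
        modes_dm = sl.loc[
            (sl["system"] == system) & (sl["sub_label"] == "DM"), "aec_mode"
        ].unique()
        if len(modes_dm) == 0:
            raise ValueError(f"no DM reference data for system {system!r}")
        ref_mode = REFERENCE_MODE.get(system, modes_dm[0])
        dm = _cell_means(sl, "DM", system, ref_mode)
        if dm.empty:
            raise ValueError(
                f"missing DM reference cell: system={system!r} mode={ref_mode!r}"
            )

        sys_sl = sl[sl["system"] == system]
        # DBT vs DM
        dbt_modes = sys_sl.loc[sys_sl["sub_label"] == "DBT", "aec_mode"].unique()
        if len(dbt_modes):
            dbt_mode = REFERENCE_MODE.get(system, dbt_modes[0])
            dbt = _cell_means(sl, "DBT", system, dbt_mode)
            for pmma, row in dbt.iterrows():
                if pmma not in dm.index:
                    raise ValueError(
                        f"missing DM reference cell: system={system!r} "
                        f"mode={ref_mode!r} pmma={pmma}"
                    )
                ref = dm.loc[pmma]
                records.append(dict(
                    comparison="DBT_vs_DM", quantity="MGD", system=system,
                    pmma_mm=pmma, ratio=row["mgd"] / ref["mgd"],
                ))
                if np.isfinite(row["cnr"]) and np.isfinite(ref["cnr"]):
                    records.append(dict(
                        comparison="DBT_vs_DM", quantity="CNR", system=system,
                        pmma_mm=pmma, ratio=row["cnr"] / ref["cnr"],
                    ))
        # CEM vs DM
        for energy, quantity in (("CEM_LE", "CNR_LE"), ("CEM_HE", "CNR_HE")):
            cem_modes = sys_sl.loc[
                sys_sl["sub_label"] == energy, "aec_mode"
            ].unique()
            if not len(cem_modes):
                continue
            cem = _cell_means(sl, energy, system, cem_modes[0])
            for pmma, row in cem.iterrows():
                if pmma not in dm.index:
                    raise ValueError(
                        f"missing DM reference cell: system={system!r} "
                        f"mode={ref_mode!r} pmma={pmma}"
                    )
                ref = dm.loc[pmma]
                if energy == "CEM_LE":  # total MGD carried once per series
                    records.append(dict(
                        comparison="CEM_vs_DM", quantity="MGD", system=system,
                        pmma_mm=pmma, ratio=row["cem_total_mgd"] / ref["mgd"],
                    ))
                if np.isfinite(row["cnr"]) and np.isfinite(ref["cnr"]):
                    records.append(dict(
                        comparison="CEM_vs_DM", quantity=quantity,
                        system=system, pmma_mm=pmma,
                        ratio=row["cnr"] / ref["cnr"],
                    ))
    ratios = pd.DataFrame(records)
    if ratios.empty:
        return ratios, ratios
    bad = ratios[~np.isfinite(ratios["ratio"])]
    if not bad.empty:
        log.warning("%d ratio(s) undefined and omitted", len(bad))
        ratios = ratios[np.isfinite(ratios["ratio"])]
    means = (
        ratios.groupby(["comparison", "quantity", "system"])  # noqa: PD010
        ["ratio"].mean().reset_index()
        .rename(columns={"ratio": "mean_ratio"})
    )
    return ratios.reset_index(drop=True), means
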