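"""CSV readers/writers and dataset validation.

Interchange formats (comma-separated, UTF-8, ISO-8601 dates, decimal point):

* ``profiles.csv`` — date, depth_m, then any of the analyte columns
  (temp_c, o2_mg_l, tp_ug_l, chla_ug_l, so4_mmol_l, no3_mmol_l, nh4_ug_l)
* ``hypsography.csv`` — depth_m, area_m2
* ``withdrawal.csv`` — date, outflow_l_s, tp_ug_l
* ``inflow.csv`` — date, tp_ug_l
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ANALYTES,
    DepthProfile,
    Hypsography,
    InflowRecord,
    LakeDataset,
    SchemaError,
    ValidationError,
    WithdrawalRecord,
)


def _read_csv(path, mandatory: tuple[str, ...]) -> pd.DataFrame:
    # round_trip parsing keeps write->read exact to the last ulp
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def read_profiles(path, analytes: tuple[str, ...] = ANALYTES) -> list[DepthProfile]:
    """Read a long-format profile table into one DepthProfile per date.

    Rows whose date or depth cannot be parsed are reported via a warning
    (never silently dropped); duplicated (date, depth) pairs raise.
    """
    df = _read_csv(path, ("date", "depth_m"))
    present = [c for c in analytes if c in df.columns]
    if not present:
        raise SchemaError(f"{path}: no analyte column found (expected one of {analytes})")

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    depths = pd.to_numeric(df["depth_m"], errors="coerce")
    bad = dates.isna() | depths.isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
        warnings.warn(
            f"{path}: {int(bad.sum())} unparseable row(s) skipped (file line(s) {rows})",
            stacklevel=2,
        )
        df, dates, depths = df[~bad], dates[~bad], depths[~bad]

    dup = pd.DataFrame({"d": dates.dt.date, "z": depths}).duplicated(keep=False)
    if dup.any():
        pair = f"({dates.dt.date[dup].iloc[0].isoformat()}, {float(depths[dup].iloc[0])} m)"
        raise ValidationError(f"{path}: duplicated (date, depth) pair {pair}")

    profiles = []
    order = np.lexsort((depths.to_numpy(), dates.to_numpy()))
    df = df.iloc[order]
    for date, grp in df.groupby(dates.iloc[order].dt.date, sort=True):
        z = pd.to_numeric(grp["depth_m"]).to_numpy(dtype=float)
        vals = {
            c: pd.to_numeric(grp[c], errors="coerce").to_numpy(dtype=float)
            for c in present
        }
        profiles.append(DepthProfile(date=date, depths=z, values=vals))
    return profiles


def read_hypsography(path) -> Hypsography:
    df = _read_csv(path, ("depth_m", "area_m2"))
    df = df.sort_values("depth_m")
    try:
        return Hypsography(df["depth_m"].to_numpy(float), df["area_m2"].to_numpy(float))
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from err


def read_withdrawal(path) -> list[WithdrawalRecord]:
    df = _read_csv(path, ("date", "outflow_l_s", "tp_ug_l"))
    dates = pd.to_datetime(df["date"], format="ISO8601")
    return [
        WithdrawalRecord(d.date(), float(q), float(tp))
        for d, q, tp in zip(dates, df["outflow_l_s"], df["tp_ug_l"])
    ]


def read_inflow(path) -> list[InflowRecord]:
    df = _read_csv(path, ("date", "tp_ug_l"))
    dates = pd.to_datetime(df["date"], format="ISO8601")
    return [InflowRecord(d.date(), float(tp)) for d, tp in zip(dates, df["tp_ug_l"])]


def read_dataset(
    profiles_path, hypsography_path, withdrawal_path=None, inflow_path=None, metadata=None
) -> LakeDataset:
    return LakeDataset(
        profiles=read_profiles(profiles_path),
        hypsography=read_hypsography(hypsography_path),
        withdrawal=read_withdrawal(withdrawal_path) if withdrawal_path else [],
        inflow=read_inflow(inflow_path) if inflow_path else [],
        metadata=metadata or {},
    )


# ---------------------------------------------------------------- writers

def write_profiles(profiles: list[DepthProfile], path) -> None:
    rows = []
    for p in profiles:
        for i, z in enumerate(p.depths):
            row = {"date": p.date.isoformat(), "depth_m": z}
            for name in ANALYTES:
                if name in p.values:
                    row[name] = p.values[name][i]
            rows.append(row)
    # %.17g guarantees float64 round-trips to full precision
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_hypsography(hyp: Hypsography, path) -> None:
    pd.DataFrame({"depth_m": hyp.depths, "area_m2": hyp.areas}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_withdrawal(records: list[WithdrawalRecord], path) -> None:
    pd.DataFrame(
        [
            {"date": r.date.isoformat(), "outflow_l_s": r.outflow_l_s, "tp_ug_l": r.tp_ug_l}
            for r in records
        ]
    ).to_csv(path, index=False, float_format="%.17g")


def write_inflow(records: list[InflowRecord], path) -> None:
    pd.DataFrame(
        [{"date": r.date.isoformat(), "tp_ug_l": r.tp_ug_l} for r in records]
    ).to_csv(path, index=False, float_format="%.17g")


def write_dataset(dataset: LakeDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_profiles(dataset.profiles, outdir / "profiles.csv")
    write_hypsography(dataset.hypsography, outdir / "hypsography.csv")
    write_withdrawal(dataset.withdrawal, outdir / "withdrawal.csv")
    write_inflow(dataset.inflow, outdir / "inflow.csv")


# ------------------------------------------------------------- validation

@dataclass
class ValidationReport:
    """Structural issues plus per-analyte temporal coverage."""

    issues: list[str] = field(default_factory=list)
    coverage: pd.DataFrame | None = None  # analyte x year, n non-missing values
    gap_years: dict[str, list[int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(dataset: LakeDataset) -> ValidationReport:
    """Check invariants and summarise which analytes cover which years.

    A gap year for an analyte is a year with no non-missing value that
    lies strictly between the analyte's first and last observed years
    (emulating a data-availability table with gaps).
    """
    report = ValidationReport()
    zmax = dataset.hypsography.max_depth
    for p in dataset.profiles:
        if p.depths[-1] > zmax + 1e-9:
            report.issues.append(
                f"{p.date}: profile depth {p.depths[-1]} m exceeds z_max {zmax} m"
            )
        if not p.has("temp_c"):
            report.issues.append(f"{p.date}: no temperature values")

    years = dataset.years
    cov = pd.DataFrame(0, index=list(ANALYTES), columns=years, dtype=int)
    for p in dataset.profiles:
        for name in ANALYTES:
            if name in p.values:
                cov.loc[name, p.date.year] += int(np.isfinite(p.values[name]).sum())
    report.coverage = cov
    for name in ANALYTES:
        present = [y for y in years if cov.loc[name, y] > 0]
        if len(present) >= 2:
            lo, hi = present[0], present[-1]
            report.gap_years[name] = [
                y for y in range(lo + 1, hi) if y in cov.columns and cov.loc[name, y] == 0
            ]
        else:
            report.gap_years[name] = []
    return report
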