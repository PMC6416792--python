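"""CSV readers/writers and the end-to-end pipeline.

Input dialects (all plain CSV with a header row):

* specimen metadata: ``leaf_id,species,saturated_weight_g,dry_weight_g,projected_area_total_m2``
* balance log (one file per leaf): ``time_s,fresh_weight_g,leaf_temp_C,air_temp_C``
  (``leaf_temp_C`` may be empty or absent)
* g_min table: ``species,t_air_C,g_min_m_per_s`` (one row per leaf)
* wax table: ``compound,compound_class,chain_length,coverage_ug_cm2[,molar_mass_g_mol]``
* cutin table: ``monomer,monomer_class,acid_chain_length,coverage_ug_cm2``
* FTIR long format: ``temperature_C,wavenumber_cm1,absorbance``

Validation errors name the offending column or row.  JSON reports are
written with sorted keys and ``repr`` floats, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .drying import (
    DryingObservation,
    GminResult,
    LeafSpecimen,
    conductance_series,
    fit_drying_curve,
    interval_driving_forces,
    morphology_traits,
    transpiration_series,
)
from .ftir import SpectrumFrame, melting_analysis
from .thermal import TemperatureSeries, arrhenius_points, fit_biphasic
from .waxes import (
    CutinMonomer,
    WaxComponent,
    class_coverage,
    cutin_summary,
    mcl,
    mole_fractions,
    split_chain_fractions,
)

__all__ = [
    "ValidationError",
    "read_specimens",
    "read_balance_log",
    "read_gmin_table",
    "read_wax_table",
    "read_cutin_table",
    "read_ftir_long",
    "write_ftir_long",
    "write_json_report",
    "analyze_drying_run",
    "run_pipeline",
]


class ValidationError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[converted.isna() & df[c].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value(s) in column {c!r}, "
                f"row(s) {[int(i) + 2 for i in bad]} (1-based incl. header)"
            )
        df[c] = converted
    return df


def read_specimens(path) -> dict:
    """Specimen metadata CSV -> {leaf_id: LeafSpecimen}."""
    df = pd.read_csv(path)
    cols = ["leaf_id", "species", "saturated_weight_g", "dry_weight_g",
            "projected_area_total_m2"]
    _require_columns(df, cols, path)
    _numeric(df, cols[2:], path)
    dup = df["leaf_id"][df["leaf_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate leaf id(s) {sorted(set(dup))}")
    out = {}
    for _, row in df.iterrows():
        try:
            out[str(row["leaf_id"])] = LeafSpecimen(
                species=str(row["species"]),
                saturated_weight=float(row["saturated_weight_g"]),
                dry_weight=float(row["dry_weight_g"]),
                projected_area_total=float(row["projected_area_total_m2"]),
            )
        except ValueError as exc:
            raise ValidationError(
                f"{path}: leaf {row['leaf_id']!r}: {exc}"
            ) from exc
    return out


def read_balance_log(path, specimen: LeafSpecimen | None = None,
                     sigma: float | None = None) -> list[DryingObservation]:
    """Balance log CSV -> observations, with basic plausibility checks.

    With a specimen and a balance sigma (g), rows whose weight falls below
    the dry weight by more than 3 sigma are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "fresh_weight_g", "air_temp_C"], path)
    has_leaf_t = "leaf_temp_C" in df.columns
    num_cols = ["time_s", "fresh_weight_g", "air_temp_C"] + (
        ["leaf_temp_C"] if has_leaf_t else []
    )
    _numeric(df, num_cols, path)
    if specimen is not None and sigma is not None:
        floor = specimen.dry_weight - 3 * sigma
        bad = df.index[df["fresh_weight_g"] < floor]
        if len(bad):
            raise ValidationError(
                f"{path}: fresh weight below dry weight by >3 sigma in "
                f"row(s) {[int(i) + 2 for i in bad]}"
            )
    obs = []
    for _, row in df.iterrows():
        lt = row["leaf_temp_C"] if has_leaf_t else None
        obs.append(
            DryingObservation(
                time=float(row["time_s"]),
                fresh_weight=float(row["fresh_weight_g"]),
                air_temp=float(row["air_temp_C"]),
                leaf_temp=None if lt is None or pd.isna(lt) else float(lt),
            )
        )
    return obs


def read_gmin_table(path) -> list[TemperatureSeries]:
    """Per-leaf g_min CSV -> one TemperatureSeries per species."""
    df = pd.read_csv(path)
    _require_columns(df, ["species", "t_air_C", "g_min_m_per_s"], path)
    _numeric(df, ["t_air_C", "g_min_m_per_s"], path)
    out = []
    for sp, grp in df.groupby("species", sort=True):
        entries = tuple(
            (float(t), tuple(float(g) for g in sub["g_min_m_per_s"]))
            for t, sub in grp.groupby("t_air_C", sort=True)
        )
        out.append(TemperatureSeries(species=str(sp), entries=entries))
    return out


def read_wax_table(path) -> list[WaxComponent]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["compound", "compound_class", "chain_length", "coverage_ug_cm2"],
        path,
    )
    _numeric(df, ["chain_length", "coverage_ug_cm2"], path)
    has_mm = "molar_mass_g_mol" in df.columns
    if has_mm:
        _numeric(df, ["molar_mass_g_mol"], path)
    out = []
    for _, row in df.iterrows():
        mm = row["molar_mass_g_mol"] if has_mm else None
        try:
            out.append(
                WaxComponent(
                    name=str(row["compound"]),
                    compound_class=str(row["compound_class"]),
                    chain_length=int(row["chain_length"]),
                    coverage=float(row["coverage_ug_cm2"]),
                    molar_mass=None if mm is None or pd.isna(mm) else float(mm),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: {row['compound']!r}: {exc}") from exc
    return out


def read_cutin_table(path) -> list[CutinMonomer]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["monomer", "monomer_class", "acid_chain_length",
             "coverage_ug_cm2"], path,
    )
    _numeric(df, ["acid_chain_length", "coverage_ug_cm2"], path)
    out = []
    for _, row in df.iterrows():
        n = row["acid_chain_length"]
        out.append(
            CutinMonomer(
                name=str(row["monomer"]),
                monomer_class=str(row["monomer_class"]),
                acid_chain_length=None if pd.isna(n) else int(n),
                coverage=float(row["coverage_ug_cm2"]),
            )
        )
    return out


def read_ftir_long(path) -> list[SpectrumFrame]:
    """Long-format spectral CSV -> frames ordered by temperature."""
    df = pd.read_csv(path)
    _require_columns(df, ["temperature_C", "wavenumber_cm1", "absorbance"], path)
    _numeric(df, ["temperature_C", "wavenumber_cm1", "absorbance"], path)
    frames = []
    for t, grp in df.groupby("temperature_C", sort=True):
        frames.append(
            SpectrumFrame(
                temperature=float(t),
                wavenumbers=grp["wavenumber_cm1"].to_numpy(dtype=float),
                absorbance=grp["absorbance"].to_numpy(dtype=float),
            )
        )
    return frames


def write_ftir_long(frames: Sequence[SpectrumFrame], path) -> None:
    rows = [
        {"temperature_C": f.temperature, "wavenumber_cm1": float(nu),
         "absorbance": float(a)}
        for f in frames
        for nu, a in zip(f.wavenumbers, f.absorbance)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_json_report(report: dict, path) -> None:
    """Deterministic JSON: sorted keys, full-precision repr floats."""
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    )


def analyze_drying_run(
    specimen: LeafSpecimen,
    obs: Sequence[DryingObservation],
    a_apo: float = 1.0,
    a_air: float = 0.0,
    leaf_air_offset: float = 0.0,
    min_plateau: int = 3,
    median_filter: bool = False,
) -> GminResult:
    """Balance log -> GminResult (flux, conductance, two-segment fit)."""
    intervals = transpiration_series(obs, specimen)
    driving = interval_driving_forces(
        obs, a_apo=a_apo, a_air=a_air, leaf_air_offset=leaf_air_offset
    )
    points = conductance_series(intervals, driving, specimen)
    return fit_drying_curve(points, min_plateau=min_plateau,
                            median_filter=median_filter)


def run_pipeline(
    specimens_csv,
    balance_logs: dict,
    out_dir,
    wax_csv=None,
    cutin_csv=None,
    ftir_csv=None,
    a_apo: float = 1.0,
    a_air: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Full study pipeline: drying fits, per-species Arrhenius, optional
    wax and FTIR reports.  Writes ``report.json`` plus per-stage CSVs to
    ``out_dir`` and returns the report dict.

    ``balance_logs`` maps leaf_id -> balance-log CSV path; every id must
    exist in the specimen table.  Raises ValidationError with the stage and
    leaf id on any per-leaf failure; an empty input set raises with
    "nothing to do".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specimens = read_specimens(specimens_csv)
    if not balance_logs and not wax_csv and not ftir_csv and not cutin_csv:
        raise ValidationError("nothing to do: no balance logs or tables given")

    report: dict = {
        "settings": {"a_apo": a_apo, "a_air": a_air, "seed": seed,
                     "version": __version__},
    }
    rows = []
    for leaf_id, log_path in sorted(balance_logs.items()):
        if leaf_id not in specimens:
            raise ValidationError(f"gmin stage, leaf {leaf_id!r}: no specimen row")
        sp = specimens[leaf_id]
        try:
            obs = read_balance_log(log_path, specimen=sp, sigma=5e-4)
            res = analyze_drying_run(sp, obs, a_apo=a_apo, a_air=a_air)
        except ValueError as exc:
            raise ValidationError(f"gmin stage, leaf {leaf_id!r}: {exc}") from exc
        traits = morphology_traits(sp)
        rows.append(
            {"leaf_id": leaf_id, "species": sp.species,
             "t_air_C": obs[0].air_temp, "g_min_m_per_s": res.g_min,
             "rwd_sc": res.rwd_sc, "plateau_points": res.plateau_points,
             "fit_rss": res.fit_rss, "lma_g_m2": traits["lma"],
             "lwc_g_g": traits["lwc"]}
        )
    if rows:
        gmin_df = pd.DataFrame(rows)
        gmin_df.to_csv(out_dir / "gmin_per_leaf.csv", index=False)
        report["gmin_per_leaf"] = rows
        arr = {}
        for sp_name, grp in gmin_df.groupby("species", sort=True):
            entries = tuple(
                (float(t), tuple(float(g) for g in sub["g_min_m_per_s"]))
                for t, sub in grp.groupby("t_air_C", sort=True)
            )
            if len(entries) >= 5:
                series = TemperatureSeries(species=str(sp_name), entries=entries)
                res = fit_biphasic(arrhenius_points(series))
                arr[str(sp_name)] = res
        if arr:
            report["arrhenius"] = arr

    if wax_csv is not None:
        comps = read_wax_table(wax_csv)
        dist = mole_fractions(comps, vlc_only=True)
        report["wax"] = {
            "class_coverage": class_coverage(comps),
            "mcl": mcl(dist),
            "chain_split": split_chain_fractions(dist),
        }
    if cutin_csv is not None:
        report["cutin"] = cutin_summary(read_cutin_table(cutin_csv))
    if ftir_csv is not None:
        curve = melting_analysis(read_ftir_long(ftir_csv))
        report["ftir"] = curve
        pd.DataFrame(curve.points, columns=["temperature_C", "nu_max_cm1"]
                     ).to_csv(out_dir / "melting_curve.csv", index=False)

    write_json_report(report, out_dir / "report.json")
    return report
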