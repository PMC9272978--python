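"""Readers and writers for the package's plain-text interchange formats.

* compression test CSVs — dialect A (raw): ``time_s, force_N,
  displacement_mm``; dialect B (processed): ``strain, stress_MPa``;
* JSON material cards and vessel configurations;
* TSV output tables (full 17-significant-digit precision, tab-separated to
  avoid decimal-comma ambiguity).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import CompositionSummary, FitResult, TestCurve, engineering_stress_strain
from .constitutive import HyperelasticMaterial
from .inflation import ExternalBC, Layer, TransmuralProfile, VesselConfig

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "read_material_card",
    "write_material_card",
    "read_vessel_config",
    "write_vessel_config",
    "write_fit_table",
    "write_summary_table",
    "write_profile_tsv",
]

_FLOAT_FMT = "%.17g"


def read_curve_csv(
    path,
    area_mm2: float | None = None,
    initial_height_mm: float | None = None,
    sample_id: str = "",
    composition: str = "",
) -> TestCurve:
    """Read one compression test CSV, auto-detecting the dialect.

    Dialect A (raw force-displacement) requires the sample geometry to be
    supplied; dialect B is already in engineering stress-strain.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty input file: {path}") from None
    cols = {c.strip() for c in df.columns}
    df.columns = [c.strip() for c in df.columns]
    sid = sample_id or path.stem
    if {"force_N", "displacement_mm"} <= cols:
        if area_mm2 is None or initial_height_mm is None:
            raise ValueError(
                f"{path}: raw-dialect CSV needs area_mm2 and initial_height_mm"
            )
        return engineering_stress_strain(
            df["force_N"].to_numpy(),
            df["displacement_mm"].to_numpy(),
            area_mm2,
            initial_height_mm,
            sample_id=sid,
            composition=composition,
        )
    if {"strain", "stress_MPa"} <= cols:
        return TestCurve(
            df["strain"].to_numpy(),
            df["stress_MPa"].to_numpy(),
            sample_id=sid,
            composition=composition,
            area_mm2=area_mm2,
            initial_height_mm=initial_height_mm,
        )
    raise ValueError(
        f"{path}: unrecognized CSV header {sorted(cols)}; expected "
        "(time_s, force_N, displacement_mm) or (strain, stress_MPa)"
    )


def write_curve_csv(curve: TestCurve, path, raw: bool = False) -> None:
    """Write a curve as dialect B, or dialect A when ``raw`` (needs geometry)."""
    path = Path(path)
    if raw:
        from .synthetic import curve_to_force_displacement

        F, dL = curve_to_force_displacement(curve)
        df = pd.DataFrame(
            {"time_s": dL / 0.1, "force_N": F, "displacement_mm": dL}  # 0.1 mm/s crosshead
        )
    else:
        df = pd.DataFrame({"strain": curve.strain, "stress_MPa": curve.stress})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- material cards --------------------------------------------------------


def write_material_card(material: HyperelasticMaterial, path) -> None:
    Path(path).write_text(json.dumps(material.to_card(), indent=1) + "\n")


def read_material_card(path) -> HyperelasticMaterial:
    return HyperelasticMaterial.from_card(json.loads(Path(path).read_text()))


# -- vessel configs --------------------------------------------------------


def write_vessel_config(vessel: VesselConfig, path) -> None:
    bc = vessel.external_bc
    cfg = {
        "name": vessel.name,
        "luminal_radius_mm": vessel.luminal_radius_mm,
        "layers": [
            {
                "label": lay.label,
                "thickness_mm": lay.thickness_mm,
                "material": lay.material.to_card(),
            }
            for lay in vessel.layers
        ],
        "external_bc": {
            "type": bc.kind,
            "params": {
                k: v
                for k, v in {
                    "P_o_MPa": bc.P_o_MPa if bc.kind == "constant_pressure" else None,
                    "E_MPa": bc.E_MPa if bc.kind == "elastic_foundation" else None,
                    "nu": bc.nu if bc.kind == "elastic_foundation" else None,
                    "outer_radius_mm": bc.outer_radius_mm,
                }.items()
                if v is not None
            },
        },
    }
    Path(path).write_text(json.dumps(cfg, indent=1) + "\n")


def read_vessel_config(path) -> VesselConfig:
    cfg = json.loads(Path(path).read_text())
    layers = tuple(
        Layer(
            thickness_mm=lay["thickness_mm"],
            material=HyperelasticMaterial.from_card(lay["material"]),
            label=lay.get("label", "custom"),
        )
        for lay in cfg["layers"]
    )
    bc_cfg = cfg.get("external_bc", {"type": "traction_free", "params": {}})
    params = bc_cfg.get("params", {})
    bc = ExternalBC(
        kind=bc_cfg["type"],
        P_o_MPa=params.get("P_o_MPa", 0.0),
        E_MPa=params.get("E_MPa", 0.0),
        nu=params.get("nu", 0.0),
        outer_radius_mm=params.get("outer_radius_mm"),
    )
    return VesselConfig(
        luminal_radius_mm=cfg["luminal_radius_mm"],
        layers=layers,
        external_bc=bc,
        name=cfg.get("name", ""),
    )


# -- TSV outputs -----------------------------------------------------------


def _fit_row(fit: FitResult) -> dict:
    row = {
        "sample": fit.sample_id,
        "composition": fit.composition,
        "family": fit.material.family,
    }
    for (i, j), v in sorted(fit.material.c.items()):
        row[f"c{i}{j}"] = v
    for k, v in enumerate(fit.material.mu, 1):
        row[f"mu{k}"] = v
    for k, v in enumerate(fit.material.alpha, 1):
        row[f"alpha{k}"] = v
    row.update(
        {
            "mu0_MPa": fit.material.mu0(),
            "r2": fit.r_squared,
            "residual_norm_MPa": fit.residual_norm,
            "stable": fit.stability.stable if fit.stability is not None else False,
            "converged": fit.converged,
            "flags": ";".join(fit.flags),
        }
    )
    return row


def write_fit_table(fits: Sequence[FitResult], path) -> pd.DataFrame:
    df = pd.DataFrame([_fit_row(f) for f in fits])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return df


def write_summary_table(summaries: Sequence[CompositionSummary], path) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "composition": s.composition,
            "family": s.family,
            "n_included": s.n_included,
            "n_excluded": s.n_excluded,
        }
        for name, m in s.mean.items():
            row[f"{name}_mean"] = m
            row[f"{name}_sd"] = s.sd[name]
        row["mu0_MPa"] = s.mean_material.mu0()
        row["excluded"] = ";".join(f"{k}:{v}" for k, v in s.excluded.items())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return df


def write_profile_tsv(profile: TransmuralProfile, path) -> pd.DataFrame:
    df = profile.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return df
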