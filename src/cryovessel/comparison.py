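"""Graft-versus-artery transmural comparison and design-target evaluation.

The pointwise figure of merit is the signed relative difference

    diff(x) = (x_graft - x_artery) / x_artery * 100 %

evaluated after resampling both transmural profiles onto a common
normalized coordinate (0 at the lumen, 1 at the outer surface, layer
interfaces aligned, piecewise linear within layers).  Points where the
reference value is numerically zero are masked rather than divided.

Three design targets summarize whether a graft reproduces the artery-like
transmural behaviour:

* I  — layer-mean hoop stress: intima > media and media <= adventitia;
* II — layer-mean radial stress magnitude strictly decreasing outward;
* III — strain stiffening: the secant slope of the intima hoop strain over
  the diastolic-systolic window (80-120 mmHg) is smaller than over
  0-80 mmHg (a concave strain-pressure curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inflation import (
    InflationResult,
    TransmuralProfile,
    VesselConfig,
    compliance,
    inflate,
    pressure_sweep,
)

__all__ = [
    "ComparisonResult",
    "DesignTargetReport",
    "relative_difference",
    "design_targets_check",
    "batch_report",
]

_FIELDS = ("sigma_theta", "sigma_r", "eps_theta", "eps_r")
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ComparisonResult:
    """Aligned relative-difference profiles (percent) and their summaries."""

    xi: np.ndarray  # normalized transmural coordinate, 0 = lumen
    diff: Mapping[str, np.ndarray]  # field -> signed % difference (NaN where masked)
    luminal: Mapping[str, float]  # field -> % difference at the lumen
    layer_mean: pd.DataFrame  # per-layer mean % difference per field
    graft_id: str = ""
    artery_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "diff", dict(self.diff))
        object.__setattr__(self, "luminal", dict(self.luminal))


@dataclass(frozen=True)
class DesignTargetReport:
    target_I: bool
    target_II: bool
    target_III: bool
    sigma_theta_layer_means: tuple[float, ...]
    abs_sigma_r_layer_means: tuple[float, ...]
    secant_low: float  # d eps_theta,intima / dP over 0-80 mmHg
    secant_high: float  # over 80-120 mmHg
    evaluated_on: str = "layer_means"


def _resample(profile: TransmuralProfile, xi_break: np.ndarray, n: int):
    """Fields of a profile on a common normalized grid with aligned layers."""
    labels = list(dict.fromkeys(profile.layer))
    if len(labels) + 1 != len(xi_break):
        raise ValueError("profiles have different layer structure")
    xi = np.linspace(0.0, 1.0, n)
    out = {}
    # per-layer local normalized coordinate mapped into [xi_break[k], xi_break[k+1]]
    xi_src = np.empty_like(profile.R_mm)
    for k, lab in enumerate(labels):
        m = profile.layer == lab
        R = profile.R_mm[m]
        local = (R - R[0]) / (R[-1] - R[0])
        xi_src[m] = xi_break[k] + local * (xi_break[k + 1] - xi_break[k])
    for f in _FIELDS:
        y = getattr(profile, f)
        out[f] = np.interp(xi, xi_src, y)
    return xi, out


def relative_difference(
    graft: TransmuralProfile, artery: TransmuralProfile, n_points: int = 201
) -> ComparisonResult:
    """Signed percent difference profiles of a graft against a reference."""
    if abs(graft.pressure_mmHg - artery.pressure_mmHg) > 1e-9:
        raise ValueError("profiles were solved at different pressures")
    labels = list(dict.fromkeys(artery.layer))
    # interface breakpoints from the reference profile's thickness fractions
    R = artery.R_mm
    bounds = [R[0]]
    for lab in labels:
        bounds.append(R[np.flatnonzero(artery.layer == lab)[-1]])
    bounds = np.asarray(bounds)
    xi_break = (bounds - bounds[0]) / (bounds[-1] - bounds[0])

    xi, g = _resample(graft, xi_break, n_points)
    _, a = _resample(artery, xi_break, n_points)

    diff = {}
    luminal = {}
    for f in _FIELDS:
        ref = a[f]
        d = np.where(np.abs(ref) > _ZERO_TOL, (g[f] - ref) / ref * 100.0, np.nan)
        diff[f] = d
        luminal[f] = float(d[0])

    layer_of_xi = np.searchsorted(xi_break[1:-1], xi, side="right")
    rows = []
    for k, lab in enumerate(labels):
        m = layer_of_xi == k
        rows.append(
            {"layer": lab, **{f: float(np.nanmean(diff[f][m])) for f in _FIELDS}}
        )
    return ComparisonResult(
        xi=xi,
        diff=diff,
        luminal=luminal,
        layer_mean=pd.DataFrame(rows),
        graft_id=getattr(graft, "name", ""),
        artery_id=getattr(artery, "name", ""),
    )


def design_targets_check(
    result: InflationResult,
    sweep: pd.DataFrame,
    use_interface_values: bool = False,
) -> DesignTargetReport:
    """Evaluate design targets I-III for one inflated vessel.

    ``sweep`` must be a :func:`cryovessel.inflation.pressure_sweep` table
    covering 0, 80 and 120 mmHg.  By default targets I/II are evaluated on
    per-layer means; ``use_interface_values`` switches to the values on the
    luminal side of each layer.
    """
    for p in (0.0, 80.0, 120.0):
        if not np.any(np.isclose(sweep["pressure_mmHg"], p)):
            raise ValueError(f"sweep is missing the required pressure {p} mmHg")

    prof = result.profile
    labels = list(dict.fromkeys(prof.layer))
    if use_interface_values:
        st = tuple(float(prof.sigma_theta[np.flatnonzero(prof.layer == lab)[0]]) for lab in labels)
        sr = tuple(float(abs(prof.sigma_r[np.flatnonzero(prof.layer == lab)[0]])) for lab in labels)
        basis = "interface_values"
    else:
        stats = prof.layer_stats().set_index("layer")
        st = tuple(float(stats.loc[lab, "sigma_theta_MPa_mean"]) for lab in labels)
        sr = tuple(float(abs(stats.loc[lab, "sigma_r_MPa_mean"])) for lab in labels)
        basis = "layer_means"

    t1 = st[0] > st[1] and st[1] <= st[2]
    t2 = all(a > b for a, b in zip(sr, sr[1:]))

    intima = sweep[sweep["layer"] == labels[0]].set_index("pressure_mmHg")["eps_theta_mean"]
    e0 = float(intima.loc[np.isclose(intima.index, 0.0)].iloc[0])
    e80 = float(intima.loc[np.isclose(intima.index, 80.0)].iloc[0])
    e120 = float(intima.loc[np.isclose(intima.index, 120.0)].iloc[0])
    s_low = (e80 - e0) / 80.0
    s_high = (e120 - e80) / 40.0
    t3 = s_high < s_low

    return DesignTargetReport(
        target_I=t1,
        target_II=t2,
        target_III=t3,
        sigma_theta_layer_means=st,
        abs_sigma_r_layer_means=sr,
        secant_low=s_low,
        secant_high=s_high,
        evaluated_on=basis,
    )


def batch_report(
    grafts: Sequence[VesselConfig],
    arteries: Sequence[VesselConfig],
    pressure_mmHg: float = 120.0,
    sweep_pressures: Sequence[float] = (0.0, 40.0, 80.0, 120.0),
    samples_per_layer: int = 32,
) -> pd.DataFrame:
    """Cross-compare every graft against every artery reference.

    Returns one row per (graft, artery) pair with luminal stresses, layer
    means, compliance of both vessels, design-target booleans of the graft
    and the luminal relative differences.  Artery solves are reused across
    graft rows; a failed solve flags its rows instead of aborting the batch.
    """
    art_cache: dict[str, dict] = {}
    for art in arteries:
        entry: dict = {"config": art}
        try:
            entry["result"] = inflate(art, pressure_mmHg, samples_per_layer=samples_per_layer)
            entry["compliance"] = compliance(art)
        except Exception as exc:  # noqa: BLE001 - row-level flagging by contract
            entry["error"] = str(exc)
        art_cache[art.name] = entry

    rows = []
    for graft in grafts:
        try:
            g_res = inflate(graft, pressure_mmHg, samples_per_layer=samples_per_layer)
            g_sweep = pressure_sweep(graft, list(sweep_pressures), samples_per_layer=8)
            g_comp = compliance(graft)
            g_targets = design_targets_check(g_res, g_sweep)
            g_err = None
        except Exception as exc:  # noqa: BLE001
            g_res = None
            g_err = str(exc)
        for art in arteries:
            a_entry = art_cache[art.name]
            row = {"graft": graft.name, "artery": art.name, "pressure_mmHg": pressure_mmHg}
            if g_err or "error" in a_entry:
                row["status"] = f"failed: {g_err or a_entry['error']}"
                rows.append(row)
                continue
            a_res = a_entry["result"]
            cmp_res = relative_difference(g_res.profile, a_res.profile)
            stats = g_res.profile.layer_stats().set_index("layer")
            row.update(
                {
                    "status": "ok",
                    "luminal_sigma_theta_MPa": float(g_res.profile.sigma_theta[0]),
                    "luminal_sigma_r_MPa": float(g_res.profile.sigma_r[0]),
                    **{
                        f"sigma_theta_{lab}_MPa": float(stats.loc[lab, "sigma_theta_MPa_mean"])
                        for lab in stats.index
                    },
                    "compliance_pct": 100.0 * g_comp,
                    "artery_compliance_pct": 100.0 * a_entry["compliance"],
                    "target_I": g_targets.target_I,
                    "target_II": g_targets.target_II,
                    "target_III": g_targets.target_III,
                    "diff_luminal_sigma_theta_pct": cmp_res.luminal["sigma_theta"],
                    "diff_luminal_eps_theta_pct": cmp_res.luminal["eps_theta"],
                }
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["graft", "artery"], kind="stable").reset_index(drop=True)
    return df
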