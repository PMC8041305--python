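"""CSV readers/writers, run configuration and the end-to-end pipeline.

CSV dialect: comma separated, '.' decimal, UTF-8, with '#'-prefixed metadata
lines of the form ``# key=value`` above the header. Temperatures are stored
in kelvin; every numeric column name carries its unit suffix.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .fitting import (
    CloudPointSeries,
    SaltFitResult,
    fit_epsilon_series,
    fit_salt_coefficients,
    linear_correlation,
)
from .models import BufferInteraction, ProteinModel
from .phase import binodal_curve, cloud_point_temperature
from .reduction import (
    DLSSeries,
    SLSConfig,
    SLSSeries,
    ViscositySeries,
    debye_fit,
    fit_interaction_diffusion,
    jones_dole_fit,
    reduce_sls,
    viscosity_from_flow,
)

__all__ = ["SchemaError", "read_table", "write_table", "RunConfig", "run_pipeline"]

SCHEMAS: dict[str, dict[str, Any]] = {
    "cloudpoint": {
        "required": ["buffer", "gamma_mg_ml", "ionic_strength_M", "t_cloud_K"],
        "optional": ["sigma_t_K"],
    },
    "dls": {"required": ["gamma_mg_ml", "D_m2_s"], "optional": []},
    "sls": {
        "required": ["conc_g_ml"],
        "optional": ["mcr_cps", "kc_over_r_mol_g"],
        "one_of": ["mcr_cps", "kc_over_r_mol_g"],
    },
    "visc": {
        "required": ["conc_M"],
        "optional": ["eta_rel", "flow_s", "density_g_cm3"],
        "one_of": ["eta_rel", "flow_s"],
    },
}


class SchemaError(ValueError):
    """Raised when a CSV header does not match the named schema."""


def _read_csv_with_meta(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    meta: dict[str, str] = {}
    lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            lines.append(line)
    text = "\n".join(lines).strip()
    if not text or len(text.splitlines()) == 0:
        return pd.DataFrame(), meta
    df = pd.read_csv(_io.StringIO(text), float_precision="round_trip")
    return df, meta


def _check_header(df: pd.DataFrame, schema_name: str) -> None:
    spec = SCHEMAS[schema_name]
    cols = list(df.columns)
    missing = [c for c in spec["required"] if c not in cols]
    extra = [c for c in cols if c not in spec["required"] + spec["optional"]]
    if missing or extra:
        expected = spec["required"] + [f"[{c}]" for c in spec["optional"]]
        raise SchemaError(
            f"schema {schema_name!r}: missing columns {missing}, unknown columns "
            f"{extra}; expected header {expected}"
        )
    one_of = spec.get("one_of")
    if one_of and len(df) > 0 and not any(c in cols for c in one_of):
        raise SchemaError(f"schema {schema_name!r}: need one of {one_of}")
    for col in cols:
        if col == "buffer":
            continue
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad])
            raise SchemaError(f"non-numeric cells in column {col!r}, rows {rows}")


def read_table(path: str | Path, schema_name: str):
    """Read a typed measurement table.

    Returns a list of :class:`CloudPointSeries` (one per buffer/gamma group)
    for the ``cloudpoint`` schema, or the matching series object for
    ``dls`` / ``sls`` / ``visc``. An empty data section yields a typed empty
    container, not an exception.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; use one of {list(SCHEMAS)}")
    df, meta = _read_csv_with_meta(path)
    if not df.empty:
        _check_header(df, schema_name)

    if schema_name == "cloudpoint":
        if df.empty:
            return []
        out = []
        for (buf, gamma), grp in df.groupby(["buffer", "gamma_mg_ml"], sort=True):
            grp = grp.sort_values("ionic_strength_M")
            sig = (
                grp["sigma_t_K"]
                if "sigma_t_K" in grp.columns
                else pd.Series([np.nan] * len(grp), index=grp.index)
            )
            obs = tuple(
                (float(i), float(t), None if pd.isna(s) else float(s))
                for i, t, s in zip(grp["ionic_strength_M"], grp["t_cloud_K"], sig)
            )
            out.append(CloudPointSeries(buffer_name=str(buf), gamma=float(gamma), observations=obs))
        return out

    if schema_name == "dls":
        pts = tuple() if df.empty else tuple(zip(df["gamma_mg_ml"], df["D_m2_s"]))
        return DLSSeries(
            points=pts,
            solvent_viscosity=float(meta.get("solvent_viscosity_mPa_s", 0.8900)),
            temperature=float(meta.get("temperature_K", 298.15)),
        )

    if schema_name == "sls":
        config = SLSConfig(
            wavelength=float(meta.get("wavelength_nm", 632.8)),
            refractive_index=float(meta.get("refractive_index", 1.332)),
            dn_dc=float(meta.get("dn_dc_ml_g", 0.185)),
            rayleigh_toluene=float(meta.get("rayleigh_toluene_cm1", 14.0e-6)),
        )
        raw = "mcr_cps" in df.columns
        col = "mcr_cps" if raw else "kc_over_r_mol_g"
        pts = tuple() if df.empty else tuple(zip(df["conc_g_ml"], df[col]))
        tol = meta.get("toluene_mcr_cps")
        return SLSSeries(
            points=pts,
            raw=raw,
            laser_intensity=float(meta.get("laser_intensity", 1.0)),
            toluene_count_rate=None if tol is None else float(tol),
            config=config,
        )

    # visc
    raw = "flow_s" in df.columns
    ref = None
    if all(k in meta for k in ("ref_flow_s", "ref_density_g_cm3", "ref_eta_mPa_s")):
        ref = (
            float(meta["ref_flow_s"]),
            float(meta["ref_density_g_cm3"]),
            float(meta["ref_eta_mPa_s"]),
        )
    if df.empty:
        return ViscositySeries(points=tuple(), raw=False, reference=ref)
    if raw:
        pts = tuple(zip(df["conc_M"], df["flow_s"], df["density_g_cm3"]))
    else:
        pts = tuple(zip(df["conc_M"], df["eta_rel"]))
    return ViscositySeries(points=pts, raw=raw, reference=ref)


def _meta_lines(meta: Mapping[str, Any] | None) -> str:
    if not meta:
        return ""
    flat: dict[str, Any] = {}
    for k, v in meta.items():
        if isinstance(v, Mapping):
            for kk, vv in v.items():
                flat[f"{k}.{kk}"] = vv
        else:
            flat[k] = v
    return "".join(f"# {k}={v}\n" for k, v in flat.items())


def write_table(series, path: str | Path) -> Path:
    """Write a series (or list of CloudPointSeries) to its CSV schema."""
    path = Path(path)
    if isinstance(series, CloudPointSeries):
        series = [series]
    if isinstance(series, list) and all(isinstance(s, CloudPointSeries) for s in series):
        rows = []
        header_meta = ""
        for s in series:
            header_meta += _meta_lines(
                None if s.meta is None else {f"{s.buffer_name}": s.meta}
            )
            for ionic, t, sig in s.observations:
                rows.append(
                    {
                        "buffer": s.buffer_name,
                        "gamma_mg_ml": s.gamma,
                        "ionic_strength_M": ionic,
                        "t_cloud_K": t,
                        "sigma_t_K": "" if sig is None else sig,
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=["buffer", "gamma_mg_ml", "ionic_strength_M", "t_cloud_K", "sigma_t_K"],
        )
        path.write_text(header_meta + df.to_csv(index=False))
        return path
    if isinstance(series, DLSSeries):
        meta = {
            "solvent_viscosity_mPa_s": series.solvent_viscosity,
            "temperature_K": series.temperature,
        }
        if series.meta:
            meta.update(series.meta)
        df = pd.DataFrame(series.points, columns=["gamma_mg_ml", "D_m2_s"])
        path.write_text(_meta_lines(meta) + df.to_csv(index=False))
        return path
    if isinstance(series, SLSSeries):
        meta: dict[str, Any] = {
            "laser_intensity": series.laser_intensity,
            "wavelength_nm": series.config.wavelength,
            "refractive_index": series.config.refractive_index,
            "dn_dc_ml_g": series.config.dn_dc,
            "rayleigh_toluene_cm1": series.config.rayleigh_toluene,
        }
        if series.toluene_count_rate is not None:
            meta["toluene_mcr_cps"] = series.toluene_count_rate
        if series.meta:
            meta.update(series.meta)
        col = "mcr_cps" if series.raw else "kc_over_r_mol_g"
        df = pd.DataFrame(series.points, columns=["conc_g_ml", col])
        path.write_text(_meta_lines(meta) + df.to_csv(index=False))
        return path
    if isinstance(series, ViscositySeries):
        meta = {}
        if series.reference is not None:
            meta = {
                "ref_flow_s": series.reference[0],
                "ref_density_g_cm3": series.reference[1],
                "ref_eta_mPa_s": series.reference[2],
            }
        if series.meta:
            meta.update(series.meta)
        cols = ["conc_M", "flow_s", "density_g_cm3"] if series.raw else ["conc_M", "eta_rel"]
        df = pd.DataFrame(series.points, columns=cols)
        path.write_text(_meta_lines(meta) + df.to_csv(index=False))
        return path
    raise TypeError(f"cannot write object of type {type(series).__name__}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end calibration run.

    File inputs: a ProteinModel JSON, a multi-buffer cloud-point CSV, and
    optional per-buffer DLS/SLS/viscometry CSVs keyed by buffer name.
    """

    model_file: Path
    cloudpoint_file: Path
    out_dir: Path
    dls_files: Mapping[str, Path] = field(default_factory=dict)
    sls_files: Mapping[str, Path] = field(default_factory=dict)
    visc_files: Mapping[str, Path] = field(default_factory=dict)
    gamma_reference: float = 90.0     # mg/mL, for the stability ordering
    n_binodal_temperatures: int = 25
    t_min_fraction: float = 0.85
    seed: int = 0
    carry_on: bool = True             # record stage failures instead of raising

    def __post_init__(self) -> None:
        for attr in ("model_file", "cloudpoint_file", "out_dir"):
            object.__setattr__(self, attr, Path(getattr(self, attr)))
        for attr in ("dls_files", "sls_files", "visc_files"):
            object.__setattr__(
                self, attr, {k: Path(v) for k, v in getattr(self, attr).items()}
            )
        for p in (self.model_file, self.cloudpoint_file):
            if not p.exists():
                raise FileNotFoundError(p)
        if self.n_binodal_temperatures < 2 or not 0 < self.t_min_fraction < 1:
            raise ValueError("invalid binodal sampling settings")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        base = Path(path).parent
        def _p(v):
            p = Path(v)
            return p if p.is_absolute() else base / p
        return cls(
            model_file=_p(d["model_file"]),
            cloudpoint_file=_p(d["cloudpoint_file"]),
            out_dir=_p(d["out_dir"]),
            dls_files={k: _p(v) for k, v in d.get("dls_files", {}).items()},
            sls_files={k: _p(v) for k, v in d.get("sls_files", {}).items()},
            visc_files={k: _p(v) for k, v in d.get("visc_files", {}).items()},
            gamma_reference=float(d.get("gamma_reference", 90.0)),
            n_binodal_temperatures=int(d.get("n_binodal_temperatures", 25)),
            t_min_fraction=float(d.get("t_min_fraction", 0.85)),
            seed=int(d.get("seed", 0)),
            carry_on=bool(d.get("carry_on", True)),
        )


def _fit_result_dict(fit: SaltFitResult) -> dict[str, Any]:
    return {
        "eps0_K": fit.buffer.eps0,
        "eps0_se_K": fit.eps0_se,
        "salt_coeff_K_L12_mol12": fit.buffer.salt_coeff,
        "salt_coeff_se": fit.salt_coeff_se,
        "n_points": fit.n_points,
        "weighted": fit.weighted,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full calibration workflow and return a deterministic report.

    Stages: read measurement tables -> invert cloud points to epsilon(I) and
    regress (eps0, a) per buffer -> reduce DLS/SLS/viscometry where supplied
    -> predict each buffer's coexistence curve -> correlation analyses and
    the buffer stability ordering. Per-stage failures are recorded under
    ``errors`` when ``carry_on`` is set.
    """
    model = ProteinModel.from_json(config.model_file)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": {
            "model_file": str(config.model_file),
            "cloudpoint_file": str(config.cloudpoint_file),
            "seed": config.seed,
            "gamma_reference_mg_ml": config.gamma_reference,
        },
        "buffers": {},
        "errors": {},
    }

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            if not config.carry_on:
                raise
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None

    series_list = read_table(config.cloudpoint_file, "cloudpoint")
    by_buffer: dict[str, list[CloudPointSeries]] = {}
    for s in series_list:
        by_buffer.setdefault(s.buffer_name, []).append(s)

    fits: dict[str, SaltFitResult] = {}
    for name in sorted(by_buffer):
        def _fit(name=name):
            pts = []
            for s in by_buffer[name]:
                pts.extend(fit_epsilon_series(s, model))
            return fit_salt_coefficients(pts, name=name)

        fit = stage(f"fit:{name}", _fit)
        if fit is None:
            continue
        fits[name] = fit
        entry: dict[str, Any] = {"interaction_fit": _fit_result_dict(fit)}

        def _binodal(name=name, fit=fit):
            curve = binodal_curve(
                model,
                fit.buffer.eps0,
                n_temperatures=config.n_binodal_temperatures,
                t_min_fraction=config.t_min_fraction,
            )
            out_csv = config.out_dir / f"binodal_{name}.csv"
            curve.to_dataframe(model).to_csv(out_csv, index=False)
            return {
                "critical_temperature_K": curve.critical_temperature,
                "critical_gamma_mg_ml": model.mass_concentration(curve.critical_density),
                "csv": out_csv.name,
            }

        binfo = stage(f"binodal:{name}", _binodal)
        if binfo:
            entry["binodal"] = binfo

        def _tcloud(name=name, fit=fit):
            return cloud_point_temperature(
                config.gamma_reference, model, fit.buffer, 0.0
            )

        t0 = stage(f"tcloud:{name}", _tcloud)
        if t0 is not None:
            entry["t_cloud_zero_salt_K"] = t0

        if name in config.dls_files:
            def _dls(name=name):
                ser = read_table(config.dls_files[name], "dls")
                r = fit_interaction_diffusion(ser)
                return {"d0_m2_s": r.d0, "kd_ml_g": r.kd, "kd_se_ml_g": r.kd_se}
            out = stage(f"dls:{name}", _dls)
            if out:
                entry["dls"] = out
        if name in config.sls_files:
            def _sls(name=name):
                ser = read_table(config.sls_files[name], "sls")
                r = debye_fit(reduce_sls(ser))
                return {"mw_g_mol": r.mw, "b22_mol_ml_g2": r.b22, "b22_se": r.b22_se}
            out = stage(f"sls:{name}", _sls)
            if out:
                entry["sls"] = out
        if name in config.visc_files:
            def _visc(name=name):
                ser = read_table(config.visc_files[name], "visc")
                reduced = viscosity_from_flow(ser) if (ser.raw or ser.reference) else [
                    (c, None, rel) for c, rel in ser.points
                ]
                r = jones_dole_fit([(c, rel) for c, _, rel in reduced])
                return {"jones_dole_A": r.a, "jones_dole_B_L_mol": r.b, "b_se": r.b_se}
            out = stage(f"visc:{name}", _visc)
            if out:
                entry["viscosity"] = out
        report["buffers"][name] = entry

    # stability ordering: higher zero-salt cloud point = less stable
    tclouds = {
        n: e["t_cloud_zero_salt_K"]
        for n, e in report["buffers"].items()
        if "t_cloud_zero_salt_K" in e
    }
    if tclouds:
        report["stability_ordering_most_stable_first"] = sorted(
            tclouds, key=lambda n: tclouds[n]
        )

    # correlation analyses across buffers
    def _corr(xs, ys):
        fit = linear_correlation(xs, ys)
        return {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "slope_se": fit.slope_se,
            "pearson_r": fit.pearson_r,
        }

    correlations: dict[str, Any] = {}
    names = sorted(n for n in report["buffers"] if n in tclouds)
    b22 = [report["buffers"][n].get("sls", {}).get("b22_mol_ml_g2") for n in names]
    kd = [report["buffers"][n].get("dls", {}).get("kd_ml_g") for n in names]
    bjd = [report["buffers"][n].get("viscosity", {}).get("jones_dole_B_L_mol") for n in names]
    eps0 = [fits[n].buffer.eps0 for n in names if n in fits]
    a_c = [fits[n].buffer.salt_coeff for n in names if n in fits]
    if len(names) >= 2 and all(v is not None for v in b22):
        correlations["t_cloud_vs_b22"] = _corr(b22, [tclouds[n] for n in names])
    if len(names) >= 2 and all(v is not None for v in kd):
        correlations["t_cloud_vs_kd"] = _corr(kd, [tclouds[n] for n in names])
    if len(names) >= 2 and all(v is not None for v in bjd):
        correlations["jones_dole_b_vs_eps0"] = _corr(eps0, bjd)
    if len(eps0) >= 2:
        correlations["a_vs_eps0"] = _corr(eps0, a_c)
    if correlations:
        report["correlations"] = correlations

    out_json = config.out_dir / "report.json"
    out_json.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    report["report_file"] = str(out_json)
    return report
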