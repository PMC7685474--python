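"""File formats, configuration and the end-to-end analysis pipeline.

Fractograms travel as CSV with a ``time_min`` column, detector columns
``uv_au`` and ``dri_riu``, and light-scattering columns ``ls_<angle>`` with
the detector angle (degrees, zero-padded) encoded in the name.  SAXS curves
use the de facto 3-column whitespace text dialect (q, I, sigma) with ``#``
comments; q is auto-detected as 1/A when max(q) < 1 and converted to 1/nm.
``run_pipeline`` ties the stages together -- calibrate, deconvolve, Berry,
binding, SAXS, shape factor -- with per-stage failure isolation.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding_stoichiometry as bs
from . import mals_analysis as mals
from . import saxs_primary as sx
from .fff_retention import (ChannelGeometry, FlowConditions, SolventConditions,
                            calibrate_thickness, radius_from_retention_time)

__all__ = [
    "Fractogram",
    "FormatError",
    "read_fractogram",
    "write_fractogram",
    "read_saxs_curve",
    "write_saxs_curve",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("af4saxs")

_LS_COL = re.compile(r"^ls_(\d+(?:\.\d+)?)$")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Fractogram:
    """Multi-detector elution time series."""

    data: pd.DataFrame
    ls_angles_deg: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, time_min: np.ndarray,
                    uv_au: np.ndarray | None = None,
                    dri_riu: np.ndarray | None = None,
                    ls_matrix: np.ndarray | None = None,
                    ls_angles_deg: np.ndarray | None = None) -> "Fractogram":
        cols: dict[str, np.ndarray] = {"time_min": np.asarray(time_min, float)}
        if uv_au is not None:
            cols["uv_au"] = np.asarray(uv_au, float)
        if dri_riu is not None:
            cols["dri_riu"] = np.asarray(dri_riu, float)
        if ls_matrix is not None:
            if ls_angles_deg is None:
                raise ValueError("ls_matrix requires ls_angles_deg")
            for j, ang in enumerate(ls_angles_deg):
                cols[f"ls_{int(round(ang)):03d}"] = np.asarray(ls_matrix[:, j],
                                                              float)
        return cls(data=pd.DataFrame(cols),
                   ls_angles_deg=(np.asarray(ls_angles_deg, float)
                                  if ls_angles_deg is not None else None))

    @property
    def time_min(self) -> np.ndarray:
        return self.data["time_min"].to_numpy()

    @property
    def uv_au(self) -> np.ndarray | None:
        return self.data["uv_au"].to_numpy() if "uv_au" in self.data else None

    @property
    def dri_riu(self) -> np.ndarray | None:
        return self.data["dri_riu"].to_numpy() if "dri_riu" in self.data else None

    @property
    def ls_columns(self) -> list[str]:
        return [c for c in self.data.columns if _LS_COL.match(c)]

    @property
    def ls_matrix(self) -> np.ndarray | None:
        cols = self.ls_columns
        return self.data[cols].to_numpy() if cols else None


def read_fractogram(path: str | Path) -> Fractogram:
    """Read a fractogram CSV, validating and time-sorting it."""
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8-sig", skipinitialspace=True)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    if "time_min" not in df.columns:
        raise FormatError(f"{path}: missing required 'time_min' column")
    t = df["time_min"].to_numpy()
    bad = np.flatnonzero(np.diff(t) < 0)
    if bad.size:
        raise FormatError(f"{path}: non-monotonic time at data row {bad[0] + 2}")
    angles, ls_cols, extra = [], [], []
    for c in df.columns:
        m = _LS_COL.match(c)
        if m:
            angles.append(float(m.group(1)))
            ls_cols.append(c)
        elif c not in ("time_min", "uv_au", "dri_riu"):
            extra.append(c)
    if "uv_au" not in df.columns and "dri_riu" not in df.columns:
        log.info("%s: no detector columns beyond time", path)
    if not ls_cols:
        log.info("%s: light-scattering detectors absent", path)
    frac = Fractogram(
        data=df[[c for c in df.columns if c not in extra]],
        ls_angles_deg=np.asarray(angles) if angles else None,
        metadata={"path": str(path),
                  "extra_columns": {c: df[c].tolist() for c in extra}})
    return frac


def write_fractogram(frac: Fractogram, path: str | Path) -> None:
    frac.data.to_csv(path, index=False)


def read_saxs_curve(path: str | Path, label: str = "",
                    concentration_mg_ml: float | None = None
                    ) -> "sx.ScatteringCurve":
    """Read a 3-column (q, I, sigma) text file with unit auto-detection."""
    path = Path(path)
    rows = []
    for line in path.read_text(encoding="utf-8-sig").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}: expected >= 3 columns, got {len(parts)}")
        try:
            rows.append([float(x) for x in parts[:3]])
        except ValueError:
            continue          # tolerate stray header lines
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    q, i, s = arr[:, 0], arr[:, 1], arr[:, 2]
    if q.max() < 1.0:
        log.info("%s: max q %.3g < 1, interpreting as 1/A and converting to "
                 "1/nm", path, q.max())
        q = q * 10.0
    if np.all(s == 0):
        log.warning("%s: zero errors; substituting 1%% of |I|", path)
        s = 0.01 * np.abs(i)
        s[s == 0] = 0.01 * max(float(np.abs(i).max()), 1e-12)
    keep = s > 0
    return sx.ScatteringCurve(q=q[keep], intensity=i[keep], sigma=s[keep],
                              label=label or path.stem,
                              concentration_mg_ml=concentration_mg_ml)


def write_saxs_curve(curve: "sx.ScatteringCurve", path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {curve.label}\n# q(1/nm)  I(q)  sigma\n")
        for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
            fh.write(f"{q:.6e} {i:.6e} {s:.6e}\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def _geometry_from_config(cfg: dict) -> ChannelGeometry:
    ch = cfg.get("channel", {})
    return ChannelGeometry(
        tip_to_tip_length_cm=ch.get("length_cm", 26.5),
        inlet_width_cm=ch.get("inlet_width_cm", 2.2),
        outlet_width_cm=ch.get("outlet_width_cm", 0.6),
        nominal_thickness_um=ch.get("spacer_um", 350.0),
        thickness_scale=ch.get("thickness_scale", 1.0),
        focus_position_cm=ch.get("focus_cm", 2.0))


def _flows_from_config(cfg: dict) -> FlowConditions:
    fl = cfg.get("flows", {})
    return FlowConditions(
        detector_flow_ml_min=fl.get("detector_ml_min", 1.0),
        cross_flow_ml_min=fl.get("crossflow_ml_min", 4.5),
        elution_duration_min=fl.get("elution_min", 30.0))


def _solvent_from_config(cfg: dict) -> SolventConditions:
    so = cfg.get("solvent", {})
    return SolventConditions(
        temperature_K=so.get("temperature_K", 298.15),
        viscosity_Pa_s=so.get("viscosity_Pa_s", 8.9e-4),
        refractive_index=so.get("refractive_index", 1.331),
        laser_wavelength_nm=so.get("laser_nm", 658.0))


REQUIRED_KEYS = ("channel", "flows", "solvent")


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and return the analysis report.

    Stage failures are isolated: a failing SAXS stage leaves the AF4 results
    intact, with the error recorded under ``errors`` with stage provenance.
    The report is deterministic given inputs and configuration.
    """
    if not config:
        raise ValueError("empty config; required sections: "
                         + ", ".join(REQUIRED_KEYS))
    geometry = _geometry_from_config(config)
    flows = _flows_from_config(config)
    solvent = _solvent_from_config(config)

    report: dict = {"config": config, "version": _version(),
                    "results": {}, "errors": {}}

    cal = config.get("calibration")
    if cal:
        try:
            geometry = calibrate_thickness(cal["reference_rh_nm"],
                                           cal["reference_tr_min"],
                                           geometry, flows, solvent)
            log.info("calibrated thickness_scale = %.5f", geometry.thickness_scale)
            report["results"]["thickness_scale"] = geometry.thickness_scale
        except Exception as exc:
            report["errors"]["calibration"] = str(exc)

    af4 = config.get("af4")
    if af4:
        try:
            frac = read_fractogram(af4["fractogram"])
            optical = mals.OpticalConstants.from_solvent(
                solvent, af4.get("dn_dc_ml_g", 0.185))
            peaks_out = []
            for pk in af4.get("peaks", []):
                window = tuple(pk["window_min"])
                entry: dict = {"window_min": list(window)}
                t_peak = _peak_time(frac, window)
                if t_peak is not None:
                    entry["peak_time_min"] = t_peak
                    try:
                        entry["rh_nm"] = radius_from_retention_time(
                            t_peak, geometry, flows, solvent
                        ).hydrodynamic_radius_nm
                    except Exception as exc:
                        entry["rh_nm"] = None
                        entry["rh_error"] = str(exc)
                prof = mals.peak_mass_profile(frac, window, optical, solvent)
                entry["mw_weight_avg_kda"] = prof.weight_average_kda \
                    if prof.determined else "n.d."
                entry["n_slices"] = prof.n_slices
                peaks_out.append(entry)
            report["results"]["af4_peaks"] = peaks_out
        except Exception as exc:
            report["errors"]["af4"] = str(exc)

    binding = config.get("binding")
    if binding:
        try:
            report["results"]["binding"] = _binding_stage(binding)
        except Exception as exc:
            report["errors"]["binding"] = str(exc)

    saxs = config.get("saxs")
    if saxs:
        try:
            report["results"]["saxs"] = _saxs_stage(saxs)
        except Exception as exc:
            report["errors"]["saxs"] = str(exc)

    return report


def _peak_time(frac: Fractogram, window: tuple[float, float]) -> float | None:
    sig = frac.uv_au if frac.uv_au is not None else frac.dri_riu
    if sig is None:
        return None
    t = frac.time_min
    m = (t >= window[0]) & (t <= window[1])
    if not np.any(m):
        return None
    return float(t[m][np.argmax(sig[m])])


def _binding_stage(cfg: dict) -> dict:
    mix = read_fractogram(cfg["mixture"])
    hsa = read_fractogram(cfg["pure_hsa"])
    gaz = read_fractogram(cfg["pure_gaz"])
    windows = cfg.get("windows") or {
        "free_gaz": [3.2, 4.25], "monomer": [4.3, 5.6], "dimer": [5.9, 7.5]}
    labels = list(windows)
    win_list = [tuple(windows[k]) for k in labels]

    mix_dec = bs.fit_baseline_and_deconvolve(mix.time_min, mix.uv_au,
                                             win_list, labels)
    hsa_dec = bs.fit_baseline_and_deconvolve(
        hsa.time_min, hsa.uv_au,
        [tuple(windows["monomer"]), tuple(windows["dimer"])],
        ["monomer", "dimer"])
    gaz_area = bs.area_under_peak(gaz.time_min, gaz.uv_au,
                                  (0.0, float(gaz.time_min[-1])))
    konv = bs.konv_from_pure_injection(gaz_area, cfg["gaz_concentration_mg_ml"],
                                       cfg.get("gaz_molar_mass_kda", 11.5))
    f_mono, _ = bs.monomer_dimer_content(hsa.time_min, hsa.uv_au,
                                         tuple(windows["monomer"]),
                                         tuple(windows["dimer"]))
    hsa_molar = cfg["hsa_concentration_mg_ml"] \
        / (cfg.get("hsa_molar_mass_kda", 66.5) * 1000.0)
    gaz_molar = cfg["gaz_mixed_concentration_mg_ml"] \
        / (cfg.get("gaz_molar_mass_kda", 11.5) * 1000.0)
    res = bs.binding_ratios(mix_dec, hsa_dec, konv, hsa_molar, f_mono, gaz_molar)
    return {
        "molar_ratio_added": gaz_molar / hsa_molar,
        "monomer_fraction": f_mono,
        "gaz_per_monomer": res.gaz_per_hsa_monomer,
        "gaz_per_dimer": res.gaz_per_hsa_dimer,
        "free_per_hsa": res.free_gaz_per_hsa_tot,
        "overall": res.overall_gaz_per_hsa,
    }


def _saxs_stage(cfg: dict) -> dict:
    curve = read_saxs_curve(cfg["curve"],
                            concentration_mg_ml=cfg.get("concentration_mg_ml"))
    out: dict = {}
    g = sx.guinier_fit(curve)
    out["rg_nm"] = g.radius_gyration_nm
    out["i0"] = g.i_zero
    out["q_range"] = list(g.q_range)
    out["guinier_linear"] = g.linearity_flag
    dmax = cfg.get("dmax_nm")
    if dmax is None:
        grid = np.arange(2.0 * g.radius_gyration_nm,
                         4.5 * g.radius_gyration_nm, 0.5)
        dmax, _ = sx.dmax_scan(curve, grid, alpha=cfg.get("alpha", "auto"))
    pddf = sx.pddf_ift(curve, dmax, alpha=cfg.get("alpha", "auto"))
    out["dmax_nm"] = dmax
    out["rg_real_nm"] = pddf.rg_real_nm
    porod = sx.porod_volume(curve, g.i_zero, g.radius_gyration_nm)
    out["vp_nm3"] = porod.porod_volume_nm3
    out["mw_porod_kda"] = sx.round_half_away(porod.mw_porod_kda)
    if "reference" in cfg:
        ref = cfg["reference"]
        out["mw_standard_kda"] = sx.mw_from_standard(
            g.i_zero, cfg["concentration_mg_ml"], ref["i_zero"],
            ref["concentration_mg_ml"], ref["mw_kda"])
    if "rh_nm" in cfg:
        out["shape_factor"] = sx.round_sig(
            sx.shape_factor(g.radius_gyration_nm, cfg["rh_nm"]).rho, 2)
    return out


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("af4saxs")
    except Exception:
        return "unknown"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
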