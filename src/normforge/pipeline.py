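"""End-to-end run: simulate/load -> describe -> calibrate -> diagnostics -> tables.

A :class:`RunConfig` fixes everything a run needs — instruments, input
paths or a simulation block, subgroup definitions, the decision thresholds
and the seed — and :func:`run_pipeline` executes the stages per instrument,
writing every artifact plus a manifest that records parameters, seeds and
per-stage summaries.  A failed stage is recorded and the instrument's
remaining stages are skipped; other instruments continue.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosswalk import build_crosswalk, evaluate_equation, fit_conversion_equation, validate_conversion
from .describe import compare_groups, moments
from .dif import olr_dif
from .grm import default_grid, eap_pattern, fit_grm, item_fit_s_chi2
from .norms import norm_levels
from .quality import quality_report
from .scales import ResponseMatrix, builtin_spec, load_responses, load_scale_spec, raw_scores, write_table
from .simulate import save_responses, simulate_dataset

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_THRESHOLDS = {
    "dif_delta_r2": 0.02,
    "s_chi2_alpha": 0.001,
    "q3_moderate": 0.24,
    "q3_large": 0.37,
    "min_group_size": 50,
}

_YOUNG = ("16-19", "20-29", "30-39", "40-49")


@dataclass
class RunConfig:
    instruments: list[str]
    out_dir: str
    seed: int = 0
    n_persons: int = 2863
    responses: dict[str, str] = field(default_factory=dict)  # instrument -> CSV path
    scale_specs: dict[str, str] = field(default_factory=dict)  # instrument -> YAML path
    norm_groups: list[str] = field(default_factory=lambda: ["gender"])
    dif_contrasts: list[str] = field(default_factory=lambda: ["gender", "age", "region"])
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    quadrature_nodes: int = 61
    quadrature_bound: float = 6.0

    def __post_init__(self) -> None:
        if not self.instruments:
            raise ValueError("at least one instrument required")
        for k, v in DEFAULT_THRESHOLDS.items():
            self.thresholds.setdefault(k, v)
        if not (0 < self.thresholds["dif_delta_r2"] < 1):
            raise ValueError("dif_delta_r2 must be in (0, 1)")
        if not (0 < self.thresholds["s_chi2_alpha"] < 1):
            raise ValueError("s_chi2_alpha must be in (0, 1)")
        for inst, path in self.responses.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"responses for {inst}: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _binary_dif_group(cov: pd.DataFrame, contrast: str) -> np.ndarray | None:
    """Map a configured contrast onto a 0/1 indicator (None when unavailable)."""
    if contrast == "gender" and "gender" in cov:
        return (cov["gender"].astype(str) == "male").to_numpy()
    if contrast == "age" and "age_group" in cov:
        return (~cov["age_group"].astype(str).isin(_YOUNG)).to_numpy()  # focal: >= 45
    if contrast == "region" and "region" in cov:
        return (cov["region"].astype(str) == "rural").to_numpy()
    return None


def _instrument_stages(inst: str, matrix: ResponseMatrix, spec, config: RunConfig,
                       out: Path, manifest_entry: dict) -> None:
    thr = config.thresholds
    grid = default_grid(config.quadrature_nodes, config.quadrature_bound)
    scales = [None] + list(spec.subscales)

    # descriptives over total scale + subscales
    desc_rows = []
    for sub in scales:
        label = spec.instrument_id if sub is None else f"{spec.instrument_id}_{sub}"
        sc = raw_scores(matrix, spec, sub)["score"]
        st = moments(sc.dropna().to_numpy())
        row = {"scale": label, **asdict(st)}
        if "gender" in matrix.covariates:
            cg = compare_groups(sc.to_numpy(), matrix.covariates["gender"].astype(str).to_numpy())
            row.update({"cohen_d_gender": cg.cohen_d, "t_gender": cg.t, "u_gender": cg.u})
        desc_rows.append(row)
    desc = pd.DataFrame(desc_rows)
    write_table(desc, out / f"{inst}_descriptives.csv")
    manifest_entry["stages"]["describe"] = {"scales": len(desc_rows)}

    # calibration on the full scale, complete cases
    complete = matrix.complete_mask()
    X = matrix.responses[complete]
    result = fit_grm(X, list(spec.items), grid)
    result.params.save(out / f"{inst}_params.json",
                       meta={"loglik": result.loglik, "iterations": result.iterations,
                             "converged": result.converged, "n": int(X.shape[0])})
    manifest_entry["stages"]["calibrate"] = {
        "n_complete": int(X.shape[0]), "loglik": result.loglik,
        "iterations": result.iterations, "converged": result.converged,
    }
    params = result.params

    # quality diagnostics + item fit
    qr = quality_report(X, params, list(spec.items), grid, thr["min_group_size"])
    fit = item_fit_s_chi2(X, params, grid, thr["s_chi2_alpha"])
    quality_payload = {
        "mokken_h": qr.scale_h,
        "mokken_interpretation": qr.h_interpretation,
        "item_h": qr.item_h,
        "monotonicity": qr.monotonicity,
        "q3": qr.q3_summary,
        "s_chi2": {
            iid: {"statistic": float(s), "df": int(d), "p": float(p), "flagged": bool(f)}
            for iid, s, d, p, f in zip(fit.item_ids, fit.statistic, fit.df, fit.p_value, fit.flagged)
        },
    }
    with open(out / f"{inst}_quality.json", "w", encoding="utf-8") as fh:
        json.dump(quality_payload, fh, indent=2)
    manifest_entry["stages"]["quality"] = {
        "mokken_h": qr.scale_h, "max_q3": qr.q3_summary["max_abs_q3"],
        "s_chi2_flagged": int(fit.flagged.sum()),
    }

    # DIF per configured contrast
    theta, _ = eap_pattern(X, params, grid)
    cov_c = matrix.covariates.loc[complete].reset_index(drop=True) if len(matrix.covariates) else pd.DataFrame()
    dif_frames = []
    for contrast in config.dif_contrasts:
        g = _binary_dif_group(cov_c, contrast) if len(cov_c) else None
        if g is None:
            continue
        try:
            d = olr_dif(X, theta, g, list(spec.items), thr["dif_delta_r2"], thr["min_group_size"])
        except ValueError as exc:
            manifest_entry["stages"].setdefault("dif_skipped", {})[contrast] = str(exc)
            continue
        d.insert(0, "contrast", contrast)
        dif_frames.append(d.reset_index())
    if dif_frames:
        dif_all = pd.concat(dif_frames, ignore_index=True)
        write_table(dif_all, out / f"{inst}_dif.csv")
        manifest_entry["stages"]["dif"] = {
            "contrasts": [f["contrast"].iloc[0] for f in dif_frames],
            "flagged": dif_all.loc[dif_all["flagged"], "item"].tolist(),
        }

    # crosswalks: pooled, plus per configured subgroup; subscales too
    xwalk_frames = []
    equations = {}
    for sub in scales:
        label = spec.instrument_id if sub is None else f"{spec.instrument_id}_{sub}"
        sub_spec = spec.subscale_spec(sub)
        sub_params = params.subset(sub_spec.items)
        table = build_crosswalk(matrix, spec, sub_params, sub, grid=grid)
        eq, _cands = fit_conversion_equation(table)
        val = validate_conversion(table, eq, matrix, spec, sub)
        eq.icc, eq.bias, eq.loa = val["icc"], val["bias"], val["loa"]
        table["T_equation"] = evaluate_equation(eq, table["raw"].to_numpy(), warn_extrapolation=False)
        table.insert(0, "scale", label)
        table.insert(1, "group", "all")
        xwalk_frames.append(table)
        equations[label] = {
            "family": eq.family, "coef": [float(c) for c in eq.coef],
            "bic": eq.bic, "icc": val["icc"], "bias": val["bias"],
            "loa": list(val["loa"]), "x_shift": eq.x_shift,
        }
        for by in config.norm_groups:
            if by not in matrix.covariates.columns:
                continue
            for level in matrix.covariates[by].astype(str).unique():
                mask = (matrix.covariates[by].astype(str) == level).to_numpy()
                try:
                    t_g = build_crosswalk(matrix, spec, sub_params, sub, group_mask=mask,
                                          grid=grid, min_group_size=thr["min_group_size"])
                except ValueError:
                    continue
                t_g.insert(0, "scale", label)
                t_g.insert(1, "group", f"{by}={level}")
                xwalk_frames.append(t_g)
    xwalk = pd.concat(xwalk_frames, ignore_index=True)
    write_table(xwalk, out / f"{inst}_crosswalk.csv")
    with open(out / f"{inst}_equations.json", "w", encoding="utf-8") as fh:
        json.dump(equations, fh, indent=2)
    manifest_entry["stages"]["crosswalk"] = {
        lbl: {"family": eq["family"], "icc": eq["icc"]} for lbl, eq in equations.items()
    }

    # seven-level norms: pooled and per subgroup
    norm_frames = []
    decimals = 0 if spec.score_type == "sum" else 2
    for sub in scales:
        label = spec.instrument_id if sub is None else f"{spec.instrument_id}_{sub}"
        sub_spec = spec.subscale_spec(sub)
        sc = raw_scores(matrix, spec, sub)["score"].dropna()
        if spec.score_type == "sum":
            rng = (0.0, float(sub_spec.max_sum))
        else:
            rng = (float(spec.response_offset),
                   float(spec.response_offset + max(k - 1 for k in sub_spec.n_categories)))
        table = norm_levels(sc.value_counts(), rng, group="all")
        frame = table.to_frame(decimals)
        frame.insert(0, "scale", label)
        norm_frames.append(frame)
        for by in config.norm_groups:
            if by not in matrix.covariates.columns:
                continue
            for level in matrix.covariates[by].astype(str).unique():
                mask = (matrix.covariates[by].astype(str) == level).to_numpy()
                sc_g = raw_scores(matrix.subset(mask), spec, sub)["score"].dropna()
                if len(sc_g) < 20:
                    continue
                t_g = norm_levels(sc_g.value_counts(), rng, group=f"{by}={level}")
                f_g = t_g.to_frame(decimals)
                f_g.insert(0, "scale", label)
                norm_frames.append(f_g)
    norms = pd.concat(norm_frames, ignore_index=True)
    write_table(norms, out / f"{inst}_norms.csv")
    manifest_entry["stages"]["norms"] = {"tables": len(norm_frames)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for every configured instrument; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dict(config.thresholds),
        "quadrature": {"nodes": config.quadrature_nodes, "bound": config.quadrature_bound},
        "instruments": {},
    }
    for idx, inst in enumerate(config.instruments):
        entry: dict = {"stages": {}}
        manifest["instruments"][inst] = entry
        try:
            if inst in config.scale_specs:
                spec = load_scale_spec(config.scale_specs[inst])
            else:
                spec = builtin_spec(inst)
            if inst in config.responses:
                matrix = load_responses(config.responses[inst], spec)
                entry["source"] = str(config.responses[inst])
            else:
                matrix, _truth = simulate_dataset(inst, config.n_persons,
                                                  config.seed + 1000 * idx)
                save_responses(matrix, spec, out / f"{inst}_responses.csv")
                entry["source"] = "simulated"
                entry["n_persons"] = config.n_persons
            _instrument_stages(inst, matrix, spec, config, out, entry)
            entry["status"] = "ok"
        except Exception as exc:  # stage failure: record, keep partial outputs
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=5)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
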