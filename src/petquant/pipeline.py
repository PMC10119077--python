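"""End-to-end orchestration: study directory in, result tables out.

Stages (each isolated; a failure in one region/model is recorded and
does not abort the run):

1. input-function construction per subject-session with blood data,
2. arterial-model fits (1TC, optionally 2TC, Logan) per region,
3. reference-model fits (SRTM, Logan reference) per region,
4. DVR tables for every requested model,
5. if both sessions are present: per-region test-retest reports
   (ICC, bias, VAR) per reference method,
6. where arterial DVRs exist: per-subject regression of each reference
   method's DVRs on the arterial 1TC DVRs.

Everything is written as TSV/JSON under the output directory together
with the effective configuration and its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blood as bl
from . import invasive as inv
from . import reference as ref
from . import reliability as rel
from .tacio import read_study_session, write_aif_tsv
from .timebase import DecayConstants, frame_midtimes

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("petquant")

_KNOWN_MODELS = ("1tc", "2tc", "logan", "srtm", "lref")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    study_dir: str
    output_dir: str
    reference_region: str = "cerebellum_white"
    models: tuple[str, ...] = ("1tc", "logan", "srtm", "lref")
    fp_mode: str = "TIME_VARYING"
    fp_late_threshold_min: float = 30.0
    t_star_min: float = 60.0
    #: reference-region clearance for the Logan reference plot:
    #: "auto" = per-session median of k2/R1 over the SRTM fits,
    #: a number = fixed value, None = omit the Cref/k2' term.
    k2_prime: float | str | None = "auto"
    weighting: str = "decay"  # decay | uniform
    grid_dt_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in _KNOWN_MODELS]
        if bad:
            raise ValueError(f"unknown models {bad}; known: {_KNOWN_MODELS}")
        if self.fp_mode not in ("TIME_VARYING", "LATE_MEAN"):
            raise ValueError(f"unknown fp_mode {self.fp_mode!r}")
        if self.weighting not in ("decay", "uniform"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if isinstance(self.k2_prime, str) and self.k2_prime != "auto":
            raise ValueError("k2_prime must be a number, 'auto', or null")
        if self.k2_prime == "auto" and "lref" in self.models and not (
            {"srtm", "1tc"} & set(self.models)
        ):
            raise ValueError(
                "k2_prime='auto' needs srtm or 1tc in the model list"
            )

    def to_dict(self) -> dict:
        return {
            "study_dir": str(self.study_dir),
            "output_dir": str(self.output_dir),
            "reference_region": self.reference_region,
            "models": list(self.models),
            "fp_mode": self.fp_mode,
            "fp_late_threshold_min": self.fp_late_threshold_min,
            "t_star_min": self.t_star_min,
            "k2_prime": self.k2_prime,
            "weighting": self.weighting,
            "grid_dt_min": self.grid_dt_min,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    return RunConfig(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    dvr_table: pd.DataFrame
    fit_table: pd.DataFrame
    trt_reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    regressions: pd.DataFrame | None = None
    pooled: dict[str, dict] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


def _discover_sessions(study_dir: Path) -> dict[tuple[str, str], Path]:
    out = {}
    for subj_dir in sorted(study_dir.glob("subject*")):
        for sess_dir in sorted(subj_dir.glob("session_*")):
            subject = subj_dir.name.removeprefix("subject")
            session = sess_dir.name.removeprefix("session_")
            out[(subject, session)] = sess_dir
    if not out:
        raise FileNotFoundError(f"no subject*/session_* directories in {study_dir}")
    return out


def _build_aif(blood_data, tac, config: RunConfig):
    bl.estimate_fwb(blood_data)
    ppf_fit = bl.fit_parent_fraction(blood_data.ppf_time, blood_data.ppf_fraction)
    fp_fun = bl.build_fp(
        blood_data.fp_time,
        blood_data.fp_fraction,
        mode=config.fp_mode,
        late_threshold_min=config.fp_late_threshold_min,
    )
    end = tac.schedule.ends_min[-1]
    grid = np.arange(0.0, end + config.grid_dt_min / 2.0, config.grid_dt_min)
    aif = bl.assemble_aif(
        blood_data, ppf_fit, fp_fun, grid, fp_mode=config.fp_mode
    )
    return aif, ppf_fit


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full quantification chain over a study directory."""
    t_start = time.time()
    study_dir = Path(config.study_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = _discover_sessions(study_dir)

    invasive_requested = any(m in config.models for m in ("1tc", "2tc", "logan"))
    if invasive_requested:
        missing = [
            str(d) for d in sessions.values() if not (d / "blood.tsv").exists()
        ]
        if missing:
            raise ValueError(
                "arterial models requested but blood.tsv missing in: "
                + ", ".join(missing)
            )

    result = PipelineResult(config=config, dvr_table=None, fit_table=None)
    fit_rows: list[dict] = []
    dvr_rows: list[dict] = []
    ref_1tc_k2: dict[tuple[str, str], float] = {}
    constants = DecayConstants()

    for (subject, session), sess_dir in sessions.items():
        stage_t = time.time()
        tac, blood_data = read_study_session(sess_dir)
        weights = (
            inv.default_frame_weights(tac.schedule, constants)
            if config.weighting == "decay"
            else np.ones(len(tac.schedule))
        )
        aif = None
        if blood_data is not None and invasive_requested:
            try:
                aif, ppf_fit = _build_aif(blood_data, tac, config)
                write_aif_tsv(
                    aif,
                    out_dir / f"aif_subject{subject}_{session}.tsv",
                    extra_meta={
                        "A0": ppf_fit.A0,
                        "T": ppf_fit.T,
                        "config_hash": config.config_hash(),
                    },
                )
            except Exception as exc:
                result.errors.append(
                    f"AIF construction failed for subject {subject} {session}: {exc}"
                )

        ref_values = (
            tac.region_values(config.reference_region)
            if config.reference_region in tac.regions
            else None
        )

        vt_by_region: dict[str, dict[str, float]] = {}
        srtm_k2p: list[float] = []
        for region in tac.regions:
            y = tac.region_values(region)
            if aif is not None:
                for model in ("1tc", "2tc"):
                    if model not in config.models:
                        continue
                    fitter = inv.fit_1tc if model == "1tc" else inv.fit_2tc
                    try:
                        params, gof = fitter(
                            y, aif, None, tac.schedule, weights,
                            dt_min=config.grid_dt_min,
                        )
                        row = {
                            "subject": subject, "session": session,
                            "region": region, "model": model,
                            "Vt": params.Vt if model == "1tc" or params.k4 > 0
                            else np.nan,
                            "ssr": gof.ssr, "aic": gof.aic, "n": gof.n,
                        }
                        for name in ("K1", "k2", "k3", "k4", "Vb"):
                            if hasattr(params, name):
                                row[name] = getattr(params, name)
                        if getattr(params, "identifiability_flags", ()):
                            row["flags"] = ";".join(params.identifiability_flags)
                        fit_rows.append(row)
                        vt_by_region.setdefault(region, {})[model] = row["Vt"]
                        if model == "1tc" and region == config.reference_region:
                            ref_1tc_k2[(subject, session)] = params.k2
                    except Exception as exc:
                        result.errors.append(
                            f"{model} fit failed: subject {subject} {session} "
                            f"{region}: {exc}"
                        )
                if "logan" in config.models:
                    try:
                        gr = inv.logan_vt(y, tac.schedule, aif, config.t_star_min)
                        fit_rows.append(
                            {
                                "subject": subject, "session": session,
                                "region": region, "model": "logan",
                                "Vt": gr.Vt, "r_squared": gr.r_squared,
                                "n": gr.n_points,
                            }
                        )
                        vt_by_region.setdefault(region, {})["logan"] = gr.Vt
                    except Exception as exc:
                        result.errors.append(
                            f"logan failed: subject {subject} {session} "
                            f"{region}: {exc}"
                        )
            if ref_values is not None and region != config.reference_region:
                if "srtm" in config.models:
                    try:
                        sr = ref.fit_srtm(
                            y, ref_values, tac.schedule, weights,
                            dt_min=config.grid_dt_min,
                        )
                        dvr_rows.append(
                            {
                                "subject": subject, "session": session,
                                "region": region, "method": "srtm",
                                "ref_region": config.reference_region,
                                "DVR": sr.DVR, "BP": sr.BP,
                                "R1": sr.R1, "k2": sr.k2,
                            }
                        )
                        if sr.R1 > 0:
                            srtm_k2p.append(sr.k2 / sr.R1)
                    except Exception as exc:
                        result.errors.append(
                            f"srtm failed: subject {subject} {session} "
                            f"{region}: {exc}"
                        )

        # LREF runs after the other models so that k2_prime='auto' can use
        # the best available reference-clearance estimate: the reference
        # region's own 1TC k2 when arterial data exist, otherwise the
        # session median of k2/R1 over the SRTM fits.
        if ref_values is not None and "lref" in config.models:
            if config.k2_prime == "auto":
                ref_fit_k2 = ref_1tc_k2.get((subject, session))
                if ref_fit_k2 is not None and ref_fit_k2 > 0:
                    k2_prime = ref_fit_k2
                elif srtm_k2p:
                    k2_prime = float(np.median(srtm_k2p))
                else:
                    k2_prime = None
            else:
                k2_prime = config.k2_prime
            for region in tac.regions:
                if region == config.reference_region:
                    continue
                try:
                    lr = ref.logan_ref(
                        tac.region_values(region), ref_values, tac.schedule,
                        t_star=config.t_star_min, k2_prime=k2_prime,
                    )
                    dvr_rows.append(
                        {
                            "subject": subject, "session": session,
                            "region": region, "method": "lref",
                            "ref_region": config.reference_region,
                            "DVR": lr.DVR, "BP": lr.BP,
                            "r_squared": lr.r_squared,
                            "k2_prime": k2_prime,
                        }
                    )
                except Exception as exc:
                    result.errors.append(
                        f"lref failed: subject {subject} {session} "
                        f"{region}: {exc}"
                    )

        # arterial DVRs: Vt ratios against the reference region
        for model in ("1tc", "2tc", "logan"):
            if model not in config.models:
                continue
            ref_vt = vt_by_region.get(config.reference_region, {}).get(model)
            if ref_vt is None or not np.isfinite(ref_vt) or ref_vt <= 0:
                continue
            for region, vts in vt_by_region.items():
                if region == config.reference_region or model not in vts:
                    continue
                vt = vts[model]
                if not np.isfinite(vt):
                    continue
                dvr = inv.dvr_from_vt(vt, ref_vt)
                dvr_rows.append(
                    {
                        "subject": subject, "session": session,
                        "region": region, "method": model,
                        "ref_region": config.reference_region,
                        "DVR": dvr, "BP": dvr - 1.0,
                    }
                )
        log.info(
            "subject %s %s processed in %.1f s",
            subject, session, time.time() - stage_t,
        )

    fit_table = pd.DataFrame(fit_rows)
    dvr_table = pd.DataFrame(dvr_rows)
    result.fit_table = fit_table
    result.dvr_table = dvr_table
    if not fit_table.empty:
        fit_table.to_csv(out_dir / "invasive_fits.tsv", sep="\t", index=False)
    if not dvr_table.empty:
        dvr_table.to_csv(out_dir / "dvr_table.tsv", sep="\t", index=False)

    # --- test-retest reliability per reference method ---------------------
    if not dvr_table.empty:
        have_sessions = set(dvr_table["session"])
        if {"test", "retest"} <= have_sessions:
            for method in ("srtm", "lref"):
                if method not in config.models:
                    continue
                sub = dvr_table[dvr_table["method"] == method]
                if sub.empty:
                    continue
                wide_t = sub[sub["session"] == "test"].pivot(
                    index="subject", columns="region", values="DVR"
                )
                wide_r = sub[sub["session"] == "retest"].pivot(
                    index="subject", columns="region", values="DVR"
                )
                common = wide_t.index.intersection(wide_r.index)
                wide_t, wide_r = wide_t.loc[common], wide_r.loc[common]
                if len(common) < 2:
                    continue
                report = rel.test_retest_report(wide_t, wide_r)
                report.to_csv(out_dir / f"test_retest_{method}.tsv", sep="\t")
                result.trt_reports[method] = report
                result.pooled[method] = rel.pooled_test_retest(wide_t, wide_r)
            if result.pooled:
                (out_dir / "test_retest_summary.json").write_text(
                    json.dumps(result.pooled, indent=1)
                )

    # --- reference-vs-arterial DVR regression (Table-4 layout) ------------
    if not dvr_table.empty and "1tc" in set(dvr_table["method"]):
        reg_rows = []
        base = dvr_table[dvr_table["method"] == "1tc"]
        for method in ("srtm", "lref"):
            sub = dvr_table[dvr_table["method"] == method]
            if sub.empty:
                continue
            for (subject, session), grp in sub.groupby(["subject", "session"]):
                b = base[(base["subject"] == subject) & (base["session"] == session)]
                merged = grp.merge(b, on="region", suffixes=("", "_1tc"))
                if len(merged) < 3:
                    continue
                try:
                    rr = rel.dvr_regression(
                        merged["DVR_1tc"].to_numpy(), merged["DVR"].to_numpy()
                    )
                except ValueError as exc:
                    result.errors.append(
                        f"regression failed: {method} subject {subject} "
                        f"{session}: {exc}"
                    )
                    continue
                reg_rows.append(
                    {
                        "method": method,
                        "ref_region": config.reference_region,
                        "subject": subject, "session": session,
                        "slope": rr.slope, "intercept": rr.intercept,
                        "r_squared": rr.r_squared, "n_regions": len(merged),
                    }
                )
        if reg_rows:
            regressions = pd.DataFrame(reg_rows)
            regressions.to_csv(
                out_dir / "dvr_regression_vs_1tc.tsv", sep="\t", index=False
            )
            summary = (
                regressions.groupby("method")[["slope", "intercept", "r_squared"]]
                .agg(["mean", "std"])
            )
            summary.to_csv(out_dir / "method_comparison.tsv", sep="\t")
            result.regressions = regressions

    effective = config.to_dict()
    effective["config_hash"] = config.config_hash()
    effective["runtime_s"] = round(time.time() - t_start, 2)
    effective["errors"] = result.errors
    (out_dir / "effective_config.yaml").write_text(yaml.safe_dump(effective))
    log.info("pipeline finished in %.1f s with %d errors",
             time.time() - t_start, len(result.errors))
    return result
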