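"""Plain-text file formats for TACs, blood data, and derived tables.

All on-disk times are seconds and fractions are percent (the units in
which acquisition tables are conventionally printed); in memory the
package uses minutes and unit fractions throughout.  Files are TSV with
'#'-prefixed metadata lines so they stay diff-able and self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .blood import BloodDataset, InputFunction
from .synthetic import FP_SAMPLE_TIMES_MIN, StudyBundle
from .timebase import (
    PART1,
    PART2,
    FrameSchedule,
    TimeActivityCurve,
)

__all__ = [
    "TacParseError",
    "read_tac_tsv",
    "write_tac_tsv",
    "read_blood_tsv",
    "write_blood_tsv",
    "read_fraction_tsv",
    "write_fraction_tsv",
    "write_aif_tsv",
    "write_study",
    "read_study_session",
]


class TacParseError(ValueError):
    """Malformed TAC/blood file; message carries the offending line."""


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _read_metadata(path: Path) -> tuple[dict[str, str], list[str], int]:
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            item = line.lstrip("#").strip()
            if "=" in item:
                key, _, val = item.partition("=")
                meta[key.strip()] = val.strip()
        elif line.strip():
            break
        else:
            body_start = i + 1
    return meta, lines[body_start:], body_start


def write_tac_tsv(tac: TimeActivityCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# reference_time_s={_fmt(tac.reference_time_s)}",
        "# units=kBq/mL",
    ]
    boundary = tac.schedule.part_boundary_s
    if boundary is not None:
        lines.append(f"# part_boundary_s={_fmt(boundary)}")
    lines.append("frame_start_s\tframe_end_s\t" + "\t".join(tac.regions))
    for i in range(len(tac.schedule)):
        row = [_fmt(tac.schedule.starts_s[i]), _fmt(tac.schedule.ends_s[i])]
        row += [_fmt(v) for v in tac.values[i]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_tac_tsv(path: str | Path) -> TimeActivityCurve:
    path = Path(path)
    meta, body, offset = _read_metadata(path)
    units = meta.get("units", "kBq/mL")
    if units != "kBq/mL":
        raise TacParseError(f"{path}: unsupported units {units!r} (expected kBq/mL)")
    if not body:
        raise TacParseError(f"{path}: no header line found")
    header = body[0].split("\t")
    if header[:2] != ["frame_start_s", "frame_end_s"]:
        raise TacParseError(
            f"{path}:{offset + 1}: header must start with "
            "'frame_start_s\\tframe_end_s'"
        )
    regions = tuple(header[2:])
    if not regions:
        raise TacParseError(f"{path}:{offset + 1}: no region columns")
    starts, ends, rows = [], [], []
    for k, line in enumerate(body[1:], start=offset + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise TacParseError(
                f"{path}:{k}: expected {len(header)} columns, got {len(parts)}"
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise TacParseError(f"{path}:{k}: {exc}") from None
        starts.append(vals[0])
        ends.append(vals[1])
        rows.append(vals[2:])
    boundary = float(meta["part_boundary_s"]) if "part_boundary_s" in meta else None
    starts_arr = np.asarray(starts)
    if boundary is None:
        labels = (PART1,) * len(starts)
    else:
        labels = tuple(
            PART2 if s >= boundary - 1e-9 else PART1 for s in starts_arr
        )
    try:
        schedule = FrameSchedule(
            starts_s=starts_arr, ends_s=np.asarray(ends), part_labels=labels
        )
        return TimeActivityCurve(
            schedule=schedule,
            regions=regions,
            values=np.asarray(rows),
            reference_time_s=float(meta.get("reference_time_s", 0.0)),
            noise_floor=float(meta.get("noise_floor", 5.0)),
        )
    except ValueError as exc:
        raise TacParseError(f"{path}: {exc}") from None


def write_blood_tsv(dataset: BloodDataset, path: str | Path) -> None:
    """Whole-blood (and paired plasma, where sampled) activities; seconds."""
    lines = ["time_s\tcwb_kBq_mL\tcp_kBq_mL"]
    plasma = dict(zip(np.round(dataset.plasma_time * 60.0, 6), dataset.plasma_activity))
    for t, c in zip(dataset.wb_time, dataset.wb_activity):
        cp = plasma.get(round(t * 60.0, 6))
        lines.append(
            "\t".join([_fmt(t * 60.0), _fmt(c), _fmt(cp) if cp is not None else "NA"])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_blood_tsv(path: str | Path) -> BloodDataset:
    path = Path(path)
    _, body, offset = _read_metadata(path)
    if not body or not body[0].startswith("time_s\tcwb_kBq_mL"):
        raise TacParseError(f"{path}: expected header 'time_s\\tcwb_kBq_mL[...]'")
    has_cp = body[0].split("\t")[2:] == ["cp_kBq_mL"]
    t, cwb, tp, cp = [], [], [], []
    for k, line in enumerate(body[1:], start=offset + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            tv, cv = float(parts[0]) / 60.0, float(parts[1])
        except (ValueError, IndexError) as exc:
            raise TacParseError(f"{path}:{k}: {exc}") from None
        t.append(tv)
        cwb.append(cv)
        if has_cp and len(parts) > 2 and parts[2] not in ("", "NA"):
            tp.append(tv)
            cp.append(float(parts[2]))
    return BloodDataset(
        wb_time=np.asarray(t),
        wb_activity=np.asarray(cwb),
        plasma_time=np.asarray(tp),
        plasma_activity=np.asarray(cp),
    )


def write_fraction_tsv(
    times_min: np.ndarray, fractions: np.ndarray, path: str | Path
) -> None:
    """Fractions stored as percent, times as seconds."""
    lines = ["time_s\tfraction_percent"]
    for t, f in zip(times_min, fractions):
        lines.append(f"{_fmt(t * 60.0)}\t{_fmt(f * 100.0)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fraction_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    _, body, offset = _read_metadata(path)
    if not body or body[0] != "time_s\tfraction_percent":
        raise TacParseError(f"{path}: expected header 'time_s\\tfraction_percent'")
    t, f = [], []
    for k, line in enumerate(body[1:], start=offset + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            t.append(float(parts[0]) / 60.0)
            f.append(float(parts[1]) / 100.0)
        except (ValueError, IndexError) as exc:
            raise TacParseError(f"{path}:{k}: {exc}") from None
    return np.asarray(t), np.asarray(f)


def write_aif_tsv(aif: InputFunction, path: str | Path, extra_meta: dict | None = None) -> None:
    meta = {"fwb": aif.fwb, "fp_mode": aif.fp_mode}
    if extra_meta:
        meta.update(extra_meta)
    lines = [f"# {k}={v}" for k, v in meta.items()]
    lines.append("time_s\taif_kBq_mL\tcwb_kBq_mL")
    for t, a, c in zip(aif.grid_min, aif.aif, aif.cwb):
        lines.append(f"{_fmt(t * 60.0)}\t{_fmt(a)}\t{_fmt(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_study(bundle: StudyBundle, out_dir: str | Path) -> Path:
    """Write a generated study as a directory tree of TSV files.

    Layout: ``subject<i>/session_<test|retest>/{tacs,blood,
    parent_fraction,fp}.tsv`` plus ``ground_truth.json`` and the
    effective configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (subj, session), tac in bundle.tacs.items():
        d = out / f"subject{subj}" / f"session_{session}"
        d.mkdir(parents=True, exist_ok=True)
        write_tac_tsv(tac, d / "tacs.tsv")
        blood = bundle.blood[(subj, session)]
        write_blood_tsv(blood, d / "blood.tsv")
        write_fraction_tsv(blood.ppf_time, blood.ppf_fraction, d / "parent_fraction.tsv")
        write_fraction_tsv(blood.fp_time, blood.fp_fraction, d / "fp.tsv")
    truth = {
        "regions": bundle.ground_truth["regions"],
        "subjects": {
            str(i): rec for i, rec in bundle.ground_truth["subjects"].items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    cfg = bundle.config
    cfg_dict = {
        "n_subjects": cfg.n_subjects,
        "regions": list(cfg.regions),
        "between_cv": cfg.between_cv,
        "within_cv": cfg.within_cv,
        "noise_scale": cfg.noise_scale,
        "blood_noise": cfg.blood_noise,
        "seed": cfg.seed,
    }
    (out / "study_config.json").write_text(json.dumps(cfg_dict, indent=1))
    return out


def read_study_session(session_dir: str | Path):
    """Read one subject-session directory back into memory.

    Returns (TimeActivityCurve, BloodDataset-with-fractions or None).
    """
    d = Path(session_dir)
    tac = read_tac_tsv(d / "tacs.tsv")
    blood = None
    if (d / "blood.tsv").exists():
        blood = read_blood_tsv(d / "blood.tsv")
        if (d / "parent_fraction.tsv").exists():
            t, f = read_fraction_tsv(d / "parent_fraction.tsv")
            blood.ppf_time, blood.ppf_fraction = t, f
        if (d / "fp.tsv").exists():
            t, f = read_fraction_tsv(d / "fp.tsv")
            blood.fp_time, blood.fp_fraction = t, f
    return tac, blood
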