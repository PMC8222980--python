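"""CSV schemas, study configuration and the end-to-end pipeline.

All inputs and outputs are plain delimited text (UTF-8, `.` decimal,
header required).  Schemas:

  curves       sample_id,treatment,conc_ug_ml,replicate,clot_time_s,censored
  plate        well,role,venom_id,replicate,time_s,rfu
  inhibition   venom_id,factor,replicate,clot_time_s,control_time_s
  teg          trace_id,time_s,amplitude_mm
  summary      group,n,mean,sd

The study configuration is a flat ``key = value`` text file (``#``
comments and blank lines ignored); :func:`run_pipeline` runs every stage
whose input path is configured, writes output CSVs plus a machine-
readable run manifest (config hash, seed, version, output hashes), and
preserves partial outputs when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activation import ROLES, FluorescencePlate, FluorescenceTrace, summarize_plate
from .assay import DEFAULT_CEILING_S, ClottingMeasurement, ConcentrationCurve
from .auc import ShiftResult, curve_auc, shift_with_replicates
from .errors import CoagKitError, ConfigError, ParseError
from .inhibition import (
    DEFAULT_INHIBITION_THRESHOLD,
    InhibitionMeasurement,
    inhibition_profile,
)
from .stats import GroupSummary, anova_from_summary, pairwise_table, tukey_pairwise
from .teg import TEGTrace, extract_teg_params

log = logging.getLogger("coagkit")

CURVE_COLUMNS = ["sample_id", "treatment", "conc_ug_ml", "replicate",
                 "clot_time_s", "censored"]
PLATE_COLUMNS = ["well", "role", "venom_id", "replicate", "time_s", "rfu"]
INHIBITION_COLUMNS = ["venom_id", "factor", "replicate", "clot_time_s",
                      "control_time_s"]
TEG_COLUMNS = ["trace_id", "time_s", "amplitude_mm"]
SUMMARY_COLUMNS = ["group", "n", "mean", "sd"]


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise ParseError(str(exc), path=path) from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s) {missing}", line=1, path=path)
    return df


def _num(df: pd.DataFrame, row: int, col: str, path, kind=float):
    raw = df.at[row, col]
    try:
        return kind(raw)
    except (TypeError, ValueError):
        # +2: header line plus 1-based numbering
        raise ParseError(f"non-numeric value {raw!r} in column {col!r}",
                         line=row + 2, path=path) from None


def read_curve_table(path, ceiling_s: float = DEFAULT_CEILING_S
                     ) -> list[ConcentrationCurve]:
    """Read clotting curves, grouped by (sample_id, treatment)."""
    df = _read_table(path, CURVE_COLUMNS)
    curves: dict[tuple[str, str], ConcentrationCurve] = {}
    for i in range(len(df)):
        cens_raw = df.at[i, "censored"]
        if cens_raw not in ("0", "1"):
            raise ParseError(f"censored flag must be 0 or 1, got {cens_raw!r}",
                             line=i + 2, path=path)
        key = (df.at[i, "sample_id"], df.at[i, "treatment"])
        curve = curves.setdefault(key, ConcentrationCurve(
            sample_id=key[0], treatment=key[1], ceiling_s=ceiling_s))
        curve.measurements.append(ClottingMeasurement(
            concentration=_num(df, i, "conc_ug_ml", path),
            replicate=_num(df, i, "replicate", path, int),
            time_s=_num(df, i, "clot_time_s", path),
            censored=cens_raw == "1"))
    return list(curves.values())


def write_curve_table(curves: list[ConcentrationCurve], path) -> None:
    pd.concat([c.to_frame() for c in curves], ignore_index=True) \
        .to_csv(path, index=False)


def read_plate_table(path, target: str = "FX") -> FluorescencePlate:
    df = _read_table(path, PLATE_COLUMNS)
    traces = []
    for (well, role, venom_id, rep), sub in df.groupby(
            ["well", "role", "venom_id", "replicate"], sort=False):
        if role not in ROLES:
            row = int(sub.index[0])
            raise ParseError(f"unknown well role {role!r}", line=row + 2, path=path)
        times = np.array([_num(df, int(i), "time_s", path) for i in sub.index])
        rfu = np.array([_num(df, int(i), "rfu", path) for i in sub.index])
        order = np.argsort(times)
        traces.append(FluorescenceTrace(
            well=well, role=role, times_s=times[order], rfu=rfu[order],
            venom_id=venom_id or None, replicate=int(rep)))
    return FluorescencePlate(traces=traces, target=target)


def write_plate_table(plate: FluorescencePlate, path) -> None:
    rows = []
    for tr in plate.traces:
        for t, r in zip(tr.times_s, tr.rfu):
            rows.append({"well": tr.well, "role": tr.role,
                         "venom_id": tr.venom_id or "", "replicate": tr.replicate,
                         "time_s": t, "rfu": r})
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_inhibition_table(path) -> list[InhibitionMeasurement]:
    df = _read_table(path, INHIBITION_COLUMNS)
    grouped: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
    for i in range(len(df)):
        key = (df.at[i, "venom_id"], df.at[i, "factor"])
        grouped.setdefault(key, []).append((
            _num(df, i, "replicate", path, int),
            _num(df, i, "clot_time_s", path),
            _num(df, i, "control_time_s", path)))
    out = []
    for (venom_id, factor), rows in grouped.items():
        rows.sort()
        out.append(InhibitionMeasurement(
            venom_id=venom_id, factor=factor,
            times_with_venom_s=tuple(r[1] for r in rows),
            times_control_s=tuple(r[2] for r in rows)))
    return out


def read_teg_table(path) -> dict[str, TEGTrace]:
    df = _read_table(path, TEG_COLUMNS)
    traces = {}
    for trace_id, sub in df.groupby("trace_id", sort=False):
        times = np.array([_num(df, int(i), "time_s", path) for i in sub.index])
        amp = np.array([_num(df, int(i), "amplitude_mm", path) for i in sub.index])
        order = np.argsort(times)
        traces[trace_id] = TEGTrace(times_s=times[order], amplitude_mm=amp[order])
    return traces


def write_teg_table(traces: dict[str, TEGTrace], path) -> None:
    rows = []
    for trace_id, tr in traces.items():
        for t, a in zip(tr.times_s, tr.amplitude_mm):
            rows.append({"trace_id": trace_id, "time_s": t, "amplitude_mm": a})
    pd.DataFrame(rows, columns=TEG_COLUMNS).to_csv(path, index=False)


def read_summary_table(path) -> list[GroupSummary]:
    df = _read_table(path, SUMMARY_COLUMNS)
    return [GroupSummary(label=df.at[i, "group"],
                         n=_num(df, i, "n", path, int),
                         mean=_num(df, i, "mean", path),
                         sd=_num(df, i, "sd", path))
            for i in range(len(df))]


def shift_table(results: list[ShiftResult],
                auc_results) -> pd.DataFrame:
    """Assemble the output shift CSV from paired shift and treated-AUC results."""
    rows = []
    for shift, auc in zip(results, auc_results):
        rows.append({
            "sample_id": shift.sample_id, "treatment": shift.treatment,
            "auc_mean": auc.mean, "auc_sd": auc.sd,
            "shift_mean": shift.mean, "shift_sd": shift.sd,
            "verdict": shift.verdict,
            "censored_fraction": auc.censored_fraction,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study configuration and pipeline

KNOWN_KEYS = {
    "curves", "plate", "inhibition", "teg", "summary", "out_dir",
    "ceiling", "alpha", "auc_axis", "activation_scalar",
    "inhibition_threshold", "shift_tolerance", "plate_target", "seed",
}


@dataclass
class StudyConfig:
    """Paths and parameters of one analysis run; every default overridable."""

    curves: Path | None = None
    plate: Path | None = None
    inhibition: Path | None = None
    teg: Path | None = None
    summary: Path | None = None
    out_dir: Path = Path("coagkit-out")
    ceiling: float = DEFAULT_CEILING_S
    alpha: float = 0.05
    auc_axis: str = "linear"
    activation_scalar: str = "auc"
    inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD
    shift_tolerance: float = 0.0
    plate_target: str = "FX"
    seed: int = 0
    raw_text: str = field(default="", repr=False)


def parse_config(path) -> StudyConfig:
    """Parse a flat ``key = value`` configuration file."""
    text = Path(path).read_text(encoding="utf-8")
    values: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = stripped.partition("=")
        key = key.strip()
        if key not in KNOWN_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
        values[key] = value.strip()
    cfg = StudyConfig(raw_text=text)
    base = Path(path).parent
    for key in ("curves", "plate", "inhibition", "teg", "summary"):
        if key in values:
            setattr(cfg, key, base / values[key])
    if "out_dir" in values:
        cfg.out_dir = base / values["out_dir"]
    for key, kind in (("ceiling", float), ("alpha", float),
                      ("inhibition_threshold", float),
                      ("shift_tolerance", float), ("seed", int)):
        if key in values:
            setattr(cfg, key, kind(values[key]))
    for key in ("auc_axis", "activation_scalar", "plate_target"):
        if key in values:
            setattr(cfg, key, values[key])
    return cfg


@dataclass
class PipelineResult:
    out_dir: Path
    stages: dict[str, str]    # stage -> "ok" | "skipped" | error text
    outputs: dict[str, Path]
    exit_status: int
    manifest_path: Path | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_curves(cfg: StudyConfig, out: Path, outputs: dict[str, Path]) -> None:
    curves = read_curve_table(cfg.curves, ceiling_s=cfg.ceiling)
    aucs = [curve_auc(c, axis=cfg.auc_axis) for c in curves]
    auc_rows = [{"sample_id": a.sample_id, "treatment": a.treatment,
                 "auc_mean": a.mean, "auc_sd": a.sd,
                 "censored_fraction": a.censored_fraction} for a in aucs]
    auc_path = out / "auc.csv"
    pd.DataFrame(auc_rows).to_csv(auc_path, index=False)
    outputs["auc"] = auc_path

    by_sample: dict[str, dict[str, ConcentrationCurve]] = {}
    for c in curves:
        by_sample.setdefault(c.sample_id, {})[c.treatment] = c
    shifts, treated_aucs = [], []
    for sample_id, group in by_sample.items():
        venom = group.get("none")
        if venom is None:
            continue
        for treatment, treated in group.items():
            if treatment == "none":
                continue
            shifts.append(shift_with_replicates(
                venom, treated, axis=cfg.auc_axis, tolerance=cfg.shift_tolerance))
            treated_aucs.append(curve_auc(treated, axis=cfg.auc_axis))
    shift_path = out / "shift.csv"
    shift_table(shifts, treated_aucs).to_csv(shift_path, index=False)
    outputs["shift"] = shift_path
    log.info("curves stage: %d curves in, %d shifts out", len(curves), len(shifts))


def _stage_plate(cfg: StudyConfig, out: Path, outputs: dict[str, Path]) -> None:
    plate = read_plate_table(cfg.plate, target=cfg.plate_target)
    results = summarize_plate(plate, scalar=cfg.activation_scalar)
    path = out / "activation.csv"
    pd.DataFrame([{"venom_id": r.venom_id, "target": r.target,
                   "percent_mean": r.mean, "percent_sd": r.sd,
                   "n": len(r.replicate_percent)} for r in results]
                 ).to_csv(path, index=False)
    outputs["activation"] = path
    log.info("plate stage: %d wells in, %d venoms out", len(plate.traces),
             len(results))


def _stage_inhibition(cfg: StudyConfig, out: Path, outputs: dict[str, Path]) -> None:
    measurements = read_inhibition_table(cfg.inhibition)
    by_venom: dict[str, list[InhibitionMeasurement]] = {}
    for m in measurements:
        by_venom.setdefault(m.venom_id, []).append(m)
    frames = []
    for venom_id, ms in by_venom.items():
        table, call = inhibition_profile(ms, threshold=cfg.inhibition_threshold)
        table["call"] = call if call is not None else ""
        frames.append(table)
    path = out / "inhibition.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    outputs["inhibition"] = path
    log.info("inhibition stage: %d measurements in", len(measurements))


def _stage_teg(cfg: StudyConfig, out: Path, outputs: dict[str, Path]) -> None:
    traces = read_teg_table(cfg.teg)
    rows = []
    for trace_id, trace in traces.items():
        p = extract_teg_params(trace)
        rows.append({"trace_id": trace_id, "SP_s": p.SP_s, "R_s": p.R_s,
                     "MA_mm": p.MA_mm, "MRTG": p.MRTG,
                     "TMRTG_min": p.TMRTG_min, "TGG": p.TGG})
    path = out / "teg_params.csv"
    pd.DataFrame(rows).to_csv(path, index=False)  # None -> empty field
    outputs["teg"] = path
    log.info("teg stage: %d traces in", len(traces))


def _stage_anova(cfg: StudyConfig, out: Path, outputs: dict[str, Path]) -> None:
    summaries = read_summary_table(cfg.summary)
    anova = anova_from_summary(summaries)
    pairs = tukey_pairwise(summaries, alpha=cfg.alpha)
    anova_path = out / "anova.json"
    anova_path.write_text(json.dumps({
        "F": anova.F, "df_between": anova.df_between,
        "df_within": anova.df_within, "p": anova.p, "alpha": cfg.alpha,
    }, indent=2))
    outputs["anova"] = anova_path
    pairwise_path = out / "pairwise.csv"
    pairwise_table(pairs).to_csv(pairwise_path, index=False)
    outputs["pairwise"] = pairwise_path
    log.info("anova stage: %d groups, %d pairs", len(summaries), len(pairs))


_STAGES = {
    "curves": _stage_curves,
    "plate": _stage_plate,
    "inhibition": _stage_inhibition,
    "teg": _stage_teg,
    "anova": _stage_anova,
}
_STAGE_INPUT = {"curves": "curves", "plate": "plate", "inhibition": "inhibition",
                "teg": "teg", "anova": "summary"}


def run_pipeline(cfg: StudyConfig) -> PipelineResult:
    """Run every configured stage; failures leave partial outputs in place.

    Exit status: 0 when all configured stages succeed, 1 when a stage's
    input fails validation/parsing, 2 when some stages succeeded and
    others failed.  Writes ``manifest.json`` recording the config hash,
    seed, package version and a SHA-256 per output, so identical
    configurations can be verified to give identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    outputs: dict[str, Path] = {}
    n_failed = n_ok = 0
    for name, fn in _STAGES.items():
        if getattr(cfg, _STAGE_INPUT[name]) is None:
            stages[name] = "skipped"
            continue
        try:
            fn(cfg, out, outputs)
            stages[name] = "ok"
            n_ok += 1
        except (CoagKitError, FileNotFoundError) as exc:
            log.error("stage %s failed: %s", name, exc)
            stages[name] = f"failed: {exc}"
            n_failed += 1
    if n_failed == 0:
        status = 0
    elif n_ok > 0:
        status = 2
    else:
        status = 1
    manifest = {
        "coagkit_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.raw_text.encode()).hexdigest(),
        "stages": stages,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in outputs.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return PipelineResult(out_dir=out, stages=stages, outputs=outputs,
                          exit_status=status, manifest_path=manifest_path)
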