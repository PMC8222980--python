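"""Synthetic study scenarios: one configuration file, a full set of CSVs.

A scenario is a flat ``key = value`` file describing a synthetic study
(venoms × treatments × assays × seed).  :func:`simulate_scenario` writes
the exact CSV schemas the analysis stages read, so a scenario plus a
study configuration exercises the entire pipeline end to end with known
ground truth.

Recognized keys (all optional):

  seed          master random seed (default 0)
  replicates    replicates per condition (default 3)
  venoms        comma-separated venom ids (default three synthetic venoms)
  treatments    comma-separated ``label:efficacy`` pairs
                (default ``antivenom:0.9,failed_treatment:0.0``)
  assays        any of curves,plate,teg,inhibition (default all)
  out_dir       output directory (default alongside the scenario file)

Per-venom ground truth is derived deterministically from the master
seed: EC50s are log-spaced across the standard concentration range and
activation rates span a 4-fold range, so downstream rankings have a
known right answer.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import INHIBITION_COLUMNS, write_curve_table, write_plate_table, write_teg_table
from .simulate import (
    ActivationSimParams,
    ClotSimParams,
    TEGSimParams,
    TreatmentSimParams,
    simulate_clotting_curve,
    simulate_fluorescence_plate,
    simulate_neutralized_curve,
    simulate_teg_trace,
)

_DEFAULT_VENOMS = ("venom_A", "venom_B", "venom_C")
_DEFAULT_TREATMENTS = (("antivenom", 0.9), ("failed_treatment", 0.0))
_ALL_ASSAYS = ("curves", "plate", "teg", "inhibition")

_KEYS = {"seed", "replicates", "venoms", "treatments", "assays", "out_dir"}


def parse_scenario(path) -> dict:
    """Parse a scenario file into a plain dict of settings."""
    settings: dict = {
        "seed": 0, "replicates": 3,
        "venoms": list(_DEFAULT_VENOMS),
        "treatments": list(_DEFAULT_TREATMENTS),
        "assays": list(_ALL_ASSAYS),
        "out_dir": Path(path).parent,
    }
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = stripped.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown scenario key {key!r}")
        if key in ("seed", "replicates"):
            settings[key] = int(value)
        elif key == "venoms":
            settings[key] = [v.strip() for v in value.split(",") if v.strip()]
        elif key == "treatments":
            pairs = []
            for item in value.split(","):
                if not item.strip():
                    continue
                label, _, eff = item.partition(":")
                pairs.append((label.strip(), float(eff)))
            settings[key] = pairs
        elif key == "assays":
            assays = [a.strip() for a in value.split(",") if a.strip()]
            unknown = set(assays) - set(_ALL_ASSAYS)
            if unknown:
                raise ConfigError(f"{path}:{lineno}: unknown assay(s) {unknown}")
            settings[key] = assays
        elif key == "out_dir":
            settings[key] = Path(path).parent / value
    return settings


def _venom_ground_truth(venoms: list[str], seed: int) -> dict[str, dict]:
    """Deterministic per-venom parameters spanning the assay's dynamic range."""
    n = len(venoms)
    ec50 = np.geomspace(0.2, 4.0, n) if n > 1 else np.array([0.5])
    k_act = np.geomspace(2e-3, 5e-4, n) if n > 1 else np.array([1e-3])
    fxa_inhibition = np.linspace(1.5, 0.8, n) if n > 1 else np.array([1.0])
    return {v: {"ec50": float(ec50[i]), "k_act": float(k_act[i]),
                "fxa_shift": float(fxa_inhibition[i]),
                "seed": seed * 1009 + i}
            for i, v in enumerate(venoms)}


def simulate_scenario(settings: dict) -> dict[str, Path]:
    """Generate every configured assay's CSV; returns {assay: path}."""
    out_dir = Path(settings["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(settings["seed"]) % (2**31 - 1)
    reps = int(settings["replicates"])
    truth = _venom_ground_truth(settings["venoms"], seed)
    written: dict[str, Path] = {}

    if "curves" in settings["assays"]:
        curves = []
        for venom_id, gt in truth.items():
            p = ClotSimParams(ec50_ug_ml=gt["ec50"], seed=gt["seed"])
            curves.append(simulate_clotting_curve(p, replicates=reps,
                                                  sample_id=venom_id))
            for label, eff in settings["treatments"]:
                t = TreatmentSimParams(label=label, efficacy=eff)
                curves.append(simulate_neutralized_curve(
                    p, t, replicates=reps, sample_id=venom_id))
        path = out_dir / "curves.csv"
        write_curve_table(curves, path)
        written["curves"] = path

    if "plate" in settings["assays"]:
        p = ActivationSimParams(noise_sd=2.0, seed=seed + 1)
        plate = simulate_fluorescence_plate(
            p, {v: gt["k_act"] for v, gt in truth.items()}, replicates=reps)
        path = out_dir / "plate.csv"
        write_plate_table(plate, path)
        written["plate"] = path

    if "teg" in settings["assays"]:
        traces = {}
        rng = np.random.default_rng(seed + 2)
        for venom_id in truth:
            for rep in range(1, reps + 1):
                p = TEGSimParams(ma_mm=float(rng.uniform(40, 70)),
                                 rate=float(rng.uniform(0.005, 0.02)),
                                 lag_s=float(rng.uniform(60, 240)),
                                 noise_sd=0.1,
                                 seed=int(rng.integers(2**31 - 1)))
                traces[f"{venom_id}-r{rep}"] = simulate_teg_trace(p)
        path = out_dir / "teg.csv"
        write_teg_table(traces, path)
        written["teg"] = path

    if "inhibition" in settings["assays"]:
        rng = np.random.default_rng(seed + 3)
        rows = []
        for venom_id, gt in truth.items():
            for factor in ("thrombin", "FIXa", "FXa", "FXIa", "FXIIa"):
                shift = gt["fxa_shift"] if factor == "FXa" else 0.0
                for rep in range(1, reps + 1):
                    control = 500.0 * float(rng.lognormal(0, 0.02))
                    with_v = control * (1.0 + shift) * float(rng.lognormal(0, 0.02))
                    rows.append({"venom_id": venom_id, "factor": factor,
                                 "replicate": rep,
                                 "clot_time_s": round(with_v, 3),
                                 "control_time_s": round(control, 3)})
        path = out_dir / "inhibition.csv"
        pd.DataFrame(rows, columns=INHIBITION_COLUMNS).to_csv(path, index=False)
        written["inhibition"] = path

    return written
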