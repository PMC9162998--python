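"""Run configuration, table readers/writers and test-fixture generation.

Run artifacts are plain text: the per-step log is a comma-separated table
(header row, '.' decimal, UTF-8, one row per control step) and every run
writes a YAML sidecar holding the resolved configuration, its hash, the seed
and the targets, so any table can be re-scored later without the original
command line.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controllers import VolumeControllerConfig
from .equilibrium import (
    DomainError,
    HemodynamicState,
    ModelConstants,
    estimate_parameters,
)
from .metrics import (
    AP_MARGIN,
    P_LA_MARGIN,
    PE_WINDOW,
    MetricsReport,
    summarize,
)
from .patient import (
    FurosemideParams,
    NoiseParams,
    PatientConfig,
    PDParams,
    PKParams,
    ProtocolConfig,
    RunResult,
    make_hf_patient,
    run_closed_loop,
)

__all__ = [
    "RunConfig",
    "REQUIRED_STATE_COLUMNS",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "save_config",
    "config_hash",
    "read_table",
    "write_run",
    "read_run_meta",
    "simulate_from_config",
    "estimate_table",
    "metrics_from_table",
    "report_text",
    "make_fixtures",
]

REQUIRED_STATE_COLUMNS = ("t", "AP", "CO", "P_LA", "P_RA")


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of one closed-loop run."""

    constants: ModelConstants = field(default_factory=ModelConstants)
    patient: PatientConfig = field(default_factory=PatientConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    seed: int = 1
    body_weight_kg: float = 20.0  # for absolute-dose bookkeeping only


def config_from_dict(d: dict) -> RunConfig:
    """Build a :class:`RunConfig` from nested plain dictionaries."""
    d = dict(d or {})
    pat = dict(d.get("patient") or {})
    sub = {}
    for key, cls in (("pk", PKParams), ("pd", PDParams),
                     ("furo", FurosemideParams), ("noise", NoiseParams)):
        if key in pat:
            sub[key] = cls(**pat.pop(key))
    proto = dict(d.get("protocol") or {})
    if "volume" in proto:
        proto["volume"] = VolumeControllerConfig(**proto.pop("volume"))
    return RunConfig(
        constants=ModelConstants(**(d.get("constants") or {})),
        patient=PatientConfig(**pat, **sub),
        protocol=ProtocolConfig(**proto),
        seed=int(d.get("seed", 1)),
        body_weight_kg=float(d.get("body_weight_kg", 20.0)),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_table(path: str | Path, require: tuple[str, ...] = REQUIRED_STATE_COLUMNS
               ) -> pd.DataFrame:
    """Read a hemodynamic time-series table, checking required columns."""
    df = pd.read_csv(path)
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} is missing required column(s): {missing}")
    return df


def _meta_path(table_path: str | Path) -> Path:
    return Path(table_path).with_suffix(".meta.yaml")


def simulate_from_config(cfg: RunConfig) -> RunResult:
    """Build the virtual patient and run the closed loop described by ``cfg``."""
    patient = make_hf_patient(cfg.patient, cfg.constants, seed=cfg.seed)
    return run_closed_loop(patient, cfg.protocol, seed=cfg.seed)


def write_run(result: RunResult, cfg: RunConfig, out: str | Path) -> Path:
    """Write the run table as CSV plus a YAML sidecar with config and targets.

    Returns the sidecar path.  Identical config+seed produce byte-identical
    files.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out, index=False)
    from . import __version__

    last = result.table.iloc[-1]
    meta = {
        "package_version": __version__,
        "seed": result.seed,
        "config_hash": config_hash(cfg),
        "config": config_to_dict(cfg),
        "targets": {
            "AP_star": float(result.targets.AP_star),
            "P_LA_star": float(result.targets.P_LA_star),
            "S_L_star": float(result.targets.S_L_star),
            "V_star": float(result.targets.V_star),
            "CO_star": float(result.targets.CO_star),
            "P_RA_star": float(result.targets.P_RA_star),
            "clamped_AP": bool(result.targets.clamped_AP),
            "clamped_P_LA": bool(result.targets.clamped_P_LA),
        },
        "baseline_estimate": asdict(result.baseline),
        "cumulative_doses": {
            "landiolol_ug_per_kg": float(last["cum_landiolol"]),
            "dextran_ml_per_kg": float(last["cum_dextran"]),
            "dextran_ml_absolute": float(last["cum_dextran"]) * cfg.body_weight_kg,
            "furosemide_mg": float(last["cum_furosemide"]),
        },
    }
    meta_path = _meta_path(out)
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return meta_path


def read_run_meta(table_path: str | Path) -> dict:
    with open(_meta_path(table_path), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def estimate_table(df: pd.DataFrame, constants: ModelConstants) -> pd.DataFrame:
    """Append per-row equilibrium-parameter columns (S_L, S_R, R, V).

    Rows violating the estimation domain (e.g. preload at or below the curve
    offset) are kept, flagged in an ``estimation_flag`` column with NaN
    parameters, never silently dropped.
    """
    out = df.copy()
    cols = {"S_L": [], "S_R": [], "R": [], "V": [], "estimation_flag": []}
    for row in df.itertuples(index=False):
        state = HemodynamicState(
            t=float(row.t), AP=float(row.AP), CO=float(row.CO),
            P_LA=float(row.P_LA), P_RA=float(row.P_RA),
        )
        try:
            p = estimate_parameters(state, constants)
            vals = (p.S_L, p.S_R, p.R, p.V, "ok")
        except DomainError as exc:
            vals = (np.nan, np.nan, np.nan, np.nan, f"domain_error: {exc}")
        for c, v in zip(cols, vals):
            cols[c].append(v)
    for c, v in cols.items():
        out[c] = v
    return out


def metrics_from_table(
    df: pd.DataFrame,
    ap_target: float,
    pla_target: float,
    window: tuple[float, float] = PE_WINDOW,
) -> dict[str, MetricsReport]:
    """Score AP and P_LA columns of a run table against their targets."""
    t = df["t"].to_numpy(dtype=float)
    return {
        "AP": summarize(t, df["AP"].to_numpy(dtype=float), ap_target,
                        "AP", "lower_bound", AP_MARGIN, window),
        "P_LA": summarize(t, df["P_LA"].to_numpy(dtype=float), pla_target,
                          "P_LA", "upper_bound", P_LA_MARGIN, window),
    }


def report_text(reports: dict[str, MetricsReport]) -> str:
    """Human-readable metrics table, one row per controlled signal."""
    hdr = (f"{'signal':<8}{'in-range %':>12}{'MDAPE %':>10}{'MDPE %':>10}"
           f"{'wobble %':>10}{'divergence %/min':>18}")
    lines = [hdr, "-" * len(hdr)]
    for name, r in reports.items():
        lines.append(
            f"{name:<8}{r.time_in_range:>12.1f}{r.MDAPE:>10.2f}{r.MDPE:>10.2f}"
            f"{r.wobble:>10.2f}{r.divergence:>18.4f}"
        )
    lines.append(f"PE window: {reports[next(iter(reports))].window} min; "
                 "in-range scored on all samples")
    return "\n".join(lines)


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the small canned inputs used by the test suite (deterministic).

    * ``pe_series.csv`` — a hand-computable PE series (t 1..5 min with
      |PE| = 10 - 0.1 t, plus the [1, 2, 9] triplet at t 6..8);
    * ``states.csv`` — five valid hemodynamic states straddling the
      heart-failure baseline;
    * ``mini_run.csv``/``.meta.yaml`` — a 5-minute closed-loop run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t = np.arange(1, 9, dtype=float)
    pe = np.concatenate([10.0 - 0.1 * np.arange(1, 6), [1.0, 2.0, 9.0]])
    pe_df = pd.DataFrame({"t": t, "pe": pe})
    paths["pe_series"] = outdir / "pe_series.csv"
    pe_df.to_csv(paths["pe_series"], index=False)

    rng = np.random.default_rng(seed)
    base = PatientConfig()
    rows = []
    for i in range(5):
        f = 1.0 + 0.05 * rng.standard_normal()
        rows.append({
            "t": float(i), "AP": base.AP * f, "CO": base.CO * f,
            "P_LA": base.P_LA * f, "P_RA": base.P_RA * f, "HR": base.HR,
        })
    paths["states"] = outdir / "states.csv"
    pd.DataFrame(rows).to_csv(paths["states"], index=False)

    cfg = RunConfig(seed=seed, protocol=ProtocolConfig(duration=5.0))
    result = simulate_from_config(cfg)
    paths["mini_run"] = outdir / "mini_run.csv"
    write_run(result, cfg, paths["mini_run"])
    return paths
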