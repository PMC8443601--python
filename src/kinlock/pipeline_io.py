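"""Configuration, file formats and end-to-end orchestration.

Formats
-------
Trace: two-column TSV ``time_s\textension_nm`` preceded by one ``#``-prefixed
JSON metadata header (concentration, force, seed, sampling rate).
Truth path: CSV ``state_label,entry_time_s`` with a JSON header line.
Dwells: CSV ``state,start_s,duration_s,censored`` plus a JSON metadata
sidecar (``<file>.meta.json``); this is also the import surface for
published dwell lists.
Fit reports: JSON.

The orchestration helpers chain simulate -> detect -> fit so that a whole
titration experiment is one call (or one CLI invocation).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .dwell_models import ThermoContext
from .inference import FitResult, bootstrap_errors, fit_global_double_exp, fit_titration_line
from .state_detection import (
    OPEN,
    DwellRecord,
    DwellSet,
    detect_transitions,
    extract_dwells,
)
from .synthetic_data import (
    ExtensionTrace,
    KineticScheme,
    ProbeGeometry,
    StatePath,
    build_oligo_scheme,
    build_recq_legf_scheme,
    build_recq_nf_scheme,
    gillespie_path,
    render_trace,
)

__all__ = [
    "RunConfig",
    "write_trace",
    "read_trace",
    "write_truth",
    "read_truth",
    "write_dwells",
    "read_dwells",
    "write_fit_report",
    "simulate_condition",
    "simulate_run",
    "analyze_traces",
    "run_titration_pipeline",
]

_SCHEME_BUILDERS = {
    "oligo": build_oligo_scheme,
    "recq_nf": build_recq_nf_scheme,
    "recq_legf": build_recq_legf_scheme,
}


class RatesConfig(BaseModel):
    k_f: float = Field(gt=0, description="closing rate, 1/s")
    k_u: float = Field(gt=0, description="opening rate, 1/s")
    k_on: float = Field(ge=0, default=0.0, description="association rate, 1/(nM s)")
    k_off: float = Field(gt=0, default=1.0, description="dissociation rate, 1/s")


class GeometryConfig(BaseModel):
    extension_closed: float = 0.0
    extension_open: float = 10.0
    noise_sd: float = Field(ge=0, default=1.5)
    sampling_rate: float = Field(gt=0, default=1300.0)
    force: float = 10.0
    force_ref: float = 10.0

    def build(self) -> ProbeGeometry:
        return ProbeGeometry(**self.model_dump())


class DetectorConfig(BaseModel):
    threshold_nm: float = Field(gt=0, default=8.0)
    smooth_window: int = Field(ge=1, default=1)
    tolerance_nm: float = Field(gt=0, default=1.5)


class FitConfig(BaseModel):
    bin_ratio: float = Field(ge=1.2, le=2.0, default=1.4)
    n_boot: int = Field(ge=2, default=100)
    method: Literal["binned", "mle"] = "binned"


class RunConfig(BaseModel):
    """Validated description of a simulated kinetic-locking experiment."""

    scheme: Literal["oligo", "recq_nf", "recq_legf"] = "oligo"
    rates: RatesConfig
    geometry: GeometryConfig = GeometryConfig()
    concentrations_nM: list[float] = Field(default_factory=lambda: [0.0])
    duration_s: float = Field(gt=0, default=100.0)
    seed: int = 0
    detector: DetectorConfig = DetectorConfig()
    fit: FitConfig = FitConfig()

    @model_validator(mode="after")
    def _check_concentrations(self) -> "RunConfig":
        if any(c < 0 for c in self.concentrations_nM):
            raise ValueError("concentrations must be >= 0")
        return self

    def build_scheme(self, c: float) -> KineticScheme:
        r = self.rates
        return _SCHEME_BUILDERS[self.scheme](r.k_f, r.k_u, r.k_on, r.k_off, c)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate_json(text)


# ---------------------------------------------------------------------------
# file formats


def write_trace(trace: ExtensionTrace, path: str | Path) -> None:
    path = Path(path)
    meta = dict(trace.metadata)
    meta["sampling_rate_Hz"] = trace.sampling_rate
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("time_s\textension_nm\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.extensions]),
                   fmt="%.6f\t%.4f")


def read_trace(path: str | Path) -> ExtensionTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing JSON metadata header")
        meta = json.loads(header.lstrip("# "))
    data = pd.read_csv(path, sep="\t", comment="#")
    rate = float(meta.get("sampling_rate_Hz"))
    return ExtensionTrace(
        times=data["time_s"].to_numpy(),
        extensions=data["extension_nm"].to_numpy(),
        sampling_rate=rate,
        metadata=meta,
    )


def write_truth(path_obj: StatePath, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps({"total_duration_s": path_obj.total_duration,
                                    "labels": list(path_obj.labels)}) + "\n")
        fh.write("state_label,entry_time_s\n")
        for lab, t in zip(path_obj.state_labels, path_obj.entry_times):
            fh.write(f"{lab},{t:.9f}\n")


def read_truth(path: str | Path) -> StatePath:
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
    df = pd.read_csv(path, comment="#")
    labels = tuple(meta["labels"])
    index = {lab: i for i, lab in enumerate(labels)}
    return StatePath(
        labels=labels,
        state_indices=np.array([index[s] for s in df["state_label"]], dtype=np.int64),
        entry_times=df["entry_time_s"].to_numpy(),
        total_duration=float(meta["total_duration_s"]),
    )


def write_dwells(dwells: DwellSet, path: str | Path) -> None:
    path = Path(path)
    dwells.to_frame().rename(columns={"start_s": "start_s"}).to_csv(path, index=False)
    sidecar = {"total_time_s": dwells.total_time, **dwells.metadata}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def read_dwells(path: str | Path) -> DwellSet:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    total = float(meta.pop("total_time_s", np.inf))
    if not np.isfinite(total):
        total = float(df["start_s"].iloc[-1] + df["duration_s"].iloc[-1]) if len(df) else 0.0
    records = [
        DwellRecord(state=row.state, start=float(row.start_s),
                    duration=float(row.duration_s), censored=bool(row.censored))
        for row in df.itertuples()
    ]
    return DwellSet(records=records, total_time=total, metadata=meta)


def write_fit_report(fit: FitResult, path: str | Path, extra: dict | None = None) -> None:
    report = {"software": {"name": "kinlock", "version": __version__}, **fit.to_dict()}
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# orchestration


def simulate_condition(config: RunConfig, c: float, seed_seq: np.random.SeedSequence) -> ExtensionTrace:
    """Simulate one concentration condition of a run.

    Path and camera noise use independent child streams of ``seed_seq`` so
    either can be regenerated alone.
    """
    path_ss, noise_ss = seed_seq.spawn(2)
    scheme = config.build_scheme(c)
    geometry = config.geometry.build()
    path = gillespie_path(scheme, config.duration_s, path_ss)
    return render_trace(
        path,
        geometry,
        noise_ss,
        scheme=scheme,
        metadata={"concentration_nM": c, "seed": config.seed},
    )


def simulate_run(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Simulate every concentration; write trace + truth files; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.concentrations_nM))
    written = []
    for c, ss in zip(config.concentrations_nM, children):
        trace = simulate_condition(config, c, ss)
        stem = f"trace_c{c:g}nM"
        trace_path = out_dir / f"{stem}.tsv"
        write_trace(trace, trace_path)
        write_truth(trace.truth, out_dir / f"{stem}.truth.csv")
        written.append(trace_path)
    return written


def analyze_traces(
    traces: list[ExtensionTrace],
    config: RunConfig,
) -> dict[float, DwellSet]:
    """Idealize each trace; return dwell sets keyed by concentration."""
    out: dict[float, DwellSet] = {}
    for trace in traces:
        if abs(trace.sampling_rate - config.geometry.sampling_rate) > 1e-9:
            raise ValueError("mixed sampling rates in one analysis run")
        transitions = detect_transitions(
            trace,
            threshold_nm=config.detector.threshold_nm,
            smooth_window=config.detector.smooth_window,
            tolerance_nm=config.detector.tolerance_nm,
        )
        c = float(trace.metadata.get("concentration_nM", 0.0))
        out[c] = extract_dwells(
            transitions,
            total_time=trace.duration,
            metadata={"concentration_nM": c},
        )
    return out


def run_titration_pipeline(
    config: RunConfig,
    locked_state: str = OPEN,
    ctx: ThermoContext = ThermoContext(),
    with_bootstrap: bool = True,
) -> dict:
    """Full simulate -> detect -> titrate pipeline for one configuration.

    Returns a report dict with per-concentration mean locked-phase dwells
    (bootstrap errors), the titration fit (Ka, dG0), and, when at least two
    concentrations are present, the global double-exponential fit.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.concentrations_nM) + 1)
    boot_rng = np.random.default_rng(children[-1])
    traces = [
        simulate_condition(config, c, ss)
        for c, ss in zip(config.concentrations_nM, children[:-1])
    ]
    dwellsets = analyze_traces(traces, config)

    concs, means, errs, counts = [], [], [], []
    for c in sorted(dwellsets):
        dur = dwellsets[c].durations(locked_state)
        if len(dur) == 0:
            continue
        boot = boot_rng.choice(dur, size=(config.fit.n_boot, len(dur)), replace=True).mean(axis=1)
        concs.append(c)
        means.append(dur.mean())
        errs.append(boot.std(ddof=1))
        counts.append(len(dur))
    titration = fit_titration_line(np.array(concs), np.array(means), np.array(errs), ctx=ctx)
    report = {
        "concentrations_nM": concs,
        "mean_locked_dwell_s": means,
        "bootstrap_sd_s": errs,
        "n_events": counts,
        "titration": titration.to_dict(),
        "seed": config.seed,
    }
    if len(concs) >= 2 and with_bootstrap:
        series = {c: dwellsets[c].durations(locked_state) for c in concs}
        fit = bootstrap_errors(
            lambda ds: fit_global_double_exp(ds, a=config.fit.bin_ratio, method=config.fit.method),
            series,
            n_boot=config.fit.n_boot,
            seed=children[-1].spawn(1)[0],
        )
        report["global_fit"] = fit.to_dict()
    return report
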