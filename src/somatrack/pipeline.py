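"""End-to-end orchestration: io -> anisotropy -> detection -> registration
-> tracking -> signal, with stage-wise artifacts so a run can be restarted
at any stage."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anisotropy import default_insert_count, interpolate_axial
from .detection import DetectionCloud, NucleusSizePrior, detect_nuclei
from .errors import PipelineStageError, SomatrackError
from .io_core import Sequence, detect_corrupted_frames, read_sequence, repair_frames
from .registration import (
    CPDParams,
    RegisteredCloud,
    RegisteredFrame,
    SimilarityTransform,
    TransformChain,
    register_sequence,
)
from .signal import (
    TraceMatrix,
    default_stimulus_windows,
    extract_raw,
    fly_quality_control,
    glow_control_filter,
    normalize,
    select_responsive,
)
from .tracking import (
    DBSCANParams,
    PROVENANCE_NAMES,
    TrajectorySet,
    track,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_KNOWN_SECTIONS = {
    "input", "seed",
    "anisotropy", "detection", "registration", "tracking", "signal", "simulate",
}
_KNOWN_KEYS = {
    "anisotropy": {"n_insert"},
    "detection": {"nucleus_diameter", "n_filters"},
    "registration": {"subset_size", "cpd_beta", "cpd_lambda", "cpd_w", "cpd_tol", "cpd_max_iter"},
    "tracking": {"eps", "min_pts", "min_support", "support_fraction"},
    "signal": {
        "threshold", "butter_cutoff", "f0_radius", "glow_min_sep_factor",
        "voronoi_radius_factor", "qc_min_responders",
    },
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    input: str | None = None
    seed: int = 0
    anisotropy: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    registration: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    signal: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _KNOWN_KEYS.items():
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# stage artifact (de)serialization

def save_detections_csv(clouds: list[DetectionCloud], path) -> None:
    rows = []
    for c in clouds:
        for (z, y, x), i in zip(c.coords_um, c.intensities):
            rows.append({"frame": c.frame, "z_um": z, "y_um": y, "x_um": x, "intensity": i})
    pd.DataFrame(rows, columns=["frame", "z_um", "y_um", "x_um", "intensity"]).to_csv(
        path, index=False
    )


def load_detections_csv(path) -> list[DetectionCloud]:
    df = pd.read_csv(path)
    T = int(df["frame"].max()) + 1 if len(df) else 0
    clouds = []
    for t in range(T):
        grp = df[df["frame"] == t]
        clouds.append(
            DetectionCloud(
                t, grp[["z_um", "y_um", "x_um"]].to_numpy(float), grp["intensity"].to_numpy(float)
            )
        )
    return clouds


def save_registered_csv(cloud: RegisteredCloud, path) -> None:
    rows = []
    for f in cloud.frames:
        for orig, rig, nr, inten in zip(f.original, f.rigid, f.nonrigid, f.intensities):
            rows.append(
                {
                    "frame": f.frame,
                    "z_um": orig[0], "y_um": orig[1], "x_um": orig[2],
                    "zrig_um": rig[0], "yrig_um": rig[1], "xrig_um": rig[2],
                    "zr_um": nr[0], "yr_um": nr[1], "xr_um": nr[2],
                    "intensity": inten,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_transforms_json(chain: TransformChain, path) -> None:
    payload = {
        "reference": chain.reference,
        "composed": [t.matrix.tolist() for t in chain.composed],
        "pairwise": {str(k): v.matrix.tolist() for k, v in chain.pairwise.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_registered(csv_path, transforms_path) -> RegisteredCloud:
    with open(transforms_path) as fh:
        payload = json.load(fh)
    chain = TransformChain(
        reference=int(payload["reference"]),
        pairwise={int(k): SimilarityTransform(np.array(v)) for k, v in payload["pairwise"].items()},
        composed=[SimilarityTransform(np.array(m)) for m in payload["composed"]],
    )
    df = pd.read_csv(csv_path)
    frames = []
    for t in range(len(chain.composed)):
        grp = df[df["frame"] == t]
        frames.append(
            RegisteredFrame(
                t,
                grp[["z_um", "y_um", "x_um"]].to_numpy(float),
                grp[["zrig_um", "yrig_um", "xrig_um"]].to_numpy(float),
                grp[["zr_um", "yr_um", "xr_um"]].to_numpy(float),
                grp["intensity"].to_numpy(float),
            )
        )
    return RegisteredCloud(frames, chain)


def save_trajectories_csv(traj: TrajectorySet, path) -> None:
    rows = []
    for i, sid in enumerate(traj.soma_ids):
        for t in range(traj.n_frames):
            z, y, x = traj.positions[i, t]
            rows.append(
                {
                    "soma_id": int(sid), "frame": t, "z_um": z, "y_um": y, "x_um": x,
                    "provenance": PROVENANCE_NAMES[int(traj.provenance[i, t])],
                }
            )
    pd.DataFrame(rows, columns=["soma_id", "frame", "z_um", "y_um", "x_um", "provenance"]).to_csv(
        path, index=False
    )


def load_trajectories_csv(path) -> TrajectorySet:
    from .tracking import PROVENANCE_CODES

    df = pd.read_csv(path)
    ids = np.sort(df["soma_id"].unique())
    T = int(df["frame"].max()) + 1
    pos = np.zeros((len(ids), T, 3))
    prov = np.zeros((len(ids), T), dtype=np.int8)
    for i, sid in enumerate(ids):
        grp = df[df["soma_id"] == sid].sort_values("frame")
        pos[i] = grp[["z_um", "y_um", "x_um"]].to_numpy(float)
        prov[i] = [PROVENANCE_CODES[p] for p in grp["provenance"]]
    return TrajectorySet(pos, prov, ids)


# ---------------------------------------------------------------------------
# stages

def _load_stage(config: RunConfig) -> Sequence:
    if config.input:
        path = Path(config.input)
        if not path.exists():
            raise PipelineStageError("io", f"input path {path} does not exist")
        seq = read_sequence(path)
    elif config.simulate:
        from .synthetic import SimulationConfig, simulate_sequence

        sim = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
        seq, _ = simulate_sequence(sim)
    else:
        raise PipelineStageError("io", "neither an input path nor a simulation config given")
    if seq.n_frames >= 5:
        bad = detect_corrupted_frames(seq)
        if bad:
            logger.info("repairing corrupted frames %s", bad)
            seq = repair_frames(seq, bad)
    if not seq.stimulus_windows:
        seq.stimulus_windows = default_stimulus_windows(seq.n_frames, seq.geometry.frame_period)
    return seq


def _detect_stage(seq: Sequence, config: RunConfig, rng: np.random.Generator):
    det_cfg = config.detection
    prior = NucleusSizePrior(float(det_cfg.get("nucleus_diameter", 3.0)))
    n_filters = int(det_cfg.get("n_filters", 10))
    n_insert = config.anisotropy.get("n_insert", "auto")
    if n_insert == "auto":
        n_insert = default_insert_count(seq.geometry)
    clouds = []
    for nuc, _ in seq.frames:
        interp = interpolate_axial(nuc, int(n_insert))
        clouds.append(detect_nuclei(interp, prior, n_filters, rng))
    return clouds, prior


def _register_stage(clouds, config: RunConfig, prior, rng):
    reg_cfg = config.registration
    params = CPDParams(
        beta=float(reg_cfg.get("cpd_beta", 2.0 * prior.diameter)),
        lamb=float(reg_cfg.get("cpd_lambda", 3.0)),
        w=float(reg_cfg.get("cpd_w", 0.0)),
        tol=float(reg_cfg.get("cpd_tol", 1e-5)),
        max_iter=int(reg_cfg.get("cpd_max_iter", 150)),
    )
    return register_sequence(clouds, m=int(reg_cfg.get("subset_size", 100)), cpd_params=params, rng=rng)


def _track_stage(registered, config: RunConfig, prior, rng) -> TrajectorySet:
    tr = config.tracking
    params = None
    if "eps" in tr and "min_pts" in tr:
        params = DBSCANParams(float(tr["eps"]), int(tr["min_pts"]))
    return track(
        registered,
        prior,
        params=params,
        min_support=int(tr.get("min_support", 3)),
        support_fraction=float(tr.get("support_fraction", 0.5)),
        rng=rng,
    )


def _signal_stage(traj: TrajectorySet, seq: Sequence, config: RunConfig, prior):
    sig = config.signal
    radius_factor = float(sig.get("voronoi_radius_factor", 1.5))
    F = extract_raw(traj, seq, max_radius=radius_factor * prior.radius)
    traces = normalize(
        F,
        window_radius=int(sig.get("f0_radius", 10)),
        cutoff_frac=float(sig.get("butter_cutoff", 0.2)),
    )
    threshold = float(sig.get("threshold", 0.1))
    responders = {
        w.label: select_responsive(traces, w, threshold) for w in seq.stimulus_windows
    }
    mean_pos = traj.positions.mean(axis=1)
    peaks = traces.normalized.max(axis=1)
    retained = glow_control_filter(
        mean_pos, peaks, float(sig.get("glow_min_sep_factor", 2.0)) * prior.diameter
    )
    try:
        qc_pass, qc_reasons = fly_quality_control(
            traces, seq.stimulus_windows, threshold,
            min_responders=int(sig.get("qc_min_responders", 5)),
        )
    except ValueError as exc:
        qc_pass, qc_reasons = False, [str(exc)]
    return traces, responders, retained, (qc_pass, qc_reasons)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write all artifacts plus a run manifest.

    Returns a result bundle with the in-memory objects and artifact paths.
    Any stage error aborts with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stages_done: list[dict] = []
    bundle: dict = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except SomatrackError as exc:
            if isinstance(exc, PipelineStageError):
                raise
            raise PipelineStageError(name, str(exc)) from exc
        stages_done.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        logger.info("stage %s done in %.2fs", name, stages_done[-1]["seconds"])
        return out

    seq = run_stage("io", _load_stage, config)
    bundle["sequence"] = seq

    clouds, prior = run_stage("detection", _detect_stage, seq, config, rng)
    save_detections_csv(clouds, outdir / "detections.csv")
    bundle["detections"] = clouds

    registered = run_stage("registration", _register_stage, clouds, config, prior, rng)
    save_registered_csv(registered, outdir / "registered.csv")
    save_transforms_json(registered.chain, outdir / "transforms.json")
    bundle["registered"] = registered

    traj = run_stage("tracking", _track_stage, registered, config, prior, rng)
    save_trajectories_csv(traj, outdir / "trajectories.csv")
    bundle["trajectories"] = traj

    traces, responders, retained, qc = run_stage(
        "signal", _signal_stage, traj, seq, config, prior
    )
    bundle.update(traces=traces, responders=responders, glow_retained=retained, qc=qc)
    _write_signal_artifacts(traj, traces, responders, retained, qc, seq, outdir)
    stages_done.append({"stage": "report", "seconds": 0.0})

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
        "stages": stages_done,
        "n_frames": seq.n_frames,
        "n_trajectories": traj.n_somata,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


def _write_signal_artifacts(traj, traces: TraceMatrix, responders, retained, qc, seq, outdir):
    T = traces.n_frames
    rows = []
    for i, sid in enumerate(traj.soma_ids):
        for t in range(T):
            rows.append(
                {"soma_id": int(sid), "frame": t, "F": traces.raw[i, t], "dff": traces.normalized[i, t]}
            )
    pd.DataFrame(rows, columns=["soma_id", "frame", "F", "dff"]).to_csv(
        outdir / "signals.csv", index=False
    )
    rrows = []
    for w in seq.stimulus_windows:
        resp = responders[w.label]
        peaks = traces.normalized[:, w.start : w.end].max(axis=1) if T else []
        for i, sid in enumerate(traj.soma_ids):
            rrows.append(
                {
                    "soma_id": int(sid), "window_label": w.label,
                    "peak": float(peaks[i]) if traj.n_somata else np.nan,
                    "responsive": bool(resp[i]),
                }
            )
    pd.DataFrame(rrows, columns=["soma_id", "window_label", "peak", "responsive"]).to_csv(
        outdir / "responders.csv", index=False
    )
    qc_pass, reasons = qc
    with open(outdir / "qc.json", "w") as fh:
        json.dump(
            {
                "pass": bool(qc_pass), "reasons": reasons,
                "glow_retained_soma_ids": [int(traj.soma_ids[i]) for i in retained],
            },
            fh, indent=2,
        )
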