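"""End-to-end orchestration: weekly QA runs, trend reports, repeatability
studies, session dataset I/O and provenance.

A weekly run executes the four analysis stages — MV planar, kV planar,
CBCT-to-CT registration, Winston-Lutz radiation isocenter — in isolation:
a failing stage becomes a structured error entry in the report and the
remaining stages still run, mirroring a workflow in which the modalities
are independent measurements of the same setup.  Reports are deterministic
given inputs; the provenance block records the config hash, seeds and
software version so byte-identical reproduction is checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import IsoQAError, ManifestError
from .images import PlanarImage, VolumeImage
from .phantom import PhantomSpec, SessionDataset, SessionTruth, default_phantom, simulate_session
from .pose import ShiftResult, planar_isocenter_shift, register_cbct_to_ct
from .stats import (
    QARecord,
    ROTATION_AXES,
    TRANSLATION_AXES,
    ToleranceSet,
    UndefinedTestError,
    drift_report,
    records_to_frame,
    summarize_trend,
    tolerance_flags,
    wilcoxon_one_sample,
)
from .winston_lutz import WLResult, fit_radiation_isocenter, wl_image_deviation

__all__ = ["QAReport", "SessionManifest", "run_weekly_qa", "report_records",
           "run_trend", "trend_to_files", "plot_trend", "repeatability_study",
           "save_session", "load_session", "config_hash", "load_config",
           "tolerances_from_config"]

log = logging.getLogger("isoqa")

_POSE_AXES = {"VRT": "vrt_mm", "LNG": "lng_mm", "LAT": "lat_mm",
              "pitch": "pitch_deg", "roll": "roll_deg", "Rtn": "rtn_deg"}


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (changes iff any value does)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    """Read a QA configuration from a YAML or JSON file.

    Recognized keys: ``tolerances`` (fields of :class:`ToleranceSet`),
    ``drift`` (``threshold_mm``, ``threshold_deg``, ``baseline_weeks``).
    Unknown keys are preserved so they enter the config hash.
    """
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ManifestError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def tolerances_from_config(config: dict) -> ToleranceSet:
    return ToleranceSet(**config.get("tolerances", {}))


@dataclass
class QAReport:
    """One week's full QA outcome: per-modality results, flags, provenance."""

    week_index: int
    mv: ShiftResult | dict | None = None
    kv: ShiftResult | dict | None = None
    cbct: ShiftResult | dict | None = None
    radiation: WLResult | dict | None = None
    flags: dict = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    def stage_failed(self, name: str) -> bool:
        return isinstance(getattr(self, name), dict) and "error" in getattr(self, name)

    def to_dict(self) -> dict:
        def conv(x):
            if x is None or isinstance(x, dict):
                return x
            return x.to_dict()

        flags = {("/".join(k) if isinstance(k, tuple) else k): v
                 for k, v in self.flags.get("per_axis", {}).items()}
        out_flags = dict(self.flags)
        if flags:
            out_flags["per_axis"] = flags
        return {"week_index": self.week_index, "mv": conv(self.mv),
                "kv": conv(self.kv), "cbct": conv(self.cbct),
                "radiation": conv(self.radiation),
                "flags": out_flags, "provenance": self.provenance}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stage(name: str, fn, report_errors: list):
    t0 = time.perf_counter()
    try:
        result = fn()
        log.info("stage %-10s ok       (%.2f s)", name, time.perf_counter() - t0)
        return result
    except IsoQAError as exc:
        log.warning("stage %-10s FAILED   (%.2f s): %s", name,
                    time.perf_counter() - t0, exc)
        report_errors.append(name)
        return {"error": {"type": type(exc).__name__, "message": str(exc)}}


def run_weekly_qa(session: "SessionDataset | SessionManifest | Path",
                  tolerances: ToleranceSet = ToleranceSet(),
                  week_index: int = 0, config: dict | None = None) -> QAReport:
    """Analyze one session: all four modality stages plus tolerance flags.

    ``session`` may be an in-memory :class:`SessionDataset`, a
    :class:`SessionManifest`, or a path to a session directory.
    """
    if isinstance(session, (str, Path)):
        session = load_session(session)
    if isinstance(session, SessionManifest):
        session = session.load()
    phantom = session.phantom
    failed: list[str] = []
    cfg = dict(config or {})
    cfg.setdefault("tolerances", tolerances.__dict__)

    def _require(value, role):
        if value is None or (isinstance(value, list) and not value):
            raise ManifestError(f"missing inputs for role {role!r}")
        return value

    report = QAReport(week_index=week_index)
    report.mv = _stage("mv", lambda: planar_isocenter_shift(
        _require(session.planar_mv, "mv"), phantom), failed)
    report.kv = _stage("kv", lambda: planar_isocenter_shift(
        _require(session.planar_kv, "kv"), phantom), failed)
    report.cbct = _stage("cbct", lambda: register_cbct_to_ct(
        _require(session.cbct, "cbct"), _require(session.ct, "ct"), phantom),
        failed)

    def _radiation():
        per_image = [wl_image_deviation(img, phantom)
                     for img in _require(session.wl_images, "wl")]
        return fit_radiation_isocenter(per_image)

    report.radiation = _stage("radiation", _radiation, failed)

    try:
        records = report_records(report)
        report.flags = tolerance_flags(records, tolerances)
    except (ManifestError, IsoQAError) as exc:
        report.flags = {"error": {"type": type(exc).__name__, "message": str(exc)},
                        "overall": False}
    report.provenance = {
        "software_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": getattr(session, "seed", None),
        "failed_stages": failed,
        "synthetic_truth": (session.truth.mv.to_dict()
                            if getattr(session, "truth", None) else None),
    }
    return report


def report_records(report: QAReport, week_index: int | None = None) -> list[QARecord]:
    """Flatten a QAReport into per-modality-axis records for trending."""
    week = report.week_index if week_index is None else week_index
    records: list[QARecord] = []
    for modality, attr in (("MV", "mv"), ("kV", "kv"), ("CBCT", "cbct")):
        res = getattr(report, attr)
        if not isinstance(res, ShiftResult):
            continue
        for axis in TRANSLATION_AXES + ROTATION_AXES:
            records.append(QARecord(week_index=week, modality=modality, axis=axis,
                                    value=float(getattr(res.pose, _POSE_AXES[axis]))))
    if isinstance(report.radiation, WLResult):
        shift = report.radiation.phantom_shift  # (LAT, LNG, VRT)
        for axis, val in zip(("LAT", "LNG", "VRT"), shift):
            records.append(QARecord(week_index=week, modality="radiation",
                                    axis=axis, value=float(val)))
    return records


def run_trend(reports, tolerances: ToleranceSet = ToleranceSet(),
              drift_threshold_mm: float = 0.4,
              drift_threshold_deg: float = 0.3) -> dict:
    """Aggregate >= 2 weekly reports into trend tables and drift flags.

    Returns a dict with the summary table (mean/SD/extreme and a Wilcoxon
    two-sided p against zero per modality-axis), the flat record table and
    the running-median drift report.
    """
    reports = list(reports)
    if len(reports) < 2:
        raise ManifestError("trend analysis needs >= 2 weekly reports")
    records: list[QARecord] = []
    for rep in reports:
        records.extend(report_records(rep))
    frame = records_to_frame(records)
    summary = summarize_trend(frame)

    pvals = []
    for _, row in summary.iterrows():
        vals = frame[(frame["modality"] == row["modality"])
                     & (frame["axis"] == row["axis"])]["value"].to_numpy()
        try:
            _, p = wilcoxon_one_sample(vals, 0.0)
        except UndefinedTestError:
            p = float("nan")
        pvals.append(p)
    summary = summary.assign(wilcoxon_p=pvals)
    drift = drift_report(frame, threshold_mm=drift_threshold_mm,
                         threshold_deg=drift_threshold_deg)
    return {"summary": summary, "records": frame, "drift": drift}


def plot_trend(trend: dict, path) -> Path:
    """Six-panel weekly trend chart (one panel per axis, one line per
    modality), with drift-flagged weeks shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = trend["records"]
    axes_order = list(TRANSLATION_AXES) + list(ROTATION_AXES)
    fig, axs = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    markers = {"MV": "o", "kV": "s", "CBCT": "*", "radiation": "D"}
    for ax, axis in zip(axs.ravel(), axes_order):
        sub = frame[frame["axis"] == axis]
        for modality, grp in sub.groupby("modality"):
            grp = grp.sort_values("week")
            ax.plot(grp["week"], grp["value"],
                    marker=markers.get(modality, "."), ms=4, lw=0.8,
                    label=modality)
        for week in trend["drift"]["flagged_weeks"]:
            ax.axvspan(week - 0.4, week + 0.4, color="red", alpha=0.15)
        units = "mm" if axis in TRANSLATION_AXES else "deg"
        ax.set_title(f"{axis} ({units})", fontsize=10)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.grid(alpha=0.3)
    axs[0, 0].legend(fontsize=8)
    for ax in axs[1]:
        ax.set_xlabel("week")
    fig.suptitle("Isocenter discrepancies from the OSMS setup position")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def trend_to_files(trend: dict, out_dir) -> dict:
    """Write the trend result as CSV (summary, records) + JSON (drift)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"summary": out / "trend_summary.csv",
             "records": out / "qa_records.csv",
             "drift": out / "drift_report.json"}
    trend["summary"].to_csv(paths["summary"], index=False)
    trend["records"].to_csv(paths["records"], index=False)
    paths["drift"].write_text(json.dumps(trend["drift"], indent=1, default=str))
    paths["plot"] = out / "trend.png"
    plot_trend(trend, paths["plot"])
    return {k: str(v) for k, v in paths.items()}


def repeatability_study(n_repeats: int = 10,
                        truth: SessionTruth = SessionTruth(),
                        phantom: PhantomSpec | None = None,
                        planar_noise: float = 0.01,
                        volume_noise_fraction: float = 0.02,
                        seed: int = 0, **session_kw) -> pd.DataFrame:
    """Repeat-measurement uncertainty: SD of estimates on an unmoved phantom.

    Renders ``n_repeats`` independently noisy sessions at the same fixed
    truth, analyzes each, and reports the per-axis standard deviation and
    maximum absolute deviation from the per-axis mean, per modality.
    """
    if n_repeats < 2:
        raise ManifestError("repeatability needs n_repeats >= 2")
    phantom = phantom or default_phantom()
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(n_repeats)]
    rows: dict[tuple, list] = {}
    for i, s in enumerate(seeds):
        ds = simulate_session(truth=truth, phantom=phantom,
                              planar_noise=planar_noise,
                              volume_noise_fraction=volume_noise_fraction,
                              seed=s, **session_kw)
        rep = run_weekly_qa(ds, week_index=i)
        for rec in report_records(rep):
            rows.setdefault((rec.modality, rec.axis, rec.units), []).append(rec.value)

    out = []
    for (modality, axis, units), vals in rows.items():
        v = np.asarray(vals, dtype=float)
        out.append({"modality": modality, "axis": axis, "units": units,
                    "n": len(v), "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)),
                    "max_abs_dev": float(np.max(np.abs(v - v.mean())))})
    return pd.DataFrame(out, columns=["modality", "axis", "units", "n",
                                      "mean", "sd", "max_abs_dev"])


# ---------------------------------------------------------------------------
# session dataset I/O
# ---------------------------------------------------------------------------

@dataclass
class SessionManifest:
    """File layout of one session on disk, with geometry and optional truth."""

    root: Path
    entries: dict

    REQUIRED = {"mv": 4, "kv": 4, "wl": 12, "ct": 1, "cbct": 1}

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.missing_roles: list[str] = []
        for role, count in self.REQUIRED.items():
            paths = self.entries.get(role, [])
            if len(paths) != count:
                # incomplete roles are carried as missing so the analysis can
                # still run the remaining stages and report the gap per-stage
                self.missing_roles.append(role)
                continue
            for p in paths:
                if not (self.root / p).exists():
                    raise ManifestError(f"missing file for role {role!r}: {p}")

    def load(self):
        """Return the session; complete manifests give a SessionDataset,
        incomplete ones a permissive stand-in with empty missing roles."""
        if self.missing_roles:
            import types

            load_planar = lambda rel: PlanarImage.read_tiff(self.root / rel)
            get = lambda role: ([load_planar(p) for p in self.entries.get(role, [])]
                                if role not in self.missing_roles else [])
            vol = lambda role: (VolumeImage.read_raw(
                (self.root / self.entries[role][0]).with_suffix(""))
                if role not in self.missing_roles else None)
            return types.SimpleNamespace(
                planar_mv=get("mv"), planar_kv=get("kv"), wl_images=get("wl"),
                ct=vol("ct"), cbct=vol("cbct"),
                phantom=self._phantom(), truth=None,
                seed=self.entries.get("seed", 0))
        return self._load_complete()

    def _phantom(self) -> PhantomSpec:
        return PhantomSpec(
            bbs=tuple((b["label"], tuple(b["position_mm"]), b["diameter_mm"])
                      for b in self.entries["phantom"]["bbs"]),
            cube_side_mm=self.entries["phantom"]["cube_side_mm"],
            bb_intensity=self.entries["phantom"]["bb_intensity"],
            plastic_intensity=self.entries["phantom"]["plastic_intensity"],
            background_intensity=self.entries["phantom"]["background_intensity"])

    def _load_complete(self) -> SessionDataset:
        phantom = self._phantom()
        truth_block = self.entries.get("truth")
        truth = SessionTruth(**{
            **{k: SessionTruth.__dataclass_fields__[k].default
               for k in ("wl_axis_jitter_mm",)},
            "mv": _pose_from_dict(truth_block["mv"]),
            "kv": _pose_from_dict(truth_block["kv"]),
            "cbct": _pose_from_dict(truth_block["cbct"]),
            "radiation_iso_mm": tuple(truth_block["radiation_iso_mm"]),
            "wl_bb_offset_mm": tuple(truth_block["wl_bb_offset_mm"]),
        }) if truth_block else SessionTruth()
        load_planar = lambda rel: PlanarImage.read_tiff(self.root / rel)
        return SessionDataset(
            ct=VolumeImage.read_raw((self.root / self.entries["ct"][0]).with_suffix("")),
            cbct=VolumeImage.read_raw((self.root / self.entries["cbct"][0]).with_suffix("")),
            planar_mv=[load_planar(p) for p in self.entries["mv"]],
            planar_kv=[load_planar(p) for p in self.entries["kv"]],
            wl_images=[load_planar(p) for p in self.entries["wl"]],
            truth=truth, phantom=phantom,
            seed=self.entries.get("seed", 0))


def _pose_from_dict(d: dict):
    from .geometry import Pose6D
    return Pose6D(**d)


def save_session(dataset: SessionDataset, directory) -> Path:
    """Write a SessionDataset as TIFFs + raw volumes + ``manifest.json``."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    entries: dict = {"mv": [], "kv": [], "wl": [], "ct": [], "cbct": []}
    for role, images in (("mv", dataset.planar_mv), ("kv", dataset.planar_kv),
                         ("wl", dataset.wl_images)):
        for i, img in enumerate(images):
            rel = f"{role}_{i:02d}.tif"
            img.write_tiff(root / rel)
            entries[role].append(rel)
    for role, vol in (("ct", dataset.ct), ("cbct", dataset.cbct)):
        vol.write_raw(root / role)
        entries[role].append(f"{role}.raw")
    entries["phantom"] = {
        "bbs": [{"label": lab, "position_mm": list(map(float, np.asarray(pos, float))),
                 "diameter_mm": diam} for lab, pos, diam in dataset.phantom.bbs],
        "cube_side_mm": dataset.phantom.cube_side_mm,
        "bb_intensity": dataset.phantom.bb_intensity,
        "plastic_intensity": dataset.phantom.plastic_intensity,
        "background_intensity": dataset.phantom.background_intensity}
    t = dataset.truth
    entries["truth"] = {"mv": t.mv.to_dict(), "kv": t.kv.to_dict(),
                        "cbct": t.cbct.to_dict(),
                        "radiation_iso_mm": list(map(float, t.radiation_iso_mm)),
                        "wl_bb_offset_mm": list(map(float, t.wl_bb_offset_mm))}
    entries["seed"] = dataset.seed
    entries["geometry"] = [img.geom.to_dict()
                           for img in dataset.planar_mv + dataset.planar_kv
                           + dataset.wl_images]
    (root / "manifest.json").write_text(json.dumps(entries, indent=1))
    return root


def load_session(directory) -> SessionDataset:
    root = Path(directory)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ManifestError(f"no manifest.json under {root}")
    entries = json.loads(manifest_path.read_text())
    return SessionManifest(root=root, entries=entries).load()
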