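"""End-to-end orchestration: simulate -> analyse -> summarise, with a manifest.

``run_all`` executes the three treatment scenarios over the full 0-24 h
redox time course, the flow-cytometry timepoints and the growth assay, and
writes a small CSV bundle:

* ``summary_table1.csv`` — grand-mean OxD (%) and Nernst potentials per
  (treatment, compartment) over the 24 h window;
* ``redox_timecourse.csv`` — per-timepoint OxD / E means +/- SEM;
* ``phases.csv`` — gated G1/S/G2 fractions per (treatment, timepoint);
* ``growth.csv`` — growth rates per treatment and interval with percentages
  of control;
* ``manifest.json`` — seed, config hash, output inventory, warnings.

All CSV content is deterministic under a fixed seed; plots (optional) are
advisory and never an analysis surface.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cellcycle import GatingParams, fit_phases, gate_debris
from .config import FLOW_TIMEPOINTS_H, SCENARIO_NAMES, NoiseParams, ScenarioConfig, scenario
from .growth import growth_rate, relative_growth
from .redox import NernstConstants, estimate_calibration, run_redox_timecourse
from .simulate import (generate_calibration_sets, generate_flow_events,
                       generate_image_set, generate_root_lengths)

__all__ = ["RunManifest", "run_all", "run_redox_scenario"]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    seed: int
    config_hash: str
    version: str
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    started_utc: str = ""
    finished_utc: str = ""

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def _config_hash(configs: list[ScenarioConfig]) -> str:
    payload = json.dumps([c.to_dict() for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_redox_scenario(config: ScenarioConfig, *, timepoints=None):
    """Simulate and analyse the imaging arm of one scenario.

    Generates the calibration pair, estimates the calibration state, renders
    ``n_replicates`` fields per timepoint and runs the full ratio -> OxD -> E
    analysis.  Returns the :class:`~rogredox.redox.RedoxSummary`.
    """
    reduced, oxidized = generate_calibration_sets(config)
    calib = estimate_calibration(reduced, oxidized)
    constants = NernstConstants.from_config(config)
    timepoints = config.timepoints_h if timepoints is None else timepoints
    sets = [generate_image_set(config, t, r)
            for t in timepoints for r in range(config.n_replicates)]
    return run_redox_timecourse(sets, calib, constants)


def run_all(out_dir: str | Path, *, seed: int = 1, n_replicates: int = 5,
            n_events: int = 100_000, noise: NoiseParams | None = None,
            gating: GatingParams = GatingParams(),
            make_plots: bool = False) -> RunManifest:
    """Run every arm of all three scenarios and write the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = [scenario(name, seed=seed, n_replicates=n_replicates, noise=noise,
                        n_events=n_events) for name in SCENARIO_NAMES]
    manifest = RunManifest(seed=seed, config_hash=_config_hash(configs),
                           version=__version__,
                           started_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()))

    table1_rows, timecourse_frames, phase_rows, growth_frames = [], [], [], []
    root_tables = {}
    for cfg in configs:
        label = cfg.treatment_label
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                summary = run_redox_scenario(cfg)

                for t in FLOW_TIMEPOINTS_H:
                    events = generate_flow_events(cfg, t)
                    ph = fit_phases(gate_debris(events, gating), gating)
                    phase_rows.append(dict(treatment=label, time_h=t,
                                           g1=ph.g1, s=ph.s, g2=ph.g2,
                                           n_gated=ph.n_gated, n_debris=ph.n_debris,
                                           g1_peak=ph.g1_peak, g2_peak=ph.g2_peak))

                root_tables[label] = generate_root_lengths(cfg)
            manifest.warnings += [f"{label}: {w.message}" for w in caught]
        except Exception as exc:  # partial-failure policy: keep other scenarios
            manifest.errors.append(f"{label}: {type(exc).__name__}: {exc}")
            continue

        g = summary.grand.copy()
        g.insert(0, "treatment", label)
        table1_rows.append(g)
        tc = summary.summary.copy()
        tc.insert(0, "treatment", label)
        timecourse_frames.append(tc)

    for interval in ((0, 24), (24, 48)):
        res = growth_rate(list(root_tables.values()), interval)
        rel = relative_growth(res)
        rel.insert(0, "interval", f"{interval[0]}-{interval[1]}h")
        growth_frames.append(rel)

    files = {
        "summary_table1.csv": pd.concat(table1_rows, ignore_index=True),
        "redox_timecourse.csv": pd.concat(timecourse_frames, ignore_index=True),
        "phases.csv": pd.DataFrame(phase_rows),
        "growth.csv": pd.concat(growth_frames, ignore_index=True),
    }
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        manifest.outputs.append(str(path))

    if make_plots:
        manifest.outputs += [str(p) for p in _make_plots(files, out)]

    manifest.finished_utc = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    manifest.save(out / "manifest.json")
    if manifest.errors:
        raise RuntimeError("scenario failures: " + "; ".join(manifest.errors))
    return manifest


def _make_plots(files: dict[str, pd.DataFrame], out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    tc = files["redox_timecourse.csv"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, comp in zip(axes, ("nucleus", "cytosol")):
        for label, grp in tc[tc.compartment == comp].groupby("treatment"):
            ax.errorbar(grp.time_h, grp.oxd_mean_pct, yerr=grp.oxd_sem_pct,
                        marker="o", ms=3, capsize=2, label=label)
        ax.set(title=comp, xlabel="time after treatment (h)", ylabel="OxD (%)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    p = out / "redox_timecourse.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    ph = files["phases.csv"]
    fig, axes = plt.subplots(1, ph.treatment.nunique(), figsize=(10, 3), sharey=True)
    for ax, (label, grp) in zip(axes, ph.groupby("treatment")):
        bottom = None
        for phase in ("g1", "s", "g2"):
            vals = 100 * grp[phase].to_numpy()
            ax.bar([str(t) for t in grp.time_h], vals, bottom=bottom, label=phase.upper())
            bottom = vals if bottom is None else bottom + vals
        ax.set(title=label, xlabel="time (h)")
    axes[0].set_ylabel("% of gated nuclei")
    axes[-1].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    p = out / "phases.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
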