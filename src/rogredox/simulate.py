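"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here: two-channel
roGFP2 image sets with label masks, fully reduced / fully oxidised
calibration fields, propidium-iodide DNA-content flow-cytometry event tables
and root-length time courses.  The generators emulate the statistical
structure of the corresponding bench measurements (shot + read noise on
pixels, replicate-to-replicate biological variability, a CV-broadened 2C/4C
DNA histogram with an S-phase bridge and low-channel debris, seedling-level
growth variability) — not the optics or chemistry that produced them.

All randomness flows from the scenario's single master seed through a
documented splitting scheme: each generator derives a child generator from
``numpy.random.SeedSequence(seed, spawn_key=(domain, scenario, timepoint,
replicate))`` so that outputs are bit-identical for identical configurations
and independent across arms of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GROWTH_TIMEPOINTS_H, SCENARIO_NAMES, ScenarioConfig
from .errors import ConfigurationError
from .images import ImageSet
from .redox import CalibrationState

__all__ = [
    "invert_ratio", "generate_image_set", "generate_calibration_sets",
    "generate_flow_events", "generate_root_lengths",
    "FlowEventTable", "RootLengthTable", "truth_calibration",
]

# RNG domain codes for the seed-splitting scheme
_DOM_IMAGES, _DOM_CALIB, _DOM_FLOW, _DOM_ROOTS = 1, 2, 3, 4

FLOW_CSV_COLUMNS = ["event_id", "fsc", "ssc", "dna_fl"]
ROOT_CSV_COLUMNS = ["treatment", "concentration_mM", "seedling_id", "time_h", "length_mm"]


def _rng(config: ScenarioConfig, domain: int, *key: int) -> np.random.Generator:
    scen = SCENARIO_NAMES.index(config.treatment_label)
    ss = np.random.SeedSequence(config.seed, spawn_key=(domain, scen, *key))
    return np.random.default_rng(ss)


def truth_calibration(config: ScenarioConfig) -> CalibrationState:
    """The generator's true calibration endpoints as a CalibrationState."""
    return CalibrationState.from_ratios(config.r_red, config.r_ox, config.k_instrument)


def invert_ratio(oxd: float, calib: CalibrationState):
    """Excitation ratio R that a probe with the given OxD produces.

    Algebraic inverse of the OxD formula:
    R = [(1-OxD) R_red + OxD k R_ox] / [(1-OxD) + OxD k]; round-trips through
    ``compute_oxd`` to machine precision.  Accepts scalars or arrays.
    """
    if not (calib.r_ox > calib.r_red):
        raise ConfigurationError("invalid calibration: R_ox <= R_red")
    if calib.k <= 0:
        raise ConfigurationError("invalid calibration: k <= 0")
    oxd = np.asarray(oxd, dtype=float)
    if np.any(oxd < 0) or np.any(oxd > 1):
        raise ConfigurationError("OxD must lie in [0, 1]")
    r = ((1.0 - oxd) * calib.r_red + oxd * calib.k * calib.r_ox) / ((1.0 - oxd) + oxd * calib.k)
    return float(r) if r.ndim == 0 else r


# --------------------------------------------------------------------------
# image generation


def _logit(x):
    return np.log(x / (1.0 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _place_cells(config: ScenarioConfig, rng: np.random.Generator):
    """Elliptical cells on a jittered grid: (center, outer axes, nucleus axes)."""
    h, w = config.image_shape
    n = config.n_cells
    ncol = int(np.ceil(np.sqrt(n * w / h)))
    nrow = int(np.ceil(n / ncol))
    cells = []
    idx = 0
    for i in range(nrow):
        for j in range(ncol):
            if idx >= n:
                break
            cy = (i + 0.5) * h / nrow + rng.uniform(-4, 4)
            cx = (j + 0.5) * w / ncol + rng.uniform(-4, 4)
            a_out = rng.uniform(11.0, 15.0)   # semi-axes, px
            b_out = rng.uniform(8.0, 11.0)
            a_nuc = max(3.5, 0.40 * a_out)
            b_nuc = max(3.0, 0.40 * b_out)
            theta = rng.uniform(0, np.pi)
            cells.append((cy, cx, a_out, b_out, a_nuc, b_nuc, theta))
            idx += 1
    return cells


def _build_mask(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int64)
    for i, (cy, cx, a_o, b_o, a_n, b_n, th) in enumerate(_place_cells(config, rng), start=1):
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        outer = (u / a_o) ** 2 + (v / b_o) ** 2 <= 1.0
        nucleus = (u / a_n) ** 2 + (v / b_n) ** 2 <= 1.0
        mask[outer & (mask == 0)] = 2 * i          # cytosol ring
        mask[nucleus & (mask > 0)] = 2 * i - 1     # nucleus nested inside
    return mask


def _render(config: ScenarioConfig, rng: np.random.Generator, mask: np.ndarray,
            oxd_per_label: dict[int, float], base488_per_label: dict[int, float],
            calib: CalibrationState) -> tuple[np.ndarray, np.ndarray]:
    """Noisy 405/488 channels from per-label OxD and base 488 intensity."""
    noise = config.noise
    clean488 = np.zeros(config.image_shape, dtype=float)
    clean405 = np.zeros(config.image_shape, dtype=float)
    for lab, base in base488_per_label.items():
        sel = mask == lab
        r = invert_ratio(oxd_per_label[lab], calib)
        clean488[sel] = base
        clean405[sel] = r * base

    def noisy(clean: np.ndarray) -> np.ndarray:
        img = clean + noise.background_level
        var = noise.photon_scale * img + noise.read_noise_sd ** 2
        if np.any(var > 0):
            img = img + rng.standard_normal(img.shape) * np.sqrt(var)
        return np.clip(img, 0.0, float(config.saturation_cap))

    return noisy(clean405), noisy(clean488)


def generate_image_set(config: ScenarioConfig, timepoint_h: int, replicate: int) -> ImageSet:
    """One simulated two-channel field for (scenario, timepoint, replicate).

    Per-cell base 488 intensities are lognormal; each compartment's true OxD
    is the scenario trajectory value jittered on the logit scale, once per
    replicate (biological variability, shared by all cells of the field) and
    once per cell; the 405 channel is the inverted-ratio image of the 488
    channel.  Shot noise scales with intensity; read noise and a uniform
    background offset are added; pixels clip at the saturation cap.
    Deterministic given (seed, timepoint, replicate).
    """
    if timepoint_h not in config.timepoints_h:
        raise ConfigurationError(
            f"timepoint {timepoint_h} h not in scenario grid {config.timepoints_h}")
    rng = _rng(config, _DOM_IMAGES, timepoint_h, replicate)
    mask = _build_mask(config, rng)
    noise = config.noise

    truth = {c: config.oxd_truth(c, timepoint_h) for c in ("nucleus", "cytosol")}
    rep_shift = {c: rng.normal(0.0, noise.replicate_logit_sd) for c in truth}

    oxd_per_label: dict[int, float] = {}
    base488_per_label: dict[int, float] = {}
    for lab in np.unique(mask):
        if lab == 0:
            continue
        comp = "nucleus" if lab % 2 == 1 else "cytosol"
        z = _logit(truth[comp]) + rep_shift[comp] + rng.normal(0.0, noise.cell_logit_sd)
        oxd_per_label[int(lab)] = float(_expit(z))
        nuc_base = rng.lognormal(np.log(2500.0), 0.25)
        base488_per_label[int(lab)] = nuc_base if comp == "nucleus" else 0.6 * nuc_base

    calib = truth_calibration(config)
    ch405, ch488 = _render(config, rng, mask, oxd_per_label, base488_per_label, calib)
    meta = dict(scenario=config.treatment_label, timepoint_h=timepoint_h,
                replicate=replicate, saturation_cap=config.saturation_cap,
                truth_oxd=truth)
    return ImageSet(ch405, ch488, mask, meta)


def generate_calibration_sets(config: ScenarioConfig) -> tuple[ImageSet, ImageSet]:
    """Fully reduced (OxD = 0) and fully oxidised (OxD = 1) calibration fields.

    Both sets share one base field (geometry and per-cell brightness), as if
    the same roots were imaged after each treatment; the oxidised 488 channel
    is the reduced one scaled by I488max/I488min = 1/k, so pooled-pixel
    calibration recovers R_red, R_ox and k.
    """
    rng_field = _rng(config, _DOM_CALIB, 0)
    mask = _build_mask(config, rng_field)
    base: dict[int, float] = {}
    for lab in np.unique(mask):
        if lab == 0:
            continue
        nuc_base = rng_field.lognormal(np.log(2500.0), 0.25)
        base[int(lab)] = nuc_base if lab % 2 == 1 else 0.6 * nuc_base

    calib = truth_calibration(config)
    sets = []
    for oxd, tag, scale, dom_key in ((0.0, "reduced", 1.0, 1),
                                     (1.0, "oxidized", 1.0 / calib.k, 2)):
        rng_noise = _rng(config, _DOM_CALIB, dom_key)
        scaled = {lab: b * scale for lab, b in base.items()}
        oxd_map = {lab: oxd for lab in base}
        ch405, ch488 = _render(config, rng_noise, mask, oxd_map, scaled, calib)
        meta = dict(scenario=config.treatment_label, calibration=tag,
                    saturation_cap=config.saturation_cap, truth_oxd=oxd)
        sets.append(ImageSet(ch405, ch488, mask.copy(), meta))
    return sets[0], sets[1]


# --------------------------------------------------------------------------
# flow cytometry


@dataclass
class FlowEventTable:
    """Flow-cytometry events: one row per nucleus (or debris particle).

    ``df`` columns: event_id, fsc, ssc, dna_fl and — in synthetic tables
    only — true_phase, the generating component (ground truth a real
    cytometer cannot provide; gating code must never read it).
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path, *, include_truth: bool = False) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = FLOW_CSV_COLUMNS + (["true_phase"] if include_truth and "true_phase" in self.df else [])
        self.df[cols].to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None) -> "FlowEventTable":
        df = pd.read_csv(path)
        missing = [c for c in FLOW_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"flow CSV {path} missing columns {missing}")
        return cls(df, metadata or {})


def _phase_counts(fractions: tuple[float, float, float], n: int) -> list[int]:
    """Integer phase counts matching the requested fractions exactly.

    Largest-remainder rounding, so counts sum to n and each count is within
    one event of fraction * n.
    """
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_flow_events(config: ScenarioConfig, timepoint_h: int,
                         n_events: int | None = None) -> FlowEventTable:
    """DNA-content events for one (scenario, timepoint).

    G1 events ~ Normal(mu, CV*mu) around the 2C position mu; G2 events ~
    Normal(2*mu, CV*2*mu) at 4C; S events are a uniform bridge on (mu, 2*mu)
    broadened by the G1 sigma; a debris fraction has exponentially decaying
    low-channel DNA fluorescence and separates from nuclei on the FSC/SSC
    scatter.  Event counts per component match the requested fractions
    exactly (largest-remainder rounding).  Deterministic given the seed.
    """
    n_events = int(n_events if n_events is not None else config.n_events)
    if n_events <= 0:
        raise ConfigurationError("n_events must be > 0")
    fractions = config.phase_truth(timepoint_h)
    rng = _rng(config, _DOM_FLOW, timepoint_h)
    noise = config.noise
    mu = config.g1_peak_position
    sigma1 = noise.flow_cv * mu

    n_debris = int(round(noise.debris_fraction * n_events))
    n_main = n_events - n_debris
    n_g1, n_s, n_g2 = _phase_counts(fractions, n_main)

    dna = np.concatenate([
        rng.normal(mu, sigma1, n_g1) if sigma1 > 0 else np.full(n_g1, mu),
        rng.uniform(mu, 2 * mu, n_s) + (rng.normal(0.0, sigma1, n_s) if sigma1 > 0 else 0.0),
        rng.normal(2 * mu, 2 * sigma1, n_g2) if sigma1 > 0 else np.full(n_g2, 2.0 * mu),
        np.minimum(rng.exponential(mu / 4.0, n_debris), 0.9 * mu) + 1.0,
    ])
    phase = np.array(["G1"] * n_g1 + ["S"] * n_s + ["G2"] * n_g2 + ["debris"] * n_debris)

    fsc = np.concatenate([rng.normal(500.0, 50.0, n_main), rng.normal(150.0, 40.0, n_debris)])
    ssc = np.concatenate([rng.normal(300.0, 40.0, n_main), rng.normal(80.0, 30.0, n_debris)])

    dna = np.maximum(dna, 1e-6)
    fsc = np.maximum(fsc, 1.0)
    ssc = np.maximum(ssc, 1.0)

    order = rng.permutation(n_events)
    df = pd.DataFrame({
        "event_id": np.arange(n_events),
        "fsc": fsc[order], "ssc": ssc[order], "dna_fl": dna[order],
        "true_phase": phase[order],
    })
    meta = dict(scenario=config.treatment_label, timepoint_h=timepoint_h,
                n_events=n_events, g1_peak_position=mu,
                truth_fractions=tuple(fractions), n_debris_truth=n_debris)
    return FlowEventTable(df, meta)


# --------------------------------------------------------------------------
# root growth


@dataclass
class RootLengthTable:
    """Root-length time course: one row per (seedling, timepoint)."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df[ROOT_CSV_COLUMNS].to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None) -> "RootLengthTable":
        df = pd.read_csv(path)
        missing = [c for c in ROOT_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"root-length CSV {path} missing columns {missing}")
        return cls(df, metadata or {})


_CONCENTRATION_MM = {"control": 0.0, "hc": 1.5, "hu": 3.0}


def generate_root_lengths(config: ScenarioConfig, *, n_seedlings: int = 30,
                          timepoints_h: tuple[int, ...] = GROWTH_TIMEPOINTS_H) -> RootLengthTable:
    """Per-seedling root lengths at the growth timepoints (default 0/24/48 h).

    Default 30 seedlings = 3 biological replicates of 10 seeds.  Each
    seedling grows at the scenario's true interval rate plus a seedling-level
    Gaussian rate deviation; recorded lengths carry Gaussian measurement
    noise.  Deterministic given the seed.
    """
    rng = _rng(config, _DOM_ROOTS, 0)
    noise = config.noise
    rows = []
    for sid in range(n_seedlings):
        length = max(0.5, rng.normal(2.0, 0.3))  # initial length, mm
        t_prev = timepoints_h[0]
        obs = {t_prev: length}
        for t in timepoints_h[1:]:
            rate = config.growth_truth((t_prev, t))
            rate = max(0.0, rate + rng.normal(0.0, noise.growth_rate_sd))
            length += rate * (t - t_prev) / 24.0
            obs[t] = length
            t_prev = t
        for t, l_true in obs.items():
            l_meas = max(0.0, l_true + rng.normal(0.0, noise.length_sd_mm))
            rows.append((config.treatment_label, _CONCENTRATION_MM[config.treatment_label],
                         sid, t, l_meas))
    df = pd.DataFrame(rows, columns=ROOT_CSV_COLUMNS)
    return RootLengthTable(df, dict(scenario=config.treatment_label, n_seedlings=n_seedlings))
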