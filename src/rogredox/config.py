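"""Scenario configurations: ground truths for the three treatment arms.

A :class:`ScenarioConfig` fully determines a simulated experiment: the true
degree of oxidation (OxD) of the roGFP2 probe in nucleus and cytosol at each
sampling time, the true G1/S/G2 phase mix of the root-tip nuclei population,
the true root growth rates, the probe/glutathione electrochemistry constants
and every noise amplitude. The three built-in scenarios are:

``control``
    untreated germinating roots — reduced compartments, stationary cell-cycle
    mix (67 % G1, 8 % S, 25 % G2), steady growth of 1.4 mm/d (0-24 h) and
    1.7 mm/d (24-48 h);
``hc``
    1.5 mM hydrogen cyanamide — an early transient cytosolic oxidation
    (OxD 0.37 at 2 h), strong oxidation of both compartments after 12 h,
    progressive G1 -> G2 shift (G1 55 % at 24 h), growth at 45 % of control
    after release;
``hu``
    3 mM hydroxyurea — early G1/S synchronisation with a transient cytosolic
    oxidation (OxD 0.32 at 2 h), reduced compartments late, growth at 72 % of
    control after release.

Per-compartment OxD trajectories are tabulated every 2 h over 0-24 h.  Each
trajectory's 13-point mean equals the treatment-level mean degree of oxidation
of its scenario (nuclei: 22.90 / 31.22 / 21.35 %; cytosol: 26.31 / 32.48 /
24.44 % for control / HC / HU), so a full time-course analysis recovers those
means by construction.  The HC nuclear trajectory additionally satisfies a
second moment condition: the mean of the per-timepoint Nernst potentials at
the default midpoint potential (-280 mV) equals -291.4 mV, which fixes the
spread of its step shape.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError

__all__ = [
    "NoiseParams",
    "ScenarioConfig",
    "scenario",
    "SCENARIO_NAMES",
    "REDOX_TIMEPOINTS_H",
    "FLOW_TIMEPOINTS_H",
    "GROWTH_TIMEPOINTS_H",
]

#: redox imaging sampling grid: every alternate hour over 24 h
REDOX_TIMEPOINTS_H: tuple[int, ...] = tuple(range(0, 25, 2))
#: flow-cytometry sampling times after transfer to treatment
FLOW_TIMEPOINTS_H: tuple[int, ...] = (0, 5, 12, 16, 24)
#: root-length measurement times (includes the 24-48 h recovery interval)
GROWTH_TIMEPOINTS_H: tuple[int, ...] = (0, 24, 48)

SCENARIO_NAMES = ("control", "hc", "hu")


@dataclass(frozen=True)
class NoiseParams:
    """Noise amplitudes for every simulated measurement modality.

    Attributes
    ----------
    photon_scale
        Variance-to-mean ratio of the shot noise on pixel intensities
        (1.0 = Poisson-like at unit gain).
    background_level
        Additive uniform background offset, intensity counts.
    read_noise_sd
        Gaussian read noise SD, intensity counts.
    replicate_logit_sd
        Replicate-to-replicate SD of the true OxD on the logit scale
        (keeps jittered values inside (0, 1)).
    cell_logit_sd
        Cell-to-cell OxD jitter within one field, logit scale.
    flow_cv
        Coefficient of variation of the G1 DNA-fluorescence peak.
    debris_fraction
        Fraction of flow events that are sub-nuclear debris.
    length_sd_mm
        Root-length measurement noise SD, mm.
    growth_rate_sd
        Seedling-to-seedling SD of the true growth rate, mm/d.
    """

    photon_scale: float = 1.0
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    replicate_logit_sd: float = 0.08
    cell_logit_sd: float = 0.03
    flow_cv: float = 0.05
    debris_fraction: float = 0.02
    length_sd_mm: float = 0.10
    growth_rate_sd: float = 0.10

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigurationError(f"noise parameter {f.name} must be >= 0, got {v}")
        if self.debris_fraction >= 1:
            raise ConfigurationError("debris_fraction must be < 1")

    @staticmethod
    def zero() -> "NoiseParams":
        """Noise-free parameters for round-trip and oracle tests."""
        return NoiseParams(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# --- frozen ground-truth tables ------------------------------------------
# OxD trajectories on the 0-24 h / 2 h grid; 13-point means equal the
# treatment-level mean OxD of each scenario.

_OXD_TRUTH: dict[str, dict[str, tuple[float, ...]]] = {
    "control": {
        "nucleus": (0.195, 0.190, 0.205, 0.220, 0.235, 0.245, 0.250,
                    0.250, 0.245, 0.240, 0.235, 0.233, 0.234),
        "cytosol": (0.21233, 0.20533, 0.22233, 0.24233, 0.26233, 0.27733,
                    0.28733, 0.29233, 0.29233, 0.28733, 0.28233, 0.27933,
                    0.27733),
    },
    "hc": {
        # step shape: no significant change for 12 h, strong oxidation after;
        # mean = 0.3122 and mean Nernst E at E0=-280 mV = -291.4 mV
        "nucleus": (0.19533, 0.18533, 0.17533, 0.16533, 0.15533, 0.16533,
                    0.18533, 0.42188, 0.45188, 0.47188, 0.48188, 0.49188,
                    0.51188),
        # transient oxidation event at 2 h (OxD 0.37), late rise; mean 0.3248
        "cytosol": (0.27937, 0.37, 0.32937, 0.29937, 0.27937, 0.26937,
                    0.26937, 0.27937, 0.29937, 0.32937, 0.36937, 0.40937,
                    0.43937),
    },
    "hu": {
        # nuclear oxidation only at 4-8 h, reduced late; mean 0.2135
        "nucleus": (0.19368, 0.22368, 0.32, 0.28368, 0.32, 0.24368, 0.20368,
                    0.18368, 0.17368, 0.16368, 0.15868, 0.15368, 0.15368),
        # cytosolic oxidation event at 2 h (OxD 0.32); mean 0.2444
        "cytosol": (0.21952, 0.32, 0.29952, 0.28952, 0.26952, 0.24952,
                    0.23952, 0.22952, 0.21952, 0.21452, 0.20952, 0.20952,
                    0.20752),
    },
}

# (G1, S, G2) truth per flow timepoint
_PHASE_TRUTH: dict[str, dict[int, tuple[float, float, float]]] = {
    "control": {t: (0.67, 0.08, 0.25) for t in FLOW_TIMEPOINTS_H},
    "hc": {
        0: (0.67, 0.08, 0.25),
        5: (0.66, 0.08, 0.26),
        12: (0.63, 0.08, 0.29),
        16: (0.60, 0.08, 0.32),
        24: (0.55, 0.08, 0.37),
    },
    "hu": {
        0: (0.67, 0.08, 0.25),
        5: (0.75, 0.15, 0.10),
        12: (0.40, 0.20, 0.40),
        16: (0.30, 0.10, 0.60),
        24: (0.55, 0.10, 0.35),
    },
}

# control absolute growth rates mm/d per interval; treated arms are the
# post-release relative factors (HC 0.45x, HU 0.72x on 0-24 h)
_CONTROL_RATE: dict[tuple[int, int], float] = {(0, 24): 1.4, (24, 48): 1.7}
_RELATIVE_RATE: dict[str, dict[tuple[int, int], float]] = {
    "control": {(0, 24): 1.0, (24, 48): 1.0},
    "hc": {(0, 24): 0.45, (24, 48): 1.0},
    "hu": {(0, 24): 0.72, (24, 48): 0.65},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full ground truth + instrument model for one simulated experiment."""

    treatment_label: str
    timepoints_h: tuple[int, ...] = REDOX_TIMEPOINTS_H
    truth_oxd: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    truth_phase_fractions: Mapping[int, tuple[float, float, float]] = field(default_factory=dict)
    truth_growth_rate: Mapping[tuple[int, int], float] = field(default_factory=dict)
    # calibration truth (instrument values; exercised over the full OxD domain)
    r_red: float = 0.2
    r_ox: float = 2.0
    k_instrument: float = 0.5
    # electrochemistry
    midpoint_potential_probe_mV: float = -280.0
    midpoint_potential_gsh_mV: float = -240.0
    gsh_total_M: float = 2.5e-3
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_replicates: int = 5
    seed: int = 0
    # image geometry
    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 20
    saturation_cap: int = 65535
    # flow
    g1_peak_position: float = 200.0
    n_events: int = 100_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.treatment_label not in SCENARIO_NAMES:
            raise ConfigurationError(
                f"unknown treatment {self.treatment_label!r}; expected one of {SCENARIO_NAMES}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not (self.r_ox > self.r_red):
            raise ConfigurationError("calibration requires R_ox > R_red")
        if self.k_instrument <= 0:
            raise ConfigurationError("instrument factor k must be > 0")
        if self.gsh_total_M <= 0:
            raise ConfigurationError("gsh_total_M must be > 0")
        self.noise.validate()
        for comp, traj in self.truth_oxd.items():
            if len(traj) != len(self.timepoints_h):
                raise ConfigurationError(
                    f"truth_oxd[{comp!r}] length {len(traj)} != {len(self.timepoints_h)} timepoints")
            for v in traj:
                if not (0.0 < v < 1.0):
                    raise ConfigurationError(f"truth OxD must lie in (0,1), got {v}")
        for t, fr in self.truth_phase_fractions.items():
            if any(x < 0 or x > 1 for x in fr):
                raise ConfigurationError(f"phase fractions at {t} h out of [0,1]: {fr}")
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ConfigurationError(f"phase fractions at {t} h sum to {sum(fr)}, not 1")

    # -- ground-truth accessors ------------------------------------------
    def oxd_truth(self, compartment: str, timepoint_h: int) -> float:
        try:
            i = self.timepoints_h.index(timepoint_h)
        except ValueError:
            raise ConfigurationError(
                f"timepoint {timepoint_h} h not in scenario grid {self.timepoints_h}") from None
        return self.truth_oxd[compartment][i]

    def phase_truth(self, timepoint_h: int) -> tuple[float, float, float]:
        try:
            return self.truth_phase_fractions[timepoint_h]
        except KeyError:
            raise ConfigurationError(
                f"no phase-fraction truth at {timepoint_h} h for {self.treatment_label}") from None

    def growth_truth(self, interval: tuple[int, int]) -> float:
        try:
            return self.truth_growth_rate[interval]
        except KeyError:
            raise ConfigurationError(
                f"no growth-rate truth for interval {interval} in {self.treatment_label}") from None

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth_oxd"] = {k: list(v) for k, v in self.truth_oxd.items()}
        d["truth_phase_fractions"] = {str(k): list(v) for k, v in self.truth_phase_fractions.items()}
        d["truth_growth_rate"] = {f"{a}-{b}": v for (a, b), v in self.truth_growth_rate.items()}
        d["timepoints_h"] = list(self.timepoints_h)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], Mapping):
            d["noise"] = NoiseParams(**d["noise"])
        d["timepoints_h"] = tuple(d.get("timepoints_h", REDOX_TIMEPOINTS_H))
        d["truth_oxd"] = {k: tuple(v) for k, v in d.get("truth_oxd", {}).items()}
        d["truth_phase_fractions"] = {
            int(k): tuple(v) for k, v in d.get("truth_phase_fractions", {}).items()}
        d["truth_growth_rate"] = {
            tuple(int(x) for x in k.split("-")): v
            for k, v in d.get("truth_growth_rate", {}).items()}
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def scenario(name: str, *, seed: int = 0, n_replicates: int = 5,
             noise: NoiseParams | None = None, **overrides) -> ScenarioConfig:
    """Build one of the three named scenarios with its default ground truth.

    Parameters
    ----------
    name
        ``"control"``, ``"hc"`` or ``"hu"`` (case-insensitive).
    seed
        Master seed; all randomness of every generator derives from it.
    n_replicates
        Biological replicates per timepoint for the imaging arm.
    noise
        Override the default :class:`NoiseParams` (e.g. ``NoiseParams.zero()``).
    overrides
        Any other :class:`ScenarioConfig` field.
    """
    key = name.lower()
    if key not in SCENARIO_NAMES:
        raise ConfigurationError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    rel = _RELATIVE_RATE[key]
    growth = {iv: _CONTROL_RATE[iv] * rel[iv] for iv in _CONTROL_RATE}
    kwargs: dict = dict(
        treatment_label=key,
        truth_oxd=dict(_OXD_TRUTH[key]),
        truth_phase_fractions=dict(_PHASE_TRUTH[key]),
        truth_growth_rate=growth,
        n_replicates=n_replicates,
        seed=seed,
    )
    if noise is not None:
        kwargs["noise"] = noise
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)
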