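"""Calibration, degree of oxidation and Nernst redox potentials for roGFP2.

The roGFP2 excitation ratio R = I405/I488 moves between two instrument-
specific endpoints: ``R_red`` (probe fully reduced, e.g. after DTT) and
``R_ox`` (fully oxidised, after H2O2).  With the instrument factor
k = I488min / I488max (488-excitation intensity of the fully reduced over the
fully oxidised probe), the degree of oxidation is

    OxD = (R - R_red) / [ k * (R_ox - R) + (R - R_red) ]

so that OxD(R_red) = 0 and OxD(R_ox) = 1 exactly.  OxD feeds two Nernst
forms (RT/zF = 12.848 mV at 298.15 K with two electrons):

    E_probe = E0_probe - (RT/zF) * ln[(1 - OxD) / OxD]
    E_GSH   = E0_gsh   - (RT/zF) * ln[2 * GSH_tot * (1 - OxD)^2 / OxD]

E_probe is the probe-couple potential; E_GSH is the glutathione-couple
potential, which through the total glutathione concentration GSH_tot (molar)
accounts for the 2 GSH -> GSSG stoichiometry.  Because roGFP2 equilibrates
with the glutathione pool via glutaredoxin, both are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .errors import (CalibrationInversionError, ConfigurationError, InputError,
                     MeasurementError, UndefinedPotentialError)
from .images import BACKGROUND, CYTOSOL, NUCLEUS, ImageSet, compartment_mask

__all__ = [
    "CalibrationState", "NernstConstants", "ROIIntensities", "RedoxSummary",
    "measure_roi", "estimate_calibration", "compute_oxd",
    "compute_e_probe", "compute_e_gsh", "run_redox_timecourse",
]

_EPS_INTENSITY = 1e-9  # floor for background-subtracted means


@dataclass(frozen=True)
class CalibrationState:
    """Sensor calibration endpoints estimated from reduced/oxidised fields."""

    r_red: float
    r_ox: float
    i488min: float  # 488-excitation intensity, fully reduced probe
    i488max: float  # 488-excitation intensity, fully oxidised probe

    def __post_init__(self) -> None:
        if self.i488min <= 0 or self.i488max <= 0:
            raise ConfigurationError("calibration intensities must be > 0")
        if not self.r_ox > self.r_red:
            raise CalibrationInversionError(
                f"R_ox ({self.r_ox:.4g}) <= R_red ({self.r_red:.4g}): "
                "reduced/oxidised sets swapped or calibration treatments failed")

    @property
    def k(self) -> float:
        """Instrument factor I488min / I488max."""
        return self.i488min / self.i488max

    @classmethod
    def from_ratios(cls, r_red: float, r_ox: float, k: float) -> "CalibrationState":
        """Build a state from ratios and the instrument factor directly."""
        if k <= 0:
            raise ConfigurationError(f"instrument factor k must be > 0, got {k}")
        return cls(r_red=r_red, r_ox=r_ox, i488min=k, i488max=1.0)


@dataclass(frozen=True)
class NernstConstants:
    """Physical constants and midpoint potentials for the Nernst forms."""

    r_gas: float = 8.315          # J / (K mol)
    temperature_K: float = 298.15
    z_electrons: int = 2
    faraday: float = 9.648e4      # C / mol
    e0_probe_mV: float = -280.0   # roGFP2 midpoint potential
    e0_gsh_mV: float = -240.0     # glutathione-couple midpoint potential
    gsh_total_M: float = 2.5e-3   # total glutathione, molar

    @property
    def rt_zf_mV(self) -> float:
        """RT/zF in millivolts (~12.848 mV at 298.15 K, z = 2)."""
        return self.r_gas * self.temperature_K / (self.z_electrons * self.faraday) * 1e3

    @classmethod
    def from_config(cls, config: ScenarioConfig) -> "NernstConstants":
        return cls(e0_probe_mV=config.midpoint_potential_probe_mV,
                   e0_gsh_mV=config.midpoint_potential_gsh_mV,
                   gsh_total_M=config.gsh_total_M)


class ROIIntensities(NamedTuple):
    """Background-subtracted mean intensities of one compartment."""

    i405: float
    i488: float
    n_saturated: int


def measure_roi(image_set: ImageSet, compartment: str) -> ROIIntensities:
    """Mean background-subtracted 405/488 intensities over one compartment.

    Background is the per-channel mean over background-labelled pixels.
    Pixels at the saturation cap in either channel are excluded from the
    compartment mean and counted in ``n_saturated``.
    """
    sel = compartment_mask(image_set.label_mask, compartment)
    if not sel.any():
        raise InputError(f"mask contains no {compartment!r} pixels")
    bg = compartment_mask(image_set.label_mask, BACKGROUND)
    if not bg.any():
        raise InputError("mask contains no background pixels")

    cap = image_set.saturation_cap
    sat = (image_set.channel_405 >= cap) | (image_set.channel_488 >= cap)
    n_sat = int((sel & sat).sum())
    ok = sel & ~sat
    if not ok.any():
        raise MeasurementError(f"every {compartment!r} pixel is saturated")

    i405 = image_set.channel_405[ok].mean() - image_set.channel_405[bg].mean()
    i488 = image_set.channel_488[ok].mean() - image_set.channel_488[bg].mean()
    return ROIIntensities(max(float(i405), _EPS_INTENSITY),
                          max(float(i488), _EPS_INTENSITY), n_sat)


def estimate_calibration(reduced: ImageSet, oxidized: ImageSet) -> CalibrationState:
    """Estimate calibration endpoints from a fully reduced / fully oxidised pair.

    Intensities are pooled over all ROI pixels (nuclei and cytosol of every
    cell), mirroring whole-proliferation-zone calibration: R_red and I488min
    come from the reduced field, R_ox and I488max from the oxidised one.

    Raises
    ------
    CalibrationInversionError
        If the resulting R_ox <= R_red, which indicates the two inputs were
        swapped or a calibration treatment failed.
    """
    def pooled(img: ImageSet) -> tuple[float, float]:
        roi = compartment_mask(img.label_mask, NUCLEUS) | compartment_mask(img.label_mask, CYTOSOL)
        if not roi.any():
            raise InputError("calibration image has no ROI pixels")
        bg = compartment_mask(img.label_mask, BACKGROUND)
        if not bg.any():
            raise InputError("calibration image has no background pixels")
        cap = img.saturation_cap
        ok = roi & (img.channel_405 < cap) & (img.channel_488 < cap)
        if not ok.any():
            raise MeasurementError("all calibration ROI pixels saturated")
        i405 = img.channel_405[ok].mean() - img.channel_405[bg].mean()
        i488 = img.channel_488[ok].mean() - img.channel_488[bg].mean()
        return max(float(i405), _EPS_INTENSITY), max(float(i488), _EPS_INTENSITY)

    i405_red, i488_red = pooled(reduced)
    i405_ox, i488_ox = pooled(oxidized)
    return CalibrationState(r_red=i405_red / i488_red, r_ox=i405_ox / i488_ox,
                            i488min=i488_red, i488max=i488_ox)


def compute_oxd(r, calib: CalibrationState, *, clamp: bool = True):
    """Degree of oxidation from the 405/488 excitation ratio.

    Ratios outside [R_red, R_ox] (routine under noise) are clamped to the
    endpoints with a warning; pass ``clamp=False`` to leave them unclamped,
    in which case OxD may fall outside [0, 1].  Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if clamp:
        out_of_range = (r < calib.r_red) | (r > calib.r_ox)
        if np.any(out_of_range):
            warnings.warn(
                f"{int(np.sum(out_of_range))} ratio value(s) outside "
                f"[R_red, R_ox]=[{calib.r_red:.4g}, {calib.r_ox:.4g}]; clamped",
                stacklevel=2)
            r = np.clip(r, calib.r_red, calib.r_ox)
    num = r - calib.r_red
    oxd = num / (calib.k * (calib.r_ox - r) + num)
    return float(oxd) if oxd.ndim == 0 else oxd


def _check_open_unit(oxd: float, what: str) -> None:
    if not (0.0 < oxd < 1.0):
        raise UndefinedPotentialError(
            f"{what} undefined at OxD={oxd}; clamp OxD into (0, 1) first")


def compute_e_probe(oxd: float, constants: NernstConstants = NernstConstants()) -> float:
    """Probe (roGFP2-couple) redox potential in mV from the degree of oxidation."""
    _check_open_unit(oxd, "probe potential")
    return constants.e0_probe_mV - constants.rt_zf_mV * np.log((1.0 - oxd) / oxd)


def compute_e_gsh(oxd_gsh: float, constants: NernstConstants = NernstConstants()) -> float:
    """Glutathione-couple potential in mV, concentration-dependent form."""
    _check_open_unit(oxd_gsh, "glutathione potential")
    if constants.gsh_total_M <= 0:
        raise ConfigurationError("gsh_total_M must be > 0")
    arg = 2.0 * constants.gsh_total_M * (1.0 - oxd_gsh) ** 2 / oxd_gsh
    return constants.e0_gsh_mV - constants.rt_zf_mV * np.log(arg)


@dataclass
class RedoxSummary:
    """Replicate-level measurements and their per-timepoint / grand summaries.

    ``measurements``: one row per (compartment, timepoint, replicate) with
    intensities, ratio, OxD and both potentials.  ``summary``: mean +/- SEM
    per (compartment, timepoint).  ``grand``: per-compartment mean over
    timepoint means with SEM across timepoints — the time-course analogue of
    a treatment-level summary table.  Averaging order is fixed: OxD and E are
    computed per replicate, then averaged.
    """

    measurements: pd.DataFrame
    summary: pd.DataFrame
    grand: pd.DataFrame
    calibration: CalibrationState
    constants: NernstConstants = field(default_factory=NernstConstants)

    def grand_mean(self, compartment: str, column: str = "oxd_pct") -> float:
        row = self.grand.loc[self.grand.compartment == compartment]
        if row.empty:
            raise InputError(f"no grand summary for compartment {compartment!r}")
        return float(row[column].iloc[0])


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def run_redox_timecourse(
    image_sets: Iterable[ImageSet],
    calib: CalibrationState,
    constants: NernstConstants = NernstConstants(),
    *,
    clamp_eps: float = 1e-4,
    pixelwise: bool = False,
) -> RedoxSummary:
    """Full ratio -> OxD -> E analysis of a time course of image sets.

    Each image set must carry ``timepoint_h`` and ``replicate`` in its
    metadata.  Per replicate, compartment ratios come from ROI-mean
    intensities (set ``pixelwise=True`` to average per-pixel ratios instead);
    OxD values are clamped into [clamp_eps, 1 - clamp_eps] before the Nernst
    step so boundary replicates yield finite potentials.
    """
    if calib is None:
        raise ConfigurationError("calibration state is required")
    rows = []
    for img in image_sets:
        meta = img.metadata
        if "timepoint_h" not in meta or "replicate" not in meta:
            raise InputError("image set metadata must include timepoint_h and replicate")
        for comp in (NUCLEUS, CYTOSOL):
            if pixelwise:
                sel = compartment_mask(img.label_mask, comp)
                bgm = compartment_mask(img.label_mask, BACKGROUND)
                b405 = img.channel_405[bgm].mean()
                b488 = img.channel_488[bgm].mean()
                num = img.channel_405[sel] - b405
                den = np.maximum(img.channel_488[sel] - b488, _EPS_INTENSITY)
                ratio = float(np.mean(num / den))
                i405, i488 = float(num.mean()), float(den.mean())
            else:
                roi = measure_roi(img, comp)
                i405, i488 = roi.i405, roi.i488
                ratio = i405 / i488
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # clamping logged in summary counts
                oxd = compute_oxd(ratio, calib)
            oxd_c = float(np.clip(oxd, clamp_eps, 1.0 - clamp_eps))
            rows.append(dict(
                compartment=comp,
                time_h=meta["timepoint_h"],
                replicate=meta["replicate"],
                i405=i405, i488=i488, ratio=ratio, oxd=oxd,
                e_probe_mV=compute_e_probe(oxd_c, constants),
                e_gsh_mV=compute_e_gsh(oxd_c, constants),
            ))
    if not rows:
        raise InputError("no image sets provided")
    meas = pd.DataFrame(rows).sort_values(["compartment", "time_h", "replicate"],
                                          ignore_index=True)

    summary = (meas.groupby(["compartment", "time_h"], as_index=False)
               .agg(oxd_mean_pct=("oxd", lambda v: 100.0 * np.mean(v)),
                    oxd_sem_pct=("oxd", lambda v: 100.0 * _sem(np.asarray(v))),
                    e_mean_mV=("e_probe_mV", "mean"),
                    e_sem_mV=("e_probe_mV", _sem),
                    e_gsh_mean_mV=("e_gsh_mV", "mean"),
                    n=("oxd", "size")))

    grand = (summary.groupby("compartment", as_index=False)
             .agg(oxd_pct=("oxd_mean_pct", "mean"),
                  oxd_sem_pct=("oxd_mean_pct", _sem),
                  e_probe_mV=("e_mean_mV", "mean"),
                  e_sem_mV=("e_mean_mV", _sem),
                  e_gsh_mV=("e_gsh_mean_mV", "mean"),
                  n_timepoints=("time_h", "size")))

    return RedoxSummary(meas, summary, grand, calib, constants)
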