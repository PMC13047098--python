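"""Configuration objects for the synthetic strip-trial simulator.

The simulator emulates on-farm corn N-rate strip trials: a small number of
fields (trials), each with parallel applicator-width plots split into subplots,
where a *transect* is a set of adjacent subplots spanning the full range of N
rates on uniform soil. Reflectance scenes are rendered by linear spectral
mixing of canopy, soil and crop-residue endmembers on a regular 3-m grid.

All N rates are kg N ha^-1, yields Mg ha^-1 at 15% moisture, lengths meters,
reflectance unitless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import yaml

BANDS: Tuple[str, ...] = ("blue", "green", "red", "nir")

#: Synthetic endmember spectra (B/G/R/NIR surface reflectance). These are
#: plausible green-canopy / bare-soil / dry-residue values chosen for the
#: simulator, not measurements from any instrument.
DEFAULT_ENDMEMBERS: Dict[str, Dict[str, float]] = {
    "canopy": {"blue": 0.03, "green": 0.08, "red": 0.05, "nir": 0.50},
    "soil": {"blue": 0.06, "green": 0.09, "red": 0.12, "nir": 0.18},
    "residue": {"blue": 0.10, "green": 0.15, "red": 0.20, "nir": 0.28},
}

#: Image-timing calendar: timing index -> (growth-stage label, period tag).
#: Timings 1-3 fall in the vegetative window (V7 through V16), 4-7 in the
#: reproductive window (R1 through R6).
DEFAULT_TIMING_CALENDAR: Dict[int, Tuple[str, str]] = {
    1: ("V7-V8", "vegetative"),
    2: ("V10-V11", "vegetative"),
    3: ("V15-V16", "vegetative"),
    4: ("R1-R2", "reproductive"),
    5: ("R3-R4", "reproductive"),
    6: ("R5", "reproductive"),
    7: ("R6", "reproductive"),
}

ARTIFACT_CLASSES: Tuple[str, ...] = (
    "moisture_low",
    "moisture_high",
    "speed_low",
    "speed_high",
    "speed_jump",
    "heading",
    "yield_outlier",
)


@dataclass
class TrialSpec:
    """Per-trial design block: treatments, geometry and residue scenario.

    ``treatments`` is an ordered list of (label, N rate) pairs; duplicated
    rates (e.g. a 50%FNR treatment applied twice for a companion study) appear
    as distinct treatments with equal rates.
    """

    trial_id: str
    fnr: float
    treatments: Tuple[Tuple[str, float], ...]
    residue_fraction: float = 0.2
    subplot_length_m: float = 55.0
    plot_width_m: float = 9.14
    replications: int = 1

    @property
    def n_rates(self) -> Tuple[float, ...]:
        return tuple(rate for _, rate in self.treatments)

    @property
    def max_n_rate(self) -> float:
        return max(self.n_rates)

    def validate(self) -> None:
        if not 0.0 <= self.residue_fraction <= 1.0:
            raise ValueError(
                f"{self.trial_id}: residue_fraction must be in [0, 1], "
                f"got {self.residue_fraction}"
            )
        if self.subplot_length_m <= 0 or self.plot_width_m <= 0:
            raise ValueError(f"{self.trial_id}: non-positive subplot dimensions")
        rates = self.n_rates
        if any(r <= 0 for r in rates):
            raise ValueError(f"{self.trial_id}: N rates must be strictly positive")
        if list(rates) != sorted(rates):
            raise ValueError(f"{self.trial_id}: N rates must be sorted ascending")
        if len(set(rates)) < 3:
            raise ValueError(
                f"{self.trial_id}: need >= 3 distinct N rates, got {len(set(rates))} "
                "(plateau models are unidentifiable otherwise)"
            )


@dataclass
class SimConfig:
    """Full simulator configuration.

    The per-transect true optimum N rate (AONR) is drawn from a normal
    distribution truncated to (0, max tested rate]; subplot expected yield
    follows the configured plateau family with its join at that AONR.
    Canopy cover per subplot and timing is either a logistic-in-timing curve
    scaled by N sufficiency ``min(1, N/AONR)**gamma`` (``canopy_response=
    "logistic"``, the default) or, for exact end-to-end recovery studies, the
    same plateau family as yield normalized to [rel0, 1]
    (``canopy_response="plateau"``).
    """

    trials: Tuple[TrialSpec, ...]
    transects_per_trial: int = 8
    buffer_adjacent_m: float = 1.5
    buffer_consecutive_m: float = 15.0
    margin_m: float = 6.0
    pixel_size_m: float = 3.0
    timing_calendar: Dict[int, Tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_TIMING_CALENDAR)
    )
    endmembers: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {m: dict(b) for m, b in DEFAULT_ENDMEMBERS.items()}
    )
    # true N-response parameters
    aonr_mean: float = 185.0
    aonr_sd: float = 25.0
    plateau_yield_mean: float = 13.0
    plateau_yield_sd: float = 0.8
    rel_yield_at_zero: float = 0.55
    yield_family: str = "quadratic_plateau"  # or "linear_plateau"
    # canopy model
    canopy_response: str = "logistic"  # or "plateau"
    canopy_gamma: float = 0.5
    canopy_rel_at_zero: float = 0.4
    canopy_logistic_rate: float = 1.4
    canopy_logistic_midpoint: float = 1.8
    # noise
    noise_sd_reflectance: float = 0.01
    noise_sd_yield: float = 0.4
    #: Round rendered scenes to whole scaled-integer counts (the 16-bit
    #: sensor-product convention, ~1e-4 reflectance resolution). A real noise
    #: source: disable it (with the other noise terms) for exact zero-noise
    #: recovery studies.
    quantize_scenes: bool = True
    # yield-monitor stream
    points_per_subplot: int = 20
    artifact_fraction: float = 0.05
    nominal_speed_mph: float = 5.0
    nominal_moisture_pct: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not self.trials:
            raise ValueError("at least one trial is required")
        for t in self.trials:
            t.validate()
        if self.transects_per_trial <= 0:
            raise ValueError("transects_per_trial must be positive")
        if self.buffer_adjacent_m < 0 or self.buffer_consecutive_m < 0:
            raise ValueError("buffers must be >= 0")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        for material in ("canopy", "soil", "residue"):
            if material not in self.endmembers:
                raise ValueError(f"endmembers missing material {material!r}")
            for band in BANDS:
                if band not in self.endmembers[material]:
                    raise ValueError(
                        f"endmember {material!r} missing band {band!r}"
                    )
                v = self.endmembers[material][band]
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"endmember {material}/{band} reflectance {v} outside [0, 1]"
                    )
        if self.canopy_response not in ("logistic", "plateau"):
            raise ValueError(f"unknown canopy_response {self.canopy_response!r}")
        if self.yield_family not in ("quadratic_plateau", "linear_plateau"):
            raise ValueError(f"unknown yield_family {self.yield_family!r}")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must be in [0, 1]")
        if not 0.0 < self.rel_yield_at_zero < 1.0:
            raise ValueError("rel_yield_at_zero must be in (0, 1)")
        if self.aonr_mean <= 0 or self.aonr_sd < 0:
            raise ValueError("invalid true-AONR distribution")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with fields replaced (convenience wrapper)."""
        return replace(self, **kwargs)

    def vegetative_timings(self) -> List[int]:
        return [t for t, (_, p) in sorted(self.timing_calendar.items())
                if p == "vegetative"]

    def reproductive_timings(self) -> List[int]:
        return [t for t, (_, p) in sorted(self.timing_calendar.items())
                if p == "reproductive"]


def default_study_design(seed: int = 0, **overrides) -> SimConfig:
    """The default three-trial study design.

    Emulates a 2021 Indiana on-farm experiment: one strip-till field following
    soybean (ST-S, high residue) and two conventionally tilled fields following
    corn (CT-C) and soybean (CT-S, low residue). Each trial has 8 reference
    transects; treatments are percentages of the farmer's normal N rate (FNR),
    with the 50%FNR treatment duplicated at CT-C and CT-S.
    """
    trials = (
        TrialSpec(
            trial_id="ST-S",
            fnr=222.0,
            treatments=(
                ("20%FNR", 44.0),
                ("40%FNR", 89.0),
                ("70%FNR", 155.0),
                ("100%FNR", 222.0),
                ("130%FNR", 289.0),
            ),
            residue_fraction=0.6,
            subplot_length_m=55.0,
            plot_width_m=9.14,
            replications=7,
        ),
        TrialSpec(
            trial_id="CT-C",
            fnr=222.0,
            treatments=(
                ("50%FNR-a", 111.0),
                ("50%FNR-b", 111.0),
                ("70%FNR", 155.0),
                ("100%FNR", 222.0),
                ("130%FNR", 289.0),
            ),
            residue_fraction=0.25,
            subplot_length_m=61.0,
            plot_width_m=18.29,
            replications=2,
        ),
        TrialSpec(
            trial_id="CT-S",
            fnr=180.0,
            treatments=(
                ("50%FNR-a", 90.0),
                ("50%FNR-b", 90.0),
                ("70%FNR", 126.0),
                ("100%FNR", 180.0),
                ("130%FNR", 234.0),
            ),
            residue_fraction=0.10,
            subplot_length_m=61.0,
            plot_width_m=18.29,
            replications=4,
        ),
    )
    cfg = SimConfig(trials=trials, seed=seed, **overrides)
    cfg.validate()
    return cfg


def simconfig_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. a parsed YAML block)."""
    d = dict(d)
    trials = []
    for tb in d.pop("trials", []):
        tb = dict(tb)
        tb["treatments"] = tuple(
            (str(lbl), float(rate)) for lbl, rate in tb["treatments"]
        )
        trials.append(TrialSpec(**tb))
    if not trials:
        return default_study_design(**d)
    if "timing_calendar" in d:
        d["timing_calendar"] = {
            int(k): (str(v[0]), str(v[1])) for k, v in d["timing_calendar"].items()
        }
    cfg = SimConfig(trials=tuple(trials), **d)
    cfg.validate()
    return cfg


def load_sim_config(path: str) -> SimConfig:
    """Load a SimConfig from a YAML file (empty file -> default design)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return simconfig_from_dict(doc)
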