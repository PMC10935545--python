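"""Run configuration for the trench simulator and analysis pipeline.

All mechanistic parameters live in :class:`SimConfig`; the external H2O2
treatment is a :class:`TreatmentSchedule`.  Configurations round-trip through
YAML (flat nested mapping) and carry a content digest used for provenance
headers in every output file.

Units are stated per field: lengths in micrometres, times in minutes,
concentrations in micromolar, fluorescence in arbitrary units (a.u.).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

GENOTYPES = ("WT", "delta_oxyR", "inert")


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant."""


@dataclass
class EnzymeInduction:
    """OxyR-controlled scavenging-enzyme induction.

    The enzyme level ``E`` is dimensionless in [0, 1].  Induction senses the
    intracellular H2O2 concentration after a transport/signalling delay, with
    a sharp Hill activation, and is diluted by growth.  Severe oxidative
    damage slows protein synthesis; the same saturating damage factor applies
    to all protein production.
    """

    delay_min: float = 2.0          # sensing delay tau before induction responds
    max_rate: float = 0.12          # min^-1, maximal induction rate constant
    hill_k_uM: float = 0.02         # half-activation of induction (intracellular)
    hill_n: float = 2.0
    basal_level: float = 0.15       # constitutive scavenging capacity (Ahp-like)
    damage_k_uM: float = 15.0       # intracellular conc. above which protein
    damage_n: float = 3.0           # synthesis collapses (sharp saturation)


@dataclass
class ReporterKinetics:
    """Transcriptional reporter (PgrxA-CFP analogue) production.

    Production per unit cell area is ``basal_rate + max_induced_rate * H(c)``
    sensing the delayed intracellular concentration; the reporter delay is
    longer than the enzyme delay because the fluorophore must mature before
    it is seen, so reporter production reflects concentrations after the
    shielding gradient has formed.  The reporter protein is stable: it is
    removed only by growth dilution and division partitioning.
    """

    basal_rate: float = 11.0            # a.u. min^-1 per unit area
    max_induced_rate: float = 824.0     # a.u. min^-1 per unit area
    hill_k_uM: float = 8.0
    hill_n: float = 1.0
    delay_min: float = 12.0             # sensing + fluorophore maturation delay
    steady_state_target: float = 7400.0  # a.u., open-end cell at 100 uM


@dataclass
class GrowthInhibition:
    """Hill inhibition of elongation by intracellular H2O2: g = 1/(1+(c/K)^m).

    The constant refers to the concentration a cell maintains internally
    after its scavenging feedback, so shielded interior cells keep growing
    while fully exposed cells at the trench opening stay strongly slowed,
    as observed along the trench during sustained treatment.
    """

    k_uM: float = 2.0
    exponent: float = 2.0


@dataclass
class DeathRule:
    """Absorbing death rule.

    A cell dies when its intracellular concentration exceeds
    ``lethal_uM + priming_coefficient_uM * E`` continuously for
    ``sustained_min`` minutes: induced (primed) cells tolerate substantially
    higher concentrations.  Dead cells stop growing permanently but remain in
    the trench as non-scavenging mass until pushed out.
    """

    lethal_uM: float = 20.0
    sustained_min: float = 5.0
    priming_coefficient_uM: float = 100.0


@dataclass
class MismatchRates:
    """Poisson rate of DNA-mismatch foci: lambda = basal + induced_per_uM * c_int * (1 - E)."""

    basal: float = 2.0e-4           # foci cell^-1 min^-1
    induced_per_uM: float = 1.0e-3  # foci cell^-1 min^-1 uM^-1


@dataclass
class Segment:
    """One treatment segment: constant concentration, or a linear ramp if
    ``c_end_uM`` is given.  Times are minutes relative to treatment start."""

    start_min: float
    end_min: float
    c_uM: float
    c_end_uM: float | None = None

    def concentration(self, t: float) -> float:
        if self.c_end_uM is None:
            return self.c_uM
        frac = (t - self.start_min) / (self.end_min - self.start_min)
        return self.c_uM + (self.c_end_uM - self.c_uM) * min(max(frac, 0.0), 1.0)


@dataclass
class TreatmentSchedule:
    """Piecewise external H2O2 concentration at the trench opening.

    Uncovered times have zero concentration.  Segments must be ordered and
    non-overlapping.
    """

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = [Segment(**s) if isinstance(s, dict) else s for s in self.segments]
        self.segments = sorted(segs, key=lambda s: s.start_min)
        prev_end = -float("inf")
        for s in self.segments:
            if s.end_min <= s.start_min:
                raise ConfigError(f"segment with non-positive duration: {s}")
            if s.c_uM < 0 or (s.c_end_uM is not None and s.c_end_uM < 0):
                raise ConfigError(f"negative concentration in segment: {s}")
            if s.start_min < prev_end:
                raise ConfigError(f"overlapping treatment segments at t={s.start_min}")
            prev_end = s.end_min

    def concentration(self, t: float) -> float:
        for s in self.segments:
            if s.start_min <= t < s.end_min:
                return s.concentration(t)
        return 0.0

    @classmethod
    def step(cls, c_uM: float, start_min: float = 0.0, end_min: float = 1e9) -> "TreatmentSchedule":
        return cls([Segment(start_min, end_min, c_uM)])

    @classmethod
    def pulse_train(cls, c_uM: float, n_pulses: int, on_min: float, off_min: float,
                    start_min: float = 0.0) -> "TreatmentSchedule":
        segs = []
        t = start_min
        for _ in range(n_pulses):
            segs.append(Segment(t, t + on_min, c_uM))
            t += on_min + off_min
        return cls(segs)

    def to_dict(self) -> dict:
        return {"segments": [dataclasses.asdict(s) for s in self.segments]}

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentSchedule":
        return cls([Segment(**s) for s in d.get("segments", [])])


@dataclass
class SimConfig:
    """All mechanistic parameters of the trench simulator.

    Defaults describe a fully loaded 25 x 1.2 um trench imaged every 3 min.
    The attenuation scale couples a barrier cell's surface area and enzyme
    level to the fraction of H2O2 it removes, f = 1 - exp(-sigma * S * E);
    the default sigma is calibrated so that a wild-type cell at treatment
    steady state removes roughly a third of the incoming H2O2.
    """

    # geometry / sampling
    trench_length_um: float = 25.0
    trench_length_sd_um: float = 4.0    # per-trench fabrication variability
    trench_width_um: float = 1.2
    width_reference_um: float = 1.2     # reference width for the bypass scaling
    width_bypass_exponent: float = 5.0  # sigma scales with (ref/width)^exponent
    n_trenches: int = 100
    frame_interval_min: float = 3.0
    t_start_min: float = -165.0
    t_end_min: float = 360.0
    substep_min: float = 0.25

    # growth and division
    mean_birth_length_um: float = 1.88
    division_cv: float = 0.12
    stress_size_exponent: float = 0.6  # division size scales with g^q (stressed cells divide smaller)
    base_elongation_rate: float = 0.028  # min^-1
    growth_noise_sd: float = 0.004       # min^-1, SD of per-cell elongation rate
    growth_heritability: float = 0.5     # mother-daughter elongation-rate correlation
    loading_mean_cells: float = 8.0

    # shielding / intracellular H2O2
    attenuation_scale: float = 0.055    # sigma, um^-2 (see module docstring)
    attenuation_mode: str = "mechanistic"  # or "fixed"
    fixed_attenuation: float = 0.323       # f used when mode == "fixed"
    internal_scavenging_strength: float = 40.0  # theta: c_int = c_loc/(1+theta*E)
    internal_relaxation_rate: float = 4.0       # min^-1, c_int relaxation

    # kinetics
    enzyme: EnzymeInduction = field(default_factory=EnzymeInduction)
    reporter: ReporterKinetics = field(default_factory=ReporterKinetics)
    marker_rate: float = 81.0            # a.u. min^-1 per unit area (constitutive)
    growth_inhibition: GrowthInhibition = field(default_factory=GrowthInhibition)
    death: DeathRule = field(default_factory=DeathRule)
    mismatch: MismatchRates = field(default_factory=MismatchRates)

    # noise
    partition_noise_sd: float = 0.015     # SD of division partition fraction
    measurement_noise_sd: float = 30.0   # a.u., additive on recorded intensities

    seed: int = 0
    genotype_mix: dict = field(default_factory=lambda: {"WT": 1.0})

    def __post_init__(self) -> None:
        for name in ("enzyme", "reporter", "growth_inhibition", "death", "mismatch"):
            val = getattr(self, name)
            if isinstance(val, dict):
                cls = {"enzyme": EnzymeInduction, "reporter": ReporterKinetics,
                       "growth_inhibition": GrowthInhibition, "death": DeathRule,
                       "mismatch": MismatchRates}[name]
                setattr(self, name, cls(**val))
        self.validate()

    def validate(self) -> None:
        positives = {
            "trench_length_um": self.trench_length_um,
            "trench_width_um": self.trench_width_um,
            "frame_interval_min": self.frame_interval_min,
            "substep_min": self.substep_min,
            "mean_birth_length_um": self.mean_birth_length_um,
            "base_elongation_rate": self.base_elongation_rate,
            "loading_mean_cells": self.loading_mean_cells,
        }
        for name, v in positives.items():
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        nonneg = {
            "growth_noise_sd": self.growth_noise_sd,
            "attenuation_scale": self.attenuation_scale,
            "partition_noise_sd": self.partition_noise_sd,
            "measurement_noise_sd": self.measurement_noise_sd,
            "division_cv": self.division_cv,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.trench_length_um < self.mean_birth_length_um:
            raise ConfigError("trench_length_um must be >= mean_birth_length_um")
        if self.attenuation_mode not in ("mechanistic", "fixed"):
            raise ConfigError(f"unknown attenuation_mode {self.attenuation_mode!r}")
        if not 0.0 <= self.fixed_attenuation < 1.0:
            raise ConfigError("fixed_attenuation must be in [0, 1)")
        if self.n_trenches < 1:
            raise ConfigError("n_trenches must be >= 1")
        if self.t_end_min <= self.t_start_min:
            raise ConfigError("t_end_min must exceed t_start_min")
        nsub = self.frame_interval_min / self.substep_min
        if abs(nsub - round(nsub)) > 1e-9:
            raise ConfigError("frame_interval_min must be a multiple of substep_min")
        mix = dict(self.genotype_mix)
        if not mix or abs(sum(mix.values()) - 1.0) > 1e-6:
            raise ConfigError("genotype_mix proportions must sum to 1")
        for g, p in mix.items():
            if g not in GENOTYPES:
                raise ConfigError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")
            if p < 0:
                raise ConfigError("genotype proportions must be >= 0")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def config_digest(config: SimConfig, schedule: TreatmentSchedule | None = None) -> str:
    """Short content hash over config (and schedule) for provenance headers."""
    payload = {"config": config.to_dict()}
    if schedule is not None:
        payload["schedule"] = schedule.to_dict()
    blob = json.dumps(payload, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_config(path, config: SimConfig, schedule: TreatmentSchedule | None = None) -> None:
    doc = {"sim": config.to_dict()}
    if schedule is not None:
        doc["schedule"] = schedule.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[SimConfig, TreatmentSchedule | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = SimConfig.from_dict(doc.get("sim", {}))
    sched = None
    if "schedule" in doc:
        sched = TreatmentSchedule.from_dict(doc["schedule"])
    return cfg, sched
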