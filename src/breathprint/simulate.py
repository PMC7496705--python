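"""Synthetic electronic-nose cohort generator.

Emulates breath measurements from a handheld e-nose with three metal-oxide
sensors on micro hotplates cycled between 260 and 340 degC. Each measurement
is a conductivity tensor of shape (36 temperature samples, 64 heat-cool
cycles, 3 sensors). Class information enters through latent volatile organic
compound (VOC) concentrations: cases and controls have different mean
log-concentration vectors, and each sensor responds to each VOC through a
temperature-dependent kernel. Device offsets, cycle-wise drift and
multiplicative lognormal noise complete the measurement model.

The generative model for one subject is

    G[t, c, s] = offset[device, s] * baseline[s, t]
                 * (1 + sum_v kernel[s, v, t] * conc_v)
                 * (1 + drift_rate) ** c
                 * exp(sigma_n * eps[t, c, s] - sigma_n**2 / 2)

with log conc_v ~ Normal(class_mean_v, subject_sd) and eps standard normal.
All factors are positive, so conductivities are strictly positive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

N_TEMP = 36
N_CYCLES = 64
N_SENSORS = 3
TEMP_MIN = 260.0
TEMP_MAX = 340.0

Label = Literal["case", "control"]
Subsite = Literal["oral", "oropharynx", "glottis", "none"]

SUBSITES: tuple[str, ...] = ("oral", "oropharynx", "glottis")

#: Smoking prevalence used for the (inert by default) smoking flag.
SMOKING_PREVALENCE = {"case": 49 / 91, "control": 26 / 72}

# Mutually orthogonal +-1 response patterns (Hadamard rows); used as the
# directions along which case mean log-concentrations shift.
_PATTERNS = {
    "shared": np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float),
    "oral": np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float),
    "oropharynx": np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float),
    "glottis": np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float),
}


class GenerationError(RuntimeError):
    """Pathological parameters produced non-finite conductivities."""


class ConfigurationError(ValueError):
    """Invalid simulation configuration (unknown device, bad counts...)."""


@dataclass(frozen=True)
class VOCSignature:
    """Latent class-dependent VOC concentration model.

    ``effect_size`` is the per-compound standardized shift (Cohen's d): the
    case mean log-concentration vector is
    ``base_mean + effect_size * subject_sd * pattern`` with ``pattern``
    entries in {-1, 0, +1}.  ``effect_size = 0`` makes the two classes
    identically distributed.  When ``subsite_specific`` is set, each tumour
    subsite uses its own (mutually orthogonal) pattern, so the pooled case
    class is heterogeneous.
    """

    n_vocs: int = 8
    base_mean: np.ndarray | None = None
    subject_sd: float = 0.35
    effect_size: float = 2.0
    subsite_specific: bool = False

    def __post_init__(self) -> None:
        if self.n_vocs < 1:
            raise ConfigurationError("n_vocs must be >= 1")
        if self.subject_sd <= 0:
            raise ConfigurationError("subject_sd must be > 0")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.base_mean is None:
            object.__setattr__(self, "base_mean", np.zeros(self.n_vocs))
        else:
            bm = np.asarray(self.base_mean, dtype=float)
            if bm.shape != (self.n_vocs,):
                raise ConfigurationError("base_mean length must equal n_vocs")
            object.__setattr__(self, "base_mean", bm)

    def _pattern(self, subsite: str) -> np.ndarray:
        key = subsite if self.subsite_specific else "shared"
        pat = _PATTERNS[key]
        return np.resize(pat, self.n_vocs)

    def class_mean(self, label: Label, subsite: str = "none") -> np.ndarray:
        """Mean log-concentration vector for a class (and subsite)."""
        if label == "control":
            return self.base_mean.copy()
        return self.base_mean + self.effect_size * self.subject_sd * self._pattern(subsite)


def _default_device_offsets(n_devices: int, n_sensors: int) -> np.ndarray:
    # fixed internal seed: device offsets are part of the model definition,
    # not of the per-cohort randomness
    rng = np.random.default_rng(1346)
    return np.exp(0.05 * rng.standard_normal((n_devices, n_sensors)))


@dataclass(frozen=True)
class SensorResponseModel:
    """Deterministic part of the sensor physics plus noise/drift levels.

    ``kernels[s, v, :]`` is the non-negative response curve of sensor ``s``
    to virtual compound ``v`` over the temperature grid; Gaussians with
    sensor- and compound-dependent peak temperatures spread over the
    260-340 degC sweep.  ``baseline`` is the clean-air conductivity curve.
    """

    n_sensors: int = N_SENSORS
    n_temp: int = N_TEMP
    n_cycles: int = N_CYCLES
    n_vocs: int = 8
    drift_rate: float = 0.002
    noise_sd: float = 0.05
    n_devices: int = 4
    temp_grid: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    baseline: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    kernels: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    device_offsets: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.temp_grid is None:
            object.__setattr__(
                self, "temp_grid", np.linspace(TEMP_MIN, TEMP_MAX, self.n_temp)
            )
        tg = np.asarray(self.temp_grid, dtype=float)
        if tg.shape != (self.n_temp,) or tg.min() < TEMP_MIN or tg.max() > TEMP_MAX:
            raise ConfigurationError("temp_grid must hold n_temp values in [260, 340]")
        object.__setattr__(self, "temp_grid", tg)

        if self.baseline is None:
            centers = np.linspace(280.0, 320.0, self.n_sensors)
            base = 1.0 + 0.4 * np.exp(
                -(((tg[None, :] - centers[:, None]) / 40.0) ** 2)
            )
            object.__setattr__(self, "baseline", base)
        base = np.asarray(self.baseline, dtype=float)
        if base.shape != (self.n_sensors, self.n_temp) or not (base > 0).all():
            raise ConfigurationError("baseline must be strictly positive, (n_sensors, n_temp)")
        object.__setattr__(self, "baseline", base)

        if self.kernels is None:
            s_idx = np.arange(self.n_sensors)[:, None, None]
            v_idx = np.arange(self.n_vocs)[None, :, None]
            # peak temperature per (sensor, voc), deterministic spread
            frac = ((v_idx + 0.5 + 2.7 * s_idx) % self.n_vocs) / self.n_vocs
            mu = TEMP_MIN + (TEMP_MAX - TEMP_MIN) * frac
            ker = 0.05 * np.exp(-(((tg[None, None, :] - mu) / 18.0) ** 2))
            object.__setattr__(self, "kernels", ker)
        ker = np.asarray(self.kernels, dtype=float)
        if ker.shape != (self.n_sensors, self.n_vocs, self.n_temp) or (ker < 0).any():
            raise ConfigurationError("kernels must be non-negative, (n_sensors, n_vocs, n_temp)")
        object.__setattr__(self, "kernels", ker)

        if self.device_offsets is None:
            object.__setattr__(
                self,
                "device_offsets",
                _default_device_offsets(self.n_devices, self.n_sensors),
            )
        off = np.asarray(self.device_offsets, dtype=float)
        if off.shape != (self.n_devices, self.n_sensors) or not (off > 0).all():
            raise ConfigurationError("device_offsets must be positive, (n_devices, n_sensors)")
        object.__setattr__(self, "device_offsets", off)


@dataclass
class Measurement:
    """One subject's breath-print: conductivity tensor plus metadata."""

    subject_id: str
    device_id: int
    label: Label
    subsite: Subsite
    smoking: bool
    tensor: np.ndarray  # (n_temp, n_cycles, n_sensors), entries > 0

    def validate(self, n_temp: int = N_TEMP, n_cycles: int = N_CYCLES,
                 n_sensors: int = N_SENSORS) -> None:
        if self.tensor.shape != (n_temp, n_cycles, n_sensors):
            raise ValueError(
                f"subject {self.subject_id}: tensor shape {self.tensor.shape} != "
                f"({n_temp}, {n_cycles}, {n_sensors})"
            )
        if not np.isfinite(self.tensor).all():
            raise ValueError(f"subject {self.subject_id}: non-finite conductivity")
        if not (self.tensor > 0).all():
            raise ValueError(f"subject {self.subject_id}: non-positive conductivity")
        if (self.subsite == "none") != (self.label == "control"):
            raise ValueError(
                f"subject {self.subject_id}: subsite 'none' iff label 'control'"
            )


@dataclass
class Cohort:
    """A set of measurements with a design manifest."""

    measurements: list[Measurement]

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.measurements])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [m.subject_id for m in self.measurements],
                "device_id": [m.device_id for m in self.measurements],
                "label": [m.label for m in self.measurements],
                "subsite": [m.subsite for m in self.measurements],
                "smoking": [m.smoking for m in self.measurements],
            }
        )

    def subset(self, mask: Sequence[bool]) -> "Cohort":
        return Cohort([m for m, keep in zip(self.measurements, mask) if keep])


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition: subsite case counts, controls, devices, seed."""

    n_cases_by_subsite: Mapping[str, int] = field(
        default_factory=lambda: {"oral": 37, "oropharynx": 34, "glottis": 20}
    )
    n_controls: int = 72
    n_devices: int = 4
    min_per_class_per_device: int = 5
    seed: int = 0

    @property
    def n_cases(self) -> int:
        return sum(self.n_cases_by_subsite.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.n_cases_by_subsite.values()) or self.n_controls < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.n_devices < 1:
            raise ConfigurationError("need at least one device")
        for name, n in (("cases", self.n_cases), ("controls", self.n_controls)):
            if n // self.n_devices < self.min_per_class_per_device:
                raise ConfigurationError(
                    f"infeasible design: {n} {name} over {self.n_devices} devices "
                    f"cannot give every device >= {self.min_per_class_per_device} "
                    f"{name} (round-robin yields {n // self.n_devices})"
                )


def simulate_subject(
    signature: VOCSignature,
    response: SensorResponseModel,
    label: Label,
    device_id: int,
    seed: int,
    subsite: Subsite = "none",
    subject_id: str = "S0",
    smoking: bool | None = None,
) -> Measurement:
    """Draw one measurement from the generative model. Deterministic per seed."""
    if not 0 <= device_id < response.n_devices:
        raise ConfigurationError(
            f"unknown device_id {device_id} (model has {response.n_devices} devices)"
        )
    if signature.n_vocs != response.n_vocs:
        raise ConfigurationError("signature and response disagree on n_vocs")
    rng = np.random.default_rng(seed)
    mean = signature.class_mean(label, subsite)
    # concentration draw first so 'same seed' aligns across classes
    conc = np.exp(mean + signature.subject_sd * rng.standard_normal(signature.n_vocs))
    eps = rng.standard_normal((response.n_temp, response.n_cycles, response.n_sensors))
    if smoking is None:
        smoking = bool(rng.random() < SMOKING_PREVALENCE[label])

    # (s, t) deterministic response to this subject's VOC mix
    excess = np.einsum("svt,v->st", response.kernels, conc)
    clean = response.device_offsets[device_id][:, None] * response.baseline * (1.0 + excess)
    drift = (1.0 + response.drift_rate) ** np.arange(response.n_cycles)
    noise = np.exp(response.noise_sd * eps - response.noise_sd**2 / 2.0)
    # (t, c, s) = clean(s, t) * drift(c) * noise(t, c, s)
    tensor = clean.T[:, None, :] * drift[None, :, None] * noise
    if not np.isfinite(tensor).all() or not (tensor > 0).all():
        raise GenerationError(
            "generated non-finite or non-positive conductivity; check drift_rate, "
            "noise_sd and kernel amplitudes"
        )
    m = Measurement(
        subject_id=subject_id,
        device_id=device_id,
        label=label,
        subsite=subsite,
        smoking=smoking,
        tensor=tensor,
    )
    m.validate(response.n_temp, response.n_cycles, response.n_sensors)
    return m


def simulate_cohort(
    design: CohortDesign,
    signature: VOCSignature | None = None,
    response: SensorResponseModel | None = None,
) -> Cohort:
    """Simulate a full case-control cohort.

    Subjects are laid out cases-by-subsite then controls; devices are
    assigned round-robin within each class so the per-device balance
    requirement holds by construction. Bitwise reproducible from
    ``design.seed``.
    """
    signature = signature or VOCSignature()
    response = response or SensorResponseModel(n_vocs=signature.n_vocs)
    design.validate()

    roster: list[tuple[Label, Subsite]] = []
    for subsite in SUBSITES:
        roster += [("case", subsite)] * design.n_cases_by_subsite.get(subsite, 0)
    roster += [("control", "none")] * design.n_controls

    seeds = np.random.SeedSequence(design.seed).generate_state(len(roster))
    measurements = []
    counters = {"case": 0, "control": 0}
    for i, (label, subsite) in enumerate(roster):
        device = counters[label] % design.n_devices
        counters[label] += 1
        prefix = "P" if label == "case" else "C"
        measurements.append(
            simulate_subject(
                signature,
                response,
                label,
                device,
                seed=int(seeds[i] % (2**31)),
                subsite=subsite,
                subject_id=f"{prefix}{i:03d}",
            )
        )
    return Cohort(measurements)


@dataclass
class BalanceReport:
    counts: pd.DataFrame  # index device_id, columns case/control
    min_required: int
    passed: bool
    failures: list[str]


def check_device_balance(cohort: Cohort, min_per_class_per_device: int = 5) -> BalanceReport:
    """Per-(device, class) counts and a pass/fail flag for the balance rule."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    man = cohort.manifest()
    counts = (
        man.groupby(["device_id", "label"]).size().unstack(fill_value=0)
    )
    for col in ("case", "control"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["case", "control"]]
    failures = []
    for device, row in counts.iterrows():
        for cls in ("case", "control"):
            if row[cls] < min_per_class_per_device:
                failures.append(
                    f"device {device}: {row[cls]} {cls} measurements "
                    f"(< {min_per_class_per_device})"
                )
    return BalanceReport(
        counts=counts,
        min_required=min_per_class_per_device,
        passed=not failures,
        failures=failures,
    )
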