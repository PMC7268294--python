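"""Protocol configuration and belt-speed arithmetic.

A split-belt session is described by a :class:`ProtocolConfig`: who walked
(mass, paretic side), how the treadmill was set up (slope, mid/slow/fast belt
speeds) and the ordered epoch plan (baseline, adaptation, post-adaptation with
planned stride counts and per-belt speeds).  The slow and fast speeds are
derived from the self-selected mid speed as 66.6% and 133.3%, which yields a
2:1 split ratio while keeping the mean belt speed equal to the mid speed in
every epoch.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

SLOW_FRACTION = 0.666
FAST_FRACTION = 1.333

EPOCH_NAMES = ("baseline_slow", "baseline_mid", "adaptation", "post_adaptation")

SIDES = ("left", "right")


class ConfigError(ValueError):
    """Invalid or inconsistent protocol configuration."""


def round2(value: float) -> float:
    """Round to 2 decimals, half away from zero (treadmill display convention)."""
    if value >= 0:
        return math.floor(value * 100.0 + 0.5) / 100.0
    return -math.floor(-value * 100.0 + 0.5) / 100.0


def derive_belt_speeds(mid_speed: float) -> tuple[float, float]:
    """Slow and fast belt speeds (m/s) from the mid speed.

    slow = round2(0.666 * mid), fast = round2(1.333 * mid).  Raises
    :class:`ConfigError` for non-positive mid speeds.
    """
    if not mid_speed > 0:
        raise ConfigError(f"mid_speed must be positive, got {mid_speed!r}")
    return round2(SLOW_FRACTION * mid_speed), round2(FAST_FRACTION * mid_speed)


@dataclass(frozen=True)
class ProcessingParams:
    """Signal-processing and windowing constants.

    All analysis constants flow from here; nothing downstream hard-codes them.
    """

    lowpass_cutoff_hz: float = 20.0          # AP force low-pass cutoff
    hs_threshold_online_n: float = 30.0      # raw normal force, online emulation
    hs_threshold_offline_n: float = 10.0     # median-filtered normal force
    median_window_ms: float = 5.0
    min_stance_ms: float = 100.0             # debounce: shortest accepted stance
    min_swing_ms: float = 100.0              # debounce: shortest accepted swing
    late_window_strides: int = 40
    early_window_strides: int = 5
    bin_size_strides: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("late_window_strides", "early_window_strides", "bin_size_strides"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("lowpass_cutoff_hz", "median_window_ms", "min_stance_ms", "min_swing_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class EpochSpec:
    """One entry of the epoch plan."""

    name: str
    planned_strides: int
    left_belt_speed: float
    right_belt_speed: float

    def __post_init__(self) -> None:
        if self.name not in EPOCH_NAMES:
            raise ConfigError(
                f"unknown epoch name {self.name!r}; expected one of {EPOCH_NAMES}"
            )
        if self.planned_strides < 1:
            raise ConfigError(f"epoch {self.name}: planned_strides must be >= 1")
        if self.left_belt_speed <= 0 or self.right_belt_speed <= 0:
            raise ConfigError(f"epoch {self.name}: belt speeds must be positive")


@dataclass(frozen=True)
class ProtocolConfig:
    """Full description of one subject session."""

    subject_id: str
    mass_kg: float
    paretic_side: str
    slope_deg: float
    mid_speed: float
    slow_speed: float = 0.0
    fast_speed: float = 0.0
    epoch_plan: tuple[EpochSpec, ...] = ()
    processing: ProcessingParams = field(default_factory=ProcessingParams)

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ConfigError(f"mass_kg must be positive, got {self.mass_kg}")
        if self.paretic_side not in SIDES:
            raise ConfigError(f"paretic_side must be 'left' or 'right', got {self.paretic_side!r}")
        if self.slope_deg < 0:
            raise ConfigError(f"slope_deg must be >= 0, got {self.slope_deg}")
        slow, fast = derive_belt_speeds(self.mid_speed)
        if self.slow_speed == 0.0:
            object.__setattr__(self, "slow_speed", slow)
        if self.fast_speed == 0.0:
            object.__setattr__(self, "fast_speed", fast)
        if abs(self.slow_speed - slow) > 0.01:
            raise ConfigError(
                f"slow_speed {self.slow_speed} inconsistent with "
                f"{SLOW_FRACTION:.1%} of mid speed ({slow})"
            )
        if abs(self.fast_speed - fast) > 0.01:
            raise ConfigError(
                f"fast_speed {self.fast_speed} inconsistent with "
                f"{FAST_FRACTION:.1%} of mid speed ({fast})"
            )
        if not self.epoch_plan:
            object.__setattr__(
                self, "epoch_plan", default_epoch_plan(self, include_baseline_slow=self.slope_deg == 0)
            )
        self._validate_epoch_plan()

    # -- helpers -------------------------------------------------------------

    @property
    def nonparetic_side(self) -> str:
        return "right" if self.paretic_side == "left" else "left"

    def belt_speed(self, epoch: EpochSpec, leg: str) -> float:
        """Belt speed under a leg ('paretic' | 'nonparetic') in an epoch."""
        side = self.paretic_side if leg == "paretic" else self.nonparetic_side
        return epoch.left_belt_speed if side == "left" else epoch.right_belt_speed

    def _validate_epoch_plan(self) -> None:
        for spec in self.epoch_plan:
            if spec.name == "adaptation":
                if not math.isclose(self.belt_speed(spec, "paretic"), self.slow_speed, abs_tol=1e-9):
                    raise ConfigError("adaptation: paretic belt must run at the slow speed")
                if not math.isclose(self.belt_speed(spec, "nonparetic"), self.fast_speed, abs_tol=1e-9):
                    raise ConfigError("adaptation: non-paretic belt must run at the fast speed")
            elif spec.name in ("baseline_mid", "post_adaptation"):
                if not (
                    math.isclose(spec.left_belt_speed, self.mid_speed, abs_tol=1e-9)
                    and math.isclose(spec.right_belt_speed, self.mid_speed, abs_tol=1e-9)
                ):
                    raise ConfigError(f"{spec.name}: both belts must run at the mid speed")
            elif spec.name == "baseline_slow":
                if not (
                    math.isclose(spec.left_belt_speed, self.slow_speed, abs_tol=1e-9)
                    and math.isclose(spec.right_belt_speed, self.slow_speed, abs_tol=1e-9)
                ):
                    raise ConfigError("baseline_slow: both belts must run at the slow speed")

    def epoch(self, name: str) -> EpochSpec:
        for spec in self.epoch_plan:
            if spec.name == name:
                return spec
        raise ConfigError(f"epoch plan has no epoch named {name!r}")


def default_epoch_plan(
    config: ProtocolConfig,
    *,
    baseline_strides: int = 50,
    adaptation_strides: int = 600,
    post_strides: int = 300,
    include_baseline_slow: bool = False,
) -> tuple[EpochSpec, ...]:
    """Default plan: (slow baseline,) mid baseline, 2:1 adaptation, tied post."""
    slow, fast, mid = config.slow_speed, config.fast_speed, config.mid_speed
    paretic_left = config.paretic_side == "left"
    plan: list[EpochSpec] = []
    if include_baseline_slow:
        plan.append(EpochSpec("baseline_slow", baseline_strides, slow, slow))
    plan.append(EpochSpec("baseline_mid", baseline_strides, mid, mid))
    plan.append(
        EpochSpec(
            "adaptation",
            adaptation_strides,
            slow if paretic_left else fast,
            fast if paretic_left else slow,
        )
    )
    plan.append(EpochSpec("post_adaptation", post_strides, mid, mid))
    return tuple(plan)


# -- on-disk form ------------------------------------------------------------

_REQUIRED_KEYS = ("subject_id", "mass_kg", "paretic_side", "slope_deg", "mid_speed")


def _config_from_mapping(raw: dict) -> ProtocolConfig:
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise ConfigError(f"config missing required key {key!r}")
    known = set(_REQUIRED_KEYS) | {"slow_speed", "fast_speed", "epoch_plan", "processing"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    processing = ProcessingParams(**raw.get("processing", {}))
    if "rng_seed" not in raw.get("processing", {}):
        logger.info("config %s: rng_seed not given, defaulting to %d",
                    raw["subject_id"], processing.rng_seed)
    plan = tuple(
        EpochSpec(
            name=e["name"],
            planned_strides=int(e["planned_strides"]),
            left_belt_speed=float(e["left_belt_speed"]),
            right_belt_speed=float(e["right_belt_speed"]),
        )
        for e in raw.get("epoch_plan", [])
    )
    config = ProtocolConfig(
        subject_id=str(raw["subject_id"]),
        mass_kg=float(raw["mass_kg"]),
        paretic_side=str(raw["paretic_side"]),
        slope_deg=float(raw["slope_deg"]),
        mid_speed=float(raw["mid_speed"]),
        slow_speed=float(raw.get("slow_speed", 0.0)),
        fast_speed=float(raw.get("fast_speed", 0.0)),
        epoch_plan=plan,
        processing=processing,
    )
    logger.info(
        "loaded config %s: slope %.1f deg, speeds %.2f/%.2f/%.2f m/s, epochs %s, seed %d",
        config.subject_id, config.slope_deg, config.slow_speed, config.mid_speed,
        config.fast_speed, [f"{e.name}:{e.planned_strides}" for e in config.epoch_plan],
        config.processing.rng_seed,
    )
    return config


def load_config(path: str | Path) -> ProtocolConfig:
    """Load and validate a YAML (or JSON) protocol configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config {path} is neither valid YAML nor JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path}: top level must be a mapping")
    return _config_from_mapping(raw)


def save_config(config: ProtocolConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through :func:`load_config`)."""
    raw = {
        "subject_id": config.subject_id,
        "mass_kg": config.mass_kg,
        "paretic_side": config.paretic_side,
        "slope_deg": config.slope_deg,
        "mid_speed": config.mid_speed,
        "slow_speed": config.slow_speed,
        "fast_speed": config.fast_speed,
        "epoch_plan": [
            {
                "name": e.name,
                "planned_strides": e.planned_strides,
                "left_belt_speed": e.left_belt_speed,
                "right_belt_speed": e.right_belt_speed,
            }
            for e in config.epoch_plan
        ],
        "processing": {
            k: getattr(config.processing, k)
            for k in ProcessingParams.__dataclass_fields__
        },
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def with_processing(config: ProtocolConfig, **kwargs) -> ProtocolConfig:
    """Copy of the config with some processing constants replaced."""
    return replace(config, processing=replace(config.processing, **kwargs))
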