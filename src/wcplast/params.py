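"""Model constants and run settings.

The model couples Wilson-Cowan units (one excitatory and one inhibitory
population each) through plastic excitatory weights ``w_ij`` and fixed
inhibitory weights ``u_ij``.  All constants live in :class:`ModelParams`;
everything that varies between runs (network size, drive, noise, length)
lives in :class:`RunSettings`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

__all__ = [
    "ModelParams",
    "RunSettings",
    "DriveSpec",
    "NoiseSpec",
    "RESONANCE_TABLE",
    "time_constants_for_resonance",
]

#: Tabulated lookup of (tau_E, tau_I) in seconds tuning a unit's resonance (Hz).
RESONANCE_TABLE: dict[int, tuple[float, float]] = {
    4: (0.017, 0.013),
    8: (0.024, 0.014),
    12: (0.011, 0.007),
    23: (0.014, 0.006),
}


def time_constants_for_resonance(f_r: float) -> tuple[float, float]:
    """Return the tabulated (tau_E, tau_I) pair for a resonance frequency.

    Only the four tabulated frequencies are valid.  For anything else use
    :func:`wcplast.model.estimate_resonance` to characterise a custom pair.
    """
    key = int(f_r)
    if key != f_r or key not in RESONANCE_TABLE:
        raise ValueError(
            f"no tabulated time constants for f_r={f_r!r}; valid values are "
            f"{sorted(RESONANCE_TABLE)}. Use estimate_resonance() to find the "
            "resonance of a custom (tau_E, tau_I) pair."
        )
    return RESONANCE_TABLE[key]


@dataclass
class ModelParams:
    """Fixed constants of the coupled Wilson-Cowan + plasticity equations.

    Intra-unit gains ``W_EE``..``W_II`` and the sigmoid shape (``m``, ``n``)
    put each unit in a stable oscillatory regime; ``tau_E``/``tau_I`` tune its
    resonance.  The Hebbian rule has gain ``gamma``, coincidence threshold
    ``h`` (squared fractional rate) and time constant ``tau_h``.  Homeostatic
    scaling pulls the time-averaged rates toward ``E_inf``/``I_inf`` on the
    ``tau_SE``/``tau_SI`` timescales.  ``W_EI`` enters the excitatory input
    with inhibitory (negative) sign.
    """

    W_EE: float = 23.0
    W_EI: float = 15.0
    W_IE: float = 35.0
    W_II: float = 0.0
    m: float = 1.0
    n: float = 4.0
    E0: float = 0.5
    I0: float = -5.0
    tau_E: float = 0.011
    tau_I: float = 0.007
    tau_h: float = 2.5
    gamma: float = 1.0
    h: float = 0.04
    E_inf: float = 0.2
    I_inf: float = 0.2
    tau_SE: float = 1.0
    tau_SI: float = 2.0
    u_fixed: float = 0.1
    w_init: float = 0.15

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "tau_h", "tau_SE", "tau_SI"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @classmethod
    def for_resonance(cls, f_r: float, **overrides) -> "ModelParams":
        """Parameters with (tau_E, tau_I) from the tabulated resonance pairs."""
        tau_E, tau_I = time_constants_for_resonance(f_r)
        return cls(tau_E=tau_E, tau_I=tau_I, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    replace = replace


@dataclass
class DriveSpec:
    """Common sinusoidal drive: ``amplitude * sin(2*pi*f_d*(t - t0))``.

    The onset ``t0`` is jittered uniformly within ``jitter_window`` ms per
    trial to wash out phase interactions between drive onset and the units'
    endogenous oscillation; before onset the drive is zero.  The same series
    is applied to every unit's excitatory population.
    """

    f_d: float = 48.0
    amplitude: float = 0.5
    jitter_window: float = 1000.0  # ms

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.f_d < 0:
            raise ValueError("f_d must be >= 0")
        if self.jitter_window < 0:
            raise ValueError("jitter_window must be >= 0")


@dataclass
class NoiseSpec:
    """Per-unit independent zero-mean unit-variance Gaussian noise, scaled by z."""

    z: float = 0.0

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z must be >= 0")


@dataclass
class RunSettings:
    """Everything that defines one simulation besides the model constants.

    ``noise_mode`` selects how the white-noise sample enters the excitatory
    sigmoid argument each step: ``"ito"`` (default) scales as ``z*xi/sqrt(dt)``
    (Euler-Maruyama reading of white noise with intensity z); ``"per_step"``
    injects ``z*xi`` directly.  ``record_activity_every`` /
    ``record_weights_every`` decimate the stored series to bound memory.
    """

    n_units: int = 2
    f_r: float = 12.0
    f_d: float = 48.0
    z: float = 0.0
    n_steps: int = 500_000
    n_discard: int = 100_000
    dt: float = 0.001
    topology: Literal["two_unit_unidirectional", "all_to_all"] = "two_unit_unidirectional"
    noise_mode: Literal["ito", "per_step"] = "ito"
    drive_amplitude: float = 0.5
    jitter_window: float = 1000.0  # ms
    record_activity_every: int = 1
    record_weights_every: int = 100

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.topology not in ("two_unit_unidirectional", "all_to_all"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "two_unit_unidirectional" and self.n_units != 2:
            raise ValueError("two_unit_unidirectional requires n_units == 2")
        if self.noise_mode not in ("ito", "per_step"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.z < 0:
            raise ValueError("z must be >= 0")
        if not (0 <= self.n_discard < self.n_steps):
            raise ValueError("need 0 <= n_discard < n_steps")
        if self.record_activity_every < 1 or self.record_weights_every < 1:
            raise ValueError("record decimation factors must be >= 1")

    @property
    def drive(self) -> DriveSpec:
        return DriveSpec(
            f_d=self.f_d, amplitude=self.drive_amplitude, jitter_window=self.jitter_window
        )

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec(z=self.z)

    def to_dict(self) -> dict:
        return asdict(self)

    replace = replace
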