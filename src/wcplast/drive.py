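"""Deterministic sinusoidal drive and Gaussian white-noise streams."""

from __future__ import annotations

import numpy as np

from .params import DriveSpec, NoiseSpec

__all__ = ["make_drive", "make_noise"]


def make_drive(
    spec: DriveSpec, n_steps: int, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Build the shared drive series and return ``(series, t0)``.

    The series is ``amplitude * sin(2*pi*f_d*(t - t0))`` for ``t >= t0`` and
    zero before, with the onset ``t0`` drawn uniformly in
    ``[0, jitter_window]`` (ms) from ``rng``.  The same series is applied to
    every unit.  The draw happens even for zero amplitude so that the
    downstream noise stream does not depend on the amplitude.
    """
    t0 = rng.uniform(0.0, spec.jitter_window / 1000.0)
    t = np.arange(n_steps) * dt
    series = np.where(
        t >= t0, spec.amplitude * np.sin(2.0 * np.pi * spec.f_d * (t - t0)), 0.0
    )
    return series, t0


def make_noise(
    spec: NoiseSpec, n_units: int, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Matrix of i.i.d. N(0, z^2) samples, shape ``(n_units, n_steps)``.

    The integration kernel draws its noise on the fly (storing the full
    stream for long runs would dominate memory); this constructor exists for
    inspection and for statistical tests of the stream itself.  Draw order is
    unit-major per step, matching the kernel.
    """
    return spec.z * rng.standard_normal((n_steps, n_units)).T
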