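"""Synthetic input generation with serialized ground truth: 1D spectra,
selective/nonselective recovery datasets, and jittered coordinate frames."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import Structure
from .nmr import DEFAULT_TAU_GRID_MS, PeakModel, Spectrum1D, pseudo_voigt

__all__ = ["GroundTruth", "gen_spectrum", "gen_recovery_dataset", "jitter_structure"]


@dataclass
class GroundTruth:
    """True generation parameters shipped with every synthetic dataset."""

    amplitudes: dict = field(default_factory=dict)       # assignment -> amp
    recovery: dict = field(default_factory=dict)         # sink assignment -> (A, T_SD ms)
    jitter_amplitude: float = 0.0                        # A
    seed: int = 0

    def to_json(self, **kw) -> str:
        d = {
            "amplitudes": self.amplitudes,
            "recovery": {k: list(v) for k, v in self.recovery.items()},
            "jitter_amplitude": self.jitter_amplitude,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2, **kw)


def _ppm_axis(ppm_range=(200.0, 0.0), n_points=2048) -> np.ndarray:
    hi, lo = ppm_range
    return np.linspace(hi, lo, n_points)


def gen_spectrum(
    peaks: list,
    amplitudes,
    noise_sd: float = 0.0,
    seed: int = 0,
    ppm_range=(200.0, 0.0),
    n_points: int = 2048,
):
    """Sum of pseudo-Voigt lines on a uniform descending ppm grid plus
    seeded Gaussian noise.  Returns (Spectrum1D, GroundTruth)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be non-negative")
    if len(amplitudes) != len(peaks):
        raise ValueError("one amplitude per peak required")
    rng = np.random.default_rng(seed)
    x = _ppm_axis(ppm_range, n_points)
    y = np.zeros_like(x)
    for amp, p in zip(amplitudes, peaks):
        y += amp * pseudo_voigt(x, p.center, p.fwhm, p.gauss_fraction)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(x))
    spec = Spectrum1D(x, y, noise_sd=noise_sd if noise_sd > 0 else None)
    gt = GroundTruth(
        amplitudes={p.assignment: float(a) for p, a in zip(peaks, amplitudes)},
        seed=seed,
    )
    return spec, gt


def gen_recovery_dataset(
    peaks: list,
    pairs: dict,
    source_assignment: str,
    tau_grid=DEFAULT_TAU_GRID_MS,
    base_amplitudes=None,
    noise_frac: float = 0.02,
    seed: int = 0,
    ppm_range=(200.0, 0.0),
    n_points: int = 2048,
):
    """Selective / nonselective spectrum series over a mixing-time grid.

    pairs maps sink assignment -> (A, T_SD ms).  The nonselective series is
    constant; in the selective series each sink amplitude is scaled by
    A*(1 - exp(-tau/T_SD)) while the source assignment keeps its full
    amplitude.  Noise is seeded Gaussian at ``noise_frac`` of the maximum
    nonselective peak height.

    Returns (tau_array, selective list, nonselective list, GroundTruth).
    """
    tau = np.asarray(tau_grid, dtype=float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("tau_grid must be strictly increasing")
    names = [p.assignment for p in peaks]
    if source_assignment not in names:
        raise ValueError(f"source {source_assignment!r} not in peak set")
    for snk in pairs:
        if snk not in names:
            raise ValueError(f"sink {snk!r} not in peak set")
    if base_amplitudes is None:
        base_amplitudes = np.ones(len(peaks))
    base_amplitudes = np.asarray(base_amplitudes, dtype=float)

    rng = np.random.default_rng(seed)
    x = _ppm_axis(ppm_range, n_points)
    peak_height = max(
        float(
            np.max(
                sum(
                    a * pseudo_voigt(x, p.center, p.fwhm, p.gauss_fraction)
                    for a, p in zip(base_amplitudes, peaks)
                )
            )
        ),
        1e-12,
    )
    noise_sd = noise_frac * peak_height

    nonselective, selective = [], []
    for t in tau:
        y_ref = np.zeros_like(x)
        y_sel = np.zeros_like(x)
        for a, p in zip(base_amplitudes, peaks):
            line = pseudo_voigt(x, p.center, p.fwhm, p.gauss_fraction)
            y_ref += a * line
            if p.assignment == source_assignment:
                y_sel += a * line
            elif p.assignment in pairs:
                A, T = pairs[p.assignment]
                y_sel += a * A * (1.0 - np.exp(-t / T)) * line
        if noise_sd > 0:
            y_ref = y_ref + rng.normal(0, noise_sd, len(x))
            y_sel = y_sel + rng.normal(0, noise_sd, len(x))
        nonselective.append(Spectrum1D(x.copy(), y_ref, noise_sd=noise_sd or None))
        selective.append(Spectrum1D(x.copy(), y_sel, noise_sd=noise_sd or None))

    gt = GroundTruth(
        amplitudes={p.assignment: float(a) for p, a in zip(peaks, base_amplitudes)},
        recovery={k: (float(v[0]), float(v[1])) for k, v in pairs.items()},
        seed=seed,
    )
    return tau, selective, nonselective, gt


def jitter_structure(s: Structure, amplitude: float, n_frames: int, seed: int = 0):
    """Pseudo-equilibrated snapshot frames: per-atom seeded Gaussian
    displacements with sd = amplitude per axis, wrapped into the box.
    Frame 0 is the input.  Returns (frames list, GroundTruth)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    frames = [s.copy()]
    for _ in range(max(n_frames - 1, 0)):
        fr = s.copy()
        if amplitude > 0:
            fr.positions = fr.positions + rng.normal(0.0, amplitude, fr.positions.shape)
        if fr.periodic:
            fr.positions = np.mod(fr.positions, fr.box)
        frames.append(fr)
    gt = GroundTruth(jitter_amplitude=float(amplitude), seed=seed)
    return frames, gt
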