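"""Synthetic volumetric calcium sessions with embedded responsive cells.

Each cell is a disjoint voxel mask with a signed response amplitude, a lag in
volumes, and a baseline intensity.  Cell voxels follow
``F0 * (1 + a * kernel(t - d))`` plus Gaussian noise; background voxels sit at
the baseline plus noise.  The response kernel is the stimulus boxcar convolved
with a normalized difference of exponentials capturing indicator kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..mapping import ResponseKernel, SampleRecording, StimulusProtocol


def make_gcamp_kernel(
    protocol: StimulusProtocol,
    tau_rise_s: float = 0.2,
    tau_decay_s: float = 1.0,
) -> ResponseKernel:
    """Session-length response kernel: stimulus boxcar * indicator impulse.

    The impulse response is the difference of exponentials
    ``exp(-t/tau_decay) - exp(-t/tau_rise)``; the discrete convolution with
    the stimulus indicator is sampled at the volume rate and normalized to a
    peak of 1 (an all-zero stimulus yields an all-zero kernel).
    """
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("time constants must be positive")
    if tau_decay_s <= tau_rise_s:
        raise ValueError("decay must be slower than rise")
    box = protocol.boxcar()
    t = np.arange(protocol.session_volumes) / protocol.volume_rate_hz
    impulse = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    kernel = np.convolve(box, impulse)[: protocol.session_volumes]
    peak = np.max(np.abs(kernel))
    if peak > 0:
        kernel = kernel / peak
    tag = "+".join(f"{d:g}s" for _, d in protocol.epochs)
    return ResponseKernel(kernel, protocol_tag=tag)


@dataclass(frozen=True)
class CellSpec:
    """One embedded cell: voxel mask, signed amplitude, lag, baseline."""

    mask: np.ndarray  # bool (Z, Y, X)
    amplitude: float
    lag_volumes: int = 0
    f0: float = 100.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("baseline must be positive")


@dataclass
class CalciumSceneParams:
    """Scene description for :func:`simulate_calcium`."""

    grid: tuple[int, int, int]  # (Z, Y, X)
    cells: list[CellSpec]
    noise_sd: float = 0.0
    background_f0: float = 100.0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    n_sessions: int = 10
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.background_f0 <= 0:
            raise ValueError("noise sd must be >= 0 and baseline > 0")
        claimed = np.zeros(self.grid, bool)
        for i, cell in enumerate(self.cells):
            if cell.mask.shape != self.grid:
                raise ValueError(f"cell {i} mask shape does not match the grid")
            if (claimed & cell.mask).any():
                raise ValueError("cell masks must be disjoint")
            claimed |= cell.mask


def _shift(kernel: np.ndarray, lag: int) -> np.ndarray:
    """Kernel delayed by ``lag`` volumes, zero-filled outside the session."""
    out = np.zeros_like(kernel)
    n = len(kernel)
    if lag >= 0:
        out[lag:] = kernel[: n - lag]
    else:
        out[: n + lag] = kernel[-lag:]
    return out


def simulate_calcium(scene: CalciumSceneParams) -> tuple[SampleRecording, dict]:
    """Generate a multi-session recording plus ground-truth labels.

    Sessions draw independent noise from per-session streams spawned off the
    master seed, so the session count can change without re-randomizing
    earlier sessions.  The returned labels carry the clean kernel, the
    positive/negative cell masks, and per-cell amplitude and lag.
    """
    kernel = make_gcamp_kernel(scene.protocol, scene.tau_rise_s, scene.tau_decay_s)
    nvol = scene.protocol.session_volumes

    clean = np.broadcast_to(
        scene.background_f0, (nvol,) + scene.grid
    ).astype(float).copy()
    for cell in scene.cells:
        resp = cell.f0 * (1.0 + cell.amplitude * _shift(kernel.trace, cell.lag_volumes))
        clean[:, cell.mask] = resp[:, None]

    sessions = []
    for s in range(scene.n_sessions):
        if scene.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence(scene.seed, spawn_key=(s,))
            )
            sessions.append(clean + rng.normal(0.0, scene.noise_sd, clean.shape))
        else:
            sessions.append(clean.copy())

    positive = np.zeros(scene.grid, bool)
    negative = np.zeros(scene.grid, bool)
    for cell in scene.cells:
        if cell.amplitude > 0:
            positive |= cell.mask
        elif cell.amplitude < 0:
            negative |= cell.mask
    labels = {
        "kernel": kernel,
        "positive_mask": positive,
        "negative_mask": negative,
        "amplitudes": [c.amplitude for c in scene.cells],
        "lags": [c.lag_volumes for c in scene.cells],
    }
    return SampleRecording(sessions, scene.protocol), labels


def default_scene(
    grid: tuple[int, int, int] = (8, 32, 64),
    n_positive: int = 6,
    n_negative: int = 3,
    amplitude: float = 0.5,
    noise_sd: float = 10.0,
    background_f0: float = 100.0,
    lags: tuple[int, ...] = (0,),
    cell_size: tuple[int, int, int] = (2, 3, 3),
    protocol: StimulusProtocol | None = None,
    n_sessions: int = 10,
    seed: int = 0,
) -> CalciumSceneParams:
    """Randomly placed disjoint box-shaped cells on a background grid.

    Default signal-to-noise: peak response ``amplitude * f0`` is 5x the noise
    sd.  Lags cycle through ``lags`` across cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10_000,)))
    claimed = np.zeros(grid, bool)
    cells: list[CellSpec] = []
    signs = [1.0] * n_positive + [-1.0] * n_negative
    dz, dy, dx = cell_size
    for i, sign in enumerate(signs):
        for _ in range(200):
            z0 = rng.integers(0, grid[0] - dz + 1)
            y0 = rng.integers(0, grid[1] - dy + 1)
            x0 = rng.integers(0, grid[2] - dx + 1)
            mask = np.zeros(grid, bool)
            mask[z0 : z0 + dz, y0 : y0 + dy, x0 : x0 + dx] = True
            if not (claimed & mask).any():
                claimed |= mask
                break
        else:
            raise RuntimeError("could not place disjoint cells; grid too crowded")
        cells.append(
            CellSpec(
                mask=mask,
                amplitude=sign * amplitude,
                lag_volumes=int(lags[i % len(lags)]),
                f0=background_f0,
            )
        )
    return CalciumSceneParams(
        grid=grid,
        cells=cells,
        noise_sd=noise_sd,
        background_f0=background_f0,
        protocol=protocol if protocol is not None else StimulusProtocol(),
        n_sessions=n_sessions,
        seed=seed,
    )
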