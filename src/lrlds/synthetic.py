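"""Synthetic two-class (or multiclass) epoch generator.

Each class is a stochastic state-space system: the transition matrix is
block-diagonal with 2x2 rotation blocks (damped oscillators at requested
frequencies, scaled to a requested spectral radius; a zero-frequency block
is a real pole), the measurement matrix is a random orthonormal channel
mixing, and trials are driven by Gaussian state noise.  On top of the
dynamics the generator adds

* a channel-common "resting" waveform — by default a 1 Hz sinusoid
  identical on every channel, the simplest signal whose rows are mutually
  similar the way resting-state background is across electrodes;
* Gaussian observation noise, either at a fixed scale or calibrated
  per-trial to a requested signal-to-noise ratio;
* sparse artifacts — exactly ``floor(fraction * m * tau)`` entries per
  trial set to ``+/- amplitude`` at random positions, emulating brief
  high-amplitude electrode/muscle glitches.

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .lds import LDSModel

#: Samples discarded at the start of every trial so covariance checks see a
#: stationary state process rather than the initial-condition transient.
BURN_IN = 50


@dataclass
class ClassSpec:
    """One class generator: damped-oscillator poles of the transition matrix.

    ``radii[i]`` is the spectral radius of block ``i`` and ``freqs_hz[i]``
    its oscillation frequency (0 gives a real 1x1 pole, otherwise a 2x2
    rotation block).  The state dimension is ``sum(2 if f > 0 else 1)``.
    """

    radii: list[float]
    freqs_hz: list[float]
    label: int = 0

    def state_dim(self) -> int:
        return sum(2 if f > 0 else 1 for f in self.freqs_hz)


@dataclass
class SimConfig:
    """Study conditions for the synthetic epochs.

    Defaults emulate a small motor-imagery-like setting: 8 channels,
    4-dimensional state per class, 200 samples at 100 Hz, two classes that
    differ in how strongly damped their oscillators are (spectral radius
    0.6 vs 0.95 — sluggish vs sustained rhythm), observation noise at
    10 dB SNR, no resting background or artifacts unless requested.
    """

    m: int = 8
    tau: int = 200
    fs: float = 100.0
    class_specs: list[ClassSpec] = field(default_factory=lambda: [
        ClassSpec(radii=[0.6, 0.6], freqs_hz=[10.0, 22.0], label=0),
        ClassSpec(radii=[0.95, 0.95], freqs_hz=[10.0, 22.0], label=1),
    ])
    state_noise_scale: float = 1.0        # std of v(t); Q = scale^2 I
    input_matrix_B_scale: float = 1.0     # state-noise gain B = scale * I
    obs_noise_scale: float = 0.0          # std of omega(t); R = scale^2 I
    obs_snr_db: float | None = 10.0       # overrides obs_noise_scale when set
    resting_amplitude: float = 0.0
    resting_freq_hz: float = 1.0
    artifact_fraction: float = 0.0
    artifact_amplitude: float = 5.0
    artifact_relative: bool = False       # amplitude is a multiple of clean std
    seed: int = 0

    def validate(self) -> None:
        for spec in self.class_specs:
            if len(spec.radii) != len(spec.freqs_hz):
                raise ValueError("radii and freqs_hz must have equal length")
            for r in spec.radii:
                if not 0 <= r < 1:
                    raise ValueError(
                        f"spectral radius must lie in [0, 1), got {r}"
                    )
        if not 0 <= self.artifact_fraction <= 1:
            raise ValueError(
                f"artifact_fraction must lie in [0, 1], got {self.artifact_fraction}"
            )
        if self.state_noise_scale < 0 or self.obs_noise_scale < 0:
            raise ValueError("noise scales must be nonnegative")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


def rotation_transition(radii, freqs_hz, fs: float) -> np.ndarray:
    """Block-diagonal transition matrix from pole radii and frequencies."""
    blocks = []
    for r, f in zip(radii, freqs_hz):
        if not 0 <= r < 1:
            raise ValueError(f"spectral radius must lie in [0, 1), got {r}")
        if f == 0:
            blocks.append(np.array([[r]]))
        else:
            th = 2 * np.pi * f / fs
            c, s = np.cos(th), np.sin(th)
            blocks.append(r * np.array([[c, -s], [s, c]]))
    n = sum(b.shape[0] for b in blocks)
    A = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        A[i:i + k, i:i + k] = b
        i += k
    return A


def make_class_model(
    spec: ClassSpec, m: int, fs: float, seed: int
) -> LDSModel:
    """Ground-truth generator model for one class, deterministic in seed."""
    A = rotation_transition(spec.radii, spec.freqs_hz, fs)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((m, n)))
    # sign-fix like the estimator so repeated builds are identical
    for j in range(n):
        k = int(np.argmax(np.abs(Q[:, j])))
        if Q[k, j] < 0:
            Q[:, j] = -Q[:, j]
    return LDSModel(
        A=A, C=Q, ybar=np.zeros(m), states=np.zeros((n, 0)),
        singular_values=np.ones(n),
        meta={"label": spec.label, "seed": seed},
    )


def _simulate_states(
    A: np.ndarray, tau: int, scale: float, b_gain: float, rng
) -> np.ndarray:
    n = A.shape[0]
    x = rng.standard_normal(n)
    X = np.empty((n, tau))
    for t in range(BURN_IN + tau):
        if t >= BURN_IN:
            X[:, t - BURN_IN] = x
        x = A @ x + b_gain * scale * rng.standard_normal(n)
    return X


def simulate_epochs(
    cfg: SimConfig,
    trials_per_class: int,
    *,
    return_components: bool = False,
):
    """Simulate labeled epochs from the per-class state-space generators.

    Per trial: iterate ``x(t+1) = A x(t) + B v(t)`` from ``x(0) ~ N(0, I)``
    with a burn-in of ``BURN_IN`` samples, observe ``y(t) = C x(t) +
    omega(t)``, then add the channel-common resting waveform and sparse
    artifacts.  When ``cfg.obs_snr_db`` is set, the observation-noise std
    is calibrated per trial from the clean signal power.

    Returns an :class:`EpochSet`; with ``return_components=True`` also a
    dict with the ground-truth models and the clean / common / artifact
    tensors (for decomposition tests).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_classes = len(cfg.class_specs)
    models = [
        make_class_model(spec, cfg.m, cfg.fs, seed=int(rng.integers(2**31)))
        for spec in cfg.class_specs
    ]
    total = n_classes * trials_per_class
    data = np.empty((total, cfg.m, cfg.tau))
    labels = np.empty(total, dtype=int)
    clean = np.zeros_like(data)
    common = np.zeros_like(data)
    artifacts = np.zeros_like(data)
    t_axis = np.arange(cfg.tau) / cfg.fs

    i = 0
    for model, spec in zip(models, cfg.class_specs):
        for _ in range(trials_per_class):
            X = _simulate_states(
                model.A, cfg.tau, cfg.state_noise_scale,
                cfg.input_matrix_B_scale, rng,
            )
            Y = model.C @ X
            clean[i] = Y
            if cfg.obs_snr_db is not None:
                sig_power = np.mean(Y**2)
                noise_std = np.sqrt(sig_power / 10 ** (cfg.obs_snr_db / 10))
            else:
                noise_std = cfg.obs_noise_scale
            Y = Y + noise_std * rng.standard_normal(Y.shape)
            if cfg.resting_amplitude:
                phase = rng.uniform(0, 2 * np.pi)
                wave = cfg.resting_amplitude * np.sin(
                    2 * np.pi * cfg.resting_freq_hz * t_axis + phase
                )
                common[i] = np.tile(wave, (cfg.m, 1))
                Y = Y + common[i]
            if cfg.artifact_fraction:
                k = int(np.floor(cfg.artifact_fraction * cfg.m * cfg.tau))
                flat = rng.choice(cfg.m * cfg.tau, size=k, replace=False)
                signs = rng.choice([-1.0, 1.0], size=k)
                amp = cfg.artifact_amplitude
                if cfg.artifact_relative:
                    amp *= float(np.std(clean[i]))
                art = np.zeros(cfg.m * cfg.tau)
                art[flat] = signs * amp
                artifacts[i] = art.reshape(cfg.m, cfg.tau)
                Y = Y + artifacts[i]
            data[i] = Y
            labels[i] = spec.label
            i += 1

    epochs = EpochSet(
        data=data, labels=labels, fs=cfg.fs,
        meta={"generator": "lrlds.synthetic", "seed": cfg.seed},
    )
    if return_components:
        return epochs, {
            "models": models,
            "clean": clean,
            "common": common,
            "artifacts": artifacts,
        }
    return epochs


def two_class_config(
    seed: int = 0,
    *,
    radii: tuple[float, float] = (0.6, 0.95),
    artifact_fraction: float = 0.0,
    artifact_amplitude: float = 5.0,
    artifact_relative: bool = False,
    obs_snr_db: float | None = 10.0,
    m: int = 8,
    tau: int = 200,
) -> SimConfig:
    """The canonical two-class benchmark conditions.

    Classes share oscillation frequencies (10 and 22 Hz, one pole in each
    sensorimotor band) and differ only in damping: spectral radius
    ``radii[0]`` vs ``radii[1]``.
    """
    specs = [
        ClassSpec(radii=[radii[0]] * 2, freqs_hz=[10.0, 22.0], label=0),
        ClassSpec(radii=[radii[1]] * 2, freqs_hz=[10.0, 22.0], label=1),
    ]
    return SimConfig(
        m=m, tau=tau, class_specs=specs, obs_snr_db=obs_snr_db,
        artifact_fraction=artifact_fraction,
        artifact_amplitude=artifact_amplitude,
        artifact_relative=artifact_relative, seed=seed,
    )


def simulate_spatial_epochs(
    trials_per_class: int,
    *,
    m: int = 6,
    tau: int = 200,
    fs: float = 100.0,
    cov_diags: tuple[tuple[float, ...], tuple[float, ...]] | None = None,
    seed: int = 0,
) -> EpochSet:
    """Two classes of Gaussian trials with planted spatial covariances.

    Each trial is spatially colored white noise with the per-class diagonal
    covariance; the default plants the class difference on the first two
    channels (variance 4 vs 1 swapped), the classic setting in which
    spatial-pattern filters are optimal.  Identical ``cov_diags`` entries
    give non-discriminable classes (chance-level accuracy).
    """
    if cov_diags is None:
        d1 = [4.0, 1.0] + [1.0] * (m - 2)
        d2 = [1.0, 4.0] + [1.0] * (m - 2)
        cov_diags = (tuple(d1), tuple(d2))
    rng = np.random.default_rng(seed)
    data = np.empty((2 * trials_per_class, m, tau))
    labels = np.empty(2 * trials_per_class, dtype=int)
    i = 0
    for label, diag in enumerate(cov_diags):
        scale = np.sqrt(np.asarray(diag, float))[:, None]
        for _ in range(trials_per_class):
            data[i] = scale * rng.standard_normal((m, tau))
            labels[i] = label
            i += 1
    return EpochSet(data=data, labels=labels, fs=fs,
                    meta={"generator": "lrlds.synthetic.spatial", "seed": seed})
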