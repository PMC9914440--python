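"""Synthetic imaging data with ground truth.

Emulates the three data streams the quantification stack consumes:

* quantum-dot SPT trajectories (1200 frames at 30 ms, ~25 nm localization
  accuracy, free or confined motion, optional blinking),
* STORM detection streams (30 000 frames at 50 ms, blinking emitters with
  repeated detections, tens-of-nm clusters, stage drift),
* widefield punctate images (16-bit, 512×512) with smooth background.

Lengths are µm for SPT and nm for STORM, matching the analysis modules;
conversions are explicit (:mod:`memdyn.trajectories`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectories import Trajectory

MOTION_MODELS = ("free_brownian", "confined_disc", "confined_ou")
DRIFT_MODELS = ("none", "linear", "random_walk")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class TrajectorySimConfig:
    """Single-particle motion model parameters.

    Defaults mirror the QD-SPT acquisition: 1200 frames, 30 ms integration,
    ~25 nm pointing accuracy. ``diffusion_coeff`` is in µm²/s. For confined
    models ``confinement_radius`` (µm) is required; the Ornstein-Uhlenbeck
    model is calibrated so its stationary per-axis standard deviation equals
    ``confinement_radius / 2``. Blinking is a two-state Markov chain on
    visibility: ``blink_off_prob`` = P(on→off) per frame, ``blink_on_prob``
    = P(off→on); the default chain never switches off.
    """

    n_frames: int = 1200
    frame_interval: float = 0.030
    diffusion_coeff: float = 0.1
    motion_model: str = "free_brownian"
    confinement_radius: float | None = None
    localization_sigma: float = 0.025
    blink_on_prob: float = 1.0
    blink_off_prob: float = 0.0
    start: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.diffusion_coeff < 0:
            raise ConfigurationError("diffusion_coeff must be >= 0")
        if self.localization_sigma < 0:
            raise ConfigurationError("localization_sigma must be >= 0")
        for p in (self.blink_on_prob, self.blink_off_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("blink probabilities must be in [0, 1]")
        if self.motion_model not in MOTION_MODELS:
            raise ConfigurationError(f"unknown motion model {self.motion_model!r}")
        if self.motion_model != "free_brownian" and not self.confinement_radius:
            raise ConfigurationError(
                f"{self.motion_model} requires a confinement_radius"
            )


@dataclass
class SceneConfig:
    """Field-of-view geometry for multi-particle SPT scenes.

    Masks are discs on the camera grid (pixel size 190 nm so that four
    pixels span 760 nm, the synaptic inclusion distance). ``masks`` maps a
    marker class (e.g. ``inhibitory``, ``excitatory``, ``endocytic``) to a
    list of ``(center_um, radius_um)`` discs. ``compartment_overrides`` maps
    a marker class to motion parameters that take over while the true
    position lies inside one of that class's discs.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 190.0
    masks: dict[str, list[tuple[tuple[float, float], float]]] = field(default_factory=dict)
    compartment_overrides: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be > 0")
        h_um = self.image_shape[0] * self.pixel_size_nm / 1000.0
        w_um = self.image_shape[1] * self.pixel_size_nm / 1000.0
        for cls, discs in self.masks.items():
            for (cx, cy), r in discs:
                if r <= 0:
                    raise ConfigurationError(f"mask disc radius must be > 0 ({cls})")
                if not (0 <= cx <= w_um and 0 <= cy <= h_um):
                    raise ConfigurationError(
                        f"disc center ({cx}, {cy}) outside image for class {cls}"
                    )

    def rasterize_masks(self) -> dict[str, np.ndarray]:
        """Binary mask image per marker class; classes must be disjoint."""
        self.validate()
        h, w = self.image_shape
        p_um = self.pixel_size_nm / 1000.0
        # pixel-center convention, 0-based indices
        xs = (np.arange(w) + 0.5) * p_um
        ys = (np.arange(h) + 0.5) * p_um
        gx, gy = np.meshgrid(xs, ys)
        out: dict[str, np.ndarray] = {}
        for cls, discs in self.masks.items():
            m = np.zeros((h, w), dtype=bool)
            for (cx, cy), r in discs:
                m |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
            out[cls] = m
        classes = list(out)
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                if np.any(out[a] & out[b]):
                    raise ConfigurationError(
                        f"mask classes {a!r} and {b!r} overlap"
                    )
        return out


@dataclass
class StormSimConfig:
    """STORM acquisition emulation: 30 000 frames at 50 ms.

    ``clusters`` is a list of ``(center_nm, radius_nm, n_emitters)``;
    emitters are placed uniformly in each disc. ``background_density`` is
    emitters per µm² over the field. Each emitter blinks in bursts: a
    Poisson number of bursts (``mean_bursts``) start at uniform frames and
    last geometric(``burst_continue_prob``) consecutive frames, one
    detection per frame. Detection position = emitter + Gaussian jitter
    (``localization_sigma``) + drift(frame).
    """

    n_frames: int = 30000
    frame_interval: float = 0.050
    field_size_nm: float = 5000.0
    clusters: list[tuple[tuple[float, float], float, int]] = field(default_factory=list)
    background_density: float = 0.0  # emitters per µm²
    mean_bursts: float = 5.0
    burst_continue_prob: float = 0.5
    localization_sigma: float = 10.0
    drift_model: str = "none"
    drift_rate_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.frame_interval <= 0 or self.field_size_nm <= 0:
            raise ConfigurationError("frame_interval and field_size_nm must be > 0")
        if self.localization_sigma < 0:
            raise ConfigurationError("localization_sigma must be >= 0")
        if self.background_density < 0:
            raise ConfigurationError("background_density must be >= 0")
        if self.drift_model not in DRIFT_MODELS:
            raise ConfigurationError(f"unknown drift model {self.drift_model!r}")
        for (_, r, n) in self.clusters:
            if r <= 0:
                raise ConfigurationError("cluster radius must be > 0")
            if n < 0:
                raise ConfigurationError("emitter counts must be >= 0")


@dataclass
class GroundTruth:
    """Truth record aligned one-to-one with emitted observations."""

    true_positions: np.ndarray | None = None  # ideal path / emitter coords
    true_labels: np.ndarray | None = None  # compartment or emitter membership
    true_drift: np.ndarray | None = None  # per-frame (dx, dy)
    visible: np.ndarray | None = None  # per-frame visibility (SPT blinking)
    extra: dict = field(default_factory=dict)


def _ou_step(pos, center, d, radius, dt, rng):
    """Exact OU update with stationary per-axis std = radius / 2."""
    s = radius / 2.0
    if d == 0:
        return pos.copy()
    k = d / s**2  # relaxation rate so that D/k = s²
    decay = np.exp(-k * dt)
    sd = s * np.sqrt(1.0 - decay**2)
    return center + (pos - center) * decay + rng.normal(0.0, sd, size=2)


def _reflect_disc(pos, center, radius):
    """Reflect a point at the boundary of a disc (single bounce)."""
    v = pos - center
    r = np.hypot(*v)
    if r <= radius or r == 0:
        return pos
    # fold radial excursion back inside
    r_new = 2 * radius - r
    r_new = max(r_new, 0.0)
    return center + v / r * r_new


def simulate_trajectory(cfg: TrajectorySimConfig) -> tuple[Trajectory, GroundTruth]:
    """Simulate one particle under the configured motion model.

    Free motion: per-axis increments are independent Gaussian with variance
    2·D·Δt; localization noise of std ``localization_sigma`` is added
    independently per visible frame afterwards. Deterministic under seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, dt, d = cfg.n_frames, cfg.frame_interval, cfg.diffusion_coeff
    center = np.asarray(cfg.start, dtype=float)
    true = np.empty((n, 2))
    true[0] = center
    step_sd = np.sqrt(2.0 * d * dt)
    for i in range(1, n):
        if cfg.motion_model == "free_brownian":
            true[i] = true[i - 1] + rng.normal(0.0, step_sd, size=2)
        elif cfg.motion_model == "confined_disc":
            cand = true[i - 1] + rng.normal(0.0, step_sd, size=2)
            true[i] = _reflect_disc(cand, center, cfg.confinement_radius)
        else:  # confined_ou
            true[i] = _ou_step(true[i - 1], center, d, cfg.confinement_radius, dt, rng)

    # two-state blinking chain on visibility, starting visible
    visible = np.ones(n, dtype=bool)
    for i in range(1, n):
        if visible[i - 1]:
            visible[i] = rng.random() >= cfg.blink_off_prob
        else:
            visible[i] = rng.random() < cfg.blink_on_prob
    if visible.sum() < 2:  # keep the trajectory constructible
        visible[:2] = True

    noise = rng.normal(0.0, cfg.localization_sigma, size=(n, 2))
    observed = true + noise
    frames = np.flatnonzero(visible)
    traj = Trajectory(
        particle_id=0, frames=frames, xy=observed[frames], frame_interval=dt
    )
    return traj, GroundTruth(true_positions=true, visible=visible)


def simulate_scene(
    scene: SceneConfig, traj_cfgs: Sequence[TrajectorySimConfig]
) -> tuple[list[Trajectory], dict[str, np.ndarray], GroundTruth]:
    """Simulate several particles over compartment masks.

    Whenever the true position lies inside a compartment disc whose class
    has an override, the local motion parameters switch to that override
    (``diffusion_coeff``, and for confined models the pull/reflection is
    toward the containing disc's center). Confined overrides act over a
    capture neighborhood of 3 disc radii rather than the disc proper: an
    Ornstein-Uhlenbeck pull that vanished exactly at the disc edge would let
    particles leak into the free regime on every boundary excursion, which
    is not the stable trapping the compartments are meant to emulate.
    Without masks this reduces to independent :func:`simulate_trajectory`
    calls.
    """
    scene.validate()
    masks = scene.rasterize_masks()
    _CAPTURE_FACTOR = 3.0

    def find_disc(pos):
        for cls, discs in scene.masks.items():
            if cls not in scene.compartment_overrides:
                continue
            ov_model = scene.compartment_overrides[cls].get("motion_model", "free_brownian")
            reach = _CAPTURE_FACTOR if ov_model in ("confined_ou", "confined_disc") else 1.0
            for (cx, cy), r in discs:
                if (pos[0] - cx) ** 2 + (pos[1] - cy) ** 2 <= (reach * r) ** 2:
                    return cls, np.array([cx, cy]), r
        return None, None, None

    trajs, truths, labels = [], [], []
    for pid, cfg in enumerate(traj_cfgs):
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        n, dt = cfg.n_frames, cfg.frame_interval
        true = np.empty((n, 2))
        true[0] = np.asarray(cfg.start, dtype=float)
        lab = np.empty(n, dtype=object)
        for i in range(1, n):
            cls, c, r = find_disc(true[i - 1])
            lab[i - 1] = cls
            if cls is None:
                d, model, radius, center = (
                    cfg.diffusion_coeff,
                    cfg.motion_model,
                    cfg.confinement_radius,
                    np.asarray(cfg.start, float),
                )
            else:
                ov = scene.compartment_overrides[cls]
                d = ov.get("diffusion_coeff", cfg.diffusion_coeff)
                model = ov.get("motion_model", cfg.motion_model)
                radius = ov.get("confinement_radius", r)
                center = c
            if model == "free_brownian":
                true[i] = true[i - 1] + rng.normal(0.0, np.sqrt(2 * d * dt), size=2)
            elif model == "confined_disc":
                cand = true[i - 1] + rng.normal(0.0, np.sqrt(2 * d * dt), size=2)
                true[i] = _reflect_disc(cand, center, radius)
            else:
                true[i] = _ou_step(true[i - 1], center, d, radius, dt, rng)
        lab[n - 1] = find_disc(true[n - 1])[0]

        visible = np.ones(n, dtype=bool)
        for i in range(1, n):
            if visible[i - 1]:
                visible[i] = rng.random() >= cfg.blink_off_prob
            else:
                visible[i] = rng.random() < cfg.blink_on_prob
        if visible.sum() < 2:
            visible[:2] = True
        observed = true + rng.normal(0.0, cfg.localization_sigma, size=(n, 2))
        frames = np.flatnonzero(visible)
        trajs.append(
            Trajectory(particle_id=pid, frames=frames, xy=observed[frames], frame_interval=dt)
        )
        truths.append(true)
        labels.append(lab)

    gt = GroundTruth(
        true_positions=np.array(truths),
        true_labels=np.array(labels, dtype=object),
    )
    return trajs, masks, gt


def _drift_trace(cfg: StormSimConfig, rng) -> np.ndarray:
    n = cfg.n_frames
    rate = np.asarray(cfg.drift_rate_nm_per_frame, dtype=float)
    if cfg.drift_model == "none":
        return np.zeros((n, 2))
    if cfg.drift_model == "linear":
        return np.outer(np.arange(n), rate)
    steps = rng.normal(0.0, 1.0, size=(n, 2)) * rate
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def simulate_storm(cfg: StormSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a STORM detection stream.

    Returns a detection table (frame, x_nm, y_nm) sorted by frame, and
    ground truth holding emitter coordinates, the emitter index of every
    detection, and the injected per-frame drift.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    emitters = []
    for (cx, cy), r, n_em in cfg.clusters:
        rr = r * np.sqrt(rng.random(n_em))
        th = rng.random(n_em) * 2 * np.pi
        emitters.append(np.column_stack([cx + rr * np.cos(th), cy + rr * np.sin(th)]))
    n_bg = rng.poisson(cfg.background_density * (cfg.field_size_nm / 1000.0) ** 2)
    if n_bg:
        emitters.append(rng.random((n_bg, 2)) * cfg.field_size_nm)
    emitters = np.vstack(emitters) if emitters else np.empty((0, 2))

    drift = _drift_trace(cfg, rng)

    frames, xs, ys, ids = [], [], [], []
    for idx, (ex, ey) in enumerate(emitters):
        n_bursts = rng.poisson(cfg.mean_bursts)
        for _ in range(n_bursts):
            start = rng.integers(0, cfg.n_frames)
            length = rng.geometric(1.0 - cfg.burst_continue_prob)
            for f in range(start, min(start + length, cfg.n_frames)):
                frames.append(f)
                xs.append(ex)
                ys.append(ey)
                ids.append(idx)
    frames = np.asarray(frames, dtype=int)
    ids = np.asarray(ids, dtype=int)
    pos = np.column_stack([xs, ys]) if len(xs) else np.empty((0, 2))
    if len(frames):
        pos = pos + rng.normal(0.0, cfg.localization_sigma, size=pos.shape)
        pos = pos + drift[frames]
    order = np.argsort(frames, kind="stable")
    dets = pd.DataFrame(
        {"frame": frames[order], "x_nm": pos[order, 0], "y_nm": pos[order, 1]}
    )
    gt = GroundTruth(
        true_positions=emitters, true_labels=ids[order], true_drift=drift
    )
    return dets, gt


def simulate_grouped_sample(
    effect: float = 1.0,
    n_cultures: int = 2,
    n_neurons_per_condition: int = 5,
    obs_range: tuple[int, int] = (12, 28),
    sigma_obs: float = 0.5,
    sigma_neuron: float = 0.05,
    sigma_culture: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Clustered log-normal observations for the resampling statistic.

    Emulates per-cluster STORM measurements nested in neurons nested in
    cultures: ``value = exp(N(0, sigma_obs²)) · neuron_effect ·
    culture_effect · (effect if treated)``. Culture effects (log-sd
    ``sigma_culture``) are large but removed by the per-culture control-median
    normalization of the balanced test; neuron effects are kept small
    (log-sd ``sigma_neuron``) because the Monte-Carlo U p-value is computed
    under an exchangeable null and is only calibrated for weak within-neuron
    correlation. Per-neuron observation counts are drawn uniformly from
    ``obs_range`` so the balanced selection is exercised. ``effect`` is the
    multiplicative treated/control shift (1.0 = null).
    """
    rng = np.random.default_rng(seed)
    neurons_per_culture = [[] for _ in range(n_cultures)]
    for cond in ("control", "treated"):
        for k in range(n_neurons_per_condition):
            neurons_per_culture[k % n_cultures].append((cond, k))
    rows = []
    for cult_idx, members in enumerate(neurons_per_culture):
        cult_eff = float(rng.lognormal(0.0, sigma_culture))
        for cond, k in members:
            neu_eff = float(rng.lognormal(0.0, sigma_neuron))
            n_obs = int(rng.integers(obs_range[0], obs_range[1] + 1))
            vals = rng.lognormal(0.0, sigma_obs, n_obs) * cult_eff * neu_eff
            if cond == "treated":
                vals = vals * effect
            for v in vals:
                rows.append(
                    {
                        "value": float(v),
                        "condition": cond,
                        "culture": f"culture{cult_idx}",
                        "neuron": f"{cond}_neuron{k}",
                    }
                )
    return pd.DataFrame(rows)


def simulate_widefield(
    puncta: Sequence[tuple[float, float, float, float]],
    image_shape: tuple[int, int] = (512, 512),
    background_level: float = 200.0,
    background_gradient: tuple[float, float] = (0.0, 0.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a 16-bit widefield image of Gaussian puncta.

    ``puncta`` rows are ``(row, col, sigma_px, amplitude)``. The image is
    smooth background (level + linear gradient) + puncta + Gaussian noise,
    clipped to the 16-bit range.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    img = (
        background_level
        + background_gradient[0] * rr
        + background_gradient[1] * cc
    )
    for (pr, pc, s, amp) in puncta:
        if not (0 <= pr < h and 0 <= pc < w):
            raise ConfigurationError(f"punctum ({pr}, {pc}) outside image")
        img = img + amp * np.exp(-(((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * s**2)))
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 2**16 - 1).astype(np.uint16)
    truth = GroundTruth(
        true_positions=np.array([[p[0], p[1]] for p in puncta], dtype=float),
        extra={
            "amplitudes": [p[3] for p in puncta],
            "sigmas_px": [p[2] for p in puncta],
            "background_level": background_level,
        },
    )
    return img, truth
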