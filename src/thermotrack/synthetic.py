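"""Ground-truthed synthetic trajectories and rendered video.

The generator emulates the statistical structure the pipeline assumes:
point-like cells rendered as Gaussian blobs on a noisy background, passive
particles undergoing Brownian motion with the temperature-correct diffusion
coefficient (Stokes-Einstein with the water viscosity model), active swimmers
in four modes (straight run, run-and-tumble, helical = projected spiral,
circular), a uniform or sheared drift field standing in for thermal
convection, and immobile surface-adherent clutter. Simulation is 2D
throughout, matching a tracking surface that works on Z projections.

Every scene is seeded; one particle's path never depends on how many other
particles exist (stable per-particle sub-seeding), so scenes are reproducible
bit-exactly and composable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Track, VideoStack
from .physics import brownian_step_sigma, brownian_D_um2_s

SWIM_MODES = ("straight", "run_and_tumble", "helical", "circular")
PASSIVE_MODES = ("brownian", "immobile")
ALL_MODES = SWIM_MODES + PASSIVE_MODES


def simulate_brownian(D: float, n: int, dt: float, seed, origin=(0.0, 0.0)) -> np.ndarray:
    """Brownian trajectory of ``n`` positions with diffusion ``D`` (um^2/s).

    I.i.d. Gaussian steps with per-axis standard deviation sqrt(2*D*dt).
    ``seed`` may be an int or a numpy Generator.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = brownian_step_sigma(D, dt)
    steps = rng.normal(0.0, sigma, size=(n - 1, 2))
    traj = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return traj + np.asarray(origin)


def simulate_swimmer(mode: str, speed: float, n: int, dt: float, seed,
                     params: dict | None = None, origin=(0.0, 0.0)) -> np.ndarray:
    """Active-swimmer trajectory of ``n`` positions in one of four modes.

    straight        constant heading (plus optional rotational diffusion).
    run_and_tumble  exponential run durations (``mean_run_s``, default 1 s)
                    separated by instantaneous reorientations to a uniform
                    new heading.
    circular        constant angular rate ``omega`` (rad/s, default 2*pi/2).
    helical         the 2D projection of a helix: drift along a fixed heading
                    with a transverse sinusoid (``amplitude_um`` default 3,
                    ``frequency_hz`` default 1).

    ``rot_diffusion`` (rad^2/s, default 0) adds heading noise to every mode
    that has a heading.
    """
    if speed <= 0:
        raise ValueError("swimming speed must be positive")
    if mode not in SWIM_MODES:
        raise ValueError(f"unknown swim mode {mode!r}; choose from {SWIM_MODES}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    rot_d = float(params.get("rot_diffusion", 0.0))
    rot_sigma = np.sqrt(2.0 * rot_d * dt)
    theta = float(params.get("heading", rng.uniform(0, 2 * np.pi)))

    pos = np.zeros((n, 2))
    if mode == "helical":
        amp = float(params.get("amplitude_um", 3.0))
        freq = float(params.get("frequency_hz", 1.0))
        phase = float(params.get("phase", rng.uniform(0, 2 * np.pi)))
        ts = np.arange(n) * dt
        along = speed * ts
        across = amp * np.sin(2 * np.pi * freq * ts + phase)
        c, s = np.cos(theta), np.sin(theta)
        pos[:, 0] = c * along - s * across
        pos[:, 1] = s * along + c * across
    elif mode == "circular":
        omega = float(params.get("omega", np.pi))
        for i in range(1, n):
            pos[i] = pos[i - 1] + speed * dt * np.array([np.cos(theta), np.sin(theta)])
            theta += omega * dt + (rng.normal(0, rot_sigma) if rot_sigma else 0.0)
    elif mode == "run_and_tumble":
        mean_run = float(params.get("mean_run_s", 1.0))
        next_tumble = rng.exponential(mean_run)
        t = 0.0
        for i in range(1, n):
            pos[i] = pos[i - 1] + speed * dt * np.array([np.cos(theta), np.sin(theta)])
            t += dt
            if rot_sigma:
                theta += rng.normal(0, rot_sigma)
            if t >= next_tumble:
                theta = rng.uniform(0, 2 * np.pi)
                next_tumble += rng.exponential(mean_run)
    else:  # straight
        for i in range(1, n):
            pos[i] = pos[i - 1] + speed * dt * np.array([np.cos(theta), np.sin(theta)])
            if rot_sigma:
                theta += rng.normal(0, rot_sigma)
    return pos + np.asarray(origin)


def apply_drift(trajectories, drift_velocity, dt: float,
                shear: float = 0.0, y_ref: float = 0.0):
    """Add a drift displacement per frame to one or many trajectories.

    ``drift_velocity`` is (vx, vy) in um/s. With nonzero ``shear`` (1/s) the
    x-drift varies linearly with a particle's initial y (multiple drift
    planes): vx_eff = vx + shear * (y0 - y_ref).
    """
    single = isinstance(trajectories, np.ndarray) and trajectories.ndim == 2
    trajs = [trajectories] if single else list(trajectories)
    vx, vy = drift_velocity
    out = []
    for traj in trajs:
        traj = np.asarray(traj, dtype=float)
        n = len(traj)
        ts = np.arange(n) * dt
        vx_eff = vx + shear * (traj[0, 1] - y_ref)
        drift = np.column_stack([vx_eff * ts, vy * ts])
        out.append(traj + drift)
    return out[0] if single else out


@dataclass
class Population:
    """One homogeneous particle population within a scene.

    ``speed`` (um/s) applies to swim modes; ``D`` (um^2/s) to brownian mode
    (derived from temperature when omitted); ``params`` passes through to
    simulate_swimmer. ``brightness`` is the rendered blob's peak amplitude.
    """

    mode: str
    count: int
    speed: float | None = None
    D: float | None = None
    params: dict = field(default_factory=dict)
    brightness: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ALL_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")

    @property
    def motile(self) -> bool:
        return self.mode in SWIM_MODES


@dataclass
class SceneConfig:
    """Full description of a synthetic scene (seed mandatory)."""

    seed: int
    frame_count: int = 150
    frame_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5          # um/px
    frame_interval: float = 1.0 / 15.0
    temperature: float = 301.15      # K; sets Brownian D when a population omits D
    particle_radius_um: float = 1.0  # hydrodynamic radius for the default D
    populations: list[Population] = field(default_factory=list)
    drift_velocity: tuple[float, float] = (0.0, 0.0)   # um/s
    drift_shear: float = 0.0                            # 1/s
    psf_sigma: float = 1.5           # px
    noise_sigma: float = 1.0         # additive Gaussian intensity noise
    chamber_depth_um: float = 1000.0  # nominal depth for volume bookkeeping

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.frame_shape[1] * self.pixel_size,
                self.frame_shape[0] * self.pixel_size)

    @property
    def volume_of_view_uL(self) -> float:
        """Field area x nominal chamber depth, in microlitres (1 uL = 1e9 um^3)."""
        w, h = self.field_um
        return w * h * self.chamber_depth_um / 1e9

    @property
    def total_particles(self) -> int:
        return sum(p.count for p in self.populations)

    @property
    def cell_concentration_per_mL(self) -> float:
        """Implied concentration: total particles per volume of view."""
        return self.total_particles / (self.volume_of_view_uL * 1e-3)


@dataclass
class ParticleTruth:
    """Ground truth for one rendered particle."""

    index: int
    mode: str
    motile: bool
    trajectory: np.ndarray      # (frame_count, 2) positions in um, pre-clipping
    speed: float | None
    D: float | None
    clipped: bool = False       # True if the particle ever left the field


@dataclass
class SceneTruth:
    """Ground-truth labels for a whole scene."""

    config: SceneConfig
    particles: list[ParticleTruth]

    @property
    def motile_fraction(self) -> float:
        n = len(self.particles)
        return sum(p.motile for p in self.particles) / n if n else 0.0

    def tracks(self) -> list[Track]:
        """Ground-truth trajectories as Track objects (for feature-level tests)."""
        dt = self.config.frame_interval
        out = []
        for p in self.particles:
            t = np.arange(len(p.trajectory)) * dt
            out.append(Track(track_id=p.index, t=t,
                             x=p.trajectory[:, 0], y=p.trajectory[:, 1]))
        return out


def _simulate_particle(pop: Population, cfg: SceneConfig, rng: np.random.Generator,
                       origin: np.ndarray) -> tuple[np.ndarray, float | None, float | None]:
    sub = np.random.default_rng(rng.integers(0, 2 ** 31))
    n, dt = cfg.frame_count, cfg.frame_interval
    if pop.mode == "immobile":
        return np.tile(origin, (n, 1)), None, None
    if pop.mode == "brownian":
        D = pop.D if pop.D is not None else brownian_D_um2_s(
            cfg.temperature, cfg.particle_radius_um)
        return simulate_brownian(D, n, dt, sub, origin=origin), None, D
    speed = pop.speed if pop.speed is not None else 20.0
    traj = simulate_swimmer(pop.mode, speed, n, dt, sub, params=pop.params,
                            origin=origin)
    return traj, speed, None


def _reflect(traj: np.ndarray, w: float, h: float) -> tuple[np.ndarray, bool]:
    """Reflect a trajectory at the field boundaries (keeps the per-frame
    particle count constant, emulating the steady-state exchange of cells
    through a real field of view). Returns (trajectory, ever_clipped)."""
    out = traj.copy()
    clipped = False
    for axis, limit in ((0, w), (1, h)):
        v = out[:, axis]
        if np.any((v < 0) | (v > limit)):
            clipped = True
            v = np.mod(v, 2 * limit)
            v = np.where(v > limit, 2 * limit - v, v)
            out[:, axis] = v
    return out, clipped


def render_scene(cfg: SceneConfig) -> tuple[VideoStack, SceneTruth]:
    """Render a scene to video and return it with its ground truth.

    Each particle is a Gaussian blob (sigma = psf_sigma px, peak =
    population brightness) at its trajectory position; drift is added to
    every non-immobile particle; additive Gaussian noise at noise_sigma.
    Deterministic per seed. Particles are reflected at the field edges;
    the truth records which ones ever touched an edge.
    """
    rng = np.random.default_rng(cfg.seed)
    h_px, w_px = cfg.frame_shape
    w_um, h_um = cfg.field_um
    n = cfg.frame_count
    dt = cfg.frame_interval

    particles: list[ParticleTruth] = []
    margin = 4 * cfg.psf_sigma * cfg.pixel_size
    idx = 0
    for pop in cfg.populations:
        for _ in range(pop.count):
            origin = np.array([
                rng.uniform(margin, w_um - margin),
                rng.uniform(margin, h_um - margin),
            ])
            traj, speed, D = _simulate_particle(pop, cfg, rng, origin)
            if pop.mode != "immobile" and cfg.drift_velocity != (0.0, 0.0):
                traj = apply_drift(traj, cfg.drift_velocity, dt,
                                   shear=cfg.drift_shear, y_ref=h_um / 2)
            traj, clipped = _reflect(traj, w_um, h_um)
            particles.append(ParticleTruth(
                index=idx, mode=pop.mode, motile=pop.motile,
                trajectory=traj, speed=speed, D=D, clipped=clipped))
            idx += 1

    frames = np.zeros((n, h_px, w_px))
    half = int(np.ceil(4 * cfg.psf_sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    brightness = []
    for pop in cfg.populations:
        brightness.extend([pop.brightness] * pop.count)
    for fi in range(n):
        img = frames[fi]
        for p, amp in zip(particles, brightness):
            x_um, y_um = p.trajectory[fi]
            cx, cy = x_um / cfg.pixel_size, y_um / cfg.pixel_size
            ix, iy = int(round(cx)), int(round(cy))
            dx, dy = cx - ix, cy - iy
            blob = amp * np.exp(-((xx - dx) ** 2 + (yy - dy) ** 2)
                                / (2 * cfg.psf_sigma ** 2))
            y0, y1 = max(0, iy - half), min(h_px, iy + half + 1)
            x0, x1 = max(0, ix - half), min(w_px, ix + half + 1)
            if y0 >= y1 or x0 >= x1:
                continue
            img[y0:y1, x0:x1] += blob[y0 - (iy - half):y1 - (iy - half),
                                      x0 - (ix - half):x1 - (ix - half)]
    if cfg.noise_sigma > 0:
        frames += rng.normal(0.0, cfg.noise_sigma, size=frames.shape)

    stack = VideoStack(frames, pixel_size=cfg.pixel_size,
                       frame_interval=cfg.frame_interval)
    return stack, SceneTruth(config=cfg, particles=particles)


def reference_scenes() -> dict[str, SceneConfig]:
    """Seeded scene catalog spanning the qualitative temperature regimes.

    Motile fraction rises from 20% (28C) through 25% (34C) to 60% (44C),
    collapses at 61C and 66C, and is zero at 84C where all motion is thermal
    drift. Brownian diffusion in each scene uses the temperature-correct
    Stokes-Einstein value for a 1 um radius particle.
    """

    def temp(celsius: float) -> float:
        return celsius + 273.15

    scenes = {
        "28C": SceneConfig(
            seed=2800, temperature=temp(28),
            populations=[
                Population("straight", 1, speed=16.0, params={"rot_diffusion": 0.05}),
                Population("run_and_tumble", 2, speed=16.0,
                           params={"mean_run_s": 1.0, "rot_diffusion": 0.05}),
                Population("helical", 1, speed=12.0,
                           params={"amplitude_um": 3.0, "frequency_hz": 1.0}),
                Population("circular", 1, speed=15.0, params={"omega": np.pi}),
                Population("brownian", 16),
                Population("immobile", 4),
            ],
        ),
        "34C": SceneConfig(
            seed=3400, temperature=temp(34),
            populations=[
                Population("straight", 2, speed=23.0, params={"rot_diffusion": 0.05}),
                Population("run_and_tumble", 3, speed=23.0,
                           params={"mean_run_s": 1.0, "rot_diffusion": 0.05}),
                Population("helical", 1, speed=15.0),
                Population("brownian", 14),
                Population("immobile", 4),
            ],
        ),
        "44C": SceneConfig(
            seed=4400, temperature=temp(44),
            populations=[
                Population("straight", 5, speed=24.0, params={"rot_diffusion": 0.05}),
                Population("run_and_tumble", 9, speed=24.0,
                           params={"mean_run_s": 1.0, "rot_diffusion": 0.05}),
                Population("helical", 1, speed=16.0),
                Population("brownian", 8),
                Population("immobile", 2),
            ],
        ),
        "61C": SceneConfig(
            seed=6100, temperature=temp(61),
            populations=[
                Population("straight", 1, speed=24.0, params={"rot_diffusion": 0.05}),
                Population("run_and_tumble", 1, speed=24.0),
                Population("brownian", 20),
                Population("immobile", 10),
            ],
            drift_velocity=(2.0, 0.0),
        ),
        "66C": SceneConfig(
            seed=6600, temperature=temp(66),
            populations=[
                Population("straight", 1, speed=23.0, params={"rot_diffusion": 0.05}),
                Population("brownian", 24),
                Population("immobile", 10),
            ],
            drift_velocity=(4.0, 1.0),
        ),
        "84C": SceneConfig(
            seed=8400, temperature=temp(84),
            populations=[
                Population("brownian", 24),
                Population("immobile", 8),
            ],
            drift_velocity=(5.0, 0.0),
            drift_shear=0.02,
        ),
    }
    return scenes
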