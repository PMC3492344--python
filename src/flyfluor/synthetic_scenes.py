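"""Synthetic paired IR / fluorescence scenes with known ground truth.

The generator emulates a group of walking flies imaged from above under two
channels. The fluorescence forward model captures the features that the
discrimination metrics exploit:

* every fly has a dim body (cuticular baseline) and a posterior Gaussian
  blob of abdominal autofluorescence;
* GFP flies additionally carry a bright anterior (thoracic) Gaussian blob;
* non-GFP flies get two small bright anterior eye spots, the worst case for
  a Front-ROI metric, emulating markers that drive expression in the eyes
  and ocelli;
* the arena can carry a linear illumination gradient, extraneous
  autofluorescent patches, and additive per-pixel Gaussian noise.

The IR channel shows dark fly silhouettes on a bright backlit background
and is independent of genotype.

Poses follow a reflective random walk; everything (poses, labels, pixels)
is reproducible from the config's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .io_data import Channel, ImageStack, Label, TrajectoryRecord
from .io_data import normalize_angle


@dataclass(frozen=True)
class SceneConfig:
    """All knobs of the synthetic scene, with intensities in camera counts.

    Defaults describe a high-contrast recording of an 18-fly group (the
    group size used throughout): thoracic GFP at twice the abdominal
    autofluorescence and modest read noise.
    """

    arena_width: int = 256
    arena_height: int = 256
    n_flies: int = 18
    gfp_fraction: float = 0.5
    n_frames: int = 20
    body_a: float = 9.0  # mean semi-major axis, px
    body_b: float = 3.5  # mean semi-minor axis, px
    body_jitter: float = 0.1  # fractional per-fly size jitter
    thorax_gfp_amp: float = 120.0
    abdomen_auto_amp: float = 60.0
    eye_auto_amp: float = 40.0
    body_base_amp: float = 25.0
    background: float = 5.0
    noise_sd: float = 6.0  # additive Gaussian, per pixel
    illum_gradient: float = 0.2  # fractional change across the arena
    arena_patch_amp: float = 0.0
    n_arena_patches: int = 0
    step_sd: float = 2.0  # px per frame
    turn_sd: float = 0.3  # radians per frame
    separation_factor: float = 2.5  # min center distance, in units of body_a; 0 = off
    dtype: str = "uint8"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1 or self.n_frames < 1:
            raise ValueError("need at least one fly and one frame")
        if not (0 <= self.gfp_fraction <= 1):
            raise ValueError("gfp_fraction must be in [0, 1]")
        amps = (
            self.thorax_gfp_amp, self.abdomen_auto_amp, self.eye_auto_amp,
            self.body_base_amp, self.noise_sd,
        )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if np.dtype(self.dtype) not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError("dtype must be uint8 or uint16")

    @property
    def n_gfp(self) -> int:
        return int(round(self.gfp_fraction * self.n_flies))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneConfig":
        return cls(**json.loads(Path(path).read_text()))


def noisy_config(seed: int = 0, **overrides) -> SceneConfig:
    """The stated low-SNR regime: thoracic GFP at twice the abdominal
    autofluorescence, per-pixel noise as large as the abdominal amplitude,
    and eye autofluorescence on."""
    base = SceneConfig(
        thorax_gfp_amp=120.0,
        abdomen_auto_amp=60.0,
        noise_sd=60.0,
        eye_auto_amp=40.0,
        seed=seed,
    )
    return replace(base, **overrides)


def random_walk_poses(config: SceneConfig) -> list[TrajectoryRecord]:
    """Reflective random-walk trajectories for every fly.

    Per frame each fly turns by Normal(0, turn_sd) and steps by a
    Normal(0, step_sd) displacement along its heading, reflecting off the
    arena walls (with a body-size margin). Per-fly semi-axes are jittered
    once around the configured means.

    Flies are solid bodies: a proposed step that would bring two centers
    closer than ``separation_factor * body_a`` is rejected (the fly stays
    put for that frame after a few retries). Set ``separation_factor = 0``
    to allow free visual overlap and exercise ROI contamination.
    """
    rng = np.random.default_rng(config.seed)
    margin = 2.0 * config.body_a
    w, h = config.arena_width, config.arena_height
    if w - 2 * margin <= 1 or h - 2 * margin <= 1:
        raise ValueError(
            f"arena {w}x{h} too small for flies of semi-major axis {config.body_a}"
        )
    min_dist = config.separation_factor * config.body_a
    j = config.body_jitter
    axes = []
    for _ in range(config.n_flies):
        a = config.body_a * (1.0 + rng.uniform(-j, j))
        b = min(a, config.body_b * (1.0 + rng.uniform(-j, j)))
        axes.append((a, b))

    def clear_of_others(x: float, y: float, skip: int) -> bool:
        if min_dist <= 0:
            return True
        return all(
            (x - xs[k]) ** 2 + (y - ys[k]) ** 2 >= min_dist**2
            for k in range(config.n_flies)
            if k != skip and xs[k] is not None
        )

    xs: list[float | None] = [None] * config.n_flies
    ys: list[float | None] = [None] * config.n_flies
    thetas = [rng.uniform(-math.pi, math.pi) for _ in range(config.n_flies)]
    for fly_id in range(config.n_flies):
        for attempt in range(1000):
            x = rng.uniform(margin, w - 1 - margin)
            y = rng.uniform(margin, h - 1 - margin)
            if clear_of_others(x, y, fly_id):
                break
        else:
            raise ValueError(
                f"arena {w}x{h} too small to place {config.n_flies} flies "
                f"{min_dist:.0f} px apart"
            )
        xs[fly_id], ys[fly_id] = x, y

    records: list[TrajectoryRecord] = []
    for frame in range(config.n_frames):
        for fly_id in range(config.n_flies):
            a, b = axes[fly_id]
            records.append(
                TrajectoryRecord(frame=frame, fly_id=fly_id, x=xs[fly_id],
                                 y=ys[fly_id], theta=thetas[fly_id], a=a, b=b)
            )
        if frame == config.n_frames - 1:
            break
        for fly_id in range(config.n_flies):
            for _ in range(5):
                theta = normalize_angle(
                    thetas[fly_id] + rng.normal(0.0, config.turn_sd)
                )
                step = rng.normal(0.0, config.step_sd)
                x = _reflect(xs[fly_id] + step * math.cos(theta), margin, w - 1 - margin)
                y = _reflect(ys[fly_id] + step * math.sin(theta), margin, h - 1 - margin)
                if clear_of_others(x, y, fly_id):
                    thetas[fly_id] = theta
                    xs[fly_id], ys[fly_id] = x, y
                    break
    return records


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    v = (v - lo) % (2.0 * span)
    return lo + (v if v <= span else 2.0 * span - v)


def render_fly(
    pose: TrajectoryRecord, label: Label, config: SceneConfig
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render one fly's noiseless fluorescence patch.

    Returns ``(patch, (x0, y0))`` where the patch's [0, 0] pixel sits at
    image coordinate (x0, y0). The patch composes, by maximum intensity, a
    filled body ellipse at ``body_base_amp``, a posterior abdominal blob at
    ``abdomen_auto_amp``, and either an anterior thoracic blob
    (``thorax_gfp_amp``, GFP flies) or two anterior eye spots
    (``eye_auto_amp``, non-GFP flies).
    """
    reach = pose.a * 1.6 + 3.0
    x0 = int(math.floor(pose.x - reach))
    y0 = int(math.floor(pose.y - reach))
    n = int(math.ceil(2 * reach)) + 1
    px, py = np.meshgrid(np.arange(x0, x0 + n), np.arange(y0, y0 + n))
    c, s = math.cos(pose.theta), math.sin(pose.theta)
    dx = px - pose.x
    dy = py - pose.y
    u = dx * c + dy * s
    v = -dx * s + dy * c

    patch = np.where(
        (u / pose.a) ** 2 + (v / pose.b) ** 2 <= 1.0, config.body_base_amp, 0.0
    )

    def blob(u0: float, v0: float, sigma: float, amp: float) -> np.ndarray:
        return amp * np.exp(-((u - u0) ** 2 + (v - v0) ** 2) / (2.0 * sigma ** 2))

    patch = np.maximum(
        patch, blob(-0.5 * pose.a, 0.0, pose.b / 2.0, config.abdomen_auto_amp)
    )
    if label is Label.GFP:
        patch = np.maximum(
            patch, blob(0.5 * pose.a, 0.0, pose.b / 2.0, config.thorax_gfp_amp)
        )
    else:
        for side in (-1.0, 1.0):
            patch = np.maximum(
                patch,
                blob(0.9 * pose.a, side * 0.6 * pose.b, pose.b / 4.0,
                     config.eye_auto_amp),
            )
    return patch, (x0, y0)


def _compose(canvas: np.ndarray, patch: np.ndarray, x0: int, y0: int) -> None:
    h, w = canvas.shape
    ph, pw = patch.shape
    sy, sx = max(0, -y0), max(0, -x0)
    ey, ex = min(ph, h - y0), min(pw, w - x0)
    if ey <= sy or ex <= sx:
        return
    view = canvas[y0 + sy:y0 + ey, x0 + sx:x0 + ex]
    np.maximum(view, patch[sy:ey, sx:ex], out=view)


def _compose_min(canvas: np.ndarray, patch: np.ndarray, x0: int, y0: int) -> None:
    """Darken canvas to the patch values where the patch is lower."""
    h, w = canvas.shape
    ph, pw = patch.shape
    sy, sx = max(0, -y0), max(0, -x0)
    ey, ex = min(ph, h - y0), min(pw, w - x0)
    if ey <= sy or ex <= sx:
        return
    view = canvas[y0 + sy:y0 + ey, x0 + sx:x0 + ex]
    np.minimum(view, patch[sy:ey, sx:ex], out=view)


def make_scene(
    config: SceneConfig,
) -> tuple[ImageStack, ImageStack, list[TrajectoryRecord], dict[int, Label]]:
    """Generate (ir, fluo, trajectories, truth) for one scene.

    ``round(gfp_fraction * n_flies)`` flies, chosen at random under the
    seed, are labeled GFP. Overlapping flies compose by maximum intensity,
    so ROI contamination by close neighbors is exercised.
    """
    rng = np.random.default_rng(config.seed + 3)
    trajectories = random_walk_poses(config)
    gfp_ids = set(
        np.random.default_rng(config.seed + 1)
        .choice(config.n_flies, size=config.n_gfp, replace=False)
        .tolist()
    )
    truth = {
        fly_id: (Label.GFP if fly_id in gfp_ids else Label.NON_GFP)
        for fly_id in range(config.n_flies)
    }

    w, h = config.arena_width, config.arena_height
    dtype = np.dtype(config.dtype)
    max_val = float(np.iinfo(dtype).max)
    gradient = 1.0 + config.illum_gradient * (
        np.arange(w, dtype=float) / max(1, w - 1) - 0.5
    )

    patch_rng = np.random.default_rng(config.seed + 2)
    patches = [
        (
            patch_rng.uniform(0, w),  # x
            patch_rng.uniform(0, h),  # y
            patch_rng.uniform(3.0, 8.0),  # sigma
        )
        for _ in range(config.n_arena_patches)
    ]

    by_frame: dict[int, list[TrajectoryRecord]] = {}
    for rec in trajectories:
        by_frame.setdefault(rec.frame, []).append(rec)

    ir_frames = np.empty((config.n_frames, h, w), dtype=dtype)
    fluo_frames = np.empty_like(ir_frames)
    ir_bg = 0.85 * max_val
    ir_fly = 0.25 * max_val
    bg_patches = np.full((h, w), config.background, dtype=float)
    if patches:
        gx, gy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        for (pxx, pyy, sig) in patches:
            bg_patches = np.maximum(
                bg_patches,
                config.arena_patch_amp
                * np.exp(-((gx - pxx) ** 2 + (gy - pyy) ** 2) / (2 * sig**2)),
            )
    for frame in range(config.n_frames):
        fluo = bg_patches.copy()
        ir = np.full((h, w), ir_bg, dtype=float)
        for rec in by_frame[frame]:
            patch, (x0, y0) = render_fly(rec, truth[rec.fly_id], config)
            _compose(fluo, patch, x0, y0)
            # IR: dark silhouette in the same local window, genotype-independent
            n = patch.shape[0]
            lx, ly = np.meshgrid(
                np.arange(x0, x0 + n, dtype=float), np.arange(y0, y0 + n, dtype=float)
            )
            c, s = math.cos(rec.theta), math.sin(rec.theta)
            du = (lx - rec.x) * c + (ly - rec.y) * s
            dv = -(lx - rec.x) * s + (ly - rec.y) * c
            sil = np.where(
                (du / rec.a) ** 2 + (dv / rec.b) ** 2 <= 1.0, ir_fly, ir_bg
            )
            _compose_min(ir, sil, x0, y0)
        fluo *= gradient[None, :]
        if config.noise_sd > 0:
            fluo += rng.normal(0.0, config.noise_sd, size=fluo.shape)
            ir += rng.normal(0.0, config.noise_sd, size=ir.shape)
        fluo_frames[frame] = np.clip(fluo, 0, max_val).astype(dtype)
        ir_frames[frame] = np.clip(ir, 0, max_val).astype(dtype)

    ir_stack = ImageStack(ir_frames, Channel.IR)
    fluo_stack = ImageStack(fluo_frames, Channel.FLUOR)
    return ir_stack, fluo_stack, trajectories, truth


# ---------------------------------------------------------------------------
# on-disk scene layout (shared by the CLI and the tests)

def save_scene(
    out_dir: str | Path,
    config: SceneConfig,
    ir: ImageStack,
    fluo: ImageStack,
    trajectories: list[TrajectoryRecord],
    truth: dict[int, Label],
) -> None:
    """Write a scene as ir.tiff, fluo.tiff, trajectories.csv, truth.csv,
    config.json in ``out_dir`` (created if missing)."""
    from .io_data import write_image_stack, write_trajectories, write_truth

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image_stack(ir, out / "ir.tiff")
    write_image_stack(fluo, out / "fluo.tiff")
    write_trajectories(trajectories, out / "trajectories.csv")
    write_truth(truth, out / "truth.csv")
    config.to_json(out / "config.json")


def load_scene(
    scene_dir: str | Path,
) -> tuple[ImageStack, list[TrajectoryRecord], dict[int, Label] | None]:
    """Read back (fluo, trajectories, truth) from a scene directory; truth
    is None when no truth.csv is present."""
    from .io_data import read_image_stack, read_trajectories, read_truth

    scene = Path(scene_dir)
    fluo = read_image_stack(scene / "fluo.tiff", Channel.FLUOR)
    trajectories = read_trajectories(scene / "trajectories.csv")
    truth_path = scene / "truth.csv"
    truth = read_truth(truth_path) if truth_path.exists() else None
    return fluo, trajectories, truth
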