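"""Synthetic two-class calcium-imaging studies.

The generator emulates 1-Hz Fluo-4 recordings of cultured astrocytes: bright
somas on a dark background, each with a fluorescence time course

    F_k(t) = F0 + sum_events A_e * exp(-(t - t_e) / tau),   t >= t_e

(instant rise, exponential decay) with event times drawn frame-wise from a
Poisson process.  The disease class models the acute response to patient
IgG: after a treatment-onset frame the event rate and amplitude are scaled
by configurable multipliers.  A pixel of cell k is its radial photometric
profile times F_k(t), plus Poisson shot noise and Gaussian read noise,
rounded and clipped to the 16-bit range.  Ground truth is the half-peak disc
of every soma, written as a label image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._util import U16_MAX, round_half_up
from .types import LabelImage, VideoStack

#: Gaussian profiles are truncated at this multiple of the half-peak radius
_HALO_FACTOR = 1.9


@dataclass
class SceneConfig:
    """Parameters of one simulated recording.

    Defaults describe a 5-minute 1-Hz recording on a 512×512 EMCCD sensor:
    30 somas of half-peak radius 8-14 px spaced at least 46 px apart (about
    1.6 soma diameters — a healthy sparse culture, and far enough that the
    smallest soma's region outgrows the 500-px elimination criterion before
    its halo meets a neighbour's), baseline ~6000 counts, transients of
    ~4000 counts decaying with an 8-frame time constant, and a treatment
    onset at frame 100 (a 100-s baseline period).  Disease recordings
    double the event rate and scale amplitudes by 1.5 after onset.
    """

    frame_shape: tuple[int, int] = (512, 512)
    n_frames: int = 300
    n_cells: int = 30
    radius_range: tuple[float, float] = (8.0, 14.0)
    min_center_distance: float = 46.0
    baseline: float = 6000.0
    amplitude: float = 4000.0
    event_rate: float = 0.03
    decay_tau: float = 8.0
    onset_frame: int = 100
    rate_mult: float = 2.0
    amp_mult: float = 1.5
    read_noise_sd: float = 50.0
    shot_noise: bool = True
    profile: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.event_rate <= 0 or self.decay_tau <= 0:
            raise ValueError("event rate and decay constant must be positive")
        if self.profile not in ("gaussian", "disc"):
            raise ValueError("profile must be 'gaussian' or 'disc'")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        H, W = self.frame_shape
        margin = self._margin(max(self.radius_range))
        if 2 * margin >= min(H, W):
            raise ValueError("cells do not fit in the frame")
        peak = self.baseline + 8 * self.amplitude * max(self.amp_mult, 1.0)
        if peak > U16_MAX:
            raise ValueError("baseline + stacked transients would saturate 16 bits")

    def _margin(self, radius: float) -> float:
        return (_HALO_FACTOR if self.profile == "gaussian" else 1.0) * radius + 1.0


@dataclass
class SimulatedVideo:
    stack: VideoStack
    truth: LabelImage
    class_label: int
    timecourses: np.ndarray  # K x T noiseless per-cell traces
    video_id: str = "video_000"


@dataclass
class SyntheticStudy:
    videos: list[SimulatedVideo] = field(default_factory=list)
    config: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0

    @property
    def class_labels(self) -> list[int]:
        return [v.class_label for v in self.videos]


def _place_cells(cfg: SceneConfig, rng: np.random.Generator):
    """Random non-overlapping centers with bounded rejection sampling."""
    H, W = cfg.frame_shape
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    lo, hi = cfg.radius_range
    for _ in range(20000):
        r = rng.uniform(lo, hi)
        m = cfg._margin(r)
        cy = rng.uniform(m, H - 1 - m)
        cx = rng.uniform(m, W - 1 - m)
        if all(
            math.hypot(cy - y0, cx - x0) >= cfg.min_center_distance
            for y0, x0 in centers
        ):
            centers.append((cy, cx))
            radii.append(r)
            if len(centers) == cfg.n_cells:
                break
    else:
        raise RuntimeError(
            f"could not place {cfg.n_cells} cells with min distance "
            f"{cfg.min_center_distance} after bounded retries"
        )
    return centers, radii


def _profile_patch(cfg: SceneConfig, cy: float, cx: float, r: float):
    """Photometric profile of one soma on its bounding box.

    Gaussian: exp(-rho^2 ln2 / r^2) (half-peak exactly at rho = r), zero past
    ``_HALO_FACTOR * r``; disc: 1 inside rho <= r.  Returns (slice, profile,
    ground-truth mask).
    """
    ext = cfg._margin(r)
    y0, y1 = int(math.floor(cy - ext)), int(math.ceil(cy + ext)) + 1
    x0, x1 = int(math.floor(cx - ext)), int(math.ceil(cx + ext)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
    gt = rho2 <= r * r
    if cfg.profile == "disc":
        prof = gt.astype(np.float64)
    else:
        prof = np.exp(-rho2 * (math.log(2.0) / (r * r)))
        prof[rho2 > (_HALO_FACTOR * r) ** 2] = 0.0
    return (slice(y0, y1), slice(x0, x1)), prof, gt


def _event_counts(cfg: SceneConfig, class_label: int, rng: np.random.Generator):
    rate = np.full(cfg.n_frames, cfg.event_rate)
    if class_label == 1:
        rate[cfg.onset_frame :] *= cfg.rate_mult
    return rng.poisson(rate)


def _timecourse(cfg: SceneConfig, class_label: int, counts: np.ndarray) -> np.ndarray:
    amp = np.full(cfg.n_frames, cfg.amplitude)
    if class_label == 1:
        amp[cfg.onset_frame :] *= cfg.amp_mult
    decay = math.exp(-1.0 / cfg.decay_tau)
    resp = np.empty(cfg.n_frames)
    acc = 0.0
    for t in range(cfg.n_frames):
        acc = acc * decay + counts[t] * amp[t]
        resp[t] = acc
    return cfg.baseline + resp


def simulate_video(
    config: SceneConfig,
    class_label: int = 0,
    events: list[list[int]] | None = None,
    video_id: str = "video_000",
) -> SimulatedVideo:
    """One recording: stack + ground-truth labels + noiseless cell traces.

    ``events`` optionally forces the event frames of each cell (a list per
    cell), bypassing the Poisson draw — handy for closed-form checks.
    """
    if class_label not in (0, 1):
        raise ValueError("class label must be 0 (control) or 1 (disease)")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    centers, radii = _place_cells(cfg, rng)

    T = cfg.n_frames
    courses = np.empty((cfg.n_cells, T))
    for k in range(cfg.n_cells):
        if events is not None:
            counts = np.bincount(np.asarray(events[k], dtype=int), minlength=T)[:T]
        else:
            counts = _event_counts(cfg, class_label, rng)
        courses[k] = _timecourse(cfg, class_label, counts)

    H, W = cfg.frame_shape
    clean = np.zeros((T, H, W), dtype=np.float32)
    truth = np.zeros((H, W), dtype=np.int32)
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        sl, prof, gt = _profile_patch(cfg, cy, cx, r)
        clean[:, sl[0], sl[1]] += (
            prof[None, :, :] * courses[k - 1][:, None, None]
        ).astype(np.float32)
        truth[sl][gt] = k

    # noise frame-by-frame to bound peak memory on full-sensor stacks
    data = np.empty((T, H, W), dtype=np.uint16)
    for t in range(T):
        frame = (
            rng.poisson(clean[t]).astype(np.float64)
            if cfg.shot_noise
            else clean[t].astype(np.float64)
        )
        if cfg.read_noise_sd > 0:
            frame += rng.normal(0.0, cfg.read_noise_sd, size=frame.shape)
        data[t] = np.clip(round_half_up(frame), 0, U16_MAX).astype(np.uint16)

    return SimulatedVideo(
        stack=VideoStack(data),
        truth=LabelImage(truth),
        class_label=class_label,
        timecourses=courses,
        video_id=video_id,
    )


def iter_study_videos(
    n_disease: int = 21,
    n_control: int = 12,
    config: SceneConfig | None = None,
    seed: int = 0,
):
    """Yield study recordings one at a time (labels: 1 disease, 0 control).

    Full-sensor stacks are large; iterating lets callers process each video
    and release it before the next one is simulated.
    """
    if n_disease < 1 or n_control < 1:
        raise ValueError("need at least one video per class")
    base = config or SceneConfig()
    labels = [1] * n_disease + [0] * n_control
    seeds = np.random.SeedSequence(seed).spawn(len(labels))
    for i, (label, seq) in enumerate(zip(labels, seeds)):
        cfg = SceneConfig(**{**asdict(base), "seed": int(seq.generate_state(1)[0] % 2**31)})
        yield simulate_video(cfg, class_label=label, video_id=f"video_{i:03d}")


def simulate_study(
    n_disease: int = 21,
    n_control: int = 12,
    config: SceneConfig | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Materialise a whole study in memory (use on small scenes)."""
    videos = list(iter_study_videos(n_disease, n_control, config, seed))
    return SyntheticStudy(videos=videos, config=config or SceneConfig(), seed=seed)


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write a study to disk in the pipeline's input layout."""
    from . import io as _io  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = {}
    for v in study.videos:
        _io.write_stack(v.stack, out / f"{v.video_id}.tif")
        _io.write_label_image(v.truth, out / f"truth_{v.video_id}.tif")
        np.savetxt(
            out / f"trace_{v.video_id}.csv",
            v.timecourses,
            delimiter=",",
            fmt="%.6f",
        )
        labels[v.video_id] = v.class_label
    (out / "labels.json").write_text(json.dumps(labels, indent=2, sort_keys=True) + "\n")
    cfg = asdict(study.config)
    cfg["study_seed"] = study.seed
    (out / "scene_config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
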