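"""Synthetic single-person action videos and low-level test fixtures.

Renders an articulated stick figure (head, torso, two arms with elbows, two
legs with knees) performing one of six actions — boxing, clapping, waving,
walking, jogging, running — on a uniform grey background with additive
Gaussian noise, emulating downsampled single-person action footage at
200 x 142 pixels.  The three locomotion classes translate the figure at
increasing gait speed with increasing leg-swing frequency; the three
arm-action classes keep the legs still and move only the upper limbs.
Jogging and running are deliberately close (speed 2 vs 4 px/frame, swing
0.15 vs 0.25 cycles/frame) so the classes are distinguishable but
confusable, as they are in real footage.

Everything is a pure function of the spec's seed: the same spec renders a
bit-identical stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon

__all__ = [
    "ACTIONS",
    "LOWER_ACTIONS",
    "UPPER_ACTIONS",
    "ActionSpec",
    "VideoStack",
    "default_spec",
    "render_action",
    "make_dataset",
    "make_bar_image",
    "make_translation_pair",
    "save_video",
    "load_video",
    "save_video_frames",
    "load_video_frames",
]

LOWER_ACTIONS = ("walking", "jogging", "running")
UPPER_ACTIONS = ("boxing", "clapping", "waving")
ACTIONS = UPPER_ACTIONS + LOWER_ACTIONS

#: per-action kinematic defaults: (gait_speed px/frame, swing frequency
#: cycles/frame, limb amplitude rad)
_ACTION_DEFAULTS = {
    "walking": (1.0, 0.09, 0.35),
    "jogging": (2.0, 0.15, 0.45),
    "running": (4.0, 0.25, 0.60),
    "boxing": (0.0, 0.12, 0.9),
    "clapping": (0.0, 0.10, 0.7),
    "waving": (0.0, 0.12, 0.8),
}

DEFAULT_SHAPE = (142, 200)


@dataclass(frozen=True)
class ActionSpec:
    action: str
    n_frames: int = 40
    frame_shape: tuple = DEFAULT_SHAPE
    limb_amplitude: float = 0.5  # radians
    limb_frequency: float = 0.1  # cycles/frame
    gait_speed: float = 0.0  # pixels/frame
    noise_sigma: float = 0.02
    clutter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action in LOWER_ACTIONS and self.gait_speed <= 0:
            raise ValueError("locomotion actions need gait_speed > 0")
        if self.action in UPPER_ACTIONS and self.gait_speed != 0:
            raise ValueError("arm actions must have gait_speed == 0")


@dataclass
class VideoStack:
    frames: np.ndarray  # (T, H, W) grayscale in [0, 1]
    label: str
    subject_id: int = 0
    fps: float = 25.0


def default_spec(action: str, seed: int = 0, n_frames: int = 40, **overrides) -> ActionSpec:
    """Spec with the per-action kinematic defaults filled in."""
    speed, freq, amp = _ACTION_DEFAULTS[action]
    kwargs = dict(
        action=action,
        n_frames=n_frames,
        gait_speed=speed,
        limb_frequency=freq,
        limb_amplitude=amp,
        seed=seed,
    )
    kwargs.update(overrides)
    return ActionSpec(**kwargs)


# ---------------------------------------------------------------------------
# rendering primitives

def _thick_line(canvas: np.ndarray, p0, p1, width: float, value: float = 1.0) -> None:
    """Draw a segment as a filled rectangle of the given width."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    norm = np.hypot(*d)
    if norm < 1e-9:
        rr, cc = disk((p0[0], p0[1]), max(width / 2, 1.0), shape=canvas.shape)
        canvas[rr, cc] = np.maximum(canvas[rr, cc], value)
        return
    perp = np.array([-d[1], d[0]]) / norm * (width / 2.0)
    corners = np.array([p0 + perp, p1 + perp, p1 - perp, p0 - perp])
    rr, cc = polygon(corners[:, 0], corners[:, 1], shape=canvas.shape)
    canvas[rr, cc] = np.maximum(canvas[rr, cc], value)


class _Skeleton:
    """Joint geometry for one subject; lengths in pixels.

    Proportions follow a ~60% frame-height figure; subject-specific style
    multipliers perturb segment lengths (style variation across subjects).
    """

    def __init__(self, frame_h: int, style_rng: np.random.Generator | None = None):
        h = 0.6 * frame_h
        u = lambda: 1.0 if style_rng is None else style_rng.uniform(0.92, 1.08)
        self.scale = h / 85.0 * u()
        s = self.scale
        self.head_r = 5.0 * s * u()
        self.neck_y = 13.0 * s
        self.shoulder_y = 18.0 * s
        self.hip_y = 44.0 * s
        self.thigh = 20.0 * s * u()
        self.shin = 20.0 * s * u()
        self.upper_arm = 13.0 * s * u()
        self.forearm = 13.0 * s * u()
        self.torso_w = 3.0 * s
        self.limb_w = 3.5 * s
        self.hip_half = 3.0 * s


def _arm_points(sk, shoulder, theta_u, theta_f):
    """theta measured from downward vertical, positive toward +x."""
    elbow = shoulder + np.array(
        [sk.upper_arm * np.cos(theta_u), sk.upper_arm * np.sin(theta_u)]
    )
    hand = elbow + np.array([sk.forearm * np.cos(theta_f), sk.forearm * np.sin(theta_f)])
    return elbow, hand


def _pose(spec: ActionSpec, sk: _Skeleton, t: int, phase: float):
    """Joint angles at frame t.  Angles from downward vertical (row axis)."""
    w = 2.0 * np.pi * spec.limb_frequency
    s = np.sin(w * t + phase)
    c = np.sin(w * t + phase + np.pi)  # opposite phase
    A = spec.limb_amplitude
    pose = {}
    if spec.action in LOWER_ACTIONS:
        pose["leg_l"] = A * s
        pose["leg_r"] = A * c
        # knees bend on the back-swing
        pose["knee_l"] = A * s - 0.3 * A * max(0.0, -s)
        pose["knee_r"] = A * c - 0.3 * A * max(0.0, -c)
        if spec.action == "walking":
            pose["arm_l"], pose["arm_r"] = 0.25 * A * c, 0.25 * A * s
            pose["fore_l"], pose["fore_r"] = pose["arm_l"], pose["arm_r"]
        else:
            # jogging/running: arms bent at the elbow, swinging
            pose["arm_l"], pose["arm_r"] = 0.5 * A * c, 0.5 * A * s
            pose["fore_l"] = pose["arm_l"] + 1.4  # ~80 deg elbow flexion
            pose["fore_r"] = pose["arm_r"] + 1.4
    else:
        pose["leg_l"] = pose["leg_r"] = 0.0
        pose["knee_l"] = pose["knee_r"] = 0.0
        if spec.action == "boxing":
            # alternating forward punches at shoulder height
            ext_l = 0.5 * (1 + np.sin(w * t + phase))
            ext_r = 0.5 * (1 + np.sin(w * t + phase + np.pi))
            pose["arm_l"] = np.pi / 2 - 0.3 * (1 - ext_l)
            pose["fore_l"] = np.pi / 2 + 0.9 * (1 - ext_l)
            pose["arm_r"] = np.pi / 2 - 0.3 * (1 - ext_r)
            pose["fore_r"] = np.pi / 2 + 0.9 * (1 - ext_r)
        elif spec.action == "clapping":
            # both hands meet periodically at upper-chest height: elbows
            # out, forearms swinging between open and crossed
            open_ = 0.5 * (1 + np.sin(w * t + phase))
            pose["arm_l"] = 1.3 + 0.1 * open_
            pose["fore_l"] = -0.8 + 1.4 * open_
            pose["arm_r"] = 1.3 + 0.1 * open_
            pose["fore_r"] = -0.8 + 1.4 * open_
        else:  # waving: right arm above the head, oscillating forearm
            pose["arm_l"] = 0.15
            pose["fore_l"] = 0.15
            pose["arm_r"] = np.pi - 0.4
            pose["fore_r"] = np.pi - 0.4 + A * np.sin(w * t + phase)
    return pose


def _render_frame(spec: ActionSpec, sk: _Skeleton, t: int, x_center: float,
                  phase: float, background: np.ndarray,
                  clutter_img: np.ndarray | None,
                  noise_rng: np.random.Generator) -> np.ndarray:
    H, W = spec.frame_shape
    canvas = np.zeros((H, W))
    y_top = (H - (sk.hip_y + sk.thigh + sk.shin)) / 2.0
    # slight vertical bounce for locomotion
    if spec.action in LOWER_ACTIONS:
        y_top += 0.06 * sk.scale * spec.gait_speed * np.sin(
            4.0 * np.pi * spec.limb_frequency * t + phase)
    head_c = np.array([y_top + sk.head_r, x_center])
    neck = np.array([y_top + sk.neck_y, x_center])
    shoulder = np.array([y_top + sk.shoulder_y, x_center])
    hip = np.array([y_top + sk.hip_y, x_center])
    pose = _pose(spec, sk, t, phase)

    rr, cc = disk(tuple(head_c), sk.head_r, shape=canvas.shape)
    canvas[rr, cc] = 1.0
    _thick_line(canvas, neck, hip, sk.torso_w)

    def leg(side, th_thigh, th_knee):
        hx = hip + np.array([0.0, side * sk.hip_half])
        knee = hx + np.array([sk.thigh * np.cos(th_thigh), sk.thigh * np.sin(th_thigh)])
        foot = knee + np.array([sk.shin * np.cos(th_knee), sk.shin * np.sin(th_knee)])
        _thick_line(canvas, hx, knee, sk.limb_w)
        _thick_line(canvas, knee, foot, sk.limb_w)

    def arm(side, th_u, th_f):
        sx = shoulder + np.array([0.0, side * sk.hip_half])
        elbow, hand = _arm_points(sk, sx, th_u, th_f)
        _thick_line(canvas, sx, elbow, 0.85 * sk.limb_w)
        _thick_line(canvas, elbow, hand, 0.85 * sk.limb_w)

    leg(-1, pose["leg_l"], pose["knee_l"])
    leg(+1, pose["leg_r"], pose["knee_r"])
    arm(-1, -pose["arm_l"] if spec.action == "clapping" else pose["arm_l"],
        -pose["fore_l"] if spec.action == "clapping" else pose["fore_l"])
    arm(+1, pose["arm_r"], pose["fore_r"])

    canvas = np.clip(gaussian_filter(canvas, 0.8), 0.0, 1.0)
    frame = 0.5 + background * (canvas < 0.05) - 0.4 * canvas
    if clutter_img is not None:
        frame = frame + clutter_img * (canvas < 0.05)
    frame = frame + noise_rng.normal(0.0, spec.noise_sigma, size=frame.shape)
    return np.clip(frame, 0.0, 1.0)


def render_action(spec: ActionSpec, subject_id: int = 0) -> VideoStack:
    """Render one action video; bit-identical for identical spec + seed."""
    rng = np.random.default_rng(spec.seed)
    style_rng = np.random.default_rng(rng.integers(2**31))
    noise_rng = np.random.default_rng(rng.integers(2**31))
    H, W = spec.frame_shape
    sk = _Skeleton(H, style_rng)
    phase = style_rng.uniform(0.0, 2.0 * np.pi)
    margin = 0.22 * W
    if spec.gait_speed > 0:
        x0 = margin * 0.7 + style_rng.uniform(0.0, 8.0)
    else:
        x0 = W / 2.0 + style_rng.uniform(-10.0, 10.0)
    # static low-contrast scene texture anchors the background for the
    # flow estimator, as real outdoor/indoor footage does
    def _texture(sigma, contrast):
        t = gaussian_filter(style_rng.standard_normal((H, W)), sigma)
        return contrast * t / max(t.std(), 1e-9)

    background = _texture(16.0, 0.05) + _texture(5.0, 0.07) + _texture(1.2, 0.12)
    clutter_img = None
    if spec.clutter:
        clutter_img = 0.12 * gaussian_filter(
            style_rng.standard_normal((H, W)), 4.0)
    frames = np.empty((spec.n_frames, H, W))
    span = W - 2.0 * margin * 0.6
    for t in range(spec.n_frames):
        x = x0 + spec.gait_speed * t
        # wrap around so long clips re-enter from the left
        x = margin * 0.6 + ((x - margin * 0.6) % span)
        frames[t] = _render_frame(spec, sk, t, x, phase, background, clutter_img, noise_rng)
    return VideoStack(frames=frames, label=spec.action, subject_id=subject_id)


def make_dataset(
    n_subjects: int,
    actions=ACTIONS,
    frames_per_video: int = 40,
    seed: int = 0,
    noise_sigma: float = 0.02,
) -> list:
    """One video per (subject, action); subject style varies via the seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence(seed)
    videos = []
    for subj, subj_seq in enumerate(root.spawn(n_subjects)):
        for act_i, action in enumerate(actions):
            vid_seed = int(subj_seq.spawn(len(actions))[act_i].generate_state(1)[0] % (2**31))
            spec = default_spec(action, seed=vid_seed, n_frames=frames_per_video,
                                noise_sigma=noise_sigma)
            videos.append(render_action(spec, subject_id=subj))
    return videos


# ---------------------------------------------------------------------------
# low-level fixtures

def make_bar_image(
    orientation: float,
    length: float = 16.0,
    width: float = 3.0,
    shape=(32, 32),
    noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """A single anti-aliased bar at the given angle through the centre.

    ``orientation`` follows the Gabor convention: the angle of the bar's
    long axis, measured from the row axis (0 = vertical stroke in image
    terms, pi/2 = horizontal), in [0, pi).
    """
    canvas = np.zeros(shape)
    if length > 0:
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        # theta=0 -> vertical bar (varying row), consistent with the Gabor
        # kernels whose carrier runs along +x at theta=0
        dy = (length / 2.0) * np.cos(orientation)
        dx = (length / 2.0) * np.sin(orientation)
        _thick_line(canvas, (cy - dy, cx - dx), (cy + dy, cx + dx), width)
        canvas = gaussian_filter(canvas, 0.6)
    if noise > 0:
        canvas = canvas + np.random.default_rng(seed).normal(0.0, noise, size=shape)
    return canvas


def make_translation_pair(shift=(0, 2), shape=(64, 64), seed: int = 0):
    """Smooth random texture and its integer-shifted (wrapped) copy.

    ``shift = (dy, dx)`` is the ground-truth displacement of the second
    frame relative to the first: flow (u, v) = (dx, dy) everywhere.
    """
    dy, dx = int(shift[0]), int(shift[1])
    rng = np.random.default_rng(seed)
    tex = gaussian_filter(rng.standard_normal(shape), 3.0)
    tex = (tex - tex.min()) / max(tex.max() - tex.min(), 1e-12)
    shifted = np.roll(tex, (dy, dx), axis=(0, 1))
    return tex, shifted


# ---------------------------------------------------------------------------
# I/O

def save_video_frames(stack: VideoStack, directory) -> None:
    """Write a video as a directory of 8-bit grayscale PNG frames."""
    from pathlib import Path

    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(stack.frames):
        iio.imwrite(directory / f"frame_{t:04d}.png",
                    (np.clip(frame, 0, 1) * 255).astype(np.uint8))


def load_video_frames(directory, label: str = "", subject_id: int = 0) -> VideoStack:
    """Read an ordered PNG frame directory back into a [0, 1] stack."""
    from pathlib import Path

    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("frame_*.png"))
    if not paths:
        raise ValueError(f"no frames found in {directory}")
    frames = np.stack([iio.imread(p).astype(float) / 255.0 for p in paths])
    return VideoStack(frames=frames, label=label, subject_id=subject_id)


def save_video(stack: VideoStack, path) -> None:
    np.savez(
        path,
        frames=stack.frames,
        label=np.array(stack.label),
        subject_id=np.array(stack.subject_id),
        fps=np.array(stack.fps),
    )


def load_video(path) -> VideoStack:
    data = np.load(path)
    return VideoStack(
        frames=data["frames"],
        label=str(data["label"]),
        subject_id=int(data["subject_id"]),
        fps=float(data["fps"]),
    )
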