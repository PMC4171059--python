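"""End-to-end two-stream pipeline: training, per-frame inference, fusion.

Per frame step the system looks at four frames (t-2 .. t+1): optical flow is
taken for the pairs (t-1, t) and (t, t+1); the flow drives the fuzzy motion
memberships and supplies the magnitude prior that guides the form pathway
("motion-guided" element selection and descriptor weighting — the model's
cross-stream interaction).  The form pathway computes a person-centred,
orientation-summed Gabor response descriptor of frame t and correlates it
against the five prototypes of each class.  Per-frame features (6 form
scores + 4 memberships + 1 group confidence = 11 values) are fused either by
limb-group gating (restrict the candidate classes to the defuzzified
upper/lower group, then take the best form score) or by a trained ELM; a
video's final label is the majority vote over its frame labels.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import downscale_local_mean

from . import classifiers, form_pathway, fuzzy_motion, motion_flow, prototypes
from .classifiers import ELMModel, PrototypeSet
from .form_pathway import GaborDictionary
from .fuzzy_motion import LOWER_CLASSES, UPPER_CLASSES, MembershipState
from .motion_flow import FlowField, FlowParams
from .synthetic_videos import VideoStack

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FrameFeatures",
    "VideoPrediction",
    "ModelBundle",
    "extract_frame_features",
    "fuse_and_label",
    "classify_video",
    "train",
    "evaluate",
    "save_bundle",
    "load_bundle",
]


@dataclass
class PipelineConfig:
    """Every numeric default of the pipeline, YAML-serialisable."""

    seed: int = 0
    prior_floor: float = 0.05  # static-region weight in the flow modulation
    n_orientations: int = 8
    n_scales: int = 1
    base_size: int = 9
    n_elements: int = 30
    saturation: float = 6.0
    norm_window: int = 15
    perturb_radius: int = 3
    perturb_orient: int = 1
    crop_height: int = 112
    crop_width: int = 80
    descriptor_downsample: int = 2
    eta: float = 0.15
    memory_N: int = 25
    tau: float = 1.0 / 25.0
    flow_xi: float = 0.02
    flow_levels: int = 4
    flow_warps: int = 3
    flow_inner: int = 10
    elm_hidden: int = 120
    elm_node_type: str = "sigmoid"
    mode: str = "gated"  # or "elm"
    descriptor_mode: str = "summed"  # or "oriented"
    train_frame_stride: int = 1
    templates_per_class: int = 8

    def flow_params(self) -> FlowParams:
        return FlowParams(
            xi=self.flow_xi,
            pyramid_levels=self.flow_levels,
            warps_per_level=self.flow_warps,
            inner_iterations=self.flow_inner,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class FrameFeatures:
    """Fused per-frame evidence from both streams (11-vector)."""

    form_scores: np.ndarray  # (6,), aligned with class_names
    motion_memberships: np.ndarray  # (4,)
    group_confidence: float
    group: str
    class_names: tuple
    match_scores: np.ndarray | None = None  # per-class ABM template scores

    def vector(self) -> np.ndarray:
        return np.concatenate(
            [self.form_scores, self.motion_memberships, [self.group_confidence]]
        )


@dataclass
class VideoPrediction:
    frame_labels: list
    final_label: str
    vote_counts: dict
    features: list  # per-frame FrameFeatures trace


@dataclass
class ModelBundle:
    config: PipelineConfig
    gdict: GaborDictionary
    templates: dict  # class -> ActiveBasisTemplate
    prototype_bank: PrototypeSet
    elm: ELMModel | None
    class_names: tuple
    train_subjects: tuple = ()


# ---------------------------------------------------------------------------
# form descriptor

def _figure_center(frame: np.ndarray) -> tuple:
    """Centroid of intensity deviation from the median (the person)."""
    dev = np.abs(frame - np.median(frame))
    peak = dev.max()
    if peak <= 1e-9:
        return (frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0
    w = np.where(dev > 0.25 * peak, dev, 0.0)
    total = w.sum()
    if total <= 0:
        return (frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    return float((w * yy).sum() / total), float((w * xx).sum() / total)


def _centered_crop(frame: np.ndarray, center, ch: int, cw: int) -> np.ndarray:
    cy, cx = int(round(center[0])), int(round(center[1]))
    r0 = cy - ch // 2
    c0 = cx - cw // 2
    pad = max(0, -r0, -c0, r0 + ch - frame.shape[0], c0 + cw - frame.shape[1])
    if pad > 0:
        frame = np.pad(frame, pad, mode="edge")
        r0 += pad
        c0 += pad
    return frame[r0 : r0 + ch, c0 : c0 + cw]


def _response_stack(crop: np.ndarray, gdict: GaborDictionary, config: PipelineConfig):
    stack = form_pathway.convolve_bank(form_pathway._normalize_frame(crop), gdict)
    return form_pathway.sigmoid_whiten(stack, config.saturation, config.norm_window)


def _descriptor_from_stack(stack, crop_shape, prior_crop, gdict: GaborDictionary,
                           descriptor_mode: str = "summed",
                           prior_floor: float = 0.3):
    """Whitened-response form descriptor, modulated by the flow prior.

    ``summed`` collapses the orientation channels into one smooth sketch
    image (robust to small pose jitter); ``oriented`` keeps the channels,
    each pooled locally (simple -> complex cells).  A uniform prior only
    rescales the descriptor, to which the downstream NCC is invariant.
    """
    half = max(gdict.kernel_half_size)
    channels = []
    for s in range(stack.n_scales):
        for k in range(stack.n_orientations):
            channels.append(
                stack.responses[s][k][
                    half : half + crop_shape[0], half : half + crop_shape[1]
                ]
            )
    if descriptor_mode == "oriented":
        desc = np.stack([gaussian_filter(c, 2.0) for c in channels])
    else:
        # smoothed sketch image: local pooling adds tolerance to pose and
        # centring jitter before prototype correlation
        desc = gaussian_filter(np.sum(channels, axis=0), 1.5)[None]
    if prior_crop is not None:
        pmax = prior_crop.max()
        if pmax > 0:
            desc = desc * (prior_floor + (1 - prior_floor) * prior_crop / pmax)[None]
    return desc


def mirror_descriptor(desc: np.ndarray, n_orientations: int) -> np.ndarray:
    """Horizontal flip in descriptor space: mirror columns and remap the
    orientation channels theta -> pi - theta."""
    flipped = desc[:, :, ::-1]
    n_scales = desc.shape[0] // n_orientations
    out = np.empty_like(flipped)
    for s in range(n_scales):
        for k in range(n_orientations):
            out[s * n_orientations + (n_orientations - k) % n_orientations] = \
                flipped[s * n_orientations + k]
    return np.ascontiguousarray(out)


def compute_descriptor(frame, flow_prior, gdict, config: PipelineConfig,
                       return_stack: bool = False):
    """Person-centred form descriptor of one frame.

    The frame is cropped around the figure centroid, downsampled, passed
    through the Gabor bank + sigmoid whitening, orientation-summed and
    modulated by the flow-magnitude prior.  ``flow_prior`` is a full-frame
    per-pixel weight map or None.
    """
    center = _figure_center(frame)
    crop = _centered_crop(np.asarray(frame, float), center,
                          config.crop_height, config.crop_width)
    ds = config.descriptor_downsample
    crop_small = downscale_local_mean(crop, (ds, ds))
    prior_crop = None
    if flow_prior is not None:
        pc = _centered_crop(np.asarray(flow_prior, float), center,
                            config.crop_height, config.crop_width)
        prior_crop = gaussian_filter(downscale_local_mean(pc, (ds, ds)), 2.0)
    stack = _response_stack(crop_small, gdict, config)
    desc = _descriptor_from_stack(stack, crop_small.shape, prior_crop, gdict,
                                  config.descriptor_mode, config.prior_floor)
    if return_stack:
        return desc, stack, crop_small
    return desc


# ---------------------------------------------------------------------------
# per-frame features

def _features_from_flows(
    frame, flow_a: FlowField, flow_b: FlowField, bundle: ModelBundle,
    state: MembershipState,
):
    """Core per-frame step given the two cached flows around frame t."""
    config = bundle.config
    e_a = motion_flow.flow_energy(flow_a)
    e_b = motion_flow.flow_energy(flow_b)
    prior = 0.5 * (e_a + e_b)

    # fuzzy update from the incoming flow (t-1, t); cells anchored to the
    # person box so upper/lower keep their body meaning
    grid = fuzzy_motion.grid_from_frame(frame)
    energies = fuzzy_motion.divide_flow(flow_a, grid)
    if energies.sum() > 0:
        peak = np.unravel_index(np.argmax(e_a), e_a.shape)
        eta_inst = fuzzy_motion.frame_membership(energies, peak, grid)
        if eta_inst.max() > 0:
            # memory coefficient: scale so the winner moves by eta per frame
            eta_inst = eta_inst * state.eta / eta_inst.max()
        state = fuzzy_motion.update_membership(state, eta_inst)
    else:
        state = fuzzy_motion.update_membership(state, np.zeros(4))
    group, confidence = fuzzy_motion.defuzzify(state)

    desc, stack, _ = compute_descriptor(frame, prior, bundle.gdict, config,
                                        return_stack=True)
    scores = classifiers.prototype_score(bundle.prototype_bank, desc)
    form_scores = np.array([scores[c] for c in bundle.class_names])
    match_scores = np.array(
        [form_pathway.match_score(bundle.templates[c], stack) for c in bundle.class_names]
    ) if bundle.templates else None
    features = FrameFeatures(
        form_scores=form_scores,
        motion_memberships=state.mu.copy(),
        group_confidence=confidence,
        group=group,
        class_names=bundle.class_names,
        match_scores=match_scores,
    )
    return features, state


def extract_frame_features(frames, bundle: ModelBundle, state: MembershipState,
                           flow_params: FlowParams | None = None):
    """Features for frame t from the window (t-2, t-1, t, t+1).

    ``frames`` is a sequence of at least 2 frames whose second-to-last entry
    is frame t; flow is estimated for (t-1, t) and (t, t+1).  Shorter
    prefixes reuse the first available pair (logged).  Returns
    ``(FrameFeatures, new_state)``.
    """
    frames = [np.asarray(f, float) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    if len(frames) < 4:
        logger.info("fewer than 4 frames in window: reusing first pair")
    params = flow_params or bundle.config.flow_params()
    t = len(frames) - 2
    prev_idx = max(t - 1, 0)
    fwd_a, _ = motion_flow.estimate_flow(frames[prev_idx], frames[prev_idx + 1], params)
    fwd_b, _ = motion_flow.estimate_flow(frames[t], frames[t + 1], params)
    return _features_from_flows(frames[t], fwd_a, fwd_b, bundle, state)


def fuse_and_label(features: FrameFeatures, mode: str = "gated",
                   elm: ELMModel | None = None) -> str:
    """Frame label from fused features.

    ``gated``: restrict candidates to the defuzzified limb group (all
    classes when the group is unknown), then argmax of the form score.
    ``elm``: predict from the 11-vector with the trained ELM.
    """
    names = features.class_names
    if mode == "elm":
        if elm is None:
            raise ValueError("ELM mode requires a trained model")
        labels, _ = classifiers.elm_predict(elm, features.vector()[None, :])
        return str(labels[0])
    if mode != "gated":
        raise ValueError(f"unknown fusion mode {mode!r}")
    if features.group == "lower":
        candidates = [c for c in names if c in LOWER_CLASSES]
    elif features.group == "upper":
        candidates = [c for c in names if c in UPPER_CLASSES]
    else:
        candidates = list(names)
    idx = [names.index(c) for c in candidates]
    best = idx[int(np.argmax(features.form_scores[idx]))]
    return names[best]


def classify_video(video: VideoStack, bundle: ModelBundle,
                   mode: str | None = None) -> VideoPrediction:
    """Frame-wise classification + majority vote over the whole video."""
    frames = np.asarray(video.frames, float)
    if frames.shape[0] < 4:
        raise ValueError("video must have at least 4 frames")
    mode = mode or bundle.config.mode
    params = bundle.config.flow_params()
    T = frames.shape[0]
    flows = [motion_flow._estimate_oneway(*_norm_pair(frames[i], frames[i + 1]), params)
             for i in range(T - 1)]
    state = MembershipState(eta=bundle.config.eta, N=bundle.config.memory_N,
                            tau=bundle.config.tau)
    labels: list = []
    feats: list = []
    score_sums = np.zeros(len(bundle.class_names))
    for t in range(1, T):
        flow_a = flows[t - 1]
        flow_b = flows[min(t, T - 2)]
        f, state = _features_from_flows(frames[t], flow_a, flow_b, bundle, state)
        lab = fuse_and_label(f, mode=mode, elm=bundle.elm)
        if t == 1:  # boundary: frame 0 reuses the first computed step
            labels.append(lab)
            feats.append(f)
        labels.append(lab)
        feats.append(f)
        score_sums = score_sums + (f.form_scores if mode == "gated" else _elm_scores(f, bundle))
    final, votes = _majority_vote(labels, score_sums, bundle.class_names)
    return VideoPrediction(frame_labels=labels, final_label=final,
                           vote_counts=votes, features=feats)


def _majority_vote(labels, score_sums, class_names):
    votes: dict = {}
    for lab in labels:
        votes[lab] = votes.get(lab, 0) + 1
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0], votes
    tie_idx = [class_names.index(c) for c in tied]  # tie: larger summed score
    return tied[int(np.argmax(np.asarray(score_sums)[tie_idx]))], votes


def relabel_prediction(pred: VideoPrediction, bundle: ModelBundle,
                       mode: str) -> VideoPrediction:
    """Re-fuse a stored per-frame feature trace under another fusion mode.

    The feature trace is independent of the fusion mode, so switching
    between gated and ELM decisions does not require re-running the
    pathways.
    """
    labels = [fuse_and_label(f, mode=mode, elm=bundle.elm) for f in pred.features]
    score_sums = np.zeros(len(bundle.class_names))
    for f in pred.features:
        score_sums += f.form_scores if mode == "gated" else _elm_scores(f, bundle)
    final, votes = _majority_vote(labels, score_sums, bundle.class_names)
    return VideoPrediction(frame_labels=labels, final_label=final,
                           vote_counts=votes, features=pred.features)


def _elm_scores(f: FrameFeatures, bundle: ModelBundle) -> np.ndarray:
    _, s = classifiers.elm_predict(bundle.elm, f.vector()[None, :])
    out = np.zeros(len(bundle.class_names))
    for j, cls in enumerate(bundle.elm.classes):
        out[bundle.class_names.index(str(cls))] = s[0, j]
    return out


def _norm_pair(a, b):
    sd = 0.5 * (a.std() + b.std())
    if sd < 1e-12:
        sd = 1.0
    return (a - a.mean()) / sd, (b - b.mean()) / sd


# ---------------------------------------------------------------------------
# training

def train(train_videos, config: PipelineConfig) -> ModelBundle:
    """Train the full bundle on a subject-disjoint training set.

    Per class: an active-basis template learned with the class-average flow
    prior, and five prototypes extracted from the (mirror-augmented) form
    descriptors.  An ELM over the per-frame 11-vectors is always fitted so
    both fusion modes are available at prediction time.
    """
    train_videos = list(train_videos)
    if not train_videos:
        raise ValueError("empty training set")
    gdict = form_pathway.build_dictionary(
        config.n_orientations, config.n_scales, config.base_size
    )
    class_names = tuple(sorted({v.label for v in train_videos}))
    bundle = ModelBundle(
        config=config, gdict=gdict, templates={},
        prototype_bank=None, elm=None, class_names=class_names,
        train_subjects=tuple(sorted({v.subject_id for v in train_videos})),
    )
    params = config.flow_params()
    desc_by_class: dict = {c: [] for c in class_names}
    crops_by_class: dict = {c: [] for c in class_names}
    prior_by_class: dict = {c: [] for c in class_names}
    feature_rows: list = []
    feature_labels: list = []

    for video in train_videos:
        frames = np.asarray(video.frames, float)
        T = frames.shape[0]
        flows = [motion_flow._estimate_oneway(*_norm_pair(frames[i], frames[i + 1]), params)
                 for i in range(T - 1)]
        state = MembershipState(eta=config.eta, N=config.memory_N, tau=config.tau)
        for t in range(1, T):
            flow_a = flows[t - 1]
            flow_b = flows[min(t, T - 2)]
            e_a = motion_flow.flow_energy(flow_a)
            prior = 0.5 * (e_a + motion_flow.flow_energy(flow_b))
            # fuzzy trace for classifier features
            grid = fuzzy_motion.grid_from_frame(frames[t])
            energies = fuzzy_motion.divide_flow(flow_a, grid)
            if energies.sum() > 0:
                peak = np.unravel_index(np.argmax(e_a), e_a.shape)
                eta_inst = fuzzy_motion.frame_membership(energies, peak, grid)
                if eta_inst.max() > 0:
                    eta_inst = eta_inst * config.eta / eta_inst.max()
                state = fuzzy_motion.update_membership(state, eta_inst)
            else:
                state = fuzzy_motion.update_membership(state, np.zeros(4))
            if (t - 1) % config.train_frame_stride != 0:
                continue
            _, conf = fuzzy_motion.defuzzify(state)
            center = _figure_center(frames[t])
            crop = _centered_crop(frames[t], center, config.crop_height, config.crop_width)
            ds = config.descriptor_downsample
            crop_small = downscale_local_mean(crop, (ds, ds))
            pc = gaussian_filter(
                downscale_local_mean(
                    _centered_crop(prior, center, config.crop_height, config.crop_width),
                    (ds, ds)), 2.0)
            stack = _response_stack(crop_small, gdict, config)
            desc = _descriptor_from_stack(stack, crop_small.shape, pc, gdict,
                                          config.descriptor_mode,
                                          config.prior_floor)
            desc_by_class[video.label].append(desc)
            if config.descriptor_mode == "oriented":
                mirrored = mirror_descriptor(desc, config.n_orientations)
            else:
                mirrored = desc[:, :, ::-1].copy()
            desc_by_class[video.label].append(mirrored)
            crops_by_class[video.label].append(crop_small)
            prior_by_class[video.label].append(pc)
            feature_rows.append((video.label, desc, state.mu.copy(), conf))
            feature_labels.append(video.label)

    # per-class templates, motion-guided
    for cls in class_names:
        crops = crops_by_class[cls][: config.templates_per_class]
        prior = np.mean(prior_by_class[cls][: config.templates_per_class], axis=0)
        bundle.templates[cls] = form_pathway.ssa_train(
            crops, gdict, config.n_elements, flow_prior=prior,
            perturb_radius=config.perturb_radius,
            perturb_orient=config.perturb_orient,
            saturation=config.saturation, local_norm_window=config.norm_window,
        )

    bundle.prototype_bank = prototypes.build_prototype_bank(
        desc_by_class, k=5, seed=config.seed
    )

    # frame-level 11-vectors for the ELM (form scores need the final bank)
    X = []
    for label, desc, mu, conf in feature_rows:
        scores = classifiers.prototype_score(bundle.prototype_bank, desc)
        X.append(np.concatenate([[scores[c] for c in class_names], mu, [conf]]))
    bundle.elm = classifiers.elm_train(
        np.asarray(X), np.asarray(feature_labels), L=config.elm_hidden,
        node_type=config.elm_node_type, seed=config.seed,
    )
    return bundle


def evaluate(test_videos, bundle: ModelBundle, mode: str | None = None):
    """Confusion matrix (rows = predicted, columns = true) and accuracy."""
    test_videos = list(test_videos)
    overlap = {v.subject_id for v in test_videos} & set(bundle.train_subjects)
    if overlap:
        raise ValueError(f"train/test subject overlap: {sorted(overlap)}")
    names = bundle.class_names
    confusion = np.zeros((len(names), len(names)), dtype=int)
    correct = 0
    predictions = []
    for video in test_videos:
        pred = classify_video(video, bundle, mode=mode)
        predictions.append(pred)
        confusion[names.index(pred.final_label), names.index(video.label)] += 1
        correct += int(pred.final_label == video.label)
    accuracy = correct / max(len(test_videos), 1)
    return confusion, accuracy, predictions


# ---------------------------------------------------------------------------
# bundle serialization

def save_bundle(bundle: ModelBundle, path) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(bundle.config.to_dict(), indent=1))
        zf.writestr("classes.json", json.dumps(
            {"class_names": list(bundle.class_names),
             "train_subjects": list(bundle.train_subjects)}))
        for cls, tpl in bundle.templates.items():
            buf = io.BytesIO()
            form_pathway.save_template(tpl, buf)
            zf.writestr(f"template_{cls}.zip", buf.getvalue())
        for cls in bundle.class_names:
            buf = io.BytesIO()
            np.save(buf, bundle.prototype_bank.prototypes[cls])
            zf.writestr(f"prototypes_{cls}.npy", buf.getvalue())
        if bundle.elm is not None:
            buf = io.BytesIO()
            classifiers.save_elm(bundle.elm, buf)
            zf.writestr("elm.zip", buf.getvalue())


def load_bundle(path) -> ModelBundle:
    with zipfile.ZipFile(path) as zf:
        config = PipelineConfig.from_dict(json.loads(zf.read("config.json")))
        meta = json.loads(zf.read("classes.json"))
        class_names = tuple(meta["class_names"])
        templates = {
            cls: form_pathway.load_template(io.BytesIO(zf.read(f"template_{cls}.zip")))
            for cls in class_names
        }
        protos = {
            cls: np.load(io.BytesIO(zf.read(f"prototypes_{cls}.npy")))
            for cls in class_names
        }
        elm = None
        if "elm.zip" in zf.namelist():
            elm = classifiers.load_elm(io.BytesIO(zf.read("elm.zip")))
    gdict = form_pathway.build_dictionary(
        config.n_orientations, config.n_scales, config.base_size
    )
    return ModelBundle(
        config=config, gdict=gdict, templates=templates,
        prototype_bank=PrototypeSet(prototypes=protos, class_names=class_names),
        elm=elm, class_names=class_names,
        train_subjects=tuple(meta["train_subjects"]),
    )
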