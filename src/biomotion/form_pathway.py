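"""Ventral ("form") pathway: Gabor dictionaries and active-basis templates.

The form stream represents a frame as a sparse set of oriented Gabor wavelet
elements.  A deformable template (active basis) is learned from training
frames by the shared sketch algorithm (SSA): a greedy matching pursuit that,
at every step, selects the dictionary element whose locally-perturbed
response summed over all training images is maximal, then inhibits nearby
correlated candidates.  A learned template scores a new frame by summing
weighted, locally-maximised element responses minus per-element
log-normalisers of an exponential background model — a log-likelihood-ratio
of "object present" against a pooled background response distribution.

Coordinates are 0-based, row-major, origin top-left.  Response lattices are
the *full* (zero-padded) convolution lattice: shape = image + kernel - 1.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import fftconvolve

__all__ = [
    "GaborElement",
    "GaborDictionary",
    "ResponseStack",
    "ActiveBasisTemplate",
    "build_dictionary",
    "convolve_bank",
    "sigmoid_whiten",
    "local_max_response",
    "ssa_train",
    "match_score",
    "save_template",
    "load_template",
]

#: default saturation of the sigmoid transform
DEFAULT_SATURATION = 6.0
#: default local-whitening window (pixels, odd)
DEFAULT_NORM_WINDOW = 15
#: default element perturbation: +-pixels and +-orientation steps
DEFAULT_PERTURB_RADIUS = 3
DEFAULT_PERTURB_ORIENT = 1
#: guard for zero-energy whitening windows
_EPS = 1e-8


@dataclass(frozen=True)
class GaborElement:
    """One selected wavelet element: lattice position + orientation/scale."""

    row: int
    col: int
    orientation_index: int
    scale_index: int
    theta: float
    omega: float


@dataclass
class GaborDictionary:
    """Bank of zero-mean, unit-norm complex Gabor kernels.

    ``kernels[s][k]`` is the kernel at scale index ``s`` and orientation
    index ``k`` (theta = k*pi/n).  The real part is the even (cosine) phase,
    the imaginary part the odd (sine) phase; both are zero-mean and the
    complex kernel has unit L2 norm.
    """

    n_orientations: int
    n_scales: int
    kernels: list  # list (scales) of list (orientations) of complex 2-D arrays
    kernel_half_size: list  # per-scale half width in pixels
    omegas: list  # per-scale spatial frequency (cycles/pixel)

    @property
    def thetas(self) -> np.ndarray:
        n = self.n_orientations
        return np.arange(n) * np.pi / n

    def iter_kernels(self):
        for s in range(self.n_scales):
            for k in range(self.n_orientations):
                yield s, k, self.kernels[s][k]


@dataclass
class ResponseStack:
    """Per-(scale, orientation) response maps on the padded lattice.

    ``responses[s][k]`` holds transformed squared magnitudes after
    :func:`sigmoid_whiten` (or raw ``|c|**2`` straight after
    :func:`convolve_bank`); ``raw[s][k]`` keeps the complex responses
    ``c = <I, beta>``.
    """

    responses: list
    raw: list | None
    n_orientations: int
    n_scales: int
    height: int
    width: int
    saturation: float | None = None

    def as_array(self) -> np.ndarray:
        """Stack of shape (n_scales, n_orientations, H, W)."""
        return np.stack([np.stack(row) for row in self.responses])


@dataclass
class ActiveBasisTemplate:
    """A learned deformable sketch: elements + weights + log-normalisers."""

    elements: list = field(default_factory=list)
    weights: list = field(default_factory=list)  # delta_i
    lambdas: list = field(default_factory=list)  # lambda_i
    log_z: list = field(default_factory=list)  # log-normaliser per element
    n_orientations: int = 0
    n_scales: int = 0
    perturb_radius: int = DEFAULT_PERTURB_RADIUS
    perturb_orient: int = DEFAULT_PERTURB_ORIENT

    def __len__(self) -> int:
        return len(self.elements)


def _gabor_kernel(size: int, theta: float, omega: float) -> np.ndarray:
    """Complex Gabor kernel: Gaussian envelope x complex carrier.

    Envelope sigma is size/5 so the kernel decays to ~0 at the border; the
    carrier runs along the axis perpendicular to the stroke orientation, so
    the kernel responds maximally to a bar *at* angle ``theta``.
    """
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # rotate so the carrier runs normal to a stroke at angle theta, with
    # theta measured from the row axis in image coordinates (rows grow down)
    xr = x * np.cos(theta) - y * np.sin(theta)
    yr = x * np.sin(theta) + y * np.cos(theta)
    sigma = size / 5.0
    envelope = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2))
    carrier = np.exp(2j * np.pi * omega * xr)
    g = envelope * carrier
    # zero-mean each phase, then unit L2 norm of the complex kernel
    g = g - envelope * (g.sum() / max(envelope.sum(), _EPS))
    g = g.real - g.real.mean() + 1j * (g.imag - g.imag.mean())
    norm = np.sqrt((np.abs(g) ** 2).sum())
    return g / max(norm, _EPS)


def build_dictionary(
    n_orientations: int, n_scales: int, base_size: int = 17
) -> GaborDictionary:
    """Build a Gabor dictionary of ``n_orientations x n_scales`` kernels.

    Orientation k has ``theta = k*pi/n``, theta in [0, pi).  The kernel
    width doubles per scale starting from ``base_size`` (odd), with the
    carrier frequency set to ~2.5 cycles per envelope so all scales keep the
    same bandpass shape.
    """
    if n_orientations < 1 or n_scales < 1:
        raise ValueError("n_orientations and n_scales must be >= 1")
    if base_size % 2 == 0:
        raise ValueError("base_size must be odd")
    kernels: list = []
    halves: list = []
    omegas: list = []
    for s in range(n_scales):
        size = base_size * (2**s)
        if size % 2 == 0:
            size += 1
        omega = 2.5 / size  # ~2.5 cycles across the envelope
        row = [
            _gabor_kernel(size, k * np.pi / n_orientations, omega)
            for k in range(n_orientations)
        ]
        kernels.append(row)
        halves.append(size // 2)
        omegas.append(omega)
    return GaborDictionary(
        n_orientations=n_orientations,
        n_scales=n_scales,
        kernels=kernels,
        kernel_half_size=halves,
        omegas=omegas,
    )


def convolve_bank(image: np.ndarray, gdict: GaborDictionary) -> ResponseStack:
    """Full (zero-padded) convolution of ``image`` with every kernel.

    Returns a stack whose ``responses`` hold the raw squared magnitudes
    ``|c|**2`` and whose ``raw`` holds the complex responses; apply
    :func:`sigmoid_whiten` before template operations.  The response lattice
    differs per scale; all maps are embedded into the largest lattice
    (centre-aligned) so elements index a single coordinate frame.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size < 1:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    max_half = max(gdict.kernel_half_size)
    H = image.shape[0] + 2 * max_half
    W = image.shape[1] + 2 * max_half
    responses: list = []
    raws: list = []
    for s in range(gdict.n_scales):
        half = gdict.kernel_half_size[s]
        off = max_half - half
        resp_row = []
        raw_row = []
        for k in range(gdict.n_orientations):
            c = fftconvolve(image, gdict.kernels[s][k], mode="full")
            full = np.zeros((H, W), dtype=complex)
            full[off : off + c.shape[0], off : off + c.shape[1]] = c
            raw_row.append(full)
            resp_row.append(np.abs(full) ** 2)
        responses.append(resp_row)
        raws.append(raw_row)
    return ResponseStack(
        responses=responses,
        raw=raws,
        n_orientations=gdict.n_orientations,
        n_scales=gdict.n_scales,
        height=H,
        width=W,
    )


def sigmoid_whiten(
    stack: ResponseStack,
    saturation: float = DEFAULT_SATURATION,
    local_norm_window: int = DEFAULT_NORM_WINDOW,
) -> ResponseStack:
    """Locally whiten and sigmoid-saturate squared magnitudes.

    Each value becomes ``saturation * tanh(|c|^2 / s_bar)`` where ``s_bar``
    is the mean squared magnitude over all orientations (per scale) in a
    ``local_norm_window`` square around the pixel.  Output lies in
    [0, saturation] and is monotone in ``|c|`` at fixed local energy.
    """
    if saturation <= 0:
        raise ValueError("saturation must be positive")
    out: list = []
    for s in range(stack.n_scales):
        energy = np.mean([stack.responses[s][k] for k in range(stack.n_orientations)], axis=0)
        local = uniform_filter(energy, size=local_norm_window, mode="nearest")
        # relative floor: low-energy (padding/background) regions must not
        # be whitened up to saturation by a vanishing denominator
        local = np.maximum(local, max(0.05 * float(energy.mean()), _EPS))
        out.append(
            [
                saturation * np.tanh(stack.responses[s][k] / local)
                for k in range(stack.n_orientations)
            ]
        )
    return ResponseStack(
        responses=out,
        raw=stack.raw,
        n_orientations=stack.n_orientations,
        n_scales=stack.n_scales,
        height=stack.height,
        width=stack.width,
        saturation=saturation,
    )


def local_max_response(
    stack: ResponseStack,
    element: GaborElement,
    perturb_radius: int = DEFAULT_PERTURB_RADIUS,
    perturb_orient: int = DEFAULT_PERTURB_ORIENT,
):
    """Maximum response over the element's local perturbation window.

    The window spans +-``perturb_radius`` pixels in row/col and
    +-``perturb_orient`` orientation steps (wrapping, since theta is defined
    modulo pi).  Ties break to the smallest (row, col, orientation) in
    lexicographic order.  Returns ``(value, (row, col, orientation_index))``.
    """
    r, c = element.row, element.col
    if not (0 <= r < stack.height and 0 <= c < stack.width):
        raise ValueError("element lies outside the response lattice")
    r0, r1 = max(0, r - perturb_radius), min(stack.height, r + perturb_radius + 1)
    c0, c1 = max(0, c - perturb_radius), min(stack.width, c + perturb_radius + 1)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("perturbation window is entirely off-lattice")
    n = stack.n_orientations
    best = -np.inf
    best_pos = None
    for do in range(-perturb_orient, perturb_orient + 1):
        k = (element.orientation_index + do) % n
        window = stack.responses[element.scale_index][k][r0:r1, c0:c1]
        idx = np.unravel_index(np.argmax(window), window.shape)
        val = window[idx]
        cand = (r0 + idx[0], c0 + idx[1], k)
        if val > best + 1e-15 or (abs(val - best) <= 1e-15 and best_pos is not None and cand < best_pos):
            # strict improvement, or equal value at smaller lexicographic index
            if val > best + 1e-15:
                best, best_pos = val, cand
            elif cand < best_pos:
                best_pos = cand
    # argmax within a single window already returns the first (smallest) index
    return float(best), best_pos


def _pooled_background_hist(stacks: Sequence[ResponseStack], saturation: float, bins: int = 50):
    """Pooled histogram of transformed responses — the background measure."""
    vals = np.concatenate(
        [np.ravel(stack.responses[s][k]) for stack in stacks
         for s in range(stack.n_scales) for k in range(stack.n_orientations)]
    )
    hist, edges = np.histogram(vals, bins=bins, range=(0.0, saturation))
    centres = 0.5 * (edges[:-1] + edges[1:])
    q = hist.astype(float)
    q /= max(q.sum(), 1.0)
    return centres, q


def _fit_lambda(delta: float, centres: np.ndarray, q: np.ndarray):
    """Solve for lambda so the tilted background mean equals ``delta``.

    The exponential family p(r) = q(r) exp(lambda r) / Z(lambda) has mean
    monotone increasing in lambda; a bisection on lambda in [-50, 50]
    matches the empirical per-element mean response delta.  Returns
    ``(lambda, log Z(lambda))``.
    """
    nz = q > 0
    r, w = centres[nz], q[nz]

    def mean_at(lam: float) -> float:
        # shift exponent for stability
        e = lam * r
        e -= e.max()
        p = w * np.exp(e)
        return float((p * r).sum() / p.sum())

    lo, hi = -50.0, 50.0
    target = float(np.clip(delta, mean_at(lo) + 1e-9, mean_at(hi) - 1e-9))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    e = lam * r
    m = e.max()
    log_z = float(m + np.log((w * np.exp(e - m)).sum()))
    return lam, log_z


def ssa_train(
    images: Sequence[np.ndarray],
    gdict: GaborDictionary,
    n_elements: int,
    flow_prior: np.ndarray | None = None,
    perturb_radius: int = DEFAULT_PERTURB_RADIUS,
    perturb_orient: int = DEFAULT_PERTURB_ORIENT,
    saturation: float = DEFAULT_SATURATION,
    local_norm_window: int = DEFAULT_NORM_WINDOW,
) -> ActiveBasisTemplate:
    """Learn an active-basis template by the shared sketch algorithm.

    Greedy matching pursuit: at each step the candidate (row, col,
    orientation, scale) maximising the sum over training images of the
    locally-maximised whitened response is selected; candidates closer than
    the kernel half-size with |orientation difference| <= 1 step are then
    inhibited.  When ``flow_prior`` (a per-pixel weight map, frame shape) is
    given, candidate scores are multiplied by the max-normalised prior at
    the candidate location — motion-guided element selection.

    Per-element weight ``delta_i`` is the mean transformed response across
    images; ``lambda_i`` and the log-normaliser come from tilting the pooled
    background response histogram until its mean matches ``delta_i``.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one training image")
    shape0 = np.asarray(images[0]).shape
    if any(np.asarray(im).shape != shape0 for im in images):
        raise ValueError("all training images must share one shape")
    if n_elements < 0:
        raise ValueError("n_elements must be >= 0")

    stacks = [
        sigmoid_whiten(convolve_bank(_normalize_frame(im), gdict), saturation, local_norm_window)
        for im in images
    ]
    template = ActiveBasisTemplate(
        n_orientations=gdict.n_orientations,
        n_scales=gdict.n_scales,
        perturb_radius=perturb_radius,
        perturb_orient=perturb_orient,
    )
    if n_elements == 0:
        return template

    H, W = stacks[0].height, stacks[0].width
    n, m = gdict.n_orientations, gdict.n_scales

    # summed-over-images local-max score per candidate (fixed during greedy)
    score = np.zeros((m, n, H, W))
    # candidates are scored at their nominal position/orientation: scoring
    # through the perturbation window would let every candidate inherit a
    # nearby peak, so neither orientation nor the inhibition distance could
    # discriminate.  The perturbation window enters through delta (below)
    # and at match time, where it absorbs deformation.
    for stack in stacks:
        for s in range(m):
            for k in range(n):
                score[s, k] += stack.responses[s][k]

    if flow_prior is not None:
        prior = np.asarray(flow_prior, dtype=float)
        if prior.shape != tuple(shape0):
            raise ValueError("flow_prior must match the image shape")
        pmax = prior.max()
        prior = prior / pmax if pmax > 0 else np.ones_like(prior)
        pad_r = (H - shape0[0]) // 2
        pad_c = (W - shape0[1]) // 2
        full_prior = np.zeros((H, W))
        full_prior[pad_r : pad_r + shape0[0], pad_c : pad_c + shape0[1]] = prior
        score = score * full_prior[None, None]

    # candidates restricted to the interior of the image support: the
    # padded convolution sees a step edge along the frame border (the
    # normalised background is non-zero), which would otherwise out-score
    # genuine structure
    allowed = np.zeros((m, n, H, W), dtype=bool)
    pad_r = (H - shape0[0]) // 2
    pad_c = (W - shape0[1]) // 2
    for s in range(m):
        inset = gdict.kernel_half_size[s] // 2
        r0, r1 = pad_r + inset, pad_r + shape0[0] - inset
        c0, c1 = pad_c + inset, pad_c + shape0[1] - inset
        if r0 < r1 and c0 < c1:
            allowed[s, :, r0:r1, c0:c1] = True
        else:
            allowed[s, :, pad_r : pad_r + shape0[0], pad_c : pad_c + shape0[1]] = True
    centres, q = _pooled_background_hist(stacks, saturation)
    for _ in range(n_elements):
        masked = np.where(allowed, score, -np.inf)
        flat = np.argmax(masked)  # first (lexicographically smallest) argmax
        s, k, r, c = np.unravel_index(flat, masked.shape)
        if not np.isfinite(masked[s, k, r, c]) or masked[s, k, r, c] <= 0:
            break
        element = GaborElement(
            row=int(r),
            col=int(c),
            orientation_index=int(k),
            scale_index=int(s),
            theta=float(k * np.pi / n),
            omega=float(gdict.omegas[s]),
        )
        delta = float(
            np.mean([local_max_response(st, element, perturb_radius, perturb_orient)[0]
                     for st in stacks])
        )
        lam, log_z = _fit_lambda(delta, centres, q)
        template.elements.append(element)
        template.weights.append(delta)
        template.lambdas.append(lam)
        template.log_z.append(log_z)
        # inhibition: suppress nearby candidates with similar orientation
        rad = gdict.kernel_half_size[s]
        rr0, rr1 = max(0, r - rad), min(H, r + rad + 1)
        cc0, cc1 = max(0, c - rad), min(W, c + rad + 1)
        yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
        near = (yy - r) ** 2 + (xx - c) ** 2 < rad**2
        for d in (-1, 0, 1):
            allowed[s, (k + d) % n, rr0:rr1, cc0:cc1] &= ~near
    return template


def match_score(template: ActiveBasisTemplate, stack: ResponseStack) -> float:
    """Template log-likelihood-ratio score on a whitened response stack.

    ``score = sum_i [delta_i * local_max_response(i) - log_z_i]`` — additive
    over elements and deterministic.  The stack must come from the same
    dictionary geometry (same orientation/scale counts).
    """
    if len(template) == 0:
        return 0.0
    if (
        stack.n_orientations != template.n_orientations
        or stack.n_scales != template.n_scales
    ):
        raise ValueError("response stack does not match template dictionary")
    total = 0.0
    for el, delta, log_z in zip(template.elements, template.weights, template.log_z):
        val, _ = local_max_response(stack, el, template.perturb_radius, template.perturb_orient)
        total += delta * val - log_z
    return float(total)


def _normalize_frame(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance per frame (lighting robustness)."""
    image = np.asarray(image, dtype=float)
    sd = image.std()
    return (image - image.mean()) / (sd if sd > 1e-12 else 1.0)


# ---------------------------------------------------------------------------
# serialization: zip archive with a JSON metadata record + flat .npy arrays

def save_template(template: ActiveBasisTemplate, path) -> None:
    """Serialize a template to a zip archive (metadata JSON + flat arrays)."""
    meta = {
        "n_orientations": template.n_orientations,
        "n_scales": template.n_scales,
        "perturb_radius": template.perturb_radius,
        "perturb_orient": template.perturb_orient,
        "n_elements": len(template),
    }
    coords = np.array(
        [[e.row, e.col, e.orientation_index, e.scale_index] for e in template.elements],
        dtype=np.int64,
    ).reshape(-1, 4)
    thetas = np.array([e.theta for e in template.elements])
    omegas = np.array([e.omega for e in template.elements])
    arrays = {
        "coords": coords,
        "theta": thetas,
        "omega": omegas,
        "delta": np.array(template.weights, dtype=float),
        "lambda": np.array(template.lambdas, dtype=float),
        "log_z": np.array(template.log_z, dtype=float),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_template(path) -> ActiveBasisTemplate:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {
            name: np.load(io.BytesIO(zf.read(name + ".npy")))
            for name in ("coords", "theta", "omega", "delta", "lambda", "log_z")
        }
    template = ActiveBasisTemplate(
        n_orientations=meta["n_orientations"],
        n_scales=meta["n_scales"],
        perturb_radius=meta["perturb_radius"],
        perturb_orient=meta["perturb_orient"],
    )
    for i in range(meta["n_elements"]):
        r, c, k, s = (int(v) for v in arrays["coords"][i])
        template.elements.append(
            GaborElement(
                row=r, col=c, orientation_index=k, scale_index=s,
                theta=float(arrays["theta"][i]), omega=float(arrays["omega"][i]),
            )
        )
        template.weights.append(float(arrays["delta"][i]))
        template.lambdas.append(float(arrays["lambda"][i]))
        template.log_z.append(float(arrays["log_z"][i]))
    return template
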