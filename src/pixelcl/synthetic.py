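"""Synthetic retinal-phantom fixtures: masks, label noise, probability maps.

The phantom emulates the geometry of a fundus segmentation mask — a circular
field of view (FOV) filled with retina, an elliptical optic disc, a small
foveal disk and a connected branching vessel tree rooted at the disc — so the
full detection/refinement pipeline can run and be validated without any real
images.  It makes no attempt at photorealism: the companion grayscale render
is a flat intensity map per class (background outside the FOV at intensity 0).

Label noise is generated in the class-conditional direction: given a
column-stochastic transition matrix ``T[i][j] = P(observed=i | true=j)``,
each pixel's observed label is drawn independently from the column of its
true class.  Optional boundary jitter additionally scrambles labels within a
band around class boundaries, emulating the tendency of real annotation
errors to concentrate at ambiguous structure boundaries.

Probability maps are simulated from the TRUE mask (a model trained past the
noise — the regime confident learning assumes): softmax of sharpness-scaled
one-hot logits plus unit Gaussian perturbations, with an optional class
confusion applied before the softmax.  A flag conditions on the noisy mask
instead, to stress-test the failure mode where the model has memorized the
noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confidence import NoiseTransition
from .schema import LabelMask, ProbMap, RETINA_SCHEMA

#: flat grayscale intensity per retinal class for the companion render
_CLASS_INTENSITY = {"background": 0, "retina": 120, "fovea": 70, "vessel": 40,
                    "optic_disc": 210}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and randomness of the retinal phantom (fractions of image size)."""

    size: int = 256
    fov_radius_frac: float = 0.48
    disc_center_frac: tuple[float, float] = (0.42, 0.72)  # (row, col)
    disc_axes_frac: tuple[float, float] = (0.075, 0.06)   # (semi-row, semi-col)
    fovea_center_frac: tuple[float, float] = (0.52, 0.38)
    fovea_radius_frac: float = 0.045
    vessel_depth: int = 4
    vessel_roots: int = 4
    vessel_step_frac: float = 0.05
    vessel_steps_per_branch: int = 5
    vessel_width_frac: float = 0.009
    vessel_width_decay: float = 0.78
    seed: int = 42

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("phantom size must be at least 32 pixels")
        r = self.fov_radius_frac
        for (cy, cx), extent in (
            (self.disc_center_frac, max(self.disc_axes_frac)),
            (self.fovea_center_frac, self.fovea_radius_frac),
        ):
            if np.hypot(cy - 0.5, cx - 0.5) + extent >= r:
                raise ValueError("structure geometry extends outside the FOV")


@dataclass(frozen=True)
class NoiseSpec:
    """Class-conditional corruption: transition matrix, optional boundary jitter."""

    transition: NoiseTransition
    jitter_width: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_width < 0:
            raise ValueError("jitter width must be nonnegative")
        if np.isnan(self.transition.matrix).any():
            raise ValueError("generative transition matrix must be fully defined")


def _stamp_disk(grid: np.ndarray, row: float, col: float, radius: float,
                value: int, protect: np.ndarray | None = None) -> None:
    r0, r1 = int(max(0, row - radius - 1)), int(min(grid.shape[0], row + radius + 2))
    c0, c1 = int(max(0, col - radius - 1)), int(min(grid.shape[1], col + radius + 2))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    inside = (yy - row) ** 2 + (xx - col) ** 2 <= radius**2
    if protect is not None:
        inside = inside & ~protect[r0:r1, c0:c1]
    grid[r0:r1, c0:c1][inside] = value


def generate_phantom(params: PhantomParams) -> tuple[LabelMask, np.ndarray]:
    """Five-class retinal phantom mask plus a flat grayscale render.

    Deterministic for a given parameter set (the seed drives the vessel
    tree).  Vessels grow from the optic-disc center as a recursive binary
    tree of jittered straight runs, thinning with depth, clipped to the FOV
    and steered away from the fovea.
    """
    rng = np.random.default_rng(params.seed)
    n = params.size
    schema = RETINA_SCHEMA
    bg, retina, fovea, vessel, disc = (schema.id_of(c) for c in
                                       ("background", "retina", "fovea", "vessel",
                                        "optic_disc"))
    grid = np.full((n, n), bg, dtype=np.int64)
    center = (n - 1) / 2.0
    yy, xx = np.ogrid[:n, :n]
    fov = (yy - center) ** 2 + (xx - center) ** 2 <= (params.fov_radius_frac * n) ** 2
    grid[fov] = retina

    dr, dc = params.disc_center_frac
    ar, ac = params.disc_axes_frac
    in_disc = (((yy - dr * n) / (ar * n)) ** 2 + ((xx - dc * n) / (ac * n)) ** 2) <= 1
    grid[in_disc & fov] = disc

    fr, fc = params.fovea_center_frac
    frad = params.fovea_radius_frac * n
    fovea_zone = (yy - fr * n) ** 2 + (xx - fc * n) ** 2 <= frad**2
    grid[fovea_zone & fov] = fovea

    # vessel tree: recursive branching random walk from the disc center
    if params.vessel_depth > 0:
        outside = ~fov
        step = params.vessel_step_frac * n

        def grow(row: float, col: float, angle: float, depth: int, width: float) -> None:
            if depth <= 0:
                return
            for _ in range(params.vessel_steps_per_branch):
                angle += rng.normal(0.0, 0.35)
                # steer away from the fovea center
                to_fovea = np.arctan2(fr * n - row, fc * n - col)
                if np.hypot(row - fr * n, col - fc * n) < 3 * frad:
                    angle = to_fovea + np.pi + rng.normal(0.0, 0.3)
                nrow = row + step * np.sin(angle)
                ncol = col + step * np.cos(angle)
                for frac in np.linspace(0.0, 1.0, max(2, int(step) + 1)):
                    prow = row + frac * (nrow - row)
                    pcol = col + frac * (ncol - col)
                    if outside[min(n - 1, max(0, int(prow))), min(n - 1, max(0, int(pcol)))]:
                        return
                    _stamp_disk(grid, prow, pcol, max(width, 0.6), vessel,
                                protect=fovea_zone | outside)
                row, col = nrow, ncol
            child_width = width * params.vessel_width_decay
            spread = rng.uniform(0.35, 0.8)
            grow(row, col, angle + spread, depth - 1, child_width)
            grow(row, col, angle - spread, depth - 1, child_width)

        width0 = params.vessel_width_frac * n
        for k in range(params.vessel_roots):
            theta = 2 * np.pi * k / params.vessel_roots + rng.uniform(-0.3, 0.3)
            grow(dr * n, dc * n, theta, params.vessel_depth, width0)

    mask = LabelMask(grid, schema)
    lut = np.array([_CLASS_INTENSITY[name] for name in schema.names], dtype=np.uint8)
    return mask, lut[grid]


def vessel_fraction_of_fov(mask: LabelMask) -> float:
    """Fraction of the field of view (non-background) occupied by vessels."""
    schema = mask.schema
    in_fov = mask.grid != schema.background_id
    return float((mask.grid == schema.id_of("vessel")).sum() / in_fov.sum())


def inject_noise(mask: LabelMask, spec: NoiseSpec) -> LabelMask:
    """Corrupt a mask per a class-conditional transition matrix.

    Each pixel's observed label is drawn independently from column ``y*`` of
    ``T``; optional boundary jitter then reassigns pixels within
    ``jitter_width`` of a class boundary to the label of a random neighbor at
    most ``jitter_width`` away.  Deterministic per seed.
    """
    T = spec.transition.matrix
    m = mask.schema.m
    if T.shape != (m, m):
        raise ValueError(f"transition matrix is {T.shape}, schema has {m} classes")
    rng = np.random.default_rng(spec.seed)
    flat_true = mask.grid.ravel()
    u = rng.random(flat_true.size)
    cdf = np.cumsum(T, axis=0)  # (observed, true) -> column-wise cdf
    noisy = np.empty_like(flat_true)
    for j in range(m):
        sel = flat_true == j
        if sel.any():
            noisy[sel] = np.searchsorted(cdf[:, j], u[sel], side="right")
    noisy = np.minimum(noisy, m - 1).reshape(mask.shape)

    if spec.jitter_width > 0:
        w = spec.jitter_width
        diff = np.zeros(mask.shape, dtype=bool)
        diff[:-1, :] |= mask.grid[:-1, :] != mask.grid[1:, :]
        diff[1:, :] |= mask.grid[:-1, :] != mask.grid[1:, :]
        diff[:, :-1] |= mask.grid[:, :-1] != mask.grid[:, 1:]
        diff[:, 1:] |= mask.grid[:, :-1] != mask.grid[:, 1:]
        from scipy.ndimage import binary_dilation

        band = binary_dilation(diff, iterations=w)
        rows, cols = np.nonzero(band)
        offr = rng.integers(-w, w + 1, size=rows.size)
        offc = rng.integers(-w, w + 1, size=rows.size)
        src_r = np.clip(rows + offr, 0, mask.shape[0] - 1)
        src_c = np.clip(cols + offc, 0, mask.shape[1] - 1)
        noisy[rows, cols] = noisy[src_r, src_c]

    return LabelMask(noisy, mask.schema)


def simulate_probmap(
    truth: LabelMask,
    sharpness: float = 6.0,
    confusion: np.ndarray | None = None,
    seed: int = 0,
) -> ProbMap:
    """Calibrated synthetic class-probability map peaked on the true class.

    Per pixel the model's belief class is the true class, or a draw from
    ``confusion`` column ``y*`` when a column-stochastic confusion matrix is
    given.  Probabilities are ``softmax(sharpness * onehot + N(0, 1))``, so
    larger sharpness concentrates mass on the belief class (one-hot in the
    limit) and the Gaussian perturbation spreads per-pixel confidence.
    """
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    m = truth.schema.m
    rng = np.random.default_rng(seed)
    belief = truth.grid.ravel().copy()
    if confusion is not None:
        confusion = np.asarray(confusion, dtype=np.float64)
        if confusion.shape != (m, m):
            raise ValueError(f"confusion matrix is {confusion.shape}, expected ({m}, {m})")
        cdf = np.cumsum(confusion, axis=0)
        u = rng.random(belief.size)
        drawn = np.empty_like(belief)
        for j in range(m):
            sel = belief == j
            if sel.any():
                drawn[sel] = np.searchsorted(cdf[:, j], u[sel], side="right")
        belief = np.minimum(drawn, m - 1)
    logits = rng.normal(0.0, 1.0, size=(belief.size, m))
    logits[np.arange(belief.size), belief] += sharpness
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    return ProbMap(probs.reshape(truth.shape + (m,)), truth.schema)


def uniform_flip_transition(m: int, flip_rate: float) -> NoiseTransition:
    """Symmetric transition: keep with prob 1-flip_rate, else uniform over the
    other classes."""
    if not 0 <= flip_rate < 1:
        raise ValueError("flip rate must lie in [0, 1)")
    T = np.full((m, m), flip_rate / (m - 1))
    np.fill_diagonal(T, 1.0 - flip_rate)
    return NoiseTransition(T)


def default_fixture(
    seed: int = 42, size: int = 256, flip_rate: float = 0.05, sharpness: float = 6.0
) -> dict:
    """The package's standard desk-scale fixture.

    A seed-42 phantom with 5% class-conditional label flips and a calibrated
    probability map conditioned on the true mask.  Returns a dict with keys
    ``truth``, ``noisy``, ``probmap``, ``transition``, ``params``.
    """
    params = PhantomParams(size=size, seed=seed)
    truth, _ = generate_phantom(params)
    transition = uniform_flip_transition(truth.schema.m, flip_rate)
    noisy = inject_noise(truth, NoiseSpec(transition, seed=seed + 1))
    probmap = simulate_probmap(truth, sharpness=sharpness, seed=seed + 2)
    return {
        "truth": truth,
        "noisy": noisy,
        "probmap": probmap,
        "transition": transition,
        "params": params,
    }
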