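"""Synthetic 2-D brain phantoms with stage-dependent atrophy.

Each phantom is a concentric construction on a dark background: an
elliptical brain outline whose outer annulus is grey matter and whose
core is white matter, with dark voids carved out of the tissue —
ventricle-like interior blobs plus thin sulcus-like notches at the rim.
Dementia stage ``s`` in {0, 1, 2, 3} maps to a monotone atrophy
schedule: the void fraction grows and the overall brain area shrinks
with stage, mimicking progressive tissue loss.  Every phantom carries an
exact per-pixel label map, so tissue areas, GWR and shrinkage ground
truth are integer-exact.

What this emulates: the trimodal background/grey/white intensity
histogram, stage-monotone shrinkage, mild Gaussian pixel noise.  What it
does not: anatomy, MRI physics (bias fields, Rician noise, partial
volume), 3-D structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# label-map codes
BACKGROUND, GREY, WHITE, VOID = 0, 1, 2, 3

#: void fraction carved out of tissue, per stage 0..3
STAGE_VOID_FRACTION = (0.02, 0.08, 0.18, 0.30)
#: brain-outline scale per stage (overall area also shrinks with atrophy)
STAGE_BRAIN_SCALE = (1.00, 0.97, 0.94, 0.90)


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom slice."""

    size: int = 128
    background_level: int = 0
    grey_level: int = 100
    white_level: int = 200
    noise_sigma: float = 0.0
    void_fraction: float = 0.02
    grey_white_area_ratio: float = 1.5
    stage: int = 0
    seed: int = 0
    brain_scale: float = 1.0

    def __post_init__(self):
        if not self.background_level < self.grey_level < self.white_level:
            raise ValueError("need background < grey < white intensity levels")
        if not 0.0 <= self.void_fraction < 1.0:
            raise ValueError("void_fraction must lie in [0, 1)")
        if self.stage not in (0, 1, 2, 3):
            raise ValueError("stage must be 0..3")


@dataclass
class PhantomTruth:
    """Exact ground truth bookkeeping for a generated phantom."""

    label_map: np.ndarray = field(repr=False)
    grey_area: int = 0
    white_area: int = 0
    void_area: int = 0
    mask_area: int = 0
    gwr: float = 0.0
    shrinkage: float = 0.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    # brain outline: ellipse with mild random eccentricity
    a = 0.44 * n * spec.brain_scale * rng.uniform(0.97, 1.03)
    b = 0.37 * n * spec.brain_scale * rng.uniform(0.97, 1.03)
    brain = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    # white core scaled so grey/white areas hit the requested ratio
    s = 1.0 / np.sqrt(1.0 + spec.grey_white_area_ratio)
    white = ((xx - cx) / (a * s)) ** 2 + ((yy - cy) / (b * s)) ** 2 <= 1.0
    labels = np.full((n, n), BACKGROUND, dtype=np.uint8)
    labels[brain] = GREY
    labels[white] = WHITE
    _carve_voids(labels, spec, rng, brain, xx, yy, cx, cy, a, b)
    for tissue in (GREY, WHITE):
        if not (labels == tissue).any():
            raise ValueError(
                f"void_fraction {spec.void_fraction} erased tissue class {tissue}")
    levels = np.array([spec.background_level, spec.grey_level,
                       spec.white_level, spec.background_level], dtype=np.float64)
    image = levels[labels]
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
    grey_area = int((labels == GREY).sum())
    white_area = int((labels == WHITE).sum())
    void_area = int((labels == VOID).sum())
    mask_area = int(brain.sum())
    truth = PhantomTruth(
        label_map=labels, grey_area=grey_area, white_area=white_area,
        void_area=void_area, mask_area=mask_area,
        gwr=grey_area / white_area,
        shrinkage=(grey_area + white_area) / mask_area,
    )
    return image, truth


def _carve_voids(labels, spec, rng, brain, xx, yy, cx, cy, a, b):
    """Carve ventricle blobs and thin rim notches up to the void budget.

    ~85% of the budget goes to interior elliptical blobs, the rest to
    thin sulcus-like grooves near the rim.  All voids stay strictly
    inside the brain outline (a one-pixel tissue shell is preserved), so
    every void is a closed hole of the tissue region and mask recovery
    by hole filling is exact up to rasterisation.
    """
    n = labels.shape[0]
    tissue_area = int(brain.sum())
    budget = spec.void_fraction * tissue_area
    if budget < 1:
        return
    # safety region: voids confined to 93% of the outline radius
    interior = ((xx - cx) / (0.93 * a)) ** 2 + ((yy - cy) / (0.93 * b)) ** 2 <= 1.0
    blob_budget = 0.85 * budget
    carved = 0
    for _ in range(200):
        if carved >= blob_budget:
            break
        # blob centre biased toward the middle (ventricles)
        r = np.sqrt(rng.uniform(0.0, 0.55))
        theta = rng.uniform(0, 2 * np.pi)
        bcx = cx + r * a * np.cos(theta)
        bcy = cy + r * b * np.sin(theta)
        remaining = blob_budget - carved
        target = min(remaining, max(4.0, 0.25 * blob_budget)) * rng.uniform(0.6, 1.0)
        rad = max(1.0, np.sqrt(target / np.pi))
        ecc = rng.uniform(0.6, 1.6)
        blob = (((xx - bcx) / (rad * ecc)) ** 2
                + ((yy - bcy) / (rad / ecc)) ** 2) <= 1.0
        blob &= interior & (labels > BACKGROUND) & (labels != VOID)
        carved += int(blob.sum())
        labels[blob] = VOID
    # sulcus-like grooves: thin radial lines through the grey annulus
    notch_budget = budget - carved
    for _ in range(60):
        if notch_budget <= 0:
            break
        theta = rng.uniform(0, 2 * np.pi)
        depth = rng.uniform(0.06, 0.14)  # fraction of the radius
        t = np.linspace(0.9 - depth, 0.9, 60)
        px = np.clip(np.round(cx + t * a * np.cos(theta)).astype(int), 0, n - 1)
        py = np.clip(np.round(cy + t * b * np.sin(theta)).astype(int), 0, n - 1)
        notch = np.zeros_like(labels, dtype=bool)
        notch[py, px] = True
        notch &= interior & (labels > BACKGROUND) & (labels != VOID)
        notch_budget -= int(notch.sum())
        labels[notch] = VOID


def stage_spec(stage: int, seed: int, size: int = 128,
               noise_sigma: float = 0.0, jitter: float = 0.15) -> PhantomSpec:
    """Phantom spec for a dementia stage with per-sample jitter.

    The void fraction is the stage schedule value scaled by
    ``U(1 - jitter, 1 + jitter)``; the brain outline shrinks with stage.
    All randomness derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    vf = STAGE_VOID_FRACTION[stage] * rng.uniform(1 - jitter, 1 + jitter)
    scale = STAGE_BRAIN_SCALE[stage] * rng.uniform(0.99, 1.01)
    return PhantomSpec(size=size, noise_sigma=noise_sigma, void_fraction=vf,
                       stage=stage, seed=seed, brain_scale=scale)


def generate_dataset(
    n_per_stage: int,
    seed: int = 0,
    size: int = 128,
    noise_sigma: float = 0.0,
    imbalanced: bool = False,
) -> tuple[list[np.ndarray], np.ndarray, list[PhantomTruth]]:
    """A labelled phantom collection across the four stages.

    Balanced by default (``n_per_stage`` each).  The imbalanced mode
    mimics the 3200 : 2240 : 897 : 64 class proportions of the public
    4-class dementia MRI set, scaled so the largest class has
    ``n_per_stage`` images.  Individual phantoms get counter-derived
    seeds, so any one of them is reproducible in isolation.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    proportions = (3200, 2240, 897, 64)
    images, labels, truths = [], [], []
    for stage in range(4):
        if imbalanced:
            count = max(1, int(round(n_per_stage * proportions[stage] / 3200)))
        else:
            count = n_per_stage
        for i in range(count):
            sub = (seed * 7919 + stage * 104729 + i * 31) % (2**31)
            spec = stage_spec(stage, sub, size=size, noise_sigma=noise_sigma)
            img, truth = generate_phantom(spec)
            images.append(img)
            labels.append(stage)
            truths.append(truth)
    return images, np.asarray(labels), truths
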