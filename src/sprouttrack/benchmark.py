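"""Synthetic end-to-end tracking benchmark.

Twenty sprouting regions, six daily frames each, with scripted branching
events, boundary noise, intensity noise and per-frame camera jitter —
the package's stand-in for experimental validation data, which is not
publicly deposited.  Each region is rendered to grayscale, pushed through
the full pipeline (registration, segmentation, skeletonization, SVM
pruning, routing, Hungarian tracking) and the recovered branch
trajectories are scored against the generator's ground truth.
"""

from __future__ import annotations

import warnings

import numpy as np

from .branching import BranchingConfig
from .phantoms import (
    BranchSpec,
    GroundTruth,
    PhantomSpec,
    TimelapseSpec,
    default_post_positions,
    generate_timelapse,
    render_timelapse,
)
from .pipeline import analyze_image_sequence
from .segfilter import LinearSVMModel, default_classifier
from .skeletonize import SkelConfig
from .tracking import BranchHistory, trajectory_metrics

IMAGE_SIZE = (300, 400)
MONOLAYER_HEIGHT = 40
TUBE_RADIUS = 6.0
ELONGATION = 30.0           # px of growth per daily frame
N_FRAMES = 6
BOUNDARY_NOISE = 2.0        # px peak of smooth radius modulation
JITTER_SHIFT = 5.0          # px, uniform per frame
JITTER_ANGLE = 1.5          # degrees
JITTER_SCALE = 0.01
TIP_TOLERANCE = 15.0        # px for trajectory agreement


def benchmark_region(seed: int) -> tuple[PhantomSpec, TimelapseSpec]:
    """Specs for one randomized sprouting region (seeded)."""
    rng = np.random.default_rng(seed)
    n_sprouts = int(rng.integers(1, 3))
    base_xs = [float(rng.uniform(160, 240))] if n_sprouts == 1 else [
        float(rng.uniform(110, 150)), float(rng.uniform(250, 290))
    ]
    y0 = IMAGE_SIZE[0] - MONOLAYER_HEIGHT
    sprouts = []
    for x in base_xs:
        ang = rng.uniform(-0.2, 0.2)
        pts = [(x, float(y0))]
        for _ in range(4):
            ang += rng.uniform(-0.2, 0.2)
            pts.append((pts[-1][0] + 40 * np.sin(ang), pts[-1][1] - 40 * np.cos(ang)))
        sprouts.append(BranchSpec(points=pts, radius=TUBE_RADIUS))
    pspec = PhantomSpec(
        image_size=IMAGE_SIZE,
        monolayer_height=MONOLAYER_HEIGHT,
        sprouts=sprouts,
        boundary_noise_amplitude=BOUNDARY_NOISE,
        seed=seed,
    )
    events = []
    for i in range(n_sprouts):
        f = int(rng.integers(2, 5))
        # branch away from the neighbouring sprout, into open gel, as
        # sprouts do where there is space for a new branch to grow
        if n_sprouts == 1:
            sign = float(rng.choice([-1.0, 1.0]))
        else:
            sign = -1.0 if base_xs[i] < IMAGE_SIZE[1] / 2 else 1.0
        ang = float(sign * rng.uniform(30, 45))
        events.append((f, i + 1, ang))
    jitter = [(0.0, 0.0, 0.0, 1.0)] + [
        (
            float(rng.uniform(-JITTER_SHIFT, JITTER_SHIFT)),
            float(rng.uniform(-JITTER_SHIFT, JITTER_SHIFT)),
            float(rng.uniform(-JITTER_ANGLE, JITTER_ANGLE)),
            float(rng.uniform(1 - JITTER_SCALE, 1 + JITTER_SCALE)),
        )
        for _ in range(N_FRAMES - 1)
    ]
    tspec = TimelapseSpec(
        n_frames=N_FRAMES,
        elongation_per_frame=ELONGATION,
        branching_events=events,
        registration_jitter=jitter,
        seed=seed + 10_000,
    )
    return pspec, tspec


def truth_tip_trajectories(gt: GroundTruth) -> dict[int, dict[int, tuple[float, float]]]:
    """Ground-truth branch id -> {frame: tip (x, y)} in canonical coords."""
    tips: dict[int, dict[int, tuple[float, float]]] = {}
    for f, fr in enumerate(gt.frames):
        for bid, route in zip(fr.route_branch_ids, fr.routes):
            n = fr.graph.nodes[route[-1]]
            tips.setdefault(bid, {})[f] = (n.x, n.y)
    return tips


def run_region(
    seed: int, classifier: LinearSVMModel | None = None
) -> tuple[BranchHistory, GroundTruth, dict]:
    """Generate, render, track and score one region."""
    classifier = classifier or default_classifier()
    pspec, tspec = benchmark_region(seed)
    _, gt = generate_timelapse(pspec, tspec)
    images = render_timelapse(gt, default_post_positions(pspec.image_size), seed=seed + 20_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, history = analyze_image_sequence(
            images,
            classifier=classifier,
            skel_cfg=SkelConfig(),
            branch_cfg=BranchingConfig(),
            monolayer_band=80,
            # tubes here are ~12 px wide with bounded 2 px raggedness; a
            # 1 px erosion removes speckle without pinching young sprouts
            erosion_radius=1,
        )
    metrics = trajectory_metrics(history, truth_tip_trajectories(gt), tolerance=TIP_TOLERANCE)
    return history, gt, metrics


def run_benchmark(n_regions: int = 20, seed: int = 0) -> dict:
    """Aggregate branch-trajectory precision and recall over regions."""
    classifier = default_classifier()
    matched = detected = true = 0
    per_region = []
    for k in range(n_regions):
        _, _, m = run_region(seed * 1000 + k, classifier)
        matched += m["matched"]
        detected += m["n_detected"]
        true += m["n_true"]
        per_region.append(m)
    return {
        "precision": matched / detected if detected else 1.0,
        "recall": matched / true if true else 1.0,
        "matched": matched,
        "n_detected": detected,
        "n_true": true,
        "per_region": per_region,
    }
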