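"""End-to-end orchestration: images or masks in, branch histories out.

Thin glue over the stage modules, in the order the method prescribes:
segmentation (for rendered images: registration to a reference frame,
gel-region masking, Otsu + morphology), AFMM skeletonization, SVM pruning
of specious segments, base-node determination and route enumeration, and
Hungarian branch association across frames.
"""

from __future__ import annotations

import numpy as np

from .branching import BranchingConfig, determine_base_nodes, enumerate_branch_routes, group_sprouts
from .preprocess import detect_posts, fit_cell_gel_interface, register_to_reference, segment_vessels
from .segfilter import LinearSVMModel, default_classifier, prune_graph
from .skeletonize import SkelConfig, skeleton_graph
from .tracking import BranchHistory, TrackedFrame, track_sequence


def analyze_mask(
    mask: np.ndarray,
    skel_cfg: SkelConfig | None = None,
    branch_cfg: BranchingConfig | None = None,
    classifier: LinearSVMModel | None = None,
) -> TrackedFrame:
    """One binary vessel mask -> routes and sprouts.

    ``classifier=None`` skips SVM pruning (pass ``default_classifier()``
    to prune with the shipped model).
    """
    graph, _ = skeleton_graph(mask, skel_cfg or SkelConfig())
    if classifier is not None and graph.n_segments:
        graph = prune_graph(graph, classifier)
    if graph.n_nodes == 0:
        return TrackedFrame(graph, [], [])
    bases, _ = determine_base_nodes(graph, branch_cfg or BranchingConfig())
    routes = enumerate_branch_routes(graph, bases)
    return TrackedFrame(graph, routes, group_sprouts(routes))


def analyze_mask_sequence(
    masks: list[np.ndarray],
    skel_cfg: SkelConfig | None = None,
    branch_cfg: BranchingConfig | None = None,
    classifier: LinearSVMModel | None = None,
) -> tuple[list[TrackedFrame], BranchHistory]:
    """Registered mask sequence -> per-frame analyses + branch history."""
    frames = [analyze_mask(m, skel_cfg, branch_cfg, classifier) for m in masks]
    diag = float(np.hypot(*masks[0].shape)) if masks else None
    return frames, track_sequence(frames, image_diagonal=diag)


def register_and_segment(
    images: list[np.ndarray],
    reference_index: int = 0,
    monolayer_band: int = 100,
    min_object_area: int = 50,
    closing_radius: int = 2,
    erosion_radius: int = 2,
) -> list[np.ndarray]:
    """Rendered grayscale frames -> registered binary vessel masks.

    All frames are aligned to the chosen reference via the posts, the
    cell-gel interface is fit on the reference, and each aligned frame is
    segmented within that shared gel region.
    """
    ref = np.asarray(images[reference_index], dtype=float)
    posts = detect_posts(ref)
    gel = fit_cell_gel_interface(ref, monolayer_band=monolayer_band, posts=posts)
    masks = []
    for i, img in enumerate(images):
        if i == reference_index:
            aligned = ref
        else:
            _, aligned = register_to_reference(np.asarray(img, dtype=float), ref)
        masks.append(
            segment_vessels(aligned, gel, min_object_area=min_object_area,
                            closing_radius=closing_radius, erosion_radius=erosion_radius)
        )
    return masks


def analyze_image_sequence(
    images: list[np.ndarray],
    reference_index: int = 0,
    skel_cfg: SkelConfig | None = None,
    branch_cfg: BranchingConfig | None = None,
    classifier: LinearSVMModel | None = "default",
    **segment_kwargs,
) -> tuple[list[TrackedFrame], BranchHistory]:
    """Full pipeline on rendered time-lapse images."""
    if classifier == "default":
        classifier = default_classifier()
    masks = register_and_segment(images, reference_index, **segment_kwargs)
    return analyze_mask_sequence(masks, skel_cfg, branch_cfg, classifier)
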