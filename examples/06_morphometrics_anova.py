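"""Morphometric comparison of two growth-factor conditions.

Simulates sprouting regions under a fast-elongation and a slow-elongation
condition, summarizes branch lengths per region and frame, and runs a
one-way ANOVA across conditions with the conventional star symbols
(ns / * / ** / *** / ****).
"""

import numpy as np

from sprouttrack import (
    BranchSpec, PhantomSpec, TimelapseSpec, analyze_mask_sequence, compare_groups,
    generate_timelapse, summarize_morphometrics,
)
from sprouttrack.phenotype import mean_sem

histories, conditions = [], []
for cond, elong in (("fast", 32.0), ("slow", 18.0)):
    for k in range(3):
        pspec = PhantomSpec(
            image_size=(260, 220), monolayer_height=36,
            sprouts=[BranchSpec(points=[(110 + 4 * k, 224), (112, 180)], radius=6)],
            seed=10 * k,
        )
        masks, _ = generate_timelapse(pspec, TimelapseSpec(n_frames=5, elongation_per_frame=elong, seed=k))
        _, hist = analyze_mask_sequence([pspec.crop_to_gel(m) for m in masks])
        histories.append(hist)
        conditions.append(cond)

table = summarize_morphometrics(histories, conditions)
summary = mean_sem(table, "length_px", by=("condition",))
print(summary.round(1).to_string(index=False))
f, p, symbol = compare_groups(table, "length_px")
print(f"\none-way ANOVA on branch length: F = {f:.1f}, p = {p:.2e}  ({symbol})")
print("fast-condition regions grow ~75% faster, so their mean branch length is")
print("larger at every day and the difference is strongly significant.")
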