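"""Render pileup windows to RGB images and inspect the colour encoding.

Each 50 bp window becomes a 256x256 image: columns of stacked base pixels
(bar height = read depth), base identity in the dominant channel, and the
deletion signatures tinting the auxiliary channels.
"""

import numpy as np

import delcall as dc

# the colour algebra on its own
bits = dc.BaseFeatureBits(is_paired=1, is_discordant=1, mapq_high=1, is_split=0)
print("column of A over 10 discordant pairs:", dc.column_base_color("A", 10, 0))
print("per-base auxiliary value (10 + 1+1+1+0):", dc.base_aux_value(10, bits))
print("final pixel colour for that base:", dc.rendered_base_color("A", 10, 0, bits))
table = dc.feature_table()
print(f"encoding table: {len(table)} (base, bits) combinations, "
      f"{len({rgb for _, _, rgb in table})} distinct colours")

# rendered windows from a simulated deletion
scene = dc.simulate_scene(30_000, [dc.DeletionSpec("chr1", 14_000, 15_000)],
                          dc.LibraryModel(coverage=30), seed=2)
stats = dc.estimate_insert_stats(scene.reads)
inside = dc.render_window_fast(scene.reads, "chr1", 14_400, stats)
outside = dc.render_window_fast(scene.reads, "chr1", 10_000, stats)
nw = lambda img: int((img != 255).any(axis=2).sum())
print(f"\nwindow inside the deletion : {nw(inside):6d} non-white pixels")
print(f"window outside the deletion: {nw(outside):6d} non-white pixels")
print("lower bars inside the deletion = depressed read depth, the CNN's",
      "primary visual cue; discordant/split tints colour the flanks.")

# labels for training come from truth intervals
truth = [(d.start, d.end) for d in scene.deletions]
print("\nlabels:", {s: dc.label_window(s, s + 50, truth)
                    for s in (10_000, 13_980, 14_400)})
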