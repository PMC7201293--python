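"""Show consensus fusion deleting a false positive shared by a minority.

Ten near-perfect candidate segmentations are generated; four of them carry
an identical spurious blob far outside the tumor (the classic isolated
false positive an individual algorithm produces).  Because 4 of 10 is less
than half, both fusion methods remove the blob entirely while the
whole-tumor Dice against ground truth stays essentially perfect.
"""

from segfuse.experiments import fp_removal_experiment

results = fp_removal_experiment(seed=7)
for method, r in results.items():
    print(f"{method:6s}: blob voxels surviving fusion = {r.blob_voxels_in_fusion}, "
          f"whole-tumor dice = {r.wt_dice:.4f}")
print("\nzero surviving blob voxels means the shared false positive was "
      "voted out; dice near 1 means the tumor itself was preserved.")
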