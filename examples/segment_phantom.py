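"""Segment a synthetic glioma phantom with the default GMM pipeline.

Builds a BraTS-style phantom (edema shell bright on FLAIR, enhancing rim
bright on T1-CE, necrotic core bright on T2), runs the three-stage
clustering pipeline, and prints per-region Dice against the known truth.
"""

from aucseg import PhantomSpec, SegConfig, evaluate_case, generate_phantom, run_pipeline

case, truth, counts = generate_phantom(PhantomSpec(noise_sd=0.05, seed=3))
print(f"phantom voxels per truth code (1=NC, 2=edema, 4=ET): {counts}")

labels, masks = run_pipeline(case, SegConfig(method="gmm"))
for name in ("wt", "et", "tc", "nc"):
    print(f"predicted {name.upper()}: {int(getattr(masks, name).sum())} voxels")

for m in evaluate_case(labels, truth):
    print(f"{m.region}: Dice {m.dice:.4f}  FPVF {m.fpvf:.4f}  FNVF {m.fnvf:.4f}")
# Dice near 1 for WT/ET means the brightest-subclass rule recovered the
# edema and rim; TC is slightly lower because cc-mode necrosis excludes a
# one-voxel shell where the dilated rim overlapped the cavity.
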