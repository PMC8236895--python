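"""Walk the semi-automatic hyper-parameter grid on one phantom.

The grid holds 96 configurations: n_cluster1 in 3..10, n_cluster2 in
3..5, and four necrosis options (cc, or t2 with n_cluster3 in 3..5), in
the order the parameters are meant to be tuned. Here we sweep only
n_cluster1 to show its monotone effect: more subclasses carve the
FLAIR-bright compartment finer, so the selected whole-tumor candidate
shrinks (false negatives grow).
"""

from aucseg import PhantomSpec, SegConfig, enumerate_tuning_grid, generate_phantom
from aucseg.io_model import normalize_case
from aucseg.pipeline import wt_candidate_mask

grid = enumerate_tuning_grid()
print(f"grid size: {len(grid)} configurations")
first = grid[0]
print(
    f"first in tuning order: n_cluster1={first.n_cluster1} "
    f"n_cluster2={first.n_cluster2} nc_seg_mode={first.nc_seg_mode}"
)

case, truth, counts = generate_phantom(PhantomSpec(noise_sd=0.02, seed=0))
norm = normalize_case(case)
true_wt = counts[1] + counts[2] + counts[4]
print(f"\ntrue WT voxels: {true_wt}")
for k in (3, 4, 5, 6, 8, 10):
    size = int(wt_candidate_mask(norm, SegConfig(n_cluster1=k)).sum())
    print(f"n_cluster1={k:2d}: WT candidate subclass {size} voxels")
# The candidate covers the edema shell (interior compartments are
# recovered later by hole filling); its size never grows with k.
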