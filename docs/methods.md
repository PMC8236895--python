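# Methods

## Model and assumptions

The pipeline is a staged, intensity-driven decomposition of a high-grade
glioma into compartments, under three radiological assumptions:

1. edema (plus tumor tissue) is the hyperintense tail of the T2-FLAIR
   intensity distribution inside the brain;
2. enhancing tumor is the hyperintense tail of T1-CE *within* the whole
   tumor;
3. necrosis is topologically interior to the enhancing rim, and — where
   that fails — is the hyperintense tail of T2 within the whole tumor.

Each stage therefore reduces to 1-D clustering of one modality's
normalized intensities on a restricted support, followed by a fixed
selection rule (highest-centroid subclass) and morphology. No spatial
regularization is used inside the clustering itself; spatial coherence
comes entirely from the morphological steps (largest component, hole
filling, one-step dilation).

The clustering support is the *brain mask*: voxels nonzero in every
present modality, matching the skull-stripped zero-background convention
of BraTS-style data. Including background voxels would waste a subclass
on the zero spike, so they are excluded everywhere.

## Normalization

Each modality is min–max normalized to [0, 1] over in-brain voxels,
independently per volume; out-of-brain voxels are set to 0. Min–max (as
opposed to z-scoring) preserves the ordering assumptions above and keeps
the clustering feature in a fixed range. A constant in-brain volume
degenerates to all zeros with a warning rather than an error, so batch
runs survive corrupt cases. Clustering operates on normalized values;
normalization is idempotent and invariant to positive affine rescaling
of the input, so raw scanner units never matter.

## Clustering backends

All four backends cluster the same 1-D samples and return centroids
sorted ascending, with hard labels; all are deterministic given
(samples, hyper-parameters, seed).

- **K-means** — hand-written full-batch Lloyd iterations with k-means++
  seeding, 10 restarts (best final objective kept), recording the
  objective after every assignment step. The restart count follows the
  common library default; a single Lloyd run can stall in a local
  minimum even at small n. Empty clusters are re-seeded at the farthest
  point from its assigned center. Stopping rule: relative objective
  decrease below `tol`.
- **Mini-batch K-means** — delegated to scikit-learn
  (`MiniBatchKMeans`, k-means++ init, one init), exposed behind the same
  result contract.
- **FCM** — alternating membership/centroid updates with fuzzifier
  m = 2 by default; a sample coincident with a centroid takes membership
  one there. Stopping rule: maximum absolute membership change below
  `tol`; non-convergence returns `converged=False` with a warning. The
  per-iteration maximum row-sum deviation is recorded so the Σ_j u_ij = 1
  constraint is auditable after the fact.
- **GMM** — univariate EM initialized from the full-batch k-means fit
  (weights from cluster fractions, means from centroids, variances from
  within-cluster variance). Responsibilities are computed in log space
  with logsumexp. Component variances are clamped to a floor (1e−6 in
  normalized units) with a warning on collapse. Stopping rule: relative
  log-likelihood change below `tol`. The full log-likelihood trace is
  kept; exact EM is monotone, so the trace is non-decreasing up to a
  ~1e−7 relative round-off/clamping allowance.

Defaults shared by all backends: `tol` 1e−4, `max_iter` 300, seed 0 —
community-standard values for intensity clustering at this scale.
If a stage requests more subclasses than there are distinct sample
values, k is reduced with a warning (this also lets noise-free synthetic
volumes, which have only a handful of distinct values, run through the
default configuration).

**Subclass selection.** The selected subclass is the one with the
highest centroid; ties break toward the subclass with more members, then
the lower index. The member-count tie-break is the robust choice when
near-duplicate centroids appear (e.g. an over-provisioned k splitting
one compartment).

## Morphology

Foreground analysis uses 26-connectivity and hole filling uses
6-connectivity background — the standard complementary pairing (a
foreground shell that is closed under 26-connectivity must not leak
background through its corners). Components are numbered in raster-scan
order, so the largest-component tie-break (lowest id) selects the
component with the smallest minimum linear voxel index. Dilation uses a
3×3×3 all-true structuring element by default and truncates the kernel
at volume borders (no padding value is invented). The implementation
delegates to `scipy.ndimage`; conformance is defined by agreement with a
brute-force BFS flood-fill oracle, which the test suite checks across
all three connectivity levels.

## Pipeline composition

- WT keeps the single largest component when no ROI is given (a single
  dominant tumor is the HGG norm; multifocal disease is handled by
  per-tumor ROIs, each cropped, segmented independently, and pasted back
  at its offset — a failing ROI is isolated with a warning so other
  tumors still segment).
- `cc`-mode necrosis dilates ET exactly once before hole filling — the
  minimal closure for near-closed rims — and *excludes* dilated-only
  voxels from NC, so NC never claims tissue the dilation invented. The
  geometric cost is a one-voxel (Chebyshev) shell of the true cavity;
  for a cavity of radius r this removes roughly a 3/r fraction of its
  volume, which is why cc-mode NC Dice plateaus around 0.7 on cavities
  of radius ~8 voxels even when the rim is segmented perfectly. `t2`
  mode has no such cap and is preferred whenever a T2 volume exists and
  the cavity is T2-bright.
- `t2`-mode TC selects the highest-mean-intensity T2 subclass inside WT
  (the same universal selection rule as the other stages), hole-fills
  it, and unites it with ET.
- Label assembly writes edema (2), then NC (1), then ET (4), giving the
  precedence ET > NC > edema where overlapping ROIs disagree.
- Stages never share information except through masks; each stage refits
  its clustering from scratch on its own support.

## Synthetic phantoms

The generator emulates exactly the features the pipeline exploits, and
no more: an ellipsoidal brain (semi-axes 27/25/23 voxels in a 64³
volume) of uniform base intensity, and spherical tumors with an edema
shell (radius 16 by default), an enhancing rim (outer 11, inner 8) and a
necrotic interior. Compartment means per modality are fixed so the three
intensity-ordering premises hold exactly at zero noise; i.i.d. Gaussian
noise (default sd 0.02, i.e. ~4σ separation between the closest
compartments) is added inside the brain and clipped to [0, 1.2]. The
necrotic compartment fills the rim interior (core radius defaults to the
rim's inner radius): the label set has no "non-enhancing tumor" class,
so a gap between core and rim would be unassignable and would break the
geometric correspondence between the rim's cavity and the NC truth.

Two controlled failure modes are built in: a cone-shaped rim gap
(aperture in degrees about the +x axis) that defeats `cc`-mode necrosis,
and an optional linear multiplicative bias field along z that lowers
tumor/brain contrast.

Cohorts draw per-case geometry uniformly from stated ranges (edema
radius 13–17, rim outer fraction 0.62–0.72 of it, rim thickness 2.5–3.5,
center jitter ±3 voxels) with per-case seeds derived from a master seed,
so point ranges reproduce identical geometry with independent noise.

What phantoms do *not* model: partial-volume effects, texture,
non-spherical shapes, multi-class intensity overlap beyond additive
noise, and registration error. Passing phantom tests therefore
demonstrates that the staging logic, selection rules, morphology and
bookkeeping are correct under the method's own assumptions — not that
the pipeline reaches any particular accuracy on clinical data, where
those assumptions degrade.

A known behavior worth stating: with the default five WT subclasses over
the phantom's four compartments, the mixture occasionally splits the
edema compartment instead of the (much larger) brain compartment; the
brightest subclass is then only part of the shell and the case fails
(Dice < 0.5), at a rate of about 1 in 20 at noise sd 0.05. This is the
same failed-detection mode the method exhibits on real data and is why
cohort statistics here use medians and success counts rather than plain
means.

## Evaluation conventions

FPVF and FNVF normalize by the reference volume (so FNVF ≤ 1). Dice of
two empty masks is defined as 1 with a warning (perfect agreement on
absence); an empty reference with a nonempty prediction gives Dice 0 and
undefined (NaN) volume fractions, which cohort summaries count as
exclusions. Cohort tables report Dice mean ± sd both over successful
cases (Dice ≥ 0.5) and over all cases, since either convention is
defensible; the success count "s/N" disambiguates.

## Problem sizes

Default phantoms are 64³ (~57k in-brain voxels), which keeps a full
four-backend comparison and a 20-case cohort run in the tens of seconds
while leaving every compartment tens of voxels across — large enough
that discretization does not dominate the Dice values being asserted.
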