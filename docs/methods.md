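# Methods

## Forward models and units

The package predicts two paramagnetic observables from a lanthanide's
anisotropic susceptibility tensor Δχ, a traceless symmetric rank-2 tensor
stored as five Cartesian components c5 = (χxx, χyy, χxy, χxz, χyz) with
χzz = −(χxx + χyy), in units of 1e-32 m³. The pseudocontact shift of a
nucleus at spherical coordinates (R, θ, φ) in the tensor principal frame
centred on the ion is

    δ = 1/(12πR³) [Δχ_ax (3cos²θ−1) + (3/2) Δχ_rh sin²θ cos2φ]   (ppm, R in Å)

and the field-induced residual dipolar coupling of a C–H vector at
orientation (θ, φ) is

    D = −(h B₀² γC γH)/(240 π³ kB T r³) [same angular factor]     (Hz)

Coordinates are Å, PCS ppm, RDC Hz, energies kcal/mol; SI constants enter
only through two prefactors. Defaults: B₀ from a 900 MHz ¹H frequency
(B₀ = 2πν/γH = 21.14 T), T = 298.15 K, r_CH = 1.095 Å. An equivalent
frame-free form, δ ∝ r̂ᵀΔχ r̂ / R³, is used **only** by the test oracle so
the two derivations check each other to 1e-10 relative.

Principal decomposition convention: eigenvalues ordered by increasing
magnitude into (χx, χy, χz) — ties broken on signed value — giving
Δχ_ax = (3/2)χz and Δχ_rh = χx − χy, with Δχ_rh/Δχ_ax ∈ [0, 2/3] under
this ordering. Eigenvectors are sign-fixed (largest component positive)
and made right-handed by flipping the x axis, so output frames are
reproducible; near-degenerate χx ≈ χy is flagged "axially symmetric".

Methyl groups: fast three-fold rotation projects each C–H coupling onto
the symmetry axis, scaling the RDC by P₂(cos β) = (3cos²β−1)/2 with
β = 110.5°, i.e. −0.316 ("about 1/3" in magnitude). The factor is
config-overridable (−1/3 is accepted as a rougher alternative) because
conventions differ between labs; it is applied after evaluating the
angular factor for the axis direction, with the same r_CH in the
prefactor.

The lanthanide position is an explicit input everywhere rather than being
inferred from a structure, keeping the computation agnostic to where the
coordinates came from (experimental model, prediction, or synthetic).

## Tensor determination

Both observables are linear in c5, so the tensor is the weighted linear
least-squares solution over all assigned protein-site rows (PCS rows in
ppm, RDC rows in Hz, each whitened by 1/σ so the two types mix on a
dimensionless scale; inverse-variance is the only weighting). Column
scaling guards conditioning; a rank-deficient design (collinear site
geometry) is reported together with the null direction in c5 space. PCS
uncertainties follow the experimental model σ = max(0.15|δ|, 0.03 ppm);
an explicitly recorded error stands, clamped from below by the 0.03 ppm
floor (≈ one linewidth).

Outlier exclusion iterates: fit, find the worst row by **studentized**
residual |r|/(σ√(1−h)) where h is the row's leverage, drop it if it
exceeds k·σ (default k = 3), refit. The leverage correction matters: a
gross error at a high-leverage site (close to the ion, large |PCS|) drags
the fit toward itself and its plain residual can hide below threshold —
with studentization a +10σ contamination is caught in ≥ 95% of noisy
replicates, without it only ~90%. Sites known to be internally mobile can
be blacklisted up front; a helper flags sites whose bond-vector order
parameter S² = (3 tr⟨b̂b̂ᵀ⟩² − 1)/2 over a frame series falls below 0.8,
since motional averaging biases their RDCs. Uncertainty is available by
case-resampling bootstrap (the 95% interval covers truth in ≥ 85% of
synthetic replicates).

## Crosspeak assignment

A glycan crosspeak carries a (PCS, RDC) pair that must be assigned
jointly. Chemical shifts fix the class — first-GlcNAc C1, second-GlcNAc
C1, or acetyl — but not the glycosylation site; multiplicities are one
first C1 and one second C1 per site and two acetyls per site, with the
acetyl's GlcNAc identity itself decided by the optimization and emitted
from the matched geometry. The cost of pairing observation o with a slot
is min over the site's candidate conformers of Σ (Δ/σ)², summing whichever
of the PCS/RDC terms exist (ND predictions or ND observations simply drop
their term). Because the three classes do not compete for slots, the
global optimum decouples into three independent rectangular linear
assignment problems, solved exactly at any scale with
`scipy.optimize.linear_sum_assignment`; exhaustive enumeration survives
only as the independent test oracle (they agree on 200+ random
instances). Observations are id-sorted before solving, so equal-cost
optima resolve deterministically. Matches are flagged acceptable within
2× experimental error (configurable). Note the published workflow this
emulates mixed tabular and visual reasoning; the explicit global cost
here can in principle diverge from a human assignment on ambiguous data.

## Ensemble clustering and boost reweighting

Frames (selection coordinates: ring atoms C1/C2/C4/C5 of the first two
GlcNAc residues plus three attachment-residue Cα, i.e. 11 atoms) are
subsampled every tenth frame and compared by plain coordinate RMSD —
frames are assumed pre-aligned on the protein; optional per-pair Kabsch
superposition exists but is off by default. Ward linkage builds the
dendrogram; it is cut with the inconsistency criterion, scanning cutoffs
0.5–4.0 in steps of 0.05 and keeping the cutoff that maximizes the number
of clusters with ≥ min_size members (ties to the smaller cutoff; frames
in smaller clusters are labeled unclustered and excluded from probability
normalization). The inconsistency depth defaults to 3: at depth 2 the
statistic saturates at 1.1547 for any merge over two much-tighter
subtrees (heights ≈ [0, 0, h] give (h − h/3)/(h√⅓)), so clean separations
become indistinguishable from noise merges and cutoff tuning loses all
discrimination; depth 3 restores it (planted 30-well fixtures: 31
recovered clusters vs 7 at depth 2). Feeding precomputed RMSDs to Ward
linkage mirrors the common MATLAB `linkage` usage; scipy's warning that
such distances may not be Euclidean is expected and suppressed at the
call site.

Boosted-ensemble populations are debiased per cluster with a second-order
cumulant estimate, ln⟨e^{βΔV}⟩ ≈ β⟨ΔV⟩ + β²σ²_ΔV/2 (order 1 available in
config), unbiased weight ∝ n_c⟨e^{βΔV}⟩, computed in log space; free
energies −kBT ln p are reported relative to the most probable cluster,
with T = 300 K (the MD temperature) and kB in kcal/mol. Representatives
are the minimum-total-energy member frames (ties to the lowest frame
index). At the realistic boost scale (ΔV sd 8 kcal/mol, β ≈ 1.68
mol/kcal) the log-weight estimator has a delta-method SE of
β²σ²/n + β⁴σ⁴/(2(n−1)) ≈ 10+ ln-units at 10³ frames per cluster: the
closed forms (constant boosts, uniform boosts) are exact, but reweighted
probabilities on realistic data are order-of-magnitude statements, and
the analysis scripts say so. The synthetic boosted generator plants
occupancies p_biased ∝ p_target/⟨e^{βΔV}⟩ using the Gaussian closed form,
so reweighting is exactly invertible in expectation and recovery is
testable against its own sampling error.

## Screening

Per site, each candidate conformer (by convention the representatives of
the four most probable clusters) is scored against the site's assigned
observations by χ² = Σ(Δ/σ)² with 2σ accept flags; candidates are listed
in descending cluster-probability order and the best model is the χ²
minimizer. Two-structure averages are screened over all candidate pairs
on a weight grid that defaults to {0.5} only (the 50:50 convention; a
finer grid is configurable), reporting pairs that strictly lower χ². A
probability-weighted average over the full ensemble is deliberately not
offered: with ~4 observables per site there is no information to support
extra weight variables, and cluster energies are not accurate enough to
fix them. A site is summarized "motionally restricted" when ≥ 75%
(configurable) of its observations are matched by at most two structures;
the summary also reports each site's largest |RDC|, since extensive
motional averaging drives RDCs toward zero while a surface-locked glycan
retains large ones. χ² with accept-fraction is this package's convention
for "agreement"; it is not a community standard.

## Synthetic study design

The generator is the package's test bed and defines its default
conditions: a rigid pseudo-protein with 20 labeled methyl sites at
10–40 Å from the ion; three glycosylation sites at 12/19/26 Å, each with
four candidate conformers (first/second C1–H1 vectors plus two acetyl
axes; minimum inter-conformer RMSD 2 Å enforced by resampling); data
sparsity of 20 PCS + 11 RDC protein rows for the Tm-like ion and 14 + 7
for the Tb-like ion, 11 glycan PCS + 8 glycan RDC after ND masking; PCS
noise 15% with a 0.03 ppm floor and Gaussian 1.6 Hz RDC noise. The two
ground-truth tensors are calibrated so the on-axis PCS at 40 Å is
−0.13 ppm (Tb-like, rhombicity 0.30) and +0.08 ppm (Tm-like, rhombicity
0.25) — opposite signs, magnitude ratio 1.63, and maximum C1–H1 RDCs of
roughly ±26 Hz at 900 MHz, all consistent with reported lanthanide-tag
behaviour. Every generator is a pure function of (parameters, seed), and
scenarios round-trip losslessly through JSON.

What the generator does **not** emulate — and hence what green tests do
not show about real data: conformational exchange broadening and peak
overlap (ND masking is random, not physics-driven), residue-level
structure within a conformer (only labeled positions and vectors exist),
force-field-realistic energetics and water-model effects, order-parameter
scaling of glycan RDCs, and contact shifts near the ion (a 5 Å warning
cutoff marks where the point-dipole PCS becomes unreliable).

## Numerical and scale choices

Problem sizes in tests and the acceptance script are desk-scale by
design: 100-replicate recovery studies, 200 random assignment instances,
a 5,000-frame / 30-well clustering fixture with min cluster size 50 (the
same 1% ratio as 500-member clusters in 50,000 frames), 2×10⁴-direction
isotropic RDC averages. End-to-end screening guarantees ("generating
conformer first, all accepts at 2σ") are asserted on noise-free glycan
observables, since with 15% noise the probability that every one of ~12
residuals stays within 2σ is only ~0.57 even for the true model; the
noisy variant is exercised for top-rank stability in the analysis
scripts. Grid-versus-pointwise field values agree to 1e-12 relative
rather than bitwise (BLAS summation order differs between the vectorized
and scalar paths). Near-field lattice points within one grid spacing of
the ion are masked NaN in field exports.

## Known limitations

Assignment and screening are staged (assign once against the full
prediction table, then screen); a joint re-optimization per candidate set
is possible through the same interfaces but is not the default. PRE,
contact shifts, residual chemical-shift anisotropy and NOE scoring are
out of scope. The CLI's `cluster` command reads multi-model PDB frame
series, which is practical only for selection-atom exports, not full
trajectories.
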