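# Methods

This note records the models, conventions and numerical choices behind
`orbpool`, and what the synthetic benchmark does and does not establish.

## Model

Each atom *i* of a system with *N* atoms is described by a local environment
vector χᵢ; an energy network maps χᵢ to a scalar εᵢ, and a pooling function
aggregates {εᵢ} (plus, for weighted heads, a weight simplex {ωᵢ}) into one
molecular scalar.  All pooling heads except `sum` are size-intensive: the
prediction is unchanged when non-interacting replicas are concatenated,
exactly for `avg`/`max` and to floating-point accuracy for
`softmax`/`wa`/`owa`/`coeff` (softmax weights are computed with
max-subtraction; weighted heads renormalize over all atoms).  The `mode`
flag (`max` for HOMO energies, `min` for IEs and LUMO energies) fixes the
sign *s* = ±1 used by `max` and by every softmax: weights ∝ exp(s·x).

Softmax pooling uses unit inverse temperature (weights exp(±ε/T) with
T = 1 eV by default): no temperature is intrinsic to the formulation and the
scale is absorbed by the learned ε; T is exposed for sensitivity studies.

### Orbital localization

For a normalized orbital c in an atom-centered basis with overlap S, the
Mulliken fraction on atom *i* is lᵢ = Σ_{μ∈i} Σ_ν c_μ c_ν S_{μν}
(Σᵢlᵢ = 1; entries can be slightly negative for non-identity overlap).
Negative fractions are passed through unclipped for analysis; when used as
weight-network labels they are clipped to zero and renormalized (with a
logged count), because supervised weights must live on the softmax codomain.

The localization index is defined here as the **normalized inverse
participation ratio**

    L = (N · Σᵢ lᵢ² − 1) / (N − 1).

L = 1 exactly for a one-hot vector, L = 0 for the uniform vector,
L ∈ [0, 1] on the simplex, L is permutation-invariant, and L is
non-decreasing under transferring mass from any atom to the maximal one
(d(Σl²) = 2(l_max − l_j)·dε ≥ 0).  Other normalized concentration measures
share these endpoint properties; the IPR form was chosen because it weights
all fractions (not just the maximum), is smooth, and is the standard
participation measure for orbitals.  It is undefined at N = 1.  Strata:
localized L ≥ 0.8 (inclusive), delocalized L < 0.4 (strict), middle band
otherwise; both thresholds are configurable.

### Joint (OWA) loss

Per system: α·(P − E_ref)² + β·Σᵢ(ωᵢ − lᵢ)²; batches average over systems.
The weight-error reduction over atoms is a plain sum (not a mean), so a
molecule's localization supervision does not weaken with its size; this is
a documented package choice.  β = 0 recovers the purely energy-based loss
used by every non-OWA head; `select_alpha_beta` grid-selects (α, β) by
validation energy RMSE with ties broken toward larger β.

### Identifiability of cross-fragment weights

The weight softmax normalizes within one system, so training on monomers
alone constrains only *within-molecule* weight differences: nothing pins
whether water atoms or CO₂ atoms receive larger raw scores when both appear
in one supersystem.  The toy experiment therefore augments the OWA training
set with a single labeled non-interacting composite (water+CO₂, labels
produced exactly by the composition rule), which pins the cross-fragment
offset.  Per-molecule weight/fraction correlations on monomer datasets are
unaffected by this ambiguity.

## Descriptor

The reference descriptor is element-resolved radial Gaussian symmetry
functions with a cosine cutoff f_c(r) = ½(cos(πr/r_cut) + 1): K centers
evenly spaced on [0.5 Å, r_cut), shared width η = 1/(2Δμ²).  Defaults
K = 16, r_cut = 5 Å; the study-scale experiments use K = 8, r_cut = 4 Å.
It is rotation/translation invariant, permutation-equivariant, and strictly
local (f_c and f_c′ vanish at the cutoff), which makes supersystem rows
exactly equal to monomer rows beyond the cutoff — the premise that lets
intensive pooling extrapolate.  Angular terms are deliberately omitted:
pooling comparisons are representation-agnostic, and richer per-atom
representations (SOAP, message passing) can be registered through the
adapter contract (any callable producing a permutation-equivariant N×D
matrix).

The model input is the z-scored descriptor row (statistics from the
training split only) concatenated with a one-hot encoding of the atom's own
element.  The radial sums see only *neighbor* identities; the atom's own
on-site identity carries most of the orbital-localization signal, so
omitting it would make the weight network unable to express lᵢ.

## Networks, training, normalization

Energy and weight networks are separate MLPs (default two tanh hidden
layers of 64 units; 32–48 in the test-scale runs), with an optional shared
trunk.  Targets are normalized by training-set mean/std; per-atom outputs
are un-normalized *per atom* (εᵢ·σ + μ) before pooling, so intensive heads
predict μ at zero network output while the sum head remains exactly
extensive (k replicas give exactly k× the monomer sum).  Optimization is
Adam (lr 1e-3 default; 3–5e-3 in the small studies), mini-batches of 32–64
molecules, early stopping on validation energy RMSE with best-parameter
restore.  All randomness (initialization, shuffling, subsampling, dataset
generation) flows from explicit integer seeds; training is bit-reproducible
given a seed.  If no validation split is tagged, 10 % of the training
records are held out deterministically; below five records the training set
doubles as the monitor set (plain convergence monitoring).

## Synthetic benchmark

The generator emulates a substituted-backbone chemical space as an
orthogonal tight-binding model: on-site energies α per site symbol,
hoppings t₀·exp(−λ(r − r₀)) cut off at 2r₀, half filling (⌊N/2⌋ occupied,
minimum one), HOMO = highest occupied eigenvalue, lᵢ = squared HOMO
coefficients (overlap = identity, so the general Mulliken path reduces to
it; that path is still implemented and tested separately).  Degenerate
HOMOs (gap < 1e-6 eV) average lᵢ over the degenerate subspace and set a
flag.  Defaults: t₀ = −2.5 eV, λ = 1.8 Å⁻¹, r₀ = 1.45 Å; backbones
2–8 sites, zig-zag with 120° angles; conjugated backbones have uniform
on-site −6 eV, saturated backbones alternate −8/−4 eV, which opens a ~4 eV
gap at half filling; 41 substituent types with on-sites evenly spanning
[−9, −3] eV, attached 1.7r₀ above a backbone site (weak coupling keeps
in-gap substituent levels sharply localized); one or two substituents per
molecule, sites at least three positions apart; Gaussian coordinate noise
σ = 0.05 Å.  These defaults produce roughly 16 % of molecules with L ≥ 0.8
and 64 % with L < 0.4, covering both regimes.  Localized HOMOs arise when a
substituent level falls in the saturated gap with a parity-consistent
electron count (e.g. an even backbone with two in-gap substituents) or just
below a conjugated band center; delocalized ones from unperturbed band-like
states.

The toy monomer fixtures store experimental ionization energies (water
12.6 eV, CO₂ 13.8 eV) directly as min-mode targets rather than deriving
them from orbital energies; monomer fractions are uniform (the ionization
of an isolated molecule belongs to the whole molecule).  Composition of
non-interacting systems takes the max/min of fragment targets per mode,
places the winning fragment's fractions (zero elsewhere), and averages
across fragments tied within 1e-9 eV.

### What the benchmark does not show

The tight-binding world has no electron–electron interaction, no geometry
relaxation, no conformational ensembles, and its "elements" are site labels
with prescribed on-site energies — the one-hot element input is therefore
far more informative than in real chemistry, where localization depends on
many-body effects the descriptor cannot read off a single symbol.  Passing
tests demonstrate the *formal* properties (intensivity, locality,
correctness of the pooling/aggregation mathematics) exactly, and the
*statistical* claims (OWA recovering localization, stratified error
orderings) only under these idealized conditions at desk scale (hundreds of
molecules, minutes of CPU), not DFT-level accuracy on real molecules.

## Study problem sizes

The packaged studies use: toy IE experiment — 2 (or 3, for OWA) training
records, ≤1500 epochs, seconds; localization recovery — 700 noiseless
molecules (550 train / 150 held out), OWA with β = 5 versus WA, three
seeds; stratified ordering — a 500-molecule pool, subsamples of 100 and
250, five seeds, heads owa (β = 1), avg, max, fixed 150-molecule test set;
intensivity audit — 100 molecules, k ∈ {2, 3, 5} replicas.  β = 5 in the
recovery study reflects that its object is the weight network (strong
localization supervision); β = 1 is the balanced default elsewhere.

## Numerical conventions

Energies in eV, coordinates in Å, 0-based atom indexing, no automatic unit
conversion.  Extended-XYZ dialect: `Properties=species:S:1:pos:R:3` plus
optional `l_frac` and `owa_weight` per-atom columns; per-structure keys
`target_energy`, `mode`, `L`, `system_id`, `fragment`, `split`; fixed float
formats make writes byte-stable and round trips exact to 1e-8 Å / 1e-10 eV.
Fraction sums are validated to 1e-6 on read and 1e-8 internally; orbital
normalization to 1e-8; weight simplices to 1e-8; replication-intensivity
audits use 1e-6 eV.  Ties in `max` pooling resolve to the first extremal
atom; Pearson correlations use the population covariance and exclude
molecules with fewer than three atoms or zero variance on either side
(logged), since R is degenerate there.
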