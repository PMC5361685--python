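# Methods

## Model

`dnaenm` models double-stranded DNA as a harmonic elastic network built on
a sequence-dependent equilibrium ("basic") structure.  One particle
represents k consecutive nucleotides on each strand; particle pair n
consists of a Watson and a Crick particle of the same base pair.  The
potential is

    V = Σ_{n,l} (C^k B_nl / 2) (|q_n − q_l| − |q⁰_n − q⁰_l|)²

with binary connection weights B over nine classes (intra-strand n±1…n±4,
cross-strand n^c and (n±1)^c…(n±4)^c) and a single spring constant C^k in
kJ/(Å²·mol).  Defaults for k ∈ {1, 3, 4, 9, 13} are the published optimal
tables; any other k requires a connectivity survey (below).  Because every
spring is at its rest length in the reference state, the Hessian is the
exact anisotropic-network form: each edge with unit bond vector u
contributes ±C·B·uuᵀ blocks.  A connected network has exactly six zero
modes (three translations exactly, three rotations to machine precision);
any other count is rejected as disconnected/degenerate.

Thermal statistics follow from equipartition: mode amplitudes
A_k² = RT/λ_k, equivalently displacement covariance RT·H⁺.  Mass is
uniform and cancels in every fluctuation index; it only scales mode
frequencies.  Temperature (default 300 K, with R = 8.314×10⁻³
kJ/(mol·K)) scales all mean-square fluctuations uniformly and cancels in
every Pearson correlation, so no validation statistic depends on it.

## Basic structure

The equilibrium geometry is rebuilt from dinucleotide base-step
parameters by the standard mid-step-triad propagation: with bend
magnitude γ = √(roll² + tilt²) and bend phase φ = atan2(tilt, roll), the
next base-pair frame is R·Rz(Ω/2−φ)·Ry(γ)·Rz(Ω/2+φ) and the origin
advances by the mid-step frame applied to (shift, slide, rise).  The
packaged parameter table is the B-DNA crystal-structure average set
(Olson and co-workers); tables are validated for the reverse-complement
sign convention (twist/roll/slide/rise invariant, tilt/shift negated) and
missing complementary steps are auto-filled by it.

One pseudo-atom per nucleotide (a C1' proxy) is placed in the base-pair
plane at the two positions ±54.5° from the minor-groove side of the
pseudo-dyad with a 10.4 Å intra-pair separation (canonical B-DNA C1'–C1'
distance).  Both placement constants are configuration values
(`PlacementConfig`).  Intra-base-pair parameters (buckle, propeller,
opening, shear, stretch, stagger) are supported through symmetric
half-transforms of the two bases but default to zero.  Sensitivity: a
crystallographic placement (10.80 Å / 65.4°, the standard-reference-frame
C1' geometry) or nonzero sequence-dependent propeller twist shift the
ensemble validation correlations at the third to fourth decimal; all
conclusions below are stable under these variations, and the defaults are
fixed once, not fitted.

Circular molecules (mitochondrial genomes) are modelled as open chains;
end trimming (below) removes the artefacts at the arbitrary
linearization point.

## Fluctuation indices

Per particle pair n, three unit vectors are built from the basic
structure: b_n (Watson→Crick atom direction), s_n (difference of
consecutive pair centers) and t_n = s_n×b_n normalized.  All reported
indices are variances/covariances of linear functionals of the particle
displacements and are evaluated exactly from covariance blocks:
per-particle MSF F^a and projections F^b, F^s, F^t; inter-strand
DF^a, DF^b, DF^s, DF^t on the relative displacement δq_n − δq_{n^c};
the step indices

    F^twist_n = ⟨|(δq_{n+1}−δq_{(n+1)^c})·t_{n+1} − (δq_n−δq_{n^c})·t_n|²⟩
    F^bend_n  = ⟨|δQ_{n+1}·R_{n+1} − δQ_n·R_n|²⟩ ,  δQ_n = (δq_n+δq_{n^c})/2

with R_n = t_n by default (configurable to b_n — the choice cancels in
coarse-vs-fine comparisons since both models share it); and the
motion-correlation matrix F^c.  The bend/twist projection vectors rotate
with the helix (~36°·k per particle step), so these two indices pick up
contributions from soft chain-scale modes through δQ·(R_{n+1}−R_n); their
absolute level therefore grows with the modelled chain length.  They are
meaningful as *profiles* along a molecule of fixed length — which is how
they are validated and used — not as transferable per-site constants.  A
strictly local alternative (projecting the relative center displacement on
a shared mid-step vector) was implemented and rejected: it degrades the
coarse-vs-fine bend correlation at k = 9 from 0.96 to 0.86, i.e. it is
*not* the quantity the published validation statistics describe.

Because the particles at chain ends have fewer neighbours, two particle
pairs (2k bp) at each end are excluded from every reported profile,
correlation and average.

## Coarse-vs-fine validation

A 1PkN model is validated against the fine 1P1N model on the same basic
structure.  Particle pair n of the coarse model sits at nucleotide
i = k·n + k0, k0 = (k−2)/2 (k even) or (k−1)/2 (k odd).  The 1P1N indices
G^• are evaluated at exactly these nucleotides, with the coarse model's
frame vectors and a step stride of k, so every coarse index has a
like-for-like fine counterpart.  Agreement per sequence is the Pearson
correlation ρ^• over the trimmed profile; ρ^c correlates the
upper-triangles (diagonal excluded) of the two motion-correlation
matrices restricted to the mapped, trimmed particles.  Constant profiles
make a Pearson correlation undefined; such cases are reported as missing
rather than zero.

Ensembles use uniform-random sequences of length 50k bp (50 particle
pairs for every k), or exact-GC sequences for the GC study
(round(gc·L) G/C positions, uniformly shuffled — "exact count" rather
than Bernoulli sampling, matching the designated-GC design).  Means and
SDs use the sample (n−1) convention; one seeded generator is threaded
through all sampling and recorded in every report.

The connectivity survey evaluates all 2⁹ = 512 binary weight tables:
per random sequence the nine class-resolved Hessian pieces are assembled
once, each candidate is diagonalized, and its objective profile (MSF by
default) is correlated with the reference (the 1P1N model, or a model
built from a known table for parameter-recovery checks).  Candidates
whose spring graph is disconnected, or connected but mechanically floppy
(internal zero modes — e.g. cross-strand-only ladders), are flagged and
ranked last.  Among tables within one standard error of the best mean
objective, the sparser table is preferred (tie-break rule of this
package).

## Numerical paths

Two exact, cross-checked evaluation routes produce the covariances:

* **Full eigendecomposition** (`normal_modes`): dense symmetric solver by
  default; a symmetric-banded path exists (the duplex network is banded
  with bandwidth ≤ 29 dofs) and produces identical spectra, but was
  measured slower than the dense solver at all relevant sizes, so dense
  is the default.  Zero modes are identified by |λ| < 10⁻¹⁰·λ_max and
  must number exactly six.
* **Sparse pseudoinverse solve** (`PseudoinverseCovariance`): selected
  columns of H⁺ from one sparse LU factorization of the saddle system
  [[H, Rb], [Rbᵀ, 0]], Rb the orthonormal rigid-body basis (an exact null
  basis here).  This is the route used by the model comparison and the
  genome scanner, where only covariance blocks at a subset of particles
  are needed: it reduces e.g. the 650-bp fine-model reference from a
  21 s eigendecomposition to a sub-second solve, and makes whole-genome
  scans (tens of thousands of dofs) tractable on one CPU.

The two routes agree to 10⁻⁹ relative on mean-square fluctuations (tested).
`fit(engine=...)` selects the route; "auto" uses modes below 1500 dofs.

## Genome scanning

The scanner builds the k = 3 model of an input FASTA record, computes
F^bend/F^twist at every step, and reports moving-window sums
MF^bend_n = Σ_{m=n…n+6} F^bend_m (window of 7 particle pairs = 21 bp,
approximately one TFAM binding footprint; `--normalize` divides by the
window size).  IUPAC-ambiguous bases (≤ 2 by default) are enumerated into
all concrete variants, each scanned separately.  A full-chain scan is
allowed up to 6000 particle pairs (≈18 kb at k = 3) by default; the
sparse solver keeps this exact and fast.  The blockwise mode
(`scan_windowed`) exists for memory-constrained cases but, because the
bend/twist indices are chain-length dependent (above), block values
describe each block as an isolated molecule and differ systematically
from the whole-chain scan — it emits a RuntimeWarning and should not be
mixed with full-scan results.  It is exact in its single-block limit.

## Test strategy and what it shows

Oracles are independent of the code paths they check: the Hessian against
central finite differences of the potential; every fluctuation index
against direct Boltzmann sampling (10⁵ draws from N(0, RT·H⁺) with the
pseudoinverse computed by numpy, each index evaluated by its literal
definition on the samples, agreement within 3 Monte-Carlo SEs); the frame
propagation against a step-by-step rotation-matrix composition; closed
forms for the uniform-helix limit.  Ensemble statistics are checked
against the published values at ±3 standard errors with ensembles of
25–100 sequences (published work used 500); problem sizes were chosen so
the whole suite runs in minutes on one CPU.

Synthetic random sequences emulate the published validation design: they
probe sequence-dependent *geometry* through the step-parameter table, but
not base-pairing breakage, ionic-strength effects or anharmonicity — so
passing tests demonstrate internal consistency of the harmonic model and
faithful reproduction of the coarse-graining behaviour, not agreement
with experiment.

## Known limitations

* Harmonic fluctuations about one minimum only: no melting, kinking,
  supercoiling or protein binding.
* The pseudo-atom placement is a C1' proxy; absolute fluctuation
  magnitudes depend on C^k (chosen, not fitted, for k > 1) and on
  placement geometry, while profile correlations are robust to both.
* Bend/twist indices are length-coupled (see above); compare profiles
  only between models of the same chain length.
* Circular genomes are analyzed as open chains.
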