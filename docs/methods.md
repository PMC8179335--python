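# Methods

`fieldunfold` analyses how a small globular protein unfolds in a strong
static electric field, and what that unfolding would look like to X-ray
experiments: single-particle imaging (SPI) with a free-electron laser and
gas-phase SAXS.  The package operates on ensembles of short (tens of ps)
gas-phase trajectories of a ubiquitin-like fold — normally produced by
molecular dynamics — and ships a scripted synthetic generator so that every
analysis stage can be validated against exact ground truth.

## The coupling-state model

The fold has five β-strands (I–V) and one α-helix (A).  The β-sheet is held
together by four native strand–strand contacts ("couplings"):

    B = (I, II),   C = (I, V),   D = (III, V),   E = (III, IV).

A coupling counts as **broken** in a frame when the centre-of-mass (COM)
distance of its two strands exceeds a threshold, 0.7 nm by default.  The
threshold is an empirical choice that yields clean diagrams, not a physical
constant; raising it can only flip bits broken→connected (a tested
monotonicity property).  Distances are computed with unweighted per-atom
COMs (uniform masses in the Cα model; a weighted option exists for all-atom
input), and equality at the threshold counts as connected (strict `>`).

Each frame then encodes as a 4-bit code `*BCDE` — `*0000` native, `*1111`
fully unfolded.  The helix gets no bit: an end-to-end criterion for it
oscillates too fast to be useful, so the state space is exactly 2⁴ = 16
codes.  Probing a run every `dt_probe` (0.05 ps default; it must divide the
frame spacing) gives a state series; counting probe-to-probe transitions
over an ensemble gives a Markovian transition count map.  Self-transitions
sit on the diagonal ("dwell"), sinks are states runs terminate in (with
per-run multiplicity), sources are visited states with no incoming edge
from a different state, and each edge is classed *unfolding* (more broken
bits), *refolding* (fewer), or *mixed* (the reverse edge also occurs).
Multi-bit jumps between consecutive probes are recorded as single direct
edges.  Nothing beyond raw counts is estimated — no lag-time analysis, no
spectral decomposition.

A run's **unfolding pathway** is the order in which its couplings first
break, e.g. `CDEB`.  The dominant pathway of an ensemble is the modal order
among runs in which all four couplings broke; runs with unbroken couplings
contribute partial orders, reported separately.  The B-before-D probability
(the discriminator between the `CDEB`-like and `CBDE`-like regimes) counts
runs where both break; simultaneous first breaks at one probe are ties,
counted as "not before" and reported.

## The synthetic generator

The generator replaces MD with a scripted, stochastic mechanism whose
ground truth is known exactly.

**Native model.**  One carbon atom per residue (76 residues by default,
with published ubiquitin strand ranges; strand IV is widened 48–49 → 48–50
for a non-degenerate COM).  The five strands are placed as blocks along the
stretch axis (+x) in the real sheet adjacency order II–I–V–III–IV, 0.55 nm
apart — below the 0.7 nm threshold, so the native state is always `*0000`.
The four couplings are then exactly the four interfaces between adjacent
blocks.  Strand residues run along y at the 0.35 nm β-rise, the helix packs
against the sheet face, loops interpolate between their flanking elements
with an out-of-plane arc, and a seeded 0.12 nm per-atom scatter (followed
by rigid per-element re-centring that restores every strand COM exactly)
disorders the lattice — a globular protein is not a crystal, and without
the scatter the native diffraction pattern carries artificial Bragg-like
anisotropy.

**Unfolding mechanism.**  A schedule scripts a break order (a permutation
of BCDE), per-coupling mean break times, Gaussian timing jitter (clipped at
zero), and a per-coupling probability that the break never happens.  When a
coupling breaks, everything tail-ward of its interface translates along the
stretch axis at `extension_rate` (0.15 nm/ps default).  Because each
coupling's COM distance depends only on its own interface separation, the
realized break order equals the script exactly whenever jitter is off — the
ground-truth-recovery property every pathway test relies on.

Two further terms give the unfolded state a realistic extended-chain shape.
Both act about strand COMs with offsets that sum to zero over each strand,
so they provably leave every coupling distance — and hence the scripted
ground truth — unchanged:

* **Axial elongation**: once one of its couplings breaks, a block's
  residues string out along the axis in sequence order, with the
  per-residue spacing saturating at 0.38 nm — the contour rise of an
  extended polypeptide; a chain cannot stretch beyond its contour length.
* **Transverse contraction**: the block's residues pull in toward the
  stretch axis on a 10 ps time constant, down to 10 % of their native
  transverse spread, the ~1 Å axis deviation of an extended Cα chain.

Finally, iid Gaussian positional noise is added per atom per frame.  The
preset value, 0.07 nm, is a typical thermal Cα root-mean-square fluctuation
in a protein; it is the run-to-run individuality that limits FRC resolution
for an otherwise homogeneous ensemble (see below).

**Ensembles.**  An ensemble draws each run's schedule from a weighted
mixture.  Component counts follow the weights *exactly* (largest-remainder
allocation, then a seeded shuffle), so a 70/30 mixture of 100 runs is 70/30
by construction, and per-run seeds derive from the master seed — the whole
ensemble is bitwise reproducible.  Field-strength presets (labels `3e4`,
`5e4`, `7e4`, `11e4`, in kV/cm) encode the qualitative regimes: the weakest
field breaks couplings late, with 3 ps jitter, two competing early orders
and a high chance that E and B never break; moderate fields give a clean
`CDEB` pathway finishing within ~20 ps; the strongest field breaks within
~10 ps with 1 ps jitter and a dominant C-then-B order.  These presets *are*
the study conditions; they were fixed from the above physical scales and are
not adjusted per analysis.

## Ensemble metrics

RMSD uses optimal least-squares rigid-body superposition (Kabsch, proper
rotation only) before comparison; the default ensemble statistic is per-run
RMSD against the shared initial structure, then mean ± σ/√N over runs, with
σ the sample (N−1) standard deviation.  An alternative "spread" mode (mean
pairwise RMSD between runs at fixed time) is provided for comparison, since
a deviation-from-start reading and an ensemble-spread reading are both
defensible.  The radius of gyration is the unweighted RMS distance from the
COM.  Under the presets, stronger field labels give (i) a non-decreasing
late-time ("plateau", operationally the mean over the last 20 % of frames)
RMSD — earlier breaks leave more time to extend — and (ii) a non-increasing
time-averaged σ/√N — tighter timing jitter makes runs more alike.  Both
trends are asserted in the acceptance suite at 16 runs per label.

Cα distance maps average all residue-pair distances over a time window and
all runs (default windows 0–10 ps and 20–50 ps).  Candidate FRET attachment
regions are found from the gain matrix (late − early): the upper triangle
is thresholded at half the maximum gain, connected components become region
pairs (1-based inclusive bounding ranges), ranked by mean gain.  In the
default fold the C-terminal tail region separates furthest from the
strand-I/II and helix regions, because coupling C (I–V) breaks first on
every scripted pathway.

## Diffraction simulation

The virtual detector is an AGIPD-like panel: 1024 × 1024 pixels of 200 μm,
25 cm downstream, 8 keV (λ = hc/E = 1.55 Å), 10¹² photons per pulse spread
uniformly over a 100 nm focal spot; the beam (+z) passes through the
junction of the four central pixels.  Momentum transfer carries no 2π
(|q| = 2 sin θ/λ), so real-space resolution is 1/q: 4.0 Å at the edge
midpoint, 3.0 Å in the corner — consistent with "scattering to at least
3.5 Å".  The per-pixel solid angle includes the cos³2θ obliquity factor.
Polarization defaults to P = 1, with a horizontal-polarization mode
(P = 1 − (cos φ sin 2θ)²) available.

Pixel intensities are expected photon counts
I(q) = I₀ r_e² P dΩ |Σᵢ fᵢ(q) e^{2πi q·Rᵢ}|², with tabulated Cromer–Mann
4-Gaussian atomic form factors evaluated at (q/2)² = (sin θ/λ)²
(spherically symmetric, static, f(0) = Z).  The mathematically identical
self + cross-term double sum (A_i = f_i², B_ij = f_i f_j cos 2πq·ΔR) is
implemented as an independent O(M²) cross-check path and the two are
asserted equal to 1e-9 relative error; the coherent sum is the production
path.  No photon noise, damage, incoherent background or detector noise is
modeled — pattern variation comes solely from structural heterogeneity
between runs.  Pattern series default to 11 time points, 0–50 ps at 5 ps.

For ensemble analyses the detector may be binned (e.g. 8× → 128² pixels of
1.6 mm covering the same solid angle); analyses in the test and acceptance
suites use binned detectors and 8–16 runs so the full pipeline runs in
seconds to minutes on one core.  Binning coarsens q-sampling, not q-range.

## FRC and the resolution limit

The pattern set at one time point is split into two equal halves (even-odd
by run index, or seeded-random), each half is averaged pixel-wise, and the
averages are compared ring by ring: FRC per ring is the Pearson correlation
over the ring's pixels (ring-mean subtracted, normalized), which is +1 for
identical rings, −1 for a negative affine relation, and ~0 for independent
noise, shrinking as 1/√n with ring size — all tested properties.  Rings are
64 equal-width q-bins from 0 to the largest full ring on the detector
(capped so each ring is populated); zero-variance rings are undefined (NaN)
and skipped.

The resolution limit at cutoff 0.5 is 1/q_max, where q_max is the upper
edge of the last ring before the first ring at or below the cutoff; if no
ring fails, the result is flagged detector-limited; if the first ring
fails, "not reached".  Limits shift by half a bin depending on the
edge-vs-centre convention, so the bin width is reported alongside.

A perfectly homogeneous ensemble (no jitter, no noise) is detector-limited
at every time point.  With thermal noise, a single-pathway ensemble sits a
little above the detector limit (~4.5–5.5 Å in the acceptance conditions).
A 50/50 two-pathway mixture (CDEB vs CBDE) resolves strictly worse during
the window where the pathways diverge structurally (15–45 ps in those
conditions): the ensemble-average structure is less well defined, and the
half-averages disagree sooner in q.  Because a single half-split of a
mixture can by chance balance the two classes across both halves — hiding
exactly the heterogeneity FRC is meant to expose — the comparison uses
limits averaged over five seeded-random splits on the q_max scale
(resolution = 1/mean q_max); this is split-level variance reduction, with
cutoff and conditions unchanged.

## Ring anisotropy (SAXS detectability)

For ensemble-averaged patterns, azimuthal profiles I_R(θ, t) are computed
within fixed resolution rings (defaults 5, 10, 15 Å; one q-bin wide),
normalized by the ring's angular mean at the first time point, with the
max/mean ratio per time as the anisotropy summary.  A spherically symmetric
arrangement gives a flat profile (ratio ≈ 1 up to speckle); a molecule
stretching along x concentrates ring intensity at specific azimuths, so the
ratio grows as unfolding proceeds.  In this package the growth is robust at
the 10 Å ring (and, mid-trajectory, at 15 Å), driven by the thin-filament
envelope of the contracted, elongated chain.

**Known limitation:** the 5 Å ring does *not* show the growth here.  At
that resolution the signal in an all-atom system comes from sub-residue
axial pair correlations along the extended backbone; a Cα-only chain
carries only the broadened 1/0.38 nm inter-residue interference, which
reaches the 5 Å ring too weakly to beat the ~2× speckle baseline of the
(shared) native structure.  Analyses of real all-atom trajectories should
see the 5 Å effect; tests assert it at 10 Å.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline's encodings, counts, statistics
and physics (geometry, interference, correlation) are correct against exact
ground truth and independent oracles, and that the qualitative field-
strength trends emerge from the stated mechanisms.  They do not validate
physical unfolding timescales, force-field realism, chain connectivity
during extension (blocks may pass through each other), radiation damage, or
absolute resolution numbers for any real protein — the generator scripts
its kinematics rather than solving dynamics, and its unfolded geometry is
an idealization.

## Numerical choices

* Units: nm and ps internally; Å and Å⁻¹ inside the diffraction and
  scattering modules (one conversion boundary).  PDB files are written in Å
  (3 decimals → 1e-3 nm round-trip precision); extended XYZ carries a
  `time=` comment and a residue-index column.
* Randomness: every stochastic step takes a seed; ensembles derive per-run
  seeds (< 2³¹) from the master seed via one generator.
* Probe commensurability tolerance 1e-9; threshold comparison strict `>`;
  weight-sum tolerance 1e-9; rings with zero variance excluded from the
  limit scan; odd pattern counts drop the last pattern with a warning.
* Superposition excludes reflections (determinant +1) by construction.
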