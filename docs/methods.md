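# Methods

This note documents the models and estimators in topplekit, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that a careful user should know about.

## Coordinates, units, boxes

All lengths are nm (GRO-native); PDB Ångströms are converted on read and
write. Energies are kJ/mol with k_B = 0.0083144621 kJ/mol/K. Only
orthorhombic boxes are supported — every analysis here is defined on a
flat rectangular membrane patch, and triclinic records are rejected with
an explicit error rather than silently orthogonalised. The minimum-image
convention is applied per axis. Centre-of-mass groups default to uniform
masses (appropriate for CG beads, where bead masses are equal or nearly
so); a per-name mass table can be supplied where atomistic masses matter.
Groups passed to COM-based operations are assumed whole; `unwrap_group`
makes a compact group whole when it straddles the boundary.

## Helix tilt and the toppled-state statistic

The orientation of the S-component is summarised by the angle between
helix 5 and the bilayer normal (+z by default; the instantaneous normal
of a fitted mid-surface is a possible refinement for strongly curved
patches but the flat-normal convention matches how tilt-vs-z profiles
are reported). The helix axis is the principal axis (largest-variance
eigenvector) of the selected backbone beads, sign-oriented from the
N-terminal half centroid to the C-terminal half; an endpoint-vector
definition is available via `axis_method="endpoints"`. The angle is
arccos of the dot product in [0, 180°] and deliberately *not* folded to
[0, 90°]: an inverted helix (180°) is physically distinct from an
upright one.

A frame is *toppled* when the tilt lies in [75°, 125°], bounds
inclusive — inclusivity is a determinism choice at a measure-zero
boundary. A replica is *stably toppled* when its toppled time fraction
strictly exceeds 0.5; frames are weighted equally (output intervals are
uniform in practice). The per-condition statistic is the fraction p̂ of
stable replicas among n, with binomial SD sqrt(p̂(1−p̂)/n) reported on
the fraction scale (`sd_scale="count"` multiplies by n).

## Leaflets, surface fits, thickness and curvature

Leaflet assignment uses phosphate beads only. Each lipid contributes one
z value (its phosphate beads averaged — cardiolipin's two phosphates
count once), and the midplane is the **mean of these per-lipid values**.
A per-bead median was considered and rejected: with a two-phosphate
species the bead counts of the two leaflets differ, and a median then
lands inside one phosphate cluster instead of the inter-leaflet gap.
Lipids within 0.5 nm of the midplane (a toolkit default, not a
literature value) are excluded as in-flight flip-flop/disordered cases.

Each leaflet surface z(x, y) is fitted with a bivariate polynomial over
the full total-degree-4 monomial basis (15 coefficients) by linear least
squares on protein-centred coordinates; rank-deficient designs (e.g.
collinear points) are an error. Thickness is z_upper − z_lower at grid
cell centres; mean curvature is the Monge-patch expression

    H = [(1+z_y²) z_xx − 2 z_x z_y z_xy + (1+z_x²) z_yy]
        / [2 (1+z_x²+z_y²)^{3/2}]

from the analytic derivatives of the fit. With this sign convention a
bowl opening toward +z has H > 0 (z = 0.05(x²+y²) gives H = 0.1 nm⁻¹ at
the origin); H is invariant under vertical offsets and flips sign under
reflection through z = 0. Whether a published curvature map shows mean
or principal curvature is often ambiguous; here it is mean curvature in
nm⁻¹, labelled as such in every output.

`MembraneMapper` computes maps per frame and averages cell-wise. Two
fitting modes exist:

- **global** — one quartic per leaflet over the whole patch. Exact for
  fields representable at degree 4 (planes, paraboloids, sphere caps
  over a modest patch).
- **local** (default) — a moving-window quartic around every grid cell,
  using the k nearest phosphate beads (default 60; at typical CG lipid
  densities of ~1.6 phosphates/nm² this is an effective window radius of
  ~3.5 nm) with periodic x/y neighbour search, evaluated at the cell
  centre via a batched normal-equation solve (a tiny 1e-12 ridge guards
  against degenerate neighbourhoods). This choice is forced by geometry:
  a single degree-4 polynomial over a 25 nm box *cannot* represent a
  Gaussian thinning dimple of σ = 2 nm together with a flat bulk (the
  best possible quartic errs by ≳ 0.1 nm at any box size), whereas the
  deformation is locally quartic to well under 0.01 nm. Local mode
  reduces to the global behaviour as the neighbour count approaches the
  whole patch. The smoothing length implies curvature features sharper
  than ~2 nm are attenuated.

Cells whose centre is within 0.3 nm (default) of a protein-bead x/y
projection are masked: excluded from fit input, reported NaN (never 0),
and flagged in the companion mask. Frames are averaged per cell over the
frames where the cell was unmasked.

## Lipid fingerprints

A residue–lipid *contact* exists when any particle of the residue is
within 0.7 nm (minimum image) of any headgroup bead — phosphatidyl or
glycerol CG beads — of the lipid; each (residue, lipid molecule) pair
counts at most once per frame. Neighbour search uses a periodic kd-tree
with the contract (enforced by test) that results equal the O(N²)
all-pairs computation exactly.

Shell membership is molecule-level: a lipid is in the annular shell iff
it has ≥1 contact with any residue, and cardiolipin is one molecule no
matter how many of its beads touch. The depletion–enrichment index of
lipid type L is

    D–E(L) = ratio(L)_shell / ratio(L)_bulk

with ratio(L)_bulk the whole-system molecule fraction. The default
estimator averages per-frame shell ratios and then divides (frames with
empty shells are skipped and counted); the `pooled` alternative pools
counts over frames first and satisfies Σ_L bulk(L)·D–E(L) = 1 exactly.
The per-frame mean is the default because it weights frames equally
regardless of shell occupancy; with stationary occupancy the two agree.

Per-residue occupancy is the fraction of frames with ≥1 contact per
(residue, lipid type); binding sites are grouped by single-linkage over
residues co-contacting the *same* lipid molecule in ≥20% of frames — a
toolkit convention for turning co-contact statistics into discrete
sites, since site identification is otherwise a visual judgement.
Headgroup density maps are 2-D histograms in protein-centred
coordinates, normalised to counts/nm²/frame.

## Umbrella sampling and WHAM

The reaction coordinate is the distance between the centres of mass of
two selections (the ECF coupling subunit and the membrane-proximal
bottom of the S-component, residues 69–75 and 127–133, in the original
application). Window files carry the restraint centre and force constant
in a header; defaults mirror the published design where stated
(K = 2500 kJ/mol/nm², 0.1 nm spacing, 303 K) and are toolkit choices
where not (bin width 0.02 nm, tolerance 1e-7 kJ/mol, max 1e6
iterations).

`validate_windows` reports per-window counts, mean-vs-centre deviation
and sample SD, and fails hard if any adjacent pair of windows shares no
occupied histogram bin (WHAM cannot bridge such a gap).

WHAM solves, on the pooled histogram H_j with biases
b_ij = exp(−βU_i(x_j)) evaluated at bin centres,

    p_j ∝ H_j / Σ_i N_i exp(βf_i) b_ij,
    exp(−βf_i) = Σ_j b_ij p_j.

The default solver first minimises the equivalent convex likelihood in
the window offsets with L-BFGS (the gauge direction is flat and
harmless), then polishes with successive substitution until
max|Δf_i| < tol — the same fixed point as plain iteration
(`method="iterative"`), verified against an independently written
dense-grid fixed-point solve in the tests. F = −kT ln p is anchored at
the profile minimum (the bound state is the natural zero for a
dissociation profile); `anchor="left"/"right"` move the reference.
Unoccupied bins inside the sampled range propagate as missing (NaN),
never zero. No Jacobian correction for the distance coordinate is
applied by default; `radial_correction=True` subtracts 2kT·ln x before
re-anchoring.

Error bars are a moving-block bootstrap: each window's sample series is
resampled in contiguous blocks whose length is the integrated
autocorrelation time (initial-positive-sequence truncation, minimum 1 —
so exactly-independent samples get block length 1), WHAM is re-run per
replicate warm-started from the full solution, and the per-bin SD of the
anchored profiles is reported. Replicates that fail to converge are
dropped and counted; more than 10% dropped is an error. A fixed seed
gives bit-identical error bars. Whole-window and Bayesian-weight
resampling are known alternatives; the moving-block scheme was chosen
because it degrades gracefully to the iid case while remaining valid for
correlated samples.

Statistical structure of the recovered profile: window-to-window free
energy offsets chain together, so the anchored profile accumulates a
random-walk error away from the anchor. With the published design
(51 windows at 0.1 nm, restraint σ = √(kT/K) ≈ 0.032 nm, 10⁴
samples/window) this is ~0.2 kJ/mol RMS over the central nanometre and
grows toward the profile ends; the error is unbiased (checked over
seeds) and is exactly what the bootstrap quantifies. The bootstrap
calibration study compares the empirical spread over independent
generator realisations to the mean bootstrap SD *in aggregate* (RMS over
bins): per-bin ratios are ill-posed at the anchor, where both SDs are
pinned near zero.

## Synthetic generators

Every generator is a pure function of its spec and a seed; per-frame
randomness uses deterministically spawned SeedSequence sub-streams, so
outputs are bitwise reproducible.

- **Bilayers**: lipids on a jittered lattice (fixed homes and types per
  trajectory; ~0.63 nm²/lipid at the defaults of a 25 nm box with 1000
  lipids/leaflet, mirroring CG bilayer densities), phosphates at
  mid ± thickness/2 with Gaussian z-noise (default σ = 0.1 nm) and small
  per-frame lateral jitter. The default composition is the bacterial
  model membrane POPE:POPG:CL 70:25:5; the stock thickness field thins
  from a 4.0 nm bulk to 3.6 nm in a σ = 2 nm Gaussian dimple, the regime
  of protein-induced thinning this toolkit is meant to map. Each lipid
  has 3–4 beads (phosphate(s), glycerol, two tails) — enough for
  leaflet, surface and contact logic; no conformational realism, no
  dynamics, no area fluctuations. Passing tests therefore demonstrate
  estimator correctness, not force-field fidelity.
- **Protein helices**: ideal α-helical backbones (3.6 beads/turn) whose
  *principal axis* is rotated exactly onto the requested tilt. The
  rotation targets the measured principal axis of the finite discrete
  cloud rather than the nominal helix axis, because phase–height
  coupling in a finite helix tilts the PCA axis by a fraction of a
  degree.
- **Tilt dynamics**: either Gaussian noise about one mean, or a two-state
  Markov chain (toppled ↔ canonical band means, exponential dwells from
  per-ps rates, started from the stationary distribution) with Gaussian
  angle noise. Stationary toppled probability k_ct/(k_ct + k_tc).
- **Shell enrichment**: lipid identities and types are fixed once with
  exact whole-system counts; each frame a multinomial draw from the
  shell composition decides which molecules sit within the contact
  shell, the rest are placed beyond a guard radius (> 2× cutoff).
  Enrichment thus arises from molecules exchanging between shell and
  bulk — as in a real trajectory — and frames survive the
  coordinate-only trajectory dialect unchanged.
- **Umbrella windows**: independent draws from the biased Boltzmann
  density by inverse-CDF on a ≤1e-3 nm grid. Independence is deliberate
  (no Markov-chain sampler), so bootstrap/error theory applies cleanly
  and block-length estimation is exercised in its iid limit.

## Problem sizes used in validation

The bundled checks run at desk scale on one CPU: thickness recovery at
50 frames × 1000 lipids/leaflet on a 0.5 nm map grid; WHAM at the full
51-window × 10⁴-sample design; bootstrap calibration at 50 repetitions
of a 15-window × 2000-sample design with 50 bootstrap replicates each;
fingerprints at 1000 lipids × 200 frames. These sizes put sampling noise
well below the stated tolerances while keeping the whole suite at a few
minutes.

## Known limitations

- Orthorhombic boxes and a flat reference normal only; strongly vesicular
  or buckled membranes are out of scope.
- Local-mode maps smooth over the neighbour-window length (~3.5 nm by
  default); sub-window curvature detail is attenuated.
- The D–E bulk ratio is the whole-system census; leaflet-resolved bulk
  normalisation is not implemented.
- WHAM is 1-D with histogram (binned) likelihood; no MBAR, no 2-D
  surfaces, no kinetics.
- No residence-time or binding free-energy analysis of individual lipid
  sites; the binding-site grouping is a reporting convention.
- The generators produce geometry, not physics: no forces, no
  integrator, no lipid conformational ensembles.
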