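# Methods

## The model

`gohinge` simulates open/closed conformational transitions of hinged
two-domain proteins with a coarse-grained, structure-based (Gō) model at
Cα resolution, and analyzes the resulting ensembles the way two-state
folding/allostery studies do: fraction-of-native-contact reaction
coordinates, a transition-path–probability (p_TP) separatrix, per-residue
local-unfolding probabilities, per-contact formation probabilities, and
potentials of mean force over rigid-body coordinates.

### Single-well potentials

Each reference conformation (open `O`, closed `C`) defines one single-well
potential over the Cα trace:

- **Bonds** — harmonic in each consecutive Cα–Cα distance,
  `V = ½ k_b (r − r₀)²`, `k_b = 100 kcal/mol/Å²`, `r₀` the reference
  distance.
- **Pseudo-bond angles** — a generic double-basin term shared by both
  wells: `V(θ) = −h ln[G(θ; θ₁, w) + G(θ; θ₂, w)]` with Gaussians at
  θ₁ = 92° (helix-like) and θ₂ = 130° (extended), width w = 20°,
  depth scale h = 4 kcal/mol. Because it is conformation-independent it
  cancels out of the O/C energy difference; its purpose is to permit both
  compact and extended local geometry without pinning the backbone to one
  well's bending pattern.
- **Dihedrals** — per-well cosine terms `k_d (1 − cos(φ − φ₀))` with the
  minimum at that conformation's native torsion; `k_d = 3 kcal/mol`.
  Per-residue multipliers expose the local-backbone-stiffness axis used to
  emulate mutations: glycine-like softening (×0.2) and proline-like
  stiffening (×5) of every torsion containing the residue.
- **Native contacts** — a 12-10-6 well
  `V(r) = ε [13(r₀/r)¹² − 18(r₀/r)¹⁰ + 4(r₀/r)⁶]` for every residue pair
  with sequence separation ≥ 3 within 8 Å of Cα–Cα distance in the
  reference; the well minimum sits exactly at the native distance with
  depth ε. Contacts shared between O and C keep each well's own native
  distance inside that well's potential.
- **Excluded volume** — `ε_ev (σ/r)¹²` with σ = 4 Å for every non-contact
  pair with separation ≥ 3.

Contact depths are a uniform base value times a global `contact_scale`
(default 2.5, compensating the conformational entropy the generic angle
term introduces; a "weak" run simply passes a different scale). A
per-contact TSV override table can replace the uniform depths with an
arbitrary energy assignment.

### Double-well mixing

The two wells combine by exponential averaging,

    E(x) = −(1/β_mix) ln[ e^{−β_mix (E_O(x) + ε_O)} + e^{−β_mix E_C(x)} ],

computed with a two-term logsumexp (overflow-safe for any energy gap).
`ε_O` tunes the relative stability of the open state; `β_mix` sets how
sharply the surface interpolates between wells — as β_mix → ∞ the mixture
approaches `min(E_O + ε_O, E_C)` and the interwell barrier is maximal,
while small β_mix smooths the crossing and accelerates transitions.
Forces are the softmax-weighted combination of the single-well forces,
`F = w_O F_O + (1 − w_O) F_C`, and match central finite differences to
better than 10⁻⁵ relative error (tested).

### Dynamics

Langevin sampling uses the BAOAB splitting (half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity update, half-drift, half-kick), which has
excellent configurational accuracy at large timesteps. Units are
kcal/mol, Å, ps, with bead mass 1 in reduced units; defaults: 15 fs
timestep, friction 0.2 ps⁻¹, 300 K. Trajectories are bit-reproducible for
a fixed seed (single-threaded jitted kernel, one noise stream). Runs
abort with the failing step index if |E| exceeds 10⁶ kcal/mol.

## The synthetic two-state system

The generator builds a 44-residue chain (configurable) of two rigid
helix-like lobes (ideal Cα spiral: 1.5 Å rise, 100°/residue, consecutive
spacing exactly 3.8 Å) joined by a 4-residue hinge. The closed form is
produced by rigidly rotating the second lobe about an axis through the
central hinge Cα, so lobe-internal geometry — and therefore every
lobe-internal contact — is identical between conformations, while the
interdomain interface differs: the closed state gains a set of C-unique
contacts, the open state keeps a few O-unique ones. Three "ligand"
pseudo-contacts (the three shortest closed-state inter-lobe pairs just
outside the contact cutoff) bridge the closed interface, emulating
substrate-mediated stabilization. A small Gaussian jitter (0.05 Å,
seed-controlled) decorates the base chain; bond lengths are renormalized
to exactly 3.8 Å afterwards so chain geometry stays valid at any jitter.

Default hinge angles are 150° (open) and 80° (closed). The choices that
matter for desk-scale study are deliberate:

- **Interface size.** At 80° the closed interface holds ≈5 unique
  contacts (2 geometric + 3 ligand). Much larger interfaces produce
  interdomain barriers that a 10⁶-step run cannot cross often enough to
  measure populations.
- **Split contact depths.** The default model gives intradomain (shared)
  contacts a 0.9 kcal/mol base depth — deep enough that the lobes stay
  native-like (Q_all ≈ 0.87 at 300 K) — and interface (state-unique and
  ligand) contacts 0.45 kcal/mol, keeping the opening/closing barrier low
  enough for ~100–150 transition paths per 10⁶ steps. With uniform deep
  contacts the transition is unsampled; with uniform shallow contacts the
  lobes partially unfold and slow refolding modes make the populations
  drift on 10⁵-step timescales. Physically, the split mirrors the fact
  that interdomain and ligand-mediated interactions are weaker per
  residue pair than core packing.
- **β_mix = 0.1 (kcal/mol)⁻¹** places the mixture in a regime where the
  mixing weights differ appreciably between wells, so ε_O has measurable
  leverage on K_eq (the first-order sensitivity d ln K_eq/d ε_O =
  β (⟨w_O⟩_O − ⟨w_O⟩_C) is of order 0.3–0.5 per kcal/mol).

The 1-D oracle is overdamped Euler–Maruyama Brownian motion on
`V(x) = h((x/a)² − 1)²` with k_BT = 1. It supplies exact expectations
(free-diffusion increments at h = 0, symmetric occupancy, and the
diffusive p_TP ≤ ½ bound) against which the basin/path/separatrix
machinery is tested independently of the protein model.

## Ensemble analysis

Frames project onto: Q_O and Q_C (fraction of state-unique contacts
formed, a contact counting as formed when its distance is ≤ 1.1× its
native distance), Q_O,all / Q_C,all (including shared contacts; a config
flag selects which native distance scores a shared contact — default each
well's own), Cα rmsd to each reference after Kabsch superposition, and
center-of-mass distances between mapped domains with configured residue
ranges (e.g. connector helices) excluded.

**Basins** are located on the Q_C histogram (12 bins, lightly smoothed):
the C core at the highest-Q_C local maximum, the O core at the first
(lowest-Q_C) local maximum — the open and closed states need not separate
along Q_O, which is why Q_C is the identifying coordinate; core
membership is likewise decided along Q_C, with radii set by the flanking
histogram minima (floor two bins). A unimodal histogram raises an error
advising recalibration of β_mix/ε_O.

**Transition paths** are maximal frame segments that leave one basin core
and reach the other without re-entering the origin core; direction
(closing/opening) is recorded. **The separatrix** is the line
`Q_C = m Q_O + b` whose band (perpendicular half-width 0.02) maximizes
p_TP = (band frames on transition paths)/(band frames) over a grid
(m ∈ [−3, 3] × 61, 41 intercepts). Three numerical guards stabilize the
argmax against counting noise: bands with fewer than min(10, n/10) frames
are skipped, candidate lines must cross the middle half of the corridor
between the basin cores, and selection uses a shrinkage-regularized score
(20 pseudo-frames at p = 0.2); the *reported* p_TP is always the raw band
fraction. For diffusive dynamics p_TP ≤ 0.5; the suite asserts this
within three standard errors on the 1-D oracle and the calibrated toy.

**Partition:** TS = band ∩ transition-path frames (with direction);
every other frame is O or C by its side of the line; K_eq = N_C/N_O
(undefined and flagged when N_O = 0). **Calibration** of ε_O toward a
target K_eq measures K_eq from counts pooled over three replicas with
fresh seeds every iteration (first 10% of each run discarded as
equilibration; reusing one seed set would tune ε_O to that set's
sampling bias, and a per-replica ratio would let a single
stuck-in-one-basin run dominate — pooling the replicas under one jointly
fitted separatrix bounds its influence). Each update moves ε_O along the
exponential-reweighting prediction, d ln K_eq/d ε_O = β(⟨w_O⟩_O −
⟨w_O⟩_C), evaluated from the measured mixing weights of the current
iteration, with harmonic damping (1, 2/3, 1/2, …) and a ±2.5 kcal/mol
clamp. The ln K_eq(ε_O) response of a two-state system is
logistic-shaped — flat near balanced populations, steep on the flanks —
so slope-extrapolating solvers (plain secant, pooled regression) are
unstable under measurement noise; the damped reweighting step needs no
empirical slope and cannot overshoot into a flank. Calibration stops at
an ε_O whose own measurement lies within tolerance (default ±25% of the
target) and always returns a measured point, never an extrapolated one.

When several independent runs measure one model (calibration replicas,
or a multi-seed production set), `analyze_runs` fits the basins and the
separatrix once on the pooled frames and extracts transition paths per
run; K_eq is then the pooled count ratio. Fitting a separate line per
run was observably the dominant noise source in K_eq at these run
lengths.

## Local statistics

Backbone pseudodihedrals α(i−1, i) are torsions over Cα atoms
(i−2, i−1, i, i+1), wrapped to (−180°, 180°]; angular comparisons always
use the minimal-image difference. Per residue and ensemble, p_folded is
the fraction of frames whose α lies within 60° (p_rigid: 20°) of the
native reference: the O/C average when |Δα| < 20°, otherwise the best of
three candidates (O value, C value, midpoint). The TS value is the
unweighted mean of the closing- and opening-direction values; empty
ensembles propagate as missing, never zero. Contact probabilities use the
same 1.1× criterion per ensemble; contacts are O-/C-characteristic when
p_O − p_C ≥ 0.2 (resp. ≤ −0.2), display filters keep max(p_O, p_C) ≥ 0.5
and |Δp| ≥ 0.1 in comparisons (all inclusive, with a 10⁻⁹ epsilon so
exact-boundary values survive roundoff). Comparison order is always
perturbed − reference.

## Potentials of mean force

PMFs are raw-histogram estimates, `F = −k_B T ln(count/max count)` in
kcal/mol (minimum exactly 0, empty bins flagged), over 40 bins padded 2%
beyond the observed range; no reweighting is applied because the
trajectory samples the mixed potential directly. Ensemble mean positions
annotate the grids; 2-D surfaces export 0.5 kcal/mol contours.

## Problem sizes and verification scope

The default study conditions are those the test-suite and the
reproduction script use: the 44-residue toy, 10⁶-step production runs
(15 ns nominal), three production seeds, calibration replicas of
4–8 × 10⁵ steps. At these sizes a calibrated system shows ≥ 5 transition
paths per run (typically ~100) and the three-seed mean K_eq recovers the
calibration target within its ±25% band.

What passing tests show — and what they do not: the synthetic system
exercises the full machinery (two-state sampling, separatrix and TS
identification, per-residue/per-contact statistics, calibration) under
geometry with rigid lobes, a single hinge and a handful of interface
contacts. It does not emulate heterogeneous contact energies, loop
insertions, multi-domain pathways (e.g. separate LID-first/NMP-first
routes), or the system-specific contact topology of a real kinase; on
real PDB pairs the same pipeline runs unchanged, but its numerical
outputs there are not covered by the toy-based tests.

## Known limitations

- The contact builder is a geometric Cα rule with uniform (or two-tier)
  depths, not an all-atom contact/energy assignment; the override table
  is the escape hatch.
- K_eq from a 10⁶-step run retains ~20–40% stochastic error per seed even
  on the calibrated toy; the three-seed mean is the quantity the package
  reports.
- p_TP-optimal separatrix selection is a regularized grid argmax; with
  very coarse Q coordinates (few unique contacts) the discrete Q levels
  limit how finely the line can be placed.
- `match_temperature` assumes mean native-contact fraction decreases
  monotonically with temperature across the bracket.
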