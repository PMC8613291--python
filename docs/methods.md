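# Methods

## Model

`nucleodrop` simulates phase separation of nucleolar material inside a
crowded nucleus. Two components are resolved:

* **Chromatin** — every chromosome of a diploid genome is a string of beads
  at 1 Mb per bead (diameter 1 σ), typed A (euchromatin-like compartment),
  B (heterochromatin-like), or C (centromeric). A subset of beads carries a
  NAD flag (nucleolus-associated domain), obtained by thresholding a
  nucleolar-to-genomic signal track at 15.0 (strictly greater); homologous
  chromosomes share the mask. The 46-chromosome system lives in a spherical
  confinement of radius R_N = 19.7 σ representing a 5 µm nucleus.
* **Nucleolar particles** — N_P coarse-grained spheres representing
  aggregates of nucleolar proteins and RNA. At full scale N_P = 500 and the
  diameter σ_p = 0.5 σ; both follow from two closed-form estimates
  implemented in `units`: the particle count of a 2R_Nu droplet at a 1 µM
  protein concentration, N_P = (4π/3)·N_A·R_Nu³·c, and a space-filling
  volume balance, (2^{1/6}σ_p/2)³·N_P / R_N³ = (R_Nu/R_nucleus)³.

All non-bonded interactions are cut-and-shifted Lennard-Jones,
U(r) = 4ε[(σ_l/r)¹² − (σ_l/r)⁶] + E_cut for r < r_c and zero beyond, with
E_cut chosen so U(r_c) = 0. Defaults (energies in k_BT, lengths in σ):

| pair class | ε | σ_l | r_c |
|---|---|---|---|
| nucleolar–nucleolar | 1.8 | σ_p | 2.0 |
| nucleolar–NAD bead | 1.8 | (σ_p+1)/2 | 2.0 |
| nucleolar–non-NAD bead | 1.0 | (σ_p+1)/2 | 2.0 |
| chromatin B–B, C–C | 0.3 | 1.0 | 2.0 |
| all other chromatin pairs | 1.0 | 1.0 | 2^{1/6} (WCA) |

σ_l for particle–bead contacts uses arithmetic mixing. The compartment
energies are a deliberately minimal stand-in for Hi-C–derived interaction
maps (out of scope here): weak like-type attraction suffices for
qualitative A/B segregation and centromere clustering. Consecutive beads
are joined by harmonic bonds (rest length 1 σ, stiffness 300 k_BT/σ²,
giving ≲6 % bond fluctuations; the reference genome model's exact bonded
terms are not public). The wall is a purely repulsive shifted LJ
(ε = 1 k_BT, σ = 0.5 σ) acting on the gap to the sphere surface, so no
particle can reach |r| = R_N.

## Dynamics

Langevin dynamics with the BAOAB splitting, all masses 1, friction
m/γ with damping time γ = 10 τ_B, time step dt = 0.008 τ_B, reduced
temperature T = 1; identical seeds give bitwise-identical trajectories.
With friction and noise switched off the scheme reduces exactly to
velocity Verlet (used for energy-conservation checks). Neighbour handling
is a Verlet list (skin 0.3 σ, rebuilt when any particle accumulates half
the skin), exact by construction; directly bonded pairs are excluded from
non-bonded forces. Freshly assembled configurations are annealed in a
"push-off" mode that clamps per-step displacements (0.05 σ) instead of
aborting, then equilibrated with every nucleolar ε set to 1.0 k_BT so no
droplets nucleate during relaxation.

Unit map: σ = 5 µm / 19.7 = 0.254 µm; τ_B = 30πησ³/k_BT = 3.6 s at
η = 10⁻² Pa·s and T = 310 K (the model temperature is an effective one;
310 K is the reference used for the mapping). A frame recorded every 2000
steps spans 57.6 s.

Numerical notes: the full-step velocity kinetic-temperature estimator
carries the usual O(dt²) bias and reads a few percent high at dt = 0.008 on
stiff, dense systems — configurational averages are far more accurate; a
condensing attractive fluid releases latent heat faster than the weak
friction drains it, so thermostat calibration must use a non-condensing
system. Instabilities (per-step displacement > 0.5 σ or non-finite energy)
raise an error naming the step.

## Free-energy machinery

The coalescence coordinate is the radius of gyration R_g of the nucleolar
particles in either of two droplets, R_g = sqrt((1/N)Σ|r_i − r_com|²).
Membership is identified once by DBSCAN when a window is initialized and
kept fixed: R_g changes by <2 % when a particle hops between droplets, so
no on-the-fly relabeling is needed (members that evaporate keep feeling
the bias; frames where the restrained pair is no longer two clusters are
flagged). A harmonic restraint (K/2)(R_g − R_c)² pins 16 windows: R_c = 2.0
plus 2.5…6.0 σ in 0.25 σ steps, with K = 100 for R_c < 3.5, 150 for
3.5 ≤ R_c < 4.0, 200 above — stiffer springs where the two-droplet branch
pulls hardest. Eight-temperature replica exchange (1.00…1.14, step 0.02)
runs per window; neighbour swaps are attempted every 100 steps with
Metropolis acceptance min{1, exp[(1/T_i − 1/T_j)(U_i − U_j)]} on the full
potential including the bias, alternating even/odd pairs; velocities are
rescaled on accepted swaps. The CV is recorded every 400 steps.

WHAM recombines the per-rung, per-window histograms (default bin 0.05 σ,
stopping when window shifts move < 10⁻⁷ k_BT); adjacent windows without
histogram overlap raise a coverage warning naming the gap. Profiles are
anchored at the two-droplet basin (the rightmost local minimum), so
barrier heights read off directly. Uncertainties come from five
consecutive equal blocks, re-solving WHAM per block on the full-data grid;
the per-bin error is the standard deviation of the block estimates.
Per-temperature profiles are computed independently per rung (no
mixed-temperature reweighting), and the entropy along the coordinate is
the central difference S = −[F(T+ΔT) − F(T−ΔT)]/(2ΔT) with ΔT = 0.02 (one
ladder step); E = F + TS, so ΔF = ΔE − TΔS holds bin-wise by construction.

## Droplet analytics

Droplets are DBSCAN clusters of nucleolar particles; defaults
eps = 1.07·2^{1/6}·σ_p (≈7 % above the pair equilibrium distance),
min_samples = 4, and a minimum droplet size of 10 particles at full scale,
rescaled in proportion to the particle count for scaled presets (floor 5) —
a fixed cut of 10 would misclassify persisting droplets of 8–9 particles
in a 60-particle system. Identities are tracked frame-to-frame by maximal
shared-particle overlap; a decrease in the count produces a merge event
(two ids map onto one) or a vanish event. Events are classified by the
pre-event trend of the vanishing cluster's mean pairwise particle distance
over a 20-frame window: a relative rise above 25 % marks diffusion-limited
Ostwald ripening (evaporation), otherwise Brownian-motion-induced
coalescence. Coarsening exponents are least-squares slopes on log–log
axes; cluster-centre mean-squared displacements are time-averaged per
track, averaged across tracks, and fitted as MSD = 6 D t^α.

## Coalescence kinetics

The committor of a configuration is estimated by shooting: trials redraw
all velocities from Maxwell–Boltzmann, run unbiased dynamics, and classify
the final frame by droplet count (1 = merged, 2 = separated, anything else
is reported separately). The neck of a fusing pair is found by projecting
the droplet particles on the leading principal axis of their position
covariance and binning an axial density profile (20 bins, 2 edge bins
excluded). Because the sphere caps at the ends of the profile are always
sparse, the neck is the minimum *between the two density peaks*, not the
global interior minimum; a valley not clearly below both peaks (< 75 % of
the smaller peak) means the profile is unimodal and the droplets have
fused. Two radius estimators are provided: the maximal particle distance
from the axis in the minimum's slab (simple, but an extreme-value
statistic and noisy for small necks), and a cross-section area estimate
sqrt(n_neck/n_peak)·R_peak from slab particle counts, which is robust to
single stray particles and is used for growth kinetics. R₀ is the mean
pre-fusion droplet radius via R = sqrt(5/3)·R_g.

## Synthetic data and what it does (not) emulate

Presets scale the full setup down while preserving the nucleolar volume
fraction σ_p³N_P/R_N³ (tiny: 4 chromosomes × 50 beads diploid, 60
particles of σ_p = 0.360 σ in R_N = 7 σ). Synthetic genomes use blocky A/B
compartments (geometric blocks, mean 5 bins), one contiguous centromeric
run (6 %, mid-chromosome), and NAD signal tracks whose above-threshold
bins form long blocks (default 20 bins in topology building) — mirroring
the concentration of real NADs on a few chromosome arms — with exactly
⌈fraction·n⌉ bins above 15.0 and an overall NAD fraction of 0.3. Initial
chain configurations are self-avoiding confined walks, each restricted to
a per-chromosome sub-sphere: interphase chromosomes occupy territories and
do not mix on the timescales simulated, and without territories NAD blocks
of different chromosomes start interleaved. Scripted trajectories embed
exact ground truth (a merge at a known frame, an evaporation with a ~2×
pairwise-distance inflation, ballistic and fractional-Brownian centre
motion) for the analytics oracles. Every fixture is bit-for-bit
reproducible under its seed.

Two deliberate departures from a naive down-scaling, both forced by
desk-scale physics and established with dedicated runs:

* **No homogeneous nucleation.** At the model's volume fractions the
  particle phase sits essentially at vapor–liquid coexistence; dispersed
  particles never nucleate within 10⁶ steps without chromatin (with
  chromatin, NAD attraction nucleates droplets heterogeneously — the same
  asymmetry the full model exhibits, amplified). Coarsening studies
  therefore start from pre-nucleated droplets, placed on NAD blocks
  (network) or at fixed positions (control).
* **Kelvin evaporation.** Droplets of tens of particles have a strongly
  elevated vapor pressure; in the chromatin-free control they evaporate
  outright — an artifact with no full-scale counterpart. Comparison
  horizons are set after the control finishes coalescing (20 000 steps ≈
  160 τ_B ≈ ten simulated minutes) and the control droplets start close
  enough to meet before eroding.

Consequently, passing desk-scale tests demonstrates the *mechanisms* —
NAD-anchored droplets resist coalescence while free droplets merge;
network coarsening is slower than free coarsening; fusion necks widen
diffusively — not the full-scale numbers (the ~7 k_BT barrier, the 56/44
committor split, β = 0.1, 76 % BMC), which require the 46-chromosome
model with 10⁷-step ensembles.

## Desk-scale study protocols (`experiments`)

* **Droplet persistence** — two droplets of 30 particles (tiny preset),
  network droplets anchored on maximally spread NAD blocks, horizon 20 000
  steps, count = median over the last quarter of frames. The network keeps
  ≥2 droplets in the majority of seeds; the control coalesces to one.
* **Coarsening contrast** — six seeded droplets of ~26 particles
  (160 particles, diameter 0.4 σ, R = 7 σ), 40 000 steps. β is the log–log
  slope of the largest cluster's mass-radius (count^{1/3}) over the active
  multi-droplet phase; the mean cluster R_g is unusable at this scale
  (evaporation and chromatin-wetted shapes dominate it). Network β ≈ 0.07
  < control β ≈ 0.14 on disjoint seed sets.
* **Fusion kinetics** — two 150-particle droplets in contact, no
  chromatin, strongly overdamped (damping time 0.5 τ_B: the velocity
  relaxation must sit far below the ~30 τ_B fusion time for coalescence to
  be friction-controlled; at γ = 10 τ_B fusion is inertial and the
  apparent exponent rises to ~1). The normalized neck radius 2R(t)/R₀
  (area estimator) is averaged over 8 seeds, median-smoothed, and fitted
  on log–log over the rise window 0.15 < 2R/R₀ < 1. The protocol
  reproduces its exponent to ±0.01 across disjoint seed pools.

## Known limitations

* Chromatin–chromatin energetics are schematic (no Hi-C fitting); radial
  chromosome positioning and contact maps are not expected to be
  quantitative.
* The committor and umbrella machinery is exercised at desk scale on toy
  and tiny systems; full-scale profiles require cluster-scale compute with
  the provided presets.
* The neck-growth window at desk droplet sizes spans barely one decade;
  the fitted exponent is a regime indicator, not a precision measurement.
* DBSCAN parameters and the ripening-classification threshold are
  heuristics (exposed as configuration), calibrated on scripted
  trajectories with known ground truth.
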