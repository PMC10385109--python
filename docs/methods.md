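# Methods

## Hydraulic network model

A ladder device is abstracted as a resistor network: supply junctions
s₁…s_N along the parent channel, collector junctions c₁…c_N, one rung
edge per bifurcating channel (width W_B, length L_B) and N−1 supply plus
N−1 collector edges (width W_P, length L_D). Flow is injected at s₁; the
anti-parallel (counter-current) configuration drains c₁, the co-current
variant drains c_N. Junction pressure losses, entrance/inertial effects,
pulsatility, compliance and any RBC feedback on the effective viscosity
(Fåhræus–Lindqvist) are all neglected: the model is purely resistive, as
appropriate at these scales (Re ≪ 1).

Each rectangular segment gets the Poiseuille resistance R = 8µL/(πr⁴)
with r = D_h/2 and D_h = 2wh/(w+h). The hydraulic-diameter treatment is a
deliberate approximation; `segment_resistance(..., mode="exact_rectangular")`
evaluates the Fourier-series rectangular-duct solution instead for
sensitivity checks (for the 10 × 10 µm square duct the two differ by
~30 % in absolute resistance, but fractional flow ratios are far less
sensitive because every segment is rescaled together). Lengths are stored
in µm and converted to SI inside the resistance computation; resistances
are reported in Pa·s·m⁻³.

The nodal solve grounds the outlet, assembles the conductance Laplacian
and solves the dense linear system directly — networks have at most tens
of nodes, so sparse or iterative machinery would be pointless. Interior
mass conservation is verified to a relative 1e-10 on every solve. Rung
flows are reported signed (supply → collector orientation); for
geometry-derived ladders they are always positive, while arbitrary
heterogeneous resistance assignments can legitimately reverse a rung.
Fractional flow ratios Qᵢ/Q_P are invariant under global length scaling,
viscosity scaling and parent-flow scaling (all scale out of the linear
system); this is why the presets whose longitudinal lengths scale by a
common factor (L_D = 30/90/150 µm with L_B = 3 L_D and fixed widths)
share one ratio vector exactly.

Zero-length lead-in/lead-out stubs are omitted from the network; nonzero
lead lengths add series edges that carry the full parent flow and
therefore change only absolute pressures, never the flow split.

A note on the co-current limit: with identical rungs the co-current split
is exactly mirror-symmetric (a consequence of the supply ↔ collector
reversal symmetry) but **not** uniform — shared supply/collector segments
couple the branch paths, so the naive equal-path-resistance argument
fails; e.g. three equal rungs with equal segments split 0.364/0.273/0.364.
Uniformity is approached only when rung resistance dominates segment
resistance.

## Synthetic transit simulator

The simulator emulates the statistical structure of tracked-cell data
without cell mechanics:

- **Arrivals.** Homogeneous Poisson process with rate H_P·A_P·v/V_RBC
  (V_RBC = 94.1 µm³), which makes the parent tube hematocrit of the
  generated table equal the target by construction. Arrivals begin one
  maximum transit time before the first frame so the channel is already
  in steady state at frame 0.
- **Lateral state.** One normalized width coordinate x ∈ [0, 1], origin
  at the wall the rungs attach to. The channel height is collapsed: the
  cross-sectional evidence the pipeline works with is width-resolved
  only. The steady profile is Beta(κ, κ): κ = 1 uniform, larger κ
  centre-concentrated; κ < 1 (wall-peaked) is rejected as unphysical
  here. κ is a free stand-in for the parachute-flow concentration — no
  measured value exists, so recovery tests treat it as a configured
  input, not an estimand.
- **Junctions.** Branch i takes the flow fraction qᵢ = Qᵢ/(remaining
  supply flow). A cell exits iff x < x*, where the separating streamline
  x* satisfies F(x*) = qᵢ with F the cumulative flow profile (plug:
  x* = qᵢ; plane-parabolic u ∝ x(1−x): 3x*²−2x*³ = qᵢ). Survivors are
  remapped by streamline continuity, F(x′) = (F(x)−F(x*))/(1−F(x*)).
  At the last junction the supply ends and all remaining cells exit, so
  cell conservation is structural.
- **Migration.** Between junctions a cell's position is redrawn from the
  steady profile with probability 1−exp(−L_D/λ) (applied at segment
  entry), a memoryless surrogate for gradual cross-streamline migration.
  λ defaults to 200 µm — the order of the branch spacings studied — and
  is a free model parameter, not a measured one. λ = ∞ freezes positions.
- **Advection.** Each cell moves at the local mean velocity of its
  segment, derived from the flow solution with the parent inlet velocity
  set to `mean_velocity` (default 1 m/s, interpreted as the
  parent-channel mean). Local-mean advection is what makes tube and
  discharge hematocrit coincide in the null model, so Hᵢ/H_P ≈ 1 without
  phase separation.
- **Snapshots.** Cells are recorded at frame times (default 200 fps, 300
  frames per set, 3 sets). At 1 m/s a branch transit can complete between
  two frames; such a transit is recorded once, at the first frame time
  after branch entry, with the axial position clamped to the branch
  outlet (axial = L_B exactly). Region-of-interest counting uses
  half-open axial intervals, so these outlet rows are excluded from
  occupancy statistics while guaranteeing that every observable transit
  appears in the table — flux counting on the table then reproduces the
  simulator's ground-truth branch counts exactly. Branch transits whose
  entry precedes the first frame are not recorded (a tracker cannot
  observe a transition it did not see start); the resulting occupancy
  edge effect is at most a frame or two per set.
- **Analytic ground truth.** `junction_exit_probabilities` propagates the
  lateral distribution through the same junction rules by deterministic
  quadrature (grid of 4096 intervals), yielding the exact per-branch
  transit probability that the simulated counts are binomial draws of.
  In the null limit it reduces to Qᵢ/Q_P.

Not modelled, by design: excluded volume and cell–cell interactions
(point particles — hematocrit enters only through the arrival rate and
the user-chosen κ(H) mapping), deformation dynamics and parachute-shape
emergence, lingering at junction apexes, and plasma-layer physics.
Passing tests therefore demonstrate the pipeline's statistical
correctness on data with this structure, not that real suspensions obey
the Beta/relaxation model.

## Estimators

- **Tube hematocrit.** H = N̄·V_RBC/V_ROI with N̄ the per-frame cell
  count in the ROI averaged over all frames of all sets (empty frames
  count zero; the total frame count must be supplied or is inferred from
  the table). This is an occupancy quantity: under non-plug profiles it
  differs from the flux-weighted discharge hematocrit. No ROI dimensions
  are prescribed by the measurement definition itself, so the ROI is a
  required input with a packaged default: full channel cross-section,
  axial span 100 µm (clipped to the branch length), placed on the
  observed lead-in for the parent channel so that junction withdrawal
  cannot bias the parent estimate.
- **Fractional RBC flux.** Fᵢ counts distinct cells whose recorded
  channel first becomes Bᵢ within the counting window; re-detections
  never double-count, and cells still inside a branch at the window end
  are counted through their entry. F_P = Σ Fᵢ; a window with F_P = 0
  raises instead of returning silent zeros.
- **Cross-sections.** Histograms of the normalized lateral position in a
  slab of configurable half-width, 10 equal half-open bins on [0, 1] by
  default (final bin closed).
- **Replicates.** Mean and sample SD (n−1) across acquisition sets; a
  single set yields SD = NaN rather than 0. Set-level spread is the
  default error summary; per-frame spread is computable from the table
  when needed.

## Reproducibility and numerical choices

Per-set generators derive from the master seed as
`SeedSequence((seed, set_index))`; identical config + seed gives
byte-identical detection tables and reports (reports embed the expanded
config, its SHA-256 and the package version, and deliberately no
timestamps). Conservation tolerances: 1e-10 relative on flow sums, 1e-12
on oracle comparisons. The quadrature grid for exit probabilities (4096
intervals, linear CDF interpolation) is accurate to well below the
binomial noise of any simulated comparison. Degenerate inputs fail
loudly: non-positive dimensions, κ < 1, empty replicate lists, zero-flux
windows and disconnected networks all raise typed errors.

## Problem sizes

Default-protocol simulations (H_P = 0.10, 1 m/s, 3 × 300 frames) inject
roughly 1.6 × 10⁵ cells per set and produce detection tables of a few
hundred thousand rows; the vectorized simulator generates a set in well
under a second, and the full test suite plus the acceptance script run in
tens of seconds on one CPU.
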