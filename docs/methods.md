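# Methods

## The model

`smcsim` simulates a coarse-grained SMC complex (SMCC) coupled to a
bead–spring DNA, with the aim of producing DNA translocation and — with
a safety-belt anchor — loop extrusion as *emergent* outcomes of an
ATP-driven conformational cycle, DNA mechanics, and thermal motion.

### DNA

DNA is a discretized worm-like chain: 5 bp per bead, bond rest length
b = 1.7 nm, 301 beads by default (1.5 kbp, 510 nm contour).

* **Bonds** are finitely extensible with a harmonic-plus-logarithmic
  form, `U = -(K R0^2/2) ln(1-((r-r0)/R0)^2)`, K = 100 kBT/nm²,
  R0 = 0.5 nm.  The RMS bond fluctuation at 300 K is 0.1 nm.
* **Bending** is harmonic in the bond angle about π.  The stiffness is
  calibrated numerically so the discrete chain has persistence length
  Lp = 50 nm: solving `-b/ln<cos γ>` = 50 with the full
  `sin γ · exp(-κγ²/2)` measure gives κ = 29.24 kBT/rad² (the
  Kratky–Porod estimate Lp/b = 29.4 is the starting guess; the angular
  measure softens the chain slightly, so the calibrated value sits just
  below it).
* **Excluded volume** is a truncated-shifted (WCA) Lennard-Jones with
  contact distance 3.5 nm, the effective DNA diameter at physiological
  salt.  No electrostatics are modeled beyond this effective diameter.

### The SMC complex

Seven rigid bodies: four arm segments (two per coiled-coil arm, 25 nm
each, 18 beads at ≤1.5 nm spacing so the ring is impenetrable to DNA),
the hinge plate carrying the *top* binding site (17 beads, 3
attractive), the ATPase bridge carrying the *middle* site (8 beads, 2
attractive), and the kleisin arc (radius 7 nm, 17 beads, 3 attractive)
carrying the *bottom* site and the exterior safety-belt anchor bead.
Total protein mass 0.25 ag, distributed uniformly over beads (results
are mass-insensitive; see the invariance test).

Bodies are coupled by stiff bonds (100 kBT/nm²) and harmonic
angles/dihedrals: elbows 30, bridge–arm joints 100, hinge attachments
30, kleisin fold dihedrals 60 and 100 kBT/rad².  Each conformational
state's bead coordinates are constructed explicitly, and the equilibrium
value of every coupling is *measured* from those coordinates, so the
bonded terms are exactly consistent with the intended minimal-energy
shapes.

Geometry choices that the structural data leave open, calibrated here
and echoed into run manifests:

* **Arm opening.**  Open states tilt each lower arm 25° outward, giving
  an arm–arm aperture of ≥ 7 nm everywhere (a 3.5 nm chain passes with
  ≥ 2 nm clearance) and a hinge height of ≈ 44 nm; in the apo state the
  elbows meet on the axis and the aperture closes below the DNA
  diameter.  Wider openings lower the hinge and were found to shorten
  captured segments.
* **Kleisin fold.**  The fold is a rotation of the kleisin arc about the
  head–head axis, towards +x (the threading direction): 45° in the apo
  and ADP states, 160° when ATP is bound (130° for the `less_folding`
  variant).  The fold dihedrals are measured about the head–head axis
  between a lower-arm bead and an off-axis kleisin bead.
* **Bottom-site groove.**  The three bottom-site beads form a groove
  *along* the threading axis (span 4.4 nm, inset 1.4 nm towards the
  pocket interior).  The groove clamps the yaw of the bound motor on the
  DNA; without this orientation memory the complex tumbles between
  cycles and stepping loses its direction.  The top and middle sites are
  rows across the hinge plate and bridge, inset so DNA binds from the
  compartment interior only.

### Interactions and state switching

Protein–DNA pair terms use a WCA-core + attractive-tail decomposition:
`U = eps_rep·WCA + eps_att·TAIL` with mixed contact distance 2.5 nm and
attraction cutoff 2.5 σ.  With `eps_rep = eps_att = ε` this is exactly
the truncated-shifted Lennard-Jones of depth ε (3.2 kBT per top- and
middle-site bead, 11 kBT per bottom-site bead); with `eps_att = 0` it is
purely repulsive.  Binding sites are switched by moving these two
scalars, never by adding or removing beads, and the ATPase bridge
appears and disappears by toggling its excluded volume.

The cycle is apo (0) → ATP (1) → ADP (2) → apo, with exponential dwells
of mean 0.4, 1.6 and 0.4 μLsec; hydrolysis (exit from state 1) is rate
limiting.  Transitions are *never* gated on DNA binding, so futile
cycles occur naturally.  Each transition is applied as a short ramp
(50 nLsec before scale-down, with friction temporarily raised tenfold)
during which equilibrium angles, site strengths and the bridge excluded
volume interpolate linearly: the power stroke is a strongly damped
quasi-static sweep.  Instantaneous switching proved numerically violent
under the reduced-friction production profile (below): it ejected the
DNA from the compartments.

### Integration

Velocity-Verlet Langevin dynamics: per-bead friction γ = m/damp
(damp = 0.5 nLsec) with matching uniform random kicks; rigid bodies
aggregate bead forces into net force and torque and rotate by a
time-reversible midpoint (Richardson) quaternion update with principal
inertia tensors from the bead masses (a small spherical-bead term keeps
collinear bodies invertible; their axial angular momentum receives no
thermostat torque and stays at zero, which the equipartition tests
account for).  Forces are capped at 100 kBT/nm — far above every
physical force scale in the model — so that transient deep overlaps
during ramps cannot inject destabilizing kinetic energy.

Pair interactions act only between DNA and anything else; protein beads
interact through body rigidity and the bonded couplings.  The neighbour
list is a skin-buffered Verlet list with a bounding-sphere prune of the
DNA × protein block, rebuilt on displacement; it reproduces the
all-pairs force sum to 1e-10.

## Units and time calibration

Lengths in nm, energies in kBT at 300 K (1 kBT = 4.14 pN·nm), time in
nLsec (1e-9 of the simulation time unit).  Simulation time maps onto
experimental seconds only through the cycle calibration: one ATPase
cycle = 0.13 s, equivalently velocity in kbp/s = mean step (nm)/44.2.

## Production profile (scale-down)

The default experiment profile divides the dwell times *and* the
friction coefficients by 10 and integrates with a 1 pLsec timestep
(five times the base step; bond-oscillation × timestep stays below 0.3).
Because every relevant transport process in the model is diffusive,
dividing the time scales and multiplying the diffusivities by the same
factor preserves per-cycle statistics while cutting the cost of a cycle
fifty-fold; the residual effect is a larger inertial time relative to
the dwells, which inflates fluctuation at the margins.  The factor is
recorded in every manifest.  With this profile a full ATPase cycle of
the 411-bead system costs ≈ 2.4×10⁵ steps ≈ 6 s on one core.

Translocation statistics are gathered the way force-ramp traces are
assembled experimentally: each cycle runs independently from the same
threaded initial condition with fresh thermal history, so the motor
always starts near the middle of the finite 1.5 kbp track.

## What the experiments produce

* **Translocation (fixed tension).**  Mean forward step ≈ 60 nm at
  0.1 pN with individual steps up to ≈ 200 nm, decreasing towards a
  ≈ 30 nm plateau at ≥ 2 pN driven by the kleisin power stroke alone;
  captured-segment sizes exceed steps by a roughly tension-independent
  slippage; step distributions are wider than segment distributions
  (diffusive smearing while the complex is unbound after hydrolysis).
* **Loop extrusion.**  With one DNA bead bonded to the kleisin exterior
  anchor, translocation extrudes an asymmetric loop.  Fixed-endpoint
  runs start at 25% relative extension (≈ 0.04 pN) with a 400 bp loop
  and estimate per-cycle tension from the time-averaged restraint force
  on the frozen termini.

## Known limitations

* **Loop-extrusion stability.**  Under the reduced-friction profile the
  safety-belt runs are only intermittently processive: every few cycles
  the re-activated bottom site can grab the anchored slack (which the
  rigid geometry keeps ~10 nm from the site at all times) instead of
  the strand delivered by the closing arms, resetting the measured loop.
  The competition is won reliably by the delivered strand only when its
  descent from the hinge outruns the parked slack, which requires the
  full timescale separation of the unscaled model; runs at the unscaled
  dwell times are beyond a single-core budget.  Extruded-loop traces
  therefore show bursts of growth punctuated by resets, and the
  loop-extrusion summary numbers carry this caveat.  Translocation,
  which has no tethered slack, does not suffer from it.
* The model is mass-insensitive by design but not friction-insensitive
  at the margins: the scale-down factor trades fidelity of rare
  mechanical events (fence crossings, re-grab races) for tractability.
* No hydrodynamic interactions, no electrostatics, no sequence
  dependence, no load force on the complex itself.

## Synthetic data and what the tests show

There is no external data; all inputs are generated.  The thermalized
DNA builder samples bond angles directly from the bending Boltzmann
weight (Rayleigh proposal, `sin γ/γ` acceptance) — it reproduces the
analytic persistence length, and serves as the independent check on the
dynamics module's sampling.  Passing tests demonstrate internal
consistency of the model (equipartition, force–extension against the
Marko–Siggia interpolation, exponential dwells, topology conservation)
and reproduction of the reference step-size scales under the scaled
profile; they do not validate the model against experimental data
beyond the printed time-calibration constants.

## Numerical choices

* Steepest-descent relaxation (≤ 1e4 iterations, displacement-capped)
  removes construction clashes before dynamics.
* Tie-breaks: equidistant DNA beads resolve to the lower index.
* The captured segment is sampled once, at the last instant of the
  ATP-bound state.
* Loop sizes and positions are read at apo checkpoints (end of each
  apo dwell).
* The topology audit counts crossings of the DNA through a fan
  triangulation of the arm–arm–kleisin ring anchored at the
  kleisin-pocket centre, where the DNA pierces the surface steeply;
  an odd crossing count means threaded.
* The safety belt is a stiff harmonic bond (100 kBT/nm², rest 1.5 nm)
  between the designated kleisin exterior bead and one DNA bead.
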