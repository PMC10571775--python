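# Methods

`hippomech` couples three component models of growth control in the
*Drosophila* wing-disc epithelium — upstream Hippo-pathway signaling, the
force-dependent conformational gating of α-catenin at adherens junctions,
and the viscoelastic mechanics of a small cell network — into one
deterministic "biochemical signaling and mechanics" (BSM) model.  This
note records the model equations, the calibration of every parameter that
is not experimentally constrained, the numerical choices, and the known
limitations.

## 1. Hippo-pathway network (`hippo_network`)

Each cell has a well-mixed cytosol and `Nm` membrane regions, each apposed
to a region of a neighboring cell (or isolated).  Species: cytosolic Fat,
Ds, Fj, Dachs, Riq, Ex, Wts, active Yki and phospho-Yki; per-region
membrane Fat, Ds, the two trans-heterodimer orientations (this cell's Fat
bound to the neighbor's Ds and vice versa), membrane Dachs, Riq, Ex, and
the three Wts complexes WA (Wts–Dachs), WR (Wts–Riq), EW (Ex–Wts).

Structure of the ODEs (units nM, minutes):

* every species has constant production and first-order degradation;
  transmembrane proteins cycle between cytosol and membrane by
  delivery/recycling rates;
* trans binding of Fat and Ds follows mass action between the cell's free
  membrane Fat (Ds) and the neighbor's free membrane Ds (Fat).  Cytosolic
  Fj multiplies the Fat side by `1 + a_F·Fj/(K_J+Fj)` (≥ 1) and the Ds
  side by `1 − a_D·Fj/(K_J+Fj)` with `a_D < 1`, so Fat–Ds binding never
  stops in the absence of Fj;
* Dachs membrane binding is scaled by a decreasing Hill function of total
  membrane Fat (free + dimerized); Riq membrane binding by an increasing
  Hill function of total membrane Ds (both `K = 5 nM`, `n = 2`).  The
  Dlish/App route and Mnb are not explicit: they are absorbed into the
  Hill inhibition and the WR-driven inactivation rate, respectively;
* cytosolic Wts binds reversibly to membrane Dachs, Riq and Ex (the three
  ±k pairs of the representative Wts equation).  The membrane partners are
  treated as scaffolds (not consumed), so total Wts — free plus the three
  complexes — is exactly conserved when production, degradation, and the
  WA/WR fates are switched off; this is a tested invariant.
* WA is routed to degradation (0.5/min) and WR to inactivating
  phosphorylation (0.5/min).  Active Wts equals ΣEW (proportionality 1;
  the Yki phosphorylation constant absorbs the scale);
* Yki is inactivated at `k_phos·ΣEW + k_exYki·ΣEx_m` and reactivated by a
  constant dephosphorylation rate.  The defaults put most of the Yki
  regulation on the Wts route (`k_phos = 0.3`, `k_exYki = 0.005`
  1/(nM·min)): the direct Ex term is a weak parallel channel, which keeps
  Yki responsive to the mechanical input that acts through Wts.

The single-cell closure used for dose–response scans pairs each membrane
region with an identical mean-field neighbor ("self pairing"), which is
the natural embedding of one cell in a homogeneous tissue: raising Fat
production then raises the neighbor's Fat too, recruiting more Ds into
dimers, which is what makes membrane Riq rise while membrane Dachs falls
along a Fat-production scan.

Rate values are not experimentally constrained.  The defaults were chosen
once so that (i) each reversible binding pair sits mid-range at baseline
(complex/free ratios of order one), and (ii) the qualitative
Fat-production dose responses hold over a 10-fold scan; they ship as the
`HippoParams` defaults and are not tuned per experiment.

Steady states are found by stiff integration (LSODA, rtol 1e−6, atol
1e−9 nM) to long time followed by a Powell-hybrid root polish; the
convergence criterion is ‖rhs‖∞ < 1e−8 × the dominant production rate.
Scan points that fail to converge are flagged in the output and the scan
continues.

## 2. Three-state α-catenin gate (`catenin_gate`)

α-catenin under tension occupies three states — C1 (fully folded), C2 (M1
exposed), C3 (M1 and the jointly folding M2/M3 region open) — connected in
a chain with Bell rates `ku_i(f) = ku_i0·e^{+f·xu_i/kBT}` (unfolding) and
`kf_i(f) = kf_i0·e^{−f·xf_i/kBT}` (refolding).  The direction convention
is fixed by the physics: force promotes unfolding.  Equilibrium occupancy
follows detailed balance on the chain,
`C1:C2:C3 = 1 : u1/f1 : u1·u2/(f1·f2)`, normalized; this matches the
integrated kinetics to 1e−8 (tested oracle).

Calibration (kBT = 4.1 pN·nm, 25 °C).  With symmetric transition
distances the crossover of step i is `kBT·ln(kf_i0/ku_i0)/(2·x_i)`, so
the two measured crossovers pin the zero-force rate ratios exactly:

* step 1: `x = 1 nm`, ratio `e^{9/4.1}` → crossover 4.50 pN;
* step 2: `x = 2 nm`, ratio `e^{40/4.1}` → crossover 10.00 pN.

The M2/M3 step uses the larger transition distance, making full unfolding
switch-like over ~2 pN; this sharpness is what produces a genuine interior
maximum of Yki along the α-catenin axis at fixed tension (section 4).  The
absolute rate scale is free (common prefactors only rescale time):
`ku10 = 0.3/s` and `ku20 = 0.03/s` place the slowest relaxation eigenvalue
so that, starting fully folded at the first crossover, all occupancies
enter and stay within 0.01 (one percent of the total pool) of equilibrium
at 2.2 s — inside the observed 2–4 s window.  The derivation is
reproducible with `scripts/calibrate_catenin.py`.

Vinculin multiplies only the C2→C1 refolding rate by `1/(1 + V/K_V)`
(`K_V = 2`): it lowers the C1–C2 crossover force, leaves the C2–C3
crossover untouched, and affects Jub only through the occupancies.

Jub binding.  Each of the `N_cat` catenin molecules at a node offers one
Jub site whose association constant depends on its state, ordered
`a3 > a1 > a2` (C2 is the M1-exposed, binding-inhibited state; C3 the
open, high-affinity state).  The free level J solves
`pool = J + N_cat·Σ_s C_s·a_s J/(1+a_s J)` (Brent's method).  Defaults
`(a1, a2, a3) = (0.012, 0.008, 0.09)` per Jub unit with a pool of 80 per
node were fixed by four simultaneous requirements: the bound-Jub minimum
falls in the observed 5–9 pN window (it sits at 6.3 pN) with
high > zero-force > minimum ordering; bound Jub rises with α-catenin
number at the tissue-model operating tensions; it falls with α-catenin at
the high end of a 600 pN/node slice; and the 20- and 80-molecule tension
slices are monotone and triphasic respectively.  Only the ordering and
the minimum's location are experimentally constrained; the rest of the
triple is a model-consistency calibration, chosen once.

The chain-lifetime form `τ = τ0·e^{(E0−γF)/kBT}` is exposed as a utility
(`bell_lifetime`) with placeholder-scale defaults; the coupled model does
not use it.

## 3. Tissue mechanics (`tissue_mechanics`)

Geometry: seven regular hexagonal cells (edge 1 μm — the measured scale of
wing-disc cell edges), giving a belt graph of 24 nodes and 30 edges plus
7 virtual cell-center nodes carrying six transverse spokes each (the
apical actomyosin network; a chord pattern was considered and rejected as
indistinguishable at this resolution while harder to grow per-cell).
Each edge is a Kelvin–Voigt element in parallel with a constant
contractile active force (KVA).  Forces are standard per-edge
spring/dashpot/active forces along the current edge direction, which
reduces to the graph-Laplacian form in the linear regime while preserving
rotational invariance.  Imposed forces act on the 18 exterior nodes along
rays from the *current* patch centroid: anchoring the rays to a fixed
point makes rigid translation of the patch second-order unstable
(translating increases the summed node–center distances by convexity),
whereas the moving centroid keeps translation force-neutral.

Stationary states are computed by L-BFGS minimization of the elastic +
active + imposed-force potential; `integrate` provides the dynamic path
(LSODA) in inertial and overdamped modes, whose stationary states agree
(tested).  Node mass is 1 pg — mechanically irrelevant (stationary states
are mass-independent, per-edge damping ratio ≈ 5, i.e. effectively
overdamped) but numerically benign.  Stationarity is declared below a
maximum node speed of 1e−4 μm/s.

Two mechanical parameter sets ship:

* the module default `KN = KT = 100 pN/μm`, `Ξ = 100 pN·s/μm`,
  `FA = 100 pN` — a soft network used for the purely mechanical
  demonstrations (swelling, stretch/compression asymmetry, contraction);
* the coupled-model default `KN = KT = 1200 pN/μm`, `FA = 255 pN`
  (`BSMConfig.mech`) — cortical stiffness at the nN/μm scale reported for
  epithelial junctions.  This choice places baseline junctional tensions
  at ≈ 100–650 pN/node across the −100…+800 pN/node boundary-force range,
  so that at 30 α-catenin molecules per node the per-molecule force sits
  just above the bound-Jub minimum (≈ 7 pN under +100 pN/node): the
  tissue operates on the rising branch of the Jub–tension curve, which is
  the regime in which increased tension recruits Jub and raises Yki.

Growth follows `dl/dt = rate·l` per edge (relative growth, positivity
automatic).  Swelling of a cell rescales its rest lengths by
√(area factor), with no volume conservation.

## 4. The coupled BSM model (`bsm_coupler`)

Operator splitting per coupling step (default 30 s over a 30 min
horizon): mechanics is relaxed quasi-statically (it equilibrates in
seconds), the catenin/Jub module is taken at quasi-equilibrium (Jub binds
in seconds), and the Hippo ODEs plus the Jub–Wts pool advance with LSODA
on the minutes timescale.  Every run starts from the coupled steady state
at the initial mechanics, so growth-on and growth-off runs are compared
from the same initial condition.

Couplings, in order around the loop:

* node tension = mean of the positive (tensile) belt-edge tensions at the
  node; compressed edges contribute zero because α-catenin transduces
  tension only.  A cell's tension is the mean over its six corners, and
  in the tissue runs each cell's biochemistry uses one aggregate membrane
  region closed by the mean-field identical-neighbor assumption —
  intercellular interaction flows through the mechanics, as in the
  experiments this module reproduces;
* per-molecule force f = cell tension / α-catenin molecules per node
  (default 30, inside the measured 26–46 molecules per edge);
* cellular Jub follows production (default 250 nM/min) and decay
  (0.5/min); the node pool offered to catenin is `0.16·[Jub]`
  molecules/node per nM, a conversion fixed once so the default
  production yields the calibrated pool of 80;
* bound Jub sequesters cytosolic Wts by mass action
  (`k_on = 0.2 /(molecule·min)`, `k_off = 0.5 /min`); sequestered Wts is
  excluded from Ex activation and turns over at the common Wts
  degradation rate — without that turnover the sequestration flux would
  vanish at steady state and Jub could not regulate Yki at all;
* growth: every edge of a cell grows at `g0·max(0, Yki − Y0)` (capped),
  with `g0 = 2e−5 /(nM·s)`, `Y0 = 4 nM` — a reference just below the
  baseline Yki so growth rates are a few per cent per half hour — and
  shared edges growing at the mean of their owners' rates;
* the active force responds to growth:
  `FA = fa0·max(0, 1 − 0.35·rate/1e−4 s⁻¹)` per edge — the FA(dl/dt)
  dependence of the momentum balance, here a decreasing function because
  freshly assembled actomyosin engages fewer crossbridges.  This is the
  channel through which unbalanced growth lowers junctional tension and
  thereby (on the rising Jub branch) Yki: it produces both the mild
  negative growth feedback and the non-cell-autonomous boundary response
  to center perturbations.

The model is deterministic; identical configurations give bit-stable
results up to solver round-off (~1e−11 in Yki).

### Operating regimes and what the tests show

At the coupled defaults, per-molecule forces at 30 molecules/node are
≈ 3.2 / 7.3 / 21.5 pN under −100 / +100 / 800 pN/node boundary forces.
The non-cell-autonomous decrease of boundary Yki with center α-catenin is
produced by the growth → FA → tension route and requires the boundary
cells to sit on the rising branch of the bound-Jub curve; that holds
under tension (+100 and 800 pN/node) and is what the test suite asserts.
Under −100 pN/node compression the boundary operating point lies on the
folded-state plateau where the same feedback is neutral-to-inverted; the
compression variant of the non-autonomous effect is therefore not an
asserted property of this parameterization.  For the same reason the
growth-on ≤ growth-off comparison is asserted at the 800 pN/node setting,
where every cell is on the rising branch; at +100 pN/node a center cell
with strongly elevated α-catenin drops below the bound-Jub minimum and
the feedback locally inverts (by ~1e−4 nM).

Scan resolutions are scaled for desk-top runtimes: the phase diagram uses
a 10 × 10 grid (tension 100–1000 pN/node — the lower edge reflects that a
junction under active contraction never sees zero tension — by α-catenin
5–100 molecules/node), and perturbation sweeps use 5 points over 30–50
molecules/node (wild type upward), at a 30 min horizon with 30 s coupling
steps.

## 5. Configuration and outputs (`io_config`)

YAML/JSON configs with one section per sub-model; unknown keys are
rejected by name, omitted keys take package defaults, and figure presets
carry the published settings (boundary α-catenin 30 molecules/node,
boundary Jub production 250 nM/min, boundary forces ±100 / 800 pN).
Results are tidy CSV; each write also produces a JSON manifest whose
checksum is the SHA-256 of the canonicalized (key-sorted) config, so the
checksum is independent of key order in the file.

## 6. Limitations

* All Hippo rate constants, the Jub affinities, and the mechanical
  constants are behavior-calibrated, not fitted to measurements; only the
  crossover forces, the settling window, the bound-Jub minimum location,
  the α-catenin density range, and the printed experiment settings are
  observationally anchored.  Conclusions should be read as qualitative.
* The synthetic tissue is 7 cells with fixed topology: no cell
  rearrangements, T1 transitions, divisions, or cell–ECM interaction, and
  no Yki transcriptional feedback on upstream pathway components (a
  slower timescale than modeled here).  Crumbs/Merlin/Kibra inputs are
  constant.
* E-cadherin/β-catenin junction assembly is not modeled; the catenin pool
  per node is a fixed parameter.
* The mean-field closure of Fat–Ds trans binding inside the coupled runs
  removes direct biochemical cell–cell coupling; signaling asymmetries
  propagate only mechanically.  The multi-region geometry exists in
  `hippo_network` for stand-alone studies.
* Stochastic kinetics are out of scope; copy numbers (tens of molecules
  per node) are small enough that fluctuations would matter in reality.
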