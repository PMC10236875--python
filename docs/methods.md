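# Methods

This note documents the models inside `tavrsim`: what is simulated, which
parameters matter, the numerical choices, and what the synthetic data do and
do not represent.

## 1. Reduced aortic-root model

The root wall is a structured surface of revolution: nodes on a grid of
circumferential angle θ (degrees) × axial coordinate z (mm), radius r(z)
interpolated monotone-cubically (PCHIP) through the five standard levels —
LVOT, annulus, sinus of Valsalva, sinotubular junction, ascending aorta —
at configurable axial positions (defaults −10, 0, +10, +20, +30 mm) and
held constant beyond the measured levels. The annulus plane is z = 0;
caudal (ventricular) is negative z. Cusp nadirs default to θ = 0/120/240°
(NCC/RCC/LCC). Because diameters are recovered from the mesh perimeter, the
generated geometry round-trips the requested perimeter-derived diameters to
within a tenth of a millimetre at the default resolution.

**Wall mechanics.** Each node carries a radial spring (N/mm) assembled from
*distributed* densities (per mm² of wall) times the node's tributary area,
so that extracted pressures are mesh independent:

| contribution | density | default | note |
|---|---|---|---|
| thin-shell hoop | E_wall·t/r² | E_wall = 2 MPa, ν = 0.45, t = 2 mm | pressure per radial displacement of a cylindrical shell |
| foundation springs | constant | 0.0367 N/mm³ | surrounding cardiac structures; equals 0.02 N/mm per node on the default 72 × 0.5 mm grid of a 25 mm root |
| septal support | constant, z < 0 | 0.15 N/mm³ | the outflow tract is muscular septum, far stiffer radially than free aortic wall |
| leaflet band | E_leaf·t_leaf/r², 0 < z < z_sinus | E_leaf = 0.6 MPa, t_leaf = 2 mm | leaflets resist expansion between annulus and sinus |

The moduli and Poisson ratios (wall 2 MPa/0.45, leaflets 0.6 MPa/0.3,
calcium 4 MPa/0.3 with 0.6 MPa yield) are the standard linear-elastic
values used in this modelling field; the spring *densities* are modelling
configuration with no clinical measurement behind them, chosen once so that
contact pressures on cohort-typical anatomy span the clinically meaningful
0–0.6 MPa range.

**Calcium.** A requested (region × cusp) volume becomes a contiguous patch
of nodes: footprint = volume / nominal thickness (2 mm), placed at a seeded
uniform position inside the cusp's 120° sector and the region's axial band
(leaflet 0→z_sinus; upper leaflet z_sinus/2→z_sinus; device landing zone
−4→0; LVOT z_lvot→−4). Per-node volumes are rescaled so the deposited total
matches the request exactly; requests beyond sector-area × 6 mm raise a
capacity error. Mechanically a deposit acts as a stiff compressive
inclusion: stiffness density E_ca·t_ca/t_wall², elastic–perfectly-plastic
with the force capped at 0.6 MPa × area (1 % hardening) — so heavily loaded
calcified nodes saturate near the yield stress, which both mirrors the
physics of crushing nodules and makes CPMax insensitive to mesh refinement.
The seeded placement reflects that *where* a leaflet segment calcifies
varies from patient to patient; it is what makes calcium sometimes intersect
the conduction region of interest and sometimes not.

## 2. Device model

Each frame is a height profile of unloaded diameters (three-segment
inflow/waist/outflow shape, PCHIP-interpolated) plus a chronic-outward-force
characteristic: per mm of frame height, force is a plateau (45/52/60/70 N/mm
for the 23/26/29/34 mm sizes) below 0.7 × the local free diameter, decaying
linearly to zero at the free diameter. Frame heights are 45 mm (Evolut PRO
23/26/29) and 50 mm (Evolut R 34); the geometric profile follows published
device dimensions, while the force constants are configuration (the real
nitinol constitutive behaviour is proprietary) chosen to preserve the size
ordering — at any common diameter a larger device pushes harder, which
drives the observed size → CPMax trend. The pericardial wrap is metadata
only. Devices live in a versioned YAML catalog and custom devices can be
registered at run time.

## 3. Deployment solver

The frame is a stack of independent circumferential rings, one per
overlapped mesh row; expressing ring force per mm of height makes the
solution independent of the axial discretization. Deployment is staged
(sheath retraction releases ring groups inflow-first, 20 steps by default);
each stage drives the released rings to equilibrium with a damped
Newton-type fixed-point update: ΔR = ω(F_frame − F_wall)/(Σk_contact +
dF/dR), ω = 0.5, converged when the largest update < 10⁻⁴ mm, with rings
clipped to [crimped, free] radius. Lateral offset toward the outer
curvature is a prescribed shift of the frame axis (default 0), entering as
a first-order correction of the wall radius seen by each ring. The
`contact_penalty` spring substitutes for wall nodes whose stiffness is
non-finite (rigid-wall limit). Nodal reactions are translated to element
pressures by splitting each node's force equally over its incident
elements and dividing by element area — total force is conserved exactly.

Verification (in the test suite): a single-ring configuration matches the
algebraic 1-DOF equilibrium R\* = (a + k·r_wall)/(b + k) to 10⁻⁶ mm; a
rigid wall recovers the force-curve value at the wall diameter to 1 %;
wall-stiffness and device-size monotonicity hold; CPI and CPMax change by
< 5 % between the default 72 × 0.5 mm mesh and 144 × 0.25 mm on the
reference anatomy. The solver has no stochastic element: identical inputs
give bitwise-identical outputs.

## 4. Scores, ROI and planning

The ROI spans θ from the NCC membranous-septum landmark (default 30°),
through the mid-course (60°), to 25° laterally beyond the RCC landmark
(90°) — the extension points away from the NCC, following the course of the
bundle — and z ∈ [−15, 0] mm. The superior boundary is the annulus; MS
depths do not clip the ROI by default (they remain landmarks/covariates),
but `clip_to_ms_depth=True` bounds the ROI inferiorly by the interpolated
MS depth for sensitivity analyses. CPI counts ROI *area* with pressure
above a numerical-zero threshold (10⁻⁶ MPa); CPMax is the ROI maximum.
Risk flags use closed comparisons at 20 %, 0.40 MPa and 5 mm. Implantation
depth is read from the frame inflow edge at the NCC/LCC angles (equal for
a coaxial frame; a warning flags frames entirely above the annulus).

The planner re-solves deployment on a depth grid (default 0–10 mm by 1 mm;
high-implant preset 0–3 mm) and recommends the argmin of CPI with CPMax
then lower depth as tie-breaks; non-converged depths are recorded and
excluded. Residual risk is flagged when the best depth still has CPMax ≥
0.40 MPa. Smaller depth values mean higher implants throughout.

## 5. Synthetic cohorts

**Statistical mode** draws the MCD label at prevalence 33.8 %, then CPI and
CPMax from the group-conditional Gaussians (MCD: 28.3 ± 15.8 % and 0.51 ±
0.20 MPa; no MCD: 15.6 ± 11.2 % and 0.36 ± 0.24 MPa) coupled by a Gaussian
copula (ρ = 0.5 — the joint analyses imply correlation without quantifying
it). Scores are untruncated by default: clipping to [0, 100] / [0, ∞)
creates ties and point masses that bias rank statistics; a clip switch
exists for presentation. Implantation depth is Normal(6.2, 2.3) mm and the
per-patient MS depth Normal(3.4, 2.2) mm, censored at 0.

**Physics mode** samples anatomies from the cohort distributions (all
Table-level means/SDs are configurable), censors non-negative quantities at
0 — censoring preserves the configured means far better than resampling
for the strongly left-truncated MS depths (landmark means 5.1/3.5/1.7 mm
average 3.43; censoring yields ≈ 3.5) — picks the device by the clinical
annulus sizing chart (≤20 → 23 mm, ≤23 → 26 mm, ≤26 → 29 mm, else 34 mm;
under the annulus distribution this reproduces the observed device mix of
≈ 44 % 29-mm PRO and ≈ 34 % 34-mm R, and an explicit mix can be supplied
instead), deploys, and draws MCD from a logistic model on (CPI, CPMax,
depth) with coefficients (−4.95, 0.02 /%, 4.0 /MPa, 0.15 /mm): the
intercept is calibrated so prevalence ≈ 33.8 % on the default pipeline and
the CPMax term dominates the linear predictor, mirroring the multivariate
finding that CPMax is the independent predictor. Solver failures are
resampled up to a retry cap, then surfaced with `converged = False`.

**Secondary outcomes.** PPM is Bernoulli at the CPI-stratum incidences
(40.5 % / 14.0 %); length of stay is log-normal with the median fixed at
4.0 days and σ = 0.8145 matching the 6/2 quartile ratio (a two-parameter
law cannot also hit both quartiles at 2.0/6.0 exactly); LVEF change is
Normal(+3.8, 8) without MCD and Normal(−1.3, 8) with MCD around a
Normal(55, 10) baseline (group SDs are plausibility choices, not measured
values); survival is exponential at 0.0476 /yr baseline with hazard ratio
3.83 on the CPMax ≥ 0.40 MPa flag (both derived from the 3-year mortality
fractions 13.3 % / 42.1 %), administratively censored at 3 years.

What passing tests on these cohorts show: that the estimators recover the
structure the generator encodes (group means, prevalence, copula, AUC,
stratum incidences, hazard ratios) at Monte-Carlo precision. What they do
not show: anything about CT segmentation error, bicuspid anatomy,
inter-site heterogeneity, cardiac motion, or the true biological link
between contact pressure and conduction injury — the outcome models are
calibrated summaries, not mechanisms.

## 6. Statistics

Odds ratios use Wald log-OR 95 % CIs with Haldane–Anscombe 0.5 correction
(flagged) on zero cells; Fisher exact p-values are two-sided. AUCs are
empirical Mann–Whitney with midrank ties and DeLong variance for the CI and
the p-value against 0.5; the binormal closed form Φ((μ₁−μ₀)/√(σ₁²+σ₀²))
serves as the independent cross-check. Youden-optimal cutoffs break ties
toward the lowest threshold. Logistic models are maximum-likelihood
(statsmodels) with a flagged, lightly ridge-penalised refit on complete
separation. Survival uses lifelines (product-limit curves, log-rank, Cox).
The two-sample t-test defaults to the Welch correction. No multiplicity
adjustment is applied (significance at p < 0.05).

## 7. Problem sizes and tolerances

Default mesh 72 × 0.5 mm (≈ 7 300 nodes; one deployment solves in well
under a second); mesh-sensitivity studies double to 144 × 0.25 mm with a
5 % pass threshold. Group-conditional AUC simulations use 100 000 draws per
group (Monte-Carlo SE ≈ 0.0015); Cox recovery checks use 5 000 per arm;
cohort-recovery tests use 20 000–100 000 records. Physics-mode cohorts run
at full resolution (≈ 0.2 s/patient); the test suite uses reduced meshes
(16 × 2.5 mm) where only statistical structure is under test.

## 8. Known limitations

Rings are mechanically independent (no axial coupling or bending of the
frame); the wall responds only radially; contact is frictionless and
axisymmetric per ring, so circumferential pressure concentration arises
only from stiffness heterogeneity (calcium), not from non-circular
anatomy. Repositioning, post-dilatation, frame rotation, cardiac motion and
leaflet coaptation are not modelled; bicuspid geometry is out of scope
(tricuspid only). Absolute pressure magnitudes inherit the configured
force-curve and spring constants; analyses that depend only on ordering,
thresholds crossed, or cohort-level statistical structure are the intended
use.
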