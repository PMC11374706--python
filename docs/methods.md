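# Methods

`prefold` determines and interrogates unfolded-state conformational
ensembles of a protein domain free in solution ("isolated") and tethered
to a large particle such as the ribosome ("RNC mode"). This note records
the models implemented, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## PRE forward model

Transverse paramagnetic relaxation enhancements of backbone amide protons
are computed with the Solomon–Bloembergen equation,

    Γ₂ = (1/15) (μ₀/4π)² γ_H² g_e² μ_B² S(S+1) [4 J(0) + 3 J(ω_H)],
    J(ω) = ⟨r⁻⁶⟩ [ S² τ_c / (1 + (ω τ_c)²) + (1 − S²) τ_t / (1 + (ω τ_t)²) ],
    τ_t  = (τ_c⁻¹ + τ_i⁻¹)⁻¹,

with the electron–proton vector averaged over an explicit spin-label
rotamer ensemble at each labelling site. The order parameter factorizes
into radial and angular parts, S² = S²_ang · S²_rad, with
S²_rad = ⟨r⁻⁶⟩⁻¹⟨r⁻³⟩² and S²_ang = (4π/5) Σ_m |⟨Y₂ᵐ⟩|², evaluated via
the second-moment tensor identity S²_ang = (3 Tr M² − 1)/2,
M_ij = ⟨u_i u_j⟩. Electron spin relaxation is neglected (τ_c ≈ τ_r), the
standard regime for nitroxide labels.

The spin prefactor is implemented as S(S+1) with S = 1/2. A variant
S(S−1) form exists in print; it equals −1/3 of the standard prefactor for
S = 1/2 and therefore produces negative rates, so it is available only
behind the `printed_spin_prefactor` toggle and is never the default. The
worked value Γ₂ ≈ 3.86 s⁻¹ (single rotamer at r = 20 Å, τ_c = 5 ns,
800 MHz) verifies the standard choice.

Key parameters (`PREParameters`): spectrometer field 800 MHz; label
internal correlation time τ_i = 500 ps; chain rotational correlation time
τ_c (scanned 1–15 ns against data for isolated chains; 3 ns is the free-
chain value used in tethering corrections); ribosome tumbling
τ_r,70S = 4.3 μs (283 K in water; the underlying value is 3.3 μs per cP);
HMQC evolution delay Δ = 5.43 ms; per-residue linewidth rates R₂_H and
R₂_MQ (100 s⁻¹ defaults for synthetic work; experimental work requires a
measured table).

Rotamer attachment superposes the library backbone frame (N, CA, C and CB
where present) onto the labelling site by least squares. A rotamer is
discarded when any of its heavy atoms beyond CB lies strictly within
2.5 Å of any protein backbone or CB atom outside the site residue — the
boundary is exactly at 2.5 Å, a contact at the cutoff is retained.
Conformers for which any site retains no rotamer are excluded from the
ensemble and the weights renormalized.

The shipped rotamer library is synthetic: 216 nitroxide sidechain
conformers enumerated over five torsions in ideal geometry, electron at
the N–O bond midpoint. It reproduces the reach and angular spread of a
published methanethiosulfonate label library but is not that library;
`load_library` accepts an external one (multi-model PDB plus optional
`rotamer_id, weight` CSV).

Intensity ratios follow
I_para/I_dia = R₂ e^(−2ΔΓ₂)/(R₂+Γ₂) × R₂MQ/(R₂MQ+Γ₂), computed from the
ensemble-averaged Γ₂; the inverse map is a bracketed root find (the ratio
is strictly monotone in Γ₂), tolerance 10⁻⁶ s⁻¹. The factor-of-two
convention in the exponent is kept identical between the forward and
inverse directions. Reference "no structure" profiles are computed on a
fully extended polyalanine chain at τ_c = 5 ns, R₂ = R₂MQ = 100 s⁻¹.

### Tethering correction

For a tethered chain the tumbling of each electron–amide vector is slowed
according to its nascent-chain order parameter over the whole weighted
ensemble, S²_NC (electron approximated by the labelling-site Cα), and the
effective correlation time interpolates between free-chain and ribosome
tumbling: τ_C,eff = S²_NC τ_r,70S + (1 − S²_NC) τ_C,iso. A single
conformer gives the rigid limit S²_NC = 1.

## Maximum-entropy reweighting

Posterior conformer weights minimize
L(w) = θ S_KL(w|w⁰) + Σ_i (Σ_α w_α y_iᵅ − Y_i)²/(2σ_i²) over the simplex,
with S_KL = Σ w ln(w/w⁰) and N_eff = exp(−S_KL). Restraint kinds:
`gaussian` (always counted), `lower_bound` (counted only while the
back-calculated average is below the bound) and `upper_bound` (only while
above). Default Γ₂ bounds for broadened-out / unattenuated peaks are
64.5 / 2.2 s⁻¹ (isolated) and 96.0 / 3.7 s⁻¹ (tethered); bound σ is the
bound value times the relative error of the underlying intensity ratio.
Measured ratios classify as: indistinguishable from 1 (1 − ratio ≤ error)
→ upper bound; missing or indistinguishable from 0 (ratio ≤ error) →
lower bound; otherwise Gaussian, with Γ₂ from numerical inversion and σ
propagated through the local derivative of the ratio curve.

Optimization uses a softmax (log-weights) parameterization with one
pinned coordinate, an analytic gradient, L-BFGS, and three starts (prior,
uniform, data-greedy) to hedge the mild non-convexity introduced by
conditional bounds; convergence at gradient norm 10⁻⁹ or relative ΔL
10⁻¹⁴. On ≤4-conformer problems the optimizer agrees with brute-force
simplex grids in L to better than 10⁻⁴.

θ is selected by L-curve analysis: reweighting across a log-spaced grid,
then the point of maximum discrete curvature of the (S_KL, χ²_red) curve
on normalized log axes (3-point finite differences). If the prior already
fits (χ²_red ≤ 1 at the largest θ) the largest θ is kept; a flat curve
falls back, flagged, to the largest θ within 5% of the minimum χ².

χ²_red is evaluated against intensity ratios where the restraint carries
one (ensemble-average Γ₂ mapped through the ratio equation) and in Γ₂
space for bound restraints while active; degrees of freedom = number of
counted restraints, bounds counted only while active at the optimum. The
optimization target itself always works in Γ₂ space. Both wirings are
explicit and independently testable.

### Iterative tethered-chain protocol

Because τ_C,eff depends on the weights through S²_NC, tethered-chain
reweighting is iterated: each round receives the weights and correlation
times of the previous round, rebuilds the conformer-level Γ₂ matrix and
re-optimizes, stopping at 20 rounds or max |Δw| < 10⁻⁶, with a per-round
χ² trace and an oscillation flag (best-χ² round returned when the ‖Δw‖₁
trace turns non-monotone). The τ update is damped (default 0.5 of the
previous round retained): on small ensembles the weights → S²_NC →
τ_C,eff → Γ₂ feedback otherwise overshoots, because the r⁻⁶-dominated
radial moment responds strongly to any weight concentration. A
truth-consistent weight vector is an exact fixed point of the cycle
(verified in the tests); recovery from an uninformative start is reliable
only in the many-conformer, high-N_eff regime that full-scale simulation
ensembles provide, and the tests therefore probe the fixed point and the
convergence trace rather than uniform-start recovery at toy size.

## Observables

All ensemble statistics respect conformer weights. Cα radius of gyration
(global, windowed 21-residue local variant, and per-selection);
hydrodynamic radius via the empirical map
R_h = R_g / [α₁(R_g − α₂N^0.33)/(N^0.60 − N^0.33) + α₃] with α₁ = 0.216 Å⁻¹,
α₂ = 4.06 Å, α₃ = 0.821, ensemble-averaged as ⟨R_h⟩ = −1/ln⟨exp(−1/R_h)⟩
(the average appropriate to diffusion data) and carrying a ±5% systematic
uncertainty; gyration-tensor asphericity Δ = (3/2)Σ(λ_i−λ̄)²/(tr T)²;
smooth native-contact fraction Q = (1/N)Σ 1/(1+exp(β(r_ij − λr⁰_ij))) with
β = 5 Å⁻¹, λ = 1.8; Cα contact maps at 10 Å with a long-range profile
restricted to sequence separation ≥ 10 (both pair normalizations
exposed).

Secondary structure is an internal Kabsch–Sander implementation
(electrostatic hydrogen-bond model, −0.5 kcal/mol cutoff; α-helix from
consecutive i→i+4 turns, strand from parallel/antiparallel bridges),
deliberately restricted to the {H, E, coil} subset needed for
unfolded-state strand/helix content; it reproduces the DSSP assignment of
ideal helices and two-strand sheets exactly in the cross-check tests.

Surface area is an internal Shrake–Rupley estimator (golden-spiral sphere
points, 960 by default; heavy atoms, Bondi radii, 1.4 Å probe),
cross-checked against an independent implementation to 2%. The
polar/apolar split assigns atoms with |partial charge| ≤ 0.3 to the
apolar class using a packaged per-atom-name charge table approximating
protein force-field backbone charges; the split is exact
(apolar + polar = total). Coincident duplicate atoms are counted once. A
`per_frame_max` option reports the per-residue maximum over frames — the
"maximum theoretical surface" reading of an unfolded ensemble — as an
explicit interpretation.

Conformational clustering follows the GROMOS algorithm on best-fit Cα
RMSD (Kabsch superposition before RMSD): iteratively take the conformer
with the largest weighted neighbour count within the cutoff (12–18 Å is
the sensible range for unfolded chains) as a centre, remove the cluster,
repeat; populations are summed weights.

Block statistics: contiguous equal-size blocks (remainder truncated),
block means weighted by summed conformer weights so reweighting
propagates into the error; the right block count equals the number of
statistically independent segments and is user-supplied — no automatic
detection is attempted.

## Energetics

Conformational entropy uses the torsion-histogram scheme with
S = −k_B Σ p ln p per residue: Pro/Gly/Ala from P(φ,ψ); residues with ≤2
sidechain torsions from P(φ,ψ,χ₁,χ₂); longer sidechains from
S[P(φ,ψ,χ₁)] + Σ_n S[P(χ_n)] − S[P(χ₁)]. Backbone histograms use 50 bins
per dimension; joint histograms in ≥3 dimensions default to 12 bins per
dimension (a 50-bin joint grid cannot be populated at any realistic
ensemble size; configurable). Residues whose χ atoms are absent (for
example backbone-only models) fall back to the backbone histogram with a
warning. Differences between ensembles are reported per residue and in
total, with −TΔS at a user temperature (default 298 K) and half-data
block SEMs.

Solvation thermodynamics from surface-area changes:
ΔC = αΔASA_apolar + βΔASA_polar with α = 0.34 ± 0.11 and β = −0.12 ± 0.12
cal mol⁻¹K⁻¹Å⁻²; ΔH_solv(333 K) = γΔASA_apolar + δΔASA_polar with
γ = −8.44 and δ = +31.4 cal mol⁻¹Å⁻² (treated with 50% relative
uncertainty); ΔS_solv(T) = ΔC_apolar ln(T/385) − ΔC_polar ln(T/335). The
minus sign on the polar entropy term is implemented as printed in the
source relation, with a `polar_sign="standard"` toggle to the all-plus
convention; outputs record which convention produced them. Uncertainties
are first-order propagations over (α, β, γ, δ).

The ribosome-binding model converts a measured rotational correlation
time to a bound fraction, p_B = (τ_exp − τ_iso)/(S²_bound·τ_bound − τ_iso)
with τ_iso = 7.7 ns and τ_bound = 3003 ns at 298 K, and to a binding free
energy ΔΔG = RT ln(1 − p_B) (negative; its magnitude is the
unfolded-state destabilization). |ΔΔG| stays below 0.1 kcal/mol for
p_B ≤ 0.15 at 298 K.

The energetic summary combines −TΔS_conf, the protein-only ΔASA split
(context atoms excluded), the solvation relations and an optional
experimental binding term into one component table, with errors combined
from block SEMs and the empirical parameter uncertainties. Sign
convention: positive ΔASA means more exposed in the first
(tethered-like) ensemble.

## Thermodynamic fits

ln K_eq(T) is fit by weighted nonlinear least squares to
ln K = −(ΔH₀ + ΔC_p(T−T₀))/(RT) + (ΔS₀ + ΔC_p ln(T/T₀))/R with T₀ = 298 K
(the van't Hoff line is the ΔC_p = 0 special case); parameter sds come
from the covariance diagonal, correlations are reported (|r| ≥ 0.8 is the
expected regime when ΔG ≈ 0 across the span), a span below 20 K with a
free ΔC_p triggers a warning, and the fit is exactly consistent under
reference-temperature reparameterization. 1D spectra are fit as sums of
Lorentzians with analytic integrals (amplitude·π·half-width),
residual-resampling bootstrap errors (200 draws by default), and an
upper-limit population of 3× the noise floor for undetectable states;
populations are normalized integrals and convert to free energies via
ΔG = −RT ln(p_a/p_b), which is exactly additive over transitions computed
from one population vector. Pulsed-field-gradient decays give D from the
linear Stejskal–Tanner form and R_h = k_BT/(6πηD); Hahn-echo decays give
R₂ by single-exponential weighted fits.

## Synthetic generator

The generator replaces cluster-scale simulation ensembles so that every
stage is testable without downloads. It emulates: heterogeneous
unfolded-state ensembles of a 114-residue domain at controllable
compactness; terminal tethering next to a repulsive flat wall; noisy PRE
ratio tables forward-generated from known truth ensembles; and ln K_eq(T)
series from known (ΔH, ΔS, ΔC_p).

Chains carry full backbones (N, H, CA, CB, C, O) in ideal peptide
geometry built by internal-coordinate placement; (φ,ψ) are drawn from a
coil library — a Gaussian mixture of a broad β basin (50%), a
polyproline-II basin (40%) and a minor α basin (10%), matching an
unfolded state with a few percent residual strand and negligible helix.
Sampling is Metropolis Monte Carlo over single-residue (φ,ψ) pivot moves
with the coil library as independence proposal (the proposal cancels the
coil prior in the acceptance ratio, so the sampler is exact for the
constrained coil measure), Cα hard-sphere self-avoidance at 4.0 Å
(sequence separation ≥ 3), optional harmonic bias
U = k(R_g − R_g*)² in kT units, and for tethered chains a pinned terminal
Cα at the origin with every atom required to stay above a flat wall at
z = −3 Å. Defaults: 100 burn-in sweeps, 4 sweeps between samples.

The study-condition helpers restrain the 114-residue synthetic Ig-like
sequence (author numbering 637–750; the sequence is a synthetic stand-in
with a β-domain-like composition, including a cysteine at position 740)
to the ensemble-mean compactness of the two states — R_g* = 34.9 Å
(isolated-like) and 44.1 Å (tethered-like) — with k = 0.5 kT/Å², chosen
so the sampled means sit on the target within a few tenths of an Å while
retaining ~1 Å of R_g fluctuation. What the generator does not emulate:
sidechains beyond CB (so sidechain torsion entropy falls back to the
backbone class, and surface burial on compaction is far weaker than in
all-atom ensembles — measurable only below R_g ≈ 25 Å for this chain),
sequence-specific ribosome interactions, and residual secondary-structure
propensities. Passing tests on these ensembles demonstrate the
correctness of the estimators, not the real system's values for
burial-driven statistics.

A coarse-grained Cα model is provided as an alternative engine: 10–12
Lennard-Jones stickiness u = λ[5(σ/r)¹² − 6(σ/r)¹⁰] (minimum −λ at
r = σ) plus Debye–Hückel screened electrostatics
(κ⁻¹ = 16 Å and a 7 Å·kT Coulomb prefactor, roughly aqueous screening at
~12 mM divalent salt; both configurable), pairs separated by < 4 residues
excluded, sampled by crankshaft/pivot Metropolis Monte Carlo (symmetric
proposals, hence detailed balance, verified against a Boltzmann-weighted
importance-sampling oracle). The per-residue stickiness scale is a
hydrophobicity ranking on [0,1], an approximation labelled as such — the
published hydrophobicity-optimized parameter set is cited by reference
only and is not shipped.

PRE datasets add Gaussian noise to forward-calculated ratios, clip to
[0, 1.2] and classify by the bound rules; noise-free datasets still carry
a 0.01 ratio uncertainty so that downstream χ² scales stay well
conditioned. K_eq series add Gaussian noise to ln K.

## Problem sizes and reproduction choices

The test suite and the acceptance script run everything at desk scale:
study ensembles of 28–30 conformers (114 residues), method-development
ensembles of 30–100 conformers (38 residues), SASA at 120–240 sphere
points, bootstrap at 10–100 draws where only the mechanism is under test.
These sizes were chosen so the whole pipeline exercises in minutes on one
CPU while keeping every assertion's statistical margin explicit.

The acceptance script's thermodynamic refits generate ln K_eq(T) series
(278–303 K, six points, 0.05 noise on ln K) from the study's fitted
parameters: isolated ΔC_p = −1.7 kcal/mol/K with ΔH = −45 and
−TΔS = +44.4 kcal/mol at 298 K (absolute isolated values chosen to give a
marginally stable domain, ΔG(298) ≈ −0.6 kcal/mol, as observed for
two-state folders probed near their midpoint); tethered short-linker
differences ΔΔH = +32.9, −TΔΔS = −34.5, ΔΔC_p = +0.9; long-linker
−TΔΔS = −10.1 with ΔC_p = −1.2. The solvation computation uses the
study's +6 nm² surface-area increase as input with an apolar fraction of
0.7 — the typical apolar share of unfolded-state surface — which yields
−TΔS_solv ≈ +11.7 kcal/mol at 298 K.

## Known limitations

- Backbone-only chains understate surface burial and carry no sidechain
  entropy; absolute ΔASA and ΔS_conf between the two study ensembles are
  not comparable to all-atom values (signs and machinery are tested
  against strongly contrasted ensembles instead).
- The iterative tethered reweighting cycle is only locally stable at toy
  ensemble sizes (see above).
- The coil library is generic; no sequence-specific (φ,ψ) propensities.
- The Kabsch–Sander subset omits 3₁₀/π helices, turns and bends.
- GROMOS clustering is O(n²) in conformers and intended for ensembles of
  at most a few thousand frames.
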