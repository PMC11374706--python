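# prefold

Unfolded-state conformational ensembles on and off the ribosome:
paramagnetic relaxation enhancement (PRE) forward modelling with explicit
spin-label rotamers, Bayesian maximum-entropy ensemble reweighting,
structural and energetic ensemble observables, and temperature-dependent
folding thermodynamics — in one importable Python package.

## Who this is for

Most proteins begin folding while still tethered to the ribosome, and the
unfolded state they fold from is structurally different there: expanded,
more solvated, and entropically destabilized relative to the same chain
free in solution. Quantifying that difference requires connecting three
things that usually live in separate tools: PRE-NMR data (the only
residue-resolved probe of long-range structure in disordered chains),
conformer ensembles whose weights must be refined against those data, and
the entropy/solvation bookkeeping that turns structural differences into
folding energetics. `prefold` is a library for that pipeline, built for
structural biologists and biophysicists analysing disordered or nascent
chains. A synthetic-ensemble generator stands in for cluster-scale
molecular dynamics so every stage can be exercised and tested on a
laptop.

## The models at the core

**PRE forward model.** Transverse PRE rates of amide protons from the
Solomon–Bloembergen equation with a model-free spectral density,

    Γ₂ = (1/15)(μ₀/4π)² γ_H² g_e² μ_B² S(S+1) [4J(0) + 3J(ω_H)],
    J(ω) = ⟨r⁻⁶⟩ [S²τ_c/(1+(ωτ_c)²) + (1−S²)τ_t/(1+(ωτ_t)²)],

averaged over an explicit 216-rotamer nitroxide label ensemble with a
steric clash filter (2.5 Å against backbone + Cβ), S² = S²_ang·S²_rad.
For ribosome-tethered chains each electron–amide vector's correlation
time interpolates between free-chain and ribosome tumbling through its
ensemble order parameter: τ_C,eff = S²_NC τ_r,70S + (1−S²_NC) τ_C,iso.
Rates map to measurable intensity ratios via
I_para/I_dia = R₂e^(−2ΔΓ₂)/(R₂+Γ₂)·R₂MQ/(R₂MQ+Γ₂), invertible by root
finding.

**Maximum-entropy reweighting.** Posterior conformer weights minimize
L = θS_KL + Σᵢ(Σ_α w_α y_iᵅ − Y_i)²/2σ_i² over the simplex, with
Gaussian restraints plus conditional lower/upper bounds for peaks
broadened beyond detection or indistinguishable from unity; θ is chosen
by L-curve (S_KL vs reduced χ²) elbow analysis, and N_eff = exp(−S_KL)
reports how much of the prior survives. Tethered chains iterate
reweighting with τ_C,eff recycling to self-consistency.

**Observables and energetics.** Weighted R_g (global and local), an
empirical R_g→R_h map, asphericity, contact maps, native-contact
fraction, Kabsch–Sander secondary structure, Shrake–Rupley surface area
with a polar/apolar split, GROMOS clustering; torsion-histogram
conformational entropy (S = −k_BΣp ln p with residue-class rules),
surface-area solvation thermodynamics
(ΔC = αΔASA_apolar + βΔASA_polar, ΔH_solv, ΔS_solv, ΔG_solv), and the
ribosome-binding model ΔΔG = RT ln(1−p_B) with p_B from rotational
correlation times.

**Thermodynamic fits.** ln K_eq(T) to the constant-ΔC_p Gibbs–Helmholtz
form (van't Hoff as the ΔC_p = 0 case), Lorentzian lineshape fitting with
bootstrap population errors, Stejskal–Tanner diffusion and
Stokes–Einstein radii, Hahn-echo R₂ fits.

## Worked example

`examples/01_synthetic_ensembles.py` generates a compact (isolated-like)
and an expanded (ribosome-tethered-like) unfolded ensemble of the
114-residue synthetic domain and compares their size:

```
isolated-like  <Rg> =  34.8 +/- 0.1 A
tethered-like  <Rg> =  43.9 +/- 0.1 A
expansion on tethering: 26 %
```

The ~26% increase in the radius of gyration is the structural signature
of the tethered unfolded state. `examples/03_reweighting.py` then
forward-generates PRE restraints from known non-uniform conformer
weights and recovers the restrained observable by reweighting:

```
theta      chi2_red   S_KL    N_eff
    1e+03    1.0648   0.116   0.890
      193    0.1574   0.164   0.849
     37.3    0.0421   0.198   0.820
      7.2    0.0093   0.254   0.775
     ...
L-curve selected theta = 37.2759
<Rg>: truth 17.87 A | uniform prior 18.11 A | posterior 18.11 A (elbow theta) | 17.85 A (smallest theta)
```

χ²_red falls and N_eff (the effective fraction of prior conformers
retained) shrinks as θ decreases; the elbow balances fit against minimal
perturbation, and tight fitting recovers the ground-truth ensemble
average ⟨R_g⟩ to well under 1%. `examples/05_thermo_fits.py` refits a
synthetic folding equilibrium series:

```
Gibbs-Helmholtz fit at T0 = 298 K:
  dH   =   -45.4 +/- 1.0 kcal/mol
  -TdS =    44.8 +/- 1.0 kcal/mol
  dCp  =   -1.70 +/- 0.11 kcal/mol/K
  dG(298) = -0.58 kcal/mol
```

— folding is enthalpy-driven against a large entropic penalty; the
difference of these decompositions between a tethered chain and its
isolated counterpart is the thermodynamic fingerprint of co-translational
folding. The remaining examples cover the PRE forward profile against the
extended-chain reference (`02`), and the structural/energetic comparison
of compact vs expanded ensembles (`04`).

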