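# redoxmap

Geometric and spectroscopic analysis of redox-cofactor chains in
ion-pumping oxidoreductases.

Multi-center redox enzymes such as the sodium-pumping NADH:quinone
oxidoreductase (Na⁺-NQR) of *Vibrio cholerae* couple fast electron
tunneling between cofactors to much slower, conformationally gated ion
transport. Understanding that coupling from structures requires a set of
quantitative measurements that no single tool provides:

- **Cofactor edge-to-edge distances.** The tunneling-relevant distance R
  between two centers is the minimum separation of their conjugated
  ("edge") heavy atoms — the isoalloxazine ring system of a flavin, the
  Fe₂S₂ rhomb of an iron–sulfur cluster, the quinone head group.
- **The empirical tunneling ruler.**
  `log₁₀ k = 15 − 0.6·R − 3.1·(ΔG + λ)²/λ`
  with R in Å, driving force ΔG and reorganization energy λ in eV. In the
  activationless limit (ΔG = −λ) a 14 Å edge separation corresponds to
  rates of 10⁶–10⁷ s⁻¹; every additional 10 Å costs six orders of
  magnitude, so a domain motion of ~20 Å gates electron flow by ~10¹².
- **Rigid-body domain motions and helix tilts** between two conformational
  states: Kabsch superposition on a static core, then rotation
  angle/axis, screw translation and maximum Cα displacement of the mobile
  domain; helix tilts from principal-axis analysis.
- **Ion-site identification from coordination geometry.** Density alone
  cannot distinguish Na⁺ from water; a first shell of 4–6 oxygen ligands
  at 2.2–2.6 Å is the Na⁺ signature, 5–8 oxygens at 2.6–3.1 Å the K⁺
  signature.
- **Channel radius profiles** by probe-sphere maximization along a
  pathway, with constriction (gate) residue reporting.
- **Spectral component models**: zero-field Mössbauer Lorentzian doublets
  (isomer shift δ, quadrupole splitting ΔE_Q) and multi-component CW
  powder EPR first-derivative spectra (axial g∥/g⊥ plus isotropic
  components), simulated and least-squares fitted.
- **Synthetic fixtures** with exactly known ground truth for every stage:
  flavin pairs at a prescribed gap, [2Fe-2S] rhombs (Fe–Fe 2.70 Å,
  Fe–S 2.28 Å), ion shells, ring channels, hinge-motion state pairs, and
  seeded noisy spectra.

The package reads standard PDB/mmCIF models (via gemmi) and is aimed at
structural biologists and spectroscopists dissecting electron-transfer
chains and ion pathways in membrane redox complexes.

## Worked example

```sh
python examples/tunneling_ruler.py
```

prints

```
activationless rate at 7.2 Å: 4.8e+10 /s
activationless rate at 27.3 Å:  0.042 /s
rate ratio (any shared dG, lambda): 1.1e+12  (10^12.06)
distance at k = 10^6.5 /s: 14.2 Å (≈ 14 Å)
```

A cofactor pair at 7.2 Å transfers electrons ~10¹² times faster than the
same pair at 27.3 Å — the Franck–Condon term cancels in the ratio, so
this holds for any shared thermodynamics — and inverting the
activationless ruler at the middle of the fast band (10⁶·⁵ s⁻¹) returns
the familiar ~14 Å design limit for productive electron transfer chains.

The other examples follow the same pattern, one capability each:
`cofactor_distances.py` (registry extraction + distance/rate chain
report), `domain_motion_demo.py` (26° hinge recovery),
`ion_site_calls.py` (Na⁺ call for a 5-oxygen shell at 2.4 Å),
`pore_profiling.py` (1.30 Å constriction on an analytic ring channel),
`spectral_fits.py` (δ = 0.300, ΔE_Q = 0.510 mm/s doublet fit; 4.0%
radical weight recovery).

There is also a thin CLI for shell use:

```sh
redoxmap distances structure.pdb --order FMN_C201,FES_F502
redoxmap motion ref.pdb mov.pdb --core A:1-20 --domain B:1-20
redoxmap report --config analysis.yaml
```

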