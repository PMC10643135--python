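"""Mössbauer doublet and powder EPR component fits on seeded synthetic data.

Simulates the zero-field doublet of an intramembranous [2Fe-2S] cluster
(isomer shift 0.3 mm/s, quadrupole splitting 0.51 mm/s, linewidth 0.24 mm/s)
with 1% noise and re-fits it; then recovers the 4% radical weight of a
two-component X-band powder EPR spectrum.
"""

import numpy as np

from redoxmap import (EprComponent, MossbauerDoublet, Spectrum1D,
                      fit_epr_weights, fit_mossbauer, simulate_epr_powder,
                      simulate_mossbauer)
from redoxmap.fixtures import make_noisy_spectrum

axis = np.linspace(-2.0, 2.0, 801)
clean = simulate_mossbauer(MossbauerDoublet(0.3, 0.51, 0.24), axis)
sigma = 0.01 * np.max(np.abs(clean.ordinate))
spec = make_noisy_spectrum("mossbauer",
                           dict(isomer_shift=0.3, quadrupole_splitting=0.51,
                                linewidth=0.24),
                           noise_sigma=sigma, seed=1, axis=axis)
fit = fit_mossbauer(spec, MossbauerDoublet(0.25, 0.40, 0.30))
p = fit.params
print(f"Mössbauer fit: δ = {p.isomer_shift:.3f} mm/s, "
      f"ΔE_Q = {p.quadrupole_splitting:.3f} mm/s, Γ = {p.linewidth:.3f} mm/s")
print(f"  (ΔE_Q uncertainty ±{fit.stderr['quadrupole_splitting']:.4f} mm/s)")

fes = EprComponent("axial", g_parallel=2.02, g_perp=1.94, linewidth_g=50.0, weight=0.96)
rad = EprComponent("isotropic", g_iso=2.01, linewidth_g=20.0, weight=0.04)
field = np.linspace(300.0, 370.0, 1401)
mix = simulate_epr_powder([fes, rad], frequency_ghz=9.40, field_mt=field)
rng = np.random.default_rng(1)
noisy = Spectrum1D(field, mix.ordinate + rng.normal(0, 0.01 * np.max(np.abs(mix.ordinate)),
                                                    field.shape), frequency_ghz=9.40)
w = fit_epr_weights(noisy, [fes, rad])
print(f"EPR component weights: cluster {w[0]:.3f}, radical {w[1]:.3f}")
print("-> δ ≈ 0.3 / ΔE_Q ≈ 0.5 mm/s is a ferredoxin-like [2Fe-2S] signature;")
print("   the small g = 2.01 radical rides on the dominant axial cluster signal.")
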