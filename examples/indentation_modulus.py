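"""Uniaxial indentation: thickness and Young's modulus of one biofilm.

Simulates an 8 mm flat-probe approach on a 200 µm biofilm of known
stiffness, then recovers thickness and modulus from the curve alone.
"""

from biofilmmech import analyze_indentation_curve, generate_indentation_curve

curve, truth = generate_indentation_curve(
    modulus_pa=10_000.0,   # 10 kPa biofilm
    thickness_m=200e-6,
    noise_sd=0.02,         # 2% force noise
    seed=7,
)
result = analyze_indentation_curve(curve)

print(f"contact at            {result.contact.delta_contact * 1e6:.1f} um")
print(f"thickness             {result.contact.thickness * 1e6:.1f} um "
      f"(truth {truth['thickness_m'] * 1e6:.0f} um)")
print(f"slope (0-20% strain)  {result.fit.slope:.3f} N/m  (R^2 = {result.fit.r_squared:.4f})")
print(f"Young's modulus       {result.modulus_pa / 1e3:.2f} kPa "
      f"(truth {truth['modulus_pa'] / 1e3:.0f} kPa)")

# The modulus comes from E = slope (1 - v^2) / (2r) with v = 0.5 and
# r = 4 mm: the force-displacement slope over the first 20% of compression,
# scaled by probe geometry.
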