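"""Map CT values to bone stiffness through the density power laws.

Trabecular bone (HU -1000..500 -> density 0..1000 kg/m^3) follows
E = 0.0004 rho^2.01 and cortical bone (HU 501..1500 -> 1001..2000)
E = 0.005 rho^2.01; teeth split into dentin/enamel at 2000 HU and the
implant carries Ti-6Al-4V constants.
"""

from tmjfem import classify_tooth_tissue, density_to_E, hu_to_density, load_material_table

table = load_material_table()
print("HU -> density -> Young's modulus:")
for hu in (-1000, -250, 0, 300, 500, 501, 1000, 1400, 1500):
    rho = hu_to_density(hu, table)
    E = density_to_E(rho, table)
    print(f"  {hu:6d} HU -> {rho:7.1f} kg/m^3 -> {E:10.1f} MPa")

for hu in (1500, 2000, 2500):
    tissue, E, nu = classify_tooth_tissue(hu, table)
    print(f"  tooth voxel at {hu} HU -> {tissue:6s} (E = {E:,.0f} MPa)")

E_ti, nu_ti = table.constant("titanium")
print(f"  implant (Ti-6Al-4V): E = {E_ti:,.0f} MPa, nu = {nu_ti}")
print("\nNote the printed table's discontinuity between the two bone laws "
      "at the regime boundary is reproduced as published, not smoothed.")
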