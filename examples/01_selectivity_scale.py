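"""Convert between enantiomeric excess and the free-energy scale.

Regression is done on ΔΔG (kcal/mol), the free-energy gap between the
competing enantiodetermining transition states, because it is additive and
unbounded; e.e. saturates at 1 and compresses differences between good
catalysts.
"""

from chirtransfer import ddg_to_ee, ee_to_ddg

T = 298.15  # kelvin (25 °C)

for ee in (0.16, 0.68, 0.87, 0.92, 0.94):
    ddg = ee_to_ddg(ee, T)
    print(f"ee = {ee:5.0%}  ->  ddG = {ddg:5.3f} kcal/mol")

print()
ddg = 1.883
print(f"ddG = {ddg} kcal/mol ->  ee = {abs(ddg_to_ee(ddg, T)):.1%}")
print(
    "\nNote how the last few percent of e.e. cost disproportionate free "
    "energy: 92 -> 94% e.e. is ~0.17 kcal/mol, the same as 16 -> 30%."
)
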