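"""The censored spIC50 potency scale and its -pIC50 counterpart.

IC50 values spanning several orders of magnitude are mapped onto [0, 1]:
anything at or above 10,000 nM counts as inactive (spIC50 = 0), anything
at or below 1 nM as maximally potent (spIC50 = 1), and the interior is
linear in log10 IC50.  The -pIC50 representation (negative log-molar
concentration, range [5, 9]) is an exact affine transform of spIC50.
"""

from qsarscreen import pic50_to_sp, scale_ic50, sp_to_pic50

for ic50 in [0.5, 1.0, 10.0, 100.0, 1_000.0, 10_000.0, 50_000.0]:
    sp = scale_ic50(ic50)
    print(f"IC50 {ic50:>9.1f} nM  ->  spIC50 {sp:.3f}  ->  -pIC50 {sp_to_pic50(sp):.2f}")

# the two representations invert each other exactly on the interior
sp = pic50_to_sp(8.348)
print(f"\n-pIC50 8.348 corresponds to spIC50 {sp:.3f} "
      f"(IC50 = {10 ** (9 - 8.348):.1f} nM)")
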