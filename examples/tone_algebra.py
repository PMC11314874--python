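"""The LIP tone algebra on a grey chart: opposites and negative grey levels.

Builds a full-range ramp chart, extracts the tone profile along its middle
row, and prints a few tones next to their LIP opposites — the negative
grey levels that would exactly cancel them (f ⊕ ⊖f = 0, i.e. stacking the
obstacle and its opposite leaves the source unattenuated).
"""

import numpy as np

import lipimage as lp

chart = lp.generate_ramp_chart(width=256, height=32)
tones, opposites = lp.ramp_profile(chart)

print("tone f   opposite (light intensifier)   f (+) opp")
f = lp.ToneImage(tones[None, :], lp.GreyScale(256.0))
residue = lp.lip_add(f, lp.lip_negate(f)).values[0]
for i in (0, 64, 128, 192, 255):
    print(f"{tones[i]:6.0f}   {opposites[i]:12.2f}              {residue[i]:.1e}")

print()
print("A tone of 128 (transmittance 0.5) needs an opposite of -256:")
print("an amplifier doubling the source flux, so the pair is transparent.")
print("Residues at machine precision confirm the opposite is exact.")
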