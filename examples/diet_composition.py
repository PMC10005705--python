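"""Omega-3/6/9 bookkeeping for a two-ingredient high-fat diet.

The fat phase is 25 g soybean oil (~13% omega-3, ~55% omega-6, 18%
omega-9) plus 245 g lard (0% omega-3, 6-10% omega-6, 44-47% omega-9).
Range-valued compositions propagate to percentage intervals.
"""

from osteomech.synthetic import diet_omega_fractions

blend = diet_omega_fractions(
    [
        (25.0, (0.13, 0.55, 0.18)),  # soybean oil
        (245.0, (0.0, (0.06, 0.10), (0.44, 0.47))),  # lard
    ]
)

for name, point, interval in [
    ("omega-3", blend.omega3, blend.omega3_interval),
    ("omega-6", blend.omega6, blend.omega6_interval),
    ("omega-9", blend.omega9, blend.omega9_interval),
]:
    print(f"{name}: {point:5.2f}%  (range {interval[0]:.2f}-{interval[1]:.2f}%)")
# The omega-9 interval brackets the 44.2% a commercial 60 kcal%-fat
# rodent diet lists for its fat phase; omega-3 stays near 1.2%.
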