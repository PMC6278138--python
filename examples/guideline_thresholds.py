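"""Print the homogeneity guideline table for a decile distribution.

The class boundaries are the Homogeneity Index values of block distributions:
s equally populated consecutive deciles.  An area scoring at or above the
4-decile block (68.53) is acceptably homogeneous; below the 6-decile block
(46.62) it is heterogeneous and should not carry a single summary decile.
"""

from ordhom import block, class_thresholds, homogeneity_index

th = class_thresholds(10)
print("Homogeneity guideline thresholds for a decile scale (n = 10)")
print(f"  class A: {th.hi4:6.2f} <= HI <= 100.00   acceptably homogeneous")
print(f"  class B: {th.hi5:6.2f} <= HI < {th.hi4:6.2f}   marginal heterogeneity")
print(f"  class C: {th.hi6:6.2f} <= HI < {th.hi5:6.2f}   judgement required")
print(f"  class D:   0.00 <= HI < {th.hi6:6.2f}   heterogeneous")
print()
print("HI over all block sizes (strictly decreasing in s):")
for s in range(1, 11):
    print(f"  s={s:2d}  HI = {homogeneity_index(block(s, 10)):6.2f}")
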