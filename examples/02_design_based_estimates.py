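"""Design-based prevalence and lift on the hand-checkable 8-person fixture.

The tiny fixture (weights 1,2,3,4,1,2,3,4; two strata of two PSUs) is small
enough to verify every number by hand: condition A is held by persons with
weights 1, 2, 3 so its weighted prevalence is 6/20 = 30%, and the B+C
combination's lift is 0.35 / (0.50 x 0.60) = 7/6.
"""

from morbmine import estimate_lift, estimate_proportion, make_fixture

ds = make_fixture("tiny_handcheck")

prev = estimate_proportion(ds.holds_mask(1 << 0).astype(float), ds)
print(f"prevalence of condition A: {100 * prev.point:.1f}% "
      f"(SE {100 * prev.se:.2f} pp, 95% CI {100 * prev.lo:.1f}-{100 * prev.hi:.1f}%)")

lift = estimate_lift((1, 2), ds)
print(f"lift of B+C: {lift.point:.4f} (95% CI {lift.lo:.2f}-{lift.hi:.2f})")

# The SE comes from Taylor linearization over the 2x2 stratum/PSU design
# (design df = 2), and the lift interval is built on the log scale, which is
# why it is asymmetric around the point estimate.
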