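"""Receptive-field algebra of the dense atrous pyramid bottleneck.

A k x k convolution with dilation d sees RF = k + (k-1)(d-1) input
pixels per axis; stacking two convolutions with fields K1, K2 gives
K1 + K2 - 1.  In the pruned dense pyramid the d=3 branch consumes the
output of the d=1 -> d=2 chain, so two 7-wide fields superpose.
"""

from scdunet import (denseaspp_input_sets, dilated_receptive_field,
                     max_receptive_field)

kernel, dilations = 3, (1, 2, 3)
schedule = denseaspp_input_sets(dilations)

print("branch | dilation | field | reads branches")
for l, d in enumerate(schedule.dilations, start=1):
    rf = dilated_receptive_field(kernel, d)
    reads = sorted(schedule.input_sets[l - 1]) or "-"
    print(f"  {l}    |    {d}     |  {rf}   | {reads}")

print(f"\nmaximum receptive field through the dense chain: "
      f"{max_receptive_field(kernel, dilations)}")
print("(3 -> 3+5-1 = 7 -> 7+7-1 = 13: the deepest path stacks all three branches)")
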