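"""Fuse multi-reader seating votes by majority rule.

Five readers each mark every joint as correctly or incorrectly seated; the
final label goes to the strict majority.  The histogram below is the
five-reader vote distribution over a 120-joint cohort.
"""

from condyseat import fuse_histogram

# joints by number of readers voting "incorrectly seated" (0..5)
histogram = [63, 12, 10, 14, 4, 17]

summary = fuse_histogram(histogram)
for key, value in summary.items():
    print(f"{key}: {value}")

# 85 joints fuse to "correct" and 35 to "incorrect"; 80 are unanimous and for
# 40 the majority rule had to break a disagreement - the non-unanimous cases
# are where automated assessment is hardest and most useful.
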