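"""Attribute importance scores from the built-in two-segment utilities.

Importance is an attribute's utility range as a percentage of the sum of
all attribute ranges within a class: the share of the achievable utility
swing that attribute controls.
"""

import pandas as pd

from partworth import ebp_preset, importance_scores

attributes, shares, utilities = ebp_preset()
table = importance_scores(utilities, attributes)

wide = table.pivot(index="attribute", columns="class", values=["importance", "rank"])
wide.columns = [f"{what}_seg{cls}" for what, cls in wide.columns]
wide = wide.loc[[a.name for a in attributes]]
pd.set_option("display.width", 120)
print(wide.round(1).to_string())

for cls, share in zip((1, 2), shares):
    top = table[table["class"] == cls].nsmallest(3, "rank")
    print(f"\nsegment {cls} ({share:.0%} of respondents) — top attributes:")
    for _, row in top.iterrows():
        print(f"  {int(row['rank'])}. {row['attribute']}: {row['importance']:.1f}%")
# Segment 1 weighs supervisor support and expected client benefit most;
# segment 2 is driven by trainer quality and an active training process.
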