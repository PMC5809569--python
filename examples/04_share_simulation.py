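"""Randomized first choice shares: basic vs enhanced training packages.

Uses the built-in segment utilities in class-level mode (each segment is
a share-weighted pseudo-respondent), simulates the basic-vs-enhanced
training scenario, then sweeps the enhanced package's supervisor-support
level to show how supervisor backing shifts uptake of the more demanding
package.
"""

from partworth import (
    RFCConfig,
    ebp_preset,
    ebp_training_scenarios,
    rfc_shares_by_class,
    sensitivity_sweep,
)
from partworth.postestimation import IndividualPartWorths

attributes, shares, utilities = ebp_preset()
scenario, supervisor = ebp_training_scenarios()
config = RFCConfig(iterations=200_000, attribute_error_scale=1.0, seed=1)

result = rfc_shares_by_class(scenario, utilities, shares, attributes, config)
print("baseline scenario (no supervisor-support difference):")
for name, share, se in zip(result.profile_names, result.shares, result.se):
    print(f"  {name}: {share:.1f}%  (MC se {se:.2f})")

# sweep supervisor support for the enhanced package, level 1 (none) -> 4 (100%)
pseudo = IndividualPartWorths(
    values=utilities, respondent_ids=["seg1", "seg2"], attributes=attributes
)
swept = sensitivity_sweep(
    scenario, "Enhanced implementation", supervisor, [1, 2, 3, 4], pseudo, config
)
print("\nenhanced-package share as its supervisor support rises (unweighted segments):")
idx = result.profile_names.index("Enhanced implementation")
for level in (1, 2, 3, 4):
    print(f"  supervisor level {level}: {swept[level].shares[idx]:.1f}%")
# The enhanced share climbs monotonically with supervisor support — the
# qualitative pattern the study reported from its sensitivity simulations.
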