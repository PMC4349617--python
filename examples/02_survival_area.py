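"""The disease-free survival-area statistic between two patient groups.

Asurv is the signed area between the groups' Kaplan-Meier curves from 0
to t_max, normalized by t_max.  With the non-metastasis group on top it
is positive; 1.0 would mean perfect separation over the whole window.
"""

from metasurv import (
    SimulationConfig,
    asurv_from_labels,
    km_estimate,
    simulate_cohort,
)
from metasurv.survival import default_t_max

cohort, _ = simulate_cohort(SimulationConfig(seed=7))
t_max = default_t_max(cohort)

curve_nm = km_estimate(
    cohort.dfs_months[cohort.class_labels == 0],
    cohort.event_flags[cohort.class_labels == 0],
)
print(f"non-distant KM curve drops at {curve_nm.breakpoints.size} event times")

area = asurv_from_labels(cohort, cohort.class_labels, t_max)
print(f"t_max = {t_max:.1f} months, group sizes = {area.group_sizes}")
print(f"real-class Asurv = {100 * area.signed_area_fraction:.2f}%")

swapped = asurv_from_labels(cohort, 1 - cohort.class_labels, t_max)
print(f"groups swapped  -> {100 * swapped.signed_area_fraction:.2f}% (sign flips)")
print()
print("A large positive area means the predicted non-metastasis group")
print("survives disease-free much longer than the predicted metastasis")
print("group; candidate gene sets are rewarded for exactly that.")
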