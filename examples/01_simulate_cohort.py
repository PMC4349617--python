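"""Generate a synthetic two-class cohort with planted prognostic markers.

The generator mirrors the structure of a surgical lung-cancer series:
two metastasis classes with strongly separated disease-free survival,
a few hundred candidate transcripts, and a small planted informative
subset that carries the class signal.
"""

from metasurv import SimulationConfig, dfs_t_test, simulate_cohort

config = SimulationConfig(seed=42)
cohort, informative = simulate_cohort(config)

t_stat, p_value, (mean_nm, mean_m) = dfs_t_test(cohort)

print(f"cohort: {cohort.n_samples} samples x {cohort.n_transcripts} transcripts")
print(f"planted informative transcripts: {informative}")
print(f"mean DFS non-distant: {mean_nm:.1f} months, distant: {mean_m:.1f} months")
print(f"two-sample t-test p = {p_value:.2e}")
print()
print("The two classes separate sharply in disease-free survival (p far")
print("below 0.001), which is exactly the structure the survival-informed")
print("fitness exploits during gene selection.")
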