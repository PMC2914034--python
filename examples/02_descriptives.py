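"""Table-1-style descriptives: who are the churners?

Summarizes baseline and round-varying characteristics by transition group
(none / single / multiple Medicaid transitions) with Welch-t or
two-proportion-z p-values against the continuously enrolled group.
"""

from medchurn import default_config, generate_dataset, summarize_by_group

dataset, _ = generate_dataset(default_config(n_persons=3000, seed=7))

table = summarize_by_group(dataset, ["age", "employed", "healthy", "income",
                                     "er_visits", "outpatient_visits", "rx_fills"])
print(table.round(3).to_string())
print("\ngroup person counts:", table.attrs["group_counts"])

# Continuously enrolled persons are older and less often employed than
# multiple-transition persons (enrollment stability is tied to age and
# employment in the generator, as in observed Medicaid populations).
# Binary rows are percentages; utilization rows are per person-round means.
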