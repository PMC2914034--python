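"""Small replicated recovery studies: why the CRE and dynamic specs matter.

Simulates panels whose individual effect loads on employment/health history
(with employment-linked churn), then measures how well each specification
recovers the true multiple-transition coefficient, and how the dynamic
specification recovers true state dependence.  Sizes here are kept small
for a quick demonstration; the test-suite runs the full 200-replication
versions.
"""

from medchurn.studies import dynamic_recovery_study, static_cre_bias_study

s = static_cre_bias_study(n_reps=10, n_persons=1500, master_seed=1)
print("multiple-transition coefficient (truth 0.10):")
print(f"  base static spec:  mean error {s['err_base'].mean():+.4f}")
print(f"  CRE (Mundlak) spec: mean error {s['err_cre'].mean():+.4f}")
print(f"  base worse than CRE in {(s['err_base'].abs() > s['err_cre'].abs()).mean():.0%} of reps")

d = dynamic_recovery_study(n_reps=10, n_persons=1500, rho=0.05, master_seed=2)
print("\nstate dependence (truth rho = 0.05 per lagged count):")
print(f"  mean rho estimate {d['rho_hat'].mean():.4f} (sd {d['rho_hat'].std(ddof=1):.4f})")
print(f"  initial-condition coefficient positive in {(d['initial_hat'] > 0).mean():.0%} of reps,"
      f" mean z = {d['initial_z'].mean():.1f}")

# The base static spec overstates the multiple-transition effect because
# churners differ in employment history, which the individual effect loads
# on; adding within-person means removes nearly all of that bias.  The
# dynamic spec recovers rho and loads strongly on the initial count.
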