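"""Run the population analysis on a small synthetic deactivation study.

Generates a seeded population (V and nonV FRA units plus RLF units, each
measured in control / deactivated / recovery conditions with sampled
deactivation effects), then assembles the full nonparametric battery:
modulation-index distributions compared between receptive-field classes
(Kolmogorov-Smirnov), the RLF type-transition table (Fisher's exact r x 2),
half-maximum and DI condition medians with Friedman tests and
Sidak-corrected Wilcoxon post hocs, and the Spearman correlation between
half-max change and threshold change.
"""

from audrf import AnalysisConfig, PopulationConfig, analyze_population, make_population

pop = make_population(PopulationConfig(
    n_v=16, n_nonv=16, n_rlf=16, n_rlf_with_fra=16, seed=42,
))
report = analyze_population(pop, AnalysisConfig(bootstrap_n=2000, seed=42))

print("condition medians (half-max in dB SPL, DI):")
for measure in ("half_max_level", "di"):
    for cond, (med, lo, hi) in report.medians[measure].items():
        print(f"  {measure:15s} {cond:12s} {med:6.2f}  [95% CI {lo:.2f} {hi:.2f}]")

print("\nRLF type transitions (control type x changed?):")
print(report.transition_table)

print("\ntest battery:")
for name, r in report.stat_results.items():
    flag = "exact" if r.exact else "asymptotic"
    print(f"  {name:45s} stat={r.statistic:7.3f}  p={r.p:.4f} ({flag})")
# Deactivated medians shift (half-max up, DI down) and recover; the KS
# comparison shows larger area changes for nonV than V units; p-values are
# flagged exact vs asymptotic as computed.
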