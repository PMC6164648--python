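"""Analytic first-bin (HC) and any-bin (QC) thresholds for various m.

Under the global null the count in a width-0.05 histogram bin is
Binomial(m, 0.05); the HC bound is its 0.95 quantile and the QC bound the
Bonferroni-corrected 1 - 0.05/20 = 0.9975 quantile.  Tukey's closed-form
normal approximation is shown for comparison.
"""

from pvhist import hc_threshold, qc_threshold, tukey_rejection_threshold

print(f"{'m':>7} {'HC bound':>9} {'QC bound':>9} {'Tukey (plug-in)':>16}")
for m in (201, 1000, 10_000, 23_332):
    tukey = tukey_rejection_threshold(m, 0.05, "plugin_variance")
    print(f"{m:>7} {hc_threshold(m):>9} {qc_threshold(m):>9} {tukey:>16}")
# At m = 1000 the exact binomial HC bound is 62 while Tukey's approximation
# first rejects at 63; the exact bound is preferred, the closed form is
# convenient for theory.
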