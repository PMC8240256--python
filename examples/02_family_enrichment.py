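"""Per-family enrichment against the constrained-shuffle bootstrap null.

Plants one repeat family at 4-fold enrichment in a peak set, re-places every
copy 200 times while preserving each copy's chromosome and distance to its
nearest TSS, and tests the observed count of attributed peaks against the
bootstrap expectation with an exact two-sided binomial test.
"""

from exapt.enrichment import enrichment_report, enrichment_to_frame
from exapt.simulate import planted_enrichment_scenario

scenario = planted_enrichment_scenario(target_ratio=4.0, n_control=1000, seed=0)
report = enrichment_report(
    scenario.peaks, scenario.repeats, scenario.tss, scenario.chromsizes,
    n_replicates=200, seed=1,
)
print(enrichment_to_frame(report).to_string(index=False))
# The FOCAL family's observed/expected ratio should sit near the planted
# 4-fold with a vanishing binomial p; the uniformly placed CONTROL family is
# *depleted* here because planted peaks are always attributed to the focal
# copy they contain - exclusive best-repeat attribution at work.
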