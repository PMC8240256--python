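"""Proto-motifs, CpG deamination paths, and in-silico consensus evolution.

Annotates the imperfect E-Box/RORE motifs of the bundled synthetic SINE
consensus, shows the mutational path that perfects each, and evolves the
consensus in silico, counting the substitutions required.
"""

from exapt.maturation import evolve_consensus, substitution_path
from exapt.simulate import default_consensus

model = default_consensus()
print(f"consensus {model.name!r}, {len(model.sequence)} nt\n")

for pm in model.proto_motifs:
    events = substitution_path(
        pm.observed, pm.canonical,
        left_flank=model.sequence[max(0, pm.offset - 1): pm.offset],
        right_flank=model.sequence[pm.offset + len(pm.observed):
                                   pm.offset + len(pm.observed) + 1],
    )
    path = ", ".join(
        f"{e.from_base}->{e.to_base}@{e.position}"
        + (" (CpG deamination)" if e.deamination_consistent else "")
        for e in events
    ) or "already canonical"
    print(f"{pm.label:8s} {pm.observed} -> {pm.canonical} [{pm.strand}]: {path}")

evolved, n = evolve_consensus(
    model,
    [(pm.label, pm.canonical) for pm in model.proto_motifs],
)
print(f"\nperfecting every motif changes {n} nt in total")
# The two 3'-end E-Boxes each mature through a single C->T transition at a
# CpG site - the fast deamination channel - while the central E-Box and the
# sense ROREs need ordinary substitutions.
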