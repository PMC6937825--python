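"""Merging a long-read chromosome set with a prior assembly.

Demonstrates the rescue rules: a short two-telomere published contig (R1),
a published contig the long reads missed entirely (R2), a published contig
75+ bp longer than its long-read analog (R3, the long-read form surviving
as an isoform), and an ordinary contig where the long-read form stands (R4).
"""

import random

from nanochrom import ChromosomeRecord, merge_assemblies

TEL5 = "CCCCAAAA" * 5
TEL3 = "TTTTGGGG" * 5
rng = random.Random(0)


def rec(rid, core, n_tel=2):
    return ChromosomeRecord(id=rid, bases=TEL5 + core + TEL3,
                            n_telomeres=n_tel, core=core)


def seq(n):
    return "".join(rng.choice("ACGT") for _ in range(n))


shared, only_pub, ordinary = seq(1200), seq(900), seq(1500)
published = [rec("pub_short", seq(450)),          # R1: < 600 bp rescue
             rec("pub_missing", only_pub),        # R2: no analog
             rec("pub_longer", shared),           # R3: analog 200 bp shorter
             rec("pub_same", ordinary)]           # R4: long-read form stands
longread = [rec("lr_truncated", shared[:1000]),
            rec("lr_same", ordinary)]

hybrid, decisions = merge_assemblies(published, longread)

print("decisions:")
for d in decisions:
    who = d.published_id or d.longread_id
    print(f"  {who:>14}  {d.action:<40} ({d.rule})")
print(f"hybrid assembly: {sorted(r.id for r in hybrid)}")
# pub_short and pub_missing are rescued; pub_longer is added while its
# truncated long-read analog is kept as an alternative-fragmentation
# isoform; pub_same is redundant with the long-read contig that stands.
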