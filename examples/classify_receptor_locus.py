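"""Classify the transcript variants of a synthetic 7TM receptor locus.

Builds a planted opioid-receptor-style locus (exon 1 encodes TM1, exons
2-3 encode TM2-TM7, plus a PTC-bearing cassette exon) and asks which
receptor products each transcript can encode.
"""

from sixtm.simulate import LocusSpec, gen_receptor_locus
from sixtm.topology import classify_products

locus = gen_receptor_locus(LocusSpec(seed=4))
print(f"locus {locus.chrom}: canonical receptor of "
      f"{len(locus.canonical_record.canonical_sequence)} residues, 7 TM domains\n")

for tx in locus.transcripts:
    call = classify_products(tx, locus.genome, locus.canonical_record)
    products = ", ".join(sorted(call.products)) or "none"
    nmd = " (NMD candidate)" if call.nmd_candidate else ""
    print(f"{tx.id:>15}: {products}{nmd}")

# The canonical transcript encodes the full 7TM receptor; skipping exon 1
# removes TM1 and translation restarts at the exon-2 AUG, giving an
# N-terminally truncated 6TM receptor; the cassette transcript encodes a
# PTC-terminated 1TM fragment plus a reinitiated 6TM product, and its
# premature stop (>= 50 nt upstream of the last junction) flags it for
# nonsense-mediated decay.
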