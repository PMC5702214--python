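"""Count breakpoint-junction reads in a single cell and call the SV.

A structural variant is genotyped by exact-matching the 30-nt sequence
spanning its breakpoint against the cell's amplicon reads; the variant is
called present when strictly more than 40 reads carry the junction.
"""

import numpy as np

from clonotrace import BreakpointJunction, call_sv_presence, count_junction_reads
from clonotrace.sv import reverse_complement

rng = np.random.default_rng(0)
junction = BreakpointJunction(
    assay_id="DEL_chr9",
    junction_seq="".join(rng.choice(list("ACGT"), size=30)),
    sv_class="deletion",
    span_kb=88.4,
)

def read_with_junction():
    flank = "".join(rng.choice(list("ACGT"), size=120))
    off = int(rng.integers(0, 121))
    return flank[:off] + junction.junction_seq + flank[off:]

reads = [read_with_junction() for _ in range(55)]          # true signal
reads += [read_with_junction()[::-1] for _ in range(10)]   # scrambled, no match
reads += [reverse_complement(read_with_junction()) for _ in range(8)]  # other strand
reads += ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(200)]

count = count_junction_reads(reads, junction, both_strands=True, cell_id="cell_0001")
call = call_sv_presence(count, min_reads=40)
print(f"{count.n_match} of {count.n_reads_scanned} reads match the junction "
      f"(both strands) -> call = {call}")
# 55 forward + 8 reverse-complement reads match; 63 > 40, so the deletion is
# present in this cell. Reversed (not complemented) reads never match.

forward_only = count_junction_reads(reads, junction, both_strands=False)
print(f"forward strand only: {forward_only.n_match} matches")
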