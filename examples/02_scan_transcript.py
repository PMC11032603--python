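"""Scan a transcript for candidate target sites of a miRNA.

Implants the seed complement (with one substitution) into a random
transcript, then shows that the 13-mer scan recovers it: the seed sequence
is the Watson-Crick complement of the miRNA's first 13 bases, and any
window of the arranged (3'->5') transcript within edit distance 4 is a hit,
expanded to a <= 3l candidate site.
"""

import numpy as np

from mirtarget.cts_scan import find_cts, seed_sequence

rng = np.random.default_rng(7)
mirna = "".join(rng.choice(list("AGCU"), size=22))
seed = str(seed_sequence(mirna))
print(f"miRNA (5'->3'): {mirna}")
print(f"seed (complement of first 13 nt): {seed}")

# build the arranged transcript with a 1-mismatch implant, then store 5'->3'
implant = "G" + seed[1:] if seed[0] != "G" else "C" + seed[1:]
arranged = ("".join(rng.choice(list("AGCU"), size=80)) + implant
            + "".join(rng.choice(list("AGCU"), size=100)))
transcript = arranged[::-1]

for w in find_cts(mirna, transcript):
    print(f"match at [{w.start},{w.end}) distance {w.distance}; "
          f"site [{w.cts_start},{w.cts_end}) = {str(w.cts_seq)[:30]}... "
          f"({w.cts_end - w.cts_start} nt)")
# The implanted window appears at arranged position 80 with distance 1;
# chance hits at distance <= 4 may appear elsewhere. Each site is ready to
# be scored by the pair model (transcript call: max probability >= 0.5).
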