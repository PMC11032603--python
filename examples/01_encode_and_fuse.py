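"""Encode a miRNA/site pair and inspect the contact map.

Builds the shared encoder at a small width, encodes one miRNA and one
candidate target site, fuses them into the diff/mul contact map and prints
its shape and value ranges. The diff block is zero wherever two bases carry
identical features; the mul block grows with co-activation.
"""

import numpy as np

from mirtarget.encoder import EncoderConfig, SequenceEncoder, encode_representation
from mirtarget.fusion import build_contact_map
from mirtarget.seqio import encode_sequence

mirna = "UGAGGUAGUAGGUUGUAUAGUU"          # let-7-like 22-mer
site = "AACUAUACAACCUACUACCUCA" + "ACGU" * 11  # complement + background

encoder = SequenceEncoder(EncoderConfig(d0=32, nl=1, nh=1, d1=8), np.random.default_rng(0))
encoder.eval()

t1 = encode_representation(encode_sequence(mirna, 24), encoder)
t2 = encode_representation(encode_sequence(site, 66), encoder)
cm = build_contact_map(t1, t2)

print(f"miRNA features:  {t1.shape}  (length x d1, all >= 0: {bool((t1 >= 0).all())})")
print(f"site features:   {t2.shape}")
print(f"contact map:     {cm.shape}  (2*d1 channels x m x n)")
print(f"diff block range [{cm[:8].min():.3f}, {cm[:8].max():.3f}], "
      f"mul block range [{cm[8:].min():.3f}, {cm[8:].max():.3f}]")
# Each channel pairs every miRNA base with every site base; a trained model
# scores this map with the CNN to localize where binding is likely.
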