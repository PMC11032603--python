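"""Contact-map fusion of a miRNA / target-site representation pair.

For representations T1' (m x d1) and T2' (n x d1) the contact map stacks,
for every feature k and base pair (i, j),

    diff[k, i, j] = |T1'[i, k] - T2'[j, k]|
    mul[k, i, j]  =  T1'[i, k] * T2'[j, k]

concatenated channel-wise as diff-then-mul into a (2*d1, m, n) array.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, concat


def build_contact_map_batch(t1: Tensor, t2: Tensor) -> Tensor:
    """Batched channels-last fusion: t1 (B, m, d1), t2 (B, n, d1) ->
    (B, m, n, 2*d1), diff channels first then mul channels."""
    if t1.shape[-1] != t2.shape[-1]:
        raise ValueError(f"feature widths differ: {t1.shape[-1]} vs {t2.shape[-1]}")
    a = t1.reshape(t1.shape[0], t1.shape[1], 1, t1.shape[2])
    b = t2.reshape(t2.shape[0], 1, t2.shape[1], t2.shape[2])
    diff = (a - b).abs()
    mul = a * b
    return concat([diff, mul], axis=-1)


def build_contact_map(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Fuse two plain (m x d1) / (n x d1) representation matrices into the
    channel-first (2*d1, m, n) contact map."""
    t1 = np.asarray(t1)
    t2 = np.asarray(t2)
    if t1.ndim != 2 or t2.ndim != 2:
        raise ValueError("representations must be 2-D (length x d1)")
    nhwc = build_contact_map_batch(Tensor(t1[None]), Tensor(t2[None])).data[0]
    return np.ascontiguousarray(nhwc.transpose(2, 0, 1))
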