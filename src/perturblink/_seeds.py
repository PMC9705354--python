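"""Deterministic sub-seed derivation.

Every randomized routine that performs several independent draws (t
perturbations, k folds, r repeats) derives one sub-seed per draw from the
user-supplied master seed, so a single integer reproduces the whole run.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def derive_seed(master_seed: int, *keys: int) -> int:
    """Derive a reproducible 31-bit sub-seed from a master seed and keys."""
    ss = np.random.SeedSequence([int(master_seed), *(int(k) for k in keys)])
    return int(ss.generate_state(1)[0] % _MOD)
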