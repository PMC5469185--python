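"""Named, independently derived random substreams.

Every stochastic stage of a run draws from its own substream, derived
from one master seed plus a stable string label.  Adding a stage (e.g.
more noise SNPs) therefore never perturbs the draws of another stage,
and any stage can be replayed in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_entropy(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``labels``.

    The same (seed, labels) pair always yields an identical stream;
    distinct labels yield statistically independent streams.
    """
    entropy = [int(seed)] + [_label_entropy(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
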