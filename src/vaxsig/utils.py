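"""Shared helpers: deterministic seed derivation and the package logger."""

from __future__ import annotations

import logging
import zlib

logger = logging.getLogger("vaxsig")


def derive_seed(seed: int, *parts: object) -> int:
    """Derive a stage seed from a global seed and a sequence of tokens.

    Every stochastic stage obtains its seed as ``derive_seed(global_seed,
    stage_name, dataset_id, ...)`` so that reruns are bit-identical and
    stages are decoupled (re-ordering one stage never shifts another
    stage's random stream). Result is kept below 2**31.
    """
    token = "|".join([str(int(seed))] + [str(p) for p in parts])
    return zlib.crc32(token.encode("utf-8")) % (2**31)
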