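"""Named, independent random-number substreams.

One master seed spawns a fixed substream per pipeline stage, so changing the
iteration count of one stage (e.g. the uncertainty loop) never perturbs the
draws of another (e.g. the exposure simulation).
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "demographics": 0,
    "consumption": 1,
    "concentration": 2,
    "frequency": 3,
    "doseresponse": 4,
    "exposure": 5,
    "sensitivity": 6,
    "uncertainty": 7,
    "bootstrap": 8,
    "subgroup_exposure": 9,
}


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )
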