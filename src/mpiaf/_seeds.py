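"""Named, independent random substreams derived from one master seed.

Every stochastic stage of the pipeline (cohort draw, EEG synthesis,
staircase responses, bootstrap resampling) pulls its generator from a
named substream so that stages are independently reproducible: changing
the number of bootstrap replicates, say, cannot perturb the cohort.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: the spawn key of a stream is its position here, so the
# mapping from name to stream never depends on call order.
STREAMS = ("cohort", "eeg", "staircase", "bootstrap", "misc")


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return the generator for substream *name* under *master_seed*.

    ``index`` selects independent children within a stream (e.g. one per
    observer) without consuming shared state.
    """
    if name not in STREAMS:
        raise ValueError(f"unknown substream {name!r}; expected one of {STREAMS}")
    key = (STREAMS.index(name), int(index))
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=key))
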