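"""Shared test helpers."""

import numpy as np

from morphodisp.superimposition import AlignedSample


def aligned_from_flat(flat, k):
    """Wrap flattened (n, 2k) coordinates as an AlignedSample for statistic tests."""
    flat = np.asarray(flat, float)
    coords = flat.reshape(len(flat), k, 2)
    return AlignedSample(
        coords=coords,
        consensus=coords.mean(axis=0),
        centroid_sizes=np.ones(len(flat)),
        specimen_ids=[f"s{i}" for i in range(len(flat))],
    )
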