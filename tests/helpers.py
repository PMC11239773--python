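import numpy as np
import pandas as pd


def make_clusters(regions, urbans, n_staff=100):
    """Hand-built cluster table from explicit region/urban vectors."""
    regions = np.asarray(regions)
    urbans = np.asarray(urbans)
    return pd.DataFrame(
        {
            "cluster_id": np.arange(1, len(regions) + 1),
            "region": regions,
            "urban": urbans,
            "n_staff": np.full(len(regions), n_staff),
        }
    )
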