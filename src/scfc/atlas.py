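"""Default synthetic parcellation scheme.

The analyses in this package operate on a fine-grained whole-brain
parcellation of 392 cortical and subcortical regions grouped into nine
networks: the seven canonical cortical resting-state networks (visual,
somatomotor, dorsal attention, ventral attention, limbic,
frontoparietal, default mode) plus subcortex and cerebellum/brainstem.
Real parcellation tables are read with :func:`scfc.io.read_parcellation`;
:func:`default_parcellation` builds a synthetic stand-in with the same
structure — 392 regions, nine networks with realistically unequal sizes
(cortical network sizes range from 22 to 79 regions), left/right/midline
hemisphere labels and plausible centroid coordinates in mm — so every
stage of the pipeline runs without any external atlas file.  Centroids
and labels are deterministic (fixed internal seed); they carry no
anatomical meaning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Parcellation

# Regions per network (sums to 392); cortical sizes span the 22-79 range
# seen when intersecting a fine functional atlas with the seven networks.
_NETWORK_SIZES = {
    "VIS": 55,
    "SOM": 52,
    "DATTN": 40,
    "VATTN": 38,
    "LIM": 22,
    "FPN": 48,
    "DMN": 79,
    "SUB": 36,
    "CER/BS": 22,
}

# Approximate centroid boxes (mm, MNI-like) per network: (x range used
# per hemisphere, y range, z range).
_BOXES = {
    "VIS": ((5, 45), (-100, -60), (-15, 25)),
    "SOM": ((5, 60), (-40, 0), (20, 70)),
    "DATTN": ((10, 50), (-70, -30), (30, 65)),
    "VATTN": ((25, 60), (-45, 15), (-5, 40)),
    "LIM": ((10, 40), (-20, 30), (-40, -5)),
    "FPN": ((20, 55), (-60, 50), (10, 55)),
    "DMN": ((5, 55), (-75, 60), (-20, 55)),
    "SUB": ((5, 35), (-35, 15), (-20, 25)),
    "CER/BS": ((0, 35), (-85, -35), (-60, -15)),
}


def default_parcellation(n_regions: int = 392) -> Parcellation:
    """Build the default synthetic 392-region, nine-network parcellation.

    For ``n_regions != 392`` the nine network sizes are rescaled
    proportionally (each network keeps at least one region), which gives
    small parcellations the same nine-network structure for fast tests.
    """
    sizes = dict(_NETWORK_SIZES)
    if n_regions != 392:
        keys = list(sizes)
        raw = np.array([sizes[k] for k in keys], dtype=float) * n_regions / 392.0
        counts = np.maximum(1, np.floor(raw).astype(int))
        # distribute the remainder to the largest fractional parts
        while counts.sum() < n_regions:
            counts[np.argmax(raw - counts)] += 1
        while counts.sum() > n_regions:
            i = np.argmax(counts - raw)
            if counts[i] > 1:
                counts[i] -= 1
            else:  # pragma: no cover - n_regions < 9
                raise ValueError("n_regions must be >= 9 to keep nine networks")
        sizes = dict(zip(keys, counts))

    rng = np.random.default_rng(392)  # fixed: the scheme is a constant
    rows = []
    rid = 0
    for net, n in sizes.items():
        (x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi) = _BOXES[net]
        for k in range(n):
            if net == "CER/BS" and k < max(1, n // 4):
                hemi = "midline"
                x = rng.uniform(-5, 5)
            else:
                hemi = "left" if k % 2 == 0 else "right"
                x = rng.uniform(x_lo, x_hi) * (-1 if hemi == "left" else 1)
            rows.append(
                {
                    "region_id": rid,
                    "label": f"{net.replace('/', '')}_{hemi[0].upper()}_{k:03d}",
                    "hemisphere": hemi,
                    "network": net,
                    "x": round(float(x), 2),
                    "y": round(float(rng.uniform(y_lo, y_hi)), 2),
                    "z": round(float(rng.uniform(z_lo, z_hi)), 2),
                }
            )
            rid += 1
    return Parcellation(pd.DataFrame(rows))
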