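"""Region tables (atlas) for labeling nodes and exporting visualizations.

The default 246-region table is *synthetic*: labels follow the naming style
of fine-grained whole-brain parcellations (lobe prefix, hemisphere,
subregion index) and centroids are deterministic invented MNI-like
coordinates (left hemisphere x < 0, right x > 0). It is a stand-in for a
published parcellation's coordinate table, structurally valid for
BrainNetViewer-style exports but carrying no anatomical meaning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_LOBES = [
    ("FRO", 62),  # frontal
    ("TEM", 40),  # temporal
    ("PAR", 30),  # parietal
    ("INS", 12),  # insular
    ("LIM", 24),  # limbic
    ("OCC", 22),  # occipital
    ("SUB", 56),  # subcortical
]


def synthetic_atlas(n_regions: int = 246) -> pd.DataFrame:
    """Deterministic synthetic region table.

    Columns: ``index`` (1-based, contiguous), ``label`` (unique), ``lobe``,
    ``x``/``y``/``z`` (invented MNI-like centroids in mm). For the default
    246 regions the lobe partition is fixed; other sizes get a proportional
    split.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_regions == 246:
        lobes = _LOBES
    else:
        total = sum(c for _, c in _LOBES)
        counts = [max(1, round(c * n_regions / total)) for _, c in _LOBES]
        while sum(counts) > n_regions:
            counts[int(np.argmax(counts))] -= 1
        while sum(counts) < n_regions:
            counts[int(np.argmin(counts))] += 1
        lobes = [(name, c) for (name, _), c in zip(_LOBES, counts)]
    rng = np.random.default_rng(246)  # fixed: the table is a constant
    rows = []
    idx = 1
    for lobe, count in lobes:
        center = rng.uniform(-60, 60, size=3)
        for k in range(count):
            hemi = "L" if k % 2 == 0 else "R"
            offset = rng.normal(scale=15.0, size=3)
            x = abs(center[0] + offset[0]) * (-1 if hemi == "L" else 1)
            rows.append(
                dict(
                    index=idx,
                    label=f"{lobe}_{hemi}_{k // 2 + 1:02d}",
                    lobe=lobe,
                    x=round(float(x), 1),
                    y=round(float(np.clip(center[1] + offset[1], -100, 70)), 1),
                    z=round(float(np.clip(center[2] + offset[2], -70, 80)), 1),
                )
            )
            idx += 1
    return pd.DataFrame(rows)


def validate_atlas(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, label uniqueness, and contiguous 1-based indices."""
    required = {"index", "label", "x", "y", "z"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    n = len(table)
    if list(table["index"]) != list(range(1, n + 1)):
        raise ValueError("atlas indices must be contiguous and 1-based")
    if table["label"].nunique() != n:
        raise ValueError("atlas labels must be unique")
    return table
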