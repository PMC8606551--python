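"""Geometric risk features and labeled dataset assembly.

Four features per (model, segment) row: the segment's myocardial volume,
the segment's ischemic percentage, the model's total myocardial volume and
its total ischemic volume. Labels come from the vulnerability protocol
(sustained and unsustained reentry are the positive class). Features
depend only on geometry — never on simulation state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import VentricleGeometry, GeometryError

__all__ = ["extract_features", "build_dataset", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ("seg_vol", "seg_isch_pct", "total_vol", "total_isch_vol")


def extract_features(geom: VentricleGeometry,
                     model_id: str = "model") -> pd.DataFrame:
    """The 17 per-segment feature rows of one model.

    Volumes are element sums (mm^3, or mm^2 x unit thickness in 2D);
    segment ischemic percentage is the ischemic share of the segment's
    own volume. Raises on empty segments.
    """
    if not np.any(geom.segment_id > 0):
        raise GeometryError("segments not assigned")
    vol = geom.element_volume
    isch = geom.region_label > 0
    total_vol = float(vol[geom.segment_id > 0].sum())
    total_isch = float(vol[(geom.segment_id > 0) & isch].sum())
    rows = []
    for seg in range(1, 18):
        m = geom.segment_id == seg
        if not m.any():
            raise GeometryError(f"AHA segment {seg} is empty")
        seg_vol = float(vol[m].sum())
        seg_isch = float(vol[m & isch].sum())
        rows.append({
            "model_id": model_id, "segment_id": seg,
            "seg_vol": seg_vol,
            "seg_isch_pct": 100.0 * seg_isch / seg_vol,
            "total_vol": total_vol,
            "total_isch_vol": total_isch,
        })
    return pd.DataFrame(rows)


def build_dataset(feature_tables, site_results: pd.DataFrame
                  ) -> pd.DataFrame:
    """Join per-model feature rows with protocol outcomes.

    ``feature_tables`` is an iterable of :func:`extract_features` outputs;
    ``site_results`` must carry ``model_id, segment, arrhythmic`` for every
    (model, segment). Returns 17 x n_models rows with a binary ``label``.
    Raises on duplicate keys or missing outcomes.
    """
    feats = pd.concat(list(feature_tables), ignore_index=True)
    dup = feats.duplicated(subset=["model_id", "segment_id"])
    if dup.any():
        keys = feats.loc[dup, ["model_id", "segment_id"]]
        raise ValueError(
            f"duplicate (model, segment) keys: {keys.values.tolist()[:5]}")
    lab = site_results.rename(columns={"segment": "segment_id"})[
        ["model_id", "segment_id", "arrhythmic"]]
    merged = feats.merge(lab, on=["model_id", "segment_id"], how="left")
    missing = merged["arrhythmic"].isna()
    if missing.any():
        keys = merged.loc[missing, ["model_id", "segment_id"]]
        raise KeyError(
            f"missing outcomes for keys: {keys.values.tolist()[:5]}")
    merged["label"] = merged["arrhythmic"].astype(int)
    return merged.drop(columns=["arrhythmic"])
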