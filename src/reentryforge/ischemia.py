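"""Concentric ischemic layers, electrophysiological grading, and the
layer-peeling augmentation operator.

The ischemic subdomain of a geometry is divided into L concentric layers by
distance from the outer ischemic surface (layer 1 = outermost rim, layer L =
core). Severity grades across layers: extracellular potassium rises linearly
from 7.5 mM at the rim to 10 mM in the core, the inner half of the layers
carries a 30% reduction of the fast sodium and L-type calcium currents
(20% in the outer half), a fixed fraction of ATP-sensitive potassium
channels is open throughout, and tissue conductivity is reduced uniformly
by 40%.

Layer peeling relabels the outermost k layers as healthy tissue and
re-grades the remaining layers from normal at the new rim to fully ischemic
in the core — each peel produces a novel, smaller-infarct virtual patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import VentricleGeometry, GeometryError

__all__ = [
    "LayeredIschemia",
    "GradingConfig",
    "PopulationMember",
    "assign_layers",
    "grade_layers",
    "peel_layers",
    "build_augmented_population",
    "population_manifest",
]


@dataclass
class LayeredIschemia:
    """Concentric layer structure of one ischemic region.

    ``element_ids`` indexes into the parent geometry's element arrays;
    ``layer_index`` runs from 1 (outermost) to ``n_layers`` (core)."""

    element_ids: np.ndarray
    layer_index: np.ndarray
    boundary_distance: np.ndarray
    n_layers: int

    @property
    def is_valid(self) -> bool:
        return self.n_layers > 0 and self.element_ids.size > 0

    def layer_sizes(self) -> np.ndarray:
        return np.bincount(self.layer_index,
                           minlength=self.n_layers + 1)[1:]


@dataclass
class GradingConfig:
    """Per-layer electrophysiological remodeling parameters."""

    K_o_outer: float = 7.5          # mM at the outermost layer
    K_o_inner: float = 10.0         # mM at the core
    inner_zone_fraction: float = 0.5
    inner_current_reduction: float = 0.30   # INa & ICaL in the inner zone
    outer_current_reduction: float = 0.20   # INa & ICaL in the outer zone
    f_ATP: float = 0.0049           # open fraction of KATP channels
    conductivity_reduction: float = 0.40    # uniform over ischemia

    def __post_init__(self):
        for name in ("inner_zone_fraction", "inner_current_reduction",
                     "outer_current_reduction", "conductivity_reduction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.f_ATP <= 1.0):
            raise ValueError(f"f_ATP must be in [0, 1], got {self.f_ATP}")
        if self.K_o_inner < self.K_o_outer:
            raise ValueError("K_o_inner must be >= K_o_outer")


def assign_layers(geom: VentricleGeometry, L: int,
                  equal_volume: bool = False):
    """Partition the ischemic subdomain into L concentric layers.

    Distance of each ischemic element to the nearest healthy element is
    binned into L equal-width bins (default) or L equal-count bins
    (``equal_volume=True``). If fewer than L distinct bins are occupied,
    the layer count is reduced with a warning.

    Returns ``(geometry, LayeredIschemia)`` — the geometry's
    ``region_label`` carries the per-element layer index.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    isch = np.flatnonzero(geom.region_label > 0)
    if isch.size == 0:
        raise GeometryError("geometry has no ischemic subdomain")
    healthy = np.flatnonzero(geom.region_label == 0)
    if healthy.size == 0:
        raise GeometryError("geometry has no healthy tissue to define the "
                            "outer ischemic surface")
    tree = cKDTree(geom.centers[healthy])
    dist, _ = tree.query(geom.centers[isch])

    if equal_volume:
        order = np.argsort(dist, kind="stable")
        layer = np.empty(isch.size, dtype=np.int64)
        layer[order] = 1 + (np.arange(isch.size) * L // isch.size)
    else:
        d_max = dist.max()
        if d_max <= 0:
            layer = np.ones(isch.size, dtype=np.int64)
        else:
            layer = np.minimum(
                np.ceil(dist / (d_max / L)).astype(np.int64), L)
            layer = np.maximum(layer, 1)

    # Compress away empty layers, preserving order.
    present = np.unique(layer)
    if present.size < L:
        warnings.warn(
            f"only {present.size} distinct distance levels; layer count "
            f"reduced from {L} to {present.size}", stacklevel=2)
    remap = {old: new + 1 for new, old in enumerate(present)}
    layer = np.array([remap[v] for v in layer], dtype=np.int64)
    L_eff = present.size

    out = geom.copy()
    out.region_label[isch] = layer
    out.metadata["n_layers"] = int(L_eff)
    layers = LayeredIschemia(element_ids=isch, layer_index=layer,
                             boundary_distance=dist, n_layers=L_eff)
    return out, layers


def grade_layers(layers, cfg: GradingConfig | None = None) -> pd.DataFrame:
    """Per-layer electrophysiological parameter table.

    Accepts a :class:`LayeredIschemia` or a plain layer count. Columns:
    ``layer, K_o, ina_scale, ical_scale, f_atp, cond_scale``. Potassium
    interpolates linearly from ``K_o_outer`` at layer 1 to ``K_o_inner``
    at layer L (a single layer is treated as fully ischemic core); current
    scales are zoned — the innermost 50% of layers (ties to inner) use the
    inner reduction; the KATP open fraction and the conductivity scale are
    uniform over all ischemic layers.
    """
    cfg = cfg or GradingConfig()
    L = layers.n_layers if isinstance(layers, LayeredIschemia) else int(layers)
    if L < 1:
        raise ValueError(f"layer count must be >= 1, got {L}")
    k = np.arange(1, L + 1)
    if L == 1:
        K_o = np.array([cfg.K_o_inner])
    else:
        K_o = cfg.K_o_outer + (k - 1) / (L - 1) * (cfg.K_o_inner
                                                   - cfg.K_o_outer)
    n_outer = int(np.floor(L * (1.0 - cfg.inner_zone_fraction)))
    inner = k > n_outer
    scale = np.where(inner, 1.0 - cfg.inner_current_reduction,
                     1.0 - cfg.outer_current_reduction)
    return pd.DataFrame({
        "layer": k,
        "K_o": K_o,
        "ina_scale": scale,
        "ical_scale": scale,
        "f_atp": np.full(L, cfg.f_ATP),
        "cond_scale": np.full(L, 1.0 - cfg.conductivity_reduction),
    })


def peel_layers(geom: VentricleGeometry, layers: LayeredIschemia, k: int):
    """Relabel the outermost k ischemic layers as healthy tissue.

    The remaining L-k layers are re-indexed 1..L-k, so re-grading spans
    normal at the new rim to fully ischemic in the core (the border zone
    regenerates). ``k >= L`` leaves no ischemic tissue; the returned
    :class:`LayeredIschemia` then reports ``is_valid == False``.
    Peeling a then b equals peeling a+b.
    """
    if k < 0:
        raise ValueError(f"peel count must be >= 0, got {k}")
    if k == 0:
        return geom.copy(), LayeredIschemia(
            element_ids=layers.element_ids.copy(),
            layer_index=layers.layer_index.copy(),
            boundary_distance=layers.boundary_distance.copy(),
            n_layers=layers.n_layers)

    keep = layers.layer_index > k
    out = geom.copy()
    out.region_label[layers.element_ids[~keep]] = 0
    new_ids = layers.element_ids[keep]
    new_layer = layers.layer_index[keep] - k
    out.region_label[new_ids] = new_layer
    new_L = max(layers.n_layers - k, 0)
    out.metadata["n_layers"] = int(new_L)
    new_layers = LayeredIschemia(
        element_ids=new_ids,
        layer_index=new_layer,
        boundary_distance=layers.boundary_distance[keep],
        n_layers=new_L if new_ids.size else 0)
    return out, new_layers


@dataclass
class PopulationMember:
    """One virtual patient: a geometry plus its layer structure and
    provenance (source patient id, number of layers peeled)."""

    patient_id: int
    peel_level: int
    geom: VentricleGeometry
    layers: LayeredIschemia
    grading: pd.DataFrame = field(repr=False, default=None)

    @property
    def model_id(self) -> str:
        return f"p{self.patient_id:03d}_peel{self.peel_level}"


def build_augmented_population(baseline, peel_set=(1, 2, 5, 10),
                               cfg: GradingConfig | None = None):
    """Expand baseline virtual patients by layer peeling.

    ``baseline`` is a list of ``(geometry, LayeredIschemia)`` pairs. Each
    patient contributes its baseline model (peel 0) plus one variant per
    peel level that still leaves ischemic tissue; peels with ``k >= L``
    are excluded. Returns a list of :class:`PopulationMember`.
    """
    if not baseline:
        raise ValueError("baseline population is empty")
    cfg = cfg or GradingConfig()
    pop = []
    for pid, (geom, layers) in enumerate(baseline):
        pop.append(PopulationMember(pid, 0, geom, layers,
                                    grade_layers(layers, cfg)))
        for k in sorted(peel_set):
            g2, l2 = peel_layers(geom, layers, k)
            if not l2.is_valid:
                continue
            pop.append(PopulationMember(pid, k, g2, l2,
                                        grade_layers(l2, cfg)))
    return pop


def population_manifest(pop) -> pd.DataFrame:
    """Per-peel-level population summary (count and global ischemia %)."""
    rows = []
    for m in pop:
        rows.append({"model_id": m.model_id, "patient_id": m.patient_id,
                     "peel_level": m.peel_level,
                     "n_layers": m.layers.n_layers,
                     "ischemia_pct": m.geom.ischemic_fraction})
    df = pd.DataFrame(rows)
    agg = df.groupby("peel_level").agg(
        n_patients=("patient_id", "nunique"),
        mean_ischemia_pct=("ischemia_pct", "mean"),
        sd_ischemia_pct=("ischemia_pct", "std"),
    ).reset_index()
    return agg
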