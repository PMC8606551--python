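"""Synthetic virtual-patient populations.

Stands in for an MRI-derived patient cohort: each virtual patient is a 2D
myocardial sheet with an embedded ischemic disc whose size varies across
patients like the clinical distribution it emulates (global ischemic
fraction with mean near 10.8% and SD near 10.5% of myocardial volume,
right-skewed), divided into 10-27 concentric layers depending on size.
Layer peeling (1, 2, 5, 10 layers) expands the baseline cohort into the
augmented population, and a vulnerability backend (surrogate by default)
labels every (model, AHA segment) pair, yielding the labeled risk
datasets used by the classification harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import build_dataset, extract_features
from .geometry import IschemiaSpec, generate_slab, assign_aha_segments, \
    assign_fibers
from .ischemia import (GradingConfig, assign_layers,
                       build_augmented_population)
from .protocol import (ProtocolConfig, SurrogateBackend,
                       VulnerabilitySummary, evaluate_population)

__all__ = ["generate_baseline_population", "synthesize_study", "StudyData",
           "ISCHEMIA_PCT_MEAN", "ISCHEMIA_PCT_SD"]

# Emulated clinical distribution of global ischemic burden (% of myocardium)
ISCHEMIA_PCT_MEAN = 10.8
ISCHEMIA_PCT_SD = 10.5


def _lognormal_params(mean: float, sd: float):
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * s2, np.sqrt(s2)


def generate_baseline_population(n_patients: int = 30, nx: int = 120,
                                 ny: int = 120, spacing: float = 0.25,
                                 seed: int = 0,
                                 grading: GradingConfig | None = None):
    """Baseline cohort of slab virtual patients.

    Ischemic fractions are drawn from a lognormal matched to the emulated
    cohort's mean and SD (clipped to [1.5, 40]% so every patient has a
    layerable region inside the sheet); sheet dimensions vary per patient
    by about +/-10% (myocardial volume differs between patients); disc
    centres jitter within the central half of the sheet; the layer count
    scales with disc radius, clipped to the 10-27 range. Returns a list
    of ``(geometry, layers)`` pairs with AHA tiling, fibers and layer
    indices assigned.
    """
    rng = np.random.default_rng(seed)
    mu, sig = _lognormal_params(ISCHEMIA_PCT_MEAN, ISCHEMIA_PCT_SD)
    out = []
    for p in range(n_patients):
        nx_p = int(rng.integers(round(0.9 * nx), round(1.1 * nx) + 1))
        ny_p = int(rng.integers(round(0.9 * ny), round(1.1 * ny) + 1))
        Lx, Ly = nx_p * spacing, ny_p * spacing
        frac = float(np.clip(rng.lognormal(mu, sig), 1.5, 40.0))
        radius = np.sqrt(frac / 100.0 * Lx * Ly / np.pi)
        cx = rng.uniform(0.3 * Lx, 0.7 * Lx)
        cy = rng.uniform(0.3 * Ly, 0.7 * Ly)
        # keep the disc inside the sheet for large draws
        cx = float(np.clip(cx, radius, Lx - radius))
        cy = float(np.clip(cy, radius, Ly - radius))
        n_layers = int(np.clip(round(radius / spacing), 10, 27))
        spec = IschemiaSpec(center=(cx, cy), radius=radius,
                            n_layers=n_layers)
        geom = generate_slab(nx_p, ny_p, spacing, spec,
                             seed=seed * 1000 + p)
        geom = assign_aha_segments(geom)
        geom = assign_fibers(geom, 0.0, 0.0)
        with warnings.catch_warnings():
            # small infarcts support fewer rings than requested; the
            # reduction is the documented behaviour, not a defect
            warnings.simplefilter("ignore")
            geom, layers = assign_layers(geom, n_layers)
        out.append((geom, layers))
    return out


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    population: list                     # PopulationMember
    summary: VulnerabilitySummary
    baseline_dataset: pd.DataFrame
    augmented_dataset: pd.DataFrame


def synthesize_study(n_patients: int = 30, seed: int = 0,
                     peel_set=(1, 2, 5, 10), nx: int = 120, ny: int = 120,
                     spacing: float = 0.25,
                     grading: GradingConfig | None = None,
                     protocol_cfg: ProtocolConfig | None = None,
                     backend_factory=None) -> StudyData:
    """Full synthetic study: cohort -> augmentation -> protocol -> datasets.

    The default backend is the seeded :class:`SurrogateBackend`; pass
    ``backend_factory(member)`` to substitute the tissue backend or a
    stub. Baseline dataset rows are the peel-0 models only; the augmented
    dataset concatenates all valid models.
    """
    grading = grading or GradingConfig()
    protocol_cfg = protocol_cfg or ProtocolConfig()
    baseline = generate_baseline_population(
        n_patients, nx=nx, ny=ny, spacing=spacing, seed=seed,
        grading=grading)
    pop = build_augmented_population(baseline, peel_set=peel_set,
                                     cfg=grading)
    if backend_factory is None:
        def backend_factory(member):
            return SurrogateBackend(member, seed=seed, cfg=protocol_cfg)
    summary = evaluate_population(pop, backend_factory, cfg=protocol_cfg)

    feats = {m.model_id: extract_features(m.geom, m.model_id) for m in pop}
    res = summary.site_results
    base_ids = [m.model_id for m in pop if m.peel_level == 0]
    baseline_ds = build_dataset(
        [feats[i] for i in base_ids],
        res[res["model_id"].isin(base_ids)])
    augmented_ds = build_dataset(feats.values(), res)
    return StudyData(population=pop, summary=summary,
                     baseline_dataset=baseline_ds,
                     augmented_dataset=augmented_ds)
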