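"""Brain volumetrics from linear measurements.

Volumes are estimated from length x width x height of each structure
with an ellipsoid model, ``V = L*W*H * pi / (6 * 1.43)``.  The four
paired structures (olfactory nerves, olfactory bulbs, telencephalon,
optic tectum) are measured on the right hemisphere only and the volume
estimate is doubled.  Species means are taken on the raw mm^3 scale;
variables enter the regressions as ``log10(1000 * x)`` (the x1000
offset keeps sub-unit volumes positive after the log).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Structures modeled, in reporting order.  Medulla is not modeled.
STRUCTURES = (
    "brain",
    "olfactory_nerves",
    "olfactory_bulbs",
    "telencephalon",
    "optic_tectum",
    "cerebellum",
)

#: Paired structures: measured on one hemisphere, volume doubled.
PAIRED = frozenset(
    {"olfactory_nerves", "olfactory_bulbs", "telencephalon", "optic_tectum"}
)

REGIONS = tuple(s for s in STRUCTURES if s != "brain")

_ELLIPSOID_CONST = math.pi / (6.0 * 1.43)

LOCALITY_COLUMNS = ("altitude_m", "longitude_deg", "latitude_deg")


def ellipsoid_volume(L, W, H):
    """Ellipsoid volume estimate ``L*W*H * pi / (6*1.43)`` in mm^3.

    Accepts scalars or arrays (mm); all dimensions must be positive.
    """
    L, W, H = (np.asarray(v, dtype=float) for v in (L, W, H))
    if np.any(L <= 0) or np.any(W <= 0) or np.any(H <= 0):
        raise ValueError("all linear dimensions must be positive")
    out = L * W * H * _ELLIPSOID_CONST
    return float(out) if out.ndim == 0 else out


def structure_volume(L, W, H, structure: str | None = None, paired: bool | None = None):
    """Volume of a named structure, doubling paired (hemispheric) ones.

    ``paired`` may be given explicitly; otherwise it is inferred from
    ``structure`` membership in :data:`PAIRED`.
    """
    if paired is None:
        if structure is None:
            raise ValueError("give either structure name or paired flag")
        if structure not in STRUCTURES:
            raise ValueError(f"unknown structure {structure!r}")
        paired = structure in PAIRED
    elif structure is not None and paired and structure not in PAIRED:
        raise ValueError(f"{structure!r} is not a paired structure")
    v = ellipsoid_volume(L, W, H)
    return 2.0 * v if paired else v


def log_scale(x):
    """``log10(1000 * x)`` for positive measurements (scalar or array)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log_scale requires positive values")
    out = np.log10(1000.0 * x)
    return float(out) if out.ndim == 0 else out


def rest_of_brain(brain, region):
    """Whole-brain volume minus the focal region, raw mm^3 scale."""
    brain = np.asarray(brain, dtype=float)
    region = np.asarray(region, dtype=float)
    if np.any(region >= brain) or np.any(region <= 0):
        raise ValueError("region volume must lie strictly between 0 and brain volume")
    out = brain - region
    return float(out) if out.ndim == 0 else out


def individual_volumes(df: pd.DataFrame) -> pd.DataFrame:
    """Per-individual structure volumes from a raw trait table.

    For each structure the table may carry either ``{s}_L/_W/_H``
    columns (mm) or a precomputed ``{s}_volume`` column (mm^3, already
    doubled for paired structures).  When both are present the volume
    column wins and a warning is logged.
    """
    out = pd.DataFrame(index=df.index)
    for col in ("species", "individual_id", "svl_mm", "mass_mg"):
        if col not in df.columns:
            raise ValueError(f"trait table missing required column {col!r}")
        out[col] = df[col]
    for col in LOCALITY_COLUMNS:
        if col in df.columns:
            out[col] = df[col]
    for s in STRUCTURES:
        vol_col = f"{s}_volume"
        lwh = [f"{s}_{d}" for d in ("L", "W", "H")]
        has_lwh = all(c in df.columns for c in lwh)
        if vol_col in df.columns:
            if has_lwh:
                logger.warning(
                    "both %s and %s present; using precomputed volumes", vol_col, lwh
                )
            out[vol_col] = df[vol_col].astype(float)
        elif has_lwh:
            out[vol_col] = structure_volume(
                df[lwh[0]], df[lwh[1]], df[lwh[2]], structure=s
            )
        else:
            raise ValueError(f"no measurements for structure {s!r}")
        if (out[vol_col] <= 0).any():
            raise ValueError(f"non-positive volume for {s!r}")
    return out


def species_means(individuals: pd.DataFrame) -> pd.DataFrame:
    """Species-level arithmetic means of raw-scale traits.

    Input rows are individuals (see :func:`individual_volumes`); output
    is one row per species with ``n_individuals`` recorded and any
    locality columns carried through.  Conflicting locality values
    within a species raise an error (each species has one site).
    """
    df = individuals
    trait_cols = ["svl_mm", "mass_mg"] + [f"{s}_volume" for s in STRUCTURES]
    loc_cols = [c for c in LOCALITY_COLUMNS if c in df.columns]
    for col, grp in ((c, df.groupby("species")[c]) for c in loc_cols):
        if (grp.nunique() > 1).any():
            bad = grp.nunique()
            raise ValueError(
                f"conflicting {col} within species: "
                f"{sorted(bad.index[bad > 1])}"
            )
    g = df.groupby("species", sort=True)
    out = g[trait_cols + loc_cols].mean()
    out.insert(0, "n_individuals", g.size())
    brain = out["brain_volume"]
    for r in REGIONS:
        if (out[f"{r}_volume"] >= brain).any():
            raise ValueError(f"species mean {r} volume exceeds whole brain")
    return out


def read_individual_csv(path: str) -> pd.DataFrame:
    """Read the individual-level trait CSV and compute volumes."""
    return individual_volumes(pd.read_csv(path))
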