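"""Chemotaxis-index scoring for two-point plate assays.

The chemotaxis index of one plate is CI = (B - A) / (A + B), where A
and B are the worm counts in the control and odorant halves of the
plate; worms in the central 1-cm band are excluded from the index.
The per-plate CI is the statistical unit of analysis (pooled-count CI
is available as a secondary output).  Counts are odorant-anchored, so
alternating the physical odorant side across trials is a no-op after
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .trackio import PlateAssay, PlateGeometry

logger = logging.getLogger("wormassay")

GROUP_KEYS = ["species", "stage", "odorant", "dilution"]


@dataclass
class ChemotaxisResult:
    plate_id: str
    species: str
    stage: str
    odorant: str
    dilution: str
    ci: float                 # in [-1, 1]; NaN when unscorable
    n_scored: int             # A + B
    n_excluded_central: int
    scorable: bool = True


def chemotaxis_index(assay: PlateAssay) -> ChemotaxisResult:
    """Per-plate CI = (B - A)/(A + B); central-zone worms are reported
    but excluded.  A plate with A + B = 0 is flagged unscorable (CI NaN)
    and excluded from downstream statistics."""
    a, b = assay.count_control, assay.count_odorant
    if a + b == 0:
        logger.warning("plate %s unscorable: no worms in scoring zones "
                       "(all %d central)", assay.plate_id, assay.count_central)
        ci, scorable = float("nan"), False
    else:
        ci, scorable = (b - a) / (a + b), True
    return ChemotaxisResult(
        plate_id=assay.plate_id, species=assay.species, stage=assay.stage,
        odorant=assay.odorant, dilution=assay.dilution,
        ci=ci, n_scored=a + b, n_excluded_central=assay.count_central,
        scorable=scorable,
    )


def pooled_chemotaxis_index(assays: Sequence[PlateAssay]) -> float:
    """Secondary output: CI computed on counts pooled across plates."""
    a = sum(x.count_control for x in assays)
    b = sum(x.count_odorant for x in assays)
    if a + b == 0:
        raise InsufficientDataError("no worms in scoring zones across plates")
    return (b - a) / (a + b)


def assign_zones(final_positions: np.ndarray, geometry: PlateGeometry,
                 odorant_side: str, plate_id: str = "plate",
                 species: str = "synthetic", stage: str = "adult",
                 odorant: str = "ET", dilution: str = "1:1000") -> PlateAssay:
    """Count final worm positions into control/odorant/central zones.

    Positions are plate-centric (mm), x along the A-B axis.  The signed
    distance from the midline decides the zone: within the central band
    -> C; otherwise the side matching ``odorant_side`` -> odorant (B),
    opposite -> control (A).  Positions outside the plate radius are
    excluded with a logged warning.
    """
    if odorant_side not in ("left", "right"):
        raise ValueError(f"odorant_side must be 'left' or 'right', got "
                         f"{odorant_side!r}")
    pos = np.asarray(final_positions, dtype=float).reshape(-1, 2)
    r = np.linalg.norm(pos, axis=1)
    outside = r > geometry.radius + 1e-9
    if outside.any():
        logger.warning("plate %s: %d position(s) outside the plate radius "
                       "excluded", plate_id, int(outside.sum()))
    pos = pos[~outside]
    x = pos[:, 0]
    central = np.abs(x) <= geometry.central_band_halfwidth
    right = x > geometry.central_band_halfwidth
    left = x < -geometry.central_band_halfwidth
    if odorant_side == "right":
        n_odor, n_ctrl = int(right.sum()), int(left.sum())
    else:
        n_odor, n_ctrl = int(left.sum()), int(right.sum())
    return PlateAssay(
        plate_id=plate_id, species=species, stage=stage, odorant=odorant,
        dilution=dilution, odorant_side=odorant_side,
        count_control=n_ctrl, count_odorant=n_odor,
        count_central=int(central.sum()),
    )


def summarize_by_condition(results: Sequence[ChemotaxisResult]) -> pd.DataFrame:
    """Per-(species, stage, odorant, dilution) distribution summary of
    per-plate CIs: n_plates, median, quartiles, min and max (matching a
    boxplot of plate values).  Unscorable plates are excluded."""
    rows = [r for r in results if r.scorable]
    dropped = len(results) - len(rows)
    if dropped:
        logger.info("summarize_by_condition: %d unscorable plate(s) excluded",
                    dropped)
    if not rows:
        logger.warning("summarize_by_condition: no scorable plates")
        return pd.DataFrame(columns=GROUP_KEYS + ["n_plates", "median_ci",
                                                  "q1_ci", "q3_ci", "min_ci",
                                                  "max_ci"])
    df = pd.DataFrame([r.__dict__ for r in rows])
    out = (df.groupby(GROUP_KEYS)["ci"]
             .agg(n_plates="size", median_ci="median",
                  q1_ci=lambda s: s.quantile(0.25),
                  q3_ci=lambda s: s.quantile(0.75),
                  min_ci="min", max_ci="max")
             .reset_index())
    return out
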