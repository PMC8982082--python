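"""Iodine-density-based lung compartment segmentation.

The lung is partitioned into three compartments by thresholds anchored to
each case's own vascular reference iodine densities (ID):

* ``PerfDef`` — malperfused: ID <= 5% of the main-pulmonary-artery (MPA)
  mean, including physically sub-zero spectral-noise voxels;
* ``PerfNorm`` — normally perfused: between 5% of the MPA mean and 50% of
  the left-atrium (LA) mean;
* ``Ves`` — vessel compartment: above 50% of the LA mean.

Thresholds are always recomputed per case from that case's reference ROIs,
never pooled across a cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume_io import VoxelVolume, validate_case_grids

logger = logging.getLogger(__name__)

# Compartment label codes.
OUTSIDE = 0
PERFDEF = 1
PERFNORM = 2
VES = 3

COMPARTMENT_NAMES = {OUTSIDE: "outside", PERFDEF: "PerfDef", PERFNORM: "PerfNorm", VES: "Ves"}

#: MPA mean ID below which contrast bolus quality is questionable (mg/mL).
LOW_CONTRAST_WARN_MGML = 5.0


@dataclass(frozen=True)
class VesselReference:
    """Mean iodine densities of the vascular reference ROIs (mg/mL)."""

    id_mpa: float
    id_la: float
    n_mpa: int
    n_la: int

    def __post_init__(self):
        if self.n_mpa < 1 or self.n_la < 1:
            raise ValueError("reference ROIs must contain at least one voxel")
        if self.id_mpa <= 0 or self.id_la <= 0:
            raise ValueError(
                "non-positive reference iodine density "
                f"(id_mpa={self.id_mpa}, id_la={self.id_la}); failed contrast bolus?"
            )


@dataclass
class CompartmentMap:
    """Per-voxel compartment labels and the thresholds that produced them.

    ``labels`` is nonzero exactly on lung-mask voxels. ``t_low`` and
    ``t_high`` are in mg iodine/mL. ``n_negative_clamped`` counts sub-zero
    IDI voxels (spectral noise) that were assigned to PerfDef.
    """

    labels: np.ndarray
    t_low: float
    t_high: float
    n_negative_clamped: int

    @property
    def thresholds(self) -> tuple[float, float]:
        return (self.t_low, self.t_high)

    @property
    def n_lung(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass(frozen=True)
class CompartmentVolumes:
    """Compartment sizes as percent of total lung volume (sum to 100)."""

    v_perfdef_pct: float
    v_perfnorm_pct: float
    v_ves_pct: float
    total_lung_ml: float


def measure_vessel_reference(
    idi: VoxelVolume, mpa_mask: VoxelVolume, la_mask: VoxelVolume
) -> VesselReference:
    """Mean iodine density over the MPA and LA reference ROIs.

    Warns below 5 mg/mL in the MPA (the quality floor used to exclude cases
    with insufficient pulmonary-arterial contrast); raises at <= 0.
    """
    validate_case_grids([idi, mpa_mask, la_mask])
    out = {}
    for name, mask in (("MPA", mpa_mask), ("LA", la_mask)):
        m = mask.values.astype(bool)
        n = int(np.count_nonzero(m))
        if n == 0:
            raise ValueError(f"empty ROI: {name} mask selects no voxels")
        out[name] = (float(idi.values[m].mean()), n)
    id_mpa, n_mpa = out["MPA"]
    id_la, n_la = out["LA"]
    if 0 < id_mpa < LOW_CONTRAST_WARN_MGML:
        logger.warning(
            "MPA mean ID %.2f mg/mL is below %.0f mg/mL; contrast bolus may be "
            "insufficient for reliable thresholds", id_mpa, LOW_CONTRAST_WARN_MGML,
        )
    return VesselReference(id_mpa=id_mpa, id_la=id_la, n_mpa=n_mpa, n_la=n_la)


def compartment_thresholds(
    ref: VesselReference, upper_reference: str = "la"
) -> tuple[float, float]:
    """(t_low, t_high) = (5% of MPA mean, 50% of LA mean) in mg/mL.

    ``upper_reference='mpa'`` switches the vessel bound to 50% of the MPA
    mean — exposed for sensitivity analysis only; the LA reading is the
    one that makes the three compartments a complete partition.
    """
    t_low = 0.05 * ref.id_mpa
    if upper_reference == "la":
        t_high = 0.50 * ref.id_la
    elif upper_reference == "mpa":
        t_high = 0.50 * ref.id_mpa
    else:
        raise ValueError(f"upper_reference must be 'la' or 'mpa', got {upper_reference!r}")
    if t_low >= t_high:
        raise ValueError(
            f"degenerate thresholds t_low={t_low:.3f} >= t_high={t_high:.3f} mg/mL; "
            "implausible MPA/LA contrast ratio"
        )
    return t_low, t_high


def segment_compartments(
    idi: VoxelVolume,
    lung_mask: VoxelVolume,
    ref: VesselReference,
    upper_reference: str = "la",
) -> CompartmentMap:
    """Label every lung voxel as PerfDef, PerfNorm or Ves.

    Boundary conventions: PerfDef is closed at t_low (ID <= 5% MPA, sub-zero
    values included and counted), PerfNorm is the half-open interval
    (t_low, t_high], Ves is open above t_high. The labels form an exact
    partition of the lung mask.
    """
    validate_case_grids([idi, lung_mask])
    t_low, t_high = compartment_thresholds(ref, upper_reference)
    lung = lung_mask.values.astype(bool)
    x = idi.values
    labels = np.zeros(x.shape, dtype=np.uint8)
    labels[lung & (x <= t_low)] = PERFDEF
    labels[lung & (x > t_low) & (x <= t_high)] = PERFNORM
    labels[lung & (x > t_high)] = VES
    n_neg = int(np.count_nonzero(lung & (x < 0)))
    if n_neg:
        logger.info("%d sub-zero IDI voxels assigned to PerfDef", n_neg)
    return CompartmentMap(labels=labels, t_low=float(t_low), t_high=float(t_high),
                          n_negative_clamped=n_neg)


def compartment_volumes(
    cmap: CompartmentMap, spacing: tuple[float, float, float]
) -> CompartmentVolumes:
    """Compartment sizes as percent of total lung volume, plus lung volume in mL."""
    counts = np.bincount(cmap.labels.ravel(), minlength=4)
    n_lung = int(counts[PERFDEF] + counts[PERFNORM] + counts[VES])
    if n_lung == 0:
        raise ValueError("compartment map contains no lung voxels")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    return CompartmentVolumes(
        v_perfdef_pct=100.0 * counts[PERFDEF] / n_lung,
        v_perfnorm_pct=100.0 * counts[PERFNORM] / n_lung,
        v_ves_pct=100.0 * counts[VES] / n_lung,
        total_lung_ml=n_lung * voxel_ml,
    )
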