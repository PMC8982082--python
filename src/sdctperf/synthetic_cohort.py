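"""Synthetic dual-energy lung phantoms with per-subgroup perfusion phenotypes.

Each phantom case emulates the inputs of the analysis pipeline: an
iodine-density image (IDI), a virtual-non-contrast image (VNC), a lung mask
and MPA/LA reference-ROI masks, all on one voxel grid, plus full ground
truth (defect and emphysema voxel sets, generator parameters, seed).

The anatomy is deliberately schematic — two ellipsoidal lungs, a cylindrical
main pulmonary artery (MPA) and a spherical left atrium (LA) in the
mediastinum. What the generator does reproduce carefully is the *intensity
structure* that drives the analysis:

* normal parenchyma iodine density near 9.1% of the MPA mean,
* wedge-shaped homogeneous near-zero-ID defects (CTEPH-like, group 4),
* diffuse patchy heterogeneous defects whose left-skewed ID distribution
  yields negative within-defect skewness (PAH / left-heart-like, groups 1/2),
* emphysema-coupled homogeneous defects with VNC values below -950 HU
  (lung-disease-like, group 3),
* MPA/LA reference intensities near the clinically observed medians
  (14.1 and 8.9 mg/mL).

Generation is a pure function of (profile, grid, seed): identical inputs
produce bit-identical cases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .volume_io import (
    SUBGROUP_LABELS,
    VoxelVolume,
    write_volume,
)

#: Fraction of the nominal PerfDef threshold (5% of MPA mean) used as the
#: upper edge of defect intensity draws, so defect voxels stay malperfused.
_DEFECT_ID_CAP_FRAC = 0.95

#: VNC intensity model (HU): normal parenchyma, emphysema, soft tissue.
VNC_PARENCHYMA_HU = -860.0
VNC_EMPHYSEMA_HU = -975.0
VNC_SOFT_TISSUE_HU = 40.0

#: Tolerance on realized defect/emphysema voxel fractions.
FRACTION_TOL = 0.05

GEOMETRIES = ("wedge", "diffuse_patchy", "emphysema_coupled", "none")


@dataclass
class SubgroupProfile:
    """Generative parameters for one PH-subgroup phantom phenotype.

    Iodine densities are mg iodine/mL; fractions are of lung voxels (0-1).
    ``defect_id_mean`` / ``defect_id_cv`` parameterize the within-defect ID
    distribution: a symmetric Gaussian for homogeneous geometries (wedge,
    emphysema_coupled) and a left-skewed scaled Beta for diffuse_patchy,
    which is what makes heterogeneous defects print negative ID skewness.
    """

    name: str
    id_mpa: float = 14.1
    id_la: float = 8.9
    parenchyma_mean_frac: float = 0.091
    parenchyma_cv: float = 0.20
    defect_fraction: float = 0.0
    defect_geometry: str = "none"
    defect_id_mean: float = 0.30
    defect_id_cv: float = 0.25
    emphysema_fraction: float = 0.0
    noise_sd_idi: float = 0.02
    noise_sd_vnc: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.defect_fraction <= 1:
            raise ValueError(f"defect_fraction must be in [0, 1], got {self.defect_fraction}")
        if not 0 <= self.emphysema_fraction <= 1:
            raise ValueError(f"emphysema_fraction must be in [0, 1], got {self.emphysema_fraction}")
        if not self.id_mpa > self.id_la > 0:
            raise ValueError(f"need id_mpa > id_la > 0, got {self.id_mpa}, {self.id_la}")
        if not 0.05 * self.id_mpa < 0.50 * self.id_la:
            raise ValueError(
                "ill-posed compartment partition: 5% of MPA mean must lie below "
                f"50% of LA mean (got {0.05 * self.id_mpa:.3f} vs {0.50 * self.id_la:.3f})"
            )
        if self.defect_geometry not in GEOMETRIES:
            raise ValueError(f"unknown defect_geometry {self.defect_geometry!r}")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom case."""

    label: str
    defect_mask: np.ndarray
    emphysema_mask: np.ndarray
    defect_fraction_realized: float
    emphysema_fraction_realized: float
    profile: SubgroupProfile
    seed: int


@dataclass
class PhantomCase:
    """One synthetic case: five grid-consistent volumes plus ground truth."""

    case_id: str
    idi: VoxelVolume
    vnc: VoxelVolume
    lung_mask: VoxelVolume
    mpa_mask: VoxelVolume
    la_mask: VoxelVolume
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# presets

def preset_profile(name: str) -> SubgroupProfile:
    """Default generative profile for one subgroup.

    Defect and emphysema fractions follow the clinically reported group
    medians (malperfused volume: control 25.6%, g1 33.7%, g2-Ipc 21.4%,
    g2-Cpc 37.2%, g3 53.7%, g4 42.5%; emphysema: g3 8.4%, g4 0.4%, other
    groups 0.1-0.3%). Geometry encodes the qualitative phenotype: sharp
    wedges for CTEPH (g4), emphysema-coupled homogeneous defects for lung
    disease (g3), diffuse patchy heterogeneous defects elsewhere.
    """
    common = dict(id_mpa=14.1, id_la=8.9, parenchyma_mean_frac=0.091)
    heterogeneous = dict(defect_geometry="diffuse_patchy",
                         defect_id_mean=0.47, defect_id_cv=0.24)
    homogeneous = dict(defect_id_mean=0.30, defect_id_cv=0.25)
    presets = {
        "control": dict(defect_fraction=0.256, emphysema_fraction=0.002,
                        **heterogeneous),
        "g1": dict(defect_fraction=0.337, emphysema_fraction=0.002, **heterogeneous),
        "g2_ipc": dict(defect_fraction=0.214, emphysema_fraction=0.001, **heterogeneous),
        "g2_cpc": dict(defect_fraction=0.372, emphysema_fraction=0.003, **heterogeneous),
        "g3": dict(defect_fraction=0.537, emphysema_fraction=0.084,
                   defect_geometry="emphysema_coupled", **homogeneous),
        "g4": dict(defect_fraction=0.425, emphysema_fraction=0.004,
                   defect_geometry="wedge", **homogeneous),
    }
    if name not in presets:
        raise ValueError(f"unknown subgroup {name!r}; expected one of {SUBGROUP_LABELS}")
    return SubgroupProfile(name=name, **common, **presets[name])


def profile_to_yaml(profile: SubgroupProfile, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(profile), fh, sort_keys=False)


def profile_from_yaml(path: str | os.PathLike) -> SubgroupProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SubgroupProfile(**data)


# ---------------------------------------------------------------------------
# geometry helpers

def _grid_coords(shape):
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def _ellipsoid(coords, center, semi):
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _anatomy(shape):
    """Lung halves, MPA/LA structures and their 50%-area measurement ROIs."""
    n = np.array(shape, dtype=float)
    coords = _grid_coords(shape)
    semi = (0.17 * n[0], 0.27 * n[1], 0.38 * n[2])
    lung_left = _ellipsoid(coords, (0.28 * n[0], 0.50 * n[1], 0.50 * n[2]), semi)
    lung_right = _ellipsoid(coords, (0.72 * n[0], 0.50 * n[1], 0.50 * n[2]), semi)

    x, y, z = coords
    # MPA: cylinder along z in the mediastinum; ROI covers the central 50%
    # of the cross-sectional area (radius / sqrt(2)).
    r_mpa = 0.05 * n.min()
    d2 = (x - 0.50 * n[0]) ** 2 + (y - 0.32 * n[1]) ** 2
    zspan = (z >= 0.38 * n[2]) & (z <= 0.62 * n[2])
    mpa_full = (d2 <= r_mpa**2) & zspan
    mpa_roi = (d2 <= r_mpa**2 / 2.0) & zspan
    # LA: sphere; ROI is the concentric sphere of half cross-sectional area.
    r_la = 0.07 * n.min()
    d2la = (x - 0.50 * n[0]) ** 2 + (y - 0.62 * n[1]) ** 2 + (z - 0.45 * n[2]) ** 2
    la_full = d2la <= r_la**2
    la_roi = d2la <= r_la**2 / 2.0

    vessels = mpa_full | la_full
    lung_left &= ~vessels
    lung_right &= ~vessels
    return lung_left, lung_right, mpa_full, mpa_roi, la_full, la_roi


def _wedge_defect(shape, lung_left, lung_right, target_n, rng):
    """Cone-shaped defects with apex at each hilum, pointing laterally.

    A cone anchored on the medial lung surface is star-shaped from its apex,
    hence connected, and touches the lung boundary by construction. The
    half-angle is chosen as the angle quantile that realizes the per-lung
    target voxel count exactly.
    """
    defect = np.zeros(shape, dtype=bool)
    # direction = lateral (away from the mediastinum) along x
    halves = [(lung_left, -1.0), (lung_right, +1.0)]
    n_lung_total = sum(int(h.sum()) for h, _ in halves)
    for half, direction in halves:
        idx = np.argwhere(half)
        if idx.size == 0:
            continue
        share = int(round(target_n * half.sum() / n_lung_total))
        if share == 0:
            continue
        # apex: the most medial lung voxel near mid y/z, jittered by seed
        medial = idx[:, 0] * (-direction)
        apex_candidates = idx[medial == medial.max()]
        apex = apex_candidates[rng.integers(len(apex_candidates))].astype(float)
        axis = np.array([direction, 0.0, 0.0])
        axis += rng.normal(0, 0.08, 3)  # small random tilt
        axis /= np.linalg.norm(axis)
        v = idx.astype(float) - apex
        dist = np.linalg.norm(v, axis=1)
        dist[dist == 0] = 1.0
        cosang = (v @ axis) / dist
        if share >= len(idx):
            chosen = idx
        else:
            order = np.argsort(-cosang, kind="stable")
            chosen = idx[order[:share]]
        defect[tuple(chosen.T)] = True
    return defect


def _blob_defect(shape, lung, target_n, radii, rng):
    """Union of random spheres inside the lung, trimmed to the exact target
    count (trim removes the last-added voxels, so blobs stay compact)."""
    lung_idx = np.argwhere(lung)
    coords = lung_idx.astype(float)
    chosen: list[np.ndarray] = []
    taken = np.zeros(len(lung_idx), dtype=bool)
    total = 0
    max_iter = 20000
    for _ in range(max_iter):
        if total >= target_n:
            break
        center = coords[rng.integers(len(coords))]
        r = rng.uniform(*radii)
        inside = np.flatnonzero(
            (~taken) & (np.einsum("ij,ij->i", coords - center, coords - center) <= r * r)
        )
        if inside.size == 0:
            continue
        if total + inside.size > target_n:
            inside = inside[: target_n - total]
        taken[inside] = True
        chosen.append(inside)
        total += inside.size
    if total < target_n:
        raise ValueError(
            f"could not place defect voxels: reached {total} of {target_n} "
            f"target voxels in {max_iter} iterations"
        )
    defect = np.zeros(shape, dtype=bool)
    order = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    defect[tuple(lung_idx[order].T)] = True
    return defect, lung_idx[order]  # ordered voxel list (blob addition order)


def _beta_params(mean_rel: float, sd_rel: float) -> tuple[float, float]:
    """Beta(a, b) matching a mean and sd on the unit interval."""
    if not 0 < mean_rel < 1:
        raise ValueError("relative defect ID mean must lie strictly inside (0, cap)")
    nu = mean_rel * (1 - mean_rel) / sd_rel**2 - 1
    if nu <= 0:
        raise ValueError("defect_id_cv too large for a Beta intensity model")
    return mean_rel * nu, (1 - mean_rel) * nu


# ---------------------------------------------------------------------------
# generation

def generate_phantom(
    profile: SubgroupProfile,
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    case_id: str | None = None,
) -> PhantomCase:
    """Generate one phantom case; a pure function of (profile, grid, seed)."""
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError(f"grid must be at least 32 voxels per axis, got {shape}")
    spacing = tuple(float(s) for s in spacing)
    rng = np.random.default_rng(seed)

    lung_left, lung_right, mpa_full, mpa_roi, la_full, la_roi = _anatomy(shape)
    lung = lung_left | lung_right
    n_lung = int(lung.sum())
    if mpa_roi.sum() == 0 or la_roi.sum() == 0:
        raise ValueError("grid too small to carve vascular reference ROIs")

    # --- defect voxel set -------------------------------------------------
    target_n = int(round(profile.defect_fraction * n_lung))
    geometry = profile.defect_geometry
    ordered_defect_idx = None
    if geometry == "none" or target_n == 0:
        defect = np.zeros(shape, dtype=bool)
    elif geometry == "wedge":
        defect = _wedge_defect(shape, lung_left, lung_right, target_n, rng)
    elif geometry == "diffuse_patchy":
        scale = min(shape) / 64.0
        defect, ordered_defect_idx = _blob_defect(
            shape, lung, target_n, (2.0 * scale, 3.5 * scale), rng
        )
    elif geometry == "emphysema_coupled":
        scale = min(shape) / 64.0
        defect, ordered_defect_idx = _blob_defect(
            shape, lung, target_n, (4.0 * scale, 7.0 * scale), rng
        )
    realized = defect.sum() / n_lung
    if abs(realized - profile.defect_fraction) > FRACTION_TOL:
        raise ValueError(
            f"realized defect fraction {realized:.3f} misses target "
            f"{profile.defect_fraction:.3f} by more than {FRACTION_TOL}"
        )

    # --- emphysema voxel set ---------------------------------------------
    emph_n = int(round(profile.emphysema_fraction * n_lung))
    emphysema = np.zeros(shape, dtype=bool)
    if emph_n > 0:
        if geometry == "emphysema_coupled" and ordered_defect_idx is not None:
            if emph_n > len(ordered_defect_idx):
                raise ValueError(
                    "emphysema_fraction exceeds defect_fraction in coupled geometry"
                )
            sel = ordered_defect_idx[:emph_n]  # first blobs -> compact regions
            emphysema[tuple(sel.T)] = True
        else:
            _, ordered = _blob_defect(shape, lung, emph_n, (1.0, 2.5), rng)
            emphysema[tuple(ordered.T)] = True

    # --- iodine-density image --------------------------------------------
    # Normal parenchyma ID is lognormal: clinical parenchyma histograms are
    # right-skewed with a thin low tail, which also keeps parenchyma from
    # leaking mass below the malperfusion threshold.
    p_mean = profile.parenchyma_mean_frac * profile.id_mpa
    sigma = float(np.sqrt(np.log1p(profile.parenchyma_cv**2)))
    mu = float(np.log(p_mean)) - sigma**2 / 2.0
    idi = rng.normal(0.5, 0.1, shape)  # faint soft-tissue iodine background
    idi[lung] = rng.lognormal(mu, sigma, n_lung)

    cap = _DEFECT_ID_CAP_FRAC * 0.05 * profile.id_mpa
    n_def = int(defect.sum())
    if n_def:
        if geometry == "diffuse_patchy":
            a, b = _beta_params(
                profile.defect_id_mean / cap,
                profile.defect_id_cv * profile.defect_id_mean / cap,
            )
            idi[defect] = cap * rng.beta(a, b, n_def)
        else:
            idi[defect] = rng.normal(
                profile.defect_id_mean,
                profile.defect_id_cv * profile.defect_id_mean,
                n_def,
            )
    emph_only = emphysema & ~defect
    n_eo = int(emph_only.sum())
    if n_eo:  # emphysematous tissue is unperfused regardless of subgroup
        idi[emph_only] = rng.normal(
            profile.defect_id_mean, profile.defect_id_cv * profile.defect_id_mean, n_eo
        )
    idi[mpa_full] = profile.id_mpa
    idi[la_full] = profile.id_la
    idi += rng.normal(0.0, profile.noise_sd_idi, shape)  # spectral noise, unclipped

    # --- virtual-non-contrast image --------------------------------------
    vnc = rng.normal(VNC_SOFT_TISSUE_HU, profile.noise_sd_vnc, shape)
    vnc[lung] = rng.normal(VNC_PARENCHYMA_HU, profile.noise_sd_vnc, n_lung)
    n_emph = int(emphysema.sum())
    if n_emph:
        vnc[emphysema] = rng.normal(VNC_EMPHYSEMA_HU, profile.noise_sd_vnc, n_emph)

    affine = np.diag([*spacing, 1.0])
    mk = lambda arr, kind: VoxelVolume(arr, spacing=spacing, affine=affine, kind=kind)
    truth = PhantomTruth(
        label=profile.name,
        defect_mask=defect,
        emphysema_mask=emphysema,
        defect_fraction_realized=float(realized),
        emphysema_fraction_realized=float(emphysema.sum() / n_lung),
        profile=profile,
        seed=int(seed),
    )
    cid = case_id if case_id is not None else f"{profile.name}_s{seed}"
    return PhantomCase(
        case_id=cid,
        idi=mk(idi.astype(np.float32), "idi"),
        vnc=mk(vnc.astype(np.float32), "vnc"),
        lung_mask=mk(lung.astype(np.uint8), "mask"),
        mpa_mask=mk(mpa_roi.astype(np.uint8), "mask"),
        la_mask=mk(la_roi.astype(np.uint8), "mask"),
        truth=truth,
    )


def case_seed(master_seed: int, index: int) -> int:
    """Stable per-case seed derived from the master seed (< 2^31)."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % 2**31)


def generate_cohort(
    counts: Mapping[str, int],
    shape: Sequence[int] = (64, 64, 64),
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> list[PhantomCase]:
    """Generate a cohort of phantoms, optionally writing volumes + tables.

    ``counts`` maps subgroup label to case count; case order (and the
    per-case seed) follows the sorted subgroup labels, so a cohort is a pure
    function of (counts, grid, seed). With ``out_dir`` the NIfTI volumes,
    ``cohort.csv`` and ``truth.csv`` are written there.
    """
    if not counts:
        raise ValueError("counts must name at least one subgroup")
    for name, n in counts.items():
        if name not in SUBGROUP_LABELS:
            raise ValueError(f"unknown subgroup {name!r}")
        if n < 0:
            raise ValueError(f"negative count for {name}")
    if sum(counts.values()) < 1:
        raise ValueError("total cohort size must be >= 1")

    cases = []
    index = 0
    for name in sorted(counts):
        profile = preset_profile(name)
        for k in range(counts[name]):
            cid = f"{name}_{k:03d}"
            cases.append(
                generate_phantom(profile, shape, spacing,
                                 seed=case_seed(seed, index), case_id=cid)
            )
            index += 1

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows, truth_rows = [], []
        for case in cases:
            paths = {}
            for tag in ("idi", "vnc", "lung_mask", "mpa_mask", "la_mask"):
                fname = f"{case.case_id}_{tag}.nii.gz"
                write_volume(getattr(case, tag), out / fname)
                paths[f"{tag}_path"] = fname
            rows.append({"case_id": case.case_id,
                         "subgroup_label": case.truth.label, **paths})
            truth_rows.append({
                "case_id": case.case_id,
                "true_label": case.truth.label,
                "defect_fraction_realized": case.truth.defect_fraction_realized,
                "emphysema_fraction_realized": case.truth.emphysema_fraction_realized,
                "seed": case.truth.seed,
            })
        pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return cases
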