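"""Synthetic FIB/SEM-like scenes with ground truth, plus transcribed tables.

Two distinct sources of test data live here:

* :func:`build_scene` rasterizes a dendrite — a gently curved capped
  cylinder, optionally carrying mushroom spines with an asymmetric
  (excitatory) synapse patch on each head and symmetric (inhibitory)
  patches on the shaft — and deposits immunogold particles on the
  membrane (uniform or parent-offspring clustered) and in the
  cytoplasm (3D Poisson), recording ground truth for every particle.
* :func:`study_tables` returns the per-dendrite count/volume
  tables transcribed from the published quantification of SK2
  immunoparticles on reconstructed CA1 dendrites, which drive the
  worked-example summaries. :func:`reference_spine_table` is a
  *synthetic* per-spine reconstruction consistent with those printed
  per-dendrite totals (the real per-spine data are not deposited).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra

from skmap.surface_model import SurfaceGraph, binarize, extract_surface
from skmap.volume_io import (
    CompartmentMeta,
    LabelVolume,
    ParticleRecord,
    SynapseMeta,
    VoxelSpacing,
)

__all__ = [
    "SceneConfig",
    "Scene",
    "build_scene",
    "study_tables",
    "reference_spine_table",
]

SHAFT_LABEL = 1


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic dendrite scene (all lengths in nm).

    Defaults mimic the scale of the reconstructed CA1 dendrites: a shaft
    about 4 μm long and 0.5 μm in radius (volume ≈ 3 μm³), spine head
    volumes 0.005-0.03 μm³, membrane particle intensities of a few tens
    of gold/μm² and an intracellular density on the order of 10² gold/μm³.
    The grid defaults to the 20-nm isotropic analysis spacing;
    anisotropic acquisition grids (5 x 5 x 20 nm) are supported and then
    resampled internally before particle placement so that deposited
    particles live on the same surface model the analyzer uses.
    """

    kind: str = "pyramidal"  # "pyramidal" (spiny) | "interneuron" (smooth)
    spacing: tuple[float, float, float] = (20.0, 20.0, 20.0)
    shaft_length: float = 4000.0
    shaft_radius: float = 500.0
    shaft_curvature_amp: float = 200.0  # sagitta of the curved axis
    n_spines: int = 13
    spine_head_radius_range: tuple[float, float] = (110.0, 190.0)
    spine_neck_length: float = 300.0
    spine_neck_radius: float = 60.0
    n_sym_synapses: int = 3
    synapse_patch_radius: float = 120.0
    particle_model: str = "clustered_surface"  # or "csr_surface"
    lambda_pm: float = 34.0  # gold/μm² (csr_surface)
    n_parents: int = 40
    offspring_per_parent: float = 5.0  # Poisson mean per parent
    offspring_spread: float = 30.0  # geodesic sigma, nm
    lambda_intra: float = 125.0  # gold/μm³
    margin: float = 800.0  # dead space around the dendrite
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pyramidal", "interneuron"):
            raise ValueError(f"unknown dendrite kind {self.kind!r}")
        if self.kind == "interneuron" and self.n_spines:
            raise ValueError("interneuron dendrites are smooth: n_spines must be 0")
        for name in ("shaft_length", "shaft_radius", "spine_neck_length",
                     "spine_neck_radius", "synapse_patch_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.particle_model not in ("csr_surface", "clustered_surface"):
            raise ValueError(f"unknown particle model {self.particle_model!r}")
        if self.particle_model == "clustered_surface" and self.offspring_spread <= 0:
            raise ValueError("offspring_spread must be positive for the clustered model")


@dataclass
class Scene:
    """A generated scene: volumes, tables and per-particle ground truth."""

    config: SceneConfig
    label_volume: LabelVolume  # acquisition grid (may be anisotropic)
    iso_volume: LabelVolume  # isotropic analysis grid
    synapse_volume: LabelVolume  # patch ids on the isotropic grid
    synapse_meta: list[SynapseMeta]
    compartments: list[CompartmentMeta]
    particles: list[ParticleRecord]
    ground_truth: pd.DataFrame
    surface: SurfaceGraph = field(repr=False, default=None)  # merged dendrite membrane

    @property
    def spine_labels(self) -> list[int]:
        return [c.label_id for c in self.compartments if c.kind == "spine"]


def _grid_coords(shape, spacing: VoxelSpacing):
    nz, ny, nx = shape
    z = (np.arange(nz) + 0.5) * spacing.dz
    y = (np.arange(ny) + 0.5) * spacing.dy
    x = (np.arange(nx) + 0.5) * spacing.dx
    return np.meshgrid(z, y, x, indexing="ij")


def _rasterize_geometry(cfg: SceneConfig, rng: np.random.Generator):
    """Rasterize shaft + spines; returns (labels, spine info list, extent)."""
    sp = VoxelSpacing(*cfg.spacing)
    reach = cfg.shaft_radius + cfg.spine_neck_length + 2 * cfg.spine_head_radius_range[1]
    ext_x = cfg.shaft_length + 2 * cfg.margin
    ext_yz = 2 * (reach + cfg.margin) if cfg.kind == "pyramidal" else 2 * (
        cfg.shaft_radius + cfg.shaft_curvature_amp + cfg.margin
    )
    ext_y = ext_yz + 2 * cfg.shaft_curvature_amp
    nx = int(np.ceil(ext_x / sp.dx))
    ny = int(np.ceil(ext_y / sp.dy))
    nz = int(np.ceil(ext_yz / sp.dz))
    Z, Y, X = _grid_coords((nz, ny, nx), sp)

    x0 = cfg.margin
    x1 = cfg.margin + cfg.shaft_length
    yc = ny * sp.dy / 2.0
    zc = nz * sp.dz / 2.0
    # gently curved axis: y wanders sinusoidally along x
    y_axis = yc + cfg.shaft_curvature_amp * np.sin(np.pi * (X - x0) / cfg.shaft_length)
    r2 = (Y - y_axis) ** 2 + (Z - zc) ** 2
    shaft = (X >= x0) & (X <= x1) & (r2 <= cfg.shaft_radius**2)
    labels = np.where(shaft, SHAFT_LABEL, 0).astype(np.int32)

    spines = []
    if cfg.n_spines:
        head_centers = []
        attempts = 0
        while len(spines) < cfg.n_spines:
            attempts += 1
            if attempts > 200 * cfg.n_spines:
                raise RuntimeError(
                    "could not place non-overlapping spines; reduce n_spines or sizes"
                )
            xs = rng.uniform(x0 + 200.0, x1 - 200.0)
            theta = rng.uniform(0, 2 * np.pi)
            r_head = rng.uniform(*cfg.spine_head_radius_range)
            ya = yc + cfg.shaft_curvature_amp * np.sin(np.pi * (xs - x0) / cfg.shaft_length)
            u = np.array([0.0, np.cos(theta), np.sin(theta)])  # (x, y, z) direction
            base = np.array([xs, ya, zc]) + u * (cfg.shaft_radius - sp.dx)
            tip = base + u * (cfg.spine_neck_length + sp.dx)
            head_c = tip + u * (0.8 * r_head)
            if any(
                np.linalg.norm(head_c - hc) < (r_head + rr) * 1.25
                for hc, rr in head_centers
            ):
                continue
            head_centers.append((head_c, r_head))
            spines.append(
                {"base": base, "tip": tip, "head_center": head_c, "head_radius": r_head,
                 "direction": u, "label": SHAFT_LABEL + 1 + len(spines)}
            )

        P = np.stack([X, Y, Z], axis=-1)  # (nz, ny, nx, 3) as (x, y, z)
        for s in spines:
            lo = np.minimum(s["base"], s["head_center"]) - (s["head_radius"] + 2 * sp.dx)
            hi = np.maximum(s["base"], s["head_center"]) + (s["head_radius"] + 2 * sp.dx)
            # bounding box in voxel indices keeps per-spine work local
            i0 = max(int(lo[0] / sp.dx), 0); i1 = min(int(hi[0] / sp.dx) + 2, nx)
            j0 = max(int(lo[1] / sp.dy), 0); j1 = min(int(hi[1] / sp.dy) + 2, ny)
            k0 = max(int(lo[2] / sp.dz), 0); k1 = min(int(hi[2] / sp.dz) + 2, nz)
            sub = P[k0:k1, j0:j1, i0:i1]
            a, b = s["base"], s["tip"]
            ab = b - a
            t = np.clip(((sub - a) @ ab) / (ab @ ab), 0.0, 1.0)
            closest = a + t[..., None] * ab
            d_neck = np.linalg.norm(sub - closest, axis=-1)
            d_head = np.linalg.norm(sub - s["head_center"], axis=-1)
            mask = (d_neck <= cfg.spine_neck_radius) | (d_head <= s["head_radius"])
            region = labels[k0:k1, j0:j1, i0:i1]
            region[mask & (region == 0)] = s["label"]
    return labels, spines, sp


def _paint_patches(
    iso: LabelVolume,
    spines: list[dict],
    cfg: SceneConfig,
    rng: np.random.Generator,
) -> tuple[LabelVolume, list[SynapseMeta]]:
    """Paint asymmetric patches on spine heads and symmetric ones on the shaft."""
    from skmap.surface_model import _boundary_mask

    syn = np.zeros(iso.shape, dtype=np.int32)
    meta: list[SynapseMeta] = []
    s = iso.spacing.dx
    patch_id = 0

    def centers_of(mask):
        vox = np.argwhere(mask)
        c = np.empty((len(vox), 3))
        c[:, 0] = (vox[:, 2] + 0.5) * s
        c[:, 1] = (vox[:, 1] + 0.5) * s
        c[:, 2] = (vox[:, 0] + 0.5) * s
        return vox, c

    for sp_info in spines:
        boundary, _ = _boundary_mask(iso.labels, sp_info["label"])
        vox, centers = centers_of(boundary)
        if len(vox) == 0:
            warnings.warn(f"spine {sp_info['label']} vanished during rasterization")
            continue
        target = sp_info["head_center"] + sp_info["direction"] * sp_info["head_radius"]
        sel = np.linalg.norm(centers - target, axis=1) <= cfg.synapse_patch_radius
        if not sel.any():  # fall back to the closest boundary voxel
            sel = np.zeros(len(vox), dtype=bool)
            sel[np.argmin(np.linalg.norm(centers - target, axis=1))] = True
        patch_id += 1
        syn[tuple(vox[sel].T)] = patch_id
        meta.append(SynapseMeta(patch_id=patch_id, type="asymmetric",
                                compartment_id=sp_info["label"]))

    if cfg.n_sym_synapses:
        boundary, _ = _boundary_mask(iso.labels, SHAFT_LABEL)
        vox, centers = centers_of(boundary)
        free = syn[tuple(vox.T)] == 0
        for _ in range(cfg.n_sym_synapses):
            candidates = np.flatnonzero(free)
            if len(candidates) == 0:
                break
            c = centers[rng.choice(candidates)]
            sel = (np.linalg.norm(centers - c, axis=1) <= cfg.synapse_patch_radius) & free
            patch_id += 1
            syn[tuple(vox[sel].T)] = patch_id
            free &= ~sel
            meta.append(SynapseMeta(patch_id=patch_id, type="symmetric",
                                    compartment_id=SHAFT_LABEL))
    return LabelVolume(labels=syn, spacing=iso.spacing), meta


def _place_pm_particles(
    surface: SurfaceGraph,
    cfg: SceneConfig,
    rng: np.random.Generator,
):
    """Sample membrane particle nodes; returns (node ids, parent cluster ids)."""
    weights = surface.areas / surface.areas.sum()
    if cfg.particle_model == "csr_surface":
        area_um2 = surface.total_area_nm2 * 1e-6
        n = rng.poisson(cfg.lambda_pm * area_um2)
        nodes = rng.choice(surface.n_nodes, size=n, replace=True, p=weights)
        return nodes, np.full(n, -1, dtype=int)

    # parent-offspring (Thomas-like) process with geodesic offspring spread
    parents = rng.choice(surface.n_nodes, size=cfg.n_parents, replace=False, p=weights)
    nodes, cluster_ids = [], []
    csgraph = surface.csgraph()
    cutoff = 5 * cfg.offspring_spread
    for cid, parent in enumerate(parents):
        n_off = rng.poisson(cfg.offspring_per_parent)
        if n_off == 0:
            continue
        d = dijkstra(csgraph, directed=False, indices=parent, limit=cutoff)
        w = np.exp(-0.5 * (d / cfg.offspring_spread) ** 2) * surface.areas
        w[~np.isfinite(d)] = 0.0
        w /= w.sum()
        chosen = rng.choice(surface.n_nodes, size=n_off, replace=True, p=w)
        nodes.extend(int(c) for c in chosen)
        cluster_ids.extend([cid] * n_off)
    return np.asarray(nodes, dtype=int), np.asarray(cluster_ids, dtype=int)


def _place_intra_particles(iso: LabelVolume, label: int, lam: float, rng: np.random.Generator):
    """Poisson deposit of intracellular particles well inside one compartment."""
    mask = iso.labels == label
    # two 26-connectivity erosions keep deposits >= 2 voxels (40 nm) from any
    # boundary voxel even diagonally, so after sub-voxel jitter they can never
    # be mistaken for membrane contact at the default 20 nm radius
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)), iterations=2)
    vox = np.argwhere(interior)
    vol_um3 = mask.sum() * iso.spacing.voxel_volume_nm3 * 1e-9
    n = rng.poisson(lam * vol_um3)
    if len(vox) == 0:
        if n:
            warnings.warn(f"compartment {label} too thin for intracellular deposits")
        return np.empty((0, 3))
    picks = vox[rng.integers(0, len(vox), size=n)]
    s = iso.spacing.dx
    pos = np.empty((n, 3))
    pos[:, 0] = (picks[:, 2] + 0.5) * s
    pos[:, 1] = (picks[:, 1] + 0.5) * s
    pos[:, 2] = (picks[:, 0] + 0.5) * s
    pos += rng.uniform(-s / 2, s / 2, size=(n, 3))
    return pos


def build_scene(cfg: SceneConfig | None = None, seed: int | None = None) -> Scene:
    """Generate a labeled dendrite scene with ground-truth particles.

    Deterministic given ``cfg.seed`` (``seed`` overrides it). The
    returned scene carries both the acquisition-grid label volume and
    the isotropic analysis volume, the synapse patch volume + metadata,
    an unclassified particle table, and a ground-truth table with each
    particle's true compartment, localization and parent cluster id
    (-1 for non-clustered placements).
    """
    if cfg is None:
        cfg = SceneConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    labels, spines, sp = _rasterize_geometry(cfg, rng)
    vol = LabelVolume(labels=labels, spacing=sp)
    if sp.is_isotropic:
        iso = vol
    else:
        from skmap.surface_model import resample_isotropic

        iso = resample_isotropic(vol, target=sp.dz)

    compartments = [CompartmentMeta(label_id=SHAFT_LABEL,
                                    kind="pyramidal_shaft" if cfg.kind == "pyramidal"
                                    else "interneuron_shaft")]
    for s_info in spines:
        compartments.append(
            CompartmentMeta(label_id=s_info["label"], kind="spine", parent_id=SHAFT_LABEL)
        )

    syn_vol, syn_meta = _paint_patches(iso, spines, cfg, rng)

    merged = binarize(iso)
    surface = extract_surface(merged, 1)
    surface.compartment_id = None  # merged dendrite membrane, not one label

    pm_nodes, pm_clusters = _place_pm_particles(surface, cfg, rng)
    jitter = rng.uniform(-5.0, 5.0, size=(len(pm_nodes), 3))
    pm_pos = surface.positions[pm_nodes] + jitter
    pm_compartments = iso.labels[tuple(surface.voxels[pm_nodes].T)]

    particles: list[ParticleRecord] = []
    gt_rows = []
    pid = 0
    for pos, comp, clus in zip(pm_pos, pm_compartments, pm_clusters):
        pid += 1
        particles.append(ParticleRecord(pid, float(pos[0]), float(pos[1]), float(pos[2])))
        gt_rows.append({"particle_id": pid, "true_compartment": int(comp),
                        "true_localization": "PM", "parent_cluster": int(clus)})
    for comp in compartments:
        pos_arr = _place_intra_particles(iso, comp.label_id, cfg.lambda_intra, rng)
        for pos in pos_arr:
            pid += 1
            particles.append(
                ParticleRecord(pid, float(pos[0]), float(pos[1]), float(pos[2]))
            )
            gt_rows.append({"particle_id": pid, "true_compartment": comp.label_id,
                            "true_localization": "intracellular", "parent_cluster": -1})

    ground_truth = pd.DataFrame(
        gt_rows, columns=["particle_id", "true_compartment", "true_localization",
                          "parent_cluster"]
    )
    return Scene(
        config=cfg,
        label_volume=vol,
        iso_volume=iso,
        synapse_volume=syn_vol,
        synapse_meta=syn_meta,
        compartments=compartments,
        particles=particles,
        ground_truth=ground_truth,
        surface=surface,
    )


# ---------------------------------------------------------------------------
# transcribed published tables


def study_tables() -> dict:
    """Per-dendrite tables transcribed from the published SK2 quantification.

    Returns a dict with:

    * ``table1`` — PM/intracellular counts in shafts and spines of six
      pyramidal-cell dendrites;
    * ``table2`` — counts, volumes and PM densities of six interneuron
      dendrites;
    * ``table3`` — shaft and spine counts, volumes and densities of the
      six pyramidal-cell dendrites;
    * ``group_means`` — the printed group mean densities (gold/μm³, with
      SEM and n) used for fold-ratio comparisons between spines, shafts
      and interneuron dendrites.
    """
    table1 = pd.DataFrame(
        {
            "dendrite": [1, 2, 3, 4, 5, 6],
            "shaft_pm": [444, 353, 167, 48, 48, 152],
            "shaft_intra": [778, 217, 550, 1156, 84, 363],
            "spine_pm": [98, 49, 118, 14, 14, 105],
            "spine_intra": [4, 5, 2, 1, 1, 4],
        }
    )
    table2 = pd.DataFrame(
        {
            "dendrite": [1, 2, 3, 4, 5, 6],
            "n_sections": [88, 104, 115, 106, 98, 147],
            "volume_um3": [3.15, 3.46, 3.81, 3.77, 3.49, 5.24],
            "n_pm": [27, 31, 35, 32, 30, 49],
            "n_intra": [194, 213, 221, 219, 222, 301],
            # per-dendrite PM density column as printed (rounded) in the table
            "density_printed": [8.58, 8.96, 9.19, 8.48, 8.58, 9.35],
        }
    )
    table3 = pd.DataFrame(
        {
            "dendrite": [1, 2, 3, 4, 5, 6],
            "shaft_sections": [147, 115, 171, 156, 79, 155],
            "shaft_pm": [444, 353, 167, 48, 48, 152],
            "shaft_volume_um3": [6.67, 3.76, 4.67, 3.74, 1.81, 4.24],
            "shaft_density_printed": [66.59, 93.92, 35.78, 12.82, 26.41, 35.82],
            "n_spines": [13, 11, 27, 6, 6, 21],
            "spine_gold": [98, 49, 118, 14, 14, 105],
            "spine_gold_min": [1, 2, 0, 0, 0, 0],
            "spine_gold_max": [17, 10, 18, 10, 11, 16],
            "spine_volume_um3": [0.25, 0.14, 0.35, 0.07, 0.06, 0.26],
        }
    )
    group_means = {
        "pm": {
            "spine": {"mean": 423.1, "sem": 15.13, "n": 62},
            "shaft": {"mean": 102.4, "sem": 46.43, "n": 6},
            "interneuron": {"mean": 8.9, "sem": 0.1, "n": 6},
        },
        "intra": {
            "spine": {"mean": 17.5, "sem": 4.1, "n": 6},
            "shaft": {"mean": 125.6, "sem": 38.2, "n": 6},
            "interneuron": {"mean": 60.0, "sem": 1.0, "n": 6},
        },
    }
    return {
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "group_means": group_means,
    }


# deterministic synthetic per-spine gold counts, one list per dendrite,
# consistent with the printed per-dendrite totals, ranges and the 22/84
# immunonegative spines
_SPINE_COUNTS = {
    1: [17, 14, 11, 10, 9, 8, 7, 6, 5, 4, 3, 3, 1],
    2: [10, 7, 6, 5, 5, 4, 3, 3, 2, 2, 2],
    3: [18, 14, 12, 11, 10, 9, 8, 7, 6, 6, 5, 4, 3, 2, 1, 1, 1] + [0] * 10,
    4: [10, 3, 1] + [0] * 3,
    5: [11, 2, 1] + [0] * 3,
    6: [16, 12, 10, 9, 8, 8, 7, 7, 6, 6, 5, 4, 3, 2, 2] + [0] * 6,
}

_NEG_SPINE_MEAN_UM3 = 0.0079  # printed mean volume of immunonegative spines


def reference_spine_table() -> pd.DataFrame:
    """Synthetic per-spine table consistent with the printed per-dendrite data.

    The study's per-spine measurements are not deposited; this table is
    a deterministic synthetic stand-in that reproduces every published
    per-dendrite aggregate: spine counts per dendrite, per-dendrite gold
    totals and min-max ranges, per-dendrite summed spine volumes, 22 of
    84 spines immunonegative, and an immunonegative mean volume of
    0.0079 μm³. Within a dendrite, immunopositive spine volumes are
    allocated proportionally to (count + 1) and immunonegative volumes
    spread symmetrically around their printed mean, so group means and
    rank tests behave like the published data while per-spine values
    remain an explicit construction.
    """
    tables = study_tables()
    t3 = tables["table3"].set_index("dendrite")
    rows = []
    for d, counts in _SPINE_COUNTS.items():
        counts = np.asarray(counts)
        assert len(counts) == t3.loc[d, "n_spines"]
        assert counts.sum() == t3.loc[d, "spine_gold"]
        v_total = float(t3.loc[d, "spine_volume_um3"])
        neg = counts == 0
        n_neg = int(neg.sum())
        neg_vols = _NEG_SPINE_MEAN_UM3 + (
            np.linspace(-0.0025, 0.0025, n_neg) if n_neg > 1 else np.zeros(n_neg)
        )
        pos_budget = v_total - neg_vols.sum()
        w = (counts[~neg] + 1).astype(float)
        pos_vols = pos_budget * w / w.sum()
        vols = np.empty(len(counts))
        vols[~neg] = pos_vols
        vols[neg] = neg_vols
        for i, (cnt, vol) in enumerate(zip(counts, vols)):
            rows.append(
                {"dendrite": d, "spine": i + 1, "gold_count": int(cnt),
                 "volume_um3": float(vol)}
            )
    return pd.DataFrame(rows)
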