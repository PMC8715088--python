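"""End-to-end orchestration: simulate -> assign -> spatial stats -> summaries.

The library functions here are what the ``skmap`` command-line tool
wraps. A run is driven by a :class:`RunConfig` whose defaults reproduce
the published analysis parameters exactly: 100 randomization replicates,
20-nm isotropic resampling, a 20-nm membrane-contact radius, and 60-nm
distance bins up to 660 nm.

A single global seed fans out into per-stage substreams (scene
generation, randomization null) via :class:`numpy.random.SeedSequence`,
so stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from skmap import summaries as summ
from skmap import spatial_stats as sps
from skmap.particle_assign import AssignmentParams, assign_and_classify, classify_localization
from skmap.surface_model import binarize, extract_surface, measure_compartment, resample_isotropic
from skmap.synthetic_scene import (
    Scene,
    SceneConfig,
    build_scene,
    study_tables,
    reference_spine_table,
)
from skmap.volume_io import (
    LabelVolume,
    VoxelSpacing,
    particles_to_frame,
    read_compartment_meta,
    read_label_volume,
    read_particle_table,
    read_synapse_meta,
    write_results,
)

__all__ = [
    "RunConfig",
    "run_analyze",
    "analyze_scene",
    "run_summarize",
    "fixture_summaries",
    "fixture_headline_values",
    "write_scene",
]


@dataclass
class RunConfig:
    """Inputs and parameters of one analysis run."""

    labels_path: str | None = None
    particles_path: str | None = None
    synapses_path: str | None = None
    synapse_meta_path: str | None = None
    compartments_path: str | None = None
    spacing: tuple[float, float, float] = (5.0, 5.0, 20.0)
    resample_target: float = 20.0
    pm_contact_radius: float = 20.0
    reps: int = 100
    seed: int = 0
    cluster_rule: str = "plus2sd"
    bin_width: float = 60.0
    limit: float = 660.0
    out_dir: str = "results"
    fixtures: str | None = None  # "study" -> summarize transcribed tables


def _spawn_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def analyze_scene(
    iso: LabelVolume,
    particles,
    compartments,
    synapse_volume: LabelVolume | None = None,
    synapse_meta=None,
    cfg: RunConfig | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs (isotropic volume).

    Returns a dict of result objects and exportable DataFrames:
    assignment counts, density table, NND/randomization/cluster results
    on the merged dendrite membrane, and per-synapse-type distance
    profiles.
    """
    cfg = cfg or RunConfig()
    params = AssignmentParams(pm_contact_radius=cfg.pm_contact_radius)
    rng_null = _spawn_seeds(cfg.seed, 2)[1]

    kinds = {c.label_id: c.kind for c in compartments}
    label_ids = sorted(kinds)
    metrics = [measure_compartment(iso, cid) for cid in label_ids]

    # localization is judged against the *outer* dendrite membrane: the
    # merged surface of all compartments, so internal spine/shaft
    # interfaces never count as plasma membrane
    merged = binarize(iso)
    surface = extract_surface(merged, 1)
    surface.compartment_id = None

    counts = assign_and_classify(particles, iso, {cid: surface for cid in label_ids}, params)

    table = summ.density_table(
        (p for p in particles if p.compartment_id is not None), metrics, kinds
    )
    breakdown = summ.percentage_breakdown(table)

    results: dict = {
        "assignment_counts": counts,
        "density": table,
        "breakdown": breakdown,
        "surface": surface,
    }

    pm_nodes, pm_ids = sps.project_particles(particles, surface)
    if len(pm_nodes) >= 2:
        nnd = sps.nnd_analysis(pm_nodes, surface)
        nnd.particle_ids = pm_ids
        rand = sps.randomization_test(
            pm_nodes, surface, reps=cfg.reps, seed=cfg.seed, rng=rng_null
        )
        raw = sps.call_clusters(pm_nodes, surface, nnd, rule=cfg.cluster_rule)
        # call_clusters saw bare node arrays, so group members are indices
        # into pm_nodes; translate them back to particle ids
        clusters = sps.ClusterSet(
            clusters=[[int(pm_ids[i]) for i in g] for g in raw.clusters],
            scattered=[[int(pm_ids[i]) for i in g] for g in raw.scattered],
            threshold_nm=raw.threshold_nm,
            rule=raw.rule,
        )
        results.update(nnd=nnd, randomization=rand, clusters=clusters)

    if synapse_volume is not None and synapse_meta:
        patch_nodes = sps.map_patches_to_surface(synapse_volume, synapse_meta, surface)
        for syn_type in ("asymmetric", "symmetric"):
            sub = {m.patch_id: patch_nodes[m.patch_id] for m in synapse_meta
                   if m.type == syn_type}
            if not sub:
                continue
            results[f"profile_{syn_type}"] = sps.synapse_profile(
                pm_nodes, sub, surface, syn_type,
                bin_width=cfg.bin_width, limit=cfg.limit,
            )
    return results


def _results_tables(particles, results: dict, cfg: RunConfig) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {
        "particles_augmented": particles_to_frame(particles),
        "density": results["density"].to_frame(),
    }
    if "nnd" in results:
        nnd = results["nnd"]
        tables["nnd_per_particle"] = pd.DataFrame(
            {"particle_id": nnd.particle_ids, "node_id": nnd.node_ids, "nnd_nm": nnd.nnds}
        )
        rand = results["randomization"]
        tables["null_means"] = pd.DataFrame({"replicate": np.arange(1, rand.reps + 1),
                                             "mean_nnd_nm": rand.null_means})
        tables["randomization_summary"] = pd.DataFrame(
            [{
                "observed_mean_nnd_nm": rand.observed_mean_nnd,
                "null_mean_nnd_nm": rand.null_mean,
                "null_sd_nnd_nm": rand.null_sd,
                "z_score": rand.z_score,
                "p_empirical": rand.p_empirical,
                "reps": rand.reps,
            }]
        )
        cl = results["clusters"]
        rows = []
        for gid, group in enumerate(cl.clusters + cl.scattered):
            for p in group:
                rows.append({"group_id": gid, "particle_id": p, "group_size": len(group),
                             "is_cluster": len(group) >= 3})
        tables["clusters"] = pd.DataFrame(
            rows, columns=["group_id", "particle_id", "group_size", "is_cluster"]
        )
    prof_rows = []
    for key in ("profile_asymmetric", "profile_symmetric"):
        if key in results:
            prof = results[key]
            for b in range(len(prof.counts)):
                prof_rows.append(
                    {"synapse_type": prof.synapse_type,
                     "bin_start_nm": prof.bin_edges[b], "bin_end_nm": prof.bin_edges[b + 1],
                     "count": int(prof.counts[b]), "proportion": prof.proportions[b]}
                )
    if prof_rows:
        tables["synapse_profiles"] = pd.DataFrame(prof_rows)
    return tables


def run_analyze(cfg: RunConfig, scene: Scene | None = None) -> dict:
    """Run the pipeline from files (or an in-memory scene) and write results.

    With ``cfg.fixtures == "study"`` the image stages are skipped and
    the transcribed per-dendrite tables are summarized instead.
    """
    out = Path(cfg.out_dir)
    if cfg.fixtures == "study":
        tables = fixture_summaries()
        write_results(tables, out, manifest=_manifest(cfg))
        return {"tables": tables}

    if scene is not None:
        iso = scene.iso_volume
        particles = scene.particles
        compartments = scene.compartments
        syn_vol, syn_meta = scene.synapse_volume, scene.synapse_meta
    else:
        vol = read_label_volume(cfg.labels_path, VoxelSpacing(*cfg.spacing))
        iso = vol if vol.spacing.is_isotropic else resample_isotropic(vol, cfg.resample_target)
        particles = read_particle_table(cfg.particles_path)
        compartments = read_compartment_meta(cfg.compartments_path)
        syn_vol = syn_meta = None
        if cfg.synapses_path and cfg.synapse_meta_path:
            syn_vol = read_label_volume(cfg.synapses_path, iso.spacing)
            syn_meta = read_synapse_meta(cfg.synapse_meta_path)

    results = analyze_scene(iso, particles, compartments, syn_vol, syn_meta, cfg)
    tables = _results_tables(particles, results, cfg)
    write_results(tables, out, manifest=_manifest(cfg, results))
    results["tables"] = tables
    return results


def _manifest(cfg: RunConfig, results: dict | None = None) -> dict:
    doc = {"parameters": asdict(cfg), "seed": cfg.seed}
    if cfg.cluster_rule == "plus2sd":
        doc["cluster_threshold_note"] = (
            "cluster threshold = mean NND + 2 SD (rule plus2sd); "
            "the mean - 2 SD reading is available as rule minus2sd"
        )
    if results and "assignment_counts" in results:
        doc["assignment_counts"] = results["assignment_counts"]
    return doc


# ---------------------------------------------------------------------------
# transcribed-table (worked example) mode


def fixture_summaries() -> dict[str, pd.DataFrame]:
    """Summaries of the transcribed per-dendrite tables, as exportable CSVs."""
    fx = study_tables()
    t1, t2, t3 = fx["table1"], fx["table2"], fx["table3"]

    shaft = pd.DataFrame({
        "compartment_id": t1["dendrite"], "kind": "pyramidal_shaft",
        "n_pm": t1["shaft_pm"], "n_intra": t1["shaft_intra"],
        "volume_um3": t3["shaft_volume_um3"],
    })
    spine = pd.DataFrame({
        "compartment_id": t1["dendrite"], "kind": "spine",
        "n_pm": t1["spine_pm"], "n_intra": t1["spine_intra"],
        "volume_um3": t3["spine_volume_um3"],
    })
    inter = pd.DataFrame({
        "compartment_id": t2["dendrite"], "kind": "interneuron_shaft",
        "n_pm": t2["n_pm"], "n_intra": t2["n_intra"],
        "volume_um3": t2["volume_um3"],
    })
    pyramidal = summ.density_table_from_counts(pd.concat([shaft, spine], ignore_index=True))
    interneuron = summ.density_table_from_counts(inter)

    spines = reference_spine_table()
    r, r_p = summ.spine_count_correlation(spines["volume_um3"], spines["gold_count"])
    cmp_res = summ.compare_spine_volumes(spines["volume_um3"], spines["gold_count"])

    gm = fx["group_means"]
    folds_pm = summ.fold_ratios({k: v["mean"] for k, v in gm["pm"].items()})
    folds_intra = summ.fold_ratios({k: v["mean"] for k, v in gm["intra"].items()})
    folds_pm.insert(0, "pool", "pm")
    folds_intra.insert(0, "pool", "intra")

    breakdown = summ.percentage_breakdown(pyramidal)
    bd_rows = [
        {"kind": k, **v} for k, v in breakdown["by_kind"].items()
    ]

    spine_stats = pd.DataFrame([{
        "n_spines": len(spines),
        "n_immunonegative": int((spines["gold_count"] == 0).sum()),
        "immunonegative_pct": 100.0 * cmp_res.negative_fraction,
        "mean_volume_positive_um3": cmp_res.mean_pos,
        "mean_volume_negative_um3": cmp_res.mean_neg,
        "mannwhitney_u": cmp_res.u_statistic,
        "mannwhitney_p": cmp_res.p_value,
        "pearson_r_volume_count": r,
        "pearson_p": r_p,
        "total_spine_volume_um3": float(spines["volume_um3"].sum()),
    }])

    return {
        "density_pyramidal": pyramidal.to_frame(),
        "density_interneuron": interneuron.to_frame(),
        "breakdown_pyramidal": pd.DataFrame(bd_rows),
        "fold_ratios": pd.concat([folds_pm, folds_intra], ignore_index=True),
        "spine_stats": spine_stats,
    }


def fixture_headline_values() -> dict[str, float]:
    """Headline numbers recomputed from the transcribed per-dendrite tables.

    Every value is calculated from the table fixtures at call time —
    counts and shares of particles across compartments, mean densities
    with the published totals-row convention (mean of per-dendrite
    densities), summed spine volume, the immunonegative spine share and
    the fold ratios between printed group mean densities.
    """
    fx = study_tables()
    t1, t2, t3 = fx["table1"], fx["table2"], fx["table3"]

    shaft_total = int((t1["shaft_pm"] + t1["shaft_intra"]).sum())
    spine_total = int((t1["spine_pm"] + t1["spine_intra"]).sum())
    grand = shaft_total + spine_total

    inter = summ.density_table_from_counts(pd.DataFrame({
        "compartment_id": t2["dendrite"], "kind": "interneuron_shaft",
        "n_pm": t2["n_pm"], "n_intra": t2["n_intra"], "volume_um3": t2["volume_um3"],
    }))
    # totals-row densities follow the published convention: the mean of the
    # per-dendrite density column as printed in the table (rounded values)
    inter_density_printed = t2["density_printed"].to_numpy()
    shaft_density_printed = t3["shaft_density_printed"].to_numpy()

    spines = reference_spine_table()
    cmp_res = summ.compare_spine_volumes(spines["volume_um3"], spines["gold_count"])
    r, _ = summ.spine_count_correlation(spines["volume_um3"], spines["gold_count"])

    gm = fx["group_means"]
    folds_pm = {
        (row.numerator, row.denominator): row
        for row in summ.fold_ratios(
            {k: v["mean"] for k, v in gm["pm"].items()}
        ).itertuples(index=False)
    }
    folds_intra = {
        (row.numerator, row.denominator): row
        for row in summ.fold_ratios(
            {k: v["mean"] for k, v in gm["intra"].items()}
        ).itertuples(index=False)
    }

    return {
        "pyramidal_total_particles": grand,
        "interneuron_total_particles": int(inter.totals["n_total"]),
        "shaft_share_pct": round(100.0 * shaft_total / grand),
        "spine_share_pct": round(100.0 * spine_total / grand),
        "shaft_pm_pct": round(100.0 * t1["shaft_pm"].sum() / shaft_total, 1),
        "spine_pm_pct": round(100.0 * t1["spine_pm"].sum() / spine_total, 1),
        "interneuron_pm_pct": round(float(inter.totals["pct_pm"]), 1),
        "interneuron_mean_pm_density": round(float(inter_density_printed.mean()), 2),
        "shaft_mean_pm_density": round(float(shaft_density_printed.mean()), 2),
        "total_spine_volume_um3": round(float(t3["spine_volume_um3"].sum()), 2),
        "immunonegative_spine_pct": round(100 * cmp_res.negative_fraction),
        "mean_volume_spine_positive_um3": cmp_res.mean_pos,
        "mean_volume_spine_negative_um3": cmp_res.mean_neg,
        "spine_volume_count_pearson_r": r,
        "pm_density_fold_spine_over_shaft": int(folds_pm[("spine", "shaft")].fold),
        "intra_density_fold_shaft_over_spine": int(folds_intra[("shaft", "spine")].fold),
    }


# ---------------------------------------------------------------------------
# scene export and report


def write_scene(scene: Scene, out_dir: str | Path) -> None:
    """Write a generated scene in the exact formats the pipeline reads."""
    from skmap.volume_io import write_label_volume, write_particle_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_label_volume(scene.iso_volume, out / "labels.tif")
    write_label_volume(scene.synapse_volume, out / "synapses.tif")
    write_particle_table(scene.particles, out / "particles.csv")
    pd.DataFrame(
        [{"patch_id": m.patch_id, "type": m.type, "compartment_id": m.compartment_id}
         for m in scene.synapse_meta]
    ).to_csv(out / "synapse_meta.csv", index=False)
    pd.DataFrame(
        [{"label_id": c.label_id, "kind": c.kind, "parent_id": c.parent_id}
         for c in scene.compartments]
    ).to_csv(out / "compartments.csv", index=False)
    scene.ground_truth.to_csv(out / "ground_truth.csv", index=False)


def run_summarize(results_dir: str | Path, report_path: str | Path | None = None,
                  figures: bool = True) -> str:
    """Render a Markdown report (and optional figures) from a results directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    lines = ["# skmap analysis report", ""]
    warn = []

    def load(name):
        p = res / f"{name}.csv"
        return pd.read_csv(p) if p.exists() else None

    density = load("density")
    if density is None:
        density = load("density_pyramidal")
    if density is not None:
        lines += ["## Per-compartment densities", "", density.to_markdown(index=False), ""]
    else:
        warn.append("no density table found")

    rs = load("randomization_summary")
    if rs is not None:
        row = rs.iloc[0]
        verdict = (
            "observed mean NND is below the null mean (clustered)"
            if row.observed_mean_nnd_nm < row.null_mean_nnd_nm
            else "observed mean NND is not below the null mean"
        )
        lines += [
            "## Membrane clustering (geodesic NND vs random null)", "",
            f"- observed mean NND: {row.observed_mean_nnd_nm:.1f} nm",
            f"- null mean ± SD over {int(row.reps)} replicates: "
            f"{row.null_mean_nnd_nm:.1f} ± {row.null_sd_nnd_nm:.1f} nm",
            f"- z = {row.z_score:.2f}, empirical p = {row.p_empirical:.4f}",
            f"- {verdict}", "",
        ]
        null = load("null_means")
        if figures and null is not None:
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.hist(null["mean_nnd_nm"], bins=20, color="0.7", label="null")
            ax.axvline(row.observed_mean_nnd_nm, color="crimson", label="observed")
            ax.set_xlabel("mean NND (nm)")
            ax.set_ylabel("replicates")
            ax.legend()
            fig.tight_layout()
            fig.savefig(res / "nnd_null_hist.png", dpi=120)
            plt.close(fig)
            lines += ["![null histogram](nnd_null_hist.png)", ""]

    clusters = load("clusters")
    if clusters is not None and len(clusters):
        in_cluster = clusters[clusters["is_cluster"]]
        sizes = in_cluster.groupby("group_id")["group_size"].first()
        n_cl = len(sizes)
        share_3_8 = (
            100.0 * ((sizes >= 3) & (sizes <= 8)).sum() / n_cl if n_cl else float("nan")
        )
        lines += [
            "## Clusters", "",
            f"- clusters (>= 3 particles): {n_cl}",
            f"- particles in clusters: {len(in_cluster)}",
            f"- scattered/isolated particles: {(~clusters['is_cluster']).sum()}",
            f"- share of clusters with 3-8 particles: {share_3_8:.0f}%", "",
        ]

    prof = load("synapse_profiles")
    if prof is not None and len(prof):
        lines += ["## Distance-to-synapse profiles", ""]
        for syn_type, sub in prof.groupby("synapse_type"):
            lines += [f"### {syn_type}", "", sub.to_markdown(index=False), ""]
            if figures:
                fig, ax = plt.subplots(figsize=(5, 3.2))
                ax.bar(sub["bin_start_nm"], sub["proportion"], width=0.9 * 60,
                       align="edge", color="0.4")
                ax.set_xlabel("distance from synapse edge (nm)")
                ax.set_ylabel("proportion of particles")
                ax.set_title(syn_type)
                fig.tight_layout()
                fig.savefig(res / f"profile_{syn_type}.png", dpi=120)
                plt.close(fig)
                lines += [f"![{syn_type} profile](profile_{syn_type}.png)", ""]

    if warn:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warn] + [""]
    text = "\n".join(lines)
    report = Path(report_path) if report_path else res / "report.md"
    report.write_text(text)
    return text
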