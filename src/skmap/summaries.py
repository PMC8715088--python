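"""Per-compartment density accounting and comparative statistics.

Reproduces the structure of the per-dendrite accounting tables used in
immunogold quantification studies: particle counts split into
plasma-membrane (PM) and intracellular pools per compartment, densities
in gold/μm³, percentage breakdowns, fold ratios between group means, the
spine volume vs particle count correlation, and the standard battery of
comparative tests (one-way ANOVA with Bonferroni post hocs,
Mann-Whitney, two-sample Kolmogorov-Smirnov).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from skmap.surface_model import CompartmentMetrics
from skmap.volume_io import ParticleRecord

__all__ = [
    "DensityTable",
    "SpineVolumeComparison",
    "density_table",
    "density_table_from_counts",
    "percentage_breakdown",
    "fold_ratios",
    "spine_count_correlation",
    "compare_spine_volumes",
    "group_tests",
    "ks_test",
]

_DENSITY_COLUMNS = [
    "compartment_id",
    "kind",
    "n_pm",
    "n_intra",
    "n_total",
    "volume_um3",
    "pm_density",
    "intra_density",
    "total_density",
    "pct_pm",
    "pct_intra",
]


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


@dataclass
class DensityTable:
    """Per-compartment counts/volumes/densities plus a totals summary.

    ``per_compartment`` has one row per compartment with counts,
    densities (count / volume) and PM percentage. ``totals`` carries the
    summed counts and volume, the pooled density (summed count / summed
    volume) and the mean ± SEM of the per-compartment densities — both
    are reported because published totals rows conventionally print the
    mean of per-dendrite densities, not the pooled quotient.
    """

    per_compartment: pd.DataFrame
    totals: dict

    def to_frame(self) -> pd.DataFrame:
        """Per-compartment rows plus one 'total' row, for CSV export."""
        tot = {
            "compartment_id": "total",
            "kind": "all",
            "n_pm": self.totals["n_pm"],
            "n_intra": self.totals["n_intra"],
            "n_total": self.totals["n_total"],
            "volume_um3": self.totals["volume_um3"],
            "pm_density": self.totals["mean_pm_density"],
            "intra_density": self.totals["mean_intra_density"],
            "total_density": self.totals["mean_total_density"],
            "pct_pm": self.totals["pct_pm"],
            "pct_intra": self.totals["pct_intra"],
        }
        return pd.concat(
            [self.per_compartment, pd.DataFrame([tot])], ignore_index=True
        )


def density_table_from_counts(counts: pd.DataFrame) -> DensityTable:
    """Build a :class:`DensityTable` from a plain counts table.

    ``counts`` needs columns ``compartment_id``, ``kind``, ``n_pm``,
    ``n_intra`` and optionally ``volume_um3``. This is the entry point
    for transcribed published tables as well as for the pipeline once
    counts are aggregated.
    """
    df = counts.copy()
    for c in ("compartment_id", "kind", "n_pm", "n_intra"):
        if c not in df.columns:
            raise ValueError(f"counts table missing column {c!r}")
    if "volume_um3" not in df.columns:
        df["volume_um3"] = np.nan
    df["n_total"] = df["n_pm"] + df["n_intra"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["pm_density"] = df["n_pm"] / df["volume_um3"]
        df["intra_density"] = df["n_intra"] / df["volume_um3"]
        df["total_density"] = df["n_total"] / df["volume_um3"]
        df["pct_pm"] = np.where(df["n_total"] > 0, 100.0 * df["n_pm"] / df["n_total"], np.nan)
        df["pct_intra"] = np.where(
            df["n_total"] > 0, 100.0 * df["n_intra"] / df["n_total"], np.nan
        )
    df = df[_DENSITY_COLUMNS].reset_index(drop=True)

    n_pm = int(df["n_pm"].sum())
    n_intra = int(df["n_intra"].sum())
    n_total = n_pm + n_intra
    vol = float(df["volume_um3"].sum())
    totals = {
        "n_compartments": len(df),
        "n_pm": n_pm,
        "n_intra": n_intra,
        "n_total": n_total,
        "volume_um3": vol,
        "pct_pm": 100.0 * n_pm / n_total if n_total else float("nan"),
        "pct_intra": 100.0 * n_intra / n_total if n_total else float("nan"),
        # mean +/- SEM over compartments (the convention of printed totals rows)
        "mean_pm_density": float(df["pm_density"].mean()),
        "sem_pm_density": _sem(df["pm_density"].dropna().to_numpy()),
        "mean_intra_density": float(df["intra_density"].mean()),
        "sem_intra_density": _sem(df["intra_density"].dropna().to_numpy()),
        "mean_total_density": float(df["total_density"].mean()),
        "sem_total_density": _sem(df["total_density"].dropna().to_numpy()),
        # pooled alternative
        "pooled_pm_density": n_pm / vol if vol else float("nan"),
        "pooled_total_density": n_total / vol if vol else float("nan"),
    }
    return DensityTable(per_compartment=df, totals=totals)


def density_table(
    records: Iterable[ParticleRecord],
    metrics: Sequence[CompartmentMetrics],
    kinds: Mapping[int, str] | None = None,
) -> DensityTable:
    """Aggregate classified particles against measured compartments.

    Every particle must be assigned and classified; a particle
    referencing a compartment absent from ``metrics`` raises.
    """
    measured = {m.compartment_id: m for m in metrics}
    counts: dict[int, dict[str, int]] = {
        cid: {"n_pm": 0, "n_intra": 0} for cid in measured
    }
    for p in records:
        if p.compartment_id is None:
            continue
        if p.compartment_id not in measured:
            raise ValueError(
                f"particle {p.particle_id} references unmeasured compartment "
                f"{p.compartment_id}"
            )
        if p.localization == "PM":
            counts[p.compartment_id]["n_pm"] += 1
        elif p.localization == "intracellular":
            counts[p.compartment_id]["n_intra"] += 1
        else:
            raise ValueError(f"particle {p.particle_id} is not classified")
    rows = [
        {
            "compartment_id": cid,
            "kind": (kinds or {}).get(cid, "unknown"),
            "n_pm": c["n_pm"],
            "n_intra": c["n_intra"],
            "volume_um3": measured[cid].volume_um3,
        }
        for cid, c in sorted(counts.items())
    ]
    return density_table_from_counts(pd.DataFrame(rows))


def percentage_breakdown(table: DensityTable, decimals: int = 1) -> dict:
    """Percentage shares of particles across compartment kinds and pools.

    Returns, per kind: its share of all particles (rounded to the whole
    percent and to ``decimals``), and its internal PM/intracellular
    split; plus the overall PM percentage.
    """
    df = table.per_compartment
    grand = int(df["n_total"].sum())
    if grand == 0:
        raise ValueError("zero total particle count; percentages undefined")
    out: dict = {"n_total": grand, "by_kind": {}}
    for kind, sub in df.groupby("kind"):
        n = int(sub["n_total"].sum())
        n_pm = int(sub["n_pm"].sum())
        share = 100.0 * n / grand
        out["by_kind"][kind] = {
            "n_total": n,
            "n_pm": n_pm,
            "n_intra": n - n_pm,
            "share_pct": round(share, decimals),
            "share_pct_int": int(round(share)),
            "pct_pm": round(100.0 * n_pm / n, decimals) if n else float("nan"),
            "pct_intra": round(100.0 * (n - n_pm) / n, decimals) if n else float("nan"),
        }
    total_pm = int(df["n_pm"].sum())
    out["pct_pm"] = round(100.0 * total_pm / grand, decimals)
    out["pct_intra"] = round(100.0 * (grand - total_pm) / grand, decimals)
    return out


def fold_ratios(group_means: Mapping[str, float]) -> pd.DataFrame:
    """Pairwise ratios of group mean densities, raw and integer-rounded.

    Ratios come in reciprocal pairs (a/b and b/a multiply to 1 before
    rounding); a zero denominator raises.
    """
    rows = []
    for a, b in combinations(group_means, 2):
        for num, den in ((a, b), (b, a)):
            if group_means[den] == 0:
                raise ZeroDivisionError(f"group {den!r} mean is zero")
            r = group_means[num] / group_means[den]
            rows.append(
                {"numerator": num, "denominator": den, "ratio": r, "fold": int(round(r))}
            )
    return pd.DataFrame(rows, columns=["numerator", "denominator", "ratio", "fold"])


def spine_count_correlation(
    volumes_um3: Sequence[float], counts: Sequence[int]
) -> tuple[float, float]:
    """Pearson correlation between spine volume and particle count.

    Returns (r, two-sided p). Needs >= 3 spines with variance in both
    variables.
    """
    v = np.asarray(volumes_um3, dtype=float)
    c = np.asarray(counts, dtype=float)
    if len(v) != len(c) or len(v) < 3:
        raise ValueError("need >= 3 paired (volume, count) observations")
    if np.std(v) == 0 or np.std(c) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.pearsonr(v, c)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SpineVolumeComparison:
    """Volumes of immunopositive (>=1 particle) vs immunonegative spines."""

    volumes_positive: np.ndarray
    volumes_negative: np.ndarray
    mean_pos: float
    sem_pos: float
    mean_neg: float
    sem_neg: float
    u_statistic: float
    p_value: float
    negative_fraction: float  # share of spines with zero particles

    @property
    def negative_pct_int(self) -> int:
        return int(round(100 * self.negative_fraction))


def compare_spine_volumes(
    volumes_um3: Sequence[float], counts: Sequence[int]
) -> SpineVolumeComparison:
    """Mann-Whitney comparison of immunopositive vs immunonegative spine volumes.

    Spine volumes are typically non-normal, hence the rank test; SciPy
    uses the exact null for small tie-free samples and the normal
    approximation otherwise. Both groups must be nonempty.
    """
    v = np.asarray(volumes_um3, dtype=float)
    c = np.asarray(counts)
    pos = v[c > 0]
    neg = v[c == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both immunopositive and immunonegative groups must be nonempty")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return SpineVolumeComparison(
        volumes_positive=pos,
        volumes_negative=neg,
        mean_pos=float(pos.mean()),
        sem_pos=_sem(pos),
        mean_neg=float(neg.mean()),
        sem_neg=_sem(neg),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        negative_fraction=len(neg) / len(v),
    )


def group_tests(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA across groups with Bonferroni-adjusted pairwise t-tests.

    Returns ``{"anova": {F, df_between, df_within, p, degenerate},
    "pairwise": DataFrame}`` where pairwise p-values are
    ``min(1, m * p_raw)`` over the m comparisons. Groups that are all
    identical constants make F undefined; the result is flagged
    degenerate rather than raising.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    degenerate = np.all(pooled == pooled[0])
    if degenerate:
        anova = {
            "F": float("nan"),
            "df_between": len(arrays) - 1,
            "df_within": len(pooled) - len(arrays),
            "p": float("nan"),
            "degenerate": True,
        }
    else:
        res = stats.f_oneway(*arrays)
        anova = {
            "F": float(res.statistic),
            "df_between": len(arrays) - 1,
            "df_within": len(pooled) - len(arrays),
            "p": float(res.pvalue),
            "degenerate": False,
        }
    pairs = list(combinations(range(len(names)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        if degenerate or (np.std(arrays[i]) == 0 and np.std(arrays[j]) == 0):
            p_raw = float("nan")
        else:
            p_raw = float(stats.ttest_ind(arrays[i], arrays[j]).pvalue)
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, m * p_raw) if np.isfinite(p_raw) else float("nan"),
            }
        )
    return {"anova": anova, "pairwise": pd.DataFrame(rows)}


def ks_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic D and p-value."""
    res = stats.ks_2samp(np.asarray(sample_a, float), np.asarray(sample_b, float))
    return float(res.statistic), float(res.pvalue)
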