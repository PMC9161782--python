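"""Stage-wise group comparisons and report generation.

Cell densities and proportions are compared between disease stages with the
two-sided Mann–Whitney–Wilcoxon test, Bonferroni-corrected within the family
of tested stage pairs per population (each ROI is one independent sample
point).  High-variance subsets can instead be screened with the Kruskal–
Wallis one-way ANOVA on ranks.  Significance stars follow the conventional
ladder: ns p > 0.05, * p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001, **** p ≤ 0.0001,
computed from the Bonferroni-adjusted p by default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LADDER = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Map a p-value to its significance stars (ns above 0.05)."""
    if not np.isfinite(p):
        return "ns"
    for cut, stars in STAR_LADDER:
        if p <= cut:
            return stars
    return "ns"


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U and p.

    Exact enumeration when the combined sample is small (n ≤ 12) and tie-free;
    otherwise the normal approximation with tie correction.  Two identical
    constant groups carry no ordinal information: U = n1*n2/2, p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return len(x) * len(y) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_mwu_bonferroni(
    values_by_stage: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
    population: str = "",
    stars_from: str = "adjusted",
) -> pd.DataFrame:
    """Pairwise stage comparisons with Bonferroni correction.

    The Bonferroni family is the list of tested pairs for this population:
    ``p_adj = min(1, p * n_pairs)``.  ``stars_from`` selects whether the star
    code reflects the adjusted (default) or raw p.
    """
    if pairs is None:
        stages = list(values_by_stage)
        pairs = [(a, b) for i, a in enumerate(stages) for b in stages[i + 1 :]]
    if stars_from not in ("adjusted", "raw"):
        raise ValueError("stars_from must be 'adjusted' or 'raw'")
    n_family = len(pairs)
    records = []
    for a, b in pairs:
        x = np.asarray(values_by_stage[a], dtype=float)
        y = np.asarray(values_by_stage[b], dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in tested pair ({a}, {b})")
        u, p = _mwu(x, y)
        p_adj = min(1.0, p * n_family)
        records.append(
            {
                "population": population,
                "stage_a": a,
                "stage_b": b,
                "n_a": len(x),
                "n_b": len(y),
                "U": u,
                "p": p,
                "p_bonferroni": p_adj,
                "stars": star_code(p_adj if stars_from == "adjusted" else p),
            }
        )
    return pd.DataFrame.from_records(records)


def kruskal_wallis(values_by_stage: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p (df = groups - 1)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_stage.values()]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("Kruskal–Wallis needs at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def render_report(
    summaries: pd.DataFrame,
    comparisons: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
    profiles: pd.DataFrame | None = None,
    out_dir: str | Path = "report",
    stage_order: tuple[str, ...] = ("NSQ", "NDBE", "Dys", "EAC"),
) -> dict[str, Path]:
    """Write the report bundle: tidy CSVs plus per-population stage figures.

    Deterministic for fixed inputs.  Produces ``summaries.csv`` and, when
    given, ``comparisons.csv`` (with star annotations), ``enrichment.csv`` and
    a per-population density strip plot, a cluster-profile heatmap and
    stage-level enrichment heatmaps.  Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "stage" not in summaries.columns or summaries["stage"].eq("").all():
        raise ValueError("summaries must carry stage labels")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out / "summaries.csv"
    summaries.to_csv(p, index=False)
    paths["summaries"] = p

    stages = [s for s in stage_order if s in set(summaries["stage"])]
    for pop, sub in summaries.groupby("phenotype"):
        fig, ax = plt.subplots(figsize=(4, 3))
        for i, stage in enumerate(stages):
            vals = sub.loc[sub["stage"] == stage, "density_per_mm2"].to_numpy()
            jitter = (np.arange(len(vals)) - (len(vals) - 1) / 2) * 0.04
            ax.plot(i + jitter, vals, "o", ms=4)
        ax.set_xticks(range(len(stages)), stages)
        ax.set_ylabel("cells / mm$^2$")
        title = pop
        if comparisons is not None and len(comparisons):
            rows = comparisons[comparisons["population"] == pop]
            annot = ", ".join(
                f"{r.stage_a}-{r.stage_b}: {r.stars}" for r in rows.itertuples()
            )
            if annot:
                title = f"{pop}\n{annot}"
        ax.set_title(title, fontsize=8)
        fig.tight_layout()
        safe = "".join(c if c.isalnum() else "_" for c in pop)
        fp = out / f"density_{safe}.png"
        fig.savefig(fp, dpi=100)
        plt.close(fig)
        paths[f"density_{pop}"] = fp

    if comparisons is not None and len(comparisons):
        p = out / "comparisons.csv"
        comparisons.to_csv(p, index=False)
        paths["comparisons"] = p

    if profiles is not None and len(profiles):
        p = out / "cluster_profiles.csv"
        profiles.to_csv(p)
        paths["profiles"] = p
        marker_cols = [c for c in profiles.columns if c != "n_cells"]
        fig, ax = plt.subplots(figsize=(6, 0.35 * len(profiles) + 1.5))
        im = ax.imshow(profiles[marker_cols].to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(marker_cols)), marker_cols, rotation=90, fontsize=7)
        ax.set_yticks(range(len(profiles)), [str(i) for i in profiles.index], fontsize=7)
        ax.set_ylabel("group")
        fig.colorbar(im, ax=ax, label="mean intensity")
        fig.tight_layout()
        fp = out / "cluster_profiles.png"
        fig.savefig(fp, dpi=100)
        plt.close(fig)
        paths["profiles_heatmap"] = fp

    if enrichment is not None and len(enrichment):
        p = out / "enrichment.csv"
        enrichment.to_csv(p, index=False)
        paths["enrichment"] = p
        key = "stage" if "stage" in enrichment.columns else "roi_id"
        for group, sub in enrichment.groupby(key):
            zcol = "mean_z" if "mean_z" in sub.columns else "z"
            mat = sub.pivot(index="reference", columns="target", values=zcol)
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(mat.to_numpy(), cmap="coolwarm", vmin=-5, vmax=5)
            ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(len(mat.index)), mat.index, fontsize=6)
            ax.set_title(f"neighborhood enrichment (z), {group}", fontsize=8)
            fig.colorbar(im, ax=ax)
            fig.tight_layout()
            fp = out / f"enrichment_{group}.png"
            fig.savefig(fp, dpi=100)
            plt.close(fig)
            paths[f"enrichment_{group}"] = fp

    return paths
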