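"""End-to-end orchestration: spectra -> coding -> loci -> markers -> stats.

Runs the whole floral color-signal analysis under a single config with
fixed seeds: smooth and code every spectrum, project it into the bee
hexagon and avian tetrahedron, extract marker points and their MAD /
minAD fit to each pollinator's discrimination optima, classify pigment
compositions, summarize groups (mean / SD / SEM), run phylogenetic
ANOVAs with Holm adjustment on the seven discrimination statistics,
test the deoxy group's hexagon area against a random-subsample null,
and estimate ancestral deoxy percentages on the tree. Stages whose
inputs are absent (no tree, no compositions) are skipped with a notice
rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry, chromatic_coding, hull_stats, markers, phylo, spectra, vision
from .chemistry import DEO90, DEO_DOMINANT, HYD_DOMINANT, PigmentComposition
from .markers import BEE_OPTIMA, HUMMINGBIRD_OPTIMA
from .phylo import Phylogeny
from .spectra import SpectrumSet

logger = logging.getLogger(__name__)

#: the seven discrimination statistics compared between pigment groups
STAT_COLUMNS = (
    "MAD_bee",
    "MAD_bird",
    "minAD400",
    "minAD500",
    "minAD460",
    "minAD540",
    "minAD600",
)


@dataclass
class PipelineConfig:
    """All tunables of one analysis run (echoed into every output)."""

    smoothing_span: float = 0.25
    region_threshold_pct: float = 10.0
    boundary_window_nm: float = 25.0
    marker_threshold_pp: float = 20.0
    bee_peaks_nm: tuple[float, ...] = vision.BEE_PEAKS_NM
    avian_peaks_nm: tuple[float, ...] = vision.AVIAN_V_PEAKS_NM
    mcp_percent: float = 95.0
    hull_n_iter: int = 100
    anova_n_sim: int = 10_000
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResults:
    config: PipelineConfig
    samples: pd.DataFrame  # one row per (sample, part)
    group_summary: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    hull_test: hull_stats.HullTestResult | None = None
    pca: chemistry.PCAResult | None = None
    tally: chemistry.CombinationTally | None = None
    ancestral: phylo.AncestralEstimates | None = None
    notices: list[str] = field(default_factory=list)


def _sample_table(
    sset: SpectrumSet,
    cfg: PipelineConfig,
    compositions_by_id: dict[str, PigmentComposition],
) -> pd.DataFrame:
    bee = vision.build_receptor_sensitivities(cfg.bee_peaks_nm, name="bee")
    bird = vision.build_receptor_sensitivities(cfg.avian_peaks_nm, name="avian_v")
    rows = []
    for s in sset:
        smoothed = spectra.smooth_spectrum(s, span=cfg.smoothing_span)
        code = chromatic_coding.code_regions(
            smoothed, cfg.region_threshold_pct, cfg.boundary_window_nm
        )
        hex_locus = vision.spectrum_locus(smoothed, bee)
        q_bird = vision.compute_quantum_catches(smoothed, bird)
        mset = markers.find_marker_points(smoothed, cfg.marker_threshold_pp)
        row: dict = {
            "sample_id": s.sample_id,
            "part": s.part,
            "code": code.as_string(),
            "color_group": chromatic_coding.classify_orange_red(code),
            "hex_x": hex_locus.coords[0],
            "hex_y": hex_locus.coords[1],
            "n_markers": len(mset),
            "marker_points_nm": ";".join(f"{p:.2f}" for p in mset.points_nm),
        }
        if q_bird.relative is not None:
            tet = vision.tetrahedral_locus(q_bird)
            row.update(tet_x=tet.coords[0], tet_y=tet.coords[1], tet_z=tet.coords[2])
        else:
            row.update(tet_x=np.nan, tet_y=np.nan, tet_z=np.nan)
        if len(mset) > 0:
            row["MAD_bee"] = markers.mean_absolute_deviation(mset, BEE_OPTIMA)
            row["MAD_bird"] = markers.mean_absolute_deviation(mset, HUMMINGBIRD_OPTIMA)
            for opt in (400, 500, 460, 540, 600):
                row[f"minAD{opt}"] = markers.minimum_absolute_deviation(mset, float(opt))
        else:
            logger.info("sample %r has no marker points; excluded from group stats", s.sample_id)
            for col in STAT_COLUMNS:
                row[col] = np.nan
        comp = compositions_by_id.get(s.sample_id)
        if comp is not None:
            row["pigment_category"] = chemistry.categorize_sample(comp)
            row["dominance"] = chemistry.classify_dominance(comp)
            row["deoxy_pct"] = comp.deoxy_share
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary_table(samples: pd.DataFrame, group_col: str = "dominance") -> pd.DataFrame:
    """Mean / SD / SEM of each discrimination statistic per group.

    Samples without marker points carry NaN statistics and drop out of
    each group's n; SEM = SD / sqrt(n).
    """
    records = []
    for group, sub in samples.groupby(group_col):
        for stat in STAT_COLUMNS:
            vals = sub[stat].dropna()
            n = len(vals)
            sd = float(vals.std(ddof=1)) if n > 1 else np.nan
            records.append(
                {
                    "group": group,
                    "statistic": stat,
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sd": sd,
                    "sem": sd / np.sqrt(n) if n > 1 else np.nan,
                }
            )
    return pd.DataFrame(records)


def run_pipeline(
    sset: SpectrumSet,
    cfg: PipelineConfig | None = None,
    compositions: list[PigmentComposition] | None = None,
    tree: Phylogeny | None = None,
) -> PipelineResults:
    """Execute every analysis stage the provided inputs allow."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    notices: list[str] = []
    comps_by_id = {c.sample_id: c for c in (compositions or [])}
    if compositions:
        unmatched = set(comps_by_id) - {s.sample_id for s in sset}
        if unmatched:
            notices.append(f"compositions without spectra: {sorted(unmatched)[:5]}...")

    samples = _sample_table(sset, cfg, comps_by_id)
    results = PipelineResults(config=cfg, samples=samples, notices=notices)

    if not compositions:
        notices.append("no compositions: chemistry, hull and phylo stages skipped")
        return results

    results.tally = chemistry.combination_frequencies(compositions)
    try:
        results.pca = chemistry.composition_pca(chemistry.composite_table(compositions))
    except ValueError as exc:
        notices.append(f"PCA skipped: {exc}")
    results.group_summary = group_summary_table(samples)

    # hexagon area of the DEO90 group vs random subsets of the whole dataset
    with_loci = samples.dropna(subset=["hex_x", "hex_y"])
    deo_pts = with_loci.loc[with_loci["pigment_category"] == DEO90, ["hex_x", "hex_y"]]
    if len(deo_pts) >= 3:
        results.hull_test = hull_stats.subsample_area_null(
            with_loci[["hex_x", "hex_y"]].to_numpy(),
            deo_pts.to_numpy(),
            n_iter=cfg.hull_n_iter,
            percent=cfg.mcp_percent,
            seed=int(rng.integers(2**31)),
        )
    else:
        notices.append("fewer than 3 DEO90 loci: hull test skipped")

    if tree is None:
        notices.append("no tree: phylogenetic stages skipped")
        return results

    # phylogenetic ANOVA of the 7 statistics between dominance groups
    per_sample = samples.drop_duplicates("sample_id").set_index("sample_id")
    usable = [
        tip
        for tip in tree.tip_labels
        if tip in per_sample.index
        and per_sample.loc[tip, "dominance"] in (DEO_DOMINANT, HYD_DOMINANT)
        and pd.notna(per_sample.loc[tip, "MAD_bee"])  # marker-less samples drop out
    ]
    missing_tips = [t for t in tree.tip_labels if t not in per_sample.index]
    if missing_tips:
        notices.append(f"tree tips without spectra pruned: {len(missing_tips)}")
    group_sizes = per_sample.loc[usable, "dominance"].value_counts() if usable else pd.Series()
    if len(usable) >= 4 and (group_sizes >= 2).sum() >= 2:
        sub = tree.prune_to(usable)
        groups = per_sample.loc[sub.tip_labels, "dominance"].to_numpy()
        anova_rows = []
        for stat in STAT_COLUMNS:
            trait = per_sample.loc[sub.tip_labels, stat].to_numpy(dtype=float)
            res = phylo.phyl_anova(
                sub, trait, groups, n_sim=cfg.anova_n_sim, seed=int(rng.integers(2**31))
            )
            anova_rows.append(
                {"statistic": stat, "F": res.f_obs, "p": res.p_sim, "sigma2": res.sigma2_hat}
            )
        anova = pd.DataFrame(anova_rows)
        anova["p_holm"] = phylo.holm_adjust(anova["p"].tolist())
        results.anova = anova

        deoxy = per_sample.loc[sub.tip_labels, "deoxy_pct"].to_numpy(dtype=float)
        results.ancestral = phylo.ancestral_states_bm(sub, deoxy)
    else:
        notices.append("too few usable tips per dominance group: phylogenetic ANOVA skipped")
    return results


def write_report(results: PipelineResults, out_dir) -> dict:
    """Write machine-readable results (JSON + CSV tables) and a text summary.

    Returns the JSON-serializable report dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.samples.to_csv(out / "samples.csv", index=False)
    report: dict = {
        "config": dataclasses.asdict(results.config),
        "config_hash": results.config.config_hash(),
        "n_samples": int(results.samples["sample_id"].nunique()),
        "notices": results.notices,
    }
    if results.group_summary is not None:
        results.group_summary.to_csv(out / "group_summary.csv", index=False)
        report["group_summary"] = results.group_summary.to_dict(orient="records")
    if results.anova is not None:
        results.anova.to_csv(out / "phyl_anova.csv", index=False)
        report["phyl_anova"] = results.anova.to_dict(orient="records")
    if results.hull_test is not None:
        h = results.hull_test
        report["hull_test"] = {
            "observed_area": h.observed_area,
            "null_mean": h.null_mean,
            "ci_low": h.ci_low,
            "ci_high": h.ci_high,
            "p_value": h.p_value,
            "p_empirical": h.p_empirical,
            "n_iter": h.n_iter,
            "subset_size": h.subset_size,
            "percent": h.percent,
        }
    if results.pca is not None:
        report["pca"] = {
            "variance_fractions": results.pca.variance_fractions.tolist(),
            "loadings": results.pca.loadings.to_dict(),
        }
    if results.tally is not None:
        t = results.tally
        report["combinations"] = {
            "n_samples": t.n_samples,
            "n_no_anthocyanin": t.n_no_anthocyanin,
            "size_counts": {str(k): v for k, v in sorted(t.size_counts.items())},
            "pair_counts": t.pair_counts,
        }
    if results.ancestral is not None:
        pd.DataFrame(
            {
                "node": results.ancestral.node_ids,
                "estimate": results.ancestral.estimates,
                "variance": results.ancestral.variances,
            }
        ).to_csv(out / "ancestral_states.csv", index=False)
        report["ancestral_root"] = results.ancestral.root_estimate
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of a report dict."""
    lines = [
        f"floricolor run (config {report['config_hash']})",
        f"samples: {report['n_samples']}",
    ]
    if "hull_test" in report:
        h = report["hull_test"]
        lines.append(
            f"DEO90 hexagon area {h['observed_area']:.4f} vs null mean "
            f"{h['null_mean']:.4f} (95% CI {h['ci_low']:.4f}-{h['ci_high']:.4f}); "
            f"one-sided t p = {h['p_value']:.2e}, empirical p = {h['p_empirical']:.4f}"
        )
    if "phyl_anova" in report:
        lines.append("phylogenetic ANOVA (dominance groups):")
        for row in report["phyl_anova"]:
            lines.append(
                f"  {row['statistic']:<9} F = {row['F']:8.2f}  p = {row['p']:.4f}"
                f"  p(Holm) = {row['p_holm']:.4f}"
            )
    if "pca" in report:
        fr = report["pca"]["variance_fractions"]
        lines.append(
            "composition PCA variance: "
            + ", ".join(f"PC{i + 1} {100 * f:.1f}%" for i, f in enumerate(fr))
        )
    for notice in report.get("notices", []):
        lines.append(f"note: {notice}")
    return "\n".join(lines) + "\n"
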