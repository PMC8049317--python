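"""Non-interactive report: profile → impute → threshold sweep → topology.

Produces a directory of machine-readable tables (JSON/CSV), figures
(PNG), GraphML graphs and a static HTML page assembling them, plus a
manifest that records the configuration and seeds so a run can be
reproduced exactly.
"""

from __future__ import annotations

import csv
import json
import logging
import platform
from pathlib import Path
from string import Template

import numpy as np

from . import __version__
from .compare import ThresholdComparison, estimate_density, mean_intensity_per_sample, threshold_sweep
from .impute import impute
from .io import write_matrix
from .mapper import MapperConfig, build_mapper, compare_topologies, detect_communities, enrich_missingness
from .matrix import ProteinMatrix
from .plots import plot_density_overlay, plot_mapper_graphs, plot_missingness_histograms
from .profile import profile_missingness

__all__ = ["run_report"]

log = logging.getLogger("protmiss")

_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>protmiss report</title>
<style>
 body { font-family: sans-serif; max-width: 1100px; margin: 2em auto; color: #222; }
 table { border-collapse: collapse; font-size: 0.85em; }
 td, th { border: 1px solid #ccc; padding: 3px 8px; text-align: right; }
 th { background: #eee; }
 img { max-width: 100%; }
 h2 { border-bottom: 1px solid #ccc; }
</style></head><body>
<h1>Missingness assessment report</h1>
<p>protmiss $version — method: <b>$method</b>, seed $seed.</p>
<h2>Explorative missingness</h2>
<pre>$profile_text</pre>
<img src="missingness_histograms.png" alt="missingness histograms">
<h2>Imputed vs non-imputed densities across thresholds</h2>
<table>
<tr><th>τ</th><th>proteins kept</th><th>% missing (kept)</th><th>peak non-imp</th>
<th>peak imp</th><th>Δpeak</th><th>KS D</th><th>KS p</th></tr>
$sweep_rows
</table>
$density_imgs
<h2>Topology comparison</h2>
<pre>$topology_text</pre>
<img src="mapper_graphs.png" alt="mapper graphs">
</body></html>
"""
)


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=1, sort_keys=True) + "\n")


def _sweep_csv(rows: list[ThresholdComparison], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["threshold", "n_proteins_kept", "pct_missing_non_imputed",
                  "pct_missing_non_imputed_prefilter", "pct_missing_imputed",
                  "q1_non_imputed", "median_non_imputed", "q3_non_imputed",
                  "q1_imputed", "median_imputed", "q3_imputed",
                  "peak_non_imputed", "peak_imputed", "peak_distance", "ks_D", "ks_p"]
        writer.writerow(header)
        for r in rows:
            writer.writerow([
                f"{r.threshold:.2f}", r.n_proteins_kept,
                f"{r.pct_missing_non_imputed:.6f}", f"{r.pct_missing_non_imputed_prefilter:.6f}",
                f"{r.pct_missing_imputed:.6f}",
                *(f"{q:.10g}" for q in r.quartiles_non_imputed),
                *(f"{q:.10g}" for q in r.quartiles_imputed),
                f"{r.peak_non_imputed:.10g}", f"{r.peak_imputed:.10g}",
                f"{r.peak_distance:.10g}", f"{r.ks_D:.10g}", f"{r.ks_p:.10g}",
            ])


def run_report(
    non_imputed: ProteinMatrix,
    method: str,
    out_dir: str | Path,
    thresholds: tuple[float, ...] | None = None,
    mapper_cfg: MapperConfig | None = None,
    mapper_threshold: float = 0.8,
    seed: int | None = 0,
    method_params: dict | None = None,
    make_figures: bool = True,
) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Stages: missingness profile → imputation with ``method`` → threshold
    sweep of density/KS comparisons → Mapper topologies of the
    non-imputed and imputed matrices (at ``mapper_threshold``), enriched
    with missingness and community structure.  A stage failure aborts with
    the stage name; outputs written before the failure are preserved.

    Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = tuple(thresholds) if thresholds else None
    stage = "profile"
    try:
        prof = profile_missingness(non_imputed)
        prof.to_json(out / "profile.json")
        with open(out / "per_sample_missingness.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "missing_fraction"])
            for s, f in zip(prof.sample_ids, prof.per_sample_fraction):
                w.writerow([s, f"{f:.10g}"])
        with open(out / "per_protein_missingness.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["protein_id", "missing_fraction"])
            for pid, f in zip(prof.protein_ids, prof.per_protein_fraction):
                w.writerow([pid, f"{f:.10g}"])
        if make_figures:
            plot_missingness_histograms(prof, out / "missingness_histograms.png")

        stage = "impute"
        result = impute(non_imputed, method, params=method_params, seed=seed)
        imputed = result.completed
        write_matrix(imputed, out / "imputed.tsv")

        stage = "compare"
        rows = (
            threshold_sweep(non_imputed, imputed, thresholds)
            if thresholds
            else threshold_sweep(non_imputed, imputed)
        )
        _write_json([r.to_dict() for r in rows], out / "threshold_sweep.json")
        _sweep_csv(rows, out / "threshold_sweep.csv")
        density_imgs = []
        if make_figures:
            for r in rows:
                keep = non_imputed.missing_fraction_per_protein() < r.threshold
                x_ni, _ = mean_intensity_per_sample(non_imputed.subset_proteins(keep))
                x_im, _ = mean_intensity_per_sample(imputed.subset_proteins(keep))
                name = f"density_tau_{int(round(r.threshold * 100)):02d}.png"
                plot_density_overlay(
                    estimate_density(x_ni), estimate_density(x_im), r, out / name
                )
                density_imgs.append(name)

        stage = "mapper"
        mapper_cfg = mapper_cfg or MapperConfig()
        keep = non_imputed.missing_fraction_per_protein() < mapper_threshold
        if not keep.any():
            raise ValueError(f"no proteins kept at mapper threshold {mapper_threshold}")
        ni_f = non_imputed.subset_proteins(keep)
        im_f = imputed.subset_proteins(keep)
        g_ni = detect_communities(enrich_missingness(build_mapper(ni_f, mapper_cfg, seed=seed), prof))
        g_im = detect_communities(enrich_missingness(build_mapper(im_f, mapper_cfg, seed=seed), prof))
        topo = compare_topologies(g_ni, g_im)
        _write_json(topo, out / "topology_comparison.json")
        g_ni.write_graphml(out / "mapper_non_imputed.graphml")
        g_im.write_graphml(out / "mapper_imputed.graphml")
        _write_json(
            {"non_imputed": g_ni.node_table(), "imputed": g_im.node_table()},
            out / "mapper_nodes.json",
        )
        if make_figures:
            plot_mapper_graphs(
                [("non-imputed", g_ni), (f"imputed ({result.method})", g_im)],
                out / "mapper_graphs.png",
                seed=seed or 0,
            )
    except Exception as exc:
        raise RuntimeError(f"report stage {stage!r} failed: {exc}") from exc

    manifest = {
        "protmiss_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "seed": seed,
        "method": result.method,
        "method_params": result.params,
        "imputation_converged": result.converged,
        "imputation_iterations": result.n_iterations_run,
        "thresholds": [r.threshold for r in rows],
        "mapper_threshold": mapper_threshold,
        "mapper_config": {
            "lens1": mapper_cfg.lens1, "lens2": mapper_cfg.lens2,
            "intervals": list(mapper_cfg.intervals), "overlap": mapper_cfg.overlap,
            "clustering_bins": mapper_cfg.clustering_bins,
            "metric": mapper_cfg.metric, "missing_policy": mapper_cfg.missing_policy,
        },
        "n_samples": non_imputed.n_samples,
        "n_proteins": non_imputed.n_proteins,
    }
    _write_json(manifest, out / "manifest.json")

    sweep_rows = "\n".join(
        f"<tr><td>{r.threshold:.2f}</td><td>{r.n_proteins_kept}</td>"
        f"<td>{r.pct_missing_non_imputed:.2f}</td><td>{r.peak_non_imputed:.3f}</td>"
        f"<td>{r.peak_imputed:.3f}</td><td>{r.peak_distance:.3f}</td>"
        f"<td>{r.ks_D:.4f}</td><td>{r.ks_p:.3g}</td></tr>"
        for r in rows
    )
    html = _PAGE.substitute(
        version=__version__,
        method=result.method,
        seed=seed,
        profile_text=prof.summary_text(),
        sweep_rows=sweep_rows,
        density_imgs="\n".join(f'<img src="{n}" alt="{n}">' for n in density_imgs),
        topology_text=json.dumps(_round_floats(topo), indent=1, sort_keys=True),
    )
    (out / "report.html").write_text(html)
    log.info("report written to %s", out)
    return manifest
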