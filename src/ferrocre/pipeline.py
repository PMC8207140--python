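"""End-to-end analysis: simulate -> cluster -> discover -> scan -> select
-> classify -> profile -> flowchart, with all report files written.

This wires the individual modules together in the order a promoter-CRE
study runs them, using the scan window -500..+150 relative to the TSS
for discovery and features, and the wide -3000..+2000 span for the
positional profiles.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import pandas as pd

from . import classify, coexpress, motifdisc, motifscan, positional, promomodel, synthgen
from .seqio import WindowSpec, extract_windows, windows_to_fasta

__all__ = ["PipelineResult", "run_pipeline", "SCAN_WINDOW", "PROFILE_SPAN"]

SCAN_WINDOW = WindowSpec(-500, 150)
PROFILE_SPAN = (-3000, 2000)


@dataclass
class PipelineResult:
    dataset: synthgen.SyntheticDataset
    regulons: coexpress.RegulonAssignment
    discovered: list[motifdisc.EnrichmentResult]
    features: pd.DataFrame
    selection: classify.FeatureSelectionResult
    report: classify.ClassifierReport
    flowchart: promomodel.FlowNode
    files: dict[str, str]


def run_pipeline(
    config: synthgen.SynthConfig | None = None,
    outdir: str = "ferrocre_out",
    seed: int | None = None,
    discovery_regulon: str = "storage",
    top_m: int = 50,
    alpha: float = 0.001,
) -> PipelineResult:
    """Run the full pipeline on a synthetic dataset and write reports."""
    if config is None:
        config = synthgen.SynthConfig()
    if seed is not None:
        config.seed = seed
    os.makedirs(outdir, exist_ok=True)
    files: dict[str, str] = {}

    # 1. simulate
    dataset = synthgen.generate_dataset(config)
    files.update(synthgen.write_dataset(dataset, os.path.join(outdir, "data")))

    # 2. cluster into regulons
    deg = coexpress.select_deg(dataset.expression, fold_threshold=2.0)
    none_genes = coexpress.select_no_response(dataset.expression, n=100)
    regulons = coexpress.cluster_regulons(
        dataset.expression, deg, coexpress.ClusterParams(), no_response_genes=none_genes
    )
    reg_path = os.path.join(outdir, "regulons.tsv")
    pd.DataFrame(
        {"label": regulons.labels, "module_id": regulons.module_ids}
    ).to_csv(reg_path, sep="\t", index_label="gene_id")
    files["regulons"] = reg_path

    # 3. promoter windows
    windows = extract_windows(dataset.genome, dataset.genes, SCAN_WINDOW)
    win_path = os.path.join(outdir, "windows.fa")
    windows_to_fasta(windows, win_path)
    files["windows"] = win_path

    # 4. k-mer discovery in one regulon vs the all-genes background
    regulon_genes = [
        g for g, lab in regulons.labels.items() if lab == discovery_regulon
    ]
    discovered = motifdisc.discover_kmers(
        {g: windows[g] for g in regulon_genes},
        windows,
        k=8,
        top_m=top_m,
        alpha=alpha,
        regulon=discovery_regulon,
    )
    disc_path = os.path.join(outdir, "discovered_motifs.tsv")
    motifdisc.write_enrichment_tsv(discovered, disc_path)
    files["discovered"] = disc_path

    # 5. presence features: catalog order, then discovered
    catalog = motifscan.load_known_catalog()
    seen = {m.consensus for m in catalog}
    extra = [
        r.motif for r in discovered[:10] if r.motif.consensus not in seen
    ]
    features = motifscan.presence_matrix(windows, catalog + extra)
    feat_path = os.path.join(outdir, "features.tsv")
    features.to_csv(feat_path, sep="\t", index_label="gene_id")
    files["features"] = feat_path

    # 6. shadow selection + boosted-tree classification on clustered labels
    labeled = regulons.labels
    X = features.loc[labeled.index]
    selection = classify.shadow_select(X, labeled, seed=config.seed)
    sel_path = os.path.join(outdir, "selection.json")
    with open(sel_path, "w") as fh:
        json.dump(
            {
                "confirmed": selection.confirmed,
                "tentative": selection.tentative,
                "rejected": selection.rejected,
                "importance_scaled": selection.importance_scaled.round(2).to_dict(),
                "n_iterations": selection.n_iterations,
            },
            fh,
            indent=1,
        )
    files["selection"] = sel_path

    model_features = selection.confirmed or list(X.columns)
    report = classify.fit_and_evaluate(
        X, labeled, seed=config.seed, feature_subset=model_features
    )
    rep_path = os.path.join(outdir, "classifier_report.json")
    report.to_json(rep_path)
    files["report"] = rep_path
    conf_path = os.path.join(outdir, "confusion.tsv")
    report.confusion_counts.to_csv(conf_path, sep="\t")
    files["confusion"] = conf_path

    # 7. positional profile + coverage for the top confirmed motif
    profile_motif = None
    for name in selection.confirmed:
        profile_motif = next(m for m in catalog + extra if m.name == name)
        break
    if profile_motif is None and (catalog + extra):
        profile_motif = catalog[3]  # IDEF1 binding site
    wide = extract_windows(
        dataset.genome, dataset.genes, WindowSpec(*PROFILE_SPAN)
    )
    hits = {
        gid: [PROFILE_SPAN[0] + off for off in motifscan.scan_window(w, profile_motif)]
        for gid, w in wide.items()
    }
    set_genes = [g for g, lab in regulons.labels.items() if lab != "none"]
    profile = positional.positional_profile(
        hits, set_genes, list(windows), span=PROFILE_SPAN
    )
    prof_path = os.path.join(outdir, "profile.tsv")
    profile.to_frame().to_csv(prof_path, sep="\t", index=False)
    files["profile"] = prof_path
    coverage = positional.coverage_by_foldchange(
        features[profile_motif.name],
        dataset.expression[dataset.expression.columns[0]],
    )
    cov_path = os.path.join(outdir, "coverage.tsv")
    coverage.to_frame().to_csv(cov_path, sep="\t", index=False)
    files["coverage"] = cov_path

    # 8. interpretable flowchart on the undersampled balanced set
    flow_features = model_features
    flow = promomodel.fit_flowchart(
        X[flow_features], labeled, class_order=sorted(labeled.unique()), seed=config.seed
    )
    txt_path = os.path.join(outdir, "flowchart.txt")
    with open(txt_path, "w") as fh:
        fh.write(promomodel.render_flowchart(flow))
    files["flowchart_txt"] = txt_path
    json_path = os.path.join(outdir, "flowchart.json")
    promomodel.flowchart_to_json(flow, json_path)
    files["flowchart_json"] = json_path

    return PipelineResult(
        dataset, regulons, discovered, features, selection, report, flow, files
    )
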