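"""End-to-end orchestration: chain the stages on fixtures or a synthetic
world, write per-stage TSV artifacts, and record a reproducibility manifest.

Stages communicate through TSV files on disk so each can also be run
standalone from the command line."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .expression import expression_stats, group_mean_anova, threshold_sweep
from .fixtures import fixture_classifications, fixture_nt_hits
from .htt import (call_htt_table, htt_family_rollup, load_taxa17_scheme,
                  tally_taxa)
from .novelty import (build_profiles, fit_novelty, predict_similar_in_all,
                      select_training_set)
from .synth import WorldSpec, generate_world
from .te import (build_classifications, check_family_consistency,
                 classify_te_transcripts, assign_family, assign_superfamily,
                 load_family_catalog, tabulate_classifications, tally_totals)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_classifications(classifications, path: Path) -> None:
    pd.DataFrame([{
        "transcript_id": c.transcript_id, "is_te": c.is_te,
        "group": c.group, "superfamily": c.superfamily,
        "family": c.family or "",
        "family_superfamily_consistent":
            "" if c.family_superfamily_consistent is None
            else c.family_superfamily_consistent}
        for c in classifications]).to_csv(path, sep="\t", index=False)


def _write_calls(calls, path: Path) -> None:
    pd.DataFrame([{
        "transcript_id": c.transcript_id,
        "top_hit_taxon": c.top_hit_taxon or "",
        "top_hit_organism": c.top_hit_organism or "",
        "is_htt": "" if c.is_htt is None else c.is_htt}
        for c in calls]).to_csv(path, sep="\t", index=False)


def run_fixture_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run taxon mapping, HTT calling, tallies and the family roll-up over
    the packaged fixture tables; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = load_family_catalog()
    scheme = load_taxa17_scheme()
    classifications = fixture_classifications()
    ids = [c.transcript_id for c in classifications]
    calls = call_htt_table(fixture_nt_hits(), ids, scheme,
                           e_nt_hit=config.e_nt_hit)

    tally = tally_taxa(calls, classifications)
    families, n_fam_transcripts = htt_family_rollup(
        calls, classifications, catalog=catalog)
    class_tally = tabulate_classifications(classifications)
    totals = tally_totals(class_tally)
    discordant = check_family_consistency(classifications, catalog)

    _write_classifications(classifications, outdir / "classifications.tsv")
    _write_calls(calls, outdir / "htt_calls.tsv")
    tally.to_csv(outdir / "tally_taxa.tsv", sep="\t")

    summary = {
        "n_te_transcripts": totals["total"],
        "per_group": totals["per_group"],
        "n_family_assigned": totals["n_family_assigned"],
        "n_distinct_families": totals["n_distinct_families"],
        "discordant_families": discordant,
        "n_with_top_hit": int(tally.loc["Total", "Total"]),
        "n_arthropod_top": int(tally.loc["Total", "Arthropoda"]),
        "n_htt": sum(1 for c in calls if c.is_htt),
        "n_virus_top": int(tally.loc["Total", "Viruses"])
        if "Viruses" in tally.columns else 0,
        "htt_families": sorted(families),
        "n_htt_families": len(families),
        "n_htt_family_transcripts": n_fam_transcripts,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_synthetic_pipeline(config: PipelineConfig, outdir: str | Path,
                           spec: WorldSpec | None = None) -> dict:
    """Generate a synthetic world, run every stage, and score calls against
    the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = WorldSpec(seed=config.random_seed)
    world = generate_world(spec)
    catalog = load_family_catalog()
    scheme = load_taxa17_scheme()

    te_ids = classify_te_transcripts(
        world.hit_tables["cdd"], world.hit_tables["repeat_lib"],
        world.te_domain_flags, e_te_candidate=config.e_te_candidate)
    superfamilies = assign_superfamily(
        world.hit_tables["repeat_lib"], world.repeat_annotation,
        transcript_ids=te_ids)
    families = assign_family(
        world.hit_tables["repeat_blastn"], catalog,
        focal_species="Litopenaeus vannamei", e_family=config.e_family)
    classifications = build_classifications(te_ids, superfamilies, families,
                                            catalog)
    calls = call_htt_table(world.hit_tables["nt"], te_ids, scheme,
                           e_nt_hit=config.e_nt_hit)

    truth = world.truth
    te_truth = set(truth.index[truth["is_te"]])
    htt_truth = set(truth.index[truth["is_htt"]])
    called_htt = {c.transcript_id for c in calls if c.is_htt}
    metrics = {
        "te_recall": len(te_ids & te_truth) / max(len(te_truth), 1),
        "te_precision": len(te_ids & te_truth) / max(len(te_ids), 1),
        "htt_recall": len(called_htt & htt_truth) / max(len(htt_truth), 1),
        "htt_precision": len(called_htt & htt_truth) /
        max(len(called_htt), 1),
    }

    # expression + novelty over the generated projects
    stats = {p: expression_stats(m) for p, m in
             world.count_matrices.items()}
    sweep = threshold_sweep(
        stats[spec.projects[0]],
        {"overall": set(truth.index), "TE": te_ids,
         "HTT": called_htt & te_ids},
        thresholds=config.mfc_thresholds)
    sweep.to_csv(outdir / "sweep.tsv", sep="\t", index_label="threshold")
    anova = group_mean_anova(world.count_matrices[spec.projects[0]],
                             subset=set(truth.index), threshold=1.0,
                             stats=stats[spec.projects[0]])

    training = select_training_set(stats, called_htt,
                                   mfc_cut=config.novelty_training_mfc)
    models, candidates = {}, {}
    for project, st in stats.items():
        profiles = build_profiles(st.group_values)
        models[project] = fit_novelty(profiles.loc[sorted(training)],
                                      seed=config.random_seed)
        candidates[project] = profiles
    predicted = predict_similar_in_all(models, candidates, exclude=te_ids)
    mimic_truth = set(truth.index[truth["is_mimic"]])
    metrics["mimic_recall"] = len(predicted & mimic_truth) / \
        max(len(mimic_truth), 1)
    background = set(truth.index) - mimic_truth - te_ids
    metrics["background_positive_rate"] = \
        len(predicted & background) / max(len(background), 1)

    _write_classifications(classifications, outdir / "classifications.tsv")
    _write_calls(calls, outdir / "htt_calls.tsv")
    pd.Series(sorted(predicted)).to_csv(
        outdir / "novelty_candidates.tsv", sep="\t", index=False,
        header=["transcript_id"])

    summary = {
        "n_transcripts": spec.n_transcripts,
        "n_te_called": len(te_ids),
        "n_htt_called": len(called_htt),
        "n_novelty_candidates": len(predicted),
        "anova_F": anova.f_stat, "anova_p": anova.p_value,
        "truth_metrics": metrics,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_all(config: PipelineConfig, outdir: str | Path,
            mode: str = "fixtures") -> dict:
    """One-command run; returns the manifest (config snapshot, seed, stage
    outputs with content digests)."""
    outdir = Path(outdir)
    if mode == "fixtures":
        summary = run_fixture_pipeline(config, outdir)
    elif mode == "synthetic":
        summary = run_synthetic_pipeline(config, outdir)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    manifest = {
        "tool_version": __version__,
        "mode": mode,
        "seed": config.random_seed,
        "config": {**asdict(config),
                   "mfc_thresholds": list(config.mfc_thresholds)},
        "outputs": {p.name: _digest(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
        "summary": summary,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
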