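"""Single-call orchestration of the full analysis.

Stage order: read + normalize inputs -> pre-test filters -> beta-binomial
differential test with BH adjustment -> reading-frame prediction ->
isoform translation and protein diff -> genomic naming -> output tables
(and optional figures for the top events by |delta PSI|).  Frame
prediction and translation run only on statistically significant events
unless ``translate_all`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .filtering import apply_filters
from .frames import agreement_matrix, frames_table, predict_frame
from .model import FilterConfig, SpliceframeError
from .protein import diffs_table, protein_diff
from .seqtools import Genome
from .stats import run_differential_test
from .viz import match_transcript, render_domain_figure, render_event_figure, \
    render_transcript_figure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    events: Path
    counts: Path
    genome: Path
    annotation: Path
    proteins: Path
    domains: Path
    out_dir: Path
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.01
    min_match_len: int = 7
    translate_all: bool = False
    figures_top: int = 0
    case_group: str | None = None
    control_group: str | None = None
    test: str = "lrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise SpliceframeError("alpha must lie in (0, 1)")


def _infer_groups(counts: pd.DataFrame, config: PipelineConfig) -> tuple[str, str]:
    labels = sorted(counts["group"].unique())
    if config.case_group and config.control_group:
        missing = {config.case_group, config.control_group} - set(labels)
        if missing:
            raise SpliceframeError(f"group label(s) {sorted(missing)} not in counts")
        return config.case_group, config.control_group
    if len(labels) != 2:
        raise SpliceframeError(f"expected 2 group labels, found {labels}")
    logger.info("groups inferred: case=%s control=%s", labels[0], labels[1])
    return labels[0], labels[1]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write results/stats/frames/funnel tables.

    Aborts with the failing stage's name; partially written outputs are
    removed on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read_inputs"
    try:
        events = io.read_event_table(config.events)
        if not events:
            raise SpliceframeError("event table is empty")
        counts = io.read_counts_table(
            config.counts, events, config.filters.min_coverage
        )
        if counts.empty:
            raise SpliceframeError("counts table is empty")
        genome = Genome(config.genome)
        gene_models = io.read_annotation_table(config.annotation)
        proteins = io.read_protein_fasta(config.proteins)
        domains = io.read_domain_table(config.domains)
        case, control = _infer_groups(counts, config)

        stage = "filtering"
        kept_events, funnel = apply_filters(
            events, counts, gene_models, config.filters
        )
        funnel_path = out / "funnel.tsv"
        funnel.to_csv(funnel_path, sep="\t", index=False)
        written.append(funnel_path)
        if not kept_events:
            raise SpliceframeError("no events survive filtering")

        stage = "differential_test"
        kept_ids = {e.event_id for e in kept_events}
        stats = run_differential_test(
            counts[counts["event_id"].isin(kept_ids)],
            case, control, alpha=config.alpha, test=config.test,
            seed=config.seed,
        )
        stats_path = out / "stats.tsv"
        stats.to_csv(stats_path, sep="\t", index=False)
        written.append(stats_path)
        n_sig = int(stats["significant"].sum())
        logger.info("%d of %d tested events significant at alpha=%g",
                    n_sig, len(stats), config.alpha)

        stage = "frame_prediction"
        sig_ids = set(stats.loc[stats["significant"], "event_id"])
        to_translate = [
            e for e in kept_events
            if config.translate_all or e.event_id in sig_ids
        ]
        predictions = [
            predict_frame(
                e, genome, proteins.get(e.gene, []),
                min_match_len=config.min_match_len,
            )
            for e in to_translate
        ]
        frames = frames_table(predictions)
        frames_path = out / "frames.tsv"
        frames.to_csv(frames_path, sep="\t", index=False)
        written.append(frames_path)
        if predictions:
            resolved = sum(p.frame != "X" for p in predictions)
            logger.info(
                "frames resolved for %d/%d events (%.1f%%)",
                resolved, len(predictions), 100 * resolved / len(predictions),
            )
            logger.info("method agreement:\n%s",
                        agreement_matrix(predictions).to_string())

        stage = "protein_diff"
        by_id = {e.event_id: e for e in kept_events}
        diffs = [
            protein_diff(by_id[p.event_id], int(p.frame), genome)
            for p in predictions
            if p.frame != "X"
        ]
        diff_df = diffs_table(diffs)

        stage = "write_results"
        results = io.write_results_table(
            kept_events, stats, frames, diff_df, out / "results.tsv"
        )
        written.append(out / "results.tsv")

        stage = "figures"
        if config.figures_top > 0:
            _render_figures(
                config, out, kept_events, stats, diffs, counts, gene_models,
                domains, sig_ids,
            )
    except SpliceframeError as err:
        for path in written:
            path.unlink(missing_ok=True)
        raise SpliceframeError(f"stage {stage}: {err}") from err

    return {
        "results": results,
        "stats": stats,
        "frames": frames,
        "funnel": funnel,
        "diffs": diff_df,
        "out_dir": out,
    }


def _render_figures(config, out, events, stats, diffs, counts, gene_models,
                    domains, sig_ids):
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    diffs_by_id = {d.event_id: d for d in diffs}
    ranked = (
        stats[stats["event_id"].isin(sig_ids)]
        .assign(abs_delta=lambda d: d["delta_psi"].abs())
        .sort_values("abs_delta", ascending=False)
        .head(config.figures_top)
    )
    by_id = {e.event_id: e for e in events}
    domains_by_gene: dict[str, list] = {}
    for d in domains:
        domains_by_gene.setdefault(d.gene, []).append(d)
    for _, row in ranked.iterrows():
        event = by_id[row["event_id"]]
        safe = event.event_id.replace("/", "_")
        psi = counts[counts["event_id"] == event.event_id]
        render_event_figure(
            event, row, diffs_by_id.get(event.event_id), psi,
            fig_dir / f"{safe}.event.png",
        )
        model = gene_models.get(event.gene)
        if model is None:
            continue
        match = match_transcript(event, model)
        render_transcript_figure(
            event, match, model, fig_dir / f"{safe}.transcript.png"
        )
        if match.transcript_id is not None:
            tx = next(t for t in model.transcripts
                      if t.transcript_id == match.transcript_id)
            render_domain_figure(
                event, tx, domains_by_gene.get(event.gene, []),
                fig_dir / f"{safe}.domains.png",
            )
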