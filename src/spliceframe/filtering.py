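"""Pre-test event filters.

Three filters run before differential testing, trimming events that could
never yield a meaningful result: events in non-coding genes, events with too
many missing PSI values, and events with near-constant PSI.  Set membership
is order-independent; the reported funnel uses the fixed order
coding -> missingness -> variability.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import FilterConfig, GeneModel, SpliceEvent, SpliceframeError

logger = logging.getLogger(__name__)


def filter_missingness(
    measurements: pd.DataFrame,
    config: FilterConfig,
    groups: tuple[str, str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Keep events with >= ``min_valid_per_group`` valid PSI in every group.

    Returns the surviving event IDs and a per-event table of valid-sample
    counts per group.
    """
    observed = sorted(measurements["group"].unique())
    if groups is None:
        if len(observed) != 2:
            raise SpliceframeError(
                f"expected exactly 2 group labels, found {observed}"
            )
        groups = tuple(observed)
    elif set(observed) - set(groups):
        raise SpliceframeError(
            f"unknown group label(s): {sorted(set(observed) - set(groups))}"
        )
    valid = (
        measurements[measurements["psi"].notna()]
        .groupby(["event_id", "group"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(groups), fill_value=0)
        .reindex(measurements["event_id"].unique(), fill_value=0)
    )
    kept = set(valid.index[(valid >= config.min_valid_per_group).all(axis=1)])
    return kept, valid.reset_index(names="event_id")


def filter_variability(
    measurements: pd.DataFrame, config: FilterConfig
) -> tuple[set[str], pd.DataFrame]:
    """Keep events whose pooled valid-PSI sample SD is >= ``min_psi_sd``.

    The SD uses the n-1 denominator over all valid PSI values of both groups.
    Events with fewer than two valid values have undefined SD and are dropped.
    """
    sd = (
        measurements[measurements["psi"].notna()]
        .groupby("event_id", sort=False)["psi"]
        .std(ddof=1)
        .reindex(measurements["event_id"].unique())
    )
    undefined = sd.index[sd.isna()]
    if len(undefined):
        logger.info("dropping %d events with undefined PSI SD", len(undefined))
    kept = set(sd.index[sd >= config.min_psi_sd])
    return kept, sd.rename("psi_sd").rename_axis("event_id").reset_index()


def filter_coding(
    events: list[SpliceEvent],
    gene_models: dict[str, GeneModel],
    config: FilterConfig,
) -> set[str]:
    """Keep events in protein-coding genes.

    Genes absent from the annotation are treated as non-coding and dropped
    with a warning, so partial annotations remain usable.
    """
    if not config.require_protein_coding:
        return {e.event_id for e in events}
    kept = set()
    missing = set()
    for e in events:
        model = gene_models.get(e.gene)
        if model is None:
            missing.add(e.gene)
            continue
        if model.biotype == "protein_coding":
            kept.add(e.event_id)
    if missing:
        logger.warning(
            "%d genes absent from annotation, their events dropped", len(missing)
        )
    return kept


def apply_filters(
    events: list[SpliceEvent],
    measurements: pd.DataFrame,
    gene_models: dict[str, GeneModel],
    config: FilterConfig,
) -> tuple[list[SpliceEvent], pd.DataFrame]:
    """Run the three filters and report the funnel.

    Returns surviving events and a funnel table (stage, events_in,
    events_out) in the reporting order coding -> missingness -> variability.
    """
    stages = []
    surviving = list(events)

    kept_coding = filter_coding(surviving, gene_models, config)
    stages.append(("coding", len(surviving), len(kept_coding)))
    surviving = [e for e in surviving if e.event_id in kept_coding]

    meas = measurements[measurements["event_id"].isin(kept_coding)]
    kept_missing, _ = filter_missingness(meas, config)
    stages.append(("missingness", len(surviving), len(kept_missing)))
    surviving = [e for e in surviving if e.event_id in kept_missing]

    meas = meas[meas["event_id"].isin(kept_missing)]
    kept_var, _ = filter_variability(meas, config)
    stages.append(("variability", len(surviving), len(kept_var)))
    surviving = [e for e in surviving if e.event_id in kept_var]

    funnel = pd.DataFrame(stages, columns=["stage", "events_in", "events_out"])
    return surviving, funnel
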