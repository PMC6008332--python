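"""Differential-splicing detection via the splicing-ratio-difference (srd)
statistic.

For one event in treatment sample *j* with splicing ratio ``SR_tj`` against
control ratios ``SR_c`` (``N_c`` controls), the score is

    srd = (1 + sum_i (SR_tj - SR_ci)) / (1 + sd(SR_c) / N_c)

with the sample standard deviation (``N_c - 1`` divisor).  An unchanged
event has srd = 1 exactly when the controls agree.  :func:`compute_srd`
implements the formula as stated (summing, not averaging, the control
differences, so the score scales with ``N_c``); the ``average`` switch is
the mean-difference variant.

Selection pipeline
------------------
Each treatment sample is compared against all controls; the resulting
per-sample srd distribution gets a power-law tail fit
(:mod:`spliceratio.tailfit`) and each event a tail significance.  The
per-event summary is the median significance across treatment samples,
compared against a dynamic background of null medians computed from the
samples themselves.  Three calibration choices make treatment and
background significances commensurable — see ``docs/methods.md`` for the
full rationale:

* the background is built by relabeling: every other assignment of the
  samples into a pseudo-treatment group of the same size (vs the
  remaining samples as pseudo-controls) is scored with the identical
  statistic, so the null medians share the observed comparison's control
  count and correlation structure;
* scores used for significance are computed on the mean-difference scale,
  so comparisons with different control counts stay commensurable;
* the tail model used for significance is the consensus (median alpha and
  cutoff) of all per-comparison fits, so a handful of genuinely changed
  events cannot flatten a treatment sample's own fit relative to the
  clean background fits; with an even number of samples the median of
  significances is interpolated geometrically (p-values combine on the
  log scale).

The default threshold is the largest significance cutoff whose estimated
false discovery rate — expected background-median events at the cutoff
over selected events — stays at or below ``fdr_target`` (default 0.20;
the relabeled background slightly over-counts nulls when real effects are
present, making the realized rate conservative); the fixed-percentile
rule (q-th percentile of background medians) is available as
``selection="percentile"``.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    ASEvent,
    JunctionKey,
    Site,
    build_events,
    classify_direction,
    compute_sr,
    group_junctions_by_site,
)
from .io import ExonAnnotation
from .tailfit import PowerLawFit, fit_power_law, significance

__all__ = [
    "SrdInput",
    "SrdScore",
    "CandidateEvent",
    "DetectionResult",
    "compute_srd",
    "event_srd",
    "combine_significance",
    "select_candidates",
    "rank_candidates",
    "map_isoforms",
    "intersect_comparisons",
    "detect",
]


@dataclass(frozen=True, slots=True)
class SrdInput:
    """Inputs of one srd evaluation: one event, one treatment sample."""

    event_id: str
    sample_id: str
    sr_t: float
    sr_controls: tuple[float, ...]


@dataclass(slots=True)
class SrdScore:
    """srd of one event in one treatment sample, with its tail significance
    once assigned."""

    event_id: str
    sample_id: str
    srd: float
    significance: float | None = None


@dataclass(frozen=True, slots=True)
class CandidateEvent:
    """A selected differential-splicing candidate."""

    event_id: str
    event_type: str
    median_significance: float
    rank_score: float
    direction: str | None


def compute_srd(sr_t: float, sr_controls: Sequence[float], average: bool = False) -> float:
    """The srd score of one event in one treatment sample.

    ``average=True`` replaces the summed numerator with the mean
    difference, removing the N_c scaling; the default follows the stated
    formula exactly.
    """
    n_c = len(sr_controls)
    if n_c < 2:
        raise ValueError("srd needs at least 2 control samples (s.d. undefined)")
    diffs = [sr_t - sr_ci for sr_ci in sr_controls]
    numerator = 1.0 + (sum(diffs) / n_c if average else sum(diffs))
    sd = statistics.stdev(sr_controls)  # N_c - 1 divisor
    return numerator / (1.0 + sd / n_c)


def event_srd(
    event: ASEvent,
    srd_inclusion: float,
    srd_skipping: float,
) -> tuple[float, JunctionKey]:
    """Per-event score: the larger of the two junctions' srd scores.

    The two junctions of a two-junction site group have complementary SRs,
    so a change pushes exactly one of them upward; taking the max captures
    both directions with a one-sided tail test.  Ties go to the inclusion
    junction.
    """
    if srd_skipping > srd_inclusion:
        return srd_skipping, event.skipping_junction
    return srd_inclusion, event.inclusion_junction


def combine_significance(p_table: pd.DataFrame) -> pd.Series:
    """Median significance across samples (columns) per event (rows).

    For an odd number of samples this is the ordinary median; for an even
    number the two middle values are interpolated geometrically, since
    p-values are log-scale quantities.
    """
    logs = np.log(p_table.to_numpy(dtype=float))
    return pd.Series(np.exp(np.median(logs, axis=1)), index=p_table.index)


def _per_sample_srd(
    events: Sequence[ASEvent],
    sr: Mapping[tuple[JunctionKey, Site], Mapping[str, float | None]],
    treatment_id: str,
    control_ids: Sequence[str],
    average: bool = False,
) -> dict[str, float]:
    """srd of every event for one (pseudo-)treatment sample; events with any
    missing SR are skipped (absent from the result)."""
    out: dict[str, float] = {}
    for ev in events:
        scores = []
        for junction in ev.junctions:
            series = sr.get((junction, ev.site))
            if series is None:
                break
            sr_t = series.get(treatment_id)
            sr_c = [series.get(c) for c in control_ids]
            if sr_t is None or any(v is None for v in sr_c):
                break
            scores.append(compute_srd(sr_t, sr_c, average=average))
        else:
            out[ev.event_id] = event_srd(ev, scores[0], scores[1])[0]
    return out


def select_candidates(
    treatment_p: pd.DataFrame,
    background_p: pd.DataFrame,
    q: float = 5.0,
    selection: str = "fdr",
    fdr_target: float = 0.20,
) -> pd.DataFrame:
    """Median-of-significance selection against the control background.

    Parameters
    ----------
    treatment_p
        events x treatment-samples table of tail significances.
    background_p
        events x control-samples table of leave-one-out significances (each
        control scored as a pseudo-treatment against the remaining
        controls).  Needs >= 3 controls.
    q
        Background percentile for ``selection="percentile"``: the threshold
        is the q-th percentile of the background medians.
    selection
        ``"fdr"`` (default): largest threshold whose estimated FDR — the
        expected number of background-like events at the threshold divided
        by the number selected — is at most ``fdr_target``.
        ``"percentile"``: fixed q-th percentile of the background medians.

    Returns a frame indexed by event id with ``median_significance``,
    ``background_median``, ``threshold`` and the boolean ``selected``.
    """
    if background_p.shape[1] < 3:
        raise ValueError("background needs >= 3 controls (leave-one-out)")
    med_t = combine_significance(treatment_p)

    # background summaries over control subsets of the treatment size, so
    # the null and observed statistics aggregate the same sample count
    k = min(treatment_p.shape[1], background_p.shape[1])
    pools = [
        combine_significance(background_p[list(cols)])
        for cols in combinations(background_p.columns, k)
    ]
    med_b = pd.concat(pools, axis=1).median(axis=1)
    background_pool = np.concatenate([p.to_numpy() for p in pools])
    background_pool = background_pool[np.isfinite(background_pool)]

    n = len(med_t)
    if selection == "percentile":
        threshold = float(np.percentile(background_pool, q))
    elif selection == "fdr":
        threshold = math.nan
        for t in np.unique(med_t.to_numpy())[::-1]:
            n_sel = int((med_t <= t).sum())
            null_expect = float(np.mean(background_pool <= t)) * n
            if n_sel and null_expect / n_sel <= fdr_target:
                threshold = float(t)
                break
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    selected = med_t <= threshold if not math.isnan(threshold) else pd.Series(
        False, index=med_t.index
    )
    out = pd.DataFrame(
        {
            "median_significance": med_t,
            "background_median": med_b,
            "threshold": threshold,
            "selected": selected,
        }
    )
    out.index.name = "event_id"
    return out


def map_isoforms(
    events: Sequence[ASEvent], annotation: Sequence[ExonAnnotation]
) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Assign annotated isoforms of each event's gene to inclusion and
    skipping classes.

    Inclusion isoforms contain the event's middle exon; skipping isoforms
    of the same gene lack it but retain exons flanking it (their junction
    spans the skipped exon).  Events without a gene or middle exon get no
    mapping.
    """
    by_gene: dict[str, dict[str, set[tuple[int, int]]]] = {}
    for exon in annotation:
        by_gene.setdefault(exon.gene_id, {}).setdefault(exon.transcript_id, set()).add(
            (exon.exon_start, exon.exon_end)
        )
    mapping: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    for ev in events:
        if ev.gene_id is None or ev.inclusion_exon is None:
            continue
        transcripts = by_gene.get(ev.gene_id, {})
        lo, hi = ev.inclusion_exon
        inclusion, skipping = [], []
        for tid, exons in sorted(transcripts.items()):
            if (lo, hi) in exons:
                inclusion.append(tid)
            elif any(e[1] < lo for e in exons) and any(e[0] > hi for e in exons):
                skipping.append(tid)
        mapping[ev.event_id] = (tuple(inclusion), tuple(skipping))
    return mapping


def rank_candidates(
    candidates: Iterable[CandidateEvent | str],
    expression: Mapping[str, Mapping[str, float]],
    isoform_map: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]],
    treatment_ids: Sequence[str],
    control_ids: Sequence[str],
) -> list[tuple[str, float]]:
    """Order candidates by the summed absolute treatment-minus-control
    expression difference of inclusion-class and skipping-class isoforms.

    ``expression`` maps sample id -> isoform id -> abundance.  Events with
    no mapped isoform score 0 and sort last; ties break by event id
    (stable).  Returns (event_id, rank_score) in final order.
    """

    def class_mean(isoforms: Sequence[str], samples: Sequence[str]) -> float:
        return float(
            np.mean(
                [sum(expression[s].get(i, 0.0) for i in isoforms) for s in samples]
            )
        )

    scored = []
    for cand in candidates:
        event_id = cand if isinstance(cand, str) else cand.event_id
        inclusion, skipping = isoform_map.get(event_id, ((), ()))
        score = 0.0
        if inclusion or skipping:
            for cls in (inclusion, skipping):
                score += abs(
                    class_mean(cls, treatment_ids) - class_mean(cls, control_ids)
                )
        scored.append((event_id, score))
    scored.sort(key=lambda t: t[0])  # stable pre-sort: ties break by event id
    scored.sort(key=lambda t: -t[1])
    return scored


def intersect_comparisons(
    selections: Mapping[str, Mapping[str, str | None]],
) -> tuple[dict[str, str | None], list[str]]:
    """Consensus of selected events across >= 1 comparisons.

    ``selections`` maps comparison id -> {event_id: direction}.  Events
    present in every comparison with a concordant direction are kept;
    events present everywhere but with discordant directions are dropped
    and reported separately.
    """
    comparisons = list(selections.values())
    if not comparisons:
        return {}, []
    common = set(comparisons[0])
    for sel in comparisons[1:]:
        common &= set(sel)
    consensus: dict[str, str | None] = {}
    discordant: list[str] = []
    for event_id in sorted(common):
        directions = {sel[event_id] for sel in comparisons}
        if len(directions) == 1:
            consensus[event_id] = directions.pop()
        else:
            discordant.append(event_id)
    return consensus, discordant


@dataclass(slots=True)
class DetectionResult:
    """Full output of one treatment-vs-control detection run."""

    events: list[ASEvent]
    table: pd.DataFrame  # one row per scored event
    fits: dict[str, PowerLawFit]  # per (pseudo-)treatment sample + consensus
    skipped: list[str] = field(default_factory=list)  # events with missing SR

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def directions(self) -> dict[str, str | None]:
        sel = self.selected
        return dict(zip(sel["event_id"], sel["direction"]))


def detect(
    junction_counts: Mapping[str, Mapping[JunctionKey, int]],
    treatment_ids: Sequence[str],
    control_ids: Sequence[str],
    annotation: Sequence[ExonAnnotation] | None = None,
    q: float = 5.0,
    selection: str = "fdr",
    fdr_target: float = 0.20,
    min_tail: int = 10,
    average: bool = False,
    max_relabelings: int = 60,
    comparison_id: str = "treatment_vs_control",
) -> DetectionResult:
    """Run the full detection stage on per-sample junction counts.

    Steps: group junctions by shared splice site; build and type events;
    compute 5'/3' SRs per sample; score each event per treatment sample
    with srd; fit a power-law tail per comparison; assign significances
    from the consensus tail model; select by median significance against
    the relabeled-sample background; attach EX/IN (or up/down) directions.

    The ``srd_*`` columns report the formula selected by ``average``
    (default: the summed-numerator form).  Significances are always
    computed on the mean-difference scale so comparisons with different
    control counts stay commensurable.
    """
    if len(control_ids) < 3:
        raise ValueError("need >= 3 control samples for the relabeled background")
    all_keys: set[JunctionKey] = set()
    for counts in junction_counts.values():
        all_keys.update(counts)
    groups = group_junctions_by_site(sorted(all_keys))
    multi = [g for g in groups if len(g.members) >= 2]
    events = build_events(multi, annotation)

    sr: dict[tuple[JunctionKey, Site], dict[str, float | None]] = {}
    for group in multi:
        for sample_id, counts in junction_counts.items():
            for ratio in compute_sr(group, counts, sample_id):
                sr.setdefault((ratio.junction, ratio.site), {})[sample_id] = ratio.value

    samples = list(treatment_ids) + list(control_ids)
    event_ids = [e.event_id for e in events]
    n_ev, n_s = len(events), len(samples)
    incl = np.full((n_ev, n_s), np.nan)
    skip = np.full((n_ev, n_s), np.nan)
    for i, ev in enumerate(events):
        series_in = sr.get((ev.inclusion_junction, ev.site), {})
        series_sk = sr.get((ev.skipping_junction, ev.site), {})
        for j, smp in enumerate(samples):
            v = series_in.get(smp)
            if v is not None:
                incl[i, j] = v
            v = series_sk.get(smp)
            if v is not None:
                skip[i, j] = v

    def split_srd(t_col: int, c_cols: Sequence[int], summed: bool = False) -> np.ndarray:
        """Vectorized per-event srd for one (pseudo-)treatment sample."""
        n_c = len(c_cols)
        out = np.full(n_ev, np.nan)
        for mat in (incl, skip):
            diff = mat[:, t_col] - mat[:, list(c_cols)].mean(axis=1)
            if summed:
                diff = diff * n_c
            sd = mat[:, list(c_cols)].std(axis=1, ddof=1)
            scores = (1.0 + diff) / (1.0 + sd / n_c)
            out = np.fmax(out, scores)  # max over the two junctions
        both = ~(np.isnan(incl[:, t_col]) | np.isnan(skip[:, t_col]))
        out[~both] = np.nan
        return out

    k = len(treatment_ids)
    observed = tuple(range(k))
    splits = [observed] + [
        c for c in combinations(range(n_s), k) if set(c) != set(observed)
    ][: max_relabelings]

    split_scores: dict[tuple[int, ...], list[np.ndarray]] = {}
    fits: dict[str, PowerLawFit] = {}
    all_fits: list[PowerLawFit] = []
    for sp in splits:
        c_cols = [j for j in range(n_s) if j not in sp]
        cols = [split_srd(t, c_cols) for t in sp]
        split_scores[sp] = cols
        for t, scores in zip(sp, cols):
            fit = fit_power_law(scores[np.isfinite(scores)], min_tail=min_tail)
            all_fits.append(fit)
            if sp == observed:
                fits[samples[t]] = fit
    consensus = PowerLawFit(
        alpha=float(np.median([f.alpha for f in all_fits])),
        xmin=float(np.median([f.xmin for f in all_fits])),
        ks_distance=float(np.median([f.ks_distance for f in all_fits])),
        n_tail=int(np.median([f.n_tail for f in all_fits])),
    )
    fits["consensus"] = consensus

    def split_median(sp: tuple[int, ...]) -> np.ndarray:
        p = np.column_stack(
            [significance(scores, consensus) for scores in split_scores[sp]]
        )
        with np.errstate(invalid="ignore"):
            return np.exp(np.median(np.log(p), axis=1))

    med_t = split_median(observed)
    background_pool = np.concatenate([split_median(sp) for sp in splits[1:]])
    background_pool = background_pool[np.isfinite(background_pool)]
    background_median = np.exp(
        np.nanmedian(
            np.log(np.column_stack([split_median(sp) for sp in splits[1:]])), axis=1
        )
    )

    complete = np.isfinite(med_t)
    skipped = [eid for eid, ok in zip(event_ids, complete) if not ok]

    n_scored = int(complete.sum())
    if selection == "percentile":
        threshold = float(np.percentile(background_pool, q))
    elif selection == "fdr":
        threshold = math.nan
        for t in np.unique(med_t[complete])[::-1]:
            n_sel = int(np.sum(med_t[complete] <= t))
            null_expect = float(np.mean(background_pool <= t)) * n_scored
            if n_sel and null_expect / n_sel <= fdr_target:
                threshold = float(t)
                break
    else:
        raise ValueError(f"unknown selection mode {selection!r}")

    # reported srd: the as-stated formula unless the average variant is asked
    t_controls = list(range(k, n_s))
    report = {
        samples[t]: split_srd(t, t_controls, summed=not average) for t in observed
    }
    obs_p = {
        samples[t]: significance(split_scores[observed][i], consensus)
        for i, t in enumerate(observed)
    }

    rows = []
    for i, ev in enumerate(events):
        if not complete[i]:
            continue
        series = sr[(ev.inclusion_junction, ev.site)]
        mean_t = float(np.nanmean([series.get(s, np.nan) for s in treatment_ids]))
        mean_c = float(np.nanmean([series.get(s, np.nan) for s in control_ids]))
        direction = classify_direction(ev, mean_t - mean_c, comparison_id).direction
        row = {
            "event_id": ev.event_id,
            "event_type": ev.event_type,
            "gene_id": ev.gene_id,
            "direction": direction,
            "delta_sr": mean_t - mean_c,
        }
        for smp in treatment_ids:
            row[f"srd_{smp}"] = float(report[smp][i])
            row[f"p_{smp}"] = float(obs_p[smp][i])
        row["median_significance"] = float(med_t[i])
        row["background_median"] = float(background_median[i])
        row["threshold"] = threshold
        row["selected"] = bool(med_t[i] <= threshold) if not math.isnan(threshold) else False
        rows.append(row)
    table = (
        pd.DataFrame(rows).sort_values("event_id", kind="mergesort").reset_index(drop=True)
    )
    return DetectionResult(events=events, table=table, fits=fits, skipped=skipped)
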