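"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the data the detection pipeline consumes in a real
experiment: STAR-style junction counts over genes carrying cassette-exon
(CA), alternative 3'/5' splice-site (A3SS/A5SS) and mutually-exclusive-exon
(MXE) structures at controlled inclusion levels (PSI); matched RSEM-style
isoform abundances; tumor cohorts with per-sample event occurrence, a
binary group label and exponential survival; and duplicate-spot microarray
tables.

Counts are negative-binomial (overdispersed, like bulk RNA-seq); baseline
PSI is Beta(2, 2) (symmetric, bounded away from 0/1); planted events shift
PSI by a configured amount in the treatment samples, signed away from the
nearer PSI boundary and clipped to (0.01, 0.99).  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import JunctionKey, pair_event_id
from .io import (
    ExonAnnotation,
    JunctionRecord,
    write_gtf_exons,
    write_run_config,
    write_star_junctions,
)

__all__ = [
    "SimulationConfig",
    "PlantedGene",
    "GroundTruth",
    "SimulatedCounts",
    "simulate_gene_models",
    "simulate_junction_counts",
    "simulate_isoform_expression",
    "simulate_cohort",
    "simulate_spot_table",
    "simulate_all",
]

#: Gene window size in transcript coordinates.
_W = 9000

# Per-type gene templates in transcript (5'->3') coordinates, 1-based
# inclusive within the gene window.  Each defines the inclusion/skipping
# transcript exon chains and the event-defining intron pair(s).
_TEMPLATES: dict[str, dict] = {
    "CA": {
        "incl_exons": [(1000, 1200), (2000, 2100), (3000, 3200)],
        "skip_exons": [(1000, 1200), (3000, 3200)],
        "inclusion_intron": (1201, 1999),
        "skipping_intron": (1201, 2999),
        "extra_pairs": [],
    },
    "A3SS": {
        "incl_exons": [(1000, 1200), (2000, 2200)],
        "skip_exons": [(1000, 1200), (2030, 2200)],
        "inclusion_intron": (1201, 1999),
        "skipping_intron": (1201, 2029),
        "extra_pairs": [],
    },
    "A5SS": {
        "incl_exons": [(1000, 1200), (2000, 2200)],
        "skip_exons": [(1000, 1100), (2000, 2200)],
        "inclusion_intron": (1201, 1999),
        "skipping_intron": (1101, 1999),
        "extra_pairs": [],
    },
    "MXE": {
        "incl_exons": [(1000, 1200), (2000, 2100), (4000, 4200)],
        "skip_exons": [(1000, 1200), (3000, 3100), (4000, 4200)],
        "inclusion_intron": (1201, 1999),
        "skipping_intron": (1201, 2999),
        # second reciprocal pair: middle-exon -> downstream-exon introns
        "extra_pairs": [((2101, 3999), (3101, 3999))],
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    # gene models / junction counts
    events_per_type: dict[str, int] = field(default_factory=lambda: {"CA": 1000})
    n_treatment: int = 2
    n_control: int = 3
    psi_beta: tuple[float, float] = (2.0, 2.0)
    n_planted: int = 50
    delta_psi: float = 0.3
    depth: float = 100.0
    dispersion: float = 0.05
    # isoform expression
    gene_level: float = 100.0
    isoform_noise_sigma: float = 0.1
    # cohort
    cohort_size: int = 200
    n_ases: int = 20
    ase_frequency: float = 0.2
    n_assoc_planted: int = 3
    odds_ratio: float = 4.0
    n_hr_planted: int = 3
    hazard_ratio: float = 2.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.05
    # microarray
    n_proteins: int = 500
    n_binders: int = 20
    # randomness
    seed: int = 17

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_treatment", "n_control", "depth", "cohort_size", "n_ases",
                     "n_proteins", "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PlantedGene:
    """One simulated gene and the splicing event its geometry realizes."""

    gene_id: str
    event_type: str
    chrom: str
    strand: str
    event_id: str
    inclusion_key: JunctionKey
    skipping_key: JunctionKey
    extra_pairs: tuple[tuple[JunctionKey, JunctionKey], ...]
    inclusion_isoform: str
    skipping_isoform: str
    exons: tuple[ExonAnnotation, ...]


@dataclass
class GroundTruth:
    """Planted effects: which events are differential and how."""

    differential: dict[str, dict]  # event_id -> {delta_psi, direction}
    cohort_assoc: list[str] = field(default_factory=list)
    cohort_hr: list[str] = field(default_factory=list)
    binders: list[str] = field(default_factory=list)


@dataclass
class SimulatedCounts:
    """Per-sample junction counts plus planted truth and the PSI draw."""

    counts: dict[str, dict[JunctionKey, int]]
    truth: GroundTruth
    psi: pd.DataFrame  # events x samples
    treatment_ids: list[str]
    control_ids: list[str]


def _map_interval(s: int, e: int, offset: int, strand: str) -> tuple[int, int]:
    """Transcript-coordinate interval to genomic, mirroring minus-strand genes."""
    if strand == "+":
        return offset + s, offset + e
    return offset + _W + 1 - e, offset + _W + 1 - s


def simulate_gene_models(
    config: SimulationConfig,
) -> tuple[list[ExonAnnotation], list[PlantedGene]]:
    """Lay out one gene per requested event on a synthetic chromosome.

    Genes alternate strands; minus-strand genes mirror the transcript
    geometry so the transcriptional 5'/3' roles are preserved.  Geometry is
    deterministic (no random draws): each type is realized exactly as the
    event classifier defines it.
    """
    annotations: list[ExonAnnotation] = []
    planted: list[PlantedGene] = []
    chrom = "chrSim"
    index = 0
    for event_type in sorted(config.events_per_type):
        n = config.events_per_type[event_type]
        tpl = _TEMPLATES[event_type]
        for _ in range(n):
            offset = index * (_W + 1000)
            strand = "+" if index % 2 == 0 else "-"
            gene_id = f"g{index:05d}_{event_type}"
            exons = []
            for iso, chain in (("incl", tpl["incl_exons"]), ("skip", tpl["skip_exons"])):
                for s, e in chain:
                    gs, ge = _map_interval(s, e, offset, strand)
                    exons.append(
                        ExonAnnotation(gene_id, f"{gene_id}_{iso}", chrom, gs, ge, strand)
                    )

            def jkey(intron: tuple[int, int]) -> JunctionKey:
                gs, ge = _map_interval(intron[0], intron[1], offset, strand)
                return (chrom, gs, ge, strand)

            incl_key = jkey(tpl["inclusion_intron"])
            skip_key = jkey(tpl["skipping_intron"])
            extra = tuple(
                (jkey(a), jkey(b)) for a, b in tpl["extra_pairs"]
            )
            event_id = pair_event_id(incl_key, skip_key)
            if event_type == "MXE":
                pair2 = pair_event_id(*extra[0])
                event_id = "MXE|" + "|".join(sorted((event_id, pair2)))
            planted.append(
                PlantedGene(
                    gene_id=gene_id,
                    event_type=event_type,
                    chrom=chrom,
                    strand=strand,
                    event_id=event_id,
                    inclusion_key=incl_key,
                    skipping_key=skip_key,
                    extra_pairs=extra,
                    inclusion_isoform=f"{gene_id}_incl",
                    skipping_isoform=f"{gene_id}_skip",
                    exons=tuple(exons),
                )
            )
            annotations.extend(exons)
            index += 1
    annotations.sort(key=lambda a: (a.chrom, a.exon_start, a.exon_end, a.transcript_id))
    return annotations, planted


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial count with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_junction_counts(
    planted: list[PlantedGene],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedCounts:
    """Draw per-sample junction read counts with planted differential events.

    Baseline PSI per event is Beta(a, b); the first ``n_planted`` randomly
    chosen events get a treatment PSI shift of ``delta_psi``, signed away
    from the nearer boundary and clipped to (0.01, 0.99) with a warning.
    Inclusion-junction counts are NB(depth * PSI, dispersion), skipping
    counts NB(depth * (1 - PSI)); MXE genes draw their reciprocal pair the
    same way.  If ``out_dir`` is given, one SJ.out.tab file is written per
    sample.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_events = len(planted)
    if not 0 <= config.n_planted <= n_events:
        raise ValueError("n_planted out of range")
    treatment_ids = [f"treat_{i + 1}" for i in range(config.n_treatment)]
    control_ids = [f"ctrl_{i + 1}" for i in range(config.n_control)]
    samples = treatment_ids + control_ids

    baseline = np.clip(
        rng.beta(*config.psi_beta, size=n_events), 0.01, 0.99
    )
    planted_idx = set(
        rng.choice(n_events, size=config.n_planted, replace=False).tolist()
    )

    truth = GroundTruth(differential={})
    psi = np.tile(baseline[:, None], (1, len(samples)))
    n_clipped = 0
    for i in planted_idx:
        sign = 1.0 if baseline[i] < 0.5 else -1.0
        shifted = baseline[i] + sign * config.delta_psi
        clipped = float(np.clip(shifted, 0.01, 0.99))
        if clipped != shifted:
            n_clipped += 1
        psi[i, : config.n_treatment] = clipped
        gene = planted[i]
        if gene.event_type == "CA":
            direction = "IN" if sign > 0 else "EX"
        else:
            direction = "up" if sign > 0 else "down"
        truth.differential[gene.event_id] = {
            "delta_psi": sign * config.delta_psi,
            "direction": direction,
            "gene_id": gene.gene_id,
        }
    if n_clipped:
        warnings.warn(f"{n_clipped} planted PSI values clipped to (0.01, 0.99)")

    counts: dict[str, dict[JunctionKey, int]] = {s: {} for s in samples}
    for i, gene in enumerate(planted):
        pairs = [(gene.inclusion_key, gene.skipping_key), *gene.extra_pairs]
        for s_idx, sample in enumerate(samples):
            p = psi[i, s_idx]
            for incl_key, skip_key in pairs:
                counts[sample][incl_key] = _nb_draw(rng, config.depth * p, config.dispersion)
                counts[sample][skip_key] = _nb_draw(
                    rng, config.depth * (1.0 - p), config.dispersion
                )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample in samples:
            records = [
                JunctionRecord(k[0], k[1], k[2], k[3], c, sample)
                for k, c in counts[sample].items()
            ]
            write_star_junctions(records, out_dir / f"{sample}.SJ.out.tab")

    psi_df = pd.DataFrame(psi, index=[g.event_id for g in planted], columns=samples)
    return SimulatedCounts(
        counts=counts,
        truth=truth,
        psi=psi_df,
        treatment_ids=treatment_ids,
        control_ids=control_ids,
    )


def simulate_isoform_expression(
    planted: list[PlantedGene],
    sim: SimulatedCounts,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, dict[str, float]]:
    """Isoform abundances consistent with the PSI draw.

    Inclusion isoform ~ gene level x PSI, skipping isoform ~ gene level x
    (1 - PSI), each with multiplicative lognormal noise.  Returns
    sample -> isoform -> expression; optionally writes one RSEM-style TSV
    per sample.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    sigma = config.isoform_noise_sigma
    expression: dict[str, dict[str, float]] = {}
    for sample in sim.psi.columns:
        table: dict[str, float] = {}
        for gene in planted:
            p = float(sim.psi.loc[gene.event_id, sample])
            level = config.gene_level * float(rng.lognormal(0.0, sigma))
            table[gene.inclusion_isoform] = level * p * float(rng.lognormal(0.0, sigma))
            table[gene.skipping_isoform] = (
                level * (1.0 - p) * float(rng.lognormal(0.0, sigma))
            )
        expression[sample] = table
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gene_of = {}
        for g in planted:
            gene_of[g.inclusion_isoform] = g.gene_id
            gene_of[g.skipping_isoform] = g.gene_id
        for sample, table in expression.items():
            df = pd.DataFrame(
                {
                    "transcript_id": list(table),
                    "gene_id": [gene_of[i] for i in table],
                    "TPM": list(table.values()),
                }
            ).sort_values("transcript_id", kind="mergesort")
            df.to_csv(out_dir / f"{sample}.isoforms.tsv", sep="\t", index=False)
    return expression


def simulate_cohort(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """A tumor cohort with planted group-association and survival effects.

    Occurrence of each ASE is Bernoulli at the baseline frequency; for the
    planted associated ASEs the occurrence odds are multiplied by the
    planted odds ratio in the group = 1 stratum.  Survival is exponential
    with the baseline hazard multiplied by the planted hazard ratio for
    each occurring hazard-planted ASE; censoring is independent
    exponential.  Association- and hazard-planted ASE sets are disjoint so
    the two effects are not confounded.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    if config.n_assoc_planted + config.n_hr_planted > config.n_ases:
        raise ValueError("more planted ASEs than ASEs")
    ase_ids = [f"ASE_{i + 1:03d}" for i in range(config.n_ases)]
    assoc_ids = ase_ids[: config.n_assoc_planted]
    hr_ids = ase_ids[config.n_assoc_planted : config.n_assoc_planted + config.n_hr_planted]

    n = config.cohort_size
    group = rng.integers(0, 2, size=n)
    f = config.ase_frequency
    f_assoc = f * config.odds_ratio / (1.0 - f + f * config.odds_ratio)
    occurrence = np.empty((n, config.n_ases), dtype=int)
    for j, ase in enumerate(ase_ids):
        p = np.full(n, f)
        if ase in assoc_ids:
            p = np.where(group == 1, f_assoc, f)
        occurrence[:, j] = rng.random(n) < p

    hr_cols = [ase_ids.index(a) for a in hr_ids]
    hazard = config.baseline_hazard * config.hazard_ratio ** occurrence[:, hr_cols].sum(axis=1)
    death = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)

    df = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1:04d}" for i in range(n)],
            "group": group,
            "time": time,
            "event": event,
        }
    )
    for j, ase in enumerate(ase_ids):
        df[ase] = occurrence[:, j]
    truth = GroundTruth(differential={}, cohort_assoc=assoc_ids, cohort_hr=hr_ids)
    return df, truth


def simulate_spot_table(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Duplicate-spot microarray table with planted binders.

    Null proteins fluoresce near background (per-spot SNR around 0-1, fold
    near 1); binders get a strong consistent signal (SNR and fold well past
    the 3/5 cutoffs, duplicate CV well under 0.15).
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    protein_ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    binder_ids = sorted(
        rng.choice(protein_ids, size=config.n_binders, replace=False).tolist()
    )
    binders = set(binder_ids)
    rows = []
    for pid in protein_ids:
        is_binder = pid in binders
        base_signal = None
        if is_binder:
            base_signal = float(rng.uniform(8.0, 20.0))  # in background-sd units
            fold_target = float(rng.uniform(8.0, 15.0))
        for rep in (1, 2):
            b_mean = float(rng.uniform(80.0, 120.0))
            b_sd = float(rng.uniform(15.0, 25.0))
            b_med = b_mean * float(rng.uniform(0.95, 1.05))
            if is_binder:
                jitter = 1.0 + float(rng.normal(0.0, 0.02))
                f_mean = b_mean + base_signal * 20.0 * jitter  # fixed sd unit: CV stable
                f_med = b_med * fold_target * jitter
            else:
                f_mean = max(0.0, b_mean + b_sd * float(rng.normal(0.3, 0.7)))
                f_med = b_med * float(rng.uniform(0.8, 1.5))
            rows.append(
                {
                    "protein_id": pid,
                    "replicate_index": rep,
                    "F635_mean": round(f_mean, 3),
                    "F635_median": round(f_med, 3),
                    "B635_mean": round(b_mean, 3),
                    "B635_median": round(b_med, 3),
                    "B635_sd": round(b_sd, 3),
                }
            )
    df = pd.DataFrame(rows)
    truth = GroundTruth(differential={}, binders=binder_ids)
    return df, truth


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Emit a complete synthetic input directory for the whole pipeline.

    Writes annotation.gtf, one SJ.out.tab and one isoform TSV per sample,
    cohort.tsv, spots.tsv, truth.json and a config echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations, planted = simulate_gene_models(config)
    write_gtf_exons(annotations, out_dir / "annotation.gtf")
    sim = simulate_junction_counts(
        planted, config, np.random.default_rng(config.seed), out_dir=out_dir
    )
    simulate_isoform_expression(
        planted, sim, config, np.random.default_rng(config.seed + 1), out_dir=out_dir
    )
    cohort, cohort_truth = simulate_cohort(config, np.random.default_rng(config.seed + 2))
    cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    spots, spot_truth = simulate_spot_table(config, np.random.default_rng(config.seed + 3))
    spots.to_csv(out_dir / "spots.tsv", sep="\t", index=False)
    truth = GroundTruth(
        differential=sim.truth.differential,
        cohort_assoc=cohort_truth.cohort_assoc,
        cohort_hr=cohort_truth.cohort_hr,
        binders=spot_truth.binders,
    )
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
        fh.write("\n")
    write_run_config(dataclasses.asdict(config), out_dir / "config.json")
    return truth
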