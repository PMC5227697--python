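"""End-to-end orchestration: simulate -> QC -> taxonomy -> decontam -> stats.

The pipeline is deterministic under a fixed seed, conserves read tallies at
every stage, and mirrors the run-level accounting of an amplicon survey
(assigned / not assigned / discarded singleton read totals with percentages).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import decontam as dc
from . import qc as qcmod
from . import simulate as sim
from . import stats as st
from . import taxonomy as tax
from .primers import DEFAULT_PRIMER_PAIRS


def round_half_up(value: float, digits: int = 1) -> float:
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible synthetic run."""

    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    qc: qcmod.QcConfig = field(default_factory=qcmod.QcConfig)
    search: tax.SearchConfig = field(default_factory=tax.SearchConfig)
    min_unique_count: int = 2
    decontam_mode: str = "derive"  # derive | fixed
    fixed_cutoff_fraction: float | None = None
    n_perm: int = 999
    n_distance_classes: int | None = None
    chao1_bias_corrected: bool = True

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Table1Row:
    label: str
    reads: int
    reads_percent: float | None
    uniques: int
    uniques_percent: float | None


def summarize_table1(
    assigned_reads: int,
    unassigned_reads: int,
    singleton_reads: int,
    assigned_uniques: int,
    unassigned_uniques: int,
    singleton_uniques: int,
) -> list[Table1Row]:
    """Four-row run summary with half-up percentages to one decimal.

    Percentages are taken against the quality-passed totals (the bottom row).
    """
    total_reads = assigned_reads + unassigned_reads + singleton_reads
    total_uniques = assigned_uniques + unassigned_uniques + singleton_uniques
    rows = []
    for label, reads, uniques in [
        ("assigned_to_species", assigned_reads, assigned_uniques),
        ("not_assigned", unassigned_reads, unassigned_uniques),
        ("discarded_singleton", singleton_reads, singleton_uniques),
    ]:
        rp = round_half_up(100.0 * reads / total_reads) if total_reads else None
        up = round_half_up(100.0 * uniques / total_uniques) if total_uniques else None
        rows.append(Table1Row(label, reads, rp, uniques, up))
    rows.append(Table1Row("total", total_reads, None, total_uniques, None))
    return rows


@dataclass
class RunReport:
    """Per-stage tallies and the run-level accounting."""

    qc_counts: dict[str, qcmod.StageCounts]
    table1: list[Table1Row]
    n_otus_initial: int
    n_otus_final: int
    cutoff: dc.CutoffDerivation | None
    stage_seconds: dict[str, float]

    def conservation_ok(self) -> bool:
        stages_ok = all(t.conserved() for t in self.qc_counts.values())
        total = self.table1[-1]
        reads_ok = total.reads == sum(r.reads for r in self.table1[:-1])
        return stages_ok and reads_ok

    def to_dict(self) -> dict:
        return {
            "qc_counts": {
                sid: [list(c) for c in tally.counts] for sid, tally in self.qc_counts.items()
            },
            "table1": [dataclasses.asdict(r) for r in self.table1],
            "n_otus_initial": self.n_otus_initial,
            "n_otus_final": self.n_otus_final,
            "cutoff": dataclasses.asdict(self.cutoff) if self.cutoff else None,
            "stage_seconds": self.stage_seconds,
            "conservation_ok": self.conservation_ok(),
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: list[sim.ReferenceRecord]
    communities: sim.CommunitySimulation
    sheet: pd.DataFrame
    truth: sim.GroundTruth
    uniques: list[tax.UniqueSequence]
    otus: list[tax.OTU]
    detection: dc.DetectionMatrix
    report: RunReport
    stats: dict


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study through every analysis stage."""
    timing: dict[str, float] = {}
    t0 = time.perf_counter()

    records = sim.generate_reference_db(config.sim)
    communities = sim.simulate_communities(config.sim, records)
    sheet = sim.build_sample_sheet(config.sim, communities.stations)
    timing["simulate_setup"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sample_inserts: dict[str, list[str]] = {}
    qc_counts: dict[str, qcmod.StageCounts] = {}
    samples = []
    for sample in sim.iter_sample_reads(config.sim, communities, records, sheet):
        samples.append(sample)
        pairs = qcmod.sample_reads_to_pairs(sample)
        inserts, tally, _ = qcmod.run_sample_qc(
            sample.sample_id, pairs, DEFAULT_PRIMER_PAIRS, config.qc
        )
        sample_inserts[sample.sample_id] = inserts
        qc_counts[sample.sample_id] = tally
    truth = sim.collect_ground_truth(communities, samples)
    timing["simulate_and_qc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    uniques, derep = tax.dereplicate(sample_inserts, config.min_unique_count)
    index = tax.ReferenceIndex(records, config.search)
    assigned: list[tuple[tax.UniqueSequence, tax.Assignment]] = []
    unassigned_reads = unassigned_uniques = 0
    for u in uniques:
        a = tax.classify_confidence(index.search(u.seq), config.search)
        if a.assigned:
            assigned.append((u, a))
        else:
            unassigned_reads += u.total_count
            unassigned_uniques += 1
    reference_by_species = {r.species: r for r in records if r.in_reference}
    otus = tax.cluster_otus(assigned, reference_by_species)
    checklist_rows = _checklist_from_records(records)
    otus = tax.curate(otus, checklist_rows)
    timing["taxonomy"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    negative_ids = set(sheet.loc[sheet["is_negative"] == 1, "sample_id"])
    reads_in_negatives = sum(
        sum(u.counts.get(sid, 0) for sid in negative_ids) for u in uniques
    )
    otus_clean, _removed = dc.filter_otus_against_negatives(otus, negative_ids)
    if config.decontam_mode == "fixed":
        if config.fixed_cutoff_fraction is None:
            raise ValueError("fixed decontam mode needs fixed_cutoff_fraction")
        cutoff = None
        fraction = config.fixed_cutoff_fraction
    else:
        cutoff = dc.derive_cutoff(
            reads_in_negatives,
            len(negative_ids),
            len(sheet),
            derep.clustered_reads,
        )
        fraction = cutoff.cutoff_fraction
    detection = dc.apply_cutoff(tax.otu_table(otus_clean), fraction, sheet)
    timing["decontam"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    assigned_reads = sum(u.total_count for u, _ in assigned)
    table1 = summarize_table1(
        assigned_reads,
        unassigned_reads,
        derep.singleton_reads,
        len(assigned),
        unassigned_uniques,
        derep.n_singletons,
    )
    stats_out = compute_run_stats(config, detection, records, communities.stations)
    timing["stats"] = time.perf_counter() - t0

    report = RunReport(qc_counts, table1, len(otus), len(otus_clean), cutoff, timing)
    result = PipelineResult(
        config, records, communities, sheet, truth, uniques, otus_clean, detection, report, stats_out
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _checklist_from_records(records: Sequence[sim.ReferenceRecord]) -> tax.Checklist:
    ghost = next((r for r in records if r.role == "ghost"), None)
    subs = {}
    for r in records:
        if r.role == "offrange" and ghost is not None:
            subs[r.species] = ghost.species
    return tax.Checklist(
        local_species=[r.species for r in records if r.local],
        genus_of={r.species: r.genus for r in records},
        substitutions=subs,
    )


def compute_run_stats(
    config: PipelineConfig,
    detection: dc.DetectionMatrix,
    records: Sequence[sim.ReferenceRecord],
    stations: pd.DataFrame | None = None,
) -> dict:
    """Community statistics of one detection matrix."""
    out: dict = {}
    out["partition"] = st.partition_by_layer(detection)
    out["replicate_accumulation"] = {
        layer: st.replicate_accumulation(detection, layer) for layer in sim.LAYERS
    }
    out["richness"] = st.richness_table(detection, config.chao1_bias_corrected)
    out["chao1_mean"] = {
        layer: st.mean_chao1(detection, layer, config.chao1_bias_corrected)
        for layer in sim.LAYERS
    }
    habitat_of = {r.species: r.habitat for r in records}
    habitat_of.update({f"{r.genus} sp.": r.habitat for r in records})
    fishery = {r.species for r in records if r.fishery}
    out["station_groups"] = st.station_group_counts(detection, habitat_of, fishery)

    if stations is not None:
        abundance = st.detection_abundance(detection)
        meta = stations.set_index("station_id").loc[abundance.index]
        nonzero = abundance.sum(axis=1) > 0
        if nonzero.sum() >= 4:
            out["correlogram"] = st.mantel_correlogram(
                abundance[nonzero],
                meta.loc[nonzero.values, ["x_m", "y_m"]].to_numpy(),
                n_classes=config.n_distance_classes,
                n_perm=config.n_perm,
                seed=config.seed,
            )
    return out


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    """Run-directory layout: config snapshot, qc/, otu/, detection/, stats/,
    report.json — one directory per stage for auditability."""
    outdir = Path(outdir)
    for sub in ("qc", "otu", "detection", "stats"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.snapshot.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=1, default=str)
    result.sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    sim.write_reference_fasta(result.records, outdir / "reference.fasta")

    qc_rows = [
        {"sample_id": sid, "stage": stage, "reads_in": n_in, "reads_out": n_out}
        for sid, tally in result.report.qc_counts.items()
        for stage, n_in, n_out in tally.counts
    ]
    pd.DataFrame(qc_rows).to_csv(outdir / "qc" / "stage_counts.tsv", sep="\t", index=False)

    tax.otu_table(result.otus).to_csv(outdir / "otu" / "otu_table.tsv", sep="\t", index=False)
    result.detection.to_tsv(outdir / "detection" / "detection_matrix.tsv")
    if result.report.cutoff is not None:
        with open(outdir / "detection" / "cutoff_derivation.json", "w") as fh:
            json.dump(dataclasses.asdict(result.report.cutoff), fh, indent=1)

    stats = result.stats
    with open(outdir / "stats" / "partition.json", "w") as fh:
        json.dump(dataclasses.asdict(stats["partition"]), fh, indent=1)
    if "correlogram" in stats:
        stats["correlogram"].to_frame().to_csv(
            outdir / "stats" / "correlogram.tsv", sep="\t", index=False
        )
    stats["richness"].to_csv(outdir / "stats" / "richness.tsv", sep="\t", index=False)
    for layer, frame in stats["replicate_accumulation"].items():
        frame.to_csv(
            outdir / "stats" / f"replicate_accumulation_{layer}.tsv", sep="\t", index=False
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=1)


# --------------------------------------------------------------------------
# ground-truth evaluation
# --------------------------------------------------------------------------
@dataclass
class RecoveryEvaluation:
    """Pipeline output checked against simulator ground truth."""

    n_expected: int
    n_recovered: int
    missing: list[str]
    contaminant_detections: int
    congener_reported_genus_low: bool

    @property
    def recovery_percent(self) -> float:
        if self.n_expected == 0:
            return float("nan")
        return round(100.0 * self.n_recovered / self.n_expected, 1)


def evaluate_recovery(result: PipelineResult, min_clean_reads: int = 10) -> RecoveryEvaluation:
    """Compare the final detection matrix with the simulated ground truth.

    A ground-truth species enters the denominator when it has at least
    ``min_clean_reads`` non-chimeric community reads in some PCR sample; it
    counts as recovered when its expected reported taxon (genus rank for the
    indistinguishable congeneric pair, the checklist substitute for the
    unbarcoded local species) appears anywhere in the detection matrix.
    """
    expected_name = sim.expected_taxon(result.records)
    clean = result.truth.clean_reads
    eligible = {
        sp for sp in clean.columns if clean[sp].max() >= min_clean_reads and sp in expected_name
    }
    expected_taxa = {expected_name[sp] for sp in eligible}
    detected_taxa = result.detection.all_species()
    missing = sorted(expected_taxa - detected_taxa)

    contaminant = next(r for r in result.records if r.role == "contaminant")
    contaminant_hits = int(
        (result.detection.detected()["taxon"] == contaminant.species).sum()
    )

    congener_genus = next(r.genus for r in result.records if r.role == "congener_a")
    genus_taxon = f"{congener_genus} sp."
    congener_otus = [o for o in result.otus if o.taxon == genus_taxon]
    congener_ok = any(
        o.rank == "genus" and o.confidence == tax.LOW for o in congener_otus
    )
    return RecoveryEvaluation(
        n_expected=len(expected_taxa),
        n_recovered=len(expected_taxa & detected_taxa),
        missing=missing,
        contaminant_detections=contaminant_hits,
        congener_reported_genus_low=congener_ok,
    )
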