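"""Negative-control-based decontamination and the detection matrix.

Two complementary steps: any unique sequence seen in a blank is removed from
every sample, and a per-sample read-fraction cut-off — projected from the
blank read load onto the whole run — declares an OTU absent from a sample
when its reads fall below that fraction of the sample total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .taxonomy import OTU, UniqueSequence


@dataclass
class CutoffDerivation:
    """Projection of the blank read load onto the full run.

    ``projected_contaminant_reads`` is the blank mean scaled to all PCR
    samples (floor-truncated); ``cutoff_fraction`` is that count over the
    clustered read total, rounded to 3 decimals as a fraction and reported as
    a percentage to one decimal.
    """

    reads_in_negatives: int
    n_negatives: int
    n_total_pcr_samples: int
    total_clustered_reads: int
    projected_contaminant_reads: int
    cutoff_fraction: float

    @property
    def cutoff_percent(self) -> float:
        return round(self.cutoff_fraction * 100, 1)


def derive_cutoff(
    reads_in_negatives: int,
    n_negatives: int,
    n_total_pcr_samples: int,
    total_clustered_reads: int,
) -> CutoffDerivation:
    """Derive the per-sample read-fraction cut-off from the blank read load."""
    if n_negatives <= 0:
        raise ValueError("cannot derive a cut-off without negative controls")
    if total_clustered_reads <= 0:
        raise ValueError("total_clustered_reads must be positive")
    projected = (reads_in_negatives * n_total_pcr_samples) // n_negatives
    fraction = round(projected / total_clustered_reads, 3)
    return CutoffDerivation(
        reads_in_negatives,
        n_negatives,
        n_total_pcr_samples,
        total_clustered_reads,
        int(projected),
        fraction,
    )


def remove_negative_sequences(
    uniques: Sequence[UniqueSequence], negative_sample_ids: Iterable[str]
) -> tuple[list[UniqueSequence], list[UniqueSequence]]:
    """Drop every unique sequence with at least one read in any blank.

    Removal applies run-wide: a single blank read disqualifies the sequence
    in all samples.  Returns (kept, removed).
    """
    negatives = set(negative_sample_ids)
    kept, removed = [], []
    for u in uniques:
        if any(u.counts.get(sid, 0) > 0 for sid in negatives):
            removed.append(u)
        else:
            kept.append(u)
    return kept, removed


def filter_otus_against_negatives(
    otus: Sequence[OTU], negative_sample_ids: Iterable[str]
) -> tuple[list[OTU], int]:
    """Apply blank-sequence removal inside each OTU; drop emptied OTUs.

    Returns the surviving OTUs and the number of reads removed.
    """
    negatives = set(negative_sample_ids)
    survivors: list[OTU] = []
    removed_reads = 0
    for otu in otus:
        kept, removed = remove_negative_sequences(otu.members, negatives)
        removed_reads += sum(u.total_count for u in removed)
        if kept:
            survivors.append(
                OTU(
                    otu.otu_id,
                    otu.taxon,
                    otu.rank,
                    otu.confidence,
                    kept,
                    otu.habitat,
                    otu.fishery,
                    otu.note,
                )
            )
    return survivors, removed_reads


@dataclass
class DetectionMatrix:
    """Station x layer x replicate x taxon read counts with detection calls.

    ``data`` is long-format with columns station, layer, replicate,
    sample_id, taxon, reads, detected.  Raw counts are preserved; the cut-off
    only drives the boolean layer.
    """

    data: pd.DataFrame
    cutoff_fraction: float

    def detected(self) -> pd.DataFrame:
        return self.data[self.data["detected"]]

    def species_by_layer(self, layer: str) -> set[str]:
        d = self.detected()
        return set(d.loc[d["layer"] == layer, "taxon"])

    def all_species(self) -> set[str]:
        return set(self.detected()["taxon"])

    def station_layer_incidence(self, station: str, layer: str) -> pd.DataFrame:
        """taxon x replicate boolean incidence for one water sample."""
        d = self.detected()
        d = d[(d["station"] == station) & (d["layer"] == layer)]
        if d.empty:
            return pd.DataFrame()
        return d.pivot_table(
            index="taxon", columns="replicate", values="detected", aggfunc="any", fill_value=False
        )

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff_fraction: float) -> "DetectionMatrix":
        frame = pd.read_csv(path, sep="\t")
        frame["detected"] = frame["detected"].astype(bool)
        return cls(frame, cutoff_fraction)


def apply_cutoff(
    otu_counts: pd.DataFrame, cutoff_fraction: float, sample_sheet: pd.DataFrame
) -> DetectionMatrix:
    """Apply the per-sample read-fraction cut-off to an OTU count table.

    ``otu_counts`` is long-format with sample_id, taxon, reads.  A taxon is
    detected in a sample iff its reads are at least ``cutoff_fraction`` of
    that sample's total (reads exactly at the boundary count as present) and
    positive.  Blanks are excluded from the matrix.
    """
    meta = sample_sheet.set_index("sample_id")
    counts = otu_counts[otu_counts["reads"] > 0].copy()
    totals = counts.groupby("sample_id")["reads"].sum()
    counts["sample_total"] = counts["sample_id"].map(totals).fillna(0)
    counts["detected"] = (counts["reads"] >= cutoff_fraction * counts["sample_total"]) & (
        counts["reads"] > 0
    )
    counts["station"] = counts["sample_id"].map(meta["station_id"])
    counts["layer"] = counts["sample_id"].map(meta["layer"])
    counts["replicate"] = counts["sample_id"].map(meta["replicate"])
    is_neg = counts["sample_id"].map(meta["is_negative"]).astype(bool)
    counts = counts[~is_neg]
    cols = ["station", "layer", "replicate", "sample_id", "taxon", "reads", "detected"]
    return DetectionMatrix(counts[cols].reset_index(drop=True), cutoff_fraction)
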