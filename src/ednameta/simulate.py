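"""Synthetic study generator: reference database, communities, amplicon reads.

Emulates a grid-sampled coastal eDNA metabarcoding survey: 47 stations, a
surface and a bottom water sample at each, three PCR replicates per sample,
plus equipment/extraction blanks (negative controls).  Every read carries a
known provenance (source species, chimera parents, or contaminant), so the
whole downstream pipeline can be validated against ground truth.

The generator is deliberately structural rather than mechanistic: species
occupy 2-D Gaussian ranges inside a rectangular bay, relative abundances
follow a log-series rank distribution, freshwater species hug a "river mouth"
corner at the surface, sequencing introduces per-base substitution errors
with 3'-declining quality, a fraction of reads are two-parent bimeras, and a
designated terrestrial contaminant leaks into blanks (and, faintly, into real
samples).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .primers import DEFAULT_PRIMER_PAIRS, PRIMER_FLANK_LENGTH, PrimerPair, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SURFACE = "surface"
BOTTOM = "bottom"
LAYERS = (SURFACE, BOTTOM)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Parameters of the simulated survey.

    Lengths are in base pairs, coordinates in metres, rates are probabilities
    in [0, 1].  ``amplicon_window`` is the admissible merged-read length range
    (insert plus both primer flanks); insert lengths are truncated so every
    amplicon falls inside it.
    """

    seed: int = 0
    n_species: int = 40
    n_stations: int = 47
    n_replicates: int = 3
    n_negative_controls: int = 30
    reads_per_sample: int = 1000
    insert_length_mean: float = 170.0
    insert_length_sd: float = 8.0
    substitution_error_rate: float = 0.003
    chimera_rate: float = 0.03
    contaminant_rate: float = 0.0135
    sample_contaminant_rate: float = 0.002
    range_scale: float = 800.0
    bay_extent: tuple[float, float] = (4000.0, 3000.0)
    congeneric_pair_divergence: float = 0.005
    read_length: int = 170
    amplicon_window: tuple[int, int] = (272, 322)
    logseries_x: float = 0.95
    occupancy_threshold: float = 0.05
    quality_mean_start: float = 38.0
    quality_drop_per_base: float = 0.1
    quality_sd: float = 3.0
    u_variant_fraction: float = 0.5
    min_reference_divergence: float = 0.03
    chimera_end_margin: int = 30

    def validate(self) -> None:
        rates = {
            "substitution_error_rate": self.substitution_error_rate,
            "chimera_rate": self.chimera_rate,
            "contaminant_rate": self.contaminant_rate,
            "sample_contaminant_rate": self.sample_contaminant_rate,
            "u_variant_fraction": self.u_variant_fraction,
            "congeneric_pair_divergence": self.congeneric_pair_divergence,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        lo, hi = self.amplicon_window
        if lo > hi:
            raise ValueError("amplicon_window must be (low, high) with low <= high")
        if hi - PRIMER_FLANK_LENGTH < 2 * self.chimera_end_margin:
            raise ValueError("amplicon_window too short for chimera breakpoints")

    @property
    def insert_window(self) -> tuple[int, int]:
        lo, hi = self.amplicon_window
        return lo - PRIMER_FLANK_LENGTH, hi - PRIMER_FLANK_LENGTH


# --------------------------------------------------------------------------
# species pool / reference database
# --------------------------------------------------------------------------
@dataclass
class ReferenceRecord:
    """One species in the simulated regional pool.

    ``in_reference`` marks species whose barcode is in the reference FASTA;
    ``in_community`` marks species that can occur in bay communities.  The two
    are decoupled on purpose: one locally occurring species lacks a reference
    barcode (its reads hit a close off-range congener, exercising curation),
    and the off-range congener plus the blank contaminant never occur in true
    communities.
    """

    accession: str
    family: str
    genus: str
    species: str
    habitat: str  # marine | freshwater | diadromous | terrestrial
    local: bool
    fishery: bool
    sequence: str
    in_reference: bool = True
    in_community: bool = True
    role: str = "ordinary"  # ordinary|congener_a|congener_b|offrange|ghost|contaminant

    def fasta_header(self) -> str:
        return (
            f"{self.accession}|{self.family}|{self.genus}|{self.species}"
            f"|{self.habitat}|local:{int(self.local)}|fishery:{int(self.fishery)}"
        )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.choice(len(arr), size=n_sub, replace=False)
    for pos in positions:
        alternatives = BASES[BASES != arr[pos]]
        arr[pos] = rng.choice(alternatives)
    return arr.tobytes().decode()


def hamming_identity(a: str, b: str) -> float:
    """Fraction of matching bases over the shorter sequence."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    x = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    y = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return float((x == y).mean())


def generate_reference_db(
    config: SimulationConfig, rng: np.random.Generator | None = None, max_retries: int = 25
) -> list[ReferenceRecord]:
    """Generate the regional species pool with its reference barcodes.

    All species pairs diverge by at least ``min_reference_divergence`` except
    the designated congeneric pair (``congeneric_pair_divergence``, rounded to
    at least one substitution) and the ghost/off-range pair (one
    substitution).  Deterministic under a fixed config seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_species
    lo, hi = config.insert_window

    lengths = []
    for _ in range(n):
        for _ in range(1000):
            length = int(round(rng.normal(config.insert_length_mean, config.insert_length_sd)))
            if lo <= length <= hi:
                break
        else:
            raise ValueError("insert length window incompatible with length distribution")
        lengths.append(length)

    for attempt in range(max_retries):
        seqs = [_random_sequence(rng, L) for L in lengths]
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if hamming_identity(seqs[i], seqs[j]) > 1.0 - config.min_reference_divergence:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not satisfy the minimum reference divergence in {max_retries} attempts"
        )

    # Congeneric pair: species 1 is a near-identical sibling of species 0.
    n_sub = max(1, int(round(config.congeneric_pair_divergence * lengths[0])))
    seqs[1] = _mutate(rng, seqs[0], n_sub)
    lengths[1] = lengths[0]

    n_freshwater = max(2, n // 10)
    records: list[ReferenceRecord] = []
    for i in range(n):
        genus_idx = 0 if i in (0, 1) else i
        genus = f"Genus{genus_idx:03d}"
        family = f"Familia{genus_idx // 5:02d}"
        epithet = ["primus", "secundus"][i] if i in (0, 1) else f"species{i:03d}"
        habitat = "marine"
        local = True
        in_community = True
        fishery = bool(rng.random() < 0.3)
        role = "ordinary"
        if i == 0:
            role = "congener_a"
        elif i == 1:
            role = "congener_b"
        elif i == 2:
            # Off-range species: in the reference DB but not local and never
            # in true communities; its locally occurring sibling lacks a
            # barcode and is appended below as the "ghost".
            role, local, in_community = "offrange", False, False
        elif i == 3:
            role, habitat, local, in_community, fishery = (
                "contaminant",
                "terrestrial",
                False,
                False,
                False,
            )
        elif 4 <= i < 4 + n_freshwater:
            habitat, fishery = "freshwater", False
        elif i % 9 == 8:
            habitat = "diadromous"
        records.append(
            ReferenceRecord(
                accession=f"SYN{i:04d}",
                family=family,
                genus=genus,
                species=f"{genus} {epithet}",
                habitat=habitat,
                local=local,
                fishery=fishery,
                sequence=seqs[i],
                in_reference=True,
                in_community=in_community,
                role=role,
            )
        )

    ghost_seq = _mutate(rng, records[2].sequence, 1)
    records.append(
        ReferenceRecord(
            accession=f"SYN{n:04d}",
            family=records[2].family,
            genus=records[2].genus,
            species=f"{records[2].genus} vicinus",
            habitat="marine",
            local=True,
            fishery=records[2].fishery,
            sequence=ghost_seq,
            in_reference=False,
            in_community=True,
            role="ghost",
        )
    )
    return records


def write_reference_fasta(records: Sequence[ReferenceRecord], path: str | Path) -> None:
    """Write the barcoded subset of the pool in the reference header dialect."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.in_reference:
                fh.write(f">{rec.fasta_header()}\n{rec.sequence}\n")


def write_checklist(records: Sequence[ReferenceRecord], path: str | Path) -> None:
    """Write the local-species checklist TSV (with the substitution map).

    Off-range reference species that stand in for an unbarcoded local sibling
    get a ``substitute_for`` entry pointing at that sibling.
    """
    ghost = next((r for r in records if r.role == "ghost"), None)
    rows = []
    for rec in records:
        if rec.habitat == "terrestrial":
            continue
        substitute = ""
        if rec.role == "offrange" and ghost is not None:
            substitute = ghost.species
        rows.append(
            {
                "species": rec.species,
                "genus": rec.genus,
                "local": int(rec.local),
                "substitute_for": substitute,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# communities
# --------------------------------------------------------------------------
@dataclass
class CommunitySimulation:
    """Per-sample expected species compositions with the generating model."""

    stations: pd.DataFrame  # station_id, x_m, y_m
    species: list[str]  # community species names, index-aligned with columns
    composition: dict[tuple[str, str], np.ndarray]  # (station_id, layer) -> rel. abundance
    truth_sets: dict[tuple[str, str], set[str]]
    centres: np.ndarray
    layer_bias: np.ndarray

    def expected_matrix(self, layer: str) -> pd.DataFrame:
        rows = {
            sid: self.composition[(sid, layer)] for sid in self.stations["station_id"]
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.species)


def station_grid(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic station layout: a regular grid clipped to n_stations."""
    ext_x, ext_y = config.bay_extent
    n = config.n_stations
    nx = max(1, int(math.ceil(math.sqrt(n * ext_x / ext_y))))
    ny = int(math.ceil(n / nx))
    xs, ys, ids = [], [], []
    k = 0
    for j in range(ny):
        for i in range(nx):
            if k >= n:
                break
            ids.append(f"St{k + 1:02d}")
            xs.append((i + 0.5) * ext_x / nx)
            ys.append((j + 0.5) * ext_y / ny)
            k += 1
    return pd.DataFrame({"station_id": ids, "x_m": xs, "y_m": ys})


def simulate_communities(
    config: SimulationConfig,
    records: Sequence[ReferenceRecord],
    rng: np.random.Generator | None = None,
    layer_bias_override: Mapping[str, float] | None = None,
) -> CommunitySimulation:
    """Build spatially autocorrelated per-sample species compositions.

    Each community species has a 2-D Gaussian occupancy kernel (width
    ``range_scale``), a surface/bottom bias, and a log-series base abundance.
    A station/layer's true pool is the set of species whose kernel weight
    exceeds ``occupancy_threshold`` and whose layer factor is positive;
    relative abundances are the renormalised products.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    stations = station_grid(config)
    pool = [r for r in records if r.in_community]
    names = [r.species for r in pool]
    s = len(pool)
    ext_x, ext_y = config.bay_extent

    centres = np.empty((s, 2))
    bias = np.empty(s)
    for i, rec in enumerate(pool):
        if rec.habitat == "freshwater":
            # river mouth corner of the bay, strongly surface biased
            centres[i] = (rng.uniform(0, 0.15 * ext_x), rng.uniform(0, 0.15 * ext_y))
            bias[i] = 0.95
        else:
            centres[i] = (rng.uniform(0, ext_x), rng.uniform(0, ext_y))
            bias[i] = rng.beta(4, 4) if rec.habitat == "marine" else rng.beta(6, 3)
        if layer_bias_override and rec.species in layer_bias_override:
            bias[i] = layer_bias_override[rec.species]

    ranks = rng.permutation(s) + 1
    base = config.logseries_x ** ranks / ranks

    xy = stations[["x_m", "y_m"]].to_numpy()
    composition: dict[tuple[str, str], np.ndarray] = {}
    truth: dict[tuple[str, str], set[str]] = {}
    for st_idx, sid in enumerate(stations["station_id"]):
        d2 = ((xy[st_idx] - centres) ** 2).sum(axis=1)
        if math.isinf(config.range_scale):
            w = np.ones(s)
        else:
            w = np.exp(-d2 / (2.0 * config.range_scale**2))
        for layer in LAYERS:
            lf = bias if layer == SURFACE else 1.0 - bias
            abund = base * w * lf
            abund[w < config.occupancy_threshold] = 0.0
            if abund.sum() <= 0:
                abund = np.zeros(s)
                abund[np.argmax(base * w)] = 1.0
            comp = abund / abund.sum()
            composition[(sid, layer)] = comp
            truth[(sid, layer)] = {names[i] for i in np.nonzero(comp)[0]}
    return CommunitySimulation(
        stations=stations,
        species=names,
        composition=composition,
        truth_sets=truth,
        centres=centres,
        layer_bias=bias,
    )


# --------------------------------------------------------------------------
# sample sheet and reads
# --------------------------------------------------------------------------
def build_sample_sheet(config: SimulationConfig, stations: pd.DataFrame) -> pd.DataFrame:
    """Sample sheet: one row per PCR sample, negatives included."""
    rows = []
    for _, st in stations.iterrows():
        for layer in LAYERS:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{st.station_id}-{layer[0].upper()}-R{rep}",
                        "station_id": st.station_id,
                        "layer": layer,
                        "replicate": rep,
                        "is_negative": 0,
                        "x_m": st.x_m,
                        "y_m": st.y_m,
                    }
                )
    for i in range(1, config.n_negative_controls + 1):
        rows.append(
            {
                "sample_id": f"NC{i:02d}",
                "station_id": "",
                "layer": "",
                "replicate": i,
                "is_negative": 1,
                "x_m": float("nan"),
                "y_m": float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SampleReads:
    """Raw paired reads of one PCR sample, with per-read provenance."""

    sample_id: str
    bases1: list[str]
    quals1: np.ndarray  # (n_reads, read_length) int16
    bases2: list[str]
    quals2: np.ndarray
    provenance: list[tuple]  # ("species", name) | ("chimera", a, b) | ("contaminant", name)

    @property
    def n_reads(self) -> int:
        return len(self.bases1)


@dataclass
class GroundTruth:
    """What was actually put into the sequencer, per sample."""

    truth_sets: dict[tuple[str, str], set[str]]
    clean_reads: pd.DataFrame  # sample_id x species -> non-chimeric community read count
    chimera_reads: dict[str, int]
    contaminant_reads: dict[str, int]
    total_reads: dict[str, int]

    def provenance_total(self) -> int:
        return int(
            self.clean_reads.to_numpy().sum()
            + sum(self.chimera_reads.values())
            + sum(self.contaminant_reads.values())
        )


def _draw_quals(rng: np.random.Generator, n_reads: int, length: int, cfg: SimulationConfig) -> np.ndarray:
    means = cfg.quality_mean_start - cfg.quality_drop_per_base * np.arange(length)
    q = rng.normal(means, cfg.quality_sd, size=(n_reads, length))
    return np.clip(np.rint(q), 2, 40).astype(np.int16)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        alternatives = BASES[BASES != arr[pos]]
        arr[pos] = alternatives[rng.integers(len(alternatives))]
    return arr.tobytes().decode()


def simulate_sample_reads(
    config: SimulationConfig,
    sample_id: str,
    composition: np.ndarray | None,
    species_names: Sequence[str],
    seq_by_name: Mapping[str, str],
    contaminant: ReferenceRecord,
    primer_pairs: Sequence[PrimerPair],
    rng: np.random.Generator,
    is_negative: bool,
) -> SampleReads:
    """Simulate one PCR sample's paired reads with provenance labels."""
    margin = config.chimera_end_margin
    if is_negative:
        n_cont = int(rng.binomial(config.reads_per_sample, config.contaminant_rate))
        n_comm = 0
    else:
        n_cont = int(rng.binomial(config.reads_per_sample, config.sample_contaminant_rate))
        n_comm = config.reads_per_sample - n_cont

    inserts: list[str] = []
    provenance: list[tuple] = []
    if n_comm:
        counts = rng.multinomial(n_comm, composition)
        species_idx = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(species_idx)
        n_chim = int(rng.binomial(n_comm, config.chimera_rate))
        support = np.nonzero(composition)[0]
        for k, si in enumerate(species_idx):
            name = species_names[si]
            if k < n_chim and len(support) >= 2:
                a = name
                b = species_names[int(rng.choice(support[support != si]))] if (support != si).any() else None
                if b is None:
                    inserts.append(seq_by_name[name])
                    provenance.append(("species", name))
                    continue
                sa, sb = seq_by_name[a], seq_by_name[b]
                hi = min(len(sa), len(sb)) - margin
                if hi <= margin:
                    inserts.append(sa)
                    provenance.append(("species", a))
                    continue
                bp = int(rng.integers(margin, hi + 1))
                inserts.append(sa[:bp] + sb[bp:])
                provenance.append(("chimera", a, b))
            else:
                inserts.append(seq_by_name[name])
                provenance.append(("species", name))
    for _ in range(n_cont):
        inserts.append(contaminant.sequence)
        provenance.append(("contaminant", contaminant.species))

    n = len(inserts)
    rl = config.read_length
    quals1 = _draw_quals(rng, n, rl, config)
    quals2 = _draw_quals(rng, n, rl, config)
    bases1: list[str] = []
    bases2: list[str] = []
    for i, insert in enumerate(inserts):
        pair = primer_pairs[0] if rng.random() < config.u_variant_fraction else primer_pairs[1]
        amplicon = pair.forward + insert + reverse_complement(pair.reverse)
        r1 = amplicon[:rl]
        r2 = reverse_complement(amplicon)[:rl]
        bases1.append(_apply_errors(rng, r1, config.substitution_error_rate))
        bases2.append(_apply_errors(rng, r2, config.substitution_error_rate))
    return SampleReads(sample_id, bases1, quals1, bases2, quals2, provenance)


def iter_sample_reads(
    config: SimulationConfig,
    communities: CommunitySimulation,
    records: Sequence[ReferenceRecord],
    sheet: pd.DataFrame,
    primer_pairs: Sequence[PrimerPair] = DEFAULT_PRIMER_PAIRS,
) -> Iterator[SampleReads]:
    """Yield reads sample by sample; deterministic under the config seed."""
    contaminant = next(r for r in records if r.role == "contaminant")
    seq_by_name = {r.species: r.sequence for r in records}
    children = np.random.SeedSequence([config.seed, 3]).spawn(len(sheet))
    for (_, row), child in zip(sheet.iterrows(), children):
        rng = np.random.default_rng(child)
        comp = None
        if not row.is_negative:
            comp = communities.composition[(row.station_id, row.layer)]
        yield simulate_sample_reads(
            config,
            row.sample_id,
            comp,
            communities.species,
            seq_by_name,
            contaminant,
            primer_pairs,
            rng,
            bool(row.is_negative),
        )


def collect_ground_truth(
    communities: CommunitySimulation, samples: Sequence[SampleReads]
) -> GroundTruth:
    clean: dict[str, dict[str, int]] = {}
    chim: dict[str, int] = {}
    cont: dict[str, int] = {}
    total: dict[str, int] = {}
    for sample in samples:
        counts: dict[str, int] = {}
        n_chim = n_cont = 0
        for label in sample.provenance:
            if label[0] == "species":
                counts[label[1]] = counts.get(label[1], 0) + 1
            elif label[0] == "chimera":
                n_chim += 1
            else:
                n_cont += 1
        clean[sample.sample_id] = counts
        chim[sample.sample_id] = n_chim
        cont[sample.sample_id] = n_cont
        total[sample.sample_id] = sample.n_reads
    frame = pd.DataFrame.from_dict(clean, orient="index").fillna(0).astype(int)
    return GroundTruth(communities.truth_sets, frame, chim, cont, total)


def write_sample_fastq(sample: SampleReads, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = (outdir / f"{sample.sample_id}_R1.fastq", outdir / f"{sample.sample_id}_R2.fastq")
    for mate, (bases, quals, path) in enumerate(
        [(sample.bases1, sample.quals1, paths[0]), (sample.bases2, sample.quals2, paths[1])], 1
    ):
        with open(path, "w") as fh:
            for i, seq in enumerate(bases):
                qual = "".join(chr(int(q) + 33) for q in quals[i])
                fh.write(f"@{sample.sample_id}.{i + 1}/{mate}\n{seq}\n+\n{qual}\n")
    return paths


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    primer_pairs: Sequence[PrimerPair] = DEFAULT_PRIMER_PAIRS,
):
    """Generate the whole study; optionally write FASTQ/FASTA/CSV artefacts.

    Returns ``(records, communities, sheet, samples, truth)``.
    """
    records = generate_reference_db(config)
    communities = simulate_communities(config, records)
    sheet = build_sample_sheet(config, communities.stations)
    samples = list(iter_sample_reads(config, communities, records, sheet, primer_pairs))
    truth = collect_ground_truth(communities, samples)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_reference_fasta(records, outdir / "reference.fasta")
        write_checklist(records, outdir / "checklist.tsv")
        sheet.to_csv(outdir / "sample_sheet.csv", index=False)
        for sample in samples:
            write_sample_fastq(sample, outdir / "fastq")
        summary = {
            "truth_sets": {
                f"{sid}/{layer}": sorted(spp) for (sid, layer), spp in truth.truth_sets.items()
            },
            "chimera_reads": truth.chimera_reads,
            "contaminant_reads": truth.contaminant_reads,
            "total_reads": truth.total_reads,
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    return records, communities, sheet, samples, truth


def expected_taxon(records: Sequence[ReferenceRecord]) -> dict[str, str]:
    """Map each community species to the taxon name the pipeline should report.

    The near-identical congeneric pair cannot be told apart at the marker and
    is expected at genus rank; the unbarcoded local species is expected under
    its own name via the checklist substitution of its off-range sibling.
    """
    mapping: dict[str, str] = {}
    congener_genus = next(r.genus for r in records if r.role == "congener_a")
    for rec in records:
        if not rec.in_community:
            continue
        if rec.role in ("congener_a", "congener_b"):
            mapping[rec.species] = f"{congener_genus} sp."
        else:
            mapping[rec.species] = rec.species
    return mapping
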