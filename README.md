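# ednameta

An environmental-DNA (eDNA) metabarcoding analysis pipeline for grid-sampled
aquatic surveys, built for ecologists who want to turn demultiplexed
paired-end 12S amplicon reads into a decontaminated species detection matrix
and community statistics — and for method developers who want every stage
testable against a synthetic survey with known ground truth.

Water samples shed fish DNA; amplifying a hyper-variable ~170 bp mitochondrial
12S fragment with fish-universal primers and sequencing it inventories the
fish community without catching a single fish.  The hard part is everything
after the sequencer: merging read pairs, separating signal from PCR chimeras
and cross-contamination, assigning taxa at species resolution, and summarising
spatial community structure.  `ednameta` implements that chain:

1. **Read QC** — 3′ quality trimming (Phred ≥ 20), overlap merging (>9 bp),
   ambiguity and length (272–322 bp) filters, de novo bimera removal, primer
   location/stripping for two primer-pair variants.
2. **Taxonomy** — run-wide dereplication with singleton discard, ≥99%
   ungapped-identity assignment against a reference barcode database,
   HIGH/MODERATE/LOW confidence grading, species-level OTUs, and two
   checklist-based curation rules (genus demotion of ambiguous calls;
   substitution of implausible non-local species).
3. **Decontamination** — removal of every sequence seen in a negative
   control, and a per-sample read-fraction cut-off projected from the blank
   read load: `C = floor(R_neg/N_neg × N_tot)`, `p = C / R_tot`.
4. **Community statistics** — replicate-based species accumulation,
   incidence Chao1 (`S_obs + f1(f1−1)/(2(f2+1))` over PCR replicates),
   surface/bottom partitions, Bray-Curtis `Σ|x−y|/Σ(x+y)`, a
   permutation-tested Mantel correlogram of community similarity against
   geographic distance, exact sample-based rarefaction, and detection
   rate/efficiency against visual-census records.
5. **Synthetic surveys** — a generator that emulates a 47-station × 2-layer
   × 3-replicate design with 30 blanks, spatially autocorrelated communities,
   sequencing errors, bimeras, and contamination, labelling every read with
   its provenance.

## Worked example

```python
from ednameta import PipelineConfig, SimulationConfig, run_pipeline, evaluate_recovery

config = PipelineConfig(
    sim=SimulationConfig(seed=1, n_species=15, n_stations=8,
                         reads_per_sample=200, n_negative_controls=4),
    n_perm=99,
)
result = run_pipeline(config)

print(result.report.cutoff)
ev = evaluate_recovery(result)
print(f"recovered {ev.recovery_percent}% of eligible species;"
      f" contaminant detections: {ev.contaminant_detections}")
print(result.stats["partition"])
```

prints

```
CutoffDerivation(reads_in_negatives=8, n_negatives=4, n_total_pcr_samples=52,
                 total_clustered_reads=7053, projected_contaminant_reads=104,
                 cutoff_fraction=0.015)
recovered 100.0% of eligible species; contaminant detections: 0
LayerPartition(surface_only=1, bottom_only=0, both=12,
               detections_surface=126, detections_bottom=135)
```

The 8 reads found across the 4 blanks project to 104 possible contaminant
reads over the 52 PCR samples, i.e. a 1.5% per-sample read-fraction cut-off;
after decontamination every ground-truth species with enough clean reads is
recovered, the planted blank contaminant is gone, and 12 of the 13 final
species appear in both the surface and bottom layers.

The same run is available from a shell:

```bash
ednameta run-all --seed 1 --n-species 15 --n-stations 8 \
    --reads-per-sample 200 --outdir run1
```

with `simulate`, `qc`, `assign`, `decontam`, and `stats` subcommands for
stage-by-stage work on files.

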