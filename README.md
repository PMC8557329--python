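# dysquant

High-throughput, operator-independent quantification of sarcolemmal
dystrophin from two-channel immunofluorescence images of transverse muscle
sections, plus a synthetic-section simulator with per-fiber ground truth.

The pipeline mirrors the mask-stain strategy used in digital muscle
histopathology: the laminin-α2 channel outlines every myofiber, fibers are
segmented as connected components of the inverted laminin network, and the
dystrophin channel is measured over each fiber's sarcolemmal ring. Per fiber
it reports:

- **mean intensity** (AU, raw 16-bit scale) over the sarcolemmal ring,
- **circumference coverage** (%): the fraction of 1° arc segments around the
  fiber centroid whose mean dystrophin signal is supra-threshold,
- **positivity** (coverage ≥ 25%),
- **coverage bin**: `B1 [0,25)`, `B2 [25,50)`, `B3 [50,75)`, `B4 [75,100]`.

Sections aggregate to mean intensity, % positive fibers, per-bin fractions /
mean intensities and ECDF curves; two replicate serial sections aggregate to
subject-level mean ± SD; cohorts are compared with an exact Mann–Whitney U
test on replicate-level values. A companion module normalizes Western-blot
band intensities to an α-actinin loading control as percent of control.

## CLI

```bash
# render a synthetic DMD-like section (2-channel 16-bit OME-TIFF + truth CSV)
dysquant simulate --preset DMD --n-fibers 500 --size 1400 --seed 7 \
    --out section.ome.tif --truth truth.csv

# quantify a section image -> fibers.csv, summary.csv, config.yaml, run.log
dysquant quantify section.ome.tif --out results/section1

# aggregate two replicate sections into a subject record
dysquant summarize --fibers results/s1/fibers.csv --fibers results/s2/fibers.csv \
    --subject-id P01 --phenotype mildBMD --out subject.csv

# batch: manifest CSV (subject_id, phenotype, image_path; 2 rows/subject)
dysquant cohort manifest.csv --out results/cohort

# pairwise exact Mann-Whitney comparisons on replicate-level values
dysquant compare --input results/cohort/replicates.csv \
    --metric mean_intensity_au --out comparisons.csv

# Western blot: band table -> percent of control
dysquant wb --input bands.csv --out wb.csv
```

Simulator presets: `CTRL`, `mildBMD`, `severeBMD-like-mild`,
`severeBMD-like-DMD`, `IMD`, `DMD` — each a mixture over the four coverage
bins plus a lognormal sarcolemmal intensity law.

## Layout

```
src/dysquant/
  simulate.py    Voronoi-based section geometry, phenotype sampling, renderer
  segment.py     laminin-mask fiber segmentation + sarcolemmal ring extraction
  fiberquant.py  per-fiber intensity / coverage / positivity / bin
  summarize.py   section + subject (2-replicate) aggregation, ECDFs
  stats.py       exact Mann-Whitney U, group summaries, Pearson r
  wb.py          Western-blot percent-of-control normalization
  pipeline.py    orchestration (quantify one image, batch a cohort manifest)
  config.py      YAML-serializable pipeline configuration
  datasets.py    bundled reference cohort table
  cli.py         click-based command line
  plots.py       optional ECDF / bin-profile figures
```

Every quantification run writes its resolved config, a log (thresholds,
exclusion counts) and the input checksum next to its outputs, and all
randomness flows from explicit seeds, so runs are bit-reproducible.
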