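# hcscreen

Analysis toolkit for multiplex image-based high-content RNAi screens of
puncta-forming markers, with the supporting quantitative assays that such a
screen typically leans on. The package covers the full path from (synthetic)
well images to validated genes:

- **`hcscreen.synthgen`** — synthetic inputs for every stage: 384-well plate
  layouts with embedded controls, an overdispersed generative model for
  per-well spot statistics (negative-binomial counts, gamma spot
  intensities), rendered two-channel well images with exact ground truth,
  qPCR Ct tables, AP-MS spectral-count runs and expression-ratio tables.
  Everything is bit-reproducible for a fixed master seed.
- **`hcscreen.imaging`** — nucleus/cytoplasm segmentation (multi-Otsu +
  distance-transform watershed), cytosolic spot detection by
  intensity/area/contrast with local-annulus background correction,
  per-well summaries, spot colocalization and tandem red/green reporter
  classification.
- **`hcscreen.platestats`** — normalization of quadruplicate wells to each
  plate's non-targeting control (sicon), z'-factor, z-score and B-score
  (Tukey median polish) normalizations, replicate R².
- **`hcscreen.hitcalling`** — the selection cascade: SD-criterion hit
  calling on both spot parameters (per-marker multipliers, 3 SD for the two
  early markers, 2 SD for the rest), top-10 + multi-marker candidate
  ranking, robust-z cytotoxicity filtering, 3-of-4 / 2-of-3 siRNA
  deconvolution validation, treatment-response categories and
  ANOVA/Bonferroni significance.
- **`hcscreen.qpcr`** — relative expression against the geometric mean of
  three reference genes, knockdown QC at the strict 0.65 cutoff, ChIP
  percent-input with MOCK/IgG control normalization.
- **`hcscreen.comppass`** — frequency-penalized spectral-count scoring
  (D / weighted / percentile-normalized scores) against a multi-bait
  background; HCIP calling at WDN ≥ 1 and APSM ≥ 2; TSV network export.
- **`hcscreen.expression`** — replicate ratio averaging with CV-based QC and
  the strict >1.3 / <0.7 fold gates for up/down gene sets, plus curated
  panel tables.
- **`hcscreen.pipeline` / `hcscreen.cli`** — end-to-end orchestration from a
  YAML config, CSV/JSON/TIFF I/O, and fixture generation.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (z'-factor window,
deconvolution truth table, end-to-end planted-hit recovery, spot detection
tolerances, qPCR parameter recovery, interaction-score brute-force
equality).

## CLI

```sh
hcscreen run-all --seed 42 --outdir out/           # full synthetic screen
hcscreen simulate --n-genes 20 --outdir sim/       # layout + well table
hcscreen quantify well_*.tiff --out wells.csv      # images -> summaries
hcscreen normalize --wells wells.csv --out norm.csv
hcscreen call-hits --normalized norm.csv --out verdicts.csv
hcscreen deconvolute --verdicts verdicts.csv --out validated.csv
hcscreen qpcr --ct-table ct.csv --target GENEA --condition siGENEA
hcscreen chip --ct-ip 22 --ct-input 25 --input-fraction 0.01
hcscreen comppass --runs counts.csv --out scores.csv --network-out net.tsv
hcscreen expression ratios_exp*.csv --out de.csv
hcscreen make-fixtures small-screen --seed 1 --outdir fixtures/
```

A config file (YAML) can set seeds, gene counts, planted effects, toxic
siRNAs, knockdown efficiencies, baseline model parameters and per-marker SD
multipliers; every run writes the resolved config next to its outputs.

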