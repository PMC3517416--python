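# crosspep

Cross-species urinary peptidomics analysis: CE-MS feature matching,
differential peptide-marker screening, three-tier rat/human peptide
orthology classification, and cleavage-site-based protease-activity
inference — plus a synthetic two-species study generator that stands in
for the original CE-MS data.

## Modules

| module | what it does |
| --- | --- |
| `crosspep.simulate` | synthetic case/control peptide studies: collagen-like references with planted cleavage motifs, fragments cut at motif midpoints, log-normal amplitudes with logistic detection, ground-truth sidecars |
| `crosspep.featmatch` | piecewise-linear mass (±50→±150 ppm) and migration-time (±1→±2.5 min) tolerance windows, internal-standard normalization, greedy consensus clustering |
| `crosspep.markers` | ≥70 % detection-frequency filter, exact/asymptotic Wilcoxon rank-sum test, Benjamini–Hochberg adjustment, significance and regulation calls |
| `crosspep.seqqc` | modification-coded sequences (p/k/m = +15.9949 Da), monoisotopic mass with ±80 ppm check, CE migration-time prediction with ±2 min check, peptide→precursor mapping with flanks |
| `crosspep.orthology` | 6-residue cleavage contexts; tier 1 = identical fragment, tier 2 = one identical cleavage site, tier 3 = ≥2-residue region overlap; regulation-gated, disjoint counting |
| `crosspep.proteases` | bundled cleavage-motif database (14 motifs; MMPs, ADAMTS4/5, CTSK, F2), strict and ≤2-mismatch relaxed matching, up/down activity tallies per protease group |
| `crosspep.report` | end-to-end pipeline with JSON manifest, early/late panel overlap (Venn counts), published-count recomputation hook |

All interchange formats are plain text: TSV peak lists and marker panels,
FASTA references, key:value simulation configs, YAML run configs.

## CLI

```sh
crosspep simulate --seed 7 --out study/            # synthetic study
crosspep cluster --peaks study/rat_peaks.tsv \
    --groups study/rat_groups.tsv \
    --standards 1046.54,2191.07,3016.49 --out consensus.tsv
crosspep markers --consensus consensus.tsv \
    --groups study/rat_groups.tsv --out markers.tsv
crosspep qc --panel study/rat_panel.tsv \
    --fasta study/rat_proteins.fasta --out qc.tsv
crosspep orthology --rat-panel study/rat_panel.tsv \
    --human-panel study/human_panel.tsv \
    --rat-fasta study/rat_proteins.fasta \
    --human-fasta study/human_proteins.fasta \
    --ortholog-map study/ortholog_map.tsv --out matches.tsv
crosspep proteases --panel study/rat_panel.tsv \
    --fasta study/rat_proteins.fasta --protein COLSIM00 --out tallies.tsv
crosspep run --config run.yaml                     # full pipeline
crosspep report --early study/rat_panel.tsv --late study/rat_panel.tsv
```

`crosspep run` takes a YAML config naming the peak lists, group map,
panels, FASTA references, ortholog map and parameters (`alpha`,
`frequency_threshold`, `top_n`, `standard_masses`, `protein_filter`,
`output_dir`), writes every stage output as TSV and a `manifest.json`
run manifest, and is byte-deterministic for a fixed config.

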