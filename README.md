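# surfquant

Quantitative analysis of cell-surface protein delivery from per-cell
fluorescence measurements, plus differential-conservation scoring of
sequence alignments. Built for experiments where live cells expressing an
epitope-tagged membrane protein (e.g. clustered protocadherin isoforms) are
co-labeled with a transfection marker (FP channel) and a surface-stain
antibody (Ab channel), imaged or run through a flow cytometer, and compared
across constructs.

From background-subtracted per-cell intensities FP<sub>cell</sub> and
Ab<sub>cell</sub>, the package computes three surface-delivery metrics per
sample and replicate:

- **f⁺** — fraction of transfected cells with Ab<sub>cell</sub> strictly
  above a surface-stain threshold (the 0.995 quantile of untagged-construct
  control cells). Transfected cells are those with FP<sub>cell</sub>
  strictly above the 0.995 quantile of mock-transfected controls, so the
  chance a designated transfected cell is actually untransfected is < 0.005.
- **Ab̄** — mean Ab<sub>cell</sub> over all transfected cells, optionally
  normalized to a positive-control sample.
- **E<sub>surface</sub>** — the slope of the least-squares line through
  (log FP<sub>bin</sub>, log Ab<sub>bin</sub>) after binning transfected
  cells by expression level: a dimensionless delivery efficiency that
  estimates the exponent *k* of an approximately power-law dose-response
  Ab ≈ a·FP<sup>k</sup> and is independent of expression level and channel
  scaling.

Also included: an exact logicle (biexponential) display transform for
intensity histograms, Welch / Dunnett / Tukey / Pearson comparisons of
replicate-level metrics, a per-column Kullback-Leibler
differential-conservation score for two-group alignments (high where each
group is conserved at a different residue), and a fully seeded synthetic
generator (cell tables, controls, image fields, toy alignments) with planted
ground truth. See `docs/methods.md` for the model, parameter defaults and
numerical caveats.

## Worked example

Generate a synthetic study (a well-trafficking sample, a non-trafficking
sample and both control types, 3 replicates each), compute metrics, and
compare groups:

```sh
surfquant simulate --out demo --seed 7 --n-cells 4000 --n-replicates 3
printf 'positive_control: surface_high\n' > cfg.yaml
surfquant metrics --cells demo/cells.csv --config cfg.yaml --out-dir demo_out
```

The metrics step logs the control-derived thresholds:

```
thresholds: t_fp=13.376 (12000 mock cells), t_ab=13.0752 (12000 untagged cells);
0 saturated cells excluded; 20 bins (log_spaced) -> demo_out
```

and `demo_out/metrics.csv` holds one row per sample-replicate:

```
   sample_id replicate_id  f_plus  ab_mean_norm  e_surface  n_transfected
surface_high           r1   0.707         0.973      1.060           1644
surface_high           r2   0.698         1.027      0.803           1538
surface_high           r3   0.688         0.999      0.803           1552
surface_null           r1   0.002         0.001     -0.008           1601
surface_null           r2   0.001         0.002     -0.235           1599
surface_null           r3   0.004        -0.002      0.732           1575
    untagged           r1   0.004         0.000      0.129           1587
...
```

The trafficking-like sample recovers its planted phenotype: f⁺ ≈ 0.70 (the
generator stains 70 % of transfected cells) and E<sub>surface</sub> ≈ 0.8
(the planted dose-response exponent), while the unstained sample sits at
f⁺ ≈ 0 with a noisy near-zero slope — at 4,000 cells per sample the
per-replicate E<sub>surface</sub> of a null sample is dominated by
background noise (see `docs/methods.md`). Replicate-level comparison:

```sh
surfquant compare --metrics demo_out/metrics.csv --metric e_surface \
    --test welch --control surface_null --tails one --out demo_out/tests.csv
```

```
     group_a      group_b method tails  statistic  p_value
surface_high surface_null  welch   one   2.383047 0.060759
    untagged surface_null  welch   one   0.331533 0.379249
```

The other subcommands: `surfquant quantify` turns TIFF image pairs plus
integer label masks into per-cell tables (median non-cell-pixel background
subtraction, saturation exclusion), and `surfquant conservation` scores an
aligned FASTA with a two-group membership CSV:

```sh
surfquant conservation --alignment demo/alignment.fasta \
    --groups demo/groups.csv --out demo_out/kldiv.csv
```

Everything is also available as a library (`import surfquant`): the CLI is
a thin layer over `surfquant.cell_quant`, `surfquant.metrics`,
`surfquant.stats`, `surfquant.conservation` and `surfquant.synthetic`.

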